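"""Spectrum scoring: parsing, preprocessing, XCorr, ranking, SQT I/O."""

import math

import numpy as np
import pytest

from compilite.chemistry import PROTON_MASS, compute_monoisotopic_mass
from compilite.engine import (
    BIN_WIDTH,
    XCORR_SCALE,
    PSM,
    SearchParams,
    Spectrum,
    TheoreticalSpectrum,
    bin_and_normalize,
    parse_spectra,
    preprocess,
    read_sqt,
    score_scan,
    subtract_background,
    theoretical_ions,
    write_ms2,
    write_sqt,
    xcorr,
    xcorr_raw,
)
from compilite.simulate import SimulationParams, build_from_records, generate_proteins, simulate_run
from compilite.store import ProteinRecord, query_mass_window


def make_spectrum(peaks, mz=800.0, charge=2, scan_id=1):
    arr = np.array(sorted(peaks), dtype=float)
    return Spectrum(scan_id=scan_id, precursor_mz=mz, precursor_charge=charge, peaks=arr)


class TestParseSpectra:
    def test_ms2_z_line(self, tmp_path):
        f = tmp_path / "a.ms2"
        f.write_text(
            "H\tExtractor\ttest\n"
            "S\t000001\t000001\t801.37\n"
            "Z\t2\t1601.73\n"
            "200.1 100.0\n300.2 50.0\n"
        )
        (s,) = parse_spectra(f)
        assert s.precursor_charge == 2
        assert s.precursor_mz == pytest.approx(801.37)
        assert s.peaks.shape == (2, 2)

    def test_mgf_pepmass_charge(self, tmp_path):
        f = tmp_path / "a.mgf"
        f.write_text(
            "BEGIN IONS\nTITLE=scan1\nPEPMASS=400.6873\nCHARGE=2+\n"
            "200.1 100.0\n300.2 50.0\nEND IONS\n"
        )
        (s,) = parse_spectra(f)
        assert s.precursor_mz == pytest.approx(400.6873)
        assert s.precursor_charge == 2

    def test_empty_scan_skipped(self, tmp_path):
        f = tmp_path / "a.ms2"
        f.write_text(
            "S\t1\t1\t801.37\nZ\t2\t1601.73\n"
            "S\t2\t2\t900.00\nZ\t2\t1798.99\n500.0 10.0\n"
        )
        scans = list(parse_spectra(f))
        assert [s.scan_id for s in scans] == [2]

    def test_missing_charge_yields_none(self, tmp_path):
        f = tmp_path / "a.ms2"
        f.write_text("S\t1\t1\t801.37\n500.0 10.0\n")
        (s,) = parse_spectra(f)
        assert s.precursor_charge is None

    def test_ms2_write_read_round_trip(self, tmp_path, small_search_setup):
        _, _, spectra, _ = small_search_setup
        f = tmp_path / "run.ms2"
        write_ms2(spectra[:10], f)
        back = list(parse_spectra(f))
        assert len(back) == 10
        for a, b in zip(spectra[:10], back):
            assert b.scan_id == a.scan_id
            assert b.precursor_charge == a.precursor_charge
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            assert b.peaks[:, 0] == pytest.approx(a.peaks[:, 0], abs=1e-4)


class TestPreprocess:
    def test_single_peak_region_scaled_to_50(self):
        s = make_spectrum([(500.0, 36.0)])
        v, _ = bin_and_normalize(s, 2)
        assert v.max() == pytest.approx(50.0)

    def test_equal_peaks_all_scaled_to_50(self):
        s = make_spectrum([(500.0, 25.0), (510.0, 25.0), (520.0, 25.0)])
        v, _ = bin_and_normalize(s, 2)
        assert sorted(v[v > 0]) == pytest.approx([50.0, 50.0, 50.0])

    def test_sqrt_transform_preserves_ratios(self):
        # adjacent peaks so both land in the same normalization region
        s = make_spectrum([(400.0, 25.0), (403.0, 100.0)])
        v, _ = bin_and_normalize(s, 2)
        nz = np.sort(v[v > 0])
        assert nz[0] / nz[1] == pytest.approx(0.5)  # sqrt(25)/sqrt(100)

    def test_precursor_peak_removed(self):
        s = make_spectrum([(800.0, 99.0), (500.0, 10.0)], mz=800.0)
        v, _ = bin_and_normalize(s, 2)
        assert np.count_nonzero(v) == 1

    def test_neutral_mass_attached(self):
        s = make_spectrum([(500.0, 1.0)], mz=801.0, charge=2)
        p = preprocess(s, 2)
        assert p.neutral_precursor_mass == pytest.approx((801.0 - PROTON_MASS) * 2)

    def test_background_subtraction_matches_naive(self, rng):
        """Closed-form v' equals per-offset mean subtraction."""
        for _ in range(20):
            v = np.zeros(400)
            idx = rng.integers(0, 400, size=20)
            v[idx] = rng.uniform(0, 50, size=20)
            fast = subtract_background(v)
            naive = np.empty_like(v)
            for i in range(len(v)):
                acc = 0.0
                for off in range(-75, 76):
                    if off == 0:
                        continue
                    j = i + off
                    if 0 <= j < len(v):
                        acc += v[j]
                naive[i] = v[i] - acc / 150.0
            assert fast == pytest.approx(naive, abs=1e-9)


class TestTheoreticalIons:
    def test_gg_fragment_mzs(self):
        theo = theoretical_ions("GG", 2, {})
        primary = set(theo.indices[theo.weights == 1.0])
        b1 = round(58.0287 / BIN_WIDTH)
        y1 = round(76.0393 / BIN_WIDTH)
        assert {b1, y1} <= primary

    @pytest.mark.parametrize("pep", ["GG", "PEPTIDE", "AAAKGGGR"])
    def test_primary_ion_count_charge1(self, pep):
        theo = theoretical_ions(pep, 2, {})
        n_primary = int((theo.weights == 1.0).sum())
        # 2(n-1) ions; bin collisions can only reduce the count
        assert n_primary <= 2 * (len(pep) - 1)
        assert n_primary >= 2 * (len(pep) - 1) - 2

    def test_charge2_fragments_only_for_charge3_precursor(self):
        pep = "PEPTIDEKR"
        n2 = theoretical_ions(pep, 2, {}).indices.size
        n3 = theoretical_ions(pep, 3, {}).indices.size
        assert n3 > n2

    def test_flank_weights(self):
        theo = theoretical_ions("GG", 2, {})
        assert set(np.unique(theo.weights)) == {0.25, 1.0}
        for i, w in zip(theo.indices, theo.weights):
            if w == 1.0:
                assert 0.25 in theo.weights[np.isin(theo.indices, [i - 1, i + 1])]

    def test_too_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            theoretical_ions("G", 2, {})


class TestXCorr:
    def test_empty_theoretical_scores_zero(self):
        s = make_spectrum([(500.0, 10.0)])
        p = preprocess(s, 2)
        theo = TheoreticalSpectrum("XX", np.array([], dtype=int), np.array([]))
        assert xcorr(p, theo) == 0.0

    def test_floor_at_zero(self):
        # all theoretical ions land on empty bins near a strong peak:
        # raw correlation is negative, reported score clamps to 0
        s = make_spectrum([(500.0, 100.0)])
        p = preprocess(s, 2)
        idx = np.array([round(505.0 / BIN_WIDTH)])
        theo = TheoreticalSpectrum("YY", idx, np.array([1.0]))
        assert xcorr_raw(p, theo) < 0
        assert xcorr(p, theo) == 0.0

    def test_matches_naive_cross_correlation(self, rng):
        """Fast dot-product form equals the naive R(0) - mean(R(tau))
        over tau in [-75, 75] on random spectra."""
        for _ in range(30):
            peaks = [(float(m), float(i)) for m, i in zip(
                rng.uniform(150, 1400, size=20), rng.uniform(1, 100, size=20)
            )]
            s = make_spectrum(peaks, mz=750.0, charge=2)
            v, _ = bin_and_normalize(s, 2)
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
            theo = theoretical_ions(pep, 2, {})
            n = len(v)

            def r(tau):
                sel = (theo.indices + tau >= 0) & (theo.indices + tau < n)
                return float(v[theo.indices[sel] + tau] @ theo.weights[sel])

            taus = [t for t in range(-75, 76) if t != 0]
            naive = (r(0) - np.mean([r(t) for t in taus])) * XCORR_SCALE
            assert xcorr_raw(preprocess(s, 2), theo) == pytest.approx(naive, abs=1e-6)

    def test_self_match_dominates_random_decoys(self, rng, small_search_setup):
        _, _, spectra, truth = small_search_setup
        s = spectra[0]
        pep, _, z = truth.scans[s.scan_id]
        p = preprocess(s, z)
        mods = {"C": 57.02146}
        self_score = xcorr(p, theoretical_ions(pep, z, mods))
        # random same-length shuffles as equal-mass decoys
        letters = list(pep)
        for _ in range(100):
            rng.shuffle(letters)
            decoy = "".join(letters)
            if decoy == pep:
                continue
            assert xcorr(p, theoretical_ions(decoy, z, mods)) < self_score


class TestScoreScan:
    def test_generating_peptide_ranks_first(self, small_search_setup):
        _, backend, spectra, truth = small_search_setup
        params = SearchParams()
        hits = misses = 0
        for s in spectra[:50]:
            psms = score_scan(s, backend, params)
            if not psms:
                continue
            if psms[0].peptide == truth.scans[s.scan_id][0]:
                hits += 1
            else:
                misses += 1
        assert hits > 0 and misses == 0

    def test_delta_cn_and_zscore_consistent_with_candidates(self, small_search_setup):
        """Recompute DeltaCN and Z-score from the full candidate set as
        an independent check of the streaming statistics."""
        _, backend, spectra, truth = small_search_setup
        params = SearchParams()
        checked = 0
        for s in spectra:
            psms = score_scan(s, backend, params)
            if len(psms) < 2 or psms[0].candidate_count < 3:
                continue
            z = s.precursor_charge
            p = preprocess(s, z)
            mods = backend.static_modifications
            raws = [
                xcorr_raw(p, theoretical_ions(pep, z, mods))
                for pep, _ in query_mass_window(
                    s.neutral_mass(z), params.precursor_tolerance_ppm, backend
                )
            ]
            scores = sorted((max(0.0, r) for r in raws), reverse=True)
            expected_delta = (scores[0] - scores[1]) / scores[0] if scores[0] else 0.0
            assert psms[0].delta_cn == pytest.approx(expected_delta, abs=1e-9)
            mean = np.mean(raws)
            std = np.std(raws)  # population
            if std > 0:
                assert psms[0].z_score == pytest.approx(
                    (max(raws) - mean) / std, abs=1e-6
                )
            checked += 1
        assert checked >= 5

    def test_delta_cn_bounds_and_tie(self, small_search_setup):
        _, backend, spectra, _ = small_search_setup
        for s in spectra[:30]:
            psms = score_scan(s, backend, SearchParams())
            for p in psms:
                assert 0.0 <= p.delta_cn <= 1.0

    def test_no_candidates_empty_list(self, small_search_setup):
        _, backend, _, _ = small_search_setup
        s = make_spectrum([(500.0, 10.0)], mz=10_000.0, charge=2)
        assert score_scan(s, backend, SearchParams()) == []

    def test_unknown_charge_tries_candidate_charges(self, small_search_setup):
        _, backend, spectra, truth = small_search_setup
        # strip the charge from a charge-2 scan; the 2+ interpretation
        # should still win and recover the generating peptide
        found = 0
        for s in spectra:
            if s.precursor_charge != 2:
                continue
            anon = Spectrum(s.scan_id, s.precursor_mz, None, s.peaks)
            psms = score_scan(anon, backend, SearchParams())
            if psms and psms[0].peptide == truth.scans[s.scan_id][0]:
                assert psms[0].charge == 2
                found += 1
            if found >= 5:
                break
        assert found >= 5

    def test_distractors_never_raise_delta_cn_or_change_xcorr(self, small_search_setup):
        records, backend, spectra, truth = small_search_setup
        extra = generate_proteins(
            SimulationParams(seed=77, n_proteins=150), id_offset=10_000, defline_prefix="extra"
        )
        big_backend = build_from_records(list(records) + extra)
        params = SearchParams()
        compared = 0
        for s in spectra[:40]:
            small_psms = score_scan(s, backend, params)
            big_psms = score_scan(s, big_backend, params)
            if not small_psms or not big_psms:
                continue
            if small_psms[0].peptide != big_psms[0].peptide:
                continue
            assert big_psms[0].xcorr == pytest.approx(small_psms[0].xcorr, abs=1e-12)
            assert big_psms[0].delta_cn <= small_psms[0].delta_cn + 1e-12
            compared += 1
        assert compared >= 20

    def test_streaming_buffer_is_bounded(self, small_search_setup):
        """Peak candidate-buffer size stays O(report_hits) no matter how
        many candidates stream through."""
        _, backend, spectra, _ = small_search_setup
        params = SearchParams(precursor_tolerance_ppm=5000.0, report_hits=3)
        for s in spectra[:10]:
            counter = [0]
            psms = score_scan(s, backend, params, _candidate_counter=counter)
            if psms and psms[0].candidate_count > 10:
                assert counter[0] <= 2 * params.report_hits + 1
                assert len(psms) <= params.report_hits

    def test_ppm_error_field(self, small_search_setup):
        _, backend, spectra, truth = small_search_setup
        s = spectra[0]
        psms = score_scan(s, backend, SearchParams())
        top = psms[0]
        expected = (
            (top.observed_neutral_mass - top.calculated_neutral_mass)
            / top.calculated_neutral_mass * 1e6
        )
        assert top.ppm_error == pytest.approx(expected)
        assert abs(top.ppm_error) < 1.0  # jitter-free run


class TestSqt:
    def test_empty_stream_header_only(self, tmp_path):
        f = tmp_path / "r.sqt"
        write_sqt([], f)
        lines = f.read_text().splitlines()
        assert all(l.startswith("H") for l in lines)

    def test_structural_counts(self, tmp_path):
        psm = PSM(
            scan_id=1, peptide="PEPTIDEK", xcorr=3.2, delta_cn=0.3, z_score=2.5,
            ppm_error=1.2, rank=1, charge=2, observed_neutral_mass=900.0,
            calculated_neutral_mass=900.001, parent_deflines=("A", "B"),
        )
        f = tmp_path / "r.sqt"
        write_sqt([[psm]], f)
        kinds = [l.split("\t")[0] for l in f.read_text().splitlines()]
        assert kinds.count("S") == 1
        assert kinds.count("M") == 1
        assert kinds.count("L") == 2

    def test_round_trip_scores(self, tmp_path, small_search_setup):
        _, backend, spectra, _ = small_search_setup
        groups = [score_scan(s, backend, SearchParams()) for s in spectra[:20]]
        groups = [g for g in groups if g]
        f = tmp_path / "r.sqt"
        write_sqt(groups, f)
        back = list(read_sqt(f))
        assert len(back) == len(groups)
        for orig, parsed in zip(groups, back):
            for a, b in zip(orig, parsed):
                assert a.peptide == b.peptide
                assert a.rank == b.rank
                assert b.xcorr == pytest.approx(a.xcorr, abs=1e-4)
                assert b.delta_cn == pytest.approx(a.delta_cn, abs=1e-4)
                assert b.z_score == pytest.approx(a.z_score, abs=1e-4)
                assert b.parent_deflines == a.parent_deflines

    def test_byte_deterministic(self, tmp_path, small_search_setup):
        _, backend, spectra, _ = small_search_setup
        groups = [score_scan(s, backend, SearchParams()) for s in spectra[:10]]
        f1, f2 = tmp_path / "a.sqt", tmp_path / "b.sqt"
        write_sqt(groups, f1)
        write_sqt(groups, f2)
        assert f1.read_bytes() == f2.read_bytes()
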