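"""Synthetic proteomes and simulated MudPIT-style MS/MS runs.

Everything here exists so the build -> search -> filter loop can be
exercised closed-loop with known ground truth. A proteome is sampled
as random residue strings; tryptic peptides inside the indexing
windows are sampled from it; each sampled peptide becomes a centroided
spectrum holding its full b/y fragment series (charge rules matching
the search engine), degraded by peak dropout, uniform noise peaks and
Gaussian ppm jitter on the precursor mass.

Fragment intensities are constant before degradation: the engine's
sqrt transform and regional normalization make scoring insensitive to
absolute intensity structure, and modelling HCD/CID intensity
propensities is out of scope. What these simulations consequently do
not probe is robustness to realistic intensity variation, chimeric
spectra, or non-tryptic background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .chemistry import (
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    compute_monoisotopic_mass,
    mz_from_neutral,
)
from .engine import PSM, SearchParams, Spectrum, search_file, write_ms2
from .filtering import FilterParams, apply_psm_gates, filter_results
from .store import (
    DigestionParams,
    ProteinRecord,
    SQLiteBackend,
    append_decoys,
    build_index,
    lookup_parents,
    read_fasta,
    tryptic_digest,
    write_fasta,
)

CANONICAL_RESIDUES = "".join(sorted(RESIDUE_MASSES))  # 20 letters

NOISE_MZ_RANGE = (200.0, 2000.0)
NOISE_INTENSITY_RANGE = (10.0, 100.0)
FRAGMENT_INTENSITY = 100.0


@dataclass
class SimulationParams:
    """Knobs of the synthetic run; defaults emulate a clean MudPIT
    acquisition: mostly 2+/3+ precursors, ~10 noise peaks per scan,
    10 % fragment dropout and 5 ppm precursor jitter."""

    seed: int = 0
    n_proteins: int = 100
    protein_length_mean: float = 300.0
    protein_length_sd: float = 100.0
    residue_frequencies: dict[str, float] | None = None  # None -> uniform
    n_spectra: int = 500
    noise_peaks: int = 10
    peak_dropout: float = 0.10
    charge_probabilities: dict[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.4}
    )
    mass_jitter_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.protein_length_mean <= 0:
            raise ValueError("protein_length_mean must be positive")
        if not (0.0 <= self.peak_dropout < 1.0):
            raise ValueError("peak_dropout must be in [0, 1)")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")
        total = sum(self.charge_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("charge probabilities must sum to 1")
        if self.residue_frequencies is not None:
            if set(self.residue_frequencies) != set(CANONICAL_RESIDUES):
                raise ValueError("residue_frequencies must cover all 20 residues")
            if abs(sum(self.residue_frequencies.values()) - 1.0) > 1e-9:
                raise ValueError("residue frequencies must sum to 1")


@dataclass
class GroundTruth:
    """scan_id -> (generating peptide, parent protein id, true charge)."""

    scans: dict[int, tuple[str, int, int]]

    def to_json(self) -> str:
        return json.dumps(
            {str(k): list(v) for k, v in sorted(self.scans.items())}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls({int(k): (v[0], int(v[1]), int(v[2])) for k, v in data.items()})


@dataclass
class AgreementReport:
    """Desk-scale analog of a small-vs-large database comparison."""

    co_filtered_scans: int = 0
    agreeing_scans: int = 0
    agreement_fraction: float = 1.0
    filtered_psms_small: int = 0
    filtered_psms_big: int = 0
    sensitivity_ratio: float = 1.0
    median_delta_cn_small: float = 0.0
    median_delta_cn_big: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# Proteome generation


def generate_proteins(
    params: SimulationParams, id_offset: int = 0, defline_prefix: str = "syn"
) -> list[ProteinRecord]:
    """Random target proteins; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    if params.residue_frequencies is None:
        probs = None
        alphabet = np.array(list(CANONICAL_RESIDUES))
    else:
        alphabet = np.array(list(CANONICAL_RESIDUES))
        probs = np.array([params.residue_frequencies[a] for a in alphabet])
    records = []
    for i in range(params.n_proteins):
        length = max(
            int(round(rng.normal(params.protein_length_mean, params.protein_length_sd))),
            20,
        )
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        records.append(
            ProteinRecord(
                protein_id=id_offset + i,
                defline=f"{defline_prefix}|{id_offset + i:06d}",
                sequence=seq,
            )
        )
    return records


def generate_proteome(
    params: SimulationParams, out_fasta: str | Path, manifest_path: str | Path | None = None
) -> list[ProteinRecord]:
    """Write a synthetic target proteome as FASTA plus a JSON manifest."""
    records = generate_proteins(params)
    write_fasta(records, out_fasta)
    if manifest_path is not None:
        manifest = {
            "seed": params.seed,
            "n_proteins": params.n_proteins,
            "proteins": [
                {"protein_id": r.protein_id, "defline": r.defline, "length": len(r.sequence)}
                for r in records
            ],
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return records


# ---------------------------------------------------------------------------
# Run simulation


def _sample_peptides(
    records: Sequence[ProteinRecord],
    digestion: DigestionParams,
    rng: np.random.Generator,
    n: int,
) -> list[tuple[str, int]]:
    """Sample n (peptide, parent protein id) pairs uniformly over all
    indexable tryptic peptides (with replacement)."""
    pool: list[tuple[str, int]] = []
    for rec in records:
        for pep, occ in tryptic_digest(rec, digestion):
            pool.append((pep, rec.protein_id))
    if not pool:
        raise ValueError("no digestible peptides under the given parameters")
    idx = rng.integers(0, len(pool), size=n)
    return [pool[i] for i in idx]


def simulate_run(
    proteome: Sequence[ProteinRecord] | str | Path,
    params: SimulationParams,
    digestion: DigestionParams | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """Simulate a centroided MS/MS run from a proteome.

    Each scan holds the full primary b/y ion series of one sampled
    tryptic peptide at constant intensity, thinned by ``peak_dropout``,
    plus ``noise_peaks`` uniform peaks; the precursor m/z carries
    Gaussian ppm jitter. Deterministic for a fixed seed.
    """
    if isinstance(proteome, (str, Path)):
        proteome = list(read_fasta(proteome))
    if not proteome:
        raise ValueError("proteome is empty")
    digestion = digestion or DigestionParams()
    rng = np.random.default_rng(params.seed + 1)
    sampled = _sample_peptides(proteome, digestion, rng, params.n_spectra)
    charges = sorted(params.charge_probabilities)
    charge_p = np.array([params.charge_probabilities[z] for z in charges])
    spectra: list[Spectrum] = []
    truth: dict[int, tuple[str, int, int]] = {}
    for scan_id, (pep, parent_id) in enumerate(sampled, start=1):
        z = int(rng.choice(charges, p=charge_p))
        mzs = _primary_ion_mzs(pep, z, digestion)
        if params.peak_dropout > 0:
            keep = rng.random(len(mzs)) >= params.peak_dropout
            if not keep.any():
                keep[rng.integers(0, len(mzs))] = True
            mzs = mzs[keep]
        intensities = np.full(len(mzs), FRAGMENT_INTENSITY)
        if params.noise_peaks:
            noise_mz = rng.uniform(*NOISE_MZ_RANGE, size=params.noise_peaks)
            noise_int = rng.uniform(*NOISE_INTENSITY_RANGE, size=params.noise_peaks)
            mzs = np.concatenate([mzs, noise_mz])
            intensities = np.concatenate([intensities, noise_int])
        order = np.argsort(mzs, kind="stable")
        neutral = compute_monoisotopic_mass(pep, digestion.static_modifications)
        if params.mass_jitter_ppm > 0:
            neutral *= 1.0 + rng.normal(0.0, params.mass_jitter_ppm) * 1e-6
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                precursor_mz=mz_from_neutral(neutral, z),
                precursor_charge=z,
                peaks=np.column_stack([mzs[order], intensities[order]]),
            )
        )
        truth[scan_id] = (pep, parent_id, z)
    return spectra, GroundTruth(truth)


def _primary_ion_mzs(
    pep: str, precursor_charge: int, digestion: DigestionParams
) -> np.ndarray:
    """Exact (unbinned) primary b/y ion m/z values, same charge rules
    as the engine's theoretical spectrum."""
    mods = digestion.static_modifications
    residue = np.array([RESIDUE_MASSES[aa] + mods.get(aa, 0.0) for aa in pep])
    prefix = np.cumsum(residue)[:-1]
    total = residue.sum()
    b = prefix
    y = total - prefix + WATER_MASS
    frag_charges = [1, 2] if precursor_charge >= 3 else [1]
    out = []
    for z in frag_charges:
        out.append((b + z * PROTON_MASS) / z)
        out.append((y + z * PROTON_MASS) / z)
    return np.concatenate(out)


def simulate_run_to_files(
    proteome_fasta: str | Path,
    params: SimulationParams,
    out_ms2: str | Path,
    out_truth: str | Path,
    digestion: DigestionParams | None = None,
) -> None:
    spectra, truth = simulate_run(proteome_fasta, params, digestion)
    write_ms2(spectra, out_ms2)
    Path(out_truth).write_text(truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# Small-vs-large database experiment


def build_from_records(
    records: Sequence[ProteinRecord],
    digestion: DigestionParams | None = None,
    path: str | Path = ":memory:",
) -> SQLiteBackend:
    """Decoy-augment and index a target protein list."""
    digestion = digestion or DigestionParams()
    backend = SQLiteBackend(path)
    build_index(append_decoys(records, digestion.decoy_prefix), digestion, backend)
    return backend


def _filtered_rank1(
    run_ms2: str | Path,
    backend: SQLiteBackend,
    search: SearchParams,
    filt: FilterParams,
) -> tuple[dict[int, str], list[float], int]:
    """Search + filter one run.

    Returns (scan -> accepted rank-1 peptide) for PSMs on accepted
    loci, the per-scan DeltaCN values of all gated rank-1 PSMs, and
    the filtered-PSM count.
    """
    groups = list(search_file(run_ms2, backend, search))
    accepted, report = filter_results(groups, backend, filt)
    accepted_ids = {l.protein_id for l in accepted}
    rank1 = [g[0] for g in groups if g]
    gated = list(apply_psm_gates(rank1, filt))
    deltas = [p.delta_cn for p in gated]
    kept: dict[int, str] = {}
    for psm in gated:
        entry = lookup_parents(psm.peptide, backend)
        if entry is None:
            continue
        if any(occ.protein_id in accepted_ids for occ in entry.occurrences):
            kept[psm.scan_id] = psm.peptide
    return kept, deltas, len(kept)


def spike_experiment(
    small_records: Sequence[ProteinRecord],
    big_records: Sequence[ProteinRecord],
    run_ms2: str | Path,
    truth: GroundTruth | None = None,
    digestion: DigestionParams | None = None,
    search: SearchParams | None = None,
    filt: FilterParams | None = None,
    small_backend: SQLiteBackend | None = None,
    big_backend: SQLiteBackend | None = None,
) -> AgreementReport:
    """Search one simulated run against a focused and an inflated
    database and compare the filtered identifications.

    ``big_records`` must contain every small-database protein sequence
    (the big database is the small one plus distractors). Reports the
    fraction of co-filtered scans assigned the identical peptide, the
    sensitivity ratio big/small, and the median DeltaCN of each run.
    """
    small_seqs = {r.sequence for r in small_records}
    big_seqs = {r.sequence for r in big_records}
    if not small_seqs <= big_seqs:
        raise ValueError("small database is not a subset of the big database")
    digestion = digestion or DigestionParams()
    search = search or SearchParams()
    filt = filt or FilterParams()
    if small_backend is None:
        small_backend = build_from_records(small_records, digestion)
    if big_backend is None:
        big_backend = build_from_records(big_records, digestion)

    kept_s, deltas_s, n_s = _filtered_rank1(run_ms2, small_backend, search, filt)
    kept_b, deltas_b, n_b = _filtered_rank1(run_ms2, big_backend, search, filt)

    co = sorted(set(kept_s) & set(kept_b))
    agree = sum(1 for sid in co if kept_s[sid] == kept_b[sid])
    report = AgreementReport(
        co_filtered_scans=len(co),
        agreeing_scans=agree,
        agreement_fraction=agree / len(co) if co else 1.0,
        filtered_psms_small=n_s,
        filtered_psms_big=n_b,
        sensitivity_ratio=n_b / n_s if n_s else 1.0,
        median_delta_cn_small=float(np.median(deltas_s)) if deltas_s else 0.0,
        median_delta_cn_big=float(np.median(deltas_b)) if deltas_b else 0.0,
    )
    return report
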