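"""SEQUEST-style spectrum scoring against streamed mass-window candidates.

The scoring pipeline follows the classic cross-correlation lineage:

1. The observed spectrum is binned at ``BIN_WIDTH`` Th, intensities are
   square-root transformed, the m/z range is split into 10 regions each
   normalized to a maximum of 50, and the +/-75-bin background mean is
   subtracted. After this subtraction the cross-correlation score
   ``R(0) - mean(R(tau), tau != 0)`` over offsets tau in [-75, 75]
   collapses to a single dot product with the theoretical spectrum.
2. The theoretical spectrum places b- and y-ions (fragment charge 1,
   plus charge 2 for precursors of charge >= 3) with weight 1.0 and
   +/-1-bin flanks with weight 0.25.
3. XCorr is the dot product scaled by 1e-4 and floored at 0 for
   reporting (the raw, possibly negative value feeds the Z-score
   statistics). DeltaCN is (XCorr1 - XCorr2)/XCorr1; the Z-score
   standardizes the top XCorr against all candidate XCorrs of the scan.

Candidates are consumed as a stream: scoring keeps a bounded top-k
buffer and running moments, never the full candidate list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import ms2 as _ms2

from .chemistry import (
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    neutral_from_mz,
    ppm_error,
)
from .store import StoreBackend, lookup_parents, query_mass_window

logger = logging.getLogger(__name__)

BIN_WIDTH = 1.0005079  # Th
N_REGIONS = 10
REGION_MAX = 50.0
BACKGROUND_OFFSET = 75  # bins, each side
FLANK_WEIGHT = 0.25
XCORR_SCALE = 1e-4
PRECURSOR_REMOVE_WINDOW = 1.5  # Th around the precursor m/z

DEFAULT_CANDIDATE_CHARGES = (2, 3)


@dataclass
class Spectrum:
    """One centroided MS/MS scan."""

    scan_id: int
    precursor_mz: float
    precursor_charge: int | None  # None -> try DEFAULT_CANDIDATE_CHARGES
    peaks: np.ndarray  # shape (n, 2): m/z, intensity; ascending m/z

    def neutral_mass(self, charge: int) -> float:
        return neutral_from_mz(self.precursor_mz, charge)


@dataclass
class ProcessedSpectrum:
    """Binned, normalized, background-subtracted observed spectrum."""

    bin_width: float
    bins: np.ndarray
    neutral_precursor_mass: float
    charge: int


@dataclass
class TheoreticalSpectrum:
    """Sparse model spectrum: (bin index, weight) for b/y ions."""

    peptide: str
    indices: np.ndarray
    weights: np.ndarray


@dataclass
class PSM:
    """A scored peptide-spectrum match."""

    scan_id: int
    peptide: str
    xcorr: float
    delta_cn: float
    z_score: float
    ppm_error: float
    rank: int
    charge: int
    observed_neutral_mass: float
    calculated_neutral_mass: float
    is_decoy_only: bool = False
    candidate_count: int = 0
    parent_deflines: tuple[str, ...] = ()


@dataclass
class SearchParams:
    """Search-time knobs. The wide 30 ppm precursor window is deliberate:
    the strict <10 ppm criterion is applied downstream at filter time."""

    precursor_tolerance_ppm: float = 30.0
    report_hits: int = 5
    candidate_charges: tuple[int, ...] = DEFAULT_CANDIDATE_CHARGES
    static_modifications: Mapping[str, float] | None = None


# ---------------------------------------------------------------------------
# Spectrum file parsing


def parse_spectra(path: str | Path, format: str | None = None) -> Iterator[Spectrum]:
    """Stream scans from an MS2 or MGF file (format inferred from the
    suffix when not given). Scans with an empty peak list are skipped
    with a warning; scans without a charge get ``precursor_charge
    None`` and are scored at the default candidate charges.
    """
    path = Path(path)
    if format is None:
        suffix = path.name.lower()
        if suffix.endswith((".ms2", ".ms2.gz")):
            format = "ms2"
        elif suffix.endswith((".mgf", ".mgf.gz")):
            format = "mgf"
        else:
            raise ValueError(f"cannot infer spectrum format from {path.name!r}")
    if format == "ms2":
        reader = _ms2.read(str(path))
        yield from _convert_ms2(reader)
    elif format == "mgf":
        reader = _mgf.read(str(path))
        yield from _convert_mgf(reader)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


def _convert_ms2(reader) -> Iterator[Spectrum]:
    for i, scan in enumerate(reader):
        params = scan["params"]
        scan_id = int(params["scan"][0])
        mz = float(params["precursor m/z"])
        charges = params.get("charge")
        charge = int(charges[0]) if charges else None
        yield from _finish_scan(scan, scan_id, mz, charge)


def _convert_mgf(reader) -> Iterator[Spectrum]:
    for i, scan in enumerate(reader):
        params = scan["params"]
        mz = float(params["pepmass"][0])
        charges = params.get("charge")
        charge = int(charges[0]) if charges else None
        scan_id = int(params.get("scans", i + 1))
        yield from _finish_scan(scan, scan_id, mz, charge)


def _finish_scan(scan, scan_id: int, mz: float, charge: int | None) -> Iterator[Spectrum]:
    mzs = np.asarray(scan["m/z array"], dtype=float)
    intensities = np.asarray(scan["intensity array"], dtype=float)
    if mzs.size == 0:
        logger.warning("scan %s has no peaks; skipped", scan_id)
        return
    order = np.argsort(mzs, kind="stable")
    peaks = np.column_stack([mzs[order], intensities[order]])
    yield Spectrum(scan_id=scan_id, precursor_mz=mz, precursor_charge=charge, peaks=peaks)


def write_ms2(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write scans in MS2 text format (S/Z header lines per scan)."""
    with open(path, "w") as fh:
        fh.write("H\tExtractor\tcompilite\n")
        for s in spectra:
            fh.write(f"S\t{s.scan_id:06d}\t{s.scan_id:06d}\t{s.precursor_mz:.5f}\n")
            if s.precursor_charge:
                mh = s.neutral_mass(s.precursor_charge) + PROTON_MASS
                fh.write(f"Z\t{s.precursor_charge}\t{mh:.5f}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.1f}\n")


# ---------------------------------------------------------------------------
# Preprocessing


def bin_and_normalize(
    spectrum: Spectrum, charge: int, bin_width: float = BIN_WIDTH
) -> tuple[np.ndarray, float]:
    """Binned, sqrt-transformed, regionally normalized intensity vector
    (before background subtraction) and the neutral precursor mass."""
    mzs = spectrum.peaks[:, 0]
    intensities = spectrum.peaks[:, 1]
    keep = np.abs(mzs - spectrum.precursor_mz) > PRECURSOR_REMOVE_WINDOW
    mzs, intensities = mzs[keep], intensities[keep]
    neutral = spectrum.neutral_mass(charge)
    # cover the fragment range: up to the singly-protonated precursor
    max_mz = max(float(mzs.max(initial=0.0)), neutral + PROTON_MASS) + 2 * bin_width
    n_bins = int(math.ceil(max_mz / bin_width)) + BACKGROUND_OFFSET + 2
    v = np.zeros(n_bins)
    idx = np.rint(mzs / bin_width).astype(int)
    np.maximum.at(v, idx, np.sqrt(intensities))

    # 10 regions across the vector, each scaled to max 50
    region_size = max(n_bins // N_REGIONS, 1)
    for r in range(N_REGIONS):
        lo = r * region_size
        hi = n_bins if r == N_REGIONS - 1 else (r + 1) * region_size
        peak = v[lo:hi].max(initial=0.0)
        if peak > 0:
            v[lo:hi] *= REGION_MAX / peak
    return v, neutral


def preprocess(
    spectrum: Spectrum, charge: int, bin_width: float = BIN_WIDTH
) -> ProcessedSpectrum:
    """Bin, sqrt-transform, regionally normalize, and background-subtract.

    The returned vector ``v'`` satisfies ``dot(t, v') = R(0) -
    mean(R(tau), tau in [-75, 75], tau != 0)`` for any theoretical
    vector ``t``, which is what :func:`xcorr` exploits.
    """
    v, neutral = bin_and_normalize(spectrum, charge, bin_width)
    return ProcessedSpectrum(
        bin_width=bin_width,
        bins=subtract_background(v),
        neutral_precursor_mass=neutral,
        charge=charge,
    )


def subtract_background(v: np.ndarray, offset: int = BACKGROUND_OFFSET) -> np.ndarray:
    """v'[i] = v[i] - mean of v over i-75..i+75 excluding i itself,
    with zero padding beyond the vector ends."""
    n = len(v)
    padded = np.concatenate([np.zeros(offset), v, np.zeros(offset)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    window = csum[2 * offset + 1 :] - csum[: n]  # sum over i-75..i+75
    return v - (window - v) / (2 * offset)


# ---------------------------------------------------------------------------
# Theoretical spectrum


def theoretical_ions(
    peptide: str,
    precursor_charge: int,
    static_modifications: Mapping[str, float] | None = None,
    bin_width: float = BIN_WIDTH,
) -> TheoreticalSpectrum:
    """b/y fragment bins for ``peptide``.

    Fragment charge 1 always; charge 2 added for precursors of charge
    >= 3. Primary bins carry weight 1.0, the two flanking bins 0.25;
    overlaps keep the maximum weight.
    """
    if len(peptide) < 2:
        raise ValueError(f"peptide {peptide!r} too short to fragment")
    mods = static_modifications or {}
    residue = np.array(
        [RESIDUE_MASSES[aa] + mods.get(aa, 0.0) for aa in peptide]
    )
    prefix = np.cumsum(residue)[:-1]  # b1..b(n-1)
    total = residue.sum()
    b_neutral = prefix
    y_neutral = total - prefix + WATER_MASS  # y(n-1)..y1
    frag_charges = [1, 2] if precursor_charge >= 3 else [1]
    weight_at: dict[int, float] = {}
    for z in frag_charges:
        mz = np.concatenate([b_neutral + z * PROTON_MASS, y_neutral + z * PROTON_MASS]) / z
        idx = np.rint(mz / bin_width).astype(int)
        for i in idx:
            weight_at[i] = 1.0
            for f in (i - 1, i + 1):
                if weight_at.get(f, 0.0) < FLANK_WEIGHT:
                    weight_at[f] = FLANK_WEIGHT
    # re-assert primaries in case a flank overwrote... (max semantics)
    for z in frag_charges:
        mz = np.concatenate([b_neutral + z * PROTON_MASS, y_neutral + z * PROTON_MASS]) / z
        for i in np.rint(mz / bin_width).astype(int):
            weight_at[i] = 1.0
    items = sorted(weight_at.items())
    return TheoreticalSpectrum(
        peptide=peptide,
        indices=np.array([i for i, _ in items], dtype=int),
        weights=np.array([w for _, w in items]),
    )


# ---------------------------------------------------------------------------
# Scoring


def xcorr(processed: ProcessedSpectrum, theoretical: TheoreticalSpectrum) -> float:
    """Reported XCorr: background-corrected correlation scaled by 1e-4,
    floored at 0."""
    return max(0.0, xcorr_raw(processed, theoretical))


def xcorr_raw(processed: ProcessedSpectrum, theoretical: TheoreticalSpectrum) -> float:
    """Unfloored XCorr (may be negative); used for Z-score statistics."""
    if theoretical.indices.size == 0:
        return 0.0
    idx = theoretical.indices
    if idx.max(initial=0) >= len(processed.bins):
        raise ValueError(
            f"theoretical ion bin {idx.max()} outside observed vector of "
            f"length {len(processed.bins)}"
        )
    valid = idx >= 0
    return float(
        processed.bins[idx[valid]] @ theoretical.weights[valid]
    ) * XCORR_SCALE


@dataclass
class _TopK:
    """Bounded buffer of best candidates, deterministic under ties.

    Keeps at most 2k entries between trims, so peak memory is O(k)
    regardless of how many candidates stream through."""

    k: int
    entries: list[tuple[float, str, float, int, float]] = field(default_factory=list)

    def push(self, xc: float, peptide: str, mass: float, charge: int, raw: float) -> None:
        self.entries.append((xc, peptide, mass, charge, raw))
        if len(self.entries) > 2 * self.k:
            self._trim()

    def _trim(self) -> None:
        self.entries.sort(key=lambda e: (-e[0], e[1]))
        del self.entries[self.k :]

    def best(self) -> list[tuple[float, str, float, int, float]]:
        self._trim()
        return self.entries


def score_scan(
    spectrum: Spectrum,
    backend: StoreBackend,
    params: SearchParams,
    _candidate_counter: list[int] | None = None,
) -> list[PSM]:
    """Score one scan against streamed mass-window candidates.

    For a known precursor charge only that charge is searched; unknown
    charges are tried at every candidate charge and the interpretation
    with the highest top XCorr wins. Returns at most
    ``params.report_hits`` PSMs ranked by descending XCorr (ties broken
    lexicographically by peptide).
    """
    charges = (
        (spectrum.precursor_charge,)
        if spectrum.precursor_charge
        else params.candidate_charges
    )
    mods = params.static_modifications
    if mods is None and hasattr(backend, "static_modifications"):
        mods = backend.static_modifications

    best_interpretation: tuple | None = None
    for charge in charges:
        neutral = spectrum.neutral_mass(charge)
        if neutral <= 0:
            continue
        processed = preprocess(spectrum, charge)
        top = _TopK(params.report_hits)
        count = 0
        s1 = 0.0
        s2 = 0.0
        for pep, mass in query_mass_window(
            neutral, params.precursor_tolerance_ppm, backend
        ):
            theo = theoretical_ions(pep, charge, mods)
            raw = xcorr_raw(processed, theo)
            xc = max(0.0, raw)
            count += 1
            s1 += raw
            s2 += raw * raw
            top.push(xc, pep, mass, charge, raw)
            if _candidate_counter is not None:
                _candidate_counter[0] = max(_candidate_counter[0], len(top.entries))
        if count == 0:
            continue
        entries = top.best()
        if best_interpretation is None or entries[0][0] > best_interpretation[0][0][0]:
            best_interpretation = (entries, count, s1, s2, neutral)

    if best_interpretation is None:
        return []
    entries, count, s1, s2, neutral = best_interpretation
    xc1 = entries[0][0]
    xc2 = entries[1][0] if len(entries) > 1 else 0.0
    delta_cn = 0.0 if xc1 == 0.0 else (xc1 - xc2) / xc1
    mean = s1 / count
    var = max(s2 / count - mean * mean, 0.0)
    std = math.sqrt(var)
    raw1 = entries[0][4]
    z = 0.0 if (count < 3 or std == 0.0) else (raw1 - mean) / std

    psms: list[PSM] = []
    for rank, (xc, pep, mass, charge, _raw) in enumerate(entries, start=1):
        parents: tuple[str, ...] = ()
        decoy_only = False
        entry = lookup_parents(pep, backend)
        if entry is not None:
            seen = {}
            for occ in entry.occurrences:
                if occ.protein_id not in seen:
                    seen[occ.protein_id] = backend.protein(occ.protein_id)
            parents = tuple(p.defline for p in seen.values())
            decoy_only = all(p.is_decoy for p in seen.values())
        psms.append(
            PSM(
                scan_id=spectrum.scan_id,
                peptide=pep,
                xcorr=xc,
                delta_cn=delta_cn,
                z_score=z,
                ppm_error=ppm_error(neutral, mass),
                rank=rank,
                charge=charge,
                observed_neutral_mass=neutral,
                calculated_neutral_mass=mass,
                is_decoy_only=decoy_only,
                candidate_count=count,
            parent_deflines=parents,
            )
        )
    return psms


def search_file(
    spectra_path: str | Path,
    backend: StoreBackend,
    params: SearchParams | None = None,
    format: str | None = None,
) -> Iterator[list[PSM]]:
    """Score every scan of a spectrum file; yields per-scan PSM lists
    (empty lists for unidentified scans are omitted)."""
    params = params or SearchParams()
    for spectrum in parse_spectra(spectra_path, format=format):
        psms = score_scan(spectrum, backend, params)
        if psms:
            yield psms


# ---------------------------------------------------------------------------
# SQT-dialect output

SQT_VERSION = "compilite-sqt 1.0"


def write_sqt(
    psm_groups: Iterable[Sequence[PSM]],
    path: str | Path,
    header_extra: Mapping[str, str] | None = None,
) -> None:
    """Write scored scans in an SQT-dialect text file.

    One S line per scan; M lines per ranked PSM carrying rank,
    calculated neutral mass, XCorr, DeltaCN and Z-score; L lines per
    parent defline. Byte output is deterministic for fixed input.
    """
    with open(path, "w") as fh:
        fh.write(f"H\tSQTGenerator\t{SQT_VERSION}\n")
        for key, value in (header_extra or {}).items():
            fh.write(f"H\t{key}\t{value}\n")
        for group in psm_groups:
            if not group:
                continue
            head = group[0]
            fh.write(
                f"S\t{head.scan_id}\t{head.charge}\t"
                f"{head.observed_neutral_mass:.5f}\t{head.candidate_count}\n"
            )
            for psm in group:
                fh.write(
                    f"M\t{psm.rank}\t{psm.calculated_neutral_mass:.5f}\t"
                    f"{psm.xcorr:.4f}\t{psm.delta_cn:.4f}\t{psm.z_score:.4f}\t"
                    f"{psm.ppm_error:.3f}\t{psm.peptide}\n"
                )
                for defline in psm.parent_deflines:
                    fh.write(f"L\t{defline}\n")


def read_sqt(path: str | Path) -> Iterator[list[PSM]]:
    """Parse an SQT-dialect file written by :func:`write_sqt`."""
    group: list[PSM] = []
    scan_id = charge = None
    observed = 0.0
    candidate_count = 0
    with open(path) as fh:
        for line in fh:
            kind, _, rest = line.rstrip("\n").partition("\t")
            if kind == "H":
                continue
            if kind == "S":
                if group:
                    yield group
                group = []
                fields = rest.split("\t")
                scan_id = int(fields[0])
                charge = int(fields[1])
                observed = float(fields[2])
                candidate_count = int(fields[3])
            elif kind == "M":
                fields = rest.split("\t")
                group.append(
                    PSM(
                        scan_id=scan_id,
                        peptide=fields[6],
                        xcorr=float(fields[2]),
                        delta_cn=float(fields[3]),
                        z_score=float(fields[4]),
                        ppm_error=float(fields[5]),
                        rank=int(fields[0]),
                        charge=charge,
                        observed_neutral_mass=observed,
                        calculated_neutral_mass=float(fields[1]),
                        candidate_count=candidate_count,
                    )
                )
            elif kind == "L":
                psm = group[-1]
                psm.parent_deflines = psm.parent_deflines + (rest,)
    if group:
        yield group
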