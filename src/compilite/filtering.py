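"""Protein-level target-decoy FDR filtering of search results.

The post-processing pipeline mirrors the DTASelect lineage:

1. Per-PSM quality gates keep rank-1 matches with |precursor mass
   error| strictly below the ppm cutoff, plus optional XCorr/DeltaCN
   floors — one PSM per scan.
2. Surviving peptides fan out to every parent protein; each parent
   accumulates a locus (distinct peptide set, spectral count, best
   XCorr). A locus is a decoy iff its parent protein record is a
   decoy; peptides mapping to both target and decoy parents count
   toward both sides and are tallied separately, because the
   two-peptide rule makes them essentially harmless at the protein
   level.
3. Loci with fewer than the minimum number of distinct peptides are
   dropped; then the least-strict locus-level best-XCorr threshold with
   (decoy loci)/(target loci) <= the FDR ceiling is selected. Accepted
   loci are the target loci at or above that threshold.

The FDR estimator is the plain decoy/target ratio for a concatenated
target-decoy database; the 2d/(t+d) variant is selectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .engine import PSM
from .store import StoreBackend, lookup_parents

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    max_protein_fdr: float = 0.01
    min_peptides_per_protein: int = 2
    max_abs_ppm: float = 10.0
    min_delta_cn: float | None = None
    min_xcorr: float | None = None
    fdr_estimator: str = "decoy_over_target"  # or "two_decoy_over_all"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_protein_fdr <= 1.0):
            raise ValueError("max_protein_fdr must be in (0, 1]")
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")
        if self.fdr_estimator not in ("decoy_over_target", "two_decoy_over_all"):
            raise ValueError(f"unknown estimator {self.fdr_estimator!r}")


@dataclass
class ProteinLocus:
    protein_id: int
    defline: str
    is_decoy: bool
    distinct_peptides: set[str] = field(default_factory=set)
    spectral_count: int = 0
    best_xcorr: float = 0.0


@dataclass
class FilterReport:
    input_psms: int = 0
    psms_after_gates: int = 0
    target_loci: int = 0
    decoy_loci: int = 0
    accepted_loci: int = 0
    decoy_loci_above_threshold: int = 0
    achieved_protein_fdr: float = 0.0
    xcorr_threshold: float = 0.0
    shared_target_decoy_peptides: int = 0
    fdr_satisfiable: bool = True

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def apply_psm_gates(
    psms: Iterable[PSM], params: FilterParams
) -> Iterator[PSM]:
    """Rank-1 PSMs passing the strict ppm gate and any score floors."""
    for psm in psms:
        if psm.rank != 1:
            continue
        if abs(psm.ppm_error) >= params.max_abs_ppm:
            continue
        if params.min_xcorr is not None and psm.xcorr < params.min_xcorr:
            continue
        if params.min_delta_cn is not None and psm.delta_cn < params.min_delta_cn:
            continue
        yield psm


def assemble_loci(
    psms: Iterable[PSM],
    backend: StoreBackend,
    report: FilterReport | None = None,
) -> list[ProteinLocus]:
    """Fan gated PSMs out to parent-protein loci.

    Every parent of every surviving peptide receives the peptide; a
    peptide with both target and decoy parents counts toward both and
    increments the shared-peptide tally in the report.
    """
    loci: dict[int, ProteinLocus] = {}
    shared: set[str] = set()
    for psm in psms:
        entry = lookup_parents(psm.peptide, backend)
        if entry is None:
            raise KeyError(
                f"peptide {psm.peptide!r} from results is missing from the "
                "index; results and index do not match"
            )
        parent_ids = sorted({occ.protein_id for occ in entry.occurrences})
        kinds = set()
        for pid in parent_ids:
            prot = backend.protein(pid)
            kinds.add(prot.is_decoy)
            locus = loci.get(pid)
            if locus is None:
                locus = ProteinLocus(pid, prot.defline, prot.is_decoy)
                loci[pid] = locus
            locus.distinct_peptides.add(psm.peptide)
            locus.spectral_count += 1
            locus.best_xcorr = max(locus.best_xcorr, psm.xcorr)
        if len(kinds) == 2:
            shared.add(psm.peptide)
    if report is not None:
        report.shared_target_decoy_peptides = len(shared)
    return sorted(loci.values(), key=lambda l: l.protein_id)


def estimate_fdr(n_target: int, n_decoy: int, estimator: str) -> float:
    if n_target == 0:
        return 0.0 if n_decoy == 0 else 1.0
    if estimator == "two_decoy_over_all":
        return 2 * n_decoy / (n_target + n_decoy)
    return n_decoy / n_target


def filter_by_protein_fdr(
    loci: Sequence[ProteinLocus], params: FilterParams
) -> tuple[list[ProteinLocus], FilterReport]:
    """Choose the least-strict best-XCorr threshold meeting the FDR
    ceiling and return the accepted target loci.

    Candidate thresholds are the distinct locus best-XCorr values (plus
    "no threshold"); among those whose decoy/target ratio is within the
    ceiling the smallest is chosen, maximizing sensitivity. With no
    satisfying threshold the accepted set is empty and the report's
    ``fdr_satisfiable`` flag is cleared.
    """
    report = FilterReport()
    eligible = [
        l for l in loci if len(l.distinct_peptides) >= params.min_peptides_per_protein
    ]
    report.target_loci = sum(1 for l in eligible if not l.is_decoy)
    report.decoy_loci = sum(1 for l in eligible if l.is_decoy)
    if report.target_loci == 0:
        logger.warning("no target loci pass the peptide-count gate")
        report.fdr_satisfiable = report.decoy_loci == 0
        return [], report

    # descending sweep over candidate thresholds, tracking counts above
    ranked = sorted(eligible, key=lambda l: -l.best_xcorr)
    best_threshold: float | None = None
    best_counts = (0, 0)
    n_t = n_d = 0
    i = 0
    n = len(ranked)
    while i < n:
        xc = ranked[i].best_xcorr
        while i < n and ranked[i].best_xcorr == xc:
            if ranked[i].is_decoy:
                n_d += 1
            else:
                n_t += 1
            i += 1
        fdr = estimate_fdr(n_t, n_d, params.fdr_estimator)
        if fdr <= params.max_protein_fdr:
            best_threshold = xc
            best_counts = (n_t, n_d)
    if best_threshold is None:
        report.fdr_satisfiable = False
        report.accepted_loci = 0
        return [], report

    accepted = [
        l
        for l in eligible
        if not l.is_decoy and l.best_xcorr >= best_threshold
    ]
    report.accepted_loci = len(accepted)
    report.xcorr_threshold = best_threshold
    report.decoy_loci_above_threshold = best_counts[1]
    report.achieved_protein_fdr = estimate_fdr(
        best_counts[0], best_counts[1], params.fdr_estimator
    )
    return accepted, report


def filter_results(
    psm_groups: Iterable[Sequence[PSM]],
    backend: StoreBackend,
    params: FilterParams | None = None,
) -> tuple[list[ProteinLocus], FilterReport]:
    """Run the full gate -> assemble -> FDR pipeline on scored scans."""
    params = params or FilterParams()
    flat = [psm for group in psm_groups for psm in group]
    gated = list(apply_psm_gates(flat, params))
    report_holder = FilterReport()
    loci = assemble_loci(gated, backend, report_holder)
    accepted, report = filter_by_protein_fdr(loci, params)
    report.input_psms = len(flat)
    report.psms_after_gates = len(gated)
    report.shared_target_decoy_peptides = report_holder.shared_target_decoy_peptides
    return accepted, report


def group_indistinguishable(
    loci: Sequence[ProteinLocus],
) -> list[list[ProteinLocus]]:
    """Collapse loci with identical peptide sets into reporting groups."""
    groups: dict[frozenset, list[ProteinLocus]] = {}
    for locus in loci:
        groups.setdefault(frozenset(locus.distinct_peptides), []).append(locus)
    out = [sorted(g, key=lambda l: l.defline) for g in groups.values()]
    out.sort(key=lambda g: (-g[0].spectral_count, g[0].defline))
    return out


def write_filtered(
    accepted: Sequence[ProteinLocus],
    report: FilterReport,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the locus table (TSV) and the filter report (JSON).

    Indistinguishable loci share one row whose defline column lists all
    member deflines separated by ``;``. Rows are ordered by descending
    spectral count, then defline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "filtered_loci.tsv"
    report_path = out_dir / "filter_report.json"
    with open(table_path, "w") as fh:
        fh.write("defline\tdistinct_peptides\tspectral_count\tbest_xcorr\n")
        for group in group_indistinguishable(accepted):
            head = group[0]
            deflines = ";".join(l.defline for l in group)
            fh.write(
                f"{deflines}\t{len(head.distinct_peptides)}\t"
                f"{head.spectral_count}\t{head.best_xcorr:.4f}\n"
            )
    report_path.write_text(report.to_json() + "\n")
    return table_path, report_path


def read_filtered(table_path: str | Path) -> list[dict]:
    """Parse a locus table written by :func:`write_filtered`."""
    rows = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            defline, n_pep, sc, xc = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "defline": defline,
                    "distinct_peptides": int(n_pep),
                    "spectral_count": int(sc),
                    "best_xcorr": float(xc),
                }
            )
    return rows
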