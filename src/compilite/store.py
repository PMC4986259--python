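"""Three-collection peptide/protein index: ProtDB, SeqDB, MassDB.

The index is built from a decoy-augmented FASTA by in-silico tryptic
digestion. Protein records live in ProtDB; each distinct peptide
sequence is a SeqDB entry carrying its neutral monoisotopic mass and
every (protein, offset) occurrence; MassDB groups peptide sequences
under a fixed-point discretized mass key so that precursor-mass window
queries are ordered key-range scans.

The storage backend is pluggable. The contract is small: append-style
writes, point lookup by peptide sequence or protein id, and an ordered
scan over a mass-key range that touches only the records in the range.
The default backend is a single-file (or in-memory) SQLite database;
any document store with an ordered index can satisfy the same contract.
"""

from __future__ import annotations

import gzip
import itertools
import json
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .chemistry import (
    DEFAULT_STATIC_MODS,
    RESIDUE_MASSES,
    WATER_MASS,
    UnknownResidueError,
    compute_monoisotopic_mass,
    discretize_mass,
    resolve_sequence,
)

logger = logging.getLogger(__name__)

DECOY_PREFIX_DEFAULT = "Reversed_"

#: Sentinel for a peptide terminus at the protein boundary.
TERMINUS = "-"

# Trypsin: cleave C-terminal to K or R unless the next residue is P.
_TRYPSIN_SITE = re.compile(r"[KR](?!P)")


class FastaParseError(ValueError):
    pass


class IndexNotBuiltError(RuntimeError):
    pass


class DoubleDecoyError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry (target or decoy); the ProtDB row."""

    protein_id: int
    defline: str
    sequence: str
    is_decoy: bool = False


@dataclass(frozen=True)
class PeptideOccurrence:
    """One placement of a peptide inside a parent protein (0-based)."""

    protein_id: int
    start_offset: int
    preceding_residue: str = TERMINUS
    following_residue: str = TERMINUS


@dataclass(frozen=True)
class SeqDBEntry:
    """A distinct peptide sequence with mass and parent occurrences."""

    peptide_sequence: str
    monoisotopic_mass: float
    occurrences: tuple[PeptideOccurrence, ...]


@dataclass(frozen=True)
class MassDBEntry:
    """All peptide sequences sharing one discretized-mass key."""

    mass_key: int
    peptide_sequences: tuple[str, ...]


@dataclass
class DigestionParams:
    """Tryptic digestion and indexing windows.

    Defaults follow common MudPIT practice: up to 2 missed cleavages,
    peptides of 6-60 residues and 600-6000 Da, and cysteine
    carbamidomethylation as the only static modification.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 60
    min_mass: float = 600.0
    max_mass: float = 6000.0
    static_modifications: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATIC_MODS)
    )
    ambiguity: str = "skip"  # skip | reject | map
    decoy_prefix: str = DECOY_PREFIX_DEFAULT

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")
        if self.min_mass > self.max_mass:
            raise ValueError("need min_mass <= max_mass")
        if self.ambiguity not in ("skip", "reject", "map"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity!r}")


@dataclass
class BuildReport:
    """Counts and bookkeeping from one index build."""

    n_proteins: int = 0
    n_target_proteins: int = 0
    n_decoy_proteins: int = 0
    n_distinct_peptides: int = 0
    n_mass_keys: int = 0
    n_occurrences: int = 0
    shared_target_decoy_peptides: int = 0
    shared_length_histogram: dict[int, int] = field(default_factory=dict)
    ambiguous_peptides_dropped: int = 0
    partial: bool = False

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["shared_length_histogram"] = {
            str(k): v for k, v in sorted(self.shared_length_histogram.items())
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# FASTA input and decoy construction


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path, decoy_prefix: str = DECOY_PREFIX_DEFAULT
) -> Iterator[ProteinRecord]:
    """Stream ProteinRecords from a (optionally gzipped) FASTA file.

    Records get sequential ids starting at 0 in file order; sequences
    are uppercased with whitespace removed. A record is flagged as a
    decoy iff its defline starts with ``decoy_prefix``.
    """
    protein_id = 0
    defline: str | None = None
    chunks: list[str] = []
    n_lines = 0
    with _open_text(path) as handle:
        for n_lines, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if defline is not None:
                    yield _make_record(protein_id, defline, chunks, decoy_prefix)
                    protein_id += 1
                defline = line[1:].strip()
                chunks = []
            else:
                if defline is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first '>' header "
                        f"at line {n_lines}"
                    )
                chunks.append(line)
    if defline is not None:
        yield _make_record(protein_id, defline, chunks, decoy_prefix)
    elif n_lines == 0:
        logger.warning("FASTA file %s is empty", path)


def _make_record(
    protein_id: int, defline: str, chunks: list[str], decoy_prefix: str
) -> ProteinRecord:
    sequence = "".join(chunks).upper().replace(" ", "")
    return ProteinRecord(
        protein_id=protein_id,
        defline=defline,
        sequence=sequence,
        is_decoy=defline.startswith(decoy_prefix),
    )


def append_decoys(
    records: Iterable[ProteinRecord], prefix: str = DECOY_PREFIX_DEFAULT
) -> Iterator[ProteinRecord]:
    """Emit all target records, then one reversed decoy per target.

    The decoy sequence is the full character reversal of the target and
    its defline is ``prefix`` + the original defline. Output ids stay
    sequential: targets keep theirs, decoys continue after the last
    target. Raises DoubleDecoyError if the input already contains a
    decoy (re-reversing would corrupt the target/decoy accounting).
    """
    targets: list[ProteinRecord] = []
    next_id = 0
    for rec in records:
        if rec.is_decoy or rec.defline.startswith(prefix):
            raise DoubleDecoyError(
                f"input record {rec.defline!r} already carries decoy prefix "
                f"{prefix!r}"
            )
        targets.append(rec)
        next_id = max(next_id, rec.protein_id + 1)
        yield rec
    for rec in targets:
        yield ProteinRecord(
            protein_id=next_id,
            defline=prefix + rec.defline,
            sequence=rec.sequence[::-1],
            is_decoy=True,
        )
        next_id += 1


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str) -> list[int]:
    """Positions i such that trypsin cuts between i-1 and i.

    Cut is C-terminal to K/R except when the following residue is P;
    returned positions are strictly internal (0 < i < len)."""
    return [m.end() for m in _TRYPSIN_SITE.finditer(sequence) if m.end() < len(sequence)]


def tryptic_digest(
    protein: ProteinRecord, params: DigestionParams
) -> list[tuple[str, PeptideOccurrence]]:
    """Fully-tryptic peptides of one protein with their occurrences.

    Emits every peptide spanning at most ``max_missed_cleavages``
    internal cleavage sites, then applies the length and mass windows
    and the residue-ambiguity policy. Duplicate sequences within one
    protein yield separate occurrences.
    """
    out: list[tuple[str, PeptideOccurrence]] = []
    for seq, start, mass in _digest_spans(protein.sequence, params):
        prev = protein.sequence[start - 1] if start > 0 else TERMINUS
        end = start + len(seq)
        nxt = protein.sequence[end] if end < len(protein.sequence) else TERMINUS
        out.append(
            (
                seq,
                PeptideOccurrence(
                    protein_id=protein.protein_id,
                    start_offset=start,
                    preceding_residue=prev,
                    following_residue=nxt,
                ),
            )
        )
    return out


def _digest_spans(
    sequence: str, params: DigestionParams, dropped: list[int] | None = None
) -> Iterator[tuple[str, int, float]]:
    """Yield (peptide, start_offset, neutral_mass) passing all filters.

    ``dropped`` (a one-element counter list) accumulates peptides
    discarded by the ``skip`` ambiguity policy.
    """
    if params.ambiguity == "map":
        sequence = resolve_sequence(sequence, "map")
    mods = params.static_modifications
    has_unknown = any(aa not in RESIDUE_MASSES for aa in sequence)
    if has_unknown and params.ambiguity == "reject":
        bad = next(i for i, aa in enumerate(sequence) if aa not in RESIDUE_MASSES)
        raise UnknownResidueError(sequence[bad], bad, sequence)
    prefix: list[float] | None = None
    if not has_unknown:
        # exact prefix sums so each span's mass is one subtraction
        prefix = [0.0]
        acc = 0.0
        for aa in sequence:
            acc += RESIDUE_MASSES[aa] + mods.get(aa, 0.0)
            prefix.append(acc)

    boundaries = [0] + cleavage_sites(sequence) + [len(sequence)]
    max_span = params.max_missed_cleavages + 1
    n = len(boundaries)
    for i in range(n - 1):
        start = boundaries[i]
        for j in range(i + 1, min(i + 1 + max_span, n)):
            end = boundaries[j]
            length = end - start
            if length < params.min_length:
                continue
            if length > params.max_length:
                break
            pep = sequence[start:end]
            if prefix is not None:
                mass = prefix[end] - prefix[start] + WATER_MASS
            elif any(aa not in RESIDUE_MASSES for aa in pep):
                if dropped is not None:
                    dropped[0] += 1
                continue
            else:
                mass = compute_monoisotopic_mass(pep, mods)
            if params.min_mass <= mass <= params.max_mass:
                yield pep, start, mass


# ---------------------------------------------------------------------------
# Backend


class StoreBackend:
    """Contract every index backend must satisfy.

    Writes are append-style and idempotent (duplicate occurrences are
    ignored). Reads are a point lookup by peptide sequence or protein
    id, and an ordered scan over a mass-key range. ``records_touched``
    counts MassDB records fetched by range scans, so scaling behaviour
    can be asserted without wall clocks.
    """

    def add_proteins(self, records: Iterable[ProteinRecord]) -> None:
        raise NotImplementedError

    def add_peptides(self, rows: Iterable[tuple[str, float, int]]) -> None:
        raise NotImplementedError

    def add_occurrences(
        self, rows: Iterable[tuple[str, int, int, str, str]]
    ) -> None:
        raise NotImplementedError

    def finalize(self, report: BuildReport, params: DigestionParams) -> None:
        raise NotImplementedError

    @property
    def is_built(self) -> bool:
        raise NotImplementedError

    def protein(self, protein_id: int) -> ProteinRecord:
        raise NotImplementedError

    def range_scan(self, key_lo: int, key_hi: int) -> Iterator[tuple[str, float]]:
        """Yield (sequence, mass) with key_lo <= mass_key <= key_hi,
        ordered by (mass, sequence)."""
        raise NotImplementedError

    def seqdb_entry(self, sequence: str) -> SeqDBEntry | None:
        raise NotImplementedError


class SQLiteBackend(StoreBackend):
    """Embedded single-file store; ``path=':memory:'`` for transient use."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA journal_mode=OFF")
        self.conn.execute("PRAGMA synchronous=OFF")
        self.records_touched = 0
        self.n_queries = 0
        self._create()

    def _create(self) -> None:
        cur = self.conn
        cur.execute(
            "CREATE TABLE IF NOT EXISTS proteins ("
            " protein_id INTEGER PRIMARY KEY, defline TEXT,"
            " sequence TEXT, is_decoy INTEGER)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS peptides ("
            " sequence TEXT PRIMARY KEY, mass REAL, mass_key INTEGER)"
        )
        cur.execute(
            "CREATE INDEX IF NOT EXISTS idx_mass_key ON peptides(mass_key)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS occurrences ("
            " sequence TEXT, protein_id INTEGER, start INTEGER,"
            " prev TEXT, next TEXT,"
            " PRIMARY KEY (sequence, protein_id, start))"
        )
        cur.execute("CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)")
        self.conn.commit()

    # -- writes

    def add_proteins(self, records: Iterable[ProteinRecord]) -> None:
        self.conn.executemany(
            "INSERT OR IGNORE INTO proteins VALUES (?,?,?,?)",
            ((r.protein_id, r.defline, r.sequence, int(r.is_decoy)) for r in records),
        )

    def add_peptides(self, rows: Iterable[tuple[str, float, int]]) -> None:
        self.conn.executemany(
            "INSERT OR IGNORE INTO peptides VALUES (?,?,?)", rows
        )

    def add_occurrences(self, rows: Iterable[tuple[str, int, int, str, str]]) -> None:
        self.conn.executemany(
            "INSERT OR IGNORE INTO occurrences VALUES (?,?,?,?,?)", rows
        )

    def finalize(self, report: BuildReport, params: DigestionParams) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('built', '1')"
        )
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('report', ?)",
            (report.to_json(),),
        )
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('static_modifications', ?)",
            (json.dumps(dict(params.static_modifications)),),
        )
        self.conn.commit()

    # -- reads

    @property
    def is_built(self) -> bool:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key='built'"
        ).fetchone()
        return bool(row and row[0] == "1")

    @property
    def static_modifications(self) -> dict[str, float]:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key='static_modifications'"
        ).fetchone()
        return json.loads(row[0]) if row else {}

    def counts(self) -> tuple[int, int, int, int]:
        """(proteins, distinct peptides, mass keys, occurrences)."""
        c = self.conn
        n_prot = c.execute("SELECT COUNT(*) FROM proteins").fetchone()[0]
        n_pep = c.execute("SELECT COUNT(*) FROM peptides").fetchone()[0]
        n_key = c.execute(
            "SELECT COUNT(DISTINCT mass_key) FROM peptides"
        ).fetchone()[0]
        n_occ = c.execute("SELECT COUNT(*) FROM occurrences").fetchone()[0]
        return n_prot, n_pep, n_key, n_occ

    def protein(self, protein_id: int) -> ProteinRecord:
        row = self.conn.execute(
            "SELECT protein_id, defline, sequence, is_decoy FROM proteins"
            " WHERE protein_id=?",
            (protein_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"no protein with id {protein_id}")
        return ProteinRecord(row[0], row[1], row[2], bool(row[3]))

    def proteins(self) -> Iterator[ProteinRecord]:
        for row in self.conn.execute(
            "SELECT protein_id, defline, sequence, is_decoy FROM proteins"
            " ORDER BY protein_id"
        ):
            yield ProteinRecord(row[0], row[1], row[2], bool(row[3]))

    def range_scan(self, key_lo: int, key_hi: int) -> Iterator[tuple[str, float]]:
        self.n_queries += 1
        cur = self.conn.execute(
            "SELECT sequence, mass FROM peptides"
            " WHERE mass_key BETWEEN ? AND ? ORDER BY mass, sequence",
            (key_lo, key_hi),
        )
        for row in cur:
            self.records_touched += 1
            yield row[0], row[1]

    def seqdb_entry(self, sequence: str) -> SeqDBEntry | None:
        row = self.conn.execute(
            "SELECT mass FROM peptides WHERE sequence=?", (sequence,)
        ).fetchone()
        if row is None:
            return None
        occ = tuple(
            PeptideOccurrence(pid, start, prev, nxt)
            for pid, start, prev, nxt in self.conn.execute(
                "SELECT protein_id, start, prev, next FROM occurrences"
                " WHERE sequence=? ORDER BY protein_id, start",
                (sequence,),
            )
        )
        return SeqDBEntry(sequence, row[0], occ)

    def seqdb_sequences(self) -> Iterator[tuple[str, float]]:
        yield from self.conn.execute(
            "SELECT sequence, mass FROM peptides ORDER BY mass, sequence"
        )

    def massdb_entries(self) -> Iterator[MassDBEntry]:
        cur = self.conn.execute(
            "SELECT mass_key, sequence FROM peptides ORDER BY mass_key, sequence"
        )
        for key, group in itertools.groupby(cur, key=lambda r: r[0]):
            yield MassDBEntry(key, tuple(r[1] for r in group))

    def close(self) -> None:
        self.conn.close()


# ---------------------------------------------------------------------------
# Build and query


_OCC_FLUSH = 200_000

_FLAG_TARGET = 1
_FLAG_DECOY = 2


def build_index(
    records: Iterable[ProteinRecord],
    params: DigestionParams,
    backend: SQLiteBackend,
) -> BuildReport:
    """Digest ``records`` and populate all three collections.

    Re-running over the same input is idempotent: occurrences are keyed
    by (sequence, protein_id, start_offset) and duplicates are ignored.
    On a backend write failure the report comes back with ``partial``
    set and the exception is re-raised by the caller's choice.
    """
    report = BuildReport()
    peptides: dict[str, float] = {}
    flags: dict[str, int] = {}
    occ_batch: list[tuple[str, int, int, str, str]] = []
    dropped = [0]
    try:
        prot_batch: list[ProteinRecord] = []
        for rec in records:
            seq = rec.sequence
            if params.ambiguity == "map":
                seq = resolve_sequence(seq, "map")
                rec = ProteinRecord(rec.protein_id, rec.defline, seq, rec.is_decoy)
            prot_batch.append(rec)
            if len(prot_batch) >= 10_000:
                backend.add_proteins(prot_batch)
                prot_batch = []
            report.n_proteins += 1
            if rec.is_decoy:
                report.n_decoy_proteins += 1
            else:
                report.n_target_proteins += 1
            flag = _FLAG_DECOY if rec.is_decoy else _FLAG_TARGET
            for pep, start, mass in _digest_spans(seq, params, dropped):
                if pep not in peptides:
                    peptides[pep] = mass
                    flags[pep] = flag
                else:
                    flags[pep] |= flag
                end = start + len(pep)
                occ_batch.append(
                    (
                        pep,
                        rec.protein_id,
                        start,
                        seq[start - 1] if start > 0 else TERMINUS,
                        seq[end] if end < len(seq) else TERMINUS,
                    )
                )
                if len(occ_batch) >= _OCC_FLUSH:
                    backend.add_occurrences(occ_batch)
                    occ_batch = []
        backend.add_proteins(prot_batch)
        backend.add_occurrences(occ_batch)
        backend.add_peptides(
            (pep, mass, discretize_mass(mass)) for pep, mass in peptides.items()
        )
    except sqlite3.Error:
        report.partial = True
        backend.finalize(report, params)
        raise

    shared = [pep for pep, f in flags.items() if f == (_FLAG_TARGET | _FLAG_DECOY)]
    report.shared_target_decoy_peptides = len(shared)
    hist: dict[int, int] = {}
    for pep in shared:
        hist[len(pep)] = hist.get(len(pep), 0) + 1
    report.shared_length_histogram = hist
    report.ambiguous_peptides_dropped = dropped[0]
    n_prot, n_pep, n_key, n_occ = backend.counts()
    report.n_proteins = n_prot
    report.n_distinct_peptides = n_pep
    report.n_mass_keys = n_key
    report.n_occurrences = n_occ
    backend.finalize(report, params)
    return report


def query_mass_window(
    neutral_mass: float,
    tolerance_ppm: float,
    backend: StoreBackend,
) -> Iterator[tuple[str, float]]:
    """Stream (peptide, mass) with |mass - neutral_mass| within the ppm
    window, ascending by mass then sequence.

    The scan touches only the mass keys covering the window, so its
    cost tracks the number of in-window peptides rather than the total
    database size.
    """
    if not backend.is_built:
        raise IndexNotBuiltError("index has not been built")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    tol = neutral_mass * tolerance_ppm * 1e-6
    key_lo = discretize_mass(max(neutral_mass - tol, 0.0))
    key_hi = discretize_mass(neutral_mass + tol)
    for seq, mass in backend.range_scan(key_lo, key_hi):
        if abs(mass - neutral_mass) <= tol:
            yield seq, mass


def lookup_parents(sequence: str, backend: StoreBackend) -> SeqDBEntry | None:
    """SeqDB point lookup; None signals an unknown sequence."""
    if not backend.is_built:
        raise IndexNotBuiltError("index has not been built")
    return backend.seqdb_entry(sequence)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Echo records as wrapped FASTA (used for decoy-augmented output)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.defline}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
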