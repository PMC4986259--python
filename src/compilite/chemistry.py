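"""Residue masses and mass arithmetic.

All masses are monoisotopic and in daltons. Peptide masses are neutral
(uncharged): the sum of residue masses plus one water for the termini.
Fragment and precursor m/z values add one proton per charge.

The residue table lists the 20 canonical amino acids. Non-canonical
codes (B, J, O, U, X, Z) are handled by a configurable ambiguity policy:
``skip`` drops peptides containing them from the index, ``reject``
raises, and ``map`` resolves U->C (selenocysteine to cysteine) and
O->K (pyrrolysine to lysine) before rejecting the rest.
"""

from __future__ import annotations

from typing import Mapping

# Monoisotopic residue masses (Da), i.e. the mass the residue contributes
# inside a peptide chain (amino acid minus water).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841392,
    "T": 101.04767847,
    "C": 103.00918478,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048491,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

WATER_MASS = 18.0105646863
PROTON_MASS = 1.00727646688

#: Residues without a defined monoisotopic mass.
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

#: ``map`` policy resolution for the two genuinely coded rare residues.
AMBIGUITY_MAP = {"U": "C", "O": "K"}

#: Default static modification: cysteine carbamidomethylation, the
#: standard alkylation adduct in MudPIT sample preparation.
DEFAULT_STATIC_MODS: dict[str, float] = {"C": 57.02146}

MASS_KEY_SCALE = 10_000  # 0.1 mDa fixed point


class UnknownResidueError(ValueError):
    """A residue without a defined mass under the active policy."""

    def __init__(self, residue: str, position: int, peptide: str):
        self.residue = residue
        self.position = position
        super().__init__(
            f"residue {residue!r} at position {position} of {peptide!r} "
            "has no defined monoisotopic mass"
        )


def resolve_sequence(sequence: str, policy: str = "skip") -> str | None:
    """Apply the ambiguity policy to a peptide/protein sequence.

    Returns the (possibly rewritten) sequence, or ``None`` when the
    ``skip`` policy drops it. ``reject`` raises UnknownResidueError.
    """
    if policy not in ("skip", "reject", "map"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    bad = [i for i, aa in enumerate(sequence) if aa not in RESIDUE_MASSES]
    if not bad:
        return sequence
    if policy == "map":
        mapped = "".join(AMBIGUITY_MAP.get(aa, aa) for aa in sequence)
        bad = [i for i, aa in enumerate(mapped) if aa not in RESIDUE_MASSES]
        if not bad:
            return mapped
        raise UnknownResidueError(mapped[bad[0]], bad[0], sequence)
    if policy == "reject":
        raise UnknownResidueError(sequence[bad[0]], bad[0], sequence)
    return None


def compute_monoisotopic_mass(
    peptide: str, static_modifications: Mapping[str, float] | None = None
) -> float:
    """Neutral monoisotopic mass of ``peptide`` in Da.

    Sum of residue masses plus one water; ``static_modifications`` maps
    residue letters to fixed mass deltas applied at every occurrence.
    Raises UnknownResidueError for residues without a defined mass.
    """
    mods = static_modifications or {}
    total = WATER_MASS
    for i, aa in enumerate(peptide):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise UnknownResidueError(aa, i, peptide) from None
        total += mods.get(aa, 0.0)
    return total


def discretize_mass(mass: float) -> int:
    """Fixed-point mass key: ``round(mass * 1e4)`` (0.1 mDa resolution).

    Deterministic and total over non-negative finite masses; the key is
    the unit of grouping in the mass-indexed peptide collection.
    """
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass}")
    return round(mass * MASS_KEY_SCALE)


def neutral_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from an observed m/z at the given positive charge."""
    return (mz - PROTON_MASS) * charge


def mz_from_neutral(mass: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons."""
    return mass / charge + PROTON_MASS


def ppm_error(observed_neutral: float, theoretical_neutral: float) -> float:
    """Signed relative precursor mass error in parts per million."""
    return (observed_neutral - theoretical_neutral) / theoretical_neutral * 1e6
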