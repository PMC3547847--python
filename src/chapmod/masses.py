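"""Monoisotopic mass arithmetic for peptides and lysine modifications.

Lysine trimethylation (+3xCH2) and acetylation (+C2H2O) differ by only
~0.0364 Da on a nominal +42 shift; telling them apart is purely a matter
of mass accuracy at the precursor level.  Everything here is therefore
derived from elemental composition rather than from rounded literature
values: compositions are the ground truth a search engine itself uses.

All masses are neutral monoisotopic masses in Da unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

__all__ = [
    "ModificationDelta",
    "MODIFICATIONS",
    "mod_delta",
    "get_modification",
    "peptide_monoisotopic_mass",
    "ppm_error",
    "discriminable",
    "mass_to_mz",
    "mz_to_neutral_mass",
    "WATER",
    "PROTON",
]

# Monoisotopic element masses (CODATA/IUPAC 2021 values, Da).
ELEMENT_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

PROTON = 1.007276466  # mass of H+ (hydrogen atom minus electron)

# Residue compositions (residue = amino acid minus water).
RESIDUE_COMPOSITION: Dict[str, Dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def _composition_mass(composition: Dict[str, int]) -> float:
    return sum(ELEMENT_MASS[el] * n for el, n in composition.items())


WATER = _composition_mass({"H": 2, "O": 1})

RESIDUE_MASS: Dict[str, float] = {
    aa: _composition_mass(comp) for aa, comp in RESIDUE_COMPOSITION.items()
}


@dataclass(frozen=True)
class ModificationDelta:
    """A named post-translational modification and its monoisotopic shift.

    ``delta_da`` is always derived from ``composition`` so that the shift
    can be re-audited against element masses.
    """

    name: str
    composition: Dict[str, int] = field(hash=False)
    target_residues: FrozenSet[str] = frozenset()

    @property
    def delta_da(self) -> float:
        return _composition_mass(self.composition)


MODIFICATIONS: Dict[str, ModificationDelta] = {
    m.name: m
    for m in [
        ModificationDelta("monomethyl", {"C": 1, "H": 2}, frozenset("K")),
        ModificationDelta("dimethyl", {"C": 2, "H": 4}, frozenset("K")),
        ModificationDelta("trimethyl", {"C": 3, "H": 6}, frozenset("K")),
        ModificationDelta("acetyl", {"C": 2, "H": 2, "O": 1}, frozenset("K")),
        ModificationDelta("carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1}, frozenset("C")),
        ModificationDelta("oxidation", {"O": 1}, frozenset("M")),
        ModificationDelta("none", {}, frozenset(RESIDUE_COMPOSITION)),
    ]
}


def get_modification(name: str) -> ModificationDelta:
    try:
        return MODIFICATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; known: {sorted(MODIFICATIONS)}"
        ) from None


def mod_delta(name: str) -> float:
    """Monoisotopic mass shift (Da) of a named modification."""
    return get_modification(name).delta_da


def peptide_monoisotopic_mass(
    sequence: str,
    mods: Sequence[Tuple[int, ModificationDelta]] = (),
) -> float:
    """Neutral monoisotopic mass of a peptide with optional modifications.

    Parameters
    ----------
    sequence : str
        Residues in the standard 20-letter alphabet.
    mods : sequence of (index, ModificationDelta)
        1-based residue indices carrying a modification.  The modified
        residue must be in the modification's target set.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None
    for idx, mod in mods:
        if not 1 <= idx <= len(sequence):
            raise ValueError(f"modification index {idx} outside peptide of length {len(sequence)}")
        residue = sequence[idx - 1]
        if residue not in mod.target_residues:
            raise ValueError(
                f"modification {mod.name!r} targets {sorted(mod.target_residues)}, "
                f"but residue {idx} of {sequence!r} is {residue!r}"
            )
        mass += mod.delta_da
    return mass


def ppm_error(observed_mass: float, theoretical_mass: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mass <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical_mass}")
    return 1e6 * (observed_mass - theoretical_mass) / theoretical_mass


def discriminable(
    precursor_mass: float,
    tol_ppm: float,
    mod_a: str | ModificationDelta,
    mod_b: str | ModificationDelta,
    one_sided: bool = False,
) -> bool:
    """Can two modifications be told apart at this precursor mass and tolerance?

    True iff the mass gap between the two shifts exceeds the combined width
    of the two symmetric tolerance windows (``2 * tol_ppm * mass``), i.e.
    the windows cannot overlap.  ``one_sided=True`` uses a single window
    width instead.
    """
    if precursor_mass <= 0 or tol_ppm <= 0:
        raise ValueError("precursor mass and tolerance must be positive")
    a = mod_a if isinstance(mod_a, ModificationDelta) else get_modification(mod_a)
    b = mod_b if isinstance(mod_b, ModificationDelta) else get_modification(mod_b)
    gap = abs(a.delta_da - b.delta_da)
    factor = 1.0 if one_sided else 2.0
    return gap > factor * tol_ppm * 1e-6 * precursor_mass


def mass_to_mz(neutral_mass: float, charge: int) -> float:
    """Observed m/z of a neutral mass at a given positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass from an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON
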