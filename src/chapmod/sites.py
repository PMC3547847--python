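"""Localization of a modification within a peptide and mapping to protein coordinates.

Given a spectrum, a peptide and a known modification, the localizer places
the modification on the candidate residue (for lysine modifications, each
K in the peptide) whose theoretical b/y ion series matches the most
observed fragments within the fragment tolerance.  The localization score
is the matched-fragment count; ``delta_score`` is the margin over the
second-best candidate, and a zero margin with multiple candidates is an
explicit ambiguous result rather than an arbitrary pick.

Coordinates are 1-based throughout, in the peptide and in the protein, so
a call reads naturally as e.g. "K315 of this protein".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .masses import (
    PROTON,
    WATER,
    RESIDUE_MASS,
    ModificationDelta,
    peptide_monoisotopic_mass,
    ppm_error,
)
from .records import SpectrumRecord

__all__ = [
    "SiteAssignment",
    "theoretical_fragments",
    "localize_site",
    "map_to_protein",
    "LocalizationError",
    "MappingError",
]


class LocalizationError(ValueError):
    """No candidate residue, or precursor does not match the peptide."""


class MappingError(ValueError):
    """Peptide absent from the protein, or present more than once."""


@dataclass(frozen=True)
class SiteAssignment:
    """A modification localized within a peptide and (optionally) a protein."""

    protein: Optional[str]
    peptide: str
    peptide_site_index: int  # 1-based within peptide
    modification: ModificationDelta
    n_matched_fragments: int
    delta_score: float
    ambiguous: bool = False
    protein_site_index: Optional[int] = None  # 1-based within protein
    candidate_counts: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.delta_score < 0:
            raise ValueError("delta_score must be >= 0")
        if not 1 <= self.peptide_site_index <= len(self.peptide):
            raise ValueError("peptide_site_index outside peptide")

    @property
    def label(self) -> str:
        """Fig-style label like ``P0001K315`` (protein, residue, position)."""
        prot = self.protein or "?"
        res = self.peptide[self.peptide_site_index - 1]
        pos = self.protein_site_index if self.protein_site_index else self.peptide_site_index
        return f"{prot}{res}{pos}"


def theoretical_fragments(
    peptide: str, mods: Sequence[Tuple[int, ModificationDelta]] = ()
) -> Tuple[List[float], List[float]]:
    """Singly-charged b- and y-ion m/z series of a (modified) peptide.

    b_i carries the first i residues plus a proton; y_i the last i residues
    plus water and a proton.  A modification on residue j shifts every b_i
    with i >= j and every y_i with i > n - j.  Returns ``n - 1`` ions per
    series.
    """
    n = len(peptide)
    if n == 0:
        raise ValueError("empty peptide")
    try:
        masses = np.array([RESIDUE_MASS[aa] for aa in peptide])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from None
    deltas = np.zeros(n)
    for idx, mod in mods:
        if not 1 <= idx <= n:
            raise ValueError(f"modification index {idx} outside peptide")
        deltas[idx - 1] += mod.delta_da
    total = masses + deltas
    prefix = np.cumsum(total)
    b = (prefix[:-1] + PROTON).tolist()
    suffix = np.cumsum(total[::-1])
    y = (suffix[:-1] + WATER + PROTON).tolist()
    return b, y


def _count_matches(theoretical: Sequence[float], observed: np.ndarray, tol_da: float) -> int:
    if observed.size == 0:
        return 0
    count = 0
    for mz in theoretical:
        idx = np.searchsorted(observed, mz)
        for j in (idx - 1, idx):
            if 0 <= j < observed.size and abs(observed[j] - mz) <= tol_da:
                count += 1
                break
    return count


def localize_site(
    spectrum: SpectrumRecord,
    peptide: str,
    modification: ModificationDelta,
    fragment_tol_da: float = 0.6,
    precursor_tol_ppm: float = 10.0,
    protein: Optional[str] = None,
) -> SiteAssignment:
    """Place ``modification`` on the best-supported residue of ``peptide``.

    Candidate residues are the positions of the modification's target
    residues in the peptide.  Each candidate is scored by the number of
    observed fragments matching its theoretical b/y series within
    ``fragment_tol_da``; the argmax wins and ``delta_score`` is its margin
    over the runner-up.  A tie between distinct candidates is returned as
    an ambiguous assignment (of the lowest tied position), never silently
    resolved.  The modified peptide mass must match the spectrum's
    precursor within ``precursor_tol_ppm``.
    """
    candidates = [
        i + 1 for i, aa in enumerate(peptide) if aa in modification.target_residues
    ]
    if not candidates:
        raise LocalizationError(
            f"peptide {peptide!r} has no residue targeted by {modification.name!r}"
        )
    expected = peptide_monoisotopic_mass(peptide) + modification.delta_da
    err = ppm_error(spectrum.precursor_neutral_mass, expected)
    if abs(err) > precursor_tol_ppm:
        raise LocalizationError(
            f"precursor {spectrum.precursor_neutral_mass:.4f} Da is {err:.1f} ppm from "
            f"the modified peptide mass {expected:.4f} Da (tolerance {precursor_tol_ppm} ppm)"
        )
    observed = np.sort(np.array([mz for mz, _ in spectrum.fragments]))
    counts = []
    for site in candidates:
        b, y = theoretical_fragments(peptide, [(site, modification)])
        counts.append(_count_matches(b, observed, fragment_tol_da)
                      + _count_matches(y, observed, fragment_tol_da))
    order = sorted(range(len(candidates)), key=lambda i: (-counts[i], candidates[i]))
    best = order[0]
    second_count = counts[order[1]] if len(order) > 1 else 0
    delta = float(counts[best] - second_count)
    ambiguous = len(candidates) > 1 and delta == 0.0
    return SiteAssignment(
        protein=protein,
        peptide=peptide,
        peptide_site_index=candidates[best],
        modification=modification,
        n_matched_fragments=int(counts[best]),
        delta_score=delta,
        ambiguous=ambiguous,
        candidate_counts=tuple(zip(candidates, counts)),
    )


def map_to_protein(assignment: SiteAssignment, protein_sequence: str,
                   protein: Optional[str] = None) -> SiteAssignment:
    """Fill in the 1-based protein coordinate of a localized site.

    The peptide must occur exactly once in the protein; zero or multiple
    occurrences raise a :class:`MappingError` (listing every candidate
    coordinate in the ambiguous case).
    """
    starts = []
    start = protein_sequence.find(assignment.peptide)
    while start >= 0:
        starts.append(start)
        start = protein_sequence.find(assignment.peptide, start + 1)
    if not starts:
        raise MappingError(f"peptide {assignment.peptide!r} not found in protein")
    if len(starts) > 1:
        coords = [s + assignment.peptide_site_index for s in starts]
        raise MappingError(
            f"peptide {assignment.peptide!r} occurs {len(starts)} times; "
            f"candidate protein sites: {coords}"
        )
    return replace(
        assignment,
        protein=protein if protein is not None else assignment.protein,
        protein_site_index=starts[0] + assignment.peptide_site_index,
    )
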