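"""Conservation of a methyl-site column across a multiple sequence alignment.

Maps a 1-based ungapped residue position of a reference sequence to its
alignment column and reports the residues, identity fraction and a
Clustal-style similarity annotation for that column and a window around
it.  Gap characters are excluded from the identity denominator; the
annotation symbols follow the Clustal convention: ``*`` invariant, ``:``
all residues within one strong similarity group, ``.`` within one weak
group, blank otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

from Bio.Align import MultipleSeqAlignment

__all__ = [
    "AlignmentColumnReport",
    "column_for_site",
    "region_conservation",
    "STRONG_GROUPS",
    "WEAK_GROUPS",
]

GAP_CHARS = frozenset("-.")

# conventional ClustalW residue similarity groups
STRONG_GROUPS = [frozenset(g) for g in
                 ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]]
WEAK_GROUPS = [frozenset(g) for g in
               ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
                "NDEQHK", "NEQHRK", "FVLIM", "HFY"]]


@dataclass(frozen=True)
class AlignmentColumnReport:
    """One alignment column anchored to a reference residue position."""

    reference_sequence: str
    reference_site: int  # 1-based ungapped position in the reference
    column_index: int  # 1-based alignment column
    residues: Dict[str, str]
    identity_fraction: float
    is_invariant: bool
    annotation: str = " "  # '*', ':', '.', or ' '

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must be in [0, 1]")


def _find_record(alignment: MultipleSeqAlignment, reference: str):
    for rec in alignment:
        if rec.id == reference:
            return rec
    raise KeyError(f"reference sequence {reference!r} not in alignment")


def _column_of_ungapped(aligned: str, site: int) -> int:
    seen = 0
    for col, ch in enumerate(aligned, start=1):
        if ch not in GAP_CHARS:
            seen += 1
            if seen == site:
                return col
    raise ValueError(
        f"site {site} beyond ungapped reference length {seen}"
    )


def _annotate(residues: Sequence[str]) -> str:
    distinct = set(residues)
    if len(distinct) == 1:
        return "*"
    if any(distinct <= g for g in STRONG_GROUPS):
        return ":"
    if any(distinct <= g for g in WEAK_GROUPS):
        return "."
    return " "


def _column_report(
    alignment: MultipleSeqAlignment, reference: str, ref_site: int, column: int
) -> AlignmentColumnReport:
    residues = {}
    for rec in alignment:
        ch = str(rec.seq)[column - 1].upper()
        if ch not in GAP_CHARS:
            residues[rec.id] = ch
    if not residues:
        raise ValueError(f"alignment column {column} contains only gaps")
    ref_res = residues.get(reference)
    if ref_res is None:
        raise ValueError(f"reference {reference!r} is gapped at column {column}")
    ident = sum(1 for r in residues.values() if r == ref_res) / len(residues)
    return AlignmentColumnReport(
        reference_sequence=reference,
        reference_site=ref_site,
        column_index=column,
        residues=residues,
        identity_fraction=ident,
        is_invariant=ident == 1.0,
        annotation=_annotate(list(residues.values())),
    )


def column_for_site(
    alignment: MultipleSeqAlignment, reference: str, site: int
) -> AlignmentColumnReport:
    """Report the alignment column holding a reference residue.

    ``site`` is the 1-based position in the *ungapped* reference sequence;
    gaps in the reference row are skipped when locating the column.
    """
    if site < 1:
        raise ValueError(f"site must be >= 1, got {site}")
    rec = _find_record(alignment, reference)
    column = _column_of_ungapped(str(rec.seq), site)
    return _column_report(alignment, reference, site, column)


def region_conservation(
    alignment: MultipleSeqAlignment, reference: str, site: int, window: int
) -> List[AlignmentColumnReport]:
    """Column reports for the site column and ±``window`` columns around it.

    Columns falling outside the alignment are truncated with a warning.
    The reference may be gapped in flanking columns; such columns are
    reported with ``reference_site`` of the anchor and identity measured
    against the modal residue instead.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    anchor = column_for_site(alignment, reference, site)
    length = alignment.get_alignment_length()
    lo, hi = anchor.column_index - window, anchor.column_index + window
    if lo < 1 or hi > length:
        warnings.warn(
            f"window [{lo}, {hi}] truncated to alignment columns [1, {length}]",
            stacklevel=2,
        )
        lo, hi = max(1, lo), min(length, hi)
    reports = []
    for col in range(lo, hi + 1):
        if col == anchor.column_index:
            reports.append(anchor)
            continue
        residues = {}
        for r in alignment:
            ch = str(r.seq)[col - 1].upper()
            if ch not in GAP_CHARS:
                residues[r.id] = ch
        if not residues:
            raise ValueError(f"alignment column {col} contains only gaps")
        ref_res = residues.get(reference)
        if ref_res is None:
            # identity against the modal residue when the reference is gapped
            counts: Dict[str, int] = {}
            for ch in residues.values():
                counts[ch] = counts.get(ch, 0) + 1
            ref_res = max(sorted(counts), key=lambda c: counts[c])
        ident = sum(1 for r in residues.values() if r == ref_res) / len(residues)
        reports.append(
            AlignmentColumnReport(
                reference_sequence=reference,
                reference_site=site,
                column_index=col,
                residues=residues,
                identity_fraction=ident,
                is_invariant=ident == 1.0,
                annotation=_annotate(list(residues.values())),
            )
        )
    return reports
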