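"""Peak-list and protein-level filters applied before interaction scoring.

Three protein-inference rules operate per purification run, in a fixed
order chosen for reproducibility (the rules themselves do not dictate one):

1. ``remove_shared_peptide_groups`` — when two or more gene products were
   identified from the exact same peptide set, the evidence cannot tell
   them apart and all of them are removed.
2. ``pick_best_isoform`` — multiple isoforms of one gene collapse to the
   isoform with the best sequence coverage (ties: higher score, then
   lexicographic protein id).
3. ``drop_single_peptide`` — proteins identified from a single peptide are
   discarded.

``filter_peaklist`` applies the spectrum-level acceptance window (precursor
mass 600–6000 Da, at least 10 fragment ions) used when peak lists are built.
All filters are idempotent and row-order independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .records import PreyObservation, SpectrumRecord

__all__ = [
    "SearchParams",
    "filter_peaklist",
    "remove_shared_peptide_groups",
    "pick_best_isoform",
    "drop_single_peptide",
    "apply_protein_filters",
]


@dataclass(frozen=True)
class SearchParams:
    """Search and peak-list acceptance parameters.

    Defaults mirror a typical Orbitrap workflow: 10 ppm precursor and
    0.6 Da fragment tolerance, tryptic digestion with up to two missed
    cleavages, peak lists restricted to 600–6000 Da precursors with at
    least 10 fragment ions.
    """

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.6
    max_missed_cleavages: int = 2
    peaklist_min_mass_da: float = 600.0
    peaklist_max_mass_da: float = 6000.0
    min_fragment_ions: int = 10

    def __post_init__(self) -> None:
        for name in (
            "precursor_tol_ppm",
            "fragment_tol_da",
            "peaklist_min_mass_da",
            "peaklist_max_mass_da",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_missed_cleavages < 0 or self.min_fragment_ions < 0:
            raise ValueError("counts must be non-negative")
        if self.peaklist_min_mass_da >= self.peaklist_max_mass_da:
            raise ValueError("peaklist_min_mass_da must be < peaklist_max_mass_da")


def filter_peaklist(
    spectra: Iterable[SpectrumRecord], params: SearchParams = SearchParams()
) -> List[SpectrumRecord]:
    """Keep spectra with precursor mass in the window and enough fragments."""
    kept = []
    for s in spectra:
        if s.precursor_neutral_mass < 0:
            raise ValueError("negative precursor mass")
        if (
            params.peaklist_min_mass_da <= s.precursor_neutral_mass <= params.peaklist_max_mass_da
            and len(s.fragments) >= params.min_fragment_ions
        ):
            kept.append(s)
    return kept


def _by_run(obs: Iterable[PreyObservation]) -> Dict[str, List[PreyObservation]]:
    runs: Dict[str, List[PreyObservation]] = {}
    for o in obs:
        runs.setdefault(o.run_id, []).append(o)
    return runs


def remove_shared_peptide_groups(obs: List[PreyObservation]) -> List[PreyObservation]:
    """Drop every protein in a run whose peptide set is identical to another gene's.

    Observations without a peptide set are kept (no evidence of sharing).
    Identical peptide sets within the same gene are isoform business and
    are left for :func:`pick_best_isoform`.
    """
    out: List[PreyObservation] = []
    for run_obs in _by_run(obs).values():
        groups: Dict[frozenset, set] = {}
        for o in run_obs:
            if o.peptide_set:
                gene = o.gene if o.gene is not None else o.protein
                groups.setdefault(o.peptide_set, set()).add(gene)
        shared = {ps for ps, genes in groups.items() if len(genes) >= 2}
        out.extend(o for o in run_obs if not (o.peptide_set and o.peptide_set in shared))
    return out


def pick_best_isoform(obs: List[PreyObservation]) -> List[PreyObservation]:
    """Collapse isoforms of one gene to the best-coverage one, per run.

    Ties on coverage break by higher score, then lexicographically smaller
    protein id, so the choice is a deterministic total order.
    """
    out: List[PreyObservation] = []
    for run_obs in _by_run(obs).values():
        best: Dict[str, PreyObservation] = {}
        for o in run_obs:
            group = o.isoform_group if o.isoform_group is not None else o.protein
            cur = best.get(group)
            if cur is None or _isoform_key(o) > _isoform_key(cur):
                best[group] = o
        chosen = set(id(o) for o in best.values())
        out.extend(o for o in run_obs if id(o) in chosen)
    return out


def _isoform_key(o: PreyObservation) -> Tuple[float, float, Tuple[int, ...]]:
    # higher coverage, then higher score, then lexicographically smaller id wins
    return (o.coverage, o.score, tuple(-ord(c) for c in o.protein))


def drop_single_peptide(obs: List[PreyObservation]) -> List[PreyObservation]:
    """Keep observations backed by at least two peptides."""
    return [o for o in obs if o.n_peptides >= 2]


def apply_protein_filters(obs: List[PreyObservation]) -> Tuple[List[PreyObservation], Dict[str, int]]:
    """Run the three inference filters in their fixed order.

    Returns the surviving observations and a per-stage record count
    (``records_in = records_out + removed`` at every stage).
    """
    counts = {"input": len(obs)}
    obs = remove_shared_peptide_groups(obs)
    counts["after_shared_peptide_removal"] = len(obs)
    obs = pick_best_isoform(obs)
    counts["after_isoform_selection"] = len(obs)
    obs = drop_single_peptide(obs)
    counts["after_single_peptide_discard"] = len(obs)
    return obs, counts
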