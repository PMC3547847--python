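"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Tuple

import pandas as pd


@dataclass(frozen=True)
class PreyObservation:
    """One protein identified in one purification run.

    ``score`` is a Mascot-like log-odds identification score (higher is
    stronger evidence).  ``induced`` distinguishes the bait-expressing run
    from its matched non-induced control.
    """

    run_id: str
    bait: str
    induced: bool
    protein: str
    score: float
    n_peptides: int = 2
    coverage: float = 0.0
    gene: Optional[str] = None
    isoform_group: Optional[str] = None
    peptide_set: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")
        if self.peptide_set is not None and self.n_peptides != len(self.peptide_set):
            object.__setattr__(self, "n_peptides", len(self.peptide_set))


@dataclass
class SpectrumRecord:
    """A peak list for one (possibly modified) peptide spectrum."""

    precursor_neutral_mass: float
    charge: int
    fragments: List[Tuple[float, float]]  # (m/z, intensity)
    peptide_hint: Optional[str] = None
    title: Optional[str] = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.precursor_neutral_mass < 0:
            raise ValueError("negative precursor mass")


OBSERVATION_COLUMNS = [
    "run_id",
    "bait",
    "induced",
    "protein",
    "score",
    "n_peptides",
    "coverage",
    "gene",
    "isoform_group",
    "peptide_set",
]


def observations_to_frame(obs: List[PreyObservation]) -> pd.DataFrame:
    """Tabulate observations; peptide sets are ';'-joined sorted strings."""
    rows = []
    for o in obs:
        rows.append(
            {
                "run_id": o.run_id,
                "bait": o.bait,
                "induced": int(o.induced),
                "protein": o.protein,
                "score": o.score,
                "n_peptides": o.n_peptides,
                "coverage": o.coverage,
                "gene": o.gene if o.gene is not None else o.protein,
                "isoform_group": o.isoform_group if o.isoform_group is not None else o.protein,
                "peptide_set": ";".join(sorted(o.peptide_set)) if o.peptide_set else "",
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def frame_to_observations(df: pd.DataFrame) -> List[PreyObservation]:
    obs = []
    for row in df.itertuples(index=False):
        pep = getattr(row, "peptide_set", "") or ""
        obs.append(
            PreyObservation(
                run_id=str(row.run_id),
                bait=str(row.bait),
                induced=bool(int(row.induced)),
                protein=str(row.protein),
                score=float(row.score),
                n_peptides=int(row.n_peptides),
                coverage=float(row.coverage),
                gene=str(getattr(row, "gene", row.protein)),
                isoform_group=str(getattr(row, "isoform_group", row.protein)),
                peptide_set=frozenset(pep.split(";")) if pep else None,
            )
        )
    return obs
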