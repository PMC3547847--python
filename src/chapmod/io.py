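"""Readers and writers for the pipeline's on-disk formats.

Runs travel as TSV, protein sequences as FASTA (Biopython), spectra as
MGF (pyteomics; PEPMASS is the observed m/z at the stated charge), ground
truth and fitted score models as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .masses import mass_to_mz, mz_to_neutral_mass
from .records import (
    OBSERVATION_COLUMNS,
    PreyObservation,
    SpectrumRecord,
    frame_to_observations,
    observations_to_frame,
)
from .scoring import InteractionCall, MatchedControlResults, ScoreModel

PathLike = Union[str, Path]


# -- run tables ------------------------------------------------------------

def write_runs_tsv(obs: Sequence[PreyObservation], path: PathLike) -> None:
    observations_to_frame(list(obs)).to_csv(path, sep="\t", index=False)


def read_runs_tsv(path: PathLike) -> List[PreyObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "bait": str, "protein": str},
                     keep_default_na=False, na_values=[""])
    df["peptide_set"] = df.get("peptide_set", "").fillna("")
    return frame_to_observations(df)


def write_calls_tsv(calls: Sequence[InteractionCall], path: PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: PathLike) -> List[InteractionCall]:
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "prey": str})
    return [
        InteractionCall(
            bait=r.bait, prey=r.prey, score=float(r.score),
            p_value=float(r.p_value), fdr=float(r.fdr), reported=bool(r.reported),
        )
        for r in df.itertuples(index=False)
    ]


# -- FASTA -----------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment(path: PathLike, fmt: str = "fasta"):
    """Aligned FASTA or Clustal multiple alignment."""
    return AlignIO.read(str(path), fmt)


# -- MGF -------------------------------------------------------------------

def write_mgf(spectra: Sequence[SpectrumRecord], path: PathLike) -> None:
    entries = []
    for i, s in enumerate(spectra):
        entries.append(
            {
                "m/z array": [mz for mz, _ in s.fragments],
                "intensity array": [inten for _, inten in s.fragments],
                "params": {
                    "title": s.title or f"spectrum_{i+1}",
                    "pepmass": (mass_to_mz(s.precursor_neutral_mass, s.charge),),
                    "charge": s.charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: PathLike) -> List[SpectrumRecord]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 1
            mz = float(params["pepmass"][0])
            spectra.append(
                SpectrumRecord(
                    precursor_neutral_mass=mz_to_neutral_mass(mz, charge),
                    charge=charge,
                    fragments=list(zip(entry["m/z array"].tolist(),
                                       entry["intensity array"].tolist())),
                    title=params.get("title"),
                )
            )
    return spectra


# -- models and truth ------------------------------------------------------

def write_models_json(results: MatchedControlResults, path: PathLike) -> None:
    payload = {
        "n_control_runs": results.n_control_runs,
        "hyperprior": dataclasses.asdict(results.hyperprior),
        "background": dataclasses.asdict(results.background),
        "models": {p: dataclasses.asdict(m) for p, m in sorted(results.score_models.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_models_json(path: PathLike) -> Dict[str, ScoreModel]:
    payload = json.loads(Path(path).read_text())
    models = {p: ScoreModel(**d) for p, d in payload["models"].items()}
    models["__background__"] = ScoreModel(**payload["background"])
    return models


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
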