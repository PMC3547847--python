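"""Synthetic AP-MS experiments with known ground truth.

The generator emulates the training design the scorer assumes: matched
pairs of purification runs per bait — a *control* run (bait not induced;
recurrent contaminants only) and an *induced* run (the same contaminant
background, plus the bait itself and its planted true interactors at
scores enriched on the log scale).  Contaminant identity and per-protein
score distributions are shared across runs so the matched-control model
is learnable: each contaminant's log score is normal with a protein-
specific location drawn from a shared hyperprior, mirroring the
hierarchical model the scorer fits.

The generator also plants trimethylated lysines on chosen proteins and
can synthesize b/y fragment spectra for the tryptic peptides covering
them (``spike_modified_peptides``).  Trypsin cleaves after K/R but not
before P; a methylated lysine is treated as cleavable.

All randomness flows from a single integer seed; identical configuration
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from pyteomics import parser as _pyt_parser

from .masses import ModificationDelta, get_modification, peptide_monoisotopic_mass
from .records import PreyObservation, SpectrumRecord
from .sites import theoretical_fragments

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_proteome",
    "spike_modified_peptides",
    "tryptic_peptides",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# residue frequencies roughly matching vertebrate proteomes; K/R kept
# common enough that tryptic peptides are short
_AA_WEIGHTS = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
     1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and distributional parameters of a synthetic experiment.

    ``score_location``/``score_scale`` parameterize the log-score
    distribution of contaminants: each contaminant protein draws its own
    location from N(score_location, between_protein_scale) and its run-level
    log scores from N(location, score_scale).  True interactors score
    ``enrichment_shift`` higher on the log scale.  ``detection_prob_control``
    is the per-run detection probability of a contaminant.
    """

    n_baits: int = 17
    n_pairs: int = 17
    proteome_size: int = 400
    contaminant_fraction: float = 0.25
    true_interactors_per_bait: int = 6
    score_location: float = 4.0
    score_scale: float = 0.5
    between_protein_scale: float = 1.0
    enrichment_shift: float = 3.0
    detection_prob_control: float = 0.9
    singleton_peptide_fraction: float = 0.05
    n_spiked_sites: int = 5
    protein_length: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_baits", "n_pairs", "proteome_size", "protein_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid configuration: {name} must be >= 1")
        for name in ("contaminant_fraction", "detection_prob_control",
                     "singleton_peptide_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid configuration: {name} must be in [0, 1]")
        if self.true_interactors_per_bait < 0 or self.n_spiked_sites < 0:
            raise ValueError("invalid configuration: counts must be >= 0")
        if self.enrichment_shift < 0:
            raise ValueError("invalid configuration: enrichment_shift must be >= 0")
        if self.score_scale <= 0 or self.between_protein_scale < 0:
            raise ValueError("invalid configuration: score_scale must be > 0")
        if self.n_baits > self.n_pairs:
            raise ValueError("invalid configuration: n_baits cannot exceed n_pairs")


@dataclass
class GroundTruth:
    """What was planted: true pairs, contaminants, spiked methyl-sites."""

    true_pairs: Set[Tuple[str, str]]
    contaminant_set: Set[str]
    spiked_sites: List[Tuple[str, int, str]]  # (protein, 1-based residue, mod name)
    sequences: Dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "contaminant_set": sorted(self.contaminant_set),
            "spiked_sites": [list(s) for s in self.spiked_sites],
        }


def generate_proteome(
    rng: np.random.Generator, n: int, length: int
) -> Dict[str, str]:
    """Random protein sequences with realistic residue frequencies."""
    probs = _AA_WEIGHTS / _AA_WEIGHTS.sum()
    alphabet = np.array(list(_AA))
    seqs = {}
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        seqs[f"P{i+1:04d}"] = seq
    return seqs


def generate_experiment(
    config: GeneratorConfig,
) -> Tuple[List[PreyObservation], GroundTruth]:
    """Generate matched control/induced runs with planted ground truth.

    Returns the observations of all ``2 * n_pairs`` runs (control first
    within each pair) and the ground truth.  The bait is always its own
    top-scoring prey in its induced runs.
    """
    rng = np.random.default_rng(config.seed)
    proteome = generate_proteome(rng, config.proteome_size, config.protein_length)
    proteins = sorted(proteome)

    n_contam = int(round(config.contaminant_fraction * config.proteome_size))
    contaminants = proteins[:n_contam]
    rest = proteins[n_contam:]
    baits = rest[: config.n_baits]
    interactor_pool = rest[config.n_baits:]

    contam_loc = {
        p: config.score_location + config.between_protein_scale * rng.standard_normal()
        for p in contaminants
    }

    true_pairs: Set[Tuple[str, str]] = set()
    prey_of: Dict[str, List[str]] = {}
    for b in baits:
        k = min(config.true_interactors_per_bait, len(interactor_pool))
        chosen = list(rng.choice(interactor_pool, size=k, replace=False)) if k else []
        prey_of[b] = [str(p) for p in chosen]
        true_pairs.update((b, str(p)) for p in chosen)

    # protein-specific baseline for planted preys, drawn from the same
    # hyperprior as contaminants; enrichment shifts it upward
    prey_loc = {
        p: config.score_location + config.between_protein_scale * rng.standard_normal()
        for b in baits
        for p in prey_of[b]
    }

    observations: List[PreyObservation] = []

    def _evidence(log_score: float) -> Tuple[int, float]:
        n_pep = max(2, int(round(np.exp(log_score) / 40.0)) + 2)
        cov = float(min(0.95, 0.05 + 0.018 * n_pep))
        return min(n_pep, 60), cov

    def _emit(run_id: str, bait: str, induced: bool, protein: str, log_score: float,
              allow_singleton: bool) -> None:
        score = float(np.exp(log_score))
        n_pep, cov = _evidence(log_score)
        if allow_singleton and rng.random() < config.singleton_peptide_fraction:
            n_pep = 1
        observations.append(
            PreyObservation(
                run_id=run_id, bait=bait, induced=induced, protein=protein,
                score=round(score, 4), n_peptides=n_pep, coverage=round(cov, 4),
                gene=protein, isoform_group=protein,
            )
        )

    for i in range(config.n_pairs):
        bait = baits[i % config.n_baits]
        for induced in (False, True):
            run_id = f"run{i+1:03d}{'i' if induced else 'c'}"
            for p in contaminants:
                if rng.random() < config.detection_prob_control:
                    ls = contam_loc[p] + config.score_scale * rng.standard_normal()
                    _emit(run_id, bait, induced, p, ls, allow_singleton=True)
            if induced:
                for p in prey_of[bait]:
                    ls = prey_loc[p] + config.enrichment_shift \
                        + config.score_scale * rng.standard_normal()
                    _emit(run_id, bait, True, p, ls, allow_singleton=False)
                # the bait itself, always the top-scoring prey of its run
                top = max((o.score for o in observations if o.run_id == run_id), default=1.0)
                bait_log = float(np.log(top * 1.5 + 1.0))
                _emit(run_id, bait, True, bait, bait_log, allow_singleton=False)

    # spike trimethyl sites on planted preys (fall back to any protein with K)
    spiked: List[Tuple[str, int, str]] = []
    candidates = sorted({p for pairs in prey_of.values() for p in pairs}) or proteins
    for p in candidates:
        if len(spiked) >= config.n_spiked_sites:
            break
        ks = [i + 1 for i, aa in enumerate(proteome[p]) if aa == "K"]
        # keep sites whose tryptic peptide is 6..25 residues so the spectrum
        # survives the 600-6000 Da peak-list window
        ks = [k for k in ks if _site_has_usable_peptide(proteome[p], k)]
        if ks:
            site = int(ks[rng.integers(0, len(ks))])
            spiked.append((p, site, "trimethyl"))

    truth = GroundTruth(
        true_pairs=true_pairs,
        contaminant_set=set(contaminants),
        spiked_sites=spiked,
        sequences=proteome,
    )
    return observations, truth


# -- tryptic digestion and spectrum synthesis ------------------------------


def tryptic_peptides(
    sequence: str, max_missed_cleavages: int = 2, min_length: int = 1
) -> List[Tuple[int, str]]:
    """Tryptic peptides (1-based start offset, sequence).

    Cleaves after K/R except before P; methylated K is treated as a normal
    cleavable lysine.  Includes forms with up to ``max_missed_cleavages``
    missed cleavages.
    """
    peptides = _pyt_parser.cleave(
        sequence, _pyt_parser.expasy_rules["trypsin"],
        missed_cleavages=max_missed_cleavages, min_length=min_length,
    )
    out = []
    for pep in sorted(peptides):
        start = 0
        while True:
            idx = sequence.find(pep, start)
            if idx < 0:
                break
            out.append((idx + 1, pep))
            start = idx + 1
    out.sort()
    return out


def _site_has_usable_peptide(sequence: str, site: int) -> bool:
    for start, pep in tryptic_peptides(sequence, max_missed_cleavages=2):
        if start <= site < start + len(pep) and 6 <= len(pep) <= 25:
            return True
    return False


def spike_modified_peptides(
    protein_id: str,
    sequence: str,
    sites: Sequence[Tuple[int, str]],
    charge: int = 2,
    max_missed_cleavages: int = 2,
) -> List[SpectrumRecord]:
    """Synthesize b/y spectra for the tryptic peptides covering given sites.

    Each site is a (1-based residue index, modification name) pair; lysine
    modifications must sit on a K.  One spectrum is produced per covering
    tryptic peptide (including missed-cleavage forms), with the precursor
    neutral mass equal to the modified peptide's monoisotopic mass and all
    singly-charged b/y ions as fragments.
    """
    spectra: List[SpectrumRecord] = []
    for site, mod_name in sites:
        if not 1 <= site <= len(sequence):
            raise ValueError(f"site {site} outside protein of length {len(sequence)}")
        mod = get_modification(mod_name)
        if sequence[site - 1] not in mod.target_residues:
            raise ValueError(
                f"site {site} of {protein_id} is {sequence[site-1]!r}, "
                f"not a valid target of {mod_name!r}"
            )
        for start, pep in tryptic_peptides(sequence, max_missed_cleavages):
            if not start <= site < start + len(pep):
                continue
            pep_idx = site - start + 1
            mods = [] if mod_name == "none" else [(pep_idx, mod)]
            mass = peptide_monoisotopic_mass(pep, mods)
            b, y = theoretical_fragments(pep, mods)
            frags = [(mz, 100.0) for mz in b] + [(mz, 50.0) for mz in y]
            frags.sort()
            spectra.append(
                SpectrumRecord(
                    precursor_neutral_mass=mass,
                    charge=charge,
                    fragments=frags,
                    peptide_hint=pep,
                    title=f"{protein_id}|{mod_name}@{site}|{pep}/{start}",
                )
            )
    return spectra
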