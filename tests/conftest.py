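import numpy as np
import pytest

from chapmod.records import PreyObservation
from chapmod.simulate import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One small synthetic experiment shared by read-only tests."""
    cfg = GeneratorConfig(seed=11, proteome_size=200, contaminant_fraction=0.3,
                          true_interactors_per_bait=4)
    obs, truth = generate_experiment(cfg)
    return cfg, obs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_obs(run_id="r1", bait="B", induced=False, protein="P", score=50.0,
             n_peptides=3, coverage=0.3, gene=None, isoform_group=None,
             peptide_set=None):
    return PreyObservation(
        run_id=run_id, bait=bait, induced=induced, protein=protein, score=score,
        n_peptides=n_peptides, coverage=coverage, gene=gene,
        isoform_group=isoform_group,
        peptide_set=frozenset(peptide_set) if peptide_set else None,
    )
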