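"""Matched-control Bayesian scoring: conjugate updates, p-values, LOO-FDR."""

import math

import numpy as np
import pytest

from chapmod.records import PreyObservation
from chapmod.scoring import (
    InteractionCall,
    MatchedControlModel,
    TrainingSet,
    empirical_fdr_curve,
    expected_contamination_bound,
    report_interactions,
)
from chapmod.simulate import GeneratorConfig, generate_experiment

from conftest import make_obs


def build_model(control_scores_by_protein, n_pairs=3, extra_induced=()):
    """Observations for n_pairs matched pairs with given per-protein control scores.

    ``control_scores_by_protein[p]`` is a list of length n_pairs; None means
    the protein is undetected in that control run.
    """
    obs = []
    for i in range(n_pairs):
        bait = f"B{i}"
        for p, scores in control_scores_by_protein.items():
            s = scores[i]
            if s is not None:
                obs.append(make_obs(run_id=f"c{i}", bait=bait, induced=False,
                                    protein=p, score=s))
        obs.append(make_obs(run_id=f"i{i}", bait=bait, induced=True,
                            protein=bait, score=500.0))
    obs.extend(extra_induced)
    training = TrainingSet(tuple((f"c{i}", f"i{i}", f"B{i}") for i in range(n_pairs)))
    return MatchedControlModel(obs, training=training)


class TestFit:
    def test_posterior_location_converges_to_constant_logscore(self):
        n = 17
        scores = {"P": [100.0] * n, "Q": [50.0] * n}
        model = build_model(scores, n_pairs=n)
        res = model.fit()
        assert res.score_models["P"].location == pytest.approx(math.log(100.0), abs=0.05)
        assert res.score_models["P"].n_control_obs == n
        assert res.score_models["P"].detection_rate == 1.0
        assert not res.score_models["P"].pooled

    def test_singleton_protein_pooled_and_matches_closed_form_update(self):
        """A protein seen once gets the conjugate NIG update of the hyperprior."""
        scores = {"P": [100.0, 110.0, 90.0], "Q": [50.0, 55.0, 45.0],
                  "R": [None, None, 200.0]}
        model = build_model(scores)
        res = model.fit()
        m = res.score_models["R"]
        assert m.pooled and m.n_control_obs == 1
        assert m.detection_rate == pytest.approx(1 / 3)
        h = res.hyperprior
        x = math.log(200.0)
        kn = h.kappa0 + 1
        mn = (h.kappa0 * h.m0 + x) / kn
        an = h.alpha0 + 0.5
        bn = h.beta0 + h.kappa0 * (x - h.m0) ** 2 / (2 * kn)
        assert m.location == pytest.approx(mn, abs=1e-9)
        assert m.scale == pytest.approx(math.sqrt(bn * (kn + 1) / (an * kn)), abs=1e-9)
        assert m.df == pytest.approx(2 * an, abs=1e-9)

    def test_unseen_protein_served_by_background(self):
        model = build_model({"P": [100.0, 100.0, 100.0]})
        res = model.fit()
        assert res.score_model_for("NEVER_SEEN") is res.background

    def test_empty_controls_is_training_error(self):
        obs = [make_obs(run_id="i0", bait="B0", induced=True, protein="X"),
               make_obs(run_id="i1", bait="B1", induced=True, protein="X")]
        training = TrainingSet((("c0", "i0", "B0"), ("c1", "i1", "B1")))
        with pytest.raises(ValueError, match="training error"):
            MatchedControlModel(obs, training=training)

    def test_training_set_needs_two_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            TrainingSet((("c0", "i0", "B0"),))


class TestPvalue:
    def test_predictive_median_scores_half(self):
        rngscores = np.exp(4.0 + 0.5 * np.random.default_rng(5).standard_normal(17))
        model = build_model({"P": list(rngscores)}, n_pairs=17)
        res = model.fit()
        m = res.score_models["P"]
        median_score = math.exp(m.location)  # symmetric predictive on log scale
        obs = make_obs(run_id="i0", bait="B0", induced=True, protein="P",
                       score=median_score)
        assert res.interaction_pvalue(obs) == pytest.approx(0.5, abs=1e-9)

    def test_p_decreases_monotonically_to_zero_in_score(self):
        model = build_model({"P": [100.0, 120.0, 90.0]})
        res = model.fit()
        ps = [
            res.interaction_pvalue(
                make_obs(run_id="i0", bait="B0", induced=True, protein="P", score=s)
            )
            for s in [50, 100, 500, 5e3, 5e5, 5e9]
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6
        assert all(0 < p <= 1 for p in ps)

    def test_tail_matches_hierarchical_monte_carlo_oracle(self, rng):
        """Predictive tail at s=100 on constant-100 controls vs brute-force MC.

        The oracle samples the NIG posterior hierarchically (sigma^2 from an
        inverse gamma via 1/Gamma, mu normal, then a new log-score) without
        using the Student-t form the implementation relies on.
        """
        n = 5
        model = build_model({"P": [100.0] * n, "Q": [40.0, 50.0, 60.0, 45.0, 55.0]},
                            n_pairs=n)
        res = model.fit()
        h = res.hyperprior
        x = np.full(n, math.log(100.0))
        xbar, ss = x.mean(), ((x - x.mean()) ** 2).sum()
        kn = h.kappa0 + n
        mn = (h.kappa0 * h.m0 + n * xbar) / kn
        an = h.alpha0 + n / 2
        bn = h.beta0 + ss / 2 + h.kappa0 * n * (xbar - h.m0) ** 2 / (2 * kn)
        ndraws = 400_000
        sigma2 = bn / rng.gamma(an, 1.0, size=ndraws)
        mu = rng.normal(mn, np.sqrt(sigma2 / kn))
        draws = rng.normal(mu, np.sqrt(sigma2))
        tail_mc = float(np.mean(draws >= math.log(100.0)))
        se = math.sqrt(tail_mc * (1 - tail_mc) / ndraws)
        p = res.interaction_pvalue(
            make_obs(run_id="i0", bait="B0", induced=True, protein="P", score=100.0)
        )
        assert abs(p - tail_mc) <= 2 * se + 1e-4


class TestLooFdr:
    def test_left_out_pair_never_trains_its_own_models(self):
        """Refit equality: holding out a control equals never having had it."""
        cfg = GeneratorConfig(seed=3, proteome_size=120, contaminant_fraction=0.3,
                              n_pairs=4, n_baits=4, true_interactors_per_bait=2)
        obs, _ = generate_experiment(cfg)
        model = MatchedControlModel(obs)
        held = model.training.pairs[0][0]
        res_excl = model.fit(exclude_controls=[held])
        stripped = [o for o in obs if o.run_id != held]
        res_strip = MatchedControlModel(stripped, training=model.training).fit(
            exclude_controls=[held]
        )
        assert set(res_excl.score_models) == set(res_strip.score_models)
        for p, m in res_excl.score_models.items():
            assert m == res_strip.score_models[p]

    def test_hand_computed_fdr_on_toy_table(self):
        """Five observed p-values against a fixed null set, checked by hand.

        null = {0.01, 0.2, 0.5} over 2 folds scaled to 2 induced runs,
        observed p = (0.005, 0.05, 0.3, 0.6, 0.9):
        raw FDR_i = (null<=p_i + 1)/2*2/i = (1/1, 2/2, 3/3, 4/4, 4/5)
        then cumulative-min from the right: (0.8, 0.8, 0.8, 0.8, 0.8).
        """
        q = empirical_fdr_curve(
            np.array([0.005, 0.05, 0.3, 0.6, 0.9]),
            np.array([0.01, 0.2, 0.5]),
            n_folds=2,
            n_induced_runs=2,
        )
        assert q == pytest.approx([0.8, 0.8, 0.8, 0.8, 0.8])

    def test_fdr_curve_above_all_pvalues_equals_null_rate_ratio(self):
        """At a threshold beyond every p-value, FDR is the plain ratio."""
        q = empirical_fdr_curve(
            np.array([0.1, 0.2, 0.3, 0.4, 1.0]),
            np.array([0.99]),  # all null p-values above observed except last
            n_folds=1,
            n_induced_runs=1,
        )
        assert q[-1] == pytest.approx((1 + 1) / 1 * 1 / 5)

    def test_all_contaminants_saturate_fdr(self):
        """With no planted truth, no interaction should look bait-specific."""
        cfg = GeneratorConfig(seed=9, proteome_size=150, contaminant_fraction=0.4,
                              true_interactors_per_bait=0, n_pairs=6, n_baits=6)
        obs, truth = generate_experiment(cfg)
        assert not truth.true_pairs
        res = MatchedControlModel(obs).fit()
        calls = res.loo_fdr(threshold=0.10)
        fdrs = np.array([c.fdr for c in calls])
        assert np.median(fdrs) > 0.8
        reported, _ = report_interactions(calls, 0.10)
        assert len(reported) <= max(3, 0.01 * len(calls))

    def test_reported_sets_nest_across_thresholds(self):
        cfg = GeneratorConfig(seed=12, proteome_size=150, contaminant_fraction=0.3,
                              n_pairs=6, n_baits=6, true_interactors_per_bait=4)
        obs, _ = generate_experiment(cfg)
        calls = MatchedControlModel(obs).fit().loo_fdr()
        sets = []
        for t in (0.02, 0.05, 0.10, 0.25):
            rep, _ = report_interactions(calls, t)
            sets.append({(c.bait, c.prey) for c in rep})
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_bait_self_rows_are_excluded(self, small_experiment):
        _, obs, _ = small_experiment
        calls = MatchedControlModel(obs).fit().score_interactions()
        assert all(c.bait != c.prey for c in calls)


class TestReport:
    def test_expected_contamination_bound_arithmetic(self):
        assert expected_contamination_bound(234, 0.10) == 24
        assert expected_contamination_bound(10, 0.10) == 1
        assert expected_contamination_bound(0, 0.10) == 0

    def test_threshold_zero_reports_nothing(self):
        calls = [InteractionCall("B", "P", 10.0, 0.001, fdr=0.0)]
        reported, bound = report_interactions(calls, 0.0)
        assert reported == [] and bound == 0

    def test_counting_and_sort_order(self):
        calls = [
            InteractionCall("B2", f"P{i}", 10.0, 0.01, fdr=0.05) for i in range(4)
        ] + [
            InteractionCall("B1", f"P{i}", 10.0, 0.2, fdr=0.15) for i in range(6)
        ]
        reported, _ = report_interactions(calls, 0.10)
        assert len(reported) == 4
        assert [c.bait for c in reported] == ["B2"] * 4
        assert [c.prey for c in reported] == sorted(c.prey for c in reported)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            report_interactions([], 1.5)
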