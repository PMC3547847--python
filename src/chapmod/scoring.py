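"""Matched-control Bayesian scoring of bait–prey interactions.

The model
---------

AP-MS purifications pick up recurrent contaminants ("frequent flyers") in
addition to genuine partners of the bait.  Given a training set of matched
purification pairs — for each bait, one *control* run with bait expression
not induced and one *induced* run — the contaminant background of each
protein is learnable from the control runs, and an induced-run score can be
judged against it.

Per-protein identification scores S are modelled as log-normal.  On
x = log S we place a normal–inverse-gamma (NIG) conjugate prior

    sigma^2 ~ Inv-Gamma(alpha0, beta0),   mu | sigma^2 ~ N(m0, sigma^2/kappa0)

whose hyperparameters are set by empirical Bayes (method of moments over
per-protein control means and variances).  The posterior predictive for a
new control-run log-score of the protein is then a Student-t

    x_new | data ~ t_{2*alpha_n}( m_n, beta_n (kappa_n + 1) / (alpha_n kappa_n) )

and the p-value of an induced observation with score s is the predictive
tail P(S >= s) = T.sf(log s).  Proteins never seen in any control run are
served by a background model pooled over all control observations.

The p-value is the tail probability *conditional on detection*; this keeps
null p-values exactly uniform (for normal samples the predictive-tail
transform is the classical t statistic).  The per-protein control detection
rate is recorded on every model, and an optional multiplicative detection
weighting (p = detection_rate * tail) can be switched on for exploration;
it deflates null p-values by the detection rate and is off by default.

FDR via leave-one-out
---------------------

Control runs contain, by construction, only non-specific content.  For
each training pair i the models are refitted on the other n-1 pairs and
every prey of control run i is scored *as if induced*: the resulting
p-values are draws from the null.  For a threshold t,

    FDR(t) = (mean null discoveries per fold at p <= t) * n_induced_runs
             / (observed discoveries at p <= t)

clipped to [0, 1] and monotonized by a cumulative minimum over decreasing
t (q-value style).  Interactions with FDR below the reporting threshold
(default 10%) are called bait-specific; the report also carries the
expected-contamination bound ceil(n_reported * threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import PreyObservation

__all__ = [
    "ScoreModel",
    "InteractionCall",
    "TrainingSet",
    "MatchedControlModel",
    "MatchedControlResults",
    "report_interactions",
    "expected_contamination_bound",
    "empirical_fdr_curve",
]

logger = logging.getLogger(__name__)

_MIN_P = 1e-300  # p-values live in (0, 1]


@dataclass(frozen=True)
class ScoreModel:
    """Posterior predictive model of one protein's control-run log-scores.

    ``location``/``scale``/``df`` parameterize the Student-t posterior
    predictive on log score; ``pooled`` marks proteins whose posterior is
    dominated by the shared hyperprior (fewer control observations than
    the pooling threshold); ``detection_rate`` is the fraction of control
    runs in which the protein was seen.
    """

    protein: str
    n_control_obs: int
    location: float
    scale: float
    df: float
    pooled: bool
    detection_rate: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in [0, 1]")

    def tail_probability(self, score: float) -> float:
        """P(S_null >= score) under the posterior predictive."""
        if score <= 0:
            return 1.0
        p = stats.t.sf(math.log(score), self.df, loc=self.location, scale=self.scale)
        return float(min(1.0, max(_MIN_P, p)))


@dataclass(frozen=True)
class InteractionCall:
    """A bait–prey pair with its significance annotations."""

    bait: str
    prey: str
    score: float
    p_value: float
    fdr: float = float("nan")
    reported: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class TrainingSet:
    """Matched (control run, induced run) pairs sharing a bait.

    ``pairs`` maps each fold to its (control_run_id, induced_run_id,
    bait) triple; leave-one-out needs at least two pairs.
    """

    pairs: Tuple[Tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("leave-one-out training needs at least 2 matched pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def control_runs(self) -> List[str]:
        return [c for c, _, _ in self.pairs]

    @property
    def induced_runs(self) -> List[str]:
        return [i for _, i, _ in self.pairs]


@dataclass(frozen=True)
class _Hyperprior:
    m0: float
    kappa0: float
    alpha0: float
    beta0: float


def _empirical_bayes_hyperprior(logscores_by_protein: Dict[str, np.ndarray]) -> _Hyperprior:
    """Method-of-moments NIG hyperparameters from per-protein control data."""
    means = []
    variances = []
    for x in logscores_by_protein.values():
        if len(x) >= 1:
            means.append(float(np.mean(x)))
        if len(x) >= 2:
            variances.append(float(np.var(x, ddof=1)))
    m0 = float(np.mean(means)) if means else 0.0
    mean_var = float(np.mean(variances)) if variances else 1.0
    mean_var = max(mean_var, 1e-6)
    var_of_means = float(np.var(means, ddof=1)) if len(means) >= 2 else mean_var
    # prior Var(mu) = E[sigma^2]/kappa0 ~ between-protein spread of means
    n_bar = float(np.mean([len(x) for x in logscores_by_protein.values()])) if logscores_by_protein else 1.0
    between = max(var_of_means - mean_var / max(n_bar, 1.0), mean_var * 1e-3)
    kappa0 = mean_var / between
    # inverse-gamma moments for sigma^2: mean = beta/(alpha-1), var = mean^2/(alpha-2)
    var_of_vars = float(np.var(variances, ddof=1)) if len(variances) >= 2 else mean_var**2
    var_of_vars = max(var_of_vars, 1e-12)
    alpha0 = 2.0 + mean_var**2 / var_of_vars
    alpha0 = float(min(max(alpha0, 2.1), 50.0))
    beta0 = mean_var * (alpha0 - 1.0)
    return _Hyperprior(m0=m0, kappa0=float(kappa0), alpha0=alpha0, beta0=float(beta0))


def _nig_posterior_predictive(
    x: np.ndarray, prior: _Hyperprior
) -> Tuple[float, float, float]:
    """Student-t (location, scale, df) of the NIG posterior predictive."""
    n = len(x)
    if n == 0:
        kn, mn, an, bn = prior.kappa0, prior.m0, prior.alpha0, prior.beta0
    else:
        xbar = float(np.mean(x))
        ss = float(np.sum((x - xbar) ** 2))
        kn = prior.kappa0 + n
        mn = (prior.kappa0 * prior.m0 + n * xbar) / kn
        an = prior.alpha0 + n / 2.0
        bn = prior.beta0 + 0.5 * ss + prior.kappa0 * n * (xbar - prior.m0) ** 2 / (2.0 * kn)
    scale = math.sqrt(bn * (kn + 1.0) / (an * kn))
    return mn, scale, 2.0 * an


class MatchedControlModel:
    """Bayesian matched-control model of AP-MS identification scores.

    Built from per-run prey observations plus the pairing of control and
    induced runs; :meth:`fit` estimates the empirical-Bayes hyperprior and
    the per-protein posteriors and returns a :class:`MatchedControlResults`.

    Parameters
    ----------
    observations : list of PreyObservation
        All observations, control and induced runs together.
    training : TrainingSet, optional
        Explicit pairing.  If omitted, it is derived by matching the
        control and induced run of each bait.
    pooling_min_obs : int
        Proteins with fewer control observations than this are flagged
        ``pooled`` (posterior dominated by the hyperprior).
    """

    def __init__(
        self,
        observations: Sequence[PreyObservation],
        training: Optional[TrainingSet] = None,
        pooling_min_obs: int = 2,
    ) -> None:
        self.observations = list(observations)
        self.pooling_min_obs = int(pooling_min_obs)
        self.training = training if training is not None else self._derive_training()
        control_ids = set(self.training.control_runs)
        if not any(o.run_id in control_ids for o in self.observations):
            raise ValueError("training error: no observations in any control run")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MatchedControlModel":
        from .records import frame_to_observations

        return cls(frame_to_observations(df), **kwargs)

    def _derive_training(self) -> TrainingSet:
        by_bait: Dict[str, Dict[bool, str]] = {}
        for o in self.observations:
            by_bait.setdefault(o.bait, {})[o.induced] = o.run_id
        pairs = tuple(
            (runs[False], runs[True], bait)
            for bait, runs in sorted(by_bait.items())
            if False in runs and True in runs
        )
        return TrainingSet(pairs=pairs)

    # -- fitting -----------------------------------------------------------

    def fit(self, exclude_controls: Iterable[str] = ()) -> "MatchedControlResults":
        """Fit control-score models, optionally holding out control runs."""
        excluded = set(exclude_controls)
        control_ids = [c for c in self.training.control_runs if c not in excluded]
        if not control_ids:
            raise ValueError("training error: all control runs excluded")
        control_set = set(control_ids)
        logscores: Dict[str, List[float]] = {}
        for o in self.observations:
            if o.run_id in control_set and o.score > 0:
                logscores.setdefault(o.protein, []).append(math.log(o.score))
        if not logscores:
            raise ValueError("training error: control runs contain no observations")
        arrays = {p: np.asarray(v) for p, v in logscores.items()}
        prior = _empirical_bayes_hyperprior(arrays)
        n_controls = len(control_ids)
        models: Dict[str, ScoreModel] = {}
        for protein, x in arrays.items():
            loc, scale, df = _nig_posterior_predictive(x, prior)
            models[protein] = ScoreModel(
                protein=protein,
                n_control_obs=len(x),
                location=loc,
                scale=scale,
                df=df,
                pooled=len(x) < self.pooling_min_obs,
                detection_rate=len(x) / n_controls,
            )
        pooled_x = np.concatenate(list(arrays.values()))
        loc, scale, df = _nig_posterior_predictive(pooled_x, prior)
        background = ScoreModel(
            protein="__background__",
            n_control_obs=len(pooled_x),
            location=loc,
            scale=scale,
            df=df,
            pooled=True,
            detection_rate=0.0,
        )
        return MatchedControlResults(
            model=self,
            score_models=models,
            background=background,
            hyperprior=prior,
            n_control_runs=n_controls,
        )


class MatchedControlResults:
    """Fitted matched-control models plus scoring, LOO-FDR and reporting."""

    def __init__(
        self,
        model: MatchedControlModel,
        score_models: Dict[str, ScoreModel],
        background: ScoreModel,
        hyperprior: _Hyperprior,
        n_control_runs: int,
    ) -> None:
        self.model = model
        self.score_models = score_models
        self.background = background
        self.hyperprior = hyperprior
        self.n_control_runs = n_control_runs

    # -- p-values ----------------------------------------------------------

    def score_model_for(self, protein: str) -> ScoreModel:
        return self.score_models.get(protein, self.background)

    def interaction_pvalue(
        self, observation: PreyObservation, detection_weighting: bool = False
    ) -> float:
        """Posterior-predictive tail p-value of one induced observation."""
        m = self.score_model_for(observation.protein)
        p = m.tail_probability(observation.score)
        if detection_weighting and m is not self.background:
            k, n = m.n_control_obs, self.n_control_runs
            d = (k + 1.0) / (n + 2.0)
            p = d * p + (1.0 - d)
        return float(min(1.0, max(_MIN_P, p)))

    def score_interactions(
        self,
        induced: Optional[Sequence[PreyObservation]] = None,
        exclude_bait_self: bool = True,
        detection_weighting: bool = False,
    ) -> List[InteractionCall]:
        """p-values for every induced-run prey (bait self-rows dropped)."""
        if induced is None:
            induced_ids = set(self.model.training.induced_runs)
            induced = [o for o in self.model.observations if o.run_id in induced_ids]
        calls = []
        for o in induced:
            if exclude_bait_self and o.protein == o.bait:
                continue
            calls.append(
                InteractionCall(
                    bait=o.bait,
                    prey=o.protein,
                    score=o.score,
                    p_value=self.interaction_pvalue(o, detection_weighting),
                )
            )
        return calls

    # -- leave-one-out FDR -------------------------------------------------

    def loo_null_pvalues(self, detection_weighting: bool = False) -> Tuple[np.ndarray, int]:
        """Null p-values from scoring each left-out control run as induced.

        For fold i the models are refitted without control run i and the
        preys of control run i — known non-specific content — are scored.
        Returns the pooled null p-values and the number of usable folds.
        """
        null_ps: List[float] = []
        n_folds = 0
        for control_id, induced_id, bait in self.model.training.pairs:
            fold_obs = [o for o in self.model.observations if o.run_id == control_id]
            if not fold_obs:
                logger.warning("leave-one-out fold %s has empty control run; skipped", control_id)
                continue
            refit = self.model.fit(exclude_controls=[control_id])
            n_folds += 1
            for o in fold_obs:
                if o.protein == bait:
                    continue
                null_ps.append(refit.interaction_pvalue(o, detection_weighting))
        return np.asarray(null_ps), n_folds

    def loo_fdr(
        self,
        calls: Optional[Sequence[InteractionCall]] = None,
        threshold: float = 0.10,
        detection_weighting: bool = False,
    ) -> List[InteractionCall]:
        """Attach leave-one-out empirical FDR values to interaction calls.

        The per-fold null discovery rate is scaled to the number of induced
        runs scored, divided by the observed discovery count at each
        p-value, clipped to [0, 1] and made monotone by a cumulative
        minimum from large p to small p.
        """
        if calls is None:
            calls = self.score_interactions(detection_weighting=detection_weighting)
        calls = list(calls)
        if not calls:
            return []
        null_ps, n_folds = self.loo_null_pvalues(detection_weighting)
        if n_folds == 0:
            raise ValueError("no usable leave-one-out folds (all control runs empty)")
        n_induced = len({o.run_id for o in self.model.observations
                         if o.run_id in set(self.model.training.induced_runs)})
        n_induced = max(n_induced, 1)
        # ties in p break by higher score then prey id for a stable order
        order = sorted(
            range(len(calls)),
            key=lambda i: (calls[i].p_value, -calls[i].score, calls[i].prey, calls[i].bait),
        )
        p_sorted = np.array([calls[i].p_value for i in order])
        qvals = empirical_fdr_curve(p_sorted, null_ps, n_folds, n_induced)
        out: List[InteractionCall] = [None] * len(calls)  # type: ignore[list-item]
        for rank, idx in enumerate(order):
            q = float(qvals[rank])
            out[idx] = replace(calls[idx], fdr=q, reported=q < threshold)
        logger.info(
            "leave-one-out FDR: %d null p-values over %d folds, %d calls",
            len(null_ps), n_folds, len(calls),
        )
        return out

    def report(
        self, calls: Sequence[InteractionCall], threshold: float = 0.10
    ) -> Tuple[List[InteractionCall], int]:
        """Bait-specific interactions at the FDR threshold; see module docs."""
        return report_interactions(calls, threshold)

    def summary(self) -> str:
        """Plain-text summary of the fitted control models."""
        n_pooled = sum(m.pooled for m in self.score_models.values())
        lines = [
            "Matched-control score model",
            "===========================",
            f"training pairs:        {self.model.training.n_pairs}",
            f"control runs used:     {self.n_control_runs}",
            f"proteins modelled:     {len(self.score_models)}",
            f"pooled to hyperprior:  {n_pooled}",
            (
                "hyperprior (NIG):      "
                f"m0={self.hyperprior.m0:.3f} kappa0={self.hyperprior.kappa0:.3f} "
                f"alpha0={self.hyperprior.alpha0:.3f} beta0={self.hyperprior.beta0:.3f}"
            ),
        ]
        return "\n".join(lines)


def empirical_fdr_curve(
    p_sorted: np.ndarray,
    null_pvalues: np.ndarray,
    n_folds: int,
    n_induced_runs: int,
) -> np.ndarray:
    """Monotone empirical FDR values for ascending observed p-values.

    For each observed p-value t, the expected false-discovery count is the
    per-fold null discovery rate at t (with a +1 pseudo-discovery, the
    usual finite-null-sample guard of permutation-style estimates) scaled
    to the number of induced runs scored; FDR(t) divides by the observed
    discovery count, clips to [0, 1] and monotonizes by cumulative minimum
    from large t downwards.
    """
    p_sorted = np.asarray(p_sorted, dtype=float)
    if np.any(np.diff(p_sorted) < 0):
        raise ValueError("p_sorted must be ascending")
    null_sorted = np.sort(np.asarray(null_pvalues, dtype=float))
    null_count = np.searchsorted(null_sorted, p_sorted, side="right")
    obs_count = np.arange(1, len(p_sorted) + 1)
    raw = np.clip((null_count + 1.0) / n_folds * n_induced_runs / obs_count, 0.0, 1.0)
    return np.minimum.accumulate(raw[::-1])[::-1]


def expected_contamination_bound(n_reported: int, threshold: float) -> int:
    """Upper bound on contaminant calls among the reported set: ceil(n * t)."""
    return int(math.ceil(n_reported * threshold))


def report_interactions(
    calls: Sequence[InteractionCall], threshold: float = 0.10
) -> Tuple[List[InteractionCall], int]:
    """Select calls with FDR below the threshold.

    Returns the reported calls sorted by (bait, fdr, prey) together with
    the expected-contamination bound ceil(n_reported * threshold).
    """
    if not 0.0 < threshold < 1.0 and threshold != 0.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    reported = [c for c in calls if not math.isnan(c.fdr) and c.fdr < threshold]
    reported.sort(key=lambda c: (c.bait, c.fdr, c.prey))
    reported = [replace(c, reported=True) for c in reported]
    return reported, expected_contamination_bound(len(reported), threshold)
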