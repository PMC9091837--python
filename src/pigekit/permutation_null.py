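"""Vial-randomization null for variance-component significance.

Variance components are bounded below by zero, so their posteriors cannot be
compared against zero directly.  The study's decision rule instead refits the
same model K times on data where the group label of every vial has been
randomly reassigned (a permutation of the existing label multiset across
vials, within block when stratified), and accepts the observed variance as
significant when it is strictly larger than at least 95% of the K null
estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .vc_inference import BayesLMM, MCMCConfig, ModelSpec, group_variance_per_draw

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "DataIntegrityError",
    "permute_vials",
    "null_distribution",
    "VialPermutationTest",
]

log = logging.getLogger(__name__)


class DataIntegrityError(ValueError):
    """A vial maps to more than one group (or block)."""


@dataclass(frozen=True)
class PermutationPlan:
    """How to randomize: K refits, whole vials reassigned, optional blocking."""

    K: int = 100
    unit: str = "vial_id"
    group: str = "group"
    stratify_by_block: bool = False
    threshold: float = 0.95
    seed: int | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class PermutationResult:
    """Observed statistic vs its vial-randomization null distribution.

    ``significant`` follows the strict rule: the observed value must exceed
    at least ceil(threshold * K) of the K null values (ties count against).
    """

    observed: float
    null_stats: np.ndarray = field(repr=False)
    threshold: float = 0.95
    n_retried: int = 0

    @property
    def K(self) -> int:
        return len(self.null_stats)

    @property
    def exceedance_count(self) -> int:
        return int(np.sum(self.observed > self.null_stats))

    @property
    def significant(self) -> bool:
        return self.exceedance_count >= ceil(self.threshold * self.K)

    def as_dict(self) -> dict:
        return {
            "observed": float(self.observed),
            "K": self.K,
            "threshold": self.threshold,
            "exceedance_count": self.exceedance_count,
            "significant": bool(self.significant),
            "n_retried": self.n_retried,
        }


def _vial_table(data: pd.DataFrame, plan: PermutationPlan) -> pd.DataFrame:
    vt = data.groupby(plan.unit, sort=True).agg(
        group=(plan.group, "first"),
        n_groups=(plan.group, "nunique"),
        block=("block", "first") if "block" in data.columns else (plan.group, "size"),
        n_blocks=("block", "nunique") if "block" in data.columns else (plan.group, "size"),
    )
    if (vt["n_groups"] > 1).any():
        bad = vt.index[vt["n_groups"] > 1].tolist()
        raise DataIntegrityError(f"vial(s) spanning two groups: {bad[:5]}")
    if plan.stratify_by_block and "block" in data.columns and (vt["n_blocks"] > 1).any():
        bad = vt.index[vt["n_blocks"] > 1].tolist()
        raise DataIntegrityError(f"vial(s) spanning two blocks: {bad[:5]}")
    return vt


def permute_vials(data: pd.DataFrame, plan: PermutationPlan, rep: int) -> pd.DataFrame:
    """Reassign group labels across whole vials; deterministic under (seed, rep).

    The label multiset is permuted, so per-group vial counts, vial membership
    and row order are unchanged; only the group column differs.  With
    ``stratify_by_block`` the shuffle happens within each block.
    """
    vt = _vial_table(data, plan)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed or 0, int(rep)]))
    new_label = {}
    if plan.stratify_by_block:
        for _, sub in vt.groupby("block", sort=True):
            labels = sub["group"].to_numpy().copy()
            rng.shuffle(labels)
            new_label.update(dict(zip(sub.index, labels)))
    else:
        labels = vt["group"].to_numpy().copy()
        rng.shuffle(labels)
        new_label.update(dict(zip(vt.index, labels)))
    out = data.copy()
    out[plan.group] = data[plan.unit].map(new_label).to_numpy()
    return out


class VialPermutationTest(BaseEstimator):
    """Significance of a group variance component via vial randomization.

    Fits the model once on the observed data, then ``K`` times on
    vial-permuted data, comparing posterior means of the per-draw group
    variance.  Null refits may use a reduced MCMC budget (``null_chains`` /
    ``null_iterations`` / ``null_warmup``) since only point estimates enter
    the comparison; refits whose chains disagree badly are retried with a
    fresh sub-seed a bounded number of times.

    Fitted attributes: ``result_`` (:class:`PermutationResult`),
    ``observed_``, ``null_stats_``, ``significant_``.
    """

    def __init__(
        self,
        model_id="M1",
        factor: str = "group",
        subset: str | None = None,
        K: int = 100,
        threshold: float = 0.95,
        stratify_by_block: bool = False,
        seed: int | None = None,
        chains: int = 4,
        iterations: int = 4000,
        warmup: int = 1000,
        null_chains: int = 2,
        null_iterations: int = 600,
        null_warmup: int = 200,
        max_retries: int = 2,
        rhat_retry: float = 1.2,
    ):
        self.model_id = model_id
        self.factor = factor
        self.subset = subset
        self.K = K
        self.threshold = threshold
        self.stratify_by_block = stratify_by_block
        self.seed = seed
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.null_chains = null_chains
        self.null_iterations = null_iterations
        self.null_warmup = null_warmup
        self.max_retries = max_retries
        self.rhat_retry = rhat_retry

    def _statistic(self, data: pd.DataFrame, reduced: bool, seed, compute_rhat: bool) -> float:
        est = BayesLMM(
            model_id=self.model_id,
            chains=self.null_chains if reduced else self.chains,
            iterations=self.null_iterations if reduced else self.iterations,
            warmup=self.null_warmup if reduced else self.warmup,
            seed=seed,
            compute_rhat=compute_rhat,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(data)
        if compute_rhat and est.rhat_ and max(est.rhat_.values()) > self.rhat_retry:
            raise _ConvergenceRetry(max(est.rhat_.values()))
        at = {"clone_type": self.subset} if self.subset is not None else None
        return float(group_variance_per_draw(est.draws_, self.factor, subset=at).mean())

    def fit(self, X: pd.DataFrame, y=None) -> "VialPermutationTest":
        data = X
        plan = PermutationPlan(
            K=self.K, group=self.factor if self.factor in data.columns else "group",
            stratify_by_block=self.stratify_by_block, threshold=self.threshold, seed=self.seed,
        )
        _vial_table(data, plan)  # fail fast on integrity problems
        ss = np.random.SeedSequence(self.seed)
        seeds = ss.generate_state(self.K + 1)
        self.observed_ = self._statistic(data, reduced=False, seed=int(seeds[0]) % 2**31,
                                         compute_rhat=False)
        n_retried = 0
        null_stats = np.empty(self.K)
        for r in range(self.K):
            permuted = permute_vials(data, plan, rep=r)
            sub_seed = int(seeds[r + 1]) % 2**31
            for attempt in range(self.max_retries + 1):
                try:
                    null_stats[r] = self._statistic(
                        permuted, reduced=True, seed=sub_seed + attempt + 1,
                        compute_rhat=attempt < self.max_retries and self.rhat_retry < np.inf,
                    )
                    break
                except _ConvergenceRetry as e:
                    n_retried += 1
                    log.warning("null refit %d not converged (rhat=%.3f); retrying", r, e.rhat)
        self.null_stats_ = null_stats
        self.result_ = PermutationResult(
            observed=self.observed_, null_stats=null_stats,
            threshold=self.threshold, n_retried=n_retried,
        )
        self.significant_ = self.result_.significant
        return self


class _ConvergenceRetry(Exception):
    def __init__(self, rhat):
        self.rhat = rhat


def null_distribution(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    plan: PermutationPlan,
    mcmc: MCMCConfig | None = None,
    factor: str = "group",
    subset: str | None = None,
    null_mcmc: MCMCConfig | None = None,
) -> PermutationResult:
    """Run the full randomization test; thin wrapper over VialPermutationTest."""
    spec = ModelSpec.from_id(spec) if isinstance(spec, str) else spec
    mcmc = mcmc or MCMCConfig()
    null_mcmc = null_mcmc or MCMCConfig(chains=2, iterations=600, warmup=200)
    est = VialPermutationTest(
        model_id=spec, factor=factor, subset=subset, K=plan.K, threshold=plan.threshold,
        stratify_by_block=plan.stratify_by_block, seed=plan.seed,
        chains=mcmc.chains, iterations=mcmc.iterations, warmup=mcmc.warmup,
        null_chains=null_mcmc.chains, null_iterations=null_mcmc.iterations,
        null_warmup=null_mcmc.warmup,
    )
    return est.fit(data).result_
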