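"""Bayesian variance-component inference for hemiclone lifespan data.

Three linear mixed models cover the study's assays (names follow the
dataset's canonical columns; ``group`` holds the population or DGRP line):

* **M1** ``lifespan ~ group + (1|vial_id)`` — among-population fit, run
  separately per clone type; the among-population variance (V_G(D+I) from
  PTGE-clones, V_G(I) from PIGE-clones) is the per-draw variance of the four
  population means.
* **M2** ``lifespan ~ group * clone_type + (1|vial_id)`` — joint fit used to
  compare V_G(I) with V_G(D+I) and to estimate the clone-type mean
  difference.
* **M3** ``lifespan ~ (1|group) + block + (1|vial_id)`` — within-population
  fit over the 38 DGRP lines; V_G(I) is the per-draw variance of the
  realized line effects.

Fits use a blocked conjugate Gibbs sampler (see :mod:`pigekit._gibbs`) with
weakly-informative autoscaled priors: normal(0, 10·sd(y)) on the intercept,
normal(0, 2.5·sd(y)/sd(x_j)) on coefficients, half-Cauchy(sd(y)) on every sd
component.  The response is centred internally, so priors act on the centred
scale and the group-variance statistic is exactly location-invariant;
intercept draws are reported back on the original scale.

Variance components are the paper-style per-draw statistics: ``var()`` (with
denominator k−1) across level means at each retained draw, and the residual
variance as the per-draw squared residual sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _gibbs

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "VCResult",
    "ConfoundingError",
    "BayesLMM",
    "fit_lmm",
    "group_variance_per_draw",
    "residual_variance",
    "summarize",
]


class ConfoundingError(ValueError):
    """The fixed-effect design is unidentifiable (singular)."""


@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter the mean structure and the random structure."""

    response: str = "lifespan_days"
    fixed: tuple = ("group",)
    interaction: bool = False
    random: tuple = ("vial_id",)
    model_id: str = "M1"

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        model_id = model_id.upper()
        if model_id == "M1":
            return cls(fixed=("group",), interaction=False, random=("vial_id",), model_id="M1")
        if model_id == "M2":
            return cls(
                fixed=("group", "clone_type"), interaction=True, random=("vial_id",), model_id="M2"
            )
        if model_id == "M3":
            return cls(fixed=("block",), interaction=False, random=("group", "vial_id"), model_id="M3")
        raise ValueError(f"unknown model id {model_id!r}; expected M1, M2 or M3")

    def formula(self) -> str:
        fx = " * ".join(self.fixed) if self.interaction else " + ".join(self.fixed)
        rnd = " + ".join(f"(1|{r})" for r in self.random)
        parts = [p for p in (fx, rnd) if p]
        return f"{self.response} ~ " + " + ".join(parts) if parts else f"{self.response} ~ 1"


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults mirror the study's published configuration.

    ``target_acceptance`` is kept for interface parity with Hamiltonian
    backends; the conjugate Gibbs backend has no step-size adaptation and
    ignores it.  With autoscaling on, prior sds are multiplied by sd(y)
    (intercept and scale components) and sd(y)/sd(x_j) (coefficients).
    """

    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    target_acceptance: float = 0.99
    seed: int | None = None
    prior_intercept_sd: float = 10.0
    prior_coef_sd: float = 2.5
    prior_scale: float = 1.0
    autoscale: bool = True

    def __post_init__(self):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclass
class VCResult:
    """Posterior summary of one variance component or derived quantity."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "mean": float(self.mean),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
        }


@dataclass
class PosteriorDraws:
    """Retained draws of an LMM fit, flattened across chains.

    ``beta`` has the intercept in column 0 followed by treatment-coded
    coefficients named in ``coef_names``; ``random`` maps each random factor
    to its realized level effects; ``scales`` holds the sd hyperparameters
    (``sd_<factor>``) and the residual sd (``sigma``).
    """

    spec: ModelSpec
    mcmc: MCMCConfig
    coef_names: list
    beta: np.ndarray
    fixed_levels: dict
    random: dict
    random_levels: dict
    scales: dict
    chain_id: np.ndarray
    iter_id: np.ndarray
    rhat: dict

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    # -- persistence ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"chain": self.chain_id, "iteration": self.iter_id}
        for j, name in enumerate(self.coef_names):
            cols[name] = self.beta[:, j]
        for factor, u in self.random.items():
            for j, lev in enumerate(self.random_levels[factor]):
                cols[f"u_{factor}[{lev}]"] = u[:, j]
        for name, v in self.scales.items():
            cols[name] = v
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")

    # -- level means ---------------------------------------------------------

    def _coef(self, name: str) -> np.ndarray:
        try:
            j = self.coef_names.index(name)
        except ValueError:
            return np.zeros(self.n_draws)
        return self.beta[:, j]

    def level_means(self, factor: str, at: dict | None = None) -> tuple:
        """Per-draw means for every level of ``factor``.

        For a fixed factor, the mean is intercept + coefficient(s), holding
        any other fixed factor at the level given in ``at`` (required when an
        interaction involves ``factor``).  For a random factor, the means are
        intercept + realized level effects.  Returns (array of shape
        (n_draws, k), list of level names).
        """
        at = dict(at or {})
        intercept = self._coef("(Intercept)")
        if factor in self.random:
            u = self.random[factor]
            return intercept[:, None] + u, list(self.random_levels[factor])
        if factor not in self.fixed_levels:
            raise KeyError(f"unknown factor {factor!r}")
        others = [f for f in self.spec.fixed if f != factor]
        if self.spec.interaction and others and not all(o in at for o in others):
            raise ValueError(
                f"model {self.spec.model_id} has an interaction; "
                f"specify the level of {others} via `at` (the clone-type subset)"
            )
        levels = self.fixed_levels[factor]
        k = len(levels)
        means = np.tile(intercept[:, None], (1, k))
        for j, lev in enumerate(levels):
            means[:, j] += self._coef(f"{factor}[{lev}]")
            for o in others:
                if o in at:
                    means[:, j] += self._coef(f"{o}[{at[o]}]")
                    if self.spec.interaction:
                        means[:, j] += self._interaction_coef(factor, lev, o, at[o])
        return means, list(levels)

    def _interaction_coef(self, f1, l1, f2, l2) -> np.ndarray:
        order = {f: i for i, f in enumerate(self.spec.fixed)}
        if order.get(f1, 0) > order.get(f2, 0):
            f1, l1, f2, l2 = f2, l2, f1, l1
        return self._coef(f"{f1}[{l1}]:{f2}[{l2}]")


def _design_matrix(data: pd.DataFrame, spec: ModelSpec):
    """Treatment-coded fixed-effect design matrix with intercept."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    fixed_levels = {}
    dummies = {}
    for f in spec.fixed:
        if f not in data.columns:
            raise KeyError(f"data has no column {f!r}")
        levels = sorted(data[f].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"fixed factor {f!r} needs >= 2 levels, found {levels}")
        fixed_levels[f] = levels
        vals = data[f].astype(str).to_numpy()
        for lev in levels[1:]:
            d = (vals == lev).astype(float)
            cols.append(d)
            names.append(f"{f}[{lev}]")
            dummies[(f, lev)] = d
    if spec.interaction and len(spec.fixed) >= 2:
        f1, f2 = spec.fixed[0], spec.fixed[1]
        for l1 in fixed_levels[f1][1:]:
            for l2 in fixed_levels[f2][1:]:
                cols.append(dummies[(f1, l1)] * dummies[(f2, l2)])
                names.append(f"{f1}[{l1}]:{f2}[{l2}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        raise ConfoundingError(
            "fixed-effect design is singular; a factor is confounded with another term"
        )
    return X, names, fixed_levels


def _rhat(groups: dict) -> dict:
    """Split-R-hat per scalar parameter block via arviz."""
    import arviz as az

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in groups.items():
            r = az.rhat(az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr))
            out[name] = float(np.nanmax(np.asarray(r.to_array())))
    return out


class BayesLMM(BaseEstimator):
    """Bayesian Gaussian LMM with per-draw variance-component statistics.

    scikit-learn style estimator: configure in ``__init__``, call
    :meth:`fit` with a lifespan DataFrame, then read fitted attributes
    (``draws_``, ``rhat_``) or call :meth:`group_variance` /
    :meth:`residual_variance`.

    Parameters
    ----------
    model_id : {"M1", "M2", "M3"} or ModelSpec
        Which of the study's models to fit (see module docstring).
    chains, iterations, warmup, seed : sampler budget and reproducibility.
    prior_intercept_sd, prior_coef_sd, prior_scale, autoscale :
        prior settings, autoscaled by sd(y) when ``autoscale`` is true.
    compute_rhat : attach split-R-hat diagnostics after sampling (skipped
        for throwaway refits inside permutation nulls).
    """

    def __init__(
        self,
        model_id="M1",
        chains: int = 4,
        iterations: int = 4000,
        warmup: int = 1000,
        seed: int | None = None,
        target_acceptance: float = 0.99,
        prior_intercept_sd: float = 10.0,
        prior_coef_sd: float = 2.5,
        prior_scale: float = 1.0,
        autoscale: bool = True,
        compute_rhat: bool = True,
        rhat_warn: float = 1.01,
    ):
        self.model_id = model_id
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.seed = seed
        self.target_acceptance = target_acceptance
        self.prior_intercept_sd = prior_intercept_sd
        self.prior_coef_sd = prior_coef_sd
        self.prior_scale = prior_scale
        self.autoscale = autoscale
        self.compute_rhat = compute_rhat
        self.rhat_warn = rhat_warn

    # ------------------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return self.model_id if isinstance(self.model_id, ModelSpec) else ModelSpec.from_id(self.model_id)

    def _mcmc(self) -> MCMCConfig:
        return MCMCConfig(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            target_acceptance=self.target_acceptance,
            seed=self.seed,
            prior_intercept_sd=self.prior_intercept_sd,
            prior_coef_sd=self.prior_coef_sd,
            prior_scale=self.prior_scale,
            autoscale=self.autoscale,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "BayesLMM":
        """Fit the model to a lifespan dataset (``y`` is ignored; sklearn API)."""
        data = X
        spec = self._spec()
        mcmc = self._mcmc()
        if spec.response not in data.columns:
            raise KeyError(f"data has no response column {spec.response!r}")
        yv = data[spec.response].to_numpy(dtype=float)
        if len(yv) < 3:
            raise ValueError("need at least 3 observations")

        Xm, coef_names, fixed_levels = _design_matrix(data, spec)
        codes, n_levels, random_levels = [], [], {}
        for r in spec.random:
            if r not in data.columns:
                raise KeyError(f"data has no column {r!r}")
            c, uniq = pd.factorize(data[r].astype(str), sort=True)
            if len(uniq) < 2:
                raise ValueError(f"random factor {r!r} needs >= 2 levels")
            codes.append(c.astype(np.int64))
            n_levels.append(len(uniq))
            random_levels[r] = list(uniq)

        ybar = float(yv.mean())
        yc = yv - ybar
        sd_y = float(yv.std(ddof=1)) if len(yv) > 1 else 1.0
        sd_y = sd_y if sd_y > 0 else 1.0

        prior_sd = np.empty(Xm.shape[1])
        prior_sd[0] = mcmc.prior_intercept_sd * (sd_y if mcmc.autoscale else 1.0)
        for j in range(1, Xm.shape[1]):
            sx = float(Xm[:, j].std(ddof=1))
            if sx == 0:
                raise ConfoundingError(f"constant predictor column {coef_names[j]!r}")
            prior_sd[j] = mcmc.prior_coef_sd * ((sd_y / sx) if mcmc.autoscale else 1.0)
        scale_A = mcmc.prior_scale * (sd_y if mcmc.autoscale else 1.0)

        raw = _gibbs.run_gibbs(
            yc, Xm, codes, n_levels, prior_sd, scale_A,
            chains=mcmc.chains, iterations=mcmc.iterations, warmup=mcmc.warmup, seed=mcmc.seed,
        )

        rhat = {}
        if self.compute_rhat:
            diag = {"beta": raw["beta"], "sigma": raw["sigma"]}
            for f in range(len(spec.random)):
                diag[f"sd_{spec.random[f]}"] = raw[f"tau:{f}"]
            rhat = _rhat(diag)
            worst = max(rhat.values())
            if worst > self.rhat_warn:
                warnings.warn(
                    f"potential scale reduction factor {worst:.3f} exceeds {self.rhat_warn}; "
                    "chains may not have converged",
                    RuntimeWarning,
                    stacklevel=2,
                )

        n_keep = mcmc.iterations - mcmc.warmup
        beta = raw["beta"].reshape(-1, Xm.shape[1]).copy()
        beta[:, 0] += ybar  # back to the original response scale
        chain_id = np.repeat(np.arange(mcmc.chains), n_keep)
        iter_id = np.tile(np.arange(n_keep), mcmc.chains)
        random = {r: raw[f"u:{f}"].reshape(-1, n_levels[f]) for f, r in enumerate(spec.random)}
        scales = {f"sd_{r}": raw[f"tau:{f}"].reshape(-1) for f, r in enumerate(spec.random)}
        scales["sigma"] = raw["sigma"].reshape(-1)

        self.draws_ = PosteriorDraws(
            spec=spec, mcmc=mcmc, coef_names=coef_names, beta=beta,
            fixed_levels=fixed_levels, random=random, random_levels=random_levels,
            scales=scales, chain_id=chain_id, iter_id=iter_id, rhat=rhat,
        )
        self.rhat_ = rhat
        self.n_draws_ = self.draws_.n_draws
        return self

    # ------------------------------------------------------------------

    def group_variance(self, factor: str, subset: str | None = None) -> np.ndarray:
        """Per-draw variance (ddof=1) across the level means of ``factor``."""
        at = {"clone_type": subset} if subset is not None else None
        return group_variance_per_draw(self.draws_, factor, subset=at)

    def residual_variance(self) -> np.ndarray:
        return residual_variance(self.draws_)


# ---------------------------------------------------------------------------
# spec-level operations (thin wrappers)
# ---------------------------------------------------------------------------


def fit_lmm(data: pd.DataFrame, spec: ModelSpec | str, mcmc: MCMCConfig | None = None) -> PosteriorDraws:
    """Fit a model and return its posterior draws."""
    spec = ModelSpec.from_id(spec) if isinstance(spec, str) else spec
    mcmc = mcmc or MCMCConfig()
    est = BayesLMM(
        model_id=spec, chains=mcmc.chains, iterations=mcmc.iterations, warmup=mcmc.warmup,
        seed=mcmc.seed, target_acceptance=mcmc.target_acceptance,
        prior_intercept_sd=mcmc.prior_intercept_sd, prior_coef_sd=mcmc.prior_coef_sd,
        prior_scale=mcmc.prior_scale, autoscale=mcmc.autoscale,
    )
    return est.fit(data).draws_


def group_variance_per_draw(
    draws: PosteriorDraws, factor: str, subset: dict | str | None = None
) -> np.ndarray:
    """The paper-style statistic: var() across level means at each draw.

    ``subset`` fixes the level of the other fixed factor(s) in an interaction
    model — for M2, ``{"clone_type": "PTGE_clone"}`` yields the V_G(D+I)
    posterior and ``{"clone_type": "PIGE_clone"}`` the V_G(I) posterior.
    """
    if isinstance(subset, str):
        subset = {"clone_type": subset}
    means, levels = draws.level_means(factor, at=subset)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    return means.var(axis=1, ddof=1)


def residual_variance(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw residual variance (squared residual sd, the Sigma posterior)."""
    return draws.scales["sigma"] ** 2


def summarize(draws_vec: np.ndarray, name: str = "") -> VCResult:
    """Posterior mean and 95% equal-tailed credible interval."""
    v = np.asarray(draws_vec, float)
    if v.size == 0:
        raise ValueError("empty posterior vector")
    lo, hi = np.quantile(v, [0.025, 0.975])
    return VCResult(name=name, mean=float(v.mean()), ci_low=float(lo), ci_high=float(hi), draws=v)
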