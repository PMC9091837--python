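"""Blocked conjugate Gibbs sampler for the Gaussian linear mixed model.

Model:  y = X beta + sum_f Z_f u_f + eps,   u_f ~ N(0, tau_f^2 I),
        eps ~ N(0, sigma^2 I),

with independent normal priors on the fixed effects and half-Cauchy priors on
every scale (tau_f, sigma), the latter made conjugate through the standard
inverse-gamma auxiliary-variable representation: sigma^2 ~ IG(1/2, 1/a),
a ~ IG(1/2, 1/A^2) implies sigma ~ half-Cauchy(A).

All full conditionals depend on the data only through per-cell sufficient
statistics (a cell = a unique combination of fixed-design row and random-factor
levels; in nested designs, a vial), so one sweep costs O(#cells) regardless of
the number of individuals.  This is what makes hundred-fold permutation refits
cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GibbsResult", "run_gibbs"]


class GibbsResult(dict):
    """Posterior draws keyed by parameter block.

    Arrays are shaped (chains, draws_per_chain, ...): ``beta`` (.., p),
    ``u:<factor>`` (.., q_f), ``tau:<factor>`` and ``sigma`` (chains, draws).
    """


def _collapse(y, X, codes):
    """Aggregate rows into cells with identical (X row, random levels)."""
    n = y.shape[0]
    key_cols = [np.ascontiguousarray(c, dtype=float) for c in codes]
    combo = np.column_stack(key_cols + [X]) if key_cols else np.ascontiguousarray(X)
    uniq, cell_of_row = np.unique(combo, axis=0, return_inverse=True)
    cell_of_row = cell_of_row.ravel()
    n_cells = uniq.shape[0]
    n_c = np.bincount(cell_of_row, minlength=n_cells).astype(float)
    sum_c = np.bincount(cell_of_row, weights=y, minlength=n_cells)
    sumsq_c = np.bincount(cell_of_row, weights=y * y, minlength=n_cells)
    # representative row index per cell (X and codes are constant within a cell)
    first_idx = np.zeros(n_cells, dtype=np.int64)
    first_idx[cell_of_row[::-1]] = np.arange(n - 1, -1, -1)
    X_c = X[first_idx]
    codes_c = [c[first_idx].astype(np.int64) for c in codes]
    return n_c, sum_c, sumsq_c, X_c, codes_c


def _invgamma(rng, shape, rate):
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def run_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    codes: list,
    n_levels: list,
    prior_beta_sd: np.ndarray,
    scale_A: float,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 1000,
    seed: int | None = None,
) -> GibbsResult:
    """Sample the LMM posterior; see module docstring for the model.

    ``codes`` holds one integer level-code array per random factor (length-n
    each); ``n_levels`` the corresponding level counts.  ``prior_beta_sd`` is
    the per-coefficient prior standard deviation (already autoscaled by the
    caller); ``scale_A`` the common half-Cauchy scale for sd components.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    n_keep = iterations - warmup
    n_factors = len(codes)

    n_c, sum_c, sumsq_c, X_c, codes_c = _collapse(y, X, codes)
    sumsq_total = sumsq_c.sum()
    XtX = (X_c * n_c[:, None]).T @ X_c
    prior_prec = 1.0 / np.asarray(prior_beta_sd, float) ** 2

    # OLS-ish start shared across chains (jittered per chain below)
    beta0 = np.linalg.solve(XtX + np.diag(prior_prec + 1e-8), X_c.T @ sum_c)
    var_y = max(float(np.var(y, ddof=1)) if n > 1 else 1.0, 1e-12)

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)

    out = GibbsResult()
    out["beta"] = np.empty((chains, n_keep, p))
    for f in range(n_factors):
        out[f"u:{f}"] = np.empty((chains, n_keep, n_levels[f]))
        out[f"tau:{f}"] = np.empty((chains, n_keep))
    out["sigma"] = np.empty((chains, n_keep))

    for ch in range(chains):
        rng = np.random.default_rng(child[ch])
        beta = beta0 + rng.normal(scale=0.1 * np.sqrt(var_y), size=p)
        u = [np.zeros(q) for q in n_levels]
        sigma2 = var_y * rng.uniform(0.5, 1.5)
        tau2 = [var_y * rng.uniform(0.05, 0.5) for _ in range(n_factors)]
        a_sig = 1.0
        a_tau = [1.0] * n_factors

        m_u = np.zeros(len(n_c))
        for f in range(n_factors):
            m_u += u[f][codes_c[f]]

        for it in range(iterations):
            # --- fixed effects ---
            A = XtX / sigma2 + np.diag(prior_prec)
            b = X_c.T @ (sum_c - n_c * m_u) / sigma2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            xb = X_c @ beta

            # --- random effects + their scales ---
            for f in range(n_factors):
                cf = codes_c[f]
                m_other = xb + m_u - u[f][cf]
                s_l = np.bincount(cf, weights=sum_c - n_c * m_other, minlength=n_levels[f])
                n_l = np.bincount(cf, weights=n_c, minlength=n_levels[f])
                prec = n_l / sigma2 + 1.0 / tau2[f]
                u[f] = s_l / sigma2 / prec + rng.standard_normal(n_levels[f]) / np.sqrt(prec)
                m_u = m_other + u[f][cf] - xb
                ssq = float(u[f] @ u[f])
                tau2[f] = max(_invgamma(rng, (n_levels[f] + 1) / 2.0, 1.0 / a_tau[f] + ssq / 2.0), 1e-300)
                a_tau[f] = _invgamma(rng, 1.0, 1.0 / scale_A**2 + 1.0 / tau2[f])

            # --- residual scale ---
            m = xb + m_u
            rss = float(sumsq_total - 2.0 * (m @ sum_c) + (n_c * m) @ m)
            sigma2 = max(_invgamma(rng, (n + 1) / 2.0, 1.0 / a_sig + max(rss, 0.0) / 2.0), 1e-300)
            a_sig = _invgamma(rng, 1.0, 1.0 / scale_A**2 + 1.0 / sigma2)

            if it >= warmup:
                k = it - warmup
                out["beta"][ch, k] = beta
                for f in range(n_factors):
                    out[f"u:{f}"][ch, k] = u[f]
                    out[f"tau:{f}"][ch, k] = np.sqrt(tau2[f])
                out["sigma"][ch, k] = np.sqrt(sigma2)

    return out
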