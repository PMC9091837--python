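"""Headline derived quantities of the PIGE analysis.

* the fraction of total paternal genetic variance explained by indirect
  effects, V_G(I) / V_G(D+I), computed per posterior draw;
* its haploid-to-diploid correction: sires transmit one haploid autosome set
  (direct effects) but their whole diploid genome can act indirectly, and
  autosomes are ~80% of the genome, so V_G(I) is scaled by f = 1 + a = 1.8
  before recomputing the fraction
  f·V_G(I) / ([V_G(D+I) − V_G(I)] + f·V_G(I));
* the PIGE-minus-PTGE clone-type mean lifespan difference;
* empirical survival curves per group from the death-check tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vc_inference import PosteriorDraws, summarize

__all__ = [
    "DerivedResult",
    "diploid_multiplier",
    "pige_fraction",
    "corrected_fraction",
    "clone_mean_difference",
    "empirical_survival",
    "plot_survival",
]

log = logging.getLogger(__name__)

#: Autosomal fraction of the D. melanogaster genome.
DEFAULT_AUTOSOMAL_FRACTION = 0.8


@dataclass
class DerivedResult:
    """Posterior summary of a derived quantity.

    ``mean`` is the mean of per-draw values; ``point_estimate`` applies the
    same formula to the posterior means of the inputs instead (the two can
    differ; both are reported for transparency).  Fractions are on the raw
    ratio scale (multiply by 100 for percent).
    """

    name: str
    mean: float
    ci_low: float
    ci_high: float
    point_estimate: float
    draws: np.ndarray = field(repr=False)
    n_excluded: int = 0

    def as_dict(self, percent: bool = False) -> dict:
        s = 100.0 if percent else 1.0
        return {
            "name": self.name,
            "mean": float(self.mean) * s,
            "ci_low": float(self.ci_low) * s,
            "ci_high": float(self.ci_high) * s,
            "point_estimate": float(self.point_estimate) * s,
            "n_excluded": self.n_excluded,
        }


def diploid_multiplier(a: float = DEFAULT_AUTOSOMAL_FRACTION) -> float:
    """Haploid-to-diploid correction multiplier f = 1 + a (1.8 at a = 0.8)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("autosomal fraction must be in [0, 1]")
    return 1.0 + a


def _paired(vi, vdi):
    vi = np.atleast_1d(np.asarray(vi, float))
    vdi = np.atleast_1d(np.asarray(vdi, float))
    if vi.shape != vdi.shape:
        raise ValueError("V_G(I) and V_G(D+I) draws must be paired (equal length)")
    return vi, vdi


def pige_fraction(vi_draws, vdi_draws) -> DerivedResult:
    """Per-draw ratio V_G(I) / V_G(D+I); draws with V_G(D+I) <= 0 excluded."""
    vi, vdi = _paired(vi_draws, vdi_draws)
    keep = vdi > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.warning("pige_fraction: excluded %d draws with V_G(D+I) <= 0", n_excluded)
    if not keep.any():
        raise ValueError("no draws with positive V_G(D+I)")
    ratio = vi[keep] / vdi[keep]
    s = summarize(ratio)
    point = float(vi[keep].mean() / vdi[keep].mean())
    return DerivedResult("pige_fraction", s.mean, s.ci_low, s.ci_high, point, ratio, n_excluded)


def corrected_fraction(vi_draws, vdi_draws, a: float = DEFAULT_AUTOSOMAL_FRACTION) -> DerivedResult:
    """Diploid-corrected fraction f·VI / ([VDI − VI] + f·VI) with f = 1 + a."""
    f = diploid_multiplier(a)
    vi, vdi = _paired(vi_draws, vdi_draws)
    denom = (vdi - vi) + f * vi
    keep = denom != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.warning("corrected_fraction: excluded %d zero-denominator draws", n_excluded)
    if not keep.any():
        raise ValueError("no draws with nonzero denominator")
    ratio = f * vi[keep] / denom[keep]
    s = summarize(ratio)
    vim, vdim = float(vi[keep].mean()), float(vdi[keep].mean())
    point = f * vim / ((vdim - vim) + f * vim)
    return DerivedResult("corrected_fraction", s.mean, s.ci_low, s.ci_high, point, ratio, n_excluded)


def clone_mean_difference(
    draws: PosteriorDraws, clone_factor: str = "clone_type", group_factor: str = "group"
) -> DerivedResult:
    """Per-draw clone-type contrast, PIGE minus PTGE, averaged over populations.

    Requires a joint (M2-style) fit with the clone-type factor; each draw's
    value is the difference of clone-type marginal means, each marginal mean
    averaging the population-level means.
    """
    if clone_factor not in draws.fixed_levels:
        raise ValueError(f"model {draws.spec.model_id} has no {clone_factor!r} factor")
    clone_levels = draws.fixed_levels[clone_factor]
    ptge = next((l for l in clone_levels if "PTGE" in l), clone_levels[0])
    pige = next(
        (l for l in clone_levels if l != ptge and "PIGE" in l),
        next(l for l in clone_levels if l != ptge),
    )
    m_pige, _ = draws.level_means(group_factor, at={clone_factor: pige})
    m_ptge, _ = draws.level_means(group_factor, at={clone_factor: ptge})
    diff = m_pige.mean(axis=1) - m_ptge.mean(axis=1)
    s = summarize(diff)
    return DerivedResult("clone_mean_difference", s.mean, s.ci_low, s.ci_high, float(diff.mean()), diff)


def empirical_survival(data: pd.DataFrame, by: str = "group") -> dict:
    """Empirical step survival curve per group.

    Returns ``{group: DataFrame(time, fraction_alive)}`` with the fraction
    alive just after each death-check time; starts at (0, 1), non-increasing,
    reaching 0 when all individuals have died (all flies were followed to
    death, so no censoring machinery is needed).
    """
    out = {}
    for g, sub in data.groupby(by, sort=True):
        t = np.sort(sub["lifespan_days"].to_numpy(dtype=float))
        times, counts = np.unique(t, return_counts=True)
        alive = 1.0 - np.cumsum(counts) / len(t)
        curve = pd.DataFrame(
            {"time": np.concatenate(([0.0], times)), "fraction_alive": np.concatenate(([1.0], alive))}
        )
        out[g] = curve
    return out


def plot_survival(curves: dict, ax=None, title: str | None = None):
    """Step plot of survival curves (one line per group)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for g, c in curves.items():
        ax.step(c["time"], c["fraction_alive"], where="post", label=str(g))
    ax.set_xlabel("age (days)")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    return ax
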