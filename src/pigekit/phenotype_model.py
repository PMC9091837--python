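"""Generative lifespan model for hemiclone offspring.

Maps each planned offspring slot of a DesignTable to a lifespan in days under
the variance-component structure the downstream analysis assumes:

    lifespan = mu + d_g·[PTGE-clone] + i_g·[generation-1 clone]
             + gi_g·[GPIGE-clone] + block offset
             + vial ~ N(0, V_vial) + residual ~ N(0, V_R)

where (d_g, i_g) are the direct and indirect effects of sire genome *g*,
drawn from a bivariate normal with variances ``V_D``, ``V_I`` and correlation
``rho_DI``, and ``gi_g`` is a grandsire indirect carryover (default variance
0, matching the null grand-offspring finding).  PTGE-clones inherit the
cloned autosomes and so express ``d_g + i_g``; PIGE-clones are genetically
standardized and express only ``i_g``.

Recorded lifespans follow the death-check schedule: flies were scored at
each food transfer, three times per week (2/2/3-day pattern) in the
among-population assay and every second day within-population, so a latent
death time is rounded up to the next check day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cross_engine import DESIGN_COLUMNS

__all__ = [
    "VarianceConfig",
    "GeneticEffects",
    "SchemaError",
    "draw_genetic_effects",
    "simulate_lifespans",
    "write_dataset",
    "read_dataset",
    "DATASET_COLUMNS",
    "CHECK_AMONG",
    "CHECK_WITHIN",
]

DATASET_COLUMNS = DESIGN_COLUMNS + ["lifespan_days"]

#: "three times per week" transfer pattern (days between checks).
CHECK_AMONG = (2, 2, 3)
#: "every second day" transfer pattern.
CHECK_WITHIN = (2,)


class SchemaError(ValueError):
    """A required dataset column is missing."""


@dataclass
class VarianceConfig:
    """Parameters of the generative lifespan model (days / days^2).

    Defaults target the published among-population point estimates
    (V_I ~ 3.86, V_D + V_I ~ 27.10 with rho_DI = 0); mu, V_vial and V_R are
    not reported in the study and are set for a realistic fly lifespan spread.
    ``check_interval`` may be a single spacing in days, a repeating pattern
    of spacings (e.g. ``(2, 2, 3)``), or 0 for continuous recording.
    """

    mu: float = 50.0
    V_D: float = 23.24
    V_I: float = 3.86
    rho_DI: float = 0.0
    V_GI: float = 0.0
    V_vial: float = 4.0
    block_effects: dict = field(default_factory=dict)
    V_R: float = 60.0
    check_interval: float | tuple = CHECK_AMONG
    n_genomes: int = 4

    def __post_init__(self):
        for name in ("V_D", "V_I", "V_GI", "V_vial", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.rho_DI) > 1:
            raise ValueError("|rho_DI| must be <= 1")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if isinstance(d["check_interval"], tuple):
            d["check_interval"] = list(d["check_interval"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VarianceConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown VarianceConfig fields: {sorted(unknown)}")
        if isinstance(d.get("check_interval"), list):
            d["check_interval"] = tuple(d["check_interval"])
        return cls(**d)


@dataclass
class GeneticEffects:
    """Per-genome direct (d), indirect (i) and grandsire-carryover (gi) effects."""

    genomes: tuple
    d: np.ndarray
    i: np.ndarray
    gi: np.ndarray

    def __post_init__(self):
        n = len(self.genomes)
        self.d = np.asarray(self.d, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.gi = np.asarray(self.gi, dtype=float)
        if not (self.d.shape == self.i.shape == self.gi.shape == (n,)):
            raise ValueError("effect arrays must match the number of genomes")

    def index_of(self, group: str) -> int:
        try:
            return self.genomes.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} has no genome in GeneticEffects") from None


def draw_genetic_effects(
    config: VarianceConfig,
    seed: int,
    genomes: tuple | None = None,
    standardize: bool = False,
    mean_d: float = 0.0,
) -> GeneticEffects:
    """Draw per-genome effects from the bivariate-normal model.

    With ``standardize=True`` the draws are affinely rescaled so that the
    sample variance (ddof=1) of ``i`` equals ``V_I`` exactly and that of
    ``d + i`` equals ``V_D + V_I + 2 rho sqrt(V_D V_I)`` exactly — useful
    when the realized among-genome variance must match a target, e.g. in
    calibration studies with few genomes.  ``mean_d`` shifts the direct
    effects (PIGE-minus-PTGE mean lifespan difference equals ``-mean(d)``).
    """
    if genomes is None:
        genomes = tuple(f"g{k + 1}" for k in range(config.n_genomes))
    n = len(genomes)
    cov = np.array(
        [
            [config.V_D, config.rho_DI * np.sqrt(config.V_D * config.V_I)],
            [config.rho_DI * np.sqrt(config.V_D * config.V_I), config.V_I],
        ]
    )
    # bivariate normal must be PSD; guaranteed by |rho|<=1, but guard exotic input
    if np.any(np.linalg.eigvalsh(cov) < -1e-12):
        raise ValueError("direct/indirect covariance matrix is not positive semidefinite")
    rng = np.random.default_rng(seed)
    di = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    d, i = di[:, 0].copy(), di[:, 1].copy()
    gi = rng.normal(0.0, np.sqrt(config.V_GI), size=n) if config.V_GI > 0 else np.zeros(n)

    if standardize:
        if n < 2:
            raise ValueError("standardize requires at least 2 genomes")
        v_total = config.V_D + config.V_I + 2 * config.rho_DI * np.sqrt(config.V_D * config.V_I)
        i = _rescale(i, rng, config.V_I)
        total = _rescale(d + i, rng, v_total)
        d = total - i
        if config.V_GI > 0:
            gi = _rescale(gi, rng, config.V_GI)
    if standardize:
        d = d - d.mean() + mean_d
    elif mean_d != 0.0:
        d = d + mean_d
    return GeneticEffects(genomes=tuple(genomes), d=d, i=i, gi=gi)


def _rescale(x: np.ndarray, rng: np.random.Generator, target_var: float) -> np.ndarray:
    x = x - x.mean()
    s = x.std(ddof=1)
    if s == 0:
        if target_var == 0:
            return x
        x = rng.normal(size=x.size)
        x -= x.mean()
        s = x.std(ddof=1)
    return x * np.sqrt(target_var) / s


def _check_days(check_interval, horizon: float) -> np.ndarray | None:
    """Cumulative death-check days covering [0, horizon]; None if continuous."""
    if check_interval is None:
        return None
    if np.isscalar(check_interval):
        if check_interval == 0:
            return None
        pattern = (float(check_interval),)
    else:
        pattern = tuple(float(c) for c in check_interval)
        if not pattern:
            return None
    if any(c <= 0 for c in pattern):
        raise ValueError("check intervals must be positive")
    days, t, k = [], 0.0, 0
    while t <= horizon + max(pattern):
        t += pattern[k % len(pattern)]
        k += 1
        days.append(t)
    return np.array(days)


def simulate_lifespans(
    design: pd.DataFrame,
    effects: GeneticEffects,
    config: VarianceConfig,
    seed: int,
    center_nuisance: bool = False,
    orthogonalize_group_noise: bool = False,
) -> pd.DataFrame:
    """Simulate one lifespan per design row.

    Two conditional-simulation modes support calibration studies (moment
    matching in the spirit of empirical-covariance multivariate draws):

    * ``center_nuisance=True`` centres the realized vial effects within each
      group x clone-type cell and the residuals within each vial, so realized
      group means equal their expectation exactly.  Appropriate when group is
      analyzed as a *fixed* factor, whose per-draw variance statistic carries
      the sampling noise of group means additively.
    * ``orthogonalize_group_noise=True`` instead fixes the nuisance
      contribution to each group's mean at exactly its expected variance
      (V_vial/vials-per-group + V_R/rows-per-group), orthogonal to the
      realized genetic effects.  Appropriate when group is analyzed as a
      *random* factor, whose shrinkage estimator subtracts expected
      group-mean noise.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SchemaError(f"design table missing columns: {missing}")
    rng = np.random.default_rng(seed)

    g_idx = np.array([effects.index_of(g) for g in design["group"]])
    clone = design["clone_type"].to_numpy()
    gen = design["generation"].to_numpy()

    genetic = np.zeros(len(design))
    is_ptge = clone == "PTGE_clone"
    is_gen1 = (gen == 1)
    is_gpige = clone == "GPIGE_clone"
    genetic[is_ptge] += effects.d[g_idx[is_ptge]]
    genetic[is_gen1] += effects.i[g_idx[is_gen1]]
    genetic[is_gpige] += effects.gi[g_idx[is_gpige]]

    blocks = design["block"].astype(str).to_numpy()
    block_off = np.array([float(config.block_effects.get(b, 0.0)) for b in blocks])

    vial_codes, vial_uniques = pd.factorize(design["vial_id"])
    vial_fx = rng.normal(0.0, np.sqrt(config.V_vial), size=len(vial_uniques))
    resid = rng.normal(0.0, np.sqrt(config.V_R), size=len(design))

    if center_nuisance:
        cell_codes, _ = pd.factorize(
            design["group"].astype(str) + "|" + design["clone_type"].astype(str)
        )
        vial_cell = np.full(len(vial_uniques), -1, dtype=int)
        vial_cell[vial_codes] = cell_codes
        for c in np.unique(vial_cell):
            m = vial_cell == c
            vial_fx[m] -= vial_fx[m].mean()
        resid -= np.bincount(vial_codes, weights=resid)[vial_codes] / np.bincount(vial_codes)[vial_codes]

    noise = vial_fx[vial_codes] + resid

    if orthogonalize_group_noise:
        g_codes, g_uniques = pd.factorize(design["group"], sort=False)
        n_groups = len(g_uniques)
        if n_groups < 3:
            raise ValueError("orthogonalize_group_noise needs >= 3 groups")
        n_g = np.bincount(g_codes).astype(float)
        c_g = np.bincount(g_codes, weights=noise) / n_g
        gbar_g = np.bincount(g_codes, weights=genetic) / n_g
        vials_per_group = pd.Series(vial_codes).groupby(g_codes).nunique().to_numpy()
        se2 = float(np.mean(config.V_vial / vials_per_group + config.V_R / n_g))
        # Gram-Schmidt: remove mean and the component along the genetic means,
        # then rescale to the expected group-mean noise variance
        z = c_g - c_g.mean()
        gdev = gbar_g - gbar_g.mean()
        if gdev @ gdev > 0:
            z = z - (z @ gdev) / (gdev @ gdev) * gdev
        sz = z.std(ddof=1)
        if sz > 0 and se2 > 0:
            z = z * np.sqrt(se2) / sz
        elif se2 == 0:
            z = np.zeros(n_groups)
        noise = noise + (z - c_g)[g_codes]

    latent = config.mu + genetic + block_off + noise

    checks = _check_days(config.check_interval, float(latent.max(initial=0.0)))
    if checks is None:
        lifespan = np.maximum(latent, 0.1)  # lifespans must be positive
    else:
        lifespan = checks[np.searchsorted(checks, np.maximum(latent, 1e-9), side="left")]

    out = design.copy()
    out["lifespan_days"] = lifespan
    return out[DATASET_COLUMNS]


def write_dataset(data: pd.DataFrame, path) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"dataset missing columns: {missing}")
    data[DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a lifespan dataset from CSV.

    ``column_map`` maps external header names to the canonical columns
    (``{"external name": "canonical name"}``), so archived files with
    different headers can be ingested directly.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for optional, default in (("generation", 1), ("block", ""), ("slot_id", None)):
        if optional not in df.columns:
            if optional == "slot_id":
                df["slot_id"] = [f"row{i}" for i in range(len(df))]
            else:
                df[optional] = default
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing columns: {missing}")
    df["block"] = df["block"].fillna("")
    return df[DATASET_COLUMNS]
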