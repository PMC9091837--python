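import numpy as np
import pandas as pd
import pytest

from pigekit.cross_engine import DESIGN_COLUMNS


def make_design(groups=("A", "B", "C", "D"), clone_type="PIGE_clone", n_vials=8, per_vial=15,
                blocks=None):
    """Small nested design table for fast inference tests."""
    rows = []
    blocks = blocks or [""]
    for g in groups:
        v = 0
        for b in blocks:
            for _ in range(n_vials // len(blocks)):
                vid = f"{g}_v{v:02d}"
                rows += [(g, clone_type, 1, vid, b, f"{vid}_s{s}") for s in range(per_vial)]
                v += 1
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def one_way_data(q=40, m=20, v_between=9.0, v_within=25.0, mu=50.0, seed=0):
    """Balanced one-way random-intercept layout with known variances."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(v_between), q)
    y = (mu + u[:, None] + rng.normal(0, np.sqrt(v_within), (q, m))).ravel()
    return pd.DataFrame(
        {
            "group": "A",
            "clone_type": "PIGE_clone",
            "generation": 1,
            "vial_id": np.repeat([f"v{i:03d}" for i in range(q)], m),
            "block": "",
            "slot_id": [f"s{i}" for i in range(q * m)],
            "lifespan_days": y,
        }
    )


@pytest.fixture
def small_design():
    return make_design()


@pytest.fixture
def quick_mcmc():
    """Reduced sampler budget for unit tests."""
    return dict(chains=2, iterations=600, warmup=200, compute_rhat=False)
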