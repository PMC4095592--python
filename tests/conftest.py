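"""Shared fixtures: small synthetic designs and matched-set generators."""

import numpy as np
import pandas as pd
import pytest

from bcrisk.association import ClogitDesign


def make_clogit_sets(
    n_sets: int,
    beta: float,
    raf: float = 0.3,
    controls_per_set: int = 3,
    seed: int = 0,
) -> ClogitDesign:
    """Matched sets drawn exactly from the conditional-logistic model.

    Each set holds ``controls_per_set + 1`` subjects with Binomial(2, raf)
    dosages; the case is chosen within the set with probability proportional
    to exp(beta * dosage), which is precisely the likelihood the fitter
    maximises, so parameter recovery is unbiased by construction.
    """
    rng = np.random.default_rng(seed)
    m = controls_per_set + 1
    g = rng.binomial(2, raf, size=(n_sets, m)).astype(float)
    w = np.exp(beta * g)
    p = w / w.sum(axis=1, keepdims=True)
    case_pos = (rng.random(n_sets)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    is_case = np.zeros((n_sets, m), dtype=bool)
    is_case[np.arange(n_sets), case_pos] = True
    return ClogitDesign(
        g.reshape(-1, 1),
        np.repeat(np.arange(n_sets), m),
        is_case.ravel(),
        ["dosage"],
    )


@pytest.fixture
def pair_design():
    """200 1:1 matched pairs with a binary exposure (closed-form testbed)."""
    rng = np.random.default_rng(42)
    n = 200
    x_case = rng.binomial(1, 0.6, n).astype(float)
    x_ctrl = rng.binomial(1, 0.4, n).astype(float)
    design = ClogitDesign(
        np.r_[x_case, x_ctrl].reshape(-1, 1),
        np.r_[np.arange(n), np.arange(n)],
        np.r_[np.ones(n, bool), np.zeros(n, bool)],
        ["x"],
    )
    n10 = int(((x_case == 1) & (x_ctrl == 0)).sum())
    n01 = int(((x_case == 0) & (x_ctrl == 1)).sum())
    return design, n10, n01


@pytest.fixture
def small_frame():
    """Subject-level matched frame with the full covariate vocabulary."""
    rng = np.random.default_rng(3)
    n_sets = 60
    rows = []
    for s in range(n_sets):
        for j in range(4):
            rows.append(
                {
                    "set_id": s,
                    "subject_id": f"S{s}_{j}",
                    "role": "case" if j == 0 else "control",
                    "education": rng.choice(["none", "primary", "secondary"]),
                    "age_first_birth": rng.choice(["<20", "20-24", "25-29/null", ">=30"]),
                    "age_menarche": rng.choice([">=14", "12-13", "<12"]),
                    "family_history": rng.choice(["no", "yes"], p=[0.9, 0.1]),
                    "biopsy_history": rng.choice(["no", "yes"], p=[0.9, 0.1]),
                    "bmi_cat": rng.choice(["<20", "20-<24", "24-<28", ">=28"]),
                    "grs_quartile": str(rng.integers(1, 5)),
                }
            )
    return pd.DataFrame(rows)
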