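"""Net reclassification improvement between risk models without and with GRS.

Cases and controls are cross-tabulated over the five absolute-risk bands
under the two models.  The NRI is the net proportion of cases moving to a
higher band plus the net proportion of controls moving lower; significance
follows the Pencina z test, and optimism from refitting on the same data is
estimated by a bootstrap that resamples matched sets, refits both models on
each replicate and averages the apparent-minus-test difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .published import RISK_BANDS


def build_reclass_table(bands_without, bands_with) -> pd.DataFrame:
    """5x5 cross-tabulation; rows = band without GRS, columns = with GRS."""
    a = pd.Categorical(bands_without, categories=RISK_BANDS)
    b = pd.Categorical(bands_with, categories=RISK_BANDS)
    if len(a) != len(b):
        raise ValueError("band vectors differ in length")
    if a.isna().any() or b.isna().any():
        raise ValueError(f"band labels must be among {RISK_BANDS}")
    tab = pd.crosstab(a, b, dropna=False)
    tab.index = pd.Index(RISK_BANDS, name="without_grs")
    tab.columns = pd.Index(RISK_BANDS, name="with_grs")
    return tab


def _movements(table: pd.DataFrame) -> tuple[int, int, int]:
    counts = table.to_numpy()
    n = int(counts.sum())
    up = int(np.triu(counts, k=1).sum())
    down = int(np.tril(counts, k=-1).sum())
    return up, down, n


@dataclass
class NriResult:
    """Reclassification summary; proportions are relative to group sizes."""

    case_up: float
    case_down: float
    control_up: float
    control_down: float
    case_component: float
    control_component: float
    nri: float
    n_cases: int
    n_controls: int
    z: float | None = None
    p: float | None = None
    case_z: float | None = None
    case_p: float | None = None
    control_z: float | None = None
    control_p: float | None = None
    apparent_nri: float | None = None
    optimism: float | None = None
    corrected_nri: float | None = None
    n_boot: int | None = None


def nri_components(case_table: pd.DataFrame, control_table: pd.DataFrame) -> NriResult:
    """NRI from case and control reclassification tables.

    case component = P(up|case) - P(down|case); control component =
    P(down|control) - P(up|control); NRI is their sum.
    """
    c_up, c_down, n_cases = _movements(case_table)
    k_up, k_down, n_controls = _movements(control_table)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("empty case or control table")
    case_up, case_down = c_up / n_cases, c_down / n_cases
    control_up, control_down = k_up / n_controls, k_down / n_controls
    case_component = case_up - case_down
    control_component = control_down - control_up
    return NriResult(
        case_up=case_up,
        case_down=case_down,
        control_up=control_up,
        control_down=control_down,
        case_component=case_component,
        control_component=control_component,
        nri=case_component + control_component,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def nri_ztest(result: NriResult) -> NriResult:
    """Pencina-style asymptotic z test for the NRI and each component.

    z = NRI / sqrt[(p_up,case + p_down,case)/n_cases +
    (p_up,control + p_down,control)/n_controls]; component tests use the
    matching single-group variance.  No movement at all leaves z undefined
    (NaN) with a flagging P of NaN.
    """
    case_var = (result.case_up + result.case_down) / result.n_cases
    control_var = (result.control_up + result.control_down) / result.n_controls

    def _test(value, var):
        if var <= 0:
            return np.nan, np.nan
        z = value / np.sqrt(var)
        return float(z), float(2 * stats.norm.sf(abs(z)))

    result.z, result.p = _test(result.nri, case_var + control_var)
    result.case_z, result.case_p = _test(result.case_component, case_var)
    result.control_z, result.control_p = _test(result.control_component, control_var)
    return result


def nri_from_bands(
    bands_without, bands_with, is_case
) -> NriResult:
    """Convenience: tables + components + z test from per-subject bands."""
    is_case = np.asarray(is_case, dtype=bool)
    bw = np.asarray(bands_without, dtype=object)
    bg = np.asarray(bands_with, dtype=object)
    case_tab = build_reclass_table(bw[is_case], bg[is_case])
    ctrl_tab = build_reclass_table(bw[~is_case], bg[~is_case])
    return nri_ztest(nri_components(case_tab, ctrl_tab))


def bootstrap_optimism(
    data: pd.DataFrame,
    fit_procedure: Callable[[pd.DataFrame], Callable[[pd.DataFrame], float]],
    b: int = 500,
    seed: int = 0,
    set_col: str = "set_id",
    max_failures: float = 0.10,
) -> tuple[float, float, float, int]:
    """Harrell-style bootstrap optimism for the NRI.

    ``fit_procedure(train)`` must refit both risk models on ``train`` (a
    subject-level frame carrying ``set_col``) and return an evaluator
    ``evaluate(frame) -> nri``.  Matched sets are resampled with replacement;
    optimism = mean over replicates of [NRI(replicate model on replicate) -
    NRI(replicate model on original)], and corrected = apparent - optimism.
    Returns (apparent, optimism, corrected, n_successful_replicates).
    """
    if b < 50:
        raise ValueError("use at least 50 bootstrap replicates")
    rng = np.random.default_rng(seed)
    apparent = fit_procedure(data)(data)
    set_ids = data[set_col].unique()
    groups = {s: df for s, df in data.groupby(set_col)}
    diffs = []
    failures = 0
    for _ in range(b):
        chosen = rng.choice(set_ids, size=len(set_ids), replace=True)
        parts = []
        for new_id, s in enumerate(chosen):
            part = groups[s].copy()
            part[set_col] = new_id
            parts.append(part)
        replicate = pd.concat(parts, ignore_index=True)
        try:
            evaluate = fit_procedure(replicate)
            diffs.append(evaluate(replicate) - evaluate(data))
        except Exception:
            failures += 1
            if failures > max_failures * b:
                raise RuntimeError(
                    f"{failures} of {b} bootstrap replicates failed to fit"
                )
    optimism = float(np.mean(diffs))
    return float(apparent), optimism, float(apparent - optimism), len(diffs)
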