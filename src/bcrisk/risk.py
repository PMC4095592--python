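"""Five-year absolute-risk projection from a matched case-control fit.

Combines three ingredients: a Kaplan-Meier estimate S_t of cohort-level
breast-cancer-free survival; the conditional-logistic coefficients beta_j
(log ORs treated as rate-ratio surrogates); and control means mu_j of each
coded covariate.  A woman's relative-risk index is
C_i = exp(sum_j beta_j (x_ij - mu_j)), and her t-year absolute risk is
P_i(t) = 1 - S_t ** C_i, banded into the five clinical categories from <1.0%
to >=2.5%.  History of breast biopsy, observed only for a minority, is
completed by logistic imputation (five draws, majority vote) before model
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import published
from .association import ClogitDesign

RISK_BANDS = published.RISK_BANDS


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier curve over distinct event times.

    ``times`` are years from enrollment to diagnosis or censoring; censored
    subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    event_times = with_events.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.asof(t)) for t in event_times])
    return SurvivalCurve(
        event_times=event_times,
        at_risk=with_events["at_risk"].to_numpy(int),
        events=with_events["observed"].to_numpy(int),
        survival=survival,
    )


def impute_biopsy(cohort: pd.DataFrame, seed: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """Complete the breast-biopsy history variable.

    Fits logistic(biopsy ~ BMI + estrogen + family history) on the observed
    subset, then for each missing record draws five Bernoulli values from the
    fitted probability and assigns the majority (five draws, so no ties).
    Returns (completed yes/no Series aligned to the cohort, audit table).
    Falls back to the observed prevalence when the fit is degenerate.
    """
    import statsmodels.api as sm

    observed = cohort["biopsy_history"].isin(["yes", "no"])
    if observed.sum() < 20:
        raise ValueError("need at least 20 observed biopsy records")
    rng = np.random.default_rng(seed)

    def _predictors(df):
        return np.column_stack(
            [
                np.ones(len(df)),
                df["bmi"].to_numpy(float),
                (df["estrogen"] == "ex").to_numpy(float),
                (df["estrogen"] == "current").to_numpy(float),
                (df["family_history"] == "yes").to_numpy(float),
            ]
        )

    obs = cohort[observed]
    y = (obs["biopsy_history"] == "yes").to_numpy(float)
    fallback = None
    if y.min() == y.max():
        fallback = float(y.mean())
    else:
        try:
            model = sm.GLM(y, _predictors(obs), family=sm.families.Binomial())
            params = model.fit(maxiter=200).params
        except Exception:  # degenerate fit: fall back to prevalence
            fallback = float(y.mean())
    completed = cohort["biopsy_history"].copy()
    missing = cohort[~observed]
    if len(missing):
        if fallback is not None:
            import warnings

            warnings.warn("biopsy imputation fell back to observed prevalence")
            p = np.full(len(missing), fallback)
        else:
            eta = _predictors(missing) @ params
            p = 1.0 / (1.0 + np.exp(-eta))
        draws = rng.random((len(missing), 5)) < p[:, None]
        majority = draws.sum(axis=1) >= 3
        completed.loc[missing.index] = np.where(majority, "yes", "no")
    audit = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "observed": observed.to_numpy(),
            "imputed_value": np.where(observed, None, completed),
        }
    )
    return completed, audit


def control_means(design: ClogitDesign) -> np.ndarray:
    """mu_j: mean of each coded model term among the design's controls."""
    return design.x[~design.is_case].mean(axis=0)


def relative_index(x: np.ndarray, beta: np.ndarray, means: np.ndarray) -> np.ndarray:
    """C_i = exp(sum_j beta_j (x_ij - mu_j)); 1.0 for the average profile."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta = np.asarray(beta, dtype=float)
    means = np.asarray(means, dtype=float)
    if x.shape[1] != beta.size or beta.size != means.size:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[1]} terms, beta {beta.size}, means {means.size}"
        )
    return np.exp((x - means) @ beta)


def assign_band(p_percent) -> np.ndarray:
    """Risk band labels for risks in percent, half-open [low, high) intervals."""
    p = np.atleast_1d(np.asarray(p_percent, dtype=float))
    idx = np.digitize(p, published.RISK_BAND_EDGES, right=False)
    return np.asarray(RISK_BANDS, dtype=object)[idx]


def five_year_risk(s5: float, c_index) -> pd.DataFrame:
    """P_i(5) = 1 - S_5^{C_i} with its risk band.

    ``s5`` is the Kaplan-Meier survival at five years, in (0, 1]; C_i > 0
    (C_i -> 0 gives zero risk).
    """
    if not 0.0 < s5 <= 1.0:
        raise ValueError("S_5 must lie in (0, 1]")
    c = np.atleast_1d(np.asarray(c_index, dtype=float))
    if (c < 0).any():
        raise ValueError("C_i must be non-negative")
    p5 = 1.0 - s5**c
    return pd.DataFrame({"c_index": c, "p5": p5, "band": assign_band(100 * p5)})


def absolute_risks(
    design: ClogitDesign, beta: np.ndarray, s5: float, subject_order: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-subject C_i, five-year risk and band from a fitted design."""
    mu = control_means(design)
    c = relative_index(design.x, beta, mu)
    out = five_year_risk(s5, c)
    if subject_order is not None:
        out.insert(0, "subject_id", np.asarray(subject_order)[design.order])
    return out
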