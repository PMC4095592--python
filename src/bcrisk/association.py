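"""Conditional logistic regression for 1:m matched case-control sets.

With exactly one case per matched set the conditional likelihood has the
closed softmax form

    l(beta) = sum over sets [ eta_case - log sum_{j in set} exp(eta_j) ],

with eta = X beta.  Matching absorbs all set-level effects, so the model has
no intercept.  The likelihood is maximised by Newton-Raphson with analytic
gradient and Hessian, step-halving on a log-likelihood decrease, and a guard
against separation (coefficients running away).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """A coefficient diverged; the likelihood has no finite maximiser."""


class NonInformativeError(ValueError):
    """A covariate has no within-set variation and cannot be estimated."""


@dataclass
class ClogitDesign:
    """Matched-set design: covariate matrix, set labels and case flags.

    Rows are sorted by set on construction; each set must contain exactly one
    case.  ``terms`` names the columns of ``x``.
    """

    x: np.ndarray
    set_ids: np.ndarray
    is_case: np.ndarray
    terms: list[str]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-D")
        if not np.isfinite(self.x).all():
            raise ValueError("non-finite covariate values in design")
        self.set_ids = np.asarray(self.set_ids)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if not (len(self.set_ids) == len(self.is_case) == self.x.shape[0]):
            raise ValueError("inconsistent design dimensions")
        if len(self.terms) != self.x.shape[1]:
            raise ValueError("terms must name every column")
        order = np.argsort(self.set_ids, kind="stable")
        self.order = order  # original-row permutation, for aligning outputs
        self.x = self.x[order]
        self.set_ids = self.set_ids[order]
        self.is_case = self.is_case[order]
        boundaries = np.flatnonzero(
            np.r_[True, self.set_ids[1:] != self.set_ids[:-1]]
        )
        self._starts = boundaries
        self._ends = np.r_[boundaries[1:], len(self.set_ids)]
        cases_per_set = np.add.reduceat(self.is_case.astype(int), self._starts)
        if not (cases_per_set == 1).all():
            raise ValueError("every set must contain exactly one case")

    @property
    def n_sets(self) -> int:
        return len(self._starts)

    def informative_terms(self) -> np.ndarray:
        """Boolean mask of columns with within-set variation in >=1 set."""
        mx = np.maximum.reduceat(self.x, self._starts, axis=0)
        mn = np.minimum.reduceat(self.x, self._starts, axis=0)
        return (mx > mn).any(axis=0)


@dataclass
class FitResult:
    """Maximum conditional-likelihood estimates for one model."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_sets: int
    terms: list[str]

    def summary(self) -> pd.DataFrame:
        """Per-term OR, 95% CI and two-sided Wald P."""
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.beta - Z95 * self.se),
                "ci_high": np.exp(self.beta + Z95 * self.se),
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def clogit_loglik(beta, design: ClogitDesign):
    """Log-likelihood with analytic gradient and Hessian at ``beta``."""
    beta = np.asarray(beta, dtype=float)
    x, starts = design.x, design._starts
    eta = x @ beta
    set_max = np.maximum.reduceat(eta, starts)
    rep = np.repeat(np.arange(design.n_sets), design._ends - starts)
    expeta = np.exp(eta - set_max[rep])
    denom = np.add.reduceat(expeta, starts)
    lse = set_max + np.log(denom)
    loglik = float(eta[design.is_case].sum() - lse.sum())

    prob = expeta / denom[rep]
    grad = x[design.is_case].sum(axis=0) - x.T @ prob
    weighted = prob[:, None] * x
    set_mean = np.add.reduceat(weighted, starts, axis=0)  # E[x] per set
    hess = -(x.T @ weighted - set_mean.T @ set_mean)
    return loglik, grad, hess


def clogit_fit(
    design: ClogitDesign,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta_bound: float = 15.0,
) -> FitResult:
    """Newton-Raphson fit from beta = 0 with step-halving.

    Convergence is gradient max-norm below ``tol``; a coefficient magnitude
    above ``beta_bound`` raises SeparationError; columns without within-set
    variation raise NonInformativeError.
    """
    info = design.informative_terms()
    if not info.all():
        bad = [t for t, ok in zip(design.terms, info) if not ok]
        raise NonInformativeError(f"no within-set variation for terms: {bad}")

    p = design.x.shape[1]
    beta = np.zeros(p)
    loglik, grad, hess = clogit_loglik(beta, design)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_hess = clogit_loglik(new_beta, design)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_grad, new_hess = clogit_loglik(new_beta, design)
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > beta_bound:
            offending = [t for t, b in zip(design.terms, beta) if abs(b) > beta_bound]
            err = SeparationError(
                f"|beta| exceeded {beta_bound} for {offending}; "
                "data are (quasi-)separated"
            )
            err.offending = offending
            raise err
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged:
        raise RuntimeError(
            f"no convergence after {max_iter} iterations "
            f"(gradient max-norm {np.max(np.abs(grad)):.2e})"
        )
    cov = np.linalg.inv(-hess)
    cov = (cov + cov.T) / 2
    return FitResult(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        loglik=loglik,
        converged=converged,
        n_iter=it,
        n_sets=design.n_sets,
        terms=list(design.terms),
    )


# ---------------------------------------------------------------------------
# category codings used across the package (first listed level = reference)

CATEGORY_LEVELS: dict[str, list[str]] = {
    "education": ["none", "primary", "secondary"],
    "age_first_birth": ["<20", "20-24", "25-29/null", ">=30"],
    "age_menarche": [">=14", "12-13", "<12"],
    "family_history": ["no", "yes"],
    "biopsy_history": ["no", "yes"],
    "bmi_cat": ["<20", "20-<24", "24-<28", ">=28"],
    "estrogen": ["non", "ex", "current"],
    "grs_quartile": ["1", "2", "3", "4"],
}


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    set_col: str = "set_id",
    case_col: str = "role",
) -> ClogitDesign:
    """Indicator-code categorical terms into a ClogitDesign.

    Terms present in CATEGORY_LEVELS are expanded to indicators against their
    first (reference) level; other columns enter as numeric.  ``case_col``
    may hold 'case'/'control' labels or booleans.
    """
    cols, names = [], []
    for term in terms:
        if term in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[term]
            vals = data[term].astype(str)
            unknown = set(vals) - set(levels)
            if unknown:
                raise ValueError(f"{term}: unknown levels {sorted(unknown)}")
            for lv in levels[1:]:
                cols.append((vals == lv).to_numpy(float))
                names.append(f"{term}[{lv}]")
        else:
            cols.append(data[term].to_numpy(float))
            names.append(term)
    x = np.column_stack(cols) if cols else np.empty((len(data), 0))
    case = data[case_col]
    is_case = (case == "case").to_numpy() if case.dtype == object else case.to_numpy(bool)
    return ClogitDesign(x, data[set_col].to_numpy(), is_case, names)


def per_snp_association(
    genotypes: pd.DataFrame, membership: pd.DataFrame
) -> pd.DataFrame:
    """Univariable per-allele conditional-logistic fit for every SNP.

    ``membership`` is the long matched-set table (set_id, subject_id, role).
    Subjects missing a SNP's genotype are dropped for that SNP; sets left
    without a case or without controls are skipped.  Per-SNP failures are
    recorded, not raised.
    """
    out = []
    for rsid in genotypes.columns:
        df = membership.merge(
            genotypes[rsid].rename("dosage"), left_on="subject_id", right_index=True
        ).dropna(subset=["dosage"])
        ncase = df.groupby("set_id")["role"].apply(lambda r: (r == "case").sum())
        sizes = df.groupby("set_id").size()
        good = ncase.index[(ncase == 1) & (sizes >= 2)]
        df = df[df["set_id"].isin(good)]
        try:
            fit = clogit_fit(build_design(df, ["dosage"]))
            row = fit.summary().iloc[0]
            out.append(
                (rsid, row["or"], row.ci_low, row.ci_high, row.se, row.beta, row.p_value, fit.n_sets, None)
            )
        except (ValueError, RuntimeError) as exc:
            out.append((rsid, *([np.nan] * 6), 0, str(exc)))
    return pd.DataFrame(
        out,
        columns=["rsid", "or", "ci_low", "ci_high", "se", "beta", "p_value", "n_sets", "error"],
    )


def trend_test(
    data: pd.DataFrame,
    factor: str,
    levels: list[str] | None = None,
    set_col: str = "set_id",
    case_col: str = "role",
):
    """Test for trend across ordered factor levels.

    The factor's levels are mapped to consecutive integers and entered as a
    single ordinal term; returns (per-unit OR, (ci_low, ci_high), P).
    """
    levels = levels or CATEGORY_LEVELS.get(factor)
    if levels is None:
        raise ValueError(f"no level ordering known for {factor}")
    observed = set(data[factor].astype(str))
    if len(observed & set(levels)) < 2:
        raise ValueError("trend test needs at least two observed levels")
    score = data[factor].astype(str).map({lv: i + 1 for i, lv in enumerate(levels)})
    if score.isna().any():
        raise ValueError(f"{factor}: levels outside {levels}")
    df = data.assign(_score=score.astype(float))
    fit = clogit_fit(build_design(df, ["_score"], set_col, case_col))
    row = fit.summary().iloc[0]
    return float(row["or"]), (float(row.ci_low), float(row.ci_high)), float(row.p_value)
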