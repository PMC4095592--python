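"""Fixed-effects meta-analysis, heterogeneity screening and the genetic risk score.

Per SNP, study effects (log OR, SE) are pooled by inverse-variance weighting;
Cochran's Q against chi-square(k-1) tests between-study heterogeneity, with
Benjamini-Hochberg FDR adjustment across the panel.  SNPs with significant
(adjusted) heterogeneity are excluded from the score unless an override keeps
them with their local-study weight.  The score for a woman is
sum(log pOR x risk-allele dosage), normalised by the mean absolute weight so
it reads on a risk-allele-count scale; quartiles are cut on the control
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def fixed_effects_pool(betas, ses, weight_scheme: str = "inverse_variance"):
    """Pool study log ORs.

    With the default inverse-variance scheme w_i = 1/se_i^2,
    pooled_beta = sum(w b)/sum(w) and pooled_se = sum(w)^(-1/2).  The
    'inverse_se' scheme (w_i = 1/se_i) reweights the mean but keeps the
    inverse-variance pooled SE.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("cannot pool zero studies")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w_var = 1.0 / ses**2
    w = w_var if weight_scheme == "inverse_variance" else 1.0 / ses
    if weight_scheme not in ("inverse_variance", "inverse_se"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    pooled_beta = float((w * betas).sum() / w.sum())
    pooled_se = float(w_var.sum() ** -0.5)
    return pooled_beta, pooled_se


def cochran_q(betas, ses, pooled_beta: float):
    """Cochran's Q heterogeneity statistic and its chi-square(k-1) P value.

    Q = sum w_i (beta_i - pooled)^2 with inverse-variance weights; k = 1
    returns (0, 0, 1) by convention.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = betas.size
    if k < 2:
        return 0.0, 0, 1.0
    w = 1.0 / ses**2
    q = float((w * (betas - pooled_beta) ** 2).sum())
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pool_studies(effects: pd.DataFrame, weight_scheme: str = "inverse_variance") -> pd.DataFrame:
    """Pool a long (rsid, study_id, beta, se) table into per-SNP rows.

    Returns one row per SNP with pooled beta/SE, study count k, Q, raw and
    FDR-adjusted heterogeneity P.
    """
    rows = []
    for rsid, grp in effects.groupby("rsid", sort=False):
        pb, pse = fixed_effects_pool(grp["beta"], grp["se"], weight_scheme)
        q, df, p_het = cochran_q(grp["beta"], grp["se"], pb)
        rows.append((rsid, pb, pse, len(grp), q, p_het))
    pooled = pd.DataFrame(
        rows, columns=["rsid", "pooled_beta", "pooled_se", "k", "q", "p_het"]
    )
    pooled["p_het_fdr"] = bh_fdr(pooled["p_het"])
    return pooled


def select_grs_snps(
    pooled: pd.DataFrame,
    het_threshold: float = 0.007,
    overrides: tuple[str, ...] = (),
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Flag which SNPs enter the score.

    SNPs whose (FDR-adjusted, by default) heterogeneity P falls below
    ``het_threshold`` are excluded; rsids in ``overrides`` stay in the score
    but with weight_source='local_only', modelling a SNP whose pooled OR is
    not applicable yet is retained on biological grounds.
    """
    unknown = set(overrides) - set(pooled["rsid"])
    if unknown:
        raise KeyError(f"override rsids not in pooled table: {sorted(unknown)}")
    pooled = pooled.copy()
    p = pooled["p_het_fdr"] if use_fdr else pooled["p_het"]
    heterogeneous = p < het_threshold
    is_override = pooled["rsid"].isin(overrides)
    pooled["included_in_grs"] = ~heterogeneous | is_override
    pooled["weight_source"] = np.where(is_override, "local_only", "pooled")
    return pooled


@dataclass
class GrsResult:
    """Per-subject scores plus the control-based quartile boundaries."""

    scores: pd.DataFrame  # subject_id, raw_score, normalized_score[, quartile]
    weights: pd.Series  # oriented positive weight per included SNP
    quartile_boundaries: tuple[float, float, float] | None = None


def compute_grs(
    genotypes: pd.DataFrame,
    effects: pd.DataFrame,
    local_betas: pd.Series | None = None,
    control_ids=None,
    missing_policy: str = "expected",
) -> GrsResult:
    """Weighted risk-allele score, normalised to an allele-count scale.

    ``effects`` needs columns rsid, pooled_beta, included_in_grs,
    weight_source; rows with weight_source='local_only' take their weight
    from ``local_betas`` (a Series indexed by rsid).  Each SNP is oriented so
    its weight is positive (dosage flipped g -> 2-g when the log OR is
    negative).  Missing dosages are imputed with twice the control
    effect-allele frequency ('expected', default) or zero ('zero') before
    orientation.  normalized = raw / mean(weights).
    """
    included = effects[effects["included_in_grs"]]
    if included.empty:
        raise ValueError("no SNPs included in the score")
    weights = {}
    for row in included.itertuples():
        if row.weight_source == "local_only":
            if local_betas is None or row.rsid not in local_betas.index:
                raise ValueError(f"{row.rsid}: local weight required but not supplied")
            weights[row.rsid] = float(local_betas[row.rsid])
        else:
            weights[row.rsid] = float(row.pooled_beta)
    missing_snps = set(weights) - set(genotypes.columns)
    if missing_snps:
        raise KeyError(f"genotypes lack score SNPs: {sorted(missing_snps)[:5]}")
    rsids = [r for r in genotypes.columns if r in weights]
    beta = np.array([weights[r] for r in rsids])
    if not np.isfinite(beta).all():
        raise ValueError("non-finite score weights")

    g = genotypes[rsids].to_numpy(float)
    if missing_policy == "expected":
        sub = g if control_ids is None else genotypes.loc[
            genotypes.index.isin(set(control_ids)), rsids
        ].to_numpy(float)
        fill = np.nanmean(sub, axis=0)  # mean dosage = 2 * control allele freq
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = fill[idx[1]]
    elif missing_policy == "zero":
        g = np.nan_to_num(g, nan=0.0)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    flip = beta < 0
    g_oriented = np.where(flip, 2.0 - g, g)
    w = np.abs(beta)
    if not (w > 0).any():
        raise ValueError("all score weights are zero; normalisation undefined")
    raw = g_oriented @ w
    normalized = raw / w.mean()
    scores = pd.DataFrame(
        {"subject_id": genotypes.index, "raw_score": raw, "normalized_score": normalized}
    )
    return GrsResult(scores=scores, weights=pd.Series(w, index=rsids))


def grs_quartiles(result: GrsResult, control_ids) -> GrsResult:
    """Assign quartiles 1-4 from control-based boundaries.

    Boundaries are the 25th/50th/75th linear-interpolation percentiles of the
    control normalised scores; intervals are half-open [low, high) with the
    top interval closed.  Requires at least four distinct control scores.
    """
    scores = result.scores
    ctrl = scores.loc[scores["subject_id"].isin(set(control_ids)), "normalized_score"]
    if len(ctrl) < 4 or ctrl.nunique() < 4:
        raise ValueError("need at least four distinct control scores for quartiles")
    q1, q2, q3 = np.percentile(ctrl, [25, 50, 75])
    quart = 1 + np.digitize(scores["normalized_score"], [q1, q2, q3], right=False)
    scores = scores.assign(quartile=quart.astype(int))
    return GrsResult(scores=scores, weights=result.weights, quartile_boundaries=(float(q1), float(q2), float(q3)))
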