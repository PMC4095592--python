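"""Sample- and SNP-level quality control for genotype dosage matrices.

Filters follow the source study's rules: subjects below a 90% call rate are
removed (and, when the subject is a case, the whole matched set goes with
it); SNPs are dropped for minor allele frequency below 1% or for deviation
from Hardy-Weinberg equilibrium in controls at P < 0.0007; panels are pruned
so that no retained pair of SNPs has dosage r^2 above 0.8, keeping the SNP
with the strongest disease association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MatchedSet


@dataclass(frozen=True)
class QcThresholds:
    sample_call_rate: float = 0.90
    snp_maf_analysis: float = 0.01
    snp_maf_selection: float = 0.05
    hwe_alpha: float = 0.0007
    ld_r2_max: float = 0.8
    hwe_method: str = "chisq"  # or "exact"

    def __post_init__(self):
        for name in ("sample_call_rate", "snp_maf_analysis", "snp_maf_selection", "hwe_alpha", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")


@dataclass
class QcReport:
    """Audit trail of QC: what was dropped and why, plus per-SNP statistics."""

    dropped_subjects: dict[str, str] = field(default_factory=dict)
    dropped_sets: list[int] = field(default_factory=list)
    dropped_snps: dict[str, str] = field(default_factory=dict)
    snp_stats: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("subject", k, v) for k, v in self.dropped_subjects.items()]
        rows += [("set", str(s), "case or too few controls removed") for s in self.dropped_sets]
        rows += [("snp", k, v) for k, v in self.dropped_snps.items()]
        return pd.DataFrame(rows, columns=["item_type", "item_id", "reason"])


class HweResult(NamedTuple):
    chi2: float
    p_value: float
    testable: bool


def call_rate(genotypes: pd.DataFrame) -> pd.Series:
    """Fraction of non-missing genotype calls per subject."""
    return genotypes.notna().mean(axis=1)


def sample_call_rate_filter(
    genotypes: pd.DataFrame,
    matched_sets: list[MatchedSet],
    threshold: float = 0.90,
    report: QcReport | None = None,
) -> tuple[pd.DataFrame, list[MatchedSet], QcReport]:
    """Remove subjects whose call rate falls below ``threshold``.

    A failing case takes its entire matched set with it; a failing control is
    removed alone, and the set is dropped only when fewer than one control
    remains.  Returns the filtered genotypes (restricted to subjects still in
    a set), surviving sets and the QC report.
    """
    report = report or QcReport()
    members = {m for s in matched_sets for m in (s.case_id, *s.control_ids)}
    unknown = members - set(genotypes.index)
    if unknown:
        raise KeyError(f"matched sets reference subjects absent from genotypes: {sorted(unknown)[:5]}")

    rate = call_rate(genotypes)
    failing = set(rate.index[rate < threshold])
    for sid in failing & members:
        report.dropped_subjects[sid] = f"call rate {rate[sid]:.3f} < {threshold}"

    kept_sets: list[MatchedSet] = []
    for s in matched_sets:
        if s.case_id in failing:
            report.dropped_sets.append(s.set_id)
            continue
        controls = tuple(c for c in s.control_ids if c not in failing)
        if len(controls) < 1:
            report.dropped_sets.append(s.set_id)
        else:
            kept_sets.append(MatchedSet(s.set_id, s.case_id, controls))
    surviving = {m for s in kept_sets for m in (s.case_id, *s.control_ids)}
    filtered = genotypes.loc[genotypes.index.isin(surviving)]
    return filtered, kept_sets, report


def effect_allele_frequency(dosages) -> float:
    """Effect-allele frequency from 0/1/2 dosages, ignoring missing."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; frequency undefined")
    return float(d.sum() / (2 * d.size))


def minor_allele_frequency(dosages) -> float:
    """MAF = min(p, 1-p) of the effect-allele frequency p."""
    p = effect_allele_frequency(dosages)
    return min(p, 1.0 - p)


def genotype_counts(dosages) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) counts = dosage (0, 1, 2) counts, missing ignored."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_chisq_test(counts: tuple[int, int, int]) -> HweResult:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    The allele frequency is estimated from the counts themselves; monomorphic
    SNPs are flagged not-testable (chi2 and P are NaN).
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(np.nan, np.nan, False)
    q = 1 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)), True)


def hwe_exact_test(counts: tuple[int, int, int]) -> HweResult:
    """Exact Hardy-Weinberg test (two-sided, by heterozygote-count probability).

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts.
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    n_b = 2 * n_bb + n_ab  # rarer-or-not allele count; symmetric below
    n_a = 2 * n - n_b
    if n_b == 0 or n_a == 0:
        return HweResult(np.nan, np.nan, False)
    n_minor = min(n_a, n_b)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(n_het) ∝ n_het log 2 + log n! - log-factorials of genotype counts
    from scipy.special import gammaln

    hom_minor = (n_minor - hets) // 2
    hom_major = (2 * n - n_minor - hets) // 2
    logp = (
        hets * np.log(2)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_ab]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_value = float(prob[prob <= obs[0] + 1e-12].sum())
    return HweResult(np.nan, min(1.0, p_value), True)


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed on subjects non-missing for both SNPs; raises when fewer than
    two such subjects remain or either vector is constant.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two subjects non-missing for both SNPs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero dosage variance; LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: pd.DataFrame,
    priority: pd.Series,
    r2_max: float = 0.8,
    r2: pd.DataFrame | None = None,
) -> list[str]:
    """Greedy LD pruning: keep the most significant SNP of each correlated group.

    SNPs are visited in ascending order of ``priority`` (association P value);
    a SNP is kept iff its r^2 with every already-kept SNP is <= ``r2_max``.
    Pairwise r^2 comes from the dosage columns, or from a precomputed
    symmetric matrix ``r2`` (e.g. reference-panel LD).  Pairs whose r^2 is
    undefined (monomorphic) never block retention.
    """
    snps = list(genotypes.columns) if r2 is None else list(r2.columns)
    missing = set(snps) - set(priority.index)
    if missing:
        raise KeyError(f"priority missing for SNPs: {sorted(missing)[:5]}")
    kept: list[str] = []
    for rsid in priority.loc[snps].sort_values(kind="stable").index:
        ok = True
        for other in kept:
            try:
                pair = ld_r2(genotypes[rsid], genotypes[other]) if r2 is None else float(r2.loc[rsid, other])
                if pair > r2_max:
                    ok = False
                    break
            except ValueError:
                continue
        if ok:
            kept.append(rsid)
    return [c for c in snps if c in kept]


def snp_filters(
    genotypes: pd.DataFrame,
    control_ids,
    thresholds: QcThresholds = QcThresholds(),
    report: QcReport | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop SNPs failing the analysis MAF threshold or HWE in controls.

    MAF is computed on all subjects (cases + controls); the HWE test runs on
    control genotypes only.  Per-SNP statistics land in the report.
    """
    report = report or QcReport()
    controls = genotypes.loc[genotypes.index.isin(set(control_ids))]
    hwe_fn = hwe_exact_test if thresholds.hwe_method == "exact" else hwe_chisq_test

    stats_rows = []
    drop = {}
    for rsid in genotypes.columns:
        col = genotypes[rsid]
        rate = float(col.notna().mean())
        maf = minor_allele_frequency(col) if col.notna().any() else np.nan
        hwe = hwe_fn(genotype_counts(controls[rsid]))
        stats_rows.append((rsid, rate, maf, hwe.chi2, hwe.p_value))
        if not np.isfinite(maf) or maf < thresholds.snp_maf_analysis:
            drop[rsid] = f"MAF {maf:.4f} < {thresholds.snp_maf_analysis}"
        elif hwe.testable and hwe.p_value < thresholds.hwe_alpha:
            drop[rsid] = f"HWE P {hwe.p_value:.2e} < {thresholds.hwe_alpha} in controls"
    report.dropped_snps.update(drop)
    report.snp_stats = pd.DataFrame(
        stats_rows, columns=["rsid", "call_rate", "maf", "hwe_chi2", "hwe_p"]
    )
    return genotypes.drop(columns=list(drop)), report


def apply_qc(
    genotypes: pd.DataFrame,
    matched_sets: list[MatchedSet],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, list[MatchedSet], QcReport]:
    """Full QC pass: sample call rate, then SNP MAF and HWE filters."""
    report = QcReport()
    genotypes, matched_sets, report = sample_call_rate_filter(
        genotypes, matched_sets, thresholds.sample_call_rate, report
    )
    control_ids = {c for s in matched_sets for c in s.control_ids}
    genotypes, report = snp_filters(genotypes, control_ids, thresholds, report)
    return genotypes, matched_sets, report
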