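"""End-to-end orchestration: simulate -> QC -> associate -> pool -> score ->
project risk -> reclassify, plus the SNP-subset experiment.

Each stage is independently reproducible: the single configured seed fans out
to per-stage child seeds by fixed offsets.  Every acceptance-relevant number
is echoed into the run report and, when an output directory is given, all
intermediate tables are written as TSV alongside a key=value run log.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, meta, published, qc, reclassify, risk, simulate
from .association import (
    ClogitDesign,
    build_design,
    clogit_fit,
    per_snp_association,
    trend_test,
)

logger = logging.getLogger(__name__)

BASE_MODEL_TERMS = [
    "education",
    "age_first_birth",
    "age_menarche",
    "family_history",
    "biopsy_history",
    "bmi_cat",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 5000
    followup_years: float = 15.0
    baseline_hazard: float = 0.002
    genotype_missing_rate: float = 0.02
    k_studies: int = 3
    heterogeneous_snps: tuple = ()
    heterogeneity_sd: float = 0.3
    het_threshold: float = 0.007
    weight_scheme: str = "inverse_variance"
    missing_policy: str = "expected"
    overrides: tuple = ()
    qc_thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    model_terms: list = field(default_factory=lambda: list(BASE_MODEL_TERMS))
    t_horizon: float = 5.0
    n_boot: int = 200
    snp_subsets: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_raw = raw.pop("qc_thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if qc_raw:
            cfg.qc_thresholds = qc.QcThresholds(**qc_raw)
        for name in ("heterogeneous_snps", "overrides", "snp_subsets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class RunReport:
    """Per-stage record counts and the headline results of a pipeline run."""

    seed: int
    n_cohort: int = 0
    n_ever_cases: int = 0
    n_sets_sampled: int = 0
    n_sets_qc: int = 0
    n_snps_input: int = 0
    n_snps_qc: int = 0
    n_cases: int = 0
    n_controls: int = 0
    s5: float = np.nan
    qc_report: qc.QcReport | None = None
    association: pd.DataFrame | None = None
    pooled: pd.DataFrame | None = None
    grs_boundaries: tuple | None = None
    quartile_or: pd.DataFrame | None = None
    trend: tuple | None = None
    fit_without: object = None
    fit_with: object = None
    nri: reclassify.NriResult | None = None
    subset_summary: pd.DataFrame | None = None


def analysis_table(
    cohort: pd.DataFrame,
    membership: pd.DataFrame,
    grs_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Subject-level analysis frame: one row per matched-set member."""
    df = membership.merge(cohort, on="subject_id", how="left", validate="m:1")
    if grs_scores is not None:
        cols = ["subject_id", "normalized_score"] + (
            ["quartile"] if "quartile" in grs_scores else []
        )
        df = df.merge(grs_scores[cols], on="subject_id", how="left", validate="m:1")
        if "quartile" in df:
            df["grs_quartile"] = df["quartile"].astype(int).astype(str)
    return df


def fit_informative(frame: pd.DataFrame, terms):
    """Fit a conditional-logistic model, dropping unestimable terms.

    Indicator levels with no within-set variation, or so sparse that they
    quasi-separate the sets (the likelihood diverges), cannot be estimated
    from a small matched sample; they are removed with a warning rather than
    aborting the whole pipeline (or a bootstrap replicate).
    """
    from .association import SeparationError

    design = build_design(frame, terms)

    def _subset(design, keep_mask):
        return ClogitDesign(
            design.x[:, keep_mask], design.set_ids, design.is_case,
            [t for t, ok in zip(design.terms, keep_mask) if ok],
        )

    info = design.informative_terms()
    if not info.all():
        logger.warning(
            "dropping terms without within-set variation: %s",
            [t for t, ok in zip(design.terms, info) if not ok],
        )
        design = _subset(design, info)
    while True:
        try:
            fit = clogit_fit(design)
            break
        except SeparationError as err:
            keep = np.array([t not in err.offending for t in design.terms])
            if not keep.any():
                raise
            logger.warning("dropping quasi-separated terms: %s", err.offending)
            design = _subset(design, keep)
    return fit, risk.control_means(design), design.terms, design


def fit_both_models(frame: pd.DataFrame, model_terms, s5: float):
    """Fit the without- and with-GRS conditional-logistic models on ``frame``.

    Returns (fit_without, fit_with, evaluate) where ``evaluate(other)`` bands
    any frame under both fitted models (coefficients and control means from
    ``frame``) and returns its NRI.
    """
    terms_without = list(model_terms)
    terms_with = terms_without + ["grs_quartile"]
    fit_w, mu_w, kept_w, _ = fit_informative(frame, terms_without)
    fit_g, mu_g, kept_g, _ = fit_informative(frame, terms_with)

    def bands_for(other: pd.DataFrame):
        dw = build_design(other, terms_without)
        dg = build_design(other, terms_with)
        iw = [dw.terms.index(t) for t in kept_w]
        ig = [dg.terms.index(t) for t in kept_g]
        cw = risk.relative_index(dw.x[:, iw], fit_w.beta, mu_w)
        cg = risk.relative_index(dg.x[:, ig], fit_g.beta, mu_g)
        bw = risk.five_year_risk(s5, cw)["band"].to_numpy()
        bg = risk.five_year_risk(s5, cg)["band"].to_numpy()
        return bw, bg, dw.is_case

    def evaluate(other: pd.DataFrame) -> float:
        bw, bg, is_case = bands_for(other)
        return reclassify.nri_components(
            reclassify.build_reclass_table(bw[is_case], bg[is_case]),
            reclassify.build_reclass_table(bw[~is_case], bg[~is_case]),
        ).nri

    return fit_w, fit_g, bands_for, evaluate


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute every stage in order on a synthetic cohort."""
    report = RunReport(seed=config.seed)
    out = io.ensure_dir(outdir) if outdir is not None else None

    # stage 1: cohort simulation
    params = simulate.CohortParams(
        n_subjects=config.n_subjects,
        followup_years=config.followup_years,
        baseline_hazard=config.baseline_hazard,
        genotype_missing_rate=config.genotype_missing_rate,
        seed=config.seed,
    )
    cohort, genotypes = simulate.simulate_cohort(params)
    report.n_cohort = len(cohort)
    report.n_ever_cases = int((cohort["case_status"] == "case").sum())
    report.n_snps_input = genotypes.shape[1]
    if report.n_ever_cases == 0:
        raise RuntimeError("simulation produced no cases; raise baseline_hazard")

    # stage 2: nested case-control sampling
    sets = simulate.sample_nested_case_control(cohort, simulate.MatchingSpec(), config.seed + 1)
    report.n_sets_sampled = len(sets)

    # stage 3: QC
    genotypes_qc, sets, qc_report = qc.apply_qc(genotypes, sets, config.qc_thresholds)
    report.qc_report = qc_report
    report.n_sets_qc = len(sets)
    report.n_snps_qc = genotypes_qc.shape[1]
    if report.n_sets_qc == 0 or report.n_snps_qc == 0:
        raise RuntimeError("QC removed every set or every SNP; nothing to analyse")
    membership = simulate.matched_sets_frame(sets)
    report.n_cases = int((membership["role"] == "case").sum())
    report.n_controls = int((membership["role"] == "control").sum())

    # stage 4: per-SNP association in the matched sample
    assoc = per_snp_association(genotypes_qc, membership)
    report.association = assoc

    # stage 5: meta-analytic pooling with the local study
    specs = [s for s in params.snp_panel if s.rsid in set(genotypes_qc.columns)]
    studies = simulate.simulate_published_studies(
        specs,
        k_studies=config.k_studies,
        heterogeneous_snps=tuple(r for r in config.heterogeneous_snps if r in genotypes_qc.columns),
        seed=config.seed + 2,
        heterogeneity_sd=config.heterogeneity_sd,
    )
    local = assoc.dropna(subset=["beta"])[["rsid", "beta", "se"]].assign(study_id="local")
    studies = pd.concat([studies, local], ignore_index=True)
    pooled = meta.pool_studies(studies, config.weight_scheme)
    pooled = meta.select_grs_snps(
        pooled, config.het_threshold, tuple(r for r in config.overrides if r in set(pooled["rsid"]))
    )
    report.pooled = pooled

    # stage 6: genetic risk score with control-based quartiles
    control_ids = set(membership.loc[membership["role"] == "control", "subject_id"])
    local_betas = assoc.set_index("rsid")["beta"]
    grs = meta.compute_grs(
        genotypes_qc, pooled, local_betas, control_ids, config.missing_policy
    )
    sample_ids = set(membership["subject_id"])
    grs.scores = grs.scores[grs.scores["subject_id"].isin(sample_ids)].reset_index(drop=True)
    grs = meta.grs_quartiles(grs, control_ids)
    report.grs_boundaries = grs.quartile_boundaries

    # stage 7: biopsy imputation and analysis frame
    sample_cohort = cohort[cohort["subject_id"].isin(sample_ids)].copy()
    completed, _ = risk.impute_biopsy(sample_cohort, seed=config.seed + 3)
    sample_cohort["biopsy_history"] = completed
    frame = analysis_table(sample_cohort, membership, grs.scores)

    # GRS-quartile association (crude) and trend
    quart_design = build_design(frame, ["grs_quartile"])
    report.quartile_or = clogit_fit(quart_design).summary()
    report.trend = trend_test(frame, "grs_quartile")

    # stage 8: survival and absolute risk
    times = np.fmin(cohort["diagnosis_time"], config.followup_years).fillna(
        config.followup_years
    )
    curve = risk.kaplan_meier(times, cohort["case_status"] == "case")
    s5 = curve.at(config.t_horizon)
    report.s5 = s5

    fit_w, fit_g, bands_for, evaluate = fit_both_models(frame, config.model_terms, s5)
    report.fit_without, report.fit_with = fit_w, fit_g
    bw, bg, is_case = bands_for(frame)
    nri = reclassify.nri_from_bands(bw, bg, is_case)

    # stage 9: bootstrap optimism correction
    if config.n_boot:
        def fit_procedure(train):
            return fit_both_models(train, config.model_terms, s5)[3]

        apparent, optimism, corrected, n_ok = reclassify.bootstrap_optimism(
            frame, fit_procedure, b=config.n_boot, seed=config.seed + 4
        )
        nri.apparent_nri, nri.optimism, nri.corrected_nri, nri.n_boot = (
            apparent,
            optimism,
            corrected,
            n_ok,
        )
    report.nri = nri

    # stage 10: SNP-subset experiment
    if config.snp_subsets:
        report.subset_summary = subset_snp_experiment(
            frame, genotypes_qc, pooled, local_betas, control_ids,
            config.model_terms, s5, config.snp_subsets, config.missing_policy,
        )

    if out is not None:
        _write_outputs(out, config, report, cohort, genotypes_qc, sets, frame, curve)
    return report


def subset_snp_experiment(
    frame: pd.DataFrame,
    genotypes: pd.DataFrame,
    pooled: pd.DataFrame,
    local_betas: pd.Series,
    control_ids,
    model_terms,
    s5: float,
    subset_sizes,
    missing_policy: str = "expected",
    snp_order: list[str] | None = None,
) -> pd.DataFrame:
    """Model discrimination as the SNP panel grows.

    For each subset size the score is recomputed from the first k SNPs of
    ``snp_order`` (default: included SNPs in panel order), the with-GRS model
    is refitted and the case/control difference in mean log five-year risk is
    reported; size 0 is the model without any genetic component.
    """
    included = pooled[pooled["included_in_grs"]]
    order = snp_order or [r for r in genotypes.columns if r in set(included["rsid"])]
    if any(k > len(order) for k in subset_sizes):
        raise ValueError("subset size exceeds available panel")
    if sorted(subset_sizes) != list(subset_sizes):
        logger.warning("subset sizes are not nested in increasing order")

    rows = []
    for k in subset_sizes:
        sub_frame = frame.copy()
        if k == 0:
            fit, mu, _, design = fit_informative(sub_frame, list(model_terms))
            c = risk.relative_index(design.x, fit.beta, mu)
            is_case = design.is_case
        else:
            chosen = order[:k]
            sub_pooled = pooled[pooled["rsid"].isin(chosen)]
            grs = meta.compute_grs(
                genotypes[chosen], sub_pooled, local_betas, control_ids, missing_policy
            )
            grs.scores = grs.scores[
                grs.scores["subject_id"].isin(set(frame["subject_id"]))
            ].reset_index(drop=True)
            grs = meta.grs_quartiles(grs, control_ids)
            sub_frame = sub_frame.drop(
                columns=[c for c in ("normalized_score", "quartile", "grs_quartile") if c in sub_frame]
            ).merge(grs.scores, on="subject_id", how="left", validate="m:1")
            sub_frame["grs_quartile"] = sub_frame["quartile"].astype(int).astype(str)
            fit, mu, _, design = fit_informative(
                sub_frame, list(model_terms) + ["grs_quartile"]
            )
            c = risk.relative_index(design.x, fit.beta, mu)
            is_case = design.is_case
        p5 = risk.five_year_risk(s5, c)["p5"].to_numpy()
        logp = np.log(np.clip(p5, 1e-12, None))
        rows.append(
            (k, float(logp[is_case].mean()), float(logp[~is_case].mean()),
             float(logp[is_case].mean() - logp[~is_case].mean()))
        )
    return pd.DataFrame(
        rows, columns=["n_snps", "mean_log_p5_cases", "mean_log_p5_controls", "difference"]
    )


def _write_outputs(out: Path, config, report, cohort, genotypes, sets, frame, curve):
    io.write_phenotypes_tsv(cohort, out / "phenotypes.tsv")
    io.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
    io.write_matched_sets_tsv(sets, out / "matched_sets.tsv")
    report.qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    report.association.to_csv(out / "association.tsv", sep="\t", index=False)
    report.pooled.to_csv(out / "pooled_effects.tsv", sep="\t", index=False)
    frame.to_csv(out / "analysis_frame.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"t": curve.event_times, "at_risk": curve.at_risk, "events": curve.events,
         "survival": curve.survival}
    ).to_csv(out / "survival_curve.tsv", sep="\t", index=False)
    if report.subset_summary is not None:
        report.subset_summary.to_csv(out / "subset_experiment.tsv", sep="\t", index=False)
    nri = report.nri
    lines = [f"seed={config.seed}", f"n_cohort={report.n_cohort}",
             f"n_ever_cases={report.n_ever_cases}", f"n_sets_sampled={report.n_sets_sampled}",
             f"n_sets_qc={report.n_sets_qc}", f"n_snps_qc={report.n_snps_qc}",
             f"n_cases={report.n_cases}", f"n_controls={report.n_controls}",
             f"s5={report.s5:.6f}"]
    if nri is not None:
        lines += [f"nri={nri.nri:.6f}", f"case_component={nri.case_component:.6f}",
                  f"control_component={nri.control_component:.6f}"]
        if nri.corrected_nri is not None:
            lines += [f"optimism={nri.optimism:.6f}", f"corrected_nri={nri.corrected_nri:.6f}"]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
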