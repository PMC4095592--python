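"""Synthetic nested case-control cohort generator.

Emulates a population-based cohort of Chinese women aged 45-74 followed for
incident breast cancer, with SNP- and covariate-driven hazards, and draws a
1:3 risk-set-sampled nested case-control study from it: for each incident
case, controls are selected among cohort members still free of breast cancer
at the case's (calendar) diagnosis date and matched on age at enrollment
(±3 years), dialect group, menopausal status, date of enrollment (±2 years)
and date of blood draw (±6 months).

The generator's defaults reproduce the source study's conditions: the 51-SNP
panel with its published control risk-allele frequencies, true per-allele
effects equal to the published pooled odds ratios, and covariate category
frequencies equal to the published control distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

EDUCATION_LEVELS = ["none", "primary", "secondary"]
AGE_FIRST_BIRTH_LEVELS = ["<20", "20-24", "25-29/null", ">=30"]
AGE_MENARCHE_LEVELS = [">=14", "12-13", "<12"]
BMI_LEVELS = ["<20", "20-<24", "24-<28", ">=28"]
ESTROGEN_LEVELS = ["non", "ex", "current"]
DIALECTS = ["Hokkien", "Cantonese"]


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: identifier, effect allele, control risk-allele
    frequency and the true per-allele log odds ratio used in simulation."""

    rsid: str
    effect_allele: str
    raf: float
    true_log_or: float

    def __post_init__(self):
        if not 0.0 < self.raf < 1.0:
            raise ValueError(f"{self.rsid}: risk-allele frequency must be in (0,1), got {self.raf}")


@dataclass
class CohortParams:
    """Parameters of the simulated cohort.

    baseline_hazard is in events per person-year for a woman with zero risk
    alleles and reference-level covariates.  The default panel carries the
    published pooled odds ratios as true effects; covariate_effects maps
    covariate name -> {level: log OR} with the reference level at 0.
    """

    n_subjects: int = 5000
    followup_years: float = 15.0
    baseline_hazard: float = 0.002
    snp_panel: list[SnpSpec] = field(default_factory=lambda: default_snp_specs())
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: default_covariate_effects()
    )
    genotype_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 100:
            raise ValueError("n_subjects must be at least 100")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if not 0 <= self.genotype_missing_rate < 1:
            raise ValueError("genotype_missing_rate must be in [0,1)")


@dataclass(frozen=True)
class MatchingSpec:
    """Matching rules for risk-set sampling of controls."""

    age_caliper_years: float = 3.0
    enrollment_caliper_days: float = 2 * DAYS_PER_YEAR
    blood_draw_caliper_days: float = 183.0
    exact_factors: tuple[str, ...] = ("dialect", "menopausal_status")
    ratio: int = 3

    def __post_init__(self):
        if min(self.age_caliper_years, self.enrollment_caliper_days, self.blood_draw_caliper_days) <= 0:
            raise ValueError("calipers must be positive")
        if self.ratio < 1:
            raise ValueError("ratio must be at least 1")


@dataclass(frozen=True)
class MatchedSet:
    """One case and its matched controls (subject ids into the cohort table).

    The sampler always emits 2-3 controls per set; downstream QC may leave a
    set with a single control, which is still informative for the conditional
    likelihood, so the type tolerates 1-3.
    """

    set_id: int
    case_id: str
    control_ids: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.control_ids) <= 3:
            raise ValueError("a matched set needs 1 to 3 controls")


def default_snp_specs() -> list[SnpSpec]:
    """SnpSpecs for the published 51-SNP panel.

    True log odds ratios are log pooled ORs; for the one SNP without an
    applicable pooled OR (rs11242675) the local estimate is used.
    """
    panel = published.snp_panel()
    ors = panel["or_pooled"].fillna(panel["or_local"])
    return [
        SnpSpec(r.rsid, r.effect_allele, float(r.raf_controls), float(np.log(o)))
        for r, o in zip(panel.itertuples(), ors)
    ]


def default_covariate_effects() -> dict[str, dict[str, float]]:
    """Generating covariate log odds ratios (reference level = 0).

    Magnitudes follow the published multivariable estimates: later age at
    first birth, earlier menarche, family history, past biopsy, high BMI and
    current estrogen use all raise the hazard.
    """
    ln = np.log
    return {
        "education": {"none": 0.0, "primary": ln(1.2), "secondary": ln(1.4)},
        "age_first_birth": {"<20": 0.0, "20-24": ln(1.05), "25-29/null": ln(1.5), ">=30": ln(1.5)},
        "age_menarche": {">=14": 0.0, "12-13": ln(1.2), "<12": ln(1.2)},
        "family_history": {"no": 0.0, "yes": ln(1.8)},
        "biopsy_history": {"no": 0.0, "yes": ln(1.4)},
        "bmi_cat": {"<20": 0.0, "20-<24": ln(1.15), "24-<28": ln(1.15), ">=28": ln(1.9)},
        "estrogen": {"non": 0.0, "ex": 0.0, "current": ln(1.5)},
    }


def bmi_category(bmi: np.ndarray | pd.Series) -> np.ndarray:
    """Map continuous BMI (kg/m^2) onto the four analysis categories."""
    idx = np.digitize(np.asarray(bmi, dtype=float), [20.0, 24.0, 28.0])
    return np.asarray(BMI_LEVELS, dtype=object)[idx]


def _draw_categorical(rng, levels, probs, n):
    probs = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs / probs.sum())


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort table and its genotype dosage matrix.

    Returns (cohort, genotypes).  cohort has one row per subject with the
    demographic, reproductive and anthropometric covariates; genotypes is a
    subjects x SNPs DataFrame of 0/1/2 effect-allele dosages with NaN for
    missing calls.  Time to breast-cancer diagnosis is exponential with rate
    baseline_hazard * exp(sum of SNP and covariate log odds ratios); subjects
    diagnosed within followup_years are ever-cases.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    dist = published.CONTROL_COVARIATE_DISTRIBUTIONS

    subject_id = np.array([f"S{i:05d}" for i in range(1, n + 1)])
    age = np.clip(rng.normal(54.9, 7.5, n), 45.0, 74.0).round(1)
    dialect = _draw_categorical(rng, DIALECTS, [0.6, 0.4], n)
    menopause_age = rng.normal(49.5, 4.3, n)
    menopausal = np.where(age >= menopause_age, "post", "pre").astype(object)
    enrollment = rng.integers(0, int(5 * DAYS_PER_YEAR), n)
    blood_draw = enrollment + rng.integers(183, 2922, n)

    cov = {
        "education": _draw_categorical(rng, EDUCATION_LEVELS, list(dist["education"].values()), n),
        "age_first_birth": _draw_categorical(
            rng, AGE_FIRST_BIRTH_LEVELS, list(dist["age_first_birth"].values()), n
        ),
        "age_menarche": _draw_categorical(
            rng, AGE_MENARCHE_LEVELS, list(dist["age_menarche"].values()), n
        ),
        "family_history": _draw_categorical(
            rng, ["no", "yes"], list(dist["family_history"].values()), n
        ),
        "estrogen": _draw_categorical(rng, ESTROGEN_LEVELS, list(dist["estrogen"].values()), n),
    }
    bmi = np.clip(
        rng.normal(published.CONTROL_BMI_MEAN, published.CONTROL_BMI_SD, n), 15.0, 40.0
    ).round(1)
    bmi_cat = bmi_category(bmi)
    biopsy_true = _draw_categorical(rng, ["no", "yes"], list(dist["biopsy_history"].values()), n)
    biopsy_observed = rng.random(n) < published.BIOPSY_OBSERVED_FRACTION
    biopsy = np.where(biopsy_observed, biopsy_true, "missing").astype(object)

    rafs = np.array([s.raf for s in params.snp_panel])
    betas = np.array([s.true_log_or for s in params.snp_panel])
    dosage = rng.binomial(2, rafs, size=(n, len(rafs))).astype(float)

    linpred = dosage @ betas
    eff = params.covariate_effects
    for name, values in (
        ("education", cov["education"]),
        ("age_first_birth", cov["age_first_birth"]),
        ("age_menarche", cov["age_menarche"]),
        ("family_history", cov["family_history"]),
        ("estrogen", cov["estrogen"]),
        ("bmi_cat", bmi_cat),
        ("biopsy_history", biopsy_true),
    ):
        if name in eff:
            lookup = eff[name]
            linpred += np.array([lookup.get(v, 0.0) for v in values])

    # centre the linear predictor so baseline_hazard sets the cohort-level
    # (geometric mean) hazard rather than the zero-dose reference hazard
    rate = params.baseline_hazard * np.exp(linpred - linpred.mean())
    t_event = rng.exponential(1.0 / rate)
    ever_case = t_event <= params.followup_years
    diagnosis_time = np.where(ever_case, t_event, np.nan)

    if params.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < params.genotype_missing_rate
        dosage[miss] = np.nan

    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "case_status": np.where(ever_case, "case", "control"),
            "age_at_enrollment": age,
            "dialect": dialect,
            "menopausal_status": menopausal,
            "enrollment_date": enrollment,
            "blood_draw_date": blood_draw,
            "diagnosis_time": diagnosis_time,
            "education": cov["education"],
            "age_first_birth": cov["age_first_birth"],
            "age_menarche": cov["age_menarche"],
            "family_history": cov["family_history"],
            "biopsy_history": biopsy,
            "bmi": bmi,
            "bmi_cat": bmi_cat,
            "estrogen": cov["estrogen"],
        }
    )
    genotypes = pd.DataFrame(
        dosage, index=pd.Index(subject_id, name="subject_id"), columns=[s.rsid for s in params.snp_panel]
    )
    return cohort, genotypes


def sample_nested_case_control(
    cohort: pd.DataFrame, spec: MatchingSpec = MatchingSpec(), seed: int = 0
) -> list[MatchedSet]:
    """Risk-set sample matched controls for every ever-case.

    Controls must be free of breast cancer at the index case's calendar
    diagnosis date and satisfy all calipers and exact matching factors; up to
    ``spec.ratio`` controls are drawn uniformly without replacement within a
    set (a subject may serve as control for more than one case, and a future
    case may act as an earlier case's control, as risk-set sampling demands).
    Cases with fewer than two eligible controls are dropped with a warning.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cases = cohort[cohort["case_status"] == "case"]
    if len(cases) == 0:
        raise ValueError("cohort contains no cases")

    rng = np.random.default_rng(seed)
    diag_cal = cohort["enrollment_date"].to_numpy(float) + cohort[
        "diagnosis_time"
    ].to_numpy(float) * DAYS_PER_YEAR  # NaN for never-cases

    age = cohort["age_at_enrollment"].to_numpy(float)
    enroll = cohort["enrollment_date"].to_numpy(float)
    blood = cohort["blood_draw_date"].to_numpy(float)
    ids = cohort["subject_id"].to_numpy()
    exact = {f: cohort[f].to_numpy() for f in spec.exact_factors}

    case_rows = np.flatnonzero(cohort["case_status"].to_numpy() == "case")
    case_rows = case_rows[np.argsort(diag_cal[case_rows], kind="stable")]

    sets: list[MatchedSet] = []
    set_id = 0
    for i in case_rows:
        free = ~(diag_cal <= diag_cal[i])  # NaN-safe: never-cases are free
        ok = (
            free
            & (np.abs(age - age[i]) <= spec.age_caliper_years)
            & (np.abs(enroll - enroll[i]) <= spec.enrollment_caliper_days)
            & (np.abs(blood - blood[i]) <= spec.blood_draw_caliper_days)
        )
        for f, vals in exact.items():
            ok &= vals == vals[i]
        ok[i] = False
        eligible = np.flatnonzero(ok)
        if len(eligible) < 2:
            logger.warning(
                "case %s dropped: only %d eligible controls", ids[i], len(eligible)
            )
            continue
        k = min(spec.ratio, len(eligible))
        chosen = rng.choice(eligible, size=k, replace=False)
        set_id += 1
        sets.append(MatchedSet(set_id, ids[i], tuple(ids[j] for j in sorted(chosen))))
    return sets


def matched_sets_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format membership table: one row per subject per set."""
    rows = []
    for s in sets:
        rows.append((s.set_id, s.case_id, "case"))
        rows.extend((s.set_id, c, "control") for c in s.control_ids)
    return pd.DataFrame(rows, columns=["set_id", "subject_id", "role"])


def simulate_published_studies(
    snp_panel: list[SnpSpec],
    k_studies: int = 3,
    heterogeneous_snps: tuple[str, ...] = (),
    seed: int = 0,
    heterogeneity_sd: float = 0.3,
    se_range: tuple[float, float] = (0.03, 0.08),
) -> pd.DataFrame:
    """Per-SNP effect tables emulating previously published studies.

    Homogeneous SNPs report the same true log OR in every study; SNPs named
    in ``heterogeneous_snps`` get study-specific log ORs spread
    N(0, heterogeneity_sd^2) around the truth.  Standard errors are drawn
    uniformly from ``se_range``.
    """
    if k_studies < 1:
        raise ValueError("k_studies must be at least 1")
    rng = np.random.default_rng(seed)
    het = set(heterogeneous_snps)
    unknown = het - {s.rsid for s in snp_panel}
    if unknown:
        raise ValueError(f"heterogeneous_snps not in panel: {sorted(unknown)}")
    rows = []
    for s in snp_panel:
        for k in range(1, k_studies + 1):
            beta = s.true_log_or
            if s.rsid in het:
                beta = beta + rng.normal(0.0, heterogeneity_sd)
            se = rng.uniform(*se_range)
            rows.append((s.rsid, f"study{k}", beta, se))
    return pd.DataFrame(rows, columns=["rsid", "study_id", "beta", "se"])
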