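"""Published inputs from the Singapore Chinese Health Study breast-cancer analysis.

This module holds the study-level numbers the rest of the package consumes as
*inputs*: the 51-SNP panel (risk-allele frequencies in controls and cases,
per-allele odds ratios with standard errors from the nested case-control
sample, pooled odds ratios from the fixed-effects meta-analysis with published
GWAS, and FDR-corrected heterogeneity P values), the printed case/control
reclassification count matrices for the five-year absolute-risk bands, and the
control-group covariate distributions used to parameterise the synthetic
cohort generator.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

#: Five-year absolute-risk bands, in percent, low to high.
RISK_BANDS = ["<1.0", "1.0-<1.5", "1.5-<2.0", "2.0-<2.5", ">=2.5"]

#: Upper band edges in percent (the last band is unbounded).
RISK_BAND_EDGES = np.array([1.0, 1.5, 2.0, 2.5])

#: SNPs removed from the genetic risk score for between-study heterogeneity.
HETEROGENEITY_EXCLUDED = ["rs11780156", "rs6504950", "rs6001930", "rs2981579"]

#: SNP kept in the score with its local (study) weight because no pooled OR
#: was applicable (significant heterogeneity but biological plausibility).
LOCAL_WEIGHT_OVERRIDES = ["rs11242675"]


def snp_panel() -> pd.DataFrame:
    """The 51-SNP panel with published frequencies and effect sizes.

    Returns a DataFrame with columns ``chrom, locus, rsid, effect_allele,
    raf_controls, raf_cases, or_local, se_local, p_local, or_pooled,
    p_het_fdr``.  ``or_pooled`` is NaN for rs11242675 (FOXQ1), for which a
    pooled OR was not applicable and the local estimate is used as the score
    weight.
    """
    path = files("bcrisk").joinpath("data/snp_panel.tsv")
    with path.open() as fh:
        panel = pd.read_csv(fh, sep="\t")
    return panel


# Reclassification counts for 411 cases and 1,212 controls.  Rows are the
# five-year risk band under the model without the genetic risk score, columns
# the band once the score is added; band order as in RISK_BANDS.
_CASE_RECLASS = [
    [109, 46, 0, 0, 0],
    [36, 123, 39, 0, 0],
    [0, 13, 19, 12, 0],
    [0, 0, 4, 2, 3],
    [0, 0, 0, 1, 4],
]
_CONTROL_RECLASS = [
    [511, 84, 0, 0, 0],
    [90, 356, 33, 0, 0],
    [0, 53, 50, 12, 0],
    [0, 0, 12, 3, 1],
    [0, 0, 0, 2, 5],
]


def reclassification_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published (case, control) 5x5 reclassification count matrices."""

    def _frame(counts):
        return pd.DataFrame(counts, index=RISK_BANDS, columns=RISK_BANDS, dtype=int)

    return _frame(_CASE_RECLASS), _frame(_CONTROL_RECLASS)


# Column totals as printed in the source table's "Total" row.  The case row
# equals the cell sums; the control row disagrees with the cells by one
# subject (printed 94/18 in the two upper-middle bands where the cells sum to
# 95/17) — an internal inconsistency of the published table.  The reported
# 2.0% of controls at >=2.0% five-year risk derives from this printed row.
RECLASS_BAND_TOTALS = {
    "case": pd.Series([145, 182, 62, 15, 7], index=RISK_BANDS),
    "control": pd.Series([601, 493, 94, 18, 6], index=RISK_BANDS),
}


# Control-group covariate distributions (proportions over the fixed category
# vocabularies), used as synthetic-cohort sampling marginals.
CONTROL_COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "education": {"none": 0.329, "primary": 0.427, "secondary": 0.243},
    "age_first_birth": {"<20": 0.175, "20-24": 0.378, "25-29/null": 0.343, ">=30": 0.104},
    "age_menarche": {">=14": 0.446, "12-13": 0.399, "<12": 0.155},
    "family_history": {"no": 0.987, "yes": 0.013},
    "biopsy_history": {"no": 0.984, "yes": 0.016},
    "estrogen": {"non": 0.933, "ex": 0.018, "current": 0.049},
}

#: Fraction of subjects with an observed (non-missing) biopsy history.
BIOPSY_OBSERVED_FRACTION = 0.132

#: Control BMI: mean and SD in kg/m^2.
CONTROL_BMI_MEAN = 23.2
CONTROL_BMI_SD = 3.2

#: Printed control quartile boundaries of the normalised genetic risk score.
GRS_CONTROL_QUARTILE_RANGE = (32.4, 65.8)
GRS_CONTROL_QUARTILE_BOUNDARIES = (43.6, 47.1, 50.6)
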