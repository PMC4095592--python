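"""Full pipeline: simulate, QC, associate, pool, score, project, reclassify.

Runs every stage on a synthetic cohort and prints the genetic-score quartile
odds ratios, the five-year-risk anchor and the optimism-corrected NRI.
"""

import logging
import warnings

from bcrisk.pipeline import PipelineConfig, run_pipeline

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore")

cfg = PipelineConfig(seed=1, n_subjects=5000, n_boot=200)
report = run_pipeline(cfg)

print(f"matched sample: {report.n_cases} cases, {report.n_controls} controls "
      f"({report.n_sets_qc} sets after QC); {report.n_snps_qc} SNPs")
print(f"five-year breast-cancer risk at the cohort average: "
      f"{100 * (1 - report.s5):.2f}%")

print("\nGRS quartile odds ratios (first quartile = reference):")
for _, row in report.quartile_or.iterrows():
    print(f"  {row.term}: {row['or']:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f})")
trend_or, ci, trend_p = report.trend
print(f"  per-quartile trend: {trend_or:.2f} (P = {trend_p:.1e})")

nri = report.nri
print(f"\nNRI adding the score to the Gail-variable model: {100 * nri.nri:.1f}%")
print(f"bootstrap optimism ({nri.n_boot} replicates): {100 * nri.optimism:.1f}%")
print(f"corrected NRI: {100 * nri.corrected_nri:.1f}%")
print(
    "\nA positive corrected NRI means genetics still improves five-year risk\n"
    "classification after discounting the refitting optimism."
)
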