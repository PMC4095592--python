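"""Tabular I/O: TSV tables and the PLINK-.raw-style genotype dialect.

All tables are tab-separated with a header row; missing genotype dosages are
written as "NA".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MatchedSet, matched_sets_frame


def write_genotypes_tsv(genotypes: pd.DataFrame, path):
    genotypes.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index("subject_id").astype(float)


def write_phenotypes_tsv(cohort: pd.DataFrame, path):
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_matched_sets_tsv(sets: list[MatchedSet], path):
    matched_sets_frame(sets).to_csv(path, sep="\t", index=False)


def read_matched_sets_tsv(path) -> list[MatchedSet]:
    df = pd.read_csv(path, sep="\t")
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        case = grp.loc[grp["role"] == "case", "subject_id"]
        controls = grp.loc[grp["role"] == "control", "subject_id"]
        if len(case) != 1:
            raise ValueError(f"set {set_id}: expected exactly one case")
        sets.append(MatchedSet(int(set_id), case.iloc[0], tuple(controls)))
    return sets


def write_plink_raw(genotypes: pd.DataFrame, path, effect_alleles: dict[str, str] | None = None):
    """Write dosages in the PLINK .raw additive dialect.

    Header: FID IID PAT MAT SEX PHENOTYPE rsid_A ...; one space-separated row
    per subject, dosage of the counted (effect) allele, NA for missing.
    """
    effect_alleles = effect_alleles or {}
    cols = [f"{rsid}_{effect_alleles.get(rsid, 'A')}" for rsid in genotypes.columns]
    with open(path, "w") as fh:
        fh.write(" ".join(["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE", *cols]) + "\n")
        for sid, row in genotypes.iterrows():
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in row.to_numpy(float)]
            fh.write(" ".join([str(sid), str(sid), "0", "0", "2", "-9", *vals]) + "\n")


def read_plink_raw(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read the PLINK .raw dialect; returns (dosages, effect alleles)."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise ValueError(f"not a PLINK .raw header: {list(df.columns[:6])}")
    snp_cols = df.columns[6:]
    alleles = {}
    renames = {}
    for col in snp_cols:
        rsid, _, allele = col.rpartition("_")
        if not rsid:
            raise ValueError(f"malformed dosage column {col!r}")
        alleles[rsid] = allele
        renames[col] = rsid
    geno = df.set_index(df["IID"].astype(str).rename("subject_id"))[snp_cols]
    geno = geno.rename(columns=renames).astype(float)
    return geno, alleles


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
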