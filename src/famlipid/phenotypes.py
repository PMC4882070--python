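"""Phenotype table: lipids, covariates, exclusion flags and affection status.

Columns: individual_id, family_id (empty for population samples), age, sex,
tc, ldl, tg, hdl (mmol/l), apob (mg/dl, optional NaN), diabetes, cancer,
lipid_med (exclusion flags), affected, subtype, proband.  Subtype is one of
"TC-only", "TG-only", "both", "none".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PHENO_COLUMNS = [
    "individual_id",
    "family_id",
    "age",
    "sex",
    "tc",
    "ldl",
    "tg",
    "hdl",
    "apob",
    "diabetes",
    "cancer",
    "lipid_med",
    "affected",
    "subtype",
    "proband",
]

SUBTYPES = ("TC-only", "TG-only", "both", "none")


class PhenotypeError(ValueError):
    """Raised when a phenotype table violates its invariants."""


def excluded_mask(pheno: pd.DataFrame) -> pd.Series:
    """Individuals excluded from affection calling and reference statistics:
    diabetes or cancer, or on lipid-lowering/estrogen medication."""
    return pheno["diabetes"] | pheno["cancer"] | pheno["lipid_med"]


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise PhenotypeError(f"phenotype table missing columns: {missing}")
    if pheno["individual_id"].duplicated().any():
        dups = pheno.loc[pheno["individual_id"].duplicated(), "individual_id"]
        raise PhenotypeError(f"duplicate individual ids: {dups.tolist()[:5]}")
    for col in ("tc", "ldl", "tg", "hdl"):
        neg = pheno[col] < 0
        if neg.any():
            raise PhenotypeError(
                f"negative {col} at rows {list(pheno.index[neg])[:5]}"
            )
    bad_sub = ~pheno["subtype"].isin(SUBTYPES)
    if bad_sub.any():
        raise PhenotypeError(
            f"unknown subtype at rows {list(pheno.index[bad_sub])[:5]}"
        )
    aff_none = pheno["affected"] & (pheno["subtype"] == "none")
    if aff_none.any():
        raise PhenotypeError(
            f"affected individuals with subtype 'none' at rows {list(pheno.index[aff_none])[:5]}"
        )
    aff_excl = pheno["affected"] & excluded_mask(pheno)
    if aff_excl.any():
        raise PhenotypeError(
            f"excluded individuals marked affected at rows {list(pheno.index[aff_excl])[:5]}"
        )
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno)
    out = pheno.copy()
    for col in ("age", "tc", "ldl", "tg", "hdl", "apob"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(
        path, sep="\t", dtype={"individual_id": str, "family_id": str}
    )
    unknown = [c for c in pheno.columns if c not in PHENO_COLUMNS]
    if unknown:
        raise PhenotypeError(f"unknown phenotype columns: {unknown}")
    for col in ("diabetes", "cancer", "lipid_med", "affected", "proband"):
        pheno[col] = pheno[col].astype(bool)
    for col in ("age", "tc", "ldl", "tg", "hdl", "apob"):
        pheno[col] = pd.to_numeric(pheno[col], errors="coerce")
    pheno["family_id"] = pheno["family_id"].where(pd.notna(pheno["family_id"]), None)
    return validate_phenotypes(pheno)


def subtype_counts_summary(n_tc_only: int, n_tg_only: int, n_both: int) -> pd.DataFrame:
    """Summary table from subtype counts: n and nearest-integer percent of
    all affected for each of TC-only / TG-only / both, plus the total row."""
    total = n_tc_only + n_tg_only + n_both
    rows = []
    for sub, n in (("TC-only", n_tc_only), ("TG-only", n_tg_only), ("both", n_both)):
        pct = int(np.round(100 * n / total)) if total else 0
        rows.append({"subtype": sub, "n": int(n), "percent": pct})
    rows.append({"subtype": "total", "n": int(total), "percent": 100 if total else 0})
    return pd.DataFrame(rows)


def subtype_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Counts and nearest-integer percentages of affected individuals by
    hyperlipidemia subtype (TC-only / TG-only / both)."""
    aff = pheno[pheno["affected"]]
    return subtype_counts_summary(
        int((aff["subtype"] == "TC-only").sum()),
        int((aff["subtype"] == "TG-only").sum()),
        int((aff["subtype"] == "both").sum()),
    )
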