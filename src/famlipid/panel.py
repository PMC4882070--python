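"""Variant panel: per-SNP metadata for the lipid score and OMIM variants.

The panel is a pandas DataFrame with one row per SNP and a fixed column
contract (see :data:`PANEL_COLUMNS`).  ``beta_ldl`` / ``beta_tg`` are signed
per-effect-allele effects (LDL-C in mmol/l, TG on the natural-log scale),
``maf`` is the population frequency of the effect allele, and frequency
classes follow the convention: common MAF > 5%, low-frequency
0.5% < MAF <= 5%, rare MAF <= 0.5%.
"""

from __future__ import annotations

import pandas as pd

PANEL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "maf",
    "beta_ldl",
    "beta_tg",
    "in_ldl_score",
    "in_tg_score",
    "omim",
    "freq_class",
]

FREQ_CLASSES = ("common", "low-frequency", "rare")


class PanelError(ValueError):
    """Raised when a variant panel violates its invariants."""


def frequency_class(maf: float) -> str:
    """Classify a minor-allele frequency as common / low-frequency / rare.

    Boundaries are inclusive on the low side of each class:
    rare: MAF <= 0.5%; low-frequency: 0.5% < MAF <= 5%; common: MAF > 5%.
    """
    if not 0 < maf <= 0.5:
        raise PanelError(f"MAF must lie in (0, 0.5], got {maf}")
    if maf <= 0.005:
        return "rare"
    if maf <= 0.05:
        return "low-frequency"
    return "common"


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate panel invariants, returning the panel unchanged.

    Checks: required columns; unique SNP ids; MAF in (0, 0.5]; effect and
    other allele differ; every SNP is in at least one score or OMIM-flagged;
    frequency class consistent with MAF.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelError(f"panel missing columns: {missing}")
    if panel["snp_id"].duplicated().any():
        dups = panel.loc[panel["snp_id"].duplicated(), "snp_id"].tolist()
        raise PanelError(f"duplicate SNP ids: {dups}")
    for i, row in panel.iterrows():
        if not 0 < row["maf"] <= 0.5:
            raise PanelError(f"row {i} ({row['snp_id']}): MAF {row['maf']} outside (0, 0.5]")
        if row["effect_allele"] == row["other_allele"]:
            raise PanelError(f"row {i} ({row['snp_id']}): effect and other allele identical")
        if not (row["in_ldl_score"] or row["in_tg_score"] or row["omim"]):
            raise PanelError(
                f"row {i} ({row['snp_id']}): belongs to no score and is not OMIM-flagged"
            )
        expected = frequency_class(row["maf"])
        if row["freq_class"] != expected:
            raise PanelError(
                f"row {i} ({row['snp_id']}): freq_class {row['freq_class']!r}, expected {expected!r}"
            )
    return panel


def read_panel(path) -> pd.DataFrame:
    """Read a variant panel from a TSV file and validate it."""
    panel = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    unknown = [c for c in panel.columns if c not in PANEL_COLUMNS]
    if unknown:
        raise PanelError(f"unknown panel columns: {unknown}")
    for col in ("in_ldl_score", "in_tg_score", "omim"):
        panel[col] = panel[col].astype(bool)
    return validate_panel(panel)


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, sep="\t", index=False)
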