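"""Weighted polygenic lipid scores.

Per-SNP weights are the coefficients of one multiple linear regression of
the trait on all score-member SNP dosages simultaneously (plus age and sex
covariates) in the unrelated reference population.  The score of an
individual is the weight-weighted sum of effect-allele dosages; missing
dosages are mean-imputed at 2xMAF.  "High" means at or above the empirical
90th percentile of the reference-population score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotypes import excluded_mask


class ScoreError(ValueError):
    """Raised for rank-deficient fits, missing weights or bad quantiles."""


@dataclass
class WeightSet:
    """Jointly fitted per-SNP weights for one trait."""

    trait: str  # "LDL" or "TG"
    weights: pd.Series  # snp_id -> weight (trait units per effect allele)
    n_fit: int
    dropped: list[str] = field(default_factory=list)  # SNPs with < 2 allele copies
    se: pd.Series | None = None  # OLS standard errors, aligned with weights

    def __post_init__(self):
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ScoreError("non-finite weights")


def estimate_weights(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    panel: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    min_allele_copies: int = 2,
) -> WeightSet:
    """Fit all score-member SNP effects on the trait at the same time.

    trait "LDL" regresses LDL-C on the natural scale; trait "TG" regresses
    log(TG), matching the simulator's (and the score's) log-scale TG
    convention.  Individuals failing exclusion filters (diabetes, cancer,
    lipid-lowering/estrogen medication) or missing the trait are dropped
    from the fit.  SNPs with fewer than ``min_allele_copies`` effect-allele
    copies among fitted individuals are dropped and listed.  Missing
    dosages are mean-imputed at 2xMAF before fitting.
    """
    member_col = {"LDL": "in_ldl_score", "TG": "in_tg_score"}[trait]
    snps = list(panel.loc[panel[member_col], "snp_id"])
    if not snps:
        raise ScoreError(f"no panel SNPs assigned to the {trait} score")
    pheno = phenotypes.set_index("individual_id").loc[genotypes.individuals]
    y_raw = pheno["ldl"] if trait == "LDL" else np.log(pheno["tg"])
    keep = (~excluded_mask(pheno) & y_raw.notna()).to_numpy()
    if keep.sum() <= len(snps) + len(covariates) + 1:
        raise ScoreError(
            f"n = {int(keep.sum())} fitted individuals insufficient for "
            f"{len(snps)} SNPs plus covariates"
        )

    cols = [genotypes.variant_index(s) for s in snps]
    X = genotypes.dosages[np.ix_(keep, cols)].copy()
    mafs = panel.set_index("snp_id").loc[snps, "maf"].to_numpy(dtype=float)
    for j in range(X.shape[1]):
        miss = np.isnan(X[:, j])
        X[miss, j] = 2 * mafs[j]

    copies = X.sum(axis=0)
    dropped = [s for s, c in zip(snps, copies) if c < min_allele_copies]
    kept_mask = copies >= min_allele_copies
    snps_kept = [s for s, k in zip(snps, kept_mask) if k]
    X = X[:, kept_mask]

    design = [np.ones(keep.sum()), ]
    for cov in covariates:
        v = pheno.loc[keep, cov]
        design.append((v == "M").astype(float).to_numpy() if cov == "sex" else v.to_numpy(dtype=float))
    C = np.column_stack(design)
    full = np.column_stack([C, X])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # identify collinear SNP columns by incremental rank
        collinear = []
        base = C
        for s, j in zip(snps_kept, range(X.shape[1])):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                collinear.append(s)
            else:
                base = cand
        raise ScoreError(f"design matrix rank deficient; collinear SNPs: {collinear}")
    y = y_raw.to_numpy(dtype=float)[keep]
    coef, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ coef
    dof = full.shape[0] - full.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(full.T @ full)
    ses = np.sqrt(np.diag(cov)[C.shape[1]:])
    weights = pd.Series(coef[C.shape[1]:], index=snps_kept, name=trait)
    return WeightSet(
        trait=trait,
        weights=weights,
        n_fit=int(keep.sum()),
        dropped=dropped,
        se=pd.Series(ses, index=snps_kept),
    )


def compute_scores(
    genotypes: GenotypeMatrix, weight_set: WeightSet, panel: pd.DataFrame
) -> pd.Series:
    """Score = sum over SNPs of weight x effect-allele dosage.

    Missing dosages are mean-imputed at 2xMAF.  Individuals missing every
    scored genotype get NaN.
    """
    snps = list(weight_set.weights.index)
    cols = [genotypes.variant_index(s) for s in snps]
    X = genotypes.dosages[:, cols].copy()
    all_missing = np.isnan(X).all(axis=1)
    mafs = panel.set_index("snp_id").loc[snps, "maf"].to_numpy(dtype=float)
    for j in range(X.shape[1]):
        miss = np.isnan(X[:, j])
        X[miss, j] = 2 * mafs[j]
    scores = X @ weight_set.weights.to_numpy()
    scores[all_missing] = np.nan
    return pd.Series(scores, index=genotypes.individuals, name=f"score_{weight_set.trait}")


def flag_high_scores(
    family_scores: pd.DataFrame,
    population_scores: pd.DataFrame,
    mendelian_carrier: pd.Series | None = None,
    q: float = 0.90,
) -> pd.DataFrame:
    """Flag individuals whose score reaches the population q-quantile.

    Inputs are frames with columns score_LDL and score_TG indexed by
    individual.  Thresholds are empirical quantiles of the population
    scores; the comparison is inclusive (>=).  Returns flags high_ldl,
    high_tg, either, both, mendelian_carrier and explained
    (either or carrier) for the family individuals.
    """
    if not 0 < q < 1:
        raise ScoreError(f"quantile must lie in (0, 1), got {q}")
    if population_scores.empty:
        raise ScoreError("population score distribution is empty")
    thr_ldl = float(np.quantile(population_scores["score_LDL"].dropna(), q))
    thr_tg = float(np.quantile(population_scores["score_TG"].dropna(), q))
    out = pd.DataFrame(index=family_scores.index)
    out["score_LDL"] = family_scores["score_LDL"]
    out["score_TG"] = family_scores["score_TG"]
    out["high_ldl"] = family_scores["score_LDL"] >= thr_ldl
    out["high_tg"] = family_scores["score_TG"] >= thr_tg
    out["either"] = out["high_ldl"] | out["high_tg"]
    out["both"] = out["high_ldl"] & out["high_tg"]
    if mendelian_carrier is None:
        mendelian_carrier = pd.Series(False, index=family_scores.index)
    out["mendelian_carrier"] = mendelian_carrier.reindex(out.index).fillna(False).astype(bool)
    out["explained"] = out["either"] | out["mendelian_carrier"]
    out.attrs["threshold_ldl"] = thr_ldl
    out.attrs["threshold_tg"] = thr_tg
    return out
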