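"""Relatedness-aware statistics: GRM, mixed-model Wald tests, prediction.

The genomic relationship matrix (GRM) averages centered, scaled genotype
products over many variants; under Hardy-Weinberg founders its diagonal is
~1 and off-diagonal entries estimate twice the kinship coefficient (0.5
for full sibs and parent-offspring).  Trait contrasts between affected and
unaffected family members use a linear mixed model with the GRM as the
covariance of a polygenic random effect, fitted by restricted maximum
likelihood through an eigendecomposition of the GRM (a single spectral
decomposition reduces every likelihood evaluation to diagonal algebra).
Binary affection is fitted with the same linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix


class FamilyStatsError(ValueError):
    """Raised for degenerate GRMs, dimension mismatches or empty families."""


def compute_grm(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.DataFrame:
    """GRM over individuals: K[i,j] = mean_k (x_ik-2p_k)(x_jk-2p_k)/(2p_k(1-p_k)).

    Allele frequencies default to estimates from the supplied sample
    (configurable via ``freqs``).  Monomorphic variants are skipped; missing
    dosages are mean-imputed at 2p before centering (contributing zero).
    """
    X = genotypes.dosages.copy()
    if freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(X, axis=0) / 2
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1) & np.isfinite(freqs)
    if not poly.any():
        raise FamilyStatsError("all variants monomorphic; GRM undefined")
    X = X[:, poly]
    p = freqs[poly]
    for j in range(X.shape[1]):
        miss = np.isnan(X[:, j])
        X[miss, j] = 2 * p[j]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]
    return pd.DataFrame(K, index=genotypes.individuals, columns=genotypes.individuals)


@dataclass
class LmmResult:
    estimate: float
    se: float
    p: float
    sigma_g2: float
    sigma_e2: float
    h: float  # sigma_g2 / (sigma_g2 + sigma_e2)
    reml_loglik: float
    beta: np.ndarray
    n: int


def _reml_profile(h: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile REML log-likelihood over total variance at mixing fraction h."""
    n, p = Xt.shape
    S = h * d + (1 - h)
    W = 1.0 / S
    XtW = Xt * W[:, None]
    XtWX = Xt.T @ XtW
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, None
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    r = yt - Xt @ beta
    rss_w = float(np.sum(r * r * W))
    if rss_w <= 0:
        return -np.inf, None
    sigma2 = rss_w / (n - p)
    _, logdet_xx = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + (n - p) * np.log(sigma2)
        + float(np.sum(np.log(S)))
        + logdet_xwx
        - logdet_xx
        + (n - p)
    )
    return ll, (beta, sigma2, XtWX)


def lmm_wald(
    y: np.ndarray,
    group: np.ndarray,
    K: pd.DataFrame | np.ndarray,
    covariates: np.ndarray | None = None,
) -> LmmResult:
    """Wald test of a group effect under y = Xb + g + e, g ~ N(0, sg2 K).

    REML over the variance mixing fraction h = sg2/(sg2+se2) via the
    eigendecomposition of K; the Wald statistic is the group coefficient
    over its GLS standard error, referred to the standard normal.  With
    K = I the fit reduces exactly to ordinary least squares (with the
    residual variance on n - p degrees of freedom).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    Km = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    if Km.shape != (n, n):
        raise FamilyStatsError(f"K shape {Km.shape} does not match n = {n}")
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n:
            cov = cov.T
        cols.extend(list(cov))
    X = np.column_stack(cols)

    Km = (Km + Km.T) / 2
    d, U = np.linalg.eigh(Km)
    tol = 1e-8 * max(1.0, float(d.max()))
    if d.min() < -tol:
        raise FamilyStatsError(
            f"GRM not positive semidefinite (min eigenvalue {d.min():.3g})"
        )
    d = np.clip(d, 0, None)
    yt, Xt = U.T @ y, U.T @ X

    grid = np.linspace(0.0, 0.99, 34)
    lls = np.array([_reml_profile(h, d, yt, Xt)[0] for h in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: -_reml_profile(h, d, yt, Xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h_hat = float(res.x)
        if _reml_profile(h_hat, d, yt, Xt)[0] < lls[k]:
            h_hat = float(grid[k])
    else:
        h_hat = float(grid[k])
    ll, aux = _reml_profile(h_hat, d, yt, Xt)
    if aux is None:
        raise FamilyStatsError("REML likelihood degenerate")
    beta, sigma2, XtWX = aux
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    est = float(beta[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    z = est / se
    p = float(2 * stats.norm.sf(abs(z)))
    return LmmResult(
        estimate=est,
        se=se,
        p=p,
        sigma_g2=h_hat * sigma2,
        sigma_e2=(1 - h_hat) * sigma2,
        h=h_hat,
        reml_loglik=float(ll),
        beta=beta,
        n=n,
    )


def ppv_npv(flags: pd.Series, affected: pd.Series) -> dict:
    """Positive/negative predictive value of one flag for affection.

    PPV = P(affected | flagged), NPV = P(unaffected | unflagged); NaN when
    the respective denominator is empty.
    """
    flags, affected = flags.align(affected, join="inner")
    f = flags.astype(bool).to_numpy()
    a = affected.astype(bool).to_numpy()
    n_flag = int(f.sum())
    n_unflag = int((~f).sum())
    return dict(
        n=len(f),
        prevalence=float(a.mean()) if len(f) else np.nan,
        ppv=float((f & a).sum() / n_flag) if n_flag else np.nan,
        npv=float((~f & ~a).sum() / n_unflag) if n_unflag else np.nan,
        n_flagged=n_flag,
    )


def prediction_report(score_flags: pd.DataFrame, affected: pd.Series) -> pd.DataFrame:
    """PPV/NPV for each score flag (high_ldl, high_tg, either, both)."""
    rows = []
    for col in ("high_ldl", "high_tg", "either", "both"):
        entry = ppv_npv(score_flags[col], affected)
        entry["flag"] = col
        rows.append(entry)
    return pd.DataFrame(rows)[["flag", "n", "prevalence", "ppv", "npv", "n_flagged"]]


def family_explained_summary(
    explained: pd.Series, phenotypes: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-family counts of affected/unaffected members whose status is
    accounted for by a high score or Mendelian variant.

    Returns (per-family frame, summary dict).  "Over half" uses strict
    inequality; "all" requires every affected member explained with at
    least one affected member.  Families with no genotyped (scored)
    members are skipped.
    """
    ph = phenotypes.set_index("individual_id")
    rows = []
    for fid, sub in ph.groupby("family_id", dropna=True):
        scored = sub.index.intersection(explained.index)
        if len(scored) == 0:
            continue
        sub = sub.loc[scored]
        exp = explained.loc[scored].astype(bool)
        aff = sub["affected"].astype(bool)
        rows.append(
            dict(
                family_id=fid,
                n_affected=int(aff.sum()),
                n_affected_explained=int((aff & exp).sum()),
                n_unaffected=int((~aff).sum()),
                n_unaffected_high=int((~aff & exp).sum()),
            )
        )
    fam = pd.DataFrame(rows)
    if fam.empty:
        raise FamilyStatsError("no families with scored members")
    with_aff = fam[fam["n_affected"] > 0]
    over_half = (with_aff["n_affected_explained"] * 2 > with_aff["n_affected"]).sum()
    all_expl = (
        (with_aff["n_affected_explained"] == with_aff["n_affected"])
    ).sum()
    summary = dict(
        n_families=len(fam),
        n_over_half=int(over_half),
        frac_over_half=float(over_half / len(fam)),
        n_all_explained=int(all_expl),
        frac_all_explained=float(all_expl / len(fam)),
        total_affected=int(fam["n_affected"].sum()),
        total_affected_explained=int(fam["n_affected_explained"].sum()),
    )
    return fam, summary


def affected_pair_correlation(
    K: pd.DataFrame,
    phenotypes: pd.DataFrame,
    family_rank: pd.Series,
) -> tuple[pd.DataFrame, dict | None]:
    """Mean pairwise genetic correlation of affected members per family,
    regressed on the family's explained-count rank.

    ``family_rank``: family_id -> rank (higher = more affected members
    explained).  Families with fewer than two genotyped affected members
    are skipped; the regression needs at least three families, otherwise
    only the per-family table is returned.
    """
    ph = phenotypes.set_index("individual_id")
    rows = []
    for fid, sub in ph.groupby("family_id", dropna=True):
        aff_ids = [i for i in sub.index[sub["affected"].astype(bool)] if i in K.index]
        if len(aff_ids) < 2:
            continue
        block = K.loc[aff_ids, aff_ids].to_numpy()
        iu = np.triu_indices(len(aff_ids), k=1)
        rows.append(
            dict(
                family_id=fid,
                n_affected=len(aff_ids),
                mean_correlation=float(block[iu].mean()),
            )
        )
    fam = pd.DataFrame(rows)
    if fam.empty:
        raise FamilyStatsError("no families with >= 2 genotyped affected members")
    fam["rank"] = fam["family_id"].map(family_rank)
    fam = fam.dropna(subset=["rank"])
    if len(fam) < 3:
        return fam, None
    reg = stats.linregress(fam["rank"], fam["mean_correlation"])
    return fam, dict(slope=float(reg.slope), p=float(reg.pvalue), r=float(reg.rvalue))
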