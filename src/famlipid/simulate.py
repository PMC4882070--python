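"""Synthetic study generator: population cohort and ascertained families.

Emulates the structure of a familial combined hyperlipidemia (FCH) study:
an unrelated population reference cohort and multi-generation families
ascertained through a hyperlipidemic proband with at least one affected
first-degree relative and at least one affected high-TG member.  Genotypes
at panel SNPs are Hardy-Weinberg draws in the population and Mendelian
gene drops within families; the APOE locus is simulated as a three-allele
haplotype (e2/e3/e4) and expanded to rs429358/rs7412 dosages so the two
SNPs are always phase-consistent.

LDL-C is additive on the natural scale; TG is additive on the log scale and
exponentiated, giving the right-skewed distribution seen in serum TG.  TC
closes over the Friedewald relation (TC = LDL-C + HDL-C + 0.45 TG) as a
simulator convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affection import PercentileTable, assign_affection, build_percentile_table
from .config import ConfigError, SimulationConfig
from .genotypes import GenotypeMatrix
from .panel import frequency_class, validate_panel
from .pedigree import (
    PedigreeError,
    first_degree_relatives,
    founders,
    topological_order,
    validate_pedigree,
)

APOE_RS429358 = "rs429358"  # effect allele C tags epsilon-4
APOE_RS7412 = "rs7412"  # effect allele T tags epsilon-2
APOA5_RS3135506 = "rs3135506"

_APOE_E2_FREQ = 0.041
_APOE_E4_FREQ = 0.18
_APOA5_MAF = 0.062

# fixed per-allele effects of the named Mendelian-gene variants
_APOE_E2_BETA_LDL = -0.45  # mmol/l per epsilon-2 allele
_APOE_E4_BETA_LDL = 0.15  # mmol/l per epsilon-4 allele
_APOA5_BETA_LOGTG = 0.25  # log(mmol/l) per Trp19 allele

_LDL_BASE = 3.3
_LDL_AGE_SLOPE = 0.012
_LDL_SEX = {"M": 0.05, "F": -0.05}
_LOGTG_BASE = float(np.log(1.30))
_LOGTG_AGE_SLOPE = 0.006
_LOGTG_SEX = {"M": 0.10, "F": -0.10}
_LOG_HDL_BASE = float(np.log(1.30))
_LOG_HDL_SD = 0.18
_LOG_HDL_SEX = {"M": -0.08, "F": 0.08}

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the lipid SNP panel.

    LDL-score and TG-score SNPs are disjoint; OMIM flags cover the named
    APOE/APOA5 variants plus randomly chosen others up to ``n_omim``.  MAFs
    are log-uniform over the configured range; signed effects are drawn so
    each SNP contributes comparably to the panel's target variance share.
    """
    config.validate()
    ps = config.panel
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = ps.n_snps
    mafs = np.exp(rng.uniform(np.log(ps.maf_range[0]), np.log(ps.maf_range[1]), size=m))
    chrom = rng.integers(1, 23, size=m).astype(str)
    pos = rng.integers(1, 250_000_000, size=m)
    alleles = [
        _ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ]
    in_ldl = np.zeros(m, dtype=bool)
    in_ldl[: ps.n_ldl] = True
    in_tg = ~in_ldl
    snp_ids = [f"snp{str(k + 1).zfill(4)}" for k in range(m)]

    # named Mendelian-gene variants occupy fixed slots
    named_idx: dict[str, int] = {}
    if ps.include_apoe:
        for slot, (sid, c, p, maf, ea, oa) in enumerate(
            [
                (APOE_RS429358, "19", 45_411_941, _APOE_E4_FREQ, "C", "T"),
                (APOE_RS7412, "19", 45_412_079, _APOE_E2_FREQ, "T", "C"),
            ]
        ):
            snp_ids[slot] = sid
            chrom[slot], pos[slot], mafs[slot] = c, p, maf
            alleles[slot] = (ea, oa)
            named_idx[sid] = slot
    if ps.include_apoa5:
        slot = ps.n_ldl  # first TG-score slot
        snp_ids[slot] = APOA5_RS3135506
        chrom[slot], pos[slot], mafs[slot] = "11", 116_662_407, _APOA5_MAF
        alleles[slot] = ("C", "G")
        named_idx[APOA5_RS3135506] = slot

    # effect sizes: equal expected per-SNP variance, rescaled so the panel
    # explains the configured fraction of each trait's variance
    beta_ldl = np.zeros(m)
    beta_tg = np.zeros(m)
    het = 2 * mafs * (1 - mafs)
    for betas, mask, h2, total_sd in (
        (beta_ldl, in_ldl, ps.h2_ldl, config.variance.total_sd_ldl),
        (beta_tg, in_tg, ps.h2_tg, config.variance.total_sd_logtg),
    ):
        raw = rng.standard_normal(m) / np.sqrt(het)
        betas[mask] = raw[mask]
        fixed = np.zeros(m, dtype=bool)
        for sid, b in (
            (APOE_RS429358, _APOE_E4_BETA_LDL),
            (APOE_RS7412, _APOE_E2_BETA_LDL),
            (APOA5_RS3135506, _APOA5_BETA_LOGTG),
        ):
            if sid in named_idx and mask[named_idx[sid]]:
                betas[named_idx[sid]] = b
                fixed[named_idx[sid]] = True
        target = h2 * total_sd**2
        fixed_var = float((het[mask & fixed] * betas[mask & fixed] ** 2).sum())
        free = mask & ~fixed
        free_var = float((het[free] * betas[free] ** 2).sum())
        if free_var > 0 and target > fixed_var:
            betas[free] *= np.sqrt((target - fixed_var) / free_var)
        elif free_var > 0:
            betas[free] = 0.0

    omim = np.zeros(m, dtype=bool)
    for slot in named_idx.values():
        omim[slot] = True
    extra = ps.n_omim - int(omim.sum())
    if extra > 0:
        candidates = np.flatnonzero(~omim)
        omim[rng.choice(candidates, size=extra, replace=False)] = True

    panel = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos.astype(int),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "maf": mafs,
            "beta_ldl": beta_ldl,
            "beta_tg": beta_tg,
            "in_ldl_score": in_ldl,
            "in_tg_score": in_tg,
            "omim": omim,
            "freq_class": [frequency_class(f) for f in mafs],
        }
    )
    return validate_panel(panel)


def simulate_background_variants(
    n: int, rng: np.random.Generator, maf_range=(0.001, 0.5)
) -> pd.DataFrame:
    """Effect-free genome-wide variants for the empirical null and the GRM.

    MAFs are log-uniform so every frequency bin is populated; positions are
    synthetic integers on chromosomes 1-22 (no linkage map).
    """
    if n <= 0:
        raise ConfigError("background variant count must be positive")
    mafs = np.exp(rng.uniform(np.log(maf_range[0]), np.log(maf_range[1]), size=n))
    return pd.DataFrame(
        {
            "snp_id": [f"bg{k + 1}" for k in range(n)],
            "chrom": rng.integers(1, 23, size=n).astype(str),
            "pos": rng.integers(1, 250_000_000, size=n).astype(int),
            "maf": mafs,
        }
    )


def simulate_null_inputs(
    pedigree: pd.DataFrame,
    case_ids: list[str],
    n_population: int,
    n_variants: int,
    rng: np.random.Generator,
    maf_range=(0.001, 0.5),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Background-variant inputs for the empirical enrichment null.

    Gene-drops ``n_variants`` effect-free variants through every family in
    ``pedigree`` (keeping the family structure of the case individuals
    fixed) and draws the population-side allele frequency of each variant
    as Binomial(2N, maf)/2N — the exact sampling distribution of an
    HWE population frequency estimate, without materialising an
    N x n_variants genotype matrix.

    Returns (case background GenotypeMatrix, frame with snp_id/chrom/pos/
    freq for the population side).
    """
    bg = simulate_background_variants(n_variants, rng, maf_range)
    case_set = set(case_ids)
    blocks, ids = [], []
    for fid in pd.unique(pedigree["family_id"]):
        ped = pedigree[pedigree["family_id"] == fid]
        if not any(i in case_set for i in ped["individual_id"]):
            continue
        gm = gene_drop(ped, bg, rng, apoe_haplotypes=False)
        keep = [k for k, i in enumerate(gm.individuals) if i in case_set]
        blocks.append(gm.dosages[keep])
        ids.extend(gm.individuals[k] for k in keep)
    if not ids:
        raise ConfigError("no case individuals found in the pedigree")
    case_gm = GenotypeMatrix(
        individuals=ids, variants=list(bg["snp_id"]), dosages=np.vstack(blocks)
    )
    pop_counts = rng.binomial(2 * n_population, bg["maf"].to_numpy())
    freqs = bg[["snp_id", "chrom", "pos"]].copy()
    freqs["freq"] = pop_counts / (2 * n_population)
    return case_gm, freqs


def _apoe_hap_freqs(panel: pd.DataFrame) -> tuple[float, float] | None:
    ids = set(panel["snp_id"])
    if APOE_RS429358 in ids and APOE_RS7412 in ids:
        f_e4 = float(panel.set_index("snp_id").loc[APOE_RS429358, "maf"])
        f_e2 = float(panel.set_index("snp_id").loc[APOE_RS7412, "maf"])
        return f_e2, f_e4
    return None


def _apoe_dosages_from_haps(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """haps: (..., 2) array of labels 2/3/4 -> (rs429358 C count, rs7412 T count)."""
    d_429358 = (haps == 4).sum(axis=-1).astype(float)
    d_7412 = (haps == 2).sum(axis=-1).astype(float)
    return d_429358, d_7412


def _draw_apoe_haps(n: int, f_e2: float, f_e4: float, rng) -> np.ndarray:
    return rng.choice([2, 3, 4], size=(n, 2), p=[f_e2, 1 - f_e2 - f_e4, f_e4])


def simulate_population_genotypes(
    panel: pd.DataFrame, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes for ``n`` unrelated individuals."""
    if n <= 0:
        raise ConfigError("population size must be positive")
    mafs = panel["maf"].to_numpy()
    if (mafs <= 0).any() or (mafs > 0.5).any():
        raise ConfigError("panel MAFs must lie in (0, 0.5]")
    dosages = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    apoe = _apoe_hap_freqs(panel)
    if apoe is not None:
        f_e2, f_e4 = apoe
        haps = _draw_apoe_haps(n, f_e2, f_e4, rng)
        d1, d2 = _apoe_dosages_from_haps(haps)
        cols = {sid: j for j, sid in enumerate(panel["snp_id"])}
        dosages[:, cols[APOE_RS429358]] = d1
        dosages[:, cols[APOE_RS7412]] = d2
    ids = [f"P{str(i + 1).zfill(6)}" for i in range(n)]
    return GenotypeMatrix(
        individuals=ids,
        variants=list(panel["snp_id"]),
        dosages=dosages,
        variant_meta=panel[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]]
        if "effect_allele" in panel.columns
        else None,
    )


def gene_drop(
    pedigree: pd.DataFrame,
    panel: pd.DataFrame,
    rng: np.random.Generator,
    apoe_haplotypes: bool = True,
) -> GenotypeMatrix:
    """Drop alleles through a pedigree: founders from Hardy-Weinberg at the
    panel MAFs, each non-founder receiving one uniformly chosen allele per
    parent per meiosis.  When both APOE SNPs are present and
    ``apoe_haplotypes`` is set, the APOE locus segregates as a single
    three-allele haplotype and is expanded to the two SNP dosages afterwards.
    """
    ped = validate_pedigree(pedigree)
    order = topological_order(ped)
    idx = {iid: k for k, iid in enumerate(order)}
    rows = ped.set_index("individual_id")
    mafs = panel["maf"].to_numpy()
    m = len(mafs)
    n = len(order)

    apoe = _apoe_hap_freqs(panel) if apoe_haplotypes else None
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    apoe_haps = np.zeros((n, 2), dtype=np.int8) if apoe is not None else None
    for iid in order:
        k = idx[iid]
        fa, mo = rows.loc[iid, "father_id"], rows.loc[iid, "mother_id"]
        if fa is None or (isinstance(fa, float) and np.isnan(fa)):
            alleles[k] = rng.random((2, m)) < mafs
            if apoe is not None:
                apoe_haps[k] = _draw_apoe_haps(1, *apoe, rng)[0]
        else:
            for h, parent in enumerate((fa, mo)):
                pick = rng.integers(0, 2, size=m)
                alleles[k, h] = alleles[idx[parent], pick, np.arange(m)]
                if apoe is not None:
                    apoe_haps[k, h] = apoe_haps[idx[parent], rng.integers(0, 2)]
    dosages = alleles.sum(axis=1).astype(float)
    if apoe is not None:
        cols = {sid: j for j, sid in enumerate(panel["snp_id"])}
        d1, d2 = _apoe_dosages_from_haps(apoe_haps)
        dosages[:, cols[APOE_RS429358]] = d1
        dosages[:, cols[APOE_RS7412]] = d2
    return GenotypeMatrix(
        individuals=order,
        variants=list(panel["snp_id"]),
        dosages=dosages,
        variant_meta=panel[
            [c for c in ("snp_id", "chrom", "pos", "effect_allele", "other_allele") if c in panel.columns]
        ],
    )


def apply_imputation_noise(
    gm: GenotypeMatrix,
    snp_id: str,
    rng: np.random.Generator,
    mean_error: float = 0.03,
    concentration: float = 30.0,
) -> GenotypeMatrix:
    """Inject imputation uncertainty into one variant.

    Each call gets a posterior ~ Beta(concentration*(1-mean_error),
    concentration*mean_error); with probability (1 - posterior) the reported
    dosage is replaced by one of the two other dosage values.  Higher
    posteriors therefore mean more reliable calls, so filtering at a
    posterior threshold trades yield for accuracy.
    """
    j = gm.variant_index(snp_id)
    n = gm.n_individuals
    a = concentration * (1 - mean_error)
    b = concentration * mean_error
    post = rng.beta(a, b, size=n)
    miscall = rng.random(n) > post
    dosages = gm.dosages.copy()
    true_d = dosages[:, j]
    for i in np.flatnonzero(miscall):
        others = [d for d in (0.0, 1.0, 2.0) if d != true_d[i]]
        dosages[i, j] = others[rng.integers(0, 2)]
    posteriors = (
        np.full_like(dosages, np.nan) if gm.posteriors is None else gm.posteriors.copy()
    )
    posteriors[:, j] = post
    return GenotypeMatrix(
        individuals=gm.individuals,
        variants=gm.variants,
        dosages=dosages,
        posteriors=posteriors,
        variant_meta=gm.variant_meta,
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    demographics: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    family_effects: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Generate lipid phenotypes from additive SNP effects.

    ``demographics``: individual_id, family_id (None for population), age,
    sex, proband.  LDL-C is additive on the natural scale; TG additive on
    the log scale then exponentiated; TC = LDL-C + HDL-C + 0.45 TG.  The
    shared-family effect (one draw per family per trait) requires family
    ids; ``family_effects`` can supply pre-drawn effects keyed by family id.
    """
    config.validate()
    vs = config.variance
    ps = config.panel
    demo = demographics.set_index("individual_id").loc[genotypes.individuals]
    n = len(demo)
    has_families = demo["family_id"].notna().any()
    if not has_families and (vs.family_ldl > 0 or vs.family_tg > 0) and family_effects is None:
        fam_ldl_var = fam_tg_var = 0.0
    else:
        fam_ldl_var = vs.family_ldl if has_families else 0.0
        fam_tg_var = vs.family_tg if has_families else 0.0

    mafs = panel["maf"].to_numpy()
    centered = genotypes.dosages - 2 * mafs
    g_ldl = centered @ panel["beta_ldl"].to_numpy()
    g_tg = centered @ panel["beta_tg"].to_numpy()

    ages = demo["age"].to_numpy(dtype=float)
    sexes = demo["sex"].to_numpy()
    sex_ldl = np.array([_LDL_SEX[s] for s in sexes])
    sex_tg = np.array([_LOGTG_SEX[s] for s in sexes])
    sex_hdl = np.array([_LOG_HDL_SEX[s] for s in sexes])

    fam_term_ldl = np.zeros(n)
    fam_term_tg = np.zeros(n)
    if has_families:
        sd_f_ldl = vs.total_sd_ldl * np.sqrt(fam_ldl_var)
        sd_f_tg = vs.total_sd_logtg * np.sqrt(fam_tg_var)
        effects = dict(family_effects or {})
        for fid in pd.unique(demo["family_id"].dropna()):
            if fid not in effects:
                effects[fid] = (
                    rng.normal(0, sd_f_ldl),
                    rng.normal(0, sd_f_tg),
                )
            mask = (demo["family_id"] == fid).to_numpy()
            fam_term_ldl[mask] = effects[fid][0]
            fam_term_tg[mask] = effects[fid][1]

    resid_sd_ldl = vs.total_sd_ldl * np.sqrt(max(1 - ps.h2_ldl - fam_ldl_var, 0.0))
    resid_sd_tg = vs.total_sd_logtg * np.sqrt(max(1 - ps.h2_tg - fam_tg_var, 0.0))

    ldl = (
        _LDL_BASE
        + _LDL_AGE_SLOPE * (ages - 45)
        + sex_ldl
        + g_ldl
        + fam_term_ldl
        + rng.normal(0, resid_sd_ldl, n)
    )
    ldl = np.maximum(ldl, 0.3)
    logtg = (
        _LOGTG_BASE
        + _LOGTG_AGE_SLOPE * (ages - 45)
        + sex_tg
        + g_tg
        + fam_term_tg
        + rng.normal(0, resid_sd_tg, n)
    )
    tg = np.exp(logtg)
    hdl = np.exp(rng.normal(_LOG_HDL_BASE + sex_hdl, _LOG_HDL_SD))
    tc = ldl + hdl + 0.45 * tg
    apob = 20 + 22 * ldl + rng.normal(0, 8, n)

    return pd.DataFrame(
        {
            "individual_id": genotypes.individuals,
            "family_id": demo["family_id"].to_numpy(),
            "age": ages,
            "sex": sexes,
            "tc": tc,
            "ldl": ldl,
            "tg": tg,
            "hdl": hdl,
            "apob": apob,
            "diabetes": rng.random(n) < config.diabetes_rate,
            "cancer": rng.random(n) < config.cancer_rate,
            "lipid_med": rng.random(n) < config.lipid_med_rate,
            "affected": False,
            "subtype": "none",
            "proband": demo["proband"].to_numpy(dtype=bool),
        }
    )


def simulate_pedigree(family_id: str, config: SimulationConfig, rng) -> pd.DataFrame:
    """One three-generation pedigree: a founder couple, their sibship, the
    sibs' spouses (founders) and grandchildren.  One second-generation sib
    is designated the index (proband candidate)."""
    recs = []
    gf, gmo = f"{family_id}_1", f"{family_id}_2"
    recs.append((family_id, gf, None, None, "M", False, 1))
    recs.append((family_id, gmo, None, None, "F", False, 1))
    counter = 3
    n2 = 1 + rng.poisson(config.mean_sibship_gen2 - 1)
    gen2 = []
    for _ in range(n2):
        iid = f"{family_id}_{counter}"
        counter += 1
        sex = "M" if rng.random() < 0.5 else "F"
        recs.append((family_id, iid, gf, gmo, sex, False, 2))
        gen2.append((iid, sex))
    proband = gen2[rng.integers(0, len(gen2))][0]
    for iid, sex in gen2:
        if rng.random() >= config.marriage_prob:
            continue
        spouse = f"{family_id}_{counter}"
        counter += 1
        sp_sex = "F" if sex == "M" else "M"
        recs.append((family_id, spouse, None, None, sp_sex, False, 2))
        father, mother = (iid, spouse) if sex == "M" else (spouse, iid)
        for _ in range(1 + rng.poisson(config.mean_sibship_gen3 - 1)):
            child = f"{family_id}_{counter}"
            counter += 1
            recs.append(
                (
                    family_id,
                    child,
                    father,
                    mother,
                    "M" if rng.random() < 0.5 else "F",
                    False,
                    3,
                )
            )
    ped = pd.DataFrame(
        recs,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "proband", "generation"],
    )
    ped.loc[ped["individual_id"] == proband, "proband"] = True
    return validate_pedigree(ped)


_GEN_AGES = {1: (62.0, 75.0), 2: (38.0, 58.0), 3: (18.0, 36.0)}


def _family_demographics(ped: pd.DataFrame, rng) -> pd.DataFrame:
    gens = ped["generation"] if "generation" in ped.columns else pd.Series(2, index=ped.index)
    ages = [rng.uniform(*_GEN_AGES[int(g)]) for g in gens]
    return pd.DataFrame(
        {
            "individual_id": ped["individual_id"],
            "family_id": ped["family_id"],
            "age": ages,
            "sex": ped["sex"],
            "proband": ped["proband"],
        }
    )


def family_passes_ascertainment(ped: pd.DataFrame, pheno: pd.DataFrame) -> bool:
    """Inclusion rule: affected proband, >= 1 affected first-degree relative
    of the proband, and >= 1 affected member with elevated TG."""
    probands = ped.loc[ped["proband"], "individual_id"]
    if len(probands) != 1:
        raise PedigreeError(
            f"family {ped['family_id'].iloc[0]} has {len(probands)} probands, expected 1"
        )
    proband = probands.iloc[0]
    status = pheno.set_index("individual_id")
    if not bool(status.loc[proband, "affected"]):
        return False
    rel = first_degree_relatives(ped, proband)
    if not any(bool(status.loc[r, "affected"]) for r in rel if r in status.index):
        return False
    high_tg = status["affected"] & status["subtype"].isin(["TG-only", "both"])
    return bool(high_tg.any())


def ascertain_families(
    candidates: list[tuple[pd.DataFrame, pd.DataFrame]],
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Filter candidate (pedigree, phenotype-with-affection) pairs by the
    ascertainment rule."""
    return [(p, ph) for p, ph in candidates if family_passes_ascertainment(p, ph)]


@dataclass
class SimulatedStudy:
    """Full synthetic study: reference population plus ascertained families."""

    config: SimulationConfig
    panel: pd.DataFrame
    percentiles: PercentileTable
    pop_genotypes: GenotypeMatrix
    pop_phenotypes: pd.DataFrame
    pedigree: pd.DataFrame = field(repr=False)
    fam_genotypes: GenotypeMatrix = field(repr=False)
    fam_phenotypes: pd.DataFrame = field(repr=False)
    # family genotypes before imputation noise (equal to fam_genotypes when
    # no noise was applied); the ground truth for concordance checks
    fam_genotypes_true: GenotypeMatrix | None = field(default=None, repr=False)

    @property
    def affected_ids(self) -> list[str]:
        return list(
            self.fam_phenotypes.loc[self.fam_phenotypes["affected"], "individual_id"]
        )


def simulate_study(
    config: SimulationConfig,
    apoe_noise: bool = True,
    max_batches: int = 200,
    ascertain: bool = True,
) -> SimulatedStudy:
    """Generate the complete synthetic study from one seeded configuration.

    Population genotypes/phenotypes are drawn first and define the
    affection thresholds; candidate families are then generated in batches
    and filtered by the ascertainment rule until the target family count is
    reached.  With ``ascertain=False`` every candidate family is kept
    (random families, used for null calibration).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)

    n = config.n_population
    pop_gm = simulate_population_genotypes(panel, n, rng)
    lo, hi = config.age_range
    pop_demo = pd.DataFrame(
        {
            "individual_id": pop_gm.individuals,
            "family_id": None,
            "age": rng.uniform(lo, hi, n),
            "sex": np.where(rng.random(n) < config.sex_ratio, "M", "F"),
            "proband": False,
        }
    )
    pop_pheno = simulate_phenotypes(pop_gm, panel, pop_demo, config, rng)
    percentiles = build_percentile_table(pop_pheno)
    pop_pheno = assign_affection(pop_pheno, percentiles)
    if apoe_noise and config.panel.include_apoe:
        pop_gm = apply_imputation_noise(
            pop_gm, APOE_RS429358, rng, mean_error=config.apoe_imputation_error
        )

    kept: list[tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]] = []
    fam_counter = 0
    batch_size = max(2 * config.n_families, 20)
    for _ in range(max_batches):
        if len(kept) >= config.n_families:
            break
        for _ in range(batch_size):
            fam_counter += 1
            fid = f"FAM{str(fam_counter).zfill(4)}"
            ped = simulate_pedigree(fid, config, rng)
            gm = gene_drop(ped, panel, rng)
            demo = _family_demographics(ped, rng)
            pheno = simulate_phenotypes(gm, panel, demo, config, rng)
            pheno = assign_affection(pheno, percentiles)
            if not ascertain or family_passes_ascertainment(ped, pheno):
                kept.append((ped, pheno, gm))
                if len(kept) >= config.n_families:
                    break
    if len(kept) < config.n_families:
        raise ConfigError(
            f"only {len(kept)} of {config.n_families} families ascertained after "
            f"{fam_counter} candidates; raise effect sizes or batches"
        )

    peds = pd.concat([p for p, _, _ in kept], ignore_index=True)
    phenos = pd.concat([ph for _, ph, _ in kept], ignore_index=True)
    all_ids = [iid for _, _, g in kept for iid in g.individuals]
    dosages = np.vstack([g.dosages for _, _, g in kept])
    fam_gm = GenotypeMatrix(
        individuals=all_ids,
        variants=list(panel["snp_id"]),
        dosages=dosages,
        variant_meta=panel[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]],
    )
    fam_gm_true = fam_gm
    if apoe_noise and config.panel.include_apoe:
        fam_gm = apply_imputation_noise(
            fam_gm, APOE_RS429358, rng, mean_error=config.apoe_imputation_error
        )
    phenos = phenos.set_index("individual_id").loc[all_ids].reset_index()
    return SimulatedStudy(
        config=config,
        panel=panel,
        percentiles=percentiles,
        pop_genotypes=pop_gm,
        pop_phenotypes=pop_pheno,
        pedigree=peds,
        fam_genotypes=fam_gm,
        fam_phenotypes=phenos,
        fam_genotypes_true=fam_gm_true,
    )
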