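"""Generator properties: determinism, Hardy-Weinberg, Mendelian transmission,
phenotype construction and ascertainment."""

import numpy as np
import pandas as pd
import pytest

from famlipid.config import ConfigError, PanelSpec, SimulationConfig, VarianceSpec
from famlipid.pedigree import validate_pedigree
from famlipid.simulate import (
    ascertain_families,
    family_passes_ascertainment,
    gene_drop,
    simulate_panel,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_population_genotypes,
    simulate_study,
)

from conftest import sib_pedigree


def test_panel_counts_and_flags(small_config):
    panel = simulate_panel(small_config)
    ps = small_config.panel
    assert len(panel) == ps.n_snps
    assert panel["in_ldl_score"].sum() == ps.n_ldl
    assert panel["in_tg_score"].sum() == ps.n_tg
    assert panel["omim"].sum() == ps.n_omim


def test_default_panel_matches_study_design():
    cfg = SimulationConfig()
    panel = simulate_panel(cfg)
    assert len(panel) == 212
    assert panel["omim"].sum() == 44


def test_panel_rejects_bad_counts():
    with pytest.raises(ConfigError):
        SimulationConfig(panel=PanelSpec(n_ldl=0)).validate()


def test_config_yaml_roundtrip(small_config, tmp_path):
    path = tmp_path / "cfg.yaml"
    small_config.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == small_config
    # a YAML-loaded config drives an identical simulation
    np.testing.assert_array_equal(
        simulate_panel(back)["maf"], simulate_panel(small_config)["maf"])


def test_single_neutral_snp_panel():
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, maf_range=(0.2499, 0.2501),
                        h2_ldl=0.0, h2_tg=0.0, include_apoe=False, include_apoa5=False)
    )
    panel = simulate_panel(cfg)
    assert (panel["freq_class"] == "common").all()
    assert np.allclose(panel[["beta_ldl", "beta_tg"]], 0)


def test_simulation_determinism(small_config):
    s1 = simulate_study(small_config)
    s2 = simulate_study(small_config)
    np.testing.assert_array_equal(s1.pop_genotypes.dosages, s2.pop_genotypes.dosages)
    np.testing.assert_array_equal(s1.fam_genotypes.dosages, s2.fam_genotypes.dosages)
    pd.testing.assert_frame_equal(s1.fam_phenotypes, s2.fam_phenotypes)
    pd.testing.assert_frame_equal(s1.panel, s2.panel)


def test_population_maf_converges(rng):
    """Sample allele frequency approaches the generating MAF (binomial SE)."""
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, maf_range=(0.0999, 0.1001),
                        include_apoe=False, include_apoa5=False)
    )
    panel = simulate_panel(cfg, rng)
    gm = simulate_population_genotypes(panel, 200_000, rng)
    freq = gm.dosages.mean(axis=0) / 2
    np.testing.assert_allclose(freq, panel["maf"], atol=0.005)


def test_population_hardy_weinberg(rng):
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, maf_range=(0.299, 0.301),
                        include_apoe=False, include_apoa5=False)
    )
    panel = simulate_panel(cfg, rng)
    n = 100_000
    gm = simulate_population_genotypes(panel, n, rng)
    p = float(panel["maf"].iloc[0])
    for j in range(2):
        counts = np.bincount(gm.dosages[:, j].astype(int), minlength=3) / n
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        np.testing.assert_allclose(counts, expected, atol=4 * np.sqrt(0.25 / n) + 0.003)


def test_population_rejects_degenerate_maf(rng, small_config):
    panel = simulate_panel(small_config, rng).copy()
    panel.loc[0, "maf"] = 0.0
    with pytest.raises(ConfigError):
        simulate_population_genotypes(panel, 10, rng)


def _one_snp_panel(maf, beta_ldl=0.0, beta_tg=0.0):
    return pd.DataFrame(
        dict(snp_id=["s1"], chrom=["1"], pos=[1000], effect_allele=["A"],
             other_allele=["G"], maf=[maf], beta_ldl=[beta_ldl], beta_tg=[beta_tg],
             in_ldl_score=[True], in_tg_score=[False], omim=[False],
             freq_class=["common"]))


def test_gene_drop_mendelian_certainty(rng, trio_pedigree):
    """Homozygous x homozygous parents always give the homozygous child."""
    panel = _one_snp_panel(0.5)
    for _ in range(20):
        gm = gene_drop(trio_pedigree, panel, rng)
        d = {i: gm.dosages[k, 0] for k, i in enumerate(gm.individuals)}
        if d["dad"] == 2 and d["mom"] == 2:
            assert d["kid1"] == 2 and d["kid2"] == 2
        if d["dad"] == 0 and d["mom"] == 0:
            assert d["kid1"] == 0 and d["kid2"] == 0


def test_gene_drop_het_cross_segregation(rng, trio_pedigree):
    """Het x het crosses give offspring dosages in 1:2:1 proportions."""
    panel = _one_snp_panel(0.5)
    counts = np.zeros(3)
    n_crosses = 0
    for _ in range(3000):
        gm = gene_drop(trio_pedigree, panel, rng)
        d = {i: gm.dosages[k, 0] for k, i in enumerate(gm.individuals)}
        if d["dad"] == 1 and d["mom"] == 1:
            n_crosses += 2
            counts[int(d["kid1"])] += 1
            counts[int(d["kid2"])] += 1
    frac = counts / n_crosses
    np.testing.assert_allclose(frac, [0.25, 0.5, 0.25], atol=4 * np.sqrt(0.25 / n_crosses))


def test_gene_drop_transmission_consistency(small_study):
    """No child dosage is Mendelianly impossible given its parents."""
    ped = small_study.pedigree.set_index("individual_id")
    gm = small_study.fam_genotypes
    idx = {i: k for k, i in enumerate(gm.individuals)}
    for iid, row in ped.iterrows():
        if row["father_id"] is None:
            continue
        child = gm.dosages[idx[iid]]
        dad = gm.dosages[idx[row["father_id"]]]
        mom = gm.dosages[idx[row["mother_id"]]]
        # rs429358 carries injected imputation noise; skip it
        noisy = gm.posteriors is not None and ~np.isnan(gm.posteriors[idx[iid]])
        ok = (child >= (dad > 1).astype(int) + (mom > 1).astype(int)) & (
            child <= 2 - (dad < 1).astype(int) - (mom < 1).astype(int)
        )
        assert np.all(ok | noisy)


def test_gene_drop_parent_offspring_kinship(rng):
    """Parent-offspring allele sharing over many loci matches kinship 1/2."""
    ped = sib_pedigree(1, 2, rng)
    mafs = rng.uniform(0.1, 0.5, 2000)
    panel = pd.DataFrame(
        dict(snp_id=[f"v{i}" for i in range(2000)], chrom="1",
             pos=np.arange(2000) * 10_000, maf=mafs))
    gm = gene_drop(ped, panel, rng, apoe_haplotypes=False)
    X = gm.dosages
    p = mafs
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]
    i_p = gm.individuals.index("F0_p1")
    i_c = gm.individuals.index("F0_c0")
    assert K[i_p, i_c] == pytest.approx(0.5, abs=0.06)


def test_phenotypes_exact_when_noise_free(rng, trio_pedigree):
    """Zero effects and zero variances leave only baseline + age/sex terms."""
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, h2_ldl=0.0, h2_tg=0.0,
                        include_apoe=False, include_apoa5=False),
        variance=VarianceSpec(total_sd_ldl=0.0, total_sd_logtg=0.0,
                              family_ldl=0.0, family_tg=0.0),
    )
    panel = simulate_panel(cfg, rng)
    gm = simulate_population_genotypes(panel, 50, rng)
    demo = pd.DataFrame(
        dict(individual_id=gm.individuals, family_id=None,
             age=rng.uniform(25, 75, 50),
             sex=np.where(rng.random(50) < 0.5, "M", "F"), proband=False))
    ph = simulate_phenotypes(gm, panel, demo, cfg, rng)
    sex_ldl = np.where(demo["sex"] == "M", 0.05, -0.05)
    expected_ldl = 3.3 + 0.012 * (demo["age"] - 45) + sex_ldl
    np.testing.assert_allclose(ph["ldl"], expected_ldl, atol=1e-12)
    sex_tg = np.where(demo["sex"] == "M", 0.10, -0.10)
    expected_tg = np.exp(np.log(1.30) + 0.006 * (demo["age"] - 45) + sex_tg)
    np.testing.assert_allclose(ph["tg"], expected_tg, atol=1e-12)


def test_phenotype_snp_effect_recovered_by_ols(rng):
    """A single simulated SNP effect is recovered by regression within 2 SE."""
    beta = 0.3
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, h2_ldl=0.0, h2_tg=0.0,
                        maf_range=(0.29, 0.31), include_apoe=False, include_apoa5=False))
    panel = simulate_panel(cfg, rng)
    panel.loc[panel["in_ldl_score"], "beta_ldl"] = beta
    n = 4000
    gm = simulate_population_genotypes(panel, n, rng)
    demo = pd.DataFrame(
        dict(individual_id=gm.individuals, family_id=None, age=np.full(n, 45.0),
             sex=["M"] * n, proband=False))
    ph = simulate_phenotypes(gm, panel, demo, cfg, rng)
    j = int(np.flatnonzero(panel["in_ldl_score"].to_numpy())[0])
    x = gm.dosages[:, j]
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, ph["ldl"].to_numpy(), rcond=None)
    resid = ph["ldl"].to_numpy() - X @ coef
    se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
    assert abs(coef[1] - beta) < 2 * se + 1e-9


def test_family_effect_intraclass_correlation(rng):
    """With family variance at half the total, sibling residual ICC ~ 0.5."""
    cfg = SimulationConfig(
        panel=PanelSpec(n_ldl=1, n_tg=1, n_omim=0, h2_ldl=0.0, h2_tg=0.0,
                        include_apoe=False, include_apoa5=False),
        variance=VarianceSpec(family_ldl=0.5, family_tg=0.5),
    )
    panel = simulate_panel(cfg, rng)
    nfam, nkids = 400, 2
    ped = sib_pedigree(nfam, nkids, rng)
    gm = gene_drop(ped, panel, rng, apoe_haplotypes=False)
    demo = pd.DataFrame(
        dict(individual_id=gm.individuals,
             family_id=[i.split("_")[0] for i in gm.individuals],
             age=np.full(len(gm.individuals), 45.0),
             sex=["M"] * len(gm.individuals), proband=False))
    ph = simulate_phenotypes(gm, panel, demo, cfg, rng)
    sib1 = ph[ph["individual_id"].str.endswith("_c0")].set_index("family_id")["ldl"]
    sib2 = ph[ph["individual_id"].str.endswith("_c1")].set_index("family_id")["ldl"]
    icc = np.corrcoef(sib1.loc[sib2.index], sib2)[0, 1]
    assert icc == pytest.approx(0.5, abs=0.08)


def test_mean_family_size_near_target(small_study):
    sizes = small_study.pedigree.groupby("family_id").size()
    assert 9 <= sizes.mean() <= 17


def test_ascertainment_rules(rng):
    """Families failing the proband / first-degree-relative / high-TG rules
    are dropped; those meeting all three are retained."""
    cfg = SimulationConfig()
    ped = simulate_pedigree("FAM1", cfg, rng)
    proband = ped.loc[ped["proband"], "individual_id"].iloc[0]
    base = pd.DataFrame(
        dict(individual_id=ped["individual_id"], affected=False, subtype="none"))

    def with_status(assignments):
        ph = base.copy()
        for iid, (aff, sub) in assignments.items():
            ph.loc[ph["individual_id"] == iid, ["affected", "subtype"]] = [aff, sub]
        return ph

    sib = ped[(ped["father_id"].notna()) & (ped["individual_id"] != proband)
              & (ped["father_id"] == ped.set_index("individual_id").loc[proband, "father_id"])]
    relative = sib["individual_id"].iloc[0] if len(sib) else ped.loc[~ped["proband"] & ped["father_id"].isna(), "individual_id"].iloc[0]

    ok = with_status({proband: (True, "TC-only"), relative: (True, "both")})
    assert family_passes_ascertainment(ped, ok)
    no_proband_aff = with_status({relative: (True, "both")})
    assert not family_passes_ascertainment(ped, no_proband_aff)
    no_relative = with_status({proband: (True, "both")})
    assert not family_passes_ascertainment(ped, no_relative)
    no_high_tg = with_status({proband: (True, "TC-only"), relative: (True, "TC-only")})
    assert not family_passes_ascertainment(ped, no_high_tg)
    assert ascertain_families([(ped, ok), (ped, no_high_tg)]) == [(ped, ok)]


def test_ascertained_families_enriched_for_affection(small_study):
    """Ascertained family members are affected far above population prevalence."""
    fam_frac = small_study.fam_phenotypes["affected"].mean()
    pop_frac = small_study.pop_phenotypes["affected"].mean()
    assert fam_frac > 1.3 * pop_frac


def test_apoe_snp_dosages_always_phase_consistent(small_study):
    """rs429358 + rs7412 true dosages never imply an epsilon-1 haplotype."""
    study = small_study
    cfg = study.config
    clean = simulate_study(cfg, apoe_noise=False)
    d1 = clean.fam_genotypes.column("rs429358")
    d2 = clean.fam_genotypes.column("rs7412")
    assert np.all(d1 + d2 <= 2)
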