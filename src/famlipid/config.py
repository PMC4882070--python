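"""Simulation configuration: the free parameters of the synthetic study.

Defaults mirror the study design being emulated: a population reference
cohort of 18,715 unrelated individuals, 53 multi-generation dyslipidemia
families of mean size ~13 ascertained through an affected proband, and a
212-SNP lipid panel of which 44 SNPs are OMIM-flagged.  Phenotype variance
decompositions are simulator conventions (documented in docs/methods.md),
not published estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class PanelSpec:
    """Counts and distributions for the simulated variant panel.

    LDL- and TG-score SNP sets are disjoint; ``n_omim`` of the total are
    OMIM-flagged.  The named APOE (rs429358/rs7412) and APOA5 (rs3135506)
    variants are included inside those counts when the flags are set.
    ``h2_ldl`` / ``h2_tg``: fraction of trait variance (LDL-C natural scale,
    TG log scale) explained jointly by the panel.
    """

    n_ldl: int = 106
    n_tg: int = 106
    n_omim: int = 44
    maf_range: tuple[float, float] = (0.002, 0.5)
    h2_ldl: float = 0.15
    h2_tg: float = 0.15
    include_apoe: bool = True
    include_apoa5: bool = True

    @property
    def n_snps(self) -> int:
        return self.n_ldl + self.n_tg

    def validate(self):
        if self.n_ldl <= 0 or self.n_tg <= 0 or self.n_omim < 0:
            raise ConfigError("panel SNP counts must be positive")
        if self.n_omim > self.n_snps:
            raise ConfigError("n_omim exceeds total panel size")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.h2_ldl < 1 and 0 <= self.h2_tg < 1):
            raise ConfigError("panel heritabilities must lie in [0, 1)")
        n_named = 2 * self.include_apoe + self.include_apoa5
        if self.include_apoe and self.n_ldl < 2:
            raise ConfigError("APOE SNPs need n_ldl >= 2")
        if self.include_apoa5 and self.n_tg < 1:
            raise ConfigError("APOA5 SNP needs n_tg >= 1")
        if self.n_omim < n_named:
            raise ConfigError("named Mendelian SNPs exceed n_omim")


@dataclass
class VarianceSpec:
    """Per-trait variance decomposition as fractions of total variance.

    ``family`` is the shared-household/polygenic-background component common
    to all members of a family (zero for population samples); the panel
    contributes its heritability from PanelSpec; the remainder is residual.
    Totals (panel h2 + family) must stay below 1.
    """

    total_sd_ldl: float = 0.9  # mmol/l
    total_sd_logtg: float = 0.5  # log(mmol/l)
    family_ldl: float = 0.15
    family_tg: float = 0.15

    def validate(self, panel: PanelSpec):
        for frac, h2, name in (
            (self.family_ldl, panel.h2_ldl, "LDL"),
            (self.family_tg, panel.h2_tg, "TG"),
        ):
            if frac < 0 or frac + h2 >= 1:
                raise ConfigError(
                    f"{name} variance fractions invalid: family={frac}, panel h2={h2}"
                )


@dataclass
class SimulationConfig:
    n_population: int = 18715
    n_families: int = 53
    mean_sibship_gen2: float = 3.2  # 1 + Poisson(mean-1)
    marriage_prob: float = 0.7
    mean_sibship_gen3: float = 2.5
    panel: PanelSpec = field(default_factory=PanelSpec)
    variance: VarianceSpec = field(default_factory=VarianceSpec)
    n_background_variants: int = 200_000
    age_range: tuple[float, float] = (25.0, 75.0)
    sex_ratio: float = 0.5  # fraction male
    diabetes_rate: float = 0.05
    cancer_rate: float = 0.03
    lipid_med_rate: float = 0.05
    apoe_imputation_error: float = 0.03  # rs429358 miscall probability scale
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_population <= 0 or self.n_families <= 0:
            raise ConfigError("cohort sizes must be positive")
        if self.n_background_variants <= 0:
            raise ConfigError("background variant count must be positive")
        if not 0 < self.sex_ratio < 1:
            raise ConfigError("sex_ratio must lie in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be increasing")
        self.panel.validate()
        self.variance.validate(self.panel)
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k in ("age_range",):
            d[k] = list(d[k])
        d["panel"]["maf_range"] = list(d["panel"]["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        panel = d.pop("panel", {})
        if "maf_range" in panel:
            panel["maf_range"] = tuple(panel["maf_range"])
        variance = d.pop("variance", {})
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        cfg = cls(panel=PanelSpec(**panel), variance=VarianceSpec(**variance), **d)
        return cfg.validate()
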