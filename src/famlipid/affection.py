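"""Affection calling from age- and sex-specific lipid percentile thresholds.

Hyperlipidemia (and hence FCH affection inside ascertained families) is
defined as total cholesterol or triglycerides at or above the 90th
percentile of the sex- and age-matched reference population.  Thresholds
are held in a PercentileTable built empirically from a reference cohort or
loaded from a TSV file, so externally published percentile curves can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import excluded_mask


class AffectionError(ValueError):
    """Raised for uncovered strata or unusable threshold tables."""


@dataclass
class PercentileTable:
    """Per-(sex, age band) thresholds for TC and TG in mmol/l.

    ``table`` columns: sex, age_lo, age_hi (inclusive band bounds in years),
    tc_p90, tg_p90.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = ["sex", "age_lo", "age_hi", "tc_p90", "tg_p90"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise AffectionError(f"percentile table missing columns: {missing}")
        if (self.table[["tc_p90", "tg_p90"]] <= 0).any().any():
            raise AffectionError("thresholds must be positive")

    def lookup(self, sex: str, age: float) -> tuple[float, float]:
        """Return (tc threshold, tg threshold) for one individual.

        Ages outside the covered range are clamped to the nearest band for
        that sex, mirroring how published percentile curves behave at the
        extremes of age.
        """
        t = self.table
        bysex = t[t["sex"] == sex]
        if len(bysex) == 0:
            raise AffectionError(f"no percentile stratum for sex={sex}")
        age = float(np.clip(age, bysex["age_lo"].min(), bysex["age_hi"].max()))
        hit = t[(t["sex"] == sex) & (t["age_lo"] <= age) & (age <= t["age_hi"])]
        if len(hit) == 0:
            raise AffectionError(f"no percentile stratum covers sex={sex}, age={age}")
        if len(hit) > 1:
            raise AffectionError(f"overlapping strata for sex={sex}, age={age}")
        row = hit.iloc[0]
        return float(row["tc_p90"]), float(row["tg_p90"])

    def lookup_many(self, sexes, ages) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised threshold lookup; same clamping semantics as lookup."""
        sexes = np.asarray(sexes)
        ages = np.asarray(ages, dtype=float)
        tc = np.full(len(ages), np.nan)
        tg = np.full(len(ages), np.nan)
        for sex in np.unique(sexes):
            bands = self.table[self.table["sex"] == sex].sort_values("age_lo")
            if len(bands) == 0:
                raise AffectionError(f"no percentile stratum for sex={sex}")
            sel = sexes == sex
            a = np.clip(ages[sel], bands["age_lo"].min(), bands["age_hi"].max())
            idx = np.searchsorted(bands["age_lo"].to_numpy(), a, side="right") - 1
            if (a > bands["age_hi"].to_numpy()[idx]).any():
                raise AffectionError(f"age gap in percentile bands for sex={sex}")
            tc[sel] = bands["tc_p90"].to_numpy()[idx]
            tg[sel] = bands["tg_p90"].to_numpy()[idx]
        return tc, tg

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "PercentileTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sex": str}))


def build_percentile_table(
    population: pd.DataFrame,
    age_bands: list[tuple[float, float]] | None = None,
    q: float = 0.90,
    min_stratum_n: int = 30,
) -> PercentileTable:
    """Empirical sex x age-band lipid percentiles from a reference cohort.

    Individuals failing exclusion filters (diabetes/cancer/medication) are
    dropped first.  Quantiles use linear interpolation.  Default bands are
    5-year bins spanning the observed age range, with the last band extended
    to the maximum age.
    """
    keep = population[~excluded_mask(population)]
    if age_bands is None:
        lo = float(np.floor(keep["age"].min() / 5) * 5)
        hi = float(np.ceil(keep["age"].max() / 5) * 5)
        edges = np.arange(lo, hi + 5, 5)
        age_bands = [
            (float(a), float(b - 1e-9) if b < edges[-1] else float(b))
            for a, b in zip(edges[:-1], edges[1:])
        ]
    rows = []
    for sex in ("M", "F"):
        for a_lo, a_hi in age_bands:
            sub = keep[
                (keep["sex"] == sex) & (keep["age"] >= a_lo) & (keep["age"] <= a_hi)
            ]
            if len(sub) < min_stratum_n:
                raise AffectionError(
                    f"stratum sex={sex}, age [{a_lo}, {a_hi}] has n={len(sub)} "
                    f"< required {min_stratum_n}"
                )
            rows.append(
                dict(
                    sex=sex,
                    age_lo=a_lo,
                    age_hi=a_hi,
                    tc_p90=float(np.quantile(sub["tc"].dropna(), q)),
                    tg_p90=float(np.quantile(sub["tg"].dropna(), q)),
                )
            )
    return PercentileTable(pd.DataFrame(rows))


def assign_affection(pheno: pd.DataFrame, table: PercentileTable) -> pd.DataFrame:
    """Assign affected status and subtype against percentile thresholds.

    affected <=> not excluded and (TC >= threshold or TG >= threshold), with
    >= inclusive at the boundary.  Excluded individuals (diabetes, cancer,
    lipid-lowering or estrogen medication) are forced unaffected with
    subtype "none".  Individuals missing both TC and TG are left unaffected
    and listed in the returned frame's ``undetermined`` column.
    """
    out = pheno.copy()
    excl = excluded_mask(out).to_numpy()
    tc = out["tc"].to_numpy(dtype=float)
    tg = out["tg"].to_numpy(dtype=float)
    undetermined = np.isnan(tc) & np.isnan(tg)
    tc_thr, tg_thr = table.lookup_many(out["sex"].to_numpy(), out["age"].to_numpy())
    with np.errstate(invalid="ignore"):
        hi_tc = ~np.isnan(tc) & (tc >= tc_thr)
        hi_tg = ~np.isnan(tg) & (tg >= tg_thr)
    affected = ~excl & ~undetermined & (hi_tc | hi_tg)
    subtype = np.full(len(out), "none", dtype=object)
    subtype[affected & hi_tc & ~hi_tg] = "TC-only"
    subtype[affected & ~hi_tc & hi_tg] = "TG-only"
    subtype[affected & hi_tc & hi_tg] = "both"
    out["affected"] = affected
    out["subtype"] = subtype
    out["undetermined"] = undetermined
    return out
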