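"""APOE isoform calling from rs429358/rs7412 and Mendelian-carrier flags.

The three common APOE protein isoforms are jointly encoded by two SNPs:
rs429358 (T>C; C tags epsilon-4) and rs7412 (C>T; T tags epsilon-2).  With
unphased genotypes the isoform pair is a deterministic function of the two
genotypes for all combinations observed in practice; combinations implying
an epsilon-1-like haplotype are flagged inconsistent rather than guessed.
Calls from an imputed rs429358 are accepted only above a posterior
probability threshold (default 0.9).

High-impact Mendelian carriers are APOE epsilon-2 homozygotes (type III
hyperlipoproteinemia risk) and APOA5 rs3135506 homozygotes
(hypertriglyceridemia risk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

ISOFORMS = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

# (rs429358 genotype, rs7412 genotype) -> isoform pair, genotypes as
# alphabetically sorted allele strings
_ISOFORM_MAP = {
    ("T/T", "T/T"): "e2e2",
    ("T/T", "C/T"): "e2e3",
    ("C/T", "C/T"): "e2e4",
    ("T/T", "C/C"): "e3e3",
    ("C/T", "C/C"): "e3e4",
    ("C/C", "C/C"): "e4e4",
}


class ApoeError(ValueError):
    """Raised for malformed genotypes or impossible denominators."""


@dataclass
class ApoeCall:
    individual_id: str
    rs429358: str | None  # genotype string or None if undetermined
    rs7412: str | None
    isoform: str  # one of ISOFORMS, "inconsistent" or "undetermined"
    posterior: float | None  # rs429358 posterior used, if any
    reason: str = ""


def _norm_gt(gt: str) -> str:
    alleles = sorted(gt.replace("|", "/").split("/"))
    if len(alleles) != 2 or any(a not in ("C", "T") for a in alleles):
        raise ApoeError(f"unrecognized APOE genotype {gt!r}")
    return "/".join(alleles)


def isoform_from_alleles(rs429358_gt: str, rs7412_gt: str) -> str:
    """Map the two unphased genotypes to an isoform pair.

    Returns "inconsistent" for combinations that imply an epsilon-1
    haplotype or an impossible phase (e.g. rs429358 C/C with any rs7412 T).
    """
    key = (_norm_gt(rs429358_gt), _norm_gt(rs7412_gt))
    return _ISOFORM_MAP.get(key, "inconsistent")


_DOSAGE_GT_429358 = {0.0: "T/T", 1.0: "C/T", 2.0: "C/C"}  # dosage counts C
_DOSAGE_GT_7412 = {0.0: "C/C", 1.0: "C/T", 2.0: "T/T"}  # dosage counts T


def call_apoe(
    genotypes: GenotypeMatrix,
    threshold: float = 0.9,
    rs429358: str = "rs429358",
    rs7412: str = "rs7412",
) -> list[ApoeCall]:
    """Call APOE isoforms for every individual.

    rs7412 is treated as directly genotyped; rs429358 may carry an
    imputation posterior, and the isoform is determined only when that
    posterior exceeds ``threshold``.
    """
    j1 = genotypes.variant_index(rs429358)
    j2 = genotypes.variant_index(rs7412)
    posts = None if genotypes.posteriors is None else genotypes.posteriors[:, j1]
    calls = []
    for i, iid in enumerate(genotypes.individuals):
        d1 = genotypes.dosages[i, j1]
        d2 = genotypes.dosages[i, j2]
        post = None if posts is None or np.isnan(posts[i]) else float(posts[i])
        if np.isnan(d2):
            calls.append(ApoeCall(iid, None, None, "undetermined", post, "rs7412 missing"))
            continue
        if np.isnan(d1):
            calls.append(ApoeCall(iid, None, _DOSAGE_GT_7412[d2], "undetermined", post, "rs429358 missing"))
            continue
        if post is not None and post <= threshold:
            calls.append(
                ApoeCall(
                    iid,
                    _DOSAGE_GT_429358[d1],
                    _DOSAGE_GT_7412[d2],
                    "undetermined",
                    post,
                    f"rs429358 posterior {post:.3f} <= {threshold}",
                )
            )
            continue
        iso = isoform_from_alleles(_DOSAGE_GT_429358[d1], _DOSAGE_GT_7412[d2])
        reason = "allele combination implies epsilon-1/ambiguous phase" if iso == "inconsistent" else ""
        calls.append(ApoeCall(iid, _DOSAGE_GT_429358[d1], _DOSAGE_GT_7412[d2], iso, post, reason))
    return calls


def calls_to_frame(calls: list[ApoeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in calls],
            "rs429358": [c.rs429358 for c in calls],
            "rs7412": [c.rs7412 for c in calls],
            "isoform": [c.isoform for c in calls],
            "posterior": [c.posterior for c in calls],
            "reason": [c.reason for c in calls],
        }
    )


def concordance_accuracy(
    observed: pd.Series, imputed: pd.Series
) -> pd.DataFrame:
    """Per-isoform concordance of imputed calls with observed phenotypes.

    Accuracy for an isoform is 100 x (n imputed as that isoform) /
    (n observed with that phenotype), over the same individuals; undefined
    (NaN) when no one carries the observed phenotype.
    """
    observed, imputed = observed.align(imputed, join="inner")
    rows = []
    for iso in ISOFORMS:
        n_obs = int((observed == iso).sum())
        n_imp = int((imputed == iso).sum())
        rows.append(
            dict(
                isoform=iso,
                n_observed=n_obs,
                n_imputed=n_imp,
                accuracy_pct=(100 * n_imp / n_obs) if n_obs else np.nan,
            )
        )
    return pd.DataFrame(rows)


def flag_mendelian_carriers(
    genotypes: GenotypeMatrix,
    apoe_calls: list[ApoeCall] | None,
    apoa5: str = "rs3135506",
) -> pd.DataFrame:
    """Carrier = APOE e2e2 or homozygous APOA5 rs3135506.

    Missing data never creates a carrier; the reason column records which
    criterion fired (or "unknown" when data were missing for both).
    """
    iso = {}
    if apoe_calls is not None:
        iso = {c.individual_id: c.isoform for c in apoe_calls}
    j = genotypes.variant_index(apoa5)
    rows = []
    for i, iid in enumerate(genotypes.individuals):
        d = genotypes.dosages[i, j]
        reasons = []
        known = False
        if iso.get(iid) == "e2e2":
            reasons.append("APOE e2e2")
        if iso.get(iid) in ISOFORMS:
            known = True
        if not np.isnan(d):
            known = True
            if d == 2.0:
                reasons.append("APOA5 rs3135506 homozygote")
        rows.append(
            dict(
                individual_id=iid,
                carrier=bool(reasons),
                reason="; ".join(reasons) if reasons else ("" if known else "unknown"),
            )
        )
    return pd.DataFrame(rows)


def genotype_frequency(n_carriers: int, n_individuals: int) -> float:
    """Fraction of individuals carrying a genotype."""
    if n_individuals <= 0:
        raise ApoeError("denominator must be positive")
    if not 0 <= n_carriers <= n_individuals:
        raise ApoeError(
            f"carrier count {n_carriers} outside [0, {n_individuals}]"
        )
    return n_carriers / n_individuals
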