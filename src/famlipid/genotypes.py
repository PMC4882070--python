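"""Genotype container and VCF input/output.

Dosages count copies of the *effect allele* (the VCF ALT allele in files we
write) and live in a float matrix with NaN for missing calls.  Imputed
variants may carry a per-entry posterior probability in [0, 1], stored in a
parallel matrix (NaN where no posterior applies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class GenotypeError(ValueError):
    """Raised on malformed genotype data or VCF records."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants effect-allele dosage matrix.

    dosages[i, j] in {0, 1, 2} or NaN (missing); posteriors[i, j] in [0, 1]
    or NaN where the call is directly genotyped.
    """

    individuals: list[str]
    variants: list[str]
    dosages: np.ndarray
    posteriors: np.ndarray | None = None
    variant_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.individuals), len(self.variants)
        if self.dosages.shape != (n, m):
            raise GenotypeError(
                f"dosage matrix shape {self.dosages.shape} != ({n}, {m})"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeError("dosages must be 0, 1, 2 or NaN")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if self.posteriors.shape != (n, m):
                raise GenotypeError("posterior matrix shape mismatch")
            ok = np.isnan(self.posteriors) | (
                (self.posteriors >= 0) & (self.posteriors <= 1)
            )
            if not ok.all():
                raise GenotypeError("posteriors must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.variants.index(snp_id)
        except ValueError:
            raise GenotypeError(f"variant {snp_id!r} not in matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(snp_id)]

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = pd.Index(self.individuals)
        rows = idx.get_indexer(list(ids))
        if (rows < 0).any():
            missing = [i for i, r in zip(ids, rows) if r < 0]
            raise GenotypeError(f"individuals not in matrix: {missing[:5]}")
        return GenotypeMatrix(
            individuals=list(ids),
            variants=list(self.variants),
            dosages=self.dosages[rows],
            posteriors=None if self.posteriors is None else self.posteriors[rows],
            variant_meta=self.variant_meta,
        )


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path, panel: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file.

    REF is the other allele and ALT the effect allele, so dosage equals the
    ALT-allele count.  Posteriors, when present, go into a per-sample IP
    field.  Variant positions come from ``panel`` (snp_id, chrom, pos,
    effect_allele, other_allele) or from ``gm.variant_meta``; without either,
    synthetic chrom/pos/alleles are emitted.
    """
    meta = panel if panel is not None else gm.variant_meta
    lookup = {}
    if meta is not None:
        lookup = meta.set_index("snp_id").to_dict("index")
    has_post = gm.posteriors is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_post:
            fh.write(
                '##FORMAT=<ID=IP,Number=1,Type=Float,'
                'Description="Imputation posterior probability">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        fmt = "GT:IP" if has_post else "GT"
        for j, vid in enumerate(gm.variants):
            info = lookup.get(vid, {})
            chrom = str(info.get("chrom", "1"))
            pos = int(info.get("pos", j + 1))
            ref = str(info.get("other_allele", "A"))
            alt = str(info.get("effect_allele", "G"))
            cells = []
            for i in range(gm.n_individuals):
                d = gm.dosages[i, j]
                gt = "./." if np.isnan(d) else _GT_STRINGS[d]
                if has_post:
                    p = gm.posteriors[i, j]
                    gt += ":." if np.isnan(p) else f":{p:.4f}"
                cells.append(gt)
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix (dosage = ALT count).

    Multi-allelic records are rejected; missing GT becomes NaN.  A per-sample
    float IP field, when present, is read back as the imputation posterior.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    variants, meta_rows, dosage_cols, post_cols = [], [], [], []
    any_post = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.ID}): ALT={rec.ALT}; split or filter first"
            )
        variants.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        meta_rows.append(
            dict(
                snp_id=variants[-1],
                chrom=rec.CHROM,
                pos=rec.POS,
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        )
        gts = np.asarray(rec.genotypes, dtype=object)
        col = np.empty(len(individuals))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        dosage_cols.append(col)
        try:
            ip = rec.format("IP")
        except KeyError:
            ip = None
        if ip is not None:
            any_post = True
            post_cols.append(np.asarray(ip, dtype=float).ravel())
        else:
            post_cols.append(np.full(len(individuals), np.nan))
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(individuals), 0))
    )
    posteriors = np.column_stack(post_cols) if (post_cols and any_post) else None
    return GenotypeMatrix(
        individuals=individuals,
        variants=variants,
        dosages=dosages,
        posteriors=posteriors,
        variant_meta=pd.DataFrame(meta_rows) if meta_rows else None,
    )
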