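"""Pedigree records and PLINK-style PED/FAM input/output.

A pedigree is a DataFrame with columns family_id, individual_id, father_id,
mother_id, sex ("M"/"F"), proband (bool).  Founders have father_id and
mother_id empty (None/NaN).  Individual ids are unique across families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "proband"]


class PedigreeError(ValueError):
    """Raised on structurally invalid pedigrees."""


def _norm_parent(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "0", 0):
        return None
    return str(v)


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns a normalized copy.

    Parents must exist in the same family (or be absent), both parents are
    present or both absent, sexes of referenced parents must be consistent,
    and no individual may be its own ancestor.
    """
    missing = [c for c in PED_COLUMNS if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree missing columns: {missing}")
    ped = ped.copy()
    ped["father_id"] = ped["father_id"].map(_norm_parent)
    ped["mother_id"] = ped["mother_id"].map(_norm_parent)
    if ped["individual_id"].duplicated().any():
        dups = ped.loc[ped["individual_id"].duplicated(), "individual_id"].tolist()
        raise PedigreeError(f"duplicate individual ids: {dups[:5]}")
    sex_of = dict(zip(ped["individual_id"], ped["sex"]))
    fam_of = dict(zip(ped["individual_id"], ped["family_id"]))
    parents = {}
    for row in ped.itertuples(index=False):
        f, m = row.father_id, row.mother_id
        if (f is None) != (m is None):
            raise PedigreeError(
                f"{row.individual_id}: one parent known, one absent (half-founders unsupported)"
            )
        if f is not None:
            for pid, want_sex in ((f, "M"), (m, "F")):
                if pid not in sex_of:
                    raise PedigreeError(f"{row.individual_id}: parent {pid} not in pedigree")
                if fam_of[pid] != row.family_id:
                    raise PedigreeError(
                        f"{row.individual_id}: parent {pid} belongs to another family"
                    )
                if sex_of[pid] != want_sex:
                    raise PedigreeError(
                        f"{row.individual_id}: parent {pid} has sex {sex_of[pid]}, expected {want_sex}"
                    )
            parents[row.individual_id] = (f, m)
    # cycle check by depth-first ancestor walk
    state: dict[str, int] = {}

    def visit(iid: str):
        if state.get(iid) == 1:
            raise PedigreeError(f"pedigree cycle involving {iid}")
        if state.get(iid) == 2:
            return
        state[iid] = 1
        for p in parents.get(iid, ()):
            visit(p)
        state[iid] = 2

    for iid in ped["individual_id"]:
        visit(iid)
    ped["proband"] = ped["proband"].astype(bool)
    return ped


def founders(ped: pd.DataFrame) -> pd.Series:
    """Boolean mask of founders (both parents absent)."""
    return ped["father_id"].isna() & ped["mother_id"].isna()


def topological_order(ped: pd.DataFrame) -> list[str]:
    """Individual ids ordered so every parent precedes its children."""
    parents = {
        r.individual_id: [p for p in (r.father_id, r.mother_id) if p is not None]
        for r in ped.itertuples(index=False)
    }
    order: list[str] = []
    seen: set[str] = set()

    def visit(iid):
        if iid in seen:
            return
        for p in parents[iid]:
            visit(p)
        seen.add(iid)
        order.append(iid)

    for iid in ped["individual_id"]:
        visit(iid)
    return order


def first_degree_relatives(ped: pd.DataFrame, iid: str) -> set[str]:
    """Parents, full/half siblings, and children of an individual."""
    rows = ped.set_index("individual_id")
    if iid not in rows.index:
        raise PedigreeError(f"{iid} not in pedigree")
    rel: set[str] = set()
    me = rows.loc[iid]
    for p in (me["father_id"], me["mother_id"]):
        if pd.notna(p):
            rel.add(p)
    for r in ped.itertuples(index=False):
        if r.individual_id == iid:
            continue
        if iid in (r.father_id, r.mother_id):
            rel.add(r.individual_id)  # child
        elif pd.notna(me["father_id"]) and (
            r.father_id == me["father_id"] or r.mother_id == me["mother_id"]
        ):
            rel.add(r.individual_id)  # sibling (shares a parent)
    return rel


_SEX_TO_PED = {"M": "1", "F": "2"}
_PED_TO_SEX = {"1": "M", "2": "F"}


def write_pedigree(ped: pd.DataFrame, path) -> None:
    """Write PLINK PED/FAM columns: FID IID FAT MOT SEX PHENO.

    PHENO encodes proband status (2 = proband, 1 = other) purely so the
    round trip preserves the flag.
    """
    ped = validate_pedigree(ped)
    with open(path, "w") as fh:
        for r in ped.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(r.family_id),
                        str(r.individual_id),
                        r.father_id or "0",
                        r.mother_id or "0",
                        _SEX_TO_PED[r.sex],
                        "2" if r.proband else "1",
                    ]
                )
                + "\n"
            )


def read_pedigree(path) -> pd.DataFrame:
    raw = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
        dtype=str,
    )
    bad = ~raw["sex"].isin(_PED_TO_SEX)
    if bad.any():
        raise PedigreeError(f"unrecognized sex codes at rows {list(raw.index[bad])[:5]}")
    ped = pd.DataFrame(
        {
            "family_id": raw["family_id"],
            "individual_id": raw["individual_id"],
            "father_id": raw["father_id"].replace("0", None),
            "mother_id": raw["mother_id"].replace("0", None),
            "sex": raw["sex"].map(_PED_TO_SEX),
            "proband": raw["pheno"] == "2",
        }
    )
    return validate_pedigree(ped)
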