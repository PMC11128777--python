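"""Cohort data model and tabular I/O.

A cohort is one row per individual: identifiers, family membership,
zygosity group, within-family role, dataset label, covariates (sex, age,
intracranial volume) and one column per regional volume in mm^3.
Missing phenotype cells are preserved as missing throughout — nothing is
imputed at this layer.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

#: Zygosity vocabulary: MZ/DZ by sex composition; DZOS = opposite-sex DZ.
#: Singleton-sibling rows may carry a missing zygosity (the twins in the
#: family define the pair's zygosity).
ZYGOSITY_GROUPS = ("MZF", "MZM", "DZF", "DZM", "DZOS")

ROLES = ("twin1", "twin2", "sibling")

#: Columns every cohort table must provide, in canonical order.
MANDATORY_COLUMNS = (
    "individual_id",
    "family_id",
    "dataset",
    "zygosity_group",
    "role",
    "sex",
    "age",
    "icv",
)

_SEX_CODES = {"F": 0.0, "M": 1.0, "0": 0.0, "1": 1.0, "0.0": 0.0, "1.0": 1.0}


@dataclass
class Individual:
    """One cohort member. ``volumes`` maps region name -> mm^3 (NaN = missing)."""

    individual_id: str
    family_id: str
    dataset: str
    zygosity_group: str | None
    role: str
    sex: float
    age: float
    icv: float
    volumes: dict[str, float]


@dataclass
class Cohort:
    """A validated collection of individuals sharing one region list.

    The canonical storage is a DataFrame (one row per individual, columns
    ``MANDATORY_COLUMNS`` + one per region); :class:`Individual` views are
    constructed on demand.
    """

    table: pd.DataFrame
    region_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cohort_table(self.table, self.region_names)

    @property
    def individuals(self) -> list[Individual]:
        out = []
        for _, row in self.table.iterrows():
            zyg = row["zygosity_group"]
            out.append(
                Individual(
                    individual_id=str(row["individual_id"]),
                    family_id=str(row["family_id"]),
                    dataset=str(row["dataset"]),
                    zygosity_group=None if pd.isna(zyg) else str(zyg),
                    role=str(row["role"]),
                    sex=float(row["sex"]),
                    age=float(row["age"]),
                    icv=float(row["icv"]),
                    volumes={r: float(row[r]) for r in self.region_names},
                )
            )
        return out

    @property
    def datasets(self) -> list[str]:
        return sorted(self.table["dataset"].unique())

    def subset(self, dataset: str) -> "Cohort":
        sub = self.table[self.table["dataset"] == dataset].reset_index(drop=True)
        return Cohort(sub.copy(), list(self.region_names), dict(self.metadata))

    def copy(self) -> "Cohort":
        return Cohort(self.table.copy(), list(self.region_names), dict(self.metadata))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FamilyBlock:
    """One family's data, ordered twin1, twin2, sibling (present members only).

    ``phenotypes`` is (n_members, n_regions) with NaN for missing cells;
    ``covariates`` is (n_members, 3) holding age, sex, icv.
    """

    family_id: str
    dataset: str
    zygosity_group: str | None
    roles: list[str]
    member_ids: list[str]
    phenotypes: np.ndarray
    covariates: np.ndarray
    region_names: list[str]

    @property
    def n_members(self) -> int:
        return len(self.roles)

    def observed_mask(self, regions: Sequence[str]) -> np.ndarray:
        idx = [self.region_names.index(r) for r in regions]
        return ~np.isnan(self.phenotypes[:, idx])


def validate_cohort_table(table: pd.DataFrame, region_names: Sequence[str]) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")
    for region in region_names:
        if region not in table.columns:
            raise SchemaError(f"region column missing: {region!r}")
    dup = table["individual_id"][table["individual_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate individual_id values: {sorted(set(map(str, dup)))}")
    zyg = table["zygosity_group"]
    bad = sorted(set(str(z) for z in zyg.dropna() if str(z) not in ZYGOSITY_GROUPS))
    if bad:
        raise ValidationError(
            f"zygosity_group values outside {ZYGOSITY_GROUPS}: {bad}"
        )
    bad_roles = sorted(set(str(r) for r in table["role"] if str(r) not in ROLES))
    if bad_roles:
        raise ValidationError(f"role values outside {ROLES}: {bad_roles}")
    # sibling rows may have NA zygosity; twin rows may not
    twin_rows = table["role"].isin(["twin1", "twin2"])
    if zyg[twin_rows].isna().any():
        ids = table.loc[twin_rows & zyg.isna(), "individual_id"].tolist()
        raise ValidationError(f"twin rows with missing zygosity_group: {ids}")
    for col, lo in (("age", 0.0), ("icv", 0.0)):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric or missing {col}")
        if (vals <= lo).any():
            raise ValidationError(f"{col} must be > {lo}")
    # per-family structural checks
    for fam, grp in table.groupby("family_id", sort=False):
        for role in ("twin1", "twin2"):
            if (grp["role"] == role).sum() > 1:
                raise IntegrityError(f"family {fam!r} has more than one {role}")
        if (grp["role"] == "sibling").sum() > 1:
            raise ValidationError(
                f"family {fam!r} has more than one singleton sibling (unsupported)"
            )
        if len(grp) > 3:
            raise IntegrityError(f"family {fam!r} has {len(grp)} members (max 3)")


def _coerce_sex(values: pd.Series) -> pd.Series:
    def one(v):
        s = str(v).strip()
        if s in _SEX_CODES:
            return _SEX_CODES[s]
        raise ValidationError(f"unrecognised sex code: {v!r} (use F/M or 0/1)")

    return values.map(one).astype(float)


def read_cohort(
    path,
    *,
    delimiter: str = "\t",
    column_map: dict[str, str] | None = None,
    region_names: Sequence[str] | None = None,
) -> Cohort:
    """Read a delimited cohort table.

    Parameters
    ----------
    path : str, Path or file-like
    delimiter : field separator (default TSV).
    column_map : optional mapping from file column names to canonical names.
    region_names : explicit region list; by default every column beyond the
        mandatory set is treated as a region, in file order.

    Missing phenotype cells (empty string or ``NA``) are preserved as NaN.
    """
    table = pd.read_csv(path, sep=delimiter, dtype={"individual_id": str, "family_id": str},
                        na_values=["NA", ""], keep_default_na=False,
                        float_precision="round_trip")
    if column_map:
        table = table.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")
    if region_names is None:
        region_names = [c for c in table.columns if c not in MANDATORY_COLUMNS]
    table["sex"] = _coerce_sex(table["sex"])
    for col in ("age", "icv", *region_names):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    table = table[list(MANDATORY_COLUMNS) + list(region_names)]
    return Cohort(table.reset_index(drop=True), list(region_names))


def write_cohort(cohort: Cohort, path, *, delimiter: str = "\t") -> None:
    """Write a cohort as delimited text; missing cells become ``NA``."""
    out = cohort.table.copy()
    out["sex"] = out["sex"].map(lambda v: "F" if v == 0 else "M")
    out.to_csv(path, sep=delimiter, index=False, na_rep="NA")


RETEST_COLUMNS = ("individual_id", "visit", "rescan_interval_days")


def read_retest(path, *, delimiter: str = "\t",
                region_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a test-retest table: individual_id, visit (test/retest),
    rescan_interval_days, then one column per region."""
    table = pd.read_csv(path, sep=delimiter, dtype={"individual_id": str},
                        na_values=["NA", ""], keep_default_na=False,
                        float_precision="round_trip")
    for col in RETEST_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"mandatory retest column missing: {col!r}")
    bad = sorted(set(table["visit"]) - {"test", "retest"})
    if bad:
        raise ValidationError(f"visit values outside {{test, retest}}: {bad}")
    if table.duplicated(subset=["individual_id", "visit"]).any():
        raise IntegrityError("an individual appears more than once per visit")
    if region_names is None:
        region_names = [c for c in table.columns if c not in RETEST_COLUMNS]
    for col in region_names:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table[list(RETEST_COLUMNS) + list(region_names)].reset_index(drop=True)


def write_retest(retest: pd.DataFrame, path, *, delimiter: str = "\t") -> None:
    retest.to_csv(path, sep=delimiter, index=False, na_rep="NA")


_ROLE_ORDER = {"twin1": 0, "twin2": 1, "sibling": 2}


def family_blocks(
    cohort: Cohort,
    dataset_filter: str | None = None,
    *,
    log: list | None = None,
) -> list[FamilyBlock]:
    """Partition a cohort into family blocks.

    Members are ordered twin1, twin2, sibling. Blocks in which every
    phenotype cell of every member is missing are dropped; the count of
    dropped families is appended to ``log`` (and stored under the key
    ``"dropped_empty_families"``) when a list is supplied.

    The partition is exhaustive and disjoint over retained individuals.
    """
    table = cohort.table
    if dataset_filter is not None:
        table = table[table["dataset"] == dataset_filter]
    blocks: list[FamilyBlock] = []
    n_dropped = 0
    regs = cohort.region_names
    if not len(table):
        if log is not None:
            log.append({"dropped_empty_families": 0})
        return blocks

    # vectorised family partition: one stable sort by (family, role)
    fam_codes, fams = pd.factorize(table["family_id"], sort=False)
    role_arr = table["role"].to_numpy()
    role_order = np.array([_ROLE_ORDER[r] for r in role_arr])
    order = np.lexsort((role_order, fam_codes))
    fc = fam_codes[order]
    starts = np.flatnonzero(np.r_[True, fc[1:] != fc[:-1]])
    ends = np.r_[starts[1:], len(fc)]
    pheno_all = table[regs].to_numpy(dtype=float)[order]
    cov_all = table[["age", "sex", "icv"]].to_numpy(dtype=float)[order]
    roles_all = role_arr[order]
    zyg_all = table["zygosity_group"].to_numpy(dtype=object)[order]
    ds_all = table["dataset"].to_numpy()[order]
    ids_all = table["individual_id"].to_numpy()[order]
    region_list = list(regs)

    for s, e in zip(starts, ends):
        fam = fams[fc[s]]
        roles = list(roles_all[s:e])
        if roles.count("twin1") > 1 or roles.count("twin2") > 1:
            raise IntegrityError(f"family {fam!r}: duplicated twin role")
        pheno = pheno_all[s:e]
        if np.isnan(pheno).all():
            n_dropped += 1
            continue
        zyg_vals = {z for z in zyg_all[s:e] if not pd.isna(z)}
        if len(zyg_vals) > 1:
            raise IntegrityError(
                f"family {fam!r}: conflicting zygosity groups {sorted(zyg_vals)}")
        ds_vals = set(ds_all[s:e])
        if len(ds_vals) > 1:
            raise IntegrityError(
                f"family {fam!r}: members span datasets {sorted(ds_vals)}")
        blocks.append(
            FamilyBlock(
                family_id=str(fam),
                dataset=str(next(iter(ds_vals))),
                zygosity_group=str(next(iter(zyg_vals))) if zyg_vals else None,
                roles=roles,
                member_ids=[str(i) for i in ids_all[s:e]],
                phenotypes=pheno,
                covariates=cov_all[s:e],
                region_names=region_list,
            )
        )
    if log is not None:
        log.append({"dropped_empty_families": n_dropped})
    return blocks
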