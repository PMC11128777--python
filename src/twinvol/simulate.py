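"""Synthetic twin cohorts with known ACE structure.

The generator draws family blocks under the classical twin model: additive
genetic factors (A) correlate 1.0 between MZ co-twins and 0.5 between DZ
co-twins and between any twin and a full sibling; shared environment (C)
is common to all family members; unique environment (E) is independent.
Multivariate structure across regions follows user-supplied genetic and
environmental correlation matrices. Means follow a linear model in age,
sex and intracranial volume. Everything is deterministic given the seed.

The default two-dataset specification emulates the composition of the
QTIM (798 individuals) and QTAB (396 individuals) twin cohorts: MZ and
same-sex/opposite-sex DZ pairs, unpaired twins, and (QTIM only) singleton
siblings of twins, with an AE variance structure whose per-region
heritabilities span roughly 0.47-0.91.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MANDATORY_COLUMNS
from .errors import ValidationError

__all__ = [
    "DatasetComposition",
    "GenerativeSpec",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_retest",
    "inject_outliers",
    "default_two_dataset_spec",
    "DEFAULT_REGIONS",
]


# 28 cerebellar regions + total volume. Means/SDs are plausible synthetic
# magnitudes (mm^3) for an ACAPULCO-style parcellation; heritabilities are
# AE-world values in the 0.47-0.91 range reported for such volumes.
_REGION_TABLE = [
    # name, mean mm^3, a2
    ("left_I_III", 4000, 0.64),
    ("right_I_III", 4100, 0.60),
    ("left_IV", 3500, 0.61),
    ("right_IV", 3600, 0.57),
    ("left_V", 8200, 0.47),
    ("right_V", 8400, 0.50),
    ("left_VI", 20000, 0.80),
    ("right_VI", 20500, 0.81),
    ("left_crus_I", 25000, 0.87),
    ("right_crus_I", 25500, 0.86),
    ("left_crus_II", 17000, 0.67),
    ("right_crus_II", 17200, 0.68),
    ("left_VIIB", 9000, 0.57),
    ("right_VIIB", 9100, 0.57),
    ("left_VIIIA", 12000, 0.55),
    ("right_VIIIA", 12100, 0.52),
    ("left_VIIIB", 8500, 0.64),
    ("right_VIIIB", 8600, 0.60),
    ("left_IX", 6500, 0.91),
    ("right_IX", 6600, 0.87),
    ("left_X", 1400, 0.64),
    ("right_X", 1420, 0.64),
    ("vermis_VI", 2500, 0.77),
    ("vermis_VII", 1200, 0.77),
    ("vermis_VIII", 2000, 0.88),
    ("vermis_IX", 1800, 0.76),
    ("vermis_X", 800, 0.74),
    ("corpus_medullare", 22000, 0.89),
    ("total_cerebellum", 130000, 0.88),
]

DEFAULT_REGIONS = [r[0] for r in _REGION_TABLE]


@dataclass
class DatasetComposition:
    """Family counts for one dataset (pairs are counted as families)."""

    n_mz_pairs: int = 0
    n_dz_pairs: int = 0          # same-sex DZ; split evenly F/M
    n_dzos_pairs: int = 0        # opposite-sex DZ
    n_unpaired: int = 0          # lone twins retained as size-1 families
    n_sib_families: int = 0      # twin-pair families augmented with one sibling

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs + self.n_dzos_pairs) + \
            self.n_unpaired + self.n_sib_families


@dataclass
class GenerativeSpec:
    """Full description of the generating model.

    ``a2``/``c2``/``e2`` are proportions of the ACE variance ``total_var``
    (mm^6) per region; each may be a single vector or a per-dataset mapping
    (heterogeneity between datasets is expressed that way — the correlation
    structure ``R_A``/``R_E`` is always shared). Mean model per region:
    ``intercept[dataset] + beta_age*age + beta_sex*sex + beta_icv*icv``.
    """

    regions: list[str]
    composition: dict[str, DatasetComposition]
    a2: object          # vector or {dataset: vector}
    c2: object
    e2: object
    total_var: np.ndarray
    R_A: np.ndarray
    R_E: np.ndarray
    R_C: np.ndarray | None = None       # defaults to identity
    intercept: dict[str, np.ndarray] = field(default_factory=dict)
    beta_age: np.ndarray | None = None
    beta_sex: np.ndarray | None = None
    beta_icv: np.ndarray | None = None
    age_mean: dict[str, float] = field(default_factory=dict)
    age_sd: dict[str, float] = field(default_factory=dict)
    age_range: dict[str, tuple] = field(default_factory=dict)
    icv_mean: float = 1.45e6
    icv_sd: float = 1.2e5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        r = len(self.regions)
        self.total_var = np.asarray(self.total_var, dtype=float)
        if self.total_var.shape != (r,):
            raise ValidationError("total_var must have one entry per region")
        for name in ("beta_age", "beta_sex", "beta_icv"):
            v = getattr(self, name)
            setattr(self, name, np.zeros(r) if v is None else np.asarray(v, float))
        for ds in self.composition:
            if ds not in self.intercept:
                self.intercept[ds] = np.zeros(r)
            self.intercept[ds] = np.asarray(self.intercept[ds], float)
            self.age_mean.setdefault(ds, 20.0)
            self.age_sd.setdefault(ds, 4.0)
            self.age_range.setdefault(ds, (9.0, 30.0))
        for ds in self.composition:
            a2, c2, e2 = self.components_for(ds)
            tot = a2 + c2 + e2
            if np.any(a2 < 0) or np.any(c2 < 0) or np.any(e2 < 0):
                raise ValidationError("a2, c2, e2 must be non-negative")
            if not np.allclose(tot, 1.0, atol=1e-8):
                raise ValidationError("a2 + c2 + e2 must sum to 1 per region")
        if self.R_C is None:
            self.R_C = np.eye(r)
        for name in ("R_A", "R_E", "R_C"):
            m = np.asarray(getattr(self, name), float)
            setattr(self, name, m)
            if m.shape != (r, r) or not np.allclose(m, m.T, atol=1e-10):
                raise ValidationError(f"{name} must be a symmetric {r}x{r} matrix")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ValidationError(f"{name} must have a unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValidationError(f"{name} is not positive semi-definite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")

    def components_for(self, dataset: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for comp in (self.a2, self.c2, self.e2):
            v = comp[dataset] if isinstance(comp, Mapping) else comp
            v = np.asarray(v, dtype=float)
            if v.ndim == 0:
                v = np.full(len(self.regions), float(v))
            out.append(v)
        return tuple(out)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Mapping):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, DatasetComposition):
                return asdict(o)
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            return o
        return {k: conv(v) for k, v in self.__dict__.items()}


@dataclass
class SyntheticTruth:
    """The generating parameters echoed back for recovery tests."""

    spec: GenerativeSpec
    seed: int
    latents: dict | None = None

    def to_dict(self) -> dict:
        return {"spec": self.spec.to_dict(), "seed": self.seed}


def default_two_dataset_spec(
    *,
    missing_rate: float = 0.01,
    seed: int = 0,
    regions: Sequence[str] | None = None,
) -> GenerativeSpec:
    """Two-dataset AE world emulating the QTIM/QTAB twin-cohort composition.

    QTIM: 115 MZ + 110 same-sex DZ + 56 opposite-sex DZ pairs, 200 unpaired
    twins and 36 sibling-augmented families (798 individuals, ages ~22 +/- 4).
    QTAB: 93 MZ + 62 same-sex DZ + 31 opposite-sex DZ pairs and 24 unpaired
    twins (396 individuals, ages ~11 +/- 1.4). Heritabilities per region are
    AE-world values in 0.47-0.91; homologous left/right pairs share genetic
    correlation 0.8 and environmental correlation 0.3.
    """
    table = _REGION_TABLE if regions is None else [
        row for row in _REGION_TABLE if row[0] in set(regions)]
    if regions is not None and len(table) != len(list(regions)):
        known = {r[0] for r in _REGION_TABLE}
        raise ValidationError(f"unknown regions: {sorted(set(regions) - known)}")
    names = [r[0] for r in table]
    means = np.array([r[1] for r in table], float)
    a2 = np.array([r[2] for r in table], float)
    r = len(names)

    R_A, R_E = np.eye(r), np.eye(r)
    for i, name in enumerate(names):
        if name.startswith("left_"):
            twin_name = "right_" + name[len("left_"):]
            if twin_name in names:
                j = names.index(twin_name)
                R_A[i, j] = R_A[j, i] = 0.8
                R_E[i, j] = R_E[j, i] = 0.3

    total_var = (0.10 * means) ** 2          # ACE variance: 10% CV around the mean
    beta_icv = means / 1.45e6                # proportional scaling with ICV
    beta_sex = 0.02 * means                  # males ~2% larger at fixed ICV
    beta_age = np.zeros(r)                   # age effects sparse/small -> 0
    comp = {
        "QTIM": DatasetComposition(n_mz_pairs=115, n_dz_pairs=110, n_dzos_pairs=56,
                                   n_unpaired=200, n_sib_families=36),
        "QTAB": DatasetComposition(n_mz_pairs=93, n_dz_pairs=62, n_dzos_pairs=31,
                                   n_unpaired=24, n_sib_families=0),
    }
    icv_mean = 1.45e6
    spec = GenerativeSpec(
        regions=names,
        composition=comp,
        a2=a2, c2=np.zeros(r), e2=1.0 - a2,
        total_var=total_var,
        R_A=R_A, R_E=R_E,
        intercept={
            "QTIM": means - beta_icv * icv_mean - beta_sex * 0.5,
            # adolescent volumes a touch smaller at the same ICV
            "QTAB": 0.97 * means - beta_icv * icv_mean - beta_sex * 0.5,
        },
        beta_age=beta_age, beta_sex=beta_sex, beta_icv=beta_icv,
        age_mean={"QTIM": 22.1, "QTAB": 11.3},
        age_sd={"QTIM": 4.3, "QTAB": 1.4},
        age_range={"QTIM": (12.0, 30.0), "QTAB": (9.0, 14.0)},
        missing_rate=missing_rate,
        seed=seed,
    )
    return spec


def small_spec(
    *,
    n_mz_pairs: int,
    n_dz_pairs: int,
    a2: float,
    c2: float = 0.0,
    regions: Sequence[str] = ("region_1",),
    n_regions: int | None = None,
    R_A: np.ndarray | None = None,
    R_E: np.ndarray | None = None,
    a2_by_region: Sequence[float] | None = None,
    total_var: float = 1.0,
    dataset: str = "SIM",
    n_dzos_pairs: int = 0,
    n_unpaired: int = 0,
    n_sib_families: int = 0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    beta_icv: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenerativeSpec:
    """Convenience builder for single-dataset simulation studies.

    Covariate effects default to zero and the mean model to a zero
    intercept, so phenotypes are pure ACE draws unless stated otherwise.
    """
    if n_regions is not None:
        regions = [f"region_{i + 1}" for i in range(n_regions)]
    regions = list(regions)
    r = len(regions)
    a2v = np.full(r, a2) if a2_by_region is None else np.asarray(a2_by_region, float)
    return GenerativeSpec(
        regions=regions,
        composition={dataset: DatasetComposition(
            n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs,
            n_dzos_pairs=n_dzos_pairs, n_unpaired=n_unpaired,
            n_sib_families=n_sib_families)},
        a2=a2v, c2=np.full(r, c2), e2=1.0 - a2v - np.full(r, c2),
        total_var=np.full(r, total_var),
        R_A=np.eye(r) if R_A is None else R_A,
        R_E=np.eye(r) if R_E is None else R_E,
        beta_age=np.full(r, beta_age),
        beta_sex=np.full(r, beta_sex),
        beta_icv=np.full(r, beta_icv),
        age_mean={dataset: 20.0}, age_sd={dataset: 4.0},
        age_range={dataset: (10.0, 30.0)},
        missing_rate=missing_rate,
        seed=seed,
    )


# kinship matrices for the A factor by family layout
def _kinship(n_members: int, mz: bool) -> np.ndarray:
    # members ordered twin1, twin2[, sibling]; sibling shares 0.5 with both twins
    K = np.full((n_members, n_members), 0.5)
    np.fill_diagonal(K, 1.0)
    if mz and n_members >= 2:
        K[0, 1] = K[1, 0] = 1.0
    return K


def _chol_psd(m: np.ndarray) -> np.ndarray:
    # Cholesky tolerant of PSD (rank-deficient) inputs via eigen clipping
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def _draw_matrix_normal(rng, n: int, L_K: np.ndarray, L_R: np.ndarray) -> np.ndarray:
    """n draws of (members x regions) latents with cov K (rows) x R (cols)."""
    m, r = L_K.shape[0], L_R.shape[0]
    Z = rng.standard_normal((n, m, r))
    return np.einsum("ij,njk,lk->nil", L_K, Z, L_R)


def simulate_cohort(
    spec: GenerativeSpec,
    *,
    keep_latents: bool = False,
) -> tuple[Cohort, SyntheticTruth]:
    """Draw a cohort under the classical twin generative model.

    Deterministic given ``spec.seed``. Returns the cohort plus a
    :class:`SyntheticTruth` echoing the generating parameters (and, when
    ``keep_latents``, the per-individual A/C/E draws).
    """
    rng = np.random.default_rng(spec.seed)
    regions = spec.regions
    r = len(regions)
    L_RA = _chol_psd(spec.R_A)
    L_RE = _chol_psd(spec.R_E)
    L_RC = _chol_psd(spec.R_C)

    rows: list[dict] = []
    latents: dict[str, np.ndarray] = {}

    for ds in sorted(spec.composition):
        comp = spec.composition[ds]
        a2, c2, e2 = spec.components_for(ds)
        sd_a = np.sqrt(a2 * spec.total_var)
        sd_c = np.sqrt(c2 * spec.total_var)
        sd_e = np.sqrt(e2 * spec.total_var)
        lo, hi = spec.age_range[ds]

        # family layouts: (tag, n_members, mz, zygosity labels per family)
        layouts: list[tuple[str, int, bool, str]] = []
        # distribute sibling-augmented families across MZ and same-sex DZ pairs
        n_sib_mz = min(comp.n_sib_families // 2, comp.n_mz_pairs)
        n_sib_dz = min(comp.n_sib_families - n_sib_mz, comp.n_dz_pairs)
        n_sib_mz += comp.n_sib_families - n_sib_mz - n_sib_dz  # remainder back to MZ
        n_sib_mz = min(n_sib_mz, comp.n_mz_pairs)
        layouts += [("mz_sib", 3, True, "MZ")] * n_sib_mz
        layouts += [("mz", 2, True, "MZ")] * (comp.n_mz_pairs - n_sib_mz)
        layouts += [("dz_sib", 3, False, "DZ")] * n_sib_dz
        layouts += [("dz", 2, False, "DZ")] * (comp.n_dz_pairs - n_sib_dz)
        layouts += [("dzos", 2, False, "DZOS")] * comp.n_dzos_pairs
        layouts += [("single", 1, False, "ANY")] * comp.n_unpaired

        fam_counter = 0
        for tag in ("mz_sib", "mz", "dz_sib", "dz", "dzos", "single"):
            group = [l for l in layouts if l[0] == tag]
            if not group:
                continue
            n = len(group)
            m = group[0][1]
            mz = group[0][2]
            A = _draw_matrix_normal(rng, n, _chol_psd(_kinship(m, mz)), L_RA)
            C = np.einsum("ij,nj->ni", L_RC, rng.standard_normal((n, r)))[:, None, :]
            C = np.broadcast_to(C, (n, m, r))
            E = np.einsum("ij,nmj->nmi", L_RE, rng.standard_normal((n, m, r)))

            # covariates
            fam_age = np.clip(rng.normal(spec.age_mean[ds], spec.age_sd[ds], n), lo, hi)
            sib_off = rng.uniform(2.0, 5.0, n) * rng.choice([-1.0, 1.0], n)
            icv_fam = rng.normal(0.0, spec.icv_sd * np.sqrt(0.5), n)
            icv_ind = rng.normal(0.0, spec.icv_sd * np.sqrt(0.5), (n, m))

            if tag == "dzos":
                first_f = rng.random(n) < 0.5
            for i in range(n):
                fam_counter += 1
                fid = f"{ds}_F{fam_counter:04d}"
                if tag in ("mz", "mz_sib"):
                    pair_sex = float(rng.random() < 0.45)       # slight F excess
                    zyg = "MZF" if pair_sex == 0.0 else "MZM"
                    sexes = [pair_sex, pair_sex]
                elif tag in ("dz", "dz_sib"):
                    pair_sex = float(rng.random() < 0.5)
                    zyg = "DZF" if pair_sex == 0.0 else "DZM"
                    sexes = [pair_sex, pair_sex]
                elif tag == "dzos":
                    zyg = "DZOS"
                    sexes = [0.0, 1.0] if first_f[i] else [1.0, 0.0]
                else:  # single unpaired twin: zygosity of the (unscanned) pair
                    sex = float(rng.random() < 0.5)
                    zyg = rng.choice(["MZF", "MZM", "DZF", "DZM", "DZOS"])
                    if zyg == "MZF" or zyg == "DZF":
                        sex = 0.0
                    elif zyg == "MZM" or zyg == "DZM":
                        sex = 1.0
                    sexes = [sex]
                roles = ["twin1", "twin2", "sibling"][:m]
                if m == 3:
                    sexes = sexes + [float(rng.random() < 0.5)]
                for k, role in enumerate(roles):
                    age = fam_age[i] if role != "sibling" else float(
                        np.clip(fam_age[i] + sib_off[i], lo, hi))
                    icv = spec.icv_mean + icv_fam[i] + icv_ind[i, k]
                    mu = (spec.intercept[ds]
                          + spec.beta_age * age
                          + spec.beta_sex * sexes[k]
                          + spec.beta_icv * icv)
                    y = mu + sd_a * A[i, k] + sd_c * C[i, k] + sd_e * E[i, k]
                    iid = f"{fid}_{role}"
                    if keep_latents:
                        latents[iid] = np.stack([A[i, k], C[i, k], E[i, k]])
                    row = {
                        "individual_id": iid,
                        "family_id": fid,
                        "dataset": ds,
                        "zygosity_group": None if role == "sibling" else zyg,
                        "role": role,
                        "sex": sexes[k],
                        "age": age,
                        "icv": icv,
                    }
                    row.update({reg: y[j] for j, reg in enumerate(regions)})
                    rows.append(row)

    table = pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + regions)
    if spec.missing_rate > 0:
        mask = rng.random((len(table), r)) < spec.missing_rate
        vals = table[regions].to_numpy()
        vals[mask] = np.nan
        table[regions] = vals
    cohort = Cohort(table, list(regions), metadata={"seed": int(spec.seed),
                                                    "generator": "twinvol.simulate"})
    truth = SyntheticTruth(spec=spec, seed=int(spec.seed),
                           latents=latents if keep_latents else None)
    return cohort, truth


def simulate_retest(
    cohort: Cohort,
    reliability,
    seed: int,
    *,
    n_subjects: int = 43,
    dataset: str | None = None,
    rescan_interval_mean: float = 113.0,
    rescan_interval_sd: float = 56.0,
) -> pd.DataFrame:
    """Draw a test-retest table whose population ICC(2,1) per region equals
    the requested reliability.

    The observed cohort value is the test visit; the retest visit is
    ``mean + rho*(y - mean) + sqrt(V*(1 - rho^2))*z`` with ``mean``/``V``
    the dataset moments of the region, so test and retest share mean and
    variance and correlate ``rho`` — the two-way random-effects
    absolute-agreement ICC. ``reliability`` may be a scalar or a
    region -> value mapping; 1 reproduces the test values exactly.
    """
    rng = np.random.default_rng(seed)
    regions = cohort.region_names
    rel = {reg: (reliability[reg] if isinstance(reliability, Mapping) else reliability)
           for reg in regions}
    for reg, rho in rel.items():
        if not 0.0 < rho <= 1.0:
            raise ValidationError(f"reliability for {reg!r} must be in (0, 1]")
    table = cohort.table
    if dataset is None:
        dataset = sorted(table["dataset"].unique())[0]
    ds_table = table[table["dataset"] == dataset]
    if n_subjects > len(ds_table):
        raise ValidationError(
            f"n_subjects={n_subjects} exceeds dataset size {len(ds_table)}")
    pick = rng.choice(len(ds_table), size=n_subjects, replace=False)
    sub = ds_table.iloc[np.sort(pick)]

    intervals = np.clip(rng.normal(rescan_interval_mean, rescan_interval_sd,
                                   n_subjects), 1.0, None)
    rows = []
    retest_vals = {}
    for reg in regions:
        y = sub[reg].to_numpy(dtype=float)
        pop = ds_table[reg].to_numpy(dtype=float)
        m = np.nanmean(pop)
        v = np.nanvar(pop, ddof=1)
        rho = rel[reg]
        if rho == 1.0:
            retest_vals[reg] = y.copy()
        else:
            z = rng.standard_normal(n_subjects)
            retest_vals[reg] = m + rho * (y - m) + np.sqrt(v * (1 - rho ** 2)) * z
    for i in range(n_subjects):
        base = {"individual_id": sub.iloc[i]["individual_id"],
                "rescan_interval_days": float(intervals[i])}
        rows.append({**base, "visit": "test",
                     **{reg: sub.iloc[i][reg] for reg in regions}})
        rows.append({**base, "visit": "retest",
                     **{reg: retest_vals[reg][i] for reg in regions}})
    cols = ["individual_id", "visit", "rescan_interval_days"] + list(regions)
    return pd.DataFrame(rows, columns=cols)


def inject_outliers(
    cohort: Cohort,
    rate: float,
    magnitude_sd: float,
    seed: int,
) -> Cohort:
    """Displace a random fraction of phenotype cells to ``magnitude_sd``
    group standard deviations from the uncontaminated group mean.

    Displacement is outward (the cell keeps the sign of its deviation), so
    every injected cell lies exactly ``magnitude_sd`` SDs from the clean
    per-dataset mean and is detectable at the 3.29-SD screening threshold.
    Injected (individual_id, region) positions are recorded under
    ``metadata["injected_outliers"]``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValidationError("rate must be in [0, 1)")
    if magnitude_sd <= 3.29:
        raise ValidationError(
            "magnitude_sd must exceed the 3.29-SD screening threshold")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    table = out.table
    injected: list[tuple[str, str]] = []
    if rate > 0:
        for ds in sorted(table["dataset"].unique()):
            ds_idx = table.index[table["dataset"] == ds]
            for reg in out.region_names:
                vals = table.loc[ds_idx, reg].to_numpy(dtype=float)
                obs = ~np.isnan(vals)
                if obs.sum() < 3:
                    continue
                m, s = vals[obs].mean(), vals[obs].std(ddof=1)
                if s == 0:
                    continue
                hit = obs & (rng.random(len(vals)) < rate)
                sign = np.sign(vals - m)
                sign[sign == 0] = 1.0
                vals[hit] = m + sign[hit] * magnitude_sd * s
                table.loc[ds_idx, reg] = vals
                injected += [(str(table.loc[j, "individual_id"]), reg)
                             for j, h in zip(ds_idx, hit) if h]
    out.metadata["injected_outliers"] = injected
    return out
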