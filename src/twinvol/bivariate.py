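"""Pairwise bivariate AE models and decomposition of phenotypic
correlations into genetic and environmental contributions.

For two traits with heritabilities h1^2, h2^2, genetic correlation r_A and
unique-environmental correlation r_E, the genetic contribution to the
phenotypic correlation is ``r_ph_a = sqrt(h1^2) * r_A * sqrt(h2^2)`` and
the environmental contribution is the E analogue; under the AE model
``r_ph = r_ph_a + r_ph_e`` exactly. Significance is assessed by refitting
with the covariance of interest fixed to zero and a likelihood-ratio
test: genetic or environmental covariance alone (df = 1), or both for the
phenotypic correlation (df = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import FitError, IntegrityError, ValidationError
from .inference import TestFamily, benjamini_hochberg
from .likelihood import FitResult, TwinModelSpec, fit, lrt

__all__ = ["BivariateDecomposition", "CorrelationMatrices",
           "fit_bivariate", "assemble_matrices"]


@dataclass
class BivariateDecomposition:
    """One region pair's correlation decomposition under the bivariate AE
    model (direct variance parameterisation; cross-trait A and E
    covariances are free parameters)."""

    region1: str
    region2: str
    r_ph: float
    r_A: float
    r_E: float
    r_ph_a: float
    r_ph_e: float
    p_ph: float
    p_a: float
    p_e: float
    h2_1: float
    h2_2: float
    converged: bool = True
    notes: list[str] = field(default_factory=list)
    fits: dict | None = None

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in (
            "region1", "region2", "r_ph", "r_A", "r_E", "r_ph_a", "r_ph_e",
            "p_ph", "p_a", "p_e", "h2_1", "h2_2", "converged")}


def fit_bivariate(
    cohort: Cohort,
    region1: str,
    region2: str,
    *,
    equate_datasets: bool = True,
    covariates=("age", "sex", "icv"),
    n_starts: int = 3,
    keep_fits: bool = False,
) -> BivariateDecomposition:
    """Bivariate AE decomposition of the correlation between two regions.

    The default configuration equates variance components across datasets
    while keeping dataset-specific means (pooled-dataset mode). With
    ``equate_datasets=False`` the cohort must contain a single dataset.
    The identity pair returns the trivial decomposition without fitting.

    ``r_ph_a`` is computed as cov_A / sqrt(V1*V2), which equals
    sqrt(h1^2)*r_A*sqrt(h2^2) whenever both A variances are positive but
    remains defined when a direct-parameterisation A estimate is negative
    (in that case ``r_A`` itself is reported as NaN with a note).
    """
    if region1 == region2:
        h2 = math.nan
        return BivariateDecomposition(
            region1, region2, 1.0, 1.0, 1.0, h2, h2, 0.0, 0.0, 0.0, h2, h2,
            notes=["identity pair: trivial decomposition"])
    if not equate_datasets and len(cohort.datasets) > 1:
        raise ValidationError(
            "equate_datasets=False requires a single-dataset cohort; "
            "subset the cohort per dataset for dataset-specific results")

    spec = TwinModelSpec(traits=(region1, region2), components=("A", "E"),
                         covariates=tuple(covariates),
                         equate_datasets=equate_datasets)
    g = "pooled" if equate_datasets else cohort.datasets[0]
    full = fit(spec, cohort, n_starts=n_starts)
    zero_a = fit(spec.with_constraints(fixes={f"covA[{g}]": 0.0}), cohort,
                 n_starts=n_starts)
    zero_e = fit(spec.with_constraints(fixes={f"covE[{g}]": 0.0}), cohort,
                 n_starts=n_starts)
    zero_ph = fit(spec.with_constraints(
        fixes={f"covA[{g}]": 0.0, f"covE[{g}]": 0.0}), cohort,
        n_starts=n_starts)

    def p_of(constrained: FitResult) -> float:
        try:
            return lrt(full, constrained)[2]
        except (FitError, ValidationError):
            return math.nan

    std = full.standardized
    notes: list[str] = []
    est = full.estimates
    A1, A2 = est[f"A[{g}|{region1}]"], est[f"A[{g}|{region2}]"]
    E1, E2 = est[f"E[{g}|{region1}]"], est[f"E[{g}|{region2}]"]
    V1, V2 = A1 + E1, A2 + E2
    covA, covE = est[f"covA[{g}]"], est[f"covE[{g}]"]
    denom = math.sqrt(V1 * V2)
    r_ph = (covA + covE) / denom
    r_ph_a = covA / denom
    r_ph_e = covE / denom
    if A1 > 0 and A2 > 0:
        r_A = covA / math.sqrt(A1 * A2)
    else:
        r_A = math.nan
        notes.append("r_A undefined: non-positive A variance estimate")
    if E1 > 0 and E2 > 0:
        r_E = covE / math.sqrt(E1 * E2)
    else:
        r_E = math.nan
        notes.append("r_E undefined: non-positive E variance estimate")
    dec = BivariateDecomposition(
        region1=region1, region2=region2,
        r_ph=float(r_ph), r_A=float(r_A), r_E=float(r_E),
        r_ph_a=float(r_ph_a), r_ph_e=float(r_ph_e),
        p_ph=p_of(zero_ph), p_a=p_of(zero_a), p_e=p_of(zero_e),
        h2_1=std.get(f"std_A[{g}|{region1}]", math.nan),
        h2_2=std.get(f"std_A[{g}|{region2}]", math.nan),
        converged=full.converged,
        notes=notes,
        fits={"full": full, "zero_a": zero_a, "zero_e": zero_e,
              "zero_ph": zero_ph} if keep_fits else None,
    )
    return dec


@dataclass
class CorrelationMatrices:
    """Symmetric r_ph / r_ph_a / r_ph_e matrices over the measure list with
    FDR significance masks (True = significant after Benjamini-Hochberg
    within the bivariate-covariances family)."""

    measures: list[str]
    r_ph: pd.DataFrame
    r_ph_a: pd.DataFrame
    r_ph_e: pd.DataFrame
    sig_ph: pd.DataFrame
    sig_a: pd.DataFrame
    sig_e: pd.DataFrame
    pairs: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("r_ph", "r_ph_a", "r_ph_e", "sig_ph", "sig_a", "sig_e"):
            getattr(self, name).to_csv(d / f"{name}.tsv", sep="\t")
        self.pairs.to_csv(d / "pairs.tsv", sep="\t", index=False)


def assemble_matrices(
    decomps: list[BivariateDecomposition],
    measures: list[str],
    *,
    alpha: float = 0.05,
) -> CorrelationMatrices:
    """Populate symmetric correlation matrices from pairwise decompositions.

    Expects one decomposition per unordered pair of measures (m*(m-1)/2);
    missing pairs are left NaN/masked with a warning, duplicate pairs with
    conflicting values raise. The diagonal is 1 for r_ph and NaN for the
    contribution matrices. Significance masks come from one
    Benjamini-Hochberg family containing all phenotypic, genetic and
    environmental zeroing tests.
    """
    m = len(measures)
    idx = {name: i for i, name in enumerate(measures)}
    seen: dict[tuple, BivariateDecomposition] = {}
    warnings: list[str] = []
    for d in decomps:
        if d.region1 not in idx or d.region2 not in idx:
            raise ValidationError(
                f"pair ({d.region1}, {d.region2}) not in the measure list")
        key = tuple(sorted((d.region1, d.region2)))
        if key in seen:
            prev = seen[key]
            same = all(
                (math.isnan(getattr(prev, f)) and math.isnan(getattr(d, f)))
                or np.isclose(getattr(prev, f), getattr(d, f), atol=1e-12)
                for f in ("r_ph", "r_ph_a", "r_ph_e"))
            if not same:
                raise IntegrityError(f"conflicting duplicate entries for pair {key}")
            continue
        seen[key] = d

    expected = {tuple(sorted((a, b))) for i, a in enumerate(measures)
                for b in measures[i + 1:]}
    missing = sorted(expected - set(seen))
    if missing:
        warnings.append(f"{len(missing)} of {len(expected)} pairs absent: "
                        f"{missing[:10]}{'...' if len(missing) > 10 else ''}")

    mats = {name: np.full((m, m), np.nan) for name in ("r_ph", "r_ph_a", "r_ph_e")}
    np.fill_diagonal(mats["r_ph"], 1.0)
    fam = TestFamily(label="bivariate_covariances", alpha=alpha)
    for (a, b), d in seen.items():
        i, j = idx[a], idx[b]
        for name, val in (("r_ph", d.r_ph), ("r_ph_a", d.r_ph_a),
                          ("r_ph_e", d.r_ph_e)):
            mats[name][i, j] = mats[name][j, i] = val
        for kind, p in (("ph", d.p_ph), ("a", d.p_a), ("e", d.p_e)):
            if np.isfinite(p):
                fam.add(f"{a}|{b}|{kind}", p)
    sig = {name: np.zeros((m, m), dtype=bool) for name in ("ph", "a", "e")}
    if fam.test_ids:
        adj = benjamini_hochberg(fam)
        for tid, rej in zip(adj["test_id"], adj["reject"]):
            a, b, kind = tid.split("|")
            i, j = idx[a], idx[b]
            sig[kind][i, j] = sig[kind][j, i] = bool(rej)

    def frame(arr):
        return pd.DataFrame(arr, index=measures, columns=measures)

    pair_rows = [d.as_row() for d in seen.values()]
    return CorrelationMatrices(
        measures=list(measures),
        r_ph=frame(mats["r_ph"]), r_ph_a=frame(mats["r_ph_a"]),
        r_ph_e=frame(mats["r_ph_e"]),
        sig_ph=frame(sig["ph"]), sig_a=frame(sig["a"]), sig_e=frame(sig["e"]),
        pairs=pd.DataFrame(pair_rows),
        warnings=warnings,
    )
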