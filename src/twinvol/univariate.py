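"""Per-region univariate workflow: saturated assumption tests, twin
correlations, ACE-family fitting with cross-dataset equating, sub-model
selection, and fixed-effect meta-analysis of dataset estimates.

Sub-model selection follows an LRT-first rule: among the sub-models (AE,
CE, E) not rejected against ACE by likelihood-ratio test at the working
alpha, the model with the lowest AIC is selected (the full ACE model is
always a candidate). Covariate significance is reported but covariates
are always retained in the variance models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, family_blocks
from .errors import FitError, ValidationError
from .likelihood import FitResult, TwinModelSpec, fit, lrt, profile_ci

__all__ = ["run_saturated", "run_univariate", "meta_analyze",
           "saturated_spec", "correlation_spec", "with_tcv_covariate"]

_MZ = ("MZF", "MZM")
_DZ = ("DZF", "DZM", "DZOS")


def with_tcv_covariate(cohort: Cohort,
                       tcv_region: str = "total_cerebellum") -> Cohort:
    """Swap total cerebellar volume in for ICV as the scaling covariate.

    Returns a cohort whose ``icv`` column holds the TCV values and whose
    region list no longer includes the TCV measure (it cannot be both
    covariate and outcome). Individuals with a missing TCV are dropped,
    with their count recorded under ``metadata["dropped_missing_tcv"]``.
    The covariate keeps the name ``icv`` in all downstream mean models.
    """
    if tcv_region not in cohort.region_names:
        raise ValidationError(f"region {tcv_region!r} not in the cohort")
    table = cohort.table.copy()
    n_before = len(table)
    table = table[table[tcv_region].notna()].copy()
    table["icv"] = table[tcv_region]
    table = table.drop(columns=[tcv_region]).reset_index(drop=True)
    regions = [r for r in cohort.region_names if r != tcv_region]
    meta = dict(cohort.metadata)
    meta["dropped_missing_tcv"] = n_before - len(table)
    meta["scaling_covariate"] = tcv_region
    return Cohort(table, regions, meta)


def _zyg_groups_present(cohort: Cohort, dataset: str) -> list[str]:
    t = cohort.table
    sub = t[(t["dataset"] == dataset) & t["zygosity_group"].notna()]
    return sorted(sub["zygosity_group"].unique())


def _n_complete_pairs(cohort: Cohort, region: str, dataset: str) -> dict[str, int]:
    counts = {"MZ": 0, "DZ": 0}
    for b in family_blocks(cohort, dataset):
        if b.zygosity_group is None:
            continue
        roles = b.roles
        if "twin1" in roles and "twin2" in roles:
            i, j = roles.index("twin1"), roles.index("twin2")
            ridx = b.region_names.index(region)
            if not (np.isnan(b.phenotypes[i, ridx]) or np.isnan(b.phenotypes[j, ridx])):
                counts["MZ" if b.zygosity_group.startswith("MZ") else "DZ"] += 1
    return counts


def saturated_spec(cohort: Cohort, region: str, dataset: str,
                   covariates=("age", "icv")) -> TwinModelSpec:
    """Fully free structure: means and variances per twin-order x zygosity
    group plus sibling terms, free per-group co-twin covariance.

    A sex regressor is exactly collinear with the group intercepts for all
    same-sex zygosity groups, so the saturated means model carries only
    age/ICV betas; sex is tested in the order/zygosity-equated model
    (see :func:`correlation_spec`).
    """
    covs = tuple(c for c in covariates if c != "sex")
    return TwinModelSpec(traits=(region,), kind="saturated", covariates=covs)


def _with_covs(spec: TwinModelSpec, covs) -> TwinModelSpec:
    from dataclasses import replace
    return replace(spec, covariates=tuple(covs))


def _order_mean_ties(zygs, dataset):
    return {f"mu[{dataset}|{z}|twin2]": f"mu[{dataset}|{z}|twin1]" for z in zygs}


def _zyg_mean_ties(zygs, dataset):
    ref = zygs[0]
    return {f"mu[{dataset}|{z}|twin1]": f"mu[{dataset}|{ref}|twin1]"
            for z in zygs[1:]}


def _order_var_ties(zygs, dataset):
    return {f"v[{dataset}|{z}|twin2]": f"v[{dataset}|{z}|twin1]" for z in zygs}


def _zyg_var_ties(zygs, dataset):
    ref = zygs[0]
    return {f"v[{dataset}|{z}|twin1]": f"v[{dataset}|{ref}|twin1]"
            for z in zygs[1:]}


def correlation_spec(cohort: Cohort, region: str, dataset: str,
                     covariates=("age", "sex", "icv")) -> TwinModelSpec:
    """Twin-correlation structure: means equated across order, zygosity
    and sibling status; variances and co-twin covariances equated across
    order and across groups within zygosity class (MZ vs DZ kept free),
    so rMZ = c_MZ/v_MZ and rDZ = c_DZ/v_DZ are maximum-likelihood
    correlations that use unpaired twins' information."""
    zygs = _zyg_groups_present(cohort, dataset)
    if not zygs:
        raise FitError(f"dataset {dataset!r}: no zygosity groups present")
    mz = [z for z in zygs if z in _MZ]
    dz = [z for z in zygs if z in _DZ]
    ties = dict(_order_mean_ties(zygs, dataset))
    ties.update(_zyg_mean_ties(zygs, dataset))
    ties.update(_order_var_ties(zygs, dataset))
    for cls in (mz, dz):
        ref = cls[0] if cls else None
        for z in cls[1:]:
            ties[f"v[{dataset}|{z}|twin1]"] = f"v[{dataset}|{ref}|twin1]"
            ties[f"c[{dataset}|{z}]"] = f"c[{dataset}|{ref}]"
    has_sib = (cohort.table[(cohort.table["dataset"] == dataset)]["role"] == "sibling").any()
    if has_sib:
        ties[f"mu[{dataset}|sib]"] = f"mu[{dataset}|{zygs[0]}|twin1]"
        ties[f"v[{dataset}|sib]"] = f"v[{dataset}|{zygs[0]}|twin1]"
    return TwinModelSpec(traits=(region,), kind="saturated",
                         covariates=tuple(covariates), ties=ties)


def run_saturated(
    cohort: Cohort,
    region: str,
    dataset: str,
    *,
    covariates=("age", "sex", "icv"),
    min_pairs: int = 20,
    compute_ci: bool = False,
    n_starts: int = 2,
) -> dict:
    """Assumption tests, covariate tests and ML twin correlations for one
    region in one dataset.

    Assumption tests form a sequential nested chain on the saturated
    structure (each constrained model is compared to the previous step):
    birth-order means -> zygosity-group means -> twin-vs-sibling means ->
    birth-order variances -> zygosity-group variances -> twin-vs-sibling
    variances. Covariate tests (age, sex, ICV; each df = 1) compare the
    order/zygosity-equated correlation model with and without the
    regressor. Contrasts that are inestimable (absent groups) are skipped
    and reported as NaN.
    """
    sub = cohort.subset(dataset)
    pairs = _n_complete_pairs(sub, region, dataset)
    if pairs["MZ"] < min_pairs or pairs["DZ"] < min_pairs:
        raise FitError(
            f"region {region!r} in {dataset!r}: {pairs} complete pairs; "
            f"floor is {min_pairs} per zygosity class")
    zygs = _zyg_groups_present(sub, dataset)
    has_sib = (sub.table["role"] == "sibling").any()
    sat_covs = tuple(c for c in covariates if c != "sex")

    base = TwinModelSpec(traits=(region,), kind="saturated", covariates=sat_covs)
    fits: dict[str, FitResult] = {}
    fits["full"] = fit(base, sub, n_starts=n_starts)

    chain = [("order_means", dict(_order_mean_ties(zygs, dataset)))]
    chain.append(("zyg_means", dict(_zyg_mean_ties(zygs, dataset))))
    if has_sib:
        chain.append(("twin_sib_means",
                      {f"mu[{dataset}|sib]": f"mu[{dataset}|{zygs[0]}|twin1]"}))
    chain.append(("order_vars", dict(_order_var_ties(zygs, dataset))))
    chain.append(("zyg_vars", dict(_zyg_var_ties(zygs, dataset))))
    if has_sib:
        chain.append(("twin_sib_vars",
                      {f"v[{dataset}|sib]": f"v[{dataset}|{zygs[0]}|twin1]"}))

    row: dict = {"region": region, "dataset": dataset,
                 "n_mz_pairs": pairs["MZ"], "n_dz_pairs": pairs["DZ"]}
    prev_key, ties_so_far = "full", {}
    for name, ties in chain:
        ties_so_far = {**ties_so_far, **ties}
        spec_c = base.with_constraints(ties=ties_so_far)
        fits[name] = fit(spec_c, sub, n_starts=n_starts)
        try:
            stat, df, p = lrt(fits[prev_key], fits[name])
        except (FitError, ValidationError):
            stat, df, p = math.nan, 0, math.nan
        row[f"p_{name}"] = p
        prev_key = name
    for name in ("twin_sib_means", "twin_sib_vars"):
        row.setdefault(f"p_{name}", math.nan)

    # covariate tests on the order/zygosity-equated model
    corr_full = correlation_spec(sub, region, dataset, covariates=covariates)
    fit_corr = fit(corr_full, sub, n_starts=n_starts)
    for c in covariates:
        dropped = _with_covs(corr_full, [x for x in covariates if x != c])
        # keep ties valid: they do not reference covariate params
        fit_drop = fit(dropped, sub, n_starts=n_starts)
        try:
            _, _, p = lrt(fit_corr, fit_drop)
        except (FitError, ValidationError):
            p = math.nan
        row[f"p_{c}"] = p
    for c in ("age", "sex", "icv"):
        row.setdefault(f"p_{c}", math.nan)

    std = fit_corr.standardized
    mz_ref = next((z for z in zygs if z in _MZ), None)
    dz_ref = next((z for z in zygs if z in _DZ), None)
    row["rMZ"] = std.get(f"r[{dataset}|{mz_ref}]", math.nan) if mz_ref else math.nan
    row["rDZ"] = std.get(f"r[{dataset}|{dz_ref}]", math.nan) if dz_ref else math.nan
    if compute_ci:
        for label, ref in (("rMZ", mz_ref), ("rDZ", dz_ref)):
            if ref is None:
                row[f"{label}_ci_low"] = row[f"{label}_ci_high"] = math.nan
                continue
            lo, hi = profile_ci(fit_corr, f"r[{dataset}|{ref}]",
                                search_halfwidth=1.5)
            row[f"{label}_ci_low"], row[f"{label}_ci_high"] = lo, hi
    row["fits"] = fits
    row["fit_correlation_model"] = fit_corr
    return row


_SUBMODELS = {"AE": ("C",), "CE": ("A",), "E": ("A", "C")}


def run_univariate(
    cohort: Cohort,
    region: str,
    *,
    covariates=("age", "sex", "icv"),
    alpha: float = 0.05,
    compute_ci: bool = True,
    force_model: str | None = None,
    n_starts: int = 3,
) -> dict:
    """ACE-family decomposition for one region with cross-dataset equating.

    Fits (1) dataset-specific ACE (separate means and variance
    components), (2) ACE with variance components equated across datasets
    (means stay dataset-specific), (3) AE/CE/E sub-models of (2); tests
    equating by LRT (df = 3 per extra dataset) and selects a sub-model by
    the LRT-first/AIC rule unless ``force_model`` pins one. When equating
    is rejected at ``alpha`` the row is flagged and per-dataset
    standardized estimates are reported alongside the pooled ones.
    """
    datasets = cohort.datasets
    multi = len(datasets) > 1
    covs = tuple(covariates)

    ace_equated = TwinModelSpec(traits=(region,), components=("A", "C", "E"),
                                covariates=covs, equate_datasets=True)
    fits: dict[str, FitResult] = {}
    fits["ACE_equated"] = fit(ace_equated, cohort, n_starts=n_starts)
    row: dict = {"region": region, "datasets": list(datasets)}

    if multi:
        ace_specific = TwinModelSpec(traits=(region,), components=("A", "C", "E"),
                                     covariates=covs, equate_datasets=False)
        fits["ACE_specific"] = fit(ace_specific, cohort, n_starts=n_starts)
        try:
            stat, df, p_eq = lrt(fits["ACE_specific"], fits["ACE_equated"])
        except FitError:
            stat, df, p_eq = math.nan, 3, math.nan
        row["equating_lrt_stat"], row["equating_lrt_df"], row["p_equating"] = stat, df, p_eq
        row["equating_rejected"] = bool(p_eq < alpha) if np.isfinite(p_eq) else False
    else:
        row["p_equating"] = math.nan
        row["equating_rejected"] = False

    # sub-models of the equated structure
    p_sub = {}
    for label, dropped in _SUBMODELS.items():
        fits[label] = fit(ace_equated.drop_components(*dropped), cohort,
                          n_starts=n_starts)
        try:
            _, _, p_sub[label] = lrt(fits["ACE_equated"], fits[label])
        except FitError:
            p_sub[label] = math.nan
        row[f"p_{label}_vs_ACE"] = p_sub[label]

    if force_model is not None:
        if force_model not in ("ACE", "AE", "CE", "E"):
            raise ValidationError(f"unknown model label {force_model!r}")
        selected = force_model
    else:
        candidates = ["ACE_equated"] + [
            m for m in ("AE", "CE", "E")
            if np.isfinite(p_sub[m]) and p_sub[m] >= alpha]
        selected = min(candidates, key=lambda m: fits[m].aic)
        selected = "ACE" if selected == "ACE_equated" else selected
    row["selected_model"] = selected
    sel_fit = fits["ACE_equated"] if selected == "ACE" else fits[selected]
    row["selected_fit_converged"] = sel_fit.converged
    row["aic_selected"] = sel_fit.aic
    for comp in ("A", "C", "E"):
        key = f"std_{comp}[pooled|{region}]"
        row[f"std_{comp}"] = sel_fit.standardized.get(key, math.nan)
    if compute_ci and sel_fit.converged:
        for comp in [c for c in ("A", "C", "E") if c in (selected if selected != "ACE" else "ACE")]:
            try:
                lo, hi = profile_ci(sel_fit, f"std_{comp}[pooled|{region}]")
            except (FitError, ValidationError):
                lo = hi = math.nan
            row[f"std_{comp}_ci_low"], row[f"std_{comp}_ci_high"] = lo, hi

    if multi and row["equating_rejected"]:
        spec_sel_specific = TwinModelSpec(
            traits=(region,), components=("A", "C", "E"), covariates=covs,
            equate_datasets=False)
        if selected != "ACE":
            spec_sel_specific = spec_sel_specific.drop_components(*_SUBMODELS[selected])
        f_spec = fit(spec_sel_specific, cohort, n_starts=n_starts)
        for d in datasets:
            for comp in ("A", "C", "E"):
                row[f"std_{comp}[{d}]"] = f_spec.standardized.get(
                    f"std_{comp}[{d}|{region}]", math.nan)
        fits["selected_specific"] = f_spec
    row["fits"] = fits
    return row


@dataclass
class PooledEstimate:
    estimate: float
    se: float
    ci95: tuple[float, float]


def meta_analyze(est1, est2) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling of two dataset estimates.

    Each input is ``(estimate, ci_low, ci_high)`` with a 95% interval; the
    standard error is taken as CI width / 3.92. A zero-width interval
    implies an infinite weight and raises.
    """
    ests, ses = [], []
    for est, lo, hi in (est1, est2):
        width = hi - lo
        if width <= 0 or not np.isfinite(width):
            raise ValidationError("CI width must be positive and finite")
        ests.append(float(est))
        ses.append(width / 3.92)
    w = np.array([1.0 / s ** 2 for s in ses])
    pooled = float(np.sum(w * np.array(ests)) / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    return PooledEstimate(pooled, se, (pooled - 1.96 * se, pooled + 1.96 * se))
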