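"""End-to-end orchestration: QC -> reliability -> saturated -> univariate
-> bivariate -> FDR, with a run manifest that suffices to reproduce the
run bit-identically."""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivariate import assemble_matrices, fit_bivariate
from .cohort import read_cohort, read_retest, write_cohort
from .errors import FitError, TwinvolError, ValidationError
from .icc import icc_table
from .inference import TestFamily, benjamini_hochberg
from .qc import DEFAULT_Z_THRESHOLD, flag_outliers
from .simulate import GenerativeSpec, simulate_cohort, simulate_retest
from .univariate import run_saturated, run_univariate, with_tcv_covariate

log = logging.getLogger("twinvol")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``cohort_path`` / ``generative_spec`` must be given.
    All thresholds are echoed into the manifest.
    """

    out_dir: str
    cohort_path: str | None = None
    retest_path: str | None = None
    generative_spec: GenerativeSpec | None = None
    simulate_retest_reliability: float | None = None
    regions: list[str] | None = None
    z_threshold: float = DEFAULT_Z_THRESHOLD
    covariates: tuple = ("age", "sex", "icv")
    alpha: float = 0.05
    pool_datasets: bool = True
    uniform_selection: bool = True
    selection_majority: float = 0.5
    compute_ci: bool = False
    run_bivariate: bool = True
    min_pairs: int = 20
    #: region name to use as the scaling covariate instead of ICV
    #: (e.g. "total_cerebellum"); that region is then excluded as an outcome
    scaling_covariate: str = "icv"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generative_spec is None):
            raise ValidationError(
                "exactly one of cohort_path / generative_spec is required")


def _manifest(config: RunConfig) -> dict:
    d = {}
    for k, v in asdict(config).items():
        if k == "generative_spec":
            v = config.generative_spec.to_dict() if config.generative_spec else None
        d[k] = v
    d["twinvol_version"] = __version__
    return d


def run_all(config: RunConfig) -> Path:
    """Execute every stage in workflow order and write all outputs.

    A stage failure is recorded in the manifest and its downstream
    dependents are skipped with provenance; identical config + seed
    produce identical outputs.
    """
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise TwinvolError(f"cannot create output directory {out}: {e}") from e
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = _manifest(config)
    manifest["stages"] = {}
    failures: list[str] = []

    def stage(name: str):
        def deco(fn):
            def run(*a, **k):
                t0 = time.time()
                try:
                    res = fn(*a, **k)
                    manifest["stages"][name] = {
                        "status": "ok", "seconds": round(time.time() - t0, 3)}
                    log.info("stage %s ok (%.2fs)", name, time.time() - t0)
                    return res
                except TwinvolError as e:
                    manifest["stages"][name] = {"status": "failed", "error": str(e)}
                    failures.append(name)
                    log.error("stage %s failed: %s", name, e)
                    return None
            return run
        return deco

    try:
        # ---- input
        if config.generative_spec is not None:
            cohort, truth = simulate_cohort(config.generative_spec)
            write_cohort(cohort, out / "cohort_input.tsv")
            (out / "synthetic_truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, default=str))
            retest = None
            if config.simulate_retest_reliability is not None:
                retest = simulate_retest(
                    cohort, config.simulate_retest_reliability,
                    seed=config.seed + 1)
        else:
            cohort = read_cohort(config.cohort_path)
            retest = read_retest(config.retest_path) if config.retest_path else None
        regions = config.regions or cohort.region_names

        # ---- QC
        @stage("qc")
        def _qc():
            clean, report = flag_outliers(cohort, config.z_threshold)
            report.to_tsv(out / "qc_report.tsv")
            return clean

        clean = _qc()
        if clean is None:
            raise TwinvolError("QC failed; aborting")
        if config.scaling_covariate != "icv":
            clean = with_tcv_covariate(clean, config.scaling_covariate)
            regions = [r for r in regions if r != config.scaling_covariate]
            log.info("scaling covariate: %s (excluded as outcome; %d rows "
                     "dropped for missing values)", config.scaling_covariate,
                     clean.metadata["dropped_missing_tcv"])

        # ---- reliability (optional)
        @stage("reliability")
        def _icc():
            table = icc_table(retest, regions)
            table.to_csv(out / "icc.tsv", sep="\t", index=False)
            return table

        if retest is not None:
            _icc()
        else:
            manifest["stages"]["reliability"] = {"status": "skipped",
                                                 "reason": "no retest table"}
            log.info("stage reliability skipped: no retest table")

        # ---- saturated
        @stage("saturated")
        def _saturated():
            rows = []
            for ds in clean.datasets:
                for region in regions:
                    try:
                        row = run_saturated(clean, region, ds,
                                            covariates=config.covariates,
                                            min_pairs=config.min_pairs)
                        row.pop("fits", None)
                        row.pop("fit_correlation_model", None)
                    except (FitError, ValidationError) as e:
                        row = {"region": region, "dataset": ds,
                               "inestimable": str(e)}
                    rows.append(row)
            df = pd.DataFrame(rows)
            # FDR within the two families the tests belong to
            for fam_label, cols in (
                ("covariates", ["p_age", "p_sex", "p_icv"]),
                ("assumptions", ["p_order_means", "p_zyg_means",
                                 "p_twin_sib_means", "p_order_vars",
                                 "p_zyg_vars", "p_twin_sib_vars"]),
            ):
                fam = TestFamily(label=fam_label, alpha=config.alpha)
                for i, r in df.iterrows():
                    for c in cols:
                        p = r.get(c, math.nan)
                        if isinstance(p, float) and np.isfinite(p):
                            fam.add(f"{i}|{c}", p)
                if fam.test_ids:
                    adj = benjamini_hochberg(fam)
                    for tid, padj in zip(adj["test_id"], adj["p_adjusted"]):
                        i, c = tid.split("|")
                        df.loc[int(i), c + "_fdr"] = padj
            df.to_csv(out / "saturated_report.tsv", sep="\t", index=False)
            return df

        _saturated()

        # ---- univariate
        @stage("univariate")
        def _univariate():
            rows = []
            for region in regions:
                try:
                    row = run_univariate(clean, region,
                                         covariates=config.covariates,
                                         alpha=config.alpha,
                                         compute_ci=config.compute_ci)
                    row.pop("fits", None)
                except (FitError, ValidationError) as e:
                    row = {"region": region, "inestimable": str(e)}
                rows.append(row)
            df = pd.DataFrame(rows)
            if config.uniform_selection and "selected_model" in df.columns:
                counts = df["selected_model"].value_counts()
                if len(counts) and counts.iloc[0] / counts.sum() > config.selection_majority:
                    winner = counts.index[0]
                    df["selected_model_uniform"] = winner
                    log.info("uniform selection: %s (majority %.0f%%)",
                             winner, 100 * counts.iloc[0] / counts.sum())
            fam = TestFamily(label="univariate_model_fits", alpha=config.alpha)
            for i, r in df.iterrows():
                for c in ("p_equating", "p_AE_vs_ACE", "p_CE_vs_ACE", "p_E_vs_ACE"):
                    p = r.get(c, math.nan)
                    if isinstance(p, float) and np.isfinite(p):
                        fam.add(f"{i}|{c}", p)
            if fam.test_ids:
                adj = benjamini_hochberg(fam)
                for tid, padj in zip(adj["test_id"], adj["p_adjusted"]):
                    i, c = tid.split("|")
                    df.loc[int(i), c + "_fdr"] = padj
            df.to_csv(out / "univariate_result.tsv", sep="\t", index=False)
            return df

        uni = _univariate()

        # ---- bivariate
        @stage("bivariate")
        def _bivariate():
            estimable = regions
            if uni is not None and "selected_fit_converged" in uni.columns:
                ok = uni[uni["selected_fit_converged"].fillna(False)]["region"]
                estimable = [r for r in regions if r in set(ok)]
            decomps = []
            for r1, r2 in combinations(estimable, 2):
                try:
                    decomps.append(fit_bivariate(
                        clean, r1, r2, equate_datasets=config.pool_datasets,
                        covariates=config.covariates))
                except (FitError, ValidationError) as e:
                    log.warning("bivariate pair (%s, %s) failed: %s", r1, r2, e)
            mats = assemble_matrices(decomps, estimable, alpha=config.alpha)
            mats.write(out / "bivariate")
            return mats

        if config.run_bivariate and len(regions) >= 2:
            _bivariate()
        else:
            manifest["stages"]["bivariate"] = {"status": "skipped"}

    finally:
        manifest["failures"] = failures
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
        log.removeHandler(handler)
        handler.close()
    return out
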