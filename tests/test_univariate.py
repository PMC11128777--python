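"""Per-region univariate workflow: assumption tests, equating, model
selection, meta-analysis."""

import math

import numpy as np
import pytest

from twinvol.errors import FitError, ValidationError
from twinvol.likelihood import TwinModelSpec, fit, lrt
from twinvol.simulate import (DatasetComposition, GenerativeSpec,
                              simulate_cohort, small_spec)
from twinvol.univariate import (meta_analyze, run_saturated, run_univariate)


def _two_dataset_spec(a2_1, a2_2, n1=150, n2=150, seed=0):
    r = 1
    return GenerativeSpec(
        regions=["region_1"],
        composition={
            "DS1": DatasetComposition(n_mz_pairs=n1, n_dz_pairs=n1),
            "DS2": DatasetComposition(n_mz_pairs=n2, n_dz_pairs=n2),
        },
        a2={"DS1": [a2_1], "DS2": [a2_2]},
        c2=np.zeros(r), e2={"DS1": [1 - a2_1], "DS2": [1 - a2_2]},
        total_var=np.ones(r), R_A=np.eye(r), R_E=np.eye(r),
        seed=seed,
    )


class TestMetaAnalyze:
    def test_identical_inputs(self):
        pooled = meta_analyze((0.8, 0.8 - 1.96 * 0.05, 0.8 + 1.96 * 0.05),
                              (0.8, 0.8 - 1.96 * 0.05, 0.8 + 1.96 * 0.05))
        assert pooled.estimate == pytest.approx(0.8)
        assert pooled.se == pytest.approx(0.05 / math.sqrt(2), rel=1e-6)

    def test_equal_weights_midpoint(self):
        pooled = meta_analyze((0.6, 0.6 - 0.196, 0.6 + 0.196),
                              (0.8, 0.8 - 0.196, 0.8 + 0.196))
        assert pooled.estimate == pytest.approx(0.7)

    def test_unequal_weights_match_explicit_oracle(self):
        se1, se2 = 0.05, 0.15
        e1, e2 = 0.5, 0.9
        pooled = meta_analyze((e1, e1 - 1.96 * se1, e1 + 1.96 * se1),
                              (e2, e2 - 1.96 * se2, e2 + 1.96 * se2))
        w1, w2 = 1 / se1 ** 2, 1 / se2 ** 2
        oracle = (w1 * e1 + w2 * e2) / (w1 + w2)
        assert pooled.estimate == pytest.approx(oracle, rel=1e-9)
        assert pooled.se == pytest.approx(math.sqrt(1 / (w1 + w2)), rel=1e-9)
        assert pooled.ci95[0] < pooled.estimate < pooled.ci95[1]

    def test_zero_width_ci_rejected(self):
        with pytest.raises(ValidationError):
            meta_analyze((0.8, 0.8, 0.8), (0.7, 0.6, 0.8))


def test_run_univariate_selects_ae_under_ae_truth():
    cohort, _ = simulate_cohort(_two_dataset_spec(0.8, 0.8, seed=51))
    row = run_univariate(cohort, "region_1", covariates=(), compute_ci=True)
    assert row["selected_model"] == "AE"
    assert row["std_A"] == pytest.approx(0.8, abs=0.08)
    assert row["std_A"] + row["std_E"] == pytest.approx(1.0, abs=1e-6)
    assert row["std_A_ci_low"] < row["std_A"] < row["std_A_ci_high"]
    assert not row["equating_rejected"]
    assert np.isfinite(row["p_equating"])


def test_run_univariate_detects_heterogeneity():
    """Strong a2 difference between datasets rejects the equating LRT and
    reports per-dataset estimates."""
    cohort, _ = simulate_cohort(_two_dataset_spec(0.8, 0.3, n1=250, n2=250,
                                                  seed=52))
    row = run_univariate(cohort, "region_1", covariates=(), compute_ci=False)
    assert row["equating_rejected"]
    assert row["std_A[DS1]"] > row["std_A[DS2]"]
    assert row["std_A[DS1]"] == pytest.approx(0.8, abs=0.12)
    assert row["std_A[DS2]"] == pytest.approx(0.3, abs=0.15)


def test_ce_not_selected_when_truth_has_no_c():
    cohort, _ = simulate_cohort(small_spec(n_mz_pairs=1500, n_dz_pairs=1500,
                                           a2=0.6, seed=53))
    row = run_univariate(cohort, "region_1", covariates=(), compute_ci=False)
    assert row["selected_model"] in ("AE", "ACE")
    assert row["p_CE_vs_ACE"] < 0.05


def test_run_saturated_reports_structure(mixed_cohort):
    cohort, _ = mixed_cohort
    row = run_saturated(cohort, "region_1", "SIM")
    for key in ("p_order_means", "p_zyg_means", "p_order_vars", "p_zyg_vars",
                "p_age", "p_sex", "p_icv", "rMZ", "rDZ"):
        assert key in row
    assert -1 <= row["rMZ"] <= 1 and -1 <= row["rDZ"] <= 1
    assert row["rMZ"] > row["rDZ"]          # a2=0.8 world
    assert row["n_mz_pairs"] >= 20 and row["n_dz_pairs"] >= 20


def test_run_saturated_min_pairs_floor():
    cohort, _ = simulate_cohort(small_spec(n_mz_pairs=5, n_dz_pairs=5,
                                           a2=0.5, seed=54))
    with pytest.raises(FitError, match="floor"):
        run_saturated(cohort, "region_1", "SIM", min_pairs=20)


def test_twin_correlations_match_generative_algebra():
    """rMZ -> a2 + c2 and rDZ -> a2/2 + c2 from the ML correlation model."""
    cohort, _ = simulate_cohort(small_spec(n_mz_pairs=1200, n_dz_pairs=1200,
                                           a2=0.6, c2=0.2, seed=55))
    row = run_saturated(cohort, "region_1", "SIM", covariates=())
    assert row["rMZ"] == pytest.approx(0.8, abs=0.05)
    assert row["rDZ"] == pytest.approx(0.5, abs=0.05)


def test_birth_order_null_calibration():
    """Order-means equality LRT is calibrated under a null generator
    (scaled-down replicate count; tolerance from the binomial SE)."""
    n_rep, alpha = 120, 0.05
    rejections = 0
    for rep in range(n_rep):
        cohort, _ = simulate_cohort(small_spec(
            n_mz_pairs=60, n_dz_pairs=60, a2=0.5, seed=1000 + rep))
        base = TwinModelSpec(traits=("region_1",), kind="saturated")
        full = fit(base, cohort, n_starts=1)
        zygs = sorted(cohort.table["zygosity_group"].dropna().unique())
        ties = {f"mu[SIM|{z}|twin2]": f"mu[SIM|{z}|twin1]" for z in zygs}
        constrained = fit(base.with_constraints(ties=ties), cohort, n_starts=1)
        _, df, p = lrt(full, constrained)
        assert df == len(zygs)
        rejections += p < alpha
    rate = rejections / n_rep
    se = math.sqrt(alpha * (1 - alpha) / n_rep)
    assert abs(rate - alpha) < 3.5 * se + 1e-9


def test_omitting_family_shared_icv_inflates_c():
    """ICV carries a family-shared component; omitting it from the means
    model pushes that variance into C."""
    spec = small_spec(n_mz_pairs=1500, n_dz_pairs=1500, a2=0.4, c2=0.0,
                      beta_icv=8e-6, seed=56)
    cohort, _ = simulate_cohort(spec)
    with_icv = fit(TwinModelSpec(traits=("region_1",),
                                 components=("A", "C", "E"),
                                 covariates=("icv",)), cohort, n_starts=2)
    without = fit(TwinModelSpec(traits=("region_1",),
                                components=("A", "C", "E")), cohort,
                  n_starts=2)
    c_with = with_icv.standardized["std_C[pooled|region_1]"]
    c_without = without.standardized["std_C[pooled|region_1]"]
    assert c_without > c_with + 0.05


def test_pooled_h2_between_dataset_estimates():
    cohort, _ = simulate_cohort(_two_dataset_spec(0.75, 0.65, n1=400, n2=400,
                                                  seed=57))
    specific = fit(TwinModelSpec(traits=("region_1",), components=("A", "E"),
                                 equate_datasets=False), cohort, n_starts=2)
    pooled = fit(TwinModelSpec(traits=("region_1",), components=("A", "E"),
                               equate_datasets=True), cohort, n_starts=2)
    h1 = specific.standardized["std_A[DS1|region_1]"]
    h2 = specific.standardized["std_A[DS2|region_1]"]
    hp = pooled.standardized["std_A[pooled|region_1]"]
    assert min(h1, h2) - 0.02 <= hp <= max(h1, h2) + 0.02


def test_tcv_covariate_mode():
    """Total cerebellar volume can replace ICV as the scaling covariate;
    it is then excluded as an outcome and its missing rows are dropped."""
    from twinvol.univariate import with_tcv_covariate
    cohort, _ = simulate_cohort(small_spec(
        n_mz_pairs=80, n_dz_pairs=80, a2=0.6, n_regions=3,
        missing_rate=0.02, seed=58))
    # volumes are positive in real data; the zero-mean test world needs a shift
    cohort.table["region_3"] = cohort.table["region_3"] + 100.0
    swapped = with_tcv_covariate(cohort, "region_3")
    assert "region_3" not in swapped.region_names
    assert swapped.region_names == ["region_1", "region_2"]
    assert not swapped.table["icv"].isna().any()
    assert swapped.metadata["scaling_covariate"] == "region_3"
    # the swapped covariate flows through a variance-model fit
    res = fit(TwinModelSpec(traits=("region_1",), components=("A", "E"),
                            covariates=("icv",)), swapped, n_starts=1)
    assert res.converged


def test_equating_lrt_power_under_heterogeneity():
    """a2 = 0.8 vs 0.4 between datasets at 250+125 pairs: the equating
    LRT detects heterogeneity in most replicates (scaled-down replicate
    count; the asserted floor allows for binomial noise)."""
    n_rep, detected = 40, 0
    for rep in range(n_rep):
        cohort, _ = simulate_cohort(_two_dataset_spec(
            0.8, 0.4, n1=250, n2=125, seed=60_000 + rep))
        full = fit(TwinModelSpec(traits=("region_1",),
                                 components=("A", "C", "E"),
                                 equate_datasets=False), cohort, n_starts=1)
        constrained = fit(TwinModelSpec(traits=("region_1",),
                                        components=("A", "C", "E"),
                                        equate_datasets=True), cohort,
                          n_starts=1)
        _, _, p = lrt(full, constrained)
        detected += p < 0.05
    assert detected / n_rep > 0.7


def test_ce_never_selected_at_large_n_without_c():
    """Model-selection consistency: with c2 = 0 truth and large samples,
    CE is never preferred (scaled-down: 10 replicates, 1,500+1,500 pairs)."""
    for rep in range(10):
        cohort, _ = simulate_cohort(small_spec(
            n_mz_pairs=1500, n_dz_pairs=1500, a2=0.6, seed=70_000 + rep))
        row = run_univariate(cohort, "region_1", covariates=(),
                             compute_ci=False, n_starts=1)
        assert row["selected_model"] != "CE"
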