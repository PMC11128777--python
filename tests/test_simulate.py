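"""Generative model checks: twin-correlation algebra, determinism,
covariate recovery, outlier injection, retest calibration."""

import numpy as np
import pandas as pd
import pytest

from twinvol.errors import ValidationError
from twinvol.simulate import (GenerativeSpec, default_two_dataset_spec,
                              inject_outliers, simulate_cohort,
                              simulate_retest, small_spec)


def pair_correlation(cohort, region, zygs):
    tb = cohort.table
    sub = tb[tb.zygosity_group.isin(zygs)]
    wide = sub.pivot(index="family_id", columns="role", values=region)
    wide = wide[["twin1", "twin2"]].dropna()
    return float(np.corrcoef(wide["twin1"], wide["twin2"])[0, 1])


MZ, DZ = ["MZF", "MZM"], ["DZF", "DZM", "DZOS"]


def test_no_familial_variance_gives_zero_twin_correlations():
    spec = small_spec(n_mz_pairs=2000, n_dz_pairs=2000, a2=0.0, seed=1)
    cohort, _ = simulate_cohort(spec)
    assert abs(pair_correlation(cohort, "region_1", MZ)) < 0.05
    assert abs(pair_correlation(cohort, "region_1", DZ)) < 0.05


def test_determinism_field_for_field():
    spec = small_spec(n_mz_pairs=50, n_dz_pairs=50, a2=0.5, n_sib_families=10,
                      n_unpaired=10, missing_rate=0.05, seed=42)
    c1, _ = simulate_cohort(spec)
    spec2 = small_spec(n_mz_pairs=50, n_dz_pairs=50, a2=0.5, n_sib_families=10,
                       n_unpaired=10, missing_rate=0.05, seed=42)
    c2, _ = simulate_cohort(spec2)
    pd.testing.assert_frame_equal(c1.table, c2.table)
    spec3 = small_spec(n_mz_pairs=50, n_dz_pairs=50, a2=0.5, n_sib_families=10,
                       n_unpaired=10, missing_rate=0.05, seed=43)
    c3, _ = simulate_cohort(spec3)
    assert not c1.table.equals(c3.table)


def test_total_variance_matches_spec():
    """Large-sample phenotypic variance ~ specified ACE variance (3%)."""
    spec = small_spec(n_mz_pairs=5000, n_dz_pairs=5000, a2=0.6, c2=0.2,
                      total_var=4.0, seed=7)
    cohort, _ = simulate_cohort(spec)
    v = np.var(cohort.table["region_1"], ddof=1)
    assert abs(v - 4.0) / 4.0 < 0.03


def test_cross_trait_cross_twin_mz_covariance():
    """MZ cross-trait cross-twin correlation ~ a1*a2*R_A[1,2] (+ e-term 0)."""
    R_A = np.array([[1.0, 0.6], [0.6, 1.0]])
    spec = small_spec(n_mz_pairs=5000, n_dz_pairs=100, a2=0.8, n_regions=2,
                      R_A=R_A, seed=8)
    cohort, _ = simulate_cohort(spec)
    tb = cohort.table[cohort.table.zygosity_group.isin(MZ)]
    w1 = tb.pivot(index="family_id", columns="role", values="region_1")
    w2 = tb.pivot(index="family_id", columns="role", values="region_2")
    r = np.corrcoef(w1["twin1"], w2["twin2"])[0, 1]
    expected = 0.8 * 0.6        # sqrt(a1^2 * a2^2) * R_A12
    assert abs(r - expected) < 0.03


def test_covariate_effects_recovered_by_ols():
    spec = small_spec(n_mz_pairs=2000, n_dz_pairs=2000, a2=0.5,
                      beta_age=0.05, beta_sex=0.4, beta_icv=2e-6, seed=9)
    cohort, _ = simulate_cohort(spec)
    tb = cohort.table
    X = np.column_stack([np.ones(len(tb)), tb["age"], tb["sex"], tb["icv"]])
    beta, *_ = np.linalg.lstsq(X, tb["region_1"], rcond=None)
    assert abs(beta[1] - 0.05) < 0.01
    assert abs(beta[2] - 0.4) < 0.05
    assert abs(beta[3] - 2e-6) < 2e-7


def test_default_world_composition():
    cohort, truth = simulate_cohort(default_two_dataset_spec(seed=3))
    tb = cohort.table
    assert len(tb) == 798 + 396
    assert set(tb["dataset"]) == {"QTIM", "QTAB"}
    assert (tb[tb.dataset == "QTIM"]["role"] == "sibling").sum() == 36
    assert (tb[tb.dataset == "QTAB"]["role"] == "sibling").sum() == 0
    assert len(cohort.region_names) == 29
    assert truth.spec.seed == 3


def test_spec_validation():
    from twinvol.simulate import DatasetComposition
    with pytest.raises(ValidationError, match="non-negative"):
        small_spec(n_mz_pairs=10, n_dz_pairs=10, a2=0.9, c2=0.3)
    with pytest.raises(ValidationError, match="sum to 1"):
        GenerativeSpec(
            regions=["r"], composition={"D": DatasetComposition(n_mz_pairs=5)},
            a2=[0.5], c2=[0.2], e2=[0.5], total_var=[1.0],
            R_A=np.eye(1), R_E=np.eye(1))
    bad_R = np.array([[1.0, 1.5], [1.5, 1.0]])   # not PSD
    with pytest.raises(ValidationError, match="positive semi-definite"):
        small_spec(n_mz_pairs=10, n_dz_pairs=10, a2=0.5, n_regions=2, R_A=bad_R)


class TestInjectOutliers:
    def test_rate_zero_unchanged(self, ae_cohort):
        cohort, _ = ae_cohort
        out = inject_outliers(cohort, 0.0, 5.0, seed=1)
        pd.testing.assert_frame_equal(out.table, cohort.table)
        assert out.metadata["injected_outliers"] == []

    def test_counts_and_placement(self):
        spec = small_spec(n_mz_pairs=2500, n_dz_pairs=2500, a2=0.5, seed=4)
        cohort, _ = simulate_cohort(spec)      # 10,000 cells, 1 region
        clean_vals = cohort.table["region_1"].to_numpy()
        m, s = clean_vals.mean(), clean_vals.std(ddof=1)
        out = inject_outliers(cohort, 0.01, 5.0, seed=5)
        injected = out.metadata["injected_outliers"]
        n = len(injected)
        assert 60 <= n <= 140            # binomial(10000, 0.01) within ~4 SD
        idx = out.table.set_index("individual_id")
        vals = np.array([idx.loc[i, "region_1"] for i, _ in injected])
        assert (np.abs(vals - m) > 3.29 * s).all()

    def test_determinism_and_validation(self, ae_cohort):
        cohort, _ = ae_cohort
        a = inject_outliers(cohort, 0.02, 5.0, seed=9)
        b = inject_outliers(cohort, 0.02, 5.0, seed=9)
        assert a.metadata["injected_outliers"] == b.metadata["injected_outliers"]
        with pytest.raises(ValidationError, match="3.29"):
            inject_outliers(cohort, 0.02, 3.0, seed=9)
        with pytest.raises(ValidationError, match="rate"):
            inject_outliers(cohort, 1.5, 5.0, seed=9)


class TestSimulateRetest:
    def test_reliability_one_copies_test(self, ae_cohort):
        cohort, _ = ae_cohort
        rt = simulate_retest(cohort, 1.0, seed=2, n_subjects=43)
        assert len(rt) == 86
        wide = rt.pivot(index="individual_id", columns="visit", values="region_1")
        np.testing.assert_allclose(wide["test"], wide["retest"])

    def test_invalid_reliability(self, ae_cohort):
        cohort, _ = ae_cohort
        with pytest.raises(ValidationError):
            simulate_retest(cohort, 0.0, seed=2)
        with pytest.raises(ValidationError):
            simulate_retest(cohort, 1.2, seed=2)

    def test_target_correlation_at_large_n(self):
        spec = small_spec(n_mz_pairs=1000, n_dz_pairs=1000, a2=0.5, seed=6)
        cohort, _ = simulate_cohort(spec)
        rt = simulate_retest(cohort, 0.9, seed=7, n_subjects=2000)
        wide = rt.pivot(index="individual_id", columns="visit", values="region_1")
        r = np.corrcoef(wide["test"], wide["retest"])[0, 1]
        assert abs(r - 0.9) < 0.02
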