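"""Penalized-spline basis, fitting, smoothing selection and inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipobrain import (BasisSpec, GeneratorConfig, build_basis,
                        fit_group_trajectories, fit_pspline, generate_cohort)
from adipobrain import test_group_effects as group_effects_test
from adipobrain import test_interaction as interaction_test
from adipobrain.exceptions import (CollinearityError, DomainError, SupportError)


def _frame(ages, y):
    return pd.DataFrame({"age": ages, "y": y})


# ---------------------------------------------------------------- basis
@settings(derandomize=True, max_examples=25, deadline=None)
@given(ages=st.lists(st.floats(20.0, 87.0), min_size=1, max_size=50))
def test_basis_rows_are_partition_of_unity(ages):
    spec = BasisSpec(age_domain=(20.0, 87.0))
    B = build_basis(spec, np.asarray(ages))
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_linear_basis_hat_functions_at_midpoint():
    spec = BasisSpec(degree=1, n_knots=11, age_domain=(0.0, 10.0))
    B = build_basis(spec, np.array([4.5]))
    row = B[0]
    nz = row[row != 0]
    assert len(nz) == 2
    np.testing.assert_allclose(nz, [0.5, 0.5])


def test_basis_column_count():
    spec = BasisSpec(degree=3, n_knots=10, age_domain=(20.0, 87.0))
    B = build_basis(spec, np.linspace(20, 87, 40))
    assert B.shape[1] == 10 + 3 - 1


def test_basis_rejects_out_of_domain_ages():
    spec = BasisSpec(age_domain=(20.0, 87.0))
    with pytest.raises(DomainError):
        build_basis(spec, np.array([19.0]))


# ---------------------------------------------------------------- fitting
def test_huge_lambda_recovers_ols_line():
    rng = np.random.default_rng(42)
    ages = rng.uniform(20, 87, 150)
    y = 3.0 + 0.5 * ages + rng.normal(0, 0.5, 150)
    fit = fit_pspline(_frame(ages, y), "y", lam=1e12)
    X = np.column_stack([np.ones_like(ages), ages])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    grid, vals = fit.fitted_grid
    assert np.max(np.abs(vals - (beta[0] + beta[1] * grid))) < 1e-6


def test_noiseless_quadratic_recovered_by_gcv_and_reml():
    rng = np.random.default_rng(3)
    ages = rng.uniform(20, 87, 200)
    y = -(ages - 40.0) ** 2 + 500.0
    for method in ("gcv", "reml"):
        fit = fit_pspline(_frame(ages, y), "y", lam="auto", method=method)
        grid, vals = fit.fitted_grid
        assert np.max(np.abs(vals - (-(grid - 40.0) ** 2 + 500.0))) < 1e-3


def test_constant_outcome_fits_constant():
    """A constant outcome reproduces itself; flexibility collapses to the
    penalty nullspace dimension (2 for a second-order penalty, 1 for first)."""
    ages = np.linspace(20, 87, 120)
    y = np.full_like(ages, 7.5)
    fit = fit_pspline(_frame(ages, y), "y", lam="auto")
    _, vals = fit.fitted_grid
    np.testing.assert_allclose(vals, 7.5, atol=1e-6)
    assert fit.edf <= 2.0 + 1e-6
    fit1 = fit_pspline(_frame(ages, y), "y",
                       spec=BasisSpec(penalty_order=1), lam="auto")
    assert fit1.edf == pytest.approx(1.0, abs=1e-6)


def test_noiseless_linear_data_pass_through_penalty_nullspace():
    ages = np.linspace(20, 87, 80)
    y = 2.0 - 0.3 * ages
    fit = fit_pspline(_frame(ages, y), "y", lam=1e8)
    grid, vals = fit.fitted_grid
    np.testing.assert_allclose(vals, 2.0 - 0.3 * grid, atol=1e-8)


def test_edf_is_nonincreasing_in_lambda():
    rng = np.random.default_rng(8)
    ages = rng.uniform(20, 87, 300)
    y = np.sin(ages / 8.0) + rng.normal(0, 0.2, 300)
    edfs = [fit_pspline(_frame(ages, y), "y", lam=l).edf
            for l in (1e-3, 1e-1, 10.0, 1e3, 1e6)]
    assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))


def test_outcome_shift_moves_curve_exactly():
    rng = np.random.default_rng(5)
    ages = rng.uniform(20, 87, 250)
    y = -(ages - 45.0) ** 2 / 10 + rng.normal(0, 3.0, 250)
    f0 = fit_pspline(_frame(ages, y), "y", lam=50.0)
    f1 = fit_pspline(_frame(ages, y + 123.0), "y", lam=50.0)
    np.testing.assert_allclose(f1.fitted_grid[1], f0.fitted_grid[1] + 123.0,
                               atol=1e-8)


def test_pure_noise_covariate_barely_moves_the_curve():
    cfg = GeneratorConfig(n_subjects=1000, seed=13)
    df = generate_cohort(cfg).df.copy()
    df["noise_cov"] = np.random.default_rng(0).normal(size=len(df))
    base = fit_pspline(df, "wm_volume", ["sex", "icv"])
    plus = fit_pspline(df, "wm_volume", ["sex", "icv", "noise_cov"])
    grid = base.fitted_grid[0]
    se = base.curve_se(grid)
    assert np.all(np.abs(plus.fitted_grid[1] - base.fitted_grid[1]) < 2 * se)


def test_collinear_covariates_raise(default_cohort):
    df = default_cohort.df.copy()
    df["icv_twin"] = df["icv"]
    with pytest.raises(CollinearityError, match="icv"):
        fit_pspline(df, "wm_volume", ["icv", "icv_twin"])


def test_complete_case_drops_missing_rows(default_cohort):
    fit = fit_pspline(default_cohort.df, "cattell", ["icv"])
    assert fit.n_dropped == default_cohort.df["cattell"].isna().sum()
    assert fit.n_obs == len(default_cohort.df) - fit.n_dropped


def test_cross_check_against_independent_smoother(default_cohort):
    """The penalized-spline curve should agree with a lowess smooth of the
    same lean-group data to within a few cm^3 over the well-supported range."""
    import statsmodels.api as sm

    from adipobrain.preprocess import classify_bmi

    df = default_cohort.df
    lean = df[classify_bmi(df["bmi"].to_numpy()) == "lean"]
    fit = fit_pspline(lean, "wm_volume")
    lw = sm.nonparametric.lowess(lean["wm_volume"], lean["age"], frac=0.35)
    grid = np.linspace(30, 80, 60)
    ours = fit.predict_curve(grid)
    theirs = np.interp(grid, lw[:, 0], lw[:, 1])
    assert np.max(np.abs(ours - theirs)) < 3.0 * fit.residual_sd / 2


# ---------------------------------------------------------------- inference
def test_interaction_negative_under_true_age_shift(default_cohort):
    t, p = interaction_test(default_cohort.df, "wm_volume", ["sex", "icv"])
    assert t < 0
    assert p < 0.01


def test_interaction_null_under_permuted_bmi(default_cohort):
    rng = np.random.default_rng(17)
    tvals = []
    for _ in range(5):
        df = default_cohort.df.copy()
        df["bmi"] = rng.permutation(df["bmi"].to_numpy())
        t, _ = interaction_test(df, "wm_volume", ["sex", "icv"])
        tvals.append(t)
    assert np.max(np.abs(tvals)) < 4.0


def test_group_coding_interaction_matches_direction(default_cohort):
    t, p = interaction_test(default_cohort.df, "wm_volume", ["sex", "icv"],
                            coding="group")
    assert t < 0 and p < 0.01


def test_group_effects_trait_direction():
    """A positive thickness offset for the heavier group should surface as a
    positive trait coefficient."""
    cfg = GeneratorConfig(n_subjects=2000, seed=21,
                          thickness_group_offset=0.05)
    df = generate_cohort(cfg).df
    eff = group_effects_test(df, "thickness", ["sex", "icv", "gw_contrast"])
    assert eff["trait"][0] > 0
    assert eff["trait"][1] < 0.05


# ------------------------------------------------------- group trajectories
def test_group_trajectories_shift_identity(default_cohort):
    pair = fit_group_trajectories(default_cohort.df, "wm_volume",
                                  ["sex", "icv"])
    g = pair.age_grid
    inner = (g >= g[0]) & (g + 10.0 <= g[-1])
    lean_shifted = np.interp(g[inner] + 10.0, g, pair.lean_curve)
    r = np.corrcoef(pair.ow_curve[inner], lean_shifted)[0, 1]
    assert r > 0.99


def test_group_trajectories_null_within_pooled_se(null_cohort):
    pair = fit_group_trajectories(null_cohort.df, "wm_volume", ["sex", "icv"])
    g = pair.age_grid
    se = np.sqrt(pair.fit_provenance[0].curve_se(g) ** 2 +
                 pair.fit_provenance[1].curve_se(g) ** 2)
    assert np.max(np.abs(pair.lean_curve - pair.ow_curve) / se) < 3.0


def test_group_trajectory_grid_spans_common_support(default_cohort):
    from adipobrain.preprocess import classify_bmi

    df = default_cohort.df
    labels = classify_bmi(df["bmi"].to_numpy())
    lean_ages = df.loc[labels == "lean", "age"]
    ow_ages = df.loc[np.isin(labels, ("overweight", "obese")), "age"]
    pair = fit_group_trajectories(df, "wm_volume", ["sex", "icv"])
    assert pair.age_grid[0] == pytest.approx(max(lean_ages.min(), ow_ages.min()))
    assert pair.age_grid[-1] == pytest.approx(min(lean_ages.max(), ow_ages.max()))


def test_group_trajectories_insufficient_support_raises(default_cohort):
    young = default_cohort.df[default_cohort.df["age"] < 50]
    with pytest.raises(SupportError):
        fit_group_trajectories(young, "wm_volume", ["sex", "icv"])
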