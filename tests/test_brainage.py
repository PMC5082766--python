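"""Volume matching: peak finding, curve inversion, delta rules and bootstrap."""

import numpy as np
import pytest

from adipobrain import (GeneratorConfig, TrajectoryPair, age_difference_curve,
                        bootstrap_brain_age, find_peak, fit_group_trajectories,
                        generate_cohort, invert_descending, summarize_brain_age)
from adipobrain.brainage import RULE_CLAMPED, RULE_TRUNCATED
from adipobrain.exceptions import DegenerateTrajectoryError
from adipobrain.pspline import age_grid


def _quadratic_pair(shift=10.0, step=0.1, lo=20.0, hi=87.0,
                    peak_age=43.0, peak_vol=470.0, curv=25.0 / 289.0):
    g = age_grid(lo, hi, step)
    lean = peak_vol - curv * (g - peak_age) ** 2
    ow = peak_vol - curv * (g + shift - peak_age) ** 2
    return TrajectoryPair(g, lean, ow, peak_age,
                          max(peak_age - shift, lo), fit_provenance=())


# ---------------------------------------------------------------- find_peak
def test_peak_of_quadratic():
    g = np.arange(20.0, 87.1, 0.5)
    assert find_peak(-(g - 40.0) ** 2, g) == 40.0


def test_peak_of_decreasing_curve_is_grid_minimum():
    g = np.arange(20.0, 87.1, 0.5)
    assert find_peak(500.0 - g, g) == 20.0


def test_peak_tie_breaks_to_youngest():
    g = np.arange(20.0, 60.0, 1.0)
    curve = np.zeros_like(g)
    curve[g == 38.0] = 5.0
    curve[g == 42.0] = 5.0
    assert find_peak(curve, g) == 38.0


def test_flat_curve_has_no_peak():
    g = np.arange(20.0, 30.0, 1.0)
    with pytest.raises(DegenerateTrajectoryError):
        find_peak(np.ones_like(g), g)


# ---------------------------------------------------------- invert_descending
def test_linear_inversion():
    g = np.arange(20.0, 87.1, 0.5)
    curve = 100.0 - g
    assert invert_descending(curve, g, peak_age=20.0, volume=40.0) == \
        pytest.approx(60.0)


def test_inversion_at_peak_volume_returns_peak_age():
    g = age_grid(20.0, 87.0, 0.1)
    curve = 470.0 - 0.0865 * (g - 43.0) ** 2
    assert invert_descending(curve, g, 43.0, 470.0 - 0.0865 * 0.0) == \
        pytest.approx(43.0)


def test_inversion_out_of_range_volume_not_found():
    g = age_grid(20.0, 87.0, 0.1)
    curve = 470.0 - 0.0865 * (g - 43.0) ** 2
    assert invert_descending(curve, g, 43.0, 100.0) is None
    assert invert_descending(curve, g, 43.0, 600.0) is None


def test_inversion_warns_on_reincreasing_limb():
    g = np.arange(0.0, 11.0, 1.0)
    curve = np.array([10., 9., 8., 7., 6., 6.5, 5., 4., 3., 2., 1.])
    with pytest.warns(RuntimeWarning):
        a = invert_descending(curve, g, 0.0, 6.75)
    assert a == pytest.approx(3.25)


# ------------------------------------------------------- age_difference_curve
def test_identical_curves_give_zero_delta():
    pair = _quadratic_pair(shift=0.0)
    cv = age_difference_curve(pair)
    assert np.nanmax(np.abs(cv.delta)) < 1e-9


def test_shifted_quadratics_recover_shift_everywhere():
    pair = _quadratic_pair(shift=7.0)
    cv = age_difference_curve(pair)
    usable = cv.valid & np.array([RULE_TRUNCATED not in f
                                  for f in cv.rule_flags])
    np.testing.assert_allclose(cv.delta[usable], 7.0, atol=0.1)


def test_negative_deltas_clamped_only_when_enabled():
    # overweight curve above lean: matched lean ages are younger
    g = age_grid(20.0, 87.0, 0.1)
    lean = 470.0 - 0.0865 * (g - 43.0) ** 2
    ow = lean + 20.0
    pair = TrajectoryPair(g, lean, ow, 43.0, 43.0, fit_provenance=())
    clamped = age_difference_curve(pair, clamp_negative=True)
    raw = age_difference_curve(pair, clamp_negative=False)
    ok = clamped.valid
    assert np.nanmin(clamped.delta[ok]) >= 0.0
    assert np.nanmin(raw.delta[raw.valid]) < 0.0
    assert any(RULE_CLAMPED in f for f in clamped.rule_flags)


def test_truncated_support_flag_at_old_ages():
    pair = _quadratic_pair(shift=10.0)
    cv = age_difference_curve(pair)
    old = cv.eval_ages > 78.0
    assert all(RULE_TRUNCATED in f for f in np.array(cv.rule_flags,
                                                     dtype=object)[old])


def test_grid_refinement_changes_delta_by_less_than_prior_step():
    coarse = age_difference_curve(_quadratic_pair(step=0.2), eval_step=1.0)
    fine = age_difference_curve(_quadratic_pair(step=0.1), eval_step=1.0)
    both = coarse.valid & fine.valid
    assert np.max(np.abs(coarse.delta[both] - fine.delta[both])) < 0.2


# ---------------------------------------------------------------- bootstrap
@pytest.fixture(scope="module")
def boot_curve():
    cohort = generate_cohort(GeneratorConfig(seed=31))
    return bootstrap_brain_age(cohort, covariates=["sex", "icv"],
                               n_iter=200, seed=7)


def test_bootstrap_ci_nesting(boot_curve):
    ok = np.isfinite(boot_curve.ci90[0]) & np.isfinite(boot_curve.ci95[0])
    assert ok.any()
    assert np.all(boot_curve.ci95[0][ok] <= boot_curve.ci90[0][ok] + 1e-9)
    assert np.all(boot_curve.ci90[1][ok] <= boot_curve.ci95[1][ok] + 1e-9)


def test_bootstrap_is_deterministic_given_seed(boot_curve):
    cohort = generate_cohort(GeneratorConfig(seed=31))
    again = bootstrap_brain_age(cohort, covariates=["sex", "icv"],
                                n_iter=200, seed=7)
    np.testing.assert_array_equal(boot_curve.delta, again.delta)
    np.testing.assert_array_equal(boot_curve.ci95[0], again.ci95[0])
    np.testing.assert_array_equal(boot_curve.ci90[1], again.ci90[1])


def test_bootstrap_pooled_resampling_also_runs():
    cohort = generate_cohort(GeneratorConfig(seed=31, n_subjects=300))
    cv = bootstrap_brain_age(cohort, covariates=["sex", "icv"], n_iter=50,
                             seed=1, resample="pooled")
    assert np.isfinite(cv.delta[cv.valid]).all()


def test_uniform_duplication_invariance():
    """Duplicating every subject k times leaves the trajectory fits (and hence
    the point estimate) unchanged once the penalty is scaled by k, since the
    penalized objective is multiplied through by k."""
    cohort = generate_cohort(GeneratorConfig(seed=33, n_subjects=250))
    df = cohort.df
    lam = (120.0, 80.0)
    pair1 = fit_group_trajectories(df, "wm_volume", ["sex", "icv"], lams=lam)
    dup = df.loc[df.index.repeat(3)].reset_index(drop=True)
    pair2 = fit_group_trajectories(dup, "wm_volume", ["sex", "icv"],
                                   lams=(3 * lam[0], 3 * lam[1]))
    np.testing.assert_allclose(pair1.lean_curve, pair2.lean_curve, atol=1e-3)
    np.testing.assert_allclose(pair1.ow_curve, pair2.ow_curve, atol=1e-3)
    cv1 = age_difference_curve(pair1)
    cv2 = age_difference_curve(pair2)
    np.testing.assert_allclose(cv1.delta, cv2.delta, atol=1e-3, equal_nan=True)


def test_curve_serialization_roundtrip(tmp_path, boot_curve):
    path = boot_curve.to_csv(tmp_path / "curve.csv")
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["age", "delta", "ci90_lo", "ci90_hi",
                                "ci95_lo", "ci95_hi", "flags"]
    assert len(df) == len(boot_curve.eval_ages)
    meta = boot_curve.meta_json(tmp_path / "meta.json")
    assert "n_bootstrap" in meta


# ---------------------------------------------------------------- summaries
def test_summary_constant_curve():
    from adipobrain import BrainAgeCurve
    ages = np.arange(50.0, 71.0, 1.0)
    cv = BrainAgeCurve(eval_ages=ages, delta=np.full_like(ages, 7.0),
                       rule_flags=[frozenset()] * len(ages))
    mean_d, max_d, age_max = summarize_brain_age(cv)
    assert (mean_d, max_d, age_max) == (7.0, 7.0, 50.0)


def test_summary_of_shifted_quadratics_matches_shift():
    cv = age_difference_curve(_quadratic_pair(shift=7.0),
                              eval_range=(50.0, 70.0))
    mean_d, max_d, _ = summarize_brain_age(cv)
    assert mean_d == pytest.approx(7.0, abs=0.1)
    assert max_d == pytest.approx(7.0, abs=0.1)


def test_summary_singleton():
    from adipobrain import BrainAgeCurve
    cv = BrainAgeCurve(eval_ages=np.array([55.0]), delta=np.array([4.2]),
                       rule_flags=[frozenset()])
    assert summarize_brain_age(cv) == (4.2, 4.2, 55.0)
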