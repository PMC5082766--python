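"""Seeded synthetic cross-sectional cohorts with adiposity-dependent brain aging.

The generator emulates the statistical structure the downstream analysis
assumes in a healthy adult lifespan cohort: ages uniform over 20-87 years,
BMI positively correlated with age, an inverted-U cerebral white-matter-volume
trajectory whose overweight/obese branch equals the lean branch evaluated at
an older age (a pure horizontal "brain-age" shift), near-linear declines of
cortical surface area and thickness, a nonlinear fluid-intelligence decline,
and image-quality ratings that worsen with age.

All randomness flows from one root seed through named per-component
substreams, so adding a column never perturbs existing columns and identical
(config, seed) pairs are byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import FLAG_COLUMNS, Cohort
from .exceptions import ConfigurationError, DomainError
from .preprocess import classify_bmi

# Per-group Bernoulli prevalences (lean, overweight, obese) of the binary
# health and sociodemographic covariates in a community aging cohort.
DEFAULT_PREVALENCES = {
    "high_bp":      (0.077, 0.200, 0.377),
    "diabetes":     (0.012, 0.040, 0.117),
    "cancer":       (0.045, 0.040, 0.117),
    "mi":           (0.004, 0.020, 0.013),
    "stroke":       (0.016, 0.000, 0.013),
    "high_chol":    (0.085, 0.113, 0.221),
    "degree":       (0.732, 0.593, 0.429),
    "income_above": (0.606, 0.560, 0.494),
    "smoker":       (0.160, 0.110, 0.060),
}

# Substream indices: each generated component owns a fixed slot so that the
# stream for one column never depends on whether another column is drawn.
_STREAMS = {"age": 0, "sex": 1, "bmi": 2, "icv": 3, "wm": 4, "area": 5,
            "thickness": 6, "gw": 7, "cattell": 8, "qc": 9, "flags": 10,
            "activity": 11, "missing": 12}

_GROUPS = ("lean", "overweight", "obese")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic data-generating model.

    The white-matter trajectory for lean subjects is a concave quadratic
    peaking at ``wm_peak_age_lean``; overweight/obese subjects follow the lean
    trajectory evaluated at ``age + true_age_shift``, so on the descending
    limb the true volume-matched brain-age difference is exactly the shift.
    """

    n_subjects: int = 473
    seed: int = 0
    age_range: tuple = (20.0, 87.0)
    #: marginal (lean, overweight, obese) proportions among BMI >= 18.5
    group_probs: tuple = (0.51, 0.31, 0.18)
    bmi_age_slope: float = 0.11           # kg m^-2 per year
    wm_peak_age_lean: float = 43.0        # years
    wm_peak_volume: float = 470.0         # cm^3
    wm_curvature: float = 25.0 / 289.0    # cm^3 per year^2
    true_age_shift: float = 10.0          # years
    wm_noise_sd: float = 15.0             # cm^3
    trajectory_family: str = "quadratic"  # or "asymmetric"
    rising_curvature_ratio: float = 1.0   # pre-peak curvature multiplier
    thickness_intercept: float = 2.55     # mm at the mid-range age
    thickness_slope: float = -0.004       # mm per year
    thickness_group_offset: float = 0.02  # mm, overweight/obese minus lean
    thickness_gw_coeff: float = 0.01      # mm per % gray-white contrast
    thickness_noise_sd: float = 0.07      # mm
    area_intercept: float = 1900.0        # cm^2 at the mid-range age
    area_slope: float = -2.8              # cm^2 per year
    area_noise_sd: float = 80.0           # cm^2
    cattell_params: tuple = (35.0, 0.05, 0.0025)  # level, rate, nonlinearity
    cattell_icv_coeff: float = 0.8        # points per 100 cm^3 of ICV
    cattell_noise_sd: float = 3.5
    cattell_missing_rate: float = 0.02
    icv_mean_female: float = 1400.0       # cm^3
    icv_mean_male: float = 1550.0         # cm^3
    icv_sd: float = 110.0                 # cm^3
    gw_contrast_mean: float = 20.0        # percent
    gw_contrast_slope: float = -0.03      # percent per year
    gw_contrast_noise_sd: float = 1.5
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    activity_mean: tuple = (47.0, 47.0, 43.0)  # kJ/d/kg per group
    activity_sd: tuple = (20.0, 22.0, 23.0)
    qc_poor_rate: float = 0.07
    qc_adequate_rate: float = 0.12
    qc_age_coefficient: float = 0.04      # log-odds of poor per year
    include_underweight: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range low must be < high")
        if not (lo <= self.wm_peak_age_lean <= hi):
            raise ConfigurationError("wm_peak_age_lean must lie inside age_range")
        if abs(sum(self.group_probs) - 1.0) > 1e-12:
            raise ConfigurationError("group_probs must sum to 1 within 1e-12")
        if any(p < 0 for p in self.group_probs):
            raise ConfigurationError("group_probs must be non-negative")
        for name in ("wm_noise_sd", "thickness_noise_sd", "area_noise_sd",
                     "cattell_noise_sd", "icv_sd", "gw_contrast_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.wm_curvature < 0:
            raise ConfigurationError("wm_curvature must be >= 0")
        if self.trajectory_family not in ("quadratic", "asymmetric"):
            raise ConfigurationError(
                "trajectory_family must be 'quadratic' or 'asymmetric'")
        for name in ("qc_poor_rate", "qc_adequate_rate", "cattell_missing_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        for flag, probs in self.covariate_prevalences.items():
            if len(probs) != 3 or any(not 0 <= p <= 1 for p in probs):
                raise ConfigurationError(
                    f"covariate_prevalences[{flag!r}] must be 3 probabilities")


def _rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component substream of the root seed."""
    key = _STREAMS[component]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


def _bmi_marginal(group_probs: tuple) -> tuple[float, float]:
    """Mean and total SD of the latent normal BMI distribution whose
    truncation at 18.5 reproduces the requested group proportions."""
    p_lean, _, p_ob = group_probs

    def eqs(x):
        mu, sig = x[0], abs(x[1])
        a, b, c = (np.array([18.5, 25.0, 30.0]) - mu) / max(sig, 1e-6)
        fa, fb, fc = stats.norm.cdf([a, b, c])
        z = max(1.0 - fa, 1e-12)
        return [(fb - fa) / z - p_lean, (1.0 - fc) / z - p_ob]

    sol, info, ier, msg = optimize.fsolve(eqs, x0=[24.0, 6.0], full_output=True)
    if ier != 1:
        raise ConfigurationError(f"group_probs not achievable by a truncated "
                                 f"normal BMI model: {msg}")
    return float(sol[0]), float(abs(sol[1]))


def _lean_trajectory(config: GeneratorConfig, age):
    """Noiseless lean white-matter trajectory, defined for any real age."""
    age = np.asarray(age, dtype=float)
    d = age - config.wm_peak_age_lean
    c_post = config.wm_curvature
    if config.trajectory_family == "asymmetric":
        c_pre = c_post * config.rising_curvature_ratio
        curv = np.where(d < 0, c_pre, c_post)
    else:
        curv = c_post
    return config.wm_peak_volume - curv * d ** 2


def trajectory_true(config: GeneratorConfig, group: str, age):
    """The noiseless generating white-matter trajectory, cm^3.

    For the overweight/obese group this is the lean trajectory evaluated at
    ``age + true_age_shift``. ``age`` must lie inside ``config.age_range``.
    """
    config.validate()
    arr = np.asarray(age, dtype=float)
    lo, hi = config.age_range
    if np.any(arr < lo) or np.any(arr > hi):
        raise DomainError(f"age outside the configured range [{lo}, {hi}]")
    key = group.lower()
    if key == "lean":
        out = _lean_trajectory(config, arr)
    elif key in ("overweight", "obese", "overweight_obese"):
        out = _lean_trajectory(config, arr + config.true_age_shift)
    else:
        raise DomainError(f"unknown group {group!r}")
    return float(out) if out.ndim == 0 else out


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a synthetic cohort under the configured generating model."""
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_subjects
    seed = config.seed
    lo, hi = config.age_range
    mid_age = 0.5 * (lo + hi)

    ages = _rng(seed, "age").uniform(lo, hi, n)
    sex_male = _rng(seed, "sex").integers(0, 2, n)

    # BMI: latent normal with an age slope, truncated below 18.5 (unless the
    # underweight tail is explicitly kept to exercise the exclusion path).
    mu, sig_total = _bmi_marginal(config.group_probs)
    var_age = (hi - lo) ** 2 / 12.0
    resid_var = sig_total ** 2 - config.bmi_age_slope ** 2 * var_age
    if resid_var <= 0:
        raise ConfigurationError(
            "bmi_age_slope too steep for the BMI spread implied by group_probs")
    rng_bmi = _rng(seed, "bmi")
    bmi = mu + config.bmi_age_slope * (ages - mid_age) + \
        rng_bmi.normal(0.0, np.sqrt(resid_var), n)
    # resample draws below the floor (18.5 by default; with the underweight
    # tail enabled, a physiological floor keeps BMI strictly positive)
    floor = 10.0 if config.include_underweight else 18.5
    for _ in range(200):
        mask = bmi < floor
        if not mask.any():
            break
        bmi[mask] = (mu + config.bmi_age_slope * (ages[mask] - mid_age)
                     + rng_bmi.normal(0.0, np.sqrt(resid_var), mask.sum()))

    group = classify_bmi(np.clip(bmi, 1e-6, None))
    heavy = np.isin(group, ("overweight", "obese"))

    # ICV per sex; the outcome scales with head size so the downstream
    # covariate adjustment has real work to do.
    icv_means = np.where(sex_male == 1, config.icv_mean_male,
                         config.icv_mean_female)
    icv = icv_means + _rng(seed, "icv").normal(0.0, config.icv_sd, n)
    icv = np.clip(icv, 900.0, None)
    icv_ref = 0.5 * (config.icv_mean_female + config.icv_mean_male)

    eff_age = ages + config.true_age_shift * heavy
    wm = _lean_trajectory(config, eff_age) * (icv / icv_ref) + \
        _rng(seed, "wm").normal(0.0, config.wm_noise_sd, n)
    wm = np.clip(wm, 1.0, None)

    area = (config.area_intercept + config.area_slope * (ages - mid_age)) * \
        (icv / icv_ref) + _rng(seed, "area").normal(0.0, config.area_noise_sd, n)
    area = np.clip(area, 1.0, None)

    gw = config.gw_contrast_mean + config.gw_contrast_slope * (ages - mid_age) \
        + _rng(seed, "gw").normal(0.0, config.gw_contrast_noise_sd, n)

    thickness = (config.thickness_intercept
                 + config.thickness_slope * (ages - mid_age)
                 + config.thickness_group_offset * heavy
                 + config.thickness_gw_coeff * (gw - config.gw_contrast_mean)
                 + _rng(seed, "thickness").normal(0.0, config.thickness_noise_sd, n))
    thickness = np.clip(thickness, 0.5, None)

    level, rate, nonlin = config.cattell_params
    cattell = (level - rate * (ages - lo) - nonlin * (ages - lo) ** 2
               + config.cattell_icv_coeff * (icv - icv_ref) / 100.0
               + _rng(seed, "cattell").normal(0.0, config.cattell_noise_sd, n))
    if config.cattell_missing_rate > 0:
        miss = _rng(seed, "missing").uniform(size=n) < config.cattell_missing_rate
        cattell = np.where(miss, np.nan, cattell)

    # QC: probability of a poor reconstruction rises with age on the
    # log-odds scale; adequate is assigned among the remainder.
    rng_qc = _rng(seed, "qc")
    logit_poor = special.logit(max(config.qc_poor_rate, 1e-12)) + \
        config.qc_age_coefficient * (ages - mid_age)
    p_poor = special.expit(logit_poor) if config.qc_poor_rate > 0 else np.zeros(n)
    u_poor = rng_qc.uniform(size=n)
    u_adeq = rng_qc.uniform(size=n)
    p_adeq = config.qc_adequate_rate / max(1.0 - config.qc_poor_rate, 1e-12)
    qc = np.where(u_poor < p_poor, "poor",
                  np.where(u_adeq < p_adeq, "adequate", "good")).astype(object)

    group_idx = np.select([group == "overweight", group == "obese"], [1, 2], 0)
    rng_flags = _rng(seed, "flags")
    flags = {}
    for name in FLAG_COLUMNS:
        probs = np.asarray(config.covariate_prevalences[name])[group_idx]
        flags[name] = (rng_flags.uniform(size=n) < probs).astype(int)

    act_mean = np.asarray(config.activity_mean)[group_idx]
    act_sd = np.asarray(config.activity_sd)[group_idx]
    activity = np.clip(act_mean + _rng(seed, "activity").standard_normal(n)
                       * act_sd, 0.0, None)

    df = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": ages,
        "sex": np.where(sex_male == 1, "male", "female"),
        "bmi": bmi,
        "icv": icv,
        "wm_volume": wm,
        "surface_area": area,
        "thickness": thickness,
        "gw_contrast": gw,
        "cattell": cattell,
        "qc": qc,
        **flags,
        "activity": activity,
    })
    return Cohort(df=df, provenance={"generator": asdict(config), "seed": seed})
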