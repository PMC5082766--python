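"""Volume-matched brain-age difference with constrained bootstrap bands.

The estimand: for each overweight/obese reference age ``a`` on the descending
limb of the group's white-matter trajectory, find the age at which the lean
trajectory attains the same volume, and report the difference

    delta(a) = age_lean(volume_ow(a)) - a

so that positive delta means the heavier group's white matter looks like that
of an older lean brain. Because the trajectory is an inverted U, three
constraint rules keep the comparison between equally mature subjects:

1. ``descending_only`` -- inversion of the lean curve is restricted to ages
   at or above its peak (never match against the maturational upstroke);
2. ``clamped_zero``    -- if the heavier group's volume exceeds the lean
   volume at the same maturity (negative delta), the difference is set to 0;
3. ``truncated_support`` -- if no lean age is old enough to reach so low a
   volume, the lean age is truncated at the oldest age on the grid.

Confidence bands are elementwise percentile intervals over bootstrap refits
of both group trajectories, resampling subjects with replacement within each
weight group; the three rules are applied inside every iteration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .exceptions import (DegenerateTrajectoryError, InputError, SummaryError,
                         SupportError)
from .pspline import BasisSpec, TrajectoryPair, age_grid, fit_group_trajectories

RULE_DESCENDING = "descending_only"
RULE_CLAMPED = "clamped_zero"
RULE_TRUNCATED = "truncated_support"


def find_peak(curve, age_grid) -> float:
    """Age of the global maximum of a trajectory; ties break to the youngest."""
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(age_grid, dtype=float)
    if curve.shape != grid.shape or grid.size < 3:
        raise InputError("curve and grid must match and have length >= 3")
    if np.any(np.diff(grid) <= 0):
        raise InputError("age grid must be sorted ascending")
    if np.ptp(curve) == 0.0:
        raise DegenerateTrajectoryError("flat trajectory has no peak")
    return float(grid[int(np.argmax(curve))])


def invert_descending(curve, age_grid, peak_age: float, volume: float,
                      monotone_tol: float = 1e-8):
    """Age at which the descending limb of ``curve`` crosses ``volume``.

    The search is restricted to ages at or above ``peak_age`` (rule 1); the
    crossing is located by bracketing adjacent grid points and linear
    interpolation. Returns ``None`` (not found) when the volume lies above
    the curve's value at the peak or below the descending limb's minimum.
    A locally re-increasing limb triggers a warning and the first crossing
    from the peak is used.
    """
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(age_grid, dtype=float)
    if not np.isfinite(volume):
        raise InputError("volume must be finite")
    i0 = int(np.argmin(np.abs(grid - peak_age)))
    if abs(grid[i0] - peak_age) > np.max(np.diff(grid)):
        raise InputError("peak_age does not lie on the grid")
    desc = curve[i0:]
    gd = grid[i0:]
    scale = max(np.ptp(curve), 1.0)
    if np.any(np.diff(desc) > monotone_tol * scale):
        warnings.warn("descending limb re-increases; using the first crossing "
                      "from the peak", RuntimeWarning, stacklevel=2)
    tol = 1e-12 * scale
    if volume > desc[0] + tol or volume < np.min(desc) - tol:
        return None
    env = np.minimum.accumulate(desc)     # first-crossing envelope
    k = int(np.searchsorted(-env, -volume))
    if k == 0:
        return float(gd[0])
    k = min(k, len(gd) - 1)
    v0, v1 = env[k - 1], env[k]
    frac = 0.0 if v0 == v1 else (v0 - volume) / (v0 - v1)
    return float(gd[k - 1] + frac * (gd[k] - gd[k - 1]))


@dataclass
class BrainAgeCurve:
    """Per-age brain-age-difference estimates with bootstrap CI bands."""

    eval_ages: np.ndarray
    delta: np.ndarray
    rule_flags: list                       # per-age frozenset of applied rules
    ci90: tuple = None                     # (low, high) arrays or None
    ci95: tuple = None
    n_bootstrap: int = 0
    valid_fraction: np.ndarray = None      # share of bootstrap iters valid per age
    provenance: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.delta)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.eval_ages)
        nan = np.full(n, np.nan)
        ci90 = self.ci90 or (nan, nan)
        ci95 = self.ci95 or (nan, nan)
        return pd.DataFrame({
            "age": self.eval_ages,
            "delta": self.delta,
            "ci90_lo": ci90[0], "ci90_hi": ci90[1],
            "ci95_lo": ci95[0], "ci95_hi": ci95[1],
            "flags": ["|".join(sorted(f)) for f in self.rule_flags],
        })

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6f",
                               lineterminator="\n")
        return path

    def meta_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_bootstrap": self.n_bootstrap,
            "eval_range": [float(self.eval_ages[0]), float(self.eval_ages[-1])],
            "n_eval_ages": int(len(self.eval_ages)),
            **{k: v for k, v in self.provenance.items()},
        }, indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _delta_core(lean_curve, ow_curve, grid, eval_ages, clamp_negative=True):
    """Vectorized delta with the three constraint rules.

    Returns (delta, a_lean, masks) where masks hold per-age booleans for the
    applied rules; pre-peak (invalid) eval ages carry NaN deltas.
    """
    pi = int(np.argmax(lean_curve))
    po = int(np.argmax(ow_curve))
    v = np.interp(eval_ages, grid, ow_curve)
    gd = grid[pi:]
    env = np.minimum.accumulate(lean_curve[pi:])
    # np.interp on the reversed (ascending) envelope: values above the lean
    # peak volume pin to the peak age (rule 1), values below the terminal
    # volume pin to the oldest grid age (rule 3).
    a_lean = np.interp(v, env[::-1], gd[::-1])
    above = v > env[0]
    below = v < env[-1]
    pre_peak = eval_ages < grid[po] - 1e-9
    delta = a_lean - eval_ages
    negative = (delta < 0) & ~pre_peak
    if clamp_negative:
        delta = np.where(negative, 0.0, delta)
    delta = np.where(pre_peak, np.nan, delta)
    masks = {
        RULE_DESCENDING: (above | pre_peak),
        RULE_CLAMPED: negative & clamp_negative,
        RULE_TRUNCATED: below & ~pre_peak,
    }
    return delta, a_lean, masks


def _masks_to_flags(masks, n):
    flags = []
    for i in range(n):
        flags.append(frozenset(name for name, m in masks.items() if m[i]))
    return flags


def age_difference_curve(pair: TrajectoryPair, eval_range=(37.0, 87.0),
                         eval_step: float = 1.0,
                         clamp_negative: bool = True) -> BrainAgeCurve:
    """Point estimates of the volume-matched brain-age difference.

    For each overweight/obese reference age in ``eval_range`` (descending
    limb only) the matched lean age is found by inverting the lean curve and
    the constraint rules are applied; see the module docstring.
    """
    grid = np.asarray(pair.age_grid, dtype=float)
    lo = max(float(eval_range[0]), grid[0])
    hi = min(float(eval_range[1]), grid[-1])
    if lo > hi:
        raise SupportError("evaluation range lies outside the trajectory grid")
    eval_ages = age_grid(lo, hi, eval_step)
    delta, _, masks = _delta_core(pair.lean_curve, pair.ow_curve, grid,
                                  eval_ages, clamp_negative)
    return BrainAgeCurve(
        eval_ages=eval_ages,
        delta=delta,
        rule_flags=_masks_to_flags(masks, len(eval_ages)),
        provenance={"eval_step": eval_step, "clamp_negative": clamp_negative,
                    "lean_peak_age": pair.lean_peak_age,
                    "ow_peak_age": pair.ow_peak_age},
    )


def bootstrap_brain_age(cohort, outcome: str = "wm_volume", covariates=(),
                        spec: BasisSpec | None = None,
                        eval_range=(37.0, 87.0), eval_step: float = 1.0,
                        n_iter: int = 10000, levels=(0.90, 0.95),
                        seed: int = 0, resample: str = "within_group",
                        clamp_negative: bool = True, grid_step: float = 0.1,
                        method: str = "gcv", min_valid_fraction: float = 0.5,
                        chunk: int = 512) -> BrainAgeCurve:
    """Brain-age-difference curve with percentile bootstrap CI bands.

    Subjects are resampled with replacement within each weight group
    (``resample="pooled"`` resamples across the whole cohort instead), both
    group trajectories are refitted per iteration at the smoothing parameters
    selected on the full sample, and the constrained delta curve is recomputed
    inside every iteration. The point estimate is the full-sample curve.
    Evaluation ages where fewer than ``min_valid_fraction`` of iterations
    produced a value are reported with the CI marked unavailable (NaN).
    """
    pair = fit_group_trajectories(cohort, outcome, covariates, spec=spec,
                                  grid_step=grid_step, method=method)
    point = age_difference_curve(pair, eval_range, eval_step, clamp_negative)
    eval_ages = point.eval_ages
    grid = pair.age_grid

    # Per-group pieces for fast weighted refits. Fitting with raw covariates
    # is equivalent to the centered fit because the constant vector lies in
    # both the spline span and the penalty nullspace; the curve is then taken
    # at the pooled covariate reference by adding mean^T beta.
    groups = []
    for fit in pair.fit_provenance:
        d = fit._design
        ns = d["ns"]
        means = fit.covariate_means.to_numpy() if len(fit.covariate_means) else np.empty(0)
        X_raw = d["X"] + means  # undo centering
        Z = np.hstack([d["B"], X_raw]) if X_raw.size else d["B"]
        A_pen = fit.lam * d["K"]
        # tiny ridge on the unpenalized block guards against covariates that
        # become constant within a resample (rare flags)
        ridge = 1e-8 * np.trace(Z.T @ Z) / max(Z.shape[1], 1)
        np.fill_diagonal(A_pen[ns:, ns:], A_pen[ns:, ns:].diagonal() + ridge)
        G = BSpline.design_matrix(grid, fit._knots, fit.basis.degree,
                                  extrapolate=False).toarray()
        groups.append({"Z": Z, "y": d["y"], "pen": A_pen, "ns": ns,
                       "means": means, "G": G, "n": Z.shape[0]})

    rng = np.random.default_rng(seed)
    n_eval = len(eval_ages)
    deltas = np.full((n_iter, n_eval), np.nan)

    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        if resample == "pooled":
            n_all = sum(g["n"] for g in groups)
            w_all = rng.multinomial(n_all, np.full(n_all, 1.0 / n_all), size=m)
            splits = np.cumsum([g["n"] for g in groups])[:-1]
            w_groups = np.split(w_all, splits, axis=1)
        elif resample == "within_group":
            w_groups = [rng.multinomial(g["n"], np.full(g["n"], 1.0 / g["n"]),
                                        size=m).astype(float) for g in groups]
        else:
            raise InputError("resample must be 'within_group' or 'pooled'")

        curves = []
        for g, w in zip(groups, w_groups):
            w = np.asarray(w, dtype=float)
            Z, y = g["Z"], g["y"]
            Aw = np.einsum("tn,ni,nj->tij", w, Z, Z, optimize=True) + g["pen"]
            bw = np.einsum("ni,tn->ti", Z, w * y)
            try:
                coef = np.linalg.solve(Aw, bw[..., None])[..., 0]
            except np.linalg.LinAlgError:
                coef = np.full((m, Z.shape[1]), np.nan)
            ns = g["ns"]
            curve = coef[:, :ns] @ g["G"].T
            if g["means"].size:
                curve = curve + (coef[:, ns:] @ g["means"])[:, None]
            curves.append(curve)

        for t in range(m):
            lc, oc = curves[0][t], curves[1][t]
            if not (np.all(np.isfinite(lc)) and np.all(np.isfinite(oc))):
                continue  # iteration contributes not-found everywhere
            d, _, _ = _delta_core(lc, oc, grid, eval_ages, clamp_negative)
            deltas[done + t] = d
        done += m

    valid = np.isfinite(deltas)
    valid_frac = valid.mean(axis=0)
    ci = {}
    for level in levels:
        alpha = (1.0 - level) / 2.0
        lo_band = np.full(n_eval, np.nan)
        hi_band = np.full(n_eval, np.nan)
        ok = valid_frac >= min_valid_fraction
        if ok.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lo_band[ok] = np.nanpercentile(deltas[:, ok], 100 * alpha, axis=0)
                hi_band[ok] = np.nanpercentile(deltas[:, ok], 100 * (1 - alpha),
                                               axis=0)
        ci[level] = (lo_band, hi_band)

    flags = [set(f) for f in point.rule_flags]
    for i in range(n_eval):
        if valid_frac[i] < min_valid_fraction:
            flags[i].add("ci_unavailable")

    return BrainAgeCurve(
        eval_ages=eval_ages,
        delta=point.delta,
        rule_flags=[frozenset(f) for f in flags],
        ci90=ci.get(0.90),
        ci95=ci.get(0.95),
        n_bootstrap=n_iter,
        valid_fraction=valid_frac,
        provenance={
            "seed": seed, "resample": resample, "eval_step": eval_step,
            "clamp_negative": clamp_negative, "levels": list(levels),
            "lambda_lean": pair.fit_provenance[0].lam,
            "lambda_ow": pair.fit_provenance[1].lam,
            "lean_peak_age": pair.lean_peak_age,
            "ow_peak_age": pair.ow_peak_age,
        },
    )


def summarize_brain_age(curve: BrainAgeCurve):
    """(mean delta, max delta, age at max) over valid, non-truncated ages."""
    usable = curve.valid & np.array(
        [RULE_TRUNCATED not in f for f in curve.rule_flags])
    if not usable.any():
        raise SummaryError("no valid evaluation ages to summarize")
    d = curve.delta[usable]
    a = curve.eval_ages[usable]
    i = int(np.argmax(d))
    return float(np.mean(d)), float(d[i]), float(a[i])
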