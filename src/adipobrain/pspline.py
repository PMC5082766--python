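"""Penalized-spline (P-spline) regression of an outcome on age.

The smooth of age is a cubic B-spline basis with a discrete difference
penalty on adjacent coefficients; linear covariates enter unpenalized.
The objective is

    || y - B theta - X beta ||^2 + lambda || D_d theta ||^2

where B is the spline design, X the covariate design and D_d the order-d
difference operator. The smoothing parameter is selected by generalized
cross-validation (default) or by restricted maximum likelihood under the
mixed-model representation of the penalty. Inference on linear terms uses the
model-based covariance with residual degrees of freedom n - edf; the smooth
term is tested by an F ratio of the model against the covariates-only fit.

Everything is computed through a Demmler-Reinsch orthogonalization so that
criterion profiles over lambda cost O(p) per evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

from .cohort import Cohort
from .exceptions import (CollinearityError, ConfigurationError, DomainError,
                         InputError, SupportError)
from .preprocess import classify_bmi

logger = logging.getLogger(__name__)

_SEX_CODE = {"female": 0.0, "male": 1.0}


@dataclass
class BasisSpec:
    """B-spline basis and penalty definition for the age smooth.

    ``n_knots`` counts knot sites spanning ``age_domain`` inclusive of both
    endpoints (so the default of 22 places 20 interior knots); the number of
    basis functions is ``n_knots + degree - 1``.
    """

    degree: int = 3
    n_knots: int = 22
    knot_placement: str = "equal"   # or "quantile"
    penalty_order: int = 2
    age_domain: tuple | None = None

    def validate(self) -> None:
        if self.degree < 1:
            raise ConfigurationError("degree must be >= 1")
        if self.n_knots < self.penalty_order + 1:
            raise ConfigurationError("n_knots must be >= penalty_order + 1")
        if self.n_knots < 2:
            raise ConfigurationError("n_knots must be >= 2")
        if self.knot_placement not in ("equal", "quantile"):
            raise ConfigurationError("knot_placement must be 'equal' or 'quantile'")
        if self.age_domain is not None and not self.age_domain[0] < self.age_domain[1]:
            raise ConfigurationError("age_domain low must be < high")

    def resolved(self, ages: np.ndarray) -> "BasisSpec":
        """Return a copy with ``age_domain`` filled from the data if unset."""
        if self.age_domain is not None:
            return self
        return BasisSpec(self.degree, self.n_knots, self.knot_placement,
                         self.penalty_order,
                         (float(np.min(ages)), float(np.max(ages))))

    def knot_vector(self, ages: np.ndarray | None = None) -> np.ndarray:
        """Knot sites spanning the domain, extended by ``degree`` equally
        spaced knots on each side (the classical P-spline construction, which
        keeps the difference-penalty nullspace equal to polynomials in age)."""
        self.validate()
        if self.age_domain is None:
            raise ConfigurationError("age_domain must be set (or resolved)")
        lo, hi = self.age_domain
        if self.knot_placement == "equal":
            sites = np.linspace(lo, hi, self.n_knots)
        else:
            if ages is None:
                raise ConfigurationError("quantile placement needs the ages")
            qs = np.quantile(ages, np.linspace(0, 1, self.n_knots))
            qs[0], qs[-1] = lo, hi
            sites = np.unique(qs)
        h_lo = sites[1] - sites[0]
        h_hi = sites[-1] - sites[-2]
        left = lo - h_lo * np.arange(self.degree, 0, -1)
        right = hi + h_hi * np.arange(1, self.degree + 1)
        return np.concatenate([left, sites, right])

    @property
    def n_basis(self) -> int:
        return self.n_knots + self.degree - 1


def age_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Regular grid from lo to hi inclusive, never overshooting hi."""
    g = np.arange(lo, hi - 1e-9, step)
    return np.append(g, hi)


def build_basis(spec: BasisSpec, ages) -> np.ndarray:
    """Evaluate the B-spline design matrix at the given ages.

    Rows are subjects, columns basis functions; each row sums to one
    (partition of unity). Ages outside ``age_domain`` raise; clamping is
    deliberately not performed.
    """
    spec.validate()
    ages = np.asarray(ages, dtype=float)
    if spec.age_domain is None:
        raise ConfigurationError("age_domain must be set before building a basis")
    lo, hi = spec.age_domain
    if np.any(ages < lo) or np.any(ages > hi):
        raise DomainError(f"ages outside the basis domain [{lo}, {hi}]")
    t = spec.knot_vector(ages)
    return BSpline.design_matrix(ages, t, spec.degree,
                                 extrapolate=False).toarray()


def difference_matrix(n: int, order: int) -> np.ndarray:
    """Order-``order`` forward-difference operator on coefficient vectors."""
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d


class _PenalizedSystem:
    """Demmler-Reinsch machinery for one penalized least-squares problem."""

    def __init__(self, Z: np.ndarray, y: np.ndarray, K: np.ndarray,
                 column_names: list[str]):
        self.n, self.p = Z.shape
        self.names = column_names
        C = Z.T @ Z
        # Sparse age coverage can leave basis columns numerically empty; a
        # tiny ridge keeps the Demmler-Reinsch factorization defined without
        # materially changing the penalized solution. Genuine covariate
        # collinearity is detected by the caller before we get here.
        scale = float(np.mean(np.diag(C))) or 1.0
        L = None
        for ridge in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = linalg.cholesky(C + ridge * scale * np.eye(self.p),
                                    lower=True)
                break
            except linalg.LinAlgError:
                continue
        if L is None:
            raise CollinearityError(
                f"rank-deficient design; columns: {column_names}")
        Linv_K = linalg.solve_triangular(L, K, lower=True)
        Kt = linalg.solve_triangular(L, Linv_K.T, lower=True).T
        s, U = linalg.eigh(0.5 * (Kt + Kt.T))
        s = np.clip(s, 0.0, None)
        s[s < 1e-12 * max(s.max(), 1.0)] = 0.0
        self.L, self.U, self.s = L, U, s
        self.Zty = Z.T @ y
        self.b = U.T @ linalg.solve_triangular(L, self.Zty, lower=True)
        self.yty = float(y @ y)
        self.null_dim = int(np.sum(s == 0.0))

    def shrink(self, lam: float) -> np.ndarray:
        return 1.0 / (1.0 + lam * self.s)

    def edf(self, lam: float) -> float:
        return float(np.sum(self.shrink(lam)))

    def rss(self, lam: float) -> float:
        g = self.shrink(lam)
        b2 = self.b ** 2
        return max(self.yty - 2 * np.sum(b2 * g) + np.sum(b2 * g ** 2), 0.0)

    def coefficients(self, lam: float) -> np.ndarray:
        g = self.shrink(lam)
        return linalg.solve_triangular(self.L, self.U @ (g * self.b),
                                       lower=True, trans="T")

    def covariance(self, lam: float, sigma2: float) -> np.ndarray:
        """Frequentist covariance sigma^2 A^-1 C A^-1 of the coefficients."""
        g = self.shrink(lam)
        M = linalg.solve_triangular(self.L, self.U * g, lower=True, trans="T")
        return sigma2 * (M @ M.T)

    def gcv(self, lam: float) -> float:
        edf = self.edf(lam)
        denom = max(self.n - edf, 1e-8)
        return self.n * self.rss(lam) / denom ** 2

    def reml(self, lam: float) -> float:
        """-2 x restricted log-likelihood, up to an additive constant."""
        g = self.shrink(lam)
        b2 = self.b ** 2
        pen_rss = self.rss(0.0) + float(np.sum(b2 * (1.0 - g)))
        m = self.null_dim
        sigma2 = max(pen_rss / max(self.n - m, 1), 1e-300)
        pos = self.s > 0
        logdet = float(np.sum(np.log1p(lam * self.s[pos])
                              - np.log(lam * self.s[pos])))
        return (self.n - m) * (np.log(sigma2) + 1.0) + logdet

    def select_lambda(self, method: str = "gcv") -> float:
        crit = self.gcv if method == "gcv" else self.reml
        # Grid descending so exact ties break toward the smoother fit.
        grid = np.logspace(10, -6, 65)
        vals = np.array([crit(l) for l in grid])
        i = int(np.argmin(vals))
        lo = np.log(grid[min(i + 1, len(grid) - 1)])
        hi = np.log(grid[max(i - 1, 0)])
        if lo >= hi:
            return float(grid[i])
        res = optimize.minimize_scalar(lambda u: crit(np.exp(u)),
                                       bounds=(lo, hi), method="bounded")
        lam_ref = float(np.exp(res.x))
        return lam_ref if crit(lam_ref) <= vals[i] else float(grid[i])


@dataclass
class PsplineFit:
    """A fitted penalized-spline model of one outcome versus age."""

    basis: BasisSpec
    spline_coefficients: np.ndarray
    covariate_coefficients: pd.Series
    lam: float
    edf: float
    residual_sd: float
    fitted_grid: tuple                      # (age grid, fitted values)
    smooth_f: tuple                         # (F statistic, p value)
    term_tests: dict                        # name -> (t statistic, p value)
    n_obs: int
    n_dropped: int
    outcome: str = ""
    method: str = "gcv"
    covariate_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    _knots: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _design: dict = field(default_factory=dict, repr=False)

    def predict_curve(self, ages) -> np.ndarray:
        """Fitted outcome at the covariate reference (cohort means)."""
        G = BSpline.design_matrix(np.asarray(ages, float), self._knots,
                                  self.basis.degree, extrapolate=False).toarray()
        return G @ self.spline_coefficients

    def curve_se(self, ages) -> np.ndarray:
        """Pointwise standard error of the fitted curve."""
        G = BSpline.design_matrix(np.asarray(ages, float), self._knots,
                                  self.basis.degree, extrapolate=False).toarray()
        ns = len(self.spline_coefficients)
        V = self._cov[:ns, :ns]
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, V, G), 0.0))

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "lambda": self.lam,
            "edf": self.edf,
            "residual_sd": self.residual_sd,
            "smooth_f": {"F": self.smooth_f[0], "p": self.smooth_f[1]},
            "term_tests": {k: {"t": v[0], "p": v[1]}
                           for k, v in self.term_tests.items()},
            "covariate_coefficients": self.covariate_coefficients.to_dict(),
            "n_obs": self.n_obs,
            "n_dropped_missing": self.n_dropped,
            "method": self.method,
            "basis": {"degree": self.basis.degree, "n_knots": self.basis.n_knots,
                      "penalty_order": self.basis.penalty_order,
                      "age_domain": list(self.basis.age_domain)},
        }


def _as_frame(data) -> pd.DataFrame:
    return data.df if isinstance(data, Cohort) else data


def _encode_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col = df[name]
    if name == "sex" or col.dtype == object:
        mapped = col.map(_SEX_CODE) if name == "sex" else None
        if mapped is None or mapped.isna().any():
            raise InputError(f"cannot encode non-numeric covariate {name!r}")
        return mapped.to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def fit_pspline(data, outcome: str, covariates=(), spec: BasisSpec | None = None,
                lam="auto", method: str = "gcv", extra_columns: dict | None = None,
                center_means: pd.Series | None = None,
                grid_step: float = 0.1) -> PsplineFit:
    """Fit the penalized spline of ``outcome`` on age with linear covariates.

    Missing values are handled by complete-case analysis (the number of
    dropped rows is logged and recorded on the fit). ``extra_columns`` are
    additional unpenalized regressors already on their final scale (used for
    interaction and group-contrast tests). ``center_means`` fixes the
    centering of the named covariates (e.g. pooled means for per-group fits);
    otherwise sample means are used.
    """
    df = _as_frame(data)
    covariates = list(covariates)
    needed = ["age", outcome] + covariates
    work = df.loc[:, [c for c in dict.fromkeys(needed)]].copy()
    if extra_columns:
        for name, vals in extra_columns.items():
            work[name] = np.asarray(vals, dtype=float)
    if work["age"].isna().any():
        raise InputError("non-finite ages in the cohort")
    complete = work.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("complete-case analysis for %s: dropped %d of %d rows",
                    outcome, n_dropped, len(work))
    work = work.loc[complete]
    y = work[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputError(f"non-finite values in outcome {outcome!r}")
    ages = work["age"].to_numpy(dtype=float)

    spec = (spec or BasisSpec()).resolved(ages)
    B = build_basis(spec, ages)
    ns = B.shape[1]

    x_names = covariates + (list(extra_columns) if extra_columns else [])
    X_cols, means = [], {}
    for name in covariates:
        col = _encode_column(work, name)
        mu = float(center_means[name]) if center_means is not None else float(col.mean())
        means[name] = mu
        X_cols.append(col - mu)
    if extra_columns:
        for name in extra_columns:
            X_cols.append(work[name].to_numpy(dtype=float))
            means[name] = 0.0
    # Covariates constant in the analysis sample are unidentifiable next to
    # the spline's intercept; drop them (their effect is absorbed into the
    # curve level at the reference) rather than failing the whole fit.
    dropped_constant = []
    if X_cols:
        keep = []
        for name, col in zip(list(x_names), X_cols):
            if np.ptp(col) < 1e-12 and name in covariates:
                dropped_constant.append(name)
            else:
                keep.append((name, col))
        if dropped_constant:
            logger.warning("dropping constant covariates %s for outcome %s",
                           dropped_constant, outcome)
            x_names = [n for n, _ in keep]
            X_cols = [c for _, c in keep]
            means = {n: means[n] for n in x_names}
    X = np.column_stack(X_cols) if X_cols else np.empty((len(y), 0))
    if len(y) <= ns + X.shape[1]:
        raise SupportError(f"n={len(y)} too small for {ns + X.shape[1]} coefficients")

    if X.size:
        X1 = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            raise CollinearityError(
                f"rank-deficient covariate design; columns: {x_names}")

    Z = np.hstack([B, X])
    D = difference_matrix(ns, spec.penalty_order)
    K = np.zeros((Z.shape[1], Z.shape[1]))
    K[:ns, :ns] = D.T @ D

    system = _PenalizedSystem(Z, y, K, ["spline"] * ns + x_names)
    if isinstance(lam, str):
        if lam != "auto":
            raise ConfigurationError("lambda must be a number or 'auto'")
        lam_used = system.select_lambda(method)
    else:
        lam_used = float(lam)
        if lam_used < 0:
            raise ConfigurationError("lambda must be >= 0")

    coef = system.coefficients(lam_used)
    theta, beta = coef[:ns], coef[ns:]
    n = len(y)
    edf = system.edf(lam_used)
    rss = system.rss(lam_used)
    sigma2 = rss / max(n - edf, 1e-8)
    cov = system.covariance(lam_used, sigma2)

    # Linear-term t tests with residual df n - edf.
    df_resid = max(n - edf, 1.0)
    term_tests = {}
    for j, name in enumerate(x_names):
        se = float(np.sqrt(max(cov[ns + j, ns + j], 0.0)))
        tstat = float(beta[j] / se) if se > 0 else np.nan
        pval = float(2 * stats.t.sf(abs(tstat), df_resid)) if np.isfinite(tstat) else np.nan
        term_tests[name] = (tstat, pval)

    # Smooth-term F: model vs covariates-only (intercept + X).
    X0 = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))
    df_num = edf - X0.shape[1]
    if df_num > 0.1 and rss > 0:
        f_stat = ((rss0 - rss) / df_num) / (rss / df_resid)
        f_p = float(stats.f.sf(f_stat, df_num, df_resid))
    else:
        f_stat, f_p = np.nan, np.nan

    lo, hi = spec.age_domain
    grid = age_grid(lo, hi, grid_step)
    knots = spec.knot_vector(ages)
    G = BSpline.design_matrix(grid, knots, spec.degree, extrapolate=False).toarray()

    return PsplineFit(
        basis=spec,
        spline_coefficients=theta,
        covariate_coefficients=pd.Series(beta, index=x_names, dtype=float),
        lam=lam_used,
        edf=float(edf),
        residual_sd=float(np.sqrt(sigma2)),
        fitted_grid=(grid, G @ theta),
        smooth_f=(float(f_stat), float(f_p)),
        term_tests=term_tests,
        n_obs=n,
        n_dropped=n_dropped,
        outcome=outcome,
        method=method,
        covariate_means=pd.Series(means, dtype=float),
        _knots=knots,
        _cov=cov,
        _design={"B": B, "X": X, "y": y, "K": K, "ns": ns, "names": x_names},
    )


def test_interaction(data, outcome: str, covariates=(), spec: BasisSpec | None = None,
                     method: str = "gcv", coding: str = "continuous"):
    """Test the age-by-BMI interaction alongside the penalized age smooth.

    Age and BMI (or the overweight/obese group indicator when
    ``coding="group"``) are mean-centered; the model gains unpenalized linear
    BMI and age x BMI terms. Returns the interaction's (t statistic, two-sided
    p value) with residual degrees of freedom n - edf.
    """
    df = _as_frame(data)
    needed = ["age", "bmi", outcome] + list(covariates)
    complete = df.loc[:, list(dict.fromkeys(needed))].notna().all(axis=1)
    df = df.loc[complete]
    age_c = df["age"].to_numpy(float) - df["age"].mean()
    if coding == "continuous":
        adip = df["bmi"].to_numpy(float)
    elif coding == "group":
        adip = np.isin(classify_bmi(df["bmi"].to_numpy(float)),
                       ("overweight", "obese")).astype(float)
    else:
        raise ConfigurationError("coding must be 'continuous' or 'group'")
    adip_c = adip - adip.mean()
    inter = age_c * adip_c
    extra = {"bmi_term": adip_c, "age_x_bmi": inter - inter.mean()}
    fit = fit_pspline(df, outcome, covariates, spec=spec, lam="auto",
                      method=method, extra_columns=extra)
    return fit.term_tests["age_x_bmi"]


def test_group_effects(data, outcome: str, covariates=(), spec: BasisSpec | None = None,
                       method: str = "gcv") -> dict:
    """Trait (group offset) and trajectory (age x group) tests with the
    lean vs overweight/obese coding, from a single augmented fit."""
    df = _as_frame(data)
    needed = ["age", "bmi", outcome] + list(covariates)
    complete = df.loc[:, list(dict.fromkeys(needed))].notna().all(axis=1)
    df = df.loc[complete]
    heavy = np.isin(classify_bmi(df["bmi"].to_numpy(float)),
                    ("overweight", "obese")).astype(float)
    age_c = df["age"].to_numpy(float) - df["age"].mean()
    heavy_c = heavy - heavy.mean()
    inter = age_c * heavy_c
    fit = fit_pspline(df, outcome, covariates, spec=spec, lam="auto",
                      method=method,
                      extra_columns={"group": heavy_c,
                                     "age_x_group": inter - inter.mean()})
    return {"trait": fit.term_tests["group"],
            "interaction": fit.term_tests["age_x_group"]}


@dataclass
class TrajectoryPair:
    """Lean and overweight/obese outcome-versus-age curves on a shared grid."""

    age_grid: np.ndarray
    lean_curve: np.ndarray
    ow_curve: np.ndarray
    lean_peak_age: float
    ow_peak_age: float
    fit_provenance: tuple = ()   # (lean PsplineFit, overweight/obese PsplineFit)

    def __post_init__(self):
        if len(self.age_grid) != len(self.lean_curve) or \
           len(self.age_grid) != len(self.ow_curve):
            raise InputError("curves and grid must have equal length")
        if not (np.all(np.isfinite(self.lean_curve))
                and np.all(np.isfinite(self.ow_curve))):
            raise InputError("trajectory curves must be finite")
        g0, g1 = self.age_grid[0], self.age_grid[-1]
        for pk in (self.lean_peak_age, self.ow_peak_age):
            if not g0 - 1e-9 <= pk <= g1 + 1e-9:
                raise InputError("peak ages must lie inside the grid")


def fit_group_trajectories(data, outcome: str = "wm_volume", covariates=(),
                           spec: BasisSpec | None = None, grid_step: float = 0.1,
                           method: str = "gcv", lams=("auto", "auto"),
                           min_group_n: int = 30,
                           min_span_years: float = 40.0) -> TrajectoryPair:
    """Independent penalized-spline fits per weight group on a common grid.

    Groups are lean versus overweight-or-obese by BMI classification. Both
    groups' covariates are centered at the pooled means, so the two curves are
    evaluated at the same covariate reference, and the grid spans the common
    age support of the two groups.
    """
    df = _as_frame(data)
    labels = classify_bmi(df["bmi"].to_numpy(float))
    lean_df = df.loc[labels == "lean"]
    ow_df = df.loc[np.isin(labels, ("overweight", "obese"))]
    problems = []
    for name, gdf in (("lean", lean_df), ("overweight/obese", ow_df)):
        span = gdf["age"].max() - gdf["age"].min() if len(gdf) else 0.0
        if len(gdf) < min_group_n or span < min_span_years:
            problems.append(f"{name}: n={len(gdf)}, age span={span:.1f}y")
    if problems:
        raise SupportError("insufficient group support: " + "; ".join(problems))

    all_ages = df["age"].to_numpy(float)
    spec = (spec or BasisSpec()).resolved(all_ages)

    pooled_means = {}
    for name in covariates:
        pooled_means[name] = float(np.mean(_encode_column(df, name)))
    pooled_means = pd.Series(pooled_means, dtype=float)

    fit_lean = fit_pspline(lean_df, outcome, covariates, spec=spec,
                           lam=lams[0], method=method,
                           center_means=pooled_means if len(covariates) else None)
    fit_ow = fit_pspline(ow_df, outcome, covariates, spec=spec,
                         lam=lams[1], method=method,
                         center_means=pooled_means if len(covariates) else None)

    lo = max(lean_df["age"].min(), ow_df["age"].min())
    hi = min(lean_df["age"].max(), ow_df["age"].max())
    grid = age_grid(lo, hi, grid_step)
    lean_curve = fit_lean.predict_curve(grid)
    ow_curve = fit_ow.predict_curve(grid)
    return TrajectoryPair(
        age_grid=grid,
        lean_curve=lean_curve,
        ow_curve=ow_curve,
        lean_peak_age=float(grid[int(np.argmax(lean_curve))]),
        ow_peak_age=float(grid[int(np.argmax(ow_curve))]),
        fit_provenance=(fit_lean, fit_ow),
    )
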