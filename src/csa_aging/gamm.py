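"""Penalized-spline mixed models for longitudinal aging curves.

The model for a global CSA outcome :math:`y_{ij}` of subject *i* at visit
*j* with age :math:`a_{ij}` is

.. math::

    y_{ij} = \\beta_0 + f(a_{ij}) + \\gamma_1 \\mathrm{sex}_i
             + \\gamma_2 \\mathrm{cohort}_i + \\gamma_3 \\mathrm{edu}_i
             + b_{0i} + \\epsilon_{ij},

with :math:`f` a cubic B-spline smooth of age penalized by a second-order
difference penalty on its coefficients, :math:`b_{0i} \\sim N(0,
\\sigma_b^2)` a subject random intercept, and :math:`\\epsilon_{ij} \\sim
N(0, \\sigma_\\epsilon^2)` residual noise.  The smooth is split into an
unpenalized linear term plus wiggly components treated as i.i.d. random
effects (the standard mixed-model representation of a penalized spline);
the smoothing parameter :math:`\\lambda = \\sigma_\\epsilon^2/\\sigma_s^2`
and the variance components are estimated jointly by REML.  The reported
effective degrees of freedom (edf) of the smooth is the trace of the
smooth's slice of the influence matrix and equals 1 at the linear limit
(:math:`\\lambda \\to \\infty`).

The smooth's significance uses the standard Wald-type approximation: the
fitted smooth values are tested against zero with a rank-truncated
pseudo-inverse of their covariance at rank round(edf), referred to an F
distribution.  This is an approximation; calibration (not digit-level
agreement with any particular implementation) is the contract, and the test
suite checks it by simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "AgingModelSpec",
    "AgingCurveFit",
    "bspline_basis",
    "fit_gamm",
    "predict_curve",
    "fit_all",
    "REPORT_ROWS",
]

REPORT_ROWS = ["s(age).p", "s(age).edf", "Cohort.p", "Education.p", "Sex.p"]

_COV_LABEL = {"cohort": "Cohort.p", "education": "Education.p", "sex": "Sex.p"}


@dataclass
class AgingModelSpec:
    """Configuration of one aging-curve model."""

    metric: str | None = None
    band: str | None = None
    statistic: str = "mean"
    n_knots: int = 5  # total knots (2 boundary + interior at age quantiles)
    degree: int = 3
    covariates: tuple[str, ...] = ("sex", "cohort", "education")
    group: str = "subject_id"

    def __post_init__(self):
        if self.n_knots < 3:
            raise ValueError("need at least 3 knots")


def _knot_vector(ages: np.ndarray, n_knots: int, degree: int) -> np.ndarray:
    """Full knot vector: `n_knots` distinct knots (boundary at the observed
    range, interior at age quantiles), boundary knots repeated degree+1 times."""
    uniq = np.unique(ages)
    n_interior = n_knots - 2
    # basis dimension = n_interior + degree + 1 must not exceed distinct ages
    while n_interior > 0 and (n_interior + degree + 1) > uniq.size:
        n_interior -= 1
    if n_interior < n_knots - 2:
        warnings.warn(
            f"only {uniq.size} distinct ages; reducing interior knots to {n_interior}"
        )
    lo, hi = float(uniq.min()), float(uniq.max())
    if hi <= lo:
        raise ValueError("ages must span a positive range")
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(ages, qs) if n_interior else np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design(ages: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    x = np.asarray(ages, float)
    out_of_range = (x < lo) | (x > hi)
    if out_of_range.any():
        warnings.warn("evaluating the age smooth outside the fitted range (extrapolation)")
    return BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree
    ).toarray()


def bspline_basis(
    ages: np.ndarray, n_knots: int = 5, degree: int = 3, center: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix and second-order difference penalty.

    Returns (B, S): B is n x p (columns mean-centered over the observations
    when `center`, so the smooth excludes the intercept); S = D2' D2 with D2
    the second-difference operator on the p spline coefficients.  S is
    positive semi-definite with a 2-dimensional null space (coefficient
    vectors linear in index), so straight-line components are unpenalized.
    """
    ages = np.asarray(ages, float)
    knots = _knot_vector(ages, n_knots, degree)
    B = _design(ages, knots, degree)
    p = B.shape[1]
    D2 = np.diff(np.eye(p), n=2, axis=0)
    S = D2.T @ D2
    if center:
        B = B - B.mean(axis=0)
    return B, S


class _SmoothReparam:
    """Mixed-model reparametrization of the penalized age smooth.

    Fixed part: centered age (the penalty's unpenalized non-constant
    direction, taken as an explicit linear term).  Random part: the penalty
    range space whitened to i.i.d. coefficients and residualized against
    {1, age} so the smooth's linear limit is exactly a straight line.
    """

    def __init__(self, ages: np.ndarray, n_knots: int, degree: int):
        ages = np.asarray(ages, float)
        self.degree = degree
        self.knots = _knot_vector(ages, n_knots, degree)
        self.age_mean = float(ages.mean())
        B = _design(ages, self.knots, degree)
        p = B.shape[1]
        D2 = np.diff(np.eye(p), n=2, axis=0)
        S = D2.T @ D2
        evals, evecs = np.linalg.eigh(S)
        pos = evals > 1e-10 * evals.max()
        self.U_pen = evecs[:, pos]
        self.scale_pen = 1.0 / np.sqrt(evals[pos])
        T = np.column_stack([np.ones_like(ages), ages - self.age_mean])
        Z_raw = B @ (self.U_pen * self.scale_pen)
        self.proj_coef, *_ = np.linalg.lstsq(T, Z_raw, rcond=None)
        self.n_pen = Z_raw.shape[1]

    def terms(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(linear column, penalized columns) of the smooth at `ages`."""
        ages = np.asarray(ages, float)
        a_c = ages - self.age_mean
        B = _design(ages, self.knots, self.degree)
        Z_raw = B @ (self.U_pen * self.scale_pen)
        T = np.column_stack([np.ones_like(ages), a_c])
        return a_c, Z_raw - T @ self.proj_coef


@dataclass
class AgingCurveFit:
    """A fitted aging-curve model (see module docstring for the model)."""

    spec: AgingModelSpec
    beta0: float
    coef_table: pd.DataFrame  # index: term; columns: coef, se, t, p
    edf_smooth: float
    smooth_p: float
    lambda_: float
    sigma2_b: float
    sigma2_e: float
    gamma_s: float  # sigma_s^2 / sigma_e^2
    gamma_b: float  # sigma_b^2 / sigma_e^2
    reml: float  # -2 * restricted log-likelihood at the optimum (up to const)
    edf_total: float
    n_obs: int
    age_range: tuple[float, float]
    # prediction internals
    _smooth: _SmoothReparam = field(repr=False)
    _theta: np.ndarray = field(repr=False)
    _V_theta: np.ndarray = field(repr=False)
    _col_slices: dict = field(repr=False)
    _cov_reference: dict = field(repr=False)
    _fitted_fixed: np.ndarray = field(repr=False)

    @property
    def resid_df(self) -> float:
        return max(self.n_obs - self.edf_total, 1.0)

    def report_row(self) -> dict:
        """One report column: smooth p/edf and covariate p-values."""
        out = {"s(age).p": self.smooth_p, "s(age).edf": self.edf_smooth}
        for cov, label in _COV_LABEL.items():
            out[label] = (
                float(self.coef_table.loc[cov, "p"])
                if cov in self.coef_table.index
                else np.nan
            )
        return out


def _sex_numeric(values: pd.Series | np.ndarray) -> np.ndarray:
    v = pd.Series(values)
    if v.dtype.kind in "fiu":
        return v.to_numpy(float)
    return (v.astype(str).str.lower() == "male").to_numpy(float)


def _reml_neg2(
    lg: np.ndarray, y: np.ndarray, X: np.ndarray, Z_s: np.ndarray, Z_b: np.ndarray
) -> float:
    """-2 restricted log-likelihood (profiled over beta and sigma_e^2),
    up to an additive constant, at log variance ratios lg = (log g_s, log g_b)."""
    g_s, g_b = np.exp(np.clip(lg, -30.0, 30.0))
    n, p = X.shape
    V0 = np.eye(n) + g_s * (Z_s @ Z_s.T) + g_b * (Z_b @ Z_b.T)
    try:
        c, low = cho_factor(V0)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_V0 = 2.0 * np.log(np.diag(c)).sum()
    Wy = cho_solve((c, low), y)
    WX = cho_solve((c, low), X)
    A = X.T @ WX
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e12
    try:
        beta = np.linalg.solve(A, X.T @ Wy)
    except np.linalg.LinAlgError:
        return 1e12
    q = float(y @ Wy - (X.T @ Wy) @ beta)
    if not np.isfinite(q) or q <= 0:
        return 1e12
    return (n - p) * np.log(q) + logdet_V0 + logdet_A


def fit_gamm(
    table: pd.DataFrame,
    spec: AgingModelSpec | None = None,
    outcome: str = "value",
    fix_gamma: dict | None = None,
) -> AgingCurveFit:
    """Fit the penalized-spline mixed model to one outcome's long table.

    `table` must contain columns `outcome`, 'age', the grouping column
    (default 'subject_id') and the covariates in `spec.covariates`.
    `fix_gamma` may pin the variance ratios {'gamma_s': ..., 'gamma_b': ...}
    instead of estimating them by REML (used by equivalence tests).
    """
    spec = spec or AgingModelSpec()
    df = table.reset_index(drop=True)
    y = df[outcome].to_numpy(float)
    ages = df["age"].to_numpy(float)
    n = y.size

    groups, _ = pd.factorize(df[spec.group])
    n_subj = groups.max() + 1
    if n_subj < 2:
        raise ValueError("random intercepts need at least 2 subjects")
    visits_per = np.bincount(groups)
    if (visits_per >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with repeated visits")

    smooth = _SmoothReparam(ages, spec.n_knots, spec.degree)
    a_c, Z_s = smooth.terms(ages)

    cols = [np.ones(n)]
    names = ["(Intercept)"]
    cov_reference: dict = {}
    for cov in spec.covariates:
        vals = _sex_numeric(df[cov]) if cov == "sex" else df[cov].to_numpy(float)
        cols.append(vals)
        names.append(cov)
        cov_reference[cov] = float(vals.mean())
    cols.append(a_c)
    names.append("age(linear)")
    X = np.column_stack(cols)
    p = X.shape[1]

    Z_b = np.zeros((n, n_subj))
    Z_b[np.arange(n), groups] = 1.0

    # degenerate input: the fixed effects already fit y (near) perfectly, so
    # the REML surface is numerically flat; collapse to the unpenalized limit
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ beta_ols
    degenerate = float(ols_resid @ ols_resid) <= 1e-12 * (1.0 + float(y @ y))

    if fix_gamma is not None and {"gamma_s", "gamma_b"} <= set(fix_gamma):
        lg_opt = np.log(
            [max(fix_gamma["gamma_s"], 1e-12), max(fix_gamma["gamma_b"], 1e-12)]
        )
        reml_val = _reml_neg2(lg_opt, y, X, Z_s, Z_b)
    elif degenerate:
        lg_opt = np.log([1e-12, 1e-12])
        reml_val = _reml_neg2(lg_opt, y, X, Z_s, Z_b)
    else:
        grid = [
            np.array([a, b])
            for a in (-8.0, -4.0, 0.0, 4.0, 8.0)
            for b in (-8.0, -4.0, 0.0, 4.0, 8.0)
        ]
        vals = [_reml_neg2(g, y, X, Z_s, Z_b) for g in grid]
        starts = [grid[int(np.argmin(vals))], np.array([0.0, 0.0])]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _reml_neg2,
                x0,
                args=(y, X, Z_s, Z_b),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e11 and best.success:
                break
        if best is None or best.fun >= 1e11:
            raise RuntimeError(
                f"REML optimization failed (criterion {best.fun if best else 'n/a'}); "
                f"grid values: {np.round(vals, 2).tolist()}"
            )
        lg_opt = best.x
        reml_val = float(best.fun)

    g_s, g_b = np.exp(np.clip(lg_opt, -30.0, 30.0))

    # variance components from the profiled criterion
    V0 = np.eye(n) + g_s * (Z_s @ Z_s.T) + g_b * (Z_b @ Z_b.T)
    c, low = cho_factor(V0)
    Wy = cho_solve((c, low), y)
    WX = cho_solve((c, low), X)
    A = X.T @ WX
    beta = np.linalg.solve(A, X.T @ Wy)
    q = float(y @ Wy - (X.T @ Wy) @ beta)
    sigma2_e = q / (n - p)
    sigma2_b = g_b * sigma2_e
    lambda_ = np.inf if g_s <= 0 else 1.0 / g_s

    # penalized-regression (working) form for edf and coefficient covariance
    C = np.column_stack([X, Z_s, Z_b])
    pen = np.concatenate(
        [
            np.zeros(p),
            np.full(Z_s.shape[1], 1.0 / max(g_s, 1e-12)),
            np.full(n_subj, 1.0 / max(g_b, 1e-12)),
        ]
    )
    M = C.T @ C + np.diag(pen)
    Minv = np.linalg.inv(M)
    theta = Minv @ (C.T @ y)
    edf_vec = 1.0 - np.diag(Minv) * pen  # diag(Minv @ C'C), pen is diagonal
    sl = {
        "fixed": slice(0, p),
        "lin": p - 1,  # age(linear) is the last fixed column
        "Zs": slice(p, p + Z_s.shape[1]),
        "Zb": slice(p + Z_s.shape[1], p + Z_s.shape[1] + n_subj),
    }
    edf_smooth = float(edf_vec[sl["lin"]] + edf_vec[sl["Zs"]].sum())
    edf_total = float(edf_vec.sum())
    V_theta = Minv * sigma2_e  # Bayesian posterior covariance of all coefficients

    # fixed-effect Wald tests from the GLS covariance
    V_beta = np.linalg.inv(A) * sigma2_e
    se = np.sqrt(np.clip(np.diag(V_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    resid_df = max(n - edf_total, 1.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), resid_df)
    coef_table = pd.DataFrame(
        {"coef": beta, "se": se, "t": tstat, "p": pvals}, index=names
    )

    # Wald-type test of the whole smooth (linear + wiggly parts)
    smooth_cols = np.r_[sl["lin"], np.arange(sl["Zs"].start, sl["Zs"].stop)]
    f_hat = C[:, smooth_cols] @ theta[smooth_cols]
    V_f = C[:, smooth_cols] @ V_theta[np.ix_(smooth_cols, smooth_cols)] @ C[:, smooth_cols].T
    r = int(max(1, round(edf_smooth)))
    evals, evecs = np.linalg.eigh(V_f)
    order = np.argsort(evals)[::-1][:r]
    lam = evals[order]
    keep = lam > max(lam.max(), 0) * 1e-10
    proj = evecs[:, order[keep]].T @ f_hat
    T_stat = float((proj**2 / lam[keep]).sum()) if keep.any() else 0.0
    r_eff = int(keep.sum()) if keep.any() else 1
    smooth_p = float(stats.f.sf(T_stat / r_eff, r_eff, resid_df))

    return AgingCurveFit(
        spec=spec,
        beta0=float(beta[0]),
        coef_table=coef_table,
        edf_smooth=edf_smooth,
        smooth_p=smooth_p,
        lambda_=float(lambda_),
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        gamma_s=float(g_s),
        gamma_b=float(g_b),
        reml=float(reml_val),
        edf_total=edf_total,
        n_obs=n,
        age_range=(float(ages.min()), float(ages.max())),
        _smooth=smooth,
        _theta=theta,
        _V_theta=V_theta,
        _col_slices=sl,
        _cov_reference=cov_reference,
        _fitted_fixed=C[:, : sl["Zs"].stop] @ theta[: sl["Zs"].stop],
    )


def predict_curve(
    fit: AgingCurveFit, age_grid: np.ndarray | None = None, n_points: int = 100
) -> pd.DataFrame:
    """Population-level aging curve with pointwise 95% CI.

    Covariates are held at their sample means (sex at the sample male
    proportion); the subject random intercept is excluded.  Returns a frame
    with columns age, fit, se, lo, hi.
    """
    lo_a, hi_a = fit.age_range
    if age_grid is None:
        age_grid = np.linspace(lo_a, hi_a, n_points)
    age_grid = np.asarray(age_grid, float)
    span = hi_a - lo_a
    if age_grid.min() < lo_a - 0.1 * span or age_grid.max() > hi_a + 0.1 * span:
        warnings.warn("age grid extends far outside the observed range (extrapolation)")

    a_c, Z_s = fit._smooth.terms(age_grid)
    sl = fit._col_slices
    m = age_grid.size
    n_theta = fit._theta.size
    R = np.zeros((m, n_theta))
    R[:, 0] = 1.0
    for j, cov in enumerate(fit.spec.covariates, start=1):
        R[:, j] = fit._cov_reference[cov]
    R[:, sl["lin"]] = a_c
    R[:, sl["Zs"]] = Z_s
    fitted = R @ fit._theta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", R, fit._V_theta, R), 0.0, None))
    return pd.DataFrame(
        {
            "age": age_grid,
            "fit": fitted,
            "se": se,
            "lo": fitted - 1.96 * se,
            "hi": fitted + 1.96 * se,
        }
    )


METRIC_ORDER = ["ALFF", "ReHo", "VMHC"]
BAND_ORDER = ["slow-3", "slow-4", "slow-5"]  # report column order (fast to slow)


def fit_all(
    table: pd.DataFrame,
    statistics: tuple[str, ...] = ("mean", "SD"),
    n_knots: int = 5,
) -> dict:
    """Fit every metric x band aging-curve model for each global statistic.

    Returns {'fits': {(statistic, metric, band): AgingCurveFit}, 'reports':
    {statistic: DataFrame}, 'errors': {...}}.  Each report mirrors the
    standard report layout: rows s(age).p, s(age).edf, Cohort.p,
    Education.p, Sex.p; one column per metric x band.
    """
    fits: dict = {}
    errors: dict = {}
    reports: dict = {}
    for statistic in statistics:
        columns = {}
        for metric in METRIC_ORDER:
            for band in BAND_ORDER:
                sub = table[
                    (table["metric"] == metric)
                    & (table["band"] == band)
                    & (table["statistic"] == statistic)
                ]
                key = (statistic, metric, band)
                label = (metric, band)
                if sub.empty:
                    continue
                spec = AgingModelSpec(
                    metric=metric, band=band, statistic=statistic, n_knots=n_knots
                )
                try:
                    fit = fit_gamm(sub, spec)
                except Exception as exc:  # per-outcome failure is not fatal
                    errors[key] = str(exc)
                    columns[label] = {row: np.nan for row in REPORT_ROWS}
                    continue
                fits[key] = fit
                columns[label] = fit.report_row()
        rep = pd.DataFrame(columns).reindex(REPORT_ROWS)
        rep.columns = pd.MultiIndex.from_tuples(rep.columns, names=["metric", "band"])
        reports[statistic] = rep
    return {"fits": fits, "reports": reports, "errors": errors}
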