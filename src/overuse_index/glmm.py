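"""Negative-binomial mixed model for cell event counts.

The event count :math:`C_{ijk}` in cell (quarter *i*, indicator *j*, system
*k*, hospital *h*) is modelled as NB2 with mean

.. math::

    \\mu = n \\exp(\\omega_i + \\psi_j + \\Phi_k + \\beta X + b_h),

where *n* is the eligible count (a log offset), :math:`\\omega_i` are quarter
fixed effects, :math:`\\psi_j` indicator fixed effects, :math:`\\Phi_k` health
system fixed effects, *X* the cell-level patient covariates (mean age,
proportion of women, median chronic-condition count), and
:math:`b_h \\sim N(0, \\sigma^2_h)` a hospital random intercept.  The NB2
variance is :math:`\\mu + \\alpha \\mu^2`.

Hospital random intercepts are integrated out with a Laplace approximation
(one adaptive quadrature point): each hospital's integral is evaluated at the
conditional mode of :math:`b_h` with a second-order curvature correction.  At
:math:`\\sigma^2_h = 0` the marginal likelihood reduces exactly to the
fixed-effects NB log-likelihood.  The marginal likelihood is maximized by a
quasi-Newton warm phase followed by Newton-Raphson with step-halving, using
the exact analytic gradient throughout; :math:`\\alpha` and
:math:`\\sigma^2_h` are optimized on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator

__all__ = [
    "DesignSpec",
    "Design",
    "build_design",
    "nb2_loglik",
    "laplace_marginal_loglik",
    "NegativeBinomialGLMM",
    "fit_nb_glmm",
    "extract_system_effects",
]

_ETA_CLIP = 30.0
_LOG_SIGMA2_MIN = -12.0  # sigma2 ~ 6e-6: the practical zero boundary


# ---------------------------------------------------------------------------
# NB2 log-likelihood and derivatives on the linear-predictor scale


def nb2_loglik(y, mu, alpha):
    """Log NB2 probability mass, variance ``mu + alpha*mu**2``.

    Stable for small ``alpha`` (Poisson limit) and large counts; broadcasts.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(y)) and np.isfinite(alpha)):
        raise ValueError("nb2_loglik requires finite inputs")
    if np.any(mu <= 0) or alpha <= 0:
        raise ValueError("nb2_loglik requires mu > 0 and alpha > 0")
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + y * np.log(mu / r)
        - (y + r) * np.log1p(mu / r)
    )


def _cell_derivs(y, eta, r):
    """Per-cell derivative ingredients of the NB2 log-likelihood.

    Returns ``(mu, w, l1, c2, c3)`` where ``l1 = dl/deta``, ``c2 = -d2l/deta2``
    and ``c3 = dc2/deta`` with ``w = mu/(r+mu)``.
    """
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    w = mu / (r + mu)
    yr = y + r
    l1 = y - yr * w
    c2 = yr * w * (1.0 - w)
    c3 = c2 * (1.0 - 2.0 * w)
    return mu, w, l1, c2, c3


def _solve_modes(y, eta0, groups, n_groups, r, sigma2, b0=None, tol=1e-11, max_iter=100):
    """Conditional modes of the hospital random intercepts, all groups at once.

    The per-group objective is strictly concave in ``b``; damped Newton with
    step clipping converges from any start.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    for _ in range(max_iter):
        _, _, l1, c2, _ = _cell_derivs(y, eta0 + b[groups], r)
        gb = np.bincount(groups, weights=l1, minlength=n_groups) - b / sigma2
        hb = np.bincount(groups, weights=c2, minlength=n_groups) + 1.0 / sigma2
        step = np.clip(gb / hb, -2.0, 2.0)
        b += step
        if np.max(np.abs(gb)) < tol * (1.0 + np.max(np.abs(b))):
            break
    else:
        worst = int(np.argmax(np.abs(gb)))
        raise RuntimeError(f"random-intercept mode search did not converge for hospital group {worst}")
    return b


def laplace_marginal_loglik(y, eta0, groups, alpha, sigma2, b0=None, return_parts=False):
    """Laplace-approximated marginal log-likelihood over hospital intercepts.

    Parameters
    ----------
    y : array
        Event counts per cell.
    eta0 : array
        Linear predictor per cell *excluding* the random intercept (fixed
        effects plus log-offset).
    groups : int array
        Hospital group code per cell (0..G-1).
    alpha, sigma2 : float
        NB2 dispersion and hospital-intercept variance.
    """
    y = np.asarray(y, dtype=float)
    eta0 = np.asarray(eta0, dtype=float)
    groups = np.asarray(groups)
    n_groups = int(groups.max()) + 1 if len(groups) else 0
    r = 1.0 / alpha
    if sigma2 <= np.exp(_LOG_SIGMA2_MIN):
        ll = float(np.sum(nb2_loglik(y, np.exp(np.clip(eta0, -_ETA_CLIP, _ETA_CLIP)), alpha)))
        if return_parts:
            return ll, np.zeros(n_groups), None
        return ll
    b = _solve_modes(y, eta0, groups, n_groups, r, sigma2, b0=b0)
    eta = eta0 + b[groups]
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    ll_cells = float(np.sum(nb2_loglik(y, mu, alpha)))
    _, _, _, c2, _ = _cell_derivs(y, eta, r)
    H = np.bincount(groups, weights=c2, minlength=n_groups) + 1.0 / sigma2
    ll = ll_cells - float(np.sum(b**2) / (2.0 * sigma2)) - 0.5 * float(np.sum(np.log(sigma2 * H)))
    if return_parts:
        return ll, b, H
    return ll


def _loglik_and_grad(theta, y, X, offset, groups, n_groups, b_cache):
    """Marginal log-likelihood and its exact gradient.

    ``theta = [beta (p), log_alpha, log_sigma2]``.  The gradient uses the
    envelope identity at the conditional modes plus the derivative of the
    Laplace curvature term (third-order cell derivatives).
    """
    p = X.shape[1]
    beta = theta[:p]
    alpha = np.exp(theta[p])
    sigma2 = np.exp(theta[p + 1])
    r = 1.0 / alpha
    eta0 = X @ beta + offset

    at_boundary = sigma2 <= np.exp(_LOG_SIGMA2_MIN) * (1 + 1e-12)
    b = _solve_modes(y, eta0, groups, n_groups, r, sigma2, b0=b_cache.get("b"))
    b_cache["b"] = b
    eta = eta0 + b[groups]
    mu, w, l1, c2, c3 = _cell_derivs(y, eta, r)
    yr = y + r

    S2 = np.bincount(groups, weights=c2, minlength=n_groups)
    S3 = np.bincount(groups, weights=c3, minlength=n_groups)
    H = S2 + 1.0 / sigma2

    ll = (
        float(np.sum(nb2_loglik(y, mu, alpha)))
        - float(np.sum(b**2) / (2.0 * sigma2))
        - 0.5 * float(np.sum(np.log(sigma2 * H)))
    )

    Hg = H[groups]
    S3g = S3[groups]
    # d/dbeta: X^T (l1 - c3/(2H) + c2*S3/(2H^2)) per cell
    cell_w = l1 - 0.5 * c3 / Hg + 0.5 * c2 * S3g / Hg**2
    g_beta = X.T @ cell_w

    # d/dlog(alpha); dr/dlog(alpha) = -r
    rm = r + mu
    l_r = digamma(y + r) - digamma(r) + np.log(r) + 1.0 - np.log(rm) - yr / rm
    l_etar = -w + yr * w / rm
    c2_r = w * (1.0 - w) - yr * w * (1.0 - 2.0 * w) / rm
    T_r = np.bincount(groups, weights=c2_r, minlength=n_groups)
    T_etar = np.bincount(groups, weights=l_etar, minlength=n_groups)
    g_la = -r * float(np.sum(l_r)) + 0.5 * r * float(np.sum((T_r + S3 * T_etar / H) / H))

    # d/dlog(sigma2)
    if at_boundary:
        g_ls2 = 0.0
    else:
        g_ls2 = float(
            np.sum(
                b**2 / (2.0 * sigma2)
                - 0.5
                + 1.0 / (2.0 * sigma2 * H)
                - S3 * b / (2.0 * sigma2 * H**2)
            )
        )

    grad = np.concatenate([g_beta, [g_la, g_ls2]])
    return ll, grad


# ---------------------------------------------------------------------------
# Design construction


@dataclass(frozen=True)
class DesignSpec:
    """Identifiability choices and covariate handling for the model design.

    ``None`` references resolve at build time: first quarter, first indicator,
    and the system contributing the most cells (ties broken lexicographically).
    """

    reference_quarter: int | None = None
    reference_indicator: int | None = None
    reference_system: str | None = None
    covariate_names: tuple[str, ...] = (
        "mean_age",
        "proportion_women",
        "median_chronic_conditions",
    )
    standardize_covariates: bool = True


@dataclass
class Design:
    X: np.ndarray
    columns: list[str]
    offset: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    group_labels: list
    quarter_levels: list
    indicator_levels: list
    system_levels: list  # reference first
    covariate_names: list
    covariate_center: np.ndarray
    covariate_scale: np.ndarray
    spec: DesignSpec = field(default=DesignSpec())


def build_design(cells: pd.DataFrame, spec: DesignSpec | None = None) -> Design:
    """Model matrices for the cell table: dummies, log-offset, hospital groups.

    Fixed-effect dummies drop the stated reference levels; the offset is
    ``log(eligible_count)``; covariates are optionally centered and scaled
    (transforms stored for reporting on the original scale); cells are grouped
    by CCN for the random intercept.
    """
    spec = spec or DesignSpec()
    cells = cells.reset_index(drop=True)
    if (cells["eligible_count"] < 1).any():
        raise ValueError("all cells must have eligible_count >= 1 (log-offset undefined)")

    quarters = sorted(cells["quarter_index"].unique())
    indicators = sorted(cells["indicator_id"].unique())
    sys_counts = cells["system_id"].value_counts()
    systems_sorted = sorted(sys_counts.index)

    ref_q = spec.reference_quarter if spec.reference_quarter is not None else quarters[0]
    ref_j = spec.reference_indicator if spec.reference_indicator is not None else indicators[0]
    if spec.reference_system is not None:
        ref_k = spec.reference_system
    else:
        top = sys_counts[sys_counts == sys_counts.max()].index
        ref_k = sorted(top)[0]
    for ref, pool, what in ((ref_q, quarters, "quarter"), (ref_j, indicators, "indicator"), (ref_k, systems_sorted, "system")):
        if ref not in pool:
            raise ValueError(f"reference {what} {ref!r} not present in the cells")

    cols, names = [np.ones(len(cells))], ["intercept"]
    for q in quarters:
        if q != ref_q:
            cols.append((cells["quarter_index"] == q).to_numpy(float))
            names.append(f"quarter[{q}]")
    for j in indicators:
        if j != ref_j:
            cols.append((cells["indicator_id"] == j).to_numpy(float))
            names.append(f"indicator[{j}]")
    system_levels = [ref_k] + [s for s in systems_sorted if s != ref_k]
    for s in system_levels[1:]:
        cols.append((cells["system_id"] == s).to_numpy(float))
        names.append(f"system[{s}]")

    cov_names, center, scale = [], [], []
    for c in spec.covariate_names:
        v = cells[c].to_numpy(float)
        sd = v.std(ddof=0)
        if sd == 0.0:
            warnings.warn(f"covariate {c!r} has zero variance and was dropped", stacklevel=2)
            continue
        m = v.mean()
        if spec.standardize_covariates:
            cols.append((v - m) / sd)
            center.append(m)
            scale.append(sd)
        else:
            cols.append(v)
            center.append(0.0)
            scale.append(1.0)
        cov_names.append(c)
        names.append(c)

    X = np.column_stack(cols)
    groups_cat = pd.Categorical(cells["ccn"].astype(str), categories=sorted(cells["ccn"].astype(str).unique()))
    return Design(
        X=X,
        columns=names,
        offset=np.log(cells["eligible_count"].to_numpy(float)),
        y=cells["event_count"].to_numpy(float),
        groups=np.asarray(groups_cat.codes, dtype=np.int64),
        group_labels=list(groups_cat.categories),
        quarter_levels=quarters,
        indicator_levels=indicators,
        system_levels=system_levels,
        covariate_names=cov_names,
        covariate_center=np.asarray(center),
        covariate_scale=np.asarray(scale),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Estimator


class NegativeBinomialGLMM(BaseEstimator):
    """NB2 mixed model with hospital random intercepts, Laplace-fitted.

    scikit-learn style: construct with hyperparameters, call :meth:`fit` with
    a cell table, read fitted attributes (trailing underscore).

    Parameters
    ----------
    reference_quarter, reference_indicator, reference_system :
        Identifiability references; ``None`` resolves to the first quarter,
        first indicator and most-populated system.
    covariates : tuple of str
        Cell-level covariate columns.
    standardize_covariates : bool
        Center/scale covariates before fitting (transforms stored).
    max_iter : int
        Newton-Raphson iteration cap (after the quasi-Newton warm phase).
    tol : float
        Relative log-likelihood change for convergence.
    gtol : float
        Gradient max-norm for convergence.

    Attributes
    ----------
    quarter_effects_, indicator_effects_, system_effects_ : pandas.Series
        Fixed effects over all levels, reference entry exactly 0.
    covariate_betas_ : pandas.Series
        Covariate coefficients on the (possibly standardized) design scale.
    dispersion_ : float
        NB2 ``alpha``.
    hospital_variance_ : float
        Random-intercept variance ``sigma2_h``.
    hospital_blups_ : pandas.Series
        Conditional modes of the hospital intercepts, by CCN.
    loglik_, converged_, n_cells_, grad_norm_ : fit diagnostics.
    params_, se_ : pandas.Series
        Full parameter vector (betas, log_alpha, log_sigma2) and standard
        errors from the observed information.
    """

    def __init__(
        self,
        reference_quarter=None,
        reference_indicator=None,
        reference_system=None,
        covariates=("mean_age", "proportion_women", "median_chronic_conditions"),
        standardize_covariates=True,
        max_iter=50,
        tol=1e-8,
        gtol=1e-5,
        verbose=0,
    ):
        self.reference_quarter = reference_quarter
        self.reference_indicator = reference_indicator
        self.reference_system = reference_system
        self.covariates = covariates
        self.standardize_covariates = standardize_covariates
        self.max_iter = max_iter
        self.tol = tol
        self.gtol = gtol
        self.verbose = verbose

    # -- internal -----------------------------------------------------------

    def _design_spec(self) -> DesignSpec:
        return DesignSpec(
            reference_quarter=self.reference_quarter,
            reference_indicator=self.reference_indicator,
            reference_system=self.reference_system,
            covariate_names=tuple(self.covariates),
            standardize_covariates=self.standardize_covariates,
        )

    def fit(self, X, y=None):
        """Fit the model to a cell table (DataFrame of cell records)."""
        cells = X
        if cells["system_id"].nunique() < 2:
            raise ValueError("at least 2 health systems are required")
        zero_sys = cells.groupby("system_id")["event_count"].sum()
        flagged = list(zero_sys[zero_sys == 0].index)
        if flagged:
            warnings.warn(
                f"systems with all-zero events (possible separation): {flagged}", stacklevel=2
            )
        design = build_design(cells, self._design_spec())
        n_groups = len(design.group_labels)
        yv, Xd, off, grp = design.y, design.X, design.offset, design.groups
        p = Xd.shape[1]

        # warm start: Poisson GLM for the fixed effects
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta0 = (
                sm.GLM(yv, Xd, family=sm.families.Poisson(), offset=off)
                .fit(maxiter=100)
                .params
            )
        theta = np.concatenate([beta0, [0.0, np.log(0.1)]])

        b_cache: dict = {}

        def negll_grad(t):
            ll, g = _loglik_and_grad(t, yv, Xd, off, grp, n_groups, b_cache)
            return -ll, -g

        bounds = [(None, None)] * p + [(-10.0, 5.0), (_LOG_SIGMA2_MIN, 5.0)]
        warm = optimize.minimize(
            negll_grad,
            theta,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        theta = warm.x
        ll, grad = _loglik_and_grad(theta, yv, Xd, off, grp, n_groups, b_cache)

        # Newton-Raphson polish with step-halving line search
        converged = False
        hess = None
        for it in range(self.max_iter):
            gnorm = np.max(np.abs(grad))
            if self.verbose:
                print(f"newton iter {it}: ll={ll:.8f} gmax={gnorm:.3e}")
            hess = self._fd_hessian(theta, yv, Xd, off, grp, n_groups, b_cache)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            if not np.all(np.isfinite(step)):
                break
            # hess approximates d(grad)/dtheta of L (negative definite at max)
            step = -step
            new_ll = -np.inf
            t_new = theta
            for _ in range(30):
                cand = np.clip(theta + step, [-np.inf] * p + [-10.0, _LOG_SIGMA2_MIN], None)
                try:
                    new_ll, new_grad = _loglik_and_grad(cand, yv, Xd, off, grp, n_groups, b_cache)
                except (RuntimeError, FloatingPointError):
                    new_ll = -np.inf
                if new_ll > ll - 1e-13 * (1 + abs(ll)):
                    t_new = cand
                    break
                step *= 0.5
            if new_ll == -np.inf:
                break
            rel = abs(new_ll - ll) / (1.0 + abs(ll))
            theta, ll, grad = t_new, new_ll, new_grad
            if rel < self.tol and np.max(np.abs(grad)) < self.gtol:
                converged = True
                break
        if hess is None:
            hess = self._fd_hessian(theta, yv, Xd, off, grp, n_groups, b_cache)

        self._store_fit(design, theta, ll, grad, hess, converged, yv, off, grp, n_groups)
        return self

    def _fd_hessian(self, theta, y, X, off, grp, n_groups, b_cache):
        """Forward-difference Hessian of the log-likelihood from the analytic gradient."""
        p = len(theta)
        _, g0 = _loglik_and_grad(theta, y, X, off, grp, n_groups, b_cache)
        H = np.empty((p, p))
        for i in range(p):
            eps = 1e-6 * (1.0 + abs(theta[i]))
            t = theta.copy()
            t[i] += eps
            _, gi = _loglik_and_grad(t, y, X, off, grp, n_groups, b_cache)
            H[:, i] = (gi - g0) / eps
        return (H + H.T) / 2.0

    def _store_fit(self, design, theta, ll, grad, hess, converged, y, off, grp, n_groups):
        p = design.X.shape[1]
        beta = theta[:p]
        alpha = float(np.exp(theta[p]))
        sigma2 = float(np.exp(theta[p + 1]))
        names = design.columns + ["log_alpha", "log_sigma2"]
        self.design_ = design
        self.params_ = pd.Series(theta, index=names)
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(-hess)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.full(len(theta), np.nan)
        self.se_ = pd.Series(se, index=names)
        self.loglik_ = float(ll)
        self.grad_norm_ = float(np.max(np.abs(grad)))
        self.converged_ = bool(converged)
        self.n_cells_ = int(len(y))
        self.dispersion_ = alpha
        self.hospital_variance_ = 0.0 if sigma2 <= np.exp(_LOG_SIGMA2_MIN) * (1 + 1e-9) else sigma2

        coef = pd.Series(beta, index=design.columns)
        self.intercept_ = float(coef["intercept"])
        q = pd.Series(0.0, index=design.quarter_levels)
        for lev in design.quarter_levels:
            key = f"quarter[{lev}]"
            if key in coef.index:
                q[lev] = coef[key]
        self.quarter_effects_ = q
        j = pd.Series(0.0, index=design.indicator_levels)
        for lev in design.indicator_levels:
            key = f"indicator[{lev}]"
            if key in coef.index:
                j[lev] = coef[key]
        self.indicator_effects_ = j
        s = pd.Series(0.0, index=design.system_levels)
        for lev in design.system_levels[1:]:
            s[lev] = coef[f"system[{lev}]"]
        self.system_effects_ = s.sort_index()
        self.reference_system_ = design.system_levels[0]
        self.covariate_betas_ = coef[design.covariate_names]
        self.covariate_center_ = pd.Series(design.covariate_center, index=design.covariate_names)
        self.covariate_scale_ = pd.Series(design.covariate_scale, index=design.covariate_names)

        eta0 = design.X @ beta + off
        if self.hospital_variance_ > 0:
            r = 1.0 / alpha
            b = _solve_modes(y, eta0, grp, n_groups, r, sigma2)
        else:
            b = np.zeros(n_groups)
        self.hospital_blups_ = pd.Series(b, index=design.group_labels)

    # -- reporting ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Parameter table: name, estimate, standard error.

        The reference system appears as an extra ``system[...]`` row with
        estimate 0 and missing SE, so the file carries all K system effects.
        """
        tab = pd.DataFrame({"estimate": self.params_, "se": self.se_}).reset_index(
            names="parameter"
        )
        ref_row = pd.DataFrame(
            {"parameter": [f"system[{self.reference_system_}]"], "estimate": [0.0], "se": [np.nan]}
        )
        return pd.concat([tab, ref_row], ignore_index=True)


def fit_nb_glmm(cells: pd.DataFrame, spec: DesignSpec | None = None, **options) -> NegativeBinomialGLMM:
    """Convenience wrapper: fit the mixed model on a cell table."""
    spec = spec or DesignSpec()
    model = NegativeBinomialGLMM(
        reference_quarter=spec.reference_quarter,
        reference_indicator=spec.reference_indicator,
        reference_system=spec.reference_system,
        covariates=spec.covariate_names,
        standardize_covariates=spec.standardize_covariates,
        **options,
    )
    return model.fit(cells)


def extract_system_effects(fit: NegativeBinomialGLMM) -> pd.Series:
    """System fixed effects over all K systems, reference included as 0."""
    return fit.system_effects_.copy()
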