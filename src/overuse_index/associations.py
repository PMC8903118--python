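"""Associations between the Overuse Index and health-system characteristics.

Feature construction (tertiles for right-skewed counts, upper-quartile flags),
unadjusted category-table tests (Pearson chi-square for multilevel
characteristics, Mantel-Haenszel linear-trend test for binary flags), OLS of
the index on characteristics with state fixed effects, nested-model likelihood
ratio comparison, and a random-state-intercept linear mixed model as a
sensitivity variant.

Missing characteristics are handled by listwise deletion (no imputation);
per-model sample sizes are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "make_tertiles",
    "upper_quartile_flag",
    "unadjusted_chi2",
    "mh_trend_test",
    "category_table",
    "category_row_percentages",
    "AssociationResult",
    "fit_ols_state_fe",
    "lr_test",
    "fit_mixed_state_re",
]


def make_tertiles(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Tertile labels {1,2,3} by empirical 1/3 and 2/3 quantiles.

    Uses the inverse-CDF (type-1) quantile; values at a cutpoint go to the
    lower tertile.  Missing values get label 0 (excluded from models).
    """
    v = pd.Series(values, dtype=float)
    obs = v.dropna().to_numpy()
    if len(obs) < 3:
        raise ValueError("at least 3 non-missing values are required for tertiles")
    if np.all(obs == obs[0]):
        raise ValueError("all values identical; tertiles are undefined")
    q1 = np.quantile(obs, 1 / 3, method="inverted_cdf")
    q2 = np.quantile(obs, 2 / 3, method="inverted_cdf")
    labels = np.where(v.isna(), 0, np.where(v <= q1, 1, np.where(v <= q2, 2, 3)))
    return labels.astype(int), (float(q1), float(q2))


def upper_quartile_flag(values) -> np.ndarray:
    """Boolean flag: strictly above the empirical 75th percentile.

    Ties at the cutpoint are False; missing values are False (and should be
    excluded upstream when missingness matters).
    """
    v = pd.Series(values, dtype=float)
    obs = v.dropna().to_numpy()
    if len(obs) < 4:
        raise ValueError("at least 4 non-missing values are required")
    q3 = np.quantile(obs, 0.75, method="inverted_cdf")
    return (v > q3).fillna(False).to_numpy()


def category_table(categories, grouping) -> pd.DataFrame:
    """Counts of systems by characteristic level (rows) and category (columns)."""
    df = pd.DataFrame({"category": categories, "group": grouping}).dropna()
    tab = pd.crosstab(df["group"], df["category"])
    return tab.reindex(columns=range(1, 6), fill_value=0)


def category_row_percentages(tab: pd.DataFrame) -> pd.DataFrame:
    """Row percentages of a category count table (each row sums to 100)."""
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def unadjusted_chi2(categories, grouping):
    """Pearson chi-square (no continuity correction) on the category x level table.

    Empty rows/columns are collapsed out (logged via warning); at least two
    occupied levels on each margin are required.
    """
    tab = category_table(categories, grouping)
    occupied_cols = tab.columns[tab.sum(axis=0) > 0]
    occupied_rows = tab.index[tab.sum(axis=1) > 0]
    if len(occupied_cols) < len(tab.columns) or len(occupied_rows) < len(tab.index):
        warnings.warn("empty rows/columns collapsed before the chi-square test", stacklevel=2)
    tab = tab.loc[occupied_rows, occupied_cols]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("fewer than 2 occupied levels after collapsing")
    stat, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(stat), int(df), float(p)


def mh_trend_test(flag, categories):
    """Mantel-Haenszel chi-square for linear trend of a binary flag across categories.

    Uses integer scores 1..5; the statistic is ``(n - 1) * r^2`` with *r* the
    Pearson correlation between the flag and the score, df = 1.
    """
    df = pd.DataFrame({"flag": flag, "cat": categories}).dropna()
    x = df["flag"].astype(float).to_numpy()
    s = df["cat"].astype(float).to_numpy()
    if len(np.unique(s)) < 2:
        raise ValueError("at least 2 occupied categories are required")
    if len(np.unique(x)) < 2:
        raise ValueError("the flag is constant; no trend is testable")
    r = np.corrcoef(x, s)[0, 1]
    stat = (len(x) - 1) * r**2
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


@dataclass
class AssociationResult:
    """Coefficient table from an association model.

    ``table`` columns: name, estimate (difference in Overuse Index), se,
    p_value.  ``model_label`` distinguishes the model-1/model-2 OLS
    configurations and the mixed-state sensitivity fit.
    """

    table: pd.DataFrame
    n_systems: int
    log_likelihood: float
    model_label: str
    extra: dict | None = None

    @property
    def n_params(self) -> int:
        return int(self.extra["n_params"]) if self.extra and "n_params" in self.extra else len(self.table)


def _build_assoc_design(data: pd.DataFrame, covariates, state_col):
    """Listwise-delete, dummy-code tertile covariates and state fixed effects."""
    cols = list(covariates) + ([state_col] if state_col else [])
    d = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    names, mats = ["intercept"], [np.ones(len(d))]
    for c in covariates:
        v = d[c]
        if v.dtype == bool or set(pd.unique(v.dropna())) <= {0, 1, True, False}:
            mats.append(v.astype(float).to_numpy())
            names.append(c)
        else:
            levels = sorted(pd.unique(v.dropna()))
            for lev in levels[1:]:
                mats.append((v == lev).astype(float).to_numpy())
                names.append(f"{c}[{lev}]")
    if state_col:
        levels = sorted(pd.unique(d[state_col].dropna()))
        singletons = [s for s, n in d[state_col].value_counts().items() if n == 1]
        if singletons:
            warnings.warn(
                f"{len(singletons)} states with a single system are absorbed by their dummy",
                stacklevel=3,
            )
        for lev in levels[1:]:
            mats.append((d[state_col] == lev).astype(float).to_numpy())
            names.append(f"state[{lev}]")
    X = np.column_stack(mats)
    # rank check: drop collinear columns, keeping the earliest of each set
    keep = np.zeros(X.shape[1], dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis:
            B = np.column_stack(basis)
            resid = col - B @ np.linalg.lstsq(B, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(col)):
            keep[j] = True
            basis.append(col)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"rank-deficient design; dropped columns: {dropped}", stacklevel=3)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return d, X, names


def fit_ols_state_fe(
    index_table: pd.DataFrame,
    characteristics: pd.DataFrame,
    covariates,
    model_label: str = "model2",
    state_col: str | None = "state",
    response: str = "oi",
) -> AssociationResult:
    """OLS of the Overuse Index on system characteristics with state fixed effects.

    ``covariates`` are characteristic columns: tertile labels (1..3) are
    dummy-coded against the first tertile, binary flags enter directly.
    Coefficients are differences in the (standardized) Overuse Index.
    ``response`` may be "oi" (default) or "raw_phi".  Rows with any missing
    covariate or state are listwise-deleted.
    """
    data = index_table.merge(characteristics, on="system_id", how="inner")
    d, X, names = _build_assoc_design(data, covariates, state_col)
    y = d[response].to_numpy(float)
    if len(y) < X.shape[1]:
        raise ValueError("fewer systems than parameters after listwise deletion")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {"name": names, "estimate": res.params, "se": res.bse, "p_value": res.pvalues}
    )
    return AssociationResult(
        table=table,
        n_systems=int(len(y)),
        log_likelihood=float(res.llf),
        model_label=model_label,
        extra={"n_params": X.shape[1], "rss": float(res.ssr), "rows": d["system_id"].tolist()},
    )


def lr_test(fit_restricted: AssociationResult, fit_full: AssociationResult):
    """Likelihood ratio test of nested association models (Gaussian likelihood).

    Requires the same response rows and a parameter superset; the statistic is
    ``2 * (ll_full - ll_restricted)`` against chi-square with df equal to the
    parameter-count difference.
    """
    rows_r = fit_restricted.extra.get("rows") if fit_restricted.extra else None
    rows_f = fit_full.extra.get("rows") if fit_full.extra else None
    if rows_r is not None and rows_f is not None and rows_r != rows_f:
        raise ValueError("the two fits use different response rows; not comparable")
    df = fit_full.n_params - fit_restricted.n_params
    if df <= 0:
        names_r = set(fit_restricted.table["name"])
        names_f = set(fit_full.table["name"])
        if names_r == names_f:
            return 0.0, 0, 1.0
        raise ValueError("models are not nested (full model has no extra parameters)")
    stat = 2.0 * (fit_full.log_likelihood - fit_restricted.log_likelihood)
    if stat < 0 and stat > -1e-8:
        stat = 0.0
    if stat < 0:
        raise ValueError("negative LR statistic; the models are not nested as claimed")
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def fit_mixed_state_re(
    index_table: pd.DataFrame,
    characteristics: pd.DataFrame,
    covariates,
    state_col: str = "state",
    response: str = "oi",
    reml: bool = False,
) -> AssociationResult:
    """Sensitivity model: random state intercepts instead of state fixed effects.

    A Gaussian linear mixed model (ML by default, so LR comparisons of fixed
    effects are valid) with the same characteristic covariates.  A state
    variance estimate at the 0 boundary is reported as 0 with a flag.
    """
    data = index_table.merge(characteristics, on="system_id", how="inner")
    if data[state_col].nunique() < 2:
        raise ValueError("at least 2 states are required for state random effects")
    d, X, names = _build_assoc_design(data, covariates, state_col=None)
    d = d.reset_index(drop=True)
    y = d[response].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=d[state_col].to_numpy())
        res = model.fit(reml=reml)
    fe = res.fe_params
    table = pd.DataFrame(
        {
            "name": names,
            "estimate": np.asarray(fe),
            "se": np.asarray(res.bse_fe),
            "p_value": np.asarray(res.pvalues)[: len(names)],
        }
    )
    state_var = float(np.asarray(res.cov_re)[0, 0])
    boundary = state_var < 1e-8
    return AssociationResult(
        table=table,
        n_systems=int(len(y)),
        log_likelihood=float(res.llf),
        model_label="mixed_state",
        extra={
            "n_params": X.shape[1],
            "state_variance": 0.0 if boundary else state_var,
            "state_variance_at_boundary": bool(boundary),
            "residual_variance": float(res.scale),
        },
    )
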