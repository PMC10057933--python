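"""Age and sex statistics on per-subject network properties.

The analysis stage works from a subject table with columns ``id, age, sex,
scanner, n_nodes, gamma, lambda, sigma`` (plus ``predicted_age`` /
``brain_pad`` when a brain-age model has run) and reproduces the shape of a
standard aging-cohort workup:

* Mann-Whitney U group comparisons of demographics and network properties
  (Bonferroni-corrected alpha 0.05/3 for the three network properties);
* linear age x sex interaction models per age stratum (split at 70 years;
  age 70.0 belongs to the upper stratum), controlling for node count and
  scanner, with main-effects refits when the interaction is absent;
* ANCOVA-style covariate-adjusted sex contrasts;
* partial correlations of each property with chronological and predicted
  brain age (alpha 0.05/2), and a test for the difference between these two
  *dependent overlapping* correlations (they share the property variable),
  using a Fisher-z statistic with a backtransformed-average correlation
  (Hittner-style; Steiger's method available);
* penalized-spline (GAM) age-trajectory curves per sex.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "StatResult",
    "NETWORK_PROPERTIES",
    "ALPHA_DEMOGRAPHICS",
    "ALPHA_NETWORK",
    "ALPHA_CORRELATION",
    "mann_whitney_u",
    "fit_interaction_glm",
    "ancova_sex_contrast",
    "partial_correlation",
    "compare_dependent_correlations",
    "fit_age_trajectory",
    "run_full_analysis",
]

NETWORK_PROPERTIES = ("gamma", "lambda", "sigma")

ALPHA_DEMOGRAPHICS = 0.05
ALPHA_NETWORK = 0.05 / 3  # Bonferroni over the three network properties
ALPHA_CORRELATION = 0.05 / 2  # Bonferroni over chronological/brain age


@dataclass
class StatResult:
    """Outcome of one statistical procedure.

    ``estimates``, ``se`` and ``p_values`` are keyed by term;
    ``p_value`` is the procedure's primary p-value, and ``alpha_used``
    records the significance level the procedure is judged against.
    """

    test_name: str
    estimates: dict = dc_field(default_factory=dict)
    se: dict = dc_field(default_factory=dict)
    p_values: dict = dc_field(default_factory=dict)
    p_value: float = np.nan
    alpha_used: float = 0.05
    covariates: tuple = ()
    extra: dict = dc_field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha_used)


# ---------------------------------------------------------- Mann-Whitney U

_EXACT_LIMIT = 12  # exact enumeration up to this combined sample size


def _u_statistic(pooled_ranks: np.ndarray, idx_a: tuple, n_a: int) -> float:
    return pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0


def mann_whitney_u(group_a, group_b, alpha: float = 0.05) -> StatResult:
    """Two-sided Mann-Whitney U test with tie handling.

    Uses full permutation enumeration of group assignments when the
    combined sample size is at most 12 (two-sided p as the probability of a
    U at least as far from its null mean), and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks under ties
    u_a = _u_statistic(ranks, tuple(range(n_a)), n_a)
    mean_u = n_a * n_b / 2.0
    if n_a + n_b <= _EXACT_LIMIT:
        dev = abs(u_a - mean_u)
        count = total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, idx, n_a)
            total += 1
            if abs(u - mean_u) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "asymptotic"
    return StatResult(
        test_name="mann_whitney_u",
        estimates={"U_a": float(u_a), "U_b": float(n_a * n_b - u_a)},
        p_values={"group": p},
        p_value=p,
        alpha_used=alpha,
        extra={"method": method, "n_a": int(n_a), "n_b": int(n_b)},
    )


# ----------------------------------------------------------- linear models


def _scanner_codes(scanner: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(scanner, sort=True)
    return codes.astype(float)


def _stratum_mask(age: pd.Series, stratum: str, split_age: float = 70.0) -> np.ndarray:
    if stratum in ("<70", "lt", "young"):
        return (age < split_age).to_numpy()
    if stratum in (">=70", "ge", "old"):
        return (age >= split_age).to_numpy()
    raise ValueError("stratum must be '<70' or '>=70'")


def _ols(y: np.ndarray, x: np.ndarray, names: list[str]):
    res = sm.OLS(y, x).fit()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = np.corrcoef(x[:, 1:], rowvar=False)
        bad = [
            (names[i + 1], names[j + 1])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return res


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def fit_interaction_glm(
    table: pd.DataFrame,
    response: str,
    stratum: str,
    split_age: float = 70.0,
    alpha: float = 0.05,
) -> StatResult:
    """Age x sex interaction model within one age stratum.

    Fits ``response ~ age + female + age:female + n_nodes + scanner`` by
    ordinary least squares (a Gaussian identity-link GLM).  Standardized
    coefficients come from refitting with every design column and the
    response z-scored (the interaction column is z-scored as formed, which
    can push standardized coefficients past 1 under the strong
    age-by-dummy collinearity of a narrow stratum).  When the interaction
    p-value is at or above ``alpha``, the main effects of age and sex are
    re-estimated from the model without the interaction term and reported
    alongside.
    """
    mask = _stratum_mask(table["age"], stratum, split_age)
    sub = table.loc[mask]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    if sub["sex"].nunique() < 2:
        raise ValueError("both sexes must be present in the stratum")
    y = sub[response].to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    female = (sub["sex"] == "F").to_numpy(dtype=float)
    n_nodes = sub["n_nodes"].to_numpy(dtype=float)
    scanner = _scanner_codes(sub["scanner"])
    names = ["const", "age", "female", "age_x_female", "n_nodes", "scanner"]
    x = np.column_stack([np.ones_like(age), age, female, age * female, n_nodes, scanner])
    res = _ols(y, x, names)
    xz = np.column_stack([np.ones_like(age), _zscore_cols(x[:, 1:])])
    yz = (y - y.mean()) / y.std(ddof=1)
    res_z = _ols(yz, xz, names)

    estimates = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    p_values = dict(zip(names, res.pvalues))
    std_beta = dict(zip(names, res_z.params))
    p_inter = float(p_values["age_x_female"])

    extra = {"standardized_beta": std_beta, "stratum": stratum, "n": int(len(sub))}
    if p_inter >= alpha:
        x_main = x[:, [0, 1, 2, 4, 5]]
        names_main = ["const", "age", "female", "n_nodes", "scanner"]
        res_main = _ols(y, x_main, names_main)
        xz_main = np.column_stack([np.ones_like(age), _zscore_cols(x_main[:, 1:])])
        res_main_z = _ols(yz, xz_main, names_main)
        extra["main_effects"] = {
            "estimates": dict(zip(names_main, res_main.params)),
            "se": dict(zip(names_main, res_main.bse)),
            "p_values": dict(zip(names_main, res_main.pvalues)),
            "standardized_beta": dict(zip(names_main, res_main_z.params)),
        }
    return StatResult(
        test_name="interaction_glm",
        estimates=estimates,
        se=se,
        p_values=p_values,
        p_value=p_inter,
        alpha_used=alpha,
        covariates=("n_nodes", "scanner"),
        extra=extra,
    )


def ancova_sex_contrast(
    table: pd.DataFrame,
    response: str,
    stratum: str,
    split_age: float = 70.0,
    alpha: float = 0.05,
) -> StatResult:
    """Covariate-adjusted sex contrast within one age stratum.

    Fits ``response ~ female + age + n_nodes + scanner`` and reports the
    adjusted group means per sex evaluated at the covariate means, their
    standard errors, and the p-value of the sex effect.
    """
    mask = _stratum_mask(table["age"], stratum, split_age)
    sub = table.loc[mask]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    if sub["sex"].nunique() < 2:
        raise ValueError("both sexes must be present in the stratum")
    y = sub[response].to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    female = (sub["sex"] == "F").to_numpy(dtype=float)
    n_nodes = sub["n_nodes"].to_numpy(dtype=float)
    scanner = _scanner_codes(sub["scanner"])
    names = ["const", "female", "age", "n_nodes", "scanner"]
    x = np.column_stack([np.ones_like(age), female, age, n_nodes, scanner])
    res = _ols(y, x, names)
    cov = res.cov_params()
    means = {}
    ses = {}
    for label, fem in (("F", 1.0), ("M", 0.0)):
        d = np.array([1.0, fem, age.mean(), n_nodes.mean(), scanner.mean()])
        means[label] = float(d @ res.params)
        ses[label] = float(np.sqrt(d @ cov @ d))
    p_sex = float(res.pvalues[1])
    return StatResult(
        test_name="ancova_sex_contrast",
        estimates={"adj_mean_F": means["F"], "adj_mean_M": means["M"],
                   "difference_F_minus_M": float(res.params[1])},
        se={"adj_mean_F": ses["F"], "adj_mean_M": ses["M"],
            "difference_F_minus_M": float(res.bse[1])},
        p_values={"sex": p_sex},
        p_value=p_sex,
        alpha_used=alpha,
        covariates=("age", "n_nodes", "scanner"),
        extra={"stratum": stratum, "n": int(len(sub))},
    )


# ----------------------------------------------------- partial correlation


def partial_correlation(x, y, covariates=None, alpha: float = 0.05) -> StatResult:
    """Correlation of x and y after removing linear effects of covariates.

    Both variables are residualized on the covariates (plus an intercept);
    the Pearson correlation of the residuals is tested on ``n - 2 - k``
    degrees of freedom, k the number of covariate columns.  With no
    covariates this reduces exactly to the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if rx.std() <= tol_x or ry.std() <= tol_y:
        warnings.warn("constant residuals; partial correlation undefined", stacklevel=2)
        return StatResult(
            test_name="partial_correlation",
            p_value=np.nan,
            alpha_used=alpha,
            extra={"defined": False, "n": int(n), "k": int(k)},
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        test_name="partial_correlation",
        estimates={"r": r},
        p_values={"r": p},
        p_value=p,
        alpha_used=alpha,
        covariates=tuple(range(k)),
        extra={"df": int(df), "t": float(t), "n": int(n), "defined": True},
    )


# --------------------------------------- dependent overlapping correlations


def compare_dependent_correlations(
    r_jk: float,
    r_jh: float,
    r_kh: float,
    n: int,
    method: str = "hittner",
    alpha: float = 0.05,
) -> StatResult:
    """Test rho_jk = rho_jh for two correlations sharing variable j.

    Here j is the overlap variable (a network property), k and h the two
    competitors (chronological and predicted brain age), and ``r_kh`` their
    correlation.  Both methods compare Fisher-z transformed correlations:

    * ``"hittner"`` uses the backtransformed average of the two z values as
      the common correlation in the variance term;
    * ``"steiger"`` uses the plain average of the two correlations.

    Returns a two-sided Z test.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must be strictly inside (-1, 1)")
    if n < 10:
        raise ValueError("n must be at least 10")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    if method == "hittner":
        r_bar = np.tanh((z_jk + z_jh) / 2.0)
    elif method == "steiger":
        r_bar = (r_jk + r_jh) / 2.0
    else:
        raise ValueError("method must be 'hittner' or 'steiger'")
    rb2 = r_bar**2
    f = min((1.0 - r_kh) / (2.0 * (1.0 - rb2)), 1.0)
    h = (1.0 - f * rb2) / (1.0 - rb2)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return StatResult(
        test_name=f"dependent_correlations_{method}",
        estimates={"Z": float(z), "r_jk": float(r_jk), "r_jh": float(r_jh)},
        p_values={"difference": p},
        p_value=p,
        alpha_used=alpha,
        extra={"n": int(n), "r_kh": float(r_kh)},
    )


# ------------------------------------------------------------ GAM curves


@dataclass
class TrajectoryFit:
    """Fitted age-trajectory curves per group (from a penalized-spline GAM)."""

    age_grid: np.ndarray
    fitted: dict  # group -> fitted values on the grid
    se: dict  # group -> pointwise standard errors
    groups: tuple

    def band(self, group: str, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        f, s = self.fitted[group], self.se[group]
        return f - z * s, f + z * s


def _select_gam_alpha(y, exog, age, spline_df, grid=(1e0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6)):
    """Pick the spline penalty by 5-fold cross-validated squared error."""
    from statsmodels.gam.api import BSplines, GLMGam

    n = len(y)
    folds = np.arange(n) % 5
    best, best_alpha = np.inf, grid[0]
    for alpha in grid:
        sse = 0.0
        for f in range(5):
            tr = folds != f
            smoother = BSplines(age[tr, None], df=[spline_df], degree=[3],
                                include_intercept=False)
            try:
                res = GLMGam(y[tr], exog=exog[tr], smoother=smoother,
                             alpha=[alpha]).fit()
            except Exception:
                sse = np.inf
                break
            te_idx = np.flatnonzero(~tr)
            inside = (age[te_idx] >= age[tr].min()) & (age[te_idx] <= age[tr].max())
            te_idx = te_idx[inside]
            if te_idx.size == 0:
                continue
            basis = smoother.transform(age[te_idx, None])
            design = np.column_stack([exog[te_idx], basis])
            pred = design @ np.asarray(res.params)
            sse += float(((y[te_idx] - pred) ** 2).sum())
        if sse < best:
            best, best_alpha = sse, alpha
    return best_alpha


def fit_age_trajectory(
    table: pd.DataFrame,
    response: str,
    by_sex: bool = True,
    n_grid: int = 50,
    spline_df: int = 6,
    penalty: float | None = None,
) -> TrajectoryFit:
    """Penalized-spline fit of a property against age, per sex.

    Each group's curve is a Gaussian GAM of ``response`` on a B-spline
    basis in age, with node count and scanner entering linearly; the curve
    is evaluated on an age grid at the group's mean covariates, with
    pointwise standard errors from the penalized coefficient covariance.
    ``penalty=None`` (default) selects the smoothing weight per group by
    5-fold cross-validation.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    groups = ("F", "M") if by_sex else ("all",)
    # evaluate on the age range covered by every group (with a small inset,
    # since the spline basis is undefined outside its knots)
    if by_sex:
        lo = max(table.loc[table["sex"] == g, "age"].min() for g in ("F", "M"))
        hi = min(table.loc[table["sex"] == g, "age"].max() for g in ("F", "M"))
    else:
        lo, hi = table["age"].min(), table["age"].max()
    span = hi - lo
    grid = np.linspace(lo + 1e-3 * span, hi - 1e-3 * span, n_grid)
    fitted, se = {}, {}
    for g in groups:
        sub = table if g == "all" else table.loc[table["sex"] == g]
        if len(sub) < 20:
            raise ValueError(f"need at least 20 subjects per group (group {g!r})")
        age = sub["age"].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
            # constant response: the curve is exactly flat
            fitted[g] = np.full(n_grid, y.mean())
            se[g] = np.zeros(n_grid)
            continue
        n_nodes = sub["n_nodes"].to_numpy(dtype=float)
        scanner = _scanner_codes(sub["scanner"])
        exog = np.column_stack([np.ones_like(age), n_nodes, scanner])
        alpha = penalty if penalty is not None else _select_gam_alpha(
            y, exog, age, spline_df
        )
        smoother = BSplines(age[:, None], df=[spline_df], degree=[3],
                            include_intercept=False)
        model = GLMGam(y, exog=exog, smoother=smoother, alpha=[alpha])
        res = model.fit()
        basis_grid = smoother.transform(grid[:, None])
        exog_grid = np.column_stack(
            [np.ones(n_grid), np.full(n_grid, n_nodes.mean()), np.full(n_grid, scanner.mean())]
        )
        design = np.column_stack([exog_grid, basis_grid])
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        fitted[g] = design @ params
        se[g] = np.sqrt(np.einsum("ij,jk,ik->i", design, cov, design))
    return TrajectoryFit(age_grid=grid, fitted=fitted, se=se, groups=groups)


# -------------------------------------------------------- full analysis


def _sex_summary_row(table: pd.DataFrame, column: str, alpha: float) -> dict:
    f = table.loc[table["sex"] == "F", column].dropna().to_numpy(dtype=float)
    m = table.loc[table["sex"] == "M", column].dropna().to_numpy(dtype=float)
    res = mann_whitney_u(f, m, alpha=alpha)
    return {
        "variable": column,
        "mean_F": f.mean(),
        "sd_F": f.std(ddof=1),
        "mean_M": m.mean(),
        "sd_M": m.std(ddof=1),
        "p_value": res.p_value,
        "alpha_used": alpha,
    }


def run_full_analysis(
    table: pd.DataFrame,
    split_age: float = 70.0,
    out_dir=None,
    dependent_corr_method: str = "hittner",
) -> dict:
    """Run the full statistical stage and emit the four table analogues.

    ``table`` must carry id, age, sex, scanner, n_nodes and the three
    network properties; predicted_age/brain_pad are optional (without them
    the brain-age comparisons are skipped with a warning).  Returns a dict
    with DataFrames ``demographics`` (sex comparison of everything),
    ``interaction`` (age x sex GLMs per stratum), ``sex_contrast`` (ANCOVA
    per stratum) and ``correlations`` (partial correlations with
    chronological/brain age plus their dependent comparison), and a
    ``manifest``.  When ``out_dir`` is given, each table is written as CSV
    and the manifest as JSON.
    """
    required = {"id", "age", "sex", "scanner", "n_nodes", *NETWORK_PROPERTIES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    has_brain_age = "predicted_age" in table.columns and table["predicted_age"].notna().all()
    if not has_brain_age:
        warnings.warn(
            "no predicted ages available; running chronological-age-only analyses",
            stacklevel=2,
        )
    table = table.copy()
    if has_brain_age and "brain_pad" not in table.columns:
        table["brain_pad"] = table["predicted_age"] - table["age"]

    # Table 1 analogue: sex comparison of demographics and properties
    demo_cols = ["age"] + (["predicted_age", "brain_pad"] if has_brain_age else [])
    demo_cols += ["n_nodes"]
    rows = [_sex_summary_row(table, c, ALPHA_DEMOGRAPHICS) for c in demo_cols]
    rows += [_sex_summary_row(table, c, ALPHA_NETWORK) for c in NETWORK_PROPERTIES]
    demographics = pd.DataFrame(rows)

    # Table 2 analogue: interaction GLMs per stratum and property
    inter_rows = []
    for stratum in ("<70", ">=70"):
        for prop in NETWORK_PROPERTIES:
            res = fit_interaction_glm(table, prop, stratum, split_age=split_age)
            std = res.extra["standardized_beta"]
            main = res.extra.get("main_effects")
            inter_rows.append(
                {
                    "stratum": stratum,
                    "property": prop,
                    "term": "age_x_female",
                    "beta": res.estimates["age_x_female"],
                    "se": res.se["age_x_female"],
                    "std_beta": std["age_x_female"],
                    "p_value": res.p_values["age_x_female"],
                    "alpha_used": res.alpha_used,
                }
            )
            source = main if main is not None else res
            for term in ("age", "female"):
                if main is not None:
                    est, s = main["estimates"][term], main["se"][term]
                    sb, p = main["standardized_beta"][term], main["p_values"][term]
                else:
                    est, s = res.estimates[term], res.se[term]
                    sb, p = std[term], res.p_values[term]
                inter_rows.append(
                    {
                        "stratum": stratum,
                        "property": prop,
                        "term": term,
                        "beta": est,
                        "se": s,
                        "std_beta": sb,
                        "p_value": p,
                        "alpha_used": res.alpha_used,
                    }
                )
    interaction = pd.DataFrame(inter_rows)

    # Table 3 analogue: ANCOVA sex contrasts per stratum and property
    sc_rows = []
    for stratum in ("<70", ">=70"):
        for prop in NETWORK_PROPERTIES:
            res = ancova_sex_contrast(table, prop, stratum, split_age=split_age)
            sc_rows.append(
                {
                    "stratum": stratum,
                    "property": prop,
                    "adj_mean_F": res.estimates["adj_mean_F"],
                    "se_F": res.se["adj_mean_F"],
                    "adj_mean_M": res.estimates["adj_mean_M"],
                    "se_M": res.se["adj_mean_M"],
                    "p_value": res.p_value,
                    "alpha_used": res.alpha_used,
                }
            )
    sex_contrast = pd.DataFrame(sc_rows)

    # Table 4 analogue: partial correlations + dependent comparison
    corr_rows = []
    if has_brain_age:
        for stratum in ("<70", ">=70"):
            mask = _stratum_mask(table["age"], stratum, split_age)
            sub = table.loc[mask]
            female = (sub["sex"] == "F").to_numpy(dtype=float)
            covs = np.column_stack(
                [female, sub["n_nodes"].to_numpy(dtype=float), _scanner_codes(sub["scanner"])]
            )
            age = sub["age"].to_numpy(dtype=float)
            pred = sub["predicted_age"].to_numpy(dtype=float)
            r_kh = partial_correlation(age, pred, covs).estimates.get("r", np.nan)
            for prop in NETWORK_PROPERTIES:
                yv = sub[prop].to_numpy(dtype=float)
                rc = partial_correlation(yv, age, covs, alpha=ALPHA_CORRELATION)
                rb = partial_correlation(yv, pred, covs, alpha=ALPHA_CORRELATION)
                cmp_res = compare_dependent_correlations(
                    rc.estimates["r"], rb.estimates["r"], r_kh, len(sub),
                    method=dependent_corr_method,
                )
                corr_rows.append(
                    {
                        "stratum": stratum,
                        "property": prop,
                        "r_chronological": rc.estimates["r"],
                        "p_chronological": rc.p_value,
                        "r_brain_age": rb.estimates["r"],
                        "p_brain_age": rb.p_value,
                        "alpha_used": ALPHA_CORRELATION,
                        "p_comparison": cmp_res.p_value,
                        "alpha_comparison": 0.05,
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    manifest = {
        "split_age": split_age,
        "strata": ["<70", ">=70"],
        "alphas": {
            "demographics": ALPHA_DEMOGRAPHICS,
            "network_properties": ALPHA_NETWORK,
            "partial_correlations": ALPHA_CORRELATION,
            "correlation_comparison": 0.05,
        },
        "models": {
            "interaction": "response ~ age + female + age:female + n_nodes + scanner",
            "ancova": "response ~ female + age + n_nodes + scanner",
            "partial_correlation_covariates": ["female", "n_nodes", "scanner"],
            "dependent_correlation_method": dependent_corr_method,
        },
        "properties": list(NETWORK_PROPERTIES),
        "n_subjects": int(len(table)),
        "brain_age_available": bool(has_brain_age),
    }
    report = {
        "demographics": demographics,
        "interaction": interaction,
        "sex_contrast": sex_contrast,
        "correlations": correlations,
        "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        demographics.to_csv(out / "table1_demographics.csv", index=False)
        interaction.to_csv(out / "table2_interaction.csv", index=False)
        sex_contrast.to_csv(out / "table3_sex_contrast.csv", index=False)
        correlations.to_csv(out / "table4_correlations.csv", index=False)
        (out / "analysis_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
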