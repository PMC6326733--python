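"""Group-difference inference and replication aggregation.

All reported effects are patient minus control. Nodewise tests are
two-sample t tests (Welch by default; pooled-variance optional).
Replication-level summaries (mean/SD of t, mean p, 10/50/90 percentiles)
mirror the rectangle plots of the simulation experiments; the multilevel
regression of t statistics on threshold x node class quantifies whether an
artifact grows with density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ttest_patient_minus_control",
    "nodewise_t_tests",
    "covaried_group_test",
    "covaried_group_t_batch",
    "aggregate_replications",
    "density_nodetype_regression",
    "module_degree_regression",
    "RegressionResult",
]

RESULT_COLUMNS = [
    "replication_id", "node", "node_class", "strategy", "cutoff",
    "t_statistic", "p_value", "df",
]


def ttest_patient_minus_control(
    patients: np.ndarray, controls: np.ndarray, equal_var: bool = False
):
    """Vectorized two-sample t over the leading (subject) axis.

    Returns ``(t, p, df)`` arrays with the patient-minus-control sign
    convention. Zero pooled variance yields t=0, p=1 (flagged upstream).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(patients, controls, axis=0, equal_var=equal_var)
        t = np.asarray(res.statistic)
        p = np.asarray(res.pvalue)
        df = np.asarray(res.df)
    zero_var = ~np.isfinite(t)
    if np.any(zero_var):
        t = np.where(zero_var, 0.0, t)
        p = np.where(zero_var, 1.0, p)
    return t, p, df


def nodewise_t_tests(
    metric_table: pd.DataFrame,
    equal_var: bool = False,
    value_col: str = "value",
) -> pd.DataFrame:
    """Two-sample t tests per (replication, node, strategy, cutoff) cell.

    ``metric_table`` is tidy: one row per subject x node with columns
    ``group`` (patient/control), ``node``, ``value`` and optional keys
    ``replication_id``, ``node_class``, ``strategy``, ``cutoff``.
    """
    keys = [
        k for k in ("replication_id", "node", "node_class", "strategy", "cutoff")
        if k in metric_table.columns
    ]
    rows = []
    for key_vals, cell in metric_table.groupby(keys, observed=True, sort=True):
        key_vals = key_vals if isinstance(key_vals, tuple) else (key_vals,)
        pat = cell.loc[cell.group == "patient", value_col].to_numpy()
        con = cell.loc[cell.group == "control", value_col].to_numpy()
        if len(pat) < 2 or len(con) < 2:
            raise ValueError(f"cell {dict(zip(keys, key_vals))} lacks one group")
        t, p, df = ttest_patient_minus_control(pat, con, equal_var=equal_var)
        rows.append(dict(zip(keys, key_vals)) | {
            "t_statistic": float(t), "p_value": float(p), "df": float(df),
        })
    return pd.DataFrame(rows)


def covaried_group_test(
    values: np.ndarray, density: np.ndarray, groups: np.ndarray, collinear_tol: float = 1e-12
) -> float:
    """t statistic for the group effect adjusting for per-subject density.

    Ordinary least squares of the nodal metric on an intercept, a
    patient indicator and per-subject graph density; returns the t of the
    group coefficient (patient minus control). With (near-)constant density
    — e.g. metrics from proportionally thresholded graphs — the covariate
    is dropped with a collinearity warning and the plain two-sample t is
    returned.
    """
    values = np.asarray(values, dtype=float)
    density = np.asarray(density, dtype=float)
    is_patient = (np.asarray(groups) == "patient").astype(float)
    if np.ptp(density) <= collinear_tol:
        warnings.warn(
            "per-subject density is constant; dropping the covariate "
            "(proportional-threshold input?)",
            stacklevel=2,
        )
        t, _, _ = ttest_patient_minus_control(
            values[is_patient == 1], values[is_patient == 0], equal_var=True
        )
        return float(t)
    return float(covaried_group_t_batch(values[:, None], density[:, None], is_patient)[0])


def covaried_group_t_batch(
    values: np.ndarray, density: np.ndarray, is_patient: np.ndarray
) -> np.ndarray:
    """Vectorized OLS group-coefficient t over trailing columns.

    ``values``/``density``: (S, K); ``is_patient``: (S,). Solves the
    3-parameter normal equations per column; validated against statsmodels
    OLS in the test suite.
    """
    s, k = values.shape
    g = np.broadcast_to(is_patient[:, None], (s, k)).astype(float)
    ones = np.ones((s, k))
    t_out = np.empty(k)
    for j in range(k):
        x = np.column_stack([ones[:, j], g[:, j], density[:, j]])
        xtx = x.T @ x
        xty = x.T @ values[:, j]
        try:
            beta = np.linalg.solve(xtx, xty)
            cov = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            t_out[j] = np.nan
            continue
        resid = values[:, j] - x @ beta
        dof = s - 3
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * cov[1, 1])
        t_out[j] = beta[1] / se if se > 0 else 0.0
    return t_out


def aggregate_replications(table: pd.DataFrame) -> pd.DataFrame:
    """Replication-aggregated summaries per node class (and cutoff).

    Pools the nodes of a class within each replication, then summarizes t
    across replications: mean, SD, mean p and the 10th/50th/90th
    percentiles that bound the rectangle plots.
    """
    if "replication_id" in table.columns and table.replication_id.nunique() < 2:
        raise ValueError("aggregation needs at least 2 replications")
    keys = [k for k in ("node_class", "strategy", "cutoff") if k in table.columns]

    def _summary(cell: pd.DataFrame) -> pd.Series:
        t = cell.t_statistic.to_numpy()
        q10, q50, q90 = np.percentile(t, [10, 50, 90])
        return pd.Series({
            "mean_t": t.mean(),
            "sd_t": t.std(ddof=1),
            "mean_p": cell.p_value.mean(),
            "t_p10": q10, "t_p50": q50, "t_p90": q90,
            "n_tests": len(cell),
        })

    out = table.groupby(keys, observed=True).apply(_summary, include_groups=False).reset_index()
    return out


def _fit_mixed(model):
    """REML fit with an optimizer fallback for near-singular toy inputs."""
    try:
        return model.fit(reml=True)
    except np.linalg.LinAlgError:
        return model.fit(reml=True, method="powell")


@dataclass(frozen=True)
class RegressionResult:
    slopes: pd.DataFrame          # per node class: B, ci_low, ci_high, t, p
    interaction_chi2: float
    interaction_df: int
    interaction_p: float
    model: object = None


def density_nodetype_regression(table: pd.DataFrame) -> RegressionResult:
    """Multilevel regression of group-difference t on cutoff x node class.

    Random intercept per replication sample; fixed effects are a per-class
    intercept and a per-class slope in the cutoff (density on the 0-1
    proportion scale). The interaction test is a Wald chi-square for
    equality of the class slopes.
    """
    import statsmodels.formula.api as smf

    if table.cutoff.nunique() < 3:
        raise ValueError(
            "need >= 3 cutoffs for a slope regression; use nodewise summaries instead"
        )
    if table.node_class.nunique() < 2:
        raise ValueError("need >= 2 node classes")
    df = table[["replication_id", "node_class", "cutoff", "t_statistic"]].copy()
    model = smf.mixedlm(
        "t_statistic ~ 0 + C(node_class) + C(node_class):cutoff",
        df,
        groups=df["replication_id"],
    )
    fit = _fit_mixed(model)
    classes = sorted(df.node_class.unique())
    slope_names = [f"C(node_class)[{c}]:cutoff" for c in classes]
    params = fit.params
    se = fit.bse
    rows = []
    for c, name in zip(classes, slope_names):
        b = params[name]
        s = se[name]
        z = b / s
        rows.append({
            "node_class": c, "B": b,
            "ci_low": b - 1.96 * s, "ci_high": b + 1.96 * s,
            "t": z, "p": 2 * sps.norm.sf(abs(z)),
        })
    # Wald test: all slopes equal (k-1 contrasts; the extra column is the
    # random-intercept variance parameter, which the restriction ignores)
    k = len(slope_names)
    contrast = np.zeros((k - 1, len(fit.model.exog_names) + 1))
    for r in range(k - 1):
        contrast[r, fit.model.exog_names.index(slope_names[0])] = 1.0
        contrast[r, fit.model.exog_names.index(slope_names[r + 1])] = -1.0
    wald = fit.wald_test(contrast, scalar=True)
    return RegressionResult(
        slopes=pd.DataFrame(rows),
        interaction_chi2=float(wald.statistic),
        interaction_df=k - 1,
        interaction_p=float(wald.pvalue),
        model=fit,
    )


def module_degree_regression(table: pd.DataFrame, target_module: str = "DMN") -> RegressionResult:
    """Multilevel regression of z-scored module degree on group x module.

    ``table`` is tidy with columns replication_id, subject, module, density,
    group and ``z`` (the z-scored within- or between-module degree,
    standardized within module x density). Fits a per-module intercept, a
    per-module patient effect and density, with a random intercept per
    replication; the ``target_module`` patient coefficient is the headline
    effect (how far, in module-standardized degree units, patients sit
    above controls).
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    df["is_patient"] = (df.group == "patient").astype(float)
    # zero-variance strata (e.g. tiny modules with no within-module edges at
    # sparse densities) carry NaN z-scores; they are excluded here, having
    # been flagged at z-scoring time
    df = df.dropna(subset=["z"]).reset_index(drop=True)
    model = smf.mixedlm(
        "z ~ 0 + C(module) + C(module):is_patient + density",
        df,
        groups=df["replication_id"],
    )
    fit = _fit_mixed(model)
    rows = []
    for m in sorted(df.module.unique()):
        name = f"C(module)[{m}]:is_patient"
        b, s = fit.params[name], fit.bse[name]
        z = b / s
        rows.append({
            "node_class": m, "B": b,
            "ci_low": b - 1.96 * s, "ci_high": b + 1.96 * s,
            "t": z, "p": 2 * sps.norm.sf(abs(z)),
        })
    slopes = pd.DataFrame(rows)
    row = slopes.loc[slopes.node_class == target_module]
    if row.empty:
        raise ValueError(f"module {target_module!r} not present in table")
    return RegressionResult(
        slopes=slopes,
        interaction_chi2=float("nan"),
        interaction_df=0,
        interaction_p=float("nan"),
        model=fit,
    )
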