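"""Regional amyloid-thickness statistics.

Per cortical parcel, three associations are computed across subjects:
a simple linear regression of amyloid SUVR on cortical thickness (Pearson
rho), a multivariable OLS model

    SUVR ~ thickness + education + age + sex + MoCA,

and the partial correlation of SUVR with thickness after removing age,
education, sex and MoCA from both.  Multiple comparisons across parcels
are handled with the Benjamini-Hochberg step-up procedure at a configurable
false-discovery rate (q = 0.1 in the reference analysis), and a helper maps
a p-value threshold back to the equivalent partial-correlation magnitude.
Group-level summaries stratify subjects by MoCA severity bins
(0-10 / 11-19 / 20-30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .phantom import MOCA_BINS, CohortTable

__all__ = [
    "SimpleRegressionResult",
    "RegressionResult",
    "FDRResult",
    "simple_regression",
    "multivariable_regression",
    "partial_correlation",
    "bh_fdr",
    "r_threshold_from_p",
    "p_from_r",
    "group_summaries",
    "compare_groups",
    "normalize_parcel_trajectories",
    "significance_stars",
]

COVARIATES = ("age", "education", "sex", "moca")
PREDICTORS = ("thickness", "education", "age", "sex", "moca")


def significance_stars(p: float) -> str:
    """Star banding for report tables: * <0.05, ** <0.01, *** <0.001, ...."""
    for stars, cut in (("*****", 1e-5), ("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


@dataclass
class SimpleRegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    slope_ci: tuple[float, float]


def simple_regression(thickness, amyloid, ci_level: float = 0.95) -> SimpleRegressionResult:
    """OLS of amyloid on thickness with Pearson rho and its two-sided p.

    The p-value comes from the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(thickness, dtype=float)
    y = np.asarray(amyloid, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = sps.linregress(x, y)
    n = x.size
    tcrit = sps.t.ppf(0.5 + ci_level / 2, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return SimpleRegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
        slope_ci=ci,
    )


@dataclass
class RegressionResult:
    """Multivariable OLS result shaped like a per-parcel report row."""

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    bse: pd.Series
    r: float  # overall correlation coefficient, sqrt(R^2)
    n: int
    ci_level: float

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.params,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
                "p": self.pvalues,
            }
        )
        df["stars"] = [significance_stars(p) for p in df["p"]]
        return df


def _design(cohort: CohortTable, parcel: int) -> tuple[np.ndarray, pd.DataFrame]:
    y = cohort.suvr(parcel)
    X = pd.DataFrame(
        {
            "thickness": cohort.thickness(parcel),
            "education": cohort.df["education"].to_numpy(dtype=float),
            "age": cohort.df["age"].to_numpy(dtype=float),
            "sex": cohort.df["sex"].to_numpy(dtype=float),
            "moca": cohort.df["moca"].to_numpy(dtype=float),
        }
    )
    return y, X


def multivariable_regression(
    cohort: CohortTable, parcel: int, ci_level: float = 0.95
) -> RegressionResult:
    """Fit SUVR ~ thickness + education + age + sex + MoCA for one parcel.

    Raises on rank deficiency, naming an offending column.  Confidence
    intervals default to 95% but the level is configurable.
    """
    y, X = _design(cohort, parcel)
    n = len(y)
    if n <= 6:
        raise ValueError("need n > 6 subjects for the multivariable model")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        for col in X.columns:
            reduced = design.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"design matrix rank deficient: column {col!r}")
        raise ValueError("design matrix rank deficient")
    fit = sm.OLS(y, design).fit()
    keep = list(X.columns)
    ci = fit.conf_int(alpha=1 - ci_level).loc[keep]
    return RegressionResult(
        params=fit.params.loc[keep],
        conf_int=ci,
        pvalues=fit.pvalues.loc[keep],
        bse=fit.bse.loc[keep],
        r=float(np.sqrt(max(fit.rsquared, 0.0))),
        n=n,
        ci_level=ci_level,
    )


def partial_correlation(
    cohort: CohortTable, parcel: int, covariates: tuple[str, ...] = COVARIATES
) -> tuple[float, float]:
    """Partial correlation of SUVR with thickness given the covariates.

    Both variables are residualized on the covariates (with intercept); the
    Pearson correlation of the residuals is returned with a two-sided p from
    the t distribution with n - 2 - k degrees of freedom, k = len(covariates).
    """
    y = cohort.suvr(parcel)
    x = cohort.thickness(parcel)
    n = len(y)
    k = len(covariates)
    if n <= k + 2:
        raise ValueError("need n > covariates + 2")
    if k == 0:
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack(
            [np.ones(n)] + [cohort.df[c].to_numpy(dtype=float) for c in covariates]
        )
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0, atol=1e-10 * max(1.0, np.abs(x).max())) or np.allclose(
        ry, 0, atol=1e-10 * max(1.0, np.abs(y).max())
    ):
        # one variable is (numerically) an exact function of the covariates:
        # nothing is left to correlate
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


@dataclass
class FDRResult:
    """Benjamini-Hochberg step-up outcome for one family of tests."""

    q: float
    pvalues: np.ndarray  # original order
    threshold: float  # largest p(k) passing; 0 if none
    reject: np.ndarray  # original order
    m: int

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def bh_fdr(pvalues, q: float = 0.1) -> FDRResult:
    """Benjamini-Hochberg step-up: reject all p <= p(k*) where k* is the
    largest k with p(k) <= k q / m (sorted ascending)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        threshold = 0.0
    else:
        threshold = float(sorted_p[passing[-1]])
    reject = p <= threshold
    return FDRResult(q=q, pvalues=p, threshold=threshold, reject=reject, m=m)


def r_threshold_from_p(p_threshold: float, n: int, k_covariates: int = 0) -> float:
    """Correlation magnitude equivalent to a two-sided p threshold.

    Inverts r = t / sqrt(t^2 + df) at the t-quantile for the threshold,
    df = n - 2 - k.
    """
    df = n - 2 - k_covariates
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    t = sps.t.ppf(1 - p_threshold / 2, df)
    return float(t / np.sqrt(t**2 + df))


def p_from_r(r: float, n: int, k_covariates: int = 0) -> float:
    """Two-sided p of a (partial) correlation under the t transform."""
    df = n - 2 - k_covariates
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    t = abs(r) * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    return float(2 * sps.t.sf(t, df))


def group_summaries(cohort: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-MoCA-group mean and SD of global cortical thickness and SUVR.

    Returns (global summary over cortical parcels, per-parcel group means).
    Single-subject groups report SD 0 with ``sd_undefined`` flagged; an
    empty group raises rather than being silently dropped.
    """
    labels = cohort.parcel_labels
    if not labels:
        raise ValueError("cohort has no parcel columns")
    thick = cohort.df[[f"thickness_{l}" for l in labels if f"thickness_{l}" in cohort.df]]
    suvr_cols = [f"suvr_{l}" for l in labels if f"thickness_{l}" in cohort.df.columns]
    suvr = cohort.df[suvr_cols]
    global_thick = thick.mean(axis=1)
    global_suvr = suvr.mean(axis=1)

    rows = []
    per_parcel = []
    for group in MOCA_BINS:
        sel = (cohort.df["moca_group"] == group).to_numpy()
        ns = int(sel.sum())
        if ns == 0:
            raise ValueError(f"MoCA group {group} is empty")
        for measure, values in (
            ("cortical_thickness_mm", global_thick[sel]),
            ("amyloid_suvr", global_suvr[sel]),
        ):
            sd = float(values.std(ddof=1)) if ns > 1 else 0.0
            rows.append(
                {
                    "moca_group": group,
                    "measure": measure,
                    "mean": float(values.mean()),
                    "sd": sd,
                    "n": ns,
                    "sd_undefined": ns == 1,
                }
            )
        for lab in labels:
            if f"thickness_{lab}" not in cohort.df.columns:
                continue
            per_parcel.append(
                {
                    "moca_group": group,
                    "label": lab,
                    "thickness_mean": float(cohort.df.loc[sel, f"thickness_{lab}"].mean()),
                    "thickness_sd": float(cohort.df.loc[sel, f"thickness_{lab}"].std(ddof=1)) if ns > 1 else 0.0,
                    "suvr_mean": float(cohort.df.loc[sel, f"suvr_{lab}"].mean()),
                    "suvr_sd": float(cohort.df.loc[sel, f"suvr_{lab}"].std(ddof=1)) if ns > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(per_parcel)


def compare_groups(
    cohort: CohortTable,
    variable: str,
    kind: str = "continuous",
    group_col: str = "moca_group",
    groups: tuple[str, str] = ("0-10", "20-30"),
) -> tuple[float, float]:
    """Two-group comparison: independent t-test or Fisher's exact test.

    Continuous variables use a two-sided independent-sample t-test;
    categorical (0/1) variables use Fisher's exact test on the 2x2 table.
    """
    a = cohort.df.loc[cohort.df[group_col] == groups[0], variable]
    b = cohort.df.loc[cohort.df[group_col] == groups[1], variable]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group among {groups}")
    if kind == "continuous":
        stat, p = sps.ttest_ind(a, b)
        return float(stat), float(p)
    if kind == "categorical":
        vals = sorted(set(cohort.df[variable].unique()))
        if len(vals) != 2:
            raise ValueError("categorical comparison requires a binary variable")
        table = [
            [int((a == vals[0]).sum()), int((a == vals[1]).sum())],
            [int((b == vals[0]).sum()), int((b == vals[1]).sum())],
        ]
        odds, p = sps.fisher_exact(table)
        return float(odds), float(p)
    raise ValueError("kind must be 'continuous' or 'categorical'")


def normalize_parcel_trajectories(per_parcel_group_means: pd.DataFrame) -> pd.DataFrame:
    """Normalize each parcel's group trajectory to the high-MoCA anchor.

    Input: per-parcel group means with columns (moca_group, label,
    thickness_mean, suvr_mean) covering all three groups.  Output per
    parcel-group row: suvr_mean divided by the high-MoCA (20-30) group's
    suvr_mean and thickness_mean minus the high-MoCA thickness, so the
    high-MoCA point maps to (1.0, 0.0).  Each parcel is dichotomized as
    'thinner' when the middle-MoCA thickness is <= the high-MoCA thickness
    (ties count as thinner), else 'thicker'.
    """
    df = per_parcel_group_means
    out_rows = []
    for label, sub in df.groupby("label"):
        got = set(sub["moca_group"])
        if got != set(MOCA_BINS):
            raise ValueError(f"parcel {label}: need all three group means, got {sorted(got)}")
        anchor = sub[sub["moca_group"] == "20-30"].iloc[0]
        if anchor["suvr_mean"] == 0:
            raise ValueError(f"parcel {label}: high-MoCA group SUVR is zero")
        middle = sub[sub["moca_group"] == "11-19"].iloc[0]
        category = (
            "thinner" if middle["thickness_mean"] <= anchor["thickness_mean"] else "thicker"
        )
        for _, row in sub.iterrows():
            out_rows.append(
                {
                    "label": label,
                    "moca_group": row["moca_group"],
                    "norm_suvr": row["suvr_mean"] / anchor["suvr_mean"],
                    "delta_thickness": row["thickness_mean"] - anchor["thickness_mean"],
                    "category": category,
                }
            )
    return pd.DataFrame(out_rows)
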