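"""Inference on coloration indices: assumptions, Box-Cox, ANOVA, Tukey.

The chain mirrors the standard factorial workflow: Shapiro-Wilk normality
checks on groups and model residuals, variance-homogeneity checks across the
four groups, a Box-Cox power transform applied when residual normality
fails, a two-way ANOVA (colony origin x incubation temperature, with
interaction, Type II sums of squares) and Tukey HSD post-hoc contrasts over
all six group pairs.

Type II sums of squares are used because the design is near-balanced (one
specimen can drop out to saturation); under exact balance they coincide
with Type I, and they are invariant to factor order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .coloration_index import group_label, validate_metadata

__all__ = [
    "AssumptionReport",
    "BoxCoxResult",
    "AnovaReport",
    "InferenceReport",
    "check_assumptions",
    "boxcox_transform",
    "two_way_anova",
    "tukey_hsd",
    "run_inference",
]


@dataclass
class AssumptionReport:
    shapiro_residuals_p: float
    shapiro_group_p: dict[str, float]
    variance_max_ratio: float
    variance_p: float
    method: str = "f"  # pairwise F-ratio tests; "levene" also available

    def to_dict(self) -> dict:
        return {
            "shapiro_residuals_p": self.shapiro_residuals_p,
            "shapiro_group_p": self.shapiro_group_p,
            "variance_max_ratio": self.variance_max_ratio,
            "variance_p": self.variance_p,
            "variance_method": self.method,
        }


@dataclass
class BoxCoxResult:
    lmbda: float
    transformed: np.ndarray
    log_likelihood: float


@dataclass
class AnovaReport:
    terms: pd.DataFrame  # index: term; columns: sum_sq, df, F, p
    residual_df: float
    tukey: pd.DataFrame | None = None
    transform: str = "none"
    boxcox_lambda: float | None = None

    @property
    def p_origin(self) -> float:
        return float(self.terms.loc["colony", "p"])

    @property
    def p_temperature(self) -> float:
        return float(self.terms.loc["temperature", "p"])

    @property
    def p_interaction(self) -> float:
        return float(self.terms.loc["colony:temperature", "p"])

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "boxcox_lambda": self.boxcox_lambda,
            "residual_df": self.residual_df,
            "anova": self.terms.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "tukey": None
            if self.tukey is None
            else self.tukey.to_dict(orient="records"),
        }


@dataclass
class InferenceReport:
    assumptions: AssumptionReport
    anova: AnovaReport
    alpha: float
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "assumptions": self.assumptions.to_dict(),
            **self.anova.to_dict(),
            "log": self.log,
        }


def _group_arrays(values: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {str(g): values[groups == g] for g in pd.unique(groups)}


def check_assumptions(
    values: np.ndarray, groups: np.ndarray, method: str = "f"
) -> AssumptionReport:
    """Shapiro-Wilk normality and variance-homogeneity checks.

    Normality is tested per group and on the pooled residuals (value minus
    group mean).  Variance homogeneity uses pairwise two-sided F-ratio tests
    across all group pairs, reporting the largest variance ratio and the
    smallest (i.e. most extreme) pairwise p-value; ``method="levene"``
    substitutes a single Levene test.
    """
    by_group = _group_arrays(values, groups)
    for g, x in by_group.items():
        if x.size < 3:
            raise ValueError(f"group {g!r} has n={x.size} < 3")
    residuals = np.concatenate([x - x.mean() for x in by_group.values()])
    shapiro_group = {g: float(st.shapiro(x).pvalue) for g, x in by_group.items()}
    shapiro_resid = float(st.shapiro(residuals).pvalue)

    if method == "levene":
        stat = st.levene(*by_group.values())
        max_ratio = _max_variance_ratio(by_group)
        var_p = float(stat.pvalue)
    elif method == "f":
        max_ratio, var_p = _pairwise_f_tests(by_group)
    else:
        raise ValueError("method must be 'f' or 'levene'")
    return AssumptionReport(
        shapiro_residuals_p=shapiro_resid,
        shapiro_group_p=shapiro_group,
        variance_max_ratio=max_ratio,
        variance_p=var_p,
        method=method,
    )


def _max_variance_ratio(by_group: dict[str, np.ndarray]) -> float:
    variances = {g: x.var(ddof=1) for g, x in by_group.items()}
    ratios = [
        max(variances[a], variances[b]) / min(variances[a], variances[b])
        if min(variances[a], variances[b]) > 0
        else 1.0
        for a, b in combinations(variances, 2)
    ]
    return float(max(ratios)) if ratios else 1.0


def _pairwise_f_tests(by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Two-sided variance-ratio F tests for every group pair.

    Returns (largest variance ratio, smallest two-sided p-value).  If all
    samples are identical the ratio is exactly 1 and p is 1.
    """
    max_ratio, min_p = 1.0, 1.0
    for a, b in combinations(by_group, 2):
        xa, xb = by_group[a], by_group[b]
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        if va >= vb:
            num, den, dfn, dfd = va, vb, xa.size - 1, xb.size - 1
        else:
            num, den, dfn, dfd = vb, va, xb.size - 1, xa.size - 1
        ratio = num / den if den > 0 else 1.0
        p = min(1.0, 2.0 * float(st.f.sf(ratio, dfn, dfd))) if den > 0 else 1.0
        max_ratio = max(max_ratio, ratio)
        min_p = min(min_p, p)
    return float(max_ratio), float(min_p)


#: Search interval for the Box-Cox exponent.  Outside roughly +/-5 the
#: power transform of data far from 1 collapses to a numerical constant
#: (catastrophic cancellation), so the profile-likelihood search is bounded.
BOXCOX_LAMBDA_BOUNDS = (-5.0, 5.0)


def boxcox_transform(values: np.ndarray, lmbda: float | None = None) -> BoxCoxResult:
    """Box-Cox power transform, lambda by profile maximum likelihood.

    transformed = (x**lambda - 1)/lambda for lambda != 0, log(x) at 0.
    The likelihood is maximized over ``BOXCOX_LAMBDA_BOUNDS`` by bounded
    scalar optimization; a fixed ``lmbda`` bypasses estimation.
    """
    from scipy.optimize import minimize_scalar

    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("Box-Cox requires a 1-D sample of size >= 2")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda is None:
        opt = minimize_scalar(
            lambda lam: -st.boxcox_llf(lam, x),
            bounds=BOXCOX_LAMBDA_BOUNDS,
            method="bounded",
        )
        lam = float(opt.x)
        transformed = st.boxcox(x, lmbda=lam)
    else:
        lam = float(lmbda)
        transformed = st.boxcox(x, lmbda=lam)
    return BoxCoxResult(
        lmbda=float(lam),
        transformed=np.asarray(transformed, dtype=float),
        log_likelihood=float(st.boxcox_llf(lam, x)),
    )


def two_way_anova(
    values: np.ndarray, colony: np.ndarray, temperature: np.ndarray
) -> AnovaReport:
    """Two-way factorial ANOVA with interaction, Type II sums of squares."""
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "colony": np.asarray(colony).astype(str),
            "temperature": np.asarray(temperature).astype(str),
        }
    )
    cells = df.groupby(["colony", "temperature"]).size()
    if len(cells) != len(df["colony"].unique()) * len(df["temperature"].unique()):
        raise ValueError("empty factorial cell; a full factorial design is required")
    if (cells < 2).any():
        raise ValueError("each factorial cell needs n >= 2")
    model = smf.ols("value ~ C(colony) * C(temperature)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(colony)": "colony",
        "C(temperature)": "temperature",
        "C(colony):C(temperature)": "colony:temperature",
        "Residual": "residual",
    }
    table = table.rename(index=rename).rename(
        columns={"PR(>F)": "p"}
    )
    residual_df = float(table.loc["residual", "df"])
    terms = table.drop(index="residual")[["sum_sq", "df", "F", "p"]]
    return AnovaReport(terms=terms, residual_df=residual_df)


def tukey_hsd(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all pairwise group contrasts.

    Returns columns group1, group2, estimate (mean difference), p_adj,
    lower, upper, reject; 4 groups give the full 6 contrasts.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2:
        raise ValueError("Tukey HSD requires at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"group(s) with n < 2: {small}")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "estimate": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "lower": np.asarray(res.confint[:, 0], dtype=float),
            "upper": np.asarray(res.confint[:, 1], dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )


def run_inference(
    indices: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    transform: str = "auto",
) -> InferenceReport:
    """Full inferential chain on an index table.

    Steps: assumption checks; Box-Cox applied when the Shapiro test on the
    untransformed-model residuals rejects at ``alpha`` (``transform="auto"``,
    the default; "always"/"never" force the branch); two-way ANOVA on the
    analysis scale; Tukey HSD on the same scale.
    """
    if transform not in ("auto", "always", "never"):
        raise ValueError("transform must be 'auto', 'always' or 'never'")
    meta = validate_metadata(meta)
    merged = indices.merge(meta, on="specimen_id", how="left", validate="1:1")
    orphans = merged.loc[merged["colony"].isna(), "specimen_id"].tolist()
    if orphans:
        raise ValueError(f"specimen(s) without metadata: {orphans[:5]}")
    values = merged["index"].to_numpy(dtype=float)
    labels = np.array(
        [group_label(c, t) for c, t in zip(merged["colony"], merged["temperature"])]
    )
    log: list[str] = []
    assumptions = check_assumptions(values, labels)
    log.append(
        f"Shapiro-Wilk on residuals: p = {assumptions.shapiro_residuals_p:.4g}"
    )

    apply_boxcox = transform == "always" or (
        transform == "auto" and assumptions.shapiro_residuals_p < alpha
    )
    lam: float | None = None
    if apply_boxcox:
        bc = boxcox_transform(values)
        analysis_values = bc.transformed
        lam = bc.lmbda
        log.append(f"Box-Cox applied, lambda = {lam:.4f}")
    else:
        analysis_values = values
        log.append("transform: none (residuals compatible with normality)")

    report = two_way_anova(
        analysis_values,
        merged["colony"].to_numpy(),
        merged["temperature"].to_numpy(),
    )
    report.tukey = tukey_hsd(analysis_values, labels, alpha=alpha)
    report.transform = "boxcox" if apply_boxcox else "none"
    report.boxcox_lambda = lam
    log.append(
        "ANOVA p-values: origin {:.4g}, temperature {:.4g}, interaction {:.4g}".format(
            report.p_origin, report.p_temperature, report.p_interaction
        )
    )
    return InferenceReport(assumptions=assumptions, anova=report, alpha=alpha, log=log)
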