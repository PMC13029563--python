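"""Method-agreement statistics.

Agreement between a candidate assay and a reference is quantified by
Deming regression (errors in both variables), Bland–Altman analysis of
pairwise differences, and the mean predictive percent error (MPPE,
signed) and mean absolute percentage error (MAPE). Heterogeneity of
calibration slopes across hematocrit levels is tested by ANCOVA with a
full covariate × group interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "PairedMeasurements",
    "DemingResult",
    "BlandAltmanResult",
    "MethodComparisonResult",
    "AncovaResult",
    "deming_regression",
    "bland_altman",
    "predictive_errors",
    "ancova_slopes",
    "compare_methods",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Reference/test value pairs for one agreement analysis."""

    reference: np.ndarray
    test: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise ValueError("reference and test must be 1-D arrays of equal length")
        if len(ref) < 3:
            raise ValueError("need at least 3 pairs")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)

    def __len__(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


def _deming_point(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    """Closed-form Deming estimate; lam = ratio of y- to x-error variance."""
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    syy = np.sum((y - ybar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    if sxy == 0:
        # No covariance: vertical/horizontal degenerate; fall back to OLS slope 0.
        return 0.0, float(ybar)
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
        2 * sxy
    )
    return float(slope), float(ybar - slope * xbar)


def deming_regression(
    pairs: PairedMeasurements, lam: float = 1.0, alpha: float = 0.05
) -> DemingResult:
    """Errors-in-both-variables line with jackknife confidence intervals.

    ``lam`` is the ratio of test- to reference-measurement error
    variances (1 = orthogonal regression, the default when replicate
    error variances are unknown). CIs use leave-one-out jackknife
    standard errors with t(n−2) quantiles.
    """
    x, y = pairs.reference, pairs.test
    if np.ptp(x) == 0:
        raise ValueError("all reference values identical: slope undefined")
    n = len(x)
    slope, intercept = _deming_point(x, y, lam)

    idx = np.arange(n)
    loo = np.array(
        [_deming_point(x[idx != i], y[idx != i], lam) for i in range(n)]
    )
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    tq = st.t.ppf(1 - alpha / 2, df=n - 2)
    return DemingResult(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope - tq * se[0], slope + tq * se[0]),
        intercept_ci=(intercept - tq * se[1], intercept + tq * se[1]),
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa: tuple[float, float]
    bias_ci: tuple[float, float]
    sd: float
    mode: str
    differences: np.ndarray

    def __post_init__(self) -> None:
        if not self.loa[0] <= self.bias <= self.loa[1]:
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(
    pairs: PairedMeasurements, mode: str = "percent_of_mean"
) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of pairwise differences.

    In ``percent_of_mean`` mode (default, matching relative acceptance
    thresholds) each difference is expressed as percent of the pairwise
    mean. LoA = bias ± 1.96·SD (n−1); the bias CI uses t(n−1)·SD/√n.
    """
    ref, tst = pairs.reference, pairs.test
    if mode == "absolute":
        d = tst - ref
    elif mode == "percent_of_mean":
        m = (tst + ref) / 2.0
        if np.any(m == 0):
            raise ValueError("zero pairwise mean: percent difference undefined")
        d = 100.0 * (tst - ref) / m
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = st.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        bias_ci=(bias - half, bias + half),
        sd=sd,
        mode=mode,
        differences=d,
    )


def predictive_errors(
    pairs: PairedMeasurements | Sequence[float], test: Sequence[float] | None = None
) -> tuple[float, float]:
    """(MPPE, MAPE): mean signed and mean absolute percent error vs reference.

    Accepts a :class:`PairedMeasurements` or two plain arrays; unlike the
    regression-based statistics this is defined for any nonempty pairing.
    """
    if isinstance(pairs, PairedMeasurements):
        ref, tst = pairs.reference, pairs.test
    else:
        ref = np.asarray(pairs, dtype=float)
        tst = np.asarray(test, dtype=float)
        if ref.shape != tst.shape or ref.size == 0:
            raise ValueError("reference and test must be equal-length nonempty arrays")
    if np.any(ref == 0):
        raise ValueError("zero reference value: percent error undefined")
    rel = 100.0 * (tst - ref) / ref
    return float(rel.mean()), float(np.abs(rel).mean())


@dataclass(frozen=True)
class MethodComparisonResult:
    """Bundle of all agreement statistics for one method pair."""

    deming: DemingResult
    bland_altman: BlandAltmanResult
    mppe: float
    mape: float

    def to_dict(self) -> dict:
        return {
            "deming": {
                "slope": self.deming.slope,
                "intercept": self.deming.intercept,
                "slope_ci": list(self.deming.slope_ci),
                "intercept_ci": list(self.deming.intercept_ci),
            },
            "bland_altman": {
                "bias": self.bland_altman.bias,
                "loa": list(self.bland_altman.loa),
                "bias_ci": list(self.bland_altman.bias_ci),
                "mode": self.bland_altman.mode,
            },
            "mppe": self.mppe,
            "mape": self.mape,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def compare_methods(
    reference: Sequence[float],
    test: Sequence[float],
    unit: str = "",
    ba_mode: str = "percent_of_mean",
    lam: float = 1.0,
) -> MethodComparisonResult:
    """Run the full agreement battery on one method pair."""
    pairs = PairedMeasurements(np.asarray(reference), np.asarray(test), unit)
    mppe, mape = predictive_errors(pairs)
    return MethodComparisonResult(
        deming=deming_regression(pairs, lam=lam),
        bland_altman=bland_altman(pairs, mode=ba_mode),
        mppe=mppe,
        mape=mape,
    )


def plot_comparison(
    pairs: PairedMeasurements, result: MethodComparisonResult, path=None
):
    """Two-panel agreement figure: Deming scatter and Bland–Altman plot.

    The Deming panel shows the fitted line and identity; the
    Bland–Altman panel shows bias, 95% limits of agreement, and ±20%
    deviation guide lines (the relative acceptance threshold).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    x, y = pairs.reference, pairs.test
    ax1.scatter(x, y, s=18, color="#333")
    span = np.array([x.min(), x.max()])
    d = result.deming
    ax1.plot(span, d.slope * span + d.intercept, "k-", label="Deming fit")
    ax1.plot(span, span, "r:", lw=1, label="identity")
    ax1.set_xlabel(f"reference {pairs.unit}".strip())
    ax1.set_ylabel(f"test {pairs.unit}".strip())
    ax1.legend(frameon=False)

    ba = result.bland_altman
    means = (x + y) / 2
    ax2.scatter(means, ba.differences, s=18, color="#333")
    ax2.axhline(ba.bias, color="k")
    for limit in ba.loa:
        ax2.axhline(limit, color="k", ls="--", lw=0.8)
    if ba.mode == "percent_of_mean":
        for guide in (20.0, -20.0):
            ax2.axhline(guide, color="r", lw=1)
        ax2.set_ylabel("difference (% of pair mean)")
    else:
        ax2.set_ylabel("difference")
    ax2.set_xlabel("pair mean")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass(frozen=True)
class AncovaResult:
    """Type III ANCOVA of response ~ covariate × group."""

    f_covariate: float
    f_factor: float
    f_interaction: float
    df_covariate: tuple[int, int]
    df_factor: tuple[int, int]
    df_interaction: tuple[int, int]
    p_covariate: float
    p_factor: float
    p_interaction: float
    slope_contrasts: pd.DataFrame  # per-level slope difference vs reference

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if k != "slope_contrasts"
        }
        d["slope_contrasts"] = self.slope_contrasts.to_dict(orient="records")
        return d


def _effect_f(table: pd.DataFrame, name: str, resid_ss: float, resid_df: float):
    ss = float(table.loc[name, "sum_sq"])
    df1 = int(table.loc[name, "df"])
    if resid_ss <= 1e-10 * max(ss, 1.0):
        # Degenerate noise-free designs: a zero-SS effect is reported as
        # F = 0 (no evidence of the effect) rather than 0/0.
        if ss <= 1e-10:
            return 0.0, 1.0, df1
        return float("inf"), 0.0, df1
    f = (ss / df1) / (resid_ss / resid_df)
    p = float(st.f.sf(f, df1, resid_df))
    return float(f), p, df1


def ancova_slopes(
    table: pd.DataFrame,
    reference_group,
    response: str = "response",
    covariate: str = "covariate",
    group: str = "group",
) -> AncovaResult:
    """Test slope/intercept heterogeneity across groups by ANCOVA.

    Fits the full-interaction model response ~ covariate × group.
    Omnibus F tests (covariate, group, interaction) use Type III sums of
    squares with sum-to-zero contrasts; per-group slope differences from
    ``reference_group`` are t-tested under treatment coding. Raises for
    designs where any group has a constant covariate.
    """
    df = table.rename(
        columns={response: "response", covariate: "covariate", group: "group"}
    )[["response", "covariate", "group"]].copy()
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, sub in df.groupby("group"):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        if sub["covariate"].nunique() < 2:
            raise ValueError(f"group {g!r} has a constant covariate: singular design")
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} not present")

    fit_sum = smf.ols("response ~ covariate * C(group, Sum)", data=df).fit()
    aov = anova_lm(fit_sum, typ=3)
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    resid_df = int(aov.loc["Residual", "df"])
    f_cov, p_cov, df_cov = _effect_f(aov, "covariate", resid_ss, resid_df)
    f_fac, p_fac, df_fac = _effect_f(aov, "C(group, Sum)", resid_ss, resid_df)
    f_int, p_int, df_int = _effect_f(aov, "covariate:C(group, Sum)", resid_ss, resid_df)

    fit_trt = smf.ols(
        f"response ~ covariate * C(group, Treatment({reference_group!r}))", data=df
    ).fit()
    rows = []
    for name in fit_trt.params.index:
        if name.startswith("covariate:"):
            level = name.split("[T.", 1)[1].rstrip("]")
            rows.append(
                {
                    "group": level,
                    "slope_diff": float(fit_trt.params[name]),
                    "t": float(fit_trt.tvalues[name]),
                    "p": float(fit_trt.pvalues[name]),
                }
            )

    return AncovaResult(
        f_covariate=f_cov,
        f_factor=f_fac,
        f_interaction=f_int,
        df_covariate=(df_cov, resid_df),
        df_factor=(df_fac, resid_df),
        df_interaction=(df_int, resid_df),
        p_covariate=p_cov,
        p_factor=p_fac,
        p_interaction=p_int,
        slope_contrasts=pd.DataFrame(rows),
    )
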