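"""Blood-to-plasma conversion and Monte Carlo error propagation.

A drug concentration measured in a dried blood spot (Cb) is converted
to the plasma concentration (Cp) through the partition model

    Cp = Cb * Vnom / (Vpred * (1 - HCT + K*HCT))

where K is the blood cell-to-plasma partition coefficient and
Vpred/Vnom the predicted and nominal blood volumes in the analysed
punch. The residual error after correcting HCT, volume, neither, or
both is quantified by Monte Carlo: measured HCT and volume are drawn
from normal distributions parameterised by the assays' validated
accuracy (mean recovery) and precision (RSD), and the relative error of
the back-calculated Cp is summarised by its median and 2.5th/97.5th
percentiles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthesize import DEFAULT_MODELS, DEFAULT_NOISE, NoiseSpec, TrueResponseModels

__all__ = [
    "CorrectionInput",
    "Scenario",
    "ErrorSummary",
    "plasma_concentration",
    "simulate_relative_error",
    "run_error_grid",
    "plot_error_grid",
    "STRATEGIES",
]

STRATEGIES = ("none", "hct_only", "volume_only", "both")

#: Typical population HCT assumed when no correction is applied.
ASSUMED_HCT = 0.4


@dataclass(frozen=True)
class CorrectionInput:
    """One sample's inputs to the blood-to-plasma conversion."""

    cb: float
    hct: float
    k: float
    vpred: float
    vnom: float

    def __post_init__(self) -> None:
        if not 0 <= self.hct < 1:
            raise ValueError("hct must lie in [0, 1)")
        if self.vnom <= 0 or self.vpred <= 0:
            raise ValueError("volumes must be positive")
        if self.k < 0:
            raise ValueError("partition coefficient must be nonnegative")


def plasma_concentration(inp: CorrectionInput) -> float:
    """Convert measured blood concentration to plasma concentration.

    Cp = Cb * Vnom / (Vpred * (1 - HCT + K*HCT)). Homogeneous of degree
    one in Cb; independent of HCT when K = 1 (analyte distributed evenly
    between cells and plasma).
    """
    partition = 1.0 - inp.hct + inp.k * inp.hct
    denom = partition * (inp.vpred / inp.vnom)
    if denom <= 0:
        raise ValueError("nonpositive partition/volume factor")
    return inp.cb / denom


@dataclass(frozen=True)
class Scenario:
    """One cell of the error-propagation grid.

    ``strategy`` selects which quantities are measured (with noise) when
    back-calculating Cp: ``none`` assumes HCT = ``assumed_hct`` and
    volume = nominal; ``hct_only``/``volume_only`` measure one of the
    two; ``both`` measures both. Noise specs default to the QC
    accuracy/precision of the hemoglobin HCT assay and the conductivity
    volume assay at the QC level nearest the scenario's truth.
    """

    true_hct: float
    k: float
    strategy: str
    hct_noise: NoiseSpec | None = None
    volume_noise: NoiseSpec | None = None
    assumed_hct: float = ASSUMED_HCT
    n_draws: int = 100_000
    seed: int = 0
    sample_vpred_when_uncorrected: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0 < self.true_hct < 1:
            raise ValueError("true_hct must lie in (0, 1)")

    def resolved_hct_noise(self) -> NoiseSpec:
        return self.hct_noise or DEFAULT_NOISE["abs"].nearest(self.true_hct)

    def resolved_volume_noise(self) -> NoiseSpec:
        return self.volume_noise or DEFAULT_NOISE["conductivity"].nearest(self.true_hct)


@dataclass(frozen=True)
class ErrorSummary:
    """Median and 95% span of the Monte Carlo relative-error draws."""

    median_rel_err: float
    p2_5: float
    p97_5: float

    def __post_init__(self) -> None:
        if not self.p2_5 <= self.median_rel_err <= self.p97_5:
            raise ValueError("percentiles must bracket the median")


def _truncated_normal_draws(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Normal draws redrawn until they fall in the open interval (lo, hi)."""
    x = rng.normal(mean, sd, n)
    bad = (x <= lo) | (x >= hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x <= lo) | (x >= hi)
    return x


def simulate_relative_error(
    scenario: Scenario,
    truth: TrueResponseModels = DEFAULT_MODELS,
) -> ErrorSummary:
    """Monte Carlo relative error of back-calculated Cp for one cell.

    The true state fixes Cp = 1, so Cb_true = 1 − HCT + K·HCT, and the
    true punch volume follows the punch-volume model at the true HCT.
    The observed blood concentration is referenced to the nominal punch
    volume (the volume at the assumed HCT), Cb_obs = Cb_true·V_true/Vnom,
    which carries the volume bias of an uncorrected assay. Per draw, the
    correction uses measured HCT ~ N(true·acc/100, true·rsd/100) if the
    strategy corrects HCT (else the assumed HCT) and measured volume
    ~ N(V_true·acc/100, V_true·rsd/100) if it corrects volume (else the
    nominal volume). Draws are truncated to the physical support
    (HCT in (0, 1), volume > 0). Relative error is 100·(Cp_est − 1).
    """
    h_true = scenario.true_hct
    k = scenario.k
    v_true = float(truth.punch_volume(h_true))
    v_nom = float(truth.punch_volume(scenario.assumed_hct))
    cb_true = 1.0 - h_true + k * h_true
    cb_obs = cb_true * v_true / v_nom

    rng = np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed), zlib.crc32(b"relative-error")])
    )
    n = scenario.n_draws

    correct_hct = scenario.strategy in ("hct_only", "both")
    correct_vol = scenario.strategy in ("volume_only", "both")

    if correct_hct:
        spec = scenario.resolved_hct_noise()
        h = _truncated_normal_draws(
            rng,
            h_true * spec.accuracy_pct / 100.0,
            h_true * spec.rsd_pct / 100.0,
            n,
            0.0,
            1.0,
        )
    else:
        h = np.full(n, scenario.assumed_hct)

    if correct_vol:
        spec = scenario.resolved_volume_noise()
        v = _truncated_normal_draws(
            rng,
            v_true * spec.accuracy_pct / 100.0,
            v_true * spec.rsd_pct / 100.0,
            n,
            0.0,
            np.inf,
        )
    elif scenario.sample_vpred_when_uncorrected:
        # Alternative reading: an uncorrected assay still analyses the true
        # volume; sample Vpred around truth instead of assuming nominal.
        spec = scenario.resolved_volume_noise()
        v = _truncated_normal_draws(
            rng,
            v_true * spec.accuracy_pct / 100.0,
            v_true * spec.rsd_pct / 100.0,
            n,
            0.0,
            np.inf,
        )
    else:
        v = np.full(n, v_nom)

    cp_est = cb_obs * v_nom / (v * (1.0 - h + k * h))
    rel_err = 100.0 * (cp_est - 1.0)
    p2_5, med, p97_5 = np.percentile(rel_err, [2.5, 50.0, 97.5])
    return ErrorSummary(median_rel_err=float(med), p2_5=float(p2_5), p97_5=float(p97_5))


def run_error_grid(
    hcts: Sequence[float] = (0.2, 0.4, 0.6),
    ks: Sequence[float] = (0.0, 1.0, 10.0),
    strategies: Sequence[str] = STRATEGIES,
    truth: TrueResponseModels = DEFAULT_MODELS,
    hct_noise: NoiseSpec | None = None,
    volume_noise: NoiseSpec | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial error grid over HCT × K × correction strategy.

    Each cell runs an independent Monte Carlo substream keyed by its
    factor combination, so dropping or reordering cells does not perturb
    the others. Returns one row per cell with the median relative error
    and its 2.5/97.5 percentiles (all in percent).
    """
    if not (len(list(hcts)) and len(list(ks)) and len(list(strategies))):
        raise ValueError("factor lists must be nonempty")
    rows = []
    for h in hcts:
        for k in ks:
            for strategy in strategies:
                cell_seed = np.random.SeedSequence(
                    [int(seed), zlib.crc32(f"{h:g}|{k:g}|{strategy}".encode())]
                ).generate_state(1)[0] % (2**31)
                summary = simulate_relative_error(
                    Scenario(
                        true_hct=float(h),
                        k=float(k),
                        strategy=strategy,
                        hct_noise=hct_noise,
                        volume_noise=volume_noise,
                        n_draws=n_draws,
                        seed=int(cell_seed),
                    ),
                    truth=truth,
                )
                rows.append(
                    {
                        "hct": float(h),
                        "k": float(k),
                        "strategy": strategy,
                        "median_rel_err": summary.median_rel_err,
                        "p2_5": summary.p2_5,
                        "p97_5": summary.p97_5,
                    }
                )
    return pd.DataFrame(rows)


def plot_error_grid(grid: pd.DataFrame, path=None):
    """Horizontal-bar panel of median relative errors with 95% spans.

    One column of panels per correction strategy, one bar per HCT × K
    scenario; dashed guides mark the ±20% critical-error band.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = list(dict.fromkeys(grid["strategy"]))
    scenarios = grid[["hct", "k"]].drop_duplicates().reset_index(drop=True)
    fig, axes = plt.subplots(
        1, len(strategies), figsize=(3.2 * len(strategies), 0.45 * len(scenarios) + 1.5),
        sharey=True,
    )
    axes = np.atleast_1d(axes)
    ypos = np.arange(len(scenarios))[::-1]
    labels = [f"HCT {r.hct:g}, K {r.k:g}" for r in scenarios.itertuples()]
    for ax, strategy in zip(axes, strategies):
        sub = grid[grid["strategy"] == strategy].set_index(["hct", "k"])
        med = [sub.loc[(r.hct, r.k), "median_rel_err"] for r in scenarios.itertuples()]
        lo = [sub.loc[(r.hct, r.k), "p2_5"] for r in scenarios.itertuples()]
        hi = [sub.loc[(r.hct, r.k), "p97_5"] for r in scenarios.itertuples()]
        err = [np.array(med) - np.array(lo), np.array(hi) - np.array(med)]
        ax.barh(ypos, med, xerr=err, color="#4878b0", height=0.6, capsize=2)
        ax.axvline(0, color="k", lw=1)
        ax.axvline(20, color="r", ls="--", lw=0.8)
        ax.axvline(-20, color="r", ls="--", lw=0.8)
        ax.set_title(strategy.replace("_", " "))
        ax.set_xlabel("relative error (%)")
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels(labels)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
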