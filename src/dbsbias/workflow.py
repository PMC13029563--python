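"""End-to-end correction workflow: decision rules and the full pipeline.

`decide_workflow` codifies the decision tree for a single sample: which
HCT estimation method, which volume method, and which corrections are
required, given how the sample was collected and what measurements are
available. `run_pipeline` drives the whole analysis on synthetic data —
generation, calibration, estimation, correction, agreement reports and
the Monte Carlo error grid — into a reproducible run directory keyed by
the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, calibration, correction, estimation, synthesize

__all__ = ["RunConfig", "SampleContext", "WorkflowDecision", "decide_workflow", "run_pipeline"]


@dataclass(frozen=True)
class SampleContext:
    """What is known about one sample before analysis."""

    volumetric: bool
    hct_known: bool
    hct_value: float | None = None
    has_scan: bool = False
    has_absorbance: bool = False
    has_conductivity: bool = False


@dataclass(frozen=True)
class WorkflowDecision:
    sample_kind: str  # volumetric | non-volumetric
    hct_method: str  # image | hb | none
    volume_method: str  # conductivity | reference | none
    strategy: str  # none | hct_only | volume_only | both


def decide_workflow(
    ctx: SampleContext,
    typical_band: tuple[float, float] = estimation.AUTO_AVERAGE_BAND,
) -> WorkflowDecision:
    """Choose estimation methods and correction strategy for a sample.

    Rules, in order:

    1. Volumetric spotting with a known HCT inside the typical band
       (calibrators matched near HCT 0.4): no correction needed.
    2. Known HCT, unknown volume (non-volumetric): correct both — the
       HCT correction uses the known value (no estimation method) and
       the volume comes from conductivity.
    3. Both unknown: correct both; HCT from the image if a scan exists,
       else from hemoglobin absorbance; volume from conductivity.

    A required method with no available measurement raises.
    """
    kind = "volumetric" if ctx.volumetric else "non-volumetric"

    if ctx.volumetric and ctx.hct_known:
        if ctx.hct_value is not None and typical_band[0] <= ctx.hct_value <= typical_band[1]:
            return WorkflowDecision(kind, "none", "none", "none")
        # Known but atypical HCT on a volumetric sample: correct HCT only.
        return WorkflowDecision(kind, "none", "none", "hct_only")

    if not ctx.has_conductivity and not ctx.volumetric:
        raise ValueError("non-volumetric sample with no volume modality available")

    volume_method = "conductivity" if not ctx.volumetric else "none"
    vol_part = "volume_only" if not ctx.volumetric else "none"

    if ctx.hct_known:
        # HCT correction uses the known reference value directly.
        hct_method = "none"
        strategy = "both" if volume_method == "conductivity" else "hct_only"
        return WorkflowDecision(kind, hct_method, volume_method, strategy)

    if ctx.has_scan:
        hct_method = "image"
    elif ctx.has_absorbance:
        hct_method = "hb"
    else:
        raise ValueError("no HCT modality available for a required HCT correction")
    strategy = "both" if volume_method == "conductivity" else "hct_only"
    return WorkflowDecision(kind, hct_method, volume_method, strategy)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic pipeline run."""

    seed: int
    n_patients: int = 23
    hct_range: tuple[float, float] = (0.35, 0.46)
    k: float = 1.0
    n_draws: int = 100_000
    grid_hcts: tuple[float, ...] = (0.2, 0.4, 0.6)
    grid_ks: tuple[float, ...] = (0.0, 1.0, 10.0)
    # The clinical cohort is analysed with the average volume curve, as
    # its HCT band is the one that justified pooling; "auto" can flip to
    # an HCT-specific curve when a noisy HCT estimate strays past the
    # band edge.
    volume_policy: str = "average"
    average_band: tuple[float, float] = estimation.AUTO_AVERAGE_BAND
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hct_range", "grid_hcts", "grid_ks", "average_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "hct_range": list(self.hct_range),
            "k": self.k,
            "n_draws": self.n_draws,
            "grid_hcts": list(self.grid_hcts),
            "grid_ks": list(self.grid_ks),
            "volume_policy": self.volume_policy,
            "average_band": list(self.average_band),
            "make_plots": self.make_plots,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full synthetic workflow into ``outdir``.

    Stages: simulate calibrators/QCs/conductivity/cohort → fit and
    validate calibrations → estimate HCT and punch volume per patient →
    convert blood to plasma concentrations → agreement reports → Monte
    Carlo error grid. Every output embeds the config hash and seed in a
    run manifest; rerunning an identical config reproduces every output
    byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **info):
        log.append({"stage": name, **info})

    models = synthesize.DEFAULT_MODELS
    noise = synthesize.DEFAULT_NOISE

    # -- stage 1: simulate ---------------------------------------------
    try:
        donors = synthesize.DonorSet(seed=config.seed)
        calibrators = synthesize.generate_calibrators(
            donors, models, {m: noise[m].unbiased() for m in ("mgv", "sa", "abs")}
        )
        qc_abs = synthesize.generate_qc_replicates(
            (0.2, 0.4, 0.6), 5, "abs", models, noise["abs"], seed=config.seed
        )
        cond_table = synthesize.generate_conductivity_table(
            models,
            noise=noise["conductivity"].nearest(0.4),
            seed=config.seed,
            replicates=6,
        )
        cohort = synthesize.generate_patient_cohort(
            config.n_patients,
            config.hct_range,
            models,
            noise={"abs": noise["abs"], "conductivity": noise["conductivity"]},
            seed=config.seed,
        )
        _write_csv(calibrators, outdir / "calibrators.csv")
        _write_csv(cond_table, outdir / "conductivity.csv")
        _write_csv(cohort, outdir / "cohort.csv")
        stage("simulate", calibrators=len(calibrators), cohort=len(cohort))
    except Exception as exc:  # pragma: no cover - abort contract
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    # -- stage 2: calibrate --------------------------------------------
    abs_cal = calibrators.query("modality == 'abs'")[["level", "response"]]
    abs_model = calibration.fit_calibration(abs_cal, "linear", "hct", "abs")
    mgv_cal = calibrators.query("modality == 'mgv'")[["level", "response"]]
    mgv_model = calibration.fit_calibration(mgv_cal, "quadratic", "hct", "mgv")
    vol_curves = {}
    for hct, sub in cond_table.groupby("hct"):
        vol_curves[float(hct)] = calibration.fit_calibration(
            sub[["conductivity", "volume"]], "linear", "conductivity", "volume"
        )
    # The average volume curve pools the per-level lines by averaging
    # their coefficients; a single OLS through all points is distorted
    # by the wide per-level intercept scatter.
    pooled = calibration.mean_of_level_coefficients(
        [vol_curves[h] for h in sorted(vol_curves)]
    )
    pooled_ols = calibration.fit_calibration(
        cond_table[["conductivity", "volume"]], "linear", "conductivity", "volume"
    )
    report = calibration.validate_calibration(abs_model, abs_cal, qc_abs)
    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "abs": abs_model.to_dict(),
        "mgv": mgv_model.to_dict(),
        "volume_curves": {f"{h:g}": m.to_dict() for h, m in vol_curves.items()},
        "volume_average": {
            "slope": pooled[0],
            "intercept": pooled[1],
            "pooling": "mean_of_levels",
        },
        "volume_pooled_ols": pooled_ols.to_dict(),
    }
    (outdir / "models.json").write_text(json.dumps(bundle, indent=2))
    (outdir / "validation.json").write_text(report.to_json())
    (outdir / "validation.txt").write_text(report.to_text())
    stage("calibrate", models=2 + len(vol_curves) + 1, validation_passed=report.passed)

    # -- stage 3: estimate ---------------------------------------------
    est_rows = []
    for row in cohort.itertuples():
        hct_est = estimation.estimate_hct(abs_model, row.abs550)
        vol_est = estimation.estimate_volume(
            row.conductivity,
            vol_curves,
            pooled,
            hct_estimate=hct_est.value,
            policy=config.volume_policy,
            band=config.average_band,
        )
        est_rows.append(
            {
                "patient": row.patient,
                "hct_est": hct_est.value,
                "hct_flags": ";".join(hct_est.flags),
                "volume_est": vol_est.volume,
                "curve_used": vol_est.curve_used,
                "volume_flags": ";".join(vol_est.flags),
            }
        )
    estimates = pd.DataFrame(est_rows)
    _write_csv(estimates, outdir / "estimates.csv")
    stage("estimate", records=len(estimates))

    # -- stage 4: correct ----------------------------------------------
    v_nom = float(models.punch_volume(correction.ASSUMED_HCT))
    merged = cohort.merge(estimates, on="patient")
    cp_true = 1.0
    corr_rows = []
    for row in merged.itertuples():
        cb_true = cp_true * (1.0 - row.true_hct + config.k * row.true_hct)
        cb_obs = cb_true * row.true_punch_volume / v_nom
        cp_est = correction.plasma_concentration(
            correction.CorrectionInput(
                cb=cb_obs,
                hct=row.hct_est,
                k=config.k,
                vpred=row.volume_est,
                vnom=v_nom,
            )
        )
        corr_rows.append(
            {
                "patient": row.patient,
                "cb_observed": cb_obs,
                "cp_estimated": cp_est,
                "cp_true": cp_true,
                "rel_err_pct": 100.0 * (cp_est - cp_true) / cp_true,
            }
        )
    corrected = pd.DataFrame(corr_rows)
    _write_csv(corrected, outdir / "corrected.csv")
    stage("correct", records=len(corrected))

    # -- stage 5: compare ----------------------------------------------
    comparison = agreement.compare_methods(
        merged["reference_hct"], merged["hct_est"], unit="HCT fraction"
    )
    (outdir / "comparison_hct.json").write_text(comparison.to_json())
    stage("compare", pairs=len(merged))

    # -- stage 6: error grid -------------------------------------------
    grid = correction.run_error_grid(
        hcts=config.grid_hcts,
        ks=config.grid_ks,
        n_draws=config.n_draws,
        seed=config.seed,
    )
    _write_csv(grid, outdir / "error_grid.csv")
    if config.make_plots:
        correction.plot_error_grid(grid, outdir / "error_grid.png")
    stage("error_grid", cells=len(grid))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": log,
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.suffix in (".csv", ".json", ".txt") and p.name != "run_manifest.json"
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
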