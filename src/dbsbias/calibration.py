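"""Calibration curves: fitting, inverse prediction, and QC validation.

Each assay modality maps hematocrit (or conductivity) to a measured
response through an unweighted least-squares line or quadratic. Samples
are quantified by inverse prediction, and a calibration is accepted
against bioanalytical rules: calibrator back-calculation within ±15% of
nominal (±20% at the LLOQ, the lowest level), QC accuracy within
85–115%, QC precision (RSD, n−1 denominator) below 15%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "InversionResult",
    "ValidationReport",
    "fit_calibration",
    "invert_calibration",
    "validate_calibration",
    "mean_of_level_coefficients",
]

CAL_TOL_PCT = 15.0
LLOQ_TOL_PCT = 20.0
QC_ACC_RANGE = (85.0, 115.0)
QC_RSD_MAX = 15.0

_N_COEF = {"linear": 2, "quadratic": 3}


class InversionError(ValueError):
    """Inverse prediction is undefined for the requested response."""


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted response curve.

    ``coefficients`` are ordered highest degree first, matching
    ``numpy.polyval``. ``range`` is the span of predictor values used in
    the fit; inversions outside it are flagged, not rejected.
    """

    kind: str
    coefficients: tuple[float, ...]
    predictor: str
    response: str
    range: tuple[float, float]
    r2: float

    def __post_init__(self) -> None:
        if self.kind not in _N_COEF:
            raise ValueError(f"kind must be linear or quadratic, got {self.kind!r}")
        if len(self.coefficients) != _N_COEF[self.kind]:
            raise ValueError(
                f"{self.kind} model needs {_N_COEF[self.kind]} coefficients"
            )
        if not self.range[0] < self.range[1]:
            raise ValueError("range must satisfy lo < hi")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    def predict(self, x):
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))

    def invert(self, y: float) -> "InversionResult":
        return invert_calibration(self, y)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        d["range"] = list(self.range)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            kind=d["kind"],
            coefficients=tuple(d["coefficients"]),
            predictor=d["predictor"],
            response=d["response"],
            range=tuple(d["range"]),
            r2=float(d["r2"]),
        )


@dataclass(frozen=True)
class InversionResult:
    """A back-calculated predictor value with an out-of-range flag."""

    value: float
    in_range: bool

    def __float__(self) -> float:
        return self.value


def fit_calibration(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    kind: str = "linear",
    predictor: str = "hct",
    response: str = "response",
) -> CalibrationModel:
    """Ordinary least squares fit of response on predictor.

    ``points`` is an iterable of (predictor, response) pairs or a
    DataFrame whose first two columns are taken in that order. Requires
    at least one more point than parameters and two distinct predictor
    values (three for a quadratic). For a constant response the fit
    degenerates to an intercept-only model and r² is defined as 0.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (predictor, response) pairs")
        x, y = arr[:, 0], arr[:, 1]

    if kind not in _N_COEF:
        raise ValueError(f"kind must be linear or quadratic, got {kind!r}")
    n_par = _N_COEF[kind]
    if len(x) < n_par + 1:
        raise ValueError(f"{kind} fit needs at least {n_par + 1} points")
    n_distinct = len(np.unique(x))
    if n_distinct < n_par:
        raise ValueError(
            f"rank-deficient design: {kind} fit needs {n_par} distinct predictor values"
        )

    coeffs = np.polyfit(x, y, n_par - 1)
    resid = y - np.polyval(coeffs, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return CalibrationModel(
        kind=kind,
        coefficients=tuple(float(c) for c in coeffs),
        predictor=predictor,
        response=response,
        range=(float(x.min()), float(x.max())),
        r2=min(1.0, r2),
    )


def invert_calibration(model: CalibrationModel, response_value: float) -> InversionResult:
    """Back-calculate the predictor giving ``response_value``.

    Linear models invert directly. Quadratic models return the smaller
    real root — the branch left of the parabola's vertex, where the
    darkening MGV curve is monotone decreasing. For HCT-type predictors
    an inversion with no root in [0, 1] is an error; otherwise results
    outside the fitted range are returned flagged.
    """
    y = float(response_value)
    if model.kind == "linear":
        m, b = model.coefficients
        if m == 0:
            raise InversionError("zero slope: calibration is not invertible")
        x = (y - b) / m
    else:
        a, b, c = model.coefficients
        if a == 0:
            raise InversionError("degenerate quadratic (a = 0)")
        disc = b * b - 4 * a * (c - y)
        if disc < 0:
            raise InversionError("response outside the parabola's reach (complex roots)")
        roots = sorted([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
        x = roots[0]
        if _is_hct(model.predictor) and not any(0.0 <= r <= 1.0 for r in roots):
            raise InversionError("both roots outside [0, 1] for an HCT calibration")
    return InversionResult(value=float(x), in_range=model.range[0] <= x <= model.range[1])


def _is_hct(predictor: str) -> bool:
    return "hct" in predictor.lower()


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the calibrator / QC acceptance rules."""

    calibrator_levels: pd.DataFrame = field(repr=False)
    qc_levels: pd.DataFrame = field(repr=False)
    lloq_level: float
    passed: bool
    failures: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "lloq_level": self.lloq_level,
            "passed": self.passed,
            "failures": list(self.failures),
            "calibrator_levels": self.calibrator_levels.to_dict(orient="records"),
            "qc_levels": self.qc_levels.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = ["Calibration validation", "======================", ""]
        lines.append(f"LLOQ level: {self.lloq_level:g} (tolerance ±{LLOQ_TOL_PCT:g}%)")
        lines.append("")
        lines.append("Calibrator back-calculation (per-level means):")
        for row in self.calibrator_levels.itertuples():
            lines.append(
                f"  level {row.level:g}: mean {row.mean_back_calculated:.4g}"
                f" dev {row.deviation_pct:+.2f}% (tol ±{row.tolerance_pct:g}%)"
                f" {'PASS' if row.passed else 'FAIL'}"
            )
        lines.append("QC accuracy / precision:")
        for row in self.qc_levels.itertuples():
            lines.append(
                f"  level {row.level:g}: accuracy {row.accuracy_pct:.1f}%"
                f" RSD {row.rsd_pct:.2f}% {'PASS' if row.passed else 'FAIL'}"
            )
        lines.append("")
        lines.append("Overall: " + ("PASS" if self.passed else "FAIL"))
        for f in self.failures:
            lines.append(f"  - {f}")
        return "\n".join(lines)


def validate_calibration(
    model: CalibrationModel,
    calibrators: pd.DataFrame,
    qc_sets: pd.DataFrame,
    per_replicate: bool = False,
) -> ValidationReport:
    """Apply the acceptance rules to calibrators and QC replicates.

    ``calibrators`` and ``qc_sets`` need columns ``level`` (nominal
    predictor value) and ``response``. Calibrator deviations are judged
    on per-level means by default (``per_replicate=True`` judges every
    replicate); the lowest calibrator level is the LLOQ with the relaxed
    ±20% tolerance. QC levels need at least two replicates.
    """
    if (calibrators["level"] == 0).any() or (qc_sets["level"] == 0).any():
        raise ValueError("nominal level of zero: percent deviation undefined")

    lloq = float(calibrators["level"].min())
    failures: list[str] = []

    cal_rows = []
    for level, grp in calibrators.groupby("level", sort=True):
        back = np.array([invert_calibration(model, y).value for y in grp["response"]])
        tol = LLOQ_TOL_PCT if float(level) == lloq else CAL_TOL_PCT
        if per_replicate:
            devs = 100.0 * (back - float(level)) / float(level)
            dev = float(np.max(np.abs(devs)))
            ok = bool(np.all(np.abs(devs) <= tol))
            dev_signed = float(devs[np.argmax(np.abs(devs))])
        else:
            mean_back = float(back.mean())
            dev_signed = 100.0 * (mean_back - float(level)) / float(level)
            ok = abs(dev_signed) <= tol
        cal_rows.append(
            {
                "level": float(level),
                "mean_back_calculated": float(back.mean()),
                "deviation_pct": dev_signed,
                "tolerance_pct": tol,
                "passed": ok,
            }
        )
        if not ok:
            failures.append(
                f"calibrator level {level:g}: back-calculation deviation "
                f"{dev_signed:+.2f}% exceeds ±{tol:g}%"
            )

    qc_rows = []
    for level, grp in qc_sets.groupby("level", sort=True):
        if len(grp) < 2:
            raise ValueError(f"QC level {level:g} needs at least 2 replicates")
        back = np.array([invert_calibration(model, y).value for y in grp["response"]])
        accuracy = 100.0 * float(back.mean()) / float(level)
        rsd = 100.0 * float(back.std(ddof=1)) / float(back.mean())
        acc_ok = QC_ACC_RANGE[0] <= accuracy <= QC_ACC_RANGE[1]
        rsd_ok = rsd < QC_RSD_MAX
        qc_rows.append(
            {
                "level": float(level),
                "accuracy_pct": accuracy,
                "rsd_pct": rsd,
                "accuracy_passed": acc_ok,
                "rsd_passed": rsd_ok,
                "passed": acc_ok and rsd_ok,
            }
        )
        if not acc_ok:
            failures.append(
                f"QC level {level:g}: accuracy {accuracy:.1f}% outside "
                f"{QC_ACC_RANGE[0]:g}-{QC_ACC_RANGE[1]:g}%"
            )
        if not rsd_ok:
            failures.append(
                f"QC level {level:g}: RSD {rsd:.2f}% not below {QC_RSD_MAX:g}%"
            )

    return ValidationReport(
        calibrator_levels=pd.DataFrame(cal_rows),
        qc_levels=pd.DataFrame(qc_rows),
        lloq_level=lloq,
        passed=not failures,
        failures=tuple(failures),
    )


def mean_of_level_coefficients(
    models: Sequence[CalibrationModel] | Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Arithmetic mean of per-level linear (slope, intercept) pairs.

    The pooled volume curve's printed slope equals the mean of the
    per-HCT slopes; this helper exposes that alternative pooling next to
    the OLS fit on the combined points.
    """
    pairs = [
        m.coefficients if isinstance(m, CalibrationModel) else tuple(m) for m in models
    ]
    if any(len(p) != 2 for p in pairs):
        raise ValueError("mean-of-levels pooling is defined for linear models only")
    arr = np.asarray(pairs, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())
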