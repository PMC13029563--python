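"""Synthetic dried blood spot data with the study's response structure.

Every downstream stage — densitometry, calibration, volume estimation,
bias correction — is exercised here on generated data: five-donor
calibrator sets across hematocrit 0.2–0.6, raster spot images whose
interior gray level and area follow the validated response models,
conductivity–volume tables per HCT level, and patient-like cohorts with
HCT in a narrow clinical band. Measurement noise is multiplicative
Gaussian parameterised by assay accuracy (mean recovery, %) and
precision (relative SD, %), the two dispersion metrics the validation
tables report.

Randomness policy: one master seed; each modality draws from its own
substream derived by hashing the modality name, so changing one
modality's parameters never perturbs another's draws.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import SpotImage

__all__ = [
    "NoiseSpec",
    "NoiseProfile",
    "DonorSet",
    "TrueResponseModels",
    "DEFAULT_MODELS",
    "DEFAULT_NOISE",
    "AVERAGE_VOLUME_CURVE",
    "DEFAULT_AREA_SCALE",
    "modality_rng",
    "generate_calibrators",
    "generate_qc_replicates",
    "generate_spot_image",
    "generate_conductivity_table",
    "generate_patient_cohort",
]

MODALITIES = ("mgv", "sa", "abs", "conductivity")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise for one assay level.

    accuracy_pct is the mean recovery in percent (100 = unbiased);
    rsd_pct the relative standard deviation in percent. A measured
    response is ``true * accuracy/100 * (1 + eps)`` with
    ``eps ~ N(0, rsd/100)`` truncated at ±4 SD so responses stay
    positive at realistic RSDs.
    """

    accuracy_pct: float = 100.0
    rsd_pct: float = 0.0
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.rsd_pct < 0:
            raise ValueError("rsd_pct must be >= 0")
        if self.accuracy_pct <= 0:
            raise ValueError("accuracy_pct must be > 0")
        if self.distribution != "gaussian":
            raise ValueError("only gaussian noise is supported")

    def apply(self, true_values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        true_values = np.asarray(true_values, dtype=float)
        eps = _truncated_normal(rng, true_values.shape, 4.0)
        return true_values * (self.accuracy_pct / 100.0) * (1.0 + eps * self.rsd_pct / 100.0)


def _truncated_normal(rng: np.random.Generator, shape, bound_sd: float) -> np.ndarray:
    """Standard normal draws with |z| <= bound_sd, by redrawing."""
    z = rng.standard_normal(shape)
    bad = np.abs(z) > bound_sd
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > bound_sd
    return z


@dataclass(frozen=True)
class NoiseProfile:
    """Level-dependent noise: QC anchors interpolated linearly in level.

    The validation tables report accuracy/precision only at the three QC
    levels; between anchors both are interpolated linearly and clamped
    at the ends of the anchor range.
    """

    anchors: Mapping[float, NoiseSpec]

    def at(self, level: float) -> NoiseSpec:
        levels = np.array(sorted(self.anchors))
        acc = np.array([self.anchors[l].accuracy_pct for l in levels])
        rsd = np.array([self.anchors[l].rsd_pct for l in levels])
        return NoiseSpec(
            accuracy_pct=float(np.interp(level, levels, acc)),
            rsd_pct=float(np.interp(level, levels, rsd)),
        )

    def nearest(self, level: float) -> NoiseSpec:
        """The anchor spec at the QC level closest to ``level``."""
        levels = sorted(self.anchors)
        return self.anchors[min(levels, key=lambda l: abs(l - level))]

    def unbiased(self) -> "NoiseProfile":
        """Same precision anchors with accuracy forced to 100%."""
        return NoiseProfile(
            {l: NoiseSpec(100.0, s.rsd_pct) for l, s in self.anchors.items()}
        )


@dataclass(frozen=True)
class DonorSet:
    """A calibrator design: donors crossed with nominal HCT levels."""

    n_donors: int = 5
    hct_levels: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        levels = tuple(float(h) for h in self.hct_levels)
        if not levels:
            raise ValueError("hct_levels must be nonempty")
        if any(not 0 < h < 1 for h in levels):
            raise ValueError("hct_levels must lie in (0, 1)")
        if list(levels) != sorted(levels):
            raise ValueError("hct_levels must be sorted ascending")
        object.__setattr__(self, "hct_levels", levels)


@dataclass(frozen=True)
class TrueResponseModels:
    """Generating ("true") response models for every modality.

    Defaults are the validated study models: a quadratic MGV–HCT curve,
    linear surface-area and absorbance curves, per-HCT conductivity
    lines of the form volume = slope * conductivity + intercept, and the
    blood volume contained in a 6 mm punch at each HCT level (from the
    average-curve back-calculation of 20 µL spots).
    """

    mgv_coeffs: tuple[float, float, float] = (161.67, -237.12, 177.64)
    sa_coeffs: tuple[float, float] = (-0.0397, 0.0922)
    abs_coeffs: tuple[float, float] = (1.137, 0.003)
    cond_lines: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: {
            0.2: (25.97, 10.19),
            0.3: (26.06, 13.15),
            0.4: (25.18, -0.01),
            0.5: (23.01, 29.78),
            0.6: (23.22, 27.60),
        }
    )
    punch_volume_by_hct: Mapping[float, float] = field(
        default_factory=lambda: {0.2: 8.4, 0.3: 9.5, 0.4: 9.6, 0.5: 10.5, 0.6: 11.4}
    )

    def __post_init__(self) -> None:
        a, b, _ = self.mgv_coeffs
        # MGV must darken monotonically with HCT over the calibrated range.
        if not (2 * a * 0.2 + b < 0 and 2 * a * 0.6 + b < 0):
            raise ValueError("MGV model must be decreasing on [0.2, 0.6]")
        vols = [self.punch_volume_by_hct[h] for h in sorted(self.punch_volume_by_hct)]
        if any(v <= 0 for v in vols) or any(np.diff(vols) < 0):
            raise ValueError("punch volumes must be positive and nondecreasing in HCT")

    # -- forward models -------------------------------------------------
    def mgv(self, hct):
        a, b, c = self.mgv_coeffs
        hct = np.asarray(hct, dtype=float)
        return a * hct**2 + b * hct + c

    def surface_area(self, hct):
        m, b = self.sa_coeffs
        return m * np.asarray(hct, dtype=float) + b

    def absorbance(self, hct):
        m, b = self.abs_coeffs
        return m * np.asarray(hct, dtype=float) + b

    def cond_line_at(self, hct: float) -> tuple[float, float]:
        """(slope, intercept) of volume = f(conductivity), interpolated in HCT."""
        levels = np.array(sorted(self.cond_lines))
        slopes = np.array([self.cond_lines[l][0] for l in levels])
        inters = np.array([self.cond_lines[l][1] for l in levels])
        return (
            float(np.interp(hct, levels, slopes)),
            float(np.interp(hct, levels, inters)),
        )

    def conductivity(self, hct: float, volume) -> np.ndarray:
        """Invert the volume line: conductivity producing ``volume`` µL."""
        slope, intercept = self.cond_line_at(hct)
        return (np.asarray(volume, dtype=float) - intercept) / slope

    def average_cond_line(self) -> tuple[float, float]:
        """Average volume line: arithmetic mean of the per-level lines.

        The per-level intercepts as printed scatter far too widely to be
        pooled by a single OLS fit through all points, but the pooled
        slope is, to printed precision, the mean of the per-level
        slopes; the mean line is therefore the generating family's
        self-consistent "average calibration curve".
        """
        arr = np.array([self.cond_lines[l] for l in sorted(self.cond_lines)])
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def average_conductivity(self, volume) -> np.ndarray:
        """Invert the average volume line at ``volume`` µL."""
        slope, intercept = self.average_cond_line()
        return (np.asarray(volume, dtype=float) - intercept) / slope

    def punch_volume(self, hct) -> np.ndarray:
        levels = np.array(sorted(self.punch_volume_by_hct))
        vols = np.array([self.punch_volume_by_hct[l] for l in levels])
        return np.interp(np.asarray(hct, dtype=float), levels, vols)

    def response(self, modality: str, hct):
        if modality == "mgv":
            return self.mgv(hct)
        if modality == "sa":
            return self.surface_area(hct)
        if modality == "abs":
            return self.absorbance(hct)
        raise ValueError(f"unknown modality: {modality!r}")


DEFAULT_MODELS = TrueResponseModels()

#: Average (pooled over HCT 0.2–0.6) volume calibration curve,
#: volume[µL] = 24.7 * conductivity[µS/cm] + 16.7.
AVERAGE_VOLUME_CURVE: tuple[float, float] = (24.7, 16.7)

#: Validated QC accuracy/precision anchors per modality.
DEFAULT_NOISE: Mapping[str, NoiseProfile] = {
    "mgv": NoiseProfile(
        {0.2: NoiseSpec(90.3, 0.87), 0.4: NoiseSpec(93.2, 2.71), 0.6: NoiseSpec(98.8, 4.77)}
    ),
    "sa": NoiseProfile(
        {0.2: NoiseSpec(103.0, 11.3), 0.4: NoiseSpec(103.0, 5.73), 0.6: NoiseSpec(99.6, 5.63)}
    ),
    "abs": NoiseProfile(
        {0.2: NoiseSpec(102.2, 2.45), 0.4: NoiseSpec(95.7, 7.44), 0.6: NoiseSpec(99.1, 5.87)}
    ),
    "conductivity": NoiseProfile(
        {0.2: NoiseSpec(96.8, 13.6), 0.4: NoiseSpec(100.0, 5.57), 0.6: NoiseSpec(99.6, 5.14)}
    ),
}

#: mm² of physical spot area per surface-area model unit, anchored so a
#: 20 µL spot at HCT 0.4 has area 113 mm² (≈12 mm diameter).
DEFAULT_AREA_SCALE = 113.0 / (-0.0397 * 0.4 + 0.0922)

#: Volume of the volumetrically applied calibration spots, µL.
CALIBRATION_SPOT_VOLUME = 20.0


def modality_rng(seed: int, modality: str) -> np.random.Generator:
    """Independent, reproducible substream for one modality."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(modality.encode())])
    )


def generate_calibrators(
    donors: DonorSet,
    models: TrueResponseModels = DEFAULT_MODELS,
    noise: Mapping[str, NoiseSpec | NoiseProfile] | None = None,
    modalities: Sequence[str] = ("mgv", "sa", "abs"),
) -> pd.DataFrame:
    """Calibrator responses for each donor × HCT level × modality.

    ``noise`` maps modality to either a flat :class:`NoiseSpec` or a
    level-interpolating :class:`NoiseProfile`; omitted modalities are
    noise-free. Returns columns (donor, level, modality, response).
    """
    noise = noise or {}
    unknown = set(noise) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modality in noise specs: {sorted(unknown)}")
    rows = []
    for modality in modalities:
        rng = modality_rng(donors.seed, modality)
        spec_src = noise.get(modality)
        for level in donors.hct_levels:
            true = float(models.response(modality, level))
            spec = (
                spec_src.at(level)
                if isinstance(spec_src, NoiseProfile)
                else (spec_src or NoiseSpec())
            )
            resp = spec.apply(np.full(donors.n_donors, true), rng)
            for donor, r in enumerate(resp, start=1):
                rows.append((donor, level, modality, float(r)))
    return pd.DataFrame(rows, columns=["donor", "level", "modality", "response"])


def generate_qc_replicates(
    levels: Sequence[float],
    n_replicates: int,
    modality: str,
    models: TrueResponseModels = DEFAULT_MODELS,
    noise: NoiseSpec | NoiseProfile | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Quality-control replicates: columns (level, replicate, response)."""
    rng = modality_rng(seed, "qc-" + modality)
    rows = []
    for level in levels:
        true = float(models.response(modality, level))
        spec = (
            noise.at(level)
            if isinstance(noise, NoiseProfile)
            else (noise or NoiseSpec())
        )
        resp = spec.apply(np.full(n_replicates, true), rng)
        for rep, r in enumerate(resp, start=1):
            rows.append((float(level), rep, float(r)))
    return pd.DataFrame(rows, columns=["level", "replicate", "response"])


def generate_spot_image(
    hct: float,
    spot_volume: float = CALIBRATION_SPOT_VOLUME,
    pixel_size: float = 0.1,
    image_noise_sd: float = 0.0,
    seed: int = 0,
    models: TrueResponseModels = DEFAULT_MODELS,
    area_scale: float = DEFAULT_AREA_SCALE,
    shape: tuple[int, int] | None = None,
    background: float = 255.0,
) -> SpotImage:
    """Render a synthetic spot: a dark disc on a white card.

    The disc's interior gray equals the MGV model at ``hct`` and its
    physical area follows the surface-area model scaled by
    ``area_scale`` (mm² per model unit) and linearly by spot volume
    relative to the 20 µL calibration volume. Pixels are foreground iff
    their center falls inside the disc; optional additive Gaussian pixel
    noise (SD in gray levels) is clipped to [0, 255].
    """
    if not 0 < hct < 1:
        raise ValueError("hct must be in (0, 1)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    area_mm2 = area_scale * float(models.surface_area(hct)) * spot_volume / CALIBRATION_SPOT_VOLUME
    if area_mm2 <= 0:
        raise ValueError("surface-area model gives nonpositive area at this HCT")
    radius_px = np.sqrt(area_mm2 / np.pi) / pixel_size

    if shape is None:
        n = int(np.ceil(2 * radius_px)) + 8
        shape = (n, n)
    rows, cols = shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    if radius_px > min(cr, cc):
        raise ValueError("disc does not fit inside the requested frame")

    rr, cc_grid = np.ogrid[:rows, :cols]
    inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius_px**2
    pixels = np.full(shape, float(background))
    pixels[inside] = float(models.mgv(hct))
    if image_noise_sd > 0:
        rng = modality_rng(seed, "image")
        pixels = np.clip(pixels + rng.normal(0.0, image_noise_sd, shape), 0.0, 255.0)
    return SpotImage(pixels=pixels, pixel_size=pixel_size)


def generate_conductivity_table(
    models: TrueResponseModels = DEFAULT_MODELS,
    volumes: Sequence[float] = (5.0, 10.0, 20.0, 30.0, 40.0),
    noise: NoiseSpec | None = None,
    seed: int = 0,
    hct_levels: Sequence[float] | None = None,
    replicates: int = 1,
) -> pd.DataFrame:
    """Conductivity readings for spotted volumes at each HCT level.

    Conductivity is the algebraic inversion of each HCT level's
    volume line, after which multiplicative noise is applied. Under the
    printed line parameters the smallest volumes can invert to negative
    conductivities; these are kept but flagged with a warning, since
    they reflect the printed calibration algebra rather than a
    generation bug. Columns: (hct, volume, replicate, conductivity).
    """
    volumes = [float(v) for v in volumes]
    if any(not 5.0 <= v <= 40.0 for v in volumes):
        raise ValueError("volumes must lie within the calibrated range 5-40 µL")
    if hct_levels is None:
        hct_levels = sorted(models.cond_lines)
    rng = modality_rng(seed, "conductivity")
    spec = noise or NoiseSpec()
    rows = []
    for hct in hct_levels:
        if float(hct) not in models.cond_lines:
            raise ValueError(f"no conductivity line defined for HCT {hct}")
        for vol in volumes:
            true_cond = float(models.conductivity(hct, vol))
            obs = spec.apply(np.full(replicates, true_cond), rng)
            for rep, c in enumerate(obs, start=1):
                rows.append((float(hct), vol, rep, float(c)))
    out = pd.DataFrame(rows, columns=["hct", "volume", "replicate", "conductivity"])
    n_neg = int((out["conductivity"] < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} synthetic conductivity value(s) are negative: the printed "
            "volume-line intercepts exceed the smallest spotted volumes",
            UserWarning,
            stacklevel=2,
        )
    return out


def generate_patient_cohort(
    n: int,
    hct_range: tuple[float, float] = (0.35, 0.46),
    models: TrueResponseModels = DEFAULT_MODELS,
    noise: Mapping[str, NoiseSpec | NoiseProfile] | None = None,
    reference_noise: NoiseSpec | None = None,
    seed: int = 0,
    conductivity_curve: str = "average",
) -> pd.DataFrame:
    """A patient-like cohort with per-sample modality responses.

    True HCT is uniform over ``hct_range`` (default the narrow clinical
    band of the study cohort). Each modality response is generated from
    the true models plus its noise spec; ``reference_hct`` emulates the
    hematology-analyzer reference with its own (default zero) noise.
    ``true_punch_volume`` interpolates the punch-volume truth at the
    sample's HCT.

    ``conductivity`` inverts a volume line at the true punch volume:
    by default the average line (mean of the per-level lines), the
    curve a narrow-HCT-band cohort is analysed with; pass
    ``conductivity_curve="hct_specific"`` to invert the per-level line
    interpolated at each sample's HCT instead. The printed per-level
    intercepts exceed typical punch volumes, so generated punch-scale
    conductivities are negative under either option — the printed
    calibration algebra propagated as-is, flagged downstream.
    """
    if conductivity_curve not in ("average", "hct_specific"):
        raise ValueError("conductivity_curve must be 'average' or 'hct_specific'")
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = hct_range
    if not 0 < lo < hi < 1:
        raise ValueError("hct_range must satisfy 0 < lo < hi < 1")
    noise = noise or {}
    hct_rng = modality_rng(seed, "patient-hct")
    true_hct = hct_rng.uniform(lo, hi, n)
    true_vol = models.punch_volume(true_hct)

    def _observe(modality: str, true_values: np.ndarray, per_level) -> np.ndarray:
        spec_src = noise.get(modality)
        rng = modality_rng(seed, "patient-" + modality)
        if spec_src is None:
            return true_values.copy()
        if isinstance(spec_src, NoiseProfile):
            out = np.empty_like(true_values)
            for i, (tv, lvl) in enumerate(zip(true_values, per_level)):
                out[i] = spec_src.at(float(lvl)).apply(np.array([tv]), rng)[0]
            return out
        return spec_src.apply(true_values, rng)

    mgv = _observe("mgv", np.asarray(models.mgv(true_hct)), true_hct)
    abs550 = _observe("abs", np.asarray(models.absorbance(true_hct)), true_hct)
    if conductivity_curve == "average":
        true_cond = np.asarray(models.average_conductivity(true_vol))
    else:
        true_cond = np.array(
            [float(models.conductivity(h, v)) for h, v in zip(true_hct, true_vol)]
        )
    cond = _observe("conductivity", true_cond, true_hct)

    ref_rng = modality_rng(seed, "patient-reference")
    reference = (reference_noise or NoiseSpec()).apply(true_hct, ref_rng)

    return pd.DataFrame(
        {
            "patient": np.arange(1, n + 1),
            "true_hct": true_hct,
            "reference_hct": reference,
            "mgv": mgv,
            "abs550": abs550,
            "conductivity": cond,
            "true_punch_volume": true_vol,
        }
    )
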