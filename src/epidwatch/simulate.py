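"""Synthetic transit-image courses with known ground truth.

The generator emulates what the surveillance pipeline must detect, not the
full physics of megavoltage imaging.  A collimated open field of uniform
fluence passes through an elliptical water-equivalent phantom; the panel
records exponentially attenuated fluence (single attenuation coefficient,
no scatter), the field edge is blurred by a Gaussian penumbra, and each
pixel carries multiplicative Gaussian noise.  Because the surveillance
metric is a *relative change* detector, first-order attenuation reproduces
every phenomenon the flags must catch:

* machine-output drift or step  -> uniform scaling of the whole image,
* anatomy change (weight loss, tumor shrinkage) -> thickness change
  inside the phantom shadow,
* acute delivery error -> single-fraction output spike.

By default the aperture lies fully inside the phantom projection, so the
high-dose low-gradient ROI sits on the in-shadow plateau and the expected
per-fraction GDSA has the closed form

    100 * (scale_f / scale_1 * exp(-mu * (dt_f - dt_1)) - 1)

relative to the fraction-1 baseline, which the ground-truth log records.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, EpidWatchError
from .io import (
    CourseSeries,
    EpidImage,
    FractionGroup,
    ImagingGeometry,
    write_rtimage,
)

SPIKE = "SPIKE"
TREND = "TREND"
OUTPUT_STEP = "OUTPUT_STEP"


@dataclass(frozen=True)
class PhantomModel:
    """Elliptical water-equivalent phantom centered on the beam axis.

    ``semi_axes_mm`` are the projection semi-axes at the isocenter plane;
    ``thickness_cm`` the uniform water-equivalent path length inside the
    ellipse; ``mu`` the linear attenuation coefficient (cm^-1, default
    0.05, about water at 6 MV).
    """

    semi_axes_mm: tuple[float, float] = (120.0, 100.0)
    thickness_cm: float = 10.0
    mu: float = 0.05

    def __post_init__(self) -> None:
        if self.thickness_cm < 0:
            raise ConfigError("thickness must be non-negative")
        if self.mu <= 0:
            raise ConfigError("mu must be positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ConfigError("semi-axes must be positive")

    def shadow_mask(self, geometry: ImagingGeometry) -> np.ndarray:
        """Boolean in-shadow mask on the panel grid (isocenter coordinates)."""
        yy, xx = _iso_grids(geometry)
        a, b = self.semi_axes_mm
        return (yy / a) ** 2 + (xx / b) ** 2 <= 1.0

    def thickness_map(self, geometry: ImagingGeometry) -> np.ndarray:
        """Per-pixel water-equivalent path length (cm) projected on the panel."""
        return np.where(self.shadow_mask(geometry), self.thickness_cm, 0.0)


@dataclass(frozen=True)
class CourseConfig:
    """Knobs of a simulated treatment course.

    Drift rates are per fraction: ``output_drift_percent_per_fraction`` is
    the machine-output slope in % (compounded), and
    ``thickness_drift_cm_per_fraction`` the anatomy change rate in cm
    (negative = weight loss / shrinkage).  ``seed`` fixes all randomness.
    """

    n_fractions: int = 10
    field_ids: tuple[str, ...] = ("F1",)
    open_field_cu: float = 1.0
    penumbra_sigma_mm: float = 3.0
    noise_sd_percent: float = 0.5
    output_drift_percent_per_fraction: float = 0.0
    thickness_drift_cm_per_fraction: float = 0.0
    seed: int = 0
    geometry: ImagingGeometry = field(default_factory=ImagingGeometry)
    aperture_mm: tuple[float, float] = (100.0, 100.0)
    start_date: dt.date = dt.date(2021, 1, 4)

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ConfigError("n_fractions must be >= 1")
        if self.noise_sd_percent < 0:
            raise ConfigError("noise SD must be non-negative")
        if not self.field_ids:
            raise ConfigError("at least one field id required")
        if self.open_field_cu <= 0:
            raise ConfigError("open_field_cu must be positive")


@dataclass(frozen=True)
class ErrorInjection:
    """A deliberate deviation injected into a simulated course.

    SPIKE and TREND multiply the delivered output by
    ``1 + magnitude_percent/100`` for ``duration_fractions`` starting at
    ``start_fraction`` (a SPIKE conventionally lasts one fraction, a TREND
    several).  OUTPUT_STEP does the same but models a persistent machine
    change; overlapping OUTPUT_STEP injections are a configuration error.
    """

    kind: str
    start_fraction: int
    magnitude_percent: float
    duration_fractions: int = 1

    def __post_init__(self) -> None:
        if self.kind not in (SPIKE, TREND, OUTPUT_STEP):
            raise ConfigError(f"unknown injection kind {self.kind!r}")
        if self.start_fraction < 1:
            raise ConfigError("start_fraction must be >= 1")
        if self.duration_fractions < 1:
            raise ConfigError("duration must be >= 1")

    def active(self, fraction: int) -> bool:
        return (
            self.start_fraction
            <= fraction
            < self.start_fraction + self.duration_fractions
        )


@dataclass
class FractionTruth:
    fraction_index: int
    output_scale: float
    thickness_delta_cm: float
    expected_gdsa_percent: float


@dataclass
class GroundTruthLog:
    """Analytic per-fraction truth for a simulated course."""

    patient_id: str
    plan_id: str
    entries: list[FractionTruth]

    @property
    def expected_gdsa(self) -> list[float]:
        return [e.expected_gdsa_percent for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fraction": e.fraction_index,
                    "output_scale": e.output_scale,
                    "thickness_delta_cm": e.thickness_delta_cm,
                    "expected_gdsa_percent": e.expected_gdsa_percent,
                }
                for e in self.entries
            ]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.9g")
        return path


def _iso_grids(geometry: ImagingGeometry) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = geometry.matrix
    pr, pc = geometry.iso_pitch_mm
    y = (np.arange(rows) - (rows - 1) / 2.0) * pr
    x = (np.arange(cols) - (cols - 1) / 2.0) * pc
    return np.meshgrid(y, x, indexing="ij")


def _aperture_mask(config: CourseConfig) -> np.ndarray:
    yy, xx = _iso_grids(config.geometry)
    hy, hx = config.aperture_mm[0] / 2.0, config.aperture_mm[1] / 2.0
    return (np.abs(yy) <= hy) & (np.abs(xx) <= hx)


def render_transit_image(
    phantom: PhantomModel,
    config: CourseConfig,
    output_scale: float = 1.0,
    thickness_delta_cm: float = 0.0,
    seed: int | Sequence[int] = 0,
    *,
    patient_id: str = "SYN000",
    plan_id: str = "PLAN1",
    field_id: str | None = None,
    acquisition: dt.datetime | None = None,
) -> EpidImage:
    """Render one noisy transit image.

    Pixel model: ``open_field_cu * output_scale * exp(-mu * (t + delta))``
    inside the phantom shadow, ``open_field_cu * output_scale`` outside,
    masked by the collimated aperture, Gaussian edge blur, then truncated
    multiplicative Gaussian noise.  Deterministic for a fixed seed.
    """
    geometry = config.geometry
    shadow = phantom.shadow_mask(geometry)
    thickness = phantom.thickness_map(geometry)
    delta = np.where(shadow, thickness_delta_cm, 0.0)
    if np.any(thickness + delta < -1e-12):
        raise EpidWatchError(
            "negative water-equivalent thickness: delta "
            f"{thickness_delta_cm} cm exceeds phantom thickness"
        )

    ideal = (
        config.open_field_cu
        * output_scale
        * np.exp(-phantom.mu * (thickness + delta))
        * _aperture_mask(config)
    )
    sigma_px = config.penumbra_sigma_mm / float(np.mean(geometry.iso_pitch_mm))
    blurred = gaussian_filter(ideal, sigma_px) if sigma_px > 0 else ideal

    if config.noise_sd_percent > 0:
        rng = np.random.default_rng(seed)
        factors = rng.normal(1.0, config.noise_sd_percent / 100.0, blurred.shape)
        pixels = np.clip(blurred * factors, 0.0, None)
    else:
        pixels = blurred

    return EpidImage(
        pixels=pixels,
        patient_id=patient_id,
        plan_id=plan_id,
        field_id=field_id or config.field_ids[0],
        acquisition=acquisition
        or dt.datetime.combine(config.start_date, dt.time(20, 0)),
        geometry=geometry,
    ).validate()


def _fraction_scales(
    config: CourseConfig, injections: Sequence[ErrorInjection]
) -> list[float]:
    for inj in injections:
        if inj.start_fraction > config.n_fractions:
            raise ConfigError(
                f"injection starts at fraction {inj.start_fraction} beyond "
                f"course of {config.n_fractions}"
            )
    steps = [inj for inj in injections if inj.kind == OUTPUT_STEP]
    for i, a in enumerate(steps):
        for b in steps[i + 1 :]:
            if any(a.active(f) and b.active(f) for f in range(1, config.n_fractions + 1)):
                raise ConfigError("overlapping OUTPUT_STEP injections")

    drift = 1.0 + config.output_drift_percent_per_fraction / 100.0
    scales = []
    for f in range(1, config.n_fractions + 1):
        scale = drift ** (f - 1)
        for inj in injections:
            if inj.active(f):
                scale *= 1.0 + inj.magnitude_percent / 100.0
        scales.append(scale)
    return scales


def _build_course(
    phantom: PhantomModel,
    config: CourseConfig,
    scales: Sequence[float],
    deltas: Sequence[float],
    dates: Sequence[dt.date],
    patient_id: str,
    plan_id: str,
) -> tuple[CourseSeries, GroundTruthLog]:
    fractions: list[FractionGroup] = []
    truths: list[FractionTruth] = []
    base_scale, base_delta = scales[0], deltas[0]
    for f, (scale, delta, day) in enumerate(zip(scales, deltas, dates), start=1):
        images = [
            render_transit_image(
                phantom,
                config,
                output_scale=scale,
                thickness_delta_cm=delta,
                seed=[config.seed % 2**31, f, k],
                patient_id=patient_id,
                plan_id=plan_id,
                field_id=fid,
                acquisition=dt.datetime.combine(day, dt.time(20, 0, f % 60)),
            )
            for k, fid in enumerate(config.field_ids)
        ]
        fractions.append(FractionGroup(fraction_index=f, date=day, images=images))
        expected = 100.0 * (
            scale / base_scale * math.exp(-phantom.mu * (delta - base_delta)) - 1.0
        )
        truths.append(FractionTruth(f, scale, delta, 0.0 if f == 1 else expected))
    series = CourseSeries(patient_id, plan_id, fractions)
    return series, GroundTruthLog(patient_id, plan_id, truths)


def generate_course(
    phantom: PhantomModel,
    config: CourseConfig,
    injections: Sequence[ErrorInjection] = (),
    *,
    patient_id: str = "SYN000",
    plan_id: str = "PLAN1",
) -> tuple[CourseSeries, GroundTruthLog]:
    """Simulate a full treatment course with its analytic ground truth.

    Fraction ``f`` is delivered with cumulative output scale
    ``(1 + drift)^(f-1)`` times any active injection factors, and
    cumulative anatomy change ``thickness_drift * (f-1)`` cm.  Fractions
    fall on consecutive calendar days starting at ``config.start_date``.
    The log's expected GDSA is exact relative to fraction 1 and is 0 there
    by construction.
    """
    scales = _fraction_scales(config, injections)
    deltas = [
        config.thickness_drift_cm_per_fraction * (f - 1)
        for f in range(1, config.n_fractions + 1)
    ]
    dates = [
        config.start_date + dt.timedelta(days=f - 1)
        for f in range(1, config.n_fractions + 1)
    ]
    return _build_course(phantom, config, scales, deltas, dates, patient_id, plan_id)


def generate_clinic_day(
    n_patients: int,
    date: dt.date,
    per_patient_config: CourseConfig,
    day_output_scale: float = 1.0,
    seed: int = 0,
    *,
    phantom: PhantomModel = PhantomModel(),
    patient_prefix: str = "DAY",
) -> list[tuple[CourseSeries, GroundTruthLog]]:
    """Simulate one clinic day: every patient treated with a shared output.

    Each patient gets a two-fraction course - a baseline on the previous
    day at unit output, then the fraction on ``date`` at
    ``day_output_scale`` - so daily clinic statistics can be formed.
    Patient-level randomness is independent across patients given the seed.
    """
    return generate_clinic_days(
        n_patients,
        [date - dt.timedelta(days=1), date],
        [1.0, day_output_scale],
        per_patient_config,
        seed,
        phantom=phantom,
        patient_prefix=patient_prefix,
    )


def generate_clinic_days(
    n_patients: int,
    dates: Sequence[dt.date],
    day_output_scales: Sequence[float],
    per_patient_config: CourseConfig,
    seed: int = 0,
    *,
    phantom: PhantomModel = PhantomModel(),
    patient_prefix: str = "DAY",
) -> list[tuple[CourseSeries, GroundTruthLog]]:
    """Simulate a synchronized multi-day clinic.

    Patient ``p``'s fraction ``f`` falls on ``dates[f-1]`` with the shared
    machine output ``day_output_scales[f-1]``; the first listed day is
    every course's baseline.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if len(dates) != len(day_output_scales):
        raise ConfigError("dates and day_output_scales lengths differ")
    out = []
    for p in range(n_patients):
        config = replace(
            per_patient_config,
            n_fractions=len(dates),
            seed=(seed * 100003 + p) % 2**31,
        )
        deltas = [0.0] * len(dates)
        course = _build_course(
            phantom,
            config,
            list(day_output_scales),
            deltas,
            list(dates),
            patient_id=f"{patient_prefix}{p:03d}",
            plan_id="PLAN1",
        )
        out.append(course)
    return out


def write_course(
    series: CourseSeries, truth: GroundTruthLog, out_dir: str | Path
) -> Path:
    """Emit a simulated course as RTIMAGE files plus a ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for group in series.fractions:
        for img in group.images:
            name = (
                f"{series.patient_id}_{series.plan_id}_fx{group.fraction_index:03d}"
                f"_{img.field_id}.dcm"
            )
            write_rtimage(img, out_dir / name)
    truth.to_csv(out_dir / f"{series.patient_id}_{series.plan_id}_truth.csv")
    return out_dir
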