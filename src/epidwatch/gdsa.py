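"""Gradient-dose segmented analysis (GDSA) of transit portal images.

GDSA summarizes one treatment fraction as a single percentage: the mean,
over the high-dose low-gradient region of the first-fraction baseline
image, of the per-pixel relative difference between the fraction and the
baseline.  The region of interest (ROI) roughly corresponds to the
projection of the planning target volume onto the imaging panel; it is
segmented once on the baseline and frozen for the whole course.

ROI construction conventions (thresholds, smoothing, gradient
normalization) are this module's own, configurable choices; see
:class:`RoiParams`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DegenerateFieldError, ValidationError, ZeroBaselineError
from .io import CourseSeries, EpidImage, validate_fraction


@dataclass(frozen=True)
class RoiParams:
    """Parameters of the high-dose, low-gradient ROI segmentation.

    dose_threshold_fraction
        A pixel enters the ROI only if its (lightly smoothed) value is at
        least this fraction of the plateau maximum.  Default 0.5.
    gradient_limit_percent_per_mm
        Maximum local relative gradient (% of local value per mm at the
        panel plane).  Default 3.0.
    min_roi_pixels
        Segmentation fails if fewer pixels qualify.  Default 100.
    smoothing_sigma_px
        Gaussian pre-smoothing (pixels) applied before thresholding so a
        single hot pixel cannot define the plateau maximum.  Default 2.
    """

    dose_threshold_fraction: float = 0.5
    gradient_limit_percent_per_mm: float = 3.0
    min_roi_pixels: int = 100
    smoothing_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dose_threshold_fraction < 1.0:
            raise ValidationError("dose_threshold_fraction must be in (0, 1)")
        if self.gradient_limit_percent_per_mm <= 0:
            raise ValidationError("gradient limit must be positive")
        if self.min_roi_pixels < 1:
            raise ValidationError("min_roi_pixels must be >= 1")


@dataclass
class RoiMask:
    """Boolean ROI over the baseline image."""

    mask: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        if int(self.mask.sum()) != self.pixel_count:
            raise ValidationError("pixel_count inconsistent with mask")


@dataclass
class GdsaRecord:
    """One fraction's GDSA mean with its identity.

    ``status`` is ``"complete"`` or ``"omitted"``; omitted fractions (field
    count inconsistent with the baseline) carry NaN and are excluded from
    every downstream statistic.
    """

    patient_id: str
    plan_id: str
    date: dt.date
    fraction_index: int
    gdsa_percent: float
    status: str = "complete"
    n_fields: int = 1
    roi_pixels: int = 0


def segment_roi(baseline: EpidImage, params: RoiParams = RoiParams()) -> RoiMask:
    """Segment the high-dose, low-gradient ROI on a baseline image.

    A pixel qualifies iff (a) the smoothed baseline there reaches
    ``dose_threshold_fraction`` of the smoothed plateau maximum and (b) the
    local relative gradient magnitude (central differences of the smoothed
    image, normalized by the local value and converted to %/mm through the
    panel pixel pitch) does not exceed the gradient limit.

    Raises :class:`DegenerateFieldError` when the image carries no signal
    or fewer than ``min_roi_pixels`` pixels qualify.
    """
    smoothed = gaussian_filter(
        baseline.pixels.astype(np.float64), params.smoothing_sigma_px
    )
    peak = float(smoothed.max())
    if peak <= 0:
        raise DegenerateFieldError("baseline image has no positive signal")

    threshold = params.dose_threshold_fraction * peak
    pitch_row, pitch_col = baseline.geometry.pixel_pitch_mm
    grad_row, grad_col = np.gradient(smoothed)
    # relative gradient in % of local value per mm, per-axis pitch
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (
            100.0
            * np.hypot(grad_row / pitch_row, grad_col / pitch_col)
            / np.where(smoothed > 0, smoothed, np.inf)
        )
    mask = (smoothed >= threshold) & (rel <= params.gradient_limit_percent_per_mm)
    count = int(mask.sum())
    if count < params.min_roi_pixels:
        raise DegenerateFieldError(
            f"ROI of {count} pixels smaller than minimum {params.min_roi_pixels}"
        )
    return RoiMask(mask=mask, pixel_count=count)


def gdsa_mean(fraction: EpidImage, baseline: EpidImage, roi: RoiMask) -> float:
    """Mean per-pixel relative difference over the ROI, in percent.

    Returns ``100 * mean((fraction - baseline) / baseline)`` over ROI
    pixels.  The baseline is always the denominator; the metric is not
    symmetric.
    """
    if fraction.pixels.shape != baseline.pixels.shape:
        raise ValidationError("fraction and baseline shapes differ")
    if roi.mask.shape != baseline.pixels.shape:
        raise ValidationError("ROI shape does not match images")
    b = baseline.pixels[roi.mask]
    if np.any(b <= 0):
        raise ZeroBaselineError("zero baseline pixel inside ROI")
    f = fraction.pixels[roi.mask]
    return float(100.0 * np.mean((f - b) / b))


def course_gdsa(
    series: CourseSeries, params: RoiParams = RoiParams()
) -> list[GdsaRecord]:
    """Per-fraction GDSA means for a whole course.

    The ROI is segmented once per field on fraction 1 and frozen.  Each
    later fraction is validated against the baseline field set; complete
    fractions get the unweighted mean of per-field GDSA values paired by
    field id, omitted ones carry NaN and status ``"omitted"``.

    Raises :class:`DegenerateFieldError` (wrapped as a course-level error)
    if any baseline field fails segmentation.
    """
    if not series.fractions:
        raise ValidationError("course has no fractions")
    baseline = series.baseline

    rois: dict[str, tuple[EpidImage, RoiMask]] = {}
    for img in baseline.images:
        try:
            rois[img.field_id] = (img, segment_roi(img, params))
        except DegenerateFieldError as exc:
            raise DegenerateFieldError(
                f"course {series.patient_id}/{series.plan_id}: baseline field "
                f"{img.field_id} failed segmentation: {exc}"
            ) from exc
    roi_pixels = sum(roi.pixel_count for _, roi in rois.values())

    records: list[GdsaRecord] = []
    for group in series.fractions:
        if group is baseline:
            status, value = "complete", 0.0
        else:
            status = validate_fraction(group, baseline)
            if status == "complete":
                per_field = [
                    gdsa_mean(img, *rois[img.field_id]) for img in group.images
                ]
                value = float(np.mean(per_field))
            else:
                value = float("nan")
        records.append(
            GdsaRecord(
                patient_id=series.patient_id,
                plan_id=series.plan_id,
                date=group.date,
                fraction_index=group.fraction_index,
                gdsa_percent=value,
                status=status,
                n_fields=len(group.images),
                roi_pixels=roi_pixels,
            )
        )
    return records


RECORD_COLUMNS = [
    "patient_id",
    "plan_id",
    "date",
    "fraction_index",
    "gdsa_percent",
    "status",
    "n_fields",
    "roi_pixels",
]


def records_to_frame(records: Sequence[GdsaRecord]) -> pd.DataFrame:
    """Tabulate GDSA records (one row per fraction)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "plan_id": r.plan_id,
                "date": r.date.isoformat(),
                "fraction_index": r.fraction_index,
                "gdsa_percent": r.gdsa_percent,
                "status": r.status,
                "n_fields": r.n_fields,
                "roi_pixels": r.roi_pixels,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def records_from_frame(frame: pd.DataFrame) -> list[GdsaRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        GdsaRecord(
            patient_id=str(row.patient_id),
            plan_id=str(row.plan_id),
            date=dt.date.fromisoformat(str(row.date)),
            fraction_index=int(row.fraction_index),
            gdsa_percent=float(row.gdsa_percent),
            status=str(row.status),
            n_fields=int(row.n_fields),
            roi_pixels=int(row.roi_pixels),
        )
        for row in frame.itertuples(index=False)
    ]


def write_records_csv(records: Sequence[GdsaRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")
    return path


def read_records_csv(path: str | Path) -> list[GdsaRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str, "plan_id": str})
    return records_from_frame(frame)
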