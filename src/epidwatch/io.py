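"""Reading, writing, validating and sorting transit portal images.

Transit images are megavoltage portal images (DICOM modality ``RTIMAGE``)
acquired by the imaging panel during treatment, with the patient in the
beam.  Pixel values are in calibrated units (CU): 1 CU corresponds to the
panel signal produced by 1 monitor unit of a 10 x 10 cm open field with no
attenuator.  This module groups images into per-patient, per-plan courses
ordered by treatment date; the first fraction of a course is the baseline
every later fraction is compared against.

Identity is carried in DICOM tags, never in filenames.  The exact tags the
reader and the synthetic writer agree on are fixed in :data:`IDENTITY_TAGS`.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian

from .errors import (
    IdentityError,
    ModalityError,
    ParseError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: DICOM SOP class for RT Image Storage.
RTIMAGE_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.1"

#: Fixed implementation UID for files emitted by :func:`write_rtimage`.
IMPLEMENTATION_UID = "2.25.859437151121463826"

#: The identity tags the reader and writer agree on, bit-exactly.
IDENTITY_TAGS = {
    "patient_id": "PatientID",
    "plan_id": "SeriesDescription",
    "field_id": "RTImageLabel",
}

_DATE_FMT = "%Y%m%d"
_TIME_FMT = "%H%M%S.%f"


@dataclass(frozen=True)
class ImagingGeometry:
    """Fixed geometry of the transit imaging panel.

    Defaults describe a panel at 154 cm source-to-imager distance with a
    43 x 43 cm sensitive area, 1280 x 1280 pixel matrix, and a nominal
    28 x 28 cm projection at the isocenter plane.

    Parameters
    ----------
    source_imager_distance_mm : float
        Source-to-imager distance (mm).
    panel_mm : (float, float)
        Physical panel size, rows x cols (mm).
    matrix : (int, int)
        Pixel matrix, rows x cols.
    iso_projection_mm : (float, float)
        Size of the panel projected to the isocenter plane (mm).
    """

    source_imager_distance_mm: float = 1540.0
    panel_mm: tuple[float, float] = (430.0, 430.0)
    matrix: tuple[int, int] = (1280, 1280)
    iso_projection_mm: tuple[float, float] = (280.0, 280.0)

    def __post_init__(self) -> None:
        if self.source_imager_distance_mm <= 0:
            raise ValidationError("source-imager distance must be positive")
        if any(p <= 0 for p in self.panel_mm) or any(
            p <= 0 for p in self.iso_projection_mm
        ):
            raise ValidationError("panel dimensions must be positive")
        if any(m < 2 for m in self.matrix):
            raise ValidationError("matrix dimensions must be >= 2")

    @property
    def pixel_pitch_mm(self) -> tuple[float, float]:
        """Pixel pitch at the panel plane (mm/pixel)."""
        return (
            self.panel_mm[0] / self.matrix[0],
            self.panel_mm[1] / self.matrix[1],
        )

    @property
    def iso_pitch_mm(self) -> tuple[float, float]:
        """Pixel pitch projected to the isocenter plane (mm/pixel)."""
        return (
            self.iso_projection_mm[0] / self.matrix[0],
            self.iso_projection_mm[1] / self.matrix[1],
        )


@dataclass
class EpidImage:
    """One transit portal image in calibrated units plus its identity.

    ``pixels`` is a float array shaped like ``geometry.matrix``; values are
    non-negative CU.  Identity fields map to the DICOM tags in
    :data:`IDENTITY_TAGS`.
    """

    pixels: np.ndarray
    patient_id: str
    plan_id: str
    field_id: str
    acquisition: dt.datetime
    geometry: ImagingGeometry = field(default_factory=ImagingGeometry)

    @property
    def date(self) -> dt.date:
        return self.acquisition.date()

    def validate(self) -> "EpidImage":
        """Check type invariants, returning self for chaining."""
        if tuple(self.pixels.shape) != tuple(self.geometry.matrix):
            raise ValidationError(
                f"pixel shape {self.pixels.shape} does not match geometry "
                f"matrix {self.geometry.matrix}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("non-finite pixel values")
        if np.any(self.pixels < 0):
            raise ValidationError("negative CU values")
        for name in ("patient_id", "plan_id", "field_id"):
            if not getattr(self, name):
                raise ValidationError(f"missing identity field {name!r}")
        return self


@dataclass
class FractionGroup:
    """All fields imaged for one patient on one treatment date."""

    fraction_index: int
    date: dt.date
    images: list[EpidImage]

    @property
    def field_ids(self) -> list[str]:
        return [img.field_id for img in self.images]


@dataclass
class CourseSeries:
    """A date-ordered treatment course for one patient and plan."""

    patient_id: str
    plan_id: str
    fractions: list[FractionGroup]

    @property
    def baseline(self) -> FractionGroup:
        return self.fractions[0]


def _identity_uid(image: EpidImage) -> str:
    """Deterministic SOP instance UID derived from the identity tuple.

    Equal identity always maps to the same UID, which keeps the writer a
    pure function of its input (re-running a simulation rewrites identical
    files).
    """
    key = "|".join(
        [
            image.patient_id,
            image.plan_id,
            image.field_id,
            image.acquisition.isoformat(),
        ]
    )
    digest = int(hashlib.sha1(key.encode()).hexdigest(), 16) % 10**36
    return f"2.25.{digest}"


def write_rtimage(image: EpidImage, path: str | Path) -> Path:
    """Write an :class:`EpidImage` as a standards-conformant RTIMAGE file.

    CU values are stored as unsigned 16-bit integers with a per-file rescale
    slope ``max_CU / 65535`` (slope 1 for an all-zero image), bounding the
    quantization error of any pixel by half of one stored step.
    """
    image.validate()
    path = Path(path)

    max_cu = float(image.pixels.max())
    slope = max_cu / 65535.0 if max_cu > 0 else 1.0
    stored = np.round(image.pixels / slope).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTIMAGE_SOP_CLASS_UID
    meta.MediaStorageSOPInstanceUID = _identity_uid(image)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = IMPLEMENTATION_UID

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RTIMAGE_SOP_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.PatientID = image.patient_id
    ds.SeriesDescription = image.plan_id
    ds.RTImageLabel = image.field_id
    ds.AcquisitionDate = image.acquisition.strftime(_DATE_FMT)
    ds.AcquisitionTime = image.acquisition.strftime(_TIME_FMT)
    ds.ContentDate = ds.AcquisitionDate

    geo = image.geometry
    ds.RTImageSID = f"{geo.source_imager_distance_mm:.10g}"
    ds.ImagePlanePixelSpacing = [
        f"{geo.pixel_pitch_mm[0]:.10g}",
        f"{geo.pixel_pitch_mm[1]:.10g}",
    ]

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = "0"
    ds.PixelData = stored.tobytes()

    try:
        ds.save_as(path, enforce_file_format=True)
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write RTIMAGE to {path}: {exc}") from exc
    return path


def read_rtimage(path: str | Path) -> EpidImage:
    """Read a transit image from an RTIMAGE DICOM file.

    Stored values are mapped to CU through the file's rescale slope and
    intercept.  A plain-text fallback (``.txt`` matrix + ``.json`` sidecar,
    see :func:`write_array_image`) is accepted for language-portable
    fixtures.

    Raises
    ------
    ParseError
        The file is not parseable DICOM.
    ModalityError
        The file's modality is not ``RTIMAGE``.
    ValidationError
        Pixel data or identity tags are missing.
    """
    path = Path(path)
    if path.suffix == ".txt":
        return read_array_image(path)
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, AttributeError, ValueError) as exc:
        raise ParseError(f"{path} is not a DICOM file: {exc}") from exc

    modality = getattr(ds, "Modality", None)
    if modality != "RTIMAGE":
        raise ModalityError(f"{path}: modality {modality!r}, expected RTIMAGE")

    for attr in (*IDENTITY_TAGS.values(), "AcquisitionDate"):
        if getattr(ds, attr, None) in (None, ""):
            raise ValidationError(f"{path}: missing tag {attr}")
    if "PixelData" not in ds:
        raise ValidationError(f"{path}: missing pixel data")

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(np.float64) * slope + intercept

    rows, cols = int(ds.Rows), int(ds.Columns)
    sid = float(getattr(ds, "RTImageSID", 1540.0))
    spacing = getattr(ds, "ImagePlanePixelSpacing", None)
    if spacing is not None:
        panel = (float(spacing[0]) * rows, float(spacing[1]) * cols)
    else:
        panel = (430.0, 430.0)
    iso = (panel[0] * 1000.0 / sid, panel[1] * 1000.0 / sid)
    geometry = ImagingGeometry(sid, panel, (rows, cols), iso)

    time_str = str(getattr(ds, "AcquisitionTime", "000000"))
    acquisition = _parse_datetime(str(ds.AcquisitionDate), time_str)

    return EpidImage(
        pixels=pixels,
        patient_id=str(ds.PatientID),
        plan_id=str(ds.SeriesDescription),
        field_id=str(ds.RTImageLabel),
        acquisition=acquisition,
        geometry=geometry,
    ).validate()


def _parse_datetime(date_str: str, time_str: str) -> dt.datetime:
    day = dt.datetime.strptime(date_str, _DATE_FMT).date()
    time_str = time_str or "000000"
    fmt = _TIME_FMT if "." in time_str else "%H%M%S"
    t = dt.datetime.strptime(time_str, fmt).time()
    return dt.datetime.combine(day, t)


def write_array_image(image: EpidImage, path: str | Path) -> Path:
    """Plain-array fallback writer: one text matrix + a JSON sidecar.

    Intended for small, human-inspectable fixtures; the DICOM path is the
    primary interchange format.
    """
    image.validate()
    path = Path(path)
    np.savetxt(path, image.pixels, fmt="%.9g")
    geo = image.geometry
    sidecar = {
        "patient_id": image.patient_id,
        "plan_id": image.plan_id,
        "field_id": image.field_id,
        "acquisition": image.acquisition.isoformat(),
        "geometry": {
            "source_imager_distance_mm": geo.source_imager_distance_mm,
            "panel_mm": list(geo.panel_mm),
            "matrix": list(geo.matrix),
            "iso_projection_mm": list(geo.iso_projection_mm),
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_array_image(path: str | Path) -> EpidImage:
    """Read an image written by :func:`write_array_image`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"{path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    g = meta["geometry"]
    geometry = ImagingGeometry(
        g["source_imager_distance_mm"],
        tuple(g["panel_mm"]),
        tuple(g["matrix"]),
        tuple(g["iso_projection_mm"]),
    )
    pixels = np.loadtxt(path, ndmin=2)
    return EpidImage(
        pixels=pixels,
        patient_id=meta["patient_id"],
        plan_id=meta["plan_id"],
        field_id=meta["field_id"],
        acquisition=dt.datetime.fromisoformat(meta["acquisition"]),
        geometry=geometry,
    ).validate()


def scan_directory(input_dir: str | Path) -> list[EpidImage]:
    """Recursively read every transit image under ``input_dir``.

    Files that fail to parse or validate are logged and skipped; a nightly
    batch must not abort on one bad file.  Sorting downstream uses tags
    only, never filenames.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise OSError(f"input directory {input_dir} is not readable")
    images: list[EpidImage] = []
    for path in sorted(input_dir.rglob("*")):
        if path.suffix not in (".dcm", ".txt"):
            continue
        try:
            images.append(read_rtimage(path))
        except (ParseError, ModalityError, ValidationError) as exc:
            log.warning("skipping %s: %s", path, exc)
    return images


def _pixel_digest(image: EpidImage) -> str:
    return hashlib.sha1(np.ascontiguousarray(image.pixels).tobytes()).hexdigest()


def sort_images(images: Iterable[EpidImage]) -> list[CourseSeries]:
    """Group images into courses by patient, plan, and acquisition date.

    One :class:`CourseSeries` per (patient_id, plan_id); images sharing a
    calendar date form one :class:`FractionGroup`; groups are
    date-ordered and fraction indices assigned 1..n chronologically.  The
    result is a pure function of the input *set*: any permutation of the
    input list yields identical output.

    A field imaged twice on one date (a re-imaged field) keeps only the
    latest acquisition; two distinct sessions on one date therefore
    collapse into a single fraction.
    """
    courses: dict[tuple[str, str], list[EpidImage]] = {}
    for img in images:
        courses.setdefault((img.patient_id, img.plan_id), []).append(img)

    out: list[CourseSeries] = []
    for (pid, plan) in sorted(courses):
        by_date: dict[dt.date, dict[str, EpidImage]] = {}
        for img in courses[(pid, plan)]:
            fields = by_date.setdefault(img.date, {})
            prev = fields.get(img.field_id)
            if prev is None or (img.acquisition, _pixel_digest(img)) > (
                prev.acquisition,
                _pixel_digest(prev),
            ):
                fields[img.field_id] = img
        fractions = [
            FractionGroup(
                fraction_index=i + 1,
                date=day,
                images=[by_date[day][fid] for fid in sorted(by_date[day])],
            )
            for i, day in enumerate(sorted(by_date))
        ]
        out.append(CourseSeries(pid, plan, fractions))
    return out


def validate_fraction(group: FractionGroup, baseline: FractionGroup) -> str:
    """Check a fraction's completeness against the baseline fraction.

    A fraction whose imaged field set differs from the baseline's (for
    example after a beam interruption) would carry a falsely high mean
    difference, so it is marked ``"omitted"`` and excluded from all
    downstream statistics; otherwise ``"complete"``.

    Raises :class:`IdentityError` if the two groups belong to different
    courses or either group repeats a field id.
    """
    for grp, name in ((group, "group"), (baseline, "baseline")):
        ids = grp.field_ids
        if len(ids) != len(set(ids)):
            raise IdentityError(f"duplicate field ids in {name}: {ids}")
    key = {(img.patient_id, img.plan_id) for img in group.images} | {
        (img.patient_id, img.plan_id) for img in baseline.images
    }
    if len(key) > 1:
        raise IdentityError(f"fraction groups from different courses: {key}")
    return "complete" if set(group.field_ids) == set(baseline.field_ids) else "omitted"
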