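"""Shared fixtures: a scaled-down imaging geometry and simulation configs.

The simulator runs on a 96 x 96 panel matrix in tests (same physical
panel size and source-imager distance as the clinical default); the GDSA
metric is a per-pixel relative mean and is resolution-independent.
"""

import datetime as dt

import numpy as np
import pytest

import epidwatch as ew

SMALL_MATRIX = (96, 96)


@pytest.fixture(scope="session")
def geometry():
    return ew.ImagingGeometry(matrix=SMALL_MATRIX)


@pytest.fixture(scope="session")
def phantom():
    return ew.PhantomModel()


@pytest.fixture
def make_config(geometry):
    """Factory for CourseConfig on the small test geometry."""

    def _make(**kwargs):
        kwargs.setdefault("geometry", geometry)
        kwargs.setdefault("noise_sd_percent", 0.0)
        return ew.CourseConfig(**kwargs)

    return _make


@pytest.fixture
def make_image(geometry):
    """Factory for a bare EpidImage with given pixels / identity."""

    def _make(
        pixels=None,
        patient_id="P1",
        plan_id="PLAN1",
        field_id="F1",
        when=dt.datetime(2021, 3, 1, 20, 0, 0),
        geom=None,
    ):
        geom = geom or geometry
        if pixels is None:
            pixels = np.ones(geom.matrix)
        return ew.EpidImage(
            pixels=np.asarray(pixels, dtype=float),
            patient_id=patient_id,
            plan_id=plan_id,
            field_id=field_id,
            acquisition=when,
            geometry=geom,
        )

    return _make


def make_record(
    gdsa,
    fraction,
    date=None,
    patient_id="P1",
    plan_id="PLAN1",
    status="complete",
):
    """Bare GdsaRecord helper for surveillance/rule tests."""
    if date is None:
        date = dt.date(2021, 3, 1) + dt.timedelta(days=fraction - 1)
    return ew.GdsaRecord(
        patient_id=patient_id,
        plan_id=plan_id,
        date=date,
        fraction_index=fraction,
        gdsa_percent=gdsa,
        status=status,
    )


def make_trace(values, patient_id="P1", **kwargs):
    """A course trace of records from a list of GDSA values."""
    return [
        make_record(v, f, patient_id=patient_id, **kwargs)
        for f, v in enumerate(values, start=1)
    ]
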