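"""Three-level flagging of GDSA records and daily clinic statistics.

Three alert rules run over the per-fraction GDSA means:

* **Type-A** - one fraction deviating by more than ±10 %: protects
  against large acute errors (machine malfunction, gross setup error).
* **Type-B** - three consecutive fractions deviating by more than ±3 %:
  protects against systematic trends (weight loss, tumor shrinkage).
* **MACHINE** - the clinic-wide daily mean changing by more than 1 %
  between two consecutive treatment days: an output or imager
  calibration shift.

"Deviation of ±X%" is interpreted as strict magnitude exceedance
(|GDSA| > X); boundary equality never flags.  Consecutiveness is counted
over complete (non-omitted) fractions in date order, and "consecutive
treatment days" means adjacent entries of the treated-day sequence
(weekends and holidays are skipped).  Omitted fractions never contribute
to flags or summaries.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .gdsa import GdsaRecord
from .io import CourseSeries

TYPE_A = "TYPE_A"
TYPE_B = "TYPE_B"
MACHINE = "MACHINE"


@dataclass(frozen=True)
class FlagConfig:
    """Thresholds of the three flag rules (all percent, all strict).

    ``type_b_same_sign`` optionally requires a Type-B run to share one
    sign; the default counts magnitude only.
    """

    type_a_threshold_percent: float = 10.0
    type_b_threshold_percent: float = 3.0
    type_b_run_length: int = 3
    machine_threshold_percent: float = 1.0
    type_b_same_sign: bool = False

    def __post_init__(self) -> None:
        if min(
            self.type_a_threshold_percent,
            self.type_b_threshold_percent,
            self.machine_threshold_percent,
        ) <= 0:
            raise ValidationError("all thresholds must be positive")
        if self.type_b_run_length < 1:
            raise ValidationError("run length must be >= 1")


@dataclass
class Flag:
    """A raised alert.

    Patient flags carry the triggering fraction indices; a MACHINE flag
    carries the two adjacent treatment dates and their daily means.
    """

    kind: str
    patient_id: str | None
    plan_id: str | None
    trigger_fractions: list[int] = field(default_factory=list)
    trigger_dates: list[dt.date] = field(default_factory=list)
    values_percent: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "patient_id": self.patient_id,
            "plan_id": self.plan_id,
            "trigger_fractions": self.trigger_fractions,
            "trigger_dates": [d.isoformat() for d in self.trigger_dates],
            "values_percent": self.values_percent,
        }


@dataclass
class DailySummary:
    """Clinic-wide GDSA distribution for one treatment day.

    The mean estimates the change in machine output; the standard
    deviation estimates patient variability.  SD is undefined (None) when
    only one fraction was treated.
    """

    date: dt.date
    n_fractions: int
    mean_percent: float
    sd_percent: float | None


def _complete(records: Sequence[GdsaRecord]) -> list[GdsaRecord]:
    return [r for r in records if r.status == "complete"]


def flag_type_a(
    records: Sequence[GdsaRecord], config: FlagConfig = FlagConfig()
) -> list[Flag]:
    """One flag per fraction whose |GDSA| strictly exceeds the Type-A threshold.

    Fraction 1 is the baseline (value 0 by construction) and can never flag.
    """
    flags = []
    for r in _complete(records):
        if abs(r.gdsa_percent) > config.type_a_threshold_percent:
            flags.append(
                Flag(
                    kind=TYPE_A,
                    patient_id=r.patient_id,
                    plan_id=r.plan_id,
                    trigger_fractions=[r.fraction_index],
                    values_percent=[r.gdsa_percent],
                )
            )
    return flags


def flag_type_b(
    records: Sequence[GdsaRecord], config: FlagConfig = FlagConfig()
) -> list[Flag]:
    """One flag per maximal run of consecutive over-threshold fractions.

    Omitted fractions are removed before consecutiveness is evaluated.  A
    maximal run of at least ``type_b_run_length`` complete fractions, each
    with |GDSA| strictly above the Type-B threshold, raises exactly one
    flag carrying every fraction of the run (one alert per trend, no
    duplicate per-window alerts).
    """
    ordered = sorted(_complete(records), key=lambda r: (r.date, r.fraction_index))
    flags: list[Flag] = []
    run: list[GdsaRecord] = []

    def close_run() -> None:
        if len(run) >= config.type_b_run_length:
            trigger = list(run)
            flags.append(
                Flag(
                    kind=TYPE_B,
                    patient_id=run[0].patient_id,
                    plan_id=run[0].plan_id,
                    trigger_fractions=[r.fraction_index for r in trigger],
                    values_percent=[r.gdsa_percent for r in trigger],
                )
            )
        run.clear()

    for r in ordered:
        exceeds = abs(r.gdsa_percent) > config.type_b_threshold_percent
        if exceeds and config.type_b_same_sign and run:
            if np.sign(r.gdsa_percent) != np.sign(run[-1].gdsa_percent):
                close_run()
        if exceeds:
            run.append(r)
        else:
            close_run()
    close_run()
    return flags


def daily_summary(records: Sequence[GdsaRecord]) -> DailySummary | None:
    """Mean and sample SD of GDSA across all complete records of one date.

    Returns None when the date has no complete records (empty-day signal).
    """
    complete = _complete(records)
    if not complete:
        return None
    dates = {r.date for r in complete}
    if len(dates) != 1:
        raise ValidationError(f"records span multiple dates: {sorted(dates)}")
    values = np.array([r.gdsa_percent for r in complete])
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return DailySummary(
        date=complete[0].date,
        n_fractions=len(values),
        mean_percent=float(values.mean()),
        sd_percent=sd,
    )


def daily_summaries(records: Sequence[GdsaRecord]) -> list[DailySummary]:
    """Per-day summaries over all patients, date-ordered."""
    by_date: dict[dt.date, list[GdsaRecord]] = {}
    for r in _complete(records):
        by_date.setdefault(r.date, []).append(r)
    out = []
    for day in sorted(by_date):
        summary = daily_summary(by_date[day])
        if summary is not None:
            out.append(summary)
    return out


def machine_output_flags(
    summaries: Sequence[DailySummary], config: FlagConfig = FlagConfig()
) -> list[Flag]:
    """Flag adjacent treated days whose means differ by more than the threshold.

    "Consecutive" means adjacent in the treated-day sequence - a Friday
    and the following Monday are consecutive treatment days.
    """
    ordered = sorted(summaries, key=lambda s: s.date)
    flags = []
    for prev, cur in zip(ordered, ordered[1:]):
        if abs(cur.mean_percent - prev.mean_percent) > config.machine_threshold_percent:
            flags.append(
                Flag(
                    kind=MACHINE,
                    patient_id=None,
                    plan_id=None,
                    trigger_dates=[prev.date, cur.date],
                    values_percent=[prev.mean_percent, cur.mean_percent],
                )
            )
    return flags


def summaries_to_frame(summaries: Sequence[DailySummary]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "date": s.date.isoformat(),
                "n_fractions": s.n_fractions,
                "mean_percent": s.mean_percent,
                "sd_percent": s.sd_percent,
            }
            for s in summaries
        ],
        columns=["date", "n_fractions", "mean_percent", "sd_percent"],
    )


def build_report(
    flag: Flag,
    records: Sequence[GdsaRecord],
    out_dir: str | Path,
    images: CourseSeries | None = None,
    *,
    plot: bool = True,
) -> Path:
    """Write a report bundle for one flag.

    The bundle directory (named deterministically from flag identity and
    date) holds ``summary.json`` - flag kind, identity, triggers, values
    and the full complete-fraction GDSA trace - plus a trace plot and,
    when the course images are supplied, baseline/trigger difference
    panels.  Identical inputs produce a byte-identical ``summary.json``.
    """
    complete = _complete(records)
    if flag.kind in (TYPE_A, TYPE_B):
        have = {r.fraction_index for r in complete
                if r.patient_id == flag.patient_id and r.plan_id == flag.plan_id}
        missing = set(flag.trigger_fractions) - have
        if missing:
            raise ValidationError(
                f"flag references fractions absent from records: {sorted(missing)}"
            )
        stamp = min(
            r.date for r in complete
            if r.patient_id == flag.patient_id
            and r.fraction_index in flag.trigger_fractions
        )
        name = f"{flag.kind}_{flag.patient_id}_{flag.plan_id}_{stamp.isoformat()}"
        trace = [
            {"fraction": r.fraction_index, "date": r.date.isoformat(),
             "gdsa_percent": r.gdsa_percent}
            for r in sorted(
                (r for r in complete if r.patient_id == flag.patient_id
                 and r.plan_id == flag.plan_id),
                key=lambda r: r.fraction_index,
            )
        ]
    else:
        name = f"{flag.kind}_{flag.trigger_dates[1].isoformat()}"
        trace = []

    bundle = Path(out_dir) / name
    bundle.mkdir(parents=True, exist_ok=True)
    summary = {"flag": flag.to_dict(), "trace": trace}
    if flag.kind == MACHINE:
        summary["daily_mean_difference_percent"] = (
            flag.values_percent[1] - flag.values_percent[0]
        )
    (bundle / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    if plot:
        _plot_trace(flag, trace, bundle / "trace.png")
    if images is not None and flag.kind in (TYPE_A, TYPE_B):
        _plot_difference_panels(flag, images, bundle)
    return bundle


def _plot_trace(flag: Flag, trace: list[dict], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    if trace:
        ax.plot(
            [t["fraction"] for t in trace],
            [t["gdsa_percent"] for t in trace],
            "o-",
            ms=4,
        )
        ax.set_xlabel("fraction")
    else:
        ax.plot(range(len(flag.values_percent)), flag.values_percent, "o-")
        ax.set_xlabel("treatment day")
    for fx in flag.trigger_fractions:
        ax.axvline(fx, color="r", lw=0.8, alpha=0.5)
    ax.set_ylabel("GDSA mean (%)")
    ax.set_title(f"{flag.kind} flag")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_difference_panels(flag: Flag, images: CourseSeries, bundle: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    baseline = {img.field_id: img for img in images.baseline.images}
    for group in images.fractions:
        if group.fraction_index not in flag.trigger_fractions:
            continue
        for img in group.images:
            base = baseline.get(img.field_id)
            if base is None:
                continue
            fig, axes = plt.subplots(1, 3, figsize=(9, 3))
            for ax, (data, title) in zip(
                axes,
                [
                    (base.pixels, "baseline"),
                    (img.pixels, f"fraction {group.fraction_index}"),
                    (img.pixels - base.pixels, "difference"),
                ],
            ):
                im = ax.imshow(data, cmap="viridis")
                ax.set_title(title, fontsize=8)
                ax.axis("off")
                fig.colorbar(im, ax=ax, fraction=0.046)
            fig.tight_layout()
            fig.savefig(
                bundle / f"diff_fx{group.fraction_index:03d}_{img.field_id}.png",
                dpi=80,
            )
            plt.close(fig)
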