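"""CSV schemas, readers/writers and input validation.

All files are UTF-8, comma-separated, header row required, ISO-8601 dates.
Internally dates are integer day indices relative to a study epoch
(default 2014-11-01); conversion happens only here.

Schemas
-------
activities.csv     city,category,activity_id,start_date,hours,boost
registrations.csv  city,date,count
participants.csv   id,city,registration_date,gender,age_years,education,
                   employment,source,baseline_started,baseline_finalized,
                   n_questionnaires,withdrawn
census.csv         city,margin,class,share        (margin in {gender, age})
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .metrics import participants_frame
from .types import (
    ActivityRecord,
    CensusMarginals,
    EDUCATION_LEVELS,
    EMPLOYMENT_LEVELS,
    GENDERS,
    InputError,
    ParticipantRecord,
    RegistrationSeries,
    SOURCES,
)

__all__ = [
    "DEFAULT_EPOCH",
    "Diagnostic",
    "ValidationReport",
    "day_to_date",
    "date_to_day",
    "write_activities",
    "read_activities",
    "write_registrations",
    "read_registrations",
    "write_participants",
    "read_participants",
    "write_census",
    "read_census",
    "validate_inputs",
]

DEFAULT_EPOCH = "2014-11-01"


def day_to_date(day, epoch: str = DEFAULT_EPOCH):
    return (pd.Timestamp(epoch) + pd.to_timedelta(day, unit="D")).strftime("%Y-%m-%d")


def date_to_day(date, epoch: str = DEFAULT_EPOCH):
    return (pd.to_datetime(date) - pd.Timestamp(epoch)).days


# ---------------------------------------------------------------- writers

def write_activities(
    activities: Iterable[ActivityRecord], path, epoch: str = DEFAULT_EPOCH
) -> None:
    df = pd.DataFrame(
        [
            {
                "city": a.city,
                "category": a.category,
                "activity_id": a.activity_id,
                "start_date": day_to_date(a.start_day, epoch),
                "hours": a.hours,
                "boost": a.boost,
            }
            for a in activities
        ]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_activities(path, epoch: str = DEFAULT_EPOCH) -> list[ActivityRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ActivityRecord(
            city=str(r.city),
            category=str(r.category),
            activity_id=str(r.activity_id),
            start_day=int(date_to_day(r.start_date, epoch)),
            hours=float(r.hours),
            boost=float(getattr(r, "boost", 1.0)),
        )
        for r in df.itertuples()
    ]


def write_registrations(
    series: Iterable[RegistrationSeries] | RegistrationSeries,
    path,
    epoch: str = DEFAULT_EPOCH,
) -> None:
    if isinstance(series, RegistrationSeries):
        series = [series]
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "city": s.city,
                    "date": [day_to_date(d, epoch) for d in s.days],
                    "count": s.counts.astype(int)
                    if np.allclose(s.counts, np.rint(s.counts))
                    else s.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_registrations(path, epoch: str = DEFAULT_EPOCH) -> list[RegistrationSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for city, g in df.groupby("city", sort=True):
        days = np.array([date_to_day(d, epoch) for d in g["date"]])
        order = np.argsort(days)
        out.append(
            RegistrationSeries(
                city=str(city),
                days=days[order],
                counts=g["count"].to_numpy(dtype=float)[order],
            )
        )
    return out


def write_participants(
    participants: Iterable[ParticipantRecord], path, epoch: str = DEFAULT_EPOCH
) -> None:
    df = participants_frame(participants).drop(columns=["age_class"])
    df["registration_date"] = [
        day_to_date(d, epoch) for d in df.pop("registration_day")
    ]
    cols = [
        "id", "city", "registration_date", "gender", "age_years", "education",
        "employment", "source", "baseline_started", "baseline_finalized",
        "n_questionnaires", "withdrawn",
    ]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_participants(path, epoch: str = DEFAULT_EPOCH) -> list[ParticipantRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ParticipantRecord(
            id=str(r.id),
            city=str(r.city),
            registration_day=int(date_to_day(r.registration_date, epoch)),
            gender=str(r.gender),
            age_years=None if pd.isna(r.age_years) else float(r.age_years),
            education=str(r.education),
            employment=str(r.employment),
            source=str(r.source),
            baseline_started=bool(r.baseline_started),
            baseline_finalized=bool(r.baseline_finalized),
            n_questionnaires=int(r.n_questionnaires),
            withdrawn=bool(r.withdrawn),
        )
        for r in df.itertuples()
    ]


def write_census(census: Iterable[CensusMarginals], path) -> None:
    """Emit per-margin shares (city,margin,class,share)."""
    rows = []
    for c in census:
        for margin in ("gender", "age"):
            for cls, share in sorted(c.margin_shares(margin).items()):
                rows.append(
                    {"city": c.city, "margin": margin, "class": cls, "share": share}
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_census(path) -> list[CensusMarginals]:
    """Reconstruct joint gender x age cells as the product of the two
    margins (independence within city is assumed at the file boundary)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for city, g in df.groupby("city", sort=True):
        gender = dict(
            zip(g[g["margin"] == "gender"]["class"], g[g["margin"] == "gender"]["share"])
        )
        age = dict(
            zip(g[g["margin"] == "age"]["class"], g[g["margin"] == "age"]["share"])
        )
        if not gender or not age:
            raise InputError(f"census for {city!r} needs both gender and age margins")
        cells = {(gk, ak): gv * av for gk, gv in gender.items() for ak, av in age.items()}
        tot = sum(cells.values())
        cells = {k: v / tot for k, v in cells.items()}
        out.append(CensusMarginals(city=str(city), cells=cells))
    return out


# ------------------------------------------------------------- validation

@dataclass(frozen=True)
class Diagnostic:
    file: str
    line: Optional[int]  # 1-based data line in the CSV (header = line 1)
    column: Optional[str]
    rule: str
    message: str


@dataclass
class ValidationReport:
    diagnostics: list[Diagnostic] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.diagnostics

    def add(self, file, line, column, rule, message) -> None:
        self.diagnostics.append(Diagnostic(str(file), line, column, rule, message))


def _check_columns(df, required, path, report) -> bool:
    missing = [c for c in required if c not in df.columns]
    for c in missing:
        report.add(path, 1, c, "required-column", f"missing column {c!r}")
    return not missing


def validate_inputs(
    activities: Optional[str] = None,
    registrations: Optional[str] = None,
    participants: Optional[str] = None,
    census: Optional[str] = None,
) -> ValidationReport:
    """Validate input CSVs against their schemas; every violation is
    reported with file, line, column and rule."""
    report = ValidationReport()

    if activities is not None:
        try:
            df = pd.read_csv(activities)
        except OSError as exc:
            raise InputError(f"cannot read {activities}: {exc}") from exc
        if _check_columns(
            df, ["city", "category", "activity_id", "start_date", "hours"],
            activities, report,
        ):
            for i, r in enumerate(df.itertuples(), start=2):
                if pd.isna(pd.to_datetime(r.start_date, errors="coerce")):
                    report.add(activities, i, "start_date", "iso-date",
                               f"unparseable date {r.start_date!r}")
                if not pd.isna(r.hours) and r.hours < 0:
                    report.add(activities, i, "hours", "range",
                               f"hours must be >= 0, got {r.hours}")
                boost = getattr(r, "boost", 1.0)
                if not pd.isna(boost) and boost <= 0:
                    report.add(activities, i, "boost", "range",
                               f"boost must be > 0, got {boost}")

    if registrations is not None:
        try:
            df = pd.read_csv(registrations)
        except OSError as exc:
            raise InputError(f"cannot read {registrations}: {exc}") from exc
        if _check_columns(df, ["city", "date", "count"], registrations, report):
            for i, r in enumerate(df.itertuples(), start=2):
                if pd.isna(pd.to_datetime(r.date, errors="coerce")):
                    report.add(registrations, i, "date", "iso-date",
                               f"unparseable date {r.date!r}")
                if not pd.isna(r.count) and r.count < 0:
                    report.add(registrations, i, "count", "range",
                               f"count must be >= 0, got {r.count}")
            for city, g in df.groupby("city"):
                days = pd.to_datetime(g["date"], errors="coerce").dropna()
                d = np.sort(days.dt.normalize().unique())
                if d.size > 1 and np.any(np.diff(d) != np.timedelta64(1, "D")):
                    report.add(registrations, None, "date", "contiguity",
                               f"city {city!r}: dates must be consecutive days")

    if participants is not None:
        try:
            df = pd.read_csv(participants)
        except OSError as exc:
            raise InputError(f"cannot read {participants}: {exc}") from exc
        required = [
            "id", "city", "registration_date", "gender", "source",
            "baseline_started", "baseline_finalized", "n_questionnaires",
            "withdrawn",
        ]
        if _check_columns(df, required, participants, report):
            for i, r in enumerate(df.itertuples(), start=2):
                if r.gender not in GENDERS:
                    report.add(participants, i, "gender", "category",
                               f"unknown gender {r.gender!r}")
                if r.source not in SOURCES:
                    report.add(participants, i, "source", "category",
                               f"unknown source {r.source!r}")
                if "education" in df.columns and r.education not in EDUCATION_LEVELS:
                    report.add(participants, i, "education", "category",
                               f"unknown education {r.education!r}")
                if "employment" in df.columns and r.employment not in EMPLOYMENT_LEVELS:
                    report.add(participants, i, "employment", "category",
                               f"unknown employment {r.employment!r}")
                if bool(r.baseline_finalized) and not bool(r.baseline_started):
                    report.add(participants, i, "baseline_finalized", "monotonicity",
                               "finalized baseline without starting it")
                if r.n_questionnaires < 0:
                    report.add(participants, i, "n_questionnaires", "range",
                               "must be >= 0")

    if census is not None:
        try:
            df = pd.read_csv(census)
        except OSError as exc:
            raise InputError(f"cannot read {census}: {exc}") from exc
        if _check_columns(df, ["city", "margin", "class", "share"], census, report):
            for i, r in enumerate(df.itertuples(), start=2):
                if r.margin not in ("gender", "age"):
                    report.add(census, i, "margin", "category",
                               f"margin must be gender|age, got {r.margin!r}")
                if not pd.isna(r.share) and not (0 <= r.share <= 1):
                    report.add(census, i, "share", "range",
                               f"share must be in [0,1], got {r.share}")
            for (city, margin), g in df.groupby(["city", "margin"]):
                tot = g["share"].sum()
                if abs(tot - 1.0) > 1e-6:
                    report.add(census, None, "share", "normalisation",
                               f"{city!r}/{margin}: shares sum to {tot:.6f}, not 1")

    return report
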