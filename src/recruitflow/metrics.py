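"""Deterministic cohort bookkeeping: attrition, withdrawal, recruitment-source
and demographic composition tables, and time efficiency of recruitment.

All percentages are kept at full precision internally; ``round_half_up``
applies the display convention (half-up, 2 decimals)."""

from __future__ import annotations

import decimal
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    ActivityRecord,
    FunnelCounts,
    InputError,
    ParticipantRecord,
    SOURCES,
)

__all__ = [
    "round_half_up",
    "participants_frame",
    "funnel_counts",
    "funnel_by_city",
    "attrition_rates",
    "withdrawal_rate",
    "source_table",
    "demographics_table",
    "time_efficiency",
]

_GROUPING_COLUMNS = {
    "overall": None,
    "gender": "gender",
    "city": "city",
    "age_class": "age_class",
    "education": "education",
    "employment": "employment",
}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the usual print convention), e.g.
    ``round_half_up(0.125, 2) == 0.13``."""
    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def participants_frame(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of participant records (adds the derived
    ``age_class`` column)."""
    rows = [
        {
            "id": p.id,
            "city": p.city,
            "registration_day": p.registration_day,
            "gender": p.gender,
            "age_years": p.age_years,
            "age_class": p.age_class,
            "education": p.education,
            "employment": p.employment,
            "source": p.source,
            "baseline_started": p.baseline_started,
            "baseline_finalized": p.baseline_finalized,
            "n_questionnaires": p.n_questionnaires,
            "withdrawn": p.withdrawn,
        }
        for p in participants
    ]
    return pd.DataFrame(rows)


def funnel_counts(participants: Iterable[ParticipantRecord]) -> FunnelCounts:
    """Overall registered / started / finalized counts."""
    ps = list(participants)
    return FunnelCounts(
        registered=len(ps),
        started=sum(p.baseline_started for p in ps),
        finalized=sum(p.baseline_finalized for p in ps),
    )


def funnel_by_city(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Funnel counts and attrition rates per city plus a total row."""
    df = participants_frame(participants)
    rows = []
    groups = [(c, g) for c, g in df.groupby("city")] + [("total", df)]
    for city, g in groups:
        f = FunnelCounts(
            registered=len(g),
            started=int(g["baseline_started"].sum()),
            finalized=int(g["baseline_finalized"].sum()),
        )
        rate_a, rate_b = attrition_rates(f)
        rows.append(
            {
                "city": city,
                "registered": f.registered,
                "started": f.started,
                "finalized": f.finalized,
                "attrition_registration_pct": rate_a,
                "attrition_baseline_pct": rate_b,
            }
        )
    return pd.DataFrame(rows)


def attrition_rates(funnel: FunnelCounts) -> tuple[float, float]:
    """Percent lost at each funnel stage.

    rate_a = 100 (registered - started) / registered — registrants who never
    started the baseline questionnaire; rate_b = 100 (started - finalized) /
    started — starters who never finalized it.  Full precision is returned;
    apply :func:`round_half_up` for display.
    """
    if funnel.registered <= 0:
        raise InputError("attrition undefined: zero registrations")
    rate_a = 100.0 * (funnel.registered - funnel.started) / funnel.registered
    if funnel.started <= 0:
        raise InputError("attrition undefined: zero baseline starters")
    rate_b = 100.0 * (funnel.started - funnel.finalized) / funnel.started
    return rate_a, rate_b


def withdrawal_rate(
    participants: Iterable[ParticipantRecord], by: Optional[str] = None
) -> pd.Series:
    """Percent of baseline starters who actively withdrew, per group.

    The denominator is participants who started the baseline questionnaire,
    not all registrants.  Groups without starters are omitted with a
    warning.
    """
    df = participants_frame(participants)
    starters = df[df["baseline_started"]]
    if by is None:
        if len(starters) == 0:
            raise InputError("withdrawal rate undefined: no baseline starters")
        rate = 100.0 * starters["withdrawn"].sum() / len(starters)
        return pd.Series({"overall": rate}, name="withdrawal_pct")
    if by not in _GROUPING_COLUMNS or _GROUPING_COLUMNS[by] is None:
        raise InputError(f"unknown grouping {by!r}")
    col = _GROUPING_COLUMNS[by]
    out = {}
    for level in df[col].unique():
        g = starters[starters[col] == level]
        if len(g) == 0:
            warnings.warn(f"group {level!r} has no baseline starters; omitted",
                          stacklevel=2)
            continue
        out[level] = 100.0 * g["withdrawn"].sum() / len(g)
    return pd.Series(out, name="withdrawal_pct").sort_index()


def source_table(
    participants: Iterable[ParticipantRecord], by: str = "overall"
) -> pd.DataFrame:
    """How participants found out about the survey: counts and row
    percentages per group.

    Tidy output with one row per (group, source): columns ``group``,
    ``source``, ``n``, ``pct`` and ``is_max`` flagging each row's most
    successful source.  Row percentages sum to 100 per group.
    """
    if by not in _GROUPING_COLUMNS:
        raise InputError(f"unknown dimension {by!r}")
    df = participants_frame(participants)
    if df.empty:
        raise InputError("no participants")
    col = _GROUPING_COLUMNS[by]
    df = df.assign(_group="overall" if col is None else df[col])
    rows = []
    for group, g in df.groupby("_group"):
        counts = g["source"].value_counts()
        total = int(counts.sum())
        pcts = 100.0 * counts / total
        top = pcts.idxmax()
        for source in [s for s in SOURCES if s in counts.index]:
            rows.append(
                {
                    "group": group,
                    "source": source,
                    "n": int(counts[source]),
                    "pct": float(pcts[source]),
                    "is_max": source == top,
                }
            )
    return pd.DataFrame(rows)


def demographics_table(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Composition of the sample per city and overall.

    Blocks: sample size, gender shares, mean age with its standard error,
    education shares and employment shares.  Share denominators exclude
    unreported values; the block's reporter count is carried in ``block_n``
    so every printed percentage can be recomputed from its own
    numerator/denominator pair.

    Tidy output: ``city``, ``block``, ``level``, ``n``, ``block_n``,
    ``pct`` (or ``mean``/``se`` for the age block).
    """
    df = participants_frame(participants)
    if df.empty:
        raise InputError("no participants")
    rows: list[dict] = []
    groups = [(c, g) for c, g in df.groupby("city")] + [("total", df)]
    for city, g in groups:
        n = len(g)
        rows.append({"city": city, "block": "participants", "level": "n",
                     "n": n, "block_n": len(df), "pct": 100.0 * n / len(df)})
        for block, col in (("gender", "gender"), ("education", "education"),
                           ("employment", "employment")):
            reported = g[g[col] != "unreported"]
            block_n = len(reported)
            for level, cnt in reported[col].value_counts().items():
                rows.append(
                    {
                        "city": city,
                        "block": block,
                        "level": level,
                        "n": int(cnt),
                        "block_n": block_n,
                        "pct": 100.0 * cnt / block_n if block_n else np.nan,
                    }
                )
        ages = g["age_years"].dropna()
        if len(ages):
            rows.append(
                {
                    "city": city,
                    "block": "age",
                    "level": "overall",
                    "n": len(ages),
                    "block_n": len(ages),
                    "mean": float(ages.mean()),
                    "se": float(ages.std(ddof=1) / np.sqrt(len(ages)))
                    if len(ages) > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def time_efficiency(
    effectiveness: dict[str, float],
    activities: Iterable[ActivityRecord],
    minutes_per_post: float = 5.0,
    social_media_categories: Optional[set[str]] = None,
) -> pd.Series:
    """Predicted participants per invested working hour, per category.

    For social-media categories, a post with no recorded hours is charged
    the flat per-post convention (``minutes_per_post`` / 60 hours), since
    posting time is rarely logged.  Categories with zero total hours are
    omitted with a warning.
    """
    acts = list(activities)

    def is_social(cat: str) -> bool:
        if social_media_categories is not None:
            return cat in social_media_categories
        low = cat.lower()
        return any(tag in low for tag in ("facebook", "twitter", "social"))

    hours: dict[str, float] = {}
    for a in acts:
        h = a.hours
        if h <= 0 and is_social(a.category):
            h = minutes_per_post / 60.0
        hours[a.category] = hours.get(a.category, 0.0) + h
    out = {}
    for cat, predicted in effectiveness.items():
        h = hours.get(cat, 0.0)
        if h <= 0:
            warnings.warn(f"category {cat!r} has zero invested hours; omitted",
                          stacklevel=2)
            continue
        out[cat] = predicted / h
    return pd.Series(out, name="participants_per_hour").sort_index()
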