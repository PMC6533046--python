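"""Core domain records for recruitment-campaign evaluation.

Dates are integer day indices relative to the study start everywhere inside
the library; conversion to ISO-8601 happens only at the file boundary
(:mod:`recruitflow.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "ConsistencyError",
    "InputError",
    "ActivityRecord",
    "RegistrationSeries",
    "ModelParams",
    "FitResult",
    "ParticipantRecord",
    "FunnelCounts",
    "CensusMarginals",
]


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. activity categories vs. model
    parameters) do not."""


class InputError(ValueError):
    """An input violates a precondition of the requested computation."""


GENDERS = ("male", "female", "unreported")
EDUCATION_LEVELS = ("university", "secondary", "primary", "none", "unreported")
EMPLOYMENT_LEVELS = (
    "full_time",
    "part_time",
    "student",
    "home_retired_unemployed",
    "unreported",
)
SOURCES = (
    "work",
    "word_of_mouth",
    "other_organizations",
    "outreach",
    "news",
    "social_media",
    "public_notice",
    "random_sampling",
    "other",
    "dont_know",
    "unreported",
)


@dataclass(frozen=True)
class ActivityRecord:
    """One recruitment action: a Facebook post, a mailing-list blast, a day
    of street recruitment, ...

    ``boost`` is an explicit intensity multiplier for activities with
    exceptional observed success; it defaults to 1 (no boost).
    """

    city: str
    category: str
    activity_id: str
    start_day: int
    hours: float
    boost: float = 1.0

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ConfigurationError(f"hours must be >= 0, got {self.hours}")
        if self.boost <= 0:
            raise ConfigurationError(f"boost must be > 0, got {self.boost}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.activity_id)

    def with_boost(self, boost: float) -> "ActivityRecord":
        return replace(self, boost=boost)


@dataclass
class RegistrationSeries:
    """Daily counts of new survey registrants for one city.

    ``days`` are consecutive integer day indices; ``counts`` the observed (or
    predicted) number of registrations on each day.
    """

    city: str
    days: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.days.shape != self.counts.shape:
            raise InputError("days and counts must have equal length")
        if self.days.size and np.any(np.diff(self.days) != 1):
            raise InputError("days must be consecutive (strictly increasing, no gaps)")
        if np.any(self.counts < 0):
            raise InputError("registration counts must be >= 0")

    @classmethod
    def from_counts(
        cls, counts: Sequence[float], city: str = "city", start_day: int = 0
    ) -> "RegistrationSeries":
        counts = np.asarray(counts, dtype=float)
        return cls(city=city, days=start_day + np.arange(counts.size), counts=counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return int(self.days.size)


@dataclass
class ModelParams:
    """Parameters of the log-normal response-curve attribution model.

    mu, sigma
        Location and dispersion of the shared log-normal density over days
        elapsed since an activity's start; one pair for all categories.
    effectiveness
        Per-category intrinsic effectiveness ``e_c`` — expected participants
        attributable to one average-intensity activity of category *c*.
    intensity
        Per-activity relative intensity ``i_ca`` (mean 1 within a category),
        keyed by ``(category, activity_id)``.
    """

    mu: float
    sigma: float
    effectiveness: Mapping[str, float]
    intensity: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        for c, e in self.effectiveness.items():
            if e < 0:
                raise ConfigurationError(f"effectiveness[{c!r}] must be >= 0, got {e}")

    @property
    def modal_lag(self) -> float:
        """Days from an activity's start to its peak effect."""
        return float(np.exp(self.mu - self.sigma**2))


@dataclass
class FitResult:
    """Everything a nonlinear least-squares fit of the attribution model
    reports: estimates, per-category inference, diagnostics and the fitted
    daily series."""

    params: ModelParams
    stderr: dict[str, float]
    t_value: dict[str, float]
    p_value: dict[str, float]
    residual_se: float
    df: int
    pseudo_r2: float
    predicted: RegistrationSeries
    per_category_predicted: dict[str, float]
    converged: bool
    n_iter: int
    sse: float
    sst: float
    mu_stderr: float = float("nan")
    sigma_stderr: float = float("nan")


@dataclass(frozen=True)
class ParticipantRecord:
    """One respondent: demographics, how they found out about the survey,
    and their participation outcomes."""

    id: str
    city: str
    registration_day: int
    gender: str = "unreported"
    age_years: Optional[float] = None
    education: str = "unreported"
    employment: str = "unreported"
    source: str = "unreported"
    baseline_started: bool = False
    baseline_finalized: bool = False
    n_questionnaires: int = 0
    withdrawn: bool = False

    def __post_init__(self) -> None:
        if self.baseline_finalized and not self.baseline_started:
            raise InputError(
                f"participant {self.id}: baseline_finalized requires baseline_started"
            )
        if self.n_questionnaires < 0:
            raise InputError(f"participant {self.id}: n_questionnaires must be >= 0")

    @property
    def age_class(self) -> str:
        if self.age_years is None:
            return "unreported"
        a = self.age_years
        if a < 20:
            return "<20"
        if a < 30:
            return "20-29"
        if a < 40:
            return "30-39"
        if a < 50:
            return "40-49"
        if a < 60:
            return "50-59"
        return "60+"


@dataclass(frozen=True)
class FunnelCounts:
    """Counts at the three stages of the participation funnel:
    registered -> started the baseline questionnaire -> finalized it."""

    registered: int
    started: int
    finalized: int

    def __post_init__(self) -> None:
        if not self.registered >= self.started >= self.finalized >= 0:
            raise InputError(
                "funnel must satisfy registered >= started >= finalized >= 0, "
                f"got ({self.registered}, {self.started}, {self.finalized})"
            )


@dataclass
class CensusMarginals:
    """City-level population distribution over gender x age class, the
    reference for representativeness testing."""

    city: str
    cells: Mapping[tuple[str, str], float]
    total_population: Optional[int] = None

    def __post_init__(self) -> None:
        for cell, share in self.cells.items():
            if share < 0:
                raise ConfigurationError(f"census share for {cell} must be >= 0")
        tot = sum(self.cells.values())
        if abs(tot - 1.0) > 1e-6:
            raise ConfigurationError(
                f"census cell shares must sum to 1 (got {tot:.8f}) for {self.city}"
            )

    def margin_shares(self, margin: str) -> dict[str, float]:
        """Collapse the joint cells onto one margin ('gender' or 'age')."""
        if margin not in ("gender", "age"):
            raise InputError(f"margin must be 'gender' or 'age', got {margin!r}")
        idx = 0 if margin == "gender" else 1
        out: dict[str, float] = {}
        for cell, share in self.cells.items():
            out[cell[idx]] = out.get(cell[idx], 0.0) + share
        return out
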