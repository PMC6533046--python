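"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates the four inputs of a recruitment evaluation — the
activity log, the daily registration series, the participant table and the
census marginals — so that every downstream stage is testable without any
external download.  Registration counts are drawn from the attribution
model's own expected daily series (Poisson by default, since registrations
are event counts; Gaussian with configurable sd is available for exactness
tests), and the generating parameters are returned as ground truth.

The default scenario mirrors the scale of a multi-city European mobility
survey: three recruitment categories whose true totals sit in the
400-1000-participant range, 20 activities per category, a 700-day study
window, a response curve with mu = 1 and sigma = 0.8 (peak effect roughly
1.4 days after an activity starts, with a long tail), and funnel
probabilities of 0.8336 (baseline started), 0.8013 (finalized | started)
and 0.1217 (withdrawn | started).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import intensities_from_hours, predict_daily
from .types import (
    ActivityRecord,
    CensusMarginals,
    ConfigurationError,
    ConsistencyError,
    ModelParams,
    ParticipantRecord,
    RegistrationSeries,
)

__all__ = [
    "HoursDistribution",
    "ScenarioConfig",
    "SyntheticDataset",
    "generate_activity_log",
    "true_params",
    "generate_registrations",
    "generate_participants",
    "generate_census",
    "generate_dataset",
]


class HoursDistribution(BaseModel):
    """Distribution of invested working hours per activity.

    ``gamma(shape, scale)`` (default, mean = shape*scale), ``uniform(a, b)``
    or ``degenerate(a)`` (every activity gets exactly ``a`` hours).
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["gamma", "uniform", "degenerate"] = "gamma"
    a: float = 2.0
    b: float = 5.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "gamma":
            return rng.gamma(self.a, self.b, size)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size)
        return np.full(size, self.a)


_DEFAULT_CATEGORIES = {
    "facebook": 22.0,
    "mailing_list": 45.0,
    "street_recruitment": 50.0,
}

_DEFAULT_GENDER = {"male": 0.46, "female": 0.54}
_DEFAULT_AGE = {"20-29": 0.22, "30-39": 0.22, "40-49": 0.20, "50-59": 0.19, "60+": 0.17}
_DEFAULT_EDUCATION = {
    "university": 0.578,
    "secondary": 0.207,
    "primary": 0.010,
    "none": 0.003,
    "unreported": 0.202,
}
_DEFAULT_EMPLOYMENT = {
    "full_time": 0.560,
    "part_time": 0.156,
    "student": 0.127,
    "home_retired_unemployed": 0.082,
    "unreported": 0.075,
}
_DEFAULT_SOURCE = {
    "work": 0.2151,
    "word_of_mouth": 0.1140,
    "other_organizations": 0.1270,
    "outreach": 0.2076,
    "news": 0.0748,
    "social_media": 0.1739,
    "public_notice": 0.0174,
    "random_sampling": 0.0338,
    "other": 0.0344,
    "dont_know": 0.0020,
}

# Census populations skew older than the opportunistically recruited sample.
_DEFAULT_CENSUS_GENDER = {"male": 0.49, "female": 0.51}
_DEFAULT_CENSUS_AGE = {
    "20-29": 0.17,
    "30-39": 0.18,
    "40-49": 0.18,
    "50-59": 0.17,
    "60+": 0.30,
}


class ScenarioConfig(BaseModel):
    """Full specification of a synthetic recruitment scenario."""

    model_config = ConfigDict(validate_assignment=True)

    n_cities: int = Field(default=1, ge=1)
    categories: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CATEGORIES)
    )
    activities_per_category: int = Field(default=20, ge=1)
    study_days: int = Field(default=700, ge=1)
    true_mu: float = 1.0
    true_sigma: float = Field(default=0.8, gt=0)
    hours_distribution: HoursDistribution = Field(default_factory=HoursDistribution)
    noise_model: Literal["poisson", "gaussian"] = "poisson"
    gaussian_sd: float = Field(default=1.0, ge=0)
    baseline_start_prob: float = Field(default=0.8336, ge=0, le=1)
    baseline_finish_prob: float = Field(default=0.8013, ge=0, le=1)
    withdrawal_prob: float = Field(default=0.1217, ge=0, le=1)
    questionnaire_mean: float = Field(default=8.0, ge=0)
    gender_marginals: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_GENDER)
    )
    age_marginals: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_AGE))
    education_marginals: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_EDUCATION)
    )
    employment_marginals: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_EMPLOYMENT)
    )
    source_marginals: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_SOURCE)
    )
    census_gender: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CENSUS_GENDER)
    )
    census_age: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CENSUS_AGE)
    )
    # activity_id -> boost applied at generation time (planted peaks)
    planted_boosts: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("categories")
    @classmethod
    def _categories_nonempty(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("categories must be nonempty")
        for name, e in v.items():
            if e < 0:
                raise ValueError(f"categories[{name!r}] effectiveness must be >= 0")
        return v

    @field_validator(
        "gender_marginals",
        "age_marginals",
        "education_marginals",
        "employment_marginals",
        "source_marginals",
        "census_gender",
        "census_age",
    )
    @classmethod
    def _normalise(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("marginal distribution must be nonempty")
        if any(p < 0 for p in v.values()):
            raise ValueError("marginal shares must be >= 0")
        tot = sum(v.values())
        if tot <= 0:
            raise ValueError("marginal shares must sum to a positive value")
        if abs(tot - 1.0) > 1e-3:
            raise ValueError(f"marginal shares must sum to 1 (got {tot:.4f})")
        return {k: p / tot for k, p in v.items()}

    def cities(self) -> list[str]:
        return [f"city_{i + 1}" for i in range(self.n_cities)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream per generation stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticDataset:
    """A complete synthetic study: inputs plus the generating truth."""

    activities: list[ActivityRecord]
    registrations: list[RegistrationSeries]
    participants: list[ParticipantRecord]
    census: list[CensusMarginals]
    truth: ModelParams
    config: ScenarioConfig = field(repr=False, default=None)


def _validate(config: ScenarioConfig) -> ScenarioConfig:
    if isinstance(config, ScenarioConfig):
        return config
    try:
        return ScenarioConfig.model_validate(config)
    except Exception as exc:  # pydantic error already names the field
        raise ConfigurationError(str(exc)) from exc


def generate_activity_log(config: ScenarioConfig) -> list[ActivityRecord]:
    """Draw the recruitment-activity log: ``activities_per_category`` records
    per category per city, start dates uniform over the study window, hours
    from the configured distribution."""
    config = _validate(config)
    rng = config.rng(1)
    out: list[ActivityRecord] = []
    for city in config.cities():
        for cat in config.categories:
            n = config.activities_per_category
            starts = rng.integers(0, config.study_days, n)
            hours = config.hours_distribution.sample(rng, n)
            for k in range(n):
                act_id = f"{city}:{cat}:{k + 1:02d}"
                out.append(
                    ActivityRecord(
                        city=city,
                        category=cat,
                        activity_id=act_id,
                        start_day=int(starts[k]),
                        hours=float(hours[k]),
                        boost=float(config.planted_boosts.get(act_id, 1.0)),
                    )
                )
    return out


def true_params(
    activities: list[ActivityRecord], config: ScenarioConfig
) -> ModelParams:
    """The generating model parameters for a drawn activity log."""
    config = _validate(config)
    return ModelParams(
        mu=config.true_mu,
        sigma=config.true_sigma,
        effectiveness=dict(config.categories),
        intensity=intensities_from_hours(activities),
    )


def generate_registrations(
    activities: list[ActivityRecord],
    truth: ModelParams,
    config: ScenarioConfig,
) -> list[RegistrationSeries]:
    """Observed daily registration counts per city: the attribution model's
    expected series plus the configured count noise, truncated at zero and
    rounded to integers."""
    config = _validate(config)
    missing = {a.category for a in activities} - set(truth.effectiveness)
    if missing:
        raise ConsistencyError(
            f"activities reference categories with no true effectiveness: "
            f"{sorted(missing)}"
        )
    rng = config.rng(2)
    days = np.arange(config.study_days)
    out: list[RegistrationSeries] = []
    for city in config.cities():
        city_acts = [a for a in activities if a.city == city]
        if city_acts:
            expected = predict_daily(city_acts, truth, days).counts
        else:
            expected = np.zeros(days.size)
        if config.noise_model == "poisson":
            counts = rng.poisson(expected).astype(float)
        else:
            noisy = rng.normal(expected, config.gaussian_sd)
            counts = np.rint(np.clip(noisy, 0.0, None))
        out.append(RegistrationSeries(city=city, days=days, counts=counts))
    return out


def _sample_levels(
    rng: np.random.Generator, marginals: dict[str, float], size: int
) -> np.ndarray:
    levels = list(marginals)
    probs = np.array([marginals[k] for k in levels])
    return rng.choice(levels, size=size, p=probs / probs.sum())


_AGE_RANGES = {
    "<20": (18.0, 20.0),
    "20-29": (20.0, 30.0),
    "30-39": (30.0, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
    "60+": (60.0, 80.0),
}


def generate_participants(
    registrations: list[RegistrationSeries] | RegistrationSeries,
    config: ScenarioConfig,
) -> list[ParticipantRecord]:
    """One participant record per registrant.

    Demographics and recruitment source are sampled independently from the
    configured marginals; the participation funnel (baseline started,
    finalized given started, withdrawn given started) and the number of
    completed follow-up questionnaires (Poisson, only for baseline
    starters) use the configured probabilities.
    """
    config = _validate(config)
    if isinstance(registrations, RegistrationSeries):
        registrations = [registrations]
    rng = config.rng(3)
    out: list[ParticipantRecord] = []
    for series in registrations:
        n = int(series.counts.sum())
        reg_days = np.repeat(series.days, series.counts.astype(int))
        genders = _sample_levels(rng, config.gender_marginals, n)
        age_classes = _sample_levels(rng, config.age_marginals, n)
        ages = np.array(
            [rng.uniform(*_AGE_RANGES[a]) for a in age_classes]
        )
        education = _sample_levels(rng, config.education_marginals, n)
        employment = _sample_levels(rng, config.employment_marginals, n)
        sources = _sample_levels(rng, config.source_marginals, n)
        started = rng.random(n) < config.baseline_start_prob
        finalized = started & (rng.random(n) < config.baseline_finish_prob)
        withdrawn = started & (rng.random(n) < config.withdrawal_prob)
        n_quest = np.where(
            started, rng.poisson(config.questionnaire_mean, n), 0
        )
        for i in range(n):
            out.append(
                ParticipantRecord(
                    id=f"{series.city}:p{i + 1:05d}",
                    city=series.city,
                    registration_day=int(reg_days[i]),
                    gender=str(genders[i]),
                    age_years=float(ages[i]),
                    education=str(education[i]),
                    employment=str(employment[i]),
                    source=str(sources[i]),
                    baseline_started=bool(started[i]),
                    baseline_finalized=bool(finalized[i]),
                    n_questionnaires=int(n_quest[i]),
                    withdrawn=bool(withdrawn[i]),
                )
            )
    return out


def pick_isolated_activity(
    activities: list[ActivityRecord],
    category: Optional[str] = None,
    min_gap: int = 3,
) -> Optional[str]:
    """Pick an activity whose start day is at least ``min_gap`` days from
    every other activity's start (optionally within one category).

    Peak-attribution experiments plant an exceptional boost on one activity
    and ask whether it is recovered; that question is only well-posed when
    the activity's peak cannot be confused with a same-day neighbour, so
    the planted activity is chosen isolated by construction.  Returns the
    activity_id, or None when no activity is isolated.
    """
    starts = [a.start_day for a in activities]
    for a in activities:
        if category is not None and a.category != category:
            continue
        if sum(abs(s - a.start_day) <= min_gap for s in starts) == 1:
            return a.activity_id
    return None


def generate_census(config: ScenarioConfig) -> list[CensusMarginals]:
    """Census gender x age-class marginals per city (independent margins)."""
    config = _validate(config)
    cells = {
        (g, a): pg * pa
        for g, pg in config.census_gender.items()
        for a, pa in config.census_age.items()
    }
    tot = sum(cells.values())
    cells = {k: v / tot for k, v in cells.items()}
    return [
        CensusMarginals(city=city, cells=dict(cells), total_population=500_000)
        for city in config.cities()
    ]


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate the full study: activity log, registration series,
    participant table, census marginals and the generating truth."""
    config = _validate(config)
    activities = generate_activity_log(config)
    truth = true_params(activities, config)
    registrations = generate_registrations(activities, truth, config)
    participants = generate_participants(registrations, config)
    census = generate_census(config)
    return SyntheticDataset(
        activities=activities,
        registrations=registrations,
        participants=participants,
        census=census,
        truth=truth,
        config=config,
    )
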