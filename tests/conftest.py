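"""Shared fixtures: small synthetic scenarios and cohort builders that
reconstruct participant microdata from published summary counts."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from recruitflow import ParticipantRecord, ScenarioConfig

# Published recruitment-source counts per city ("how did you find out about
# this survey?"), reconstructed at the participant level for table tests.
CITIES = ("antwerp", "barcelona", "london", "orebro", "rome", "vienna", "zurich")

SOURCE_COUNTS = {
    "work": (376, 199, 317, 343, 337, 233, 495),
    "word_of_mouth": (195, 369, 146, 15, 244, 155, 95),
    "other_organizations": (289, 113, 282, 36, 141, 315, 182),
    "outreach": (132, 665, 198, 550, 158, 329, 187),
    "news": (98, 41, 110, 51, 253, 109, 138),
    "social_media": (311, 220, 243, 33, 533, 275, 244),
    "public_notice": (13, 19, 22, 9, 90, 27, 6),
    "random_sampling": (0, 0, 0, 360, 0, 0, 0),
    "other": (28, 95, 125, 0, 88, 25, 7),
    "dont_know": (3, 6, 3, 4, 0, 4, 2),
}

GENDER_COUNTS = {
    "male": (689, 706, 600, 530, 1130, 682, 585),
    "female": (756, 1021, 846, 871, 714, 790, 771),
}

EDUCATION_COUNTS = {
    "university": (1044, 1100, 875, 691, 1015, 756, 699),
    "secondary": (191, 249, 151, 319, 530, 371, 406),
    "primary": (6, 11, 1, 26, 0, 37, 22),
    "none": (4, 6, 6, 0, 3, 3, 3),
}

# Participation funnel: registered -> started baseline -> finalized baseline.
FUNNEL = (12825, 10691, 8567)

# Withdrawals among baseline starters.
WITHDRAWN_OVERALL = 1301
WITHDRAWN_BY_CITY = {"orebro": (311, 1401), "rome": (82, 1844)}


def build_participants(city_field_counts: dict[str, dict[str, int]],
                       field: str, **common) -> list[ParticipantRecord]:
    """Expand per-city counts of one categorical field into records."""
    ids = itertools.count(1)
    out = []
    for city, counts in city_field_counts.items():
        for level, n in counts.items():
            for _ in range(n):
                out.append(
                    ParticipantRecord(
                        id=f"p{next(ids)}",
                        city=city,
                        registration_day=0,
                        **{field: level},
                        **common,
                    )
                )
    return out


@pytest.fixture(scope="session")
def source_cohort() -> list[ParticipantRecord]:
    """One record per participant with the published city x source counts."""
    per_city = {
        city: {src: SOURCE_COUNTS[src][i] for src in SOURCE_COUNTS}
        for i, city in enumerate(CITIES)
    }
    return build_participants(per_city, "source")


@pytest.fixture(scope="session")
def demographic_cohort() -> list[ParticipantRecord]:
    """Participants with the published gender and education margins.

    Gender and education are assigned independently within each city (their
    joint distribution was never published); each margin is exact.
    """
    ids = itertools.count(1)
    out = []
    for i, city in enumerate(CITIES):
        genders = [g for g in GENDER_COUNTS for _ in range(GENDER_COUNTS[g][i])]
        n_city = len(genders)
        edus = [e for e in EDUCATION_COUNTS for _ in range(EDUCATION_COUNTS[e][i])]
        edus += ["unreported"] * (n_city - len(edus))
        for g, e in zip(genders, edus):
            out.append(
                ParticipantRecord(
                    id=f"p{next(ids)}", city=city, registration_day=0,
                    gender=g, education=e,
                )
            )
    return out


@pytest.fixture(scope="session")
def withdrawal_cohort() -> list[ParticipantRecord]:
    """Baseline starters with the published withdrawal counts per city;
    cities without a published breakdown are pooled into 'elsewhere'."""
    ids = itertools.count(1)
    out = []
    total_started = FUNNEL[1]
    rest_started = total_started - sum(n for _, n in WITHDRAWN_BY_CITY.values())
    rest_withdrawn = WITHDRAWN_OVERALL - sum(
        w for w, _ in WITHDRAWN_BY_CITY.values()
    )
    blocks = dict(WITHDRAWN_BY_CITY, elsewhere=(rest_withdrawn, rest_started))
    for city, (withdrawn, started) in blocks.items():
        for k in range(started):
            out.append(
                ParticipantRecord(
                    id=f"p{next(ids)}", city=city, registration_day=0,
                    baseline_started=True, withdrawn=k < withdrawn,
                )
            )
    return out


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """A fast scenario for pipeline and generator tests."""
    return ScenarioConfig(
        study_days=200,
        activities_per_category=5,
        categories={"facebook": 30.0, "mailing_list": 50.0},
        seed=42,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
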