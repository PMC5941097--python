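"""The packaged osteoporotic-fracture treatment-gap study.

Three chained identifications, shipped both as Python builders and as YAML
documents under ``cohortforge/data``:

1. *incident osteoporotic fracture cohort* — adults (50+) with a first
   in-window hip or vertebral fracture diagnosis (ICD-9 820, 805, 806)
   between 2010 and 2014, excluding anyone with malignant neoplasm
   (140-208), an osteoporotic fracture, Paget disease (731.0), or an
   anti-osteoporosis dispensing in the year before the index date;
2. *continued follow-up within 3 months* — members of (1) with a hospital
   encounter 1-90 days after index;
3. *AOM initiation within 1 year* — members of (1) with an
   anti-osteoporosis dispensing 1-365 days after index.

Both chained lists use the incident cohort as their denominator, matching
the reported treatment-gap percentages.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .engine import (
    Criterion,
    IdentificationSpec,
    IndexRule,
    ObservationWindow,
)
from .synthetic import DEFAULT_WINDOW, FixtureSpec

TOPIC_INDEX = "incident osteoporotic fracture cohort"
TOPIC_FOLLOWUP = "continued follow-up within 3 months"
TOPIC_TREATED = "AOM initiation within 1 year"

#: cohort-flow category counts of the packaged worked example
EXAMPLE_FLOW_COUNTS = {
    "eligible_untreated": 1344,
    "eligible_treated": 464,
    "no_followup": 385,
    "prior_malignancy": 557,
    "prior_fracture": 1769,
    "prior_aom": 179,
}


def fracture_study_specs() -> list[IdentificationSpec]:
    """The three-spec identification queue of the worked example."""
    window = DEFAULT_WINDOW
    index = IndexRule(template="osteoporotic_fracture",
                      settings=frozenset({"outpatient", "admission", "emergency"}),
                      washout="none")
    lookback = (-365, -1)
    return [
        IdentificationSpec(
            topic=TOPIC_INDEX,
            observation=window,
            index=index,
            criteria=(
                Criterion("age at least 50", "require_presence", age_minimum=50),
                Criterion("prior malignant neoplasm", "exclude_if_present",
                          template="malignancy", window=lookback),
                Criterion("prior osteoporotic fracture", "exclude_if_present",
                          template="osteoporotic_fracture", window=lookback),
                Criterion("prior Paget disease", "exclude_if_present",
                          template="paget", window=lookback),
                Criterion("prior AOM use", "exclude_if_present",
                          template="aom", window=lookback),
            ),
        ),
        IdentificationSpec(
            topic=TOPIC_FOLLOWUP,
            source_list=TOPIC_INDEX,
            observation=window,
            index=index,
            criteria=(
                Criterion("follow-up visit within 3 months", "require_presence",
                          encounter=True, window=(1, 90)),
            ),
        ),
        IdentificationSpec(
            topic=TOPIC_TREATED,
            source_list=TOPIC_INDEX,
            observation=window,
            index=index,
            criteria=(
                Criterion("AOM dispensing within 1 year", "require_presence",
                          template="aom", window=(1, 365)),
            ),
        ),
    ]


def example_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Fixture spec whose categories force the worked example's flow counts."""
    return FixtureSpec(seed=seed, **EXAMPLE_FLOW_COUNTS)


def packaged_data_path(name: str) -> Path:
    """Path of a YAML document shipped under ``cohortforge/data``."""
    with resources.as_file(resources.files("cohortforge") / "data" / name) as p:
        return Path(p)
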