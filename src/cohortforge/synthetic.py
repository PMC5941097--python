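"""Synthetic longitudinal EHR generators.

Two modes cover two distinct needs:

*Fixture mode* builds a dataset in which every patient belongs to exactly
one cohort-flow category of the packaged osteoporotic-fracture study —
eligible and treated, eligible and untreated, indexed but lost to
follow-up, excluded for a single specific reason, or never indexed — so
that running the packaged identification chain reproduces the requested
attrition counts *exactly*.  Categories are mutually exclusive by
construction, which makes sequential attrition attribution unambiguous.

*Population mode* draws patients independently from stated distributions
(age, sex, BMI, yearly fracture incidence, treatment and follow-up
probabilities, background comorbidity rates) so that the engine's estimated
proportions can be checked against the generating parameters.

Both modes are deterministic given their seed: all randomness flows through
one ``numpy.random.Generator`` created from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_store import CARE_SETTINGS, EhrDataset
from .engine import ObservationWindow
from .templates import AOM_DRUGS

#: observation span of the packaged worked example
DEFAULT_WINDOW = ObservationWindow("2010-01-01", "2014-12-31")

HIP_CODES = ("820.8", "820.21", "820.0")
VERTEBRAL_CODES = ("805.4", "806.00", "805.2")
MALIGNANCY_CODES = ("162.9", "174.9", "185", "153.3")
PAGET_CODE = "731.0"
OCCUPATIONS = ("retired", "homemaker", "service", "unknown")

#: cohort-flow categories of the fixture, in a fixed generation order
FIXTURE_CATEGORIES = (
    "eligible_untreated", "eligible_treated", "no_followup",
    "prior_malignancy", "prior_fracture", "prior_aom",
    "under_50", "paget_history", "outside_window",
)
_CATEGORY_PREFIX = {
    "eligible_untreated": "EU", "eligible_treated": "ET", "no_followup": "NF",
    "prior_malignancy": "PM", "prior_fracture": "PF", "prior_aom": "PA",
    "under_50": "U5", "paget_history": "PG", "outside_window": "OW",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Per-category patient counts plus demographic composition.

    Default demographic fractions and moments mirror the treated cohort of
    the worked example (82.76% female, 71.98% married, 99.78% normal
    income; age 76.47 (SD 10.10) years, BMI 22.95 (SD 3.86) kg/m²).
    """

    eligible_untreated: int = 0
    eligible_treated: int = 0
    no_followup: int = 0
    prior_malignancy: int = 0
    prior_fracture: int = 0
    prior_aom: int = 0
    under_50: int = 0
    paget_history: int = 0
    outside_window: int = 0
    observation: ObservationWindow = DEFAULT_WINDOW
    seed: int = 0
    female_fraction: float = 384 / 464
    married_fraction: float = 334 / 464
    normal_income_fraction: float = 463 / 464
    age_mean: float = 76.47
    age_sd: float = 10.10
    bmi_mean: float = 22.95
    bmi_sd: float = 3.86

    def __post_init__(self):
        for name in FIXTURE_CATEGORIES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for category {name}")

    @property
    def counts(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FIXTURE_CATEGORIES}


def fixture_spec_from_mapping(doc: Mapping) -> FixtureSpec:
    """Build a :class:`FixtureSpec` from a parsed YAML mapping."""
    kwargs = dict(doc.get("counts", {}))
    unknown = set(kwargs) - set(FIXTURE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown fixture categories: {sorted(unknown)}")
    if "observation" in doc:
        obs = doc["observation"]
        kwargs["observation"] = ObservationWindow(obs["start"], obs["end"])
    for key in ("seed", "female_fraction", "married_fraction", "normal_income_fraction",
                "age_mean", "age_sd", "bmi_mean", "bmi_sd"):
        if key in doc:
            kwargs[key] = doc[key]
    return FixtureSpec(**kwargs)


def _quarter_anchor_dates(window: ObservationWindow) -> list[pd.Timestamp]:
    """One representative index day per calendar quarter (the 15th day)."""
    periods = pd.period_range(pd.Timestamp(window.start), pd.Timestamp(window.end), freq="Q")
    anchors = []
    for p in periods:
        anchor = p.start_time.normalize() + pd.Timedelta(days=14)
        if pd.Timestamp(window.start) <= anchor <= pd.Timestamp(window.end):
            anchors.append(anchor)
    if not anchors:
        anchors = [pd.Timestamp(window.start)]
    return anchors


def _demographics(spec: FixtureSpec, category: str, i: int, n: int,
                  anchor: pd.Timestamp, rng: np.random.Generator) -> dict:
    """One patient row; deterministic categorical allocation, seeded moments."""
    if category == "under_50":
        age = int(rng.integers(25, 50))
    else:
        # clipped at 52 so age-based exclusion never bleeds into other categories
        age = int(np.clip(round(rng.normal(spec.age_mean, spec.age_sd)), 52, 105))
    birth = anchor - pd.DateOffset(years=age) - pd.Timedelta(days=183)
    bmi = float(np.round(np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd), 12.0, 45.0), 1))
    row = {
        "patient_id": f"{_CATEGORY_PREFIX[category]}{i:05d}",
        "birth_date": birth,
        "sex": "female" if i < round(spec.female_fraction * n) else "male",
        "bmi": np.nan if i % 11 == 10 else bmi,
        "marital_status": "married" if i < round(spec.married_fraction * n) else "unmarried",
        "income_level": "normal" if i < round(spec.normal_income_fraction * n) else "low",
        "occupation": OCCUPATIONS[i % len(OCCUPATIONS)],
        "death_date": anchor + pd.Timedelta(days=200) if category == "no_followup" else pd.NaT,
    }
    return row


def generate_fixture(spec: FixtureSpec) -> EhrDataset:
    """Deterministic dataset forcing the packaged study's attrition counts.

    Running the packaged identification chain on the result yields::

        index cohort      = eligible_untreated + eligible_treated + no_followup
        follow-up cohort  = eligible_untreated + eligible_treated
        treated cohort    = eligible_treated

    and per-criterion exclusions equal to the corresponding category counts
    (``prior_fracture`` patients are indexed only in the first observation
    year so their earlier fracture code predates the window).
    """
    rng = np.random.default_rng(spec.seed)
    window = spec.observation
    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    anchors = _quarter_anchor_dates(window)
    early_anchors = [a for a in anchors if a <= start + pd.Timedelta(days=364)] or anchors[:1]

    patients, events, encounters = [], [], []

    for category in FIXTURE_CATEGORIES:
        n = getattr(spec, category)
        pool = early_anchors if category == "prior_fracture" else anchors
        for i in range(n):
            if category == "outside_window":
                anchor = end + pd.Timedelta(days=90)
            else:
                anchor = pool[i % len(pool)]
            patients.append(_demographics(spec, category, i, n, anchor, rng))
            pid = patients[-1]["patient_id"]
            setting = CARE_SETTINGS[i % len(CARE_SETTINGS)]

            # qualifying fracture diagnosis (hip / vertebral / both)
            kind = i % 3
            codes = ([HIP_CODES[i % 3]] if kind == 0
                     else [VERTEBRAL_CODES[i % 3]] if kind == 1
                     else [HIP_CODES[(i + 1) % 3], VERTEBRAL_CODES[(i + 1) % 3]])
            for code in codes:
                events.append({"patient_id": pid, "event_date": anchor,
                               "dimension": "diagnosis", "code": code,
                               "setting": setting, "duration_days": pd.NA})
            encounters.append({"patient_id": pid, "encounter_date": anchor,
                               "setting": setting})

            if category in ("eligible_untreated", "eligible_treated"):
                encounters.append({"patient_id": pid,
                                   "encounter_date": anchor + pd.Timedelta(days=30),
                                   "setting": "outpatient"})
            if category == "eligible_treated":
                events.append({"patient_id": pid,
                               "event_date": anchor + pd.Timedelta(days=60),
                               "dimension": "pharmacy",
                               "code": AOM_DRUGS[i % len(AOM_DRUGS)],
                               "setting": "outpatient", "duration_days": 30})
            if category == "no_followup":
                # next contact falls outside the 3-month follow-up window
                encounters.append({"patient_id": pid,
                                   "encounter_date": anchor + pd.Timedelta(days=120),
                                   "setting": "outpatient"})
            if category == "prior_malignancy":
                events.append({"patient_id": pid,
                               "event_date": anchor - pd.Timedelta(days=100),
                               "dimension": "diagnosis",
                               "code": MALIGNANCY_CODES[i % len(MALIGNANCY_CODES)],
                               "setting": "outpatient", "duration_days": pd.NA})
            if category == "prior_fracture":
                prior = min(anchor - pd.Timedelta(days=180), start - pd.Timedelta(days=1))
                events.append({"patient_id": pid, "event_date": prior,
                               "dimension": "diagnosis",
                               "code": HIP_CODES[i % 3] if i % 2 else VERTEBRAL_CODES[i % 3],
                               "setting": "outpatient", "duration_days": pd.NA})
            if category == "prior_aom":
                events.append({"patient_id": pid,
                               "event_date": anchor - pd.Timedelta(days=100),
                               "dimension": "pharmacy",
                               "code": AOM_DRUGS[i % len(AOM_DRUGS)],
                               "setting": "outpatient", "duration_days": 30})
            if category == "paget_history":
                events.append({"patient_id": pid,
                               "event_date": anchor - pd.Timedelta(days=100),
                               "dimension": "diagnosis", "code": PAGET_CODE,
                               "setting": "outpatient", "duration_days": pd.NA})

    return EhrDataset.from_records(patients, events, encounters)


# ---------------------------------------------------------------------------
# population mode


@dataclass(frozen=True)
class PopulationParams:
    """Generating distributions for the stochastic population mode.

    Defaults emulate the worked example's regime: an elderly hospital
    population (age 76.47 ± 10.10 years at the start of observation, 82.8%
    female, BMI 22.95 ± 3.86), a 6% yearly hip/vertebral fracture incidence
    over a five-year window, a 21% probability of anti-osteoporosis
    treatment within a year of the index fracture, an 82% probability of a
    follow-up visit within three months, and modest background rates of the
    exclusion-relevant histories.
    """

    n_patients: int = 5000
    yearly_incidence: float = 0.06
    p_treat: float = 0.21
    p_fu: float = 0.82
    age_mean: float = 76.47
    age_sd: float = 10.10
    female_fraction: float = 0.828
    bmi_mean: float = 22.95
    bmi_sd: float = 3.86
    married_fraction: float = 0.72
    normal_income_fraction: float = 0.998
    prior_malignancy_rate: float = 0.08
    prior_aom_rate: float = 0.04
    prior_fracture_rate: float = 0.05
    paget_rate: float = 0.005
    observation: ObservationWindow = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for f in fields(self):
            if f.name.startswith(("p_", "prior_", "paget", "yearly")) or f.name.endswith("fraction"):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must lie in [0, 1], got {v}")


def population_params_from_mapping(doc: Mapping) -> PopulationParams:
    """Build :class:`PopulationParams` from a parsed YAML mapping."""
    kwargs = {k: v for k, v in doc.items() if k != "observation"}
    valid = {f.name for f in fields(PopulationParams)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown population parameters: {sorted(unknown)}")
    if "observation" in doc:
        obs = doc["observation"]
        kwargs["observation"] = ObservationWindow(obs["start"], obs["end"])
    return PopulationParams(**kwargs)


def generate_population(params: PopulationParams) -> EhrDataset:
    """Independent patients drawn from the stated distributions.

    Fracture events arise from per-year Bernoulli draws across the
    observation span; the first in-window fracture is the implied index
    event, and treatment (uniform day in [+1, +365]), follow-up (uniform
    day in [+1, +90]) and lookback histories (uniform day in [-365, -1])
    are anchored to it.  Non-fractured patients contribute one background
    encounter so every table stays exercised.
    """
    rng = np.random.default_rng(params.seed)
    window = params.observation
    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    years = range(window.start.year, window.end.year + 1)

    patients, events, encounters = [], [], []
    for i in range(params.n_patients):
        pid = f"P{i:06d}"
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18.0, 105.0))
        birth = start - pd.Timedelta(days=int(round(age * 365.25)))
        bmi = float(np.round(np.clip(rng.normal(params.bmi_mean, params.bmi_sd), 12.0, 45.0), 1))
        patients.append({
            "patient_id": pid,
            "birth_date": birth,
            "sex": "female" if rng.random() < params.female_fraction else "male",
            "bmi": np.nan if rng.random() < 0.1 else bmi,
            "marital_status": "married" if rng.random() < params.married_fraction else "unmarried",
            "income_level": "normal" if rng.random() < params.normal_income_fraction else "low",
            "occupation": OCCUPATIONS[int(rng.integers(0, len(OCCUPATIONS)))],
            "death_date": pd.NaT,
        })

        fracture_dates = []
        for year in years:
            if rng.random() < params.yearly_incidence:
                y0 = pd.Timestamp(f"{year}-01-01")
                ylen = (pd.Timestamp(f"{year}-12-31") - y0).days + 1
                d = y0 + pd.Timedelta(days=int(rng.integers(0, ylen)))
                fracture_dates.append(min(max(d, start), end))
        for d in fracture_dates:
            code = (HIP_CODES if rng.random() < 0.5 else VERTEBRAL_CODES)[int(rng.integers(0, 3))]
            setting = CARE_SETTINGS[int(rng.integers(0, len(CARE_SETTINGS)))]
            events.append({"patient_id": pid, "event_date": d, "dimension": "diagnosis",
                           "code": code, "setting": setting, "duration_days": pd.NA})
            encounters.append({"patient_id": pid, "encounter_date": d, "setting": setting})

        if fracture_dates:
            index = min(fracture_dates)
            if rng.random() < params.p_fu:
                encounters.append({"patient_id": pid,
                                   "encounter_date": index + pd.Timedelta(days=int(rng.integers(1, 91))),
                                   "setting": "outpatient"})
            if rng.random() < params.p_treat:
                events.append({"patient_id": pid,
                               "event_date": index + pd.Timedelta(days=int(rng.integers(1, 366))),
                               "dimension": "pharmacy",
                               "code": AOM_DRUGS[int(rng.integers(0, len(AOM_DRUGS)))],
                               "setting": "outpatient", "duration_days": 30})
            if rng.random() < params.prior_malignancy_rate:
                events.append({"patient_id": pid,
                               "event_date": index - pd.Timedelta(days=int(rng.integers(1, 366))),
                               "dimension": "diagnosis",
                               "code": MALIGNANCY_CODES[int(rng.integers(0, len(MALIGNANCY_CODES)))],
                               "setting": "outpatient", "duration_days": pd.NA})
            if rng.random() < params.prior_aom_rate:
                events.append({"patient_id": pid,
                               "event_date": index - pd.Timedelta(days=int(rng.integers(1, 366))),
                               "dimension": "pharmacy",
                               "code": AOM_DRUGS[int(rng.integers(0, len(AOM_DRUGS)))],
                               "setting": "outpatient", "duration_days": 30})
            if rng.random() < params.paget_rate:
                events.append({"patient_id": pid,
                               "event_date": index - pd.Timedelta(days=int(rng.integers(1, 366))),
                               "dimension": "diagnosis", "code": PAGET_CODE,
                               "setting": "outpatient", "duration_days": pd.NA})
            if rng.random() < params.prior_fracture_rate:
                d = start - pd.Timedelta(days=int(rng.integers(1, 366)))
                events.append({"patient_id": pid, "event_date": d,
                               "dimension": "diagnosis",
                               "code": (HIP_CODES if rng.random() < 0.5 else VERTEBRAL_CODES)[0],
                               "setting": "outpatient", "duration_days": pd.NA})
        else:
            span = (end - start).days + 1
            encounters.append({"patient_id": pid,
                               "encounter_date": start + pd.Timedelta(days=int(rng.integers(0, span))),
                               "setting": CARE_SETTINGS[int(rng.integers(0, len(CARE_SETTINGS)))]})

    return EhrDataset.from_records(patients, events, encounters)
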