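"""The three surveillance report views over stored patient lists.

* characteristics — descriptive statistics of a cohort (age at index, BMI,
  sex, marital status, income level, occupation);
* longitudinal trend — members bucketed by index date into calendar
  months/quarters/years, optionally stratified, optionally as the
  proportion of a nested cohort over its source cohort per bucket;
* source record (attrition) — the included/excluded counts of every
  identification step, walked from the root list of the hierarchy down to
  the requested leaf.

All views are plain tables (pandas DataFrames) with an optional text
rendering; charting is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .ehr_store import EhrDataset
from .engine import DataMart, EngineError, PatientList, age_at
from .templates import TemplateLibrary, builtin_templates

INTERVALS = {"monthly": "M", "quarterly": "Q", "yearly": "Y"}
STRATA_VARIABLES = ("sex", "fracture_type")

CONTINUOUS_VARIABLES = ("age_at_index", "bmi")
CATEGORICAL_VARIABLES = ("sex", "marital_status", "income_level", "occupation")


class ReportError(ValueError):
    """Invalid report request (unknown stratum, bad nesting, ...)."""


def format_percent(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Render ``100 * numerator / denominator`` with half-up rounding.

    >>> format_percent(1808, 2193, 2)
    '82.44%'
    """
    if decimals not in (0, 1, 2):
        raise ReportError(f"decimals must be 0, 1 or 2, got {decimals}")
    if denominator <= 0:
        raise ReportError("denominator must be positive")
    ratio = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return f"{ratio.quantize(quantum, rounding=ROUND_HALF_UP)}%"


# ---------------------------------------------------------------------------
# characteristics


@dataclass
class CharacteristicsReport:
    """Cohort demographic summary.

    ``continuous`` maps variable -> {mean, sd, n_nonmissing} (sd is the
    sample standard deviation, n-1 denominator); ``categorical`` maps
    variable -> {level -> (count, percent)} with percents over ``n``.
    """

    n: int
    continuous: dict[str, dict[str, float]]
    categorical: dict[str, dict[str, tuple[int, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, stats in self.continuous.items():
            rows.append({"variable": var, "level": "", "statistic": "mean",
                         "value": stats["mean"]})
            rows.append({"variable": var, "level": "", "statistic": "sd",
                         "value": stats["sd"]})
            rows.append({"variable": var, "level": "", "statistic": "n_nonmissing",
                         "value": stats["n_nonmissing"]})
        for var, levels in self.categorical.items():
            for level, (count, percent) in levels.items():
                rows.append({"variable": var, "level": level, "statistic": "count",
                             "value": count})
                rows.append({"variable": var, "level": level, "statistic": "percent",
                             "value": percent})
        return pd.DataFrame(rows, columns=["variable", "level", "statistic", "value"])

    def render(self, decimals: int = 2) -> str:
        lines = [f"n = {self.n}"]
        for var, stats in self.continuous.items():
            lines.append(
                f"{var}: mean {stats['mean']:.{decimals}f} "
                f"(SD {stats['sd']:.{decimals}f}, n = {stats['n_nonmissing']})"
            )
        for var, levels in self.categorical.items():
            parts = [
                f"{level} {count} ({format_percent(count, self.n, decimals)})"
                for level, (count, percent) in levels.items()
            ]
            lines.append(f"{var}: " + "; ".join(parts))
        return "\n".join(lines)


def summarize_characteristics(ds: EhrDataset, plist: PatientList) -> CharacteristicsReport:
    """Demographics of a patient list, with age computed at each index date."""
    if len(plist) == 0:
        return CharacteristicsReport(n=0, continuous={}, categorical={})
    members = pd.DataFrame(
        {"patient_id": list(plist.members), "index_date": list(plist.members.values())}
    )
    merged = members.merge(ds.patients, on="patient_id", how="left", validate="1:1")
    if merged["birth_date"].isna().any():
        missing = merged.loc[merged["birth_date"].isna(), "patient_id"].tolist()
        raise ReportError(f"list members not found in dataset: {missing[:10]}")

    ages = pd.Series(
        [age_at(b, d) for b, d in zip(merged["birth_date"], merged["index_date"])],
        dtype=float,
    )
    continuous = {}
    for var, series in (("age_at_index", ages), ("bmi", merged["bmi"])):
        valid = series.dropna()
        continuous[var] = {
            "mean": float(valid.mean()) if len(valid) else math.nan,
            "sd": float(valid.std(ddof=1)) if len(valid) > 1 else math.nan,
            "n_nonmissing": int(len(valid)),
        }

    n = len(merged)
    categorical = {}
    for var in CATEGORICAL_VARIABLES:
        col = merged[var].fillna("unknown")
        counts = col.value_counts()
        categorical[var] = {
            str(level): (int(count), 100.0 * count / n)
            for level, count in counts.items()
        }
    return CharacteristicsReport(n=n, continuous=continuous, categorical=categorical)


# ---------------------------------------------------------------------------
# trends


@dataclass
class TrendSeries:
    """Calendar-bucketed counts (and optional proportions) of a cohort.

    ``rows`` columns: bucket, stratum, numerator_count, denominator_count,
    proportion.  For a plain incidence trend numerator and denominator both
    carry the bucket count and the proportion is NaN; for a proportion
    trend the numerator cohort is nested in the denominator cohort and
    empty-denominator buckets report a NaN proportion.
    """

    interval: str
    strata: Optional[str]
    rows: pd.DataFrame

    def render(self, decimals: int = 1) -> str:
        lines = []
        for r in self.rows.itertuples():
            label = f"{r.bucket}" + (f" [{r.stratum}]" if r.stratum else "")
            if pd.isna(r.proportion):
                lines.append(f"{label}: {int(r.denominator_count)}")
            else:
                lines.append(
                    f"{label}: {int(r.numerator_count)}/{int(r.denominator_count)} "
                    f"({format_percent(int(r.numerator_count), int(r.denominator_count), decimals)})"
                )
        return "\n".join(lines)


def _bucket_label(period: pd.Period, interval: str) -> str:
    if interval == "monthly":
        return f"{period.year}-{period.month:02d}"
    if interval == "quarterly":
        return f"{period.year} Q{period.quarter}"
    return str(period.year)


def _bucket_labels_for_span(start, end, interval: str) -> list[str]:
    freq = INTERVALS[interval]
    periods = pd.period_range(pd.Timestamp(start), pd.Timestamp(end), freq=freq)
    return [_bucket_label(p, interval) for p in periods]


def _member_frame(
    plist: PatientList,
    strata: Optional[str],
    ds: Optional[EhrDataset],
    library: Optional[TemplateLibrary],
    interval: str,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {"patient_id": list(plist.members), "index_date": list(plist.members.values())}
    )
    if len(df):
        periods = pd.PeriodIndex(df["index_date"], freq=INTERVALS[interval])
        df["bucket"] = [_bucket_label(p, interval) for p in periods]
    else:
        df["bucket"] = pd.Series([], dtype=object)
    if strata is None:
        df["stratum"] = ""
    elif strata == "sex":
        if ds is None:
            raise ReportError("sex stratification requires the dataset")
        sex = ds.patients.set_index("patient_id")["sex"]
        df["stratum"] = df["patient_id"].map(sex).fillna("unknown")
    elif strata == "fracture_type":
        if ds is None:
            raise ReportError("fracture_type stratification requires the dataset")
        df["stratum"] = _fracture_types(ds, plist, library)
    else:
        raise ReportError(f"unknown stratum variable {strata!r}")
    return df


def _fracture_types(
    ds: EhrDataset, plist: PatientList, library: Optional[TemplateLibrary]
) -> list[str]:
    """Classify each member by which fracture code set matched on the index day."""
    library = library or builtin_templates()
    hip = library.get("hip_fracture")
    vert = library.get("vertebral_fracture")
    ev = ds.events[ds.events["dimension"] == "diagnosis"]
    ev = ev[ev["patient_id"].isin(plist.members)]
    on_index = ev[ev["event_date"] == ev["patient_id"].map(plist.members)]
    from .engine import _code_mask  # shared memoised matcher

    hip_ids = set(on_index.loc[_code_mask(on_index["code"], hip), "patient_id"])
    vert_ids = set(on_index.loc[_code_mask(on_index["code"], vert), "patient_id"])
    out = []
    for pid in plist.members:
        h, v = pid in hip_ids, pid in vert_ids
        out.append("both" if h and v else "hip" if h else "vertebral" if v else "other")
    return out


def _span_for(plist: PatientList):
    if plist.observation is not None:
        return plist.observation.start, plist.observation.end
    dates = list(plist.members.values())
    return min(dates), max(dates)


def incidence_trend(
    plist: PatientList,
    interval: str = "quarterly",
    strata: Optional[str] = None,
    ds: Optional[EhrDataset] = None,
    library: Optional[TemplateLibrary] = None,
) -> TrendSeries:
    """Newly indexed members per calendar bucket over the observation span.

    Buckets are calendar-aligned (quarters are Jan-Mar, Apr-Jun, Jul-Sep,
    Oct-Dec) and contiguous: empty buckets appear with zero counts.
    """
    if interval not in INTERVALS:
        raise ReportError(f"unknown interval {interval!r}")
    df = _member_frame(plist, strata, ds, library, interval)
    if len(plist) == 0 and plist.observation is None:
        rows = pd.DataFrame(columns=["bucket", "stratum", "numerator_count",
                                     "denominator_count", "proportion"])
        return TrendSeries(interval, strata, rows)

    labels = _bucket_labels_for_span(*_span_for(plist), interval)
    strata_levels = sorted(df["stratum"].unique()) if len(df) else [""]
    counts = df.groupby(["bucket", "stratum"]).size()
    rows = []
    for stratum in strata_levels:
        for label in labels:
            c = int(counts.get((label, stratum), 0))
            rows.append({"bucket": label, "stratum": stratum,
                         "numerator_count": c, "denominator_count": c,
                         "proportion": np.nan})
    return TrendSeries(interval, strata, pd.DataFrame(rows))


def proportion_trend(
    numerator_list: PatientList,
    denominator_list: PatientList,
    interval: str = "quarterly",
    strata: Optional[str] = None,
    ds: Optional[EhrDataset] = None,
    library: Optional[TemplateLibrary] = None,
) -> TrendSeries:
    """Per-bucket share of a nested cohort over its source cohort.

    The numerator members must be a subset of the denominator members
    (e.g. treated patients over all incident patients).
    """
    if interval not in INTERVALS:
        raise ReportError(f"unknown interval {interval!r}")
    extra = set(numerator_list.members) - set(denominator_list.members)
    if extra:
        raise ReportError(
            f"numerator is not nested in denominator ({len(extra)} extra member(s))"
        )
    num = _member_frame(numerator_list, strata, ds, library, interval)
    den = _member_frame(denominator_list, strata, ds, library, interval)
    labels = _bucket_labels_for_span(*_span_for(denominator_list), interval)
    strata_levels = sorted(den["stratum"].unique()) if len(den) else [""]
    num_counts = num.groupby(["bucket", "stratum"]).size()
    den_counts = den.groupby(["bucket", "stratum"]).size()
    rows = []
    for stratum in strata_levels:
        for label in labels:
            n = int(num_counts.get((label, stratum), 0))
            d = int(den_counts.get((label, stratum), 0))
            rows.append({
                "bucket": label, "stratum": stratum,
                "numerator_count": n, "denominator_count": d,
                "proportion": (n / d) if d else np.nan,
            })
    return TrendSeries(interval, strata, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# attrition (source record)


@dataclass
class AttritionReport:
    """Step-level included/excluded counts from root list to leaf."""

    rows: pd.DataFrame  # case_number, topic, parent, step, excluded, remaining

    def render(self) -> str:
        lines = []
        for r in self.rows.itertuples():
            excl = "" if pd.isna(r.excluded) else f" (excluded {int(r.excluded)})"
            lines.append(f"[{r.case_number}] {r.topic} / {r.step}: {int(r.remaining)}{excl}")
        return "\n".join(lines)


def attrition_report(mart: DataMart, case_number: str) -> AttritionReport:
    """Walk parent links from the requested list up to its root and emit
    every identification step in root-to-leaf order."""
    chain: list[PatientList] = []
    seen: set[str] = set()
    current: Optional[str] = case_number
    while current is not None:
        if current in seen:
            raise ReportError(f"cycle in patient-list hierarchy at {current!r}")
        seen.add(current)
        try:
            plist = mart.get(current)
        except EngineError as exc:
            raise ReportError(str(exc)) from exc
        chain.append(plist)
        current = plist.parent
    chain.reverse()

    rows = []
    for plist in chain:
        rows.append({
            "case_number": plist.case_number, "topic": plist.topic,
            "parent": plist.parent, "step": "index",
            "excluded": np.nan, "remaining": plist.attrition.index_count,
        })
        for step in plist.attrition.steps:
            rows.append({
                "case_number": plist.case_number, "topic": plist.topic,
                "parent": plist.parent, "step": step.label,
                "excluded": step.excluded, "remaining": step.remaining,
            })
    return AttritionReport(pd.DataFrame(
        rows, columns=["case_number", "topic", "parent", "step", "excluded", "remaining"]
    ))
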