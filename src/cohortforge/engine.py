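"""Declarative cohort identification with attrition provenance.

The engine executes *identification specs*: find each patient's index date
(first qualifying diagnosis inside an observation window), then apply an
ordered list of inclusion/exclusion criteria whose time windows are signed
day-offsets relative to the index date.  Every run produces a
:class:`PatientList` — a reusable, uniquely numbered cohort stored in a
:class:`DataMart` — carrying a step-by-step :class:`AttritionRecord` and the
wall-clock cost of the query.  A list may name a previously stored list as
its source population, giving the mart a traceable hierarchy of nested
cohorts.

Window conventions
------------------
Criterion windows are inclusive day-offset intervals ``[low, high]``
relative to the index date: a 1-year lookback is ``[-365, -1]``, treatment
ascertainment within a year is ``[+1, +365]``, a 3-month follow-up window is
``[+1, +90]``.  Events on the index day itself (offset 0) belong to neither
lookback nor follow-up.

Attrition attribution is sequential: a patient excludable by several
criteria is counted only under the first one in declared order, so the
per-step counts are disjoint and sum with the final cohort size back to the
index count.  The final member set itself does not depend on criterion
order.
"""

from __future__ import annotations

import json
import logging
import time
import uuid
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .ehr_store import CARE_SETTINGS, EhrDataset
from .templates import (
    DEFAULT_AOM_DURATIONS,
    Template,
    TemplateLibrary,
    builtin_templates,
    match_code,
)

logger = logging.getLogger(__name__)

WASHOUT_MODES = ("first_ever", "none")
ACTIONS = ("exclude_if_present", "require_presence")


class EngineError(ValueError):
    """Invalid spec, unresolvable reference, or malformed mart state."""


def _as_date(v) -> date:
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    return pd.Timestamp(v).date()


@dataclass(frozen=True)
class ObservationWindow:
    """Inclusive calendar interval delimiting the study period."""

    start: date
    end: date

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.start > self.end:
            raise EngineError(f"observation window out of order: {self.start} > {self.end}")


@dataclass(frozen=True)
class IndexRule:
    """How the index event is chosen.

    ``washout`` controls the new-user restriction applied at indexing time:
    ``"first_ever"`` (default) admits a patient only when no matching
    diagnosis exists anywhere before the observation window, while
    ``"none"`` takes the first matching diagnosis inside the window and
    leaves any washout to explicit lookback criteria.
    """

    template: str
    settings: Optional[frozenset] = None
    washout: str = "first_ever"

    def __post_init__(self):
        if self.settings is not None:
            settings = frozenset(self.settings)
            bad = settings - set(CARE_SETTINGS)
            if bad:
                raise EngineError(f"index rule: unknown settings {sorted(bad)}")
            object.__setattr__(self, "settings", settings)
        if self.washout not in WASHOUT_MODES:
            raise EngineError(f"index rule: unknown washout mode {self.washout!r}")


@dataclass(frozen=True)
class Criterion:
    """One ordered inclusion/exclusion step.

    Exactly one target must be set: a ``template`` reference (events on the
    template's dimension), ``encounter=True`` (hospital contacts), or an
    ``age_minimum`` in completed years.  Age criteria take no window and
    always mean "keep members aged at least the threshold at index".
    """

    label: str
    action: str
    template: Optional[str] = None
    encounter: bool = False
    age_minimum: Optional[int] = None
    window: Optional[tuple[int, int]] = None
    settings: Optional[frozenset] = None

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise EngineError(f"criterion {self.label!r}: unknown action {self.action!r}")
        targets = sum([self.template is not None, bool(self.encounter),
                       self.age_minimum is not None])
        if targets != 1:
            raise EngineError(f"criterion {self.label!r}: exactly one target required")
        if self.age_minimum is not None:
            if self.window is not None:
                raise EngineError(f"criterion {self.label!r}: age criteria carry no window")
        else:
            if self.window is None:
                raise EngineError(f"criterion {self.label!r}: window required")
            low, high = self.window
            if low > high:
                raise EngineError(f"criterion {self.label!r}: window out of order")
            object.__setattr__(self, "window", (int(low), int(high)))
        if self.settings is not None:
            settings = frozenset(self.settings)
            bad = settings - set(CARE_SETTINGS)
            if bad:
                raise EngineError(f"criterion {self.label!r}: unknown settings {sorted(bad)}")
            object.__setattr__(self, "settings", settings)


@dataclass(frozen=True)
class IdentificationSpec:
    """A complete declarative cohort definition."""

    topic: str
    observation: ObservationWindow
    index: IndexRule
    criteria: tuple[Criterion, ...] = ()
    source_list: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise EngineError(f"spec {self.topic!r}: criterion labels must be unique")

    def validate(self, library: TemplateLibrary) -> None:
        tmpl = library.get(self.index.template)
        if tmpl.dimension != "diagnosis":
            raise EngineError(
                f"spec {self.topic!r}: index template {tmpl.name!r} is not diagnosis-dimension"
            )
        for c in self.criteria:
            if c.template is not None:
                library.get(c.template)


@dataclass(frozen=True)
class AttritionStep:
    label: str
    excluded: int
    remaining: int


@dataclass
class AttritionRecord:
    """Index count followed by per-criterion exclusion bookkeeping."""

    index_count: int
    steps: list[AttritionStep] = field(default_factory=list)

    @property
    def final_count(self) -> int:
        return self.steps[-1].remaining if self.steps else self.index_count

    def check_conserved(self) -> None:
        remaining = self.index_count
        for step in self.steps:
            if step.remaining != remaining - step.excluded:
                raise EngineError(f"attrition not conserved at step {step.label!r}")
            remaining = step.remaining


@dataclass
class PatientList:
    """A stored identification result: the patient-level data-mart entry."""

    case_number: str
    topic: str
    members: dict[str, pd.Timestamp]
    attrition: AttritionRecord
    observation: ObservationWindow
    parent: Optional[str] = None
    created_at: Optional[datetime] = None
    cost: float = 0.0

    def __len__(self) -> int:
        return len(self.members)


class DataMart:
    """Insertion-ordered collection of patient lists plus an audit log."""

    def __init__(self):
        self._lists: dict[str, PatientList] = {}
        self.audit: list[dict] = []

    def add(self, plist: PatientList) -> None:
        if plist.case_number in self._lists:
            raise EngineError(f"duplicate case number {plist.case_number!r}")
        self._lists[plist.case_number] = plist

    def get(self, case_number: str) -> PatientList:
        try:
            return self._lists[case_number]
        except KeyError:
            raise EngineError(f"unknown case number {case_number!r}") from None

    def resolve(self, ref: str) -> PatientList:
        """Look up a list by case number, else by topic (latest wins)."""
        if ref in self._lists:
            return self._lists[ref]
        matches = [pl for pl in self._lists.values() if pl.topic == ref]
        if not matches:
            raise EngineError(f"no list with case number or topic {ref!r}")
        return matches[-1]

    def __contains__(self, case_number: str) -> bool:
        return case_number in self._lists

    def __len__(self) -> int:
        return len(self._lists)

    @property
    def lists(self) -> list[PatientList]:
        return list(self._lists.values())

    # -- persistence (one directory per case number) ------------------------

    def save(self, directory) -> None:
        base = Path(directory)
        base.mkdir(parents=True, exist_ok=True)
        for pl in self._lists.values():
            sub = base / pl.case_number
            sub.mkdir(exist_ok=True)
            members = pd.DataFrame(
                {"patient_id": list(pl.members),
                 "index_date": [pd.Timestamp(d).strftime("%Y-%m-%d") for d in pl.members.values()]}
            )
            members.to_csv(sub / "members.csv", index=False, lineterminator="\n")
            meta = {
                "case_number": pl.case_number,
                "topic": pl.topic,
                "parent": pl.parent,
                "created_at": pl.created_at.isoformat() if pl.created_at else None,
                "cost_seconds": pl.cost,
                "observation": {"start": pl.observation.start.isoformat(),
                                "end": pl.observation.end.isoformat()},
                "attrition": {
                    "index_count": pl.attrition.index_count,
                    "steps": [{"label": s.label, "excluded": s.excluded,
                               "remaining": s.remaining} for s in pl.attrition.steps],
                },
            }
            (sub / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
        with open(base / "audit.jsonl", "w") as fh:
            for entry in self.audit:
                fh.write(json.dumps(entry) + "\n")

    @classmethod
    def load(cls, directory) -> "DataMart":
        base = Path(directory)
        mart = cls()
        metas = []
        for sub in sorted(base.iterdir()):
            if not (sub / "metadata.json").exists():
                continue
            meta = json.loads((sub / "metadata.json").read_text())
            members_df = pd.read_csv(sub / "members.csv", dtype=str)
            members = {
                str(r.patient_id): pd.Timestamp(r.index_date)
                for r in members_df.itertuples()
            }
            att = AttritionRecord(
                index_count=meta["attrition"]["index_count"],
                steps=[AttritionStep(s["label"], s["excluded"], s["remaining"])
                       for s in meta["attrition"]["steps"]],
            )
            created = meta.get("created_at")
            metas.append(PatientList(
                case_number=meta["case_number"],
                topic=meta["topic"],
                members=members,
                attrition=att,
                observation=ObservationWindow(meta["observation"]["start"],
                                              meta["observation"]["end"]),
                parent=meta.get("parent"),
                created_at=datetime.fromisoformat(created) if created else None,
                cost=float(meta.get("cost_seconds", 0.0)),
            ))
        for pl in sorted(metas, key=lambda p: (p.created_at or datetime.min.replace(tzinfo=timezone.utc))):
            mart.add(pl)
        audit_path = base / "audit.jsonl"
        if audit_path.exists():
            with open(audit_path) as fh:
                mart.audit = [json.loads(line) for line in fh if line.strip()]
        return mart


# ---------------------------------------------------------------------------
# core operations


def age_at(birth_date, on_date) -> int:
    """Completed years between two dates (birthday-anniversary arithmetic)."""
    b = _as_date(birth_date)
    o = _as_date(on_date)
    if b > o:
        raise EngineError(f"birth_date {b} after on_date {o}")
    years = o.year - b.year
    if (o.month, o.day) < (b.month, b.day):
        years -= 1
    return years


def _code_mask(codes: pd.Series, template: Template) -> pd.Series:
    """Vectorised match_code over a code column (memoised on unique codes)."""
    matched = {c for c in codes.unique() if match_code(c, template)}
    return codes.isin(matched)


def find_index_dates(
    ds: EhrDataset,
    rule: IndexRule,
    window: ObservationWindow,
    library: Optional[TemplateLibrary] = None,
    source: Optional[PatientList] = None,
) -> dict[str, pd.Timestamp]:
    """Earliest qualifying diagnosis date per patient inside the window.

    With washout ``"first_ever"`` a patient is dropped when any matching
    diagnosis predates the window start.  The result is keyed by patient id
    in sorted order; patients without a qualifying date are absent.
    """
    library = library or builtin_templates()
    tmpl = library.get(rule.template)
    if tmpl.dimension != "diagnosis":
        raise EngineError(f"index template {tmpl.name!r} is not diagnosis-dimension")

    ev = ds.events
    mask = (ev["dimension"] == "diagnosis") & _code_mask(ev["code"], tmpl)
    if rule.settings is not None:
        mask &= ev["setting"].isin(rule.settings)
    sub = ev[mask]
    if source is not None:
        sub = sub[sub["patient_id"].isin(source.members)]
    if sub.empty:
        return {}

    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    first_any = sub.groupby("patient_id")["event_date"].min()
    in_window = sub[(sub["event_date"] >= start) & (sub["event_date"] <= end)]
    first_in_window = in_window.groupby("patient_id")["event_date"].min()

    out: dict[str, pd.Timestamp] = {}
    for pid in sorted(first_in_window.index):
        if rule.washout == "first_ever" and first_any[pid] < start:
            continue
        out[pid] = first_in_window[pid]
    return out


def apply_criterion(
    ds: EhrDataset,
    members: Mapping[str, pd.Timestamp],
    criterion: Criterion,
    library: Optional[TemplateLibrary] = None,
) -> tuple[dict[str, pd.Timestamp], int]:
    """Evaluate one criterion; returns (survivors, excluded_count).

    ``exclude_if_present`` drops members with at least one matching
    event/encounter inside the index-relative window; ``require_presence``
    keeps only such members; ``age_minimum`` keeps members whose completed
    age at index reaches the threshold.
    """
    library = library or builtin_templates()
    members = dict(members)
    if not members:
        return {}, 0

    if criterion.age_minimum is not None:
        births = ds.patients.set_index("patient_id")["birth_date"]
        survivors = {
            pid: idx for pid, idx in members.items()
            if age_at(births[pid], idx) >= criterion.age_minimum
        }
        return survivors, len(members) - len(survivors)

    if criterion.template is not None:
        tmpl = library.get(criterion.template)
        tab = ds.events
        mask = (tab["dimension"] == tmpl.dimension) & _code_mask(tab["code"], tmpl)
        date_col = "event_date"
    else:
        tab = ds.encounters
        mask = pd.Series(True, index=tab.index)
        date_col = "encounter_date"
    if criterion.settings is not None:
        mask &= tab["setting"].isin(criterion.settings)

    sub = tab[mask & tab["patient_id"].isin(members)]
    low, high = criterion.window
    if sub.empty:
        hit: set[str] = set()
    else:
        offsets = (sub[date_col] - sub["patient_id"].map(members)).dt.days
        hit = set(sub.loc[(offsets >= low) & (offsets <= high), "patient_id"])

    if criterion.action == "exclude_if_present":
        survivors = {pid: idx for pid, idx in members.items() if pid not in hit}
    else:
        survivors = {pid: idx for pid, idx in members.items() if pid in hit}
    return survivors, len(members) - len(survivors)


def run_identification(
    ds: EhrDataset,
    spec: IdentificationSpec,
    mart: Optional[DataMart] = None,
    library: Optional[TemplateLibrary] = None,
) -> PatientList:
    """Execute one spec: index, criteria in order, attrition, storage.

    An empty index set is a valid (empty) result, not an error.  When a
    mart is given, the spec's ``source_list`` is resolved against it and
    the fresh list is stored in it.
    """
    library = library or builtin_templates()
    spec.validate(library)
    source = None
    if spec.source_list is not None:
        if mart is None:
            raise EngineError(f"spec {spec.topic!r} names a source list but no mart given")
        source = mart.resolve(spec.source_list)

    t0 = time.perf_counter()
    members = find_index_dates(ds, spec.index, spec.observation, library, source)
    attrition = AttritionRecord(index_count=len(members))
    for criterion in spec.criteria:
        members, excluded = apply_criterion(ds, members, criterion, library)
        attrition.steps.append(AttritionStep(criterion.label, excluded, len(members)))
    cost = time.perf_counter() - t0
    attrition.check_conserved()

    plist = PatientList(
        case_number=str(uuid.uuid4()),
        topic=spec.topic,
        members=members,
        attrition=attrition,
        observation=spec.observation,
        parent=source.case_number if source is not None else None,
        created_at=datetime.now(timezone.utc),
        cost=cost,
    )
    if mart is not None:
        mart.add(plist)
    return plist


def run_batch(
    specs: Sequence[IdentificationSpec],
    ds: EhrDataset,
    mart: DataMart,
    library: Optional[TemplateLibrary] = None,
) -> list[PatientList]:
    """Run specs strictly first-in-first-out with per-task audit entries.

    A failing spec is logged in the audit trail and skipped; later specs
    still run.  Returns the successful lists in submission order.
    """
    results: list[PatientList] = []
    for spec in specs:
        started = datetime.now(timezone.utc).isoformat()
        try:
            plist = run_identification(ds, spec, mart, library)
        except Exception as exc:  # noqa: BLE001 — queue must keep going
            logger.error("identification %r failed: %s", spec.topic, exc)
            mart.audit.append({
                "timestamp": started,
                "topic": spec.topic,
                "status": "failed",
                "error": str(exc),
            })
            continue
        mart.audit.append({
            "timestamp": started,
            "case_number": plist.case_number,
            "topic": plist.topic,
            "status": "ok",
            "cost_seconds": plist.cost,
            "n_identified": len(plist),
        })
        results.append(plist)
    return results


# ---------------------------------------------------------------------------
# pharmacy duration normalisation (opt-in exposure correction)


def normalize_pharmacy_durations(
    ds: EhrDataset,
    durations: Optional[Mapping[str, int]] = None,
    nominal_threshold: int = 30,
) -> EhrDataset:
    """Correct dispensing rows whose recorded duration understates exposure.

    Some long-acting drugs (annual or semi-annual injections) are recorded
    as 1-day prescriptions.  For pharmacy rows whose drug appears in
    ``durations`` with a canonical duration above ``nominal_threshold``
    days and whose recorded ``duration_days`` is 1, the recorded value is
    replaced by the canonical one.  Returns a new dataset; the input is
    untouched.
    """
    durations = dict(DEFAULT_AOM_DURATIONS if durations is None else durations)
    ev = ds.events.copy()
    eligible = {drug for drug, days in durations.items() if days > nominal_threshold}
    mask = (
        (ev["dimension"] == "pharmacy")
        & ev["code"].isin(eligible)
        & (ev["duration_days"] == 1)
    )
    ev.loc[mask, "duration_days"] = ev.loc[mask, "code"].map(durations).astype("Int64")
    return EhrDataset(patients=ds.patients.copy(), events=ev, encounters=ds.encounters.copy())


# ---------------------------------------------------------------------------
# spec files


def _criterion_from_mapping(doc: Mapping) -> Criterion:
    window = doc.get("window")
    return Criterion(
        label=doc["label"],
        action=doc["action"],
        template=doc.get("template"),
        encounter=bool(doc.get("encounter", False)),
        age_minimum=doc.get("age_minimum"),
        window=tuple(window) if window is not None else None,
        settings=frozenset(doc["settings"]) if doc.get("settings") else None,
    )


def spec_from_mapping(doc: Mapping) -> IdentificationSpec:
    """Build an :class:`IdentificationSpec` from a parsed YAML/JSON mapping."""
    try:
        obs = doc["observation"]
        index = doc["index"]
        return IdentificationSpec(
            topic=doc["topic"],
            observation=ObservationWindow(obs["start"], obs["end"]),
            index=IndexRule(
                template=index["template"],
                settings=frozenset(index["settings"]) if index.get("settings") else None,
                washout=index.get("washout", "first_ever"),
            ),
            criteria=tuple(_criterion_from_mapping(c) for c in doc.get("criteria", [])),
            source_list=doc.get("source_list"),
        )
    except KeyError as exc:
        raise EngineError(f"study spec is missing required field {exc}") from exc


def load_specs(path) -> list[IdentificationSpec]:
    """Read one spec or a ``queue`` of specs from a YAML/JSON document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise EngineError(f"{path}: not a study-spec document")
    items = doc["queue"] if "queue" in doc else [doc]
    return [spec_from_mapping(item) for item in items]
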