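"""Independent per-patient reference interpreter used as a test oracle.

Deliberately naive: pure-python loops over row dicts, its own regex-based
code matching and its own date arithmetic, sharing no code paths with the
package's vectorised engine.
"""

from __future__ import annotations

import re
from datetime import date


def add_years(d: date, k: int) -> date:
    try:
        return d.replace(year=d.year + k)
    except ValueError:  # Feb 29 anniversary in a non-leap year
        return d.replace(year=d.year + k, month=3, day=1)


def naive_age(birth: date, on: date) -> int:
    """Completed years by walking birthday anniversaries."""
    k = 0
    while add_years(birth, k + 1) <= on:
        k += 1
    return k


def naive_code_matches(code: str, template) -> bool:
    for p in template.patterns:
        if p.kind == "exact":
            if code == p.value:
                return True
        elif p.kind == "prefix":
            if re.fullmatch(re.escape(p.value) + r"(\..*)?", code):
                return True
        else:  # range
            m = re.fullmatch(r"(\d{3})(\..*)?", code)
            if m and p.low <= int(m.group(1)) <= p.high:
                return True
    return False


def dataset_rows(ds):
    """Convert an EhrDataset into plain per-patient python structures."""
    import pandas as pd

    patients = {}
    for r in ds.patients.itertuples():
        patients[r.patient_id] = {
            "birth": r.birth_date.date() if pd.notna(r.birth_date) else None,
            "sex": r.sex,
        }
    events: dict[str, list] = {pid: [] for pid in patients}
    for r in ds.events.itertuples():
        events[r.patient_id].append(
            {"date": r.event_date.date(), "dimension": r.dimension,
             "code": r.code, "setting": r.setting}
        )
    encounters: dict[str, list] = {pid: [] for pid in patients}
    for r in ds.encounters.itertuples():
        encounters[r.patient_id].append(
            {"date": r.encounter_date.date(), "setting": r.setting}
        )
    return patients, events, encounters


def naive_identify(rows, spec, library, source_members=None):
    """Run one identification spec patient by patient.

    Returns (members: dict pid -> date, attrition: list of
    (label, excluded, remaining)) mirroring the engine's contract.
    """
    patients, events, encounters = rows
    tmpl = library.get(spec.index.template)
    start, end = spec.observation.start, spec.observation.end

    members = {}
    pool = patients if source_members is None else source_members
    for pid in sorted(pool):
        dx_dates = [
            e["date"] for e in events[pid]
            if e["dimension"] == "diagnosis"
            and naive_code_matches(e["code"], tmpl)
            and (spec.index.settings is None or e["setting"] in spec.index.settings)
        ]
        in_win = [d for d in dx_dates if start <= d <= end]
        if not in_win:
            continue
        if spec.index.washout == "first_ever" and any(d < start for d in dx_dates):
            continue
        members[pid] = min(in_win)

    attrition = []
    for crit in spec.criteria:
        survivors = {}
        for pid, idx in members.items():
            if crit.age_minimum is not None:
                keep = naive_age(patients[pid]["birth"], idx) >= crit.age_minimum
            else:
                low, high = crit.window
                if crit.template is not None:
                    ctmpl = library.get(crit.template)
                    rows_ = [
                        e for e in events[pid]
                        if e["dimension"] == ctmpl.dimension
                        and naive_code_matches(e["code"], ctmpl)
                    ]
                else:
                    rows_ = encounters[pid]
                if crit.settings is not None:
                    rows_ = [e for e in rows_ if e["setting"] in crit.settings]
                hit = any(low <= (e["date"] - idx).days <= high for e in rows_)
                keep = (not hit) if crit.action == "exclude_if_present" else hit
            if keep:
                survivors[pid] = idx
        attrition.append((crit.label, len(members) - len(survivors), len(survivors)))
        members = survivors
    return members, attrition
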