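"""Reusable clinical-order templates (code sets) and their matching semantics.

A *template* names a set of clinical codes on one dimension (diagnosis,
pharmacy, procedure, laboratory) so a cohort definition can refer to
"osteoporotic fracture" or "anti-osteoporosis medication" instead of raw
code lists.  Three pattern kinds are supported:

``exact``
    the code string itself (``731.0`` matches only ``731.0``);
``prefix``
    an ICD-9 three-character category stem: ``820`` matches ``820`` and any
    dotted subcode ``820.x``, but never ``8200`` — categories are exactly
    three characters and subcodes follow a decimal point;
``range``
    an inclusive pair of integer ICD-9 categories (``140``–``208``); a
    code matches when its leading category is a three-digit integer inside
    the bounds.  V- and E-codes never match a numeric range.

Pharmacy templates match dispensing records exact-only against lowercase
canonical drug names.  Libraries are persisted as a single version-tagged
YAML document so they can be reviewed, diffed and shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

from .ehr_store import DIMENSIONS

LIBRARY_SCHEMA_VERSION = 1

#: Canonical lowercase names of the anti-osteoporosis medications (AOMs)
#: covered by the built-in ``aom`` template.
AOM_DRUGS = (
    "alendronate",
    "zolendronate",
    "ibandronate",
    "denosumab",
    "raloxifene",
    "teriparatide",
    "estradiol valerate",
    "conjugated estrogens",
    "calcitonin",
)

#: Default pharmacological exposure durations (days) for drugs whose
#: dispensing records commonly carry a nominal 1-day duration even though a
#: single administration covers a long interval (e.g. annual infusions).
DEFAULT_AOM_DURATIONS = {
    "zolendronate": 365,
    "denosumab": 180,
    "ibandronate": 90,
}


class TemplateError(ValueError):
    """Raised for malformed templates, patterns, or library documents."""


@dataclass(frozen=True)
class CodePattern:
    """One matching rule inside a template.

    Parameters
    ----------
    kind : {"exact", "prefix", "range"}
    value : str, optional
        The code (exact) or category stem (prefix); unused for ranges.
    low, high : int, optional
        Inclusive 3-digit ICD-9 category bounds; ranges only.
    """

    kind: str
    value: str | None = None
    low: int | None = None
    high: int | None = None

    def __post_init__(self) -> None:
        if self.kind in ("exact", "prefix"):
            if not self.value:
                raise TemplateError(f"{self.kind} pattern requires a non-empty value")
            if self.low is not None or self.high is not None:
                raise TemplateError(f"{self.kind} pattern takes no bounds")
        elif self.kind == "range":
            if self.low is None or self.high is None:
                raise TemplateError("range pattern requires low and high bounds")
            if self.low > self.high:
                raise TemplateError(f"range bounds out of order: {self.low} > {self.high}")
            if self.value is not None:
                raise TemplateError("range pattern takes no value")
        else:
            raise TemplateError(f"unknown pattern kind {self.kind!r}")


def pattern_matches(code: str, pattern: CodePattern) -> bool:
    """True iff ``code`` satisfies one pattern (see module docstring)."""
    if pattern.kind == "exact":
        return code == pattern.value
    if pattern.kind == "prefix":
        return code == pattern.value or code.startswith(pattern.value + ".")
    # range: leading category must be a 3-digit integer inside the bounds
    category = code.split(".", 1)[0]
    if len(category) != 3 or not category.isdigit():
        return False
    return pattern.low <= int(category) <= pattern.high


@dataclass(frozen=True)
class Template:
    """A named clinical-order definition on one dimension."""

    name: str
    dimension: str
    patterns: tuple[CodePattern, ...]
    description: str = ""
    public: bool = True

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise TemplateError(f"template {self.name!r}: unknown dimension {self.dimension!r}")
        if not self.patterns:
            raise TemplateError(f"template {self.name!r}: needs at least one pattern")
        if self.dimension != "diagnosis" and any(p.kind == "range" for p in self.patterns):
            raise TemplateError(
                f"template {self.name!r}: range patterns are diagnosis-only"
            )
        object.__setattr__(self, "patterns", tuple(self.patterns))


def match_code(code: str, template: Template) -> bool:
    """True iff ``code`` matches any pattern of ``template``."""
    if not code:
        raise TemplateError("cannot match an empty code")
    return any(pattern_matches(code, p) for p in template.patterns)


class TemplateLibrary:
    """Name-keyed collection of templates with unique names."""

    def __init__(self, templates: Iterator[Template] | None = None):
        self._templates: dict[str, Template] = {}
        for t in templates or ():
            self.add(t)

    def add(self, template: Template) -> None:
        if template.name in self._templates:
            raise TemplateError(f"duplicate template name {template.name!r}")
        self._templates[template.name] = template

    def get(self, name: str) -> Template:
        try:
            return self._templates[name]
        except KeyError:
            raise TemplateError(f"unknown template {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._templates

    def __len__(self) -> int:
        return len(self._templates)

    def __iter__(self) -> Iterator[Template]:
        return iter(self._templates.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemplateLibrary):
            return NotImplemented
        return self._templates == other._templates

    @property
    def names(self) -> list[str]:
        return list(self._templates)


def builtin_templates() -> TemplateLibrary:
    """The packaged library for the osteoporotic-fracture worked example.

    Contains the hip (ICD-9 820) and vertebral (805, 806) fracture code
    sets, their union, the malignant-neoplasm category range 140-208, Paget
    disease of bone (731.0), and the nine anti-osteoporosis medications.
    """
    hip = (CodePattern("prefix", "820"),)
    vertebral = (CodePattern("prefix", "805"), CodePattern("prefix", "806"))
    lib = TemplateLibrary()
    lib.add(Template("hip_fracture", "diagnosis", hip, "Hip fracture (ICD-9 820)"))
    lib.add(Template("vertebral_fracture", "diagnosis", vertebral,
                     "Vertebral fracture (ICD-9 805, 806)"))
    lib.add(Template("osteoporotic_fracture", "diagnosis", hip + vertebral,
                     "Hip or vertebral fracture (ICD-9 820, 805, 806)"))
    lib.add(Template("malignancy", "diagnosis", (CodePattern("range", low=140, high=208),),
                     "Malignant neoplasm (ICD-9 140-208)"))
    lib.add(Template("paget", "diagnosis", (CodePattern("exact", "731.0"),),
                     "Paget disease of bone (ICD-9 731.0)"))
    lib.add(Template("aom", "pharmacy",
                     tuple(CodePattern("exact", d) for d in AOM_DRUGS),
                     "Anti-osteoporosis medications"))
    return lib


# ---------------------------------------------------------------------------
# persistence


def _pattern_to_doc(p: CodePattern) -> dict:
    if p.kind == "range":
        return {"kind": "range", "low": p.low, "high": p.high}
    return {"kind": p.kind, "value": p.value}


def _pattern_from_doc(doc: dict) -> CodePattern:
    kind = doc.get("kind")
    if kind == "range":
        return CodePattern("range", low=doc.get("low"), high=doc.get("high"))
    return CodePattern(kind, value=doc.get("value"))


def save_library(lib: TemplateLibrary, path: str | Path) -> None:
    """Write a library as one YAML document (schema-versioned)."""
    doc = {
        "version": LIBRARY_SCHEMA_VERSION,
        "templates": [
            {
                "name": t.name,
                "dimension": t.dimension,
                "description": t.description,
                "public": t.public,
                "patterns": [_pattern_to_doc(p) for p in t.patterns],
            }
            for t in lib
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_library(path: str | Path) -> TemplateLibrary:
    """Read a library document; duplicate names or bad dimensions are fatal."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "templates" not in doc:
        raise TemplateError(f"{path}: not a template-library document")
    lib = TemplateLibrary()
    for tdoc in doc["templates"]:
        try:
            patterns = tuple(_pattern_from_doc(p) for p in tdoc.get("patterns", []))
            template = Template(
                name=tdoc["name"],
                dimension=tdoc.get("dimension", ""),
                patterns=patterns,
                description=tdoc.get("description", ""),
                public=bool(tdoc.get("public", True)),
            )
        except (KeyError, TemplateError) as exc:
            raise TemplateError(f"template {tdoc.get('name', '?')!r}: {exc}") from exc
        lib.add(template)
    return lib
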