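"""Controlled vocabulary for RCPath colorectal cancer reporting fields.

The Royal College of Pathologists (RCPath) dataset for colorectal cancer
defines a fixed list of reportable items (specimen type, tumour type and
site, maximum diameter, TNM components, grade, node counts and resection
status), each with a closed value set.  This module loads that vocabulary
from a versioned JSON document, normalises free-text surface forms onto
canonical values ("T4A" -> "pT4a", "45 mm" -> 45), maps specific TNM
sub-stages onto their broad categories (pT4a -> pT4), and runs cross-field
sanity checks (e.g. metastatic node count versus pN bin).

Every other module treats the objects defined here as the single source of
truth for what a field value *is*.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "FieldSchema",
    "CanonicalValue",
    "SchemaNotFoundError",
    "SchemaSet",
    "ConsistencyFinding",
    "load_schema_set",
    "get_field_schema",
    "normalize_value",
    "to_broad",
    "check_report_consistency",
    "FIELD_NAMES",
]

_SCHEMA_RESOURCE = "rcpath_colorectal_v1.json"

# Surface forms that mean "the report does not state this field", for any field.
_GENERIC_NA = frozenset(
    {
        "na",
        "n/a",
        "not available",
        "not stated",
        "not reported",
        "not specified",
        "unknown",
        "cannot be assessed",
        "not assessable",
        "missing",
        "none given",
    }
)

_NUMERIC_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*"
    r"(mm|millimetres?|millimeters?|cm|centimetres?|centimeters?|"
    r"(?:lymph\s+)?nodes?)?\s*\.?\s*$",
    re.IGNORECASE,
)


class SchemaNotFoundError(KeyError):
    """Raised when a field name is not part of the loaded schema."""


@dataclass(frozen=True)
class CanonicalValue:
    """A validated value for one field: canonical string or integer."""

    field: str
    value: str | int
    is_na: bool = False

    def __str__(self) -> str:  # display form used in proforma and JSON keys
        return str(self.value)


@dataclass(frozen=True)
class FieldSchema:
    """Vocabulary, aliases and granularity map for a single query field."""

    name: str
    label: str
    kind: str  # "categorical" | "numeric"
    categorical_values: tuple[str, ...]
    na_sentinel: str
    aliases: Mapping[str, str]
    broad_map: Mapping[str, str]
    numeric_range: tuple[int, int] | None = None
    unit: str | None = None
    tnm_prefix: bool = False
    catch_all: str | None = None
    catch_all_pattern: str | None = None
    descriptions: Mapping[str, str] = dc_field(default_factory=dict)
    example_snippet: str = ""
    example_value: str = ""
    ordinal_scale: tuple[str, ...] = ()

    @property
    def na_value(self) -> CanonicalValue:
        return CanonicalValue(self.name, self.na_sentinel, True)

    def canonical_values(self) -> tuple[CanonicalValue, ...]:
        """All canonical values; for numeric fields, the NA sentinel only."""
        if self.kind == "numeric":
            return (self.na_value,)
        return tuple(
            CanonicalValue(self.name, v, v == self.na_sentinel)
            for v in self.categorical_values
        )

    def surface_forms(self, canonical: str) -> list[str]:
        """Surface strings that normalise to ``canonical`` (aliases + variants)."""
        forms = [canonical]
        forms += [a for a, c in self.aliases.items() if c == canonical]
        if self.tnm_prefix and canonical.lower().startswith("p"):
            bare = canonical[1:]
            forms += [bare, bare.upper(), bare.lower()]
        # dedupe preserving order; case variants are kept deliberately, since
        # reports really do write "T4A" and "t4a" and prompts should say so
        seen: set[str] = set()
        out = []
        for f in forms:
            if f not in seen:
                seen.add(f)
                out.append(f)
        return out


class SchemaSet:
    """The full field schema document (one object per field), versioned."""

    def __init__(self, doc: Mapping) -> None:
        self.schema_name: str = doc["schema_name"]
        self.version: str = doc["version"]
        self.proforma_order: tuple[str, ...] = tuple(doc["proforma_order"])
        self._fields: dict[str, FieldSchema] = {}
        for name, spec in doc["fields"].items():
            values = tuple(spec.get("values", []))
            broad = dict(spec.get("broad_map", {}))
            # totalise + idempotence: values without an entry map to themselves
            for v in values:
                broad.setdefault(v, v)
            rng = spec.get("numeric_range")
            self._fields[name] = FieldSchema(
                name=name,
                label=spec["label"],
                kind=spec["kind"],
                categorical_values=values,
                na_sentinel=spec["na_sentinel"],
                aliases={k.casefold(): v for k, v in spec.get("aliases", {}).items()},
                broad_map=broad,
                numeric_range=tuple(rng) if rng else None,
                unit=spec.get("unit"),
                tnm_prefix=bool(spec.get("tnm_prefix", False)),
                catch_all=spec.get("catch_all"),
                catch_all_pattern=spec.get("catch_all_pattern"),
                descriptions=spec.get("descriptions", {}),
                example_snippet=spec.get("example", {}).get("snippet", ""),
                example_value=spec.get("example", {}).get("value", ""),
                ordinal_scale=tuple(spec.get("ordinal_scale", [])),
            )
        self._label_to_name = {
            fs.label.casefold(): fs.name for fs in self._fields.values()
        }

    @property
    def field_names(self) -> tuple[str, ...]:
        return self.proforma_order

    def __contains__(self, name: str) -> bool:
        return name in self._fields

    def get(self, name: str) -> FieldSchema:
        try:
            return self._fields[name]
        except KeyError:
            raise SchemaNotFoundError(
                f"unknown field {name!r}; supported: {sorted(self._fields)}"
            ) from None

    def field_for_label(self, label: str) -> str | None:
        return self._label_to_name.get(label.strip().casefold())


def load_schema_set() -> SchemaSet:
    """Load the packaged RCPath colorectal schema document."""
    text = (
        resources.files("pathstruct.data").joinpath(_SCHEMA_RESOURCE).read_text("utf-8")
    )
    return SchemaSet(json.loads(text))


_DEFAULT: SchemaSet | None = None


def default_schema_set() -> SchemaSet:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_schema_set()
    return _DEFAULT


FIELD_NAMES: tuple[str, ...] = tuple(
    json.loads(
        resources.files("pathstruct.data").joinpath(_SCHEMA_RESOURCE).read_text("utf-8")
    )["proforma_order"]
)


def get_field_schema(name: str, schema_set: SchemaSet | None = None) -> FieldSchema:
    """Return the schema for one of the supported RCPath fields."""
    return (schema_set or default_schema_set()).get(name)


def normalize_value(
    field: str, raw: str | int | float, schema_set: SchemaSet | None = None
) -> CanonicalValue | None:
    """Map a surface string onto a canonical value, or ``None`` if unparseable.

    Matching is case-insensitive and whitespace-trimmed: canonical spellings
    first, then aliases, then (for TNM fields) a systematic strip/add of the
    "p" prefix, then numeric parsing with unit stripping (cm converted to mm).
    ``None`` is the explicit invalid marker — never a guess — so vote counting
    can treat unparseable replies uniformly.
    """
    fs = get_field_schema(field, schema_set)
    if isinstance(raw, bool):
        return None
    if isinstance(raw, (int, float)):
        raw = str(int(raw)) if float(raw).is_integer() else str(raw)
    if not isinstance(raw, str):
        return None
    s = raw.strip().strip('"').strip()
    if not s:
        return None
    key = s.casefold()

    if key in _GENERIC_NA or key == fs.na_sentinel.casefold():
        return fs.na_value

    if fs.kind == "categorical":
        for v in fs.categorical_values:
            if key == v.casefold():
                return CanonicalValue(field, v, v == fs.na_sentinel)
        if key in fs.aliases:
            v = fs.aliases[key]
            return CanonicalValue(field, v, v == fs.na_sentinel)
        if fs.tnm_prefix:
            candidate = key if key.startswith("p") else "p" + key
            for v in fs.categorical_values:
                if candidate == v.casefold():
                    return CanonicalValue(field, v, v == fs.na_sentinel)
        if fs.catch_all and fs.catch_all_pattern:
            if re.search(fs.catch_all_pattern, key):
                return CanonicalValue(field, fs.catch_all, fs.catch_all == fs.na_sentinel)
        return None

    # numeric field
    m = _NUMERIC_RE.match(s)
    if not m:
        return None
    number = float(m.group(1))
    unit = (m.group(2) or "").lower()
    if unit.startswith("c"):  # centimetres -> millimetres
        number *= 10.0
    value = int(round(number))
    lo, hi = fs.numeric_range  # type: ignore[misc]
    if not lo <= value <= hi:
        return None
    return CanonicalValue(field, value, False)


def to_broad(
    field: str, value: CanonicalValue, schema_set: SchemaSet | None = None
) -> CanonicalValue:
    """Collapse a sub-staged value onto its broad category (pT4a -> pT4).

    Identity for fields without a granularity split, for numeric values and
    for NA sentinels.  Raises ``ValueError`` for non-canonical input.
    """
    fs = get_field_schema(field, schema_set)
    if value.field != field:
        raise ValueError(f"value belongs to field {value.field!r}, not {field!r}")
    if fs.kind == "numeric":
        if value.is_na or isinstance(value.value, int):
            return value
        raise ValueError(f"non-canonical numeric value {value.value!r} for {field!r}")
    if value.value not in fs.broad_map:
        raise ValueError(f"{value.value!r} is not a canonical value of {field!r}")
    broad = fs.broad_map[str(value.value)]
    return CanonicalValue(field, broad, broad == fs.na_sentinel)


@dataclass(frozen=True)
class ConsistencyFinding:
    code: str
    message: str


# standard TNM binning of metastatic node count onto broad pN categories
def pn_bin_for_count(metastatic: int) -> str:
    if metastatic == 0:
        return "pN0"
    if metastatic <= 3:
        return "pN1"
    return "pN2"


def _values_of(report) -> Mapping[str, CanonicalValue]:
    """Accept a StructuredReport or a plain field -> CanonicalValue mapping."""
    results = getattr(report, "results", None)
    if results is not None:
        return {f: r.final_value for f, r in results.items()}
    return report


def check_report_consistency(
    report, schema_set: SchemaSet | None = None
) -> list[ConsistencyFinding]:
    """Cross-field sanity checks on a structured report; never mutates.

    Checks: metastatic node count must not exceed examined count, and the
    reported pN category must agree with the metastatic count under the
    standard bins (0 -> pN0, 1-3 -> pN1, >=4 -> pN2) when both are present.
    """
    values = _values_of(report)
    ss = schema_set or default_schema_set()
    findings: list[ConsistencyFinding] = []

    examined = values.get("examined_nodes")
    metastatic = values.get("metastatic_nodes")
    status = values.get("lymph_node_status")

    if (
        examined is not None
        and metastatic is not None
        and not examined.is_na
        and not metastatic.is_na
        and int(metastatic.value) > int(examined.value)
    ):
        findings.append(
            ConsistencyFinding(
                "node_count_inversion",
                f"metastatic nodes ({metastatic.value}) exceed examined nodes "
                f"({examined.value})",
            )
        )

    if (
        metastatic is not None
        and status is not None
        and not metastatic.is_na
        and not status.is_na
    ):
        expected = pn_bin_for_count(int(metastatic.value))
        broad_status = to_broad("lymph_node_status", status, ss)
        if str(broad_status.value) != expected:
            findings.append(
                ConsistencyFinding(
                    "pn_bin_mismatch",
                    f"lymph node status {status.value} inconsistent with "
                    f"{metastatic.value} metastatic nodes (expected {expected})",
                )
            )
    return findings


def is_missing(value: CanonicalValue | None) -> bool:
    """Treat every field-specific NA sentinel (NA/pTX/pNX/pMX/RX) as missing."""
    return value is None or value.is_na


def iter_all_canonical(
    schema_set: SchemaSet | None = None,
) -> Iterable[CanonicalValue]:
    ss = schema_set or default_schema_set()
    for name in ss.field_names:
        yield from ss.get(name).canonical_values()
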