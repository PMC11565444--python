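"""Prompt construction, backend contract and reply parsing.

All model-specific behaviour sits behind one small interface: a backend is
anything with ``sample(prompt, n_samples, seed) -> list[str]`` that returns
exactly ``n_samples`` verbatim reply strings and never raises on malformed
model output (malformed replies are returned as-is and surface as
``parse_ok=False`` after parsing).

Prompts follow a five-component structure — role, task, format constraints,
examples, and uncertainty handling — with two phrasings (variants) per field
for the extractor and one for the validator.  The two variants deliberately
reword and reorder the same instructions: disagreement between them is part
of the confidence signal.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .field_schema import (
    CanonicalValue,
    FieldSchema,
    SchemaSet,
    default_schema_set,
    normalize_value,
)

__all__ = [
    "PromptSpec",
    "RawReply",
    "Backend",
    "LiveBackend",
    "SECTION_KEYS",
    "NA_DISPLAY",
    "build_extractor_prompt",
    "build_validator_prompt",
    "parse_extraction_reply",
    "parse_validator_reply",
    "parse_prompt_metadata",
    "child_seed",
]

SECTION_KEYS = ("role", "task", "format_constraints", "examples", "uncertainty_handling")

#: surface form the prompts tell the model to use for missing information
NA_DISPLAY = "Not Available"

_CASE_MARKER_RE = re.compile(r"\[\[case:(.+?)\]\]")
_QUERY_FIELD_RE = re.compile(r"^Query field: (.+)$", re.MULTILINE)
_EXTRACTOR_VALUE_RE = re.compile(r"^Extractor's answer: (.+)$", re.MULTILINE)


@dataclass(frozen=True)
class PromptSpec:
    """A rendered prompt plus its five named sections."""

    agent: str  # "extractor" | "validator"
    field: str
    variant: int  # 1 | 2 for the extractor, 1 for the validator
    sections: Mapping[str, str]
    rendered: str


@dataclass(frozen=True)
class RawReply:
    """A verbatim model reply and the result of parsing it."""

    text: str
    parse_ok: bool
    payload: Mapping = dc_field(default_factory=dict)


@runtime_checkable
class Backend(Protocol):
    """Contract: exactly ``n_samples`` reply strings, reproducible per seed."""

    def sample(self, prompt: str, n_samples: int, seed: int) -> list[str]: ...


def child_seed(*parts) -> int:
    """Derive a deterministic sub-seed (< 2**31) from mixed int/str parts."""
    ints = [
        int(p) if isinstance(p, (int, np.integer)) else zlib.crc32(str(p).encode())
        for p in parts
    ]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# prompt templates


def _load_template(name: str) -> list[tuple[str, str]]:
    """Read a template file into an ordered list of (section, text) blocks."""
    text = resources.files("pathstruct.templates").joinpath(name).read_text("utf-8")
    blocks: list[tuple[str, str]] = []
    current: str | None = None
    buf: list[str] = []
    for line in text.splitlines():
        m = re.fullmatch(r"\[(\w+)\]", line)
        if m:
            if current is not None:
                blocks.append((current, "\n".join(buf).strip()))
            current = m.group(1)
            buf = []
        else:
            buf.append(line)
    if current is not None:
        blocks.append((current, "\n".join(buf).strip()))
    return blocks


_TEMPLATE_CACHE: dict[str, list[tuple[str, str]]] = {}


def _template(name: str) -> list[tuple[str, str]]:
    if name not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[name] = _load_template(name)
    return _TEMPLATE_CACHE[name]


def _value_guide(fs: FieldSchema) -> str:
    """Enumerate allowed values with descriptions and alias spellings."""
    if fs.kind == "numeric":
        lo, hi = fs.numeric_range  # type: ignore[misc]
        unit = "millimetres" if fs.unit == "mm" else "a count"
        return (
            f"- an integer between {lo} and {hi} ({unit}); report centimetre\n"
            f"  measurements converted to millimetres\n"
            f'- "{NA_DISPLAY}" when the report does not state it'
        )
    lines = []
    for v in fs.categorical_values:
        desc = fs.descriptions.get(v, "")
        alts = [a for a in fs.surface_forms(v) if a != v]
        line = f"- {v}"
        if desc:
            line += f": {desc}"
        if alts:
            line += " (may also be written as " + ", ".join(f'"{a}"' for a in alts) + ")"
        lines.append(line)
    return "\n".join(lines)


def _render(
    blocks: list[tuple[str, str]], subs: Mapping[str, str], case_marker: str | None
) -> tuple[dict[str, str], str]:
    sections: dict[str, str] = {}
    rendered_parts: list[str] = []
    for key, raw in blocks:
        text = raw.format(**subs)
        sections[key] = text
        rendered_parts.append(text)
    rendered = "\n\n".join(rendered_parts)
    if case_marker:
        rendered += f"\n\n[[case:{case_marker}]]"
    return sections, rendered


def build_extractor_prompt(
    field: str,
    variant: int,
    report_text: str,
    schema: FieldSchema | None = None,
    schema_set: SchemaSet | None = None,
    case_marker: str | None = None,
) -> PromptSpec:
    """Render one of the two extractor prompt variants for a query field.

    ``case_marker`` appends a machine-resolvable case identifier footer; it is
    used only with the simulated backend and never in production prompts.
    """
    if variant not in (1, 2):
        raise ValueError("extractor prompt variant must be 1 or 2")
    if not report_text:
        raise ValueError("report_text must be non-empty")
    ss = schema_set or default_schema_set()
    fs = schema or ss.get(field)
    subs = {
        "field_label": fs.label,
        "value_guide": _value_guide(fs),
        "report_text": report_text,
        "example_snippet": fs.example_snippet,
        "example_value": fs.example_value,
        "na_display": NA_DISPLAY,
    }
    sections, rendered = _render(
        _template(f"extractor_v{variant}.txt"), subs, case_marker
    )
    return PromptSpec("extractor", field, variant, sections, rendered)


def build_validator_prompt(
    field: str,
    report_text: str,
    extractor_value: CanonicalValue,
    schema: FieldSchema | None = None,
    schema_set: SchemaSet | None = None,
    case_marker: str | None = None,
) -> PromptSpec:
    """Render the validator prompt embedding the extractor's answer."""
    if not report_text:
        raise ValueError("report_text must be non-empty")
    if extractor_value is None or str(extractor_value.value) == "":
        raise ValueError("extractor_value must be a canonical value or NA sentinel")
    ss = schema_set or default_schema_set()
    fs = schema or ss.get(field)
    subs = {
        "field_label": fs.label,
        "value_guide": _value_guide(fs),
        "report_text": report_text,
        "extractor_value": str(extractor_value.value),
        "example_value": fs.example_value,
        "na_display": NA_DISPLAY,
    }
    sections, rendered = _render(_template("validator.txt"), subs, case_marker)
    return PromptSpec("validator", field, 1, sections, rendered)


def parse_prompt_metadata(prompt: str, schema_set: SchemaSet | None = None) -> dict:
    """Recover (agent, field, case id, extractor value) from a rendered prompt.

    Used by the simulated backend to decide what a "model" should reply.
    """
    ss = schema_set or default_schema_set()
    m = _QUERY_FIELD_RE.search(prompt)
    if not m:
        raise ValueError("prompt carries no query-field line")
    field = ss.field_for_label(m.group(1))
    if field is None:
        raise ValueError(f"prompt names unknown field label {m.group(1)!r}")
    mv = _EXTRACTOR_VALUE_RE.search(prompt)
    mc = _CASE_MARKER_RE.search(prompt)
    return {
        "agent": "validator" if mv else "extractor",
        "field": field,
        "extractor_value": mv.group(1) if mv else None,
        "case_id": mc.group(1) if mc else None,
    }


# ---------------------------------------------------------------------------
# reply parsing


def _first_json_object(text: str):
    """Return the first JSON object embedded in ``text``, or None.

    Tolerates code fences and surrounding prose; when several objects are
    present the first decodable one wins (documented policy).
    """
    stripped = text.strip()
    try:
        obj = json.loads(stripped)
        if isinstance(obj, dict):
            return obj
    except (json.JSONDecodeError, ValueError):
        pass
    decoder = json.JSONDecoder()
    for i, ch in enumerate(text):
        if ch != "{":
            continue
        try:
            obj, _ = decoder.raw_decode(text[i:])
        except (json.JSONDecodeError, ValueError):
            continue
        if isinstance(obj, dict):
            return obj
    return None


def _norm_key(key: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", key.casefold()).strip()


def parse_extraction_reply(
    raw: str,
    field: str,
    schema: FieldSchema | None = None,
    schema_set: SchemaSet | None = None,
) -> RawReply:
    """Parse an extractor reply into a canonical value; failures are data.

    The query-field key is matched case-insensitively (punctuation and
    underscores ignored); a single-key object is accepted regardless of its
    key name.  The value is normalised via ``normalize_value``; anything that
    does not normalise yields ``parse_ok=False``.
    """
    ss = schema_set or default_schema_set()
    fs = schema or ss.get(field)
    obj = _first_json_object(raw)
    if obj is None or not obj:
        return RawReply(raw, False)
    candidates = {_norm_key(fs.label), _norm_key(fs.name)}
    value = None
    if len(obj) == 1:
        value = next(iter(obj.values()))
    else:
        for k, v in obj.items():
            if _norm_key(str(k)) in candidates:
                value = v
                break
        else:
            return RawReply(raw, False)
    canonical = normalize_value(field, value, ss)
    if canonical is None:
        return RawReply(raw, False)
    return RawReply(raw, True, {"value": canonical})


def parse_validator_reply(raw: str) -> RawReply:
    """Parse a validator reply holding Correctness/Confidence/Corrected.

    Correctness is case-folded to {"correct", "incorrect"}; Confidence must
    be an integer in [0, 100]; Corrected is kept as a string (normalised
    later, against the query field's schema).  Any missing or invalid label
    yields ``parse_ok=False``.
    """
    obj = _first_json_object(raw)
    if obj is None:
        return RawReply(raw, False)
    by_key = {_norm_key(str(k)): v for k, v in obj.items()}
    try:
        correctness = str(by_key["correctness"]).strip().casefold()
        confidence = by_key["confidence"]
        corrected = by_key["corrected"]
    except KeyError:
        return RawReply(raw, False)
    if correctness not in ("correct", "incorrect"):
        return RawReply(raw, False)
    if isinstance(confidence, bool) or not isinstance(confidence, (int, float)):
        return RawReply(raw, False)
    if float(confidence) != int(confidence) or not 0 <= int(confidence) <= 100:
        return RawReply(raw, False)
    if not isinstance(corrected, (str, int, float)) or isinstance(corrected, bool):
        return RawReply(raw, False)
    return RawReply(
        raw,
        True,
        {
            "correctness": correctness,
            "confidence": int(confidence),
            "corrected": str(corrected),
        },
    )


# ---------------------------------------------------------------------------
# live backend (optional; never used by the test suite)


class LiveBackend:
    """Backend that calls a hosted chat-completion API.

    Model name and sampling temperature are configuration, not code.  The
    client library is imported lazily so the package works fully offline;
    constructing this class without it installed raises immediately.
    """

    def __init__(
        self,
        model: str = "gpt-4-turbo",
        temperature: float = 1.0,
        max_retries: int = 3,
    ) -> None:
        try:
            import openai  # type: ignore
        except ImportError as exc:  # pragma: no cover - needs network extras
            raise ImportError(
                "the live backend requires the 'openai' client library; "
                "install it or use the simulated backend"
            ) from exc
        self._client = openai.OpenAI(max_retries=max_retries)
        self.model = model
        self.temperature = temperature

    def sample(self, prompt: str, n_samples: int, seed: int) -> list[str]:  # pragma: no cover
        resp = self._client.chat.completions.create(
            model=self.model,
            temperature=self.temperature,
            n=n_samples,
            seed=seed,
            messages=[{"role": "user", "content": prompt}],
        )
        out = [c.message.content or "" for c in resp.choices]
        # the contract requires exactly n_samples replies
        while len(out) < n_samples:
            out.append("")
        return out[:n_samples]
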