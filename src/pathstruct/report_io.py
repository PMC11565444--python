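"""Standardised output: RCPath-style proforma text, JSON interchange, readers.

A :class:`StructuredReport` holds one :class:`~pathstruct.agents.FieldResult`
per extracted field in the fixed RCPath proforma order.  It renders to a
human-readable proforma (one labelled line per field, confidence as an
integer percent) and serialises losslessly to JSON — vote counts, all
validator terms, tie flags and calibration state survive a round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .agents import AggregatedExtraction, FieldResult, ValidatorAggregate
from .field_schema import (
    CanonicalValue,
    SchemaSet,
    default_schema_set,
    normalize_value,
)

__all__ = [
    "StructuredReport",
    "SchemaVersionError",
    "render_proforma_text",
    "write_json",
    "read_json",
    "read_report_text",
]

logger = logging.getLogger(__name__)

JSON_FORMAT_VERSION = "1.0"


class SchemaVersionError(ValueError):
    """The serialised document was produced under a different schema version."""


@dataclass
class StructuredReport:
    """Final per-field values and confidences for one pathology report."""

    report_id: str
    results: dict[str, FieldResult]
    schema_version: str = JSON_FORMAT_VERSION
    generated_at: str = ""  # optional ISO timestamp; empty keeps output reproducible
    pipeline_config_digest: str = ""

    def __post_init__(self) -> None:
        ss = default_schema_set()
        order = {f: i for i, f in enumerate(ss.proforma_order)}
        self.results = dict(
            sorted(self.results.items(), key=lambda kv: order.get(kv[0], len(order)))
        )

    def values(self) -> dict[str, CanonicalValue]:
        return {f: r.final_value for f, r in self.results.items()}


def _display_confidence(result: FieldResult) -> int:
    if result.calibrated_confidence is not None:
        return int(round(result.calibrated_confidence * 100))
    return int(round(result.raw_confidence))


def render_proforma_text(
    report: StructuredReport,
    show_confidence: bool = True,
    schema_set: SchemaSet | None = None,
) -> str:
    """Fixed-order labelled lines; NA sentinels rendered verbatim (pTX etc.)."""
    ss = schema_set or default_schema_set()
    lines = [f"RCPath colorectal cancer dataset — report {report.report_id}"]
    for f, result in report.results.items():
        label = ss.get(f).label
        line = f"{label}: {result.final_value}"
        if show_confidence:
            line += f" (confidence {_display_confidence(result)})"
        lines.append(line)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON interchange


def _value_doc(v: CanonicalValue) -> dict:
    return {"value": v.value, "is_na": v.is_na}


def _value_from_doc(field: str, doc: Mapping, ss: SchemaSet) -> CanonicalValue:
    cv = normalize_value(field, doc["value"], ss)
    if cv is None or cv.is_na != bool(doc["is_na"]):
        raise ValueError(f"invalid serialised value {doc!r} for field {field!r}")
    return cv


def write_json(report: StructuredReport) -> str:
    """Serialise to a stable-key-order JSON document."""
    doc = {
        "format": "pathstruct.structured_report",
        "schema_version": report.schema_version,
        "report_id": report.report_id,
        "generated_at": report.generated_at,
        "pipeline_config_digest": report.pipeline_config_digest,
        "results": [],
    }
    for f, r in report.results.items():
        e, v = r.extraction, r.validation
        doc["results"].append(
            {
                "field": f,
                "final_value": _value_doc(r.final_value),
                "raw_confidence": r.raw_confidence,
                "calibrated_confidence": r.calibrated_confidence,
                "extraction": {
                    "value": _value_doc(e.value),
                    "e_confidence": e.e_confidence,
                    "vote_counts": [
                        {**_value_doc(val), "count": c}
                        for val, c in sorted(
                            e.vote_counts.items(), key=lambda kv: str(kv[0].value)
                        )
                    ],
                    "n_requested": e.n_requested,
                    "n_valid": e.n_valid,
                    "tie": e.tie,
                },
                "validation": {
                    "v_correct": v.v_correct,
                    "v_confidence": v.v_confidence,
                    "v_correction": v.v_correction,
                    "v_pct_correct": v.v_pct_correct,
                    "corrected_value": _value_doc(v.corrected_value),
                    "modal_self_confidence": v.modal_self_confidence,
                    "n_requested": v.n_requested,
                    "n_valid": v.n_valid,
                    "tie": v.tie,
                },
            }
        )
    return json.dumps(doc, indent=2)


def read_json(doc: str, schema_set: SchemaSet | None = None) -> StructuredReport:
    """Parse and validate a serialised report; lossless inverse of write_json."""
    ss = schema_set or default_schema_set()
    data = json.loads(doc)
    version = data.get("schema_version")
    if version != JSON_FORMAT_VERSION:
        raise SchemaVersionError(
            f"document schema_version {version!r} != supported {JSON_FORMAT_VERSION!r}"
        )
    results: dict[str, FieldResult] = {}
    for item in data["results"]:
        f = item["field"]
        ss.get(f)
        ext = item["extraction"]
        val = item["validation"]
        extraction = AggregatedExtraction(
            field=f,
            value=_value_from_doc(f, ext["value"], ss),
            e_confidence=float(ext["e_confidence"]),
            vote_counts={
                _value_from_doc(f, vc, ss): int(vc["count"])
                for vc in ext["vote_counts"]
            },
            n_requested=int(ext["n_requested"]),
            n_valid=int(ext["n_valid"]),
            tie=bool(ext["tie"]),
        )
        validation = ValidatorAggregate(
            field=f,
            v_correct=float(val["v_correct"]),
            v_confidence=float(val["v_confidence"]),
            v_correction=float(val["v_correction"]),
            v_pct_correct=float(val["v_pct_correct"]),
            corrected_value=_value_from_doc(f, val["corrected_value"], ss),
            modal_self_confidence=int(val["modal_self_confidence"]),
            n_requested=int(val["n_requested"]),
            n_valid=int(val["n_valid"]),
            tie=bool(val["tie"]),
        )
        calibrated = item.get("calibrated_confidence")
        results[f] = FieldResult(
            field=f,
            final_value=_value_from_doc(f, item["final_value"], ss),
            raw_confidence=float(item["raw_confidence"]),
            extraction=extraction,
            validation=validation,
            calibrated_confidence=None if calibrated is None else float(calibrated),
        )
    return StructuredReport(
        report_id=data["report_id"],
        results=results,
        schema_version=version,
        generated_at=data.get("generated_at", ""),
        pipeline_config_digest=data.get("pipeline_config_digest", ""),
    )


# ---------------------------------------------------------------------------
# report text input


def read_report_text(path: str | Path) -> dict[str, str]:
    """Read report texts: a .txt file, a directory of .txt files, or a
    two-column delimited table (report_id, text).

    Text passes through unmodified apart from UTF-8 decoding — no cleaning
    that could alter downstream extraction.
    """
    p = Path(path)
    if p.is_dir():
        out: dict[str, str] = {}
        for f in sorted(p.glob("*.txt")):
            out[f.stem] = _read_one(f)
        if not out:
            raise OSError(f"no .txt reports found in directory {p}")
        return out
    if not p.exists():
        raise OSError(f"cannot read report input {p}: no such file")
    if p.suffix.lower() in (".tsv", ".csv"):
        import pandas as pd

        df = pd.read_csv(p, sep=None, engine="python", dtype=str).fillna("")
        if df.shape[1] < 2:
            raise ValueError("report table needs two columns: report_id, text")
        id_col, text_col = df.columns[0], df.columns[1]
        return {str(r[id_col]): str(r[text_col]) for _, r in df.iterrows()}
    return {p.stem: _read_one(p)}


def _read_one(f: Path) -> str:
    text = f.read_text("utf-8")
    if not text.strip():
        logger.warning("report file %s is empty", f)
    return text
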