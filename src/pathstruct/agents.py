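"""Extractor and Validator aggregation: repeated sampling and majority votes.

The Extractor asks the model the same question many times (N_E = 20 replies,
split evenly over two prompt phrasings) and keeps the modal answer; the share
of replies agreeing with the mode is its consistency (EConfidence).  The
Validator then judges the Extractor's answer N_Va = 10 times, producing three
labels per reply — Correctness, Confidence (0-100) and Corrected — whose
per-label modal consistencies, together with the share of replies asserting
correctness, feed the five-term confidence score.

Tie policy (applies to every modal vote): among tied values the NA sentinel
wins if present (a tie signals insufficient evidence), otherwise the
lexicographically smallest canonical value; the tie is always flagged.
Parse-failed replies are never re-requested — they count against the
denominator, so malformed output depresses confidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .confidence import ConfidenceTerms, PlattModel, apply_platt, compute_raw_confidence
from .field_schema import (
    CanonicalValue,
    SchemaSet,
    default_schema_set,
    normalize_value,
)
from .llm_interface import (
    Backend,
    RawReply,
    build_extractor_prompt,
    build_validator_prompt,
    child_seed,
    parse_extraction_reply,
    parse_validator_reply,
)

__all__ = [
    "AggregatedExtraction",
    "ValidatorAggregate",
    "FieldResult",
    "PipelineError",
    "aggregate_votes",
    "run_extractor",
    "aggregate_validator",
    "resolve_final_value",
    "extract_report",
    "CONFIDENCE_BUCKET",
]

#: validator self-reported confidences are bucketed to this width before the
#: modal vote, so 89 vs 90 does not break otherwise-unanimous replies
CONFIDENCE_BUCKET = 5


class PipelineError(RuntimeError):
    """A backend or aggregation failure, carrying the field it occurred in."""


@dataclass(frozen=True)
class AggregatedExtraction:
    field: str
    value: CanonicalValue
    e_confidence: float
    vote_counts: Mapping[CanonicalValue, int]
    n_requested: int
    n_valid: int
    tie: bool = False


@dataclass(frozen=True)
class ValidatorAggregate:
    field: str
    v_correct: float
    v_confidence: float
    v_correction: float
    v_pct_correct: float
    corrected_value: CanonicalValue
    modal_self_confidence: int
    n_requested: int
    n_valid: int
    tie: bool = False


@dataclass
class FieldResult:
    field: str
    final_value: CanonicalValue
    raw_confidence: float
    extraction: AggregatedExtraction
    validation: ValidatorAggregate
    calibrated_confidence: float | None = None


def _tie_key(value) -> tuple:
    # NA sentinel first (conservative), then lexicographic on the string form
    if isinstance(value, CanonicalValue):
        return (0 if value.is_na else 1, str(value.value))
    return (1, str(value))


def _modal(counter: Counter) -> tuple[object, int, bool]:
    """Modal element under the documented tie policy; returns (value, count, tie)."""
    if not counter:
        raise ValueError("empty vote counter")
    top = max(counter.values())
    tied = [v for v, c in counter.items() if c == top]
    winner = min(tied, key=_tie_key)
    return winner, top, len(tied) > 1


def aggregate_votes(
    replies: Sequence[RawReply],
    field: str,
    schema_set: SchemaSet | None = None,
    n_requested: int | None = None,
) -> AggregatedExtraction:
    """Majority vote over parsed extractor replies.

    Only ``parse_ok`` replies are counted; their values are already
    normalised, so alias spellings of the same answer pool into one bucket.
    ``e_confidence`` divides by ``n_requested`` so invalid replies depress
    confidence.  With zero valid replies the NA sentinel is returned at
    confidence 0.
    """
    ss = schema_set or default_schema_set()
    fs = ss.get(field)
    if n_requested is None:
        n_requested = len(replies)
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    if len(replies) != n_requested:
        raise ValueError(
            f"got {len(replies)} replies for n_requested={n_requested}"
        )
    counts: Counter = Counter(
        r.payload["value"] for r in replies if r.parse_ok
    )
    n_valid = sum(counts.values())
    if n_valid == 0:
        return AggregatedExtraction(
            field, fs.na_value, 0.0, {}, n_requested, 0, tie=False
        )
    value, top, tie = _modal(counts)
    return AggregatedExtraction(
        field=field,
        value=value,
        e_confidence=top / n_requested,
        vote_counts=dict(counts),
        n_requested=n_requested,
        n_valid=n_valid,
        tie=tie,
    )


def run_extractor(
    report_text: str,
    field: str,
    backend: Backend,
    n_total: int = 20,
    seed: int = 0,
    schema_set: SchemaSet | None = None,
    case_marker: str | None = None,
) -> AggregatedExtraction:
    """Request ``n_total`` replies (half per prompt variant) and aggregate."""
    if n_total % 2 != 0 or n_total < 2:
        raise ValueError("n_total must be an even number >= 2 (split over 2 prompts)")
    ss = schema_set or default_schema_set()
    replies: list[RawReply] = []
    for variant in (1, 2):
        prompt = build_extractor_prompt(
            field, variant, report_text, schema_set=ss, case_marker=case_marker
        )
        try:
            texts = backend.sample(
                prompt.rendered, n_total // 2, child_seed(seed, field, variant)
            )
        except Exception as exc:
            raise PipelineError(f"backend failed for field {field!r}: {exc}") from exc
        if len(texts) != n_total // 2:
            raise PipelineError(
                f"backend returned {len(texts)} replies for field {field!r}, "
                f"expected {n_total // 2}"
            )
        replies.extend(parse_extraction_reply(t, field, schema_set=ss) for t in texts)
    return aggregate_votes(replies, field, ss, n_requested=n_total)


def _bucket(confidence: int) -> int:
    return int(round(confidence / CONFIDENCE_BUCKET)) * CONFIDENCE_BUCKET


def aggregate_validator(
    replies: Sequence[RawReply],
    extractor_value: CanonicalValue,
    field: str,
    schema_set: SchemaSet | None = None,
    n_requested: int | None = None,
) -> ValidatorAggregate:
    """Aggregate validator replies into per-label consistencies.

    Each label votes independently: the modal value's frequency over
    ``n_requested`` is that label's consistency term.  Corrected values are
    normalised before voting; unparseable corrections map to the NA sentinel.
    ``v_pct_correct`` is the share of replies asserting the extractor was
    correct (over ``n_requested``).
    """
    ss = schema_set or default_schema_set()
    fs = ss.get(field)
    if n_requested is None:
        n_requested = len(replies)
    if len(replies) != n_requested:
        raise ValueError(f"got {len(replies)} replies for n_requested={n_requested}")
    valid = [r for r in replies if r.parse_ok]
    if not valid:
        return ValidatorAggregate(
            field, 0.0, 0.0, 0.0, 0.0, fs.na_value, 0, n_requested, 0
        )
    correctness = Counter(r.payload["correctness"] for r in valid)
    confidences = Counter(_bucket(r.payload["confidence"]) for r in valid)
    corrections: Counter = Counter()
    for r in valid:
        # normalise the Corrected label against the field schema; unparseable
        # corrections fall back to the NA sentinel
        cv = normalize_value(field, r.payload["corrected"], ss)
        corrections[cv if cv is not None else fs.na_value] += 1

    _, c_top, c_tie = _modal(correctness)
    conf_value, conf_top, conf_tie = _modal(confidences)
    corr_value, corr_top, corr_tie = _modal(corrections)
    n_correct = correctness.get("correct", 0)
    return ValidatorAggregate(
        field=field,
        v_correct=c_top / n_requested,
        v_confidence=conf_top / n_requested,
        v_correction=corr_top / n_requested,
        v_pct_correct=n_correct / n_requested,
        corrected_value=corr_value,
        modal_self_confidence=int(conf_value),
        n_requested=n_requested,
        n_valid=len(valid),
        tie=c_tie or conf_tie or corr_tie,
    )


def resolve_final_value(
    extraction: AggregatedExtraction,
    validation: ValidatorAggregate,
    correction_threshold: float = 0.5,
) -> CanonicalValue:
    """Apply the validator's correction when the majority says "incorrect".

    The correction triggers on ``v_pct_correct < correction_threshold``
    (strict), so an exact tie keeps the extractor's value.
    """
    if extraction.field != validation.field:
        raise ValueError("extraction and validation refer to different fields")
    if validation.v_pct_correct < correction_threshold:
        return validation.corrected_value
    return extraction.value


def _terms(
    extraction: AggregatedExtraction,
    validation: ValidatorAggregate,
    vconfidence_mode: str,
) -> ConfidenceTerms:
    if vconfidence_mode == "consistency":
        v_conf = validation.v_confidence
    elif vconfidence_mode == "self_report":
        v_conf = validation.modal_self_confidence / 100.0
    else:
        raise ValueError("vconfidence_mode must be 'consistency' or 'self_report'")
    return ConfidenceTerms(
        e_confidence=extraction.e_confidence,
        v_correct=validation.v_correct,
        v_confidence=v_conf,
        v_correction=validation.v_correction,
        v_pct_correct=validation.v_pct_correct,
    )


def extract_report(
    report_text: str,
    fields: Iterable[str],
    backend: Backend,
    calibration: Mapping[str, PlattModel] | None = None,
    seed: int = 0,
    n_extractor: int = 20,
    n_validator: int = 10,
    report_id: str = "report",
    schema_set: SchemaSet | None = None,
    vconfidence_mode: str = "consistency",
    correction_threshold: float = 0.5,
    embed_case_marker: bool = False,
):
    """Run the full two-stage pipeline for one report.

    Fields are processed independently — one query field per prompt.  Returns
    a :class:`~pathstruct.report_io.StructuredReport` ordered by the RCPath
    proforma.  ``embed_case_marker`` appends the report id to every prompt so
    the simulated backend can resolve ground truth; it is never used with a
    live backend.
    """
    from .report_io import StructuredReport  # local import to avoid a cycle

    ss = schema_set or default_schema_set()
    fields = list(fields)
    for f in fields:
        ss.get(f)  # raises SchemaNotFoundError early
    marker = report_id if embed_case_marker else None
    results: dict[str, FieldResult] = {}
    for f in sorted(fields, key=ss.proforma_order.index):
        extraction = run_extractor(
            report_text, f, backend, n_total=n_extractor, seed=seed,
            schema_set=ss, case_marker=marker,
        )
        vprompt = build_validator_prompt(
            f, report_text, extraction.value, schema_set=ss, case_marker=marker
        )
        try:
            vtexts = backend.sample(
                vprompt.rendered, n_validator, child_seed(seed, f, "validator")
            )
        except Exception as exc:
            raise PipelineError(f"backend failed for field {f!r}: {exc}") from exc
        vreplies = [parse_validator_reply(t) for t in vtexts]
        validation = aggregate_validator(
            vreplies, extraction.value, f, ss, n_requested=n_validator
        )
        final = resolve_final_value(extraction, validation, correction_threshold)
        raw_conf = compute_raw_confidence(_terms(extraction, validation, vconfidence_mode))
        result = FieldResult(f, final, raw_conf, extraction, validation)
        if calibration and f in calibration:
            result.calibrated_confidence = apply_platt(calibration[f], raw_conf)
        results[f] = result
    return StructuredReport(report_id=report_id, results=results, schema_version=ss.version)
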