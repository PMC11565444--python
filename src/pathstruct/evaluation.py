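"""Scoring extractions against manual truth: accuracy, kappa, AUROC, abstention.

Each (report, field) extraction is compared with a manually extracted truth
value after normalisation; exact match yields label 1, otherwise 0.  TNM
fields can be scored at two granularities: "specific" compares sub-stages
(pT4a vs pT4b) while "broad" collapses both sides first (both become pT4).

Agreement is summarised by accuracy (mean label) and Cohen's kappa (chance-
corrected agreement on the category pairs).  Whether confidence flags errors
is measured by the AUROC of confidence against the 0/1 labels, and by
abstention (rejection) curves: at each confidence threshold, the fraction of
extractions rejected and the accuracy over those accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .field_schema import (
    CanonicalValue,
    SchemaSet,
    default_schema_set,
    normalize_value,
    to_broad,
)

__all__ = [
    "ValidationRecord",
    "AbstentionPoint",
    "UndefinedMetricError",
    "score_extractions",
    "accuracy",
    "cohen_kappa",
    "auroc",
    "abstention_curve",
    "load_truth_table",
    "per_field_summary",
]

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this input (e.g. single-class AUROC)."""


@dataclass(frozen=True)
class ValidationRecord:
    report_id: str
    field: str
    extracted: CanonicalValue
    truth: CanonicalValue
    label: int
    confidence: float


@dataclass(frozen=True)
class AbstentionPoint:
    threshold: float
    rejected_fraction: float
    accepted_accuracy: float | None  # None when every extraction is rejected


def _coerce_truth(
    field: str, raw, ss: SchemaSet
) -> CanonicalValue | None:
    if isinstance(raw, CanonicalValue):
        return raw
    return normalize_value(field, raw, ss)


def score_extractions(
    reports: Iterable,
    truth_table: Mapping[tuple[str, str], object],
    granularity: str = "specific",
    schema_set: SchemaSet | None = None,
    na_as_match: bool = True,
    use_calibrated: bool = False,
) -> list[ValidationRecord]:
    """Label every extracted field against the truth table.

    ``reports`` is an iterable of StructuredReport; ``truth_table`` maps
    (report_id, field) to a truth value (surface string or CanonicalValue).
    Extractions without a truth entry are skipped (count logged).  With
    ``granularity="broad"`` both sides are collapsed via ``to_broad`` first.
    NA extracted against NA truth counts as a match when ``na_as_match``.
    """
    if granularity not in ("specific", "broad"):
        raise ValueError("granularity must be 'specific' or 'broad'")
    ss = schema_set or default_schema_set()
    records: list[ValidationRecord] = []
    skipped = 0
    for report in reports:
        for f, result in report.results.items():
            ss.get(f)  # unknown field -> SchemaNotFoundError
            key = (report.report_id, f)
            if key not in truth_table:
                skipped += 1
                continue
            truth = _coerce_truth(f, truth_table[key], ss)
            if truth is None:
                skipped += 1
                continue
            extracted = result.final_value
            if granularity == "broad":
                extracted = to_broad(f, extracted, ss)
                truth = to_broad(f, truth, ss)
            if extracted.is_na and truth.is_na:
                label = 1 if na_as_match else 0
            else:
                label = int(
                    extracted.is_na == truth.is_na and extracted.value == truth.value
                )
            conf = (
                result.calibrated_confidence
                if use_calibrated and result.calibrated_confidence is not None
                else result.raw_confidence
            )
            records.append(
                ValidationRecord(report.report_id, f, extracted, truth, label, conf)
            )
    if skipped:
        logger.info("score_extractions: skipped %d extractions without truth", skipped)
    return records


def accuracy(records: Sequence[ValidationRecord]) -> float:
    """Mean of the 0/1 correctness labels."""
    if not records:
        raise ValueError("accuracy is undefined on an empty record list")
    return float(np.mean([r.label for r in records]))


def cohen_kappa(records: Sequence[ValidationRecord]) -> float:
    """Chance-corrected agreement between extracted and truth categories.

    kappa = (p_o - p_e) / (1 - p_e); when both raters are constant and equal
    (p_e = 1) the conventional value 1.0 is returned.
    """
    if len(records) < 2:
        raise ValueError("cohen_kappa needs >= 2 records")
    a = [str(r.extracted.value) for r in records]
    b = [str(r.truth.value) for r in records]
    if len(set(a)) == 1 and len(set(b)) == 1:
        return 1.0 if a[0] == b[0] else 0.0
    return float(cohen_kappa_score(a, b))


def auroc(confidences: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC of confidence as a correctness detector (Mann-Whitney statistic)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise UndefinedMetricError("AUROC undefined with a single label class")
    return float(roc_auc_score(y, np.asarray(confidences, dtype=float)))


def abstention_curve(
    records: Sequence[ValidationRecord],
    thresholds: Sequence[float] | None = None,
) -> list[AbstentionPoint]:
    """Rejection analysis: reject extractions with confidence < threshold.

    Rejection is strict, so threshold 0 rejects nothing and the curve starts
    at the full-coverage accuracy.  When everything is rejected the accepted
    accuracy is ``None``, never a fabricated number.
    """
    conf = np.asarray([r.confidence for r in records], dtype=float)
    labels = np.asarray([r.label for r in records], dtype=int)
    if thresholds is None:
        thresholds = sorted({0.0, *conf.tolist()})
    points = []
    n = len(records)
    for t in thresholds:
        accepted = conf >= t
        n_acc = int(accepted.sum())
        points.append(
            AbstentionPoint(
                threshold=float(t),
                rejected_fraction=(n - n_acc) / n if n else 0.0,
                accepted_accuracy=float(labels[accepted].mean()) if n_acc else None,
            )
        )
    return points


def load_truth_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a delimited (report_id, field, value) table into a lookup dict."""
    # keep_default_na=False: "NA" is a legitimate value in this vocabulary
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    expected = {"report_id", "field", "value"}
    if not expected <= set(df.columns):
        raise ValueError(f"truth table must have columns {sorted(expected)}")
    return {
        (row.report_id, row.field): row.value
        for row in df.itertuples(index=False)
        if isinstance(row.value, str) and row.value != ""
    }


def per_field_summary(
    records: Sequence[ValidationRecord],
) -> pd.DataFrame:
    """Per-field accuracy, kappa and AUROC in one flat table."""
    rows = []
    by_field: dict[str, list[ValidationRecord]] = {}
    for r in records:
        by_field.setdefault(r.field, []).append(r)
    for f, recs in by_field.items():
        try:
            auc = auroc([r.confidence for r in recs], [r.label for r in recs])
        except UndefinedMetricError:
            auc = float("nan")
        rows.append(
            {
                "field": f,
                "n": len(recs),
                "accuracy": accuracy(recs),
                "kappa": cohen_kappa(recs) if len(recs) >= 2 else float("nan"),
                "auroc": auc,
            }
        )
    return pd.DataFrame(rows)
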