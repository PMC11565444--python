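import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathstruct.agents import AggregatedExtraction, FieldResult, ValidatorAggregate
from pathstruct.field_schema import CanonicalValue, load_schema_set, normalize_value
from pathstruct.report_io import StructuredReport

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema_set():
    return load_schema_set()


def make_field_result(
    field: str,
    value,
    raw_confidence: float = 80.0,
    calibrated: float | None = None,
) -> FieldResult:
    """A structurally valid FieldResult for tests that only need values."""
    cv = (
        value
        if isinstance(value, CanonicalValue)
        else normalize_value(field, str(value))
    )
    assert cv is not None, f"test value {value!r} not canonical for {field}"
    extraction = AggregatedExtraction(
        field=field, value=cv, e_confidence=0.8, vote_counts={cv: 16},
        n_requested=20, n_valid=20, tie=False,
    )
    validation = ValidatorAggregate(
        field=field, v_correct=0.9, v_confidence=0.8, v_correction=0.9,
        v_pct_correct=0.9, corrected_value=cv, modal_self_confidence=90,
        n_requested=10, n_valid=10, tie=False,
    )
    return FieldResult(field, cv, raw_confidence, extraction, validation, calibrated)


def make_report(report_id: str, values: dict, confidences: dict | None = None) -> StructuredReport:
    confidences = confidences or {}
    results = {
        f: make_field_result(f, v, confidences.get(f, 80.0))
        for f, v in values.items()
    }
    return StructuredReport(report_id=report_id, results=results)


def random_structured_report(rng: np.random.Generator, ss, report_id: str) -> StructuredReport:
    """A random but schema-valid StructuredReport for round-trip testing."""
    fields = [f for f in ss.proforma_order if rng.random() < 0.8] or ["histologic_grade"]
    results = {}
    for f in fields:
        fs = ss.get(f)
        if fs.kind == "numeric":
            lo, hi = fs.numeric_range
            pool = [CanonicalValue(f, int(rng.integers(lo, hi + 1)), False), fs.na_value]
        else:
            pool = list(fs.canonical_values())
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = list(rng.choice(len(pool), size=k, replace=False))
        n_req = 20
        counts = {}
        budget = n_req
        for idx in chosen:
            c = int(rng.integers(1, max(2, budget // len(chosen) + 1)))
            budget -= c
            counts[pool[idx]] = c
        value = max(counts, key=counts.get)
        e_conf = counts[value] / n_req
        extraction = AggregatedExtraction(
            f, value, e_conf, counts, n_req, sum(counts.values()),
            tie=bool(rng.random() < 0.1),
        )
        validation = ValidatorAggregate(
            f,
            v_correct=float(rng.integers(0, 11)) / 10,
            v_confidence=float(rng.integers(0, 11)) / 10,
            v_correction=float(rng.integers(0, 11)) / 10,
            v_pct_correct=float(rng.integers(0, 11)) / 10,
            corrected_value=pool[int(rng.integers(len(pool)))],
            modal_self_confidence=int(rng.integers(0, 101)),
            n_requested=10,
            n_valid=int(rng.integers(0, 11)),
            tie=bool(rng.random() < 0.1),
        )
        raw_conf = float(rng.uniform(0, 100))
        calibrated = float(rng.uniform(0, 1)) if rng.random() < 0.5 else None
        results[f] = FieldResult(f, value, raw_conf, extraction, validation, calibrated)
    return StructuredReport(report_id=report_id, results=results)
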