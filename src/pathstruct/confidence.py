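"""Five-term extraction confidence and its Platt rescaling.

The raw confidence for a query field q is the arithmetic mean of five
fractions, scaled to [0, 100]:

    C_q = (EConfidence + VCorrect + VConfidence + VCorrection + V%Correct) / 5 * 100

where EConfidence is the extractor's reply consistency, VCorrect /
VConfidence / VCorrection are the consistencies of the validator's three
output labels, and V%Correct is the share of validator replies asserting the
extraction is correct.  No single term is trusted on its own: chat models are
frequently consistent while being wrong, so agreement across two differently
phrased prompting routes is what carries the signal.

Because raw confidences cluster near the top of the scale, they are rescaled
per field with Platt's method: two coefficients (A_q, B_q) of a sigmoid

    P(correct | C_q) = 1 / (1 + exp(A_q * C_q + B_q))

are fitted by maximum likelihood against 0/1 correctness labels, using
Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2) to avoid
overfitting the extremes.  The transform is strictly monotone, so ranking
metrics (AUROC, abstention ordering) are unchanged by calibration.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ConfidenceTerms",
    "PlattModel",
    "DegenerateFitError",
    "compute_raw_confidence",
    "fit_platt",
    "apply_platt",
    "save_calibration",
    "load_calibration",
]


class DegenerateFitError(ValueError):
    """Raised when calibration labels contain a single class.

    Callers should fall back to identity scaling (report raw C_q / 100).
    """


@dataclass(frozen=True)
class ConfidenceTerms:
    """The five fractions entering the raw confidence, each in [0, 1]."""

    e_confidence: float
    v_correct: float
    v_confidence: float
    v_correction: float
    v_pct_correct: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.e_confidence,
            self.v_correct,
            self.v_confidence,
            self.v_correction,
            self.v_pct_correct,
        )


@dataclass(frozen=True)
class PlattModel:
    """Fitted sigmoid recalibration for one field: p = 1/(1+exp(a*c + b))."""

    field: str
    a_coef: float
    b_coef: float
    n_fit: int


def compute_raw_confidence(terms: ConfidenceTerms) -> float:
    """Mean of the five terms, scaled to [0, 100].  Pure and deterministic."""
    values = terms.as_tuple()
    for v in values:
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            raise ValueError(f"confidence term {v!r} outside [0, 1]")
    return sum(values) / 5.0 * 100.0


def fit_platt(
    raw_confidences: Sequence[float],
    labels: Sequence[int],
    field: str = "",
    grad_tol: float = 1e-8,
    max_iter: int = 200,
) -> PlattModel:
    """Fit (A_q, B_q) by maximum likelihood with Platt's target smoothing.

    ``labels`` are 0/1 correctness indicators.  Both classes must be present;
    otherwise :class:`DegenerateFitError` is raised and the caller should use
    identity scaling instead.
    """
    c = np.asarray(raw_confidences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if c.ndim != 1 or c.shape != y.shape or c.size < 2:
        raise ValueError("need >= 2 paired (confidence, label) points")
    if np.any((c < 0) | (c > 100)):
        raise ValueError("raw confidences must lie in [0, 100]")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0 or 1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateFitError(
            f"calibration for field {field!r} needs both correct and incorrect "
            "examples; fall back to identity scaling"
        )
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, t_pos, t_neg)

    def objective(ab: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = ab
        z = a * c + b
        # p = sigmoid(-z); nll = -(t log p + (1-t) log(1-p))
        nll = float(np.sum(t * np.logaddexp(0.0, z) + (1.0 - t) * np.logaddexp(0.0, -z)))
        resid = t - expit(-z)
        return nll, np.array([float(resid @ c), float(resid.sum())])

    x0 = np.array([0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-14},
    )
    a, b = res.x
    return PlattModel(field=field, a_coef=float(a), b_coef=float(b), n_fit=int(c.size))


def apply_platt(model: PlattModel, raw: float) -> float:
    """Calibrated probability for a raw confidence in [0, 100].

    Strictly monotone in ``raw`` (direction set by the sign of ``a_coef``).
    """
    arr = np.asarray(raw, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("raw confidence must lie in [0, 100]")
    out = expit(-(model.a_coef * arr + model.b_coef))
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def save_calibration(models: Mapping[str, PlattModel], path: str | Path) -> None:
    doc = {f: dataclasses.asdict(m) for f, m in models.items()}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True), "utf-8")


def load_calibration(path: str | Path) -> dict[str, PlattModel]:
    doc = json.loads(Path(path).read_text("utf-8"))
    return {f: PlattModel(**spec) for f, spec in doc.items()}
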