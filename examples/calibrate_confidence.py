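"""Platt-rescale raw confidences so they track observed error rates.

Runs the pipeline over 120 synthetic reports, scores each extraction against
truth, fits per-field sigmoid coefficients (A_q, B_q), and prints what a raw
confidence of 60/80/95 means as a calibrated probability of correctness.
Raw scores cluster near the top of the scale — the model is "confidently
wrong" at times — so calibrated probabilities are the numbers to act on.
"""

import numpy as np

from pathstruct.confidence import DegenerateFitError, apply_platt, fit_platt
from pathstruct.evaluation import score_extractions
from pathstruct.synthetic_data import (
    ResponderProfile,
    SimulatedBackend,
    extract_cases,
    generate_cohort,
    truth_lookup,
    truth_table,
)

FIELDS = ["histologic_grade", "tumour_site", "local_invasion", "resection"]

cases, _ = generate_cohort(120, seed=7)
profile = ResponderProfile(accuracy=0.75, validator_informativeness=0.9)
backend = SimulatedBackend(profile, truth_lookup(cases), salt=7)
reports = extract_cases(cases, backend, fields=FIELDS, seed=7, correction_threshold=0.0)
records = score_extractions(reports, truth_table(cases))

print(f"{'field':20s} {'A_q':>8s} {'B_q':>8s}   P(correct) at raw 60 / 80 / 95")
for field in FIELDS:
    recs = [r for r in records if r.field == field]
    try:
        model = fit_platt([r.confidence for r in recs], [r.label for r in recs], field)
    except DegenerateFitError:
        print(f"{field:20s} all extractions same class; identity scaling applies")
        continue
    p = apply_platt(model, np.array([60.0, 80.0, 95.0]))
    print(
        f"{field:20s} {model.a_coef:8.4f} {model.b_coef:8.3f}   "
        f"{p[0]:.2f} / {p[1]:.2f} / {p[2]:.2f}"
    )
print(
    "\nA negative A_q means higher raw confidence -> higher calibrated"
    " probability; the sigmoid midpoint sits at C_q = -B_q/A_q."
)
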