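"""Extract all RCPath fields from one synthetic pathology report.

Generates a report with known ground truth, runs the two-stage pipeline
against the simulated backend (reply accuracy 0.85), and prints the resulting
proforma next to the truth.  Each line carries the raw confidence C_q: the
mean of the extractor's reply consistency, the validator's three label
consistencies and the share of validator replies endorsing the extraction,
scaled to 0-100.  Low values flag fields worth a manual look.
"""

from pathstruct.report_io import render_proforma_text
from pathstruct.synthetic_data import (
    ResponderProfile,
    SimulatedBackend,
    extract_cases,
    generate_case,
)

case = generate_case(seed=42)
print("--- free-text report " + "-" * 40)
print(case.report_text)

backend = SimulatedBackend(
    ResponderProfile(accuracy=0.85), {case.report_id: case.true_values}, salt=42
)
[report] = extract_cases([case], backend, seed=42)

print("\n--- structured output " + "-" * 40)
print(render_proforma_text(report))

print("--- against ground truth " + "-" * 37)
for field, result in report.results.items():
    truth = case.true_values[field]
    mark = "ok " if result.final_value == truth else "ERR"
    print(f"{mark} {field:20s} extracted={result.final_value!s:22s} truth={truth}")
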