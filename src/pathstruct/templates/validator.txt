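[role]
You are a senior pathologist auditing structured data that was extracted from
colorectal cancer pathology reports against the RCPath colorectal dataset.
[task]
Another reader extracted the field below from the report. Decide whether the
extraction is correct, state your confidence, and give the value you believe
is right.
Query field: {field_label}
Extractor's answer: {extractor_value}
Allowed values for this field:
{value_guide}
Report:
<<<REPORT
{report_text}
REPORT>>>
[format_constraints]
Respond with a single JSON object with exactly three keys:
"Correctness" ("Correct" or "Incorrect"), "Confidence" (an integer from 0 to
100), and "Corrected" (the value you believe is right; repeat the extractor's
answer if it is correct). Do not add any other text.
[examples]
Example response: {{"Correctness": "Correct", "Confidence": 90, "Corrected": "{example_value}"}}
[uncertainty_handling]
If the report does not contain enough information to verify this field, the
correct value is "{na_display}"; judge the extractor's answer against that.
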