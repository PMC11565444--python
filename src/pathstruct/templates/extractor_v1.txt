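[role]
You are a consultant gastrointestinal pathologist with extensive experience in
colorectal cancer reporting under the Royal College of Pathologists (RCPath)
dataset for histopathological reporting of colorectal cancer.
[task]
Read the pathology report below and extract the value of a single field.
Query field: {field_label}
Allowed values and the ways they may appear in reports:
{value_guide}
Report:
<<<REPORT
{report_text}
REPORT>>>
[format_constraints]
Respond with a single JSON object containing exactly one key, "{field_label}",
whose value is the extracted answer taken from the allowed values above.
Response shape: {{"{field_label}": "<value>"}}. Do not add any other text.
[examples]
Example report fragment: "{example_snippet}"
Expected response: {{"{field_label}": "{example_value}"}}
[uncertainty_handling]
Some reports are ambiguous or do not mention this field at all. If there is
not sufficient information in the report to determine the value, respond with
"{na_display}" rather than guessing.
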