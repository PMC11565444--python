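# Methods

## Pipeline model

`pathstruct` treats structured reporting as independent single-field queries:
one prompt asks for exactly one RCPath field, with the full value vocabulary,
per-value descriptions and alias spellings in the prompt, a worked example,
and an explicit instruction to answer "Not Available" rather than guess.
Two agents run per field:

* **Extractor** — N_E = 20 replies, 10 per prompt variant. Replies are
  parsed (first JSON object wins; code fences and prose are tolerated),
  normalised against the field schema, and majority-voted. Parse failures
  are never re-requested: they count against the denominator, so a model
  that answers unparseably is *less* confident by construction.
* **Validator** — N_Va = 10 replies judging the extractor's answer, each a
  JSON object with `Correctness`, `Confidence` (0–100 integer) and
  `Corrected`. Each label votes separately; self-reported confidences are
  bucketed to the nearest 5 before voting so 89-vs-90 jitter cannot break
  unanimity (bucket width is a constant, `CONFIDENCE_BUCKET`).

**Tie policy** (every modal vote): the NA sentinel wins any tie it is part
of — a tie is evidence of insufficient information — otherwise the
lexicographically smallest canonical value wins, and the tie is flagged in
the output. This makes aggregation deterministic and auditable.

**Correction**: when fewer than half the validator replies assert
correctness (strict `v_pct_correct < 0.5`; the threshold is a pipeline
argument), the final value is the validator's modal `Corrected` value. An
exact 50/50 split keeps the extractor's answer.

**Confidence**: C_q is the unweighted mean of five fractions
(EConfidence, VCorrect, VConfidence, VCorrection, V%Correct) × 100. The
VConfidence term defaults to the *consistency* of the bucketed Confidence
label; `vconfidence_mode="self_report"` switches it to the modal
self-reported value / 100, since the plain-language reading of the term is
genuinely ambiguous. Consistency is the default because the other four terms
are consistencies, and a self-reported number would be the only term the
model can inflate directly.

## Vocabulary and normalisation

The schema ships as a versioned JSON document (one object per field) so
other tumour datasets can be dropped in without code changes. Canonical
casing is title-case for category labels ("High") and lower-case "p" for TNM
codes ("pT4a"). NA sentinels are field-specific (NA, pTX, pNX, pMX, RX);
specimen type has no NA entry in the RCPath value set, so "Other" doubles as
its missing sentinel, and any unlisted but recognisably procedural string
("…ectomy", "…resection") normalises to "Other" rather than being guessed
into a named procedure. Numeric fields store integers (millimetres for
diameter, counts for nodes); centimetre quotes are converted (×10). TNM
fields accept systematic surface variants (strip/add the "p" prefix, any
casing), and a bare "T4" normalises to broad pT4, never silently to a
sub-stage. `to_broad` collapses sub-stages (pT4a→pT4, pN1c→pN1, pM1b→pM1)
and is idempotent; evaluation can run at either granularity.

## Platt calibration

Coefficients (A_q, B_q) of p = 1/(1+exp(A_q·c + B_q)) are fitted per field
by maximum likelihood with Platt's smoothed targets t₊=(N₊+1)/(N₊+2),
t₋=1/(N₋+2), via L-BFGS-B on the two-parameter negative log-likelihood with
analytic gradient (gradient tolerance 1e-8, ≤200 iterations, intercept
started at log(N₋+1)/(N₊+1)). Single-class label sets raise a
`DegenerateFitError` instructing identity scaling — an un-calibratable field
should stay visibly uncalibrated. The transform is strictly monotone, so
AUROC and abstention orderings are identical before and after calibration;
a test asserts this exactly.

## Synthetic data: what it emulates and what it does not

`generate_case` samples a mutually consistent truth (metastatic ≤ examined
nodes; pN category derived from the metastatic count via the standard bins
0→pN0, 1–3→pN1, ≥4→pN2), drops each field from the text with probability
0.1 (missingness), and renders one of three styles — narrative prose,
semi-tabular, terse summary — using alias spellings 30% of the time. Value
distributions are chosen to look like a colorectal resection series (pT3
modal stage, ~45% node-negative, 82% M0, 85% R0, diameters 10–130 mm).

`generate_cohort` adds exponential survival with log-hazard
0.5·(T−3) + 0.6·N + 0.9·M over the ordinally coded broad stage (baseline
hazard 0.01/month, independent exponential censoring at 0.01/month, ~35%
censoring). The exponential form keeps closed-form sanity checks easy; the
coefficients double as the weights of the TNM linear risk score so that
recovery is testable.

The **simulated backend** draws a latent "extractable" state per
(report, field) with probability `accuracy`; replies for extractable pairs
centre on the truth, otherwise on a wrong value (stable primary wrong value
with probability `concentration`, else a random alternative; numeric errors
are near-miss ±geometric perturbations, never the truth itself). Marginally
each reply is correct with probability `accuracy`, but replies within a
report agree — the documented failure mode of chat models, which are often
consistent while wrong. This is what makes "pipeline accuracy ≈ configured
accuracy" a meaningful recovery target; with independent per-reply errors,
20-way majority voting would trivially push accuracy toward 1. Validator
replies are truth-informed with probability `validator_informativeness` and
report the *flipped* judgment otherwise, so informativeness 0.5 carries no
signal at all; `Corrected` repeats the extractor's value when judging
"Correct", is the truth when an informed reply judges "Incorrect", and is a
random alternative otherwise.

What passing these tests shows: the aggregation, confidence, calibration,
evaluation and survival machinery is correct, and the confidence score
separates errors whenever the validator carries any signal. What it does
not show: anything about a real model's extraction accuracy on real
reports — synthetic text is far cleaner than scanned, translated or handwritten
clinical reports, and the simulated validator's error structure is stylised. Real
deployments must calibrate on their own manually validated subset.

## Experiment designs used by the acceptance checks

* Accuracy-recovery and confidence-AUROC experiments run with the correction
  stage disabled (`correction_threshold=0`): the simulated validator's
  informed corrections equal the truth, so leaving correction on would
  silently repair nearly every error and make both "accuracy recovers p"
  and "confidence flags errors" vacuous. Correction logic is exercised by
  its own unit tests and stays on (threshold 0.5) in the default pipeline.
* The confidence experiments use four fields at heterogeneous accuracies
  (0.9/0.9/0.6/0.6) over 300 reports and 5 seeds; the uninformative profile
  sets informativeness 0.5 and concentration 1.0 (consistently wrong
  replies), which drives AUROC to ~0.5 and demonstrates why reply
  consistency alone is not reliability.
* Prognosis recovery uses cohorts with missingness 0 (a survival analysis
  presupposes recorded stage); n=300 for the TNM-driven cohort, n=500 for
  the null cohort, 5 seeds each. With the default 10% missingness the
  NA-median fill dilutes the c-index by ~0.02.
* Problem sizes throughout (200–300 reports, 2000 calibration points,
  10,000 vote multisets) are chosen so every claim is measured with
  comfortable statistical margin while the whole battery runs in well under
  a minute.

## Numerical and degenerate-input conventions

* Cohen's kappa with both raters constant and equal returns 1.0 (the
  formula's 0/0 case); kappa and accuracy otherwise come from scikit-learn
  and plain means.
* AUROC is undefined on single-class labels and raises, never returns a
  placeholder; ties count 0.5 (Mann–Whitney convention, matched exactly by
  a pairwise oracle in the tests).
* Abstention rejects strictly below the threshold, so threshold 0 keeps
  everything; an all-rejected point carries `None`, never a fabricated
  accuracy.
* The c-index counts Harrell-permissible pairs (earlier time is an event);
  score ties count 0.5; pairs tied on event time with both events count 1
  on a score tie and 0.5 otherwise. lifelines, which drops tied-time pairs,
  is used as an independent cross-check on tie-free times only.
* Kaplan–Meier and the log-rank test delegate to lifelines; the log-rank
  wrapper raises on zero total events.
* Median-split stratification sends scores ≤ median to the low-risk group
  (odd cohorts give low-risk the extra member; an all-equal cohort is all
  low-risk, with a warning).
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  derivation (`child_seed`), so every pipeline run, generator and CLI
  command is bit-reproducible; prompts render byte-identically.

## Known limitations

* The live backend is a minimal adapter and deliberately untested here; it
  requires the vendor client library and network access.
* The linear ordinal risk score is a stand-in for a learned survival model;
  it exists to exercise and test the survival utilities, not to be a good
  prognostic model.
* Cross-field consistency checking covers node-count inversion and pN-bin
  agreement; with a single distant-metastasis field there is no second
  source to check pM against.
* Only the RCPath colorectal vocabulary ships; other tumour streams need a
  new schema JSON (the code is schema-agnostic).
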