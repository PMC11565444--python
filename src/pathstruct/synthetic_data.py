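"""Synthetic pathology reports, survival cohorts and a simulated model backend.

Real colorectal pathology reports (and the commercial model that reads them)
are replaced for offline work by three generators:

* :func:`generate_case` samples a mutually consistent set of ground-truth
  field values (metastatic nodes never exceed examined nodes; the pN category
  follows the metastatic count) and renders them into free text using one of
  three report styles (narrative, semi-tabular, terse), sometimes through
  alias spellings ("T4A" for pT4a) so normalisation is exercised.
* :func:`generate_cohort` adds survival outcomes whose exponential hazard is
  a linear function of the ordinally coded pT/pN/pM stage, with independent
  exponential censoring — so a TNM-driven risk score is prognostic by
  construction and a zero-coefficient cohort is null by construction.
* :class:`SimulatedBackend` answers extractor and validator prompts from the
  ground truth under a configurable :class:`ResponderProfile`.

Accuracy semantics of the simulated extractor: each (report, field) carries a
latent "extractable" state drawn with probability ``accuracy``.  Replies for
an extractable pair centre on the truth; otherwise they centre on a wrong
value.  Marginally each reply is the true value with probability ``accuracy``
— but replies within a report agree with each other, mirroring the observed
failure mode of chat models, which are frequently consistent while being
wrong.  Majority voting therefore recovers an end-to-end accuracy of
``accuracy`` itself rather than an inflated one.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .field_schema import (
    CanonicalValue,
    SchemaSet,
    default_schema_set,
    pn_bin_for_count,
)
from .llm_interface import NA_DISPLAY, child_seed, parse_prompt_metadata
from .prognosis import SurvivalRecord, ordinal_code

__all__ = [
    "CaseConfig",
    "CohortConfig",
    "GroundTruthCase",
    "ResponderProfile",
    "SimulatedBackend",
    "generate_case",
    "generate_cohort",
    "extract_cases",
    "export_cohort",
    "truth_lookup",
    "truth_table",
    "TNM_WEIGHTS",
]

#: weights of the TNM-based linear risk score used in the prognostic analyses;
#: chosen equal to the default hazard coefficients of the cohort generator
TNM_WEIGHTS = {"local_invasion": 0.5, "lymph_node_status": 0.6, "distant_metastasis": 0.9}

_TEMPLATES = ("narrative", "tabular", "terse")


@dataclass(frozen=True)
class CaseConfig:
    """Distributional knobs for a single synthetic report."""

    missingness: float = 0.1  # per-field probability the report omits the item
    alias_rate: float = 0.3  # probability a value is written via an alias form
    templates: tuple[str, ...] = _TEMPLATES

    def validate(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must lie in [0, 1]")
        if not 0.0 <= self.alias_rate <= 1.0:
            raise ValueError("alias_rate must lie in [0, 1]")
        unknown = set(self.templates) - set(_TEMPLATES)
        if unknown or not self.templates:
            raise ValueError(f"unknown template styles: {sorted(unknown)}")


@dataclass(frozen=True)
class CohortConfig:
    """Survival-generating model: log-hazard linear in coded pT, pN, pM."""

    case: CaseConfig = dc_field(default_factory=CaseConfig)
    coef_t: float = 0.5
    coef_n: float = 0.6
    coef_m: float = 0.9
    baseline_hazard: float = 0.01  # events per month at the reference stage
    censor_rate: float = 0.01  # exponential censoring rate; 0 = no censoring

    def validate(self) -> None:
        self.case.validate()
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruthCase:
    report_id: str
    true_values: Mapping[str, CanonicalValue]  # NA sentinel where missing
    latent_values: Mapping[str, CanonicalValue]  # pre-missingness staging
    report_text: str
    missing_fields: frozenset[str]
    style: str


@dataclass(frozen=True)
class ResponderProfile:
    """Behaviour of the simulated extractor/validator model.

    ``accuracy`` may be a single float or a per-field mapping: probability
    that a reply carries the true value.  ``concentration`` sets how wrong
    replies spread over alternatives (1 = all mass on one stable wrong value).
    ``validator_informativeness`` is the probability a validator reply judges
    the extraction against the truth rather than blindly endorsing it.
    """

    accuracy: float | Mapping[str, float] = 0.9
    concentration: float = 0.7
    malformed_rate: float = 0.02
    validator_informativeness: float = 0.9
    self_report_noise: float = 5.0  # sd of the 0-100 Confidence label

    def accuracy_for(self, field: str) -> float:
        if isinstance(self.accuracy, Mapping):
            return float(self.accuracy[field])
        return float(self.accuracy)

    def validate(self) -> None:
        rates = [self.concentration, self.malformed_rate, self.validator_informativeness]
        if isinstance(self.accuracy, Mapping):
            rates += list(self.accuracy.values())
        else:
            rates.append(self.accuracy)
        for r in rates:
            if not 0.0 <= float(r) <= 1.0:
                raise ValueError(f"profile rate {r!r} outside [0, 1]")
        if self.self_report_noise < 0:
            raise ValueError("self_report_noise must be >= 0")


# ---------------------------------------------------------------------------
# ground-truth sampling


def _sample_values(rng: np.random.Generator, ss: SchemaSet) -> dict[str, CanonicalValue]:
    def cv(field: str, value) -> CanonicalValue:
        fs = ss.get(field)
        return CanonicalValue(field, value, value == fs.na_sentinel)

    values: dict[str, CanonicalValue] = {}
    values["specimen_type"] = cv(
        "specimen_type",
        str(
            rng.choice(
                [v for v in ss.get("specimen_type").categorical_values if v != "Other"]
            )
        ),
    )
    values["tumour_type"] = cv(
        "tumour_type",
        "Adenocarcinoma" if rng.random() < 0.85 else "Mucinous adenocarcinoma",
    )
    sites = [v for v in ss.get("tumour_site").categorical_values if v != "NA"]
    values["tumour_site"] = cv("tumour_site", str(rng.choice(sites)))
    values["maximum_diameter"] = cv("maximum_diameter", int(rng.integers(10, 131)))
    t_stage = str(
        rng.choice(
            ["pTIS", "pT0", "pT1", "pT2", "pT3", "pT4a", "pT4b"],
            p=[0.03, 0.02, 0.08, 0.17, 0.45, 0.15, 0.10],
        )
    )
    values["local_invasion"] = cv("local_invasion", t_stage)
    values["histologic_grade"] = cv(
        "histologic_grade", "High" if rng.random() < 0.3 else "Low"
    )
    examined = int(rng.integers(4, 61))
    if rng.random() < 0.45:
        metastatic = 0
    else:
        metastatic = int(min(rng.geometric(0.35), examined, 50))
    values["examined_nodes"] = cv("examined_nodes", examined)
    values["metastatic_nodes"] = cv("metastatic_nodes", metastatic)
    bin_ = pn_bin_for_count(metastatic)
    if bin_ == "pN0":
        n_stage = "pN0"
    elif bin_ == "pN1":
        n_stage = str(rng.choice(["pN1a", "pN1b", "pN1c"], p=[0.5, 0.4, 0.1]))
    else:
        n_stage = "pN2a" if metastatic <= 6 else "pN2b"
    values["lymph_node_status"] = cv("lymph_node_status", n_stage)
    values["distant_metastasis"] = cv(
        "distant_metastasis",
        str(rng.choice(["pM0", "pM1a", "pM1b", "pM1c"], p=[0.82, 0.09, 0.05, 0.04])),
    )
    values["resection"] = cv(
        "resection", str(rng.choice(["R0", "R1", "R2"], p=[0.85, 0.10, 0.05]))
    )
    return values


def _surface(
    rng: np.random.Generator, fs, value: CanonicalValue, alias_rate: float
) -> str:
    if fs.kind == "numeric":
        return str(value.value)
    forms = fs.surface_forms(str(value.value))
    if len(forms) > 1 and rng.random() < alias_rate:
        return str(rng.choice(forms[1:]))
    return str(value.value)


def _render_text(
    rng: np.random.Generator,
    ss: SchemaSet,
    values: Mapping[str, CanonicalValue],
    missing: frozenset[str],
    style: str,
    alias_rate: float,
) -> str:
    sf = {
        f: _surface(rng, ss.get(f), v, alias_rate)
        for f, v in values.items()
        if f not in missing
    }
    if style == "tabular":
        lines = ["COLORECTAL RESECTION - PATHOLOGY REPORT", ""]
        lines += [f"{ss.get(f).label}: {sf[f]}" for f in ss.proforma_order if f in sf]
        return "\n".join(lines)
    if style == "terse":
        bits = []
        if "tumour_site" in sf:
            bits.append(sf["tumour_site"])
        if "tumour_type" in sf:
            bits.append(sf["tumour_type"].lower())
        if "maximum_diameter" in sf:
            bits.append(f"{sf['maximum_diameter']}mm")
        if "histologic_grade" in sf:
            bits.append(f"grade {sf['histologic_grade']}")
        if "local_invasion" in sf:
            bits.append(sf["local_invasion"])
        if "lymph_node_status" in sf:
            bits.append(sf["lymph_node_status"])
        if "metastatic_nodes" in sf and "examined_nodes" in sf:
            bits.append(f"{sf['metastatic_nodes']}/{sf['examined_nodes']} nodes")
        elif "examined_nodes" in sf:
            bits.append(f"{sf['examined_nodes']} nodes examined")
        elif "metastatic_nodes" in sf:
            bits.append(f"{sf['metastatic_nodes']} nodes positive")
        if "distant_metastasis" in sf:
            bits.append(sf["distant_metastasis"])
        if "resection" in sf:
            bits.append(sf["resection"])
        head = f"Dx ({sf['specimen_type']})" if "specimen_type" in sf else "Dx"
        return head + ": " + "; ".join(bits) + "."
    # narrative
    s = []
    if "specimen_type" in sf:
        s.append(f"The specimen received is a {sf['specimen_type'].lower()}.")
    if "tumour_site" in sf:
        s.append(f"A tumour is identified in the {sf['tumour_site'].lower()}.")
    if "maximum_diameter" in sf:
        s.append(f"It measures {sf['maximum_diameter']} mm in maximum diameter.")
    if "tumour_type" in sf:
        s.append(f"Histology shows {sf['tumour_type'].lower()}.")
    if "histologic_grade" in sf:
        s.append(f"The tumour is {sf['histologic_grade'].lower()} grade.")
    if "local_invasion" in sf:
        s.append(f"Depth of invasion corresponds to {sf['local_invasion']}.")
    if "examined_nodes" in sf:
        s.append(f"A total of {sf['examined_nodes']} lymph nodes were examined.")
    if "metastatic_nodes" in sf:
        s.append(f"{sf['metastatic_nodes']} nodes contain metastatic carcinoma.")
    if "lymph_node_status" in sf:
        s.append(f"Nodal stage: {sf['lymph_node_status']}.")
    if "distant_metastasis" in sf:
        s.append(f"Distant metastatic status: {sf['distant_metastasis']}.")
    if "resection" in sf:
        s.append(f"Resection status: {sf['resection']}.")
    if not s:
        s.append("Specimen received; no further details are recorded.")
    return " ".join(s)


def generate_case(
    seed: int,
    config: CaseConfig | None = None,
    report_id: str | None = None,
    schema_set: SchemaSet | None = None,
) -> GroundTruthCase:
    """Sample one synthetic report with known ground truth (deterministic per seed)."""
    config = config or CaseConfig()
    config.validate()
    ss = schema_set or default_schema_set()
    rng = np.random.default_rng(seed)
    latent = _sample_values(rng, ss)
    missing = frozenset(
        f for f in ss.proforma_order if rng.random() < config.missingness
    )
    truth = {
        f: (ss.get(f).na_value if f in missing else latent[f])
        for f in ss.proforma_order
    }
    style = str(rng.choice(list(config.templates)))
    text = _render_text(rng, ss, latent, missing, style, config.alias_rate)
    return GroundTruthCase(
        report_id=report_id or f"SYN-{seed}",
        true_values=truth,
        latent_values=latent,
        report_text=text,
        missing_fields=missing,
        style=style,
    )


def generate_cohort(
    n: int,
    seed: int,
    config: CohortConfig | None = None,
    schema_set: SchemaSet | None = None,
) -> tuple[list[GroundTruthCase], list[SurvivalRecord]]:
    """Synthetic cohort with TNM-driven exponential survival.

    The hazard for case i is ``h0 * exp(bT*(T_i - 3) + bN*N_i + bM*M_i)``
    with T/N/M the ordinal codes of the latent (pre-missingness) stage;
    censoring times are independent Exp(censor_rate).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or CohortConfig()
    config.validate()
    ss = schema_set or default_schema_set()
    rng = np.random.default_rng(child_seed(seed, "cohort"))
    cases: list[GroundTruthCase] = []
    records: list[SurvivalRecord] = []
    for i in range(n):
        case = generate_case(
            child_seed(seed, "case", i), config.case, report_id=f"SYN-{i:05d}",
            schema_set=ss,
        )
        cases.append(case)
        lp = (
            config.coef_t * (ordinal_code("local_invasion", case.latent_values["local_invasion"], ss) - 3.0)
            + config.coef_n * ordinal_code("lymph_node_status", case.latent_values["lymph_node_status"], ss)
            + config.coef_m * ordinal_code("distant_metastasis", case.latent_values["distant_metastasis"], ss)
        )
        hazard = config.baseline_hazard * float(np.exp(lp))
        death = rng.exponential(1.0 / hazard)
        censor = rng.exponential(1.0 / config.censor_rate) if config.censor_rate > 0 else np.inf
        time = float(min(death, censor))
        records.append(
            SurvivalRecord(case.report_id, time, int(death <= censor))
        )
    return cases, records


# ---------------------------------------------------------------------------
# simulated backend


class SimulatedBackend:
    """Answers extractor/validator prompts from ground truth, fully seeded.

    Prompts must embed a ``[[case:<report_id>]]`` footer resolvable in the
    truth lookup (the pipeline adds it with ``embed_case_marker=True``).
    """

    def __init__(
        self,
        profile: ResponderProfile,
        truth: Mapping[str, Mapping[str, CanonicalValue]],
        schema_set: SchemaSet | None = None,
        salt: int = 0,
    ) -> None:
        profile.validate()
        self.profile = profile
        self.truth = truth
        self.ss = schema_set or default_schema_set()
        self.salt = salt

    # -- latent extractability: stable per (report, field) ------------------
    def _latent_rng(self, kind: str, case_id: str, field: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.salt, zlib.crc32(f"{kind}|{case_id}|{field}".encode())]
        )

    def _extractable(self, case_id: str, field: str) -> bool:
        u = float(self._latent_rng("x", case_id, field).random())
        return u < self.profile.accuracy_for(field)

    def _alternatives(self, field: str, truth: CanonicalValue) -> list[CanonicalValue]:
        fs = self.ss.get(field)
        if fs.kind == "numeric":
            # numeric alternatives handled separately (near-miss perturbation)
            raise AssertionError("use _wrong_numeric for numeric fields")
        return [v for v in fs.canonical_values() if v != truth]

    def _wrong_numeric(
        self, rng: np.random.Generator, field: str, truth: CanonicalValue
    ) -> CanonicalValue:
        fs = self.ss.get(field)
        lo, hi = fs.numeric_range  # type: ignore[misc]
        if truth.is_na:
            return CanonicalValue(field, int(rng.integers(lo, hi + 1)), False)
        k = int(rng.geometric(0.5))
        sign = 1 if rng.random() < 0.5 else -1
        candidate = int(truth.value) + sign * k
        if not lo <= candidate <= hi:
            candidate = int(truth.value) - sign * k
        candidate = int(np.clip(candidate, lo, hi))
        if candidate == int(truth.value):  # range-clip collision: step away
            candidate = candidate + 1 if candidate + 1 <= hi else candidate - 1
        return CanonicalValue(field, candidate, False)

    def _wrong_value(
        self, rng: np.random.Generator, case_id: str, field: str, truth: CanonicalValue
    ) -> CanonicalValue:
        """Wrong value per the concentration profile; never equals truth."""
        fs = self.ss.get(field)
        if fs.kind == "numeric":
            if rng.random() < self.profile.concentration:
                # stable primary wrong value for this (report, field)
                return self._wrong_numeric(self._latent_rng("w", case_id, field), field, truth)
            return self._wrong_numeric(rng, field, truth)
        alts = self._alternatives(field, truth)
        primary = alts[int(self._latent_rng("w", case_id, field).integers(len(alts)))]
        if rng.random() < self.profile.concentration:
            return primary
        return alts[int(rng.integers(len(alts)))]

    def _surface_of(self, rng: np.random.Generator, value: CanonicalValue) -> str:
        if value.is_na and rng.random() < 0.5:
            return NA_DISPLAY
        fs = self.ss.get(value.field)
        if fs.kind == "numeric" and not value.is_na:
            return str(value.value)
        forms = fs.surface_forms(str(value.value))
        if len(forms) > 1 and rng.random() < 0.3:
            return str(rng.choice(forms[1:]))
        return str(value.value)

    def _truth_for(self, case_id: str, field: str) -> CanonicalValue:
        try:
            return self.truth[case_id][field]
        except KeyError:
            raise RuntimeError(
                f"simulated backend cannot resolve case {case_id!r} / field {field!r}"
            ) from None

    def sample(self, prompt: str, n_samples: int, seed: int) -> list[str]:
        meta = parse_prompt_metadata(prompt, self.ss)
        case_id = meta["case_id"]
        if case_id is None:
            raise RuntimeError("prompt carries no [[case:...]] marker")
        field = meta["field"]
        truth = self._truth_for(case_id, field)
        rng = np.random.default_rng([seed, zlib.crc32(prompt.encode()), self.salt])
        if meta["agent"] == "extractor":
            return [
                self._extractor_reply(rng, case_id, field, truth)
                for _ in range(n_samples)
            ]
        return [
            self._validator_reply(rng, case_id, field, truth, meta["extractor_value"])
            for _ in range(n_samples)
        ]

    def _extractor_reply(
        self, rng: np.random.Generator, case_id: str, field: str, truth: CanonicalValue
    ) -> str:
        if rng.random() < self.profile.malformed_rate:
            return "I cannot determine this field from the report provided."
        if self._extractable(case_id, field):
            value = truth
        else:
            value = self._wrong_value(rng, case_id, field, truth)
        label = self.ss.get(field).label
        return json.dumps({label: self._surface_of(rng, value)})

    def _validator_reply(
        self,
        rng: np.random.Generator,
        case_id: str,
        field: str,
        truth: CanonicalValue,
        extractor_surface: str | None,
    ) -> str:
        if rng.random() < self.profile.malformed_rate:
            return "Unable to validate."
        from .field_schema import normalize_value

        extracted = normalize_value(field, extractor_surface or "", self.ss)
        actually_correct = extracted is not None and (
            (extracted.is_na and truth.is_na) or extracted == truth
        )
        informed = rng.random() < self.profile.validator_informativeness
        # an informed reply reports the actual correctness; an uninformed one
        # flips it, so informativeness 0.5 carries no signal at all
        judged_correct = actually_correct if informed else not actually_correct
        if judged_correct:
            corrected = extractor_surface or NA_DISPLAY
        elif informed:
            corrected = str(truth.value)
        else:
            wrong = self._wrong_value(rng, case_id, field, truth)
            corrected = str(wrong.value)
        center = 50.0 + (40.0 if judged_correct else -40.0) * self.profile.validator_informativeness
        conf = int(np.clip(round(rng.normal(center, self.profile.self_report_noise)), 0, 100))
        return json.dumps(
            {
                "Correctness": "Correct" if judged_correct else "Incorrect",
                "Confidence": conf,
                "Corrected": corrected,
            }
        )


# ---------------------------------------------------------------------------
# conveniences used by tests, examples and the CLI


def extract_cases(
    cases: Sequence[GroundTruthCase],
    backend,
    fields: Sequence[str] | None = None,
    seed: int = 0,
    schema_set: SchemaSet | None = None,
    **pipeline_kwargs,
):
    """Run the full pipeline over synthetic cases (marker embedded)."""
    from .agents import extract_report

    ss = schema_set or default_schema_set()
    fields = list(fields) if fields is not None else list(ss.proforma_order)
    return [
        extract_report(
            case.report_text,
            fields,
            backend,
            seed=child_seed(seed, case.report_id),
            report_id=case.report_id,
            schema_set=ss,
            embed_case_marker=True,
            **pipeline_kwargs,
        )
        for case in cases
    ]


def truth_lookup(cases: Sequence[GroundTruthCase]) -> dict[str, Mapping[str, CanonicalValue]]:
    return {c.report_id: c.true_values for c in cases}


def truth_table(cases: Sequence[GroundTruthCase]) -> dict[tuple[str, str], CanonicalValue]:
    return {
        (c.report_id, f): v for c in cases for f, v in c.true_values.items()
    }


def export_cohort(
    cases: Sequence[GroundTruthCase],
    records: Sequence[SurvivalRecord],
    out_dir: str | Path,
) -> None:
    """Write report texts, truth table and survival table in pipeline formats."""
    out = Path(out_dir)
    reports_dir = out / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        (reports_dir / f"{case.report_id}.txt").write_text(case.report_text, "utf-8")
    truth_lines = ["report_id\tfield\tvalue"]
    for case in cases:
        for f, v in case.true_values.items():
            truth_lines.append(f"{case.report_id}\t{f}\t{v.value}")
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n", "utf-8")
    surv_lines = ["report_id\ttime\tevent"]
    for r in records:
        surv_lines.append(f"{r.report_id}\t{r.time:.6f}\t{r.event}")
    (out / "survival.tsv").write_text("\n".join(surv_lines) + "\n", "utf-8")
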