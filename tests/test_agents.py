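"""Majority voting, validator aggregation and the two-stage pipeline."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from pathstruct.agents import (
    AggregatedExtraction,
    ValidatorAggregate,
    aggregate_validator,
    aggregate_votes,
    extract_report,
    resolve_final_value,
    run_extractor,
)
from pathstruct.field_schema import CanonicalValue, normalize_value
from pathstruct.llm_interface import RawReply
from pathstruct.synthetic_data import (
    ResponderProfile,
    SimulatedBackend,
    generate_case,
)


def vote(field: str, value) -> RawReply:
    cv = value if isinstance(value, CanonicalValue) else normalize_value(field, value)
    assert cv is not None
    return RawReply("", True, {"value": cv})


MALFORMED = RawReply("gibberish", False)


def vreply(correctness="correct", confidence=90, corrected="pT3") -> RawReply:
    return RawReply(
        "", True,
        {"correctness": correctness, "confidence": confidence, "corrected": corrected},
    )


class TestAggregateVotes:
    def test_simple_majority_and_confidence(self):
        replies = [vote("local_invasion", "pT3")] * 15 + [vote("local_invasion", "pT2")] * 5
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.value == "pT3"
        assert agg.e_confidence == pytest.approx(0.75)
        assert not agg.tie

    def test_unanimous_not_available(self):
        replies = [vote("local_invasion", "Not Available")] * 20
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.is_na and agg.value.value == "pTX"
        assert agg.e_confidence == 1.0

    def test_tie_prefers_na_sentinel(self):
        replies = [vote("local_invasion", "pT4")] * 10 + [
            vote("local_invasion", "Not Available")
        ] * 10
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.is_na and agg.tie

    def test_tie_between_values_is_lexicographic(self):
        replies = [vote("local_invasion", "pT3")] * 5 + [vote("local_invasion", "pT2")] * 5
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.value == "pT2" and agg.tie

    def test_aliases_pool_into_one_bucket(self):
        replies = [
            vote("local_invasion", "T4A"),
            vote("local_invasion", "pT4a"),
            vote("local_invasion", "t4a"),
            vote("local_invasion", "pT2"),
        ]
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.value == "pT4a"
        assert agg.vote_counts[normalize_value("local_invasion", "pT4a")] == 3

    def test_malformed_replies_depress_confidence(self):
        replies = [vote("histologic_grade", "High")] * 12 + [MALFORMED] * 8
        agg = aggregate_votes(replies, "histologic_grade")
        assert agg.value.value == "High"
        assert agg.e_confidence == pytest.approx(12 / 20)
        assert agg.n_valid == 12

    def test_zero_valid_replies_returns_na_at_zero_confidence(self):
        agg = aggregate_votes([MALFORMED] * 4, "resection")
        assert agg.value.value == "RX" and agg.value.is_na
        assert agg.e_confidence == 0.0 and agg.n_valid == 0

    def test_reply_count_must_match_n_requested(self):
        with pytest.raises(ValueError):
            aggregate_votes([vote("resection", "R0")], "resection", n_requested=5)

    @given(
        st.lists(
            st.sampled_from(["pT2", "pT3", "pT4", "Not Available", "<bad>"]),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_bruteforce_oracle(self, raw_values):
        replies = [
            MALFORMED if v == "<bad>" else vote("local_invasion", v) for v in raw_values
        ]
        agg = aggregate_votes(replies, "local_invasion")
        # independent oracle: plain counting + documented tie policy
        counts = Counter(
            normalize_value("local_invasion", v) for v in raw_values if v != "<bad>"
        )
        if not counts:
            assert agg.value.is_na and agg.e_confidence == 0.0
            return
        top = max(counts.values())
        tied = [v for v, c in counts.items() if c == top]
        expected = min(tied, key=lambda v: (0 if v.is_na else 1, str(v.value)))
        assert agg.value == expected
        assert agg.e_confidence == pytest.approx(top / len(raw_values))
        assert agg.tie == (len(tied) > 1)

    @given(st.permutations([("pT2", 4), ("pT3", 4), ("<bad>", 2)]))
    def test_invariant_under_reply_permutation(self, spec):
        raw = [v for v, n in spec for _ in range(n)]
        replies = [
            MALFORMED if v == "<bad>" else vote("local_invasion", v) for v in raw
        ]
        agg = aggregate_votes(replies, "local_invasion")
        assert agg.value.value == "pT2" and agg.e_confidence == 0.4


class _CountingBackend:
    """Backend double: records (n_samples, seed) calls, replies a constant."""

    def __init__(self, reply='{"Local Invasion": "pT2"}'):
        self.calls = []
        self.reply = reply

    def sample(self, prompt, n_samples, seed):
        self.calls.append((n_samples, seed))
        return [self.reply] * n_samples


class TestRunExtractor:
    def test_even_split_across_two_prompt_variants(self):
        backend = _CountingBackend()
        agg = run_extractor("some report", "local_invasion", backend, n_total=20)
        assert [n for n, _ in backend.calls] == [10, 10]
        assert len({s for _, s in backend.calls}) == 2  # distinct per-variant seeds
        assert agg.n_requested == 20 and agg.e_confidence == 1.0

    def test_minimal_unanimous_run(self):
        agg = run_extractor("r", "local_invasion", _CountingBackend(), n_total=2)
        assert agg.value.value == "pT2" and agg.e_confidence == 1.0

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError):
            run_extractor("r", "local_invasion", _CountingBackend(), n_total=7)

    def test_deterministic_with_simulated_backend(self):
        case = generate_case(11)
        backend = SimulatedBackend(
            ResponderProfile(accuracy=0.7), {case.report_id: case.true_values}, salt=11
        )
        a = run_extractor(
            case.report_text, "tumour_site", backend, seed=3, case_marker=case.report_id
        )
        b = run_extractor(
            case.report_text, "tumour_site", backend, seed=3, case_marker=case.report_id
        )
        assert a == b


class TestAggregateValidator:
    FIELD = "local_invasion"
    EXTRACTED = normalize_value(FIELD, "pT3")

    def test_unanimous_replies(self):
        agg = aggregate_validator([vreply()] * 10, self.EXTRACTED, self.FIELD)
        assert (
            agg.v_correct == agg.v_confidence == agg.v_correction == agg.v_pct_correct == 1.0
        )
        assert agg.corrected_value.value == "pT3"

    def test_split_correctness(self):
        replies = [vreply("correct")] * 7 + [vreply("incorrect")] * 3
        agg = aggregate_validator(replies, self.EXTRACTED, self.FIELD)
        assert agg.v_pct_correct == pytest.approx(0.7)
        assert agg.v_correct == pytest.approx(0.7)

    def test_confidence_label_tie(self):
        replies = [vreply(confidence=90)] * 5 + [vreply(confidence=80)] * 5
        agg = aggregate_validator(replies, self.EXTRACTED, self.FIELD)
        assert agg.v_confidence == pytest.approx(0.5)
        assert agg.tie

    def test_confidence_bucketing_absorbs_jitter(self):
        # 89 vs 90 fall in the same 5-wide bucket: unanimity preserved
        replies = [vreply(confidence=89)] * 5 + [vreply(confidence=90)] * 5
        agg = aggregate_validator(replies, self.EXTRACTED, self.FIELD)
        assert agg.v_confidence == 1.0

    def test_corrections_normalised_before_voting(self):
        replies = [
            vreply(corrected="T4A"),
            vreply(corrected="pT4a"),
            vreply(corrected="pT2"),
        ]
        agg = aggregate_validator(replies, self.EXTRACTED, self.FIELD)
        assert agg.corrected_value.value == "pT4a"
        assert agg.v_correction == pytest.approx(2 / 3)

    def test_unparseable_correction_maps_to_na(self):
        agg = aggregate_validator(
            [vreply(corrected="banana")] * 3, self.EXTRACTED, self.FIELD
        )
        assert agg.corrected_value.is_na

    def test_zero_valid_replies(self):
        agg = aggregate_validator([MALFORMED] * 5, self.EXTRACTED, self.FIELD)
        assert agg.v_correct == agg.v_pct_correct == 0.0
        assert agg.corrected_value.is_na and agg.n_valid == 0


class TestResolveFinalValue:
    @staticmethod
    def _pair(v_pct_correct: float):
        field = "local_invasion"
        ext_value = normalize_value(field, "pT2")
        corrected = normalize_value(field, "pT3")
        extraction = AggregatedExtraction(
            field, ext_value, 0.9, {ext_value: 18}, 20, 20
        )
        validation = ValidatorAggregate(
            field, 0.8, 0.8, 0.8, v_pct_correct, corrected, 90, 10, 10
        )
        return extraction, validation

    def test_majority_correct_keeps_extractor_value(self):
        ext, val = self._pair(0.9)
        assert resolve_final_value(ext, val).value == "pT2"

    def test_majority_incorrect_applies_correction(self):
        ext, val = self._pair(0.2)
        assert resolve_final_value(ext, val).value == "pT3"

    def test_exact_tie_favours_no_correction(self):
        ext, val = self._pair(0.5)
        assert resolve_final_value(ext, val).value == "pT2"

    def test_threshold_is_configurable(self):
        ext, val = self._pair(0.4)
        assert resolve_final_value(ext, val, correction_threshold=0.0).value == "pT2"


class TestExtractReport:
    def test_all_fields_give_one_result_each(self, schema_set):
        case = generate_case(21)
        backend = SimulatedBackend(
            ResponderProfile(), {case.report_id: case.true_values}, salt=21
        )
        report = extract_report(
            case.report_text,
            schema_set.field_names,
            backend,
            seed=1,
            report_id=case.report_id,
            embed_case_marker=True,
        )
        assert list(report.results) == list(schema_set.field_names)
        for r in report.results.values():
            assert 0.0 <= r.raw_confidence <= 100.0
            assert r.calibrated_confidence is None

    def test_empty_field_list_makes_no_backend_calls(self):
        backend = _CountingBackend()
        report = extract_report("text", [], backend)
        assert report.results == {} and backend.calls == []

    def test_perfect_profile_yields_confidence_100_everywhere(self):
        case = generate_case(22)
        profile = ResponderProfile(
            accuracy=1.0,
            malformed_rate=0.0,
            validator_informativeness=1.0,
            self_report_noise=0.0,
        )
        backend = SimulatedBackend(profile, {case.report_id: case.true_values}, salt=22)
        report = extract_report(
            case.report_text,
            ["histologic_grade", "local_invasion", "examined_nodes"],
            backend,
            seed=5,
            report_id=case.report_id,
            embed_case_marker=True,
        )
        for f, r in report.results.items():
            assert r.raw_confidence == pytest.approx(100.0)
            assert r.final_value == case.true_values[f]

    def test_unknown_field_rejected_before_any_backend_call(self):
        backend = _CountingBackend()
        with pytest.raises(KeyError):
            extract_report("text", ["bananas"], backend)
        assert backend.calls == []
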