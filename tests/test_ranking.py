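"""AICc computation and candidate ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblemage.fitting import FitResult
from ensemblemage.ranking import RankingTable, aicc, rank_candidates, render_report


def _aicc_oracle(ssr, k, n):
    """Independently coded closed form (kept deliberately separate from the
    implementation under test)."""
    correction = (2.0 * k * (k + 1.0)) / (n - k - 1.0)
    return n * math.log(ssr) - n * math.log(n) + 2.0 * k + correction


def _result(name, ssr, k, n=25, params=None):
    return FitResult(
        candidate=name,
        parameters=params or {},
        ssr=ssr,
        k=k,
        n=n,
        starts_attempted=1,
        starts_converged=1,
        seed=0,
    )


class TestAicc:
    def test_hand_evaluated_value(self):
        # 25*ln(0.251/25) + 2*3 + 2*3*4/21
        assert aicc(0.251, 3, 25) == pytest.approx(-107.887, abs=5e-4)

    def test_parameter_penalty_difference(self):
        # going from k=3 to k=4 at fixed SSR costs 2 + 40/20 - 24/21
        diff = aicc(0.251, 4, 25) - aicc(0.251, 3, 25)
        assert diff == pytest.approx(2.857, abs=5e-4)

    def test_ssr_ratio_identity(self):
        for s, s2 in [(0.3, 0.05), (1.7, 1.7), (0.049, 0.251)]:
            assert aicc(s, 5, 25) - aicc(s2, 5, 25) == pytest.approx(25 * math.log(s / s2))

    def test_undefined_when_k_too_large(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(0.1, 24, 25)

    def test_zero_ssr_diverges_with_guidance(self):
        with pytest.raises(ValueError, match="interpolat"):
            aicc(0.0, 3, 25)

    @given(
        ssr=st.floats(1e-6, 1e3),
        k=st.integers(1, 20),
        n=st.integers(5, 200),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_matches_independent_oracle(self, ssr, k, n):
        if n - k - 1 < 1:
            return
        assert aicc(ssr, k, n) == pytest.approx(_aicc_oracle(ssr, k, n), abs=1e-12, rel=1e-12)

    @given(k=st.integers(1, 15), n=st.integers(20, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_increasing_in_ssr_and_k_penalty(self, k, n):
        if n - k - 2 < 1:
            return
        assert aicc(0.2, k, n) < aicc(0.3, k, n)
        penalty = lambda kk: 2 * kk + 2 * kk * (kk + 1) / (n - kk - 1)  # noqa: E731
        assert penalty(k) < penalty(k + 1)


class TestRanking:
    def test_sorted_with_consecutive_ranks(self):
        table = rank_candidates(
            [_result("A", 0.3, 3), _result("B", 0.05, 6), _result("C", 0.8, 2)]
        )
        assert [e.candidate for e in table] == ["B", "A", "C"]
        assert [e.rank for e in table] == [1, 2, 3]
        assert table.entries[0].delta_aicc == 0.0
        assert all(e.delta_aicc >= 0 for e in table)

    def test_tie_breaks_on_smaller_k_then_name(self):
        # equal AICc by construction: same ssr, same k -> name decides
        t = rank_candidates([_result("Z", 0.2, 3), _result("A", 0.2, 3)])
        assert [e.candidate for e in t] == ["A", "Z"]
        # same AICc, different k: build ssr2 so the AICc matches exactly
        s3 = 0.2
        target = aicc(s3, 3, 25)
        s5 = math.exp((target - 10 - 60 / 19) / 25) * 25
        t2 = rank_candidates([_result("big", s5, 5), _result("small", s3, 3)])
        assert t2.entries[0].candidate == "small"

    def test_single_result(self):
        t = rank_candidates([_result("only", 0.1, 2)])
        assert t.entries[0].rank == 1
        assert t.entries[0].delta_aicc == 0.0

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            rank_candidates([_result("A", 0.1, 2, n=25), _result("B", 0.1, 2, n=24)])

    def test_oversized_candidate_listed_unranked(self):
        t = rank_candidates([_result("ok", 0.1, 3), _result("huge", 0.01, 24)])
        huge = t.entry("huge")
        assert huge.rank is None
        assert "undefined" in huge.note
        assert t.entries[-1].candidate == "huge"

    def test_adaptation_attached_from_best_fit(self, candidate_models):
        from ensemblemage.hog import reference_parameters

        res = _result("C5c", 0.2, 3, params=reference_parameters())
        t = rank_candidates([res], models={"C5c": candidate_models["C5c"]})
        e = t.entry("C5c")
        assert e.adaptation == "adapted"
        assert e.adaptation_readout == pytest.approx(0.0, abs=1e-6)


class TestReport:
    def test_empty_table_renders_headers_only(self, tmp_path):
        out = render_report(RankingTable(entries=[]), tmp_path)
        assert "Rank" in out["md"]
        assert (tmp_path / "ranking.csv").read_text().startswith("rank,candidate")

    def test_json_round_trips_to_equal_table(self):
        import json

        t = rank_candidates([_result("A", 0.3, 3), _result("B", 0.05, 6)])
        out = render_report(t)
        back = RankingTable.from_dict(json.loads(out["json"]))
        assert back.to_dict() == t.to_dict()

    def test_three_decimal_formatting(self):
        t = rank_candidates([_result("A", 0.123456, 3)])
        assert "0.123" in render_report(t)["md"]
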