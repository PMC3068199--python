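"""Shock-protocol integration, adaptation classification, feature extraction."""

import math

import numpy as np
import pytest

from ensemblemage.model import (
    KineticLaw,
    Parameter,
    Reaction,
    ReactionModel,
    SpeciesDef,
    symbolic_odes,
)
from ensemblemage.simulate import (
    ShockProtocol,
    classify_adaptation,
    extract_features,
    moiety_drift,
    simulate,
)


def _decay_model(k=1.0, a0=1.0):
    return ReactionModel(
        name="decay",
        species=[SpeciesDef("A", "dynamic", a0)],
        reactions=[Reaction("r", ["A"], [], KineticLaw("mass_action", ["k"]))],
        parameters={"k": Parameter("k", value=k)},
    )


class TestProtocol:
    def test_parse_round_trip(self):
        p = ShockProtocol.parse("0:0.4,30:0.4,60:0.4")
        assert p.shocks == [(0.0, 0.4), (30.0, 0.4), (60.0, 0.4)]
        assert str(p) == "0:0.4,30:0.4,60:0.4"

    @pytest.mark.parametrize("shocks", [[(10.0, 1.0), (5.0, 1.0)], [(0.0, -1.0)], [(-2.0, 1.0)]])
    def test_invalid_protocols_rejected(self, shocks):
        with pytest.raises(ValueError):
            ShockProtocol(shocks=shocks)


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        res = simulate(_decay_model(k=1.0), None, ShockProtocol([], horizon=10.0), t_eval=[10.0])
        assert res["A"][0] == pytest.approx(math.exp(-10.0), abs=1e-8)

    def test_no_stimulus_stays_at_initial_state(self, truth_model):
        res = simulate(truth_model, None, ShockProtocol([], horizon=60.0))
        for sid in ("Hog1", "PHog1", "Glycerol"):
            assert np.allclose(res[sid], res[sid][0])
        assert np.allclose(res["PHog1"], 0.0, atol=1e-10)

    def test_shock_is_exact_step_in_input(self, truth_model):
        res = simulate(truth_model, None, ShockProtocol([(0.0, 1.0)], horizon=30.0))
        assert np.allclose(res["OuterOsmolarity"], 1.0)

    def test_sample_at_shock_time_reports_pre_shock_state(self, truth_model):
        proto = ShockProtocol([(0.0, 0.5), (30.0, 0.5)], horizon=60.0)
        res = simulate(truth_model, None, proto, t_eval=[30.0, 31.0])
        assert res["OuterOsmolarity"][0] == pytest.approx(0.5)
        assert res["OuterOsmolarity"][1] == pytest.approx(1.0)

    def test_params_outside_bounds_rejected(self, truth_model):
        with pytest.raises(ValueError, match="bounds"):
            simulate(truth_model, {"k_v9": 1e9}, ShockProtocol([], horizon=1.0))

    def test_tolerance_convergence(self, truth_model):
        proto = ShockProtocol([(0.0, 1.0)], horizon=60.0)
        a = simulate(truth_model, None, proto, rtol=1e-8, atol=1e-10)
        b = simulate(truth_model, None, proto, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(a["PHog1"] - b["PHog1"])) < 1e-6

    @pytest.mark.parametrize("candidate", ["C5c", "C6a", "C8b", "C10"])
    def test_moiety_conservation_along_trajectory(self, candidate_models, candidate):
        model = candidate_models[candidate]
        res = simulate(model, None, ShockProtocol([(0.0, 1.0), (30.0, 0.5)], horizon=90.0))
        assert moiety_drift(res, model) < 1e-6


class TestAdaptation:
    def test_truth_model_adapts_at_1M(self, truth_model):
        status, readout = classify_adaptation(truth_model, dose=1.0)
        assert status == "adapted"
        assert abs(readout) < 0.01

    def test_threshold_splits_at_five_percent(self, truth_model):
        # the decision is a pure threshold on the read-out value
        from ensemblemage.simulate import ADAPTATION_THRESHOLD

        assert ADAPTATION_THRESHOLD == 0.05

    def test_c5c_steady_state_is_analytically_zero(self, candidate_models):
        """With glycerol production proportional to P-Hog1 and no efflux,
        dGlycerol/dt = k*PHog1 forces PHog1 = 0 at any steady state."""
        import sympy as sp

        odes = symbolic_odes(candidate_models["C5c"])
        g = odes["Glycerol"]
        phog = sp.Symbol("PHog1")
        sols = sp.solve(g, phog)
        assert sols == [0]

    @pytest.mark.parametrize("candidate", ["C5c", "C7c", "C8c"])
    def test_no_efflux_candidates_have_zero_output_steady_state(
        self, candidate_models, candidate
    ):
        """With P-Hog1-driven glycerol production and no efflux, the glycerol
        balance forces P-Hog1 = 0 at any steady state (perfect adaptation)."""
        import sympy as sp

        model = candidate_models[candidate]
        odes = symbolic_odes(model)
        assert sp.solve(odes["Glycerol"], sp.Symbol("PHog1")) == [0]

    @pytest.mark.parametrize("candidate", ["C10", "C6a", "C6b"])
    def test_desensitization_candidates_keep_output_on(self, candidate_models, candidate, rng):
        """With positive rates and constant positive input, the steady state
        of a desensitisation-only candidate has P-Hog1 > 0: check by running
        to a long horizon and confirming the output never returns to zero."""
        model = candidate_models[candidate]
        params = {pid: float(v) for pid, v in zip(model.parameters, rng.uniform(0.2, 2.0, len(model.parameters)))}
        res = simulate(model, params, ShockProtocol([(0.0, 1.0)], horizon=400.0))
        tail = res["PHog1"][res.times > 300.0]
        assert np.min(tail) > 0.0
        assert np.mean(tail) > 1e-4


class TestFeatures:
    def test_monotone_decay_peaks_at_zero(self):
        res = simulate(_decay_model(), None, ShockProtocol([(0.0, 1.0)], horizon=10.0))
        # no input species in this toy model: protocol shocks have no target
        feats = extract_features(res, observable="A")
        assert feats["peak_time"] == 0.0
        assert feats["peak_value"] == pytest.approx(1.0)

    def test_constant_zero_trace(self, truth_model):
        res = simulate(truth_model, None, ShockProtocol([], horizon=10.0))
        feats = extract_features(res)
        assert feats["peak_value"] == pytest.approx(0.0, abs=1e-12)
        assert feats["final_value"] == pytest.approx(0.0, abs=1e-12)
        assert feats["per_shock_peaks"] == []

    def test_triple_shock_gives_three_comparable_peaks(self, truth_model):
        proto = ShockProtocol([(0.0, 0.4), (30.0, 0.4), (60.0, 0.4)], horizon=90.0)
        res = simulate(truth_model, None, proto)
        peaks = extract_features(res)["per_shock_peaks"]
        assert len(peaks) == 3
        # each response clears its pre-shock trough by a wide margin
        t, y = res.times, res["PHog1"]
        for i, t0 in enumerate([0.0, 30.0, 60.0]):
            pre = y[np.argmin(np.abs(t - t0))] if t0 > 0 else 0.0
            assert peaks[i] > 5 * pre or pre < 0.01
        assert min(peaks) > 0.8 * max(peaks)
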