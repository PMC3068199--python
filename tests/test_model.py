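"""Core model representation: validation, compiled ODEs, moiety analysis."""

import numpy as np
import pytest

from ensemblemage.model import (
    KineticLaw,
    Parameter,
    Reaction,
    ReactionModel,
    SpeciesDef,
    build_rhs,
    conserved_moieties,
    stoichiometry_matrix,
    validate_model,
)


def _two_state(k=2.0):
    return ReactionModel(
        name="ab",
        species=[SpeciesDef("A", "dynamic", 0.5), SpeciesDef("B", "dynamic", 0.0)],
        reactions=[Reaction("r1", ["A"], ["B"], KineticLaw("mass_action", ["k"]))],
        parameters={"k": Parameter("k", value=k)},
    )


class TestValidation:
    def test_master_validates(self, master):
        assert validate_model(master) == []

    def test_dangling_reference_named(self, master):
        broken = master.copy()
        broken.species = [s for s in broken.species if s.id != "Pbs2"]
        msgs = validate_model(broken)
        assert any("v7" in m and "Pbs2" in m for m in msgs)

    def test_nonpositive_bound_rejected(self):
        m = _two_state()
        m.parameters["k"] = Parameter("k", value=1.0, lower=0.0)
        assert any("lower bound" in v for v in validate_model(m))

    def test_duplicate_species_rejected(self):
        m = _two_state()
        m.species.append(SpeciesDef("A", "dynamic", 0.1))
        assert any("duplicate species" in v for v in validate_model(m))

    def test_derived_without_rule_rejected(self):
        m = _two_state()
        m.species.append(SpeciesDef("S", "derived", 0.0))
        assert any("no assignment rule" in v for v in validate_model(m))

    def test_parameter_shared_by_two_laws_rejected(self):
        m = _two_state()
        m.reactions.append(Reaction("r2", ["B"], ["A"], KineticLaw("mass_action", ["k"])))
        assert any("referenced by both" in v for v in validate_model(m))


class TestRhs:
    def test_mass_action_closed_form(self):
        rhs, state_ids, param_ids = build_rhs(_two_state(k=2.0))
        dy = rhs(0.0, [0.5, 0.0], [2.0])
        d = dict(zip(state_ids, dy))
        assert d["A"] == pytest.approx(-1.0)
        assert d["B"] == pytest.approx(+1.0)

    def test_truth_model_stationary_off_stimulus(self, truth_model):
        rhs, state_ids, param_ids = build_rhs(truth_model)
        y0 = [truth_model.get_species(s).initial_value for s in state_ids]
        pv = [truth_model.parameters[p].value for p in param_ids]
        assert np.allclose(rhs(0.0, y0, pv), 0.0)

    def test_unknown_template_is_hard_error(self):
        m = _two_state()
        m.reactions[0].law = KineticLaw("hill", ["k"])
        with pytest.raises(ValueError):
            build_rhs(m)

    @pytest.mark.parametrize("candidate", ["C5c", "C6a", "C8a", "C10"])
    def test_moiety_rows_sum_to_zero_at_random_states(self, candidate_models, candidate, rng):
        """d/dt of every conserved pool is identically zero, state-independent."""
        model = candidate_models[candidate]
        rhs, state_ids, param_ids = build_rhs(model)
        pools = conserved_moieties(model)
        assert pools
        pv = rng.uniform(0.01, 2.0, size=len(param_ids))
        for _ in range(100):
            y = rng.uniform(0.0, 1.5, size=len(state_ids))
            dy = dict(zip(state_ids, rhs(0.0, y, pv)))
            for members, _total in pools:
                assert abs(sum(dy[s] for s in members)) < 1e-12


class TestMoieties:
    def _brute_force_left_null(self, model):
        """Independent numeric oracle: SVD left-null-space of N."""
        N, sids, _ = stoichiometry_matrix(model)
        u, s, _vt = np.linalg.svd(N)
        null_dim = N.shape[0] - int(np.sum(s > 1e-10))
        return null_dim, N, sids

    @pytest.mark.parametrize(
        "candidate,expected",
        [
            ("C10", [{"Sho1", "Sho1a", "Sho1i"}, {"Ste11", "Ste11a"}, {"Pbs2", "PPbs2"}, {"Hog1", "PHog1"}]),
            ("C5c", [{"Hog1", "PHog1"}]),
        ],
    )
    def test_fixture_pools(self, candidate_models, candidate, expected):
        model = candidate_models[candidate]
        pools = conserved_moieties(model)
        got = [set(m) for m, _ in pools]
        for want in expected:
            assert want in got
        # cross-check count against the numeric null-space dimension
        null_dim, N, sids = self._brute_force_left_null(model)
        assert len([p for p in pools]) <= null_dim
        # and each reported pool really is a left-null vector
        for members, _total in pools:
            v = np.array([1.0 if s in members else 0.0 for s in sids])
            assert np.allclose(v @ N, 0.0)

    def test_pure_production_has_no_product_pool(self):
        m = ReactionModel(
            name="prod",
            species=[SpeciesDef("G", "dynamic", 0.0)],
            reactions=[Reaction("r", [], ["G"], KineticLaw("zero_order", ["v"]))],
            parameters={"v": Parameter("v", 1.0)},
        )
        assert all("G" not in members for members, _ in conserved_moieties(m))


def test_michaelis_menten_reduces_to_mass_action_at_large_km():
    """MM rate -> mass-action rate as Km -> inf with Vmax/Km fixed."""
    from ensemblemage.model import rate_expression
    import sympy as sp

    rxn_mm = Reaction("r", ["S"], ["P"], KineticLaw("michaelis_menten", ["Vmax", "Km"]))
    rxn_ma = Reaction("r", ["S"], ["P"], KineticLaw("mass_action", ["k"]))
    S = sp.Symbol("S")
    Vmax, Km, k = sp.symbols("Vmax Km k", positive=True)
    mm = rate_expression(rxn_mm)
    ma = rate_expression(rxn_ma)
    for s_val in (0.01, 0.3, 1.0):
        km = 200.0 * s_val
        ratio = float(
            (mm.subs({S: s_val, Vmax: km * 1.7, Km: km}) / ma.subs({S: s_val, k: 1.7}))
        )
        assert abs(ratio - 1.0) < 0.01
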