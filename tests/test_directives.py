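"""Candidate generation: cascades, provenance, determinism, error handling."""

import pytest

from ensemblemage import hog
from ensemblemage.directives import (
    CandidateSpec,
    Directive,
    DirectiveError,
    apply_directives,
    dump_candidate_specs,
    generate_ensemble,
    load_candidate_specs,
    write_provenance,
)
from ensemblemage.io_native import dump_model
from ensemblemage.model import validate_model


def test_empty_directive_list_is_identity(master):
    model, rec = apply_directives(master, CandidateSpec("copy", []))
    assert len(model.species) == len(master.species)
    assert len(model.reactions) == len(master.reactions)
    assert set(model.parameters) == set(master.parameters)
    assert rec.cascade_deleted_reactions == []


def test_c5c_structure(ensemble):
    model, rec = ensemble["C5c"]
    assert len(model.reactions) == 3
    assert len(model.parameters) == 3
    assert sorted(r.id for r in model.reactions) == ["v10", "v11", "v9"]
    # Hog1 activation rewired to the osmotic imbalance signal
    assert model.get_reaction("v9").law.catalyst == "Signal"


def test_every_candidate_validates_with_no_orphan_parameters(ensemble):
    for name, (model, rec) in ensemble.items():
        assert validate_model(model) == [], name
        reachable = {pid for r in model.reactions for pid in r.law.parameter_ids}
        assert set(model.parameters) == reachable, name
        assert (rec.n_species, rec.n_parameters) == (
            len(model.species),
            len(model.parameters),
        ), name


def test_signatures_match_expected_counts(ensemble):
    got = {
        name: (len(model.species), len(model.parameters))
        for name, (model, _) in ensemble.items()
    }
    assert got == hog.EXPECTED_SIGNATURES


def test_pbs2_deletion_without_substitute_is_error(master):
    spec = CandidateSpec(
        "bad",
        [Directive("delete_species", target="Pbs2"), Directive("delete_species", target="PPbs2")],
    )
    with pytest.raises(DirectiveError, match="v9"):
        apply_directives(master, spec)
    # with the substitution covering v9's catalyst the same deletions succeed
    ok = CandidateSpec(
        "ok",
        [
            Directive("substitute_modifier", target="v9", old_species="PPbs2", new_species="Sho1a"),
            Directive("delete_species", target="Pbs2"),
            Directive("delete_species", target="PPbs2"),
        ],
    )
    model, rec = apply_directives(master, ok)
    assert set(rec.cascade_deleted_reactions) == {"v7", "v8"}
    assert model.get_reaction("v9").law.catalyst == "Sho1a"


def test_substitute_to_deleted_species_is_error(master):
    spec = CandidateSpec(
        "bad",
        [
            Directive("substitute_modifier", target="v9", old_species="PPbs2", new_species="Ste11a"),
            Directive("delete_species", target="Ste11a"),
        ],
    )
    with pytest.raises(DirectiveError, match="Ste11a"):
        apply_directives(master, spec)


def test_directive_on_missing_id_names_it(master):
    with pytest.raises(DirectiveError, match="v99"):
        apply_directives(master, CandidateSpec("bad", [Directive("delete_reaction", target="v99")]))
    with pytest.raises(DirectiveError, match="Xyz"):
        apply_directives(master, CandidateSpec("bad", [Directive("delete_species", target="Xyz")]))


def test_spec_is_not_idempotent_on_reduced_model(ensemble, master):
    """Re-applying a spec to its own output raises (targets are gone)."""
    c5c_model, _ = ensemble["C5c"]
    spec = next(s for s in hog.candidate_specs() if s.name == "C5c")
    with pytest.raises(DirectiveError):
        apply_directives(c5c_model, spec)


def test_duplicate_candidate_names_rejected(master):
    specs = [CandidateSpec("X", []), CandidateSpec("X", [])]
    with pytest.raises(DirectiveError, match="duplicate"):
        generate_ensemble(master, specs)


def test_one_bad_spec_does_not_abort_the_others(master):
    specs = [
        CandidateSpec("good", []),
        CandidateSpec("bad", [Directive("delete_species", target="Nope")]),
    ]
    results, errors = generate_ensemble(master, specs)
    assert [m.name for m, _ in results] == ["good"]
    assert "bad" in errors and "Nope" in errors["bad"]


def test_generation_deterministic(master):
    specs = hog.candidate_specs()
    a, _ = generate_ensemble(master, specs)
    b, _ = generate_ensemble(master, specs)
    for (ma, _), (mb, _) in zip(a, b):
        assert dump_model(ma) == dump_model(mb)


def test_provenance_report_contents(ensemble):
    md, js = write_provenance([rec for _m, rec in ensemble.values()])
    # C5c: whole cascade + rewiring documented
    for sid in ("Sho1", "Sho1a", "Sho1i", "Ste11", "Ste11a", "Pbs2", "PPbs2"):
        assert f"delete species {sid}" in md
    assert "substitute modifier PPbs2 -> Signal in v9" in md
    # C10: glycerol module removed, stimulus rebound to external osmolarity
    assert "delete species Glycerol" in md
    assert "set input (stimulus) species to OuterOsmolarity" in md
    assert "provenance" in js or js.startswith("[")


def test_empty_provenance_report(tmp_path):
    md, js = write_provenance([], tmp_path)
    assert "Candidate provenance" in md
    assert (tmp_path / "provenance.json").read_text() == "[]"


def test_spec_yaml_round_trip(tmp_path):
    specs = hog.candidate_specs()
    path = tmp_path / "directives.yaml"
    dump_candidate_specs(specs, path)
    loaded = load_candidate_specs(path)
    assert dump_candidate_specs(loaded) == dump_candidate_specs(specs)
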