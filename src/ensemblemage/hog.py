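"""Built-in fixture: the Sho1-branch HOG-pathway master model and its
candidate ensemble.

The master network combines every mechanism under test for the shutdown of
Sho1-branch signalling after osmotic shock:

* a receptor module with active (``Sho1a``) and desensitised (``Sho1i``)
  forms, where phosphorylated Hog1 drives desensitisation (reaction v3) —
  the *desensitisation* (D) feedback;
* the MAP-kinase cascade Ste11 -> Pbs2 -> Hog1 as
  phosphorylation/dephosphorylation cycles (v5–v10);
* glycerol accumulation driven by P-Hog1 (v11) and constitutively (v12),
  with a channel-regulated efflux (v13), feeding back on the stimulus via
  ``Signal = max(OuterOsmolarity - Glycerol, 0)`` — the *integrator* (I)
  feedback that can produce perfect adaptation.

Protein species are fractions of their conserved totals (each total = 1);
``Glycerol``, ``OuterOsmolarity`` and ``Signal`` are in M (KCl equivalents);
time is in minutes.  Osmotic shocks are instantaneous increments of
``OuterOsmolarity``.

Twelve candidates are derived from the master by directives; each is named
``C<number of components>`` with a letter for the glycerol-handling variant.
Their (components, parameters) signatures are:
C5c(5,3) C5b(5,4) C5a(5,7) C6b(6,6) C6a(6,12) C7c(7,5) C7b(7,6) C7a(7,9)
C8c(8,7) C8b(8,8) C8a(8,11) C10(10,20).
"""

from __future__ import annotations

from .directives import CandidateSpec, Directive
from .model import (
    AssignmentRule,
    KineticLaw,
    Parameter,
    Reaction,
    ReactionModel,
    SpeciesDef,
)

__all__ = [
    "build_master",
    "candidate_specs",
    "reference_parameters",
    "FEEDBACK_CLASS",
    "EXPECTED_SIGNATURES",
]

#: feedback mechanism per candidate: D = Sho1 desensitisation,
#: I = integrator (glycerol) feedback
FEEDBACK_CLASS = {
    "C10": "D",
    "C6a": "D",
    "C6b": "D",
    "C8a": "D+I",
    "C8b": "D+I",
    "C8c": "D+I",
    "C7a": "I",
    "C7b": "I",
    "C7c": "I",
    "C5a": "I",
    "C5b": "I",
    "C5c": "I",
}

#: candidate -> (component count, free parameter count)
EXPECTED_SIGNATURES = {
    "C5c": (5, 3),
    "C5b": (5, 4),
    "C5a": (5, 7),
    "C6b": (6, 6),
    "C6a": (6, 12),
    "C7c": (7, 5),
    "C7b": (7, 6),
    "C7a": (7, 9),
    "C8c": (8, 7),
    "C8b": (8, 8),
    "C8a": (8, 11),
    "C10": (10, 20),
}


def _mm(rid: str, substrate: str, product: str, catalyst: str | None) -> Reaction:
    mods = [(catalyst, "catalyst")] if catalyst else []
    return Reaction(
        id=rid,
        substrates=[substrate],
        products=[product],
        law=KineticLaw("michaelis_menten", [f"Vmax_{rid}", f"Km_{rid}"], mods),
    )


def build_master() -> ReactionModel:
    """The 12-component, 13-reaction master model.

    Reaction map: v1 Sho1->Sho1a (stimulated by the designated input, here
    Signal); v2 reverse; v3 Sho1a->Sho1i catalysed by PHog1; v4 Sho1i->Sho1;
    v5/v6 Ste11 cycle (v5 catalysed by Sho1a); v7/v8 Pbs2 cycle (v7 by
    Ste11a); v9/v10 Hog1 cycle (v9 by PPbs2); v11 glycerol production by
    PHog1; v12 constitutive glycerol production; v13 glycerol efflux
    inhibited by Signal (channel closure).
    """
    species = [
        SpeciesDef("Sho1", "dynamic", 1.0),
        SpeciesDef("Sho1a", "dynamic", 0.0),
        SpeciesDef("Sho1i", "dynamic", 0.0),
        SpeciesDef("Ste11", "dynamic", 1.0),
        SpeciesDef("Ste11a", "dynamic", 0.0),
        SpeciesDef("Pbs2", "dynamic", 1.0),
        SpeciesDef("PPbs2", "dynamic", 0.0),
        SpeciesDef("Hog1", "dynamic", 1.0),
        SpeciesDef("PHog1", "dynamic", 0.0),
        SpeciesDef("Glycerol", "dynamic", 0.0),
        SpeciesDef("OuterOsmolarity", "input", 0.0),
        SpeciesDef("Signal", "derived", 0.0),
    ]
    reactions = [
        _mm("v1", "Sho1", "Sho1a", "Signal"),
        _mm("v2", "Sho1a", "Sho1", None),
        _mm("v3", "Sho1a", "Sho1i", "PHog1"),
        _mm("v4", "Sho1i", "Sho1", None),
        _mm("v5", "Ste11", "Ste11a", "Sho1a"),
        _mm("v6", "Ste11a", "Ste11", None),
        _mm("v7", "Pbs2", "PPbs2", "Ste11a"),
        _mm("v8", "PPbs2", "Pbs2", None),
        _mm("v9", "Hog1", "PHog1", "PPbs2"),
        _mm("v10", "PHog1", "Hog1", None),
        Reaction("v11", [], ["Glycerol"], KineticLaw("mass_action", ["k_v11"], [("PHog1", "catalyst")])),
        Reaction("v12", [], ["Glycerol"], KineticLaw("zero_order", ["v0_v12"])),
        Reaction(
            "v13",
            ["Glycerol"],
            [],
            KineticLaw("regulated_efflux", ["Vmax_v13", "Km_v13", "Ki_v13"], [("Signal", "inhibitor")]),
        ),
    ]
    pids = [pid for r in reactions for pid in r.law.parameter_ids]
    parameters = {pid: Parameter(id=pid, value=1.0, lower=1e-6, upper=1e3) for pid in pids}
    return ReactionModel(
        name="hog_sho1_master",
        species=species,
        reactions=reactions,
        rules=[AssignmentRule("Signal", "max(OuterOsmolarity - Glycerol, 0)")],
        events=[],
        parameters=parameters,
        stimulus="Signal",
    )


def _swap_mass(*rids: str) -> list[Directive]:
    return [Directive("swap_kinetics", target=r, new_template="mass_action") for r in rids]


def _del_species(*sids: str) -> list[Directive]:
    return [Directive("delete_species", target=s) for s in sids]


def _del_reactions(*rids: str) -> list[Directive]:
    return [Directive("delete_reaction", target=r) for r in rids]


def candidate_specs() -> list[CandidateSpec]:
    """The 12 candidate directive sets, from fullest (C10) to simplest (C5c).

    Branch structure: C10/C6a/C6b keep only the desensitisation feedback
    (glycerol module deleted, OuterOsmolarity drives v1 directly);
    C8* keep both feedbacks; C7* drop the desensitised receptor form;
    C5* drop the receptor entirely (Signal drives Hog1 activation).  The
    a/b/c letters are the glycerol variants: (a) regulated efflux +
    constitutive production, (b) constitutive (mass-action) efflux,
    (c) no efflux.
    """
    no_glycerol = [
        Directive("set_input", new_species="OuterOsmolarity"),
        *_del_species("Glycerol", "Signal"),
    ]
    drop_cascade = [
        # remove the Ste11/Pbs2 layers; Hog1 activation re-wired to Sho1a
        Directive("substitute_modifier", target="v9", old_species="PPbs2", new_species="Sho1a"),
        *_del_species("Pbs2", "PPbs2", "Ste11", "Ste11a"),
    ]
    mass_core = _swap_mass("v1", "v2", "v3", "v4", "v9", "v10")
    no_sho1i = _del_species("Sho1i")  # cascades v3, v4
    drop_v12 = _del_reactions("v12")
    efflux_mass = [Directive("swap_kinetics", target="v13", new_template="mass_action")]
    no_efflux = _del_reactions("v12", "v13")

    c8a = drop_cascade + mass_core
    c7a = c8a + no_sho1i
    # C5: no receptor at all — Signal itself drives Hog1 activation, so v9's
    # catalyst is rebound straight from PPbs2 to Signal
    c5a = [
        Directive("substitute_modifier", target="v9", old_species="PPbs2", new_species="Signal"),
        *_del_species("Pbs2", "PPbs2", "Ste11", "Ste11a", "Sho1i", "Sho1", "Sho1a"),
        *_swap_mass("v9", "v10"),
    ]

    specs = [
        CandidateSpec("C10", list(no_glycerol)),
        CandidateSpec("C6a", no_glycerol + drop_cascade),
        CandidateSpec("C6b", no_glycerol + drop_cascade + mass_core),
        CandidateSpec("C8a", list(c8a)),
        CandidateSpec("C8b", c8a + drop_v12 + efflux_mass),
        CandidateSpec("C8c", c8a + no_efflux),
        CandidateSpec("C7a", list(c7a)),
        CandidateSpec("C7b", c7a + drop_v12 + efflux_mass),
        CandidateSpec("C7c", c7a + no_efflux),
        CandidateSpec("C5a", list(c5a)),
        CandidateSpec("C5b", c5a + drop_v12 + efflux_mass),
        CandidateSpec("C5c", c5a + no_efflux),
    ]
    return specs


def reference_parameters() -> dict[str, float]:
    """Ground-truth rate constants for C5c used by the synthetic data.

    Chosen so a 1 M shock drives the P-Hog1 fraction to a peak around
    0.85–0.9 within a few minutes, with decline below 0.05 by 30–60 min:
    k_v9 activation 5 /(M min), k_v10 relaxation 1 /min, k_v11 glycerol
    production 0.12 M/min per unit P-Hog1 fraction.
    """
    return {"k_v9": 5.0, "k_v10": 1.0, "k_v11": 0.12}
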