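# Methods

## Model representation

A model is a list of species (roles: `dynamic`, `input`, `derived`),
irreversible unit-stoichiometry reactions with rate laws drawn from four
templates, assignment rules for derived species, timed-addition events,
and a parameter table with fitting bounds.  The representation is
deliberately declarative: the same object drives validation, symbolic ODE
compilation (sympy → lambdified right-hand side), stoichiometric analysis,
YAML serialisation and SBML L3V1 export.

Units in the HOG fixture: proteins are fractions of their conserved totals
(each total normalised to 1, consistent with treating P-Hog1 as 100%
phosphorylatable at saturation); `Glycerol`, `OuterOsmolarity` and
`Signal` are in M (KCl equivalents); time is in minutes.  Volume change,
turgor and transcription are deliberately abstracted away; an osmotic
shock is an instantaneous increment of `OuterOsmolarity`.

The osmotic imbalance is clamped: `Signal = max(OuterOsmolarity −
Glycerol, 0)`.  Without the clamp a glycerol overshoot would turn the
stimulus negative and drive unphysical de-activation; with it the
integrator feedback simply switches off once the imbalance is resolved.

Conserved pools are found as non-negative integer vectors in the left
null space of the stoichiometry matrix (exact rational arithmetic).  In
the fixture these are the phosphoform pools (e.g. {Hog1, PHog1}), and
their conservation along trajectories is used as an integration check.

## Candidate generation

Candidates are derived from the master by declarative directives.  Design
choices that were genuinely open:

- **Deleting a species cascades** to every reaction in which it is a
  substrate or product, and sweeps parameters no longer referenced by any
  rate law, and removes rules/events that mention it.
- **A modifier left dangling is an error**, never silently dropped.  The
  interesting candidates rewire catalysis (Hog1 activation driven by
  Sho1a or by Signal once the kinase cascade is removed); silently
  dropping a catalyst would change a model's meaning without a trace, so
  the directive set must rebind it explicitly (`substitute_modifier`).
- **Directive order is normalised** (rebindings, then kinetic swaps, then
  reaction deletions, then species deletions) so directive sets are
  declarative rather than procedural, and deletion order within a set
  cannot change the outcome.
- **`set_input`** re-designates which species drives pathway stimulation
  by rebinding every modifier reference to the current stimulus species.
  Integrator models are driven by `Signal`; desensitisation-only models
  (whose glycerol module is deleted) by `OuterOsmolarity` directly.

Each candidate carries a provenance record (master hash, directives,
cascade consequences, resulting counts), rendered as markdown + JSON, so
unsuccessful candidates remain documented.

The fixture's kinetics: the Michaelis–Menten master rate laws are kept in
the D-branch originals (C10, C6a); all other candidates swap to mass
action.  This is the only assignment under which every candidate's name
(component count) and parameter count are mutually consistent with the
2-parameters-per-MM / 1-per-mass-action / 3-per-regulated-efflux
bookkeeping.  Component counting includes `OuterOsmolarity` and `Signal`
where retained.

## Simulation

LSODA (stiff-capable) with relative tolerance 1e−8 (1e−7 inside the
fitting objective; the reported SSR is re-evaluated at 1e−8).  Shocks are
handled by integrator restart — the integration stops at each shock time,
the input is incremented, and integration resumes — never by stepping
across the discontinuity.  A sample that falls exactly on a shock time
reports the pre-shock state.  Output grid: 0.5 min unless overridden.

**Adaptation read-out.**  A candidate is classified *not adapted* when its
P-Hog1 read-out one hour after a 1 M shock exceeds 5% of total Hog1.  The
read-out is the mean over t ∈ [55, 65] min rather than the instantaneous
t = 60 value: re-fitted desensitisation models can settle into sustained
oscillations, where a point read-out would be phase-sensitive; the
windowed mean is robust to that and coincides with the steady state for
non-oscillatory fits.  The 1 M dose is the strongest single shock in the
study design.

**Analytic structure worth knowing.**  Every no-efflux integrator variant
(suffix c) satisfies d[Glycerol]/dt = k·[P-Hog1], so any steady state has
P-Hog1 = 0 exactly — perfect adaptation is structural, independent of
parameter values.  Desensitisation-only models with strictly positive
rates and a constant positive input have P-Hog1 > 0 at steady state.

## Parameter estimation

Unweighted least squares: SSR = Σ (simulated P-Hog1 fraction − scaled
observation)², simulated at the observation times exactly.  The observed
values are compared to the model fraction directly (100%-phosphorylatable
assumption; no fitted scale factor) and no weighting scheme is applied.

Multi-start protocol: 20 start points sampled log-uniformly within the
bounds [1e−6, 1e3] (the lower bound is part of the study design; the
upper bound is generous), each refined with a trust-region-reflective
least-squares step (2-point finite-difference Jacobian) in log₁₀ space,
capped at 60 objective evaluations per parameter.  A start whose
simulation fails contributes an infinite objective and is discarded; the
best converged start wins.  Randomness: one documented generator
(`numpy.random.default_rng`); per-candidate seeds are master seed +
candidate index.

## Model discrimination

AICc = n·ln(SSR/n) + 2k + 2k(k+1)/(n−k−1), the standard least-squares
small-sample criterion.  Candidates are sorted ascending; ties break on
smaller k, then name.  A candidate with n − k − 1 < 1 has no defined AICc
and is listed unranked at the bottom with a note rather than dropped; an
SSR of exactly 0 is reported as an exact interpolant rather than ranked
(the log diverges).  Akaike weights and model averaging are out of scope.

## Synthetic data

The generator emulates the study's P-Hog1 blot quantifications, which are
not publicly deposited.  Ground truth is C5c — the simplest integrator
candidate — at documented reference rates (k_v9 = 5 /(M·min), k_v10 =
1 /min, k_v11 = 0.12 M/min per unit P-Hog1): a 1 M shock then peaks at
≈ 0.82 within ~1 min and declines below 0.05 well before 60 min.

Design (25 fitting points): single 1 M shock, 10 samples on [0, 60] min;
double 0.5 M shock at t = 0 and 30, 10 samples on [0, 60]; single 0.2 M
shock, 5 samples on [0, 30].  The sampling grids and doses are this
package's choice of a realistic design — denser early where the response
moves fastest — as the original sampling schedule is not published.
Noise is additive Gaussian, sd = 8% of the noise-free peak, truncated at
zero; all series are then scaled jointly by 1/(max + sd).  With this
calibration the scaled maximum lands at 0.92 ± 0.01 across seeds.  A
triple-shock series (0.4 M at t = 0/30/60) is generated for validation
only and scaled so its maximum matches the scaled 1 M series maximum.

What the generator does *not* emulate: blot-to-blot normalisation error,
saturation nonlinearity of densitometry, correlated errors within a blot,
and biological replicate variance.  A passing recovery or ranking test
therefore demonstrates the machinery and the discriminability of the
mechanisms under idealised noise, not performance on real blots.

**Identifiability.**  The double-shock series carries the discriminating
signature: a full-sized second response at t = 30, which irreversible
desensitisation cannot reproduce after complete first-shock adaptation.
Within C5c itself, the 25-point design identifies the glycerol rate
k_v11 well (≲ 20% at the default noise) and pins the predicted response
to within a couple of noise standard deviations, but k_v9 and k_v10
individually are sloppy — the activation rise (~1 min) is faster than
the sampling, so essentially only their ratio is constrained, and even
the ratio inherits amplified noise because the peak level saturates in
it.  Noise-free data recovers all three parameters to < 1e−3 relative.

**Pseudo-adaptation of desensitisation fits.**  Against data generated by
a perfect adaptor, the best fit of a desensitisation-only candidate
(C6a/C6b) is a corner of parameter space where receptor recovery
(Sho1i → Sho1) is driven to the lower bound: the receptor pool is
absorbed into the desensitised form, the output decays to ~0 within the
hour, and the 5%-threshold read-out classifies the model as adapted —
at the price of a crippled second-shock response and an SSR an order of
magnitude worse than the integrator models.  Landscape scans (60
independent starts) confirm that every C6a optimum with a sustained
read-out above 5% fits worse than this pseudo-adapting corner.  Under
these synthetic conditions the feedback mechanisms are therefore
discriminated by fit quality and parsimony (SSR, AICc) more sharply than
by the steady-state read-out alone; the full 10-species candidate C10,
whose best fit oscillates around an elevated level (read-out ≈ 0.18),
is the one flagged not-adapted.

## Problem sizes and determinism

The shipped study runs 12 candidates × 20 starts on 25 points; the full
pipeline takes on the order of ten minutes on one CPU, dominated by the
12- and 20-parameter Michaelis–Menten candidates.  All stochastic steps
(noise, start sampling) derive from a single master seed; re-running with
the same seed is bit-identical.

## Known limitations

- Rate laws are limited to the four templates; free-text kinetics,
  compartments/volumes, and stochastic simulation are out of scope.
- SBML import requires the kinetic-template annotation this package
  writes; foreign SBML with arbitrary MathML rate laws is rejected with
  an explicit error rather than mis-parsed.
- The local refiner is not a global optimiser; for the 20-parameter
  candidate the best-of-20-starts SSR is a practical, seed-reproducible
  summary, not a certified global minimum.  This does not affect the
  ranking conclusion, which is driven by the AICc correction term.
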