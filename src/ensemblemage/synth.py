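"""Synthetic P-Hog1 time courses standing in for the osmotic-shock data.

No public accessions exist for the original Western-blot measurements, so
the fitting target is generated from the best-supported candidate (C5c,
integrator feedback, no glycerol efflux) at its reference rate constants,
under the study's shock design:

* single 1 M shock at t = 0, 10 samples on [0, 60] min,
* double 0.5 M shock at t = 0 and t = 30, 10 samples on [0, 60] min,
* single 0.2 M shock at t = 0, 5 samples on [0, 30] min,

for 25 fitting points in total.  Additive Gaussian noise (sd = 0.08 x the
noise-free peak, truncated at zero) emulates blot quantification error, and
all series are scaled jointly by 1 / (max + sd) — the convention that maps
the strongest measured response to just under 1 (about 0.92 with the
default calibration).  The ground truth is recorded in ``meta`` so recovery
tests can close the loop.

A separate triple-shock series (3 x 0.4 M, 30-min intervals, [0, 90] min)
is generated for validation only and scaled so its maximum equals the
maximum of the scaled 1 M single-shock series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hog
from .directives import apply_directives
from .fitting import ObservationSeries, ObservationSet
from .simulate import ShockProtocol, compile_model, simulate

__all__ = [
    "SyntheticConfig",
    "scale_series",
    "generate_fitting_dataset",
    "generate_triple_shock_dataset",
    "build_truth_model",
]

_DEFAULT_SERIES = [
    ("single_1M", ShockProtocol([(0.0, 1.0)], horizon=61.0),
     [0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0]),
    ("double_0.5M", ShockProtocol([(0.0, 0.5), (30.0, 0.5)], horizon=61.0),
     [0.0, 2.0, 5.0, 10.0, 20.0, 29.0, 32.0, 35.0, 45.0, 60.0]),
    ("single_0.2M", ShockProtocol([(0.0, 0.2)], horizon=31.0),
     [0.0, 2.0, 5.0, 15.0, 30.0]),
]


@dataclass
class SyntheticConfig:
    seed: int = 1
    #: absolute noise sd; ``None`` means 0.08 x the noise-free peak
    noise_sd: float | None = None
    noise_sd_factor: float = 0.08
    series: list = field(default_factory=lambda: list(_DEFAULT_SERIES))


def build_truth_model():
    """The generating model: C5c at the reference rate constants."""
    master = hog.build_master()
    spec = next(s for s in hog.candidate_specs() if s.name == "C5c")
    model, _ = apply_directives(master, spec)
    return model.with_parameters(hog.reference_parameters())


def scale_series(values: np.ndarray, sd: float) -> np.ndarray:
    """Divide by (max(values) + sd), the blot-normalisation convention.

    With sd = 0 the maximum maps to exactly 1; with sd > 0 it lands just
    below 1.  All-zero input is an error (nothing to scale against).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    m = float(np.max(values)) if values.size else 0.0
    if m == 0.0:
        raise ValueError("cannot scale an all-zero series")
    return values / (m + sd)


def generate_fitting_dataset(config: SyntheticConfig | None = None) -> ObservationSet:
    """Simulate the truth model under the shock design, add noise, scale.

    Returns an :class:`ObservationSet` with 25 points whose ``meta`` records
    the ground-truth parameters, the noise sd, the scale factor and the
    noise-free values.
    """
    config = config or SyntheticConfig()
    model = build_truth_model()
    cm = compile_model(model)
    clean: list[np.ndarray] = []
    for _sid, proto, times in config.series:
        res = simulate(cm, None, proto, t_eval=np.asarray(times, dtype=float))
        clean.append(res["PHog1"])
    peak = max(float(np.max(c)) for c in clean)
    sd = config.noise_sd if config.noise_sd is not None else config.noise_sd_factor * peak

    rng = np.random.default_rng(config.seed)
    noisy = [np.maximum(c + rng.normal(0.0, sd, size=c.shape), 0.0) for c in clean]

    global_max = max(float(np.max(v)) for v in noisy)
    scale = 1.0 / (global_max + sd)
    series = [
        ObservationSeries(series_id=sid, protocol=proto, times=np.asarray(times, float), values=v * scale)
        for (sid, proto, times), v in zip(config.series, noisy)
    ]
    return ObservationSet(
        series=series,
        observable="PHog1",
        meta={
            "truth_model": model.name,
            "truth_parameters": hog.reference_parameters(),
            "noise_sd": sd,
            "scale_factor": scale,
            "clean_values": [c.tolist() for c in clean],
            "seed": config.seed,
        },
    )


def generate_noise_free_dataset(config: SyntheticConfig | None = None) -> ObservationSet:
    """Noise-free, unscaled variant for self-consistency and recovery tests."""
    config = config or SyntheticConfig()
    model = build_truth_model()
    cm = compile_model(model)
    series = []
    for sid, proto, times in config.series:
        res = simulate(cm, None, proto, t_eval=np.asarray(times, dtype=float))
        series.append(
            ObservationSeries(series_id=sid, protocol=proto, times=np.asarray(times, float), values=res["PHog1"])
        )
    return ObservationSet(
        series=series,
        observable="PHog1",
        meta={"truth_model": model.name, "truth_parameters": hog.reference_parameters(), "noise_sd": 0.0},
    )


def generate_triple_shock_dataset(
    config: SyntheticConfig | None = None,
    reference: ObservationSet | None = None,
) -> ObservationSet:
    """Validation-only triple-shock series (0.4 M at t = 0/30/60, [0, 90]).

    The series maximum is scaled to the maximum of the scaled 1 M
    single-shock fitting series (``reference``; regenerated from the same
    config when not supplied).  Not part of the n = 25 fitting set.
    """
    config = config or SyntheticConfig()
    if reference is None:
        reference = generate_fitting_dataset(config)
    ref_max = max(float(np.max(s.values)) for s in reference.series if s.series_id == "single_1M")

    model = build_truth_model()
    proto = ShockProtocol([(0.0, 0.4), (30.0, 0.4), (60.0, 0.4)], horizon=91.0)
    times = np.concatenate([np.array([0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 29.0]) + off for off in (0.0, 30.0, 60.0)])
    res = simulate(model, None, proto, t_eval=times)
    clean = res["PHog1"]
    sd = config.noise_sd if config.noise_sd is not None else config.noise_sd_factor * max(float(np.max(clean)), 1e-12)
    rng = np.random.default_rng(config.seed + 104729)  # decouple from the fitting noise stream
    noisy = np.maximum(clean + rng.normal(0.0, sd, size=clean.shape), 0.0)
    m = float(np.max(noisy))
    values = noisy * (ref_max / m) if m > 0 else noisy
    return ObservationSet(
        series=[ObservationSeries(series_id="triple_0.4M", protocol=proto, times=times, values=values)],
        observable="PHog1",
        meta={
            "truth_model": model.name,
            "truth_parameters": hog.reference_parameters(),
            "noise_sd": sd,
            "scaled_to": ref_max,
            "validation_only": True,
        },
    )
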