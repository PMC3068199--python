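"""Parameter estimation: bounded multi-start least squares against scaled
P-Hog1 time courses.

Each observation series carries its own shock protocol; the objective is the
unweighted sum of squared residuals between the simulated P-Hog1 fraction
and the scaled data, under the convention that 100% of total Hog1 is
phosphorylatable (no fitted scale factor).  Start points are sampled
log-uniformly within the bounds and refined by a trust-region-reflective
least-squares step in log10 parameter space, which keeps rate constants
positive and evens out the many orders of magnitude the bounds span.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ReactionModel
from .simulate import CompiledModel, ShockProtocol, SimulationError, compile_model

__all__ = [
    "ObservationSeries",
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "ssr",
    "fit_candidate",
    "fit_ensemble",
]


@dataclass
class ObservationSeries:
    series_id: str
    protocol: ShockProtocol
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times within a series must be strictly increasing")


@dataclass
class ObservationSet:
    """Scaled P-Hog1 observations, the fitting target.  ``n`` is the total
    point count over all series (25 in the study design)."""

    series: list[ObservationSeries]
    observable: str = "PHog1"
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(sum(len(s.times) for s in self.series))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for t, v in zip(s.times, s.values):
                rows.append(
                    {
                        "series_id": s.series_id,
                        "time_min": float(t),
                        "value": float(v),
                        "protocol": str(s.protocol),
                    }
                )
        return pd.DataFrame(rows, columns=["series_id", "time_min", "value", "protocol"])

    def to_csv(self, path: str | Path | None = None) -> str:
        text = self.to_frame().to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_csv(source: str | Path) -> "ObservationSet":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            df = pd.read_csv(source)
        else:
            df = pd.read_csv(io.StringIO(source))
        series = []
        for sid, grp in df.groupby("series_id", sort=False):
            proto = ShockProtocol.parse(str(grp["protocol"].iloc[0]))
            horizon = max([t for t, _ in proto.shocks] + [float(grp["time_min"].max())]) + 1.0
            proto.horizon = horizon
            series.append(
                ObservationSeries(
                    series_id=str(sid),
                    protocol=proto,
                    times=grp["time_min"].to_numpy(),
                    values=grp["value"].to_numpy(),
                )
            )
        return ObservationSet(series=series)


@dataclass
class FitConfig:
    n_starts: int = 20
    seed: int = 1
    lower: float = 1e-6
    upper: float = 1e3
    #: integration tolerances used inside the objective (final SSR is
    #: re-evaluated at the reporting tolerance below)
    rtol: float = 1e-7
    atol: float = 1e-9
    report_rtol: float = 1e-8
    report_atol: float = 1e-10
    #: cap on objective evaluations per start, scaled by parameter count
    max_nfev_per_param: int = 60
    xtol: float = 1e-10
    ftol: float = 1e-10


@dataclass
class FitResult:
    candidate: str
    parameters: dict[str, float]
    ssr: float
    k: int
    n: int
    starts_attempted: int
    starts_converged: int
    seed: int
    start_ssrs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "ssr": float(self.ssr),
            "k": self.k,
            "n": self.n,
            "starts_attempted": self.starts_attempted,
            "starts_converged": self.starts_converged,
            "seed": self.seed,
        }


class FitError(RuntimeError):
    pass


log = logging.getLogger("ensemblemage.fitting")


def _residuals(
    cm: CompiledModel,
    pvec: np.ndarray,
    observations: ObservationSet,
    rtol: float,
    atol: float,
) -> np.ndarray:
    obs_idx = cm.state_ids.index(observations.observable) if observations.observable in cm.state_ids else None
    res = []
    for s in observations.series:
        states = cm.integrate(pvec, s.protocol, s.times, rtol=rtol, atol=atol)
        if obs_idx is not None:
            sim = states[:, obs_idx]
        else:  # observable is a derived species
            traj = {sid: states[:, i] for i, sid in enumerate(cm.state_ids)}
            sim = cm.derived_trajectories(s.times, traj)[observations.observable]
        res.append(sim - s.values)
    return np.concatenate(res)


def ssr(
    model: ReactionModel | CompiledModel,
    params: dict[str, float],
    observations: ObservationSet,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Sum of squared residuals of the simulated observable against the data,
    with simulation evaluated at the observation times exactly."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    values = cm.model.parameter_values()
    values.update({k: float(v) for k, v in params.items()})
    pvec = np.array([values[p] for p in cm.param_ids])
    r = _residuals(cm, pvec, observations, rtol, atol)
    return float(np.dot(r, r))


def fit_candidate(
    model: ReactionModel | CompiledModel,
    observations: ObservationSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Multi-start bounded least-squares fit of one candidate.

    Start points are sampled log-uniformly in the bounds; each is refined by
    ``scipy.optimize.least_squares`` (trust-region reflective, 2-point
    finite-difference Jacobian) in log10 space.  A start whose simulation
    fails contributes an infinite objective and is discarded.  Reproducible
    given ``config.seed``.  Raises :class:`FitError` if no start converges.
    """
    config = config or FitConfig()
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    pids = cm.param_ids
    k = len(pids)
    if k == 0:
        raise FitError(f"{cm.model.name}: no free parameters to fit")
    lo = np.array([max(cm.model.parameters[p].lower, config.lower) for p in pids])
    hi = np.array([min(cm.model.parameters[p].upper, config.upper) for p in pids])
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    rng = np.random.default_rng(config.seed)
    starts = rng.uniform(log_lo, log_hi, size=(config.n_starts, k))

    def objective(theta: np.ndarray) -> np.ndarray:
        try:
            with warnings.catch_warnings():
                # bad start points make LSODA complain before we discard them
                warnings.simplefilter("ignore")
                return _residuals(cm, 10.0 ** theta, observations, config.rtol, config.atol)
        except (SimulationError, OverflowError, FloatingPointError):
            return np.full(observations.n, 1e6)

    best = None
    start_ssrs: list[float] = []
    n_conv = 0
    diagnostics: list[str] = []
    for theta0 in starts:
        try:
            sol = least_squares(
                objective,
                theta0,
                bounds=(log_lo, log_hi),
                method="trf",
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=1e-12,
                max_nfev=config.max_nfev_per_param * max(k, 4),
            )
        except Exception as exc:  # noqa: BLE001 - per-start failures are data
            diagnostics.append(str(exc))
            start_ssrs.append(float("inf"))
            continue
        s = float(2.0 * sol.cost)
        if not np.isfinite(s) or s >= 1e11:
            diagnostics.append("objective not finite (simulation failures)")
            start_ssrs.append(float("inf"))
            continue
        n_conv += 1
        start_ssrs.append(s)
        log.debug("%s start %d: ssr=%.6g nfev=%d", cm.model.name, len(start_ssrs), s, sol.nfev)
        if best is None or s < best[1]:
            best = (sol.x, s)
    if best is None:
        raise FitError(
            f"{cm.model.name}: no start converged; diagnostics: " + "; ".join(diagnostics[:5])
        )
    theta_best, _ = best
    values = {pid: float(10.0 ** th) for pid, th in zip(pids, theta_best)}
    final_ssr = ssr(cm, values, observations, rtol=config.report_rtol, atol=config.report_atol)
    return FitResult(
        candidate=cm.model.name,
        parameters=values,
        ssr=final_ssr,
        k=k,
        n=observations.n,
        starts_attempted=config.n_starts,
        starts_converged=n_conv,
        seed=config.seed,
        start_ssrs=start_ssrs,
    )


def fit_ensemble(
    models: list[ReactionModel],
    observations: ObservationSet,
    config: FitConfig | None = None,
) -> tuple[list[FitResult], dict[str, str]]:
    """Fit every candidate independently.

    Per-candidate seeds are derived as ``master seed + candidate index`` so
    runs are reproducible yet starts differ across candidates.  Partial
    failures are reported in the returned error map, not raised.
    """
    config = config or FitConfig()
    results: list[FitResult] = []
    errors: dict[str, str] = {}
    for i, model in enumerate(models):
        sub = FitConfig(**{**config.__dict__, "seed": config.seed + i})
        try:
            results.append(fit_candidate(model, observations, sub))
            log.info(
                "fitted %s: ssr=%.6g k=%d converged=%d/%d",
                model.name,
                results[-1].ssr,
                results[-1].k,
                results[-1].starts_converged,
                sub.n_starts,
            )
        except (FitError, ValueError) as exc:
            errors[model.name] = str(exc)
            log.warning("fit failed for %s: %s", model.name, exc)
    return results, errors
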