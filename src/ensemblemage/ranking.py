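"""AICc-based ranking of fitted candidate models.

For least-squares fits the small-sample Akaike criterion is

    AICc = n * ln(SSR / n) + 2k + 2k(k + 1) / (n - k - 1)

with SSR the sum of squared residuals, k the number of fitted parameters
and n the number of data points.  Lower is better: the criterion trades
goodness of fit against model complexity, and the correction term blows up
as k approaches n - 1, which is what demotes heavily parameterised models
on small data sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .fitting import FitResult
from .model import ReactionModel
from .simulate import classify_adaptation

__all__ = ["aicc", "RankingEntry", "RankingTable", "rank_candidates", "render_report"]


def aicc(ssr: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion for a least-squares fit.

    Raises ``ValueError`` when the correction is undefined (n - k - 1 < 1)
    or when SSR is not strictly positive (an SSR of 0 means the candidate
    interpolates the data exactly; report it as such rather than ranking).
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be positive integers")
    if n - k - 1 < 1:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} < 1 (k={k}, n={n})")
    if ssr < 0:
        raise ValueError("SSR must be non-negative")
    if ssr == 0:
        raise ValueError(
            "AICc diverges at SSR = 0; the candidate interpolates the data exactly "
            "— report it as an exact interpolant instead of ranking it"
        )
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class RankingEntry:
    rank: int | None
    candidate: str
    k: int
    ssr: float
    aicc: float | None
    delta_aicc: float | None
    feedback: str | None = None
    adaptation: str | None = None
    adaptation_readout: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "candidate": self.candidate,
            "k": self.k,
            "ssr": self.ssr,
            "aicc": self.aicc,
            "delta_aicc": self.delta_aicc,
            "feedback": self.feedback,
            "adaptation": self.adaptation,
            "adaptation_readout": self.adaptation_readout,
            "note": self.note,
        }


@dataclass
class RankingTable:
    entries: list[RankingEntry]
    n: int | None = None
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def entry(self, candidate: str) -> RankingEntry:
        for e in self.entries:
            if e.candidate == candidate:
                return e
        raise KeyError(candidate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [e.to_dict() for e in self.entries],
            columns=[
                "rank",
                "candidate",
                "k",
                "ssr",
                "aicc",
                "delta_aicc",
                "feedback",
                "adaptation",
                "adaptation_readout",
                "note",
            ],
        )

    def to_dict(self) -> dict:
        return {"n": self.n, "entries": [e.to_dict() for e in self.entries], "meta": self.meta}

    @staticmethod
    def from_dict(d: dict) -> "RankingTable":
        entries = [RankingEntry(**e) for e in d["entries"]]
        return RankingTable(entries=entries, n=d.get("n"), meta=d.get("meta", {}))


def rank_candidates(
    results: list[FitResult],
    models: dict[str, ReactionModel] | None = None,
    feedback: dict[str, str] | None = None,
    adaptation_dose: float = 1.0,
) -> RankingTable:
    """Sort fitted candidates by ascending AICc.

    Ties break on smaller k, then name.  Candidates whose AICc is undefined
    (n - k - 1 < 1) are listed unranked at the bottom with an explanatory
    note rather than dropped.  When ``models`` is given, each candidate's
    perfect-adaptation status at the given dose is attached, computed from
    its best-fit parameters.
    """
    if not results:
        return RankingTable(entries=[], n=None)
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"mixed data sizes across results: {sorted(ns)}")
    n = ns.pop()

    ranked, unranked = [], []
    for r in results:
        note = ""
        try:
            a = aicc(r.ssr, r.k, n)
        except ValueError as exc:
            a = None
            note = str(exc)
        entry = RankingEntry(
            rank=None,
            candidate=r.candidate,
            k=r.k,
            ssr=r.ssr,
            aicc=a,
            delta_aicc=None,
            feedback=(feedback or {}).get(r.candidate),
            note=note,
        )
        if models is not None and r.candidate in models:
            status, readout = classify_adaptation(
                models[r.candidate], r.parameters, dose=adaptation_dose
            )
            entry.adaptation = status
            entry.adaptation_readout = readout
        (ranked if a is not None else unranked).append(entry)

    ranked.sort(key=lambda e: (e.aicc, e.k, e.candidate))
    unranked.sort(key=lambda e: (e.k, e.candidate))
    best = ranked[0].aicc if ranked else None
    for i, e in enumerate(ranked, start=1):
        e.rank = i
        e.delta_aicc = e.aicc - best
    return RankingTable(entries=ranked + unranked, n=n)


def _fmt(x, digits=3):
    if x is None:
        return ""
    return f"{x:.{digits}f}"


def render_report(table: RankingTable, out_dir: str | Path | None = None) -> dict[str, str]:
    """Render the ranking as markdown, CSV and JSON (3-decimal formatting).

    Returns ``{"md": ..., "csv": ..., "json": ...}``; writes
    ``ranking.{md,csv,json}`` under ``out_dir`` when given.
    """
    header = ["Rank", "Model", "k", "SSR", "AICc", "dAICc", "feedback", "adaptation"]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for e in table:
        lines.append(
            "| "
            + " | ".join(
                [
                    str(e.rank) if e.rank is not None else "—",
                    e.candidate,
                    str(e.k),
                    _fmt(e.ssr),
                    _fmt(e.aicc),
                    _fmt(e.delta_aicc),
                    e.feedback or "",
                    (e.adaptation or "") + (f" ({_fmt(e.adaptation_readout)})" if e.adaptation_readout is not None else ""),
                ]
            )
            + " |"
        )
    md = "\n".join(["# Model ranking", ""] + lines) + "\n"

    df = table.to_frame()
    for col in ("ssr", "aicc", "delta_aicc", "adaptation_readout"):
        df[col] = df[col].map(lambda v: None if pd.isna(v) else round(float(v), 3))
    csv = df.to_csv(index=False)
    js = json.dumps(table.to_dict(), indent=2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "ranking.md").write_text(md)
        (out / "ranking.csv").write_text(csv)
        (out / "ranking.json").write_text(js)
    return {"md": md, "csv": csv, "json": js}
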