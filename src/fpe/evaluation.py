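"""Top-k precision, precision–recall and jackknife curves, method comparison.

All measures are computed against a ground-truth essential set.  For a
ranking r and cutoff k, with hits(k) = |top-k ∩ truth|:

* precision(k) = hits(k) / k,
* recall(k)    = hits(k) / |truth|,
* jackknife    = the cumulative-hit curve k ↦ hits(k),

linked by the identity hits(k) = k·precision(k) = |truth|·recall(k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import EssentialSet

__all__ = [
    "RankedList",
    "CurvePoints",
    "precision_at_k",
    "pr_curve",
    "jackknife_curve",
    "compare_methods",
]


@dataclass
class RankedList:
    """A method's ranking, best candidate first; IDs are unique."""

    method: str
    proteins: list[str]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError(f"ranking for {self.method!r} contains duplicate IDs")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class CurvePoints:
    """Ordered (x, y) curve samples; x is non-decreasing."""

    x: np.ndarray
    y: np.ndarray
    xlabel: str
    ylabel: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("x must be non-decreasing")


def _hits(ranking: Sequence[str], truth: EssentialSet) -> np.ndarray:
    """Cumulative true-essential counts at every cutoff 1…len."""
    flags = np.fromiter((p in truth for p in ranking), dtype=int, count=len(ranking))
    return np.cumsum(flags)


def precision_at_k(ranking: RankedList | Sequence[str], truth: EssentialSet, k: int) -> float:
    """|top-k ∩ truth| / k."""
    proteins = ranking.proteins if isinstance(ranking, RankedList) else list(ranking)
    if not 1 <= k <= len(proteins):
        raise ValueError(f"k={k} out of range 1..{len(proteins)}")
    return sum(1 for p in proteins[:k] if p in truth) / k


def pr_curve(ranking: RankedList | Sequence[str], truth: EssentialSet) -> CurvePoints:
    """Precision–recall pairs over every cutoff of the ranking."""
    if len(truth) == 0:
        raise ValueError("truth set is empty")
    proteins = ranking.proteins if isinstance(ranking, RankedList) else list(ranking)
    hits = _hits(proteins, truth)
    k = np.arange(1, len(proteins) + 1)
    return CurvePoints(
        x=hits / len(truth), y=hits / k, xlabel="recall", ylabel="precision"
    )


def jackknife_curve(ranking: RankedList | Sequence[str], truth: EssentialSet) -> CurvePoints:
    """Cumulative count of true essentials as a function of the rank cutoff."""
    proteins = ranking.proteins if isinstance(ranking, RankedList) else list(ranking)
    hits = _hits(proteins, truth)
    k = np.arange(1, len(proteins) + 1)
    return CurvePoints(x=k, y=hits, xlabel="rank", ylabel="cumulative true essentials")


def average_counts(
    rankings: Iterable[RankedList],
    truth: EssentialSet,
    cutoffs: Sequence[int] = (100, 200, 300, 400, 500, 600),
    method: str = "mean",
) -> pd.DataFrame:
    """Mean true-essential counts per cutoff over repeated stochastic runs.

    Intended for averaging several seeded runs of the same method; returns a
    single-row table like :func:`compare_methods`.
    """
    table = compare_methods(rankings, truth, cutoffs=cutoffs)
    if table.empty:
        raise ValueError("no rankings supplied")
    row: dict[str, object] = {"method": method}
    for c in cutoffs:
        row[f"top{c}"] = float(table[f"top{c}"].mean())
    return pd.DataFrame([row])


def compare_methods(
    rankings: Iterable[RankedList],
    truth: EssentialSet,
    cutoffs: Sequence[int] = (100, 200, 300, 400, 500, 600),
) -> pd.DataFrame:
    """True-essential counts per method × cutoff, one row per method.

    A cutoff beyond a ranking's length reports the count at full length
    (rankings of candidate-set methods are shorter than whole-network
    rankings; each is evaluated over its own length).
    """
    rows = []
    for r in rankings:
        hits = _hits(r.proteins, truth)
        row: dict[str, object] = {"method": r.method}
        for c in cutoffs:
            row[f"top{c}"] = int(hits[min(c, len(hits)) - 1]) if len(hits) else 0
        rows.append(row)
    return pd.DataFrame(rows)
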