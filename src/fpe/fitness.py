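"""GSC: the combined essentiality measure and candidate-set fitness.

Per protein the GSC component mixes the three biological scores,

    gsc(i) = SL(i) × [α·PeC(i) + (1 − α)·PC(i)],

with α ∈ [0, 1] weighting co-expression topology (PeC) against complex
membership (PC); subcellular-location frequency (SL) gates both.  The
fitness of a candidate set is the sum of its members' components, so the
fitness-maximizing size-Q set is exactly the top Q proteins by gsc — that
closed form is what the stochastic optimizer is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .scoring import ProteinScoreTable

__all__ = [
    "GSCConfig",
    "protein_gsc",
    "gsc_values",
    "attach_gsc",
    "gsc_fitness",
    "rank_descending",
]


@dataclass
class GSCConfig:
    """Mixing weight for the GSC measure; α = 0.6 is the recommended default."""

    alpha: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


def protein_gsc(
    scores: ProteinScoreTable, protein: str, config: GSCConfig | None = None
) -> float:
    """Per-protein GSC component SL × [α·PeC + (1 − α)·PC]."""
    if config is None:
        config = GSCConfig()
    if protein not in scores:
        raise KeyError(f"protein {protein!r} has no score row")
    pec, sl, pc = scores.row(protein)
    return sl * (config.alpha * pec + (1.0 - config.alpha) * pc)


def gsc_values(
    scores: ProteinScoreTable, config: GSCConfig | None = None
) -> dict[str, float]:
    """The GSC component for every scored protein, as a flat map."""
    if config is None:
        config = GSCConfig()
    a = config.alpha
    return {
        p: scores.sl[p] * (a * scores.pec[p] + (1.0 - a) * scores.pc[p])
        for p in scores.pec
    }


def attach_gsc(scores: ProteinScoreTable, config: GSCConfig | None = None) -> ProteinScoreTable:
    """Fill the table's ``combined`` column in place and return the table."""
    scores.combined = gsc_values(scores, config)
    return scores


def gsc_fitness(
    candidate: Iterable[str],
    scores: ProteinScoreTable | Mapping[str, float],
    config: GSCConfig | None = None,
) -> float:
    """Fitness of a candidate set: Σ of members' GSC components (empty → 0).

    ``scores`` may be a full score table or a precomputed gsc map.
    """
    if isinstance(scores, ProteinScoreTable):
        return sum(protein_gsc(scores, p, config) for p in candidate)
    return sum(scores[p] for p in candidate)


def rank_descending(
    proteins: Iterable[str],
    scores: ProteinScoreTable | Mapping[str, float],
    config: GSCConfig | None = None,
) -> list[str]:
    """Order proteins by GSC component descending; ties break by ID ascending."""
    if isinstance(scores, ProteinScoreTable):
        gsc = {p: protein_gsc(scores, p, config) for p in proteins}
    else:
        gsc = {p: scores[p] for p in proteins}
    return sorted(gsc, key=lambda p: (-gsc[p], p))
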