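"""The three biological per-protein essentiality scores: PeC, SL and PC.

* **PeC** couples topology with co-expression: for each interaction the
  probability that the partners are co-clustered is the product of the edge
  clustering coefficient and the Pearson correlation of the partners'
  expression time courses, p_c(i, j) = ECC(i, j) × PCC(i, j), and
  PeC(i) = Σ_{v ∈ N_i} p_c(i, v).
* **SL** scores a protein by the frequency, among the annotation records of
  known essential proteins, of the subcellular locations the protein itself
  is annotated with: F(r) = S_r / |S| and SL(i) = Σ_{r ∈ C(i)} F(r).
* **PC** counts the known protein complexes a protein belongs to.

Missing data is neutral by construction: a protein absent from the
expression matrix contributes 0 to every p_c, a protein with no subcellular
record has SL = 0, and a protein in no complex has PC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_io import (
    ComplexCatalog,
    EssentialSet,
    ExpressionMatrix,
    ProteinNetwork,
    SubcellularData,
)
from .topology import EdgeScoreMap, edge_clustering_coefficient

__all__ = [
    "ProteinScoreTable",
    "LocationFrequencyTable",
    "pearson",
    "co_cluster_probability",
    "pec_scores",
    "location_frequencies",
    "sl_scores",
    "pc_scores",
    "build_score_table",
]


@dataclass
class ProteinScoreTable:
    """Per-protein PeC, SL and PC, plus the combined GSC component.

    ``combined`` is filled by :func:`fpe.fitness.attach_gsc`; every network
    node has a row, and proteins known only from the biological files may
    carry rows too (they can be scored but never enter a candidate set).
    """

    pec: dict[str, float]
    sl: dict[str, float]
    pc: dict[str, int]
    combined: dict[str, float] = field(default_factory=dict)

    @property
    def proteins(self) -> set[str]:
        return set(self.pec)

    def __contains__(self, pid: str) -> bool:
        return pid in self.pec

    def row(self, pid: str) -> tuple[float, float, int]:
        return self.pec[pid], self.sl[pid], self.pc[pid]

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein": sorted(self.pec),
            }
        )
        df["pec"] = df["protein"].map(self.pec)
        df["sl"] = df["protein"].map(self.sl)
        df["pc"] = df["protein"].map(self.pc)
        if self.combined:
            df["gsc"] = df["protein"].map(self.combined)
        return df


@dataclass
class LocationFrequencyTable:
    """Frequency of each location among essential proteins' records.

    F(r) = S_r / |S| where S is the sub-multiset of annotation records whose
    protein is a known essential; frequencies over all observed locations sum
    to 1.
    """

    frequencies: dict[str, float]
    n_records: int

    def __getitem__(self, location: str) -> float:
        return self.frequencies.get(location, 0.0)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length expression vectors.

    Returns 0.0 when either vector has zero variance (the correlation is
    undefined there; zero is the neutral co-expression value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def co_cluster_probability(
    ecc: EdgeScoreMap, expr: ExpressionMatrix, edge: tuple[str, str]
) -> float:
    """p_c(i, j) = ECC(i, j) × PCC(i, j); 0 if either profile is missing."""
    i, j = edge
    if i not in expr or j not in expr:
        return 0.0
    return ecc[edge] * pearson(expr[i], expr[j])


def pec_scores(
    network: ProteinNetwork,
    expr: ExpressionMatrix,
    ecc: EdgeScoreMap | None = None,
) -> dict[str, float]:
    """PeC(i) = Σ over neighbors v of p_c(i, v); isolated proteins score 0."""
    if ecc is None:
        ecc = edge_clustering_coefficient(network)
    scores: dict[str, float] = {n: 0.0 for n in network.nodes}
    for i, j in network.edge_list():
        p_c = co_cluster_probability(ecc, expr, (i, j))
        scores[i] += p_c
        scores[j] += p_c
    return scores


def location_frequencies(
    subcell: SubcellularData,
    essential: EssentialSet,
    exclude: Iterable[str] = (),
) -> LocationFrequencyTable:
    """Tabulate location frequencies over known-essential annotation records.

    ``exclude`` removes proteins from the frequency estimation (useful to
    avoid circularity when the excluded proteins are themselves being
    evaluated); by default the full known-essential list is used.
    """
    excluded = set(exclude)
    counted = essential.members - excluded
    s_records = [(p, loc) for p, loc in subcell.records if p in counted]
    if not s_records:
        raise ValueError(
            "no essential protein carries a subcellular record; "
            "every SL score would be 0"
        )
    n = len(s_records)
    freqs: dict[str, float] = {}
    for _, loc in s_records:
        freqs[loc] = freqs.get(loc, 0.0) + 1.0
    for loc in freqs:
        freqs[loc] /= n
    return LocationFrequencyTable(frequencies=freqs, n_records=n)


def sl_scores(
    subcell: SubcellularData, freq: LocationFrequencyTable
) -> dict[str, float]:
    """SL(i) = Σ over i's annotated locations of F(location).

    Only proteins present in the annotation set receive a row; any protein
    with no record has SL = 0 by the neutral-default rule (applied in
    :func:`build_score_table`).
    """
    scores: dict[str, float] = {}
    for pid, loc in subcell.records:
        scores[pid] = scores.get(pid, 0.0) + freq[loc]
    return scores


def pc_scores(catalog: ComplexCatalog) -> dict[str, int]:
    """PC(i) = number of catalog complexes containing protein i."""
    scores: dict[str, int] = {}
    for complex_members in catalog:
        for pid in complex_members:
            scores[pid] = scores.get(pid, 0) + 1
    return scores


def build_score_table(
    network: ProteinNetwork,
    expr: ExpressionMatrix,
    subcell: SubcellularData,
    catalog: ComplexCatalog,
    essential: EssentialSet,
    exclude_from_frequencies: Iterable[str] = (),
) -> ProteinScoreTable:
    """Assemble the full PeC/SL/PC table over every relevant protein.

    Rows cover the union of network nodes and proteins seen in the
    biological files; missing values take the neutral defaults (0).
    """
    freq = location_frequencies(subcell, essential, exclude=exclude_from_frequencies)
    pec = pec_scores(network, expr)
    sl = sl_scores(subcell, freq)
    pc = pc_scores(catalog)
    universe = network.nodes | set(sl) | set(pc)
    return ProteinScoreTable(
        pec={p: pec.get(p, 0.0) for p in universe},
        sl={p: sl.get(p, 0.0) for p in universe},
        pc={p: pc.get(p, 0) for p in universe},
    )
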