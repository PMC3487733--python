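"""Beta-diversity analysis: community matrices, Bray-Curtis, ANOSIM.

Analytical units (site or substrate aggregates) are rows of a unit x MOTU
abundance matrix.  Abundances may be Hellinger-transformed (square root of
relative abundance) before Bray-Curtis dissimilarity; dendrograms come from
complete-linkage agglomeration of the dissimilarities, and the separation
of predefined unit groups (e.g. forested vs non-forested sites) is tested
with rank-based ANOSIM under random relabeling permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from ._util import rng_for
from .io_formats import SpecimenRecord
from .motu import MotuPartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommunityMatrix:
    """Unit x MOTU abundance table with optional unit grouping."""

    unit_labels: tuple[str, ...]
    motu_labels: tuple[str, ...]
    counts: np.ndarray  # shape (units, motus), non-negative
    grouping: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        if len(set(self.motu_labels)) != len(self.motu_labels):
            raise ValueError("MOTU column labels must be unique")
        if self.counts.shape != (len(self.unit_labels), len(self.motu_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative abundance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.unit_labels), columns=list(self.motu_labels)
        )


def build_matrix(
    metadata: Iterable[SpecimenRecord],
    partition: MotuPartition,
    aggregate_by: str = "site",
    year: Optional[int] = None,
    method: Optional[str] = None,
) -> CommunityMatrix:
    """Aggregate specimen counts into a unit x MOTU community matrix.

    ``aggregate_by`` is "site" (rows are site_ids, grouping = site_type)
    or "substrate" (rows are substrates).  Optional ``year``/``method``
    filters restrict to the systematic survey.  Units that end up with no
    specimens are dropped with a logged warning.
    """
    if aggregate_by not in ("site", "substrate"):
        raise ValueError(f"unknown aggregation {aggregate_by!r}")
    field = "site_id" if aggregate_by == "site" else "substrate"
    rows: dict[str, dict[str, int]] = {}
    grouping: dict[str, str] = {}
    for m in metadata:
        if year is not None and m.year != year:
            continue
        if method is not None and m.method != method:
            continue
        motu = partition.assignment.get(m.specimen_id)
        if motu is None:  # specimen without a MOTU-grade sequence
            continue
        unit = getattr(m, field)
        rows.setdefault(unit, {})[motu] = rows.setdefault(unit, {}).get(motu, 0) + 1
        if aggregate_by == "site":
            grouping[unit] = m.site_type
    units = sorted(rows)
    empty = [u for u in units if not rows[u]]
    for u in empty:
        logger.warning("dropping empty unit %s", u)
        units.remove(u)
    motus = sorted({m for r in rows.values() for m in r})
    counts = np.zeros((len(units), len(motus)), dtype=int)
    motu_idx = {m: j for j, m in enumerate(motus)}
    for i, u in enumerate(units):
        for m, c in rows[u].items():
            counts[i, motu_idx[m]] = c
    return CommunityMatrix(
        tuple(units),
        tuple(motus),
        counts,
        grouping=grouping if aggregate_by == "site" else None,
    )


def hellinger(matrix: CommunityMatrix) -> CommunityMatrix:
    """Hellinger transform: y'_ij = sqrt(y_ij / rowsum_i).

    Every transformed row has unit sum of squares.  Zero rows must be
    filtered before transforming.
    """
    sums = matrix.counts.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        bad = [matrix.unit_labels[i] for i in np.flatnonzero(sums[:, 0] == 0)]
        raise ValueError(f"zero-abundance rows must be filtered first: {bad}")
    return CommunityMatrix(
        matrix.unit_labels,
        matrix.motu_labels,
        np.sqrt(matrix.counts / sums),
        matrix.grouping,
    )


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def pairwise_bray_curtis(matrix: CommunityMatrix) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis among the units of a community matrix."""
    n = len(matrix.unit_labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(matrix.counts[i], matrix.counts[j])
    return DissimilarityMatrix(matrix.unit_labels, d)


def mean_dissimilarity(dm: DissimilarityMatrix) -> float:
    """Arithmetic mean over unordered unit pairs."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 units")
    return float(dm.condensed().mean())


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree: ordered leaf labels + SciPy linkage."""

    labels: tuple[str, ...]
    linkage: np.ndarray


def complete_linkage(dm: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with cluster distance = max pairwise.

    Merge heights are non-decreasing (complete linkage is monotone).
    """
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 units to cluster")
    Z = linkage(dm.condensed(), method="complete")
    return Dendrogram(dm.labels, Z)


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def anosim(
    dm: DissimilarityMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    All n(n-1)/2 dissimilarities are ranked with mid-ranks for ties;
    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2.  The p-value counts uniformly random relabelings (within
    the observed group-size profile) whose R is at least the observed one,
    including the observed labeling in numerator and denominator, so the
    smallest attainable p is 1/(n_permutations + 1).
    """
    labels = list(dm.labels)
    n = len(labels)
    try:
        g = np.asarray([groups[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"unit {e} has no group") from e
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ranks = rankdata(dm.condensed())  # mid-ranks for ties
    M = n * (n - 1) / 2
    iu, ju = np.triu_indices(n, k=1)

    codes = np.searchsorted(uniq, g)

    def r_stat(code_vec: np.ndarray) -> float:
        within = code_vec[iu] == code_vec[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    observed = r_stat(codes)
    rng = rng_for(seed, "anosim")
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(codes)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(float(observed), float(p), n_permutations, seed)
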