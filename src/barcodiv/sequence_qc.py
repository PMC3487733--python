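"""Sequence quality grading and sequencing-success summaries.

Two quality grades are applied to recovered COI barcodes:

* **BIN grade** — length strictly greater than 500 bp and strictly fewer
  than 1% ambiguous sites; the grade required for species-proxy (BIN-like)
  assignment of a sequence on its own.
* **MOTU grade** — length of 300 bp or longer with the same <1% ambiguity
  bound; the grade required for inclusion in threshold clustering.

The boundary semantics (strict ">500", inclusive "≥300", strict "<1%")
are deliberate and tested; every BIN-grade sequence is also MOTU-grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .io_formats import BarcodeSequence, SpecimenRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Quality bounds; defaults are the standard barcode-survey settings."""

    bin_min_length: int = 500  # exclusive: length must be > this
    motu_min_length: int = 300  # inclusive: length must be >= this
    max_ambiguous_fraction: float = 0.01  # exclusive: fraction must be < this

    def __post_init__(self):
        if self.motu_min_length > self.bin_min_length:
            raise ValueError("motu_min_length must be <= bin_min_length")
        if not 0 < self.max_ambiguous_fraction < 1:
            raise ValueError("max_ambiguous_fraction must be in (0, 1)")


def passes_bin_grade(seq: BarcodeSequence, t: QcThresholds = QcThresholds()) -> bool:
    """True iff length > bin_min_length and ambiguous fraction < the bound."""
    if seq.length == 0:
        logger.warning("zero-length sequence %s fails QC", seq.specimen_id)
        return False
    return seq.length > t.bin_min_length and seq.ambiguous_fraction < t.max_ambiguous_fraction


def passes_motu_grade(seq: BarcodeSequence, t: QcThresholds = QcThresholds()) -> bool:
    """True iff length >= motu_min_length and ambiguous fraction < the bound."""
    if seq.length == 0:
        return False
    return seq.length >= t.motu_min_length and seq.ambiguous_fraction < t.max_ambiguous_fraction


@dataclass(frozen=True)
class SuccessSummary:
    """Overall and per-group sequencing-success rates."""

    attempted: int
    recovered: int
    per_group: Mapping[str, tuple[int, int]]  # group -> (attempted, recovered)

    @property
    def rate(self) -> float:
        return self.recovered / self.attempted if self.attempted else float("nan")

    def group_rate(self, group: str) -> float:
        a, r = self.per_group[group]
        return r / a if a else float("nan")

    @property
    def rate_pct(self) -> float:
        """Success rate as a percentage to 1 decimal place, as reported."""
        from ._util import round_half_up

        return round_half_up(100.0 * self.rate, 1)


def summarize_success(
    metadata: Iterable[SpecimenRecord],
    recovered_ids: set[str],
    group_by: str = "order",
) -> SuccessSummary:
    """Tally sequencing success overall and per taxonomic group.

    ``recovered_ids`` must be a subset of the metadata specimen ids; each
    metadata row counts as one attempted specimen.
    """
    metadata = list(metadata)
    ids = {m.specimen_id for m in metadata}
    stray = recovered_ids - ids
    if stray:
        raise ValueError(f"recovered ids not in metadata: {sorted(stray)[:5]}")
    per: dict[str, list[int]] = {}
    for m in metadata:
        g = getattr(m, group_by)
        per.setdefault(g, [0, 0])[0] += 1
        if m.specimen_id in recovered_ids:
            per[g][1] += 1
    return SuccessSummary(
        attempted=len(metadata),
        recovered=len(recovered_ids),
        per_group={g: (a, r) for g, (a, r) in per.items()},
    )


@dataclass(frozen=True)
class HomogeneityResult:
    statistic: float
    df: int
    p: float
    warning: str | None = None


def success_homogeneity_test(
    per_group: Mapping[str, tuple[int, int]]
) -> HomogeneityResult:
    """Pearson chi-square test of equal recovery success across groups.

    The contingency table is groups x {recovered, failed}; df = groups - 1.
    No continuity correction is applied (the standard r x c test).  A table
    with an expected cell below 1 still returns a result, with a warning
    attached.
    """
    if len(per_group) < 2:
        raise ValueError("need at least 2 groups")
    table = []
    for g, (attempted, recovered) in per_group.items():
        if attempted <= 0:
            raise ValueError(f"group {g!r} has no attempted specimens")
        if recovered > attempted:
            raise ValueError(f"group {g!r}: recovered > attempted")
        table.append([recovered, attempted - recovered])
    col_sums = [sum(row[j] for row in table) for j in (0, 1)]
    if 0 in col_sums:
        # all groups fully succeeded (or fully failed): rates are equal by
        # construction and the chi-square table is degenerate
        return HomogeneityResult(
            statistic=0.0,
            df=len(table) - 1,
            p=1.0,
            warning="degenerate table (a column is all zero); rates identical",
        )
    res = stats.chi2_contingency(table, correction=False)
    warning = None
    if (res.expected_freq < 1).any():
        warning = "expected cell count below 1; chi-square approximation unreliable"
    return HomogeneityResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        warning=warning,
    )
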