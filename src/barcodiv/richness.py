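"""Richness estimation: accumulation curves, terminal slopes, Chao1.

Specimen-based accumulation curves are built by Monte-Carlo resampling
(random permutations of the specimen order, 1000 iterations by default);
the closed-form hypergeometric rarefaction E[S(n)] is provided both as a
fast exact alternative and as the convergence oracle for the Monte-Carlo
curve.  Survey completeness is diagnosed from the slope of the mean curve
over its last `window` specimens (default 10): a terminal slope above 0.1
marks a group as very undersampled, above 0.01 as modestly undersampled,
otherwise well sampled.  Total richness is projected with Chao1 from the
singleton and doubleton counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from ._util import round_half_up, rng_for
from .io_formats import SpecimenRecord
from .motu import MotuPartition


@dataclass(frozen=True)
class AbundanceSpectrum:
    """Frequency-count summary of one group: f_k = # MOTUs seen k times."""

    group_label: str
    f: Mapping[int, int]

    @staticmethod
    def from_abundances(abundances: Iterable[int], group_label: str = "") -> "AbundanceSpectrum":
        f: dict[int, int] = {}
        for a in abundances:
            a = int(a)
            if a <= 0:
                raise ValueError("abundances must be positive")
            f[a] = f.get(a, 0) + 1
        return AbundanceSpectrum(group_label, f)

    @staticmethod
    def from_labels(motu_labels: Iterable[str], group_label: str = "") -> "AbundanceSpectrum":
        counts: dict[str, int] = {}
        for lab in motu_labels:
            counts[lab] = counts.get(lab, 0) + 1
        return AbundanceSpectrum.from_abundances(counts.values(), group_label)

    @property
    def S_obs(self) -> int:
        return sum(self.f.values())

    @property
    def N(self) -> int:
        return sum(k * v for k, v in self.f.items())

    @property
    def f1(self) -> int:
        return self.f.get(1, 0)

    @property
    def f2(self) -> int:
        return self.f.get(2, 0)

    def abundances(self) -> np.ndarray:
        return np.array([k for k, v in sorted(self.f.items()) for _ in range(v)])


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean Monte-Carlo accumulation curve for one group.

    ``mean_richness[n-1]`` is the expected number of MOTUs among the first
    n randomly ordered specimens; ``sd`` is the across-iteration spread.
    """

    group_label: str
    mean_richness: np.ndarray
    sd: np.ndarray
    n_iterations: int
    rng_seed: int

    @property
    def N(self) -> int:
        return len(self.mean_richness)


def accumulation_curve(
    specimen_motus: Sequence[str],
    iterations: int = 1000,
    seed: int = 0,
    group_label: str = "",
) -> AccumulationCurve:
    """Monte-Carlo specimen-based accumulation curve.

    Each iteration draws a fresh uniformly random permutation of the
    specimens (full Fisher-Yates reshuffle, seeded per (group, iteration)
    so curves are reproducible independently of execution order) and
    records the number of distinct MOTUs among the first n specimens.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    labels = np.asarray(specimen_motus)
    N = len(labels)
    if N < 1:
        raise ValueError("need at least one specimen")
    _, codes = np.unique(labels, return_inverse=True)
    total = np.zeros(N)
    total_sq = np.zeros(N)
    for it in range(iterations):
        rng = rng_for(seed, group_label, it)
        perm = rng.permutation(N)
        permuted = codes[perm]
        first = np.zeros(N, dtype=bool)
        _, first_idx = np.unique(permuted, return_index=True)
        first[first_idx] = True
        curve = np.cumsum(first)
        total += curve
        total_sq += curve.astype(float) ** 2
    mean = total / iterations
    var = np.maximum(total_sq / iterations - mean**2, 0.0)
    return AccumulationCurve(
        group_label=group_label,
        mean_richness=mean,
        sd=np.sqrt(var),
        n_iterations=iterations,
        rng_seed=seed,
    )


def analytic_rarefaction(spectrum: AbundanceSpectrum, n: int) -> float:
    """Exact expected richness E[S(n)] under hypergeometric subsampling.

    E[S(n)] = S_obs - sum_i C(N - N_i, n) / C(N, n) over MOTU abundances
    N_i, evaluated with log-binomials for overflow safety.
    """
    N = spectrum.N
    if not 0 <= n <= N:
        raise ValueError(f"n must be in [0, {N}], got {n}")
    if n == 0:
        return 0.0

    def log_binom(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_binom(N, n)
    missing = 0.0
    for k, count in spectrum.f.items():
        if N - k >= n:
            missing += count * math.exp(log_binom(N - k, n) - denom)
    return spectrum.S_obs - missing


class Completeness(Enum):
    WELL_SAMPLED = "well_sampled"
    MODESTLY_UNDERSAMPLED = "modestly_undersampled"
    VERY_UNDERSAMPLED = "very_undersampled"


@dataclass(frozen=True)
class CompletenessCall:
    terminal_slope: float
    window: int
    category: Completeness


def categorize_slope(slope: float) -> Completeness:
    """Strict boundaries: >0.1 very undersampled; >0.01 modest; else well."""
    if slope > 0.1:
        return Completeness.VERY_UNDERSAMPLED
    if slope > 0.01:
        return Completeness.MODESTLY_UNDERSAMPLED
    return Completeness.WELL_SAMPLED


def terminal_slope(curve: AccumulationCurve, window: int = 10) -> CompletenessCall:
    """Slope of the mean curve over its last `window` specimens.

    slope = (S(N) - S(N - window)) / window, MOTUs per specimen.  Groups
    with N <= window cannot be sloped and should be pooled into "Others".
    """
    N = curve.N
    if N <= window:
        raise ValueError(
            f"curve has only {N} specimens (window {window}); "
            "pool this group into 'Others' before slope analysis"
        )
    s = (curve.mean_richness[N - 1] - curve.mean_richness[N - 1 - window]) / window
    return CompletenessCall(float(s), window, categorize_slope(float(s)))


class ChaoVariant(Enum):
    CLASSIC = "classic"
    BIAS_CORRECTED = "bias_corrected"


@dataclass(frozen=True)
class ChaoEstimate:
    estimate: float
    se: float
    variant: ChaoVariant
    S_obs: int


def chao1(
    spectrum: AbundanceSpectrum,
    variant: ChaoVariant | str = ChaoVariant.BIAS_CORRECTED,
) -> ChaoEstimate:
    """Chao1 richness estimate with standard error.

    Point estimates::

        classic:         S_obs + f1^2 / (2 f2)            (f2 > 0)
                         S_obs + f1 (f1-1) / 2            (f2 = 0)
        bias_corrected:  S_obs + f1 (f1-1) / (2 (f2+1))

    Variances are the Chao (1987, Biometrics 43:783-791) estimator family
    as implemented in EstimateS/SpadeR::

        classic, f2>0:   f2 (r^2/2 + r^3 + r^4/4),  r = f1/f2
        bias-corrected:  f1(f1-1)/(2(f2+1)) + f1(2f1-1)^2/(4(f2+1)^2)
                         + f1^2 f2 (f1-1)^2 / (4 (f2+1)^4)
        f2=0 (either):   f1(f1-1)/2 + f1(2f1-1)^2/4 - f1^4/(4 S_hat)

    The default variant is bias-corrected, matching the behavior of the
    standard community-ecology estimator implementations.
    """
    if isinstance(variant, str):
        variant = ChaoVariant(variant)
    S, f1, f2 = spectrum.S_obs, spectrum.f1, spectrum.f2
    if S < 1:
        raise ValueError("empty spectrum")
    if f1 == 0:
        return ChaoEstimate(float(S), 0.0, variant, S)
    if variant is ChaoVariant.CLASSIC:
        est = S + (f1**2 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2)
    else:
        est = S + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 > 0:
        if variant is ChaoVariant.CLASSIC:
            r = f1 / f2
            var = f2 * (r**2 / 2 + r**3 + r**4 / 4)
        else:
            var = (
                f1 * (f1 - 1) / (2 * (f2 + 1))
                + f1 * (2 * f1 - 1) ** 2 / (4 * (f2 + 1) ** 2)
                + f1**2 * f2 * (f1 - 1) ** 2 / (4 * (f2 + 1) ** 4)
            )
    else:
        var = f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4 - f1**4 / (4 * est)
    return ChaoEstimate(float(est), math.sqrt(max(var, 0.0)), variant, S)


# ---------------------------------------------------------------------------
# Group selection and increase accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisGroup:
    """One analysis unit: a family kept separate, or a pooled 'Others'."""

    label: str
    order: str
    specimen_ids: tuple[str, ...]
    pooled: bool


def group_for_analysis(
    metadata: Iterable[SpecimenRecord],
    partition: MotuPartition,
    min_specimens: int = 100,
    min_motus: int = 10,
) -> list[AnalysisGroup]:
    """Select families for separate accumulation analysis, pool the rest.

    A family is analyzed separately iff it has more than ``min_specimens``
    specimens or more than ``min_motus`` MOTUs (strict inequalities); the
    remaining families of each order are pooled into one "Others" group.
    Only specimens present in the partition are considered.
    """
    meta = [m for m in metadata if m.specimen_id in partition.assignment]
    by_family: dict[tuple[str, str], list[str]] = {}
    order_first_seen: list[str] = []
    for m in meta:
        key = (m.order, m.family)
        by_family.setdefault(key, []).append(m.specimen_id)
        if m.order not in order_first_seen:
            order_first_seen.append(m.order)
    groups: list[AnalysisGroup] = []
    pooled: dict[str, list[str]] = {}
    for (order, family), sids in by_family.items():
        n_motus = len({partition.assignment[s] for s in sids})
        if len(sids) > min_specimens or n_motus > min_motus:
            groups.append(AnalysisGroup(family, order, tuple(sids), pooled=False))
        else:
            pooled.setdefault(order, []).extend(sids)
    for order in order_first_seen:
        if order in pooled:
            groups.append(AnalysisGroup("Others", order, tuple(pooled[order]), pooled=True))
    return groups


@dataclass(frozen=True)
class RichnessIncrease:
    additional: int
    percent: Optional[float]  # exact; None when the core set is empty

    @property
    def percent_rounded(self) -> Optional[int]:
        return None if self.percent is None else round_half_up(self.percent)


def richness_increase(core_motus: set, augmented_motus: set) -> RichnessIncrease:
    """Additional MOTUs and % increase from augmenting a core survey.

    Requires core ⊆ augmented: the augmented survey contains the core one.
    """
    if not core_motus <= augmented_motus:
        raise ValueError("core MOTU set must be a subset of the augmented set")
    additional = len(augmented_motus) - len(core_motus)
    if not core_motus:
        return RichnessIncrease(additional, None)
    return RichnessIncrease(additional, 100.0 * additional / len(core_motus))


def percent_change(new_count: float, reference_count: float) -> int:
    """(new - reference) / reference x 100, rounded half-up to an integer."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return round_half_up(100.0 * (new_count - reference_count) / reference_count)
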