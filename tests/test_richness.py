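"""Accumulation curves, rarefaction oracle, Chao1, slopes and increases."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodiv.richness import (
    AbundanceSpectrum,
    ChaoVariant,
    Completeness,
    accumulation_curve,
    analytic_rarefaction,
    categorize_slope,
    chao1,
    group_for_analysis,
    percent_change,
    richness_increase,
    terminal_slope,
)


def _labels_from_abundances(abunds):
    out = []
    for i, a in enumerate(abunds):
        out.extend([f"m{i}"] * a)
    return out


# --- accumulation curves --------------------------------------------------


def test_single_motu_curve_is_constant_one():
    c = accumulation_curve(["m"] * 12, iterations=10, seed=0)
    assert np.allclose(c.mean_richness, 1.0)


def test_all_distinct_curve_is_identity():
    c = accumulation_curve([f"m{i}" for i in range(15)], iterations=10, seed=0)
    assert np.allclose(c.mean_richness, np.arange(1, 16))


def test_curve_endpoints_and_monotonicity():
    labels = _labels_from_abundances([4, 3, 2, 1, 1, 1])
    c = accumulation_curve(labels, iterations=200, seed=1)
    assert c.mean_richness[0] == 1.0
    assert c.mean_richness[-1] == 6.0  # S_obs exactly, every iteration
    assert (np.diff(c.mean_richness) >= -1e-12).all()


def test_curve_requires_iterations_and_specimens():
    with pytest.raises(ValueError):
        accumulation_curve(["m"], iterations=0)
    with pytest.raises(ValueError):
        accumulation_curve([], iterations=10)


def test_monte_carlo_matches_enumeration_oracle():
    """Tiny case: mean over all equally likely orderings, enumerated."""
    labels = ["a", "a", "b"]
    exact = np.zeros(3)
    perms = list(itertools.permutations(range(3)))
    for p in perms:
        seen = set()
        for n, idx in enumerate(p):
            seen.add(labels[idx])
            exact[n] += len(seen)
    exact /= len(perms)
    c = accumulation_curve(labels, iterations=3000, seed=2)
    mc_se = c.sd / math.sqrt(c.n_iterations)
    assert (np.abs(c.mean_richness - exact) <= 3 * mc_se + 1e-9).all()


def test_monte_carlo_converges_to_analytic_rarefaction():
    spectrum = AbundanceSpectrum.from_abundances([4, 3, 2, 1, 1, 1])
    labels = _labels_from_abundances([4, 3, 2, 1, 1, 1])
    expected = np.array([analytic_rarefaction(spectrum, n) for n in range(1, 13)])
    gaps = {}
    for iters in (100, 1000):
        c = accumulation_curve(labels, iterations=iters, seed=3)
        mc_se = c.sd / math.sqrt(iters)
        assert (np.abs(c.mean_richness - expected) <= 3 * mc_se + 1e-9).all()
        gaps[iters] = np.abs(c.mean_richness - expected).max()
    assert gaps[1000] <= gaps[100] + 1e-9  # error shrinks with iterations


def test_curves_reproducible_for_same_seed():
    labels = _labels_from_abundances([5, 2, 1])
    a = accumulation_curve(labels, iterations=50, seed=9)
    b = accumulation_curve(labels, iterations=50, seed=9)
    assert np.array_equal(a.mean_richness, b.mean_richness)


# --- analytic rarefaction -------------------------------------------------


def test_rarefaction_boundary_values():
    spectrum = AbundanceSpectrum.from_abundances([4, 3, 2, 1, 1, 1])
    assert analytic_rarefaction(spectrum, spectrum.N) == pytest.approx(6.0)
    assert analytic_rarefaction(spectrum, 1) == pytest.approx(1.0)
    assert analytic_rarefaction(spectrum, 0) == 0.0
    with pytest.raises(ValueError):
        analytic_rarefaction(spectrum, spectrum.N + 1)


def test_rarefaction_small_case_by_hand():
    """(2,1) at n=2: 2 - C(1,2)/C(3,2) - C(2,2)/C(3,2) = 5/3."""
    spectrum = AbundanceSpectrum.from_abundances([2, 1])
    assert analytic_rarefaction(spectrum, 2) == pytest.approx(5 / 3)


# --- terminal slope -------------------------------------------------------


def test_slope_of_identity_curve_is_one():
    c = accumulation_curve([f"m{i}" for i in range(20)], iterations=5, seed=0)
    call = terminal_slope(c)
    assert call.terminal_slope == pytest.approx(1.0)
    assert call.category is Completeness.VERY_UNDERSAMPLED


def test_slope_of_saturated_curve_is_zero():
    c = accumulation_curve(["m"] * 20, iterations=5, seed=0)
    call = terminal_slope(c)
    assert call.terminal_slope == pytest.approx(0.0)
    assert call.category is Completeness.WELL_SAMPLED


@pytest.mark.parametrize(
    "slope,category",
    [
        (0.007, Completeness.WELL_SAMPLED),
        (0.200, Completeness.VERY_UNDERSAMPLED),
        (0.1, Completeness.MODESTLY_UNDERSAMPLED),  # boundary: strict > 0.1
        (0.01, Completeness.WELL_SAMPLED),  # boundary: strict > 0.01
        (0.05, Completeness.MODESTLY_UNDERSAMPLED),
    ],
)
def test_slope_categories(slope, category):
    assert categorize_slope(slope) is category


def test_small_group_instructs_pooling():
    c = accumulation_curve(["a", "b", "a"], iterations=5, seed=0)
    with pytest.raises(ValueError, match="[Oo]thers"):
        terminal_slope(c, window=10)


# --- Chao1 ----------------------------------------------------------------


def test_chao1_worked_example():
    """Abundances (1,1,2,3): classic 4 + 4/2 = 6.0; bias-corrected 4.5."""
    spectrum = AbundanceSpectrum.from_abundances([1, 1, 2, 3])
    assert chao1(spectrum, ChaoVariant.CLASSIC).estimate == pytest.approx(6.0)
    assert chao1(spectrum, ChaoVariant.BIAS_CORRECTED).estimate == pytest.approx(4.5)


def test_chao1_no_singletons_returns_s_obs():
    spectrum = AbundanceSpectrum.from_abundances([2, 3, 4])
    est = chao1(spectrum)
    assert est.estimate == 3.0
    assert est.se == 0.0


def test_chao1_against_vegan_frozen_value():
    """Abundances (1,1,1,2,2,3,5): R vegan::estimateR gives S.chao1 = 8.0
    (bias-corrected), frozen here as an independent cross-check; the
    classic variant evaluates by hand to 7 + 9/4 = 9.25."""
    spectrum = AbundanceSpectrum.from_abundances([1, 1, 1, 2, 2, 3, 5])
    assert chao1(spectrum, ChaoVariant.BIAS_CORRECTED).estimate == pytest.approx(8.0)
    est = chao1(spectrum, ChaoVariant.CLASSIC)
    assert est.estimate == pytest.approx(7 + 9 / 4)
    # classic variance f2 (r^2/2 + r^3 + r^4/4), r = f1/f2 = 3/2
    var = 2 * ((1.5**2) / 2 + 1.5**3 + (1.5**4) / 4)
    assert est.se == pytest.approx(math.sqrt(var))


@settings(max_examples=80, derandomize=True)
@given(st.lists(st.integers(1, 12), min_size=1, max_size=40))
def test_chao1_at_least_s_obs_and_bc_below_classic(abunds):
    spectrum = AbundanceSpectrum.from_abundances(abunds)
    classic = chao1(spectrum, ChaoVariant.CLASSIC)
    bc = chao1(spectrum, ChaoVariant.BIAS_CORRECTED)
    assert classic.estimate >= spectrum.S_obs
    assert bc.estimate >= spectrum.S_obs
    assert classic.se >= 0 and bc.se >= 0
    if spectrum.f2 > 0 and spectrum.f1 > 1:
        assert bc.estimate <= classic.estimate


def test_chao1_empty_spectrum_errors():
    with pytest.raises(ValueError):
        chao1(AbundanceSpectrum("", {}))


def test_chao1_recovers_true_richness_under_uniform_sampling():
    """Uniform detectability, 200 species sampled to N=1000: the mean
    estimate over seeded replicates lands within 10% of the truth."""
    rng = np.random.default_rng(2024)
    true_S = 200
    estimates = []
    for _ in range(200):
        counts = rng.multinomial(1000, np.full(true_S, 1 / true_S))
        spectrum = AbundanceSpectrum.from_abundances(counts[counts > 0])
        estimates.append(chao1(spectrum).estimate)
    assert abs(np.mean(estimates) - true_S) / true_S < 0.10


# --- grouping and increase accounting ------------------------------------


def _records(fam_specs):
    """fam_specs: list of (family, n_specimens, n_motus)."""
    from barcodiv.io_formats import SpecimenRecord
    from barcodiv.motu import MotuPartition

    recs, assign = [], {}
    i = 0
    for fam, n_spec, n_motus in fam_specs:
        for k in range(n_spec):
            sid = f"s{i}"
            recs.append(
                SpecimenRecord(sid, "Mesostigmata", fam, "", "CH01", "forested", "moss", "berlese", 2010)
            )
            assign[sid] = f"{fam}_m{k % n_motus}"
            i += 1
    return recs, MotuPartition(15, assign)


@pytest.mark.parametrize(
    "n_spec,n_motus,separate",
    [
        (93, 18, True),  # passes the MOTU criterion alone
        (99, 9, False),  # fails both -> pooled
        (101, 2, True),  # passes the specimen criterion alone
        (100, 10, False),  # boundaries are strict
    ],
)
def test_family_selection_rule(n_spec, n_motus, separate):
    recs, part = _records([("Fam", n_spec, n_motus), ("Tiny", 3, 1)])
    groups = group_for_analysis(recs, part)
    labels = {g.label for g in groups}
    if separate:
        assert "Fam" in labels
    else:
        assert "Fam" not in labels
        assert "Others" in labels


def test_pooled_others_collects_remaining_families():
    recs, part = _records([("A", 120, 5), ("B", 10, 2), ("C", 8, 3)])
    groups = {g.label: g for g in group_for_analysis(recs, part)}
    assert set(groups) == {"A", "Others"}
    assert len(groups["Others"].specimen_ids) == 18


def test_richness_increase_worked_rows():
    """899 total with 206 added -> 30%; 327 with 71 added -> 28%."""
    aug = {f"m{i}" for i in range(899)}
    core = {f"m{i}" for i in range(899 - 206)}
    inc = richness_increase(core, aug)
    assert inc.additional == 206
    assert inc.percent == pytest.approx(100 * 206 / 693)
    assert inc.percent_rounded == 30
    aug2 = {f"m{i}" for i in range(327)}
    core2 = {f"m{i}" for i in range(327 - 71)}
    assert richness_increase(core2, aug2).percent_rounded == 28


def test_richness_increase_edge_cases():
    s = {"a", "b"}
    assert richness_increase(s, s).percent_rounded == 0
    assert richness_increase(set(), {"a"}).percent is None
    with pytest.raises(ValueError):
        richness_increase({"a", "z"}, {"a"})


@pytest.mark.parametrize(
    "new,ref,expected", [(135, 76, 78), (327, 144, 127), (437, 122, 258), (50, 50, 0)]
)
def test_percent_change(new, ref, expected):
    assert percent_change(new, ref) == expected


def test_percent_change_zero_reference_errors():
    with pytest.raises(ValueError):
        percent_change(10, 0)
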