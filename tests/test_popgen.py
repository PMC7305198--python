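"""Diversity/divergence statistics vs brute-force oracles, window logic, LD pruning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camelscan import (
    GenomicWindow,
    PopulationPanel,
    balding_nichols_sites,
    dxy_window,
    fst_window,
    individual_heterozygosity,
    ld_prune,
    make_windows,
    pi_window,
    tajimas_d,
    theta_w,
    three_pop_panel,
    window_statistics,
)
from camelscan.popgen import tajima_constants, watterson_a

from helpers import make_matrix, random_matrix, two_pop_panel
from oracles import dxy_oracle, fst_oracle, pi_oracle, tajima_oracle, theta_oracle

# ---------------------------------------------------------------------------
# window grid


@pytest.mark.parametrize(
    "length,size,step,expected_starts",
    [
        (250_000, 100_000, 50_000, [0, 50_000, 100_000, 150_000]),
        (25_000, 10_000, 10_000, [0, 10_000]),
        (9_999, 10_000, 10_000, []),
    ],
)
def test_make_windows_grid(length, size, step, expected_starts):
    wins = make_windows({"s": length}, size, step)
    assert [w.start for w in wins] == expected_starts
    assert all(w.end - w.start == size for w in wins)


def test_make_windows_rejects_bad_step():
    with pytest.raises(ValueError):
        make_windows({"s": 1000}, 10, 20)


def test_window_requires_positive_span():
    with pytest.raises(ValueError):
        GenomicWindow("s", 10, 10)


# ---------------------------------------------------------------------------
# single-statistic examples


def test_pi_single_site_two_diploids():
    m = make_matrix([[1, 1]], positions=[50])
    panel = PopulationPanel.from_mapping({"D": ["s1", "s2"]})
    w = GenomicWindow("scaf_1", 0, 100)
    # alt count 2 of 4 alleles: 2*2*2/(4*3)/100
    assert pi_window(m, panel, "D", w, 100) == pytest.approx(2 * 2 * 2 / 12 / 100, abs=1e-15)


def test_pi_monomorphic_window_is_zero():
    m = make_matrix([[0, 0], [2, 2]])
    panel = PopulationPanel.from_mapping({"D": ["s1", "s2"]})
    assert pi_window(m, panel, "D", GenomicWindow("scaf_1", 0, 100)) == 0.0


def test_theta_harmonic_normalisation():
    # S=3 segregating sites, n=4 alleles, 100 bp: 3/(11/6)/100
    m = make_matrix([[0, 1], [1, 0], [1, 2], [0, 0]])
    panel = PopulationPanel.from_mapping({"D": ["s1", "s2"]})
    w = GenomicWindow("scaf_1", 0, 100)
    assert theta_w(m, panel, "D", w, 100) == pytest.approx(3 / (11 / 6) / 100, rel=1e-12)
    assert watterson_a(3) == pytest.approx(11 / 6)


def test_theta_single_diploid_identity():
    # n = 2 alleles: a_1 = 1 so theta = S / length
    m = make_matrix([[1], [1], [0]], samples=["x"])
    panel = PopulationPanel.from_mapping({"D": ["x"]})
    assert theta_w(m, panel, "D", GenomicWindow("scaf_1", 0, 50), 50) == pytest.approx(2 / 50)


def test_tajima_nan_when_no_segregating_sites():
    m = make_matrix([[0, 0]])
    panel = PopulationPanel.from_mapping({"D": ["s1", "s2"]})
    assert np.isnan(tajimas_d(m, panel, "D", GenomicWindow("scaf_1", 0, 100)))


def test_dxy_examples():
    panel = two_pop_panel(["s1", "s2", "s3", "s4"], 2)
    w = GenomicWindow("scaf_1", 0, 10)
    # fixed difference: d = 1, 10 bp accessible
    m = make_matrix([[2, 2, 0, 0]])
    assert dxy_window(m, panel, "D", "F", w, 10) == pytest.approx(0.1)
    # identical monomorphic populations
    m = make_matrix([[0, 0, 0, 0]])
    assert dxy_window(m, panel, "D", "F", w, 10) == 0.0
    # p_A = p_B = 0.5 -> d = 0.5
    m = make_matrix([[1, 1, 1, 1]])
    assert dxy_window(m, panel, "D", "F", w, 1) == pytest.approx(0.5)


def test_fst_identical_populations_clamps_to_zero():
    m = make_matrix([[1, 0, 1, 0]])
    panel = two_pop_panel(["s1", "s2", "s3", "s4"], 2)
    assert fst_window(m, panel, "D", "F", GenomicWindow("scaf_1", 0, 100)) == 0.0


def test_fst_reciprocally_fixed_site_near_one():
    geno = [[2] * 50 + [0] * 50]
    samples = [f"s{i}" for i in range(100)]
    m = make_matrix(geno, samples=samples)
    panel = two_pop_panel(samples, 50)
    assert fst_window(m, panel, "D", "F", GenomicWindow("scaf_1", 0, 100)) > 0.95


def test_fst_symmetric_in_populations(rng):
    m = random_matrix(rng, n_ind=8, n_sites=40)
    panel = two_pop_panel(m.samples, 4)
    w = GenomicWindow("scaf_1", 0, 100_000)
    assert fst_window(m, panel, "D", "F", w) == pytest.approx(
        fst_window(m, panel, "F", "D", w), abs=1e-12
    )


def test_heterozygosity_examples():
    m = make_matrix([[1, 0], [1, 2], [1, 0]], positions=[100, 200, 300])
    w = GenomicWindow("scaf_1", 0, 10_000)
    het = individual_heterozygosity(m, w, 10_000)
    assert het[0] == pytest.approx(3e-4)
    assert het[1] == 0.0


def test_heterozygosity_equals_self_pi(rng):
    # het of one individual equals pi computed on its own two alleles
    m = random_matrix(rng, n_ind=1, n_sites=30, missing_rate=0.0)
    panel = PopulationPanel.from_mapping({"D": m.samples})
    w = GenomicWindow("scaf_1", 0, 100_000)
    het = individual_heterozygosity(m, w, 100_000)[0]
    assert het == pytest.approx(pi_window(m, panel, "D", w, 100_000), abs=1e-15)


def test_dxy_self_relates_to_pi_by_sample_size_factor(rng):
    # D_XY of a population against itself is the uncorrected 2pq average;
    # pi applies the n/(n-1) correction
    m = random_matrix(rng, n_ind=6, n_sites=40, missing_rate=0.0)
    panel = PopulationPanel.from_mapping({"D": m.samples})
    w = GenomicWindow("scaf_1", 0, 100_000)
    n = 2 * 6
    dxy_self = dxy_window(m, panel, "D", "D", w, 1.0)
    pi = pi_window(m, panel, "D", w, 1.0)
    assert dxy_self * n / (n - 1) == pytest.approx(pi, rel=1e-12, abs=1e-15)


# ---------------------------------------------------------------------------
# oracle agreement on random matrices (the deep 500-matrix version lives in
# the acceptance suite; this is a fast regression check)


def test_statistics_match_bruteforce_oracles(rng):
    for _ in range(40):
        n_ind = int(rng.integers(4, 9))
        n_sites = int(rng.integers(5, 60))
        m = random_matrix(rng, n_ind=n_ind, n_sites=n_sites)
        n_a = n_ind // 2
        panel = two_pop_panel(m.samples, n_a)
        w = GenomicWindow("scaf_1", 0, 100_000)
        rows = range(n_sites)
        ia = list(range(n_a))
        ib = list(range(n_a, n_ind))
        assert pi_window(m, panel, "D", w, 1000.0) == pytest.approx(
            pi_oracle(m, ia, rows, 1000.0), abs=1e-10
        )
        assert theta_w(m, panel, "D", w, 1000.0) == pytest.approx(
            theta_oracle(m, ia, rows, 2 * n_a, 1000.0), abs=1e-10
        )
        assert dxy_window(m, panel, "D", "F", w, 1000.0) == pytest.approx(
            dxy_oracle(m, ia, ib, rows, 1000.0), abs=1e-10
        )
        got = fst_window(m, panel, "D", "F", w)
        want = fst_oracle(m, ia, ib, rows)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-10)
        got_d = tajimas_d(m, panel, "D", w)
        want_d = tajima_oracle(m, ia, rows, 2 * n_a)
        if np.isnan(want_d):
            assert np.isnan(got_d)
        else:
            assert got_d == pytest.approx(want_d, abs=1e-10)


def test_window_statistics_consistent_with_single_window_ops(rng):
    m = random_matrix(rng, n_ind=9, n_sites=80, length=30_000)
    panel = PopulationPanel.from_mapping(
        {"D": m.samples[:3], "B": m.samples[3:6], "F": m.samples[6:]}
    )
    ws = window_statistics(m, panel, size=10_000, step=5_000)
    for _, row in ws.iterrows():
        w = GenomicWindow(row["scaffold"], int(row["start"]), int(row["end"]))
        assert row["pi_D"] == pytest.approx(pi_window(m, panel, "D", w), abs=1e-12)
        assert row["dxy_B_F"] == pytest.approx(
            dxy_window(m, panel, "B", "F", w), abs=1e-12
        )
        got = fst_window(m, panel, "D", "B", w)
        if np.isnan(got):
            assert np.isnan(row["fst_D_B"])
        else:
            assert row["fst_D_B"] == pytest.approx(got, abs=1e-12)


def test_tajima_constants_textbook_n10():
    k = tajima_constants(10)
    assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
    assert k["b1"] == pytest.approx(11 / 27)


# ---------------------------------------------------------------------------
# LD pruning


def test_ld_prune_identical_columns_keeps_one():
    m = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1]], positions=[100, 200])
    kept = ld_prune(m, seed=0)
    assert len(kept) == 1


def test_ld_prune_orthogonal_columns_keeps_both():
    m = make_matrix([[0, 0, 2, 2], [0, 2, 0, 2]], positions=[100, 200])
    kept = ld_prune(m, seed=0)
    assert len(kept) == 2


def test_ld_prune_zero_variance_site_retained():
    m = make_matrix([[1, 1, 1, 1], [0, 1, 2, 1]], positions=[100, 200])
    kept = ld_prune(m, seed=0)
    assert len(kept) == 2


def test_ld_prune_postcondition_no_linked_pairs(rng):
    # oracle: exhaustive pair check on the retained set
    m = random_matrix(rng, n_ind=10, n_sites=200, missing_rate=0.1, length=2_000_000)
    kept = ld_prune(m, window_bases=1_000_000, r2_max=0.5, seed=3)
    pos = m.sites["pos"].to_numpy()
    from camelscan.popgen import _r2

    for i, j in itertools.combinations(kept, 2):
        if abs(int(pos[j]) - int(pos[i])) <= 1_000_000:
            assert _r2(m.genotypes[i], m.genotypes[j]) <= 0.5


def test_ld_prune_deterministic_under_seed(rng):
    m = random_matrix(rng, n_ind=8, n_sites=100, length=500_000)
    assert np.array_equal(ld_prune(m, seed=11), ld_prune(m, seed=11))


# ---------------------------------------------------------------------------
# Balding-Nichols calibration


def test_balding_nichols_zero_drift_limit():
    m = balding_nichols_sites([1e-6, 1e-6, 1e-6], n_sites=200, n_sample=30, seed=5)
    panel = three_pop_panel(30)
    freqs = []
    for pop in ("D", "B", "F"):
        idx = panel.indices(m.samples, pop)
        sub = m.genotypes[:, idx]
        freqs.append(sub.sum(axis=1) / (2 * sub.shape[1]))
    spread = np.abs(freqs[0] - freqs[1]) + np.abs(freqs[1] - freqs[2])
    # binomial sampling noise at n=30 dwarfs drift; check agreement loosely
    assert np.quantile(spread, 0.5) < 0.2


def test_balding_nichols_deterministic():
    a = balding_nichols_sites([0.1, 0.1, 0.1], 50, 10, seed=9)
    b = balding_nichols_sites([0.1, 0.1, 0.1], 50, 10, seed=9)
    assert np.array_equal(a.genotypes, b.genotypes)


def test_balding_nichols_rejects_invalid_f():
    with pytest.raises(ValueError):
        balding_nichols_sites([0.0, 0.1, 0.1], 10)
    with pytest.raises(ValueError):
        balding_nichols_sites([0.1, 1.0, 0.1], 10)


def test_balding_nichols_fst_recovery_single_seed():
    m = balding_nichols_sites([0.1, 0.1, 0.1], n_sites=5000, n_sample=20, seed=1)
    panel = three_pop_panel(20)
    w = GenomicWindow("bn_1", 0, m.contigs["bn_1"])
    est = fst_window(m, panel, "D", "B", w)
    assert est == pytest.approx(0.1, abs=0.03)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_watterson_a_positive_and_monotone(n):
    n = n % 500 + 2
    assert watterson_a(n) > watterson_a(n - 1)
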