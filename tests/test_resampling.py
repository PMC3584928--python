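import numpy as np
import pytest
from scipy import stats as sps

from introndyn.resampling import (
    effective_exon_number,
    positional_homogeneity,
    shared_loss_exact,
    shared_loss_mc,
    spacing_regularity,
)


# ----------------------------------------------------------------------
# shared parallel losses
# ----------------------------------------------------------------------
def test_exact_hypergeometric_values():
    assert shared_loss_exact(20, 8, 8, 6) == pytest.approx(1945 / 125970)
    assert shared_loss_exact(20, 8, 8, 0) == pytest.approx(1.0)
    assert shared_loss_exact(4, 2, 2, 2) == pytest.approx(1 / 6)


def test_mc_trivial_bounds():
    assert shared_loss_mc(20, 8, 8, 0, trials=100, seed=0).estimate == 1.0
    assert shared_loss_mc(5, 5, 5, 5, trials=100, seed=0).estimate == 1.0


def test_mc_matches_exact_within_three_se():
    exact = shared_loss_exact(20, 8, 8, 6)
    misses = 0
    for seed in range(20):
        res = shared_loss_mc(20, 8, 8, 6, trials=20_000, seed=seed)
        se = np.sqrt(exact * (1 - exact) / res.trials)
        if abs(res.estimate - exact) >= 3 * se:
            misses += 1
    assert misses <= 1  # 3-sigma misses should be very rare


def test_uniform_weights_reproduce_unweighted_draws():
    a = shared_loss_mc(20, 8, 8, 6, trials=5000, seed=3)
    b = shared_loss_mc(20, 8, 8, 6, trials=5000, weights=[2.0] * 20, seed=3)
    # equal weights shift all Gumbel keys by the same constant: same draws
    assert a.estimate == b.estimate


def test_weighting_favours_heavy_positions():
    # one extremely loss-prone subset makes large overlaps near-certain
    w = [100.0] * 8 + [0.01] * 12
    res = shared_loss_mc(20, 8, 8, 6, trials=4000, weights=w, seed=0)
    assert res.estimate > 0.9


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        shared_loss_mc(20, 25, 8, 2)
    with pytest.raises(ValueError):
        shared_loss_mc(20, 8, 8, 9)
    with pytest.raises(ValueError):
        shared_loss_mc(20, 8, 8, 2, weights=[1.0] * 5)


# ----------------------------------------------------------------------
# spacing regularity
# ----------------------------------------------------------------------
def test_ne_equal_exons_is_maximal():
    coords = np.arange(100, 1800, 100)  # 17 introns, 18 equal exons of 100
    assert effective_exon_number(coords, 1800) == pytest.approx(18.0)
    res = spacing_regularity(coords, 1800, n_sims=10_000, seed=1)
    assert res.p_value <= 0.01


def test_ne_clustered_introns_near_one():
    coords = np.linspace(1, 17, 17)  # all in the first 1% of the gene
    ne = effective_exon_number(coords, 1800)
    assert ne < 1.5
    res = spacing_regularity(coords, 1800, n_sims=2000, seed=1)
    assert res.p_value > 0.95


def test_single_midpoint_intron_gives_two_exons():
    assert effective_exon_number([900.0], 1800) == pytest.approx(2.0)


def test_ne_scale_invariance():
    coords = np.array([130.0, 400.0, 410.0, 1200.0])
    for stat in ("effective_exons", "inverse_simpson"):
        a = effective_exon_number(coords, 1800, stat)
        b = effective_exon_number(coords * 7.5, 1800 * 7.5, stat)
        assert a == pytest.approx(b)


def test_spacing_input_validation():
    with pytest.raises(ValueError, match="duplicate"):
        effective_exon_number([5.0, 5.0], 10)
    with pytest.raises(ValueError, match="inside"):
        effective_exon_number([0.0, 5.0], 10)


def test_spacing_pvalues_uniform_under_null():
    """Random insertions should give uniform p-values (KS at alpha 0.01)."""
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(200):
        coords = rng.random(17) * 1800
        ps.append(
            spacing_regularity(coords, 1800, n_sims=400,
                               seed=int(rng.integers(2**31))).p_value
        )
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
# positional homogeneity
# ----------------------------------------------------------------------
def test_one_intron_per_bin_is_perfectly_homogeneous():
    coords = np.arange(10) * 100 + 50  # one per decile of a length-1000 gene
    res = positional_homogeneity(coords, 1000, n_bins=10, n_sims=2000, seed=0)
    assert res.chi2 == 0.0
    assert res.p_value == 1.0
    assert res.bin_counts == (1,) * 10


def test_fully_clustered_introns_rejected():
    coords = np.full(20, 5.0)
    res = positional_homogeneity(coords, 1000, n_bins=10, n_sims=20_000, seed=0)
    assert res.chi2 == pytest.approx(((20 - 2) ** 2 + 9 * 4) / 2)  # 180
    assert res.p_value < 0.001


def test_homogeneity_validation():
    with pytest.raises(ValueError, match="bins"):
        positional_homogeneity([1.0], 1000, n_bins=1)
    with pytest.raises(ValueError, match="shorter"):
        positional_homogeneity([1.0], 5, n_bins=10)
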