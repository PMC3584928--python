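import numpy as np
import pytest

from introndyn import DatedTree, Event, EventHistory, branch_rates, event_times, time_profile
from introndyn.simulate import SimParams, random_dated_tree, simulate_history
from introndyn.tree import TreeError


def _losses(branch, n):
    return [Event(branch, f"p{i:02d}", "loss_all") for i in range(n)]


def test_three_losses_on_twelve_ma_branch(toy_tree):
    # toy_tree: (A:10,B:10)R:85 -- use a 12 Ma branch instead
    tree = DatedTree.from_newick("(A:12.0,B:12.0)R:5.0;")
    rates = branch_rates(EventHistory(_losses("A", 3)), tree)
    assert rates.loc["A", "loss_rate"] == pytest.approx(0.25)
    assert rates.loc["B", "loss_rate"] == 0.0
    assert rates.loc["B", "gain_rate"] == 0.0


def test_mixed_events_rates():
    tree = DatedTree.from_newick("(A:4.0,B:4.0)R:5.0;")
    events = [Event("A", "p1", "gain"), Event("A", "p2", "gain"),
              Event("A", "p3", "loss_all")]
    rates = branch_rates(EventHistory(events), tree)
    assert rates.loc["A", "gain_rate"] == pytest.approx(0.5)
    assert rates.loc["A", "loss_rate"] == pytest.approx(0.25)


def test_partial_losses_count_as_losses():
    tree = DatedTree.from_newick("(A:4.0,B:4.0)R:5.0;")
    events = [Event("A", "p1", "loss_all"), Event("A", "p2", "loss_partial")]
    rates = branch_rates(EventHistory(events), tree)
    assert rates.loc["A", "loss_rate"] == pytest.approx(0.5)
    assert rates.loc["A", "loss_partial_rate"] == pytest.approx(0.25)


def test_zero_length_branch_with_events_errors():
    tree = DatedTree.from_newick("(A:0.0,B:4.0)R:5.0;")
    with pytest.raises(TreeError, match="zero-length"):
        branch_rates(EventHistory([Event("A", "p1", "gain")]), tree)


def test_profile_single_branch_single_bin():
    tree = DatedTree.from_newick("(A:12.0);")
    prof = time_profile(EventHistory(_losses("A", 3)), tree, bin_width=12.0)
    assert prof.n_lineages[0] == 1
    assert prof.loss_rate[0] == pytest.approx(0.25)


def test_profile_averages_contemporaneous_branches():
    tree = DatedTree.from_newick("(A:10.0,B:10.0)R:0.0;")
    events = _losses("A", 2) + _losses("B", 4)  # rates 0.2 and 0.4
    prof = time_profile(EventHistory(events), tree, bin_width=10.0)
    assert prof.loss_rate[0] == pytest.approx(0.3)


def test_nonultrametric_profile_rejected():
    tree = DatedTree.from_newick("(A:10.0,B:12.0)R:0.0;")
    with pytest.raises(TreeError, match="ultrametric"):
        time_profile(EventHistory([]), tree)


def test_midquantile_event_placement():
    tree = DatedTree.from_newick("(A:12.0,B:12.0)R:5.0;")
    timed = event_times(EventHistory(_losses("A", 3)), tree)
    times = sorted(e.time for e in timed.events)
    assert times == pytest.approx([2.0, 6.0, 10.0])


@pytest.mark.parametrize("method", ["density", "midpoint"])
def test_conservation_identity_on_simulations(method):
    """sum over bins of rate x width x lineages recovers the event totals."""
    rng = np.random.default_rng(31)
    for _ in range(10):
        tree = random_dated_tree(n_tips=10, rng=rng)
        _, truth = simulate_history(tree, SimParams(seed=int(rng.integers(2**31))))
        history = truth.to_species_history()
        prof = time_profile(history, tree, bin_width=10.0, method=method)
        g_res, l_res = prof.conservation_residual()
        assert abs(g_res) < 1e-9 and abs(l_res) < 1e-9


def test_stem_burst_profile_shape():
    """Gain maximum in the oldest bin; losses dominate gains in the younger
    half once the burst is over."""
    rng = np.random.default_rng(77)
    tree = random_dated_tree(n_tips=24, rng=rng)
    _, truth = simulate_history(
        tree, SimParams(gain_rate=2e-6, loss_rate=1.5e-3, stem_burst=17, seed=5)
    )
    prof = time_profile(truth.to_species_history(), tree, bin_width=10.0)
    n = len(prof.gain_rate)
    oldest_gain_bin = int(np.argmax(prof.gain_rate))
    assert oldest_gain_bin >= n * 0.75  # the burst sits in the oldest bins
    young = slice(0, n // 2)
    assert prof.loss_rate[young].sum() > prof.gain_rate[young].sum()
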