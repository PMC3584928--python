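import itertools

import numpy as np
import pytest

from introndyn import (
    CostScheme,
    DatedTree,
    brute_force_min_cost,
    collapse_to_species,
    reconstruct_all,
    reconstruct_position,
)
from introndyn.matrix import ABSENT_ALL, PRESENT_ALL, PRESENT_SOME, STATE_UNKNOWN
from introndyn.simulate import SimParams, random_dated_tree, simulate_history
from introndyn.tree import TreeError

COSTS = CostScheme()  # gain 10, loss 1, root absent


def test_cost_scheme_validation():
    with pytest.raises(ValueError):
        CostScheme(gain=0.0)
    with pytest.raises(ValueError):
        CostScheme(gain=1.0, loss=2.0)


def test_single_gain_for_two_present_sisters(six_tip_tree):
    profile = {t: ABSENT_ALL for t in "ABCDEF"}
    profile.update(A=PRESENT_ALL, B=PRESENT_ALL)
    events, cost, n_tied = reconstruct_position(profile, six_tip_tree, COSTS)
    assert cost == pytest.approx(10.0)
    assert [(e.branch, e.kind) for e in events] == [("N4", "gain")]
    assert n_tied == 1


def test_single_gain_plus_losses_beats_two_gains():
    """Two distant present tips on an 8-tip balanced tree: a single gain
    plus 4 clade losses (cost 14) beats two gains (20) at 10:1 weights;
    the minimum is verified against exhaustive enumeration."""
    tree = DatedTree.from_newick(
        "(((A:1,B:1):1,(C:2,D:2)cd:1):1,((E:2,F:2)ef:1,(G:2,H:2):1):1)root:5;"
    )
    profile = {t: ABSENT_ALL for t in "ABCDEFGH"}
    profile.update(A=PRESENT_ALL, E=PRESENT_ALL)
    events, cost, _ = reconstruct_position(profile, tree, COSTS)
    assert cost == pytest.approx(14.0)
    assert cost == pytest.approx(brute_force_min_cost(profile, tree, COSTS))
    kinds = [e.kind for e in events]
    assert kinds.count("gain") == 1 and kinds.count("loss_all") == 4


def test_parallel_gains_win_when_losses_pile_up():
    """On a ladder tree where a single rootward gain would force 11 losses,
    two independent gains (cost 20) are preferred."""
    newick = "(A1:1,(A2:2,(A3:3,(A4:4,(A5:5,(A6:6,(A7:7,(A8:8,(A9:9,(A10:10,(A11:11,(A12:12,A13:12.5):0.5):1):1):1):1):1):1):1):1):1):1)root:5;"
    tree = DatedTree.from_newick(newick)
    profile = {f"A{i}": ABSENT_ALL for i in range(1, 14)}
    profile.update(A1=PRESENT_ALL, A13=PRESENT_ALL)
    events, cost, _ = reconstruct_position(profile, tree, COSTS)
    assert cost == pytest.approx(20.0)
    assert cost == pytest.approx(brute_force_min_cost(profile, tree, COSTS))
    assert sorted(e.branch for e in events if e.kind == "gain") == ["A1", "A13"]


def test_brute_force_trivial_profiles(six_tip_tree):
    all_absent = {t: ABSENT_ALL for t in "ABCDEF"}
    assert brute_force_min_cost(all_absent, six_tip_tree, COSTS) == 0.0
    all_present = {t: PRESENT_ALL for t in "ABCDEF"}
    assert brute_force_min_cost(all_present, six_tip_tree, COSTS) == pytest.approx(10.0)


def test_brute_force_caps_tree_size():
    rng = np.random.default_rng(0)
    big = random_dated_tree(n_tips=20, rng=rng)
    with pytest.raises(TreeError, match="internal nodes"):
        brute_force_min_cost({}, big, COSTS)


def test_dp_equals_brute_force_with_unknowns_and_partials(six_tip_tree):
    """Random profiles over the full 4-state alphabet."""
    states = [ABSENT_ALL, PRESENT_ALL, PRESENT_SOME, STATE_UNKNOWN]
    rng = np.random.default_rng(17)
    for _ in range(80):
        profile = {t: states[rng.integers(4)] for t in "ABCDEF"}
        _, cost, _ = reconstruct_position(profile, six_tip_tree, COSTS)
        assert cost == pytest.approx(
            brute_force_min_cost(profile, six_tip_tree, COSTS)
        )


def test_dollo_limit_single_gain_per_position(six_tip_tree):
    """With an overwhelming gain cost every present-anywhere pattern gets
    exactly one gain."""
    costs = CostScheme(gain=1e9, loss=1.0)
    for bits in itertools.product([ABSENT_ALL, PRESENT_ALL], repeat=6):
        if PRESENT_ALL not in bits:
            continue
        profile = dict(zip("ABCDEF", bits))
        events, _, _ = reconstruct_position(profile, six_tip_tree, costs)
        assert sum(e.kind == "gain" for e in events) == 1


def test_partial_loss_recorded_at_tip(six_tip_tree):
    profile = {t: PRESENT_ALL for t in "ABCDEF"}
    profile["C"] = PRESENT_SOME
    events, cost, _ = reconstruct_position(profile, six_tip_tree, COSTS)
    partial = [e for e in events if e.kind == "loss_partial"]
    assert [(e.branch, e.position_id) for e in partial] == [("C", "pos")]
    assert cost == pytest.approx(10.0 + 1.0)


def test_all_unknown_position_yields_no_events(six_tip_tree):
    profile = {t: STATE_UNKNOWN for t in "ABCDEF"}
    events, cost, _ = reconstruct_position(profile, six_tip_tree, COSTS)
    assert events == [] and cost == 0.0


def test_reconstruction_replays_to_observed_states():
    rng = np.random.default_rng(23)
    for _ in range(10):
        tree = random_dated_tree(n_tips=10, rng=rng)
        matrix, _ = simulate_history(
            tree, SimParams(unknown_prob=0.1, seed=int(rng.integers(2**31)))
        )
        profile = collapse_to_species(matrix)
        history = reconstruct_all(profile, tree)
        assert history.consistent_with(profile, tree)


def test_stem_burst_gains_mapped_to_stem():
    rng = np.random.default_rng(4)
    tree = random_dated_tree(n_tips=8, rng=rng)
    matrix, truth = simulate_history(
        tree, SimParams(gain_rate=0.0, loss_rate=0.0, stem_burst=17, seed=0)
    )
    history = reconstruct_all(collapse_to_species(matrix), tree)
    gains = [e for e in history.events if e.kind == "gain"]
    assert len(gains) == 17
    assert all(e.branch == tree.root.id for e in gains)
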