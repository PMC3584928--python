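import numpy as np
import pandas as pd
import pytest

from introndyn import DatedTree, IntronMatrix
from introndyn.contexts import COLUMNS, SpliceContextSet
from introndyn.matrix import IntronPosition
from introndyn.simulate import (
    SimParams,
    SpliceSimParams,
    emit_splice_contexts,
    simulate_history,
)
from introndyn.siteinfo import (
    consensus_string,
    flank_counts,
    information_profile,
    phase_distribution_test,
    small_sample_correction,
    splice_site_stats,
)


def _contexts(rows):
    return SpliceContextSet(pd.DataFrame(rows, columns=COLUMNS))


def _row(i, phase=0, present=True, up="AG", down="GT", donor="GTAAG",
         acc="TAG", length=56, age="recent"):
    return {
        "copy_id": f"c{i}", "species": "X", "position_id": f"p{i:02d}",
        "phase": phase, "age_class": age, "intron_present": present,
        "flank_up": up, "flank_down": down,
        "donor": donor if present else "", "acceptor": acc if present else "",
        "length_bp": length if present else 0,
    }


def test_flank_tally_is_exact():
    ctx = _contexts([_row(i, up="AG", down="GT") for i in range(10)])
    counts = flank_counts(ctx)["all"]
    assert counts.loc["A", "-2"] == 10
    assert counts.loc["G", "-1"] == 10
    assert counts.loc["G", "+1"] == 10
    assert counts.loc["T", "+2"] == 10
    assert counts.to_numpy().sum() == 40


def test_phase_strata_partition_records():
    rows = [_row(i, phase=i % 3) for i in range(12)]
    strata = flank_counts(_contexts(rows), "phase")
    total = sum(c.to_numpy().sum() for c in strata.values())
    assert total == 4 * 12
    assert strata["phase0"].to_numpy().sum() == 4 * 4


def test_stratum_independence():
    """Adding records to one stratum leaves the other strata unchanged."""
    base = [_row(i, phase=0) for i in range(5)]
    more = base + [_row(100 + i, phase=1, up="CC", down="CC") for i in range(5)]
    a = flank_counts(_contexts(base), "phase")
    b = flank_counts(_contexts(more), "phase")
    assert a["phase0"].equals(b["phase0"])
    assert a["phase2"].equals(b["phase2"])


def test_information_pure_column():
    counts = pd.DataFrame({"x": [0, 0, 1000, 0]}, index=list("ACGT"))
    prof = information_profile(counts, seed=0)
    assert prof.table.loc["x", "bits"] == pytest.approx(2 - small_sample_correction(1000), abs=1e-6)
    assert prof.table.loc["x", "bits"] == pytest.approx(1.998, abs=1e-3)
    lo, hi = prof.table.loc["x", ["ci_low", "ci_high"]]
    assert lo <= prof.table.loc["x", "bits"] <= hi


def test_information_flat_column_floors_at_zero():
    counts = pd.DataFrame({"x": [250, 250, 250, 250]}, index=list("ACGT"))
    prof = information_profile(counts, seed=0)
    assert prof.table.loc["x", "bits"] == 0.0


def test_information_permutation_invariance():
    rng = np.random.default_rng(2)
    c = rng.integers(1, 50, size=4)
    a = information_profile(pd.DataFrame({"x": c}, index=list("ACGT")), ci_draws=0, seed=0)
    b = information_profile(
        pd.DataFrame({"x": c[[2, 0, 3, 1]]}, index=list("ACGT")), ci_draws=0, seed=0
    )
    assert a.table.loc["x", "bits"] == pytest.approx(b.table.loc["x", "bits"])


def test_empty_column_flagged_not_raised():
    counts = pd.DataFrame({"x": [0, 0, 0, 0]}, index=list("ACGT"))
    prof = information_profile(counts, seed=0)
    assert prof.table.loc["x", "n"] == 0
    assert np.isnan(prof.table.loc["x", "bits"])


def test_uniform_flanks_carry_little_information():
    """At the study's sample size (n = 478) near-uniform flanks give mean
    column information below 0.05 bits."""
    rng = np.random.default_rng(6)
    rows = []
    bases = np.array(list("ACGT"))
    for i in range(478):
        up = "".join(bases[rng.integers(4, size=2)])
        down = "".join(bases[rng.integers(4, size=2)])
        rows.append(_row(i, up=up, down=down))
    counts = flank_counts(_contexts(rows))["all"]
    prof = information_profile(counts, seed=0)
    assert prof.bits.mean() < 0.05


def test_g_enriched_flank_recovered():
    """With G|intron|G enrichment at 0.5 the +1 G frequency estimates 0.5."""
    tree = DatedTree.from_newick("(A:1.0,B:1.0)R:5.0;")
    matrix, _ = simulate_history(
        tree, SimParams(gain_rate=0.0, loss_rate=0.0, stem_burst=500,
                        n_codons=2000, seed=3)
    )
    ctx = emit_splice_contexts(matrix, SpliceSimParams(flank_inner_g=0.5, seed=4))
    counts = flank_counts(ctx)["all"]
    n = counts["+1"].sum()
    freq = counts.loc["G", "+1"] / n
    assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)


def test_splice_site_stats_consensus_and_gc():
    rows = [_row(i, donor="GCAAG" if i < 13 else "GTAAG") for i in range(478)]
    stats = splice_site_stats(_contexts(rows), ci_draws=100, seed=0)
    assert stats.gc_donor_fraction == pytest.approx(13 / 478)
    assert stats.n_gc_donors == 13
    assert stats.donor_consensus == "GTAAG"
    assert stats.acceptor_consensus == "TAG"


def test_simulated_donor_consensus_and_g5():
    tree = DatedTree.from_newick("(A:1.0,B:1.0)R:5.0;")
    matrix, _ = simulate_history(
        tree, SimParams(gain_rate=0.0, loss_rate=0.0, stem_burst=600,
                        n_codons=2000, seed=5)
    )
    ctx = emit_splice_contexts(matrix, SpliceSimParams(g5_prob=0.9, seed=6))
    stats = splice_site_stats(ctx, ci_draws=100, seed=0)
    n = stats.n_donors
    g5_freq = ctx.present["donor"].str[4].eq("G").mean()
    assert abs(g5_freq - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)
    assert stats.donor_consensus[:2] == "GT"
    assert stats.donor_consensus[2] == "R"  # purine-biased position 3
    assert stats.acceptor_consensus == "YAG"


def _phase_matrix(counts3):
    positions, k = [], 0
    for phase, n in enumerate(counts3):
        for _ in range(n):
            positions.append(IntronPosition(f"p{k:03d}", k, phase))
            k += 1
    copies = pd.DataFrame({"species": ["A"]}, index=pd.Index(["A|c1"], name="copy_id"))
    return IntronMatrix(copies, positions, np.ones((1, k), dtype=np.int8))


def test_phase_test_uniform_counts():
    res = phase_distribution_test(_phase_matrix((10, 10, 10)))
    assert res.chi2 == 0.0 and res.p_asymptotic == pytest.approx(1.0)


def test_phase_test_moderate_excess():
    res = phase_distribution_test(_phase_matrix((18, 28, 18)))
    assert res.chi2 == pytest.approx(3.125)
    assert res.p_asymptotic > 0.05  # not significant, like a mild phase-1 excess


def test_phase_test_extreme_bias():
    res = phase_distribution_test(_phase_matrix((64, 0, 0)))
    assert res.chi2 == pytest.approx(128.0)
    assert res.p_asymptotic < 1e-6


def test_phase_test_small_sample_simulated_p():
    res = phase_distribution_test(_phase_matrix((3, 1, 0)), n_sims=4000, seed=0)
    assert res.p_exact is not None
    assert 0.0 <= res.p_exact <= 1.0


def test_consensus_ambiguity_codes():
    counts = pd.DataFrame(
        {"1": [50, 0, 50, 0], "2": [0, 55, 0, 45], "3": [25, 25, 25, 25]},
        index=list("ACGT"),
    )
    assert consensus_string(counts) == "RYN"
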