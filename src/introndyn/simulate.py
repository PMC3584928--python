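"""Forward simulation of intron gain/loss along a dated tree.

The generative model is a continuous-time birth/death of introns on a grid
of insertable *slots* (codon x phase combinations of the protein
alignment): gains arrive into empty slots at a (piecewise-constant in
time) rate per slot per Ma, present introns are lost independently at a
constant rate per Ma, and a configurable burst of gains on the stem branch
mimics the rapid invasion of the freshly transferred, intronless gene.
Gene duplications clone a copy's intron complement instantaneously, after
which copies evolve independently, so partial (some-copy) losses emerge
naturally.  Unknown stretches of sequence are emulated by masking a
contiguous run of positions in randomly chosen tip copies.

A paired generator emits splice-context sequences (exonic flanks, GT/GC
donor with a strongly conserved G at position 5, yAG acceptor, short
low-variance lognormal intron lengths) for every simulated occurrence.

Every stochastic output is a deterministic function of the seed, and the
true event log replays exactly to the emitted tip matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .contexts import COLUMNS as CONTEXT_COLUMNS, SpliceContextSet
from .events import Event, EventHistory
from .matrix import ABSENT, PRESENT, UNKNOWN, IntronMatrix, IntronPosition
from .tree import DatedTree, Node

__all__ = [
    "SimParams",
    "SpliceSimParams",
    "SlotExhaustionError",
    "TrueHistory",
    "simulate_history",
    "emit_splice_contexts",
    "random_dated_tree",
    "preset_study_scale",
    "PRESET_SIM_PARAMS",
    "PRESET_SPLICE_PARAMS",
]

RateSpec = Union[float, Sequence[tuple[float, float, float]]]


class SlotExhaustionError(RuntimeError):
    """All insertable slots are occupied; rerun with more codons (n_codons)."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the gain/loss simulator.

    gain_rate: per empty slot per Ma; either a constant or a piecewise
        schedule of (older_age, younger_age, rate) intervals (ages in Ma
        before present; outside the schedule the rate is 0).
    loss_rate: per present intron per Ma.
    n_codons: insertable codons; slots = 3 * n_codons (one per phase).
    stem_burst: forced number of gains on the stem branch (the
        post-transfer invasion; 17 matches the reconstructed ancestral
        intron count).
    duplications: (branch_id, age) gene duplications; the age must lie on
        the branch.
    copy_loss_prob: probability that each non-primary copy reaching a tip
        has been lost (dropped from the matrix).
    unknown_prob: per tip copy, probability of masking a contiguous run of
        positions as unknown sequence.
    unknown_run: (min, max) length of the masked run, in positions.
    """

    gain_rate: RateSpec = 1.4e-5
    loss_rate: float = 1.2e-3
    n_codons: int = 200
    stem_burst: int = 17
    duplications: tuple[tuple[str, float], ...] = ()
    copy_loss_prob: float = 0.0
    unknown_prob: float = 0.0
    unknown_run: tuple[int, int] = (3, 12)
    seed: Optional[int] = None

    @property
    def n_slots(self) -> int:
        return 3 * self.n_codons

    def validate(self) -> None:
        rates = [self.loss_rate]
        if isinstance(self.gain_rate, (int, float)):
            rates.append(float(self.gain_rate))
        else:
            for older, younger, r in self.gain_rate:
                if older <= younger:
                    raise ValueError("gain-rate interval must have older > younger age")
                rates.append(float(r))
        for r in rates:
            if not (math.isfinite(r) and r >= 0):
                raise ValueError("rates must be finite and non-negative")
        if not 0 <= self.copy_loss_prob <= 1 or not 0 <= self.unknown_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.stem_burst < 0 or self.n_codons <= 0:
            raise ValueError("stem_burst >= 0 and n_codons > 0 required")

    def gain_rate_at(self, age: float) -> float:
        if isinstance(self.gain_rate, (int, float)):
            return float(self.gain_rate)
        for older, younger, r in self.gain_rate:
            if younger <= age < older:
                return float(r)
        return 0.0

    def gain_breakpoints(self) -> list[float]:
        if isinstance(self.gain_rate, (int, float)):
            return []
        pts = set()
        for older, younger, _ in self.gain_rate:
            pts.update((older, younger))
        return sorted(pts)


# ----------------------------------------------------------------------
# raw event log
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RawEvent:
    kind: str  # gain | loss | duplication | copy_drop | mask
    branch: str
    age: Optional[float]
    copy: int
    slot: Optional[int] = None
    new_copy: Optional[int] = None
    mask_start: Optional[int] = None
    mask_len: Optional[int] = None


class TrueHistory:
    """Complete, timestamped event log of one simulation run."""

    def __init__(self, events: list[RawEvent], positions: list[IntronPosition],
                 slot_to_pid: dict[int, str], n_slots: int):
        self.events = events
        self.positions = positions
        self.slot_to_pid = slot_to_pid
        self.n_slots = n_slots

    @property
    def has_duplications(self) -> bool:
        return any(e.kind == "duplication" for e in self.events)

    def stem_positions(self, tree: DatedTree) -> list[str]:
        """Observable positions gained on the stem branch (the 'ancestral'
        intron set)."""
        out = []
        for e in self.events:
            if e.kind == "gain" and e.branch == tree.root.id and e.slot in self.slot_to_pid:
                out.append(self.slot_to_pid[e.slot])
        return sorted(set(out))

    def to_species_history(self) -> EventHistory:
        """Species-level event history (gain / loss_all), for comparison
        with parsimony reconstructions.  Only valid for single-copy
        simulations (no duplications); only observable positions are kept.
        """
        if self.has_duplications:
            raise ValueError(
                "species-level truth is only defined for single-copy "
                "simulations (no duplications)"
            )
        events = []
        for e in self.events:
            if e.slot not in self.slot_to_pid:
                continue
            pid = self.slot_to_pid[e.slot]
            if e.kind == "gain":
                events.append(Event(e.branch, pid, "gain", e.age))
            elif e.kind == "loss":
                events.append(Event(e.branch, pid, "loss_all", e.age))
        return EventHistory(events)

    def replay(self, tree: DatedTree) -> IntronMatrix:
        """Rebuild the tip matrix purely from the recorded events."""
        by_branch: dict[str, list[RawEvent]] = {}
        for e in self.events:
            by_branch.setdefault(e.branch, []).append(e)
        tip_copies: dict[str, list[tuple[int, np.ndarray]]] = {}

        def walk(node: Node, copies: list[tuple[int, np.ndarray]]):
            for e in by_branch.get(node.id, []):
                if e.kind == "gain":
                    for cid, state in copies:
                        if cid == e.copy:
                            state[e.slot] = True
                elif e.kind == "loss":
                    for cid, state in copies:
                        if cid == e.copy:
                            state[e.slot] = False
                elif e.kind == "duplication":
                    src = next(s for c, s in copies if c == e.copy)
                    copies.append((e.new_copy, src.copy()))
                elif e.kind == "copy_drop":
                    copies[:] = [(c, s) for c, s in copies if c != e.copy]
            if node.is_leaf():
                tip_copies[node.id] = copies
            else:
                for i, child in enumerate(node.children):
                    sub = copies if i == len(node.children) - 1 else [
                        (c, s.copy()) for c, s in copies
                    ]
                    walk(child, sub)

        root_state = np.zeros(self.n_slots, dtype=bool)
        walk(tree.root, [(0, root_state)])
        matrix = _matrix_from_tips(tree, tip_copies, self.positions, self.slot_to_pid)
        for e in self.events:
            if e.kind == "mask":
                row = matrix.copy_ids.index(f"{e.branch}|c{e.copy}")
                matrix.states[row, e.mask_start:e.mask_start + e.mask_len] = UNKNOWN
        return matrix


def _matrix_from_tips(tree, tip_copies, positions, slot_to_pid) -> IntronMatrix:
    slots = sorted(slot_to_pid, key=lambda s: slot_to_pid[s])
    copy_ids, species, rows = [], [], []
    for tip in tree.leaves():
        for cid, state in tip_copies[tip.id]:
            copy_ids.append(f"{tip.id}|c{cid}")
            species.append(tip.id)
            rows.append([PRESENT if state[s] else ABSENT for s in slots])
    copies = pd.DataFrame({"species": species},
                          index=pd.Index(copy_ids, name="copy_id"))
    arr = np.array(rows, dtype=np.int8).reshape(len(copy_ids), len(positions))
    return IntronMatrix(copies, positions, arr)


# ----------------------------------------------------------------------
# the simulator
# ----------------------------------------------------------------------
def simulate_history(
    tree: DatedTree, params: SimParams = SimParams()
) -> tuple[IntronMatrix, TrueHistory]:
    """Simulate intron gain/loss along ``tree``; return the tip matrix and
    the true event log (which replays exactly to the matrix)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_slots = params.n_slots
    if params.stem_burst > n_slots:
        raise SlotExhaustionError(
            f"stem burst of {params.stem_burst} exceeds {n_slots} slots; "
            "increase n_codons"
        )
    if params.stem_burst > 0 and tree.stem_length is None:
        raise ValueError("stem burst requested but the tree has no stem branch")

    dups: dict[str, list[float]] = {}
    for branch, age in params.duplications:
        lo, hi = tree.branch_interval(branch)
        if not (lo < age <= hi):
            raise ValueError(
                f"duplication age {age} outside branch {branch!r} interval "
                f"({lo:.3g}, {hi:.3g}]"
            )
        dups.setdefault(branch, []).append(age)
    for ages in dups.values():
        ages.sort(reverse=True)

    breakpoints = params.gain_breakpoints()
    events: list[RawEvent] = []
    copy_counter = itertools.count(1)
    tip_copies: dict[str, list[tuple[int, np.ndarray]]] = {}

    def pick_kth(state: np.ndarray, k: int, want: bool) -> int:
        return int(np.flatnonzero(state == want)[k])

    def gillespie(branch: str, t_hi: float, t_lo: float,
                  copies: list[tuple[int, np.ndarray]]) -> None:
        """Rate-driven gains/losses on one constant-rate segment."""
        t = t_hi
        loss = params.loss_rate
        g = params.gain_rate_at((t_hi + t_lo) / 2 if t_hi > t_lo else t_lo)
        while t > t_lo:
            n_present = np.array([s.sum() for _, s in copies], dtype=float)
            n_empty = n_slots - n_present
            copy_rates = g * n_empty + loss * n_present
            lam = copy_rates.sum()
            if lam <= 0:
                break
            t -= rng.exponential(1.0 / lam)
            if t <= t_lo:
                break
            i = rng.choice(len(copies), p=copy_rates / lam)
            cid, state = copies[i]
            if rng.random() < g * n_empty[i] / copy_rates[i]:
                slot = pick_kth(state, rng.integers(int(n_empty[i])), False)
                state[slot] = True
                events.append(RawEvent("gain", branch, t, cid, slot=slot))
            else:
                slot = pick_kth(state, rng.integers(int(n_present[i])), True)
                state[slot] = False
                events.append(RawEvent("loss", branch, t, cid, slot=slot))

    def evolve_branch(node: Node, t_top: float,
                      copies: list[tuple[int, np.ndarray]],
                      burst_ages: list[float]) -> None:
        """Simulate the branch above ``node`` from age t_top down to node.age."""
        t_bot = node.age
        marks = [(a, "dup") for a in dups.get(node.id, [])]
        marks += [(a, "burst") for a in burst_ages]
        marks += [(a, "rate") for a in breakpoints if t_bot < a < t_top]
        marks.sort(key=lambda m: -m[0])
        t = t_top
        for age, kind in marks:
            gillespie(node.id, t, age, copies)
            t = age
            if kind == "dup":
                i = int(rng.integers(len(copies)))
                cid, state = copies[i]
                new_cid = next(copy_counter)
                copies.append((new_cid, state.copy()))
                events.append(RawEvent("duplication", node.id, age, cid,
                                       new_copy=new_cid))
            elif kind == "burst":
                cid, state = copies[0]
                n_empty = n_slots - int(state.sum())
                if n_empty == 0:
                    raise SlotExhaustionError(
                        "all slots occupied during stem burst; increase n_codons"
                    )
                slot = pick_kth(state, rng.integers(n_empty), False)
                state[slot] = True
                events.append(RawEvent("gain", node.id, age, cid, slot=slot))
        gillespie(node.id, t, t_bot, copies)

    def walk(node: Node, copies: list[tuple[int, np.ndarray]]):
        if node.is_leaf():
            kept = []
            for j, (cid, state) in enumerate(copies):
                if j > 0 and rng.random() < params.copy_loss_prob:
                    events.append(RawEvent("copy_drop", node.id, None, cid))
                else:
                    kept.append((cid, state))
            tip_copies[node.id] = kept
            return
        for i, child in enumerate(node.children):
            sub = copies if i == len(node.children) - 1 else [
                (c, s.copy()) for c, s in copies
            ]
            evolve_branch(child, node.age, sub, [])
            walk(child, sub)

    root_copies = [(0, np.zeros(n_slots, dtype=bool))]
    stem = tree.stem_length
    if stem is not None and stem > 0:
        burst_ages = sorted(
            rng.uniform(tree.root.age, tree.root.age + stem, params.stem_burst),
            reverse=True,
        )
        evolve_branch(tree.root, tree.root.age + stem, root_copies, list(burst_ages))
    elif params.stem_burst > 0:  # zero-length stem: burst at the root instant
        cid, state = root_copies[0]
        for _ in range(params.stem_burst):
            slot = pick_kth(state, rng.integers(n_slots - int(state.sum())), False)
            state[slot] = True
            events.append(RawEvent("gain", tree.root.id, tree.root.age, cid, slot=slot))
    walk(tree.root, root_copies)

    # observable positions: present in at least one surviving tip copy
    observed = np.zeros(n_slots, dtype=bool)
    for copies in tip_copies.values():
        for _, state in copies:
            observed |= state
    slots = np.flatnonzero(observed)
    width = max(2, len(str(len(slots))))
    slot_to_pid = {int(s): f"p{i + 1:0{width}d}" for i, s in enumerate(slots)}
    positions = [
        IntronPosition(slot_to_pid[int(s)], int(s) // 3, int(s) % 3) for s in slots
    ]
    matrix = _matrix_from_tips(tree, tip_copies, positions, slot_to_pid)

    # unknown-sequence masking (contiguous runs in random tip copies)
    if params.unknown_prob > 0 and len(positions) > 0:
        lo, hi = params.unknown_run
        for row, copy_id in enumerate(matrix.copy_ids):
            if rng.random() >= params.unknown_prob:
                continue
            run = int(min(rng.integers(lo, hi + 1), len(positions)))
            start = int(rng.integers(0, len(positions) - run + 1))
            matrix.states[row, start:start + run] = UNKNOWN
            tip, cid = copy_id.rsplit("|c", 1)
            events.append(RawEvent("mask", tip, None, int(cid),
                                   mask_start=start, mask_len=run))

    history = TrueHistory(events, positions, slot_to_pid, n_slots)
    return matrix, history


# ----------------------------------------------------------------------
# splice-context emission
# ----------------------------------------------------------------------
_BASES = np.array(list("ACGT"))


def _base_probs(spec: dict[str, float]) -> np.ndarray:
    p = np.array([spec.get(b, 0.0) for b in "ACGT"], dtype=float)
    if p.sum() <= 0:
        raise ValueError("base probabilities must sum to a positive value")
    return p / p.sum()


@dataclass(frozen=True)
class SpliceSimParams:
    """Sequence model for splice contexts.

    Intron lengths are lognormal, parameterised by their mean and median in
    bp (61.6 / 56 match the study gene); donors start GT (or GC with
    probability ``gc_donor_prob``), continue with a purine-biased position
    3 and near-uniform position 4, and carry a strongly conserved G at
    position 5; acceptors are yAG.  Exonic flanks are near-uniform with a
    mild G enrichment at the two bases abutting the intron (the weak
    G|intron|G protosplice signal).
    """

    mean_bp: float = 61.6
    median_bp: float = 56.0
    gc_donor_prob: float = 0.027
    g5_prob: float = 0.80
    donor3_probs: tuple[float, float, float, float] = (0.42, 0.08, 0.42, 0.08)  # ACGT
    donor4_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    acceptor_y_probs: tuple[float, float, float, float] = (0.05, 0.45, 0.05, 0.45)
    flank_inner_g: float = 0.30
    seed: Optional[int] = None

    def __post_init__(self):
        if self.mean_bp < self.median_bp or self.median_bp <= 0:
            raise ValueError("need mean_bp >= median_bp > 0 for a lognormal model")
        for p in (self.gc_donor_prob, self.g5_prob, self.flank_inner_g):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def lognorm_mu(self) -> float:
        return math.log(self.median_bp)

    @property
    def lognorm_sigma(self) -> float:
        return math.sqrt(2.0 * math.log(self.mean_bp / self.median_bp))


def _draw_bases(rng, n: int, probs: np.ndarray) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=probs)]


def emit_splice_contexts(
    matrix: IntronMatrix,
    params: SpliceSimParams = SpliceSimParams(),
    ancestral_positions: Optional[set[str]] = None,
    include_absent: bool = False,
) -> SpliceContextSet:
    """Emit one splice-context record per present intron (plus flank-only
    records for absent states when ``include_absent``)."""
    rng = np.random.default_rng(params.seed)
    ancestral = ancestral_positions or set()
    uniform = np.full(4, 0.25)
    inner = _base_probs({"G": params.flank_inner_g,
                         "A": (1 - params.flank_inner_g) / 3,
                         "C": (1 - params.flank_inner_g) / 3,
                         "T": (1 - params.flank_inner_g) / 3})

    records = []
    pres_idx = []
    for i, copy_id in enumerate(matrix.copy_ids):
        for j, pos in enumerate(matrix.positions):
            state = matrix.states[i, j]
            if state == UNKNOWN:
                continue
            if state == ABSENT and not include_absent:
                continue
            records.append((copy_id, matrix.species.iloc[i], pos, state == PRESENT))
            if state == PRESENT:
                pres_idx.append(len(records) - 1)

    n = len(records)
    n_pres = len(pres_idx)
    flank_m2 = _draw_bases(rng, n, uniform)
    flank_m1 = _draw_bases(rng, n, inner)
    flank_p1 = _draw_bases(rng, n, inner)
    flank_p2 = _draw_bases(rng, n, uniform)
    d2 = np.where(rng.random(n_pres) < params.gc_donor_prob, "C", "T")
    d3 = _draw_bases(rng, n_pres, _base_probs(dict(zip("ACGT", params.donor3_probs))))
    d4 = _draw_bases(rng, n_pres, _base_probs(dict(zip("ACGT", params.donor4_probs))))
    g5 = params.g5_prob
    other = _base_probs({"A": 1, "C": 1, "T": 1})
    d5 = np.where(rng.random(n_pres) < g5, "G", _draw_bases(rng, n_pres, other))
    a1 = _draw_bases(rng, n_pres, _base_probs(dict(zip("ACGT", params.acceptor_y_probs))))
    lengths = np.maximum(
        np.rint(rng.lognormal(params.lognorm_mu, params.lognorm_sigma, n_pres)),
        8,
    ).astype(int)

    rows = []
    k = 0
    for idx, (copy_id, species, pos, present) in enumerate(records):
        row = {
            "copy_id": copy_id,
            "species": species,
            "position_id": pos.position_id,
            "phase": pos.phase,
            "age_class": "ancestral" if pos.position_id in ancestral else "recent",
            "intron_present": present,
            "flank_up": flank_m2[idx] + flank_m1[idx],
            "flank_down": flank_p1[idx] + flank_p2[idx],
            "donor": "",
            "acceptor": "",
            "length_bp": 0,
        }
        if present:
            row["donor"] = "G" + d2[k] + d3[k] + d4[k] + d5[k]
            row["acceptor"] = a1[k] + "AG"
            row["length_bp"] = int(lengths[k])
            k += 1
        rows.append(row)
    return SpliceContextSet(pd.DataFrame(rows, columns=CONTEXT_COLUMNS))


# ----------------------------------------------------------------------
# study-scale preset
# ----------------------------------------------------------------------
def random_dated_tree(
    n_tips: int = 24,
    root_age: float = 363.0,
    stem_length: Optional[float] = 85.0,
    min_age: float = 15.0,
    rng: Optional[np.random.Generator] = None,
    tip_prefix: str = "Sp",
) -> DatedTree:
    """Random ultrametric tree by sequential pairwise joins at sorted
    uniform ages; the final join is pinned at ``root_age``."""
    rng = rng if rng is not None else np.random.default_rng()
    if n_tips < 2:
        raise ValueError("need at least two tips")
    ages = sorted(rng.uniform(min_age, 0.92 * root_age, n_tips - 2))
    ages.append(root_age)
    groups: list[tuple[Node, float]] = [
        (Node(id=f"{tip_prefix}{i + 1:02d}", label=None), 0.0) for i in range(n_tips)
    ]
    counter = itertools.count(1)
    for age in ages:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        (a, a_age), (b, b_age) = groups[i], groups[j]
        a.length = age - a_age
        b.length = age - b_age
        parent = Node(id=f"N{next(counter)}", label=None, children=[a, b])
        a.parent = b.parent = parent
        groups[j:j + 1] = []
        groups[i] = (parent, age)
    root = groups[0][0]
    return DatedTree(root, stem_length=stem_length)


def _preset_duplications(tree: DatedTree, rng: np.random.Generator,
                         target_extra: int = 18, cap: int = 24
                         ) -> tuple[tuple[str, float], ...]:
    branches = [b for b in tree.branches(include_stem=False)]
    lengths = np.array([tree.branch_length(b) for b in branches])
    desc = {}
    for b in branches:
        node = tree[b]
        desc[b] = sum(1 for n in _subtree(node) if n.is_leaf())
    dups = []
    extra = 0
    for _ in range(60):
        if extra >= target_extra:
            break
        b = branches[int(rng.choice(len(branches), p=lengths / lengths.sum()))]
        if extra + desc[b] > cap:
            continue
        lo, hi = tree.branch_interval(b)
        age = float(rng.uniform(lo, hi))
        dups.append((b, age))
        extra += desc[b]
    return tuple(dups)


def _subtree(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


#: study-scale simulation defaults: 17-gain stem burst, slow trickle of
#: later gains, loss-dominated subsequent evolution
PRESET_SIM_PARAMS = dict(
    gain_rate=1.4e-5,
    loss_rate=1.2e-3,
    n_codons=200,
    stem_burst=17,
    copy_loss_prob=0.12,
    unknown_prob=0.08,
)
PRESET_SPLICE_PARAMS = dict(
    mean_bp=61.6,
    median_bp=56.0,
    gc_donor_prob=0.027,
    g5_prob=0.80,
)


def preset_study_scale(
    seed: Optional[int] = None, return_history: bool = False
):
    """A full study-scale synthetic dataset.

    24 species (root ~363 Ma below an 85 Ma stem), duplications yielding
    ~42 gene copies, a 17-intron stem burst and rates chosen so that the
    expected number of intron positions is ~64 and the expected number of
    occurrences ~480 (8-22 introns per copy).
    """
    rng = np.random.default_rng(seed)
    tree = random_dated_tree(rng=rng)
    dups = _preset_duplications(tree, rng)
    sim_seed = int(rng.integers(2**31 - 1))
    ctx_seed = int(rng.integers(2**31 - 1))
    params = SimParams(duplications=dups, seed=sim_seed, **PRESET_SIM_PARAMS)
    matrix, history = simulate_history(tree, params)
    contexts = emit_splice_contexts(
        matrix,
        SpliceSimParams(seed=ctx_seed, **PRESET_SPLICE_PARAMS),
        ancestral_positions=set(history.stem_positions(tree)),
        include_absent=True,
    )
    if return_history:
        return tree, matrix, contexts, history
    return tree, matrix, contexts
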