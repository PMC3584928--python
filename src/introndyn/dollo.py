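"""Weighted (Dollo-like) parsimony reconstruction of intron gains and losses.

For each intron position, the species-level presence/absence pattern is
mapped onto the dated species tree by two-state Sankoff dynamic programming
under asymmetric costs (a gain costs much more than a loss, default 10:1;
true Dollo behaviour is the limit of an infinite gain cost).  The state at
the top of the stem branch is fixed to *absent*: the gene arrived by
horizontal transfer from an intronless bacterial donor.

Species-level conventions mirror the single-event counting of paralog
losses: a species whose copies disagree (``present_some``) is treated as
present for the tree inference and one partial-loss event is recorded on
its tip branch; a loss affecting all copies of a clade is one event on one
branch.  ``unknown`` species constrain nothing.

Among equal-cost histories the tie is broken deterministically by
preferring the *present* state (gains as rootward, losses as tipward as
possible); the number of tied optimal assignments is reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

from .events import Event, EventHistory, GAIN, LOSS_ALL, LOSS_PARTIAL
from .matrix import (
    ABSENT_ALL,
    PRESENT_ALL,
    PRESENT_SOME,
    STATE_UNKNOWN,
    SpeciesProfile,
)
from .tree import DatedTree, TreeError

__all__ = ["CostScheme", "reconstruct_position", "reconstruct_all",
           "brute_force_min_cost"]

_INF = math.inf
_ABSENT, _PRESENT = 0, 1
_VALID = {ABSENT_ALL, PRESENT_ALL, PRESENT_SOME, STATE_UNKNOWN}


@dataclass(frozen=True)
class CostScheme:
    """Event costs for the weighted parsimony mapping."""

    gain: float = 10.0
    loss: float = 1.0
    root_state: str = "absent"  # state at the top of the stem branch

    def __post_init__(self):
        if not (self.gain > 0 and self.loss > 0):
            raise ValueError("gain and loss costs must be positive")
        if self.gain < self.loss:
            raise ValueError("gain cost must be >= loss cost (gains are rarer)")
        if self.root_state not in ("absent", "present"):
            raise ValueError("root_state must be 'absent' or 'present'")

    def transition(self, parent: int, child: int) -> float:
        if parent == child:
            return 0.0
        return self.gain if child == _PRESENT else self.loss

    @property
    def root_state_code(self) -> int:
        return _PRESENT if self.root_state == "present" else _ABSENT


def _tip_costs(state: str) -> tuple[float, float]:
    """(cost if absent, cost if present) for a terminal species state."""
    if state == ABSENT_ALL:
        return 0.0, _INF
    if state in (PRESENT_ALL, PRESENT_SOME):
        return _INF, 0.0
    if state == STATE_UNKNOWN:
        return 0.0, 0.0
    raise ValueError(f"invalid species state {state!r}")


def reconstruct_position(
    profile: Mapping[str, str],
    tree: DatedTree,
    costs: CostScheme = CostScheme(),
    position_id: str = "pos",
) -> tuple[list[Event], float, int]:
    """Reconstruct one intron position.

    ``profile`` maps species -> state (absent_all / present_all /
    present_some / unknown); species of the tree missing from the mapping
    are treated as unknown.  Returns ``(events, cost, n_tied_optima)``
    where cost includes one loss per recorded partial loss.
    """
    tips = set(tree.taxa)
    extra = sorted(set(profile) - tips)
    if extra:
        raise TreeError(f"profile species not in tree: {', '.join(extra)}")
    for sp, st in profile.items():
        if st not in _VALID:
            raise ValueError(f"invalid state {st!r} for species {sp!r}")

    # bottom-up: minimal subtree cost and number of optimal assignments,
    # conditioned on the node's own state
    cost: dict[str, list[float]] = {}
    ways: dict[str, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            c_abs, c_pres = _tip_costs(profile.get(node.id, STATE_UNKNOWN))
            cost[node.id] = [c_abs, c_pres]
            ways[node.id] = [1, 1]
            continue
        c = [0.0, 0.0]
        w = [1, 1]
        for s in (_ABSENT, _PRESENT):
            for child in node.children:
                options = [
                    cost[child.id][t] + costs.transition(s, t)
                    for t in (_ABSENT, _PRESENT)
                ]
                best = min(options)
                c[s] += best
                w[s] *= sum(
                    ways[child.id][t]
                    for t in (_ABSENT, _PRESENT)
                    if options[t] == best
                )
        cost[node.id] = c
        ways[node.id] = w

    # stem: the state above the root is fixed by the cost scheme
    rs = costs.root_state_code
    totals = [cost[tree.root.id][s] + costs.transition(rs, s) for s in (_ABSENT, _PRESENT)]
    total = min(totals)
    n_tied = sum(ways[tree.root.id][s] for s in (_ABSENT, _PRESENT) if totals[s] == total)

    events: list[Event] = []
    if math.isinf(total):  # unsatisfiable only if costs were infinite
        raise ValueError("no finite-cost reconstruction")

    # top-down backtrace; ties resolved toward 'present' (rootward gains,
    # tipward losses)
    assign: dict[str, int] = {}
    root_choices = [s for s in (_PRESENT, _ABSENT) if totals[s] == total]
    assign[tree.root.id] = root_choices[0]
    if assign[tree.root.id] != rs:
        kind = GAIN if assign[tree.root.id] == _PRESENT else LOSS_ALL
        events.append(Event(tree.root.id, position_id, kind))
    for node in tree.preorder():
        s = assign[node.id]
        for child in node.children:
            options = {
                t: cost[child.id][t] + costs.transition(s, t)
                for t in (_ABSENT, _PRESENT)
            }
            best = min(options.values())
            t = next(t for t in (_PRESENT, _ABSENT) if options[t] == best)
            assign[child.id] = t
            if t != s:
                kind = GAIN if t == _PRESENT else LOSS_ALL
                events.append(Event(child.id, position_id, kind))

    # partial losses: one event per species whose paralogs disagree
    n_partial = 0
    for sp in sorted(tips):
        if profile.get(sp) == PRESENT_SOME:
            events.append(Event(sp, position_id, LOSS_PARTIAL))
            n_partial += 1
    return events, total + n_partial * costs.loss, n_tied


def reconstruct_all(
    profile: SpeciesProfile,
    tree: DatedTree,
    costs: CostScheme = CostScheme(),
) -> EventHistory:
    """Reconstruct every position of a species profile; concatenate events."""
    all_events: list[Event] = []
    total = 0.0
    tied: dict[str, int] = {}
    for pid in profile.position_ids:
        column = profile.column(pid)
        events, cost, n_tied = reconstruct_position(column, tree, costs, pid)
        all_events.extend(events)
        total += cost
        tied[pid] = n_tied
    return EventHistory(all_events, cost=total, tied_optima=tied)


def brute_force_min_cost(
    profile: Mapping[str, str],
    tree: DatedTree,
    costs: CostScheme = CostScheme(),
    max_internal: int = 12,
) -> float:
    """Exhaustive minimum cost over all internal-state assignments.

    Verification oracle for :func:`reconstruct_position`; enumerates all
    2^(number of internal nodes) assignments, so trees are capped at
    ``max_internal`` internal nodes.  Applies the same species-state and
    partial-loss conventions as the dynamic program.
    """
    internal = [n for n in tree.preorder() if not n.is_leaf()]
    if len(internal) > max_internal:
        raise TreeError(
            f"{len(internal)} internal nodes exceeds brute-force cap {max_internal}"
        )
    tips = tree.leaves()
    rs = costs.root_state_code
    n_partial = sum(1 for sp in tips if profile.get(sp.id) == PRESENT_SOME)
    best = _INF
    for combo in itertools.product((_ABSENT, _PRESENT), repeat=len(internal)):
        assign = {n.id: s for n, s in zip(internal, combo)}
        c = costs.transition(rs, assign[tree.root.id])
        for node in internal:
            if node.parent is not None:
                c += costs.transition(assign[node.parent.id], assign[node.id])
        for tip in tips:
            t_abs, t_pres = _tip_costs(profile.get(tip.id, STATE_UNKNOWN))
            ps = assign[tip.parent.id] if tip.parent else rs
            c += min(t_abs + costs.transition(ps, _ABSENT),
                     t_pres + costs.transition(ps, _PRESENT))
        best = min(best, c)
    return best + n_partial * costs.loss
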