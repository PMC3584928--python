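"""Event histories: gains and losses assigned to tree branches.

An event lives on a branch, identified by the id of the node below it (the
stem branch carries the root id).  Three kinds are distinguished, following
the convention that a loss affecting every gene copy of a clade is a single
event while a loss restricted to some paralogs of a terminal species is a
*partial* loss recorded on that tip branch:

- ``gain``          intron inserted on the branch
- ``loss_all``      intron lost from all copies of the descendant clade
- ``loss_partial``  intron lost from some, but not all, copies (tips only)
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .matrix import ABSENT_ALL, PRESENT_ALL, PRESENT_SOME, STATE_UNKNOWN
from .tree import DatedTree, TreeError

__all__ = ["Event", "EventHistory", "write_event_report", "read_event_report",
           "read_events_tsv", "GAIN", "LOSS_ALL", "LOSS_PARTIAL"]

GAIN = "gain"
LOSS_ALL = "loss_all"
LOSS_PARTIAL = "loss_partial"
KINDS = (GAIN, LOSS_ALL, LOSS_PARTIAL)
LOSS_KINDS = (LOSS_ALL, LOSS_PARTIAL)


@dataclass(frozen=True)
class Event:
    branch: str
    position_id: str
    kind: str
    time: Optional[float] = None  # age in Ma, if known (simulated truth)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


class EventHistory:
    """A set of gain/loss events plus the reconstruction cost that produced it."""

    def __init__(
        self,
        events: Iterable[Event],
        cost: float = 0.0,
        tied_optima: Optional[dict[str, int]] = None,
    ):
        self.events = list(events)
        self.cost = float(cost)
        #: per position: number of distinct minimum-cost internal-state
        #: assignments (1 = the reconstruction is unique)
        self.tied_optima = dict(tied_optima or {})

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventHistory):
            return NotImplemented
        return (
            sorted(self.events, key=_event_key) == sorted(other.events, key=_event_key)
            and math.isclose(self.cost, other.cost, rel_tol=0, abs_tol=1e-9)
            and self.tied_optima == other.tied_optima
        )

    # ------------------------------------------------------------------
    def counts_by_kind(self) -> dict[str, int]:
        out = {k: 0 for k in KINDS}
        for e in self.events:
            out[e.kind] += 1
        return out

    def per_branch_counts(self, tree: DatedTree) -> pd.DataFrame:
        """Event counts per branch (rows in tree preorder)."""
        branches = tree.branches()
        counts = {b: {k: 0 for k in KINDS} for b in branches}
        for e in self.events:
            if e.branch not in counts:
                raise TreeError(f"event on branch {e.branch!r} not in tree")
            counts[e.branch][e.kind] += 1
        df = pd.DataFrame.from_dict(counts, orient="index")
        df.index.name = "branch"
        return df

    def positions(self) -> list[str]:
        return sorted({e.position_id for e in self.events})

    # ------------------------------------------------------------------
    def replay(self, tree: DatedTree, position_ids: Optional[list[str]] = None) -> pd.DataFrame:
        """Replay events from an all-absent root state down the tree.

        Returns the implied species-level terminal states (DataFrame species
        x positions, values absent_all / present_all / present_some).
        Raises if the event set is internally inconsistent (e.g. a loss on a
        branch where the intron is not present).
        """
        if position_ids is None:
            position_ids = self.positions()
        by_bp: dict[tuple[str, str], list[Event]] = {}
        for e in self.events:
            if e.branch not in tree:
                raise TreeError(f"event on branch {e.branch!r} not in tree")
            by_bp.setdefault((e.branch, e.position_id), []).append(e)
        tips = tree.taxa
        out = pd.DataFrame(ABSENT_ALL, index=sorted(tips), columns=position_ids)
        out.index.name = "species"
        for pid in position_ids:
            state: dict[str, bool] = {}
            partial: dict[str, bool] = {}
            for node in tree.preorder():
                parent_state = state[node.parent.id] if node.parent else False
                s = parent_state
                for e in by_bp.get((node.id, pid), []):
                    if e.kind == GAIN:
                        if s:
                            raise ValueError(
                                f"gain of {pid} on {node.id} but already present"
                            )
                        s = True
                    elif e.kind == LOSS_ALL:
                        if not s:
                            raise ValueError(
                                f"loss of {pid} on {node.id} but not present"
                            )
                        s = False
                    else:  # partial loss: only meaningful at a tip
                        if not node.is_leaf():
                            raise ValueError(
                                f"partial loss of {pid} on internal branch {node.id}"
                            )
                        if not s:
                            raise ValueError(
                                f"partial loss of {pid} at {node.id} but not present"
                            )
                        partial[node.id] = True
                state[node.id] = s
            for tip in tips:
                if partial.get(tip):
                    out.loc[tip, pid] = PRESENT_SOME
                elif state[tip]:
                    out.loc[tip, pid] = PRESENT_ALL
        return out

    def consistent_with(self, profile, tree: DatedTree) -> bool:
        """True if replaying the events reproduces every non-unknown
        species-level state of ``profile``."""
        replayed = self.replay(tree, list(profile.states.columns))
        obs = profile.states
        for sp in obs.index:
            for pid in obs.columns:
                want = obs.loc[sp, pid]
                if want == STATE_UNKNOWN:
                    continue
                if replayed.loc[sp, pid] != want:
                    return False
        return True


def _event_key(e: Event):
    return (e.branch, e.position_id, e.kind, -1.0 if e.time is None else e.time)


# ----------------------------------------------------------------------
# reports
# ----------------------------------------------------------------------
EVENTS_FILENAME = "events.tsv"
SUMMARY_FILENAME = "summary.json"


def write_event_report(history: EventHistory, tree: DatedTree, out_dir) -> None:
    """Write ``events.tsv`` + ``summary.json`` into ``out_dir``.

    Rows are ordered deterministically: branch preorder, then position id,
    then kind, then time.
    """
    for e in history.events:
        if e.branch not in tree:
            raise TreeError(f"event on branch {e.branch!r} not in tree")
    os.makedirs(out_dir, exist_ok=True)
    events = sorted(
        history.events,
        key=lambda e: (tree.preorder_rank(e.branch), e.position_id, e.kind,
                       -1.0 if e.time is None else e.time),
    )
    with open(os.path.join(out_dir, EVENTS_FILENAME), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["branch", "position_id", "kind", "time_ma"])
        for e in events:
            w.writerow([e.branch, e.position_id, e.kind,
                        "" if e.time is None else repr(e.time)])
    summary = {
        "n_events": len(history),
        **{f"n_{k}": v for k, v in history.counts_by_kind().items()},
        "cost": history.cost,
        "tied_optima": history.tied_optima,
    }
    with open(os.path.join(out_dir, SUMMARY_FILENAME), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_events_tsv(path) -> list[Event]:
    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["branch", "position_id", "kind", "time_ma"]:
            raise ValueError(f"{path}: unexpected event file header")
        for row in reader:
            if not row:
                continue
            t = None if row[3] == "" else float(row[3])
            events.append(Event(row[0], row[1], row[2], t))
    return events


def read_event_report(out_dir) -> EventHistory:
    events = read_events_tsv(os.path.join(out_dir, EVENTS_FILENAME))
    with open(os.path.join(out_dir, SUMMARY_FILENAME)) as fh:
        summary = json.load(fh)
    return EventHistory(events, cost=summary["cost"],
                        tied_optima=summary.get("tied_optima", {}))
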