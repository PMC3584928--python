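"""Intron presence/absence matrices and species-level profiles.

The matrix has one row per *gene copy* (a species may carry several
paralogous copies) and one column per *intron position*.  A position is a
codon index in the protein alignment (0-based) plus a phase: phase 0 means
the intron sits between codons, phases 1/2 after the first/second base of
the codon.  States are present (1), absent (0) or unknown (?); unknown
marks stretches where the underlying sequence is not available and is
excluded from every count and denominator.

TSV dialect (fixed, no auto-detection)::

    copy_id  species  p01  p02 ...
    alignment_coordinate     12   45 ...
    phase                    0    1 ...
    PchrA    P_chrysosporium 1    0 ...
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "IntronPosition",
    "IntronMatrix",
    "SpeciesProfile",
    "MatrixError",
    "read_intron_matrix",
    "write_intron_matrix",
    "collapse_to_species",
]

PRESENT, ABSENT, UNKNOWN = 1, 0, -1
_STATE_TO_SYMBOL = {PRESENT: "1", ABSENT: "0", UNKNOWN: "?"}
_SYMBOL_TO_STATE = {v: k for k, v in _STATE_TO_SYMBOL.items()}

# species-level collapsed states
ABSENT_ALL = "absent_all"
PRESENT_ALL = "present_all"
PRESENT_SOME = "present_some"
STATE_UNKNOWN = "unknown"


class MatrixError(ValueError):
    """Raised for malformed intron matrices."""


@dataclass(frozen=True, order=True)
class IntronPosition:
    """An intron insertion point: alignment codon index + phase."""

    position_id: str
    alignment_coordinate: int  # 0-based codon index in the protein alignment
    phase: int  # 0, 1 or 2

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise MatrixError(
                f"position {self.position_id!r}: phase {self.phase} not in {{0,1,2}}"
            )
        if self.alignment_coordinate < 0:
            raise MatrixError(f"position {self.position_id!r}: negative coordinate")

    @property
    def nucleotide_offset(self) -> int:
        """Insertion point on the coding sequence, in nucleotides (3c + phase)."""
        return 3 * self.alignment_coordinate + self.phase


class IntronMatrix:
    """Gene copies x intron positions with states present/absent/unknown."""

    def __init__(
        self,
        copies: pd.DataFrame,
        positions: list[IntronPosition],
        states: np.ndarray,
    ):
        """``copies``: DataFrame with index copy_id and column 'species';
        ``states``: int8 array (n_copies, n_positions) over {1, 0, -1}."""
        if list(copies.columns) != ["species"]:
            raise MatrixError("copies frame must have exactly one column: species")
        if copies.index.has_duplicates:
            raise MatrixError("duplicate copy ids")
        seen: set[tuple[int, int]] = set()
        for pos in positions:
            key = (pos.alignment_coordinate, pos.phase)
            if key in seen:
                raise MatrixError(
                    f"duplicate (coordinate, phase) pair {key} at {pos.position_id!r}"
                )
            seen.add(key)
        ids = [p.position_id for p in positions]
        if len(set(ids)) != len(ids):
            raise MatrixError("duplicate position ids")
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(copies), len(positions)):
            raise MatrixError(
                f"states shape {states.shape} does not match "
                f"{len(copies)} copies x {len(positions)} positions"
            )
        bad = ~np.isin(states, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            raise MatrixError("states must be 1 (present), 0 (absent) or -1 (unknown)")
        self.copies = copies
        self.positions = list(positions)
        self.states = states

    # ------------------------------------------------------------------
    @property
    def copy_ids(self) -> list[str]:
        return list(self.copies.index)

    @property
    def position_ids(self) -> list[str]:
        return [p.position_id for p in self.positions]

    @property
    def species(self) -> pd.Series:
        return self.copies["species"]

    @property
    def n_present(self) -> int:
        """Total number of intron occurrences (present states)."""
        return int((self.states == PRESENT).sum())

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def position(self, position_id: str) -> IntronPosition:
        for p in self.positions:
            if p.position_id == position_id:
                return p
        raise MatrixError(f"no position {position_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.copies.index, columns=self.position_ids
        )

    def validate_against_tree(self, tree) -> None:
        tips = set(tree.taxa)
        missing = sorted(set(self.species) - tips)
        if missing:
            raise MatrixError(
                f"species not found among tree tips: {', '.join(missing)}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntronMatrix):
            return NotImplemented
        return (
            self.copies.equals(other.copies)
            and self.positions == other.positions
            and np.array_equal(self.states, other.states)
        )

    # ------------------------------------------------------------------
    def write(self, path) -> None:
        write_intron_matrix(self, path)

    @classmethod
    def read(cls, path) -> "IntronMatrix":
        return read_intron_matrix(path)


def write_intron_matrix(matrix: IntronMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["copy_id", "species", *matrix.position_ids])
        w.writerow(
            ["alignment_coordinate", "", *(p.alignment_coordinate for p in matrix.positions)]
        )
        w.writerow(["phase", "", *(p.phase for p in matrix.positions)])
        for i, copy_id in enumerate(matrix.copy_ids):
            row = [copy_id, matrix.species.iloc[i]]
            row += [_STATE_TO_SYMBOL[s] for s in matrix.states[i]]
            w.writerow(row)


def read_intron_matrix(path) -> IntronMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 3:
        raise MatrixError(f"{path}: expected header + 2 metadata rows")
    header, coord_row, phase_row = rows[0], rows[1], rows[2]
    if header[:2] != ["copy_id", "species"]:
        raise MatrixError(f"{path}: header must start with copy_id<TAB>species")
    if coord_row[0] != "alignment_coordinate" or phase_row[0] != "phase":
        raise MatrixError(
            f"{path}: metadata rows must be 'alignment_coordinate' then 'phase'"
        )
    pos_ids = header[2:]
    try:
        coords = [int(x) for x in coord_row[2:]]
        phases = [int(x) for x in phase_row[2:]]
    except ValueError as e:
        raise MatrixError(f"{path}: non-integer coordinate or phase: {e}") from None
    if not (len(coords) == len(phases) == len(pos_ids)):
        raise MatrixError(f"{path}: metadata rows do not match header width")
    positions = [
        IntronPosition(pid, c, ph) for pid, c, ph in zip(pos_ids, coords, phases)
    ]
    copy_ids, species, states = [], [], []
    for row in rows[3:]:
        if not row:
            continue
        if len(row) != len(header):
            raise MatrixError(f"{path}: row for {row[0]!r} has wrong width")
        copy_ids.append(row[0])
        species.append(row[1])
        try:
            states.append([_SYMBOL_TO_STATE[s] for s in row[2:]])
        except KeyError as e:
            raise MatrixError(
                f"{path}: copy {row[0]!r}: state symbol {e.args[0]!r} not in {{1,0,?}}"
            ) from None
    copies = pd.DataFrame({"species": species}, index=pd.Index(copy_ids, name="copy_id"))
    arr = np.array(states, dtype=np.int8).reshape(len(copy_ids), len(positions))
    return IntronMatrix(copies, positions, arr)


class SpeciesProfile:
    """Species x position collapsed states.

    ``states``: DataFrame (index species, columns position ids) with values
    absent_all / present_all / present_some / unknown.  Deterministic in the
    matrix content (invariant to copy row order).
    """

    def __init__(self, states: pd.DataFrame, copy_counts: pd.Series):
        self.states = states
        self.copy_counts = copy_counts

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    @property
    def position_ids(self) -> list[str]:
        return list(self.states.columns)

    def column(self, position_id: str) -> dict[str, str]:
        return self.states[position_id].to_dict()

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpeciesProfile):
            return NotImplemented
        return self.states.equals(other.states) and self.copy_counts.equals(
            other.copy_counts
        )


def collapse_to_species(matrix: IntronMatrix) -> SpeciesProfile:
    """Collapse gene copies to one row per species.

    Per species and position, considering only non-unknown copies: present in
    all -> ``present_all``; present in none -> ``absent_all``; mixed ->
    ``present_some`` (an intron lost in some, but not all, paralogs).  If
    every copy is unknown the species state is ``unknown``.
    """
    if len(matrix.copies) == 0:
        raise MatrixError("matrix has no gene copies")
    frame = matrix.to_frame()
    sp_order = list(dict.fromkeys(matrix.species))  # first-appearance order
    out = {}
    counts = {}
    for sp in sp_order:
        block = frame.loc[(matrix.species == sp).values]
        counts[sp] = len(block)
        arr = block.to_numpy()
        known = arr != UNKNOWN
        n_known = known.sum(axis=0)
        n_present = ((arr == PRESENT) & known).sum(axis=0)
        col = np.where(
            n_known == 0,
            STATE_UNKNOWN,
            np.where(
                n_present == 0,
                ABSENT_ALL,
                np.where(n_present == n_known, PRESENT_ALL, PRESENT_SOME),
            ),
        )
        out[sp] = col
    states = pd.DataFrame.from_dict(out, orient="index", columns=matrix.position_ids)
    states.index.name = "species"
    # sort species for row-order independence
    states = states.sort_index()
    copy_counts = pd.Series(counts, name="n_copies").sort_index()
    copy_counts.index.name = "species"
    return SpeciesProfile(states, copy_counts)
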