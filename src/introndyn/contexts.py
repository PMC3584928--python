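"""Splice-context records for intron occurrences.

Each record carries, for one (gene copy, intron position) pair, the exonic
flank around the insertion point (two bases upstream, two downstream: the
-2,-1 | +1,+2 context of the protosplice model), the first five intronic
bases (donor site, canonically GTrnG), the last three intronic bases
(acceptor, canonically yAG), the intron length and an age class (ancestral
introns gained on the post-transfer stem vs. more recent gains).  Records
for copies *lacking* the intron at a position (flank only) may be included
to compare sequence information in the presence vs. absence of the intron.
"""

from __future__ import annotations

import csv
import math
import re
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = ["SpliceContextSet", "ContextError", "read_contexts", "write_contexts",
           "contexts_from_fasta"]

_NT = re.compile(r"^[ACGTN]*$")

COLUMNS = [
    "copy_id", "species", "position_id", "phase", "age_class",
    "intron_present", "flank_up", "flank_down", "donor", "acceptor", "length_bp",
]
MIN_INTRON_BP = 8  # shortest intron that can contain both splice sites


class ContextError(ValueError):
    """Raised for malformed splice-context records."""


class SpliceContextSet:
    """A validated table of splice-context records (see module docstring)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ContextError(f"missing columns: {', '.join(missing)}")
        frame = frame[COLUMNS].reset_index(drop=True)
        for i, row in frame.iterrows():
            label = f"record {i} ({row['copy_id']}/{row['position_id']})"
            for col in ("flank_up", "flank_down", "donor", "acceptor"):
                val = row[col]
                if isinstance(val, str) and val and not _NT.match(val):
                    raise ContextError(f"{label}: {col} {val!r} has non-ACGTN symbol")
            if row["phase"] not in (0, 1, 2):
                raise ContextError(f"{label}: phase {row['phase']} not in {{0,1,2}}")
            if row["intron_present"]:
                if len(row["donor"]) != 5 or len(row["acceptor"]) != 3:
                    raise ContextError(
                        f"{label}: donor must be 5 nt and acceptor 3 nt"
                    )
                if not (isinstance(row["length_bp"], (int, np.integer))
                        or (isinstance(row["length_bp"], float) and row["length_bp"].is_integer())):
                    raise ContextError(f"{label}: length_bp must be an integer")
                if row["length_bp"] < MIN_INTRON_BP:
                    raise ContextError(
                        f"{label}: intron length {row['length_bp']} < {MIN_INTRON_BP} bp"
                    )
        self.frame = frame

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpliceContextSet):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def present(self) -> pd.DataFrame:
        """Records where the intron is present (one per intron occurrence)."""
        return self.frame[self.frame["intron_present"].astype(bool)]

    @property
    def absent(self) -> pd.DataFrame:
        """Flank-only records at homologous sites lacking the intron."""
        return self.frame[~self.frame["intron_present"].astype(bool)]

    def lengths(self) -> pd.Series:
        return self.present["length_bp"].astype(int)

    def write(self, path) -> None:
        write_contexts(self, path)

    @classmethod
    def read(cls, path) -> "SpliceContextSet":
        return read_contexts(path)


def write_contexts(contexts: SpliceContextSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COLUMNS)
        for _, row in contexts.frame.iterrows():
            present = bool(row["intron_present"])
            w.writerow([
                row["copy_id"], row["species"], row["position_id"],
                int(row["phase"]), row["age_class"], "1" if present else "0",
                row["flank_up"], row["flank_down"],
                row["donor"] if present else ".",
                row["acceptor"] if present else ".",
                int(row["length_bp"]) if present else ".",
            ])


def read_contexts(path) -> SpliceContextSet:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != COLUMNS:
            raise ContextError(f"{path}: unexpected header")
        for row in reader:
            if not row:
                continue
            present = row[5] == "1"
            rows.append({
                "copy_id": row[0], "species": row[1], "position_id": row[2],
                "phase": int(row[3]), "age_class": row[4],
                "intron_present": present,
                "flank_up": row[6], "flank_down": row[7],
                "donor": row[8] if present else "",
                "acceptor": row[9] if present else "",
                "length_bp": int(row[10]) if present else 0,
            })
    return SpliceContextSet(pd.DataFrame(rows, columns=COLUMNS))


def contexts_from_fasta(
    fasta_path,
    coords_path,
    matrix=None,
    age_classes: Optional[dict[str, str]] = None,
) -> SpliceContextSet:
    """Extract splice contexts from unspliced gene sequences.

    ``coords_path`` is a TSV with columns copy_id, position_id, start, end
    (1-based inclusive nucleotide coordinates of the intron on the unspliced
    sequence).  Phase and species are taken from ``matrix`` when given
    (phase 0 and species == copy_id otherwise).  ``age_classes`` maps
    position_id -> ancestral/recent (default: recent).
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    coords = pd.read_csv(coords_path, sep="\t", dtype={"copy_id": str, "position_id": str})
    for col in ("copy_id", "position_id", "start", "end"):
        if col not in coords.columns:
            raise ContextError(f"{coords_path}: missing column {col!r}")
    phases = {}
    species = {}
    if matrix is not None:
        phases = {p.position_id: p.phase for p in matrix.positions}
        species = matrix.species.to_dict()
    rows = []
    for _, rec in coords.iterrows():
        copy_id, pid = rec["copy_id"], rec["position_id"]
        start, end = int(rec["start"]), int(rec["end"])
        if copy_id not in seqs:
            raise ContextError(f"copy {copy_id!r} not in FASTA")
        seq = seqs[copy_id]
        if not (1 <= start <= end <= len(seq)):
            raise ContextError(f"{copy_id}/{pid}: coordinates outside sequence")
        intron = seq[start - 1:end]
        up = seq[max(0, start - 3):start - 1].rjust(2, "N")
        down = seq[end:end + 2].ljust(2, "N")
        rows.append({
            "copy_id": copy_id,
            "species": species.get(copy_id, copy_id),
            "position_id": pid,
            "phase": phases.get(pid, 0),
            "age_class": (age_classes or {}).get(pid, "recent"),
            "intron_present": True,
            "flank_up": up,
            "flank_down": down,
            "donor": intron[:5],
            "acceptor": intron[-3:],
            "length_bp": len(intron),
        })
    return SpliceContextSet(pd.DataFrame(rows, columns=COLUMNS))
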