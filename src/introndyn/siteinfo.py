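"""Information-content statistics of exonic flanks and splice sites.

Information per alignment column is the sequence-logo quantity

    R(n) = 2 - H(f) - e(n),   e(n) = 3 / (2 ln(2) n)

in bits for the 4-letter alphabet, where H is the base-2 Shannon entropy of
the observed base frequencies and e(n) the standard small-sample
correction; values are floored at 0.  Uncertainty is summarized by a
Bayesian 95% credible interval: base frequencies are resampled from a
Dirichlet posterior (symmetric prior, default Dirichlet(1)), the
information recomputed per draw, and the 2.5/97.5 percentiles taken
(widened, if needed, to contain the point estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contexts import SpliceContextSet, ContextError
from .matrix import IntronMatrix

__all__ = [
    "InformationProfile",
    "SpliceSiteStats",
    "PhaseTestResult",
    "flank_counts",
    "splice_site_counts",
    "information_profile",
    "splice_site_stats",
    "phase_distribution_test",
    "consensus_string",
]

BASES = ("A", "C", "G", "T")
FLANK_COLUMNS = ("-2", "-1", "+1", "+2")
DONOR_COLUMNS = ("d1", "d2", "d3", "d4", "d5")
ACCEPTOR_COLUMNS = ("a1", "a2", "a3")
LN2 = float(np.log(2.0))

#: IUPAC code for each subset of {A, C, G, T}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def _tally(strings: pd.Series, columns: tuple[str, ...], what: str) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(BASES), columns=list(columns), dtype=int)
    for rec_id, s in strings.items():
        if len(s) != len(columns):
            raise ContextError(f"{what} of record {rec_id} has wrong length: {s!r}")
        for col, base in zip(columns, s):
            if base == "N":
                continue  # undetermined base: excluded from the tally
            if base not in BASES:
                raise ContextError(
                    f"{what} of record {rec_id}: symbol {base!r} not in ACGTN"
                )
            counts.loc[base, col] += 1
    return counts


def _strata(frame: pd.DataFrame, stratum: str) -> dict[str, pd.DataFrame]:
    if stratum == "all":
        return {"all": frame}
    if stratum == "phase":
        return {f"phase{p}": frame[frame["phase"] == p] for p in (0, 1, 2)}
    if stratum == "age_class":
        return {a: frame[frame["age_class"] == a] for a in ("ancestral", "recent")}
    if stratum == "presence":
        return {
            "present": frame[frame["intron_present"].astype(bool)],
            "absent": frame[~frame["intron_present"].astype(bool)],
        }
    raise ValueError(
        f"unknown stratum {stratum!r}; use all/phase/age_class/presence"
    )


def flank_counts(
    contexts: SpliceContextSet, stratum: str = "all"
) -> dict[str, pd.DataFrame]:
    """Base-count tables (4 x 4: columns -2, -1, +1, +2) of the exonic
    flanks, per stratum.  Strata with no records are returned with all-zero
    counts.  The -2/-1 bases come from the exon upstream of the insertion
    point, +1/+2 from the exon downstream; ``stratum="presence"`` contrasts
    copies carrying the intron with copies lacking it at the homologous
    coordinate (flank-only records)."""
    out = {}
    for name, block in _strata(contexts.frame, stratum).items():
        flanks = block["flank_up"] + block["flank_down"]
        out[name] = _tally(flanks, FLANK_COLUMNS, "flank")
    return out


def splice_site_counts(
    contexts: SpliceContextSet, stratum: str = "all"
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """(donor 4x5, acceptor 4x3) base-count tables per stratum, from
    intron-bearing records only."""
    present = contexts.frame[contexts.frame["intron_present"].astype(bool)]
    out = {}
    for name, block in _strata(present, stratum).items():
        donor = _tally(block["donor"], DONOR_COLUMNS, "donor")
        acceptor = _tally(block["acceptor"], ACCEPTOR_COLUMNS, "acceptor")
        out[name] = (donor, acceptor)
    return out


# ----------------------------------------------------------------------
@dataclass
class InformationProfile:
    """Per-column frequencies, information (bits) and credible intervals."""

    table: pd.DataFrame  # columns: n, bits, ci_low, ci_high, freq_A..freq_T

    @property
    def bits(self) -> pd.Series:
        return self.table["bits"]

    def __getitem__(self, column: str) -> pd.Series:
        return self.table.loc[column]


def _bits_from_freq(freq: np.ndarray, correction: float = 0.0) -> np.ndarray:
    """2 - H(freq) - correction, floored at 0; freq along the last axis."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    return np.maximum(2.0 + plogp.sum(axis=-1) - correction, 0.0)


def small_sample_correction(n: int) -> float:
    return 3.0 / (2.0 * LN2 * n)


def information_profile(
    counts: pd.DataFrame,
    correction: bool = True,
    ci_draws: int = 2000,
    seed: Optional[int] = None,
    prior: float = 1.0,
) -> InformationProfile:
    """Information content per column of a 4 x k base-count table.

    Columns with n = 0 are flagged with NaN bits rather than raising.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for col in counts.columns:
        c = counts[col].reindex(list(BASES)).to_numpy(dtype=float)
        n = int(c.sum())
        if n == 0:
            rows.append({"column": col, "n": 0, "bits": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         **{f"freq_{b}": np.nan for b in BASES}})
            continue
        freq = c / n
        e_n = small_sample_correction(n) if correction else 0.0
        bits = float(_bits_from_freq(freq, e_n))
        if ci_draws > 0:
            draws = rng.dirichlet(c + prior, size=ci_draws)
            bits_draws = _bits_from_freq(draws, e_n)
            lo, hi = np.percentile(bits_draws, [2.5, 97.5])
            lo, hi = min(float(lo), bits), max(float(hi), bits)
        else:
            lo = hi = bits
        rows.append({"column": col, "n": n, "bits": bits,
                     "ci_low": lo, "ci_high": hi,
                     **{f"freq_{b}": freq[i] for i, b in enumerate(BASES)}})
    table = pd.DataFrame(rows).set_index("column")
    return InformationProfile(table)


# ----------------------------------------------------------------------
def consensus_string(counts: pd.DataFrame, ambiguity_threshold: float = 0.25) -> str:
    """IUPAC consensus: per column, the code for every base whose frequency
    reaches the threshold (majority base if none does)."""
    out = []
    for col in counts.columns:
        c = counts[col].reindex(list(BASES)).to_numpy(dtype=float)
        n = c.sum()
        if n == 0:
            out.append("N")
            continue
        members = frozenset(b for b, x in zip(BASES, c / n) if x >= ambiguity_threshold)
        if not members:
            members = frozenset([BASES[int(np.argmax(c))]])
        out.append(_IUPAC[members])
    return "".join(out)


@dataclass
class SpliceSiteStats:
    donor_consensus: str
    acceptor_consensus: str
    gc_donor_fraction: float
    n_donors: int
    n_gc_donors: int
    donor_profile: InformationProfile
    acceptor_profile: InformationProfile


def splice_site_stats(
    contexts: SpliceContextSet,
    ci_draws: int = 2000,
    seed: Optional[int] = None,
) -> SpliceSiteStats:
    """Consensus, per-position information and GC-donor fraction of the 5'
    pentamer and 3' trimer splice sites."""
    donor, acceptor = splice_site_counts(contexts, "all")["all"]
    present = contexts.present
    n = len(present)
    n_gc = int(present["donor"].str.startswith("GC").sum())
    bad = present[~present["donor"].str.match(r"^G[TC]")]
    if len(bad):
        raise ContextError(
            f"{len(bad)} donor site(s) do not start with GT or GC, e.g. "
            f"{bad['donor'].iloc[0]!r}"
        )
    return SpliceSiteStats(
        donor_consensus=consensus_string(donor),
        acceptor_consensus=consensus_string(acceptor),
        gc_donor_fraction=n_gc / n if n else float("nan"),
        n_donors=n,
        n_gc_donors=n_gc,
        donor_profile=information_profile(donor, ci_draws=ci_draws, seed=seed),
        acceptor_profile=information_profile(acceptor, ci_draws=ci_draws, seed=seed),
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PhaseTestResult:
    counts: tuple[int, int, int]
    chi2: float
    p_asymptotic: float  # chi-square, df = 2
    p_exact: Optional[float]  # multinomial simulation, when expected counts < 5
    n_sims: int


def phase_distribution_test(
    matrix: IntronMatrix, n_sims: int = 10_000, seed: Optional[int] = None
) -> PhaseTestResult:
    """Goodness of fit of the position phase distribution against 1:1:1."""
    phases = np.array([p.phase for p in matrix.positions])
    if len(phases) == 0:
        raise ValueError("matrix has no intron positions")
    counts = np.bincount(phases, minlength=3)
    n = counts.sum()
    expected = n / 3.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p_asym = float(sps.chi2.sf(chi2, df=2))
    p_exact = None
    if expected < 5:
        rng = np.random.default_rng(seed)
        sim = rng.multinomial(n, [1 / 3] * 3, size=n_sims)
        chi2_sim = ((sim - expected) ** 2 / expected).sum(axis=1)
        p_exact = float((chi2_sim >= chi2 - 1e-12).mean())
    return PhaseTestResult(tuple(int(c) for c in counts), chi2, p_asym,
                           p_exact, n_sims)
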