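# Methods

## Data model and conventions

An intron position is addressed by its 0-based codon index in the protein
alignment plus a phase in {0, 1, 2}; phase 0 means insertion before the
codon's first base, so the nucleotide-level insertion point on the coding
sequence is `3·codon + phase`. This makes (coordinate, phase) a total
order, which is what the sliding-candidate detector exploits: two
positions whose insertion points are exactly 1 bp apart and that never
co-occur in a single gene copy are reported as a candidate displacement
(detection is purely coordinate-based; flank similarity is not used, so
the output is labelled *candidate*).

States are present/absent/unknown. "Unknown" marks stretches where the
underlying sequence is unavailable; it is excluded from every count and
denominator, contributes zero cost to both states in the parsimony
dynamic program, and never constrains replay checks. The matrix TSV
dialect is fixed (header of position ids, then an `alignment_coordinate`
and a `phase` metadata row, then one row per gene copy with states coded
`1/0/?`); no auto-detection, for bit-exact reproducibility.

Trees are rooted, dated (branch lengths in Ma) and, for any
through-time computation, ultrametric (checked, tolerance 1e-6 Ma on tip
ages). Every branch is identified by the node below it. The root may
carry its own edge — the *stem* branch — representing the interval
between the gene's arrival in the genome and the first sampled
speciation; gains reconstructed above the root land on this branch.

## Species-level collapse and partial losses

When a species carries several gene copies, its per-position state is
collapsed over non-unknown copies: present in all → `present_all`,
present in none → `absent_all`, mixed → `present_some`. For tree
inference `present_some` is treated as *present* at the terminal, and one
partial-loss event is recorded on the tip branch per such species and
position, regardless of how many copies lost the intron. This mirrors the
single-event counting convention for paralog losses (discriminating
parallel losses in paralogs from a single pre-duplication loss is rarely
possible) and deliberately *underestimates* the loss rate; the alternative
(one event per copy) would overestimate it whenever the gene tree is
unresolved.

## Weighted parsimony reconstruction

Two-state Sankoff dynamic programming per position, linear in tree size,
with costs `gain = 10`, `loss = 1` by default (configurable). The 10:1
asymmetry encodes the standard expectation that parallel losses are far
more frequent than parallel gains; true Dollo reconstruction is the limit
of an infinite gain cost, and with the default weights a second gain is
only inferred when the alternative requires ten or more extra losses. The
state above the root is hard-fixed to *absent* (a horizontally acquired,
primitively intronless gene); this is configurable for reuse on other
systems.

Among equal-cost histories the backtrace prefers the *present* state at
every choice point, which places gains as rootward and losses as tipward
as possible — a deterministic convention, not a biological claim. The
number of tied minimum-cost assignments per position is computed by a
counting DP and reported (`tied_optima`), so a user can see where the
history is not unique. An exhaustive oracle enumerating all
2^(internal nodes) assignments (trees capped at 12 internal nodes)
verifies the DP in the test suite over all 64 patterns on several 6-tip
trees, including profiles with unknown and partial states.

## Rates through time

Per-branch rates are event count / branch length. For the profile,
events are assumed to have occurred evenly along their branch: each
branch contributes its constant per-Ma rate over whatever part of a time
bin it overlaps, and the bin value is the mean over lineages alive in the
bin,

    value(bin) = Σ_b rate_b · overlap(b, bin) / (n_lineages(bin) · width).

This reading makes the conservation identity
`Σ_bins value · width · n_lineages = total events` hold exactly (up to
float rounding; asserted at 1e-9), which the discrete alternative —
placing the k events of a branch at mid-quantile fractions (i − ½)/k and
rating each bin by its own overlap — does not when branches partially
overlap bins. The mid-quantile placement is still available:
`method="midpoint"` bins the placed events and divides by
`n_lineages · width` (also exactly conservative), and `event_times`
exposes the placed ages. Whether the original analysis averaged over
branches or summed and divided by total lineages is not decidable from
its description; the per-bin mean across alive branches is the default
and the alternative is one line of code away. Bin width defaults to 10 Ma.

Partial losses count as losses in all rate outputs and are also reported
separately.

## Resampling tests

*Parallel losses.* Two lineages draw n1 and n2 loss positions without
replacement from a pool; the statistic is P(overlap ≥ k). Sampling uses
Gumbel-top-k keys (`log w + Gumbel`), which is exactly successive
weighted sampling without replacement and reduces to uniform sampling
when weights are equal — with the same seed the weighted and unweighted
paths produce identical draws. The uniform case has the closed form
`Σ_{k≥k_min} C(n1,k) C(pool−n1, n2−k) / C(pool, n2)` (hypergeometric
tail), used as an oracle; binomial standard errors are reported. Whether
"6 parallel losses among eight" means 8-vs-8 or 6-vs-8 draws is
ambiguous in the source analysis; all four numbers are free parameters
here, with 8-vs-8, k ≥ 6 as the documented default in the acceptance
script.

*Spacing regularity.* Exon lengths are the gaps between consecutive
intron coordinates (plus the two gene ends); the effective number of
exons is `Ne = exp(−Σ pᵢ ln pᵢ)` on exon-length fractions. The exact
formula behind the published statistic is not reprinted in the source;
the exponential-entropy form is adopted because it is maximal (= exon
count) exactly for equal exons, which is the property the test uses, and
the inverse-Simpson form `1/Σ pᵢ²` (same maximal property) is available
behind the `statistic` parameter. The p-value is one-sided
(P(Ne_sim ≥ Ne_obs): over-regularity relative to random spacing), with
insertion sites simulated continuously uniform. Null calibration
(uniform p-values under random insertion) is asserted in the tests by a
KS check over 200 simulated genes.

*Positional homogeneity.* Chi-square of bin counts (default ten
equal-length alignment segments) against uniform, with the p-value from
multinomial simulation rather than the asymptotic distribution, since
per-bin expectations are often below 5 at realistic intron counts.

## Information content

Per column, information is `2 − H(f) − 3/(2 ln 2 · n)` bits, floored at
0 — the standard sequence-logo estimator with its small-sample
correction. Uncertainty: frequencies are drawn from the Dirichlet
posterior under a symmetric prior (default Dirichlet(1); the prior
pseudo-count is a parameter, e.g. ½ for Jeffreys), the corrected
information recomputed per draw, and the 2.5/97.5 percentiles taken; the
interval is widened, if necessary, to contain the point estimate. At the
study-like scale (n = 478, interior frequencies) measured coverage of the
true information is ≈ 95% (93–97% asserted over 1000 simulated columns in
the test suite). Columns with n = 0 are flagged (NaN) rather than
raising, so empty strata propagate visibly.

"Absent-site" strata are defined operationally: flank records are emitted
for gene copies scored absent at a position, at the homologous
coordinate, and the `presence` stratification contrasts them with
intron-bearing copies. The "ancestral" age class is taken from the
reconstruction or simulation output (positions gained on the stem
branch), never hard-coded.

## The simulator

Continuous-time per-branch Gillespie simulation on a grid of
`3 · n_codons` insertable slots: gains into empty slots at a
piecewise-constant-in-time rate per slot per Ma, losses of present
introns at a constant per-intron rate, exponential waiting times,
events timestamped in Ma so the rate profile can be validated against
truth. A configurable burst of gains is placed uniformly on the stem
branch. Duplications clone a copy instantaneously at a specified branch
and age, after which copies evolve independently (the simplest model
consistent with observed partial losses); each non-primary copy reaching
a tip is dropped with probability `copy_loss_prob`. Unknown regions are
emulated by masking a contiguous run of positions in randomly chosen tip
copies. Only positions present in at least one surviving tip copy become
matrix columns (observability), exactly as in real data. The full event
log replays deterministically to the emitted matrix, and all outputs are
bit-reproducible under a fixed seed.

Splice contexts are drawn per occurrence: lognormal lengths
parameterised by mean and median (defaults 61.6 / 56 bp, i.e.
σ = √(2 ln(mean/median)) ≈ 0.44 — short introns with low dispersion),
donor `G[T|C]rnG` with GC probability 0.027 and a conserved G at position
5 (default probability 0.8), acceptor `yAG`, and near-uniform exonic
flanks with a mild G enrichment (0.30) at the two bases abutting the
intron — a weak protosplice-like signal.

`preset_study_scale` bundles these into a study-scale dataset: a random
24-species ultrametric tree (root pinned at 363 Ma under an 85 Ma stem,
join ages uniform), duplications sampled proportional to branch length
until ~18 extra tip copies accrue (~40 copies after copy loss), stem
burst 17, gain 1.4e-5 per slot per Ma, loss 1.2e-3 per intron per Ma.
These rates were calibrated once so the *expected* output sits at ~64
observable positions, ~480 intron occurrences and ~13 introns per copy,
then frozen; individual seeds vary within roughly 44–86 positions and
10–16 introns/copy.

What the simulator does **not** emulate: nucleotide evolution of exons,
selection on intron content, intron sliding (sliding is a detection
feature only), gene-tree/species-tree discordance, and hidden paralogy.
Consequently, passing tests show that the pipeline is internally
consistent and statistically calibrated under its own generative
assumptions — not that parsimony reconstructions on real data are
unbiased where those assumptions fail (in particular, parallel losses in
sister lineages are merged into one parental loss, so loss counts are
conservative: measured event-level recovery is ~97% in a homoplasy-sparse
regime, dropping to ~70% at study-scale loss rates purely through this
merging).

## Problem sizes in the test suite

Oracle comparisons use 6-tip trees (all 64 patterns, exhaustive
enumeration); replay and conservation identities run on 100 and 20
simulated datasets of 8–16 species; null calibration uses 200 genes × 400
simulations; credible-interval coverage uses 1000 columns at n = 478;
recovery uses 50 seeds of the 24-species configuration; the envelope
check runs the preset over 100 seeds. These sizes keep every property
statistically meaningful while the whole suite remains quick to run.

## Known limitations

- The parsimony mapping is species-level; gene-tree-aware reconciliation
  and ML gain/loss inference are out of scope by design.
- Partial losses are costed but not placed in time within the tip branch.
- The exact weight the original analysis used for its parsimony mapping
  is unknown (only an ML gain:loss bias of 1:10 is stated); 10:1 is
  adopted by analogy and configurable.
- The credible-interval construction ("Bayesian 95%") is underspecified
  in the source; the Dirichlet-resampling choice and its prior are
  parameters, not claims about the original computation.
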