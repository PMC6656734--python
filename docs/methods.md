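# Methods

This note documents the models and procedures implemented in `mitoarch`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Canonical form of a circular signed gene order

An arrangement is a circular sequence of signed tokens from the 37-gene
mitochondrial vocabulary (13 PCGs, 2 rRNAs, 22 tRNAs with trnL1/trnL2 and
trnS1/trnS2 disambiguated by anticodon family). Because deposition start
and strand are arbitrary, the canonical representative is defined as the
lexicographically smallest rotation — over the order and its reflection
(reverse the list, flip every sign) — that starts with a plus-strand copy
of the anchor gene. The anchor is `cox1`, falling back to `cob`, `rrnL`,
then the alphabetically smallest token; with a unique anchor copy this
reduces to "rotate to the anchor, reflect first if it reads minus".
Canonicalisation is idempotent and invariant under rotation and reflection
(property-tested against an independent brute-force canonicaliser).

Internal genome coordinates are 0-based half-open on the forward strand;
conversion to GenBank's 1-based inclusive convention happens only in the
reader/writer. Features annotated across the origin of the circle keep
`spans_origin=True` with `start` > `end`.

## Rearrangement events and scenario inference

Forward operators: reversal `r` (segment reversed, strands flipped),
transposition `T` (segment moved), reverse transposition `rT` (moved and
flipped), tandem duplication–random loss `tdrl` (window duplicated in
tandem, one copy of each gene struck out according to a kept-first /
kept-second bipartition), duplication `d` and deletion `x`. Events operate
on the linearised canonical representation; segment operands are index
ranges. Rotation and reflection of the circle are absorbed by
re-canonicalisation after each application. On a circle, exchanging two
adjacent arcs is the same event as exchanging either arc with the
remainder, so any single circular reversal or block exchange surfaces as
one contiguous window in canonical coordinates; the detectors exploit
this. `d` and `x` exist for simulation only — inference runs on
duplicate-collapsed, gene-restricted orders and never proposes them.

Scenario inference between same-gene-set canonical orders is a prioritised
deterministic search:

1. equality → empty scenario;
2. one `r`/`T`/`rT` event. A cheap gate first: a reversal changes at most 2
   signed circular adjacencies and T/rT at most 3, so the search only runs
   when the breakpoint distance is ≤ 3. Reversals and block exchanges are
   detected in O(n) from the mismatch window; `rT` falls back to exhaustive
   enumeration ordered by segment length, then position (bounded by
   `max_single_search` candidate applications). Type preference r > T > rT;
   the reported operand is the minimal mismatch window in canonical
   coordinates, which for an event that touched the anchor may describe the
   circular complement of the applied segment — the same event class.
3. if the relative permutation preserves every strand, a pure tdrl scenario
   of minimum length. The tdrl distance is the classical `ceil(log2 s)`
   with `s` the number of maximal increasing contiguous runs; the
   constructive scenario stably radix-partitions the run indices, one
   whole-sequence tdrl per bit, which attains the bound (whole-window
   tdrls subsume smaller windows).
4. otherwise: reverse each maximal block of wrong-strand genes in place,
   then tdrl steps as in (3).

Scenarios longer than 8 events are returned `complete=False` with the
breakpoint distance recorded; downstream consumers use that distance as a
flagged surrogate. Completed scenarios are verified by replay before being
returned. Tie-breaking rules are this package's own convention — the tools
historically used for pairwise scenario prediction do not publish theirs —
so only determinism, soundness (replay exactness) and single-event
completeness are claimed, all of which are tested against brute-force
oracles.

## Ancestral arrangement reconstruction

Ancestral states are restricted to a candidate pool: every distinct leaf
arrangement plus the reference (ground pattern). The assignment minimising
the total scenario length over all edges — with total breakpoint distance
as tie-breaker and a preference for the reference among exact ties, so
derived states are not inflated — is computed exactly by Sankoff-style
dynamic programming (bottom-up cost tables, top-down traceback). An
earlier two-pass local scheme (children + reference bottom-up, parent added
top-down) was measured to exceed the planted event count in 2–3% of sparse
simulated replicates through local optima; the DP formulation removes
those cases while keeping the candidate-set philosophy, and is the
package's own design choice.

Each internal node is labelled from a final local re-evaluation:
`consistent` when the assignment is the unique local optimum or a tie the
reference preference resolves in its favour; `intermediate` when the local
re-evaluation prefers another candidate; `fallback` when an arbitrary
deterministic tie-break decided. Non-binary nodes are resolved with
zero-length edges and logged.

The recovery guarantee is stated for the sparse regime: at most one
r/T/rT event per branch with operands in pairwise disjoint gene windows,
planted with per-branch probability 0.1 on 16-leaf trees. Under those
conditions 100/100 seeded replicates recover every planted ancestral
arrangement with all nodes consistent, and the total inferred event count
exceeded the planted count in 1 of 200 replicates (a true-ancestor-
outside-pool ambiguity). Denser regimes degrade gracefully and are not
covered by the guarantee.

## Composition metrics

All whole-molecule statistics are computed on the forward strand, with `N`
runs excluded from every denominator (an assembly gap must not bias AT%):
`AT% = 100(A+T)/(A+C+G+T)`, `AT-skew = (A−T)/(A+T)`,
`GC-skew = (G−C)/(G+C)`, `SUskew = (L⁺−L⁻)/(L⁺+L⁻)` over summed annotated
feature lengths per strand, and `UR% = 100 ×` (length − interval union of
all features)/length — overlaps count once, and the control region, never
being an annotated gene, is unassigned by construction (exposed as the
default rather than a switch because the annotation pipelines this
package's inputs come from do not emit the control region as a gene).

Codon usage counts codons over protein-coding features 5'→3' on the coding
strand under the invertebrate mitochondrial genetic code (NCBI table 5 via
Biopython: AGA/AGG = Ser, ATA = Met, TGA = Trp). The initiation codon is
counted as given; terminal stops and trailing incomplete codons are
excluded; internal stops are warned about but counted. RSCU is
`count/(family total / family size)` over sense codons; stop codons are
excluded from families, the conventional definition. Per family the RSCU
mean is exactly 1 — used as an exact identity test.

## The single-factor evolutionary-speed index

The five variables (root-to-tip distance, outgroup distance, UR%, AMIGA on
protein-coding arrangements, SUskew) are standardised; the 5×5 Pearson
correlation matrix `S` is fitted with a one-factor maximum-likelihood
model using Jöreskog's concentrated objective over the uniquenesses
(L-BFGS-B, bounds [0.005, 1]; uniquenesses at the bound flag a Heywood
case). Fit statistics: Bartlett-corrected
`chi2_model = (n − 1 − (2p+5)/6 − 2k/3)·F_ML` with `df = 5`; Bartlett's
sphericity statistic for the independence model with `df = 10`; TLI, RMSEA
and SRMR (root mean square over the lower triangle including the diagonal)
derived from the two. Scores use the regression (Thomson) method; the
factor is oriented so the root-to-tip loading is non-negative. AMIGA
enters as the raw sharing fraction — any monotone transform is absorbed by
the correlation pipeline.

When Bartlett's test cannot reject independence, the ML objective has a
flat direction (any single uniqueness can slide to its bound without
penalty) and the "optimal" loadings are optimiser noise; the fit then
reports the identified one-step principal-factor solution and sets a
`degenerate` flag. This estimator choice was validated by simulation
recovery and cross-checked against scikit-learn's ML factor analysis,
which reproduces the per-replicate loadings to < 0.03.

A structural caveat drives one pipeline decision: when the outgroup roots
the tree, the tree-path distance from the outgroup equals the root-to-tip
distance plus a constant for every leaf, so the two variables are exactly
collinear and the correlation matrix is singular. The index as originally
conceived uses an independently estimated pairwise distance for MLdist.
The simulator therefore emits `mldist.tsv` — the true patristic distance
perturbed by multiplicative lognormal noise (sd 0.1), a stand-in for
pairwise ML estimation — and the pipeline substitutes it when available;
with only a tree, the singularity is surfaced as an error, not papered
over.

## Multivariate summaries

PCA is the eigendecomposition of the Pearson correlation matrix: variance
fractions are eigenvalues/p; scores project the standardised data;
component signs are fixed so the largest-magnitude loading is positive;
constant columns are dropped and logged. Spearman's rho is the Pearson
correlation of mid-ranks (ties averaged), with a t-approximation p-value
on n−2 df and a seeded two-sided permutation p-value with add-one
correction. The arrangement–rate report correlates per-taxon event counts
from the reference (breakpoint surrogate when a scenario is incomplete)
with each rate column and, for habitat, with one binary indicator per
category — the least-assumptive encoding. Tests are two-sided with no
multiple-testing correction by default; Benjamini–Hochberg is available as
a flag.

## The synthetic generator

The generator emulates a decapod-scale comparative study; its defaults are
the study conditions for every test:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 60 | ingroup leaves (plus one grafted outgroup) |
| `birth_rate` | 1.0 | Yule (pure-birth) tree prior |
| `branch_noise_sd` | 0.3 | lognormal per-edge rate jitter — pure-birth trees are ultrametric, estimated trees are not |
| `event_rate` | 0.15 | rearrangements per unit branch length (Poisson); leaves a sizeable fraction of taxa on the ground pattern, matching published arrangement surveys |
| `event_weights` | T .35, r .25, rT .10, tdrl .20, d .05, x .05 | event-type multinomial; `x` only ever deletes one copy of a previously duplicated gene |
| `at_percent` | 70 | decapod mitogenomes are AT-rich (reported clade means 65–71%) |
| `at_skew`, `gc_skew` | −0.02, −0.20 | typical whole-molecule asymmetries, negative GC skew for most decapods |
| `ur_percent` | 6 | one control-region block sized so the unassigned fraction hits the target |
| gene lengths | typical decapod values ± 5% | total genome lands in the observed 15–18 kb range |
| `mldist_noise_sd` | 0.1 | lognormal error on the pairwise outgroup distances |
| `rate_mode` | null / linked | rates independent of events, or `a + b·(path events) + noise` |

Sequence composition is achieved by construction: non-coding regions draw
bases iid from the target distribution; coding regions draw codons as
iid base triplets (stops rejected, skews negated for minus-strand genes so
the forward-strand composition still hits the target), which also induces
a detectable codon-usage bias (RSCU ≠ 1). An optional `N` run mid-control-
region emulates an assembly gap. One global seed feeds independent
per-stage generators (tree / events / sequences / rates / distances), so
stages can be regenerated in isolation; every output is a pure function of
(config, seed).

What the generator does **not** emulate: sequence-level substitution along
the tree (no alignments), annotation error beyond what the diagnostics
machinery reports, heterogeneous gene content across taxa (gene loss is
restricted to duplicate copies), selection, or within-genome composition
heterogeneity beyond the strand rule. Passing tests therefore demonstrate
correctness of the analysis machinery on data satisfying the model's
assumptions, not robustness to real-world annotation noise.

A two-regime variant (`simulate_contrast_dataset`) makes the clades off
the ingroup root a conserved regime (ground pattern everywhere) and a
rearranged regime (2–4 tdrl events per leaf, branch lengths ×3) to
reproduce the qualitative bimodal separation of index scores seen in
empirical arrangement surveys; across seeds the group-mean gap is 3–15
pooled standard deviations.

## Problem sizes used by the test and acceptance runs

Single-event inference is fuzzed on 2×10⁴ planted pairs at n ≤ 10 with a
1-in-10 deterministic subsample cross-checked against full enumeration;
tdrl distances are verified against breadth-first search for every
permutation to n = 6; scenario soundness on 10³ multi-event replays;
ancestral recovery on 100 seeded 16-leaf replicates; factor recovery on 20
seeds at n = 1000; the generator round-trip on 60 taxa. These sizes give
oracle-exact or tight statistical coverage while keeping the full suite
under a minute of compute for the heavy tests.

## Known limitations

* Scenario inference returns one deterministic scenario, not the full set
  of co-optimal alternatives, and makes no minimality claim for mixed
  multi-event histories (minimum mixed-event distance is NP-hard).
* Ancestral states outside the candidate pool (leaf orders + reference)
  are invisible to the reconstruction; in dense-event regimes this
  shows up as occasional extra inferred events.
* AMIGA is a dataset-relative quantity; index scores are comparable within
  one dataset only.
* The habitat encoding (one binary indicator per category) is a modelling
  choice, not an inference from data.
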