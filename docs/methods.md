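# Methods

## The experiment this package analyzes

A TF-centered yeast one-hybrid screen inverts the classical assay: the
transcription factor of interest (fused to an activation domain) is the
bait, and the prey is a library of reporter plasmids each carrying a short
fully random insert — here 7 nt, giving a 4^7 = 16,384-sequence space —
between fixed vector flanks upstream of *HIS3*. Clones whose insert the TF
binds grow under selection; the pooled survivors' insert region is PCR
amplified (a 125-nt amplicon) and sequenced. The computational task is to
recover the inserts from the reads, decide which insert sequences are
over-represented relative to the library design, and summarize the bound
sequences as position weight matrices.

## Amplicon model and insert extraction

The amplicon is `upstream_flank + N*k + downstream_flank`, with the flanks
constant and the insert the only variable region. The packaged template is
the printed 125-nt library oligo; note it carries a 9-nt N-run as printed,
while the screen was designed around 7-nt inserts — both variants are
available (`default_template()` / `design_template(k)`) and k is a free
parameter throughout.

Extraction matches the `anchor_len`-suffix of the upstream flank and the
`anchor_len`-prefix of the downstream flank against the read and its
reverse complement, allowing up to `max_mismatch` Hamming mismatches each
(no indels), and requires the two anchors exactly k bases apart. A read
yields an insert only if that placement is unique and the insert contains
no N. Defaults: `anchor_len=12`, `max_mismatch=1`. With a per-base
substitution rate e, the chance a 12-mer anchor carries >1 error is
~66·e², so at e=0.001 essentially every read whose anchors survive has at
most one mismatch per anchor; reads with indels are simply not extracted.
Amplicon sequencing is unstranded, so both strands are searched; uniqueness
is evaluated over placements on both strands, which makes extraction
strand-invariant (property-tested).

Paired-end mates are extracted independently; concordant pairs count once,
discordant pairs are dropped as ambiguous.

## Read QC

Three whole-read filters in fixed order (first failing rule wins): adapter
as exact substring, N fraction > 5%, mean Phred quality <= 10. "Quality
<= 10" is read as the per-read mean; a per-base-minimum mode exists behind
a flag. No trimming: the protocol removes whole low-quality reads. The
category counts partition the input and filtering is idempotent (both
property-tested).

## Enrichment: the exact uniform null

The saturated design makes the null exactly known: with N extracted reads
and no binding, each k-mer count is Binomial(N, 4^-k). Each of the 4^k
k-mers (including unobserved ones — they belong to the test family) gets an
exact upper-tail p-value P(X >= c), Benjamini–Hochberg corrected across all
4^k tests (default q <= 0.05). This formalizes "more repetitions means more
likely bound" as a calibrated test, and is deliberately independent of
alignment-based motif discovery: a k-mer can be strongly enriched even when
its neighborhood is too heterogeneous for an aligner to flag.

One caveat is built into the design rather than the test: reads from the
same surviving colony are not independent draws, so with sequencing depth d
per colony even a single false-positive colony lifts its k-mer to count ~d.
The binomial p-value is therefore calibrated per *read*, not per *colony*;
at high depth the enriched list includes surviving background k-mers, and
the known-motif read counts (`count_motif_reads`, exact and any-offset
substring modes) plus motif discovery on the unique-insert set are the
depth-robust summaries.

Library diagnostics: coverage (observed fraction of the 4^k space) and the
Gini coefficient of the full count vector (zeros included).

## Motif discovery

1. **Seeding.** K-mers passing q <= 0.05 and fold >= 2 are greedily
   clustered: the highest-count unassigned k-mer seeds a cluster absorbing
   all unassigned k-mers within Hamming radius 1 of the seed. Deterministic
   given the (count, lexicographic) sort.
2. **Refinement.** Per cluster and per width w (default 4..k), an OOPS
   ("one occurrence per sequence") expectation–maximization over the
   cluster's unique members: each sequence holds exactly one motif
   occurrence at a uniform-prior offset; background is uniform 0.25/base.
   E-step: posterior offset distributions under the current matrix; M-step:
   re-estimate with pseudocount 0.25 per cell. Initialization puts 0.7 mass
   on each base of the cluster's most frequent w-substring (count-weighted),
   0.1 elsewhere; tol 1e-6 on the log-likelihood, max 200 iterations. The
   observed-data log-likelihood is non-decreasing every iteration (asserted
   in tests on the recorded trace).
3. **Ranking.** The best width per cluster is kept and models are ranked by
   log-likelihood ratio against the pure-background model.

EM runs on unique inserts by default, matching a protocol that deduplicates
("assembles") inserts before motif analysis; a count-weighted mode is a
flag. Motifs are confined to the insert — the flanks are constant and would
dominate any cross-boundary motif. OOPS rather than ZOOPS/ANR is the
defensible simplification for fixed-length 7-mers that each survived
selection. Output is MEME minimal motif format (round-trips to 1e-6) plus a
TSV summary; no attempt is made to reproduce any particular external tool's
motif count, which is version-dependent.

Consensus strings are the per-position argmax; a degenerate IUPAC rendering
(bases holding >= 30% of a column) is also provided.

## Saturation analytics

Expected distinct inserts after m uniform draws from S = 4^k:
S(1-(1-1/S)^m), via `expm1`/`log1p` for stability. Probability of full
coverage: exact inclusion–exclusion in integer/rational arithmetic for
S <= 64; for larger S the same alternating sum is evaluated in log space
(lgamma terms, truncated once terms fall below 1e-18), which is accurate to
~1e-8 wherever the expected number of missing inserts mu = S(1-1/S)^m is
<= 16, and falls back to exp(-mu) — labeled "poisson" — only where the
probability is below ~1e-7. The plain Poisson form alone has worst-case
absolute error ~0.02 at S=64 near the coverage transition, which is why the
series evaluation is the default.

Quantifying the design argument: at m = 150,000 and S = 16,384 the expected
distinct-insert count is 16,382.3, but the probability that *every* 7-mer
is present is only ~0.18 (about 1.7 k-mers expected missing). "Saturated"
is therefore accurate in expectation and ~99.99% coverage terms, not as a
guarantee of completeness; the package computes this rather than assuming
it.

## The simulator: what it emulates and what it does not

Emulated: uniform i.i.d. colony sampling over the insert space (150,000
colonies default); selection as match-or-false-positive per colony;
per-colony sequencing depth; unstranded reads; i.i.d. substitution errors
with constant Phred qualities Q = -10·log10(e) capped at 40 (Q30 at the
default e=0.001); full per-colony/per-read ground truth; byte-identical
output under a fixed seed.

Not emulated: binding-strength gradation (the 3-AT dose response is
collapsed into a single false-positive rate, since no quantitative
binding-vs-growth model is available), PCR duplicates and amplification
jackpots, indel sequencing errors, learned per-cycle quality profiles,
colony growth kinetics, synthesis bias in the oligo pool. Passing tests on
simulated data therefore demonstrate correctness of the algorithms under
the stated stochastic model, not robustness to these real-data effects —
in particular, real amplicon data with indel errors will show a lower
extraction rate than the simulator predicts.

Defaults without a stated experimental value, chosen once: false-positive
survival rate 0.02 and depth 50 reads/colony (with both canonical ERF
elements — AGCCGCC and (A/G)GCCGA — planted in substring mode this yields
~3,100 survivors and ~157,000 reads at the 150,000-colony scale, the same
order as a real pooled-survivor sequencing run); substitution rate 0.001
matching a Q30 short-read run.

## Numerical and determinism choices

Exact binomial tails via `scipy.stats.binom.sf`; BH via statsmodels (tested
against an independent hand-written step-up). Enrichment ties break by
q-value, then fold (descending), then k-mer. Cluster seeding and EM inputs
are sorted, making `discover_motifs` byte-deterministic. All coordinates
are 0-based half-open internally. Stage seeds are spawned from the master
seed via `numpy.random.SeedSequence`, kept below 2^31.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the screen at its design scale
of 150,000 colonies with depth 5–50 (up to ~157,000 reads), the EM
parameter-recovery experiment at 200 sequences × 50 replicates, and exact
coverage-probability enumeration at S <= 4, m <= 10 — sizes at which every
closed-form oracle in the tests is itself exactly computable.

## Known limitations

- The per-read binomial null ignores colony-level clustering (see above);
  a per-colony null would require deduplication by colony, which sequencing
  alone cannot provide without UMIs.
- Hamming-only anchor matching drops indel-bearing reads.
- OOPS assumes every cluster member carries the motif; contaminating
  members dilute the matrix rather than being assigned zero occurrences.
- The full-scale published read counts depend on the original trimming
  tool's unstated settings and the deposited raw data, and are not
  reproduced desk-scale.
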