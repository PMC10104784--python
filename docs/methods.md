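# Methods

## The entropy statistic

The unit of analysis is the 4-mer: four consecutive CpGs in reference
order. A read contributes to a 4-mer only if it carries a valid call at
all four positions; its configuration (b1, b2, b3, b4) maps to epiallele
index 8·b1 + 4·b2 + 2·b3 + b4. Entropy is Shannon entropy in bits of the
epiallele frequency vector, divided by 4 (the maximum for 16 equally
frequent categories), so it lies in [0, 1] with the two anchors H = 0
(single epiallele) and H = 1 (uniform over all 16). 0·log 0 is taken as 0.
The per-4-mer mean methylation is the fraction of methylated calls among
the 4·N constituent calls.

The plug-in estimator is biased downward at finite coverage: i.i.d.
Bernoulli(0.5) calls at 150× give a mean 4-mer entropy of about 0.96, not
1. The coverage window (default 10–150 reads, both bounds inclusive)
bounds that bias and guards against PCR stacks; 4-mers outside the window
are absent from the output, not zero.

Windowing: 4-mers are enumerated sliding by one CpG (default) or in
disjoint blocks of four. Downstream feature means are insensitive to the
choice at the tolerances used here; both modes are exposed because dense
sliding output matches per-4-mer tooling conventions while disjoint
windows make read-per-4-mer bookkeeping exact in the clone generator. The
reference CpG set is the union of positions observed in the input (or a
supplied CpG list); no genome sequence is required anywhere.

## Input conventions

Coordinates are 0-based half-open throughout; a CpG is identified by the
plus-strand C position, and minus-strand calls are destranded by pos − 1.
Nanopore-style call tables carry a signed log-likelihood ratio; calls with
|LLR| < 2.5 are discarded, while tables without a likelihood column
(bisulfite read extraction) bypass the filter entirely. Within one read,
duplicate calls at a position are collapsed when they agree; conflicting
duplicates drop the position and flag the read — ambiguity must not
fabricate an epiallele.

Feature derivation follows the standard definitions: 1 kb non-overlapping
tiles, CGI shores as the 2 kb flanks of each island, shelves as the 2 kb
beyond the shores, truncated at chromosome bounds and deliberately not
merged between neighbouring islands.

## Feature aggregation

Feature means are unweighted arithmetic means of per-CpG rates (at least
3 covered CpGs, else missing) or of 4-mer entropies (a 4-mer belongs to a
feature when any of its positions falls inside; an all-inside mode
exists). Whether a weighted mean would better reflect coverage is an open
modelling choice; the unweighted mean is implemented as the convention.
Cross-sample comparisons keep features non-missing in all samples by
default; a 0.8 fraction accommodates long time-courses. Replicates are
averaged per CpG first (mean of rates; depths summed), then aggregated.

## In-silico bulk

Per 4-mer, the bulk pools epiallele counts over clones and resamples at
c = the average per-clone coverage, rounded half-to-even; 4-mers rounding
to c = 0 are skipped. Each of the 100 rounds draws a multinomial(c,
pooled proportions) — i.e. sampling with replacement, which keeps rounds
i.i.d. and remains well defined when c exceeds any single clone's
coverage — and the mean entropy/methylation across rounds is reported.
Because the bulk value inherits the plug-in bias at coverage c while each
clone's entropy carries the bias at its own coverage, clone–bulk
contrasts are most interpretable when clone coverages are similar.

Randomness: every 4-mer uses its own substream derived from (seed,
crc32(fourmer_id)), so results are independent of evaluation order and
parallel chunking.

## Concordance and its null

A read spans an island iff its aligned interval fully contains the island
interval. Reads spanning fewer than two complete hyper CGIs are dropped
first; islands with fewer than ten spanning reads are then discarded;
pairs require at least ten shared reads. Medians are per island over all
its spanning reads (pair-independent, "unphased"), with the even-count
median the midpoint of the two central values; per-read island means need
at least one call inside (configurable). Ties at the median count to the
low side, exactly as the predicate is written. The null permutes the
y-values 100 times against fixed medians and reports the mean; its exact
expectation (n_hx·n_hy + n_lx·n_ly)/n² is implemented as
`exact_null_mean` and used as the oracle in tests. All unordered
same-chromosome pairs are enumerated; no maximum distance is imposed.
When read spans are not known (call tables carry no alignment columns),
the span is approximated by the outermost calls; the generator snaps its
island bounds to the islands' CpGs so that spanning is well defined.

## Hyper-CGI calling

Thresholds are taken literally: mean difference strictly > 0.1; strictly
more than half of the CpGs covered in *both* conditions with per-CpG
difference ≥ 0.1 (the both-covered denominator is a deliberate choice —
using all island CpGs would conflate coverage with effect); baseline
exclusion inclusive at ≥ 0.2; knockout gain inclusive at ≥ 0.2. The DMR
criterion can only rescue a call that already passes the mean-difference
test, never remove one; DMRs come from an external caller as a BED track
with q-values (only hyper-direction intervals with q < 0.05 are used) and
DMR calling itself is out of scope. Islands with fewer than 3 covered
CpGs in either condition report status `missing`.

## The synthetic generator

The generator formalizes, as sampling models, methylation regimes that
are described mechanistically in the literature; no claim is made that
the parameters match any biological process quantitatively. It emulates:

* **bimodal somatic-like methylomes** — per-CpG levels near 0.03 or 0.85;
* **disordered intermediate methylomes** — every call i.i.d.
  Bernoulli(m), the maximal-entropy allelic-heterogeneity model;
* **clones** — *dynamic*: clones redraw calls i.i.d. (clone entropy ≈
  bulk entropy); *static*: each clone fixes one inherited pattern per CpG
  (drawn once at P(methylated) = m) copied onto reads with per-call error
  ε (clone entropy ≈ the error entropy, low; pooled entropy high);
* **long reads** — per read a latent propensity u_r ~ Beta(α, β); calls
  in island c are Bernoulli(ρ·u_r + (1 − ρ)·v_rc) with v_rc an
  independent per-(read, island) Beta draw; ρ = 0 gives independent
  islands, ρ = 1 fully coordinated molecules;
* **condition pairs** — planted classes `hyper` (baseline 0.05, gain to
  0.50), `neutral` (0.05/0.05) and `excluded` (0.25/0.80) cycling across
  islands, with highly methylated background CpGs; counts are exact
  expectations at depth 100 by default, binomial when noise is enabled.

Defaults (chosen once as realistic study conditions): 8 clones, 200
4-mers per clone at 50× — inside the 10–150× scoring window and deep
enough that plug-in bias does not blur the clone/bulk contrast; static
copy error ε = 0.02; long-read layout of 25 independent blocks × 5
islands (20 CpGs each, 2 kb apart) × 40 spanning reads, giving 250 pairs
with Beta(2, 2) propensities; background inter-CpG gap 100 bp, islands
ten-fold denser. A configurable fraction (default 0.1) of synthetic
nanopore likelihoods falls below the 2.5 threshold to exercise the
filter.

What the generator does **not** emulate: sequence context, bisulfite
conversion failure, basecalling error structure, coverage biases,
chromosome-scale domains (PMD/HMD), or correlated errors along a read.
Passing tests therefore demonstrate the correctness and calibration of
the statistics under their own model assumptions, not performance on real
sequencing data.

## Determinism

All randomness descends from explicit integer seeds through named
substreams (numpy `default_rng` seeded with `[seed, crc32(name)]`); the
full simulate → analyse chain is bit-reproducible, and the CLI records
inputs, parameters, seed and version in a JSON manifest per run.

## Problem sizes

Test and example runs use the generator defaults above (≈ 80,000 clone
read–4-mer draws; 250 island pairs × 100 shuffles; 20-island differential
methylomes). These sizes give stable medians and calibration estimates
(permutation standard error on the pooled mean delta ≈ 0.007) while
keeping any single analysis in the seconds range.

## Known limitations

* Entropy, like any plug-in estimator, is coverage-dependent; compare
  samples at matched coverage or rely on the bulk-resampling machinery,
  which equalizes coverage by construction.
* Read spans inferred from outermost calls underestimate aligned spans;
  supplying islands whose bounds are CpG-snapped (as the generator does)
  avoids false negatives in spanning detection.
* The concordance statistic conditions on the observed medians; for
  strongly skewed per-read mean distributions the null can sit well away
  from 0.5, which is why the shuffle null is always reported alongside.
* `missing` hyper-CGI statuses are reported, not silently dropped;
  downstream set comparisons should decide explicitly how to treat them.
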