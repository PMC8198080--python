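# Methods

This note records the statistical definitions the package implements, the
conventions chosen where the field admits more than one, what the
synthetic generators do and do not emulate, and known limitations.

## Sequence model and validation

A coding sequence is uppercase DNA (U normalized to T on input), length a
multiple of 3, beginning ATG, ending in {TAA, TAG, TGA}, with no internal
stop and no ambiguous base. Validation is advisory: failing records are
excluded with a reason code (NO_START, NO_TERMINAL_STOP, INTERNAL_STOP,
AMBIGUOUS_BASE, BAD_LENGTH) and a strict mode aborts instead. The genetic
code is fixed to the standard nuclear table; all target species are
mammals, and alternative codes are out of scope. Species labels come from
the caller (sample sheet / CLI flag), never from free-text FASTA headers.

Composition percentages are computed over the whole CDS with the terminal
stop codon **included by default** (the transcript-level convention);
RSCU, ENc, CAI and P2 always exclude stops, and Met/Trp where noted,
because synonymous-choice indices are defined over degenerate sense
codons only. The `include_stop` flag exposes the other composition
convention. GC3 is defined over **all** third codon positions (not
synonymous-only "GC3s"); one definition is used everywhere — the
composition module is the single source of GC3 consumed by the neutrality
regression and the ENc–GC3 curve.

## Dinucleotide odds ratios

Observed frequencies come from overlapping width-2 windows, step 1,
counted within each record (windows never span record boundaries) and
pooled. Two expectations are exposed and never silently interchanged:

- `UNIFORM`: expected = 1/16 for every dinucleotide. This is the
  convention of the study's published table, whose expected column is
  0.0625 throughout.
- `MONO_PRODUCT`: expected[XY] = f(X)·f(Y) from pooled mononucleotide
  frequencies — the conventional relative-abundance measure.

The two disagree whenever base composition is uneven; the package treats
the choice as an explicit analysis parameter rather than correcting one
into the other. Classification uses strict inequalities: odds < 0.78
UNDER, > 1.23 OVER, boundary values NORMAL.

Reproduction bound: the bundled published observed frequencies are printed
rounded to 7 decimals. Dividing by 1/16 multiplies that rounding error by
16, so the published ratios are reproducible from the published observed
column only to ≈ 8.5e-7 (16·5e-8 plus the printed ratio's own half-ulp);
tests assert at that derived bound, not at machine precision.

## RSCU

RSCU_ij = x_ij · k_i / Σ_j x_ij over the 59 sense codons of the 18
degenerate families (nine 2-fold, Ile 3-fold, five 4-fold, Leu/Ser/Arg
6-fold; Met, Trp, stops excluded). Family sums equal the degeneracy by
construction; an unobserved family yields flagged-ABSENT values rather
than zeros. Classification: > 1.6 overrepresented, > 1 preferred, < 0.6
underrepresented, boundaries fall to the non-extreme class.

Cross-species averaging is the unweighted arithmetic mean of per-species
RSCU tables; a pooled (count-weighted) average is available by summing
CodonCountTables first. The two differ when species contribute unequal
transcript counts, and published cross-species "average" columns are not
always the unweighted mean of their printed per-species values — neither
mode is asserted against such cells.

`shared_preferred` defaults to the strict definition RSCU > 1 in every
table. An `inclusive` (≥ 1) switch exists for published inputs rounded to
two decimals, where a value just above 1 prints as 1.00; on the bundled
five-species table the inclusive reading reproduces the study's 14 shared
codons exactly, the strict reading a 12-codon subset.

Heatmap ordering uses average-linkage agglomerative clustering on
Euclidean distances (scipy), rows = codons, columns = species;
deterministic given input order with scipy's lowest-index tie-break.

## ENc

Wright's estimator per family: F̂ = (n·Σp_j² − 1)/(n − 1) with p_j =
x_j/n. Families with n < 2, and families where F̂ ≤ 0 (possible at tiny
counts, e.g. a two-fold family observed once each way), are excluded from
their degeneracy-class mean — the estimator carries no usable signal
there. ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. An empty 3-fold class
(Ile unobserved) is imputed as F̄₃ = (F̄₂ + F̄₄)/2; any other empty class
raises (the gene is too short to score). The raw value can exceed 61 by
sampling noise (uniform usage at finite counts); results are clamped to
the definitional [20, 61] with the raw value retained.

Interpretive thresholds (e.g. the common "ENc ≤ 35 = strong bias" rule)
are left to the report layer; the package emits the value.

The expectation under pure compositional drive is
ENc*(s) = 2 + s + 29/(s² + (1−s)²) for GC3 fraction s ∈ [0, 1];
ENc–GC3 deviations are observed − expected, with the fraction of
sequences below the curve summarized.

## CAI

Relative adaptiveness w_ij = f_ij / max_j f_ij within each family, from a
reference table's per-thousand frequencies. A zero reference frequency is
replaced by the frequency a 0.5 count would have had in the reference
corpus (pseudo-count applied on the count scale before per-thousand
conversion) so that log w is finite. CAI = exp of the count-weighted mean
of ln w over sense codons excluding Met, Trp and stops; an all-optimal
query scores exactly 1.

## P2

Codon classes (third-position pyrimidines within weak- and strong-start
codons): WWC = {AAC, AUC, UAC, UUC}, WWU = {AAU, AUU, UAU, UUU},
SSC = {CCC, CGC, GCC, GGC}, SSU = {CCU, CGU, GCU, GGU}.

The default mode computes class **means of RSCU** and takes the WWY/SSY
denominators as the 8-codon union means, so
P2 = 2(WWC + SSU)/(WWU + WWC + SSU + SSC). Read literally with 4-codon
sums, the textbook formula (WWC + SSU)/(WWY + SSY) does not reproduce the
study's published per-species table; the union-mean reading reproduces
every cell to two decimals for all five species and the overall value as
their mean, and is therefore the default. The classic count-based variant
(same formula over codon counts) is retained as `COUNT_CLASSIC` for
comparability with the wider literature. Values above 0.5 are reported as
translational-selection bias.

## Neutrality, PR2, correlations

Neutrality is OLS of GC12 on GC3 across sequences (scipy linregress);
slope×100 is reported as the mutational contribution in percent and
100×(1−slope) as the selection contribution. Pearson r and two-tailed p
come from the t transform with n−2 df; no multiple-testing correction is
applied anywhere (none is conventional for these tables). A constant GC3
raises DEGENERATE_X.

PR2 uses all third codon positions: per-sequence points from that
sequence's third-position percentages, the overall point from unweighted
dataset means (equal to the pooled point when sequences have equal codon
counts). Zero denominators flag the affected axis rather than raising.

## Phylogeny

K2P: transitions (A↔G, C↔T) proportion P and transversions proportion Q
over pairwise-deleted sites (any non-ACGT character in either sequence
excludes the site — MEGA's common default, exposed as the only mode since
complete deletion can always be done by pre-masking);
d = −½ln(1−2P−Q) − ¼ln(1−2Q), raising SATURATION when a log argument is
non-positive. Alignment itself is out of scope: input must be equal
length, with a convenience trim-to-shortest mode for same-gene CDS sets.

Neighbor joining is the Saitou–Nei agglomeration with the standard
Q-criterion, ties broken by the lowest active-index pair, negative branch
lengths clamped to zero with a log note, and the final three nodes
resolved in closed form. Newick output orders children by their smallest
leaf label, giving byte-stable text. On additive matrices NJ reproduces
the generating tree's path lengths exactly (tested against an
independent random-join oracle up to 8 taxa and cross-checked
topologically against scikit-bio's NJ).

## tRNA adaptation

The preferred codon per amino acid is the family RSCU maximum (ties to
the lexicographically first codon, logged). Its cognate anticodon is the
strict Watson–Crick reverse complement (DNA alphabet, 5'→3' as in
GtRNAdb); it is "optimal" when its gene count equals the family maximum
and is positive. Wobble decoding (G:U, inosine) is deliberately not
modeled — the matching reproduces the strict-complement reasoning of the
study's tables — but `adaptation_report` accepts a custom cognate
function as an extension hook. Met and Trp are reported descriptively
and excluded from optimality statistics.

The bundled mouse tRNA panel contains one internally inconsistent
published cell: the Met row's items (9/8) sum to 17 while the printed
total is 13 (every other split-count Met row sums to its printed total).
The strict parser refuses the row; `on_total_mismatch="keep"` loads it
with the item sum, and the discrepancy is surfaced, not patched.

## Synthetic data

Generators emulate a curated single-gene mammalian transcript set: valid
CDSs, several hundred codons, grouped into species-like families.
Defaults: amino-acid choice uniform over the 18 degenerate families with
Met/Trp at low weight (all RSCU families exercised), body length in the
hundreds of codons, one named RNG stream per call from a single integer
seed, no global state.

- `generate_biased_set(theta)`: per-family codon probabilities
  interpolate between uniform (θ=0) and one-hot on a designated GC-ending
  preferred codon (θ=1); ENc decreases monotonically in θ with exact
  endpoints 61 (clamped) and 20.
- `generate_neutrality_set(m, …)`: per sequence a latent GC3 target t is
  drawn uniformly in `gc3_range` (default 0.3–0.7, wide enough that
  per-sequence sampling noise attenuates the fitted slope by < 4%);
  third-position G/C mass is set to t within each family, and the
  positions-1/2 G/C propensity to 0.5 + m(t − midpoint) + Gaussian noise
  (default SD 1.5 percent points), realized by an exponential tilt on
  codon weights solved per sequence (Brent root-find). OLS of realized
  GC12 on realized GC3 recovers m within ±0.1 at 200 sequences × 500
  codons.
- `make_fixtures`: an ortholog-like five-species corpus descended from a
  single ancestor by codon-level substitution (synonymous and
  amino-acid-changing rates per species), keeping pairwise divergence in
  the K2P-correctable range, plus a reference usage table and tRNA table
  per species.

What the generators do **not** emulate: isochore structure, codon
autocorrelation along the sequence, realistic amino-acid composition,
indels/alignment error, or substitution along a tree with explicit
transition/transversion rates (fixtures needing known P/Q construct them
directly). Passing tests therefore demonstrate correctness of the
statistics and their contracts, not that real mammalian data will show
any particular effect size.

Sampling-noise bounds in tests are derived a priori from the binomial
SD of the relevant estimator at the stated sample size (e.g. at ~20k
codons a 6-fold family RSCU has SD ≈ 0.068, so deviations are asserted
within 3.5 SD), and stochastic checks are run at fixed seeds.

## Problem sizes

Default test and demonstration runs use corpora of 4–10 sequences of
100–2000 codons, 200-sequence gradients for slope recovery, and ≤ 8 taxa
for tree oracles — sizes at which every contract above is sharp while the
whole suite stays fast.

## Known limitations

- No wobble-aware tRNA adaptation index (tAI) — out of scope.
- No alignment; phylogeny requires equal-length input.
- CAI requires a full 64-codon reference table; partial tables are
  rejected rather than imputed beyond the zero-frequency pseudo-count.
- Dataset-level values published for the original 34-transcript NCBI set
  (mean GC 50.626%, mean ENc 57.656, mean CAI 0.773, neutrality slope
  0.302, ENc–GC3 r = −0.7131) depend on an accession list not bundled
  here; the pipeline reproduces the methods, and those numbers are
  reproducible only with that retrieval.
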