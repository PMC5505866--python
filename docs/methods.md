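# Methods

This note documents the statistical models, parameter defaults and design
decisions behind `ntmemory`, in the order the pipeline runs them.

## Synthetic data generator

The generator emulates a nuclear-transfer memory experiment: endoderm donor
cells, IVF-embryo ectoderm and NT-embryo ectoderm profiled by bulk RNA-seq,
with matched H3K4me3 ChIP-seq (IP + input) over a single synthetic chromosome.

**Expression model.** Each transcript draws a baseline log2 expression from
N(6, 1.5) (arbitrary log2 units of relative abundance). Its planted class
adds per-group offsets of size `memory_log2fc` (default 3 log2 units):

| class              | donor | IVF ectoderm | NT ectoderm                |
|--------------------|-------|--------------|----------------------------|
| ON_memory          | b     | b − fc       | b − fc + retention·fc      |
| OFF_memory         | b − fc| b            | b − retention·fc           |
| reprogrammed_down  | b     | b − fc       | b − fc                     |
| reprogrammed_up    | b − fc| b            | b                          |
| unchanged          | b     | b            | b                          |

Relative abundances are renormalized within each group, so group-level CPMs
are exact expectations. Counts are negative binomial with mean
`library_size × fraction × batch_multiplier` and variance *m + φm²*; φ = 0
falls back to Poisson. The NB parameterization matches the DE test, so the
planted dispersion is the quantity the test estimates.

**Defaults as study conditions.** Sample sizes default to the 3/11/12
donor/IVF/NT design of the emulated study across 3 batches. Values the study
does not pin down were chosen once as realistic for this kind of experiment
and are not tuned: library sizes uniform in 1–2 M reads (a modest bulk depth
that keeps desk-scale reruns fast while leaving median transcripts hundreds
of counts deep), φ = 0.1 (typical bulk biological dispersion),
`memory_log2fc` = 3 with `nt_retention` = 0.8 (strong donor effects of which
most persists in NT tissue, echoing the observation that memory genes remain
strongly misregulated), class proportions 6/6/27/27/34% mirroring the rough
relative sizes of the reported memory/reprogrammed/unaffected fractions, and
a per-batch log-normal scale multiplier with sd 0.2 — a batch is a set of
samples produced together, and a global scale offset is the minimal structure
the double z-score stage is designed to remove.

**Chromatin model.** One TSS per transcript, placed on a fixed pitch so TSS
windows and peaks never overlap or leave the chromosome (a transcript whose
window would not fit raises an error rather than being silently dropped).
Input coverage is per-base Poisson(background, default rate 2). IP coverage
is Poisson(background) outside peaks and Poisson(background × enrichment)
inside each transcript's planted peak, centered on its TSS; enrichment 1
therefore makes IP and input exchangeable. Peak width is drawn normally per
class — ON_memory (3000 ± 300 bp, 6× enrichment) versus reprogrammed_down
(800 ± 150 bp, 3×) encodes the broader/stronger ON-memory promoter domains
the chromatin analyses are meant to detect; other classes sit between.
Every base of coverage counts as one aligned read, so a track's total mapped
reads equal its summed coverage — self-consistent with the per-million
normalization below. All draws come from seeded generators (expression from
`seed`, chromatin from a child stream of the same seed) in a fixed documented
order, so identical configs reproduce byte-identical outputs.

**What the generator does not emulate:** read-level artifacts (mapping,
duplicates, GC bias), transcript-length bias in counts, correlated
co-expression modules, overlapping genes, and peak-calling noise (peaks are
the planted intervals). Passing tests therefore demonstrate correctness of
the statistics and bookkeeping under the stated model, not robustness to
every artifact of real libraries.

## Expression statistics

CPM = count / column total × 10⁶; RPKM = CPM / transcript length in kb; the
identity RPKM = CPM/length_kb is tested exactly. The expression filter keeps
transcripts with CPM > 1 (strict) in all donor samples, or in ≥70% of IVF or
of NT samples (8/11 passes, 7/11 fails).

**Exact NB test.** The engine used by the original analysis is not fully
specified, so the package ships a self-contained common-dispersion exact
conditional test in the Robinson–Smyth style, documented as such:

1. Library sizes are column totals; counts are scaled to their geometric-mean
   common library.
2. Unless supplied, a common dispersion is estimated by pooled method of
   moments: φ̂ = Σ(v − m)/Σm² over within-group means/variances of all
   transcripts, clipped at 0.
3. Group sums of adjusted counts are rounded; under the null both groups
   share one mean, making the group sums NB(n_g·m₀, φ/n_g). The two-sided
   p-value sums the conditional probability of every split of the pooled
   total no more likely than the observed one (at φ = 0 the conditional law
   is exactly binomial, which the test suite checks against an
   exact-rational enumeration to 1e-9). A relative tolerance of 1e-10 in the
   "no more likely" comparison absorbs floating-point near-ties of
   analytically tied splits.
4. logFC = log2((CPM̄_A + c)/(CPM̄_B + c)) with prior count c = 0.5 for finite
   values with stable signs.

Consequence of the stand-in: DE gene counts on real data will not numerically
match any particular edgeR configuration; the properties that matter —
type-I calibration (measured at ~5% on null simulations), oracle agreement at
φ = 0, antisymmetry — are enforced by tests. TMM normalization, tagwise
dispersion and GLM designs are out of scope.

FDR is Benjamini–Hochberg (via statsmodels) across the transcripts that
passed the expression filter; the procedure choice is a package decision —
only "FDR" is specified upstream. Mann–Whitney uses exact enumeration for
n ≤ 12 without ties, otherwise the tie-corrected normal approximation.

## Memory classification

All threshold comparisons are strict; boundary values (FDR = 0.05,
log2FC = 1.5, RPKM = 1) fail their clause — the truth-table test pins every
boundary. "Donor RPKM > 1" is applied in **all** donor samples (the stricter
of the two printed readings). Rule order is fixed: treatment exclusion →
memory classes → reprogrammed classes → resistant-other → unclassified; the
clause that fired is recorded per transcript.

The donor-only carve-out (donor-expressed transcripts silent in IVF/NT remain
reprogrammed-down even when NT/IVF is nominally significant) needs to know
which transcripts are expressed in the ectoderm groups. "Silent" is not
precisely defined upstream ("RPKM < 1 in some or all samples"), so
`classify_xenopus` takes an explicit boolean mask and the pipeline constructs
it with the study's own expressed-in-group convention: RPKM > 1 in ≥70% of
the group's samples, in either ectoderm group. Without a mask the carve-out
is inactive and such transcripts fall to resistant-other.

Sign-discordant resistant transcripts (significant in both donor/IVF and
NT/IVF with opposite signs) get explicit `resistant_other_up/_down` classes
so the four-way partition of the reprogramming-resistant set is reproducible.
The human fold-change-only variant uses the printed cutoff 2.3 exactly (not
log2(5) ≈ 2.3219); its >5-fold subclasses map onto the `fc3_flag` with the
printed subclass name kept in provenance. Replicate intersection keeps a
class (and the 3FC flag) only when every experiment assigned it.

## Chromatin analyses

The histone methylation level over an interval is
`depth_IP/(N_IP/10⁶) − depth_input/(N_input/10⁶)` using mean per-base depth,
which makes bin values bin-size-invariant (whether the original analysis
summed or averaged within bins is unstated; the comparison properties hold
either way). Negative levels are kept. Windows default to 4 kb in 50 bp bins
(80 bins) centered `[TSS − w/2, TSS + w/2)`; 2 kb reproduces the human
reanalysis setting and is a parameter, as is the bin size. Coordinates are
0-based half-open throughout. For minus-strand transcripts the bin order is
reversed so bin 0 is always most upstream — the orientation convention is a
package choice. Windows that leave the chromosome are skipped with a logged
warning. Metaplots are bin-wise means per gene set; integral levels
(sum over bins) and TSS-spanning peak widths are compared with the two-sided
two-sample KS test (asymptotic p).

Peak breadth takes, per transcript, the widest called peak whose half-open
interval contains the TSS base ("spanning" is containment, not window
overlap); the widest-peak tie-break is deterministic and conservative toward
the breadth comparison. Transcripts without a spanning peak are omitted.
Multiple transcripts sharing a TSS are not deduplicated.

## Structure analyses

The double z-score standardizes each transcript row within each batch
(sample sd, n − 1), then across all samples; after stage 2 every row has mean
0 and sd 1. Rows are the only axis on which this removes technical
between-batch variability at the gene level, hence the orientation choice.
Constant row slices are set to zero with a warning rather than dropped
(shape-preserving); single-sample batches are an error.

Hierarchical clustering applies the Ward criterion to *unsquared* Euclidean
distances — the "ward.D" convention, which is what the quoted setting of the
original toolchain executes. scipy's built-in Ward is the ward.D2 variant, so
the Lance–Williams recurrence is implemented here directly (exhaustive
O(n³) search, fine for sample-level problems), with smallest-index
tie-breaking and a 1e-9 clamp on float-noise height inversions (Ward linkage
is mathematically monotone). The test suite replays the merge history against
an independently coded naive recurrence.

PCA is correlation-mode (variables standardized to unit variance, n − 1
convention) computed by SVD of the standardized matrix; the upstream
description of the PCA call is internally inconsistent (the quoted parameter
belongs to a different routine), and correlation-mode is the reading
implemented. Zero-variance variables are dropped with a warning. Heatmap
fold-change matrices use log2((value + c)/(reference mean + c)) with c = 1 by
default, matching the log2(1 + RPKM) axis convention of the MA table; c is a
parameter (the doubling-adds-one identity holds at c = 0).

## Pipeline and problem sizes

All cutoffs are configuration with the printed values as defaults, so the
human variant and alternative window sizes are presets, not code forks. Every
run stamps its outputs with a hash of the scientific configuration (output
location excluded) and the seed; rerunning a stage from persisted
intermediates reproduces the full-run outputs.

The validation scenarios use problem sizes chosen as the package's own
desk-scale defaults: 5,000 null transcripts (4 vs 4 samples, φ = 0.1) for
type-I calibration; 2,000 transcripts for recovery of planted effects; 700
transcripts with ~200 ON-memory and ~200 reprogrammed-down TSSs for the
chromatin contrasts; 800 transcripts, 2 batches for batch-robust clustering.
At these sizes the realized ON-memory donor/IVF log2 fold change recovers the
planted value within ±0.2, ON-memory recall exceeds 90%, under 1% of planted
unchanged transcripts receive a memory label, both chromatin KS comparisons
separate the planted classes at p < 0.001, and clustering after the double
z-score partitions samples by biological group (adjusted Rand index 1.0
against groups). `scripts/acceptance.py` recomputes exactly these quantities.

## Known limitations

* The exact NB test is a documented stand-in for an unspecified DE engine;
  absolute DE counts on real data are configuration-dependent.
* The simulator's independence assumptions (no co-expression, no
  length bias) make recovery rates optimistic relative to real libraries.
* Peak sets are consumed, never called; peak-calling noise is outside the
  model.
* The ward.D implementation targets sample-level matrices (≤ a few hundred
  observations), not transcript-level clustering of whole transcriptomes;
  heatmap row ordering at transcript scale uses the same code and inherits
  the O(n³) cost.
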