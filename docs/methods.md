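# Methods

`exondys` implements a desk-scale re-creation of an exon-array systems
analysis of a two-tissue (skeletal muscle, fibroblast), two-condition
(respiratory-chain disease, control) transcriptome study.  This note
documents the models, the defaults and why, what the synthetic data
emulate, and the numerical choices.

## Probe model and summarization

Probe intensities are modelled multiplicatively:

    PM[i, j] = theta[j] * phi[i] + eps[i, j]

with `theta[j]` the expression index of sample `j` for a probeset and
`phi[i]` the affinity of probe `i`.  `liwong_summarize` fits this model
by alternating least squares: with `phi` fixed, each `theta[j]` has a
closed-form solution, and vice versa.  The scale ambiguity (`c*theta`,
`phi/c`) is resolved by the constraint `sum(phi^2) = n_probes`, so
`theta` carries the intensity scale and the fit is equivariant under
rescaling the input.  Convergence is declared when the largest relative
change of any parameter falls below `1e-6` (at most 50 iterations); the
per-iteration sum of squared residuals is recorded and is non-increasing
by construction of exact ALS.

Outlier handling is a single re-fit pass.  Because the least-squares
rank-one fit is easily hijacked by a gross corruption (a single 10x cell
distorts theta and phi enough that its own residual no longer stands
out), the pass has two parts: a robust pre-screen on the log2 scale
(median polish residuals beyond 3 robust SDs, MAD-based) masks gross
corruptions before fitting, and after convergence any cell whose
residual exceeds 3 robust SDs is flagged; probes with more than half
their cells flagged are dropped, and the model is re-fitted once.
Residual scales at floating-point noise level are treated as exactly
zero so that exact rank-one input is never "cleaned".  The reduced
multiplicative model is used throughout (no probe-specific variance
terms, no iterative outlier schedule).

Gene-level indexes are obtained by running the same fit over a gene's
sense probeset index vectors (probesets play the probe role).
Antisense and background probesets are excluded from gene-level data.

## Normalization

Arrays are normalized by lowess against a per-probe median pseudo-array:
for each array, a locally weighted regression (span 0.3) of its log2
ratio to the reference, as a function of reference log2 intensity, is
subtracted.  The reference is the median rather than any single array so
normalization is symmetric and robust.  Lowess removes constant and
smoothly intensity-dependent biases essentially exactly (a linear bias
is removed to machine precision); normalization is idempotent up to
lowess interpolation error, which concentrates in the sparse intensity
tails.

## Differential expression

The moderated statistic is `d = (mean_a - mean_b) / (s + s0)` with `s`
the pooled standard error of the mean difference and `s0` a fudge
constant chosen among the percentiles {0, 5, ..., 100} of `s` to
minimize the coefficient of variation of window-wise MADs of `d` across
the `s` range (ties go to the smallest candidate; the choice is
deterministic and order-invariant).  Significance comes from group-label
permutations: all `C(n, n_a)` assignments when that count is at most
10,000 (p is then the exact count ratio including the identity
assignment, so p > 0), otherwise sampled assignments with the +1
correction.  p-values are computed against the pooled permutation
distribution of all features — the classic choice, which also makes p
monotone in |d| across features.  The FDR at a cut is the median over
permutations of the number of permuted |d| above the cut divided by the
observed count, without pi0 correction.  Balanced permutations are not
enforced.  Signed significance scores are `sign(change) * -log10 p`.

## Sub-gene events

Within each gene-region (5'-UTR, 3'-UTR, individual exon set,
antisense), the smallest-p probeset represents the region and is
Bonferroni-corrected by the region's probeset count.  An alternative
event requires adjusted p < 0.05 and either a direction opposite to the
gene-level change or a raw p at least `ratio_k` (default 10) times
smaller than the gene-level p.  The ratio arm concretizes "much more
significant than the gene" as an explicit, tunable fold; opposite
direction wins when both arms fire.  Ties on the smallest p break
lexicographically for determinism.

Antisense analyses are restricted to *effective* probesets: mean log2
expression above the pooled background mean + 2 background SDs in at
least half the samples.  The generator emits background-only probesets
for this; on real data the lowest-decile antisense probesets stand in.

## UTR statistics

AU-rich elements are classified by the motif ladder AUUUA, W-AUUUA-W,
... up to WWWW-AUUUA-WWWW (W = A/U; DNA input with U = T; N never
matches); a 3'-UTR gets the longest motif it contains, so the ladder is
monotone under flank extension.  Group statistics compare each class's
mean 3'-UTR percent change against the no-ARE class by Welch's t-test.

Positional profiles assign 3'-UTR probes to 1% relative-position bins
(0 = transcript 5' end, strand-flipped for minus-strand genes), average
the exon-adjusted probe log2 intensity (probe minus the transcript-last
exon's index, so gene-level changes cancel) per group and bin, smooth
with lowess, and report the least-squares slope of the disease-minus-
control curve.  Empty bins are missing, never zero.

The 5'-UTR baseline association uses baseline = mean control log2
5'-UTR index minus mean control log2 gene index, correlated (Spearman)
with the 5'-UTR percent change; a lowess trend is exported for
plotting.  The terminal oligopyrimidine (TOP) detector requires a C
start and an initial pyrimidine run of at least 5 within the first 15
bases.

## Regulator activity

PWMs are pseudocount-regularized (0.01 per cell) column-stochastic
matrices.  Window similarity is the probability-sum score min-max
scaled per matrix, so the consensus scores exactly 1; both strands are
scanned and all windows at or above the similarity threshold (default
0.95) are reported.  A gene belongs to a TF's target set when its
scoped sequence (promoter or intron) has at least one match.  Target-set
activity is a Welch test of target vs non-target percent change;
site-interaction tests partition genes into both/only-A/only-B and test
both-vs-each.  Gene-set concordance uses the weighted running-sum
enrichment score (hit steps proportional to |stat|^w, miss steps
-1/(N - N_hits); the sum ends at 0 by construction) with significance
by gene-label permutation, exhaustive for small sets.  Gene-label
rather than sample-label permutation is used because desk-scale group
sizes make phenotype permutation underpowered.  Over-representation is
the hypergeometric upper tail.

## Cross-tissue synthesis

Genes significant in one or both tissues fall into 8 subsets (4 sign
combinations for both-significant, 2 directions for each
single-tissue); the inverse fraction is the share of both-significant
genes changing in opposite directions.  The global inverse-dysregulation
statistic is the Pearson correlation of signed significance scores over
the shared gene universe.

Per-gene-pair correlations are combined across the four tissue-by-
disease sample groups on the Fisher z scale with sampling variance
`1/(n-3)`, the DerSimonian-Laird moment estimator of the between-group
variance tau^2, random-effects weights `1/(v + tau^2)`, and a normal
approximation for p.  |r| = 1 is clamped to 0.999999 with a warning.
Correlations use Pearson on log2 indexes.  The focal-gene-vs-gene-set
summary runs the meta-correlation per member and t-tests the combined r
values against zero; the correlation screen requires r > 0 and p < 0.05
in every tissue, on disease samples.

## Synthetic data: what it emulates, and what it does not

The generator builds gene models (5'-UTR, exons with introns, 3'-UTR;
one sense probeset per segment, 12 probes across the 3'-UTR for
positional analysis; antisense probesets over the 5'-UTR for a fraction
of genes), sequences (promoter/intron with planted PWM consensus sites
exactly for member genes and accidental matches scrubbed; 3'-UTRs
carrying exactly the planted ARE class), and intensities following the
summarization model: `theta * phi * exp(eps)` with log-normal probe
affinities (ln-SD 0.4) and Gaussian log2 noise (SD 0.1).

Default study conditions: 12 disease vs 8 control samples per tissue
(the cohort sizes of the motivating study design); baseline log2
abundance N(10, 1); background probesets at log2 = 4, i.e. roughly two
orders of magnitude below median signal, so the effective-probeset
mixture is separable.  Planted effect classes are mutually exclusive
per gene: 25% carry a gene-level 1.0 log2 fold change (60% of them
sign-flipped in the second tissue, emulating inverse tissue responses),
10% a 3'-UTR-only 1.0 log2 override, 25% ARE-ladder shifts (+8% for the
basic pentamer, +16% for extended motifs, mirrored with opposite sign in
the second tissue), 10% a 3'-UTR positional gradient of 1.0 log2 per
unit relative position.  Antisense structure is drawn independently:
40% of genes carry an antisense probeset, of which 30% stay at
background ("absent") and 10% respond oppositely to their sense
transcript.  Optional correlation modules add a per-sample latent
factor with signed loadings to plant co-expression for the
meta-correlation and screen analyses.

Not emulated: scanner/spatial artifacts, batch structure, probe
sequence biases (GC, cross-hybridization), alternative splicing beyond
region-level overrides, and any real genome annotation.  Passing the
recovery tests therefore shows the estimators are correct under their
own model assumptions — not that those assumptions hold on any real
array dataset.

## Problem sizes

Tests and the acceptance script run deliberately scaled-down problems
chosen as the package's own desk-scale conditions: 20–240 genes,
300–400 permutations, 1,000-feature null panels, 10 kb oracle scans.
The statistics involved are n-independent (exact enumeration where
feasible, calibrated sampling elsewhere), so the scaled runs exercise
the same code paths as genome-scale inputs.

## Known limitations

- The reduced Li-Wong model omits the original's probe-variance
  weighting and full iterative outlier schedule.
- FDR has no pi0 estimation and is not monotonized across cuts.
- The "significantly smaller than the gene p" arm of the event rule is
  a ratio heuristic; the threshold is exposed as `ratio_k`.
- Lowess normalization is only approximately idempotent in sparse
  intensity tails.
- PWM similarity is probability-sum scoring; log-odds scoring against a
  background model is not implemented.
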