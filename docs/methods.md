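# Methods

This note documents the statistical model behind `chemoscreen`, the
defaults it ships with and why, what the synthetic-screen generator does
and does not emulate, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Screen scoring pipeline

### Design and notation

A chemogenetic screen compares a drug-treated knockout pool against a
vehicle (mock/DMSO) pool, both grown from a common T0 baseline sampled
right after selection. Counts arrive as a guides × samples integer matrix;
the sample sheet assigns each sample an arm (T0 / mock / treated), a
compound (null for T0, optionally null for a shared vehicle arm), and
biological / technical replicate labels. A treated sample for compound *c*
and biological replicate *b* requires a mock with the same *b*; a mock with
a null compound matches every compound.

### Stages

1. **Depth normalization.** Each column is scaled to counts-per-million
   (any positive scale cancels in fold changes; CPM keeps numbers
   readable). A zero-depth column is a hard error.
2. **Log fold change.** `LFC = log2((CPM + c)/(CPM_T0 + c))` with
   pseudocount `c = 0.5`. The pseudocount prevents −∞ on dropout guides
   while perturbing guides that pass the T0 filter (raw count ≥ 30,
   i.e. CPM ≫ 0.5 at realistic depths) negligibly. Multiple T0 samples are
   averaged on the normalized scale before the ratio.
3. **Filters.** Guides whose *raw* mean T0 count is below 30 are removed
   (the rule is stated on read counts, so it is applied pre-normalization);
   genes with fewer than 3 surviving guides are removed from scoring.
   Non-targeting control guides flow through normalization and LFC for
   diagnostics but never form genes. Both filters are monotone in their
   thresholds.
4. **Technical averaging.** LFCs are arithmetically averaged over technical
   replicates, leaving one value per guide × (arm, compound, bio rep).
5. **Residual effects.** Per guide and biological replicate,
   `M = LFC_treated − LFC_mock` and `A = (LFC_treated + LFC_mock)/2`. M is
   the drug-specific component of abundance change: shared fitness dropout,
   guide-level drift and T0 sampling noise cancel because both arms share
   the same baseline and background. A is the M-A abscissa along which
   intensity-dependent distortions live.
6. **Loess normalization.** A robust locally weighted linear regression of
   M on A (tricube weights over the `span = 0.3` nearest-neighbour
   fraction, 4 Tukey-biweight robustifying iterations) is fit per compound
   with biological replicates pooled, and subtracted:
   `M_norm = M − fit(A)`. This removes smooth A-dependent bias — including
   the global compositional shift that depth normalization introduces when
   many guides change abundance in one direction. The smoother is
   statsmodels' `lowess`; `delta` defaults to 1% of the A range (fits are
   interpolated between near-identical A values), which is exact for
   locally linear trends and is the standard speed/accuracy trade-off at
   tens of thousands of points. Passing `delta=0` gives the exact
   per-point smoother, which the test suite compares against an
   independent brute-force tricube weighted-least-squares oracle. Only
   locally linear fits (degree 1) are supported.
7. **Variance prior.** Gene variances are modelled hierarchically as
   `s_g² | σ_g² ~ σ_g² χ²_{d_g}/d_g` with `σ_g² ~ s0² d0/χ²_{d0}`. The
   hyperparameters are estimated by the method of moments on log
   variances: with `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`, the excess of
   `Var(e_g)` over the mean sampling variance `ψ′(d_g/2)` identifies
   `ψ′(d0/2)`; d0 is recovered by Newton inversion of the trigamma
   function and `s0² = exp(mean(e_g) + ψ(d0/2) − log(d0/2))`. When the
   observed spread does not exceed its sampling component the prior
   degenerates to complete pooling (`d0 = ∞`) with `s0²` the mean observed
   variance, so that identical inputs return themselves. At least 20
   informative genes are required.
8. **Moderated t.** Per gene, the `M_norm` values (guides × biological
   replicates pooled, `n` observations, `d_g = n − 1`) give
   `effect = mean`, `s̃² = (d0 s0² + d_g s_g²)/(d0 + d_g)`,
   `t = effect/√(s̃²/n)`, two-sided p from a t distribution with
   `d0 + d_g` degrees of freedom (normal tail at `d0 = ∞`; the ordinary
   one-sample t at `d0 = 0`). Pooling guide × replicate observations
   ignores within-guide correlation across replicates; with planted
   gene-level effects inherited identically by guides this is slightly
   anti-conservative in principle, but the null-screen calibration test
   (Kolmogorov–Smirnov on 2,000 null genes) shows the p-values are
   near-uniform under the generator's noise model. Genes with fewer than
   2 observations are excluded with a warning. p-values are clipped below
   at the smallest positive double so downstream FDR input stays in (0, 1].
9. **FDR and hit calling.** Benjamini–Hochberg step-up q-values
   (`q_i = min_{p_j ≥ p_i} m p_j / rank_j`, capped at 1, order-preserving).
   Hits are `effect > 0.5` (resistant) or `effect < −0.5` (sensitive) with
   `q < 0.4`; all inequalities strict, so effect = 0.5 or q = 0.4 exactly
   is not a hit. The permissive q threshold is the screen's operating
   point: a discovery screen tolerating up to 40% false discoveries in
   exchange for recall, with hits expected to be validated individually.
10. **Cross-compound specificity.** Over a shared gene universe, a gene
    hit in the same direction in *every* compound is `non_specific`
    (excluded from compound-specific interpretation — such genes usually
    reflect generic proliferation or assay artifacts rather than
    pathway-specific biology); a hit in exactly one compound is
    `compound_specific`; a hit in two or more (including all compounds
    with mixed directions) is `shared_subset`.

### Defaults that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_t0` | 30 | raw reads | guides below this are too noisy to trust |
| `min_guides` | 3 | guides/gene | ≥ 3 independent reagents per scored gene |
| `pseudocount` | 0.5 | CPM | avoids −∞; negligible above the T0 filter |
| `span` | 0.3 | fraction | standard M-A normalization window |
| `robust_iters` | 4 | iterations | standard robust-loess practice |
| `effect_cut` | 0.5 | log2 | screen's effect-size threshold |
| `fdr_cut` | 0.4 | q | screen's discovery operating point |

## Synthetic-screen generator

The generator emulates a genome-scale knockout library screened under the
design above, with known per-gene truth for recovery evaluation.

Per guide: T0 abundance `~ lognormal(0, 0.5)` (library skew from cloning
and infection — sdlog 0.5 gives an IQR of about 2-fold, typical of a
well-maintained pooled library); a per-guide log2 drift `~ N(0, 0.3)`
shared between arms (guide-level heterogeneity that cancels in M but
spreads guides along A); per gene: an optional per-doubling fitness rate
(default 15% of genes, `U(−0.4, −0.05)` — from mildly deleterious to
near-essential over 10 population doublings) applied to both arms, and an
interaction effect (default 5% resistant at +1.5 and 5% sensitive at −1.5
log2) applied only to the treated arm. An optional smooth `bias_fn(A)` is
added to the treated log2 expectation — the artifact the loess stage
exists to remove. Counts are negative binomial with mean
`share × depth` (default 500 expected reads/guide) and inverse-dispersion
`nb_size = 10` (Poisson at `nb_size = ∞`); technical replicates are
independent redraws of the same expectations. All randomness derives from
one seed through per-sample substreams, so output is byte-reproducible and
independent of evaluation order. `fold_coverage` exposes the cells- (or
reads-) per-guide arithmetic used to sanity-check screen scale (e.g. a
70,948-guide library held at 15 million cells per replicate is ~211-fold,
above the usual 200-fold floor).

What the generator does **not** emulate: multiple lentiviral integrations
per cell, guide-efficiency heterogeneity (available as a hook but off by
default — planted effects are inherited identically by a gene's guides),
copy-number artifacts, PCR jackpotting beyond NB dispersion, and
clone-level drift that correlates across arms nonlinearly. Passing tests
therefore demonstrate correctness of the *pipeline arithmetic and its
statistical calibration under this noise model*, not performance on any
particular real screen.

## Interval statistics

Coordinates are 0-based half-open internally (BED convention); conversion
to 1-based inclusive display coordinates is centralized in `to_display`.
Promoter windows default to 4 kb upstream / 1 kb downstream of the TSS
(a 5,000 bp window), oriented by strand (minus-strand windows are the
mirror image; a strand-unaware mode treats every TSS as plus-strand, and
an unknown strand is only accepted with symmetric extents). Windows are
truncated at the chromosome start with a warning. Fragment counting uses
≥ 1 bp overlap; a fragment may count toward several windows.

Fisher's exact test enumerates the hypergeometric support of the observed
margins and sums the probabilities of tables whose point probability does
not exceed the observed one (relative tolerance 1e-7 against ties lost to
floating-point rounding); the enumeration is vectorized so exhaustive
sweeps are cheap. The odds ratio is the sample `(ad)/(bc)`, with the
Haldane–Anscombe +0.5 correction applied iff any cell is zero.

## Assay models

The competitive-proliferation index double-normalizes a marker ratio:
first to its own day-0 value, then to the matched untreated series —
making the index 1 under no drug-specific effect and scale-invariant per
arm. Relative viability is the mean signal over the mean untreated signal.
Dose–response uses a 4-parameter log-logistic
`r = bottom + (top − bottom)/(1 + (dose/IC50)^hill)` fit by bounded
least squares (`bottom ≥ 0`, `top ≤ 1.5` on the untreated-normalized
scale, `hill ∈ [0.2, 10]`, IC50 bounded relative to the dosed range) with
multi-start initialization from dose quantiles and hill ∈ {0.5, 1, 2, 4};
starting IC50s from dose *quantiles* makes the fit equivariant under
rescaling all doses. Flat response data is rejected as unidentifiable
rather than fit; at least 5 distinct doses are required.

## Numerical choices and degenerate inputs

* Trigamma inversion: Newton iteration with the asymptotic guards
  `x ≈ 1/√y` (y large) and `x ≈ 1/y` (y small); converges to ~1e-12
  relative in a handful of steps.
* `0/0` in the moderated t (zero effect with zero posterior variance,
  possible only at `d0 = 0`) is defined as t = 0, p = 1.
* All-identical residuals per gene (e.g. a treated arm scored against an
  identical mock) yield a degenerate complete-pooling prior and zero
  effects rather than an error.
* BH input strictly in (0, 1]; ties share a q-value via stable sorting.
* Loess requires ≥ 10 rows, non-constant A, and a span window of ≥ 2
  points, each with a diagnostic error.

## Problem sizes used in the checks

The behavioural test suite runs the full pipeline at 2,000 genes ×
4 guides × 3 biological replicates with 500 expected reads/guide
(NB size 10): one null screen for calibration (p-value KS statistic,
hit-rate bound) and five seeds with 100 + 100 planted ±1.5 interaction
genes for recovery (recall and empirical FDR averaged over seeds). The
smoother oracle runs on 200-point grids, the BH oracle on 10,000 random
vectors of length ≤ 20, and the exact-test oracle over every 2×2 table
with total ≤ 60. These sizes make the whole suite run in well under a
minute apart from the exhaustive exact-test sweep (~half a minute).

## Known limitations

* Within-guide correlation across biological replicates is ignored in the
  degrees-of-freedom accounting (see stage 8).
* The loess stage assumes the A-dependent bias is smooth and shared
  across a compound's replicates; replicate-specific bias is not modelled.
* The moderated-t prior assumes a single global variance distribution;
  strong variance structure (e.g. by guide abundance class) is absorbed
  only through d0 shrinking toward 0.
* Gene-level effects are treated as exchangeable across a gene's guides;
  no guide-quality weighting is applied.
* IC50s from the 4PL fit are conditional on the chosen functional form;
  interpolation-based definitions will differ when the curve is asymmetric.
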