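# Methods

This note documents the statistical model, the estimators, the synthetic
data the tests run on, and the numerical and design choices a maintainer
would want to know. Notation: two GWAS with per-SNP z-scores $z_1, z_2$
and two-sided p-values $p_1, p_2$ on a common reference SNP set; $N$ SNPs
after harmonization.

## Model and estimators

Each trait's summary statistics are treated as draws from a two-group
mixture: a SNP is null (z standard normal after corrections) or associated.
No parametric form is assumed for the non-null component; all estimators
are empirical tail-area quantities with the null proportion fixed at
$\pi_0 = 1$, which makes every FDR estimate a conservative upper bound.

**Marginal FDR.** $\widehat{\mathrm{FDR}}(p_i) = p_i \cdot N / \#\{j :
p_j \le p_i\}$, clamped to $(0,1]$. Comparisons are inclusive, so ties and
duplicated p-values are well defined (the SNP itself always counts).

**Conditional FDR.** With the conditioning stratum $S_i = \{j : p_{2j}
\le p_{2i}\}$,
$$\widehat{\mathrm{condFDR}}(p_1 \mid p_2)_i
 = p_{1i}\,\frac{|S_i|}{\#\{j \in S_i : p_{1j} \le p_{1i}\}} .$$
The exact per-SNP implementation sweeps $p_2$ in ascending order and
counts joint dominance with a Fenwick tree, inserting tie groups before
querying them ($O(N \log N)$; verified to machine precision against an
$O(N^2)$ counting oracle in the tests).

**Conjunction FDR.** $\widehat{\mathrm{conjFDR}}_i = \max$ of the two
conditional FDRs taken in both trait orders; discoveries are SNPs below
the FDR level (default 0.01 — one expected false positive per hundred
reported findings). The maximum makes the statistic symmetric and
direction-agnostic; it is small only when both traits carry evidence.

**Surface estimation and LD.** LD correlates neighboring SNPs and biases
raw empirical cdfs, so the pipeline evaluates the conditional estimator at
the nodes of a $201 \times 201$ grid of $-\log_{10} p$ breakpoints
(0 to 20 per axis) using only the SNPs kept by one random-pruning pass,
repeats this over an ensemble of pruning masks (default 100), averages
node values across masks, enforces monotone non-increase along the primary
significance axis by cumulative minimum, and assigns every SNP — pruned
ones included — a value by bilinear interpolation in $-\log_{10} p$ space.
Grid nodes beyond the data support take the boundary value (flat
extension): forward fill along the significance axis, then along the
conditioning axis, with a conservative 1.0 only where a mask supports
nothing at all. Monotonization can only lower raw node values, so node
consistency with the exact estimator is asserted on the un-monotonized
surface.

**Random pruning.** "One random SNP per LD block" is operationalized
greedily: visit SNPs in a seeded random order and keep a SNP iff its
$r^2$ with every already-kept SNP is $\le 0.8$. Every kept pair respects
the threshold and every dropped SNP is tagged by a kept one (maximality);
within a block of perfect proxies each member is selected uniformly
across seeds. Ensemble seeds derive deterministically from a base seed.

**Genomic control.** $\lambda = \mathrm{median}(z^2)/0.4549$, clamped
below at 1 (deflation is never "corrected" upward); corrected
$z \mapsto z/\sqrt{\lambda}$ with p recomputed. The constant 0.4549 is the
conventional rounding of the 1-df chi-square median (0.45494); the
estimator is exactly idempotent. Known limitation: on a strongly polygenic
trait the median is shifted by true signal, so genomic control
over-corrects — the standard conservative behavior.

**Sample-overlap decorrelation.** Shared control individuals make the two
traits' *null* z-scores correlated. The correlation is estimated on a
pruned SNP set with $|z| < 2$ in both traits; because restricting a
bivariate normal to a box attenuates its correlation (a true 0.3 yields a
sample correlation of about 0.25 at this threshold), the forward
attenuation map is computed by Gauss–Legendre quadrature and inverted
(Brent's method) to de-bias the estimate. The pair is then whitened by
the symmetric inverse square root of $[[1,\rho],[\rho,1]]$, which
preserves unit marginal variances and the exchangeability of the traits
that the conjunction statistic assumes. A degenerate estimate
($|\rho| \to 1$, e.g. identical inputs) is rejected. The adjustment
assumes the null set is dominated by true nulls; heavy polygenicity
inside the $|z|<2$ box can distort it.

**Region exclusion.** The extended MHC (chr6:29,528,318–33,373,649, hg19)
is excluded by default before surface fitting, and the surfaces are refit
on the remainder; its exceptional LD extent can otherwise dominate the
fit. The nicotinic acetylcholine receptor cluster
(chr15:78,686,690–79,231,478) is available as an optional exclusion, as
are arbitrary BED or `chr:start-end` regions. Coordinates are 1-based
inclusive internally; BED input is converted from 0-based half-open.

**Harmonization.** Alleles are matched to the reference directly, swapped
(z-sign flip), complemented, or complement-swapped (flip); strand-ambiguous
A/T and C/G SNPs are dropped because allele frequencies are not assumed
available to resolve them. When z and p disagree beyond 0.05 in
$-\log_{10} p$ (beyond rounding), z wins and p is recomputed, since z
carries the sign needed downstream. p-values at or below 1e-300 are
clamped before log transforms. A study covering less than 20% of the
reference set fails a coverage gate rather than silently degrading.

**Stratified Q-Q and enrichment.** Q-Q curves of trait 1 are drawn within
nested strata $p_2 < 1, 0.1, 0.01, 0.001$ on plotting positions
$(i-0.5)/n$, per pruning mask, and averaged on a fixed theoretical grid
(masks have different sizes, so raw order statistics do not align);
emission is truncated at $-\log_{10} p = 7.3$ (genome-wide significance)
to focus on the polygenic component — truncation affects display only,
never FDR fitting. Enrichment of a stratum is tested by regressing $z_1^2$
on an intercept, the total LD score, and the stratum-restricted LD score
(weights $1/\max(\ell,1)$); fold enrichment is the stratum's heritability
share over its SNP share, with a delete-one block jackknife (200
contiguous blocks) for the standard error and a one-sided test of
fold > 1. With a stratum containing fraction $f$ of SNPs whose per-SNP
heritability is multiplied by $m$, the true share-based fold is
$m/(1+(m-1)f)$ — the tests therefore plant multipliers on small strata
(1–2%) where this is within a few percent of $m$. A trait whose total
heritability signal is within two jackknife SEs of zero is flagged
non-informative instead of reporting an unstable ratio. Bonferroni
adjustment uses 12 tests by default (four secondary traits × three
strata), the convention for a four-cancer screen.

## Synthetic data

`simulate_panel` builds a block-diagonal LD panel: blocks of `block_size`
SNPs with within-block correlation $\rho_{\mathrm{LD}}^{|i-j|}$ (hence
$r^2 = \rho_{\mathrm{LD}}^{2|i-j|}$), laid contiguously along synthetic
chromosomes 1–22 starting at 29 Mb with 10 kb spacing (so chromosome 6
SNPs genuinely fall in the MHC window once a chromosome holds more than
~53 SNPs). `simulate_gwas_pair` draws causal sets from a four-component
mixture (shared / trait-1-only / trait-2-only / null), shared effect
sizes from a bivariate normal with correlation `effect_corr` (sign-mixed
pleiotropy occurs whenever `effect_corr` < 1), and z-scores by the
infinitesimal mapping $E[z] = \sqrt{n}\,R\,\beta$ with block-wise
correlated noise; overlapping controls enter as a per-SNP noise
correlation `rho_overlap`, and confounding as a multiplicative
$\sqrt{\lambda}$ on z. Per-causal effect variances are set so the causal
contributions sum to the trait heritability; a combination implying
per-causal variance above 1 is rejected. One Cholesky factor serves all
blocks, so simulation is vectorized and linear in SNPs.

Defaults (800 × 25 = 20,000 SNPs, $\rho_{\mathrm{LD}} = 0.9$,
$n_1 = 75{,}000$, $n_2 = 40{,}000$, $h^2_1 = 0.04$, $h^2_2 = 0.02$,
$\pi_{\mathrm{shared}} = \pi_1 = \pi_2 = 0.005$, `effect_corr` = 0.5)
were chosen once to make the desk-scale run *behave* like the real
analyses this workflow is used for: genomic inflation λ ≈ 1.1–1.3,
a null-correlation estimate near zero, clear stratified-Q-Q deflection,
and a handful of conjunction loci at conjFDR < 0.01 with mixed effect
directions. The heritabilities are "effective" values for a 20k-SNP
panel; real GWAS spread comparable per-SNP power over millions of SNPs.
What the generator does *not* emulate: allele-frequency spectra,
liability-scale case-control ascertainment, recombination-map LD, and
long-range LD beyond a block — so passing tests demonstrate estimator
correctness and calibration under block LD, not robustness to every
feature of real data.

## Study conditions used by the test suite

- **Null calibration**: 100 fully null independent pairs of 20,000 SNPs
  with block LD; the mean false-discovery proportion of conjFDR < 0.01
  calls (a replicate with any call scores 1) must stay within 2× the
  nominal level. Residual within-block LD below the 0.8 pruning threshold
  is the dominant source of the rare null discovery.
- **Recovery**: shared-architecture pairs (20,000 SNPs, $n = 50{,}000$
  each, $h^2 = 0.03$ each, $\pi_{\mathrm{shared}} = 0.01$, no
  trait-specific causals, `effect_corr` = 0.9) — per-causal
  non-centrality 7.5, i.e. moderate power. Conjunction calling must keep
  locus-level FDP ≤ 0.2 and out-yield marginal-FDR calling on either
  single trait over true shared blocks. The conjunction's advantage is
  real but conditional: with abundant trait-specific polygenicity the
  marginal empirical cdf is liberalized as much as the conditioning is,
  and single-trait calling can recover more shared loci — the conjunction
  buys specificity (locus FDP near zero) and its yield advantage where
  cross-trait overlap dominates the architectures. The conditional FDR
  alone out-yields the marginal FDR at shared SNPs much more generally.
- **Q-Q ordering**: 100,000 SNPs, $h^2 = 0.08$, $\pi_{\mathrm{shared}} =
  0.05$, purely shared architecture; deflections must be monotone in
  conditioning stringency at every defined grid point beyond theoretical
  quantile 2.
- **Enrichment**: 50,000 SNPs, $n = 100{,}000$, baseline $h^2 = 0.5$,
  2% stratum at 2× per-SNP heritability (true share-based fold 1.96),
  20 replicates; recovery asserted on the replicate mean at the
  jackknife-SE scale.
- Replicate-level tests use pruning ensembles of 5–10 iterations rather
  than the production default of 100 — ensemble size shrinks Monte-Carlo
  variance of the surface but does not move its center, so small
  ensembles are the appropriate problem size for replicated experiments,
  while single production runs keep the 100-iteration default.

## Numerical choices and edge cases

- p-values clamped to $[10^{-300}, 1]$ before logs; FDR values clamped to
  $(0, 1]$.
- Inclusive (≤) comparisons everywhere; the conditioning stratum always
  contains the SNP itself, so no estimator divides by zero.
- Clumping ranks hits by (conjFDR, trait-1 p, SNP id) — fully
  deterministic, input-order invariant; lead SNPs of distinct loci have
  pairwise $r^2 \le 0.2$.
- LD pairs absent from a `.ld` file are $r^2 = 0$ (sparse windowed
  dialect); duplicate pair rows are tolerated when consistent and an
  error when conflicting; $r^2$ outside $[0,1]$ is an error.
- Degenerate inputs: identical z-vectors in overlap estimation, empty or
  full enrichment strata, strata with fewer than 50 SNPs (curve emitted
  but flagged unstable), zero-heritability traits (enrichment flagged
  non-informative), empty discovery sets (empty tables, no error).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline outputs are byte-identical across
  runs at a fixed seed.

## Known limitations

- $\pi_0 = 1$ and ensemble-averaged empirical cdfs make all FDR values
  conservative upper bounds; no local (density-based) fdr variant is
  provided.
- The overlap correction models shared controls as a constant bivariate
  null correlation; it does not estimate per-study intercepts, and known
  overlap counts are not used.
- Genomic control by the median chi-square over-corrects polygenic
  signal; λ is reported in provenance so users can judge.
- The enrichment regression is a two-predictor instantiation of
  stratified LD-score regression; it tests fold enrichment of a stratum,
  not heritability point estimation on real data.
- Whether the strata of the enrichment test should be nested or disjoint
  is a modeling choice; nested strata are implemented, matching the Q-Q
  presentation.
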