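# Methods

This note documents the models, statistics, and design choices behind
`evsort`, and what its synthetic-data experiments do and do not show.

## The paired EV/cell design

The unit of analysis is a gene × sample count matrix over a full
factorial design: Location (EV vs cell-of-origin NSC) × Sex (F/M) ×
ethanol dose (0, 120, 320 mg/dL) × pregnancy (three biological
replicates), 36 samples.  Each EV sample is paired with exactly one
cell sample sharing its (sex, dose, pregnancy) cell; the pregnancy is
treated as a within-subject factor, so dose contrasts are paired over
the six (pregnancy × sex) units.

## Synthetic data generator

Counts are negative binomial with mean μ and variance μ + αμ²
(α = `nb_dispersion`, default 0.05 — mid-range for bulk RNA-seq
biological replicates).  The log2 mean of gene g in sample j is a sum
of:

* a baseline drawn uniformly on `baseline_log_mean_range`
  (default 3–9 log2 units, i.e. typical counts of ~10–500);
* a Location effect (± `location_lfc`, default 2) on a
  `frac_location_de` subset (default 10%);
* a sex effect within one compartment (± `sex_lfc`, default 1.5) on
  compartment-specific subsets (5% EV, 3% cell — EVs carry more
  sex-variance than cells, mirroring the asymmetry the design is meant
  to probe);
* a dose-monotone **sorting** effect: +δ(dose) in EV and −δ(dose) in
  Cell on a `frac_sorted` subset (default 5%), δ = {0, 0.75, 1.5}
  log2 at the three doses.  The symmetric split encodes transcripts
  enriched in vesicles at the expense of the producing cell;
* module structure: `n_modules` (5) blocks of `module_size` (50)
  genes sharing a per-sample latent factor with loading
  `module_factor_sd` (1.0).  The first member of each block carries a
  double loading and the block's highest baseline expression and is
  recorded as the planted hub — a hub is by construction both strongly
  connected and well measured, since kME ranking cannot distinguish a
  high-loading gene whose counts are too low to measure from an
  ordinary member.  Two modules are linked to traits (module 1 to
  Location, module 2 to Sex) by mixing the standardized trait encoding
  into the factor at correlation 0.85;
* a gene × pregnancy random intercept (sd 0.3) shared by all samples
  of a pregnancy, producing the pregnancy-to-pregnancy variation the
  repeated-measures design is there to absorb;
* a per-sample library size factor (log2-uniform on ±1 unless an
  explicit expected-total interval is given).

All planted gene subsets are disjoint (validated), every effect is
recorded in a `GroundTruth` object, and identical configurations
reproduce bit-identically.

What the generator does **not** emulate: count outliers and batch
artifacts, rRNA contamination, gene–gene correlation outside the
planted modules, compositional (library-fraction) coupling between
sorting genes and the rest of the transcriptome, and any real
mouse-genome annotation.  Passing recovery tests therefore show that
the statistics detect the effects they are designed for at realistic
noise levels — not that real EV data will be as clean.

The single-cell generator emulates a sparse clustered matrix: a
background transcriptome (1000 genes, ~0.5 counts/cell) sets the cell
depth and a rare signature (0.02 counts/cell) is elevated 8-fold in the
expressing clusters only.  It models neither droplet chemistry nor
doublets.

## Normalization

Size factors are median-of-ratios: factor_j = median over genes (with a
positive geometric mean across samples) of count_gj / geomean_g,
rescaled to geometric mean 1; if no gene is expressed everywhere the
code falls back to total-count scaling with a warning.  Normalized
values are `log2(count/factor + 1)`.  This shifted log deliberately
replaces regularized-log/VST transforms: every downstream statistic is
correlation- or rank-based (WGCNA) or a paired within-gene contrast
(effect sizes), and is insensitive to the difference, while the
pseudocount keeps zeros finite.  One visible consequence: planted
log-fold effects on genes near the pseudocount scale are slightly
compressed (a 3.0 log2 planted contrast measures ≈ 2.9 through the
pipeline, part of which is also the ~5% of shifted genes leaking into
the size-factor medians).

## Differential expression

The two-group Wald test computes per-gene normalized group means,
a pooled method-of-moments dispersion `α̂ = (v − m)/m²` clipped to
[0, 10] (Poisson floor; the cap avoids degenerate SEs from noisy
moment estimates), adds 0.5 normalized counts to group means before
taking logs, and forms `z = (log2 m₁ − log2 m₂)/SE` with the
delta-method SE `sqrt(Σ_groups (m + αm²)/(n m² ln²2))`.  Genes with all
zeros are reported with p = 1 and flagged.  The test's claims are
calibration claims: measured type-I error under the null design is
≈ 0.04 at n = 9 vs 9 (slightly conservative because the moment
dispersion over-estimates α for low-dispersion genes where negative
moment estimates are floored at zero), and empirical FDR at BH 0.05 on
mixed simulations stays within 1.5× nominal.  It does not implement
GLM factorials, dispersion shrinkage, or independent filtering, and it
makes no equivalence claim to any shrinkage-based DE tool.

## Paired effect-size selection

Hedges' g uses the difference-score standardizer
`g = (mean(d)/sd(d))·J`, `J = 1 − 3/(4(n−1)−1)` — the natural choice
for a repeated-measures contrast where the paired difference is the
quantity of interest (paired standardizers differ between tools; this
one is stated explicitly and oracle-tested).  The CI is normal-theory,
`g ± t_{0.975,n−1}·sqrt(1/n + g²/(2n))`; at n = 6 it differs little
from noncentral-t inversion.  "Non-zero-containing CI" is implemented
as the CI excluding zero — the only reading that yields a selection
criterion.  The joint three-criteria rule is strongly conservative at
n = 6: under the null ~0.5% of genes are selected (the df = 5 critical
value and the g²/(2n) term in the SE widen the interval well beyond
its asymptotic 5% exclusion rate, which simulations confirm is reached
by n ≈ 60).  Selection is monotone in each threshold.

The EV:cell ratio statistic forms `R = log2 EV − log2 Cell` per pair
and applies the same paired dose contrast to R.  Any additive effect
shared by both compartments cancels in R exactly, so ratio selection
has built-in discriminant validity: compartment-shared DE genes are
excluded (≤ 0.4% false positives in simulations) while symmetric
sorting genes are detected with the correct (positive, into-EV)
direction.

## Signed WGCNA

Adjacency `((1 + cor)/2)^β` with β = 14 for the joint 36-sample
network, 9 for single-compartment networks, and 6 for consensus; the
unsigned TOM formula is applied to the signed adjacency (the common
default).  Diagonal conventions: adjacency 0 when computing
connectivity, TOM 1.  Modules come from average-linkage clustering of
1 − TOM with a static branch cut at 0.95 × the dendrogram's maximum
merge height — cutting just below the top merges keeps weakly attached
background genes out of module branches (higher cuts measurably
contaminate planted modules); branches under `min_module_size` (30) go
to grey.  Provisional modules are merged iteratively while any
eigengene pair has dissimilarity 1 − cor below the merge height (0.20;
0.25 for consensus), i.e. eigengenes correlated above 0.8 collapse
into one module.  Merging is idempotent.  Eigengenes are the
unit-variance first principal component of the standardized module
expression, sign-aligned to the module mean profile; kME is the
gene–eigengene correlation, and the hub is the member with maximal
kME (ties broken by gene id).  Module labels follow the conventional
color sequence in decreasing size order, so names are reproducible but
carry no meaning beyond rank.

Soft-power selection regresses log10 p(k) on log10 binned k and picks
the smallest power whose signed R² reaches 0.8 (argmax otherwise).
Note that data with a few equal-sized strong modules has a bimodal
connectivity distribution that no power makes scale-free; the fit
criterion behaves as intended only when connectivity is heavy-tailed
(heterogeneous module sizes, graded memberships), which is how the
relevant test constructs its input.  Fixed-β mode (a one-element
candidate list, or passing β directly) bypasses selection.

## Consensus analysis

The second TOM is power-transformed so its 0.95 off-diagonal quantile
matches the first's, and the consensus is the element-wise minimum
(diagonal reset to 1).  Quantile scaling assumes the TOM tail is
background-dominated, which holds when module pairs are a small
fraction of all gene pairs — as in any realistically sized universe.
Module correspondence uses the two-sided Fisher exact test (sum of all
hypergeometric outcomes no more probable than observed) on the 2×2
membership table per module pair.  The combined module–trait table
keeps sign × min(|r_EV|, |r_Cell|) when the two sets agree in sign and
emits NA when they disagree (an exact zero on either side is
sign-indeterminate and also NA); per-set significance flags are carried
so NA cells significant in one set can be marked.

## ORA and single-cell scoring

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) with BH correction across sets, ordered by gene ratio
(overlap / query genes in any set) then p.  The universe defaults to
the expression matrix's genes, not the collection's union — ORA is
sensitive to this choice, so it is explicit and configurable.

Single cells are normalized as `log2(1 + 10⁴·count/total)`; the
composite signature score is the sum (configurable to mean — only
relative cluster comparisons matter) of normalized values over the
signature, and a cell is "expressing" when its score strictly exceeds
log2 4.  Raising the threshold can only lower expressing fractions
(monotone), and cluster summaries are invariant to cell order.

## Reproducibility

Every stage's randomness flows from one global seed through named
SHA-256-derived substreams, so toggling a stage never perturbs another
stage's draws and all derived seeds stay below 2³¹.  The pipeline
writes a manifest (config snapshot, input hashes, output list) that
suffices for an exact, byte-identical rerun.  Tabular output is TSV
with "." decimals and literal "NA" for missing values.

## Problem sizes

Simulated experiments use 2000–3000 genes × 36 samples for
calibration/PCA/DE checks, 600 genes for network recovery (5 × 50
module genes plus background), and 200–800 cells for single-cell
checks — large enough for stable Monte-Carlo estimates at the default
effect sizes while keeping the full suite and the acceptance script in
the seconds-to-minutes range.

## Known limitations

* The DE stand-in has no factorial/interaction structure; sex and dose
  are analyzed within strata, and the design is not powered for
  sex × dose interactions.
* The static-cut + eigengene-merge module detector is simpler than
  dynamic hybrid tree cutting; it is deterministic and sufficient for
  block-structured synthetic data but will fragment nested or very
  unequal real modules more readily.
* Real-data headline counts from deep 40k-gene datasets are outside
  the scope of the desk-scale simulations; recovery results quantify
  method behavior under the generator's assumptions only.
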