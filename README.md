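# evsort

Statistical toolkit for asking how the RNA cargo of **extracellular
vesicles (EVs)** diverges from the transcriptome of their
**cell-of-origin neural stem cells (NSCs)** — by compartment, by fetal
sex, and under ethanol exposure.  It is aimed at transcriptomics
analysts working with paired EV/cell bulk RNA-seq designs (here: 2
locations × 2 sexes × 3 ethanol doses × 3 pregnancies, 36 samples with
every EV sample paired to its producing cell sample) and at anyone who
wants a compact, fully testable re-implementation of the surrounding
analysis stack.

## What it computes

* **Normalization & PCA** — median-of-ratios size factors, shifted-log
  values, PCA of the most variant transcripts.
* **Differential expression** — a calibrated two-group
  negative-binomial Wald test (method-of-moments dispersion,
  delta-method SE) with Benjamini–Hochberg correction.
* **Cargo-sorting statistics** — the package's centerpiece.  For a dose
  contrast within a compartment, or on the per-pair log EV:cell ratio
  `R_g = log2 EV_g − log2 Cell_g`, genes are selected by three joint
  criteria on n paired (pregnancy × sex) units:

  * paired t-test `p < 0.05`,
  * Hedges' g with `|g| > 0.4`, where `g = (mean(d)/sd(d))·J`,
    `J = 1 − 3/(4(n−1)−1)`,
  * a 95% CI for g, `g ± t_{0.975,n−1}·sqrt(1/n + g²/(2n))`, that
    excludes zero.

  Because the ratio contrast cancels any shift shared by both
  compartments, selection on `R` isolates genuine sorting of
  transcripts into vesicles.
* **Signed WGCNA** — adjacency `a_ij = ((1+cor)/2)^β`, topological
  overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)`,
  average-linkage clustering, eigengene merging, module membership
  (kME), gene/module significance, hub genes, module–trait correlation
  with the Student p-value `t = r√(n−2)/√(1−r²)`.
* **Consensus networks** — element-wise minimum of quantile-scaled EV
  and cell TOMs, module correspondence via Fisher's exact test, and the
  min-abs/NA combined module–trait table.
* **ORA** — hypergeometric over-representation against GMT gene sets.
* **Single-cell signature mapping** — per-cell composite score over a
  signature with a strict `> log2 4` expressing cutoff and per-cluster
  expressing fractions.
* **Synthetic data** — a first-class generator of paired
  negative-binomial counts (variance `μ + αμ²`) with planted location,
  sex, sorting, module, and pregnancy effects recorded as ground truth,
  plus a clustered single-cell generator and GMT collections with
  decoys.

## Worked example

```sh
evsort simulate --out-dir data --n-genes 2000 --seed 7
evsort pca   --counts data/counts.tsv --meta data/metadata.tsv --out pca.tsv
evsort shift --counts data/counts.tsv --meta data/metadata.tsv \
             --mode ratio --dose 320 --out shift.tsv
evsort wgcna --counts data/counts.tsv --meta data/metadata.tsv --out-prefix net/
```

prints

```
wrote 2000 genes x 36 samples to data/
PC1 explains 46.38% of variance
{"comparison": "EV:cell ratio dose 320 vs 0", "n_genes": 2000,
 "n_selected": 100, "n_increased": 98, "n_decreased": 2, ...}
8 modules
```

PC1 carrying ~46% of the variance is the EV-vs-cell axis — the
compartments separate with no overlap.  The ratio-shift line says that
at the 320 mg/dL dose 100 genes pass the three selection criteria and
98 of them moved *into* EVs (the generator plants 100 sorting genes
with a +1.5/−1.5 log2 dose shift, so this is the planted signal being
recovered with two false negatives at this seed).  The module–trait
table written by the `wgcna` step shows the planted structure the same
way:

```
           Location   Sex  Pregnancy  Alcohol
turquoise      0.96 -0.01      -0.01    -0.03
blue          -0.99  0.08       0.03    -0.01
green         -0.13  0.80       0.01     0.02
...
```

with the blue eigengene correlating at r = −0.99 (p ≈ 1e−32, n = 36)
with Location and the green module recovering the planted sex-linked
module (r = 0.80).

`evsort run` executes the whole pipeline (simulate → pca → de → shift →
wgcna → consensus → ora) into one output directory with a JSON manifest
that makes the run byte-reproducible; `evsort ora` and `evsort cellsig`
cover gene-set enrichment and single-cell composite-signature scoring.

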