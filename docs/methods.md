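# Methods

This note documents the models and procedures implemented in `riscmir`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices that
matter for reproducibility.

## 1. qPCR quantification (`riscmir.qpcr`)

### Model

Threshold-cycle values follow the standard exponential-amplification model:
one PCR cycle doubles the product, so a log2 unit of abundance corresponds
to one Ct cycle, with lower Ct meaning higher abundance. The within-animal
contrast of treated versus contralateral dentate gyrus removes animal-level
variation; the fold change for assay *a* in animal *i* is

    FC_ai = 2^-(dCt_treated - dCt_control)

computed on normalizer-relative ΔCt values. Group estimates are arithmetic
means of per-animal folds (a geometric-mean option exists behind a flag;
the arithmetic mean is the default because group summaries of per-animal
folds are conventionally reported as plain averages). The Ago2-IP/input
ratio — the measure of differential RISC association — is likewise formed
within animal (fold in the IP divided by fold in the input) and then
averaged, never from group-level folds: the two fractions come from the
same tissue sample, and pairing them preserves that correlation.

### Normalization

* **Global mean** (default for large panels): each sample's Ct values are
  centred on that sample's mean over all detected assays. This assumes most
  assays are unregulated; the per-sample output mean is exactly 0
  (tolerance 1e-9) and the transform is invariant to per-sample additive
  shifts (pipetting/loading offsets). A warning is emitted below 100
  detected assays per sample, where the "mostly unregulated" assumption
  gets fragile.
* **Reference assay**: ΔCt against a single assay detected in every sample;
  the reference row is removed from the output. Housekeeping-gene
  normalization for mRNA targets is the same operation.
* **Reference selection**: for every candidate detected in all samples, a
  fixed-effects ANOVA of Ct on the experimental design factors (main
  effects only — the model is a stability screen, not an inference target,
  and interaction terms at n = 3–6 per cell would be noise) gives a model
  F-test p; stability means high p and low overall SD. The two criteria are
  combined by rank-sum because no principled composite scale exists between
  a p-value and an SD; ties break by smaller SD, then lexically, for
  determinism. An exactly constant assay gets p = 1, SD = 0 rather than a
  division-by-zero failure.

### Detection filtering

Assays with any missing Ct or Ct strictly above the limit (default 40
cycles, the conventional end of a qPCR run) are excluded from the table
they are filtered on; exactly-40 is retained. Exclusion is contrast-local
by construction — callers filter the subset entering a given contrast — so
an assay undetected only in one condition does not silently poison others,
while an assay undetected in its control samples has no valid fold change
and drops out of that analysis entirely.

### Tests

* Paired two-sided t-test on per-animal ΔΔCt differences, with single-step
  Bonferroni (p_adj = min(1, m·p)) over the panel. Pairing is the default
  because the design is within-animal; an unpaired variant would discard
  the design's main strength. Zero-variance differences with nonzero mean
  are reported as p = 0 with a degeneracy flag rather than an error, so a
  noiseless pipeline run stays inspectable.
* One-way ANOVA with Fisher's (protected) LSD: pairwise t statistics use
  the pooled within-group mean square and its degrees of freedom, unadjusted
  per LSD convention. With two groups, F equals the squared pooled t — a
  property the tests verify numerically.

### Standard curves

OLS of Ct on log10 input quantity over ≥3 distinct dilutions. Efficiency is
10^(−1/slope) − 1 (slope −3.3219 ⇔ 100% efficiency); a non-negative slope is
an error, r² < 0.98 and efficiency outside (0, 1.1] warn. Quantities are
recovered by inverting the line; the fit is per run — pooling curves across
runs assumes equal efficiency, which we do not.

## 2. Consensus target prediction (`riscmir.consensus`)

### Statistic

Within each source, genes are ranked by quality score (best = 1; tied
scores receive the average of the ranks they span — average ties keep the
rank sum fixed and make the column exchangeable under permutation, which
competition ranking would break). Scores are never compared across sources;
each source's rank universe is its own list length. The rank product is the
geometric mean of a gene's ranks over all sources, computed in the log
domain to avoid overflow for long lists.

### Missingness

A gene absent from exactly one source has that rank imputed — by default
the arithmetic mean of its observed ranks, a choice that is neutral with
respect to the gene's own evidence (median and worst-rank+1 alternatives
are available; worst+1 penalizes absence, which conflates "not predicted"
with "predicted badly"). Genes absent from two or more sources are
discarded and counted: with only a minority of sources reporting, the
geometric mean is dominated by imputation, not evidence.

### Null distribution and error control

The null shuffles each source's observed rank column independently over the
genes that source predicts, re-applies imputation, and recomputes rank
products — preserving each source's exact rank distribution and the
missingness pattern. Per gene,

    p_perm(g) = (1 + #{permutations: null RP(g) <= RP(g)}) / (n_perm + 1)

with the +1 pseudo-count so p is never 0; at the default 1000 permutations
the floor is 1/1001. Comparisons use a 1e-9 relative tolerance so exact
rank-product ties arising from integer ranks are not split by log-domain
rounding. Fewer than 100 permutations trigger an "unstable estimates"
warning.

The per-gene p-value is exactly calibrated (a pure-noise gene is uniform —
the tests confirm ~5% of null genes at p ≤ 0.05) but it is a *per-gene*
error rate: selecting "p ≤ 0.05" from 2000 genes admits ~100 false
positives regardless of signal. Classical rank-product software therefore
reports the pfp (percentage of false prediction), an FDR-like quantity:

    pfp(g) = E[#null genes with RP <= RP(g)] / rank(g)

estimated from the pooled null rank products and monotonized from the worst
rank product downward (so a better-ranked gene never carries a larger pfp).
`RankProductResult` carries both quantities. The retention rule applies to
the pfp by default: it is the quantity the established rank-product
packages print, it is the only one of the two under which a
significance-style cutoff controls the false discovery proportion, and it
is the natural reading of a permissive "keep everything not demonstrably
inconsistent" pre-filter. The default rule is deliberately permissive
(keep pfp > 0.5, i.e. drop only genes whose ranking is less consistent
than the null median) so true targets are not eliminated before pathway
analysis; the conventional `le:0.05` rule is a first-class option and is
what the planted-recovery benchmarks use.

Whether imputation should precede or follow permutation is genuinely open;
re-imputing inside each permutation was chosen because it compares each
imputed gene against a null constructed the same way, keeping its p-value
calibrated.

### Ortholog projection

Sources reporting targets in another species are projected through an
ortholog table from which every pair participating in a one-to-many or
many-to-one relation has been removed — direct orthologs only, no
arbitrary resolution. Unmapped genes are dropped and counted.

## 3. Pathway over-representation (`riscmir.enrichment`)

One-sided hypergeometric tail P(X ≥ k) for overlap k between the target
list (n genes, after dropping genes absent from the universe — counting
them as failures would deflate both p and the fold estimate) and a pathway
of K genes in a universe of M. The universe defaults to all genes annotated
to at least one pathway; an explicit universe may override it and must
cover the annotation. Fold enrichment is k/(nK/M). No multiple-testing
correction beyond the p ≤ 0.05 flag by default — the output mirrors the
conventional over-representation report — with an optional
Benjamini–Hochberg column. The tail is delegated to `scipy.stats.hypergeom`
(log-domain internally); the test suite checks it against exact integer
combinatorics and full draw enumeration for small universes.

## 4. Synthetic data (`riscmir.synthetic`)

The generators produce the *statistical structure* the analysis assumes,
with known truth:

* **Prediction sources** (defaults: 2000 genes, 4 sources, 50 planted
  targets, top-5% placement, 10% per-source dropout — the scale of a
  typical per-miRNA prediction download and a planted signal strong enough
  to be recoverable but not trivial): non-planted scores are exchangeable
  uniform noise; planted genes are placed by quantile assignment at random
  positions within the top fraction of each source where present, so the
  stated placement holds exactly rather than in expectation. Dropout
  exercises both the imputation path (one source missing) and the discard
  path (two or more). One source uses a lower-is-better score to exercise
  direction handling.
* **Ct experiment** (defaults: 6 animals per group — the study's qPCR
  validation n — four groups crossing stimulation with NMDAR blockade, two
  fractions, 48 assays as a desk-scale stand-in for a 384-well card,
  σ_Ct = 0.2 cycles, a typical technical SD for replicated TaqMan assays):
  control-side Ct = assay baseline (uniform 18–35) + an animal offset that
  cancels within the pair; treated-side Ct subtracts the planted log2 fold
  change and adds N(0, σ_Ct) noise — additive Gaussian on the cycle scale,
  i.e. log-normal multiplicative on quantity, the standard qPCR error
  model. One designated assay is effect-free everywhere and serves as the
  planted stable reference; AP5 groups carry no effect unless planted,
  making NMDAR-dependence contrasts testable. Not emulated: amplification
  efficiency differences between assays, technical-replicate structure,
  plate effects, or regulation in the contralateral control — so passing
  recovery tests demonstrates correctness of the estimators under the
  stated noise model, not robustness to those real-world artifacts.
* **Pathway database** (defaults: 100 pathways of 40–80 genes from a
  3000-gene universe, 200 targets, planted fold 4): the planted pathway's
  overlap is fixed at round(fold · nK/M) and the remaining targets are
  drawn outside that pathway, so the emitted files reproduce the planted
  overlap exactly; fold 1 degenerates to a fully uniform (null) list.

All generators accept a single integer seed and are bit-reproducible.

## 5. Pipeline (`riscmir.pipeline`, `riscmir.cli`)

One YAML config drives the three stages; every parameter defaults to the
study's stated value (detection limit 40, 1000 permutations, retention
`gt:0.5`, α = 0.05). A single config seed is expanded into per-miRNA
substreams via `numpy.random.SeedSequence`, so adding a miRNA does not
perturb the others' results. The manifest records parameters and per-stage
record counts (read, dropped at projection, discarded by the missing-source
rule, retained) and two runs with the same config are byte-identical.
Unknown config keys fail before any computation. CLI exit codes: 0 success,
2 config error, 3 data/format error, 4 computation error.

## 6. Verification scales and limitations

The test suite and `scripts/acceptance.py` run everything at desk scale:
exact enumeration oracles for the permutation p (3×2 instances) and
hypergeometric tail (universes ≤ 20 plus the 8652/2118760 worked case),
10-seed calibration and recovery runs at 500–2000 genes with 1000
permutations, 20-seed pathway recovery, and 100-seed fold-change recovery
at n = 6 animals. These sizes make every check re-runnable in seconds to
minutes while leaving the planted signals comfortably inside the regimes
the estimators are designed for.

Known limitations: no closed-form rank-product distribution (permutation
only); no per-assay efficiency correction; no mixed-effects Ct models; no
topology-aware pathway statistics; identifier handling is limited to the
supplied ortholog table.
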