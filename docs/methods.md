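# Methods

`vascrisk` scores a candidate drug's cardiovascular-risk similarity from its
transcriptomic response in a two-cell-type vascular model (endothelial cells,
EC, and smooth muscle cells, SMC, profiled separately under atheroprone
conditions).  The pipeline compares the candidate's differential-expression
(DE) profile against a reference database of compound responses measured in
the same system, pathway by pathway, and asks whether the candidate resembles
the drugs that carry cardiovascular-risk boxed warnings.  Because the real
reference database is proprietary, the package ships a synthetic generator
with planted ground truth; every statistical claim the test suite makes is a
claim about that generator's output.

## Pathway similarity

For a query contrast *q*, a reference contrast *r* and a pathway *P*, the
similarity is the Spearman rank correlation (average ranks for ties) of
log2 fold changes over the genes of *P* that are present in both contrasts
and have a DE p-value < α (default 0.05) in *either* contrast.  The engine
evaluates the full Cartesian product queries × reference compounds ×
pathways per cell type.  Design points:

- **min_genes = 5** (floor 3): a rank correlation over fewer points is
  noise; records below the floor are kept with an undefined-ρ marker so the
  Cartesian product bookkeeping never loses a cell, and are excluded from
  every downstream test.
- One **designated treatment per reference compound** — the highest tested
  concentration — enters the product (low-dose responses in this system are
  weak, and mixing doses would double-count compounds).
- Gene identifiers are opaque strings matched exactly after whitespace
  trimming; identifier translation is out of scope.
- The hot loop uses a local average-rank routine (tie-free vectors take the
  classic 1 − 6Σd²/(n(n²−1)) closed form); its agreement with a brute-force
  rank-correlation oracle is pinned by tests over tied and untied inputs.

## Risk association

For each (query, pathway, cell type) the defined ρ values are split by the
references' risk flag and tested twice, both one-sided because the question
is directional (do risk drugs correlate *more*?):

- **Mann-Whitney U**, alternative "risk ρ stochastically greater"; exact
  null distribution for tie-free samples of combined size ≤ 20, normal
  approximation with tie and continuity corrections otherwise.
- **Fisher's exact test** on the 2×2 table (risk flag) × (ρ > 0), one-sided
  for enrichment of risk drugs among positively correlated drugs.  The odds
  ratio is (ad)/(bc) with an infinity marker on a zero denominator.

A pathway is called **shared** when the decision rule holds; the default
rule is Mann-Whitney p < α with Fisher reported alongside, and the
conjunction ("both") or Fisher alone are config options.  No multiplicity
correction is applied across pathways by default — the per-pathway
significance threshold is a nominal p < 0.05 — but Benjamini-Hochberg
across pathways is available (`correction: bh`).  A query that matches a
database compound id is excluded from its own reference set.

The **shared-pathway count** per query and cell type is the headline
summary.  Its null reference is the central 99% interval of
Binomial(n_pathways, α) — the count distribution expected if every pathway
test were an independent α-level coin.  The **gene-name randomization
control** permutes the query's gene labels against its statistics rows
(preserving the full multiset of fold changes and p-values) and re-runs the
engine; 100 randomization seeds by default.

## Differential-expression stand-in

Reference pipelines for this kind of data fit negative-binomial GLMs with
dispersion shrinkage.  This package deliberately uses a simpler, fully
specified recipe — CPM normalization, log2 fold change with a 0.5 prior
count, Welch's t-test on log2(CPM + 0.5), Benjamini-Hochberg FDR — because
the DE stage is plumbing here, not the contribution: it must be
deterministic, transparent, and honour the contrast-table contract that the
similarity and classification stages consume.  DEG counting uses FDR ≤ 0.10.
Genes with zero variance in both groups get p = 1 when the means agree
(p = 0 otherwise, the infinite-t limit).

## Synthetic database generator

The generator emulates the reference screen: 111 compounds (107 clinical
stage, 33 risk-flagged), two cell types, 4 replicates per treatment, one
shared vehicle-control replicate group per cell type, and an
atheroprone-vs-atheroprotective baseline contrast.  The generative model is
described in `vascrisk.synth`; the key choices:

- **Gene loading vectors per pathway, scaled by per-compound activations.**
  A latent pathway signature must live at the *gene* level for rank
  correlations between compounds to carry signal; a constant pathway-level
  shift plus independent gene noise would correlate at zero.  Risk compounds
  agree with the planted signature's activation sign on each of the 10 risk
  pathways with probability (1 + signature_corr)/2 (default 0.95); all other
  activations are independent N(0, 1) draws.
- **Calibration in closed form**: the loading standard deviation is chosen
  so a fully activated pathway gene has E|log2FC| = effect_size (default
  1.0) after adding N(0, noise_sd²) gene noise (default 0.3).  When
  effect_size is small relative to noise_sd the loading clips at zero and
  the planted signal vanishes — the null configuration.
- **Gene noise is idiosyncratic per compound**, so even the null
  configuration (effect_size = 0) produces real, compound-specific DE.
  This matters: the p < 0.05 gene filter then passes enough genes for ρ to
  be defined, while cross-compound correlations remain exactly null — the
  configuration under which the engine's false-positive rate is measured.
- **EC attenuation 0.25**: the planted risk structure is an SMC phenomenon;
  EC carries the same activations scaled down, keeping the two-cell-type
  plumbing honest without making EC a second positive control.
- **Counts** are negative-binomial (dispersion 0.05, library size 5×10⁶)
  around depth × baseline × 2^log2FC, with a log-normal baseline abundance
  profile; contrasts are computed through the DE stage so emitted tables
  carry realistic estimation noise.
- **Side-effect labels** threshold a linear function of the SMC pathway
  activations at the median (balanced classes), flipped with probability
  label_noise (default 0.05).  The first side effect ("arteriosclerosis")
  loads on the risk pathways and is therefore learnable from the features.
- **Query profiles**: `risk_like` activates every risk pathway exactly as
  the signature does (a febuxostat-like compound); `neutral` draws small
  independent activations (sd 0.15) everywhere, emulating a
  transcriptionally quiet compound with no coherent risk-pathway response
  (an oxypurinol-like compound).  The neutral scale is deliberately small:
  under the planted model *any* sizeable positive activation of a risk
  pathway is genuinely risk-correlated, so a "neutral" compound must be
  quiet on those pathways, not merely uncorrelated on average.
- All randomness flows from one seed through named `SeedSequence` child
  streams (structure, activations, gene noise, counts, labels), so
  identical configs reproduce byte-identical databases.

What the generator does **not** emulate: overlapping pathway membership
(disjoint by default; a Reactome-like overlap option exists but planted
truth is then ambiguous), compound-specific dose-response shapes, batch
effects, correlated gene-gene noise within pathways beyond the shared
loading, and any real biology of the perturbations.  Passing tests
demonstrate that the *statistical machinery* is calibrated and recovers
structure it was told to plant — not that the method would reach the same
conclusions on real vascular RNA-seq.

## Side-effect classifier harness

Features per compound are the per-gene log2 fold changes and log2 mean
expression values from both cell types' designated contrasts.  Evaluation is
bootstrap cross-validation: each of 150 bootstrap iterations draws a fresh
stratified 80/20 train/test split, resamples the training side with
replacement (stratified), selects features *inside* the training portion
only, fits, and scores the held-out treatments by AUC.  The per-model score
is the mean bootstrap AUC and the best model per side effect is the arg-max
(ties broken lexicographically and logged).

- **Feature selection**: genes DE (FDR ≤ 0.10) versus the atheroprone
  control in ≥ 10% of training treatments; both feature kinds of a selected
  gene enter.  An empty selection falls back to top-k training variance
  (logged).  A `max_features` cap (default 2000, keeping the most frequently
  DE genes) bounds the fit cost; with ~2000 informative-ish genes the cap
  binds rarely and deterministically.
- **Models**: lasso and ridge logistic regression (liblinear), elastic-net
  logistic loss (SGD), linear- and RBF-kernel SVMs, random forest, kNN.
  Continuous features are z-scored with training-fitted parameters for all
  but the random forest.  Hyperparameters come from small fixed grids tuned
  by inner stratified k-fold CV (k = 10 by default, reduced when a class is
  too small) on the training portion only.
- **Permutation null**: with `permute_labels=True` the labels are freshly
  permuted at every bootstrap iteration, so the 150-bootstrap mean AUC is a
  Monte-Carlo estimate of the permutation-null expectation (0.5).  A single
  fixed permutation is *not* a reliable null here: it can align by chance
  with the dominant risk-signature cluster in the features and shift the
  whole mean by ±0.05.
- A bootstrap whose fit fails is recorded as NaN and excluded from the mean
  with a warning; splits are derived from the seed alone so all models see
  identical resampling (paired comparison).

## Numerical and interface choices

- TSV everywhere (tab-separated, UTF-8, header mandatory, "." = missing);
  GMT for pathway sets; YAML for run configuration with every analysis
  constant (α = 0.05, FDR ≤ 0.10, k = 10, B = 150, 100 randomization seeds)
  as a config default.
- Pipeline outputs are byte-reproducible for a fixed config and seed; the
  run manifest records config echo, seed, versions, per-stage counts and
  timings.
- Undefined statistics are markers (None / NaN / ±inf), never exceptions:
  empty label groups, all-tied ranks, zero-denominator odds ratios and
  single-class AUCs all degrade to excluded records.

## Problem sizes used by the test suite

The acceptance-level tests run the generator at the reference composition
(111 compounds, 2000 genes, 100 pathways).  Null calibration uses 500
simulated neutral queries against the null database; the randomization
control uses 100 seeds; oracle-equivalence tests sweep 1000 random vectors
per primitive and every small contingency table (N ≤ 12).  Unit tests use a
12-compound database, which is deliberately underpowered — power properties
are only asserted at the reference scale.

## Known limitations

- The DE stand-in is not a negative-binomial GLM; its p-values are
  anti-conservative for very low counts and it applies no TMM-style
  compositional normalization.
- Disjoint pathways make planted-truth recovery unambiguous but easier than
  the heavily overlapping Reactome hierarchy.
- The shared-pathway decision rule (Mann-Whitney alone, nominal p < 0.05)
  is one of several defensible readings; the count it produces is sensitive
  to that choice, which is why the rule is a config option.
- Bootstrap-resampled training sets contain duplicates; penalized models
  see mildly optimistic effective regularization as a result, identically
  across the compared models.
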