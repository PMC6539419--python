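# Methods

## Data model

All stages operate on an `AbundanceMatrix`: a features × samples table of
finite, non-negative measurements (metabolite peak areas or expression
units) with a staged, replicated `SampleDesign` (default NEC/PEC/GE × 3
replicates) and per-feature annotations (name, compound class, KEGG-style
pathway ids).  Tables are UTF-8 TSV with a header row; sample columns are
aligned to the design **by identifier, never by position**.  Missing cells
are not allowed: zeros are legal measurements and are handled by an
explicit imputation step, keeping I/O validation strict.  Feature ids are
case-sensitive opaque strings (metabolite ids mix `pmb`/`pme`/`pmc`/`pmd`
prefixes; genes look like `Gh_D05G1280`).

## Differential accumulation

A contrast is a `ComparisonSpec` (test stage over reference stage; the
canonical three are PEC:NEC, GE:PEC, GE:NEC).  For each feature:

* **Fold change** on imputed raw-scale stage means, FC = mean(test)/mean(ref),
  with log₂FC = log₂(FC) exactly.  Zeros are first replaced by half the
  global minimum positive value (`half_min_positive`, default) or an added
  pseudocount.  Raw-scale ratios are used because published fold-change
  tables are raw-scale; normalisation is applied only to the multivariate
  models.
* **PLS-DA VIP** from a two-class PLS-DA fit on log₂(x+1),
  mean-centred, unit-variance-scaled replicate profiles.  Components are
  extracted by sequential NIPALS (univariate response −1/+1):
  w_a ∝ X_a'y with ‖w_a‖ = 1, t_a = X_a w_a, loading p_a = X_a't_a/t_a't_a,
  response coefficient b_a, deflation X_{a+1} = X_a − t_a p_a'.  The sign
  convention (first non-zero weight entry positive) and input-order
  tie-breaking make fits deterministic.  VIP uses the Wold formulation over
  all extracted components with SSY_a = b_a² t_a't_a, giving the exact
  identity Σ VIP² = p that the tests assert.  Default `n_components = 2`;
  extraction truncates with a warning when the residual rank is exhausted.
  VIP is computed per two-class contrast, not across all three stages.
* **Welch t-test** (default; Student optional) on log₂(x+1) values,
  two-sided.  Degenerate zero-variance-both-groups features get p = 1 when
  the means agree and p = 0 otherwise, by convention.

Status assignment is inclusive at the boundaries exactly as the thresholds
are written: up ⇔ FC ≥ 2 and VIP ≥ 1; down ⇔ FC ≤ 0.5 and VIP ≥ 1.  The
p < 0.05 filter is **on by default** and can be disabled
(`--no-p-filter`): the two published statements of the rule differ on
whether the p criterion applies, so both behaviours are reachable.  Genes
use |log₂FC| ≥ 1 with BH FDR < 0.05 instead of VIP; precomputed
differential-gene tables are accepted and passed through.

Descriptive summaries: three-way Venn partition into the 7 disjoint
regions; compound-class census (unannotated features count as "other",
fractions sum to 1); hierarchical clustering with 1 − Pearson r distance
and average linkage on log₂(x+1) profiles for heatmap ordering, with
constant rows pinned at the maximum distance 2.0.

## Pathway enrichment

One-sided over-representation: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), where N is the annotated detected background,
K the pathway's background members, n the annotated differential features
and k the differential members.  This equals a one-sided Fisher's exact
test on the 2×2 table.  The background is all detected features carrying at
least one pathway annotation — self-contained and conventional — not an
external pathway universe, so counts are reproducible offline.  Multiplicity
is controlled with Benjamini–Hochberg (the default reading of "FDR"),
significance at FDR < 0.05.  The reported enrichment factor is
(k/n)/(K/N); a k/K variant is exposed via `factor_definition="hit_ratio"`
since plot conventions differ.  Pathways with k = 0 are omitted; results
sort by p with ties broken by pathway id.  Co-mapped pathways are the
intersection of the metabolite-side and gene-side enrichment vocabularies
(k ≥ 1 on each side), reported with both results attached.

## Association and networks

Pearson correlation of log₂(x+1) profiles over the samples of the two
compared stages.  Two modes:

* `replicates` (default): all replicates of both stages (6 points in the
  default design).  This is the statistically meaningful mode.
* `stage_means`: the two stage means only.  Any non-degenerate pair then
  yields exactly ±1 — degenerate as a statistic, but it is the only mode
  consistent with curated pair tables that print PCC values of exactly ±1,
  so it is provided for compatibility.

Pairs with a zero-variance profile are excluded with a logged reason, never
imputed.  The nine-quadrant class is the exact 3×3 map
(metabolite status, gene status) → {1..9} with (up,down)→1, (up,up)→3,
(unchanged,unchanged)→5, (down,down)→7, (down,up)→9 and so on; quadrants
3/7 are co-directional, 1/9 discordant.  The network keeps pairs with
|PCC| **strictly** greater than the threshold (default 0.8), signs edges by
the correlation sign, and takes nodes from passing edges only; construction
has set semantics (idempotent, order-independent).  Exports: GraphML
(round-trippable, node `kind` and edge `sign`/`pcc` attributes), SIF with
`pos`/`neg` interactions, and a flat edge TSV.

The shipped curated pair tables are verbatim transcriptions, including one
internally inconsistent printed row (a gene with positive log₂FC but
PCC = −1 against upregulated metabolites); transcription fidelity is
preferred over correction.

## Quality control

Sample–sample Pearson correlation across features and PCA of the
samples × features matrix, both on log₂(x+1) by default (peak areas span
orders of magnitude; the original normalisation is unspecified, so both
raw and log transforms are exposed, as are centring and unit-variance
scaling for PCA).  Variance fraction of component k is σ_k²/Σσ² from the
SVD; fractions over all components sum to 1.  Constant sample columns
yield explicitly undefined (NaN) correlation entries rather than silent
zeros.  Pooled QC "mix" samples are supported as an extra stage label but
not required.

## Synthetic data

The generator emulates the study design: 581 metabolites and 2000 genes
over NEC/PEC/GE × 3 replicates.

* **Baselines**: per-feature log-normal, natural-log mean 13.8 (≈10⁶ peak
  area units) and sd 1.5.
* **Noise**: multiplicative log-normal per replicate with
  sd = ln(1 + CV); default CV = 0.1, a free choice since replicate scatter
  is not recoverable from printed values.
* **Planted effects**: per contrast, blocks of features multiplied by
  2^(log₂ effect) in the test stage (default |effect| = 3, the weakest
  regime the recovery guarantees are stated for).  Default planted counts
  (50/15 up/down for PEC:NEC, 40/20 for GE:PEC, 50/15 for GE:NEC) are a
  deliberately scaled-down differential load: planting the full published
  DAM counts would require a jointly constrained three-stage effect matrix,
  whereas disjoint moderate blocks keep each feature's truth unambiguous.
  Ground truth is therefore **derived from the realized stage-effect
  matrix**, not from the planting list: a feature perturbed in PEC for the
  PEC:NEC contrast is truthfully "down" in GE:PEC, and truth stays
  consistent with the emitted matrices by construction.
* **True zeros**: a fraction (default 0.02) of unplanted features have
  their first-stage baseline set to exactly 0 (plus optional per-effect
  `zero_reference` planting).  After half-minimum imputation these produce
  the 10⁴-scale fold changes seen in real widely-targeted data; truth marks
  them "up" wherever the zeroed stage is the reference.
* **Classes**: compound-class labels apportioned by the deterministic
  largest-remainder rule from the published census mix (amino acids 15%,
  flavones 15%, organic acids 12%, lipids 11%, nucleotides 10%, remainder
  "other").
* **Pathways**: planted over-represented pathways draw a specified number
  of members from the first contrast's true differential set; every feature
  additionally gets 0–2 background pathways from a pool of 30.
* **Pairs**: planted gene–metabolite couplings overwrite the gene's log₂
  profile with an affine transform (slope ±1) of the metabolite's log₂
  replicate profile plus noise, so the replicate-level PCC converges to the
  target sign exactly as CV → 0.

What the generator does **not** emulate: chromatographic/instrument drift,
batch effects, missing-at-random dropout, correlated noise between
features, pooled QC samples, or realistic pathway topology.  Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not performance on real LC-MS
data.

## Numerical choices and determinism

* Hypergeometric tails via scipy's survival function (log-space stable);
  verified against exact rational enumeration to 1e-12 for all population
  sizes ≤ 60.
* BH adjustment via statsmodels, input order preserved.
* log₂(x+1) is the single transform used everywhere a log scale is needed,
  so zero-containing profiles never need special-casing downstream of
  imputation.
* Every stochastic component takes an explicit seed; one run seed drives
  the whole pipeline, and identical config + seed reproduces byte-identical
  result bundles (the manifest stores the config hash and record counts;
  timing goes to stderr only).
* Worked-table comparisons use "printed precision": half a unit in the last
  printed decimal of the log₂FC plus the propagated half-ulp of the fold
  change itself, which is printed to 3 significant figures.  Two of the 25
  table rows differ from naive re-rounding only because of that FC
  rounding.

## Problem sizes used in checks

Recovery metrics are computed at the full study design (581 metabolites,
3 × 3 samples) over 20 generator seeds for sensitivity/FDR and pathway
recovery, and over 50 seeds at 300 metabolites for the no-signal pathway
false-positive rate — sizes chosen so the whole verification suite runs in
seconds while the averages are stable.

## Known limitations

* With 3 replicates per stage the Welch test is low-powered; the default
  p-filter can suppress genuinely large fold changes with noisy replicates.
* `stage_means` correlation is sign-only information; treat those networks
  as qualitative.
* PLS-DA VIP depends on the number of components; the Σ VIP² = p identity
  holds for any choice, but individual rankings can shift between 1 and 2
  components.
* Enrichment assumes exchangeable features; hierarchically related
  pathways are tested marginally without topology awareness.
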