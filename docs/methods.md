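# Methods

## Data model

The unit of analysis is a **feature table**: 27 protein extracts (codes
`A1`–`A9` animal, `D1`–`D9` dairy, `P1`–`P9` plant) by quantitative
variables carrying a unit and a variable-set tag. The packaged dataset
has 51 columns: 34 active composition variables (macronutrients, eight
minerals, vitamins A and C, TBARS and carbonyl oxidation markers, and an
18-amino-acid aminogram), 7 gastric-phase and 7 intestinal-phase
digestate variables (Biuret protein, Direct Detect peptides,
fluorescamine free NH₂, ABTS/FRAP/DPPH % inhibition, ORAC), and 3
excluded bookkeeping columns (dry matter and the two aminogram totals,
which are linear combinations of other columns and belong to no latent
variable). Cell values are means of triplicate assays; cells printed as
"n.r." (not retrieved — 25 cells: 7 complex-carbohydrate, 14 vitamin-A,
4 TBARS) are masked, with the original token kept.

## Missing values and standardization

The default missing policy is `zero`: a not-retrieved analyte is treated
as absent/below detection, which is the natural reading for retinol in
non-plant extracts assayed by a plant-specific method. `column_min` and
`column_mean` are available because the choice is a judgement call; on
columns without masked cells all policies are bit-identical.
Columns are standardized to mean 0, sample (n−1) sd 1. The sd convention
is irrelevant to everything downstream (Pearson distance and k-means
partitions are invariant to uniform column rescaling); it is fixed purely
for reproducibility. Zero-variance columns are an error, reported by
name.

## Variable clustering

Dissimilarity between variables is the Pearson distance d = 1 − r
(range 0–2), computed on the standardized matrix. Agglomeration uses
Ward's minimum-variance criterion via the Lance–Williams recurrence

    d(a∪b, x) = [(n_a+n_x) d(a,x) + (n_b+n_x) d(b,x) − n_x d(a,b)] / (n_a+n_b+n_x)

in two dialects: `d` (default) applies the recurrence directly to the
dissimilarities — the historical formulation used by several legacy
statistics packages — while `d2` applies it to squared dissimilarities
and reports square-root heights (the variance-minimizing formulation;
equivalent to scipy's `ward` on a condensed matrix, against which it is
cross-checked). On the packaged dataset the `d` dialect reproduces all
15 published latent-variable member sets at the default cuts
(9 composition, 3 gastric, 3 intestinal); `d2` differs only in placing
lysine with the large protein/amino-acid block rather than with
Thr/Ile/Val/Leu. Ties in merge height are broken toward the pair with
the smallest cluster indices (leaves first, then creation order), making
trees platform-deterministic. Cutting removes the k−1 highest merges;
cuts are nested in k by construction. Cluster counts per variable set
are configuration (defaults 9/3/3); no automatic cut-height selection is
attempted because no selection criterion is defensible at n = 27.

Heat-map seriation clusters both axes the same way; leaf order is the
plain left-subtree-first traversal (no optimal leaf ordering — only
determinism is required).

## Leveling

Each latent variable is discretized by k-means on its standardized
member columns with k ∈ {2, 3}, 50 restarts, k-means++ seeding from a
fixed base seed (1499). At n = 27 and k ≤ 3 this reliably finds the
global optimum of the within-cluster sum of squares (verified against an
exhaustive-partition oracle on small instances). Clusters are ordered by
the unweighted mean of their centroid coordinates in z-space and
labelled H/(M)/L; exact score ties fall back to cluster size (larger =
higher), and a complete tie is an error. The per-latent k defaults to
the published choice (3 for BiuretORAC_G, Peptides_I, Antiox_I, TIVLK,
and the Cys/Trp block; otherwise 2) and is overridable.

A reproducibility caveat: re-leveling the packaged dataset reproduces
the published partitions exactly for 6 of the 15 latent variables —
including both worked examples (the 15-extract high-protein class of
Prot_HFDSEP and the 5-extract high class of TIVLK) and the published
small-class exclusions — but not for the remainder, where the original
software's k-means evidently converged to different (sometimes
non-optimal, e.g. the calcium block's D3) partitions that cannot be
recovered from the printed means under any preprocessing we examined
(standardized, raw, or 1-D block averages). Regression tests therefore
pin the reproducible partitions and the published reference table, not
full re-derivation of every row. Two further published rows print their
Medium and Low columns inverted relative to centroid magnitude; the
packaged reference preserves the print, and comparisons are made on
partitions and high classes.

## Small-class filter and MCA

Before MCA, any latent variable with a level held by ≤ `min_class_size`
extracts (default 2) is dropped: in the chi-square metric a rare
category receives mass 1/c_j and would dominate an axis by itself. On
the published assignments this removes exactly the vitamin-A/oxidation
and Cr/K/Na/Gly/Ala blocks, leaving Q = 13 latent variables and J = 31
categories. (The original factor-map caption counts 30 categories; the
published table yields 31, and the implementation reports what it
builds.)

MCA is computed as plain correspondence analysis of the indicator
matrix: P = Z/ΣZ, row/column masses r and c, SVD of
D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; eigenvalues are squared singular values,
truncated at 1e−12; principal coordinates follow the standard transition
formulas (checked to 1e−8 in tests). Total inertia is (J − Q)/Q and
percent inertia is the raw share 100·λ_s/Σλ — no Benzécri/Greenacre
correction, matching the convention of the R package used in the
original analysis (the published 21.38 + 15.29 = 36.67 is consistent
only with raw shares). Axis signs are fixed by making the
top-contributing category positive on each axis. On the published
assignments this yields 21.38% / 15.29% on the first two axes.

The screening report groups extracts by their dim-1/dim-2 sign quadrant,
with a configurable dead zone (default |coord| < 0.25 on both axes →
"center", i.e. undifferentiated). The dead-zone radius is a free
parameter; no principled value exists.

## Synthetic data

The generator emulates the statistical structure the workflow assumes:
b independent variable blocks, each driven by one latent factor;
variable value = loading · offset(planted level) + noise_sd · ε with iid
standard-normal ε, all randomness from one seed. Defaults mirror the
study's shape: 27 extracts in three origin groups, blocks of 3–5
variables, loading 0.9, noise sd 0.3, level offsets in sd units (3-sd
gaps make leveling unambiguous). It does **not** model heteroscedastic
assay noise, unit heterogeneity, cross-block correlation, or missingness
— the workflow standardizes everything, so recovery tests exercise the
clustering/leveling/MCA chain, not robustness to real assay artefacts.
Passing recovery tests (variable-partition ARI = 1, exact level
recovery, axis-1 sign separation of planted groups) show the chain is
correct on data satisfying its assumptions, not that the latent blocks
in any real dataset are as clean.

## Problem sizes and determinism

Everything is small: matrices are 27 × ≤48, trees ≤48 leaves (the O(n³)
linkage is instantaneous), k-means is 50 restarts at n = 27, MCA is an
SVD of a 27 × 31 matrix. The full workflow runs in about a second;
oracle-equivalence test batches (100 random linkage instances, 100
exhaustive k-means enumerations, 50 CA eigendecompositions) complete in
seconds. Reruns with a fixed configuration are byte-identical, which is
asserted on the persisted outputs.

## Known limitations

- The published k-means partitions are only partially reproducible (see
  Leveling); the workflow documents and pins what is.
- The Ward dialect of the original software is undocumented; `d` is the
  default because it reproduces the published member sets, `d2` is one
  switch away.
- No supplementary individuals/variables in MCA, no fuzzy level
  membership, no k > 3, no bootstrap support on dendrograms.
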