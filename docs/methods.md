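# Methods

This note documents the models and procedures implemented in `pfcnet`, the
parameter defaults and why they were chosen, the numerical conventions, what
the synthetic-data generator does and does not emulate, and known
limitations.

## Sequence similarity network and clusters

Proteins are nodes; an edge joins two proteins whose best pairwise hit
passes **identity ≥ 80 %** and **coverage ≥ 80 %**, the threshold pair
commonly used in similarity-network studies of protein families.
Conventions:

- *Coverage side.* Coverage is stored per sequence (alignment columns ÷
  sequence length × 100, clamped at 100).  The threshold is applied to
  **both** sides by default (mutual coverage), the conservative reading; a
  `coverage_mode` switch (`both | query | either`) supports sensitivity
  checks.
- *Inclusive comparisons.* Thresholds use ≥, so an 80.0/80.0 hit is kept.
- *One hit per pair.* Reciprocal and duplicate hits collapse at read time to
  the single hit with the highest percent identity.
- *Cluster numbering.* Components of size ≥ 2 are sorted by their smallest
  member id and numbered 1..k, so ids are deterministic.

A desk-scale all-vs-all Smith–Waterman (BLOSUM62, gap open 11, extend 1, via
Biopython's `PairwiseAligner`) substitutes for an external search tool on
small catalogs.  Percent identity is identities ÷ alignment columns × 100.

## Functional homogeneity and dark clusters

For a cluster of `N_prot` proteins whose members carry `N_annot` unique
annotation terms in a database (KEGG orthologs or eggNOG descriptions):

    N_annot = 1        ->  F_hom = 1
    N_annot > 1        ->  F_hom = 1 - N_annot / N_prot   (floored at 0)
    N_annot = 0        ->  F_hom undefined (missing)

Unannotated members count in `N_prot` (the cluster size) but contribute no
terms; when multi-term proteins push `N_annot` above `N_prot` the score is
floored at 0 to keep the [0, 1] contract.  Clusters scoring below 0.8 (or
0.5) in *both* databases are tagged `low_08` / `low_05` but never excluded:
eggNOG descriptions in particular can name the same function differently,
deflating scores artifactually.

A cluster is **dark** when both functional scores are missing and no member
MAG is annotated below the phylum level.  Dark-vs-other abundance is
compared per sample with a two-sided Wilcoxon rank-sum test: exact null
enumeration when both groups have ≤ 8 tie-free observations, otherwise the
tie-corrected normal approximation; a sample where every abundance is
identical reports p = 1 and is flagged degenerate.

## Abundance normalization

    abundance[g, s] = count[g, s] / (gene_length_nt[g] * total_reads[s]) * scale

with `scale = 1e9`.  The divisor is each sample's **total sequenced reads**
(mapped + unmapped): environmental metagenomes differ strongly in both depth
and mapping rate, and a within-mapped (TPM-style) normalization would
inflate samples where few reads map.  Gene length is in nucleotides.
Cluster abundance is the arithmetic mean over member proteins per sample.

## Environmental curation

Order: **filter → scale/center → impute** (defaults in `PrepConfig`).

- *Near-zero variance*: a variable (or cluster profile) is flagged when the
  percent of distinct values is below 10 **and** the most-common /
  second-most-common frequency ratio exceeds 95/5 = 19 (single-valued
  vectors always flagged).  The conjunction is the convention of the
  standard preprocessing tools; an `or` mode exists for the stricter
  disjunctive reading.
- *Correlation filter*: greedily, while any quantitative pair has |Pearson
  r| > 0.90 (the common preprocessing default), the member with the larger
  mean absolute correlation to the remaining quantitative variables is
  dropped.  Qualitative variables are exempt.
- *Scaling*: observed entries of each quantitative variable are centered and
  scaled to sd 1 (n − 1 denominator); qualitative variables untouched.
- *Imputation*: each missing cell is replaced by the mean of that variable
  over the **k = 5 nearest samples** having it observed.  Sample distance is
  Euclidean over quantitative variables observed in both samples, divided by
  the number of shared variables; qualitative variables do not enter the
  metric.  Distance ties break by sample-id order, making imputation
  deterministic.  This imputer is written in-package because the stated
  rule (shared-variable-normalized distance, neighbor filtering on the
  target variable, ordered tie-breaks) differs from generic k-NN imputers.

## Random-forest environmental screen

Per cluster profile `y` over samples, with the curated environmental table
as predictors (qualitative variables one-hot encoded, all levels kept —
forests need no reference level; recorded in the result metadata):

- 10 repeats (default); each draws a random **75/25 train/test split**,
  rounding the training size up (93 samples → 70).
- Within the training set, `mtry` (features tried per split) is tuned over
  **{5, 6, 7, 8, 9}** by **5-fold cross-validation minimizing RMSE**; the
  conventional default `mtry = floor(sqrt(p))` is 7 at 52 predictors, so the
  grid brackets it.  Forests use **500 trees**.
- Metrics follow the resample-averaged convention of caret-style training
  frameworks: R² is the squared Pearson correlation between held-out-fold
  predictions and observations, averaged per fold and then over folds and
  repeats (`r2_definition="sse"` switches to 1 − SSE/SST).  The winner is
  refit on the full training set for the test-set R².
- Variable importance is permutation importance on the test set: each
  original variable's column block (dummy columns jointly) is permuted 3
  times and the mean MSE increase converted to ranks 1..v per repeat (ties
  keep variable order); ranks average over repeats.  The grouped permutation
  is implemented in-package because off-the-shelf permutation importance
  permutes single columns, which splits a factor's importance across its
  dummies.
- Classification uses strict thresholds on the mean CV R²: > 0.5 → `hle`
  (highly linked to environment), > 0.25 → `linked`, else `none`.
- A repeat whose training response is constant records R² = 0 and is
  flagged.

`ScreenConfig.scaled()` (3 repeats, 100 trees, same protocol otherwise) is
the desk-scale profile used by the pipeline default and the test suite; the
full 10 × 500 profile is `ScreenConfig()`.

## Constrained correspondence analysis

Given the non-negative response table `Y` (samples × clusters) and design
`X` (qualitative variables one-hot encoded dropping the first level):

1. `P = Y / total`; row masses `r`, column masses `c`;
   `Q = (P − r cᵀ) / sqrt(r cᵀ)`.  Total inertia = ΣQ².
2. `X` is r-weighted-centered and row-weighted by √r; linearly dependent
   columns are dropped greedily (earlier columns preferred) with a warning.
3. `Q` is least-squares-projected onto the weighted design; the SVD of the
   fitted part gives eigenvalues (squared singular values, summing to the
   constrained inertia) and scores.
4. Scores are reported in species-focused scaling: feature scores
   `V · d / √c`, site scores `U / √r` (unit-inertia linear-combination
   scores), biplot scores = r-weighted correlations of design columns with
   site scores.  Each axis is oriented so its largest-magnitude biplot score
   is positive (SVD signs are arbitrary).

Eigenvalues and inertias agree with R's `vegan::cca` to ~1e-10 (checked in
the test suite against both vegan and an explicit eigendecomposition
oracle).  The CCA is implemented in-package because the pipeline needs the
inertia decomposition, the permutation scheme below, and a stepwise AIC not
exposed together by existing wrappers.

- *Permutation test*: sample rows of `X` are permuted;
  `p = (1 + #{perm stat ≥ observed}) / (1 + n_perm)` with the
  constrained-inertia fraction as statistic.
- *Stepwise selection*: bidirectional greedy search on
  `AIC = n·log(residual_inertia / n) + 2(k + 1)`, `k` = fitted constraint
  columns (0 for the empty model).  Each sweep tries forward additions
  first, then backward drops, and stops at a fixed point; ties break by
  variable order.  Constrained-ordination AIC is not uniquely defined in the
  literature, so the formula is fixed here explicitly for reproducibility.
- *Barycenters*: per group (pathway, phylum, …), the mean and (n − 1)-sd of
  member feature scores per axis; groups below a minimum size (default 10)
  are flagged, not dropped.

## Synthetic data: what it emulates, and what it does not

- **Families**: each family grows from a random root (80–400 aa) by point
  substitutions at a set per-site rate; no indels by default, so coverage
  stays at 100 % and the identity threshold is the active margin.  Members
  are assigned round-robin to MAGs; "dark" families are fully unannotated
  and hosted on phylum-only MAGs.
- **Environment**: 93 samples (the regime of a modest ocean survey), 24
  standard-normal quantitative variables with planted high correlations
  (0.95, 0.92 — exercising the correlation filter), 4 qualitative variables
  with 8/4/3/2 levels (province-, region-, season-, layer-like), and 6.6 %
  missingness completely at random.  The *latent* (complete) table drives
  planted abundance signals; the masked table is what curation sees —
  missingness is treated as a measurement artifact, not a biological one.
- **Abundances**: linked clusters follow `base + slope·driver + noise`
  (clipped at 0) with signal-to-noise `slope·sd(driver)/noise_sd = 3` by
  default; noise clusters are lognormal i.i.d.; near-constant clusters are
  constant except three perturbed samples, constructed to satisfy both
  near-zero-variance conditions.  Cluster targets are distributed to member
  proteins with multiplicative jitter normalized to mean 1, so cluster
  means recover targets exactly.
- **Counts** invert the normalization exactly (optionally
  Poisson-resampled).

Not emulated: realistic oceanographic covariance structure, phylogenetically
realistic sequence evolution, indel-rich homology, compositional coupling
between clusters, and spatial autocorrelation of samples.  Passing tests
therefore demonstrate that the chain recovers *planted* structure under
clean assumptions, not that real abundance profiles are this predictable.

## Problem sizes and determinism

The test suite and the pipeline's default synthetic fixture run at desk
scale: 20 linked + 20 noise + 5 near-constant clusters over 93 samples for
screen calibration, with the scaled (3 × 100) screen profile; toy tables
(≤ 10 × 8) for ordination oracles; 50 random pairs ≤ 60 aa for the
alignment oracle; 200 runs × 99 permutations for permutation-test
calibration.  A master seed fans out to per-stage seeds via a stage-name
hash, so stages are independently reproducible and two runs of the same
configuration produce byte-identical TSVs (floats are written with `%.17g`
and read back with round-trip parsing).

## Known limitations

- The screen's power at signal-to-noise 3 sits close to the 0.5 R²
  threshold when the planted driver is itself removed by the correlation
  filter (its surviving proxy carries r² ≈ 0.85 of the signal); such
  clusters can land in `linked` rather than `hle`.
- Percent identity from a single best local alignment can differ from a
  heuristic search tool's HSP bookkeeping on gappy alignments.
- The rank-sum exact path requires tie-free data; heavily tied small
  samples fall back to the asymptotic approximation.
- CCA scaling constants follow the package's own convention (documented
  above); other software multiplies scores by additional constants, so
  compare shapes and eigenvalues, not raw score magnitudes.
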