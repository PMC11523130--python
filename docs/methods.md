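# Methods

This note documents the statistical procedures implemented in `mycodiv`,
the defaults and why they were chosen, what the simulator does and does not
emulate, and the package's numerical conventions and limitations.

## Data model

All community statistics consume a `FeatureTable`: a features × samples
matrix of non-negative OTU/ASV counts (QIIME2 TSV export orientation).
Grouped analyses additionally need `SampleMetadata` (sample → treatment,
replicate) with at least two groups of two samples. The SQI consumes a
`SoilTable` of observations × quantitative indicators; observations may be
treatment means or treatment × replicate rows — the pipeline supports both
and stamps which was used in its output, since published field studies are
often ambiguous on this point. Missing soil values are a hard error rather
than being imputed: the intended inputs are small, complete agronomic
tables, and silent imputation could shift the PCA weights.

## Filtering and community operations

The low-count filter keeps a feature iff **some** sample holds at least
`min_count` reads of it (default 4) — the per-library minimum-count
semantics of common web pipelines. A total-count variant is available via
`per_sample=False`. Filtering precedes the Venn partition and the diversity
computations.

Venn partitions classify each feature by the exact set of sample supersets
(e.g. farmer practice / partial / full conservation agriculture) in which it
has a positive count; regions are disjoint and exhaustive by construction.
The treatment → superset mapping is user-supplied, not hard-coded.

Rarefaction uses the exact hypergeometric expectation
`E[S_n] = Σ_i [1 − C(N−N_i, n) / C(N, n)]`, evaluated with log-gamma
arithmetic to avoid overflow; no resampling is involved.

## Alpha diversity

Shannon entropy uses natural logarithms by default (a `base` argument is
exposed); Simpson is reported in Gini–Simpson form `1 − Σ p_i²`. Chao1 uses
the classic estimator `S_obs + F1²/(2 F2)` when doubletons exist and the
bias-corrected `S_obs + F1(F1−1)/2` when `F2 = 0`. ACE uses the standard
rare-class coverage estimator with `rare_cutoff = 10`; when every rare
individual is a singleton the coverage estimate is zero and the function
falls back to Chao1, flagging the fallback. Fisher's α solves
`S = α ln(1 + N/α)` by bracketed root finding to 10⁻¹⁰ and is undefined for
`S_obs = 0` or `S_obs ≥ N` (reported as NaN in the per-sample table).
Indices are computed on filtered, unrarefied counts; no rarefying is applied
before index computation.

## Beta diversity

Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` is computed between raw count
columns (scipy's implementation). PCoA applies Gower double-centering
`B = −½ J D² J`, a symmetric eigendecomposition, and returns coordinates
`v_k √λ_k` on positive axes only; negative eigenvalues of non-Euclidean
inputs are reported but excluded from coordinates, and no Lingoes/Cailliez
correction is applied by default (none is standard for Bray–Curtis PCoA in
this literature).

ANOSIM ranks all `M = n(n−1)/2` pairwise dissimilarities with mid-ranks for
ties and computes `R = (r̄_between − r̄_within)/(M/4) ∈ [−1, 1]`. The
p-value is `(1 + #{R_perm ≥ R_obs})/(permutations + 1)` over seeded label
permutations; the default 999 permutations makes the smallest attainable
p-value 0.001. Note that with very few samples the permutation distribution
is coarse (with two groups of three, only 10 distinct label partitions
exist), so the test is conservative at small n — its type-I rate at
α = 0.05 is far below nominal there, which is inherent to the statistic and
not a defect of the implementation.

## Soil quality index

The SQI procedure is standardized-PCA minimum-data-set selection followed by
non-linear scoring and weighted aggregation.

**PCA.** Indicators are z-scored (denominator n−1) and the correlation
matrix eigendecomposed; variance shares are `λ_k / Σλ`. A constant
indicator is an error (it has no correlation structure and would poison the
z-score).

**Selection rules** (defaults: `eig_min = 0.9`, `var_min = 5 %`,
`loading_floor = 0.40`, `loading_window = 10 %`, `r_max = 0.60`): retained
components need both an eigenvalue ≥ `eig_min` and a variance share ≥
`var_min`; per retained component, candidates have |loading| ≥
`loading_floor` or within `loading_window` of the component's top |loading|;
among candidates of one component, correlation pruning keeps the top
|loading| candidate and admits the rest in descending |loading| order only
while all pairwise |r| with already-kept candidates stay below `r_max`.
Design choices made here where the methodology is genuinely open: loading
*signs* are ignored throughout (eigenvector sign is arbitrary); pruning is
greedy by descending |loading| (no canonical order exists in the
literature); component weights are split equally among the m indicators a
component contributes, then globally renormalized so `Σ W_i = 1`. The audit
log records every decision so alternative orderings can be diagnosed.

**Scoring.** `S = a/(1 + (x/x0)^b)` with `a = 1`, `b = −2.5`
(more-is-better) or `+2.5` (less-is-better), and `x0` the indicator's mean
across the scored observations. For `a = 1` the sign flip is equivalent to
`1 − S`; the sign-flip form is primary. `S(x0) = a/2` exactly;
`S` is strictly monotone and bounded in `(0, a)`; because `x` enters only
through `x/x0`, multiplying an indicator column by any positive constant
leaves all scores, and hence the SQI, unchanged. Non-positive indicator
values are rejected (the power of a non-positive ratio is undefined); all
standard agronomic indicators are strictly positive.

**Aggregation.** `SQI = Σ W_i S_i` over the MDS indicators; with weights
summing to 1 the index lies in `(0, 1]`. By default EC (salinity) is scored
less-is-better and all other packaged indicators more-is-better.

## Group statistics

Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) reference. One-way
ANOVA uses the classical F; its compact letter display derives from
Tukey-HSD pairwise decisions at α = 0.05 via the insertion algorithm
(groups share a letter iff the pairwise comparison did not reject). The
post-hoc procedure for field-trial letter displays is rarely stated in
publications; Tukey HSD is the default here, with uncorrected pairwise
rank tests behind the Kruskal–Wallis letters. Pearson correlation matrices
carry two-sided t-test significance flags at a configurable α (default
0.05).

## Simulation

`gen_community` draws, per sample, a composition from a Dirichlet centred
on its treatment's base composition (concentration parameter controls
replicate variability; default 200) and counts from a multinomial at the
treatment's depth — the standard overdispersed Dirichlet-multinomial model
for amplicon counts. The default truth mirrors the reference trial's scale:
7 treatments × 3 replicates, ~1 000 features, depth 30 000, with a shared
log-normal rank-abundance backbone (σ = 1.5) and group-specific log-normal
tilts. `gen_soil` draws truncated-Gaussian replicate noise around
per-treatment indicator means (defaulting to the packaged trial table, CV
5 %) and negative-binomial earthworm counts (dispersion 30). The simulator
does **not** emulate sequencing error, chimeras, taxonomy misassignment,
spatial field structure, or inter-indicator correlation in the soil noise —
so passing tests demonstrate correctness of the downstream statistics under
the stated sampling model, not robustness to upstream artefacts of real
amplicon data.

`gen_known_sqi_case` plants a two-factor structure whose analysis outcome is
known exactly: two orthogonal latent patterns each drive a three-indicator
block (driver + two echoes built from perturbation patterns made exactly
orthogonal to everything else via QR), giving an exactly block-diagonal
correlation matrix with within-block correlations 0.95 and 0.80. The PCA
must retain exactly two components, and correlation pruning must reduce
each block to its driver, so the designed MDS is known without running the
pipeline; the expected SQI ordering is computed from the planted block
eigenvalues and the scoring formula directly.

## Numerical conventions and problem sizes

Output TSVs carry 6 significant digits; every stochastic stage takes an
explicit seed and the run manifest records it, making pipeline runs
byte-reproducible. Symmetry is enforced to 10⁻¹² in dissimilarity matrices;
PCoA treats eigenvalues below 10⁻¹⁰ × max as zero. Tests exercise the
estimators at modest scales chosen to be statistically informative while
keeping the suite fast: estimator recovery samples a 50-species community at
depths up to 2 000 (1 000 replicate draws at depth 500 for the Chao1 median
check), and the ANOSIM null-calibration study uses 10 000 simulated
6-sample datasets with 199 label permutations each — at α = 0.05 the
rejection decision (p ≤ 0.05 iff at most 9 permuted R exceed the observed)
has the same expectation as with more permutations.

## Known limitations

- The SQI selection thresholds are those conventional in the minimum-data-
  set literature but remain study-specific tuning knobs; with ≤ 7
  observations the PCA loadings, and hence the MDS, are sensitive to single
  observations.
- ANOSIM is valid for balanced designs with exchangeable samples; it is not
  a substitute for PERMANOVA when dispersions differ strongly between
  groups (PERMANOVA is intentionally out of scope).
- Phylogenetic diversity metrics (UniFrac, Faith's PD) are out of scope —
  the target workflow carries no tree.
- BIOM/HDF5 binary formats are not read; use QIIME2's TSV export.
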