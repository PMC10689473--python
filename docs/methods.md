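# Methods

This note documents the statistical models implemented in `tmecrosstalk`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
affect results.

## Quality control and normalization

Cells are retained when total UMI ≥ `min_umi` (default 1000), the number
of genes with ≥ 1 transcript ≥ `min_genes` (default 500), and the fraction
of UMIs on mitochondrial genes (symbols prefixed `MT-`) ≤ `max_mito_frac`
(default 0.20). All three comparisons are inclusive at the boundary.
Filtering is idempotent.

The per-cell size factor is total counts divided by the median total; the
normalized value is log(1 + count / size factor), natural log. The
total/median estimator is the simplest depth correction consistent with
the filters above; it is exposed through the `NormMatrix.size_factors`
field for callers that want a different estimator. log1p preserves
per-cell rank order, which the downstream AUC scoring relies on.

## Gini informative-feature selection

For gene g with cluster-mean expression m₁..m_K, the Gini coefficient is

    G = Σᵢ Σⱼ |mᵢ − mⱼ| / (2 K² m̄),

computed with the sorted-means identity in O(K log K). G ∈ [0, 1 − 1/K],
is invariant to positive rescaling of the means, and strictly decreases
under an additive shift — it rewards cluster-specific expression.
Because clusters are needed before informative features exist, the
pipeline bootstraps: an initial Louvain clustering on the 2,000 highest-
variance genes provides labels for a single Gini refinement pass. One pass
keeps the procedure deterministic; defaults `n_features = 1000`,
`n_pcs = 30` are typical scales for cohort-level data and are exposed in
configuration. Louvain runs on the k = 20 nearest-neighbor graph of PCA
coordinates; UMAP uses the cosine metric with 30 neighbors. Louvain
tie-breaking is fixed by seeding the graph library's RNG.

## Shrunken negative-binomial exact test

Counts follow NB with variance μ + φμ². With y = k/s (s the size factor),
Var(y) = μ/s + φμ², so the pooled within-group method-of-moments estimate
is φ̂ = (s² − μ̂ · mean(1/s)) / μ̂², clamped at zero. Dispersions are
shrunk toward the target ξ = mean of the positive φ̂ with weight

    δ = clip( Σ_g Var̂(φ̂_g) / Σ_g (φ̂_g − ξ)² , 0, 1),

the James–Stein-type weight that minimizes estimated mean squared error;
the sampling variance is approximated by the delta method as
Var̂(φ̂_g) ≈ 2 s_g⁴ / ((n−1) μ̂_g⁴). Every shrunken value lies between
φ̂_g and ξ. On a 2,000-gene null panel the estimated δ ≈ 0.9, i.e. heavy
pooling, which is what stabilizes the exact test at 50-cell group sizes.

Significance is a conditional exact test on the two group sums given
their total t: each group sum is moment-matched to an NB with mean
μ̂₀ Σs_c and variance μ̂₀ Σs_c + φ* μ̂₀² Σs_c², all t+1 splits are
enumerated in log space, and the two-sided p-value is the normalized
probability of splits no more probable than the observed one. As φ* → 0
this reduces exactly to the conditional binomial (Poisson) test, which is
the oracle used in the test suite (agreement to 1e-10 on all totals ≤ 30).
Measured type-I error at α = 0.05 on the null panel is ≈ 0.044.

Genes detected in fewer than 3 cells are excluded from testing and FDR
(reported with p = 1); log2 fold change uses pseudocount 1 on group-mean
normalized expression, which bounds fold changes for dropout-heavy genes
at the cost of attenuating them. A gene is significant when
BH-FDR < α (default 0.05; 0.01 is exposed for stricter volcano-style
calls) and |log2FC| > `lfc_min` (default 1). The Mann–Whitney fallback
uses scipy's exact null where available and the tie-corrected normal
approximation otherwise, with the same decoration.

## AUC signature scoring

Genes are ranked per cell by decreasing expression, ties broken by a
fixed random permutation drawn once per run from the seed (the statistic
is tie-sensitive; a frozen permutation makes it deterministic). For a set
with s members and window W = ⌈top_frac · G⌉ (default top_frac = 0.05,
the convention of AUC-recovery scoring), the score is

    Σ_{members with rank r ≤ W} (W − r + 1)  /  Σ_{k=1..W} min(k, s),

i.e. the area under the recovery step-curve normalized by its maximum.
Scores are invariant to monotone per-cell transforms. Rescaling maps each
set's scores affinely to [0, 100] over the scored population (a per-sample
switch is deliberately not the default; rescaling across the population
keeps scores comparable between samples). Ternary SC/TA/CC weights are the
three rescaled scores normalized to sum to 1; all-zero cells are flagged
unassigned rather than placed at the centroid. Cycling fractions call a
cell cycling when max(S, G2M) exceeds the 75th percentile of that maximum
in the reference arm; gene lists for S/G2M/EMT/exhaustion are
configuration inputs, not hard-coded.

## Receptor–ligand crosstalk

Per patient, carcinoma cells are tested against the patient's
normal-adjacent epithelium; genes with FDR < 0.05 and positive log2FC that
appear in the receptor–ligand database qualify (no fold-change floor at
this step — the floor applies to general DEG calls, not to the
interaction screen; `min_lfc` is configurable). The TME-side criterion is
one-vs-rest significance among non-epithelial tumor cells, matching the
marker-gene methodology used for cell-type annotation. Edges are
directional (receptor-on-epithelium vs ligand-on-epithelium analyzed
separately); `n_patients` counts patients supporting the epithelial gene,
and receptors are ranked by (n_patients desc, degree desc, gene asc).
Cross-species overlap keeps only one-to-one ortholog rows. No minimum
expression fraction is imposed on the TME counterpart (not part of the
stated procedure; adding one is a one-line filter on the DE table).

ECM-network analysis computes per-edge Pearson correlations in two cell
populations and compares mean |r| with a paired one-sided Wilcoxon test;
edges touching zero-variance genes are excluded from the summary.

## Macrophage states and fate bias

Louvain clusters of the macrophage subset are merged into IL1B/SPP1/C1QC
states by the hallmark with the highest cluster-mean expression after
normalizing each hallmark by its overall mean — raw means would let a
constitutively high marker claim every cluster. Clusters with all hallmark
means zero are flagged unassigned. State signatures are the top 50
significantly upregulated one-vs-rest genes per state; genes claimed by
several states go to the state where they rank best, so signatures are
disjoint.

State probabilities come from an iterative anchor-growing classifier
rather than the original random-forest fate-bias iteration: that
published procedure depends on package-version defaults, so this package
implements a fully specified variant that preserves the contract
(iterative classification producing normalized per-cell fate biases).
Anchors are the top quartile of own-signature AUC score per state and
carry probability 1 for their state. Remaining cells are classified by
the label fractions of their k = 25 nearest anchors under cosine distance
on the per-state score vectors; each iteration absorbs the most confident
10% into the anchor set, and a cell's probabilities are its vote
fractions at absorption. Anchor quantile 0.25, absorption decile, and k
are unstated anywhere upstream and are all exposed in configuration.
Because scores are rank-based the probabilities are invariant to uniform
rescaling of the expression matrix. On planted programs at fold 4
(300 cells/state/arm) hard-label accuracy and mean own-state probability
exceed 0.99.

Condition comparisons use Welch t-tests on per-cell state probabilities;
immune-fraction coupling uses per-sample Pearson r with an OLS fit and
95% CI, requiring ≥ 3 samples, with an optional sample-subset filter
(all vs tumor-only).

## Sample comparisons

Pseudo-bulk vectors are per-sample means of normalized expression.
Heterogeneity is the mean pairwise cosine distance among min(500, n)
cells sampled without replacement (zero vectors excluded); it is 0 iff
all sampled cells are collinear with non-negative components and is
bounded by 2. The paired one-sided t test runs across patients carrying
both tissues of a configured pair (default tumor vs tumoroid, alternative
"tumor more heterogeneous").

LFC concordance regresses in-vitro on in-vivo log2 fold changes with an
intercept (the comparison line y = x does not imply through-origin
fitting; a through-origin option exists and this is the one genuinely
unverifiable choice). Slopes for all genes and the receptor/ligand subset
are compared with z = (b_all − b_rl)/√(SE²_all + SE²_rl), p = 1 − Φ(z).
The RL subset is nested inside "all genes", so the Z test's independence
assumption is violated by construction; the package reproduces that
construction and the caveat stands. Quadrant counts use strict signs.
Genes enter the pair table only if tested in both contrasts (≥ 3 detected
cells per group), which keeps all LFCs finite. Under a null with equal
sub-slopes the Z-test p-values are uniform (KS-checked over 500
replicates in the test suite).

## CODEX analysis

Each channel's intensities are fit with a two-component univariate
Gaussian mixture by EM, initialized at the 20th/80th percentile with the
pooled variance (deterministic initialization removes EM's seed
sensitivity for well-separated components). The log-likelihood is
asserted non-decreasing at every iteration; convergence is Δloglik < 1e-8
or 500 iterations. Component weight < 1e-3 or variance collapse triggers
a single-component fallback in which every cell is retained. Cells with
posterior probability of the higher-mean component < 0.5 get denoised
intensity 0 (hard assignment — the simplest reading of
background-component removal; the boundary case 0.5 retains); retained
cells keep their raw intensity, log1p-transformed. Retaining raw rather
than posterior-scaled values is configurable via `log_transform` and the
fit object, which exposes the full posterior parameters.

Neighborhood composition takes each cell's k = 6 nearest neighbors by
Euclidean distance in image units (composition is scale-invariant, so no
micron conversion), self excluded and ties broken by cell id, and
averages neighbor-type fractions per reference type; rows sum to 1 by
construction. The proportion test is chi-square with continuity
correction, switching to Fisher's exact test when any expected count is
below 5.

## Synthetic-data generator

`simulate_counts` emulates: patient-paired tumor / normal-adjacent arms
with ~10 coarse cell types per arm, NB counts with per-gene log-normal
baseline means (log-mean −1, log-sd 1, i.e. a realistic dropout-heavy
depth at ~1,100 UMIs/cell over 2,000 genes), per-type marker blocks
(25 genes at fold 8), three macrophage programs (30 genes at fold 4,
headed by the hallmark gene itself), planted receptor–ligand effects
acting multiplicatively on carcinoma means of configured patient subsets
(so the true log2FC is exactly the configured effect), log-uniform
library sizes over [0.5, 2] (exercising size-factor correction), and
epithelial-only tumoroid/organoid arms whose per-gene log2FC is
`invitro_slope` × the in-vivo effect plus Gaussian noise (slope default
0.6, noise sd 0.2 — mid-range attenuation). One global seed drives
split per-operation streams, so each stage is reproducible in isolation.

It deliberately does not emulate transcriptome-wide co-expression
structure, doublets, or ambient RNA; passing tests therefore demonstrate
correctness of the procedures under the stated generative model, not
robustness to those artifacts of real droplet data.

`simulate_codex` places each cell type in a Gaussian spatial cluster on a
square field (grid centers, cluster scale 30 image units in a 1000-unit
field) and draws each channel from N(5, 0.2²) when the cell's type
expresses the marker and N(1, 0.2²) otherwise, clipped at zero.

Problem sizes used by the test suite and `scripts/acceptance.py` — 2,000
null genes at 50 vs 50 cells for calibration, 1,800 macrophages for state
recovery, a 5-patient / 10-edge cohort (~3,250 cells) for crosstalk,
5,000 LFC pairs plus 500 null replicates for concordance, and 10,000
cells for the neighborhood checks — were chosen so each stage has enough
replication for its tolerance while the whole suite runs in minutes on a
laptop.

## Known limitations

- The dispersion-shrinkage weight uses a delta-method variance
  approximation; very low-expression genes (μ̂ near zero) are excluded by
  the detection filter rather than modeled.
- The moment-matched NB for a sum of NB counts is an approximation when
  size factors vary strongly within a group.
- The fate-bias classifier is a specified variant, not a reimplementation
  of the original random-forest procedure; probabilities are comparable
  in contract, not numerically identical.
- Batch correction, doublet detection, covariate-adjusted DE, and
  pseudo-replicate mixed models are out of scope.
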