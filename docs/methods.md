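# Methods

## Data model and preprocessing

A multiplex single-cell qPCR experiment yields, per cell and gene assay,
either a quantification cycle (Cq) or no amplification. Expression is
converted to relative quantities **RQ = 2^(Cq_off − Cq)** with respect to the
off-scale cutoff `cq_cutoff` (default 28 cycles — a conventional
post-preamplification bound; the value only shifts the log2 scale's origin).
Reactions with Cq above the cutoff are treated as non-detects. No
reference-gene normalization is applied: expression is reported per cell, and
GAPDH serves purely as a cell-quality gate — cells without GAPDH detection
are removed, and a plate passes QC when positivity exceeds
`min_gapdh_positivity` (0.80, the sort-efficiency bar).

Downstream analyses use two log2 views:

- **unimputed** (`log2_rq`): non-detects stay missing; all frequency/level
  statistics use this view, so levels always average real measurements;
- **imputed** (`log2_rq_imputed`): non-detects are filled
  `imputation_offset` (default 1.0) log2 units below the gene's minimum
  detected value (0 for never-detected genes). Only multivariate steps (PCA,
  SOM, correlation, clustering) consume this view. One unit below the
  observed floor keeps non-detects ranked lowest without inflating variance;
  the detection mask is never modified by any transform.

Three scaling conventions, each recorded in the matrix provenance:
per-gene autoscaling (z-score, sample SD; PCA view), per-cell autoscaling
(a global normalization that removes per-cell differences in absolute RNA
content; used for the subgroup PCA view and the classifier), and per-gene
mean-centering (heatmap convention; also the per-dataset step of the
cross-dataset combination). Constant rows/columns autoscale to zeros with a
logged warning rather than aborting, so degenerate synthetic inputs pass
through. Sample (n−1) SD is used everywhere and is part of the documented
contract, making test expectations exact.

## Subpopulation discovery

Cell-to-cell Spearman correlations (average-rank ties, so imputed floor
values tie deterministically) are computed on the imputed log2 matrix. Each
cell's feature vector is its row of correlations to every cell; agglomerative
clustering (Euclidean distance, average linkage by default) cut at
`n_subgroups` = 5 reproduces the manual five-subgroup split. Because the
original grouping was performed manually from a dendrogram, the cut emulates
an analyst's judgement: if the literal cut isolates tiny outlier twigs
(fewer than `min_cluster_size` = 4 cells), the cut is deepened until five
substantive groups exist and twig cells are folded into the nearest group by
mean feature distance (`min_cluster_size=1` restores the literal cut). The
subgroup containing both normal and activated cells — the mixed cluster — is
then split by cell class, yielding six states.

A Kohonen self-organizing map (3×2 grid matching the six states, Gaussian
neighbourhood, linearly decaying learning rate and radius, 5000 online
updates, deterministic for a fixed seed; lowest unit index wins assignment
ties) provides an independent confirmation of the subgroup structure on
per-cell autoscaled data. The SOM is implemented in-package. Its role is
confirmatory: unit assignments agree substantially with the planted states
and are nearly pure in condition, but a six-prototype quantizer cannot fully
separate the deliberately adjacent primed and proto-myofibroblast states
(nor can k-means with restarts, which bounds what any prototype method can
achieve on this geometry), so exact state recovery is the job of the
correlation clustering plus the class split, not the SOM.

## Group statistics and bimodality

Per (gene, group): frequency = detected fraction of QC-passed cells; level =
mean log2 RQ over detected cells only; SEM = sample SD / √n_pos. Differential
comparisons (two-sided Student t by default; one-way ANOVA and Mann–Whitney
available) run on detected cells only, with at least two detected cells per
side, at α = 0.05 per gene without multiple-testing correction — matching the
per-gene significance marking convention; a Benjamini–Hochberg option exists
but is off by default. The stratified mean-vs-mean comparison draws its
"significance area" as the per-gene t-test non-rejection region: a gene lies
outside the area exactly when the two-sample test rejects, which makes the
flagged set definitionally consistent with the differential table.

Bimodality of one gene in one group is assessed on detected log2 values
(non-detects are a separate channel and are excluded from the mixture): a
closed-form single Gaussian competes against a two-component mixture fitted
by EM (spherical components, 10 restarts with k-means++ initialization, 500
max iterations, tolerance 1e−8, SD floor 1e−3), selected by BIC. For k = 2
the low/high boundary is the point between the sorted means where the
posterior responsibility crosses 0.5; detected cells at or above it are
"high", all other cells "low". Model selection is consistent as separation
grows; at the default noise level and n ≈ 90 the two-component model wins for
most draws, but an individual draw's log-likelihood gain can fall below the
BIC penalty, so selection on a single cohort is seed-dependent near that
boundary — a property of the statistics, not of the implementation.

## Differentiation model

The pseudo-temporal score is `s(g,k) = f(g,k) × max(E(g,k), 0)` with the
level factor clipped at zero so sub-unit RQ levels cannot flip the product's
sign; frequencies enter as fractions (a linear-RQ level convention is
available behind a switch; it changes scale, not ordering). Marker rules
operationalize the state naming:

- stem-like: highest mean pluripotency-group score (normal side);
- naive: lowest mean activation score (ACTA2, COL1A1, TNC, FN1, FAP, MMP2)
  among the remaining normal states; primed: the remainder;
- secretory myofibroblast: highest mean soluble-factor score (CXCL12, PDGFA,
  VEGFA, HGF) among activated states; ECM-regulating: highest COL1A1/FN1
  score among the rest; proto-myofibroblast: the remainder.

Rules are shipped as an editable mapping (gene lists per criterion); ties
break to the lower state id with a logged warning. `order_states` then
arranges labelled states onto the canonical timeline; partial label sets
(e.g. a normal-only run) keep their relative order. Gene profiles are
hierarchically clustered (Euclidean, average linkage) and genes whose score
range exceeds 5× the median gene range are flagged for separate plotting.

## Classification of patient-derived cells

The reference space is a PCA fitted on per-cell autoscaled, fully observed
reference data with one centroid per state in the first `n_pcs` score
dimensions. The package default is **n_pcs = 3**: six centroids are not
reliably separable in two dimensions because the rare stem-like state's
discriminating direction carries little total variance and falls outside the
top two components; three components restore it while keeping the
nearest-centroid rule simple. Mahalanobis distances were rejected because
per-state covariances are poorly estimated at 9–42 cells per state. Test
cells are autoscaled per cell with their own statistics (the normalization
that absorbs their larger global-expression variability), projected with the
frozen reference center/scale/loadings — never refitted — and assigned to
the nearest centroid by Euclidean distance, with ties broken toward the
earlier timeline state (the conservative activation call). Loadings are
sign-fixed (largest-magnitude loading positive) so scores are reproducible.

## Synthetic study design

The generator plants the statistical structure the analysis assumes, with
full ground truth. Defaults encode the study conditions: 92 control + 91
experimental CAF cells (six states; stem-like rare at ~10% of the normal
side: 9/41/42 and 31/30/30 cells per state), 77 normal + 75 CAF patient
cells, the 43-gene panel, GAPDH detection 0.95. Per gene and state the design
specifies a detection probability f and a detected-expression mean μ (log2
RQ); a cell draws Bernoulli(f) detection (true absence, not censoring — a
censoring mode exists for robustness tests) and, when detected,
log2 RQ ~ Normal(μ + cell offset, √(σ_bio² + σ_tech²)) converted to
Cq = cutoff − log2 RQ. Defaults: σ_bio = 1.0 log2 units, σ_tech = 0.5 cycles,
per-cell global-scale offset SD 0.5 (reference) / 1.0 (patient) —
plausibility choices, all config-exposed.

Trajectory archetypes: transitional genes vary μ across states at
near-constant high detection (activation markers ramp up along the timeline;
CAV1/CD44/VIM ramp down); switch-like genes vary f at near-constant μ (HGF,
CCL5, pluripotency on only in stem-like cells, BCSC-like genes enriched on
the normal side). The stem-like state additionally carries the
quiescence/anoikis-resistance signature (pluripotency + CCL5 + CDKN1A up,
proliferation markers down, moderately higher COL1A1/FN1/MMP2/HGF, lower
ACTA2/TNC/ALDH1A3). ACTA2 in activated cells is drawn from a two-component
mixture (means 3 and 7 log2 RQ — 4 log2 units apart — equal weights),
independent of state, and the drawn component is recorded in the truth. The
primed and proto-myofibroblast archetypes are deliberately adjacent so that
they form the mixed cluster under correlation clustering while remaining
separable by the classifier — the same tension the real data shows.

The planted cluster truth on the reference therefore has five groups (stem,
naive, primed+proto, ECM, secretory); the state truth has six. Patient
normal cells draw states from a 0.10/0.60/0.30 stem/naive/primed mixture;
patient CAFs sit on a uniform interpolation between the primed and proto
archetypes, labelled with the nearer endpoint.

What the generator does **not** emulate: plate spatial effects,
preamplification bias, censoring-type dropout (off by default), cell-cycle
or batch covariance between genes (noise is independent per gene given the
state), and FACS doublets. Passing tests therefore demonstrate that the
pipeline recovers planted structure under the stated noise model, not that
it is robust to every artefact of real instruments.

## Problem sizes and determinism

All tests and the acceptance script run the full study-sized design (183 +
152 cells, 43 genes) — no scaling down was needed. Every stochastic step
(generation, EM restarts, SOM training) takes an explicit seed; the pipeline
manifest records seeds and SHA-256 digests of all outputs, and a rerun with
the same config and seed is bit-identical.

## Known limitations

- The panel's group assignments beyond the genes named in running text are a
  reconstruction from canonical group members (the original panel table is a
  figure); the total is fixed at 43.
- The pipeline's automatic mixed-cluster detection assumes exactly one
  subgroup mixes conditions; plates where clustering fragments differently
  abort at the labelling stage rather than guessing.
- Nearest-centroid classification gives hard assignments only; cells unlike
  any reference state are still assigned to the nearest one.
- The pseudo-timeline is an ordering over discrete subgroups; no per-cell
  continuous pseudotime is inferred.
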