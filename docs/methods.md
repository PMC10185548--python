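# Methods

This note documents the models and procedures implemented in `neurokd`, the
defaults they use, and the choices made where the design was genuinely open.
Problem sizes quoted for tests and benchmarks are the package's own desk
scale; the pipeline itself has no size assumptions beyond memory.

## Deconvolution by marker-adjusted residuals

Bulk expression is modelled per gene g as

    y_g = Xβ_g + Σ_c γ_{g,c} m_c + ε_g

where X holds an intercept plus the adjusted covariates (categoricals
dummy-coded, all columns centered) and m_c is the normalized expression of
cell type c's single marker gene (standardized by default; a flag disables
standardization since it is not determined whether raw or standardized
markers are the convention). The cell-type residual for target cell type t
is the OLS residual plus the fitted target-marker effect added back.

The add-back uses γ_{g,t} · m_t⊥, where m_t⊥ is the component of the target
marker orthogonal to every other regressor, rather than γ_{g,t} · m_t. The
two coincide when the marker is uncorrelated with the covariates, but only
the orthogonalized form guarantees the defining property of the output: the
stored residual is exactly orthogonal to every adjusted covariate and to the
other cell types' markers, and is centered (so no recentering is applied
after add-back). Marker genes themselves are excluded from the output rows —
regressing a marker on itself is degenerate.

Counts are normalized as log2(1 + CPM); the pseudocount of 1 keeps zeros at
zero, and re-normalization of already-normalized input is refused. The
low-expression filter keeps genes with CPM strictly above 1 in at least 30%
of samples (both thresholds configurable); read-level corrections (GC,
length, precision weights) are out of scope, so log2-CPM is the package's
normalization.

Variance partition analysis reports, per gene, each term's marginal partial
R² (full-model R² minus the R² without that term's columns), rescaled
together with the residual share to sum to one. Fixed effects only: the
partial-R² output answers the same interpretive question as a mixed-model
partition without random-effect machinery.

The marker-robustness check rebuilds the residual with the mean of a random
subset of a candidate marker pool in place of the single marker and reports
the per-gene correlation between the two residuals (median and IQR per
draw), quantifying how much the result depends on the single-marker choice.

## Association statistics

Differential expression is a per-gene Welch two-sample t-test on residuals,
BH-corrected, flagged at q < 0.05; the effect is the case − control mean
difference. Moderated (empirical-Bayes) statistics are deliberately
omitted — at the sample sizes this pipeline targets the Welch test is the
simpler, assumption-lighter choice.

cis-eQTL mapping tests every (gene, variant) pair on the same chromosome
with |position − TSS| ≤ window (default 1 Mb, both bounds inclusive, strand
ignored) by OLS of residual on allele dosage; BH runs across all tested
pairs (the convention of matrix-eQTL-style tools), and a gene is an eQTL
gene when any of its pairs reaches q < 0.01. Residuals are already
covariate-adjusted, so no further covariates enter.

BH q-values come from the step-up procedure; the two-stage (BKY) variant
estimates the null fraction in a first pass and reruns the step-up with it,
so its q-values are elementwise ≤ BH. Both delegate to
`statsmodels.stats.multitest` behind the package's interface.

Set-overlap statistics share one core: a 2×2 table over a finite universe,
sample odds ratio ad/bc (∞ on degenerate tables with a > 0), two-sided
Fisher p, and percentages of each set overlapped. The sampling-based variant
draws |A|-sized random sets from the universe and reports the +1-smoothed
empirical p, matching the hypergeometric tail in expectation.

## Co-expression modules

Adjacency is |cor|^β on case samples only (β = 6.5 default; signed mode
available). The topological overlap matrix is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).

Modules come from average-linkage hierarchical clustering of 1 − TOM with a
static cut (height 0.995) and merging of clusters below the minimum size
(default 30) into the retained cluster with the highest mean inter-cluster
TOM; if no cluster reaches the minimum size, genes stay unassigned. This is
a deterministic stand-in for dynamic tree cutting; block-recovery tests
(ARI ≥ 0.9 on planted blocks, zero modules on noise) validate it at desk
scale.

A module eigengene is the first principal component of the standardized
member matrix, unit variance, with a canonical sign (largest-magnitude
element positive) so the summary is invariant under flipping all member
rows. Trait association uses one-way ANOVA for categorical traits and an
OLS slope t-test for numeric ones; p-values are BH-corrected per trait
across modules.

Module selection tests each module for Fisher enrichment of the DE
signature and of neuronal markers, BH across all (module × set) tests,
selecting at q < 0.05 on either; enrichments for other cell types' markers
are reported but never drive selection. The seeding gene set is the union
of selected modules' members.

## pathFinder expansion

The background pathway graph may contain directed and undirected edges; each
undirected edge becomes two anti-parallel directed edges that are mutually
exclusive within a single path. From every seed gene a depth-first search
enumerates node-simple paths, stopping at K edges (default 4; this K is a
free parameter distinct from the key-driver K) or at a node with no
unvisited successor. A stopped path containing at least two seeds
contributes all nodes from the start up to the seed farthest along the path
(along-path distance, not graph distance). Node-simplicity bounds the
enumeration; the explicitly forbidden configuration — the two-cycle of an
undirected pair — is a special case of it. Only the expanded node set is
passed to network learning; the pathway edges are discarded so the network
structure stays data-driven. Equivalence with an exhaustive path-enumeration
oracle is tested on random graphs.

## Causal network learning

Structure learning maximizes a decomposable score: per node, the Gaussian
BIC −(n/2)·log(RSS/n) − ((|parents|+1)/2)·log n computed from the
standardized bootstrap covariance, plus per-edge log structure priors. The
search is greedy hill climbing over add/delete/reverse moves with
acyclicity enforced per move, in-degree capped (default 3), lexicographic
tie-breaking, and move deltas cached per target node so only affected
candidates are re-evaluated after each step. One DAG is learned per
bootstrap resample of the samples (default 50); the posterior of a directed
edge is its frequency across the ensemble, and thresholding at a cut-off in
(0, 1] gives the final network. Thresholded networks may contain cycles
(members are DAGs, the consensus need not be); the metadata records whether
the result is acyclic.

The eQTL structure prior multiplies the score of edges out of eQTL genes by
λ_source (default 2) and of edges into eQTL genes from non-eQTL genes by
λ_sink (default 0.5): genes under detectable cis genetic control are treated
as perturbation sources. λ = 1 on both sides reproduces the unprioritized
run bit-for-bit at a fixed seed.

A known property of this design: individual bootstrap DAGs carry a few
resampling-noise edges (duplicated samples add roughly one unit of
noncentrality to each null pairwise statistic), but such edges do not
replicate across the ensemble — at posterior cut-off 0.5 a null (independent
genes) network is empty. Sparsity claims should therefore be read at the
posterior level, not per bootstrap DAG.

Bottom-up orientation uses each gene's best cis variant as an instrument.
With instruments L_A, L_B on both genes, the models {A ~ L_A; B ~ A + L_B}
and {B ~ L_B; A ~ B + L_A} are compared by total BIC. With a single
instrument L on A, the decision requires the marginal L–B association first
(instrument relevance to the pair — its absence is the signature of the
reverse or disconnected model, so the pair is left undetermined) and then
compares {A ~ L; B ~ A} against {B ~ 1; A ~ B + L} by BIC. A pure
conditional-independence rule at level α was rejected as the default: it
abstains in a fraction α of true-chain cases by construction, while the BIC
comparison is consistent and retains abstention under irrelevant
instruments. Pairs with no instrument are undetermined. The *predictive*
model variant applies these decisions to the thresholded network (flip by
default, drop optional); the *bayes* variant is the thresholded ensemble
alone. The published method this variant stands in for combines top-down
search with bottom-up causal tests in a proprietary formulation; the
definition above is this package's fully specified version of that
synthesis.

The recovery benchmark (30-gene SEM, 300 samples, edge weights 0.4–0.9 in
magnitude, 10 seeds) plants cis instruments at the SEM's source genes with
the cis window below the variant spacing, so each gene tests only its own
variant. That is the regime the prior encodes — instrumented genes acting
as causal sources. When instruments are planted on sink genes instead, the
prior's premise is violated and it degrades recovery; users should enable
the prior only where the perturbation-source interpretation of their eQTLs
is plausible.

## Key driver analysis and prioritization

The background subnetwork is the union of k-step *undirected* neighborhoods
of the target genes (k defaults to K); enrichment then uses *directed*
reachability within that subnetwork — "neighborhood" and "downstream
neighborhood" are deliberately different notions. For each node and each
k = 1..K (default 6), the hypergeometric upper tail of |D_k(v) ∩ targets|
is computed with the background subnetwork (minus v) as the universe; the
minimum over k is the node's p, BH across nodes, key drivers at q < 0.05.
Exactness is tested against a brute-force oracle (explicit reachability
plus combinatorial tail summation) on random networks.

The impact score of a gene in one network is Σ over reachable effectors e
of 1/(L(e)·C(e)): L(e) the directed shortest-path length, C(e) the product
of in-degrees of intermediate nodes along a shortest path chosen to
minimize that product (a BFS-layer dynamic program; ties lexicographic).
A direct edge to a sole-parent effector contributes exactly 1, and an extra
hop never increases a contribution. The aggregate impact is the mean over
networks containing the gene; the effector set defaults to the DE signature
restricted to network nodes. The robustness score is the count of distinct
datasets plus gene-set tags plus model types among networks where the gene
is a key driver, tie-broken by total network count. Both formulas are this
package's documented defaults (the published scores are specified only in
inaccessible supplementary material) and are pluggable.

Prioritization follows the rank ledger: top-50 by each score; replicated
genes kept when ranked ≤ 15 in at least one list; top-3 unique picks per
list; curated-set members found in either top list; then user-flagged
extras. Every selection carries its rule as a label. On cohorts too small
for any gene to reach KDA significance, the aggregate table falls back to
all tested genes (with zero driver calls recorded) so the ranking and the
ledger remain well defined.

## Validation analytics

Downstream subnetworks are full directed reachability below a node
(optionally depth-bounded; the root is excluded from the gene set).
Knockdown-signature enrichment uses Fisher's exact test at raw p < 0.05 —
mirroring the validation design, which reports per-target significance
without FDR — with the knockdown DE table corrected by the two-stage FDR at
q < 0.05. The consensus subnetwork pools each root's downstream edges
across networks and counts, per directed edge, the number of contributing
networks. Shortest paths to designated sink genes return all co-minimal
directed paths. Pathway enrichment (GMT collections) is Fisher at p < 0.05
over the declared universe, pathways disjoint from the universe skipped.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, not any real
cohort. Per cell type, gene expression follows a shared linear-Gaussian SEM
on a random truth DAG (random topological order; each ordered pair an edge
with probability density/(n−1); signed weights, magnitude uniform in
[0.4, 0.9]) with independent noise realizations per cell type. Case effects
(default 1 SD) and cis-eQTL effects (default 0.8 SD/allele, each planted
gene assigned its own nearest variant) act in the designated neuron cell
type only, so deconvolution — not raw bulk — is what exposes them. One
marker gene per cell type is expressed at a high level (10 units over a
0.2-SD baseline) in exactly that cell type; markers are excluded from the
DAG and from DE effects. Cell fractions are Dirichlet with neuron-heavy
base proportions (0.45/0.10/0.20/0.05/0.20, concentration 30) mirroring
cortex. Bulk = fraction-weighted mixture + covariate effects (batch, sex,
age, RIN-like; modest loadings) + N(0, 0.5) noise. Genotypes are
Hardy–Weinberg dosages at MAFs uniform in the configured range, on one
synthetic chromosome at 10 kb spacing, which keeps the 1 Mb cis window
meaningful at toy scale. One high-out-degree key regulator is wired by
default as a root feeding 80% of the DE genes, giving key driver analysis a
planted answer.

What the generator does not emulate: linkage disequilibrium, read-level
count noise, non-linear regulation, cell-type-specific covariate effects,
and marker genes that are imperfect proxies for their cell type. Passing
recovery tests therefore demonstrate correctness of the procedures under
the model's own assumptions, not performance on real cohorts.

## Numerical and reproducibility choices

All randomness flows from named substreams of one seed (stage name hashed
into the seed sequence), so skipping stages never shifts other stages'
draws, and identical configurations reproduce outputs byte-for-byte.
Degenerate inputs have defined behavior: zero-variance genes in DE give
t = 0, p = 1; constant genes are rejected by correlation-based stages with
the gene named; empty pathway/GMT inputs and malformed lines raise with
file and line; empty subnetworks in enrichment report p = 1 with a flag.
Tolerances: cell-fraction simplex 1e-9, variance-fraction normalization
1e-6, residual orthogonality 1e-6 relative, round-trip I/O 1e-12. Test and
benchmark problem sizes (200–400 subjects, 30–200 genes, 10–50 bootstraps)
are the package's desk scale, chosen so the full suite runs in minutes on
one CPU; the published analyses this mirrors operated on 9k–14k-gene
networks, which the same code addresses only with substantially more
compute.
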