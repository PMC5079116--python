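# Methods

`scnpheno` implements a complete analysis chain for single-cell qPCR panels of
suprachiasmatic-nucleus (SCN) neurons: quality control, comparative-Ct
normalization, correlation-network construction, community-structure
phenotype discovery, cluster validation, and ligand–receptor signaling-role
inference between phenotype groups. This note records the models, the
parameters that matter, the numerical conventions, and the choices made where
the design was genuinely open.

## Normalization model

Raw measurements are cycle-threshold (Ct) values; lower Ct means more
transcript. Normalization is the standard two-step comparative-Ct scheme:

1. **−ΔCt** — per cell, each gene is referenced to the mean Ct of the
   housekeeping set (default `Actb`, `Hprt`, `Atp5b`):
   `−ΔCt(g, c) = mean_h Ct(h, c) − Ct(g, c)`. Higher −ΔCt = higher
   expression. This removes per-cell loading/RNA-content offsets.
2. **−ΔΔCt** — per gene, the median across *all* retained cells (both
   treatment groups pooled) is subtracted, so zero is the per-gene median and
   values are comparable across treatments. Per-treatment centering is
   available behind a flag but is not the default.
3. **Modified z** — −ΔΔCt divided by the per-gene population SD (ddof = 0,
   which makes the unit-SD invariant exact). This is a display normalization;
   it is a positive affine rescaling of each gene and therefore preserves
   gene–gene Pearson correlations exactly. It does *not* preserve cell–cell
   correlations, which is why all cell-level analyses run on −ΔΔCt.

Housekeeping candidates can be ranked by a pairwise-variation stability
measure: `M_j = mean_k SD_cells(Ct_j − Ct_k)` over the other candidates
(sample SD, ddof = 1); lower M = more stable, ties break on the gene label.

**Non-detects.** Reactions that never amplify are kept as an explicit mask
plus a placeholder Ct at the detection limit (default 40 cycles). The default
policy treats them as missing for correlations and PCA, as *negative* for
positive/negative expression calls, and optionally floor-imputes them at the
detection limit. Binary "positive" calls use strictly `−ΔΔCt > 0`; exact zero
(the median) is negative.

QC defaults: a cell is excluded if any housekeeping gene fails to amplify
(`failed_reaction`), if every assay is non-detect (`loading`), or if more
than 70% of assays are non-detect (`signal`); a gene is excluded if
non-detect in more than 90% of cells or flagged as contaminated. All
thresholds are configurable and the report reconciles counts exactly.

## Correlation networks

Similarity is the Pearson correlation on pairwise-complete observations,
with a minimum of 10 shared observations per pair (pairs below the minimum
are NA; NA never makes an edge). Study-level defaults for the thresholded
graphs are r > 0.5 (strict) for gene graphs and r ≥ 0.5 (non-strict) for
cell graphs; only positive correlations form edges by default.
`permutation_threshold` re-derives empirical null quantiles — each
permutation shuffles every gene row independently across cells, destroying
covariance while preserving marginals — in a pooled mode (quantile of all
null pairwise r) and a family-wise mode (quantile of the per-permutation
maximum). It reports rather than overrides the fixed defaults, so headline
results stay tied to the printed constants.

Conditional gene networks re-run the gene graph inside a cell subset (e.g.
the Vip-positive cells) and require at least 10 passing cells. Minimum
spanning trees use Kruskal's algorithm on `1 − r` with lexicographic
tie-breaks on the node-pair labels, so the tree is deterministic;
disconnected structures return a spanning forest with a warning.

## Community detection

Phenotype groups are communities of the cell correlation graph found with
the leading-eigenvector modularity method, written from scratch:

* modularity matrix `B_ij = A_ij − k_i k_j / (2m)` (unweighted adjacency by
  default; edges are already thresholded);
* recursive bisection by the sign of the leading eigenvector of the
  generalized submatrix `B^(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik`, stopping when
  the leading eigenvalue is ≤ 1e−9 or the modularity gain
  `ΔQ = sᵀB^(g)s/(4m)` is non-positive;
* determinism is engineered: the eigenvector sign is fixed so its
  largest-magnitude component is positive, and components below 1e−12 are
  assigned to the side that maximizes ΔQ (ties to the positive side).

**Fine-tuning (default on).** Plain spectral bisection is known to fall
short of attainable modularity. Three refinement stages run by default:
iterated Kernighan–Lin sweeps after each bisection (single-node moves across
the cut, downhill moves allowed, best prefix kept, repeated until no sweep
improves); a final multiway node-move refinement over the whole partition
with one spare community slot; and tentative spectral splits of individual
communities kept only when overall Q strictly improves — a community can be
exactly indivisible in isolation while a split combined with cross-community
moves raises Q. The refinement also restarts from two deterministic
alternative partitions (everything in one community; all singletons) and
keeps the best-Q result. On random graphs of ≤ 10 nodes this reaches the
exhaustive-search maximum modularity almost always and stays within 0.013 of
it in the worst observed case; `fine_tune=False` gives the plain method.

**Residual pooling.** After detection, cells with graph degree below 1 and
all members of communities smaller than 5% of the node count (rounded up)
are pooled into a residual group — the analogue of neurons with minimal or
no supra-threshold correlations. Remaining groups are renumbered 1..K by
descending size; the residual group takes id K+1. Both knobs are recorded in
the partition provenance.

## Validation statistics

* **Silhouette**: `s(i) = (b(i) − a(i)) / max(a(i), b(i))` with `a(i)` the
  mean within-cluster dissimilarity (self excluded) and `b(i)` the smallest
  mean dissimilarity to another cluster; singletons score 0; per-cluster
  arithmetic means are reported. The default dissimilarity for group
  validation is Euclidean distance in the 2-D classical-MDS plane of the
  cell `1 − r` matrix (scores are reported alongside the MDS embedding); a
  flag switches to `1 − r` in full expression space. Both are reported
  because the choice materially changes the numbers.
* **PCA**: covariance PCA on −ΔΔCt (centering only — the units are already
  comparable cycles), gene-wise mean imputation for missing values (flagged),
  variance fractions = eigenvalue/trace, loading signs fixed so the
  largest-magnitude loading per component is positive. Correlation-mode PCA
  sits behind a flag.
* **Classical MDS**: Torgerson double centering, eigen-embedding, negative
  eigenvalues truncated with a diagnostic, coordinates centered and
  deterministically reflected.
* **Gene modules**: agglomerative clustering with distance `1 − r` and
  average linkage (the linkage choice is a package decision, recorded in
  provenance), cut at k modules, constant genes excluded with a warning.
* **Rank-sum test** (spatial positioning): exact enumeration when
  `n_A + n_B ≤ 20` with no ties, otherwise the normal approximation with
  midrank tie correction and continuity correction. Returns the rank-sum of
  the first sample and the two-sided p.

## Signaling-role inference

For a ligand–receptor pair, each cell's role is the sign quadrant of its
(−ΔΔCt ligand, −ΔΔCt receptor): **source** (+, ≤0), **target** (≤0, +),
**autocrine** (+, +), and **none** (≤0, ≤0, no dominant signaling role).
Cells missing either gene are "none" with a missing flag and are excluded
from that pair's counts.

Group enrichment in a role uses the one-sided (over-representation)
hypergeometric tail on the 2×2 table [group∩regime, group∖regime;
non-group∩regime, non-group∖regime]. No multiple-testing adjustment is
applied by default — the table is reported in full with exact p-values — and
a Benjamini–Hochberg mode is available behind a flag. Significance defaults
to α = 0.05.

The **dominant-interaction screen** retains a pair when its observed
ligand–receptor correlation across analyzed cells exceeds the 0.95 quantile
of a null built by shuffling the receptor vector only (the minimal
permutation destroying the association while preserving both marginals);
1000 permutations by default, seeded. The correlation is computed across all
analyzed cells by default; a per-group mode is provided.

The directed group network adds an edge `G_s → G_t` for every retained pair
with `G_s` significantly enriched as source and `G_t` as target, plus
autocrine self-loops, weighted by the respective group fractions, in
deterministic order (pair name, then group ids).

## Synthetic data: what it emulates and what it does not

The generator produces Ct-scale data so the full normalization path is
exercised. Defaults (the frozen study conditions): 200 cells, 60 genes,
4 planted groups with 10-gene signatures shifted 3 Ct cycles, per-gene
noise SD 1 cycle, per-cell loading offset SD 0.3 cycles (removed by −ΔCt),
housekeeping noise at half the gene noise, 27% dark-adapted (DD) cells, a
3-cycle immediate-early-gene shift in light-pulsed (LP) cells, a Vip-like
45% non-detect rate in the groups where Vip is low, detection limit 40
cycles, and truncated-discrete-Gaussian spatial placement on the 7×7 grid
(ventral-core bias for group 1, dorsal-shell for group 2, diffuse for 3–4).
Per-gene baselines are evenly spaced over 22–30 cycles (housekeeping at 19),
so profiles have variance even at zero noise.

Ligand–receptor roles use a two-level block design: the ligand is high
(−3 cycles) in the source and autocrine groups and low (+3) elsewhere, the
receptor high in target and autocrine groups. Group proportions are
0.15/0.15/0.35/0.35 with one autocrine group per pair so that (a) each gene
is high in exactly half the cells, which pins the pooled median into the gap
between expression levels and makes the sign quadrants recoverable, and
(b) the autocrine fraction a = 0.35 gives a planted ligand–receptor
correlation of 4a − 1 = 0.4, detectably above the permutation null at the
default sample size. The signature magnitudes are calibration choices of
this package, frozen after a 20-seed recovery calibration (median ARI 1.0),
not values taken from any measured dataset.

Not emulated: qPCR amplification kinetics and preamplification bias,
circadian time courses (single time point), animal-to-animal structure,
continuous (non-block) expression gradients, and correlated dropout across
genes. Passing the planted-recovery tests therefore shows the pipeline
recovers block-structured phenotypes under Gaussian cycle noise; it does not
by itself certify performance on real single-cell heterogeneity.

## Numerical conventions and degenerate inputs

Eigen-decompositions use LAPACK `eigh` on dense symmetric matrices (the
graphs have at most a few hundred nodes). Apportionment of cells to groups
uses largest-remainder rounding; all randomness flows through explicit
`numpy` Generators seeded from user-supplied integers — there is no hidden
global state, and equal (config, seed) reproduces every artifact
bit-for-bit (the pipeline manifest records SHA-256 hashes of every emitted
table). Degenerate cases are explicit: empty post-QC datasets and
single-cluster silhouettes raise; zero-variance genes are excluded with
warnings; an edgeless cell graph pools every cell into the residual group
with a warning rather than failing the run.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
200-cell default datasets (20 seeds for recovery statistics), 200-graph
random suites of ≤ 10-node graphs for the modularity oracle (exhaustive
search by restricted-growth-string enumeration), 500 runs × 100 permutations
for screen calibration, and brute-force oracles on fixtures of up to 60
items. These sizes give stable statistics while keeping any single check
under half a minute on one CPU. The study-data checks (published sample
counts, PCA variance, marker fractions, group sizes, silhouettes, enrichment
fractions) require the supplementary raw-Ct tables, which are not
redistributable with the package; `scnpheno.io.load_study_tables` documents
the expected layout under `data/supplementary/`.

## Known limitations

* Modularity maximization is NP-hard; the refinement stack is a heuristic
  and can in principle fall short on adversarial graphs, though no shortfall
  above 0.013 was observed across thousands of small random graphs.
* Missing-data Pearson uses pairwise-complete observations, so the
  correlation matrix is not guaranteed positive semidefinite; MDS truncates
  the resulting negative eigenvalues and reports the unrecovered fraction.
* Enrichment p-values are unadjusted by design (matching the reporting
  convention the package follows); users scanning many pairs/groups should
  enable the BH mode.
* The regime quadrants dichotomize expression at the median; cells near the
  median carry sign noise, and genes with heavy dropout shift the detected
  median upward (fewer low cells detected), which biases the high/low split
  for that gene — visible as reduced source fractions for dropout-prone
  ligands such as Vip.
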