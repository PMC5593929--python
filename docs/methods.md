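# Methods

This note documents the models and procedures implemented in `micronet`,
the defaults and why, what the synthetic generators emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Compositional preprocessing

16S counts are compositional: only relative information is identified, and
any analysis on raw proportions induces spurious negative correlation. All
model fitting therefore happens in centred log-ratio (clr) coordinates:
counts + pseudocount are closed to proportions p and mapped to
`ln p_j − mean_k ln p_k`. Rows sum to zero by construction and the transform
is invariant to per-sample scaling.

- **Pseudocount** default 1 count per cell (simple, reproducible;
  configurable). Zero counts with a zero pseudocount are rejected.
- **Sample filter**: depth ≥ 1000 reads by default.
- **Taxon filter**: present in strictly more than 20 % of samples
  (`min_prevalence=0.2`, strict inequality) and mean relative abundance
  ≥ 0.01 % (`min_mean_relabund=1e-4`). The abundance rule is applied to the
  *mean* relative abundance across samples — a per-sample variant would be
  non-deterministic in which samples count — and filtering order is
  depth → abundance → prevalence (configurable).
- **Intergroup distances** operate on a caller-supplied distance matrix
  (e.g. UniFrac computed elsewhere). Each replicate pairs the smaller group
  with a without-replacement shuffle of the larger (disjoint cross-group
  pairs) and averages; 999 replicates by default. The mean over replicates
  converges to the expectation under uniformly random perfect cross-matching.

## Network inference (neighbourhood selection + StARS)

For each taxon j, an L1-penalised linear regression of clr_j on all other
clr columns (columns standardised, so λ is on a correlation scale and
λ_max = max |off-diagonal correlation|). An edge i–j exists when either
neighbourhood selects the other (OR rule; AND available), with sign from
the sum of the two directed coefficients. Constant clr columns yield
isolated nodes with a warning.

StARS: N = 50 subsamples of size `min(⌊10√n⌋, ⌊0.8 n⌋)` drawn without
replacement; at each λ of a 30-point log-spaced path (λ_min/λ_max = 0.01)
the per-pair selection frequency f gives instability 2f(1−f); the mean over
pairs is monotonised (non-decreasing as λ decreases) and the **smallest λ**
with monotonised instability ≤ β = 0.05 is selected — the densest stable
graph, the canonical StARS rule. If no λ qualifies the densest path graph
is returned with a warning flag. Edge confidences are the selection
frequencies at the selected λ; the reported network is the full-data refit
at that λ, with nodes restricted by the prevalence rule and annotated with
family-level taxonomy and geometric-mean relative abundance.

The source method description prints a "variability threshold of 0.05%".
Taken literally (β = 0.0005) the threshold is unattainable on realistic
data — subsample instability never falls that low before the monotonised
curve crosses it — so the canonical 0.05 is the default; both are
accepted via configuration.

## Graphlet topology

Orbit counts (orbits 0–14 of the connected graphlets on 2–4 nodes) are
exact: degree and closed-form 3-node counts, plus ESU enumeration of
connected 4-node induced subgraphs classified by internal degree sequence
(which identifies every ≤4-node connected graph uniquely). An independent
brute-force oracle (all subsets + isomorphism matching) backs the tests.

The graphlet correlation matrix is the Spearman correlation of the 11
non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11} across nodes, after
appending a dummy node with all counts 1 so that constant columns still
have defined correlations (any correlation still undefined after the dummy
is set to 0). GCD is the Frobenius norm over the full matrix (upper-triangle
variant available; exactly √2 smaller). Embedding is classical Torgerson
MDS of the pairwise GCD matrix, reporting the first two coordinates, the
eigenvalue spectrum and the raw 2-D stress.

## Robustness and keystones

Natural connectivity uses the unweighted adjacency spectrum,
`ln((1/N) Σ exp(λ_i))`; it is 0 for an edgeless graph and monotonically
non-increasing under edge removal. Attack curves remove nodes until one
remains, recording the value after each removal; targeted orderings
(degree, betweenness) are computed **once on the intact graph** (static;
dynamic recomputation available by flag — static is deterministic and the
common convention), random attacks average 30 orderings. Betweenness is
exact unnormalised Brandes. Keystone score = degree-rank + betweenness-rank
(average ranks on ties; rank 1 = highest), residual ties broken by higher
geometric-mean abundance then taxon id — an explicit operationalisation of
"hub and bottleneck", which the source leaves unstated.

## Cross-experiment edge recovery

All node pairs among the common taxa are ranked by descending confidence
(ties lexical, fully deterministic); sweeping the cutoff k gives precision,
recall, F1, TPR and FPR against the other experiment's network as truth
(presence at its selected λ). The headline is max-F1, judged against the
at-random baseline = truth edge density. Negatives are the truth's
non-edges within the common-taxa universe.

## Multilevel sparse PLS for ΔIgA

- **Response**: per-subject consecutive-time differences of sIgA (first
  time point drops out), pooled, centred, scaled to unit variance; a
  zero-variance guard returns zeros with a degenerate flag.
  Difference-from-baseline is available as a configuration.
- **Design**: X_w = X − subject means + grand mean (split-plot within
  decomposition; idempotent, removes between-subject variation exactly;
  singleton subjects are rejected by name).
- **Fit**: PLS1 in regression mode, 2 components default; each loading
  vector is soft-thresholded so that exactly `keep_per_component` (default
  8) taxa survive, then normalised; coefficients map back through
  B = W(PᵀW)⁻¹C. With no thresholding and enough components this
  reproduces OLS (tested).
- **Stability selection**: 100 refits on 50 % subject-level subsamples
  (resampling subjects preserves the multilevel structure); a taxon's score
  is its selection frequency.
- **Iterative filter**: for m in {all, 32, 16, 8, 4} the model is refitted
  on the top-m taxa by stability and scored on an independent experiment by
  out-of-sample r² = 1 − SSE/SST (not clamped; can be negative); the refit
  with the best oos r² is returned.
- **"Significance at α = 0.05"** is operationalised as a stability score
  exceeding the 95th percentile of scores under response permutation,
  since no test formula is given in the source.

## IgA-Seq coating index

`ICI = (ra⁺ + ε)/(ra⁻ + ε)` per taxon and sample; ε defaults to one read
at the deepest fraction as a relative abundance, so ICI is finite and the
reciprocal identity ICI(pos,neg)·ICI(neg,pos) = 1 holds exactly. Taxa are
ranked by median log2 ICI; "consistently over-coated" = median > 0 in
≥ 75 % of samples (an invented consensus rule — the source used LEfSe,
which is out of scope here).

## Synthetic generators (the ground-truth world)

Counts follow a logistic-normal multinomial: latent z ~ N(0, Ω⁻¹) with Ω a
positive-definite precision whose off-diagonal support is exactly the
target graph (edge weight 0.5, diagonal raised to |λ_min| + 0.1), softmax
to a composition, multinomial at a depth uniform in 2 000–20 000 reads.
Defaults echo a desk-scale murine 16S study (p = 40–53 taxa, n = 100–150
samples; the sPLS world uses 53 taxa with train n = 96 and test n = 57
response samples and a support of 8 taxa with |β| = 1, noise sd 0.5).
Graph topologies: band (path-band diagonals), cluster (dense blocks),
scale-free (preferential attachment), all with exact edge counts. The
two-condition design shares a fixed edge set and removes a designated
keystone hub (degree 8 by default) from the perturbed condition. IgA-Seq
fractions sort each taxon into IgA+ with probability a/(1+a) of its coating
affinity. Every generator is a pure function of (parameters, seed).

What the generators do **not** emulate: taxon-specific abundance
heterogeneity (latent means are 0), overdispersion beyond multinomial,
time autocorrelation within subjects, phylogenetic structure, and
sequencing artefacts. A green recovery test therefore establishes that the
estimators recover the stated statistical structure at realistic size and
depth — not that they are robust to every real-data pathology.

Note that clr closure makes even independent latents show a −1/(p−1)
baseline pairwise correlation (≈ −0.11 at p = 10, observed down to −0.15
with the multinomial layer); tests assert this consequence rather than
exact zero correlation.

## Numerical choices

- λ path from the standardised clr data; lasso solved by coordinate
  descent (scikit-learn `lasso_path`) over the whole path per node.
- Spearman ties: average ranks. Edge-sign ties (zero coefficient sum):
  sign 0, edge kept.
- Edge ranking and keystone ties: lexical taxon-id order, so all rankings
  are bit-reproducible.
- All randomness flows from one master seed through named CRC-derived
  substreams (`pipeline.substream`), each < 2³¹; the pipeline manifest
  records every per-stage seed.

## Known limitations

- StARS at β = 0.05 returns the *densest* stable graph; on n ≈ 150
  samples this trades precision (~0.6–0.8 observed on synthetic data) for
  recall (~1.0). Downstream graphlet signatures inherit that false-edge
  noise, which can mask subtler topology contrasts between conditions —
  the cross-condition embedding separation test currently passes 7/10
  seeds against its 8/10 threshold for exactly this reason.
- GCD compares 11×11 correlation matrices; for networks under ~30 nodes
  the Spearman estimates are themselves noisy.
- The sPLS selected set is the union of per-component supports (up to
  `n_components × keep_per_component` taxa); correlated neighbours of true
  predictors are sometimes selected in their place.
- Weighted (confidence-weighted) robustness variants, 5-node graphlets,
  and covariance-mode (graphical lasso) inference are out of scope.
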