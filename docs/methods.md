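# Methods

`plankton_assembly` implements the quantitative-ecology chain used to study
how lake plankton communities (bacterial 16S and eukaryotic 18S ASV tables)
assemble over time: taxonomic and phylogenetic beta diversity, null-model
partitioning of assembly processes, the Sloan neutral community model,
Levins' niche breadth, Mantel correlograms of phylogenetic niche signal,
distance-decay relationships, co-occurrence networks, the trophic lake
index, and environmental heterogeneity. A synthetic-data generator produces
communities under known assembly regimes so every stage can be verified
against ground truth.

## Inputs and preprocessing

The universal input is a sample x ASV count table with a per-sample group
label (e.g. sampling month), a rooted Newick phylogeny whose tips are the
ASV ids, and per-sample metadata (coordinates) and environment
(physicochemistry) tables. Samples and ASVs are aligned by exact string
match across all artifacts; the tree is pruned to the shared ASV set.

Default preprocessing follows common amplicon practice: ASVs with fewer
than 20 reads total are removed, then samples are rarefied without
replacement to the minimum sample depth (multivariate hypergeometric
draw, seeded). The filter/rarefy order is configurable because survey
pipelines differ on it; rarefaction itself is optional.

## Beta diversity and its decomposition

Taxonomic dissimilarity is Bray-Curtis (on within-sample relative
abundances by default). Total dissimilarity D between samples x and y is
decomposed in the Podani-family quantitative scheme: with
A = sum_j min(x_j, y_j), B = sum_j (x_j - min), C = sum_j (y_j - min),

    D        = (B + C) / (2A + B + C)      (percentage difference = Bray-Curtis)
    Repl     = 2 min(B, C) / (2A + B + C)  (balanced species replacement)
    RichDiff = |B - C| / (2A + B + C)      (richness / abundance difference)

so D = Repl + RichDiff holds exactly and the ternary triplet
(S, Repl, RichDiff) with S = 1 - D sums to one. The Podani family was
chosen over Baselga's precisely because its D *is* Bray-Curtis; the
Baselga variant is available behind a flag for comparison.

Phylogenetic dissimilarity is the abundance-weighted beta mean nearest
taxon distance (betaMNTD): the average patristic distance from each taxon
in one sample to its closest relative in the other, weighted by relative
abundance (presence/absence weighting is a switch). Patristic distances
come from a single postorder sweep over the tree.

## Null-model assembly partitioning

betaNTI is the z-score of observed betaMNTD against a taxa-shuffle null:
tip labels are permuted across the whole phylogeny, preserving richness
and abundances while randomizing relatedness. By default one common set of
permutations serves all pairs (the convention of the picante-style tools
this framework follows, and much faster); a per-pair mode derives an
independent seeded null per pair from a stable hash of (master seed, i, j)
and gives identical results serial or concurrent. If a pair's null is
degenerate (zero variance, e.g. both samples hold identical taxa sets) and
the observation matches it, betaNTI is 0 — no phylogenetic divergence
signal — and the Raup-Crick index decides the class.

RC_bray locates the observed Bray-Curtis within a community-randomization
null that preserves each sample's richness and total reads: membership is
drawn without replacement with probability proportional to regional
occupancy (Gumbel top-k sampling), each drawn taxon is seeded with one
read, and the remaining reads are allocated multinomially by regional
relative abundance. RC = 2[(#{null < obs} + 0.5 #{null = obs})/n_null] - 1;
ties count at half weight so RC stays symmetric about zero. Published
implementations differ in these details, so the chosen variant is stated
here and carried in output headers.

Pairs are classified by the standard thresholds: homogeneous selection
(betaNTI < -2), variable selection (betaNTI > 2), dispersal limitation
(|betaNTI| < 2 and RC > 0.95), homogenizing dispersal (|betaNTI| < 2 and
RC < -0.95), undominated otherwise; boundary values fall to undominated by
strict inequality. Aggregates: deterministic = both selection classes,
stochastic = the rest, homogenizing = homogeneous selection + homogenizing
dispersal, differentiating = variable selection + dispersal limitation,
and the species-sorting-to-dispersal-limitation ratio
(selection classes / dispersal limitation). n_null defaults to 999.

## Sloan neutral model

With community size N (default: mean library size) and migration rate m,
the stationary relative abundance of a taxon with regional mean p follows
Beta(Nmp, Nm(1-p)). Nm is estimated by bounded nonlinear least squares (on
log Nm, three log-spaced starts) of observed occurrence frequency on mean
relative abundance, and m = Nm/N; fit quality is R^2 = 1 - SSE/SStot, with
a Wilson 95% envelope partitioning taxa into above/within/below.

Two evaluations of the model's occurrence probability are provided. The
classical form uses a detection threshold d = 1/N:
F(p) = 1 - I_d(Nmp, Nm(1-p)). For read-count data this approximation
systematically overstates Nm (~25% at m = 0.1, N = 2x10^4 on data whose
counts are exactly beta-binomial), so the default fit uses the exact
occurrence probability of the same model for an N-read sample,
1 - E[(1-q)^N] = 1 - B(Nmp, Nm(1-p)+N)/B(Nmp, Nm(1-p)),
which recovers the generating migration rate to within a few percent.
`detection="threshold"` reproduces the classical fit exactly.

## Niche breadth

Levins' B_j = 1 / sum_i P_ij^2, with P_ij the share of taxon j's reads in
sample i, ranges from 1 (single-sample specialist) to the number of
samples (perfectly even generalist) and depends only on proportions. The
community-level Bcom is the read-share-weighted mean of within-group B
(an unweighted mean is reported alongside, as conventions differ).

## Phylogenetic niche signal (Mantel correlogram)

Each ASV's niche value per environmental variable is its abundance-weighted
mean environment, after z-scoring variables so distances are unit-free;
niche distance is Euclidean. Patristic distances are cut into equal-width
classes (Sturges count by default); per class the Mantel statistic is the
negated Pearson correlation between the niche-distance vector and the
class-membership indicator — positive r at short distances means close
relatives have similar niches. Significance comes from permuting taxa
labels of the niche matrix (999 by default), with a progressive Holm
correction in class order. All non-empty classes are tested, which covers
the full phylogenetic depth, not just the short half.

## Distance decay, networks, trophic index, heterogeneity

Distance decay regresses pairwise community similarity (1 - Bray-Curtis,
or 1 - betaMNTD) on great-circle distance in km (haversine, Earth radius
6371 km), reporting the OLS slope and R^2 plus a Mantel test; no transform
is applied to either axis.

Co-occurrence networks use ASVs present in strictly more than half of a
group's samples, Spearman correlations (mid-rank ties, t-approximation
p-values) on relative abundances, and retain edges with |rho| > 0.6 and
p < 0.01. The absolute value is deliberate: negative edges are retained
and the positive:negative edge ratio reported. No multiple-testing
correction is applied by default (the raw-p convention of this literature);
Benjamini-Hochberg is available. Core nodes are the top-k by shortest-path
betweenness on the unweighted graph, ties broken lexicographically.

The trophic lake index combines Chl-a (ug/L), TP, TN and COD (mg/L):
TLI_j = 10(a_j + b_j ln x_j) with the widely used Chinese-lake
coefficients (Chl-a: 2.5/1.086; TP: 9.436/1.624; TN: 5.453/1.694; COD:
0.109/2.661) and correlation-derived weights W_j = r_j^2 / sum r^2 from
r = (1, 0.84, 0.82, 0.83). Both are plain data and swappable. Classes:
< 30 oligotrophic, 30-50 mesotrophic, 50-60 light eutrophic, 60-70 middle
eutrophic, >= 70 hypereutrophic. The bloom flag is strictly Chl-a > 40
ug/L (configurable to >=).

Environmental heterogeneity is the dispersion of samples in jointly
z-scored physicochemical space: both the mean within-group pairwise
Euclidean distance and the mean distance-to-centroid (PERMDISP-flavoured;
the latter is the headline statistic because it is robust to group size).
Group contrasts are tested by permuting group labels (999 by default,
seeded). Zero-variance variables are dropped with a warning.

## Synthetic communities

The generator encodes four assembly regimes at study-like sizes (27
samples/group, 2000 taxa, 2x10^4 reads/sample; lognormal source pools,
meanlog 0, sdlog 2):

* **Neutral**: sample-level relative abundances are Dirichlet with
  concentration N m p (the stationary large-N form of the neutral model),
  then multinomial reads. Marginal counts are exactly beta-binomial — the
  same model the Sloan fit assumes.
* **Selection**: a Brownian trait evolves on a simulated birth-death tree
  (Gillespie, ultrametric; traits standardized), and expected abundance is
  the source pool Gaussian-filtered by trait-environment mismatch with
  bandwidth sigma_sel (trait-SD units). Each sample then drifts around
  that expectation (Dirichlet, concentration N * sel_drift_m * w) before
  the read draw. The drift is essential, not cosmetic: without it,
  replicate samples under a shared filter contain the *same* dominant
  taxa, shared taxa contribute zero nearest-taxon distance under any
  relabelling, and no betaMNTD null can register the clustering that
  homogeneous selection produces in real surveys, where selection acts on
  clades while drift decides which clade members appear where. Homogeneous
  scenarios place the environment at +1 trait SD (an environment off the
  trait median filters a phylogenetically coherent subset); variable
  scenarios alternate samples between -1.5 and +1.5.
* **Dispersal limitation**: samples sit in n_clusters distant spatial
  clusters (~100 km apart, ~1 km jitter) whose pools drifted independently
  from a common pool via Dirichlet(drift_concentration * p) — the
  stationary limit of repeated neutral resampling, which perturbs dominant
  as well as rare taxa.
* **Environment panels** draw physicochemistry from plausible eutrophic
  urban-lake ranges, with Chl-a log-uniform on (2.2, 40] / (40, 564] ug/L
  for non-bloom/bloom samples at a controllable bloom fraction, and
  turbidity positively coupled to Chl-a.

The frozen reference scenarios used by the verification suite
(`preset_scenario`) fix strong filtering (sigma_sel = 0.2, sel_drift_m =
0.01) for the selection regimes and three cluster pools
(drift_concentration = 50) for dispersal limitation.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific amplification bias, temporal autocorrelation within a
group, interaction-driven (non-Gaussian) selection, and mixed regimes
acting simultaneously. Passing recovery checks therefore demonstrates
that the estimators identify their intended signals under their own
generating assumptions — not that any real community is so classified.

## Verification design and problem sizes

The test suite checks, at sizes chosen to keep a desk-scale run practical:
exact decomposition identities on 1000 random pairs; betaNTI
self-calibration on 200 community pairs with independent pool-to-tree
assignments across ten 200-tip trees (999 nulls); RC self-calibration on
200 pairs of null-generated communities whose generation weights are
iterated to the fixed point where realized regional abundances reproduce
themselves (999 nulls) — without that fixed point the plug-in null is not
exchangeable with the data and the extreme-RC rate is inflated regardless
of sample count; regime recovery over 10 seeds each at 27 samples with
1000-2000 taxa and 99 nulls; Sloan recovery at the full 2000-taxa scenario;
correlogram behaviour over 100 replicates of 100-tip trees (999
permutations); closed-form niche breadths; planted-block network recovery
(two 10-taxon blocks over a 60-taxon uncorrelated background, so
compositional closure does not manufacture cross-block edges); and
brute-force oracle equivalence for betaMNTD, Bray-Curtis, Spearman and
haversine at 1e-10.

## Numerical choices and degenerate inputs

Seeds: a single master seed; stage seeds are SHA-256 hashes of
(seed, stage, group) reduced below 2^31, so adding stages never perturbs
other stages' randomness. Distance matrices are symmetrized and
diagonal-zeroed after construction; Bray-Curtis is validated to [0, 1].
Pairs of empty samples yield missing decomposition rows. A constant
distance matrix is an error in Mantel tests; constant ASV vectors yield
NaN correlations and are excluded from networks. The Sloan fit refuses
degenerate tables in which every taxon occupies every sample. Trophic
classification requires strictly positive Chl-a/TN/TP/COD (ln x).
Percentages are reported to two decimals.

## Known limitations

The betaNTI shared-null mode trades per-pair null independence for a ~20x
speedup; both modes are available, and the per-pair mode's stable seeding
guarantees serial/concurrent equivalence. The taxa-shuffle null pool is the whole tip set of the
aligned tree (per-group pools are a configuration choice left to the
caller). The correlogram tests all non-empty classes rather than vegan's
half-range default. TLI coefficients and trophic cut points follow the
common Chinese-lake convention; surveys using other conventions must
inject their own coefficient set. No per-taxon assembly attribution
(iCAMP-style binning) is provided.
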