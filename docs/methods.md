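# Methods

## The individual metabolic connectome

`jsseconn` builds a brain network for a *single* FDG-PET scan, rather
than for a group. The premise is that two brain regions whose voxel
intensity distributions are similar share a similar regional glucose
metabolism profile, and that this similarity is a usable surrogate for
metabolic connectivity. Each of the 90 AAL cerebral regions (45 per
hemisphere, cerebellum excluded) contributes a sample of normalized
voxel intensities; the connection weight between regions i and j is

    w_ij = 1 − D_JS(P_i ‖ P_j)

where P_i is a kernel density estimate of region i's intensity
distribution and D_JS is the Jensen-Shannon divergence with logarithms
taken base 2:

    D_JS(P ‖ Q) = ½ D_KL(P ‖ M) + ½ D_KL(Q ‖ M),   M = (P + Q)/2.

With base-2 logarithms D_JS lies in [0, 1], is symmetric, and is finite
even when the two supports are disjoint (where it attains exactly 1);
these three properties are what make it preferable to the raw
Kullback-Leibler divergence for defining an undirected, bounded
adjacency matrix. The result per subject is a symmetric 90 × 90
similarity matrix with zero diagonal and entries in [0, 1].

Whether the adjacency should store the divergence or its complement is
a genuine modeling choice; the similarity convention (strong edge =
similar metabolism) is the default because downstream thresholding and
hub analysis assume that larger weights mean stronger connections. A
`edge_weight="divergence"` switch inverts this.

### Density estimation and discretization

Each ROI's PDF is a Gaussian-kernel density with Silverman's
rule-of-thumb bandwidth, h = 0.9·min(SD, IQR/1.34)·n^(−1/5), evaluated
per region pair on a common 256-point grid spanning the pooled sample
range of the two regions padded by three bandwidths on each side. The
pair-specific grid guarantees that both densities and their mixture
share support while adapting to the local intensity range; the
evaluated densities are renormalized to probability mass vectors so the
divergences are plain finite sums. Zero-spread samples fall back to a
bandwidth floor of 1e-6·max(1, |mean|), turning the density into a
near-point mass instead of a singularity. In the KL sum, terms with
P(i) = 0 contribute nothing and P(i) > 0 with Q(i) = 0 yields +inf; no
epsilon flooring is applied anywhere, because inside the JS divergence
the mixture M ≥ P/2 on P's support makes every term finite.

Because the grid, the bandwidths and the samples all scale together,
the connectome is exactly invariant to a global rescaling of a
subject's intensities — which is why proportional-scaling global
normalization (in-brain mean set to 1) is sufficient preprocessing.

## Graph features over the sparsity sweep

Each weighted network is binarized at 49 sparsity thresholds, 0.02 to
0.50 in steps of 0.01: at sparsity s exactly floor(s × 4005) strongest
edges are kept (4005 = 90·89/2), with ties broken by lexicographic
pair order so the edge set is reproducible. Edge sets are nested along
the sweep.

On every binary graph the package computes

* global metrics: clustering coefficient Cp, characteristic path
  length Lp, normalized γ = Cp/⟨Cp_null⟩ and λ = Lp/⟨Lp_null⟩,
  small-worldness σ = γ/λ, global efficiency, local efficiency,
  modularity Q (greedy agglomerative maximization), degree
  assortativity Ar, hierarchy Hr, and synchronization Sr;
* nodal metrics: degree, nodal efficiency, betweenness (unnormalized
  Brandes pair-fraction sum), mean shortest path length, and nodal
  clustering.

γ and λ are normalized by the means over a degree-preserving
Maslov-Sneppen null ensemble (10·|E| attempted swaps per surrogate,
seeded). The standalone default is 100 surrogates per graph; the
cohort-level feature extraction uses 20 per threshold, which keeps the
ensemble means stable enough for feature purposes at a fifth of the
cost. Hierarchy is the exponent β of C(k) ∝ k^(−β) fitted over nodes
with degree > 1 and positive clustering; synchronization is the
Laplacian eigenratio λ₂/λ_max. No standard definition of modularity
can exceed 1 and no Laplacian eigenratio is negative, so the Q ≈ 10
and Sr < 0 magnitudes sometimes quoted for such pipelines are not
reproducible under any convention; the standard definitions are used
here without adjustment.

Disconnected graphs are expected at the sparse end of the sweep: Lp
and nodal path length average over connected pairs only, while the
efficiency metrics score unreachable pairs as zero — every feature
stays finite across the whole sweep. A threshold whose normalized
metric is undefined (e.g. a triangle-free null ensemble) contributes
zero to the sum. Per metric, the *sum* of its 49 values across the
sweep (the "area under the curve" in the threshold sense) is the one
feature per metric per subject used downstream; global metrics are
AUC-summed exactly like nodal ones, for symmetry.

Hubs are nodes whose degree (or betweenness) exceeds the mean plus one
population standard deviation over the 90 nodes; a `ddof` switch gives
the sample-SD variant.

## Outcome classification

Three feature blocks enter a multi-kernel SVM: the 4005 connection
weights (x¹), the 11 global AUC features (x²), and the 450 nodal AUC
features (x³). Each block gets a linear kernel k_m(x, x′) = xᵀx′ on
z-scored features, and the MK-SVM solves the standard soft-margin dual
on the convex combination K = Σ_m β_m K_m with β_m ≥ 0, Σβ_m = 1:

    max_α Σᵢαᵢ − ½ ΣᵢΣⱼ αᵢαⱼyᵢyⱼ Σₘ βₘkₘ(xᵢᵐ, xⱼᵐ)
    s.t. Σᵢαᵢyᵢ = 0,  0 ≤ αᵢ ≤ C

with decision function f(x) = sign(Σᵢ yᵢαᵢ Σₘ βₘkₘ(xᵢᵐ, xᵐ) + b).
At a vertex of the β simplex this reduces exactly to a single-kernel
SVM, which the tests verify coefficient-for-coefficient. The QP itself
is delegated to libsvm (through scikit-learn); the kernel combination,
the β search and the validation protocol are this package's own. The
positive class is SZF (seizure free), encoded +1, and sign(0) maps
to +1.

Validation is nested leave-one-out cross-validation. In each outer
fold (one subject held out) the training set alone determines: the
feature-selection masks — a two-sample pooled-variance t test keeps
connection and nodal features with p < 0.05, while the 11-dim global
block is always retained — the per-feature standardization statistics,
and the hyperparameters, chosen by an inner leave-one-out grid search
over C ∈ {2⁻⁵, …, 2⁵} (11 values) and a regular simplex grid over β
(step 0.1 by default, 66 points; step 0.25, 15 points, for the large
seeded validation runs). Ties in inner accuracy resolve to the smaller
C, then to the earlier β in grid order. The held-out subject cannot
influence any of these computations, a property the test suite asserts
directly by mutating held-out features.

Consensus connections are those passing the t-test selection in
*every* outer fold — the leakage-free reading in which the test is
recomputed per loop on training data only. Performance is summarized
as accuracy, sensitivity and specificity from the pooled confusion
table, plus a ROC curve over the decision values whose trapezoid AUC
equals the normalized Mann-Whitney statistic. Correlated ROC curves
are compared with DeLong's placement-value test; a zero-variance
difference returns p = 1 by convention.

## The synthetic cohort generator

No patient imaging is distributed, so the generator fabricates
cohorts with the geometry the pipeline expects: two groups (default
20 + 20 subjects), 90 regions, 200 voxels per region. Region r has a
cohort-level baseline mean drawn from U(0.8, 1.2) in normalized
intensity units; each subject adds a global offset ~ N(0, (0.5·σ)²)
mimicking the between-subject scale variation that global
normalization removes; voxels are Gaussian with SD σ = 0.1. A group
effect is injected into chosen disjoint region pairs: the pair shares
one baseline mean, and in SZR subjects the second region is shifted by
δ·σ (default δ = 3), which lowers that pair's JS similarity in SZR.
The phantom-NIfTI mode writes the identical samples into cuboid
parcels of a label volume, so the image path (read → normalize →
extract → build) provably reproduces the direct-sample path.

What the generator does *not* emulate: PET point-spread and
partial-volume effects, anatomically shaped and differently sized
regions, spatially correlated noise, and the weak, heterogeneous
effect sizes of real clinical cohorts. Passing the effect-recovery
tests therefore demonstrates that the machinery is correct and
leakage-free — not that real surgical outcomes are predictable at any
particular accuracy. The published headline numbers for this kind of
analysis come from private patient data and are out of reach of a
synthetic validation by construction.

## Problem sizes and numerical choices

* Validation runs use 20 + 20 subjects, 200 voxels/ROI, 10 injected
  pairs at δ = 3, β grid step 0.25, 20 null surrogates per threshold;
  one full run (connectomes, features, nested LOOCV, permuted-label
  null) completes in a few minutes on one core.
* All randomness flows through `numpy.random.default_rng` seeds;
  rewiring uses an explicit xorshift generator inside the jitted swap
  loop so ensembles are bit-reproducible.
* Probability mass vectors must sum to 1 within 1e-9; network symmetry
  is enforced at 1e-12; dual feasibility |Σαy| at 1e-6.
* The permuted-label calibration asserts accuracy inside the 95%
  binomial band around 50% (n = 40: [0.345, 0.655]).

## Known limitations

* Betweenness and shortest paths treat the binary graphs as unweighted
  by design; weighted-graph metric variants are not provided.
* Greedy modularity is a deterministic heuristic; Q is the score of
  its partition, not a global optimum.
* The t-test selector assumes approximately Gaussian features with
  pooled variance; no multiple-comparison correction is applied, by
  design, since selection is internal to the cross-validation.
* With weak signal and thousands of candidate connections, nested
  LOOCV accuracy can dip below chance (a known artifact of
  selection-heavy pipelines at small n); the permutation-null test
  bounds this behavior but does not remove it.
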