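# Methods

This note documents the statistical model behind `litmap`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## 1. Corpus and terms

Records carry id, title, abstract, language, document type and year.
Filtering removes records with missing fields, non-matching language or
document type, and duplicate ids (first occurrence kept); the operation is
idempotent.

Terms are contiguous 2- and 3-token n-grams of the lowercased abstract
(tokens split on non-alphanumeric characters, no stemming). Frequency is
**document frequency** — the number of records containing the term at
least once — because the downstream co-occurrence statistic is also
abstract-level and binary; a raw occurrence count is available as a
switch (`count_mode="occurrence"`). Whether titles participate in
detection is a switch too (default: abstract only). Ties in the ranking
break lexicographically so the list is reproducible. Exclusion
dictionaries (general-language terms, brain-region names) are versioned
one-term-per-line text files applied before ranking. A deep-learning
part-of-speech extractor can replace this stage entirely: the rest of the
pipeline only consumes the ranked `TermList`.

## 2. Semantic graph, embedding, clustering

The co-occurrence matrix counts, for each term pair, the records whose
detected-term set contains both (diagonal = document frequency).
Similarity is the cosine between co-occurrence rows, **including** the
diagonal (switchable); each node keeps its 15 most similar partners, and
the edge set is the union of per-node selections (union symmetrization is
the common kNN-graph dialect; mutual-kNN would orphan peripheral terms).
All-zero rows become isolated nodes with a warning.

node2vec embeds the graph: second-order walks with return parameter p,
in-out parameter q, transitions proportional to edge weight within the
bias scheme; skip-gram with negative sampling (5 negatives,
unigram^0.75 noise distribution, word2vec-style reduced windows, linear
learning-rate decay) trains one vector per node. Defaults: d = 700
(mirroring the production-scale choice of a large embedding space),
p = q = 1, walk length 30, 20 walks/node, window 10, 5 epochs. The
implementation is single-threaded and seeded end-to-end, so a fixed seed
gives bit-identical embeddings; tests use smaller d (32–64) since
synthetic graphs have a few hundred nodes.

K-means (k-means++ seeding, 10 restarts, best inertia) partitions the
embedding. k is selected by the Kneedle elbow rule on the (k, inertia)
curve: normalize both axes to [0, 1], flip the decreasing convex curve to
increasing concave, and take the first local maximum of the difference to
the diagonal that stays above its sensitivity threshold (S = 1). A curve
without a qualifying local maximum returns an explicit "no knee", never a
guess. The mean silhouette is computed post hoc for candidate k
(singletons contribute s(i) = 0, the sklearn convention).

## 3. Article assignment and prevalence profiles

An article belongs to community c iff ≥ 1 detected term is labeled c;
multi-assignment is expected and unweighted (no weighting by the number
of detected terms). Prevalence profiles use case-insensitive substring
matching of dictionary strings against title + abstract (scope
switchable). Substring matching can over-match short strings, so the
default dictionary prefers multiword or morphologically distinctive
strings. Empty communities are reported as missing, never as 0%.

## 4. ALE

* **Kernel.** Isotropic Gaussian, σ = FWHM / (2√(2 ln 2)), FWHM fixed at
  10 mm for **all** studies regardless of sample size (deliberately not
  the sample-size-adaptive variant). The kernel is evaluated at
  voxel-center offsets, truncated at 3.5σ, and normalized to unit sum, so
  it is a probability kernel; one focus deposits exactly one unit of
  mass. Within a study, foci combine by voxel-wise **maximum** (the
  modern convention; union-probability available as a switch), so
  multiple nearby peaks do not multiply-count.
* **Combination.** ALE(v) = 1 − ∏_s (1 − MA_s(v)) — the probability that
  at least one study activates at v under independence.
* **Voxel null.** Two models:
  * `histogram` (default, the classic analytic null): pool each study's
    in-mask MA values into a histogram (bin width 1e-5), combine
    histograms pairwise under the union formula with mass the product of
    bin masses, re-binned each step; p(v) is the upper tail at the
    observed ALE. This assumes the MA marginal is the same at every voxel
    (spatial stationarity), which is accurate away from the mask
    boundary. **On masks comparable in size to the kernel it is badly
    biased near edges** — measured errors up to ~0.4 in p on a 6³-voxel
    mask — which matters for desk-scale simulations, not for brain-sized
    masks where boundary voxels are a small fraction.
  * `relocation`: the exact per-voxel null under uniform focus
    relocation — the same null model the cluster permutations sample.
    For a study with n foci, P(MA(v) ≤ w) = F_v(w)^n with F_v computed by
    exact enumeration (mask-kernel level-set convolutions); per-voxel
    distributions combine across studies on the bin lattice, with voxels
    sharing identical boundary profiles deduplicated. Cost scales with
    mask size; intended for small grids, where it agrees with a
    brute-force relocation oracle to Monte-Carlo error.
  All binned-null arithmetic is exact to one bin: intermediate re-binning
  can legitimately move a tie mass across a single bin edge, so oracle
  comparisons bracket at one-bin resolution.
* **z transform.** z(v) = Φ⁻¹(1 − p(v)), p floored at the smallest
  positive double, z clipped at ±38.5 (the float64 quantile limit).
* **Cluster-level FWE.** Supra-threshold voxels (voxel p < 0.001) group
  by 26-connectivity (6 available). The cluster-forming p is converted to
  an ALE-value threshold via the null; each permutation redraws every
  study's foci uniformly over in-mask voxel centers (focus count
  preserved), recomputes ALE, re-applies the same threshold and records
  the maximum cluster statistic; cluster p_fwe uses the add-one
  convention (1 + b)/(1 + n). Re-deriving the threshold from a
  recomputed analytic null each permutation would change nothing
  statistically (the same rule is applied to observed and permuted data)
  and costs orders of magnitude more, so the fixed-threshold form is
  used. Statistics: `extent` (voxel count, default) and `mass` (sum of
  z). Extent is a small-integer statistic; under sparse nulls rank ties
  make its Monte-Carlo p conservative in a lattice-dependent way, so
  calibration studies should prefer mass. Measured family-wise
  false-positive rate at α = 0.05 under uniform-foci nulls: 0.040 (mass)
  and 0.035 (extent) over 200 simulated datasets at probe time.
* **Spaces.** Inputs are validated as MNI152-style mm; other space tags
  are rejected unless explicitly overridden. Talairach conversion is out
  of scope.

## 5. Convergence

Overlap maps count communities whose **binary cluster-level significance
masks** cover each voxel (not unthresholded maps; min-z export exists for
inspection). The robustness mask keeps voxels reaching the overlap
threshold (default 4) at *every* granularity level, so it shrinks
monotonically as levels are added; its 26-connected components are the
convergence ROIs, each with an unweighted center of mass in mm.
Granularity levels default to the term counts {1200, 1500, 2000, 2285}
at production scale; synthetic runs use levels matched to corpus size.

## 6. Specificity

The ROI statistic is the **unthresholded** cluster mass: the sum of z
over a fixed ROI (not over supra-threshold voxels — the ROI is already
fixed by the robustness analysis, and thresholding inside it would
discard graded evidence). The null redraws |matched| studies without
replacement from a reference pool of non-matching studies, one RNG
stream, independent iterations; p is add-one Monte-Carlo. ROI-flagged
studies are **included** in the matched set by default (p-values then
indicative; `exclude_roi_flag` switches them off).

Validity caveat: the Monte-Carlo p is exactly uniform under the null
only when the matched set is exchangeable with pool draws. When the
matched set is independent of a *small* fixed pool, every p inherits that
pool's quantile error (of relative order √(n_draw/n_pool)); with a pool
much larger than the draw this is negligible, and the calibration test
uses the exchangeable design.

## 7. Synthetic generators: what a green test establishes

The corpus generator plants disjoint per-community term vocabularies
(2- and 3-token terms), draws each abstract's terms with replacement from
its community under a Zipf(rank^−1.1) law (about 6 terms per abstract,
Poisson), mixes in one foreign-community term with probability 0.02 by
default, interleaves filler words from a disjoint vocabulary (so fillers
can never be detected as terms), and plants single-token measure-marker
words at per-community rates. The coordinate generator scatters each
study's foci around its community locus or the shared locus
(Bernoulli per focus, Gaussian jitter, default sd 5 mm — the order of
between-study localization scatter) with uniform in-mask noise foci, and
the reference pool is uniform-foci only, matching the support of the ALE
permutation null.

Not emulated: grammatical text (terms are bags, so the tagger-free
extractor is exact by construction), citation structure, realistic
spatial autocorrelation of brain activations, inter-study differences in
smoothing or sample size, and the ROI-table curation process (modeled
only as a per-study input flag). A green recovery test therefore
establishes the correctness of the pipeline's statistics and plumbing on
a corpus whose generative assumptions match the method's, not performance
on real literature.

## 8. Numerical choices and degenerate inputs

* Seeds: one master seed; every stage seed is derived by hashing
  (master, stage name, stage indices), all < 2³¹; full runs are
  byte-identical under a fixed master seed.
* Bin widths: 1e-5 (production null), relaxed to 1e-4/1e-3 in simulation
  studies where only rank-consistency between observed and null matters.
* Ties: term ranking and kNN selection break lexicographically; the
  Monte-Carlo p counts ties as exceedances (add-one convention).
* Degenerate inputs: empty masks, empty corpora, k > n, pools smaller
  than the matched set, zero-resolution grids and loci outside the mask
  raise `ConfigError` naming the offending field. Foci outside the mask
  are projected to the nearest in-mask voxel center with a warning. A
  single-voxel mask yields a degenerate permutation null and p_fwe = 1.
* Minimum studies per ALE defaults to 7 in the pipeline (very small
  study sets cannot reach cluster significance and are skipped with a
  log message, mirroring the sleep-disorders situation at production
  scale).

## 9. Known limitations

* The histogram voxel null is boundary-biased on small masks (see §4);
  use the relocation null there.
* node2vec/SGNS hyperparameters beyond d are conventions, not fitted;
  community recovery on well-separated synthetic corpora is insensitive
  to them, real corpora may not be.
* The specificity p is per-ROI; no family-wise correction across ROIs is
  applied (reported per ROI by design).
* Embeddings, and hence exact cluster label indices, are
  implementation-defined up to relabeling; all cross-granularity logic
  uses counts and masks, never label identity.
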