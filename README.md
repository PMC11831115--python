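# litmap

**Semantic communities in a scientific literature corpus, and where they
converge in the brain.**

`litmap` is a reusable pipeline for a question that comes up whenever a
widely used concept (arousal, salience, effort, …) spans many fields of
research: do the different research communities that use the term share a
common neural substrate? The pipeline answers it in four stages:

1. **Literature mining.** Bibliographic records are filtered and
   deduplicated; the most frequent multiword terms (2–3 word n-grams, with
   exclusion dictionaries for general language and brain-region names) are
   ranked by document frequency.
2. **Semantic communities.** Terms become nodes of a graph whose edges
   carry the cosine similarity between term co-occurrence profiles,
   sparsified to each term's 15 nearest neighbors. The graph is embedded
   with node2vec (biased second-order random walks + skip-gram with
   negative sampling) and partitioned with K-means; the number of
   communities k is chosen by the Kneedle elbow criterion on the inertia
   curve and validated with the mean silhouette. Articles are projected
   onto every community whose terms they mention, and per-community
   physiological-measure prevalence profiles are computed by dictionary
   matching.
3. **Coordinate-based meta-analysis (ALE).** For each community, the peak
   coordinates of its neuroimaging studies are blurred with a fixed-FWHM
   (10 mm) Gaussian probability kernel into modeled-activation maps
   MA_s(v), combined across studies as

       ALE(v) = 1 − ∏_s (1 − MA_s(v)),

   tested voxel-wise against an analytic null (weighted convolution of the
   per-study MA histograms under the random-spatial-association
   assumption; an exact per-voxel focus-relocation null is also available),
   and corrected at cluster level by family-wise-error Monte-Carlo
   permutations of foci (cluster-forming p < 0.001, α = 0.05).
4. **Convergence and specificity.** Per-community significance masks are
   overlapped; voxels where ≥ 4 (or 5) communities overlap at *every*
   semantic granularity level form the robustness mask, whose connected
   components are convergence ROIs. For each ROI, a Monte-Carlo
   cluster-mass test (sum of voxel z over the ROI; 10,000 draws of
   equally many non-matching studies) asks whether the activation is
   specific to the query-matched literature:
   p = (1 + #{null ≥ observed}) / (1 + n_iter).

Every stage is testable without any download: the `litmap.synthetic`
module generates corpora with planted term communities (Zipf-like term
frequencies, controllable cross-community mixing, planted measure-marker
words) and coordinate studies with planted per-community loci plus one
shared locus, so recovery can be scored against ground truth.

## Worked example

Run the full synthetic demonstration (seven planted communities, two
granularity levels, one shared activation locus):

```sh
litmap run-all --seed 1 --out-dir demo_run
```

which prints (exact output, deterministic under the seed):

```json
{
 "term_ari": 1.0,
 "planted_k": 7,
 "selected_k": {"150": 7, "210": 7},
 "shared_locus_hit": true,
 "robustness_retains_shared_locus": true,
 "specificity_p": 0.005,
 "n_ale_runs": 14
}
```

Reading the report: the semantic pipeline recovered the seven planted term
communities perfectly (adjusted Rand index 1.0 against generator truth),
the elbow criterion selected k = 7 at both granularity levels (150 and 210
terms), 14 per-community ALE meta-analyses ran (7 communities × 2
granularities), the voxel with the highest cross-community overlap is the
planted shared locus and it survives the cross-granularity conjunction,
and the ROI's activation is specific to the matched studies (Monte-Carlo
p = 0.005 = 1/200, the smallest value attainable at 199 null draws).
`demo_run/` then contains every artifact: the corpus (JSONL), term list
and edge tables (TSV), cluster solutions (JSON), per-community cluster
tables (TSV), overlap/robustness maps (NIfTI), ROI table, specificity
results, and a `manifest.json` with the SHA-256 of every file.

Library use mirrors the CLI; see the docstrings of `litmap.ale.run_ale`,
`litmap.semantic_graph`, `litmap.specificity.specificity_test`, and
`litmap.pipeline.simulate_and_run`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full synthetic pipeline from scratch at the given seed (every
stage seeded from it), checks that the run completes, prints the recovery
report, and writes the results JSON. The statistical guarantees
themselves (ALE union identity, analytic-null correctness against
brute-force Monte-Carlo oracles, family-wise-error calibration,
planted-community and shared-locus recovery, specificity calibration and
power, bit-level determinism) are asserted in `tests/test_acceptance.py`.

## Scope notes

Out of scope by design: live PubMed/Web of Science retrieval,
deep-language-model part-of-speech tagging (the term extractor is a
deterministic n-gram frequency contract with pluggable exclusion
dictionaries), UMAP layouts and figure rendering, surface projection and
atlas overlays, and Talairach-space conversion (inputs are validated as
MNI152-style mm coordinates). See `docs/methods.md` for the statistical
model, parameter defaults, and known limitations.
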