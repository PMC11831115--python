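import dataclasses
import json

import numpy as np
import pytest

from litmap.corpus import detect_terms, extract_terms, TermList, tokenize
from litmap.grid import ConfigError, GridSpec
from litmap.synthetic import (
    CoordConfig,
    CorpusConfig,
    generate_coordinate_studies,
    generate_corpus,
    generate_reference_db,
)

SMALL_SPEC = GridSpec(resolution_mm=6.0, semi_axes_mm=(40.0, 48.0, 40.0))


# ---------------------------------------------------------------------------
# corpus generator


def test_single_community_all_articles_map_to_it():
    cfg = CorpusConfig(n_communities=1, terms_per_community=10,
                       n_articles_per_community=20, cross_community_mixing=0.0, seed=1)
    _, truth = generate_corpus(cfg)
    assert all(cs == {0} for cs in truth.article_communities.values())


def test_disjoint_communities_no_mixing_no_crossings():
    cfg = CorpusConfig(n_communities=2, terms_per_community=10, n_shared_terms=0,
                       n_articles_per_community=40, cross_community_mixing=0.0, seed=2)
    records, truth = generate_corpus(cfg)
    vocab0 = set(truth.community_vocab[0])
    vocab1 = set(truth.community_vocab[1])
    tl = TermList([(t, 1) for t in sorted(vocab0 | vocab1)])
    for r in records:
        present = detect_terms(r, tl)
        assert not (present & vocab0 and present & vocab1)
        # truth recoverable from term membership alone
        assert truth.article_communities[r.record_id] == {
            0 if present & vocab0 else 1
        }


def test_corpus_deterministic_under_seed():
    cfg = CorpusConfig(seed=1, n_articles_per_community=10)
    r1, t1 = generate_corpus(cfg)
    r2, t2 = generate_corpus(cfg)
    assert r1 == r2
    assert t1.term_community == t2.term_community
    assert t1.article_communities == t2.article_communities


def test_zipf_rank_frequency_slope():
    """Log-log slope of term draw counts over the top half of ranks is the
    configured exponent within 10%."""
    expo = 1.1
    cfg = CorpusConfig(n_communities=1, terms_per_community=40,
                       n_articles_per_community=4000, terms_per_abstract_mean=6.0,
                       cross_community_mixing=0.0, zipf_exponent=expo, seed=3)
    records, truth = generate_corpus(cfg)
    occ = extract_terms(records, 10_000, count_mode="occurrence")
    counts = [occ.frequency(t) for t in truth.community_vocab[0]]
    ranks = np.arange(1, len(counts) + 1)
    top = slice(0, len(counts) // 2)
    slope = np.polyfit(np.log(ranks[top]), np.log(np.array(counts)[top]), 1)[0]
    assert abs(-slope - expo) < 0.1 * expo


def test_measure_markers_planted_at_configured_rate():
    cfg = CorpusConfig(n_communities=1, n_articles_per_community=300,
                       measure_dictionary_rates={0: {"heart": 0.5}}, seed=4)
    records, truth = generate_corpus(cfg)
    n = sum(1 for r in records if "electrocardiography" in r.abstract)
    assert n == sum(1 for m in truth.article_measures.values() if "heart" in m)
    assert 0.5 - 3 * 0.029 < n / 300 < 0.5 + 3 * 0.029  # 3 binomial sigma


def test_corpus_config_errors_name_the_field():
    with pytest.raises(ConfigError, match="cross_community_mixing"):
        CorpusConfig(cross_community_mixing=1.5)
    with pytest.raises(ConfigError, match="n_communities"):
        CorpusConfig(n_communities=0)
    with pytest.raises(ConfigError, match="zipf_exponent"):
        CorpusConfig(zipf_exponent=-1)


# ---------------------------------------------------------------------------
# coordinate generator


def test_zero_noise_limit_foci_at_locus():
    cfg = CoordConfig(n_studies_per_community=5, foci_per_study_range=(2, 4),
                      focus_sd=1e-9, p_focus_at_shared=0.0, p_noise_focus=0.0,
                      community_locus={0: (0.0, 0.0, 0.0)}, mask_spec=SMALL_SPEC, seed=5)
    studies = generate_coordinate_studies(cfg, [0])
    for s in studies:
        assert np.allclose(s.foci, 0.0, atol=1e-6)


def test_all_foci_at_shared_locus_when_p_is_one():
    cfg = CoordConfig(n_studies_per_community=5, focus_sd=1e-9, p_focus_at_shared=1.0,
                      p_noise_focus=0.0, community_locus={0: (12.0, 0.0, 0.0)},
                      shared_locus=(0.0, 6.0, 0.0), mask_spec=SMALL_SPEC, seed=6)
    for s in generate_coordinate_studies(cfg, [0]):
        assert np.allclose(s.foci, [0.0, 6.0, 0.0], atol=1e-6)


def test_focus_empirical_mean_near_locus():
    """Law of large numbers: with sd=4 and 200 single-community studies the
    empirical mean focus is within 1 mm of the planted locus."""
    cfg = CoordConfig(n_studies_per_community=200, foci_per_study_range=(3, 8),
                      focus_sd=4.0, p_focus_at_shared=0.0, p_noise_focus=0.0,
                      community_locus={0: (6.0, -6.0, 0.0)}, mask_spec=SMALL_SPEC, seed=7)
    foci = np.vstack([s.foci for s in generate_coordinate_studies(cfg, [0])])
    assert np.linalg.norm(foci.mean(axis=0) - np.array([6.0, -6.0, 0.0])) < 1.0


def test_all_foci_inside_mask_and_deterministic():
    cfg = CoordConfig(n_studies_per_community=10, focus_sd=25.0, p_noise_focus=0.3,
                      mask_spec=SMALL_SPEC, seed=8)
    grid = cfg.grid()
    s1 = generate_coordinate_studies(cfg, [0, 1, 2])
    s2 = generate_coordinate_studies(cfg, [0, 1, 2])
    for a, b in zip(s1, s2):
        assert a.study_id == b.study_id and np.array_equal(a.foci, b.foci)
    for s in s1:
        assert grid.contains_mm(s.foci).all()


def test_locus_outside_mask_rejected():
    cfg = CoordConfig(community_locus={0: (500.0, 0.0, 0.0)}, mask_spec=SMALL_SPEC)
    with pytest.raises(ConfigError, match="locus"):
        generate_coordinate_studies(cfg, [0])


# ---------------------------------------------------------------------------
# reference pool


def test_reference_db_zero_studies_rejected():
    with pytest.raises(ConfigError, match="n_studies"):
        generate_reference_db(CoordConfig(mask_spec=SMALL_SPEC), 0)


def test_reference_db_reproducible():
    cfg = CoordConfig(mask_spec=SMALL_SPEC, seed=9)
    a = generate_reference_db(cfg, 12)
    b = generate_reference_db(cfg, 12)
    assert all(np.array_equal(x.foci, y.foci) for x, y in zip(a, b))
    assert all("non-matching" in s.tags for s in a)


def test_reference_mean_pairwise_distance_matches_uniform_oracle():
    """Monte-Carlo oracle: mean pairwise distance of pooled reference foci
    matches 1e5 uniform voxel-center draws in the same mask."""
    cfg = CoordConfig(mask_spec=SMALL_SPEC, foci_per_study_range=(3, 8), seed=10)
    grid = cfg.grid()
    foci = np.vstack([s.foci for s in generate_reference_db(cfg, 150)])
    rng = np.random.default_rng(1234)
    coords = grid.mask_coords_mm
    a = coords[rng.integers(0, len(coords), 100_000)]
    b = coords[rng.integers(0, len(coords), 100_000)]
    expected = np.linalg.norm(a - b, axis=1).mean()
    pairs_a = foci[rng.integers(0, len(foci), 50_000)]
    pairs_b = foci[rng.integers(0, len(foci), 50_000)]
    got = np.linalg.norm(pairs_a - pairs_b, axis=1).mean()
    assert abs(got - expected) / expected < 0.03
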