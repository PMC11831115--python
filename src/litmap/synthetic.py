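"""Synthetic corpora and coordinate studies with known ground truth.

The generators emulate the structure of the real inputs without requiring
any download: abstracts are bags of multiword terms drawn from overlapping
thematic communities with Zipf-like term frequencies (plus filler words
from a disjoint vocabulary), articles carry physiological-measure marker
words at community-specific rates, and coordinate studies scatter their
peak foci around planted per-community loci plus one shared locus, with
optional uniform in-mask noise foci. Every generator is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ale import CoordinateStudy
from .corpus import BibRecord
from .grid import BrainGrid, ConfigError, GridSpec

__all__ = [
    "CorpusConfig",
    "CoordConfig",
    "CorpusTruth",
    "generate_corpus",
    "generate_coordinate_studies",
    "generate_reference_db",
]

#: marker word planted in an abstract when an article "uses" a measure;
#: single tokens so they never enter the 2-3-gram term ranking
MEASURE_MARKERS = {
    "pupil": "pupillometry",
    "heart": "electrocardiography",
    "respiration": "spirometry",
    "blood": "sphygmomanometry",
    "EDA": "electrodermal",
}

_N_FILLER = 400


@dataclass(frozen=True)
class CorpusConfig:
    """Stated world of a synthetic corpus.

    ``cross_community_mixing`` is the probability that an abstract draws
    one of its terms from a foreign community; ``zipf_exponent`` shapes the
    within-community rank-frequency law of term draws;
    ``measure_dictionary_rates`` maps community -> measure category ->
    probability that an article of that community carries the category's
    marker word.
    """

    n_communities: int = 7
    terms_per_community: int = 30
    n_shared_terms: int = 0
    n_articles_per_community: int = 150
    terms_per_abstract_mean: float = 6.0
    cross_community_mixing: float = 0.02
    zipf_exponent: float = 1.1
    measure_dictionary_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_communities", "terms_per_community", "n_articles_per_community"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.n_shared_terms < 0:
            raise ConfigError("n_shared_terms: must be >= 0")
        if self.n_shared_terms and self.n_communities < 2:
            raise ConfigError("n_shared_terms: needs >= 2 communities")
        if self.terms_per_abstract_mean <= 0:
            raise ConfigError("terms_per_abstract_mean: must be > 0")
        if not 0.0 <= self.cross_community_mixing <= 1.0:
            raise ConfigError("cross_community_mixing: must be in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent: must be > 0")
        for c, rates in self.measure_dictionary_rates.items():
            for cat, p in rates.items():
                if cat not in MEASURE_MARKERS:
                    raise ConfigError(
                        f"measure_dictionary_rates: unknown category {cat!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"measure_dictionary_rates: rate for {c}/{cat} not in [0, 1]"
                    )


@dataclass
class CorpusTruth:
    """Ground truth of a generated corpus, for scoring recovery."""

    term_community: dict[str, int]
    article_communities: dict[str, set[int]]
    article_measures: dict[str, set[str]]
    community_vocab: dict[int, list[str]]


def _make_vocab(config: CorpusConfig) -> tuple[dict[int, list[str]], dict[str, int]]:
    """Per-community term vocabularies; shared terms appear in two vocabs
    but are owned (in the truth map) by their home community."""
    vocab: dict[int, list[str]] = {c: [] for c in range(config.n_communities)}
    home: dict[str, int] = {}
    for c in range(config.n_communities):
        for i in range(config.terms_per_community):
            stem = f"c{c}w{i}"
            toks = [stem + "a", stem + "b"] + ([stem + "c"] if i % 3 == 0 else [])
            term = " ".join(toks)
            vocab[c].append(term)
            home[term] = c
    for j in range(config.n_shared_terms):
        term = f"sh{j}a sh{j}b"
        c1 = j % config.n_communities
        c2 = (j + 1) % config.n_communities
        vocab[c1].append(term)
        vocab[c2].append(term)
        home[term] = c1
    return vocab, home


def generate_corpus(config: CorpusConfig) -> tuple[list[BibRecord], CorpusTruth]:
    """Generate bibliographic records plus ground-truth maps.

    Each abstract is a space-joined bag of multiword terms interleaved with
    filler words from a disjoint vocabulary (so fillers can never be
    detected as terms). Terms are drawn with replacement from the article's
    community vocabulary with Zipf(rank^-zipf_exponent) weights; with
    probability ``cross_community_mixing`` one term is drawn from a foreign
    community instead. Measure marker words are planted at the configured
    per-community rates and recorded in the truth.
    """
    rng = np.random.default_rng(config.seed)
    vocab, home = _make_vocab(config)
    fillers = [f"x{j}" for j in range(_N_FILLER)]

    weights = {}
    for c, terms in vocab.items():
        w = (np.arange(len(terms)) + 1.0) ** (-config.zipf_exponent)
        weights[c] = w / w.sum()

    records: list[BibRecord] = []
    art_comm: dict[str, set[int]] = {}
    art_meas: dict[str, set[str]] = {}
    n = 0
    for c in range(config.n_communities):
        rates = config.measure_dictionary_rates.get(c, {})
        for _a in range(config.n_articles_per_community):
            n += 1
            rid = f"{10_000_000 + n}"
            k = max(1, rng.poisson(config.terms_per_abstract_mean))
            terms = list(rng.choice(vocab[c], size=k, p=weights[c]))
            if (
                config.n_communities > 1
                and rng.random() < config.cross_community_mixing
            ):
                other = int(rng.integers(0, config.n_communities - 1))
                if other >= c:
                    other += 1
                terms[-1] = str(rng.choice(vocab[other], p=weights[other]))
            markers = {cat for cat, pr in rates.items() if rng.random() < pr}

            chunks: list[str] = []
            for t in terms:
                chunks.append(" ".join(rng.choice(fillers, size=int(rng.integers(1, 4)))))
                chunks.append(t)
            chunks.append(" ".join(rng.choice(fillers, size=2)))
            for cat in sorted(markers):
                # chunk boundaries keep term token sequences contiguous
                chunks.insert(int(rng.integers(0, len(chunks) + 1)), MEASURE_MARKERS[cat])
            abstract = " ".join(chunks)

            records.append(
                BibRecord(
                    record_id=rid,
                    title=f"Synthetic study {rid}",
                    abstract=abstract,
                    language="en",
                    doc_type="Article",
                    year=int(2000 + rng.integers(0, 24)),
                    source="synthetic",
                )
            )
            art_comm[rid] = {home[t] for t in terms}
            art_meas[rid] = markers

    return records, CorpusTruth(home, art_comm, art_meas, vocab)


# ---------------------------------------------------------------------------
# coordinate studies


@dataclass(frozen=True)
class CoordConfig:
    """Stated world of a synthetic coordinate dataset.

    Each focus is the study's community locus, or the shared locus (with
    probability ``p_focus_at_shared``), plus isotropic Gaussian jitter of
    ``focus_sd`` mm — or, with probability ``p_noise_focus``, a uniform
    draw over in-mask voxel centers. ``community_locus=None`` auto-places
    the loci evenly on a circle at half the mask's extent.
    """

    n_studies_per_community: int = 20
    foci_per_study_range: tuple[int, int] = (3, 8)
    community_locus: dict[int, tuple[float, float, float]] | None = None
    shared_locus: tuple[float, float, float] = (0.0, 0.0, 0.0)
    focus_sd: float = 5.0
    p_focus_at_shared: float = 0.3
    p_noise_focus: float = 0.1
    mask_spec: GridSpec = GridSpec()
    seed: int = 0

    def __post_init__(self):
        if self.n_studies_per_community < 1:
            raise ConfigError("n_studies_per_community: must be >= 1")
        lo, hi = self.foci_per_study_range
        if lo < 1 or hi < lo:
            raise ConfigError("foci_per_study_range: need 1 <= lo <= hi")
        if self.focus_sd <= 0:
            raise ConfigError("focus_sd: must be > 0")
        for name in ("p_focus_at_shared", "p_noise_focus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")

    def grid(self) -> BrainGrid:
        return self.mask_spec.make()

    def loci_for(self, communities: list[int], grid: BrainGrid) -> dict[int, np.ndarray]:
        if self.community_locus is not None:
            loci = {c: np.asarray(self.community_locus[c], dtype=float) for c in communities}
        else:
            ext = grid.mask_coords_mm.max(axis=0)  # mm half-extents
            radius = 0.5 * min(ext[0], ext[1])
            loci = {}
            for i, c in enumerate(sorted(communities)):
                ang = 2.0 * np.pi * i / max(len(communities), 1)
                loci[c] = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        for c, locus in loci.items():
            if not grid.contains_mm(locus[None, :])[0]:
                raise ConfigError(f"community_locus: locus for community {c} outside mask")
        if not grid.contains_mm(np.asarray(self.shared_locus, float)[None, :])[0]:
            raise ConfigError("shared_locus: outside mask")
        return loci


def _project_inside(grid: BrainGrid, foci: np.ndarray) -> np.ndarray:
    inside = grid.contains_mm(foci)
    if not inside.all():
        foci = foci.copy()
        foci[~inside] = grid.nearest_in_mask(foci[~inside])
    return foci


def generate_coordinate_studies(
    config: CoordConfig, communities: list[int]
) -> list[CoordinateStudy]:
    """Generate per-community coordinate studies around planted loci."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    loci = config.loci_for(list(communities), grid)
    mask_mm = grid.mask_coords_mm
    lo, hi = config.foci_per_study_range
    studies: list[CoordinateStudy] = []
    for c in sorted(communities):
        for s in range(config.n_studies_per_community):
            nf = int(rng.integers(lo, hi + 1))
            foci = np.empty((nf, 3))
            for i in range(nf):
                if rng.random() < config.p_noise_focus:
                    foci[i] = mask_mm[rng.integers(0, len(mask_mm))]
                else:
                    base = (
                        np.asarray(config.shared_locus, float)
                        if rng.random() < config.p_focus_at_shared
                        else loci[c]
                    )
                    foci[i] = base + rng.normal(0.0, config.focus_sd, size=3)
            foci = _project_inside(grid, foci)
            studies.append(
                CoordinateStudy(
                    study_id=f"c{c}-s{s:03d}",
                    foci=foci,
                    space="MNI",
                    sample_size=int(rng.integers(15, 41)),
                    tags=frozenset({f"community:{c}"}),
                )
            )
    return studies


def generate_reference_db(config: CoordConfig, n_studies: int) -> list[CoordinateStudy]:
    """Reference pool of non-matching studies: uniform in-mask foci only.

    Emulates a database of studies that do not mention the query concept,
    used as the sampling pool for the specificity null.
    """
    if n_studies < 1:
        raise ConfigError("n_studies: must be >= 1")
    rng = np.random.default_rng(config.seed + 1_000_003)
    grid = config.grid()
    mask_mm = grid.mask_coords_mm
    lo, hi = config.foci_per_study_range
    studies = []
    for s in range(n_studies):
        nf = int(rng.integers(lo, hi + 1))
        foci = mask_mm[rng.integers(0, len(mask_mm), size=nf)]
        studies.append(
            CoordinateStudy(
                study_id=f"ref-{s:04d}",
                foci=foci,
                space="MNI",
                sample_size=int(rng.integers(15, 41)),
                tags=frozenset({"reference", "non-matching"}),
            )
        )
    return studies
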