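"""End-to-end orchestration: corpus -> terms -> semantic graph -> communities
-> article assignment -> per-community ALE -> overlap -> robustness -> ROIs
-> specificity.

A single :class:`PipelineConfig` (one JSON document) drives the run; every
artifact is written under the output directory together with the config
hash, and a manifest lists all outputs with their SHA-256, so a rerun with
the same master seed is byte-identical and any stage can be replayed from
its serialized inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io
from .ale import ALEParams, ALEResult, CoordinateStudy, run_ale
from .assignment import assign_articles, AssignmentTable
from .convergence import (
    overlap_map,
    robustness_conjunction,
    rois_from_robustness,
)
from .corpus import extract_terms, filter_records, load_records, load_exclusion_dict
from .grid import ConfigError, GridSpec
from .semantic_graph import (
    build_cooccurrence,
    cosine_knn,
    embed_graph,
    kmeans_cluster,
    select_k_elbow,
)
from .specificity import specificity_test
from .synthetic import (
    CoordConfig,
    CorpusConfig,
    generate_coordinate_studies,
    generate_corpus,
    generate_reference_db,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_and_run", "demo_config"]

#: granularity levels (numbers of top terms) used for the robustness
#: conjunction on a full-scale corpus
DEFAULT_GRANULARITIES = (1200, 1500, 2000, 2285)


def derive_seed(master: int, *parts) -> int:
    """Deterministic per-stage seed from the master seed (< 2^31)."""
    key = "litmap:" + ":".join(str(p) for p in (master, *parts))
    h = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one full analysis run.

    When ``simulate`` is true the corpus and coordinate studies come from
    the synthetic generators; otherwise ``corpus_path`` (JSONL) and
    ``studies_path``/``reference_path`` (TSV) are read.
    """

    simulate: bool = True
    corpus_path: str | None = None
    corpus_format: str = "jsonl"
    studies_path: str | None = None
    reference_path: str | None = None
    exclusion_dict_paths: dict[str, str] = field(default_factory=dict)

    corpus_cfg: CorpusConfig = field(default_factory=CorpusConfig)
    coord_cfg: CoordConfig = field(default_factory=CoordConfig)
    n_reference_studies: int = 150

    language: str = "en"
    doc_types: tuple[str, ...] = ("Article",)
    granularities: tuple[int, ...] = DEFAULT_GRANULARITIES
    knn_k: int = 15
    embed_dim: int = 700
    embed_params: dict = field(
        default_factory=lambda: dict(
            p=1.0, q=1.0, walks_per_node=20, walk_length=30, window=10, epochs=5
        )
    )
    k_clusters: int | None = None  # None: choose by elbow
    k_range: tuple[int, ...] = tuple(range(2, 16))
    n_restarts: int = 10

    ale: ALEParams = field(default_factory=ALEParams)
    min_studies_per_ale: int = 7
    overlap_threshold: int = 4
    specificity_n_iter: int = 1000
    specificity_bin_width: float | None = None  # None: ale.bin_width

    master_seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=io._default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale synthetic configuration exercising every stage.

    Seven planted communities, two granularity levels, a small ellipsoid
    mask; chosen to finish in minutes on one CPU while leaving every
    statistical mechanism intact.
    """
    corpus_cfg = CorpusConfig(
        n_communities=7,
        terms_per_community=30,
        n_articles_per_community=100,
        cross_community_mixing=0.02,
        measure_dictionary_rates={
            0: {"pupil": 0.6, "heart": 0.2},
            1: {"heart": 0.6, "EDA": 0.4},
            2: {"heart": 0.5, "blood": 0.3},
            3: {"EDA": 0.5, "heart": 0.3},
            4: {"blood": 0.2},
            5: {"respiration": 0.6},
            6: {"respiration": 0.5},
        },
        seed=derive_seed(seed, "corpus-cfg"),
    )
    coord_cfg = CoordConfig(
        n_studies_per_community=10,
        foci_per_study_range=(3, 7),
        focus_sd=5.0,
        p_focus_at_shared=0.35,
        p_noise_focus=0.1,
        mask_spec=GridSpec(resolution_mm=6.0, semi_axes_mm=(40.0, 48.0, 40.0)),
        seed=derive_seed(seed, "coord-cfg"),
    )
    return PipelineConfig(
        corpus_cfg=corpus_cfg,
        coord_cfg=coord_cfg,
        n_reference_studies=140,
        granularities=(150, 210),
        embed_dim=64,
        embed_params=dict(p=1.0, q=1.0, walks_per_node=10, walk_length=40, window=5, epochs=3),
        k_clusters=None,
        k_range=tuple(range(2, 13)),
        ale=ALEParams(bin_width=1e-4, n_perm=200, min_studies=5),
        min_studies_per_ale=5,
        overlap_threshold=4,
        specificity_n_iter=199,
        specificity_bin_width=1e-3,
        master_seed=seed,
    )


# ---------------------------------------------------------------------------


def _link_studies_to_records(studies, truth) -> list[CoordinateStudy]:
    """Give synthetic coordinate studies the record_ids of corpus articles
    of the same planted community, so assignment drives the ALE grouping
    exactly as it would for a real coordinate database."""
    by_comm: dict[int, list[str]] = {}
    for rid, comms in truth.article_communities.items():
        for c in comms:
            by_comm.setdefault(c, []).append(rid)
    for c in by_comm:
        by_comm[c].sort()
    used: set[str] = set()
    out = []
    cursor: dict[int, int] = {}
    for s in studies:
        comm = next(
            (int(t.split(":", 1)[1]) for t in sorted(s.tags) if t.startswith("community:")),
            None,
        )
        pool = by_comm.get(comm, [])
        i = cursor.get(comm, 0)
        while i < len(pool) and pool[i] in used:
            i += 1
        if i < len(pool):
            rid = pool[i]
            cursor[comm] = i + 1
            used.add(rid)
        else:  # more studies than articles: keep the synthetic id
            rid = s.study_id
        out.append(replace(s, study_id=rid))
    return out


@dataclass
class PipelineState:
    """In-memory results of a run (the manifest's living counterpart)."""

    records: list = None
    truth: object = None
    studies: list = None
    reference: list = None
    term_list: object = None
    solutions: dict = None  # granularity -> ClusterSolution
    elbow: dict = None  # granularity -> ElbowResult
    assignments: dict = None  # granularity -> AssignmentTable
    ale_results: dict = None  # (granularity, community) -> ALEResult
    overlaps: dict = None  # granularity -> OverlapMap
    robustness: object = None
    rois: list = None
    specificity: list = None


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, state: PipelineState | None = None
) -> dict:
    """Execute all stages in order and return the manifest.

    On stage failure the manifest (with the failing stage and the error) is
    still written before the exception propagates. Pass a
    :class:`PipelineState` to also receive in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = state if state is not None else PipelineState()
    chash = config.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "master_seed": config.master_seed,
        "stages": {},
        "status": "running",
    }

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "files": {f.name: io.sha256_file(f) for f in files},
            "seconds": round(time.time() - t0, 3),
        }

    try:
        _run_stages(config, out, st, manifest, record)
        manifest["status"] = "complete"
    except Exception as e:  # noqa: BLE001 - manifest must record the failure
        manifest["status"] = "failed"
        manifest["failed_stage"] = manifest.get("current_stage", "unknown")
        manifest["error"] = f"{type(e).__name__}: {e}"
        io.write_json(manifest, out / "manifest.json")
        raise
    manifest.pop("current_stage", None)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_stages(config, out, st, manifest, record):
    seed = config.master_seed

    # -- corpus ------------------------------------------------------------
    manifest["current_stage"] = "corpus"
    t0 = time.time()
    if config.simulate:
        st.records, st.truth = generate_corpus(config.corpus_cfg)
    else:
        st.records, _rejects = load_records(config.corpus_path, config.corpus_format)
        st.truth = None
    st.records = filter_records(
        st.records, language=config.language, doc_types=tuple(config.doc_types)
    )
    io.write_records_jsonl(st.records, out / "corpus.jsonl")
    files = [out / "corpus.jsonl"]
    if st.truth is not None:
        io.write_json(
            {
                "term_community": st.truth.term_community,
                "article_communities": {
                    k: sorted(v) for k, v in st.truth.article_communities.items()
                },
                "article_measures": {
                    k: sorted(v) for k, v in st.truth.article_measures.items()
                },
            },
            out / "truth.json",
        )
        files.append(out / "truth.json")
    record("corpus", files, t0)

    # -- coordinate studies --------------------------------------------------
    manifest["current_stage"] = "studies"
    t0 = time.time()
    if config.simulate:
        raw = generate_coordinate_studies(
            config.coord_cfg, list(range(config.corpus_cfg.n_communities))
        )
        st.studies = _link_studies_to_records(raw, st.truth)
        st.reference = generate_reference_db(config.coord_cfg, config.n_reference_studies)
    else:
        st.studies = io.read_studies_tsv(config.studies_path)
        st.reference = (
            io.read_studies_tsv(config.reference_path) if config.reference_path else []
        )
    io.write_studies_tsv(st.studies, out / "studies.tsv")
    io.write_studies_tsv(st.reference, out / "reference.tsv")
    record("studies", [out / "studies.tsv", out / "reference.tsv"], t0)

    # -- term extraction -----------------------------------------------------
    manifest["current_stage"] = "terms"
    t0 = time.time()
    exclusions = {
        name: load_exclusion_dict(p) for name, p in config.exclusion_dict_paths.items()
    }
    max_terms = max(config.granularities)
    st.term_list = extract_terms(st.records, max_terms, exclusions or None)
    io.write_termlist_tsv(st.term_list, out / "terms.tsv")
    record("terms", [out / "terms.tsv"], t0)

    # -- semantic graph + clustering per granularity --------------------------
    manifest["current_stage"] = "semantic_graph"
    t0 = time.time()
    st.solutions, st.elbow = {}, {}
    files = []
    grans = [g for g in config.granularities if g <= len(st.term_list)] or [
        len(st.term_list)
    ]
    for g in grans:
        tl = st.term_list.head(g)
        co = build_cooccurrence(st.records, tl)
        graph = cosine_knn(co, k=config.knn_k)
        emb = embed_graph(
            graph,
            d=config.embed_dim,
            seed=derive_seed(seed, "embed", g),
            **config.embed_params,
        )
        if config.k_clusters is None:
            res = select_k_elbow(
                emb,
                list(config.k_range),
                n_restarts=config.n_restarts,
                seed=derive_seed(seed, "elbow", g),
            )
            st.elbow[g] = res
            k = res.k
            if k is None:
                raise ConfigError(
                    f"k_clusters: no knee found at granularity {g}; set k explicitly"
                )
        else:
            k = config.k_clusters
        sol = kmeans_cluster(
            emb, k, n_restarts=config.n_restarts, seed=derive_seed(seed, "kmeans", g)
        )
        sol.selection_trace = st.elbow[g].trace if g in st.elbow else []
        st.solutions[g] = sol
        io.write_edges_tsv(graph, out / f"edges_g{g}.tsv")
        io.write_json(
            {
                "k": sol.k,
                "labels": sol.labels,
                "inertia": sol.inertia,
                "silhouette_mean": sol.silhouette_mean,
                "selection_trace": sol.selection_trace,
                "config_hash": manifest["config_hash"],
                "seed": derive_seed(seed, "kmeans", g),
            },
            out / f"clusters_g{g}.json",
        )
        files += [out / f"edges_g{g}.tsv", out / f"clusters_g{g}.json"]
    record("semantic_graph", files, t0)

    # -- article assignment ----------------------------------------------------
    manifest["current_stage"] = "assignment"
    t0 = time.time()
    st.assignments = {}
    files = []
    for g, sol in st.solutions.items():
        tl = st.term_list.head(g)
        table = assign_articles(st.records, sol.labels, tl)
        st.assignments[g] = table
        path = out / f"assignments_g{g}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("record_id\tcommunities\n")
            for rid in sorted(table.assignments):
                fh.write(f"{rid}\t{','.join(map(str, sorted(table.assignments[rid])))}\n")
        files.append(path)
    record("assignment", files, t0)

    # -- per-community ALE -----------------------------------------------------
    manifest["current_stage"] = "ale"
    t0 = time.time()
    grid = config.coord_cfg.grid() if config.simulate else None
    if grid is None:
        raise ConfigError("coord_cfg: a mask/grid spec is required for the ALE stage")
    st.ale_results = {}
    files = []
    for g, table in st.assignments.items():
        groups: dict[int, list[CoordinateStudy]] = {}
        for s in st.studies:
            for c in table.assignments.get(s.study_id, frozenset()):
                groups.setdefault(c, []).append(s)
        for c, studies in sorted(groups.items()):
            if len(studies) < config.min_studies_per_ale:
                logger.info(
                    "granularity %d community %d: %d studies < %d, skipped",
                    g, c, len(studies), config.min_studies_per_ale,
                )
                continue
            params = replace(config.ale, seed=derive_seed(seed, "ale", g, c))
            res = run_ale(studies, grid, params)
            st.ale_results[(g, c)] = res
            path = out / f"ale_g{g}_c{c}_clusters.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("cluster_id\textent\tmass\tpeak_x\tpeak_y\tpeak_z\tp_fwe\tsignificant\n")
                for cl in res.clusters:
                    fh.write(
                        f"{cl.cluster_id}\t{cl.extent}\t{cl.mass:.6g}\t"
                        f"{cl.peak_mm[0]:.1f}\t{cl.peak_mm[1]:.1f}\t{cl.peak_mm[2]:.1f}\t"
                        f"{cl.p_fwe:.6g}\t{int(cl.significant)}\n"
                    )
            files.append(path)
    record("ale", files, t0)

    # -- overlap + robustness ---------------------------------------------------
    manifest["current_stage"] = "convergence"
    t0 = time.time()
    st.overlaps = {}
    files = []
    from .ale import VoxelMap

    for g in st.assignments:
        masks = {
            c: VoxelMap(grid, res.sig_mask.astype(float), "mask")
            for (gg, c), res in st.ale_results.items()
            if gg == g
        }
        if not masks:
            continue
        st.overlaps[g] = overlap_map(masks)
        om = VoxelMap(grid, st.overlaps[g].counts.astype(float), "overlap")
        io.write_voxelmap_nifti(om, out / f"overlap_g{g}.nii")
        files.append(out / f"overlap_g{g}.nii")
    if len(st.overlaps) >= 2:
        st.robustness = robustness_conjunction(st.overlaps, config.overlap_threshold)
        rb = VoxelMap(grid, st.robustness.mask.astype(float), "mask")
        io.write_voxelmap_nifti(rb, out / "robustness.nii")
        files.append(out / "robustness.nii")
        st.rois = rois_from_robustness(st.robustness)
    else:
        st.robustness, st.rois = None, []
    path = out / "rois.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("roi_id\tn_voxels\tcom_x\tcom_y\tcom_z\n")
        for r in st.rois:
            fh.write(
                f"{r.roi_id}\t{r.size}\t{r.com_mm[0]:.1f}\t{r.com_mm[1]:.1f}\t{r.com_mm[2]:.1f}\n"
            )
    files.append(path)
    record("convergence", files, t0)

    # -- specificity --------------------------------------------------------------
    manifest["current_stage"] = "specificity"
    t0 = time.time()
    st.specificity = []
    files = []
    spec_params = replace(
        config.ale,
        bin_width=config.specificity_bin_width or config.ale.bin_width,
    )
    for roi in st.rois or []:
        if len(st.reference) < len(st.studies):
            logger.warning("reference pool smaller than matched set; specificity skipped")
            break
        res = specificity_test(
            st.studies,
            st.reference,
            roi,
            grid,
            ale_params=spec_params,
            n_iter=config.specificity_n_iter,
            seed=derive_seed(seed, "specificity", roi.roi_id),
        )
        st.specificity.append(res)
        path = out / f"specificity_roi{roi.roi_id}.json"
        io.write_json(
            {
                "roi_id": res.roi_id,
                "observed_mass": res.observed_mass,
                "p_mc": res.p_mc,
                "n_iter": res.n_iter,
                "seed": res.seed,
                "config_hash": manifest["config_hash"],
            },
            path,
        )
        null_path = out / f"specificity_roi{roi.roi_id}_null.tsv"
        np.savetxt(null_path, res.null_masses, fmt="%.8g", header="null_mass", comments="")
        files += [path, null_path]
    record("specificity", files, t0)


# ---------------------------------------------------------------------------


def simulate_and_run(
    corpus_cfg: CorpusConfig,
    coord_cfg: CoordConfig,
    pipeline_cfg: PipelineConfig | None = None,
    out_dir: str | Path = "litmap_run",
) -> tuple[dict, dict]:
    """Generate synthetic data, run the full pipeline, score recovery.

    Returns ``(manifest, report)`` where the report compares the run
    against generator truth: adjusted Rand index of term communities,
    selected k vs planted k, whether the planted shared locus is hit by
    the overlap argmax and retained by the robustness conjunction, and the
    specificity Monte-Carlo p for the ROI nearest the shared locus.
    """
    from sklearn.metrics import adjusted_rand_score

    cfg = pipeline_cfg or demo_config()
    cfg = replace(cfg, simulate=True, corpus_cfg=corpus_cfg, coord_cfg=coord_cfg)
    st = PipelineState()
    manifest = run_pipeline(cfg, out_dir, state=st)

    g_max = max(st.solutions)
    sol = st.solutions[g_max]
    known = [t for t in sol.labels if t in st.truth.term_community]
    ari = (
        float(
            adjusted_rand_score(
                [st.truth.term_community[t] for t in known],
                [sol.labels[t] for t in known],
            )
        )
        if known
        else float("nan")
    )

    grid = cfg.coord_cfg.grid()
    shared_vox = tuple(grid.mm_to_voxel(np.asarray(coord_cfg.shared_locus, float))[0])
    shared_hit = False
    for om in st.overlaps.values():
        peak = om.counts.max()
        argmax = np.argwhere(om.counts == peak)
        if any(tuple(v) == shared_vox for v in argmax):
            shared_hit = True
    robust_retains = bool(st.robustness is not None and st.robustness.mask[shared_vox])

    spec_p = None
    if st.specificity:
        # ROI nearest the planted shared locus
        def dist(res):
            roi = next(r for r in st.rois if r.roi_id == res.roi_id)
            return float(np.linalg.norm(roi.com_mm - np.asarray(coord_cfg.shared_locus)))

        spec_p = min(st.specificity, key=dist).p_mc

    report = {
        "term_ari": ari,
        "planted_k": corpus_cfg.n_communities,
        "selected_k": {g: r.k for g, r in st.elbow.items()},
        "shared_locus_hit": bool(shared_hit),
        "robustness_retains_shared_locus": robust_retains,
        "specificity_p": spec_p,
        "n_ale_runs": len(st.ale_results),
    }
    io.write_json(report, Path(out_dir) / "report.json")
    return manifest, report
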