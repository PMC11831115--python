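"""Serialization of pipeline artifacts.

Plain-text interchange formats throughout: JSONL for bibliographic
records, long-format TSV (one row per focus, Sleuth/NeuroQuery style) for
coordinate studies, TSV for term lists and edge tables, NIfTI-1 for voxel
maps, JSON for configs, truth maps and manifests. All writers are
deterministic: stable key order, no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ale import CoordinateStudy, VoxelMap
from .corpus import BibRecord, TermList
from .grid import BrainGrid, ConfigError


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# -- bibliographic records ---------------------------------------------------


def write_records_jsonl(records: list[BibRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(dataclasses.asdict(r), sort_keys=True) + "\n")


# -- term lists --------------------------------------------------------------


def write_termlist_tsv(term_list: TermList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tfrequency\n")
        for t, f in term_list.terms:
            fh.write(f"{t}\t{f}\n")


def read_termlist_tsv(path: str | Path) -> TermList:
    df = pd.read_csv(path, sep="\t")
    return TermList([(str(t), int(f)) for t, f in zip(df["term"], df["frequency"])])


# -- coordinate studies ------------------------------------------------------

_STUDY_COLS = ["study_id", "space", "x", "y", "z", "n", "roi_table_flag", "tags"]


def write_studies_tsv(studies: list[CoordinateStudy], path: str | Path) -> None:
    """One row per focus; study-level fields repeated on each row."""
    rows = []
    for s in studies:
        for x, y, z in s.foci:
            rows.append(
                dict(
                    study_id=s.study_id,
                    space=s.space,
                    x=x,
                    y=y,
                    z=z,
                    n="" if s.sample_size is None else s.sample_size,
                    roi_table_flag=int(s.roi_table_flag),
                    tags=",".join(sorted(s.tags)),
                )
            )
    pd.DataFrame(rows, columns=_STUDY_COLS).to_csv(path, sep="\t", index=False)


def read_studies_tsv(path: str | Path) -> list[CoordinateStudy]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "tags": str})
    if list(df.columns) != _STUDY_COLS:
        raise ConfigError(f"studies file {path}: expected columns {_STUDY_COLS}")
    studies = []
    for sid, g in df.groupby("study_id", sort=False):
        first = g.iloc[0]
        n = first["n"]
        tags = first["tags"]
        studies.append(
            CoordinateStudy(
                study_id=str(sid),
                foci=g[["x", "y", "z"]].to_numpy(dtype=float),
                space=str(first["space"]),
                sample_size=None if pd.isna(n) or n == "" else int(n),
                roi_table_flag=bool(first["roi_table_flag"]),
                tags=frozenset() if pd.isna(tags) or not tags else frozenset(str(tags).split(",")),
            )
        )
    return studies


# -- voxel maps --------------------------------------------------------------


def write_voxelmap_nifti(vmap: VoxelMap, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vmap.values, dtype=np.float64), vmap.grid.affine)
    img.header["descrip"] = vmap.kind.encode()
    # fixed timestamps are irrelevant for NIfTI; content is deterministic
    nib.save(img, str(path))


def read_voxelmap_nifti(path: str | Path, kind: str | None = None) -> VoxelMap:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.get_fdata())
    mask = np.isfinite(values)
    if kind is None:
        kind = img.header["descrip"].tobytes().decode().strip("\x00") or "mask"
    grid = BrainGrid(values.shape, np.asarray(img.affine), mask)
    return VoxelMap(grid, values, kind)


# -- graphs and embeddings ---------------------------------------------------


def write_edges_tsv(graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_i\tterm_j\tweight\n")
        for (i, j), w in sorted(graph.edges.items()):
            fh.write(f"{graph.terms[i]}\t{graph.terms[j]}\t{w:.10g}\n")


def write_embedding_tsv(embedding, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\t" + "\t".join(f"d{i}" for i in range(embedding.vectors.shape[1])) + "\n")
        for t, v in zip(embedding.terms, embedding.vectors):
            fh.write(t + "\t" + "\t".join(f"{x:.8g}" for x in v) + "\n")
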