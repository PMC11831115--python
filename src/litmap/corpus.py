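"""Bibliographic records: loading, filtering, multiword-term extraction.

Terms are contiguous lowercase 2- and 3-token n-grams ranked by document
frequency (number of records whose abstract contains the term), after
removal of exclusion dictionaries (general-language terms, brain-region
names). The deep-learning part-of-speech tagger used in some literature
pipelines is replaced by this deterministic frequency contract; a custom
extractor can be plugged in wherever a ``TermList`` is accepted, since the
downstream pipeline only consumes the ranked list.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .grid import ConfigError

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")

REQUIRED_FIELDS = ("record_id", "title", "abstract", "language", "doc_type", "year")


@dataclass(frozen=True)
class BibRecord:
    """One article's identifiers and text fields (PubMed-style)."""

    record_id: str
    title: str
    abstract: str
    language: str = "en"
    doc_type: str = "Article"
    year: int | None = None
    source: str = ""


@dataclass(frozen=True)
class Reject:
    line: int
    reason: str


@dataclass
class TermList:
    """Ranked multiword terms with their corpus frequencies.

    ``terms`` is ordered by non-increasing frequency (ties broken
    lexicographically); every term is a lowercase string of 2 or 3 tokens
    absent from all applied exclusion dictionaries.
    """

    terms: list[tuple[str, int]]
    exclusions_applied: list[str] = field(default_factory=list)
    count_mode: str = "document"

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_strings(self) -> list[str]:
        return [t for t, _ in self.terms]

    def frequency(self, term: str) -> int:
        return dict(self.terms)[term]

    def head(self, n: int) -> "TermList":
        """The ``n`` highest-ranked terms (a granularity level)."""
        return TermList(self.terms[:n], list(self.exclusions_applied), self.count_mode)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters; no stemming."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


# ---------------------------------------------------------------------------
# loading and filtering


def _record_from_mapping(row: dict, line: int, source: str) -> BibRecord | Reject:
    rid = str(row.get("record_id") or row.get("id") or "").strip()
    if not rid:
        return Reject(line, "missing record_id")
    abstract = str(row.get("abstract") or "").strip()
    if not abstract:
        return Reject(line, "missing abstract")
    year = row.get("year")
    try:
        year = int(year) if year not in (None, "") else None
    except (TypeError, ValueError):
        return Reject(line, f"bad year {year!r}")
    return BibRecord(
        record_id=rid,
        title=str(row.get("title") or ""),
        abstract=abstract,
        language=str(row.get("language") or ""),
        doc_type=str(row.get("doc_type") or ""),
        year=year,
        source=source,
    )


def load_records(path: str | Path, format: str = "jsonl") -> tuple[list[BibRecord], list[Reject]]:
    """Read bibliographic records from JSONL or TSV.

    Returns ``(records, rejects)`` where each reject carries the 1-based
    line number and the reason the row was dropped.
    """
    path = Path(path)
    if format not in ("jsonl", "tsv"):
        raise ConfigError(f"format: unknown format {format!r}")
    records: list[BibRecord] = []
    rejects: list[Reject] = []
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as e:
                    rejects.append(Reject(i, f"invalid JSON: {e.msg}"))
                    continue
                out = _record_from_mapping(row, i, str(path))
                (records if isinstance(out, BibRecord) else rejects).append(out)
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            for i, row in enumerate(reader, start=2):  # header is line 1
                out = _record_from_mapping(row, i, str(path))
                (records if isinstance(out, BibRecord) else rejects).append(out)
    if rejects:
        for r in rejects:
            logger.warning("%s line %d rejected: %s", path, r.line, r.reason)
    return records, rejects


def filter_records(
    records: list[BibRecord],
    required_fields: tuple[str, ...] = REQUIRED_FIELDS,
    language: str | None = "en",
    doc_types: tuple[str, ...] | None = ("Article",),
) -> list[BibRecord]:
    """Select complete, language/doc-type matching, deduplicated records.

    Records missing any required field are removed, then language and
    document-type filters apply, then duplicates by ``record_id`` are
    removed keeping the first occurrence. Removal counts are logged.
    The operation is idempotent.
    """
    counts = {"missing_field": 0, "language": 0, "doc_type": 0, "duplicate": 0}
    seen: set[str] = set()
    out: list[BibRecord] = []
    for r in records:
        vals = {f: getattr(r, f) for f in required_fields}
        if any(v is None or (isinstance(v, str) and not v.strip()) for v in vals.values()):
            counts["missing_field"] += 1
            continue
        if language is not None and r.language != language:
            counts["language"] += 1
            continue
        if doc_types is not None and r.doc_type not in doc_types:
            counts["doc_type"] += 1
            continue
        if r.record_id in seen:
            counts["duplicate"] += 1
            continue
        seen.add(r.record_id)
        out.append(r)
    logger.info(
        "filter_records: kept %d of %d (%s)",
        len(out),
        len(records),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return out


# ---------------------------------------------------------------------------
# term extraction and detection


def load_exclusion_dict(path: str | Path) -> frozenset[str]:
    """One lowercase term per line, UTF-8; blank lines and '#' comments skipped."""
    terms = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                terms.add(" ".join(tokenize(line)))
    return frozenset(terms)


def _ngrams(tokens: list[str], n_tokens: tuple[int, ...]) -> list[str]:
    out = []
    for n in n_tokens:
        out.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return out


def extract_terms(
    records: list[BibRecord],
    max_terms: int,
    exclusion_dicts: dict[str, frozenset[str]] | None = None,
    n_tokens: tuple[int, ...] = (2, 3),
    count_mode: str = "document",
) -> TermList:
    """Rank the most frequent multiword terms of a corpus.

    Candidates are contiguous token 2-grams and 3-grams of the lowercased
    abstracts. ``count_mode="document"`` (default) counts the number of
    records containing the term at least once; ``"occurrence"`` counts
    every occurrence. Terms found in any exclusion dictionary are removed
    before ranking; ties are broken lexicographically.
    """
    if max_terms < 1:
        raise ConfigError("max_terms: must be >= 1")
    if not records:
        raise ConfigError("records: empty corpus")
    if count_mode not in ("document", "occurrence"):
        raise ConfigError(f"count_mode: unknown mode {count_mode!r}")
    excluded: set[str] = set()
    names: list[str] = []
    for name, terms in (exclusion_dicts or {}).items():
        excluded |= set(terms)
        names.append(name)

    freq: dict[str, int] = {}
    for r in records:
        grams = _ngrams(tokenize(r.abstract), n_tokens)
        if count_mode == "document":
            grams = set(grams)
        for g in grams:
            if g not in excluded:
                freq[g] = freq.get(g, 0) + 1

    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return TermList(ranked[:max_terms], names, count_mode)


def detect_terms(
    record: BibRecord, term_list: TermList, include_title: bool = False
) -> set[str]:
    """Terms of ``term_list`` whose token sequence occurs contiguously in
    the record's abstract (token-boundary aware, so no mid-word matches)."""
    if not len(term_list):
        raise ConfigError("term_list: empty")
    text = record.abstract + (" " + record.title if include_title else "")
    tokens = tokenize(text)
    lengths = sorted({len(t.split()) for t in term_list.term_strings})
    present = set(_ngrams(tokens, tuple(lengths)))
    return present & set(term_list.term_strings)
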