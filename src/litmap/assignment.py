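"""Project articles onto semantic communities; dictionary prevalence profiles.

An article belongs to community c iff at least one detected term carries
label c, so multi-assignment is the norm: an abstract mentioning both
"heart rate" (physiology) and "stress disorder" (stress disorders)
projects onto both fields. Prevalence profiles count, per community, the
percentage of member articles that mention any string of a measure
dictionary (case-insensitive substring match) — the "physiological
measure profile" of a research field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import BibRecord, TermList, detect_terms
from .grid import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentTable",
    "MeasureDictionary",
    "DEFAULT_MEASURE_DICTIONARY",
    "assign_articles",
    "dictionary_prevalence",
]

#: physiological arousal measures and their match strings; multiword
#: strings are preferred where possible to limit substring over-matching
DEFAULT_MEASURE_DICTIONARY = {
    "pupil": ["pupil diameter", "pupillometry", "pupillary response", "eye tracking"],
    "heart": ["heart rate", "cardiac activity", "electrocardiogra", "heart period"],
    "respiration": ["respiration rate", "respiratory rate", "breathing rate", "spirometr"],
    "blood": ["blood pressure", "systolic", "diastolic", "sphygmomanometr"],
    "EDA": ["skin conductance", "electrodermal", "galvanic skin"],
}


@dataclass
class MeasureDictionary:
    """Category -> list of lowercase match strings (all lists nonempty)."""

    categories: dict[str, list[str]]

    def __post_init__(self):
        for cat, strings in self.categories.items():
            if not strings:
                raise ConfigError(f"categories: empty match list for {cat!r}")
        self.categories = {
            cat: [s.lower() for s in strings] for cat, strings in self.categories.items()
        }

    @classmethod
    def default(cls) -> "MeasureDictionary":
        return cls({k: list(v) for k, v in DEFAULT_MEASURE_DICTIONARY.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "MeasureDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    def matches(self, text: str, category: str) -> bool:
        low = text.lower()
        return any(s in low for s in self.categories[category])


@dataclass
class AssignmentTable:
    """record_id -> set of community indices, at one granularity.

    A record with no detected terms maps to the empty set; sets of size
    greater than one are expected and meaningful.
    """

    assignments: dict[str, frozenset[int]]
    granularity: int

    def members(self, community: int) -> list[str]:
        return sorted(r for r, cs in self.assignments.items() if community in cs)

    def communities(self) -> set[int]:
        out: set[int] = set()
        for cs in self.assignments.values():
            out |= cs
        return out


def assign_articles(
    records: list[BibRecord],
    term_communities: dict[str, int],
    term_list: TermList,
    include_title: bool = False,
) -> AssignmentTable:
    """Assign each record to every community with >= 1 detected term.

    ``term_communities`` must label every term of ``term_list``. The result
    is deterministic and independent of record order.
    """
    missing = set(term_list.term_strings) - set(term_communities)
    if missing:
        raise ConfigError(
            f"term_communities: {len(missing)} term(s) unlabeled, e.g. {sorted(missing)[:3]}"
        )
    table = {}
    for rec in records:
        detected = detect_terms(rec, term_list, include_title=include_title)
        table[rec.record_id] = frozenset(term_communities[t] for t in detected)
    return AssignmentTable(table, granularity=len(term_list))


def dictionary_prevalence(
    records_by_community: dict[int, list[BibRecord]],
    dictionary: MeasureDictionary,
    scope: str = "title_abstract",
) -> dict[int, dict[str, float]]:
    """Percentage of each community's articles matching each category.

    Matching is case-insensitive substring search over the title plus
    abstract (``scope="abstract"`` restricts to the abstract, mirroring
    the ambiguity of what counts as the searched "item"). Empty
    communities are reported as missing, not as zero.
    """
    if scope not in ("title_abstract", "abstract"):
        raise ConfigError(f"scope: unknown scope {scope!r}")
    out: dict[int, dict[str, float]] = {}
    for c, recs in records_by_community.items():
        if not recs:
            logger.warning("community %s is empty; prevalence undefined", c)
            continue
        prof = {}
        for cat in dictionary.categories:
            n = sum(
                1
                for r in recs
                if dictionary.matches(
                    r.abstract if scope == "abstract" else r.title + " " + r.abstract,
                    cat,
                )
            )
            prof[cat] = 100.0 * n / len(recs)
        out[c] = prof
    return out
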