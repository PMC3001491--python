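"""IDF-weighted cosine associative search and MeSH tag suggestion.

Associative search ranks a personal library against one or more selected
papers by cosine similarity between sparse term vectors: each record's
unigram term frequencies over title+abstract, weighted by the background
IDF. Multiple seed papers are combined by summing their vectors (ranking is
invariant to the overall scale of the query vector, so sum and centroid are
equivalent).

Tag suggestion mirrors the key-term machinery at the MeSH level: a heading
over-represented in a set of papers relative to the background (by the
hypergeometric point probability) is proposed as a tag, its name normalized
from comma-inverted MeSH form ("Neoplasms, Experimental") to a readable
lowercase tag ("experimental neoplasms").
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter

from .background import BackgroundStats
from .corpus import BiblioRecord, Corpus
from .keyterms import hypergeom_point_prob

__all__ = [
    "TermVector",
    "TagSuggestion",
    "build_term_vector",
    "cosine",
    "associative_search",
    "suggest_tags",
    "normalize_mesh_tag",
    "DEFAULT_PROB_THRESHOLD",
    "DEFAULT_MAX_SUGGESTIONS",
]

DEFAULT_PROB_THRESHOLD = 0.01
DEFAULT_MAX_SUGGESTIONS = 10


@dataclasses.dataclass(frozen=True)
class TermVector:
    entries: dict[str, float]
    norm: float

    @classmethod
    def from_entries(cls, entries: dict[str, float]) -> "TermVector":
        entries = {t: w for t, w in entries.items() if w != 0.0}
        return cls(entries=entries, norm=math.sqrt(sum(w * w for w in entries.values())))

    def __add__(self, other: "TermVector") -> "TermVector":
        summed = dict(self.entries)
        for t, w in other.entries.items():
            summed[t] = summed.get(t, 0.0) + w
        return TermVector.from_entries(summed)


def build_term_vector(record: BiblioRecord, stats: BackgroundStats) -> TermVector:
    """tf x idf over title+abstract unigrams; tf is the raw count."""
    tf = Counter(record.title_tokens())
    tf.update(record.abstract_tokens())
    return TermVector.from_entries(
        {t: c * stats.idf_of(t) for t, c in tf.items()}
    )


def cosine(a: TermVector, b: TermVector) -> float:
    """Cosine similarity in [0, 1]; 0 whenever either vector is zero."""
    if a.norm == 0.0 or b.norm == 0.0:
        return 0.0
    small, large = (a, b) if len(a.entries) <= len(b.entries) else (b, a)
    dot = sum(w * large.entries.get(t, 0.0) for t, w in small.entries.items())
    return dot / (a.norm * b.norm)


def associative_search(
    seed_ids: list[str],
    library: Corpus,
    stats: BackgroundStats,
    top_m: int | None = None,
) -> list[tuple[str, float]]:
    """Rank non-seed library records by cosine to the summed seed vector.

    Returns (record_id, similarity) pairs sorted by descending similarity,
    ties broken by ascending record ID; at most ``top_m`` pairs when given.
    """
    if not seed_ids:
        raise ValueError("seed set is empty")
    for sid in seed_ids:
        if sid not in library:
            raise KeyError(f"unknown seed record_id {sid!r}")
    query = TermVector.from_entries({})
    for sid in dict.fromkeys(seed_ids):
        query = query + build_term_vector(library[sid], stats)
    seed_set = set(seed_ids)
    ranked = [
        (rec.record_id, cosine(query, build_term_vector(rec, stats)))
        for rec in library
        if rec.record_id not in seed_set
    ]
    ranked.sort(key=lambda pair: (-pair[1], pair[0]))
    return ranked if top_m is None else ranked[:top_m]


def normalize_mesh_tag(mesh_term: str) -> str:
    """Readable tag name from a MeSH heading.

    Comma-inverted headings are un-inverted (segments split on commas,
    reversed, space-joined) and the result lowercased; idempotent.
    """
    segments = [s.strip() for s in mesh_term.split(",")]
    return " ".join(reversed([s for s in segments if s])).lower()


@dataclasses.dataclass(frozen=True)
class TagSuggestion:
    mesh_term: str
    tag_name: str
    set_count: int
    bg_count: int
    probability: float


def suggest_tags(
    set_ids: list[str],
    library: Corpus,
    stats: BackgroundStats,
    max_suggestions: int = DEFAULT_MAX_SUGGESTIONS,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> list[TagSuggestion]:
    """Suggest tags for a set of papers from over-represented MeSH headings.

    A heading qualifies when its document frequency in the set exceeds the
    background expectation |set| * bg_count / corpus_size and its
    hypergeometric point probability is at or below ``prob_threshold``;
    suggestions are sorted by ascending probability (ties lexicographic on
    the heading) and truncated to ``max_suggestions``.
    """
    if max_suggestions < 1 or prob_threshold <= 0:
        raise ValueError("max_suggestions and prob_threshold must be positive")
    if not set_ids:
        raise ValueError("paper set is empty")
    records = []
    for sid in dict.fromkeys(set_ids):
        if sid not in library:
            raise KeyError(f"unknown record_id {sid!r}")
        records.append(library[sid])

    set_size = len(records)
    bg_size = stats.corpus_size
    set_count: Counter[str] = Counter()
    for rec in records:
        set_count.update(rec.mesh_terms)

    out: list[TagSuggestion] = []
    for mesh, x in set_count.items():
        bg = stats.mesh_doc_count.get(mesh, x)
        if x <= set_size * bg / bg_size:
            continue
        prob = hypergeom_point_prob(x, set_size, bg, bg_size)
        if prob <= prob_threshold:
            out.append(
                TagSuggestion(
                    mesh_term=mesh,
                    tag_name=normalize_mesh_tag(mesh),
                    set_count=x,
                    bg_count=bg,
                    probability=prob,
                )
            )
    out.sort(key=lambda s: (s.probability, s.mesh_term))
    return out[:max_suggestions]
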