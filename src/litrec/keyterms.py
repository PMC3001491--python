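"""Hypergeometric key-term extraction from a seed library.

Given a set of seed records (a user's papers of interest), every N-gram that
occurs in at least one seed record is a candidate key term. Under the urn
model, drawing |seed| records from a corpus of size M in which the term
occurs in K records, the number of seed records containing the term is
hypergeometric; a candidate is over-represented when its observed seed
document frequency x exceeds the expectation |seed| * K / M. Each
over-represented candidate is scored by the hypergeometric point probability
P[X = x], and the k lowest-probability candidates become the key terms, with
query weight -ln(probability).

Counting is at document level (records containing the term), matching the
draws-are-papers reading of the urn model; the upper-tail p-value
P[X >= x] is available as an option for users who want a conservative score.
"""

from __future__ import annotations

import dataclasses
import math

from scipy.stats import hypergeom

from .background import BackgroundStats, iter_ngrams, record_ngram_fields
from .corpus import Corpus

__all__ = [
    "KeyTerm",
    "SeedProfile",
    "hypergeom_point_prob",
    "hypergeom_tail_prob",
    "extract_key_terms",
    "DEFAULT_K_LIMIT",
]

DEFAULT_K_LIMIT = 75

# floor avoids -log(0) when scipy underflows the pmf for extreme parameters
_MIN_PROB = 1e-300


def _check_params(seed_hits: int, seed_size: int, bg_hits: int, bg_size: int) -> None:
    if not (0 <= seed_hits <= seed_size <= bg_size):
        raise ValueError(
            f"need 0 <= seed_hits <= seed_size <= bg_size, got "
            f"({seed_hits}, {seed_size}, {bg_hits}, {bg_size})"
        )
    if not (seed_hits <= bg_hits <= bg_size):
        raise ValueError(
            f"need seed_hits <= bg_hits <= bg_size, got "
            f"({seed_hits}, {seed_size}, {bg_hits}, {bg_size})"
        )


def hypergeom_point_prob(
    seed_hits: int, seed_size: int, bg_hits: int, bg_size: int
) -> float:
    """P[X = seed_hits], X ~ Hypergeometric(bg_size, bg_hits, seed_size).

    The probability that exactly ``seed_hits`` of the ``seed_size`` drawn
    records carry the term when ``bg_hits`` of the ``bg_size`` corpus records
    carry it.
    """
    _check_params(seed_hits, seed_size, bg_hits, bg_size)
    return float(hypergeom.pmf(seed_hits, bg_size, bg_hits, seed_size))


def hypergeom_tail_prob(
    seed_hits: int, seed_size: int, bg_hits: int, bg_size: int
) -> float:
    """Upper-tail P[X >= seed_hits] (conservative over-representation score)."""
    _check_params(seed_hits, seed_size, bg_hits, bg_size)
    return float(hypergeom.sf(seed_hits - 1, bg_size, bg_hits, seed_size))


@dataclasses.dataclass(frozen=True)
class KeyTerm:
    term: str
    seed_doc_count: int
    background_doc_count: int
    probability: float
    weight: float


@dataclasses.dataclass(frozen=True)
class SeedProfile:
    """Key terms plus the seed set's author and journal-scope context.

    key_terms are sorted by ascending probability (descending weight), ties
    broken lexicographically on the term string; at most k_limit entries.
    """

    key_terms: tuple[KeyTerm, ...]
    seed_authors: frozenset[str]
    seed_scopes: frozenset[str]
    k_limit: int

    def terms(self) -> tuple[str, ...]:
        return tuple(kt.term for kt in self.key_terms)

    def without_terms(self, stop_terms: set[str]) -> "SeedProfile":
        """Copy of the profile with the given term strings removed."""
        return dataclasses.replace(
            self,
            key_terms=tuple(
                kt for kt in self.key_terms if kt.term not in stop_terms
            ),
        )


def extract_key_terms(
    seed_ids: list[str],
    corpus: Corpus,
    stats: BackgroundStats,
    k_limit: int = DEFAULT_K_LIMIT,
    tail: bool = False,
) -> SeedProfile:
    """Extract the k lowest-probability over-represented N-grams of a seed set.

    Parameters
    ----------
    seed_ids : record IDs of the seed library; must all be in ``corpus``.
    stats : background statistics built over the same corpus normalization.
    k_limit : maximum number of key terms retained (default 75).
    tail : score with the upper-tail probability instead of the point
        probability.
    """
    if not seed_ids:
        raise ValueError("seed set is empty")
    if k_limit < 1:
        raise ValueError(f"k_limit must be >= 1, got {k_limit}")
    seen_ids: dict[str, None] = {}
    for sid in seed_ids:
        if sid not in corpus:
            raise KeyError(f"unknown seed record_id {sid!r}")
        seen_ids.setdefault(sid, None)
    seed_records = [corpus[sid] for sid in seen_ids]

    max_n = stats.ngrams.max_n
    bg_size = stats.corpus_size
    seed_size = len(seed_records)

    seed_doc_count: dict[str, int] = {}
    for rec in seed_records:
        title_ngrams, abstract_ngrams = record_ngram_fields(rec, max_n)
        for term in set(title_ngrams) | set(abstract_ngrams):
            seed_doc_count[term] = seed_doc_count.get(term, 0) + 1

    score = hypergeom_tail_prob if tail else hypergeom_point_prob
    candidates: list[KeyTerm] = []
    for term, x in seed_doc_count.items():
        bg_hits = stats.ngrams.term_doc_count.get(term, x)
        if x <= seed_size * bg_hits / bg_size:  # not over-represented
            continue
        prob = max(score(x, seed_size, bg_hits, bg_size), _MIN_PROB)
        candidates.append(
            KeyTerm(
                term=term,
                seed_doc_count=x,
                background_doc_count=bg_hits,
                probability=prob,
                weight=-math.log(prob),
            )
        )

    candidates.sort(key=lambda kt: (kt.probability, kt.term))
    authors = frozenset(a for rec in seed_records for a in rec.authors)
    scopes = frozenset(s for rec in seed_records for s in rec.journal_subject_terms)
    return SeedProfile(
        key_terms=tuple(candidates[:k_limit]),
        seed_authors=authors,
        seed_scopes=scopes,
        k_limit=k_limit,
    )
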