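"""The recent-literature recommendation engine.

The engine turns a seed library into a structured query — key terms with
hypergeometric weights, the seed authors, and the seed journal scopes — and
ranks the records registered in a recency window (default: the three calendar
months preceding the query date) by a linear additive score:

    total = term_score + author_score + scope_score

    term_score   = sum over matched key terms t of
                   weight(t) * (title_boost if t occurs in the title else 1)
    author_score = author_bonus * |record authors  ∩  seed authors|
    scope_score  = scope_bonus if the record's journal scope intersects the
                   seed scopes else 0

A record is admitted only if it matches at least one key term (after
stop-term filtering) and contains every must-term. Ties in the ranking are
broken by ascending record ID so outputs are reproducible. Disabling the
window (window_months=None) turns the same machinery into an associative
search of the whole corpus against an arbitrary seed set.

The additive concretization and its default coefficients (title_boost 2.0;
author_bonus and scope_bonus one median key-term weight each, so that no
single context signal can outvote the term evidence) are this package's
design; all three are configurable.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime
import statistics
from typing import Optional

from .background import BackgroundStats, record_ngram_fields
from .corpus import BiblioRecord, Corpus, tokenize
from .keyterms import DEFAULT_K_LIMIT, SeedProfile, extract_key_terms

__all__ = [
    "StructuredQuery",
    "RankedHit",
    "months_before",
    "filter_target_window",
    "build_query",
    "score_candidate",
    "recommend",
    "DEFAULT_WINDOW_MONTHS",
    "DEFAULT_TITLE_BOOST",
]

DEFAULT_WINDOW_MONTHS = 3
DEFAULT_TITLE_BOOST = 2.0


def months_before(d: datetime.date, months: int) -> datetime.date:
    """Calendar-month subtraction with day clamping (May 31 - 3 -> Feb 28/29)."""
    total = d.year * 12 + (d.month - 1) - months
    year, month0 = divmod(total, 12)
    month = month0 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return datetime.date(year, month, day)


def filter_target_window(
    corpus: Corpus,
    as_of_date: datetime.date,
    window_months: int = DEFAULT_WINDOW_MONTHS,
    exclude_ids: frozenset[str] = frozenset(),
) -> list[str]:
    """Record IDs registered in the half-open window (as_of - months, as_of].

    The seed library itself is passed as ``exclude_ids`` so a user is never
    recommended papers already in their collection.
    """
    if window_months < 1:
        raise ValueError(f"window_months must be >= 1, got {window_months}")
    lower = months_before(as_of_date, window_months)
    return [
        rec.record_id
        for rec in corpus
        if rec.record_id not in exclude_ids
        and lower < rec.registered_date <= as_of_date
    ]


@dataclasses.dataclass(frozen=True)
class StructuredQuery:
    profile: SeedProfile
    as_of_date: datetime.date
    title_boost: float = DEFAULT_TITLE_BOOST
    author_bonus: float = 0.0
    scope_bonus: float = 0.0
    window_months: Optional[int] = DEFAULT_WINDOW_MONTHS
    stop_terms: frozenset[str] = frozenset()
    must_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.title_boost < 1:
            raise ValueError("title_boost must be >= 1")
        if self.author_bonus < 0 or self.scope_bonus < 0:
            raise ValueError("author_bonus and scope_bonus must be >= 0")


@dataclasses.dataclass(frozen=True)
class RankedHit:
    record_id: str
    term_score: float
    author_score: float
    scope_score: float
    total: float
    matched_terms: tuple[str, ...]


def _normalize_term(term: str) -> str:
    """Run a user-supplied stop/must term through corpus normalization."""
    return " ".join(tokenize(term).tokens)


def build_query(
    profile: SeedProfile,
    as_of_date: datetime.date,
    title_boost: float = DEFAULT_TITLE_BOOST,
    author_bonus: Optional[float] = None,
    scope_bonus: Optional[float] = None,
    window_months: Optional[int] = DEFAULT_WINDOW_MONTHS,
    stop_terms: frozenset[str] = frozenset(),
    must_terms: frozenset[str] = frozenset(),
) -> StructuredQuery:
    """Assemble a StructuredQuery, applying stop-term filtering to the profile.

    ``author_bonus`` / ``scope_bonus`` default to the median key-term weight
    of the (filtered) profile; stop and must terms are normalized with the
    corpus tokenizer before use.
    """
    stop = frozenset(_normalize_term(t) for t in stop_terms)
    must = frozenset(_normalize_term(t) for t in must_terms)
    profile = profile.without_terms(stop)
    weights = [kt.weight for kt in profile.key_terms]
    median_w = statistics.median(weights) if weights else 0.0
    return StructuredQuery(
        profile=profile,
        as_of_date=as_of_date,
        title_boost=title_boost,
        author_bonus=median_w if author_bonus is None else author_bonus,
        scope_bonus=median_w if scope_bonus is None else scope_bonus,
        window_months=window_months,
        stop_terms=stop,
        must_terms=must,
    )


def score_candidate(
    record: BiblioRecord, query: StructuredQuery
) -> Optional[RankedHit]:
    """Score one candidate; None if it fails the admission rules.

    Admission requires at least one matched key term and the presence of
    every must-term anywhere in the record's title or abstract.
    """
    max_n = max((len(kt.term.split()) for kt in query.profile.key_terms), default=1)
    for t in query.must_terms:
        max_n = max(max_n, len(t.split()))
    title_ngrams, abstract_ngrams = record_ngram_fields(record, max_n)
    title_set, abstract_set = set(title_ngrams), set(abstract_ngrams)
    present = title_set | abstract_set

    if any(t not in present for t in query.must_terms):
        return None

    term_score = 0.0
    matched: list[str] = []
    for kt in query.profile.key_terms:
        if kt.term in title_set:
            term_score += kt.weight * query.title_boost
            matched.append(kt.term)
        elif kt.term in abstract_set:
            term_score += kt.weight
            matched.append(kt.term)
    if not matched:
        return None

    author_score = query.author_bonus * len(
        set(record.authors) & query.profile.seed_authors
    )
    scope_score = (
        query.scope_bonus
        if record.journal_subject_terms & query.profile.seed_scopes
        else 0.0
    )
    return RankedHit(
        record_id=record.record_id,
        term_score=term_score,
        author_score=author_score,
        scope_score=scope_score,
        total=term_score + author_score + scope_score,
        matched_terms=tuple(matched),
    )


def recommend(
    seed_ids: list[str],
    corpus: Corpus,
    stats: BackgroundStats,
    as_of_date: datetime.date,
    top_m: int = 20,
    k_limit: int = DEFAULT_K_LIMIT,
    title_boost: float = DEFAULT_TITLE_BOOST,
    author_bonus: Optional[float] = None,
    scope_bonus: Optional[float] = None,
    window_months: Optional[int] = DEFAULT_WINDOW_MONTHS,
    stop_terms: frozenset[str] = frozenset(),
    must_terms: frozenset[str] = frozenset(),
) -> list[RankedHit]:
    """Rank the recent target set against a seed library.

    Composes key-term extraction, stop/must filtering, window filtering, and
    candidate scoring; returns at most ``top_m`` hits sorted by descending
    total score, ties broken by ascending record ID. ``window_months=None``
    ranks every non-seed record (corpus-wide associative mode).
    """
    if top_m < 1:
        raise ValueError(f"top_m must be >= 1, got {top_m}")
    profile = extract_key_terms(seed_ids, corpus, stats, k_limit=k_limit)
    query = build_query(
        profile,
        as_of_date,
        title_boost=title_boost,
        author_bonus=author_bonus,
        scope_bonus=scope_bonus,
        window_months=window_months,
        stop_terms=stop_terms,
        must_terms=must_terms,
    )
    exclude = frozenset(seed_ids)
    if window_months is None:
        target_ids = [r.record_id for r in corpus if r.record_id not in exclude]
    else:
        target_ids = filter_target_window(
            corpus, as_of_date, window_months, exclude
        )
    hits = []
    for rid in target_ids:
        hit = score_candidate(corpus[rid], query)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.total, h.record_id))
    return hits[:top_m]
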