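"""Independent brute-force recomputations used as test oracles.

Everything here is written against the package's *contracts*, not its code:
hypergeometric probabilities come from math.comb closed forms, N-gram counts
from explicit sliding windows, month arithmetic from one-month-at-a-time
decrements, and ranking from naive O(seeds x candidates x terms) loops. Only
the pinned text normalization (litrec.tokenize) is shared, since golden
token output is the package's published contract.
"""

import datetime
import math
from collections import Counter

from litrec import tokenize


def hypergeom_pmf(x, n, K, M):
    """P[X = x] drawing n from M with K marked, by the math.comb closed form."""
    if x < max(0, n + K - M) or x > min(n, K):
        return 0.0
    return math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)


def field_tokens(record):
    return (list(tokenize(record.title).tokens),
            list(tokenize(record.abstract).tokens))


def sliding_ngrams(tokens, max_n):
    out = []
    for n in range(1, max_n + 1):
        for i in range(len(tokens) - n + 1):
            out.append(" ".join(tokens[i:i + n]))
    return out


def record_ngrams(record, max_n):
    title, abstract = field_tokens(record)
    return sliding_ngrams(title, max_n) + sliding_ngrams(abstract, max_n)


def ngram_tables(corpus, max_n):
    doc, tot = Counter(), Counter()
    for rec in corpus:
        grams = record_ngrams(rec, max_n)
        tot.update(grams)
        doc.update(set(grams))
    return dict(doc), dict(tot)


def month_lower_bound(as_of, months):
    """First day NOT in the window: as_of shifted back month by month."""
    year, month, day = as_of.year, as_of.month, as_of.day
    for _ in range(months):
        month -= 1
        if month == 0:
            month, year = 12, year - 1
    while True:
        try:
            return datetime.date(year, month, day)
        except ValueError:
            day -= 1


def naive_key_terms(seed_ids, corpus, max_n, k_limit):
    """(term, seed_count, bg_count, prob, weight) rows, selection included."""
    bg_doc, _ = ngram_tables(corpus, max_n)
    M = len(corpus.records)
    seeds = [corpus[s] for s in dict.fromkeys(seed_ids)]
    n = len(seeds)
    seed_doc = Counter()
    for rec in seeds:
        seed_doc.update(set(record_ngrams(rec, max_n)))
    rows = []
    for term, x in seed_doc.items():
        K = bg_doc[term]
        if x <= n * K / M:
            continue
        p = hypergeom_pmf(x, n, K, M)
        rows.append((term, x, K, p, -math.log(p)))
    rows.sort(key=lambda r: (r[3], r[0]))
    return rows[:k_limit]


def contains_run(tokens, term):
    needle = term.split()
    k = len(needle)
    return any(tokens[i:i + k] == needle for i in range(len(tokens) - k + 1))


def naive_recommend(seed_ids, corpus, max_n, k_limit, as_of, window_months,
                    title_boost=2.0, top_m=10**9):
    """Full-pipeline recomputation with default median-weight bonuses."""
    key_rows = naive_key_terms(seed_ids, corpus, max_n, k_limit)
    weights = sorted(r[4] for r in key_rows)
    if weights:
        mid = len(weights) // 2
        median_w = (weights[mid] if len(weights) % 2
                    else (weights[mid - 1] + weights[mid]) / 2)
    else:
        median_w = 0.0
    seeds = [corpus[s] for s in dict.fromkeys(seed_ids)]
    seed_authors = {a for rec in seeds for a in rec.authors}
    seed_scopes = {s for rec in seeds for s in rec.journal_subject_terms}
    lower = month_lower_bound(as_of, window_months)
    hits = []
    for rec in corpus:
        if rec.record_id in set(seed_ids):
            continue
        if not (lower < rec.registered_date <= as_of):
            continue
        title, abstract = field_tokens(rec)
        term_score, matched = 0.0, []
        for term, _, _, _, w in key_rows:
            if contains_run(title, term):
                term_score += w * title_boost
                matched.append(term)
            elif contains_run(abstract, term):
                term_score += w
                matched.append(term)
        if not matched:
            continue
        author_score = median_w * len(set(rec.authors) & seed_authors)
        scope_score = median_w if rec.journal_subject_terms & seed_scopes else 0.0
        hits.append((rec.record_id, term_score, author_score, scope_score,
                     term_score + author_score + scope_score, tuple(matched)))
    hits.sort(key=lambda h: (-h[4], h[0]))
    return hits[:top_m]


def dense_cosine(a, b):
    terms = sorted(set(a) | set(b))
    va = [a.get(t, 0.0) for t in terms]
    vb = [b.get(t, 0.0) for t in terms]
    dot = sum(x * y for x, y in zip(va, vb))
    na = math.sqrt(sum(x * x for x in va))
    nb = math.sqrt(sum(y * y for y in vb))
    return 0.0 if na == 0 or nb == 0 else dot / (na * nb)


def naive_tfidf(record, corpus):
    """tf x idf unigram vector recomputed from scratch."""
    M = len(corpus.records)
    title, abstract = field_tokens(record)
    tf = Counter(title + abstract)
    out = {}
    for t, c in tf.items():
        df = sum(
            1 for r in corpus
            if t in field_tokens(r)[0] or t in field_tokens(r)[1]
        )
        idf = math.log(M / df)
        if idf:
            out[t] = c * idf
    return out
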