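"""Date-window filtering, structured-query scoring, and ranking."""

import datetime

import pytest

from litrec import (
    Corpus,
    GeneratorConfig,
    build_background_stats,
    build_query,
    extract_key_terms,
    filter_target_window,
    generate,
    recommend,
    score_candidate,
)
from litrec.recommend import DEFAULT_WINDOW_MONTHS, months_before

import _oracles
from conftest import make_record


class TestWindow:
    def test_default_window_is_three_months(self):
        assert DEFAULT_WINDOW_MONTHS == 3

    @pytest.mark.parametrize(
        "as_of, months, expected",
        [("2010-06-30", 3, "2010-03-30"),
         ("2010-05-31", 3, "2010-02-28"),   # day clamping
         ("2012-05-31", 3, "2012-02-29"),   # leap year
         ("2010-01-15", 1, "2009-12-15")],  # year wrap
    )
    def test_month_arithmetic(self, as_of, months, expected):
        got = months_before(datetime.date.fromisoformat(as_of), months)
        assert got.isoformat() == expected

    def test_boundary_inclusion(self):
        as_of = datetime.date(2010, 6, 30)
        corpus = Corpus([
            make_record("on", date="2010-06-30"),       # exactly as_of: in
            make_record("lower", date="2010-03-30"),    # exactly as_of-3m: out
            make_record("just_in", date="2010-03-31"),  # one day inside
            make_record("old", date="2010-03-29"),      # below window
            make_record("future", date="2010-07-01"),   # after as_of
        ])
        assert filter_target_window(corpus, as_of, 3) == ["on", "just_in"]

    def test_exclusion_of_seed_ids(self):
        corpus = Corpus([make_record("a", date="2010-06-01"),
                         make_record("b", date="2010-06-02")])
        got = filter_target_window(corpus, datetime.date(2010, 6, 30), 3,
                                   exclude_ids=frozenset({"a"}))
        assert got == ["b"]

    def test_survivors_match_loop_oracle(self):
        corpus, _ = generate(GeneratorConfig(n_records=120, seed=11))
        as_of = datetime.date(2010, 5, 15)
        got = set(filter_target_window(corpus, as_of, 3))
        lower = _oracles.month_lower_bound(as_of, 3)
        expected = {r.record_id for r in corpus
                    if lower < r.registered_date <= as_of}
        assert got == expected


def stable_term(profile):
    """First key term whose string survives re-tokenization unchanged.

    Tests that plant a key term into raw record text need a term whose
    stemmed form is a fixed point of the tokenizer.
    """
    from litrec import tokenize
    return next(kt for kt in profile.key_terms
                if " ".join(tokenize(kt.term).tokens) == kt.term)


class TestScoring:
    @pytest.fixture()
    def seed_query(self, tiny_corpus, tiny_stats):
        profile = extract_key_terms(["1002", "1003"], tiny_corpus, tiny_stats)
        return build_query(profile, datetime.date(2010, 6, 30))

    def test_no_shared_key_term_means_no_hit(self, tiny_corpus, seed_query):
        assert score_candidate(tiny_corpus["1006"], seed_query) is None

    def test_single_abstract_term_closed_form(self, tiny_corpus, tiny_stats):
        profile = extract_key_terms(["1002", "1003"], tiny_corpus, tiny_stats)
        kt = stable_term(profile)
        record = make_record("x", abstract=f"a sentence mentioning {kt.term} only",
                             authors=["Nobody Q"], date="2010-06-01")
        query = build_query(profile, datetime.date(2010, 6, 30),
                            author_bonus=0.0, scope_bonus=0.0)
        hit = score_candidate(record, query)
        assert hit is not None
        assert hit.matched_terms == (kt.term,)
        assert hit.total == pytest.approx(kt.weight)

    def test_title_match_gets_boost(self, tiny_corpus, tiny_stats):
        profile = extract_key_terms(["1002", "1003"], tiny_corpus, tiny_stats)
        kt = stable_term(profile)
        in_title = make_record("t", title=kt.term, date="2010-06-01")
        in_abstract = make_record("a", abstract=kt.term, date="2010-06-01")
        query = build_query(profile, datetime.date(2010, 6, 30),
                            title_boost=2.0, author_bonus=0.0, scope_bonus=0.0)
        assert score_candidate(in_title, query).term_score == pytest.approx(
            2.0 * score_candidate(in_abstract, query).term_score)

    def test_score_decomposition_sums(self, bench):
        corpus, labels, stats = bench
        seed_ids = [rid for rid, t in labels.items() if t == 1][:8]
        hits = recommend(seed_ids, corpus, stats,
                         as_of_date=datetime.date(2010, 6, 30), top_m=50)
        assert hits
        for h in hits:
            assert h.total == pytest.approx(
                h.term_score + h.author_score + h.scope_score)
            assert h.matched_terms

    def test_author_and_scope_contributions(self, tiny_corpus, tiny_stats):
        profile = extract_key_terms(["1002", "1003"], tiny_corpus, tiny_stats)
        kt = stable_term(profile)
        record = make_record(
            "x", abstract=kt.term, authors=["Garcia M", "Smith JB"],
            scopes=["Developmental Biology"], date="2010-06-01")
        query = build_query(profile, datetime.date(2010, 6, 30),
                            author_bonus=1.5, scope_bonus=0.75)
        hit = score_candidate(record, query)
        assert hit.author_score == pytest.approx(3.0)  # two matched authors
        assert hit.scope_score == pytest.approx(0.75)


class TestRecommend:
    def test_top_m_never_fabricates_hits(self, tiny_corpus, tiny_stats):
        hits = recommend(["1002", "1003"], tiny_corpus, tiny_stats,
                         as_of_date=datetime.date(2010, 6, 30),
                         window_months=6, top_m=1000)
        assert len(hits) <= len(tiny_corpus) - 2
        assert all(h.record_id not in {"1002", "1003"} for h in hits)

    def test_stop_terms_never_increase_term_score(self, bench):
        corpus, labels, stats = bench
        seed_ids = [rid for rid, t in labels.items() if t == 0][:8]
        base = recommend(seed_ids, corpus, stats,
                         as_of_date=datetime.date(2010, 6, 30),
                         author_bonus=0.0, scope_bonus=0.0, top_m=10**6)
        profile = extract_key_terms(seed_ids, corpus, stats)
        stop = frozenset([profile.key_terms[0].term, profile.key_terms[3].term])
        stopped = recommend(seed_ids, corpus, stats,
                            as_of_date=datetime.date(2010, 6, 30),
                            author_bonus=0.0, scope_bonus=0.0, top_m=10**6,
                            stop_terms=stop)
        base_scores = {h.record_id: h.term_score for h in base}
        for h in stopped:
            assert h.term_score <= base_scores[h.record_id] + 1e-9
            assert not set(h.matched_terms) & stop

    def test_must_terms_only_shrink_the_hit_set(self, bench):
        corpus, labels, stats = bench
        seed_ids = [rid for rid, t in labels.items() if t == 2][:8]
        base = recommend(seed_ids, corpus, stats,
                         as_of_date=datetime.date(2010, 6, 30), top_m=10**6)
        must = frozenset(["topic2sig00"])
        constrained = recommend(seed_ids, corpus, stats,
                                as_of_date=datetime.date(2010, 6, 30),
                                top_m=10**6, must_terms=must)
        assert {h.record_id for h in constrained} <= {h.record_id for h in base}
        assert len(constrained) < len(base)

    def test_ranking_invariant_under_corpus_permutation(self, tiny_corpus):
        reordered = Corpus(list(reversed(tiny_corpus.records)))
        kwargs = dict(as_of_date=datetime.date(2010, 6, 30),
                      window_months=6, top_m=10)
        a = recommend(["1002", "1003"], tiny_corpus,
                      build_background_stats(tiny_corpus), **kwargs)
        b = recommend(["1002", "1003"], reordered,
                      build_background_stats(reordered), **kwargs)
        assert a == b

    def test_window_disabled_ranks_all_non_seed_records(self, tiny_corpus, tiny_stats):
        hits = recommend(["1002", "1003"], tiny_corpus, tiny_stats,
                         as_of_date=datetime.date(2010, 6, 30),
                         window_months=None, top_m=1000)
        # 1004 shares the regeneration/zebrafish vocabulary, 1005 "signal";
        # 1001 and 1006 share no key term at all
        assert {h.record_id for h in hits} == {"1004", "1005"}

    def test_matches_naive_pipeline_on_small_corpus(self, tiny_corpus, tiny_stats):
        as_of = datetime.date(2010, 6, 30)
        hits = recommend(["1002", "1003"], tiny_corpus, tiny_stats,
                         as_of_date=as_of, window_months=6, top_m=100)
        oracle = _oracles.naive_recommend(["1002", "1003"], tiny_corpus, 5, 75,
                                          as_of, 6)
        assert [h.record_id for h in hits] == [o[0] for o in oracle]
        for h, o in zip(hits, oracle):
            assert h.total == pytest.approx(o[4], rel=1e-9)
            assert h.matched_terms == o[5]
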