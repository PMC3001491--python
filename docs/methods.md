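# Methods

## The model

`litrec` frames literature recommendation as enrichment testing plus
structured-query retrieval. A user's library is a sample of n records drawn
from a background corpus of M records. For any term t contained in K of the
M records, the number of library records containing t is, under the null of
interest-free sampling, hypergeometric; a term whose observed library
document frequency x exceeds its expectation nK/M and whose point
probability P(X = x) is small is evidence of a topical interest. The k
lowest-probability terms (k capped at 75) become a weighted query, the
weight being the surprisal −ln P. The same urn model is reused at the MeSH
heading level for tag suggestion.

Two modelling choices deserve flagging:

* **Document-level counting.** Both x and K count *records containing* the
  term, not token occurrences. The urn model draws papers, so occurrence
  counts would break exchangeability (a term used ten times in one abstract
  is one draw, not ten).
* **Point probability, not tail.** The significance score is P(X = x)
  rather than P(X ≥ x). For over-represented terms the two are close and
  induce near-identical rankings; the pmf is kept as the default and an
  upper-tail option (`tail=True` in `extract_key_terms`,
  `hypergeom_tail_prob`) is provided for users who want a conservative
  p-value semantics. Probabilities are floored at 1e-300 before taking
  logs so extreme enrichment cannot produce an infinite weight.

## Scoring

The retrieval score is a linear additive concretization of a
natural-language query of the form "find papers containing at least one key
term, weighting by term weight, with extra credit for shared authors and
in-scope journals":

    total = Σ_t∈matched w(t)·(title_boost if t in title else 1)
          + author_bonus·|authors ∩ seed_authors|
          + scope_bonus·1[scopes ∩ seed_scopes ≠ ∅]

Defaults: `title_boost = 2.0`; `author_bonus` and `scope_bonus` each default
to the median key-term weight of the filtered profile. The rationale for the
median coupling: context bonuses should matter about as much as one typical
term match, so they can break ties between topically similar candidates but
can never outvote an entire profile of term evidence. Author credit is
count-scaled (each shared author adds one bonus) because shared co-author
sets are stronger evidence than a single shared name; scope credit is binary
because journal scope lists are coarse. All three are plain parameters.

Admission requires at least one matched key term; user-supplied stop terms
are removed from the profile before scoring and must-terms are required to
occur in the candidate's text. Stop/must terms pass through the corpus
tokenizer first, so users can type natural phrases.

The recency window is half-open: (as_of − window_months, as_of], with
calendar-month arithmetic and day clamping (May 31 minus 3 months is the
last day of February). The window default is 3 months; `window_months=None`
disables filtering and turns the engine into a corpus-wide associative
ranker. Final ties are broken by ascending record ID so outputs are
deterministic.

## Text normalization

Tokenization is pinned, since every statistic is defined over its output:
lowercase; split on non-alphanumeric runs; drop purely numeric tokens
shorter than two digits; drop stop words (a small fixed English list shipped
with the package); stem with a classic Porter (1980) stemmer implemented in
`litrec/_porter.py`. Stemming is iterated to a fixed point and stems that
land on the stop list are dropped, which makes normalization closed under
re-tokenization (an invariant the tests rely on); for almost all words one
Porter pass is already stable. N-grams (N = 1..5) are contiguous token runs
within a field and never span the title/abstract boundary. The five-token
ceiling matches the operational maximum key-phrase length; longer N-grams
almost never recur across documents and would inflate the dictionary.

IDF is the unsmoothed natural log, idf(t) = ln(M/df(t)), computed over
titles+abstracts. Out-of-vocabulary terms get idf = ln(M) (treated as
df = 1), needed when a seed record uses a term absent from the indexed
background. Term vectors for associative search use raw term frequency
times IDF over unigrams; sub-linear tf damping was considered and left out
of the default because the abstracts involved are short enough that raw
counts rarely exceed 3–4. Multi-paper seeds are combined by vector sum;
cosine is scale-invariant, so this is equivalent to the centroid.

## Tag names

MeSH headings are frequently comma-inverted ("Neoplasms, Experimental").
The tag normalizer splits on commas, reverses the segments, joins with
spaces and lowercases, which un-inverts such headings into readable tags
("experimental neoplasms") and is idempotent. Suggestion thresholds default
to probability ≤ 0.01 and at most 10 suggestions — small enough that a
suggestion list stays glanceable, loose enough to surface all genuinely
enriched headings in libraries of a few dozen papers.

## Synthetic corpora

The generator plants exactly the regularities the pipeline exploits, and
nothing else. Each record draws a topic; each token is, with probability
`signature_rate` (default 0.30), a uniform draw from the topic's 12
signature terms, with probability `background_rate` (default 0.02) per
other topic a draw from that topic's signatures (cross-topic leakage), and
otherwise a uniform draw from a 2000-word background vocabulary. The
defaults give a strongly but not trivially separable corpus: roughly a
third of each abstract is topical signal, and every off-topic document
still contains a couple of leaked signature tokens, so ranking must rely on
accumulated evidence rather than single-term presence. Setting
`signature_rate == background_rate` produces a null corpus with no
detectable plant, used to check that the extractor does not hallucinate
structure. Authors come preferentially (0.7) from a per-topic community of
10; journal scope is the topic's subject term with probability 0.9; each of
the topic's 3 MeSH headings is assigned with probability 0.8 plus common
headings ("Humans", ...) at 0.4; dates are uniform over the first half of
2010 so a 3-month window retains about half the corpus. Vocabulary words
are constructed to be fixed points of the tokenizer, so token-level
guarantees are exact.

What the generator does **not** emulate: real word-frequency (Zipfian)
distributions, syntax, multi-topic documents, citation structure,
time-varying topic popularity, or MeSH hierarchy. Passing recovery tests
therefore demonstrates that the machinery finds planted statistical
structure under its own model assumptions — not that it achieves any
particular precision on real MEDLINE text.

## Problem sizes and numerics

The shipped benchmark uses 500 records, 4 topics, and 10-record seed sets,
sizes at which every hypergeometric tail is exactly computable and
brute-force oracle recomputation of the whole pipeline is fast; oracle
equivalence is additionally checked across 25 corpora of 40–180 records.
Hypergeometric probabilities come from `scipy.stats.hypergeom`; tests
verify them against `math.comb` closed forms and literal draw enumeration
up to population 12. Score sums are ordinary floats; when two candidates'
totals are mathematically equal, summation order can differ in the last ulp
between independent implementations, so cross-implementation comparisons
treat positions within an exact score tie as interchangeable (within the
package itself ties are broken by record ID, deterministically).

## Interfaces and formats

The corpus lives in a JSONL dialect (one UTF-8 object per line; writer
output is canonical, so read→write round-trips byte-identically) or a
MEDLINE-XML subset (PMID, ArticleTitle, AbstractText, AuthorList, MedlineTA,
JournalSubjectList, MeshHeadingList, DateCreated); both readers yield
identical in-memory corpora for equivalent content. The background index is
a versioned JSON container of the count tables; IDF is recomputed on load.
Author names are matched after collapsing to lowercase single-space form —
coarser identity resolution (initials vs full names, homonyms) is out of
scope.

DOI extraction accepts `10.<registrant>/<suffix>` with an optional `doi:`
prefix and trims trailing sentence punctuation, which PDF text commonly
glues onto identifiers. Title lookup matches a record's normalized title as
a contiguous token subsequence of the normalized text and requires at least
4 title tokens by default, suppressing false hits from short generic titles.
Filename wildcards are fixed to `$TITLE`, `$YEAR`, `$JOURNAL`,
`$FIRSTAUTHOR`, `$PMID`; field values have filesystem-unsafe characters
replaced by `_`, are length-capped at 120 characters, and missing fields
render as `unknown`.

## Known limitations

* Key-term candidacy treats nested N-grams independently (a selected bigram
  does not suppress its unigrams), so query weight partially double-counts
  phrases; a subsumption rule would change the cap semantics.
* The additive retrieval score is one concretization of a structured IR
  query; other weightings (e.g. multiplicative or learned) are plausible.
* Associative-search vectors use title+abstract, not full text.
* The generator's independence assumptions make recovery easier than on
  real corpora; reported precisions are upper bounds in that sense.
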