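import datetime

import pytest

from litrec import (
    BiblioRecord,
    Corpus,
    GeneratorConfig,
    build_background_stats,
    generate,
)


def make_record(rid, title="", abstract="", authors=(), journal="",
                scopes=(), mesh=(), date="2010-03-15"):
    return BiblioRecord(
        record_id=rid,
        title=title,
        abstract=abstract,
        authors=tuple(authors),
        journal=journal,
        journal_subject_terms=frozenset(scopes),
        mesh_terms=frozenset(mesh),
        registered_date=datetime.date.fromisoformat(date),
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    """Hand-built 6-record corpus with an obvious shared topic in 1002-1004."""
    return Corpus([
        make_record("1001", title="transcription factor binding",
                    abstract="chromatin immunoprecipitation assays of binding sites",
                    authors=["Smith JB", "Tanaka K"], journal="Genome Res",
                    scopes=["Genetics"], mesh=["Transcription Factors"],
                    date="2010-01-10"),
        make_record("1002", title="zebrafish heart regeneration",
                    abstract="cardiomyocyte proliferation drives zebrafish heart regeneration",
                    authors=["Garcia M", "Smith JB"], journal="Dev Biol",
                    scopes=["Developmental Biology"],
                    mesh=["Zebrafish", "Regeneration", "Neoplasms, Experimental"],
                    date="2010-02-20"),
        make_record("1003", title="zebrafish fin regeneration signals",
                    abstract="wnt signaling in zebrafish fin regeneration",
                    authors=["Garcia M"], journal="Dev Biol",
                    scopes=["Developmental Biology"],
                    mesh=["Zebrafish", "Regeneration"],
                    date="2010-03-05"),
        make_record("1004", title="regeneration of zebrafish retina",
                    abstract="muller glia mediate zebrafish retina regeneration",
                    authors=["Chen L"], journal="Dev Dyn",
                    scopes=["Developmental Biology"],
                    mesh=["Zebrafish", "Regeneration", "Retina"],
                    date="2010-03-25"),
        make_record("1005", title="bacterial chemotaxis networks",
                    abstract="signal transduction in bacterial chemotaxis",
                    authors=["Novak P"], journal="J Bacteriol",
                    scopes=["Microbiology"], mesh=["Chemotaxis", "Escherichia coli"],
                    date="2010-04-12"),
        make_record("1006", title="protein folding kinetics",
                    abstract="kinetic analysis of two state protein folding",
                    authors=["Okafor C"], journal="Biochemistry",
                    scopes=["Biochemistry"], mesh=["Protein Folding", "Kinetics"],
                    date="2010-05-30"),
    ])


@pytest.fixture(scope="session")
def tiny_stats(tiny_corpus):
    return build_background_stats(tiny_corpus, max_n=5)


@pytest.fixture(scope="session")
def bench():
    """The shipped planted-topic benchmark: corpus, labels, stats."""
    corpus, labels = generate(GeneratorConfig(seed=2010))
    stats = build_background_stats(corpus)
    return corpus, labels, stats
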