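"""Corpus engine: dedup, linkage, alias matching, counting, validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from beebias.corpus import (
    InvertedIndex,
    SourceRecord,
    UnifiedDocument,
    build_alias_library,
    count_genus_mentions,
    dedup_within_source,
    match_countries,
    match_cross_source,
    normalize_doi,
    title_similarity,
    tokenize_and_stem,
    validate_counts,
    UNKNOWN_YEAR,
)
from beebias.porter import stem
from beebias.synth import CorpusSpec, default_genus_table, default_species_names, gen_corpus


def rec(record_id, source="wos", **kwargs):
    return SourceRecord(record_id=record_id, source=source, **kwargs)


def doc(doc_id, title="", abstract="", year=2000):
    return UnifiedDocument(doc_id=doc_id, provenance="wos_only", year=year,
                           title=title, abstract=abstract, doi=None)


# ---------------------------------------------------------------------------
# stemming and tokenisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "word,expected",
    [
        ("pollinating", "pollin"),
        ("pollination", "pollin"),
        ("bees", "bee"),
        ("bee", "bee"),
        ("caresses", "caress"),
        ("ponies", "poni"),
        ("feed", "feed"),
        ("motoring", "motor"),
        ("hopping", "hop"),
        ("happy", "happi"),
        ("sky", "sky"),
        ("relational", "relat"),
        ("apis", "api"),
    ],
)
def test_porter_stems_known_words(word, expected):
    assert stem(word) == expected


def test_tokenize_and_stem_examples():
    assert tokenize_and_stem("Pollinating bees!") == ["pollin", "bee"]
    assert tokenize_and_stem("") == []
    # determinism: equal inputs give equal sequences across calls
    text = "The honeybee Apis mellifera forages on flowering plants."
    assert tokenize_and_stem(text) == tokenize_and_stem(text)


# ---------------------------------------------------------------------------
# DOI normalisation and within-source dedup
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("DOI:10.1000/ABC", "10.1000/abc"),
        ("  10.5281/zenodo.12345 ", "10.5281/zenodo.12345"),
        ("", None),
        (None, None),
        ("doi: 10.1/X", "10.1/x"),
    ],
)
def test_normalize_doi(raw, expected):
    assert normalize_doi(raw) == expected


def test_dedup_keeps_first_per_native_id():
    r1 = rec("U1", doi="X")
    r2 = rec("U1", doi="Y")
    assert dedup_within_source([r1, r2]) == [r1]


def test_dedup_collapses_normalised_doi_collisions():
    r1 = rec("U1", doi="x")
    r2 = rec("U2", doi="DOI:x")
    assert dedup_within_source([r1, r2]) == [r1]


def test_dedup_null_dois_never_collide():
    r1 = rec("U1")
    r2 = rec("U2")
    assert dedup_within_source([r1, r2]) == [r1, r2]


def test_dedup_rejects_mixed_sources():
    with pytest.raises(ValueError, match="mix"):
        dedup_within_source([rec("U1", "wos"), rec("E1", "scopus")])


@given(
    st.lists(
        st.tuples(st.integers(0, 5), st.one_of(st.none(), st.integers(0, 3))),
        max_size=20,
    )
)
def test_dedup_is_idempotent(raw):
    records = [
        rec(f"U{i}", doi=None if d is None else f"10.1/{d}") for i, d in raw
    ]
    once = dedup_within_source(records)
    assert dedup_within_source(once) == once


# ---------------------------------------------------------------------------
# cross-source linkage
# ---------------------------------------------------------------------------

def test_doi_merge_defines_intersection():
    res = match_cross_source([rec("U1", doi="10.1/x")], [rec("E1", "scopus", doi="DOI:10.1/X")])
    assert len(res.intersection) == 1
    assert res.wos_only == [] and res.scopus_only == []
    assert res.intersection[0].provenance == "both"


def test_title_year_match_links_caseless_identical_titles():
    a = rec("U1", title="Bee decline in Europe", year=2005)
    b = rec("E1", "scopus", title="Bee Decline in Europe", year=2005)
    assert title_similarity(a.title, b.title) == 1.0
    res = match_cross_source([a], [b], sim_threshold=0.9)
    assert len(res.intersection) == 1


def test_title_match_requires_same_year():
    a = rec("U1", title="Bee decline in Europe", year=2005)
    b = rec("E1", "scopus", title="Bee decline in Europe", year=2006)
    res = match_cross_source([a], [b])
    assert res.intersection == []
    assert res.union_size == 2


def test_invalid_similarity_threshold_rejected():
    with pytest.raises(ValueError):
        match_cross_source([], [], sim_threshold=1.5)


def test_partition_identity_on_random_corpora():
    for seed in range(5):
        corpus = gen_corpus(CorpusSpec(seed=seed, n_docs=120))
        wos = dedup_within_source(corpus.wos)
        scopus = dedup_within_source(corpus.scopus)
        res = match_cross_source(wos, scopus)
        assert res.union_size == len(res.documents)
        # every source record accounted for exactly once
        assert 2 * len(res.intersection) + len(res.wos_only) + len(res.scopus_only) == (
            len(wos) + len(scopus)
        )


def test_no_duplicates_means_empty_intersection():
    corpus = gen_corpus(CorpusSpec(seed=3, n_docs=100, duplicate_rate=0.0))
    res = match_cross_source(corpus.wos, corpus.scopus)
    assert res.intersection == []


# ---------------------------------------------------------------------------
# alias library
# ---------------------------------------------------------------------------

def test_alias_library_generates_binomial_abbreviations():
    lib = build_alias_library(
        default_genus_table(3), species_names={"Apis": ["Apis mellifera"]}
    )
    phrases = {a.phrase: a.kind for a in lib.entries["Apis"].aliases}
    assert phrases.get("a. mellifera") == "abbreviation"
    abbrev = next(a for a in lib.entries["Apis"].aliases if a.kind == "abbreviation")
    assert abbrev.stemmed == ("a", "mellifera")


def test_alias_library_attaches_common_names_and_canonical_name():
    lib = build_alias_library(default_genus_table(6))
    apis = {a.phrase for a in lib.entries["Apis"].aliases}
    assert "apis" in apis and "honeybee" in apis and "honey bee" in apis
    osmia = {a.phrase for a in lib.entries["Osmia"].aliases}
    assert "mason bee" in osmia


def test_alias_multivalued_cell_split_on_delimiters():
    table = [{"genus": "Osmia", "aliases": "mason bee; mason bees"},
             {"genus": "Apis"}, {"genus": "Bombus"}]
    lib = build_alias_library(table, common_names={})
    kinds = [a.phrase for a in lib.entries["Osmia"].aliases if a.kind == "common_name"]
    assert sorted(kinds) == ["mason bee", "mason bees"]


def test_alias_library_rejects_duplicate_genus_rows():
    with pytest.raises(ValueError, match="duplicate genus"):
        build_alias_library([{"genus": "Apis"}, {"genus": "Apis"}], common_names={})


def test_alias_mapped_to_two_genera_is_an_error():
    table = [{"genus": "Apis", "aliases": "honey bee"},
             {"genus": "Bombus", "aliases": "honey bee"}]
    with pytest.raises(ValueError, match="honey bee"):
        build_alias_library(table, common_names={})


def test_ambiguous_abbreviations_are_dropped_with_warning():
    table = [{"genus": "Andrena"}, {"genus": "Apis"}]
    species = {"Andrena": ["Andrena mellifera"], "Apis": ["Apis mellifera"]}
    with pytest.warns(UserWarning, match="ambiguous"):
        lib = build_alias_library(table, common_names={}, species_names=species)
    for genus in ("Andrena", "Apis"):
        assert all(a.kind != "abbreviation" for a in lib.entries[genus].aliases)


# ---------------------------------------------------------------------------
# inverted index and counting
# ---------------------------------------------------------------------------

def test_posting_lists_have_set_semantics():
    index = InvertedIndex.build([doc("d1", abstract="bee bee")])
    assert index.lookup("bee") == frozenset({"d1"})


def test_shared_token_appears_in_both_posting_lists():
    index = InvertedIndex.build([doc("d1", abstract="apis forages"),
                                 doc("d2", abstract="apis nests")])
    assert index.lookup(stem("apis")) == frozenset({"d1", "d2"})
    assert index.lookup("unseen") == frozenset()


def test_duplicate_doc_ids_rejected():
    with pytest.raises(ValueError, match="duplicate doc_id"):
        InvertedIndex.build([doc("d1"), doc("d1")])


def test_phrase_match_requires_consecutive_tokens():
    index = InvertedIndex.build(
        [doc("hit", abstract="the honey bee forages"),
         doc("miss", abstract="honey and a bee")]
    )
    phrase = tuple(tokenize_and_stem("honey bee"))
    assert index.phrase_docs(phrase) == {"hit"}


def build_counting_fixture(texts, years=None):
    years = years or [2000] * len(texts)
    docs = [doc(f"d{i}", abstract=t, year=y) for i, (t, y) in enumerate(zip(texts, years))]
    lib = build_alias_library(default_genus_table(6), species_names=default_species_names(6))
    return InvertedIndex.build(docs), lib


def test_document_counts_once_per_genus():
    index, lib = build_counting_fixture(["The honeybee Apis mellifera forages"])
    counts = count_genus_mentions(index, lib)
    assert counts.counts == {("Apis", 2000): 1}


def test_multi_genus_document_increments_each_and_cooccurrence():
    index, lib = build_counting_fixture(["Apis and Bombus share flowers"])
    counts = count_genus_mentions(index, lib)
    assert counts.counts == {("Apis", 2000): 1, ("Bombus", 2000): 1}
    assert counts.cooccurrence == {("Apis", "Bombus"): 1}


def test_high_confidence_mode_excludes_abbreviations():
    index, lib = build_counting_fixture(["A. mellifera only"])
    assert count_genus_mentions(index, lib, mode="full").counts == {("Apis", 2000): 1}
    assert count_genus_mentions(index, lib, mode="high_confidence").counts == {}


def test_unknown_year_documents_fall_into_sentinel_bucket():
    docs = [doc("d1", abstract="Apis mellifera", year=None)]
    lib = build_alias_library(default_genus_table(3))
    counts = count_genus_mentions(InvertedIndex.build(docs), lib)
    assert counts.counts == {("Apis", UNKNOWN_YEAR): 1}


def test_planted_mentions_recovered_exactly_on_clean_corpus():
    corpus = gen_corpus(CorpusSpec(seed=11, n_docs=250))
    res = match_cross_source(
        dedup_within_source(corpus.wos), dedup_within_source(corpus.scopus)
    )
    index = InvertedIndex.build(res.documents)
    for mode in ("full", "high_confidence"):
        counts = count_genus_mentions(index, corpus.library, mode=mode)
        assert counts.counts == corpus.true_counts(mode)


# ---------------------------------------------------------------------------
# country gazetteer
# ---------------------------------------------------------------------------

GAZ = {"Brazil": "BRA", "USA": "USA", "United States": "USA", "Niger": "NER"}


def test_gazetteer_exact_matches():
    assert match_countries("sampled in Brazil and the USA", GAZ) == {"BRA", "USA"}


def test_gazetteer_requires_whole_phrase_boundaries():
    assert match_countries("brazilwood extract", GAZ) == set()
    assert match_countries("nigeria survey", GAZ) == set()


def test_gazetteer_unknown_toponym_and_duplicates():
    assert match_countries("Atlantis", GAZ) == set()
    assert match_countries("USA and United States", GAZ) == {"USA"}


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

def test_validation_perfect_agreement():
    auto = {"Apis": 10, "Bombus": 5, "Osmia": 2, "Andrena": 7}
    report = validate_counts(auto, dict(auto))
    assert report.spearman_rho == pytest.approx(1.0)
    assert report.mae == 0 and report.rmse == 0
    assert report.ols_slope == pytest.approx(1.0)


def test_validation_linear_rescaling():
    auto = {"Apis": 20, "Bombus": 10, "Osmia": 4, "Andrena": 14}
    manual = {g: v / 2 for g, v in auto.items()}
    report = validate_counts(auto, manual)
    assert report.pearson_r == pytest.approx(1.0)
    assert report.ols_slope == pytest.approx(0.5)


def test_validation_spearman_matches_naive_rank_oracle(rng):
    genera = [f"g{i}" for i in range(25)]
    auto = {g: float(v) for g, v in zip(genera, rng.integers(0, 50, 25))}
    manual = {g: auto[g] + float(rng.normal(0, 5)) for g in genera}
    report = validate_counts(auto, manual)
    a = np.array([auto[g] for g in genera])
    m = np.array([manual[g] for g in genera])
    oracle = np.corrcoef(sps.rankdata(a), sps.rankdata(m))[0, 1]
    assert report.spearman_rho == pytest.approx(oracle, abs=1e-12)
    assert report.mae <= report.rmse


def test_validation_needs_three_shared_genera():
    with pytest.raises(ValueError, match="3 shared"):
        validate_counts({"a": 1, "b": 2}, {"a": 1, "b": 2})


def test_validation_precision_wilson_interval_brackets_estimate():
    auto = {"a": 1, "b": 2, "c": 3}
    report = validate_counts(auto, auto, labelled_sample=(90, 100))
    assert report.precision == pytest.approx(0.9)
    lo, hi = report.precision_ci
    assert lo < 0.9 < hi
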