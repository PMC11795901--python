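"""Frequency tables, binomial z-scores, rare-term filter, candidate flag."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from searchminer import (
    AnalysisConfig,
    DataError,
    RecordSet,
    TermStats,
    all_keywords_table,
    build_population_model,
    filter_rare,
    freetext_table,
    generate_records,
    mesh_table,
    qualifier_table,
    relative_recall,
    z_score,
)
from searchminer.analysis import Z_ABSENT, Z_NEG_CLAMP, _z_for
from searchminer.fixtures import random_fixture_spec
from searchminer.population import PopulationModel
from searchminer.textprep import token_surfaces

from conftest import make_record


# Frozen expected values evaluated independently from the closed form
# (x - n*p0)/sqrt(n*p0*(1-p0)); the 7.98... case is additionally
# cross-checked by Monte Carlo below.
@pytest.mark.parametrize(
    "x, n, p0, expected",
    [
        (30, 100, 0.3, 0.0),  # x equals expectation
        (30, 100, 0.1, 6.666666666666667),  # 20/sqrt(9)
        (0, 50, 0.2, -3.5355339059327373),  # -10/sqrt(8)
        (6, 10, 0.05, 7.980238751210129),  # 5.5/sqrt(0.475)
    ],
)
def test_z_score_closed_form(x, n, p0, expected):
    assert z_score(x, n, p0) == pytest.approx(expected, abs=1e-12)


def test_z_score_agrees_with_monte_carlo_binomial_sampler():
    """The score standardizes the binomial: over many draws of X~Bin(n,p0),
    mean(z) ~ 0 and sd(z) ~ 1."""
    rng = random.Random(12345)
    n, p0 = 100, 0.1
    zs = [
        z_score(sum(rng.random() < p0 for _ in range(n)), n, p0)
        for _ in range(20000)
    ]
    mean = sum(zs) / len(zs)
    sd = math.sqrt(sum((z - mean) ** 2 for z in zs) / (len(zs) - 1))
    assert abs(mean) < 0.03
    assert abs(sd - 1) < 0.03


@pytest.mark.parametrize("p0", [0.0, 1.0, -0.1, 1.5])
def test_z_score_rejects_degenerate_p0(p0):
    with pytest.raises(ValueError):
        z_score(5, 10, p0)


def test_p0_one_clamp_rule():
    assert _z_for(10, 10, 1.0) == 0.0
    assert _z_for(9, 10, 1.0) == Z_NEG_CLAMP


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=0, max_value=500),
    st.floats(min_value=0.001, max_value=0.999),
)
def test_z_score_algebraic_identity_and_monotonicity(n, x, p0):
    x = min(x, n)
    z = z_score(x, n, p0)
    phat = x / n
    assert z == pytest.approx((phat - p0) / math.sqrt(p0 * (1 - p0) / n), abs=1e-12)
    if x < n:
        assert z_score(x + 1, n, p0) > z


def test_freetext_table_hand_example():
    """10 records, 6 containing 'tumour' (9 occurrences), p0 = 0.05."""
    records = []
    for i in range(10):
        if i < 3:
            text = "tumour tumour filler"
        elif i < 6:
            text = "tumour filler"
        else:
            text = "filler"
        records.append(make_record(i + 1, title=text))
    pop = PopulationModel(n_pop=100, doc_freq={"tumour": 5, "filler": 100})
    table = freetext_table(RecordSet(records), pop)
    row = next(r for r in table if r.term == "tumour")
    assert row.documents == 6
    assert row.documents_pct == pytest.approx(60.0)
    assert row.term_frequency == 9
    assert row.z == pytest.approx(7.980238751210129, abs=1e-12)
    assert row.is_candidate is False
    # filler is in every population record (p0 = 1) and misses 0 dev records
    filler = next(r for r in table if r.term == "filler")
    assert filler.z == 0.0


def test_absent_term_gets_sentinel_and_candidate_flag(tiny_population):
    records = RecordSet([make_record(i, title="zebrafish cancer") for i in range(5)])
    table = freetext_table(records, tiny_population)
    by_term = {r.term: r for r in table}
    assert by_term["zebrafish"].z == 10000
    assert by_term["zebrafish"].is_candidate is True
    assert by_term["cancer"].z != 10000


def test_table_sorted_by_z_descending_ties_alphabetical(tiny_population):
    records = RecordSet([make_record(i, title="alpha beta cancer") for i in range(5)])
    table = freetext_table(records, tiny_population)
    zs = [r.z for r in table]
    assert zs == sorted(zs, reverse=True)
    sentinels = [r.term for r in table if r.z == 10000]
    assert sentinels == sorted(sentinels)


def test_all_empty_texts_give_empty_table_with_warning(tiny_population, caplog):
    records = RecordSet([make_record(1), make_record(2)])
    with caplog.at_level("WARNING"):
        table = freetext_table(records, tiny_population)
    assert table == []
    assert "empty" in caplog.text


def test_empty_dev_set_is_an_error(tiny_population):
    with pytest.raises(DataError):
        freetext_table(RecordSet([]), tiny_population)


def test_mesh_and_qualifier_tables_split_the_keyword(tiny_population, mesh_dict):
    records = RecordSet(
        [make_record(1, keywords=["Neoplasms/diagnosis", "Neoplasms/therapy"])]
    )
    mesh_rows = mesh_table(records, tiny_population, mesh_dict)
    assert len(mesh_rows) == 1
    assert mesh_rows[0].term == "Neoplasms"
    assert mesh_rows[0].documents == 1
    assert mesh_rows[0].term_frequency is None  # column skipped for MeSH
    qual_rows = qualifier_table(records, tiny_population, mesh_dict)
    assert {(r.term, r.documents, r.term_frequency) for r in qual_rows} == {
        ("diagnosis", 1, 1),
        ("therapy", 1, 1),
    }


def test_non_mesh_keyword_in_neither_controlled_table(tiny_population, mesh_dict):
    records = RecordSet([make_record(1, keywords=["my lab keyword"])])
    assert mesh_table(records, tiny_population, mesh_dict) == []
    assert qualifier_table(records, tiny_population, mesh_dict) == []
    assert all_keywords_table(records) == [("my lab keyword", 1)]


def test_qualifier_term_frequency_can_exceed_documents(tiny_population, mesh_dict):
    records = RecordSet(
        [
            make_record(1, keywords=["Neoplasms/therapy", "Breast Neoplasms/therapy"]),
            make_record(2, keywords=["Humans"]),
        ]
    )
    rows = qualifier_table(records, tiny_population, mesh_dict)
    row = rows[0]
    assert row.term == "therapy"
    assert row.documents == 1
    assert row.term_frequency == 2


def test_mesh_full_coverage_gives_100_pct(tiny_population, mesh_dict):
    records = RecordSet(
        [make_record(1, keywords=["Humans"]), make_record(2, keywords=["Humans"])]
    )
    rows = mesh_table(records, tiny_population, mesh_dict)
    assert rows[0].documents == 2
    assert rows[0].documents_pct == pytest.approx(100.0)


def test_mesh_sentinel_when_population_lacks_section(mesh_dict, caplog):
    pop = PopulationModel(n_pop=100, doc_freq={"cancer": 10})
    records = RecordSet([make_record(1, keywords=["Humans"])])
    with caplog.at_level("WARNING"):
        rows = mesh_table(records, pop, mesh_dict)
    assert rows[0].z == 10000
    assert "sentinel" in caplog.text


def test_all_keywords_counts_raw_strings_sorted(tiny_population):
    records = RecordSet(
        [
            make_record(1, keywords=["Neoplasms/diagnosis", "Neoplasms/therapy"]),
            make_record(2, keywords=["Neoplasms/therapy"]),
            make_record(3, keywords=["Neoplasms/therapy"]),
            make_record(4),
        ]
    )
    assert all_keywords_table(records) == [
        ("Neoplasms/therapy", 3),
        ("Neoplasms/diagnosis", 1),
    ]


def _row(documents, n):
    return TermStats(
        term="t", documents=documents, documents_pct=100 * documents / n, z=0.0
    )


@pytest.mark.parametrize(
    "documents, n, kept",
    [
        (1, 50, False),  # only 1 record
        (4, 50, False),  # 8% < 10%
        (6, 50, True),  # 12%, both clauses pass
        (2, 10, True),  # 20%
        (5, 100, False),  # 5% < 10% despite 5 records
    ],
)
def test_filter_rare_or_combination(documents, n, kept):
    rows = filter_rare([_row(documents, n)], n)
    assert bool(rows) is kept


def test_relative_recall_is_documents_pct():
    assert relative_recall(_row(6, 10)) == pytest.approx(60.0)
    assert relative_recall(_row(10, 10)) == pytest.approx(100.0)
    assert relative_recall(_row(1, 3)) == pytest.approx(100 / 3)


def _naive_freetext_counts(records):
    docs, tf = {}, {}
    for rec in records:
        tokens = token_surfaces(rec.title) + token_surfaces(rec.abstract)
        for t in tokens:
            tf[t] = tf.get(t, 0) + 1
        for t in set(tokens):
            docs[t] = docs.get(t, 0) + 1
    return docs, tf


def test_freetext_table_matches_naive_recount_and_formula(mesh_dict, seeded_rng, tiny_population):
    """Oracle equivalence on random fixture sets: documents, %, term
    frequency from a naive scan; z from the closed form to 1e-12."""
    from searchminer.population import lookup_p0

    for _ in range(25):
        records, truth = generate_records(random_fixture_spec(seeded_rng))
        n = len(records.records)
        table = freetext_table(records, tiny_population)
        docs, tf = _naive_freetext_counts(records)
        assert {r.term for r in table} == set(docs)
        for r in table:
            assert r.documents == docs[r.term] == truth.doc_freq.get(r.term, docs[r.term])
            assert r.term_frequency == tf[r.term]
            assert r.documents_pct == pytest.approx(100 * docs[r.term] / n, abs=1e-12)
            p0 = lookup_p0(tiny_population, r.term)
            if p0 is None:
                assert r.z == Z_ABSENT
            else:
                assert r.z == pytest.approx(
                    (r.documents - n * p0) / math.sqrt(n * p0 * (1 - p0)), abs=1e-12
                )


def test_every_dev_term_lands_in_exactly_one_table_family(tiny_population, mesh_dict):
    """Free-text terms come only from titles/abstracts; keyword-derived
    names only from the MeSH/qualifier/all-keywords tables."""
    records = RecordSet(
        [
            make_record(1, title="cancer screening", keywords=["Humans", "my lab keyword"]),
            make_record(2, abstract="cancer cells", keywords=["Neoplasms/therapy"]),
        ]
    )
    free = {r.term for r in freetext_table(records, tiny_population)}
    mesh_terms = {r.term for r in mesh_table(records, tiny_population, mesh_dict)}
    qual_terms = {r.term for r in qualifier_table(records, tiny_population, mesh_dict)}
    keyword_rows = {k for k, _ in all_keywords_table(records)}
    assert free == {"cancer", "screening", "cells"}
    assert mesh_terms == {"Humans", "Neoplasms"}
    assert qual_terms == {"therapy"}
    # every raw keyword string is in the all-keywords table
    assert keyword_rows == {"Humans", "my lab keyword", "Neoplasms/therapy"}
    assert free.isdisjoint(keyword_rows)
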