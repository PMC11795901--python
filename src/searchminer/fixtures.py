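"""Synthetic record sets with planted, known term statistics.

Real test sets for search-strategy development (sets of known relevant
PubMed records) cannot be bundled, so this module generates record sets
whose titles and abstracts are built from a controlled vocabulary with
per-term inclusion probabilities, and whose keywords are drawn from a pool
of descriptor/qualifier strings. Alongside the records it returns the
*realized* frequencies — an exact recount of what was actually generated,
not the expectation — so analysis tables can be asserted exactly rather
than statistically.

The generated text is a bag of vocabulary terms, not English prose: it
exercises counting, ranking and scoring, not linguistic edge cases (those
live in the tokenizer tests).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .ris import PUBMED, RecordSet, RISRecord
from .textprep import MeSHDictionary


@dataclass
class FixtureSpec:
    """Recipe for one synthetic record set.

    vocabulary
        List of ``(term, inclusion_probability, mean_repeats)`` triples:
        each record contains *term* with the given probability, and when
        present it occurs about ``mean_repeats`` times (>= 1).
    mesh_pool
        List of ``(raw_keyword, inclusion_probability)`` pairs; raw
        keywords may be descriptor/qualifier combinations like
        ``"Neoplasms/therapy"``.
    """

    n_records: int
    vocabulary: list[tuple[str, float, float]]
    mesh_pool: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for term, p, mean in self.vocabulary:
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {term!r} outside [0, 1]")
            if mean < 1:
                raise ValueError(f"mean_repeats for {term!r} must be >= 1")
        for kw, p in self.mesh_pool:
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {kw!r} outside [0, 1]")


@dataclass
class FixtureTruth:
    """Realized (recounted-from-output) frequencies of a generated set."""

    doc_freq: dict[str, int]
    term_freq: dict[str, int]
    keyword_counts: dict[str, int]


def _repeats(rng: random.Random, mean: float) -> int:
    base = int(mean)
    frac = mean - base
    return max(1, base + (1 if rng.random() < frac else 0))


def generate_records(spec: FixtureSpec) -> tuple[RecordSet, FixtureTruth]:
    """Generate a record set and its realized frequency truth.

    Deterministic per ``spec.seed``: the same spec always yields the same
    records and the same truth.
    """
    rng = random.Random(spec.seed)
    records: list[RISRecord] = []
    doc_freq: dict[str, int] = {}
    term_freq: dict[str, int] = {}
    keyword_counts: dict[str, int] = {}
    for i in range(spec.n_records):
        words: list[str] = []
        present: list[str] = []
        for term, p, mean in spec.vocabulary:
            if rng.random() < p:
                reps = _repeats(rng, mean)
                words.extend([term] * reps)
                present.append(term)
                term_freq[term] = term_freq.get(term, 0) + reps
        for term in present:
            doc_freq[term] = doc_freq.get(term, 0) + 1
        rng.shuffle(words)
        n_title = min(3, len(words))
        title = " ".join(words[:n_title])
        abstract = " ".join(words[n_title:])
        keywords = [kw for kw, p in spec.mesh_pool if rng.random() < p]
        for kw in keywords:
            keyword_counts[kw] = keyword_counts.get(kw, 0) + 1
        records.append(
            RISRecord(
                record_id=str(100001 + i),
                ref_type="JOUR",
                authors=[f"Author {i + 1}"],
                title=title,
                abstract=abstract,
                year="2022",
                keywords=keywords,
            )
        )
    return (
        RecordSet(records, source_dialect=PUBMED),
        FixtureTruth(doc_freq=doc_freq, term_freq=term_freq, keyword_counts=keyword_counts),
    )


#: a small vocabulary of plausible biomedical title/abstract words used by
#: the random-spec helper below
_BASE_TERMS = [
    "cancer", "tumour", "therapy", "screening", "cells", "risk",
    "patients", "survival", "breast", "lung", "treatment", "clinical",
    "trial", "cohort", "outcome", "biomarker", "diagnosis", "gene",
    "expression", "mutation",
]

_MESH_POOL = [
    ("Neoplasms/diagnosis", 0.3),
    ("Neoplasms/therapy", 0.3),
    ("*Neoplasms/genetics", 0.1),
    ("Humans", 0.8),
    ("Female", 0.4),
    ("Early Detection of Cancer", 0.2),
    ("my lab keyword", 0.15),
]


def random_fixture_spec(
    rng: random.Random, n_records: int | None = None
) -> FixtureSpec:
    """Draw a random but valid :class:`FixtureSpec` for property tests."""
    n = n_records if n_records is not None else rng.randint(3, 30)
    n_terms = rng.randint(3, len(_BASE_TERMS))
    vocab = [
        (t, round(rng.uniform(0.05, 1.0), 3), round(rng.uniform(1.0, 3.0), 2))
        for t in rng.sample(_BASE_TERMS, n_terms)
    ]
    return FixtureSpec(
        n_records=n,
        vocabulary=vocab,
        mesh_pool=_MESH_POOL,
        seed=rng.randrange(2**31),
    )


_FIXTURE_DESCRIPTORS = [
    "Neoplasms",
    "Breast Neoplasms",
    "Lung Neoplasms",
    "Humans",
    "Female",
    "Male",
    "Adult",
    "Aged",
    "Middle Aged",
    "Child",
    "Animals",
    "Mice",
    "Early Detection of Cancer",
    "Mass Screening",
    "Risk Factors",
    "Survival Analysis",
    "Prognosis",
    "Biomarkers",
    "Gene Expression",
    "Mutation",
    "Cohort Studies",
    "Clinical Trials as Topic",
    "Decision Making",
    "Decision Making, Shared",
    "Systematic Reviews as Topic",
    "Information Storage and Retrieval",
    "Data Mining",
    "Quality of Life",
    "Treatment Outcome",
    "Antineoplastic Agents",
]

_FIXTURE_QUALIFIERS = [
    "diagnosis",
    "therapy",
    "genetics",
    "epidemiology",
    "etiology",
    "drug therapy",
    "surgery",
    "prevention & control",
    "mortality",
    "adverse effects",
]


def mini_mesh_dictionary() -> MeSHDictionary:
    """A miniature MeSH dictionary for tests and examples.

    Covers the descriptor/qualifier strings the synthetic keyword pool
    uses, including "Neoplasms", "Humans", "diagnosis" and "therapy".
    """
    return MeSHDictionary(
        descriptors=_FIXTURE_DESCRIPTORS,
        qualifiers=_FIXTURE_QUALIFIERS,
        version_label="mini-fixture",
    )
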