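"""Frequency tables and binomial z-scores for candidate search terms.

The overrepresentation statistic is the one-sample proportion z-score
without continuity correction,

    z = (x - n * p0) / sqrt(n * p0 * (1 - p0)),

where x is the number of development-set records containing the term, n the
development-set size, and p0 the term's document probability in the
population set. Terms absent from the population set receive the sentinel
z = 10,000 — they are maximally overrepresented by construction. Terms at
or above the cut-off (default z >= 20, an empirically established
threshold) are flagged as candidate search terms.

Four tables are produced: free-text terms from titles and abstracts, MeSH
descriptors, MeSH qualifiers (subheadings), and a z-score-free table of all
raw keyword strings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import DataError
from .population import FREETEXT, MESH, QUALIFIER, PopulationModel, lookup_p0
from .ris import RecordSet
from .textprep import MeSHDictionary, parse_keyword, token_surfaces

logger = logging.getLogger(__name__)

#: z assigned to terms absent from the population set
Z_ABSENT = 10000.0
#: z assigned when p0 == 1 but the term misses some dev records
Z_NEG_CLAMP = -10000.0


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis.

    z_cutoff
        Candidate-term threshold on the z-score (default 20).
    rare_min_documents / rare_min_pct
        The rare-term view filter hides terms appearing in fewer than
        ``rare_min_documents`` records or in less than ``rare_min_pct``
        percent of records (defaults: 2 and 10, i.e. hide terms in only one
        record or under 10% of the set).
    kwic_window
        Words of context on each side of a keyword-in-context hit.
    max_skip
        Largest number of intervening words counted in the skip-gram table.
    """

    z_cutoff: float = 20.0
    rare_min_documents: int = 2
    rare_min_pct: float = 10.0
    kwic_window: int = 2
    max_skip: int = 2

    def __post_init__(self):
        if self.z_cutoff < 0 or self.rare_min_documents < 0 or self.rare_min_pct < 0:
            raise ValueError("thresholds must be >= 0")
        if self.kwic_window < 1:
            raise ValueError("kwic_window must be >= 1")
        if self.max_skip < 0:
            raise ValueError("max_skip must be >= 0")


@dataclass
class TermStats:
    """One row of a frequency table."""

    term: str
    documents: int
    documents_pct: float
    z: float
    term_frequency: int | None = None
    is_candidate: bool = False


def z_score(x: int, n: int, p0: float) -> float:
    """Normal-approximation binomial z for x successes in n trials at p0."""
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"need 0 <= x <= n and n >= 1, got x={x}, n={n}")
    return (x - n * p0) / math.sqrt(n * p0 * (1 - p0))


def _z_for(x: int, n: int, p0: float | None) -> float:
    if p0 is None:
        return Z_ABSENT
    if p0 >= 1.0:
        # term present in every population record: overrepresentation is
        # impossible; undefined variance needs a deterministic rule
        return 0.0 if x == n else Z_NEG_CLAMP
    return z_score(x, n, p0)


def _sorted_rows(rows: list[TermStats]) -> list[TermStats]:
    # z descending, alphabetical tie-break for determinism
    return sorted(rows, key=lambda r: (-r.z, r.term))


def _make_row(
    term: str, x: int, n: int, p0: float | None, tf: int | None, cfg: AnalysisConfig
) -> TermStats:
    z = _z_for(x, n, p0)
    return TermStats(
        term=term,
        documents=x,
        documents_pct=100.0 * x / n,
        z=z,
        term_frequency=tf,
        is_candidate=z >= cfg.z_cutoff,
    )


def freetext_table(
    dev: RecordSet, pop: PopulationModel, cfg: AnalysisConfig | None = None
) -> list[TermStats]:
    """Frequency and z-score table for every unique title/abstract term.

    All identified terms are kept — rare-term hiding is a separate view
    filter (:func:`filter_rare`), never applied here.
    """
    cfg = cfg or AnalysisConfig()
    if not dev.records:
        raise DataError("development set is empty")
    n = len(dev.records)
    docs: dict[str, int] = {}
    tf: dict[str, int] = {}
    any_text = False
    for rec in dev:
        tokens = token_surfaces(rec.title) + token_surfaces(rec.abstract)
        if tokens:
            any_text = True
        for t in tokens:
            tf[t] = tf.get(t, 0) + 1
        for t in set(tokens):
            docs[t] = docs.get(t, 0) + 1
    if not any_text:
        logger.warning("every record has empty title and abstract; empty table")
        return []
    rows = [
        _make_row(t, x, n, lookup_p0(pop, t, FREETEXT), tf[t], cfg)
        for t, x in docs.items()
    ]
    return _sorted_rows(rows)


def _keyword_tables_input(dev: RecordSet, dictionary: MeSHDictionary):
    """Per-record parsed keyword entries, skipping malformed strings."""
    for rec in dev:
        entries = []
        for raw in rec.keywords:
            try:
                entries.append(parse_keyword(raw))
            except DataError:
                logger.warning(
                    "record %s: skipping malformed keyword %r", rec.record_id, raw
                )
        yield rec, entries


def mesh_table(
    dev: RecordSet,
    pop: PopulationModel,
    dictionary: MeSHDictionary,
    cfg: AnalysisConfig | None = None,
) -> list[TermStats]:
    """Frequency/z table of MeSH descriptors found in the dictionary.

    Descriptors occur at most once per record, so the term-frequency column
    is omitted (it would duplicate the document count).
    """
    cfg = cfg or AnalysisConfig()
    if not dev.records:
        raise DataError("development set is empty")
    n = len(dev.records)
    docs: dict[str, int] = {}
    for _rec, entries in _keyword_tables_input(dev, dictionary):
        names = {
            dictionary.canonical_descriptor(e.descriptor)
            for e in entries
            if dictionary.is_descriptor(e.descriptor)
        }
        for name in names:
            docs[name] = docs.get(name, 0) + 1
    if docs and not pop.mesh_doc_freq:
        logger.warning(
            "population model has no MeSH section: every descriptor "
            "receives the z=10000 sentinel"
        )
    rows = [
        _make_row(t, x, n, lookup_p0(pop, t, MESH), None, cfg)
        for t, x in docs.items()
    ]
    return _sorted_rows(rows)


def qualifier_table(
    dev: RecordSet,
    pop: PopulationModel,
    dictionary: MeSHDictionary,
    cfg: AnalysisConfig | None = None,
) -> list[TermStats]:
    """Frequency/z table of MeSH qualifiers (subheadings).

    Unlike descriptors, a qualifier may occur several times in one record
    (attached to different descriptors), so term frequency is reported.
    """
    cfg = cfg or AnalysisConfig()
    if not dev.records:
        raise DataError("development set is empty")
    n = len(dev.records)
    docs: dict[str, int] = {}
    tf: dict[str, int] = {}
    for _rec, entries in _keyword_tables_input(dev, dictionary):
        names = [
            dictionary.canonical_qualifier(e.qualifier)
            for e in entries
            if e.qualifier is not None and dictionary.is_qualifier(e.qualifier)
        ]
        for name in names:
            tf[name] = tf.get(name, 0) + 1
        for name in set(names):
            docs[name] = docs.get(name, 0) + 1
    if docs and not pop.qualifier_doc_freq:
        logger.warning(
            "population model has no qualifier section: every qualifier "
            "receives the z=10000 sentinel"
        )
    rows = [
        _make_row(t, x, n, lookup_p0(pop, t, QUALIFIER), tf[t], cfg)
        for t, x in docs.items()
    ]
    return _sorted_rows(rows)


def all_keywords_table(dev: RecordSet) -> list[tuple[str, int]]:
    """Verbatim keyword strings with absolute frequencies, no z-scores.

    Descriptor/qualifier combinations stay distinct ("Neoplasms/diagnosis"
    and "Neoplasms/therapy" are two rows). Sorted by frequency descending,
    ties alphabetical.
    """
    if not dev.records:
        raise DataError("development set is empty")
    counts: dict[str, int] = {}
    for rec in dev:
        for raw in rec.keywords:
            counts[raw] = counts.get(raw, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def filter_rare(
    rows: list[TermStats], n: int, cfg: AnalysisConfig | None = None
) -> list[TermStats]:
    """View filter hiding rare terms.

    A row is hidden when it appears in fewer than ``cfg.rare_min_documents``
    records OR in less than ``cfg.rare_min_pct`` percent of the *n* records
    behind the table.
    """
    cfg = cfg or AnalysisConfig()
    return [
        r
        for r in rows
        if r.documents >= cfg.rare_min_documents
        and r.documents_pct >= cfg.rare_min_pct
    ]


def relative_recall(row: TermStats) -> float:
    """Share of the record set a single term retrieves, in percent."""
    return row.documents_pct
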