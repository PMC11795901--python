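"""Keyword-in-context concordance and the 2-word skip-gram table.

KWIC shows every occurrence of a user query (which may be multi-word or
hyphenated — queries are tokenized with the same rules as the records, so
"decision-making" matches "decision making") together with a window of
preceding and succeeding words.

The skip-gram table counts every ordered token pair whose members are
separated by at most ``max_skip`` intervening words, per field (pairs never
span the title/abstract boundary), reporting both per-skip-distance and
total frequencies. It surfaces word combinations worth searching with
proximity operators: "shared making" is a skip-1 gram of
"shared decision making".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .ris import RecordSet, RISRecord
from .textprep import ABSTRACT, TITLE, token_surfaces

NO_TITLE = "NO_TITLE"
NO_ABSTRACT = "NO_ABSTRACT"


@dataclass
class KWICHit:
    """One occurrence of the query with its surrounding word window."""

    record_id: str
    field: str
    left: list[str]
    match: list[str]
    right: list[str]

    def render(self) -> str:
        return " ".join(
            [*self.left, "[" + " ".join(self.match) + "]", *self.right]
        )


@dataclass
class KWICResult:
    """All hits plus summary counts for one query."""

    query_tokens: list[str]
    window: int
    hits: list[KWICHit]

    @property
    def total_occurrences(self) -> int:
        return len(self.hits)

    @property
    def matching_records(self) -> int:
        return len({h.record_id for h in self.hits})


def display_field(record: RISRecord, which: str) -> str:
    """Title or abstract text with the blank-field placeholder applied."""
    if which == TITLE:
        return record.title if record.title.strip() else NO_TITLE
    if which == ABSTRACT:
        return record.abstract if record.abstract.strip() else NO_ABSTRACT
    raise ValueError(f"unknown field {which!r}")


def kwic(records: RecordSet, query: str, window: int = 2) -> KWICResult:
    """Find every contiguous occurrence of *query* in titles and abstracts.

    The query is tokenized exactly like record text; a window of at most
    *window* tokens is attached on each side (shorter at field boundaries).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = token_surfaces(query)
    if not q:
        raise DataError(f"query {query!r} has no searchable tokens")
    m = len(q)
    hits: list[KWICHit] = []
    for rec in records:
        for fieldname, text in ((TITLE, rec.title), (ABSTRACT, rec.abstract)):
            tokens = token_surfaces(text)
            for i in range(len(tokens) - m + 1):
                if tokens[i : i + m] == q:
                    hits.append(
                        KWICHit(
                            record_id=rec.record_id,
                            field=fieldname,
                            left=tokens[max(0, i - window) : i],
                            match=tokens[i : i + m],
                            right=tokens[i + m : i + m + window],
                        )
                    )
    return KWICResult(query_tokens=q, window=window, hits=hits)


@dataclass
class SkipGramStat:
    """An ordered word pair with per-skip-distance and total counts."""

    first: str
    second: str
    counts_by_skip: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts_by_skip.values())


def skipgram_table(records: RecordSet, max_skip: int = 2) -> list[SkipGramStat]:
    """Count all ordered 2-word combinations up to *max_skip* skipped words.

    Within each field of each record, the token pair at positions (i, j)
    contributes one occurrence at skip distance k = j - i - 1 whenever
    k <= max_skip. Sorted by total frequency descending, ties alphabetical
    by (first, second).
    """
    if max_skip < 0:
        raise ValueError("max_skip must be >= 0")
    counts: dict[tuple[str, str], dict[int, int]] = {}
    for rec in records:
        for text in (rec.title, rec.abstract):
            tokens = token_surfaces(text)
            for i in range(len(tokens)):
                for j in range(i + 1, min(i + 2 + max_skip, len(tokens))):
                    pair = (tokens[i], tokens[j])
                    by_skip = counts.setdefault(pair, {})
                    k = j - i - 1
                    by_skip[k] = by_skip.get(k, 0) + 1
    stats = [
        SkipGramStat(first=f, second=s, counts_by_skip=dict(sorted(c.items())))
        for (f, s), c in counts.items()
    ]
    return sorted(stats, key=lambda g: (-g.total, g.first, g.second))
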