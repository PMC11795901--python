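"""Reading and writing bibliographic record sets in RIS format.

Two dialects are supported: the RIS-like export produced by PubMed
(AU/TI/AB/PY tags plus AN accession numbers) and the standard EndNote RIS
export (A1/T1/N1/Y1). Only the tags the downstream analysis uses are
retained; everything else in the file is ignored silently.

Retained tags: TY (reference type), AN (accession number / PMID),
AU or A1 (author), TI or T1 (title), AB or N1 (abstract),
PY or Y1 (publication year), KW or DE (keywords incl. MeSH strings),
ER (end of reference).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import DataError, RISParseError

logger = logging.getLogger(__name__)

#: tag -> canonical field name
_TAG_FIELDS = {
    "TY": "ref_type",
    "AN": "record_id",
    "AU": "author",
    "A1": "author",
    "TI": "title",
    "T1": "title",
    "AB": "abstract",
    "N1": "abstract_n1",
    "PY": "year",
    "Y1": "year",
    "KW": "keyword",
    "DE": "keyword",
}

_TAG_LINE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")
# something that looks like it was meant to be a tag but lacks the
# mandatory "<TAG>  - " separator
_BROKEN_TAG = re.compile(r"^[A-Z][A-Z0-9]\s{0,1}-")

_YEAR_RUN = re.compile(r"\d{4}")

PUBMED = "pubmed"
ENDNOTE = "endnote"
AUTO = "auto"


@dataclass
class RISRecord:
    """One bibliographic record with exactly the fields the analysis uses."""

    record_id: str
    ref_type: str = ""
    authors: list[str] = field(default_factory=list)
    title: str = ""
    abstract: str = ""
    year: str = ""
    keywords: list[str] = field(default_factory=list)


@dataclass
class RecordSet:
    """An ordered set of records plus the dialect they were read from."""

    records: list[RISRecord]
    source_dialect: str = PUBMED

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _finish_block(raw_tags: dict[str, list[str]], index: int) -> RISRecord:
    """Assemble an ``RISRecord`` from the tag->values map of one ER block."""
    record_id = ""
    if raw_tags.get("record_id"):
        record_id = raw_tags["record_id"][0].strip()
    if not record_id:
        record_id = f"REC{index}"
        logger.warning("record %d has no AN tag; synthesized id %r", index, record_id)

    abstract = ""
    if raw_tags.get("abstract"):
        abstract = raw_tags["abstract"][0]
        if raw_tags.get("abstract_n1"):
            logger.warning(
                "record %s has both AB and N1; AB wins, N1 ignored", record_id
            )
    elif raw_tags.get("abstract_n1"):
        abstract = raw_tags["abstract_n1"][0]

    year = ""
    if raw_tags.get("year"):
        m = _YEAR_RUN.search(raw_tags["year"][0])
        if m:
            year = m.group(0)

    return RISRecord(
        record_id=record_id,
        ref_type=(raw_tags.get("ref_type") or [""])[0],
        authors=list(raw_tags.get("author", [])),
        title=(raw_tags.get("title") or [""])[0],
        abstract=abstract,
        year=year,
        keywords=list(raw_tags.get("keyword", [])),
    )


def _detect_dialect(tag_counts: dict[str, int]) -> str:
    endnote_score = sum(tag_counts.get(t, 0) for t in ("A1", "T1", "N1", "Y1"))
    pubmed_score = sum(tag_counts.get(t, 0) for t in ("AU", "TI", "AB", "PY", "AN"))
    if endnote_score > 0 and pubmed_score == 0:
        return ENDNOTE
    if pubmed_score > 0 and endnote_score == 0:
        return PUBMED
    if endnote_score > pubmed_score:
        return ENDNOTE
    if pubmed_score == endnote_score:
        logger.warning("ambiguous RIS dialect; defaulting to pubmed")
    return PUBMED


def parse_ris(stream: str, dialect: str = AUTO) -> RecordSet:
    """Parse RIS text into a :class:`RecordSet`.

    Parameters
    ----------
    stream
        Full file contents as UTF-8 text. CRLF and LF line endings are both
        accepted.
    dialect
        ``"pubmed"``, ``"endnote"``, or ``"auto"`` to infer the dialect from
        which author/title/abstract/year tags the file uses.

    Raises
    ------
    RISParseError
        On a malformed tag line (named with its line number) or when the
        stream contains no records.
    DataError
        When two records share the same AN accession number.
    """
    if dialect not in (PUBMED, ENDNOTE, AUTO):
        raise ValueError(f"unknown dialect {dialect!r}")

    records: list[RISRecord] = []
    raw_tags: dict[str, list[str]] = {}
    current_field: str | None = None
    in_block = False
    tag_counts: dict[str, int] = {}

    for line_no, line in enumerate(stream.split("\n"), start=1):
        line = line.rstrip("\r")
        m = _TAG_LINE.match(line)
        if m:
            tag, value = m.group(1), m.group(2).strip()
            tag_counts[tag] = tag_counts.get(tag, 0) + 1
            if tag == "ER":
                records.append(_finish_block(raw_tags, len(records) + 1))
                raw_tags = {}
                current_field = None
                in_block = False
                continue
            in_block = True
            fieldname = _TAG_FIELDS.get(tag)
            current_field = fieldname
            if fieldname is None:
                continue  # unknown tag: ignored, but owns continuation lines
            if fieldname in ("author", "keyword"):
                raw_tags.setdefault(fieldname, []).append(value)
            else:
                # repeated scalar tags: first occurrence wins
                raw_tags.setdefault(fieldname, [value])
            continue
        if not line.strip():
            current_field = None
            continue
        if _BROKEN_TAG.match(line):
            raise RISParseError(
                f"malformed tag line (missing '  - ' separator): {line.strip()!r}",
                line_no,
            )
        if not in_block:
            raise RISParseError(
                f"unexpected text outside a record block: {line.strip()!r}", line_no
            )
        # continuation of the previous tag, joined with a single space
        if current_field is not None and current_field in raw_tags:
            values = raw_tags[current_field]
            values[-1] = values[-1] + " " + line.strip()

    if in_block and raw_tags:
        logger.warning("trailing record block without ER tag was kept")
        records.append(_finish_block(raw_tags, len(records) + 1))

    if not records:
        raise RISParseError("empty record set")

    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise DataError(f"duplicate record id {rec.record_id!r}")
        seen.add(rec.record_id)

    if dialect == AUTO:
        dialect = _detect_dialect(tag_counts)
    return RecordSet(records=records, source_dialect=dialect)


_WRITE_TAGS = {
    PUBMED: {"author": "AU", "title": "TI", "abstract": "AB", "year": "PY"},
    ENDNOTE: {"author": "A1", "title": "T1", "abstract": "N1", "year": "Y1"},
}


def write_ris(records: RecordSet) -> str:
    """Serialize a :class:`RecordSet` back to RIS text.

    The output uses the record set's source dialect tag names, omits empty
    fields, and ends lines with LF. ``parse_ris(write_ris(s))`` reproduces
    ``s`` field-for-field on all retained tags.
    """
    if not records.records:
        raise DataError("cannot write an empty record set")
    tags = _WRITE_TAGS[records.source_dialect]
    lines: list[str] = []
    for rec in records.records:
        if rec.ref_type:
            lines.append(f"TY  - {rec.ref_type}")
        lines.append(f"AN  - {rec.record_id}")
        for author in rec.authors:
            lines.append(f"{tags['author']}  - {author}")
        if rec.title:
            lines.append(f"{tags['title']}  - {rec.title}")
        if rec.abstract:
            lines.append(f"{tags['abstract']}  - {rec.abstract}")
        if rec.year:
            lines.append(f"{tags['year']}  - {rec.year}")
        for kw in rec.keywords:
            lines.append(f"KW  - {kw}")
        lines.append("ER  - ")
        lines.append("")
    return "\n".join(lines)
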