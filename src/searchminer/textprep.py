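"""Term definition for free text and decomposition of keyword strings.

A free-text *term* is a word without hyphens, without Unicode symbol or
punctuation characters, and which is not a number. Hyphenated words are
split into their components ("self-aware" becomes "self" and "aware"),
matching how major search platforms treat hyphens. Letters from any script
(Greek, Cyrillic, ...) are kept; purely numeric pieces such as "2022" or
"3.5" are dropped, while alphanumeric identifiers like "p53" survive.

Keyword strings from the KW/DE tags are decomposed into a MeSH-style
descriptor, an optional qualifier (subheading) after the first "/", and a
major-topic flag from a leading "*".
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass

from .errors import DataError

logger = logging.getLogger(__name__)

#: hyphen/dash characters that split words: ASCII hyphen-minus, the Unicode
#: hyphen/dash block U+2010..U+2015, and the minus sign U+2212
_HYPHENS = "-‐‑‒–—―−"
_HYPHEN_SPLIT = re.compile("[" + _HYPHENS + "]")

#: a "number": optional sign, digits with optional "." or "," separators
_NUMBER = re.compile(r"[+-]?\d+(?:[.,]\d+)*")

TITLE = "title"
ABSTRACT = "abstract"


@dataclass(frozen=True)
class Token:
    """One surviving term occurrence within a title or abstract."""

    surface: str
    position: int
    field: str = TITLE


def _strip_symbols_punct(piece: str) -> str:
    return "".join(
        c for c in piece if unicodedata.category(c)[0] not in ("S", "P")
    )


def token_surfaces(text: str) -> list[str]:
    """Tokenize *text* and return just the case-folded term strings."""
    out: list[str] = []
    for chunk in text.split():
        for piece in _HYPHEN_SPLIT.split(chunk):
            if _NUMBER.fullmatch(piece):
                continue
            piece = _strip_symbols_punct(piece)
            if not piece or _NUMBER.fullmatch(piece):
                continue
            out.append(piece.casefold())
    return out


def tokenize_freetext(text: str, field: str = TITLE) -> list[Token]:
    """Split *text* into terms.

    Splits on whitespace and on hyphen/dash characters, strips all Unicode
    symbol (S*) and punctuation (P*) characters, drops purely numeric
    pieces, case-folds the survivors, and numbers them consecutively from 0.
    """
    return [
        Token(surface=s, position=i, field=field)
        for i, s in enumerate(token_surfaces(text))
    ]


@dataclass(frozen=True)
class KeywordEntry:
    """A keyword string decomposed into descriptor / qualifier / major flag.

    ``raw`` always equals the reassembly
    ``("*" if major_topic else "") + descriptor + ("/" + qualifier if any)``.
    """

    raw: str
    descriptor: str
    qualifier: str | None = None
    major_topic: bool = False


def parse_keyword(raw: str) -> KeywordEntry:
    """Decompose one keyword string.

    A leading ``*`` marks a major topic and is removed; the first ``/``
    separates descriptor from qualifier. No dictionary validation happens
    here.
    """
    raw = raw.strip()
    if not raw:
        raise DataError("malformed keyword: empty string")
    major = raw.startswith("*")
    body = raw[1:] if major else raw
    descriptor, sep, qualifier = body.partition("/")
    if not descriptor:
        raise DataError(f"malformed keyword: {raw!r}")
    return KeywordEntry(
        raw=raw,
        descriptor=descriptor,
        qualifier=qualifier if sep else None,
        major_topic=major,
    )


class MeSHDictionary:
    """Name lists of MeSH descriptors and qualifiers (subheadings).

    Lookup is case-insensitive; the canonical (dictionary) casing is kept
    for display. Loaded from two plain-text files (one name per line, ``#``
    comments allowed) or from a MeSH descriptor XML file.
    """

    def __init__(
        self,
        descriptors: set[str] | list[str],
        qualifiers: set[str] | list[str],
        version_label: str = "",
    ):
        self._descriptors = {d.casefold(): d for d in descriptors}
        self._qualifiers = {q.casefold(): q for q in qualifiers}
        self.version_label = version_label

    @property
    def descriptors(self) -> set[str]:
        return set(self._descriptors.values())

    @property
    def qualifiers(self) -> set[str]:
        return set(self._qualifiers.values())

    def is_descriptor(self, name: str) -> bool:
        return name.casefold() in self._descriptors

    def is_qualifier(self, name: str) -> bool:
        return name.casefold() in self._qualifiers

    def canonical_descriptor(self, name: str) -> str | None:
        return self._descriptors.get(name.casefold())

    def canonical_qualifier(self, name: str) -> str | None:
        return self._qualifiers.get(name.casefold())

    @staticmethod
    def _read_name_list(path) -> list[str]:
        names = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    names.append(line)
        return names

    @classmethod
    def from_text_files(
        cls, descriptor_path, qualifier_path, version_label: str = ""
    ) -> "MeSHDictionary":
        return cls(
            cls._read_name_list(descriptor_path),
            cls._read_name_list(qualifier_path),
            version_label=version_label or "text-files",
        )

    @classmethod
    def from_mesh_xml(cls, path, version_label: str = "") -> "MeSHDictionary":
        """Load DescriptorName / QualifierName elements from MeSH XML."""
        from lxml import etree

        tree = etree.parse(str(path))
        descriptors = [
            e.text.strip()
            for e in tree.iter("DescriptorName")
            for e in e.iter("String")
            if e.text
        ]
        qualifiers = [
            e.text.strip()
            for e in tree.iter("QualifierName")
            for e in e.iter("String")
            if e.text
        ]
        return cls(descriptors, qualifiers, version_label or "mesh-xml")


MESH_DESCRIPTOR = "mesh_descriptor"
MESH_QUALIFIER_BEARING = "mesh_qualifier_bearing"
NON_MESH = "non_mesh"


def classify_keyword(entry: KeywordEntry, dictionary: MeSHDictionary) -> set[str]:
    """Classify one keyword entry against the dictionary.

    Returns a set of labels: ``mesh_descriptor`` when the descriptor is a
    dictionary name, plus ``mesh_qualifier_bearing`` when the entry's
    qualifier is a dictionary qualifier name (counted independently of
    descriptor validity), or ``{"non_mesh"}`` when neither holds. Non-MeSH
    keywords appear only in the all-keywords table.
    """
    labels: set[str] = set()
    if dictionary.is_descriptor(entry.descriptor):
        labels.add(MESH_DESCRIPTOR)
    if entry.qualifier is not None and dictionary.is_qualifier(entry.qualifier):
        labels.add(MESH_QUALIFIER_BEARING)
    if not labels:
        labels.add(NON_MESH)
    return labels
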