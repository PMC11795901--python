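"""The population model: the binomial null for term overrepresentation.

A population model holds the number of background documents (e.g. a random
sample of PubMed records) and, for each term, the number of those documents
that contain it at least once — a *document* frequency, not an occurrence
count, because the z-score models per-document sampling. Free-text terms,
MeSH descriptors and qualifiers are tracked in three separate maps so each
analysis table can query a matched null.

Models persist as a diff-able three-section UTF-8 TSV::

    #searchminer-population v1
    #label <provenance>
    #n_pop <count>
    #section freetext
    term<TAB>count
    ...
    #section mesh
    ...
    #section qualifier
    ...
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import DataError
from .ris import RecordSet
from .textprep import MeSHDictionary, parse_keyword, token_surfaces

logger = logging.getLogger(__name__)

FORMAT_MARKER = "#searchminer-population v1"

FREETEXT = "freetext"
MESH = "mesh"
QUALIFIER = "qualifier"

_SECTIONS = (FREETEXT, MESH, QUALIFIER)


@dataclass
class PopulationModel:
    """Document-frequency background counts for the binomial null.

    All map keys are case-folded; counts satisfy ``1 <= c <= n_pop`` and
    zero-count terms are simply absent.
    """

    n_pop: int
    doc_freq: dict[str, int] = field(default_factory=dict)
    mesh_doc_freq: dict[str, int] = field(default_factory=dict)
    qualifier_doc_freq: dict[str, int] = field(default_factory=dict)
    label: str = ""

    def _map_for(self, vocabulary: str) -> dict[str, int]:
        if vocabulary == FREETEXT:
            return self.doc_freq
        if vocabulary == MESH:
            return self.mesh_doc_freq
        if vocabulary == QUALIFIER:
            return self.qualifier_doc_freq
        raise ValueError(f"unknown vocabulary {vocabulary!r}")

    def validate(self) -> None:
        if self.n_pop <= 0:
            raise DataError("population model requires n_pop > 0")
        for section in _SECTIONS:
            for term, count in self._map_for(section).items():
                if not 1 <= count <= self.n_pop:
                    raise DataError(
                        f"population count out of range for {term!r} "
                        f"({section}): {count} not in [1, {self.n_pop}]"
                    )


def build_population_model(
    records: RecordSet,
    dictionary: MeSHDictionary | None = None,
    label: str = "",
) -> PopulationModel:
    """Count per-record term presence over a background record set.

    For each record, every distinct token in its title + abstract adds one
    to that term's document frequency; analogously each distinct descriptor
    and qualifier parsed from the record's keywords. Tokenization is
    identical to the analysis-side tokenizer, so test-set terms look up the
    right null.
    """
    if not records.records:
        raise DataError("cannot build a population model from an empty record set")
    doc_freq: dict[str, int] = {}
    mesh: dict[str, int] = {}
    qual: dict[str, int] = {}
    for rec in records:
        terms = set(token_surfaces(rec.title)) | set(token_surfaces(rec.abstract))
        for t in terms:
            doc_freq[t] = doc_freq.get(t, 0) + 1
        descriptors: set[str] = set()
        qualifiers: set[str] = set()
        for raw in rec.keywords:
            try:
                entry = parse_keyword(raw)
            except DataError:
                logger.warning(
                    "record %s: skipping malformed keyword %r", rec.record_id, raw
                )
                continue
            descriptors.add(entry.descriptor.casefold())
            if entry.qualifier is not None:
                qualifiers.add(entry.qualifier.casefold())
        for d in descriptors:
            mesh[d] = mesh.get(d, 0) + 1
        for q in qualifiers:
            qual[q] = qual.get(q, 0) + 1
    return PopulationModel(
        n_pop=len(records.records),
        doc_freq=doc_freq,
        mesh_doc_freq=mesh,
        qualifier_doc_freq=qual,
        label=label,
    )


def lookup_p0(model: PopulationModel, term: str, vocabulary: str = FREETEXT):
    """Null probability of *term*, or ``None`` when absent from the model.

    Absence is meaningful: absent terms receive the z = 10,000 sentinel in
    the frequency tables rather than a computed score.
    """
    count = model._map_for(vocabulary).get(term.casefold())
    if count is None:
        return None
    return count / model.n_pop


def save_population_model(model: PopulationModel, path) -> None:
    """Write the model to its three-section TSV format."""
    model.validate()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(FORMAT_MARKER + "\n")
        if model.label:
            fh.write(f"#label\t{model.label}\n")
        fh.write(f"#n_pop\t{model.n_pop}\n")
        for section in _SECTIONS:
            fh.write(f"#section\t{section}\n")
            counts = model._map_for(section)
            for term in sorted(counts):
                fh.write(f"{term}\t{counts[term]}\n")


def load_population_model(path) -> PopulationModel:
    """Read a model back; lossless inverse of :func:`save_population_model`.

    A file missing a section loads with that map empty and a logged
    warning (forward compatibility); a bad version line, negative counts or
    counts exceeding ``n_pop`` are load errors.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != FORMAT_MARKER:
        raise DataError(
            f"unrecognized population model format in {path} "
            f"(expected first line {FORMAT_MARKER!r})"
        )
    n_pop: int | None = None
    label = ""
    maps: dict[str, dict[str, int]] = {s: {} for s in _SECTIONS}
    seen_sections: set[str] = set()
    current: dict[str, int] | None = None
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#label\t"):
            label = line.split("\t", 1)[1]
            continue
        if line.startswith("#n_pop\t"):
            n_pop = int(line.split("\t", 1)[1])
            continue
        if line.startswith("#section\t"):
            name = line.split("\t", 1)[1].strip()
            if name not in maps:
                raise DataError(f"unknown section {name!r} in population model")
            seen_sections.add(name)
            current = maps[name]
            continue
        if current is None:
            raise DataError(f"line {line_no}: data before any #section header")
        term, sep, count_s = line.partition("\t")
        if not sep:
            raise DataError(f"line {line_no}: expected term<TAB>count")
        try:
            count = int(count_s)
        except ValueError as exc:
            raise DataError(f"line {line_no}: bad count {count_s!r}") from exc
        current[term] = count
    if n_pop is None:
        raise DataError("population model file lacks an #n_pop line")
    for missing in set(_SECTIONS) - seen_sections:
        logger.warning(
            "population model %s lacks the %r section; using an empty map "
            "(all %s terms will receive the z=10000 sentinel)",
            path,
            missing,
            missing,
        )
    model = PopulationModel(
        n_pop=n_pop,
        doc_freq=maps[FREETEXT],
        mesh_doc_freq=maps[MESH],
        qualifier_doc_freq=maps[QUALIFIER],
        label=label,
    )
    model.validate()
    return model
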