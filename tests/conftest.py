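import random

import pytest

from searchminer import (
    AnalysisConfig,
    RecordSet,
    RISRecord,
    build_population_model,
    mini_mesh_dictionary,
)


@pytest.fixture
def mesh_dict():
    return mini_mesh_dictionary()


@pytest.fixture
def cfg():
    return AnalysisConfig()


def make_record(record_id, title="", abstract="", keywords=None, **kw):
    return RISRecord(
        record_id=str(record_id),
        ref_type="JOUR",
        title=title,
        abstract=abstract,
        keywords=list(keywords or []),
        **kw,
    )


@pytest.fixture
def tiny_population(mesh_dict):
    """100-record background: 'cancer' in 10, 'cells' in 30, 'humans' MeSH in 50."""
    records = []
    for i in range(100):
        title = []
        if i < 10:
            title.append("cancer")
        if i < 30:
            title.append("cells")
        title.append("filler")
        keywords = ["Humans"] if i < 50 else []
        records.append(make_record(i + 1, title=" ".join(title), keywords=keywords))
    return build_population_model(RecordSet(records), mesh_dict, label="tiny")


@pytest.fixture
def seeded_rng():
    return random.Random(20240611)
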