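"""Reproducible 2:1 development/validation split and OVID PMID lists.

The test set is partitioned at random into a development set (terms are
derived from it) and a validation set (used afterwards to check that the
chosen terms also retrieve the held-out records). The split is a pure
function of the ordered record ids and an integer seed, which is reported
back so the pseudo-random partition can be reproduced exactly — e.g. in a
peer-review process. The PRNG is CPython's Mersenne Twister
(``random.Random``), which the language reference guarantees to be stable
across platforms and versions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

from .errors import DataError
from .ris import RecordSet

logger = logging.getLogger(__name__)

PRNG_NAME = "python-random-mt19937"


@dataclass
class SplitResult:
    """The two subsets plus the seed that reproduces them."""

    development: RecordSet
    validation: RecordSet
    seed: int
    prng: str = PRNG_NAME


def _dev_size(n: int) -> int:
    # round-half-up(2n/3); the fractional part is always 0, 1/3 or 2/3
    return (4 * n + 3) // 6


def split_records(records: RecordSet, seed: int | None = None) -> SplitResult:
    """Split *records* 2:1 into development and validation sets.

    With no seed given, one is drawn and reported in the result (the
    "applied random seed"). The same ordered records and seed always give
    the same split. Record order within each subset follows input order.
    """
    n = len(records.records)
    if n < 3:
        raise DataError("test set too small to split (need at least 3 records)")
    if seed is None:
        seed = random.SystemRandom().randrange(2**31)
        logger.info("no seed given; applied random seed %d", seed)
    rng = random.Random(seed)
    k = _dev_size(n)
    dev_idx = set(rng.sample(range(n), k))
    dev = [rec for i, rec in enumerate(records.records) if i in dev_idx]
    val = [rec for i, rec in enumerate(records.records) if i not in dev_idx]
    return SplitResult(
        development=RecordSet(dev, records.source_dialect),
        validation=RecordSet(val, records.source_dialect),
        seed=seed,
    )


def pmids_to_ovid(records: RecordSet) -> str:
    """Render the records' PMIDs as an Ovid unique-identifier search line.

    Non-numeric record ids are skipped with a warning; the output is
    ``(id1 or id2 or ...).ui.`` in record order.
    """
    ids = []
    for rec in records:
        if rec.record_id.isdigit():
            ids.append(rec.record_id)
        else:
            logger.warning("skipping non-numeric record id %r", rec.record_id)
    if not ids:
        raise DataError("no numeric PMIDs to format for OVID")
    return "(" + " or ".join(ids) + ").ui."
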