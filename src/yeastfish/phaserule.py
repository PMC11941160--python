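"""Deterministic cell-cycle phase assignment from SPB count, budding and
DAPI morphology.

The decision list codifies the classic marker logic for fixed yeast: one
SPB in an unbudded cell with a compact nucleus is G1; a budded cell with
one SPB and a compact mother-confined nucleus is S; two SPBs occur only in
G2; a nucleus stretched through the bud neck marks early mitosis and a
divided nucleus late mitosis.  Buds mirror their mother's phase with a
"-Bud" suffix.  Anything conflicting (e.g. an unbudded cell with two SPBs)
is left unassigned rather than guessed, so downstream statistics can
exclude it.
"""

from __future__ import annotations

from typing import Sequence

from yeastfish.cellgeom import CellRecord
from yeastfish.phases import bud_label

UNASSIGNED = "unassigned"


def classify_rule(record: CellRecord, mother: CellRecord | None = None) -> str:
    """Phase label for one cell record (first matching rule wins).

    Buds require their linked ``mother`` record (already classified or
    classifiable); they mirror its phase with the ``-Bud`` suffix.
    """
    if record.is_bud:
        if mother is None or mother.cell_id != record.mother_id:
            return UNASSIGNED
        mphase = mother.phase or classify_rule(mother)
        if mphase in (UNASSIGNED, None) or mphase == "G1":
            return UNASSIGNED
        return bud_label(mphase)

    d = record.dapi
    if d.flagged:
        return UNASSIGNED
    budded = record.bud_id is not None
    compact = d.n_blobs == 1 and not d.crosses_neck
    if not budded and record.spb_count == 1 and compact:
        return "G1"
    if budded and record.spb_count == 1 and compact:
        return "S"
    if budded and record.spb_count == 2 and compact:
        return "G2"
    if budded and d.n_blobs == 1 and d.crosses_neck:
        return "Early-M"
    if budded and d.n_blobs == 2:
        return "Late-M"
    return UNASSIGNED


def classify_all(records: Sequence[CellRecord]) -> list[CellRecord]:
    """Classify mothers first, then buds (which mirror their mothers).

    Deterministic and independent of the input order.
    """
    by_id = {r.cell_id: r for r in records}
    for r in records:
        if not r.is_bud:
            r.phase = classify_rule(r)
    for r in records:
        if r.is_bud:
            r.phase = classify_rule(r, by_id.get(r.mother_id))
    return list(records)
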