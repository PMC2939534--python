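"""High-level orchestration: the align -> pair -> report flow as one call.

This is the library face of the CLI's ``search`` subcommand; examples,
tests and the acceptance script use it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pairing import (
    InsertModel,
    PairHit,
    TagReport,
    estimate_insert_model,
    group_by_fragment,
    tally,
)
from .seedalign import AlignParams, TagHit, align_library
from .seqio import PairedReadLibrary, SequenceRecord
from .tagreport import CoverageProfile, coverage


@dataclass
class SearchResult:
    """Everything one library-vs-query search produces, in memory."""

    query: SequenceRecord
    library: PairedReadLibrary
    hits: list[TagHit]
    pairhits: list[PairHit]
    profile: CoverageProfile
    report: TagReport
    insert: InsertModel


def search(
    query: SequenceRecord,
    library: PairedReadLibrary,
    params: AlignParams | None = None,
    insert: InsertModel | None = None,
    estimate_insert: bool = False,
) -> SearchResult:
    """Align a paired library to a query and assemble all derived products.

    With ``estimate_insert`` the insert model is re-estimated from
    orientation-valid both-mapped pairs (falling back to ``insert`` when
    there are too few), and placements are computed under the refined
    model.
    """
    params = params or AlignParams()
    insert = insert or InsertModel(1000, 50, 850, 1150)
    hits = align_library(library, query, params)
    pairhits = group_by_fragment(hits, library, insert)
    if estimate_insert:
        refined = estimate_insert_model(pairhits, fallback=insert)
        if refined is not insert:
            insert = refined
            pairhits = group_by_fragment(hits, library, insert)
    profile = coverage(pairhits, query.length, query_id=query.id)
    report = tally(pairhits, library.name)
    return SearchResult(
        query=query, library=library, hits=hits, pairhits=pairhits,
        profile=profile, report=report, insert=insert,
    )
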