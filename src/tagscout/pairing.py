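"""Pair geometry: fragment grouping, concordance, and mate-placement envelopes.

Illumina paired-end fragments are sequenced FR ("innie"): mate 1 reads the
forward strand from the fragment's left end, mate 2 reads the reverse
strand from its right end, and the outer fragment length (5' end to 5'
end, inclusive of both reads) is approximately known.  That geometry is
what lets a fragment with only one mate matching the query place its
partner: the unmapped mate must sit within a bounded interval — the
*placement envelope* — on one side of the anchor, on the opposite strand.
Envelopes may extend beyond the query (negative coordinates, or past its
end); such off-query placements are exactly the promoter/flank-capture use
case, so they are first-class and reported on a signed extended axis.

All geometry uses each mate's *projected* full-read interval (the
alignment extended to the read's ends along its diagonal), so partially
aligned cross-species tags are placed correctly.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .errors import ValidationError
from .seedalign import TagHit, _hit_sort_key
from .seqio import PairedReadLibrary, ReadKey

logger = logging.getLogger(__name__)

BOTH_CONCORDANT = "both_concordant"
BOTH_DISCORDANT = "both_discordant"
SINGLE_END = "single_end"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class InsertModel:
    """Outer fragment-length model for an FR paired library.

    ``L_min``/``L_max`` are hard inclusive bounds on the outer fragment
    length (5' end of mate 1 to 5' end of mate 2, both reads included).
    """

    mean: float
    sd: float
    L_min: int
    L_max: int
    orientation: str = "FR"

    def __post_init__(self) -> None:
        if not (0 < self.L_min <= self.mean <= self.L_max):
            raise ValidationError(
                f"insert model requires 0 < L_min <= mean <= L_max, got "
                f"L_min={self.L_min}, mean={self.mean}, L_max={self.L_max}"
            )
        if self.sd < 0:
            raise ValidationError("insert sd must be >= 0")
        if self.orientation != "FR":
            raise ValidationError("only FR (forward-reverse) orientation is supported")


@dataclass(frozen=True)
class MatePlacement:
    """Envelope of feasible positions for an unmapped mate.

    Coordinates are 0-based half-open on the extended query axis; they may
    be negative or exceed the query length (off-query flanks).  The
    envelope is the union of all feasible mate intervals, so its width is
    always (L_max - L_min) + mate read length.
    """

    envelope_start: int
    envelope_end: int
    strand: str
    anchor: ReadKey


@dataclass(frozen=True)
class PairHit:
    """Per-fragment unit: best hit per mate, concordance class, placement."""

    fragment_id: str
    hit1: TagHit | None
    hit2: TagHit | None
    category: str
    placement: MatePlacement | None = None


@dataclass(frozen=True)
class TagReport:
    """Library-level tally: fragments with both mates hit vs exactly one.

    The two counts are disjoint by construction; ``n_total_hits`` is
    2*n_read_pairs + n_single_reads.
    """

    library_name: str
    n_read_pairs: int
    n_single_reads: int

    @property
    def n_total_hits(self) -> int:
        return 2 * self.n_read_pairs + self.n_single_reads


def implied_fragment_length(hit1: TagHit, hit2: TagHit) -> int | None:
    """Outer fragment length implied by two mapped mates, or None if the
    orientation is invalid (same strand, or minus mate left of plus mate)."""
    if hit1.strand == hit2.strand:
        return None
    plus, minus = (hit1, hit2) if hit1.strand == "+" else (hit2, hit1)
    ps, pe = plus.projected_interval()
    ms, me = minus.projected_interval()
    if ps > ms:  # plus-strand mate must lie left of the minus-strand mate
        return None
    return me - ps


def classify(hit1: TagHit, hit2: TagHit, model: InsertModel) -> str:
    """Concordance of a both-mapped pair under the insert model."""
    L = implied_fragment_length(hit1, hit2)
    if L is None:
        return BOTH_DISCORDANT
    return BOTH_CONCORDANT if model.L_min <= L <= model.L_max else BOTH_DISCORDANT


def infer_mate_envelope(hit: TagHit, mate_read_len: int, model: InsertModel) -> MatePlacement:
    """Placement envelope for the unmapped partner of a single-end hit.

    A '+' anchor puts the missing mate on '-' to its right; a '-' anchor
    puts it on '+' to its left.  Bounds follow from the hard fragment
    length window [L_min, L_max].
    """
    s, e = hit.projected_interval()
    r = mate_read_len
    if hit.strand == "+":
        return MatePlacement(
            envelope_start=s + model.L_min - r,
            envelope_end=s + model.L_max,
            strand="-",
            anchor=hit.read_key,
        )
    return MatePlacement(
        envelope_start=e - model.L_max,
        envelope_end=e - model.L_min + r,
        strand="+",
        anchor=hit.read_key,
    )


def group_by_fragment(
    hits: list[TagHit],
    library: PairedReadLibrary,
    model: InsertModel,
    include_unmapped: bool = False,
) -> list[PairHit]:
    """Group per-read hits into per-fragment PairHits.

    Per mate the best hit (score desc, q_start asc, '+' first) is kept.
    Fragments with no hit at all are omitted unless ``include_unmapped``.
    Output is ordered by fragment id for determinism.
    """
    by_mate: dict[str, dict[int, TagHit]] = {}
    for hit in hits:
        if hit.read_key.fragment_id not in library.fragments:
            raise ValidationError(f"hit references unknown read {hit.read_key}")
        slot = by_mate.setdefault(hit.read_key.fragment_id, {})
        prev = slot.get(hit.read_key.mate_index)
        if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
            slot[hit.read_key.mate_index] = hit

    out: list[PairHit] = []
    frag_ids = sorted(by_mate) if not include_unmapped else sorted(library.fragments)
    for frag_id in frag_ids:
        slot = by_mate.get(frag_id, {})
        h1, h2 = slot.get(1), slot.get(2)
        if h1 and h2:
            out.append(PairHit(frag_id, h1, h2, classify(h1, h2, model)))
        elif h1 or h2:
            anchor = h1 or h2
            mate_idx = 2 if h1 else 1
            mate_len = library.read_length(ReadKey(frag_id, mate_idx))
            placement = infer_mate_envelope(anchor, mate_len, model)
            out.append(PairHit(frag_id, h1, h2, SINGLE_END, placement))
        else:
            out.append(PairHit(frag_id, None, None, UNMAPPED))
    return out


def estimate_insert_model(pairhits: list[PairHit], fallback: InsertModel) -> InsertModel:
    """Robust insert-model estimate from orientation-valid both-mapped pairs.

    Median / scaled MAD over implied fragment lengths; bounds at mean +/- 3 sd,
    floored at twice the read length.  Falls back (with a logged reason)
    below 30 usable pairs.
    """
    lengths: list[int] = []
    max_read_len = 0
    for ph in pairhits:
        if ph.hit1 is None or ph.hit2 is None:
            continue
        L = implied_fragment_length(ph.hit1, ph.hit2)
        if L is None:
            continue
        lengths.append(L)
        max_read_len = max(max_read_len, ph.hit1.read_len, ph.hit2.read_len)
    if len(lengths) < 30:
        logger.info(
            "insert estimation: only %d orientation-valid pairs (< 30); using fallback model",
            len(lengths),
        )
        return fallback
    med = statistics.median(lengths)
    mad = statistics.median(abs(x - med) for x in lengths)
    sd = 1.4826 * mad
    floor = 2 * max_read_len
    L_min = max(int(round(med - 3 * sd)), floor)
    L_max = max(int(round(med + 3 * sd)), L_min)
    mean = min(max(med, L_min), L_max)
    return InsertModel(mean=mean, sd=sd, L_min=L_min, L_max=L_max)


def tally(pairhits: list[PairHit], library_name: str) -> TagReport:
    """Table-style tally: both-mapped fragments vs exactly-one-mapped."""
    n_pairs = sum(1 for p in pairhits if p.category in (BOTH_CONCORDANT, BOTH_DISCORDANT))
    n_single = sum(1 for p in pairhits if p.category == SINGLE_END)
    return TagReport(library_name=library_name, n_read_pairs=n_pairs, n_single_reads=n_single)
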