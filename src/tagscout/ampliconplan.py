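"""Selection of tags flanking a target region and their pairing into PCR
amplicon plans.

A tag can serve as a primer-design substrate in two ways: a *direct hit*
(the read itself aligned to the query) or an *extrapolated* tag (the read
did not align, but its mate did, so pair geometry confines it to a
placement envelope — possibly upstream of the query, which is how
promoters are reached).  Forward plans need a plus-strand tag on the left
and a minus-strand tag on the right; the expected product size is measured
5' end to 5' end (the outer product, the convention PCR product sizes are
reported in).  Envelope uncertainty propagates into a product size range:
a direct hit contributes a point, each extrapolated endpoint widens the
range by exactly its envelope width.

Tags are offered as sequences with GC/Tm metrics, not as optimized
primers; primer refinement is left to the bench.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import TilingError, ValidationError
from .pairing import SINGLE_END, PairHit
from .seqio import PairedReadLibrary, ReadKey, reverse_complement

DIRECT_HIT = "direct_hit"
EXTRAPOLATED = "extrapolated"


@dataclass(frozen=True)
class TagCandidate:
    """A tag usable for primer design near a target window.

    ``position`` is the hit interval (direct) or the placement envelope
    (extrapolated) on the extended query axis.  ``sequence`` is the tag's
    residues oriented 5'->3' on the forward axis; the annealing-strand
    primer sequence for a '-' candidate is its reverse complement.
    """

    fragment_id: str
    source: str  # direct_hit | extrapolated
    position: tuple[int, int]
    strand: str
    sequence: str
    gc_fraction: float | None
    tm_celsius: float | None

    @property
    def midpoint(self) -> float:
        return (self.position[0] + self.position[1]) / 2

    @property
    def five_prime_range(self) -> tuple[int, int]:
        """Feasible extended-axis positions of the tag's 5' end.

        Direct hits are points; extrapolated tags span their envelope
        extremes (the conservative convention: the full envelope width
        counts as 5'-end uncertainty).
        """
        a, b = self.position
        if self.source == DIRECT_HIT:
            return (a, a) if self.strand == "+" else (b, b)
        return (a, b)


@dataclass(frozen=True)
class AmpliconPlan:
    """A forward/reverse tag pairing with its expected product-size range."""

    forward: TagCandidate
    reverse: TagCandidate
    product_min: int
    product_max: int
    overlap_ok: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.product_min <= self.product_max):
            raise ValidationError(
                f"invalid product range [{self.product_min}, {self.product_max}]"
            )

    @property
    def covered_interval(self) -> tuple[int, int]:
        """Extended-axis span this amplicon can cover, evaluated at the
        envelope outer extremes; its length equals ``product_max``."""
        return (self.forward.five_prime_range[0], self.reverse.five_prime_range[1])


def primer_metrics(seq: str) -> tuple[float, float]:
    """(GC fraction, melting temperature °C) of a primer substrate.

    Wallace rule 2(A+T) + 4(G+C) below 14 nt; the standard GC-content
    approximation 64.9 + 41*((G+C) - 16.4)/len otherwise.  N makes a
    sequence unsuitable and is an error.
    """
    if len(seq) < 10:
        raise ValidationError(f"primer substrate too short ({len(seq)} nt, need >= 10)")
    if "N" in seq:
        raise ValidationError("primer substrate contains N")
    gc = sum(1 for ch in seq if ch in "GC")
    at = len(seq) - gc
    if len(seq) < 14:
        tm = 2.0 * at + 4.0 * gc
    else:
        tm = 64.9 + 41.0 * (gc - 16.4) / len(seq)
    return gc / len(seq), tm


def _oriented_sequence(residues: str, aligned_strand: str) -> str:
    # 5'->3' on the forward axis: minus-strand tags flip.
    return residues if aligned_strand == "+" else reverse_complement(residues)


def _make_candidate(
    fragment_id: str, source: str, position: tuple[int, int], strand: str, residues: str
) -> TagCandidate:
    seq = _oriented_sequence(residues, strand)
    try:
        gc, tm = primer_metrics(seq)
    except ValidationError:
        gc, tm = None, None
    return TagCandidate(fragment_id, source, position, strand, seq, gc, tm)


def candidate_tags(
    pairhits: list[PairHit],
    window: tuple[int, int],
    want_strand: str,
    library: PairedReadLibrary | None = None,
) -> list[TagCandidate]:
    """All tags of the wanted orientation intersecting an extended-axis window.

    Direct-hit tags are matched on their hit interval and aligned strand;
    extrapolated tags on their envelope and expected strand.  Candidates
    are sorted by proximity of their midpoint to the window midpoint (ties
    by fragment id).
    """
    a, b = window
    if not a < b:
        raise ValidationError(f"empty window [{a},{b})")
    w_mid = (a + b) / 2
    out: list[TagCandidate] = []

    def residues_of(key: ReadKey) -> str:
        if library is None:
            return ""
        return library.get_read(key).residues

    for ph in pairhits:
        for hit in (ph.hit1, ph.hit2):
            if hit is None or hit.strand != want_strand:
                continue
            if hit.q_end > a and hit.q_start < b:
                out.append(
                    _make_candidate(
                        ph.fragment_id, DIRECT_HIT, (hit.q_start, hit.q_end), hit.strand,
                        residues_of(hit.read_key),
                    )
                )
        if ph.category == SINGLE_END and ph.placement is not None:
            pl = ph.placement
            if pl.strand == want_strand and pl.envelope_end > a and pl.envelope_start < b:
                mate_idx = 3 - pl.anchor.mate_index
                out.append(
                    _make_candidate(
                        ph.fragment_id, EXTRAPOLATED, (pl.envelope_start, pl.envelope_end),
                        pl.strand, residues_of(ReadKey(ph.fragment_id, mate_idx)),
                    )
                )
    out.sort(key=lambda c: (abs(c.midpoint - w_mid), c.fragment_id, c.source))
    return out


def _pair_product_range(fwd: TagCandidate, rev: TagCandidate) -> tuple[int, int]:
    f_lo, f_hi = fwd.five_prime_range
    r_lo, r_hi = rev.five_prime_range
    return (r_lo - f_hi, r_hi - f_lo)


def plan_amplicons(
    fwd: list[TagCandidate],
    rev: list[TagCandidate],
    target: tuple[int, int],
    max_product: int,
    min_overlap: int = 0,
) -> list[AmpliconPlan]:
    """Greedy minimal tiling of ``target`` by forward/reverse tag pairings.

    Amplicon spans are evaluated at the envelope outer extremes (a span's
    length is exactly ``product_max``), successive spans overlap by at
    least ``min_overlap`` bp, and no product may exceed ``max_product`` at
    its envelope-maximal size.  Raises :class:`TilingError` naming the
    uncovered sub-interval when no admissible pairing extends the tiling.
    """
    if max_product <= 0:
        raise ValidationError("max_product must be > 0")
    t0, t1 = target
    if not t0 < t1:
        raise ValidationError(f"empty target interval [{t0},{t1})")

    pairs: list[tuple[tuple[int, int], TagCandidate, TagCandidate]] = []
    for f in fwd:
        if f.strand != "+":
            continue
        for r in rev:
            if r.strand != "-":
                continue
            pmin, pmax = _pair_product_range(f, r)
            if pmin <= 0 or pmax > max_product:
                continue
            pairs.append(((pmin, pmax), f, r))
    plans: list[AmpliconPlan] = []
    reach = t0
    first = True
    while reach < t1:
        start_limit = t0 if first else reach - min_overlap
        best = None
        best_rank = None
        for (pmin, pmax), f, r in pairs:
            cov_start, cov_end = f.five_prime_range[0], r.five_prime_range[1]
            if cov_start > start_limit or cov_end <= reach:
                continue
            # farthest reach wins; ties broken deterministically
            rank = (-cov_end, cov_start, f.fragment_id, r.fragment_id)
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best = (cov_end, (pmin, pmax), f, r)
        if best is None:
            raise TilingError(
                f"no admissible amplicon covers [{reach}, {t1}) "
                f"(forward tag needed at or left of {start_limit})",
                uncovered=(reach, t1),
            )
        cov_end, (pmin, pmax), f, r = best
        plans.append(
            AmpliconPlan(
                forward=f, reverse=r, product_min=pmin, product_max=pmax,
                overlap_ok=not first,
            )
        )
        reach = cov_end
        first = False
    return plans


def write_plans(plans: list[AmpliconPlan], path) -> None:
    """plans.tsv: one row per amplicon plan."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "#fwd_fragment\tfwd_source\tfwd_start\tfwd_end\tfwd_gc\tfwd_tm\t"
            "rev_fragment\trev_source\trev_start\trev_end\trev_gc\trev_tm\t"
            "product_min\tproduct_max\toverlaps_previous\n"
        )
        for p in plans:
            f, r = p.forward, p.reverse
            fgc = "" if f.gc_fraction is None else f"{f.gc_fraction:.3f}"
            ftm = "" if f.tm_celsius is None else f"{f.tm_celsius:.1f}"
            rgc = "" if r.gc_fraction is None else f"{r.gc_fraction:.3f}"
            rtm = "" if r.tm_celsius is None else f"{r.tm_celsius:.1f}"
            fh.write(
                f"{f.fragment_id}\t{f.source}\t{f.position[0]}\t{f.position[1]}\t{fgc}\t{ftm}\t"
                f"{r.fragment_id}\t{r.source}\t{r.position[0]}\t{r.position[1]}\t{rgc}\t{rtm}\t"
                f"{p.product_min}\t{p.product_max}\t{int(p.overlap_ok)}\n"
            )
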