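"""User-facing outputs: coverage profiles, region enrichment, text pile-up
map, and the BED/TSV/FASTA files a search run writes.

File conventions: BED6 with 0-based half-open intervals for direct hits;
extended-axis placements go to TSV (BED forbids negative coordinates);
TSV headers are comment lines starting '#'; all files are LF-terminated
text.  Human-facing coordinates inside the map are labeled on the same
0-based extended axis used internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pairing import SINGLE_END, MatePlacement, PairHit, TagReport
from .seedalign import TagHit
from .seqio import PairedReadLibrary, ReadKey, SequenceRecord


@dataclass
class CoverageProfile:
    """Per-base tag depth over the query (direct hits only)."""

    query_id: str
    depth: np.ndarray  # int array, length == query length

    @property
    def total(self) -> int:
        return int(self.depth.sum())


def _iter_hits(pairhits: list[PairHit]):
    for ph in pairhits:
        for hit in (ph.hit1, ph.hit2):
            if hit is not None:
                yield ph, hit


def coverage(pairhits: list[PairHit], query_len: int, query_id: str = "query") -> CoverageProfile:
    """Depth of direct tag alignments per query base.

    Extrapolated envelopes are *not* counted: coverage reports observed
    alignment, not inference.  The sum of depths equals the sum of hit
    interval lengths (conservation rule).
    """
    diff = np.zeros(query_len + 1, dtype=np.int64)
    for _, hit in _iter_hits(pairhits):
        if hit.q_start < 0 or hit.q_end > query_len:
            raise ValidationError(
                f"hit {hit.read_key} interval [{hit.q_start},{hit.q_end}) outside query of length {query_len}"
            )
        diff[hit.q_start] += 1
        diff[hit.q_end] -= 1
    return CoverageProfile(query_id=query_id, depth=np.cumsum(diff[:query_len]))


def enrichment(pairhits: list[PairHit], interval: tuple[int, int]) -> float | None:
    """Fraction of hit midpoints falling in [a, b); None when there are no
    hits at all (undefined, deliberately not 0)."""
    a, b = interval
    if not a < b:
        raise ValidationError(f"empty interval [{a},{b})")
    total = 0
    inside = 0
    for _, hit in _iter_hits(pairhits):
        total += 1
        mid = (hit.q_start + hit.q_end) / 2
        if a <= mid < b:
            inside += 1
    if total == 0:
        return None
    return inside / total


# ---------------------------------------------------------------- text map


def _axis_bounds(pairhits: list[PairHit], query_len: int) -> tuple[int, int]:
    lo, hi = 0, query_len
    for ph in pairhits:
        if ph.placement is not None:
            lo = min(lo, ph.placement.envelope_start)
            hi = max(hi, ph.placement.envelope_end)
    return lo, hi


def render_map(pairhits: list[PairHit], query_len: int, width: int = 100) -> list[str]:
    """Deterministic ASCII pile-up of tags along the (extended) query axis.

    '>' and '<' mark plus/minus direct tags, '?' an extrapolated mate
    envelope, and '·' bridges the two blocks of a both-mapped pair.  Rows
    are packed greedily into the first free row.  Negative axis start
    (off-query 5' placements) is explicit in the header.
    """
    if width < 40:
        raise ValidationError("map width must be >= 40 columns")
    lo, hi = _axis_bounds(pairhits, query_len)
    span = max(hi - lo, 1)

    def col(pos: int) -> int:
        c = int((pos - lo) * width / span)
        return min(max(c, 0), width - 1)

    lines = [
        f"# tag map: axis {lo}..{hi} (0-based; query occupies 0..{query_len}; negative = 5' flank)",
        f"# glyphs: '>' plus tag, '<' minus tag, '?' inferred mate envelope, '·' pair bridge",
    ]
    ruler = ["-"] * width
    for tick in range(0, width, 10):
        ruler[tick] = "|"
    lines.append("".join(ruler))

    # one drawable entity per PairHit: list of (start_col, end_col, glyph)
    entities = []
    for ph in sorted(pairhits, key=lambda p: (min(x for x in _extent(p)), p.fragment_id)):
        blocks = []
        for hit in (ph.hit1, ph.hit2):
            if hit is not None:
                glyph = ">" if hit.strand == "+" else "<"
                blocks.append((col(hit.q_start), col(hit.q_end - 1), glyph))
        if ph.placement is not None:
            blocks.append((col(ph.placement.envelope_start), col(ph.placement.envelope_end - 1), "?"))
        if not blocks:
            continue
        bridge = ph.hit1 is not None and ph.hit2 is not None
        entities.append((blocks, bridge, ph.fragment_id))

    rows: list[list[str]] = []
    occupied: list[list[bool]] = []
    for blocks, bridge, _frag in entities:
        lo_c = min(b[0] for b in blocks)
        hi_c = max(b[1] for b in blocks)
        row_idx = None
        for i, occ in enumerate(occupied):
            if not any(occ[max(lo_c - 1, 0) : hi_c + 2]):
                row_idx = i
                break
        if row_idx is None:
            rows.append([" "] * width)
            occupied.append([False] * width)
            row_idx = len(rows) - 1
        row, occ = rows[row_idx], occupied[row_idx]
        if bridge or len(blocks) > 1:
            for c in range(lo_c, hi_c + 1):
                if row[c] == " ":
                    row[c] = "·"
        for bs, be, glyph in blocks:
            for c in range(bs, be + 1):
                row[c] = glyph
        for c in range(max(lo_c - 1, 0), min(hi_c + 2, width)):
            occ[c] = True
    lines.extend("".join(r) for r in rows)
    return lines


def _extent(ph: PairHit) -> list[int]:
    xs: list[int] = []
    for hit in (ph.hit1, ph.hit2):
        if hit is not None:
            xs.extend((hit.q_start, hit.q_end))
    if ph.placement is not None:
        xs.extend((ph.placement.envelope_start, ph.placement.envelope_end))
    return xs or [0]


# ---------------------------------------------------------------- file I/O


def write_outputs(
    pairhits: list[PairHit],
    profile: CoverageProfile,
    report: TagReport,
    outdir: str | os.PathLike,
    library: PairedReadLibrary | None = None,
    query_id: str = "query",
    map_width: int = 100,
) -> dict[str, str]:
    """Write the search result files into ``outdir``.

    hits.bed        BED6, one line per direct TagHit (0-based half-open)
    placements.tsv  extrapolated mate envelopes on the signed extended axis
    report.tsv      Table-style per-library tally
    coverage.tsv    per-base depth
    map.txt         ASCII pile-up
    tags.fasta      sequences of all hit and placed tags (primer substrate)

    Returns a name -> path mapping.  Multi-library runs write one
    directory per library and combine the report rows separately.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, name) for name in (
        "hits.bed", "placements.tsv", "report.tsv", "coverage.tsv", "map.txt", "tags.fasta")}

    with open(paths["hits.bed"], "w", newline="\n") as fh:
        for ph, hit in _iter_hits(pairhits):
            fh.write(
                f"{query_id}\t{hit.q_start}\t{hit.q_end}\t{hit.read_key}\t{hit.score}\t{hit.strand}\n"
            )

    with open(paths["placements.tsv"], "w", newline="\n") as fh:
        if True:
            fh.write("# extrapolated mate envelopes; coordinates on the signed extended query axis\n")
            fh.write("#fragment\tanchor\tanchor_start\tanchor_end\tanchor_strand\tenvelope_start\tenvelope_end\tenvelope_strand\n")
        for ph in pairhits:
            if ph.placement is None:
                continue
            anchor_hit = ph.hit1 or ph.hit2
            pl = ph.placement
            fh.write(
                f"{ph.fragment_id}\t{pl.anchor}\t{anchor_hit.q_start}\t{anchor_hit.q_end}\t"
                f"{anchor_hit.strand}\t{pl.envelope_start}\t{pl.envelope_end}\t{pl.strand}\n"
            )

    with open(paths["report.tsv"], "w", newline="\n") as fh:
        if True:
            fh.write("# Read pairs = fragments with both mates hit; Single reads = fragments with exactly one mate hit (disjoint counts)\n")
            fh.write("#Dataset\tRead pairs\tSingle reads\tTotal hits\n")
        fh.write(
            f"{report.library_name}\t{report.n_read_pairs}\t{report.n_single_reads}\t{report.n_total_hits}\n"
        )

    with open(paths["coverage.tsv"], "w", newline="\n") as fh:
        fh.write("#pos\tdepth\n")
        for i, d in enumerate(profile.depth):
            fh.write(f"{i}\t{int(d)}\n")

    query_len = len(profile.depth)
    with open(paths["map.txt"], "w", newline="\n") as fh:
        for line in render_map(pairhits, query_len, width=map_width):
            fh.write(line + "\n")

    with open(paths["tags.fasta"], "w", newline="\n") as fh:
        if library is not None:
            for ph in pairhits:
                keys: list[ReadKey] = []
                for hit in (ph.hit1, ph.hit2):
                    if hit is not None:
                        keys.append(hit.read_key)
                if ph.category == SINGLE_END:
                    anchor = (ph.hit1 or ph.hit2).read_key
                    keys.append(ReadKey(ph.fragment_id, 3 - anchor.mate_index))
                for key in keys:
                    rec = library.get_read(key)
                    fh.write(f">{key}\n{rec.residues}\n")
    return paths


def read_hits_bed(path: str | os.PathLike) -> list[tuple[str, TagHit]]:
    """Re-read hits.bed into (query_id, TagHit) tuples.

    Match/mismatch counts are not stored in BED; they are reconstructed so
    that score and identity bookkeeping stays consistent under the default
    +1/-2 scoring (matches - mismatches*2 == score, matches+mismatches == len).
    Read length is unknown from BED alone and set to the aligned length.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            qid, s, e, name, score, strand = line.rstrip("\n").split("\t")
            q_start, q_end, score = int(s), int(e), int(score)
            length = q_end - q_start
            # invert score = m - 2x, m + x = length  (default scoring)
            mismatches = (length - score) // 3
            matches = length - mismatches
            key = _parse_read_key(name)
            out.append(
                (
                    qid,
                    TagHit(
                        read_key=key,
                        q_start=q_start,
                        q_end=q_end,
                        r_start=0,
                        r_end=length,
                        strand=strand,
                        score=score,
                        matches=matches,
                        mismatches=mismatches,
                        read_len=length,
                    ),
                )
            )
    return out


def _parse_read_key(name: str) -> ReadKey:
    frag, _, mate = name.rpartition("/")
    return ReadKey(frag, int(mate))


def read_placements(path: str | os.PathLike) -> list[tuple[str, MatePlacement]]:
    """Re-read placements.tsv into (fragment_id, MatePlacement) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            frag, anchor, _as, _ae, _astrand, es, ee, strand = line.rstrip("\n").split("\t")
            out.append(
                (
                    frag,
                    MatePlacement(
                        envelope_start=int(es),
                        envelope_end=int(ee),
                        strand=strand,
                        anchor=_parse_read_key(anchor),
                    ),
                )
            )
    return out


def read_tags_fasta(path: str | os.PathLike) -> dict[str, SequenceRecord]:
    """Re-read tags.fasta keyed by 'fragment/mate' name."""
    from .seqio import parse_fasta

    try:
        records = parse_fasta(path)
    except Exception:
        return {}
    return {rec.id: rec for rec in records}
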