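"""Sequence I/O: FASTA/FASTQ reading and writing, read-name normalization.

Nucleotide sequences are normalized to the alphabet {A, C, G, T, N}:
lowercase is uppercased, U becomes T, and non-ACGTN IUPAC ambiguity codes
(R, Y, S, W, K, M, B, D, H, V) are mapped to N with a logged warning.
Characters outside the IUPAC nucleotide set are a hard error.

Paired FASTQ files are joined into a :class:`PairedReadLibrary`, pairing
records positionally and verifying that the mate names agree.  Read names
are resolved into ``(fragment_id, mate_index)`` keys by :func:`mate_key`,
which recognizes the common dialects (``/1``-``/2`` suffixes, ``_1``-``_2``
suffixes, Casava 1.8 ``NAME 1:...`` comments) and falls back to the file of
origin when the name carries no mate tag.

Coordinates everywhere in this package are 0-based half-open.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID = set("ACGTN")
_AMBIG = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class ReadKey:
    """Identifies one mate of one fragment: ``(fragment_id, mate_index)``."""

    fragment_id: str
    mate_index: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.mate_index not in (1, 2):
            raise ValidationError(f"mate_index must be 1 or 2, got {self.mate_index}")

    def __str__(self) -> str:
        return f"{self.fragment_id}/{self.mate_index}"


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and ambiguity codes->N; reject non-IUPAC characters."""
    s = raw.upper().replace("U", "T")
    if set(s) <= VALID:
        return s
    out = []
    warned = False
    for ch in s:
        if ch in VALID:
            out.append(ch)
        elif ch in _AMBIG:
            if not warned:
                logger.warning("%s: IUPAC ambiguity code(s) mapped to N", context)
                warned = True
            out.append("N")
        else:
            raise ValidationError(f"{context}: invalid residue {ch!r} (not an IUPAC nucleotide)")
    return "".join(out)


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N complements to N."""
    if not set(s) <= VALID:
        bad = sorted(set(s) - VALID)
        raise ValidationError(f"reverse_complement: invalid residue(s) {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def _as_handle(source: str | os.PathLike) -> io.TextIOBase:
    # Accept a path, or raw FASTA/FASTQ text (handy in tests and examples).
    if isinstance(source, os.PathLike) or (
        isinstance(source, str)
        and source != ""
        and "\n" not in source
        and not source.startswith(">")
        and not source.startswith("@")
    ):
        return open(source)
    return io.StringIO(str(source))


def parse_fasta(source: str | os.PathLike) -> list[SequenceRecord]:
    """Parse FASTA from a path or raw text into normalized records.

    Raises
    ------
    FormatError
        on empty input, duplicate ids, or invalid residues.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _as_handle(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
            try:
                residues = normalize_residues(str(rec.seq), context=f"record {rec.id!r}")
            except ValidationError as exc:
                raise FormatError(str(exc)) from exc
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError("no records found in FASTA input")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns, LF line endings."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def mate_key(read_name: str, file_of_origin: int | None = None) -> ReadKey:
    """Resolve a read name into a (fragment_id, mate_index) key.

    Dialects are tried in a fixed priority order: ``/1``-``/2`` suffix,
    ``_1``-``_2`` suffix, Casava 1.8 ``NAME 1:...`` comment; otherwise the
    mate index is taken from ``file_of_origin`` (1-based file number) with
    the full name as fragment id.
    """
    if not read_name:
        raise ValidationError("empty read name")
    if len(read_name) > 2 and read_name[-2] == "/" and read_name[-1] in "12":
        return ReadKey(read_name[:-2], int(read_name[-1]))
    if len(read_name) > 2 and read_name[-2] == "_" and read_name[-1] in "12":
        return ReadKey(read_name[:-2], int(read_name[-1]))
    if " " in read_name:
        head, _, comment = read_name.partition(" ")
        first = comment.split(":", 1)[0]
        if first in ("1", "2"):
            return ReadKey(head, int(first))
    if file_of_origin in (1, 2):
        return ReadKey(read_name, file_of_origin)
    raise ValidationError(
        f"cannot determine mate index of read {read_name!r} (no /1, _1 or Casava tag, no file of origin)"
    )


@dataclass
class PairedReadLibrary:
    """Mate-1/mate-2 reads keyed by fragment id.

    ``fragments`` maps fragment_id -> (mate1 record, mate2 record).  Quality
    strings are retained on parse but never used downstream: the search is
    identity-based.
    """

    name: str
    fragments: dict[str, tuple[SequenceRecord, SequenceRecord]] = field(default_factory=dict)
    qualities: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.fragments)

    def get_read(self, key: ReadKey) -> SequenceRecord:
        try:
            pair = self.fragments[key.fragment_id]
        except KeyError:
            raise ValidationError(f"unknown fragment {key.fragment_id!r} in library {self.name!r}") from None
        return pair[key.mate_index - 1]

    def read_length(self, key: ReadKey) -> int:
        return len(self.get_read(key))

    def iter_reads(self) -> Iterator[tuple[ReadKey, SequenceRecord]]:
        for frag_id, (r1, r2) in self.fragments.items():
            yield ReadKey(frag_id, 1), r1
            yield ReadKey(frag_id, 2), r2

    def read_length_stats(self) -> tuple[int, int, float]:
        """(min, max, mean) read length over the library."""
        lens = [len(r) for _, r in self.iter_reads()]
        if not lens:
            return (0, 0, 0.0)
        return (min(lens), max(lens), sum(lens) / len(lens))


def _parse_fastq_records(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """(full name, residues, quality) per record; wraps Biopython's parser."""
    out: list[tuple[str, str, str]] = []
    with _as_handle(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed FASTQ near line {4 * idx + 1}: {exc}"
                ) from exc
            name = rec.description or rec.id
            try:
                residues = normalize_residues(str(rec.seq), context=f"read {name!r}")
            except ValidationError as exc:
                raise FormatError(str(exc)) from exc
            qual = "".join(chr(q + 33) for q in rec.letter_annotations.get("phred_quality", []))
            out.append((name, residues, qual))
            idx += 1
    return out


def parse_fastq_pair(
    path1: str | os.PathLike, path2: str | os.PathLike, name: str = "library"
) -> PairedReadLibrary:
    """Join two FASTQ files into a paired library.

    Records are paired positionally; the fragment ids derived from the read
    names must agree at every position.
    """
    recs1 = _parse_fastq_records(path1)
    recs2 = _parse_fastq_records(path2)
    if len(recs1) != len(recs2):
        raise FormatError(f"record count mismatch ({len(recs1)} vs {len(recs2)})")
    lib = PairedReadLibrary(name=name)
    for pos, ((n1, s1, q1), (n2, s2, q2)) in enumerate(zip(recs1, recs2), start=1):
        k1 = mate_key(n1, file_of_origin=1)
        k2 = mate_key(n2, file_of_origin=2)
        if k1.fragment_id != k2.fragment_id:
            raise FormatError(
                f"mate name disagreement at record {pos}: {k1.fragment_id!r} vs {k2.fragment_id!r}"
            )
        if k1.fragment_id in lib.fragments:
            raise FormatError(f"duplicate fragment id {k1.fragment_id!r}")
        lib.fragments[k1.fragment_id] = (
            SequenceRecord(id=str(ReadKey(k1.fragment_id, 1)), residues=s1),
            SequenceRecord(id=str(ReadKey(k1.fragment_id, 2)), residues=s2),
        )
        lib.qualities[k1.fragment_id] = (q1, q2)
    return lib


def parse_fastq_interleaved(path: str | os.PathLike, name: str = "library") -> PairedReadLibrary:
    """Parse an interleaved FASTQ (records alternate mate 1, mate 2)."""
    recs = _parse_fastq_records(path)
    if len(recs) % 2 != 0:
        raise FormatError(f"interleaved FASTQ has odd record count ({len(recs)})")
    lib = PairedReadLibrary(name=name)
    for pos in range(0, len(recs), 2):
        (n1, s1, q1), (n2, s2, q2) = recs[pos], recs[pos + 1]
        k1 = mate_key(n1, file_of_origin=1)
        k2 = mate_key(n2, file_of_origin=2)
        if k1.fragment_id != k2.fragment_id:
            raise FormatError(
                f"mate name disagreement at record {pos + 1}: {k1.fragment_id!r} vs {k2.fragment_id!r}"
            )
        if k1.fragment_id in lib.fragments:
            raise FormatError(f"duplicate fragment id {k1.fragment_id!r}")
        lib.fragments[k1.fragment_id] = (
            SequenceRecord(id=str(ReadKey(k1.fragment_id, 1)), residues=s1),
            SequenceRecord(id=str(ReadKey(k1.fragment_id, 2)), residues=s2),
        )
        lib.qualities[k1.fragment_id] = (q1, q2)
    return lib


def write_fastq_pair(
    library: PairedReadLibrary, path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    """Write the library back out as two 4-line FASTQ files."""
    with open(path1, "w", newline="\n") as f1, open(path2, "w", newline="\n") as f2:
        for frag_id, (r1, r2) in library.fragments.items():
            q1, q2 = library.qualities.get(frag_id, ("I" * len(r1), "I" * len(r2)))
            f1.write(f"@{frag_id}/1\n{r1.residues}\n+\n{q1}\n")
            f2.write(f"@{frag_id}/2\n{r2.residues}\n+\n{q2}\n")


def load_query(path: str | os.PathLike, max_query_len: int = 5000, multi: bool = False) -> list[SequenceRecord]:
    """Load and validate query FASTA: length cap, single record unless ``multi``."""
    records = parse_fasta(path)
    if not multi and len(records) > 1:
        raise ValidationError(f"expected a single query record, found {len(records)} (use multi mode)")
    for rec in records:
        if rec.length > max_query_len:
            raise ValidationError(
                f"query {rec.id!r} is {rec.length} bp, exceeding the {max_query_len} bp limit"
            )
    return records
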