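"""Synthetic data: diverged ortholog genomes and paired-read libraries with
ground truth.

The generator emulates the cross-species situation the search is built
for: a reference query whose ortholog in an unassembled genome differs by
region — coding sequence conserved far better than the downstream flank,
which in turn beats the upstream/promoter flank (defaults 86% / 60% / 41%
per-base identity).  Short paired reads are drawn from the ortholog-bearing
genome in FR orientation with a truncated-normal outer fragment length, so
every read's true origin (interval and strand) is known and every
geometric inference downstream can be checked against truth.

Everything is a pure function of its inputs and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .pairing import InsertModel
from .seqio import (
    PairedReadLibrary,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_fastq_pair,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class DivergenceSpec:
    """Region-wise divergence plan for deriving an ortholog from a reference.

    ``regions`` is a list of ``(start, end, target_identity)`` intervals
    that must partition the reference.  Each base of a region is
    independently substituted with probability ``1 - target_identity``.
    Indels (length 1-3, uniform) are off by default: the downstream
    aligner is gap-free, so indels measure robustness, not correctness.
    """

    regions: tuple[tuple[int, int, float], ...]
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, ident in self.regions:
            if not 0.0 <= ident <= 1.0:
                raise ValidationError(f"target identity {ident} outside [0,1]")
        if not 0.0 <= self.indel_rate <= 0.1:
            raise ValidationError("indel_rate must be in [0, 0.1]")

    def validate_partition(self, length: int) -> None:
        regs = sorted(self.regions)
        if not regs:
            raise ValidationError("no regions given")
        if regs[0][0] != 0 or regs[-1][1] != length:
            raise ValidationError(f"regions must span [0,{length})")
        for (s1, e1, _), (s2, e2, _) in zip(regs, regs[1:]):
            if e1 > s2:
                raise ValidationError(f"regions [{s1},{e1}) and [{s2},{e2}) overlap")
            if e1 < s2:
                raise ValidationError(f"gap between regions at [{e1},{s2})")


@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-read simulation settings (GAII-style fixed-length FR pairs)."""

    coverage: float = 30.0
    read_len: int = 75
    insert: InsertModel = field(default_factory=lambda: InsertModel(1000, 50, 850, 1150))
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValidationError("coverage must be > 0")
        if self.read_len < 8:
            raise ValidationError("read_len too short")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValidationError("error_rate must be in [0, 0.1]")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T sequence."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_regions(
    ref: SequenceRecord, spec: DivergenceSpec
) -> tuple[SequenceRecord, dict[tuple[int, int], float]]:
    """Derive a diverged ortholog from ``ref`` region by region.

    Returns the ortholog and the realized per-region identity (fraction of
    reference bases left unchanged by substitution; indel-inserted bases
    are not counted).
    """
    spec.validate_partition(ref.length)
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    realized: dict[tuple[int, int], float] = {}
    for start, end, ident in sorted(spec.regions):
        kept = 0
        region_out: list[str] = []
        i = start
        while i < end:
            base = ref.residues[i]
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                if rng.random() < 0.5:  # insertion before this base
                    ins_len = int(rng.integers(1, 4))
                    region_out.append(random_sequence(ins_len, rng))
                else:  # deletion of 1-3 bases
                    del_len = int(rng.integers(1, 4))
                    i += del_len
                    continue
            if base == "N" or rng.random() >= (1.0 - ident):
                region_out.append(base)
                kept += 1
            else:
                region_out.append(_OTHER[base][int(rng.integers(0, 3))])
            i += 1
        out.append("".join(region_out))
        realized[(start, end)] = kept / (end - start)
    ortholog = SequenceRecord(
        id=f"{ref.id}_ortholog", residues="".join(out), description="diverged copy"
    )
    return ortholog, realized


@dataclass(frozen=True)
class FragmentTruth:
    """Ground-truth placement of one simulated fragment on the genome."""

    fragment_id: str
    start: int
    end: int  # start + outer fragment length

    def intervals(self, read_len: int) -> tuple[tuple[int, int, str], tuple[int, int, str]]:
        """((start, end, strand) for mate 1, same for mate 2)."""
        return (
            (self.start, self.start + read_len, "+"),
            (self.end - read_len, self.end, "-"),
        )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        if arr[i] in _OTHER:
            arr[i] = _OTHER[arr[i]][int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_pairs(
    genome: SequenceRecord, spec: ReadSimSpec, name: str = "simlib"
) -> tuple[PairedReadLibrary, list[FragmentTruth]]:
    """Draw FR read pairs from ``genome`` at the requested fold coverage.

    Fragment count is round(coverage * genome_len / (2 * read_len)); outer
    lengths are Normal(mean, sd) truncated to [L_min, L_max] and rounded;
    mate 1 is the fragment's first ``read_len`` bases, mate 2 the reverse
    complement of its last ``read_len`` bases.  Per-base substitution
    errors at ``error_rate``; constant quality 'I'.
    """
    ins = spec.insert
    if genome.length < ins.L_max:
        raise ValidationError(
            f"genome of {genome.length} bp shorter than L_max={ins.L_max}"
        )
    rng = np.random.default_rng(spec.seed)
    n_frag = int(round(spec.coverage * genome.length / (2 * spec.read_len)))
    lib = PairedReadLibrary(name=name)
    truth: list[FragmentTruth] = []
    g = genome.residues
    qual = "I" * spec.read_len
    for i in range(n_frag):
        # truncated-normal outer length by rejection; degenerate sd -> mean
        while True:
            L = ins.mean if ins.sd == 0 else rng.normal(ins.mean, ins.sd)
            L = int(round(L))
            if ins.L_min <= L <= ins.L_max:
                break
        start = int(rng.integers(0, genome.length - L + 1))
        frag_id = f"sim{i:06d}"
        m1 = _apply_errors(g[start : start + spec.read_len], spec.error_rate, rng)
        m2 = _apply_errors(
            reverse_complement(g[start + L - spec.read_len : start + L]),
            spec.error_rate,
            rng,
        )
        lib.fragments[frag_id] = (
            SequenceRecord(id=f"{frag_id}/1", residues=m1),
            SequenceRecord(id=f"{frag_id}/2", residues=m2),
        )
        lib.qualities[frag_id] = (qual, qual)
        truth.append(FragmentTruth(frag_id, start, start + L))
    return lib, truth


def write_truth(truth: list[FragmentTruth], read_len: int, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#fragment\tgenome_start\tgenome_end\tmate1_start\tmate1_end\tmate1_strand\tmate2_start\tmate2_end\tmate2_strand\n")
        for t in truth:
            (s1, e1, st1), (s2, e2, st2) = t.intervals(read_len)
            fh.write(f"{t.fragment_id}\t{t.start}\t{t.end}\t{s1}\t{e1}\t{st1}\t{s2}\t{e2}\t{st2}\n")


# scenario constants: 4.5-kb query whose first 1 kb is promoter/upstream,
# middle 1.5 kb coding, last 2 kb downstream; ortholog identities per
# region 41% / 86% / 60%; ortholog embedded mid-way in a 20-kb background.
WD40_QUERY_LEN = 4500
WD40_REGIONS = ((0, 1000, 0.41), (1000, 2500, 0.86), (2500, 4500, 0.60))
WD40_CODING = (1000, 2500)
WD40_GENOME_LEN = 20_000
WD40_EMBED_AT = 7750
WD40_INSERT = InsertModel(1000, 50, 850, 1150)
WD40_COVERAGE = 30.0
WD40_READ_LEN = 75
WD40_ERROR_RATE = 0.005


@dataclass
class ScenarioBundle:
    """In-memory fixture bundle for the WD40-style recovery scenario."""

    query: SequenceRecord
    coding: tuple[int, int]
    ortholog: SequenceRecord
    genome: SequenceRecord
    library: PairedReadLibrary
    truth: list[FragmentTruth]
    unrelated_library: PairedReadLibrary
    insert: InsertModel
    read_len: int
    embed_offset: int
    realized_identity: dict[tuple[int, int], float]
    paths: dict[str, str] = field(default_factory=dict)


def scenario_wd40(seed: int, outdir: str | os.PathLike | None = None) -> ScenarioBundle:
    """Build the full cross-species recovery fixture.

    A random 4.5-kb query (upstream/coding/downstream at 41/86/60%
    ortholog identity), the ortholog embedded in a 20-kb background
    genome, a 30x 2x75 FR library from that genome, and a second library
    drawn from an unrelated random genome (the expected-zero control).
    With ``outdir`` the bundle is also written to disk (FASTA/FASTQ/BED/TSV).
    """
    master = np.random.default_rng(seed)
    sub = lambda: int(master.integers(0, 2**31 - 1))  # noqa: E731

    query = SequenceRecord(
        id="query", residues=random_sequence(WD40_QUERY_LEN, np.random.default_rng(sub()))
    )
    div = DivergenceSpec(regions=WD40_REGIONS, seed=sub())
    ortholog, realized = mutate_regions(query, div)

    bg_rng = np.random.default_rng(sub())
    left = random_sequence(WD40_EMBED_AT, bg_rng)
    right = random_sequence(WD40_GENOME_LEN - WD40_EMBED_AT - ortholog.length, bg_rng)
    genome = SequenceRecord(id="genome", residues=left + ortholog.residues + right)

    sim = ReadSimSpec(
        coverage=WD40_COVERAGE, read_len=WD40_READ_LEN, insert=WD40_INSERT,
        error_rate=WD40_ERROR_RATE, seed=sub(),
    )
    library, truth = simulate_pairs(genome, sim, name="ortholog_library")

    unrelated_genome = SequenceRecord(
        id="unrelated", residues=random_sequence(WD40_GENOME_LEN, np.random.default_rng(sub()))
    )
    unrelated_sim = ReadSimSpec(
        coverage=WD40_COVERAGE, read_len=WD40_READ_LEN, insert=WD40_INSERT,
        error_rate=WD40_ERROR_RATE, seed=sub(),
    )
    unrelated_library, _ = simulate_pairs(unrelated_genome, unrelated_sim, name="unrelated_library")

    bundle = ScenarioBundle(
        query=query, coding=WD40_CODING, ortholog=ortholog, genome=genome,
        library=library, truth=truth, unrelated_library=unrelated_library,
        insert=WD40_INSERT, read_len=WD40_READ_LEN, embed_offset=WD40_EMBED_AT,
        realized_identity=realized,
    )
    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        p = {name: os.path.join(outdir, name) for name in (
            "query.fasta", "coding.bed", "ortholog.fasta", "genome.fasta",
            "reads_1.fastq", "reads_2.fastq",
            "unrelated_1.fastq", "unrelated_2.fastq", "truth.tsv")}
        write_fasta([query], p["query.fasta"])
        with open(p["coding.bed"], "w", newline="\n") as fh:
            fh.write(f"query\t{WD40_CODING[0]}\t{WD40_CODING[1]}\tcoding\n")
        write_fasta([ortholog], p["ortholog.fasta"])
        write_fasta([genome], p["genome.fasta"])
        write_fastq_pair(library, p["reads_1.fastq"], p["reads_2.fastq"])
        write_fastq_pair(unrelated_library, p["unrelated_1.fastq"], p["unrelated_2.fastq"])
        write_truth(truth, WD40_READ_LEN, p["truth.tsv"])
        bundle.paths = p
    return bundle
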