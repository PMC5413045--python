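"""Small-RNA read preprocessing: raw reads to genome-aligned 18-30 nt sequences.

Stage order is fixed: stop-oligo removal -> 3' adapter trimming ->
deduplication -> decoy (non-miRNA ncRNA) filtering -> length filtering ->
exact genome alignment.  Every stage logs read counts (in read units, i.e.
weighted by multiplicity) so totals are conserved.

Decoy filtering mimics a short-query BLASTn screen: a read is removed when
its best plus-strand local alignment (match +1, mismatch -2, gap -2) to any
decoy has identity >= 90% over columns spanning >= 90% of the read length.
Alignment goes through Bio.Align.PairwiseAligner; a score bound is used to
skip hopeless read/decoy pairs (an alignment with identity >= 0.9 over
>= 0.9 L columns scores at least 0.9*0.9*L - 2*0.1*0.9*L = 0.63 L).

Genome alignment is exact-match, both strands, all occurrences; masked (N)
positions never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "ProcessedRead",
    "AlignmentHit",
    "StageLog",
    "drop_stop_oligo",
    "trim_adapter",
    "length_filter",
    "dedupe",
    "decoy_filter",
    "mask_genome",
    "align_perfect",
    "preprocess_library",
    "read_fastx",
    "write_processed_fasta",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class ProcessedRead:
    """A deduplicated read: sequence, multiplicity, originating library."""

    sequence: str
    count: int
    library_id: str


@dataclass(frozen=True)
class AlignmentHit:
    """Perfect-match placement of a read (0-based, half-open)."""

    read: ProcessedRead
    chromosome: str
    start: int
    end: int
    strand: str  # "+" or "-"


class StageLog:
    """Per-stage read accounting; retained + removed == input at every stage."""

    def __init__(self):
        self.rows = []

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.rows.append({"stage": stage, "input": n_in, "retained": n_out,
                          "removed": n_in - n_out})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "input", "retained", "removed"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def drop_stop_oligo(reads: list[str], stop_seq: str) -> list[str]:
    """Remove reads containing the stop oligonucleotide as a substring."""
    if not stop_seq:
        raise ValueError("stop_seq must be non-empty")
    return [r for r in reads if stop_seq not in r]


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Trim the 3' adapter; None when no adapter match is found.

    The read is cut at the leftmost position where a prefix of the adapter of
    length >= ``min_overlap`` matches exactly, or where any adapter prefix
    runs off the read end.  Reads without an adapter match are discarded
    because the insert size is then unknown.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    probe = adapter[:min_overlap]
    pos = read.find(probe)
    while pos != -1:
        if read[pos:pos + len(adapter)] == adapter[:len(read) - pos]:
            return read[:pos]
        pos = read.find(probe, pos + 1)
    # adapter running off the end with < min_overlap columns
    for k in range(min(min_overlap - 1, len(read)), 0, -1):
        if read.endswith(adapter[:k]):
            return read[:-k]
    return None


def length_filter(reads: list, min_len: int = 18, max_len: int = 30) -> list:
    """Keep reads (str or ProcessedRead) with length in [min_len, max_len]."""
    def L(r):
        return len(r.sequence if isinstance(r, ProcessedRead) else r)
    return [r for r in reads if min_len <= L(r) <= max_len]


def dedupe(reads: list[str], library_id: str) -> list[ProcessedRead]:
    """Collapse identical sequences to one ProcessedRead with a count."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    return [ProcessedRead(seq, c, library_id) for seq, c in sorted(counts.items())]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def best_local_identity(query: str, subject: str,
                        aligner: Align.PairwiseAligner | None = None) -> tuple[float, int]:
    """(identity, span) of the best-scoring plus-strand local alignment.

    Identity is the fraction of identical columns of the optimal-score
    alignment; span is its column count (including gap columns).  Returns
    (0.0, 0) when nothing aligns.
    """
    aligner = aligner or _make_aligner()
    alignments = aligner.align(subject, query)
    if len(alignments) == 0:
        return 0.0, 0
    aln = alignments[0]
    counts = aln.counts()
    span = counts.identities + counts.mismatches + counts.gaps
    if span == 0:
        return 0.0, 0
    return counts.identities / span, span


def matches_decoy(read: str, decoy_seqs: list[str], min_identity: float = 0.90,
                  min_coverage: float = 0.90,
                  aligner: Align.PairwiseAligner | None = None) -> bool:
    """True when the read's best local alignment to any decoy passes the gate."""
    aligner = aligner or _make_aligner()
    L = len(read)
    span_needed = min_coverage * L
    # lower bound on the score of any alignment passing both gates
    score_bound = span_needed * (min_identity - 2 * (1 - min_identity))
    for decoy in decoy_seqs:
        if read in decoy:
            return True
        if len(decoy) < 4 or L < 4:
            continue
        if aligner.score(decoy, read) < score_bound:
            continue
        identity, span = best_local_identity(read, decoy, aligner)
        if identity >= min_identity and span >= span_needed:
            return True
    return False


def decoy_filter(reads: list, decoy_seqs: list[str], min_identity: float = 0.90,
                 min_coverage: float = 0.90) -> list:
    """Remove reads homologous to the decoy ncRNA set (plus strand only)."""
    if not decoy_seqs:
        raise ValueError("decoy set must be non-empty")
    aligner = _make_aligner()

    def seq(r):
        return r.sequence if isinstance(r, ProcessedRead) else r

    return [r for r in reads
            if not matches_decoy(seq(r), decoy_seqs, min_identity, min_coverage, aligner)]


def mask_genome(genome: dict[str, str], intervals: list[tuple[str, int, int]]) -> dict[str, str]:
    """Hard-mask (replace with N) the given 0-based half-open intervals."""
    masked = {name: list(seq) for name, seq in genome.items()}
    for chrom, start, end in intervals:
        if chrom not in masked:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(masked[chrom])):
            raise ValueError(f"interval {(chrom, start, end)} out of bounds")
        for i in range(start, end):
            masked[chrom][i] = "N"
    return {name: "".join(seq) for name, seq in masked.items()}


def align_perfect(reads: list[ProcessedRead], genome: dict[str, str]
                  ) -> tuple[list[AlignmentHit], list[ProcessedRead]]:
    """All exact occurrences of each read on both strands of the genome.

    Reads containing N never match (masking rule).  Reads with zero hits are
    returned separately; they feed the known-miRNA rescue pass.
    """
    hits: list[AlignmentHit] = []
    unaligned: list[ProcessedRead] = []
    cache: dict[str, list[tuple[str, int, int, str]]] = {}
    for read in reads:
        seq = read.sequence
        if seq not in cache:
            found = []
            if "N" not in seq:
                rc = reverse_complement(seq)
                for chrom, ref in genome.items():
                    pos = ref.find(seq)
                    while pos != -1:
                        found.append((chrom, pos, pos + len(seq), "+"))
                        pos = ref.find(seq, pos + 1)
                    pos = ref.find(rc)
                    while pos != -1:
                        found.append((chrom, pos, pos + len(seq), "-"))
                        pos = ref.find(rc, pos + 1)
            cache[seq] = found
        if cache[seq]:
            for chrom, s, e, strand in cache[seq]:
                hits.append(AlignmentHit(read, chrom, s, e, strand))
        else:
            unaligned.append(read)
    return hits, unaligned


def preprocess_library(raw_reads: list[str], library_id: str, adapter: str,
                       stop_seq: str, decoy_seqs: list[str], *,
                       min_len: int = 18, max_len: int = 30,
                       min_identity: float = 0.90, min_overlap: int = 6
                       ) -> tuple[list[ProcessedRead], StageLog]:
    """Run the fixed preprocessing cascade on one library's raw reads."""
    log = StageLog()
    n0 = len(raw_reads)
    no_stop = drop_stop_oligo(raw_reads, stop_seq)
    log.add("stop_oligo", n0, len(no_stop))

    trimmed = []
    for r in no_stop:
        t = trim_adapter(r, adapter, min_overlap)
        if t:
            trimmed.append(t)
    log.add("adapter", len(no_stop), len(trimmed))

    unique = dedupe(trimmed, library_id)

    def total(rs):
        return sum(r.count for r in rs)

    no_decoy = decoy_filter(unique, decoy_seqs, min_identity)
    log.add("decoy", total(unique), total(no_decoy))

    sized = length_filter(no_decoy, min_len, max_len)
    log.add("length", total(no_decoy), total(sized))
    return sized, log


# ------------------------------------------------------------------
# I/O
# ------------------------------------------------------------------

def read_fastx(path) -> list[str]:
    """Sequences from a FASTA or FASTQ file (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_processed_fasta(reads: list[ProcessedRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">seq_{i}_x{r.count}\n{r.sequence}\n")


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    rows = [{"read_id": h.read.sequence, "chrom": h.chromosome, "start": h.start,
             "end": h.end, "strand": h.strand, "count": h.read.count} for h in hits]
    pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand", "count"]
                 ).to_csv(path, sep="\t", index=False)
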