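"""Pre-alignment read processing.

Adapter removal (exact match), all-base quality filtering, 18-30 nt length
filtering, collapsing to unique sequences with counts, and optional
in-silico depletion of blocklisted sequences (e.g. a 2S rRNA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class CollapsedRead:
    """A unique post-filtering small-RNA sequence with its read count."""

    sequence: str
    count: int
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class ProcessingStats:
    raw: int = 0
    kept: int = 0
    low_quality: int = 0
    too_short: int = 0
    too_long: int = 0
    no_adapter: int = 0  # informational; such reads are kept whole, then length-filtered
    depleted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def trim_adapter(seq: str, adapter: str, min_prefix: int = 5) -> tuple[str, bool]:
    """Remove the adapter and everything 3' of it.

    The full adapter is located by exact substring match; failing that, a
    terminal exact match of an adapter prefix (>= ``min_prefix`` nt) at the
    read end is trimmed, since the adapter may be truncated by the read
    length. Returns (trimmed sequence, adapter_found).
    """
    pos = seq.find(adapter)
    if pos >= 0:
        return seq[:pos], True
    max_k = min(len(adapter) - 1, len(seq))
    for k in range(max_k, min_prefix - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k], True
    return seq, False


def process_fastq(
    fastq: str | Path,
    adapter: str,
    q_min: int = 20,
    len_min: int = 18,
    len_max: int = 30,
    library_id: str = "",
) -> tuple[list[CollapsedRead], ProcessingStats]:
    """Trim, filter, and collapse a FASTQ (phred+33) file.

    A read is kept only if, after adapter removal, every retained base has
    phred quality >= ``q_min`` and the insert length is within
    [``len_min``, ``len_max``]. Survivors are collapsed to unique sequences
    with summed counts, ordered by descending count then sequence.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    stats = ProcessingStats()
    counter: Counter[str] = Counter()
    q_cut = chr(q_min + 33)
    with open(fastq) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{index + 1}: {exc}") from exc
            index += 1
            stats.raw += 1
            seq = seq.upper()
            insert, found = trim_adapter(seq, adapter)
            if not found:
                stats.no_adapter += 1
            qual = qual[: len(insert)]
            if any(q < q_cut for q in qual):
                stats.low_quality += 1
                continue
            if len(insert) < len_min:
                stats.too_short += 1
                continue
            if len(insert) > len_max:
                stats.too_long += 1
                continue
            counter[insert] += 1
            stats.kept += 1
    reads = [
        CollapsedRead(sequence=s, count=c, library_id=library_id)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return reads, stats


def deplete_sequences(
    reads: Sequence[CollapsedRead],
    blocklist: Iterable[str],
    stats: ProcessingStats | None = None,
) -> list[CollapsedRead]:
    """Remove reads equal to, or substrings of, any blocklist sequence.

    Matching is sense-strand only (blocklisted species are sequenced in
    their annotated orientation). An empty blocklist is the identity.
    """
    block = [b.upper() for b in blocklist]
    kept: list[CollapsedRead] = []
    n_depleted = 0
    for read in reads:
        if any(read.sequence in b for b in block):
            n_depleted += read.count
        else:
            kept.append(read)
    if stats is not None:
        stats.depleted += n_depleted
    return kept


def load_blocklist(fasta: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")]


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads in the count-encoded header dialect ``>seq{i}_x{count}``."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f">seq{i + 1}_x{read.count}\n{read.sequence}\n")


def read_collapsed_fasta(path: str | Path, library_id: str = "") -> list[CollapsedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        reads.append(CollapsedRead(sequence=str(rec.seq).upper(), count=count, library_id=library_id))
    return reads


def write_stats_tsv(stats: ProcessingStats, path: str | Path, library_id: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("library_id\t" + "\t".join(stats.as_dict()) + "\n")
        fh.write(library_id + "\t" + "\t".join(str(v) for v in stats.as_dict().values()) + "\n")
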