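"""Exact and bounded-mismatch alignment plus priority-ordered annotation.

The exact-match index reports all perfect occurrences of a query on both
strands (equivalent to an ungapped aligner in 0-mismatch mode). Reads
mapping to multiple loci receive uniform 1/k weights. Each read gets one
representative class by intersecting the union of its hits with the
annotation layers in priority order:

    miRNA > structural small RNA (tRNA/rRNA/snoRNA/snRNA/ncRNA)
    > cis-NAT (21 nt only) > TE consensus > exon > intron > intergenic

TE subtypes split by read length: 21 nt -> TE-siRNA, >= 23 nt -> TE-piRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._intervals import Interval, IntervalIndex
from ._seq import revcomp, validate_dna
from .reference import ReferenceBundle

CLASS_PRIORITY = (
    "mirna",
    "structural",
    "cisnat",
    "te",
    "exon",
    "intron",
    "intergenic",
)


@dataclass(frozen=True)
class AlignmentHit:
    sequence: str
    contig: str
    start: int  # 0-based, half-open end
    end: int
    strand: str
    match_flags: tuple[bool, ...] = ()
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("hit span does not equal read length")


@dataclass(frozen=True)
class WeightedAssignment:
    sequence: str
    hit: AlignmentHit
    weight: float


@dataclass(frozen=True)
class ClassAnnotation:
    sequence: str
    representative_class: str
    subtype: str = ""


class ExactIndex:
    """Exact-match lookup of short queries against a set of reference contigs.

    Seeds on the first ``k`` bases (queries must be >= k long) and verifies
    the full match; both strands are searched.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 14):
        self.k = k
        self._contigs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._contigs.items():
            validate_dna(seq, context=f"contig {name}")
        if not self._contigs:
            raise ValueError("reference must be non-empty")
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self._contigs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((name, pos))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        out = []
        for contig, pos in self._seeds.get(query[: self.k], ()):
            if self._contigs[contig].startswith(query, pos):
                out.append((contig, pos))
        return out

    def query(self, sequence: str) -> list[AlignmentHit]:
        """All perfect hits of ``sequence`` on either strand, deterministic order."""
        sequence = sequence.upper()
        if len(sequence) < self.k:
            raise ValueError(f"query shorter than seed length k={self.k}")
        hits = []
        for contig, pos in self._occurrences(sequence):
            hits.append(AlignmentHit(sequence, contig, pos, pos + len(sequence), "+"))
        rc = revcomp(sequence)
        for contig, pos in self._occurrences(rc):
            hits.append(AlignmentHit(sequence, contig, pos, pos + len(sequence), "-"))
        hits.sort(key=lambda h: (h.contig, h.start, h.strand))
        return hits


def align_mismatch(
    query: str,
    reference: str,
    max_mm: int = 3,
    offsets: Sequence[int] | None = None,
    allow_overhang: bool = False,
) -> AlignmentHit | None:
    """Best ungapped alignment of ``query`` against ``reference``.

    Scans every offset (or only the supplied candidate offsets); the best
    hit has the fewest mismatches, ties broken leftmost. Returns None when
    the minimum exceeds ``max_mm``. With ``allow_overhang`` (used when
    realigning full reads against a pre-miRNA), query positions falling
    outside the reference count as mismatches.
    """
    query, reference = query.upper(), reference.upper()
    n, m = len(query), len(reference)
    if offsets is None:
        if n > m:
            return None
        offsets = range(m - n + 1)
    best: tuple[int, int, tuple[bool, ...]] | None = None
    for off in offsets:
        if not allow_overhang and (off < 0 or off + n > m):
            continue
        flags = tuple(
            0 <= off + i < m and query[i] == reference[off + i] for i in range(n)
        )
        mm = n - sum(flags)
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, off, flags)
    if best is None:
        return None
    mm, off, flags = best
    return AlignmentHit(
        sequence=query,
        contig="",
        start=off,
        end=off + n,
        strand="+",
        match_flags=flags,
        n_mismatches=mm,
    )


def distribute_multimappers(hits: Sequence[AlignmentHit]) -> list[WeightedAssignment]:
    """Uniform 1/k weight per locus; weights sum to 1 per read."""
    if not hits:
        raise ValueError("read has no hits")
    w = 1.0 / len(hits)
    return [WeightedAssignment(h.sequence, h, w) for h in hits]


class Annotator:
    """Priority-ordered representative-class assignment for mapped reads."""

    def __init__(self, bundle: ReferenceBundle, te_index: ExactIndex | None = None):
        self.bundle = bundle
        self._mirna_idx = IntervalIndex(loc.hairpin for loc in bundle.mirnas)
        self._layer_idx = {
            layer: IntervalIndex(bundle.layers.get(layer, []))
            for layer in ("structural", "cisnat", "exon", "intron")
        }
        if te_index is None and bundle.te_consensus:
            te_index = ExactIndex(bundle.te_consensus)
        self.te_index = te_index

    def annotate_class(self, sequence: str, hits: Sequence[AlignmentHit]) -> ClassAnnotation:
        """Representative class from the union of all hits of a read.

        Sense-strand overlap is required for miRNA/structural/exon/intron;
        cis-NAT overlap is strand-agnostic (siRNAs arise from both strands)
        and additionally requires a 21-nt read; TE membership is an exact
        match to a consensus sequence on either strand.
        """
        if not hits:
            raise ValueError("annotate_class requires >= 1 genome hit")
        seq = sequence.upper()
        for h in hits:
            if self._mirna_idx.any_overlap(h.contig, h.start, h.end, h.strand):
                return ClassAnnotation(seq, "mirna")
        for h in hits:
            iv = next(self._layer_idx["structural"].overlapping(h.contig, h.start, h.end, h.strand), None)
            if iv is not None:
                return ClassAnnotation(seq, "structural", subtype=iv.subtype)
        if len(seq) == 21:
            for h in hits:
                if self._layer_idx["cisnat"].any_overlap(h.contig, h.start, h.end):
                    return ClassAnnotation(seq, "cisnat", subtype="cisNAT-siRNA")
        if self.te_index is not None and self.te_index.query(seq):
            if len(seq) == 21:
                subtype = "TE-siRNA"
            elif len(seq) >= 23:
                subtype = "TE-piRNA"
            else:
                subtype = ""
            return ClassAnnotation(seq, "te", subtype=subtype)
        for layer in ("exon", "intron"):
            for h in hits:
                if self._layer_idx[layer].any_overlap(h.contig, h.start, h.end, h.strand):
                    return ClassAnnotation(seq, layer)
        return ClassAnnotation(seq, "intergenic")


def class_composition(
    annotations: Sequence[ClassAnnotation], counts: Sequence[int]
) -> pd.DataFrame:
    """Weighted read counts and fractions per representative class.

    ``counts`` are the collapsed-read counts parallel to ``annotations``.
    Fractions sum to 1 over mapped reads.
    """
    if not annotations:
        raise ValueError("empty library: no annotated reads")
    if len(annotations) != len(counts):
        raise ValueError("annotations and counts must be parallel")
    totals: dict[tuple[str, str], float] = {}
    for ann, c in zip(annotations, counts):
        key = (ann.representative_class, ann.subtype)
        totals[key] = totals.get(key, 0.0) + c
    rows = [
        {"class": cls, "subtype": sub, "weighted_count": n}
        for (cls, sub), n in sorted(totals.items())
    ]
    df = pd.DataFrame(rows)
    df["fraction"] = df["weighted_count"] / df["weighted_count"].sum()
    order = {c: i for i, c in enumerate(CLASS_PRIORITY)}
    return df.sort_values(
        ["class", "subtype"], key=lambda s: s.map(order).fillna(99) if s.name == "class" else s
    ).reset_index(drop=True)


def pirna_cluster_distribution(
    te_reads: Sequence[tuple[str, Sequence[AlignmentHit], int]],
    clusters: Iterable[Interval],
) -> pd.DataFrame:
    """Per-cluster weighted counts of TE-siRNAs (21 nt) and TE-piRNAs (>= 23 nt).

    ``te_reads`` is (sequence, genome hits, count) for TE-class reads. Each
    read's count is split 1/k over its genome hits; hits inside a cluster
    accrue to that cluster, the rest to "outside".
    """
    clusters = list(clusters)
    idx = IntervalIndex(clusters)
    names = [iv.name for iv in clusters] + ["outside"]
    table = {name: {"TE-siRNA": 0.0, "TE-piRNA": 0.0} for name in names}
    for seq, hits, count in te_reads:
        if len(seq) == 21:
            subtype = "TE-siRNA"
        elif len(seq) >= 23:
            subtype = "TE-piRNA"
        else:
            continue
        if not hits:
            continue
        w = count / len(hits)
        for h in hits:
            iv = next(idx.overlapping(h.contig, h.start, h.end), None)
            table[iv.name if iv is not None else "outside"][subtype] += w
    df = pd.DataFrame(table).T
    df.index.name = "cluster"
    return df.reset_index()
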