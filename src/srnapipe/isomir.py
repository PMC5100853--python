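"""isomiR classification: canonical / noncanonical / 3' non-templated addition.

A read that perfectly matches the genome is canonical when its interval
equals an annotated mature miRNA locus, and noncanonical when it falls
inside the "noncanonical window" (mature locus extended 2 nt at the 5' end
and 5 nt at the 3' end) without equalling the mature interval.

NTA detection operates on reads with NO perfect genome match: the last
three nucleotides are trimmed, the trimmed body realigned perfectly to the
genome, hits falling inside a noncanonical window are kept, and the full
untrimmed read is then realigned (ungapped, <= 3 mismatches) against the
pre-miRNA. Only terminal mismatch patterns MMX, MXX, XXX over the last
three positions qualify; the tail is the contiguous mismatching suffix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._intervals import Interval
from .align import AlignmentHit, ExactIndex, align_mismatch
from .reference import ReferenceBundle, read_mirna_gff3, _read_fasta

logger = logging.getLogger(__name__)

ISOFORM_KINDS = ("canonical", "noncanonical", "nta")

_PATTERNS = {
    (True, True, False): ("MMX", 1),
    (True, False, False): ("MXX", 2),
    (False, False, False): ("XXX", 3),
}


@dataclass(frozen=True)
class MirnaAnnotation:
    """One mature miRNA with its hairpin context and noncanonical window."""

    mirna_id: str
    hairpin_id: str
    contig: str
    strand: str
    hairpin_iv: tuple[int, int]
    mature_iv: tuple[int, int]
    window_iv: tuple[int, int]
    hairpin_seq: str
    mature_seq: str
    window_clipped: bool = False

    def local_offset(self, start: int, end: int) -> int:
        """Hairpin-local (5'->3' oriented) offset of a genomic interval start."""
        if self.strand == "+":
            return start - self.hairpin_iv[0]
        return self.hairpin_iv[1] - end

    def five_prime_offset(self, start: int, end: int) -> int:
        if self.strand == "+":
            return abs(start - self.mature_iv[0])
        return abs(end - self.mature_iv[1])

    def window_contains(self, contig: str, start: int, end: int, strand: str) -> bool:
        return (
            contig == self.contig
            and strand == self.strand
            and self.window_iv[0] <= start
            and end <= self.window_iv[1]
        )


@dataclass(frozen=True)
class IsoformCall:
    sequence: str
    mirna_id: str
    isoform: str  # canonical | noncanonical | nta | unassigned
    tail: str = ""
    match_pattern: str = ""
    mirna_ids: tuple[str, ...] = ()  # all equally-good loci (multi-mapper split)

    def __post_init__(self) -> None:
        if self.isoform == "nta" and not (1 <= len(self.tail) <= 3):
            raise ValueError("NTA tail must be 1-3 nt")


def build_mirna_refs(
    gff3: str | Path,
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    ext5: int = 2,
    ext3: int = 5,
) -> list[MirnaAnnotation]:
    """Build annotations from a miRBase-dialect GFF3 plus hairpin/mature FASTAs."""
    loci = read_mirna_gff3(gff3)
    hairpins = _read_fasta(hairpin_fasta)
    matures = _read_fasta(mature_fasta)
    annotations = []
    for locus in loci:
        for m in locus.matures:
            annotations.append(
                _make_annotation(
                    m,
                    locus.hairpin,
                    hairpins[locus.hairpin.name],
                    matures[m.name],
                    ext5,
                    ext3,
                )
            )
    return annotations


def build_mirna_refs_from_bundle(
    bundle: ReferenceBundle, ext5: int = 2, ext3: int = 5
) -> list[MirnaAnnotation]:
    annotations = []
    for locus in bundle.mirnas:
        for m in locus.matures:
            annotations.append(
                _make_annotation(
                    m,
                    locus.hairpin,
                    bundle.hairpin_seq(locus),
                    bundle.mature_seq(m),
                    ext5,
                    ext3,
                )
            )
    return annotations


def _make_annotation(
    mature: Interval,
    hairpin: Interval,
    hairpin_seq: str,
    mature_seq: str,
    ext5: int,
    ext3: int,
) -> MirnaAnnotation:
    if not hairpin.contains(mature.contig, mature.start, mature.end, mature.strand):
        raise ValueError(f"mature {mature.name} not within hairpin {hairpin.name}")
    if mature.strand == "+":
        w0, w1 = mature.start - ext5, mature.end + ext3
    else:
        w0, w1 = mature.start - ext3, mature.end + ext5
    clipped = w0 < hairpin.start or w1 > hairpin.end
    if clipped:
        logger.warning("noncanonical window of %s clipped to hairpin bounds", mature.name)
    w0, w1 = max(w0, hairpin.start), min(w1, hairpin.end)
    return MirnaAnnotation(
        mirna_id=mature.name,
        hairpin_id=hairpin.name,
        contig=mature.contig,
        strand=mature.strand,
        hairpin_iv=(hairpin.start, hairpin.end),
        mature_iv=(mature.start, mature.end),
        window_iv=(w0, w1),
        hairpin_seq=hairpin_seq.upper(),
        mature_seq=mature_seq.upper(),
        window_clipped=clipped,
    )


def classify_templated(
    sequence: str,
    genome_hits: Sequence[AlignmentHit],
    annotations: Sequence[MirnaAnnotation],
) -> IsoformCall:
    """Classify a perfectly genome-matched read as canonical / noncanonical.

    Canonical requires interval equality with a mature locus (equivalently,
    sequence identity with the mature miRNA); noncanonical requires strict
    containment in the noncanonical window. Canonical wins over
    noncanonical across a multi-mapper's hits; equally-good loci are all
    retained (for fractional weights) with ties on the reported primary
    locus broken by smallest 5'-offset, then lexicographic id.
    """
    candidates: dict[str, list[tuple[int, str]]] = {"canonical": [], "noncanonical": []}
    for h in genome_hits:
        for ann in annotations:
            if h.contig != ann.contig or h.strand != ann.strand:
                continue
            if (h.start, h.end) == ann.mature_iv:
                candidates["canonical"].append((0, ann.mirna_id))
            elif ann.window_contains(h.contig, h.start, h.end, h.strand):
                candidates["noncanonical"].append(
                    (ann.five_prime_offset(h.start, h.end), ann.mirna_id)
                )
    for isoform in ("canonical", "noncanonical"):
        found = sorted(set(candidates[isoform]))
        if found:
            ids = tuple(sorted({mid for _, mid in found}))
            return IsoformCall(
                sequence=sequence,
                mirna_id=found[0][1],
                isoform=isoform,
                mirna_ids=ids,
            )
    return IsoformCall(sequence=sequence, mirna_id="", isoform="unassigned")


def detect_nta(
    sequence: str,
    genome_index: ExactIndex,
    annotations: Sequence[MirnaAnnotation],
    max_mm: int = 3,
    min_body: int = 15,
) -> IsoformCall | None:
    """3'-NTA detection for reads without any perfect genome match.

    Returns an NTA call (tail = the contiguous mismatching 3' suffix of
    length 1-3) or None. A read with a perfect genome match anywhere is not
    an NTA candidate. Body positions beyond the pre-miRNA 3' end count as
    mismatches.
    """
    sequence = sequence.upper()
    if genome_index.query(sequence):
        return None  # perfect match wins; handled by the templated route
    trimmed = sequence[:-3]
    if len(trimmed) < min_body:
        return None
    try:
        body_hits = genome_index.query(trimmed)
    except ValueError:
        return None
    found: list[tuple[int, str, str, str]] = []  # (5'offset, id, tail, pattern)
    for h in body_hits:
        for ann in annotations:
            if not ann.window_contains(h.contig, h.start, h.end, h.strand):
                continue
            off = ann.local_offset(h.start, h.end)
            realigned = align_mismatch(
                sequence, ann.hairpin_seq, max_mm=max_mm, offsets=[off], allow_overhang=True
            )
            if realigned is None:
                continue
            flags = realigned.match_flags
            if not all(flags[:-3]):
                continue  # mismatches are only tolerated at the 3'-most 3 nt
            key = _PATTERNS.get(flags[-3:])
            if key is None:
                continue
            pattern, tail_len = key
            found.append(
                (ann.five_prime_offset(h.start, h.end), ann.mirna_id, sequence[-tail_len:], pattern)
            )
    if not found:
        return None
    found.sort()
    _, primary_id, tail, pattern = found[0]
    ids = tuple(sorted({mid for _, mid, t, p in found if (t, p) == (tail, pattern)}))
    return IsoformCall(
        sequence=sequence,
        mirna_id=primary_id,
        isoform="nta",
        tail=tail,
        match_pattern=pattern,
        mirna_ids=ids,
    )


def quantify_isoforms(
    calls: Sequence[IsoformCall],
    counts: Sequence[int],
    mirna_ids: Sequence[str],
) -> pd.DataFrame:
    """Weighted per-miRNA counts of the three isoform types.

    Each call's read count is split uniformly across its equally-good loci.
    All requested miRNAs are retained as rows (zeros when absent).
    """
    if len(calls) != len(counts):
        raise ValueError("calls and counts must be parallel")
    table = pd.DataFrame(
        0.0, index=pd.Index(sorted(set(mirna_ids)), name="mirna_id"), columns=list(ISOFORM_KINDS)
    )
    for call, n in zip(calls, counts):
        if call.isoform not in ISOFORM_KINDS:
            continue
        targets = call.mirna_ids or (call.mirna_id,)
        w = n / len(targets)
        for mid in targets:
            if mid in table.index:
                table.loc[mid, call.isoform] += w
    return table


def isoform_summary(components: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-sample-set isoform totals and percentages.

    ``components`` has one row per sample set and RPM columns
    canonical / noncanonical / nta. Percentages are component / total x 100
    rounded to ``decimals``.
    """
    out = components[list(ISOFORM_KINDS)].copy()
    out["total"] = out.sum(axis=1)
    for kind in ISOFORM_KINDS:
        out[f"{kind}_pct"] = (100.0 * out[kind] / out["total"]).round(decimals)
    return out


def distributions(
    calls: Sequence[IsoformCall], counts: Sequence[int]
) -> dict[str, pd.Series]:
    """Length histogram and first-nucleotide frequencies of canonical calls,
    plus tail-sequence frequencies of NTA calls. Each table sums to 1."""
    length: dict[int, float] = {}
    first: dict[str, float] = {}
    tails: dict[str, float] = {}
    for call, n in zip(calls, counts):
        if call.isoform == "canonical":
            length[len(call.sequence)] = length.get(len(call.sequence), 0.0) + n
            first[call.sequence[0]] = first.get(call.sequence[0], 0.0) + n
        elif call.isoform == "nta":
            tails[call.tail] = tails.get(call.tail, 0.0) + n

    def _norm(d: dict) -> pd.Series:
        s = pd.Series(d, dtype=float).sort_index()
        return s / s.sum() if len(s) else s

    return {
        "length": _norm(length),
        "first_nt": _norm(first),
        "tail": _norm(tails),
    }
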