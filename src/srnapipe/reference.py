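"""Reference bundle: genome sequence plus annotation layers.

The bundle groups everything the annotation stages need: the genome FASTA,
miRNA loci (hairpins with nested mature arms), BED layers for structural
RNAs / cis-NAT loci / piRNA clusters / exons / introns, and transposable
element (TE) consensus sequences. Round-trips to a plain-text directory
(FASTA / GFF3 / BED6) so every stage can also run from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._intervals import Interval
from ._seq import revcomp

LAYER_NAMES = ("structural", "cisnat", "pirna_cluster", "exon", "intron", "te_copy")


@dataclass(frozen=True)
class MirnaLocus:
    """A hairpin (pre-miRNA) locus with its mature arm(s).

    ``hairpin`` and each mature interval are genomic, 0-based half-open,
    and every mature interval must lie within the hairpin.
    """

    hairpin: Interval
    matures: tuple[Interval, ...]

    def __post_init__(self) -> None:
        for m in self.matures:
            if not self.hairpin.contains(m.contig, m.start, m.end, m.strand):
                raise ValueError(
                    f"mature {m.name} [{m.start},{m.end}) not within hairpin "
                    f"{self.hairpin.name} [{self.hairpin.start},{self.hairpin.end})"
                )


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    mirnas: list[MirnaLocus] = field(default_factory=list)
    layers: dict[str, list[Interval]] = field(default_factory=dict)
    te_consensus: dict[str, str] = field(default_factory=dict)

    # ---- sequence access -------------------------------------------------
    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.genome[contig][start:end]
        return seq if strand == "+" else revcomp(seq)

    def hairpin_seq(self, locus: MirnaLocus) -> str:
        h = locus.hairpin
        return self.fetch(h.contig, h.start, h.end, h.strand)

    def mature_seq(self, mature: Interval) -> str:
        return self.fetch(mature.contig, mature.start, mature.end, mature.strand)

    # ---- I/O -------------------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["genome"] = outdir / "genome.fa"
        _write_fasta(paths["genome"], self.genome.items())

        paths["te"] = outdir / "te_consensus.fa"
        _write_fasta(paths["te"], self.te_consensus.items())

        paths["hairpin"] = outdir / "hairpin.fa"
        _write_fasta(
            paths["hairpin"],
            ((loc.hairpin.name, self.hairpin_seq(loc)) for loc in self.mirnas),
        )
        paths["mature"] = outdir / "mature.fa"
        _write_fasta(
            paths["mature"],
            ((m.name, self.mature_seq(m)) for loc in self.mirnas for m in loc.matures),
        )

        paths["gff3"] = outdir / "mirna.gff3"
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for i, loc in enumerate(self.mirnas):
                h = loc.hairpin
                fh.write(
                    f"{h.contig}\t.\tmiRNA_primary_transcript\t{h.start + 1}\t{h.end}\t.\t"
                    f"{h.strand}\t.\tID=MI{i:07d};Name={h.name}\n"
                )
                for j, m in enumerate(loc.matures):
                    fh.write(
                        f"{m.contig}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                        f"ID=MIMAT{i:05d}{j:02d};Name={m.name};Derives_from=MI{i:07d}\n"
                    )

        for layer, intervals in self.layers.items():
            p = outdir / f"{layer}.bed"
            with open(p, "w") as fh:
                for iv in intervals:
                    name = f"{iv.subtype}:{iv.name}" if iv.subtype else iv.name
                    fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            paths[layer] = p

        # in-silico depletion blocklist: any structural locus flagged "2S_rRNA"
        two_s = [
            (iv.name, self.fetch(iv.contig, iv.start, iv.end, iv.strand))
            for iv in self.layers.get("structural", [])
            if iv.name == "2S_rRNA"
        ]
        if two_s:
            paths["blocklist"] = outdir / "blocklist.fa"
            _write_fasta(paths["blocklist"], two_s)
        return paths

    @classmethod
    def from_dir(cls, refdir: str | Path) -> "ReferenceBundle":
        refdir = Path(refdir)
        genome = _read_fasta(refdir / "genome.fa")
        te_path = refdir / "te_consensus.fa"
        te = _read_fasta(te_path) if te_path.exists() else {}
        mirnas = read_mirna_gff3(refdir / "mirna.gff3") if (refdir / "mirna.gff3").exists() else []
        layers = {}
        for layer in LAYER_NAMES:
            p = refdir / f"{layer}.bed"
            if p.exists():
                layers[layer] = read_bed(p)
        return cls(genome=genome, mirnas=mirnas, layers=layers, te_consensus=te)


def _write_fasta(path: Path, records) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED6 layer; names of the form ``subtype:name`` split back out."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            subtype = ""
            if ":" in name:
                subtype, name = name.split(":", 1)
            intervals.append(
                Interval(contig, start, end, strand=strand, name=name, subtype=subtype)
            )
    return intervals


def read_mirna_gff3(path: str | Path) -> list[MirnaLocus]:
    """Parse a miRBase-dialect GFF3 (pre-miRNA features with mature children)."""
    hairpins: dict[str, Interval] = {}
    children: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            iv = Interval(
                contig, int(start) - 1, int(end), strand=strand, name=attr.get("Name", attr.get("ID", ""))
            )
            if ftype == "miRNA_primary_transcript":
                hairpins[attr["ID"]] = iv
            elif ftype == "miRNA":
                children.setdefault(attr["Derives_from"], []).append(iv)
    loci = []
    for hid, hiv in hairpins.items():
        loci.append(MirnaLocus(hairpin=hiv, matures=tuple(children.get(hid, ()))))
    return loci
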