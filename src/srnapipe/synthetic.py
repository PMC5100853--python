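"""Synthetic reference bundle and simulated small-RNA libraries.

Generates a toy genome carrying miRNA hairpins (with annotated mature
arms), structural RNA loci, TE copies, cis-NAT pairs and gene models, and
then simulates FASTQ libraries for a 2-genotype x 3-timepoint x 3-replicate
design with known per-read ground truth (source locus, isoform type, tail).

miRNA abundances follow five planted expression classes (A-E) whose
genotype x timepoint mean-RPM templates mimic maternal loading and zygotic
synthesis, with loss/delay of zygotic synthesis in the mutant. Per-library
counts are negative-binomial around those means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from ._intervals import Interval
from ._seq import revcomp
from .reference import MirnaLocus, ReferenceBundle

GENOTYPES = ("wt", "mut")
TIMEPOINTS = ("UF0_2h", "F0_2h", "F2_4h")
CLASS_LABELS = ("A", "B", "C", "D", "E")

DesignPoint = tuple[str, str, int]  # (genotype, timepoint, replicate)

#: Mean-RPM templates per class, (UF0_2h, F0_2h, F2_4h). Wild-type values
#: track the reported per-class averages; the mutant shows absent (class A)
#: or delayed/reduced (B, C) zygotic synthesis and near-wild-type behaviour
#: for the maternal-dominated classes (D, E).
CLASS_PROFILES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {"wt": (1.4, 18.0, 72.6), "mut": (1.2, 1.1, 2.1)},
    "B": {"wt": (23.7, 702.0, 5557.0), "mut": (23.9, 38.9, 320.0)},
    "C": {"wt": (1301.0, 7821.0, 24042.0), "mut": (1301.0, 2100.0, 5752.0)},
    "D": {"wt": (46.1, 58.0, 71.9), "mut": (73.9, 28.1, 47.8)},
    "E": {"wt": (1031.0, 1269.0, 1798.0), "mut": (1502.0, 659.0, 1166.0)},
}

DEFAULT_ISOFORM_FRACTIONS = {
    "canonical": 0.70,
    "templated_5p": 0.02,
    "templated_3p": 0.10,
    "nta": 0.18,
}

#: Tail frequencies (DNA alphabet; U is written T). Dominated by mono/di
#: adenylation, with uridylation next.
DEFAULT_NTA_TAIL_FREQS = {
    "A": 0.49,
    "AA": 0.16,
    "T": 0.10,
    "AAA": 0.05,
    "C": 0.06,
    "G": 0.02,
    "TT": 0.05,
    "AT": 0.04,
    "CC": 0.03,
}

DEFAULT_BACKGROUND_FRACTIONS = {
    "structural": 0.40,
    "te_pirna": 0.22,
    "te_sirna": 0.10,
    "cisnat": 0.05,
    "exon": 0.10,
    "intron": 0.05,
    "intergenic": 0.08,
}

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

TRUTH_COLUMNS = (
    "read_id",
    "source_class",
    "subtype",
    "mirna_id",
    "isoform_planted",
    "isoform",
    "tail_planted",
    "tail",
    "insert",
    "low_quality",
)


class SizingError(ValueError):
    """Genome too small to place all requested features."""


def full_design() -> list[DesignPoint]:
    return [
        (g, t, r) for g in GENOTYPES for t in TIMEPOINTS for r in (1, 2, 3)
    ]


def library_id(point: DesignPoint) -> str:
    g, t, r = point
    return f"{g}_{t}_r{r}"


@dataclass
class SimulationConfig:
    n_mirnas_per_class: int = 4
    n_te_families: int = 3
    n_structural_loci: int = 8
    n_cisnat_pairs: int = 2
    genome_length: int = 120_000
    design: list[DesignPoint] = field(default_factory=full_design)
    library_depth_mean: float = 50_000.0
    nb_dispersion: float = 0.1
    isoform_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOFORM_FRACTIONS)
    )
    nta_tail_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NTA_TAIL_FREQS)
    )
    background_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_FRACTIONS)
    )
    adapter: str = DEFAULT_ADAPTER
    raw_read_length: int = 55
    low_quality_fraction: float = 0.01
    profile_jitter_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirnas_per_class", "n_te_families", "n_structural_loci", "n_cisnat_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.genome_length <= 0 or self.library_depth_mean <= 0:
            raise ValueError("genome_length and library_depth_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for label, probs in (
            ("isoform_fractions", self.isoform_fractions),
            ("nta_tail_freqs", self.nta_tail_freqs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} sums to {total}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{label} has negative entries")
        unknown = set(self.isoform_fractions) - {
            "canonical", "templated_5p", "templated_3p", "nta",
        }
        if unknown:
            raise ValueError(f"unknown isoform kinds: {sorted(unknown)}")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        for g, t, r in self.design:
            if g not in GENOTYPES or t not in TIMEPOINTS:
                raise ValueError(f"bad design point {(g, t, r)}")

    @property
    def n_mirnas(self) -> int:
        return self.n_mirnas_per_class * len(CLASS_LABELS)


@dataclass
class TruthTable:
    """Planted ground truth: class label and expected RPM per miRNA."""

    config: SimulationConfig
    bundle: ReferenceBundle
    mirna_class: pd.Series  # mirna_id -> class label
    expected_rpm: pd.DataFrame  # index mirna_id, columns (genotype, timepoint)

    def expected_rpm_at(self, genotype: str, timepoint: str) -> pd.Series:
        return self.expected_rpm[(genotype, timepoint)]


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

_HAIRPIN_LEN = 90
_MATURE_OFFSET = 15  # 5' offset of the mature arm within the hairpin
_MATURE_LEN = 22


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class _Allocator:
    """Sequential left-to-right feature placement with random gaps."""

    def __init__(self, rng: np.random.Generator, genome_length: int):
        self.rng = rng
        self.cursor = 100
        self.limit = genome_length - 100

    def take(self, length: int) -> tuple[int, int]:
        start = self.cursor + int(self.rng.integers(60, 220))
        end = start + length
        if end > self.limit:
            raise SizingError(
                f"genome too small: needed up to {end} bases, have {self.limit}"
            )
        self.cursor = end
        return start, end


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the toy genome and all annotation layers. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    genome = list(_random_dna(rng, config.genome_length))
    contig = "chr_sim"
    alloc = _Allocator(rng, config.genome_length)

    # --- miRNA hairpins with one mature arm each
    mirnas: list[MirnaLocus] = []
    for i in range(config.n_mirnas):
        start, end = alloc.take(_HAIRPIN_LEN)
        strand = "+" if rng.random() < 0.5 else "-"
        hairpin = Interval(contig, start, end, strand=strand, name=f"sim-mir-{i + 1}")
        a, b = _MATURE_OFFSET, _MATURE_OFFSET + _MATURE_LEN
        if strand == "+":
            ms, me = start + a, start + b
        else:
            ms, me = end - b, end - a
        mature = Interval(contig, ms, me, strand=strand, name=f"sim-miR-{i + 1}-5p")
        mirnas.append(MirnaLocus(hairpin=hairpin, matures=(mature,)))

    # --- structural RNA loci (first one is a 30-nt 2S rRNA for depletion tests)
    structural: list[Interval] = []
    subtypes = ["rRNA", "tRNA", "snoRNA", "snRNA", "ncRNA"]
    for i in range(config.n_structural_loci):
        if i == 0:
            length, name, subtype = 30, "2S_rRNA", "rRNA"
        else:
            length = int(rng.integers(80, 200))
            subtype = subtypes[i % len(subtypes)]
            name = f"sim-{subtype}-{i}"
        start, end = alloc.take(length)
        strand = "+" if rng.random() < 0.5 else "-"
        structural.append(Interval(contig, start, end, strand=strand, name=name, subtype=subtype))

    # --- TE consensus sequences, each inserted at two genomic copies
    te_consensus: dict[str, str] = {}
    te_copies: list[Interval] = []
    for j in range(config.n_te_families):
        te_len = int(rng.integers(300, 600))
        name = f"sim-TE{j + 1}"
        consensus = _random_dna(rng, te_len)
        te_consensus[name] = consensus
        for copy_idx, strand in enumerate(("+", "-" if rng.random() < 0.5 else "+")):
            start, end = alloc.take(te_len)
            inserted = consensus if strand == "+" else revcomp(consensus)
            genome[start:end] = list(inserted)
            te_copies.append(
                Interval(contig, start, end, strand=strand, name=f"{name}.copy{copy_idx + 1}", subtype=name)
            )

    # --- piRNA clusters around the first copy of up to two TE families
    clusters = []
    for k, copy in enumerate(te_copies[::2][:2]):
        clusters.append(
            Interval(
                contig,
                max(0, copy.start - 150),
                copy.end + 150,
                strand="+",
                name=f"sim-cluster-{k + 1}",
            )
        )

    # --- cis-NAT pairs: overlapping antisense transcripts
    cisnat: list[Interval] = []
    for i in range(config.n_cisnat_pairs):
        start, end = alloc.take(480)
        cisnat.append(Interval(contig, start, start + 300, strand="+", name=f"sim-cisnat-{i + 1}a"))
        cisnat.append(Interval(contig, start + 180, end, strand="-", name=f"sim-cisnat-{i + 1}b"))

    # --- simple gene models (exon-intron-exon)
    exons: list[Interval] = []
    introns: list[Interval] = []
    for i in range(3):
        strand = "+" if rng.random() < 0.5 else "-"
        s1, e1 = alloc.take(200)
        exons.append(Interval(contig, s1, e1, strand=strand, name=f"sim-gene-{i + 1}.ex1"))
        s2, e2 = alloc.take(150)
        introns.append(Interval(contig, s2, e2, strand=strand, name=f"sim-gene-{i + 1}.in1"))
        s3, e3 = alloc.take(200)
        exons.append(Interval(contig, s3, e3, strand=strand, name=f"sim-gene-{i + 1}.ex2"))

    # deliberately overlap an exon with the first hairpin so the priority
    # rule (miRNA before exon) is exercised
    h0 = mirnas[0].hairpin
    exons.append(
        Interval(contig, max(0, h0.start - 10), h0.end + 10, strand=h0.strand, name="sim-gene-ov.ex")
    )

    return ReferenceBundle(
        genome={contig: "".join(genome)},
        mirnas=mirnas,
        layers={
            "structural": structural,
            "cisnat": cisnat,
            "pirna_cluster": clusters,
            "exon": exons,
            "intron": introns,
            "te_copy": te_copies,
        },
        te_consensus=te_consensus,
    )


def build_truth(config: SimulationConfig, bundle: ReferenceBundle) -> TruthTable:
    """Assign class labels and per-miRNA expected RPM profiles.

    miRNAs are assigned to classes in contiguous blocks; each miRNA gets a
    lognormal abundance jitter applied to its whole profile so class shape
    is preserved while members differ in level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    mirna_ids = [loc.matures[0].name for loc in bundle.mirnas]
    labels = [CLASS_LABELS[i // config.n_mirnas_per_class] for i in range(len(mirna_ids))]
    jitter = np.exp(rng.normal(0.0, config.profile_jitter_sd, len(mirna_ids)))
    cols = pd.MultiIndex.from_product([GENOTYPES, TIMEPOINTS], names=["genotype", "timepoint"])
    values = np.zeros((len(mirna_ids), len(cols)))
    for i, lab in enumerate(labels):
        for j, (g, t) in enumerate(cols):
            values[i, j] = CLASS_PROFILES[lab][g][TIMEPOINTS.index(t)] * jitter[i]
    expected = pd.DataFrame(values, index=pd.Index(mirna_ids, name="mirna_id"), columns=cols)
    return TruthTable(
        config=config,
        bundle=bundle,
        mirna_class=pd.Series(labels, index=expected.index, name="class"),
        expected_rpm=expected,
    )


def generate_truth(config: SimulationConfig) -> TruthTable:
    return build_truth(config, generate_reference(config))


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p)
    out[mean <= 0] = 0
    return out


def _effective_nta(tail: str, template: str) -> tuple[str, str]:
    """Resolve a planted tail against the genomic template.

    Returns ``(isoform, effective_tail)`` where isoform is ``nta`` when a
    clean non-templated suffix remains, ``noncanonical`` when the whole tail
    happens to match the template (fully templated extension), and
    ``nta_invalid`` when mismatches are interrupted by a terminal match
    (no contiguous mismatching suffix -> not detectable as NTA).
    """
    flags = [i < len(template) and tail[i] == template[i] for i in range(len(tail))]
    if all(flags):
        return "noncanonical", ""  # fully templated extension
    run = 0
    for f in reversed(flags):
        if f:
            break
        run += 1
    if run > 0 and all(flags[: len(flags) - run]):
        return "nta", tail[-run:]
    return "nta_invalid", ""


def _mirna_read(
    rng: np.random.Generator,
    bundle: ReferenceBundle,
    locus: MirnaLocus,
    isoform: str,
    tail_choices: tuple[list[str], list[float]],
) -> tuple[str, str, str, str]:
    """Build one miRNA read -> (insert, effective_isoform, planted_tail, effective_tail)."""
    hp = bundle.hairpin_seq(locus)
    a, b = _MATURE_OFFSET, _MATURE_OFFSET + _MATURE_LEN
    if isoform == "canonical":
        return hp[a:b], "canonical", "", ""
    if isoform == "templated_5p":
        ext = int(rng.integers(1, 3))  # window allows up to 2 nt upstream
        return hp[a - ext : b], "noncanonical", "", ""
    if isoform == "templated_3p":
        ext = int(rng.integers(1, 6))  # window allows up to 5 nt downstream
        return hp[a : b + ext], "noncanonical", "", ""
    if isoform == "nta":
        tails, probs = tail_choices
        tail = tails[rng.choice(len(tails), p=probs)]
        template = hp[b : b + len(tail)]
        effective, eff_tail = _effective_nta(tail, template)
        return hp[a:b] + tail, effective, tail, eff_tail
    raise ValueError(f"unknown isoform kind {isoform!r}")


def _interval_read(rng: np.random.Generator, bundle, iv: Interval, length_range, strand=None) -> str:
    lo, hi = length_range
    length = int(rng.integers(lo, min(hi, len(iv)) + 1))
    start = iv.start + int(rng.integers(0, len(iv) - length + 1))
    use_strand = strand if strand is not None else iv.strand
    return bundle.fetch(iv.contig, start, start + length, use_strand)


def _intergenic_gaps(bundle: ReferenceBundle, min_len: int = 40) -> list[Interval]:
    occupied: list[tuple[int, int]] = [(m.hairpin.start, m.hairpin.end) for m in bundle.mirnas]
    for ivs in bundle.layers.values():
        occupied.extend((iv.start, iv.end) for iv in ivs)
    occupied.sort()
    contig = next(iter(bundle.genome))
    glen = len(bundle.genome[contig])
    gaps, cursor = [], 0
    for s, e in occupied + [(glen, glen)]:
        if s - cursor >= min_len:
            gaps.append(Interval(contig, cursor, s, strand="+", name="intergenic"))
        cursor = max(cursor, e)
    return gaps


def simulate_library(
    truth: TruthTable,
    design_point: DesignPoint,
    fastq_path: str | Path,
    truth_path: str | Path,
) -> pd.DataFrame:
    """Simulate one library, writing FASTQ (phred+33) and a truth sidecar TSV.

    Returns the sidecar as a DataFrame. One independent RNG stream per
    library, derived from (config.seed, design point).
    """
    config = truth.config
    if design_point not in config.design:
        raise ValueError(f"design point {design_point} not in configured design")
    genotype, timepoint, replicate = design_point
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, 777, GENOTYPES.index(genotype), TIMEPOINTS.index(timepoint), replicate]
        )
    )
    bundle = truth.bundle
    lib = library_id(design_point)
    depth = config.library_depth_mean

    iso_kinds = sorted(config.isoform_fractions)
    iso_probs = np.array([config.isoform_fractions[k] for k in iso_kinds])
    tails = sorted(config.nta_tail_freqs)
    tail_probs = [config.nta_tail_freqs[t] for t in tails]
    tail_choices = (tails, list(np.array(tail_probs) / np.sum(tail_probs)))

    rows: list[tuple] = []  # (insert, source_class, subtype, mirna_id, iso_planted, iso, tailp, tail)

    # --- miRNA reads
    rpm = truth.expected_rpm_at(genotype, timepoint)
    means = rpm.to_numpy() * depth / 1e6
    counts = _nb_counts(rng, means, config.nb_dispersion)
    for locus, n in zip(bundle.mirnas, counts):
        if n == 0:
            continue
        mid = locus.matures[0].name
        kinds = rng.choice(len(iso_kinds), size=int(n), p=iso_probs)
        for k in kinds:
            planted = iso_kinds[k]
            insert, effective, tailp, tail = _mirna_read(rng, bundle, locus, planted, tail_choices)
            rows.append((insert, "mirna", "", mid, planted, effective, tailp, tail))

    # --- background reads
    bg_frac = {k: v for k, v in config.background_fractions.items() if v > 0}
    bg_total_mean = max(0.0, depth * (1.0 - rpm.sum() / 1e6)) * sum(bg_frac.values())
    n_bg = rng.poisson(bg_total_mean)
    bg_classes = sorted(bg_frac)
    bg_p = np.array([bg_frac[c] for c in bg_classes])
    bg_counts = rng.multinomial(n_bg, bg_p / bg_p.sum())
    gaps = _intergenic_gaps(bundle)
    cisnat_overlaps = _cisnat_overlap_regions(bundle)
    for cls, n in zip(bg_classes, bg_counts):
        for _ in range(int(n)):
            if cls == "structural":
                iv = bundle.layers["structural"][rng.integers(len(bundle.layers["structural"]))]
                insert = _interval_read(rng, bundle, iv, (18, 30))
                rows.append((insert, "structural", iv.name, "", "", "", "", ""))
            elif cls == "te_sirna":
                iv = bundle.layers["te_copy"][rng.integers(len(bundle.layers["te_copy"]))]
                strand = "+" if rng.random() < 0.5 else "-"
                insert = _interval_read(rng, bundle, iv, (21, 21), strand=strand)
                rows.append((insert, "te_sirna", iv.subtype, "", "", "", "", ""))
            elif cls == "te_pirna":
                iv = bundle.layers["te_copy"][rng.integers(len(bundle.layers["te_copy"]))]
                strand = "+" if rng.random() < 0.5 else "-"
                insert = _interval_read(rng, bundle, iv, (23, 29), strand=strand)
                rows.append((insert, "te_pirna", iv.subtype, "", "", "", "", ""))
            elif cls == "cisnat":
                iv = cisnat_overlaps[rng.integers(len(cisnat_overlaps))]
                strand = "+" if rng.random() < 0.5 else "-"
                insert = _interval_read(rng, bundle, iv, (21, 21), strand=strand)
                rows.append((insert, "cisnat", "", "", "", "", "", ""))
            elif cls in ("exon", "intron"):
                layer = bundle.layers[cls]
                iv = layer[rng.integers(len(layer))]
                insert = _interval_read(rng, bundle, iv, (19, 26))
                rows.append((insert, cls, "", "", "", "", "", ""))
            elif cls == "intergenic":
                iv = gaps[rng.integers(len(gaps))]
                insert = _interval_read(rng, bundle, iv, (18, 30))
                rows.append((insert, "intergenic", "", "", "", "", "", ""))
            else:
                raise ValueError(f"unknown background class {cls!r}")

    order = rng.permutation(len(rows))
    fastq_path, truth_path = Path(fastq_path), Path(truth_path)
    sidecar_rows = []
    with open(fastq_path, "w") as fq:
        for out_idx, row_idx in enumerate(order):
            insert, source, subtype, mid, isop, iso, tailp, tail = rows[row_idx]
            read_id = f"{lib}:r{out_idx:07d}"
            filler_n = max(0, config.raw_read_length - len(insert) - len(config.adapter))
            raw = (insert + config.adapter + _random_dna(rng, filler_n))[: config.raw_read_length]
            qual = ["I"] * len(raw)
            low_q = rng.random() < config.low_quality_fraction
            if low_q:
                # the failing base lands inside the insert so the flag always
                # corresponds to a read the quality filter must discard
                qual[int(rng.integers(0, max(len(insert), 1)))] = "4"  # Q19
            fq.write(f"@{read_id}\n{raw}\n+\n{''.join(qual)}\n")
            sidecar_rows.append(
                (read_id, source, subtype, mid, isop, iso, tailp, tail, insert, int(low_q))
            )
    sidecar = pd.DataFrame(sidecar_rows, columns=list(TRUTH_COLUMNS))
    sidecar.to_csv(truth_path, sep="\t", index=False)
    return sidecar


def _cisnat_overlap_regions(bundle: ReferenceBundle) -> list[Interval]:
    """Overlap region of each annotated antisense pair (the siRNA source)."""
    ivs = bundle.layers.get("cisnat", [])
    pairs: dict[str, list[Interval]] = {}
    for iv in ivs:
        pairs.setdefault(iv.name[:-1], []).append(iv)
    regions = []
    for key, members in sorted(pairs.items()):
        if len(members) == 2:
            lo = max(members[0].start, members[1].start)
            hi = min(members[0].end, members[1].end)
            if hi > lo:
                regions.append(Interval(members[0].contig, lo, hi, strand="+", name=key))
    return regions or ivs


def simulate_design(
    truth: TruthTable, outdir: str | Path
) -> pd.DataFrame:
    """Simulate every library in the configured design; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for point in truth.config.design:
        lib = library_id(point)
        fq = outdir / f"{lib}.fastq"
        tr = outdir / f"{lib}.truth.tsv"
        simulate_library(truth, point, fq, tr)
        records.append(
            {
                "library_id": lib,
                "genotype": point[0],
                "timepoint": point[1],
                "replicate": point[2],
                "fastq": str(fq),
                "truth": str(tr),
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def make_overlap_demo(seed: int, universe_size: int = 2000, enrichment: float = 2.0):
    """Toy gene lists with planted enrichment for the overlap stage demo.

    Returns (universe_size, list_a, list_b) where membership in list_b is
    ``enrichment`` times more likely inside list_a than outside.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    genes = [f"g{i:05d}" for i in range(universe_size)]
    in_a = rng.random(universe_size) < 0.25
    p_b = np.where(in_a, min(1.0, 0.15 * enrichment), 0.15)
    in_b = rng.random(universe_size) < p_b
    list_a = {g for g, f in zip(genes, in_a) if f}
    list_b = {g for g, f in zip(genes, in_b) if f}
    return universe_size, list_a, list_b
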