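"""Tests for the exact-match index, mismatch alignment, weights and annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe._intervals import Interval
from srnapipe._seq import revcomp
from srnapipe.align import (
    Annotator,
    ExactIndex,
    align_mismatch,
    class_composition,
    distribute_multimappers,
    pirna_cluster_distribution,
)
from srnapipe.reference import ReferenceBundle


def _naive_hits(query, genome):
    """Brute-force oracle: scan both strands with str.find."""
    found = []
    for contig, seq in genome.items():
        for target, strand in ((query, "+"), (revcomp(query), "-")):
            start = seq.find(target)
            while start >= 0:
                found.append((contig, start, strand))
                start = seq.find(target, start + 1)
    return sorted(found)


class TestExactIndex:
    def test_unique_hit_coordinates(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        idx = ExactIndex({"c": seq})
        query = seq[100:120]
        hits = idx.query(query)
        assert [(h.contig, h.start, h.end, h.strand) for h in hits] == [("c", 100, 120, "+")]

    def test_both_strand_hits(self):
        core = "ACGTTGCAAGGCTTACGGTC"
        genome = {"c": "TTTT" + core + "GGGG" + revcomp(core) + "AAAA"}
        idx = ExactIndex(genome)
        hits = idx.query(core)
        assert {(h.start, h.strand) for h in hits} == {(4, "+"), (28, "-")}

    def test_random_reads_recovered(self, bundle, genome_index):
        rng = np.random.default_rng(1)
        contig = next(iter(bundle.genome))
        seq = bundle.genome[contig]
        for _ in range(1000):
            length = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(seq) - length))
            query = seq[start : start + length]
            hits = genome_index.query(query)
            assert any(h.start == start and h.strand == "+" for h in hits)

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            ExactIndex({"c": "ACGTXACGT" * 5})

    def test_short_query_rejected(self, genome_index):
        with pytest.raises(ValueError, match="seed length"):
            genome_index.query("ACGT")

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_oracle_equivalence(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        genome = {"g": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])}
        idx = ExactIndex(genome)
        start = data.draw(st.integers(0, 270))
        query = genome["g"][start : start + 25]
        got = sorted((h.contig, h.start, h.strand) for h in idx.query(query))
        assert got == _naive_hits(query, genome)


def _hamming_oracle(query, reference, max_mm):
    best = None
    for off in range(len(reference) - len(query) + 1):
        mm = sum(a != b for a, b in zip(query, reference[off : off + len(query)]))
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, off)
    return best


class TestAlignMismatch:
    def test_identical(self):
        hit = align_mismatch("ACGTACGT", "ACGTACGT")
        assert hit.n_mismatches == 0 and all(hit.match_flags)

    def test_four_mismatches_rejected(self):
        assert align_mismatch("AAAAAAAA", "AATATATT", max_mm=3) is None

    def test_query_longer_than_reference(self):
        assert align_mismatch("ACGTACGTACGT", "ACGT") is None

    def test_overhang_counts_as_mismatch(self):
        hit = align_mismatch("ACGTAC", "ACGT", offsets=[0], allow_overhang=True)
        assert hit.n_mismatches == 2 and hit.match_flags == (True,) * 4 + (False, False)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), max_mm=st.integers(0, 4))
    def test_brute_force_oracle(self, seed, max_mm):
        rng = np.random.default_rng(seed)
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        query = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
        hit = align_mismatch(query, ref, max_mm=max_mm)
        oracle = _hamming_oracle(query, ref, max_mm)
        if oracle is None:
            assert hit is None
        else:
            assert (hit.n_mismatches, hit.start) == oracle


class TestDistributeMultimappers:
    @pytest.mark.parametrize("k,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_uniform_weights(self, genome_index, bundle, k, expected):
        contig = next(iter(bundle.genome))
        seq = bundle.genome[contig]
        hits = genome_index.query(seq[50:70])[:1] * k
        weighted = distribute_multimappers(hits)
        assert all(w.weight == expected for w in weighted)
        assert sum(w.weight for w in weighted) == pytest.approx(1.0, abs=1e-9)

    def test_no_hits_error(self):
        with pytest.raises(ValueError):
            distribute_multimappers([])


def _toy_bundle():
    """Tiny hand-built genome: one hairpin, one tRNA, one cis-NAT pair, one
    exon and one TE consensus copy at known coordinates."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2_000)])
    te = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    genome = seq[:1500] + te + seq[1600:]
    hairpin = Interval("c", 100, 190, "+", name="hp1")
    mature = Interval("c", 115, 137, "+", name="miR-1")
    from srnapipe.reference import MirnaLocus

    return ReferenceBundle(
        genome={"c": genome},
        mirnas=[MirnaLocus(hairpin=hairpin, matures=(mature,))],
        layers={
            "structural": [Interval("c", 300, 400, "+", name="tRNA-1", subtype="tRNA")],
            "cisnat": [
                Interval("c", 500, 800, "+", name="nat1a"),
                Interval("c", 680, 980, "-", name="nat1b"),
            ],
            "exon": [
                Interval("c", 1100, 1300, "+", name="ex1"),
                Interval("c", 90, 200, "+", name="ex-over-mir"),
            ],
            "intron": [Interval("c", 1300, 1450, "+", name="in1")],
            "pirna_cluster": [],
            "te_copy": [Interval("c", 1500, 1600, "+", name="te1.copy1", subtype="te1")],
        },
        te_consensus={"te1": te},
    )


@pytest.fixture(scope="module")
def toy():
    bundle = _toy_bundle()
    return bundle, ExactIndex(bundle.genome), Annotator(bundle)


class TestAnnotateClass:
    def test_mirna_beats_exon(self, toy):
        bundle, idx, ann = toy
        read = bundle.genome["c"][115:137]  # inside hairpin AND inside ex-over-mir
        a = ann.annotate_class(read, idx.query(read))
        assert a.representative_class == "mirna"

    def test_structural_subtype(self, toy):
        bundle, idx, ann = toy
        read = bundle.genome["c"][310:332]
        a = ann.annotate_class(read, idx.query(read))
        assert (a.representative_class, a.subtype) == ("structural", "tRNA")

    def test_cisnat_requires_21nt(self, toy):
        bundle, idx, ann = toy
        read21 = bundle.genome["c"][700:721]
        read22 = bundle.genome["c"][700:722]
        a21 = ann.annotate_class(read21, idx.query(read21))
        a22 = ann.annotate_class(read22, idx.query(read22))
        assert a21.representative_class == "cisnat"
        assert a22.representative_class == "intergenic"  # no other layer there

    def test_te_length_subtypes(self, toy):
        bundle, idx, ann = toy
        for length, subtype in ((21, "TE-siRNA"), (25, "TE-piRNA"), (22, "")):
            read = bundle.genome["c"][1510 : 1510 + length]
            a = ann.annotate_class(read, idx.query(read))
            assert (a.representative_class, a.subtype) == ("te", subtype)

    def test_exon_and_intron_and_intergenic(self, toy):
        bundle, idx, ann = toy
        for start, expected in ((1150, "exon"), (1320, "intron"), (1700, "intergenic")):
            read = bundle.genome["c"][start : start + 22]
            a = ann.annotate_class(read, idx.query(read))
            assert a.representative_class == expected

    def test_unmapped_read_is_error(self, toy):
        _, _, ann = toy
        with pytest.raises(ValueError):
            ann.annotate_class("ACGT" * 6, [])

    def test_priority_monotonicity(self, toy):
        """Adding a lower-priority layer never changes a read's class."""
        bundle, idx, _ = toy
        annotator_full = Annotator(bundle)
        stripped = ReferenceBundle(
            genome=bundle.genome,
            mirnas=bundle.mirnas,
            layers={**bundle.layers, "exon": [], "intron": []},
            te_consensus=bundle.te_consensus,
        )
        annotator_stripped = Annotator(stripped)
        rng = np.random.default_rng(3)
        for _ in range(200):
            start = int(rng.integers(0, 1970))
            read = bundle.genome["c"][start : start + 22]
            hits = idx.query(read)
            full = annotator_full.annotate_class(read, hits).representative_class
            stripped_cls = annotator_stripped.annotate_class(read, hits).representative_class
            if stripped_cls not in ("exon", "intron", "intergenic"):
                assert full == stripped_cls


class TestClassComposition:
    def test_pure_mirna(self, toy):
        bundle, idx, ann = toy
        read = bundle.genome["c"][115:137]
        a = ann.annotate_class(read, idx.query(read))
        df = class_composition([a], [10])
        assert df.loc[df["class"] == "mirna", "fraction"].item() == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            class_composition([], [])

    def test_sidecar_composition_recovered(self, sim_library, bundle, genome_index):
        """Weighted class fractions match the planted composition within 3 sigma."""
        from srnapipe.preprocess import process_fastq

        fastq, sidecar = sim_library
        reads, _ = process_fastq(fastq, "TGGAATTCTCGGGTGCCAAGG")
        annotator = Annotator(bundle)
        anns, counts = [], []
        for r in reads:
            hits = genome_index.query(r.sequence)
            if hits:
                anns.append(annotator.annotate_class(r.sequence, hits))
                counts.append(r.count)
        df = class_composition(anns, counts).groupby("class")["weighted_count"].sum()
        total = df.sum()
        truth_counts = sidecar[sidecar.low_quality == 0]["source_class"].value_counts()
        for cls, expected in (
            ("structural", truth_counts.get("structural", 0)),
            ("cisnat", truth_counts.get("cisnat", 0)),
            ("intron", truth_counts.get("intron", 0)),
        ):
            p = expected / truth_counts.sum()
            sigma = np.sqrt(p * (1 - p) * total)
            assert abs(df.get(cls, 0) - p * total) < 3 * sigma + 10, cls

    def test_weight_conservation(self, sim_library, genome_index):
        from srnapipe.preprocess import process_fastq

        fastq, _ = sim_library
        reads, _ = process_fastq(fastq, "TGGAATTCTCGGGTGCCAAGG")
        total_weight = 0.0
        mapped_counts = 0
        for r in reads[:2000]:
            hits = genome_index.query(r.sequence)
            if hits:
                mapped_counts += r.count
                total_weight += sum(w.weight for w in distribute_multimappers(hits)) * r.count
        assert total_weight == pytest.approx(mapped_counts, rel=1e-9)


class TestPirnaClusterDistribution:
    def _mk_read(self, bundle, idx, start, length):
        seq = bundle.genome["c"][start : start + length]
        return seq, idx.query(seq), 1

    def test_all_inside_one_cluster(self, toy):
        bundle, idx, _ = toy
        clusters = [Interval("c", 1490, 1610, "+", name="cl1")]
        reads = [self._mk_read(bundle, idx, 1510 + i, 25) for i in range(5)]
        df = pirna_cluster_distribution(reads, clusters).set_index("cluster")
        assert df.loc["cl1", "TE-piRNA"] == 5
        assert df.loc["outside", "TE-piRNA"] == 0

    def test_split_70_30(self, toy):
        bundle, idx, _ = toy
        clusters = [
            Interval("c", 1490, 1555, "+", name="clA"),
            Interval("c", 1555, 1610, "+", name="clB"),
        ]
        reads = [self._mk_read(bundle, idx, 1500, 25) for _ in range(7)]
        reads += [self._mk_read(bundle, idx, 1570, 25) for _ in range(3)]
        df = pirna_cluster_distribution(reads, clusters).set_index("cluster")
        assert df.loc["clA", "TE-piRNA"] == 7 and df.loc["clB", "TE-piRNA"] == 3

    def test_empty_cluster_file(self, toy):
        bundle, idx, _ = toy
        reads = [self._mk_read(bundle, idx, 1510, 25)]
        df = pirna_cluster_distribution(reads, []).set_index("cluster")
        assert df.loc["outside", "TE-piRNA"] == 1
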