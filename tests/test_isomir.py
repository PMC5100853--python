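"""Tests for canonical/noncanonical classification and 3'-NTA detection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from srnapipe._intervals import Interval
from srnapipe.align import ExactIndex
from srnapipe.isomir import (
    IsoformCall,
    build_mirna_refs,
    build_mirna_refs_from_bundle,
    classify_templated,
    detect_nta,
    distributions,
    isoform_summary,
    quantify_isoforms,
)
from srnapipe.reference import MirnaLocus, ReferenceBundle


def _flat_bundle(strand="+"):
    """One hairpin on a small genome with mature at hairpin-local [15, 37)."""
    rng = np.random.default_rng(7)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    hairpin = Interval("c", 200, 290, strand, name="hp1")
    if strand == "+":
        mature = Interval("c", 215, 237, strand, name="miR-x")
    else:
        mature = Interval("c", 253, 275, strand, name="miR-x")
    return ReferenceBundle(genome={"c": genome}, mirnas=[MirnaLocus(hairpin, (mature,))])


@pytest.fixture(scope="module", params=["+", "-"])
def flat(request):
    bundle = _flat_bundle(request.param)
    refs = build_mirna_refs_from_bundle(bundle)
    return bundle, ExactIndex(bundle.genome), refs


class TestBuildMirnaRefs:
    def test_window_arithmetic_plus(self):
        bundle = _flat_bundle("+")
        ann = build_mirna_refs_from_bundle(bundle)[0]
        assert ann.mature_iv == (215, 237)
        assert ann.window_iv == (213, 242)  # -2 at 5', +5 at 3'

    def test_window_arithmetic_minus(self):
        bundle = _flat_bundle("-")
        ann = build_mirna_refs_from_bundle(bundle)[0]
        assert ann.mature_iv == (253, 275)
        assert ann.window_iv == (248, 277)  # genomic: -5 low side, +2 high side

    def test_window_clipped_at_hairpin_edge(self, caplog):
        rng = np.random.default_rng(8)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        hairpin = Interval("c", 100, 160, "+", name="hp")
        mature = Interval("c", 100, 122, "+", name="m")  # flush with hairpin start
        bundle = ReferenceBundle(genome={"c": genome}, mirnas=[MirnaLocus(hairpin, (mature,))])
        ann = build_mirna_refs_from_bundle(bundle)[0]
        assert ann.window_iv[0] == 100 and ann.window_clipped

    def test_mature_outside_hairpin_rejected(self):
        hairpin = Interval("c", 100, 160, "+", name="hp")
        mature = Interval("c", 90, 112, "+", name="m")
        with pytest.raises(ValueError, match="within hairpin"):
            MirnaLocus(hairpin, (mature,))

    def test_from_files(self, ref_dir, bundle):
        refs = build_mirna_refs(
            ref_dir / "mirna.gff3", ref_dir / "hairpin.fa", ref_dir / "mature.fa"
        )
        assert len(refs) == len(bundle.mirnas)
        for ann in refs:
            m0, m1 = ann.mature_iv
            w0, w1 = ann.window_iv
            h0, h1 = ann.hairpin_iv
            assert h0 <= w0 <= m0 < m1 <= w1 <= h1
            assert len(ann.mature_seq) == m1 - m0
            off = ann.local_offset(m0, m1)
            assert ann.hairpin_seq[off : off + len(ann.mature_seq)] == ann.mature_seq


class TestClassifyTemplated:
    def test_exact_mature_is_canonical(self, flat):
        bundle, idx, refs = flat
        read = refs[0].mature_seq
        call = classify_templated(read, idx.query(read), refs)
        assert call.isoform == "canonical" and call.mirna_id == "miR-x"

    def test_templated_3p_extension_is_noncanonical(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        read = ann.hairpin_seq[off : off + 24]  # +2 templated 3' nt
        call = classify_templated(read, idx.query(read), refs)
        assert call.isoform == "noncanonical"

    def test_three_nt_upstream_is_unassigned(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        read = ann.hairpin_seq[off - 3 : off + 22]  # starts 3 nt outside the -2 window
        call = classify_templated(read, idx.query(read), refs)
        assert call.isoform == "unassigned"

    def test_truncation_inside_window_is_noncanonical(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        read = ann.hairpin_seq[off : off + 20]  # 2 nt shorter than mature
        call = classify_templated(read, idx.query(read), refs)
        assert call.isoform == "noncanonical"


def _nta_read(ann, tail):
    off = ann.local_offset(*ann.mature_iv)
    return ann.hairpin_seq[off : off + 22] + tail


def _mismatch_base(template_char):
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[template_char]


class TestDetectNta:
    def test_mono_tail_mmx(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        tail = _mismatch_base(ann.hairpin_seq[off + 22])
        read = _nta_read(ann, tail)
        call = detect_nta(read, idx, refs)
        assert call is not None
        assert (call.isoform, call.tail, call.match_pattern) == ("nta", tail, "MMX")

    def test_tri_tail_xxx(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        tail = "".join(_mismatch_base(ann.hairpin_seq[off + 22 + i]) for i in range(3))
        call = detect_nta(_nta_read(ann, tail), idx, refs)
        assert call is not None
        assert (call.tail, call.match_pattern) == (tail, "XXX")

    def test_interior_mismatch_rejected(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        read = list(ann.mature_seq)
        read[5] = _mismatch_base(read[5])
        assert detect_nta("".join(read), idx, refs) is None

    def test_perfect_match_elsewhere_wins(self, flat):
        """A read with any perfect genome match is not an NTA candidate."""
        bundle, idx, refs = flat
        contig = next(iter(bundle.genome))
        read = bundle.genome[contig][600:624]  # perfect match away from the hairpin
        assert detect_nta(read, idx, refs) is None

    def test_short_body_rejected(self, flat):
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        tail = _mismatch_base(ann.hairpin_seq[off + 15])
        short = ann.hairpin_seq[off : off + 15] + tail  # trimmed body would be 13 nt
        assert detect_nta(short, idx, refs) is None

    def test_trim_realign_consistency(self, flat):
        """Removing a detected tail yields a canonical/noncanonical read."""
        _, idx, refs = flat
        ann = refs[0]
        off = ann.local_offset(*ann.mature_iv)
        for tail_len in (1, 2, 3):
            tail = "".join(
                _mismatch_base(ann.hairpin_seq[off + 22 + i]) for i in range(tail_len)
            )
            read = _nta_read(ann, tail)
            call = detect_nta(read, idx, refs)
            assert call is not None and call.tail == tail
            body = read[: len(read) - len(call.tail)]
            templated = classify_templated(body, idx.query(body), refs)
            assert templated.isoform in ("canonical", "noncanonical")


class TestSidecarOracle:
    def test_all_planted_isoforms_recovered(self, sim_library, genome_index, mirna_refs):
        """Every planted miRNA read classifies to its effective truth, per read."""
        _, sidecar = sim_library
        rows = sidecar[(sidecar.low_quality == 0) & (sidecar.source_class == "mirna")]
        cache = {}
        for seq, grp in rows.groupby("insert"):
            hits = genome_index.query(seq)
            if hits:
                call = classify_templated(seq, hits, mirna_refs)
            else:
                call = detect_nta(seq, genome_index, mirna_refs)
            cache[seq] = call
        for _, row in rows.iterrows():
            call = cache[row["insert"]]
            if row["isoform"] in ("canonical", "noncanonical", "nta"):
                assert call is not None and call.isoform == row["isoform"]
                assert call.tail == row["tail"]
                assert call.mirna_id == row["mirna_id"]
            else:  # nta_invalid: must NOT be called NTA
                assert call is None or call.isoform == "unassigned"


class TestQuantifyIsoforms:
    def test_canonical_only(self):
        calls = [IsoformCall("SEQ", "miR-1", "canonical", mirna_ids=("miR-1",))]
        table = quantify_isoforms(calls, [100], ["miR-1", "miR-2"])
        assert table.loc["miR-1"].tolist() == [100.0, 0.0, 0.0]
        assert table.loc["miR-2"].tolist() == [0.0, 0.0, 0.0]  # absent row retained

    def test_multimapper_split(self):
        calls = [IsoformCall("SEQ", "miR-1", "canonical", mirna_ids=("miR-1", "miR-2"))]
        table = quantify_isoforms(calls, [10], ["miR-1", "miR-2"])
        assert table["canonical"].tolist() == [5.0, 5.0]

    def test_mixture_recovered(self, sim_library, genome_index, mirna_refs, truth):
        _, sidecar = sim_library
        rows = sidecar[(sidecar.low_quality == 0) & (sidecar.source_class == "mirna")]
        calls, counts = [], []
        for seq, grp in rows.groupby("insert"):
            hits = genome_index.query(seq)
            call = (
                classify_templated(seq, hits, mirna_refs)
                if hits
                else detect_nta(seq, genome_index, mirna_refs)
            )
            if call is not None and call.isoform in ("canonical", "noncanonical", "nta"):
                calls.append(call)
                counts.append(len(grp))
        table = quantify_isoforms(calls, counts, list(truth.mirna_class.index))
        expected = rows.groupby("isoform").size()
        for kind in ("canonical", "noncanonical", "nta"):
            assert table[kind].sum() == pytest.approx(expected.get(kind, 0), abs=1e-6)


class TestIsoformSummary:
    def test_table_shape_percentages(self):
        components = pd.DataFrame(
            {
                "canonical": [103105.0, 744043.2],
                "noncanonical": [13902.3, 92198.8],
                "nta": [32837.7, 63846.7],
            },
            index=["set1", "set2"],
        )
        out = isoform_summary(components)
        assert out.loc["set1", "canonical_pct"] == 68.8
        assert out.loc["set2", "canonical_pct"] == 82.7

    def test_single_nonzero_component(self):
        components = pd.DataFrame(
            {"canonical": [50.0], "noncanonical": [0.0], "nta": [0.0]}, index=["s"]
        )
        out = isoform_summary(components)
        assert out.loc["s", "canonical_pct"] == 100.0


class TestDistributions:
    def test_trivial_canonical(self):
        calls = [IsoformCall("T" + "A" * 21, "m", "canonical", mirna_ids=("m",))]
        d = distributions(calls, [5])
        assert d["length"].to_dict() == {22: 1.0}
        assert d["first_nt"].to_dict() == {"T": 1.0}
        assert d["tail"].empty

    def test_tail_mix_recovered(self, sim_library):
        _, sidecar = sim_library
        nta_rows = sidecar[(sidecar.isoform == "nta") & (sidecar.low_quality == 0)]
        calls = [
            IsoformCall(r["insert"], r["mirna_id"], "nta", tail=r["tail"], match_pattern="MMX")
            for _, r in nta_rows.iterrows()
        ]
        d = distributions(calls, [1] * len(calls))
        empirical = nta_rows["tail"].value_counts(normalize=True)
        for tail, freq in empirical.items():
            assert d["tail"][tail] == pytest.approx(freq, abs=1e-9)
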