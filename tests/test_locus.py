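import pandas as pd
import pytest

from crisprcensus.annotation import AnnotatedProtein, ProfileHit, ProteinRecord
from crisprcensus.locus import (CrisprArray, assemble_neighborhoods, classify_all,
                                classify_locus, is_complete, trim_boundaries)


def gene_table(n, genome="G1", contig="c1", strands=None):
    rows = []
    for i in range(1, n + 1):
        start = 1 + (i - 1) * 350
        rows.append({"protein_id": f"p{i:03d}", "genome_id": genome,
                     "contig": contig, "start": start, "end": start + 299,
                     "strand": (strands[i - 1] if strands else "+"), "rank": i})
    return pd.DataFrame(rows)


def annotate(genes, family_at):
    """family_at: {rank: family}; one strong hit per annotated gene."""
    out = {}
    for r in genes.itertuples():
        fam = family_at.get(r.rank)
        if fam is None:
            continue
        rec = ProteinRecord(r.protein_id, r.genome_id, r.contig, r.start,
                            r.end, r.strand, r.rank)
        out[r.protein_id] = AnnotatedProtein(
            rec, [ProfileHit(r.protein_id, fam, 1e-10, 200.0, 0.9, 1, 90)])
    return out


class TestAssembly:
    def test_flank_window_around_single_seed(self, reg2025, profile_map):
        genes = gene_table(40)
        anns = annotate(genes, {20: "cas1"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=10)
        assert len(loci) == 1
        lo, hi = loci[0].rank_range
        assert (lo, hi) == (10, 30)
        assert len(loci[0].members) == 21

    def test_truncation_at_contig_end(self, reg2025, profile_map):
        genes = gene_table(12)
        anns = annotate(genes, {3: "cas1"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=10)
        assert loci[0].rank_range == (1, 12)

    def test_nearby_seeds_merge_into_one_locus(self, reg2025, profile_map):
        genes = gene_table(60)
        anns = annotate(genes, {20: "cas1", 25: "cas9"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=10)
        assert len(loci) == 1
        assert loci[0].rank_range == (10, 35)
        assert sorted(loci[0].seeds) == ["p020", "p025"]

    def test_merge_is_order_independent_and_nonoverlapping(self, reg2025, profile_map):
        genes = gene_table(100)
        for seeds in ([20, 25, 70], [70, 25, 20], [25, 70, 20]):
            anns = annotate(genes, {r: "cas1" for r in seeds})
            loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map)
            ranges = sorted(l.rank_range for l in loci)
            assert ranges == [(10, 35), (60, 80)]
            for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
                assert b1 < a2

    def test_missing_seed_protein_is_an_error(self, reg2025, profile_map):
        genes = gene_table(5)
        rec = ProteinRecord("ghost", "G1", "c1", 1, 300, "+", 99)
        anns = {"ghost": AnnotatedProtein(
            rec, [ProfileHit("ghost", "cas1", 1e-10, 200.0, 0.9, 1, 90)])}
        with pytest.raises(KeyError, match="ghost"):
            assemble_neighborhoods(genes, anns, [], reg2025, profile_map)

    def test_array_attachment_within_flank_distance(self, reg2025, profile_map):
        genes = gene_table(60)
        anns = annotate(genes, {30: "cas1"})
        near = CrisprArray("c1", genes.iloc[40]["start"] - 40,
                           genes.iloc[40]["start"] - 20, 30, 4, "G1")
        far = CrisprArray("c1", genes.iloc[57]["start"] - 40,
                          genes.iloc[57]["start"] - 20, 30, 4, "G1")
        loci = assemble_neighborhoods(genes, anns, [near, far], reg2025,
                                      profile_map, flank=10)
        assert loci[0].arrays == [near]


class TestTrim:
    def test_margin_extends_to_strand_switch(self, reg2025, profile_map):
        # directon +,+,cas(+),+ then a minus gene: margin extends right to
        # rank 4 and stops there
        strands = ["+", "+", "+", "+", "-", "-"]
        genes = gene_table(6, strands=strands)
        anns = annotate(genes, {3: "cas1"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=1)
        assert loci[0].rank_range == (2, 4)
        trimmed = trim_boundaries(loci[0], genes, profile_map)
        assert trimmed.rank_range == (1, 4)

    def test_flanks_beyond_directon_are_dropped(self, reg2025, profile_map):
        strands = ["-", "-", "+", "+", "+", "-", "-"]
        genes = gene_table(7, strands=strands)
        anns = annotate(genes, {4: "cas1"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=3)
        assert loci[0].rank_range == (1, 7)
        trimmed = trim_boundaries(loci[0], genes, profile_map)
        assert trimmed.rank_range == (3, 5)

    def test_directon_bounded_locus_is_a_fixpoint(self, reg2025, profile_map):
        strands = ["-", "+", "+", "+", "-"]
        genes = gene_table(5, strands=strands)
        anns = annotate(genes, {2: "cas1", 4: "cas9"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map, flank=1)
        once = trim_boundaries(loci[0], genes, profile_map)
        twice = trim_boundaries(once, genes, profile_map)
        assert once.rank_range == twice.rank_range == (2, 4)

    def test_single_gene_locus_unchanged(self, reg2025, profile_map):
        genes = gene_table(1)
        anns = annotate(genes, {1: "cas1"})
        loci = assemble_neighborhoods(genes, anns, [], reg2025, profile_map)
        trimmed = trim_boundaries(loci[0], genes, profile_map)
        assert trimmed.rank_range == (1, 1)


def build_locus(families, reg, profile_map, with_array=False, strands=None):
    genes = gene_table(len(families) + 2)
    fam_at = {i + 2: f for i, f in enumerate(families)}
    anns = annotate(genes, fam_at)
    arrays = []
    if with_array:
        last = genes.iloc[len(families)]["end"]
        arrays = [CrisprArray("c1", int(last) + 10, int(last) + 200, 30, 5, "G1")]
    loci = assemble_neighborhoods(genes, anns, arrays, reg, profile_map)
    assert len(loci) == 1
    return loci[0]


class TestClassification:
    def test_type_vii_operon(self, reg2025, profile_map):
        locus = build_locus(["cas14", "cas7", "cas5", "cas6"], reg2025,
                            profile_map, with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        assert (c.cas_type, c.subtype) == ("VII", "VII")
        ok, _ = is_complete(locus, c, reg2025, profile_map)
        assert ok  # no adaptation module needed

    def test_iii_e_without_cas10(self, reg2025, profile_map):
        locus = build_locus(["cas7-11e"], reg2025, profile_map, with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype == "III-E"

    def test_cas10_presence_disqualifies_iii_e(self, reg2025, profile_map):
        locus = build_locus(["cas7-11e", "cas10"], reg2025, profile_map,
                            with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype != "III-E"

    def test_no_signature_evidence_is_unclassified(self, reg2025, profile_map):
        locus = build_locus(["cas1", "cas2", "cas6"], reg2025, profile_map)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype == "unclassified" and c.cas_type == "unclassified"

    def test_minimal_ii_c_beats_ii_a_and_ii_b(self, reg2025, profile_map):
        locus = build_locus(["cas9", "cas1", "cas2"], reg2025, profile_map,
                            with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype == "II-C"

    def test_classification_invariant_under_gene_order_reversal(self, reg2025,
                                                                profile_map):
        fams = ["cas8e", "cas7", "cas5", "cas3", "cas1", "cas2"]
        a = classify_locus(build_locus(fams, reg2025, profile_map, True),
                           reg2025, profile_map)
        b = classify_locus(build_locus(fams[::-1], reg2025, profile_map, True),
                           reg2025, profile_map)
        assert (a.subtype, a.cas_type) == (b.subtype, b.cas_type) == ("I-E", "I")


class TestCompleteness:
    def test_iii_g_complete_without_array(self, reg2025, profile_map):
        locus = build_locus(["cas10", "cas5", "cas7", "csx26"], reg2025, profile_map)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype == "III-G"
        ok, _ = is_complete(locus, c, reg2025, profile_map)
        assert ok

    def test_i_e_missing_cas7_is_incomplete(self, reg2025, profile_map):
        locus = build_locus(["cas8e", "cas5", "cas3", "cas1", "cas2"], reg2025,
                            profile_map, with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        assert c.subtype == "I-E"
        ok, reason = is_complete(locus, c, reg2025, profile_map)
        assert not ok and "cas7" in reason

    def test_missing_adaptation_module_blocks_completeness(self, reg2025,
                                                           profile_map):
        locus = build_locus(["cas8e", "cas7", "cas5", "cas3"], reg2025,
                            profile_map, with_array=True)
        c = classify_locus(locus, reg2025, profile_map)
        ok, reason = is_complete(locus, c, reg2025, profile_map)
        assert not ok and "adaptation" in reason

    def test_unclassified_locus_is_incomplete_with_reason(self, reg2025,
                                                          profile_map):
        locus = build_locus(["cas1"], reg2025, profile_map)
        c = classify_locus(locus, reg2025, profile_map)
        ok, reason = is_complete(locus, c, reg2025, profile_map)
        assert not ok and reason
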