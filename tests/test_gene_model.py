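"""Coordinate arithmetic, variant application and splicing derivations."""

import pytest
from hypothesis import given, strategies as st

from minisplice import (
    CANONICAL,
    CVariant,
    INTRON_RETENTION,
    IsoformSpec,
    MiniGene,
    Segment,
    apply_variant,
    build_fixture,
    cryptic_donor,
    inserted_sequence,
    read_minigene,
    resolve_position,
    shared_prefix_len,
    splice,
    splice_map,
    write_minigene,
)
from minisplice.gene_model import (
    CoordinateError,
    GeneModelError,
    ReferenceMismatchError,
    base_at,
    position_to_coding,
)

from conftest import random_minigene


class TestStructureValidation:
    def test_must_start_and_end_with_exon(self):
        with pytest.raises(GeneModelError):
            MiniGene("g", (Segment("i", "intron", "GTAG"),), 1, 0)

    def test_noncanonical_intron_rejected_unless_flagged(self):
        segs = (
            Segment("e1", "exon", "AAAA"),
            Segment("i1", "intron", "TTTTTT"),
            Segment("e2", "exon", "CCCC"),
        )
        with pytest.raises(GeneModelError):
            MiniGene("g", segs, 1, 0)
        g = MiniGene("g", segs, 1, 0, enforce_canonical=False)
        assert g.introns[0].seq == "TTTTTT"

    def test_invalid_characters_rejected(self):
        with pytest.raises(GeneModelError):
            MiniGene("g", (Segment("e1", "exon", "ACGN"),), 1, 0)


class TestResolvePosition:
    def test_donor_plus_five(self, gene, fixture_cfg):
        anchor = fixture_cfg.coding_anchor + fixture_cfg.exon_lens[0] - 1
        assert anchor == 2240
        assert resolve_position(gene, anchor, 5) == ("intron16", 5)

    def test_exonic_identity(self, gene):
        assert resolve_position(gene, 2121, 0) == ("exon16", 1)
        assert resolve_position(gene, 2240, 0) == ("exon16", 120)

    def test_acceptor_minus_one(self, gene):
        # first base of the next exon, one base back into the intron
        assert resolve_position(gene, 2241, -1) == ("intron16", 130)

    def test_offset_beyond_intron_is_error(self, gene):
        with pytest.raises(CoordinateError):
            resolve_position(gene, 2240, 131)

    def test_anchor_outside_range_is_error(self, gene):
        with pytest.raises(CoordinateError):
            resolve_position(gene, 99999, 0)

    def test_nonzero_offset_at_interior_anchor_is_error(self, gene):
        with pytest.raises(CoordinateError):
            resolve_position(gene, 2150, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_over_every_addressable_base(self, seed):
        g = random_minigene(seed)
        seen = set()
        for anchor, offset in g.iter_addressable():
            label, pos = resolve_position(g, anchor, offset)
            assert position_to_coding(g, label, pos) == (anchor, offset)
            seen.add((label, pos))
        assert len(seen) == sum(len(s.seq) for s in g.segments)


class TestApplyVariant:
    def test_plus_five_substitution(self, gene, variant):
        mut = apply_variant(gene, variant)
        assert base_at(mut, variant.anchor, 5) == "A"
        assert base_at(gene, variant.anchor, 5) == "G"  # input untouched
        diffs = [
            (a.label, i)
            for a, b in zip(gene.segments, mut.segments)
            for i, (x, y) in enumerate(zip(a.seq, b.seq))
            if x != y
        ]
        assert diffs == [("intron16", 4)]

    def test_involution(self, gene, variant):
        mut = apply_variant(gene, variant)
        back = apply_variant(mut, CVariant(variant.anchor, variant.offset, "A", "G"))
        assert [s.seq for s in back.segments] == [s.seq for s in gene.segments]

    def test_reference_mismatch_refused(self, gene, variant):
        with pytest.raises(ReferenceMismatchError):
            apply_variant(gene, CVariant(variant.anchor, 5, "C", "A"))


class TestSplice:
    def test_all_canonical_is_exon_concatenation(self, gene):
        assert splice(gene, IsoformSpec.all_canonical(3)) == "".join(
            e.seq for e in gene.exons
        )

    def test_cryptic_donor_inserts_six_bases(self, mutant, gene):
        spec = IsoformSpec.single(3, 0, cryptic_donor(6))
        iso = splice(mutant, spec)
        canonical = splice(gene, IsoformSpec.all_canonical(3))
        e1 = len(gene.exons[0].seq)
        assert len(iso) == len(canonical) + 6
        assert iso[e1 : e1 + 6] == mutant.introns[0].seq[:6]
        assert iso[:e1] == canonical[:e1] and iso[e1 + 6 :] == canonical[e1:]

    def test_retention_adds_full_intron(self, mutant, gene):
        iso = splice(mutant, IsoformSpec.single(3, 0, INTRON_RETENTION))
        assert len(iso) == sum(len(e.seq) for e in gene.exons) + 130

    def test_cryptic_without_gt_is_error(self, mutant):
        # fixture intron16 position +6/+7 is GG on the mutant allele
        with pytest.raises(GeneModelError):
            splice(mutant, IsoformSpec.single(3, 0, cryptic_donor(5)))

    def test_junction_map(self, mutant):
        _, junc_can = splice_map(mutant, IsoformSpec.all_canonical(3))
        assert junc_can == [120, 200, 290]
        _, junc_ins = splice_map(mutant, IsoformSpec.single(3, 0, cryptic_donor(6)))
        assert junc_ins == [126, 206, 296]
        _, junc_ret = splice_map(mutant, IsoformSpec.single(3, 0, INTRON_RETENTION))
        assert junc_ret == [330, 420]

    @pytest.mark.parametrize("seed", range(8))
    def test_length_bookkeeping_all_single_intron_specs(self, seed):
        g = random_minigene(seed)
        exonic = sum(len(e.seq) for e in g.exons)
        n = g.n_introns
        assert len(splice(g, IsoformSpec.all_canonical(n))) == exonic
        for i, intron in enumerate(g.introns):
            iso = splice(g, IsoformSpec.single(n, i, INTRON_RETENTION))
            assert len(iso) == exonic + len(intron.seq)
            for r in range(1, len(intron.seq) - 1):
                if intron.seq[r : r + 2] == "GT":
                    iso = splice(g, IsoformSpec.single(n, i, cryptic_donor(r)))
                    assert len(iso) == exonic + r


class TestInsertedSequence:
    def test_cryptic_insert_is_first_six_intron_bases(self, mutant):
        ins = inserted_sequence(mutant, IsoformSpec.single(3, 0, cryptic_donor(6)))
        assert ins == mutant.introns[0].seq[:6] == "GTAAAG"

    def test_retention_insert_is_whole_intron(self, mutant):
        ins = inserted_sequence(mutant, IsoformSpec.single(3, 0, INTRON_RETENTION))
        assert ins == mutant.introns[0].seq and len(ins) == 130

    def test_all_canonical_inserts_nothing(self, gene):
        assert inserted_sequence(gene, IsoformSpec.all_canonical(3)) == ""

    def test_multi_intron_aberration_unsupported(self, mutant):
        spec = IsoformSpec([INTRON_RETENTION, INTRON_RETENTION, CANONICAL])
        with pytest.raises(GeneModelError):
            inserted_sequence(mutant, spec)

    @pytest.mark.parametrize("seed", range(8))
    def test_cryptic_insert_is_prefix_of_retention_insert(self, seed):
        g = random_minigene(seed)
        n = g.n_introns
        for i, intron in enumerate(g.introns):
            ret_ins = inserted_sequence(g, IsoformSpec.single(n, i, INTRON_RETENTION))
            for r in range(1, len(intron.seq) - 1):
                if intron.seq[r : r + 2] == "GT":
                    cry = inserted_sequence(g, IsoformSpec.single(n, i, cryptic_donor(r)))
                    assert ret_ins.startswith(cry)


class TestSharedPrefix:
    def test_fixture_inserts_share_six_bases(self, mutant):
        ins6 = inserted_sequence(mutant, IsoformSpec.single(3, 0, cryptic_donor(6)))
        ret = inserted_sequence(mutant, IsoformSpec.single(3, 0, INTRON_RETENTION))
        assert shared_prefix_len(ins6, ret) == 6

    @given(st.text(alphabet="ACGT", max_size=30), st.text(alphabet="ACGT", max_size=30))
    def test_matches_character_comparison_oracle(self, a, b):
        expected = 0
        for x, y in zip(a, b):
            if x != y:
                break
            expected += 1
        assert shared_prefix_len(a, b) == expected

    def test_empty(self):
        assert shared_prefix_len("", "ACGT") == 0
        assert shared_prefix_len("GTAAGG", "GTAAGGTT") == 6


class TestSerialization:
    def test_fasta_json_roundtrip(self, gene, tmp_path):
        write_minigene(gene, tmp_path / "g.fasta", tmp_path / "g.json")
        back = read_minigene(tmp_path / "g.fasta", tmp_path / "g.json")
        assert back == gene
        header = (tmp_path / "g.fasta").read_text().splitlines()[0]
        assert header == f">{gene.name}|exon16|exon"
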