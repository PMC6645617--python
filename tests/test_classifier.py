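"""Signature derivation and junction-signature read classification."""

import random

import pytest

from minisplice import (
    ClassifierParams,
    CVariant,
    IsoformSpec,
    MiniGene,
    ReadSetSpec,
    Segment,
    build_signatures,
    classify_read,
    classify_reads,
    classify_readset,
    make_exact_counts_readset,
    simulate_reads,
    splice,
)
from minisplice import classifier as clf
from minisplice.classifier import ClassifierError
from minisplice.gene_model import INTRON_RETENTION, apply_variant, cryptic_donor


class TestBuildSignatures:
    def test_four_pairwise_distinct_signatures(self, signatures, params):
        assert len(signatures) == 4
        assert [s.category for s in signatures] == [
            clf.WT,
            clf.INS6,
            clf.RETENTION,
            clf.RETENTION,
        ]
        anchors = [s.anchor for s in signatures]
        assert len(set(anchors)) == 4
        for a in anchors:
            assert len(a) == params.window

    def test_degenerate_sequence_raises(self):
        # intron whose first 4 bases equal the next exon's first 4 bases makes
        # the retention 5' boundary indistinguishable from the WT junction
        segs = (
            Segment("e1", "exon", "ACCTTGCAACCT"),
            Segment("i1", "intron", "GTACGTCCAG"),
            Segment("e2", "exon", "GTACTTCGCATT"),
        )
        gene = MiniGene("degen", segs, 1, 0)
        v = CVariant(12, 3, "A", "G")
        with pytest.raises(ClassifierError, match="min_overhang"):
            build_signatures(gene, v, 4, ClassifierParams(min_overhang=4, max_mismatches=0))

    def test_variant_only_changes_windows_containing_it(
        self, gene, mutant, variant, fixture_cfg, params
    ):
        # signatures are built on the mutant allele; rebuilding from a gene
        # whose +5 base is reverted differs only inside windows covering +5
        ref_like = build_signatures(gene, variant, fixture_cfg.retained_len, params)
        alt_sigs = {s.name: s for s in ref_like}
        # manual windows from the reference allele isoforms
        ref_ins = splice(gene, IsoformSpec.single(3, 0, cryptic_donor(6)))
        s = alt_sigs["cryptic_junction"]
        ref_window = ref_ins[s.window_start : s.window_start + len(s.anchor)]
        assert sum(a != b for a, b in zip(ref_window, s.anchor)) == 1  # the +5 base
        assert alt_sigs["wt_junction"].anchor in splice(gene, IsoformSpec.all_canonical(3))

    def test_exonic_variant_rejected(self, gene, params):
        with pytest.raises(ClassifierError):
            build_signatures(gene, CVariant(2150, 0, "A", "G"), 6, params)


class TestClassifyRead:
    def test_wt_junction_read(self, gene, signatures, params, variant):
        canonical = splice(gene, IsoformSpec.all_canonical(3))
        read = canonical[100:140]  # spans the exon16|exon17 junction at 120
        res = classify_read(read, signatures, params, variant)
        assert res.category == clf.WT and res.mismatches == 0
        assert res.allele == clf.ALLELE_NOT_COVERED

    def test_ins6_junction_read(self, mutant, signatures, params, variant):
        iso = splice(mutant, IsoformSpec.single(3, 0, cryptic_donor(6)))
        read = iso[100:146]
        res = classify_read(read, signatures, params, variant)
        assert res.category == clf.INS6
        assert res.allele == clf.ALLELE_ALT  # the insertion contains the +5 base

    def test_read_inside_exon18_is_ambiguous(self, gene, signatures, params):
        seq = gene.segment("exon18").seq
        res = classify_read(seq[5:45], signatures, params)
        assert res.category == clf.AMBIGUOUS and res.mismatches == -1

    def test_retention_read_covering_plus_five_is_alt(
        self, mutant, signatures, params, variant
    ):
        iso = splice(mutant, IsoformSpec.single(3, 0, INTRON_RETENTION))
        read = iso[110:150]  # exon16|intron16 boundary at 120, +5 at 124
        res = classify_read(read, signatures, params, variant)
        assert res.category == clf.RETENTION and res.allele == clf.ALLELE_ALT

    def test_one_substitution_tolerated_two_rejected(
        self, gene, signatures, params, variant
    ):
        canonical = splice(gene, IsoformSpec.all_canonical(3))
        read = list(canonical[100:140])
        read[22] = "A" if read[22] != "A" else "C"  # inside the junction window
        assert classify_read("".join(read), signatures, params).category == clf.WT
        read[24] = "A" if read[24] != "A" else "C"
        assert classify_read("".join(read), signatures, params).category == clf.AMBIGUOUS

    def test_short_read_rejected(self, signatures, params):
        with pytest.raises(ClassifierError):
            classify_read("ACGT", signatures, params)


class TestClassifyReadset:
    def test_exact_counts_recovered(self, gene, variant, signatures, params, tmp_path):
        counts = {clf.WT: 2970, clf.INS6: 1670, clf.RETENTION: 460}
        rs = make_exact_counts_readset(gene, counts, variant)
        rs.write_fastq(tmp_path / "r.fastq")
        got, df = classify_readset(tmp_path / "r.fastq", signatures, params, variant)
        assert got == {
            clf.WT: 2970,
            clf.INS6: 1670,
            clf.RETENTION: 460,
            clf.AMBIGUOUS: 0,
            clf.CONFLICT: 0,
        }
        assert len(df) == 5100

    def test_empty_fastq_all_zero(self, signatures, params, tmp_path):
        (tmp_path / "empty.fastq").write_text("")
        counts, df = classify_readset(tmp_path / "empty.fastq", signatures, params)
        assert all(v == 0 for v in counts.values()) and len(df) == 0

    def test_malformed_fastq_reports_record(self, signatures, params, tmp_path):
        (tmp_path / "bad.fastq").write_text("@r1\nACGT\n+\nFF\n")  # qual/seq mismatch
        with pytest.raises(ClassifierError, match="record"):
            classify_readset(tmp_path / "bad.fastq", signatures, params)

    def test_counts_equal_truth_tallies_error_free(
        self, gene, variant, signatures, params
    ):
        spec = ReadSetSpec(n=3000, seed=21, error_rate=0.0)
        rs = simulate_reads(gene, spec, variant)
        df = classify_reads(rs.ids, rs.seqs, signatures, params, variant)
        merged = rs.truth.merge(df, on="read_id", suffixes=("_true", ""))
        informative = merged[merged["junction_informative"]]
        assert (informative["category"] == informative["category_true"]).all()
        tallies = informative["category_true"].value_counts().to_dict()
        got = clf.count_categories(df)
        assert {k: got[k] for k in tallies} == tallies


class TestClassifierProperties:
    def test_raising_max_mismatches_never_loses_reads(
        self, gene, variant, signatures
    ):
        spec = ReadSetSpec(n=3000, seed=33, error_rate=0.01)  # error-heavy
        rs = simulate_reads(gene, spec, variant)
        n_assigned = []
        for mm in (0, 1):
            params = ClassifierParams(min_overhang=8, max_mismatches=mm)
            df = classify_reads(rs.ids, rs.seqs, signatures, params, variant)
            n_assigned.append((df["category"] != clf.AMBIGUOUS).sum())
        assert n_assigned[1] >= n_assigned[0]

    def test_invariant_to_read_order(self, gene, variant, signatures, params):
        spec = ReadSetSpec(n=500, seed=17)
        rs = simulate_reads(gene, spec, variant)
        df = classify_reads(rs.ids, rs.seqs, signatures, params, variant)
        perm = list(range(len(rs.ids)))
        random.Random(0).shuffle(perm)
        df2 = classify_reads(
            [rs.ids[i] for i in perm], [rs.seqs[i] for i in perm], signatures, params, variant
        )
        a = df.set_index("read_id").sort_index()
        b = df2.set_index("read_id").sort_index()
        assert a.equals(b)

    def test_invariant_to_quality_strings(
        self, gene, variant, signatures, params, tmp_path
    ):
        rs = make_exact_counts_readset(gene, {clf.WT: 20, clf.RETENTION: 20}, variant)
        rs.write_fastq(tmp_path / "q37.fastq")
        with open(tmp_path / "q2.fastq", "w") as fh:
            for rid, seq in zip(rs.ids, rs.seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{'#' * len(seq)}\n")
        c1, d1 = classify_readset(tmp_path / "q37.fastq", signatures, params, variant)
        c2, d2 = classify_readset(tmp_path / "q2.fastq", signatures, params, variant)
        assert c1 == c2 and d1.equals(d2)


class TestGeometry:
    def test_informative_probability_matches_enumeration(self, signatures):
        # brute-force enumeration over start positions
        for cat in clf.ISOFORM_CATEGORIES:
            windows = clf.category_windows(signatures, cat)
            iso_len = windows[0][2]
            R = 150
            n_starts = iso_len - R + 1
            expected = sum(
                1
                for s in range(n_starts)
                if any(s <= a and b <= s + R for a, b, _ in windows)
            )
            assert clf.informative_start_count(iso_len, R, windows) == expected
            assert clf.informative_probability(signatures, cat, R) == expected / n_starts

    def test_expected_classified_proportions_normalized(self, signatures):
        props = {clf.WT: 0.5823, clf.INS6: 0.3275, clf.RETENTION: 0.0902}
        q = clf.expected_classified_proportions(signatures, 150, props)
        assert abs(sum(q.values()) - 1.0) < 1e-12
        # retention's two windows make it relatively easier to observe
        assert q[clf.RETENTION] > props[clf.RETENTION]
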