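"""Extraction, cut assignment, filtering, splitting, flank augmentation, TSV I/O."""

import numpy as np
import pytest

from mircleave import (
    AmbiguousArm,
    ExtendedPrecursor,
    GenomicAnnotation,
    assign_cut_sites,
    augment,
    extract_extended_precursor,
    filter_records,
    pairwise_identity,
    read_tsv,
    sample_flanks,
    split_dataset,
    write_tsv,
)
from mircleave.records import reverse_complement


def _chrom(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _prec(start, end, rid="mir-1", strand="+", chrom="chr1"):
    return GenomicAnnotation(rid, rid, chrom, start, end, strand, "precursor")


class TestExtraction:
    def test_full_flanks(self):
        chrom = _chrom(1000)
        rec = extract_extended_precursor(chrom, _prec(401, 460))
        assert len(rec.extended_seq) == 660
        assert (rec.flank_left_len, rec.flank_right_len) == (300, 300)
        assert rec.precursor_span == (300, 360)
        assert rec.precursor_seq == chrom[400:460].replace("T", "U")

    def test_chromosome_edge_truncates(self):
        rec = extract_extended_precursor(_chrom(1000), _prec(41, 100))
        assert (rec.flank_left_len, rec.flank_right_len) == (40, 300)

    def test_neighbor_truncates(self):
        nb = _prec(301, 350, rid="mir-0")
        rec = extract_extended_precursor(_chrom(1000), _prec(401, 460), [nb])
        assert rec.flank_left_len == 50
        # cross-strand neighbors are ignored
        nb_minus = _prec(301, 350, rid="mir-0", strand="-")
        rec2 = extract_extended_precursor(_chrom(1000), _prec(401, 460), [nb_minus])
        assert rec2.flank_left_len == 300

    def test_minus_strand_reverse_complements(self):
        chrom = _chrom(1000)
        rec = extract_extended_precursor(chrom, _prec(401, 460, strand="-"))
        expected = reverse_complement(chrom[100:760].replace("T", "U"))
        assert rec.extended_seq == expected
        assert rec.precursor_span == (300, 360)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            extract_extended_precursor(_chrom(100), _prec(50, 200))

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            extract_extended_precursor("ACGTX" * 100, _prec(100, 150))

    def test_n_bases_propagate(self):
        rec = extract_extended_precursor("ACGTN" * 200, _prec(401, 460))
        assert "N" in rec.extended_seq


class TestAssignCuts:
    def _rec(self, m5=(30, 52), m3=(60, 82)):
        seq = "A" * 120
        return ExtendedPrecursor(
            "r", "t", seq, precursor_span=(30, 82), mature5p_span=m5, mature3p_span=m3
        )

    def test_convention(self):
        # precursor fold: 5' arm [0,22), loop around the middle, 3' arm
        db = "(" * 22 + "." * 8 + ")" * 22
        rec = assign_cut_sites(self._rec(), db)
        assert rec.cuts == {"DR5": 30, "DC5": 52, "DC3": 60, "DR3": 82}

    def test_loop_overlap_raises(self):
        db = "(" * 10 + "." * 32 + ")" * 10
        with pytest.raises(AmbiguousArm):
            assign_cut_sites(self._rec(), db)

    def test_single_mature_on_3p_arm(self):
        rec = self._rec(m5=(60, 82), m3=None)
        db = "(" * 22 + "." * 8 + ")" * 22
        rec = assign_cut_sites(rec, db)
        assert set(rec.cuts) == {"DC3", "DR3"}
        assert rec.mature3p_span == (60, 82)
        assert rec.mature5p_span is None

    def test_multiple_hairpins_flagged(self):
        db = "((...))" + "." * 38 + "((...))"
        rec = assign_cut_sites(self._rec(), db)
        assert "structure_ambiguous" in rec.flags


class TestFiltering:
    def _base(self, **kw):
        kw.setdefault("mature5p_span", (30, 52))
        kw.setdefault("mature3p_span", (60, 82))
        return ExtendedPrecursor("r", "t", "ACGU" * 30, (30, 82), **kw)

    def test_missing_mature_dropped(self):
        rec = self._base(mature5p_span=None)
        kept, dropped = filter_records([rec], require_both_mature=True)
        assert not kept and dropped[0][1] == "missing_mature"
        kept, dropped = filter_records([rec], require_both_mature=False)
        assert kept and not dropped

    def test_loop_overlap_dropped(self):
        rec = self._base()
        rec.flags.add("loop_overlap")
        _, dropped = filter_records([rec])
        assert dropped[0][1] == "loop_overlap"

    def test_annotation_mismatch_dropped(self):
        rec = self._base()
        rec.annotated_mature_seqs["5p"] = "U" * 22
        _, dropped = filter_records([rec])
        assert dropped[0][1] == "inconsistent_annotation"
        ok = self._base()
        ok.annotated_mature_seqs["5p"] = ok.mature_seq("5p")
        kept, _ = filter_records([ok])
        assert kept


def _random_records(n, rng, length=80):
    nts = np.array(list("ACGU"))
    recs = []
    for i in range(n):
        seq = "".join(nts[rng.integers(0, 4, size=length)])
        recs.append(ExtendedPrecursor(f"r{i}", "t", seq, (10, length - 10)))
    return recs


class TestSplit:
    def test_ratios_on_dissimilar_records(self, rng):
        recs = _random_records(10, np.random.default_rng(1))
        split = split_dataset(recs, seed=0)
        sizes = sorted(map(len, split))
        assert sizes == [1, 1, 8]

    def test_identical_records_stay_together(self):
        recs = _random_records(6, np.random.default_rng(2))
        twin = ExtendedPrecursor("twin", "t", recs[0].extended_seq, recs[0].precursor_span)
        split = split_dataset(recs + [twin], seed=1)
        for part in split:
            ids = {r.record_id for r in part}
            assert ("r0" in ids) == ("twin" in ids)

    def test_invariant_no_cross_split_similarity(self):
        rng = np.random.default_rng(3)
        recs = _random_records(20, rng)
        # add near-duplicates of a few records
        for i in range(5):
            seq = list(recs[i].extended_seq)
            seq[5] = "A" if seq[5] != "A" else "C"
            recs.append(ExtendedPrecursor(f"dup{i}", "t", "".join(seq), (10, 70)))
        split = split_dataset(recs, seed=4)
        for r in split.train:
            for s in split.validation + split.test:
                assert pairwise_identity(r.extended_seq, s.extended_seq) < 0.8

    def test_single_cluster_degenerate(self):
        base = _random_records(1, np.random.default_rng(5))[0]
        clones = [
            ExtendedPrecursor(f"c{i}", "t", base.extended_seq, base.precursor_span)
            for i in range(4)
        ]
        with pytest.warns(UserWarning, match="one identity cluster"):
            split = split_dataset(clones, seed=0)
        assert len(split.train) == 4 and not split.validation and not split.test

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(_random_records(2, np.random.default_rng(0)))


class TestFlankSampling:
    def test_augmentation_cardinality_and_range(self, small_split):
        recs = small_split.train[:6]
        out = augment(recs, n_samples=10, seed=9)
        assert len(out) == 60
        for r in out:
            assert 30 <= r.flank_left_len <= 50
            assert 30 <= r.flank_right_len <= 50

    def test_determinism(self, small_split):
        rec = small_split.train[0]
        a = sample_flanks(rec, n_samples=5, seed=17)
        b = sample_flanks(rec, n_samples=5, seed=17)
        assert [r.extended_seq for r in a] == [r.extended_seq for r in b]
        assert [r.cuts for r in a] == [r.cuts for r in b]

    def test_mature_sequences_preserved(self, small_split):
        for rec in small_split.train[:10]:
            for out in sample_flanks(rec, n_samples=3, seed=1):
                assert out.mature_seq("5p") == rec.mature_seq("5p")
                assert out.mature_seq("3p") == rec.mature_seq("3p")
                d5 = out.extended_seq[out.cuts["DR5"] : out.cuts["DC5"]]
                assert d5 == rec.mature_seq("5p")

    def test_short_flank_clamped_with_warning(self):
        rec = ExtendedPrecursor("r", "t", "ACGU" * 20, (5, 75))
        with pytest.warns(UserWarning, match="clamping"):
            out = sample_flanks(rec, min_flank=30, max_flank=50, n_samples=1, seed=0)
        assert out[0].flank_left_len == 5


class TestTsvRoundTrip:
    def test_byte_stable(self, small_split, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(small_split.train, p1)
        write_tsv(read_tsv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fields_survive(self, small_split, tmp_path):
        p = tmp_path / "a.tsv"
        write_tsv(small_split.train, p)
        back = read_tsv(p)
        for a, b in zip(small_split.train, back):
            assert a.record_id == b.record_id
            assert a.extended_seq == b.extended_seq
            assert a.cuts == b.cuts
            assert a.dot_bracket == b.dot_bracket
            assert a.structure_array == b.structure_array


def test_gff3_fasta_pipeline(tmp_path):
    """End-to-end dataset building from miRBase-style GFF3 + genome FASTA."""
    from mircleave.workflows import build_dataset_from_files

    rng = np.random.default_rng(8)
    # plant a designed hairpin on the plus strand of a random chromosome
    from mircleave import SynthConfig, generate_record

    synth = generate_record(SynthConfig(mismatch_rate=0.0, bulge_rate=0.0, seed=0), rng)
    chrom_seq = ("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])
                 + synth.extended_seq.replace("U", "T")
                 + "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)]))
    offset = 400  # 0-based genomic start of the synthetic extended sequence
    p0, p1 = synth.precursor_span
    m5, m3 = synth.mature5p_span, synth.mature3p_span

    fasta = tmp_path / "genome.fa"
    fasta.write_text(">chr1\n" + "\n".join(
        chrom_seq[i : i + 60] for i in range(0, len(chrom_seq), 60)) + "\n")

    def line(start0, end0, feat, attrs):
        return f"chr1\t.\t{feat}\t{start0 + offset + 1}\t{end0 + offset}\t.\t+\t.\t{attrs}"

    gff = tmp_path / "mir.gff3"
    gff.write_text(
        "##gff-version 3\n"
        + line(p0, p1, "miRNA_primary_transcript", "ID=MI0001;Name=syn-mir-1") + "\n"
        + line(m5[0], m5[1], "miRNA", "ID=MIMAT1;Name=syn-miR-1-5p;Derives_from=MI0001") + "\n"
        + line(m3[0], m3[1], "miRNA", "ID=MIMAT2;Name=syn-miR-1-3p;Derives_from=MI0001") + "\n"
    )

    kept, dropped = build_dataset_from_files(gff, fasta, species="syn", engine="builtin")
    assert len(kept) == 1 and not dropped
    rec = kept[0]
    assert rec.precursor_seq == synth.precursor_seq
    assert rec.mature_seq("5p") == synth.mature_seq("5p")
    assert rec.mature_seq("3p") == synth.mature_seq("3p")
    # cut indices follow the convention relative to the mature spans
    assert rec.cuts["DR5"] == rec.mature5p_span[0]
    assert rec.cuts["DC5"] == rec.mature5p_span[1]
    assert rec.cuts["DC3"] == rec.mature3p_span[0]
    assert rec.cuts["DR3"] == rec.mature3p_span[1]
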