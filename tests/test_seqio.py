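"""Sequence IO: FASTA/GenBank parsing, region and gene extraction,
haplotype collapsing and concatenation building."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioRecord
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

from numtscreen.seqio import (
    GeneFeature,
    SequenceFormatError,
    SequenceRecord,
    build_concatenation,
    collapse_haplotypes,
    extract_gene,
    extract_region,
    read_fasta,
    read_genbank_features,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def _write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_three_entries_in_file_order(self, tmp_path):
        p = _write(tmp_path, ">a group=Q1\nACGT\n>b\nGGTT\n>c group=ASL\nTTAA\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b", "c"]
        assert [r.group for r in recs] == ["Q1", None, "ASL"]

    def test_non_iupac_character_names_offender(self, tmp_path):
        p = _write(tmp_path, ">ok\nACGT\n>bad\nACJT\n")
        with pytest.raises(SequenceFormatError, match="bad.*J|J.*bad"):
            read_fasta(p)

    def test_duplicate_id_rejected_with_line(self, tmp_path):
        p = _write(tmp_path, ">a\nACGT\n>a\nGGTT\n")
        with pytest.raises(SequenceFormatError, match="duplicate id 'a' at line 3"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(SequenceFormatError, match="no FASTA records"):
            read_fasta(_write(tmp_path, ""))

    def test_round_trip_records_and_bytes(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [
            SequenceRecord(
                id=f"s{i}",
                residues="".join(rng.choice(list("ACGT"), size=137)),
                group="G1" if i % 2 else None,
            )
            for i in range(5)
        ]
        p1 = tmp_path / "a.fasta"
        write_fasta(recs, p1)
        back = read_fasta(p1)
        assert [(r.id, r.group, r.residues) for r in back] == [
            (r.id, r.group, r.residues) for r in recs
        ]
        p2 = tmp_path / "b.fasta"
        write_fasta(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


def _toy_mitogenome(tmp_path, n_cds=13, n_rrna=2, gene_len=30, name="mt.gb"):
    rng = np.random.default_rng(5)
    total = (n_cds + n_rrna) * gene_len
    seq = "".join(rng.choice(list("ACGT"), size=total))
    rec = BioRecord(Seq(seq), id="MT001", name="MT001",
                    annotations={"molecule_type": "DNA"})
    names = [f"cds{i + 1}" for i in range(n_cds)] + [f"rrn{i + 1}" for i in range(n_rrna)]
    for i, gname in enumerate(names):
        ftype = "CDS" if i < n_cds else "rRNA"
        strand = -1 if i == 1 else 1  # second gene on the minus strand
        rec.features.append(
            SeqFeature(
                SimpleLocation(i * gene_len, (i + 1) * gene_len, strand=strand),
                type=ftype,
                qualifiers={"gene": [gname]},
            )
        )
    p = tmp_path / name
    SeqIO.write(rec, p, "genbank")
    return p, seq


class TestGenBank:
    def test_thirteen_cds_two_rrna_gives_fifteen_genes(self, tmp_path):
        p, _ = _toy_mitogenome(tmp_path)
        recs = read_genbank_features(p)
        assert len(recs) == 1
        assert len(recs[0].features) == 15
        for f in recs[0].features:
            extracted = extract_gene(recs[0], f.name)
            assert len(extracted) == 30

    def test_minus_strand_gene_reverse_complemented(self, tmp_path):
        p, seq = _toy_mitogenome(tmp_path)
        rec = read_genbank_features(p)[0]
        minus = next(f for f in rec.features if f.strand == "-")
        extracted = extract_gene(rec, minus.name)
        expected = str(Seq(seq[minus.start - 1 : minus.end]).reverse_complement())
        assert extracted.residues == expected

    def test_single_gene_record(self, tmp_path):
        p, _ = _toy_mitogenome(tmp_path, n_cds=1, n_rrna=0, name="one.gb")
        rec = read_genbank_features(p)[0]
        assert [f.name for f in rec.features] == ["cds1"]

    def test_record_without_origin_rejected(self, tmp_path):
        text = (
            "LOCUS       NOSEQ                     12 bp    DNA     linear   INV 01-JAN-2000\n"
            "DEFINITION  no sequence.\n"
            "ACCESSION   NOSEQ\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             1..12\n"
            '                     /gene="x"\n'
            "ORIGIN\n"
            "//\n"
        )
        p = tmp_path / "noseq.gb"
        p.write_text(text)
        with pytest.raises(SequenceFormatError, match="ORIGIN"):
            read_genbank_features(p)


class TestExtractRegion:
    def test_barcode_window_is_657_bp(self):
        rec = SequenceRecord(id="g", residues="A" * 1542)
        out = extract_region(rec, 783, 1439)
        assert len(out) == 657
        assert out.id == "g:783-1439"

    def test_whole_sequence_identity(self):
        rec = SequenceRecord(id="g", residues="ACGTACGT")
        assert extract_region(rec, 1, 8).residues == rec.residues

    def test_inverted_coordinates_rejected(self):
        rec = SequenceRecord(id="g", residues="ACGTACGT")
        with pytest.raises(SequenceFormatError):
            extract_region(rec, 5, 4)

    def test_out_of_range_states_length(self):
        rec = SequenceRecord(id="g", residues="ACGT")
        with pytest.raises(SequenceFormatError, match="length 4"):
            extract_region(rec, 2, 9)

    @given(seq=dna, data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_length_arithmetic(self, seq, data):
        start = data.draw(st.integers(1, len(seq)))
        end = data.draw(st.integers(start, len(seq)))
        rec = SequenceRecord(id="x", residues=seq)
        assert len(extract_region(rec, start, end)) == end - start + 1


class TestCollapse:
    def test_exact_multiplicities(self):
        s = "ACGT" * 10
        recs = [
            SequenceRecord(id="a", residues=s),
            SequenceRecord(id="b", residues=s),
            SequenceRecord(id="c", residues=s[:-1] + "C"),
        ]
        hs = collapse_haplotypes(recs, "exact")
        assert sorted(h.multiplicity for h in hs.haplotypes) == [1, 2]
        assert hs.total_members == 3

    def test_prefix_merging_depends_on_mode(self):
        long = "ACGTA" * 20  # 100 bp
        recs = [
            SequenceRecord(id="full", residues=long),
            SequenceRecord(id="short", residues=long[:60]),
        ]
        assert len(collapse_haplotypes(recs, "exact")) == 2
        merged = collapse_haplotypes(recs, "length-aware")
        assert len(merged) == 1
        assert sorted(merged.haplotypes[0].member_ids) == ["full", "short"]

    def test_all_distinct(self):
        recs = [
            SequenceRecord(id=f"s{i}", residues="ACGT"[i] * 10) for i in range(4)
        ]
        hs = collapse_haplotypes(recs, "exact")
        assert len(hs) == 4
        assert all(h.multiplicity == 1 for h in hs.haplotypes)

    def test_empty_input_rejected(self):
        with pytest.raises(SequenceFormatError):
            collapse_haplotypes([])

    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=3, max_size=12), min_size=1, max_size=20),
        mode=st.sampled_from(["exact", "length-aware"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_multiplicity_conservation(self, seqs, mode):
        recs = [SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]
        hs = collapse_haplotypes(recs, mode)
        assert hs.total_members == len(recs)
        assert len({h.residues for h in hs.haplotypes}) == len(hs.haplotypes)


def _sample(name, genes):
    """genes: dict name -> sequence laid out head-to-tail on the plus strand."""
    residues = "".join(genes.values())
    feats = []
    pos = 1
    for g, seq in genes.items():
        feats.append(GeneFeature(g, pos, pos + len(seq) - 1, "+"))
        pos += len(seq)
    return SequenceRecord(id=name, residues=residues, features=feats)


class TestConcatenation:
    def test_single_gene_identity(self):
        rng = np.random.default_rng(1)
        g = "".join(rng.choice(list("ACGT"), size=90))
        samples = [_sample("s1", {"a": g}), _sample("s2", {"a": g})]
        cat = build_concatenation(samples, ["a"])
        assert cat.total_length == 90
        assert cat.sequences["s1"] == g

    def test_equal_length_additivity(self):
        rng = np.random.default_rng(2)
        mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        samples = [
            _sample(f"s{i}", {"a": mk(300), "b": mk(150)}) for i in range(3)
        ]
        cat = build_concatenation(samples, ["a", "b"])
        assert cat.total_length == 450
        assert cat.boundaries == [("a", 0, 300), ("b", 300, 450)]

    def test_insertion_trimmed_to_flush_columns(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=120))
        b = "".join(rng.choice(list("ACGT"), size=90))
        b_ins = b[:40] + "TGA" + b[40:]  # one 3 bp insertion in sample 2
        samples = [_sample("s1", {"a": a, "b": b}), _sample("s2", {"a": a, "b": b_ins})]
        cat = build_concatenation(samples, ["a", "b"])
        longer_raw = 120 + 93
        assert cat.total_length == longer_raw - 3
        assert cat.sequences["s1"] == a + b

    def test_boundaries_tile_total_length(self):
        rng = np.random.default_rng(4)
        mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        samples = [_sample(f"s{i}", {"x": mk(60), "y": mk(33), "z": mk(45)}) for i in range(2)]
        cat = build_concatenation(samples, ["x", "y", "z"])
        pos = 0
        for _, start, end in cat.boundaries:
            assert start == pos
            pos = end
        assert pos == cat.total_length
        assert all(len(s) == cat.total_length for s in cat.sequences.values())

    def test_missing_gene_names_sample(self):
        s1 = _sample("s1", {"a": "ACGTACGTA"})
        s2 = SequenceRecord(id="s2", residues="ACGTACGTA", features=[])
        with pytest.raises(SequenceFormatError, match="s2.*'a'"):
            build_concatenation([s1, s2], ["a"])
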