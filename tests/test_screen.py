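"""Four-criterion pseudogene screening: panel building, individual
criteria, gating, and the per-group summary arithmetic."""

import numpy as np
import pytest

from numtscreen.screen import (
    GroupCounts,
    ScreenError,
    build_reference_panel,
    is_nonsynonymous,
    screen_criterion_i,
    screen_criterion_ii,
    screen_criterion_iii,
    screen_criterion_iv,
    screen_dataset,
    translate_mt,
)
from numtscreen.seqio import SequenceRecord
from numtscreen.simulate import SimConfig, simulate_reference_gene


@pytest.fixture(scope="module")
def gene():
    """A clean 1,542 bp protein-coding gene (no internal stops)."""
    return simulate_reference_gene(SimConfig(seed=5)).residues


class TestPanel:
    def test_identical_proteins_fully_conserved(self):
        panel = build_reference_panel(["MKLV" * 5] * 12)
        assert panel.conserved_mask.all()

    def test_single_difference_breaks_one_column(self):
        base = "MKLVWRQHSTAP"
        other = base[:7] + "A" + base[8:]
        panel = build_reference_panel([base, base, other])
        assert not panel.conserved_mask[7]
        assert panel.conserved_mask.sum() == len(base) - 1

    def test_planted_variable_sites_recovered(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        variable = {5, 17, 40}
        rows = [base]
        for r in range(5):
            row = list(base)
            for col in variable:
                row[col] = "W" if base[col] != "W" else "Y"
            rows.append("".join(row))
        panel = build_reference_panel(rows)
        assert set(np.flatnonzero(~panel.conserved_mask)) == variable

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ScreenError):
            build_reference_panel(["MKLV"])


class TestCriterionI:
    def test_interior_deletion_flagged(self, gene):
        partial = gene[700:1200]
        lesioned = partial[:49] + partial[50:]  # drop ref position 750
        flag, events = screen_criterion_i(lesioned, gene)
        assert flag
        assert events[0].kind == "deletion"

    def test_clean_partial_not_flagged(self, gene):
        flag, events = screen_criterion_i(gene[782:1439], gene)
        assert not flag and events == []


class TestCriterionII:
    def test_paper_style_clean_groups_have_no_stops(self, gene):
        # an exact excerpt of a functional gene translates cleanly
        partial = gene[782:1439]
        flag, stops = screen_criterion_ii(partial, frame_offset=2)
        assert not flag and stops == []

    def test_mid_frame_taa_flagged_with_coordinate(self, gene):
        partial = gene[782:1439]  # frame_offset 2, first codon at offset 1
        start = 1 + 3 * 50  # partial offset of an in-frame codon
        lesioned = partial[:start] + "TAA" + partial[start + 3 :]
        flag, stops = screen_criterion_ii(
            lesioned, frame_offset=2, ref_offset=783, reference_length=len(gene)
        )
        assert flag
        assert stops == [783 + start]

    def test_tga_is_tryptophan_not_stop(self, gene):
        partial = gene[782:1439]
        start = 1 + 3 * 50
        lesioned = partial[:start] + "TGA" + partial[start + 3 :]
        flag, stops = screen_criterion_ii(lesioned, frame_offset=2)
        assert not flag
        assert "*" not in translate_mt(lesioned[1:])


def _nonsyn_variant(gene, ref_pos):
    """A base at 1-based ref_pos that changes the amino acid."""
    for b in "ACGT":
        if b != gene[ref_pos - 1] and is_nonsynonymous(gene, ref_pos, b):
            ci = (ref_pos - 1) // 3
            cod = gene[3 * ci : 3 * ci + 3]
            p = (ref_pos - 1) % 3
            alt = cod[:p] + b + cod[p + 1 :]
            if translate_mt(alt) != "*":
                return b
    return None


class TestCriterionIII:
    def test_outlier_divergence_flagged(self, gene):
        # ~40 substitutions in an 836 bp fragment (= 4.78%) vs a tight group
        rng = np.random.default_rng(9)
        partial = gene[603:1439]  # 836 bp
        group = [partial, partial, partial]
        out = list(partial)
        idx = rng.choice(len(partial), size=40, replace=False)
        for i in idx:
            out[i] = next(b for b in "ACGT" if b != partial[i])
        flag, evidence = screen_criterion_iii("".join(out), group, gene)
        assert flag
        assert any(kind == "outlier" for kind, _ in evidence)

    def test_dense_terminal_stretch_flagged(self, gene):
        # an 87 bp stretch of non-synonymous changes at the 3' end
        partial = gene[782:1439]
        out = list(partial)
        planted = 0
        pos = len(partial) - 87
        while pos < len(partial) and planted < 12:
            ref_pos = 783 + pos
            b = _nonsyn_variant(gene, ref_pos)
            if b:
                out[pos] = b
                planted += 1
            pos += 7
        assert planted >= 9
        flag, evidence = screen_criterion_iii(
            "".join(out), [partial, partial, partial], gene
        )
        assert flag
        assert any(kind == "cluster" for kind, _ in evidence)

    def test_consensus_identical_not_flagged(self, gene):
        partial = gene[782:1439]
        flag, _ = screen_criterion_iii(partial, [partial, partial, partial], gene)
        assert not flag

    def test_single_terminal_substitution_is_not_a_cluster(self, gene):
        partial = gene[782:1439]
        b = _nonsyn_variant(gene, 783 + 2)
        assert b is not None
        out = partial[:2] + b + partial[3:]
        flag, evidence = screen_criterion_iii(out, [partial] * 3, gene)
        assert not flag

    def test_decoy_identity_flags_foreign_sequence(self, gene):
        rng = np.random.default_rng(10)
        partial = gene[782:1439]
        decoy = list(partial)
        for i in np.flatnonzero(rng.random(len(decoy)) < 0.12):
            decoy[i] = rng.choice([x for x in "ACGT" if x != partial[i]])
        decoy = "".join(decoy)
        flag, evidence = screen_criterion_iii(
            decoy, [partial] * 4, gene, decoys=[decoy]
        )
        assert flag
        assert any(kind == "decoy" for kind, _ in evidence)


@pytest.fixture(scope="module")
def panel(gene):
    return build_reference_panel([translate_mt(gene)] * 12)


class TestCriterionIV:
    def test_substitution_at_conserved_column_flagged(self, gene, panel):
        partial = gene[782:1439]
        # make a non-synonymous change at an in-frame codon
        pos = 1 + 3 * 40
        b = _nonsyn_variant(gene, 783 + pos)
        assert b is not None
        lesioned = partial[:pos] + b + partial[pos + 1 :]
        flag, cols, status = screen_criterion_iv(lesioned, gene, panel)
        assert status == "ok"
        assert flag
        expected_col = (783 + pos - 1) // 3 + 1
        assert cols == [expected_col]

    def test_variable_column_not_flagged(self, gene):
        prot = translate_mt(gene)
        partial = gene[782:1439]
        pos = 1 + 3 * 40
        b = _nonsyn_variant(gene, 783 + pos)
        lesioned = partial[:pos] + b + partial[pos + 1 :]
        # panel already varies at the lesioned column
        col = (783 + pos - 1) // 3
        loose = [prot, prot[:col] + "A" + prot[col + 1 :], prot[:col] + "G" + prot[col + 1 :]]
        panel = build_reference_panel(loose)
        flag, cols, status = screen_criterion_iv(lesioned, gene, panel)
        assert not flag and cols == []

    def test_short_translation_reported_not_flagged(self, gene, panel):
        short = gene[782:782 + 60]  # 20 codons < assessable minimum
        flag, cols, status = screen_criterion_iv(short, gene, panel)
        assert status == "too_short"
        assert not flag


class TestDataset:
    def test_reference_only_input_all_zero(self, gene):
        recs = [
            SequenceRecord(id="ref_barcode", residues=gene[782:1439], group="G")
        ]
        panel = build_reference_panel([translate_mt(gene)] * 3)
        report, flags = screen_dataset(recs, {"G": gene}, panel)
        g = report.groups["G"]
        assert (g.count_i, g.count_ii, g.count_iii, g.count_iv, g.union) == (0,) * 5
        assert g.percent == 0.0

    def test_union_bounds_hold_on_fixture(self, default_screen):
        report, flags = default_screen
        for g in report.groups.values():
            assert g.union <= g.count_i + g.count_ii + g.count_iii + g.count_iv
            assert g.union >= max(g.count_i, g.count_ii, g.count_iii, g.count_iv)
            assert g.percent == round(100 * g.union / g.total, 1)

    def test_criterion_iv_gated_on_indels(self, default_screen):
        report, flags = default_screen
        for fl in flags.values():
            if fl.flag_i:
                assert not fl.analysed_at_aa_level
                assert not fl.flag_iv
            if fl.flag_iv:
                assert fl.analysed_at_aa_level

    def test_missing_group_reference_rejected(self, gene):
        recs = [SequenceRecord(id="x", residues=gene[782:1439], group="G")]
        with pytest.raises(ScreenError, match="G"):
            screen_dataset(recs, {})

    def test_percent_arithmetic_matches_published_rows(self):
        # union/total -> percent as printed in the published summary table
        assert GroupCounts(212, 67, 0, 25, 47, 116).percent == 54.7
        assert GroupCounts(33, 7, 0, 0, 10, 17).percent == 51.5
        assert GroupCounts(37, 9, 0, 4, 10, 20).percent == 54.1
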