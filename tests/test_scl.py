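"""Subcellular-location cascade and the two curation filters."""

from __future__ import annotations

import pytest

from lacogs.config import PipelineConfig
from lacogs.io_core import ProteinRecord
from lacogs.scl import (
    SCLCall,
    SECRETOME_CLASSES,
    detect_outside_in,
    heuristic_scl,
    hydrophobic_stretches,
    screen_proteins,
    small_sec_filter,
)

HYDROPHILIC_TAIL = "DDEESSGGNNQQTTDDEESSGGNNQQTT"


def rec(seq, pid="p"):
    return ProteinRecord(pid, "g", seq)


class TestCascade:
    def test_plain_hydrophilic_is_intracellular(self):
        call = heuristic_scl(rec("M" + "DGESNQKT" * 5))
        assert call.scl_class == "INTRACELLULAR"
        assert not call.is_secretome

    def test_sec_signal(self):
        call = heuristic_scl(rec("MKK" + "L" * 10 + "AQA" + HYDROPHILIC_TAIL * 3))
        assert call.scl_class == "SEC_SECRETED"

    def test_tat_signal_needs_twin_arginine(self):
        call = heuristic_scl(rec("MRR" + "L" * 10 + "AQA" + HYDROPHILIC_TAIL * 3))
        assert call.scl_class == "TAT_SECRETED"

    def test_lipobox(self):
        call = heuristic_scl(rec("MKLAGC" + HYDROPHILIC_TAIL * 4))
        assert call.scl_class == "LIPID_ANCHORED"

    def test_n_anchor_without_cleavage(self):
        call = heuristic_scl(rec("MKK" + "L" * 12 + HYDROPHILIC_TAIL * 4))
        assert call.scl_class == "N_ANCHORED"
        assert call.tm_span is not None

    def test_cell_wall_anchor(self):
        call = heuristic_scl(rec("M" + HYDROPHILIC_TAIL * 4 + "LPKTG" + "A" * 12 + "KRK"))
        assert call.scl_class == "CELL_WALL_ANCHORED"

    def test_c_terminal_anchor(self):
        call = heuristic_scl(rec("M" + HYDROPHILIC_TAIL * 4 + "DD" + "L" * 10 + "RK"))
        assert call.scl_class == "C_ANCHORED"

    def test_multi_tm_is_not_secretome(self):
        seq = "M" + HYDROPHILIC_TAIL * 2 + "L" * 10 + HYDROPHILIC_TAIL * 2 + "L" * 10 + HYDROPHILIC_TAIL * 2
        call = heuristic_scl(rec(seq))
        assert call.scl_class == "MULTI_TM"
        assert not call.is_secretome

    def test_determinism(self):
        seq = "MKK" + "L" * 10 + "AQA" + HYDROPHILIC_TAIL * 3
        assert heuristic_scl(rec(seq)) == heuristic_scl(rec(seq))

    def test_secretome_vocabulary(self):
        assert "MULTI_TM" not in SECRETOME_CLASSES
        assert "INTRACELLULAR" not in SECRETOME_CLASSES
        with pytest.raises(ValueError):
            SCLCall("p", "OUTER_SPACE")


class TestOutsideIn:
    def anchor(self, before, after):
        seq = "M" + before + "L" * 12 + after + HYDROPHILIC_TAIL * 4
        call = heuristic_scl(rec(seq))
        assert call.scl_class == "N_ANCHORED", seq
        return rec(seq), call

    def test_positive_charge_before_helix_is_normal_topology(self):
        p, call = self.anchor("KR", "DD")
        assert detect_outside_in(p, call) is False

    def test_charge_only_downstream_flags_outside_in(self):
        p, call = self.anchor("DD", "DK")
        assert detect_outside_in(p, call) is True

    def test_no_downstream_charge_within_window_is_not_flagged(self):
        p, call = self.anchor("DD", "DDDDDDDDDD")
        assert detect_outside_in(p, call) is False

    def test_wrong_class_is_error(self):
        p = rec("M" + HYDROPHILIC_TAIL)
        call = heuristic_scl(p)
        with pytest.raises(ValueError):
            detect_outside_in(p, call)

    def test_screen_reclassifies_outside_in(self):
        p, _ = self.anchor("DD", "DK")
        calls, events = screen_proteins([p])
        assert calls[p.protein_id].scl_class == "INTRACELLULAR"
        assert (p.protein_id, "outside_in") in events


class TestSmallSecFilter:
    def sec(self, body_len):
        seq = "MKK" + "L" * 10 + "AQA" + ("DGESNQKT" * 20)[: body_len - 16]
        p = rec(seq)
        call = heuristic_scl(p)
        assert call.scl_class == "SEC_SECRETED"
        assert p.length == body_len
        return p, call

    def test_79_residue_sec_only_dropped(self):
        p, call = self.sec(79)
        assert small_sec_filter(p, call) is False

    def test_80_residue_sec_kept(self):
        p, call = self.sec(80)
        assert small_sec_filter(p, call) is True

    def test_non_sec_class_always_kept(self):
        p = rec("MKLAGC" + "DGESNQKT" * 8)
        call = heuristic_scl(p)
        assert call.scl_class == "LIPID_ANCHORED"
        assert p.length < 80
        assert small_sec_filter(p, call) is True

    def test_junction_markers_do_not_count_toward_length(self):
        p, call = self.sec(79)
        marked = ProteinRecord("p", "g", p.sequence[:40] + "x" + p.sequence[40:])
        assert small_sec_filter(marked, call) is False  # still 79 real residues

    def test_screen_removes_dropped_protein_from_secretome(self):
        p, _ = self.sec(79)
        calls, events = screen_proteins([p])
        assert not calls[p.protein_id].is_secretome
        assert (p.protein_id, "small_sec") in events


class TestOverride:
    def test_table_entry_beats_heuristic(self):
        p = rec("M" + HYDROPHILIC_TAIL * 4)  # heuristic: INTRACELLULAR
        calls, _ = screen_proteins([p], {p.protein_id: "NONCLASSICAL_SECRETED"})
        assert calls[p.protein_id].scl_class == "NONCLASSICAL_SECRETED"
        assert calls[p.protein_id].source == "table"
        assert calls[p.protein_id].is_secretome


def test_hydrophobic_stretch_detection_merges_windows():
    spans = hydrophobic_stretches("DDDD" + "L" * 12 + "DDDD")
    assert len(spans) == 1
    s, e = spans[0]
    assert s <= 4 and e >= 14
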