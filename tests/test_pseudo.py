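"""Fragment flagging, frameshift concatenation and reassignment."""

from __future__ import annotations

import pytest

from lacogs.clustering import LaCOG
from lacogs.config import PipelineConfig
from lacogs.homology import rank_hits
from lacogs.io_core import ProteinRecord
from lacogs.pseudo import (
    PseudoAssembly,
    assemble_adjacent_fragments,
    flag_fragment_candidates,
    flag_start_anomalies,
)
from lacogs.synthetic import _encode, _revcomp
import random

from test_homology import mk_hit


def family_of(*lengths):
    fam = LaCOG("LaCOG00001")
    lens = {}
    for i, L in enumerate(lengths):
        pid = f"m{i}"
        fam.add(pid, "seed")
        lens[pid] = L
    return fam, lens


class TestFlagging:
    def test_short_low_coverage_protein_is_flagged(self):
        fam, lens = family_of(500, 480, 520)
        p = ProteinRecord("frag", "g", "M" * 150)
        table = rank_hits([mk_hit("frag", "m0", 80, aln=140, qlen=150, slen=500)])
        assert flag_fragment_candidates(p, fam, lens, table) is True

    def test_full_length_member_not_flagged(self):
        fam, lens = family_of(500, 480, 520)
        fam.add("m3", "seed")
        lens["m3"] = 505
        p = ProteinRecord("m3", "g", "M" * 505)
        table = rank_hits([mk_hit("m3", "m0", 300, aln=480, qlen=505, slen=500)])
        assert flag_fragment_candidates(p, fam, lens, table) is False

    def test_length_boundary_is_strict(self):
        # exactly 0.6 x median must NOT flag
        fam, lens = family_of(500, 500, 500)
        table_low_cov = rank_hits([mk_hit("x", "m0", 80, aln=200, qlen=300, slen=500)])
        at = ProteinRecord("x", "g", "M" * 300)       # 0.6 * 500
        below = ProteinRecord("x", "g", "M" * 299)
        assert flag_fragment_candidates(at, fam, lens, table_low_cov) is False
        assert flag_fragment_candidates(below, fam, lens, table_low_cov) is True

    def test_no_family_hit_not_flagged(self):
        fam, lens = family_of(500, 500)
        p = ProteinRecord("y", "g", "M" * 100)
        assert flag_fragment_candidates(p, fam, lens, rank_hits([])) is False


def plant_pair(seq, strand="+", gap=4, seed=0):
    """Contig + two fragment records realising a mid-protein frameshift."""
    rng = random.Random(seed)
    h = len(seq) // 2
    nt1, nt2 = _encode(seq[:h], rng), _encode(seq[h:], rng)
    pad = "".join(rng.choice("ACGT") for _ in range(30))
    filler = "".join(rng.choice("C") for _ in range(gap - 3))
    contig = pad + nt1 + "TAA" + filler + nt2 + "TAA" + pad
    s1, e1 = len(pad) + 1, len(pad) + len(nt1)
    s2 = e1 + gap + 1
    e2 = s2 + len(nt2) - 1
    if strand == "-":
        contig = _revcomp(contig)
        L = len(contig)
        s1, e1, s2, e2 = L - e1 + 1, L - s1 + 1, L - e2 + 1, L - s2 + 1
    f1 = ProteinRecord("f1", "g", seq[:h], contig_id="ctg", start=s1, end=e1, strand=strand)
    f2 = ProteinRecord("f2", "g", seq[h:], contig_id="ctg", start=s2, end=e2, strand=strand)
    return [f1, f2], {"ctg": contig}


FULL = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHD"


class TestAssembly:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_concatenation_recovers_full_protein(self, strand):
        frags, contigs = plant_pair(FULL, strand=strand)
        out = assemble_adjacent_fragments(frags, contigs)
        assert len(out) == 1
        a = out[0]
        assert a.assembled_sequence.count("x") == 1
        assert a.assembled_sequence.replace("x", "") == FULL
        assert a.fragment_ids == ["f1", "f2"]  # 5'->3' of the coding strand
        assert a.strand == strand

    def test_single_candidate_no_assembly(self):
        frags, contigs = plant_pair(FULL)
        assert assemble_adjacent_fragments(frags[:1], contigs) == []

    def test_opposite_strands_not_grouped(self):
        frags, contigs = plant_pair(FULL)
        frags[1].strand = "-"
        assert assemble_adjacent_fragments(frags, contigs) == []

    def test_gap_beyond_maximum_not_grouped(self):
        frags, contigs = plant_pair(FULL)
        cfg = PipelineConfig(max_fragment_gap=2)
        assert assemble_adjacent_fragments(frags, contigs, cfg) == []

    def test_large_overlap_is_error(self):
        frags, contigs = plant_pair(FULL)
        frags[1].start = frags[0].end - 10
        with pytest.raises(ValueError, match="overlap"):
            assemble_adjacent_fragments(frags, contigs)

    def test_junction_count_invariant_enforced(self):
        with pytest.raises(ValueError, match="junction"):
            PseudoAssembly("a", ["f1", "f2", "f3"], "g", "c", (1, 9), "+", "AAxBB")

    def test_missing_coordinates_skipped(self):
        frags, contigs = plant_pair(FULL)
        frags[0].contig_id = None
        assert assemble_adjacent_fragments(frags, contigs) == []


class TestPlantedPairs:
    def test_all_planted_pairs_detected_and_reassigned(self, mini_dataset, mini_result):
        ds, res = mini_dataset, mini_result
        assert len(res.assemblies) == len(ds.truth.pseudo_pairs)
        by_frag = {tuple(a.fragment_ids): a for a in res.assemblies}
        mem = res.membership
        for pp in ds.truth.pseudo_pairs:
            a = by_frag[tuple(pp.fragment_ids)]
            assert a.assembled_sequence.count("x") == len(pp.fragment_ids) - 1
            assert a.assembled_sequence.replace("x", "") == pp.full_sequence
            family_cluster = {
                mem.get(m)
                for m in ds.truth.family_members[pp.family_id]
                if m not in res.consumed_fragments
            }
            assert family_cluster == {a.assigned_cluster}

    def test_fragments_do_not_leak_into_outputs(self, mini_result):
        consumed = mini_result.consumed_fragments
        assert consumed
        member_of = mini_result.membership
        assert not (consumed & set(member_of))
        assert not (consumed & set(mini_result.scl_calls))
        assert not consumed & {v.protein_id for v in mini_result.verdicts}


class TestStartAnomalies:
    def test_truncated_member_flagged(self):
        seqs = {
            "a": "M" + FULL[1:],
            "b": FULL,
            "c": FULL[40:],  # 40-residue N-terminal truncation
        }
        fam = LaCOG("C")
        recs = {}
        for pid, s in seqs.items():
            fam.add(pid, "seed")
            recs[pid] = ProteinRecord(pid, "g", s)
        flagged = flag_start_anomalies(fam, recs)
        assert [f[0] for f in flagged] == ["c"]
        assert flagged[0][2] > 20

    def test_homogeneous_family_clean(self):
        fam = LaCOG("C")
        recs = {}
        for pid in ("a", "b", "c"):
            fam.add(pid, "seed")
            recs[pid] = ProteinRecord(pid, "g", FULL)
        assert flag_start_anomalies(fam, recs) == []
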