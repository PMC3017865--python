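"""Aligner, hit ranking and the BBH relation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from lacogs.config import PipelineConfig
from lacogs.homology import (
    Hit,
    align_local,
    all_vs_all,
    compute_bbh,
    evalue_for,
    rank_hits,
    raw_to_bits,
)
from lacogs.io_core import ProteinRecord

from oracles import bbh_oracle, sw_score_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def mk_hit(q, s, bits, evalue=None, aln=100, qlen=100, slen=100):
    ev = evalue if evalue is not None else 2.0 ** (-bits) * 1e4
    return Hit(q, s, bits, ev, 0.5, aln, (1, aln), (1, aln),
               aln / qlen, aln / slen, qlen, slen)


class TestAlignLocal:
    def test_self_alignment_is_perfect(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        h = align_local(seq, seq)
        assert h.identity == 1.0
        assert h.q_cov == h.s_cov == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_dp(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice(AA) for _ in range(rng.randrange(8, 40)))
        b = "".join(rng.choice(AA) for _ in range(rng.randrange(8, 40)))
        expected_raw = sw_score_oracle(a, b)
        h = align_local(a, b)
        if expected_raw <= 0:
            assert h is None
        else:
            assert h.bitscore == pytest.approx(raw_to_bits(expected_raw))

    def test_classic_pair_matches_oracle(self):
        a, b = "PAWHEAE", "HEAGAWGHEE"
        assert align_local(a, b).bitscore == pytest.approx(
            raw_to_bits(sw_score_oracle(a, b))
        )

    def test_no_positive_pair_gives_no_hit(self):
        # C vs P scores -3 under BLOSUM62; nothing aligns positively
        assert align_local("CCCC", "PPPP") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MKL")

    def test_junction_wildcard_scores_zero(self):
        plain = align_local("MKTAYIAKQR", "MKTAYIAKQR")
        with_x = align_local("MKTAYxIAKQR", "MKTAYIAKQR")
        # the x column contributes nothing but does not break the alignment
        assert with_x.bitscore <= plain.bitscore


class TestRankHits:
    def test_tie_broken_by_subject_id(self):
        hits = [mk_hit("q", "c", 50), mk_hit("q", "b", 70), mk_hit("q", "a", 70)]
        table = rank_hits(hits)
        assert [h.subject_id for h in table.hits_for("q")] == ["a", "b", "c"]

    def test_self_hit_excluded(self):
        table = rank_hits([mk_hit("q", "q", 99)])
        assert table.hits_for("q") == []

    def test_duplicate_pair_keeps_best(self):
        table = rank_hits([mk_hit("q", "s", 40), mk_hit("q", "s", 90)])
        assert len(table.hits_for("q")) == 1
        assert table.hits_for("q")[0].bitscore == 90

    def test_large_random_order_matches_sort_oracle(self):
        rng = random.Random(0)
        hits = [
            mk_hit("q", f"s{i:04d}", rng.randrange(20, 80), evalue=rng.random())
            for i in range(1000)
        ]
        table = rank_hits(hits)
        expected = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        assert [h.subject_id for h in table.hits_for("q")] == [
            h.subject_id for h in expected
        ]


def random_bbh_instance(seed):
    """A random cross-genome hit set plus its genome partition."""
    rng = random.Random(seed)
    n_genomes = rng.randrange(2, 5)
    prots = [f"p{i:02d}" for i in range(rng.randrange(4, 30))]
    genome_of = {p: f"g{rng.randrange(n_genomes)}" for p in prots}
    hits = []
    for q in prots:
        for s in prots:
            if q == s or rng.random() < 0.4:
                continue
            bits = rng.uniform(20, 120)
            qlen = rng.randrange(50, 300)
            slen = rng.randrange(50, 300)
            aln = rng.randrange(20, max(qlen, slen) + 1)
            hits.append(mk_hit(q, s, bits, aln=aln, qlen=qlen, slen=slen))
    return hits, genome_of


class TestBBH:
    def test_mutual_best_full_length(self):
        hits = [mk_hit("a", "b", 60), mk_hit("b", "a", 60)]
        pairs = compute_bbh(rank_hits(hits), {"a": "X", "b": "Y"})
        assert len(pairs) == 1
        p = next(iter(pairs))
        assert {p.protein_a, p.protein_b} == {"a", "b"}

    def test_below_bitscore_threshold_rejected(self):
        hits = [mk_hit("a", "b", 45), mk_hit("b", "a", 45)]
        assert compute_bbh(rank_hits(hits), {"a": "X", "b": "Y"}) == set()

    def test_below_overlap_threshold_rejected(self):
        hits = [mk_hit("a", "b", 80, aln=40), mk_hit("b", "a", 80, aln=40)]
        assert compute_bbh(rank_hits(hits), {"a": "X", "b": "Y"}) == set()

    def test_asymmetric_best_gives_no_pair(self):
        # a's best in Y is b, but b's best in X is c
        hits = [
            mk_hit("a", "b", 60), mk_hit("b", "a", 55),
            mk_hit("b", "c", 70), mk_hit("c", "b", 70),
        ]
        genome_of = {"a": "X", "c": "X", "b": "Y"}
        pairs = compute_bbh(rank_hits(hits), genome_of)
        assert {frozenset((p.protein_a, p.protein_b)) for p in pairs} == {
            frozenset(("b", "c"))
        }

    def test_within_genome_hits_ignored(self):
        hits = [mk_hit("a", "b", 90), mk_hit("b", "a", 90)]
        assert compute_bbh(rank_hits(hits), {"a": "X", "b": "X"}) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        hits, genome_of = random_bbh_instance(seed)
        got = compute_bbh(rank_hits(hits), genome_of)
        got_sets = {frozenset((p.protein_a, p.protein_b)) for p in got}
        assert got_sets == bbh_oracle(hits, genome_of)

    @given(st.integers(0, 1000), st.floats(50, 120))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_raising_bitscore_never_adds_pairs(self, seed, threshold):
        hits, genome_of = random_bbh_instance(seed)
        table = rank_hits(hits)
        base = compute_bbh(table, genome_of, PipelineConfig())
        strict = compute_bbh(
            table, genome_of, PipelineConfig(bbh_min_bitscore=threshold)
        )
        base_sets = {frozenset((p.protein_a, p.protein_b)) for p in base}
        strict_sets = {frozenset((p.protein_a, p.protein_b)) for p in strict}
        assert strict_sets <= base_sets


def test_all_vs_all_is_symmetric_and_gated():
    rng = random.Random(1)
    prots = [
        ProteinRecord(f"p{i}", f"g{i % 2}",
                      "".join(rng.choice(AA) for _ in range(60)))
        for i in range(6)
    ]
    # two near-identical proteins guarantee at least one strong pair
    prots.append(ProteinRecord("q0", "g0", prots[0].sequence[:50] + "AAAAA"))
    cfg = PipelineConfig(kmer_prescreen_min=0)
    table = all_vs_all(prots, cfg)
    for q, hs in table.by_query.items():
        for h in hs:
            back = [x for x in table.hits_for(h.subject_id) if x.subject_id == q]
            assert back, "every hit must exist in both directions"
            assert back[0].bitscore == pytest.approx(h.bitscore)
            assert h.evalue <= cfg.initial_evalue_max
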