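"""Uniform top-k extension, BBH cores, naming, and the QC sweep."""

from __future__ import annotations

import copy
import random

import pytest

from lacogs.clustering import (
    LaCOG,
    build_bbh_cores,
    extend_by_uniform_top3,
    form_new_clusters,
    membership_map,
    name_new_clusters,
    qc_distant_sweep,
)
from lacogs.config import PipelineConfig
from lacogs.homology import BBHPair, rank_hits

from oracles import topk_assignment_oracle
from test_homology import mk_hit


def make_clusters(spec: dict[str, list[str]]) -> dict[str, LaCOG]:
    out = {}
    for cid, members in spec.items():
        c = LaCOG(cid)
        for m in members:
            c.add(m, "seed")
        out[cid] = c
    return out


class TestUniformTopK:
    def test_top3_within_one_cluster_assigns(self):
        clusters = make_clusters({"A": ["p1", "p2", "p3"], "B": ["p4", "p5"]})
        table = rank_hits([
            mk_hit("q", "p1", 90), mk_hit("q", "p3", 80),
            mk_hit("q", "p2", 70), mk_hit("q", "p4", 60),
        ])
        decisions = extend_by_uniform_top3(clusters, table, ["q"])
        assert decisions[0].target_cluster_id == "A"
        assert "q" in clusters["A"].members

    def test_top3_spanning_clusters_vetoes(self):
        clusters = make_clusters({"A": ["p1", "p2", "p3"], "B": ["p4", "p5"]})
        table = rank_hits([
            mk_hit("q", "p1", 90), mk_hit("q", "p4", 80), mk_hit("q", "p2", 70),
        ])
        decisions = extend_by_uniform_top3(clusters, table, ["q"])
        assert decisions[0].target_cluster_id is None

    def test_size_two_cluster_uses_top2(self):
        clusters = make_clusters({"A": ["p1", "p2", "p3"], "B": ["p4", "p5"]})
        table = rank_hits([
            mk_hit("q", "p4", 90), mk_hit("q", "p5", 80), mk_hit("q", "p1", 70),
        ])
        decisions = extend_by_uniform_top3(clusters, table, ["q"])
        assert decisions[0].rule == "top2_size2"
        assert decisions[0].target_cluster_id == "B"

    def test_no_hits_unassigned(self):
        clusters = make_clusters({"A": ["p1", "p2", "p3"]})
        decisions = extend_by_uniform_top3(clusters, rank_hits([]), ["q"])
        assert decisions[0].rule == "none"
        assert decisions[0].target_cluster_id is None

    def test_unclustered_subject_vetoes_by_default(self):
        clusters = make_clusters({"A": ["p1", "p2", "p3"]})
        table = rank_hits([
            mk_hit("q", "p1", 90), mk_hit("q", "z", 80), mk_hit("q", "p2", 70),
            mk_hit("q", "p3", 60),
        ])
        decisions = extend_by_uniform_top3(clusters, table, ["q"])
        assert decisions[0].target_cluster_id is None
        relaxed = make_clusters({"A": ["p1", "p2", "p3"]})
        decisions = extend_by_uniform_top3(
            relaxed, table, ["q"], PipelineConfig(unclustered_hits_veto=False)
        )
        assert decisions[0].target_cluster_id == "A"

    def test_already_clustered_query_is_error(self):
        clusters = make_clusters({"A": ["p1", "p2"]})
        with pytest.raises(ValueError):
            extend_by_uniform_top3(clusters, rank_hits([]), ["p1"])

    def test_no_cascade_within_one_pass(self):
        # q2's top hits include q1; q1 is assigned in this pass, but the
        # snapshot semantics mean q2 must not ride on that assignment
        clusters = make_clusters({"A": ["p1", "p2", "p3"]})
        table = rank_hits([
            mk_hit("q1", "p1", 90), mk_hit("q1", "p2", 80), mk_hit("q1", "p3", 70),
            mk_hit("q2", "p1", 90), mk_hit("q2", "q1", 80), mk_hit("q2", "p2", 70),
        ])
        decisions = {d.protein_id: d for d in
                     extend_by_uniform_top3(clusters, table, ["q1", "q2"])}
        assert decisions["q1"].target_cluster_id == "A"
        assert decisions["q2"].target_cluster_id is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_rule_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randrange(10, 50)
        prots = [f"p{i:02d}" for i in range(n)]
        n_clusters = rng.randrange(1, 8)
        clusters: dict[str, list[str]] = {f"C{k}": [] for k in range(n_clusters)}
        pool = prots[:]
        rng.shuffle(pool)
        for cid in clusters:
            size = rng.randrange(2, 6)
            clusters[cid] = [pool.pop() for _ in range(min(size, len(pool) - 5))]
        clusters = {c: m for c, m in clusters.items() if len(m) >= 2}
        queries = sorted(pool)
        hits = []
        for q in queries:
            subjects = rng.sample([p for p in prots if p != q],
                                  rng.randrange(0, min(8, n - 1)))
            for s in subjects:
                hits.append(mk_hit(q, s, rng.uniform(20, 100)))
        table = rank_hits(hits)
        lac = make_clusters(clusters)
        member_of = membership_map(lac)
        sizes = {cid: len(m) for cid, m in clusters.items()}
        decisions = extend_by_uniform_top3(lac, table, queries)
        for d in decisions:
            ranked = [h.subject_id for h in table.hits_for(d.protein_id)]
            assert d.target_cluster_id == topk_assignment_oracle(
                ranked, member_of, sizes
            )


class TestCores:
    def test_single_pair_core_both_modes(self):
        pairs = {BBHPair("a", "b", 60, 60)}
        for mode in ("clique", "component"):
            cores = build_bbh_cores(pairs, PipelineConfig(bbh_core_mode=mode))
            assert cores == [frozenset(("a", "b"))]

    def test_path_graph_split_by_mode(self):
        pairs = {BBHPair("a", "b", 80, 80), BBHPair("b", "c", 60, 60)}
        comp = build_bbh_cores(pairs, PipelineConfig(bbh_core_mode="component"))
        assert comp == [frozenset(("a", "b", "c"))]
        cliq = build_bbh_cores(pairs, PipelineConfig(bbh_core_mode="clique"))
        assert cliq == [frozenset(("a", "b"))]  # higher-score seed wins; c left out

    def test_triangle_is_one_clique(self):
        pairs = {
            BBHPair("a", "b", 80, 80),
            BBHPair("b", "c", 60, 60),
            BBHPair("a", "c", 70, 70),
        }
        assert build_bbh_cores(pairs) == [frozenset(("a", "b", "c"))]

    def test_empty_pairs_no_cores(self):
        assert build_bbh_cores(set()) == []

    def test_new_cluster_naming_starts_at_90001(self):
        cores = [frozenset(("a", "b")), frozenset(("c", "d"))]
        named = name_new_clusters(cores, {})
        assert sorted(named) == ["LaCOG90001", "LaCOG90002"]
        assert named["LaCOG90001"].members == {"a", "b"}

    def test_naming_skips_existing_ids(self):
        existing = make_clusters({"LaCOG90001": ["x", "y"]})
        named = name_new_clusters([frozenset(("a", "b"))], existing)
        assert sorted(named) == ["LaCOG90002"]

    def test_form_new_clusters_absorbs_remaining(self):
        cores = [frozenset(("a", "b", "c"))]
        table = rank_hits([
            mk_hit("r", "a", 90), mk_hit("r", "b", 80), mk_hit("r", "c", 70),
        ])
        clusters, decisions = form_new_clusters(cores, {}, ["r"], table)
        assert clusters["LaCOG90001"].members == {"a", "b", "c", "r"}
        assert decisions[0].target_cluster_id == "LaCOG90001"

    def test_form_new_clusters_empty_remaining(self):
        clusters, decisions = form_new_clusters(
            [frozenset(("a", "b"))], {}, [], rank_hits([])
        )
        assert sorted(clusters) == ["LaCOG90001"]
        assert decisions == []


class TestQCSweep:
    def test_no_unclustered_zero_rounds(self):
        clusters = make_clusters({"C": ["p1", "p2"]})
        assignments, rounds = qc_distant_sweep(clusters, [], rank_hits([]))
        assert assignments == {} and rounds == 0

    def test_simple_absorption(self):
        clusters = make_clusters({"C": ["p1", "p2"]})
        table = rank_hits([mk_hit("u", "p1", 60, evalue=1e-4, qlen=70, slen=100)])
        assignments, rounds = qc_distant_sweep(clusters, ["u"], table)
        assert assignments == {"u": "C"} and rounds == 1

    def test_chain_needs_two_rounds(self):
        clusters = make_clusters({"C": ["p1", "p2"]})
        table = rank_hits([
            mk_hit("u1", "p1", 60, evalue=1e-4, qlen=80, slen=100),
            mk_hit("u2", "u1", 60, evalue=1e-4, qlen=80, slen=80),
        ])
        assignments, rounds = qc_distant_sweep(clusters, ["u1", "u2"], table)
        assert assignments == {"u1": "C", "u2": "C"}
        assert rounds == 2

    @pytest.mark.parametrize(
        "evalue,ratio,expected",
        [
            (1e-3, 0.6, True),   # both at the boundary: accepted
            (2e-3, 0.6, False),  # E-value just over
            (1e-3, 0.59, False), # length ratio just under
        ],
    )
    def test_boundary_thresholds(self, evalue, ratio, expected):
        clusters = make_clusters({"C": ["p1", "p2"]})
        qlen = int(round(100 * ratio))
        table = rank_hits([mk_hit("u", "p1", 60, evalue=evalue, qlen=qlen, slen=100)])
        assignments, _ = qc_distant_sweep(clusters, ["u"], table)
        assert (assignments == {"u": "C"}) is expected

    def test_query_coverage_mode(self):
        clusters = make_clusters({"C": ["p1", "p2"]})
        table = rank_hits([mk_hit("u", "p1", 60, evalue=1e-4, aln=65, qlen=100, slen=400)])
        cfg = PipelineConfig(distant_criterion_mode="query_coverage")
        assignments, _ = qc_distant_sweep(clusters, ["u"], table, cfg)
        assert assignments == {"u": "C"}  # q_cov 0.65 >= 0.6; ratio 0.25 would fail

    def test_monotone_growth_and_termination(self):
        rng = random.Random(3)
        clusters = make_clusters({"C": ["p1", "p2"]})
        # a chain u0 <- u1 <- ... <- u9 resolves one protein per round
        hits = [mk_hit("u0", "p1", 60, evalue=1e-5, qlen=90, slen=100)]
        for i in range(1, 10):
            hits.append(mk_hit(f"u{i}", f"u{i-1}", 60, evalue=1e-5, qlen=90, slen=90))
        table = rank_hits(hits)
        unclustered = [f"u{i}" for i in range(10)]
        sizes = [len(clusters["C"].members)]
        assignments, rounds = qc_distant_sweep(clusters, unclustered, table)
        assert rounds == 10
        assert len(assignments) == 10
        assert len(clusters["C"].members) == 12
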