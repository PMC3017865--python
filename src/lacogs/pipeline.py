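"""End-to-end orchestration of the cluster-construction pipeline.

Stage order:

1. all-vs-all similarity search (built-in aligner, or a supplied hit table);
2. extension of seed clusters by the uniform top-3 rule;
3. BBH cores over the still-unclustered proteins;
4. naming of new clusters ("9"-prefixed ids) and a second top-3 pass;
5. subcellular-location screen (table override or heuristic cascade),
   with the outside-in and small-Sec-only filters;
6. pseudogene stage: fragment flagging, concatenation with 'x' junctions,
   reassignment — assembled pseudoproteins replace their fragments in
   clusters and in all downstream accounting;
7. iterative distant-homolog quality-control sweep.  Running the sweep
   after fragment replacement keeps the length-ratio criterion meaningful:
   half-length fragments sitting inside clusters would otherwise act as
   low bars for short unrelated proteins to clear;
8. secretome extraction by the at-least-half majority rule;
9. ORFan / distant-homolog classification of the leftovers;
10. per-genome summaries, phyletic patterns and domain architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import PipelineConfig
from .clustering import (
    AssignmentDecision,
    LaCOG,
    build_bbh_cores,
    extend_by_uniform_top3,
    form_new_clusters,
    membership_map,
    qc_distant_sweep,
)
from .comparative import (
    ArchitectureProfile,
    PhyleticPattern,
    classify_phyletic_patterns,
    profile_architectures,
)
from .homology import HitTable, all_vs_all, compute_bbh
from .io_core import GenomeBundle, ProteinRecord
from .orfans import UnclusteredVerdict, classify_unclustered
from .pseudo import (
    PseudoAssembly,
    assemble_adjacent_fragments,
    flag_fragment_candidates,
    flag_start_anomalies,
    reassign_assembly,
)
from .scl import SCLCall, screen_proteins
from .secretome import (
    GenomeSummary,
    SecretomeCluster,
    extract_secretome_lacogs,
    summarize_genomes,
)


@dataclass
class RunResult:
    genomes: list[GenomeBundle]
    config: PipelineConfig
    hit_table: HitTable
    clusters: dict[str, LaCOG]
    decisions: dict[str, AssignmentDecision]
    qc_assignments: dict[str, str]
    qc_rounds: int
    scl_calls: dict[str, SCLCall]
    screen_events: list[tuple[str, str]]
    assemblies: list[PseudoAssembly]
    flagged_unassembled: list[str]
    consumed_fragments: set[str]
    start_anomalies: list[tuple[str, str, int, list[int]]]
    verdicts: list[UnclusteredVerdict]
    secretome_clusters: list[SecretomeCluster]
    below_majority: list[tuple[str, str]]
    summaries: list[GenomeSummary]
    patterns: list[PhyleticPattern]
    architectures: list[ArchitectureProfile]
    genome_of: dict[str, str]

    @property
    def membership(self) -> dict[str, str]:
        return membership_map(self.clusters)


def run_pipeline(
    genomes: list[GenomeBundle],
    config: PipelineConfig | None = None,
    *,
    hit_table: HitTable | None = None,
    scl_table: dict[str, str] | None = None,
    domain_map: dict | None = None,
    seed_clusters: dict[str, list[str]] | None = None,
    reference_hits: HitTable | None = None,
    surface_domains: set[str] | None = None,
    contigs: dict[str, str] | None = None,
    log=None,
) -> RunResult:
    """Run every stage and return the complete in-memory result."""
    cfg = config or PipelineConfig()
    domain_map = domain_map or {}

    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    proteins: list[ProteinRecord] = []
    for g in genomes:
        for p in g.proteins:
            if cfg.exclude_plasmids and p.contig_id and "plasmid" in p.contig_id.lower():
                continue
            proteins.append(p)
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids across genomes: {dup[:5]}")
    records = {p.protein_id: p for p in proteins}
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    total_inputs = {g.genome_id: 0 for g in genomes}
    for p in proteins:
        total_inputs[p.genome_id] += 1
    all_contigs: dict[str, str] = dict(contigs or {})
    for g in genomes:
        if g.contigs:
            all_contigs.update(g.contigs)

    # 1. similarity search
    if hit_table is None:
        say(f"aligning {len(proteins)} proteins all-vs-all")
        hit_table = all_vs_all(proteins, cfg)
    say(f"hit table: {len(hit_table)} hits")

    # 2. seed extension
    clusters: dict[str, LaCOG] = {}
    decisions: dict[str, AssignmentDecision] = {}
    if seed_clusters:
        for cid in sorted(seed_clusters):
            members = [m for m in seed_clusters[cid] if m in records]
            if len(members) < 2:
                continue  # singleton seeds re-enter the unclustered pool
            c = LaCOG(cid, origin="seed_extended")
            for m in members:
                c.add(m, "seed")
            clusters[cid] = c
        member_of = membership_map(clusters)
        queries = [p for p in records if p not in member_of]
        for d in extend_by_uniform_top3(clusters, hit_table, queries, cfg):
            decisions[d.protein_id] = d
        say(f"seed extension: {len(clusters)} seed clusters")

    # 3-4. BBH cores and new clusters
    member_of = membership_map(clusters)
    unclustered = sorted(set(records) - set(member_of))
    pairs = compute_bbh(hit_table, genome_of, cfg, restrict_to=set(unclustered))
    cores = build_bbh_cores(pairs, cfg)
    say(f"BBH: {len(pairs)} pairs -> {len(cores)} cores")
    core_members = {m for c in cores for m in c}
    remaining = [p for p in unclustered if p not in core_members]
    clusters, new_decisions = form_new_clusters(cores, clusters, remaining, hit_table, cfg)
    for d in new_decisions:
        decisions[d.protein_id] = d
    say(f"clusters after formation: {len(clusters)}")

    # 5. SCL screen
    scl_calls, screen_events = screen_proteins(proteins, scl_table, cfg)

    # 6. pseudogene stage
    member_of = membership_map(clusters)
    lengths = {p.protein_id: p.length for p in proteins}
    candidates: list[ProteinRecord] = []
    for pid in sorted(records):
        p = records[pid]
        cid = member_of.get(pid)
        if cid is None:
            best = next(
                (h for h in hit_table.hits_for(pid) if h.subject_id in member_of),
                None,
            )
            cid = member_of.get(best.subject_id) if best else None
        if cid is None:
            continue
        if flag_fragment_candidates(p, clusters[cid], lengths, hit_table, cfg):
            candidates.append(p)
    assemblies = assemble_adjacent_fragments(candidates, all_contigs, cfg)
    consumed: set[str] = set()
    for a in assemblies:
        consumed.update(a.fragment_ids)
    flagged_unassembled = sorted(
        p.protein_id for p in candidates if p.protein_id not in consumed
    )
    # fragments leave their clusters; assemblies are offered to clusters
    for c in clusters.values():
        for m in sorted(c.members & consumed):
            c.members.discard(m)
            c.member_provenance.pop(m, None)
    clusters = {cid: c for cid, c in clusters.items() if len(c.members) >= 2}
    member_of = membership_map(clusters)
    subjects = [records[m] for m in sorted(member_of)]
    for a in assemblies:
        reassign_assembly(a, clusters, subjects, cfg)
        rec = a.as_protein()
        records[a.assembly_id] = rec
        genome_of[a.assembly_id] = a.genome_id
        call = a.scl_after
        scl_calls[a.assembly_id] = call
        for fid in a.fragment_ids:
            scl_calls.pop(fid, None)
    say(f"pseudogenes: {len(candidates)} candidates, {len(assemblies)} assemblies")

    # 7. QC distant sweep (fragments already replaced)
    member_of = membership_map(clusters)
    pool = sorted(set(scl_calls) - set(member_of))
    qc_assignments, qc_rounds = qc_distant_sweep(clusters, pool, hit_table, cfg)
    say(f"QC sweep: {len(qc_assignments)} absorbed in {qc_rounds} rounds")

    # start-codon anomaly report (suggestion only)
    anomalies: list[tuple[str, str, int, list[int]]] = []
    for cid in sorted(clusters):
        anomalies.extend(flag_start_anomalies(clusters[cid], records, all_contigs, cfg))

    # 8. secretome extraction
    sec_clusters, below = extract_secretome_lacogs(clusters, scl_calls, cfg)
    say(f"secretome clusters: {len(sec_clusters)}")

    # 9. leftovers
    member_of = membership_map(clusters)
    leftovers = sorted(set(scl_calls) - set(member_of))
    verdicts = classify_unclustered(
        leftovers,
        reference_hits,
        clustered=set(member_of),
        config=cfg,
        scl_calls=scl_calls,
        domain_map=domain_map,
        surface_domains=surface_domains,
    )

    # 10. summaries and comparative analysis
    summaries = summarize_genomes(
        genomes, clusters, scl_calls, verdicts, genome_of, total_inputs
    )
    patterns = classify_phyletic_patterns(clusters, genomes, genome_of, cfg)
    lengths = {pid: records[pid].length for pid in records}
    architectures = profile_architectures(clusters, domain_map, lengths)

    return RunResult(
        genomes=genomes,
        config=cfg,
        hit_table=hit_table,
        clusters=clusters,
        decisions=decisions,
        qc_assignments=qc_assignments,
        qc_rounds=qc_rounds,
        scl_calls=scl_calls,
        screen_events=screen_events,
        assemblies=assemblies,
        flagged_unassembled=flagged_unassembled,
        consumed_fragments=consumed,
        start_anomalies=anomalies,
        verdicts=verdicts,
        secretome_clusters=sec_clusters,
        below_majority=below,
        summaries=summaries,
        patterns=patterns,
        architectures=architectures,
        genome_of=genome_of,
    )
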