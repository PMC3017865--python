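"""Secretome cluster extraction and per-genome summaries.

A cluster is a secretome cluster when at least half of its members (the
``secretome_majority_fraction``, ties included) carry a secretome
subcellular location.  Within an emitted cluster only the secretome
members are exported; mixed families are flagged.  Secretome members of
below-majority clusters are reported in a side table rather than dropped
silently, mirroring the manual inspection such families receive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import PipelineConfig
from .clustering import LaCOG
from .scl import SCLCall


@dataclass
class SecretomeCluster:
    cluster_id: str
    n_members: int
    secretome_members: set[str]
    secretome_fraction: float
    mixed_flag: bool


@dataclass
class GenomeSummary:
    genome_id: str
    total_proteins: int
    secretome_size: int
    secretome_pct: float
    in_lacog: int
    distant_homologs: int
    orfans: int
    n_lacogs: int


def extract_secretome_lacogs(
    clusters: Mapping[str, LaCOG],
    calls: Mapping[str, SCLCall],
    config: PipelineConfig | None = None,
) -> tuple[list[SecretomeCluster], list[tuple[str, str]]]:
    """Apply the majority rule to every cluster.

    Returns the emitted secretome clusters and a ``(cluster_id,
    protein_id)`` side list of secretome members stranded in
    below-majority clusters.  Every member must have an SCL call.
    """
    cfg = config or PipelineConfig()
    emitted: list[SecretomeCluster] = []
    below: list[tuple[str, str]] = []
    for cid in sorted(clusters):
        c = clusters[cid]
        if not c.members:
            continue
        sec: set[str] = set()
        for m in c.members:
            call = calls.get(m)
            if call is None:
                raise ValueError(f"member {m} of {cid} has no SCL call")
            if call.is_secretome:
                sec.add(m)
        frac = len(sec) / len(c.members)
        if frac >= cfg.secretome_majority_fraction:
            emitted.append(
                SecretomeCluster(
                    cluster_id=cid,
                    n_members=len(c.members),
                    secretome_members=sec,
                    secretome_fraction=frac,
                    mixed_flag=0.0 < frac < 1.0,
                )
            )
        else:
            below.extend((cid, m) for m in sorted(sec))
    return emitted, below


def summarize_genomes(
    genomes,
    clusters: Mapping[str, LaCOG],
    calls: Mapping[str, SCLCall],
    verdicts,
    genome_of: Mapping[str, str],
    total_inputs: Mapping[str, int],
) -> list[GenomeSummary]:
    """Per-genome secretome bookkeeping (Table-style roles).

    ``secretome_size`` counts secretome-called entities attributed to the
    genome (assembled pseudoproteins count once; their consumed fragments
    do not).  The trichotomy ``secretome_size == in_lacog +
    distant_homologs + orfans`` holds by construction.  ``n_lacogs``
    counts secretome-containing clusters with at least one member from the
    genome.
    """
    member_of: dict[str, str] = {}
    for cid, c in clusters.items():
        for m in c.members:
            member_of[m] = cid
    verdict_by_pid = {v.protein_id: v for v in verdicts}

    out: list[GenomeSummary] = []
    for g in sorted(genomes, key=lambda g: g.genome_id):
        gid = g.genome_id
        pids = [p for p, gg in genome_of.items() if gg == gid and p in calls]
        sec = [p for p in pids if calls[p].is_secretome]
        in_lacog = [p for p in sec if p in member_of]
        distant = [
            p for p in sec
            if p in verdict_by_pid and verdict_by_pid[p].category == "DISTANT_HOMOLOG_NONLAB"
        ]
        orfans = [
            p for p in sec
            if p in verdict_by_pid and verdict_by_pid[p].category == "ORFAN"
        ]
        lacog_ids = {member_of[p] for p in in_lacog}
        total = total_inputs.get(gid, len(pids))
        out.append(
            GenomeSummary(
                genome_id=gid,
                total_proteins=total,
                secretome_size=len(sec),
                secretome_pct=100.0 * len(sec) / total if total else 0.0,
                in_lacog=len(in_lacog),
                distant_homologs=len(distant),
                orfans=len(orfans),
                n_lacogs=len(lacog_ids),
            )
        )
    return out
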