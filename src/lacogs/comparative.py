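"""Phyletic-pattern classification and domain-architecture profiling.

The presence/absence profile of each cluster across the genome panel is
classified with a strict precedence:

1. UBIQUITOUS — missing in at most ``ubiquitous_max_missing`` genomes
   (default 1: fully conserved or lacking in a single genome);
2. NICHE_SPECIFIC(tag) — every present genome carries one common niche
   tag and at least two genomes are present;
3. SPECIES_SPECIFIC — confined to one species with at least two strains
   present;
4. STRAIN_SPECIFIC — present in exactly one genome;
5. VARIABLE — everything else.

Architecture profiling renders each member's ordered N->C domain string
with consecutive repeats collapsed (``LysM×2+NLPC_P60``); clusters whose
members disagree are flagged heterogeneous.  A suggested split (members
grouped by architecture string) is reported but never applied to the
cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import PipelineConfig
from .clustering import LaCOG
from .io_core import GenomeBundle


@dataclass
class PhyleticPattern:
    cluster_id: str
    presence: dict[str, int]  # genome_id -> member count (all genomes keyed)
    n_present: int
    category: str  # e.g. "UBIQUITOUS", "NICHE_SPECIFIC(GI-tract)"


@dataclass
class ArchitectureProfile:
    cluster_id: str
    member_architectures: dict[str, str]
    heterogeneous_flag: bool

    def suggested_split(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for pid, arch in sorted(self.member_architectures.items()):
            groups.setdefault(arch, []).append(pid)
        return groups


def classify_presence(
    present: set[str],
    genomes: list[GenomeBundle],
    config: PipelineConfig | None = None,
) -> str:
    """Classify one presence set over the genome panel (precedence above)."""
    cfg = config or PipelineConfig()
    if not present:
        raise ValueError("a cluster must be present in at least one genome")
    n_missing = len(genomes) - len(present)
    if n_missing <= cfg.ubiquitous_max_missing:
        return "UBIQUITOUS"
    by_id = {g.genome_id: g for g in genomes}
    if len(present) >= 2:
        all_tags = sorted({t for g in genomes for t in g.niche_tags})
        for tag in all_tags:
            if all(tag in by_id[gid].niche_tags for gid in present):
                return f"NICHE_SPECIFIC({tag})"
        species = {by_id[gid].species_label for gid in present}
        if len(species) == 1:
            return "SPECIES_SPECIFIC"
    if len(present) == 1:
        return "STRAIN_SPECIFIC"
    return "VARIABLE"


def classify_phyletic_patterns(
    clusters: Mapping[str, LaCOG],
    genomes: list[GenomeBundle],
    genome_of: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> list[PhyleticPattern]:
    cfg = config or PipelineConfig()
    out: list[PhyleticPattern] = []
    gids = [g.genome_id for g in genomes]
    for cid in sorted(clusters):
        c = clusters[cid]
        presence = {gid: 0 for gid in gids}
        for m in c.members:
            gid = genome_of.get(m)
            if gid in presence:
                presence[gid] += 1
        present = {gid for gid, n in presence.items() if n > 0}
        if not present:
            continue
        out.append(
            PhyleticPattern(
                cluster_id=cid,
                presence=presence,
                n_present=len(present),
                category=classify_presence(present, genomes, cfg),
            )
        )
    return out


def _architecture_string(domains: list[tuple[str, int, int, float]]) -> str:
    """Ordered N->C architecture with repeats collapsed.

    Overlapping hits are resolved by higher score, then earlier start.
    """
    chosen: list[tuple[str, int, int]] = []
    for acc, s, e, score in sorted(domains, key=lambda d: (-d[3], d[1], d[0])):
        if all(e < cs or s > ce for _a, cs, ce in chosen):
            chosen.append((acc, s, e))
    chosen.sort(key=lambda d: d[1])
    parts: list[str] = []
    counts: list[int] = []
    for acc, _s, _e in chosen:
        if parts and parts[-1] == acc:
            counts[-1] += 1
        else:
            parts.append(acc)
            counts.append(1)
    return "+".join(
        f"{acc}×{n}" if n > 1 else acc for acc, n in zip(parts, counts)
    )


def profile_architectures(
    clusters: Mapping[str, LaCOG],
    domain_map: Mapping[str, list[tuple[str, int, int, float]]],
    protein_lengths: Mapping[str, int] | None = None,
) -> list[ArchitectureProfile]:
    """Per-cluster domain architecture strings.

    Domains extending beyond the protein span are ignored when lengths are
    known.  Clusters with at least two distinct member strings are flagged
    heterogeneous.
    """
    out: list[ArchitectureProfile] = []
    for cid in sorted(clusters):
        c = clusters[cid]
        archs: dict[str, str] = {}
        for m in sorted(c.members):
            doms = domain_map.get(m, [])
            if protein_lengths is not None and m in protein_lengths:
                doms = [d for d in doms if 1 <= d[1] and d[2] <= protein_lengths[m]]
            archs[m] = _architecture_string(doms)
        flag = len(set(archs.values())) >= 2
        out.append(ArchitectureProfile(cid, archs, flag))
    return out
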