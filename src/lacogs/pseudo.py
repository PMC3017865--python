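"""Frameshifted pseudogene detection and fragment concatenation.

A pseudogene split by a frameshift is annotated as two (or more) short
adjacent ORFs whose products each match only part of a full-length family
member.  The stages here:

* *flagging* — a protein is a fragment candidate when it is shorter than
  ``fragment_length_fraction`` (0.6) of its family's median member length
  and its best family hit covers less than ``fragment_subject_cov_max``
  (0.6) of the subject;
* *assembly* — adjacent candidates (same contig and strand, genomic gap
  at most ``max_fragment_gap`` nt) are translated from their annotated
  gene regions in the annotated frame, with no start-codon requirement
  and truncation at the first stop, and concatenated in genomic order
  (5'->3' of the coding strand) with a literal ``x`` at each junction;
* *reassignment* — the concatenated protein is searched against the
  clustered proteins (the junction ``x`` scores zero against everything)
  and offered to clusters by the uniform top-k rule; its subcellular
  location is re-predicted on the assembled sequence.

Candidates that find no adjacent partner are reported as
flagged-but-unassembled.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional

from Bio.Seq import Seq

from .config import PipelineConfig
from .clustering import LaCOG, AssignmentDecision, _decide_top_k, membership_map
from .homology import Hit, HitTable, search_one_vs_all
from .io_core import ProteinRecord
from .scl import SCLCall, heuristic_scl


@dataclass
class PseudoAssembly:
    """A concatenated frameshift-fragment protein."""

    assembly_id: str
    fragment_ids: list[str]  # genomic order, 5'->3' of the coding strand
    genome_id: str
    contig_id: str
    span: tuple[int, int]
    strand: str
    assembled_sequence: str  # literal 'x' at each junction
    assigned_cluster: Optional[str] = None
    scl_after: Optional[SCLCall] = None

    def __post_init__(self) -> None:
        if len(self.fragment_ids) < 2:
            raise ValueError("an assembly needs at least two fragments")
        if self.assembled_sequence.count("x") != len(self.fragment_ids) - 1:
            raise ValueError("junction count must equal fragments - 1")

    def as_protein(self) -> ProteinRecord:
        return ProteinRecord(
            protein_id=self.assembly_id,
            genome_id=self.genome_id,
            sequence=self.assembled_sequence,
            contig_id=self.contig_id,
            start=self.span[0],
            end=self.span[1],
            strand=self.strand,
            description="concatenated pseudoprotein",
        )


def flag_fragment_candidates(
    protein: ProteinRecord,
    family: LaCOG,
    member_lengths: Mapping[str, int],
    hit_table: HitTable,
    config: PipelineConfig | None = None,
) -> bool:
    """True when the protein looks like a fragment of its family's proteins.

    Requires at least one hit into the family.  The length test is a
    strict less-than against the median length of the other members.
    """
    cfg = config or PipelineConfig()
    others = [
        member_lengths[m]
        for m in family.members
        if m != protein.protein_id and m in member_lengths
    ]
    if not others:
        return False
    best: Optional[Hit] = None
    for h in hit_table.hits_for(protein.protein_id):
        if h.subject_id in family.members and h.subject_id != protein.protein_id:
            best = h
            break
    if best is None:
        return False
    median = statistics.median(others)
    return (
        protein.length < cfg.fragment_length_fraction * median
        and best.s_cov < cfg.fragment_subject_cov_max
    )


def _translate_region(contig: str, start: int, end: int, strand: str) -> str:
    """Translate an annotated gene region in its frame, stopping at the
    first stop codon; no start codon is required."""
    nt = contig[start - 1 : end]
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(to_stop=True))
    return aa


def assemble_adjacent_fragments(
    candidates: list[ProteinRecord],
    contigs: Mapping[str, str],
    config: PipelineConfig | None = None,
    id_prefix: str = "pseudo",
) -> list[PseudoAssembly]:
    """Group adjacent fragment candidates and concatenate their translations.

    Candidates without coordinates or contig sequence are skipped; groups
    of one produce no assembly.  Fragments overlapping by more than one
    codon are an ambiguous annotation and a hard error.
    """
    cfg = config or PipelineConfig()
    usable = [
        p
        for p in candidates
        if p.contig_id is not None
        and p.start is not None
        and p.end is not None
        and p.strand in ("+", "-")
        and p.contig_id in contigs
    ]
    groups: dict[tuple[str, str, str], list[ProteinRecord]] = {}
    for p in usable:
        groups.setdefault((p.genome_id, p.contig_id, p.strand), []).append(p)

    assemblies: list[PseudoAssembly] = []
    counter: dict[str, int] = {}
    for (gid, ctg, strand) in sorted(groups):
        frags = sorted(groups[(gid, ctg, strand)], key=lambda p: p.start)
        chain: list[ProteinRecord] = []
        chains: list[list[ProteinRecord]] = []
        for p in frags:
            if chain and p.start - chain[-1].end - 1 <= cfg.max_fragment_gap:
                if p.start <= chain[-1].end - 3:
                    raise ValueError(
                        f"fragments {chain[-1].protein_id} and {p.protein_id} "
                        f"overlap by more than a codon"
                    )
                chain.append(p)
            else:
                if len(chain) >= 2:
                    chains.append(chain)
                chain = [p]
        if len(chain) >= 2:
            chains.append(chain)
        for chain in chains:
            ordered = chain if strand == "+" else list(reversed(chain))
            parts = [
                _translate_region(contigs[ctg], p.start, p.end, strand)
                for p in ordered
            ]
            n = counter.get(gid, 0) + 1
            counter[gid] = n
            assemblies.append(
                PseudoAssembly(
                    assembly_id=f"{gid}_{id_prefix}{n:03d}",
                    fragment_ids=[p.protein_id for p in ordered],
                    genome_id=gid,
                    contig_id=ctg,
                    span=(min(p.start for p in chain), max(p.end for p in chain)),
                    strand=strand,
                    assembled_sequence="x".join(parts),
                )
            )
    return assemblies


def reassign_assembly(
    assembly: PseudoAssembly,
    clusters: dict[str, LaCOG],
    subjects: list[ProteinRecord],
    config: PipelineConfig | None = None,
) -> PseudoAssembly:
    """Search the assembled sequence and offer it to clusters by top-k.

    The junction 'x' is a zero-scoring wildcard inside the aligner.  The
    assembly's subcellular location is re-predicted from the assembled
    sequence.  Mutates ``clusters`` when assigned; fills ``assigned_cluster``
    and ``scl_after``.
    """
    cfg = config or PipelineConfig()
    hits = search_one_vs_all(
        assembly.assembled_sequence, assembly.assembly_id, subjects, cfg
    )
    member_of = membership_map(clusters)
    decision = _decide_top_k(assembly.assembly_id, hits, member_of, clusters, cfg)
    if decision.target_cluster_id is not None:
        clusters[decision.target_cluster_id].add(assembly.assembly_id, "pseudo_assembly")
        assembly.assigned_cluster = decision.target_cluster_id
    assembly.scl_after = heuristic_scl(assembly.as_protein(), cfg)
    return assembly


def flag_start_anomalies(
    cluster: LaCOG,
    records: Mapping[str, ProteinRecord],
    contigs: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> list[tuple[str, str, int, list[int]]]:
    """Members whose N-terminus disagrees with the family's longest member.

    A member aligned to the longest member with an N-terminal
    overhang/truncation larger than ``start_overhang_min`` residues is
    flagged.  When the member's nucleotide context is available, in-frame
    upstream/downstream ATG/GTG/TTG positions are suggested.  Suggestion
    only — sequences are never modified.  Returns
    ``(protein_id, cluster_id, overhang, suggestions)`` tuples.
    """
    cfg = config or PipelineConfig()
    members = [records[m] for m in sorted(cluster.members) if m in records]
    if len(members) < 3:
        return []
    longest = max(members, key=lambda p: (p.length, p.protein_id))
    flagged: list[tuple[str, str, int, list[int]]] = []
    for p in members:
        if p.protein_id == longest.protein_id:
            continue
        hits = search_one_vs_all(p.sequence, p.protein_id, [longest], cfg)
        if not hits:
            continue
        h = hits[0]
        # offset between where the alignment starts on each sequence:
        # a large positive value means the member is missing N-terminal
        # residues present in the longest member (or vice versa).
        overhang = abs((h.s_span[0] - 1) - (h.q_span[0] - 1))
        if overhang > cfg.start_overhang_min:
            sugg: list[int] = []
            if (
                contigs is not None
                and p.contig_id in (contigs or {})
                and p.start is not None
                and p.end is not None
                and p.strand == "+"
            ):
                contig = contigs[p.contig_id]
                window = 3 * (overhang + 10)
                for pos in range(max(0, p.start - 1 - window), p.start - 1 + window, 3):
                    codon = contig[pos : pos + 3]
                    if codon in ("ATG", "GTG", "TTG") and (p.start - 1 - pos) % 3 == 0:
                        sugg.append(pos + 1)
            flagged.append((p.protein_id, cluster.cluster_id, overhang, sugg))
    return flagged
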