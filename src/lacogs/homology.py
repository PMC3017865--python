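"""Pairwise similarity search and the bidirectional-best-hit relation.

The built-in aligner computes exact Smith-Waterman local alignments under
BLOSUM62 with affine gaps (open 11, extend 1), the scoring used by
protein database search.  Bit scores follow the Karlin-Altschul
transformation with fixed gapped parameters (lambda = 0.267, K = 0.041);
the expectation value is ``m * D * 2**-bits`` with m the query length
and D a *fixed* effective database size (``effective_db_residues``,
default 1e5 residues).  A constant search-space term keeps a hit's
E-value independent of what else happens to be in the batch — results
are reproducible protein-by-protein — while giving the permissive
``E < 1`` intake gate the database-scale stringency it is meant to
have; with a pair-level E-value that gate would admit random hits from
every short protein.  When hits come from an external search instead,
the E-values of the input file are preserved.

An all-vs-all run first collects candidate pairs sharing at least one
k-mer (k = 5 by default); every candidate is then aligned exactly.  The
prescreen can be disabled (``kmer_prescreen_min = 0``) to force alignment
of every pair.

The 'x' junction marker of concatenated pseudoproteins scores zero against
every residue, so junctions neither reward nor penalise an alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import PipelineConfig
from .io_core import ProteinRecord

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041
LN2 = math.log(2.0)

GAP_OPEN = 11
GAP_EXTEND = 1


def _wildcard_blosum62():
    """BLOSUM62 with the X row/column zeroed (wildcard scores 0 vs all)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    alphabet = m.alphabet
    xi = alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return out


_MATRIX = _wildcard_blosum62()


def _make_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _MATRIX
    al.open_gap_score = -float(GAP_OPEN)
    al.extend_gap_score = -float(GAP_EXTEND)
    return al


def raw_to_bits(score: float) -> float:
    return (KARLIN_LAMBDA * score - math.log(KARLIN_K)) / LN2


def evalue_for_bits(bits: float, m: int, db_residues: float) -> float:
    return m * db_residues * 2.0 ** (-bits)


def evalue_for(score: float, m: int, n: int, db_residues: float | None = None) -> float:
    """Expectation value for a raw score; ``db_residues`` fixes the
    effective search space (defaults to the subject length: pair-level)."""
    return m * (db_residues if db_residues is not None else n) * 2.0 ** (
        -raw_to_bits(score)
    )


@dataclass
class Hit:
    """One directed pairwise similarity hit."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    identity: float  # fraction of aligned columns that are identical
    aln_length: int  # alignment columns including gaps
    q_span: tuple[int, int]  # 1-based inclusive aligned interval on the query
    s_span: tuple[int, int]
    q_cov: float  # aligned query residues / query length
    s_cov: float
    qlen: int
    slen: int

    def rank_key(self):
        return (-self.bitscore, self.evalue, self.subject_id)


class HitTable:
    """Per-query ranked hit lists.

    Each list is sorted by (bitscore desc, evalue asc, subject id asc) and
    contains at most one hit per (query, subject) pair — the best-scoring
    one is kept.
    """

    def __init__(self, by_query: dict[str, list[Hit]] | None = None,
                 self_hits_excluded: bool = True):
        self.by_query: dict[str, list[Hit]] = by_query or {}
        self.self_hits_excluded = self_hits_excluded

    def hits_for(self, query_id: str) -> list[Hit]:
        return self.by_query.get(query_id, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_query.values())

    def all_hits(self) -> Iterable[Hit]:
        for q in self.by_query:
            yield from self.by_query[q]


def rank_hits(hits: Iterable[Hit], exclude_self: bool = True) -> HitTable:
    """Group raw hits by query, deduplicate pairs, and rank deterministically."""
    best: dict[tuple[str, str], Hit] = {}
    for h in hits:
        if exclude_self and h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or h.rank_key() < prev.rank_key():
            best[key] = h
    by_query: dict[str, list[Hit]] = {}
    for h in best.values():
        by_query.setdefault(h.query_id, []).append(h)
    for q in by_query:
        by_query[q].sort(key=Hit.rank_key)
    return HitTable(by_query, self_hits_excluded=exclude_self)


def align_local(
    seq_a: str,
    seq_b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Align.PairwiseAligner | None = None,
) -> Optional[Hit]:
    """Exact local alignment of two sequences; None when nothing scores > 0."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    al = aligner or _make_aligner()
    a = seq_a.upper()
    b = seq_b.upper()
    score = al.score(a, b)
    if score <= 0:
        return None
    aln = al.align(a, b)[0]
    return _hit_from_alignment(aln, score, query_id, subject_id, len(a), len(b))


def _hit_from_alignment(aln, score, query_id, subject_id, m, n,
                        db_residues: float | None = None) -> Hit:
    counts = aln.counts()
    identities = counts.identities
    aln_length = counts.aligned + counts.gaps
    qa, sa = aln.aligned  # per-sequence aligned block coordinates (0-based)
    q_res = int(sum(e - s for s, e in qa))
    s_res = int(sum(e - s for s, e in sa))
    q_span = (int(qa[0][0]) + 1, int(qa[-1][1]))
    s_span = (int(sa[0][0]) + 1, int(sa[-1][1]))
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        bitscore=raw_to_bits(score),
        evalue=evalue_for(score, m, n, db_residues),
        identity=identities / counts.aligned if counts.aligned else 0.0,
        aln_length=int(aln_length),
        q_span=q_span,
        s_span=s_span,
        q_cov=q_res / m,
        s_cov=s_res / n,
        qlen=m,
        slen=n,
    )


def _candidate_pairs(proteins: list[ProteinRecord], k: int, min_shared: int):
    """Indices of protein pairs sharing at least ``min_shared`` k-mers."""
    from collections import Counter, defaultdict

    buckets: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(proteins):
        seq = p.sequence.upper()
        for km in {seq[j : j + k] for j in range(len(seq) - k + 1)}:
            if "X" in km:
                continue
            buckets[km].append(i)
    counts: Counter[tuple[int, int]] = Counter()
    for idx in buckets.values():
        if len(idx) < 2:
            continue
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                counts[(idx[a], idx[b])] += 1
    return [pair for pair, c in sorted(counts.items()) if c >= min_shared]


def _min_score_for_evalue(emax: float, m: int, n: float) -> float:
    """Smallest raw score whose E-value could pass the gate for lengths m, n."""
    bits_needed = math.log2(m * n / emax)
    return (bits_needed * LN2 + math.log(KARLIN_K)) / KARLIN_LAMBDA


def all_vs_all(
    proteins: list[ProteinRecord], config: PipelineConfig | None = None
) -> HitTable:
    """Built-in all-vs-all search emitting hits in both directions.

    Pairs are prescreened by shared k-mers, scored exactly, and fully
    aligned (traceback, identity, coverage) only when the score can pass
    the E-value gate.  Self hits are excluded from the ranked table.
    """
    cfg = config or PipelineConfig()
    al = _make_aligner()
    n_prot = len(proteins)
    if cfg.kmer_prescreen_min > 0:
        pairs = _candidate_pairs(proteins, cfg.kmer_prescreen_k, cfg.kmer_prescreen_min)
    else:
        pairs = [(i, j) for i in range(n_prot) for j in range(i + 1, n_prot)]
    seqs = [p.sequence.upper() for p in proteins]
    hits: list[Hit] = []
    for i, j in pairs:
        a, b = seqs[i], seqs[j]
        score = al.score(a, b)
        if score <= 0:
            continue
        db = cfg.effective_db_residues
        if (
            evalue_for(score, len(a), len(b), db) > cfg.initial_evalue_max
            and evalue_for(score, len(b), len(a), db) > cfg.initial_evalue_max
        ):
            continue
        aln = al.align(a, b)[0]
        fwd = _hit_from_alignment(
            aln, score, proteins[i].protein_id, proteins[j].protein_id, len(a), len(b),
            db_residues=db,
        )
        hits.append(fwd)
        hits.append(
            Hit(
                query_id=fwd.subject_id,
                subject_id=fwd.query_id,
                bitscore=fwd.bitscore,
                evalue=evalue_for_bits(fwd.bitscore, len(b), db),
                identity=fwd.identity,
                aln_length=fwd.aln_length,
                q_span=fwd.s_span,
                s_span=fwd.q_span,
                q_cov=fwd.s_cov,
                s_cov=fwd.q_cov,
                qlen=fwd.slen,
                slen=fwd.qlen,
            )
        )
    return rank_hits(hits, exclude_self=True)


def search_one_vs_all(
    query_seq: str,
    query_id: str,
    subjects: list[ProteinRecord],
    config: PipelineConfig | None = None,
) -> list[Hit]:
    """Ranked hits of a single query sequence against a protein set."""
    cfg = config or PipelineConfig()
    al = _make_aligner()
    q = query_seq.upper()
    hits: list[Hit] = []
    for s in subjects:
        if s.protein_id == query_id:
            continue
        b = s.sequence.upper()
        score = al.score(q, b)
        if score <= 0:
            continue
        if evalue_for(score, len(q), len(b), cfg.effective_db_residues) > cfg.initial_evalue_max:
            continue
        aln = al.align(q, b)[0]
        hits.append(
            _hit_from_alignment(
                aln, score, query_id, s.protein_id, len(q), len(b),
                db_residues=cfg.effective_db_residues,
            )
        )
    hits.sort(key=Hit.rank_key)
    return hits


# ---------------------------------------------------------------------------
# BBH


@dataclass(frozen=True)
class BBHPair:
    """A mutual best-hit pair across two genomes (a < b lexicographically)."""

    protein_a: str
    protein_b: str
    bitscore_ab: float
    bitscore_ba: float

    @property
    def total_bitscore(self) -> float:
        return self.bitscore_ab + self.bitscore_ba


def _hit_survives(h: Hit, cfg: PipelineConfig) -> bool:
    if h.bitscore < cfg.bbh_min_bitscore:
        return False
    denom = (
        max(h.qlen, h.slen)
        if cfg.bbh_overlap_denominator == "longer"
        else min(h.qlen, h.slen)
    )
    return h.aln_length / denom >= cfg.bbh_min_overlap


def compute_bbh(
    hit_table: HitTable,
    genome_of: Mapping[str, str],
    config: PipelineConfig | None = None,
    restrict_to: set[str] | None = None,
) -> set[BBHPair]:
    """Bidirectional best hits across genomes under the bit-score/overlap gates.

    The best hit of a protein in another genome is its highest-ranked
    *surviving* hit there (ties already broken by the hit-table order), so
    a protein never has two BBH partners within one genome.  Within-genome
    hits are ignored: the relation is cross-genome by definition.
    """
    cfg = config or PipelineConfig()
    best: dict[tuple[str, str], Hit] = {}
    for q, hits in hit_table.by_query.items():
        if restrict_to is not None and q not in restrict_to:
            continue
        gq = genome_of.get(q)
        seen_genomes: set[str] = set()
        for h in hits:
            gs = genome_of.get(h.subject_id)
            if gs is None or gs == gq:
                continue
            if restrict_to is not None and h.subject_id not in restrict_to:
                continue
            if gs in seen_genomes:
                continue
            if _hit_survives(h, cfg):
                best[(q, gs)] = h
                seen_genomes.add(gs)
    pairs: set[BBHPair] = set()
    for (q, _gs), h in best.items():
        s = h.subject_id
        back = best.get((s, genome_of[q]))
        if back is not None and back.subject_id == q and q < s:
            pairs.add(BBHPair(q, s, h.bitscore, back.bitscore))
    return pairs
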