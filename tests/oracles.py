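"""Independent brute-force oracles used by the test suite.

Deliberately written from first principles, without reusing the package's
own code paths, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_ext: float = 1.0) -> float:
    """Exhaustive Gotoh local-alignment score under BLOSUM62.

    Affine convention matching the package's aligner: a gap of length k
    scores -(gap_open + (k - 1) * gap_ext).
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            s = _B62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def topk_assignment_oracle(
    ranked_subjects: list[str],
    member_of: dict[str, str],
    cluster_sizes: dict[str, int],
    k_default: int = 3,
) -> str | None:
    """Exhaustive check of the uniform top-k rule over every cluster."""
    matches = []
    for cid, size in cluster_sizes.items():
        k = 2 if size == 2 else k_default
        if len(ranked_subjects) < k:
            continue
        if all(member_of.get(s) == cid for s in ranked_subjects[:k]):
            matches.append(cid)
    assert len(matches) <= 1, "top-k prefix cannot lie in two clusters"
    return matches[0] if matches else None


def bbh_oracle(hits, genome_of, min_bits=50.0, min_overlap=0.5):
    """O(n^2) enumeration of bidirectional best hits.

    ``hits``: iterable of objects with query_id, subject_id, bitscore,
    evalue, aln_length, qlen, slen.  Best = lexicographically smallest
    (-bitscore, evalue, subject_id) among surviving cross-genome hits.
    """
    surviving = [
        h
        for h in hits
        if h.bitscore >= min_bits
        and h.aln_length / max(h.qlen, h.slen) >= min_overlap
        and genome_of[h.query_id] != genome_of[h.subject_id]
    ]
    best: dict[tuple[str, str], str] = {}
    key: dict[tuple[str, str], tuple] = {}
    for h in surviving:
        slot = (h.query_id, genome_of[h.subject_id])
        k = (-h.bitscore, h.evalue, h.subject_id)
        if slot not in key or k < key[slot]:
            key[slot] = k
            best[slot] = h.subject_id
    pairs = set()
    for (q, gs), s in best.items():
        if best.get((s, genome_of[q])) == q:
            pairs.add(frozenset((q, s)))
    return pairs


def majority_oracle(labels: list[bool], fraction: float = 0.5) -> bool:
    """A cluster is a secretome cluster iff #secretome/#members >= fraction."""
    return sum(labels) / len(labels) >= fraction


def phyletic_oracle(
    present: set[str],
    all_genomes: list[str],
    species: dict[str, str],
    niches: dict[str, set[str]],
    max_missing: int = 1,
) -> str:
    """Brute-force phyletic category with the documented precedence."""
    if len(all_genomes) - len(present) <= max_missing:
        return "UBIQUITOUS"
    if len(present) >= 2:
        tags = sorted(set().union(*niches.values())) if niches else []
        for t in tags:
            if all(t in niches.get(g, set()) for g in present):
                return f"NICHE_SPECIFIC({t})"
        if len({species[g] for g in present}) == 1:
            return "SPECIES_SPECIFIC"
    if len(present) == 1:
        return "STRAIN_SPECIFIC"
    return "VARIABLE"
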