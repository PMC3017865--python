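"""Classification of proteins left outside all clusters.

After clustering, every leftover protein is searched against reference
(non-LAB) proteomes.  A protein with at least one surviving reference hit
under the distant-homolog criterion (E <= 1e-3 and length ratio, or
aligned coverage, >= 0.6) is a *distant homolog in non-LAB*; a protein
with none is an *ORFan* — no detectable homolog in any other sequenced
genome.  Reference searches are supplied as hit tables; no reference
database is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .config import PipelineConfig
from .clustering import _distant_criterion
from .homology import Hit, HitTable
from .scl import SCLCall


@dataclass
class UnclusteredVerdict:
    protein_id: str
    category: str  # "DISTANT_HOMOLOG_NONLAB" | "ORFAN"
    best_reference_hit: Optional[Hit] = None
    pseudo_suspect: bool = False

    def __post_init__(self) -> None:
        if self.category == "ORFAN" and self.best_reference_hit is not None:
            raise ValueError("an ORFan cannot carry a reference hit")


def classify_unclustered(
    unclustered: Iterable[str],
    reference_hits: HitTable | None,
    clustered: set[str] | None = None,
    config: PipelineConfig | None = None,
    scl_calls: Mapping[str, SCLCall] | None = None,
    domain_map: Mapping[str, list] | None = None,
    surface_domains: set[str] | None = None,
) -> list[UnclusteredVerdict]:
    """Split unclustered proteins into distant homologs and ORFans.

    ``reference_hits`` may be None (no reference search available), in
    which case everything is an ORFan.  A protein simultaneously present
    in ``clustered`` is a hard error — the caller must uphold the
    trichotomy (cluster member, distant homolog, or ORFan).

    ORFans without a secretome location but carrying a domain from
    ``surface_domains`` (accessions typical of extracellular proteins) are
    flagged as pseudogene suspects; they are not reclassified.
    """
    cfg = config or PipelineConfig()
    clustered = clustered or set()
    verdicts: list[UnclusteredVerdict] = []
    for pid in sorted(set(unclustered)):
        if pid in clustered:
            raise ValueError(f"protein {pid} is already in a cluster")
        best: Optional[Hit] = None
        if reference_hits is not None:
            for h in reference_hits.hits_for(pid):
                if _distant_criterion(h, cfg):
                    best = h
                    break
        if best is not None:
            verdicts.append(UnclusteredVerdict(pid, "DISTANT_HOMOLOG_NONLAB", best))
            continue
        suspect = False
        if scl_calls is not None and domain_map is not None and surface_domains:
            call = scl_calls.get(pid)
            if call is not None and not call.is_secretome:
                accs = {d[0] for d in domain_map.get(pid, [])}
                suspect = bool(accs & surface_domains)
        verdicts.append(UnclusteredVerdict(pid, "ORFAN", pseudo_suspect=suspect))
    return verdicts
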