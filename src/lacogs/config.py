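"""Pipeline configuration.

Every numeric threshold used by the clustering, quality-control, secretome
and pseudogene stages lives here, so that a single object documents the
parameterisation of a run and can be serialised into the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal


@dataclass
class PipelineConfig:
    """Thresholds and switches for a full pipeline run.

    Defaults follow the standard parameterisation of the method:

    * similarity search with a permissive expectation gate (``E < 1``) and
      the low-complexity filter disabled;
    * bidirectional-best-hit (BBH) cores gated at bit score 50 and 50%
      sequence overlap;
    * cluster extension by the "uniform top 3" rule (top 2 when the target
      cluster has exactly two members);
    * the distant-homolog sweep at ``E <= 1e-3`` and query/hit length ratio
      >= 0.6;
    * secretome clusters require at least half of the members to carry a
      secretome subcellular location;
    * proteins shorter than 80 residues whose only export feature is a
      Sec-type signal peptide are removed;
    * clusters created in this run are numbered with a leading "9".
    """

    # similarity search
    initial_evalue_max: float = 1.0
    low_complexity_filter: bool = False
    kmer_prescreen_k: int = 5
    kmer_prescreen_min: int = 1  # 0 disables the prescreen entirely
    # fixed effective database size (residues) for built-in E-values; a
    # constant keeps results independent of batch composition while giving
    # the E < 1 gate the database-scale stringency it is meant to have.
    # Default: the scale of a multi-genome LAB panel (~26 genomes x ~2000
    # proteins x ~300 residues).
    effective_db_residues: float = 1.5e7

    # BBH cores
    bbh_min_bitscore: float = 50.0
    bbh_min_overlap: float = 0.50
    bbh_overlap_denominator: Literal["longer", "shorter"] = "longer"
    bbh_core_mode: Literal["clique", "component"] = "clique"

    # uniform top-k extension
    top_k: int = 3
    unclustered_hits_veto: bool = True

    # distant-homolog quality-control sweep
    distant_evalue_max: float = 1e-3
    distant_length_ratio_min: float = 0.6
    distant_criterion_mode: Literal["length_ratio", "query_coverage"] = "length_ratio"

    # secretome extraction
    secretome_majority_fraction: float = 0.5
    min_len_sec_only: int = 80

    # subcellular-location heuristic
    hydro_window: int = 7
    hydro_threshold: float = 1.5
    signal_region_len: int = 45
    lipobox_region_len: int = 35
    tail_region_len: int = 50
    downstream_charge_window: int = 10

    # pseudogene assembly
    fragment_length_fraction: float = 0.6
    fragment_subject_cov_max: float = 0.6
    max_fragment_gap: int = 300
    start_overhang_min: int = 20

    # phyletic classification
    ubiquitous_max_missing: int = 1

    # naming / misc
    new_cluster_prefix: str = "9"
    cluster_id_digits: int = 5
    exclude_plasmids: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bbh_min_overlap",
            "distant_length_ratio_min",
            "secretome_majority_fraction",
            "fragment_length_fraction",
            "fragment_subject_cov_max",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if self.top_k < 2:
            raise ValueError(f"top_k must be >= 2, got {self.top_k}")
        if not self.new_cluster_prefix.isdigit():
            raise ValueError("new_cluster_prefix must be a digit string")
        if len(self.new_cluster_prefix) >= self.cluster_id_digits:
            raise ValueError("new_cluster_prefix longer than the id number")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
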