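"""File formats and core record types.

The pipeline exchanges data through a small set of plain-text dialects:

* protein FASTA with an optional ``key=value`` header annotation
  (``genome_id=``, ``contig=``, ``start=``, ``end=``, ``strand=``);
* similarity hit tables in the 12-column tabular search format **plus two
  extra columns** ``qlen`` and ``slen`` (columns 13-14), which are required
  because the overlap and length-ratio rules cannot be computed from the
  standard 12 columns;
* per-protein SCL, domain and gene-feature tables, and a cluster table
  mapping cluster ids to comma-separated member lists;
* the output TSVs written by :func:`write_outputs`.

All outputs are byte-deterministic for identical inputs: clusters are
sorted by id, members lexicographically, and floats use a fixed format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .scl import SCL_CLASSES

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """One annotated protein with optional genomic coordinates."""

    protein_id: str
    genome_id: str
    sequence: str
    contig_id: Optional[str] = None
    start: Optional[int] = None  # 1-based inclusive, forward-strand coords
    end: Optional[int] = None
    strand: Optional[str] = None  # "+" | "-"
    description: str = ""
    is_pseudo_fragment: bool = False

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"{self.protein_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeBundle:
    """A genome's proteins plus its species and niche labels."""

    genome_id: str
    species_label: str = ""
    niche_tags: set[str] = field(default_factory=set)
    proteins: list[ProteinRecord] = field(default_factory=list)
    contigs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for p in self.proteins:
            if p.genome_id != self.genome_id:
                raise ValueError(
                    f"protein {p.protein_id} carries genome {p.genome_id!r}, "
                    f"bundle is {self.genome_id!r}"
                )


# ---------------------------------------------------------------------------
# FASTA

_HEADER_KEYS = {"genome_id", "contig", "start", "end", "strand"}


def read_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA with the ``key=value`` header dialect.

    ``genome_id`` serves as a default when a header carries no explicit
    ``genome_id=`` tag.  Trailing ``*`` stop symbols are stripped; sequences
    are uppercased.  Duplicate ids and non-amino-acid characters are hard
    errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        kv: dict[str, str] = {}
        extra_desc: list[str] = []
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                if k in _HEADER_KEYS:
                    kv[k] = v
                    continue
            extra_desc.append(tok)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - AA_LETTERS
        if bad:
            raise ValueError(
                f"{path}: non-amino-acid character(s) {sorted(bad)} in {pid!r}"
            )
        records.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=kv.get("genome_id", genome_id or ""),
                sequence=seq,
                contig_id=kv.get("contig"),
                start=int(kv["start"]) if "start" in kv else None,
                end=int(kv["end"]) if "end" in kv else None,
                strand=kv.get("strand"),
                description=" ".join(extra_desc),
            )
        )
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = []
    for p in proteins:
        parts = [f"genome_id={p.genome_id}"]
        if p.contig_id is not None:
            parts.append(f"contig={p.contig_id}")
        if p.start is not None:
            parts.append(f"start={p.start}")
        if p.end is not None:
            parts.append(f"end={p.end}")
        if p.strand is not None:
            parts.append(f"strand={p.strand}")
        if p.description:
            parts.append(p.description)
        recs.append(
            SeqRecord(Seq(p.sequence), id=p.protein_id, description=" ".join(parts))
        )
    SeqIO.write(recs, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Contig id -> uppercase nucleotide sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Hit tables (tabular search dialect + qlen/slen)


def read_hit_table(path: str | Path, config: PipelineConfig | None = None):
    """Parse a 14-column tabular hit file into a ranked HitTable.

    Columns: query, subject, %identity, aln_length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore, qlen, slen.  Rows with
    E-value above ``initial_evalue_max`` are dropped at load time.
    """
    from .homology import Hit, rank_hits

    cfg = config or PipelineConfig()
    path = Path(path)
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 14:
                raise ValueError(
                    f"{path}:{lineno}: expected 14 tab-separated columns "
                    f"(the 12 standard ones plus qlen and slen), got {len(cols)}"
                )
            try:
                (q, s, pident, alen, _mm, _go, qs, qe, ss, se, ev, bits, qlen, slen) = (
                    cols[0], cols[1], float(cols[2]), int(cols[3]), cols[4],
                    cols[5], int(cols[6]), int(cols[7]), int(cols[8]),
                    int(cols[9]), float(cols[10]), float(cols[11]),
                    int(cols[12]), int(cols[13]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if ev > cfg.initial_evalue_max:
                continue
            hits.append(
                Hit(
                    query_id=q,
                    subject_id=s,
                    bitscore=bits,
                    evalue=ev,
                    identity=pident / 100.0,
                    aln_length=alen,
                    q_span=(qs, qe),
                    s_span=(min(ss, se), max(ss, se)),
                    q_cov=(qe - qs + 1) / qlen,
                    s_cov=(abs(se - ss) + 1) / slen,
                    qlen=qlen,
                    slen=slen,
                )
            )
    return rank_hits(hits, exclude_self=True)


def write_hit_table(table, path: str | Path) -> None:
    """Write a HitTable back into the 14-column dialect."""
    with open(path, "w") as fh:
        for q in sorted(table.by_query):
            for h in table.by_query[q]:
                mism = int(round(h.aln_length * (1.0 - h.identity)))
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.identity * 100:.2f}",
                            str(h.aln_length),
                            str(mism),
                            "0",
                            str(h.q_span[0]),
                            str(h.q_span[1]),
                            str(h.s_span[0]),
                            str(h.s_span[1]),
                            f"{h.evalue:.3g}",
                            f"{h.bitscore:.1f}",
                            str(h.qlen),
                            str(h.slen),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Annotation tables


def read_scl_table(path: str | Path) -> dict[str, str]:
    """protein_id -> SCL class; labels outside the vocabulary are hard errors."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected protein_id<TAB>class")
            pid, label = cols[0], cols[1]
            if label not in SCL_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown SCL class {label!r}; "
                    f"valid labels: {sorted(SCL_CLASSES)}"
                )
            out[pid] = label
    return out


def read_domain_table(path: str | Path) -> dict[str, list[tuple[str, int, int, float]]]:
    """protein_id -> [(domain_accession, start, end, score)], 1-based spans."""
    out: dict[str, list[tuple[str, int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected protein_id, accession, start, end, score"
                )
            pid, acc, s, e, sc = cols[0], cols[1], int(cols[2]), int(cols[3]), float(cols[4])
            out.setdefault(pid, []).append((acc, s, e, sc))
    return out


def read_feature_table(path: str | Path) -> dict[str, tuple[str, int, int, str]]:
    """protein_id -> (contig, start, end, strand)."""
    out: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected protein_id, contig, start, end, strand"
                )
            out[cols[0]] = (cols[1], int(cols[2]), int(cols[3]), cols[4])
    return out


def read_cluster_table(path: str | Path) -> dict[str, list[str]]:
    """cluster_id -> member protein ids (comma-separated second column)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cluster_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected cluster_id<TAB>members")
            if cols[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate cluster id {cols[0]!r}")
            out[cols[0]] = [m for m in cols[1].split(",") if m]
    return out


def read_annotation_tables(
    scl_path: str | Path | None = None,
    domain_path: str | Path | None = None,
    feature_path: str | Path | None = None,
    cluster_path: str | Path | None = None,
):
    """Load the optional annotation inputs; absent paths give empty maps.

    Seed clusters of size >= 2 are usable as extension targets; singleton
    entries are returned separately — their members go back into the
    unclustered pool and are re-clustered from scratch.
    """
    scl = read_scl_table(scl_path) if scl_path else {}
    dom = read_domain_table(domain_path) if domain_path else {}
    feat = read_feature_table(feature_path) if feature_path else {}
    clusters = read_cluster_table(cluster_path) if cluster_path else {}
    extendable = {cid: m for cid, m in clusters.items() if len(m) >= 2}
    singletons = {cid: m for cid, m in clusters.items() if len(m) < 2}
    return scl, dom, feat, extendable, singletons


# ---------------------------------------------------------------------------
# Output writing

FLOAT_FMT = "{:.4f}"


def _w(fh: TextIO, *cols) -> None:
    fh.write("\t".join(str(c) for c in cols) + "\n")


def write_outputs(result, outdir: str | Path) -> None:
    """Write the full deterministic output set of a pipeline run.

    Files: clusters.tsv, assignments.tsv, secretome_clusters.tsv,
    below_majority_secretome.tsv, orfans.tsv, distant_homologs.tsv,
    pseudo_assemblies.fasta/.tsv, start_anomalies.tsv, scl_report.tsv,
    phyletic_patterns.tsv, architectures.tsv, genome_summary.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "clusters.tsv", "w") as fh:
        _w(fh, "cluster_id", "members", "origin", "n_members")
        for cid in sorted(result.clusters):
            c = result.clusters[cid]
            _w(fh, cid, ",".join(sorted(c.members)), c.origin, len(c.members))

    with open(outdir / "assignments.tsv", "w") as fh:
        _w(fh, "protein_id", "cluster_id", "rule", "provenance", "examined_hits")
        rows = []
        for cid in sorted(result.clusters):
            c = result.clusters[cid]
            for pid in sorted(c.members):
                rows.append((pid, cid, c.provenance.get(pid, "")))
        for pid, cid, prov in sorted(rows):
            dec = result.decisions.get(pid)
            rule = dec.rule if dec else ""
            examined = (
                ";".join(f"{sid}:{tc or '-'}" for sid, tc in dec.top_hits_examined)
                if dec
                else ""
            )
            _w(fh, pid, cid, rule, prov, examined)

    with open(outdir / "secretome_clusters.tsv", "w") as fh:
        _w(
            fh, "cluster_id", "n_members", "n_secretome",
            "secretome_fraction", "mixed_flag", "secretome_members",
        )
        for sc in sorted(result.secretome_clusters, key=lambda s: s.cluster_id):
            _w(
                fh, sc.cluster_id, sc.n_members, len(sc.secretome_members),
                FLOAT_FMT.format(sc.secretome_fraction), int(sc.mixed_flag),
                ",".join(sorted(sc.secretome_members)),
            )

    with open(outdir / "below_majority_secretome.tsv", "w") as fh:
        _w(fh, "protein_id", "cluster_id", "scl_class")
        for cid, pid in sorted(result.below_majority, key=lambda t: (t[1], t[0])):
            _w(fh, pid, cid, result.scl_calls[pid].scl_class)

    with open(outdir / "orfans.tsv", "w") as fh:
        _w(fh, "protein_id", "genome_id", "scl_class", "is_secretome", "pseudo_suspect")
        for v in sorted(result.verdicts, key=lambda v: v.protein_id):
            if v.category != "ORFAN":
                continue
            call = result.scl_calls[v.protein_id]
            _w(
                fh, v.protein_id, result.genome_of.get(v.protein_id, ""),
                call.scl_class, int(call.is_secretome), int(v.pseudo_suspect),
            )

    with open(outdir / "distant_homologs.tsv", "w") as fh:
        _w(
            fh, "protein_id", "genome_id", "scl_class", "is_secretome",
            "best_ref_subject", "evalue", "bitscore",
        )
        for v in sorted(result.verdicts, key=lambda v: v.protein_id):
            if v.category != "DISTANT_HOMOLOG_NONLAB":
                continue
            call = result.scl_calls[v.protein_id]
            h = v.best_reference_hit
            _w(
                fh, v.protein_id, result.genome_of.get(v.protein_id, ""),
                call.scl_class, int(call.is_secretome),
                h.subject_id, f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            )

    asms = sorted(result.assemblies, key=lambda a: a.assembly_id)
    with open(outdir / "pseudo_assemblies.fasta", "w") as fh:
        for a in asms:
            fh.write(f">{a.assembly_id} genome_id={a.genome_id} contig={a.contig_id}\n")
            fh.write(a.assembled_sequence + "\n")
    with open(outdir / "pseudo_assemblies.tsv", "w") as fh:
        _w(
            fh, "assembly_id", "genome_id", "contig_id", "fragments",
            "span_start", "span_end", "strand", "assigned_cluster", "scl_after",
        )
        for a in asms:
            _w(
                fh, a.assembly_id, a.genome_id, a.contig_id,
                ",".join(a.fragment_ids), a.span[0], a.span[1], a.strand,
                a.assigned_cluster or "-",
                a.scl_after.scl_class if a.scl_after else "-",
            )

    with open(outdir / "start_anomalies.tsv", "w") as fh:
        _w(fh, "protein_id", "cluster_id", "overhang", "suggested_starts")
        for pid, cid, over, sugg in sorted(result.start_anomalies):
            _w(fh, pid, cid, over, ",".join(str(s) for s in sugg) or "-")

    with open(outdir / "scl_report.tsv", "w") as fh:
        _w(fh, "protein_id", "scl_class", "is_secretome", "source", "filters")
        fired: dict[str, list[str]] = {}
        for pid, ev in result.screen_events:
            fired.setdefault(pid, []).append(ev)
        for pid in sorted(result.scl_calls):
            c = result.scl_calls[pid]
            _w(fh, pid, c.scl_class, int(c.is_secretome), c.source,
               ";".join(fired.get(pid, [])) or "-")

    genome_ids = sorted(g.genome_id for g in result.genomes)
    with open(outdir / "phyletic_patterns.tsv", "w") as fh:
        _w(fh, "cluster_id", "category", "n_present", *genome_ids)
        for p in sorted(result.patterns, key=lambda p: p.cluster_id):
            _w(
                fh, p.cluster_id, p.category, p.n_present,
                *[p.presence.get(g, 0) for g in genome_ids],
            )

    with open(outdir / "architectures.tsv", "w") as fh:
        _w(fh, "cluster_id", "protein_id", "architecture", "heterogeneous_flag")
        for prof in sorted(result.architectures, key=lambda a: a.cluster_id):
            for pid in sorted(prof.member_architectures):
                _w(fh, prof.cluster_id, pid, prof.member_architectures[pid] or "-",
                   int(prof.heterogeneous_flag))

    with open(outdir / "genome_summary.tsv", "w") as fh:
        _w(
            fh, "genome_id", "total_proteins", "secretome_size", "secretome_pct",
            "in_lacog", "distant_homologs", "orfans", "n_lacogs",
        )
        for s in sorted(result.summaries, key=lambda s: s.genome_id):
            _w(
                fh, s.genome_id, s.total_proteins, s.secretome_size,
                FLOAT_FMT.format(s.secretome_pct), s.in_lacog,
                s.distant_homologs, s.orfans, s.n_lacogs,
            )


def write_manifest(path: str | Path, config: PipelineConfig, seed: int,
                   input_checksums: dict[str, str], stages: list[str]) -> None:
    """Run manifest: config snapshot, input checksums, seed, tool version."""
    from . import __version__

    payload = {
        "tool": "lacogs",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": dict(sorted(input_checksums.items())),
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
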