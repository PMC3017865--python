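"""Synthetic proteome generator with planted ground truth.

Generates a panel of bacterial genomes in which every downstream
observation is planted and therefore checkable:

* ortholog families derived from a random ancestor by point substitution
  to a target within-family identity (no indels by default, so
  length-ratio criteria hold trivially inside families);
* secretome members carrying an unambiguous signal grammar for their
  planted location class (lipobox, Sec/Tat signal peptide, uncleaved
  N-anchor, C-anchor, LPxTG cell-wall anchor) — the grammars are
  co-designed with the rule cascade of :mod:`lacogs.scl` so the planted
  class is always recovered;
* non-classically secreted singletons that carry *no* sequence signal
  (that is what non-classical secretion means) and are therefore declared
  through the SCL table;
* frameshifted pseudogene pairs: one genome's family member is written
  back to nucleotides, split near the middle by a +1 frameshift, and
  re-annotated as two adjacent ORFs with coordinates on a contig;
* ORFans and distant-homolog singletons, the latter given fabricated hits
  against a mock non-LAB reference.

Hydrophobic stretches, lipoboxes and sortase motifs arising by chance in
non-signal regions are scrubbed, so location classes are unambiguous by
construction.  Everything is driven by one integer seed; a given
configuration is byte-reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .homology import Hit, HitTable, rank_hits
from .io_core import GenomeBundle, ProteinRecord, write_fasta
from .scl import heuristic_scl

# Robinson-Robinson style background amino-acid frequencies.
_BG_AA = "ACDEFGHIKLMNPQRSTVWY"
_BG_W = [7.8, 1.9, 5.4, 6.3, 3.9, 7.4, 2.2, 5.1, 5.7, 9.0,
         2.2, 4.5, 5.2, 4.3, 5.1, 7.1, 5.8, 6.4, 1.3, 3.2]
_HYDROPHILIC = "DENQSTGK"
_HYDRO_RUN = "LIVF"

_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "AGA"],
    "S": ["TCT", "TCC", "AGT"], "T": ["ACT", "ACC", "ACA"], "V": ["GTT", "GTC", "GTA"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Grammar classes the rule cascade can see; NONCLASSICAL_SECRETED is
# sequence-invisible and planted through the SCL table instead.
GRAMMAR_CLASSES = (
    "SEC_SECRETED",
    "LIPID_ANCHORED",
    "N_ANCHORED",
    "CELL_WALL_ANCHORED",
    "TAT_SECRETED",
    "C_ANCHORED",
)


@dataclass
class SyntheticConfig:
    n_genomes: int = 4
    proteins_per_genome: int = 500
    n_families: int = 100
    within_identity: float = 0.8
    secretome_fraction: float = 0.08
    n_pseudogene_pairs: int = 10
    n_species_specific_families: int = 4
    n_niche_specific_families: int = 6
    n_missing_one_families: int = 10
    n_secretome_orfans_per_genome: int = 2
    n_secretome_distant_per_genome: int = 1
    n_intracellular_distant_per_genome: int = 2
    ancestor_len_range: tuple[int, int] = (240, 400)
    orfan_len_range: tuple[int, int] = (60, 90)
    indel_mode: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.within_identity < 1.0:
            raise ValueError("within_identity must be in (0, 1)")
        if not 0.0 <= self.secretome_fraction <= 1.0:
            raise ValueError("secretome_fraction must be in [0, 1]")
        restricted = (
            self.n_species_specific_families
            + self.n_niche_specific_families
            + self.n_missing_one_families
        )
        if restricted > self.n_families:
            raise ValueError("restricted-presence families exceed n_families")
        n_sec_fam = self.n_secretome_families
        if n_sec_fam < 0:
            raise ValueError("secretome fraction too small for the planted singletons")
        if n_sec_fam > self.n_families - restricted:
            raise ValueError(
                "infeasible configuration: secretome fraction requires more "
                "all-present families than exist"
            )

    @classmethod
    def scaled(
        cls,
        n_genomes: int = 4,
        proteins_per_genome: int = 500,
        n_families: int = 100,
        within_identity: float = 0.8,
        seed: int = 42,
    ) -> "SyntheticConfig":
        """A feasible configuration for an arbitrary panel size.

        Shrinks the planted sub-family counts (species-/niche-specific,
        missing-one, pseudogene pairs, singleton classes) proportionally so
        small panels remain generable with the same structure.
        """
        f = n_families
        n_ss = min(4, f // 10)
        n_ns = min(6, f // 8)
        n_mo = min(10, f // 5)
        sec_orf, sec_dist, intra_dist = 2, 1, 2
        n_sec = round(0.08 * proteins_per_genome) - sec_orf - sec_dist
        while n_sec < 1 and (sec_orf or sec_dist):
            if sec_orf:
                sec_orf -= 1
            elif sec_dist:
                sec_dist -= 1
            n_sec = round(0.08 * proteins_per_genome) - sec_orf - sec_dist
        n_sec = max(0, min(n_sec, f - n_ss - n_ns - n_mo))
        return cls(
            n_genomes=n_genomes,
            proteins_per_genome=proteins_per_genome,
            n_families=n_families,
            within_identity=within_identity,
            secretome_fraction=(n_sec + sec_orf + sec_dist) / proteins_per_genome,
            n_pseudogene_pairs=min(10, n_sec),
            n_species_specific_families=n_ss,
            n_niche_specific_families=n_ns,
            n_missing_one_families=n_mo,
            n_secretome_orfans_per_genome=sec_orf,
            n_secretome_distant_per_genome=sec_dist,
            n_intracellular_distant_per_genome=intra_dist,
            seed=seed,
        )

    @property
    def n_secretome_families(self) -> int:
        per_genome_sec = round(self.secretome_fraction * self.proteins_per_genome)
        return (
            per_genome_sec
            - self.n_secretome_orfans_per_genome
            - self.n_secretome_distant_per_genome
        )


@dataclass
class PseudoPairTruth:
    fragment_ids: list[str]
    family_id: str
    genome_id: str
    contig_id: str
    full_sequence: str
    strand: str


@dataclass
class SyntheticTruth:
    """Planted ground truth covering every generated protein exactly once."""

    family_of: dict[str, str]           # protein -> family (family members only)
    family_members: dict[str, list[str]]
    scl_of: dict[str, str]              # every protein -> planted class
    secretome_families: set[str]
    pseudo_pairs: list[PseudoPairTruth]
    orfan_ids: set[str]                 # planted singletons without reference hits
    distant_ids: set[str]               # planted singletons with reference hits
    expected_phyletic: dict[str, str]   # family -> expected category
    expected_architecture: dict[str, str]  # protein -> expected arch string
    species_of: dict[str, str]
    niche_of: dict[str, list[str]]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genomes: list[GenomeBundle]
    truth: SyntheticTruth
    scl_table: dict[str, str]
    domain_map: dict[str, list[tuple[str, int, int, float]]]
    feature_map: dict[str, tuple[str, int, int, str]]
    reference_hits: HitTable
    surface_domains: set[str]

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for g in self.genomes for p in g.proteins]

    def contigs(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in self.genomes:
            if g.contigs:
                out.update(g.contigs)
        return out

    def fabricated_hit_table(self) -> HitTable:
        """Hit table fabricated directly from the planted families.

        Bit score is ``2 x identical residues`` — a monotone stand-in whose
        ordering is all the clustering rules consume.  Useful for
        aligner-free tests of the clustering stages.
        """
        hits: list[Hit] = []
        seq_of = {p.protein_id: p.sequence for p in self.all_proteins()}
        for fam, members in self.truth.family_members.items():
            real = [m for m in members if m in seq_of]
            for i, a in enumerate(real):
                for b in real[i + 1 :]:
                    sa, sb = seq_of[a], seq_of[b]
                    n = min(len(sa), len(sb))
                    ident = sum(1 for x, y in zip(sa, sb) if x == y)
                    bits = 2.0 * ident
                    ev = len(sa) * len(sb) * 2.0 ** (-bits)
                    for q, s, ql, sl in ((a, b, len(sa), len(sb)), (b, a, len(sb), len(sa))):
                        hits.append(
                            Hit(q, s, bits, ev, ident / n, n, (1, n), (1, n),
                                n / ql, n / sl, ql, sl)
                        )
        return rank_hits(hits, exclude_self=True)

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the pipeline's on-disk dialects + truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in self.genomes:
            write_fasta(g.proteins, outdir / f"{g.genome_id}.faa")
            if g.contigs:
                with open(outdir / f"{g.genome_id}.fna", "w") as fh:
                    for cid in sorted(g.contigs):
                        fh.write(f">{cid}\n{g.contigs[cid]}\n")
        with open(outdir / "genomes.tsv", "w") as fh:
            fh.write("genome_id\tspecies\tniche_tags\n")
            for g in self.genomes:
                fh.write(
                    f"{g.genome_id}\t{g.species_label}\t{','.join(sorted(g.niche_tags))}\n"
                )
        with open(outdir / "scl.tsv", "w") as fh:
            fh.write("protein_id\tscl_class\n")
            for pid in sorted(self.scl_table):
                fh.write(f"{pid}\t{self.scl_table[pid]}\n")
        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("protein_id\tdomain_accession\tstart\tend\tscore\n")
            for pid in sorted(self.domain_map):
                for acc, s, e, sc in self.domain_map[pid]:
                    fh.write(f"{pid}\t{acc}\t{s}\t{e}\t{sc:.1f}\n")
        with open(outdir / "features.tsv", "w") as fh:
            fh.write("protein_id\tcontig\tstart\tend\tstrand\n")
            for pid in sorted(self.feature_map):
                ctg, s, e, st = self.feature_map[pid]
                fh.write(f"{pid}\t{ctg}\t{s}\t{e}\t{st}\n")
        from .io_core import write_hit_table

        write_hit_table(self.reference_hits, outdir / "reference_hits.tsv")
        truth = {
            "family_of": self.truth.family_of,
            "family_members": self.truth.family_members,
            "scl_of": self.truth.scl_of,
            "secretome_families": sorted(self.truth.secretome_families),
            "orfan_ids": sorted(self.truth.orfan_ids),
            "distant_ids": sorted(self.truth.distant_ids),
            "expected_phyletic": self.truth.expected_phyletic,
            "pseudo_pairs": [
                {
                    "fragment_ids": p.fragment_ids,
                    "family_id": p.family_id,
                    "genome_id": p.genome_id,
                    "contig_id": p.contig_id,
                    "full_sequence": p.full_sequence,
                    "strand": p.strand,
                }
                for p in self.truth.pseudo_pairs
            ],
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence construction helpers


def _draw_body(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BG_AA, weights=_BG_W, k=n))


def _grammar_parts(scl_class: str, rng: random.Random) -> tuple[str, str]:
    """(prefix, suffix) realising one signal grammar.

    Hydrophobic cores are drawn per call so different families do not
    share identical signal sequences.
    """
    hydro = lambda n: "".join(rng.choice(_HYDRO_RUN) for _ in range(n))
    if scl_class == "SEC_SECRETED":
        return "MKK" + hydro(8) + "DDAQA", ""
    if scl_class == "TAT_SECRETED":
        return "MRR" + hydro(8) + "DDAQA", ""
    if scl_class == "LIPID_ANCHORED":
        box = rng.choice("LVI") + rng.choice("ASTVIG") + rng.choice("GAS") + "C"
        return "MK" + box, ""
    if scl_class == "N_ANCHORED":
        return "MKK" + hydro(12), ""
    if scl_class == "C_ANCHORED":
        return "M", "DD" + hydro(9) + "RK"
    if scl_class == "CELL_WALL_ANCHORED":
        wall = "".join(rng.choice("AILV") for _ in range(12))
        return "M", "LPKTG" + wall + "KRK"
    # intracellular / non-classical: plain sequence
    return "M", ""


def _sanitized_protein(
    scl_class: str,
    total_len: int,
    rng: random.Random,
    cfg: PipelineConfig,
    body: str | None = None,
    grammar: tuple[str, str] | None = None,
) -> tuple[str, str, str]:
    """Build (prefix, body, suffix) whose cascade class equals the target.

    ``grammar`` fixes the (prefix, suffix) pair so every member of a family
    shares the ancestor's signal; when absent a fresh grammar is drawn.
    The body is resampled locally until no accidental feature (hydrophobic
    stretch, lipobox, LPxTG, stray cleavage alanines for the N-anchor
    grammar) changes the classification.
    """
    target = scl_class if scl_class in GRAMMAR_CLASSES else "INTRACELLULAR"
    prefix, suffix = grammar if grammar is not None else _grammar_parts(scl_class, rng)
    body_len = max(20, total_len - len(prefix) - len(suffix))
    if body is None:
        body = _draw_body(rng, body_len)
    for _ in range(200):
        if scl_class == "N_ANCHORED":
            body = body[:15].replace("A", "S") + body[15:]
        seq = prefix + body + suffix
        probe = ProteinRecord("probe", "probe", seq)
        if heuristic_scl(probe, cfg).scl_class == target:
            return prefix, body, suffix
        body = _scrub_body(body, prefix, seq, rng, cfg)
    raise RuntimeError(f"could not realise grammar for {scl_class}")


def _scrub_body(body: str, prefix: str, seq: str, rng: random.Random,
                cfg: PipelineConfig) -> str:
    """Replace body residues implicated in accidental sequence features."""
    from .scl import _LIPOBOX_RE, _LPXTG_RE, hydrophobic_stretches

    chars = list(body)
    off = len(prefix)
    body_end = off + len(body)

    def redraw(lo: int, hi: int) -> None:
        for i in range(max(lo, off), min(hi, body_end)):
            chars[i - off] = rng.choice(_HYDROPHILIC)

    fixed = False
    for s, e in hydrophobic_stretches(seq, cfg.hydro_window, cfg.hydro_threshold):
        if e >= off and s < body_end:
            redraw(s, e + 1)
            fixed = True
    m = _LIPOBOX_RE.search(seq[: cfg.lipobox_region_len])
    if m and m.end() > off:
        redraw(m.start(), m.end())
        fixed = True
    for m in _LPXTG_RE.finditer(seq, max(0, len(seq) - cfg.tail_region_len)):
        if m.end() > off and m.start() < body_end:
            redraw(m.start(), m.end())
            fixed = True
    if not fixed:
        # last resort: resample a random window
        i = rng.randrange(len(chars))
        chars[i] = rng.choice(_HYDROPHILIC)
    return "".join(chars)


def _mutate_body(body: str, rate: float, rng: random.Random) -> str:
    out = []
    for c in body:
        if rng.random() < rate:
            alt = c
            while alt == c:
                alt = rng.choices(_BG_AA, weights=_BG_W, k=1)[0]
            out.append(alt)
        else:
            out.append(c)
    return "".join(out)


def _encode(aa: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[c]) for c in aa)


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# generation


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic panel (deterministic in ``config.seed``)."""
    cfg = config or SyntheticConfig()
    pcfg = PipelineConfig()
    rng = random.Random(cfg.seed)
    G = cfg.n_genomes
    gids = [f"G{i + 1:02d}" for i in range(G)]

    species_of: dict[str, str] = {}
    niche_of: dict[str, list[str]] = {}
    for i, gid in enumerate(gids):
        if G >= 2 and i < 2:
            species_of[gid] = "SpeciesA"
        else:
            species_of[gid] = f"Species{chr(ord('B') + i - 2)}" if i >= 2 else "SpeciesA"
        niche_of[gid] = ["GI-tract"] if (G >= 4 and i >= G - 2) else []

    # ----- family layout
    n_ss = cfg.n_species_specific_families if G >= 2 else 0
    n_ns = cfg.n_niche_specific_families if G >= 4 else 0
    n_mo = cfg.n_missing_one_families if G >= 2 else 0
    fam_ids = [f"FAM{i:03d}" for i in range(cfg.n_families)]
    presence: dict[str, list[str]] = {}
    expected_phyletic: dict[str, str] = {}
    n_full = cfg.n_families - n_ss - n_ns - n_mo
    for i, fam in enumerate(fam_ids):
        if i < n_full:
            presence[fam] = list(gids)
            expected_phyletic[fam] = "UBIQUITOUS"
        elif i < n_full + n_mo:
            missing = gids[(i - n_full) % G]
            presence[fam] = [g for g in gids if g != missing]
            expected_phyletic[fam] = "UBIQUITOUS"
        elif i < n_full + n_mo + n_ns:
            presence[fam] = gids[-2:]
            expected_phyletic[fam] = "NICHE_SPECIFIC(GI-tract)"
        else:
            presence[fam] = gids[:2]
            expected_phyletic[fam] = "SPECIES_SPECIFIC"

    sec_fams = fam_ids[: cfg.n_secretome_families]  # all-present by layout
    fam_class: dict[str, str] = {}
    for i, fam in enumerate(fam_ids):
        if fam in sec_fams:
            fam_class[fam] = GRAMMAR_CLASSES[i % len(GRAMMAR_CLASSES)]
        else:
            fam_class[fam] = "INTRACELLULAR"

    pseudo_fams = sec_fams[: cfg.n_pseudogene_pairs]
    pseudo_genome = {
        fam: gids[i % G] for i, fam in enumerate(pseudo_fams)
    }

    mut_rate = 1.0 - cfg.within_identity ** 0.5

    proteins: dict[str, list[ProteinRecord]] = {g: [] for g in gids}
    contigs: dict[str, dict[str, str]] = {g: {} for g in gids}
    family_of: dict[str, str] = {}
    family_members: dict[str, list[str]] = {f: [] for f in fam_ids}
    scl_of: dict[str, str] = {}
    scl_table: dict[str, str] = {}
    domain_map: dict[str, list[tuple[str, int, int, float]]] = {}
    feature_map: dict[str, tuple[str, int, int, str]] = {}
    pseudo_pairs: list[PseudoPairTruth] = []
    expected_arch: dict[str, str] = {}

    # LysM-style repeat-variation family: first cell-wall-anchored family.
    lysm_fam = next((f for f in sec_fams if fam_class[f] == "CELL_WALL_ANCHORED"), None)

    counter = {g: 0 for g in gids}

    def new_pid(g: str) -> str:
        counter[g] += 1
        return f"{g}_{counter[g]:04d}"

    _ancestors: dict[str, str] = {}
    for fidx, fam in enumerate(fam_ids):
        scl_class = fam_class[fam]
        total_len = rng.randrange(*cfg.ancestor_len_range)
        prefix, anc_body, suffix = _sanitized_protein(scl_class, total_len, rng, pcfg)
        _ancestors[fam] = prefix + anc_body + suffix
        cat_acc = f"CAT{fidx:03d}"
        grammar = (prefix, suffix)
        for midx, g in enumerate(presence[fam]):
            body = _mutate_body(anc_body, mut_rate, rng)
            if cfg.indel_mode and rng.random() < 0.3:
                cut = rng.randrange(10, max(11, len(body) - 10))
                body = body[:cut] + body[cut + rng.randrange(1, 4):]
            _p, body, _s = _sanitized_protein(
                scl_class, total_len, rng, pcfg, body=body, grammar=grammar
            )
            seq = prefix + body + suffix
            if fam in pseudo_fams and g == pseudo_genome[fam]:
                strand = "-" if fidx % 5 == 4 else "+"
                pid1, pid2 = new_pid(g), new_pid(g)
                frags, ctg_id, ctg_seq = _plant_frameshift(
                    seq, g, (pid1, pid2), len(pseudo_pairs), strand, rng
                )
                contigs[g][ctg_id] = ctg_seq
                for fr in frags:
                    proteins[g].append(fr)
                    family_of[fr.protein_id] = fam
                    family_members[fam].append(fr.protein_id)
                    call = heuristic_scl(fr, pcfg)
                    scl_of[fr.protein_id] = call.scl_class
                    scl_table[fr.protein_id] = call.scl_class
                    feature_map[fr.protein_id] = (
                        fr.contig_id, fr.start, fr.end, fr.strand
                    )
                # fragment ids in 5'->3' order of the coding strand (the
                # order an assembly concatenates them in)
                pseudo_pairs.append(
                    PseudoPairTruth([pid1, pid2], fam, g, ctg_id, seq, strand)
                )
                continue
            pid = new_pid(g)
            proteins[g].append(ProteinRecord(pid, g, seq))
            family_of[pid] = fam
            family_members[fam].append(pid)
            scl_of[pid] = scl_class
            scl_table[pid] = scl_class
            if scl_class != "INTRACELLULAR":
                n = len(seq)
                doms: list[tuple[str, int, int, float]] = []
                cat_start = max(1, n - len(suffix) - 70)
                cat_end = n - len(suffix) - 10
                if fam == lysm_fam:
                    copies = (midx % 3) + 1
                    pos = len(prefix) + 5
                    for _c in range(copies):
                        doms.append(("LysM", pos, pos + 39, 60.0))
                        pos += 45
                    doms.append((cat_acc, cat_start, cat_end, 80.0))
                    expected_arch[pid] = (
                        (f"LysM×{copies}" if copies > 1 else "LysM") + f"+{cat_acc}"
                    )
                else:
                    doms.append((cat_acc, cat_start, cat_end, 80.0))
                    expected_arch[pid] = cat_acc
                domain_map[pid] = doms

    # ----- planted singletons: secretome orfans/distants, intracellular distants
    # Singletons must stay singletons: enforce separation from every family
    # by redrawing any draw with a non-trivial local similarity to a family
    # ancestor (raw Smith-Waterman score >= 45, comfortably below the
    # weakest similarity the E < 1 intake gate can admit).
    from .homology import _make_aligner

    aligner = _make_aligner()
    ancestor_seqs = list(_ancestors.values())

    def _separated_body(total_len: int) -> str:
        for _ in range(50):
            _p, body, _s = _sanitized_protein("INTRACELLULAR", total_len, rng, pcfg)
            if all(aligner.score("M" + body, anc) < 45.0 for anc in ancestor_seqs):
                return body
        raise RuntimeError("could not draw a family-separated singleton")

    ref_hits: list[Hit] = []
    orfan_ids: set[str] = set()
    distant_ids: set[str] = set()

    def add_singleton(g: str, scl_class: str, in_reference: bool, tag: str) -> None:
        total_len = rng.randrange(*cfg.orfan_len_range)
        body = _separated_body(total_len)
        pid = new_pid(g)
        rec = ProteinRecord(pid, g, "M" + body, description=tag)
        proteins[g].append(rec)
        scl_of[pid] = scl_class
        scl_table[pid] = scl_class
        if in_reference:
            distant_ids.add(pid)
            qlen = rec.length
            slen = max(30, int(round(qlen * 0.9)))
            n = min(qlen, slen)
            ref_hits.append(
                Hit(pid, f"NONLAB_{len(ref_hits) + 1:04d}", 90.0, 1e-6, 0.45,
                    n, (1, n), (1, n), n / qlen, n / slen, qlen, slen)
            )
        else:
            orfan_ids.add(pid)

    for g in gids:
        for _ in range(cfg.n_secretome_orfans_per_genome):
            add_singleton(g, "NONCLASSICAL_SECRETED", False, "secretome orfan")
        for _ in range(cfg.n_secretome_distant_per_genome):
            add_singleton(g, "NONCLASSICAL_SECRETED", True, "secretome distant homolog")
        for _ in range(cfg.n_intracellular_distant_per_genome):
            add_singleton(g, "INTRACELLULAR", True, "distant homolog")

    # ----- background filler up to the per-genome size
    for g in gids:
        while len(proteins[g]) < cfg.proteins_per_genome:
            total_len = rng.randrange(*cfg.orfan_len_range)
            body = _separated_body(total_len)
            pid = new_pid(g)
            proteins[g].append(ProteinRecord(pid, g, "M" + body, description="orfan"))
            scl_of[pid] = "INTRACELLULAR"
            scl_table[pid] = "INTRACELLULAR"
            orfan_ids.add(pid)

    genomes = [
        GenomeBundle(
            genome_id=g,
            species_label=species_of[g],
            niche_tags=set(niche_of[g]),
            proteins=proteins[g],
            contigs=contigs[g] or None,
        )
        for g in gids
    ]
    truth = SyntheticTruth(
        family_of=family_of,
        family_members=family_members,
        scl_of=scl_of,
        secretome_families=set(sec_fams),
        pseudo_pairs=pseudo_pairs,
        orfan_ids=orfan_ids,
        distant_ids=distant_ids,
        expected_phyletic=expected_phyletic,
        expected_architecture=expected_arch,
        species_of=species_of,
        niche_of=niche_of,
    )
    return SyntheticDataset(
        config=cfg,
        genomes=genomes,
        truth=truth,
        scl_table=scl_table,
        domain_map=domain_map,
        feature_map=feature_map,
        reference_hits=rank_hits(ref_hits, exclude_self=True),
        surface_domains={"LysM"} | {f"CAT{i:03d}" for i in range(cfg.n_families)},
    )


def _plant_frameshift(
    full_seq: str,
    genome_id: str,
    pids: tuple[str, str],
    pair_index: int,
    strand: str,
    rng: random.Random,
) -> tuple[list[ProteinRecord], str, str]:
    """Split a protein's gene by a +1 frameshift into two annotated ORFs.

    Layout on the coding strand: pad, codons of the N-terminal half, a
    stop codon, one inserted base (the frameshift), codons of the
    C-terminal half, a stop codon, pad.  On the minus strand the whole
    contig is reverse-complemented and the coordinates remapped.
    """
    h = len(full_seq) // 2
    aa1, aa2 = full_seq[:h], full_seq[h:]
    nt1, nt2 = _encode(aa1, rng), _encode(aa2, rng)
    pad1 = "".join(rng.choice("ACGT") for _ in range(60))
    pad2 = "".join(rng.choice("ACGT") for _ in range(60))
    contig = pad1 + nt1 + "TAA" + "C" + nt2 + "TAA" + pad2
    s1, e1 = 61, 60 + len(nt1)
    s2 = e1 + 5  # stop codon (3) + inserted base (1), then the next ORF
    e2 = s2 + len(nt2) - 1
    ctg_id = f"{genome_id}_ctg{pair_index + 1:02d}"
    if strand == "-":
        contig = _revcomp(contig)
        L = len(contig)
        s1, e1 = L - e1 + 1, L - s1 + 1
        s2, e2 = L - e2 + 1, L - s2 + 1
    frag1 = ProteinRecord(pids[0], genome_id, aa1, contig_id=ctg_id,
                          start=s1, end=e1, strand=strand,
                          description="pseudogene fragment")
    frag2 = ProteinRecord(pids[1], genome_id, aa2, contig_id=ctg_id,
                          start=s2, end=e2, strand=strand,
                          description="pseudogene fragment")
    # genomic order within the file follows coordinates
    frags = sorted([frag1, frag2], key=lambda p: p.start)
    return frags, ctg_id, contig
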