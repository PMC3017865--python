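# Methods

`lacogs` reconstructs a bacterial secretome family database from per-genome
protein sets: it clusters proteomes into ortholog families (LaCOGs),
screens every protein's subcellular location (SCL), extracts the families
that are predominantly extracellular or surface-associated, reconstructs
frameshifted pseudogenes, and classifies families by their distribution
across the genome panel.  This note records the model, the parameter
choices, and the places where the design was genuinely open.

## Similarity search

The built-in engine computes **exact Smith–Waterman local alignments**
under BLOSUM62 with affine gaps (open 11, extend 1).  Raw scores are
converted to bits with the Karlin–Altschul transformation using the
standard gapped parameters for this scoring system (λ = 0.267, K = 0.041):
`bits = (λ·S − ln K)/ln 2`.

The expectation value is `E = m · D · 2^−bits`, where `m` is the query
length and `D` a **fixed effective database size**
(`effective_db_residues`, default 1.5 × 10⁷ residues — the scale of a
~26-genome LAB panel).  Two properties motivated this form:

* *Batch independence.*  With a constant `D`, a hit's E-value never
  depends on what else happens to be in the run, so incremental updates
  and subsets reproduce identical hit attributes.
* *Gate stringency.*  The intake gate is deliberately permissive
  (`E < 1`, low-complexity filtering off).  An E-value computed on the
  pair scale (`m · n`) would let essentially every chance similarity of a
  short protein through that gate; because family members are mutually
  similar, a chance match to one member implies equal-score matches to
  all of them, and the top-3 extension rule (below) would absorb
  unrelated singletons.  A database-scale `D` gives `E < 1` the meaning
  it has in a real database search.

Hit tables supplied from an external search keep the E-values of the
file; they must carry `qlen`/`slen` as columns 13–14, since the
overlap and length-ratio rules are not computable from the 12 standard
columns.

All-vs-all runs prescreen candidate pairs by shared 5-mers (≥ 1 shared
k-mer, configurable, 0 = align every pair).  Every candidate is then
aligned exactly; the prescreen only decides *which* pairs are aligned.
A pair without a single shared 5-mer cannot reach the scores any
downstream rule consumes at these sequence lengths, so the prescreen is a
compute filter, not a scoring heuristic.

The junction marker `x` of concatenated pseudoproteins is mapped to a
wildcard scoring 0 against every residue, so junctions neither reward nor
penalise an alignment.

## Clustering

1. **Seed extension ("uniform top 3").**  A query joins an existing
   cluster C iff its top k ranked hits all lie in C, with k = 3, or k = 2
   when |C| = 2.  Ranking is (bitscore desc, E-value asc, subject id asc);
   the tie rule makes "best hit" total.  Hits to unclustered proteins
   occupy ranks and veto the assignment — the conservative reading of
   "all of the top 3"; `unclustered_hits_veto = False` skips them
   instead.  Assignments in one pass are decided against a frozen
   snapshot and applied afterwards, so the result is independent of query
   order (no cascade).  A consequence worth knowing: two unseeded
   siblings of a seeded family can veto each other and split into a new
   cluster; the relaxed veto mode completes the family instead.
2. **BBH cores.**  Cross-genome bidirectional best hits, gated at bit
   score ≥ 50 and overlap ≥ 50%.  The overlap denominator is the longer
   sequence (configurable to the shorter).  The default `clique` mode
   grows maximal cliques greedily from the highest-total-bitscore pair —
   the stringent reading in which every member pair is mutually best;
   `component` mode takes connected components (every member is the BBH
   of at least one other member).
3. **New clusters.**  Cores get fresh ids whose numeric part starts with
   "9" (LaCOG90001, …), numbered in order of their smallest member id;
   the remaining proteins get a second uniform top-3 pass against all
   clusters.  Seed-cluster ids are never renamed, which is what makes
   incremental updates id-stable.
4. **Quality-control sweep.**  Iteratively, an unclustered protein joins
   the cluster of its best surviving hit *whose subject is clustered*
   (E ≤ 1e-3 and `min(qlen,slen)/max(qlen,slen) ≥ 0.6`; the alternative
   `query_coverage` mode uses aligned query coverage ≥ 0.6 instead).
   Newly assigned proteins are valid targets in the next round; clusters
   only grow and the sweep terminates in at most one round per protein.

## Subcellular-location screen

A deterministic rule cascade stands in for a dedicated SCL predictor so
the pipeline runs with zero external tools; a per-protein SCL table
always overrides it.  Both share one nine-class vocabulary; the secretome
is {lipid-anchored, N-anchored, C-anchored, Sec-secreted, Tat-secreted,
non-classically secreted, cell-wall-anchored}; multi-TM (integral
membrane) and intracellular proteins are excluded by definition.

Cascade order and signals: (i) lipobox `[LVI][ASTVIG][GAS]C` within the
first 35 residues; (ii) an N-terminal hydrophobic stretch (Kyte–Doolittle
window of 7, mean > 1.5, merged windows trimmed to their hydrophobic
core) starting within the first 45 residues with an A-x-A
signal-peptidase motif near its end → Sec (Tat when a twin-arginine RR
precedes the core); (iii) the same stretch without a cleavage motif →
N-anchored; (iv) LPxTG within the last 50 residues followed by a TM
stretch and a charged tail → cell-wall-anchored; (v) a single TM stretch
in the last 50 residues → C-anchored; (vi) ≥ 2 stretches → multi-TM;
(vii) otherwise intracellular.  Trimming the merged hydropathy windows to
their hydrophobic core matters: the flanking charged residues bordering a
helix must stay *outside* the span for the topology rule below to see
them.  Non-classical secretion is sequence-invisible (that is what
"non-classical" means), so the cascade never emits it; it can only come
from the table.

Two curation filters follow:

* **Outside-in topology.**  An N-anchored call with zero K/R before the
  helix and ≥ 1 K/R within 10 residues after it has its C-terminus inside
  the cell and is reclassified intracellular (positive-inside rule).
* **Small Sec-only proteins.**  Predicted Sec substrates shorter than 80
  residues with no other positive feature (no lipobox, LPxTG, or extra
  TM) are removed from the secretome — the mature part is too small to be
  an extracellular domain.  The bound is strict ("smaller than 80"):
  79 drops, 80 stays.  Junction `x` characters do not count toward the
  length.

## Pseudogene reconstruction

A protein is a **fragment candidate** when it is shorter than 0.6 × the
median length of its family's other members (strict less-than) *and* its
best family hit covers < 60% of the subject.  The 0.6/0.6 pair
operationalises "represents only a fragment of the protein"; both are
configurable.  The family is the protein's own cluster, or the cluster of
its best clustered hit for unclustered proteins.

Adjacent candidates (same contig and strand, genomic gap ≤ 300 nt,
configurable) are translated from their annotated gene regions in the
annotated frame — no start codon required, truncated at the first stop —
and concatenated 5'→3' of the coding strand with a literal `x` at each
junction (the number of `x` characters is fragments − 1 by construction).
Fragments overlapping by more than one codon are an ambiguous annotation
and a hard error.  The assembled protein is searched against the
clustered proteins and offered to clusters by the same uniform top-k
rule; its SCL is re-predicted from the assembled sequence.  Assemblies
replace their fragments everywhere downstream: cluster membership, SCL
accounting, genome summaries, ORFan classification.  Candidates with no
adjacent partner are reported as flagged-but-unassembled.

The pseudogene stage runs **before** the QC sweep.  Half-length fragments
sitting inside clusters would otherwise act as low bars for the
length-ratio criterion — a short unrelated protein compared against a
fragment can show a ratio ≥ 0.6 that it could never show against a
full-length member.  Replacing fragments with full-length assemblies
first keeps the criterion meaningful.

A start-codon audit flags cluster members whose alignment to the family's
longest member leaves an N-terminal overhang > 20 residues, and suggests
in-frame ATG/GTG/TTG positions when nucleotide context is available.  It
is a report only; sequences are never modified.

## Secretome extraction and summaries

A cluster is a secretome cluster when ≥ half of its members (ties
included: fraction ≥ 0.5) carry a secretome SCL.  Only the secretome
members of an emitted cluster are exported; clusters with any
non-secretome member are flagged mixed.  Secretome members of
below-majority clusters go to a side table instead of being dropped
silently.  Per-genome summaries report the trichotomy — every secretome
protein is in a cluster, a distant homolog, or an ORFan — and the counts
reconcile by construction.

Unclustered proteins with ≥ 1 surviving hit (same gates as the QC sweep)
in a supplied reference (non-LAB) hit table are distant homologs; the
rest are ORFans.  ORFans without a secretome location but carrying a
domain typical of extracellular proteins are flagged as pseudogene
suspects, not reclassified.

## Comparative analysis

Phyletic categories, in strict precedence: UBIQUITOUS (missing in ≤ 1
genome by default), NICHE_SPECIFIC(tag) (all present genomes share one
niche tag, ≥ 2 genomes — the ≥ 2 floor keeps single strains from
swallowing the category), SPECIES_SPECIFIC (one species, ≥ 2 strains),
STRAIN_SPECIFIC (one genome), VARIABLE.  Niche tags are inputs, not
hard-coded lists.  Domain architectures are rendered N→C with consecutive
repeats collapsed (`LysM×2+CAT007`); overlapping hits are resolved by
higher score, then earlier start; clusters with ≥ 2 distinct member
strings are flagged heterogeneous and a suggested split is reported but
never applied to membership.

## The synthetic panel

The generator plants every structure the pipeline is supposed to find, so
all tests run against known truth with no downloads.

* **Families.**  100 families (default) with one member per genome;
  ancestors are 240–400 residues drawn from background amino-acid
  frequencies; orthologs derive by point substitution at rate
  `1 − √identity` per site so *pairwise* member identity matches the 0.8
  target.  No indels by default (length-ratio criteria then hold
  trivially within families); an indel mode exists for stress tests.
  Presence layouts plant ubiquitous, missing-in-one, niche-confined and
  species-confined families.
* **Secretome grammars.**  Planted secretome families carry an
  unambiguous signal for their class (Sec/Tat signal peptide with a
  per-family random hydrophobic core, lipobox, uncleaved N-anchor,
  C-anchor, LPxTG + wall segment).  Grammar and cascade are co-designed:
  accidental features elsewhere in a sequence (chance hydrophobic
  stretches, lipoboxes, LPxTG, stray cleavage alanines) are scrubbed by
  local resampling, so every grammar-planted protein classifies to its
  planted class — a property the suite asserts exhaustively.  Hydrophobic
  cores are drawn per family so families do not share identical signals.
  Non-classically secreted singletons carry no signal and are declared
  through the SCL table, mirroring how such proteins are known in
  practice.
* **Singleton separation.**  ORFans and distant-homolog singletons
  (60–90 residues, matching the observation that unclustered hypothetical
  ORFs are typically below 100 aa) are redrawn until their best local
  alignment against every family ancestor stays below raw score 45 —
  comfortably below what the E < 1 intake gate can admit — so planted
  singletons cannot be absorbed by chance.  Distant homologs get
  fabricated reference hits (E = 1e-6, length ratio 0.9); ORFans get
  none.
* **Pseudogenes.**  For 10 families (default), one genome's member is
  back-translated codon-by-codon, split near the middle by a +1
  frameshift, and re-annotated as two adjacent ORFs (stop codon + 1
  inserted base between them, gap 4 nt) with coordinates on a generated
  contig; one pair is planted on the minus strand.  Concatenating the
  annotated translations reproduces the full protein exactly, so the
  ≥ 95% junction-excluded identity check has headroom for real-data
  noise while the synthetic case is exact.
* **Default scale.**  4 genomes × 500 proteins: 37 secretome families
  + 2 secretome ORFans + 1 secretome distant homolog per genome = 8% of
  each proteome, inside the 6–10% band the per-genome summaries are
  expected to show.

What the generator does **not** emulate: realistic phylogeny, codon bias,
paralog expansions, genome rearrangement, domain shuffling, or real
signal-peptide sequence diversity.  Passing the recovery tests therefore
shows the *rules* are implemented correctly and are mutually consistent,
not that the thresholds would achieve the same precision on real
proteomes.

## Numerical choices and degenerate inputs

* Ranking ties break by subject id; clique growth breaks ties by total
  bitscore then id; new-cluster numbering follows smallest member id —
  every ordering is total, which is what makes two runs byte-identical.
* Queries with fewer ranked hits than k are never assigned (there is no
  "top 3" to be uniform).
* Cluster tables with singleton seed entries are dissolved back into the
  unclustered pool and re-clustered from scratch.
* Clusters reduced below 2 members by fragment removal are dissolved.
* Empty inputs produce header-only tables; duplicate protein ids, unknown
  SCL labels, malformed hit rows and 12-column hit files are hard errors
  with the offending id or line number.

## Problem sizes

The suite and the acceptance script run the full pipeline on the default
panel (2000 proteins, built-in aligner, ~20 s on one core; generation
with the separation screen ~90 s), oracle batteries of 100 random
instances each, exhaustive enumerations (2^n secretome labelings for
n ≤ 10, all presence patterns for ≤ 6 genomes), and a byte-determinism
rerun on a reduced panel (3 × 120 proteins).

## Known limitations

* The heuristic SCL cascade is a rule-of-thumb classifier; on real
  proteomes a dedicated predictor should be supplied via the SCL table.
* Only the frameshift/adjacency pathway of pseudogene repair is
  automated; N-/C-terminal truncations without a second annotated ORF
  are flagged at best (start-anomaly report), never concatenated.
* In-paralog expansion (Inparanoid-style) is not implemented; within-
  genome paralogs cluster only through the top-k extension, so a family
  present in a single genome is recoverable only via seed clusters.
* Stable new-cluster numbering across successive incremental updates is
  out of scope; numbering restarts at ⟨prefix⟩0001 per run (seed ids are
  stable, new ids are not).
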