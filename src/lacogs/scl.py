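"""Subcellular-location (SCL) screening.

Assigns each protein one of nine location classes and applies the two
false-positive filters used when curating predicted secretomes:

* the *outside-in* topology rule — an N-terminally anchored protein whose
  positively charged residues sit exclusively downstream of the
  transmembrane helix has its C-terminus inside the cell and is therefore
  reclassified as intracellular;
* the *small Sec-only* rule — proteins shorter than 80 residues whose only
  export feature is a Sec-type signal peptide are removed from the
  predicted secretome, because the mature part is too small to form an
  extracellular domain.

The built-in classifier is a deterministic rule cascade over sequence
features (lipobox, Kyte-Doolittle hydrophobic stretches, signal-peptidase
cleavage motif, LPxTG sortase motif).  It exists so the pipeline runs with
no external predictor; when a per-protein SCL table is supplied it always
overrides the heuristic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from .config import PipelineConfig

if TYPE_CHECKING:  # pragma: no cover
    from .io_core import ProteinRecord

# Controlled vocabulary. The first seven classes constitute the secretome
# (surface-associated or released); MULTI_TM marks integral membrane
# proteins, which are excluded from the secretome by definition.
SECRETOME_CLASSES = frozenset(
    {
        "LIPID_ANCHORED",
        "N_ANCHORED",
        "C_ANCHORED",
        "SEC_SECRETED",
        "TAT_SECRETED",
        "NONCLASSICAL_SECRETED",
        "CELL_WALL_ANCHORED",
    }
)
SCL_CLASSES = frozenset(SECRETOME_CLASSES | {"MULTI_TM", "INTRACELLULAR"})

# Kyte-Doolittle hydropathy. 'X' (unknown residue) and the literal 'x'
# junction marker of concatenated pseudoproteins are neutral (0.0) so a
# junction inside a hydrophobic stretch does not break the stretch.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_LIPOBOX_RE = re.compile(r"[LVI][ASTVIG][GAS]C")
_LPXTG_RE = re.compile(r"LP.TG")


@dataclass
class SCLCall:
    """Predicted (or supplied) subcellular location for one protein."""

    protein_id: str
    scl_class: str
    source: str = "heuristic"  # "heuristic" | "table"
    tm_span: Optional[tuple[int, int]] = None  # 1-based inclusive residue span

    def __post_init__(self) -> None:
        if self.scl_class not in SCL_CLASSES:
            raise ValueError(
                f"unknown SCL class {self.scl_class!r}; "
                f"valid: {sorted(SCL_CLASSES)}"
            )

    @property
    def is_secretome(self) -> bool:
        return self.scl_class in SECRETOME_CLASSES


def hydrophobic_stretches(
    seq: str, window: int = 7, threshold: float = 1.5
) -> list[tuple[int, int]]:
    """Maximal hydrophobic stretches as 0-based inclusive spans.

    A position belongs to a stretch when it is covered by a length-``window``
    window whose mean Kyte-Doolittle hydropathy exceeds ``threshold``;
    overlapping and touching windows are merged, and each merged span is
    trimmed to its hydrophobic core (flanking residues with non-positive
    hydropathy that a passing window happened to cover are not part of the
    membrane-spanning segment — the charged residues bordering a helix must
    stay outside the span for topology rules to see them).
    """
    n = len(seq)
    if n < window:
        return []
    vals = [KYTE_DOOLITTLE.get(c.upper(), 0.0) for c in seq]
    acc = 0.0
    spans: list[tuple[int, int]] = []
    for i in range(n - window + 1):
        if i == 0:
            acc = sum(vals[:window])
        else:
            acc += vals[i + window - 1] - vals[i - 1]
        if acc / window > threshold:
            s, e = i, i + window - 1
            if spans and s <= spans[-1][1] + 1:
                spans[-1] = (spans[-1][0], e)
            else:
                spans.append((s, e))
    trimmed: list[tuple[int, int]] = []
    for s, e in spans:
        while s < e and vals[s] <= 0.0:
            s += 1
        while e > s and vals[e] <= 0.0:
            e -= 1
        trimmed.append((s, e))
    return trimmed


def _find_cleavage(seq: str, stretch_end: int) -> Optional[int]:
    """A-x-A signal-peptidase motif near the end of the hydrophobic core.

    Searched with the first alanine at 0-based positions
    ``stretch_end - 3 .. stretch_end + 8``; the window reaches slightly into
    the stretch because the -3/-1 alanines of a cleavage site are themselves
    mildly hydrophobic and often absorbed into it.
    """
    for i in range(max(0, stretch_end - 3), stretch_end + 9):
        if i + 2 < len(seq) and seq[i] == "A" and seq[i + 2] == "A":
            return i
    return None


def heuristic_scl(protein: "ProteinRecord", config: PipelineConfig | None = None) -> SCLCall:
    """Rule-cascade subcellular location prediction.

    Cascade order: lipobox -> cleavable N-terminal signal (Sec/Tat) ->
    uncleaved N-terminal anchor -> LPxTG cell-wall anchor -> C-terminal
    anchor -> multi-TM -> intracellular.  Deterministic in the sequence.
    """
    cfg = config or PipelineConfig()
    seq = protein.sequence.upper()
    if not seq:
        raise ValueError(f"empty sequence for {protein.protein_id}")
    n = len(seq)
    stretches = hydrophobic_stretches(seq, cfg.hydro_window, cfg.hydro_threshold)

    # (i) lipoprotein: lipobox with the anchor cysteine in the N-terminal region
    if _LIPOBOX_RE.search(seq[: cfg.lipobox_region_len]):
        return SCLCall(protein.protein_id, "LIPID_ANCHORED")

    # (ii)/(iii) N-terminal hydrophobic core
    nterm = next((sp for sp in stretches if sp[0] < cfg.signal_region_len), None)
    if nterm is not None:
        s, e = nterm
        cleav = _find_cleavage(seq, e)
        further = [sp for sp in stretches if sp[0] > e]
        if cleav is not None and not further:
            # the twin-arginine pair sits right before the hydrophobic core
            # and its first window can swallow it; look two residues in
            if "RR" in seq[: s + 2]:
                return SCLCall(protein.protein_id, "TAT_SECRETED", tm_span=(s + 1, e + 1))
            return SCLCall(protein.protein_id, "SEC_SECRETED", tm_span=(s + 1, e + 1))
        if cleav is None and not further:
            return SCLCall(protein.protein_id, "N_ANCHORED", tm_span=(s + 1, e + 1))
        # N-terminal TM plus additional TMs: fall through to (iv)/(vi)

    # (iv) sortase substrate: LPxTG followed by a TM stretch and a charged tail
    tail_start = max(0, n - cfg.tail_region_len)
    m = _LPXTG_RE.search(seq, tail_start)
    if m:
        # the membrane-spanning stretch follows the motif; its first window
        # may begin inside the motif's tail, so require it to extend past it
        after = [sp for sp in stretches if sp[1] >= m.end()]
        if after:
            s, e = after[0]
            if any(c in "KR" for c in seq[e + 1 :]):
                return SCLCall(protein.protein_id, "CELL_WALL_ANCHORED", tm_span=(s + 1, e + 1))

    # (v) single C-terminal TM anchor
    if len(stretches) == 1 and stretches[0][0] >= tail_start:
        s, e = stretches[0]
        return SCLCall(protein.protein_id, "C_ANCHORED", tm_span=(s + 1, e + 1))

    # (vi) integral membrane protein
    if len(stretches) >= 2:
        return SCLCall(protein.protein_id, "MULTI_TM")

    # (vii) default
    return SCLCall(protein.protein_id, "INTRACELLULAR")


def detect_outside_in(
    protein: "ProteinRecord", call: SCLCall, config: PipelineConfig | None = None
) -> bool:
    """Positive-inside diagnosis of a wrongly oriented N-terminal anchor.

    True when no K/R precedes the transmembrane helix but at least one K/R
    lies immediately downstream of it (within ``downstream_charge_window``
    residues): the C-terminus is then cytoplasmic and the protein is not
    part of the secretome.
    """
    cfg = config or PipelineConfig()
    if call.scl_class != "N_ANCHORED" or call.tm_span is None:
        raise ValueError(
            f"outside-in check applies to N_ANCHORED calls with a TM span, "
            f"got {call.scl_class} for {protein.protein_id}"
        )
    seq = protein.sequence.upper()
    s, e = call.tm_span  # 1-based inclusive
    before = seq[: s - 1]
    after = seq[e : e + cfg.downstream_charge_window]
    return not any(c in "KR" for c in before) and any(c in "KR" for c in after)


def small_sec_filter(
    protein: "ProteinRecord", call: SCLCall, config: PipelineConfig | None = None
) -> bool:
    """Return True to *keep* the protein in the predicted secretome.

    Dropped only when shorter than ``min_len_sec_only`` residues, classified
    SEC_SECRETED, and carrying no other positive feature (no lipobox, no
    LPxTG, no additional TM stretch).  Junction markers ('x') of assembled
    pseudoproteins do not count toward the length.
    """
    cfg = config or PipelineConfig()
    if call.scl_class != "SEC_SECRETED":
        return True
    seq = protein.sequence.upper()
    eff_len = len(protein.sequence) - protein.sequence.count("x")
    if eff_len >= cfg.min_len_sec_only:
        return True
    if _LIPOBOX_RE.search(seq[: cfg.lipobox_region_len]):
        return True
    if _LPXTG_RE.search(seq, max(0, len(seq) - cfg.tail_region_len)):
        return True
    if len(hydrophobic_stretches(seq, cfg.hydro_window, cfg.hydro_threshold)) > 1:
        return True
    return False


def screen_proteins(
    proteins: list["ProteinRecord"],
    scl_table: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, SCLCall], list[tuple[str, str]]]:
    """Assign an SCLCall to every protein and apply both curation filters.

    Returns the call map and a list of ``(protein_id, filter_name)`` events:
    ``outside_in`` marks reclassification to INTRACELLULAR, ``small_sec``
    marks removal from the secretome (class set to INTRACELLULAR so the
    protein no longer counts as extracellular downstream).
    """
    cfg = config or PipelineConfig()
    table = scl_table or {}
    calls: dict[str, SCLCall] = {}
    events: list[tuple[str, str]] = []
    for p in proteins:
        if p.protein_id in table:
            call = SCLCall(p.protein_id, table[p.protein_id], source="table")
        else:
            call = heuristic_scl(p, cfg)
        if call.scl_class == "N_ANCHORED" and call.tm_span is not None:
            if detect_outside_in(p, call, cfg):
                call = SCLCall(p.protein_id, "INTRACELLULAR", source=call.source)
                events.append((p.protein_id, "outside_in"))
        if call.is_secretome and not small_sec_filter(p, call, cfg):
            call = SCLCall(p.protein_id, "INTRACELLULAR", source=call.source)
            events.append((p.protein_id, "small_sec"))
        calls[p.protein_id] = call
    return calls, events
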