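"""Catalytic-triad assembly and classification for LPT/FITM proteins.

The PAP2-superfamily active site is built from two conserved blocks: C2
carries the first histidine (H-1, the H of "SGH") and C3 carries the second
histidine (H-2) and the third triad residue precisely spaced four later
(D-3 in classic LPT enzymes, typically E-3 in FITMs, occasionally Q or H).
Because the catalytic centre always faces the lumen of the secretory pathway,
topology-aware assembly requires C2 in a luminal loop and C3 in a later
luminal loop (C2 closes the long loop 3/4, C3 sits in the short loop 5/6).

The FITM-flavoured context of C3 is scored against the 14-position extended
consensus ``TAØYF-H-TØØ-E-KØØG`` (Ø hydrophobic = F/I/L/V), whose F at -1 and
K at +5 relative to H-2 are individually flagged as the most conserved
satellite positions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

from . import motifs
from .topology import LUMINAL, Topology, enumerate_loops

#: Extended C3 consensus, offsets -5..+8 around H-2. Sets are residue classes
#: (Ø = hydrophobic); single characters are literals.
C3_CONTEXT_CONSENSUS: list[frozenset[str] | str] = [
    "T", "A", motifs.HYDROPHOBIC, "Y", "F",
    "H",
    "T", motifs.HYDROPHOBIC, motifs.HYDROPHOBIC,
    "E",
    "K", motifs.HYDROPHOBIC, motifs.HYDROPHOBIC, "G",
]
C3_CONTEXT_OFFSETS = range(-5, 9)

CLASSIFICATIONS = (
    "LPT_canonical",
    "FITM_typical",
    "FITM_variant",
    "likely_inactive",
    "incomplete",
)


@dataclass
class TriadAssignment:
    """Positions and identities of H-1, H-2 and the third triad residue.

    ``h1_pos`` is the H of the C2 block, ``h2_pos`` the H of the C3 block and
    ``third_pos = h2_pos + 4`` its partner (D-3 in LPTs, E-3 in FITMs). The
    context score counts matches to the 14-position extended C3 consensus.
    """

    h1_pos: Optional[int] = None
    h1_res: Optional[str] = None
    h2_pos: Optional[int] = None
    h2_res: Optional[str] = None
    third_pos: Optional[int] = None
    third_res: Optional[str] = None
    c2_middle: Optional[str] = None
    context_score: int = 0
    f_minus1: bool = False
    k_plus5: bool = False
    classification: str = "incomplete"

    @property
    def complete(self) -> bool:
        return self.h1_pos is not None and self.h2_pos is not None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TriadAssignment":
        return cls(**d)


def score_c3_context(seq: str, h2_pos: int) -> tuple[int, bool, bool]:
    """Score the extended C3 consensus around H-2 (1-based position).

    Returns (score 0-14, F at -1 present, K at +5 present). Positions outside
    the sequence simply do not score.
    """
    score = 0
    for offset, want in zip(C3_CONTEXT_OFFSETS, C3_CONTEXT_CONSENSUS):
        pos = h2_pos + offset  # 1-based
        if not (1 <= pos <= len(seq)):
            continue
        res = seq[pos - 1]
        if (res in want) if isinstance(want, frozenset) else (res == want):
            score += 1
    f_minus1 = 1 <= h2_pos - 1 <= len(seq) and seq[h2_pos - 2] == "F"
    k_plus5 = 1 <= h2_pos + 5 <= len(seq) and seq[h2_pos + 4] == "K"
    return score, f_minus1, k_plus5


def classify_triad(t: TriadAssignment, lenient: bool = False) -> str:
    """Classify a triad assignment; total over all residue triples and missing states.

    Rules, in order: missing C2 or C3 -> incomplete; H-2 substituted ->
    likely_inactive (the pseudo-enzyme signature: LPR/PRG proteins carry N or
    S here); H-1 substituted -> likely_inactive (FITM_variant in lenient
    mode, acknowledging substrate-dependent effects seen in bacterial
    homologues); third residue D -> LPT_canonical, E -> FITM_typical,
    Q or H -> FITM_variant, anything else -> likely_inactive.
    """
    if not t.complete:
        return "incomplete"
    if t.h2_res != "H":
        return "likely_inactive"
    if t.h1_res != "H":
        return "FITM_variant" if lenient else "likely_inactive"
    if t.third_res == "D":
        return "LPT_canonical"
    if t.third_res == "E":
        return "FITM_typical"
    if t.third_res in ("Q", "H"):
        return "FITM_variant"
    return "likely_inactive"


def _loop_order(loops) -> dict[str, int]:
    return {lp.label: i for i, lp in enumerate(loops)}


def find_triad(
    seq: str,
    top: Optional[Topology] = None,
    middle_class: frozenset[str] = motifs.C2_MIDDLE_DEFAULT,
    third_class: frozenset[str] = motifs.C3_THIRD_DEFAULT,
    lenient: bool = False,
) -> TriadAssignment:
    """Assemble the best C2/C3 pair into a TriadAssignment.

    With a topology, C2 must lie in a luminal loop and C3 in a *later* luminal
    loop; without one, any C3 strictly downstream of a C2 qualifies. Among
    eligible pairs the one maximizing the extended-consensus context score
    wins (ties: smallest h2_pos, then smallest separation). Absence of either
    block yields classification "incomplete".
    """
    c2_hits = motifs.scan_c2(seq, middle_class)
    c3_hits = motifs.scan_c3(seq, third_class)

    if top is not None:
        loops = enumerate_loops(top)
        motifs.assign_hits_to_loops(c2_hits, loops)
        motifs.assign_hits_to_loops(c3_hits, loops)
        order = _loop_order(loops)
        c2_hits = [h for h in c2_hits if h.side == LUMINAL]
        c3_hits = [h for h in c3_hits if h.side == LUMINAL]
        pairs = [
            (c2, c3)
            for c2 in c2_hits
            for c3 in c3_hits
            if order[c3.loop_label] > order[c2.loop_label]
        ]
    else:
        pairs = [
            (c2, c3) for c2 in c2_hits for c3 in c3_hits if c3.span[0] > c2.span[1]
        ]

    if not pairs:
        return TriadAssignment(classification="incomplete")

    def key(pair):
        c2, c3 = pair
        h2 = c3.detail["h_pos"]
        h1 = c2.detail["h_pos"]
        score, _, _ = score_c3_context(seq, h2)
        return (-score, h2, h2 - h1)

    c2, c3 = min(pairs, key=key)
    h1_pos = c2.detail["h_pos"]
    h2_pos = c3.detail["h_pos"]
    third_pos = c3.detail["third_pos"]
    score, f_minus1, k_plus5 = score_c3_context(seq, h2_pos)
    t = TriadAssignment(
        h1_pos=h1_pos,
        h1_res=seq[h1_pos - 1],
        h2_pos=h2_pos,
        h2_res=seq[h2_pos - 1],
        third_pos=third_pos,
        third_res=seq[third_pos - 1],
        c2_middle=c2.detail["middle"],
        context_score=score,
        f_minus1=f_minus1,
        k_plus5=k_plus5,
    )
    t.classification = classify_triad(t, lenient=lenient)
    return t
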