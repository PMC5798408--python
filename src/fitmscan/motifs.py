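"""Short-linear-motif scanners for ER retention signals and LPT active-site blocks.

Motif classes covered:

* di-arginine ER retrieval signals ``RR``, ``RxR``, ``RxxR`` (cytoplasmic,
  COP-I recognised, can occur anywhere in cytoplasmic loops);
* C-terminal lysine-based retrieval signals ``KKxx``/``KxKxx`` and their
  proven variants ``RKxx``, ``RxKxx``, ``KxRxx``, ``HxHxx``, ``KxHxx``;
* the LPT/PAP2 active-site blocks C1 (``K-x6-RP``), C2 (``[ST]-[GSDTL]-H``,
  canonically "SGH") and C3 (``H-x-x-x-[DEQH]``, canonically "HxxxD/E");
* the FITM-specific luminal loop 1/2 motif ``[K]xNØØN`` where ``Ø`` is a
  hydrophobic residue from {F, I, L, V} and the bracketed K is preferred but
  not required;
* paired cysteines likely to form the disulphide bridge of luminal loop 3/4.

Spans are 1-based inclusive within the scanned string. Ambiguity codes
(X/B/Z/U) never satisfy a literal or residue-class position; only pure
wildcard ``x`` positions accept them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from .topology import Loop

#: The hydrophobic residue class written Ø in the motif notation.
HYDROPHOBIC = frozenset("FILV")
#: Default middle-residue class of C2 ([S/T]-x-H): G canonical, S/D/T/L known variants.
C2_MIDDLE_DEFAULT = frozenset("GSDTL")
#: Default third-triad residue class of C3 (HxxxD/E plus rarer Q/H).
C3_THIRD_DEFAULT = frozenset("DEQH")

DIARG_CLASSES = {1: "RR", 2: "RxR", 3: "RxxR"}


@dataclass
class MotifHit:
    """One matched motif instance.

    ``span`` is 1-based inclusive; ``matched`` equals the scanned string over
    that span. ``loop_label``/``side`` are filled by
    :func:`assign_hits_to_loops` when a topology is available; ``detail``
    carries class-specific annotations (e.g. the C2 middle residue).
    """

    motif_class: str
    span: tuple[int, int]
    matched: str
    loop_label: Optional[str] = None
    side: Optional[str] = None
    detail: dict = field(default_factory=dict)

    def shifted(self, offset: int) -> "MotifHit":
        """Return a copy with the span moved by ``offset`` residues."""
        detail = dict(self.detail)
        for key in ("h_pos", "third_pos"):
            if key in detail:
                detail[key] = detail[key] + offset
        return MotifHit(
            motif_class=self.motif_class,
            span=(self.span[0] + offset, self.span[1] + offset),
            matched=self.matched,
            loop_label=self.loop_label,
            side=self.side,
            detail=detail,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MotifHit":
        d = dict(d)
        d["span"] = tuple(d["span"])
        return cls(**d)


def scan_diarginine(seq: str, mode: str = "greedy") -> list[MotifHit]:
    """Find di-arginine motifs: two R residues at distance 1 (RR), 2 (RxR) or 3 (RxxR).

    ``greedy`` (default) scans left to right and pairs each unconsumed R with
    its nearest downstream R at distance <= 3, consuming both, so one arginine
    cluster yields a non-inflated count. ``all_pairs`` reports every
    qualifying R pair. The wildcard position(s) may be any residue, R included.
    """
    if mode not in ("greedy", "all_pairs"):
        raise ValueError(f"unknown di-arginine mode {mode!r}")
    positions = [i for i, c in enumerate(seq) if c == "R"]  # 0-based
    hits: list[MotifHit] = []

    def make_hit(i: int, j: int) -> MotifHit:
        return MotifHit(
            motif_class=DIARG_CLASSES[j - i],
            span=(i + 1, j + 1),
            matched=seq[i : j + 1],
        )

    if mode == "all_pairs":
        for a, i in enumerate(positions):
            for j in positions[a + 1 :]:
                if j - i > 3:
                    break
                hits.append(make_hit(i, j))
    else:
        consumed: set[int] = set()
        for a, i in enumerate(positions):
            if i in consumed:
                continue
            partner = next((j for j in positions[a + 1 :] if j - i <= 3), None)
            if partner is not None:
                consumed.add(i)
                consumed.add(partner)
                hits.append(make_hit(i, partner))
    return hits


#: C-terminal retrieval patterns in priority order: (class, {offset-from-end: residue}, span length).
CTERM_PATTERNS: list[tuple[str, dict[int, str], int]] = [
    ("KKxx", {-4: "K", -3: "K"}, 4),
    ("KxKxx", {-5: "K", -3: "K"}, 5),
    ("RKxx", {-4: "R", -3: "K"}, 4),
    ("RxKxx", {-5: "R", -3: "K"}, 5),
    ("KxRxx", {-5: "K", -3: "R"}, 5),
    ("HxHxx", {-5: "H", -3: "H"}, 5),
    ("KxHxx", {-5: "K", -3: "H"}, 5),
]


def scan_cterminal_retrieval(seq: str) -> Optional[MotifHit]:
    """Test the extreme C-terminus for a lysine-based retrieval signal.

    The final five residues are checked against the canonical di-lysine
    signals and their proven variants in priority order; the first match is
    returned. Only patterns that fit are tested on sequences shorter than 5.
    """
    n = len(seq)
    for name, constraints, span_len in CTERM_PATTERNS:
        if n < span_len:
            continue
        if all(seq[n + off] == res for off, res in constraints.items()):
            return MotifHit(
                motif_class=name,
                span=(n - span_len + 1, n),
                matched=seq[n - span_len :],
            )
    return None


def scan_c1(region: str) -> list[MotifHit]:
    """C1 block of the LPT active site: K, six wildcards, R, P (9 residues)."""
    hits = []
    for i in range(len(region) - 8):
        if region[i] == "K" and region[i + 7] == "R" and region[i + 8] == "P":
            hits.append(
                MotifHit(motif_class="C1", span=(i + 1, i + 9), matched=region[i : i + 9])
            )
    return hits


def scan_c2(region: str, middle_class: frozenset[str] = C2_MIDDLE_DEFAULT) -> list[MotifHit]:
    """C2 block ([S/T]-[middle]-H, canonically "SGH"); the H is candidate H-1."""
    hits = []
    for i in range(len(region) - 2):
        if region[i] in "ST" and region[i + 1] in middle_class and region[i + 2] == "H":
            hits.append(
                MotifHit(
                    motif_class="C2",
                    span=(i + 1, i + 3),
                    matched=region[i : i + 3],
                    detail={"first": region[i], "middle": region[i + 1], "h_pos": i + 3},
                )
            )
    return hits


def scan_c3(region: str, third_class: frozenset[str] = C3_THIRD_DEFAULT) -> list[MotifHit]:
    """C3 block (H-x-x-x-[D/E/Q/H]); the H is candidate H-2, last residue the third triad member."""
    hits = []
    for i in range(len(region) - 4):
        if region[i] == "H" and region[i + 4] in third_class:
            hits.append(
                MotifHit(
                    motif_class="C3",
                    span=(i + 1, i + 5),
                    matched=region[i : i + 5],
                    detail={"third": region[i + 4], "h_pos": i + 1, "third_pos": i + 5},
                )
            )
    return hits


def scan_kxn(region: str) -> list[MotifHit]:
    """[K]xNØØN: any residue, wildcard, N, two hydrophobics (FILV), N.

    ``has_K`` records whether the first position carries the predominant K.
    """
    hits = []
    for i in range(len(region) - 5):
        if (
            region[i + 2] == "N"
            and region[i + 3] in HYDROPHOBIC
            and region[i + 4] in HYDROPHOBIC
            and region[i + 5] == "N"
        ):
            hits.append(
                MotifHit(
                    motif_class="KxN",
                    span=(i + 1, i + 6),
                    matched=region[i : i + 6],
                    detail={"has_K": region[i] == "K"},
                )
            )
    return hits


def detect_cys_pair(region: str) -> Optional[MotifHit]:
    """Paired cysteines (potential disulphide bridge), meant for luminal loop 3/4.

    With two or more cysteines present, returns one hit spanning the first to
    the last cysteine, recording the total count.
    """
    positions = [i for i, c in enumerate(region) if c == "C"]
    if len(positions) < 2:
        return None
    first, last = positions[0], positions[-1]
    return MotifHit(
        motif_class="CYS_PAIR",
        span=(first + 1, last + 1),
        matched=region[first : last + 1],
        detail={"count": len(positions)},
    )


def assign_hits_to_loops(hits: Iterable[MotifHit], loops: list[Loop]) -> list[MotifHit]:
    """Annotate each hit with the loop wholly containing its span.

    Hits overlapping a TMD boundary get ``loop_label=None, side=None`` and are
    excluded from side-filtered counts downstream.
    """
    out = []
    for hit in hits:
        hit.loop_label = None
        hit.side = None
        for lp in loops:
            if lp.contains(hit.span):
                hit.loop_label = lp.label
                hit.side = lp.side
                break
        out.append(hit)
    return out


def filter_by_side(hits: Iterable[MotifHit], side: str) -> list[MotifHit]:
    return [h for h in hits if h.side == side]
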