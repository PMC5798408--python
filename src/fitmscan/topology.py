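"""Membrane topology: representation, single-sequence prediction, loop anatomy.

A topology is a per-residue state string over ``i`` (cytoplasmic), ``M``
(membrane) and ``o`` (luminal). Transmembrane domains (TMDs) are the maximal
``M`` runs; the segments between them are loops, numbered ``1/2`` for the loop
between TMD 1 and TMD 2 and so on, flanked by the N-terminal and C-terminal
segments. Polytopic ER proteins of the family studied here typically have six
TMDs with the long luminal loop 3/4 carrying most of the conserved machinery.

When no external topology is supplied, :func:`predict_topology` offers a
classic single-sequence heuristic: sliding-window Kyte–Doolittle hydropathy to
find candidate helices, and the von Heijne positive-inside rule (K+R counting
in near-membrane cytoplasmic flanks) to orient them. An externally supplied
topology (e.g. from a dedicated predictor) always takes precedence in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CYTOPLASMIC = "cytoplasmic"
LUMINAL = "luminal"

_SIDE_OF_STATE = {"i": CYTOPLASMIC, "o": LUMINAL}
_STATE_OF_SIDE = {CYTOPLASMIC: "i", LUMINAL: "o"}

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    # ambiguity codes: treat as neutral/hydrophilic so they never seed a TMD
    "X": -0.5, "B": -3.5, "Z": -3.5, "U": 2.5,
}


class TopologyError(ValueError):
    """Raised for inconsistent topology state strings or parameters."""


@dataclass(frozen=True)
class PredictorParams:
    """Tunable parameters of the hydropathy/positive-inside predictor.

    window/threshold are the Kyte–Doolittle sliding-window size and the mean
    hydropathy a window centre must reach to be called membrane; candidate
    runs closer than ``merge_gap`` are merged, runs longer than
    ``max_tmd_len`` are trimmed symmetrically and runs shorter than
    ``min_tmd_len`` discarded. ``flank_window`` is how far into a cytoplasmic
    loop (from a TMD end) K/R residues are counted for orientation;
    ``whole_loop`` counts entire loops instead.
    """

    window: int = 19
    threshold: float = 1.6
    min_tmd_len: int = 15
    max_tmd_len: int = 25
    merge_gap: int = 3
    flank_window: int = 15
    whole_loop: bool = False


@dataclass
class Loop:
    """One non-membrane segment: label, side, and 1-based inclusive span.

    ``span`` is ``None`` for zero-length terminal segments (sequence starting
    or ending inside the membrane).
    """

    label: str
    side: str
    span: tuple[int, int] | None

    def __len__(self) -> int:
        return 0 if self.span is None else self.span[1] - self.span[0] + 1

    def contains(self, span: tuple[int, int]) -> bool:
        return self.span is not None and self.span[0] <= span[0] and span[1] <= self.span[1]


@dataclass
class Topology:
    """Per-residue states plus derived TMD spans and N-terminal side."""

    states: str
    tmds: list[tuple[int, int]] = field(default_factory=list)
    n_term_side: str = CYTOPLASMIC

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_tmds(self) -> int:
        return len(self.tmds)

    def flipped(self) -> "Topology":
        """Swap every i<->o state (orientation flip)."""
        swapped = self.states.translate(str.maketrans("io", "oi"))
        return from_states(swapped)


def from_states(states: str) -> Topology:
    """Build a :class:`Topology` from a state string.

    TMDs are maximal ``M`` runs; the N-terminal side is the side of the first
    non-``M`` state. A topology whose loops do not alternate sides across each
    membrane span (or that is all-``M``) is rejected.
    """
    if not states:
        raise TopologyError("empty state string")
    for pos, char in enumerate(states, start=1):
        if char not in "iMo":
            raise TopologyError(f"unknown topology state {char!r} at position {pos}")
    if set(states) == {"M"}:
        raise TopologyError("all-membrane state string has no sidedness")

    tmds: list[tuple[int, int]] = []
    loops_states: list[str] = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        if states[i] == "M":
            tmds.append((i + 1, j))
        else:
            loops_states.append(states[i])
        i = j
    for a, b in zip(loops_states, loops_states[1:]):
        if a == b:
            raise TopologyError(
                "side alternation violated: same side on both flanks of a membrane span"
            )
    first_non_m = next(c for c in states if c != "M")
    return Topology(states=states, tmds=tmds, n_term_side=_SIDE_OF_STATE[first_non_m])


def enumerate_loops(top: Topology) -> list[Loop]:
    """List all non-membrane segments with labels and sides, N- to C-terminal.

    For ``k`` TMDs this returns ``k + 1`` loops: ``N-term``, ``1/2`` ...
    ``(k-1)/k``, ``C-term`` (a 0-TMD topology yields the single ``N-term``
    segment covering the whole sequence). Zero-length terminal segments are
    returned with ``span=None`` and the geometrically correct side.
    """
    n = len(top.states)
    k = top.n_tmds
    if k == 0:
        return [Loop("N-term", top.n_term_side, (1, n))]

    bounds: list[tuple[int, int] | None] = []
    prev_end = 0
    for start, end in top.tmds:
        seg = (prev_end + 1, start - 1)
        bounds.append(seg if seg[0] <= seg[1] else None)
        prev_end = end
    tail = (prev_end + 1, n)
    bounds.append(tail if tail[0] <= tail[1] else None)

    labels = ["N-term"] + [f"{i}/{i + 1}" for i in range(1, k)] + ["C-term"]

    # Side of each loop: read off the states where the loop is non-empty,
    # then alternate outwards to fill empty terminal segments.
    sides: list[str | None] = []
    for span in bounds:
        sides.append(_SIDE_OF_STATE[top.states[span[0] - 1]] if span is not None else None)
    for idx, side in enumerate(sides):
        if side is None:
            neighbour = sides[idx + 1] if idx == 0 else sides[idx - 1]
            assert neighbour is not None  # only terminal segments can be empty
            sides[idx] = LUMINAL if neighbour == CYTOPLASMIC else CYTOPLASMIC
    return [Loop(lab, side, span) for lab, side, span in zip(labels, sides, bounds)]


def loop_by_label(loops: list[Loop], label: str) -> Loop | None:
    for lp in loops:
        if lp.label == label:
            return lp
    return None


def _candidate_tmds(seq: str, params: PredictorParams) -> list[tuple[int, int]]:
    """Maximal above-threshold hydropathy runs, merged and trimmed (0-based)."""
    n = len(seq)
    w = params.window
    half = w // 2
    values = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    kernel = np.ones(w) / w
    means = np.convolve(values, kernel, mode="valid")  # centre i+half
    marked = means >= params.threshold

    runs: list[list[int]] = []
    for centre_idx, flag in enumerate(marked):
        pos = centre_idx + half  # 0-based residue of window centre
        if flag:
            if runs and pos == runs[-1][1] + 1:
                runs[-1][1] = pos
            else:
                runs.append([pos, pos])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    # Expand each core over contiguous hydrophobic residues: charged flanking
    # residues depress edge windows and shrink the marked run, so the run of
    # above-threshold centres underestimates the helix ends.
    expanded: list[list[int]] = []
    for start, end in merged:
        while start > 0 and values[start - 1] >= params.threshold:
            start -= 1
        while end < n - 1 and values[end + 1] >= params.threshold:
            end += 1
        if expanded and start <= expanded[-1][1]:
            start = expanded[-1][1] + 1
        expanded.append([start, end])

    out: list[tuple[int, int]] = []
    for start, end in expanded:
        length = end - start + 1
        if length > params.max_tmd_len:
            trim = length - params.max_tmd_len
            start += trim // 2
            end -= trim - trim // 2
            length = params.max_tmd_len
        if length >= params.min_tmd_len:
            out.append((start, end))
    return out


def _basic_count(seq: str, top: Topology, params: PredictorParams) -> int:
    """K+R residues in cytoplasmic loops, within flank_window of a TMD end."""
    total = 0
    for lp in enumerate_loops(top):
        if lp.side != CYTOPLASMIC or lp.span is None:
            continue
        lo, hi = lp.span
        if params.whole_loop or top.n_tmds == 0:
            eligible = range(lo, hi + 1)
        else:
            near: set[int] = set()
            for t_start, t_end in top.tmds:
                if t_end == lo - 1:  # TMD immediately before this loop
                    near.update(range(lo, min(hi, lo + params.flank_window - 1) + 1))
                if t_start == hi + 1:  # TMD immediately after
                    near.update(range(max(lo, hi - params.flank_window + 1), hi + 1))
            eligible = sorted(near)
        total += sum(1 for pos in eligible if seq[pos - 1] in "KR")
    return total


def predict_topology(seq: str, params: PredictorParams | None = None) -> Topology:
    """Predict a topology from sequence alone (deterministic).

    TMDs come from sliding-window Kyte–Doolittle hydropathy; orientation is
    the assignment (N-terminus in or out) that maximizes K+R in near-membrane
    cytoplasmic flanks (positive-inside rule), ties resolved to a cytoplasmic
    N-terminus.
    """
    params = params or PredictorParams()
    seq = seq.upper()
    if len(seq) < params.window:
        raise TopologyError(
            f"sequence length {len(seq)} shorter than hydropathy window {params.window}"
        )
    tmds0 = _candidate_tmds(seq, params)

    def build_states(first_side: str) -> str:
        chars = []
        side = first_side
        prev = 0
        for start, end in tmds0:
            chars.append(side * (start - prev))
            chars.append("M" * (end - start + 1))
            side = "o" if side == "i" else "i"
            prev = end + 1
        chars.append(side * (len(seq) - prev))
        return "".join(chars)

    if not tmds0:
        return from_states("i" * len(seq))

    candidates = [from_states(build_states(s)) for s in ("i", "o")]
    scores = [_basic_count(seq, t, params) for t in candidates]
    best = candidates[0] if scores[0] >= scores[1] else candidates[1]
    return best
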