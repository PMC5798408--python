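"""Synthetic polytopic membrane proteins with planted motifs and exact ground truth.

The generator assembles a protein loop/TMD/loop/... from a residue-composition
model chosen for testability rather than realism: loops are drawn from a
hydrophilic background alphabet that excludes every motif-forming residue
(R, K, H, C, the hydrophobic class F/I/L/V, and A, whose hydropathy sits above
the TMD-calling threshold), and TMDs from a strongly hydrophobic alphabet.
Planted motifs are written over the background at requested offsets, so the
emitted ground truth (topology states plus exact motif spans) is complete:
scanners should find exactly the planted motifs, nothing else.

A deterministic repair pass guards the one leak in that argument: background
residues adjacent to a planted motif can complete a second, unplanned pattern
(e.g. a background E four residues after a planted C2 histidine completes a
spurious C3). Such positions are resampled until no unplanned hit remains;
planted and membrane residues are never touched. Plantings whose own residues
create extra hits (e.g. two di-arginine motifs closer than four residues,
whose arginines cross-pair) cannot be repaired and are rejected.

Families are mutated copies of one generated protein: per-site substitutions
at a fixed probability, drawn from the background alphabet in loops and from
the TMD alphabet in membrane spans, never inside planted motif spans unless
requested — so planted-motif recovery and di-arginine counts survive
divergence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import motifs
from .seqio import ProteinRecord
from .topology import CYTOPLASMIC, LUMINAL, Topology, enumerate_loops, from_states

BACKGROUND_DEFAULT = "DEGNPQSTY"
TMD_ALPHABET_DEFAULT = "LIVF"

CTERM_CLASSES = {name for name, _, _ in motifs.CTERM_PATTERNS}
DIARG_CLASSES = set(motifs.DIARG_CLASSES.values())


class GenerationError(ValueError):
    """Raised when a spec cannot yield a sequence with exact ground truth."""


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to write into a loop.

    ``offset`` is 0-based within the loop. ``text`` overrides the canonical
    instance (it must still contain the class pattern, which defines the
    ground-truth span).
    """

    motif_class: str
    loop_label: str
    offset: int
    text: Optional[str] = None


@dataclass
class SyntheticSpec:
    """Blueprint of one synthetic protein (deterministic given ``seed``)."""

    n_tmds: int = 6
    tmd_len: int = 21
    loop_lens: Sequence[int] = ()
    n_term_side: str = CYTOPLASMIC
    planted: Sequence[PlantedMotif] = ()
    background_alphabet: str = BACKGROUND_DEFAULT
    tmd_alphabet: str = TMD_ALPHABET_DEFAULT
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if not self.loop_lens:
            self.loop_lens = [20] + [14] * max(0, self.n_tmds - 1) + ([12] if self.n_tmds else [])
        if len(self.loop_lens) != self.n_tmds + 1:
            raise GenerationError(
                f"need {self.n_tmds + 1} loop lengths for {self.n_tmds} TMDs, got {len(self.loop_lens)}"
            )


@dataclass
class GroundTruth:
    """Topology states and the exact spans of every planted motif."""

    states: str
    hits: list[motifs.MotifHit] = field(default_factory=list)

    def by_class(self, motif_class: str) -> list[motifs.MotifHit]:
        return [h for h in self.hits if h.motif_class == motif_class]


def _canonical_text(motif_class: str, rng: np.random.Generator, bg: str) -> str:
    # wildcards avoid D/E/Q/H so an H inside the planted text (HxHxx, KxHxx)
    # can never complete a spurious C3 within the text itself
    safe = [c for c in bg if c not in "DEQH"] or list(bg)
    x = lambda: safe[rng.integers(len(safe))]
    phi = lambda: "FILV"[rng.integers(4)]
    if motif_class == "RR":
        return "RR"
    if motif_class == "RxR":
        return "R" + x() + "R"
    if motif_class == "RxxR":
        return "R" + x() + x() + "R"
    if motif_class == "KKxx":
        return "KK" + x() + x()
    if motif_class == "KxKxx":
        return "K" + x() + "K" + x() + x()
    if motif_class == "RKxx":
        return "RK" + x() + x()
    if motif_class == "RxKxx":
        return "R" + x() + "K" + x() + x()
    if motif_class == "KxRxx":
        return "K" + x() + "R" + x() + x()
    if motif_class == "HxHxx":
        return "H" + x() + "H" + x() + x()
    if motif_class == "KxHxx":
        return "K" + x() + "H" + x() + x()
    if motif_class == "C1":
        return "K" + "".join(x() for _ in range(6)) + "RP"
    if motif_class == "C2":
        return "SGH"
    if motif_class == "C3":
        return "H" + x() + x() + x() + "E"
    if motif_class == "KxN":
        return "K" + x() + "N" + phi() + phi() + "N"
    if motif_class == "CYS_PAIR":
        return "C" + x() + x() + "C"
    raise GenerationError(f"unknown motif class {motif_class!r}")


def _truth_hit(motif_class: str, text: str) -> motifs.MotifHit:
    """Locate the class pattern inside the planted text (span within text)."""
    if motif_class in DIARG_CLASSES:
        cands = [h for h in motifs.scan_diarginine(text, "all_pairs") if h.motif_class == motif_class]
    elif motif_class in CTERM_CLASSES:
        hit = motifs.scan_cterminal_retrieval(text)
        cands = [hit] if hit is not None and hit.motif_class == motif_class else []
    elif motif_class == "C1":
        cands = motifs.scan_c1(text)
    elif motif_class == "C2":
        cands = motifs.scan_c2(text)
    elif motif_class == "C3":
        cands = motifs.scan_c3(text)
    elif motif_class == "KxN":
        cands = motifs.scan_kxn(text)
    elif motif_class == "CYS_PAIR":
        hit = motifs.detect_cys_pair(text)
        cands = [hit] if hit is not None else []
    else:
        raise GenerationError(f"unknown motif class {motif_class!r}")
    if not cands:
        raise GenerationError(
            f"planted text {text!r} does not contain the {motif_class} pattern"
        )
    return cands[0]


def _loop_labels(n_tmds: int) -> list[str]:
    if n_tmds == 0:
        return ["N-term"]
    return ["N-term"] + [f"{i}/{i + 1}" for i in range(1, n_tmds)] + ["C-term"]


def _find_unplanned(seq: str, truth: GroundTruth) -> list[motifs.MotifHit]:
    """Hits in the assembled sequence that are not planted ground truth."""
    expected: dict[str, set[tuple[int, int]]] = {}
    for h in truth.hits:
        key = "diarg" if h.motif_class in DIARG_CLASSES else h.motif_class
        expected.setdefault(key, set()).add(h.span)

    unplanned: list[motifs.MotifHit] = []
    for h in motifs.scan_diarginine(seq, "all_pairs"):
        if h.span not in expected.get("diarg", set()):
            unplanned.append(h)
    for scanner, key in ((motifs.scan_c1, "C1"), (motifs.scan_c2, "C2"),
                         (motifs.scan_c3, "C3"), (motifs.scan_kxn, "KxN")):
        for h in scanner(seq):
            if h.span not in expected.get(key, set()):
                unplanned.append(h)
    cterm = motifs.scan_cterminal_retrieval(seq)
    if cterm is not None and cterm.span not in expected.get(cterm.motif_class, set()):
        unplanned.append(cterm)
    return unplanned


def generate_protein(spec: SyntheticSpec) -> tuple[ProteinRecord, GroundTruth]:
    """Assemble one synthetic protein; deterministic given ``spec.seed``.

    Raises :class:`GenerationError` when a planted motif does not fit its
    loop, a C-terminal signal is not flush with the sequence end, plantings
    overlap, or planted residues themselves create unplanned motif hits.
    """
    rng = np.random.default_rng(spec.seed)
    bg, tmd_ab = spec.background_alphabet, spec.tmd_alphabet
    labels = _loop_labels(spec.n_tmds)

    # 0-based global start of each segment, loops interleaved with TMDs
    loop_starts: dict[str, int] = {}
    chunks: list[np.ndarray] = []
    states: list[str] = []
    side = "i" if spec.n_term_side == CYTOPLASMIC else "o"
    pos = 0
    tmd_positions: set[int] = set()
    for k, (label, L) in enumerate(zip(labels, spec.loop_lens)):
        loop_starts[label] = pos
        chunks.append(rng.choice(list(bg), size=L))
        states.append(side * L)
        pos += L
        if k < spec.n_tmds:
            chunks.append(rng.choice(list(tmd_ab), size=spec.tmd_len))
            states.append("M" * spec.tmd_len)
            tmd_positions.update(range(pos, pos + spec.tmd_len))
            pos += spec.tmd_len
            side = "o" if side == "i" else "i"
    seq = np.concatenate(chunks) if chunks else np.array([], dtype="<U1")
    total_len = pos
    state_str = "".join(states)

    loop_len = dict(zip(labels, spec.loop_lens))
    planted_positions: set[int] = set()
    truth_hits: list[motifs.MotifHit] = []
    occupied: dict[str, list[tuple[int, int]]] = {lab: [] for lab in labels}

    for pm in spec.planted:
        if pm.loop_label not in loop_starts:
            raise GenerationError(f"no loop {pm.loop_label!r} for motif {pm.motif_class}")
        text = pm.text if pm.text is not None else _canonical_text(pm.motif_class, rng, bg)
        L = loop_len[pm.loop_label]
        if pm.offset < 0 or pm.offset + len(text) > L:
            raise GenerationError(
                f"motif {pm.motif_class} (len {len(text)}) does not fit loop "
                f"{pm.loop_label} (len {L}) at offset {pm.offset}"
            )
        if pm.motif_class in CTERM_CLASSES:
            flush = pm.loop_label == labels[-1] and pm.offset + len(text) == L
            if not flush:
                raise GenerationError(
                    f"C-terminal motif {pm.motif_class} must end at the sequence end"
                )
        span_local = (pm.offset, pm.offset + len(text) - 1)
        for lo, hi in occupied[pm.loop_label]:
            if not (span_local[1] < lo or span_local[0] > hi):
                raise GenerationError(
                    f"planted motifs overlap in loop {pm.loop_label} "
                    f"({pm.motif_class} at offset {pm.offset})"
                )
        occupied[pm.loop_label].append(span_local)

        g0 = loop_starts[pm.loop_label] + pm.offset  # 0-based global start
        seq[g0 : g0 + len(text)] = list(text)
        planted_positions.update(range(g0, g0 + len(text)))
        hit = _truth_hit(pm.motif_class, text).shifted(g0)
        truth_hits.append(hit)

    truth = GroundTruth(states=state_str, hits=truth_hits)

    # Repair pass: resample background residues that complete unplanned motifs.
    protected = planted_positions | tmd_positions
    for _ in range(200):
        seq_str = "".join(seq)
        unplanned = _find_unplanned(seq_str, truth)
        if not unplanned:
            break
        touched = False
        for h in unplanned:
            for p in range(h.span[0] - 1, h.span[1]):  # back to 0-based
                if p not in protected:
                    seq[p] = bg[rng.integers(len(bg))]
                    touched = True
        if not touched:
            raise GenerationError(
                "planted motifs themselves create unplanned hits "
                f"(e.g. {unplanned[0].motif_class} at {unplanned[0].span}); "
                "space plantings at least 6 residues apart"
            )
    else:
        raise GenerationError("could not eliminate unplanned motif hits")

    seq_str = "".join(seq)
    loops = enumerate_loops(from_states(state_str))
    motifs.assign_hits_to_loops(truth.hits, loops)
    rec = ProteinRecord(id=spec.name, sequence=seq_str, description="synthetic", source="synthetic")
    return rec, truth


def topology_of(truth: GroundTruth) -> Topology:
    """The ground-truth topology object of a generated protein."""
    return from_states(truth.states)


def generate_family(
    n: int,
    spec: SyntheticSpec,
    divergence: float,
    seed: Optional[int] = None,
    mutate_motifs: bool = False,
) -> list[tuple[ProteinRecord, GroundTruth]]:
    """``n`` mutated copies of one generated protein.

    Each member ``i`` gets its own substream (derived from ``seed`` and
    ``i``), so member sequences do not depend on ``n``. Substitutions are
    drawn per site with probability ``divergence``, from the background
    alphabet in loops and the TMD alphabet in membrane spans; planted motif
    spans are exempt unless ``mutate_motifs`` is set.
    """
    if not 0 <= divergence <= 1:
        raise GenerationError(f"divergence must be in [0, 1], got {divergence}")
    base_rec, base_truth = generate_protein(spec)
    base_seed = spec.seed if seed is None else seed
    planted = set()
    for h in base_truth.hits:
        planted.update(range(h.span[0] - 1, h.span[1]))
    is_tmd = [c == "M" for c in base_truth.states]

    members: list[tuple[ProteinRecord, GroundTruth]] = []
    for i in range(n):
        rng = np.random.default_rng([base_seed, i])
        chars = list(base_rec.sequence)
        draws = rng.random(len(chars))
        for p, (c, u) in enumerate(zip(chars, draws)):
            if u >= divergence:
                continue
            if p in planted and not mutate_motifs:
                continue
            pool = spec.tmd_alphabet if is_tmd[p] else spec.background_alphabet
            options = [a for a in pool if a != c]
            if options:
                chars[p] = options[rng.integers(len(options))]
        seq = "".join(chars)
        hits = [
            replace(h, matched=seq[h.span[0] - 1 : h.span[1]]) for h in base_truth.hits
        ]
        rec = ProteinRecord(
            id=f"{spec.name}_{i:03d}",
            sequence=seq,
            description=f"synthetic family member {i}",
            source="synthetic",
        )
        members.append((rec, GroundTruth(states=base_truth.states, hits=hits)))
    return members


def random_spec(
    rng: np.random.Generator,
    n_tmds: Optional[int] = None,
    name: str = "synthetic",
) -> SyntheticSpec:
    """A random, well-separated planting blueprint for recovery testing.

    Loops are at least 12 residues, planted motifs keep a 4-residue margin
    from loop edges and at least 6 residues between plantings, and C-terminal
    signals are planted flush at the end of cytoplasmic C-terminal segments
    only — the regime in which scanners and the topology predictor recover
    the ground truth exactly.
    """
    if n_tmds is None:
        n_tmds = int(rng.integers(2, 7))
    loop_lens = [int(rng.integers(16, 36)) for _ in range(n_tmds + 1)]
    n_term_side = CYTOPLASMIC if rng.random() < 0.5 else LUMINAL
    labels = _loop_labels(n_tmds)

    sides = {}
    side = n_term_side
    for lab in labels:
        sides[lab] = side
        side = LUMINAL if side == CYTOPLASMIC else CYTOPLASMIC

    planted: list[PlantedMotif] = []
    lens = {
        "RR": 2, "RxR": 3, "RxxR": 4, "C1": 9, "C2": 3, "C3": 5,
        "KxN": 6, "CYS_PAIR": 4,
    }
    margin, gap = 4, 6
    for lab, L in zip(labels, loop_lens):
        if sides[lab] == CYTOPLASMIC:
            choices = ["RR", "RxR", "RxxR"]
            k = int(rng.integers(0, 3))
        else:
            choices = ["C1", "C2", "C3", "KxN", "CYS_PAIR"]
            k = int(rng.integers(0, 3))
        cursor = margin
        cys_planted = False
        for _ in range(k):
            cls = choices[int(rng.integers(len(choices)))]
            if cls == "CYS_PAIR":
                # one disulphide pair per loop: detection spans first-to-last Cys
                if cys_planted:
                    continue
                cys_planted = True
            if cursor + lens[cls] > L - margin:
                break
            planted.append(PlantedMotif(cls, lab, cursor))
            cursor += lens[cls] + gap + int(rng.integers(0, 4))

    # optional C-terminal retrieval signal, flush at the sequence end
    if n_tmds > 0 and sides[labels[-1]] == CYTOPLASMIC and rng.random() < 0.5:
        cterm_list = sorted(CTERM_CLASSES)
        cls = cterm_list[int(rng.integers(len(cterm_list)))]
        length = 4 if cls in ("KKxx", "RKxx") else 5
        L = loop_lens[-1]
        tail_free = all(
            pm.loop_label != labels[-1] or pm.offset + lens[pm.motif_class] <= L - length - gap
            for pm in planted
        )
        if tail_free:
            planted.append(PlantedMotif(cls, labels[-1], L - length))

    return SyntheticSpec(
        n_tmds=n_tmds,
        loop_lens=loop_lens,
        n_term_side=n_term_side,
        planted=planted,
        seed=int(rng.integers(2**31 - 1)),
        name=name,
    )
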