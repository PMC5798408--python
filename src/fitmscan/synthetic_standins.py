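"""Synthetic stand-in proteins emulating the published anatomy of the two
budding-yeast FITM paralogues.

These are NOT the real Scs3p (YGL126W) or Yft2p (YDR319C) sequences — they
are fully synthetic 6-TMD constructs whose *planted* motif anatomy reproduces
the coordinates and counts reported for the real proteins: the Scs3p-like
stand-in carries six di-arginine motifs in cytoplasmic loops and its third
triad residue (E-3) at position 354; the Yft2p-like stand-in carries zero
cytoplasmic di-arginines, H-1 at position 178 and E-3 at position 243, plus
the luminal loop 1/2 [K]xNØØN motif and the loop 3/4 cysteine pair. Tests
built on them are planted-ground-truth recovery tests, not assertions about
the natural sequences.

Both stand-ins embed the full 14-residue extended C3 consensus
(TALYFHTLLEKLLG) so the context scorer sees a perfect-consensus site.
"""

from __future__ import annotations

from .seqio import ProteinRecord
from .synth import GroundTruth, PlantedMotif, SyntheticSpec, generate_protein
from .topology import Topology, from_states

#: Perfect instance of the extended C3 consensus TAØYF-H-TØØ-E-KØØG.
C3_CONSENSUS_TEXT = "TALYFHTLLEKLLG"


def yft2_like(seed: int = 2319) -> tuple[ProteinRecord, Topology, GroundTruth]:
    """275-residue 6-TMD stand-in with the Yft2p-style motif anatomy.

    Planted ground truth: no arginines anywhere (0 cytoplasmic di-arginine
    motifs), [K]xNØØN in luminal loop 1/2, cysteine pair and C2 (SGH, H-1 at
    178) in luminal loop 3/4, extended C3 consensus in luminal loop 5/6 with
    H-2 at 239 and E-3 at 243, no C-terminal retrieval signal.
    """
    spec = SyntheticSpec(
        n_tmds=6,
        tmd_len=21,
        # segments: N-term 1-24, TMD1 25-45, loop1/2 46-69, TMD2 70-90,
        # loop2/3 91-104, TMD3 105-125, loop3/4 126-182, TMD4 183-203,
        # loop4/5 204-212, TMD5 213-233, loop5/6 234-249, TMD6 250-270,
        # C-term 271-275
        loop_lens=[24, 24, 14, 57, 9, 16, 5],
        n_term_side="cytoplasmic",
        planted=[
            PlantedMotif("KxN", "1/2", 4),            # 50-55
            PlantedMotif("CYS_PAIR", "3/4", 6),       # 132-135
            PlantedMotif("C2", "3/4", 50),            # 176-178, H-1 at 178
            PlantedMotif("C3", "5/6", 0, text=C3_CONSENSUS_TEXT),  # H-2 239, E-3 243
        ],
        seed=seed,
        name="yft2_like",
    )
    rec, truth = generate_protein(spec)
    return rec, from_states(truth.states), truth


def scs3_like(seed: int = 3126) -> tuple[ProteinRecord, Topology, GroundTruth]:
    """390-residue 6-TMD stand-in with the Scs3p-style motif anatomy.

    Planted ground truth: six di-arginine motifs in cytoplasmic loops (three
    in the N-terminal segment, two in loop 2/3, one in loop 4/5), cysteine
    pair and C2 in the long luminal loop 3/4, extended C3 consensus in
    luminal loop 5/6 with E-3 at 354, no [K]xNØØN (largely absent from this
    paralogue group), no C-terminal retrieval signal.
    """
    spec = SyntheticSpec(
        n_tmds=6,
        tmd_len=21,
        # segments: N-term 1-40, TMD1 41-61, loop1/2 62-85, TMD2 86-106,
        # loop2/3 107-126, TMD3 127-147, loop3/4 148-290, TMD4 291-311,
        # loop4/5 312-321, TMD5 322-342, loop5/6 343-363, TMD6 364-384,
        # C-term 385-390
        loop_lens=[40, 24, 20, 143, 10, 21, 6],
        n_term_side="cytoplasmic",
        planted=[
            PlantedMotif("RR", "N-term", 4),          # 5-6
            PlantedMotif("RR", "N-term", 14),         # 15-16
            PlantedMotif("RxxR", "N-term", 24),       # 25-28
            PlantedMotif("RR", "2/3", 3),             # 110-111
            PlantedMotif("RxR", "2/3", 11),           # 118-120
            PlantedMotif("RR", "4/5", 2),             # 314-315
            PlantedMotif("CYS_PAIR", "3/4", 10),      # 158-161
            PlantedMotif("C2", "3/4", 122),           # 270-272, H-1 at 272
            PlantedMotif("C3", "5/6", 2, text=C3_CONSENSUS_TEXT),  # H-2 350, E-3 354
        ],
        seed=seed,
        name="scs3_like",
    )
    rec, truth = generate_protein(spec)
    return rec, from_states(truth.states), truth
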