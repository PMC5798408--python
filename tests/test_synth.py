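"""Synthetic generator: determinism, ground-truth consistency, family divergence."""

import numpy as np
import pytest

from fitmscan import motifs
from fitmscan.synth import (
    GenerationError,
    PlantedMotif,
    SyntheticSpec,
    generate_family,
    generate_protein,
    random_spec,
    topology_of,
)
from fitmscan.topology import enumerate_loops, predict_topology


def spec_6tmd(**kw):
    defaults = dict(
        n_tmds=6,
        loop_lens=[20, 14, 14, 40, 14, 14, 12],
        planted=[
            PlantedMotif("RR", "2/3", 4),
            PlantedMotif("C2", "3/4", 8),
            PlantedMotif("C3", "5/6", 4),
        ],
        seed=1,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestGenerateProtein:
    def test_deterministic_given_seed(self):
        a, _ = generate_protein(spec_6tmd())
        b, _ = generate_protein(spec_6tmd())
        assert a.sequence == b.sequence

    def test_seed_changes_sequence(self):
        a, _ = generate_protein(spec_6tmd(seed=1))
        b, _ = generate_protein(spec_6tmd(seed=2))
        assert a.sequence != b.sequence

    def test_planted_motifs_recovered_with_exact_spans(self):
        rec, truth = generate_protein(spec_6tmd())
        seq = rec.sequence
        (rr,) = truth.by_class("RR")
        assert [h.span for h in motifs.scan_diarginine(seq)] == [rr.span]
        (c2,) = truth.by_class("C2")
        assert [h.span for h in motifs.scan_c2(seq)] == [c2.span]
        (c3,) = truth.by_class("C3")
        assert [h.span for h in motifs.scan_c3(seq)] == [c3.span]

    def test_truth_matches_emitted_sequence(self):
        rec, truth = generate_protein(spec_6tmd())
        assert len(truth.states) == len(rec.sequence)
        for h in truth.hits:
            assert h.matched == rec.sequence[h.span[0] - 1 : h.span[1]]

    def test_no_arginine_background_means_no_diarg_hits(self):
        rec, _ = generate_protein(spec_6tmd(planted=[]))
        assert "R" not in rec.sequence
        assert motifs.scan_diarginine(rec.sequence) == []

    def test_motif_too_large_for_loop(self):
        with pytest.raises(GenerationError, match="does not fit"):
            generate_protein(spec_6tmd(planted=[PlantedMotif("C1", "2/3", 10)]))

    def test_cterm_motif_must_be_flush(self):
        with pytest.raises(GenerationError, match="sequence end"):
            generate_protein(spec_6tmd(planted=[PlantedMotif("KKxx", "C-term", 0)]))

    def test_overlapping_plants_rejected(self):
        with pytest.raises(GenerationError, match="overlap"):
            generate_protein(
                spec_6tmd(planted=[PlantedMotif("RR", "2/3", 4), PlantedMotif("RxR", "2/3", 5)])
            )

    def test_ground_truth_has_loop_and_side(self):
        _, truth = generate_protein(spec_6tmd())
        (rr,) = truth.by_class("RR")
        assert (rr.loop_label, rr.side) == ("2/3", "cytoplasmic")
        (c2,) = truth.by_class("C2")
        assert (c2.loop_label, c2.side) == ("3/4", "luminal")


class TestGenerateFamily:
    def test_zero_divergence_identical(self):
        fam = generate_family(4, spec_6tmd(), divergence=0.0)
        seqs = {rec.sequence for rec, _ in fam}
        assert len(seqs) == 1

    def test_members_independent_of_family_size(self):
        small = generate_family(3, spec_6tmd(), divergence=0.05)
        large = generate_family(6, spec_6tmd(), divergence=0.05)
        for (a, _), (b, _) in zip(small, large):
            assert a.sequence == b.sequence

    def test_divergence_preserves_planted_motifs(self):
        fam = generate_family(20, spec_6tmd(), divergence=0.05)
        for rec, truth in fam:
            spans = {h.span for h in truth.hits if h.motif_class == "RR"}
            assert {h.span for h in motifs.scan_diarginine(rec.sequence)} >= spans
            c2_spans = {h.span for h in truth.hits if h.motif_class == "C2"}
            assert {h.span for h in motifs.scan_c2(rec.sequence)} >= c2_spans

    def test_mutate_motifs_can_destroy_them(self):
        fam = generate_family(10, spec_6tmd(), divergence=0.9, mutate_motifs=True)
        destroyed = sum(
            1 for rec, _ in fam if not motifs.scan_diarginine(rec.sequence)
        )
        assert destroyed > 0

    def test_divergence_out_of_range(self):
        with pytest.raises(GenerationError):
            generate_family(2, spec_6tmd(), divergence=1.5)


class TestRandomSpecRecovery:
    def test_planted_recovery_and_topology_on_random_specs(self):
        rng = np.random.default_rng(99)
        for i in range(30):
            spec = random_spec(rng, name=f"r{i}")
            rec, truth = generate_protein(spec)
            seq = rec.sequence
            want = {
                h.span for h in truth.hits if h.motif_class in ("RR", "RxR", "RxxR")
            }
            assert {h.span for h in motifs.scan_diarginine(seq)} == want
            pred = predict_topology(seq)
            assert pred.n_tmds == spec.n_tmds

    @pytest.mark.parametrize("n_term_side", ["cytoplasmic", "luminal"])
    def test_orientation_recovered_with_planted_basic_loops(self, n_term_side):
        # arginines planted near TMD ends of the cytoplasmic loops only:
        # the positive-inside rule must recover the planted N-terminal side
        cyto_loops = ["N-term", "2/3", "4/5", "C-term"] if n_term_side == "cytoplasmic" \
            else ["1/2", "3/4", "5/6"]
        spec = SyntheticSpec(
            n_tmds=6,
            loop_lens=[18, 18, 18, 18, 18, 18, 18],
            n_term_side=n_term_side,
            planted=[PlantedMotif("RR", lab, off) for lab in cyto_loops for off in (4, 12)],
            seed=21,
        )
        rec, truth = generate_protein(spec)
        pred = predict_topology(rec.sequence)
        assert pred.n_tmds == 6
        assert pred.n_term_side == topology_of(truth).n_term_side


class TestLoopPartition:
    def test_truth_topology_partitions_sequence(self):
        rec, truth = generate_protein(spec_6tmd())
        top = topology_of(truth)
        loops = enumerate_loops(top)
        assert sum(len(lp) for lp in loops) + sum(b - a + 1 for a, b in top.tmds) == len(rec.sequence)
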