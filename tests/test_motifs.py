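"""Motif scanners against brute-force oracles, plus loop assignment rules."""

import itertools

import pytest
from hypothesis import given, strategies as st

from fitmscan import motifs
from fitmscan.topology import enumerate_loops, from_states

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- independent oracles -------------------------------------------------

def oracle_all_pairs(seq):
    """Every pair of R residues at distance <= 3 (exhaustive enumeration)."""
    rs = [i for i, c in enumerate(seq) if c == "R"]
    return sorted(
        (i + 1, j + 1) for i, j in itertools.combinations(rs, 2) if j - i <= 3
    )


def oracle_greedy(seq):
    """Left-to-right nearest-partner pairing, re-derived independently."""
    rs = [i for i, c in enumerate(seq) if c == "R"]
    pairs, used = [], set()
    for idx, i in enumerate(rs):
        if i in used:
            continue
        for j in rs[idx + 1 :]:
            if j in used:
                continue
            if j - i <= 3:
                pairs.append((i + 1, j + 1))
                used.update((i, j))
                break
            break
    return sorted(pairs)


def oracle_cterm(seq):
    """Exhaustive check of the seven retrieval patterns on the final 5 residues."""
    n = len(seq)
    def at(k):
        return seq[n + k] if n + k >= 0 else None
    if n >= 4 and at(-4) == "K" and at(-3) == "K":
        return "KKxx"
    if n >= 5 and at(-5) == "K" and at(-3) == "K":
        return "KxKxx"
    if n >= 4 and at(-4) == "R" and at(-3) == "K":
        return "RKxx"
    if n >= 5 and at(-5) == "R" and at(-3) == "K":
        return "RxKxx"
    if n >= 5 and at(-5) == "K" and at(-3) == "R":
        return "KxRxx"
    if n >= 5 and at(-5) == "H" and at(-3) == "H":
        return "HxHxx"
    if n >= 5 and at(-5) == "K" and at(-3) == "H":
        return "KxHxx"
    return None


# --- di-arginine ---------------------------------------------------------

class TestDiarginine:
    def test_simple_rr(self):
        (hit,) = motifs.scan_diarginine("MRRA")
        assert (hit.motif_class, hit.span, hit.matched) == ("RR", (2, 3), "RR")

    def test_rrrr_counting_conventions(self):
        assert len(motifs.scan_diarginine("RRRR", "all_pairs")) == 6
        greedy = motifs.scan_diarginine("RRRR", "greedy")
        assert [h.span for h in greedy] == [(1, 2), (3, 4)]

    def test_wildcard_may_be_arginine(self):
        spans = {h.span for h in motifs.scan_diarginine("RAR", "all_pairs")}
        assert spans == {(1, 3)}
        spans = {h.span for h in motifs.scan_diarginine("RRR", "all_pairs")}
        assert spans == {(1, 2), (2, 3), (1, 3)}

    def test_empty_sequence(self):
        assert motifs.scan_diarginine("") == []

    @pytest.mark.parametrize("mode,oracle", [("greedy", oracle_greedy), ("all_pairs", oracle_all_pairs)])
    def test_exhaustive_ra_strings(self, mode, oracle):
        for n in range(13):
            for combo in itertools.product("RA", repeat=n):
                seq = "".join(combo)
                got = sorted(h.span for h in motifs.scan_diarginine(seq, mode))
                assert got == oracle(seq), seq

    def test_random_30mers_match_oracle(self, rng):
        for _ in range(1000):
            seq = "".join(rng.choice(list(AA), size=30))
            assert sorted(h.span for h in motifs.scan_diarginine(seq, "greedy")) == oracle_greedy(seq)
            assert sorted(h.span for h in motifs.scan_diarginine(seq, "all_pairs")) == oracle_all_pairs(seq)

    @given(st.text(alphabet=AA, max_size=40))
    def test_greedy_at_most_all_pairs_and_disjoint(self, seq):
        greedy = motifs.scan_diarginine(seq, "greedy")
        assert len(greedy) <= len(motifs.scan_diarginine(seq, "all_pairs"))
        ends = [p for h in greedy for p in h.span]
        assert len(ends) == len(set(ends))  # each arginine in at most one greedy hit

    def test_spans_match_sequence(self, rng):
        seq = "".join(rng.choice(list(AA), size=60))
        for mode in ("greedy", "all_pairs"):
            for h in motifs.scan_diarginine(seq, mode):
                assert h.matched == seq[h.span[0] - 1 : h.span[1]]


# --- C-terminal retrieval ------------------------------------------------

class TestCterminal:
    @pytest.mark.parametrize(
        "tail,expected",
        [
            ("WKKAA", "KKxx"),
            ("KAKAA", "KxKxx"),
            ("WRKAA", "RKxx"),
            ("RAKAA", "RxKxx"),
            ("KARAA", "KxRxx"),
            ("HAHAA", "HxHxx"),
            ("KAHAA", "KxHxx"),
            ("WAKKA", None),
            ("AAAAA", None),
        ],
    )
    def test_pattern_table(self, tail, expected):
        hit = motifs.scan_cterminal_retrieval("MSSSS" + tail)
        assert (hit.motif_class if hit else None) == expected

    def test_exhaustive_final5_against_oracle(self):
        for combo in itertools.product("KRHA", repeat=5):
            seq = "MSS" + "".join(combo)
            hit = motifs.scan_cterminal_retrieval(seq)
            assert (hit.motif_class if hit else None) == oracle_cterm(seq)

    def test_short_sequences(self):
        assert motifs.scan_cterminal_retrieval("KKAA").motif_class == "KKxx"
        assert motifs.scan_cterminal_retrieval("KAA") is None

    @given(st.text(alphabet=AA, min_size=5, max_size=30), st.text(alphabet=AA, max_size=20))
    def test_nterminal_extension_invariance(self, seq, prefix):
        base = motifs.scan_cterminal_retrieval(seq)
        extended = motifs.scan_cterminal_retrieval(prefix + seq)
        assert (base is None) == (extended is None)
        if base is not None:
            assert base.motif_class == extended.motif_class

    def test_ambiguity_codes_never_match(self):
        assert motifs.scan_cterminal_retrieval("MSSXKAA") is None  # X is not K/R/H
        assert motifs.scan_cterminal_retrieval("MSSBKAA") is None


# --- active-site blocks --------------------------------------------------

class TestActiveSiteBlocks:
    def test_c1_literal(self):
        (hit,) = motifs.scan_c1("KAAAAAARP")
        assert hit.span == (1, 9)
        assert motifs.scan_c1("KAAAAAARA") == []

    def test_c2_variants(self):
        (hit,) = motifs.scan_c2("ASGHA")
        assert hit.span == (2, 4) and hit.detail["h_pos"] == 4
        (hit,) = motifs.scan_c2("ASSHA")
        assert hit.detail["middle"] == "S"
        assert motifs.scan_c2("ASGAA") == []

    def test_c3_third_residues(self):
        for third, found in [("E", True), ("D", True), ("Q", True), ("H", True), ("G", False)]:
            hits = motifs.scan_c3(f"HAAA{third}")
            assert bool(hits) == found
            if found:
                assert hits[0].detail["third"] == third
                assert hits[0].detail["third_pos"] == hits[0].detail["h_pos"] + 4

    def test_kxn_hydrophobic_class(self):
        (hit,) = motifs.scan_kxn("KANLVN")
        assert hit.detail["has_K"] is True
        (hit,) = motifs.scan_kxn("AANLVN")
        assert hit.detail["has_K"] is False
        assert motifs.scan_kxn("KANLAN") == []  # A is not in FILV

    def test_cys_pair_rules(self):
        hit = motifs.detect_cys_pair("ACDDCA")
        assert hit.span == (2, 5) and hit.detail["count"] == 2
        assert motifs.detect_cys_pair("ACDDDA") is None
        hit = motifs.detect_cys_pair("CACAC")
        assert hit.span == (1, 5) and hit.detail["count"] == 3

    def test_ambiguity_never_fills_class_positions(self):
        assert motifs.scan_c2("AXGHA") == []  # X not in [ST]
        assert motifs.scan_c3("HAAAX") == []  # X not in [DEQH]
        assert motifs.scan_kxn("KANXVN") == []  # X not hydrophobic
        # but pure wildcard positions accept anything, X included
        assert len(motifs.scan_c3("HXXXE")) == 1
        assert len(motifs.scan_kxn("XXNLVN")) == 1


# --- loop assignment -----------------------------------------------------

class TestLoopAssignment:
    def test_sides_and_boundary_rule(self):
        states = "iiiiii" + "M" * 15 + "oooooo"
        loops = enumerate_loops(from_states(states))
        inside = motifs.MotifHit("RR", (2, 3), "RR")
        straddle = motifs.MotifHit("RR", (6, 7), "RR")  # 7 is in the TMD
        luminal = motifs.MotifHit("RR", (23, 24), "RR")
        motifs.assign_hits_to_loops([inside, straddle, luminal], loops)
        assert (inside.loop_label, inside.side) == ("N-term", "cytoplasmic")
        assert (straddle.loop_label, straddle.side) == (None, None)
        assert luminal.side == "luminal"
        assert motifs.filter_by_side([inside, straddle, luminal], "cytoplasmic") == [inside]
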