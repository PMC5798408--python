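"""Per-protein retention profiling, ER-localization calls, family statistics.

The localization rule mirrors the motif-based prediction used for recently
duplicated FITM paralogues: a C-terminal di-lysine signal (or proven variant)
or at least two di-arginine motifs predict ER residence; exactly one
di-arginine is called "unsure"; none means "not ER". Family statistics are
descriptive (mean and SD of the di-arginine count, fraction with a C-terminal
signal), matching how large paralogue families were contrasted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from . import motifs
from .seqio import ProteinRecord
from .topology import CYTOPLASMIC, LUMINAL, Topology, enumerate_loops, loop_by_label
from .triad import TriadAssignment, find_triad

ER = "ER"
UNSURE = "unsure"
NOT_ER = "not_ER"


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the profiling run.

    ``diarg_mode``: greedy (non-overlapping pairing, default) or all_pairs.
    ``luminal_restrict``: scan the active-site blocks (C1/C2/C3/KxN) only in
    luminal loops when a topology is available (the catalytic centre always
    faces the lumen); without a topology the whole sequence is scanned.
    """

    diarg_mode: str = "greedy"
    middle_class: frozenset = motifs.C2_MIDDLE_DEFAULT
    third_class: frozenset = motifs.C3_THIRD_DEFAULT
    luminal_restrict: bool = True
    lenient_triad: bool = False


@dataclass
class RetentionProfile:
    """Motif counts, triad assignment and localization call for one protein."""

    id: str
    n_diarg_total: int = 0
    n_diarg_cyto: Optional[int] = None
    cterm_motif: Optional[str] = None
    kxn_present: bool = False
    kxn_has_K: bool = False
    cys_pair_34: bool = False
    triad: TriadAssignment = field(default_factory=TriadAssignment)
    localization: str = NOT_ER
    hits: list[motifs.MotifHit] = field(default_factory=list)

    def to_row(self) -> dict:
        t = self.triad
        return {
            "id": self.id,
            "n_diarg_total": self.n_diarg_total,
            "n_diarg_cyto": self.n_diarg_cyto,
            "cterm_motif": self.cterm_motif,
            "localization": self.localization,
            "kxn_present": self.kxn_present,
            "kxn_has_K": self.kxn_has_K,
            "cys_pair_34": self.cys_pair_34,
            "h1_pos": t.h1_pos,
            "h1_res": t.h1_res,
            "h2_pos": t.h2_pos,
            "h2_res": t.h2_res,
            "third_pos": t.third_pos,
            "third_res": t.third_res,
            "c2_middle": t.c2_middle,
            "context_score": t.context_score,
            "triad_class": t.classification,
        }

    def to_dict(self) -> dict:
        d = self.to_row()
        d["triad"] = self.triad.to_dict()
        d["hits"] = [h.to_dict() for h in self.hits]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RetentionProfile":
        return cls(
            id=d["id"],
            n_diarg_total=d["n_diarg_total"],
            n_diarg_cyto=d["n_diarg_cyto"],
            cterm_motif=d["cterm_motif"],
            kxn_present=d["kxn_present"],
            kxn_has_K=d["kxn_has_K"],
            cys_pair_34=d["cys_pair_34"],
            triad=TriadAssignment.from_dict(d["triad"]),
            localization=d["localization"],
            hits=[motifs.MotifHit.from_dict(h) for h in d["hits"]],
        )


@dataclass
class FamilyStats:
    """Descriptive per-family aggregates over retention profiles."""

    label: str
    n: int
    mean_diarg: float
    sd_diarg: float
    n_cterm: int
    n_kxn: int
    count_field: str = "total"

    @property
    def cterm_fraction(self) -> float:
        return self.n_cterm / self.n


@dataclass
class GroupComparison:
    """Pairwise contrast of two family aggregates."""

    label_a: str
    label_b: str
    mean_diff: float
    cterm_fraction_a: float
    cterm_fraction_b: float
    cterm_fraction_ratio: Optional[float]
    more_er_like: str  # label_a, label_b, or "mixed"


def classify_er_localization(cterm_present: bool, n_diarg: int) -> str:
    """Motif-based localization call.

    C-terminal di-lysine (or proven variant) or >= 2 di-arginines -> ER;
    exactly 1 di-arginine -> unsure; none -> not ER.
    """
    if n_diarg < 0:
        raise ValueError(f"negative di-arginine count: {n_diarg}")
    if cterm_present or n_diarg >= 2:
        return ER
    return UNSURE if n_diarg == 1 else NOT_ER


def build_profile(
    rec: ProteinRecord,
    top: Optional[Topology] = None,
    config: ScanConfig | None = None,
) -> RetentionProfile:
    """Run every scanner over one protein and derive its localization call.

    ``n_diarg_total`` counts motifs over the whole sequence (high-throughput
    mode, luminal motifs included); ``n_diarg_cyto`` is only computed when a
    topology is present, counting hits wholly inside cytoplasmic loops
    (boundary-straddling hits excluded). The localization rule uses the
    cytoplasmic count when available, the total otherwise.
    """
    config = config or ScanConfig()
    seq = rec.sequence
    if top is not None and len(top) != len(seq):
        raise ValueError(
            f"{rec.id}: topology length {len(top)} != sequence length {len(seq)}"
        )

    diarg_hits = motifs.scan_diarginine(seq, mode=config.diarg_mode)
    cterm_hit = motifs.scan_cterminal_retrieval(seq)
    c1_hits = motifs.scan_c1(seq)
    c2_hits = motifs.scan_c2(seq, config.middle_class)
    c3_hits = motifs.scan_c3(seq, config.third_class)
    kxn_hits = motifs.scan_kxn(seq)

    n_diarg_cyto: Optional[int] = None
    cys_hit = None
    if top is not None:
        loops = enumerate_loops(top)
        for group in (diarg_hits, c1_hits, c2_hits, c3_hits, kxn_hits):
            motifs.assign_hits_to_loops(group, loops)
        if cterm_hit is not None:
            motifs.assign_hits_to_loops([cterm_hit], loops)
        n_diarg_cyto = sum(1 for h in diarg_hits if h.side == CYTOPLASMIC)
        if config.luminal_restrict:
            c1_hits = motifs.filter_by_side(c1_hits, LUMINAL)
            c2_hits = motifs.filter_by_side(c2_hits, LUMINAL)
            c3_hits = motifs.filter_by_side(c3_hits, LUMINAL)
            kxn_hits = motifs.filter_by_side(kxn_hits, LUMINAL)
        loop34 = loop_by_label(loops, "3/4")
        if loop34 is not None and loop34.span is not None:
            lo, hi = loop34.span
            cys_hit = motifs.detect_cys_pair(seq[lo - 1 : hi])
            if cys_hit is not None:
                cys_hit = cys_hit.shifted(lo - 1)
                cys_hit.loop_label, cys_hit.side = loop34.label, loop34.side
    else:
        cys_hit = motifs.detect_cys_pair(seq)

    triad = find_triad(
        seq,
        top,
        middle_class=config.middle_class,
        third_class=config.third_class,
        lenient=config.lenient_triad,
    )

    n_for_rule = n_diarg_cyto if n_diarg_cyto is not None else len(diarg_hits)
    localization = classify_er_localization(cterm_hit is not None, n_for_rule)

    all_hits = list(diarg_hits) + c1_hits + c2_hits + c3_hits + kxn_hits
    if cterm_hit is not None:
        all_hits.append(cterm_hit)
    if cys_hit is not None:
        all_hits.append(cys_hit)

    return RetentionProfile(
        id=rec.id,
        n_diarg_total=len(diarg_hits),
        n_diarg_cyto=n_diarg_cyto,
        cterm_motif=cterm_hit.motif_class if cterm_hit is not None else None,
        kxn_present=bool(kxn_hits),
        kxn_has_K=any(h.detail.get("has_K") for h in kxn_hits),
        cys_pair_34=cys_hit is not None,
        triad=triad,
        localization=localization,
        hits=all_hits,
    )


def aggregate_family(
    profiles: list[RetentionProfile], count_field: str = "total", label: str = "family"
) -> FamilyStats:
    """Mean/SD of the chosen di-arginine count plus C-terminal/KxN tallies.

    ``count_field`` selects total (whole-sequence) or cyto (topology-mode)
    counts; requesting cyto when any profile lacks it is an error naming the
    offending ids. SD is the population standard deviation (n denominator),
    so a single-member family has SD 0.
    """
    if not profiles:
        raise ValueError("cannot aggregate an empty family")
    if count_field == "total":
        counts = [p.n_diarg_total for p in profiles]
    elif count_field == "cyto":
        missing = [p.id for p in profiles if p.n_diarg_cyto is None]
        if missing:
            raise ValueError(f"profiles missing cytoplasmic counts: {', '.join(missing)}")
        counts = [p.n_diarg_cyto for p in profiles]
    else:
        raise ValueError(f"unknown count_field {count_field!r}")
    n = len(counts)
    mean = sum(counts) / n
    sd = math.sqrt(sum((c - mean) ** 2 for c in counts) / n)
    return FamilyStats(
        label=label,
        n=n,
        mean_diarg=mean,
        sd_diarg=sd,
        n_cterm=sum(1 for p in profiles if p.cterm_motif is not None),
        n_kxn=sum(1 for p in profiles if p.kxn_present),
        count_field=count_field,
    )


def compare_groups(a: FamilyStats, b: FamilyStats) -> GroupComparison:
    """Contrast two families: mean difference, C-terminal fractions, verdict.

    A group is "more ER-like" when it has both the strictly higher mean
    di-arginine count and at least as high a fraction of members with a
    C-terminal signal; anything else is "mixed".
    """
    if a.count_field != b.count_field:
        raise ValueError(
            f"count_field mismatch: {a.count_field!r} vs {b.count_field!r}"
        )
    fa, fb = a.cterm_fraction, b.cterm_fraction
    ratio = (fa / fb) if fb > 0 else None
    if a.mean_diarg > b.mean_diarg and fa >= fb:
        verdict = a.label
    elif b.mean_diarg > a.mean_diarg and fb >= fa:
        verdict = b.label
    else:
        verdict = "mixed"
    return GroupComparison(
        label_a=a.label,
        label_b=b.label,
        mean_diff=a.mean_diarg - b.mean_diarg,
        cterm_fraction_a=fa,
        cterm_fraction_b=fb,
        cterm_fraction_ratio=ratio,
        more_er_like=verdict,
    )
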