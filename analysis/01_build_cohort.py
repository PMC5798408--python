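#!/usr/bin/env python
"""Build the synthetic study cohort and write it to results/cohort/.

Generates (a) the two synthetic yeast-paralogue stand-ins whose planted motif
anatomy follows the published coordinates (Scs3p-like: six cytoplasmic
di-arginine motifs, E-3 at 354; Yft2p-like: none, H-1 at 178, E-3 at 243) and
(b) two 6-TMD synthetic families built to the published family conditions
(40 members averaging 3.7 di-arginine motifs, 4 with KKxx, versus 52 members
averaging 1.6, none with a C-terminal signal). Emits FASTA, topology
annotations, ground-truth JSON and the group table used by later steps.
"""

import json
from pathlib import Path

from fitmscan import seqio
from fitmscan import synthetic_standins as standins
from fitmscan.synth import PlantedMotif, SyntheticSpec, generate_protein

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20171228

LOOP_LENS = [22, 14, 14, 40, 14, 14, 14]
DIARG_SLOTS = [("N-term", 4), ("N-term", 12), ("2/3", 4), ("4/5", 4)]


def family_member(name, idx, n_diarg, with_kkxx, seed):
    planted = [PlantedMotif("RR", lab, off) for lab, off in DIARG_SLOTS[:n_diarg]]
    if with_kkxx:
        planted.append(PlantedMotif("KKxx", "C-term", LOOP_LENS[-1] - 4))
    spec = SyntheticSpec(
        n_tmds=6, loop_lens=LOOP_LENS, planted=planted,
        seed=seed + idx, name=f"{name}_{idx:03d}",
    )
    return generate_protein(spec)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    records, topologies, truths, groups = [], {}, {}, {}

    for builder, label in ((standins.scs3_like, "standins"), (standins.yft2_like, "standins")):
        rec, top, truth = builder()
        records.append(rec)
        topologies[rec.id] = truth.states
        truths[rec.id] = [h.to_dict() for h in truth.hits]
        groups[rec.id] = label

    for i, c in enumerate([4] * 28 + [3] * 12):
        rec, truth = family_member("scs3fam", i, c, with_kkxx=(i < 4), seed=SEED)
        records.append(rec)
        topologies[rec.id] = truth.states
        truths[rec.id] = [h.to_dict() for h in truth.hits]
        groups[rec.id] = "scs3_like"
    for i, c in enumerate([2] * 31 + [1] * 21):
        rec, truth = family_member("yft2fam", i, c, with_kkxx=False, seed=SEED + 1000)
        records.append(rec)
        topologies[rec.id] = truth.states
        truths[rec.id] = [h.to_dict() for h in truth.hits]
        groups[rec.id] = "yft2_like"

    seqio.write_fasta(records, OUT / "cohort.fasta")
    seqio.write_topology_annotation(topologies, OUT / "cohort.topo.tsv")
    (OUT / "cohort.truth.json").write_text(json.dumps(truths, indent=1) + "\n")
    (OUT / "groups.tsv").write_text("".join(f"{k}\t{v}\n" for k, v in groups.items()))

    print(f"wrote {len(records)} proteins "
          f"({sum(1 for g in groups.values() if g == 'scs3_like')} Scs3p-like family, "
          f"{sum(1 for g in groups.values() if g == 'yft2_like')} Yft2p-like family, "
          f"2 stand-ins) to {OUT}")


if __name__ == "__main__":
    main()
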