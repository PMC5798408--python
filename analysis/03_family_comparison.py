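#!/usr/bin/env python
"""Family-level motif statistics and the Scs3p-like vs Yft2p-like contrast.

Aggregates the per-protein profiles from step 02 into per-family descriptive
statistics (mean and SD of the di-arginine count, members with a C-terminal
retrieval signal or [K]xNØØN) in the high-throughput mode (whole-sequence
counts, no topology link), then contrasts the two synthetic paralogue
families. Run 01 and 02 first.
"""

from pathlib import Path

from fitmscan import profiles, seqio
from fitmscan.profiles import RetentionProfile

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    profs = [RetentionProfile.from_dict(d) for d in seqio.read_report_json(BASE / "profiles.json")]
    table = seqio.read_group_table(BASE / "cohort" / "groups.tsv")
    by_id = {p.id: p for p in profs}

    stats = {}
    for label in ("scs3_like", "yft2_like"):
        members = [by_id[pid] for pid in table.members(label)]
        stats[label] = profiles.aggregate_family(members, "total", label=label)

    out = BASE / "family_stats.tsv"
    with open(out, "w") as fh:
        fh.write("label\tn\tmean_diarg\tsd_diarg\tn_cterm\tn_kxn\n")
        for st in stats.values():
            fh.write(
                f"{st.label}\t{st.n}\t{st.mean_diarg:.3f}\t{st.sd_diarg:.3f}"
                f"\t{st.n_cterm}\t{st.n_kxn}\n"
            )

    cmp = profiles.compare_groups(stats["scs3_like"], stats["yft2_like"])
    with open(BASE / "family_comparison.tsv", "w") as fh:
        fh.write("a\tb\tmean_diff\tcterm_frac_a\tcterm_frac_b\tmore_er_like\n")
        fh.write(
            f"{cmp.label_a}\t{cmp.label_b}\t{cmp.mean_diff:.3f}"
            f"\t{cmp.cterm_fraction_a:.3f}\t{cmp.cterm_fraction_b:.3f}\t{cmp.more_er_like}\n"
        )

    for st in stats.values():
        print(
            f"{st.label}: n={st.n}, mean di-arginine={st.mean_diarg:.2f} "
            f"(SD {st.sd_diarg:.2f}), C-terminal signal {st.n_cterm}/{st.n}"
        )
    print(
        f"verdict: {cmp.more_er_like} is more ER-like "
        f"(mean difference {cmp.mean_diff:.2f} di-arginine motifs)"
    )
    print(f"wrote {out} and {BASE/'family_comparison.tsv'}")


if __name__ == "__main__":
    main()
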