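"""Global repertoire metrics: VJ usage, PCA, summary statistics, persistence.

Shows that VJ gene usage is highly correlated between replicates and across
visits within a participant but separates participants in a PCA of usage
vectors; tabulates mean CDR3 length, mutation load and subclass mix per
sample; and tracks how many visits each of the highly sampled participant's
clusters is detected at.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, ensure_dirs, get_cohort

from bcrep.clustering import cluster_repertoire
from bcrep.metrics import (
    persistence,
    summary_metrics,
    usage_correlation,
    vj_pca,
    vj_usage,
)


def main() -> None:
    ensure_dirs()
    cohort = get_cohort()

    # replicate vs cross-participant usage correlation (IgG)
    day0 = {
        s.replicate: s
        for s in cohort.select(participant="P01", isotype="IgG", day=0)
    }
    r_pcr = usage_correlation(vj_usage(day0["pcr1"]), vj_usage(day0["pcr2"]))
    r_bio = usage_correlation(vj_usage(day0["bio1"]), vj_usage(day0["bio2"]))
    others = [cohort.select(participant=p, isotype="IgG")[0] for p in ("P02", "P03")]
    r_between = usage_correlation(vj_usage(day0["bio1"]), vj_usage(others[0]))
    print(f"VJ usage Pearson r: PCR replicates {r_pcr:.4f}, "
          f"biological replicates {r_bio:.4f}, between participants {r_between:.4f}")

    # PCA over one IgG usage vector per participant (+ all P01 visits)
    usages, labels, participants = [], [], []
    for p in cohort.participants:
        if p == "P01":
            for day in sorted({s.day for s in cohort.select(participant=p, isotype="IgG")}):
                s = cohort.select(participant=p, isotype="IgG", day=day, replicate="bio1")[0]
                usages.append(vj_usage(s)); labels.append(s.label); participants.append(p)
        else:
            s = cohort.select(participant=p, isotype="IgG")[0]
            usages.append(vj_usage(s)); labels.append(s.label); participants.append(p)
    coords, explained = vj_pca(usages, labels)
    coords["participant"] = participants
    coords.to_csv(RESULTS / "vj_pca.tsv", sep="\t")
    xy = coords[["PC1", "PC2"]].to_numpy()
    p01_idx = [i for i, p in enumerate(participants) if p == "P01"]
    within = np.mean([
        np.linalg.norm(xy[i] - xy[j]) for i in p01_idx for j in p01_idx if i < j
    ])
    between = np.mean([
        np.linalg.norm(xy[i] - xy[j])
        for i in p01_idx for j in range(len(xy)) if participants[j] != "P01"
    ])
    print(f"PCA: first two components explain {explained.sum() * 100:.0f}% of "
          f"VJ usage variance; P01's five visits sit {within:.3f} apart vs "
          f"{between:.3f} from other participants")

    rows = []
    for s in cohort.samples:
        m = summary_metrics(s)
        rows.append(
            {"participant": s.participant, "day": s.day, "isotype": s.isotype,
             "replicate": s.replicate,
             "mean_cdr3_length": round(m.mean_cdr3_length, 2),
             "mean_v_mutations": round(m.mean_v_mutations, 2),
             **{f"pct_{k}": round(v * 100, 1) for k, v in m.subclass_proportions.items()}}
        )
    pd.DataFrame(rows).to_csv(RESULTS / "summary_metrics.tsv", sep="\t", index=False)

    # persistence of clusters across P01's visits
    pers_rows = []
    for iso in ("IgA", "IgG", "IgM"):
        samples = cohort.select(participant="P01", isotype=iso)
        cs = cluster_repertoire(samples, k=12)
        table = persistence(cs, samples)
        total = sum(table.summary.values())
        multi = sum(n for t, n in table.summary.items() if t > 1)
        print(f"{iso}: {multi / total * 100:.0f}% of {total} clusters detected "
              f"on more than one visit")
        for t, n in sorted(table.summary.items()):
            pers_rows.append({"isotype": iso, "n_timepoints": t, "n_clusters": n})
    pd.DataFrame(pers_rows).to_csv(RESULTS / "persistence.tsv", sep="\t", index=False)
    print("wrote results/vj_pca.tsv, summary_metrics.tsv, persistence.tsv")


if __name__ == "__main__":
    main()
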