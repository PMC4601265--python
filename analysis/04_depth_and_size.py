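"""Sequencing and sampling depth: rarefaction, Chao, capture-recapture.

Rarefies each isotype's day-0 sample from the highly sampled participant,
extrapolates cluster richness with the Chao estimator, and reports the
depth needed to capture 90% of clusters.  Builds a capture-recapture table
from the IgG biological replicate pairs (Chapman estimates of effective
repertoire size per visit, percent sampled, day-to-day fluctuation ratios)
and quantifies replicate overlap for PCR vs biological pairs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, ensure_dirs, get_cohort

from bcrep.clustering import classify_abundance, cluster_repertoire
from bcrep.depth import (
    chapman,
    depth_for_fraction,
    extrapolate,
    overlap_min,
    percent_sampled,
    rarefy,
)


def rarefaction(cohort) -> None:
    rows = []
    for iso in ("IgA", "IgG", "IgM"):
        sample = cohort.select(isotype=iso, participant="P01", day=0)[0]
        cs = cluster_repertoire(sample, k=12)
        labels = [cs.assignments[(sample.key, r.id)] for r in sample.records]
        curve = extrapolate(
            rarefy(labels, step=250, repeats=10, seed=cohort.seed + 5),
            target_depth=50_000, step=500,
        )
        need90 = depth_for_fraction(curve, 0.9)
        rows.append(
            {"isotype": iso, "depth": len(labels), "observed_clusters": curve.s_obs,
             "chao_estimate": round(curve.chao_estimate, 1),
             "pct_captured": round(curve.s_obs / curve.chao_estimate * 100, 1),
             "depth_for_90pct": need90}
        )
        print(f"{iso}: {curve.s_obs} clusters observed, Chao estimate "
              f"{curve.chao_estimate:.0f}; 90% capture needs ~{need90:.0f} reads")
    pd.DataFrame(rows).to_csv(RESULTS / "rarefaction.tsv", sep="\t", index=False)


def capture_recapture(cohort) -> None:
    rows = []
    for day in sorted({s.day for s in cohort.select(participant="P01", isotype="IgG")}):
        s1 = cohort.select(participant="P01", isotype="IgG", day=day, replicate="bio1")[0]
        s2 = cohort.select(participant="P01", isotype="IgG", day=day, replicate="bio2")[0]
        cs = cluster_repertoire([s1, s2], k=12)
        ids1, ids2 = cs.ids_for(s1.key), cs.ids_for(s2.key)
        ab1 = {c for c in ids1 if classify_abundance(cs.by_id(c), s1.key) == "abundant"}
        ab2 = {c for c in ids2 if classify_abundance(cs.by_id(c), s2.key) == "abundant"}
        total_est = chapman(len(ids1), len(ids2), len(ids1 & ids2))
        ab_est = chapman(len(ab1), len(ab2), len(ab1 & ab2))
        rows.append(
            {"day": day, "total_clusters": len(ids1), "abundant_clusters": len(ab1),
             "total_size_estimate": round(total_est, 0),
             "abundant_size_estimate": round(ab_est, 0),
             "total_pct_sampled": percent_sampled(len(ids1), total_est),
             "abundant_pct_sampled": percent_sampled(len(ab1), ab_est)}
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "capture_recapture.tsv", sep="\t", index=False)
    ratio_total = table["total_size_estimate"].max() / table["total_size_estimate"].min()
    ratio_ab = table["abundant_size_estimate"].max() / table["abundant_size_estimate"].min()
    print("capture-recapture (IgG biological replicates):")
    print(table.to_string(index=False))
    print(f"size-estimate fluctuation across days: {ratio_total:.1f}x total, "
          f"{ratio_ab:.1f}x abundant")


def replicate_overlap(cohort) -> None:
    rows = []
    for day in sorted({s.day for s in cohort.select(participant="P01", isotype="IgG")}):
        for design, rep_labels in (("pcr", ("pcr1", "pcr2")), ("biological", ("bio1", "bio2"))):
            pair = [
                cohort.select(participant="P01", isotype="IgG", day=day, replicate=r)[0]
                for r in rep_labels
            ]
            cs = cluster_repertoire(pair, k=12)
            ids = [cs.ids_for(s.key) for s in pair]
            abundant = [
                {c for c in sample_ids if classify_abundance(cs.by_id(c), s.key) == "abundant"}
                for sample_ids, s in zip(ids, pair)
            ]
            rows.append(
                {"day": day, "design": design,
                 "total_overlap_pct": round(overlap_min(*ids), 1),
                 "abundant_overlap_pct": round(overlap_min(*abundant), 1)}
            )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "replicate_overlap.tsv", sep="\t", index=False)
    means = table.groupby("design")[["total_overlap_pct", "abundant_overlap_pct"]].mean()
    print("mean replicate overlap (% of smaller replicate's clusters):")
    print(means.round(1).to_string())


def main() -> None:
    ensure_dirs()
    cohort = get_cohort()
    rarefaction(cohort)
    capture_recapture(cohort)
    replicate_overlap(cohort)
    print("wrote results/rarefaction.tsv, capture_recapture.tsv, replicate_overlap.tsv")


if __name__ == "__main__":
    main()
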