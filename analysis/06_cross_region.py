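#!/usr/bin/env python
"""Cross-region correlations of cluster-mean representation values across
subjects, between the recovered fusiform clusters.

Found: with a shared per-subject responsiveness factor in the generator,
cluster-mean logo-grapheme representations correlate positively across
subjects between the left and right middle fusiform (and between left middle
and anterior fusiform), echoing the between-region coupling analysis."""

import json

import pandas as pd

from analysis_common import ensure_results, load_or_run_cohort

from votrsa import cluster_mean_representation, cross_region_correlation
from votrsa import pipeline as pl
from votrsa import synthetic as syn


PAIRS = [
    ("logo L-mid vs R-mid", ("logo_grapheme", "RW"), "L_mid_FG", ("logo_grapheme", "RW"), "R_mid_FG"),
    ("logo L-ant vs R-mid", ("logo_grapheme", "RW"), "L_ant_FG", ("logo_grapheme", "RW"), "R_mid_FG"),
    ("logo L-mid vs L-ant", ("logo_grapheme", "RW"), "L_mid_FG", ("logo_grapheme", "RW"), "L_ant_FG"),
    ("logo L-ant vs semantic L-ant", ("logo_grapheme", "RW"), "L_ant_FG", ("semantic", "RW"), "L_ant_FG"),
]


def main():
    results = ensure_results()
    cohort = load_or_run_cohort()
    rsa = pl.group_rsa(cohort)
    rows = []
    for name, key_a, lab_a, key_b, lab_b in PAIRS:
        res_a, res_b = rsa[key_a], rsa[key_b]
        _, ca = pl.best_cluster_dice(res_a["clusters"], cohort.anatomy.mask(syn.LABELS[lab_a]))
        _, cb = pl.best_cluster_dice(res_b["clusters"], cohort.anatomy.mask(syn.LABELS[lab_b]))
        if not (ca and cb):
            continue
        va = cluster_mean_representation(res_a["maps"], res_a["clusters"].cluster_mask(ca))
        vb = cluster_mean_representation(res_b["maps"], res_b["clusters"].cluster_mask(cb))
        rho, p = cross_region_correlation(va, vb)
        rows.append({"pair": name, "rho": rho, "p": p, "n_subjects": len(va)})
    df = pd.DataFrame(rows)
    df.to_csv(results / "cross_region_correlations.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    (results / "cross_region_correlations.json").write_text(
        json.dumps(rows, indent=2)
    )


if __name__ == "__main__":
    main()
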