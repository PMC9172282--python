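#!/usr/bin/env python
"""Group activation analysis on the demonstration cohort: one-sample t over
subject contrast effects, BH-FDR (q<.05) voxel threshold, strict cluster
extent (> 10), and the posterior-to-anterior gradient profile in the left
fusiform.

Found: each condition-selective mean shift surfaces as a cluster in its
planted subregion, and the gradient peaks of the radical, abstract-
orthography and lexical contrasts are ordered posterior < middle < anterior
along y — the functional-gradient signature."""

import json

from analysis_common import ensure_results, load_or_run_cohort

from votrsa import pipeline as pl
from votrsa.group import gradient_profile
from votrsa import synthetic as syn


def main():
    results = ensure_results()
    cohort = load_or_run_cohort()
    activation = pl.group_activation(cohort)
    for name, res in activation.items():
        res["clusters"].to_tsv(results / f"activation_{name}_clusters.tsv")
    mask = cohort.anatomy.mask(syn.LEFT_FG_LABELS)
    for name in ("radical", "abstract_orthography", "lexical"):
        prof = gradient_profile(
            activation[name]["t"].data, mask, cohort.anatomy.affine, n_bins=9
        )
        prof.to_csv(results / f"gradient_{name}.tsv", sep="\t", index=False)
    peaks = pl.gradient_peak_positions(activation, cohort.anatomy)
    summary = {
        "gradient_peaks_mm": peaks,
        "ordered_posterior_to_anterior":
            peaks["radical"] < peaks["abstract_orthography"] < peaks["lexical"],
        "clusters_per_contrast": {k: len(v["clusters"]) for k, v in activation.items()},
    }
    (results / "group_activation_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
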