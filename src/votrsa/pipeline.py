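"""End-to-end orchestration of the published analysis order on a cohort.

Per subject: condition-level GLM (five activation contrasts) and trial-wise
GLM (120-trial least-squares-all design), then searchlight maps of the
logo-grapheme model (RW, PW, FW) and the semantic model (RW) inside the ROI.
Group level: one-sample t maps, FDR + cluster-extent for activation,
uncorrected p + cluster-extent for RSA, gradient profiles along y, and
cross-region correlations of cluster-mean representation values.

The same machinery runs the validation path (error-trial and low-accuracy
subject exclusion) so both analyses can be compared on one cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    CONTRAST_PRESETS,
    build_design_matrix,
    compute_contrast,
    fit_glm,
    preset_contrast,
)
from .group import (
    extract_clusters,
    fdr_threshold,
    gradient_profile,
    group_onesample_t,
)
from .images import LabelVolume, StatMap
from .rdm import RDM
from .searchlight import (
    RepresentationMap,
    SearchlightSpec,
    TrialBetaSeries,
    dice_overlap,
    group_rsa_inference,
    searchlight_representation_map,
)
from .stimuli import (
    LOGO_CONDITIONS,
    EmbeddingTable,
    StimulusSet,
    build_logo_grapheme_rdm,
    build_semantic_rdm,
)
from .synthetic import (
    LABELS,
    LEFT_FG_LABELS,
    ROI_LABELS,
    PlantConfig,
    default_plant_config,
    generate_events,
    generate_stimulus_set,
    make_phantom_anatomy,
    simulate_subject_bold,
)

#: the four searchlight analyses: (model kind, condition)
RSA_KEYS = (
    ("logo_grapheme", "RW"),
    ("logo_grapheme", "PW"),
    ("logo_grapheme", "FW"),
    ("semantic", "RW"),
)


def build_model_rdms(
    stimuli: StimulusSet, emb: EmbeddingTable, convention: str = "dice"
) -> dict[tuple[str, str], RDM]:
    """The four theoretical RDMs keyed by (model kind, condition)."""
    models = {
        ("logo_grapheme", c): build_logo_grapheme_rdm(stimuli.for_condition(c), convention)
        for c in LOGO_CONDITIONS
    }
    models[("semantic", "RW")] = build_semantic_rdm(stimuli.for_condition("RW"), emb)
    return models


@dataclass
class CohortData:
    """Everything the group level needs, accumulated over the subject loop."""

    anatomy: LabelVolume
    stimuli: StimulusSet
    emb: EmbeddingTable
    models: dict
    roi_mask: np.ndarray
    rsa_maps: dict = field(default_factory=dict)  # key -> [RepresentationMap]
    rsa_maps_valid: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)  # contrast -> [3D effect map]
    behavior: list = field(default_factory=list)
    events: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)


def subject_first_level(run, events, motion, brain_mask, drift_cutoff: float = 128.0):
    """Both first-level fits for one subject: condition-wise and trial-wise."""
    n_scans = run.n_scans
    Xc = build_design_matrix(
        events, n_scans, run.tr, motion, "per_condition", drift_cutoff
    )
    betas_cond = fit_glm(run, Xc, brain_mask)
    Xt = build_design_matrix(events, n_scans, run.tr, motion, "per_trial", drift_cutoff)
    betas_trial = fit_glm(run, Xt, brain_mask)
    return betas_cond, betas_trial


def subject_rsa_maps(
    betas_trial,
    models: dict,
    spec: SearchlightSpec,
    roi_mask: np.ndarray,
    accurate_only: bool = False,
) -> dict[tuple[str, str], RepresentationMap]:
    """Searchlight representation maps for the four model/condition analyses.

    With ``accurate_only`` the trial set is restricted to correct responses,
    and the model RDM is subset to the same stimuli so pair alignment is
    preserved (the validation path)."""
    out = {}
    for kind, cond in RSA_KEYS:
        model = models[(kind, cond)]
        series = TrialBetaSeries.from_beta_image(betas_trial, cond, order=model.labels)
        if accurate_only:
            keep = [s for s, a in zip(series.stim_ids, series.accuracy) if a == 1]
            series = series.subset(keep)
            model = model.subset(keep)
        out[(kind, cond)] = searchlight_representation_map(series, model, spec, roi_mask)
    return out


def simulate_and_analyze_cohort(
    seed: int,
    n_subjects: int = 20,
    grid: str = "small",
    plants: PlantConfig | None = None,
    spec: SearchlightSpec | None = None,
    drift_cutoff: float = 128.0,
    validation: bool = False,
    exclusion_acc_condition: str = "PW",
    exclusion_acc_threshold: float = 0.5,
) -> CohortData:
    """Simulate a cohort and run every subject through both first-level paths.

    ``validation=True`` additionally computes the error-trial-excluded RSA
    maps and applies the low-accuracy subject exclusion to that path.
    """
    plants = default_plant_config() if plants is None else plants
    spec = SearchlightSpec() if spec is None else spec
    anatomy = make_phantom_anatomy(grid)
    stimuli, emb = generate_stimulus_set(seed)
    models = build_model_rdms(stimuli, emb)
    roi_mask = anatomy.mask(ROI_LABELS)
    brain = anatomy.brain_mask

    cohort = CohortData(anatomy, stimuli, emb, models, roi_mask)
    for i in range(n_subjects):
        events = generate_events(seed, stimuli, subject=i)
        sub = simulate_subject_bold(seed, i, anatomy, events, stimuli, emb, plants)
        betas_cond, betas_trial = subject_first_level(
            sub.run, events, sub.motion, brain, drift_cutoff
        )
        for name in CONTRAST_PRESETS:
            eff = compute_contrast(betas_cond, preset_contrast(name), output="effect")
            cohort.effects.setdefault(name, []).append(eff.data)
        for key, m in subject_rsa_maps(betas_trial, models, spec, roi_mask).items():
            cohort.rsa_maps.setdefault(key, []).append(m)
        acc = events.accuracy_by_condition()
        if validation:
            if acc[exclusion_acc_condition] < exclusion_acc_threshold:
                cohort.excluded_subjects.append(sub.subject)
            else:
                maps_v = subject_rsa_maps(
                    betas_trial, models, spec, roi_mask, accurate_only=True
                )
                for key, m in maps_v.items():
                    cohort.rsa_maps_valid.setdefault(key, []).append(m)
        cohort.events[sub.subject] = events
        rt = events.frame.groupby("trial_type", observed=True).rt.mean()
        for cond in acc.index:
            cohort.behavior.append(
                {"subject": sub.subject, "condition": cond,
                 "acc": float(acc[cond]), "rt": float(rt[cond])}
            )
    return cohort


def group_rsa(
    cohort: CohortData,
    valid: bool = False,
    p_threshold: float = 0.05,
    min_cluster_size: int = 10,
    connectivity: int = 18,
) -> dict:
    """Group RSA inference for each of the four analyses."""
    source = cohort.rsa_maps_valid if valid else cohort.rsa_maps
    out = {}
    for key, maps in source.items():
        t, p, clusters = group_rsa_inference(
            maps, cohort.roi_mask, p_threshold, min_cluster_size, connectivity
        )
        out[key] = {"t": t, "p": p, "clusters": clusters, "maps": maps}
    return out


def group_activation(
    cohort: CohortData,
    q_fdr: float = 0.05,
    min_cluster_size: int = 10,
    connectivity: int = 18,
) -> dict:
    """Group activation maps: one-sample t over subject contrast effects,
    BH-FDR voxel threshold, then the strict cluster-extent rule."""
    brain = cohort.anatomy.brain_mask
    out = {}
    for name, effect_maps in cohort.effects.items():
        t, p, df = group_onesample_t(effect_maps, brain, tail="two")
        survivors, crit = fdr_threshold(np.nan_to_num(p, nan=1.0), brain, q_fdr)
        clusters = extract_clusters(
            survivors, t, cohort.anatomy.affine, min_cluster_size, connectivity
        )
        out[name] = {
            "t": StatMap(t, cohort.anatomy.affine, "t", df),
            "p": p,
            "critical_p": crit,
            "clusters": clusters,
        }
    return out


def best_cluster_dice(clusters, truth_mask: np.ndarray) -> tuple[float, int]:
    """Dice of the cluster best overlapping a truth mask (0 when none)."""
    best, best_id = 0.0, 0
    for cid in clusters.frame.cluster_id:
        d = dice_overlap(clusters.cluster_mask(cid), truth_mask)
        if d > best:
            best, best_id = d, int(cid)
    return best, best_id


def fg_labels_with_cluster(
    clusters, anatomy: LabelVolume, fg_labels, coverage: float = 0.5
) -> set[str]:
    """Fusiform subregion labels expressing an effect.

    A subregion counts as expressing the effect when surviving clusters cover
    more than ``coverage`` of its voxels (default: majority coverage).  The
    voxelwise threshold is deliberately liberal (p < .05 uncorrected), so
    small chance blobs occur; a region-level representational code engages the
    bulk of the region, which fractional coverage captures and isolated blobs
    do not.
    """
    inv = {v: k for k, v in anatomy.label_names.items()}
    hit = set()
    occupied = clusters.label_volume > 0
    for lab in fg_labels:
        region = anatomy.mask(lab)
        if np.logical_and(occupied, region).sum() > coverage * region.sum():
            hit.add(inv.get(lab, str(lab)))
    return hit


def gradient_peak_positions(
    activation: dict,
    anatomy: LabelVolume,
    contrasts=("radical", "abstract_orthography", "lexical"),
    n_bins: int = 9,
) -> dict[str, float]:
    """Peak-bin y position (mm) of each contrast's group-t profile along the
    left fusiform posterior-to-anterior axis."""
    mask = anatomy.mask(LEFT_FG_LABELS)
    out = {}
    for name in contrasts:
        prof = gradient_profile(
            activation[name]["t"].data, mask, anatomy.affine, axis=1, n_bins=n_bins
        )
        out[name] = float(prof.bin_center_mm[prof["mean"].idxmax()])
    return out


def recovery_metrics(cohort: CohortData, rsa: dict, activation: dict) -> dict:
    """Headline phantom-recovery summary.

    Dice of the recovered logo-grapheme cluster (PW map) against the planted
    left middle fusiform label and of the semantic cluster (RW map) against
    the planted left anterior fusiform label; the fusiform dissociation
    pattern; and the posterior<middle<anterior ordering of the three
    activation-contrast gradient peaks.
    """
    anatomy = cohort.anatomy
    all_fg = [LABELS[k] for k in (
        "L_post_FG", "L_mid_FG", "L_ant_FG", "R_post_FG", "R_mid_FG", "R_ant_FG")]

    dice_logo, _ = best_cluster_dice(
        rsa[("logo_grapheme", "PW")]["clusters"], anatomy.mask(LABELS["L_mid_FG"])
    )
    dice_sem, _ = best_cluster_dice(
        rsa[("semantic", "RW")]["clusters"], anatomy.mask(LABELS["L_ant_FG"])
    )
    pw_fg = fg_labels_with_cluster(rsa[("logo_grapheme", "PW")]["clusters"], anatomy, all_fg)
    rw_fg = fg_labels_with_cluster(rsa[("logo_grapheme", "RW")]["clusters"], anatomy, all_fg)
    peaks = gradient_peak_positions(activation, anatomy)
    return {
        "dice_logo_middle_fg": dice_logo,
        "dice_semantic_anterior_fg": dice_sem,
        "pw_logo_fg_labels": sorted(pw_fg),
        "rw_logo_fg_labels": sorted(rw_fg),
        "pw_logo_only_middle": pw_fg == {"L_mid_FG"},
        "rw_logo_in_mid_and_ant": {"L_mid_FG", "L_ant_FG"} <= rw_fg,
        "gradient_peaks_mm": peaks,
        "gradient_ordered": peaks["radical"] < peaks["abstract_orthography"] < peaks["lexical"],
    }
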