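"""Synthetic cohorts: stimulus rosters, embeddings, phantom anatomy, and 4D
BOLD runs with planted representational geometry.

The generator emulates the study conditions of the experiment it tests: four
character-likeness conditions x 40 trials, 600-ms stimuli with 4-6 s jittered
ISI, TR = 720 ms, and multivoxel patterns in designated fusiform/occipital
subregions that linearly encode logo-grapheme and semantic feature structure.
The phantom anatomy places a posterior/middle/anterior fusiform triplet plus an
inferior occipital region in each hemisphere along the y (posterior-anterior)
axis; pattern plants mirror the dissociation under study (logo-grapheme
structure in the middle fusiform, semantic structure in the anterior fusiform),
and condition-mean shifts create the univariate activation gradient.

All randomness flows from a single master seed through named substreams
(roster, events, patterns, noise, behavior) so stages can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve, lfilter

from .errors import ConfigurationError
from .glm import EventTable, canonical_hrf
from .images import BOLDRun, LabelVolume
from .searchlight import TrialBetaSeries
from .stimuli import CONDITIONS, LOGO_CONDITIONS, EmbeddingTable, Stimulus, StimulusSet

# named substreams off the master seed
_STREAMS = {"roster": 0, "events": 1, "patterns": 2, "noise": 3, "behavior": 4}

# default experimental constants (the study conditions)
TR_S = 0.72
STIM_DURATION_S = 0.6
ISI_RANGE_S = (4.0, 6.0)
N_PER_CONDITION = 40
EMBEDDING_DIM = 300

# behavioral generator defaults: condition means (and across-subject SDs)
# ordered so PW accuracy is lowest and PW RT highest
ACC_MEANS = {"RW": 0.95, "PW": 0.80, "FW": 0.96, "SC": 0.98}
ACC_SDS = {"RW": 0.07, "PW": 0.20, "FW": 0.06, "SC": 0.05}
RT_MEANS_MS = {"RW": 794.0, "PW": 939.0, "FW": 780.0, "SC": 729.0}
RT_TRIAL_SD_MS = 150.0
RT_SUBJECT_SD_MS = 100.0
# subject x condition interaction: individual condition effects vary, keeping
# the repeated-measures F at a realistic magnitude
RT_COND_SUBJECT_SD_MS = 120.0

# phantom label numbering
LABELS = {
    "background": 1,
    "L_post_FG": 11,
    "L_mid_FG": 12,
    "L_ant_FG": 13,
    "R_post_FG": 21,
    "R_mid_FG": 22,
    "R_ant_FG": 23,
    "L_IOG": 31,
    "R_IOG": 32,
}
ROI_LABELS = (11, 12, 13, 21, 22, 23, 31, 32)
LEFT_FG_LABELS = (11, 12, 13)

GRID_PROFILES = {"default": (40, 48, 38), "small": (26, 44, 22)}


def rng_stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, hierarchical substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], *extra))
    )


def make_phantom_anatomy(
    grid: str | tuple[int, int, int] = "default",
    voxel_mm: float = 2.0,
    box: tuple[int, int, int] = (6, 6, 5),
    gap: int = 4,
) -> LabelVolume:
    """Integer-labelled phantom anatomy.

    Four region boxes per hemisphere (inferior occipital, then posterior,
    middle, anterior fusiform) are laid out along ascending y, mirror-symmetric
    across the x midline, inside a background "brain" slab.  The affine is
    diagonal ``voxel_mm`` with the grid centered on the origin, so y mm
    increases posterior to anterior.
    """
    shape = GRID_PROFILES[grid] if isinstance(grid, str) else tuple(grid)
    nx, ny, nz = shape
    bx, by, bz = box
    span_y = 4 * by + 3 * gap
    if span_y + 4 > ny or bx * 2 + 4 > nx or bz + 4 > nz:
        raise ConfigurationError(f"grid {shape} too small for box {box} / gap {gap}")
    lx0 = max(2, round(nx * 0.16))
    y0 = (ny - span_y) // 2
    z0 = (nz - bz) // 2

    data = np.zeros(shape, dtype=np.int32)
    y_order = ["IOG", "post_FG", "mid_FG", "ant_FG"]
    for idx, region in enumerate(y_order):
        ys = y0 + idx * (by + gap)
        left = LABELS[f"L_{region}"]
        right = LABELS[f"R_{region}"]
        data[lx0 : lx0 + bx, ys : ys + by, z0 : z0 + bz] = left
        data[nx - lx0 - bx : nx - lx0, ys : ys + by, z0 : z0 + bz] = right
    # background brain slab with a margin around the labelled regions
    m = 3
    brain = np.zeros(shape, dtype=bool)
    brain[
        max(0, lx0 - m) : min(nx, nx - lx0 + m),
        max(0, y0 - m) : min(ny, y0 + span_y + m),
        max(0, z0 - m) : min(nz, z0 + bz + m),
    ] = True
    data[brain & (data == 0)] = LABELS["background"]

    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return LabelVolume(data, affine, dict(LABELS))


def generate_stimulus_set(
    seed: int,
    n_per_condition: int = N_PER_CONDITION,
    token_pool_size: int = 12,
    embedding_dim: int = EMBEDDING_DIM,
    embedding_latent_dim: int = 8,
) -> tuple[StimulusSet, EmbeddingTable]:
    """Roster of 4 x ``n_per_condition`` stimuli plus RW embeddings.

    RW/PW/FW items are distinct 2-token logo-grapheme sets drawn from a shared
    token pool, so pairwise overlap varies over {0, 1, 2} shared tokens.  SC
    items have empty sets.  Stroke counts, pixel fractions and (donor)
    frequencies are the same shuffled multiset in every condition, so the
    matching report passes by construction.  RW embeddings carry a low-rank
    latent structure plus isotropic noise, then unit normalization, giving the
    semantic RDM realistic spread.
    """
    rng = rng_stream(seed, "roster")
    pairs = list(itertools.combinations(range(token_pool_size), 2))
    if len(pairs) < n_per_condition:
        raise ConfigurationError(
            f"token pool of {token_pool_size} yields only {len(pairs)} distinct "
            f"2-token sets; need {n_per_condition}"
        )
    strokes = rng.integers(6, 15, size=n_per_condition)
    pixfrac = rng.uniform(0.25, 0.45, size=n_per_condition)
    freq = np.exp(rng.normal(3.0, 1.0, size=n_per_condition))

    stimuli: list[Stimulus] = []
    for cond in CONDITIONS:
        order = rng.permutation(n_per_condition)
        if cond in LOGO_CONDITIONS:
            chosen = rng.choice(len(pairs), size=n_per_condition, replace=False)
            sets = [frozenset(f"u{t:02d}" for t in pairs[c]) for c in chosen]
        else:
            sets = [frozenset()] * n_per_condition
        for i in range(n_per_condition):
            stimuli.append(
                Stimulus(
                    id=f"{cond}{i:02d}",
                    condition=cond,
                    logo_graphemes=sets[i],
                    stroke_count=int(strokes[order[i]]),
                    pixel_fraction=float(pixfrac[order[i]]),
                    frequency=float(freq[order[i]]) if cond != "SC" else float("nan"),
                )
            )
    stimset = StimulusSet(stimuli)

    loadings = rng.normal(size=(embedding_latent_dim, embedding_dim))
    vecs = {}
    for s in stimset.for_condition("RW"):
        latent = rng.normal(size=embedding_latent_dim)
        v = latent @ loadings + 0.5 * np.sqrt(embedding_dim / embedding_latent_dim) * rng.normal(size=embedding_dim)
        vecs[s.id] = v / np.linalg.norm(v)
    return stimset, EmbeddingTable(vecs)


def generate_events(
    seed: int,
    stimuli: StimulusSet,
    subject: int = 0,
    acc_means: dict | None = None,
    acc_sds: dict | None = None,
    start_s: float = 8.0,
    duration_s: float = STIM_DURATION_S,
    isi_range_s: tuple[float, float] = ISI_RANGE_S,
) -> EventTable:
    """One subject's randomized event table.

    Trials present each roster stimulus once in random order, 600-ms duration,
    ISI uniform on [4, 6] s.  Accuracy is Bernoulli with per-condition rates
    drawn once per subject around the configured means (PW lowest); RTs are
    Gaussian around per-condition means with a subject-level shift.
    """
    rng = rng_stream(seed, "events", subject)
    brng = rng_stream(seed, "behavior", subject)
    acc_means = dict(ACC_MEANS if acc_means is None else acc_means)
    acc_sds = dict(ACC_SDS if acc_sds is None else acc_sds)
    subject_acc = {
        c: float(np.clip(brng.normal(acc_means[c], acc_sds[c]), 0.02, 1.0))
        for c in CONDITIONS
    }
    rt_shift = brng.normal(0.0, RT_SUBJECT_SD_MS)
    rt_cond_shift = {c: brng.normal(0.0, RT_COND_SUBJECT_SD_MS) for c in CONDITIONS}

    order = rng.permutation(len(stimuli))
    items = [stimuli.stimuli[i] for i in order]
    onset = start_s
    rows = []
    for s in items:
        acc = int(rng.random() < subject_acc[s.condition])
        rt = max(
            250.0,
            rng.normal(
                RT_MEANS_MS[s.condition] + rt_shift + rt_cond_shift[s.condition],
                RT_TRIAL_SD_MS,
            ),
        )
        rows.append(
            {
                "onset": round(onset, 3),
                "duration": duration_s,
                "trial_type": s.condition,
                "stim_id": s.id,
                "accuracy": acc,
                "rt": round(rt, 1),
            }
        )
        onset += duration_s + rng.uniform(*isi_range_s)
    return EventTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class RegionPlant:
    """Pattern plant: voxels of ``label`` linearly encode ``feature``
    ("logo_grapheme" indicator vectors or "semantic" embedding vectors) for
    trials of the listed conditions, with the given effect amplitude."""

    label: int
    feature: str
    conditions: tuple[str, ...]
    amplitude: float = 2.0

    def __post_init__(self):
        if self.feature not in ("logo_grapheme", "semantic"):
            raise ConfigurationError(f"unknown feature source {self.feature!r}")
        if self.amplitude < 0:
            raise ConfigurationError("plant amplitude must be nonnegative")


@dataclass
class PlantConfig:
    """Generative model for one cohort's planted effects and noise.

    ``plants`` define representational (pattern) structure; ``mean_shifts``
    (label -> condition -> amplitude) define univariate activation effects.
    Noise: per-trial-amplitude Gaussian noise, AR(1) scan noise, slow cosine
    drift, and a multiplicative subject-level amplitude jitter.
    """

    plants: list[RegionPlant] = field(default_factory=list)
    mean_shifts: dict[int, dict[str, float]] = field(default_factory=dict)
    baseline: float = 5.0
    amp_noise_sd: float = 1.0
    ts_noise_sd: float = 1.0
    ar_coef: float = 0.3
    drift_period_s: float = 128.0
    drift_amp: float = 1.0
    subject_amp_jitter: float = 0.2

    def __post_init__(self):
        if self.amp_noise_sd <= 0 or self.ts_noise_sd <= 0:
            raise ConfigurationError("noise SDs must be positive")


def default_plant_config(amplitude: float = 2.0, shift: float = 1.0) -> PlantConfig:
    """The cohort the pipeline is designed to recover.

    Logo-grapheme structure lives in the left middle fusiform for RW and PW
    (abstract orthography), in the left anterior fusiform for RW only (lexical
    orthography, alongside the RW semantic code), in the right middle fusiform
    for RW, and bilaterally in inferior occipital cortex for all three
    character-like conditions (early visual/radical coding).  Condition-mean
    shifts create the posterior-to-anterior univariate gradient: FW-selective
    posterior FG, PW-selective middle FG, RW-selective anterior FG, and
    SC-selective inferior occipital cortex.
    """
    L = LABELS
    plants = [
        RegionPlant(L["L_mid_FG"], "logo_grapheme", ("RW", "PW"), amplitude),
        RegionPlant(L["L_ant_FG"], "logo_grapheme", ("RW",), amplitude),
        RegionPlant(L["L_ant_FG"], "semantic", ("RW",), amplitude),
        RegionPlant(L["R_mid_FG"], "logo_grapheme", ("RW",), amplitude),
        RegionPlant(L["L_IOG"], "logo_grapheme", ("RW", "PW", "FW"), amplitude),
        RegionPlant(L["R_IOG"], "logo_grapheme", ("RW", "PW", "FW"), amplitude),
    ]
    mean_shifts = {
        L["L_post_FG"]: {"FW": shift},
        L["L_mid_FG"]: {"PW": shift},
        L["L_ant_FG"]: {"RW": shift},
        L["L_IOG"]: {"SC": shift},
    }
    return PlantConfig(plants=plants, mean_shifts=mean_shifts)


def null_plant_config() -> PlantConfig:
    """Noise-only cohort: no pattern plants, no mean shifts."""
    return PlantConfig(plants=[], mean_shifts={})


def _feature_matrix(
    feature: str, stim_ids: list[str], stimuli: StimulusSet, emb: EmbeddingTable
) -> np.ndarray:
    """(n_trials, dim) feature vectors for a plant's encoding model."""
    if feature == "semantic":
        return np.stack([emb[s] for s in stim_ids])
    tokens = sorted({t for s in stimuli if s.logo_graphemes for t in s.logo_graphemes})
    tok_idx = {t: i for i, t in enumerate(tokens)}
    F = np.zeros((len(stim_ids), len(tokens)))
    for r, sid in enumerate(stim_ids):
        for t in stimuli.by_id(sid).logo_graphemes:
            F[r, tok_idx[t]] = 1.0
    return F


def trial_amplitudes(
    seed: int,
    subject: int,
    anatomy: LabelVolume,
    trial_conditions: list[str],
    trial_stim_ids: list[str],
    stimuli: StimulusSet,
    emb: EmbeddingTable,
    plants: PlantConfig,
) -> np.ndarray:
    """True per-trial response amplitude for every brain voxel.

    Returns (n_trials, n_brain_voxels) for the voxels of ``anatomy.brain_mask``
    in C order: baseline + condition-mean shifts + planted pattern structure
    (z-scored per voxel within each plant condition, scaled by the plant
    amplitude and the subject's jitter factor) + Gaussian amplitude noise.
    """
    prng = rng_stream(seed, "patterns", subject)
    nrng = rng_stream(seed, "noise", subject, 0)
    brain = anatomy.brain_mask
    flat_label = anatomy.data[brain]
    n_vox = int(brain.sum())
    n_trials = len(trial_conditions)
    conds = np.asarray(trial_conditions)

    A = plants.baseline + nrng.normal(0.0, plants.amp_noise_sd, size=(n_trials, n_vox))
    for label, shifts in plants.mean_shifts.items():
        vox = flat_label == label
        for cond, amp in shifts.items():
            A[np.ix_(conds == cond, vox)] += amp
    # one amplitude factor per subject, shared by all plants: responsive
    # subjects carry stronger codes everywhere, which couples regions across
    # subjects the way between-subject correlations require
    jitter = max(0.1, 1.0 + plants.subject_amp_jitter * prng.normal())
    for plant in plants.plants:
        vox = np.nonzero(flat_label == plant.label)[0]
        if vox.size == 0:
            raise ConfigurationError(f"plant label {plant.label} absent from anatomy")
        for cond in plant.conditions:
            rows = np.nonzero(conds == cond)[0]
            sids = [trial_stim_ids[r] for r in rows]
            F = _feature_matrix(plant.feature, sids, stimuli, emb)
            W = prng.normal(size=(vox.size, F.shape[1]))
            S = F @ W.T  # (n_cond_trials, n_vox_label)
            S = (S - S.mean(axis=0)) / np.maximum(S.std(axis=0), 1e-12)
            A[np.ix_(rows, vox)] += plant.amplitude * jitter * S
    return A


@dataclass
class SubjectData:
    """One simulated subject: run, events, motion, and ground-truth amplitudes."""

    subject: str
    run: BOLDRun
    events: EventTable
    motion: np.ndarray
    true_amplitudes: np.ndarray | None = None


def _event_regressors(onsets, durations, n_scans, tr, oversample=16) -> np.ndarray:
    """(n_scans, n_events) HRF-convolved single-event regressors (fast path:
    one canonical event kernel shifted per onset)."""
    dt = tr / oversample
    n_hi = n_scans * oversample
    hrf = canonical_hrf(dt)
    cols = np.zeros((n_scans, len(onsets)))
    scan_hi = np.arange(n_scans) * oversample
    for e, (onset, dur) in enumerate(zip(onsets, durations)):
        a = int(round(onset / dt))
        b = max(a + 1, int(round((onset + dur) / dt)))
        box = np.ones(b - a)
        resp = fftconvolve(box, hrf)
        idx = scan_hi - a
        ok = (idx >= 0) & (idx < resp.size)
        cols[ok, e] = resp[idx[ok]]
    return cols


def simulate_subject_bold(
    seed: int,
    subject: int,
    anatomy: LabelVolume,
    events: EventTable,
    stimuli: StimulusSet,
    emb: EmbeddingTable,
    plants: PlantConfig,
    tr: float = TR_S,
    tail_s: float = 20.0,
) -> SubjectData:
    """Simulate one subject's preprocessed 4D BOLD run.

    Each trial contributes amplitude x (boxcar * HRF); AR(1) scan noise, a
    slow cosine drift and a constant offset are added.  The motion table is
    small-amplitude smoothed noise (nuisance regressors exercise the GLM; no
    motion corruption is injected).
    """
    nrng = rng_stream(seed, "noise", subject, 1)
    f = events.frame
    n_scans = int(np.ceil((f.onset.iloc[-1] + f.duration.iloc[-1] + tail_s) / tr))
    brain = anatomy.brain_mask
    A = trial_amplitudes(
        seed, subject, anatomy,
        list(f.trial_type), list(f.stim_id.astype(str)), stimuli, emb, plants,
    )
    D = _event_regressors(f.onset.to_numpy(), f.duration.to_numpy(), n_scans, tr)
    series = (D.astype(np.float32) @ A.astype(np.float32))  # (n_scans, n_vox)

    noise = nrng.standard_normal(size=series.shape, dtype=np.float32)
    noise *= plants.ts_noise_sd
    if plants.ar_coef:
        noise = lfilter([1.0], [1.0, -plants.ar_coef], noise, axis=0).astype(np.float32)
    series += noise
    del noise
    t = np.arange(n_scans) * tr
    phase = nrng.uniform(0, 2 * np.pi)
    drift_amp = nrng.normal(0.0, plants.drift_amp, size=series.shape[1])
    series += np.outer(
        np.cos(2 * np.pi * t / plants.drift_period_s + phase), drift_amp
    ).astype(np.float32)
    series += 100.0

    data = np.zeros(anatomy.data.shape + (n_scans,), dtype=np.float32)
    data[brain] = series.T
    motion = gaussian_filter1d(
        nrng.normal(0.0, 0.05, size=(n_scans, 6)), sigma=10.0, axis=0
    )
    run = BOLDRun(data, anatomy.affine.copy(), tr)
    return SubjectData(f"sub-{subject + 1:02d}", run, events, motion, A)


def simulate_trial_betas(
    seed: int,
    subject: int,
    anatomy: LabelVolume,
    stimuli: StimulusSet,
    emb: EmbeddingTable,
    plants: PlantConfig,
    beta_noise_sd: float = 0.0,
) -> dict[str, TrialBetaSeries]:
    """Amplitude-level shortcut: per-condition trial beta volumes drawn
    directly from the generative amplitude model, bypassing BOLD synthesis and
    GLM estimation.  ``beta_noise_sd`` adds independent estimation-noise
    surrogate on top of the amplitude noise.

    Used for large Monte-Carlo runs (e.g. null calibration) where the
    time-series round-trip — whose estimator is validated separately — would
    dominate runtime.
    """
    order = [(s.condition, s.id) for c in LOGO_CONDITIONS for s in stimuli.for_condition(c)]
    conds = [c for c, _ in order]
    sids = [s for _, s in order]
    A = trial_amplitudes(seed, subject, anatomy, conds, sids, stimuli, emb, plants)
    if beta_noise_sd:
        nrng = rng_stream(seed, "noise", subject, 2)
        A = A + nrng.normal(0.0, beta_noise_sd, size=A.shape)
    brain = anatomy.brain_mask
    out = {}
    conds_arr = np.asarray(conds)
    for c in LOGO_CONDITIONS:
        rows = np.nonzero(conds_arr == c)[0]
        vol = np.full(anatomy.data.shape + (rows.size,), np.nan, dtype=np.float32)
        vol[brain] = A[rows].T
        out[c] = TrialBetaSeries(
            data=vol,
            stim_ids=[sids[r] for r in rows],
            condition=c,
            affine=anatomy.affine.copy(),
        )
    return out


def generate_cohort(
    seed: int,
    n_subjects: int,
    outdir,
    grid: str = "default",
    plants: PlantConfig | None = None,
    overwrite: bool = False,
    box: tuple[int, int, int] = (6, 6, 5),
    gap: int = 4,
) -> dict:
    """Write a complete cohort to ``outdir`` in a minimal BIDS-like layout.

    sub-XX/func/ holds the 4D run (NIfTI), events TSV and motion TSV; the
    shared anatomy, stimulus manifest, embeddings and a manifest JSON recording
    every seed and parameter live at the root.
    """
    from . import io as _io

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigurationError(f"{outdir} exists and is not empty (use overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    plants = default_plant_config() if plants is None else plants

    anatomy = make_phantom_anatomy(grid, box=box, gap=gap)
    stimuli, emb = generate_stimulus_set(seed)
    _io.write_label_volume(anatomy, outdir / "anatomy.nii.gz")
    stimuli.to_tsv(outdir / "stimuli.tsv")
    emb.to_tsv(outdir / "embeddings.tsv")

    for i in range(n_subjects):
        events = generate_events(seed, stimuli, subject=i)
        sub = simulate_subject_bold(seed, i, anatomy, events, stimuli, emb, plants)
        func = outdir / sub.subject / "func"
        func.mkdir(parents=True, exist_ok=True)
        _io.write_bold_run(sub.run, func / f"{sub.subject}_task-lexical_bold.nii.gz")
        events.to_tsv(func / f"{sub.subject}_task-lexical_events.tsv")
        np.savetxt(func / f"{sub.subject}_task-lexical_motion.tsv", sub.motion, delimiter="\t")

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "grid": grid,
        "tr_s": TR_S,
        "plants": [asdict(p) for p in plants.plants],
        "mean_shifts": {str(k): v for k, v in plants.mean_shifts.items()},
        "noise": {
            "baseline": plants.baseline,
            "amp_noise_sd": plants.amp_noise_sd,
            "ts_noise_sd": plants.ts_noise_sd,
            "ar_coef": plants.ar_coef,
            "drift_period_s": plants.drift_period_s,
            "drift_amp": plants.drift_amp,
            "subject_amp_jitter": plants.subject_amp_jitter,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
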