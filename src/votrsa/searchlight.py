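"""Searchlight representational similarity analysis.

At every voxel of a cortical ROI, trial-wise beta patterns are read from a
sphere of configurable radius (default 6 mm).  The neural RDM at that center
is one minus the Pearson correlation between every pair of trial patterns;
its rank correlation (Spearman ρ, average ranks for ties) with a theoretical
RDM, Fisher-transformed (z = atanh ρ), is the representation value at that
voxel.  Group inference is a positive one-tailed one-sample t over subjects'
z maps with an uncorrected p threshold and a strict cluster-extent rule.

Spheres at ROI edges use in-mask voxels only; centers whose sphere retains
fewer than the minimum voxel count (default 10) are NaN.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidRDMError, UndefinedCorrelationError
from .glm import BetaImage
from .group import ClusterTable, extract_clusters, group_onesample_t
from .images import StatMap
from .rdm import RDM, tril_indices


@dataclass(frozen=True)
class SearchlightSpec:
    """Searchlight parameters: sphere radius in mm, minimum in-mask voxels
    per sphere, and the atlas labels that define the ROI (default: bilateral
    fusiform 55/56 and inferior occipital 53/54 in AAL3 numbering)."""

    radius_mm: float = 6.0
    min_voxels: int = 10
    roi_labels: tuple[int, ...] = (55, 56, 53, 54)
    rho_clip: float = 0.999999

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ConfigurationError("radius must be positive")


def sphere_offsets(radius_mm: float, voxel_size) -> np.ndarray:
    """All integer voxel offsets whose mm displacement norm is <= radius.

    ``voxel_size`` is a scalar or length-3 sequence of voxel dimensions in mm.
    The center (0,0,0) is always included; a radius smaller than every voxel
    dimension yields a single-voxel sphere with a warning.
    """
    if radius_mm <= 0:
        raise ConfigurationError("radius must be positive")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if np.any(vs <= 0):
        raise ConfigurationError("voxel sizes must be positive")
    lim = np.floor(radius_mm / vs).astype(int)
    ranges = [np.arange(-l, l + 1) for l in lim]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm2 = np.sum((grid * vs) ** 2, axis=1)
    offsets = grid[mm2 <= radius_mm**2 + 1e-9]
    if len(offsets) == 1:
        warnings.warn("radius below voxel size: single-voxel sphere")
    return offsets


@dataclass
class TrialBetaSeries:
    """Trial-wise beta volumes for one condition, in canonical stimulus order.

    ``data`` is (x, y, z, n_trials); ``stim_ids`` give the RDM labels.
    """

    data: np.ndarray
    stim_ids: list[str]
    condition: str
    affine: np.ndarray
    accuracy: np.ndarray | None = None

    def __post_init__(self):
        if self.data.shape[-1] != len(self.stim_ids):
            raise ConfigurationError("trial count does not match stim_ids")

    @property
    def n_trials(self) -> int:
        return len(self.stim_ids)

    @classmethod
    def from_beta_image(
        cls, betas: BetaImage, condition: str, order: list[str] | None = None
    ) -> "TrialBetaSeries":
        """Collect one condition's trial betas from a trial-wise GLM fit,
        reordered to ``order`` (default: stimulus-id sort) so neural and model
        RDMs share label order."""
        if betas.trial_info is None:
            raise ConfigurationError("beta image has no trial-wise columns")
        info = betas.trial_info
        sub = info[info.condition == condition]
        if sub.empty:
            raise ConfigurationError(f"no trials for condition {condition!r}")
        by_id = dict(zip(sub.stim_id.astype(str), sub.column))
        ids = sorted(by_id) if order is None else [s for s in order if s in by_id]
        idx = [betas.column_index(by_id[s]) for s in ids]
        acc = dict(zip(sub.stim_id.astype(str), sub.accuracy))
        return cls(
            data=betas.betas[..., idx],
            stim_ids=list(ids),
            condition=condition,
            affine=betas.affine.copy(),
            accuracy=np.asarray([acc[s] for s in ids], dtype=float),
        )

    def subset(self, keep_ids) -> "TrialBetaSeries":
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.stim_ids) if s in keep]
        return TrialBetaSeries(
            data=self.data[..., idx],
            stim_ids=[self.stim_ids[i] for i in idx],
            condition=self.condition,
            affine=self.affine,
            accuracy=None if self.accuracy is None else self.accuracy[idx],
        )


def _sphere_indices(center, offsets, mask):
    """In-mask voxel indices of the sphere at ``center`` (tuple of arrays)."""
    coords = np.asarray(center)[None, :] + offsets
    ok = np.all((coords >= 0) & (coords < np.asarray(mask.shape)[None, :]), axis=1)
    coords = coords[ok]
    i, j, k = coords[:, 0], coords[:, 1], coords[:, 2]
    inmask = mask[i, j, k]
    return i[inmask], j[inmask], k[inmask]


def _pattern_rdm_values(patterns: np.ndarray) -> np.ndarray:
    """Correlation-distance matrix (1 − Pearson r) between trial patterns.

    ``patterns`` is (n_voxels, n_trials).  Trials with zero pattern variance
    produce NaN cells (missing pairs); the diagonal is forced to zero.
    """
    p = patterns - patterns.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("vt,vt->t", p, p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (p.T @ p) / np.outer(norms, norms)
    d = 1.0 - r
    d[norms == 0, :] = np.nan
    d[:, norms == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0, out=d)  # NaN cells propagate through clip


def neural_rdm_at(
    center,
    series: TrialBetaSeries,
    spec: SearchlightSpec,
    mask: np.ndarray,
    offsets: np.ndarray | None = None,
) -> RDM:
    """Neural RDM at one searchlight center: 1 − Pearson r between every pair
    of trial beta patterns over the sphere's in-mask voxels."""
    if offsets is None:
        vs = np.linalg.norm(series.affine[:3, :3], axis=0)
        offsets = sphere_offsets(spec.radius_mm, vs)
    i, j, k = _sphere_indices(center, offsets, mask)
    if i.size < spec.min_voxels:
        raise ConfigurationError(
            f"sphere at {tuple(center)} has {i.size} in-mask voxels "
            f"(minimum {spec.min_voxels})"
        )
    patterns = series.data[i, j, k, :]
    return RDM(list(series.stim_ids), _pattern_rdm_values(patterns), "neural")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties; NaN pairs are
    dropped pairwise.  Returns NaN when either rank vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise UndefinedCorrelationError("fewer than 3 defined pairs")
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def correlate_rdms(neural: RDM, model: RDM, rho_clip: float = 0.999999) -> float:
    """Spearman ρ between the paired lower-triangle vectors of a neural and a
    model RDM, Fisher-transformed: z = atanh(ρ).

    |ρ| = 1 is clipped to ``rho_clip`` before atanh so group t tests stay
    finite.  Undefined correlations (constant ranks) return NaN.
    """
    if neural.labels != model.labels:
        raise InvalidRDMError("neural and model RDMs must share labels and order")
    rho = spearman_rho(neural.vector(), model.vector())
    if not np.isfinite(rho):
        return float("nan")
    return float(np.arctanh(np.clip(rho, -rho_clip, rho_clip)))


@dataclass
class RepresentationMap:
    """Per-subject searchlight map of Fisher-z representation values for one
    model (logo_grapheme | semantic) and one condition, with the per-center
    sphere-size volume."""

    z: np.ndarray
    sphere_size: np.ndarray
    affine: np.ndarray
    model_kind: str
    condition: str


def searchlight_representation_map(
    series: TrialBetaSeries,
    model: RDM,
    spec: SearchlightSpec,
    roi_mask: np.ndarray,
) -> RepresentationMap:
    """Fisher-z model-brain correlation at every in-ROI searchlight center.

    Deterministic given its inputs.  Centers with fewer than ``spec.min_voxels``
    in-ROI sphere voxels are NaN.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ConfigurationError("empty ROI mask")
    if model.labels != series.stim_ids:
        model = model.subset(series.stim_ids)
        if model.labels != series.stim_ids:
            raise InvalidRDMError("model RDM does not cover the trial stimuli")
    vs = np.linalg.norm(series.affine[:3, :3], axis=0)
    offsets = sphere_offsets(spec.radius_mm, vs)
    n = series.n_trials
    li, lj = tril_indices(n)
    model_vec = model.vector()
    model_ok = np.isfinite(model_vec)
    # precompute model ranks for the common no-missing-cell fast path
    mr = stats.rankdata(model_vec[model_ok])
    mr_c = mr - mr.mean()
    mr_sd = mr.std()

    z = np.full(roi_mask.shape, np.nan)
    sphere_size = np.zeros(roi_mask.shape, dtype=np.int32)
    clip = spec.rho_clip
    for center in np.argwhere(roi_mask):
        i, j, k = _sphere_indices(center, offsets, roi_mask)
        c = tuple(center)
        sphere_size[c] = i.size
        if i.size < spec.min_voxels:
            continue
        d = _pattern_rdm_values(series.data[i, j, k, :])
        vec = d[li, lj]
        ok = np.isfinite(vec) & model_ok
        if ok.sum() < 3:
            continue
        if ok.all() and model_ok.all():
            nr = stats.rankdata(vec)
            sd = nr.std()
            if sd == 0 or mr_sd == 0:
                continue
            rho = float(np.mean((nr - nr.mean()) * mr_c) / (sd * mr_sd))
        else:
            rho = spearman_rho(vec, model_vec)
            if not np.isfinite(rho):
                continue
        z[c] = np.arctanh(np.clip(rho, -clip, clip))
    return RepresentationMap(z, sphere_size, series.affine.copy(), model.kind, series.condition)


def group_rsa_inference(
    maps: list[RepresentationMap],
    mask: np.ndarray,
    p_threshold: float = 0.05,
    min_cluster_size: int = 10,
    connectivity: int = 18,
) -> tuple[StatMap, np.ndarray, ClusterTable]:
    """Group inference on subjects' representation maps: positive one-tailed
    one-sample t, uncorrected p threshold, strict cluster-extent rule.

    Returns (group t StatMap, voxelwise p volume, cluster table).
    """
    affine = maps[0].affine
    t, p, df = group_onesample_t([m.z for m in maps], mask, tail="greater")
    with np.errstate(invalid="ignore"):
        survivors = np.nan_to_num(p, nan=1.0) < p_threshold
    survivors &= mask
    clusters = extract_clusters(
        survivors, t, affine, min_size=min_cluster_size, connectivity=connectivity
    )
    return StatMap(t, affine, kind="t", df=df), p, clusters


def cluster_mean_representation(
    maps: list[RepresentationMap], cluster_mask: np.ndarray
) -> np.ndarray:
    """Per-subject mean Fisher-z inside a cluster."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ConfigurationError("empty cluster")
    return np.array([float(np.nanmean(m.z[cluster_mask])) for m in maps])


def cross_region_correlation(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Across-subject Spearman correlation between two regions' cluster-mean
    representation values, with two-tailed p (exact permutation p for n <= 9,
    asymptotic otherwise)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("subject vectors must share length")
    n = a.size
    if n < 4:
        raise ConfigurationError("need at least 4 subjects")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant subject vector")
    rho = spearman_rho(a, b)
    if n <= 9:
        rb = stats.rankdata(b)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = spearman_rho(a, rb[list(perm)])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(a, b).pvalue)
    return float(rho), float(p)


def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) between two boolean volumes."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)
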