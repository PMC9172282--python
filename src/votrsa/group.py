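"""Group-level inference, multiplicity control, clusters, gradients, behavior.

Voxelwise group inference is a one-sample t against zero over subjects, with
Benjamini-Hochberg FDR control (activation analysis) or an uncorrected p
threshold (searchlight RSA), followed in both cases by a strict cluster-extent
rule (components of size > min_size survive).  Gradient profiles average a map
within equal-width bins of the posterior-to-anterior (y) mm coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    ConfigurationError,
    DegenerateConditionError,
    IncompleteDesignError,
)
from .images import StatMap, voxel_to_mm
from .stimuli import CONDITIONS

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def group_onesample_t(
    maps: list[np.ndarray], mask: np.ndarray, tail: str = "two"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Voxelwise one-sample t of subject maps against 0 with n−1 df.

    ``tail``: "two", "greater" (positive one-tailed) or "less".  Voxels with
    zero across-subject variance (or any non-finite subject value) are NaN; a
    warning reports their count.  Returns (t volume, p volume, df).
    """
    if len(maps) < 3:
        raise ConfigurationError("group t-test needs at least 3 subjects")
    data = np.stack([np.asarray(m, dtype=float) for m in maps])
    if any(m.shape != mask.shape for m in data):
        raise ConfigurationError("subject maps are not on a common grid")
    n = data.shape[0]
    df = n - 1
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~mask] = np.nan
    bad = mask & ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} in-mask voxels have undefined t (zero variance)")
        t[bad] = np.nan
    if tail == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ConfigurationError(f"unknown tail {tail!r}")
    p = np.where(np.isfinite(t), p, np.nan)
    return t, p, df


def fdr_threshold(
    p: np.ndarray, mask: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over in-mask voxels.

    Returns the survivor mask and the adaptive critical p (the largest sorted
    p(i) with p(i) <= i*q/m; 0.0 when nothing is rejected).  NaN p values
    inside the mask are treated as non-rejections but still count toward m.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("empty mask")
    pv = np.asarray(p, dtype=float)[mask]
    finite = np.isfinite(pv)
    if finite.any() and (pv[finite].min() < 0 or pv[finite].max() > 1):
        raise ConfigurationError("p values outside [0, 1]")
    m = pv.size
    order = np.argsort(np.where(finite, pv, np.inf))
    sorted_p = pv[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    if passing.size == 0:
        crit = 0.0
    else:
        crit = float(sorted_p[passing[-1]])
    survivors = np.zeros_like(np.asarray(p), dtype=bool)
    survivors[mask] = np.where(finite, pv <= crit, False) if crit > 0 else False
    return survivors, crit


@dataclass
class ClusterTable:
    """Connected suprathreshold components with size and peak statistics."""

    frame: pd.DataFrame
    label_volume: np.ndarray  # integer cluster ids, 0 = background

    def __len__(self):
        return len(self.frame)

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.label_volume == cluster_id

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def extract_clusters(
    survivors: np.ndarray,
    stat: np.ndarray,
    affine: np.ndarray,
    min_size: int = 10,
    connectivity: int = 18,
) -> ClusterTable:
    """Connected components of the survivor mask; components with size
    <= ``min_size`` are dropped (strict "size > min_size" rule).

    Peak is the in-cluster maximum of |stat|, reported with its mm coordinate.
    """
    if connectivity not in _CONNECTIVITY:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labelled, n = ndimage.label(np.asarray(survivors, dtype=bool), structure=structure)
    rows = []
    out = np.zeros_like(labelled)
    next_id = 0
    stat = np.asarray(stat, dtype=float)
    order = []
    for lab in range(1, n + 1):
        comp = labelled == lab
        size = int(comp.sum())
        if size <= min_size:
            continue
        vals = np.where(comp, np.abs(np.nan_to_num(stat)), -np.inf)
        peak_idx = np.unravel_index(np.argmax(vals), vals.shape)
        order.append((size, lab, comp, peak_idx))
    # larger clusters first, ties broken by first-found label for determinism
    order.sort(key=lambda x: (-x[0], x[1]))
    for size, _lab, comp, peak_idx in order:
        next_id += 1
        out[comp] = next_id
        peak_mm = voxel_to_mm(affine, np.asarray(peak_idx))
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_stat": float(stat[peak_idx]),
                "peak_i": peak_idx[0],
                "peak_j": peak_idx[1],
                "peak_k": peak_idx[2],
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
            }
        )
    cols = [
        "cluster_id", "size", "peak_stat",
        "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    ]
    return ClusterTable(pd.DataFrame(rows, columns=cols), out)


def gradient_profile(
    vol: np.ndarray,
    roi_mask: np.ndarray,
    affine: np.ndarray,
    axis: int = 1,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean in-ROI value within equal-width bins of the mm coordinate along
    ``axis`` (default y), ordered posterior → anterior (ascending mm).

    Returns a frame of (bin_center_mm, mean, count); empty bins are dropped
    with a warning when fewer than ``n_bins`` bins are occupied.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ConfigurationError("empty ROI")
    ijk = np.argwhere(roi_mask)
    mm = voxel_to_mm(affine, ijk)[:, axis]
    vals = np.asarray(vol, dtype=float)[roi_mask]
    edges = np.linspace(mm.min(), mm.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(mm, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin_center_mm": 0.5 * (edges[b] + edges[b + 1]),
                "mean": float(np.nanmean(vals[sel])),
                "count": int(sel.sum()),
            }
        )
    if len(rows) < n_bins:
        warnings.warn(f"only {len(rows)} of {n_bins} bins occupied in ROI")
    return pd.DataFrame(rows)


def behavioral_stats(table: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA and Bonferroni-corrected paired t tests.

    ``table`` is long-format with columns subject, condition, acc, rt
    (one row per subject x condition).  For each measure the ANOVA F has
    df (k−1, (k−1)(n−1)) with no sphericity correction; the six pairwise
    paired t tests carry Bonferroni-adjusted p (family size 6).
    """
    from statsmodels.stats.anova import AnovaRM

    need = {"subject", "condition", "acc", "rt"}
    if need - set(table.columns):
        raise IncompleteDesignError(f"behavior table missing {need - set(table.columns)}")
    pivot_check = table.pivot_table(
        index="subject", columns="condition", values="acc", aggfunc="count"
    )
    if pivot_check.isna().any().any() or set(pivot_check.columns) != set(CONDITIONS):
        raise IncompleteDesignError("behavior table has missing subject x condition cells")

    out = {}
    pairs = [
        (a, b) for i, a in enumerate(CONDITIONS) for b in CONDITIONS[i + 1 :]
    ]
    m = len(pairs)  # Bonferroni family: all 6 pairs of 4 conditions
    for measure in ("acc", "rt"):
        res = AnovaRM(table, depvar=measure, subject="subject", within=["condition"]).fit()
        row = res.anova_table.iloc[0]
        wide = table.pivot(index="subject", columns="condition", values=measure)
        pairwise = []
        for a, b in pairs:
            t, p = stats.ttest_rel(wide[a], wide[b])
            pairwise.append(
                {
                    "pair": f"{a}-{b}",
                    "t": float(t),
                    "df": len(wide) - 1,
                    "p_uncorrected": float(p),
                    "p_bonferroni": float(min(1.0, p * m)),
                }
            )
        out[measure] = {
            "F": float(row["F Value"]),
            "df1": int(row["Num DF"]),
            "df2": int(row["Den DF"]),
            "p": float(row["Pr > F"]),
            "pairwise": pd.DataFrame(pairwise),
            "means": wide.mean().to_dict(),
        }
    return out


def apply_exclusions(
    events_by_subject: dict[str, "pd.DataFrame"],
    acc_condition: str = "PW",
    acc_threshold: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Validation-path exclusions.

    Drops subjects whose accuracy in ``acc_condition`` is below
    ``acc_threshold`` (the "< 50%" rule), then drops inaccurate trials for the
    retained subjects.  Returns the filtered events and a report of counts
    removed at each step.  If exclusion would empty a condition for a retained
    subject, a :class:`DegenerateConditionError` is raised.
    """
    report = {
        "subjects_in": len(events_by_subject),
        "excluded_subjects": [],
        "trials_removed": {},
    }
    kept: dict[str, pd.DataFrame] = {}
    for sub, ev in events_by_subject.items():
        f = ev.frame if hasattr(ev, "frame") else ev
        cond_acc = f.loc[f.trial_type == acc_condition, "accuracy"].mean()
        if cond_acc < acc_threshold:
            report["excluded_subjects"].append(sub)
            continue
        filtered = f[f.accuracy == 1].copy()
        for cond in CONDITIONS:
            if (f.trial_type == cond).any() and not (filtered.trial_type == cond).any():
                raise DegenerateConditionError(
                    f"subject {sub}: exclusion removed every {cond} trial"
                )
        report["trials_removed"][sub] = int(len(f) - len(filtered))
        kept[sub] = filtered
    report["subjects_out"] = len(kept)
    report["total_trials_removed"] = int(sum(report["trials_removed"].values()))
    return kept, report
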