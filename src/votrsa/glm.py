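"""First-level modelling: HRF, design matrices, OLS beta estimation, contrasts.

The event-related design is modelled by convolving per-event boxcars with the
canonical double-gamma HRF, sampled at scan times.  Nuisance structure follows
the conventional event-related recipe: six motion parameters, a discrete-cosine
drift basis (default 128-s cutoff), and an intercept.  Fixation is the implicit
(unmodelled) baseline, so "condition versus fixation" is the condition
regressor's own beta.

Trial-wise estimation uses a single least-squares-all GLM with one column per
RW/PW/FW trial (120 columns for the default design); SC trials are absorbed by
one nuisance condition column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import (
    ConfigurationError,
    ContrastSpecError,
    SingularDesignError,
    TimingError,
    InvalidStimulusError,
)
from .images import BOLDRun, StatMap
from .stimuli import CONDITIONS, LOGO_CONDITIONS

# canonical double-gamma parameters (response delay 6 s, undershoot delay 16 s,
# dispersions 1, response/undershoot ratio 6, 32-s support)
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


def canonical_hrf(dt: float, duration: float = HRF_LENGTH) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, unit peak.

    h(t) = g(t; 6, 1) − g(t; 16, 1)/6 with g a gamma density, rescaled so the
    maximum of the sampled kernel is 1.  h(0) = 0 and the kernel has a single
    sign change (positive lobe, then undershoot).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    h = gamma_dist.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    h = h - gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    ) / HRF_RATIO
    return h / h.max()


@dataclass
class EventTable:
    """Trial timing and response metadata for one run.

    Columns: onset (s), duration (s), trial_type (condition), stim_id,
    accuracy (0/1), rt (ms).
    """

    frame: pd.DataFrame

    REQUIRED = ("onset", "duration", "trial_type", "stim_id", "accuracy", "rt")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"event table missing columns: {missing}")
        f = self.frame
        if not np.all(np.diff(f.onset.to_numpy()) > 0):
            raise TimingError("onsets must be strictly increasing")
        if not np.all(f.duration.to_numpy() > 0):
            raise TimingError("durations must be positive")
        bad = set(f.trial_type) - set(CONDITIONS)
        if bad:
            raise InvalidStimulusError(f"unknown conditions in events: {sorted(bad)}")

    def __len__(self):
        return len(self.frame)

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.frame[self.frame.trial_type == condition]

    def accuracy_by_condition(self) -> pd.Series:
        return self.frame.groupby("trial_type", observed=True).accuracy.mean()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class DesignMatrix:
    """Time x regressors design with named columns.

    ``task_columns`` are the convolved predictors of interest; everything else
    (motion, drift, intercept, SC nuisance) is nuisance.  ``trial_info`` maps
    per-trial columns to their condition/stimulus/accuracy (trial-wise designs
    only).
    """

    frame: pd.DataFrame
    task_columns: list[str]
    trial_info: pd.DataFrame | None = None

    def __post_init__(self):
        cols = list(self.frame.columns)
        if len(set(cols)) != len(cols):
            raise ConfigurationError("design matrix column names must be unique")
        X = self.frame[self.task_columns].to_numpy()
        if X.size and np.any(np.all(X == 0.0, axis=0)):
            dead = [c for c in self.task_columns if not self.frame[c].any()]
            raise ConfigurationError(f"all-zero task columns: {dead}")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def dct_drift_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis (SPM convention), constant term excluded.

    Keeps the K = floor(2 * T / cutoff) slowest cosines, T the run duration.
    """
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    i = np.arange(n_scans)
    basis = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * i + 1) * k / (2 * n_scans))
        for k in range(1, order + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n_scans, 0))


def _convolved_column(
    onsets, durations, n_scans: int, tr: float, oversample: int = 16
) -> np.ndarray:
    """Boxcar train convolved with the canonical HRF, sampled at scan times."""
    dt = tr / oversample
    n_hi = n_scans * oversample
    train = np.zeros(n_hi)
    for onset, dur in zip(onsets, durations):
        a = int(round(onset / dt))
        b = max(a + 1, int(round((onset + dur) / dt)))
        train[a : min(b, n_hi)] += 1.0  # overlapping events superpose
    hrf = canonical_hrf(dt)
    conv = np.convolve(train, hrf)[:n_hi]
    return conv[::oversample]


def build_design_matrix(
    events: EventTable,
    n_scans: int,
    tr: float,
    motion: np.ndarray | None = None,
    granularity: str = "per_condition",
    drift_cutoff: float = 128.0,
    oversample: int = 16,
) -> DesignMatrix:
    """Build the first-level design.

    granularity ``per_condition`` gives one convolved column per condition;
    ``per_trial`` gives one column per RW/PW/FW trial (the 120-trial design)
    plus a single SC nuisance column.  Motion (n_scans x 6), a DCT drift basis
    and an intercept are appended as nuisances.
    """
    f = events.frame
    end = n_scans * tr
    if np.any(f.onset + f.duration > end):
        raise TimingError("events extend past the end of the scan")
    cols: dict[str, np.ndarray] = {}
    task: list[str] = []
    trial_info = None

    if granularity == "per_condition":
        for cond in CONDITIONS:
            sub = events.for_condition(cond)
            if len(sub):
                cols[cond] = _convolved_column(
                    sub.onset.to_numpy(), sub.duration.to_numpy(), n_scans, tr, oversample
                )
                task.append(cond)
    elif granularity == "per_trial":
        keys = [
            (row.trial_type, row.stim_id)
            for row in f.itertuples()
            if row.trial_type in LOGO_CONDITIONS
        ]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (condition, stim_id) trial ids")
        info = []
        for k, row in enumerate(f.itertuples()):
            if row.trial_type not in LOGO_CONDITIONS:
                continue
            name = f"t{k:03d}_{row.trial_type}_{row.stim_id}"
            cols[name] = _convolved_column(
                [row.onset], [row.duration], n_scans, tr, oversample
            )
            task.append(name)
            info.append(
                {
                    "column": name,
                    "condition": row.trial_type,
                    "stim_id": row.stim_id,
                    "accuracy": row.accuracy,
                }
            )
        trial_info = pd.DataFrame(info)
        sc = events.for_condition("SC")
        if len(sc):
            cols["SC_nuisance"] = _convolved_column(
                sc.onset.to_numpy(), sc.duration.to_numpy(), n_scans, tr, oversample
            )
    else:
        raise ConfigurationError(f"unknown granularity {granularity!r}")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ConfigurationError(
                f"motion table must be (n_scans, 6), got {motion.shape}"
            )
        for i in range(6):
            cols[f"motion_{i + 1}"] = motion[:, i]
    drift = dct_drift_basis(n_scans, tr, drift_cutoff)
    for i in range(drift.shape[1]):
        cols[f"drift_{i + 1}"] = drift[:, i]
    cols["intercept"] = np.ones(n_scans)

    frame = pd.DataFrame(cols, index=np.arange(n_scans) * tr)
    return DesignMatrix(frame, task, trial_info)


@dataclass
class BetaImage:
    """Voxelwise OLS fit: one 3D coefficient volume per regressor, residual
    variance and degrees of freedom, plus the design metadata contrasts need."""

    betas: np.ndarray  # (x, y, z, p)
    sigma2: np.ndarray  # (x, y, z)
    df: int
    columns: list[str]
    task_columns: list[str]
    xtx_inv: np.ndarray  # (p, p)
    mask: np.ndarray
    affine: np.ndarray
    trial_info: pd.DataFrame | None = None

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise ContrastSpecError(f"unknown design column {name!r}") from None

    def beta_volume(self, name: str) -> np.ndarray:
        return self.betas[..., self.column_index(name)]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns implicated in a rank deficiency (small R diagonal)."""
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.nonzero(d <= tol)[0]]


def fit_glm(run: BOLDRun, design: DesignMatrix, mask: np.ndarray) -> BetaImage:
    """Ordinary-least-squares fit of the design at every in-mask voxel.

    Residual variance uses df = T − rank(X); a rank-deficient design raises
    :class:`SingularDesignError` naming the collinear columns.
    """
    X = design.values
    if X.shape[0] != run.n_scans:
        raise ConfigurationError(
            f"design rows ({X.shape[0]}) != run length ({run.n_scans})"
        )
    if mask.shape != run.shape:
        raise ConfigurationError("mask shape does not match run grid")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(_collinear_columns(X, design.columns))

    Y = run.data[mask].T.astype(float)  # (T, V)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    df = X.shape[0] - p
    s2 = np.einsum("tv,tv->v", resid, resid) / df

    shape = run.shape
    betas = np.full(shape + (p,), np.nan)
    betas[mask] = B.T
    sigma2 = np.full(shape, np.nan)
    sigma2[mask] = s2
    return BetaImage(
        betas=betas,
        sigma2=sigma2,
        df=df,
        columns=design.columns,
        task_columns=list(design.task_columns),
        xtx_inv=np.linalg.inv(X.T @ X),
        mask=mask.copy(),
        affine=run.affine.copy(),
        trial_info=None if design.trial_info is None else design.trial_info.copy(),
    )


@dataclass(frozen=True)
class ContrastSpec:
    """Named weight vector over design columns (task columns only)."""

    name: str
    weights: dict[str, float] = field(default_factory=dict)


#: The five activation contrasts, as (positive condition, negative condition):
#: each "X versus fixation" is the condition beta against the implicit baseline.
CONTRAST_PRESETS = {
    "lexical": ("RW", "PW"),  # lexical access
    "word_form": ("PW", "FW"),  # orthographic legality
    "abstract_orthography": ("PW", "RW"),
    "radical": ("FW", "RW"),
    "basic_visual": ("SC", "RW"),
}


def preset_contrast(name: str) -> ContrastSpec:
    pos, neg = CONTRAST_PRESETS[name]
    return ContrastSpec(name, {pos: 1.0, neg: -1.0})


def compute_contrast(
    betas: BetaImage, contrast: ContrastSpec, output: str = "t"
) -> StatMap:
    """Voxelwise contrast map: t = cᵀβ / sqrt(σ̂² · cᵀ(XᵀX)⁻¹c).

    ``output="effect"`` returns the raw contrast estimate cᵀβ instead (the
    per-subject input to group one-sample tests).  Zero residual variance with
    a nonzero effect yields ±inf, flagged by the caller via isfinite.
    """
    if not contrast.weights or all(w == 0 for w in contrast.weights.values()):
        raise ContrastSpecError("contrast weights are empty or all zero")
    nontask = [c for c in contrast.weights if c not in betas.task_columns]
    if nontask:
        raise ContrastSpecError(f"contrast touches non-task columns: {nontask}")
    p = len(betas.columns)
    c = np.zeros(p)
    for name, w in contrast.weights.items():
        c[betas.column_index(name)] = w
    effect = betas.betas @ c
    if output == "effect":
        return StatMap(effect, betas.affine, kind="effect", df=betas.df)
    var_factor = float(c @ betas.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(betas.sigma2 * var_factor)
    return StatMap(t, betas.affine, kind="t", df=betas.df)
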