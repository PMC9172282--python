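"""Volume containers shared across pipeline stages.

All volumes carry a 4x4 voxel-to-mm affine; millimetre coordinates are derived
only through it.  Statistic volumes are NaN outside their analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to mm coordinates via the affine."""
    ijk = np.asarray(ijk, dtype=float)
    single = ijk.ndim == 1
    out = np.atleast_2d(ijk) @ affine[:3, :3].T + affine[:3, 3]
    return out[0] if single else out


@dataclass
class BOLDRun:
    """One subject's 4D functional run (x, y, z, t)."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ConfigurationError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.tr <= 0:
            raise ConfigurationError("TR must be positive")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ConfigurationError("affine is not invertible")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class StatMap:
    """Voxelwise statistic volume (t, z, rho, p, or effect size)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "t"
    df: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("StatMap data must be 3D")


@dataclass
class LabelVolume:
    """Integer-labelled anatomy / atlas volume."""

    data: np.ndarray
    affine: np.ndarray
    label_names: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.round(self.data).astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)

    def mask(self, labels) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``labels``."""
        if np.isscalar(labels):
            labels = [labels]
        return np.isin(self.data, np.asarray(list(labels)))

    @property
    def brain_mask(self) -> np.ndarray:
        return self.data > 0
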