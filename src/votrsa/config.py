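"""Run configuration: every stage parameter in one serializable record.

Defaults equal the published analysis settings where the source analysis
states them (thresholds, searchlight radius, trial counts); the remaining
knobs (connectivity, drift cutoff, overlap convention) carry conventional
defaults and are echoed into every output directory for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    # design
    tr_s: float = 0.72
    n_per_condition: int = 40
    stim_duration_s: float = 0.6
    isi_range_s: tuple = (4.0, 6.0)
    # first level
    drift_cutoff_s: float = 128.0
    hrf_oversample: int = 16
    # theoretical RDMs
    overlap_convention: str = "dice"
    # activation group stats
    activation_q_fdr: float = 0.05
    activation_p_voxel: float = 0.05
    cluster_min_size: int = 10
    cluster_connectivity: int = 18
    # searchlight RSA
    searchlight_radius_mm: float = 6.0
    searchlight_min_voxels: int = 10
    rsa_p_voxel: float = 0.05
    rho_clip: float = 0.999999
    atlas_roi_labels: tuple = (55, 56, 53, 54)
    # exclusions
    exclusion_acc_condition: str = "PW"
    exclusion_acc_threshold: float = 0.5
    # gradient
    gradient_axis: int = 1
    gradient_n_bins: int = 9
    # synthetic data
    seed: int = 0
    n_subjects: int = 20
    grid: str = "default"
    plant_amplitude: float = 2.0
    mean_shift: float = 1.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (auto-detected); unknown keys rejected."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("isi_range_s", "atlas_roi_labels"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def content_hash(path) -> str:
    """SHA-256 of a file's bytes (provenance record for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
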