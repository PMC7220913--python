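"""Run configuration with the published parameter defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SynthConfig:
    """Synthetic-cohort parameters used when no input data are supplied."""

    n_participants: int = 120
    n_nodes: int = 32
    n_pos_edges: int = 10
    n_neg_edges: int = 10
    effect_r: float = 0.4
    gf_mean: float = 60.0
    gf_sd: float = 8.0
    retest_reliability_t2: float = 0.7
    retest_reliability_t3: float = 0.5
    external_scale: float = 1.5
    external_offset: float = 20.0
    external_noise_sd: float = 2.0
    fd_spike_rate: float = 0.02


@dataclass
class RunConfig:
    """All stage parameters, with published defaults.

    Preprocessing: discard 7 initial volumes, FD spike threshold 0.5 mm,
    retention floor 80%, mean-FD limit 0.15 mm, motion limits 2 mm / 2 deg,
    behavioral outliers at 2 SD, band-pass 0.01-0.10 Hz.  Mask/parcellation:
    WM probability 0.90, group coverage 0.80, subcortical removal 0.25,
    K = 128 nodes.  Model: selection p 0.01, 20-fold x 50 repeats, 5000
    permutations.
    """

    n_discard: int = 7
    tr_seconds: float = 2.0
    fd_threshold_mm: float = 0.5
    min_retention: float = 0.80
    max_mean_fd_mm: float = 0.15
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    outlier_k_sd: float = 2.0
    wm_threshold: float = 0.90
    group_coverage: float = 0.80
    subcortical_threshold: float = 0.25
    band_low_hz: float = 0.01
    band_high_hz: float = 0.10
    n_nodes: int = 128
    selection_p: float = 0.01
    alpha_motion: float = 0.05
    variant: str = "glm"
    kfold_k: int = 20
    kfold_repeats: int = 50
    permutations: int = 5000
    run_permutation: bool = False
    seed: int = 0
    input_dir: str | None = None
    output_dir: str = "wmcpm_out"
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)
        checks = [
            (self.n_discard >= 0, "n_discard must be non-negative"),
            (self.fd_threshold_mm > 0, "fd_threshold_mm must be positive"),
            (0 <= self.min_retention <= 1, "min_retention must lie in [0, 1]"),
            (0 < self.band_low_hz < self.band_high_hz, "band edges must be ordered"),
            (0 < self.selection_p < 1, "selection_p must lie in (0, 1)"),
            (self.kfold_k >= 2, "kfold_k must be >= 2"),
            (self.permutations >= 1, "permutations must be >= 1"),
            (self.variant in ("glm", "positive", "negative"), "unknown variant"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
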