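"""Synthetic cohorts with planted edge-behavior effects.

Every generator is deterministic given its seed.  The edge model plants, for
each chosen edge, a population correlation of exactly ``effect_r`` (with the
requested sign) between the edge value and the participant's latent trait:

    edge = sign * effect_r * z + sqrt(1 - effect_r**2) * noise

where ``z`` is the standardized latent trait and ``noise`` is independent
standard normal.  All remaining edges are pure noise.  Behavioral scores are
the latent trait mapped to the requested mean/SD and rounded to integers
(test totals are integer counts).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .maskparc import Volume3D
from .preprocess import MotionTrace, compute_fd

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_retest",
    "generate_external",
    "generate_motion_trace",
    "generate_toy_volume",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator."""

    n_participants: int = 300
    n_nodes: int = 128
    n_pos_edges: int = 20
    n_neg_edges: int = 20
    effect_r: float = 0.4
    gf_mean: float = 60.0
    gf_sd: float = 8.0
    retest_reliability: float = 0.7
    external_scale: float = 1.0
    external_offset: float = 0.0
    external_noise_sd: float = 0.0
    fd_spike_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_pos_edges + self.n_neg_edges > n_edges:
            raise ValueError(
                f"n_pos_edges + n_neg_edges = {self.n_pos_edges + self.n_neg_edges} "
                f"exceeds available edges {n_edges} for n_nodes={self.n_nodes}"
            )
        if not 0.0 <= self.effect_r < 1.0:
            raise ValueError("effect_r must lie in [0, 1)")
        for name in ("retest_reliability", "fd_spike_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2


@dataclass
class GroundTruth:
    """What was planted: edge sets, latent traits, and the external affine map."""

    pos_edges: np.ndarray
    neg_edges: np.ndarray
    latent: np.ndarray
    effect_r: float
    external_scale: float = 1.0
    external_offset: float = 0.0
    n_nodes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pos_edges = np.asarray(self.pos_edges, dtype=int)
        self.neg_edges = np.asarray(self.neg_edges, dtype=int)
        if np.intersect1d(self.pos_edges, self.neg_edges).size:
            raise ValueError("planted positive and negative edge sets must be disjoint")

    def write(self, path: str | Path) -> None:
        payload = {
            "pos_edges": self.pos_edges.tolist(),
            "neg_edges": self.neg_edges.tolist(),
            "latent": np.asarray(self.latent).tolist(),
            "effect_r": self.effect_r,
            "external_scale": self.external_scale,
            "external_offset": self.external_offset,
            "n_nodes": self.n_nodes,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _planted_edges(n_participants: int, n_edges: int, pos: np.ndarray, neg: np.ndarray,
                   effect_r: float, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Edge matrix with the planted correlation structure; unit variance per edge."""
    edges = rng.standard_normal((n_participants, n_edges))
    mix = np.sqrt(1.0 - effect_r**2)
    if pos.size:
        edges[:, pos] = effect_r * z[:, None] + mix * edges[:, pos]
    if neg.size:
        edges[:, neg] = -effect_r * z[:, None] + mix * edges[:, neg]
    return edges


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a training cohort and its ground truth.

    Returns a cohort whose planted edges correlate with the behavioral score
    at ``spec.effect_r`` in expectation (positive and negative sets by sign),
    while all other edges are independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_edges = spec.n_participants, spec.n_edges

    chosen = rng.choice(n_edges, size=spec.n_pos_edges + spec.n_neg_edges, replace=False)
    pos = np.sort(chosen[: spec.n_pos_edges])
    neg = np.sort(chosen[spec.n_pos_edges:])

    z = rng.standard_normal(n)
    gf = np.round(spec.gf_mean + spec.gf_sd * z)
    edges = _planted_edges(n, n_edges, pos, neg, spec.effect_r, z, rng)

    # motion summary independent of the trait so it cannot carry signal
    mean_fd = np.abs(rng.normal(0.08, 0.03, size=n))
    age = np.round(rng.normal(20.0, 1.0, size=n), 1)
    sex = rng.integers(0, 2, size=n).astype(float)

    ids = np.array([f"sub-{i:04d}" for i in range(n)])
    cohort = Cohort(ids=ids, gf=gf, edges=edges, mean_fd=mean_fd, age=age, sex=sex,
                    n_nodes=spec.n_nodes, session="time1")
    truth = GroundTruth(pos_edges=pos, neg_edges=neg, latent=z, effect_r=spec.effect_r,
                        external_scale=spec.external_scale,
                        external_offset=spec.external_offset,
                        n_nodes=spec.n_nodes, seed=spec.seed)
    return cohort, truth


def generate_retest(cohort: Cohort, truth: GroundTruth, reliability: float,
                    seed: int, session: str = "time2") -> Cohort:
    """Retest session: same participants and scores, attenuated edge reliability.

    Each edge column is mixed with fresh unit-variance noise so that the
    edgewise test-retest correlation equals ``reliability`` analytically
    (session-1 edge columns have unit population variance).
    """
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must lie in [0, 1]")
    if cohort.n_participants != len(truth.latent):
        raise ValueError("cohort and ground truth disagree on participant count")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(cohort.edges.shape)
    edges = reliability * cohort.edges + np.sqrt(1.0 - reliability**2) * noise
    return Cohort(ids=cohort.ids.copy(), gf=cohort.gf.copy(), edges=edges,
                  mean_fd=np.abs(rng.normal(0.08, 0.03, size=cohort.n_participants)),
                  age=cohort.age.copy(), sex=cohort.sex.copy(),
                  n_nodes=cohort.n_nodes, session=session)


def generate_external(spec: SyntheticSpec, truth: GroundTruth, seed: int) -> Cohort:
    """External cohort: same planted edge sets, affinely re-scaled scores.

    score = external_scale * (gf_mean + gf_sd * latent) + external_offset + noise
    """
    rng = np.random.default_rng(seed)
    n = spec.n_participants
    z = rng.standard_normal(n)
    latent_gf = spec.gf_mean + spec.gf_sd * z
    score = (truth.external_scale * latent_gf + truth.external_offset
             + spec.external_noise_sd * rng.standard_normal(n))
    edges = _planted_edges(n, spec.n_edges, truth.pos_edges, truth.neg_edges,
                           truth.effect_r, z, rng)
    ids = np.array([f"ext-{i:04d}" for i in range(n)])
    return Cohort(ids=ids, gf=score, edges=edges,
                  mean_fd=np.abs(rng.normal(0.08, 0.03, size=n)),
                  age=np.round(rng.normal(21.0, 1.5, size=n), 1),
                  sex=rng.integers(0, 2, size=n).astype(float),
                  n_nodes=spec.n_nodes, session="external")


def generate_motion_trace(n_frames: int, fd_spike_rate: float, seed: int,
                          spike_amplitude_mm: float = 1.0) -> MotionTrace:
    """Rigid-body motion trace whose FD spikes above 0.5 mm at the given rate.

    Baseline jitter is small enough that FD stays far below the 0.5 mm
    threshold; spikes are sustained single-frame translation steps so each
    selected frame produces exactly one supra-threshold FD value.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not 0.0 <= fd_spike_rate <= 1.0:
        raise ValueError("fd_spike_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    params = np.zeros((n_frames, 6))
    params[:, :3] = np.cumsum(rng.normal(0.0, 0.005, size=(n_frames, 3)), axis=0)
    params[:, 3:] = np.cumsum(rng.normal(0.0, 5e-5, size=(n_frames, 3)), axis=0)

    spikes = rng.random(n_frames - 1) < fd_spike_rate  # frames 1..n-1
    signs = rng.choice([-1.0, 1.0], size=spikes.sum())
    axes = rng.integers(0, 3, size=spikes.sum())
    for frame, sign, axis in zip(np.flatnonzero(spikes) + 1, signs, axes):
        params[frame:, axis] += sign * spike_amplitude_mm
    trace = MotionTrace(params=params)
    return compute_fd(trace)


def generate_toy_volume(shape: tuple[int, int, int], n_components: int,
                        seed: int) -> tuple[Volume3D, Volume3D]:
    """Toy probability + network-label volumes for the mask/parcellation stage.

    The probability volume holds high tissue probability inside
    ``n_components`` disjoint slabs and low noise outside; the label volume
    assigns each slab a label in 1..n_components (capped at 11 networks by
    cycling).  Values are always clamped to [0, 1].
    """
    if any(s <= 0 for s in shape):
        raise ValueError("shape dimensions must be positive")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    prob = np.clip(rng.normal(0.05, 0.03, size=shape), 0.0, 1.0)
    labels = np.zeros(shape, dtype=int)

    # disjoint slabs along the first axis, separated by one-voxel gaps
    usable = shape[0]
    slab = max(1, usable // n_components - (1 if n_components > 1 else 0))
    start = 0
    for comp in range(n_components):
        stop = min(start + slab, usable)
        if start >= stop:
            break
        prob[start:stop, :, :] = np.clip(rng.normal(0.97, 0.01, size=(stop - start,) + shape[1:]),
                                         0.0, 1.0)
        labels[start:stop, :, :] = comp % 11 + 1
        start = stop + 1
    return Volume3D(values=prob), Volume3D(values=labels)
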