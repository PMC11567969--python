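"""Surrogate behavioral and measurement data, plus the behavior metrics.

These generators emulate the non-simulated inputs of a mesoscale imaging
experiment — calcium fluorescence traces with photobleaching drift, pupil
boundary landmarks, and grayscale facial video frames — so the
preprocessing and behavior-state analyses are testable end to end without
recordings.  The metrics themselves (pupil fit, motion energy, locomotion
labeling) operate on any data in the right shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from sklearn.cluster import KMeans

from .network import TrialTensor

__all__ = [
    "FrameStack",
    "PupilObservation",
    "PupilFit",
    "LocomotionLabels",
    "generate_surrogate_calcium",
    "generate_pupil_points",
    "fit_pupil",
    "generate_motion_frames",
    "motion_energy",
    "classify_locomotion",
]


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class FrameStack:
    """Grayscale video: ``frames[t]`` is an H x W nonnegative intensity image."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("frame intensities must be finite and nonnegative")
        self.frames = f


@dataclass
class PupilFit:
    """Circle fit of pupil landmarks: center, radial parameter and area.

    ``radius`` is the fitted radial distance d (the parameter of the
    least-squares problem); ``diameter = 2 * radius``.  ``area`` is the
    ellipse approximation from the two landmark pair distances.
    """

    center: np.ndarray
    radius: float
    diameter: float
    area: float


@dataclass
class PupilObservation:
    """Four pupil-boundary landmarks, optionally with their circle fit."""

    points: np.ndarray  # 4 x 2
    fit: PupilFit | None = None


def generate_surrogate_calcium(
    rates: TrialTensor,
    rng: np.random.Generator,
    decay_tau: float = 0.7,
    bleach_slope: float = -0.02,
    noise_std: float = 0.1,
) -> TrialTensor:
    """Turn firing-rate traces into calcium-fluorescence-like traces.

    Each trace is the rectified rate convolved with a single-exponential
    indicator kernel (decay constant ``decay_tau`` s, GCaMP6f-like), plus a
    linear photobleaching trend of ``bleach_slope`` per second and additive
    Gaussian noise — exactly the artifacts the preprocessing (detrend +
    z-score) is meant to remove.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    dt = 1.0 / rates.sample_rate
    a = float(np.exp(-dt / decay_tau))
    x = np.clip(rates.data, 0.0, None)
    # exponential kernel as an IIR filter along time: y[t] = x[t] + a*y[t-1]
    y = signal.lfilter([1.0], [1.0, -a], x, axis=-1)
    t = np.arange(rates.n_time) * dt
    y = y + bleach_slope * t
    if noise_std > 0:
        y = y + rng.normal(0.0, noise_std, size=y.shape)
    return rates.with_data(y)


def generate_pupil_points(
    center,
    radii,
    jitter_std: float = 0.0,
    rng: np.random.Generator | None = None,
    angle: float = 0.0,
) -> PupilObservation:
    """Four landmarks at the axis extremes of a pupil ellipse, with jitter.

    Points 0/1 are the major-axis pair, 2/3 the minor-axis pair; Gaussian
    jitter of ``jitter_std`` pixels emulates landmark-labeling error.
    """
    r_major, r_minor = radii
    if r_major <= 0 or r_minor <= 0:
        raise ValueError("radii must be positive")
    c = np.asarray(center, dtype=float)
    u = np.array([np.cos(angle), np.sin(angle)])
    v = np.array([-np.sin(angle), np.cos(angle)])
    pts = np.stack([c + r_major * u, c - r_major * u, c + r_minor * v, c - r_minor * v])
    if jitter_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        pts = pts + rng.normal(0.0, jitter_std, size=pts.shape)
    return PupilObservation(points=pts)


def _pair_points(points: np.ndarray) -> tuple[float, float]:
    """Pair each landmark with its farthest partner (opposite boundary point)."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    far = int(d[0].argmax())
    rest = [i for i in range(1, 4) if i != far]
    return float(d[0, far]), float(d[rest[0], rest[1]])


def fit_pupil(points) -> PupilFit:
    """Least-squares circle fit to four boundary landmarks.

    Minimizes ``sum_i (d_i^2 - d^2)^2`` over center (cx, cy) and radial
    parameter d, where ``d_i`` is the distance from landmark i to the
    center.  The area is the ellipse approximation ``pi*(p1/2)*(p2/2)``
    from the two opposite-landmark pair distances p1, p2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("points must be 4 x 2")
    span = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-9 * max(1.0, np.abs(span).max())) < 2:
        raise DegenerateGeometryError("landmarks are collinear")

    def resid(p):
        cx, cy, d = p
        di2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        return di2 - d**2

    c0 = pts.mean(axis=0)
    d0 = float(np.mean(np.linalg.norm(pts - c0, axis=1)))
    sol = optimize.least_squares(resid, x0=[c0[0], c0[1], d0], max_nfev=2000)
    cx, cy, d = sol.x
    d = abs(float(d))
    p1, p2 = _pair_points(pts)
    area = np.pi * (p1 / 2.0) * (p2 / 2.0)
    return PupilFit(center=np.array([cx, cy]), radius=d, diameter=2.0 * d, area=float(area))


def generate_motion_frames(
    n_frames: int,
    shape: tuple[int, int],
    movement_frames,
    rng: np.random.Generator,
    frame_rate: float = 30.0,
    baseline_noise: float = 0.5,
    movement_amp: float = 20.0,
) -> FrameStack:
    """Synthetic grayscale video: static scene + noise, with bursts of change.

    Frames listed in ``movement_frames`` receive large random intensity
    perturbations (animal movement); all frames carry small sensor noise.
    """
    h, w = shape
    scene = rng.uniform(50.0, 200.0, size=(h, w))
    frames = np.clip(scene[None] + rng.normal(0.0, baseline_noise, size=(n_frames, h, w)), 0, None)
    for f in movement_frames:
        frames[f] = np.clip(frames[f] + rng.normal(0.0, movement_amp, size=(h, w)), 0, None)
    return FrameStack(frames=frames, frame_rate=frame_rate)


def motion_energy(stack) -> np.ndarray:
    """Frame-to-frame motion energy: Frobenius norm of successive differences."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a T x H x W stack with T >= 2")
    diffs = np.diff(frames, axis=0)
    return np.sqrt(np.sum(diffs**2, axis=(1, 2)))


@dataclass
class LocomotionLabels:
    """Per-trial behavioral-state labels: 0 = quiet, 1 = locomotive."""

    labels: np.ndarray
    degenerate: bool
    threshold: float | None = None


def classify_locomotion(
    energy: np.ndarray,
    rng: np.random.Generator | None = None,
    method: str = "kmeans",
    threshold: float | None = None,
) -> LocomotionLabels:
    """Split trials into quiet vs locomotive from per-trial motion energy.

    Default is unsupervised 1-D two-class k-means on the per-trial pre-onset
    motion energies (the higher-energy cluster is labeled locomotive);
    ``method="threshold"`` applies a fixed cutoff instead.  If all energies
    coincide the result is a flagged single-class labeling, not an error.
    """
    e = np.asarray(energy, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("need >= 2 trials")
    if np.allclose(e, e[0]):
        return LocomotionLabels(labels=np.zeros(e.size, dtype=int), degenerate=True)
    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires a threshold")
        return LocomotionLabels(labels=(e > threshold).astype(int), degenerate=False, threshold=threshold)
    if method != "kmeans":
        raise ValueError(f"unknown method {method!r}")
    seed = int(rng.integers(2**31)) if rng is not None else 0
    km = KMeans(n_clusters=2, n_init=10, max_iter=100, random_state=seed)
    raw = km.fit_predict(e[:, None])
    hi = int(km.cluster_centers_.ravel().argmax())
    labels = (raw == hi).astype(int)
    cut = float(km.cluster_centers_.ravel().mean())
    return LocomotionLabels(labels=labels, degenerate=False, threshold=cut)
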