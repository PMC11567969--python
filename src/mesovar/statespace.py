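"""State-space analyses: correlation-distance MDS embedding, velocity-based
energy landscape, behavior readout and initial-state clustering.

The energy landscape is a proxy: the "energy" of a visited population state
is its one-step state-space speed under the network dynamics — slow regions
(attractor wells) have low energy, fast transient regions high energy.  The
sampled states are embedded in 2-D by classical multidimensional scaling on
a correlation dissimilarity, and the speeds are interpolated onto a regular
grid for visualization and well-depth measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .network import Connectivity, InputProjection, NetworkParams, TrialTensor
from .variability import _population_vectors, _window_slice

__all__ = [
    "Embedding",
    "EnergyLandscape",
    "StateClusters",
    "embed_mds",
    "state_speed",
    "evolve_states",
    "build_energy_landscape",
    "behavior_readout_pc2",
    "cluster_initial_states",
    "class_correlation",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not admit the requested construction."""


@dataclass
class Embedding:
    """2-D MDS coordinates of sampled population states."""

    coords: np.ndarray  # S x 2
    distance_mode: str
    stress: float
    kept: np.ndarray  # indices of input states that were embedded


@dataclass
class EnergyLandscape:
    """Gridded speed-proxy energy surface over an embedding."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    surface: np.ndarray  # NaN outside the convex hull of samples
    sample_coords: np.ndarray
    sample_energy: np.ndarray

    def well_depth(self) -> float:
        """Median sampled energy minus the surface minimum (well prominence)."""
        return float(np.nanmedian(self.sample_energy) - np.nanmin(self.surface))


@dataclass
class StateClusters:
    """Two-way k-means partition of per-trial initial-state features."""

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    degenerate: bool
    inner_corr: float | None = None
    inter_corr: float | None = None


def embed_mds(states: np.ndarray, literal_negative_corr: bool = False) -> Embedding:
    """Classical (Torgerson) MDS of states under correlation dissimilarity.

    Pairwise dissimilarity is ``1 - r`` (Pearson); this is a monotone shift
    of the negative correlation that keeps dissimilarities nonnegative so
    the double-centered Gram matrix is well posed.  ``literal_negative_corr``
    uses ``-r`` directly instead.  Constant state vectors (undefined r) are
    excluded and reported through ``kept``.  Kruskal stress-1 of the 2-D
    configuration is returned as a diagnostic.
    """
    x = np.asarray(states, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need an S x N matrix with S >= 3")
    sd = x.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < 3:
        raise DegenerateGeometryError("fewer than 3 non-constant states")
    r = np.corrcoef(x[kept])
    delta = (-r) if literal_negative_corr else (1.0 - r)
    np.fill_diagonal(delta, 0.0)
    # Torgerson: B = -0.5 * J delta^2 J, top-2 eigenpairs
    s = kept.size
    j = np.eye(s) - np.ones((s, s)) / s
    b = -0.5 * j @ (delta**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    d_emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    iu = np.triu_indices(s, k=1)
    denom = np.sum(delta[iu] ** 2)
    stress = float(np.sqrt(np.sum((d_emb[iu] - delta[iu]) ** 2) / denom)) if denom > 0 else 0.0
    mode = "negative_pearson" if literal_negative_corr else "one_minus_pearson"
    return Embedding(coords=coords, distance_mode=mode, stress=stress, kept=kept)


def state_speed(states_t: np.ndarray, states_next: np.ndarray) -> np.ndarray:
    """Energy proxy per state: Euclidean norm of the one-step displacement."""
    a = np.asarray(states_t, dtype=float)
    b = np.asarray(states_next, dtype=float)
    if a.shape != b.shape:
        raise ValueError("states_t and states_next must have matching shapes")
    return np.linalg.norm(b - a, axis=-1)


def evolve_states(
    states: np.ndarray,
    conn: Connectivity,
    params: NetworkParams,
    proj: InputProjection | None = None,
    drive: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministically advance each row one Euler step (noise off).

    Convenience for the energy landscape: given sampled states ``S x N``,
    returns the states one integration step later under the autonomous (or
    constantly driven) dynamics.
    """
    x = np.atleast_2d(np.asarray(states, dtype=float))
    h_ext = 0.0
    if proj is not None and drive is not None:
        h_ext = proj.weights.T @ np.asarray(drive, dtype=float)
    dx = (params.dt / params.tau) * (-x + np.tanh(x) @ conn.matrix.T + h_ext)
    return x + dx


def build_energy_landscape(
    embedding: Embedding,
    energies: np.ndarray,
    grid_size: int = 60,
    outlier_pct: float = 99.0,
    smooth_sigma: float = 1.0,
) -> EnergyLandscape:
    """Interpolate sampled energies onto a regular grid over the embedding.

    Energies above the ``outlier_pct`` percentile are discarded (singular
    fast states distort the color scale), the remainder are linearly
    interpolated over the sample bounding box, smoothed with a 2-D Gaussian
    kernel of ``smooth_sigma`` grid cells, and left NaN outside the convex
    hull of the samples.
    """
    coords = embedding.coords
    e = np.asarray(energies, dtype=float)
    if coords.shape[0] != e.shape[0]:
        raise ValueError("energies must align with embedded states")
    if coords.shape[0] < 4:
        raise DegenerateGeometryError("need >= 4 sample points")
    span = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-10 * max(1.0, np.abs(span).max())) < 2:
        raise DegenerateGeometryError("sample points are collinear")
    if outlier_pct is not None and outlier_pct < 100:
        thr = np.percentile(e, outlier_pct)
        keep = e <= thr
    else:
        keep = np.ones(e.size, dtype=bool)
    pts, vals = coords[keep], e[keep]
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    surface = griddata(pts, vals, (mx, my), method="linear")
    if smooth_sigma > 0:
        mask = np.isfinite(surface)
        filled = np.where(mask, surface, 0.0)
        num = gaussian_filter(filled, smooth_sigma, mode="reflect")
        den = gaussian_filter(mask.astype(float), smooth_sigma, mode="reflect")
        with np.errstate(invalid="ignore"):
            sm = np.where(den > 1e-12, num / den, np.nan)
        surface = np.where(mask, sm, np.nan)
    return EnergyLandscape(
        grid_x=gx, grid_y=gy, surface=surface, sample_coords=pts, sample_energy=vals
    )


def behavior_readout_pc2(tensor: TrialTensor, return_model: bool = False):
    """Second principal component of population activity, per trial.

    PCA is fitted once on the time-concatenated trials (neurons as
    variables) so the readout is comparable across trials; the PC2 score
    time course of each trial is returned as an ``N_T x T`` array.  The sign
    convention fixes the first nonzero loading of each component positive.
    Mirrors the observation that low-order PCs of large populations track
    global movement/state rather than the stimulus.
    """
    data = tensor.data
    n_t, n, t = data.shape
    x = np.moveaxis(data, 1, 2).reshape(n_t * t, n)  # samples x neurons
    rank = np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-10 * max(1.0, np.abs(x).max()))
    if rank < 2:
        raise DegenerateGeometryError("population activity has rank < 2")
    pca = PCA(n_components=2, svd_solver="full" if min(x.shape) < 500 else "randomized", random_state=0)
    scores = pca.fit_transform(x)
    for c in range(2):
        load = pca.components_[c]
        first = load[np.flatnonzero(np.abs(load) > 1e-12)[0]]
        if first < 0:
            pca.components_[c] *= -1
            scores[:, c] *= -1
    readout = scores[:, 1].reshape(n_t, t)
    return (readout, pca) if return_model else readout


def cluster_initial_states(readout: np.ndarray, rng: np.random.Generator) -> StateClusters:
    """Two-way k-means on per-trial pre-stimulus readout windows.

    ``readout`` is ``N_T x F`` (typically a 20-frame pre-stimulus window of
    the PC2 readout per trial).  Euclidean k-means with k=2, at most 100
    iterations and 10 restarts, best inertia kept; deterministic given the
    generator.  If all rows coincide the result is flagged degenerate.
    """
    x = np.atleast_2d(np.asarray(readout, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    if np.allclose(x, x[0]):
        return StateClusters(
            labels=np.zeros(x.shape[0], dtype=int),
            centroids=np.vstack([x[0], x[0]]),
            inertia=0.0,
            degenerate=True,
        )
    seed = int(rng.integers(2**31))
    km = KMeans(n_clusters=2, n_init=10, max_iter=100, random_state=seed)
    labels = km.fit_predict(x)
    return StateClusters(
        labels=labels, centroids=km.cluster_centers_, inertia=float(km.inertia_), degenerate=False
    )


def class_correlation(tensor, labels, window=None) -> tuple[float, float]:
    """Mean within-class vs across-class population-vector correlation.

    Trials are split by ``labels`` (e.g. the two initial-state clusters);
    returns the mean pairwise Pearson correlation of window-averaged
    population vectors within classes (``inner``) and across classes
    (``inter``).  A singleton class contributes no inner pairs; if no class
    has 2 trials the inner value is NaN.
    """
    labels = np.asarray(labels)
    pv = _population_vectors(tensor, window)
    if np.unique(labels).size < 2:
        raise ValueError("need two non-empty classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c = np.corrcoef(pv)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(pv.shape[0], k=1)
    inner_vals = c[iu][same[iu]]
    inter_vals = c[iu][~same[iu]]
    inner = float(np.nanmean(inner_vals)) if inner_vals.size else float("nan")
    inter = float(np.nanmean(inter_vals)) if inter_vals.size else float("nan")
    return inner, inter
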