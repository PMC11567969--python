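"""Population decoding: leave-one-trial-out KNN with three neuron/feature
selection sweeps (field-of-view radius, PCA dimensionality, and
reliability-ranked pools).

Each trial is one decoding unit: its feature vector concatenates the
activity of the selected neurons over a 1-s post-stimulus window
(``N_neuron x N_time`` elements).  The decoder is KNN (default K = 1,
Euclidean distance) under leave-one-trial-out cross-validation; ties in
distance are broken by lowest trial index, ties in the vote by lowest
label, so decoding is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .network import TrialTensor
from .variability import single_neuron_variance

__all__ = [
    "DecodingResult",
    "RankedSweep",
    "knn_loto",
    "fov_radius_sweep",
    "pca_dimension_sweep",
    "reliability_ranked_sweep",
]


@dataclass
class DecodingResult:
    """Accuracy, per-trial predictions, and optionally a sweep table."""

    accuracy: float
    per_trial_pred: np.ndarray
    sweep: pd.DataFrame | None = None


def _default_window(tensor: TrialTensor, window) -> tuple[int, int]:
    return tensor.post_window(1.0) if window is None else window


def _features(tensor: TrialTensor, window, neuron_subset) -> np.ndarray:
    a, b = _default_window(tensor, window)
    data = tensor.data[:, :, a:b]
    if neuron_subset is not None:
        neuron_subset = np.asarray(neuron_subset, dtype=int)
        if neuron_subset.size == 0:
            raise ValueError("empty neuron subset")
        data = data[:, neuron_subset, :]
    return data.reshape(data.shape[0], -1)


def _loto_predict(features: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    dist = cdist(features, features)
    np.fill_diagonal(dist, np.inf)
    preds = np.empty(labels.shape[0], dtype=labels.dtype)
    for j in range(labels.shape[0]):
        order = np.argsort(dist[j], kind="stable")  # stable sort -> lowest index on ties
        votes = labels[order[:k]]
        vals, counts = np.unique(votes, return_counts=True)
        preds[j] = vals[counts.argmax()]  # np.unique is sorted -> lowest label on vote ties
    return preds


def knn_loto(
    tensor: TrialTensor,
    window=None,
    neuron_subset=None,
    k: int = 1,
) -> DecodingResult:
    """Leave-one-trial-out KNN decoding of stimulus labels.

    Requires at least 2 trials per class so every held-out trial has a
    same-class neighbor available in principle.
    """
    labels = np.asarray(tensor.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need >= 2 trials per class for leave-one-trial-out")
    feats = _features(tensor, window, neuron_subset)
    preds = _loto_predict(feats, labels, k)
    return DecodingResult(accuracy=float(np.mean(preds == labels)), per_trial_pred=preds)


def fov_radius_sweep(
    tensor: TrialTensor,
    radii,
    center=None,
    window=None,
    k: int = 1,
) -> DecodingResult:
    """Decoding accuracy as the imaged field of view grows.

    Neurons within each radius of ``center`` (default: mean position) form
    the decoding pool; pools are nested, so the neuron count is
    non-decreasing in radius.  In a center-weighted input topology the curve
    typically rises while informative central neurons accumulate, then
    falls as peripheral noise neurons dilute the distance metric.  Radii
    that include no neurons yield NaN accuracy (flagged, not raised).
    """
    if tensor.neuron_positions is None:
        raise ValueError("tensor has no neuron positions")
    pos = np.asarray(tensor.neuron_positions, dtype=float)
    center = pos.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    d = np.linalg.norm(pos - center[None, :], axis=1)
    rows = []
    last = None
    for r in radii:
        subset = np.flatnonzero(d <= r)
        if subset.size == 0:
            rows.append({"radius": r, "n_neurons": 0, "accuracy": np.nan})
            continue
        res = knn_loto(tensor, window=window, neuron_subset=subset, k=k)
        last = res
        rows.append({"radius": r, "n_neurons": int(subset.size), "accuracy": res.accuracy})
    sweep = pd.DataFrame(rows)
    if last is None:
        raise ValueError("no radius contained any neuron")
    return DecodingResult(accuracy=last.accuracy, per_trial_pred=last.per_trial_pred, sweep=sweep)


def pca_dimension_sweep(
    tensor: TrialTensor,
    n_components_list,
    window=None,
    k: int = 1,
    global_fit: bool = False,
) -> DecodingResult:
    """Decoding accuracy against the number of principal components kept.

    By default the PCA basis is re-fitted on the training trials of every
    leave-one-out fold (leakage-safe); ``global_fit=True`` fits once on all
    trials instead.  Component counts above the feature rank are truncated
    with a warning.  Because principal subspaces are nested, each fold fits
    a single decomposition at the largest requested count and slices it.
    """
    labels = np.asarray(tensor.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need >= 2 trials per class")
    feats = _features(tensor, window, None)
    n_t = feats.shape[0]
    max_rank = min(n_t - 1, feats.shape[1])
    comps = sorted(set(int(m) for m in n_components_list))
    if comps[0] < 1:
        raise ValueError("component counts must be >= 1")
    if comps[-1] > max_rank:
        import warnings

        warnings.warn(f"component counts above rank {max_rank} truncated")
        comps = [m for m in comps if m <= max_rank] or [max_rank]
    m_max = comps[-1]

    if global_fit:
        pca = PCA(n_components=m_max, svd_solver="full", random_state=0).fit(feats)
        z = pca.transform(feats)
        acc = {}
        for m in comps:
            preds = _loto_predict(z[:, :m], labels, k)
            acc[m] = float(np.mean(preds == labels))
    else:
        preds_m = {m: np.empty(n_t, dtype=labels.dtype) for m in comps}
        for j in range(n_t):
            train = np.delete(np.arange(n_t), j)
            m_fit = min(m_max, train.size - 1)
            pca = PCA(n_components=m_fit, svd_solver="auto", random_state=0).fit(feats[train])
            z_tr = pca.transform(feats[train])
            z_te = pca.transform(feats[j : j + 1])
            for m in comps:
                mm = min(m, m_fit)
                dists = np.linalg.norm(z_tr[:, :mm] - z_te[:, :mm], axis=1)
                order = np.argsort(dists, kind="stable")
                votes = labels[train][order[:k]]
                vals, cnts = np.unique(votes, return_counts=True)
                preds_m[m][j] = vals[cnts.argmax()]
        acc = {m: float(np.mean(preds_m[m] == labels)) for m in comps}

    sweep = pd.DataFrame({"n_components": comps, "accuracy": [acc[m] for m in comps]})
    best_m = comps[-1]
    preds_final = preds_m[best_m] if not global_fit else None
    return DecodingResult(
        accuracy=acc[best_m],
        per_trial_pred=preds_final if preds_final is not None else np.array([]),
        sweep=sweep,
    )


@dataclass
class RankedSweep:
    """Reliability-ranked vs random neuron-pool decoding curves."""

    pool_sizes: np.ndarray
    ranked_accuracy: np.ndarray
    random_mean: np.ndarray
    random_std: np.ndarray
    order: np.ndarray  # neurons sorted by ascending evaluation-set variability


def _stratified_split(labels: np.ndarray, split_ratio: float, rng: np.random.Generator):
    eval_idx, dec_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_eval = int(round(split_ratio * idx.size))
        n_eval = min(max(n_eval, 2), idx.size - 2)
        eval_idx.extend(idx[:n_eval])
        dec_idx.extend(idx[n_eval:])
    return np.sort(np.array(eval_idx)), np.sort(np.array(dec_idx))


def _subset_tensor(tensor: TrialTensor, idx: np.ndarray) -> TrialTensor:
    return TrialTensor(
        data=tensor.data[idx],
        sample_rate=tensor.sample_rate,
        labels=np.asarray(tensor.labels)[idx],
        onset_idx=tensor.onset_idx,
        offset_idx=tensor.offset_idx,
        neuron_positions=tensor.neuron_positions,
    )


def reliability_ranked_sweep(
    tensor: TrialTensor,
    rng: np.random.Generator,
    split_ratio: float = 0.5,
    pool_sizes=None,
    n_random: int = 20,
    window=None,
    k: int = 1,
) -> RankedSweep:
    """Low-variability-first neuron selection vs random selection.

    Trials are split (class-stratified, disjoint) into a neuron *evaluation*
    set and a *decoding* set.  Per-neuron trial variability is measured on
    the evaluation set only and neurons are added to the decoding pool in
    ascending-variability order; decoding accuracy on the decoding set is
    compared with ``n_random`` random orderings at matched pool sizes.
    Measuring reliability on held-out trials prevents selection from leaking
    label information into the decoder.
    """
    labels = np.asarray(tensor.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 4:
        raise ValueError("need >= 4 trials per class to split into two usable sets")
    eval_idx, dec_idx = _stratified_split(labels, split_ratio, rng)
    eval_t = _subset_tensor(tensor, eval_idx)
    dec_t = _subset_tensor(tensor, dec_idx)
    w = _default_window(tensor, window)
    snv = single_neuron_variance(eval_t, window=w)
    snv = np.where(np.isfinite(snv), snv, np.inf)  # undefined -> least reliable
    order = np.argsort(snv, kind="stable")
    n = tensor.n_neurons
    if pool_sizes is None:
        pool_sizes = np.unique(np.round(np.geomspace(1, n, num=8)).astype(int))
    pool_sizes = np.asarray(sorted(set(int(p) for p in pool_sizes)))
    if pool_sizes[-1] > n or pool_sizes[0] < 1:
        raise ValueError("pool sizes must lie in [1, n_neurons]")
    ranked = np.array(
        [knn_loto(dec_t, window=w, neuron_subset=order[:p], k=k).accuracy for p in pool_sizes]
    )
    rand = np.empty((n_random, pool_sizes.size))
    for s in range(n_random):
        perm = rng.permutation(n)
        rand[s] = [knn_loto(dec_t, window=w, neuron_subset=perm[:p], k=k).accuracy for p in pool_sizes]
    return RankedSweep(
        pool_sizes=pool_sizes,
        ranked_accuracy=ranked,
        random_mean=rand.mean(axis=0),
        random_std=rand.std(axis=0),
        order=order,
    )
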