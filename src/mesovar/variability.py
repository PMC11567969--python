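"""Trial-to-trial variability statistics on trial tensors.

The central quantity is the normalized trial variance

    V = (1/N_T) * sum_j ||R_j - Rbar||_F^2 / ||Rbar||_F^2

where ``R_j`` is the neurons-x-time response matrix of trial ``j`` and
``Rbar`` the across-trial mean.  V is dimensionless, invariant to overall
rescaling of the responses, and undefined when the mean response is
identically zero — undefined values are raised or propagated as NaN, never
silently reported as 0.  The same statistic is evaluated per timepoint
(``V(t)``) and per neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.ndimage import gaussian_filter1d

from .network import TrialTensor

__all__ = [
    "VariabilityResult",
    "variability_summary",
    "SweepTable",
    "RelaxationFit",
    "preprocess_traces",
    "trial_variance",
    "timepoint_variance",
    "normalize_variability_trace",
    "single_neuron_variance",
    "population_vector_correlation",
    "functional_connectivity",
    "responsive_counts",
    "fit_relaxation_constants",
    "sweep_and_fit",
    "compute_osi",
]


class UndefinedVarianceError(ValueError):
    """Trial variance is undefined: the mean response has zero norm."""


def _as_array(tensor) -> np.ndarray:
    data = tensor.data if isinstance(tensor, TrialTensor) else np.asarray(tensor, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a TrialTensor or trials x neurons x time array")
    return data


def _window_slice(window, n_time: int) -> slice:
    if window is None:
        return slice(0, n_time)
    a, b = window
    if not 0 <= a < b <= n_time:
        raise ValueError(f"window {window} out of bounds for T={n_time}")
    return slice(a, b)


@dataclass
class VariabilityResult:
    """Bundle of the variability statistics over one analysis window."""

    v_total: float
    v_trace: np.ndarray
    per_neuron: np.ndarray
    window: tuple[int, int]


def variability_summary(tensor, window=None) -> VariabilityResult:
    """Total, per-frame and per-neuron trial variance over one window."""
    data = _as_array(tensor)
    if window is None:
        window = (0, data.shape[2])
    return VariabilityResult(
        v_total=trial_variance(tensor, window=window),
        v_trace=timepoint_variance(tensor, window=window),
        per_neuron=single_neuron_variance(tensor, window=window),
        window=tuple(window),
    )


def preprocess_traces(raw):
    """Linear detrend then z-score each neuron trace.

    Removes the slow photobleaching drift of fluorescence recordings and
    puts every trace on a common scale (mean 0, unit std).  Traces with zero
    residual variance map to all-zeros rather than dividing by zero.
    Accepts a TrialTensor (each trial trace handled separately), an N x T
    matrix, or a 1-D trace; returns the same shape/type.
    """
    if isinstance(raw, TrialTensor):
        return raw.with_data(preprocess_traces(raw.data))
    x = np.asarray(raw, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    flat = x.reshape(-1, x.shape[-1])
    det = signal.detrend(flat, axis=-1, type="linear")
    sd = det.std(axis=-1, keepdims=True)
    out = np.where(sd > 1e-12, det / np.where(sd > 0, sd, 1.0), 0.0)
    return out.reshape(x.shape)


def trial_variance(tensor, window=None) -> float:
    """Normalized across-trial variance V of the windowed responses."""
    data = _as_array(tensor)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    r = data[:, :, _window_slice(window, data.shape[2])]
    rbar = r.mean(axis=0)
    denom = float(np.sum(rbar**2))
    if denom == 0.0:
        raise UndefinedVarianceError("mean response has zero Frobenius norm")
    num = float(np.sum((r - rbar) ** 2)) / r.shape[0]
    return num / denom


def timepoint_variance(tensor, window=None) -> np.ndarray:
    """Time-resolved trial variance V(t), one value per frame.

    Frames whose mean population state is exactly zero are undefined and
    returned as NaN (propagated as missing, not as zero).
    """
    data = _as_array(tensor)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    r = data[:, :, _window_slice(window, data.shape[2])]
    rbar = r.mean(axis=0)  # N x T
    denom = np.sum(rbar**2, axis=0)  # per frame
    num = np.sum((r - rbar) ** 2, axis=(0, 1)) / r.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return v


def normalize_variability_trace(
    trace: np.ndarray, baseline_window: tuple[int, int], smoothing_sigma: float = 0.0
) -> np.ndarray:
    """Subtract the pre-stimulus baseline mean, then Gaussian-smooth.

    ``smoothing_sigma`` is in frames; 0 disables smoothing.  Smoothing uses
    reflect padding so a constant trace stays constant.
    """
    trace = np.asarray(trace, dtype=float)
    a, b = baseline_window
    if not 0 <= a < b <= trace.shape[-1]:
        raise ValueError("empty or out-of-range baseline window")
    out = trace - np.nanmean(trace[..., a:b], axis=-1, keepdims=True)
    if smoothing_sigma > 0:
        out = gaussian_filter1d(out, smoothing_sigma, axis=-1, mode="reflect")
    return out


def single_neuron_variance(tensor, window=None) -> np.ndarray:
    """Per-neuron trial variance: V restricted to each neuron's 1 x T block.

    Neurons whose mean trace is identically zero get NaN.
    """
    data = _as_array(tensor)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    r = data[:, :, _window_slice(window, data.shape[2])]
    rbar = r.mean(axis=0)  # N x T
    denom = np.sum(rbar**2, axis=1)  # per neuron
    num = np.sum((r - rbar) ** 2, axis=(0, 2)) / r.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)


def _population_vectors(tensor, window) -> np.ndarray:
    data = _as_array(tensor)
    return data[:, :, _window_slice(window, data.shape[2])].mean(axis=2)  # trials x neurons


def population_vector_correlation(tensor, window=None) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlation of window-averaged population vectors.

    Returns the full trial x trial correlation matrix (NaN where a vector
    has zero variance) and the mean over unordered trial pairs.
    """
    pv = _population_vectors(tensor, window)
    if pv.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    sd = pv.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c = np.corrcoef(pv)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, 1.0)
    iu = np.triu_indices(pv.shape[0], k=1)
    return c, float(np.nanmean(c[iu]))


def functional_connectivity(tensor, window=None) -> np.ndarray:
    """Neuron-pair Pearson correlations within the window, trial-averaged.

    Rows/columns of neurons that are constant within a trial are NaN for
    that trial and excluded from the average; the diagonal is 1.
    """
    data = _as_array(tensor)
    w = _window_slice(window, data.shape[2])
    if w.stop - w.start < 3:
        raise ValueError("window length must be >= 3")
    mats = []
    for j in range(data.shape[0]):
        x = data[j][:, w]
        sd = x.std(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c = np.corrcoef(x)
        c[sd == 0, :] = np.nan
        c[:, sd == 0] = np.nan
        mats.append(c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fc = np.nanmean(np.stack(mats), axis=0)
    np.fill_diagonal(fc, 1.0)
    return fc


def responsive_counts(
    tensor,
    threshold: float = 1.96,
    max_trials: int = 6,
    window=None,
    quantile: float | None = None,
) -> np.ndarray:
    """Number of neurons responsive in at least m of the first ``max_trials`` trials.

    A neuron is responsive on a trial when the absolute mean of its
    post-onset response exceeds ``threshold`` (z-units; traces are assumed
    preprocessed).  With ``quantile=q`` the threshold is instead the
    per-trial top/bottom ``q`` quantile rule.  ``counts[m-1]`` is the number
    of neurons responsive in >= m trials; the sequence is non-increasing.
    """
    data = _as_array(tensor)
    if isinstance(tensor, TrialTensor) and window is None:
        window = tensor.post_window(1.0)
    if max_trials > data.shape[0]:
        raise ValueError("max_trials exceeds trial count")
    resp = data[:max_trials, :, _window_slice(window, data.shape[2])].mean(axis=2)  # trials x neurons
    if quantile is not None:
        lo = np.quantile(resp, quantile, axis=1, keepdims=True)
        hi = np.quantile(resp, 1 - quantile, axis=1, keepdims=True)
        hits = (resp <= lo) | (resp >= hi)
    else:
        hits = np.abs(resp) > threshold
    n_hits = hits.sum(axis=0)
    return np.array([(n_hits >= m).sum() for m in range(1, max_trials + 1)])


@dataclass
class RelaxationFit:
    """Exponential time constants of a variability trace around a stimulus."""

    tau_descent: float
    tau_rise: float
    descent_ok: bool
    rise_ok: bool
    diagnostics: dict


def _fit_exponential(
    seg: np.ndarray, dt: float, asymptote: float | None = None
) -> tuple[float, bool, float]:
    """Least-squares fit of ``a + b*exp(-t/tau)``; multi-start over tau.

    With ``asymptote`` given, ``a`` is pinned to it and only (b, tau) are
    fitted — needed when the segment ends well before saturation, where a
    free asymptote leaves tau unidentifiable.
    """
    t = np.arange(seg.size) * dt
    span = max(seg.size * dt, dt)

    def resid(p):
        if asymptote is None:
            a, b, tau = p
        else:
            a, (b, tau) = asymptote, p
        return a + b * np.exp(-t / tau) - seg

    best = None
    a0 = seg[-1] if asymptote is None else asymptote
    b0 = seg[0] - a0
    for tau0 in (0.1 * span, 0.3 * span, span):
        x0 = [a0, b0, tau0] if asymptote is None else [b0, tau0]
        lo = [-np.inf] * (len(x0) - 1) + [dt / 10.0]
        hi = [np.inf] * (len(x0) - 1) + [10.0 * span]
        try:
            res = optimize.least_squares(resid, x0=x0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return np.nan, False, np.nan
    tau = float(best.x[-1])
    ss_res = 2 * best.cost
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return tau, bool(best.success), r2


def fit_relaxation_constants(
    trace: np.ndarray,
    onset_idx: int,
    offset_idx: int,
    sample_rate: float,
    rise_asymptote: float | None = None,
    descent_asymptote: float | None = None,
) -> RelaxationFit:
    """Descent/rise time constants of V(t) around a stimulus.

    Fits ``a + b*exp(-t/tau)`` separately to the onset->offset descent of
    the variability trace (convergence toward the stimulus attractor) and
    to the post-offset rise back to baseline.  Because the inter-trial
    process is stationary, the rise recovers toward the pre-stimulus
    baseline; passing that baseline as ``rise_asymptote`` pins the fit's
    plateau, which keeps tau identifiable when the recording ends before
    the recovery saturates.  Non-convergent fits are flagged, not raised.
    """
    trace = np.asarray(trace, dtype=float)
    dt = 1.0 / sample_rate
    descent = trace[onset_idx:offset_idx]
    rise = trace[offset_idx:]
    if descent.size < 5 or rise.size < 5:
        raise ValueError("need >= 5 points in each fit segment")
    tau_d, ok_d, r2_d = _fit_exponential(descent, dt, asymptote=descent_asymptote)
    # the rise is a saturating increase: same model, negative b, same tau meaning
    tau_r, ok_r, r2_r = _fit_exponential(rise, dt, asymptote=rise_asymptote)
    return RelaxationFit(
        tau_descent=tau_d,
        tau_rise=tau_r,
        descent_ok=ok_d,
        rise_ok=ok_r,
        diagnostics={"r2_descent": r2_d, "r2_rise": r2_r},
    )


@dataclass
class SweepTable:
    """Log-linear fit of trial variance against a stimulation factor."""

    rows: pd.DataFrame  # columns: factor, v_total, seed
    slope: float
    intercept: float
    r_squared: float


def sweep_and_fit(results) -> SweepTable:
    """Ordinary least squares of ln(V) on a stimulation factor.

    ``results`` is an iterable of ``(factor, v_total)`` or
    ``(factor, v_total, seed)`` rows (or a mapping factor -> V).  Rows with
    V <= 0 are excluded with a warning since ln(V) is undefined there.
    """
    if isinstance(results, dict):
        rows = [(k, v, 0) for k, v in results.items()]
    else:
        rows = [tuple(r) if len(r) == 3 else (r[0], r[1], 0) for r in results]
    df = pd.DataFrame(rows, columns=["factor", "v_total", "seed"])
    bad = df["v_total"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} rows with V <= 0 from log-linear fit")
        df = df[~bad]
    if df["factor"].nunique() < 3:
        raise ValueError("need >= 3 distinct factor levels")
    fit = stats.linregress(df["factor"], np.log(df["v_total"]))
    return SweepTable(
        rows=df.reset_index(drop=True),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def compute_osi(tensor, window=None, rectify: bool = True) -> np.ndarray:
    """Orientation selectivity index per neuron.

    Stimulus classes are treated as orientations equally spaced over 180°,
    so with K classes the orthogonal orientation of class ``c`` is class
    ``(c + K//2) % K``.  OSI = (r_pref - r_orth) / (r_pref + r_orth) on
    trial-mean responses, rectified to nonnegative by default (OSI then lies
    in [0, 1]).  Neurons with r_pref + r_orth == 0 are NaN.
    """
    if not isinstance(tensor, TrialTensor):
        raise ValueError("compute_osi needs a TrialTensor with labels")
    classes = np.unique(tensor.labels)
    k = classes.size
    if k < 2:
        raise ValueError("need >= 2 orientation classes")
    if window is None:
        window = (tensor.onset_idx, tensor.offset_idx)
    w = _window_slice(window, tensor.n_time)
    resp = tensor.data[:, :, w].mean(axis=2)  # trials x neurons
    if rectify:
        resp = np.clip(resp, 0.0, None)
    class_mean = np.stack([resp[tensor.labels == c].mean(axis=0) for c in classes])  # K x N
    pref = class_mean.argmax(axis=0)
    orth = (pref + k // 2) % k
    n_idx = np.arange(class_mean.shape[1])
    r_pref = class_mean[pref, n_idx]
    r_orth = class_mean[orth, n_idx]
    denom = r_pref + r_orth
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = np.where(denom > 0, (r_pref - r_orth) / np.where(denom > 0, denom, 1.0), np.nan)
    return osi
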