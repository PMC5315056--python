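"""Nuisance regressor construction and simultaneous high-pass + regression.

Physiological denoising follows the retrospective image-correction approach:
each slice is assigned a cardiac phase (position within the current heart
beat) and a respiratory phase (amplitude-histogram phase with slope sign),
and Fourier expansions of these phases form slice-specific regressors.
Auxiliary regressors (CSF signal, heart rate, motion, task) and the
discrete-cosine high-pass basis enter the same ordinary-least-squares
design, so filtering and noise regression happen simultaneously and no
spectral misspecification is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


class PhysioError(ValueError):
    pass


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# slice timing
# ---------------------------------------------------------------------------

def slice_times(trigger_times, tr: float, n_slices: int) -> np.ndarray:
    """Acquisition time of each slice in each volume, shape (n_slices, T).

    Slices are assumed acquired in ascending order, evenly spread over the
    TR; slice s of volume k is stamped at ``trigger_k + (s + 0.5) * TR / S``.
    """
    trigger_times = np.asarray(trigger_times, dtype=float)
    offsets = (np.arange(n_slices) + 0.5) * tr / n_slices
    return trigger_times[None, :] + offsets[:, None]


# ---------------------------------------------------------------------------
# cardiac / respiratory phase
# ---------------------------------------------------------------------------

def detect_beats(trace, fs: float, min_interval_s: float = 0.3) -> np.ndarray:
    """Beat times (s) from local-maximum detection on the cardiac trace."""
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) == 0:
        raise PhysioError("cardiac trace is constant; no beats detectable")
    idx, _ = sps.find_peaks(trace, distance=max(1, int(min_interval_s * fs)),
                            prominence=0.2 * np.ptp(trace))
    if idx.size < 2:
        raise PhysioError("fewer than 2 beats detected on the cardiac trace")
    return idx / fs


def cardiac_phase(physio, times) -> np.ndarray:
    """Cardiac phase in [0, 2*pi) at the given acquisition times.

    theta_c(t) = 2*pi*(t - t_k)/(t_{k+1} - t_k) for t in [t_k, t_{k+1}),
    with beats detected on the recorded pulse trace.  Times before the
    first / after the last beat use the nearest interval's period.
    """
    beats = detect_beats(physio.cardiac, physio.fs)
    times = np.asarray(times, dtype=float)
    k = np.searchsorted(beats, times, side="right") - 1
    k = np.clip(k, 0, beats.size - 2)
    t0 = beats[k]
    period = beats[k + 1] - beats[k]
    frac = (times - t0) / period
    return 2 * np.pi * np.mod(frac, 1.0)


def respiratory_phase(physio, times) -> np.ndarray:
    """Respiratory phase in (-pi, pi] at the given acquisition times.

    theta_r = pi * H(|a(t)|) * sign(da/dt), where H is the normalized
    cumulative histogram of absolute respiratory amplitude over the whole
    run (computed here as the empirical CDF, i.e. the infinitesimal-bin
    limit of the histogram).
    """
    r = np.asarray(physio.resp, dtype=float)
    if np.ptp(r) == 0:
        raise PhysioError("respiratory trace is constant")
    times = np.asarray(times, dtype=float)
    t_grid = np.arange(r.size) / physio.fs
    amp = np.interp(times, t_grid, r)
    slope_grid = np.gradient(r, 1.0 / physio.fs)
    slope = np.interp(times, t_grid, slope_grid)
    sorted_abs = np.sort(np.abs(r))
    frac = np.searchsorted(sorted_abs, np.abs(amp), side="right") / r.size
    sgn = np.where(slope >= 0, 1.0, -1.0)
    return np.pi * frac * sgn


@dataclass
class PhysioPhases:
    """Cardiac / respiratory phase per slice per volume, shape (S, T)."""

    theta_c: np.ndarray
    theta_r: np.ndarray

    def __post_init__(self):
        self.theta_c = np.asarray(self.theta_c, dtype=float)
        self.theta_r = np.asarray(self.theta_r, dtype=float)
        if self.theta_c.shape != self.theta_r.shape:
            raise DesignError("phase arrays must share shape (n_slices, T)")
        if not (np.all(np.isfinite(self.theta_c)) and np.all(np.isfinite(self.theta_r))):
            raise DesignError("non-finite phases")


def compute_phases(physio, tr: float, n_slices: int) -> PhysioPhases:
    st = slice_times(physio.trigger_times, tr, n_slices)
    return PhysioPhases(theta_c=cardiac_phase(physio, st),
                        theta_r=respiratory_phase(physio, st))


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------

def retroicor_n_columns(cardiac_order: int, resp_order: int, interaction_order: int) -> int:
    return 2 * cardiac_order + 2 * resp_order + 4 * interaction_order ** 2


def build_retroicor(phases: PhysioPhases, cardiac_order: int = 4,
                    resp_order: int = 4, interaction_order: int = 2):
    """Slice-specific Fourier regressor set, shape (S, T, P).

    Columns: sin/cos(m*theta_c) for m=1..cardiac_order, sin/cos(n*theta_r)
    for n=1..resp_order, then sin/cos(m*theta_c + n*theta_r) and
    sin/cos(m*theta_c - n*theta_r) for m,n=1..interaction_order.  The
    default orders (4, 4, 2) give the standard 32-regressor set.
    """
    tc, tr_ = phases.theta_c, phases.theta_r
    cols, labels = [], []
    for m in range(1, cardiac_order + 1):
        cols += [np.sin(m * tc), np.cos(m * tc)]
        labels += [f"c{m}_sin", f"c{m}_cos"]
    for n in range(1, resp_order + 1):
        cols += [np.sin(n * tr_), np.cos(n * tr_)]
        labels += [f"r{n}_sin", f"r{n}_cos"]
    for m in range(1, interaction_order + 1):
        for n in range(1, interaction_order + 1):
            for sgn, tag in ((1, "p"), (-1, "m")):
                arg = m * tc + sgn * n * tr_
                cols += [np.sin(arg), np.cos(arg)]
                labels += [f"x{m}{tag}{n}_sin", f"x{m}{tag}{n}_cos"]
    if not cols:
        S, T = tc.shape
        return np.zeros((S, T, 0)), []
    mat = np.stack(cols, axis=-1)  # (S, T, P)
    assert mat.shape[-1] == retroicor_n_columns(cardiac_order, resp_order,
                                                interaction_order)
    return mat, labels


def build_highpass_basis(n_volumes: int, tr: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Discrete-cosine high-pass basis, shape (T, K).

    K = floor(2 * T * TR / cutoff); column k has frequency k / (2 * T * TR),
    strictly below 1/cutoff.  Returns zero columns (with a warning) when the
    cutoff period exceeds the run length.
    """
    if cutoff_s <= 2 * tr:
        raise DesignError("high-pass cutoff must exceed 2*TR")
    duration = n_volumes * tr
    K = int(np.floor(2 * duration / cutoff_s))
    if K <= 0:
        warnings.warn("high-pass cutoff longer than the run; no basis columns")
        return np.zeros((n_volumes, 0))
    t = np.arange(n_volumes)
    basis = np.stack([np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
                      for k in range(1, K + 1)], axis=1)
    return basis


def heart_rate_column(physio, times, smooth_beats: int = 6) -> np.ndarray:
    """Smoothed instantaneous beats-per-minute sampled at the given times.

    Instantaneous BPM (60 / inter-beat interval, stamped at interval
    midpoints) is moving-averaged over ``smooth_beats`` intervals and
    linearly interpolated.
    """
    beats = detect_beats(physio.cardiac, physio.fs)
    intervals = np.diff(beats)
    bpm = 60.0 / intervals
    mid = 0.5 * (beats[:-1] + beats[1:])
    if bpm.size >= smooth_beats:
        kernel = np.ones(smooth_beats) / smooth_beats
        smoothed = np.convolve(bpm, kernel, mode="same")
        # fix edge bias of 'same' convolution with a running mean
        counts = np.convolve(np.ones_like(bpm), kernel, mode="same")
        smoothed = smoothed / counts
    else:
        smoothed = np.full_like(bpm, bpm.mean())
    return np.interp(np.asarray(times, dtype=float), mid, smoothed)


def csf_column(data4d: np.ndarray, region_slice_mask: np.ndarray,
               percentile: float = 90.0) -> np.ndarray:
    """Mean time course of the top-variance voxels within a region.

    Voxels whose temporal variance lies at or above the given percentile
    (top 10 percent by default) of the region's variance distribution are
    averaged.  ``data4d`` is (x, y, T) for one slice; the mask is (x, y).
    """
    vox = data4d[region_slice_mask]  # (V, T)
    if vox.shape[0] == 0:
        raise DesignError("empty CSF/cord region on slice")
    var = vox.var(axis=1)
    if np.all(var == 0):
        raise DesignError("zero-variance CSF/cord region")
    thr = np.percentile(var, percentile)
    sel = var >= thr
    return vox[sel].mean(axis=0)


def hrf_double_gamma(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak ~5 s, undershoot ~15 s)."""
    from scipy.stats import gamma as gamma_dist
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    h[t < 0] = 0.0
    return h


def task_column(event_times, times) -> np.ndarray:
    """Unit impulses at event times convolved with the canonical HRF."""
    times = np.asarray(times, dtype=float)
    col = np.zeros_like(times)
    for ev in np.asarray(event_times, dtype=float):
        col += hrf_double_gamma(times - ev)
    return col


def build_pca_regressors(slice_data: np.ndarray, slice_mask: np.ndarray,
                         n_components: int) -> np.ndarray:
    """First principal-component time courses of a slice's masked voxels.

    ``slice_data`` is (x, y, T); the returned components are unit-norm,
    mutually orthogonal time series, shape (T, n).  If the mask holds fewer
    voxels than requested, all available components are returned with a
    warning.
    """
    vox = slice_data[slice_mask]  # (V, T)
    if vox.shape[0] == 0:
        raise DesignError("empty mask for PCA regressors")
    X = vox - vox.mean(axis=1, keepdims=True)
    n_avail = min(X.shape)
    if n_avail < n_components:
        warnings.warn(f"only {n_avail} PCA components available "
                      f"({n_components} requested)")
    n = min(n_components, n_avail)
    # right singular vectors = component time courses
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    comps = vt[:n].T  # (T, n)
    # deterministic sign: largest-magnitude element positive
    for j in range(comps.shape[1]):
        k = np.argmax(np.abs(comps[:, j]))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    return comps


# ---------------------------------------------------------------------------
# design assembly and regression
# ---------------------------------------------------------------------------

@dataclass
class NuisanceDesign:
    """Per-slice regressor matrix with labelled columns.

    ``matrix`` has shape (S, T, P) (or (T, P) for a single slice);
    ``labels`` has length P; ``n_highpass`` columns at the front (after the
    intercept handled by :func:`regress_nuisance`) form the cosine basis.
    """

    matrix: np.ndarray
    labels: list = field(default_factory=list)
    n_highpass: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim == 2:
            self.matrix = self.matrix[None]
        if self.matrix.shape[-1] != len(self.labels):
            raise DesignError("label count does not match column count")
        flat = self.matrix.reshape(-1, self.matrix.shape[-1])
        if flat.shape[1] and np.any(np.all(flat == 0, axis=0)):
            bad = [self.labels[j] for j in
                   np.nonzero(np.all(flat == 0, axis=0))[0]]
            raise DesignError(f"all-zero design columns: {bad}")

    def for_slice(self, s: int) -> np.ndarray:
        return self.matrix[s]

    def to_tsv(self, path, slice_index: int = 0):
        import pandas as pd
        pd.DataFrame(self.matrix[slice_index], columns=self.labels).to_csv(
            path, sep="\t", index=False)


def regress_nuisance(series: np.ndarray, design: np.ndarray,
                     add_intercept: bool = True) -> np.ndarray:
    """OLS residuals of time series against a design matrix.

    ``series`` is (T,) or (T, V); ``design`` is (T, P).  An intercept is
    prepended unless disabled.  Rank-deficient designs are handled by the
    minimum-norm least-squares solution (equivalent to dropping collinear
    columns) with a warning; residuals are orthogonal to the design's
    column space either way.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DesignError("design rows must equal series length")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(f"rank-deficient design ({rank}/{X.shape[1]}); "
                      "collinear columns effectively dropped")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid[:, 0] if squeeze else resid
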