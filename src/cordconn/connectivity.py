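"""Horn time-course extraction and connectivity indices.

Connectivity between the four gray-matter horns is summarized as four
indices: dorsal-dorsal (DD), ventral-ventral (VV), within-hemicord
dorsal-ventral (W, mean of LD-LV and RD-RV) and between-hemicord
dorsal-ventral (B, mean of LD-RV and RD-LV), computed from full Pearson
correlation, partial correlation (from the inverse sample correlation
matrix), or L1-regularized partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .images import HORNS, Fmri4D

INDICES = ("DD", "VV", "W", "B")


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricSpec:
    """Connectivity metric: FULL, PARTIAL, or REGPARTIAL (penalty weight lam).

    For REGPARTIAL the off-diagonal L1 penalty on the precision matrix is
    lam / T (T = number of time points), a scale-free convention on
    standardized series; lam -> 0 recovers PARTIAL.
    """

    metric: str = "FULL"
    lam: float = 5.0

    def __post_init__(self):
        if self.metric not in ("FULL", "PARTIAL", "REGPARTIAL"):
            raise MetricError(f"unknown metric {self.metric!r}")
        if self.lam < 0:
            raise MetricError("lam must be >= 0")


@dataclass
class CorrelationSet:
    """The four horn-to-horn indices plus laterality differences."""

    r_dd: float
    r_vv: float
    r_w: float
    r_b: float
    w_diff: float
    b_diff: float
    matrix: pd.DataFrame = None

    def as_series(self) -> pd.Series:
        return pd.Series({"DD": self.r_dd, "VV": self.r_vv, "W": self.r_w,
                          "B": self.r_b, "W_diff": self.w_diff,
                          "B_diff": self.b_diff})


def extract_timecourses(data, masks) -> pd.DataFrame:
    """Unweighted mean time course over all mask voxels, per horn.

    Returns a (4, T) DataFrame indexed LD, LV, RD, RV.
    """
    arr = data.data if isinstance(data, Fmri4D) else np.asarray(data)
    rows = {}
    for h in HORNS:
        m = np.asarray(masks[h], dtype=bool)
        if not m.any():
            raise MetricError(f"horn mask {h} is empty")
        rows[h] = arr[m].mean(axis=0)
    return pd.DataFrame(rows).T.loc[list(HORNS)]


def bandpass_filter(ts, low_hz: float = 0.01, high_hz: float = 0.08,
                    tr: float = 1.89, order: int = 4):
    """Zero-phase 4th-order Butterworth band-pass along the time axis.

    ``ts`` is (..., T); the pass-band must lie inside (0, Nyquist).
    """
    nyq = 1.0 / (2.0 * tr)
    if not (0 < low_hz < high_hz < nyq):
        raise MetricError(f"pass-band ({low_hz}, {high_hz}) Hz outside (0, {nyq:.4f})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=1.0 / tr, output="sos")
    values = ts.to_numpy() if isinstance(ts, pd.DataFrame) else np.asarray(ts, dtype=float)
    out = sps.sosfiltfilt(sos, values, axis=-1)
    if isinstance(ts, pd.DataFrame):
        return pd.DataFrame(out, index=ts.index, columns=ts.columns)
    return out


def _standardize(ts: np.ndarray) -> np.ndarray:
    sd = ts.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise MetricError("constant time series; correlation undefined")
    return (ts - ts.mean(axis=1, keepdims=True)) / sd


def _partial_from_precision(P: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def connectivity_matrix(ts, spec: MetricSpec = MetricSpec()) -> pd.DataFrame:
    """4x4 horn-to-horn connectivity matrix for the requested metric.

    FULL: Pearson correlations.  PARTIAL: rho_ij = -P_ij / sqrt(P_ii P_jj)
    with P the inverse of the sample correlation matrix (the correlation of
    each pair after regressing out the remaining two horns).  REGPARTIAL:
    the same transform applied to the graphical-lasso precision estimate
    with off-diagonal penalty lam / T.
    """
    if isinstance(ts, pd.DataFrame):
        labels = list(ts.index)
        values = ts.to_numpy(dtype=float)
    else:
        values = np.asarray(ts, dtype=float)
        labels = list(HORNS)
    if values.ndim != 2 or values.shape[0] != 4:
        raise MetricError("expected a 4 x T time-course matrix")
    T = values.shape[1]
    if T <= 4:
        raise MetricError("need more than 4 time points")
    Z = _standardize(values)
    C = np.corrcoef(Z)
    if spec.metric == "FULL":
        out = C
    elif spec.metric == "PARTIAL":
        if np.linalg.cond(C) > 1e12:
            raise MetricError("singular correlation matrix; consider REGPARTIAL")
        out = _partial_from_precision(np.linalg.inv(C))
    else:  # REGPARTIAL
        from sklearn.covariance import graphical_lasso
        alpha = spec.lam / T
        if alpha == 0:
            out = _partial_from_precision(np.linalg.inv(C))
        else:
            with warnings.catch_warnings():
                # tiny residual dual gaps are irrelevant at our 4x4 scale
                warnings.simplefilter("ignore")
                _, precision = graphical_lasso(C, alpha=alpha, max_iter=500,
                                               tol=1e-6)
            out = _partial_from_precision(precision)
    out = np.clip(out, -1.0, 1.0)
    return pd.DataFrame(out, index=labels, columns=labels)


def summarize(matrix) -> CorrelationSet:
    """Collapse a labelled 4x4 matrix into the four indices + laterality.

    W averages (LD,LV) and (RD,RV); B averages (LD,RV) and (RD,LV).
    W_diff = (LD,LV) - (RD,RV); B_diff = (RV,LD) - (RD,LV) (positive means
    left-dorsal-with-left-ventral resp. right-ventral-with-left-dorsal is
    the stronger of the averaged pair).
    """
    if not isinstance(matrix, pd.DataFrame) or set(matrix.index) != set(HORNS):
        raise MetricError("matrix must be a DataFrame labelled with LD, LV, RD, RV")
    g = matrix.loc
    return CorrelationSet(
        r_dd=float(g["LD", "RD"]),
        r_vv=float(g["LV", "RV"]),
        r_w=float((g["LD", "LV"] + g["RD", "RV"]) / 2.0),
        r_b=float((g["LD", "RV"] + g["RD", "LV"]) / 2.0),
        w_diff=float(g["LD", "LV"] - g["RD", "RV"]),
        b_diff=float(g["RV", "LD"] - g["RD", "LV"]),
        matrix=matrix,
    )


def group_average(values) -> float:
    """Plain arithmetic mean of per-subject correlations (no Fisher z).

    The plain mean carries a small conservative (downward) bias relative to
    the Fisher-z-averaged mean, which is preferred here.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise MetricError("need at least one value")
    return float(values.mean())


@dataclass
class TSNRReport:
    """Voxel-wise temporal SNR map plus per-horn (x segment) summaries."""

    tsnr_map: np.ndarray
    table: pd.DataFrame = None  # rows horn, cols segment -> mean tSNR


def compute_tsnr(data, masks=None, segments: dict = None) -> TSNRReport:
    """tSNR = temporal mean / temporal sd per voxel (0 where sd is 0).

    If ``masks`` (a horn mask set) is given, per-horn means are tabulated;
    with ``segments`` (name -> binary mask) additionally per segment.
    """
    arr = data.data if isinstance(data, Fmri4D) else np.asarray(data)
    mean = arr.mean(axis=-1)
    sd = arr.std(axis=-1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} voxels with zero temporal sd; tSNR set to 0")
    tsnr = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd))
    table = None
    if masks is not None:
        seg_items = list(segments.items()) if segments else [("whole", None)]
        rows = {}
        for h in HORNS:
            rows[h] = {}
            for seg_name, seg_mask in seg_items:
                m = np.asarray(masks[h], dtype=bool)
                if seg_mask is not None:
                    m = m & np.asarray(seg_mask, dtype=bool)
                rows[h][seg_name] = float(tsnr[m].mean()) if m.any() else np.nan
        table = pd.DataFrame(rows).T
    return TSNRReport(tsnr_map=tsnr, table=table)


def group_tsnr(reports: list) -> pd.DataFrame:
    """Group mean and standard error of per-subject tSNR summary tables."""
    stacked = np.stack([r.table.to_numpy() for r in reports])
    mean = stacked.mean(axis=0)
    sem = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0]) \
        if stacked.shape[0] > 1 else np.zeros_like(mean)
    t0 = reports[0].table
    out = {}
    for j, col in enumerate(t0.columns):
        out[f"{col}_mean"] = mean[:, j]
        out[f"{col}_sem"] = sem[:, j]
    return pd.DataFrame(out, index=t0.index)
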