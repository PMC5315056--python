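"""Shared preprocessing: base denoising and per-subject pipeline assets.

The base design applied to every subject combines, per slice, the
discrete-cosine high-pass basis (100 s cutoff), the 32 cardiac/respiratory
Fourier regressors, the top-variance CSF signal, smoothed heart rate, x/y
motion and the task regressor, in a single OLS fit (filtering and noise
regression are simultaneous).  Analysis-pipeline variants then add optional
slice-wise nuisance regressors (WM mean, 4 CSF principal components,
10 non-spinal principal components) on top of the base residuals.

Because all per-slice operations are linear, an ROI mean over many slices
equals the voxel-count-weighted combination of per-slice ROI means; the
pipeline therefore carries per-slice horn means rather than full volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nuisance as nuis
from .images import HORNS, Fmri4D
from .masks import HornMaskSet, build_ns_mask, build_wm_mask
from .connectivity import (MetricSpec, bandpass_filter, connectivity_matrix,
                           summarize)


def build_base_design(fmri: Fmri4D, atlas, physio, task_times,
                      cutoff_s: float = 100.0,
                      orders=(4, 4, 2)) -> nuis.NuisanceDesign:
    """Per-slice base design: HP basis + Fourier set + CSF + HR + motion + task."""
    S, T = fmri.n_slices, fmri.n_volumes
    st = nuis.slice_times(physio.trigger_times, fmri.tr, S)
    phases = nuis.PhysioPhases(theta_c=nuis.cardiac_phase(physio, st),
                               theta_r=nuis.respiratory_phase(physio, st))
    retro, retro_labels = nuis.build_retroicor(phases, *orders)
    hp = nuis.build_highpass_basis(T, fmri.tr, cutoff_s)
    region = (atlas.cord + atlas.csf) >= 0.5
    hr = nuis.heart_rate_column(physio, st)             # (S, T)
    motion = physio.motion if physio.motion is not None else np.zeros((T, 2))
    task = nuis.task_column(task_times, st) if task_times is not None and \
        len(task_times) else None
    if task is None:
        warnings.warn("no task events; task regressor dropped")
    cols, labels = [], []
    K = hp.shape[1]
    mats = []
    for s in range(S):
        csf_col = nuis.csf_column(fmri.data[:, :, s, :], region[:, :, s])
        parts = [np.broadcast_to(hp.T, (K, T)), retro[s].T,
                 csf_col[None, :], hr[s][None, :], motion.T]
        if task is not None:
            parts.append(task[s][None, :])
        mats.append(np.concatenate(parts, axis=0).T)    # (T, P)
    labels = [f"hp{k + 1}" for k in range(K)] + retro_labels + \
        ["csf", "hr", "motion_x", "motion_y"] + (["task"] if task is not None else [])
    return nuis.NuisanceDesign(matrix=np.stack(mats), labels=labels, n_highpass=K)


def denoise(fmri: Fmri4D, atlas, physio, task_times=None,
            cutoff_s: float = 100.0, add_mean: bool = False) -> Fmri4D:
    """Base-design OLS residuals, slice by slice, over the whole volume."""
    design = build_base_design(fmri, atlas, physio, task_times, cutoff_s)
    out = np.empty_like(fmri.data, dtype=float)
    nx, ny = fmri.data.shape[:2]
    for s in range(fmri.n_slices):
        Y = fmri.data[:, :, s, :].reshape(nx * ny, -1).T       # (T, V)
        resid = nuis.regress_nuisance(Y, design.for_slice(s))
        out[:, :, s, :] = resid.T.reshape(nx, ny, -1)
    if add_mean:
        out += fmri.data.mean(axis=-1, keepdims=True)
    return Fmri4D(data=out, voxel_size=fmri.voxel_size, tr=fmri.tr)


@dataclass
class NuisanceBank:
    """Optional slice-wise nuisance regressors for pipeline variants.

    wm: (S, T, 1) mean white-matter series; csf_pcs: (S, T, 4); ns_pcs:
    (S, T, 10), all computed from the base residuals.
    """

    wm: np.ndarray
    csf_pcs: np.ndarray
    ns_pcs: np.ndarray

    def columns(self, which, s: int) -> np.ndarray:
        parts = []
        if "WM" in which:
            parts.append(self.wm[s])
        if "CSF" in which:
            parts.append(self.csf_pcs[s])
        if "NS" in which:
            parts.append(self.ns_pcs[s])
        if not parts:
            T = self.wm.shape[1]
            return np.zeros((T, 0))
        return np.concatenate(parts, axis=1)


def build_nuisance_bank(residuals: Fmri4D, atlas, n_csf: int = 4,
                        n_ns: int = 10) -> NuisanceBank:
    wm_mask = build_wm_mask(atlas.wm, atlas.gm)
    csf_mask = atlas.csf >= 0.5
    ns_mask = build_ns_mask(atlas.cord >= 0.5, csf_mask,
                            fov_mask=atlas.body >= 0.5)
    S, T = residuals.n_slices, residuals.n_volumes
    wm = np.zeros((S, T, 1))
    csf_pcs = np.zeros((S, T, n_csf))
    ns_pcs = np.zeros((S, T, n_ns))
    for s in range(S):
        slab = residuals.data[:, :, s, :]
        if wm_mask[:, :, s].any():
            wm[s, :, 0] = slab[wm_mask[:, :, s]].mean(axis=0)
        comps = nuis.build_pca_regressors(slab, csf_mask[:, :, s], n_csf)
        csf_pcs[s, :, :comps.shape[1]] = comps
        comps = nuis.build_pca_regressors(slab, ns_mask[:, :, s], n_ns)
        ns_pcs[s, :, :comps.shape[1]] = comps
    return NuisanceBank(wm=wm, csf_pcs=csf_pcs, ns_pcs=ns_pcs)


@dataclass
class SliceMeans:
    """Per-slice horn mean time courses and voxel counts for one mask set."""

    means: dict          # horn -> (S, T)
    counts: dict         # horn -> (S,)


def slice_horn_means(residuals: Fmri4D, masks: HornMaskSet) -> SliceMeans:
    S, T = residuals.n_slices, residuals.n_volumes
    means = {h: np.zeros((S, T)) for h in HORNS}
    counts = {h: np.zeros(S) for h in HORNS}
    for h in HORNS:
        m = masks[h]
        for s in range(S):
            sel = m[:, :, s]
            counts[h][s] = sel.sum()
            if counts[h][s]:
                means[h][s] = residuals.data[:, :, s, :][sel].mean(axis=0)
    return SliceMeans(means=means, counts=counts)


@dataclass
class SubjectAssets:
    """Everything a pipeline variant needs for one subject."""

    slice_means: dict            # "PROB"/"COG" -> SliceMeans
    bank: NuisanceBank
    tr: float
    n_volumes: int
    subject: str = ""
    extras: dict = field(default_factory=dict)


def prepare_subject(fmri: Fmri4D, physio, atlas, prob_masks: HornMaskSet,
                    cog_masks: HornMaskSet, task_times=None,
                    subject: str = "") -> SubjectAssets:
    """Base-denoise one subject and precompute pipeline inputs."""
    residuals = denoise(fmri, atlas, physio, task_times)
    bank = build_nuisance_bank(residuals, atlas)
    return SubjectAssets(
        slice_means={"PROB": slice_horn_means(residuals, prob_masks),
                     "COG": slice_horn_means(residuals, cog_masks)},
        bank=bank, tr=fmri.tr, n_volumes=fmri.n_volumes, subject=subject)


def roi_timecourses(assets: SubjectAssets, roi: str,
                    nuisance_set=(), segment_slices=None) -> pd.DataFrame:
    """(4, T) horn time courses after optional extra nuisance regression.

    Slice-wise regressors are regressed from per-slice horn means, which
    are then combined across slices weighted by voxel counts (identical to
    voxel-wise regression followed by ROI averaging, both being linear).
    ``segment_slices`` optionally restricts to a set of z slices.
    """
    sm = assets.slice_means[roi]
    S, T = next(iter(sm.means.values())).shape
    slices = range(S) if segment_slices is None else segment_slices
    out = {}
    for h in HORNS:
        num = np.zeros(T)
        den = 0.0
        for s in slices:
            c = sm.counts[h][s]
            if c == 0:
                continue
            series = sm.means[h][s]
            X = assets.bank.columns(nuisance_set, s)
            if X.shape[1]:
                series = nuis.regress_nuisance(series, X)
            num += c * series
            den += c
        if den == 0:
            raise ValueError(f"horn {h} empty over the requested slices")
        out[h] = num / den
    return pd.DataFrame(out).T.loc[list(HORNS)]


def run_pipeline(assets: SubjectAssets, roi: str = "PROB", filt: str = "HP",
                 nuisance_set=(), metric: MetricSpec = MetricSpec(),
                 segment_slices=None):
    """One subject through one analysis pipeline -> CorrelationSet."""
    ts = roi_timecourses(assets, roi, nuisance_set, segment_slices)
    if filt == "BP":
        ts = bandpass_filter(ts, tr=assets.tr)
    elif filt != "HP":
        raise ValueError(f"unknown temporal filter {filt!r}")
    return summarize(connectivity_matrix(ts, metric))


def prepare_synthetic_cohort(config) -> list:
    """Simulate a cohort in memory and prepare per-subject pipeline assets."""
    from .masks import build_cog_horn_masks, build_prob_horn_masks
    from .synthetic import make_atlas, simulate_subject, subject_seeds

    atlas = make_atlas(config)
    prob = build_prob_horn_masks(atlas.gm)
    cog = build_cog_horn_masks(prob)
    assets = []
    for i, seed in enumerate(subject_seeds(config)):
        fmri, physio, _ = simulate_subject(atlas, config, seed=seed)
        assets.append(prepare_subject(fmri, physio, atlas, prob, cog,
                                      task_times=config.task_times(),
                                      subject=f"sub-{i + 1:02d}"))
    return assets


def cohort_indices(assets_list, roi: str = "COG", filt: str = "HP",
                   nuisance_set=(), metric: MetricSpec = MetricSpec()) -> pd.DataFrame:
    """Per-subject DataFrame of the four indices for one pipeline."""
    rows = {}
    for assets in assets_list:
        cs = run_pipeline(assets, roi=roi, filt=filt,
                          nuisance_set=nuisance_set, metric=metric)
        rows[assets.subject] = cs.as_series()
    return pd.DataFrame(rows).T
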