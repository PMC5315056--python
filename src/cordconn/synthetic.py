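"""Synthetic spinal-cord fMRI cohorts with known ground-truth connectivity.

The generator emulates an axial resting-state acquisition of the cervical
cord (default: 16 slices x 250 volumes at TR 1.89 s, 1 mm in-plane grid,
four spinal segments C6-T1).  Each subject receives, per segment, a latent
4-dimensional "horn" signal with a prescribed 4x4 correlation matrix
``R_true``; the voxel signal is the gray-matter-profile-weighted mixture of
these latents plus cardiac/respiratory Fourier confounds (phase-locked to
the emitted physiological recording), CSF-channel signals, non-spinal
structured artifacts, slow drift and thermal noise, optionally followed by
an in-plane Gaussian point-spread blur.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation, gaussian_filter, gaussian_filter1d

from .images import HORNS, AtlasBundle, Fmri4D
from . import nuisance as nuis


class ConfigError(ValueError):
    pass


class SizingError(ConfigError):
    """Grid too small for the requested cord geometry."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def horn_correlation_matrix(dd: float, vv: float, w: float, b: float) -> np.ndarray:
    """Build the 4x4 latent correlation matrix from the four summary indices.

    Order (LD, LV, RD, RV): (LD,RD)=dd, (LV,RV)=vv, (LD,LV)=(RD,RV)=w,
    (LD,RV)=(RD,LV)=b.
    """
    R = np.eye(4)
    idx = {h: i for i, h in enumerate(HORNS)}
    pairs = {("LD", "RD"): dd, ("LV", "RV"): vv,
             ("LD", "LV"): w, ("RD", "RV"): w,
             ("LD", "RV"): b, ("RD", "LV"): b}
    for (a, c), v in pairs.items():
        R[idx[a], idx[c]] = R[idx[c], idx[a]] = v
    return R


# population whole-cord group means serve as calibration of the generator
DEFAULT_R_TRUE = horn_correlation_matrix(dd=0.22, vv=0.22, w=0.02, b=-0.08)


@dataclass
class SimConfig:
    """All tunable knobs of the synthetic cohort generator.

    Amplitudes are in percent-of-baseline units (baseline 100); the latent
    horn signal has unit variance so ``amp_gm`` is the BOLD fluctuation
    amplitude at a pure gray-matter voxel.
    """

    nx: int = 40
    ny: int = 40
    nz: int = 16
    tr: float = 1.89
    n_volumes: int = 250
    n_subjects: int = 20
    segment_names: tuple = ("C6", "C7", "C8", "T1")
    segment_boundaries: tuple = (0, 4, 8, 12, 16)  # z ranges, rostral first
    r_true: object = None  # 4x4 matrix or list of one per segment
    amp_gm: float = 1.0
    sigma_thermal: float = 0.4
    cardiac_bpm_mean: float = 70.0
    cardiac_bpm_sd: float = 5.0
    resp_brpm_mean: float = 16.0
    resp_brpm_sd: float = 2.0
    amp_cardiac: float = 0.8
    amp_resp: float = 0.6
    amp_csf: float = 2.0
    amp_ns: float = 1.0
    amp_drift: float = 1.5
    amp_task: float = 0.0
    latent_ar: float = 0.3          # AR(1) coefficient of latent horn signals
    blur_sigma_vox: float = 0.0     # in-plane point-spread sd, voxels
    baseline: float = 100.0
    physio_fs: float = 100.0
    task_interval_s: float = 15.0
    voxel_size: tuple = (1.0, 1.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- helpers ----------------------------------------------------------
    def r_true_per_segment(self) -> list:
        n_seg = len(self.segment_names)
        r = self.r_true
        if r is None:
            r = DEFAULT_R_TRUE
        r = np.asarray(r, dtype=float)
        if r.ndim == 2:
            mats = [r] * n_seg
        elif r.ndim == 3 and r.shape[0] == n_seg:
            mats = list(r)
        else:
            raise ConfigError("r_true must be 4x4 or one 4x4 per segment")
        for m in mats:
            _check_correlation(np.asarray(m))
        return [np.asarray(m, dtype=float) for m in mats]

    def task_times(self) -> np.ndarray:
        dur = self.n_volumes * self.tr
        return np.arange(self.task_interval_s, dur, self.task_interval_s)

    def validate(self):
        if self.n_volumes < 2:
            raise ConfigError("n_volumes must be >= 2")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("amp_gm", "sigma_thermal", "amp_cardiac", "amp_resp",
                     "amp_csf", "amp_ns", "amp_drift", "amp_task",
                     "blur_sigma_vox"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.cardiac_bpm_mean <= 0 or self.resp_brpm_mean <= 0:
            raise ConfigError("physiological rates must be positive")
        if len(self.segment_boundaries) != len(self.segment_names) + 1:
            raise ConfigError("segment_boundaries must bracket segment_names")
        if tuple(self.segment_boundaries) != tuple(sorted(self.segment_boundaries)):
            raise ConfigError("segment_boundaries must be increasing")
        if self.segment_boundaries[0] != 0 or self.segment_boundaries[-1] != self.nz:
            raise ConfigError("segments must tile the z range")
        self.r_true_per_segment()  # validates PSD

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path):
        d = asdict(self)
        if d["r_true"] is not None:
            d["r_true"] = np.asarray(d["r_true"]).tolist()
        for key in ("segment_names", "segment_boundaries", "voxel_size"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("segment_names", "segment_boundaries", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _check_correlation(R: np.ndarray):
    if R.shape != (4, 4):
        raise ConfigError("R_true must be 4x4")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ConfigError("R_true must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ConfigError("R_true must have unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ConfigError("R_true must be positive semi-definite")


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

# in-plane geometry of the cord cross-section (voxel units).  The dorsal
# horns reach toward the dorsal cord surface; the ventral horns are bulkier
# and sit deeper, so the thresholded dorsal and ventral regions approach to
# about a one-voxel gap, as in the real gray-matter atlas.
_DORSAL_DX, _DORSAL_DY = 3.4, -3.5
_VENTRAL_DX, _VENTRAL_DY = 2.8, 2.2
_DORSAL_SIG = (1.2, 1.9)
_VENTRAL_SIG = (1.3, 1.6)
_BRIDGE_AMP, _BRIDGE_SIG = 0.42, (2.2, 1.0)
_CORD_RX, _CORD_RY = 7.0, 6.2
_CSF_GAP = 1.0    # pia mater: the CSF ring stands off the cord surface
_CSF_THICK = 2.5
_BODY_MARGIN = 8.0


_BUMP_FLOOR = 0.12  # truncation level: GM probability is compactly supported


def _bump(xx, yy, cx, cy, sig):
    """Truncated Gaussian horn profile with compact support.

    Real probabilistic gray-matter maps fall to exactly zero within the
    surrounding white matter; an untruncated Gaussian would leak a little
    of every horn's signal across the whole cord cross-section and thereby
    mix ROI time courses even without any point spread.
    """
    g = np.exp(-0.5 * (((xx - cx) / sig[0]) ** 2 + ((yy - cy) / sig[1]) ** 2))
    return np.clip((g - _BUMP_FLOOR) / (1.0 - _BUMP_FLOOR), 0.0, None)


def make_atlas(config: SimConfig) -> AtlasBundle:
    """Probabilistic gray/white/CSF/cord/segment maps for the synthetic cord.

    Gray matter is a butterfly of four Gaussian horn profiles plus a weak
    central-gray bridge (sub-threshold at 50%); ventral horns sit closer to
    the midline than dorsal horns, as in the real cord.  CSF is a ring
    around the cord split into four angular channels; everything within the
    body ellipse but outside the dilated cord+CSF is "non-spinal" tissue.
    """
    nx, ny, nz = config.nx, config.ny, config.nz
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    need = _CORD_RX + _CSF_GAP + _CSF_THICK + _BODY_MARGIN + 1
    if cx < need or cy < need or min(nx, ny) < 2 * need:
        raise SizingError(f"grid {nx}x{ny} too small; need >= {int(2 * need) + 1} "
                          "voxels in-plane for cord + CSF ring + outer tissue")
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    gm = np.zeros((nx, ny, nz))
    horn_weights = {h: np.zeros((nx, ny, nz)) for h in HORNS}
    cord = np.zeros((nx, ny, nz))
    csf = np.zeros((nx, ny, nz))
    body = np.zeros((nx, ny, nz))
    for z in range(nz):
        taper = 1.0 - 0.04 * z / max(nz - 1, 1)  # slight caudal narrowing
        centers = {
            "LD": (cx - _DORSAL_DX * taper, cy + _DORSAL_DY * taper, _DORSAL_SIG),
            "RD": (cx + _DORSAL_DX * taper, cy + _DORSAL_DY * taper, _DORSAL_SIG),
            "LV": (cx - _VENTRAL_DX * taper, cy + _VENTRAL_DY * taper, _VENTRAL_SIG),
            "RV": (cx + _VENTRAL_DX * taper, cy + _VENTRAL_DY * taper, _VENTRAL_SIG),
        }
        rho = np.sqrt(((xx - cx) / (_CORD_RX * taper)) ** 2
                      + ((yy - cy) / (_CORD_RY * taper)) ** 2)
        cord_z = 1.0 / (1.0 + np.exp(8.0 * (rho - 1.0)))
        cord_z = np.where(rho <= 0.8, 1.0, cord_z)
        cord[:, :, z] = cord_z

        # gray matter lives strictly inside the cord: window the horn
        # profiles by the cord so no latent signal leaks into the CSF ring
        bridge = _BRIDGE_AMP * _bump(xx, yy, cx, cy, _BRIDGE_SIG)
        total = bridge.copy()
        for h, (hx, hy, sig) in centers.items():
            w = _bump(xx, yy, hx, hy, sig)
            # the horn signal profiles have pairwise-disjoint supports; the
            # central-gray bridge contributes GM probability but no latent
            # signal (it is discarded from ROI masks downstream anyway)
            horn_weights[h][:, :, z] = w * cord_z
            total += w
        gm[:, :, z] = np.clip(total, 0.0, 1.0) * cord_z
        rho_in = np.sqrt(((xx - cx) / (_CORD_RX * taper + _CSF_GAP)) ** 2
                         + ((yy - cy) / (_CORD_RY * taper + _CSF_GAP)) ** 2)
        inner = 1.0 / (1.0 + np.exp(8.0 * (rho_in - 1.0)))
        rho_out = np.sqrt(((xx - cx) / (_CORD_RX * taper + _CSF_GAP + _CSF_THICK)) ** 2
                          + ((yy - cy) / (_CORD_RY * taper + _CSF_GAP + _CSF_THICK)) ** 2)
        outer = 1.0 / (1.0 + np.exp(8.0 * (rho_out - 1.0)))
        csf[:, :, z] = np.clip(outer - inner, 0.0, 1.0)
        rho_body = np.sqrt(
            ((xx - cx) / (_CORD_RX + _CSF_GAP + _CSF_THICK + _BODY_MARGIN)) ** 2
            + ((yy - cy) / (_CORD_RY + _CSF_GAP + _CSF_THICK + _BODY_MARGIN)) ** 2)
        body[:, :, z] = 1.0 / (1.0 + np.exp(6.0 * (rho_body - 1.0)))

    wm = np.clip(cord - gm, 0.0, 1.0)

    # CSF channels: four angular sectors of the ring
    ang = np.arctan2(yy - cy, xx - cx)  # (-pi, pi]
    sector = ((ang + np.pi) // (np.pi / 2)).astype(int) % 4 + 1
    channels = np.where(csf >= 0.5, sector[:, :, None], 0)

    # segment maps: per-slice membership weight x cord profile; the last
    # slice of each non-final segment splits its mass 50/50 with the next
    # segment (an exact tie, resolved rostrally downstream)
    segments = {}
    bounds = config.segment_boundaries
    n_seg = len(config.segment_names)
    weights = np.zeros((n_seg, nz))
    for i in range(n_seg):
        weights[i, bounds[i]:bounds[i + 1]] = 1.0
    for i in range(n_seg - 1):
        zb = bounds[i + 1] - 1  # last slice of segment i: mass split 50/50
        weights[i, zb] = 0.5
        weights[i + 1, zb] = 0.5
    for i, name in enumerate(config.segment_names):
        segments[name] = cord * weights[i][None, None, :]

    return AtlasBundle(gm=gm, wm=wm, csf=csf, cord=cord, body=body,
                       segments=segments, csf_channels=channels,
                       horn_weights=horn_weights, voxel_size=config.voxel_size)


def segment_of_slice(config: SimConfig) -> np.ndarray:
    """Segment index for each z slice (boundary ties go to the rostral segment)."""
    bounds = config.segment_boundaries
    out = np.zeros(config.nz, dtype=int)
    for i in range(len(config.segment_names)):
        out[bounds[i]:bounds[i + 1]] = i
    return out


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass
class PhysioRecording:
    """Physiological log: pulse trace, respiratory belt, triggers, motion."""

    fs: float
    cardiac: np.ndarray
    resp: np.ndarray
    trigger_times: np.ndarray
    motion: np.ndarray = None  # (T, 2) x/y translation per volume

    def __post_init__(self):
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.cardiac.shape != self.resp.shape:
            raise ConfigError("cardiac and respiratory traces must align")

    @property
    def duration(self) -> float:
        return self.cardiac.size / self.fs

    def to_tsv(self, path):
        n = self.cardiac.size
        t = np.arange(n) / self.fs
        trig = np.zeros(n)
        trig[np.clip(np.rint(self.trigger_times * self.fs).astype(int), 0, n - 1)] = 1.0
        motion = self.motion if self.motion is not None else np.zeros((self.trigger_times.size, 2))
        # step-interpolate per-volume motion onto the log grid
        vol_idx = np.clip(np.searchsorted(self.trigger_times, t, side="right") - 1,
                          0, motion.shape[0] - 1)
        df = pd.DataFrame({
            "time_s": t, "cardiac": self.cardiac, "resp": self.resp,
            "trigger": trig,
            "motion_x": motion[vol_idx, 0], "motion_y": motion[vol_idx, 1],
        })
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "PhysioRecording":
        df = pd.read_csv(path, sep="\t")
        fs = 1.0 / np.median(np.diff(df["time_s"].to_numpy()))
        trig_t = df.loc[df["trigger"] > 0.5, "time_s"].to_numpy()
        # recover per-volume motion from the step trace
        idx = np.clip(np.rint(trig_t * fs).astype(int), 0, len(df) - 1)
        motion = df[["motion_x", "motion_y"]].to_numpy()[idx]
        return cls(fs=float(np.round(fs, 6)), cardiac=df["cardiac"].to_numpy(),
                   resp=df["resp"].to_numpy(), trigger_times=trig_t,
                   motion=motion)


def _ar1(n, phi, rng, sd=1.0):
    x = np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi ** 2) if abs(phi) < 1 else sd
    e = rng.normal(0, innov_sd, n)
    x[0] = rng.normal(0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def simulate_physio(config: SimConfig, seed=None) -> PhysioRecording:
    """Cardiac pulse trace, respiratory belt trace, triggers and motion log.

    The cardiac trace is a sum of harmonics of a jittered beat train (beat
    peaks at the beat times); the respiratory trace is a sinusoid with
    slowly drifting rate and amplitude.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.physio_fs
    duration = config.n_volumes * config.tr
    n = int(np.round(duration * fs))
    t = np.arange(n) / fs

    # --- beat train -------------------------------------------------------
    mean_int = 60.0 / config.cardiac_bpm_mean
    beats = [0.0]
    # AR(1) beat-rate jitter so rate wanders slowly, as real heart rate does
    dev = 0.0
    while beats[-1] < duration + 2 * mean_int:
        dev = 0.7 * dev + rng.normal(0, config.cardiac_bpm_sd * np.sqrt(1 - 0.7 ** 2))
        bpm = max(20.0, config.cardiac_bpm_mean + dev)
        beats.append(beats[-1] + 60.0 / bpm)
    beats = np.asarray(beats)
    # fraction through the current beat, piecewise linear
    k = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, beats.size - 2)
    frac = (t - beats[k]) / (beats[k + 1] - beats[k])
    # single-peaked pulse waveform (one unambiguous maximum per beat)
    cardiac = np.exp(3.0 * (np.cos(2 * np.pi * frac) - 1.0))

    # --- respiration ------------------------------------------------------
    slow = gaussian_filter1d(rng.normal(0, 1, n), sigma=5 * fs, mode="nearest")
    slow = slow / max(slow.std(), 1e-12)
    rate_hz = (config.resp_brpm_mean + config.resp_brpm_sd * slow) / 60.0
    rate_hz = np.clip(rate_hz, 0.02, None)
    phase = 2 * np.pi * np.cumsum(rate_hz) / fs
    amp_slow = gaussian_filter1d(rng.normal(0, 1, n), sigma=8 * fs, mode="nearest")
    amp_slow = amp_slow / max(amp_slow.std(), 1e-12)
    resp = (1.0 + 0.15 * amp_slow) * np.sin(phase)

    triggers = np.arange(config.n_volumes) * config.tr
    motion = np.column_stack([_ar1(config.n_volumes, 0.9, rng, sd=0.08)
                              for _ in range(2)])
    return PhysioRecording(fs=fs, cardiac=cardiac, resp=resp,
                           trigger_times=triggers, motion=motion)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Realized latent signals and confound time courses for one subject."""

    latents: dict              # segment name -> (4, T) horn latent signals
    confounds: dict            # name -> array (per-slice confounds are (S, T))
    r_true: list               # per-segment 4x4 matrices actually used
    seed: int = 0

    def to_json(self, path):
        d = {
            "seed": int(self.seed),
            "r_true": [np.asarray(m).tolist() for m in self.r_true],
            "latents": {k: np.asarray(v).tolist() for k, v in self.latents.items()},
            "confounds": {k: np.asarray(v).tolist() for k, v in self.confounds.items()},
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(latents={k: np.asarray(v) for k, v in d["latents"].items()},
                   confounds={k: np.asarray(v) for k, v in d["confounds"].items()},
                   r_true=[np.asarray(m) for m in d["r_true"]],
                   seed=d["seed"])


def _latent_signals(R: np.ndarray, T: int, phi: float, rng) -> np.ndarray:
    """(4, T) zero-mean unit-variance AR(1) signals with correlation R."""
    white = np.stack([_ar1(T, phi, rng) for _ in range(4)])
    white = (white - white.mean(axis=1, keepdims=True))
    white /= white.std(axis=1, keepdims=True)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(4))
    return L @ white


def _smooth_noise(T, rng, sigma=2.0):
    x = gaussian_filter1d(rng.normal(0, 1, T), sigma=sigma, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(atlas: AtlasBundle, config: SimConfig, seed=None):
    """Generate one subject: (Fmri4D, PhysioRecording, GroundTruth)."""
    if atlas.shape != (config.nx, config.ny, config.nz):
        raise ConfigError("atlas and config grids differ")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_physio, r_latent, r_csf, r_ns, r_drift, r_coef, r_noise = \
        [np.random.default_rng(s) for s in ss.spawn(7)]

    nx, ny, nz, T = config.nx, config.ny, config.nz, config.n_volumes
    physio = simulate_physio(config, seed=r_physio)
    phases = nuis.compute_phases(physio, config.tr, nz)
    r_mats = config.r_true_per_segment()
    seg_of_z = segment_of_slice(config)

    # latent horn signals, one 4xT set per segment
    latents = {}
    for i, name in enumerate(config.segment_names):
        latents[name] = _latent_signals(r_mats[i], T, config.latent_ar, r_latent)

    # subject-level Fourier coefficients for the physiological confounds
    def fourier_series(theta, orders, rng):
        out = np.zeros_like(theta)
        for m in range(1, orders + 1):
            a, b = rng.normal(0, 0.7 ** (m - 1), 2)
            out += a * np.cos(m * theta) + b * np.sin(m * theta)
        return out

    cardiac_conf = fourier_series(phases.theta_c, 3, r_coef)   # (S, T)
    resp_conf = fourier_series(phases.theta_r, 2, r_coef)
    for arr in (cardiac_conf, resp_conf):
        sd = arr.std()
        if sd > 0:
            arr /= sd

    # four CSF channels: one common pulsation component (all channels are
    # driven by the same cardiac/respiratory cycle) plus channel-specific
    # flow profiles
    csf_common = _smooth_noise(T, r_csf)
    rho_csf = 0.5
    csf_signals = np.stack([np.sqrt(rho_csf) * csf_common
                            + np.sqrt(1 - rho_csf) * _smooth_noise(T, r_csf)
                            for _ in range(4)])  # (4, T)

    # non-spinal structured artifacts: random smooth fields x smooth time courses
    cordb = atlas.cord >= 0.5
    csfb = atlas.csf >= 0.5
    ns_region = (atlas.body >= 0.5) & ~binary_dilation(cordb | csfb,
                                                       structure=np.ones((3, 3, 3)))
    ns_fields = []
    for _ in range(3):
        f = gaussian_filter(r_ns.normal(0, 1, (nx, ny, nz)), sigma=(3, 3, 0.5))
        f = np.abs(f) * ns_region
        m = f.max()
        ns_fields.append(f / m if m > 0 else f)
    ns_signals = np.stack([_smooth_noise(T, r_ns) for _ in range(3)])

    # slow drift per slice
    tt = np.arange(T) / max(T - 1, 1)
    drift = np.zeros((nz, T))
    for s in range(nz):
        d = r_drift.normal() * (tt - 0.5) + r_drift.normal() * np.cos(np.pi * tt)
        sd = d.std()
        drift[s] = d / sd if sd > 0 else d

    task = nuis.task_column(config.task_times(),
                            nuis.slice_times(physio.trigger_times, config.tr, nz))

    # spatial gain fields for the physiological confounds
    g_card = 0.3 * atlas.body + 0.5 * atlas.cord + 1.0 * atlas.csf
    g_resp = 0.6 * atlas.body + 0.4 * atlas.csf

    baseline = 2.0 + (config.baseline - 2.0) * atlas.body
    data = np.empty((nx, ny, nz, T))
    for s in range(nz):
        seg = config.segment_names[seg_of_z[s]]
        z = latents[seg]  # (4, T)
        slab = np.broadcast_to(baseline[:, :, s, None], (nx, ny, T)).copy()
        for hi, h in enumerate(HORNS):
            w = atlas.horn_weights[h][:, :, s]
            if w.max() > 0:
                slab += config.amp_gm * w[:, :, None] * z[hi][None, None, :]
        slab += (config.amp_cardiac * g_card[:, :, s, None]
                 * cardiac_conf[s][None, None, :])
        slab += (config.amp_resp * g_resp[:, :, s, None]
                 * resp_conf[s][None, None, :])
        if config.amp_csf > 0:
            ch = atlas.csf_channels[:, :, s]
            for c in range(4):
                m = ch == c + 1
                if m.any():
                    slab[m] += config.amp_csf * csf_signals[c][None, :]
        if config.amp_ns > 0:
            for f, sig in zip(ns_fields, ns_signals):
                slab += config.amp_ns * f[:, :, s, None] * sig[None, None, :]
        slab += config.amp_drift * atlas.body[:, :, s, None] * drift[s][None, None, :]
        if config.amp_task > 0:
            gm_s = atlas.gm[:, :, s]
            slab += config.amp_task * gm_s[:, :, None] * task[s][None, None, :]
        data[:, :, s, :] = slab

    if config.blur_sigma_vox > 0:
        # in-plane point-spread applied to the noiseless composite
        data = gaussian_filter(data, sigma=(config.blur_sigma_vox,
                                            config.blur_sigma_vox, 0, 0))
    if config.sigma_thermal > 0:
        data += r_noise.normal(0, config.sigma_thermal, data.shape)

    truth = GroundTruth(
        latents=latents,
        confounds={"cardiac": cardiac_conf, "resp": resp_conf,
                   "csf": csf_signals, "ns": ns_signals, "drift": drift,
                   "task": task},
        r_true=r_mats, seed=int(seed))
    fmri = Fmri4D(data=data, voxel_size=config.voxel_size, tr=config.tr)
    return fmri, physio, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def subject_seeds(config: SimConfig) -> list:
    """Deterministic per-subject seeds derived from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % (2 ** 31))
            for child in ss.spawn(config.n_subjects)]


def simulate_cohort(config: SimConfig, outdir) -> dict:
    """Write a full cohort to disk; returns the manifest.

    Layout: ``atlas/`` (NIfTI maps), ``sub-XX/func.nii.gz``,
    ``sub-XX/physio.tsv``, ``sub-XX/truth.json``, plus ``manifest.yaml``
    and ``config.yaml``.  A failed subject write is cleaned up before the
    error propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = make_atlas(config)
    atlas.save(outdir / "atlas")
    config.to_yaml(outdir / "config.yaml")
    seeds = subject_seeds(config)
    manifest = {"master_seed": int(config.seed), "n_subjects": config.n_subjects,
                "task_times_s": [float(x) for x in config.task_times()],
                "subjects": []}
    for i, seed in enumerate(seeds):
        sub = f"sub-{i + 1:02d}"
        subdir = outdir / sub
        try:
            subdir.mkdir(exist_ok=True)
            fmri, physio, truth = simulate_subject(atlas, config, seed=seed)
            fmri.save(subdir / "func.nii.gz")
            physio.to_tsv(subdir / "physio.tsv")
            truth.to_json(subdir / "truth.json")
        except Exception:
            shutil.rmtree(subdir, ignore_errors=True)
            raise
        manifest["subjects"].append({"id": sub, "seed": int(seed)})
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest


def load_cohort(cohort_dir):
    """Yield (subject_id, Fmri4D, PhysioRecording, GroundTruth) from disk."""
    cohort_dir = Path(cohort_dir)
    manifest = yaml.safe_load((cohort_dir / "manifest.yaml").read_text())
    for entry in manifest["subjects"]:
        sub = entry["id"]
        fmri = Fmri4D.load(cohort_dir / sub / "func.nii.gz")
        physio = PhysioRecording.from_tsv(cohort_dir / sub / "physio.tsv")
        truth = GroundTruth.from_json(cohort_dir / sub / "truth.json")
        yield sub, fmri, physio, truth
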