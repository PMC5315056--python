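"""ROI and nuisance mask construction from probabilistic maps.

Horn ROIs are built slice-by-slice from the thresholded probabilistic
gray-matter map: supra-threshold voxels are split into the four horns by
quadrant around the per-slice gray-matter centroid, a one-voxel dorsoventral
gap is enforced, and the minimal left-right distance between the ventral
horns is equalized to that between the dorsal horns by discarding
central-gray voxels (so that a systematically smaller ventral gap cannot
bias ventral-ventral correlations).  Center-of-gravity (COG) masks keep a
single voxel per horn per slice.  All threshold comparisons are inclusive
(>=); coordinates are 0-based voxel indices with +y = ventral.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation

from .images import HORNS, save_map, load_map


class MaskError(ValueError):
    pass


_DIL = np.ones((3, 3, 3), dtype=bool)  # 1-voxel 3D dilation kernel


@dataclass
class HornMaskSet:
    """Binary masks for the four gray-matter horns (LD, LV, RD, RV)."""

    masks: dict                      # horn name -> bool array (x, y, z)
    provenance: str = "PROB"         # PROB or COG
    segment: str = None

    def __post_init__(self):
        if set(self.masks) != set(HORNS):
            raise MaskError(f"expected masks for {HORNS}")
        self.masks = {h: np.asarray(m, dtype=bool) for h, m in self.masks.items()}
        arrs = list(self.masks.values())
        for a in arrs[1:]:
            if a.shape != arrs[0].shape:
                raise MaskError("horn masks must share a grid")
        union = np.zeros(arrs[0].shape, dtype=int)
        for a in arrs:
            union += a
        if union.max() > 1:
            raise MaskError("horn masks must be pairwise disjoint")

    def __getitem__(self, horn):
        return self.masks[horn]

    @property
    def shape(self):
        return self.masks["LD"].shape

    def counts(self) -> dict:
        return {h: int(m.sum()) for h, m in self.masks.items()}

    def restricted(self, segment_mask: np.ndarray, segment: str) -> "HornMaskSet":
        return HornMaskSet(
            masks={h: m & np.asarray(segment_mask, dtype=bool)
                   for h, m in self.masks.items()},
            provenance=self.provenance, segment=segment)

    def save(self, outdir, voxel_size=(1.0, 1.0, 5.0)):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for h, m in self.masks.items():
            save_map(m.astype(float), outdir / f"horn_{h}.nii.gz", voxel_size)
        sidecar = {"provenance": self.provenance, "segment": self.segment}
        (outdir / "horn_masks.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, indir) -> "HornMaskSet":
        indir = Path(indir)
        sidecar = json.loads((indir / "horn_masks.json").read_text())
        masks = {h: load_map(indir / f"horn_{h}.nii.gz") >= 0.5 for h in HORNS}
        return cls(masks=masks, provenance=sidecar["provenance"],
                   segment=sidecar["segment"])


@dataclass
class SegmentMaskSet:
    """Binary, pairwise-disjoint segment masks in rostral-to-caudal order."""

    masks: dict = field(default_factory=dict)  # segment name -> bool array

    def __post_init__(self):
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        union = None
        for a in self.masks.values():
            union = a.astype(int) if union is None else union + a
        if union is not None and union.max() > 1:
            raise MaskError("segment masks must be pairwise disjoint")

    def __getitem__(self, name):
        return self.masks[name]

    @property
    def names(self):
        return tuple(self.masks)


# ---------------------------------------------------------------------------
# per-slice helpers
# ---------------------------------------------------------------------------

def _min_dist(a_xy: np.ndarray, b_xy: np.ndarray) -> float:
    """Minimal Euclidean distance between two in-plane voxel sets."""
    if a_xy.size == 0 or b_xy.size == 0:
        return np.inf
    d2 = ((a_xy[:, None, :] - b_xy[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))


def _min_chebyshev(a_xy: np.ndarray, b_xy: np.ndarray) -> float:
    if a_xy.size == 0 or b_xy.size == 0:
        return np.inf
    return float(np.abs(a_xy[:, None, :] - b_xy[None, :, :]).max(-1).min())


def _split_quadrants(coords: np.ndarray):
    """Assign supra-threshold in-plane voxels to horns by centroid quadrant.

    Voxels exactly on the centroid's x or y line belong to the central gray
    and are left unassigned.
    """
    cx, cy = coords.mean(axis=0)
    out = {}
    for h in HORNS:
        sel_x = coords[:, 0] < cx if h[0] == "L" else coords[:, 0] > cx
        sel_y = coords[:, 1] < cy if h[1] == "D" else coords[:, 1] > cy
        out[h] = coords[sel_x & sel_y]
    return out, (cx, cy)


def _enforce_gap(horn_xy: dict, cy: float, min_gap: float = 1.0):
    """Remove boundary rows nearest the centroid until the dorsoventral
    in-plane Chebyshev gap is at least ``min_gap`` empty voxels."""
    for _ in range(1000):
        dors = np.concatenate([horn_xy["LD"], horn_xy["RD"]]) if \
            horn_xy["LD"].size + horn_xy["RD"].size else np.empty((0, 2))
        vent = np.concatenate([horn_xy["LV"], horn_xy["RV"]]) if \
            horn_xy["LV"].size + horn_xy["RV"].size else np.empty((0, 2))
        if _min_chebyshev(dors, vent) >= min_gap + 1:
            return horn_xy
        ys = np.unique(np.concatenate([dors[:, 1], vent[:, 1]]))
        y_star = ys[np.argmin(np.abs(ys - cy))]
        horn_xy = {h: c[c[:, 1] != y_star] for h, c in horn_xy.items()}
    return horn_xy


def _equalize_lr_distance(horn_xy: dict, cx: float, max_iter: int = 200):
    """Equalize the minimal left-right distance of ventral vs dorsal horns.

    Iteratively discards the central-most column band of the currently
    closer pair (symmetrically from its left and right mask), i.e. the
    voxels belonging to the central gray matter, until the two minimal
    distances agree.
    """
    for _ in range(max_iter):
        d_v = _min_dist(horn_xy["LV"], horn_xy["RV"])
        d_d = _min_dist(horn_xy["LD"], horn_xy["RD"])
        if not np.isfinite(d_v) or not np.isfinite(d_d):
            return horn_xy
        if abs(d_v - d_d) < 1e-9:
            return horn_xy
        pair = ("LV", "RV") if d_v < d_d else ("LD", "RD")
        band = min(np.abs(h[:, 0] - cx).min() for h in
                   (horn_xy[pair[0]], horn_xy[pair[1]]))
        new = {}
        emptied = False
        for h in pair:
            keep = np.abs(horn_xy[h][:, 0] - cx) > band + 1e-9
            if not keep.any():
                emptied = True
            new[h] = horn_xy[h][keep]
        if emptied:
            warnings.warn("left-right distance equalization would empty a "
                          "horn; stopping early")
            return horn_xy
        horn_xy.update(new)
    warnings.warn("left-right distance equalization did not converge")
    return horn_xy


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_prob_horn_masks(gm_prob: np.ndarray, threshold: float = 0.5) -> HornMaskSet:
    """Probabilistic (PROB) horn masks from the gray-matter map.

    Done separately per slice; slices are merged at the end.  Raises if any
    horn ends up empty on every slice.
    """
    gm_prob = np.asarray(gm_prob, dtype=float)
    if gm_prob.min() < 0 or gm_prob.max() > 1 + 1e-9:
        raise MaskError("gm_prob must lie in [0, 1]")
    nx, ny, nz = gm_prob.shape
    out = {h: np.zeros((nx, ny, nz), dtype=bool) for h in HORNS}
    for z in range(nz):
        coords = np.argwhere(gm_prob[:, :, z] >= threshold)
        if coords.size == 0:
            continue
        horn_xy, (cx, cy) = _split_quadrants(coords)
        horn_xy = _enforce_gap(horn_xy, cy)
        horn_xy = _equalize_lr_distance(horn_xy, cx)
        for h, c in horn_xy.items():
            if c.size:
                out[h][c[:, 0], c[:, 1], z] = True
    empty = [h for h, m in out.items() if not m.any()]
    if empty:
        raise MaskError(f"horn(s) empty on every slice: {empty}")
    return HornMaskSet(masks=out, provenance="PROB")


def build_cog_horn_masks(prob_masks: HornMaskSet) -> HornMaskSet:
    """Center-of-gravity (COG) masks: one voxel per horn per nonempty slice.

    The voxel is the mask member nearest the horn's in-plane centroid
    (ties broken lexicographically), then combined across slices.
    """
    nz = prob_masks.shape[2]
    out = {h: np.zeros(prob_masks.shape, dtype=bool) for h in HORNS}
    for h in HORNS:
        for z in range(nz):
            coords = np.argwhere(prob_masks[h][:, :, z])
            if coords.size == 0:
                warnings.warn(f"horn {h} empty on slice {z}; no COG voxel")
                continue
            centroid = coords.mean(axis=0)
            d2 = ((coords - centroid) ** 2).sum(axis=1)
            best = d2.min()
            cands = coords[d2 <= best + 1e-12]
            cands = cands[np.lexsort((cands[:, 0], cands[:, 1]))]
            x, y = cands[0]
            out[h][x, y, z] = True
    return HornMaskSet(masks=out, provenance="COG")


def build_segment_masks(segment_probs: dict, threshold: float = 0.5) -> SegmentMaskSet:
    """Threshold per-segment probabilistic maps and remove overlap.

    Overlap voxels go to the segment with the higher probability; exact
    ties go to the more rostral segment (earlier in dict order).
    """
    names = list(segment_probs)
    probs = np.stack([np.asarray(segment_probs[n], dtype=float) for n in names])
    supra = probs >= threshold
    any_supra = supra.any(axis=0)
    masked = np.where(supra, probs, -np.inf)
    # argmax takes the first maximum -> rostral wins exact ties
    winner = np.argmax(masked, axis=0)
    out = {}
    for i, name in enumerate(names):
        out[name] = any_supra & (winner == i)
    return SegmentMaskSet(masks=out)


def intersect_horn_segments(horns: HornMaskSet, segments: SegmentMaskSet) -> dict:
    """Per-segment horn mask sets (plain set intersection)."""
    out = {}
    for seg in segments.names:
        restricted = horns.restricted(segments[seg], seg)
        if any(not m.any() for m in restricted.masks.values()):
            warnings.warn(f"empty horn/segment intersection in {seg}")
        out[seg] = restricted
    return out


def build_wm_mask(wm_prob: np.ndarray, gm_prob: np.ndarray,
                  wm_threshold: float = 0.10, gm_threshold: float = 0.50) -> np.ndarray:
    """White-matter nuisance mask: WM >= 10% minus the dilated GM >= 50% mask."""
    mask = (np.asarray(wm_prob) >= wm_threshold) & \
        ~binary_dilation(np.asarray(gm_prob) >= gm_threshold, structure=_DIL)
    if not mask.any():
        raise MaskError("white-matter mask is empty")
    return mask


def build_ns_mask(cord_mask: np.ndarray, csf_mask: np.ndarray,
                  fov_mask: np.ndarray = None) -> np.ndarray:
    """Non-spinal mask: invert(dilate(cord | CSF)), optionally within a FOV."""
    mask = ~binary_dilation(np.asarray(cord_mask, dtype=bool)
                            | np.asarray(csf_mask, dtype=bool), structure=_DIL)
    if fov_mask is not None:
        mask &= np.asarray(fov_mask, dtype=bool)
    if not mask.any():
        raise MaskError("non-spinal mask is empty")
    return mask
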