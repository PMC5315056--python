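"""In-memory containers for 4D fMRI data and probabilistic atlases, with NIfTI-1 I/O.

All maps live on a single common voxel grid (no registration is performed):
axis 0 = x (left-right), axis 1 = y (posterior-anterior, so +y is ventral),
axis 2 = z (rostro-caudal slice axis), axis 3 = time.  Coordinates are
0-based voxel indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

SLICE_AXIS = 2

# canonical horn order used everywhere: left/right x dorsal/ventral
HORNS = ("LD", "LV", "RD", "RV")


class GridError(ValueError):
    """Raised when arrays do not share the expected grid/shape."""


@dataclass
class Fmri4D:
    """A 4D fMRI acquisition: intensity array plus grid metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities. Must be finite.
    voxel_size : tuple of float
        Voxel edge lengths in mm, (dx, dy, dz).
    tr : float
        Repetition time in seconds (time between volumes).
    slice_axis : int
        Axis along which slices were acquired (always 2 here).
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 5.0)
    tr: float = 1.89
    slice_axis: int = SLICE_AXIS

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise GridError(f"expected 4D array, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise GridError("non-finite values in 4D data")
        if self.tr <= 0:
            raise GridError("TR must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    def save(self, path):
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self._affine())
        img.header.set_zooms(tuple(self.voxel_size) + (self.tr,))
        nib.save(img, str(path))

    def _affine(self):
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    @classmethod
    def load(cls, path) -> "Fmri4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.89
        return cls(data=data, voxel_size=tuple(float(z) for z in zooms[:3]), tr=tr)


def save_map(arr: np.ndarray, path, voxel_size=(1.0, 1.0, 5.0)):
    """Write a 3D map (probabilistic or binary) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                          np.diag(list(voxel_size) + [1.0]))
    nib.save(img, str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


@dataclass
class AtlasBundle:
    """Probabilistic tissue maps on the template grid.

    gm/wm/csf/cord/body are probability maps in [0, 1]; ``segments`` maps
    segment name (rostral to caudal order) to its probabilistic map;
    ``csf_channels`` is an integer label map (0 = not CSF, 1..4 = channel).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    cord: np.ndarray
    body: np.ndarray
    segments: dict = field(default_factory=dict)
    csf_channels: np.ndarray = None
    horn_weights: dict = field(default_factory=dict)  # per-horn signal profile
    voxel_size: tuple = (1.0, 1.0, 5.0)

    def __post_init__(self):
        shape = self.gm.shape
        for name in ("wm", "csf", "cord", "body"):
            if getattr(self, name).shape != shape:
                raise GridError(f"{name} map not on the same grid as gm")
        for prob in (self.gm, self.wm, self.csf, self.cord, self.body):
            if prob.min() < 0 or prob.max() > 1 + 1e-9:
                raise GridError("probability map outside [0, 1]")

    @property
    def shape(self):
        return self.gm.shape

    @property
    def segment_names(self):
        return tuple(self.segments)

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("gm", "wm", "csf", "cord", "body"):
            save_map(getattr(self, name), outdir / f"{name}.nii.gz", self.voxel_size)
        for seg, arr in self.segments.items():
            save_map(arr, outdir / f"segment_{seg}.nii.gz", self.voxel_size)
        if self.csf_channels is not None:
            save_map(self.csf_channels, outdir / "csf_channels.nii.gz", self.voxel_size)
        for horn, arr in self.horn_weights.items():
            save_map(arr, outdir / f"hornweight_{horn}.nii.gz", self.voxel_size)
        meta = {"segments": list(self.segments), "voxel_size": list(self.voxel_size)}
        (outdir / "atlas.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, indir) -> "AtlasBundle":
        indir = Path(indir)
        meta = json.loads((indir / "atlas.json").read_text())
        kwargs = {name: load_map(indir / f"{name}.nii.gz")
                  for name in ("gm", "wm", "csf", "cord", "body")}
        segments = {seg: load_map(indir / f"segment_{seg}.nii.gz")
                    for seg in meta["segments"]}
        channels_path = indir / "csf_channels.nii.gz"
        channels = load_map(channels_path) if channels_path.exists() else None
        if channels is not None:
            channels = np.rint(channels).astype(int)
        horn_weights = {}
        for horn in HORNS:
            p = indir / f"hornweight_{horn}.nii.gz"
            if p.exists():
                horn_weights[horn] = load_map(p)
        return cls(segments=segments, csf_channels=channels,
                   horn_weights=horn_weights,
                   voxel_size=tuple(meta["voxel_size"]), **kwargs)
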