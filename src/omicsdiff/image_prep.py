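"""Turn 3D grayscale volumes into fixed-size normalised 2D projections.

The imaging pipeline mirrors standard breast-MRI preprocessing: a 3D volume
(varying slice counts) is collapsed to a 2D orthographic projection along a
named anatomical axis — maximum-intensity projection by default, which is
the standard 2D rendering for contrast-enhanced breast MRI — then resized to
a square target (default 128 x 128) with nearest-pixel interpolation, and
min-max normalised into the value range the diffusion model trains on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Volume3D",
    "Projection2D",
    "orthographic_project",
    "resize_nearest",
    "normalize",
    "load_volume",
    "load_image",
    "save_png",
]

AXES = ("sagittal", "coronal", "axial")


class AxisError(ValueError):
    pass


@dataclass(frozen=True)
class Volume3D:
    """A 3D grayscale volume with named anatomical axes.

    ``axis_labels[i]`` names the i-th array axis; ``spacing`` is the optional
    voxel size in mm.
    """

    voxels: np.ndarray
    axis_labels: tuple = AXES
    spacing: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("volume must be 3D with at least one slice per axis")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("voxel intensities must be finite and non-negative")
        if len(self.axis_labels) != 3 or len(set(self.axis_labels)) != 3:
            raise ValueError("need three distinct axis labels")
        object.__setattr__(self, "voxels", v.astype(np.float64))


@dataclass(frozen=True)
class Projection2D:
    """A square-able grayscale image in a declared value range."""

    pixels: np.ndarray
    value_range: tuple = (0.0, np.inf)  # 'raw' = whatever the source had
    provenance: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("projection must be a 2D array")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixels must be finite")
        lo, hi = self.value_range
        if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
            raise ValueError("pixels fall outside the declared value range")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self):
        return self.pixels.shape


def orthographic_project(vol: Volume3D, axis: str = "sagittal",
                         mode: str = "max") -> Projection2D:
    """Collapse the volume along ``axis`` by ray-wise max or mean."""
    if axis not in vol.axis_labels:
        raise AxisError(f"unknown axis {axis!r}; volume has {vol.axis_labels}")
    if mode not in ("max", "mean"):
        raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
    ax = vol.axis_labels.index(axis)
    reducer = np.max if mode == "max" else np.mean
    pix = reducer(vol.voxels, axis=ax)
    return Projection2D(pix, value_range=(0.0, np.inf),
                        provenance=f"project:{axis}:{mode}")


def resize_nearest(img: Projection2D, size: int) -> Projection2D:
    """Resize to size x size by nearest-pixel lookup.

    Output pixel (i, j) copies source pixel (floor((i+0.5)*H/size),
    floor((j+0.5)*W/size)) — half-pixel centers, so ties cannot occur and no
    new intensity values are introduced.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    h, w = img.pixels.shape
    rows = np.floor((np.arange(size) + 0.5) * h / size).astype(int)
    cols = np.floor((np.arange(size) + 0.5) * w / size).astype(int)
    pix = img.pixels[np.ix_(rows, cols)]
    return Projection2D(pix, value_range=img.value_range,
                        provenance=img.provenance + f"|resize:{size}")


def normalize(img: Projection2D, target_range=(-1.0, 1.0),
              source_max: float | None = None) -> Projection2D:
    """Affine-map observed [min, max] (or [0, source_max]) onto target_range.

    Constant images map to the midpoint of the target range.  The map is
    monotone, so pixel ranks are preserved.
    """
    lo_t, hi_t = target_range
    if not hi_t > lo_t:
        raise ValueError("target range must be non-degenerate")
    p = img.pixels
    if source_max is not None:
        lo_s, hi_s = 0.0, float(source_max)
    else:
        lo_s, hi_s = float(p.min()), float(p.max())
    if hi_s == lo_s:
        out = np.full_like(p, (lo_t + hi_t) / 2.0)
    else:
        out = (p - lo_s) / (hi_s - lo_s) * (hi_t - lo_t) + lo_t
        out = np.clip(out, lo_t, hi_t)
    return Projection2D(out, value_range=(lo_t, hi_t),
                        provenance=img.provenance + f"|norm:{target_range}")


# -- I/O -------------------------------------------------------------------


def load_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) volume; intensities shifted to >= 0 if the
    scanner stored signed values."""
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if data.ndim > 3:
        data = data[..., 0]
    if data.min() < 0:
        data = data - data.min()
    return Volume3D(data)


def load_image(path) -> Projection2D:
    """Read a 2D grayscale PNG/TIFF (or a .npy float dump)."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("F"), dtype=np.float64)
    return Projection2D(arr, value_range=(float(arr.min()), float(arr.max())),
                        provenance=f"load:{path.name}")


def save_png(img: Projection2D, path, bit_depth: int = 8) -> None:
    """Write as 8- or 16-bit grayscale PNG, min-max scaled; a lossless .npy
    float sidecar can be kept for round-trip-exact pipelines."""
    from PIL import Image

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    p = img.pixels
    rng = p.max() - p.min()
    scaled = (p - p.min()) / rng if rng > 0 else np.zeros_like(p)
    top = 2**bit_depth - 1
    q = np.round(scaled * top).astype(np.uint8 if bit_depth == 8 else np.uint16)
    Image.fromarray(q, mode="L" if bit_depth == 8 else "I;16").save(str(path))
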