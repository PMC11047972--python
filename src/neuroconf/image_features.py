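"""Intensity statistics along branching segments and tubularity predicates.

The energy function compares the mean intensity and intensity standard
deviation sampled under two segments; artifact rules additionally ask whether
a branch is supported by tubular (vessel-like) image signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import BoundsError, DegenerateSegmentError

__all__ = [
    "ImageVolume",
    "TubularityMask",
    "SegmentFeatures",
    "segment_intensity_stats",
    "point_has_tubularity",
    "branch_has_tubularity",
]


@dataclass
class ImageVolume:
    """A 3D intensity grid indexed ``data[z, y, x]``.

    ``dtype_max`` is the normalization constant used to make intensity-based
    energies commensurate with the angular term (255 for 8-bit, 65535 for
    16-bit; the data maximum for float input).
    """

    data: np.ndarray
    dtype_max: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ImageVolume":
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            m = float(np.iinfo(arr.dtype).max)
        else:
            m = float(arr.max()) if arr.size and arr.max() > 0 else 1.0
        return cls(arr, m)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class TubularityMask:
    """Boolean vesselness mask over the same grid as its source volume."""

    data: np.ndarray
    response: np.ndarray | None = None  # raw vesselness, kept for diagnostics

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)


@dataclass
class SegmentFeatures:
    """Mean intensity I, population standard deviation sigma, sample count."""

    mean_intensity: float
    intensity_sd: float
    n_samples: int


def _sample(vol: ImageVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of (x, y, z) points; outside points clip to the border."""
    pts = np.asarray(points, dtype=float)
    # map_coordinates wants (z, y, x) rows
    coords = pts[:, ::-1].T
    return ndi.map_coordinates(vol.data.astype(float), coords, order=1, mode="nearest")


def segment_intensity_stats(vol: ImageVolume, seg, normalize: bool = False) -> SegmentFeatures:
    """Mean and population SD of the image sampled at a segment's points.

    With ``normalize=True`` intensities are divided by ``vol.dtype_max`` (the
    convention used inside the energy function).
    """
    points = getattr(seg, "points", seg)
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise DegenerateSegmentError("cannot compute stats of an empty segment")
    vals = _sample(vol, points)
    if normalize:
        vals = vals / vol.dtype_max
    return SegmentFeatures(float(vals.mean()), float(vals.std()), len(vals))


def point_has_tubularity(mask: TubularityMask, p) -> bool:
    """True iff the mask is set at voxel ``p`` (x, y, z) or any of its 26 neighbors.

    The lenient (OR over the neighborhood) reading: a strict AND would reject
    every surface point of a one-voxel-thick tube.
    """
    x, y, z = (int(round(c)) for c in p)
    nz, ny, nx = mask.data.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise BoundsError(f"point {(x, y, z)} outside grid {mask.data.shape}")
    sl = mask.data[
        max(z - 1, 0) : z + 2,
        max(y - 1, 0) : y + 2,
        max(x - 1, 0) : x + 2,
    ]
    return bool(sl.any())


def branch_has_tubularity(mask: TubularityMask, points, threshold: float = 0.70) -> bool:
    """True iff >= ``threshold`` of the branch's node positions have tubularity.

    ``points`` is an (N, 3) array of (x, y, z) node positions; positions are
    rounded to voxels and out-of-grid positions count as non-tubular.  The
    threshold is inclusive.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise DegenerateSegmentError("branch has no points")
    hits = 0
    for p in pts:
        try:
            if point_has_tubularity(mask, p):
                hits += 1
        except BoundsError:
            pass
    return hits / len(pts) >= threshold - 1e-12
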