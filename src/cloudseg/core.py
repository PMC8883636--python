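"""Core domain types: grayscale images, 2D interest regions, the pixel-features
point cloud, 3D grayscale boxes and binary segmentation masks.

The central idea is a bijection between the pixels of a 2D interest region and a
3D point set: pixel (row, col) with intensity v becomes the point
``(x=col, y=row, z=v)``.  A 3D box shares the region's 2D footprint and is
parameterized along the grayscale axis by its center ``l_h`` and width ``l_w``;
its top and bottom act as thresholding values, so boxed points project back to
a binary segmentation mask.

Conventions
-----------
* coordinates are 0-based, row-major; 2D boxes are half-open
  ``[r0, r1) x [c0, c1)``,
* the grayscale interval of a 3D box is closed on both ends: the top and
  bottom threshold values belong to the object,
* point layout is ``(x=column, y=row, z=grayscale)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "ROIBox2D",
    "PixelCloud",
    "Box3D",
    "SegMask",
    "image_to_cloud",
    "points_in_box",
    "box_to_mask",
    "clip_box",
    "BoundsError",
    "FootprintMismatchError",
    "EmptyCloudError",
    "ConfigError",
    "ParseError",
]

GRAY_MIN = 0.0
GRAY_MAX = 255.0

# ITU-R BT.601 luminance weights used to collapse RGB inputs to 8-bit gray.
_BT601 = np.array([0.299, 0.587, 0.114])


class BoundsError(ValueError):
    """A box or region does not lie within its image."""


class FootprintMismatchError(ValueError):
    """A 3D box and a point cloud do not share the same 2D footprint."""


class EmptyCloudError(ValueError):
    """An operation that requires points received an empty cloud."""


class ConfigError(ValueError):
    """Invalid configuration or unusable input data."""


class ParseError(ValueError):
    """A record in an interchange file could not be parsed or validated."""


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale image (2D uint8 array, intensities 0-255)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("GrayImage requires a non-empty 2D array")
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise ValueError("grayscale values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return int(self.values.shape[0])

    @property
    def width(self) -> int:
        return int(self.values.shape[1])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GrayImage":
        """Build from a 2D gray or (H, W, 3) RGB array (BT.601 luminance)."""
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] in (3, 4):
            arr = np.clip(np.round(arr[..., :3].astype(float) @ _BT601), 0, 255)
        return cls(arr)

    @classmethod
    def from_file(cls, path: str | Path) -> "GrayImage":
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "F"):
                raise ConfigError(
                    f"{path}: 16-bit/float images are not supported; "
                    "convert to 8-bit grayscale first"
                )
            if im.mode in ("RGB", "RGBA", "P"):
                return cls.from_array(np.asarray(im.convert("RGB")))
            return cls(np.asarray(im.convert("L")))

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.values, mode="L").save(path)


@dataclass(frozen=True)
class ROIBox2D:
    """A 2D interest region: half-open pixel box [r0, r1) x [c0, c1).

    ``score`` is the detector confidence in [0, 1]; ``label`` names the object
    class the region is expected to contain.
    """

    r0: int
    c0: int
    r1: int
    c1: int
    score: float = 1.0
    label: str = "object"

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError(f"degenerate ROI box {self.as_tuple()}")
        if self.r0 < 0 or self.c0 < 0:
            raise ValueError(f"negative ROI corner {self.as_tuple()}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"ROI score {self.score} outside [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.r1 - self.r0

    @property
    def n_cols(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.n_rows * self.n_cols

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.r0, self.c0, self.r1, self.c1)

    def same_extent(self, other: "ROIBox2D") -> bool:
        return self.as_tuple() == other.as_tuple()

    def validate_within(self, height: int, width: int) -> None:
        if self.r1 > height or self.c1 > width:
            raise BoundsError(
                f"ROI {self.as_tuple()} exceeds image bounds {height}x{width}"
            )

    def clipped(self, height: int, width: int) -> "ROIBox2D":
        return replace(
            self,
            r0=max(self.r0, 0),
            c0=max(self.c0, 0),
            r1=min(self.r1, height),
            c1=min(self.c1, width),
        )


@dataclass(frozen=True)
class PixelCloud:
    """The pixel-features point cloud of one interest region.

    ``points`` is an (N, 3) float array with columns (x=col, y=row, z=gray);
    coordinates are absolute image coordinates.  A cloud built from an ROI is
    in bijection with the ROI's pixels (N == n_rows * n_cols).
    """

    points: np.ndarray
    roi: ROIBox2D

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must form an (N, 3) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def save_xyz(self, path: str | Path) -> None:
        """Export as ASCII XYZ, one 'x y z' triple per line."""
        np.savetxt(path, self.points, fmt="%.1f")

    @classmethod
    def load_xyz(cls, path: str | Path, roi: ROIBox2D) -> "PixelCloud":
        return cls(np.loadtxt(path, ndmin=2), roi)


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned 3D box: 2D footprint plus a grayscale interval.

    The grayscale interval is ``[l_h - l_w/2, l_h + l_w/2]``, closed on both
    ends.  Anchors, proposals and refined boxes are all instances of this type
    and differ only in how (l_h, l_w) were produced.
    """

    l_h: float
    l_w: float
    footprint: ROIBox2D

    @property
    def z_lo(self) -> float:
        return self.l_h - self.l_w / 2.0

    @property
    def z_hi(self) -> float:
        return self.l_h + self.l_w / 2.0

    @property
    def interval(self) -> tuple[float, float]:
        return (self.z_lo, self.z_hi)

    @property
    def volume(self) -> float:
        return self.footprint.area * max(self.z_hi - self.z_lo, 0.0)


def clip_box(box: Box3D) -> Box3D:
    """Clip a box's grayscale interval to [0, 255].

    If the width is non-positive or the clipped interval is empty, the interval
    is floored at one gray level centered on the clipped ``l_h`` (re-clipped to
    the gray range), so a degenerate regression output can never produce an
    empty segment.
    """
    lo = max(box.z_lo, GRAY_MIN)
    hi = min(box.z_hi, GRAY_MAX)
    if box.l_w <= 0 or lo > hi:
        c = min(max(box.l_h, GRAY_MIN), GRAY_MAX)
        lo = max(c - 0.5, GRAY_MIN)
        hi = min(c + 0.5, GRAY_MAX)
    return Box3D(l_h=(lo + hi) / 2.0, l_w=hi - lo, footprint=box.footprint)


def image_to_cloud(image: GrayImage, roi: ROIBox2D) -> PixelCloud:
    """Map every pixel of an interest region to one 3D point.

    Point (x, y, z) has x = column index, y = row index, z = the image value
    at (row, column); the mapping is a bijection with the ROI pixels.
    """
    roi.validate_within(image.height, image.width)
    sub = image.values[roi.r0 : roi.r1, roi.c0 : roi.c1]
    rows, cols = np.mgrid[roi.r0 : roi.r1, roi.c0 : roi.c1]
    pts = np.column_stack(
        [cols.ravel().astype(float), rows.ravel().astype(float), sub.ravel().astype(float)]
    )
    return PixelCloud(points=pts, roi=roi)


def points_in_box(cloud: PixelCloud, box: Box3D) -> PixelCloud:
    """Select the cloud points whose grayscale lies inside the box interval.

    The interval test is closed on both ends.  The cloud and the box must share
    the same 2D footprint.
    """
    if not box.footprint.same_extent(cloud.roi):
        raise FootprintMismatchError(
            f"box footprint {box.footprint.as_tuple()} != cloud ROI {cloud.roi.as_tuple()}"
        )
    z = cloud.z
    keep = (z >= box.z_lo) & (z <= box.z_hi)
    return PixelCloud(points=cloud.points[keep], roi=cloud.roi)


def box_to_mask(image: GrayImage, box: Box3D) -> "SegMask":
    """Rasterize a 3D box back into a full-size binary segmentation mask.

    A pixel is foreground iff it lies inside the box footprint and its value
    lies inside the closed grayscale interval; this equals rasterizing
    ``points_in_box(image_to_cloud(image, footprint), box)``.
    """
    fp = box.footprint
    fp.validate_within(image.height, image.width)
    mask = np.zeros((image.height, image.width), dtype=np.uint8)
    sub = image.values[fp.r0 : fp.r1, fp.c0 : fp.c1].astype(float)
    mask[fp.r0 : fp.r1, fp.c0 : fp.c1] = (sub >= box.z_lo) & (sub <= box.z_hi)
    return SegMask(values=mask)


@dataclass(frozen=True)
class SegMask:
    """A binary segmentation mask with the shape of its source image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("SegMask requires a 2D array")
        if arr.dtype != np.uint8:
            arr = arr.astype(np.uint8)
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "values", arr)

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def union(self, other: "SegMask") -> "SegMask":
        return SegMask(np.maximum(self.values, other.values))

    def save(self, path: str | Path) -> None:
        """Write as PNG with foreground 255, background 0."""
        Image.fromarray(self.values * np.uint8(255), mode="L").save(path)

    @classmethod
    def from_file(cls, path: str | Path) -> "SegMask":
        with Image.open(path) as im:
            return cls((np.asarray(im.convert("L")) > 127).astype(np.uint8))
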