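"""Image I/O and shared 2D/3D primitives.

Axis order is (z, y, x) everywhere, 0-based. Stacks are single-channel
8- or 16-bit TIFFs; annotation masks are tri-level 8-bit images with
0 = background, 128 = nucleus, 255 = chromocenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import disk

TRILEVEL_VALUES = (0, 128, 255)


@dataclass
class ZStack:
    """A single-channel confocal z-stack.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Non-negative intensities.
    voxel_size : tuple of float
        (dz, dy, dx) in micrometres. Defaults to (1, 1, 1) when the
        acquisition metadata is unknown, in which case downstream areas
        are reported in pixel units.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ZStack requires a 3D (z, y, x) array")
        if self.voxels.shape[0] < 1:
            raise ValueError("ZStack requires at least one slice")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.isfinite(self.voxels).all():
            raise ValueError("ZStack intensities must be finite")
        if (self.voxels < 0).any():
            raise ValueError("ZStack intensities must be non-negative")
        dz, dy, dx = self.voxel_size
        if dy <= 0 or dx <= 0:
            raise ValueError("voxel_size dy and dx must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def bit_depth(self) -> int:
        return 16 if self.voxels.dtype.itemsize > 1 else 8


@dataclass
class Image2D:
    """A 2D image with an optional physical pixel size (dy, dx) in µm."""

    pixels: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.isfinite(self.pixels).all():
            raise ValueError("Image2D requires finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_zstack(path, voxel_size=None) -> ZStack:
    """Read a single-channel multi-page TIFF as a :class:`ZStack`.

    Slices are taken in page order. ``voxel_size`` overrides any TIFF
    resolution metadata; with neither available the size defaults to
    (1, 1, 1) and areas fall back to pixel units.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta_size = _voxel_size_from_tiff(tif)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("single channel required: stack must be a grayscale multi-page TIFF")
    # an RGB(A) page shows up as a trailing axis of length 3 or 4
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("single channel required: multi-channel TIFF not supported")
    if voxel_size is None:
        voxel_size = meta_size if meta_size is not None else (1.0, 1.0, 1.0)
    return ZStack(arr, tuple(float(v) for v in voxel_size))


def _voxel_size_from_tiff(tif) -> tuple[float, float, float] | None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        xnum, xden = xres.value
        ynum, yden = yres.value
        if xnum == 0 or ynum == 0:
            return None
        dx = xden / xnum
        dy = yden / ynum
        dz = 1.0
        ij = tif.imagej_metadata
        if ij and "spacing" in ij:
            dz = float(ij["spacing"])
        return (dz, dy, dx)
    except Exception:
        return None


def write_zstack(stack: ZStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")


def z_project(stack: ZStack, method: str = "max") -> Image2D:
    """Project a stack along z.

    ``method="max"`` takes the pixelwise maximum; ``method="std"`` the
    population (divide-by-N) standard deviation, matching common
    imaging-software behaviour.
    """
    if method == "max":
        proj = stack.voxels.max(axis=0)
    elif method == "std":
        proj = stack.voxels.astype(np.float64).std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown projection method {method!r}; use 'max' or 'std'")
    dz, dy, dx = stack.voxel_size
    return Image2D(proj, (dy, dx))


def median_filter2d(image: Image2D, radius: int) -> Image2D:
    """Median filter over a disk of the given radius (pixels).

    Radius 0 is the identity. Edges are handled by reflection.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return Image2D(image.pixels.copy(), image.pixel_size)
    footprint = disk(int(radius))
    out = ndi.median_filter(image.pixels, footprint=footprint, mode="reflect")
    return Image2D(out, image.pixel_size)


def write_trilevel_mask(mask, path) -> None:
    """Write a tri-level annotation mask as an 8-bit image.

    Pixel values must be exactly {0, 128, 255}: background, nucleus,
    chromocenter. The file round-trips losslessly.
    """
    pixels = np.asarray(getattr(mask, "pixels", mask))
    bad = ~np.isin(pixels, TRILEVEL_VALUES)
    if bad.any():
        offending = np.unique(pixels[bad])
        raise ValueError(
            f"tri-level mask may only contain values {TRILEVEL_VALUES}; found {offending.tolist()}"
        )
    tifffile.imwrite(str(path), pixels.astype(np.uint8), photometric="minisblack")


def read_trilevel_mask(path) -> np.ndarray:
    """Read a tri-level mask back as a uint8 array, validating its values."""
    pixels = tifffile.imread(str(path))
    if pixels.ndim != 2:
        raise ValueError("tri-level mask must be a single 2D image")
    if not np.isin(pixels, TRILEVEL_VALUES).all():
        raise ValueError(f"file is not a tri-level mask (values outside {TRILEVEL_VALUES})")
    return pixels.astype(np.uint8)
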