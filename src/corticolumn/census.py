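"""Census coding of rectangular receptive fields.

A receptive field is a rectangle of the image split into a 3x3 grid of
sub-regions.  Each sub-region contributes one bit: 1 if its mean brightness
is at least the mean brightness of the whole rectangle, 0 otherwise.  The
nine bits are packed row-major with the top-left sub-region in the least
significant bit, giving an integer census code ``C`` with ``0 <= C < 512``.
The code is invariant to affine changes of brightness (gain > 0, offset),
which is what makes it usable as a detection feature.

All rectangle means are computed from an integral image (summed-area
table), so a mean costs four lookups regardless of rectangle size.
Coordinates are 0-based; rectangles are half-open: ``[x0, x0+w) x
[y0, y0+h)``.  Image arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "Region",
    "CodeMap",
    "load_grey",
    "to_grey",
    "build_integral",
    "build_integral_stack",
    "rect_sum",
    "block_mean",
    "subregion_bounds",
    "encode",
    "encode_at",
    "encode_stack",
    "decode",
    "pattern_image",
    "code_map",
]

#: Rec.601 luma weights used to collapse RGB input to grey levels.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle ``[x0, x0+w) x [y0, y0+h)`` in pixels."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"degenerate region {self.w}x{self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h


@dataclass(frozen=True)
class CodeMap:
    """Dense grid of census codes scanned over an aperture.

    ``codes[i, j]`` is the code of the region whose top-left corner is
    ``(x0 + j*stride, y0 + i*stride)``; only positions where the region
    lies fully inside the aperture are present.
    """

    codes: np.ndarray
    x0: int
    y0: int
    stride: int
    region_w: int
    region_h: int

    def to_csv(self, path) -> None:
        """Write one ``x,y,code`` row per grid cell."""
        with open(path, "w") as fh:
            fh.write("x,y,code\n")
            for i in range(self.codes.shape[0]):
                for j in range(self.codes.shape[1]):
                    x = self.x0 + j * self.stride
                    y = self.y0 + i * self.stride
                    fh.write(f"{x},{y},{self.codes[i, j]}\n")


def to_grey(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3]) array to integer grey levels.

    Color input is converted with Rec.601 luma weights and rounded to the
    nearest integer grey level.
    """
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = np.rint(arr[..., :3].astype(np.float64) @ _LUMA)
    if arr.ndim != 2:
        raise ValueError(f"expected 2D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite brightness")
    if np.min(arr) < 0:
        raise ValueError("image contains negative brightness")
    return arr


def load_grey(path) -> np.ndarray:
    """Load a PNG/JPEG as an integer grey-level array (8-bit or luma)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im)
        else:
            arr = np.asarray(im.convert("RGB"))
    return to_grey(arr).astype(np.int64)


def build_integral(image: np.ndarray) -> np.ndarray:
    """Summed-area table of shape (H+1, W+1); exact for integer input.

    ``S[y, x]`` is the sum of the image over ``[0, x) x [0, y)``, so any
    rectangle sum is four lookups.
    """
    image = to_grey(image)
    dtype = np.int64 if np.issubdtype(image.dtype, np.integer) else np.float64
    ii = np.zeros((image.shape[0] + 1, image.shape[1] + 1), dtype=dtype)
    np.cumsum(np.cumsum(image, axis=0, dtype=dtype), axis=1, out=ii[1:, 1:])
    return ii


def build_integral_stack(windows: np.ndarray) -> np.ndarray:
    """Integral images for a stack of same-size windows, shape (n, H+1, W+1)."""
    windows = np.asarray(windows)
    if windows.ndim != 3:
        raise ValueError("expected (n, H, W) stack")
    dtype = np.int64 if np.issubdtype(windows.dtype, np.integer) else np.float64
    n, h, w = windows.shape
    ii = np.zeros((n, h + 1, w + 1), dtype=dtype)
    np.cumsum(np.cumsum(windows, axis=1, dtype=dtype), axis=2, out=ii[:, 1:, 1:])
    return ii


def _check_bounds(ii: np.ndarray, region: Region) -> None:
    h, w = ii.shape[-2] - 1, ii.shape[-1] - 1
    if region.x0 < 0 or region.y0 < 0 or region.x0 + region.w > w or region.y0 + region.h > h:
        raise IndexError(
            f"region {region} outside image {w}x{h}"
        )


def rect_sum(ii: np.ndarray, region: Region):
    """Sum of brightness over the region, four integral-image lookups."""
    _check_bounds(ii, region)
    x0, y0, x1, y1 = region.x0, region.y0, region.x0 + region.w, region.y0 + region.h
    return ii[..., y1, x1] - ii[..., y0, x1] - ii[..., y1, x0] + ii[..., y0, x0]


def block_mean(ii: np.ndarray, region: Region) -> float:
    """Mean brightness of a rectangular fragment."""
    return rect_sum(ii, region) / region.area


def subregion_bounds(region: Region) -> list[Region]:
    """The nine sub-regions f_0..f_8 of a receptive field, row-major.

    Cut points sit at ``round(k*extent/3)`` for k = 0..3, which tiles the
    region exactly for any width/height >= 3 (e.g. w=10 gives column
    widths 3, 4, 3).
    """
    if region.w < 3 or region.h < 3:
        raise ValueError(f"coding region must be at least 3x3, got {region.w}x{region.h}")
    xs = [region.x0 + int(k * region.w / 3 + 0.5) for k in range(4)]
    ys = [region.y0 + int(k * region.h / 3 + 0.5) for k in range(4)]
    return [
        Region(xs[c], ys[r], xs[c + 1] - xs[c], ys[r + 1] - ys[r])
        for r in range(3)
        for c in range(3)
    ]


def encode(ii: np.ndarray, region: Region) -> int:
    """Census code of one receptive field.

    Bit ``n = 3*r + c`` is 1 iff the mean of sub-region (row r, col c) is
    >= the mean of the whole region (ties count as 1).  For integer
    integral images the comparison is done on cross-multiplied integer
    sums, so it is exact.
    """
    _check_bounds(ii, region)
    total = rect_sum(ii, region)
    code = 0
    exact = np.issubdtype(np.asarray(total).dtype, np.integer)
    for n, sub in enumerate(subregion_bounds(region)):
        s = rect_sum(ii, sub)
        if exact:
            hit = int(s) * region.area >= int(total) * sub.area
        else:
            hit = s / sub.area >= total / region.area
        if hit:
            code |= 1 << n
    return code


def _rect_sums_at(ii: np.ndarray, x0, y0, w: int, h: int):
    """Vectorized rectangle sums at broadcastable origin arrays.

    For a 2D integral image, ``x0``/``y0`` are arrays of origins.  For a
    stacked (n, H+1, W+1) integral image, scalar origins give per-window
    sums.
    """
    if ii.ndim == 2:
        return ii[y0 + h, x0 + w] - ii[y0, x0 + w] - ii[y0 + h, x0] + ii[y0, x0]
    return (
        ii[:, y0 + h, x0 + w] - ii[:, y0, x0 + w] - ii[:, y0 + h, x0] + ii[:, y0, x0]
    )


def _encode_many(ii: np.ndarray, x0, y0, region: Region) -> np.ndarray:
    """Census codes of ``region`` translated to origins ``(x0, y0)``.

    ``region`` holds window-relative geometry; ``x0``/``y0`` are arrays of
    window origins (2D integral image) or scalars (stacked windows).
    Comparison is exact (cross-multiplied) for integer tables.
    """
    subs = subregion_bounds(region)
    total = _rect_sums_at(ii, x0 + region.x0, y0 + region.y0, region.w, region.h)
    exact = np.issubdtype(ii.dtype, np.integer)
    codes = np.zeros(np.shape(total), dtype=np.int64)
    for n, sub in enumerate(subs):
        s = _rect_sums_at(ii, x0 + sub.x0, y0 + sub.y0, sub.w, sub.h)
        if exact:
            hit = s * region.area >= total * sub.area
        else:
            hit = s * (1.0 / sub.area) >= total * (1.0 / region.area)
        codes |= hit.astype(np.int64) << n
    return codes


def encode_at(ii: np.ndarray, xs: np.ndarray, ys: np.ndarray, region: Region) -> np.ndarray:
    """Codes of a window-relative region at many window origins of one image."""
    return _encode_many(ii, np.asarray(xs), np.asarray(ys), region)


def encode_stack(ii_stack: np.ndarray, region: Region) -> np.ndarray:
    """Codes of one region across a stack of same-size windows."""
    return _encode_many(ii_stack, 0, 0, region)


def decode(code: int) -> np.ndarray:
    """3x3 binary pattern of a census code (inverse of the bit packing)."""
    if not 0 <= code < 512:
        raise ValueError(f"census code must be in [0, 512), got {code}")
    bits = (code >> np.arange(9)) & 1
    return bits.reshape(3, 3).astype(np.uint8)


def pattern_image(
    pattern: np.ndarray, cell: int = 10, lo: int = 50, hi: int = 200
) -> np.ndarray:
    """Block image realizing a 3x3 binary pattern (1 -> hi, 0 -> lo)."""
    pattern = np.asarray(pattern, dtype=np.uint8).reshape(3, 3)
    levels = np.where(pattern > 0, hi, lo).astype(np.int64)
    return np.kron(levels, np.ones((cell, cell), dtype=np.int64))


def code_map(
    ii: np.ndarray,
    aperture: Region,
    region_size: tuple[int, int],
    stride: int,
) -> CodeMap:
    """Dense census-code map of overlapping receptive fields in an aperture.

    Positions whose region would poke outside the aperture are omitted.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rw, rh = region_size
    if rw > aperture.w or rh > aperture.h:
        raise ValueError("region size does not fit inside the aperture")
    xs = np.arange(aperture.x0, aperture.x0 + aperture.w - rw + 1, stride)
    ys = np.arange(aperture.y0, aperture.y0 + aperture.h - rh + 1, stride)
    gx, gy = np.meshgrid(xs, ys)
    codes = encode_at(ii, gx.ravel(), gy.ravel(), Region(0, 0, rw, rh))
    return CodeMap(
        codes=codes.reshape(len(ys), len(xs)).astype(np.int16),
        x0=int(aperture.x0),
        y0=int(aperture.y0),
        stride=stride,
        region_w=rw,
        region_h=rh,
    )
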