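"""Deterministic synthetic data: glyph windows, backgrounds, phantoms.

Two families of fixtures make every part of the package trainable and
testable without external data:

* digit glyphs rendered from a built-in public-domain 5x7 bitmap font
  onto detector-window-sized crops, with photometric jitter (gain,
  offset), geometric jitter (shift, scale) and additive Gaussian noise —
  training material for cascade columns;
* microscopy-like phantoms — bright disks standing in for neuron somas
  and thin curvilinear strokes for neural processes on a noisy
  background — inputs for the lateral-inhibition layer, emitted together
  with their ground truth.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "FONT_5X7",
    "GlyphSpec",
    "PhantomSpec",
    "render_glyph",
    "render_glyph_set",
    "render_backgrounds",
    "render_phantom",
    "write_dataset",
]

#: 5x7 dot-matrix digit font, one string row per scanline, '#' = on.
FONT_5X7 = {
    0: ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    9: ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
}


def _glyph_bitmap(digit: int) -> np.ndarray:
    rows = FONT_5X7[digit]
    return np.array([[c == "1" for c in row] for row in rows], dtype=np.uint8)


@dataclass(frozen=True)
class GlyphSpec:
    """Rendering conditions for digit training windows.

    Defaults: 24 px canonical window, foreground/background grey levels
    200/60, gain jitter +-15%, offset jitter +-20 grey levels, shift
    jitter +-2 px, scale jitter +-10%, noise sigma 8 grey levels.
    """

    window: int = 24
    fg: int = 200
    bg: int = 60
    gain_range: tuple[float, float] = (0.85, 1.15)
    offset_range: tuple[float, float] = (-20.0, 20.0)
    shift: int = 2
    scale_jitter: float = 0.10
    noise_sigma: float = 8.0
    fill: float = 0.75  # glyph height as a fraction of the window
    seed: int = 0


def render_glyph(
    digit: int,
    spec: GlyphSpec = GlyphSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One jittered window of a digit glyph (uint8, window x window).

    With ``rng=None`` the rendering is jitter- and noise-free: the glyph
    is the nearest-neighbour-scaled font bitmap, centered, at the nominal
    foreground/background levels.
    """
    bitmap = _glyph_bitmap(digit)
    f = spec.window * spec.fill / bitmap.shape[0]
    dx = dy = 0.0
    gain, offset = 1.0, 0.0
    noise = None
    if rng is not None:
        f *= 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter)
        dx = rng.uniform(-spec.shift, spec.shift)
        dy = rng.uniform(-spec.shift, spec.shift)
        gain = rng.uniform(*spec.gain_range)
        offset = rng.uniform(*spec.offset_range)
        noise = rng.normal(0.0, spec.noise_sigma, (spec.window, spec.window))
    gh = max(1, int(bitmap.shape[0] * f + 0.5))
    gw = max(1, int(bitmap.shape[1] * f + 0.5))
    ry = (np.arange(gh) * bitmap.shape[0] // gh).clip(max=bitmap.shape[0] - 1)
    rx = (np.arange(gw) * bitmap.shape[1] // gw).clip(max=bitmap.shape[1] - 1)
    scaled = bitmap[np.ix_(ry, rx)]
    win = np.full((spec.window, spec.window), float(spec.bg))
    y0 = int((spec.window - gh) / 2 + dy + 0.5)
    x0 = int((spec.window - gw) / 2 + dx + 0.5)
    y0 = min(max(y0, 0), spec.window - gh)
    x0 = min(max(x0, 0), spec.window - gw)
    win[y0 : y0 + gh, x0 : x0 + gw] = np.where(scaled > 0, float(spec.fg), float(spec.bg))
    win = gain * win + offset
    if noise is not None:
        win = win + noise
    return np.clip(np.rint(win), 0, 255).astype(np.uint8)


def render_glyph_set(
    spec: GlyphSpec,
    n_per_class: int,
    digits: tuple[int, ...] = tuple(range(10)),
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced stack of jittered glyph windows with digit labels."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    windows, labels = [], []
    for d in digits:
        for _ in range(n_per_class):
            windows.append(render_glyph(d, spec, rng))
            labels.append(d)
    return np.stack(windows), np.array(labels)


def render_backgrounds(
    size: tuple[int, int],
    style: str = "noise",
    n: int = 1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Glyph-free background images (uint8) in one of three styles.

    ``noise`` is smoothed Gaussian noise, ``gradient`` a random linear
    ramp, ``texture`` a sinusoidal grating with mild noise.
    """
    from scipy import ndimage

    if n < 1:
        raise ValueError("n must be >= 1")
    w, h = size
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if style == "noise":
            img = ndimage.gaussian_filter(rng.normal(128.0, 70.0, (h, w)), sigma=1.5)
        elif style == "gradient":
            ang = rng.uniform(0, 2 * np.pi)
            yy, xx = np.mgrid[0:h, 0:w]
            ramp = np.cos(ang) * xx + np.sin(ang) * yy
            lo, hi = sorted(rng.uniform(0, 255, 2))
            span = ramp.max() - ramp.min()
            img = lo + (hi - lo) * (ramp - ramp.min()) / (span if span else 1.0)
        elif style == "texture":
            ang = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.05, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            yy, xx = np.mgrid[0:h, 0:w]
            img = 128 + 80 * np.sin(freq * (np.cos(ang) * xx + np.sin(ang) * yy) + phase)
            img = img + rng.normal(0.0, 10.0, (h, w))
        else:
            raise ValueError(f"unknown background style {style!r}")
        out.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Microscopy-like phantom: bright somas and thin processes on noise."""

    size: tuple[int, int] = (192, 192)
    n_somas: int = 5
    soma_diameter: float = 12.0
    soma_diameter_sd: float = 0.0
    n_processes: int = 3
    process_width: int = 2
    process_length: tuple[int, int] = (40, 80)
    background: float = 40.0
    soma_brightness: float = 220.0
    process_brightness: float = 150.0
    noise_sigma: float = 4.0
    seed: int = 0


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Render a phantom and its ground truth.

    Returns ``(image, truth)`` where ``truth`` has a ``somas`` list of
    dicts (cx, cy, diameter) and a ``processes`` list of polylines.
    Somas are placed disjointly by rejection sampling; an overcrowded
    spec (no placement found in 1000 attempts) raises.
    """
    w, h = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), spec.background, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    somas = []
    for _ in range(spec.n_somas):
        d = max(3.0, spec.soma_diameter + rng.normal(0.0, spec.soma_diameter_sd))
        placed = False
        for _attempt in range(1000):
            cx = rng.uniform(d, w - d)
            cy = rng.uniform(d, h - d)
            if all(
                (cx - s["cx"]) ** 2 + (cy - s["cy"]) ** 2 > (d / 2 + s["diameter"] / 2 + 4) ** 2
                for s in somas
            ):
                placed = True
                break
        if not placed:
            raise ValueError("overcrowded phantom: cannot place somas disjointly")
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (d / 2) ** 2
        img[mask] = spec.soma_brightness
        somas.append({"cx": float(cx), "cy": float(cy), "diameter": float(d)})
    processes = []
    for _ in range(spec.n_processes):
        length = int(rng.integers(spec.process_length[0], spec.process_length[1] + 1))
        x = rng.uniform(10, w - 10)
        y = rng.uniform(10, h - 10)
        ang = rng.uniform(0, 2 * np.pi)
        pts = [(x, y)]
        for _step in range(length):
            ang += rng.normal(0.0, 0.15)
            x = min(max(x + np.cos(ang), 1), w - 2)
            y = min(max(y + np.sin(ang), 1), h - 2)
            pts.append((x, y))
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= (spec.process_width / 2.0) ** 2
            img[mask] = np.maximum(img[mask], spec.process_brightness)
        processes.append([(float(px), float(py)) for px, py in pts])
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, (h, w))
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, {"somas": somas, "processes": processes}


def write_dataset(
    directory, windows: np.ndarray, labels: np.ndarray, prefix: str = "sample"
) -> Path:
    """Write windows as PNGs plus a ``manifest.csv`` (path, label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "label"])
        for i, (win, lab) in enumerate(zip(windows, labels)):
            name = f"{prefix}_{i:05d}.png"
            Image.fromarray(win).save(directory / name)
            wr.writerow([name, int(lab)])
    return manifest


def write_truth_csv(truth: dict, path) -> None:
    """Phantom soma ground truth as CSV (id, cx, cy, diameter)."""
    with open(path, "w") as fh:
        fh.write("id,cx,cy,diameter\n")
        for i, s in enumerate(truth["somas"]):
            fh.write(f"{i},{s['cx']},{s['cy']},{s['diameter']}\n")
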