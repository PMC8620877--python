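"""Multi-scale sliding-window detection with spatial grouping.

A trained column only decides single canonical windows; this module slides
that window over a full image at a pyramid of scales (the window grows by
``scale_factor`` per level; the integral image is built once and reused)
and then groups overlapping raw accepts into detections.  Grouping plays
the role of the hidden layer that spatially connects the individual
cascade decisions: raw boxes are merged by single-link connected
components under an intersection-over-union threshold, and components
with enough members emit one averaged box.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .cascade import CascadeColumn, evaluate_positions
from .census import build_integral, to_grey

__all__ = ["RawAccept", "Detection", "scan", "group_detections", "detect", "save_detections", "draw_detections"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawAccept:
    """One accepted window in original-image coordinates."""

    x: int
    y: int
    w: int
    h: int
    score: float


@dataclass(frozen=True)
class Detection:
    """Grouped detection: averaged box, mean margin score, member count."""

    x: int
    y: int
    w: int
    h: int
    object_type: str
    score: float
    support: int


def scan(
    image: np.ndarray,
    column: CascadeColumn,
    scale_factor: float = 1.2,
    stride: int = 2,
    min_size: tuple[int, int] | None = None,
) -> list[RawAccept]:
    """All windows of the scale pyramid the cascade accepts.

    ``stride`` applies at the base scale and grows proportionally with the
    window.  ``min_size`` skips pyramid levels whose window is smaller.
    Returns raw accepts in original-image pixels; an image smaller than
    the canonical window yields an empty list with a warning.
    """
    image = to_grey(np.asarray(image))
    ww, wh = column.window_size
    if image.shape[1] < ww or image.shape[0] < wh:
        log.warning("image %dx%d smaller than window %dx%d",
                    image.shape[1], image.shape[0], ww, wh)
        return []
    if scale_factor <= 1.0:
        raise ValueError("scale_factor must be > 1")
    ii = build_integral(image)
    accepts: list[RawAccept] = []
    s = 1.0
    while True:
        cw, ch = int(ww * s + 0.5), int(wh * s + 0.5)
        if cw > image.shape[1] or ch > image.shape[0]:
            break
        if min_size is None or (cw >= min_size[0] and ch >= min_size[1]):
            st = max(1, int(stride * s + 0.5))
            gx, gy = np.meshgrid(
                np.arange(0, image.shape[1] - cw + 1, st),
                np.arange(0, image.shape[0] - ch + 1, st),
            )
            xs, ys = gx.ravel(), gy.ravel()
            acc, margins, _ = evaluate_positions(column, ii, xs, ys, scale=s)
            for i, m in zip(acc, margins):
                accepts.append(RawAccept(int(xs[i]), int(ys[i]), cw, ch, float(m)))
        s *= scale_factor
    return accepts


def _iou(a: RawAccept, b: RawAccept) -> float:
    x1, y1 = max(a.x, b.x), max(a.y, b.y)
    x2, y2 = min(a.x + a.w, b.x + b.w), min(a.y + a.h, b.y + b.h)
    inter = max(0, x2 - x1) * max(0, y2 - y1)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union else 0.0


def group_detections(
    raw: list[RawAccept],
    overlap_min: float = 0.3,
    min_neighbors: int = 2,
    object_type: str = "Object",
) -> list[Detection]:
    """Merge raw accepts into detections by single-link IoU components.

    Boxes whose pairwise IoU reaches ``overlap_min`` join the same
    component (union-find); components with at least ``min_neighbors``
    members emit one detection whose box and score are the member means.
    The result is independent of the order of the raw accepts.
    """
    n = len(raw)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _iou(raw[i], raw[j]) >= overlap_min:
                ri, rj = find(i), find(j)
                if ri != rj:
                    # deterministic union: smaller root wins
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[RawAccept]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(raw[i])
    out = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) < min_neighbors:
            continue
        out.append(
            Detection(
                x=int(round(np.mean([m.x for m in members]))),
                y=int(round(np.mean([m.y for m in members]))),
                w=int(round(np.mean([m.w for m in members]))),
                h=int(round(np.mean([m.h for m in members]))),
                object_type=object_type,
                score=float(np.mean([m.score for m in members])),
                support=len(members),
            )
        )
    return out


def detect(
    image: np.ndarray,
    column: CascadeColumn,
    scale_factor: float = 1.2,
    stride: int = 2,
    overlap_min: float = 0.3,
    min_neighbors: int = 2,
) -> list[Detection]:
    """Scan then group: the full detection pipeline for one image."""
    raw = scan(image, column, scale_factor=scale_factor, stride=stride)
    return group_detections(raw, overlap_min, min_neighbors, column.object_type)


def save_detections(detections: list[Detection], path, fmt: str = "json") -> None:
    """Write detections as JSON or CSV (x, y, w, h, type, score, support)."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump([asdict(d) for d in detections], fh, indent=1)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["x", "y", "w", "h", "object_type", "score", "support"])
            for d in detections:
                wr.writerow([d.x, d.y, d.w, d.h, d.object_type, d.score, d.support])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def draw_detections(image: np.ndarray, detections: list[Detection]):
    """Annotated copy of the image with detection boxes burned in (PIL)."""
    from PIL import Image, ImageDraw

    arr = np.clip(to_grey(np.asarray(image)), 0, 255).astype(np.uint8)
    im = Image.fromarray(arr).convert("RGB")
    draw = ImageDraw.Draw(im)
    for d in detections:
        draw.rectangle([d.x, d.y, d.x + d.w - 1, d.y + d.h - 1], outline=(255, 0, 0))
    return im
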