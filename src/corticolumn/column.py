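"""Cortical-column view of a trained cascade detector.

Every component of the detector maps onto one of seven functional layers
of a model cortical column:

====================  =====================================================
role                  detector component
====================  =====================================================
input                 the integral image
polymorphic           brightness-coding elements (one per distinct
                      receptive field used by the column)
inner_pyramidal       weak classifiers
inner_granular        strong classifiers (cascade stages)
outer_pyramidal       spatial connection of stage decisions (grouping)
outer_granular        output neuron holding the found-object locations
axonal                declared excite/suppress links to other columns
====================  =====================================================

This module provides the layer census (element counts, thresholds,
activation functions, positions over the field of view), activation traces
of a column analyzing an image region, deterministic 2D renders and 3D
point/edge export of the activity, and the XML model file format
(Face.xml-style) with its parameter bounds: a column may hold 0-100
stages, each stage 1-1000 weak sensors, coding kernels cover at most 1024
pixels, and every receptive field reads 9 sub-regions.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .boosting import StrongClassifier
from .cascade import CascadeColumn
from .census import Region, build_integral, to_grey
from .weak import N_CODES, WeakClassifier

__all__ = [
    "LAYER_ROLES",
    "LayerCensus",
    "ActivationTrace",
    "StageActivity",
    "layer_census",
    "activation_trace",
    "render_activity",
    "export_3d",
    "save_column_xml",
    "load_column_xml",
    "read_column_header",
]

#: The seven functional layer roles, in bottom-up order.
LAYER_ROLES = (
    "input",
    "polymorphic",
    "inner_pyramidal",
    "inner_granular",
    "outer_pyramidal",
    "outer_granular",
    "axonal",
)

MAX_STAGES = 100
MAX_SENSORS_PER_STAGE = 1000
MAX_KERNEL_AREA = 1024  # polymorphic element connectivity limit (32x32)
SUBREGIONS_PER_FIELD = 9


class ColumnModelError(ValueError):
    """Raised when a column model violates its structural bounds."""


def _validate(column: CascadeColumn) -> None:
    if not 0 <= column.num_stages <= MAX_STAGES:
        raise ColumnModelError(f"NumStages {column.num_stages} outside [0, {MAX_STAGES}]")
    for k, sc in enumerate(column.stages):
        if not 1 <= len(sc.weaks) <= MAX_SENSORS_PER_STAGE:
            raise ColumnModelError(
                f"NumSensor({k}) = {len(sc.weaks)} outside [1, {MAX_SENSORS_PER_STAGE}]"
            )
        for wc in sc.weaks:
            if wc.region.area > MAX_KERNEL_AREA:
                raise ColumnModelError(
                    f"kernel {wc.region.w}x{wc.region.h} exceeds {MAX_KERNEL_AREA} pixels"
                )


@dataclass
class LayerCensus:
    """Element counts and parameters of the seven layers of one column."""

    counts: dict[str, int]
    thresholds: dict[str, object]
    activation: dict[str, str]
    positions: dict[str, list[tuple[float, float]]]
    num_sensors: list[int]  # NumSensor(K): weak classifiers in stage K

    @property
    def roles(self) -> tuple[str, ...]:
        return LAYER_ROLES


def layer_census(column: CascadeColumn) -> LayerCensus:
    """Count the neuron-like elements of every layer of a trained column.

    Polymorphic elements are the distinct receptive fields referenced by
    the column's weak classifiers; each weak classifier is one
    inner-pyramidal element; each cascade stage one inner-granular
    element.  NumSensor(K) is the number of weaks in stage K.
    """
    if column.num_stages == 0:
        raise ColumnModelError("untrained column: no stages to census")
    _validate(column)
    regions: list[Region] = []
    seen: set[Region] = set()
    weak_pos: list[tuple[float, float]] = []
    for sc in column.stages:
        for wc in sc.weaks:
            weak_pos.append((wc.region.x0 + wc.region.w / 2, wc.region.y0 + wc.region.h / 2))
            if wc.region not in seen:
                seen.add(wc.region)
                regions.append(wc.region)
    num_sensors = [len(sc.weaks) for sc in column.stages]
    counts = {
        "input": 1,
        "polymorphic": len(regions),
        "inner_pyramidal": sum(num_sensors),
        "inner_granular": column.num_stages,
        "outer_pyramidal": 1,
        "outer_granular": 1,
        "axonal": len(column.axonal_links),
    }
    thresholds = {
        "input": None,
        "polymorphic": "block mean of the whole receptive field",
        "inner_pyramidal": "likelihood ratio > 0",
        "inner_granular": [sc.theta for sc in column.stages],
        "outer_pyramidal": "IoU-component support >= min_neighbors",
        "outer_granular": "all stages fired",
        "axonal": None,
    }
    activation = {
        "input": "summed-area accumulation",
        "polymorphic": "9-bit census comparison (step at the block mean)",
        "inner_pyramidal": "binary likelihood-ratio step",
        "inner_granular": "weighted vote with strict threshold",
        "outer_pyramidal": "integrate-and-fire over overlapping accepts",
        "outer_granular": "integrate-and-fire (AND over stages)",
        "axonal": "pass-through excite/suppress",
    }
    positions = {
        "input": [(column.window_size[0] / 2, column.window_size[1] / 2)],
        "polymorphic": [(r.x0 + r.w / 2, r.y0 + r.h / 2) for r in regions],
        "inner_pyramidal": weak_pos,
        "inner_granular": [
            (column.window_size[0] / 2, column.window_size[1] / 2) for _ in column.stages
        ],
        "outer_pyramidal": [(column.window_size[0] / 2, column.window_size[1] / 2)],
        "outer_granular": [(column.window_size[0] / 2, column.window_size[1] / 2)],
        "axonal": [(0.0, 0.0) for _ in column.axonal_links],
    }
    return LayerCensus(counts, thresholds, activation, positions, num_sensors)


@dataclass
class StageActivity:
    """Activity of one inner-granular element while analyzing a window."""

    stage: int
    score: float
    theta: float
    active_weaks: list[int]
    codes: list[int]  # census code seen by each weak of the stage, in order
    fired: bool


@dataclass
class ActivationTrace:
    """Per-layer active elements for the best-scoring window of a region."""

    window: tuple[int, int, int, int]  # x, y, w, h in image pixels
    stages: list[StageActivity]
    stages_evaluated: int
    accepted: bool
    object_type: str = "Object"

    @property
    def active_polymorphic(self) -> list[tuple[int, int, int]]:
        """(stage, weak, code) triples of coding elements driving firing weaks."""
        out = []
        for sa in self.stages:
            for k in sa.active_weaks:
                out.append((sa.stage, k, sa.codes[k]))
        return out


def activation_trace(
    column: CascadeColumn, image: np.ndarray, region: Region | None = None
) -> ActivationTrace:
    """Trace the column's activity on the best window of an image region.

    All canonical-size windows inside ``region`` are scored (no
    short-circuit); the window passing the most stages — ties broken by
    total normalized margin — is traced layer by layer.  The reported
    ``stages_evaluated`` follows cascade semantics: evaluation stops at
    the first rejecting stage.
    """
    image = to_grey(np.asarray(image))
    ww, wh = column.window_size
    if region is None:
        region = Region(0, 0, image.shape[1], image.shape[0])
    if (
        region.x0 < 0
        or region.y0 < 0
        or region.x0 + region.w > image.shape[1]
        or region.y0 + region.h > image.shape[0]
    ):
        raise IndexError(f"region {region} outside image")
    if region.w < ww or region.h < wh:
        raise ValueError("region smaller than the canonical window")
    if column.num_stages == 0:
        raise ColumnModelError("untrained column")
    ii = build_integral(image)
    gx, gy = np.meshgrid(
        np.arange(region.x0, region.x0 + region.w - ww + 1),
        np.arange(region.y0, region.y0 + region.h - wh + 1),
    )
    xs, ys = gx.ravel(), gy.ravel()

    from .census import encode_at

    passed = np.zeros(xs.size, dtype=np.int64)
    margin = np.zeros(xs.size)
    alive = np.ones(xs.size, dtype=bool)
    for sc in column.stages:
        score = np.zeros(xs.size)
        for wc in sc.weaks:
            score += wc.weight * wc.response(encode_at(ii, xs, ys, wc.region))
        fired = score > sc.theta
        passed += alive & fired
        margin += np.where(alive, (score - sc.theta) / (sc.total_weight or 1.0), 0.0)
        alive &= fired
    best = int(np.lexsort((margin, passed))[-1])
    bx, by = int(xs[best]), int(ys[best])

    stages: list[StageActivity] = []
    evaluated = 0
    accepted = True
    for si, sc in enumerate(column.stages):
        codes = [int(encode_at(ii, np.array([bx]), np.array([by]), wc.region)[0]) for wc in sc.weaks]
        responses = [int(wc.response(c)) for wc, c in zip(sc.weaks, codes)]
        score = float(sum(wc.weight * r for wc, r in zip(sc.weaks, responses)))
        fired = score > sc.theta
        if accepted:
            evaluated += 1
        stages.append(
            StageActivity(
                stage=si,
                score=score,
                theta=sc.theta,
                active_weaks=[k for k, r in enumerate(responses) if r],
                codes=codes,
                fired=fired,
            )
        )
        if not fired:
            accepted = False
    return ActivationTrace(
        window=(bx, by, ww, wh),
        stages=stages,
        stages_evaluated=evaluated,
        accepted=accepted,
        object_type=column.object_type,
    )


# -- rendering ---------------------------------------------------------------

_BG = (24, 24, 32)
_INACTIVE = (96, 96, 96)
_ACTIVE = (0, 200, 0)
_TOP_ACTIVE = (220, 40, 40)


def render_activity(trace: ActivationTrace, column: CascadeColumn, cell: int = 14):
    """Deterministic 2D raster of the column's active elements.

    One row of dots per layer, bottom-up: inactive elements grey, active
    inner-layer elements green, the active output pyramid red.  Returns a
    PIL image (byte-stable for a fixed trace and palette).
    """
    census = layer_census(column)
    n_cols = max(max(census.counts.values()), 1)
    width = cell * (n_cols + 2)
    height = cell * (len(LAYER_ROLES) + 2)
    im = Image.new("RGB", (width, height), _BG)
    draw = ImageDraw.Draw(im)
    active = _active_sets(trace, column)
    for li, role in enumerate(LAYER_ROLES):
        yy = height - (li + 2) * cell
        for ei in range(census.counts[role]):
            xx = cell * (ei + 1)
            is_active = ei in active[role]
            if role in ("outer_granular", "axonal") and is_active:
                color = _TOP_ACTIVE
            elif is_active:
                color = _ACTIVE
            else:
                color = _INACTIVE
            r = cell // 3
            draw.ellipse([xx - r, yy - r, xx + r, yy + r], fill=color)
    return im


def _active_sets(trace: ActivationTrace, column: CascadeColumn) -> dict[str, set[int]]:
    """Flat per-layer indices of active elements implied by a trace."""
    census = layer_census(column)
    region_index = {}
    regions = []
    weak_offset = []
    off = 0
    for sc in column.stages:
        weak_offset.append(off)
        off += len(sc.weaks)
        for wc in sc.weaks:
            if wc.region not in region_index:
                region_index[wc.region] = len(regions)
                regions.append(wc.region)
    active: dict[str, set[int]] = {role: set() for role in LAYER_ROLES}
    active["input"].add(0)
    for sa in trace.stages[: trace.stages_evaluated]:
        for k in sa.active_weaks:
            active["inner_pyramidal"].add(weak_offset[sa.stage] + k)
            active["polymorphic"].add(region_index[column.stages[sa.stage].weaks[k].region])
        if sa.fired:
            active["inner_granular"].add(sa.stage)
    if trace.accepted:
        active["outer_pyramidal"].add(0)
        active["outer_granular"].add(0)
        active["axonal"].update(range(census.counts["axonal"]))
    return active


def export_3d(trace: ActivationTrace, column: CascadeColumn):
    """Vertex and edge tables of the column in 3D (z = layer index).

    Returns ``(vertices, edges)``: vertices are dicts with id, layer, x,
    y, z, active; edges link each element to its layer-below driver.
    Intended to be written as plain CSV for external viewers.
    """
    census = layer_census(column)
    active = _active_sets(trace, column)
    vertices = []
    ids: dict[tuple[str, int], int] = {}
    vid = 0
    for li, role in enumerate(LAYER_ROLES):
        for ei, (px, py) in enumerate(census.positions[role]):
            ids[(role, ei)] = vid
            vertices.append(
                {
                    "id": vid,
                    "layer": role,
                    "x": float(px),
                    "y": float(py),
                    "z": float(li),
                    "active": int(ei in active[role]),
                }
            )
            vid += 1
    edges = []
    # weak -> its coding element, stage -> its weaks, output chain
    region_index = {}
    regions = []
    for sc in column.stages:
        for wc in sc.weaks:
            if wc.region not in region_index:
                region_index[wc.region] = len(regions)
                regions.append(wc.region)
    wi = 0
    for si, sc in enumerate(column.stages):
        for wc in sc.weaks:
            edges.append(
                {
                    "src": ids[("polymorphic", region_index[wc.region])],
                    "dst": ids[("inner_pyramidal", wi)],
                }
            )
            edges.append({"src": ids[("inner_pyramidal", wi)], "dst": ids[("inner_granular", si)]})
            wi += 1
        edges.append({"src": ids[("inner_granular", si)], "dst": ids[("outer_pyramidal", 0)]})
    for ei in range(census.counts["polymorphic"]):
        edges.append({"src": ids[("input", 0)], "dst": ids[("polymorphic", ei)]})
    edges.append({"src": ids[("outer_pyramidal", 0)], "dst": ids[("outer_granular", 0)]})
    for ei in range(census.counts["axonal"]):
        edges.append({"src": ids[("outer_granular", 0)], "dst": ids[("axonal", ei)]})
    return vertices, edges


def export_3d_csv(trace: ActivationTrace, column: CascadeColumn, vertices_path, edges_path) -> None:
    """Write the 3D export as two CSV tables."""
    vertices, edges = export_3d(trace, column)
    with open(vertices_path, "w") as fh:
        fh.write("id,layer,x,y,z,active\n")
        for v in vertices:
            fh.write(f"{v['id']},{v['layer']},{v['x']},{v['y']},{v['z']},{v['active']}\n")
    with open(edges_path, "w") as fh:
        fh.write("src,dst\n")
        for e in edges:
            fh.write(f"{e['src']},{e['dst']}\n")


# -- XML model files ---------------------------------------------------------

def _fmt_hist(hist: np.ndarray) -> str:
    vals = hist.tolist()
    if all(float(v).is_integer() for v in vals):
        return " ".join(str(int(v)) for v in vals)
    return " ".join(repr(float(v)) for v in vals)


def save_column_xml(column: CascadeColumn, path) -> None:
    """Serialize a column to its XML model file.

    The layout mirrors the introspection vocabulary: a ``CorticalColumn``
    root with ``objectType``, window size and ``numStages``; one ``Stage``
    per strong classifier carrying its strict ``threshold`` and
    ``numSensor``; one ``Weak`` per weak classifier with its vote weight,
    receptive-field geometry, decision rule and the two 512-bin code
    histograms.  Serialization is byte-deterministic for a given column.
    """
    _validate(column)
    root = ET.Element(
        "CorticalColumn",
        objectType=column.object_type,
        windowWidth=str(column.window_size[0]),
        windowHeight=str(column.window_size[1]),
        numStages=str(column.num_stages),
    )
    for sc in column.stages:
        stage = ET.SubElement(
            root, "Stage", threshold=repr(float(sc.theta)), numSensor=str(len(sc.weaks))
        )
        for wc in sc.weaks:
            weak = ET.SubElement(
                stage,
                "Weak",
                weight=repr(float(wc.weight)),
                x=str(wc.region.x0),
                y=str(wc.region.y0),
                w=str(wc.region.w),
                h=str(wc.region.h),
                rule=wc.rule,
            )
            ET.SubElement(weak, "HistPos").text = _fmt_hist(wc.hist_pos)
            ET.SubElement(weak, "HistNeg").text = _fmt_hist(wc.hist_neg)
    if column.history:
        hist_el = ET.SubElement(root, "History")
        for entry in column.history:
            ET.SubElement(
                hist_el, "Entry", **{k: repr(v) for k, v in sorted(entry.items())}
            )
    if column.axonal_links:
        links = ET.SubElement(root, "AxonalLinks")
        for link in column.axonal_links:
            ET.SubElement(links, "Link", target=str(link["target"]), mode=str(link["mode"]))
    ET.indent(root)
    data = ET.tostring(root, encoding="unicode")
    with open(path, "w") as fh:
        fh.write(data + "\n")


def _req(el: ET.Element, attr: str) -> str:
    v = el.get(attr)
    if v is None:
        raise ColumnModelError(f"<{el.tag}> missing required attribute {attr!r}")
    return v


def _parse_hist(weak: ET.Element, tag: str) -> np.ndarray:
    el = weak.find(tag)
    if el is None or el.text is None:
        raise ColumnModelError(f"<Weak> missing <{tag}> histogram")
    vals = np.array([float(v) for v in el.text.split()])
    if vals.size != N_CODES:
        raise ColumnModelError(f"<{tag}> has {vals.size} bins, expected {N_CODES}")
    return vals


def read_column_header(path) -> dict:
    """Cheap header parse: ObjectType, window size, NumStages, NumSensor(K)."""
    tree = ET.parse(path)
    root = tree.getroot()
    if root.tag != "CorticalColumn":
        raise ColumnModelError(f"unexpected root element <{root.tag}>")
    num_stages = int(_req(root, "numStages"))
    if not 0 <= num_stages <= MAX_STAGES:
        raise ColumnModelError(f"numStages {num_stages} outside [0, {MAX_STAGES}]")
    return {
        "object_type": _req(root, "objectType"),
        "window_size": (int(_req(root, "windowWidth")), int(_req(root, "windowHeight"))),
        "num_stages": num_stages,
        "num_sensors": [int(_req(st, "numSensor")) for st in root.findall("Stage")],
    }


def load_column_xml(path) -> CascadeColumn:
    """Load a column model; decisions reproduce the saved column exactly."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ColumnModelError(f"malformed column XML: {exc}") from exc
    root = tree.getroot()
    header = read_column_header(path)
    stages: list[StrongClassifier] = []
    window = header["window_size"]
    for st in root.findall("Stage"):
        weaks = []
        for wk in st.findall("Weak"):
            region = Region(
                int(_req(wk, "x")), int(_req(wk, "y")), int(_req(wk, "w")), int(_req(wk, "h"))
            )
            weaks.append(
                WeakClassifier(
                    region=region,
                    hist_pos=_parse_hist(wk, "HistPos"),
                    hist_neg=_parse_hist(wk, "HistNeg"),
                    weight=float(_req(wk, "weight")),
                    rule=wk.get("rule", "support"),
                )
            )
        if not weaks:
            raise ColumnModelError("<Stage> holds no <Weak> elements")
        stages.append(
            StrongClassifier(weaks=weaks, theta=float(_req(st, "threshold")), window_size=window)
        )
    if len(stages) != header["num_stages"]:
        raise ColumnModelError(
            f"numStages={header['num_stages']} but found {len(stages)} <Stage> elements"
        )
    history = []
    hist_el = root.find("History")
    if hist_el is not None:
        import ast

        for entry in hist_el.findall("Entry"):
            history.append({k: ast.literal_eval(v) for k, v in entry.attrib.items()})
    links = []
    links_el = root.find("AxonalLinks")
    if links_el is not None:
        for link in links_el.findall("Link"):
            links.append({"target": _req(link, "target"), "mode": _req(link, "mode")})
    column = CascadeColumn(
        object_type=header["object_type"],
        window_size=window,
        stages=stages,
        history=history,
        axonal_links=links,
    )
    _validate(column)
    return column
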