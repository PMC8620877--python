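"""Serial cascades of strong classifiers — the detector "column".

A window is accepted only if every stage accepts it; evaluation stops at
the first rejecting stage, so background windows are cheap.  Training
appends stages until a global false-accept target is met or the negative
pool is exhausted: after each stage the negatives are re-bootstrapped from
false positives the current cascade still produces on background images,
which is what drives the false-accept rate down geometrically.  The growth
history is recorded so the build-up of the column can be inspected and
visualized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .boosting import StrongClassifier, adaboost_train, enumerate_features, select_threshold
from .census import Region, build_integral, encode_at
from .weak import TrainingSet

__all__ = [
    "StageGoals",
    "CascadeColumn",
    "cascade_train",
    "cascade_classify",
    "evaluate_positions",
    "scale_region",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageGoals:
    """Training schedule targets for one cascade.

    d_min:   minimum detection rate each stage must keep on validation
             positives (per-stage threshold selection target).
    f_max:   maximum fraction of the current negatives a stage may accept.
    far_target: stop training once the empirical per-window false-accept
             rate on background scanning falls below this.
    """

    d_min: float = 0.995
    f_max: float = 0.5
    far_target: float = 1e-5
    max_stages: int = 20
    max_weaks_per_stage: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.d_min <= 1.0:
            raise ValueError("d_min must be in (0, 1]")
        if not 0.0 < self.f_max < 1.0:
            raise ValueError("f_max must be in (0, 1)")


@dataclass
class CascadeColumn:
    """Trained detector: ordered stages sharing one canonical window size."""

    object_type: str
    window_size: tuple[int, int]
    stages: list[StrongClassifier] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    axonal_links: list[dict] = field(default_factory=list)

    @property
    def num_stages(self) -> int:
        return len(self.stages)

    def classify(self, window_ii: np.ndarray):
        return cascade_classify(window_ii, self)


def scale_region(r: Region, s: float, window: tuple[int, int]) -> Region:
    """Receptive field rescaled with the detection window, clamped inside it."""
    ww, wh = window
    w = max(3, int(r.w * s + 0.5))
    h = max(3, int(r.h * s + 0.5))
    x = min(int(r.x0 * s + 0.5), ww - w)
    y = min(int(r.y0 * s + 0.5), wh - h)
    return Region(max(0, x), max(0, y), min(w, ww), min(h, wh))


def cascade_classify(window_ii: np.ndarray, column: CascadeColumn):
    """Decide one canonical window.

    Returns ``(decision, stages_evaluated, scores)`` where ``scores`` holds
    the vote score of every stage actually evaluated; evaluation
    short-circuits at the first rejection.
    """
    scores: list[float] = []
    for sc in column.stages:
        s = sc.score_window(window_ii)
        scores.append(s)
        if s <= sc.theta:
            return 0, len(scores), scores
    return 1, len(scores), scores


def evaluate_positions(
    column: CascadeColumn,
    ii: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    scale: float = 1.0,
):
    """Run the cascade at many window origins of one integral image.

    The window (and every receptive field) is scaled by ``scale``.
    Returns ``(accepted_index, margins, stages_evaluated)``: indices into
    ``xs``/``ys`` of accepted windows, their mean per-stage margin
    ``(score - theta)`` normalized by the stage's total vote weight, and
    the per-position count of stages evaluated.
    """
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    window = (
        max(3, int(column.window_size[0] * scale + 0.5)),
        max(3, int(column.window_size[1] * scale + 0.5)),
    )
    alive = np.arange(xs.size)
    margin_sum = np.zeros(xs.size)
    n_eval = np.zeros(xs.size, dtype=np.int64)
    for sc in column.stages:
        if alive.size == 0:
            break
        score = np.zeros(alive.size)
        for wc in sc.weaks:
            r = scale_region(wc.region, scale, window)
            codes = encode_at(ii, xs[alive], ys[alive], r)
            score += wc.weight * wc.response(codes)
        n_eval[alive] += 1
        tw = sc.total_weight or 1.0
        margin_sum[alive] += (score - sc.theta) / tw
        alive = alive[score > sc.theta]
    n = max(1, len(column.stages))
    return alive, margin_sum[alive] / n, n_eval


def _resize_window(crop: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if crop.shape == (size[1], size[0]):
        return crop.astype(np.int64)
    im = Image.fromarray(np.clip(crop, 0, 255).astype(np.uint8))
    return np.asarray(im.resize(size, Image.BILINEAR)).astype(np.int64)


def _sample_negatives(
    backgrounds: list[np.ndarray],
    window: tuple[int, int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random multi-scale background crops resized to the canonical window."""
    ww, wh = window
    out = []
    scales = (1.0, 1.4, 2.0)
    for _ in range(n):
        bg = backgrounds[rng.integers(len(backgrounds))]
        s = scales[rng.integers(len(scales))]
        cw, ch = min(int(ww * s), bg.shape[1]), min(int(wh * s), bg.shape[0])
        x = rng.integers(bg.shape[1] - cw + 1)
        y = rng.integers(bg.shape[0] - ch + 1)
        out.append(_resize_window(bg[y : y + ch, x : x + cw], window))
    return np.stack(out)


def _bootstrap_negatives(
    column: CascadeColumn,
    backgrounds: list[np.ndarray],
    n_wanted: int,
    rng: np.random.Generator,
    stride: int = 3,
    scale_factor: float = 1.3,
):
    """Collect background windows the current cascade still accepts.

    Returns ``(crops, scanned, found)`` where ``scanned`` counts every
    window evaluated — the empirical per-window false-accept rate is
    ``found / scanned``.
    """
    ww, wh = column.window_size
    crops: list[np.ndarray] = []
    scanned = 0
    found = 0
    order = rng.permutation(len(backgrounds))
    for bi in order:
        bg = np.asarray(backgrounds[bi])
        ii = build_integral(bg)
        s = 1.0
        while True:
            cw, ch = int(ww * s + 0.5), int(wh * s + 0.5)
            if cw > bg.shape[1] or ch > bg.shape[0]:
                break
            st = max(1, int(stride * s + 0.5))
            gx, gy = np.meshgrid(
                np.arange(0, bg.shape[1] - cw + 1, st),
                np.arange(0, bg.shape[0] - ch + 1, st),
            )
            xs, ys = gx.ravel(), gy.ravel()
            acc, _, _ = evaluate_positions(column, ii, xs, ys, scale=s)
            scanned += xs.size
            found += acc.size
            for i in acc:
                if len(crops) < n_wanted:
                    crops.append(
                        _resize_window(
                            bg[ys[i] : ys[i] + ch, xs[i] : xs[i] + cw], (ww, wh)
                        )
                    )
            s *= scale_factor
    return crops, scanned, found


def cascade_train(
    positives: np.ndarray,
    backgrounds: list[np.ndarray],
    goals: StageGoals = StageGoals(),
    seed: int = 0,
    object_type: str = "Object",
    pool: list[Region] | None = None,
    rule: str = "support",
) -> CascadeColumn:
    """Train a cascade column on object windows and background images.

    ``positives`` is an (n, H, W) stack of canonical-size object windows
    (at least 50); a quarter of them is held out for per-stage threshold
    selection.  Stages are appended until the empirical false-accept rate
    on background scanning reaches ``goals.far_target``, the background
    pool yields no more false positives (early success), or
    ``goals.max_stages`` is hit.  All sampling is driven by ``seed``.
    """
    positives = np.asarray(positives)
    if positives.ndim != 3 or positives.shape[0] < 50:
        raise ValueError("need an (n, H, W) stack of at least 50 positive windows")
    if not backgrounds:
        raise ValueError("need at least one background image")
    rng = np.random.default_rng(seed)
    window = (positives.shape[2], positives.shape[1])
    if pool is None:
        pool = enumerate_features(window)

    perm = rng.permutation(positives.shape[0])
    n_val = max(1, positives.shape[0] // 4)
    val_pos = positives[perm[:n_val]].astype(np.int64)
    train_pos = positives[perm[n_val:]].astype(np.int64)
    val_ts = TrainingSet(val_pos, np.ones(len(val_pos), dtype=np.int8))

    n_neg = len(train_pos)
    negatives = _sample_negatives(backgrounds, window, n_neg, rng)

    column = CascadeColumn(object_type=object_type, window_size=window)
    for stage_idx in range(goals.max_stages):
        ts = TrainingSet(
            np.concatenate([train_pos, negatives]),
            np.concatenate(
                [np.ones(len(train_pos), dtype=np.int8), np.zeros(len(negatives), dtype=np.int8)]
            ),
        )
        neg_slice = slice(len(train_pos), len(ts))
        sc = None
        stage_far = 1.0
        n_weaks = 1
        while True:
            sc = adaboost_train(ts, pool, rounds=n_weaks, rule=rule)
            select_threshold(sc, sc.scores(val_ts), goals.d_min)
            stage_far = float(np.mean(sc.scores(ts)[neg_slice] > sc.theta))
            if stage_far <= goals.f_max or n_weaks >= goals.max_weaks_per_stage:
                break
            n_weaks = min(n_weaks * 2, goals.max_weaks_per_stage)
        if sc is None or stage_far > goals.f_max:
            log.warning("stage %d cannot reach f_max=%.3f (far=%.3f); stopping",
                        stage_idx, goals.f_max, stage_far)
            if sc is None:
                break
        column.stages.append(sc)
        frr_val = float(np.mean(sc.scores(val_ts) <= sc.theta))
        crops, scanned, found = _bootstrap_negatives(column, backgrounds, n_neg, rng)
        far_emp = found / scanned if scanned else 0.0
        column.history.append(
            {
                "stage": stage_idx,
                "n_weaks": len(sc.weaks),
                "theta": sc.theta,
                "stage_far": stage_far,
                "stage_frr_val": frr_val,
                "n_negatives": int(len(negatives)),
                "bootstrap_scanned": int(scanned),
                "bootstrap_found": int(found),
                "far_empirical": far_emp,
            }
        )
        log.info(
            "stage %d: %d weaks, theta=%.3f, far=%.3f, frr_val=%.3f, bootstrap %d/%d",
            stage_idx, len(sc.weaks), sc.theta, stage_far, frr_val, found, scanned,
        )
        if not crops:
            log.info("background pool exhausted; early success")
            break
        if far_emp <= goals.far_target:
            break
        negatives = np.stack(crops)
        if len(negatives) < 50:
            # too few hard negatives for stable histograms: pad with fresh
            # random crops (they are easy, but keep the class populated)
            extra = _sample_negatives(backgrounds, window, 50 - len(negatives), rng)
            negatives = np.concatenate([negatives, extra])
    if not column.stages:
        raise RuntimeError("cascade training produced no stages")
    return column
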