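"""AdaBoost strong classifiers over receptive-field features.

Discrete AdaBoost in the Viola-Jones style: each round refits every
candidate receptive field's histograms to the current sample weights,
selects the feature with the smallest weighted error, gives it a vote
weight ``omega = ln((1 - eps) / eps)`` and reweights the samples
multiplicatively.  The strong decision is

    H = 1  iff  sum_k omega_k * h_k(code_k) > Theta

with a strict threshold Theta chosen on validation positives so that a
target detection rate d_min is met.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .census import Region
from .weak import TrainingSet, WeakClassifier, fit_histograms, response_table

__all__ = [
    "StrongClassifier",
    "enumerate_features",
    "adaboost_train",
    "strong_response",
    "select_threshold",
]

log = logging.getLogger(__name__)

_EPS_CLAMP = 1e-10


def enumerate_features(
    window_size: tuple[int, int],
    size_set: list[tuple[int, int]] | None = None,
    stride: int = 3,
) -> list[Region]:
    """Deterministic, duplicate-free pool of candidate receptive fields.

    ``size_set`` lists kernel (w, h) pairs; positions are laid on a grid
    with the given stride.  Kernels must be at least 3x3 to be codable.
    """
    ww, wh = window_size
    if size_set is None:
        size_set = [(s, s) for s in (6, 9, 12, 18) if s <= min(ww, wh)]
        size_set.append((ww, wh))
    seen: set[Region] = set()
    pool: list[Region] = []
    for kw, kh in size_set:
        if kw < 3 or kh < 3 or kw > ww or kh > wh:
            continue
        for y in range(0, wh - kh + 1, stride):
            for x in range(0, ww - kw + 1, stride):
                r = Region(x, y, kw, kh)
                if r not in seen:
                    seen.add(r)
                    pool.append(r)
    if not pool:
        raise ValueError(f"empty feature pool for window {ww}x{wh}")
    return pool


@dataclass
class StrongClassifier:
    """Thresholded weighted vote of weak classifiers (one cascade stage)."""

    weaks: list[WeakClassifier]
    theta: float
    window_size: tuple[int, int]
    train_errors: list[float] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return float(sum(w.weight for w in self.weaks))

    def scores(self, ts: TrainingSet) -> np.ndarray:
        """Vote score sum_k omega_k h_k for every window of a training set."""
        out = np.zeros(len(ts))
        for wc in self.weaks:
            out += wc.weight * wc.response(ts.codes(wc.region))
        return out

    def score_window(self, window_ii: np.ndarray) -> float:
        return float(
            sum(wc.weight * wc.respond_window(window_ii) for wc in self.weaks)
        )

    def decide(self, scores: np.ndarray) -> np.ndarray:
        return scores > self.theta


def adaboost_train(
    samples,
    pool: list[Region],
    rounds: int,
    rule: str = "support",
) -> StrongClassifier:
    """Train a strong classifier by greedy AdaBoost over the feature pool.

    Sample weights start uniform.  Each round the pool feature with the
    minimum weighted error is taken (first in pool order on ties); a
    feature whose response table is identical to an already selected one
    is skipped.  Errors are clamped to keep vote weights finite on
    separable data.  The initial threshold is the majority-vote point
    ``Theta = sum(omega)/2``; use :func:`select_threshold` to retarget it.
    """
    ts = samples if isinstance(samples, TrainingSet) else TrainingSet.from_samples(samples)
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    y = (ts.labels == 1).astype(np.int8)
    if not y.any() or y.all():
        raise ValueError("training set must contain both labels")
    n = len(ts)
    w = np.full(n, 1.0 / n)

    # Response columns per feature; under the support rule these depend only
    # on which codes appear among positives, so they are fixed for the stage.
    resp = np.empty((n, len(pool)), dtype=np.uint8)
    for j, region in enumerate(pool):
        hp, hn = fit_histograms(ts, region)
        resp[:, j] = response_table(hp, hn, rule)[ts.codes(region)]

    weaks: list[WeakClassifier] = []
    errors: list[float] = []
    used: set[bytes] = set()
    mis = resp != y[:, None]  # n x F misclassification indicators
    for _ in range(rounds):
        eps = w @ mis  # weighted error of every feature
        order = np.argsort(eps, kind="stable")
        j_best = -1
        for j in order:
            sig = resp[:, j].tobytes()
            if sig not in used:
                j_best = int(j)
                break
        if j_best < 0:
            break
        eps_k = float(eps[j_best])
        if abs(eps_k - 0.5) < 1e-12 and np.all(np.abs(eps - 0.5) < 1e-12):
            warnings.warn("no usable feature: every weighted error is 0.5", stacklevel=2)
            break
        used.add(resp[:, j_best].tobytes())
        eps_c = min(max(eps_k, _EPS_CLAMP), 1.0 - _EPS_CLAMP)
        omega = float(np.log((1.0 - eps_c) / eps_c))
        region = pool[j_best]
        # Stored histograms must reproduce the response column used for
        # selection.  Under the support rule the weighted refit has the same
        # support, so weighted counts are stored; under laplace the table
        # depends on the counts themselves, so the unweighted fit is kept.
        hp, hn = fit_histograms(ts, region, weights=w if rule == "support" else None)
        weaks.append(
            WeakClassifier(region=region, hist_pos=hp, hist_neg=hn, weight=omega, rule=rule)
        )
        errors.append(eps_k)
        # multiplicative update: correctly classified samples are downweighted
        beta = eps_c / (1.0 - eps_c)
        w = w * np.where(mis[:, j_best], 1.0, beta)
        w /= w.sum()
    if not weaks:
        raise ValueError("boosting selected no features")
    sc = StrongClassifier(
        weaks=weaks,
        theta=sum(wk.weight for wk in weaks) / 2.0,
        window_size=ts.window_size,
        train_errors=errors,
    )
    return sc


def strong_response(window_ii: np.ndarray, sc: StrongClassifier) -> int:
    """Strong decision for one canonical window: 1 iff the vote exceeds Theta."""
    return int(sc.score_window(window_ii) > sc.theta)


def select_threshold(
    sc: StrongClassifier, validation_positives, d_min: float = 0.995
) -> float:
    """Largest threshold retaining at least ``d_min`` of validation positives.

    Scores the validation positives, takes the k-th largest score with
    ``k = ceil(d_min * n)`` and sets Theta just below it (the decision is
    a strict inequality).  If ``d_min`` cannot be met Theta falls back
    to 0 with a warning.  The chosen Theta is stored on ``sc`` and
    returned.
    """
    if not 0.0 < d_min <= 1.0:
        raise ValueError("d_min must be in (0, 1]")
    if isinstance(validation_positives, TrainingSet):
        scores = sc.scores(validation_positives)
        scores = scores[validation_positives.labels == 1]
    else:
        scores = np.asarray(validation_positives, dtype=float)
    if scores.size == 0:
        raise ValueError("no validation positives")
    k = int(np.ceil(d_min * scores.size))
    kth = np.sort(scores)[::-1][k - 1]
    theta = float(np.nextafter(kth, -np.inf))
    if theta < 0.0:
        warnings.warn(f"detection rate {d_min} unattainable; threshold set to 0", stacklevel=2)
        theta = 0.0
    sc.theta = theta
    return theta
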