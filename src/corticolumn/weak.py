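"""Likelihood-ratio weak classifiers over census-code histograms.

A weak classifier watches one receptive field of the detection window.  Its
class-conditional code distributions are estimated as histograms over the
512 possible codes, one from the object ("useful signal") samples and one
from the background samples.  The activation is the likelihood ratio

    L = p(code | object) / p(code | background)

and the decision is the printed rule: fire (1) iff L > 0, i.e. iff the code
has ever been observed with nonzero weight among object samples.  An
optional Laplace-smoothed variant (fire iff L > 1) is provided for
robustness; the support rule is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .census import Region, build_integral_stack, encode, encode_stack

__all__ = [
    "N_CODES",
    "TrainingSample",
    "TrainingSet",
    "WeakClassifier",
    "fit_histograms",
    "likelihood_ratio",
    "weak_response",
    "response_table",
]

N_CODES = 512

#: decision rules: "support" is the faithful printed rule (fire iff the
#: likelihood ratio is nonzero); "laplace" add-one smooths both histograms
#: and fires iff the smoothed ratio exceeds 1.
RULES = ("support", "laplace")


@dataclass(frozen=True)
class TrainingSample:
    """One canonical-size window with its label (1 = object, 0 = background)."""

    window: np.ndarray
    label: int


class TrainingSet:
    """Stack of labelled windows with cached per-region code columns.

    Precomputes the integral image of every window once; ``codes(region)``
    then returns the vector of census codes of that receptive field across
    all samples, cached so boosting can revisit features cheaply.
    """

    def __init__(self, windows: np.ndarray, labels: np.ndarray):
        windows = np.asarray(windows)
        labels = np.asarray(labels, dtype=np.int8)
        if windows.ndim != 3 or windows.shape[0] != labels.shape[0]:
            raise ValueError("windows must be (n, H, W) matching labels")
        self.windows = windows
        self.labels = labels
        self.ii = build_integral_stack(windows)
        self._code_cache: dict[Region, np.ndarray] = {}

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_size(self) -> tuple[int, int]:
        return self.windows.shape[2], self.windows.shape[1]

    def codes(self, region: Region) -> np.ndarray:
        out = self._code_cache.get(region)
        if out is None:
            out = encode_stack(self.ii, region)
            self._code_cache[region] = out
        return out

    @classmethod
    def from_samples(cls, samples: list[TrainingSample]) -> "TrainingSet":
        if not samples:
            raise ValueError("empty training set")
        shape = samples[0].window.shape
        if any(s.window.shape != shape for s in samples):
            raise ValueError("all windows must share the canonical size")
        return cls(
            np.stack([s.window for s in samples]),
            np.array([s.label for s in samples]),
        )


def fit_histograms(
    samples, region: Region, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional code histograms of one receptive field.

    Returns ``(hist_pos, hist_neg)``, the (optionally weighted) counts of
    each census code among object and background samples.  Both labels
    must be present.
    """
    ts = samples if isinstance(samples, TrainingSet) else TrainingSet.from_samples(samples)
    pos = ts.labels == 1
    if not pos.any() or pos.all():
        raise ValueError("training set must contain both labels")
    codes = ts.codes(region)
    if weights is None:
        weights = np.ones(len(ts))
    hist_pos = np.bincount(codes[pos], weights=weights[pos], minlength=N_CODES)
    hist_neg = np.bincount(codes[~pos], weights=weights[~pos], minlength=N_CODES)
    return hist_pos, hist_neg


def likelihood_ratio(code: int, hist_pos: np.ndarray, hist_neg: np.ndarray) -> float:
    """Ratio of class-conditional code densities at one code.

    Background density zero with nonzero object density yields ``inf``;
    both zero yields 0 (the code is simply unknown).
    """
    tp, tn = hist_pos.sum(), hist_neg.sum()
    dp = hist_pos[code] / tp if tp > 0 else 0.0
    dn = hist_neg[code] / tn if tn > 0 else 0.0
    if dn == 0.0:
        return float("inf") if dp > 0 else 0.0
    return float(dp / dn)


def response_table(
    hist_pos: np.ndarray, hist_neg: np.ndarray, rule: str = "support"
) -> np.ndarray:
    """512-entry binary lookup table code -> {0, 1} for a decision rule."""
    if rule == "support":
        return (hist_pos > 0).astype(np.uint8)
    if rule == "laplace":
        dp = (hist_pos + 1.0) / (hist_pos.sum() + N_CODES)
        dn = (hist_neg + 1.0) / (hist_neg.sum() + N_CODES)
        return (dp > dn).astype(np.uint8)
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


@dataclass
class WeakClassifier:
    """One receptive field with its histograms, decision rule and weight.

    ``region`` is window-relative.  ``weight`` is the vote weight assigned
    by boosting (ln((1-eps)/eps)).
    """

    region: Region
    hist_pos: np.ndarray
    hist_neg: np.ndarray
    weight: float = 1.0
    rule: str = "support"
    table: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.table is None:
            self.table = response_table(self.hist_pos, self.hist_neg, self.rule)

    def response(self, code) -> np.ndarray:
        """Binary response for a code or array of codes."""
        return self.table[code]

    def respond_window(self, window_ii: np.ndarray) -> int:
        """Response for a single canonical window's integral image."""
        return int(self.table[encode(window_ii, self.region)])


def weak_response(code: int, wc: WeakClassifier) -> int:
    """Binary decision of a weak classifier at one census code."""
    return int(wc.response(code))
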