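"""Shared fixtures: synthetic datasets and trained columns.

Training is deterministic (fixed seeds), so session-scoped fixtures are
safe to share across test modules.  The "study" column is trained at the
scale the package's own error-rate checks use (2000 positive digit
windows, 50 mixed-style backgrounds); the "small" column trades accuracy
for speed in structural tests.
"""

import numpy as np
import pytest

import corticolumn as cc
from corticolumn.cascade import StageGoals, cascade_train


def make_backgrounds(n_each: int, size: int, seed: int) -> list[np.ndarray]:
    out = []
    for i, style in enumerate(("noise", "gradient", "texture")):
        out.extend(cc.render_backgrounds((size, size), style, n_each, seed=seed + i))
    return out


@pytest.fixture(scope="session")
def study_positives() -> np.ndarray:
    windows, _ = cc.render_glyph_set(cc.GlyphSpec(seed=7), 2000, digits=(3,))
    return windows


@pytest.fixture(scope="session")
def study_backgrounds() -> list[np.ndarray]:
    # 51 backgrounds, 17 per style
    return make_backgrounds(17, 128, seed=1)


@pytest.fixture(scope="session")
def study_column(study_positives, study_backgrounds):
    return cascade_train(
        study_positives,
        study_backgrounds,
        StageGoals(),
        seed=11,
        object_type="Digit3",
    )


@pytest.fixture(scope="session")
def small_column():
    positives, _ = cc.render_glyph_set(cc.GlyphSpec(seed=3), 300, digits=(5,))
    backgrounds = make_backgrounds(4, 96, seed=40)
    return cascade_train(
        positives,
        backgrounds,
        StageGoals(max_stages=5),
        seed=5,
        object_type="Digit5",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
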