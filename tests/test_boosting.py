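"""AdaBoost strong classifiers: feature pools, training, thresholds."""

import numpy as np
import pytest

import corticolumn as cc
from corticolumn.boosting import (
    StrongClassifier,
    adaboost_train,
    enumerate_features,
    select_threshold,
    strong_response,
)
from corticolumn.census import Region
from corticolumn.weak import N_CODES, TrainingSet, WeakClassifier

# Two independently codable receptive fields on a 60x30 window: each half
# is a block image realizing a chosen census code.
REGION_A = Region(0, 0, 30, 30)
REGION_B = Region(30, 0, 30, 30)


def two_field_window(code_a: int, code_b: int) -> np.ndarray:
    return np.hstack([cc.pattern_image(cc.decode(code_a)), cc.pattern_image(cc.decode(code_b))])


def two_field_set(pos, neg) -> TrainingSet:
    windows = np.stack([two_field_window(a, b) for a, b in pos + neg])
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=np.int8)
    return TrainingSet(windows, labels)


def oracle_adaboost(resp: np.ndarray, y: np.ndarray, rounds: int):
    """Plain-loop discrete AdaBoost over precomputed response columns."""
    n, nf = resp.shape
    w = np.full(n, 1.0 / n)
    picks, epss, omegas = [], [], []
    used = set()
    for _ in range(rounds):
        errs = [
            sum(w[i] for i in range(n) if resp[i, j] != y[i]) for j in range(nf)
        ]
        j = min(
            (j for j in range(nf) if tuple(resp[:, j]) not in used),
            key=lambda j: errs[j],
        )
        used.add(tuple(resp[:, j]))
        eps = errs[j]
        beta = eps / (1 - eps)
        picks.append(j)
        epss.append(eps)
        omegas.append(np.log(1 / beta))
        for i in range(n):
            if resp[i, j] == y[i]:
                w[i] *= beta
        w /= w.sum()
    return picks, epss, omegas


class TestEnumerateFeatures:
    def test_single_full_window_kernel(self):
        assert len(enumerate_features((24, 24), [(24, 24)], 1)) == 1

    def test_grid_counting(self):
        assert len(enumerate_features((24, 24), [(9, 9)], 3)) == 36

    def test_mixed_sizes_match_brute_force(self):
        sizes = [(9, 9), (12, 6), (24, 24)]
        pool = enumerate_features((24, 24), sizes, 4)
        brute = {
            (x, y, kw, kh)
            for kw, kh in sizes
            for y in range(0, 24 - kh + 1, 4)
            for x in range(0, 24 - kw + 1, 4)
        }
        assert len(pool) == len(brute)
        assert len(set(pool)) == len(pool)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            enumerate_features((24, 24), [(30, 30)], 1)


class TestAdaboost:
    def test_separable_toy_is_perfect_in_one_round(self):
        ts = two_field_set([(10, 20)] * 3, [(12, 22)] * 3)
        sc = adaboost_train(ts, [REGION_A], rounds=1)
        assert sc.train_errors == [0.0]
        assert (sc.decide(sc.scores(ts)) == (ts.labels == 1)).all()

    def test_four_sample_trace_matches_hand_run(self):
        """Two rounds on a 4-sample set reproduce the hand-computed trace:
        round 1 picks the first field at eps 1/4 (omega ln 3), round 2 the
        second at eps 1/6 (omega ln 5)."""
        ts = two_field_set([(10, 20), (11, 21)], [(10, 22), (12, 20)])
        sc = adaboost_train(ts, [REGION_A, REGION_B], rounds=2)
        assert [w.region for w in sc.weaks] == [REGION_A, REGION_B]
        assert sc.train_errors == pytest.approx([0.25, 1 / 6])
        assert [w.weight for w in sc.weaks] == pytest.approx([np.log(3), np.log(5)])

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        """Selected features, errors and weights agree with an independent
        plain-loop AdaBoost on the same response columns."""
        pool = [REGION_A, REGION_B]
        for _ in range(5):
            pos = [(int(a), int(b)) for a, b in rng.integers(1, 30, (6, 2))]
            neg = [(int(a), int(b)) for a, b in rng.integers(1, 60, (6, 2))]
            ts = two_field_set(pos, neg)
            y = (ts.labels == 1).astype(int)
            resp = np.stack(
                [
                    np.array([int(c in {a for a, _ in pos}) for c in ts.codes(REGION_A)]),
                    np.array([int(c in {b for _, b in pos}) for c in ts.codes(REGION_B)]),
                ],
                axis=1,
            )
            try:
                picks, epss, omegas = oracle_adaboost(resp, y, 2)
            except (ZeroDivisionError, ValueError):
                continue  # separable or degenerate pool: plain oracle stops
            if 0.0 in epss:
                continue
            sc = adaboost_train(ts, pool, rounds=2)
            assert [pool.index(w.region) for w in sc.weaks] == picks
            assert sc.train_errors == pytest.approx(epss)
            assert [w.weight for w in sc.weaks] == pytest.approx(omegas)

    def test_training_error_bound(self, rng):
        """Unthresholded-vote training error <= prod_k 2 sqrt(eps_k(1-eps_k))."""
        pos = [(int(a), int(b)) for a, b in rng.integers(1, 40, (20, 2))]
        neg = [(int(a), int(b)) for a, b in rng.integers(1, 80, (20, 2))]
        ts = two_field_set(pos, neg)
        sc = adaboost_train(ts, [REGION_A, REGION_B], rounds=2)
        err = np.mean(sc.decide(sc.scores(ts)) != (ts.labels == 1))
        bound = np.prod([2 * np.sqrt(e * (1 - e)) for e in sc.train_errors])
        assert err <= bound + 1e-12

    def test_no_usable_feature_warns(self):
        ts = two_field_set([(10, 20), (12, 22)], [(10, 20), (12, 22)])
        with pytest.warns(UserWarning, match="no usable feature"):
            with pytest.raises(ValueError):
                adaboost_train(ts, [REGION_A], rounds=1)

    def test_deterministic(self):
        ts = two_field_set([(10, 20), (11, 21), (13, 23)], [(12, 22), (14, 20)])
        sc1 = adaboost_train(ts, [REGION_A, REGION_B], rounds=2)
        sc2 = adaboost_train(ts, [REGION_A, REGION_B], rounds=2)
        assert [w.region for w in sc1.weaks] == [w.region for w in sc2.weaks]
        assert [w.weight for w in sc1.weaks] == [w.weight for w in sc2.weaks]


def manual_strong(weights, responses, theta) -> tuple[StrongClassifier, np.ndarray]:
    """Strong classifier from constant-response weaks plus a probe window."""
    weaks = []
    for w, r in zip(weights, responses):
        weaks.append(
            WeakClassifier(
                region=Region(0, 0, 3, 3),
                hist_pos=np.ones(N_CODES) if r else np.zeros(N_CODES),
                hist_neg=np.ones(N_CODES),
                weight=w,
            )
        )
    sc = StrongClassifier(weaks=weaks, theta=theta, window_size=(3, 3))
    window_ii = cc.build_integral(np.arange(9).reshape(3, 3))
    return sc, window_ii


class TestStrongResponse:
    def test_vote_above_threshold_fires(self):
        sc, ii = manual_strong([0.6, 0.3], [1, 0], 0.5)
        assert strong_response(ii, sc) == 1

    def test_no_votes_never_fires(self):
        sc, ii = manual_strong([0.6, 0.3], [0, 0], 0.0)
        assert strong_response(ii, sc) == 0

    def test_score_exactly_at_threshold_rejects(self):
        sc, ii = manual_strong([0.5], [1], 0.5)
        assert strong_response(ii, sc) == 0

    def test_raising_threshold_shrinks_accept_set(self, rng):
        scores = rng.uniform(0, 3, 100)
        sc, _ = manual_strong([1.0], [1], 0.0)
        prev = np.ones(100, dtype=bool)
        for theta in np.linspace(0, 3, 7):
            sc.theta = theta
            cur = sc.decide(scores)
            assert not np.any(cur & ~prev)
            prev = cur


class TestSelectThreshold:
    def test_full_detection_puts_theta_below_minimum_score(self):
        sc, _ = manual_strong([1.0], [1], 0.0)
        theta = select_threshold(sc, np.array([0.9, 0.7, 0.4]), d_min=1.0)
        assert theta < 0.4 and np.nextafter(theta, np.inf) >= 0.4

    def test_two_thirds_detection_sits_below_second_score(self):
        sc, _ = manual_strong([1.0], [1], 0.0)
        theta = select_threshold(sc, np.array([0.9, 0.7, 0.4]), d_min=2 / 3)
        assert 0.4 < theta < 0.7
        assert np.mean(np.array([0.9, 0.7, 0.4]) > theta) >= 2 / 3

    def test_raising_dmin_never_raises_theta(self):
        sc, _ = manual_strong([1.0], [1], 0.0)
        scores = np.array([0.95, 0.8, 0.6, 0.3, 0.1])
        thetas = [select_threshold(sc, scores, d) for d in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(thetas, thetas[1:]))

    def test_unattainable_rate_falls_back_to_zero(self):
        sc, _ = manual_strong([1.0], [1], 0.0)
        with pytest.warns(UserWarning, match="unattainable"):
            theta = select_threshold(sc, np.array([0.0, 0.0, 0.5]), d_min=1.0)
        assert theta == 0.0
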