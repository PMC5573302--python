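"""F-measure voting, NSGA-II search and the three-kernel SVR ensemble."""

import numpy as np
import pytest

from oncolattice.regressor import (ClassificationCounts, KernelSpec,
                                   RegressorEnsemble, classification_counts,
                                   discretize_for_metrics, f_measure,
                                   fit_ensemble, nsga2, nsga2_search,
                                   predict_q, _crowding_distance,
                                   _non_dominated_sort)


class TestFMeasure:
    def test_perfect_classifier(self):
        assert f_measure(ClassificationCounts(tp=10, fp=0, fn=0)) == 1.0

    def test_no_true_positives_defined_as_zero(self):
        assert f_measure(ClassificationCounts(tp=0, fp=3, fn=2, tn=5)) == 0.0

    def test_harmonic_mean_arithmetic(self):
        # precision 0.8, recall 2/3 -> F = 2*0.8*(2/3)/(0.8 + 2/3)
        c = ClassificationCounts(tp=8, fp=2, fn=4)
        assert f_measure(c) == pytest.approx(0.7273, abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassificationCounts(tp=-1)


class TestDiscretization:
    def test_sign_agreement_cases(self):
        assert discretize_for_metrics(0.4, 0.7).tp == 1
        assert discretize_for_metrics(-0.1, 0.1).fn == 1
        assert discretize_for_metrics(-0.3, -0.6).tn == 1
        assert discretize_for_metrics(0.3, -0.6).fp == 1

    def test_perfect_predictor_scores_one(self):
        y = np.linspace(-0.9, 0.9, 25)
        assert f_measure(classification_counts(y, y)) == 1.0

    def test_bin_agreement_variant(self):
        # 4 bins over [-1, 1]: 0.1 and 0.4 share bin 2, 0.1 and 0.6 do not
        assert discretize_for_metrics(0.1, 0.4, bins=4).tp == 1
        assert discretize_for_metrics(0.1, 0.6, bins=4).fn == 1

    def test_vectorised_counts_match_singles(self, rng):
        qp = rng.uniform(-1, 1, 60)
        qt = rng.uniform(-1, 1, 60)
        total = classification_counts(qp, qt)
        acc = ClassificationCounts()
        for a, b in zip(qp, qt):
            acc = acc + discretize_for_metrics(a, b)
        assert (total.tp, total.fp, total.fn, total.tn) == \
            (acc.tp, acc.fp, acc.fn, acc.tn)


class TestNsga2:
    def test_front_is_mutually_non_dominated(self, rng):
        # concave bi-objective: maximize (x, 1 - x^2) on [0, 2]
        X, F = nsga2(lambda x: (x[0], 1 - x[0] ** 2),
                     np.array([[0.0, 2.0]]), 16, 10, rng)
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not ((F[i] >= F[j]).all() and (F[i] > F[j]).any())

    def test_front_non_domination_and_hypervolume_each_generation(self, rng):
        history = []

        def watch(X, F):
            history.append(F.copy())

        nsga2(lambda x: (x[0], 1 - x[0] ** 2), np.array([[0.0, 2.0]]),
              16, 8, rng, on_generation=watch)

        def hypervolume(F, ref=(-0.1, -3.1)):
            # 2-D hypervolume by sweeping the sorted front
            pts = sorted({(f[0], f[1]) for f in F}, reverse=True)
            hv, prev_y = 0.0, ref[1]
            for x, y in pts:
                if y > prev_y:
                    hv += (x - ref[0]) * (y - prev_y)
                    prev_y = y
            return hv

        # hypervolume of the accumulated non-dominated archive: the search
        # keeps adding quality, never losing it
        archive = np.zeros((0, 2))
        hvs = []
        for F in history:
            merged = np.vstack([archive, F])
            keep = [i for i in range(len(merged))
                    if not any((merged[j] >= merged[i]).all()
                               and (merged[j] > merged[i]).any()
                               for j in range(len(merged)))]
            archive = merged[keep]
            hvs.append(hypervolume(archive))
        for a, b in zip(hvs, hvs[1:]):
            assert b >= a - 1e-12
        assert hvs[-1] > 0
        for F in history:
            for i in range(len(F)):
                for j in range(len(F)):
                    if i != j:
                        assert not ((F[i] >= F[j]).all() and (F[i] > F[j]).any())

    def test_front_agrees_with_grid_search_oracle(self, rng):
        # Schaffer-style problem; oracle = dense grid non-dominated set
        f = lambda x: (-(x[0] ** 2), -((x[0] - 2.0) ** 2))  # noqa: E731
        X, F = nsga2(lambda x: f(x), np.array([[-2.0, 4.0]]), 24, 30, rng)
        # analytic Pareto set is x in [0, 2]
        assert ((X >= -0.1) & (X <= 2.1)).all()
        grid = np.linspace(-2, 4, 2001)
        GF = np.array([f([x]) for x in grid])
        # every found point must be within tolerance of some oracle point
        for fx in F:
            d = np.abs(GF - fx).sum(axis=1).min()
            assert d < 0.05


class TestKernelSearch:
    def _toy_data(self, rng, n=60):
        X = rng.uniform(-1, 1, (n, 3))
        y = np.tanh(X[:, 0] - 0.5 * X[:, 1])
        return X, y

    def test_search_returns_valid_specs(self, rng):
        X, y = self._toy_data(rng)
        front, F, best = nsga2_search(X, y, "rbf", pop_size=8, generations=3,
                                      rng=rng)
        assert best in front
        for spec in front:
            assert spec.kernel == "rbf" and spec.C > 0 and spec.gamma > 0
        # selection rule: no front member has a strictly higher F-measure
        assert F[:, 2].max() == pytest.approx(
            F[[i for i, s in enumerate(front) if s == best][0], 2])

    def test_empty_window_rejected(self, rng):
        with pytest.raises(ValueError):
            nsga2_search(np.zeros((0, 2)), np.zeros(0), "rbf", rng=rng)


class StubModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def stub_ensemble(values, weights):
    fams = ("rbf", "poly", "sigmoid")
    return RegressorEnsemble(
        models={f: StubModel(v) for f, v in zip(fams, values)},
        weights=dict(zip(fams, weights)),
        specs={f: KernelSpec(f, 1.0, 0.1, 1.0) for f in fams})


class TestEnsemble:
    def test_equal_weight_vote_is_plain_mean(self):
        ens = stub_ensemble([0.2, 0.4, 0.6], [1.0, 1.0, 1.0])
        assert predict_q(ens, np.zeros(3)) == pytest.approx(0.4)

    def test_single_positive_weight_dominates(self):
        ens = stub_ensemble([0.2, 0.9, -0.5], [0.0, 1.0, 0.0])
        assert predict_q(ens, np.zeros(3)) == pytest.approx(0.9)

    def test_output_clipped_to_q_range(self):
        ens = stub_ensemble([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        assert predict_q(ens, np.zeros(3)) == 1.0

    def test_all_zero_weights_rejected(self):
        ens = stub_ensemble([0.1, 0.1, 0.1], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            ens.predict(np.zeros((1, 3)))

    def test_fit_on_smooth_noiseless_target(self, rng):
        X = rng.uniform(-1, 1, (80, 2))
        y = np.clip(0.8 * X[:, 0], -1, 1)
        ens = fit_ensemble(X, y, pop_size=8, generations=3, rng=rng)
        assert ens.usable
        assert ens.weights["rbf"] > 0.8
        pred = ens.predict(X)
        assert np.abs(pred - y).mean() < 0.15

    def test_degenerate_identical_window(self, rng):
        X = np.ones((20, 2))
        y = np.full(20, 0.3)
        ens = fit_ensemble(X, y, pop_size=6, generations=2, rng=rng)
        pred = ens.predict(np.ones((5, 2)))
        assert np.allclose(pred, pred[0])  # constant predictor

    def test_refit_reproducibility(self):
        rng1 = np.random.default_rng(77)
        X = rng1.uniform(-1, 1, (50, 2))
        y = np.tanh(X.sum(axis=1))
        e1 = fit_ensemble(X, y, pop_size=6, generations=2,
                          rng=np.random.default_rng(9))
        e2 = fit_ensemble(X, y, pop_size=6, generations=2,
                          rng=np.random.default_rng(9))
        Xq = rng1.uniform(-1, 1, (10, 2))
        assert np.array_equal(e1.predict(Xq), e2.predict(Xq))

    def test_undersized_window_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            fit_ensemble(np.zeros((3, 2)), np.zeros(3), rng=rng)

    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.uniform(-1, 1, (40, 2))
        y = np.tanh(X[:, 0])
        ens = fit_ensemble(X, y, pop_size=6, generations=2, rng=rng)
        ens.save(tmp_path / "ens.pkl")
        back = RegressorEnsemble.load(tmp_path / "ens.pkl")
        assert np.array_equal(ens.predict(X), back.predict(X))
        assert "rbf" in back.report()

    def test_ensemble_not_worse_than_worst_member(self):
        """Aggregation-beats-single-kernel property over 20 synthetic
        Q-regression tasks: ensemble MAPE <= max single-kernel MAPE."""
        master = np.random.default_rng(2024)
        wins = 0
        for task in range(20):
            rng = np.random.default_rng(master.integers(2**31))
            X = rng.uniform(-1, 1, (70, 3))
            w = rng.normal(size=3)
            y = np.tanh(X @ w + 0.05 * rng.normal(size=70))
            Xte = rng.uniform(-1, 1, (40, 3))
            yte = np.tanh(Xte @ w)
            ens = fit_ensemble(X, y, pop_size=8, generations=3, rng=rng)

            def mape(pred):
                nz = np.abs(yte) > 1e-3
                return np.mean(np.abs((pred[nz] - yte[nz]) / yte[nz]))

            member_mapes = [mape(m.predict(Xte))
                            for f, m in ens.models.items()
                            if ens.weights[f] > 0]
            wins += mape(ens.predict(Xte)) <= max(member_mapes) + 1e-12
        assert wins == 20


class TestSortingPrimitives:
    def test_non_dominated_sort_ranks_correctly(self):
        F = np.array([[1.0, 1.0], [0.5, 0.5], [1.0, 0.2], [0.2, 1.0],
                      [0.1, 0.1]])
        fronts = _non_dominated_sort(F)
        assert set(fronts[0]) == {0}
        assert set(fronts[1]) == {1, 2, 3}
        assert set(fronts[2]) == {4}

    def test_crowding_distance_extremes_are_infinite(self):
        F = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        d = _crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert np.isfinite(d[1])
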