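import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.utils.estimator_checks import check_estimator  # noqa: F401  (import guard)

import corridors as c
from corridors.sdm import ThinningConfig, min_pairwise_distance


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.9, 0.1), (1, 0), 1.0),
            ((0.1, 0.9), (1, 0), 0.0),
            ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5),
            # enumerate the four presence-absence pairs: 0.8>0.6, 0.8>0.2,
            # 0.4<0.6, 0.4>0.2 -> 3/4
            ((0.8, 0.6, 0.4, 0.2), (1, 0, 1, 0), 0.75),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert c.auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            c.auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        # scores on a 0.01 lattice so monotone transforms cannot collapse
        # genuinely distinct values at float precision
        st.lists(st.integers(-500, 500), min_size=4, max_size=30),
        st.data(),
    )
    def test_matches_sklearn_and_is_monotone_invariant(self, raw, data):
        scores = [v / 100 for v in raw]
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        ours = c.auc(scores, labels)
        assert ours == pytest.approx(roc_auc_score(labels, scores))
        transformed = np.exp(0.5 * np.asarray(scores))  # strictly monotone
        assert c.auc(transformed, labels) == pytest.approx(ours)


class TestCollinearityScreen:
    def test_self_and_negation_pairs(self, small_stack):
        report = c.collinearity_screen(small_stack)
        self_rows = report[report.layer_a == report.layer_b]
        assert np.allclose(self_rows.r, 1.0)
        assert self_rows.flagged.all()

    def test_negated_layer_flagged_at_minus_one(self, small_stack):
        lay = small_stack.layers["smooth_0"]
        stack = c.PredictorStack(
            layers={"a": lay, "b": lay.with_values(-lay.values)}, names=["a", "b"]
        )
        row = c.collinearity_screen(stack).query("layer_a=='a' and layer_b=='b'")
        assert row.r.iloc[0] == pytest.approx(-1.0)
        assert bool(row.flagged.iloc[0])

    def test_independent_noise_layers_uncorrelated(self):
        rng = np.random.default_rng(8)
        grids = {
            k: c.RasterGrid(rng.standard_normal((100, 100))) for k in ("a", "b")
        }
        stack = c.PredictorStack(layers=grids, names=["a", "b"])
        row = c.collinearity_screen(stack).query("layer_a=='a' and layer_b=='b'")
        assert abs(row.r.iloc[0]) < 0.05  # null sd ~ 1/sqrt(10^4)

    def test_constant_layer_reported_undefined(self, small_stack):
        stack = c.PredictorStack(
            layers={
                "a": small_stack.layers["smooth_0"],
                "flat": small_stack.grid.with_values(
                    np.ones(small_stack.grid.shape)
                ),
            },
            names=["a", "flat"],
        )
        row = c.collinearity_screen(stack).query("layer_a=='a' and layer_b=='flat'")
        assert not bool(row.defined.iloc[0])
        assert np.isnan(row.r.iloc[0])


class TestThinning:
    def test_close_pair_collapses_to_one(self):
        ps = c.PresenceSet("x", [[0, 0], [10, 0]])
        out = c.thin_points(ps, ThinningConfig(100.0), seed=0)
        assert len(out) == 1

    def test_zero_distance_is_identity(self):
        ps = c.PresenceSet("x", [[0, 0], [10, 0], [20, 0]])
        out = c.thin_points(ps, ThinningConfig(0.0), seed=0)
        assert np.array_equal(out.points, ps.points)

    def test_lattice_matches_bruteforce_greedy_for_same_shuffle(self):
        xx, yy = np.meshgrid(np.arange(5) * 1000.0, np.arange(5) * 1000.0)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        ps = c.PresenceSet("x", pts)
        seed, min_d = 11, 1500.0
        out = c.thin_points(ps, ThinningConfig(min_d), seed=seed)
        # independent re-run of the stated greedy rule on the same shuffle
        order = np.random.default_rng(seed).permutation(len(pts))
        kept = []
        for i in order:
            if all(np.hypot(*(pts[i] - pts[j])) >= min_d for j in kept):
                kept.append(i)
        assert len(out) == len(kept)
        assert np.array_equal(out.points, pts[np.array(kept)])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1.0, 5000.0))
    def test_min_distance_property_holds_exactly(self, seed, min_d):
        rng = np.random.default_rng(seed)
        ps = c.PresenceSet("x", rng.uniform(0, 10_000, (40, 2)))
        out = c.thin_points(ps, ThinningConfig(min_d), seed=seed)
        assert min_pairwise_distance(out.points) >= min_d


class TestPseudoAbsences:
    def test_random_equal_matches_presence_count(self, small_stack):
        rng = np.random.default_rng(0)
        ps = c.PresenceSet("impala", rng.uniform(0, 50_000, (37, 2)))
        absences = c.generate_pseudo_absences(small_stack.grid, ps, "random_equal",
                                              seed=1)
        assert len(absences) == 37
        assert absences.source_label == "absence"

    def test_absences_avoid_presence_cells(self, small_stack):
        grid = small_stack.grid
        rng = np.random.default_rng(2)
        ps = c.PresenceSet("x", rng.uniform(0, 50_000, (200, 2)))
        absences = c.generate_pseudo_absences(grid, ps, "random_equal", seed=3)
        pr, pc = grid.cell_of(ps.points[:, 0], ps.points[:, 1])
        ar, ac = grid.cell_of(absences.points[:, 0], absences.points[:, 1])
        taken = set(zip(pr.tolist(), pc.tolist()))
        assert not any((r, col) in taken for r, col in zip(ar, ac))

    def test_request_exceeding_cells_rejected(self):
        # grid with a single valid cell
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1] = False
        grid = c.RasterGrid(np.zeros((3, 3)), nodata_mask=mask)
        ps = c.PresenceSet("x", np.empty((0, 2)))
        with pytest.raises(ValueError, match="available"):
            c.generate_pseudo_absences(grid, ps, "random", n=2, seed=0)

    def test_uniformity_over_quadrants(self):
        grid = c.RasterGrid(np.zeros((110, 110)), cell_size=1000.0)
        ps = c.PresenceSet("x", np.empty((0, 2)))
        absences = c.generate_pseudo_absences(grid, ps, "random", n=10_000, seed=5)
        r, col = grid.cell_of(absences.points[:, 0], absences.points[:, 1])
        quad = 2 * (r >= 55) + (col >= 55)
        counts = np.bincount(quad, minlength=4)
        assert np.all(np.abs(counts - 2500) <= 150)  # 3 sd multinomial


def _separable_data(n=60, p=3, seed=0):
    """Two classes split by a unit margin on the first predictor."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, p))
    X[:n, 0] = rng.uniform(0.5, 2.0, n)
    X[n:, 0] = rng.uniform(-2.0, -0.5, n)
    y = np.r_[np.ones(n, int), np.zeros(n, int)]
    return X, y


class TestEnsembleEstimator:
    def test_separable_data_all_families_perfect_and_retained(self):
        X, y = _separable_data()
        est = c.EnsembleSuitabilityModel(
            families=("logistic", "maxent"), retention_auc=0.9, reps=3,
            random_state=0,
        ).fit(X, y)
        for lr in est.learners_:
            assert lr.mean_auc == pytest.approx(1.0)
            assert lr.retained
        assert sum(est.weights_.values()) == pytest.approx(1.0)

    def test_random_labels_give_null_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 4))
        y = np.r_[np.ones(500, int), np.zeros(500, int)]
        est = c.EnsembleSuitabilityModel(
            families=("logistic",), retention_auc=0.0, reps=5, random_state=0
        ).fit(X, y)
        assert est.learners_[0].mean_auc == pytest.approx(0.5, abs=0.1)

    def test_probabilities_bounded_and_contributions_normalized(self):
        X, y = _separable_data(seed=2)
        est = c.EnsembleSuitabilityModel(
            families=("logistic", "boosted_trees"), retention_auc=0.5, reps=3,
            random_state=1,
        ).fit(X, y)
        p = est.predict_proba(X)[:, 1]
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(est.predictor_contributions_ >= 0)
        assert est.predictor_contributions_.sum() == pytest.approx(100.0, abs=1e-6)

    def test_nothing_retained_raises_actionable_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        y = rng.integers(0, 2, 80)
        y[:5], y[-5:] = 1, 0
        with pytest.raises(ValueError, match="retention_auc"):
            c.EnsembleSuitabilityModel(
                families=("logistic",), retention_auc=0.999, reps=3, random_state=0
            ).fit(X, y)

    def test_fit_is_deterministic_given_random_state(self):
        X, y = _separable_data(seed=4)
        maps = []
        for _ in range(2):
            est = c.EnsembleSuitabilityModel(
                families=("logistic", "random_forest"), retention_auc=0.5,
                reps=3, random_state=7,
            ).fit(X, y)
            maps.append(est.predict_proba(X)[:, 1])
        assert np.array_equal(maps[0], maps[1])

    def test_sklearn_get_set_params_round_trip(self):
        est = c.EnsembleSuitabilityModel(reps=4)
        params = est.get_params()
        assert params["reps"] == 4
        est.set_params(retention_auc=0.5)
        assert est.retention_auc == 0.5


class TestRasterEnsemble:
    def test_known_species_map_recovered(self, small_stack):
        spec = c.SyntheticSpeciesSpec(
            "syn", {"smooth_0": 2.0, "distance_0": -1.5}, intercept=-1.0
        )
        truth = c.true_suitability(spec, small_stack)
        pres = c.sample_transect_presences(truth, 1000.0, 0.7, seed=21,
                                           species="syn")
        absences = c.generate_pseudo_absences(small_stack.grid, pres,
                                              "random_equal", seed=22)
        model, smap = c.fit_ensemble(
            pres, absences, small_stack, families=("logistic",),
            retention_auc=0.5, reps=3, seed=23,
        )
        assert c.map_correlation(smap.grid, truth) >= 0.8
        v = smap.grid.values[smap.grid.valid_mask]
        assert v.min() >= 0 and v.max() <= 1
        report = model.report()
        contrib = report.filter(like="contrib_").iloc[0]
        assert contrib.sum() == pytest.approx(100.0, abs=1e-6)


class TestStacking:
    def test_seven_half_maps_sum_to_three_point_five(self, small_stack):
        half = c.SuitabilityMap(
            grid=small_stack.grid.with_values(np.full(small_stack.grid.shape, 0.5)),
            species_label="s",
        )
        stacked = c.stack_suitability([half] * 7)
        np.testing.assert_allclose(
            stacked.grid.values[stacked.grid.valid_mask], 3.5
        )
        assert stacked.n_species == 7

    def test_single_map_stack_is_identity(self, small_stack):
        m = c.SuitabilityMap(
            grid=small_stack.grid.with_values(
                np.random.default_rng(0).uniform(size=small_stack.grid.shape)
            ),
            species_label="s",
        )
        stacked = c.stack_suitability([m])
        np.testing.assert_allclose(stacked.grid.values, m.grid.values)

    def test_shape_mismatch_rejected(self, small_stack):
        a = c.SuitabilityMap(
            grid=small_stack.grid.with_values(np.zeros(small_stack.grid.shape)),
            species_label="a",
        )
        b = c.SuitabilityMap(grid=c.RasterGrid(np.zeros((5, 5))), species_label="b")
        with pytest.raises(ValueError):
            c.stack_suitability([a, b])

    def test_nodata_propagates_to_stack(self, small_stack):
        mask = np.zeros(small_stack.grid.shape, dtype=bool)
        mask[0, 0] = True
        m1 = c.SuitabilityMap(
            grid=c.RasterGrid(np.full(small_stack.grid.shape, 0.5),
                              cell_size=1000.0, nodata_mask=mask),
            species_label="a",
        )
        m2 = c.SuitabilityMap(
            grid=c.RasterGrid(np.full(small_stack.grid.shape, 0.5),
                              cell_size=1000.0),
            species_label="b",
        )
        stacked = c.stack_suitability([m1, m2])
        assert stacked.grid.nodata_mask[0, 0]
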