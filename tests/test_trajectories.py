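"""Trajectory fitting, shape clustering, and cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import canberra
from scipy.stats import rankdata

import cytoaging as ca
from cytoaging.trajectories import DEFAULT_GRID, Trajectory


def make_traj(values, name="t", grid=DEFAULT_GRID):
    return Trajectory(feature=name, grid=np.asarray(grid, float),
                      values=np.asarray(values, float), edf=3.0)


class TestFitTrajectory:
    def test_linear_values_reproduced(self, rng):
        ages = np.concatenate([[5.0, 75.0], rng.uniform(5, 75, 200)])
        vals = 0.04 * ages - 1.2
        tr = ca.fit_trajectory(ages, vals, df=3)
        np.testing.assert_allclose(tr.values, 0.04 * tr.grid - 1.2, atol=1e-6)

    def test_constant_values_give_flat_trajectory(self, rng):
        ages = rng.uniform(5, 75, 60)
        tr = ca.fit_trajectory(ages, np.full(60, 0.7), df=3)
        np.testing.assert_allclose(tr.values, 0.7, atol=1e-8)

    def test_effective_df_near_target(self, rng):
        ages = rng.uniform(5, 75, 150)
        vals = np.sin(ages / 10) + rng.normal(0, 0.2, 150)
        tr = ca.fit_trajectory(ages, vals, df=3)
        assert tr.edf == pytest.approx(3.0, abs=1e-4)

    def test_grid_restricted_to_5_75(self, rng):
        assert DEFAULT_GRID[0] == 5.0 and DEFAULT_GRID[-1] == 75.0
        assert np.all(np.diff(DEFAULT_GRID) == pytest.approx(0.5))

    def test_non_finite_trajectory_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_traj(np.full(len(DEFAULT_GRID), np.nan))


class TestClustering:
    def test_canberra_metric_hand_value(self):
        # definition check on a 2-vector pair: |1-3|/(1+3) = 0.5
        assert canberra([1, 2], [3, 2]) == pytest.approx(0.5)

    def test_identical_trajectories_share_a_cluster(self, rng):
        base = np.sin(DEFAULT_GRID / 15)
        trajs = {
            "a": make_traj(base, "a"),
            "b": make_traj(base, "b"),
            "c": make_traj(-base + 0.1 * rng.normal(size=len(DEFAULT_GRID)), "c"),
            "d": make_traj(DEFAULT_GRID * 0.01, "d"),
            "e": make_traj(-DEFAULT_GRID * 0.02, "e"),
        }
        cl = ca.cluster_trajectories(trajs, n_clusters=4)
        assert cl.labels["a"] == cl.labels["b"]

    def test_planted_shapes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = ca.CohortConfig(n_per_group={"CTR": 250, "REL": 250},
                              n_features_per_cluster=(8, 4, 8, 4),
                              noise_sd=0.3, seed=4)
        coh = ca.generate_cohort(cfg)
        fits = ca.fit_cohort_trajectories(coh, groups=("CTR", "REL"))
        cl = ca.cluster_trajectories(fits)
        truth = coh.feature_meta["cluster"]
        assert adjusted_rand_score(truth, cl.labels[truth.index]) >= 0.9

    def test_invariant_to_feature_order(self, rng):
        shapes = [np.sin(DEFAULT_GRID / 15), -DEFAULT_GRID * 0.02,
                  (DEFAULT_GRID - 40) ** 2 / 500, DEFAULT_GRID * 0.015]
        trajs = {}
        for i in range(12):
            base = shapes[i % 4]
            trajs[f"f{i}"] = make_traj(base + 0.01 * rng.normal(size=len(DEFAULT_GRID)), f"f{i}")
        cl1 = ca.cluster_trajectories(trajs)
        rev = dict(reversed(list(trajs.items())))
        cl2 = ca.cluster_trajectories(rev)
        assert cl1.labels.sort_index().equals(cl2.labels.sort_index())


class TestComparison:
    def _fits(self, offset=0.0):
        rng = np.random.default_rng(1)
        fits_a, fits_b = {}, {}
        for i in range(6):
            base = np.sin(DEFAULT_GRID / 20 + i)
            fits_a[f"f{i}"] = make_traj(base, f"f{i}")
            fits_b[f"f{i}"] = make_traj(base + offset, f"f{i}")
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=[f"f{i}" for i in range(6)])
        cl = ca.TrajectoryClustering(labels=labels, linkage_matrix=np.empty((0, 4)))
        return fits_a, fits_b, cl

    def test_constant_offset_recovered_exactly(self):
        fits_a, fits_b, cl = self._fits(offset=0.3)
        comp = ca.compare_trajectories(fits_a, fits_b, cl)
        assert np.allclose(comp.features["shift"], 0.3)
        assert np.allclose(comp.clusters["mean_shift"], 0.3)

    def test_self_comparison_is_null(self):
        fits_a, _, cl = self._fits()
        comp = ca.compare_trajectories(fits_a, fits_a, cl)
        assert np.allclose(comp.features["shift"], 0.0)
        assert np.all(comp.features["crossings"] == 0)

    def test_translation_equivariance(self):
        fits_a, fits_b, cl = self._fits(offset=0.1)
        c1 = ca.compare_trajectories(fits_a, fits_b, cl)
        shifted_b = {k: make_traj(t.values + 0.25, k) for k, t in fits_b.items()}
        c2 = ca.compare_trajectories(fits_a, shifted_b, cl)
        np.testing.assert_allclose(
            c2.features["shift"], c1.features["shift"] + 0.25, atol=1e-12
        )

    def test_single_member_cluster_has_missing_p(self):
        fits_a, fits_b, _ = self._fits(offset=0.2)
        labels = pd.Series([1, 1, 1, 1, 1, 2], index=[f"f{i}" for i in range(6)])
        cl = ca.TrajectoryClustering(labels=labels, linkage_matrix=np.empty((0, 4)))
        comp = ca.compare_trajectories(fits_a, fits_b, cl)
        assert np.isnan(comp.clusters.loc[2, "p"])


class TestInitialTrendAndCrossings:
    def test_monotone_trajectories(self):
        up = make_traj(DEFAULT_GRID * 0.01)
        flat = make_traj(np.zeros_like(DEFAULT_GRID))
        assert ca.initial_trend(up) > 0
        assert ca.initial_trend(flat) == 0.0

    def test_parabola_with_vertex_at_10_matches_enumeration(self):
        vals = (DEFAULT_GRID - 10.0) ** 2
        tr = make_traj(vals)
        sel = (DEFAULT_GRID >= 5) & (DEFAULT_GRID <= 15)
        oracle = np.mean(np.diff(vals[sel]))
        assert ca.initial_trend(tr) == pytest.approx(oracle)

    def test_crossing_counts(self):
        a = make_traj(np.ones_like(DEFAULT_GRID))
        b = make_traj(np.zeros_like(DEFAULT_GRID))
        assert ca.count_crossings(a, b) == 0
        assert ca.count_crossings(a, a) == 0
        # a sine built to cross zero 3 times over the grid
        wave = make_traj(np.sin(3.1 * np.pi * (DEFAULT_GRID - 5) / 70.0))
        signs = np.sign(wave.values)
        signs = signs[signs != 0]
        brute = int(np.sum(signs[1:] != signs[:-1]))
        assert brute == 3
        assert ca.count_crossings(wave, b) == brute

    def test_touch_without_sign_change_is_not_a_crossing(self):
        vals = np.zeros_like(DEFAULT_GRID)
        vals[:50] = 1.0
        vals[50] = 0.0
        vals[51:] = 1.0
        assert ca.count_crossings(make_traj(vals), make_traj(np.zeros_like(vals))) == 0


class TestSpearmanScreen:
    def test_feature_equal_to_age_has_rho_one(self, small_cohort):
        coh = small_cohort
        vals = coh.values.copy()
        vals[coh.features[0]] = coh.age
        coh2 = ca.CohortTable(values=vals, age=coh.age, group=coh.group,
                              covariates=coh.covariates, feature_meta=coh.feature_meta)
        screen = ca.spearman_age_screen(coh2)
        assert screen.loc[coh.features[0], "rho"] == pytest.approx(1.0)

    def test_independent_feature_near_zero(self, rng):
        cfg = ca.CohortConfig(n_per_group={"CTR": 500},
                              n_features_per_cluster=(0, 0, 0, 2), stable_drift=0.0,
                              seed=31)
        coh = ca.generate_cohort(cfg)
        screen = ca.spearman_age_screen(coh, groups=("CTR",))
        n = screen["n"].iloc[0]
        assert np.all(screen["rho"].abs() < 3 / np.sqrt(n))

    def test_ten_point_table_matches_midrank_oracle(self, rng):
        ages = np.array([4.0, 8, 8, 15, 22, 30, 41, 55, 55, 70])
        vals = np.array([2.0, 1, 5, 4, 4, 8, 7, 9, 12, 11])
        # brute-force oracle: Pearson correlation of midranks
        ra, rv = rankdata(ages), rankdata(vals)
        oracle = np.corrcoef(ra, rv)[0, 1]
        meta = pd.DataFrame({"domain": ["count"], "cluster": [1], "amplitude": [1.0],
                             "skewed": [False], "map_base": [1.0]},
                            index=pd.Index(["f0"], name="feature"))
        idx = pd.Index([f"S{i}" for i in range(10)], name="subject_id")
        coh = ca.CohortTable(
            values=pd.DataFrame({"f0": vals}, index=idx),
            age=pd.Series(ages, index=idx, name="age"),
            group=pd.Series(["CTR"] * 10, index=idx, name="group"),
            covariates=pd.DataFrame(index=idx),
            feature_meta=meta,
        )
        screen = ca.spearman_age_screen(coh, groups=("CTR",))
        assert screen.loc["f0", "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_reported_missing(self, small_cohort):
        coh = small_cohort
        vals = coh.values.copy()
        vals[coh.features[1]] = 5.0
        coh2 = ca.CohortTable(values=vals, age=coh.age, group=coh.group,
                              covariates=coh.covariates, feature_meta=coh.feature_meta)
        screen = ca.spearman_age_screen(coh2)
        assert np.isnan(screen.loc[coh.features[1], "rho"])
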