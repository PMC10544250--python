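"""Kruskal-Wallis + Dunn testing and the age-vs-disease feature partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoaging as ca


def brute_force_kw_dunn(values, groups, pair):
    """Textbook rank formulas computed by explicit sorting (oracle)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    order = np.argsort(values, kind="stable")
    n = len(values)
    # midranks by explicit scan over sorted values
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    labs = list(dict.fromkeys(groups))
    # H with tie correction
    H = 0.0
    for g in labs:
        r = ranks[groups == g]
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    _, t = np.unique(values, return_counts=True)
    H /= 1.0 - np.sum(t**3 - t) / (n**3 - n)
    # Dunn z for the requested pair
    a, b = pair
    ra, rb = ranks[groups == a], ranks[groups == b]
    tie = np.sum(t**3 - t) / (12.0 * (n - 1))
    var = (n * (n + 1) / 12.0 - tie) * (1.0 / len(ra) + 1.0 / len(rb))
    z = (ra.mean() - rb.mean()) / np.sqrt(var)
    return H, z


# a printed 8-observation, 3-group toy table (with a tie)
TOY_VALUES = [1.2, 3.4, 3.4, 5.1, 2.2, 6.0, 4.4, 0.9]
TOY_GROUPS = ["CTR", "CTR", "REL", "REL", "REL", "T1D", "T1D", "T1D"]


class TestKruskalDunn:
    def test_toy_table_matches_brute_force_oracle(self):
        quant = pd.DataFrame({"f": TOY_VALUES})
        res = ca.kruskal_dunn(quant, pd.Series(TOY_GROUPS),
                              comparisons=[("T1D", "CTR")])
        H_oracle, z_oracle = brute_force_kw_dunn(TOY_VALUES, TOY_GROUPS, ("T1D", "CTR"))
        assert res.kruskal.loc["f", "H"] == pytest.approx(H_oracle, abs=1e-12)
        z = res.dunn.set_index("feature").loc["f", "z"]
        assert z == pytest.approx(z_oracle, abs=1e-12)

    def test_dunn_antisymmetry(self):
        quant = pd.DataFrame({"f": TOY_VALUES})
        groups = pd.Series(TOY_GROUPS)
        za = ca.kruskal_dunn(quant, groups, comparisons=[("T1D", "CTR")]).dunn["z"][0]
        zb = ca.kruskal_dunn(quant, groups, comparisons=[("CTR", "T1D")]).dunn["z"][0]
        assert za == pytest.approx(-zb, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        quant = pd.DataFrame({"f": TOY_VALUES})
        groups = pd.Series(TOY_GROUPS)
        r1 = ca.kruskal_dunn(quant, groups)
        r2 = ca.kruskal_dunn(np.exp(quant), groups)
        assert r1.kruskal.loc["f", "H"] == pytest.approx(r2.kruskal.loc["f", "H"])
        pd.testing.assert_frame_equal(r1.dunn, r2.dunn)

    def test_null_rejection_rate_near_nominal(self, rng):
        n = 60
        groups = pd.Series(np.repeat(["CTR", "REL", "RSK", "T1D"], n))
        quant = pd.DataFrame(rng.uniform(size=(4 * n, 300)),
                             columns=[f"f{j}" for j in range(300)])
        res = ca.kruskal_dunn(quant, groups)
        rate = (res.kruskal["p"] < 0.05).mean()
        assert 0.02 < rate < 0.09  # binomial fluctuation around 5%

    def test_shifted_group_has_largest_positive_z(self, rng):
        n = 80
        groups = pd.Series(np.repeat(["CTR", "REL", "T1D"], n))
        x = rng.normal(0, 1, 3 * n)
        x[2 * n:] += 1.0
        res = ca.kruskal_dunn(pd.DataFrame({"f": stats.norm.cdf(x)}), groups)
        dunn = res.dunn.set_index("pair")
        assert dunn.loc["T1D vs CTR", "z"] > 0
        assert dunn.loc["T1D vs REL", "z"] > 0
        # both disease contrasts dwarf the null REL-vs-CTR comparison
        assert dunn.loc["T1D vs CTR", "z"] > abs(dunn.loc["REL vs CTR", "z"])

    def test_bh_adjustment_monotone_and_conservative(self, rng):
        n = 40
        groups = pd.Series(np.repeat(["CTR", "T1D"], n))
        quant = pd.DataFrame(rng.uniform(size=(2 * n, 50)),
                             columns=[f"f{j}" for j in range(50)])
        res = ca.kruskal_dunn(quant, groups)
        d = res.dunn.sort_values("p")
        assert np.all(d["p_adj"].to_numpy() >= d["p"].to_numpy() - 1e-15)
        assert np.all(np.diff(d["p_adj"].to_numpy()) >= -1e-15)

    def test_tiny_group_excluded_with_warning(self, caplog, rng):
        groups = pd.Series(["CTR"] * 20 + ["T1D"] * 20 + ["RSK"])
        quant = pd.DataFrame({"f": rng.uniform(size=41)})
        with caplog.at_level("WARNING"):
            res = ca.kruskal_dunn(quant, groups)
        assert not any("RSK" in p for p in res.dunn["pair"])

    def test_effect_direction_and_size(self, rng):
        n = 100
        groups = pd.Series(np.repeat(["CTR", "T1D"], n))
        x = np.concatenate([rng.uniform(0, 1, n), rng.uniform(0.2, 1.2, n)])
        res = ca.kruskal_dunn(pd.DataFrame({"f": x}), groups)
        assert res.effects.loc["f", "direction"] == 1.0
        assert res.effects.loc["f", "effect_size"] == pytest.approx(0.2, abs=0.07)


class TestPartition:
    def _inputs(self, age_p, dis_p, rho=0.5, effect=0.2):
        screen = pd.DataFrame({"rho": [rho], "p": [age_p], "n": [200]},
                              index=pd.Index(["f"], name="feature"))
        dunn = pd.DataFrame({"feature": ["f"], "pair": ["T1D vs CTR"],
                             "z": [2.0], "p": [dis_p], "p_adj": [dis_p]})
        kw = pd.DataFrame({"H": [1.0], "p": [dis_p], "p_adj": [dis_p]},
                          index=pd.Index(["f"], name="feature"))
        effects = pd.DataFrame({"direction": [1.0], "effect_size": [effect]},
                               index=pd.Index(["f"], name="feature"))
        comp = ca.ComparisonResult(kruskal=kw, dunn=dunn, effects=effects)
        return screen, comp

    @pytest.mark.parametrize("age_p,dis_p,label", [
        (1e-6, 0.9, "age-only"),
        (0.9, 1e-6, "disease-only"),
        (1e-6, 1e-6, "both"),
        (0.9, 0.9, "neither"),
    ])
    def test_labels_follow_flag_definitions(self, age_p, dis_p, label):
        screen, comp = self._inputs(age_p, dis_p)
        part = ca.partition_features(screen, comp)
        assert part.table.loc["f", "label"] == label
        assert part.counts[label] == 1

    def test_missing_feature_raises(self):
        screen, comp = self._inputs(0.5, 0.5)
        screen2 = screen.rename(index={"f": "other"})
        with pytest.raises(ValueError, match="missing"):
            ca.partition_features(screen2, comp)

    def test_planted_partition_recovered(self):
        # cluster 1 = age-only, cluster 2 = both, cluster 4 = disease-only
        cfg = ca.CohortConfig(
            n_per_group={"CTR": 200, "REL": 150, "T1D": 200},
            n_features_per_cluster=(10, 10, 0, 10),
            amplitude_range=(0.8, 1.2), stable_drift=0.0,
            disease_shift=(0.0, 0.5, 0.0, 0.5), aging_acceleration_years=0.0,
            seed=33,
        )
        coh = ca.generate_cohort(cfg)
        screen = ca.spearman_age_screen(coh, groups=("CTR", "REL"))
        quant, _ = ca.age_normalize(coh, reference_groups=("CTR", "REL"))
        comp = ca.kruskal_dunn(quant, coh.group, comparisons=[("T1D", "CTR")])
        part = ca.partition_features(screen, comp)
        truth = coh.feature_meta["cluster"].map({1: "age-only", 2: "both",
                                                4: "disease-only"})
        agree = (part.table["label"] == truth.loc[part.table.index])
        for cls in ("age-only", "both", "disease-only"):
            assert agree[truth == cls].sum() >= 8, cls

    def test_no_significant_features_all_neither(self, rng):
        n = 50
        screen = pd.DataFrame(
            {"rho": rng.normal(0, 0.05, n), "p": rng.uniform(0.5, 1, n), "n": 100},
            index=pd.Index([f"f{j}" for j in range(n)], name="feature"),
        )
        dunn = pd.DataFrame({"feature": [f"f{j}" for j in range(n)],
                             "pair": "T1D vs CTR", "z": 0.1,
                             "p": rng.uniform(0.5, 1, n)})
        dunn["p_adj"] = 1.0
        comp = ca.ComparisonResult(
            kruskal=pd.DataFrame(index=screen.index), dunn=dunn,
            effects=pd.DataFrame({"direction": 0.0, "effect_size": 0.0},
                                 index=screen.index),
        )
        part = ca.partition_features(screen, comp)
        assert part.counts == {"age-only": 0, "disease-only": 0, "both": 0,
                               "neither": n}
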