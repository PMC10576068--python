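import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import coverphylo.community as cdata
import coverphylo.stats as cstats
from conftest import make_table


def euclidean_dm(y: np.ndarray, index) -> pd.DataFrame:
    D = np.abs(y[:, None] - y[None, :])
    return pd.DataFrame(D, index=index, columns=index)


class TestSuppressionSummary:
    @pytest.fixture
    def table(self):
        rows = []
        for b, ctl, trt in [("b1", 1900, 15), ("b2", 2100, 25)]:
            rows.append(("s1", "2020", b, f"{b}c", "control", "a", "weed", ctl))
            rows.append(("s1", "2020", b, f"{b}t", "rye", "a", "weed", trt))
            rows.append(("s1", "2020", b, f"{b}t", "rye", "rye", "cover_crop", 5000))
        return make_table(rows)

    def test_percent_suppression_arithmetic(self, table):
        out = cstats.suppression_summary(table).set_index("treatment")
        assert out.loc["control", "suppression_pct"] == 0.0
        # control mean 2000, rye mean 20 -> 99%
        assert out.loc["rye", "suppression_pct"] == pytest.approx(99.0)

    def test_negative_suppression_not_clipped(self):
        table = make_table(
            [
                ("s1", "2020", "b1", "c1", "control", "a", "weed", 2000.0),
                ("s1", "2020", "b1", "t1", "rye", "a", "weed", 2500.0),
            ]
        )
        out = cstats.suppression_summary(table).set_index("treatment")
        assert out.loc["rye", "suppression_pct"] == pytest.approx(-25.0)

    def test_zero_control_mean_flagged(self):
        table = make_table(
            [
                ("s1", "2020", "b1", "c1", "control", "a", "weed", 0.0),
                ("s1", "2020", "b1", "t1", "rye", "a", "weed", 10.0),
            ]
        )
        out = cstats.suppression_summary(table).set_index("treatment")
        assert not out.loc["rye", "defined"]
        assert np.isnan(out.loc["rye", "suppression_pct"])

    def test_unknown_taxa_count_toward_totals(self):
        table = make_table(
            [
                ("s1", "2020", "b1", "c1", "control", "a", "weed", 1000.0),
                ("s1", "2020", "b1", "c1", "control", "x", "unknown", 1000.0),
                ("s1", "2020", "b1", "t1", "rye", "a", "weed", 20.0),
            ]
        )
        out = cstats.suppression_summary(table).set_index("treatment")
        assert out.loc["control", "mean_biomass"] == pytest.approx(2000.0)

    def test_invariant_to_plot_order(self, table):
        shuffled = cdata.CommunityTable(
            table.data.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        a = cstats.suppression_summary(table)
        b = cstats.suppression_summary(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestPermanova:
    def _design(self, groups):
        idx = [f"p{i}" for i in range(len(groups))]
        return pd.DataFrame({"treatment": groups}, index=idx), idx

    def test_pseudo_f_equals_classical_anova_f(self, rng):
        y = rng.normal(0, 1, 18)
        groups = np.repeat(["a", "b", "c"], 6)
        design, idx = self._design(groups)
        D = euclidean_dm(y, idx)
        res = cstats.permanova(D, design, ["treatment"], n_perm=9, seed=0)
        f_classic = sps.f_oneway(*(y[groups == g] for g in "abc")).statistic
        f_mine = float(res.table.loc[0, "pseudo_F"])
        assert f_mine == pytest.approx(f_classic, abs=1e-9)

    def test_sum_of_squares_additivity(self, rng):
        y = rng.normal(0, 1, 24)
        groups = np.repeat(["a", "b", "c", "d"], 6)
        sites = np.tile(np.repeat(["s1", "s2"], 3), 4)
        idx = [f"p{i}" for i in range(24)]
        design = pd.DataFrame({"treatment": groups, "site": sites}, index=idx)
        res = cstats.permanova(
            euclidean_dm(y, idx), design, ["site", "treatment"], n_perm=9, seed=0
        )
        ss = res.table.set_index("term")["ss"]
        assert ss.sum() == pytest.approx(res.total_ss, abs=1e-9)

    def test_p_floor_add_one_rule(self, rng):
        # overwhelming group separation: observed F exceeds every permuted F
        y = np.concatenate([rng.normal(0, 0.01, 8), rng.normal(100, 0.01, 8)])
        design, idx = self._design(np.repeat(["a", "b"], 8))
        res = cstats.permanova(euclidean_dm(y, idx), design, ["treatment"], n_perm=999, seed=1)
        assert res.table.loc[0, "p_value"] == pytest.approx(1 / 1000)

    def test_reproducible_for_fixed_seed(self, rng):
        y = rng.normal(0, 1, 12)
        design, idx = self._design(np.repeat(["a", "b", "c"], 4))
        D = euclidean_dm(y, idx)
        r1 = cstats.permanova(D, design, ["treatment"], n_perm=99, seed=7)
        r2 = cstats.permanova(D, design, ["treatment"], n_perm=99, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_matches_skbio_one_factor(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        X = rng.gamma(1, 1, (15, 4))
        groups = np.repeat(["a", "b", "c"], 5)
        idx = [f"p{i}" for i in range(15)]
        bc = cdata.bray_curtis(pd.DataFrame(np.log1p(X), index=idx))
        design = pd.DataFrame({"treatment": groups}, index=idx)
        mine = cstats.permanova(bc, design, ["treatment"], n_perm=9, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(bc.to_numpy(), ids=idx), grouping=list(groups),
            permutations=9,
        )
        assert float(mine.table.loc[0, "pseudo_F"]) == pytest.approx(
            theirs["test statistic"], abs=1e-9
        )

    def test_identical_plots_rejected(self):
        idx = ["p0", "p1", "p2", "p3"]
        D = pd.DataFrame(np.zeros((4, 4)), index=idx, columns=idx)
        design = pd.DataFrame({"treatment": ["a", "a", "b", "b"]}, index=idx)
        with pytest.raises(ValueError, match="no multivariate variation"):
            cstats.permanova(D, design, ["treatment"], n_perm=9, seed=0)

    def test_single_level_term_rejected(self, rng):
        y = rng.normal(0, 1, 6)
        design, idx = self._design(["a"] * 6)
        with pytest.raises(ValueError, match="treatment"):
            cstats.permanova(euclidean_dm(y, idx), design, ["treatment"], n_perm=9, seed=0)

    def test_strata_keep_labels_within_site(self, rng):
        y = rng.normal(0, 1, 16)
        idx = [f"p{i}" for i in range(16)]
        design = pd.DataFrame(
            {
                "treatment": np.tile(np.repeat(["a", "b"], 4), 2),
                "site": np.repeat(["s1", "s2"], 8),
            },
            index=idx,
        )
        res = cstats.permanova(
            euclidean_dm(y, idx), design, ["treatment"], n_perm=49, seed=0, strata="site"
        )
        assert 0 < res.table.loc[0, "p_value"] <= 1


class TestBetaDispersion:
    def test_two_point_group_distances(self):
        # 1-D geometry: group g at 0 and 2 -> centroid 1, both distances 1
        pts = np.array([0.0, 2.0, 10.0, 10.0, 12.0])
        idx = [f"p{i}" for i in range(5)]
        groups = pd.Series(["g", "g", "h", "h", "h"], index=idx)
        res = cstats.beta_dispersion(euclidean_dm(pts, idx), groups, n_perm=19, seed=0)
        assert res.distances["p0"] == pytest.approx(1.0)
        assert res.distances["p1"] == pytest.approx(1.0)

    def test_identical_group_members_zero_dispersion(self):
        pts = np.array([5.0, 5.0, 5.0, 1.0, 3.0])
        idx = [f"p{i}" for i in range(5)]
        groups = pd.Series(["g", "g", "g", "h", "h"], index=idx)
        res = cstats.beta_dispersion(euclidean_dm(pts, idx), groups, n_perm=19, seed=0)
        assert np.allclose(res.distances[["p0", "p1", "p2"]], 0.0, atol=1e-9)

    def test_group_means_are_means_of_member_distances(self, rng):
        pts = rng.normal(0, 1, 10)
        idx = [f"p{i}" for i in range(10)]
        groups = pd.Series(np.repeat(["g", "h"], 5), index=idx)
        res = cstats.beta_dispersion(euclidean_dm(pts, idx), groups, n_perm=19, seed=0)
        for g in ("g", "h"):
            members = res.distances[groups == g]
            assert res.group_means[g] == pytest.approx(members.mean())

    def test_singleton_group_rejected(self):
        pts = np.array([0.0, 1.0, 2.0])
        idx = ["p0", "p1", "p2"]
        groups = pd.Series(["g", "g", "h"], index=idx)
        with pytest.raises(ValueError, match="h"):
            cstats.beta_dispersion(euclidean_dm(pts, idx), groups, n_perm=9, seed=0)

    def test_mirror_groups_rarely_significant(self, rng):
        # two groups with identical internal geometry: homogeneity holds
        hits = 0
        runs = 50
        for k in range(runs):
            local = np.random.default_rng(k)
            half = local.normal(0, 1, 6)
            pts = np.concatenate([half, half + 50.0])  # translated copy
            idx = [f"p{i}" for i in range(12)]
            groups = pd.Series(np.repeat(["g", "h"], 6), index=idx)
            res = cstats.beta_dispersion(
                euclidean_dm(pts, idx), groups, n_perm=99, seed=k
            )
            if res.p_value <= 0.05:
                hits += 1
        assert hits / runs <= 0.10

    def test_bray_curtis_negative_eigenvalues_handled(self, rng):
        X = rng.gamma(0.5, 5, (12, 6))
        idx = [f"p{i}" for i in range(12)]
        bc = cdata.bray_curtis(pd.DataFrame(X, index=idx))
        groups = pd.Series(np.repeat(["g", "h"], 6), index=idx)
        res = cstats.beta_dispersion(bc, groups, n_perm=19, seed=0)
        assert np.all(res.distances >= 0)
        assert np.isfinite(res.f_statistic)


class TestOneSampleTest:
    def test_symmetric_values_give_t_zero_p_one(self):
        res = cstats.one_sample_test([-1.0, 1.0, -1.0, 1.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_t_and_p(self):
        res = cstats.one_sample_test([1.0, 2.0, 3.0, 4.0])
        assert res.t_statistic == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3
        assert res.p_value == pytest.approx(0.0305, abs=2e-4)

    @pytest.mark.parametrize("bad", [[5.0], [5.0, 5.0, 5.0]])
    def test_degenerate_samples_rejected(self, bad):
        with pytest.raises(ValueError, match="degenerate"):
            cstats.one_sample_test(bad)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        hits = sum(
            cstats.one_sample_test(rng.normal(0, 1, 10)).p_value < 0.05
            for _ in range(500)
        )
        assert 0.03 <= hits / 500 <= 0.07


class TestTreatmentContrast:
    def _mpd_table(self, pairs):
        rows = []
        for b, (t_val, c_val) in enumerate(pairs):
            rows.append(
                {"plot": f"b{b}t", "site": "s1", "year": "2020", "block": f"b{b}",
                 "treatment": "rye", "mpd": t_val, "n_taxa": 5,
                 "defined": not np.isnan(t_val)}
            )
            rows.append(
                {"plot": f"b{b}c", "site": "s1", "year": "2020", "block": f"b{b}",
                 "treatment": "control", "mpd": c_val, "n_taxa": 5,
                 "defined": not np.isnan(c_val)}
            )
        return pd.DataFrame(rows)

    def test_identical_pairs_give_t_zero_p_one(self):
        out = cstats.treatment_contrast(self._mpd_table([(2.0, 2.0)] * 4))
        assert out.loc[0, "t_statistic"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_undefined_pairs_dropped_and_counted(self):
        out = cstats.treatment_contrast(
            self._mpd_table([(2.0, 1.0), (2.5, 1.0), (np.nan, 1.0), (2.0, np.nan)])
        )
        assert out.loc[0, "n_pairs"] == 2
        assert out.loc[0, "n_dropped"] == 2

    def test_all_pairs_dropped_flags_not_testable(self):
        out = cstats.treatment_contrast(
            self._mpd_table([(np.nan, 1.0), (np.nan, 1.0)])
        )
        assert not out.loc[0, "testable"]

    def test_holm_adjustment_monotone(self):
        table = pd.concat(
            [
                self._mpd_table([(2.0, 1.0), (2.2, 1.1), (2.4, 0.9), (2.1, 1.2)]),
            ]
        )
        out = cstats.treatment_contrast(table, adjust="holm")
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()


def test_holm_matches_hand_example():
    p = np.array([0.01, 0.04, 0.03])
    adj = cstats.holm_adjust(p)
    assert adj == pytest.approx([0.03, 0.06, 0.06])
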