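"""Metric operations vs brute-force oracles; resampling-null behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import paintscope as ps
from paintscope.metrics import MetricError

from conftest import toy_profile


class TestMedianReplicateCorrelation:
    def test_identical_rows_give_one(self, ):
        pm, df = toy_profile(seed=0)
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        df.loc[1, feats] = df.loc[0, feats]
        r_c, _ = ps.median_replicate_correlation(df, pm)
        assert r_c["A"] == pytest.approx(1.0)

    def test_exact_negatives_give_minus_one(self):
        pm, df = toy_profile(seed=0)
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        df.loc[1, feats] = -df.loc[0, feats].to_numpy()
        r_c, _ = ps.median_replicate_correlation(df, pm)
        assert r_c["A"] == pytest.approx(-1.0)

    def test_matches_bruteforce_over_all_pairs(self, desk_profile, desk_sim):
        platemap = desk_sim[0]
        r_c, excluded = ps.median_replicate_correlation(desk_profile, platemap)
        assert excluded == []
        # independent brute force for a few compounds
        data = desk_profile.data
        feats = [f for f in desk_profile.features if f != "Metadata_Object_Count"]
        for comp in ["C001", "C045", "C090"]:
            rows = data[data["Metadata_Compound"] == comp][feats].to_numpy()
            pairs = [stats.pearsonr(a, b).statistic
                     for a, b in itertools.combinations(rows, 2)]
            assert len(pairs) == 6
            assert r_c[comp] == pytest.approx(np.median(pairs), abs=1e-10)

    def test_compound_with_single_well_excluded(self):
        pm, df = toy_profile(seed=1)
        df = df.drop(index=1).reset_index(drop=True)  # A has one well left
        r_c, excluded = ps.median_replicate_correlation(df, pm)
        assert excluded == ["A"]
        assert set(r_c.index) == {"B", "C"}


class TestPercentile:
    def test_linear_interpolation_convention(self):
        assert ps.percentile(list(range(100)), 95) == pytest.approx(94.05)

    def test_constant_values(self):
        assert ps.percentile([3.3] * 7, 95) == pytest.approx(3.3)

    def test_q100_is_max(self):
        assert ps.percentile([1.0, 9.0, 4.0], 100) == 9.0

    def test_empty_error(self):
        with pytest.raises(MetricError):
            ps.percentile([], 95)


class TestSampleNull:
    def test_default_null_size(self):
        assert ps.MetricConfig().null_size == 10_000
        assert ps.MetricConfig().threshold_percentile == 95.0

    def test_length_and_determinism(self):
        pm, df = toy_profile(seed=2)
        a = ps.sample_null(df, pm, group_size=2, K=500, seed=3)
        b = ps.sample_null(df, pm, group_size=2, K=500, seed=3)
        assert len(a) == 500
        np.testing.assert_array_equal(a, b)

    def test_k_one_threshold_is_the_element(self):
        pm, df = toy_profile(seed=2)
        null = ps.sample_null(df, pm, group_size=2, K=1, seed=0)
        assert ps.percentile(null, 95) == null[0]

    def test_noise_null_centered_on_zero(self):
        rng = np.random.default_rng(0)
        n_feat, K = 100, 2000
        pmap = ps.generate_jumpmoa_layout(seed=0)
        wells = pmap.treatments.index.tolist()
        df = pd.DataFrame(rng.standard_normal((len(wells), n_feat)),
                          columns=[f"Cells_Intensity_F{i}_DNA"
                                   for i in range(n_feat)])
        df.insert(0, "Metadata_Plate", "p")
        df.insert(1, "Metadata_Well", wells)
        null = ps.sample_null(df, pmap, group_size=4, K=K, seed=1)
        assert abs(null.mean()) <= 3 / np.sqrt(K * n_feat) * 10

    def test_distinctness_unsatisfiable(self):
        pm, df = toy_profile(seed=0)
        with pytest.raises(MetricError, match="distinct"):
            ps.sample_null(df, pm, group_size=4, K=10, seed=0)

    def test_moa_mode_rejects_same_moa_pairs(self):
        pm, df = toy_profile(seed=4)
        # make every A and B well identical: a same-MOA (A, B) draw would
        # yield a null statistic of exactly 1, so none may appear
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        for row in (1, 2, 3):
            df.loc[row, feats] = df.loc[0, feats].to_numpy()
        null = ps.sample_null(df, pm, group_size=2, K=300,
                              mode="non-matching-moa", seed=0)
        assert not np.any(null == 1.0)


class TestScoresAndLeaderboards:
    def test_percent_score_arithmetic(self):
        assert ps.percent_score(80, 60) == 70
        assert ps.percent_score(0, 0) == 0

    def test_percent_score_range_check(self):
        with pytest.raises(MetricError):
            ps.percent_score(-1, 50)

    def test_duplicate_settings_mean_aggregated(self):
        df = pd.DataFrame({"setting": ["s1", "s1"], "percent_score": [70, 80]})
        board = ps.normalize_leaderboard(df)
        assert len(board) == 1
        assert board.loc[0, "percent_score"] == 75

    def test_normalized_to_best(self):
        df = pd.DataFrame({"setting": ["a", "b", "c"],
                           "percent_score": [50, 40, 30]})
        board = ps.normalize_leaderboard(df)
        assert board["normalized_score"].tolist() == [100, 80, 60]
        assert board["place"].tolist() == [1, 2, 3]

    def test_single_setting(self):
        df = pd.DataFrame({"setting": ["only"], "percent_score": [42.0]})
        assert ps.normalize_leaderboard(df)["normalized_score"].tolist() == [100]

    def test_ties_all_100_ordered_by_label(self):
        df = pd.DataFrame({"setting": ["b", "a"], "percent_score": [50, 50]})
        board = ps.normalize_leaderboard(df)
        assert board["normalized_score"].tolist() == [100, 100]
        assert board["setting"].tolist() == ["a", "b"]

    def test_all_zero_error(self):
        df = pd.DataFrame({"setting": ["a"], "percent_score": [0.0]})
        with pytest.raises(MetricError):
            ps.normalize_leaderboard(df)


def _oracle_reject(rng, n, labels, K, g):
    """Mirror of the documented rejection-sampling draw protocol."""
    out = []
    while len(out) < K:
        need = K - len(out)
        cand = rng.integers(0, n, size=(need, g))
        for row in cand:
            row = row.tolist()
            if len(set(row)) < g:
                continue
            if len({labels[i] for i in row}) < g:
                continue
            out.append(row)
    return out[:K]


class TestToyPlateOracle:
    """Exhaustive hand computation on a 6-well plate, shared seeds."""

    SEED = 7
    K = 200

    @pytest.fixture()
    def toy(self):
        return toy_profile(seed=11)

    def _corr(self, df):
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        return np.corrcoef(df[feats].to_numpy())

    def test_percent_replicating_equals_bruteforce(self, toy):
        pm, df = toy
        corr = self._corr(df)
        wells_of = {"A": [0, 1], "B": [2, 3], "C": [4, 5]}
        r_c = {c: corr[i, j] for c, (i, j) in wells_of.items()}
        labels = ["A", "A", "B", "B", "C", "C"]
        rng = np.random.default_rng([self.SEED, 1])
        draws = _oracle_reject(rng, 6, labels, self.K, 2)
        null = [corr[i, j] for i, j in draws]
        t = np.percentile(null, 95)
        expect = 100.0 * np.mean([v > t for v in r_c.values()])
        frag = ps.percent_replicating(
            df, pm, ps.MetricConfig(null_size=self.K), seed=self.SEED)
        assert frag.threshold == pytest.approx(t, abs=1e-12)
        assert frag.value == pytest.approx(expect)
        for c in wells_of:
            assert frag.per_compound[c] == pytest.approx(r_c[c], abs=1e-12)

    def test_percent_matching_equals_bruteforce(self, toy):
        pm, df = toy
        corr = self._corr(df)
        wells_of = {"A": [0, 1], "B": [2, 3], "C": [4, 5]}
        # foreground: A vs B cross pairs (both MOA M1); C singleton-excluded
        cross = [corr[i, j] for i in wells_of["A"] for j in wells_of["B"]]
        m = {"A": np.median(cross), "B": np.median(cross)}
        comps = ["A", "B", "C"]  # sorted order used by the null sampler
        moa = ["M1", "M1", "M2"]
        rng = np.random.default_rng([self.SEED, 2])
        draws = _oracle_reject(rng, 3, moa, self.K, 2)
        null = []
        for c1, c2 in draws:
            vals = [corr[i, j] for i in wells_of[comps[c1]]
                    for j in wells_of[comps[c2]]]
            null.append(np.median(vals))
        t = np.percentile(null, 95)
        expect = 100.0 * np.mean([v > t for v in m.values()])
        frag = ps.percent_matching(
            df, pm, ps.MetricConfig(null_size=self.K), seed=self.SEED)
        assert frag.threshold == pytest.approx(t, abs=1e-12)
        assert frag.value == pytest.approx(expect)
        assert frag.excluded == ["C"]


class TestPercentReplicating:
    def test_identical_replicates_with_noise_controls(self, platemap):
        rng = np.random.default_rng(0)
        n_feat = 20
        rows, wlabs = [], []
        for comp, wells in platemap.replicate_wells().items():
            vec = rng.standard_normal(n_feat)
            for wlab in wells:
                rows.append(vec)
                wlabs.append(wlab)
        df = pd.DataFrame(np.asarray(rows),
                          columns=[f"Cells_Intensity_F{i}_DNA"
                                   for i in range(n_feat)])
        df.insert(0, "Metadata_Plate", "p")
        df.insert(1, "Metadata_Well", wlabs)
        frag = ps.percent_replicating(df, platemap,
                                      ps.MetricConfig(null_size=1000), seed=0)
        assert frag.threshold < 1.0
        assert frag.value == 100.0

    def test_default_layout_matching_census(self, desk_profile, desk_sim):
        platemap = desk_sim[0]
        frag = ps.percent_matching(desk_profile, platemap,
                                   ps.MetricConfig(null_size=500), seed=0)
        assert frag.n_evaluated == 86
        assert len(frag.excluded) == 4

    @settings(max_examples=8, deadline=None)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, scale, shift):
        pm, df = toy_profile(seed=5, n_features=12)
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        cfg = ps.MetricConfig(null_size=100)
        base = ps.percent_replicating(df, pm, cfg, seed=1)
        df2 = df.copy()
        df2[feats] = df2[feats] * scale + shift
        moved = ps.percent_replicating(df2, pm, cfg, seed=1)
        assert moved.value == base.value
        np.testing.assert_allclose(moved.null, base.null, atol=1e-9)

    def test_feature_permutation_invariance(self):
        pm, df = toy_profile(seed=6, n_features=10)
        feats = [c for c in df.columns if not c.startswith("Metadata_")]
        cfg = ps.MetricConfig(null_size=100)
        base = ps.percent_replicating(df, pm, cfg, seed=2)
        perm = list(np.random.default_rng(0).permutation(feats))
        df2 = df[["Metadata_Plate", "Metadata_Well"] + perm]
        moved = ps.percent_replicating(df2, pm, cfg, seed=2)
        np.testing.assert_allclose(moved.null, base.null, atol=1e-9)
        assert moved.value == base.value


class TestProfileStrengthModel:
    def test_fit_summary_and_score(self, desk_profile, desk_sim):
        platemap = desk_sim[0]
        model = ps.ProfileStrength(desk_profile, platemap,
                                   ps.MetricConfig(null_size=1000))
        res = model.fit(seed=1)
        assert res.percent_score == pytest.approx(
            (res.percent_replicating + res.percent_matching) / 2)
        text = res.summary()
        assert "Percent replicating" in text
        assert "Percent score" in text

    def test_save_roundtrip(self, desk_profile, desk_sim, tmp_path):
        platemap = desk_sim[0]
        res = ps.ProfileStrength(desk_profile, platemap,
                                 ps.MetricConfig(null_size=200)).fit(seed=1)
        path = res.save(tmp_path / "res.json",
                        null_csv=tmp_path / "null.csv")
        import json
        d = json.loads(path.read_text())
        assert d["percent_score"] == pytest.approx(res.percent_score)
        null = pd.read_csv(tmp_path / "null.csv")
        assert len(null) == 200
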