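"""Probe handling, normalization, NIPALS PLS, VIP and bootstrap ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from striacov.expression import (
    ExpressionMatrix,
    PLSModel,
    ProbeTable,
    bootstrap_vip_ranking,
    cv_pls_accuracy,
    differential_stability,
    filter_probes,
    fit_pls,
    match_samples_to_voxels,
    normalize_expression,
    predict_pls,
    scaled_robust_sigmoid,
    select_probe_by_differential_stability,
    vip_scores,
)
from striacov.map_prep import Mask


def make_probe_table(expression, gene_ids, probe_ids=None, flags=None, donors=None, coords=None):
    expression = np.asarray(expression, dtype=float)
    n_probes, n_samples = expression.shape
    if probe_ids is None:
        probe_ids = [f"P{i}" for i in range(n_probes)]
    if flags is None:
        flags = np.ones_like(expression, dtype=bool)
    if donors is None:
        donors = np.array(["D1"] * n_samples)
    if coords is None:
        coords = np.column_stack(
            [np.arange(n_samples), np.zeros(n_samples), np.zeros(n_samples)]
        ).astype(float)
    return ProbeTable(
        probes=pd.DataFrame({"probe_id": probe_ids, "gene_id": gene_ids}),
        expression=expression,
        background_exceeded=flags,
        donor_ids=donors,
        coords_mm=coords,
    )


class TestFilterProbes:
    def test_threshold_behaviour(self, rng):
        n = 100
        flags = np.vstack(
            [
                np.ones(n, bool),  # always exceeds -> kept
                np.r_[np.ones(49, bool), np.zeros(51, bool)],  # 49% -> removed
                np.r_[np.ones(50, bool), np.zeros(50, bool)],  # exactly 50% -> kept
            ]
        )
        pt = make_probe_table(
            rng.standard_normal((3, n)), ["G1", "G2", "G3"], flags=flags
        )
        kept = filter_probes(pt)
        assert kept.probes["gene_id"].tolist() == ["G1", "G3"]

    def test_empty_result_warns_not_raises(self, rng, caplog):
        pt = make_probe_table(
            rng.standard_normal((1, 10)), ["G1"], flags=np.zeros((1, 10), bool)
        )
        with caplog.at_level("WARNING"):
            out = filter_probes(pt)
        assert len(out.probes) == 0


class TestDifferentialStability:
    def three_donor_table(self, rng, probe_noise=(0.0, 1.5)):
        # 3 donors x 6 shared locations; probe 0 replicates identically,
        # probe 1 is noisy -> lower DS
        n_loc = 6
        donors = np.repeat(["D1", "D2", "D3"], n_loc)
        coords = np.tile(
            np.column_stack([np.arange(n_loc), np.zeros(n_loc), np.zeros(n_loc)]),
            (3, 1),
        ).astype(float)
        profile = rng.standard_normal(n_loc)
        rows = []
        for noise in probe_noise:
            rows.append(
                np.concatenate(
                    [profile + noise * rng.standard_normal(n_loc) for _ in range(3)]
                )
            )
        return make_probe_table(
            np.vstack(rows), ["G1", "G1"], probe_ids=["Pa", "Pb"],
            donors=donors, coords=coords,
        ), profile

    def test_identical_replication_gives_ds_one(self, rng):
        pt, _ = self.three_donor_table(rng)
        ds = differential_stability(pt)
        assert ds[0] == pytest.approx(1.0)

    def test_matches_explicit_donor_pair_loop(self, rng):
        pt, _ = self.three_donor_table(rng, probe_noise=(0.4, 1.2))
        ds = differential_stability(pt)
        donors = ["D1", "D2", "D3"]
        for p in range(2):
            x = pt.expression[p].reshape(3, 6)
            rs = []
            for i in range(3):
                for j in range(i + 1, 3):
                    rs.append(np.corrcoef(x[i], x[j])[0, 1])
            assert ds[p] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_selection_prefers_stable_probe_and_breaks_ties_by_id(self, rng):
        pt, _ = self.three_donor_table(rng)
        expr = select_probe_by_differential_stability(pt)
        assert expr.gene_ids == ["G1"]
        np.testing.assert_array_equal(expr.values[:, 0], pt.expression[0])
        # identical probes -> tie broken by probe_id order
        tie = make_probe_table(
            np.vstack([pt.expression[0], pt.expression[0]]),
            ["G1", "G1"], probe_ids=["Pz", "Pa"],
            donors=pt.donor_ids, coords=pt.coords_mm,
        )
        out = select_probe_by_differential_stability(tie)
        np.testing.assert_array_equal(out.values[:, 0], pt.expression[0])

    def test_single_donor_rejected(self, rng):
        pt = make_probe_table(rng.standard_normal((2, 5)), ["G1", "G2"])
        with pytest.raises(ValueError, match="2 donors"):
            differential_stability(pt)


class TestSampleMatching:
    def striatal_mask(self):
        coords = np.array(
            [[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0], [0.0, 2, 0]], dtype=float
        )
        return Mask(np.array([10, 11, 12, 13]), coords)

    def make_expr(self, coords):
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        return ExpressionMatrix(
            values=np.arange(n * 2, dtype=float).reshape(n, 2),
            gene_ids=["G1", "G2"],
            coords_mm=coords,
            donor_ids=np.array([f"D{i}" for i in range(n)]),
        )

    def test_voxel_center_matches_exactly(self):
        expr = self.make_expr([[2.0, 0, 0]])
        matched, dropped = match_samples_to_voxels(expr, self.striatal_mask())
        assert dropped == 0
        assert matched.matched_voxel_id.tolist() == [11]

    def test_far_sample_dropped(self):
        expr = self.make_expr([[2.0, 0, 0], [9.1, 0, 0]])  # 5.1 mm past voxel 12
        matched, dropped = match_samples_to_voxels(expr, self.striatal_mask())
        assert dropped == 1
        assert matched.n_samples == 1

    def test_default_radius_is_3mm(self):
        near = self.make_expr([[6.9, 0, 0]])  # 2.9 mm from voxel 12
        far = self.make_expr([[7.1, 0, 0]])  # 3.1 mm from voxel 12
        assert match_samples_to_voxels(near, self.striatal_mask())[1] == 0
        assert match_samples_to_voxels(far, self.striatal_mask())[1] == 1


class TestScaledRobustSigmoid:
    def test_range_and_extremes(self, rng):
        x = rng.standard_normal(30)
        out = scaled_robust_sigmoid(x)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_strictly_monotone(self, rng):
        x = np.sort(rng.standard_normal(20))
        out = scaled_robust_sigmoid(x)
        assert np.all(np.diff(out) > 0)

    def test_median_maps_to_half_before_rescale(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        med, iqr = 3.0, 2.0
        s = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        assert s[2] == pytest.approx(0.5)
        out = scaled_robust_sigmoid(x)
        np.testing.assert_allclose(out, (s - s.min()) / (s.max() - s.min()))

    def test_zero_iqr_falls_back_to_half(self):
        np.testing.assert_array_equal(
            scaled_robust_sigmoid(np.array([1.0, 1.0, 1.0, 1.0])), 0.5
        )

    def test_normalization_never_mixes_donors(self, rng):
        values = rng.standard_normal((10, 3))
        donors = np.array(["D1"] * 5 + ["D2"] * 5)
        coords = np.column_stack([np.arange(10), np.zeros(10), np.zeros(10)]).astype(float)
        expr = ExpressionMatrix(values, ["G1", "G2", "G3"], coords, donors)
        out1 = normalize_expression(expr)
        tampered = values.copy()
        tampered[5:] += 100.0  # change D2 only
        expr2 = ExpressionMatrix(tampered, ["G1", "G2", "G3"], coords, donors)
        out2 = normalize_expression(expr2)
        np.testing.assert_allclose(out1.values[:5], out2.values[:5])


class TestPLS:
    def test_single_driving_gene_dominates_weights(self, rng):
        x = rng.standard_normal((30, 6))
        y = 2.0 * x[:, 3] + 0.01 * rng.standard_normal(30)
        model = fit_pls(x, y, 1)
        assert np.argmax(np.abs(model.x_weights[:, 0])) == 3

    def test_first_weights_match_cross_covariance_svd(self, rng):
        """First weight vector equals the dominant singular vector of X'y."""
        x = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        model = fit_pls(x, y, 2, standardize=False)
        xc = x - x.mean(axis=0)
        yc = (y - y.mean()) / y.std()
        w_oracle = xc.T @ yc
        w_oracle /= np.linalg.norm(w_oracle)
        dot = np.dot(model.x_weights[:, 0], w_oracle)
        np.testing.assert_allclose(model.x_weights[:, 0], np.sign(dot) * w_oracle, atol=1e-10)

    def test_matches_sklearn_nipals_predictions(self, rng):
        x = rng.standard_normal((25, 12))
        y = x @ rng.standard_normal(12) + rng.standard_normal(25)
        for k in (1, 3, 5):
            mine = fit_pls(x, y, k)
            sk = PLSRegression(n_components=k, scale=True).fit(x, y)
            np.testing.assert_allclose(
                predict_pls(mine, x), sk.predict(x).ravel(), atol=1e-8
            )

    def test_in_sample_r2_non_decreasing(self, rng):
        x = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        r2 = []
        for k in range(1, 6):
            model = fit_pls(x, y, k)
            resid = y - predict_pls(model, x)
            r2.append(1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2))
        assert np.all(np.diff(r2) >= -1e-12)

    def test_component_budget_enforced(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(rng.standard_normal((5, 8)), rng.standard_normal(5), 5)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(rng.standard_normal((6, 3)), np.ones(6), 1)


class TestCVAccuracy:
    def test_folds_partition_samples(self, rng):
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(23, dtype=int)
        for _, te in kf.split(np.zeros((23, 1))):
            seen[te] += 1
        assert np.all(seen == 1)

    def test_reproducible_with_seed(self, rng):
        x = rng.standard_normal((40, 10))
        y = x[:, 0] + rng.standard_normal(40)
        a = cv_pls_accuracy(x, y, components=(2, 3), n_repeats=2, rng=7)
        b = cv_pls_accuracy(x, y, components=(2, 3), n_repeats=2, rng=7)
        assert a == b

    def test_planted_signal_predicts_well(self, rng):
        x = rng.standard_normal((60, 30))
        y = x[:, :5] @ np.ones(5) + 0.3 * rng.standard_normal(60)
        out = cv_pls_accuracy(x, y, components=(2, 3, 4), n_repeats=2, rng=1)
        assert out["mean_r"] >= 0.5


class TestVIP:
    def test_sum_of_squares_identity(self, rng):
        for _ in range(5):
            n, p, k = 20, rng.integers(4, 12), 3
            x = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            model = fit_pls(x, y, k)
            vip = vip_scores(model)
            assert np.sum(vip**2) == pytest.approx(p, abs=1e-9)

    def test_single_component_proportional_to_weights(self, rng):
        x = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        model = fit_pls(x, y, 1)
        vip = vip_scores(model)
        expected = np.sqrt(6) * np.abs(model.x_weights[:, 0])
        np.testing.assert_allclose(vip, expected, atol=1e-10)

    def test_matches_literal_formula_two_components(self, rng):
        x = rng.standard_normal((18, 5))
        y = rng.standard_normal(18)
        model = fit_pls(x, y, 2)
        p = 5
        total = model.ss.sum()
        expected = np.sqrt(
            p
            * sum(
                model.ss[k]
                * (model.x_weights[:, k] / np.linalg.norm(model.x_weights[:, k])) ** 2
                for k in range(2)
            )
            / total
        )
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-12)

    def test_zero_ss_rejected(self, rng):
        model = fit_pls(rng.standard_normal((10, 4)), rng.standard_normal(10), 2)
        model.ss = np.zeros(2)
        with pytest.raises(ValueError, match="VIP undefined"):
            vip_scores(model)


class TestBootstrapRanking:
    def test_identical_gene_columns_rank_adjacent_by_id(self, rng):
        x = rng.standard_normal((30, 5))
        x[:, 3] = x[:, 1]  # duplicate column
        y = x[:, 0] + 0.5 * rng.standard_normal(30)
        ranking = bootstrap_vip_ranking(
            x, y, gene_ids=["GA", "GB", "GC", "GB2", "GE"], n_components=2, n_boot=50,
            rng=3,
        )
        rank_b = int(ranking.loc[ranking["gene_id"] == "GB", "rank"].iloc[0])
        rank_b2 = int(ranking.loc[ranking["gene_id"] == "GB2", "rank"].iloc[0])
        assert abs(rank_b - rank_b2) == 1
        assert rank_b < rank_b2  # GB before GB2 by id

    def test_signal_genes_rank_high(self, rng):
        n, p = 60, 40
        x = rng.standard_normal((n, p))
        y = x[:, :4] @ np.ones(4) + 0.3 * rng.standard_normal(n)
        ranking = bootstrap_vip_ranking(
            x, y, gene_ids=[f"G{i}" for i in range(p)], n_components=3, n_boot=100,
            rng=4,
        )
        top = set(ranking.head(6)["gene_id"])
        assert {"G0", "G1", "G2", "G3"} <= top

    def test_ranks_are_a_permutation(self, rng):
        x = rng.standard_normal((25, 8))
        y = x[:, 0] + rng.standard_normal(25)
        ranking = bootstrap_vip_ranking(
            x, y, gene_ids=[f"G{i}" for i in range(8)], n_components=2, n_boot=20, rng=5
        )
        assert sorted(ranking["rank"]) == list(range(1, 9))
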