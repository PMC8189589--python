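"""CCA core, permutation schemes, mode test machinery, influence maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from striacov.cca import (
    PermutationScheme,
    _make_splits,
    _matching_rounds,
    _split_statistic,
    _test_correlation,
    block_permutation,
    covariation_influence,
    cross_validated_mode_test,
    fit_cca,
    fit_mode,
    scheme_from_manifest,
    score_scans,
)
from striacov.map_prep import fit_pca, project_pca


def cca_eigen_oracle(x, y):
    """First canonical correlation from the dense generalized eigenproblem."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    sxx = x.T @ x
    syy = y.T @ y
    sxy = x.T @ y
    m = linalg.solve(sxx, sxy) @ linalg.solve(syy, sxy.T)
    evals = np.linalg.eigvals(m)
    return float(np.sqrt(np.max(evals.real)))


class TestFitCCA:
    def test_identical_blocks_give_r_one(self, rng):
        x = rng.standard_normal((10, 3))
        assert fit_cca(x, x).canonical_r == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("shape", [(8, 3), (8, 4)])
    def test_matches_generalized_eigenproblem(self, rng, shape):
        for _ in range(5):
            x = rng.standard_normal(shape)
            y = rng.standard_normal(shape)
            mode = fit_cca(x, y)
            assert mode.canonical_r == pytest.approx(cca_eigen_oracle(x, y), abs=1e-8)

    def test_invariant_under_invertible_transform(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 3))
        a = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        r1 = fit_cca(x, y).canonical_r
        r2 = fit_cca(x, y @ a).canonical_r
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_rank_deficient_rejected(self, rng):
        x = rng.standard_normal((8, 3))
        x[:, 2] = x[:, 0] + x[:, 1]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cca(x, rng.standard_normal((8, 3)))

    def test_canonical_r_nonnegative(self, rng):
        for _ in range(10):
            mode = fit_cca(rng.standard_normal((9, 2)), rng.standard_normal((9, 2)))
            assert 0 <= mode.canonical_r <= 1


class TestScoring:
    def test_training_rows_reproduce_variates(self, planted_cohort):
        cohort, _ = planted_cohort
        mode = fit_mode(cohort.roi_maps, cohort.brain_maps, k=4)
        scores = score_scans(mode, cohort.roi_maps, cohort.brain_maps)
        np.testing.assert_allclose(scores, mode.variates, atol=1e-10)

    def test_duplicated_row_gets_duplicated_scores(self, planted_cohort):
        cohort, _ = planted_cohort
        mode = fit_mode(cohort.roi_maps, cohort.brain_maps, k=3)
        roi = np.vstack([cohort.roi_maps[0], cohort.roi_maps[0]])
        brain = np.vstack([cohort.brain_maps[0], cohort.brain_maps[0]])
        scores = score_scans(mode, roi, brain)
        np.testing.assert_allclose(scores[0], scores[1])

    def test_held_out_scores_track_latent(self, planted_cohort):
        cohort, truth = planted_cohort
        n = len(cohort.manifest)
        train = np.arange(0, n - 6)
        test = np.arange(n - 6, n)
        mode = fit_mode(cohort.roi_maps, cohort.brain_maps, k=6, fit_rows=train)
        scores = score_scans(mode, cohort.roi_maps[test], cohort.brain_maps[test])
        r = abs(np.corrcoef(scores[:, 0], truth.latent_scores[test])[0, 1])
        assert r >= 0.5

    def test_dimension_mismatch_rejected(self, planted_cohort):
        cohort, _ = planted_cohort
        mode = fit_mode(cohort.roi_maps, cohort.brain_maps, k=3)
        with pytest.raises(ValueError):
            score_scans(mode, cohort.roi_maps[:, :10], cohort.brain_maps)


def toy_manifest():
    rows = []
    for s in range(3):
        rows += [(f"P{s}", "placebo"), (f"P{s}", "drug")]
    rows += [("U0", "placebo"), ("U1", "drug")]
    return pd.DataFrame(rows, columns=["subject_id", "condition"])


class TestBlockPermutation:
    def test_enumeration_three_pairs_two_singles(self, rng):
        """3 paired + 2 single subjects admit exactly 3! * 2! = 12 permutations."""
        scheme = scheme_from_manifest(toy_manifest(), "block")
        seen = set()
        for _ in range(3000):
            seen.add(tuple(block_permutation(scheme, rng)))
        assert len(seen) == 12

    def test_pairs_never_separated(self, rng):
        scheme = scheme_from_manifest(toy_manifest(), "block")
        for _ in range(200):
            perm = block_permutation(scheme, rng)
            for blk in scheme.blocks:
                if len(blk) == 2:
                    src = perm[blk]
                    assert abs(src[1] - src[0]) == 1  # same source block, in order

    def test_free_permutation_reaches_all_orders(self, rng):
        scheme = PermutationScheme(kind="free", n_scans=3)
        seen = {tuple(block_permutation(scheme, rng)) for _ in range(500)}
        assert seen == set(itertools.permutations(range(3)))

    def test_unpartnered_block_size_rejected(self, rng):
        manifest = pd.DataFrame(
            [("A", "placebo"), ("A", "drug"), ("B", "placebo")],
            columns=["subject_id", "condition"],
        )
        scheme = scheme_from_manifest(manifest, "block")
        with pytest.raises(ValueError, match="no same-size partner"):
            block_permutation(scheme, rng)


class TestModeTest:
    def test_fast_path_matches_general_cca(self, rng):
        """The diagonally-whitened inner loop equals fit_cca on PCA scores."""
        x = rng.standard_normal((30, 25))
        y = rng.standard_normal((30, 40))
        train = np.sort(rng.choice(30, 24, replace=False))
        test = np.setdiff1d(np.arange(30), train)
        fast = _split_statistic(x, y, train, test, (2, 3, 4))
        for i, k in enumerate((2, 3, 4)):
            bx, by = fit_pca(x, k, train), fit_pca(y, k, train)
            px, cy = project_pca(bx, x), project_pca(by, y)
            mode = fit_cca(px[train], cy[train])
            slow = _test_correlation(px[test] @ mode.u, cy[test] @ mode.v)
            assert fast[i] == pytest.approx(slow, abs=1e-12)

    def test_pair_preserving_splits_keep_subjects_together(self, rng):
        rows = [(f"P{s}", c) for s in range(10) for c in ("placebo", "drug")]
        rows += [("U0", "placebo"), ("U1", "drug")]
        manifest = pd.DataFrame(rows, columns=["subject_id", "condition"])
        splits = _make_splits(manifest, 20, 0.75, pair_preserving=True, rng=rng)
        subject = manifest["subject_id"].to_numpy()
        for train, test in splits:
            assert not (set(subject[train]) & set(subject[test]))

    def test_detects_planted_mode(self, planted_cohort):
        cohort, _ = planted_cohort
        res = cross_validated_mode_test(
            cohort.roi_maps,
            cohort.brain_maps,
            cohort.manifest,
            k_values=(2, 3, 4),
            n_splits=15,
            n_perm=60,
            rng=0,
        )
        assert res.p_value <= 0.05
        assert res.mean_oos_r > 0.3
        assert res.mean_oos_r == pytest.approx(np.mean(list(res.per_k_r.values())))

    def test_in_sample_r_exceeds_out_of_sample(self, planted_cohort):
        cohort, _ = planted_cohort
        mode = fit_mode(cohort.roi_maps, cohort.brain_maps, k=4)
        res = cross_validated_mode_test(
            cohort.roi_maps,
            cohort.brain_maps,
            cohort.manifest,
            k_values=(4,),
            n_splits=15,
            n_perm=1,
            rng=0,
        )
        assert mode.canonical_r >= res.per_k_r[4]

    def test_null_distribution_centered_near_zero(self, null_cohort):
        cohort, _ = null_cohort
        res = cross_validated_mode_test(
            cohort.roi_maps,
            cohort.brain_maps,
            cohort.manifest,
            k_values=(2, 3),
            n_splits=10,
            n_perm=100,
            rng=0,
        )
        assert abs(res.null_distribution.mean()) < 0.1

    def test_invalid_n_perm_rejected(self, null_cohort):
        cohort, _ = null_cohort
        with pytest.raises(ValueError, match="n_perm"):
            cross_validated_mode_test(
                cohort.roi_maps, cohort.brain_maps, cohort.manifest, n_perm=0
            )


class TestMatching:
    def test_tied_scores_count_as_failure(self, planted_cohort):
        cohort, _ = planted_cohort
        roi = np.vstack([cohort.roi_maps, cohort.roi_maps[:1]])
        brain = np.vstack([cohort.brain_maps, cohort.brain_maps[:1]])
        n = roi.shape[0]
        # hold out the duplicated pair: identical scores in both modalities
        acc = _matching_rounds(roi, brain, [np.array([0, n - 1])], k=4)
        assert acc == 0.0

    def test_needs_at_least_four_scans(self, rng):
        from striacov.cca import matching_accuracy_test

        manifest = pd.DataFrame(
            [("A", "placebo"), ("A", "drug")], columns=["subject_id", "condition"]
        )
        with pytest.raises(ValueError, match="at least 4"):
            matching_accuracy_test(
                rng.standard_normal((2, 5)), rng.standard_normal((2, 5)), manifest
            )


class TestInfluence:
    def test_variate_column_has_influence_one(self, rng):
        v = rng.standard_normal(8)
        data = np.column_stack([v, rng.standard_normal((8, 3))])
        infl = covariation_influence(data, v)
        assert infl.values[0] == pytest.approx(1.0)

    def test_constant_voxel_gets_zero(self, rng):
        data = np.column_stack([np.full(6, 2.0), rng.standard_normal(6)])
        infl = covariation_influence(data, rng.standard_normal(6))
        assert infl.values[0] == 0.0

    def test_matches_per_voxel_loop(self, rng):
        data = rng.standard_normal((5, 10))
        v = rng.standard_normal(5)
        infl = covariation_influence(data, v)
        for j in range(10):
            expected = np.corrcoef(data[:, j], v)[0, 1]
            assert infl.values[j] == pytest.approx(expected, abs=1e-12)

    def test_sign_flips_with_variate(self, rng):
        data = rng.standard_normal((7, 4))
        v = rng.standard_normal(7)
        np.testing.assert_allclose(
            covariation_influence(data, v).values,
            -covariation_influence(data, -v).values,
            atol=1e-12,
        )

    def test_bounded_in_unit_interval(self, rng):
        infl = covariation_influence(rng.standard_normal((9, 20)), rng.standard_normal(9))
        assert np.all(np.abs(infl.values) <= 1.0)

    def test_too_few_scans_rejected(self, rng):
        with pytest.raises(ValueError, match="3 scans"):
            covariation_influence(rng.standard_normal((2, 4)), rng.standard_normal(2))
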