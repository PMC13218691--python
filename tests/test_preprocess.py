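"""Cleaning, splitting, normalization and target construction."""

import numpy as np
import pandas as pd
import pytest

import genopotential as gp
from genopotential.preprocess import (CohortParseError, apply_normalizers,
                                      build_target, clean_cohort,
                                      fit_normalizers, inject_feature_noise,
                                      read_cohort, read_processed,
                                      split_cohort, write_processed)
from genopotential.simulate import CohortTable, write_cohort


def _toy_cohort(ids, speed, endurance=None, strength=None, genos=None):
    n = len(ids)
    endurance = endurance if endurance is not None else [0.0] * n
    strength = strength if strength is not None else [0.0] * n
    genos = genos if genos is not None else np.zeros((n, 2))
    return CohortTable(
        ids=np.array(ids),
        genotypes=pd.DataFrame(np.asarray(genos, dtype=float),
                               columns=[f"m{j}" for j in
                                        range(np.asarray(genos).shape[1])]),
        phenotypes=pd.DataFrame({"speed": np.asarray(speed, float),
                                 "endurance": np.asarray(endurance, float),
                                 "strength": np.asarray(strength, float)}),
        historical=pd.DataFrame(index=range(n)),
    )


class TestReadCohort:
    def test_inner_join_drops_unmatched(self, tmp_path):
        g = pd.DataFrame({"id": ["a", "b", "c", "d"], "m0": [0, 1, 2, 1]})
        p = pd.DataFrame({"id": ["a", "b", "c"], "speed": [1., 2., 3.],
                          "endurance": [1., 2., 3.], "strength": [1., 2., 3.]})
        g.to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        p.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
        cohort, dropped = read_cohort(tmp_path / "g.tsv", tmp_path / "p.tsv")
        assert cohort.n == 3
        assert dropped == ["d"]

    def test_write_read_round_trip(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        loaded, dropped = read_cohort(paths["genotypes"], paths["phenotypes"],
                                      paths["truth"])
        assert dropped == []
        np.testing.assert_array_equal(loaded.ids, small_cohort.ids)
        np.testing.assert_allclose(loaded.genotypes.to_numpy(),
                                   small_cohort.genotypes.to_numpy())
        np.testing.assert_allclose(loaded.phenotypes.to_numpy(),
                                   small_cohort.phenotypes.to_numpy())
        np.testing.assert_allclose(loaded.true_genetic_value,
                                   small_cohort.true_genetic_value)

    def test_duplicate_header_token_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("id\tspeed\tspeed\n1\t2\t3\n")
        (tmp_path / "g.tsv").write_text("id\tm0\na\t1\n")
        with pytest.raises(CohortParseError, match="speed"):
            read_cohort(tmp_path / "g.tsv", tmp_path / "bad.tsv")

    def test_zero_overlap_is_hard_error(self, tmp_path):
        (tmp_path / "g.tsv").write_text("id\tm0\na\t1\n")
        (tmp_path / "p.tsv").write_text(
            "id\tspeed\tendurance\tstrength\nzz\t1\t1\t1\n")
        with pytest.raises(CohortParseError, match="overlap"):
            read_cohort(tmp_path / "g.tsv", tmp_path / "p.tsv")


class TestCleanCohort:
    def test_defect_free_cohort_unchanged(self):
        # bounded values: nothing can sit beyond 3 SD, no dupes, no NaN
        vals = list(np.linspace(-1.0, 1.0, 40))
        cohort = _toy_cohort([f"i{k}" for k in range(40)], speed=vals,
                             endurance=vals, strength=vals,
                             genos=np.random.default_rng(0).random((40, 3)))
        cleaned, report = clean_cohort(cohort)
        assert cleaned.n == cohort.n
        assert (report.n_duplicates, report.n_missing,
                report.n_outliers) == (0, 0, 0)

    def test_three_sd_rule_removes_planted_extreme(self):
        # 100 zeros and one 50: mean ~0.495, sample SD ~4.975, 3SD ~14.9
        cohort = _toy_cohort([f"i{k}" for k in range(101)],
                             speed=[0.0] * 100 + [50.0])
        cleaned, report = clean_cohort(cohort)
        assert report.n_outliers == 1
        assert cleaned.n == 100
        assert "i100" in report.removed_ids["outliers"]

    def test_small_n_insensitivity_of_3sd_rule(self):
        # speed [0,0,0,0,100]: |100-20| = 80 < 3 * 44.7 -> nothing removed
        cohort = _toy_cohort(list("abcde"), speed=[0, 0, 0, 0, 100])
        cleaned, report = clean_cohort(cohort)
        assert report.n_outliers == 0
        assert cleaned.n == 5

    def test_duplicates_keep_first_then_missing_then_outliers(self):
        genos = np.zeros((6, 2))
        genos[2, 0] = np.nan
        cohort = _toy_cohort(["a", "a", "b", "c", "d", "e"],
                             speed=[1, 9, 1, 1, 1, 1], genos=genos)
        cleaned, report = clean_cohort(cohort)
        assert report.n_duplicates == 1          # second 'a' dropped
        assert report.n_missing == 1             # 'b' has NaN genotype
        # survivor 'a' keeps speed=1 (first occurrence)
        assert cleaned.phenotypes["speed"].iloc[0] == 1

    def test_row_permutation_does_not_change_removed_ids(self, small_cohort):
        _, defects = gp.inject_data_defects(
            small_cohort,
            gp.SimulationConfig(n_individuals=300, n_markers=40, n_blocks=4,
                                n_causal=20, seed=7,
                                defect_rates=(0.02, 0.0, 0.01)))
        cfg = gp.SimulationConfig(n_individuals=300, n_markers=40, n_blocks=4,
                                  n_causal=20, seed=7,
                                  defect_rates=(0.02, 0.0, 0.01))
        dirty, _ = gp.inject_data_defects(small_cohort, cfg)
        _, rep1 = clean_cohort(dirty)
        rng = np.random.default_rng(0)
        perm = rng.permutation(dirty.n)
        from genopotential.preprocess import _subset
        shuffled = _subset(dirty, perm)
        _, rep2 = clean_cohort(shuffled)
        assert set(rep1.removed_ids["outliers"]) == set(
            rep2.removed_ids["outliers"])

    def test_empty_after_cleaning_is_error(self):
        cohort = _toy_cohort(["a", "b"], speed=[1, 2],
                             genos=np.full((2, 2), np.nan))
        with pytest.raises(ValueError, match="empty"):
            clean_cohort(cohort)


class TestSplit:
    def test_811_sizes(self):
        ids = [f"i{k}" for k in range(1000)]
        s = split_cohort(ids, seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == (800, 100, 100)

    def test_remainder_goes_to_test(self):
        ids = [f"i{k}" for k in range(1003)]
        s = split_cohort(ids, seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == (802, 100, 101)

    def test_determinism_and_seed_sensitivity(self):
        ids = [f"i{k}" for k in range(50)]
        assert split_cohort(ids, 3).to_dict() == split_cohort(ids, 3).to_dict()
        assert split_cohort(ids, 3).train != split_cohort(ids, 4).train

    @pytest.mark.parametrize("n", [10, 11, 37, 100])
    def test_partition_disjoint_and_exhaustive(self, n):
        ids = [f"i{k}" for k in range(n)]
        s = split_cohort(ids, seed=5)
        parts = [set(s.train), set(s.validation), set(s.test)]
        assert sum(len(p) for p in parts) == n
        assert parts[0] | parts[1] | parts[2] == set(ids)

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            split_cohort([f"i{k}" for k in range(9)], seed=0)


class TestNormalization:
    def _fit(self, genos, speed):
        n = len(speed)
        cohort = _toy_cohort([f"i{k}" for k in range(n)], speed=speed,
                             endurance=list(np.arange(n, dtype=float)),
                             strength=list(np.arange(n, dtype=float) * 2),
                             genos=genos)
        split = gp.SplitIndex(train=list(cohort.ids), validation=[], test=[],
                              seed=0)
        return cohort, split, fit_normalizers(cohort, split)

    def test_minmax_endpoints(self):
        cohort, split, params = self._fit(
            np.array([[2.0], [4.0], [6.0]]), [1.0, 2.0, 3.0])
        from genopotential.preprocess import normalize_genotypes
        out = normalize_genotypes(cohort.genotypes, params)
        np.testing.assert_allclose(out["m0"].to_numpy(), [0.0, 0.5, 1.0])

    def test_zscore_with_sample_sd(self):
        cohort, split, params = self._fit(
            np.array([[0.0], [1.0], [2.0]]), [1.0, 2.0, 3.0])
        from genopotential.preprocess import zscore_indicators
        z = zscore_indicators(cohort.phenotypes, params)
        np.testing.assert_allclose(z["speed"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_out_of_range_value_not_clipped(self):
        cohort, split, params = self._fit(
            np.array([[2.0], [4.0], [6.0]]), [1.0, 2.0, 3.0])
        from genopotential.preprocess import normalize_genotypes
        test = pd.DataFrame({"m0": [8.0]})
        out = normalize_genotypes(test, params)
        np.testing.assert_allclose(out["m0"].to_numpy(), [1.5])

    def test_constant_train_column_maps_to_zero(self):
        cohort, split, params = self._fit(
            np.array([[3.0], [3.0], [3.0]]), [1.0, 2.0, 3.0])
        from genopotential.preprocess import normalize_genotypes
        out = normalize_genotypes(cohort.genotypes, params)
        np.testing.assert_allclose(out["m0"].to_numpy(), [0.0, 0.0, 0.0])

    def test_zero_variance_indicator_is_error(self):
        cohort = _toy_cohort(["a", "b", "c"], speed=[1.0, 1.0, 1.0],
                             endurance=[1., 2., 3.], strength=[1., 2., 3.])
        split = gp.SplitIndex(train=["a", "b", "c"], validation=[], test=[],
                              seed=0)
        with pytest.raises(ValueError, match="speed"):
            fit_normalizers(cohort, split)

    def test_invertibility(self, small_cohort):
        split = split_cohort(small_cohort.ids, seed=1)
        params = fit_normalizers(small_cohort, split)
        from genopotential.preprocess import normalize_genotypes
        normed = normalize_genotypes(small_cohort.genotypes, params)
        span = params.geno_max - params.geno_min
        back = normed * span + params.geno_min
        keep = [c for c in normed.columns if span[c] > 0]
        np.testing.assert_allclose(back[keep].to_numpy(),
                                   small_cohort.genotypes[keep].to_numpy(),
                                   atol=1e-10)

    def test_no_leakage_params_depend_on_train_only(self, small_cohort):
        split = split_cohort(small_cohort.ids, seed=1)
        params = fit_normalizers(small_cohort, split)
        mask = np.isin(small_cohort.ids, np.asarray(split.train))
        from genopotential.preprocess import _subset
        train_only = _subset(small_cohort, mask)
        split_t = gp.SplitIndex(train=list(train_only.ids), validation=[],
                                test=[], seed=1)
        refit = fit_normalizers(train_only, split_t)
        pd.testing.assert_series_equal(params.geno_min, refit.geno_min)
        pd.testing.assert_series_equal(params.indicator_mean,
                                       refit.indicator_mean)
        assert params.target_mean == refit.target_mean


class TestTarget:
    def test_worked_three_individual_example(self):
        cohort = _toy_cohort(["a", "b", "c"], speed=[1., 2., 3.],
                             endurance=[1., 2., 3.], strength=[1., 2., 3.])
        split = gp.SplitIndex(train=["a", "b", "c"], validation=[], test=[],
                              seed=0)
        params = fit_normalizers(cohort, split)
        y = build_target(cohort, params)
        np.testing.assert_allclose(y, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_individual_at_train_means_scores_zero(self, small_cohort):
        split = split_cohort(small_cohort.ids, seed=1)
        params = fit_normalizers(small_cohort, split)
        mean_row = small_cohort.copy()
        probe = _toy_cohort(["p"],
                            speed=[params.indicator_mean["speed"]],
                            endurance=[params.indicator_mean["endurance"]],
                            strength=[params.indicator_mean["strength"]])
        y = build_target(probe, params)
        np.testing.assert_allclose(y, [0.0], atol=1e-12)
        _ = mean_row

    def test_identical_indicator_columns_reduce_to_zscore(self):
        vals = [3., 5., 6., 10.]
        cohort = _toy_cohort(list("abcd"), speed=vals, endurance=vals,
                             strength=vals)
        split = gp.SplitIndex(train=list("abcd"), validation=[], test=[],
                              seed=0)
        params = fit_normalizers(cohort, split)
        y = build_target(cohort, params)
        v = np.asarray(vals)
        z = (v - v.mean()) / v.std(ddof=1)
        np.testing.assert_allclose(y, z, atol=1e-12)


class TestFeatureNoiseAndPersistence:
    def test_zero_sd_identity(self, small_dataset):
        out = inject_feature_noise(small_dataset.X, 0.0, seed=0)
        pd.testing.assert_frame_equal(out, small_dataset.X)

    def test_noise_sd_and_genotype_columns_only(self):
        X = pd.DataFrame(np.zeros((2000, 502)))
        out = inject_feature_noise(X, 0.05, seed=1, n_genotype_cols=500)
        delta = (out - X).to_numpy()
        assert abs(delta[:, :500].std() - 0.05) < 0.001
        np.testing.assert_array_equal(delta[:, 500:], 0.0)

    def test_noise_reproducible(self, small_dataset):
        a = inject_feature_noise(small_dataset.X, 0.1, seed=3,
                                 n_genotype_cols=small_dataset.n_genotype_cols)
        b = inject_feature_noise(small_dataset.X, 0.1, seed=3,
                                 n_genotype_cols=small_dataset.n_genotype_cols)
        pd.testing.assert_frame_equal(a, b)

    def test_processed_round_trip(self, small_dataset, tmp_path):
        write_processed(small_dataset, tmp_path)
        loaded = read_processed(tmp_path)
        np.testing.assert_allclose(loaded.X.to_numpy(),
                                   small_dataset.X.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(loaded.y, small_dataset.y, atol=1e-9)
        assert loaded.split.to_dict() == small_dataset.split.to_dict()
        assert loaded.n_genotype_cols == small_dataset.n_genotype_cols

    def test_feature_mode_genotype_only(self, small_cohort):
        ds = gp.preprocess_cohort(small_cohort, seed=7,
                                  features="genotype-only")
        assert ds.X.shape[1] == ds.n_genotype_cols

    def test_dataset_has_no_missing_values(self, small_dataset):
        assert not small_dataset.X.isna().any().any()
        assert np.all(np.isfinite(small_dataset.y))
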