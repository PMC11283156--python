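"""Synthetic cohort generation, cleaning filters, partitioning, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedcopd.cohort import (
    Z95,
    ClientShard,
    CohortConfig,
    CohortError,
    FeatureSpec,
    ci_to_moments,
    feature_cols,
    generate_cohort,
    partition,
    preprocess,
    read_cohort_csv,
    simulate_mean_ci,
    train_test_split_shard,
    write_cohort_csv,
)
from conftest import toy_cohort


class TestCIInversion:
    def test_published_age_interval(self):
        mean, sd = ci_to_moments(77.6, 80.0, 220)
        assert mean == pytest.approx(78.8)
        assert sd == pytest.approx(9.08, abs=0.01)

    def test_degenerate_interval(self):
        assert ci_to_moments(5.0, 5.0, 100) == (5.0, 0.0)

    def test_closed_form_inversion(self):
        mean, sd = ci_to_moments(0.0, 3.919928, 100)
        assert mean == pytest.approx(1.959964)
        assert sd == pytest.approx(10.0, rel=1e-6)

    def test_reversed_interval_rejected(self):
        with pytest.raises(CohortError):
            ci_to_moments(2.0, 1.0, 10)
        with pytest.raises(CohortError):
            ci_to_moments(1.0, 2.0, 1)

    @given(
        lo=st.floats(-100, 100),
        width=st.floats(0, 50),
        n=st.integers(2, 10_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_forward_ci_roundtrip(self, lo, width, n):
        """Moments plugged back into mean ± z·sd/√n recover the interval."""
        hi = lo + width
        mean, sd = ci_to_moments(lo, hi, n)
        half = Z95 * sd / np.sqrt(n)
        assert mean - half == pytest.approx(lo, abs=1e-9)
        assert mean + half == pytest.approx(hi, abs=1e-9)


class TestGeneration:
    def test_published_cohort_structure(self, default_cohort):
        assert len(default_cohort) == 408
        assert (default_cohort["sex"] == "male").sum() == 345
        assert (default_cohort["label"] == 0).sum() == 220
        assert (default_cohort["label"] == 1).sum() == 188
        assert len(feature_cols(default_cohort)) == 40

    def test_sex_counts_exact_per_group(self, default_cohort):
        mild = default_cohort[default_cohort["label"] == 0]
        severe = default_cohort[default_cohort["label"] == 1]
        assert (mild["sex"] == "male").sum() == 188
        assert (severe["sex"] == "male").sum() == 157

    def test_determinism(self):
        cfg = CohortConfig(seed=42)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_seed_changes_output(self):
        a = generate_cohort(CohortConfig(seed=1))
        b = generate_cohort(CohortConfig(seed=2))
        assert not a[feature_cols(a)].equals(b[feature_cols(b)])

    def test_group_means_near_ci_midpoints(self):
        """Many draws at the printed group size centre on the CI midpoint."""
        from fedcopd.cohort import draw_feature

        cfg = CohortConfig()
        rng = np.random.default_rng(3)
        for spec in cfg.features:
            for group in (0, 1):
                lo, hi = spec.ci(group)
                mid = 0.5 * (lo + hi)
                n = cfg.group_size(group)
                _, sd = ci_to_moments(lo, hi, n)
                draws = draw_feature(spec, group, n, 50_000, rng)
                # mean of 50k draws: tolerance 4 standard errors
                tol = max(4 * sd / np.sqrt(50_000), 1e-9)
                assert draws.mean() == pytest.approx(mid, abs=tol), spec.name

    def test_empirical_ci_recovery_single_feature(self):
        """Quick fidelity check: simulated CI of the mild-group age mean."""
        spec = CohortConfig().features[0]
        lo, hi = simulate_mean_ci(spec, group=0, n=220, n_replicates=2000, seed=9)
        assert lo == pytest.approx(77.6, abs=0.15)
        assert hi == pytest.approx(80.0, abs=0.15)

    def test_missingness_injection(self):
        cfg = CohortConfig(missing_rate=0.2, seed=5)
        cohort = generate_cohort(cfg)
        frac = cohort[feature_cols(cohort)].isna().mean().mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_filler_features_uninformative(self):
        """Filler columns have the same (standard normal) law in both groups."""
        cohort = generate_cohort(CohortConfig(seed=8))
        filler = feature_cols(cohort)[7:]
        for group in (0, 1):
            sub = cohort.loc[cohort["label"] == group, filler].to_numpy()
            assert abs(sub.mean()) < 0.05
            assert sub.std() == pytest.approx(1.0, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(CohortError):
            CohortConfig(n_mild=0)
        with pytest.raises(CohortError):
            CohortConfig(n_features_total=3)
        with pytest.raises(CohortError):
            CohortConfig(missing_rate=1.0)
        with pytest.raises(CohortError):
            FeatureSpec("x", (2.0, 1.0), (0.0, 1.0))

    def test_csv_roundtrip(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_mild=5, n_severe=5,
                                              male_counts={0: 3, 1: 3},
                                              missing_rate=0.1, seed=2))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        pd.testing.assert_frame_equal(cohort, back, check_dtype=False)


class TestPreprocess:
    def test_feature_above_threshold_dropped(self):
        cohort = toy_cohort(
            {"fA": [np.nan, np.nan] + [1.0] * 8, "fB": [1.0] * 10},
            labels=[0] * 5 + [1] * 5,
        )
        out = preprocess(cohort)
        assert "fA" not in out.columns
        assert len(out) == 10
        assert out.attrs["preprocess"]["n_dropped_features"] == 1

    def test_feature_at_threshold_survives_record_dropped(self):
        cohort = toy_cohort(
            {"fA": [np.nan] + [1.0] * 9, "fB": [1.0] * 10},
            labels=[0] * 5 + [1] * 5,
        )
        out = preprocess(cohort)  # 1/10 = 0.10, not > 0.10
        assert "fA" in out.columns
        assert len(out) == 9
        assert out.attrs["preprocess"]["n_dropped_records"] == 1

    def test_clean_cohort_identity(self, default_cohort):
        out = preprocess(default_cohort)
        pd.testing.assert_frame_equal(
            out, default_cohort.reset_index(drop=True)
        )

    def test_idempotent(self):
        cfg = CohortConfig(n_mild=50, n_severe=50, male_counts={0: 30, 1: 30},
                           missing_rate=0.05, seed=4)
        once = preprocess(generate_cohort(cfg))
        twice = preprocess(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_is_explicit_error(self):
        all_missing = toy_cohort({"fA": [np.nan] * 4}, labels=[0, 1, 0, 1])
        with pytest.raises(CohortError, match="feature"):
            preprocess(all_missing)
        # every record incomplete, but no feature above threshold
        spread = toy_cohort(
            {f"f{i}": [np.nan if i == j else 1.0 for j in range(20)] for i in range(20)},
            labels=[0, 1] * 10,
        )
        with pytest.raises(CohortError, match="record"):
            preprocess(spread)


class TestPartition:
    def test_equal_thirds(self, default_cohort):
        shards = partition(default_cohort, k=3, samples_per_client=136, seed=0)
        assert [len(s) for s in shards] == [136, 136, 136]

    def test_single_client_is_random_subsample(self, default_cohort):
        (shard,) = partition(default_cohort, k=1, samples_per_client=100, seed=1)
        assert len(shard) == 100
        assert set(shard["record_id"]).issubset(set(default_cohort["record_id"]))

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_for_any_seed(self, default_cohort, seed):
        shards = partition(default_cohort, k=3, samples_per_client=100, seed=seed)
        ids = [set(s["record_id"]) for s in shards]
        assert ids[0] & ids[1] == set()
        assert ids[0] & ids[2] == set()
        assert ids[1] & ids[2] == set()
        assert len(ids[0] | ids[1] | ids[2]) == 300

    def test_oversubscription_rejected(self, default_cohort):
        with pytest.raises(CohortError):
            partition(default_cohort, k=3, samples_per_client=200, seed=0)


class TestTrainTestSplit:
    @pytest.mark.parametrize(
        "n,ratio,expected",
        [(136, (7, 3), (95, 41)), (10, (5, 5), (5, 5)), (10, (9, 1), (9, 1))],
    )
    def test_split_sizes(self, default_cohort, n, ratio, expected):
        shard = default_cohort.head(n)
        cs = train_test_split_shard(shard, ratio, seed=0)
        assert (len(cs.train), len(cs.test)) == expected

    def test_disjoint_and_exhaustive(self, default_cohort):
        shard = default_cohort.head(50)
        cs = train_test_split_shard(shard, (7, 3), seed=5)
        train_ids, test_ids = set(cs.train["record_id"]), set(cs.test["record_id"])
        assert train_ids & test_ids == set()
        assert train_ids | test_ids == set(shard["record_id"])

    def test_too_small_shard_rejected(self, default_cohort):
        with pytest.raises(CohortError):
            train_test_split_shard(default_cohort.head(1), (7, 3), seed=0)

    def test_both_sides_nonempty_at_extreme_ratio(self, default_cohort):
        cs = train_test_split_shard(default_cohort.head(2), (99, 1), seed=0)
        assert len(cs.train) == 1 and len(cs.test) == 1

    def test_standardization_uses_train_statistics(self, default_cohort):
        cs = train_test_split_shard(default_cohort.head(50), (7, 3), seed=1)
        Xtr, _, Xte, _ = cs.arrays()
        np.testing.assert_allclose(Xtr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xtr.std(axis=0), 1.0, atol=1e-12)
        # test-set columns are transformed but not re-centred on themselves
        assert not np.allclose(Xte.mean(axis=0), 0.0, atol=1e-6)
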