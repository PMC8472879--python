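"""Dataset construction: capping, split modes, personalization partitions."""

import numpy as np
import pytest
from scipy import stats

from ppgbp import datasets as ds


def _pool(rng, subject_sizes: dict[str, int], length=20) -> ds.WindowSet:
    X, y, sid, off = [], [], [], []
    for subject, n in subject_sizes.items():
        X.append(rng.normal(size=(n, length, 1)))
        base = rng.uniform(90, 150)
        y.append(np.column_stack([base + rng.normal(0, 3, n),
                                  base / 2 + rng.normal(0, 2, n)]))
        sid += [subject] * n
        off += list(range(0, 875 * n, 875))
    return ds.WindowSet(X=np.concatenate(X), y=np.concatenate(y),
                        subject=np.array(sid), offset=np.array(off),
                        hr=np.full(len(sid), 70.0), snr=np.zeros(len(sid)))


class TestCap:
    def test_small_subject_untouched(self, rng):
        pool = _pool(rng, {"a": 500, "b": 100})
        capped = ds.cap_subjects(pool, cap=2000, seed=0)
        assert len(capped) == 600

    def test_large_subject_capped_exactly(self, rng):
        pool = _pool(rng, {"a": 5000, "b": 100})
        capped = ds.cap_subjects(pool, cap=2000, seed=0)
        assert (capped.subject == "a").sum() == 2000
        assert (capped.subject == "b").sum() == 100

    def test_deterministic_under_seed(self, rng):
        pool = _pool(rng, {"a": 3000})
        a = ds.cap_subjects(pool, cap=1000, seed=5)
        b = ds.cap_subjects(pool, cap=1000, seed=5)
        assert np.array_equal(a.offset, b.offset)


class TestNonMixed:
    def test_subject_disjoint_and_exhaustive(self, rng):
        pool = _pool(rng, {f"s{i}": 50 for i in range(10)})
        split = ds.split_non_mixed(pool, 6, 2, 2, seed=1)
        groups = [set(split.train.subject), set(split.val.subject),
                  set(split.test.subject)]
        assert sum(len(g) for g in groups) == 10
        assert not (groups[0] & groups[1] or groups[0] & groups[2]
                    or groups[1] & groups[2])
        assert set(split.subject_assignment.values()) <= {
            "train", "val", "test", "excluded"}

    def test_oversized_request_scaled_down_proportionally(self, rng):
        pool = _pool(rng, {f"s{i}": 30 for i in range(10)})
        with pytest.warns(UserWarning):
            split = ds.split_non_mixed(pool, 3750, 625, 625, seed=1)
        n_tr = len(set(split.train.subject))
        n_va = len(set(split.val.subject))
        assert n_tr / max(n_va, 1) == pytest.approx(3750 / 625, rel=0.5)

    def test_same_seed_identical(self, rng):
        pool = _pool(rng, {f"s{i}": 40 for i in range(8)})
        a = ds.split_non_mixed(pool, 5, 1, 2, seed=9)
        b = ds.split_non_mixed(pool, 5, 1, 2, seed=9)
        assert np.array_equal(a.train.offset, b.train.offset)
        assert set(a.test.subject) == set(b.test.subject)


class TestMixed:
    def test_fraction_arithmetic(self, rng):
        pool = _pool(rng, {f"s{i}": 60 for i in range(5)})
        split = ds.split_mixed(pool, seed=2)
        n = len(pool)
        assert len(split.train) == int(round(2 / 3 * n))
        assert len(split.train) + len(split.val) + len(split.test) == n

    def test_subjects_leak_across_partitions(self, rng):
        """Most test samples share a subject with training data."""
        pool = _pool(rng, {f"s{i}": 200 for i in range(5)})
        split = ds.split_mixed(pool, seed=3)
        train_subjects = set(split.train.subject)
        leaked = np.isin(split.test.subject, sorted(train_subjects)).mean()
        assert leaked > 0.99

    def test_same_seed_identical(self, rng):
        pool = _pool(rng, {f"s{i}": 50 for i in range(4)})
        a = ds.split_mixed(pool, seed=4)
        b = ds.split_mixed(pool, seed=4)
        assert np.array_equal(a.test.offset, b.test.offset)

    def test_mixed_and_non_mixed_label_distributions_similar(self, rng):
        pool = _pool(rng, {f"s{i}": 100 for i in range(20)})
        mixed = ds.split_mixed(pool, seed=5)
        nm = ds.split_non_mixed(pool, 13, 3, 4, seed=5)
        ks = stats.ks_2samp(mixed.train.y[:, 0], nm.train.y[:, 0])
        assert ks.statistic < 0.35


class TestPersonalization:
    def test_first20_partition_arithmetic_n100(self, rng):
        pool = _pool(rng, {"a": 100})
        part = ds.make_personalization_partition(pool, "first_20", seed=0)
        assert len(part.calibration) == 20
        assert len(part.test) == 40
        assert len(part.spare_pool) == 40
        # calibration is the temporal head, test the temporal tail
        assert part.calibration.offset.max() < part.spare_pool.offset.min()
        assert part.spare_pool.offset.max() < part.test.offset.min()

    def test_n10_sizes(self, rng):
        pool = _pool(rng, {"a": 10})
        part = ds.make_personalization_partition(pool, "first_20", seed=0)
        assert len(part.calibration) == 2
        assert len(part.test) == 4

    def test_test_set_identical_across_strategies(self, rng):
        pool = _pool(rng, {"a": 57})
        first = ds.make_personalization_partition(pool, "first_20", seed=3)
        rand = ds.make_personalization_partition(pool, "random_20", seed=3)
        assert first.test.window_ids() == rand.test.window_ids()

    def test_random20_draws_only_from_allowed_pool(self, rng):
        pool = _pool(rng, {"a": 50})
        part = ds.make_personalization_partition(pool, "random_20", seed=1)
        test_ids = part.test.window_ids()
        assert not (part.calibration.window_ids() & test_ids)

    def test_too_few_windows_errors(self, rng):
        pool = _pool(rng, {"a": 5})
        with pytest.raises(ValueError):
            ds.make_personalization_partition(pool, "first_20")


def test_split_invariants_enforced(rng):
    """Constructing an overlapping split raises immediately."""
    pool = _pool(rng, {"a": 30, "b": 30})
    half = pool.subset(np.arange(30))
    with pytest.raises(AssertionError):
        ds.DatasetSplit(mode="mixed", train=half, val=half,
                        test=pool.subset(np.arange(30, 60)))


def test_build_pool_applies_plausibility_filter():
    """Engineered out-of-range subjects contribute no windows."""
    from ppgbp import synthetic as syn
    cfg = syn.CohortConfig(n_subjects=3, seed=6, fraction_reject_material=1.0,
                           subject_size_distribution={"median_s": 100.0,
                                                      "sigma_log": 0.1},
                           min_duration_s=60.0, max_duration_s=150.0)
    cohort = syn.generate_cohort(cfg)
    from ppgbp.preprocess import WindowingConfig
    with pytest.raises(ValueError, match="nothing to concatenate"):
        ds.build_pool(cohort.records,
                      windowing=WindowingConfig("const_time", 7))
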