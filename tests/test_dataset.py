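"""Dataset assembly: z-scoring, stratified splits, averaged samples, and
the no-leakage guarantee between test folds and training samples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scenevep import dataset
from scenevep.montage import CHANNELS_17, CHANNELS_19
from tests.conftest import make_epochset


def _random_epochs(n_trials=40, seed=0, participants=("P00",), images=None):
    rng = np.random.default_rng(seed)
    if images is None:
        images = [f"img{k % 8}" for k in range(n_trials)]
    pids = [participants[k % len(participants)] for k in range(n_trials)]
    data = rng.standard_normal((n_trials, 19, 1200))
    return make_epochset(data, images, participant_ids=pids)


def _table_for(images, categories=None):
    uniq = list(dict.fromkeys(images))
    rng = np.random.default_rng(0)
    cats = categories or [f"cat{k % 4}" for k in range(len(uniq))]
    vals = rng.normal(-2, 0.5, len(uniq))
    med = np.median(vals)
    return pd.DataFrame({
        "image_id": uniq, "category": cats,
        "naturalness": [k % 2 for k in range(len(uniq))],
        "openness": [(k // 2) % 2 for k in range(len(uniq))],
        "roughness_value": vals, "roughness": (vals > med).astype(int)})


class TestZScore:
    def test_unit_moments_over_model_window(self):
        z = dataset.zscore_trials(_random_epochs())
        assert z.data.shape[1:] == (17, 500)
        assert tuple(z.channels) == CHANNELS_17
        assert np.abs(z.data.mean(axis=2)).max() < 1e-6
        assert np.abs(z.data.std(axis=2) - 1).max() < 1e-5

    def test_affine_invariance(self):
        eps = _random_epochs(n_trials=4, seed=1)
        scaled = eps.copy()
        scaled.data = (eps.data * 3.7 - 11.0).astype(np.float32)
        a = dataset.zscore_trials(eps)
        b = dataset.zscore_trials(scaled)
        assert np.allclose(a.data, b.data, atol=1e-4)

    def test_constant_trace_is_named_error(self):
        eps = _random_epochs(n_trials=3, seed=2)
        eps.data[1, 5, :] = 4.0
        with pytest.raises(ValueError, match="C4"):
            dataset.zscore_trials(eps)

    def test_rejected_trials_dropped(self):
        eps = _random_epochs(n_trials=6, seed=3)
        eps.trials.loc[2, "rejected"] = True
        z = dataset.zscore_trials(eps)
        assert z.n_trials == 5


class TestSplit:
    def test_two_per_category_five_folds(self, tiny_stimuli):
        _, table = tiny_stimuli
        plan = dataset.make_split(table, n_folds=5, seed=0)
        assert sorted(plan["image_id"]) == sorted(table["image_id"])
        assert set(plan["fold"]) <= set(range(5))
        merged = plan.merge(table, on="image_id")
        per_cat = merged.groupby(["category", "fold"]).size().unstack(fill_value=0)
        assert (per_cat.max(axis=1) - per_cat.min(axis=1) <= 1).all()
        sizes = sorted(plan.groupby("fold").size(), reverse=True)
        assert sum(sizes) == 26 and max(sizes) - min(sizes) <= 2

    def test_partition_at_full_scale(self):
        images = [f"i{k}" for k in range(232)]
        table = _table_for(images, categories=[f"c{k % 13}" for k in range(232)])
        plan = dataset.make_split(table, n_folds=5, seed=1)
        assert plan["image_id"].nunique() == 232
        assert len(plan) == 232  # each image in exactly one test fold

    def test_seeded_determinism(self, tiny_stimuli):
        _, table = tiny_stimuli
        a = dataset.make_split(table, 5, seed=7)
        b = dataset.make_split(table, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_folds_rejected(self, tiny_stimuli):
        _, table = tiny_stimuli
        with pytest.raises(ValueError):
            dataset.make_split(table, n_folds=1)


class TestTrainingSamples:
    def test_identical_trials_average_to_the_trial(self):
        eps = _random_epochs(n_trials=8, seed=4, images=["only"] * 8)
        eps.data[:] = eps.data[0]
        table = _table_for(["only"], categories=["cat0"])
        z = dataset.zscore_trials(eps)
        plan = pd.DataFrame({"image_id": ["only"], "fold": [1]})
        samples = dataset.make_training_samples(z, table, plan, 0,
                                                n_avg_range=(2, 4),
                                                n_samples=5, seed=0)
        for s in samples:
            assert np.allclose(s.data, z.data[0], atol=1e-6)

    def test_seeded_reproducibility(self):
        eps = _random_epochs(n_trials=40, seed=5)
        table = _table_for(eps.trials["image_id"])
        z = dataset.zscore_trials(eps)
        plan = dataset.make_split(table, 4, seed=0)
        kw = dict(n_avg_range=(2, 4), n_samples=20, seed=11)
        a = dataset.make_training_samples(z, table, plan, 0, **kw)
        b = dataset.make_training_samples(z, table, plan, 0, **kw)
        assert [s.trial_indices for s in a] == [s.trial_indices for s in b]
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_variance_of_mean_scales_as_one_over_k(self):
        """Averaging k i.i.d. unit-variance trials leaves ~1/k variance."""
        rng = np.random.default_rng(6)
        n_rep, k = 100, 30
        data = rng.standard_normal((n_rep * k, 19, 1200))
        eps = make_epochset(data, ["im"] * (n_rep * k))
        z = dataset.zscore_trials(eps)
        table = _table_for(["im"], categories=["c"])
        plan = pd.DataFrame({"image_id": ["im"], "fold": [1]})
        samples = dataset.make_training_samples(z, table, plan, 0,
                                                n_avg_range=(k, k),
                                                n_samples=n_rep, seed=0)
        var = np.mean([s.data.var() for s in samples])
        assert 0.8 / k < var < 1.2 / k

    def test_count_and_fold_validation(self):
        eps = _random_epochs(n_trials=24, seed=7)
        table = _table_for(eps.trials["image_id"])
        z = dataset.zscore_trials(eps)
        plan = dataset.make_split(table, 4, seed=0)
        samples = dataset.make_training_samples(z, table, plan, 0,
                                                n_avg_range=(2, 3),
                                                n_samples=37, seed=0)
        assert len(samples) == 37
        with pytest.raises(ValueError):
            dataset.make_training_samples(z, table, plan, 9, n_samples=1)

    def test_no_test_fold_leakage(self):
        """No training sample of fold f contains a trial of an image whose
        test fold is f (asserted on trial provenance)."""
        eps = _random_epochs(n_trials=48, seed=8, participants=("P00", "P01"))
        table = _table_for(eps.trials["image_id"])
        z = dataset.zscore_trials(eps)
        plan = dataset.make_split(table, 4, seed=2)
        fold_of = dict(zip(plan["image_id"], plan["fold"]))
        for fold in range(4):
            samples = dataset.make_training_samples(
                z, table, plan, fold, n_avg_range=(2, 3), n_samples=50, seed=3)
            for s in samples:
                for t in s.trial_indices:
                    assert fold_of[z.trials["image_id"].iloc[t]] != fold


class TestTestSamples:
    def test_one_sample_per_participant_image_and_deterministic(self):
        eps = _random_epochs(n_trials=48, seed=9, participants=("P00", "P01"))
        table = _table_for(eps.trials["image_id"])
        z = dataset.zscore_trials(eps)
        plan = dataset.make_split(table, 4, seed=0)
        a = dataset.make_test_samples(z, table, plan, 0)
        b = dataset.make_test_samples(z, table, plan, 0)
        n_test_images = (plan["fold"] == 0).sum()
        assert len(a) <= 2 * n_test_images
        keys = {(s.participant_id, s.image_id) for s in a}
        assert len(keys) == len(a)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_single_trial_average_is_the_trial(self):
        eps = _random_epochs(n_trials=8, seed=10,
                             images=[f"im{k}" for k in range(8)])
        table = _table_for(eps.trials["image_id"])
        z = dataset.zscore_trials(eps)
        plan = pd.DataFrame({"image_id": table["image_id"],
                             "fold": [0] * 4 + [1] * 4})
        for s in dataset.make_test_samples(z, table, plan, 0):
            (t,) = s.trial_indices
            assert np.array_equal(s.data, z.data[t])


class TestRoughnessDeviated:
    def test_extremes_selected(self):
        table = _table_for([f"i{k}" for k in range(5)])
        table["roughness_value"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = dataset.select_roughness_deviated(table, n_keep=2)
        assert sorted(out["roughness_value"]) == [1.0, 5.0]

    def test_identity_and_median_exclusion(self):
        table = _table_for([f"i{k}" for k in range(7)])
        table["roughness_value"] = np.arange(7, dtype=float)
        full = dataset.select_roughness_deviated(table, n_keep=7)
        assert len(full) == 7
        near = dataset.select_roughness_deviated(table, n_keep=6)
        assert 3.0 not in set(near["roughness_value"])  # the median image
        with pytest.raises(ValueError):
            dataset.select_roughness_deviated(table, n_keep=8)


class TestLabels:
    def test_category_codes_follow_canonical_order(self, tiny_stimuli):
        _, table = tiny_stimuli
        codes, names = dataset.encode_labels(table, "category")
        assert len(names) == 13
        assert set(codes.values()) == set(range(13))

    def test_binary_labels_passthrough(self, tiny_stimuli):
        _, table = tiny_stimuli
        for kind in ("naturalness", "openness", "roughness"):
            codes, names = dataset.encode_labels(table, kind)
            assert names == ["0", "1"]
            assert set(codes.values()) <= {0, 1}
        with pytest.raises(ValueError):
            dataset.encode_labels(table, "color")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_zscore_moments_property(seed):
    """Any nondegenerate trial set z-scores to unit moments."""
    rng = np.random.default_rng(seed)
    data = rng.normal(rng.normal(0, 10), 1 + rng.random() * 5, (2, 19, 1200))
    eps = make_epochset(data, ["a", "b"])
    z = dataset.zscore_trials(eps)
    assert np.abs(z.data.mean(axis=2)).max() < 1e-6
    assert np.abs(z.data.std(axis=2) - 1).max() < 1e-5
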