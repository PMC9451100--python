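import numpy as np
import pytest

from toxmlpath.datamodel import MultiLabelDataset, ValidationError
from toxmlpath.mlsmote import MlsmoteConfig, imbalance_profile, mlsmote_augment

from conftest import random_dataset


def _dataset(X, Y):
    n, dim = X.shape
    return MultiLabelDataset(X, Y, [f"g{i}" for i in range(dim)],
                             [f"l{i}" for i in range(Y.shape[1])],
                             [f"s{i}" for i in range(n)])


class TestImbalanceProfile:
    def test_balanced_counts(self):
        Y = np.zeros((20, 2), dtype=int)
        Y[:10, 0] = 1
        Y[10:, 1] = 1
        prof = imbalance_profile(Y)
        np.testing.assert_array_equal(prof.irlbl, [1.0, 1.0])
        assert prof.mean_ir == 1.0

    def test_hand_computed_ratio(self):
        Y = np.zeros((10, 2), dtype=int)
        Y[:8, 0] = 1
        Y[:2, 1] = 1
        prof = imbalance_profile(Y)
        np.testing.assert_array_equal(prof.irlbl, [1.0, 4.0])
        assert prof.mean_ir == 2.5

    def test_zero_count_label_flagged_infinite_and_excluded(self):
        Y = np.zeros((6, 2), dtype=int)
        Y[:6, 0] = 1
        prof = imbalance_profile(Y)
        assert np.isinf(prof.irlbl[1])
        assert prof.mean_ir == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            imbalance_profile(np.zeros((4, 3), dtype=int))


class TestMlsmoteAugment:
    def test_balanced_dataset_returned_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        Y = np.zeros((10, 2), dtype=int)
        Y[:5, 0] = 1
        Y[5:, 1] = 1
        ds = _dataset(X, Y)
        out, prov = mlsmote_augment(ds, MlsmoteConfig(seed=0))
        assert out.n == ds.n
        assert prov == []

    def test_shared_label_bag_propagates_label(self, rng):
        # all members of label 0's bag carry label 0 -> every synthetic does
        X = rng.normal(size=(12, 3))
        Y = np.zeros((12, 3), dtype=int)
        Y[:4, 0] = 1
        Y[:, 1] = 1  # majority label
        Y[4:6, 2] = 1
        ds = _dataset(X, Y)
        out, prov = mlsmote_augment(ds, MlsmoteConfig(seed=0, max_rounds=1))
        synth = out.labels[out.synthetic]
        from_label0 = [p.triggering_label == 0 for p in prov]
        assert synth[np.array(from_label0), 0].all()

    def test_seed_determinism(self, rng):
        ds = random_dataset(rng, n=25, dim=4, L=5,
                            prevalences=[0.6, 0.3, 0.2, 0.1, 0.1])
        out1, p1 = mlsmote_augment(ds, MlsmoteConfig(seed=3))
        out2, p2 = mlsmote_augment(ds, MlsmoteConfig(seed=3))
        np.testing.assert_array_equal(out1.features, out2.features)
        np.testing.assert_array_equal(out1.labels, out2.labels)
        assert p1 == p2

    def test_zero_label_guard_fires_on_adversarial_vote(self):
        # voters disagreeing on every label, none reaching strict majority:
        # the ranking yields all-zero and the guard forces the triggering label
        from toxmlpath.mlsmote import apply_zero_label_guard, majority_vote_labels

        voters = np.array([
            [1, 0, 0, 1, 0],
            [0, 1, 0, 0, 1],
            [0, 0, 1, 0, 0],
            [1, 0, 0, 0, 1],
        ])  # every column has at most 2 of 4 votes -> no strict majority
        vote = majority_vote_labels(voters)
        assert vote.sum() == 0
        labels, fired = apply_zero_label_guard(vote, triggering_label=2)
        assert fired
        assert labels[2] == 1 and labels.sum() == 1

    def test_guard_untouched_when_vote_nonzero(self):
        from toxmlpath.mlsmote import apply_zero_label_guard, majority_vote_labels

        voters = np.array([[1, 0], [1, 0], [1, 1]])
        vote = majority_vote_labels(voters)
        np.testing.assert_array_equal(vote, [1, 0])
        labels, fired = apply_zero_label_guard(vote, triggering_label=1)
        assert not fired
        np.testing.assert_array_equal(labels, vote)

    def test_bag_voting_always_carries_triggering_label(self, rng):
        # every voter comes from the triggering label's own positive bag,
        # so the vote always sets that label and the guard stays dormant
        ds = random_dataset(rng, n=40, dim=4, L=6,
                            prevalences=[0.6, 0.4, 0.2, 0.1, 0.08, 0.05])
        out, prov = mlsmote_augment(ds, MlsmoteConfig(seed=9))
        assert prov, "expected synthetic samples"
        for i, p in enumerate(prov):
            assert out.labels[ds.n + i, p.triggering_label] == 1
            assert not p.guard_fired

    def test_mean_ir_never_increases(self, rng):
        for trial in range(25):
            ds = random_dataset(rng, n=40, dim=5, L=6,
                                prevalences=rng.uniform(0.05, 0.6, 6))
            before = imbalance_profile(ds.labels).mean_ir
            out, _ = mlsmote_augment(ds, MlsmoteConfig(seed=trial))
            after = imbalance_profile(out.labels).mean_ir
            assert after <= before + 1e-12

    def test_no_all_zero_synthetic_labels(self, rng):
        for trial in range(20):
            ds = random_dataset(rng, n=30, dim=4, L=5,
                                prevalences=rng.uniform(0.05, 0.5, 5))
            out, _ = mlsmote_augment(ds, MlsmoteConfig(seed=trial))
            synth = out.labels[out.synthetic]
            if len(synth):
                assert (synth.sum(axis=1) >= 1).all()

    def test_synthetic_points_on_seed_neighbor_segment(self, rng):
        ds = random_dataset(rng, n=30, dim=4, L=5,
                            prevalences=[0.6, 0.3, 0.15, 0.1, 0.08])
        out, prov = mlsmote_augment(ds, MlsmoteConfig(seed=5))
        for i, p in enumerate(prov):
            row = out.features[ds.n + i]
            seed_f = out.features[p.seed_index]
            neigh_f = out.features[p.neighbor_index]
            expected = seed_f + p.u * (neigh_f - seed_f)
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_originals_preserved_verbatim(self, rng):
        ds = random_dataset(rng, n=30, dim=4, L=5,
                            prevalences=[0.6, 0.3, 0.15, 0.1, 0.08])
        out, _ = mlsmote_augment(ds, MlsmoteConfig(seed=5))
        np.testing.assert_array_equal(out.features[: ds.n], ds.features)
        np.testing.assert_array_equal(out.labels[: ds.n], ds.labels)
        assert not out.synthetic[: ds.n].any()
        assert out.synthetic[ds.n:].all()

    def test_redraw_guard_mode_also_avoids_zero_vectors(self, rng):
        ds = random_dataset(rng, n=30, dim=4, L=5,
                            prevalences=[0.6, 0.3, 0.15, 0.1, 0.08])
        out, prov = mlsmote_augment(ds, MlsmoteConfig(seed=2, guard="redraw"))
        synth = out.labels[out.synthetic]
        if len(synth):
            assert (synth.sum(axis=1) >= 1).all()
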