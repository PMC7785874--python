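"""Dice loss, patch samplers, the training loop contract, and ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raunet.cascade import BoundaryBox
from raunet.errors import (
    ConfigurationError,
    DegenerateVolumeError,
    ShapeError,
    TrainingDivergedError,
)
from raunet.ndnn import Tensor
from raunet.network import NetworkSpec, build_raunet1
from raunet.preprocessing import Volume
from raunet.training import (
    PatchPair,
    TrainConfig,
    dice_loss,
    ensemble_predict,
    kfold_split,
    liver_patch_spec,
    sample_liver_patches,
    sample_liver_slices,
    sample_tumor_patches,
    train,
    tumor_patch_spec,
)


class TestDiceLoss:
    def test_perfect_match_is_zero(self):
        g = np.array([1.0, 0.0, 1.0, 1.0])
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-4)

    def test_disjoint_masks_give_one(self):
        s = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([0.0, 0.0, 1.0, 1.0])
        assert dice_loss(s, g) == pytest.approx(1.0, abs=1e-4)

    def test_four_voxel_half_overlap(self):
        s = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(s, g) == pytest.approx(0.5, abs=1e-4)

    def test_empty_empty_defined_by_smoothing(self):
        z = np.zeros(8)
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-6)

    def test_tensor_and_array_paths_agree(self, rng):
        s = rng.uniform(size=(2, 3, 4)).astype(np.float32)
        g = (rng.uniform(size=(2, 3, 4)) > 0.5).astype(np.float32)
        t = dice_loss(Tensor(s), g)
        assert t.item() == pytest.approx(dice_loss(s, g), abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            dice_loss(np.zeros(3), np.zeros(4))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=2, max_size=24))
    def test_binary_symmetry_and_range(self, bits):
        s = np.array(bits, dtype=float)
        g = np.roll(s, 1)
        a, b = dice_loss(s, g), dice_loss(g, s)
        assert a == pytest.approx(b)
        assert -1e-6 <= a <= 1.0 + 1e-6

    def test_flipping_a_wrong_voxel_toward_truth_decreases_loss(self, rng):
        g = (rng.uniform(size=32) > 0.5).astype(float)
        s = g.copy()
        wrong = 3
        s[wrong] = 1.0 - g[wrong]
        worse = dice_loss(s, g)
        s[wrong] = g[wrong]
        assert dice_loss(s, g) < worse

    def test_gradient_flows_through_tensor_path(self):
        s = Tensor(np.array([0.4, 0.6, 0.2], dtype=np.float32), requires_grad=True)
        loss = dice_loss(s, np.array([1.0, 1.0, 0.0]))
        loss.backward()
        assert s.grad is not None and np.isfinite(s.grad).all()


@pytest.fixture(scope="module")
def sampled(preprocessed_case, liver_box):
    vol, liver, _ = preprocessed_case
    spec = liver_patch_spec(count_per_volume=6, shape=(64, 64, 16))
    return sample_liver_patches(vol, liver, liver_box, spec, seed=77)


class TestLiverPatchSampling:
    def test_every_patch_has_spec_shape(self, sampled):
        for p in sampled:
            assert p.image.shape == (64, 64, 16, 1)
            assert p.label.shape == (64, 64, 16, 1)

    def test_labels_are_binary(self, sampled):
        for p in sampled:
            assert set(np.unique(p.label)) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, preprocessed_case, liver_box):
        vol, liver, _ = preprocessed_case
        spec = liver_patch_spec(count_per_volume=3, shape=(64, 64, 16))
        a = sample_liver_patches(vol, liver, liver_box, spec, seed=5)
        b = sample_liver_patches(vol, liver, liver_box, spec, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)

    def test_patches_come_from_inside_the_box(self, preprocessed_case, liver_box):
        # sentinel: voxels outside the box are set to -1, which can never
        # appear in a patch cut from the box region
        vol, liver, _ = preprocessed_case
        marked = np.full(vol.data.shape, -1.0, dtype=np.float32)
        marked[liver_box.slices()] = vol.data[liver_box.slices()]
        mv = Volume(marked, vol.spacing, vol.affine)
        spec = liver_patch_spec(count_per_volume=4, shape=(64, 64, 16))
        for p in sample_liver_patches(mv, liver, liver_box, spec, seed=3):
            assert p.image.min() >= 0.0

    def test_thin_box_is_padded_and_masked(self, preprocessed_case):
        vol, liver, _ = preprocessed_case
        thin = BoundaryBox(30, 120, 30, 120, 20, 27)  # 8 axial slices
        spec = liver_patch_spec(count_per_volume=2, shape=(64, 64, 16))
        patches = sample_liver_patches(vol, liver, thin, spec, seed=1)
        for p in patches:
            assert p.image.shape == (64, 64, 16, 1)
            assert p.loss_mask is not None
            assert p.loss_mask[:, :, 8:].max() == 0.0  # padding masked out


class TestTumorPatchSampling:
    def test_default_count_is_150(self, preprocessed_case):
        vol, liver, tumor = preprocessed_case
        spec = tumor_patch_spec(shape=(32, 32, 8))
        patches = sample_tumor_patches(vol, liver, tumor, spec, seed=9)
        assert len(patches) == 150

    def test_at_least_one_patch_contains_tumor(self, preprocessed_case):
        vol, liver, tumor = preprocessed_case
        spec = tumor_patch_spec(count_per_volume=10, shape=(32, 32, 8))
        patches = sample_tumor_patches(vol, liver, tumor, spec, seed=9)
        assert any(p.label.sum() > 0 for p in patches)

    def test_balanced_sampling_centers_half_on_tumor(self, preprocessed_case):
        vol, liver, tumor = preprocessed_case
        spec = tumor_patch_spec(count_per_volume=10, shape=(33, 33, 9))
        patches = sample_tumor_patches(vol, liver, tumor, spec, seed=9)
        # odd patch sizes keep the center voxel at index shape//2 after clipping
        center_hits = sum(int(p.label[16, 16, 4, 0]) for p in patches[:5])
        assert center_hits >= 4  # tumor-drawn centers, modulo boundary clipping

    def test_tumor_free_liver_yields_tumor_free_patches(self, preprocessed_case):
        vol, liver, _ = preprocessed_case
        no_tumor = np.zeros_like(liver)
        spec = tumor_patch_spec(count_per_volume=8, shape=(32, 32, 8))
        patches = sample_tumor_patches(vol, liver, no_tumor, spec, seed=2)
        assert len(patches) == 8
        assert all(p.label.sum() == 0 for p in patches)

    def test_empty_liver_rejected(self, preprocessed_case):
        vol, liver, tumor = preprocessed_case
        with pytest.raises(DegenerateVolumeError):
            sample_tumor_patches(vol, np.zeros_like(liver), tumor,
                                 tumor_patch_spec(count_per_volume=4), seed=0)


class TestSliceSampling:
    def test_positive_and_negative_slice_mix(self, preprocessed_case):
        vol, liver, _ = preprocessed_case
        samples = sample_liver_slices(vol, liver, seed=4, size=64)
        n_pos = int(liver.any(axis=(0, 1)).sum())
        assert len(samples) == n_pos + round(n_pos / 3)
        assert all(s.image.shape == (64, 64, 1) for s in samples)
        assert sum(s.label.max() == 0 for s in samples) == round(n_pos / 3)


class TestTrainLoop:
    @staticmethod
    def _slice_patches(rng, n=4):
        patches = []
        for _ in range(n):
            img = rng.uniform(size=(32, 32, 1)).astype(np.float32)
            lbl = (img > 0.5).astype(np.float32)
            patches.append(PatchPair(image=img, label=lbl))
        return patches

    def test_same_seed_gives_identical_history(self, rng):
        patches = self._slice_patches(rng)
        histories = []
        for _ in range(2):
            model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2, seed=8))
            _, h = train(model, patches, TrainConfig(epochs=2, batch_size=2, seed=8))
            histories.append(h)
        assert histories[0].equals(histories[1])

    def test_history_schema_and_lr_column(self, rng):
        model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2, seed=8))
        _, h = train(model, self._slice_patches(rng), TrainConfig(epochs=2, seed=1))
        assert list(h.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        assert (h.lr == 0.001).all()

    def test_non_finite_loss_aborts(self, rng):
        model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2, seed=8))
        bad = [PatchPair(image=np.full((32, 32, 1), np.nan, dtype=np.float32),
                         label=np.zeros((32, 32, 1), dtype=np.float32))]
        with pytest.raises(TrainingDivergedError):
            train(model, bad, TrainConfig(epochs=1, seed=0))

    def test_empty_patch_set_rejected(self):
        model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2))
        with pytest.raises(ConfigurationError):
            train(model, [], TrainConfig(epochs=1))


class TestEnsemble:
    def test_single_model_identity(self, rng):
        model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2, seed=0))
        x = rng.uniform(size=(32, 32)).astype(np.float32)
        solo = ensemble_predict([model], x)
        np.testing.assert_array_equal(solo, ensemble_predict([model, model], x))

    def test_mean_matches_member_average(self, rng):
        models = [build_raunet1(NetworkSpec(dimensionality=2, base_channels=2, seed=s))
                  for s in (1, 2, 3)]
        x = rng.uniform(size=(32, 32)).astype(np.float32)
        members = [ensemble_predict([m], x) for m in models]
        fused = ensemble_predict(models, x)
        np.testing.assert_allclose(fused, np.mean(members, axis=0), atol=1e-6)
        assert fused.min() >= 0.0 and fused.max() <= 1.0

    def test_mismatched_specs_rejected(self):
        a = build_raunet1(NetworkSpec(dimensionality=2, base_channels=2))
        b = build_raunet1(NetworkSpec(dimensionality=2, base_channels=4))
        with pytest.raises(ConfigurationError):
            ensemble_predict([a, b], np.zeros((32, 32), dtype=np.float32))

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ConfigurationError):
            ensemble_predict([], np.zeros((32, 32)))


class TestKFold:
    def test_partition_and_stratification(self):
        has_tumor = [True] * 10 + [False] * 5
        splits = kfold_split(has_tumor, folds=5, seed=3)
        assert len(splits) == 5
        all_val = sorted(i for _, val in splits for i in val)
        assert all_val == list(range(15))
        for _, val in splits:
            assert sum(has_tumor[i] for i in val) == 2  # 10 tumor cases / 5 folds
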