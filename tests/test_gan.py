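"""Joint CycleGAN + classifier: loss bookkeeping, determinism, and the
difference-image contracts. Training runs here are deliberately tiny."""

import numpy as np
import pytest

from angiograde import nn
from angiograde.frames import AngioFrame, Grade, Phase
from angiograde.gan import (
    DifferenceImage,
    GanBundle,
    TrainConfig,
    classify_grade,
    difference_image,
    fake_normal,
    loss_components,
    train_joint,
    _build_bundle,
    _to_batch,
)
from angiograde.synth import generate_dataset


def _frames(eyes):
    return [f for e in eyes for f in (e.early, e.late)]


@pytest.fixture(scope="module")
def tiny_eyes():
    return generate_dataset(3, 3, 3, seed=55, image_size=32)


@pytest.fixture(scope="module")
def tiny_bundle(tiny_eyes):
    cfg = TrainConfig(image_size=32, epochs=2, batch_size=3, n_blocks=2,
                      clf_finetune_epochs=3)
    return train_joint(_frames(tiny_eyes), cfg, seed=11)


class TestTrainConfig:
    def test_invalid_values(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lambda_cyc=-1)
        with pytest.raises(ValueError):
            TrainConfig(adv_mode="wasserstein")


class TestTrainJoint:
    def test_losses_finite_and_generator_loss_decreases(self, tiny_bundle):
        trace = tiny_bundle.loss_trace
        for entry in trace:
            assert all(np.isfinite(v) for v in entry.values())
        assert trace[-1]["gen_total"] < trace[0]["gen_total"]

    def test_missing_domain_rejected(self, tiny_eyes):
        abnormal_only = [e.early for e in tiny_eyes if e.grade is not Grade.NORMAL]
        with pytest.raises(ValueError, match="domain"):
            train_joint(abnormal_only, TrainConfig(image_size=32, epochs=1), seed=0)

    def test_seeded_determinism(self, tiny_eyes):
        cfg = TrainConfig(image_size=32, epochs=1, batch_size=3, n_blocks=2,
                          clf_finetune_epochs=1)
        b1 = train_joint(_frames(tiny_eyes), cfg, seed=3)
        b2 = train_joint(_frames(tiny_eyes), cfg, seed=3)
        assert b1.loss_trace == b2.loss_trace
        np.testing.assert_array_equal(
            b1.g_x.state_dict()["0.W"], b2.g_x.state_dict()["0.W"]
        )

    def test_objective_decomposes_into_independent_terms(self, tiny_eyes):
        """With the classification weight removed, the joint objective equals
        the sum of separately computed adversarial + cycle (+ identity)
        terms."""
        cfg = TrainConfig(image_size=32, lambda_cls=0.0, n_blocks=2)
        bundle = _build_bundle(cfg, seed=2)
        x = _to_batch([e.early for e in tiny_eyes if e.grade is Grade.NORMAL], 32)
        y = _to_batch([e.early for e in tiny_eyes if e.grade is not Grade.NORMAL], 32)
        comp = loss_components(bundle, x, y, np.zeros(len(x), int), np.ones(len(y), int))
        # independent recomputation from the raw networks
        fake_x, _ = bundle.g_x.forward(y)
        fake_y, _ = bundle.g_y.forward(x)
        adv = (
            nn.mse_loss(bundle.d_x.forward(fake_x)[0], 1.0)[0]
            + nn.mse_loss(bundle.d_y.forward(fake_y)[0], 1.0)[0]
        )
        cyc = (
            nn.l1_loss(bundle.g_y.forward(fake_x)[0], y)[0]
            + nn.l1_loss(bundle.g_x.forward(fake_y)[0], x)[0]
        )
        ident = (
            nn.l1_loss(bundle.g_x.forward(x)[0], x)[0]
            + nn.l1_loss(bundle.g_y.forward(y)[0], y)[0]
        )
        assert comp["cls"] == 0.0
        assert comp["gen_total"] == pytest.approx(
            adv + cfg.lambda_cyc * cyc + cfg.lambda_id * ident, rel=1e-6
        )


class TestFakeNormal:
    def test_shape_and_range(self, tiny_bundle, tiny_eyes):
        out = fake_normal(tiny_bundle, tiny_eyes[0].early)
        assert out.image.shape == tiny_eyes[0].early.image.shape
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_resamples_other_sizes(self, tiny_bundle):
        frame = AngioFrame(image=np.random.default_rng(0).random((48, 48)), phase=Phase.EARLY)
        out = fake_normal(tiny_bundle, frame)
        assert out.image.shape == (48, 48)

    def test_untrained_bundle_rejected(self):
        bundle = _build_bundle(TrainConfig(image_size=32, n_blocks=2), seed=0)
        frame = AngioFrame(image=np.zeros((32, 32)), phase=Phase.EARLY)
        with pytest.raises(ValueError, match="untrained"):
            fake_normal(bundle, frame)


class TestDifferenceImage:
    def test_identical_frames_zero(self, tiny_eyes):
        d = difference_image(tiny_eyes[0].early, tiny_eyes[0].early)
        assert not d.values.any()

    def test_oracle_twin_recovers_planted_blob(self, pdr_eye):
        d = difference_image(pdr_eye.late, pdr_eye.late_clean)
        lkm = pdr_eye.truth_masks.leakage
        np.testing.assert_allclose(
            d.values[~lkm & ~pdr_eye.truth_masks.nonperfusion], 0.0, atol=1e-6
        )
        assert d.values[lkm].mean() > 0.1

    def test_antisymmetry(self, tiny_eyes):
        a, b = tiny_eyes[0].early, tiny_eyes[1].early
        np.testing.assert_array_equal(
            difference_image(a, b).values, -difference_image(b, a).values
        )

    def test_shape_mismatch(self, tiny_eyes):
        small = AngioFrame(image=np.zeros((8, 8)), phase=Phase.LATE)
        with pytest.raises(ValueError):
            difference_image(tiny_eyes[0].late, small)


class TestClassifyGrade:
    def test_probabilities_sum_to_one(self, tiny_bundle, tiny_eyes):
        p = classify_grade(tiny_bundle, tiny_eyes[0].early)
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert (p >= 0).all()

    def test_deterministic(self, tiny_bundle, tiny_eyes):
        p1 = classify_grade(tiny_bundle, tiny_eyes[4].late)
        p2 = classify_grade(tiny_bundle, tiny_eyes[4].late)
        np.testing.assert_array_equal(p1, p2)


class TestBundleSerialization:
    def test_round_trip_bit_exact(self, tiny_bundle, tiny_eyes, tmp_path):
        path = tmp_path / "bundle.zip"
        tiny_bundle.save(path)
        again = GanBundle.load(path)
        for name in GanBundle._NETS:
            s1 = getattr(tiny_bundle, name).state_dict()
            s2 = getattr(again, name).state_dict()
            assert set(s1) == set(s2)
            for k in s1:
                np.testing.assert_array_equal(s1[k], s2[k])
        p1 = classify_grade(tiny_bundle, tiny_eyes[0].early)
        p2 = classify_grade(again, tiny_eyes[0].early)
        np.testing.assert_array_equal(p1, p2)
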