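import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfdiff.diffusion import (
    DiffTrainConfig,
    condition_features,
    cosine_schedule,
    cycle_splits,
    ddim_step,
    forward_diffuse,
    make_subsequence,
    sample,
    train_diffusion,
    training_loss,
    PatchDenoiser,
)
from sfdiff.fixtures import ShapeSpec, binarize_pairs, make_dataset, make_shape


@pytest.fixture(scope="module")
def schedule():
    return cosine_schedule(800)


class TestCosineSchedule:
    def test_abar_monotone_and_bounded(self, schedule):
        ab = schedule.alpha_bar
        assert len(ab) == 800
        assert np.all(np.diff(ab) < 0)
        assert ab[0] >= 0.99
        assert ab[-1] <= 0.01

    def test_alphas_ordered_and_in_unit_interval(self, schedule):
        a = schedule.alphas
        assert np.all((a > 0) & (a < 1))
        # non-increasing in t (clipping produces ties at the 0.999 cap)
        assert np.all(np.diff(a) <= 1e-12)

    def test_cumulative_product_identity(self, schedule):
        """abar_t equals the brute-force running product of the alphas."""
        prod = 1.0
        for t in range(1, 801):
            prod *= schedule.alphas[t - 1]
            assert abs(prod - schedule.alpha_bar[t - 1]) < 1e-10

    def test_boundary_abar0_is_one(self, schedule):
        assert schedule.alpha_bar_at(0) == 1.0

    def test_T_too_small(self):
        with pytest.raises(ValueError):
            cosine_schedule(1)


class TestSubsequence:
    def test_uniform_stride_80_of_800(self, schedule):
        ss = make_subsequence(schedule, 80)
        assert len(ss) == 80
        assert np.array_equal(ss.tau, np.arange(10, 801, 10))

    def test_identity_when_S_equals_T(self):
        ss = make_subsequence(20, 20)
        assert np.array_equal(ss.tau, np.arange(1, 21))

    def test_non_divisible_lengths(self):
        ss = make_subsequence(10, 3)
        assert np.all(np.diff(ss.tau) > 0)
        assert ss.tau[-1] == 10
        assert np.all((ss.tau >= 1) & (ss.tau <= 10))

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            make_subsequence(10, 0)


class TestForwardDiffuse:
    def test_limits(self, schedule):
        rng = np.random.default_rng(0)
        x0 = rng.uniform(-1, 1, (16, 16))
        eps = rng.standard_normal((16, 16))
        # t = 1: abar ~ 1 -> x_t ~ x0;  t = T: abar ~ 0 -> x_t ~ eps
        assert np.allclose(forward_diffuse(x0, eps, 1, schedule), x0,
                           atol=0.15)
        assert np.allclose(forward_diffuse(x0, eps, 800, schedule), eps,
                           atol=1e-3)

    def test_variance_preserved_for_unit_variance_input(self, schedule):
        """Var(x_t) = 1 for unit-variance signal and noise, any t
        (Monte-Carlo over ~1e5 pixels)."""
        rng = np.random.default_rng(1)
        for t in (100, 400, 700):
            x0 = rng.standard_normal((320, 320))
            eps = rng.standard_normal((320, 320))
            assert abs(forward_diffuse(x0, eps, t, schedule).var() - 1.0) \
                < 0.02

    def test_t_out_of_range(self, schedule):
        x = np.zeros((4, 4))
        with pytest.raises(ValueError):
            forward_diffuse(x, x, 0, schedule)
        with pytest.raises(ValueError):
            forward_diffuse(x, x, 801, schedule)


class _FixedNoise:
    def __init__(self, eps):
        self.eps = eps

    def predict_noise(self, x_t, cond, t):
        return self.eps


class TestTrainingLoss:
    def test_oracle_model_zero_loss(self, schedule):
        rng = np.random.default_rng(2)
        x0 = rng.uniform(-1, 1, (16, 16))
        eps = rng.standard_normal((16, 16))
        L = training_loss(_FixedNoise(eps), x0, None, 300, eps, schedule)
        assert L < 1e-20

    def test_zero_model_scores_noise_power(self, schedule):
        rng = np.random.default_rng(3)
        x0 = rng.uniform(-1, 1, (128, 128))
        eps = rng.standard_normal((128, 128))
        L = training_loss(_FixedNoise(np.zeros((128, 128))), x0, None, 300,
                          eps, schedule)
        assert abs(L - 1.0) < 0.05
        assert L >= 0


class TestDdim:
    @pytest.mark.parametrize("length_S", [80, 40, 13, 800])
    def test_inversion_with_true_noise(self, schedule, length_S):
        """Supplying the true noise as the prediction makes the reverse
        trajectory land exactly on x0, for any valid sub-sequence."""
        rng = np.random.default_rng(4)
        x0 = rng.uniform(-1, 1, (64, 64))
        eps = rng.standard_normal((64, 64))
        taus = make_subsequence(schedule, length_S).tau
        x = forward_diffuse(x0, eps, int(taus[-1]), schedule)
        prevs = np.concatenate([[0], taus[:-1]])
        for tc, tp in zip(taus[::-1], prevs[::-1]):
            x = ddim_step(x, eps, schedule, int(tc), int(tp))
        assert np.max(np.abs(x - x0)) <= 1e-6

    def test_step_to_abar_one_returns_x0hat(self, schedule):
        rng = np.random.default_rng(5)
        x0 = rng.uniform(-1, 1, (8, 8))
        eps = rng.standard_normal((8, 8))
        x_t = forward_diffuse(x0, eps, 500, schedule)
        out = ddim_step(x_t, eps, schedule, 500, 0)
        assert np.allclose(out, x0, atol=1e-12)

    def test_linearity_zero_in_zero_out(self, schedule):
        z = np.zeros((8, 8))
        assert np.allclose(ddim_step(z, z, schedule, 400, 200), 0.0)


@pytest.fixture(scope="module")
def sampling_setup():
    sch = cosine_schedule(800)
    ss = make_subsequence(sch, 20)
    cell = make_shape(ShapeSpec(kind="ellipse", aspect_ratio=2.0,
                                area=400.0, resolution=32,
                                pixel_size=2.2))
    den = PatchDenoiser(5, (16,), sch, seed=0)
    return den, cell, sch, ss


class TestSample:
    def test_seeded_determinism(self, sampling_setup):
        setup = sampling_setup
        den, cell, sch, ss = setup
        a = sample(den, cell, sch, ss, seed=3)
        b = sample(den, cell, sch, ss, seed=3)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self, sampling_setup):
        setup = sampling_setup
        den, cell, sch, ss = setup
        a = sample(den, cell, sch, ss, seed=3)
        b = sample(den, cell, sch, ss, seed=4)
        assert not np.array_equal(a, b)


class TestTrainDiffusion:
    def test_thirteen_cycle_split_protocol(self):
        splits = cycle_splits(1293, 13, 100, seed=1)
        test_sizes = [len(t) for _, t in splits]
        assert test_sizes == [100] * 12 + [93]
        all_test = np.concatenate([t for _, t in splits])
        assert len(np.unique(all_test)) == 1293
        for train, test in splits:
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 1293

    def test_seeded_training_reproducible(self):
        pairs = binarize_pairs(
            make_dataset(8, shape_ranges={"resolution": 48,
                                          "pixel_size": 2.2,
                                          "area": (900.0, 1200.0)}, seed=3)
        )
        cfg = DiffTrainConfig(epochs=3, batch_size=4, pixels_per_image=64,
                              hidden=(16,), prior_epochs=2, seed=5)
        a = train_diffusion(pairs, cfg)
        b = train_diffusion(pairs, cfg)
        assert np.allclose(a.loss_history, b.loss_history)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_diffusion([])


class TestGenerationStatistics:
    def test_foreground_fraction_near_training_statistic(self, tiny_model,
                                                         tiny_pairs):
        """Generated foreground mass stays within +/-50% of the training-set
        mean foreground fraction."""
        train_frac = np.mean(
            [(np.asarray(p.sf_image.data) >= 128).mean()
             for p in tiny_pairs[:190]]
        )
        gen = []
        for j, p in enumerate(tiny_pairs[190:192]):
            for i in range(8):
                img = tiny_model.generate(p.mask, seed=4000 + 100 * j + i)
                gen.append((img.data >= 128).mean())
        assert 0.5 * train_frac <= np.mean(gen) <= 1.5 * train_frac
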