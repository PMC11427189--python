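"""Single-step environment: observation matrix, reward, bookkeeping."""

import numpy as np
import pytest

import saoslo as s
from saoslo import aberrations as ab
from saoslo import presets
from saoslo.env import SAOEnv


@pytest.fixture(scope="module")
def env3(small_system):
    return presets.scaled_down_env(small_system, seed=0)


def _zero_sample(n_target=3):
    return ab.AberrationSample(
        target_coeffs=np.zeros(n_target), noise_coeffs=np.zeros(13),
        target_indices=tuple(range(4, 4 + n_target)))


def test_full_scale_observation_shape(default_system):
    env = SAOEnv(default_system, "train_uniform", bias=0.5, seed=1)
    obs = env.reset()
    assert obs.shape == (25, 13)  # 2*12+1 observations, metric + 12 codes


def test_observation_matrix_invariants(env3):
    """Across many episodes: metric column normalised to max 1, exactly one
    unbiased row, one nonzero probe code elsewhere, stable row order."""
    for seed in range(60):
        obs = env3.reset(np.random.default_rng(seed))
        metrics, codes = obs[:, 0], obs[:, 1:]
        assert obs.shape == (7, 4)
        assert metrics.max() == 1.0
        assert np.all(metrics >= 0)
        nonzero_per_row = np.count_nonzero(codes, axis=1)
        assert nonzero_per_row[0] == 0
        assert np.all(nonzero_per_row[1:] == 1)
        # fixed order: mode p probed at rows 2p+1 (-b) and 2p+2 (+b)
        for p in range(3):
            assert codes[2 * p + 1, p] == -1.0
            assert codes[2 * p + 2, p] == +1.0


def test_probe_symmetry_at_zero_aberration(env3):
    """With a flat hidden wavefront the -b and +b rows are equal."""
    obs = env3.observe(_zero_sample())
    metrics = obs[:, 0]
    for p in range(3):
        a, b = metrics[2 * p + 1], metrics[2 * p + 2]
        assert abs(a - b) <= 1e-9 * max(a, b)


def test_perfect_correction_reward(env3):
    """Cancelling the target aberration exactly (no higher-order noise)
    recovers the flat-wavefront metric: reward 1."""
    samp = ab.AberrationSample(
        target_coeffs=np.array([0.08, -0.05, 0.03]),
        noise_coeffs=np.zeros(13), target_indices=(4, 5, 6))
    env3.observe(samp)
    reward, done = env3.step(-samp.target_coeffs)
    assert done is True
    assert reward == pytest.approx(1.0, abs=1e-9)


def test_zero_action_reward_below_one(env3):
    env3.observe(ab.AberrationSample(
        target_coeffs=np.array([0.1, 0.0, -0.06]),
        noise_coeffs=np.zeros(13), target_indices=(4, 5, 6)))
    reward, _ = env3.step(np.zeros(3))
    assert reward < 1.0


def test_reward_peak_on_correction_grid(env3):
    """No action on a +-0.05 um grid around the exact correction beats it
    (the flat wavefront maximises the metric)."""
    target = np.array([0.06, -0.04, 0.02])
    samp = ab.AberrationSample(target_coeffs=target,
                               noise_coeffs=np.zeros(13),
                               target_indices=(4, 5, 6))
    env3.observe(samp)
    best, _ = env3.step(-target)
    for dx in (-0.05, 0.0, 0.05):
        for dy in (-0.05, 0.0, 0.05):
            for dz in (-0.05, 0.0, 0.05):
                r, _ = env3.step(-target + np.array([dx, dy, dz]))
                assert r <= best + 1e-9


def test_episode_image_budget(small_system):
    """One episode costs exactly (2N+1) + k image formations."""
    env = presets.scaled_down_env(small_system, seed=3)
    k = 10
    before = small_system.render_count
    env.reset()
    rng = np.random.default_rng(0)
    rewards = env.evaluate_action_batch(np.zeros(3), rng.normal(0, 0.02, (k, 3)))
    assert small_system.render_count - before == (2 * 3 + 1) + k
    assert rewards.shape == (k,)


def test_batch_of_zero_profiles_identical(env3):
    env3.reset(np.random.default_rng(5))
    rewards = env3.evaluate_action_batch(np.array([0.01, 0.0, -0.02]),
                                         np.zeros((5, 3)))
    assert np.all(rewards == rewards[0])


def test_reward_invariant_to_sample_rescaling(small_system):
    """The metric is quadratic in intensity, so a uniform sample rescale
    cancels in the reward ratio."""
    scaled = s.SystemModel(sample_image=small_system.sample_image * 7.5,
                           grid_size=64, pupil_radius=32, kernel_size=17)
    e1 = presets.scaled_down_env(small_system)
    e2 = presets.scaled_down_env(scaled)
    samp = ab.AberrationSample(target_coeffs=np.array([0.07, -0.02, 0.04]),
                               noise_coeffs=np.zeros(13),
                               target_indices=(4, 5, 6))
    e1.observe(samp)
    e2.observe(samp)
    r1, _ = e1.step(np.zeros(3))
    r2, _ = e2.step(np.zeros(3))
    assert r1 == pytest.approx(r2, rel=1e-9)


def test_action_validation(env3):
    env3.reset(np.random.default_rng(1))
    with pytest.raises(ValueError):
        env3.step(np.zeros(5))
    with pytest.raises(ValueError):
        env3.step(np.array([np.nan, 0.0, 0.0]))


def test_metric_noise_option(small_system):
    noisy = presets.scaled_down_env(small_system, metric_noise_sd=0.05, seed=9)
    obs1 = noisy.observe(_zero_sample())
    obs2 = noisy.observe(_zero_sample())
    assert not np.array_equal(obs1[:, 0], obs2[:, 0])


def test_degenerate_state_raises(small_system, monkeypatch):
    """If every acquisition returns a zero metric the episode is unusable
    and reset must fail loudly rather than emit a NaN matrix."""
    env = presets.scaled_down_env(small_system, seed=0)
    monkeypatch.setattr(env, "_raw_metric", lambda *a, **k: 0.0)
    with pytest.raises(s.env.DegenerateStateError):
        env.reset(np.random.default_rng(0))


def test_baseline_metric_override(small_system):
    env = presets.scaled_down_env(small_system, baseline_metric=123.0)
    assert env.baseline_metric == 123.0
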