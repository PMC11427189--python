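"""Reference configurations: the full-scale study setup and a desk-scale
training protocol.

The full setup corrects N = 12 modes (Noll 4-15) on the 128-px simulator
with 40,000 episodes and 15 noise profiles per episode — hours of CPU time.
The scaled-down protocol keeps the same structure at a size a laptop CPU
covers in minutes: N = 3 modes (defocus + both astigmatisms), a 64-px
sample, 3,000 episodes with 10 noise profiles, and a narrower (64-unit)
recurrent width with faster learning rates, which the shorter run needs to
converge.  It is the setting used by the package's own training tests.
"""

from __future__ import annotations

import numpy as np

from .agent import TrainingSchedule
from .env import SAOEnv
from .optics import SystemModel
from .samples import generate_sample_image

__all__ = ["scaled_down_system", "scaled_down_env", "scaled_down_schedule",
           "SCALED_TARGET_INDICES"]

SCALED_TARGET_INDICES = (4, 5, 6)


def scaled_down_system(sample_seed: int = 7, fiber_diameter: float = 3.0,
                       **kwargs) -> SystemModel:
    """64-px sample on a 64-px pupil grid (128-px FFT), 17-px kernel."""
    sample = generate_sample_image("fibers", 64, sample_seed)
    kwargs.setdefault("grid_size", 64)
    kwargs.setdefault("pupil_radius", 32)
    kwargs.setdefault("kernel_size", 17)
    return SystemModel(sample_image=sample, fiber_diameter=fiber_diameter,
                       **kwargs)


def scaled_down_env(system: SystemModel | None = None, config="train_uniform",
                    bias: float = 0.5, seed: int = 0, **env_kwargs) -> SAOEnv:
    if system is None:
        system = scaled_down_system()
    return SAOEnv(system, config, target_indices=SCALED_TARGET_INDICES,
                  bias=bias, seed=seed, **env_kwargs)


def scaled_down_schedule(episodes: int = 3000, seed: int = 0,
                         **overrides) -> TrainingSchedule:
    defaults = dict(
        episodes=episodes,
        warmup_episodes=episodes // 10,
        noise_profiles_per_episode=10,
        exploration_sd0=0.08,
        batch_size=128,
        actor_lr=1e-3,
        critic_lr=3e-3,
        updates_per_episode=4,
        hidden=64,
        seed=seed,
    )
    defaults.update(overrides)
    return TrainingSchedule(**defaults)
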