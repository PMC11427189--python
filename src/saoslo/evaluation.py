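"""Residual-error metrics and the Monte-Carlo benchmark harness.

Performance is scored as residual RMS wavefront error over the corrected
target modes,

    RMS_WFE = sqrt( sum_i (c_i + a_i)^2 ),

where ``c_i`` is the true target coefficient and ``a_i`` the applied
correction (Noll normalisation makes coefficient space an isometry of
wavefront RMS).  Higher-order noise modes are deliberately excluded: they
are outside the correction space, so including them would add a constant
floor unrelated to method quality.  A correction is conventionally called
diffraction-limited when RMS_WFE <= lambda/14 (the Marechal criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import aberrations as ab
from . import baselines as bl
from .env import SAOEnv
from .optics import SystemModel
from .samples import generate_sample_image  # noqa: F401  (re-export)

__all__ = [
    "rms_wfe", "marechal_threshold", "EvalStats", "run_benchmark",
    "default_system", "generate_sample_image",
]

#: Seed of the default sample texture; fixed so "the default simulator"
#: names one reproducible object.
DEFAULT_SAMPLE_SEED = 7
DEFAULT_SAMPLE_KIND = "fibers"


def rms_wfe(true_coeffs: np.ndarray, predicted_correction: np.ndarray) -> float:
    """Residual RMS wavefront error (um) over the target modes."""
    t = np.asarray(true_coeffs, dtype=float)
    c = np.asarray(predicted_correction, dtype=float)
    if t.shape != c.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {c.shape}")
    return float(np.sqrt(np.sum((t + c) ** 2)))


def marechal_threshold(wavelength: float) -> float:
    """Diffraction-limited RMS wavefront error bound, lambda/14 (um)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / 14.0


def default_system(sample_kind: str = DEFAULT_SAMPLE_KIND, sample_size: int = 128,
                   sample_seed: int = DEFAULT_SAMPLE_SEED, **kwargs) -> SystemModel:
    """The default 128-px benchmark simulator with a fixed seeded sample."""
    sample = generate_sample_image(sample_kind, sample_size, sample_seed)
    return SystemModel(sample_image=sample, **kwargs)


@dataclass
class EvalStats:
    """Per-trial residual errors and their summary for one method/config."""

    method: str
    config: str
    bias: float
    n_trials: int
    seed: Optional[int]
    wavelength: float
    rms: np.ndarray = field(repr=False)
    rewards: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def mean(self) -> float:
        return float(self.rms.mean())

    @property
    def sd(self) -> float:
        return float(self.rms.std(ddof=1)) if self.n_trials > 1 else 0.0

    @property
    def marechal(self) -> float:
        return marechal_threshold(self.wavelength)

    @property
    def frac_diffraction_limited(self) -> float:
        """Empirical fraction of trials at or below the Marechal bound."""
        return float(np.mean(self.rms <= self.marechal))

    @property
    def frac_diffraction_limited_gauss(self) -> float:
        """Gaussian extrapolation of the same fraction from mean and SD."""
        if self.sd == 0:
            return float(self.mean <= self.marechal)
        return float(stats.norm.cdf((self.marechal - self.mean) / self.sd))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"trial": np.arange(self.n_trials), "rms_wfe": self.rms})
        if self.rewards is not None:
            df["reward"] = self.rewards
        df.insert(0, "method", self.method)
        df.insert(1, "config", self.config)
        return df

    def summary(self) -> dict:
        return {
            "method": self.method, "config": self.config, "bias": self.bias,
            "n_trials": self.n_trials, "seed": self.seed,
            "mean_rms_wfe": self.mean, "sd_rms_wfe": self.sd,
            "marechal_um": self.marechal,
            "frac_diffraction_limited_empirical": self.frac_diffraction_limited,
            "frac_diffraction_limited_gaussian": self.frac_diffraction_limited_gauss,
        }


def run_benchmark(method: str, config, n_trials: int, rng,
                  system: Optional[SystemModel] = None, bias: float = 0.2,
                  checkpoint=None, plan: Optional[bl.ZMHCPlan] = None,
                  target_indices=None, compute_rewards: bool = False) -> EvalStats:
    """Monte-Carlo benchmark of one correction method.

    Per trial: draw an aberration (target modes + higher-order noise), run
    the method on the simulator, and score the residual RMS wavefront
    error.  The aberration sequence is a pure function of the seed, so two
    methods benchmarked with the same seed face bitwise-identical draws.

    Parameters
    ----------
    method
        ``"zero"`` (no correction), ``"parabolic"``, ``"zmhc"`` or
        ``"agent"`` (requires ``checkpoint``).
    config
        Aberration configuration name (``"A"``/``"B"``/``"C"``) or object.
    bias
        Probe bias for ``parabolic`` and for the agent's observations
        (the agent uses its own trained bias stored in the checkpoint).
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    if isinstance(config, str):
        config = ab.CONFIGS[config]
    if target_indices is not None:
        config = ab.restrict_config(config, target_indices)
    if system is None:
        system = default_system()
    basis = system.make_basis(tuple(config.target_indices)
                              + tuple(config.noise_indices))
    n_target = len(config.target_indices)
    clip_limit = max(d[2] for d in config.mode_dists)

    # identical draws for every method at the same seed
    samples = [ab.sample_aberration(config, rng) for _ in range(n_trials)]

    agent_env = None
    if method == "agent":
        if checkpoint is None:
            raise ValueError("method 'agent' requires a checkpoint")
        from .agent import ActorPolicy
        policy = (checkpoint if isinstance(checkpoint, ActorPolicy)
                  else ActorPolicy.from_checkpoint(checkpoint))
        if policy.n_modes != n_target:
            raise ValueError(
                f"checkpoint predicts {policy.n_modes} modes, config has {n_target}")
        agent_env = SAOEnv(system, config, bias=policy.bias)

    rms = np.empty(n_trials)
    rewards = np.empty(n_trials) if compute_rewards else None
    for t, sample in enumerate(samples):
        if method == "zero":
            correction = np.zeros(n_target)
        elif method == "parabolic":
            obs = bl.acquire_bias_observations(
                system, basis, sample.full_coeffs(), n_target, bias)
            correction = bl.parabolic_correct(obs, limit=clip_limit)
        elif method == "zmhc":
            correction, _ = bl.zmhc_correct(
                system, basis, sample.full_coeffs(), n_target,
                plan or bl.ZMHCPlan())
        elif method == "agent":
            obs_matrix = agent_env.observe(sample)
            correction = policy.act(obs_matrix)
        else:
            raise ValueError(f"unknown method {method!r}")
        rms[t] = rms_wfe(sample.target_coeffs, correction)
        if compute_rewards:
            resid = np.concatenate(
                [sample.target_coeffs + correction, sample.noise_coeffs])
            m = system.metric_for_coeffs(resid, basis)
            m0 = system.metric_for_coeffs(np.zeros(basis.n_modes), basis)
            rewards[t] = m / m0
    return EvalStats(method=method, config=config.name, bias=bias,
                     n_trials=n_trials, seed=seed,
                     wavelength=system.wavelength, rms=rms, rewards=rewards)
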