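"""Single-step sensorless-AO environment.

Each episode hides a random aberration in the simulated SLO and exposes a
(2N+1)-row observation matrix built from image-sharpness metrics:

* one unbiased acquisition, then for each of the N target modes an
  acquisition with a negative and with a positive probe bias ``b`` (default
  0.5 um) added to that mode only;
* the metric column is normalised by its maximum, so it lies in [0, 1] with
  exactly one entry equal to 1;
* the remaining N columns carry the probe code of each row ({-1, 0, +1}).

``step`` applies a candidate correction (added to the hidden target
coefficients; higher-order noise stays) and returns the ratio of the
residual metric to the flat-wavefront reference metric as the reward, with
``done`` always true — the agent makes a single prediction per episode.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import aberrations as ab
from .optics import SystemModel, sharpness_metric

__all__ = ["DegenerateStateError", "SAOEnv"]


class DegenerateStateError(RuntimeError):
    """All observation metrics vanished: the optics configuration carries no
    usable sharpness signal."""


class SAOEnv:
    """Single-step episodic environment over a :class:`SystemModel`.

    Parameters
    ----------
    system
        Configured simulator (must carry a sample image).
    config
        Aberration configuration name or :class:`AberrationConfig` used by
        :meth:`reset`.
    target_indices
        Noll indices the agent corrects (defaults to the configuration's).
    bias
        Probe-observation coefficient magnitude, micrometres.
    metric_noise_sd
        Optional relative SD of multiplicative Gaussian noise on every
        acquired metric (emulates instrument intensity fluctuation).
    baseline_metric
        Override for the reward denominator; defaults to the metric of the
        flat (all-coefficients-zero) wavefront, computed once.  An override
        supports bench-style operation where flatness is only approximate.
    extra_aberration
        Optional fixed coefficient vector over ``target_indices`` added to
        every hidden aberration (a static system imperfection).
    """

    def __init__(self, system: SystemModel, config="A",
                 target_indices: Optional[Sequence[int]] = None,
                 bias: float = 0.5, metric_noise_sd: float = 0.0,
                 baseline_metric: Optional[float] = None,
                 extra_aberration: Optional[np.ndarray] = None,
                 seed: Optional[int] = None):
        if bias <= 0:
            raise ValueError("bias must be positive")
        if isinstance(config, str):
            config = ab.CONFIGS[config]
        if target_indices is not None:
            config = ab.restrict_config(config, target_indices)
        self.system = system
        self.config = config
        self.target_indices = tuple(config.target_indices)
        self.noise_indices = tuple(config.noise_indices)
        self.bias = float(bias)
        self.metric_noise_sd = float(metric_noise_sd)
        self.basis = system.make_basis(self.target_indices + self.noise_indices)
        self.n_modes = len(self.target_indices)
        self._rng = np.random.default_rng(seed)
        self.extra_aberration = (
            np.zeros(self.n_modes) if extra_aberration is None
            else np.asarray(extra_aberration, dtype=float))
        self.hidden: Optional[ab.AberrationSample] = None
        self._baseline_override = baseline_metric
        self._baseline: Optional[float] = None
        if baseline_metric is None:
            self.baseline_metric  # acquire the reference once, up front

    # ------------------------------------------------------------------
    @property
    def n_observations(self) -> int:
        return 2 * self.n_modes + 1

    @property
    def baseline_metric(self) -> float:
        """Reward denominator: flat-wavefront metric unless overridden."""
        if self._baseline_override is not None:
            return self._baseline_override
        if self._baseline is None:
            zero = np.zeros(self.basis.n_modes)
            self._baseline = self.system.metric_for_coeffs(zero, self.basis)
        return self._baseline

    def _raw_metric(self, target_coeffs: np.ndarray,
                    noise_coeffs: np.ndarray, rng=None) -> float:
        full = np.concatenate([target_coeffs, noise_coeffs])
        m = self.system.metric_for_coeffs(full, self.basis)
        if self.metric_noise_sd > 0:
            rng = self._rng if rng is None else rng
            m *= max(0.0, 1.0 + rng.normal(0.0, self.metric_noise_sd))
        return m

    def _hidden_target(self) -> np.ndarray:
        return self.hidden.target_coeffs + self.extra_aberration

    # ------------------------------------------------------------------
    def reset(self, rng=None) -> np.ndarray:
        """Draw a fresh hidden aberration and acquire the observation matrix.

        Returns an array of shape ``(2N+1, N+1)``: normalised metric column
        followed by the N-column probe-code block.  Row 0 is unbiased; rows
        ``2p+1`` / ``2p+2`` probe mode ``p`` (ascending Noll) with ``-b`` /
        ``+b``.
        """
        rng = self._rng if rng is None else np.random.default_rng(rng)
        return self.observe(ab.sample_aberration(self.config, rng), rng)

    def observe(self, sample: ab.AberrationSample, rng=None) -> np.ndarray:
        """Install ``sample`` as the hidden aberration and acquire the
        observation matrix (same layout as :meth:`reset`)."""
        self.hidden = sample
        target = self._hidden_target()
        n = self.n_modes
        metrics = np.empty(self.n_observations)
        codes = np.zeros((self.n_observations, n))
        metrics[0] = self._raw_metric(target, self.hidden.noise_coeffs, rng)
        for p in range(n):
            for row, sign in ((2 * p + 1, -1.0), (2 * p + 2, +1.0)):
                probe = target.copy()
                probe[p] += sign * self.bias
                metrics[row] = self._raw_metric(probe, self.hidden.noise_coeffs, rng)
                codes[row, p] = sign
        peak = metrics.max()
        if peak <= 0:
            raise DegenerateStateError("all observation metrics are zero")
        return np.column_stack([metrics / peak, codes])

    def step(self, action: np.ndarray) -> tuple[float, bool]:
        """Apply a correction and return ``(reward, done=True)``.

        The reward is the metric of the residual wavefront (hidden target
        plus action, higher-order noise retained) divided by the
        flat-wavefront reference metric.
        """
        if self.hidden is None:
            raise RuntimeError("call reset() before step()")
        action = np.asarray(action, dtype=float)
        if action.shape != (self.n_modes,):
            raise ValueError(f"action must have {self.n_modes} entries")
        if not np.all(np.isfinite(action)):
            raise ValueError("action contains non-finite values")
        m = self._raw_metric(self._hidden_target() + action,
                             self.hidden.noise_coeffs)
        return m / self.baseline_metric, True

    def evaluate_action_batch(self, base_action: np.ndarray,
                              noise_profiles: np.ndarray) -> np.ndarray:
        """Rewards for ``base_action + profile`` for each of k >= 1 noise
        profiles, all against the current hidden aberration."""
        noise_profiles = np.atleast_2d(np.asarray(noise_profiles, dtype=float))
        if noise_profiles.shape[0] < 1:
            raise ValueError("at least one noise profile required")
        return np.array([self.step(base_action + p)[0] for p in noise_profiles])
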