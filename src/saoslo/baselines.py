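"""Model-based sensorless-AO baselines.

Two classical metric-maximisation strategies over the same probe geometry
as the learned agent:

* parabolic maximization — per mode, fit the parabola through the metric at
  probe offsets ``{-b, 0, +b}`` and move to its vertex (2N+1 images);
* Zernike-mode hill climbing (ZMHC) — coordinate search scanning each mode
  over 11 evenly spaced offsets, in three rounds of shrinking span
  (+-0.2, +-0.1, +-0.05 um), for 11*N images per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BiasObservations", "acquire_bias_observations", "parabolic_correct",
    "parabolic_raw_vertex_estimate", "ZMHCPlan", "zmhc_image_count",
    "zmhc_correct",
]


# ---------------------------------------------------------------------------
# parabolic maximization
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BiasObservations:
    """Per-mode metric triples at probe offsets {-b, 0, +b}."""

    b: float                 # probe bias, um
    m0: float                # unbiased metric (shared across modes)
    m_plus: np.ndarray       # metric at +b per mode
    m_minus: np.ndarray      # metric at -b per mode

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("bias must be positive")
        if self.m0 < 0 or np.any(self.m_plus < 0) or np.any(self.m_minus < 0):
            raise ValueError("metrics must be nonnegative")
        if self.m_plus.shape != self.m_minus.shape:
            raise ValueError("m_plus / m_minus length mismatch")


def acquire_bias_observations(system, basis, hidden_full_coeffs: np.ndarray,
                              n_target: int, bias: float) -> BiasObservations:
    """Form the 2N+1 probe acquisitions on a simulator.

    ``hidden_full_coeffs`` is the full coefficient vector over ``basis``
    (targets first); probes perturb the first ``n_target`` entries only.
    """
    m0 = system.metric_for_coeffs(hidden_full_coeffs, basis)
    m_plus = np.empty(n_target)
    m_minus = np.empty(n_target)
    for p in range(n_target):
        for sign, out in ((+1.0, m_plus), (-1.0, m_minus)):
            probe = hidden_full_coeffs.copy()
            probe[p] += sign * bias
            out[p] = system.metric_for_coeffs(probe, basis)
    return BiasObservations(bias, m0, m_plus, m_minus)


def parabolic_raw_vertex_estimate(obs: BiasObservations) -> np.ndarray:
    """Per-mode aberration estimate ``b*(M+ - M-) / (2M+ - 4M0 + 2M-)``.

    On a concave metric parabola peaking at ``-a`` (hidden aberration
    ``a``), this evaluates to ``+a``; the correction to apply is its
    negation (see :func:`parabolic_correct`).
    """
    num = obs.b * (obs.m_plus - obs.m_minus)
    den = 2 * obs.m_plus - 4 * obs.m0 + 2 * obs.m_minus
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(den != 0, num / den, 0.0)
    return est


def parabolic_correct(obs: BiasObservations, limit: float = 0.2,
                      return_flags: bool = False):
    """Per-mode correction from three-point parabolic maximization.

    For each mode, the parabola through ``(-b, M-), (0, M0), (+b, M+)`` is
    maximised and its vertex abscissa returned as the correction to add to
    the wavefront.  Modes whose triple is flat or convex (denominator
    ``2M+ - 4M0 + 2M-`` >= 0, i.e. no interior peak) get correction 0 and
    are flagged; vertex magnitudes are clamped to ``limit``.
    """
    den = 2 * obs.m_plus - 4 * obs.m0 + 2 * obs.m_minus
    degenerate = den >= 0
    correction = -parabolic_raw_vertex_estimate(obs)
    correction = np.where(degenerate, 0.0, np.clip(correction, -limit, limit))
    if return_flags:
        return correction, degenerate
    return correction


# ---------------------------------------------------------------------------
# Zernike-mode hill climbing
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ZMHCPlan:
    """Round schedule: (span limit um, number of scan values) per round."""

    rounds: tuple = ((0.2, 11), (0.1, 11), (0.05, 11))

    def __post_init__(self):
        limits = [r[0] for r in self.rounds]
        if any(later >= earlier for earlier, later in zip(limits, limits[1:])):
            raise ValueError("round limits must be strictly decreasing")
        if any(n % 2 == 0 or n < 3 for _, n in self.rounds):
            raise ValueError("scan counts must be odd and >= 3")

    @property
    def final_resolution(self) -> float:
        """Coefficient resolution set by the last round's step size."""
        limit, n = self.rounds[-1]
        return 2 * limit / (n - 1)


def zmhc_image_count(plan: ZMHCPlan, n_modes: int):
    """(images per round, total images) for the coordinate search."""
    per_round = [n * n_modes for _, n in plan.rounds]
    return per_round, sum(per_round)


def zmhc_correct(system, basis, hidden_full_coeffs: np.ndarray,
                 n_target: int, plan: ZMHCPlan = ZMHCPlan(),
                 metric_fn=None) -> tuple[np.ndarray, int]:
    """Coordinate-search correction: returns ``(correction, images_formed)``.

    Per round and per mode (ascending Noll), the current estimate is
    perturbed over ``n`` evenly spaced offsets spanning ``+-limit`` around
    it; the offset with the best metric (first on ties) is kept before
    moving to the next mode.  Other modes stay at their current estimates,
    so the scan metric reflects the partially corrected wavefront.
    """
    if metric_fn is None:
        def metric_fn(correction):
            probe = hidden_full_coeffs.copy()
            probe[:n_target] += correction
            return system.metric_for_coeffs(probe, basis)

    estimate = np.zeros(n_target)
    images = 0
    for limit, n_values in plan.rounds:
        offsets = np.linspace(-limit, limit, n_values)
        for p in range(n_target):
            best_m, best_off = -np.inf, 0.0
            for off in offsets:
                trial = estimate.copy()
                trial[p] += off
                m = metric_fn(trial)
                images += 1
                if m > best_m:
                    best_m, best_off = m, off
            estimate[p] += best_off
    return estimate, images
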