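"""Random wavefront-aberration generation.

Aberrations are expressed as Zernike coefficient vectors (micrometres) over
the 12 target modes (Noll 4-15, radial degrees 2-4) plus small
"higher-order" noise on Noll 16-28 (radial degrees 5-6) that emulates the
uncorrectable residual content of a real eye.

Three evaluation configurations are provided:

* ``A`` — i.i.d. uniform on [-0.15, 0.15] um (the training distribution);
* ``B`` — i.i.d. zero-mean Gaussian, SD 0.06 um (0.4x the limit), truncated
  to [-0.15, 0.15] um, so ~80% of coefficients stay within half the limit
  and ~98.8% of an untruncated draw would respect it;
* ``C`` — Gaussian with SD decreasing by radial order (0.08 / 0.06 /
  0.04 um for degrees 2 / 3 / 4), truncated to [-0.2, 0.2] um; a proxy for
  mouse-eye statistics where low orders dominate.

Truncation is implemented as resample-until-inside, which preserves the
Gaussian density shape inside the limit rather than piling mass onto the
boundary; hard clipping is available via ``truncation="clip"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AberrationConfig", "AberrationSample", "CONFIGS",
    "sample_target_aberration", "sample_higher_order_noise",
    "sample_aberration", "truncated_normal", "within_limit_fraction",
]

TARGET_INDICES = tuple(range(4, 16))
NOISE_INDICES = tuple(range(16, 29))

#: Table of target-mode groups by radial degree (used by configuration C).
RADIAL_GROUPS = {2: (4, 5, 6), 3: (7, 8, 9, 10), 4: (11, 12, 13, 14, 15)}


def truncated_normal(rng: np.random.Generator, sd: float, clip: float,
                     size: int, method: str = "resample") -> np.ndarray:
    """Zero-mean Gaussian draws with |x| <= clip.

    ``method="resample"`` redraws out-of-range values (truncated-normal
    density); ``method="clip"`` projects them onto the boundary.
    """
    x = rng.normal(0.0, sd, size)
    if method == "clip":
        return np.clip(x, -clip, clip)
    bad = np.abs(x) > clip
    while np.any(bad):
        x[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(x) > clip
    return x


def within_limit_fraction(sd: float, limit: float) -> float:
    """Probability that an (untruncated) N(0, sd) draw lies within +-limit."""
    z = limit / sd
    return float(stats.norm.cdf(z) - stats.norm.cdf(-z))


@dataclass(frozen=True)
class AberrationConfig:
    """Distribution of the target-mode coefficients for one configuration."""

    name: str
    target_indices: tuple = TARGET_INDICES
    #: per-mode (kind, scale, clip): kind "uniform" -> U(-scale, scale);
    #: kind "gauss" -> N(0, scale) truncated to +-clip.
    mode_dists: tuple = ()
    noise_indices: tuple = NOISE_INDICES
    noise_sd: float = 0.01
    noise_clip: float = 0.025
    truncation: str = "resample"

    def __post_init__(self):
        if set(self.target_indices) & set(self.noise_indices):
            raise ValueError("target and noise indices must be disjoint")
        if len(self.mode_dists) != len(self.target_indices):
            raise ValueError("one distribution per target mode required")
        for kind, scale, clip in self.mode_dists:
            if scale <= 0:
                raise ValueError("distribution scale must be positive")
            if kind == "gauss" and clip < scale:
                raise ValueError("clip limit below one SD is not supported")


def _gauss_cfg(name: str, sd_by_mode: dict, clip: float) -> AberrationConfig:
    return AberrationConfig(
        name=name,
        mode_dists=tuple(("gauss", sd_by_mode[j], clip) for j in TARGET_INDICES),
    )


CONFIGS: dict[str, AberrationConfig] = {
    "A": AberrationConfig(
        name="A", mode_dists=tuple(("uniform", 0.15, 0.15) for _ in TARGET_INDICES)),
    "train_uniform": AberrationConfig(
        name="train_uniform",
        mode_dists=tuple(("uniform", 0.15, 0.15) for _ in TARGET_INDICES)),
    "B": _gauss_cfg("B", {j: 0.06 for j in TARGET_INDICES}, clip=0.15),
    "C": _gauss_cfg(
        "C",
        {j: sd for deg, sd in ((2, 0.08), (3, 0.06), (4, 0.04))
         for j in RADIAL_GROUPS[deg]},
        clip=0.2),
}


@dataclass(frozen=True)
class AberrationSample:
    """One drawn wavefront: target coefficients plus higher-order noise."""

    target_coeffs: np.ndarray           # aligned with target_indices, um
    noise_coeffs: np.ndarray            # aligned with noise_indices, um
    target_indices: tuple = TARGET_INDICES
    noise_indices: tuple = NOISE_INDICES

    def full_coeffs(self) -> np.ndarray:
        """Concatenated (target, noise) coefficient vector."""
        return np.concatenate([self.target_coeffs, self.noise_coeffs])


def restrict_config(config, target_indices) -> AberrationConfig:
    """A copy of ``config`` restricted to a subset of its target modes
    (used for reduced-mode training runs)."""
    if isinstance(config, str):
        config = CONFIGS[config]
    target_indices = tuple(target_indices)
    pos = {j: p for p, j in enumerate(config.target_indices)}
    missing = [j for j in target_indices if j not in pos]
    if missing:
        raise ValueError(f"modes {missing} not in configuration {config.name!r}")
    return AberrationConfig(
        name=config.name,
        target_indices=target_indices,
        mode_dists=tuple(config.mode_dists[pos[j]] for j in target_indices),
        noise_indices=config.noise_indices,
        noise_sd=config.noise_sd,
        noise_clip=config.noise_clip,
        truncation=config.truncation,
    )


def sample_target_aberration(config: AberrationConfig,
                             rng: np.random.Generator,
                             size: int | None = None) -> np.ndarray:
    """Draw target-mode coefficients (um) under the given configuration.

    Returns shape ``(n_modes,)``, or ``(size, n_modes)`` when ``size`` is
    given (vectorised draws for distributional checks).
    """
    n = size or 1
    out = np.empty((n, len(config.target_indices)))
    for p, (kind, scale, clip) in enumerate(config.mode_dists):
        if kind == "uniform":
            out[:, p] = rng.uniform(-scale, scale, n)
        elif kind == "gauss":
            out[:, p] = truncated_normal(rng, scale, clip, n, config.truncation)
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    return out if size else out[0]


def sample_higher_order_noise(rng: np.random.Generator,
                              noise_indices=NOISE_INDICES,
                              sd: float = 0.01, clip: float = 0.025,
                              method: str = "resample") -> np.ndarray:
    """Small Gaussian coefficients on the uncorrected high-order modes."""
    return truncated_normal(rng, sd, clip, len(noise_indices), method)


def sample_aberration(config, rng: np.random.Generator) -> AberrationSample:
    """Draw a full :class:`AberrationSample` (targets + high-order noise)."""
    if isinstance(config, str):
        try:
            config = CONFIGS[config]
        except KeyError:
            raise ValueError(f"unknown aberration configuration {config!r}") from None
    return AberrationSample(
        target_coeffs=sample_target_aberration(config, rng),
        noise_coeffs=sample_higher_order_noise(
            rng, config.noise_indices, config.noise_sd, config.noise_clip,
            config.truncation),
        target_indices=config.target_indices,
        noise_indices=config.noise_indices,
    )
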