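# saoslo — sensorless adaptive optics for confocal SLO imaging

Optical aberrations — from the eye itself in retinal imaging — blur
confocal scanning-laser-ophthalmoscope (SLO) images. *Sensorless* adaptive
optics (SAO) corrects them without a wavefront sensor: a deformable mirror
(DM) applies trial Zernike modes, an image-sharpness metric scores each
trial image, and an optimizer infers the correction. The catch is speed:
coordinate-search methods such as Zernike-mode hill climbing (ZMHC) need
hundreds of image acquisitions per correction, which live imaging cannot
afford.

`saoslo` implements a single-step alternative: from just **2N + 1**
sharpness observations (one unbiased, plus a ±0.5 µm probe of each of the
N corrected modes), a recurrent actor network predicts all N Zernike
coefficients at once. The actor–critic pair is trained by deterministic
policy gradient against a Fourier-optics simulator of the confocal SLO,
with an immediate (single-step) reward and no target networks, and can be
adapted to a perturbed system by brief transfer learning. The package
contains:

- `saoslo.zernike`, `saoslo.optics` — Noll-indexed Zernike basis and the
  image-formation chain: pupil `P = A·exp(−i·2π/λ·W)` with
  `W(x,y) = Σ cᵢ Zᵢ(x,y)`, intensity PSF `h = |FFT{P}|²`, confocal
  effective PSF `h_s = h₁·(f ⊛ h₂)` with a uniform-disk collection fiber
  `f` a few Airy-disk diameters wide, image `I = h_s ⊛ r_f`, and the
  sharpness metric `m = Σ I²`;
- `saoslo.aberrations` — random aberration draws: uniform ±0.15 µm
  training draws and the evaluation configurations A (uniform), B
  (Gaussian SD 0.06 µm, clip ±0.15), C (Gaussian SD 0.08/0.06/0.04 µm by
  radial order, clip ±0.2), plus small higher-order noise on Noll 16–28;
- `saoslo.env` — the single-step environment: observation matrix
  (metric column normalised by its maximum + {−1, 0, +1} probe codes),
  reward `m(residual)/m(flat)`, `done` always true;
- `saoslo.agent`, `saoslo.nn` — LSTM actor and critic with exact
  numpy backpropagation, replay memory, annealed multi-profile
  exploration (k noise profiles per episode → k transitions), warm-up
  phase, and transfer learning;
- `saoslo.baselines` — parabolic maximization (three-point vertex per
  mode from the same 2N+1 observations) and three-round ZMHC;
- `saoslo.evaluation` — residual RMS wavefront error
  `RMS_WFE = √Σᵢ(cᵢ+aᵢ)²` over the corrected modes, the Maréchal
  criterion λ/14, and a seeded Monte-Carlo benchmark harness;
- `saoslo.samples` — seeded synthetic fluorescence textures
  (lens-tissue-like fibres, ganglion-cell mosaics).

## Worked example

Train a 3-mode agent at desk scale (about five minutes on one CPU core)
and compare it with the model-based baselines on identical aberrations:

```python
import saoslo as s
from saoslo import presets

system = presets.scaled_down_system()          # 64-px sample, fiber 3 ADD
env = presets.scaled_down_env(system)          # modes 4-6, bias 0.5 um
ckpt, trace = s.train(env, presets.scaled_down_schedule())

kw = dict(system=system, target_indices=(4, 5, 6))
for method, extra in [("zero", {}), ("parabolic", {"bias": 0.5}),
                      ("agent", {"checkpoint": ckpt})]:
    st = s.run_benchmark(method, "B", 200, 123, **kw, **extra)
    print(f"{method:9s} mean RMS-WFE {st.mean:.4f} um")
```

Output from this run:

```
zero      mean RMS-WFE 0.0949 um
parabolic mean RMS-WFE 0.0657 um
agent     mean RMS-WFE 0.0338 um
```

The zero line is the uncorrected aberration level; parabolic maximization
halves it from the same 7 observations; the trained agent halves it again
(0.034 µm is below the Maréchal bound λ/14 = 0.0349 µm, i.e.
diffraction-limited on average). The full 12-mode, 40,000-episode
configuration is available as `scripts/train_full.py` (hours of CPU).

A command-line entry point mirrors the library:
`saoslo train|transfer|correct|benchmark|make-fixtures --help`.

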