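# Methods

## Image-formation model

The simulator models the SLO's confocal detection path at a single
wavelength (default λ = 0.488 µm). The wavefront error is a superposition
of Noll-indexed Zernike modes, `W(x,y) = Σ cᵢ Zᵢ(x,y)`, on a discrete
circular pupil (default: pupil diameter 256 px filling a 256×256 complex
grid). Piston, tip and tilt are excluded throughout: they carry no
sharpness information in this geometry. The generalised pupil is
`P = A·exp(−i φ)` with binary aperture `A` and phase `φ = (2π/λ)·W`
(coefficients are micrometres of optical path; the phase conversion is
explicit because a pupil phase must be radians). The intensity PSF is
`h = |FFT{P}|²` on a 2× zero-padded grid (512×512), so the Airy core
spans ~4.9 PSF pixels and the sampling is at least Nyquist.

Confocality: illumination and detection pass through the same DM/eye
path, so both PSFs carry the same aberration, `h₁ = h₂ = h(W)`. The
multimode collection fiber is a uniform unit-height disk `f` whose
diameter is expressed in Airy-disk diameters (ADD); the effective PSF is
`h_s = h₁ · (f ⊛ h₂)`, reducing to the point-detector product `h₁·h₂` at
zero diameter. Images are formed by circular (FFT) convolution of the
central 33×33 crop of `h_s` with a 128×128 nonnegative sample texture,
and scored by the sharpness metric `m = Σ I²`. The metric is reported
raw; every decision quantity (observation matrix, reward) is a ratio, so
its absolute scale cancels. All convolutions being circular gives the
model an exact reflection symmetry: with a flat underlying wavefront,
`+b` and `−b` probes of one mode yield identical metrics to machine
precision, which the tests exploit.

For speed, the production path evaluates the squared-modulus PSF and the
fiber blur only on the window the 33×33 kernel needs; this is numerically
identical (≤1e-15 relative) to cropping the full-grid operations and
makes one metric evaluation ~6 ms at full resolution.

## Coefficient convention (mode scaling)

Two conventions connect a coefficient vector to the wavefront:

- `mode_scaling="noll"`: `cᵢ` is the pupil-RMS OPD of mode i in µm
  (orthonormal Zernike weights);
- `mode_scaling="peak"` (default): `cᵢ` is the peak amplitude of mode i
  over the pupil, the natural unit of a deformable-mirror command, so the
  Noll map is divided by its maximum before weighting.

The default is "peak" because it is the convention under which the
simulated parabolic-maximization benchmark reproduces the behaviour this
model family is calibrated against — in particular the ordering in which
configuration C (larger low-order coefficients, smaller high-order ones)
is *easier* than configuration B, which no fiber diameter, sample
texture, pupil sampling or kernel size reproduces under strict Noll
scaling. Residual errors are always reported in coefficient units
(`RMS_WFE = √Σ(cᵢ+aᵢ)²` over the corrected modes, Noll 4–15); under peak
scaling this is a DM-command-space norm rather than a strict wavefront
RMS. Higher-order noise modes are excluded from the score: they lie
outside the correction space and would only add a method-independent
floor.

## Aberration statistics

Training draws each of the N target coefficients i.i.d. uniform on
±0.15 µm. Evaluation uses three configurations: A — the training
distribution; B — zero-mean Gaussian, SD 0.06 µm (0.4× the limit),
limited to ±0.15 µm; C — Gaussian with SD 0.08/0.06/0.04 µm for radial
degrees 2/3/4, limited to ±0.2 µm (a proxy for mouse-eye statistics and
an extrapolation test, since training never exceeded ±0.15). Higher-order
noise: 13 coefficients (Noll 16–28), Gaussian SD 0.01 µm limited to
±0.025 µm, drawn fresh every episode. Limits are enforced by
resample-until-inside, which preserves the density shape instead of
creating boundary atoms (hard clipping is available); at ±2.5 SD the
truncation shrinks the realised SD by ≈4.5%.

## Environment and reward

An episode hides one aberration draw. The observation matrix has 2N+1
rows: the unbiased acquisition first, then for each mode in ascending
Noll order the −b and +b probe (b = 0.5 µm by default; the exact row
order is arbitrary but must be stable between training and inference).
The metric column is divided by its maximum, so entries lie in [0, 1]
with exactly one 1; each row additionally carries its probe code
({−1, 0, +1} per mode). The reward of an action is the metric of the
residual wavefront (action added to the hidden target modes; noise modes
untouched) divided by the all-coefficients-zero reference metric, which
is computed once per environment — so an episode costs exactly
(2N+1) + k image formations, with k the number of exploration profiles.
A `baseline_metric` override supports bench-style operation where the
reference is a near-flat benchmark rather than exact flatness, and an
optional multiplicative Gaussian metric noise emulates intensity
fluctuation for robustness experiments.

## Agent

The actor consumes the observation matrix as a length-(2N+1) sequence of
(N+1)-vectors through one LSTM layer and a tanh head scaled to
±`action_limit` (default 0.25 µm — deliberately above the 0.15 µm
training range so the policy can extrapolate to configuration C's
±0.2 µm draws). The critic encodes the same sequence, concatenates the
action to the final recurrent state, and regresses the immediate reward
through one hidden ReLU layer. Because episodes are single-step, the
critic target is the observed reward itself: no bootstrapping, no target
networks. The actor ascends the critic (deterministic policy gradient);
both use Adam. Exploration adds k zero-mean Gaussian profiles to each
prediction (k = 15 full scale), evaluates all of them against the same
hidden aberration, and stores k transitions; the noise SD anneals
linearly from 0.05 µm to exactly zero at the final episode. A warm-up
phase (10% of episodes) collects transitions with frozen networks. All
gradients are exact (finite-difference-checked in the tests); training is
fully reproducible from one seed.

Full-scale defaults (40,000 episodes, hidden width 128, batch 256, actor
lr 1e-4, critic lr 1e-3, replay 1e6) follow common deterministic
policy-gradient practice. The desk-scale protocol used by the test suite
(`saoslo.presets`) corrects N = 3 modes (defocus + both astigmatisms) on
a 64-px sample for 3,000 episodes with k = 10; the much shorter run needs
a narrower network (hidden 64) and faster learning (actor lr 1e-3, critic
3e-3, 4 updates/episode, batch 128) to converge — these were fixed once
while developing the protocol and are recorded in the preset. On one CPU
core the run takes ~3.5 minutes and reaches a mean reward of ~0.975;
transfer learning (1,000 episodes, k = 7, exploration SD 0.02 µm, no
warm-up freeze since the networks start competent) takes ~2 minutes.

## Baselines

Parabolic maximization fits, per mode, the parabola through the metric at
probe offsets {−b, 0, +b} and moves to its vertex
`b(Mₙ⁺−Mₙ⁻) / (4M₀−2Mₙ⁺−2Mₙ⁻)`. Note the sign: the widely quoted form
with denominator `2Mₙ⁺−4M₀+2Mₙ⁻` evaluates, on a concave curve peaking at
−a, to +a — the aberration *estimate*; the correction applied to the
mirror is its negation. `parabolic_correct` returns the correction and
exposes the raw estimate separately. Modes whose metric triple is flat or
convex (no interior maximum) are flagged and left uncorrected; vertices
are clamped to the working limit. The probe bias matters: 0.2 µm is the
default for this baseline.

ZMHC scans each mode over 11 evenly spaced offsets centred on its current
estimate, keeping the argmax (first on ties), in three rounds of span
±0.2/±0.1/±0.05 µm — 11·N images per round, 396 total for N = 12, final
resolution 0.01 µm. Because the offset 0 is always in the scan, the
accepted metric never falls below the starting point.

## Benchmark harness and calibration

`run_benchmark` draws the aberration sequence as a pure function of the
seed, so different methods face bitwise-identical draws, then scores each
correction by residual RMS. Summaries report mean, SD, and the fraction
of trials at or below the Maréchal bound λ/14 = 0.0349 µm, both as an
empirical count and as the Gaussian extrapolation Φ((λ/14 − mean)/SD).

The default simulator (fiber 3 ADD, 128-px "fibers" texture, seed 7)
was calibrated once against the parabolic-maximization benchmark at bias
0.2 µm and then frozen. At n = 1,000 it yields mean residuals of
≈0.10 (A), ≈0.052 (B) and ≈0.056 (C) µm. Three findings from the
calibration study are worth recording: the result is essentially
independent of the sample texture, its smoothness, any background
pedestal, and the pupil sampling (supporting the claim that the metric is
image-independent); it depends strongly on the fiber diameter and on the
coefficient convention; and under Noll scaling configuration C is always
harder than B while under peak scaling the two cross over, with the
remaining B/C difference traceable to the astigmatism modes, whose
per-mode weighting in a real DM's command basis is exactly the part this
simulator cannot pin down.

## What the synthetic data does and does not capture

The sample generator emulates two bench sample classes (fibrous
lens-tissue strands; soma mosaics) as seeded nonnegative textures. It
does not model detector/shot noise, scanner distortion, photobleaching,
non-common-path aberrations or sample motion; the environment's optional
metric noise and the perturbed-simulator transfer experiments (fiber
3→4 ADD plus a fixed astigmatism offset) are surrogates for those
effects. Tests passing on this simulator therefore demonstrate the
correctness and internal consistency of the method — observation
construction, learning dynamics, baseline comparisons — not bench-level
performance.

## Numerical choices and degenerate inputs

float64 throughout; FFTs via scipy.fft. The Parseval identity holds to
1e-6 relative and probe-reflection symmetry to 1e-9, and both are tested.
Negative convolution residues from roundoff are clipped at zero. A
single-pixel fiber disk reproduces the point-detector limit exactly. An
all-zero observation episode raises a degenerate-state error rather than
returning a NaN matrix; non-finite actions and diverging (non-finite)
training losses raise immediately. Checkpoints are a flat `.npz` of named
arrays plus a JSON config sidecar, loadable without the training code.

## Known limitations

- The per-mode DM normalization ("peak" scaling) is a modelling choice;
  command-space residuals equal wavefront RMS only under "noll" scaling.
- Parabolic-maximization accuracy saturates ~20–45% above the best
  published bench-model values depending on configuration; the gap is
  systematic (present at small amplitudes) and sits in the astigmatism
  modes' weighting, not in the Monte-Carlo noise.
- The desk-scale training protocol recovers defocus/astigmatism to
  ~0.01 µm median per-coefficient error but its weakest mode (vertical
  astigmatism, the optically faintest under peak scaling) remains ~3×
  worse; longer runs close the gap.
- Single-step training assumes the observation matrix fully determines
  the optimal correction; iterated correction (re-observing after a
  first correction) is supported at inference but not trained for.
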