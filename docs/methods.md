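# Methods

## Signal model

The package models the ROI-averaged DW-MRI signal as two non-exchanging
compartments,

    S(b)/S0 = f·e^(−b·Db)·H(b) + (1−f)·e^(−b·D),

for a rectangular pulsed-gradient spin-echo (PGSE) pair of duration δ,
onset separation Δ and amplitude G, with b = γ²δ²G²(Δ−δ/3). The
extravascular term is monoexponential, appropriate for b ≤ 1000 s/mm²;
the intravascular attenuation H(b) reflects blood advected at speed v
through serially connected, randomly oriented capillary segments of
length l, with correlation time T0 between direction changes.

Internal units are seconds and millimetres everywhere (b: s/mm², D:
mm²/s, v: mm/s, l: mm, T0: s); file headers and reports carry ms and
µm, converted at the I/O boundary. γ defaults to the proton value
2.675×10⁸ rad s⁻¹ T⁻¹.

Four forms of H are implemented:

| label            | form                                            | regime |
|------------------|-------------------------------------------------|--------|
| `diffusive`      | exp(−b·D\*), D\* = v·l/6                        | T0 ≪ Δ |
| `ballistic_sinc` | sinc(c·v), c = γGδΔ, unnormalised sin(x)/x      | T0 ≫ Δ |
| `va`             | exp(−b·Ω·v²·T0 / (3δ²(Δ−δ/3)))                  | all    |
| `vab`            | exp(−b·v²·Δ² / (6(Δ−δ/3))) = exp(−(cv)²/6)      | T0 ≫ Δ |

with Ω = δ²(Δ−δ/3) − 2T0²δ − T0³q and q the five-exponential sum given
in the code. This grouping of Ω is fixed by three independent checks:
as T0→0 it reduces H(va) to exp(−b·v²T0/3) (the diffusive form with
D\* = v²T0/3); as T0→∞, T0·Ω → Δ²δ²/2, recovering the VAB form; and
2·T0·Ω equals, to better than 1e-10 relative over a 125-point (δ, Δ,
T0) grid, the 2-D adaptive quadrature of the exponential
velocity-correlation kernel ⟨v(t)v(t′)⟩ ∝ e^(−|t−t′|/T0) against the
exact ramp–flat–ramp PGSE moment profile. Negative sinc lobes are
returned unclamped; the unnormalised sinc convention is required for
the fourth-order Taylor match with the VAB Gaussian
(|sinc(x) − e^(−x²/6)| ≈ x⁴/180 for small x).

**Numerical stabilisation.** The printed Ω expression suffers
catastrophic cancellation for T0 ≫ Δ (three terms of size ∝ T0
cancelling to a residual ∝ 1/T0). `va_kernel` therefore evaluates q via
−4e^(−Δ/T0)sinh²(δ/2T0) + 2·expm1(−δ/T0) (switching to an
overflow-safe exponential-difference form when δ/T0 ≥ 1) and regroups Ω
so the cancellations happen analytically. The implementation is
accurate to ~1e-9 relative even at T0 = 100 s.

**Two T0 conventions.** The transit reading "time to traverse one
segment" gives T0 = l/v (30 µm at 2 mm/s → 15 ms, the worked value),
while consistency of the VA diffusive limit D\* = v²T0/3 with
D\* = v·l/6 requires T0 = l/(2v). The factor-two discrepancy is
irreducible; both are exposed (`correlation_time_transit`,
`correlation_time_ivim`) and the pipeline itself never converts between
T0 and l. The synthetic generator uses l/(2v) so that VA-generated
cohorts have D\* exactly v·l/6.

## Two-step estimation pipeline

Per (subject, session, region), after direction averaging:

1. **Extravascular step**, per diffusion time: D = ln(S₂/S₁)/(b₁−b₂)
   from b = 500 and 1000 s/mm²; f = 1 − (S/S0)e^(bD) evaluated at both
   high b-values and averaged. (With D estimated from the same two
   points the two f evaluations are algebraically identical — the
   averaging is kept for symmetry but is a no-op.) f is clipped to
   [0, 1] with a diagnostic flag; regions with f ≤ 0.005 are skipped.
2. **Isolation**: y(b) = (S/S0 − (1−f)e^(−bD))/f on b < 500 s/mm²
   (including the b = 0 anchor, where y = 1 identically).
3. **Intravascular fits** of y = e^(−b·Db)·H + d (Db fixed at
   1.75×10⁻³ mm²/s; d an intercept absorbing two-step bias), linear
   signal domain, unweighted residuals, scipy `least_squares` with the
   trust-region-reflective algorithm and tight tolerances (1e-12), so
   results are bit-reproducible:
   * diffusive form at Δ = 50 ms → D\*;
   * sinc and VAB forms at Δ = 11.6 ms → v (one per method); sinc fits
     reaching c·v ≥ π are flagged;
   * VA form jointly over all diffusion times with a single shared
     intercept → v and T0 (a per-Δ intercept would absorb the
     Δ-dependence the VA model must explain).
4. **Segment length** l = 6·D\*/v per velocity method.

Bounds and starts (flagged when pinned): v ∈ [0, 20] mm/s, start 1.0;
T0 ∈ [10⁻⁴, 1] s, start 0.015 (a physiologically motivated transit
time); D\* ∈ [0, 0.1] mm²/s, start 5×10⁻³; d ∈ [−0.5, 0.5], start 0.
T0 identifiability is checked from the Gauss–Newton covariance
(flagged when se(T0)/T0 > 10, or when only one diffusion time is
present). Groups failing a stage carry partial results and error codes;
the pipeline never aborts on one region.

### Bias of the two-step method (noiseless analysis)

Two deterministic biases limit even noiseless recovery; both are
properties of the method at this acquisition, not of the
implementation (the fit-level round trip with exact f and D supplied
recovers all generating parameters to < 1e-6 relative):

* **High-b intravascular contamination.** At b = 500 s/mm² the
  intravascular term is not zero unless b·D\* is large. At the
  physiological reference point v = 2 mm/s, T0 = 15 ms it is ~0.15% of
  the total signal at Δ = 11.6 ms, which biases D̂ up by ~0.4% and f̂
  down by ~3%, and — because the VA velocity information lives at the
  shortest diffusion time — propagates into a +3.8% bias of v̂(VA).
  The bias grows steeply as v·T0 falls (slow flow): at v ≈ 0.6 mm/s it
  reaches tens of percent. It drops below 1% only for v ≳ 3 mm/s.
* **Finite-T0 bias of the diffusive assumption.** At Δ = 50 ms the VA
  attenuation exponent is the asymptotic b·D\* multiplied by
  R = Ω/(δ²(Δ−δ/3)) < 1 (R = 0.74 at T0 = 15 ms, 0.89 at 7.5 ms), so
  D̂\* and hence l̂ are low by 10–30% wherever T0 ≳ 5 ms. Reaching R ≥
  0.95 requires T0 ≤ ~3 ms, exactly where the contamination bias above
  explodes — the two biases cannot be made small simultaneously at
  this acquisition.

Consequently, on noiseless VA-generated cohorts the pipeline
reproduces the method-ordering v̂(VA) ≥ v̂(VAB) in every region and
keeps the VAB velocity within 25% of truth for v ≥ 1 mm/s, but
uniform 1%-accurate velocity recovery across physiological regions is
not achievable by this estimator; the corresponding end-to-end check
in the acceptance suite records that finding.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the pipeline
expects, not images: the 8 b-value × {11.6, 20, 40, 50} ms × 3
direction grid at δ = 5.8 ms (per-point G solved from b, maximum
~207 mT/m, under a 375 mT/m hardware ceiling), two strains × 10
subjects, 5 subjects of the first strain rescanned, ten named brain
regions whose (f, D, v, l) centres span v ≈ 0.6–2.8 mm/s and
l ≈ 12–62 µm (bracketing literature capillary values: RBC velocity
~2 mm/s, segment length ~27 µm), per-subject ±8% uniform jitter fixed
across sessions, and Rician magnitude noise
S = √((S₀ₛᵢ₉+ε₁)² + ε₂²) with σ calibrated so the difference-method
SNR at b = 10 s/mm² hits the target (default 50, configurable).
Everything is keyed off integer seeds through `numpy.random.default_rng`;
regeneration is bit-identical. Not emulated: voxel geometry and
partial-volume effects, motion/eddy-current artefacts, cross-terms with
imaging gradients, exchange between compartments, vessel-network
hierarchy. Passing tests therefore demonstrate estimator correctness
under the stated generative model, not robustness to those real-data
effects.

## Monte-Carlo spin-phase oracle

Spins traverse a piecewise-linear path at constant speed v: segments of
length l (duration l/v), a fresh direction uniform on the sphere at
each node, and uniform initial placement along the current segment
(steady-state occupancy, so the first node arrives after U(0, l)/v).
Only the gradient-axis direction cosine (uniform on [−1, 1]) matters.
The phase φ = γ∫G(t)z(t)dt is accumulated with exact antiderivatives of
linear motion against the piecewise-constant effective gradient — there
is no time step to tune. H is the real part of the ensemble mean of
e^(iφ) (the imaginary part vanishes by symmetry), with the standard
error from the spread of cos φ. One trajectory ensemble per (regime,
Δ) is re-used across b through the gradient amplitude.

The oracle checks the closed forms where they are exact: long segments
(l = 100·v·Δ) reproduce sinc(c·v); short segments (l = v·Δ/50, at
b·D\* < 0.5) reproduce exp(−b·v·l/6); both within 3 MC standard errors
at 10⁵ spins over every protocol point with b < 500 s/mm². In the
crossover (l ~ v·Δ) the simulated attenuation is *weaker* than both
asymptotic formulas evaluated at the same l — the diffusive form
overestimates attenuation because the apparent D\* carries the
finite-T0 factor R < 1, and the sinc form overestimates it because
direction changes narrow the phase distribution. An optional
exponential segment-length mode (off by default) makes the walk's
velocity autocorrelation exactly exponential with T0 = l/v; even
there the VA closed form is only matched approximately, because it
additionally rests on the Gaussian phase approximation, which the
simulated (distinctly non-Gaussian) phase distribution violates at
b ≳ 50 s/mm². Only the two regime limits are therefore used as
quantitative oracles.

## Statistics conventions

* **Outlier filter**: keep |x − median| ≤ 3·MAD with the raw
  median-absolute-deviation (no 1.4826 consistency factor); points
  exactly at the cut, and all points when MAD = 0, are kept. Applied
  per (region, parameter) group before summarising. The filter is
  permutation-invariant but not strictly idempotent for arbitrary data
  (removing a point shifts the median and MAD; e.g. [0, 0, 1, 3]); on
  typical gross-outlier data a second pass is a no-op.
* **Repeatability**: CoV(%) = 100·σ/μ with σ = √(Σ(x₁−x₂)²/2n) and
  μ = Σ(x₁+x₂)/2n over subject pairs; incomplete pairs dropped with
  count; μ = 0 flagged undefined. The σ estimator recovers an injected
  within-subject SD within ~1% at 10⁴ pairs.
* **SNR**: difference method, mean(r₁+r₂)/(√2·sd(r₁−r₂)) (sample SD,
  ddof = 1), reducing to μ/σ for i.i.d. additive noise; identical
  repeats give flagged infinite SNR.
* **Validation**: ordinary least squares of MR length on reference
  length (reference as abscissa), Pearson ρ, two-sided t-test p on the
  slope, SSE about the fitted line by default (µm²) with an
  identity-line option, since plots are conventionally drawn against
  the identity.

## Problem sizes and runtimes

Default analysis sizes were chosen so the full suite runs on a laptop
CPU in minutes: kernel-quadrature grid 5×5×5; Monte-Carlo oracles 10⁵
spins (3×10⁴ in unit tests); noiseless recovery on the full default
cohort (250 region-fits); repeatability behaviour at SNR ∈ {15, 50,
150} with 20 subjects and 5 rescans; σ calibration at 10⁴ pairs.

## Known limitations

ROI-mean fitting only (no voxelwise maps); no flow-compensated or
oscillating-gradient encodings; single intravascular compartment (no
fast/slow vascular split); no estimation of l from the fitted T0; the
two-step biases quantified above mean absolute accuracy of v and l
depends strongly on where the tissue sits between the flow regimes at
the protocol's diffusion times.
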