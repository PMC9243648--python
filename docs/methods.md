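# Methods

## Scope

`lrbcsim` couples three components: (i) a layered-skin Monte Carlo
photon-transport simulator, (ii) the two-wavelength modified Beer–Lambert
estimator of the red-blood-cell pathlength index L<sub>RBC</sub> and its
calibration arithmetic, and (iii) a synthetic lock-in reflectometer that
stands in for the measurement hardware. The simulator validates the
estimator; the synthesizer exercises the full signal chain.

## Skin model

The canonical model (`data/seven_layer_skin.yaml`) is a semi-infinite
stack of seven layers — stratum corneum (0.02 mm), vital epidermis
(0.08 mm), upper vascular plexus (0.1 mm, 20% blood at baseline),
reticular dermis (1.5 mm, 4%), deep vascular plexus (0.2 mm, 10%),
subcutaneous fat (1.0 mm, 5%) and muscle (semi-infinite, 40%) — each with
absorption μa (per wavelength and perfusion state), scattering μs,
Henyey–Greenstein anisotropy g and refractive index n. μs and g are
treated as independent of wavelength and blood fraction; the muscle
layer is held fixed at all perfusion states. Units package-wide: lengths
in mm, coefficients in mm⁻¹; L<sub>RBC</sub> converted to μm at output.

Perfusion is parameterized by a blood scale s ∈ [0.1, 3.0] multiplying
every baseline blood fraction (except muscle). At the tabulated scales
0.1/1.0/3.0 the fixture's μa values are authoritative and used verbatim
— including the vital-epidermis 780 nm column (0.338/0.339/0.338), which
is not monotone and is reproduced per column without smoothing. At
intermediate scales μa is the volume-fraction mixture
Cb·μa,blood + (1−Cb)·μa,tissue with per-layer blood/tissue coefficients
solved from the 0.1×/1.0× columns (upper plexus at 590 nm:
μa,blood ≈ 1.046, μa,tissue ≈ 0.0297 mm⁻¹). The tabulated columns are
*not* exactly linear in Cb — the linear fit overpredicts several 3.0×
entries (upper plexus 590 nm: 0.64 extrapolated vs 0.471 tabulated),
presumably a vessel-packaging-type correction whose form we do not
attempt to reverse-engineer. The package therefore logs a warning when
an intermediate-scale model is built for layers where the extrapolation
to 3.0× disagrees with the table by more than 2%.

## Monte Carlo transport

Standard weighted-packet conventions for multilayer media:

- launch at the origin, normal incidence; specular loss
  ((n_above−n₁)/(n_above+n₁))² at entry;
- step sampling s = −ln ξ/μt with dimensionless-pathlength continuation
  across boundaries; absorption deposit ΔW = W·μa/μt per interaction;
- Henyey–Greenstein polar angle via the inverse CDF (isotropic when
  g = 0), uniform azimuth;
- unpolarized Fresnel reflection/refraction at every index mismatch,
  with total internal reflection; exit through the top surface tallied at
  the radius √(x²+y²) of the crossing point (cylindrical symmetry);
- Russian roulette below weight 10⁻⁴: survive with probability 1/10 at
  ×10 weight (expectation-conserving). Threshold and survival factor are
  config-exposed since they are conventions, not physics.

Tallies are per incident packet: specular reflectance, diffuse
reflectance (with raw exit radii and weights retained), transmittance
(zero for semi-infinite models), absorbed fraction, and the net roulette
imbalance. Their sum closes to 1 at bookkeeping precision (~1e-9); with
the imbalance folded into the expectation, the physical components close
within 0.5% at 10⁵ packets. Radial profiles use 0.1 mm annuli centered
at 0.1·k mm (edges 0.05 + 0.1·k; innermost half-bin [0, 0.05) centered
at 0; overflow bin beyond `max_radius`). Detector-window intensities
(Ne) are computed from the raw exit radii, not the bins.

RNG: numba's per-thread Mersenne Twister, seeded explicitly inside the
kernel; a run is bit-reproducible from (model, config). Run averaging
uses per-run seeds base+k and reports the per-bin standard error.

Oracles in the test suite: Beer–Lambert transmittance of non-scattering
slabs (3 optical depths, 3 SE); the semi-infinite isotropic-scattering
benchmark Rd = 0.41749 at single-scattering albedo 0.9 with matched
boundary (the classic plane-albedo table value); exact pooled-versus-
averaged tally identities; cross-seed statistical consistency.

## The LRBC estimator

L<sub>RBC</sub> = [ln(I₀(590)/I₀(780)) + ln(Iₑ(780)/Iₑ(590))] /
[PF(590)·μ_eff(590) − RPF·μ_eff(780)], natural logarithms (a base-10
convention would rescale results by ln 10 ≈ 2.303). In simulation the
incident term is exactly zero (equal packets per wavelength); in
voltage mode it is ln of the calibrated ratio V₀(590)/V₀(780). Negative
values are returned with a warning, never clipped, so drift stays
visible; nonpositive voltage samples are flagged NaN, not dropped.

Constants and their provenance:

| constant | default | units | provenance |
|---|---|---|---|
| μ_eff ratio 590/780 | 14.87 | – | published red-blood-cell optical constants |
| PF(590) | 1 | – | convention: LRBC proportional to geometric pathlength |
| RPF = PF(780)/PF(590) | 2.20 | – | occlusion-calibration mean (see below) |
| V₀(590)/V₀(780) | 1.21 | – | bench calibration worked example |
| μ_eff(590) | 41.0 | mm⁻¹ | calibrated, see below |

**The absolute μ_eff scale is a calibration, not a literature value.**
Published blood optics constrains the 590/780 ratio (14.87) tightly, but
the absolute effective attenuation of red blood cells in perfused skin
microvessels is not separately fixed here, and plausible whole-blood to
packed-cell values span tens of mm⁻¹. We pin it with the model's
baseline operating point: the canonical model at baseline perfusion
gives ln(Ne₇₈₀/Ne₅₉₀) = 0.561 on the 0.5–1.2 mm window (5 × 10⁵
packets/wavelength), and μ_eff(590) = 41.0 mm⁻¹ places the baseline
L<sub>RBC</sub> at ≈ 16 μm — the scale one expects from the first-order
geometric estimate (a single traversal of the upper vascular plexus:
20% blood × 100 μm = 20 μm). Both μ_eff values are config-exposed, every
reported LRBC can carry the constants used, and *relative* LRBC changes
between perfusion states are exactly independent of this choice (the
scale cancels in ratios — a tested invariant).

Averaging order: Ne is averaged across runs first and one LRBC is
computed from the averaged intensities. (Computing per-run LRBCs and
averaging differs only at second order in the MC noise; the chosen
order matches averaging raw intensities before taking logs.)

## RPF estimation and V₀ calibration

During a venous occlusion the attenuation change at each wavelength is
ΔA(λ) = PF(λ)·μ_eff(λ)·ΔL<sub>RBC</sub>, so regressing Δln Vₑ(780) on
Δln Vₑ(590) and scaling the slope by 14.87 yields RPF. Implementation:
per-channel baselines are the arithmetic means over the pre-inflation
window; the regression is unweighted OLS with intercept (slope only
used) over 10–70 s after inflation — the first 10 s excludes the
inflation transient. Per-channel gains cancel in Δln, a tested
invariance. The estimate degrades gracefully with noise because the
780 nm excursion is only a few percent; recovery on the package's own
generator is ~5% (median, noisy) — consistent with the large
between-test spread such a regression shows on real skin.

V₀ calibration: V₀(λ) = VR(λ)·V₀′(λ)/VR′(λ) from the low-gain (V₀′,
VR′) and high-gain (VR) readings against a Delrin reflection standard;
only the 590/780 ratio enters the estimator. The bench worked example
(V₀′/VR′ = 1840 and 2880, VR ratio 1.89) gives 1.21.

## Synthetic reflectometer

What it emulates: LED carriers at 1100 Hz (590 nm) and 1000 Hz (780 nm)
sampled at 50 k-samples/s, intensity envelopes driven by an occlusion
scenario, additive white Gaussian noise proportional to the local
envelope, and software lock-in demodulation — windowed in-phase/
quadrature products, amplitude 2·√(⟨x·sin⟩² + ⟨x·cos⟩²) per 1000-sample
window (20 ms = 22 cycles at 1100 Hz and 20 at 1000 Hz, so the carriers
are exactly orthogonal per window; measured cross-talk < 10⁻⁶). Output
rate 50 samples/s. The hardware chain (DC offsets, 200 Hz high-pass,
photodiode gains) is collapsed into envelope × carrier + noise, because
the estimators are gain-invariant.

Scenario defaults are the study conditions: 180 s baseline / 180 s
occlusion / 180 s release; end-of-occlusion intensity drops 25% (590 nm)
and 3% (780 nm); monophasic scenarios ramp linearly, biphasic ones take
an initial step of 40% of the total drop (chosen so the implied LRBC
jump is ~4 μm, a clearly "near-vertical" onset) followed by a ramp;
exponential release recovery with τ = 10 s; relative noise sd 0.01 (1%
per raw sample leaves ≈ 0.04% envelope noise after the 1000-sample
lock-in, matching visually clean demodulated traces). Generation is
deterministic per seed.

For recovery tests with exact ground truth the generator also runs
inverse-first: given a target LRBC(t) and constants, the 590 nm envelope
is computed by inverting the voltage estimator with the 780 nm envelope
prescribed. The end-to-end suite recovers a configured 4 μm/min LRBC
ramp within 10% and the envelope-implied RPF within 5%/10%
(noiseless/noisy) across ≥ 20 seeds.

What the generator does *not* emulate: arterial pulsation, cuff-pressure
physiology, 1/f and mains interference, detector nonlinearity, probe
motion. Passing recovery tests therefore demonstrates correctness of the
estimator chain under the stated signal model, not robustness to every
artifact of real recordings.

## Numerical and design choices

- Lock-in filtering uses integer-cycle window averaging rather than an
  IIR low-pass; the real instrument's filter is unspecified, so exact
  orthogonality was preferred over fidelity to unknown hardware.
- Roulette threshold 10⁻⁴, survival 1/10; bins and overflow as above;
  all config-exposed.
- Degenerate inputs: zero-variance regressors, nonpositive intensities,
  mismatched grids and inconsistent constants raise immediately;
  the estimator denominator must be positive at construction.
- YAML model configs round-trip floats bit-exactly (repr-based); CSV
  output uses 9 significant digits.
- Problem sizes: the acceptance pipeline uses 10⁵ packets × 5 averaged
  runs per wavelength per blood scale, which puts the per-condition
  Monte Carlo standard error of Ne near 0.3% and of LRBC near 1%; the
  unit suite uses 10³–5×10⁴ packets per test.

## Known limitations

- The estimator treats blood and bloodless tissue as independent
  attenuators and compresses path statistics into a single pathlength
  factor per wavelength; it is an index calibrated to a model, not an
  absolute micrometry of vessels.
- The simulated detection annulus counts all exiting packets regardless
  of exit angle; a real fiber's numerical aperture and the slightly
  different 780 nm fiber offsets are not modeled. This biases the
  absolute 780/590 intensity contrast (and hence the μ_eff calibration
  above) relative to any specific instrument.
- Simulated LRBC responds somewhat asymmetrically to hypoperfusion
  (−36% at 0.1× blood) versus hyperemia (+49 to +51% at 3.0×) on this model
  and window; the relative-change invariants (monotonicity, μ_eff-scale
  independence) are the robust outputs.
- Intermediate blood scales interpolate the 0.1×/1.0× columns linearly
  in Cb; the tabulated 3.0× nonlinearity means interpolated hyperemic
  states above baseline are approximations.
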