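# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `psprmap`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Optical forward model

The chip is modeled as a stratified, isotropic, linear medium: semi-infinite
BK7 prism (n = 1.51), 2 nm chromium adhesion layer (3.24 + 3.49i), gold film
(0.16 + 5.34i, nominal 44–48 nm), a probe monolayer treated as a homogeneous
effective-medium slab, and semi-infinite aqueous buffer, all at λ = 850 nm.
These optical constants are fixed; only the incidence angle, Au thickness and
the probe slab's (thickness, index) are ever fitted.

Complex amplitude reflectivities r_p, r_s come from the Abelès
characteristic-matrix method with per-layer admittances q = cosθ/n (p) and
q = n·cosθ (s). The normal component n·cosθ is computed as √(n² − n₀²sin²θ₀)
with the branch Im ≥ 0 (decaying evanescent fields; on the real axis Re ≥ 0).
A second, interface-recursive implementation of the same physics exists purely
as a cross-check; the test suite holds the two to |Δr| < 1e−10 on random
stacks.

**Observable.** The instrument interferes p against s through an analyzer, so
the modeled signal is the p−s differential phase, baseline-referenced:
Δφ(n) = [φ_p(n) − φ_s(n)] − [φ_p(n₀) − φ_s(n₀)]. Because only differences
from baseline are used, the global phase-sign convention of r_p (which differs
between textbook formulations) drops out.

**Unwrapping.** Δφ is unwrapped along the RI grid; if the phase still moves by
more than π/2 between neighbors, midpoints are inserted (up to 8 rounds)
before giving up with an explicit grid-too-coarse error. The default working
grid is 301 samples over the calibration RI span extended by 10% on each side
("slightly larger than the data" made concrete; the margin allows moderate
extrapolation of converted signals beyond the calibration range).

## Meta-model

The sampled curve is split into three contiguous chunks of equal point count
(sizes differ by at most one) and each chunk is fitted with an ordinary
least-squares cubic. Polynomials are fitted and stored in the scaled variable
w = (ri − origin)/scale (origin = curve center, scale = half-span) so
coefficients stay O(1); the physical span is only ~3e−3 RIU and raw-coordinate
cubics would lose ~9 digits to cancellation. No continuity constraint is
imposed at the joints; the joint mismatch is monitored via the stored maximum
residual and tested to stay within 2× of it.

Inversion solves the cubic within each segment's domain and keeps real roots
inside the domain. With several candidates, the root nearest the previous
sample wins (temporal continuity); without history, the root on the monotone
branch containing the baseline is used. A phase that falls into the small gap
at a segment joint is mapped to the nearest attainable value provided the gap
is within 5× the fit residual; anything farther out of range raises — never
silent clipping.

**Capacity limit (important).** Near critical coupling (Au ≳ 46 nm at these
constants) the mapping curve concentrates 2.5–3.3 rad of phase swing into a
sub-1e−3 RIU knee. Three cubics track the 44 nm curve to ~4e−4 rad (below the
0.001 rad instrument noise) but only to ~5e−3 rad at 46 nm and ~5e−2 rad at
48 nm. This is a representational limit of the three-segment cubic scheme
itself, not of the fit; it propagates into the calibration SSR floor and into
cross-chip conversion agreement (see Limitations).

## Calibration optimizer

The objective builds the trial stack, computes the Fresnel curve, meta-models
it, and scores SSR = Σ_k (Δφ_meta(n_k) − Δφ_k)² in rad² over the five
calibration points, baseline included as an ordinary zero-phase residual with
equal weight. Degenerate trials (no resonance in the window, unwrap failure)
receive a large finite penalty (1e3 rad²) instead of raising, so the surrogate
can steer away from them.

The search is a seeded trust-region Gaussian-process expected-improvement
loop:

- Internally the angle is parametrized as an *offset from the trial stack's
  own resonance-dip angle* (dip located by a vectorized coarse scan plus
  parabolic refinement). Phase interrogation operates a fraction of a degree
  above the dip, and in dip-offset coordinates the SSR landscape is nearly
  separable — in absolute angle the optimum tracks the dip as the film
  parameters move, producing a narrow curved valley that plain GP-EI
  navigates poorly.
- 20 Latin-hypercube trials seed a Matérn-5/2 ARD GP on log10 SSR, fitted to
  the points near the incumbent; candidates are drawn inside an adaptive
  trust region (expand ×2 on repeated success, shrink /1.7 on repeated
  failure, restart wide on collapse), augmented with axis-aligned pattern
  moves and moves along the principal directions of the current best points
  (the equivalent-model ridge). Expected improvement and greedy GP-mean
  selection alternate.
- Everything is a pure function of (inputs, seed); identical seeds reproduce
  the trace bit-for-bit. Default budget: 120 iterations.

Single-wavelength pSPR cannot uniquely identify the probe layer: families of
(angle, d_Au, d_p, n_p) produce near-identical mapping functions. The package
treats mapping-function recovery as the contract and provides
`equivalent_model_check` (max |RI_a(φ) − RI_b(φ)| over a phase grid) to
quantify the degeneracy; two independent runs on the same calibration agree
to < 1e−5 RIU over the calibration phase range while their parameter vectors
differ in the third decimal or more.

## Conversion

Before inversion the mean phase over a leading baseline window (default 60 s;
the generator's staircase/binding fixtures hold baseline that long) is
subtracted. The Δ-RI reference point is the model's own inversion of phase 0,
which absorbs the meta-model's sub-noise residual at the baseline so an
all-zero phasogram converts to an all-zero sensorgram exactly. Samples outside
the model's valid phase range raise with the offending indices listed.
Consistency reports resample onto the intersection time window by linear
interpolation and tabulate pairwise RMS differences in RIU.

## Kinetics

1:1 Langmuir only. Association fits ΔS(t) = ΔS_max(1 − e^{−τ(t−t₀)}), with τ
read as the observed rate constant in s⁻¹ (τ = k_on·C + k_off). Dissociation
fits a single exponential with rate k_off; |k_off| < 1e−10 s⁻¹ is flagged
`no_decay`. Initial guesses are deterministic: ΔS_max ← last sample, τ ←
inverse time-to-63%, ΔS₀ ← first sample, k_off ← endpoint log-ratio.
`derive_constants` computes k_on = (τ − k_off)/C and K_D = k_off/k_on and
rejects τ ≤ k_off as a concentration/fit inconsistency. Note that with the
published anti-CD9 rates (τ = 1.88e−3 s⁻¹, k_off = 1.75e−4 s⁻¹ at
C ≈ 3.98e−8 M) this arithmetic yields K_D ≈ 4.09 nM.

## Instrument simulation (GLIA)

The beating model is I(t) = I₀(1 + µ sin ωt)[1 + m cos(Δϕ_a sin ωt − ϕ_SPR)]
with depth Δϕ_a = 2π(ne−no)βLΔi/λ₀². Demodulation correlates the
mean-removed record against RX = cos(Δϕ_a sin ωt) and RY = sin(Δϕ_a sin ωt).
The closed forms used for inversion are derived from this model via the
Jacobi–Anger expansion:

    X = (I₀m/2)[cosϕ·(1 + J₀(2a) − 2J₀²(a)) + µ sinϕ·(J₁(2a) − 2J₀(a)J₁(a))]
    Y = (I₀m/2)[sinϕ·(1 − J₀(2a)) + µ cosϕ·J₁(2a)] + I₀µJ₁(a)

The µJ₁(a) offset in Y has unknown scale relative to the quadratures and is
the reason the depth is tuned to the first J₁ zero (3.8317 rad), where it
vanishes; the remaining 2×2 linear system in (cosϕ, sinϕ) is inverted exactly
for the configured µ and the phase recovered by atan2, making extraction
invariant to positive rescaling of (X, Y). The high-pass filter is exact mean
removal over an integer number of periods — the simulator controls sampling,
so tests are bit-reproducible; a real instrument would use a causal filter.
Sampling uses ≥ 64 points/period so that aliased Bessel harmonics are below
1e−14.

## Synthetic world

Generators are pure functions of (parameters, seed). Defaults encode the
stated measurement conditions: five-point calibration at reference RIs
1.3342/1.3346/1.3349/1.3364 over a baseline buffer fixed at 1.3340 (running
PBS, just below the first NaCl reference; the buffer RI itself is a
convention), i.i.d. Gaussian phase noise σ = 0.001 rad, default ground-truth
chip at 66.4°, Au 46 nm, probe 7.5 nm (≈22 bp at 0.34 nm/bp) with effective
index 1.40, and an ROI-pair generator applying the documented Δd_Au = 1.2 nm,
Δθ = 0.05° offsets. Binding phasograms compose a Langmuir RI time-course with
the chip's exact Fresnel phase map (sample RIs are folded into the curve grid
so no interpolation error enters the ground truth).

What the generator does **not** emulate: bulk-vs-surface response separation,
baseline drift, temperature effects, film roughness/damping spread, spikes,
or camera/ROI spatial averaging. A green end-to-end test therefore
establishes correctness of the signal chain under the stated noise model, not
robustness to real-world artifacts.

## Known limitations

- **Sharp-chip meta-model bias.** As described above, the three-cubic scheme
  cannot represent near-critically-coupled chips (Au ≈ 46–48 nm with the
  ideal-constant film) at the 0.001 rad level. Consequences, all measured by
  the acceptance tests: the 46/48 nm fidelity checks exceed 1e−3 rad; the
  noiseless five-point SSR at the *true* chip parameters is ~7e−6 rad²
  (log10 ≈ −5.15) for the default 46 nm chip, so deep (< 1e−6 rad²) optima
  exist only in thin corner regions of the parameter box that a 150-trial
  search rarely reaches; and conversions through 48 nm chips carry ~1e−5 RIU
  systematic error at the flat ends of the curve. Real films' broader
  resonances (roughness, damping) are gentler — the 44 nm family member
  passes all of these checks with margin.
- Parameters are reported for completeness but are not physically
  interpretable individually (single-wavelength degeneracy).
- No multi-wavelength or spectral modeling; no anisotropic or graded layers;
  no mass-transport-limited or bivalent kinetics.
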