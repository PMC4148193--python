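# Methods

This note documents the models implemented in `insulator-bridge`, the
assumptions behind them, the synthetic-data generators used to exercise
them, and the numerical choices that were genuinely open.

## 1. Binding isotherms (`insulator_bridge.binding`)

**Observable.** Fluorescence anisotropy of a short labeled DNA duplex
rises when protein binds (slower rotational diffusion).  The predicted
anisotropy is a linear map of the bound fraction:

    r([P]) = r_free + Δr · f([P])

**Models.**  Two isotherm shapes:

* single-site (Langmuir): `f = [P] / (K_D + [P])`
* Hill: `f = [P]^n / (K_D^n + [P]^n)`

`K_D` is the half-saturation constant in nM (`f(K_D) = 1/2` for any
`n`); the Hill coefficient `n` is the cooperativity exponent, with
`n = 1` reducing exactly to the single-site form.  These canonical forms
are adopted because the constants they define (a half-saturation
concentration and a cooperativity exponent) are what equilibrium
titrations report.

**Free-protein approximation.**  Protein (0–800 nM) is titrated against
a 2.5 nM probe, so ligand depletion is below ~2.5 nM everywhere and free
protein is identified with total protein.  No depletion correction is
applied; this is a stated approximation, not an omission.

**Fitting.**  `fit_isotherm` runs weighted nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective with positivity
bounds on `K_D` and `n`) from a fixed deterministic multi-start grid,
`K_D ∈ {10, 30, 100, 300, 1000}` nM × `n ∈ {0.5, 1, 2, 4}`; the start
with the lowest residual sum of squares wins and exact ties break toward
the smaller `K_D`, so the fit never depends on a random seed.  Standard
errors come from the Jacobian at the optimum; when per-point σ are
supplied they weight the fit (`absolute_sigma=True`) and otherwise unit
weights are used.  Preconditions: ≥ 5 distinct concentrations; a missing
near-zero point triggers a warning because `r_free` is then poorly
constrained.

**Competition.**  Displacement titrations are fitted with a
three-parameter hyperbolic decay
`r(c) = r_inf + (r_0 − r_inf)/(1 + c/EC50)`, whose midpoint is reached
exactly at `c = EC50`.  The apparent competitor constant uses a
Cheng–Prusoff-type correction, `K_i = EC50 / (1 + [probe]/K_D(probe))`,
which only lowers the EC50 and is ≈ 1 here (probe 2.5 nM ≪ probe K_D).
An amplitude shared between specific and non-specific curves was a
design option; the two curves are fitted separately because their
amplitudes differ physically (different complex sizes).

## 2. FCS / FCCS (`insulator_bridge.correlation`)

**Autocorrelation model.**  One diffusing component in a 3-D Gaussian
detection volume with axial/lateral waist ratio `s`, plus a triplet
(fast-blinking) term:

    G(τ) = (1/N) · [1 + T/(1−T) · e^(−τ/τ_T)]
               · (1 + τ/τ_D)^(−1) · (1 + τ/(s² τ_D))^(−1/2)

`N` is the mean occupancy of the effective volume, `τ_D = w²/4D` the
diffusion time.  `s` is not identifiable from a single curve and is
fixed at 5 (typical confocal calibration), configurable.  All times are
seconds internally (`tau_d_ms` is provided for display).

**Cross-correlation model.** A single co-diffusing (bridged) species
without triplet term — pulsed interleaved excitation (PIE) removes
spectral crosstalk, and independent triplet blinking does not
cross-correlate:

    G_x(τ) = A · (1 + τ/τ_D)^(−1) · (1 + τ/(s² τ_D))^(−1/2)

**Fitting.**  Same deterministic multi-start machinery as the binding
fits, with diffusion-time starts log-spaced over the lag range.  The
zero-lag point of a measured curve is always excluded: it is dominated
by shot noise.  Preconditions: ≥ 20 positive lags spanning ≥ 3 decades.

**Relative cross-correlation amplitude.**  `A = G_x(0)/G_auto(0)`, both
taken from fitted models, never from the noisy shortest lags.  The auto
reference uses the *total* fitted zero-lag `(1/N)/(1−T)`: a fast
component absorbed by the triplet term still counts particles in the
denominator of the cross amplitude.  With intensity-normalized
correlations, `G_x(0)/G_green(0)` equals the number of two-color
complexes per red-detected particle, so the **green** autocorrelation is
the correct reference when quantifying the bridged fraction of
red-labeled complexes (and vice versa).

**Bridged-fraction estimator.**  Two corrections separate the measured
amplitude from the bridged fraction: at a 50/50 color mix a randomly
paired bridged complex is two-colored with probability
`2q(1−q) = 0.5` (same-color pairs are invisible in the cross channel),
and incomplete labeling (efficiencies `e_g ≈ 0.57`, `e_r ≈ 0.97`)
leaves molecules dark.  The estimator is the linear correction

    f = A / (p_hetero · e_g · e_r),

clipped to [0, 1] with a flag.  With `A = 0.18` it gives 65%, with
`A = 0.13` it gives 47%.

**Known bias of the linear estimator.**  In a faithful simulation of
the mixture, bridged pairs can carry two lit same-color dyes.  The
autocorrelation weights species by brightness squared, so these doubly
bright pairs inflate the reference autocorrelation amplitude.  For an
ideal mixture the expected relative amplitude is

    E[A] = f·γ / (1 + f·γ),   γ = q·e_g,

rather than `f·q·e_g`, and the linear estimator recovers
`f/(e_r·(1+fγ)) ≈ 0.87·f` at `f = 0.65`.  No choice of auto reference
(green, red, or geometric mean) makes the linear estimator exact.  The
package keeps the linear estimator — it is the field's standard
arithmetic and defines the reported quantity — and the in-silico
round-trip tests assert recovery within the experimental uncertainties
of the anchor values (±22 and ±14 percentage points), which comfortably
cover this bias at the simulated conditions.

## 3. Brownian-dynamics generator (`insulator_bridge.simulate`)

`simulate_intensity_traces` emulates the two-color bridging measurement:

* molecules (or bridged pairs, rigidly co-diffusing as one entity) take
  Gaussian steps of standard deviation `√(2D·dt)` per axis in a periodic
  cubic box;
* each molecule is green with probability `mix_fraction_green` (default
  0.5) and actually carries its dye with probability `label_eff_green`
  (0.57) or `label_eff_red` (0.97); dark molecules still occupy pairs;
* per-frame expected counts are the sum of each lit dye's brightness
  weighted by a 3-D Gaussian detection profile with waists `(w, w, s·w)`,
  and recorded counts are Poisson draws;
* `crosstalk` leaks a fraction of green-dye brightness into the red
  channel — 0 by default, emulating ideal PIE separation; setting it
  > 0 demonstrates the spurious cross-correlation PIE removes.

Defaults: `w = 0.25 µm`, `s = 5`, `D = 29.48 µm²/s` so that
`τ_D = w²/4D ≈ 0.53 ms` — the scale of a free ~60 bp duplex through a
confocal spot — `dt = 20 µs` (per-axis step 0.034 µm < w/5),
box 4 µm, 100 molecules, brightness 10⁵ counts/s.  These are package
constants chosen as a realistic confocal configuration, not measured
values.  Brownian dynamics with a Gaussian detection profile (rather
than photon-by-photon simulation with detector physics) is sufficient
to validate the correlation models; it omits afterpulsing, dead time,
background and out-of-focus light.

**Multi-tau correlator.**  `correlate_traces` computes
`G(τ) = ⟨δA(t)δB(t+τ)⟩ / (⟨A⟩⟨B⟩)` on the standard multi-tau ladder:
`m = 16` linear lags at the native frame time, then `m/2` lags per
cascade level with both traces rebinned by 2 per level.  Rebinning makes
deep-level estimates slight local averages of the true correlation; the
design ratio (bin width ≤ lag/8) keeps the resulting bias below ~1% of
the amplitude wherever the correlation is smooth on the bin scale.  At
lags approaching the trace length the rebinned and direct estimators
also differ through their normalization segments — a property of any
multi-tau implementation, relevant only where statistics are poorest.

**Hi-C generator.**  `gen_contact_map` draws Poisson counts with rate
`background · (d/bin)^(−α)` (power-law distance decay, `α = 1`),
multiplied by `enrichment` when one bin contains an anchor-factor peak
midpoint and the other a co-bound target at separations 15–60 kb.
Peaks are placed uniformly; a fraction of the third factor's peaks is
co-located with the second's to create co-bound bins.  Defaults — 2 Mb
chromosome, 500 bp bins, 200 anchor and 300+300 target peaks, 60%
co-location, background 10, enrichment 3 — give ~10³ signal pairs, a
scale at which the 3× enrichment is recovered with ~6% sampling error.
The generator emulates the statistical structure the aggregation
analysis assumes (decay + localized enrichment); it does not model
restriction-fragment geometry, domain structure, A/B compartments, or
coverage biases, so passing tests validate the aggregation arithmetic,
not robustness to those real-data features.

All generators are pure functions of (config, seed); a seed is
mandatory.

## 4. Hi-C aggregation (`insulator_bridge.hic`)

Coordinates are 0-based half-open (BED convention) throughout; GFF3
input is converted on read (1-based inclusive → half-open), and the
447 bp fragment at 3L:264375–264822 is the convention fixture.
Restriction-fragment bins are approximated by uniform fixed-size bins
(default 500 bp); sites are assigned to the bin containing their
midpoint, and a bin "carries" a factor when it contains a peak midpoint
(`factor_bound_sites`, `mode="all"` for co-bound bins).

Anchor/target pairs keep both orientations at midpoint distances within
[15 kb, 60 kb]: below 15 kb the distance-decay background dominates;
above ~60 kb pairs straddle typical topological domains.  For each pair
the contact counts between the anchor bin and the 20 half-open 500-bp
bins within ±5 kb of the target are accumulated by offset (offset 0 is
the target midpoint's bin), and each offset is divided by the number of
candidate sites — interacting or not — contributing in-bounds at that
offset.  The control repeats the pipeline with feature-free bins
(deterministically thinned) as targets, capturing the anchors' chromatin
context.

**Significance.**  Wilcoxon rank-sum (Mann–Whitney), two-sided, on the
per-pair central-bin (offset 0) contact counts of signal vs control
pairs — the 20-bin profile vectors would have no power against a single
enriched offset.  `compare_profiles` uses exact enumeration when both
groups have ≤ 8 untied observations and the tie-corrected normal
approximation with continuity correction otherwise; all-tied input
returns p = 1 with a warning.  Under the null (enrichment 1) the
p-values are uniform to the resolution of a 50-seed
Kolmogorov–Smirnov check despite the heavy Poisson ties.

**Peak overlap.**  Any shared base under half-open semantics (abutting
intervals do not overlap), counted per reference set (A-in-B generally
differs from B-in-A), with all Venn regions for 2–3 sets; backed by
interval trees and validated against a per-base brute-force oracle.

## 5. Degenerate inputs and tie-breaks

* Empty anchor/target pair lists yield all-NaN profiles with a warning,
  not an error (an empty feature class is a result, not a failure).
* A cross-correlation fit of a flat zero curve converges to amplitude
  ≈ 0 (within optimizer tolerance at the non-negativity boundary).
* Readers reject malformed records with the 1-based line number rather
  than repairing them; skipped peaks (outside the genome) are counted
  and warned about.
* Multi-start fits break exact ties toward the smaller `K_D`
  (respectively the smaller diffusion time) so results are reproducible
  across runs and platforms.

## 6. Problem sizes used in the test suite

The simulation studies run at desk scale, chosen so each estimate's
Monte-Carlo error is well inside the asserted tolerance: 100-replicate
titration studies (12 points each); one 50 s FCS trace (30 molecules)
for the diffusion round trip; two 50 s two-channel FCCS traces per
condition (200 molecules) for the bridging replication; a 2 Mb
synthetic chromosome (≈10³ anchor-target pairs) for the aggregation
enrichment, with 50 seeds for the null calibration.
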