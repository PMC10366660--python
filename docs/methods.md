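# Methods

`inta` implements interferometric nanoparticle tracking analysis: the joint
estimation of a nanoparticle's hydrodynamic diameter and effective
refractive index (RI) from a single-particle tracking recording, and the
use of that pair to discriminate extracellular vesicles (EVs, RI ≈ 1.37)
from large lipoproteins (chylomicrons/ULDL and VLDL, RI ≈ 1.45–1.57),
which overlap EVs in size and dominate them in number in blood plasma.

## Measurement model

A particle diffusing in an aqueous buffer is observed at frame rate
`1/Δt` inside a bounded observation volume (field of view × axial
detection slab). Two observables are formed per particle:

* **Diffusion → size.** Per-axis displacements obey `Var(Δx) = 2DΔt`;
  the Stokes–Einstein relation `D = k_B T / (3π η d)` converts the
  diffusion constant to a hydrodynamic diameter. Defaults: `T = 298.15 K`,
  `η = 8.9×10⁻⁴ Pa·s` (water at 25 °C).
* **iSCAT contrast → cross-section → RI.** The interferometric contrast
  scales with the scattered field, `C = A·√σ`, where `σ` is the total
  scattering cross-section and `A` an instrument calibration constant.
  Given `d` and `σ`, the *effective RI* is the index of the homogeneous
  sphere that reproduces `σ` at that size, found by inverting the
  Lorenz–Mie series (module `mie`). In the operating regime (d ≤ 250 nm
  at λ = 525 nm, n ≤ 2.5) `σ(n)` is strictly increasing, so the inversion
  is unique; at d = 300 nm the first Mie resonance caps the monotone
  domain near n ≈ 2.4.

Optics defaults are `λ = 525 nm` (vacuum) and `n_m = 1.33`; both are
configuration, not physics — they only shift the contrast↔σ calibration,
which is itself configurable.

## Diffusion estimation

`estimate.estimate_diffusion` uses the covariance-based estimator (CVE)

    D̂ = ⟨Δx²⟩/(2Δt) + ⟨Δx_t·Δx_{t+1}⟩/Δt,

averaged over x and y, with consecutive-frame displacements only. The
lag-1 covariance term cancels i.i.d. static localization noise, making the
estimator unbiased without tuning parameters; its standard error comes
from the known CVE variance formula and is stored per record.

## RI precision gate (IQR_S)

RI precision collapses for weak scatterers: the relative error on contrast
grows as σ shrinks, and the same contrast error maps to a larger RI error
for small particles. To quantify this per particle, `simulated_iqr`
redraws the particle's per-frame contrasts about its measured contrast
(`sd` = the configured per-frame contrast noise, or the trajectory's
empirical sd), re-takes the median, re-inverts to RI at fixed diameter,
and reports the interquartile range of the resulting RI sample (`IQR_S`).
Records pass the precision gate when `IQR_S < 0.05` (configurable);
population RI medians use passing records only. Inversion inside the
Monte Carlo uses a cached monotone σ(n) lookup table (512 points on
[n_m, 2.5]); out-of-bracket draws clamp to the bracket edges.

## Synthetic measurements

`simulate` generates ground-truth-labelled recordings:

* **Populations.** Diameters are lognormal and RIs truncated-normal, both
  matched to a median and interquartile range (log-sd = ln(q75/q25)/2z₀.₇₅).
  Shipped presets (median (IQR)): EV 97 (79–120) nm, RI 1.37 (1.36–1.38);
  ULDL 57 (48–71) nm, RI 1.52 (1.48–1.57); VLDL 46 (41–52) nm, RI
  1.49 (1.45–1.52), with concentrations 1.58×10¹², 8.56×10¹³ and
  2.80×10¹³ /mL respectively.
* **Trajectories.** 3D Brownian steps (per-axis variance 2DΔt) at 5 kHz,
  entry uniform in the observation volume at t = 0, truncation at the
  first frame outside the 7.1 µm FOV or the ±1 µm axial slab. The axial
  detection depth defaults to 2.0 µm: iSCAT detects sub-wavelength
  particles over a few µm of defocus, and a first-passage analysis shows
  that a ±0.5 µm slab would discard ~70% of trajectories at the >100
  localization filter while skewing the kept sample ~10% large — harsher
  than any real recording of this kind.
* **Contrasts.** `C = A√σ + N(0, noise_sd)` per frame, with defaults
  `A = 5×10⁻³ /√nm²` and `noise_sd = 2×10⁻³`, chosen so EV contrasts are
  ~10⁻² (typical for iSCAT), per-frame SNR is ~4.6 for a median EV and
  ~1.8 for a median VLDL, and the IQR_S = 0.05 gate bites below
  d ≈ 35–50 nm — reproducing the qualitative observation that RI becomes
  imprecise for small biological particles.
* **Counts.** Expected trajectory count = total concentration × detection
  volume (FOV² × depth ≈ 10⁻¹⁰ mL), Poisson-distributed and split
  multinomially by population concentration. Because particles enter only
  at t = 0, counts are duration-independent; concentration calibration and
  application use the same convention, so the factor absorbs it.

What the generator does **not** model: axial contrast modulation
(contrast is constant per particle up to additive noise), hydrodynamic
wall effects, particle–particle interactions, flow, re-entering particles
(a re-entry would be a new particle id), and polydisperse shape or
core–shell structure. Passing tests therefore demonstrate correctness of
the estimation chain under these idealized conditions, not performance on
real recordings with depth-dependent contrast or drift.

## Population summaries and acquisition-bias corrections

The per-record estimates are deliberately raw. `population_summary`
applies two corrections when reporting population medians:

1. **Survival reweighting.** Slow (large) particles survive the
   >100-localization filter more often; kept samples over-represent them
   (measured ≈ +6% on the EV preset median). Each record is weighted by
   the inverse of the Monte-Carlo survival probability of its diameter
   under the configured geometry (length-biased sampling correction).
2. **Log-convexity shrinkage.** `d ∝ 1/D̂` turns symmetric noise in `D̂`
   into a right-skewed factor whose log-mean is ≈ Var(D̂)/2D̂²; each
   diameter is shrunk by `exp(−Var/2D²)` using the record's own CVE
   standard error (measured ≈ +2% on the median without it).

Both corrections derive from the acquisition model, carry no free
constants, and can be disabled (`selection_correction=False`).
Classification features remain uncorrected.

## Classification

A random forest (200 trees, class-balanced bootstrap, fixed seed) is
trained on pure-sample record tables over (diameter, log₁₀σ, RI); log σ
only stabilizes the decades-spanning cross-section for inspection — tree
splits are scale-invariant. `P(EV) ≥ 0.8` labels EV, `P(LP) ≥ 0.8` labels
LP, anything between is *unclassified*; ties go to the label. Relative EV
concentration is `n_EV/(n_EV+n_LP)` among confidently classified records.
Expected mixture fractions are formed the way a bench comparison would
form them — from the kept-trajectory rates of the measured pure samples —
since EVs and VLDLs pass the localization filter at different rates.

## Image-level stage

`frames` closes the loop at the pixel level. Rendering stamps each
localization as a radially symmetric spot (Gaussian core, σ = 1.6 px, one
negative ring at r = 4 px) with peak amplitude equal to the contrast on a
unit background, plus Gaussian pixel noise. Recovery:

* **Background.** Pixel-wise rolling temporal median (subtract or divide
  mode). An optional `median_guard` excludes the central ±g frames from
  the window: a slowly diffusing particle lingers near its own past
  positions, and a plain centred median partially contains it, leaving a
  motion-correlated residue that biased CVE diffusion estimates by ~+18%
  in our measurements; a guard of 30 frames at a 201-frame window reduced
  that to ~+2%. The first and last window/2 frames of a stack use
  edge-replicated medians and are degraded; a negligible fraction of a
  10-minute recording, but synthetic closure movies carry particle-free
  pre/post-roll for this reason.
* **Detection.** Radial variance transform: per pixel, the variance of
  mean intensities on integer-radius rings r ∈ [1, 6]; ring means are
  normalized by the in-frame ring fraction so the response is exactly
  zero on constant frames and offset-invariant everywhere. Local maxima
  above a robust threshold (median + 8×1.4826×MAD of the response),
  separated by at least the ring diameter, are refined to subpixel by
  3-point parabolic interpolation (~0.2 px at amplitude SNR 5).
* **Linking.** Greedy nearest-neighbour within
  `4√(2·D(40 nm)·Δt)/pixel` by default, with `link_memory = 3` frames of
  gap tolerance (distance cap growing diffusively with the gap): with
  zero memory the probability of recovering an L-frame track intact is
  `(1−p_miss)^L`, which collapses for L > 150 at any realistic per-frame
  miss rate. Trajectories with ≤ 100 localizations are discarded.

## Concentration and plasma back-calculation

A through-origin least-squares line of known concentration against
trajectories-per-10-minutes over a bead dilution series (≥3 points
spanning ≥10×) gives the calibration factor; sample concentration is
`count × (600 s/duration) × factor × dilution`. The plasma concentration
before EV enrichment is `measured / (recovery × V_plasma/V_final)` with
shipped presets SEC (80%, 0.5→0.1 mL), DMC (33%, 0.5→0.1 mL) and DG
(25%, 6→0.1 mL). Reported values round to 2 significant figures; full
precision is kept internally. No size-dependent detection-efficiency
correction is applied to counts — a known limitation of the
absolute-concentration route, which is calibrated against a single bead
size.

## Problem sizes

Default verification sizes, chosen to give each check adequate
statistical power on a single CPU: parameter recovery uses ~600–1200 kept
trajectories; mixture quantification trains on ~800 EV/700 VLDL records
and quantifies five mixtures of ~650 records each; the detection closure
renders twenty 64×64 px movies of three particles each (~23 tracks longer
than 150 frames, ~10⁴ pooled displacements). The precision-gate grid runs
400 Monte-Carlo draws per cell.

## Known limitations

* The contrast noise level and calibration amplitude are simulation
  parameters, not instrument measurements; absolute mislabel rates
  depend on them (the qualitative ordering does not).
* The effective-RI model is a homogeneous sphere; core–shell vesicle
  optics and absorption are out of scope.
* Trajectory truncation at the volume boundary is abrupt; real contrast
  fades with defocus.
* Concentration quantification inherits the bead-calibration convention
  and applies no detection-efficiency correction across sizes.
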