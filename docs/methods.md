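# Methods

This note documents the model, the numerical choices, and the limits of what
the synthetic experiments can demonstrate.

## Tissue model and chromophores

The skin model has three plane-parallel layers: an epidermis of adjustable
thickness `t_epi`, an upper dermis fixed at 0.2 mm (approximately the upper
vascular plexus), and a semi-infinite lower dermis.  Deeper structures
(lower plexus, subcutis) are not modeled separately; their influence on
reflectance at ≤1.2 mm source–detector separation is minor.  All layers
share one reduced-scattering spectrum — a Mie power law plus a Rayleigh
(λ⁻⁴) term, both normalized at 600 nm, so the amplitude α *is* μs′(600).
Epidermal absorption is a melanin power law, 48.4 (λ/550)⁻ᵝᵐᵉˡ mm⁻¹ at unit
melanin fraction, with the slope β_mel free so that different melanin types
can be represented.  Dermal absorption mixes tabulated oxy- and
deoxyhemoglobin whole-blood spectra by the saturation `s` (shared by both
dermis layers), scaled by the blood tissue fraction of each layer and by a
vessel-packaging factor.

Whole-blood absorption assumes hematocrit 0.43 and MCHC 345 g/L RBC
(≈148.35 g hemoglobin / L blood; molar mass 64 500 g/mol) and the
natural-log convention.  The bundled extinction table
(`data/hemoglobin_extinction_synthetic.tsv`) is a **synthetic
re-tabulation**: smooth anchor values reconstructed to approximate the
published oxy (Zijlstra-family) and deoxy (Prahl-family) compilations with
the correct band structure (Q-band twin peaks at ~542/576 nm for HbO₂, the
single 555 nm Hb peak, the ~758 nm deoxy bump and the NIR isosbestic point,
here at ≈796 nm).  Point values are only accurate to roughly ±15 %.  This
limits absolute comparability of fitted blood fractions with
instrument-grade analyses, but none of the package's validation quantities
depend on the absolute hemoglobin scale: the sampling-depth simulations take
their absorption coefficients directly from the published median optical
properties, and the parameter-recovery study generates and refits spectra
with the same table.

### Vessel packaging

The correction uses the cylindrical-vessel mean-transmittance form
c_vp = (1 − exp(−2 μa,bl R)) / (2 μa,bl R), equivalent to averaging
Beer–Lambert transmittance over traversal lengths uniform on [0, 2R].  The
default vessel radius is R = 5 µm (configurable); with median blood
parameters this gives c_vp ≈ 0.85–0.95 across the band, consistent with the
magnitude of published dermal absorption medians.  c_vp is evaluated at the
saturation-mixed blood absorption rather than per hemoglobin species; the
difference is far below the other model uncertainties.

## Monte Carlo engine

Transport is simulated without absorption ("white" Monte Carlo): photon
steps are drawn from the scattering coefficient alone, and the geometric
pathlength inside every layer is recorded per detected photon.  Any
absorption spectrum can then be applied afterwards by multiplying each
photon's weight with exp(−Σ_l μa,l L_l), which is what makes a single photon
basis reusable across all wavelengths and chromophore settings.

Optical constants not fixed by the instrument description are declared
defaults: Henyey–Greenstein phase function with g = 0.8 in all layers,
tissue index 1.4, probe-side (fiber contact) index 1.5, fiber core radii
0.1 mm, numerical aperture 0.37.  Launch positions are uniform over the
source fiber face with directions in the fiber acceptance cone; Fresnel
reflection/refraction is applied at the probe interface and any internal
index step.  Detection exploits rotational symmetry: a photon leaving the
surface within the acceptance angle anywhere on the annular ring
|r − ρ| ≤ r_fiber is recorded with the weight factor r_fiber/(4ρ) (fiber
face area over ring area), which reduces variance by roughly the ring/face
area ratio without biasing any of the per-photon quantities.

Photons are terminated by escape, by Russian roulette below weight 10⁻⁴
(survival factor 10 — inactive in absorption-free runs, where weights stay
at 1), or by crossing a maximum tracked depth (default 20 mm) or total
pathlength (default 2 m).  With absorption applied downstream, paths long
enough to reach those cutoffs carry weights that are negligible for both
reflectance and the 63 % depth quantile at these separations; energy
conservation in the matched-index absorption-free test is verified with the
cutoffs widened.  The random stream is an inline xorshift64* generator;
runs are bit-reproducible for a fixed seed and batch size, with per-batch
and per-cell seeds derived through `numpy.random.SeedSequence`.

The photon basis is a grid over epidermis thickness
{0.015, 0.04, 0.08, 0.15, 0.25} mm and reduced scattering
{0.4 … 7.0} mm⁻¹ (log-spaced; the level value is μs′ of the simulated,
wavelength-agnostic cell).  Cells are three-layer stacks with homogeneous
scattering, so layer boundaries are optically transparent and only the
pathlength bookkeeping differs between thickness levels.  Model spectra are
interpolated bilinearly in (t_epi, log μs′) — the log axis linearizes the
dominant scattering dependence — and at grid nodes the interpolation
reproduces the node evaluation exactly.  Spectra are synthesized
photon-by-photon (the stored-pathlength reference route); the basis
serializes losslessly to HDF5.

## Inverse solver

The objective is the sum over both detectors of squared relative residuals
on the unmasked channels (the 770–810 nm notch of the instrument's laser
filter is carried but ignored), after profiling out one multiplicative scale
factor per detector in closed form — the instrument has no absolute
intensity calibration, and the scale minimization k = Σy/Σy², y = model /
measured, is exact.  The cost function of the original instrument's
analysis is not published; relative least squares with profiled scales is
this package's choice.

Minimization is bounded trust-region-reflective least squares over the nine
free parameters, bounds α∈[0.5,5], β∈[0,4], γ∈[0,1], t_epi∈[0.01,0.3] mm,
f_mel∈[0,1], β_mel∈[1,8], f_blood∈[0,0.1], s∈[0,1].  Because the
nine-dimensional landscape has distant near-equivalent basins — epidermal
thickness and melanin fraction trade off at nearly constant absorbance
product — the search is structured: 24 Latin-hypercube starts (melanin and
blood fractions drawn log-uniformly), short polish runs from the 12 most
promising, full convergence (tolerance 10⁻⁸) from the best two, and finally
product-preserving "basin hops" that re-optimize from kicks along the
(t_epi, f_mel) degeneracy.  On noiseless synthetic spectra this reaches the
global optimum (objective ≲10⁻¹⁵) reliably; on noisy spectra residuals land
at the noise floor.  Scattering parameters that would push μs′(λ) outside
the basis grid are clipped during evaluation and discouraged by a soft
penalty residual.

Exclusion rules mirror the cohort pipeline's data-quality screening: fits
with relative RMS residual above 0.10 or fitted upper-dermis blood fraction
below 0.002 are flagged (reasons "fit error" / "low blood").  Both
thresholds are package defaults; the original thresholds are unpublished.

## Sampling depth

For each detector and wavelength, a point cloud is drawn with exactly 20
positions (configurable) uniform in arc length along every detected photon's
path, each point weighted by the photon's absorption-scaled final weight.
The sampling depth is the depth at which the cumulative weight of the
depth-sorted points first reaches 1 − 1/e ≈ 63 % of the total, with linear
interpolation between adjacent points to remove discretization bias for
small clouds.  Per-wavelength depths for a parameter set are evaluated at
the four bracketing basis cells and combined bilinearly.

## Synthetic cohort

The real cohort's raw spectra are access-restricted, so the generator
emulates them: each subject's parameters are drawn independently from
marginals whose median and quartiles match the published cohort values
(log-normal for the positive skewed parameters, with σ = ln(q75/q25)/2z₀.₇₅
and the median matched exactly; truncated normal for saturation).  The
epidermis is parameterized through the melanin absorbance product
μa,epi(570)·t_epi — the quantity the inverse problem actually determines and
whose cohort distribution is published — with the melanin fraction derived
per subject from the product, thickness and slope.  Drawing thickness and
melanin fraction independently instead produces joint extremes (thick and
fully pigmented epidermis at the same time) that the real cohort does not
contain and that destroy blood-parameter identifiability.  True
between-parameter correlations are unpublished; independence of the
remaining marginals is an explicit modeling choice, and draws whose
scattering spectrum or thickness would leave the basis grid are redrawn
(this touches only far tails, leaving medians intact).  An optional seasonal
multiplier modulates the melanin product by measurement month (summer ≈2.5×
the early-spring minimum); it is off by default.

Measured-like spectra are the forward model output times per-channel
multiplicative Gaussian noise (default sd 1 %) plus an optional additive
floor (default 0), on a 5 nm wavelength grid with the notch mask applied.
What the synthetic experiments therefore demonstrate is *internal*
consistency — that the inverse solver recovers the generating parameters
under the declared noise — not robustness to instrument drift, probe
pressure, inter-subject phase-function variation, or chromophores absent
from the model.

## Problem sizes and accuracy of the validation quantities

The acceptance computation uses 3.2×10⁶ launched photons for the 475 nm
depth case (~3×10⁴ detected paths at 0.4 mm) and 8×10⁶ for 850 nm
(~2.7×10⁴ at 1.2 mm); the depth quantile's Monte Carlo standard error is
well below 1 % at these sizes, so the comparison against the published
values is bias- not variance-limited.  The recovery study uses a
30 000-photon-per-cell basis, 50 subjects and 1 % noise.  At that noise the
90th-percentile saturation error comes out at ≈3–4 percentage points and
the 90th-percentile relative blood-fraction error at ≈18–28 % depending on
the cohort draw.  The worst-decile subjects are low-blood draws
(f_blood,1 ≈ 0.002–0.008) whose blood parameters are intrinsically weakly
identified: refitting them starting from the true parameters reproduces the
same errors at equal or lower objective, so these figures reflect the
information content of the spectra under the declared noise model, not
solver quality.  This is the same phenomenon that motivates the pipeline's
low-blood exclusion rule, whose default threshold (0.002) flags only the
most extreme cases.

## Known limitations

- The hemoglobin fixture is an approximate reconstruction (above).
- Probe details of the commercial instrument (true fiber radii, NA, index
  assumptions) are unpublished; the declared defaults reproduce the
  published sampling depths within ~10 %.
- The phase function is a single Henyey–Greenstein with fixed g; fitted
  scattering amplitudes are conditional on that choice.
- Epidermal thickness and melanin fraction are reported individually by the
  solver but only their product is trustworthy.
- The statistics module reproduces the cohort-study machinery
  (median/IQR summaries, Mann–Whitney, Kruskal–Wallis with Dunn–Bonferroni
  post hoc, OLS age trend); the published group-difference tables themselves
  require the restricted cohort data and are out of scope.
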