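# skindrs

Inverse Monte Carlo analysis of diffuse reflectance spectroscopy (DRS) of
human skin: a three-layer tissue model, a white Monte Carlo photon-transport
engine, spectral synthesis by Beer–Lambert pathlength scaling, a multi-start
inverse solver, a photon sampling-depth statistic, a synthetic-cohort
generator, and the nonparametric statistics used for cohort summaries.

## Who this is for

Fiber-probe DRS instruments measure broadband light (475–850 nm here)
backscattered from skin at short source–detector separations (0.4 and
1.2 mm).  Inverting such spectra with a layered Monte Carlo model yields *in
vivo* optical properties of direct clinical interest — hemoglobin tissue
fraction, oxygen saturation, melanin content, reduced scattering — without
biopsies.  This package implements that full analysis chain for a
three-layer skin model and is aimed at researchers in tissue optics who want
a tested, reproducible reference implementation.

## The model

Skin is modeled as an epidermis of thickness `t_epi` over a 0.2 mm upper
dermis and a semi-infinite lower dermis.  All layers share the reduced
scattering spectrum

    μs′(λ) = α [ (1−γ)(λ/600)^−β + γ(λ/600)^−4 ]        [mm⁻¹]

(α = μs′ at 600 nm, β the Mie decay, γ the Rayleigh fraction).  The
epidermis absorbs through melanin,

    μa,epi(λ) = f_mel · 48.4 (λ/550)^−β_mel              [mm⁻¹],

and each dermis layer n through blood,

    μa,n(λ) = f_blood,n · c_vp · ( s μa,oxy(λ) + (1−s) μa,deoxy(λ) ),

with whole-blood spectra for hematocrit 43 % and MCHC 345 g/L, a shared
oxygen saturation `s`, and the vessel-packaging factor
`c_vp = (1 − e^(−2 μa,bl R)) / (2 μa,bl R)` correcting for blood confined to
discrete vessels of radius `R`.

Forward spectra come from absorption-free ("white") Monte Carlo simulations
on a grid of epidermis thicknesses and scattering levels, storing the
per-layer pathlength of every detected photon; absorption is applied
afterwards per photon via Beer–Lambert and the grid is interpolated
bilinearly in (t_epi, log μs′).  The inverse solver fits the nine free
parameters (α, β, γ, t_epi, f_mel, β_mel, f_blood,1, f_blood,2, s) by
multi-start relative least squares with per-detector scale factors profiled
out analytically.  The sampling depth of each channel is the depth above
which 63 % (1 − 1/e) of the detected photons' weighted path positions lie.

## Worked example

```python
import numpy as np
from skindrs import (ProbeGeometry, build_basis, SkinModelParams,
                     model_reflectance, fit, FitConfig, depth_profile)

probe = ProbeGeometry()                       # 0.4 / 1.2 mm separations
basis = build_basis(
    t_epi_levels=[0.015, 0.04, 0.08, 0.15, 0.25],
    mus_r_levels=[0.4, 0.75, 1.4, 2.6, 4.5, 7.0],
    probe=probe, n_photons=40_000, seed=42,
)

truth = SkinModelParams.from_values(
    alpha=1.99, beta=0.82, gamma=0.31, t_epi=0.063, f_mel=0.05,
    beta_mel=4.3, f_blood_1=0.011, f_blood_2=0.0075, s=0.5,
)
spectrum = model_reflectance(truth, basis)     # clean two-channel spectrum
result = fit(spectrum, basis, FitConfig(seed=1))
print(round(result.objective, 12),
      round(result.params.dermis_upper.f_blood, 6),
      round(result.params.dermis_upper.s, 6))
```

prints

```
0.0 0.011 0.5
```

i.e. refitting the model's own noiseless output recovers the blood fraction
(0.011) and oxygen saturation (0.50) exactly, with a zero residual — the
basic self-consistency of the forward/inverse pair.  On noisy spectra (1 %
channel noise) the fitted saturation is typically within a few percentage
points and the blood fraction within ~10–20 % relative, while epidermal
thickness and melanin fraction are only jointly determined through their
absorbance product μa,epi × t_epi.

A command-line interface mirrors the library (`skindrs build-basis`,
`skindrs fit`, `skindrs sampling-depth`, `skindrs synth-cohort`,
`skindrs summarize`, `skindrs compare`).

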