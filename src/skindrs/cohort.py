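"""Synthetic cohort generator.

The real cohort spectra are access-restricted; this module emulates them by
drawing skin-model parameters from marginal distributions whose median and
quartiles match the values reported for the 3526 analyzed subjects, pushing
each draw through the forward model, and adding measurement noise.  Each
skewed, strictly positive parameter uses a log-normal marginal (median and
IQR-ratio matched in closed form); oxygen saturation uses a truncated normal.
Parameters are drawn independently -- the true between-parameter correlations
are unpublished, and independence is an explicit modeling choice.

Draws are clipped to physiologically plausible ranges, and draws whose
reduced-scattering spectrum or epidermal thickness would leave the Monte
Carlo basis grid are redrawn, so clipping only trims far tails and leaves
the medians essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import MCBasis
from .forward import (
    ReflectanceSpectrum,
    SkinModelParams,
    default_wavelengths,
    model_reflectance,
)

__all__ = ["ParameterSpec", "CohortSpec", "draw_parameters", "generate_spectra"]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class ParameterSpec:
    """Marginal distribution of one parameter: median with quartiles.

    ``kind`` is "lognormal" (default, positive skewed parameters) or
    "normal"; both are truncated to ``clip``.
    """

    median: float
    q25: float
    q75: float
    clip: tuple
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.q25 < self.median < self.q75:
            raise ValueError(
                f"percentiles must be ordered: {self.q25}, {self.median}, {self.q75}"
            )
        if self.kind not in ("lognormal", "normal"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")

    def moments(self) -> tuple:
        """(mu, sigma) of the underlying normal (log scale for lognormal)."""
        if self.kind == "lognormal":
            mu = np.log(self.median)
            sigma = np.log(self.q75 / self.q25) / (2.0 * _Z75)
        else:
            mu = self.median
            sigma = (self.q75 - self.q25) / (2.0 * _Z75)
        return mu, sigma

    def ppf(self, q) -> np.ndarray:
        """Quantile function of the (untruncated) fitted marginal."""
        from scipy.stats import norm

        mu, sigma = self.moments()
        x = norm.ppf(q, loc=mu, scale=sigma)
        return np.exp(x) if self.kind == "lognormal" else x

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu, sigma = self.moments()
        x = rng.normal(mu, sigma, size=n)
        v = np.exp(x) if self.kind == "lognormal" else x
        return np.clip(v, *self.clip)


def _default_parameter_specs() -> dict:
    """Marginals matched to the cohort medians and IQRs.

    The epidermis is parameterized through the melanin absorbance product
    ``mel_product`` = mua_epi(570 nm) * t_epi, the quantity the inverse
    problem actually determines (thickness and melanin fraction individually
    are nearly degenerate) and whose cohort distribution is published;
    ``f_mel`` is derived per subject from the product, the thickness and the
    melanin slope.  Drawing thickness and melanin fraction independently
    instead would produce joint extremes (thick *and* fully pigmented
    epidermis) that the real cohort does not contain.
    """
    return {
        "alpha": ParameterSpec(1.99, 1.78, 2.38, clip=(0.7, 3.5)),
        "beta": ParameterSpec(0.82, 0.55, 1.2, clip=(0.05, 2.2)),
        "gamma": ParameterSpec(0.31, 0.21, 0.39, clip=(0.02, 0.65)),
        "t_epi": ParameterSpec(0.063, 0.013, 0.191, clip=(0.016, 0.24)),
        "mel_product": ParameterSpec(0.13, 0.073, 0.23, clip=(0.005, 1.2)),
        "beta_mel": ParameterSpec(4.3, 2.9, 5.8, clip=(1.2, 7.5)),
        "f_blood_1": ParameterSpec(0.011, 0.0071, 0.016, clip=(5e-4, 0.06)),
        "f_blood_2": ParameterSpec(0.0075, 0.0058, 0.010, clip=(5e-4, 0.06)),
        "s": ParameterSpec(0.50, 0.41, 0.60, clip=(0.05, 0.95), kind="normal"),
    }


_F_MEL_CLIP = (0.003, 0.6)
_MEL_PRODUCT_REF_NM = 570.0


def _derive_f_mel(mel_product, t_epi, beta_mel):
    """Melanin fraction from the absorbance product at 570 nm."""
    mp = np.asarray(mel_product, dtype=float)
    te = np.asarray(t_epi, dtype=float)
    bm = np.asarray(beta_mel, dtype=float)
    mua_unit = 48.4 * (_MEL_PRODUCT_REF_NM / 550.0) ** (-bm)
    return np.clip(mp / (mua_unit * te), *_F_MEL_CLIP)


#: Seasonal multipliers of f_mel (month 1..12, no measurements in July);
#: scaled so that summer epidermal melanin is roughly 2.5x the spring minimum,
#: matching the reported March-to-June range.  Disabled by default.
_MONTH_F_MEL_FACTOR = {
    1: 0.80, 2: 0.75, 3: 0.70, 4: 0.80, 5: 1.10, 6: 1.60,
    8: 1.55, 9: 1.35, 10: 1.15, 11: 0.95, 12: 0.85,
}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic-cohort configuration.

    ``mus_r_range`` / ``t_epi_range`` define feasibility for the Monte Carlo
    basis the spectra will be synthesized against; infeasible draws are
    redrawn (rejection sampling).
    """

    n_subjects: int = 50
    seed: int = 0
    noise_multiplicative_sd: float = 0.01
    noise_additive_sd: float = 0.0
    parameters: dict = field(default_factory=_default_parameter_specs)
    vessel_radius: float = 0.005
    month_effect: bool = False
    age_range: tuple = (50.0, 65.0)
    mus_r_range: tuple = (0.4, 7.0)
    t_epi_range: tuple = (0.016, 0.24)
    wavelength_step_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def draw_parameters(spec: CohortSpec) -> tuple:
    """Draw per-subject model parameters and covariates.

    Returns ``(params_list, covariates)`` where ``covariates`` is a DataFrame
    with subject id, sex, age, BMI category and measurement month.  Draws are
    seed-reproducible; subjects whose scattering spectrum or epidermal
    thickness would leave the basis grid are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.parameters)
    n = spec.n_subjects

    draws = {k: spec.parameters[k].draw(rng, n) for k in names}

    # feasibility: mus'(475) and mus'(850) inside range, t_epi inside range
    # (mus' is monotone in wavelength for beta > 0, so the endpoints suffice)
    def infeasible() -> np.ndarray:
        r = 475.0 / 600.0
        hi_f = (1 - draws["gamma"]) * r ** (-draws["beta"]) + draws["gamma"] * r ** -4.0
        r2 = 850.0 / 600.0
        lo_f = (1 - draws["gamma"]) * r2 ** (-draws["beta"]) + draws["gamma"] * r2 ** -4.0
        mus_hi = draws["alpha"] * hi_f
        mus_lo = draws["alpha"] * lo_f
        return (
            (mus_hi > spec.mus_r_range[1])
            | (mus_lo < spec.mus_r_range[0])
            | (draws["t_epi"] < spec.t_epi_range[0])
            | (draws["t_epi"] > spec.t_epi_range[1])
        )

    for _round in range(100):
        bad = infeasible()
        if not bad.any():
            break
        n_bad = int(bad.sum())
        for k in names:
            draws[k][bad] = spec.parameters[k].draw(rng, n_bad)
    else:
        raise RuntimeError("could not draw feasible cohort parameters")

    sex = rng.choice(["male", "female"], size=n)
    age = rng.uniform(*spec.age_range, size=n)
    bmi = rng.choice(
        ["healthy", "overweight", "obese"], size=n, p=[0.36, 0.43, 0.21]
    )
    months = [m for m in range(1, 13) if m != 7]
    month = rng.choice(months, size=n)
    if spec.month_effect:
        factors = np.array([_MONTH_F_MEL_FACTOR[m] for m in month])
        draws["mel_product"] = np.clip(
            draws["mel_product"] * factors, *spec.parameters["mel_product"].clip
        )
    f_mel = _derive_f_mel(
        draws["mel_product"], draws["t_epi"], draws["beta_mel"]
    )

    params_list = [
        SkinModelParams.from_values(
            alpha=draws["alpha"][i],
            beta=draws["beta"][i],
            gamma=draws["gamma"][i],
            t_epi=draws["t_epi"][i],
            f_mel=f_mel[i],
            beta_mel=draws["beta_mel"][i],
            f_blood_1=draws["f_blood_1"][i],
            f_blood_2=draws["f_blood_2"][i],
            s=draws["s"][i],
            vessel_radius=spec.vessel_radius,
        )
        for i in range(n)
    ]
    covariates = pd.DataFrame(
        {
            "subject": np.arange(n),
            "sex": sex,
            "age": age,
            "bmi_group": bmi,
            "month": month,
        }
    )
    return params_list, covariates


def generate_spectra(
    params_list,
    basis: MCBasis,
    spec: CohortSpec,
) -> list[ReflectanceSpectrum]:
    """Noisy measured-like spectra for each subject.

    Forward-model output is multiplied channel-wise by ``1 + sd * eps`` and
    offset by an additive Gaussian floor; per-subject noise streams derive
    from the cohort seed.  The notch mask is applied (channels kept, flagged).
    """
    wl = default_wavelengths(spec.wavelength_step_nm)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(len(params_list))
    out = []
    for params, ss in zip(params_list, child_seeds):
        clean = model_reflectance(params, basis, wavelengths=wl)
        rng = np.random.default_rng(ss)
        noisy = clean.intensities * (
            1.0 + spec.noise_multiplicative_sd * rng.standard_normal(clean.intensities.shape)
        )
        if spec.noise_additive_sd > 0:
            noisy = noisy + spec.noise_additive_sd * rng.standard_normal(
                clean.intensities.shape
            )
        out.append(
            ReflectanceSpectrum(
                wavelengths=wl,
                intensities=noisy,
                mask=clean.mask,
                separations=clean.separations,
            )
        )
    return out
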