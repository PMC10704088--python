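"""Closed-form chromophore spectra for the three-layer skin model.

The model describes forearm skin as one epidermis layer on top of two dermis
layers.  Its optical-property spectra are built from three closed forms:

* reduced scattering, shared by all layers::

      mus'(lambda) = alpha * ((1 - gamma) (lambda/600)^-beta + gamma (lambda/600)^-4)

  where ``alpha`` is mus' at the 600 nm reference, ``beta`` the Mie scattering
  decay and ``gamma`` the Rayleigh fraction;

* melanin absorption in the epidermis::

      mua_mel(lambda) = 48.4 * (lambda/550)^-beta_mel        [mm^-1]

  scaled by the melanin volume fraction ``f_mel`` of the layer;

* hemoglobin absorption in each dermis layer::

      mua_n(lambda) = f_blood_n * c_vp_n * (s * mua_oxy + (1 - s) * mua_deoxy)

  where ``f_blood`` is the blood tissue fraction, ``s`` the hemoglobin oxygen
  saturation (shared by both dermis layers) and ``c_vp`` a vessel-packaging
  correction accounting for hemoglobin being confined to discrete vessels.

Whole-blood absorption assumes hematocrit 43 % and a mean cell hemoglobin
concentration of 345 g/L RBC.  All lengths are millimetres, all wavelengths
nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ScatteringParams",
    "EpidermisParams",
    "DermisLayerParams",
    "HemoglobinTable",
    "reduced_scattering",
    "melanin_absorption",
    "blood_absorption",
    "vessel_packing_factor",
    "dermis_absorption",
    "compile_hemoglobin_table",
    "HEMATOCRIT",
    "MCHC_G_PER_L",
    "HB_MOLAR_MASS",
    "WHOLE_BLOOD_HB_MOLARITY",
]

# Blood composition constants.
HEMATOCRIT = 0.43
MCHC_G_PER_L = 345.0  # g hemoglobin per litre of red blood cells
HB_MOLAR_MASS = 64500.0  # g/mol (tetramer)
#: Molar hemoglobin concentration of whole blood [mol/L].
WHOLE_BLOOD_HB_MOLARITY = HEMATOCRIT * MCHC_G_PER_L / HB_MOLAR_MASS

_SCATTER_REF_NM = 600.0
_MELANIN_REF_NM = 550.0
_MELANIN_REF_MUA = 48.4  # mm^-1 at 550 nm for unit melanin fraction


@dataclass(frozen=True)
class ScatteringParams:
    """Three-parameter reduced-scattering spectrum (shared across layers).

    alpha
        Reduced scattering coefficient at 600 nm [mm^-1].
    beta
        Mie scattering decay exponent (dimensionless).
    gamma
        Rayleigh scattering fraction in [0, 1].
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class EpidermisParams:
    """Epidermis layer: thickness [mm], melanin fraction, melanin slope."""

    t_epi: float
    f_mel: float
    beta_mel: float

    def __post_init__(self) -> None:
        if not self.t_epi > 0:
            raise ValueError(f"t_epi must be positive, got {self.t_epi}")
        if not 0.0 <= self.f_mel <= 1.0:
            raise ValueError(f"f_mel must be in [0, 1], got {self.f_mel}")
        if not self.beta_mel > 0:
            raise ValueError(f"beta_mel must be positive, got {self.beta_mel}")


@dataclass(frozen=True)
class DermisLayerParams:
    """One dermis layer.

    f_blood
        Blood tissue (volume) fraction.
    s
        Hemoglobin oxygen saturation, 0..1 (shared across dermis layers in
        the full skin model).
    vessel_radius
        Mean blood-vessel radius [mm] used by the vessel-packaging correction.
    thickness
        Layer thickness [mm]; ``inf`` for the semi-infinite lower dermis.
    """

    f_blood: float
    s: float
    vessel_radius: float = 0.005
    thickness: float = float("inf")

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_blood <= 1.0:
            raise ValueError(f"f_blood must be in [0, 1], got {self.f_blood}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if not self.vessel_radius > 0:
            raise ValueError(f"vessel_radius must be positive, got {self.vessel_radius}")
        if not self.thickness > 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")


@dataclass(frozen=True)
class HemoglobinTable:
    """Whole-blood absorption spectra on a dense wavelength grid.

    ``mu_a_oxy`` / ``mu_a_deoxy`` are absorption coefficients [mm^-1] of fully
    oxygenated / deoxygenated whole blood (natural-log convention).
    """

    wavelengths: np.ndarray
    mu_a_oxy: np.ndarray
    mu_a_deoxy: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be a strictly increasing 1-D grid")
        for name in ("mu_a_oxy", "mu_a_deoxy"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid shape")
            if not np.all(v > 0):
                raise ValueError(f"{name} must be strictly positive")

    def _check_range(self, lambda_nm: np.ndarray) -> None:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside tabulated range [{lo:g}, {hi:g}] nm; "
                "extrapolation is not allowed"
            )

    def oxy(self, lambda_nm):
        """Interpolated mu_a of fully oxygenated whole blood [mm^-1]."""
        self._check_range(lambda_nm)
        return np.interp(lambda_nm, self.wavelengths, self.mu_a_oxy)

    def deoxy(self, lambda_nm):
        """Interpolated mu_a of fully deoxygenated whole blood [mm^-1]."""
        self._check_range(lambda_nm)
        return np.interp(lambda_nm, self.wavelengths, self.mu_a_deoxy)

    def isosbestic_wavelength(self, lo: float = 650.0, hi: float = 900.0) -> float:
        """Wavelength of the red/NIR oxy-deoxy crossing within [lo, hi] nm."""
        self._check_range([lo, hi])
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        diff = self.mu_a_oxy[m] - self.mu_a_deoxy[m]
        sign = np.sign(diff)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size == 0:
            raise ValueError("no isosbestic crossing found in the requested range")
        i = idx[0]
        wl = self.wavelengths[m]
        # linear root between the bracketing grid points
        return float(wl[i] - diff[i] * (wl[i + 1] - wl[i]) / (diff[i + 1] - diff[i]))


def _as_positive_wavelength(lambda_nm):
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return lam


def reduced_scattering(lambda_nm, p: ScatteringParams):
    """Reduced scattering coefficient mus'(lambda) [mm^-1].

    Mixture of a Mie power law and a Rayleigh (lambda^-4) term, both
    normalized at 600 nm so that ``mus'(600) == alpha`` exactly.
    """
    lam = _as_positive_wavelength(lambda_nm)
    x = lam / _SCATTER_REF_NM
    out = p.alpha * ((1.0 - p.gamma) * x ** (-p.beta) + p.gamma * x ** (-4.0))
    return out if np.ndim(lambda_nm) else float(out)


def melanin_absorption(lambda_nm, beta_mel: float):
    """Melanin absorption spectrum [mm^-1] for unit melanin fraction.

    ``48.4 * (lambda/550)^-beta_mel``; multiplied by ``f_mel`` it gives the
    epidermal absorption coefficient.
    """
    lam = _as_positive_wavelength(lambda_nm)
    if not beta_mel > 0:
        raise ValueError(f"beta_mel must be positive, got {beta_mel}")
    out = _MELANIN_REF_MUA * (lam / _MELANIN_REF_NM) ** (-beta_mel)
    return out if np.ndim(lambda_nm) else float(out)


def blood_absorption(lambda_nm, s: float, table: HemoglobinTable):
    """Whole-blood absorption [mm^-1] at oxygen saturation ``s``.

    Linear mixture ``s * mua_oxy + (1 - s) * mua_deoxy`` on the tabulated grid.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"saturation must be in [0, 1], got {s}")
    out = s * table.oxy(lambda_nm) + (1.0 - s) * table.deoxy(lambda_nm)
    return out if np.ndim(lambda_nm) else float(out)


def vessel_packing_factor(mu_a_blood, vessel_radius: float):
    """Vessel-packaging correction factor in (0, 1].

    Hemoglobin confined to discrete cylindrical vessels absorbs less than the
    same amount distributed homogeneously.  The correction equals the mean
    transmittance of light traversing a vessel of radius ``R``, with traversal
    lengths uniform on [0, 2R]::

        c_vp = (1 - exp(-2 mu_a_blood R)) / (2 mu_a_blood R)

    and tends to 1 as ``mu_a_blood * R -> 0`` (the analytic limit is used for
    tiny arguments).
    """
    if not vessel_radius > 0:
        raise ValueError(f"vessel_radius must be positive, got {vessel_radius}")
    mu = np.asarray(mu_a_blood, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu_a_blood must be non-negative")
    x = 2.0 * mu * vessel_radius
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x < 1e-9, 1.0 - x / 2.0, -np.expm1(-x) / np.where(x > 0, x, 1.0))
    return out if np.ndim(mu_a_blood) else float(out)


def dermis_absorption(lambda_nm, d: DermisLayerParams, table: HemoglobinTable):
    """Dermal absorption coefficient [mm^-1].

    ``f_blood * c_vp * (s mua_oxy + (1-s) mua_deoxy)`` with the packaging
    factor evaluated at the saturation-mixed whole-blood absorption.
    """
    mu_bl = blood_absorption(lambda_nm, d.s, table)
    cvp = vessel_packing_factor(mu_bl, d.vessel_radius)
    out = d.f_blood * np.asarray(cvp) * np.asarray(mu_bl)
    return out if np.ndim(lambda_nm) else float(out)


@lru_cache(maxsize=1)
def compile_hemoglobin_table(
    lo_nm: float = 450.0, hi_nm: float = 900.0, step_nm: float = 1.0
) -> HemoglobinTable:
    """Compile the whole-blood absorption table from the bundled fixture.

    The fixture stores decadic molar extinction coefficients [cm^-1/M]; they
    are converted to natural-log whole-blood absorption [mm^-1] via

        mu_a = ln(10) * eps * C_Hb / 10,    C_Hb = Hct * MCHC / M_Hb,

    i.e. hematocrit 43 %, MCHC 345 g/L RBC (~148.35 g hemoglobin per litre of
    whole blood) and a hemoglobin molar mass of 64 500 g/mol.  Anchors are
    interpolated onto a dense grid with a shape-preserving (PCHIP) spline.
    """
    ref = resources.files("skindrs.data") / "hemoglobin_extinction_synthetic.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    eps_oxy = df["eps_hbo2_cm1_M"].to_numpy(dtype=float)
    eps_deoxy = df["eps_hb_cm1_M"].to_numpy(dtype=float)
    if wl[0] > lo_nm or wl[-1] < hi_nm:
        raise ValueError("hemoglobin fixture does not cover the requested range")
    grid = np.arange(lo_nm, hi_nm + 0.5 * step_nm, step_nm)
    conv = np.log(10.0) * WHOLE_BLOOD_HB_MOLARITY / 10.0  # (cm^-1/M) -> mm^-1
    oxy = PchipInterpolator(wl, eps_oxy)(grid) * conv
    deoxy = PchipInterpolator(wl, eps_deoxy)(grid) * conv
    return HemoglobinTable(wavelengths=grid, mu_a_oxy=oxy, mu_a_deoxy=deoxy)
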