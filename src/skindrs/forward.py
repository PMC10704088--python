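"""Forward model: synthesize two-separation reflectance spectra.

Given the nine-parameter skin model (scattering alpha/beta/gamma, epidermis
t_epi/f_mel/beta_mel, blood fractions of the two dermis layers and a shared
oxygen saturation), the model reflectance at each wavelength is obtained by

1. evaluating the per-layer absorption coefficients,
2. Beer-Lambert scaling of every detected photon in the four basis cells
   bracketing (t_epi, mus'(lambda)) -- weight * exp(-sum_l mua_l L_l),
3. bilinear interpolation of the cell reflectances in (t_epi, log mus').

Intensities are detected-weight fractions per launched photon (arbitrary
units); comparison with measured spectra uses per-detector scale factors
fitted in the inverse solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chromophores as chrom
from ._kernel import _interp_spectra
from .engine import MCBasis

__all__ = [
    "SkinModelParams",
    "ReflectanceSpectrum",
    "layer_absorptions",
    "model_reflectance",
    "default_wavelengths",
    "notch_mask",
    "WAVELENGTH_RANGE",
    "NOTCH_RANGE",
]

WAVELENGTH_RANGE = (475.0, 850.0)
#: Channels inside this band are masked out (laser-suppression notch filter).
NOTCH_RANGE = (770.0, 810.0)
UPPER_DERMIS_THICKNESS = 0.2  # mm


@dataclass(frozen=True)
class SkinModelParams:
    """Complete parameter set of the three-layer skin model.

    The two dermis layers must share the oxygen saturation; scattering is
    shared by all layers.
    """

    scattering: chrom.ScatteringParams
    epidermis: chrom.EpidermisParams
    dermis_upper: chrom.DermisLayerParams
    dermis_lower: chrom.DermisLayerParams

    def __post_init__(self) -> None:
        if self.dermis_upper.s != self.dermis_lower.s:
            raise ValueError("dermis layers must share the oxygen saturation")

    @classmethod
    def from_values(
        cls,
        alpha: float,
        beta: float,
        gamma: float,
        t_epi: float,
        f_mel: float,
        beta_mel: float,
        f_blood_1: float,
        f_blood_2: float,
        s: float,
        vessel_radius: float = 0.005,
    ) -> "SkinModelParams":
        return cls(
            scattering=chrom.ScatteringParams(alpha, beta, gamma),
            epidermis=chrom.EpidermisParams(t_epi, f_mel, beta_mel),
            dermis_upper=chrom.DermisLayerParams(
                f_blood_1, s, vessel_radius, UPPER_DERMIS_THICKNESS
            ),
            dermis_lower=chrom.DermisLayerParams(
                f_blood_2, s, vessel_radius, float("inf")
            ),
        )

    #: order of the nine free parameters in vector form
    VECTOR_FIELDS = (
        "alpha", "beta", "gamma", "t_epi", "f_mel", "beta_mel",
        "f_blood_1", "f_blood_2", "s",
    )

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.scattering.alpha,
                self.scattering.beta,
                self.scattering.gamma,
                self.epidermis.t_epi,
                self.epidermis.f_mel,
                self.epidermis.beta_mel,
                self.dermis_upper.f_blood,
                self.dermis_lower.f_blood,
                self.dermis_upper.s,
            ]
        )

    @classmethod
    def from_vector(cls, x, vessel_radius: float = 0.005) -> "SkinModelParams":
        return cls.from_values(*[float(v) for v in x], vessel_radius=vessel_radius)


@dataclass
class ReflectanceSpectrum:
    """Wavelength-indexed intensities at each source-detector separation.

    ``mask`` is True for valid channels; masked (notch) channels carry data
    but are excluded from fitting.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray  # (n_wl, n_detectors)
    mask: np.ndarray
    separations: tuple = (0.4, 1.2)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.intensities.shape != (self.wavelengths.size, len(self.separations)):
            raise ValueError("intensities must be (n_wavelengths, n_detectors)")
        if self.mask.shape != self.wavelengths.shape:
            raise ValueError("mask must match the wavelength grid")

    def to_frame(self) -> pd.DataFrame:
        cols = {"wavelength_nm": self.wavelengths}
        for k, sep in enumerate(self.separations):
            cols[f"intensity_d{int(round(sep * 10)):02d}"] = self.intensities[:, k]
        cols["mask"] = self.mask.astype(int)
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, separations: tuple = (0.4, 1.2)) -> "ReflectanceSpectrum":
        df = pd.read_csv(path, sep="\t")
        icols = [c for c in df.columns if c.startswith("intensity_d")]
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            intensities=df[icols].to_numpy(),
            mask=df["mask"].to_numpy().astype(bool),
            separations=separations,
        )


def default_wavelengths(step_nm: float = 5.0) -> np.ndarray:
    """Analysis grid over 475-850 nm."""
    lo, hi = WAVELENGTH_RANGE
    return np.arange(lo, hi + 0.5 * step_nm, step_nm)


def notch_mask(wavelengths) -> np.ndarray:
    """True outside the 770-810 nm laser-suppression notch."""
    wl = np.asarray(wavelengths, dtype=float)
    return ~((wl >= NOTCH_RANGE[0]) & (wl <= NOTCH_RANGE[1]))


def layer_absorptions(
    params: SkinModelParams,
    lambda_nm,
    table: chrom.HemoglobinTable | None = None,
) -> np.ndarray:
    """Per-layer absorption coefficients (epidermis, upper dermis, lower dermis).

    Returns an array of shape (n_wavelengths, 3) [mm^-1].
    """
    if table is None:
        table = chrom.compile_hemoglobin_table()
    lam = np.atleast_1d(np.asarray(lambda_nm, dtype=float))
    mua_epi = params.epidermis.f_mel * chrom.melanin_absorption(
        lam, params.epidermis.beta_mel
    )
    mua_1 = chrom.dermis_absorption(lam, params.dermis_upper, table)
    mua_2 = chrom.dermis_absorption(lam, params.dermis_lower, table)
    return np.column_stack([mua_epi, np.atleast_1d(mua_1), np.atleast_1d(mua_2)])


class _FitPack:
    """Flattened basis arrays for the numba spectral-synthesis kernel."""

    def __init__(self, basis: MCBasis):
        ni, nj = basis.shape
        nd = basis.n_detectors
        Ls, ws = [], []
        off = np.zeros((ni, nj, nd, 2), dtype=np.int64)
        launched = np.zeros((ni, nj))
        cursor = 0
        for i in range(ni):
            for j in range(nj):
                rec = basis.cell(i, j)
                launched[i, j] = rec.launched_weight
                for d in range(nd):
                    m = rec.detector == d
                    Ls.append(rec.pathlengths[m])
                    ws.append(rec.weight[m])
                    off[i, j, d, 0] = cursor
                    cursor += int(m.sum())
                    off[i, j, d, 1] = cursor
        self.L_all = np.ascontiguousarray(np.concatenate(Ls))
        self.w_all = np.concatenate(ws)
        self.off = off
        self.launched = launched
        self.t_levels = basis.t_epi_levels
        self.log_m_levels = np.log(basis.mus_r_levels)
        self.n_detectors = nd


_PACK_CACHE: dict[int, _FitPack] = {}


def _fit_pack(basis: MCBasis) -> _FitPack:
    key = id(basis)
    pack = _PACK_CACHE.get(key)
    if pack is None:
        pack = _FitPack(basis)
        _PACK_CACHE.clear()  # keep at most one basis resident
        _PACK_CACHE[key] = pack
    return pack


def _bracket(levels: np.ndarray, value: float, axis: str, clip: bool):
    lo, hi = levels[0], levels[-1]
    if value < lo or value > hi:
        if not clip:
            raise ValueError(
                f"{axis} = {value:g} outside the basis grid [{lo:g}, {hi:g}]"
            )
        value = min(max(value, lo), hi)
    j = int(np.searchsorted(levels, value, side="right") - 1)
    j = min(max(j, 0), levels.size - 2)
    frac = (value - levels[j]) / (levels[j + 1] - levels[j])
    return j, float(frac), value


def model_reflectance(
    params: SkinModelParams,
    basis: MCBasis,
    wavelengths=None,
    table: chrom.HemoglobinTable | None = None,
    clip_to_grid: bool = False,
) -> ReflectanceSpectrum:
    """Model spectrum for ``params`` via Beer-Lambert scaling of ``basis``.

    mus'(lambda) and t_epi must lie inside the basis grid unless
    ``clip_to_grid`` is set (used by the inverse solver, which penalizes the
    overshoot separately).  Interpolation is bilinear in (t_epi, log mus').
    """
    if wavelengths is None:
        wavelengths = default_wavelengths()
    wl = np.asarray(wavelengths, dtype=float)
    pack = _fit_pack(basis)

    i0, wt_i, _ = _bracket(pack.t_levels, params.epidermis.t_epi, "t_epi", clip_to_grid)

    mus_r = chrom.reduced_scattering(wl, params.scattering)
    mus_r = np.atleast_1d(mus_r)
    j_idx = np.empty(wl.size, dtype=np.int64)
    wt_j = np.empty(wl.size)
    for m, v in enumerate(mus_r):
        j, frac, v_used = _bracket(
            np.exp(pack.log_m_levels), float(v), f"mus'({wl[m]:g} nm)", clip_to_grid
        )
        # interpolate on the log-mus' axis
        lv = np.log(v_used)
        j_idx[m] = j
        wt_j[m] = (lv - pack.log_m_levels[j]) / (
            pack.log_m_levels[j + 1] - pack.log_m_levels[j]
        )

    mua = layer_absorptions(params, wl, table)
    inten = _interp_spectra(
        pack.L_all,
        pack.w_all,
        pack.off,
        pack.launched,
        i0,
        wt_i,
        j_idx,
        wt_j,
        mua,
        pack.n_detectors,
    )
    return ReflectanceSpectrum(
        wavelengths=wl,
        intensities=inten,
        mask=notch_mask(wl),
        separations=tuple(basis.probe.separations),
    )
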