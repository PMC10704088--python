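"""Sampling-depth statistic from photon-path point clouds.

The sampling depth of a detector channel is the depth above which 63 %
(1 - 1/e) of the detected photons' weighted path positions lie: a point cloud
is drawn uniformly along every detected photon's path (the same number of
points per photon), each point carries the photon's final weight after
absorption, and the depth where the cumulative weight first reaches
(1 - 1/e) of the total is reported, with linear interpolation between
adjacent sorted points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernel import _beer_lambert_weights
from .engine import DepthPointCloud, MCBasis, PhotonRecords, compress_paths
from .forward import SkinModelParams, layer_absorptions

__all__ = [
    "DepthResult",
    "sampling_depth",
    "depth_from_records",
    "depth_profile",
    "DEPTH_FRACTION",
    "DEFAULT_POINTS_PER_PHOTON",
]

#: Cumulative-weight fraction defining the sampling depth.
DEPTH_FRACTION = 1.0 - math.exp(-1.0)
DEFAULT_POINTS_PER_PHOTON = 20


@dataclass(frozen=True)
class DepthResult:
    separation: float      # mm
    wavelength: float      # nm (nan when not wavelength-specific)
    depth: float           # mm
    n_photons: int
    n_points: int


def sampling_depth(cloud: DepthPointCloud, fraction: float = DEPTH_FRACTION) -> float:
    """Weighted depth quantile of a point cloud at ``fraction`` (default 1-1/e).

    Points are sorted by depth; the cumulative weight is treated as piecewise
    linear between consecutive points and the depth at which it first reaches
    ``fraction`` of the total is returned.
    """
    if cloud.depth.size == 0:
        raise ValueError("empty point cloud")
    w_total = float(cloud.weight.sum())
    if not w_total > 0:
        raise ValueError("point cloud has no positive weight")
    order = np.argsort(cloud.depth, kind="stable")
    d = cloud.depth[order]
    cw = np.cumsum(cloud.weight[order])
    target = fraction * w_total
    k = int(np.searchsorted(cw, target, side="left"))
    k = min(k, d.size - 1)
    if k == 0:
        return float(d[0])
    if cw[k] == cw[k - 1]:
        return float(d[k])
    f = (target - cw[k - 1]) / (cw[k] - cw[k - 1])
    return float(d[k - 1] + f * (d[k] - d[k - 1]))


def depth_from_records(
    records: PhotonRecords,
    mu_a: np.ndarray,
    separation: float,
    detector: int,
    points_per_photon: int = DEFAULT_POINTS_PER_PHOTON,
    seed: int = 0,
    wavelength: float = float("nan"),
) -> DepthResult:
    """Sampling depth for one detector of a path-stored photon set.

    ``mu_a`` is the per-layer absorption triple [mm^-1] applied to the stored
    pathlengths via Beer-Lambert before weighting the cloud.
    """
    rec = records.select(detector)
    if len(rec) == 0:
        raise ValueError(f"no detected photons for detector {detector}")
    w = _beer_lambert_weights(rec.pathlengths, rec.weight, np.asarray(mu_a, dtype=float))
    cloud = compress_paths(rec, points_per_photon, seed, weights=w)
    return DepthResult(
        separation=separation,
        wavelength=wavelength,
        depth=sampling_depth(cloud),
        n_photons=len(rec),
        n_points=cloud.depth.size,
    )


def depth_profile(
    params: SkinModelParams,
    basis: MCBasis,
    lambda_nm: float,
    points_per_photon: int = DEFAULT_POINTS_PER_PHOTON,
    seed: int = 0,
) -> list[DepthResult]:
    """Sampling depth per separation at one wavelength.

    The depth is evaluated at the four basis cells bracketing
    (t_epi, mus'(lambda)) with absorption applied at ``lambda_nm``, then
    bilinearly interpolated.  Requires a basis built with path storage.
    """
    from . import chromophores as chrom
    from .forward import _bracket, _fit_pack

    pack = _fit_pack(basis)
    if not basis.cell(0, 0).has_paths:
        raise ValueError("basis was built without path storage")
    i0, wt_i, _ = _bracket(pack.t_levels, params.epidermis.t_epi, "t_epi", False)
    mus_r = chrom.reduced_scattering(lambda_nm, params.scattering)
    j0, _, v_used = _bracket(
        np.exp(pack.log_m_levels), float(mus_r), f"mus'({lambda_nm:g} nm)", False
    )
    wt_j = (np.log(v_used) - pack.log_m_levels[j0]) / (
        pack.log_m_levels[j0 + 1] - pack.log_m_levels[j0]
    )
    mua = layer_absorptions(params, lambda_nm)[0]

    results = []
    for d, sep in enumerate(basis.probe.separations):
        val = 0.0
        n_ph = 0
        n_pt = 0
        for ci, fi in ((0, 1.0 - wt_i), (1, wt_i)):
            for cj, fj in ((0, 1.0 - wt_j), (1, wt_j)):
                if fi * fj == 0.0:
                    continue
                res = depth_from_records(
                    basis.cell(i0 + ci, j0 + cj),
                    mua,
                    separation=sep,
                    detector=d,
                    points_per_photon=points_per_photon,
                    seed=seed + 97 * (ci * 2 + cj),
                    wavelength=lambda_nm,
                )
                val += fi * fj * res.depth
                n_ph += res.n_photons
                n_pt += res.n_points
        results.append(
            DepthResult(
                separation=sep,
                wavelength=lambda_nm,
                depth=val,
                n_photons=n_ph,
                n_points=n_pt,
            )
        )
    return results
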