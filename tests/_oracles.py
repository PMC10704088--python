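"""Independent oracles used by the test suite.

These are deliberately separate from the package implementation: closed-form
diffusion theory, exhaustive rank-statistic enumeration, direct quadrature,
and brute-force cumulative sums.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Fresnel reflectance for light leaving a medium with relative index n_rel."""
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


def diffusion_reflectance(rho: float, mua: float, mus_r: float, n_rel: float) -> float:
    """Spatially resolved diffuse reflectance R(rho) [mm^-2] of a semi-infinite
    medium: extrapolated-boundary dipole with fluence and flux terms weighted
    by the Fresnel angular moments (Kienle-Patterson form)."""
    mut = mua + mus_r
    z0 = 1.0 / mut
    D = 1.0 / (3.0 * mut)
    mueff = math.sqrt(3.0 * mua * mut)
    r_phi = quad(
        lambda t: 2.0 * math.sin(t) * math.cos(t) * fresnel_unpolarized(math.cos(t), n_rel),
        0.0, math.pi / 2.0,
    )[0]
    r_j = quad(
        lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2 * fresnel_unpolarized(math.cos(t), n_rel),
        0.0, math.pi / 2.0,
    )[0]
    A = (1.0 + r_j) / (1.0 - r_phi)
    zb = 2.0 * A * D
    r1 = math.sqrt(z0 * z0 + rho * rho)
    r2 = math.sqrt((z0 + 2.0 * zb) ** 2 + rho * rho)
    phi = (math.exp(-mueff * r1) / r1 - math.exp(-mueff * r2) / r2) / (4.0 * math.pi * D)
    jz = (
        z0 * (mueff + 1.0 / r1) * math.exp(-mueff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * math.exp(-mueff * r2) / r2**2
    ) / (4.0 * math.pi)
    return 0.25 * (1.0 - r_phi) * phi + 0.5 * (1.0 - r_j) * jz


def vessel_packing_quadrature(mu_a_blood: float, radius: float) -> float:
    """Mean transmittance across a vessel with traversal lengths uniform on
    [0, 2R], evaluated by numeric quadrature."""
    if mu_a_blood == 0.0:
        return 1.0
    val, _ = quad(lambda t: math.exp(-mu_a_blood * t), 0.0, 2.0 * radius)
    return val / (2.0 * radius)


def mann_whitney_u(x, y) -> float:
    """U statistic of the first sample, from the rank-sum definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact p-value by full enumeration of group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n_x = x.size
    u_obs = mann_whitney_u(x, y)
    n_total = pooled.size
    mean_u = n_x * (n_total - n_x) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n_total), n_x):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(comb)] = True
        u = mann_whitney_u(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def kruskal_h(groups: list) -> float:
    """Kruskal-Wallis H with tie correction, from first principles."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = rankdata(pooled)
    N = pooled.size
    h = 0.0
    idx = 0
    for g in groups:
        n_g = len(g)
        r_g = ranks[idx: idx + n_g].sum()
        h += r_g * r_g / n_g
        idx += n_g
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie


def weighted_quantile_bruteforce(depths, weights, fraction) -> float:
    """Cumulative-sum weighted quantile with linear interpolation between
    sorted points (independent re-derivation of the depth statistic)."""
    order = np.argsort(depths)
    d = np.asarray(depths, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    target = fraction * cw[-1]
    for k in range(d.size):
        if cw[k] >= target:
            if k == 0 or cw[k] == cw[k - 1]:
                return float(d[k]) if k > 0 else float(d[0])
            f = (target - cw[k - 1]) / (cw[k] - cw[k - 1])
            return float(d[k - 1] + f * (d[k] - d[k - 1]))
    return float(d[-1])
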