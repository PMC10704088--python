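"""Numba kernels: layered photon transport and Beer-Lambert spectral synthesis.

Coordinate convention: z grows downward from the tissue surface (z = 0), the
source fiber center is at the origin.  All lengths in mm.  The transport is
absorption-free ("white" Monte Carlo); absorption enters later by scaling each
detected photon's weight with exp(-sum_l mua_l * L_l) over its per-layer
pathlengths.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TWO_PI = 2.0 * math.pi

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rng_next(s):
    """xorshift64* step; returns (state, uniform in [0, 1))."""
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    return s, float((s * _U64(2685821657736338717)) >> _U64(11)) * _INV53


@njit(cache=True, inline="always")
def _rng_init(seed):
    s = _U64(seed) * _U64(2862933555777941757) + _U64(3037000493)
    if s == _U64(0):
        s = _U64(0x9E3779B97F4A7C15)
    for _ in range(8):  # warm-up to decorrelate nearby seeds
        s, _u = _rng_next(s)
    return s


@njit(cache=True, inline="always")
def _fresnel_r(n1, n2, cos_i):
    """Unpolarized Fresnel reflection coefficient; cos_i = |cos(incidence)|.

    Returns (R, cos_t); cos_t is 0 under total internal reflection.
    """
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    sin_t = n1 / n2 * math.sqrt(sin_i2)
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _spin(state, ux, uy, uz, g):
    """Sample a Henyey-Greenstein deflection and rotate the direction."""
    state, u = _rng_next(state)
    if g == 0.0:
        cos_t = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    sin_t = math.sqrt(1.0 - cos_t * cos_t)
    # azimuth via rejection sampling of a unit 2-vector (no trig calls)
    while True:
        state, a = _rng_next(state)
        state, b = _rng_next(state)
        a = 2.0 * a - 1.0
        b = 2.0 * b - 1.0
        r2 = a * a + b * b
        if 1e-12 < r2 <= 1.0:
            break
    inv = 1.0 / math.sqrt(r2)
    cos_p = a * inv
    sin_p = b * inv
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nuz = -sin_t * cos_p * den + uz * cos_t
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return state, nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _simulate_batch(
    seed,
    n_photons,
    z_bot,            # (L,) lower boundary depth of each layer; z_bot[-1] = max depth
    mus,              # (L,) scattering coefficient per layer [mm^-1]
    g_arr,            # (L,) anisotropy per layer
    n_arr,            # (L,) refractive index per layer
    n_ext,            # external (probe-side) refractive index
    src_r,            # source fiber core radius [mm]
    cos_src_min,      # cos of max launch angle in the external medium
    det_sep,          # (D,) detector center separations [mm]
    det_r,            # detector fiber core radius [mm]
    det_factor,       # (D,) annulus-to-fiber-face weight factor
    sin_acc,          # max sin(exit angle in external medium) accepted
    w_roulette,
    roulette_surv,
    max_path,
    max_steps,
    store_paths,      # bool
    # pre-allocated outputs
    pl_out,           # (cap, L) per-layer pathlengths of detected photons
    w_out,            # (cap,) detected weights (incl. annulus factor)
    r_out,            # (cap,) exit radii
    det_out,          # (cap,) detector index
    off_out,          # (cap+1,) vertex offsets
    path_z,           # (vcap,) vertex depths
    path_s,           # (vcap,) vertex cumulative arc lengths
    pbuf_z,           # (pcap,) per-photon scratch
    pbuf_s,
):
    """Trace ``n_photons`` and record those exiting into a detector.

    Returns (n_detected, n_vertices, launched_w, exited_w, lost_w, overflow).
    ``overflow`` is 1 if the detected-photon or vertex capacity was exhausted;
    the caller must rerun the batch with larger buffers (same seed).
    """
    state = _rng_init(seed)
    nlay = mus.shape[0]
    ndet = det_sep.shape[0]
    cap = w_out.shape[0]
    vcap = path_z.shape[0]
    pcap = pbuf_z.shape[0]

    pl = np.zeros(nlay, dtype=np.float64)

    n_det_ph = 0
    vcur = 0
    launched = 0.0
    exited = 0.0
    lost = 0.0
    off_out[0] = 0

    for _ph in range(n_photons):
        # --- launch: uniform over the fiber face, cone in the external medium
        state, u = _rng_next(state)
        rr = src_r * math.sqrt(u)
        state, u = _rng_next(state)
        phi0 = _TWO_PI * u
        x = rr * math.cos(phi0)
        y = rr * math.sin(phi0)
        z = 0.0
        state, u = _rng_next(state)
        cos_e = 1.0 - u * (1.0 - cos_src_min)
        refl, cos_t = _fresnel_r(n_ext, n_arr[0], cos_e)
        state, u = _rng_next(state)
        if u < refl:
            continue  # specularly reflected at the probe interface
        launched += 1.0
        sin_t = n_ext / n_arr[0] * math.sqrt(max(0.0, 1.0 - cos_e * cos_e))
        state, u = _rng_next(state)
        psi = _TWO_PI * u
        ux = sin_t * math.cos(psi)
        uy = sin_t * math.sin(psi)
        uz = cos_t

        w = 1.0
        lay = 0
        for l in range(nlay):
            pl[l] = 0.0
        s_tot = 0.0
        nv = 0
        if store_paths:
            pbuf_z[0] = 0.0
            pbuf_s[0] = 0.0
            nv = 1
        alive = True
        steps = 0

        while alive:
            state, u = _rng_next(state)
            step = -math.log(1.0 - u) / mus[lay]
            # propagate the step, possibly across layer boundaries
            while True:
                steps += 1
                if steps > max_steps or s_tot > max_path:
                    lost += w
                    alive = False
                    break
                z_top = z_bot[lay - 1] if lay > 0 else 0.0
                if uz > 0.0:
                    d_b = (z_bot[lay] - z) / uz
                elif uz < 0.0:
                    d_b = (z_top - z) / uz
                else:
                    d_b = 1e30
                if step <= d_b:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    pl[lay] += step
                    s_tot += step
                    break  # scatter at the new position
                # move to the boundary
                x += ux * d_b
                y += uy * d_b
                z += uz * d_b
                pl[lay] += d_b
                s_tot += d_b
                step -= d_b
                if uz < 0.0 and lay == 0:
                    # top surface
                    refl, cos_t = _fresnel_r(n_arr[0], n_ext, -uz)
                    state, u = _rng_next(state)
                    if u < refl:
                        uz = -uz
                        z = 0.0
                        if store_paths and nv < pcap:
                            pbuf_z[nv] = 0.0
                            pbuf_s[nv] = s_tot
                            nv += 1
                        continue
                    # transmitted out of the tissue
                    exited += w
                    sin_i = math.sqrt(max(0.0, 1.0 - uz * uz))
                    sin_e = n_arr[0] / n_ext * sin_i
                    rex = math.sqrt(x * x + y * y)
                    if sin_e <= sin_acc:
                        for k in range(ndet):
                            if abs(rex - det_sep[k]) <= det_r:
                                if n_det_ph >= cap:
                                    return n_det_ph, vcur, launched, exited, lost, 1
                                for l in range(nlay):
                                    pl_out[n_det_ph, l] = pl[l]
                                w_out[n_det_ph] = w * det_factor[k]
                                r_out[n_det_ph] = rex
                                det_out[n_det_ph] = k
                                if store_paths:
                                    if nv < pcap:
                                        pbuf_z[nv] = 0.0
                                        pbuf_s[nv] = s_tot
                                        nv += 1
                                    if vcur + nv > vcap:
                                        return n_det_ph, vcur, launched, exited, lost, 1
                                    for m in range(nv):
                                        path_z[vcur + m] = pbuf_z[m]
                                        path_s[vcur + m] = pbuf_s[m]
                                    vcur += nv
                                off_out[n_det_ph + 1] = vcur
                                n_det_ph += 1
                                break
                    alive = False
                    break
                elif uz > 0.0 and lay == nlay - 1:
                    # crossed the maximum tracked depth
                    lost += w
                    alive = False
                    break
                else:
                    nl = lay + 1 if uz > 0.0 else lay - 1
                    if n_arr[lay] == n_arr[nl]:
                        step *= mus[lay] / mus[nl]
                        lay = nl
                        continue
                    refl, cos_t = _fresnel_r(n_arr[lay], n_arr[nl], abs(uz))
                    state, u = _rng_next(state)
                    if u < refl:
                        uz = -uz
                        if store_paths and nv < pcap:
                            pbuf_z[nv] = z
                            pbuf_s[nv] = s_tot
                            nv += 1
                        continue
                    sin_i = math.sqrt(max(0.0, 1.0 - uz * uz))
                    if sin_i > 1e-12:
                        # transverse components scale with sin_t / sin_i
                        fac = n_arr[lay] / n_arr[nl]
                        ux *= fac
                        uy *= fac
                    uz = cos_t if uz > 0.0 else -cos_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    if store_paths and nv < pcap:
                        pbuf_z[nv] = z
                        pbuf_s[nv] = s_tot
                        nv += 1
                    step *= mus[lay] / mus[nl]
                    lay = nl
                    continue
            if not alive:
                break
            # scatter
            if store_paths:
                if nv >= pcap:
                    lost += w
                    break  # pathological path; drop the photon
                pbuf_z[nv] = z
                pbuf_s[nv] = s_tot
                nv += 1
            state, ux, uy, uz = _spin(state, ux, uy, uz, g_arr[lay])
            if w < w_roulette:
                state, u = _rng_next(state)
                if u * roulette_surv < 1.0:
                    w *= roulette_surv
                else:
                    alive = False  # roulette kill (unbiased, not tallied)

    return n_det_ph, vcur, launched, exited, lost, 0


@njit(cache=True)
def _beer_lambert_weights(pathlengths, weights, mua):
    """Per-photon weights after absorption: w * exp(-sum_l mua[l] * L[:, l])."""
    n = pathlengths.shape[0]
    nlay = pathlengths.shape[1]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        a = 0.0
        for l in range(nlay):
            a += mua[l] * pathlengths[i, l]
        out[i] = weights[i] * math.exp(-a)
    return out


@njit(cache=True)
def _interp_spectra(
    L_all,        # (N, 3) pathlengths, cells/detectors concatenated
    w_all,        # (N,)
    off,          # (ni, nj, nd, 2) start/stop slices into L_all
    launched,     # (ni, nj) launched weight per cell
    i0,           # lower t_epi node index
    wt_i,         # weight of the upper t_epi node
    j_idx,        # (nwl,) lower scattering node index per wavelength
    wt_j,         # (nwl,) weight of the upper scattering node
    mua,          # (nwl, 3) per-layer absorption per wavelength
    nd,
):
    """Bilinearly interpolated model reflectance, per wavelength and detector."""
    nwl = mua.shape[0]
    out = np.zeros((nwl, nd), dtype=np.float64)
    for m in range(nwl):
        a0 = mua[m, 0]
        a1 = mua[m, 1]
        a2 = mua[m, 2]
        ja = j_idx[m]
        for d in range(nd):
            val = 0.0
            for ci in range(2):
                ii = i0 + ci
                fi = wt_i if ci == 1 else 1.0 - wt_i
                if fi == 0.0:
                    continue
                for cj in range(2):
                    jj = ja + cj
                    fj = wt_j[m] if cj == 1 else 1.0 - wt_j[m]
                    if fj == 0.0:
                        continue
                    s = 0.0
                    start = off[ii, jj, d, 0]
                    stop = off[ii, jj, d, 1]
                    for p in range(start, stop):
                        s += w_all[p] * math.exp(
                            -(a0 * L_all[p, 0] + a1 * L_all[p, 1] + a2 * L_all[p, 2])
                        )
                    val += fi * fj * s / launched[ii, jj]
            out[m, d] = val
    return out


@njit(cache=True)
def _sample_path_points(path_z, path_s, offsets, k_points, seed):
    """Draw ``k_points`` uniform arc-length positions per photon path.

    Returns a (n_photons * k_points,) array of depths; points of photon ``i``
    occupy the slice [i * k_points, (i+1) * k_points).
    """
    np.random.seed(seed)
    n = offsets.shape[0] - 1
    out = np.empty(n * k_points, dtype=np.float64)
    for i in range(n):
        a = offsets[i]
        b = offsets[i + 1]
        total = path_s[b - 1]
        for k in range(k_points):
            target = np.random.random() * total
            # binary search for the segment containing `target`
            lo = a
            hi = b - 1
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if path_s[mid] <= target:
                    lo = mid
                else:
                    hi = mid
            ds = path_s[hi] - path_s[lo]
            if ds <= 0.0:
                out[i * k_points + k] = path_z[lo]
            else:
                f = (target - path_s[lo]) / ds
                out[i * k_points + k] = path_z[lo] + f * (path_z[hi] - path_z[lo])
    return out
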