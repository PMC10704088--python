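"""Layered-medium white Monte Carlo engine with fiber-probe detection.

Photons are launched from a source fiber in contact with the skin surface and
traced through a stack of plane-parallel layers with Henyey-Greenstein
scattering and Fresnel boundaries.  No absorption is applied during transport;
instead the geometric pathlength inside every layer is stored per detected
photon so that absorption can be added afterwards with Beer-Lambert scaling
(the "white Monte Carlo" technique).  Detection uses annular rings at the
source-detector separations, exploiting rotational symmetry: a photon exiting
anywhere on the ring centred at separation ``rho`` is accepted with the weight
factor (fiber face area) / (ring area) = r_fiber / (4 rho).

z grows downward from the surface; the source center is the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np

from ._kernel import _sample_path_points, _simulate_batch

__all__ = [
    "LayerStack",
    "ProbeGeometry",
    "PhotonRecords",
    "DepthPointCloud",
    "simulate",
    "build_basis",
    "compress_paths",
    "MCBasis",
    "three_layer_stack",
]

#: Default maximum tracked depth [mm]; photons diffusing deeper are dropped.
DEFAULT_MAX_DEPTH = 20.0
#: Default maximum total pathlength [mm].
DEFAULT_MAX_PATH = 2000.0

#: Default basis grid: epidermis thickness levels [mm] spanning the cohort
#: range, and reduced scattering levels [mm^-1] covering mus'(lambda) for
#: plausible scattering parameters over 475-850 nm.
DEFAULT_T_EPI_LEVELS = (0.015, 0.04, 0.08, 0.15, 0.25)
DEFAULT_MUS_R_LEVELS = (0.4, 0.75, 1.4, 2.6, 4.5, 7.0)


@dataclass(frozen=True)
class LayerStack:
    """Plane-parallel layer stack (top to bottom).

    The last layer is treated as semi-infinite; its ``thickness`` entry only
    serves validation and may be ``inf``.  Transport below ``max_depth`` is
    truncated (photons there are tallied as lost).
    """

    thickness: tuple      # mm per layer
    mus: tuple            # scattering coefficient mm^-1 per layer
    g: tuple              # anisotropy per layer
    n: tuple              # refractive index per layer
    n_external: float = 1.5
    max_depth: float = DEFAULT_MAX_DEPTH

    def __post_init__(self) -> None:
        L = len(self.thickness)
        if L < 1:
            raise ValueError("at least one layer is required")
        for name in ("mus", "g", "n"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} must have one entry per layer")
        if any(t <= 0 for t in self.thickness):
            raise ValueError("layer thicknesses must be positive")
        if any(m <= 0 for m in self.mus):
            raise ValueError("scattering coefficients must be positive")
        if any(not (0.0 <= gv < 1.0) for gv in self.g):
            raise ValueError("anisotropy must be in [0, 1)")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.thickness)

    def boundaries(self) -> np.ndarray:
        """Lower boundary depth of each layer; the last is ``max_depth``."""
        z = np.cumsum(np.asarray(self.thickness, dtype=float))
        z[-1] = self.max_depth
        if np.any(np.diff(np.concatenate(([0.0], z))) <= 0):
            raise ValueError("max_depth must exceed the finite layer thicknesses")
        return z


def three_layer_stack(
    t_epi: float,
    mus: float,
    g: float = 0.8,
    n_tissue: float = 1.4,
    n_external: float = 1.5,
    upper_dermis_thickness: float = 0.2,
    max_depth: float = DEFAULT_MAX_DEPTH,
) -> LayerStack:
    """Epidermis / upper dermis (0.2 mm) / semi-infinite lower dermis stack
    with homogeneous scattering properties."""
    return LayerStack(
        thickness=(t_epi, upper_dermis_thickness, float("inf")),
        mus=(mus, mus, mus),
        g=(g, g, g),
        n=(n_tissue, n_tissue, n_tissue),
        n_external=n_external,
        max_depth=max_depth,
    )


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-optic probe: source at the origin, detector rings at ``separations``."""

    separations: tuple = (0.4, 1.2)  # mm
    source_radius: float = 0.1       # mm
    detector_radius: float = 0.1     # mm
    numerical_aperture: float = 0.37

    def __post_init__(self) -> None:
        if self.source_radius <= 0 or self.detector_radius <= 0:
            raise ValueError("fiber radii must be positive")
        if not 0 < self.numerical_aperture <= 1.0:
            raise ValueError("numerical aperture must be in (0, 1]")
        for sep in self.separations:
            if sep - self.detector_radius <= self.source_radius:
                raise ValueError(
                    f"detector at {sep} mm overlaps the source fiber"
                )

    def annulus_factors(self) -> np.ndarray:
        """Fiber-face-to-ring area ratio per detector: r_det / (4 sep)."""
        return np.array(
            [self.detector_radius / (4.0 * s) for s in self.separations]
        )


@dataclass
class PhotonRecords:
    """Detected-photon set (struct-of-arrays).

    ``pathlengths[i, l]`` is the geometric pathlength of photon ``i`` in layer
    ``l``; ``weight`` includes the annular detection factor; ``detector``
    indexes ``probe.separations``.  When paths were stored, photon ``i``'s
    polyline occupies ``path_z[path_offsets[i]:path_offsets[i+1]]`` with
    matching cumulative arc lengths in ``path_s``.
    """

    pathlengths: np.ndarray
    weight: np.ndarray
    exit_radius: np.ndarray
    detector: np.ndarray
    n_emitted: int
    launched_weight: float
    exited_weight: float
    lost_weight: float
    seed: int
    path_offsets: np.ndarray | None = None
    path_z: np.ndarray | None = None
    path_s: np.ndarray | None = None

    def __len__(self) -> int:
        return self.weight.shape[0]

    @property
    def has_paths(self) -> bool:
        return self.path_offsets is not None

    def select(self, detector: int) -> "PhotonRecords":
        """Subset of records for one detector index."""
        m = self.detector == detector
        kw = {}
        if self.has_paths:
            idx = np.nonzero(m)[0]
            lengths = self.path_offsets[idx + 1] - self.path_offsets[idx]
            new_off = np.concatenate(([0], np.cumsum(lengths)))
            z = np.empty(new_off[-1])
            s = np.empty(new_off[-1])
            for k, i in enumerate(idx):
                a, b = self.path_offsets[i], self.path_offsets[i + 1]
                z[new_off[k]:new_off[k + 1]] = self.path_z[a:b]
                s[new_off[k]:new_off[k + 1]] = self.path_s[a:b]
            kw = dict(path_offsets=new_off, path_z=z, path_s=s)
        return PhotonRecords(
            pathlengths=self.pathlengths[m],
            weight=self.weight[m],
            exit_radius=self.exit_radius[m],
            detector=self.detector[m],
            n_emitted=self.n_emitted,
            launched_weight=self.launched_weight,
            exited_weight=self.exited_weight,
            lost_weight=self.lost_weight,
            seed=self.seed,
            **kw,
        )

    def reflectance(self, n_detectors: int) -> np.ndarray:
        """Detected weight fraction per detector (per launched unit weight)."""
        out = np.zeros(n_detectors)
        for k in range(n_detectors):
            out[k] = self.weight[self.detector == k].sum() / self.launched_weight
        return out


@dataclass(frozen=True)
class DepthPointCloud:
    """Weighted depth samples drawn uniformly along detected photon paths."""

    depth: np.ndarray
    weight: np.ndarray
    points_per_photon: int


def _concat_records(parts: list[PhotonRecords], seed: int) -> PhotonRecords:
    store = parts[0].has_paths
    kw = {}
    if store:
        lengths = [p.path_z.shape[0] for p in parts]
        z = np.concatenate([p.path_z for p in parts]) if parts else np.empty(0)
        s = np.concatenate([p.path_s for p in parts])
        offs = [parts[0].path_offsets]
        shift = lengths[0]
        for p in parts[1:]:
            offs.append(p.path_offsets[1:] + shift)
            shift += p.path_z.shape[0]
        kw = dict(path_offsets=np.concatenate(offs), path_z=z, path_s=s)
    return PhotonRecords(
        pathlengths=np.concatenate([p.pathlengths for p in parts]),
        weight=np.concatenate([p.weight for p in parts]),
        exit_radius=np.concatenate([p.exit_radius for p in parts]),
        detector=np.concatenate([p.detector for p in parts]),
        n_emitted=sum(p.n_emitted for p in parts),
        launched_weight=sum(p.launched_weight for p in parts),
        exited_weight=sum(p.exited_weight for p in parts),
        lost_weight=sum(p.lost_weight for p in parts),
        seed=seed,
        **kw,
    )


def simulate(
    stack: LayerStack,
    probe: ProbeGeometry,
    n_photons: int,
    seed: int,
    store_paths: bool = True,
    batch_size: int = 500_000,
    roulette_weight: float = 1e-4,
    roulette_survival: float = 10.0,
    max_path: float = DEFAULT_MAX_PATH,
    max_steps: int = 1_000_000,
) -> PhotonRecords:
    """Trace ``n_photons`` through ``stack`` and return the detected set.

    Bit-reproducible for fixed ``seed`` and ``batch_size``.  Photon launch
    directions fill the source-fiber acceptance cone; detection requires exit
    within a detector ring and within the fiber acceptance angle.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    z_bot = stack.boundaries()
    mus = np.asarray(stack.mus, dtype=float)
    g_arr = np.asarray(stack.g, dtype=float)
    n_arr = np.asarray(stack.n, dtype=float)
    det_sep = np.asarray(probe.separations, dtype=float)
    det_factor = probe.annulus_factors()
    sin_acc = min(1.0, probe.numerical_aperture / stack.n_external)
    cos_src_min = math.sqrt(max(0.0, 1.0 - sin_acc * sin_acc))

    n_batches = (n_photons + batch_size - 1) // batch_size
    batch_seeds = np.random.SeedSequence(seed).generate_state(n_batches)
    pbuf_z = np.empty(1 << 17)
    pbuf_s = np.empty(1 << 17)

    parts: list[PhotonRecords] = []
    remaining = n_photons
    for b in range(n_batches):
        nb = min(batch_size, remaining)
        remaining -= nb
        cap = max(1024, nb // 8)
        vcap = max(1 << 16, cap * 96) if store_paths else 1
        while True:
            pl_out = np.empty((cap, stack.n_layers))
            w_out = np.empty(cap)
            r_out = np.empty(cap)
            det_out = np.empty(cap, dtype=np.int8)
            off_out = np.zeros(cap + 1, dtype=np.int64)
            path_z = np.empty(vcap)
            path_s = np.empty(vcap)
            nd, nvert, launched, exited, lost, overflow = _simulate_batch(
                int(batch_seeds[b]) & 0x7FFFFFFF,
                nb,
                z_bot,
                mus,
                g_arr,
                n_arr,
                stack.n_external,
                probe.source_radius,
                cos_src_min,
                det_sep,
                probe.detector_radius,
                det_factor,
                sin_acc,
                roulette_weight,
                roulette_survival,
                max_path,
                max_steps,
                store_paths,
                pl_out,
                w_out,
                r_out,
                det_out,
                off_out,
                path_z,
                path_s,
                pbuf_z,
                pbuf_s,
            )
            if overflow:
                cap *= 2
                vcap *= 2
                continue
            break
        kw = {}
        if store_paths:
            kw = dict(
                path_offsets=off_out[: nd + 1].copy(),
                path_z=path_z[:nvert].copy(),
                path_s=path_s[:nvert].copy(),
            )
        parts.append(
            PhotonRecords(
                pathlengths=pl_out[:nd].copy(),
                weight=w_out[:nd].copy(),
                exit_radius=r_out[:nd].copy(),
                detector=det_out[:nd].copy(),
                n_emitted=nb,
                launched_weight=launched,
                exited_weight=exited,
                lost_weight=lost,
                seed=seed,
                **kw,
            )
        )
    return _concat_records(parts, seed)


def compress_paths(
    records: PhotonRecords,
    points_per_photon: int,
    seed: int,
    weights: np.ndarray | None = None,
) -> DepthPointCloud:
    """Uniform arc-length point cloud over all detected photon paths.

    Exactly ``points_per_photon`` positions are drawn per photon regardless of
    its total pathlength; every point carries the photon's (optionally
    absorption-scaled) final weight.
    """
    if points_per_photon < 1:
        raise ValueError("points_per_photon must be >= 1")
    if len(records) == 0:
        return DepthPointCloud(np.empty(0), np.empty(0), points_per_photon)
    if not records.has_paths:
        raise ValueError("records were simulated without path storage")
    w = records.weight if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != len(records):
        raise ValueError("weights must have one entry per photon")
    depths = _sample_path_points(
        records.path_z,
        records.path_s,
        records.path_offsets,
        points_per_photon,
        int(seed) & 0x7FFFFFFF,
    )
    return DepthPointCloud(
        depth=depths,
        weight=np.repeat(w, points_per_photon),
        points_per_photon=points_per_photon,
    )


@dataclass
class MCBasis:
    """Grid of absorption-free simulations over (epidermis thickness x scattering).

    Axis levels are strictly increasing; ``mus_r_levels`` holds the reduced
    scattering coefficient mus' = mus (1 - g) of each scattering level (the
    levels are wavelength-agnostic: at analysis time the model's mus'(lambda)
    selects the bracketing levels).  Every cell is a three-layer stack
    (epidermis / 0.2 mm upper dermis / semi-infinite lower dermis) with
    homogeneous scattering, simulated with identical probe geometry and photon
    count.
    """

    t_epi_levels: np.ndarray
    mus_r_levels: np.ndarray
    probe: ProbeGeometry
    n_photons: int
    seed: int
    g: float
    n_tissue: float
    n_external: float
    upper_dermis_thickness: float
    max_depth: float
    cells: list  # cells[i][j] -> PhotonRecords

    @property
    def shape(self) -> tuple:
        return (len(self.t_epi_levels), len(self.mus_r_levels))

    @property
    def n_detectors(self) -> int:
        return len(self.probe.separations)

    def cell(self, i: int, j: int) -> PhotonRecords:
        return self.cells[i][j]

    def save(self, path) -> None:
        """Persist to HDF5 (layout: /meta attrs, /grid axes, /cell_i_j/...)."""
        with h5py.File(path, "w") as f:
            meta = f.create_group("meta")
            meta.attrs["n_photons"] = self.n_photons
            meta.attrs["seed"] = self.seed
            meta.attrs["g"] = self.g
            meta.attrs["n_tissue"] = self.n_tissue
            meta.attrs["n_external"] = self.n_external
            meta.attrs["upper_dermis_thickness"] = self.upper_dermis_thickness
            meta.attrs["max_depth"] = self.max_depth
            meta.attrs["separations"] = np.asarray(self.probe.separations)
            meta.attrs["source_radius"] = self.probe.source_radius
            meta.attrs["detector_radius"] = self.probe.detector_radius
            meta.attrs["numerical_aperture"] = self.probe.numerical_aperture
            grid = f.create_group("grid")
            grid.create_dataset("t_epi_levels", data=self.t_epi_levels)
            grid.create_dataset("mus_r_levels", data=self.mus_r_levels)
            for i in range(self.shape[0]):
                for j in range(self.shape[1]):
                    rec = self.cells[i][j]
                    gcell = f.create_group(f"cell_{i}_{j}")
                    gcell.attrs["n_emitted"] = rec.n_emitted
                    gcell.attrs["launched_weight"] = rec.launched_weight
                    gcell.attrs["exited_weight"] = rec.exited_weight
                    gcell.attrs["lost_weight"] = rec.lost_weight
                    gcell.attrs["seed"] = rec.seed
                    gcell.create_dataset("pathlengths", data=rec.pathlengths)
                    gcell.create_dataset("weight", data=rec.weight)
                    gcell.create_dataset("exit_radius", data=rec.exit_radius)
                    gcell.create_dataset("detector", data=rec.detector)
                    if rec.has_paths:
                        gcell.create_dataset("path_offsets", data=rec.path_offsets)
                        gcell.create_dataset("path_z", data=rec.path_z)
                        gcell.create_dataset("path_s", data=rec.path_s)

    @classmethod
    def load(cls, path) -> "MCBasis":
        with h5py.File(path, "r") as f:
            meta = f["meta"].attrs
            probe = ProbeGeometry(
                separations=tuple(float(s) for s in meta["separations"]),
                source_radius=float(meta["source_radius"]),
                detector_radius=float(meta["detector_radius"]),
                numerical_aperture=float(meta["numerical_aperture"]),
            )
            t_levels = f["grid/t_epi_levels"][:]
            m_levels = f["grid/mus_r_levels"][:]
            cells = []
            for i in range(len(t_levels)):
                row = []
                for j in range(len(m_levels)):
                    g = f[f"cell_{i}_{j}"]
                    kw = {}
                    if "path_offsets" in g:
                        kw = dict(
                            path_offsets=g["path_offsets"][:],
                            path_z=g["path_z"][:],
                            path_s=g["path_s"][:],
                        )
                    row.append(
                        PhotonRecords(
                            pathlengths=g["pathlengths"][:],
                            weight=g["weight"][:],
                            exit_radius=g["exit_radius"][:],
                            detector=g["detector"][:],
                            n_emitted=int(g.attrs["n_emitted"]),
                            launched_weight=float(g.attrs["launched_weight"]),
                            exited_weight=float(g.attrs["exited_weight"]),
                            lost_weight=float(g.attrs["lost_weight"]),
                            seed=int(g.attrs["seed"]),
                            **kw,
                        )
                    )
                cells.append(row)
            return cls(
                t_epi_levels=t_levels,
                mus_r_levels=m_levels,
                probe=probe,
                n_photons=int(meta["n_photons"]),
                seed=int(meta["seed"]),
                g=float(meta["g"]),
                n_tissue=float(meta["n_tissue"]),
                n_external=float(meta["n_external"]),
                upper_dermis_thickness=float(meta["upper_dermis_thickness"]),
                max_depth=float(meta["max_depth"]),
                cells=cells,
            )


def build_basis(
    t_epi_levels,
    mus_r_levels,
    probe: ProbeGeometry,
    n_photons: int,
    seed: int,
    g: float = 0.8,
    n_tissue: float = 1.4,
    n_external: float = 1.5,
    upper_dermis_thickness: float = 0.2,
    max_depth: float = DEFAULT_MAX_DEPTH,
    store_paths: bool = False,
    progress: bool = False,
) -> MCBasis:
    """Simulate one absorption-free cell per (t_epi, mus') grid node.

    ``mus_r_levels`` are reduced scattering coefficients mus' [mm^-1]; the
    simulated scattering coefficient of a level is mus'/(1-g).  Per-cell seeds
    derive deterministically from ``seed``.
    """
    t_levels = np.asarray(t_epi_levels, dtype=float)
    m_levels = np.asarray(mus_r_levels, dtype=float)
    for name, lv in (("t_epi_levels", t_levels), ("mus_r_levels", m_levels)):
        if lv.size < 2:
            raise ValueError(f"{name} needs at least two levels")
        if not np.all(np.diff(lv) > 0):
            raise ValueError(f"{name} must be strictly increasing")
    cell_seeds = np.random.SeedSequence(seed).generate_state(t_levels.size * m_levels.size)
    cells = []
    for i, t in enumerate(t_levels):
        row = []
        for j, mr in enumerate(m_levels):
            stack = three_layer_stack(
                t_epi=t,
                mus=mr / (1.0 - g),
                g=g,
                n_tissue=n_tissue,
                n_external=n_external,
                upper_dermis_thickness=upper_dermis_thickness,
                max_depth=max_depth,
            )
            cseed = int(cell_seeds[i * m_levels.size + j]) & 0x7FFFFFFF
            rec = simulate(stack, probe, n_photons, cseed, store_paths=store_paths)
            row.append(rec)
            if progress:
                print(f"cell ({i},{j}): t_epi={t:g} mm, mus'={mr:g} -> {len(rec)} detected")
        cells.append(row)
    return MCBasis(
        t_epi_levels=t_levels,
        mus_r_levels=m_levels,
        probe=probe,
        n_photons=n_photons,
        seed=seed,
        g=g,
        n_tissue=n_tissue,
        n_external=n_external,
        upper_dermis_thickness=upper_dermis_thickness,
        max_depth=max_depth,
        cells=cells,
    )
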