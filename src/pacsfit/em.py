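"""EM density scoring: Gaussian map simulation, cross-correlation, rigid fitting.

A simulated map deposits one isotropic 3-D Gaussian per atom.  The nominal
resolution sets the kernel width; by default FWHM = resolution, i.e.
``sigma = resolution / (2 sqrt(2 ln 2))``.  The Situs pdb2vol-style
convention ``sigma = resolution / (2 sqrt(3))`` is selectable — the
cross-correlation ranking of conformations is insensitive to the choice,
absolute CC values shift slightly.

The score between two maps on a common lattice is the normalized voxel-wise
dot product

.. math::

    CC = \\frac{\\sum_i \\rho_{m,i}\\,\\rho_{t,i}}
              {\\sqrt{\\sum_i \\rho_{m,i}^2 \\; \\sum_i \\rho_{t,i}^2}}

with no thresholding or masking of either map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .structmodel import Conformation, TransformRT

__all__ = [
    "DensityMap",
    "kernel_sigma",
    "simulate_map",
    "cc",
    "resample_map",
    "rigid_body_fit",
    "refine_placement",
    "read_mrc",
    "write_mrc",
    "read_sit",
]


@dataclass
class DensityMap:
    """A 3-D density grid.

    ``rho[ix, iy, iz]`` is the density at position
    ``origin + (ix, iy, iz) * voxel`` (voxel centers), Angstrom.
    """

    origin: np.ndarray
    voxel: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        voxel = np.asarray(self.voxel, dtype=float)
        if voxel.ndim == 0:
            voxel = np.repeat(voxel, 3)
        self.voxel = voxel.reshape(3)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 3:
            raise ValueError("rho must be a 3-D array")
        if np.any(self.voxel <= 0):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("non-finite densities")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.rho.shape

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) physical corners of the voxel-center lattice."""
        upper = self.origin + (np.array(self.dims) - 1) * self.voxel
        return self.origin.copy(), upper

    def total(self) -> float:
        """Integral of the density: sum(rho) * voxel volume."""
        return float(self.rho.sum() * np.prod(self.voxel))

    def same_geometry(self, other: "DensityMap", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.voxel, other.voxel, atol=atol)
        )


def kernel_sigma(resolution: float, convention: str = "fwhm") -> float:
    """Gaussian kernel width (Å) for a nominal map resolution.

    ``"fwhm"``: FWHM = resolution.  ``"situs"``: sigma = resolution/(2*sqrt(3)),
    approximating pdb2vol's kernel.
    """
    if convention == "fwhm":
        return resolution / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if convention == "situs":
        return resolution / (2.0 * math.sqrt(3.0))
    raise ValueError(f"unknown kernel convention {convention!r}")


def _deposit(
    coords: np.ndarray,
    weights: np.ndarray,
    origin: np.ndarray,
    voxel: np.ndarray,
    dims: tuple[int, int, int],
    sigma: float,
    cutoff_sigmas: float = 4.0,
) -> np.ndarray:
    """Sum separable per-atom Gaussians onto a given lattice."""
    rho = np.zeros(dims)
    norm1d = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    half = cutoff_sigmas * sigma
    axes = [origin[k] + voxel[k] * np.arange(dims[k]) for k in range(3)]
    for xyz, w in zip(coords, weights):
        g = []
        sl = []
        ok = True
        for k in range(3):
            lo = int(np.searchsorted(axes[k], xyz[k] - half, side="left"))
            hi = int(np.searchsorted(axes[k], xyz[k] + half, side="right"))
            if hi <= lo:
                ok = False
                break
            ax = axes[k][lo:hi]
            g.append(norm1d * np.exp(-((ax - xyz[k]) ** 2) / (2.0 * sigma**2)))
            sl.append(slice(lo, hi))
        if not ok:
            continue  # atom entirely outside the lattice
        rho[sl[0], sl[1], sl[2]] += w * (
            g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        )
    return rho


def simulate_map(
    conf: Conformation,
    voxel: float = 1.0,
    resolution: float = 5.0,
    pad: float = 10.0,
    weights: np.ndarray | None = None,
    kernel: str = "fwhm",
    geometry: DensityMap | tuple | None = None,
) -> DensityMap:
    """Simulate a density map from atomic coordinates.

    Each atom deposits a unit-integral isotropic Gaussian (weight 1 per atom
    by default).  The lattice spans the coordinates plus ``pad`` on every
    side, or an explicit ``geometry`` (a DensityMap or an
    ``(origin, voxel, dims)`` tuple) when the map must live on a target
    lattice for cross-correlation.
    """
    if conf.n_atoms == 0:
        raise ValueError("empty conformation")
    if geometry is None and resolution < 2.0 * voxel:
        raise ValueError(
            f"resolution {resolution} Å undersampled at voxel {voxel} Å "
            "(need resolution >= 2*voxel)"
        )
    sigma = kernel_sigma(resolution, kernel)
    w = np.ones(conf.n_atoms) if weights is None else np.asarray(weights, float)
    if geometry is not None:
        if isinstance(geometry, DensityMap):
            origin, vox, dims = geometry.origin, geometry.voxel, geometry.dims
        else:
            origin, vox, dims = geometry
            origin = np.asarray(origin, float)
            vox = np.asarray(vox, float).reshape(-1)
            if vox.size == 1:
                vox = np.repeat(vox, 3)
    else:
        vox = np.repeat(float(voxel), 3)
        lo = conf.coords.min(axis=0) - pad
        hi = conf.coords.max(axis=0) + pad
        dims = tuple(int(np.ceil((hi[k] - lo[k]) / vox[k])) + 1 for k in range(3))
        origin = lo
    rho = _deposit(conf.coords, w, origin, vox, tuple(dims), sigma)
    return DensityMap(origin, vox, rho)


def cc(model_map: DensityMap, target_map: DensityMap) -> float:
    """Cross-correlation coefficient of two maps on an identical lattice."""
    if not model_map.same_geometry(target_map):
        raise ValueError("maps have different grid geometry; resample first")
    a = model_map.rho.ravel()
    b = target_map.rho.ravel()
    na, nb = float(a @ a), float(b @ b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("all-zero map has no defined correlation")
    return float((a @ b) / math.sqrt(na * nb))


def resample_map(src: DensityMap, geometry: DensityMap | tuple) -> DensityMap:
    """Trilinear resampling onto another lattice; outside voxels are zero."""
    from scipy.ndimage import map_coordinates

    if isinstance(geometry, DensityMap):
        origin, voxel, dims = geometry.origin, geometry.voxel, geometry.dims
    else:
        origin, voxel, dims = geometry
        origin = np.asarray(origin, float)
        voxel = np.asarray(voxel, float).reshape(-1)
        if voxel.size == 1:
            voxel = np.repeat(voxel, 3)
    lo_s, hi_s = src.extent
    lo_t = origin
    hi_t = origin + (np.array(dims) - 1) * voxel
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise ValueError("no overlap between source and target extents")
    grids = np.meshgrid(
        *[origin[k] + voxel[k] * np.arange(dims[k]) for k in range(3)],
        indexing="ij",
    )
    idx = [(grids[k] - src.origin[k]) / src.voxel[k] for k in range(3)]
    rho = map_coordinates(
        src.rho, np.array(idx), order=1, mode="constant", cval=0.0
    )
    return DensityMap(origin, voxel, rho)


def _fit_orientations(n: int) -> "np.ndarray":
    """Deterministic quasi-uniform rotation seeds (as rotation matrices)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(n, random_state=np.random.RandomState(20160705))
    return rot.as_matrix()


def rigid_body_fit(
    conf: Conformation,
    target: DensityMap,
    resolution: float = 5.0,
    n_orientations: int = 60,
    kernel: str = "fwhm",
    weights: np.ndarray | None = None,
    refine_maxiter: int = 300,
) -> tuple[TransformRT, float]:
    """Place a conformation into a target map, maximizing cross-correlation.

    Strategy: translate the model centroid onto the map's density centroid,
    score a quasi-uniform set of orientation seeds about that point (plus
    the identity placement), then refine the best seed's six rigid-body
    parameters with a derivative-free simplex search.  The returned CC is
    the correlation evaluated at the returned transform and is never below
    the identity-placement CC.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    if float(np.abs(target.rho).sum()) == 0.0:
        raise ValueError("target map is all zero")
    w = np.ones(conf.n_atoms) if weights is None else np.asarray(weights, float)
    sigma = kernel_sigma(resolution, kernel)
    geom = (target.origin, target.voxel, target.dims)

    def score_coords(coords: np.ndarray) -> float:
        rho = _deposit(coords, w, target.origin, target.voxel, target.dims, sigma)
        if rho.sum() == 0.0:
            return 0.0
        m = DensityMap(target.origin, target.voxel, rho)
        return cc(m, target)

    centroid = conf.coords.mean(axis=0)
    total = float(target.rho.clip(min=0).sum())
    axes = [
        target.origin[k] + target.voxel[k] * np.arange(target.dims[k])
        for k in range(3)
    ]
    com = np.array(
        [
            float((target.rho.clip(min=0).sum(axis=tuple(j for j in range(3) if j != k)) * axes[k]).sum())
            / total
            for k in range(3)
        ]
    )

    # candidate transforms: x -> R (x - centroid) + centroid + t
    candidates: list[tuple[np.ndarray, np.ndarray]] = [(np.eye(3), np.zeros(3))]
    t_seed = com - centroid
    candidates.append((np.eye(3), t_seed))
    for R in _fit_orientations(n_orientations):
        candidates.append((R, t_seed))

    best_cc = -np.inf
    best_R, best_t = np.eye(3), np.zeros(3)
    for R, t in candidates:
        coords = (conf.coords - centroid) @ R.T + centroid + t
        value = score_coords(coords)
        if value > best_cc:
            best_cc, best_R, best_t = value, R, t

    def objective(params: np.ndarray) -> float:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        coords = (conf.coords - centroid) @ R.T + centroid + params[3:]
        return -score_coords(coords)

    x0 = np.concatenate([Rotation.from_matrix(best_R).as_rotvec(), best_t])
    result = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": refine_maxiter, "xatol": 1e-3, "fatol": 1e-6},
    )
    if -result.fun > best_cc:
        best_cc = -result.fun
        best_R = Rotation.from_rotvec(result.x[:3]).as_matrix()
        best_t = result.x[3:]

    # convert "rotate about centroid then shift" into a global R, t
    R = best_R
    t = centroid + best_t - R @ centroid
    return TransformRT(R, t), float(best_cc)


def refine_placement(
    conf: Conformation,
    target: DensityMap,
    start: TransformRT,
    resolution: float = 5.0,
    kernel: str = "fwhm",
    weights: np.ndarray | None = None,
    maxiter: int = 150,
) -> TransformRT:
    """Locally re-refine a rigid placement (no orientation re-seeding).

    Used during a cascade to absorb slow pose drift: the six rigid
    parameters are refined around ``start`` by simplex search, and the
    refined transform is returned only if it does not lower the
    correlation.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    w = np.ones(conf.n_atoms) if weights is None else np.asarray(weights, float)
    sigma = kernel_sigma(resolution, kernel)

    def score_transform(R: np.ndarray, t: np.ndarray) -> float:
        coords = conf.coords @ R.T + t
        rho = _deposit(coords, w, target.origin, target.voxel, target.dims, sigma)
        if rho.sum() == 0.0:
            return 0.0
        return cc(DensityMap(target.origin, target.voxel, rho), target)

    def objective(params: np.ndarray) -> float:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return -score_transform(R, params[3:])

    x0 = np.concatenate(
        [Rotation.from_matrix(start.rotation).as_rotvec(), start.translation]
    )
    base = -objective(x0)
    result = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-6},
    )
    if -result.fun <= base:
        return start
    return TransformRT(
        Rotation.from_rotvec(result.x[:3]).as_matrix(), result.x[3:]
    )


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 2014 map; axis order is normalized to x, y, z.

    Only orthogonal cells (all angles 90°) are supported.  The physical
    origin is taken from the ORIGIN header words when set, else from
    NX/NY/NZSTART times the voxel size.
    """
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read MRC map {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise ValueError("non-orthogonal cells are not supported")
    dims = (m.grid.nu, m.grid.nv, m.grid.nw)
    voxel = np.array([cell.a / dims[0], cell.b / dims[1], cell.c / dims[2]])
    origin = np.array([m.header_float(i) for i in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    rho = np.array(m.grid, copy=True)
    return DensityMap(origin, voxel, rho)


def write_mrc(dmap: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 (mode 2, 32-bit float), x,y,z axis order."""
    grid = gemmi.FloatGrid(*dmap.dims)
    grid.set_unit_cell(
        gemmi.UnitCell(
            dmap.voxel[0] * dmap.dims[0],
            dmap.voxel[1] * dmap.dims[1],
            dmap.voxel[2] * dmap.dims[2],
            90,
            90,
            90,
        )
    )
    np.asarray(grid)[...] = dmap.rho.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, value in zip((50, 51, 52), dmap.origin):
        m.set_header_float(i, float(value))
    m.write_ccp4_map(str(path))


def read_sit(path) -> DensityMap:
    """Read a Situs ASCII map (.sit / .situs).

    Header line: ``voxel origin_x origin_y origin_z nx ny nz``; the density
    values follow in x-fastest order.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 8:
        raise ValueError(f"{path}: truncated Situs file")
    voxel = float(tokens[0])
    origin = np.array([float(t) for t in tokens[1:4]])
    nx, ny, nz = (int(float(t)) for t in tokens[4:7])
    values = np.array([float(t) for t in tokens[7:]])
    if values.size != nx * ny * nz:
        raise ValueError(
            f"{path}: expected {nx * ny * nz} densities, found {values.size}"
        )
    # Situs stores x fastest; our layout is rho[ix, iy, iz]
    rho = values.reshape((nz, ny, nx)).transpose(2, 1, 0)
    return DensityMap(origin, np.repeat(voxel, 3), rho)
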