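"""Synthetic two-state benchmark system and simulated target data.

A coarse two-domain hinge protein stands in for real open/closed benchmark
pairs: two helical Cα-bead arms joined at a hinge bead, with the second arm
rotated about the hinge axis between the two states.  It exercises exactly
the global shape change that SAXS and EM scores must detect, at a size
(60 beads) where a full cascade runs in minutes.

Target data mirrors how low-resolution targets are prepared for validation
studies: the SAXS target is the per-q mean over an ensemble of L sampled
conformations of the target state, with sigma(q) the per-q standard
deviation over the same ensemble; the EM target is a Gaussian-smoothed map
of the target state at a stated voxel size and resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import DensityMap, simulate_map
from .saxs import (
    FormFactorModel,
    ScatteringProfile,
    debye_profile,
    ensemble_average_profile,
)
from .structmodel import Atom, Conformation, ca_rmsd

__all__ = [
    "ToySystemSpec",
    "make_two_state_toy",
    "make_target_saxs",
    "make_target_map",
]

#: default q grid for toy targets (Å⁻¹): the low-angle range where a
#: 60-bead object's shape lives
DEFAULT_Q = np.linspace(0.0, 0.3, 31)


@dataclass
class ToySystemSpec:
    """Geometry of the two-state hinge toy.

    Each domain is a helical arm of ``n_res_domain*`` beads with
    consecutive-bead spacing ``bead_spacing`` Å (the virtual Cα-Cα
    distance).  ``hinge_angle_deg`` rotates domain 2 about an axis through
    the hinge bead between the "open" (straight) and "closed" (bent)
    states.  ``jitter`` adds a small deterministic coordinate perturbation
    so the chain is not perfectly symmetric.
    """

    n_res_domain1: int = 30
    n_res_domain2: int = 30
    hinge_angle_deg: float = 45.0
    bead_spacing: float = 3.8
    helix_radius: float = 2.3
    helix_rise: float = 1.5
    curvature_deg: float = 40.0
    jitter: float = 0.05
    rng_seed: int = 0


def _helical_arm(n: int, spec: ToySystemSpec) -> np.ndarray:
    """Beads on a helix whose axis curves gently in the y-z plane.

    The axis starts along +z and its tangent rotates by ``curvature_deg``
    in total over the chain (about the x axis), giving the molecule a
    banana-like shape.  The curvature plane coincides with the hinge-bend
    plane, so the two states are planar-curved in the same plane; it breaks
    the axial symmetry of a straight rod, which would otherwise make the
    low-resolution density blind to the plane in which the hinge opens.
    Consecutive beads are ``bead_spacing`` apart up to the small correction
    introduced by the curvature.
    """
    r = spec.helix_radius
    rise = spec.helix_rise
    chord = spec.bead_spacing**2 - rise**2
    if chord <= 0:
        raise ValueError("helix_rise must be smaller than bead_spacing")
    if 2.0 * r < np.sqrt(chord):
        raise ValueError("helix_radius too small for the requested bead spacing")
    dtheta = 2.0 * np.arcsin(np.sqrt(chord) / (2.0 * r))
    gamma = np.deg2rad(spec.curvature_deg) / max(n - 1, 1)  # axis turn per bead
    xhat = np.array([1.0, 0.0, 0.0])
    axis_point = np.zeros(3)
    coords = np.empty((n, 3))
    for k in range(n):
        phi = gamma * k
        tangent = np.array([0.0, np.sin(phi), np.cos(phi)])
        binormal = np.cross(tangent, xhat)
        theta = dtheta * k
        coords[k] = (
            axis_point
            + r * (np.cos(theta) - 1.0) * xhat
            + r * np.sin(theta) * binormal
        )
        axis_point = axis_point + rise * tangent
    return coords


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle_rad).as_matrix()


def make_two_state_toy(
    spec: ToySystemSpec | None = None,
) -> tuple[Conformation, Conformation]:
    """Build the (closed, open) pair of Cα-bead conformations.

    The open state is a continuous two-arm helical chain; the closed state
    shares domain 1 and has domain 2 rigidly rotated by the hinge angle
    about the x axis through the hinge bead.  Atom count and ordering are
    identical between the states, and the construction is fully determined
    by ``spec.rng_seed``.

    Raises ``ValueError`` when the two states are too similar
    (Cα RMSD <= 3 Å, e.g. at hinge angle 0).
    """
    spec = spec or ToySystemSpec()
    n1, n2 = spec.n_res_domain1, spec.n_res_domain2
    n = n1 + n2
    rng = np.random.default_rng(spec.rng_seed)
    open_coords = _helical_arm(n, spec)
    open_coords = open_coords + rng.normal(scale=spec.jitter, size=(n, 3))

    hinge = open_coords[n1 - 1]
    R = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(spec.hinge_angle_deg))
    closed_coords = open_coords.copy()
    closed_coords[n1:] = (open_coords[n1:] - hinge) @ R.T + hinge

    atoms = [
        Atom(name="CA", residue_number=i + 1, residue_name="ALA", chain_id="A", element="C")
        for i in range(n)
    ]
    closed = Conformation(atoms=atoms, coords=closed_coords, id="toy/closed")
    open_ = Conformation(atoms=list(atoms), coords=open_coords, id="toy/open")
    rmsd = ca_rmsd(closed, open_)
    if rmsd <= 3.0:
        raise ValueError(
            f"open/closed RMSD {rmsd:.2f} Å <= 3 Å; increase the hinge angle"
        )
    return closed, open_


def make_target_saxs(
    state: Conformation,
    sampler,
    L: int = 100,
    q: np.ndarray | None = None,
    rng_seed: int = 0,
    ff: FormFactorModel | None = None,
) -> ScatteringProfile:
    """Simulated target SAXS profile from an ensemble around a state.

    Runs the sampler from ``state`` for ``L`` frames, computes each frame's
    Debye profile, and averages: the target intensity is the per-q mean of
    the L curves and sigma(q) their per-q sample standard deviation.
    """
    if L < 2:
        raise ValueError("need L >= 2 for a defined sigma")
    q = DEFAULT_Q if q is None else np.asarray(q, float)
    frames = sampler(state, L, rng_seed)
    profiles = [debye_profile(f, q, ff) for f in frames]
    return ensemble_average_profile(profiles)


def make_target_map(
    state: Conformation,
    voxel: float = 1.0,
    resolution: float = 5.0,
    pad: float = 25.0,
) -> DensityMap:
    """Gaussian-smoothed target density map of a state (defaults: 1 Å voxel,
    5 Å resolution).

    The generous default padding keeps the other state's conformations --
    and everything a cascade samples between the two -- inside the lattice,
    so no model density is ever clipped at the map edge during scoring
    (clipping would bias the normalized correlation)."""
    return simulate_map(state, voxel=voxel, resolution=resolution, pad=pad)
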