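"""Conformational-sampling backends for the cascade.

The cascade is sampler-agnostic: anything callable as
``sampler(seed_conf, n_frames, seed)`` returning a list of conformations can
drive it.  Two backends live here:

* a built-in desk-scale sampler — Metropolis Monte Carlo on Cα beads under a
  harmonic elastic-network (ENM) energy rebuilt from each seed's contact map,
  cheap enough that a full cascade runs in minutes on one CPU; and
* a subprocess contract for external simulation engines that exchange frames
  as multi-model PDB.

The built-in sampler makes no claim to molecular-mechanics realism; it
produces stereochemically sane, chain-connected fluctuations around a seed,
which is all the selection logic needs.
"""

from __future__ import annotations

import logging
import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structmodel import (
    Conformation,
    read_multi_model_pdb,
    write_pdb,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerSpec",
    "ElasticNetwork",
    "EnmMcSampler",
    "enm_mc_propagate",
    "preliminary_run",
    "ExternalSampler",
    "external_propagate",
]


@dataclass
class SamplerSpec:
    """Parameters of a sampling backend.

    For the built-in ENM-MC sampler: ``cutoff`` (Å) builds the contact
    network and ``sweeps_per_frame`` Monte-Carlo sweeps separate successive
    snapshots.  Each sweep mixes two move types: one Gaussian trial
    displacement of ``step_size`` Å per bead, plus ``mode_moves_per_sweep``
    collective trials along the seed network's three softest normal modes
    with amplitude ``mode_step`` — single-bead moves relax local geometry
    while the collective moves let quasi-rigid domains actually go
    somewhere.  ``temperature`` is kT in units of the spring energy
    (long-range springs have k = 1 per Å²; sequence-local pairs are
    stiffened by ``bond_factor`` / ``local_factor`` so bonded distances and
    secondary-structure-like geometry stay close to the seed's).
    For external engines only ``command_template`` matters.
    """

    kind: str = "builtin_enm_mc"
    frames_to_return: int = 20
    sweeps_per_frame: int = 5
    temperature: float = 3.0
    cutoff: float = 10.0
    step_size: float = 0.3
    bond_factor: float = 200.0
    local_factor: float = 60.0
    mode_moves_per_sweep: int = 2
    mode_step: float = 1.3
    boost_steps: int = 200
    boost_amplitude: float = 3.0
    boost_temperature_factor: float = 25.0
    command_template: str = ""

    def __post_init__(self) -> None:
        if self.frames_to_return < 1:
            raise ValueError("frames_to_return must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


class ElasticNetwork:
    """Harmonic springs between Cα beads within a distance cutoff.

    Spring rest lengths equal the seed's pair distances, so the seed is the
    exact energy minimum; the network therefore re-centers on each new seed,
    which is what lets the cascade ratchet a structure away from where it
    started.  Spring constants depend on sequence separation: k_spring for
    long-range contacts, ``local_factor`` times stiffer for pairs within 4
    residues (preserving local, secondary-structure-like geometry) and
    ``bond_factor`` times stiffer for the i,i+1 virtual bonds.
    """

    def __init__(
        self,
        coords: np.ndarray,
        cutoff: float = 10.0,
        k_spring: float = 1.0,
        bond_factor: float = 200.0,
        local_factor: float = 60.0,
    ):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        from scipy.spatial.distance import pdist, squareform

        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if n < 2:
            raise ValueError("need at least 2 beads")
        dmat = squareform(pdist(coords))
        ii, jj = np.where((dmat < cutoff) & (np.arange(n)[:, None] < np.arange(n)))
        if len(ii) == 0:
            raise ValueError("no contacts within cutoff")
        graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp > 1:
            raise ValueError(
                f"contact network is disconnected ({n_comp} components); "
                "increase the cutoff"
            )
        self.n = n
        self.i = ii
        self.j = jj
        self.d0 = dmat[ii, jj]
        sep = np.abs(ii - jj)
        self.k = np.where(
            sep == 1,
            bond_factor * k_spring,
            np.where(sep <= 4, local_factor * k_spring, k_spring),
        )
        # per-bead neighbor lists for incremental energy updates
        self._nb: list[tuple[np.ndarray, np.ndarray]] = []
        for b in range(n):
            mask = (ii == b) | (jj == b)
            partners = np.where(ii[mask] == b, jj[mask], ii[mask])
            self._nb.append((partners, np.where(mask)[0]))

    def energy(self, coords: np.ndarray) -> float:
        d = np.linalg.norm(coords[self.i] - coords[self.j], axis=1)
        return float(0.5 * np.sum(self.k * (d - self.d0) ** 2))

    def bead_energy(self, coords: np.ndarray, bead: int, pos: np.ndarray) -> float:
        """Energy of the springs touching one bead, with that bead at ``pos``."""
        partners, springs = self._nb[bead]
        d = np.linalg.norm(coords[partners] - pos, axis=1)
        return float(0.5 * np.sum(self.k[springs] * (d - self.d0[springs]) ** 2))

    def hessian(self, coords: np.ndarray) -> np.ndarray:
        """3n x 3n anisotropic-network Hessian at the given coordinates."""
        n = self.n
        H = np.zeros((3 * n, 3 * n))
        for idx in range(len(self.i)):
            a, b = self.i[idx], self.j[idx]
            dv = coords[b] - coords[a]
            d = np.linalg.norm(dv)
            if d == 0:
                raise ValueError("coincident beads in network")
            block = self.k[idx] * np.outer(dv, dv) / d**2
            H[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] -= block
            H[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] -= block
            H[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] += block
            H[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] += block
        return H

    def low_modes(self, coords: np.ndarray, n_modes: int = 3) -> np.ndarray:
        """Lowest non-trivial normal modes, shape (n_modes, n, 3).

        Raises ``ValueError`` when more than six near-zero modes exist
        (degenerate geometry, e.g. collinear beads).
        """
        H = self.hessian(coords)
        evals, evecs = np.linalg.eigh(H)
        scale = max(float(evals[-1]), 1e-12)
        near_zero = int(np.sum(evals < 1e-8 * scale))
        if near_zero > 6:
            raise ValueError(
                f"{near_zero} near-zero modes (expected 6 rigid-body modes); "
                "geometry is degenerate"
            )
        modes = evecs[:, near_zero : near_zero + n_modes].T
        return modes.reshape(len(modes), self.n, 3)


def _require_ca_beads(conf: Conformation) -> None:
    if not all(a.name == "CA" for a in conf.atoms):
        raise ValueError(
            "the built-in ENM-MC sampler operates on Cα-bead models only; "
            "map your structure to its Cα trace first"
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _network_from_spec(coords: np.ndarray, spec: SamplerSpec) -> ElasticNetwork:
    return ElasticNetwork(
        coords,
        cutoff=spec.cutoff,
        bond_factor=spec.bond_factor,
        local_factor=spec.local_factor,
    )


def _mc_sweeps(
    coords: np.ndarray,
    network: ElasticNetwork,
    spec: SamplerSpec,
    rng: np.random.Generator,
    n_sweeps: int,
    modes: np.ndarray | None = None,
) -> int:
    """Run mixed Metropolis sweeps in place; returns accepted moves.

    Each sweep proposes one Gaussian displacement per bead (in random
    order), followed by ``spec.mode_moves_per_sweep`` collective trials
    along the supplied normal modes.
    """
    n = network.n
    kt = spec.temperature
    accepted = 0
    for _ in range(n_sweeps):
        order = rng.permutation(n)
        trials = rng.normal(scale=spec.step_size, size=(n, 3))
        urand = rng.random(n)
        for t, bead in enumerate(order):
            old = coords[bead]
            new = old + trials[t]
            de = network.bead_energy(coords, bead, new) - network.bead_energy(
                coords, bead, old
            )
            if de <= 0 or (kt > 0 and urand[t] < math.exp(-de / kt)):
                coords[bead] = new
                accepted += 1
        if modes is not None:
            energy = network.energy(coords)
            for _ in range(spec.mode_moves_per_sweep):
                c = rng.normal(scale=spec.mode_step, size=len(modes))
                trial = coords + np.tensordot(c, modes, axes=1)
                e_trial = network.energy(trial)
                de = e_trial - energy
                if de <= 0 or (kt > 0 and rng.random() < math.exp(-de / kt)):
                    coords[...] = trial
                    energy = e_trial
                    accepted += 1
    return accepted


def enm_mc_propagate(
    seed_conf: Conformation,
    spec: SamplerSpec,
    rng_seed,
) -> list[Conformation]:
    """Propagate a Cα-bead model by elastic-network Monte Carlo.

    Builds the network from the seed's contacts within ``spec.cutoff`` and
    returns ``spec.frames_to_return`` snapshots taken every
    ``spec.sweeps_per_frame`` sweeps.  Sweeps mix per-bead displacements
    with collective moves along the seed network's three softest modes;
    when the mode computation is degenerate the collective moves are
    skipped with a warning.  Deterministic given the seed value.
    """
    _require_ca_beads(seed_conf)
    rng = _as_rng(rng_seed)
    network = _network_from_spec(seed_conf.coords, spec)
    modes: np.ndarray | None = None
    if spec.mode_moves_per_sweep > 0:
        try:
            modes = network.low_modes(seed_conf.coords, n_modes=3)
        except ValueError as exc:
            logger.warning("collective moves disabled: %s", exc)
    coords = seed_conf.coords.copy()
    frames = []
    for f in range(spec.frames_to_return):
        _mc_sweeps(coords, network, spec, rng, spec.sweeps_per_frame, modes)
        frames.append(
            seed_conf.with_coords(coords.copy(), new_id=f"{seed_conf.id}/frame{f}")
        )
    return frames


def _boost_phase(
    coords: np.ndarray,
    network: ElasticNetwork,
    spec: SamplerSpec,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Collective Metropolis moves along the 3 lowest non-trivial modes.

    The desk-scale analogue of mode-amplified enhanced sampling: trial moves
    are random combinations of the seed network's soft modes with an
    amplified step, accepted at an elevated effective temperature
    (``boost_temperature_factor`` times kT) on the collective subspace, so
    large-scale motions appear quickly.
    """
    modes = network.low_modes(coords, n_modes=3)
    kt = spec.temperature * spec.boost_temperature_factor
    energy = network.energy(coords)
    snapshots = []
    snap_every = max(1, spec.boost_steps // 10)
    for step in range(spec.boost_steps):
        c = rng.normal(scale=spec.boost_amplitude, size=len(modes))
        trial = coords + np.tensordot(c, modes, axes=1)
        e_trial = network.energy(trial)
        de = e_trial - energy
        if de <= 0 or (kt > 0 and rng.random() < math.exp(-de / kt)):
            coords[...] = trial
            energy = e_trial
        if (step + 1) % snap_every == 0:
            snapshots.append(coords.copy())
    return snapshots


def preliminary_run(
    initial: Conformation,
    spec: SamplerSpec,
    rng_seed,
    boost: bool = False,
) -> list[Conformation]:
    """Initial exploration from the starting structure.

    Ordinary ENM-MC propagation, optionally preceded by a phase of
    collective moves along the seed network's three softest normal modes
    with amplified step size.  If the Hessian is degenerate (more than six
    near-zero modes) the boost is disabled with a warning and plain
    propagation proceeds.
    """
    _require_ca_beads(initial)
    rng = _as_rng(rng_seed)
    frames: list[Conformation] = []
    start = initial
    if boost:
        network = _network_from_spec(initial.coords, spec)
        coords = initial.coords.copy()
        try:
            snapshots = _boost_phase(coords, network, spec, rng)
        except ValueError as exc:
            logger.warning("mode boost disabled: %s", exc)
        else:
            frames.extend(
                initial.with_coords(snap, new_id=f"{initial.id}/boost{i}")
                for i, snap in enumerate(snapshots)
            )
            start = initial.with_coords(coords, new_id=f"{initial.id}/boosted")
    frames.extend(enm_mc_propagate(start, spec, rng))
    return frames


class EnmMcSampler:
    """Callable wrapper satisfying the cascade's sampler contract."""

    def __init__(self, spec: SamplerSpec | None = None, boost_preliminary: bool = False):
        self.spec = spec or SamplerSpec()
        self.boost_preliminary = boost_preliminary

    def __call__(
        self, seed_conf: Conformation, n_frames: int, seed
    ) -> list[Conformation]:
        spec = self.spec
        if n_frames != spec.frames_to_return:
            spec = SamplerSpec(**{**spec.__dict__, "frames_to_return": n_frames})
        return enm_mc_propagate(seed_conf, spec, seed)

    def preliminary(
        self, initial: Conformation, n_frames: int, seed
    ) -> list[Conformation]:
        spec = self.spec
        if n_frames != spec.frames_to_return:
            spec = SamplerSpec(**{**spec.__dict__, "frames_to_return": n_frames})
        return preliminary_run(initial, spec, seed, boost=self.boost_preliminary)


def external_propagate(
    seed_conf: Conformation,
    spec: SamplerSpec,
    rng_seed: int,
    scratch: str | Path | None = None,
) -> list[Conformation]:
    """Run an external simulation engine through a command template.

    The template must contain ``{input}``, ``{output}``, ``{seed}`` and
    ``{steps}`` placeholders; the engine reads a single-model PDB, runs
    ``{steps}`` of whatever dynamics it implements, and writes a multi-model
    PDB with exactly ``spec.frames_to_return`` models.  On engine failure or
    a frame-count mismatch the scratch directory is preserved for
    inspection.
    """
    template = spec.command_template
    for placeholder in ("{input}", "{output}", "{seed}", "{steps}"):
        if placeholder not in template:
            raise ValueError(f"command template lacks {placeholder}")
    workdir = Path(scratch) if scratch else Path(tempfile.mkdtemp(prefix="pacsfit_ext_"))
    workdir.mkdir(parents=True, exist_ok=True)
    in_path = workdir / "seed.pdb"
    out_path = workdir / "frames.pdb"
    write_pdb(seed_conf, in_path)
    command = template.format(
        input=shlex.quote(str(in_path)),
        output=shlex.quote(str(out_path)),
        seed=int(rng_seed),
        steps=spec.sweeps_per_frame * spec.frames_to_return,
    )
    result = subprocess.run(command, shell=True, capture_output=True, text=True)
    if result.returncode != 0:
        raise RuntimeError(
            f"external engine failed (exit {result.returncode}): {command}\n"
            f"stderr: {result.stderr[-2000:]}\nscratch preserved at {workdir}"
        )
    frames = read_multi_model_pdb(out_path)
    if len(frames) != spec.frames_to_return:
        raise RuntimeError(
            f"engine returned {len(frames)} frames, expected "
            f"{spec.frames_to_return}; scratch preserved at {workdir}"
        )
    for i, frame in enumerate(frames):
        frame.id = f"{seed_conf.id}/ext{i}"
    return frames


class ExternalSampler:
    """Sampler-contract wrapper around :func:`external_propagate`."""

    def __init__(self, spec: SamplerSpec):
        if not spec.command_template:
            raise ValueError("external sampler needs a command template")
        self.spec = spec

    def __call__(self, seed_conf, n_frames, seed) -> list[Conformation]:
        spec = self.spec
        if n_frames != spec.frames_to_return:
            spec = SamplerSpec(**{**spec.__dict__, "frames_to_return": n_frames})
        return external_propagate(seed_conf, spec, seed)

    def preliminary(self, initial, n_frames, seed) -> list[Conformation]:
        return self(initial, n_frames, seed)
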