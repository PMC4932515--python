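"""Atomic-structure data model: PDB I/O, superposition, RMSD, radius of gyration.

Coordinates are in Angstrom throughout.  A :class:`Conformation` is an ordered
list of atom records plus an ``(n, 3)`` coordinate array; atom ordering is
stable under copy and rigid transformation, which the cascade relies on when
it hands seed structures between cycles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Conformation",
    "TransformRT",
    "read_pdb",
    "write_pdb",
    "ca_coords",
    "kabsch_superpose",
    "ca_rmsd",
    "radius_of_gyration",
]


@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates live in ``Conformation.coords``)."""

    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    element: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class Conformation:
    """An atomic model: ordered atoms + coordinates in Angstrom.

    Parameters
    ----------
    atoms
        Per-atom records, in file/creation order.
    coords
        ``(n, 3)`` float array, Angstrom.
    id
        Provenance string, e.g. ``"cycle3/rep7/frame12"``.
    """

    atoms: list[Atom]
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.atoms) != len(self.coords):
            raise ValueError(
                f"{len(self.atoms)} atoms but {len(self.coords)} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self, new_id: str | None = None) -> "Conformation":
        return Conformation(
            atoms=list(self.atoms),
            coords=self.coords.copy(),
            id=self.id if new_id is None else new_id,
        )

    def with_coords(self, coords: np.ndarray, new_id: str | None = None) -> "Conformation":
        """Same atoms, new coordinates (used by samplers and transforms)."""
        return Conformation(
            atoms=list(self.atoms),
            coords=np.asarray(coords, dtype=float),
            id=self.id if new_id is None else new_id,
        )

    def transformed(self, t: "TransformRT") -> "Conformation":
        return self.with_coords(t.apply(self.coords))


@dataclass(frozen=True)
class TransformRT:
    """A proper rigid-body transform: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "TransformRT":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "TransformRT":
        return TransformRT(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "TransformRT") -> "TransformRT":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return TransformRT(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


class PDBParseError(ValueError):
    """Raised for malformed or unusable PDB input."""


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_pdb(
    path,
    chain: str | None = None,
    model: int = 0,
    include_hetatm: bool = False,
) -> Conformation:
    """Read a PDB file into a :class:`Conformation`.

    Altloc groups are resolved to the highest-occupancy alternative (ties go
    to the first listed); HETATM records are excluded unless requested.

    Parameters
    ----------
    path
        PDB file path.
    chain
        Chain identifier; ``None`` keeps every chain.
    model
        Model index for multi-model files (0-based).
    include_hetatm
        Keep HETATM records (water and ligands) as well.
    """
    path = str(path)
    try:
        structure = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    except FileNotFoundError:
        raise
    if len(structure) == 0:
        raise PDBParseError(f"{path}: no models found")
    if model >= len(structure):
        raise PDBParseError(
            f"{path}: model index {model} out of range ({len(structure)} models)"
        )
    gmodel = structure[model]
    if chain is not None and gmodel.find_chain(chain) is None:
        available = ", ".join(ch.name for ch in gmodel)
        raise PDBParseError(f"{path}: chain {chain!r} not found (have: {available})")

    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    for gchain in gmodel:
        if chain is not None and gchain.name != chain:
            continue
        for residue in gchain:
            is_het = residue.het_flag == "H"
            if is_het and not include_hetatm:
                continue
            for atom in _resolve_altlocs(residue):
                atoms.append(
                    Atom(
                        name=atom.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=gchain.name,
                        element=atom.element.name,
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                    )
                )
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not atoms:
        raise PDBParseError(f"{path}: selection is empty (chain={chain!r})")
    return Conformation(atoms=atoms, coords=np.array(coords), id=path)


def write_pdb(conf: Conformation, path) -> None:
    """Write a conformation as a single-model PDB file.

    Residue numbers above 9999 do not fit the fixed-width PDB ``resSeq``
    column and raise ``ValueError`` (hybrid-36 is deliberately not emitted;
    the cascade's own structures are renumbered well below the limit).
    """
    _write_models([conf], path)


def write_multi_model_pdb(confs: list[Conformation], path) -> None:
    """Write conformations as MODEL/ENDMDL records (frame-exchange format)."""
    _write_models(confs, path)


def _write_models(confs: list[Conformation], path) -> None:
    if not confs:
        raise ValueError("no conformations to write")
    structure = gemmi.Structure()
    structure.name = "pacsfit"
    for imodel, conf in enumerate(confs):
        if conf.n_atoms == 0:
            raise ValueError("cannot write an empty conformation")
        gmodel = gemmi.Model(str(imodel + 1))
        chain_map: dict[str, gemmi.Chain] = {}
        for atom, xyz in zip(conf.atoms, conf.coords):
            if atom.residue_number > 9999:
                raise ValueError(
                    f"residue number {atom.residue_number} exceeds the PDB "
                    "fixed-width limit of 9999"
                )
            cid = atom.chain_id or "A"
            if cid not in chain_map:
                chain_map[cid] = gemmi.Chain(cid)
            gchain = chain_map[cid]
            if (
                len(gchain) == 0
                or gchain[-1].seqid.num != atom.residue_number
                or gchain[-1].name != atom.residue_name
            ):
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_number, " ")
                gchain.add_residue(res)
            gatom = gemmi.Atom()
            gatom.name = atom.name
            gatom.element = gemmi.Element(atom.element or "X")
            gatom.occ = atom.occupancy
            gatom.b_iso = atom.b_factor
            gatom.pos = gemmi.Position(*xyz)
            gchain[-1].add_atom(gatom)
        for gchain in chain_map.values():
            gmodel.add_chain(gchain)
        structure.add_model(gmodel)
    structure.write_pdb(str(path))


def read_multi_model_pdb(path) -> list[Conformation]:
    """Read every model of a multi-model PDB as a list of conformations."""
    path = str(path)
    try:
        structure = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    frames = []
    for imodel in range(len(structure)):
        frames.append(read_pdb(path, model=imodel))
        frames[-1].id = f"{path}#model{imodel}"
    if not frames:
        raise PDBParseError(f"{path}: no models found")
    return frames


def ca_coords(conf: Conformation) -> np.ndarray:
    """Coordinates of Cα atoms, one per residue, in residue order.

    A residue lacking a CA atom is skipped with a warning rather than an
    error, since truncated loops are common in crystal structures.
    """
    mask = np.array([a.name == "CA" for a in conf.atoms])
    if not mask.any():
        raise ValueError("conformation has no CA atoms")
    n_res = len({(a.chain_id, a.residue_number) for a in conf.atoms})
    n_ca = int(mask.sum())
    if n_ca < n_res:
        logger.warning(
            "%d of %d residues lack a CA atom; they are skipped", n_res - n_ca, n_res
        )
    return conf.coords[mask]


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[TransformRT, float]:
    """Least-squares rigid superposition of matched point sets (Kabsch).

    Returns the proper-rotation transform minimizing the RMSD of
    ``transform(mobile)`` against ``reference``, and that minimal RMSD.
    Reflections are excluded by construction.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = TransformRT(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return transform, rmsd


def ca_rmsd(a: Conformation, b: Conformation, superpose: bool = True) -> float:
    """Cα RMSD between two conformations, in Angstrom.

    Residue correspondence is positional over the Cα list.  With
    ``superpose=True`` (default) the minimized RMSD after Kabsch
    superposition is returned; otherwise the RMSD in the current frames.
    """
    xa, xb = ca_coords(a), ca_coords(b)
    if len(xa) != len(xb):
        raise ValueError(
            f"CA count mismatch ({len(xa)} vs {len(xb)}); select a common "
            "residue range before comparing"
        )
    if superpose:
        _, rmsd = kabsch_superpose(xa, xb)
        return rmsd
    return float(np.sqrt(((xa - xb) ** 2).sum() / len(xa)))


def radius_of_gyration(conf: Conformation, ca_only: bool = True) -> float:
    """Radius of gyration: RMS distance of atoms from their centroid (Å).

    Unweighted by default — every selected atom counts equally; with
    ``ca_only`` the selection is the Cα trace, matching the coarse level at
    which scattering profiles are computed here.
    """
    xyz = ca_coords(conf) if ca_only else conf.coords
    if len(xyz) == 0:
        raise ValueError("empty selection")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum() / len(xyz)))
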