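"""Benchmark computations on published crystal structures.

These helpers recompute reference numbers for the classic open/closed
benchmark systems (adenylate kinase 1AKE/4AKE, the GroEL monomer 1OEL) from
locally supplied PDB files.  The structures themselves are not bundled;
download them from the PDB (e.g. ``https://files.rcsb.org/download/1AKE.pdb``)
into a directory and point these functions at it.
"""

from __future__ import annotations

from pathlib import Path

from .em import rigid_body_fit, simulate_map
from .structmodel import Conformation, ca_coords, ca_rmsd, read_pdb

__all__ = [
    "load_benchmark_structure",
    "open_closed_ca_rmsd",
    "residue_count",
    "initial_fit_cc",
]


def load_benchmark_structure(path, chain: str = "A") -> Conformation:
    """Read one chain of a benchmark PDB entry (protein atoms only)."""
    return read_pdb(path, chain=chain)


def open_closed_ca_rmsd(
    closed_path, open_path, chain: str = "A", n_residues: int | None = None
) -> float:
    """Cα RMSD between the closed and open crystal structures of a pair.

    Residue correspondence is positional; ``n_residues`` truncates both
    Cα lists to a common length when the constructs differ slightly.
    """
    a = read_pdb(closed_path, chain=chain)
    b = read_pdb(open_path, chain=chain)
    xa, xb = ca_coords(a), ca_coords(b)
    if n_residues is not None:
        xa, xb = xa[:n_residues], xb[:n_residues]
    n = min(len(xa), len(xb))
    from .structmodel import kabsch_superpose

    _, rmsd = kabsch_superpose(xa[:n], xb[:n])
    return rmsd


def residue_count(path, chain: str) -> int:
    """Number of residues with a Cα atom in one chain of a PDB entry."""
    conf = read_pdb(path, chain=chain)
    return len(ca_coords(conf))


def initial_fit_cc(
    mobile_path,
    target_path,
    chain: str = "A",
    voxel: float = 1.0,
    resolution: float = 5.0,
) -> float:
    """CC of one crystal structure rigid-body fitted into the simulated map
    of the other (voxel and resolution as in the validation setup)."""
    mobile = read_pdb(mobile_path, chain=chain)
    target = read_pdb(target_path, chain=chain)
    target_map = simulate_map(target, voxel=voxel, resolution=resolution, pad=15.0)
    _, cc_value = rigid_body_fit(mobile, target_map, resolution=resolution)
    return cc_value
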