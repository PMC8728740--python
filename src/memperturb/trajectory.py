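"""Trajectory container and multi-frame GRO/PDB input/output.

Coordinates are stored in nm as read (wrapped if the file is wrapped); times
in ns; box vectors are the orthorhombic lengths in nm.  Unwrapping is done on
demand by consumers and never mutates the stored trajectory.

File parsing and writing are delegated to mdtraj; this module adapts its
containers to the role-annotated :class:`~memperturb.topology.Topology`.
Binary formats (XTC/TRR) are deliberately not parsed here: load them with
mdtraj against a matching topology file and hand the result to
:func:`from_mdtraj` — that function is the documented adapter seam.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import mdtraj as md
import numpy as np

from .config import ConfigurationError
from .topology import (
    Atom,
    DEFAULT_ROLE_SPEC,
    RoleSpec,
    Topology,
    assign_initial_leaflets,
    classify_resname,
)


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates format or ordering invariants."""


@dataclass
class Trajectory:
    """Frames of atom positions with an orthorhombic periodic box.

    Attributes
    ----------
    times : (n_frames,) float array, ns, strictly increasing.
    xyz : (n_frames, n_atoms, 3) float array, nm.
    box : (n_frames, 3) float array of box lengths, nm.
    topology : role-annotated topology.
    """

    times: np.ndarray
    xyz: np.ndarray
    box: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise TrajectoryFormatError("xyz must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.xyz) or len(self.box) != len(self.xyz):
            raise TrajectoryFormatError("times, xyz and box must share frame count")
        if len(self.times) == 0:
            raise TrajectoryFormatError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryFormatError("frame times must be strictly increasing")
        if np.any(self.box <= 0):
            raise TrajectoryFormatError("box vectors must be positive")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise TrajectoryFormatError(
                f"{self.xyz.shape[1]} coordinates per frame but "
                f"{self.topology.n_atoms} topology atoms"
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def slice_frames(self, sel: slice | Sequence[int]) -> "Trajectory":
        idx = np.arange(self.n_frames)[sel]
        return Trajectory(self.times[idx], self.xyz[idx], self.box[idx], self.topology)


def _atoms_from_mdtraj(top: md.Topology) -> list[Atom]:
    atoms = []
    for a in top.atoms:
        resname = a.residue.name
        atoms.append(
            Atom(
                index=a.index,
                name=a.name,
                mol_id=a.residue.index,
                mol_kind=classify_resname(resname),
                resname=resname,
            )
        )
    return atoms


def from_mdtraj(
    t: md.Trajectory,
    role_spec: RoleSpec = DEFAULT_ROLE_SPEC,
) -> Trajectory:
    """Adapt an mdtraj trajectory (any format mdtraj can load) to a Trajectory.

    mdtraj keeps nm/ps units; times are converted to ns.
    """
    if t.unitcell_lengths is None:
        raise TrajectoryFormatError("trajectory has no periodic box information")
    raw_times = np.asarray(t.time, dtype=float)
    if len(raw_times) > 1 and np.any(np.diff(raw_times) < 0):
        bad = int(np.nonzero(np.diff(raw_times) < 0)[0][0]) + 1
        raise TrajectoryFormatError(f"frame times decrease at frame {bad}")
    atoms = _atoms_from_mdtraj(t.topology)
    xyz0 = np.asarray(t.xyz[0], dtype=float)
    from .topology import resolve_roles

    roles = resolve_roles(atoms, xyz0, role_spec)
    leaflet0 = assign_initial_leaflets(atoms, roles, xyz0)
    topology = Topology(atoms=atoms, roles=roles, leaflet0=leaflet0)
    times_ns = np.asarray(t.time, dtype=float) / 1000.0
    if len(times_ns) > 1 and np.all(np.diff(times_ns) == 0):
        # files without time stamps: fall back to frame index in ns
        times_ns = np.arange(len(times_ns), dtype=float)
    return Trajectory(
        times=times_ns,
        xyz=np.asarray(t.xyz, dtype=float),
        box=np.asarray(t.unitcell_lengths, dtype=float),
        topology=topology,
    )


def read_trajectory(
    path: str | Path,
    role_spec: RoleSpec = DEFAULT_ROLE_SPEC,
) -> Trajectory:
    """Read a multi-frame GRO or PDB trajectory and resolve roles.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    TrajectoryFormatError
        For unparsable frames or non-monotone frame times.
    ConfigurationError
        When a required role pattern matches zero atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".xtc", ".trr", ".dcd"):
        raise TrajectoryFormatError(
            f"binary format {suffix} needs a topology file; load it with "
            "mdtraj.load(path, top=...) and call memperturb.from_mdtraj"
        )
    if suffix not in (".gro", ".pdb"):
        raise TrajectoryFormatError(f"unsupported trajectory format {suffix!r}")
    try:
        t = md.load(str(path))
    except Exception as exc:  # mdtraj raises assorted exception types
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc
    return from_mdtraj(t, role_spec)


def to_mdtraj(traj: Trajectory) -> md.Trajectory:
    """Convert to an mdtraj trajectory (one residue per molecule)."""
    top = md.Topology()
    chain = top.add_chain()
    res_by_mol: dict[int, md.core.topology.Residue] = {}
    for a in traj.topology.atoms:
        if a.mol_id not in res_by_mol:
            res_by_mol[a.mol_id] = top.add_residue(a.resname, chain)
        try:
            elem = md.element.Element.getBySymbol(a.name[0])
        except KeyError:
            elem = md.element.virtual
        top.add_atom(a.name, elem, res_by_mol[a.mol_id])
    t = md.Trajectory(
        xyz=np.asarray(traj.xyz, dtype=np.float32),
        topology=top,
        time=np.asarray(traj.times) * 1000.0,
        unitcell_lengths=np.asarray(traj.box, dtype=np.float32),
        unitcell_angles=np.full((traj.n_frames, 3), 90.0, dtype=np.float32),
    )
    return t


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame GRO (or PDB, by extension) file.

    Round trip through :func:`read_trajectory` reproduces coordinates within
    the 0.001 nm precision of the GRO format.
    """
    path = Path(path)
    if traj.n_frames == 0:
        raise TrajectoryFormatError("refusing to write an empty trajectory")
    t = to_mdtraj(traj)
    try:
        t.save(str(path))
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc
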