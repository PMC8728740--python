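"""Per-frame membrane structural metrics.

Leaflet assignment, area per lipid (APL), phosphate-to-phosphate membrane
thickness (global and local-neighborhood variants), membrane center, and the
depth *d* of a permeation enhancer below/above the bilayer midplane.

The bilayer normal is the z axis throughout; boxes are orthorhombic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pbc import min_image_scalar, min_image_vectors
from .trajectory import Trajectory
from .topology import atom_mass


@dataclass
class MembraneMetricsSeries:
    """Per-frame structure metrics plus per-enhancer depth series."""

    times: np.ndarray
    apl: np.ndarray              # nm^2
    thickness_pp: np.ndarray     # nm, phosphate-plane separation
    z_center: np.ndarray         # nm
    pe_depth: dict[int, np.ndarray]  # pe mol id -> |z_com - z_center| per frame

    @property
    def leaflet_thickness(self) -> np.ndarray:
        return self.thickness_pp / 2.0

    def frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "apl_nm2": self.apl,
                "thickness_pp_nm": self.thickness_pp,
                "leaflet_thickness_nm": self.leaflet_thickness,
                "z_center_nm": self.z_center,
            }
        )

    def depth_table(self) -> pd.DataFrame:
        cols = {"time_ns": self.times}
        for pe_id, d in self.pe_depth.items():
            cols[f"d_pe{pe_id}_nm"] = d
        return pd.DataFrame(cols)


def assign_leaflets(traj: Trajectory, frame: int = 0) -> dict[int, str]:
    """Assign each phosphate-bearing lipid to the upper or lower leaflet.

    Sign of the phosphate z about the median phosphate z of the frame.  POPC
    does not flip in these systems, so the frame-0 assignment is valid for
    the whole trajectory (checked by :func:`verify_no_lipid_flipflop`).
    """
    phos = traj.topology.role_indices("phosphate")
    if phos.size == 0:
        raise ValueError("topology has no phosphate role atoms")
    z = traj.xyz[frame, phos, 2]
    z_med = float(np.median(z))
    out: dict[int, str] = {}
    for i, zi in zip(phos, z):
        mol = traj.topology.atoms[i].mol_id
        out[mol] = "upper" if zi >= z_med else "lower"
    lipid_ids = set(traj.topology.molecule_ids("POPC"))
    missing = lipid_ids - set(out)
    if missing:
        raise ValueError(f"lipids without a phosphate site: {sorted(missing)[:5]}")
    return out


def verify_no_lipid_flipflop(traj: Trajectory) -> bool:
    """True when every lipid keeps its frame-0 leaflet in all frames."""
    ref = assign_leaflets(traj, 0)
    for f in range(1, traj.n_frames):
        if assign_leaflets(traj, f) != ref:
            return False
    return True


def leaflet_phosphate_indices(traj: Trajectory, frame: int = 0) -> dict[str, np.ndarray]:
    """Phosphate atom indices split by leaflet."""
    labels = assign_leaflets(traj, frame)
    phos = traj.topology.role_indices("phosphate")
    mols = np.array([traj.topology.atoms[i].mol_id for i in phos])
    lab = np.array([labels[m] for m in mols])
    return {"upper": phos[lab == "upper"], "lower": phos[lab == "lower"]}


def area_per_lipid(traj: Trajectory, frame: int, n_leaflet_lipids: int = 64) -> float:
    """Lateral box area divided by the lipid count of one leaflet (nm^2).

    Inserted enhancers never enter the denominator; the reference count is
    the leaflet's lipid complement (64 by convention here).
    """
    if n_leaflet_lipids <= 0:
        raise ValueError("n_leaflet_lipids must be positive")
    bx, by = traj.box[frame, 0], traj.box[frame, 1]
    return float(bx * by / n_leaflet_lipids)


def membrane_center(traj: Trajectory, frame: int) -> float:
    """Midpoint of the two leaflets' mean phosphate z (nm)."""
    leaf = leaflet_phosphate_indices(traj)
    zu = traj.xyz[frame, leaf["upper"], 2].mean()
    zl = traj.xyz[frame, leaf["lower"], 2].mean()
    return float((zu + zl) / 2.0)


def membrane_thickness(traj: Trajectory, frame: int, mode: str = "global", k: int = 6) -> float:
    """Phosphate-plane separation (nm).

    ``global``: difference between the leaflets' mean phosphate z.
    ``local``: for every phosphate, the |z| distance to the mean z of its *k*
    nearest opposite-leaflet phosphates (nearest in xy under minimum image),
    averaged over all phosphates of both leaflets.

    Leaflet thickness is half the returned value.
    """
    leaf = leaflet_phosphate_indices(traj)
    up, lo = leaf["upper"], leaf["lower"]
    if up.size == 0 or lo.size == 0:
        raise ValueError("both leaflets must contain phosphates")
    xyz = traj.xyz[frame]
    box = traj.box[frame]
    if mode == "global":
        return float(abs(xyz[up, 2].mean() - xyz[lo, 2].mean()))
    if mode != "local":
        raise ValueError(f"unknown thickness mode {mode!r}")

    def one_side(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        dxy = min_image_vectors(xyz[a, None, :2], xyz[None, b, :2], box[:2])
        r2 = np.sum(dxy**2, axis=-1)
        kk = min(k, b.size)
        nearest = np.argpartition(r2, kk - 1, axis=1)[:, :kk]
        zb = xyz[b, 2][nearest].mean(axis=1)
        dz = min_image_scalar(xyz[a, 2] - zb, box[2])
        return np.abs(dz)

    per_lipid = np.concatenate([one_side(up, lo), one_side(lo, up)])
    return float(per_lipid.mean())


def pe_depth(traj: Trajectory, frame: int, pe_id: int) -> float:
    """|z| distance (nm) of an enhancer's heavy-atom COM from the membrane center.

    Minimum-image handled along z, so a wrapped enhancer reports the same
    depth as an unwrapped one.
    """
    idx = traj.topology.atom_indices(pe_id)
    if idx.size == 0:
        raise KeyError(f"unknown PE molecule {pe_id}")
    names = [traj.topology.atoms[i].name for i in idx]
    heavy = np.array([i for i, n in zip(idx, names) if not n.upper().startswith("H")])
    w = np.array([atom_mass(traj.topology.atoms[i].name) for i in heavy])
    box_z = traj.box[frame, 2]
    zc = membrane_center(traj, frame)
    # COM under PBC: accumulate minimum-image offsets about the first atom
    z = traj.xyz[frame, heavy, 2]
    z_rel = z[0] + min_image_scalar(z - z[0], box_z)
    z_com = float(np.average(z_rel, weights=w))
    return float(abs(min_image_scalar(z_com - zc, box_z)))


def membrane_metrics_series(
    traj: Trajectory,
    n_leaflet_lipids: int = 64,
    thickness_mode: str = "global",
    k: int = 6,
) -> MembraneMetricsSeries:
    """Compute APL, thickness, membrane center and PE depths for every frame."""
    n = traj.n_frames
    apl = np.empty(n)
    thick = np.empty(n)
    zc = np.empty(n)
    pe_ids = traj.topology.molecule_ids("PE")
    depth = {pe: np.empty(n) for pe in pe_ids}
    for f in range(n):
        apl[f] = area_per_lipid(traj, f, n_leaflet_lipids)
        thick[f] = membrane_thickness(traj, f, mode=thickness_mode, k=k)
        zc[f] = membrane_center(traj, f)
        for pe in pe_ids:
            depth[pe][f] = pe_depth(traj, f, pe)
    return MembraneMetricsSeries(
        times=traj.times.copy(), apl=apl, thickness_pp=thick, z_center=zc, pe_depth=depth
    )
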