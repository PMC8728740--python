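"""Chain order parameters and lateral diffusion.

The deuterium order parameter of a C–H bond against the bilayer normal
(fixed to +z for these planar membranes) is

    S_CD = ⟨ (3 cos²θ − 1) / 2 ⟩,

1 for perfect alignment with the normal, −0.5 for bonds lying in the
membrane plane, 0 for an isotropic distribution.  When hydrogens are not
present (united-atom or synthetic chains) the two C–H directions of carbon
n are reconstructed from the backbone geometry of C(n−1), C(n), C(n+1):
they lie in the plane spanned by the in-plane bisector of the two C–C
bonds and the normal of the C–C–C plane, at the tetrahedral half-angle.

Lateral diffusion follows the 2-D Einstein relation: D_L is slope/4 of a
least-squares line through the mean squared displacement, which is averaged
over molecules and over all sliding time origins (computed with the FFT
autocorrelation identity).  Per-leaflet center-of-mass motion is removed
before the MSD so leaflet drift does not contaminate the estimate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geometry import assign_leaflets
from .pbc import min_image_vectors
from .trajectory import Trajectory

#: Half of the tetrahedral H–C–H angle.
_TETRA_HALF = math.radians(109.47 / 2.0)


@dataclass
class OrderProfile:
    """Per-carbon order parameters along an acyl chain."""

    carbons: list[str]
    s_cd: np.ndarray
    n_vectors: np.ndarray

    @property
    def chain_average(self) -> float:
        return float(np.average(self.s_cd, weights=self.n_vectors))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"carbon": self.carbons, "s_cd": self.s_cd, "n_vectors": self.n_vectors}
        )


@dataclass
class DiffusionEstimate:
    """MSD curve and the Einstein-relation diffusion coefficient."""

    lags: np.ndarray          # ns
    msd: np.ndarray           # nm^2
    D: float                  # nm^2/ns
    D_se: float
    fit_window: tuple[int, int]   # inclusive lag-index range used for the fit

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ns": self.lags, "msd_nm2": self.msd})


def order_parameter(vectors: np.ndarray) -> float:
    """S_CD of a set of bond vectors against the +z axis.

    Vectors need not be normalized.  Always in [−0.5, 1].
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValueError("vectors must be a non-empty (n, 3) array")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    cos2 = (v[:, 2] / norms) ** 2
    return float(np.mean(1.5 * cos2 - 0.5))


def reconstruct_ch_vectors(
    r_prev: np.ndarray, r: np.ndarray, r_next: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two C–H unit vectors of a methylene carbon from its neighbors.

    Orthogonal-bisector construction: with b₁, b₂ the unit C–C bonds, the
    C–H bonds point along cos(α)·s ± sin(α)·w where s = −(b₁+b₂)/|b₁+b₂|,
    w = b₁×b₂/|b₁×b₂| and α is half the tetrahedral angle.  Inputs may be
    stacked (…, 3) arrays.
    """
    b1 = r_prev - r
    b2 = r_next - r
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    s = -(b1 + b2)
    ns = np.linalg.norm(s, axis=-1, keepdims=True)
    if np.any(ns < 1e-10):
        raise ValueError("collinear backbone: C-H reconstruction is degenerate")
    s = s / ns
    w = np.cross(b1, b2)
    w = w / np.linalg.norm(w, axis=-1, keepdims=True)
    ca, sa = math.cos(_TETRA_HALF), math.sin(_TETRA_HALF)
    return ca * s + sa * w, ca * s - sa * w


def _chain_number(name: str) -> int | None:
    m = re.match(r"^C(\d+)$", name)
    return int(m.group(1)) if m else None


def _popc_chain_atoms(traj: Trajectory, chain: str) -> dict[int, list[int]]:
    """Per-lipid ordered tail-carbon atom indices for sn-1 ('sn1') or sn-2."""
    prefix = "C3" if chain == "sn1" else "C2"
    per_mol: dict[int, list[tuple[int, int]]] = {}
    for i in traj.topology.role_indices("tail_carbon_last3"):
        a = traj.topology.atoms[i]
        if a.name.startswith(prefix):
            per_mol.setdefault(a.mol_id, []).append((int(a.name[2:]), i))
    return {m: [i for _, i in sorted(v)] for m, v in per_mol.items()}


def _explicit_hydrogens(traj: Trajectory, carbon_idx: int) -> list[int]:
    """Hydrogens of the tail-hydrogen role bonded to a carbon (frame-0 proximity)."""
    top = traj.topology
    c = traj.xyz[0, carbon_idx]
    out = []
    for h in top.role_indices("tail_hydrogen_last3"):
        if top.atoms[h].mol_id == top.atoms[carbon_idx].mol_id:
            if np.linalg.norm(traj.xyz[0, h] - c) <= 0.15:
                out.append(h)
    return out


def order_profile(
    traj: Trajectory, chain: str = "sn1", frames: slice | None = None
) -> OrderProfile:
    """POPC acyl-chain order profile from explicit or reconstructed C–H bonds.

    Carbons with explicit bonded hydrogens contribute their measured C–H
    vectors; interior carbons without hydrogens contribute reconstructed
    ones.  Terminal carbons without hydrogens (no two backbone neighbors)
    are skipped.
    """
    chains = _popc_chain_atoms(traj, chain)
    if not chains:
        raise ValueError(f"no tail carbons found for chain {chain!r}")
    fsel = frames if frames is not None else slice(None)
    frame_idx = np.arange(traj.n_frames)[fsel]

    by_carbon: dict[str, list[np.ndarray]] = {}
    for mol, carbons in chains.items():
        for pos, ci in enumerate(carbons):
            name = traj.topology.atoms[ci].name
            hs = _explicit_hydrogens(traj, ci)
            if hs:
                vecs = traj.xyz[np.ix_(frame_idx, hs)] - traj.xyz[frame_idx, ci][:, None, :]
                by_carbon.setdefault(name, []).append(vecs.reshape(-1, 3))
            elif 0 < pos < len(carbons) - 1:
                h1, h2 = reconstruct_ch_vectors(
                    traj.xyz[frame_idx, carbons[pos - 1]],
                    traj.xyz[frame_idx, ci],
                    traj.xyz[frame_idx, carbons[pos + 1]],
                )
                by_carbon.setdefault(name, []).append(
                    np.concatenate([h1, h2], axis=0)
                )
    if not by_carbon:
        raise ValueError("no C-H vectors could be formed for the selection")
    names = sorted(by_carbon)
    s = np.array([order_parameter(np.concatenate(by_carbon[n])) for n in names])
    n_vec = np.array([sum(len(v) for v in by_carbon[n]) for n in names])
    return OrderProfile(carbons=names, s_cd=s, n_vectors=n_vec)


def pe_order_parameter(
    traj: Trajectory, frames: slice | None = None
) -> dict[str, tuple[float, float]]:
    """Chain-average order parameter per enhancer species.

    C–H vectors are reconstructed from the enhancer chain backbone.  Returns
    ``{species: (mean over molecules, sd over molecules)}``.
    """
    top = traj.topology
    fsel = frames if frames is not None else slice(None)
    frame_idx = np.arange(traj.n_frames)[fsel]
    per_mol: dict[int, list[tuple[int, int]]] = {}
    for i in top.role_indices("pe_chain"):
        a = top.atoms[i]
        num = _chain_number(a.name)
        if num is not None:
            per_mol.setdefault(a.mol_id, []).append((num, i))
    if not per_mol:
        raise ValueError("no enhancer chain carbons in topology")
    per_species: dict[str, list[float]] = {}
    for mol, pairs in per_mol.items():
        carbons = [i for _, i in sorted(pairs)]
        if len(carbons) < 3:
            raise ValueError(
                f"PE molecule {mol} has fewer than 3 chain carbons; "
                "cannot reconstruct C-H vectors"
            )
        vecs = []
        for pos in range(1, len(carbons) - 1):
            h1, h2 = reconstruct_ch_vectors(
                traj.xyz[frame_idx, carbons[pos - 1]],
                traj.xyz[frame_idx, carbons[pos]],
                traj.xyz[frame_idx, carbons[pos + 1]],
            )
            vecs.extend([h1, h2])
        per_species.setdefault(top.pe_species(mol), []).append(
            order_parameter(np.concatenate(vecs))
        )
    return {
        sp: (float(np.mean(v)), float(np.std(v, ddof=0)))
        for sp, v in per_species.items()
    }


# -- mean squared displacement ----------------------------------------------

def msd_all_origins(positions: np.ndarray) -> np.ndarray:
    """MSD over all sliding time origins, averaged over molecules.

    *positions* has shape (n_frames, n_molecules, n_dims) and must already be
    unwrapped.  Uses the FFT autocorrelation decomposition, O(n log n).
    """
    x = np.asarray(positions, dtype=float)
    n, m, d = x.shape
    cols = x.reshape(n, m * d)
    D = cols**2
    # S2 via FFT autocorrelation
    F = np.fft.rfft(cols, 2 * n, axis=0)
    acf = np.fft.irfft(F * np.conj(F), 2 * n, axis=0)[:n].real
    denom = (n - np.arange(n))[:, None]
    S2 = acf / denom
    # S1 via the running-sum recursion, vectorized
    Q0 = 2.0 * D.sum(axis=0)
    tails = D[:-1] + D[::-1][:-1]          # D[m-1] + D[n-m] for m = 1..n-1
    cs = np.cumsum(tails, axis=0)
    S1 = np.empty_like(S2)
    S1[0] = Q0 / n
    S1[1:] = (Q0[None, :] - cs) / denom[1:]
    per_col = S1 - 2.0 * S2
    return per_col.reshape(n, m, d).sum(axis=2).mean(axis=1)


def fit_diffusion(
    lags: np.ndarray,
    msd: np.ndarray,
    fit_window: tuple[float, float] = (0.1, 0.9),
    n_dims: int = 2,
) -> tuple[float, float, tuple[int, int]]:
    """Weighted least-squares Einstein fit: D = slope / (2 d) over the window.

    The line is fit through the origin — MSD(0) = 0 identically for
    diffusive trajectories — with weights ∝ 1/τ⁴, i.e. assuming the
    standard deviation of the sliding-origin MSD estimator grows like τ²
    across the window.  Unweighted fitting lets the few, strongly
    correlated long-lag points dominate and roughly triples the estimator's
    scatter.  MSD residuals along the lag axis are strongly correlated, so
    no per-point standard error is reported here; see
    :func:`lateral_diffusion`, which estimates the uncertainty by splitting
    the molecules into independent groups.
    """
    n = len(lags)
    i0 = max(1, int(math.floor(fit_window[0] * (n - 1))))
    i1 = int(math.ceil(fit_window[1] * (n - 1)))
    if i1 - i0 < 1:
        raise ValueError("degenerate MSD fit window")
    t = lags[i0 : i1 + 1]
    y = msd[i0 : i1 + 1]
    w = 1.0 / t**4
    denom = np.sum(w * t * t)
    if denom == 0:
        raise ValueError("degenerate MSD fit window")
    slope = np.sum(w * t * y) / denom
    return slope / (2 * n_dims), 0.0, (i0, i1)


def lateral_diffusion(
    positions: np.ndarray,
    times: np.ndarray,
    config: AnalysisConfig | None = None,
) -> DiffusionEstimate:
    """Diffusion coefficient of planar trajectories (already unwrapped).

    *positions*: (n_frames, n_molecules, 2) in nm; *times* in ns with
    uniform spacing.  Requires at least 100 frames.
    """
    if config is None:
        config = AnalysisConfig()
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 100:
        raise ValueError("need at least 100 frames for a diffusion estimate")
    msd = msd_all_origins(positions)
    lags = np.asarray(times, dtype=float) - times[0]
    D, _, win = fit_diffusion(lags, msd, config.msd_fit_window, n_dims=2)
    # standard error from independent molecule groups
    n_mol = positions.shape[1]
    n_groups = min(8, n_mol)
    se = 0.0
    if n_groups >= 2:
        bounds = np.linspace(0, n_mol, n_groups + 1, dtype=int)
        sub = [
            fit_diffusion(
                lags, msd_all_origins(positions[:, a:b]), config.msd_fit_window, 2
            )[0]
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        se = float(np.std(sub, ddof=1) / math.sqrt(n_groups))
    return DiffusionEstimate(lags=lags, msd=msd, D=float(D), D_se=se, fit_window=win)


def lateral_diffusion_from_traj(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    leaflet: str = "upper",
) -> DiffusionEstimate:
    """D_L of the POPC phosphates in one leaflet (the enhancer-bearing one).

    Phosphate xy positions are unwrapped by accumulating minimum-image
    steps, the leaflet's center-of-mass drift is removed per frame, and the
    MSD fit proceeds as in :func:`lateral_diffusion`.
    """
    if config is None:
        config = AnalysisConfig()
    labels = assign_leaflets(traj, 0)
    phos = traj.topology.role_indices("phosphate")
    sel = np.array(
        [i for i in phos if labels[traj.topology.atoms[i].mol_id] == leaflet]
    )
    if sel.size == 0:
        raise ValueError(f"no phosphates in leaflet {leaflet!r}")
    xy = traj.xyz[:, sel, :2]
    steps = min_image_vectors(xy[:-1], xy[1:], traj.box[1:, None, :2])
    unwrapped = np.concatenate([xy[:1], xy[:1] + np.cumsum(steps, axis=0)])
    unwrapped = unwrapped - unwrapped.mean(axis=1, keepdims=True)  # COM drift removal
    return lateral_diffusion(unwrapped, traj.times, config)
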