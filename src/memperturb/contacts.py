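"""Water permeation counting and fractional-interaction (mixing) statistics.

Water permeation: the number of distinct water molecules whose water site
lies within ``r_water`` (0.5 nm) of the terminal acyl-tail region — the last
three carbons of both POPC chains plus their hydrogens — reported per frame
and normalized per lipid (128 lipids in the reference bilayer).

Fractional interactions: unique molecule pairs in contact (headgroup sites
closer than ``contact_cutoff``) are counted per species pair, corrected for
abundance by dividing by the number of possible pairs, and row-normalized:

    ĉ_ij = C_ij / (N_i N_j)   (i ≠ j),    ĉ_ii = C_ii / (N_i (N_i−1)/2),
    f_ij = ĉ_ij / Σ_k ĉ_ik.

This correction provably yields f = 0.5 everywhere for an ideally mixed
two-component system, the calibration point for a randomly mixed membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .geometry import leaflet_phosphate_indices
from .pbc import min_image_distances
from .trajectory import Trajectory


@dataclass
class WaterPermeationSeries:
    """Per-frame counts of waters near the acyl-tail terminal region."""

    times: np.ndarray
    counts: np.ndarray
    n_lipids: int

    @property
    def per_lipid(self) -> np.ndarray:
        return self.counts / self.n_lipids

    @property
    def mean(self) -> float:
        return float(self.per_lipid.mean())

    @property
    def sd(self) -> float:
        return float(self.per_lipid.std(ddof=0))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "n_waters": self.counts,
                "per_lipid": self.per_lipid,
            }
        )


@dataclass
class FractionMatrix:
    """Contact counts, abundance-corrected rates and row-normalized fractions."""

    species: list[str]
    counts: np.ndarray        # symmetric mean pair counts C_ij
    abundances: np.ndarray    # mean N_i
    rates: np.ndarray         # ĉ_ij
    fractions: np.ndarray     # f_ij, rows sum to 1

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.species, columns=self.species)

    def long_table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                rows.append(
                    {
                        "species_i": a,
                        "species_j": b,
                        "contacts": self.counts[i, j],
                        "rate": self.rates[i, j],
                        "fraction": self.fractions[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _distinct_water_count(
    tail_xyz: np.ndarray,
    water_xyz: np.ndarray,
    water_mols: np.ndarray,
    box: np.ndarray,
    r: float,
) -> int:
    if water_xyz.shape[0] == 0 or tail_xyz.shape[0] == 0:
        return 0
    tree = cKDTree(np.mod(water_xyz, box), boxsize=box)
    hits = tree.query_ball_point(np.mod(tail_xyz, box), r)
    idx = {w for lst in hits for w in lst}
    return len({int(water_mols[w]) for w in idx})


def water_near_tails(
    traj: Trajectory, frame: int, config: AnalysisConfig | None = None
) -> int:
    """Distinct waters within ``r_water`` of the terminal tail region (one frame)."""
    if config is None:
        config = AnalysisConfig()
    top = traj.topology
    tail = np.concatenate(
        [top.role_indices("tail_carbon_last3"), top.role_indices("tail_hydrogen_last3")]
    )
    waters = top.role_indices("water_site")
    if tail.size == 0:
        raise ValueError("no terminal tail atoms in topology")
    water_mols = np.array([top.atoms[i].mol_id for i in waters])
    return _distinct_water_count(
        traj.xyz[frame, tail], traj.xyz[frame, waters], water_mols,
        traj.box[frame], config.r_water,
    )


def water_permeation_series(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    n_lipids: int | None = None,
) -> WaterPermeationSeries:
    """Per-frame water-permeation counts with mean ± sd, normalized per lipid."""
    if config is None:
        config = AnalysisConfig()
    if n_lipids is None:
        n_lipids = len(traj.topology.molecule_ids("POPC")) or 128
    counts = np.array(
        [water_near_tails(traj, f, config) for f in range(traj.n_frames)]
    )
    return WaterPermeationSeries(times=traj.times.copy(), counts=counts, n_lipids=n_lipids)


def contact_counts(
    positions: np.ndarray,
    labels: Sequence[str],
    box: float | np.ndarray,
    cutoff: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Unique in-contact molecule pairs per species pair (one configuration).

    *positions* is (n, d) with d = 2 or 3; *box* the periodic box lengths
    (scalar for a square plane).  Returns (species, C, N) with C symmetric.
    """
    positions = np.asarray(positions, dtype=float)
    labels = np.asarray(labels)
    n, d = positions.shape
    box_arr = np.full(d, float(box)) if np.isscalar(box) else np.asarray(box, dtype=float)[:d]
    species = sorted(set(labels.tolist()))
    s_index = {s: i for i, s in enumerate(species)}
    C = np.zeros((len(species), len(species)))
    N = np.array([(labels == s).sum() for s in species], dtype=float)
    tree = cKDTree(np.mod(positions, box_arr), boxsize=box_arr)
    for a, b in tree.query_pairs(cutoff):
        i, j = s_index[labels[a]], s_index[labels[b]]
        C[i, j] += 1
        if i != j:
            C[j, i] += 1
    return species, C, N


def fraction_matrix_from_counts(
    species: list[str], C: np.ndarray, N: np.ndarray
) -> FractionMatrix:
    """Abundance-corrected, row-normalized fractions from mean counts."""
    keep = N > 0
    if not keep.all():
        dropped = [s for s, k in zip(species, keep) if not k]
        warnings.warn(f"omitting absent species {dropped}", stacklevel=2)
        species = [s for s, k in zip(species, keep) if k]
        C = C[np.ix_(keep, keep)]
        N = N[keep]
    pairs = np.outer(N, N)
    np.fill_diagonal(pairs, N * (N - 1) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(pairs > 0, C / pairs, 0.0)
        row = rates.sum(axis=1, keepdims=True)
        fractions = np.where(row > 0, rates / row, np.nan)
    return FractionMatrix(
        species=species, counts=C, abundances=N, rates=rates, fractions=fractions
    )


def mixing_fractions(
    configurations: Sequence[tuple[np.ndarray, Sequence[str]]],
    box: float | np.ndarray,
    cutoff: float,
) -> FractionMatrix:
    """Fraction matrix averaged over planar configurations.

    Raw pair counts are averaged over configurations first, then corrected
    and normalized (counts-then-normalize convention).
    """
    species_ref: list[str] | None = None
    C_sum = None
    N_sum = None
    for positions, labels in configurations:
        species, C, N = contact_counts(positions, labels, box, cutoff)
        if species_ref is None:
            species_ref, C_sum, N_sum = species, C, N
        else:
            if species != species_ref:
                raise ValueError("configurations have inconsistent species")
            C_sum = C_sum + C
            N_sum = N_sum + N
    m = len(configurations)
    return fraction_matrix_from_counts(species_ref, C_sum / m, N_sum / m)


def fractional_interactions(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    frames: Sequence[int] | None = None,
    leaflet: str = "upper",
) -> FractionMatrix:
    """POPC/enhancer mixing statistics in the enhancer-bearing leaflet.

    Contact sites are the phosphate atom for POPC and the reference
    (headgroup) atom for enhancers.  Only molecules resident in *leaflet*
    enter the matrix: the leaflet's lipids, plus enhancers whose reference
    atom is currently within ``r_expel`` of those lipids' phosphates.  Raw
    contact counts and abundances are averaged over frames before the
    correction and normalization.
    """
    if config is None:
        config = AnalysisConfig()
    top = traj.topology
    leaf_phos = leaflet_phosphate_indices(traj)[leaflet]
    pe_ids = top.molecule_ids("PE")
    pe_refs = np.array([top.pe_reference_index(pe) for pe in pe_ids], dtype=int)
    if frames is None:
        frames = range(traj.n_frames)
    species_ref: list[str] | None = None
    C_sum = None
    N_sum = None
    n_used = 0
    for f in frames:
        box = traj.box[f]
        sites = [traj.xyz[f, leaf_phos]]
        labels = ["POPC"] * leaf_phos.size
        if pe_refs.size:
            d = min_image_distances(
                traj.xyz[f, pe_refs], traj.xyz[f, leaf_phos], box
            ).min(axis=1)
            resident = d <= config.r_expel
            sites.append(traj.xyz[f, pe_refs[resident]])
            labels += [top.pe_species(pe) for pe, r in zip(pe_ids, resident) if r]
        positions = np.concatenate(sites)
        if positions.shape[0] < 2:
            continue
        species, C, N = contact_counts(positions, labels, box, config.contact_cutoff)
        if species_ref is None:
            species_ref, C_sum, N_sum = species, C, N
        elif species == species_ref:
            C_sum, N_sum = C_sum + C, N_sum + N
        else:
            # align species sets that vary frame-to-frame (PEs may all leave)
            union = sorted(set(species_ref) | set(species))
            def expand(sp, M, n):
                big_C = np.zeros((len(union), len(union)))
                big_N = np.zeros(len(union))
                idx = [union.index(s) for s in sp]
                big_C[np.ix_(idx, idx)] = M
                big_N[idx] = n
                return big_C, big_N
            C_sum, N_sum = expand(species_ref, C_sum, N_sum)
            C2, N2 = expand(species, C, N)
            C_sum, N_sum = C_sum + C2, N_sum + N2
            species_ref = union
        n_used += 1
    if n_used == 0:
        raise ValueError("fewer than two molecules in the analyzed leaflet")
    return fraction_matrix_from_counts(species_ref, C_sum / n_used, N_sum / n_used)
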