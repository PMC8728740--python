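"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without an MD engine:

* :func:`make_bilayer_trajectory` builds a two-leaflet POPC-like bilayer
  (64 lipids per leaflet by default, phosphate planes at ±1.95 nm about the
  box-z midpoint inside a 6.60 × 6.60 × 9.35 nm box) with permeation-enhancer
  molecules following scripted z-paths: stay, expulsion into water, flip-flop
  through the core, crossing of the periodic z-boundary, or expulsion with
  later re-entry.  The returned :class:`GroundTruth` is derived from an
  independent geometric re-scan of the emitted coordinates, not from the
  script's intent alone.
* :func:`make_brownian_walkers` — planar random walks with known D.
* :func:`make_orientation_ensemble` — bond-vector sets with known order.
* :func:`make_umbrella_samples` — Boltzmann samples of a known 1-D potential
  under harmonic biases.
* :func:`make_lattice_mixture` — planar two-species configurations with
  controllable mixing.

Generators are bitwise-reproducible under a fixed seed.  The scripted
dynamics are deliberately not physical (piecewise-linear paths, static
lipids): they exist to make event commit frames and analytic expectations
unambiguous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import AnalysisConfig, R_KCAL
from .free_energy import UmbrellaWindow
from .pbc import min_image_distances, min_image_scalar
from .topology import Atom, Topology
from .trajectory import Trajectory

EVENT_KINDS = ("stay", "expel", "flipflop", "pbc_cross", "expel_return")

#: Map from script kind to the event label the detector should report.
KIND_TO_EVENT = {
    "expel": "expulsion",
    "expel_return": "expulsion",
    "flipflop": "flip_flop",
    "pbc_cross": "pbc_crossing_as_expulsion",
}

# tetrahedral zig-zag geometry for synthetic chains (nm)
_CC_RISE = 0.126
_CC_LATERAL = 0.0433
_CH_BOND = 0.109


@dataclass(frozen=True)
class ScriptedEvent:
    """One scheduled episode for one enhancer molecule.

    ``pe_index`` is the ordinal of the enhancer (0-based, in insertion order);
    ``start``/``end`` bracket the transit in frames.  ``expel_return`` takes
    ``return_start``/``return_end`` in *params*.
    """

    pe_index: int
    kind: str
    start: int = 0
    end: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind != "stay" and not (0 <= self.start < self.end):
            raise ValueError("event must satisfy 0 <= start < end")


@dataclass
class EventScript:
    """Per-enhancer schedule of scripted episodes."""

    events: Sequence[ScriptedEvent]

    def __post_init__(self) -> None:
        by_pe: dict[int, list[ScriptedEvent]] = {}
        for ev in self.events:
            by_pe.setdefault(ev.pe_index, []).append(ev)
        for pe, evs in by_pe.items():
            evs = sorted((e for e in evs if e.kind != "stay"), key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping events for PE {pe}")

    def for_pe(self, pe_index: int) -> list[ScriptedEvent]:
        return sorted(
            (e for e in self.events if e.pe_index == pe_index and e.kind != "stay"),
            key=lambda e: e.start,
        )

    @classmethod
    def all_stay(cls, n_pe: int) -> "EventScript":
        return cls([ScriptedEvent(i, "stay") for i in range(n_pe)])


@dataclass(frozen=True)
class ExpectedEvent:
    pe_id: int
    kind: str
    commit_frame: int


@dataclass
class GroundTruth:
    """Expected detector output for a scripted trajectory.

    ``states`` holds the per-frame geometric state of every enhancer
    (``initial_leaflet`` / ``other_leaflet`` / ``water`` / ``interior``) from
    a brute-force re-scan of the emitted coordinates; ``remaining`` counts
    enhancers in their initial leaflet per frame (interior transit counts as
    still-in-membrane for its origin leaflet).
    """

    pe_ids: list[int]
    events: list[ExpectedEvent]
    remaining: np.ndarray
    states: np.ndarray  # (n_frames, n_pe) of state strings

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)


def _chain_positions(head: np.ndarray, n_carbons: int, direction: float) -> np.ndarray:
    """Tetrahedral zig-zag of carbons starting at *head*, advancing along z."""
    out = np.empty((n_carbons, 3))
    for i in range(n_carbons):
        out[i] = head + np.array(
            [_CC_LATERAL * (-1) ** i, 0.0, direction * _CC_RISE * i]
        )
    return out


def _scan_states(
    xyz: np.ndarray,
    box: np.ndarray,
    pe_refs: np.ndarray,
    upper_phos: np.ndarray,
    lower_phos: np.ndarray,
    leaflet0: Sequence[str],
    r_expel: float,
) -> np.ndarray:
    """Brute-force per-frame state of every enhancer (re-scan oracle).

    States are relative to each enhancer's initial leaflet; the bilayer core
    (far from both phosphate sets but between the planes) is ``interior``.
    """
    n_frames, n_pe = xyz.shape[0], len(pe_refs)
    states = np.empty((n_frames, n_pe), dtype=object)
    for f in range(n_frames):
        bx = box[f]
        zu = xyz[f, upper_phos, 2].mean()
        zl = xyz[f, lower_phos, 2].mean()
        zc = (zu + zl) / 2.0
        half = abs(zu - zl) / 2.0
        refs = xyz[f, pe_refs]
        du = min_image_distances(refs, xyz[f, upper_phos], bx).min(axis=1)
        dl = min_image_distances(refs, xyz[f, lower_phos], bx).min(axis=1)
        for p in range(n_pe):
            in_up, in_lo = du[p] <= r_expel, dl[p] <= r_expel
            if in_up and in_lo:
                leaf = "upper" if du[p] <= dl[p] else "lower"
            elif in_up:
                leaf = "upper"
            elif in_lo:
                leaf = "lower"
            else:
                dz = abs(min_image_scalar(refs[p, 2] - zc, bx[2]))
                states[f, p] = "interior" if dz < half else "water"
                continue
            states[f, p] = (
                "initial_leaflet" if leaf == leaflet0[p] else "other_leaflet"
            )
    return states


def _truth_from_states(
    states: np.ndarray, pe_ids: list[int], script: EventScript
) -> GroundTruth:
    n_frames, n_pe = states.shape
    events: list[ExpectedEvent] = []
    for p in range(n_pe):
        for ev in script.for_pe(p):
            dest = (
                "water"
                if ev.kind in ("expel", "expel_return")
                else "other_leaflet"
            )
            window = range(ev.start, n_frames)
            commit = next((f for f in window if states[f, p] == dest), None)
            if commit is None:
                raise RuntimeError(
                    f"scripted {ev.kind} for PE index {p} never reached {dest}"
                )
            events.append(ExpectedEvent(pe_ids[p], KIND_TO_EVENT[ev.kind], commit))
    # interior transit keeps the previously held membrane state
    remaining = np.zeros(n_frames, dtype=int)
    for p in range(n_pe):
        held = "initial_leaflet"
        for f in range(n_frames):
            s = states[f, p]
            if s != "interior":
                held = s
            if held == "initial_leaflet":
                remaining[f] += 1
    return GroundTruth(pe_ids=pe_ids, events=events, remaining=remaining, states=states)


def _pe_z_offset(
    kind_events: list[ScriptedEvent],
    n_frames: int,
    depth0: float,
    half: float,
    r_expel: float,
    box_z: float,
) -> np.ndarray:
    """Unwrapped z of the reference atom relative to the membrane center."""
    z = np.full(n_frames, depth0)
    z_out = half + r_expel + 0.6
    for ev in kind_events:
        t = np.arange(n_frames)
        if ev.kind in ("expel", "expel_return"):
            ramp = np.clip((t - ev.start) / (ev.end - ev.start), 0, 1)
            z = np.where(t >= ev.start, depth0 + (z_out - depth0) * ramp, z)
            if ev.kind == "expel_return":
                rs = ev.params.get("return_start")
                re_ = ev.params.get("return_end")
                if rs is None or re_ is None or not (ev.end <= rs < re_ <= n_frames):
                    raise ValueError(
                        "expel_return needs return_start/return_end after end"
                    )
                back = np.clip((t - rs) / (re_ - rs), 0, 1)
                z = np.where(t >= rs, z_out + (depth0 - z_out) * back, z)
        elif ev.kind == "flipflop":
            ramp = np.clip((t - ev.start) / (ev.end - ev.start), 0, 1)
            z = np.where(t >= ev.start, depth0 - 2 * depth0 * ramp, z)
        elif ev.kind == "pbc_cross":
            # exit through the near z-face, re-enter the opposite one
            span = box_z - 2 * depth0
            ramp = np.clip((t - ev.start) / (ev.end - ev.start), 0, 1)
            z = np.where(t >= ev.start, depth0 + span * ramp, z)
    return z


def make_bilayer_trajectory(
    n_per_leaflet: int = 64,
    n_pe: int = 22,
    script: EventScript | None = None,
    box: tuple[float, float, float] = (6.60, 6.60, 9.35),
    n_frames: int = 100,
    seed: int = 0,
    dt_ns: float = 1.0,
    leaflet_half_thickness: float = 1.95,
    phosphate_jitter: float = 0.05,
    pe_depth0: float = 1.5,
    pe_resname: str = "CAPR",
    n_pe_chain: int = 10,
    n_interior_waters: int = 0,
    water_xy_spacing: float = 0.66,
    water_z_spacing: float = 0.5,
    r_expel: float = 0.9,
) -> tuple[Trajectory, GroundTruth]:
    """Build a scripted bilayer trajectory and its ground truth.

    Phosphates of the two leaflets sit on jittered planes at ±1.95 nm about
    the box-z midpoint (the pure-POPC leaflet half-thickness); acyl tails
    point inward as ideal zig-zags with explicit terminal hydrogens; waters
    fill the slabs outside the membrane; enhancers are inserted into the
    upper leaflet and follow the scripted z-paths.  Lipids are static across
    frames — the fixture isolates event/metric logic from thermal noise.

    ``pbc_cross`` segments should be short (a few frames): a crosser that
    lingers in bulk water longer than the detector's debounce window is, by
    design, committed as an expulsion — exactly the convention used when
    counting events.
    """
    if script is None:
        script = EventScript.all_stay(n_pe)
    if n_pe > n_per_leaflet:
        raise ValueError("n_pe must not exceed n_per_leaflet")
    for ev in script.events:
        if not (0 <= ev.pe_index < n_pe):
            raise ValueError(f"script references unknown PE index {ev.pe_index}")
        if ev.kind != "stay" and ev.end > n_frames:
            raise ValueError("scripted event extends past the trajectory")
    rng = np.random.default_rng(seed)
    bx, by, bz = box
    zc = bz / 2.0
    half = leaflet_half_thickness
    g = math.ceil(math.sqrt(n_per_leaflet))
    if g * water_xy_spacing > bx * 10:  # pragma: no cover - sanity only
        raise ValueError("box too small for lattice placement")
    sx, sy = bx / g, by / g

    atoms: list[Atom] = []
    coords0: list[np.ndarray] = []  # per-atom frame-0 positions
    roles: dict[str, set[int]] = {
        "phosphate": set(),
        "tail_carbon_last3": set(),
        "tail_hydrogen_last3": set(),
        "water_site": set(),
        "pe_reference": set(),
        "pe_chain": set(),
    }
    leaflet0: dict[int, str] = {}
    mol_id = 0

    def add_atom(name: str, kind: str, resname: str, pos: np.ndarray) -> int:
        idx = len(atoms)
        atoms.append(Atom(idx, name, mol_id, kind, resname))
        coords0.append(np.asarray(pos, dtype=float))
        return idx

    sn1 = [("C314", "H14X", "H14Y"), ("C315", "H15X", "H15Y"), ("C316", "H16X", "H16Y")]
    sn2 = [("C216", "H16R", "H16S"), ("C217", "H17R", "H17S"), ("C218", "H18R", "H18S")]

    tail_depths = np.array([0.55, 0.43, 0.30])  # |z - z_center| of last-3 carbons
    upper_phos_idx: list[int] = []
    lower_phos_idx: list[int] = []
    for leaflet, sign, store in (("upper", 1.0, upper_phos_idx), ("lower", -1.0, lower_phos_idx)):
        placed = 0
        for i in range(g):
            for j in range(g):
                if placed >= n_per_leaflet:
                    break
                x, y = (i + 0.5) * sx, (j + 0.5) * sy
                zp = zc + sign * (half + rng.normal(0.0, phosphate_jitter))
                store.append(add_atom("P", "POPC", "POPC", [x, y, zp]))
                for chain, ylat in ((sn1, -0.25), (sn2, 0.25)):
                    for ci, (cname, h1, h2) in enumerate(chain):
                        cz = zc + sign * tail_depths[ci]
                        cx = x + _CC_LATERAL * (-1) ** ci
                        cpos = np.array([cx, y + ylat, cz])
                        roles["tail_carbon_last3"].add(
                            add_atom(cname, "POPC", "POPC", cpos)
                        )
                        roles["tail_hydrogen_last3"].add(
                            add_atom(h1, "POPC", "POPC", cpos + [0, _CH_BOND, 0])
                        )
                        roles["tail_hydrogen_last3"].add(
                            add_atom(h2, "POPC", "POPC", cpos + [0, -_CH_BOND, 0])
                        )
                roles["phosphate"].add(store[-1])
                leaflet0[mol_id] = leaflet
                mol_id += 1
                placed += 1

    # enhancers: reference atom C1 at depth0 in the upper leaflet, chain inward
    pe_ids: list[int] = []
    pe_ref_idx: list[int] = []
    pe_base_xy: list[tuple[float, float]] = []
    for p in range(n_pe):
        i, j = p % g, p // g
        # lattice corners, between four lipids
        x, y = i * sx + 0.001, j * sy + 0.001
        head = np.array([x, y, zc + pe_depth0])
        chain = _chain_positions(head, n_pe_chain, -1.0)
        for ci in range(n_pe_chain):
            idx = add_atom(f"C{ci + 1}", "PE", pe_resname, chain[ci])
            roles["pe_chain"].add(idx)
            if ci == 0:
                roles["pe_reference"].add(idx)
                pe_ref_idx.append(idx)
        pe_ids.append(mol_id)
        pe_base_xy.append((x, y))
        leaflet0[mol_id] = "upper"
        mol_id += 1

    # waters outside the membrane slab
    buffer = 0.35
    z_levels = []
    zlo = zc - half - buffer
    zhi = zc + half + buffer
    z = 0.2
    while z < zlo:
        z_levels.append(z)
        z += water_z_spacing
    z = zhi
    while z < bz - 0.2:
        z_levels.append(z)
        z += water_z_spacing
    nwx = int(bx // water_xy_spacing)
    nwy = int(by // water_xy_spacing)
    for zw in z_levels:
        for i in range(nwx):
            for j in range(nwy):
                roles["water_site"].add(
                    add_atom("O", "water", "HOH", [(i + 0.5) * water_xy_spacing,
                                                   (j + 0.5) * water_xy_spacing, zw])
                )
                mol_id += 1

    # optional interior waters pinned 0.25 nm below upper-leaflet terminal carbons
    if n_interior_waters > 0:
        term = [i for i in sorted(roles["tail_carbon_last3"])
                if atoms[i].name == "C218" and leaflet0[atoms[i].mol_id] == "upper"]
        if n_interior_waters > len(term):
            raise ValueError("too many interior waters requested")
        for t in term[:n_interior_waters]:
            pos = coords0[t] + np.array([0.0, 0.0, -0.25])
            roles["water_site"].add(add_atom("O", "water", "HOH", pos))
            mol_id += 1

    xyz0 = np.array(coords0)
    n_atoms = len(atoms)

    # per-frame coordinates: lipids and waters static, PEs follow their script
    xyz = np.broadcast_to(xyz0, (n_frames, n_atoms, 3)).copy()
    lateral_jitter = rng.normal(0.0, 0.01, size=(n_frames, n_pe, 2))
    for p in range(n_pe):
        evs = script.for_pe(p)
        for ev in evs:
            if ev.kind == "pbc_cross" and (ev.end - ev.start) > 8:
                warnings.warn(
                    "long pbc_cross transit may commit as a bulk-water expulsion",
                    stacklevel=2,
                )
        zoff = _pe_z_offset(evs, n_frames, pe_depth0, half, r_expel, bz)
        base = np.arange(pe_ref_idx[p], pe_ref_idx[p] + n_pe_chain)
        for f in range(n_frames):
            dz = (zc + zoff[f]) - xyz0[pe_ref_idx[p], 2]
            xyz[f, base, 2] = xyz0[base, 2] + dz
            xyz[f, base, 0] = xyz0[base, 0] + lateral_jitter[f, p, 0]
            xyz[f, base, 1] = xyz0[base, 1] + lateral_jitter[f, p, 1]
    xyz = np.mod(xyz, np.array(box))

    topology = Topology(
        atoms=atoms,
        roles={k: frozenset(v) for k, v in roles.items()},
        leaflet0=leaflet0,
    )
    traj = Trajectory(
        times=np.arange(n_frames) * dt_ns,
        xyz=xyz,
        box=np.tile(np.array(box), (n_frames, 1)),
        topology=topology,
    )

    states = _scan_states(
        xyz,
        traj.box,
        np.array(pe_ref_idx),
        np.array(upper_phos_idx),
        np.array(lower_phos_idx),
        ["upper"] * n_pe,
        r_expel,
    )
    truth = _truth_from_states(states, pe_ids, script)
    return traj, truth


def make_brownian_walkers(
    D: float, n_walkers: int, dt: float, n_steps: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Independent 2-D random walks with diffusion coefficient *D* (nm²/ns).

    Returns ``(times, positions)`` with positions of shape
    ``(n_steps + 1, n_walkers, 2)``; per-axis increments are Gaussian with
    variance ``2 D dt``.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2 * D * dt) if D > 0 else 0.0,
                       size=(n_steps, n_walkers, 2))
    pos = np.zeros((n_steps + 1, n_walkers, 2))
    np.cumsum(steps, axis=0, out=pos[1:])
    times = np.arange(n_steps + 1) * dt
    return times, pos


def make_orientation_ensemble(
    mode: str, n: int, seed: int = 0, theta0: float | None = None
) -> np.ndarray:
    """Unit bond vectors with known orientational order.

    ``aligned`` → all along +z (order parameter 1); ``perpendicular`` →
    uniform in the xy-plane (−0.5); ``isotropic`` → uniform on the sphere
    (0); ``cone`` → uniform azimuth at fixed polar angle *theta0* (radians).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if mode == "aligned":
        v = np.zeros((n, 3))
        v[:, 2] = 1.0
        return v
    if mode == "perpendicular":
        phi = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    if mode == "isotropic":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if mode == "cone":
        if theta0 is None:
            raise ValueError("cone mode needs theta0")
        phi = rng.uniform(0, 2 * np.pi, n)
        s, c = np.sin(theta0), np.cos(theta0)
        return np.column_stack([s * np.cos(phi), s * np.sin(phi), np.full(n, c)])
    raise ValueError(f"unknown mode {mode!r}")


def make_umbrella_samples(
    U: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    centers: Sequence[float],
    k: float = 239.0,
    n_samples: int = 50_000,
    T: float = 310.15,
    seed: int = 0,
    grid_points: int = 4001,
) -> list[UmbrellaWindow]:
    """Draw Boltzmann samples of potential *U* under harmonic window biases.

    *U* is either a callable (kcal/mol as a function of the reaction
    coordinate in nm) or a ``(xi, U)`` table.  Sampling is exact
    inverse-CDF sampling of exp(−[U + ½k(ξ−ξᵢ)²]/RT) on a fine grid, so the
    only deviation from the target density is the grid resolution.  The
    default spring (239 kcal/mol/nm², i.e. the conventional 1000 kJ/mol/nm²
    pulling spring) gives adjacent-window overlap at 0.1 nm spacing.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    RT = R_KCAL * T
    centers = np.asarray(centers, dtype=float)
    sigma = math.sqrt(RT / k)
    if callable(U):
        lo = centers.min() - 6 * sigma
        hi = centers.max() + 6 * sigma
        grid = np.linspace(lo, hi, grid_points)
        Ug = np.asarray(U(grid), dtype=float)
    else:
        xi_tab, U_tab = (np.asarray(a, dtype=float) for a in U)
        if np.any(centers < xi_tab.min()) or np.any(centers > xi_tab.max()):
            raise ValueError("window centers outside the potential's support")
        grid = np.linspace(xi_tab.min(), xi_tab.max(), grid_points)
        Ug = np.interp(grid, xi_tab, U_tab)
    if not np.all(np.isfinite(Ug)):
        raise ValueError("potential must be finite on the sampling grid")
    rng = np.random.default_rng(seed)
    windows = []
    for xi_c in centers:
        e = Ug + 0.5 * k * (grid - xi_c) ** 2
        p = np.exp(-(e - e.min()) / RT)
        # trapezoidal CDF: a plain cumsum shifts every sample by half a grid
        # cell, which downstream reweighting reads as a k·Δx/2 tilt
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]))])
        cdf /= cdf[-1]
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(xi_c), k=float(k), samples=samples))
    return windows


def double_well_potential(xi: np.ndarray) -> np.ndarray:
    """Reference 1-D potential (kcal/mol): two membrane wells, flat water plateau.

    Wells near 0.45 and 1.20 nm from the membrane center, a barrier between
    them, and ~0 beyond 1.6 nm so the bulk-water zone can serve as the PMF
    reference.
    """
    xi = np.asarray(xi, dtype=float)
    return (
        -2.0 * np.exp(-(((xi - 0.45) / 0.22) ** 2))
        + 1.2 * np.exp(-(((xi - 0.85) / 0.15) ** 2))
        - 3.2 * np.exp(-(((xi - 1.20) / 0.18) ** 2))
    )


def make_lattice_mixture(
    n_a: int,
    n_b: int,
    mixing: str = "ideal",
    strength: float = 1.0,
    seed: int = 0,
    density: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Planar two-species configuration with controllable mixing.

    Returns ``(positions, labels, box_side)``; *density* is molecules/nm².
    ``ideal`` places both species uniformly at random (the randomly-mixed
    calibration case); ``demixed`` confines a fraction *strength* of each
    species to opposite half-boxes, so ``strength=1`` is full segregation.
    """
    n = n_a + n_b
    if n < 2:
        raise ValueError("need at least two molecules")
    rng = np.random.default_rng(seed)
    box = math.sqrt(n / density)
    pos = rng.uniform(0, box, size=(n, 2))
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    if mixing == "ideal":
        rng.shuffle(labels)
        return pos, labels, box
    if mixing == "demixed":
        if not (0.0 < strength <= 1.0):
            raise ValueError("strength must be in (0, 1]")
        seg = rng.random(n) < strength
        half = box / 2.0
        for i in range(n):
            if seg[i]:
                x = pos[i, 0] % half
                pos[i, 0] = x if labels[i] == "A" else x + half
        return pos, labels, box
    raise ValueError(f"unknown mixing mode {mixing!r}")
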