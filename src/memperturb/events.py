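"""Permeation-enhancer event detection.

An enhancer belongs to a leaflet while its reference (headgroup) atom lies
within ``r_expel`` (0.9 nm) of any of that leaflet's phosphate atoms, under
the minimum-image convention.  A committed move from a leaflet into the bulk
water phase is an expulsion; a committed move to the opposite leaflet is a
flip-flop when the molecule transited the bilayer interior, but counts only
as an expulsion when it got there by crossing the periodic z-boundary.  New
states must persist ``debounce_frames`` consecutive frames before they
commit, which suppresses double counting of molecules oscillating at the
0.9 nm shell.

Internally the far-from-phosphates region is split into *exterior water*
(beyond the phosphate planes — this is what can commit an expulsion) and
*interior* transit through the bilayer core (never an event by itself); the
bilayer core is geometrically farther than 0.9 nm from all phosphates, so
without this split every genuine flip-flop would log a spurious expulsion.
Re-entry into the membrane after an expulsion is tracked in the occupancy
series but never erases the expulsion already counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geometry import leaflet_phosphate_indices, membrane_center, membrane_thickness
from .pbc import min_image_distances, min_image_scalar, unwrap_series
from .trajectory import Trajectory

STATE_NAMES = ("initial_leaflet", "other_leaflet", "water")
EVENT_KINDS = ("expulsion", "flip_flop", "pbc_crossing_as_expulsion")


@dataclass(frozen=True)
class EventRecord:
    """One committed leaflet-departure event of one enhancer."""

    pe_id: int
    kind: str                 # expulsion | flip_flop | pbc_crossing_as_expulsion
    departure_frame: int
    commit_frame: int
    origin_leaflet: str       # upper | lower
    destination: str          # water | other_leaflet

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.departure_frame > self.commit_frame:
            raise ValueError("departure must not follow commit")


@dataclass
class OccupancySeries:
    """Per-frame enhancer counts in {initial leaflet, other leaflet, water}."""

    times: np.ndarray
    counts: np.ndarray        # (n_frames, 3) ordered as STATE_NAMES
    n_pe: int

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(STATE_NAMES))
        df.insert(0, "time_ns", self.times)
        return df


def _instantaneous_states(
    traj: Trajectory, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int], np.ndarray]:
    """Per-frame 4-state classification for every enhancer.

    Returns (states, z_ref, z_center, pe_ids, half_thickness) where states
    is an (n_frames, n_pe) array of codes: 0 initial leaflet, 1 other
    leaflet, 2 exterior water, 3 interior.
    """
    top = traj.topology
    pe_ids = top.molecule_ids("PE")
    refs = np.array([top.pe_reference_index(pe) for pe in pe_ids])
    leaf = leaflet_phosphate_indices(traj)
    up, lo = leaf["upper"], leaf["lower"]
    init = np.array([top.leaflet0.get(pe, "upper") == "upper" for pe in pe_ids])

    n_frames, n_pe = traj.n_frames, len(pe_ids)
    states = np.empty((n_frames, n_pe), dtype=np.int8)
    z_ref = np.empty((n_frames, n_pe))
    z_center = np.empty(n_frames)
    half = np.empty(n_frames)
    for f in range(n_frames):
        box = traj.box[f]
        r = traj.xyz[f, refs]
        z_ref[f] = r[:, 2]
        du = min_image_distances(r, traj.xyz[f, up], box).min(axis=1)
        dl = min_image_distances(r, traj.xyz[f, lo], box).min(axis=1)
        zc = (traj.xyz[f, up, 2].mean() + traj.xyz[f, lo, 2].mean()) / 2.0
        z_center[f] = zc
        half[f] = abs(traj.xyz[f, up, 2].mean() - traj.xyz[f, lo, 2].mean()) / 2.0
        in_up = du <= config.r_expel
        in_lo = dl <= config.r_expel
        if config.expulsion_reference == "initial":
            # expulsion judged against the initial leaflet's phosphates only
            d_init = np.where(init, du, dl)
            in_init = d_init <= config.r_expel
            in_other = np.where(init, in_lo, in_up)
        else:
            in_init = np.where(init, in_up, in_lo)
            in_other = np.where(init, in_lo, in_up)
            both = in_init & in_other
            if both.any():
                d_init = np.where(init, du, dl)
                d_other = np.where(init, dl, du)
                nearer_init = d_init <= d_other
                in_init = in_init & (~both | nearer_init)
                in_other = in_other & (~both | ~nearer_init)
        dz = np.abs(min_image_scalar(r[:, 2] - zc, box[2]))
        interior = ~in_init & ~in_other & (dz < half[f])
        states[f] = np.select(
            [in_init, in_other, interior], [0, 1, 3], default=2
        )
    return states, z_ref, z_center, pe_ids, half


def classify_state(
    traj: Trajectory, frame: int, pe_id: int, config: AnalysisConfig | None = None
) -> str:
    """Instantaneous membership of one enhancer in one frame.

    ``initial_leaflet`` / ``other_leaflet`` when within ``r_expel`` of that
    leaflet's phosphates (ties resolve to the nearer leaflet), ``water``
    otherwise.
    """
    if config is None:
        config = AnalysisConfig()
    sub = traj.slice_frames([frame])
    states, _, _, pe_ids, _ = _instantaneous_states(sub, config)
    try:
        p = pe_ids.index(pe_id)
    except ValueError:
        raise KeyError(f"unknown PE molecule {pe_id}") from None
    code = states[0, p]
    return {0: "initial_leaflet", 1: "other_leaflet", 2: "water", 3: "water"}[code]


def detect_events(
    traj: Trajectory, config: AnalysisConfig | None = None
) -> tuple[list[EventRecord], OccupancySeries]:
    """Run the debounced state machine over every enhancer.

    Raises ``ValueError`` when the trajectory is shorter than the debounce
    window.
    """
    if config is None:
        config = AnalysisConfig()
    if traj.n_frames < config.debounce_frames:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames, fewer than "
            f"debounce_frames={config.debounce_frames}"
        )
    states, z_ref, z_center, pe_ids, half = _instantaneous_states(traj, config)
    top = traj.topology
    n_frames, n_pe = states.shape
    box_z = traj.box[:, 2]
    leaflet_names = {True: ("upper", "lower"), False: ("lower", "upper")}

    records: list[EventRecord] = []
    committed = np.zeros((n_frames, n_pe), dtype=np.int8)  # codes 0/1/2 only
    for p in range(n_pe):
        init_upper = top.leaflet0.get(pe_ids[p], "upper") == "upper"
        z_unw = unwrap_series(z_ref[:, p], box_z)
        cur = 0  # committed 3-state code; enhancers start in their leaflet
        cur4 = 0
        pend_state = -1
        pend_start = 0
        pend_len = 0
        series = np.empty(n_frames, dtype=np.int8)
        for f in range(n_frames):
            s = states[f, p]
            if s == cur4:
                pend_state = -1
            elif s == pend_state:
                pend_len += 1
            else:
                pend_state, pend_start, pend_len = s, f, 1
            if pend_state >= 0 and pend_len >= config.debounce_frames:
                new4 = pend_state
                commit_frame = pend_start
                prev_occurrences = np.nonzero(states[:commit_frame, p] == cur4)[0]
                departure = int(prev_occurrences[-1]) if prev_occurrences.size else 0
                if cur in (0, 1) and new4 in (0, 1) and new4 != cur:
                    jump = abs(z_unw[commit_frame] - z_unw[departure])
                    window = slice(departure, commit_frame + 1)
                    dz = np.abs(
                        min_image_scalar(
                            z_ref[window, p] - z_center[window], box_z[window]
                        )
                    )
                    through_core = bool(np.any(dz < half[window]))
                    origin, other = leaflet_names[init_upper]
                    origin_lab = origin if cur == 0 else other
                    kind = (
                        "flip_flop"
                        if jump <= box_z[commit_frame] / 2.0 and through_core
                        else "pbc_crossing_as_expulsion"
                    )
                    records.append(
                        EventRecord(
                            pe_id=pe_ids[p],
                            kind=kind,
                            departure_frame=departure,
                            commit_frame=commit_frame,
                            origin_leaflet=origin_lab,
                            destination="other_leaflet",
                        )
                    )
                elif cur in (0, 1) and new4 == 2:
                    origin, other = leaflet_names[init_upper]
                    records.append(
                        EventRecord(
                            pe_id=pe_ids[p],
                            kind="expulsion",
                            departure_frame=departure,
                            commit_frame=commit_frame,
                            origin_leaflet=origin if cur == 0 else other,
                            destination="water",
                        )
                    )
                # water -> leaflet is a silent re-entry; interior commits no event
                cur4 = new4
                if new4 != 3:
                    series[pend_start:f + 1] = new4
                    cur = new4
                pend_state = -1
            series[f] = cur
        committed[:, p] = series

    counts = np.zeros((n_frames, 3), dtype=int)
    for code in (0, 1, 2):
        counts[:, code] = (committed == code).sum(axis=1)
    occupancy = OccupancySeries(times=traj.times.copy(), counts=counts, n_pe=n_pe)
    return records, occupancy


def remaining_series(occupancy: OccupancySeries) -> np.ndarray:
    """Per-frame count of enhancers still in their initial leaflet."""
    return occupancy.counts[:, 0].copy()


def events_table(records: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pe_id": r.pe_id,
                "kind": r.kind,
                "departure_frame": r.departure_frame,
                "commit_frame": r.commit_frame,
                "origin_leaflet": r.origin_leaflet,
                "destination": r.destination,
            }
            for r in records
        ],
        columns=[
            "pe_id",
            "kind",
            "departure_frame",
            "commit_frame",
            "origin_leaflet",
            "destination",
        ],
    )


def event_summary(records: list[EventRecord]) -> dict[str, int]:
    return {
        "expulsions": sum(r.kind == "expulsion" for r in records),
        "flipflops": sum(r.kind == "flip_flop" for r in records),
        "pbc_crossings": sum(r.kind == "pbc_crossing_as_expulsion" for r in records),
    }
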