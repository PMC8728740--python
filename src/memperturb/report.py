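"""Pipeline orchestration and the consolidated run report.

``run_pipeline`` executes the analysis stages in dependency order on one
trajectory, writes per-stage CSV tables plus a single ``report.json``, and
returns the report dictionary.  A stage failure is recorded in the report
under that stage's ``error`` key and aborts only the stages that depend on
it; the caller decides the exit status from :func:`report_failed`.

The report layout is published as ``schema/report.schema.json`` inside the
package; :func:`validate_report` performs a structural check (required keys
and primitive types) against that layout.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .contacts import fractional_interactions, water_permeation_series
from .events import detect_events, event_summary, events_table, remaining_series
from .free_energy import compute_partition, load_windows, wham_solve
from .geometry import membrane_metrics_series
from .ordering import lateral_diffusion_from_traj, order_profile, pe_order_parameter
from .trajectory import Trajectory, read_trajectory

logger = logging.getLogger("memperturb")

ALL_STAGES = (
    "events",
    "structure",
    "order",
    "diffusion",
    "water",
    "contacts",
    "free_energy",
)


def load_schema() -> dict:
    """The published report schema shipped with the package."""
    ref = importlib.resources.files("memperturb") / "schema" / "report.schema.json"
    return json.loads(ref.read_text())


def validate_report(report: dict) -> None:
    """Structural validation of a run report against the published schema.

    Checks required keys and primitive types; raises ``ValueError`` on the
    first violation.
    """
    schema = load_schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["package"] != "memperturb":
        raise ValueError("report package field must be 'memperturb'")
    if not isinstance(report["version"], str):
        raise ValueError("version must be a string")
    if not isinstance(report["seed"], int):
        raise ValueError("seed must be an integer")
    if not isinstance(report["config"], dict):
        raise ValueError("config must be an object")
    if not isinstance(report["stages"], dict):
        raise ValueError("stages must be an object")
    for name, section in report["stages"].items():
        if not isinstance(section, dict):
            raise ValueError(f"stage section {name!r} must be an object")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(
    trajectory: str | Path | Trajectory,
    config: AnalysisConfig | None = None,
    stages: Sequence[str] | None = None,
    output_dir: str | Path = ".",
    windows_meta: str | Path | None = None,
    stride: int = 1,
    n_leaflet_lipids: int = 64,
) -> dict:
    """Run selected stages and write CSV tables plus ``report.json``.

    ``free_energy`` runs only when *windows_meta* points at an umbrella
    window table; it is independent of the trajectory stages.
    """
    if config is None:
        config = AnalysisConfig()
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "package": "memperturb",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    traj: Trajectory | None = None
    needs_traj = [s for s in stages if s != "free_energy"]
    if needs_traj:
        if isinstance(trajectory, Trajectory):
            traj = trajectory
        else:
            traj = read_trajectory(trajectory)
        if stride > 1:
            traj = traj.slice_frames(slice(None, None, stride))

    def run_stage(name, fn):
        try:
            report["stages"][name] = _jsonable(fn())
            logger.info("stage %s done", name)
        except Exception as exc:  # stage isolation is the point here
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"error": str(exc)}

    if "events" in stages:
        def _events():
            records, occupancy = detect_events(traj, config)
            events_table(records).to_csv(out / "events.csv", index=False)
            occupancy.table().to_csv(out / "occupancy.csv", index=False)
            summary = event_summary(records)
            summary["n_pe"] = occupancy.n_pe
            summary["final_remaining"] = int(remaining_series(occupancy)[-1])
            return summary
        run_stage("events", _events)

    if "structure" in stages:
        def _structure():
            series = membrane_metrics_series(traj, n_leaflet_lipids=n_leaflet_lipids)
            series.frame_table().to_csv(out / "structure.csv", index=False)
            series.depth_table().to_csv(out / "pe_depth.csv", index=False)
            return {
                "apl_nm2_mean": series.apl.mean(),
                "apl_nm2_sd": series.apl.std(ddof=0),
                "thickness_pp_nm_mean": series.thickness_pp.mean(),
                "thickness_pp_nm_sd": series.thickness_pp.std(ddof=0),
                "leaflet_thickness_nm_mean": series.leaflet_thickness.mean(),
            }
        run_stage("structure", _structure)

    if "order" in stages:
        def _order():
            prof = order_profile(traj, "sn1")
            prof.table().to_csv(out / "order_sn1.csv", index=False)
            section = {
                "popc_sn1_chain_average": prof.chain_average,
                "popc_sn1_per_carbon": dict(zip(prof.carbons, prof.s_cd)),
            }
            if traj.topology.molecule_ids("PE"):
                section["pe_species"] = {
                    sp: {"mean": m, "sd": s}
                    for sp, (m, s) in pe_order_parameter(traj).items()
                }
            return section
        run_stage("order", _order)

    if "diffusion" in stages:
        def _diffusion():
            est = lateral_diffusion_from_traj(traj, config)
            est.table().to_csv(out / "msd.csv", index=False)
            return {"D_nm2_ns": est.D, "D_se": est.D_se,
                    "fit_window": list(est.fit_window)}
        run_stage("diffusion", _diffusion)

    if "water" in stages:
        def _water():
            series = water_permeation_series(traj, config)
            series.table().to_csv(out / "water.csv", index=False)
            return {"per_lipid_mean": series.mean, "per_lipid_sd": series.sd,
                    "n_lipids": series.n_lipids}
        run_stage("water", _water)

    if "contacts" in stages:
        def _contacts():
            fm = fractional_interactions(traj, config)
            fm.table().to_csv(out / "contacts.csv")
            fm.long_table().to_csv(out / "contacts_long.csv", index=False)
            return {
                "species": fm.species,
                "fractions": fm.fractions,
            }
        run_stage("contacts", _contacts)

    if "free_energy" in stages and windows_meta is not None:
        def _free_energy():
            windows = load_windows(windows_meta)
            pmf = wham_solve(windows, config)
            pmf.table().to_csv(out / "pmf.csv", index=False)
            part = compute_partition(pmf, T=config.T)
            return {
                "delta_g_kcal_mol": part.delta_g,
                "min_location_nm": part.min_location,
                "co_over_ci": part.co_over_ci,
                "convention": part.convention,
                "T_K": part.T,
                "wham_converged": pmf.converged,
                "wham_iterations": pmf.n_iter,
            }
        run_stage("free_energy", _free_energy)

    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def report_failed(report: dict) -> bool:
    """True when any executed stage recorded an error."""
    return any("error" in s for s in report["stages"].values())
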