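"""Analysis configuration.

All lengths are in nm, times in ns, energies in kcal/mol and temperatures
in K throughout the package.  The gas constant ``R_KCAL`` is fixed in
kcal·mol⁻¹·K⁻¹ to match that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

#: Ideal gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Body temperature in K, the temperature of all analyses by default.
BODY_TEMPERATURE = 310.15


class ConfigurationError(ValueError):
    """Raised for invalid analysis configuration or role resolution."""


@dataclass
class AnalysisConfig:
    """Tunable parameters shared by the analysis stages.

    Parameters
    ----------
    r_expel
        Distance cutoff (nm) from a leaflet's phosphate atoms beyond which a
        permeation enhancer no longer counts as a member of that leaflet.
    r_water
        Cutoff (nm) for counting water molecules near the terminal acyl-tail
        region.
    contact_cutoff
        Headgroup-site distance (nm) below which two molecules are in contact.
    T
        Temperature in K.
    debounce_frames
        Number of consecutive frames a new membership state must persist
        before an event is committed.
    msd_fit_window
        Fractions of the maximum lag time delimiting the MSD fit interval.
    pmf_bin_width
        Reaction-coordinate histogram bin width (nm) for WHAM.
    pmf_min_count
        Minimum total samples a bin needs to be treated as populated.  The
        Poisson noise floor of a bin's free energy is ~RT/√n; the default
        (100) masks bins whose floor exceeds a tenth of RT.
    wham_tol
        Convergence threshold (kcal/mol) on the window free-energy update.
    wham_max_iter
        Iteration cap for the WHAM self-consistency loop.
    water_reference_zone
        Interval of distance-from-membrane-center (nm) whose mean free energy
        defines the zero of the PMF (bulk water).
    expulsion_reference
        ``"both"`` tests the distance criterion against the phosphates of both
        leaflets; ``"initial"`` against the initially occupied leaflet only.
    """

    r_expel: float = 0.9
    r_water: float = 0.5
    contact_cutoff: float = 0.9
    T: float = BODY_TEMPERATURE
    debounce_frames: int = 5
    msd_fit_window: tuple[float, float] = (0.1, 0.9)
    pmf_bin_width: float = 0.05
    pmf_min_count: int = 100
    wham_tol: float = 1e-6
    wham_max_iter: int = 100_000
    water_reference_zone: tuple[float, float] = (2.3, float("inf"))
    expulsion_reference: str = "both"
    seed: int = 0

    #: Gas constant; fixed, not a free parameter.
    R: float = field(default=R_KCAL, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.msd_fit_window
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                f"msd_fit_window must satisfy 0 < lo < hi < 1, got {self.msd_fit_window}"
            )
        for name in ("r_expel", "r_water", "contact_cutoff", "pmf_bin_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.wham_tol <= 0:
            raise ConfigurationError("wham_tol must be positive")
        if self.T <= 0:
            raise ConfigurationError("T must be positive")
        if self.debounce_frames < 1:
            raise ConfigurationError("debounce_frames must be >= 1")
        if self.expulsion_reference not in ("both", "initial"):
            raise ConfigurationError(
                "expulsion_reference must be 'both' or 'initial'"
            )

    @property
    def RT(self) -> float:
        """Thermal energy R·T in kcal/mol."""
        return self.R * self.T

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a YAML file mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("msd_fit_window", "water_reference_zone"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def load_config(path: Optional[str | Path]) -> AnalysisConfig:
    """Return the configuration at *path*, or the defaults when *path* is None."""
    if path is None:
        return AnalysisConfig()
    return AnalysisConfig.from_yaml(path)
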