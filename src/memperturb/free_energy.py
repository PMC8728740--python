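"""Umbrella-sampling free energies: WHAM, ΔG, and the partition ratio.

The weighted histogram analysis method combines biased window histograms
into one unbiased probability profile by self-consistent iteration of

    P(b) = Σ_i n_i(b) / Σ_j N_j exp[(F_j − w_j(b)) / RT]
    exp(−F_j / RT) = Σ_b P(b) exp(−w_j(b) / RT)

with harmonic biases w_j(b) = ½ k_j (ξ_b − ξ_j)².  The potential of mean
force is G(b) = −RT ln P(b), shifted so its mean over the bulk-water
reference zone is zero.

``partition_ratio`` converts a membrane/water free-energy difference into
the outside/inside concentration ratio.  Two conventions are provided:

* ``"paper"`` — Co/Ci = exp(ΔG / (ln 10 · R · T)).  This log₁₀-style form
  is what reproduces the published caprylate/caprate/SNAC ratio table from
  its printed ΔG values.
* ``"boltzmann"`` — Co/Ci = exp(ΔG / (R · T)), the textbook two-phase
  partition form.

Both are implemented because the published table is internally consistent
only under the first; whether that reflects a deliberate log₁₀ convention
cannot be settled from the numbers alone, so neither intent is asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import log_ndtr, logsumexp

from .config import AnalysisConfig, R_KCAL


class ConvergenceError(RuntimeError):
    """Raised when WHAM cannot run (e.g. disconnected windows)."""


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate from one umbrella window."""

    center: float            # nm
    k: float                 # kcal/mol/nm^2; 0 means unbiased
    samples: np.ndarray      # nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("umbrella window must contain samples")
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class PMFProfile:
    """Binned free-energy curve with the water phase as reference."""

    bin_centers: np.ndarray   # nm (distance from the membrane center)
    G: np.ndarray             # kcal/mol; NaN on unpopulated bins
    F: np.ndarray             # per-window free energies, kcal/mol
    converged: bool
    n_iter: int
    bin_width: float

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.G)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"xi_nm": self.bin_centers, "G_kcal_mol": self.G})


@dataclass
class PartitionResult:
    """ΔG between the membrane minimum and water, and the implied Co/Ci."""

    delta_g: float            # kcal/mol, G(minimum) − G(water reference)
    min_location: float       # nm from the membrane center
    T: float
    co_over_ci: float
    convention: str


def _log_phi_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Φ(b) − Φ(a)) for a < b, stable in both tails."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # reflect so the interval sits in the lower tail, where log_ndtr is stable
    flip = (a + b) > 0
    aa = np.where(flip, -b, a)
    bb = np.where(flip, -a, b)
    hi = log_ndtr(bb)
    lo = log_ndtr(aa)
    with np.errstate(divide="ignore", invalid="ignore"):
        return hi + np.log1p(-np.exp(np.minimum(lo - hi, 0.0)))


def _log_bin_bias_weight(
    k: float, center: float, edges: np.ndarray, RT: float
) -> np.ndarray:
    """log of the bin-averaged Boltzmann factor of a harmonic bias.

    log ⟨exp(−½k(ξ−c)²/RT)⟩ over each bin, evaluated analytically.  Using
    the bin average instead of the bin-center value removes the dominant
    histogram discretization error of WHAM: the within-bin variation of the
    bias grows like k·|ξ_b − c|·Δξ and reaches kcal/mol size in bins far
    from the window center.
    """
    n_bins = edges.size - 1
    if k == 0:
        return np.zeros(n_bins)
    s = math.sqrt(RT / k)
    a = (edges[:-1] - center) / s
    b = (edges[1:] - center) / s
    width = np.diff(edges)
    return math.log(math.sqrt(2 * math.pi) * s) + _log_phi_diff(a, b) - np.log(width)


def _window_graph_connected(counts: np.ndarray) -> bool:
    """True when windows overlap into one connected component via shared bins."""
    n_win = counts.shape[0]
    adj = (counts > 0) @ (counts > 0).T  # windows sharing >=1 populated bin
    seen = np.zeros(n_win, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.nonzero(adj[i] & ~seen)[0].tolist())
    return bool(seen.all())


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    config: AnalysisConfig | None = None,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution on a uniform half-open bin grid.

    The self-consistency iteration runs on an internal grid ten times finer
    than the output bins and the resulting probability is aggregated back;
    histogram-discretization errors of WHAM scale with the squared bin
    width, so the refinement makes them negligible at the output
    resolution while leaving the unbiased (k = 0) single-window limit
    exactly equal to direct Boltzmann inversion of the output histogram.

    Deterministic given its inputs: F is initialized to zero and the bin
    grid is anchored to integer multiples of the bin width, so the result is
    invariant (to numerical tolerance) under window reordering and under
    histogram-preserving subsampling.
    """
    if config is None:
        config = AnalysisConfig()
    if len(windows) == 0:
        raise ValueError("no umbrella windows supplied")
    RT = config.RT
    width = config.pmf_bin_width
    refine = 10
    fine = width / refine
    if bin_range is not None:
        # an explicit range puts replicates on one shared grid; samples
        # falling outside it are discarded
        all_min, all_max = bin_range
    else:
        all_min = min(w.samples.min() for w in windows)
        all_max = max(w.samples.max() for w in windows)
    lo = math.floor(all_min / width) * width
    hi = math.ceil(all_max / width) * width
    n_bins = round((hi - lo) / width)
    edges = lo + width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fine_edges = lo + fine * np.arange(n_bins * refine + 1)

    counts = np.zeros((len(windows), n_bins * refine))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=fine_edges)
    N = counts.sum(axis=1)
    total_fine = counts.sum(axis=0)
    total = total_fine.reshape(n_bins, refine).sum(axis=1)
    pop = total >= config.pmf_min_count
    if not pop.any():
        raise ConvergenceError("no bin reaches the minimum occupancy")
    if len(windows) > 1 and not _window_graph_connected(counts):
        raise ConvergenceError(
            "umbrella windows do not overlap into a connected set of bins"
        )

    # bin-averaged Boltzmann factors of the biases, log ⟨e^{−w_j/RT}⟩_b
    log_wt = np.vstack(
        [_log_bin_bias_weight(w.k, w.center, fine_edges, RT) for w in windows]
    )

    logN = np.log(N)
    with np.errstate(divide="ignore"):
        log_counts_fine = np.log(total_fine)
    F = np.zeros(len(windows))
    converged = False
    it = 0
    for it in range(1, config.wham_max_iter + 1):
        log_den = logsumexp(logN[:, None] + F[:, None] / RT + log_wt, axis=0)
        logP = log_counts_fine - log_den  # -inf on empty fine bins
        F_new = -RT * logsumexp(logP[None, :] + log_wt, axis=1)
        F_new -= F_new[0]
        delta = np.max(np.abs(F_new - F))
        F = F_new
        if delta < config.wham_tol:
            converged = True
            break

    log_den = logsumexp(logN[:, None] + F[:, None] / RT + log_wt, axis=0)
    logP_fine = log_counts_fine - log_den
    logP = logsumexp(logP_fine.reshape(n_bins, refine), axis=1)
    G = np.where(pop, -RT * logP, np.nan)

    zone_lo, zone_hi = config.water_reference_zone
    ref = pop & (np.abs(centers) >= zone_lo) & (np.abs(centers) <= zone_hi)
    if ref.any():
        G = G - np.nanmean(G[ref])
    else:
        # no sampled water zone: anchor the minimum at zero instead
        G = G - np.nanmin(G)
    return PMFProfile(
        bin_centers=centers,
        G=G,
        F=F,
        converged=converged,
        n_iter=it,
        bin_width=width,
    )


def boltzmann_inversion(
    window: UmbrellaWindow, config: AnalysisConfig | None = None
) -> PMFProfile:
    """Direct −RT·ln(histogram) of one unbiased window, on the WHAM grid.

    The unbiased (k = 0) single-window limit of :func:`wham_solve` equals
    this profile; the pair is kept separate so they can cross-check each
    other.
    """
    if config is None:
        config = AnalysisConfig()
    RT = config.RT
    width = config.pmf_bin_width
    lo = math.floor(window.samples.min() / width) * width
    hi = math.ceil(window.samples.max() / width) * width
    edges = lo + width * np.arange(round((hi - lo) / width) + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist, _ = np.histogram(window.samples, bins=edges)
    with np.errstate(divide="ignore"):
        G = np.where(
            hist >= config.pmf_min_count, -RT * np.log(hist.astype(float)), np.nan
        )
    zone_lo, zone_hi = config.water_reference_zone
    ref = np.isfinite(G) & (np.abs(centers) >= zone_lo) & (np.abs(centers) <= zone_hi)
    G = G - (np.nanmean(G[ref]) if ref.any() else np.nanmin(G))
    return PMFProfile(centers, G, np.zeros(1), True, 0, width)


def extract_delta_g(
    pmf: PMFProfile, membrane_zone: tuple[float, float] = (0.0, 1.95)
) -> tuple[float, float]:
    """Free-energy minimum inside the membrane zone, relative to water.

    Returns ``(delta_g, min_location)`` with the location as distance from
    the membrane center (nm).  The water reference is already the PMF zero.
    """
    lo, hi = membrane_zone
    mask = pmf.populated & (np.abs(pmf.bin_centers) >= lo) & (np.abs(pmf.bin_centers) <= hi)
    if not mask.any():
        raise ValueError("membrane zone contains no populated bins")
    sub = np.where(mask, pmf.G, np.inf)
    i = int(np.argmin(sub))
    return float(pmf.G[i]), float(abs(pmf.bin_centers[i]))


def partition_ratio(
    delta_g: float,
    T: float = 310.15,
    convention: str = "paper",
    R: float = R_KCAL,
) -> float:
    """Outside/inside concentration ratio implied by ΔG (kcal/mol).

    See the module docstring for the two conventions; ``"paper"`` (the
    default) divides ΔG by ln 10 · R · T and reproduces the published
    ratio table, ``"boltzmann"`` is the textbook exp(ΔG/RT).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if convention == "paper":
        return math.exp(delta_g / (math.log(10.0) * R * T))
    if convention == "boltzmann":
        return math.exp(delta_g / (R * T))
    raise ValueError(f"unknown convention {convention!r}")


def compute_partition(
    pmf: PMFProfile,
    membrane_zone: tuple[float, float] = (0.0, 1.95),
    T: float = 310.15,
    convention: str = "paper",
) -> PartitionResult:
    """ΔG, minimum location and Co/Ci from a water-referenced PMF."""
    dg, loc = extract_delta_g(pmf, membrane_zone)
    return PartitionResult(
        delta_g=dg,
        min_location=loc,
        T=T,
        co_over_ci=partition_ratio(dg, T, convention),
        convention=convention,
    )


def aggregate_replicates(
    pmfs: Sequence[PMFProfile],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and sample standard deviation over replicate PMFs.

    All replicates must share the bin grid.  Returns
    ``(bin_centers, mean, sd)``; sd uses ddof=1 (sample definition) and is 0
    for a single replicate's populated bins only when replicates coincide.
    """
    if len(pmfs) < 2:
        raise ValueError("need at least two replicates")
    ref = pmfs[0].bin_centers
    for p in pmfs[1:]:
        if p.bin_centers.shape != ref.shape or not np.allclose(p.bin_centers, ref):
            raise ValueError("replicate PMFs are on mismatched bin grids")
    G = np.vstack([p.G for p in pmfs])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(G, axis=0)
    sd = np.full(ref.shape, np.nan)
    ok = np.isfinite(G).all(axis=0)
    if ok.any():
        sd[ok] = np.std(G[:, ok], axis=0, ddof=1)
    mean[~np.isfinite(G).any(axis=0)] = np.nan
    return ref, mean, sd


# -- plain-text window input -------------------------------------------------

def read_umbrella_samples(path: str | Path, column: int = 1) -> np.ndarray:
    """Read the reaction-coordinate column of a two-column time/ξ text file."""
    data = np.loadtxt(path, comments=("#", "@"))
    if data.ndim == 1:
        data = data[None, :]
    return data[:, column]


def load_windows(metadata_path: str | Path) -> list[UmbrellaWindow]:
    """Load umbrella windows from a CSV or YAML metadata table.

    The table needs columns/keys ``center`` (nm), ``k`` (kcal/mol/nm²) and
    ``file`` (sample file path, relative to the metadata file).
    """
    metadata_path = Path(metadata_path)
    if metadata_path.suffix.lower() in (".yaml", ".yml"):
        with open(metadata_path) as fh:
            rows = yaml.safe_load(fh)
    else:
        rows = pd.read_csv(metadata_path).to_dict("records")
    windows = []
    for row in rows:
        sample_path = metadata_path.parent / str(row["file"])
        windows.append(
            UmbrellaWindow(
                center=float(row["center"]),
                k=float(row["k"]),
                samples=read_umbrella_samples(sample_path),
            )
        )
    return windows
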