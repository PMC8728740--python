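# Methods

Units throughout: lengths in nm, times in ns, energies in kcal/mol,
temperatures in K, with the gas constant fixed at
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 310.15 K (body
temperature). Bilayers are planar and z-normal; boxes are orthorhombic.
Coordinates are stored exactly as read (wrapped if the file is wrapped);
consumers unwrap on demand and never mutate the stored trajectory.

## Trajectory model and roles

A trajectory is a sequence of frames (time, positions, box lengths) over a
role-annotated topology. Roles — phosphate headgroup atoms, the last three
carbons of each acyl chain and their hydrogens, water sites, and each
enhancer's reference (headgroup) atom and chain carbons — are resolved from
configurable atom-name patterns (CHARMM-style defaults), with tail
hydrogens bound to their carbon by first-frame proximity rather than by
enumerating every hydrogen name. Multi-frame GRO and PDB files are parsed
and written through mdtraj; binary formats are supported through the
`from_mdtraj` adapter rather than re-parsed here. GRO stores three
decimals in nm, so write/read round trips are exact to 0.001 nm.

The enhancer reference atom anchors all distance criteria. It defaults to
the C1/N1/O1 headgroup heavy atom (the carboxylate carbon for fatty acids);
no published criterion names the anchor, so it is exposed in `RoleSpec`.

## Event detection

Instantaneous membership: an enhancer belongs to a leaflet when its
reference atom lies within `r_expel` = 0.9 nm (minimum image) of any of
that leaflet's phosphates; ties inside both cutoffs resolve to the nearer
leaflet. The far-from-phosphates region is split internally into
**exterior water** (|z − z_center| beyond the phosphate half-plane) and
**interior** transit through the bilayer core. This split is load-bearing:
the core of a 3.9 nm bilayer is itself farther than 0.9 nm from every
phosphate, so a literal two-region reading of the distance rule would log a
spurious expulsion for every flip-flop. Expulsion means *into the water
phase*, so only exterior water can commit one; interior transit commits no
event. The public `classify_state` keeps the simple three-state view
(leaflet / leaflet / water).

The per-enhancer state machine commits a new state only after it persists
`debounce_frames` (default 5) consecutive frames, suppressing double counts
from molecules oscillating at the 0.9 nm shell. Committed transitions map
to events as follows:

* leaflet → exterior water: **expulsion**;
* leaflet → other leaflet with unwrapped z-jump > box_z/2 between departure
  and commit: **pbc_crossing_as_expulsion** (the molecule left through a
  z-face and re-entered the opposite one — geometrically the only way to
  reach the other leaflet from outside without passing the core);
* leaflet → other leaflet otherwise, provided the path passed through the
  core (|z − z_center| < leaflet half-thickness at some frame):
  **flip_flop**; a transition that satisfies neither test is conservatively
  recorded as a boundary crossing.

z-paths are unwrapped by accumulating minimum-image per-frame steps.
Re-entry after expulsion updates the occupancy series but never erases the
expulsion already counted (event counts are cumulative). A boundary
crosser that lingers in bulk water longer than the debounce window commits
as an expulsion — consistent with counting crossings as expulsions — so
scripted crossings in the synthetic module should transit in a few frames.

## Structure metrics

* APL = box_x·box_y / n_leaflet_lipids with n = 64 by default; inserted
  enhancers never enter the denominator.
* Membrane center = midpoint of the two leaflets' mean phosphate z.
* Thickness: `global` is the difference of leaflet mean phosphate z;
  `local(k)` averages, over every phosphate, its |Δz| to the mean z of its
  k = 6 nearest opposite-leaflet phosphates (xy minimum image) — a
  neighborhood variant in the spirit of published local-thickness
  algorithms without their full normal-field machinery. Leaflet thickness
  is half the P–P value. Both modes are provided because published
  leaflet-thickness numbers rarely state which was used.
* Enhancer depth d = |z_COM(heavy atoms) − z_center|, minimum-imaged in z,
  with element masses guessed from atom names.

Leaflet assignment (sign of phosphate z about the median) is taken from
frame 0; `verify_no_lipid_flipflop` checks the assumption that lipids never
change leaflet, which holds for POPC on these timescales.

## Order parameters

S_CD(n) = ⟨(3 cos²θ − 1)/2⟩ over molecules and frames, θ between the C–H
bond of carbon n and +z. The normal is fixed to +z; no instantaneous
normal is estimated. Explicit hydrogens are used where present (bound by
proximity); otherwise the two C–H directions of carbon n are reconstructed
from C(n−1), C(n), C(n+1) by the orthogonal-bisector construction at the
tetrahedral half-angle, which enables united-atom and synthetic chains.
The sn-1 chain is the default selection; enhancer chains are reported as a
per-species average with the standard deviation over molecules.

## Lateral diffusion

MSD(τ) is averaged over molecules and all sliding time origins (FFT
autocorrelation decomposition, O(n log n)). For trajectory input, the
phosphate xy positions of the enhancer-bearing leaflet are unwrapped and
the leaflet's per-frame center-of-mass displacement removed, so collective
leaflet drift cannot masquerade as diffusion. D_L is the slope/4 of a
line through the origin fit over lags in `msd_fit_window` (default
[0.1, 0.9] of the maximum lag) by weighted least squares with weights
∝ 1/τ⁴, i.e. treating the sliding-origin MSD's standard deviation as
growing like τ² across the window. The zero intercept is exact for
diffusive motion (MSD(0) = 0); the weighting matters because the few,
strongly correlated long-lag points otherwise dominate the fit and roughly
triple its scatter. MSD residuals are correlated along τ, so the reported
standard error comes from refitting independent molecule subgroups (up to
8) rather than from per-point residuals.

## Contacts and mixing

Water permeation counts distinct water molecules whose water site lies
within `r_water` = 0.5 nm (inclusive, minimum image, periodic KD-tree) of
any terminal-tail atom; the series is normalized per lipid (128 in the
reference bilayer) and summarized as mean ± sd over frames.

Fractional interactions: unique in-contact molecule pairs (headgroup sites
— phosphate for POPC, the reference atom for enhancers — closer than
`contact_cutoff` = 0.9 nm) are counted per species pair, corrected for
abundance by the number of possible pairs, ĉ_ij = C_ij/(N_i N_j) for
i ≠ j and C_ii/(N_i(N_i−1)/2), then row-normalized. The correction is
stated explicitly because it provably calibrates ideal two-component
mixing to f = 0.5 in every cell. Only molecules resident in the
enhancer-bearing leaflet enter the matrix (lipids of that leaflet, plus
enhancers currently within `r_expel` of its phosphates). Raw counts and
abundances are averaged over frames *before* correction and normalization;
the alternative order (normalize per frame, then average) differs only
when occupancies fluctuate, and the chosen order is the package's
convention, not a claim about any published pipeline.

## Umbrella sampling and WHAM

Windows carry a center ξᵢ, spring constant k and samples of ξ. The WHAM
equations

    P(b) = Σ_i n_i(b) / Σ_j N_j exp[(F_j − w_j(b))/RT],
    exp(−F_j/RT) = Σ_b P(b) exp(−w_j(b)/RT)

are iterated from F = 0 until max|ΔF_j| < `wham_tol` (10⁻⁶ kcal/mol,
capped at 10⁵ iterations; exceeding the cap returns a result flagged
unconverged). Windows that do not overlap into one connected component of
shared populated bins raise an error. Two numerical choices matter:

* **Bias handling.** exp(−w_j/RT) is integrated analytically over each
  bin (Gaussian CDF differences in log space) instead of evaluated at bin
  centers; the within-bin bias variation grows like k·|ξ_b − ξ_j|·Δξ and
  reaches kcal/mol magnitude in bins far from a window's center.
* **Internal refinement.** The iteration runs on a grid 10× finer than
  the output bins (default output width 0.05 nm) and aggregates the
  probability afterwards. Remaining discretization errors scale with the
  squared fine width and are negligible; the k = 0 single-window limit
  stays exactly equal to direct Boltzmann inversion of the output
  histogram (kept as a separate routine so the two can cross-check).

Bins with fewer than `pmf_min_count` = 100 total samples are masked: a
bin's Poisson noise floor is ≈ RT/√n, and the default masks bins whose
floor exceeds a tenth of RT. G = −RT ln P is shifted so its mean over the
`water_reference_zone` (distance from the membrane center ≥ 2.3 nm by
default, beyond the 1.95 nm leaflet plus headgroups) is zero; without a
sampled reference zone the minimum is anchored at zero instead. An
explicit `bin_range` puts replicate PMFs on one shared grid for pointwise
mean/sd aggregation (sample sd, ddof = 1).

ΔG is the minimum of G over the membrane zone (default within 1.95 nm of
the center), reported with its location; the sign convention is
G(membrane minimum) − G(water), so a repulsive interior gives ΔG > 0.
Statistical-inefficiency/autocorrelation corrections are out of scope (the
synthetic sampler draws independent samples); the seam is the
`UmbrellaWindow.samples` array, which callers may subsample.

### Partition-ratio convention

Two conversions from ΔG to the outside/inside concentration ratio are
implemented. The `paper` convention, C_o/C_i = exp(ΔG/(ln 10·R·T)), is
the one that reproduces the published ratio table for
caprylate/caprate/SNAC from its printed ΔG values (e.g. 0.99 → 2.01,
−2.21 → 0.21 at 310.15 K) to ±0.01; the textbook `boltzmann` convention
exp(ΔG/RT) does not (it gives 0.03 for ΔG = −2.21). Whether the ln 10
factor is a deliberate log₁₀ convention or an arithmetic artifact cannot be
determined from the numbers, so both are provided and neither intent is
asserted; `paper` is the default because reproducing the table is the
primary use.

## Synthetic data: what it emulates and what it does not

`make_bilayer_trajectory` builds 64+64 phosphate lattices on jittered
planes at ±1.95 nm about the box-z midpoint of a 6.60 × 6.60 × 9.35 nm box
(the published pure-POPC geometry, embedded by construction), ideal
all-trans zig-zag tails with explicit terminal hydrogens, single-site
waters outside the membrane slab, and enhancers that follow piecewise-
linear scripted z-paths (stay / expel / flip-flop / boundary-cross /
expel-then-return) with small lateral jitter. Piecewise-linear paths make
commit frames unambiguous for precision/recall testing. Ground truth is
derived from a brute-force geometric re-scan of the emitted coordinates,
not from script intent, so generator and detector can disagree in tests.
Interior waters are placed only on request, pinned 0.25 nm below terminal
carbons, giving an exact expected permeation count.

Lipids are static and dynamics are not physical: passing tests certify the
*operators* (event logic, geometry, estimators, WHAM) against known truth,
not force-field realism. Observables that genuinely require the original
500 ns simulations — expulsion fractions per species, APL and thickness
shifts with concentration, PMF minimum locations per enhancer — are
outside what synthetic fixtures can certify and are deliberately not
asserted anywhere.

Other generators: 2-D Brownian walkers (Gaussian increments, variance
2·D·dt per axis), orientation ensembles (aligned/in-plane/isotropic/cone)
with closed-form order parameters, exact inverse-CDF Boltzmann samples of
tabulated or callable 1-D potentials under harmonic biases (trapezoidal
CDF — a plain cumulative sum shifts samples by half a grid cell, which
WHAM reads as a spurious k·Δx/2 tilt), and ideal/demixed planar lattice
mixtures. The default umbrella spring, 239 kcal/mol/nm² (the conventional
1000 kJ/mol/nm² pulling spring), gives adjacent-window overlap at the
0.1 nm spacing of the published layout; the reference double-well
potential has wells at 0.45 and 1.20 nm and is flat beyond 1.6 nm so a
1.6–1.9 nm zone can serve as the bulk-water reference. All generators are
bitwise-reproducible under a fixed seed.

## Problem sizes used in tests

The test suite and acceptance checks run on: scripted bilayers of 128
lipids, up to 22 enhancers and 160 frames; 512 Brownian walkers × 10⁴
steps for diffusion recovery (within 5%); 20 umbrella windows × 5×10⁴
samples for PMF recovery (within 0.15 kcal/mol over populated bins);
10⁵-vector ensembles for the isotropic order limit (|S| ≤ 0.01); and
1024-molecule lattice mixtures averaged over 5 configurations for the
0.5 ± 0.02 mixing calibration — sizes at which the closed-form error
estimates above put the expected deviations comfortably inside those
bounds.

## Known limitations

* Orthorhombic boxes only; the bilayer normal is fixed to +z.
* No Voronoi per-lipid areas, curvature or undulation analysis; no
  aggregate/micelle lifetime statistics.
* The water-site model treats one atom per water as the counting site.
* The percent-to-count rule rounds half away from zero; published anchor
  counts (5% → 3, 35% → 22 of 64) are reproduced, other percentages follow
  the same rule.
* The mM conversion assumes a fixed 0.030 nm³ molecular volume of water at
  310 K and is informational only.
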