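"""Composition bookkeeping: insertion counts and number concentrations."""

from __future__ import annotations

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Volume of one water molecule in bulk at ~310 K, nm^3.
WATER_MOLECULAR_VOLUME_NM3 = 0.030


def pe_count_from_percent(percent: float, n_leaflet_lipids: int = 64) -> int:
    """Number of enhancer molecules for a given mole-% of one leaflet's lipids.

    5% of a 64-lipid leaflet gives 3 molecules and 35% gives 22, the
    convention used when building the simulated systems.
    """
    if percent < 0:
        raise ValueError("percent must be non-negative")
    return int(round(percent / 100.0 * n_leaflet_lipids))


def number_concentration_to_mM(n_pe: int, n_water: int) -> float:
    """Enhancer concentration in mM implied by counts of PEs and waters.

    The aqueous volume is estimated as ``n_water * v_w`` with
    ``v_w = 0.030 nm^3`` per water; the result is n_pe / (V * N_A) in mmol/L.
    Informational utility — reported concentrations depend on the water model
    and equilibrated volume.
    """
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    if n_pe < 0:
        raise ValueError("n_pe must be non-negative")
    volume_nm3 = n_water * WATER_MOLECULAR_VOLUME_NM3
    volume_L = volume_nm3 * 1e-24
    mol = n_pe / N_AVOGADRO
    return mol / volume_L * 1e3
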