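"""WHAM, ΔG extraction, replicate aggregation and the partition ratio."""

import numpy as np
import pytest

from memperturb import (
    AnalysisConfig,
    PMFProfile,
    UmbrellaWindow,
    aggregate_replicates,
    boltzmann_inversion,
    compute_partition,
    double_well_potential,
    extract_delta_g,
    load_windows,
    make_umbrella_samples,
    partition_ratio,
    wham_solve,
)
from memperturb.config import R_KCAL
from memperturb.free_energy import ConvergenceError

CENTERS = np.arange(20) * 0.1
REF_ZONE = (1.6, 1.9)


@pytest.fixture(scope="module")
def recovery_cfg():
    return AnalysisConfig(water_reference_zone=REF_ZONE)


@pytest.fixture(scope="module")
def double_well_windows():
    return make_umbrella_samples(
        double_well_potential, CENTERS, k=239.0, n_samples=20_000, seed=17
    )


class TestPartitionRatio:
    # printed free-energy differences and outside/inside ratios for
    # caprylate, caprate and SNAC at all-atom and coarse-grained resolution
    TABLE = [
        (0.99, 2.01),
        (-2.21, 0.21),
        (-1.30, 0.40),
        (-2.92, 0.13),
        (-4.40, 0.04),
        (-3.25, 0.10),
    ]

    @pytest.mark.parametrize("dg,expected", TABLE)
    def test_published_table_round_trip(self, dg, expected):
        assert partition_ratio(dg, T=310.15, convention="paper") == pytest.approx(
            expected, abs=0.01
        )

    def test_zero_dg_is_unity_in_both_conventions(self):
        assert partition_ratio(0.0, convention="paper") == pytest.approx(1.0)
        assert partition_ratio(0.0, convention="boltzmann") == pytest.approx(1.0)

    def test_boltzmann_convention_formula(self):
        dg, T = -2.21, 310.15
        assert partition_ratio(dg, T, "boltzmann") == pytest.approx(
            np.exp(dg / (R_KCAL * T))
        )

    def test_conventions_differ_by_ln10_scaling(self):
        dg = -1.3
        a = partition_ratio(dg, convention="paper")
        b = partition_ratio(dg, convention="boltzmann")
        assert np.log(a) * np.log(10.0) == pytest.approx(np.log(b))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            partition_ratio(1.0, T=-5)
        with pytest.raises(ValueError):
            partition_ratio(1.0, convention="nonsense")


class TestWham:
    def test_unbiased_single_window_equals_boltzmann_inversion(self):
        rng = np.random.default_rng(0)
        w = UmbrellaWindow(center=0.0, k=0.0, samples=rng.normal(1.0, 0.3, 100_000))
        cfg = AnalysisConfig(water_reference_zone=(0.0, 10.0))
        g1 = wham_solve([w], cfg).G
        g2 = boltzmann_inversion(w, cfg).G
        assert np.nanmax(np.abs(g1 - g2)) < 1e-9

    def test_double_well_recovery(self, double_well_windows, recovery_cfg):
        pmf = wham_solve(double_well_windows, recovery_cfg)
        assert pmf.converged
        U = double_well_potential(pmf.bin_centers)
        ref = (
            pmf.populated
            & (pmf.bin_centers >= REF_ZONE[0])
            & (pmf.bin_centers <= REF_ZONE[1])
        )
        U = U - U[ref].mean()
        err = np.nanmax(np.abs(pmf.G - U)[pmf.populated])
        assert err < 0.15

    def test_window_reordering_invariance(self, double_well_windows, recovery_cfg):
        g1 = wham_solve(double_well_windows, recovery_cfg).G
        g2 = wham_solve(double_well_windows[::-1], recovery_cfg).G
        assert np.nanmax(np.abs(g1 - g2)) < 1e-9

    def test_histogram_preserving_duplication_invariance(
        self, double_well_windows, recovery_cfg
    ):
        doubled = [
            UmbrellaWindow(w.center, w.k, np.concatenate([w.samples, w.samples]))
            for w in double_well_windows
        ]
        g1 = wham_solve(double_well_windows, recovery_cfg).G
        g2 = wham_solve(doubled, recovery_cfg).G
        assert np.nanmax(np.abs(g1 - g2)) < 1e-9

    def test_translation_equivariance(self, recovery_cfg):
        shift = 0.35  # a multiple of the bin width keeps grids commensurate
        wins = make_umbrella_samples(
            double_well_potential, CENTERS, k=239.0, n_samples=5000, seed=5
        )
        moved = [
            UmbrellaWindow(w.center + shift, w.k, w.samples + shift) for w in wins
        ]
        cfg2 = AnalysisConfig(
            water_reference_zone=(REF_ZONE[0] + shift, REF_ZONE[1] + shift)
        )
        p1 = wham_solve(wins, recovery_cfg)
        p2 = wham_solve(moved, cfg2)
        assert np.allclose(p2.bin_centers - shift, p1.bin_centers, atol=1e-9)
        assert np.nanmax(np.abs(p1.G - p2.G)) < 1e-9

    def test_disjoint_windows_rejected(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.0, 500.0, rng.normal(0.0, 0.03, 2000))
        w2 = UmbrellaWindow(5.0, 500.0, rng.normal(5.0, 0.03, 2000))
        with pytest.raises(ConvergenceError, match="overlap"):
            wham_solve([w1, w2], AnalysisConfig(water_reference_zone=(0, 10)))

    def test_max_iter_flags_unconverged(self, double_well_windows):
        cfg = AnalysisConfig(
            water_reference_zone=REF_ZONE, wham_max_iter=3, wham_tol=1e-12
        )
        pmf = wham_solve(double_well_windows, cfg)
        assert not pmf.converged
        assert pmf.n_iter == 3
        assert np.isfinite(pmf.G[pmf.populated]).all()


class TestDeltaG:
    def _flat_pmf(self, g_values, centers):
        return PMFProfile(
            bin_centers=np.asarray(centers, float),
            G=np.asarray(g_values, float),
            F=np.zeros(1),
            converged=True,
            n_iter=1,
            bin_width=0.05,
        )

    def test_flat_profile_gives_zero(self):
        pmf = self._flat_pmf(np.zeros(10), np.arange(10) * 0.1)
        dg, loc = extract_delta_g(pmf, (0.0, 0.9))
        assert dg == 0.0

    def test_constructed_well(self, recovery_cfg):
        wins = make_umbrella_samples(
            lambda x: -2.0 * np.exp(-(((np.asarray(x) - 1.2) / 0.15) ** 2)),
            CENTERS, k=239.0, n_samples=20_000, seed=9,
        )
        pmf = wham_solve(wins, recovery_cfg)
        dg, loc = extract_delta_g(pmf, (0.0, 1.5))
        assert dg == pytest.approx(-2.0, abs=0.1)
        assert loc == pytest.approx(1.2, abs=recovery_cfg.pmf_bin_width)

    def test_repulsive_barrier_positive(self, recovery_cfg):
        wins = make_umbrella_samples(
            lambda x: 1.5 * np.exp(-(((np.asarray(x) - 0.8) / 0.4) ** 2)),
            CENTERS, k=239.0, n_samples=20_000, seed=10,
        )
        pmf = wham_solve(wins, recovery_cfg)
        dg, _ = extract_delta_g(pmf, (0.5, 1.1))
        assert dg > 0

    def test_empty_zone_rejected(self):
        pmf = self._flat_pmf(np.zeros(5), np.arange(5) * 0.1)
        with pytest.raises(ValueError):
            extract_delta_g(pmf, (3.0, 4.0))

    def test_compute_partition_bundles_result(self, recovery_cfg, double_well_windows):
        pmf = wham_solve(double_well_windows, recovery_cfg)
        part = compute_partition(pmf, (0.0, 1.5), T=310.15)
        assert part.co_over_ci == pytest.approx(
            partition_ratio(part.delta_g, 310.15, "paper")
        )
        assert part.delta_g < 0
        assert part.co_over_ci > 0


class TestReplicates:
    def _pmf(self, g):
        return PMFProfile(np.arange(len(g)) * 0.05, np.asarray(g, float),
                          np.zeros(1), True, 1, 0.05)

    def test_identical_replicates_have_zero_sd(self):
        p = self._pmf([0.0, -1.0, -2.0])
        _, mean, sd = aggregate_replicates([p, p, p])
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, p.G)

    def test_constant_offset_sample_sd(self):
        c = 0.8
        p1 = self._pmf([0.0, -1.0, -2.0])
        p2 = self._pmf([c, -1.0 + c, -2.0 + c])
        _, _, sd = aggregate_replicates([p1, p2])
        # sample sd (ddof=1) of {g, g+c} is c/sqrt(2)
        assert np.allclose(sd, c / np.sqrt(2))

    def test_generator_replicates_sd_bounded(self, recovery_cfg):
        pmfs = []
        for seed in (21, 22, 23):
            wins = make_umbrella_samples(
                double_well_potential, CENTERS, k=239.0, n_samples=10_000, seed=seed
            )
            pmfs.append(wham_solve(wins, recovery_cfg, bin_range=(-0.5, 2.5)))
        grids = [p.bin_centers.shape for p in pmfs]
        assert len(set(grids)) == 1
        _, mean, sd = aggregate_replicates(pmfs)
        ok = np.isfinite(sd)
        # replicate scatter stays within a few times the per-bin noise floor
        assert np.nanmax(sd[ok]) < 0.2

    def test_mismatched_grids_rejected(self):
        p1 = self._pmf([0.0, 1.0])
        p2 = self._pmf([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="grid"):
            aggregate_replicates([p1, p2])


class TestWindowIO:
    def test_csv_metadata_and_sample_files(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = []
        for i, c in enumerate((0.5, 0.6)):
            samples = rng.normal(c, 0.05, 500)
            f = tmp_path / f"win{i}.xvg"
            np.savetxt(f, np.column_stack([np.arange(500) * 0.002, samples]))
            rows.append(f"{c},239.0,win{i}.xvg")
        meta = tmp_path / "windows.csv"
        meta.write_text("center,k,file\n" + "\n".join(rows) + "\n")
        wins = load_windows(meta)
        assert len(wins) == 2
        assert wins[0].n == 500
        assert wins[1].center == 0.6

    def test_comment_lines_ignored(self, tmp_path):
        f = tmp_path / "w.xvg"
        f.write_text("# pull output\n@ legend\n0.0 0.51\n0.002 0.49\n")
        from memperturb.free_energy import read_umbrella_samples

        assert read_umbrella_samples(f).tolist() == [0.51, 0.49]
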