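"""WHAM reconstruction, corrections, alignment, and error estimators."""

from dataclasses import replace

import numpy as np
import pytest

import glycopair as gp
from glycopair.synthetic import (
    LangevinConfig,
    biased_radial_pdf,
    make_reference_potential,
    simulate_umbrella_window,
    simulate_window_2d,
)
from glycopair.wham import (
    UmbrellaWindow,
    _wham_fixed_point,
    align_profile,
    align_surface_tail,
    bootstrap_error,
    segment_error,
    solve_wham_1d,
    solve_wham_2d,
    volume_entropy_correction,
    volume_entropy_correction_2d,
)

from conftest import AIMD_EDGES


class TestSolve1D:
    def test_single_unbiased_window_is_boltzmann_inversion(self, thermo):
        """With one window and zero bias the WHAM fixed point reduces to
        G = -kT ln h + C exactly."""
        rng = np.random.default_rng(0)
        samples = np.abs(rng.normal(0.5, 0.05, size=5000)) + 1e-3
        w = UmbrellaWindow(r0=0.5, k=0.0, samples=samples)
        edges = np.arange(0.3, 0.7 + 1e-12, 0.01)
        prof, sol = solve_wham_1d([w], edges, thermo)
        h, _ = np.histogram(samples, bins=edges)
        occupied = h > 0
        expected = -thermo.kT * np.log(h[occupied] / h.sum())
        diff = prof.G[occupied] - expected
        assert np.allclose(diff, diff[0], atol=1e-9)  # constant offset only
        assert sol.converged

    def test_matches_direct_reweighting_oracle(self, thermo):
        """Two heavily overlapping windows on a known well: WHAM agrees
        with pooled direct reweighting using quadrature window offsets."""
        pot = make_reference_potential("single_well")
        k = 500.0
        centers = [0.40, 0.42]
        cfg = LangevinConfig(n_steps=400_000, n_equil=20_000, seed=6)
        windows = [
            simulate_umbrella_window(pot, c, k, replace(cfg, seed=cfg.seed + i))
            for i, c in enumerate(centers)
        ]
        edges = np.arange(0.25, 0.70 + 1e-12, 0.005)
        bc = 0.5 * (edges[:-1] + edges[1:])
        prof, _ = solve_wham_1d(windows, edges, thermo)

        # oracle: F_i from quadrature over the analytic density, no iteration
        r_grid = np.linspace(0.15, 1.2, 40001)
        logp0 = 2 * np.log(r_grid) - thermo.beta * np.asarray(pot.energy(r_grid))
        p0 = np.exp(logp0 - logp0.max())
        z0 = np.trapezoid(p0, r_grid)
        f_quad = []
        for w in windows:
            zi = np.trapezoid(p0 * np.exp(-thermo.beta * w.bias(r_grid)), r_grid)
            f_quad.append(-thermo.kT * np.log(zi / z0))
        hists = [np.histogram(w.samples, bins=edges)[0] for w in windows]
        num = sum(hists)
        den = sum(
            w.n_samples * np.exp(-thermo.beta * (w.bias(bc) - fi))
            for w, fi in zip(windows, f_quad)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            g_oracle = -thermo.kT * np.log(num / den)
        mask = (num > 50) & np.isfinite(prof.G)
        diff = prof.G[mask] - g_oracle[mask]
        diff -= diff.mean()
        assert np.max(np.abs(diff)) < 0.1

    def test_fixed_point_independent_of_initialization(self, aimd_windows, thermo):
        hist = np.stack(
            [np.histogram(w.samples, bins=AIMD_EDGES)[0] for w in aimd_windows]
        )
        bc = 0.5 * (AIMD_EDGES[:-1] + AIMD_EDGES[1:])
        bias = np.stack([w.bias(bc) for w in aimd_windows])
        rng = np.random.default_rng(11)
        p1, _, s1 = _wham_fixed_point(hist, bias, thermo.beta, 1e-9, 200_000)
        p2, _, s2 = _wham_fixed_point(
            hist, bias, thermo.beta, 1e-9, 200_000,
            f_init=rng.uniform(-5, 5, size=len(aimd_windows)),
        )
        assert s1.converged and s2.converged
        np.testing.assert_allclose(s1.window_offsets, s2.window_offsets, atol=1e-6)
        m = np.isfinite(p1)
        np.testing.assert_allclose(p1[m], p2[m], rtol=1e-6)

    def test_merging_identical_windows_preserves_profile(self, thermo):
        pot = make_reference_potential("single_well")
        cfg = LangevinConfig(n_steps=50_000, n_equil=5000, seed=2)
        w1 = simulate_umbrella_window(pot, 0.4, 2000.0, cfg)
        w2 = simulate_umbrella_window(pot, 0.4, 2000.0, replace(cfg, seed=3))
        merged = UmbrellaWindow(
            r0=0.4, k=2000.0, samples=np.concatenate([w1.samples, w2.samples])
        )
        edges = np.arange(0.3, 0.55 + 1e-12, 0.005)
        pa, _ = solve_wham_1d([w1, w2], edges, thermo)
        pb, _ = solve_wham_1d([merged], edges, thermo)
        m = pa.occupied & pb.occupied
        diff = pa.G[m] - pb.G[m]
        assert np.max(np.abs(diff - diff.mean())) < 1e-6

    def test_nonconvergence_is_flagged_not_silent(self, aimd_windows, thermo):
        with pytest.warns(gp.wham.WHAMConvergenceWarning):
            prof, sol = solve_wham_1d(
                aimd_windows, AIMD_EDGES, thermo, tolerance=1e-12, max_iter=3
            )
        assert not sol.converged
        assert prof.metadata["converged"] is False

    def test_empty_interior_bins_are_nan(self, thermo):
        w = UmbrellaWindow(
            r0=0.4, k=0.0, samples=np.array([0.35, 0.36, 0.45, 0.46])
        )
        edges = np.arange(0.34, 0.48 + 1e-12, 0.01)
        prof, _ = solve_wham_1d([w], edges, thermo)
        assert np.isnan(prof.G[~prof.occupied]).all()
        assert np.any(~prof.occupied)

    def test_out_of_range_samples_counted(self, thermo):
        w = UmbrellaWindow(r0=0.4, k=0.0, samples=np.array([0.35, 0.9, 1.1]))
        edges = np.arange(0.3, 0.5, 0.01)
        prof, _ = solve_wham_1d([w], edges, thermo)
        assert prof.metadata["n_out_of_range"] == 2

    def test_no_windows_rejected(self, thermo):
        with pytest.raises(ValueError, match="at least one"):
            solve_wham_1d([], np.arange(0.3, 0.5, 0.01), thermo)


class TestVolumeEntropyCorrection:
    def test_closed_form_values(self, thermo):
        """+2kT ln r is 0 at r = 1 nm and -3.458 kJ/mol at r = 0.5 nm, 300 K."""
        prof = gp.FreeEnergyProfile(
            bin_centers=np.array([0.5, 1.0]), G=np.array([0.0, 0.0])
        )
        corr = volume_entropy_correction(prof, thermo)
        assert corr.G[1] == pytest.approx(0.0, abs=1e-12)
        assert corr.G[0] == pytest.approx(
            2 * 0.0083144626 * 300 * np.log(0.5), abs=1e-9
        )
        assert corr.G[0] == pytest.approx(-3.458, abs=1e-3)

    def test_double_application_rejected(self, thermo):
        prof = gp.FreeEnergyProfile(
            bin_centers=np.array([0.5]), G=np.array([1.0])
        )
        once = volume_entropy_correction(prof, thermo)
        with pytest.raises(ValueError, match="already"):
            volume_entropy_correction(once, thermo)

    def test_flat_landscape_yields_flat_corrected_profile(self, thermo):
        """Umbrella sampling a wall-only landscape: after the Jacobian
        correction the profile matches the (nearly zero) potential."""
        flat = make_reference_potential("flat")
        cfg = LangevinConfig(n_steps=2_000_000, n_equil=20_000, seed=11)
        centers = [round(0.32 + 0.05 * i, 2) for i in range(8)]
        ws = gp.generate_window_set(flat, centers, 1000.0, cfg)
        edges = np.arange(0.30, 0.72 + 1e-12, 0.005)
        prof, _ = solve_wham_1d(ws, edges, thermo)
        prof = volume_entropy_correction(prof, thermo)
        prof = align_profile(prof, "large_distance")
        m = (prof.bin_centers >= 0.34) & (prof.bin_centers <= 0.68) & prof.occupied
        resid = prof.G[m] - np.asarray(flat.energy(prof.bin_centers[m]))
        assert np.max(np.abs(resid)) < 0.3


class TestAlignment:
    def test_ssp_minimum_is_zero_after_alignment(self, aimd_profile):
        m = (
            (aimd_profile.bin_centers >= 0.45)
            & (aimd_profile.bin_centers <= 0.65)
            & aimd_profile.occupied
        )
        assert np.nanmin(aimd_profile.G[m]) == pytest.approx(0.0, abs=1e-12)

    def test_alignment_preserves_pairwise_differences(self, aimd_windows, thermo):
        prof, _ = solve_wham_1d(aimd_windows, AIMD_EDGES, thermo)
        a = align_profile(prof, "ssp_minimum")
        b = align_profile(prof, "large_distance")
        m = prof.occupied
        da = a.G[m] - a.G[m][0]
        db = b.G[m] - b.G[m][0]
        np.testing.assert_allclose(da, db, atol=1e-12)

    def test_tail_alignment_recovers_absolute_well_depth(
        self, aimd_windows, aimd_potential, thermo
    ):
        """Zeroing at large distance makes G at the BDP minimum match the
        absolute analytic well value (oracle: the analytic curve referenced
        to the same tail span, since the ladder stops at ~0.68 nm where U
        is not yet fully zero).  Tolerance 1.0 kJ/mol: the last occupied
        bins hold few counts, so the tail shift itself carries a few
        tenths kJ/mol of noise."""
        prof, _ = solve_wham_1d(aimd_windows, AIMD_EDGES, thermo)
        prof = volume_entropy_correction(prof, thermo)
        prof = align_profile(prof, "large_distance", n_tail=3)
        ex = aimd_potential.mode_extrema()
        m = (
            (prof.bin_centers >= 0.28)
            & (prof.bin_centers <= 0.35)
            & prof.occupied
        )
        g_bdp = np.nanmin(prof.G[m])
        tail_idx = np.flatnonzero(prof.occupied)[-3:]
        u_tail = float(
            np.mean(np.asarray(aimd_potential.energy(prof.bin_centers[tail_idx])))
        )
        assert g_bdp == pytest.approx(ex["bdp"][1] - u_tail, abs=1.0)

    def test_alignment_without_occupied_range_rejected(self, thermo):
        prof = gp.FreeEnergyProfile(
            bin_centers=np.array([0.3, 0.35]), G=np.array([1.0, 2.0])
        )
        with pytest.raises(ValueError, match="SSP search range"):
            align_profile(prof, "ssp_minimum")


class TestErrorEstimators:
    def test_duplicated_data_gives_zero_segment_error(self, thermo):
        rng = np.random.default_rng(5)
        block = np.abs(rng.normal(0.45, 0.03, size=400)) + 1e-3
        w = UmbrellaWindow(r0=0.45, k=1000.0, samples=np.tile(block, 5))
        edges = np.arange(0.3, 0.6 + 1e-12, 0.01)
        err = segment_error(
            [w], edges, thermo, n_segments=5, align="none",
            entropy_correction=False,
        )
        m = np.isfinite(err)
        assert m.any()
        assert np.nanmax(err[m]) < 1e-9

    def test_too_few_segments_rejected(self, aimd_windows, thermo):
        with pytest.raises(ValueError, match="n_segments"):
            segment_error(aimd_windows, AIMD_EDGES, thermo, n_segments=1)

    def test_degenerate_bootstrap_error_is_zero(self, thermo):
        w = UmbrellaWindow(r0=0.4, k=100.0, samples=np.full(50, 0.4))
        edges = np.arange(0.3, 0.5 + 1e-12, 0.01)
        err = bootstrap_error(
            [w], edges, thermo, n_boot=20, seed=3, align="none",
            entropy_correction=False,
        )
        m = np.isfinite(err)
        assert np.nanmax(err[m]) == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_is_seeded_reproducible(self, thermo):
        rng = np.random.default_rng(5)
        w = UmbrellaWindow(
            r0=0.45, k=1000.0, samples=np.abs(rng.normal(0.45, 0.03, 500)) + 1e-3
        )
        edges = np.arange(0.35, 0.55 + 1e-12, 0.01)
        kwargs = dict(n_boot=10, seed=9, align="none", entropy_correction=False)
        e1 = bootstrap_error([w], edges, thermo, **kwargs)
        e2 = bootstrap_error([w], edges, thermo, **kwargs)
        np.testing.assert_array_equal(e1, e2)


class TestSolve2D:
    def test_separable_marginals_match_1d(self, thermo):
        """On U(r1) + U(r2) the marginal of the 2D solution agrees with a
        1D solution built from the same x-series."""
        pot = make_reference_potential("single_well")
        centers = [0.30, 0.38, 0.46, 0.54, 0.62]
        k = 1500.0
        cfg = LangevinConfig(n_steps=30_000, n_equil=5000, seed=5)
        wins = []
        for i, c1 in enumerate(centers):
            for j, c2 in enumerate(centers):
                wcfg = replace(cfg, seed=cfg.seed + 101 * (5 * i + j))
                wins.append(simulate_window_2d(pot, pot, (c1, c2), (k, k), wcfg))
        edges = np.arange(0.26, 0.70 + 1e-12, 0.01)
        surf, sol = solve_wham_2d(wins, (edges, edges), thermo)
        assert sol.converged
        w1 = [
            UmbrellaWindow(r0=w.r0[0], k=w.k[0], samples=w.samples[:, 0])
            for w in wins
        ]
        prof, _ = solve_wham_1d(w1, edges, thermo)
        p2 = np.where(surf.occupied, np.exp(-surf.G / thermo.kT), 0.0)
        px = p2.sum(axis=1)
        with np.errstate(divide="ignore"):
            gx = -thermo.kT * np.log(px / px.sum())
        m = (
            np.isfinite(prof.G)
            & np.isfinite(gx)
            & (prof.bin_centers >= 0.30)
            & (prof.bin_centers <= 0.64)
        )
        d = gx[m] - prof.G[m]
        assert np.max(np.abs(d - d.mean())) < 0.5

    def test_2d_entropy_correction_closed_form(self, thermo):
        surf = gp.Surface2D(
            x_centers=np.array([0.5, 1.0]),
            y_centers=np.array([0.5, 1.0]),
            G=np.zeros((2, 2)),
        )
        corr = volume_entropy_correction_2d(surf, thermo)
        one_d = 2 * thermo.kT * np.log(0.5)
        assert corr.G[0, 0] == pytest.approx(2 * one_d, abs=1e-9)
        assert corr.G[0, 0] == pytest.approx(-6.917, abs=2e-3)
        assert corr.G[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert corr.G[0, 1] == pytest.approx(one_d, abs=1e-9)
        with pytest.raises(ValueError, match="already"):
            volume_entropy_correction_2d(corr, thermo)

    def test_swapping_coordinates_transposes_surface(self, thermo):
        pot = make_reference_potential("single_well")
        cfg = LangevinConfig(n_steps=10_000, n_equil=1000, seed=5)
        w = simulate_window_2d(pot, pot, (0.38, 0.46), (1500.0, 1500.0), cfg)
        swapped = gp.UmbrellaWindow2D(
            r0=(w.r0[1], w.r0[0]),
            k=(w.k[1], w.k[0]),
            samples=w.samples[:, ::-1],
        )
        edges = np.arange(0.26, 0.70 + 1e-12, 0.01)
        s1, _ = solve_wham_2d([w], (edges, edges), thermo)
        s2, _ = solve_wham_2d([swapped], (edges, edges), thermo)
        m = np.isfinite(s1.G)
        np.testing.assert_allclose(s1.G[m], s2.G.T[m], atol=1e-9)

    def test_tail_alignment_zeroes_far_corner(self, thermo):
        rng = np.random.default_rng(1)
        g = np.full((6, 6), np.nan)
        # occupy a diagonal band; the four occupied cells farthest out in
        # r1 + r2 are known by construction
        occupied_cells = [(1, 1), (2, 2), (3, 3), (3, 4), (4, 3), (4, 4), (5, 5)]
        for ij in occupied_cells:
            g[ij] = rng.normal()
        far4 = [(5, 5), (4, 4), (3, 4), (4, 3)]
        surf = gp.Surface2D(
            x_centers=np.linspace(0.3, 0.8, 6),
            y_centers=np.linspace(0.3, 0.8, 6),
            G=g,
        )
        aligned = align_surface_tail(surf, n_tail=2)
        assert np.mean([aligned.G[ij] for ij in far4]) == pytest.approx(
            0.0, abs=1e-12
        )
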