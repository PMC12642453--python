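import numpy as np
import pytest

from mlipal import (AxisPositionCV, BiasPotential, Configuration,
                    DistancePredicate, FESEstimate, HarmonicRestraint,
                    MDParams, Trajectory, UmbrellaWindow, barrier,
                    boltzmann_samples, classify_fraction, production_wtmetad,
                    reweight_fes, run_md, run_umbrella, wham)
from mlipal.free_energy import histogram_overlap
from mlipal.units import KB

T = 300.0
KBT = KB * T


def dw_energy(x, hb=0.2):
    return hb * (np.asarray(x) ** 2 - 1.0) ** 2


def make_windows(n=12, k=2.0, samples=30000, seed=0, span=1.6, hb=5 * KBT):
    rng = np.random.default_rng(seed)
    dense = np.linspace(-2.2, 2.2, 4001)
    return [
        UmbrellaWindow(center=c0, k=k, temperature=T,
                       samples=boltzmann_samples(
                           lambda x: dw_energy(x, hb), dense, T, samples, rng,
                           bias_fn=lambda x, c0=c0: 0.5 * k * (np.asarray(x) - c0) ** 2))
        for c0 in np.linspace(-span, span, n)
    ]


class TestUmbrellaSampling:
    def test_sample_count_without_equilibration(self, double_well, dw_config):
        cv = AxisPositionCV(0, 0, name="x")
        p = MDParams(timestep=0.5, temperature=T, seed=1)
        windows = run_umbrella(double_well, cv, [-1.0, 0.0, 1.0], k=5.0, T=T,
                               time_per_window=100.0, equil=0.0, p=p,
                               start=dw_config, stride=5, seed=2)
        assert all(len(w.samples) == 200 // 5 for w in windows)

    def test_harmonic_restraint_variance_matches_gaussian(self, dw_config):
        # umbrella on a harmonic well: combined stiffness is analytic
        class Quad:
            def energy_forces(self, c):
                x = c.positions[0, 0]
                f = np.zeros_like(c.positions)
                f[0, 0] = -2.0 * x
                return x * x, f

        cv = AxisPositionCV(0, 0, name="x")
        k_umb = 6.0
        p = MDParams(timestep=0.5, temperature=T, seed=3)
        (w,) = run_umbrella(Quad(), cv, [0.0], k=k_umb, T=T,
                            time_per_window=100000.0, equil=5000.0, p=p,
                            start=dw_config, stride=5, seed=3)
        k_eff = 2.0 + k_umb  # V'' of x² is 2, plus the restraint
        assert np.var(w.samples) == pytest.approx(KBT / k_eff, rel=0.1)

    def test_overlap_metric_symmetric(self):
        windows = make_windows(n=3, samples=5000)
        assert histogram_overlap(windows[0], windows[1]) == pytest.approx(
            histogram_overlap(windows[1], windows[0]))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, k=1.0, samples=np.array([]))


class TestWHAM:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(4)
        dense = np.linspace(-2.2, 2.2, 4001)
        samples = boltzmann_samples(dw_energy, dense, T, 100000, rng)
        w = UmbrellaWindow(center=0.0, k=1e-12, samples=samples,
                           temperature=T)
        est = wham([w], T, bins=60)
        counts, edges = np.histogram(samples, bins=60,
                                     range=(est.grid[0] - (est.grid[1] - est.grid[0]) / 2,
                                            est.grid[-1] + (est.grid[1] - est.grid[0]) / 2))
        mask = counts > 0
        ref = -KBT * np.log(counts[mask])
        ref -= ref.min()
        np.testing.assert_allclose(est.F[mask], ref, atol=1e-6)

    def test_recovers_double_well_from_exact_samples(self):
        est = wham(make_windows(samples=100000, seed=7), T, bins=400)
        mask = (est.grid >= -1.5) & (est.grid <= 1.5) & np.isfinite(est.F)
        ref = dw_energy(est.grid[mask], hb=5 * KBT)
        ref -= ref.min()
        err = np.abs((est.F[mask] - est.F[mask].min()) - ref)
        assert err.max() < 0.3 * KBT

    def test_scale_invariance_under_count_doubling(self):
        windows = make_windows(n=6, samples=20000, seed=5)
        doubled = [UmbrellaWindow(center=w.center, k=w.k,
                                  samples=np.concatenate([w.samples, w.samples]),
                                  temperature=T) for w in windows]
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        a = wham(windows, T, bins=100, grid_range=(lo, hi))
        b = wham(doubled, T, bins=100, grid_range=(lo, hi))
        mask = np.isfinite(a.F) & np.isfinite(b.F)
        np.testing.assert_allclose(a.F[mask], b.F[mask], atol=1e-6)

    def test_window_order_invariance(self):
        windows = make_windows(n=6, samples=20000, seed=6)
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        a = wham(windows, T, bins=100, grid_range=(lo, hi))
        b = wham(windows[::-1], T, bins=100, grid_range=(lo, hi))
        np.testing.assert_allclose(a.F, b.F, atol=1e-9)


class TestReweightFES:
    def test_zero_bias_reduces_to_unweighted_kde(self):
        rng = np.random.default_rng(8)
        samples = rng.normal(0.0, 0.3, 20000)
        cv = AxisPositionCV(0, 0, name="x")
        empty = BiasPotential([cv], h0=0.01, gamma=15, T=T, tau_deposit=100,
                              sigma=0.1)
        grid = np.linspace(-1, 1, 101)
        est = reweight_fes(samples, empty, T, bandwidth=0.05, grid=grid)
        # harmonic free energy: F = kBT x²/(2σ²) + C
        ref = KBT * grid**2 / (2 * 0.3**2)
        mask = np.abs(grid) < 0.75
        assert np.abs((est.F - est.F[mask].min())[mask] - ref[mask]).max() \
            < 0.15 * KBT

    def test_bandwidth_validation_and_degenerate_series(self):
        cv = AxisPositionCV(0, 0, name="x")
        b = BiasPotential([cv], h0=0.01, gamma=15, T=T, tau_deposit=100,
                          sigma=0.1)
        with pytest.raises(ValueError):
            reweight_fes(np.array([1.0, 2.0]), b, T, 0.0, np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            reweight_fes(np.array([1.0]), b, T, 0.02, np.linspace(0, 1, 5))


class TestBarrier:
    def test_analytic_double_well_profile(self):
        grid = np.linspace(-1.5, 1.5, 601)
        f = FESEstimate(grid=grid, F=dw_energy(grid))
        dg, ts = barrier(f, (-1.2, -0.8), (0.8, 1.2))
        assert dg == pytest.approx(0.2, abs=1e-4)
        assert ts == pytest.approx(0.0, abs=0.01)

    def test_symmetric_forward_equals_reverse(self):
        grid = np.linspace(-1.5, 1.5, 601)
        f = FESEstimate(grid=grid, F=dw_energy(grid))
        fwd, _ = barrier(f, (-1.2, -0.8), (0.8, 1.2))
        rev, _ = barrier(f, (0.8, 1.2), (-1.2, -0.8))
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_noisy_profile_within_sigma_band(self):
        rng = np.random.default_rng(9)
        grid = np.linspace(-1.5, 1.5, 301)
        sigma = 0.01
        f = FESEstimate(grid=grid,
                        F=dw_energy(grid) + rng.normal(0, sigma, grid.size))
        dg, _ = barrier(f, (-1.2, -0.8), (0.8, 1.2))
        assert dg == pytest.approx(0.2, abs=4 * sigma)

    def test_empty_basin_rejected(self):
        grid = np.linspace(-1, 1, 101)
        f = FESEstimate(grid=grid, F=dw_energy(grid))
        with pytest.raises(ValueError):
            barrier(f, (5.0, 6.0), (0.8, 1.2))


class TestFESEstimate:
    def test_min_shift_and_tsv_roundtrip(self, tmp_path):
        grid = np.linspace(0, 1, 11)
        f = FESEstimate(grid=grid, F=grid + 3.0)
        assert f.F.min() == 0.0
        path = tmp_path / "fes.tsv"
        f.to_tsv(path)
        back = FESEstimate.read_tsv(path)
        np.testing.assert_allclose(back.F, f.F, rtol=1e-12)

    def test_sigma_shrinks_with_reps(self, double_well, dw_config):
        cv = AxisPositionCV(0, 0, name="x")
        params = dict(h0=0.02, gamma=15.0, T=T, tau_deposit=50.0, sigma=0.1)
        grid = np.linspace(-1.4, 1.4, 141)
        est2 = production_wtmetad(double_well, cv, params, T, time=10000.0,
                                  reps=2, start=dw_config, grid=grid,
                                  seeds=[1, 2], stride=10)
        est6 = production_wtmetad(double_well, cv, params, T, time=10000.0,
                                  reps=6, start=dw_config, grid=grid,
                                  seeds=[1, 2, 3, 4, 5, 6], stride=10)
        mask = np.abs(grid) < 1.2
        band2 = 1.96 * est2.sigma[mask].mean() / np.sqrt(2)
        band6 = 1.96 * est6.sigma[mask].mean() / np.sqrt(6)
        assert band6 < band2

    def test_identical_seeds_give_zero_sigma(self, double_well, dw_config):
        cv = AxisPositionCV(0, 0, name="x")
        params = dict(h0=0.02, gamma=15.0, T=T, tau_deposit=50.0, sigma=0.1)
        est = production_wtmetad(double_well, cv, params, T, time=2000.0,
                                 reps=3, start=dw_config,
                                 grid=np.linspace(-1.4, 1.4, 71),
                                 seeds=[7, 7, 7], stride=10)
        np.testing.assert_allclose(est.sigma, 0.0, atol=1e-12)

    def test_single_rep_sigma_zero(self, double_well, dw_config):
        cv = AxisPositionCV(0, 0, name="x")
        params = dict(h0=0.02, gamma=15.0, T=T, tau_deposit=50.0, sigma=0.1)
        est = production_wtmetad(double_well, cv, params, T, time=1000.0,
                                 reps=1, start=dw_config,
                                 grid=np.linspace(-1.4, 1.4, 71), seeds=[3])
        np.testing.assert_array_equal(est.sigma, 0.0)


class TestClassifyFraction:
    def _trajectory(self, path_xs):
        frames = [Configuration(positions=[[x, 0, 0], [0, 0, 0]],
                                elements=["C", "C"]) for x in path_xs]
        return Trajectory(frames=frames, velocities=[],
                          times=np.arange(len(frames), dtype=float))

    def test_always_true_and_unreachable(self):
        trajs = [self._trajectory([1.0, 2.0]) for _ in range(5)]
        always = DistancePredicate([(0, 1, ">", 0.1)])
        never = DistancePredicate([(0, 1, ">", 100.0)])
        assert classify_fraction(trajs, always)["fraction"] == 1.0
        assert classify_fraction(trajs, never)["fraction"] == 0.0

    def test_conjunction_semantics(self):
        t = self._trajectory([1.0, 3.0])
        # both conditions must hold on the SAME frame
        p = DistancePredicate([(0, 1, ">", 2.0), (0, 1, "<", 2.5)])
        assert not p.on_trajectory(t)
        p2 = DistancePredicate([(0, 1, ">", 2.0), (0, 1, "<", 3.5)])
        assert p2.on_trajectory(t)

    def test_wilson_interval(self):
        trajs = [self._trajectory([3.0]) for _ in range(30)] + \
                [self._trajectory([1.0]) for _ in range(70)]
        out = classify_fraction(trajs, DistancePredicate([(0, 1, ">", 2.0)]))
        assert out["fraction"] == pytest.approx(0.30)
        lo, hi = out["ci95"]
        assert lo == pytest.approx(0.2189, abs=1e-3)
        assert hi == pytest.approx(0.3958, abs=1e-3)

    def test_escape_fraction_increases_with_temperature(self, double_well):
        # basin-escape predicate on unbiased runs mirrors the ion-pair
        # separation trend: higher T, more escapes over a fixed horizon
        cv = AxisPositionCV(0, 0, name="x")

        def fraction_at(temp, seeds):
            hits = 0
            for s in seeds:
                start = double_well.make_configuration((-1.0,))
                p = MDParams(timestep=0.5, temperature=temp, n_steps=8000,
                             seed=s)
                t = run_md(start, double_well, p, stride=20, cvs=[cv])
                hits += bool((t.cv_series["x"] > 0.8).any())
            return hits / len(seeds)

        seeds = range(10)
        assert fraction_at(900.0, seeds) >= fraction_at(300.0, seeds)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            classify_fraction([], DistancePredicate([(0, 1, ">", 1.0)]))
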