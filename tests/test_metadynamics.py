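import numpy as np
import pytest

from mlipal import (AxisPositionCV, BiasPotential, Dataset, Hill, MDParams,
                    average_biases, fes_from_bias, read_hills, select_restart,
                    write_hills, wtmetad_run)
from mlipal.units import KB


def make_bias(cv=None, h0=0.01, gamma=15.0, T=300.0, tau=100.0, sigma=0.1):
    cvs = [cv] if cv is not None else [AxisPositionCV(0, 0, name="x")]
    return BiasPotential(cvs, h0=h0, gamma=gamma, T=T, tau_deposit=tau,
                         sigma=sigma)


class TestBiasEvaluation:
    def test_empty_bias_is_zero(self):
        b = make_bias()
        assert b.energy([0.3]) == 0.0
        assert b.gradient([0.3]) == pytest.approx([0.0])

    def test_single_hill_center_value_and_linearity(self):
        b = make_bias()
        b.add_hill(Hill(centers=(0.5,), widths=(0.1,), height=0.01))
        assert b.energy([0.5]) == pytest.approx(0.01)
        b2 = make_bias()
        for _ in range(2):
            b2.add_hill(Hill(centers=(0.5,), widths=(0.1,), height=0.01))
        for s in np.linspace(-1, 1, 21):
            assert b2.energy([s]) == pytest.approx(2 * b.energy([s]),
                                                   rel=1e-12)

    def test_gradient_zero_at_center_and_decays(self):
        b = make_bias()
        b.add_hill(Hill(centers=(0.2,), widths=(0.1,), height=0.05))
        assert b.gradient([0.2]) == pytest.approx([0.0], abs=1e-15)
        assert abs(b.gradient([0.2 + 1.0])[0]) < 1e-10  # 10 sigma away

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        b = make_bias()
        for _ in range(20):
            b.add_hill(Hill(centers=(rng.uniform(-1, 1),),
                            widths=(rng.uniform(0.05, 0.3),),
                            height=rng.uniform(0.001, 0.02)))
        h = 1e-7
        for s in rng.uniform(-1.2, 1.2, 50):
            fd = (b.energy([s + h]) - b.energy([s - h])) / (2 * h)
            assert b.gradient([s])[0] == pytest.approx(fd, rel=1e-6,
                                                       abs=1e-12)

    def test_energy_grid_matches_scalar_energy(self):
        b = make_bias()
        b.add_hill(Hill(centers=(0.1,), widths=(0.2,), height=0.03))
        b.add_hill(Hill(centers=(-0.4,), widths=(0.1,), height=0.01))
        grid = np.linspace(-1, 1, 31)
        np.testing.assert_allclose(b.energy_grid(grid),
                                   [b.energy([s]) for s in grid], rtol=1e-13)

    def test_multi_cv_bias(self):
        cvs = [AxisPositionCV(0, 0, name="x"), AxisPositionCV(0, 1, name="y")]
        b = BiasPotential(cvs, h0=0.02, gamma=50, T=300, tau_deposit=25,
                          sigma=(0.1, 0.2))
        b.add_hill(Hill(centers=(0.0, 1.0), widths=(0.1, 0.2), height=0.02))
        assert b.energy([0.0, 1.0]) == pytest.approx(0.02)
        expected = 0.02 * np.exp(-0.5 * ((0.1 / 0.1) ** 2 + (0.2 / 0.2) ** 2))
        assert b.energy([0.1, 1.2]) == pytest.approx(expected, rel=1e-12)


class TestWellTemperedLaw:
    def test_height_at_zero_bias_is_h0(self):
        b = make_bias(h0=0.01)
        assert b.next_height([0.0]) == pytest.approx(0.01)

    def test_e_folding_by_construction(self):
        b = make_bias(h0=0.01, gamma=15, T=300)
        vfold = KB * (15 - 1) * 300.0
        b.add_hill(Hill(centers=(0.0,), widths=(1e6,), height=vfold))
        assert b.next_height([0.0]) == pytest.approx(0.01 / np.e, rel=1e-6)

    def test_repeated_deposition_decays_and_follows_the_law(self):
        b = make_bias(h0=0.01, gamma=15, T=300)
        denom = KB * (15 - 1) * 300.0
        heights = []
        for _ in range(200):
            v_before = b.energy([0.0])
            hill = b.deposit([0.0])
            assert hill.height == pytest.approx(
                0.01 * np.exp(-v_before / denom), rel=1e-10)
            heights.append(hill.height)
        assert all(a > b_ for a, b_ in zip(heights, heights[1:]))
        assert all(h <= 0.01 for h in heights)
        # saturation: tail increments become small (Cauchy-like partial sums)
        assert heights[-1] < 0.2 * heights[0]
        assert sum(heights[100:]) < sum(heights[:100])

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            make_bias(gamma=1.0)


class TestWtmetadRun:
    def test_no_hills_when_run_shorter_than_period(self, double_well,
                                                   dw_config):
        b = make_bias(tau=100.0)
        p = MDParams(timestep=0.5, temperature=300, n_steps=100, seed=1)
        _, bout = wtmetad_run(dw_config, double_well, b, p)
        assert bout.n_hills == 0

    def test_hill_count_matches_cadence(self, double_well, dw_config):
        b = make_bias(tau=100.0)
        p = MDParams(timestep=0.5, temperature=300, n_steps=2000, seed=1)
        _, bout = wtmetad_run(dw_config, double_well, b, p)
        assert bout.n_hills == 10  # floor(1000 fs / 100 fs)

    def test_deposit_phase_carries_over(self, double_well, dw_config):
        b = make_bias(tau=100.0)
        p = MDParams(timestep=0.5, temperature=300, n_steps=100, seed=1)
        # 50 fs run with 80 fs already elapsed -> one deposit after 20 fs
        _, bout = wtmetad_run(dw_config, double_well, b, p, deposit_phase=80.0)
        assert bout.n_hills == 1

    def test_input_bias_is_not_mutated(self, double_well, dw_config):
        b = make_bias(tau=50.0)
        b.add_hill(Hill(centers=(0.0,), widths=(0.1,), height=0.01))
        p = MDParams(timestep=0.5, temperature=300, n_steps=1000, seed=2)
        _, bout = wtmetad_run(dw_config, double_well, b, p)
        assert b.n_hills == 1
        assert bout.n_hills > 1
        assert bout.hills[0] is b.hills[0]  # inherited hill shared

    def test_barrier_crossing_under_bias(self, double_well, dw_config):
        cv = AxisPositionCV(0, 0, name="x")
        b = BiasPotential([cv], h0=0.01, gamma=15, T=300, tau_deposit=100,
                          sigma=0.1)
        p = MDParams(timestep=0.5, temperature=300, n_steps=200000, seed=5)
        traj, _ = wtmetad_run(dw_config, double_well, b, p, stride=10)
        assert (traj.cv_series["x"] > 0).any()  # both wells visited


class TestAverageBiases:
    def test_single_run_identity(self):
        b = make_bias()
        b.add_hill(Hill(centers=(0.3,), widths=(0.1,), height=0.01))
        avg = average_biases([b])
        grid = np.linspace(-1, 1, 41)
        np.testing.assert_allclose(avg.energy_grid(grid),
                                   b.energy_grid(grid), atol=1e-15)

    def test_identical_runs_average_to_one_run(self):
        b = make_bias()
        for c in (0.1, -0.5):
            b.add_hill(Hill(centers=(c,), widths=(0.1,), height=0.01))
        avg = average_biases([b, b, b])
        grid = np.linspace(-1, 1, 41)
        np.testing.assert_allclose(avg.energy_grid(grid),
                                   b.energy_grid(grid), atol=1e-12)

    def test_disjoint_new_hills_give_pointwise_mean(self):
        base = make_bias()
        r1, r2 = base.spawn(), base.spawn()
        r1.add_hill(Hill(centers=(-0.8,), widths=(0.1,), height=0.01))
        r2.add_hill(Hill(centers=(0.8,), widths=(0.1,), height=0.01))
        avg = average_biases([r1, r2])
        grid = np.linspace(-1.5, 1.5, 61)
        expected = 0.5 * (r1.energy_grid(grid) + r2.energy_grid(grid))
        np.testing.assert_allclose(avg.energy_grid(grid), expected,
                                   atol=1e-15)

    def test_inherited_prefix_kept_at_full_height(self):
        base = make_bias()
        base.add_hill(Hill(centers=(0.0,), widths=(0.1,), height=0.01))
        r1, r2 = base.spawn(), base.spawn()
        r1.add_hill(Hill(centers=(-0.5,), widths=(0.1,), height=0.008))
        r2.add_hill(Hill(centers=(0.5,), widths=(0.1,), height=0.008))
        avg = average_biases([r1, r2])
        assert avg.energy([0.0]) >= 0.01  # full-height inherited hill
        grid = np.linspace(-1.5, 1.5, 61)
        expected = (base.energy_grid(grid)
                    + 0.5 * 0.008 * np.exp(-0.5 * ((grid + 0.5) / 0.1) ** 2)
                    + 0.5 * 0.008 * np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2))
        np.testing.assert_allclose(avg.energy_grid(grid), expected,
                                   atol=1e-15)

    def test_permutation_invariance(self):
        base = make_bias()
        runs = []
        for c in (-0.6, 0.0, 0.6):
            r = base.spawn()
            r.add_hill(Hill(centers=(c,), widths=(0.1,), height=0.01))
            runs.append(r)
        grid = np.linspace(-1, 1, 31)
        a = average_biases(runs).energy_grid(grid)
        b = average_biases(runs[::-1]).energy_grid(grid)
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError):
            average_biases([make_bias(gamma=15), make_bias(gamma=50)])


class TestSelectRestart:
    def test_zero_bias_returns_lowest_energy(self, double_well):
        ds = Dataset()
        for x in (-1.0, -0.5, 0.9):
            ds.append(double_well.label(double_well.make_configuration((x,))))
        b = make_bias()
        chosen = select_restart(ds, b, b.cvs)
        assert chosen.positions[0, 0] == pytest.approx(-1.0)

    def test_hill_on_minimum_redirects_restart(self, double_well):
        ds = Dataset()
        for x in (-1.0, 0.9):
            ds.append(double_well.label(double_well.make_configuration((x,))))
        b = make_bias()
        b.add_hill(Hill(centers=(-1.0,), widths=(0.1,), height=5.0))
        chosen = select_restart(ds, b, b.cvs)
        assert chosen.positions[0, 0] == pytest.approx(0.9)

    def test_single_item(self, double_well):
        ds = Dataset([double_well.label(double_well.make_configuration((0.3,)))])
        assert select_restart(ds, make_bias(), None).positions[0, 0] == \
            pytest.approx(0.3)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            select_restart(Dataset(), make_bias(), None)


class TestFesFromBias:
    def test_zero_bias_flat_zero(self):
        f = fes_from_bias(make_bias(), np.linspace(-1, 1, 11))
        np.testing.assert_array_equal(f.F, 0.0)

    def test_large_gamma_limit_is_negative_bias(self):
        b = make_bias(gamma=1e9)
        b.add_hill(Hill(centers=(0.0,), widths=(0.2,), height=0.05))
        grid = np.linspace(-1, 1, 41)
        f = fes_from_bias(b, grid)
        v = b.energy_grid(grid)
        np.testing.assert_allclose(f.F, -(v - v.max()), rtol=1e-6)

    def test_prefactor(self):
        b = make_bias(gamma=15)
        b.add_hill(Hill(centers=(0.0,), widths=(0.2,), height=0.05))
        grid = np.linspace(-1, 1, 41)
        f = fes_from_bias(b, grid)
        v = b.energy_grid(grid)
        expected = -(15 / 14) * v
        np.testing.assert_allclose(f.F, expected - expected.min(), rtol=1e-9)


class TestHillsIO:
    def test_roundtrip_bias_energy(self, tmp_path):
        rng = np.random.default_rng(2)
        b = make_bias(h0=0.013, gamma=50, T=298, tau=25)
        for _ in range(3):
            b.add_hill(Hill(centers=(rng.uniform(-1, 1),), widths=(0.1,),
                            height=rng.uniform(0.005, 0.013),
                            time=rng.uniform(0, 100)))
        path = tmp_path / "HILLS"
        write_hills(b, path)
        back = read_hills(path)
        assert back.gamma == b.gamma
        assert back.h0 == b.h0
        assert back.T == b.T
        grid = np.linspace(-1.5, 1.5, 101)
        np.testing.assert_allclose(back.energy_grid(grid),
                                   b.energy_grid(grid), rtol=1e-12,
                                   atol=1e-18)

    def test_empty_bias_header_only(self, tmp_path):
        path = tmp_path / "HILLS"
        write_hills(make_bias(), path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert all(l.startswith("#!") for l in lines)
        assert read_hills(path).n_hills == 0

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("#! FIELDS time x sigma_x height biasf\n"
                        "0.0 0.1 0.1 0.01 15.0\n"
                        "bad line\n")
        with pytest.raises(ValueError, match="line 3"):
            read_hills(path)
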