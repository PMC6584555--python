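"""Scalar contractions, synthetic signal generators, SA/SR statistics, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plateletuq as pq
from plateletuq.stress_signals import TENSOR_COMPONENTS


def tensor(times, **comps):
    arr = np.zeros((len(times), 6))
    for k, v in comps.items():
        arr[:, TENSOR_COMPONENTS.index(k)] = v
    return pq.TensorStressHistory(np.asarray(times, float), arr)


class TestContraction:
    times = [0.0, 1.0]

    @pytest.mark.parametrize(
        "comps, variant, expected",
        [
            ({"xy": 100.0}, "a", 100.0),            # calibration-device loading
            ({"xy": 100.0}, "b", np.sqrt(2 / 3) * 100),
            ({"xy": 100.0}, "c", 0.0),
            ({"xy": 100.0}, "b_single", 100 / np.sqrt(3)),
            ({"xx": 100.0, "yy": 100.0, "zz": 100.0}, "a", 0.0),
            ({"xx": 100.0, "yy": 100.0, "zz": 100.0}, "b", 0.0),
            ({"xx": 100.0, "yy": 100.0, "zz": 100.0}, "c", 100.0),
        ],
    )
    def test_reference_states(self, comps, variant, expected):
        h = pq.contract_tensor(tensor(self.times, **comps), variant)
        assert h.tau == pytest.approx(expected, abs=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            pq.contract_tensor(tensor(self.times, xy=1.0), "z")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        comps=st.lists(st.floats(-500, 500), min_size=6, max_size=6),
        k=st.floats(0, 50),
        variant=st.sampled_from(["a", "b", "c"]),
    )
    def test_nonnegative_and_positively_homogeneous(self, comps, k, variant):
        t = np.array([0.0, 1.0])
        base = pq.TensorStressHistory(t, np.tile(comps, (2, 1)))
        scaled = pq.TensorStressHistory(t, k * np.tile(comps, (2, 1)))
        tau0 = pq.contract_tensor(base, variant).tau
        tauk = pq.contract_tensor(scaled, variant).tau
        assert np.all(tau0 >= 0)
        assert tauk == pytest.approx(k * tau0, rel=1e-12, abs=1e-9)

    def test_block_independence(self):
        """τ_c ignores the shear block; τ_b ignores the normal block."""
        shear = {"xy": 30.0, "xz": -20.0, "yz": 5.0}
        normal = {"xx": 80.0, "yy": -10.0, "zz": -70.0}
        both = {**shear, **normal}
        for variant, invariant_block in (("c", normal), ("b", shear)):
            a = pq.contract_tensor(tensor(self.times, **invariant_block), variant).tau
            b = pq.contract_tensor(tensor(self.times, **both), variant).tau
            assert b == pytest.approx(a, rel=1e-12)


class TestUniformGenerator:
    def test_constant_signal(self):
        h = pq.generate_uniform_stress(500, 0.0, duration=1.0, dt=1e-4)
        assert np.all(h.tau == 500.0)
        assert h.times[0] == 0.0 and h.times[-1] == pytest.approx(1.0)

    def test_sine_bounds(self):
        h = pq.generate_uniform_stress(2e4, 0.1, freq=50, duration=1.0, dt=1e-4)
        assert h.tau.min() == pytest.approx(1.8e4, rel=1e-3)
        assert h.tau.max() == pytest.approx(2.2e4, rel=1e-3)

    def test_mean_over_integer_periods(self):
        h = pq.generate_uniform_stress(2e4, 0.1, freq=50, duration=1.0, dt=1e-4)
        # trapezoidal mean over 50 full periods
        mean = np.trapezoid(h.tau, h.times) / h.residence_time
        assert mean == pytest.approx(2e4, rel=1e-4)

    def test_full_modulation_rejected(self):
        with pytest.raises(ValueError, match="amp_frac"):
            pq.generate_uniform_stress(500, 1.0)


class TestPumpLikeGenerator:
    def test_two_order_region_jump(self):
        h = pq.generate_pump_like_stress([(0.7, 10.0), (0.4, 1000.0)], dt=1e-3)
        early = h.tau[h.times < 0.7]
        late = h.tau[(h.times >= 0.7) & (h.times < 1.1)]
        assert late.mean() / early.mean() == pytest.approx(100.0, rel=1e-9)

    def test_seed_determinism(self):
        sched = [(0.1, 100.0, 0.3, 500.0), (0.1, 800.0, 0.2, 300.0)]
        h1 = pq.generate_pump_like_stress(sched, dt=1e-4, seed=42)
        h2 = pq.generate_pump_like_stress(sched, dt=1e-4, seed=42)
        h3 = pq.generate_pump_like_stress(sched, dt=1e-4, seed=43)
        assert np.array_equal(h1.tau, h2.tau)
        assert not np.array_equal(h1.tau, h3.tau)

    def test_zero_fluctuation_is_piecewise_constant(self):
        h = pq.generate_pump_like_stress([(0.1, 50.0, 0.0, 100.0)], dt=1e-3, seed=1)
        assert np.all(h.tau == 50.0)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="schedule"):
            pq.generate_pump_like_stress([])

    def test_fluctuation_amplitude_and_nonnegativity(self):
        h = pq.generate_pump_like_stress([(0.5, 100.0, 0.3, 400.0)], dt=1e-4, seed=7)
        assert np.all(h.tau >= 0)
        assert h.tau.std() == pytest.approx(30.0, rel=0.15)


class TestStressStatistics:
    def test_sa_constant(self):
        h = pq.generate_uniform_stress(500, 0.0, duration=1.0, dt=1e-4)
        sa, H = pq.stress_accumulation(h)
        assert sa == pytest.approx(500.0, rel=1e-12)
        assert H[0] == 0.0
        assert np.all(np.diff(H) >= 0)

    def test_sa_two_samples(self):
        h = pq.ScalarStressHistory(np.array([0.0, 0.1]), np.array([100.0, 300.0]))
        sa, _ = pq.stress_accumulation(h)
        assert sa == pytest.approx(20.0)

    def test_sa_linear_ramp(self):
        t = np.linspace(0, 1, 2001)
        h = pq.ScalarStressHistory(t, t.copy())
        sa, _ = pq.stress_accumulation(h)
        assert sa == pytest.approx(0.5, rel=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(refine=st.integers(1, 6))
    def test_sa_invariant_under_refinement_of_piecewise_linear(self, refine):
        t = np.array([0.0, 0.3, 0.7, 1.0])
        tau = np.array([10.0, 200.0, 50.0, 120.0])
        fine_t = np.unique(np.concatenate(
            [np.linspace(t[i], t[i + 1], refine + 1) for i in range(3)]))
        fine = np.interp(fine_t, t, tau)
        sa_coarse, _ = pq.stress_accumulation(pq.ScalarStressHistory(t, tau))
        sa_fine, _ = pq.stress_accumulation(pq.ScalarStressHistory(fine_t, fine))
        assert sa_fine == pytest.approx(sa_coarse, rel=1e-12)

    def test_sr_constant_is_zero(self):
        h = pq.generate_uniform_stress(500, 0.0, duration=0.1, dt=1e-3)
        sr, _ = pq.stress_rate(h)
        assert sr == 0.0

    def test_sr_two_samples(self):
        h = pq.ScalarStressHistory(np.array([0.0, 0.1]), np.array([100.0, 300.0]))
        sr, _ = pq.stress_rate(h)
        assert sr == pytest.approx(2000.0)

    def test_sr_sinusoid_matches_mean_abs_derivative(self):
        # τ = 2e4·(1 + 0.1 sin(2π·50 t)) → SR → (2/π)·2000·2π·50 = 4e5
        h = pq.generate_uniform_stress(2e4, 0.1, freq=50, duration=1.0, dt=1e-4)
        sr, _ = pq.stress_rate(h)
        assert sr == pytest.approx(4e5, rel=0.01)

    def test_sr_cumulative_mean_final_matches_scalar(self):
        h = pq.generate_uniform_stress(2e4, 0.1, freq=50, duration=0.1, dt=1e-4)
        sr_final, _ = pq.stress_rate(h, "final_mean")
        sr_cum, series = pq.stress_rate(h, "cumulative_mean")
        assert sr_cum == pytest.approx(sr_final, rel=1e-12)
        assert series[0] == 0.0

    def test_summary_fields(self):
        h = pq.generate_uniform_stress(500, 0.0, duration=1.0, dt=1e-3)
        s = pq.summarize_stress(h)
        assert s.sa == pytest.approx(500.0)
        assert s.sr == 0.0
        assert s.residence_time == pytest.approx(1.0)
        assert s.tau_min == s.tau_max == 500.0


class TestValidation:
    def test_negative_stress_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            pq.ScalarStressHistory(np.array([0.0, 1.0]), np.array([-1.0, 1.0]))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pq.ScalarStressHistory(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pq.ScalarStressHistory(np.array([0.0]), np.array([1.0]))


class TestIO:
    def test_scalar_round_trip(self, tmp_path):
        h = pq.generate_uniform_stress(2e4, 0.1, duration=0.01, dt=1e-4)
        f = tmp_path / "h.csv"
        pq.write_stress_history(h, f, seed=3)
        back = pq.read_stress_history(f)
        np.testing.assert_allclose(back.tau, h.tau, rtol=1e-9)
        np.testing.assert_allclose(back.times, h.times, rtol=1e-9)

    def test_tensor_round_trip(self, tmp_path, shear_tensor):
        f = tmp_path / "t.csv"
        pq.write_stress_history(shear_tensor, f)
        back = pq.read_stress_history(f)
        assert isinstance(back, pq.TensorStressHistory)
        np.testing.assert_allclose(back.components, shear_tensor.components, rtol=1e-9)

    def test_pa_units_converted_on_read(self, tmp_path):
        f = tmp_path / "pa.csv"
        f.write_text("# units: Pa\ntime,tau\n0.0,50\n1.0,50\n")
        h = pq.read_stress_history(f)
        assert np.all(h.tau == 500.0)

    def test_single_row_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("time,tau\n0.0,50\n")
        with pytest.raises(ValueError, match="2 samples"):
            pq.read_stress_history(f)

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("time,sigma\n0.0,50\n1.0,50\n")
        with pytest.raises(ValueError, match="columns"):
            pq.read_stress_history(f)
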