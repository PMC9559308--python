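"""Unit and property tests for flow-follower trace processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyncompart.profiles import Profile
from dyncompart.synthetic import piecewise_speed_spec, simulate_flow_follower
from dyncompart.traces import (
    AxialKinematics,
    ReactorGeometry,
    SensorTrace,
    axial_velocity,
    baseline_pressure,
    estimate_gas_holdup,
    fluid_density,
    pressure_to_position,
    process_device,
    read_kinematics_csv,
    read_traces_csv,
    write_kinematics_csv,
    write_traces_csv,
)

G = 9.81


def make_trace(t, P, T=306.0, rho_p=950.0, device="d0"):
    return SensorTrace(device, t, P, np.full_like(np.asarray(t, float), T), rho_p)


class TestGasHoldup:
    @pytest.mark.parametrize(
        "v_s, D, expected",
        [
            (0.0, 5.3, 0.0),
            (0.215, 5.3, 0.1712),  # direct evaluation of the correlation
            (0.1, 5.3, 0.0971),
        ],
    )
    def test_values(self, v_s, D, expected):
        assert estimate_gas_holdup(v_s, D) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_gas_velocity(self):
        v = np.linspace(0.0, 0.5, 200)
        eps = estimate_gas_holdup(v, 5.3)
        assert np.all(np.diff(eps) > 0)
        assert np.all((eps >= 0) & (eps < 1))

    @pytest.mark.parametrize("bad", [dict(v_s=-0.1, D=5.3), dict(v_s=0.1, D=0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            estimate_gas_holdup(**bad)


class TestFluidDensity:
    def test_ungassed_limit(self):
        assert fluid_density(0.0, 1030.0, 1.2) == 1030.0

    def test_all_gas_limit(self):
        assert fluid_density(1 - 1e-12, 1030.0, 1.2) == pytest.approx(1.2, abs=1e-6)

    def test_example(self):
        assert fluid_density(0.171, 1030.0, 1.2) == pytest.approx(854.0, abs=0.1)

    @settings(max_examples=50, derandomize=True)
    @given(eps=st.floats(0.0, 0.999))
    def test_convex_combination(self, eps):
        rho = fluid_density(eps, 1030.0, 1.2)
        assert 1.2 <= rho <= 1030.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fluid_density(1.0)


class TestBaselinePressure:
    def test_constant_input(self):
        t = np.arange(0.0, 7200.0)
        tr = make_trace(t, np.full(t.size, 2e5))
        base = baseline_pressure(tr)
        assert np.allclose(base, 2e5)

    def test_periodic_signal_tracks_envelope_maximum(self):
        # triangle wave, period 60 s << 1 hr window -> baseline = max
        t = np.arange(0.0, 3 * 3600.0)
        tri = 1e5 + 2e5 * np.abs((t / 60.0) % 2 - 1)
        base = baseline_pressure(make_trace(t, tri))
        interior = slice(2000, -2000)
        assert np.allclose(base[interior], 3e5, rtol=1e-6)

    def test_rising_envelope_tracked_with_bounded_lag(self):
        t = np.arange(0.0, 4 * 3600.0)
        rate = 5.0  # Pa/s volume-growth ramp
        tri = 2e5 + rate * t + 1e4 * np.abs((t / 60.0) % 2 - 1)
        base = baseline_pressure(make_trace(t, tri))
        envelope = 2e5 + rate * t + 1e4
        interior = slice(3600, -3600)
        lag_seconds = np.abs(base[interior] - envelope[interior]) / rate
        assert lag_seconds.max() <= 3600.0

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 600.0)
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            baseline_pressure(make_trace(t, np.full(t.size, 2e5)))


class TestPressureToPosition:
    def test_bottom(self):
        assert pressure_to_position(2e5, 2e5, 900.0) == 0.0

    def test_ten_metres(self):
        assert pressure_to_position(2e5 - 88290.0, 2e5, 900.0) == pytest.approx(10.0)

    def test_midpoint(self):
        H = 20.0
        P_max = 3e5
        P = P_max - 0.5 * 900.0 * G * H
        assert pressure_to_position(P, P_max, 900.0) == pytest.approx(H / 2)

    def test_clipping(self):
        assert pressure_to_position(2e5 + 500.0, 2e5, 900.0) == 0.0
        assert pressure_to_position(1e5, 3e5, 900.0, H_L=16.0) == 16.0

    def test_bad_density(self):
        with pytest.raises(ValueError):
            pressure_to_position(1e5, 2e5, 0.0)


class TestAxialVelocity:
    def test_constant_and_ramp(self):
        t = np.arange(100.0)
        assert np.allclose(axial_velocity(t, np.full(100, 3.0)), 0.0)
        assert np.allclose(axial_velocity(t, 0.2 * t, smooth_window=0), 0.2)

    def test_sine_truncation_error(self):
        # second-order central differences: error O(omega^2 dt^2)
        t = np.arange(0.0, 600.0)
        A, om = 5.0, 2 * np.pi / 120.0
        v = axial_velocity(t, A * np.sin(om * t), smooth_window=0)
        err = np.abs(v[2:-2] - A * om * np.cos(om * t[2:-2]))
        assert err.max() < A * om**3 / 6 * 1.5  # 1.5x analytic bound

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            axial_velocity(np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(4))


class TestProcessDevice:
    def geom(self, H=18.0):
        return ReactorGeometry(D=5.3, H_total=H)

    def synthetic_trace(self, z, H_L=16.0, rho=1030.0, p_head=1.2e5):
        t = np.arange(z.size, dtype=float)
        P = p_head + rho * G * (H_L - z)
        return make_trace(t, P)

    def bouncing_z(self, n, H_L=16.0, speed=0.5):
        # deterministic triangular trajectory bottom <-> top
        t = np.arange(n, dtype=float)
        period = 2 * H_L / speed
        return H_L * np.abs((t / (period / 2)) % 2 - 1)

    def test_zero_gas_flow_gives_liquid_density(self):
        z = self.bouncing_z(3 * 3600)
        tr = self.synthetic_trace(z)
        dev = process_device(tr, self.geom(), Profile.constant(0.0))
        assert np.all(dev.eps == 0)
        assert np.allclose(dev.rho_f, 1030.0)
        interior = slice(1800, -1800)
        assert np.abs(dev.kin.z[interior] - z[interior]).max() < 0.02 * 16.0

    def test_slow_headspace_drift_absorbed_by_baseline(self):
        z = self.bouncing_z(4 * 3600)
        t = np.arange(z.size, dtype=float)
        tr0 = self.synthetic_trace(z)
        # slowly varying positive offset (realistic headspace fluctuation),
        # period >> 2 x rolling window
        offset = 5e3 * 0.5 * (1 + np.sin(2 * np.pi * t / (12 * 3600.0)))
        tr1 = make_trace(t, tr0.P + offset)
        k0 = process_device(tr0, self.geom(), Profile.constant(0.0)).kin
        k1 = process_device(tr1, self.geom(), Profile.constant(0.0)).kin
        interior = slice(1800, -1800)
        rms = np.sqrt(np.mean((k1.z[interior] - k0.z[interior]) ** 2))
        assert rms < 0.01 * 16.0

    def test_headspace_step_absorbed_away_from_transition(self):
        z = self.bouncing_z(4 * 3600)
        t = np.arange(z.size, dtype=float)
        tr0 = self.synthetic_trace(z)
        step_at = t.size // 2
        tr1 = make_trace(t, tr0.P + np.where(t >= step_at, 2.1e4, 0.0))
        k0 = process_device(tr0, self.geom(), Profile.constant(0.0)).kin
        k1 = process_device(tr1, self.geom(), Profile.constant(0.0)).kin
        far = np.abs(t - step_at) > 3600.0
        far[:1800] = far[-1800:] = False
        assert np.abs(k1.z[far] - k0.z[far]).max() < 0.01 * 16.0

    def test_round_trip_piecewise_field(self):
        # noise-free walk through a prescribed field: recovered z within 1% RMS
        spec = piecewise_speed_spec([(5.0, 0.35), (11.0, 0.9), (16.0, 0.45)])
        trace, truth = simulate_flow_follower(spec, noise_sigma=0.0, seed=5, duration=3 * 3600.0)
        dev = process_device(trace, spec.geometry, spec.gas)
        interior = (trace.t > 1800) & (trace.t < trace.t[-1] - 1800)
        rms = np.sqrt(np.mean((dev.kin.z[interior] - truth.z[interior]) ** 2))
        assert rms < 0.01 * 16.0


class TestTraceIO:
    def test_csv_round_trips(self, tmp_path):
        t = np.arange(0.0, 100.0)
        traces = [
            make_trace(t, 2e5 + 100 * np.sin(t / 7), device="a"),
            make_trace(t, 2.2e5 + np.cos(t / 5), rho_p=900.0, device="b"),
        ]
        p = tmp_path / "traces.csv"
        write_traces_csv(p, traces)
        back = read_traces_csv(p)
        assert [tr.device_id for tr in back] == ["a", "b"]
        assert np.allclose(back[0].P, traces[0].P)
        assert back[1].rho_p == 900.0

        kins = [AxialKinematics("a", t, np.abs(np.sin(t / 9)), np.cos(t / 9))]
        pk = tmp_path / "kin.csv"
        write_kinematics_csv(pk, kins)
        back_k = read_kinematics_csv(pk)
        assert np.allclose(back_k[0].v_z, kins[0].v_z)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("device_id,t_s\na,0\na,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_traces_csv(p)


class TestTraceValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            make_trace(np.array([0.0, 0.0, 1.0]), np.full(3, 1e5))
        with pytest.raises(ValueError):
            make_trace(np.array([0.0, 1.0]), np.array([1e5, -1.0]))
        with pytest.raises(ValueError):
            make_trace(np.array([0.0]), np.array([1e5]))
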