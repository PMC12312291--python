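import numpy as np
import pytest

from oscifluor import (
    LightProtocol,
    ModelState,
    calibrate,
    dark_adapted_state,
    o2_rate,
    atp_rate_per_synthase,
    periodic_steady,
    simulate,
    steady_state,
)
from oscifluor.model import electron_flux_psii, ode_rhs, pq_reoxidation_flux
from oscifluor.simulate import SimulationTrace
from oscifluor.fluorescence import quench_factor


class TestSteadyState:
    def test_residual_norm_below_tolerance(self, wt):
        st = steady_state(1000.0, wt)
        d = ode_rhs(0.0, st.as_array(), 1000.0, wt)
        scale = np.array([wt.PQ_tot, 1, 1, wt.A_tot, 1, 1])
        assert np.max(np.abs(d) / scale) < 1e-8

    def test_electron_flux_balance_at_fixed_point(self, wt):
        st = steady_state(1000.0, wt)
        j2 = electron_flux_psii(st, 1000.0, wt)
        jbf = pq_reoxidation_flux(st, wt)
        assert abs(j2 - jbf) / j2 < 1e-6

    def test_dark_fixed_point_has_relaxed_quenchers(self, wt):
        st = steady_state(0.0, wt)
        assert st.Zea == pytest.approx(0.0, abs=2e-3)
        assert st.PsbS_act == pytest.approx(0.0, abs=2e-3)
        assert st.PQ_ox == wt.PQ_tot
        assert o2_rate(st, 0.0, wt) == pytest.approx(0.0, abs=1e-9)
        assert abs(atp_rate_per_synthase(st, wt)) < 1.0

    def test_npq4_fixed_point_fluoresces_more_than_wt(self, wt):
        from oscifluor import chlf, genotype_preset, rcii_closed

        npq4 = genotype_preset("npq4")
        f = {}
        for name, p in (("WT", wt), ("npq4", npq4)):
            st = steady_state(1000.0, p)
            q = quench_factor(st.Zea, st.PsbS_act, p)
            f[name] = chlf(rcii_closed(st, 1000.0, p), q, p)
        assert f["npq4"] > f["WT"]

    def test_negative_light_rejected(self, wt):
        with pytest.raises(ValueError):
            steady_state(-1.0, wt)


class TestRates:
    def test_o2_is_electron_flux_over_four(self, wt):
        st = steady_state(700.0, wt)
        assert o2_rate(st, 700.0, wt) == pytest.approx(
            electron_flux_psii(st, 700.0, wt) / 4.0
        )

    def test_atp_per_synthase_is_twice_per_psii(self, wt):
        from oscifluor.model import rate_v5

        st = steady_state(700.0, wt)
        assert atp_rate_per_synthase(st, wt) == pytest.approx(2.0 * rate_v5(st, wt))


class TestSimulate:
    def test_constant_light_converges_to_steady_state(self, wt):
        proto = LightProtocol(u_min=100, u_max=800, segments=[],
                              pre_illum=(4000.0, 450.0))
        tr = simulate(proto, wt)
        target = steady_state(450.0, wt).as_array()
        final = np.array([tr.PQ_ox[-1], tr.PI_ox[-1], tr.H_L[-1],
                          tr.ATP[-1], tr.Zea[-1], tr.PsbS_act[-1]])
        np.testing.assert_allclose(final, target, rtol=2e-3, atol=2e-3)

    def test_identical_inputs_give_bitwise_identical_traces(self, wt):
        proto = LightProtocol(u_min=100, u_max=400, segments=[(5.0, 3)],
                              pre_illum=(30.0, 250.0), quantization=22)
        a = simulate(proto, wt)
        b = simulate(proto, wt)
        np.testing.assert_array_equal(a.ChlF, b.ChlF)
        np.testing.assert_array_equal(a.H_L, b.H_L)

    def test_states_stay_within_bounds_over_random_protocols(self, wt):
        rng = np.random.default_rng(17)
        for _ in range(3):
            T = float(rng.choice([2.0, 7.0, 31.0]))
            u1 = float(rng.uniform(50, 650))
            proto = LightProtocol(u_min=100, u_max=100 + u1,
                                  segments=[(T, 2)],
                                  pre_illum=(20.0, 100 + u1 / 2))
            tr = simulate(proto, wt)
            assert np.all(tr.PQ_ox >= 0) and np.all(tr.PQ_ox <= wt.PQ_tot)
            assert np.all(tr.PI_ox >= 0) and np.all(tr.PI_ox <= 1)
            assert np.all(tr.H_L > 0)
            assert np.all(tr.ATP >= 0) and np.all(tr.ATP <= wt.A_tot)
            assert np.all((tr.Zea >= 0) & (tr.Zea <= 1))
            assert np.all((tr.PsbS_act >= 0) & (tr.PsbS_act <= 1))
            assert np.all((tr.ChlF > 0) & (tr.ChlF <= 1))

    def test_trace_grid_and_labels(self, wt):
        proto = LightProtocol(u_min=100, u_max=200, segments=[(5.0, 2)],
                              pre_illum=(10.0, 150.0))
        tr = simulate(proto, wt)
        assert np.allclose(np.diff(tr.time), 0.1)
        assert set(tr.segment) == {"pre", "T5"}
        assert tr.cycle[tr.segment == "pre"].max() == 0
        assert tr.cycle[tr.segment == "T5"].max() == 2

    def test_csv_round_trip(self, wt, tmp_path):
        import json
        import pandas as pd

        proto = LightProtocol(u_min=100, u_max=200, segments=[(5.0, 2)],
                              pre_illum=(5.0, 150.0))
        tr = simulate(proto, wt)
        tr.to_csv(tmp_path / "t.csv", metadata_path=tmp_path / "t.json")
        df = pd.read_csv(tmp_path / "t.csv")
        assert len(df) == tr.time.size
        meta = json.loads((tmp_path / "t.json").read_text())
        assert meta["parameters"]["k1_plus"] == 250.0
        assert meta["protocol"]["u_max"] == 200


class TestPeriodicSteady:
    def fake(self, chlf_by_cycle, T=10.0, dt=0.1):
        ncyc = len(chlf_by_cycle)
        n = int(T / dt)
        t = np.arange(n * ncyc) * dt
        chlf = np.concatenate(chlf_by_cycle)
        return SimulationTrace(
            time=t, light=np.ones(n * ncyc), PQ_ox=None, PI_ox=None, H_L=None,
            ATP=None, Zea=None, PsbS_act=None, RCII_closed=None, ChlF=chlf,
            NPQ=None, segment=np.full(n * ncyc, "T10", dtype=object),
            cycle=(t // T).astype(int) + 1,
        )

    def test_strictly_periodic_trace_gives_zero(self):
        base = 0.4 + 0.1 * np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        tr = self.fake([base] * 4)
        assert np.all(periodic_steady(tr, "T10") == 0.0)

    def test_constant_offset_drift_gives_rms_equal_to_drift(self):
        base = 0.4 + 0.1 * np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        d = 0.013
        tr = self.fake([base + i * d for i in range(4)])
        np.testing.assert_allclose(periodic_steady(tr, "T10"), d, rtol=1e-12)

    def test_fewer_than_two_cycles_is_an_error(self):
        base = np.full(100, 0.4)
        tr = self.fake([base])
        with pytest.raises(ValueError):
            periodic_steady(tr, "T10")


class TestFrequencyResponse:
    @staticmethod
    def loop_fit(wt, T, ncyc, u1):
        from oscifluor import extract_loop, fit_harmonics

        proto = LightProtocol(u_min=450 - u1, u_max=450 + u1,
                              segments=[(float(T), ncyc)],
                              pre_illum=(600.0, 450.0))
        tr = simulate(proto, wt)
        loop = extract_loop(tr, f"T{T:g}")
        return fit_harmonics(loop.phase * loop.T, loop.chlf, loop.T)

    def test_low_pass_attenuation_of_the_fundamental(self, wt):
        """The fluorescence response behaves like an RC low-pass filter:
        the first-harmonic amplitude at T = 1 s is below that at T = 10 s
        for the same forcing amplitude."""
        a1_fast = self.loop_fit(wt, 1, 10, 350.0).amplitudes[0]
        a1_slow = self.loop_fit(wt, 10, 5, 350.0).amplitudes[0]
        assert a1_fast < a1_slow

    def test_higher_harmonics_vanish_quadratically_for_small_amplitudes(self, wt):
        """Halving a small forcing amplitude must cut the 2nd harmonic by
        ~4x (quadratic leading nonlinearity); 3rd/4th harmonics stay at
        least an order of magnitude below the 2nd."""
        full = self.loop_fit(wt, 10, 5, 50.0)
        half = self.loop_fit(wt, 10, 5, 25.0)
        assert half.amplitudes[1] <= 0.35 * full.amplitudes[1]
        assert full.amplitudes[2] < 0.1 * full.amplitudes[1]
        assert full.amplitudes[3] < 0.1 * full.amplitudes[1]


class TestCalibrate:
    def test_recalibrating_shipped_defaults_is_a_noop(self, wt):
        out = calibrate(wt)
        for f in ("sigma_II", "k2", "k5", "beta_H"):
            assert getattr(out, f) == pytest.approx(getattr(wt, f), rel=1e-6)

    def test_shipped_defaults_place_lumen_H_around_quencher_activation(self, wt):
        assert steady_state(1000.0, wt).H_L > wt.KQ_PsbS
        assert 0.15 <= steady_state(100.0, wt).H_L <= 1.0
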