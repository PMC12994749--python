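"""Stochastic linker/cortex kinetics, oscillation signal, bleb detection."""

import numpy as np
import pytest

from blebsim import kinetics as kin
from blebsim import structures as st


@pytest.fixture()
def rates():
    return kin.KineticRates()


class TestBellLaw:
    def test_zero_force_gives_base_rate(self, rates):
        assert kin.linker_dissociation_rate(0.0, rates) == rates.k_off0

    def test_force_fb_ln2_doubles_rate(self, rates):
        f = rates.F_b * np.log(2.0)
        assert kin.linker_dissociation_rate(f, rates) == pytest.approx(
            2.0 * rates.k_off0)

    @pytest.mark.parametrize("f", [0.5, 1.7, 4.0])
    def test_doubling_force_multiplies_by_exp_f_over_fb(self, rates, f):
        k1 = kin.linker_dissociation_rate(f, rates)
        k2 = kin.linker_dissociation_rate(2 * f, rates)
        assert k2 / k1 == pytest.approx(np.exp(f / rates.F_b))

    def test_compressed_linkers_use_zero_force(self, rates):
        assert kin.linker_dissociation_rate(-3.0, rates) == rates.k_off0


class TestLinkerSampling:
    def test_modulated_rate_at_pi_over_two(self, rates):
        # k_on_eff = 1.2 k_adh_on at theta = pi/2 (amplitude 0.2)
        lnk = st.LinkerEnsemble(bound=np.zeros(1), site_capacity=1e6)
        theta = np.array([np.pi / 2])
        dt = 1e-3
        kin.sample_linker_kinetics(lnk, np.zeros(1), rates, theta, None, dt,
                                   modulate=True)
        expect = 1.2 * rates.k_adh_on * 1e6 * dt
        assert lnk.bound[0] == pytest.approx(expect)

    def test_zero_rates_leave_state_unchanged(self):
        zero = kin.KineticRates(k_adh_on=0.0, k_off0=0.0)
        lnk = st.LinkerEnsemble(bound=np.full(8, 5.0))
        rng = np.random.default_rng(0)
        kin.sample_linker_kinetics(lnk, np.ones(8), zero, np.zeros(8), rng, 1e-2)
        assert np.all(lnk.bound == 5.0)

    def test_stationary_occupancy_matches_two_state_markov(self):
        # bound fraction -> k_on/(k_on + k_off) at fixed force
        rates = kin.KineticRates(k_adh_on=2.0, k_off0=1.0, F_b=1.0)
        force = 1.0 * np.log(2.0)          # k_off = 2 -> occupancy 1/2
        n_nodes, cap = 400, 10.0
        lnk = st.LinkerEnsemble(bound=np.full(n_nodes, 5.0), site_capacity=cap)
        rng = np.random.default_rng(42)
        dt = 0.02
        samples = []
        for i in range(4000):
            kin.sample_linker_kinetics(lnk, np.full(n_nodes, force), rates,
                                       np.zeros(n_nodes), rng, dt)
            if i > 1000 and i % 25 == 0:
                samples.append(lnk.bound.mean() / cap)
        mean = np.mean(samples)
        se = np.std(samples) / np.sqrt(len(samples))
        assert abs(mean - 0.5) < 3 * max(se, 0.005)

    def test_counts_stay_in_range_and_reproducible(self):
        rates = kin.KineticRates(k_adh_on=5.0, k_off0=2.0)
        out = []
        for _ in range(2):
            lnk = st.LinkerEnsemble(bound=np.full(32, 10.0))
            rng = np.random.default_rng(123)
            for _ in range(200):
                kin.sample_linker_kinetics(lnk, np.ones(32), rates,
                                           np.zeros(32), rng, 1e-2)
                assert np.all(lnk.bound >= 0)
                assert np.all(lnk.bound <= lnk.site_capacity)
            out.append(lnk.bound.copy())
        assert np.array_equal(out[0], out[1])


class TestCortexTurnover:
    def _setup(self, n=64):
        cortex = st.CortexState.circle(n, 9.8, (40.0, 40.0))
        membrane = st.MembraneState.circle(n, 10.0, (40.0, 40.0))
        return cortex, membrane

    def test_detached_decay_is_first_order_with_no_assembly(self):
        cortex, membrane = self._setup()
        rates = kin.KineticRates(k_act_decay=2.0)
        detach_time = np.full(64, np.inf)
        attached = np.zeros(64, dtype=bool)
        rng = np.random.default_rng(1)
        n0 = cortex.n_act.copy()
        t, dt = 0.0, 1e-2
        prev = cortex.n_act.copy()
        for _ in range(100):
            kin.update_cortex_turnover(cortex, membrane, attached, detach_time,
                                       rates, rng, dt, t)
            assert np.all(cortex.n_act <= prev)     # no upward transitions
            prev = cortex.n_act.copy()
            t += dt
        expect = n0 * np.exp(-rates.k_act_decay * t)
        assert cortex.n_act.mean() == pytest.approx(expect.mean(), rel=0.05)

    def test_zero_rates_leave_cortex_unchanged(self):
        cortex, membrane = self._setup()
        rates = kin.KineticRates(k_act_on=0.0, k_act_off=0.0, k_myo_on=0.0,
                                 k_myo_off=0.0)
        before = cortex.n_act.copy()
        kin.update_cortex_turnover(cortex, membrane, np.ones(64, bool),
                                   np.full(64, np.inf), rates,
                                   np.random.default_rng(0), 1e-2, 0.0)
        assert np.array_equal(cortex.n_act, before)

    def test_attached_stationary_mean_is_reference_level(self):
        cortex, membrane = self._setup(n=200)
        cortex.n_act_bar = 50.0
        cortex.n_act[:] = 50.0
        rates = kin.KineticRates(k_act_on=4.0, k_act_off=4.0)
        rng = np.random.default_rng(7)
        attached = np.ones(200, dtype=bool)
        detach_time = np.full(200, np.inf)
        means = []
        t = 0.0
        dt = 5e-3
        for i in range(4000):
            kin.update_cortex_turnover(cortex, membrane, attached, detach_time,
                                       rates, rng, dt, t)
            t += dt
            if i > 500 and i % 100 == 0:   # ~2 correlation times apart
                means.append(cortex.n_act.mean())
        mean = np.mean(means)
        se = np.std(means) / np.sqrt(len(means))
        # exact stationary mean of the tau-leaped chain:
        # Poisson birth k_on*nbar*dt vs binomial death prob 1 - exp(-k_off dt)
        expect = 50.0 * rates.k_act_on * dt / -np.expm1(-rates.k_act_off * dt)
        assert abs(mean - expect) < 3 * max(se, 0.1)

    def test_cortex_reseeds_under_bleb_after_delay(self):
        cortex, membrane = self._setup()
        rates = kin.KineticRates(recruit_delay=0.1, seed_fraction=0.05)
        cortex.alive[:5] = False
        cortex.n_act[:5] = 0.0
        detach_time = np.full(64, np.inf)
        detach_time[:5] = 0.0
        kin.update_cortex_turnover(cortex, membrane, np.ones(64, bool),
                                   detach_time, rates, None, 1e-3, 0.05)
        assert not cortex.alive[:5].any()           # delay not yet elapsed
        kin.update_cortex_turnover(cortex, membrane, np.ones(64, bool),
                                   detach_time, rates, None, 1e-3, 0.15)
        assert cortex.alive[:5].all()
        assert np.allclose(cortex.n_act[:5], 0.05 * cortex.n_act_bar)


class TestOscillation:
    def test_constant_when_high_equals_low(self):
        s = kin.OscillationSignal(period=20.0, high_level=0.7, low_level=0.7)
        assert kin.oscillation_value(s, 3.0) == 0.7
        assert kin.oscillation_value(s, 17.0) == 0.7

    def test_periodicity(self):
        s = kin.OscillationSignal(period=20.0)
        for t in (0.0, 4.9, 10.0, 13.3):
            assert kin.oscillation_value(s, t) == kin.oscillation_value(s, t + 20.0)

    def test_duty_cycle_waveform(self):
        s = kin.OscillationSignal(period=20.0, duty_fraction=0.5,
                                  high_level=1.0, low_level=0.2)
        assert kin.oscillation_value(s, 5.0) == 1.0
        assert kin.oscillation_value(s, 15.0) == 0.2

    def test_none_signal_is_unity(self):
        assert kin.oscillation_value(None, 12.3) == 1.0


class TestBlebDetection:
    def _mk(self, n=64):
        membrane = st.MembraneState.circle(n, 10.0, (40.0, 40.0))
        lnk = st.LinkerEnsemble.saturated(n)
        return membrane, lnk

    def test_all_bound_no_event(self):
        membrane, lnk = self._mk()
        log = kin.BlebEventLog()
        assert not kin.detect_bleb_nucleation(lnk, membrane, log, 0.0)
        assert len(log) == 0

    def test_detachment_arc_logged_at_its_angle(self):
        membrane, lnk = self._mk()
        theta = np.degrees(membrane.polar_angles())
        arc = np.flatnonzero((theta > 25) & (theta < 35))
        lnk.bound[arc] = 0.0
        log = kin.BlebEventLog()
        kin.detect_bleb_nucleation(lnk, membrane, log, 1.0, threshold_nodes=1)
        assert len(log) == 1
        assert np.degrees(log.angles[0]) == pytest.approx(30.0, abs=6.0)

    def test_below_threshold_is_ignored(self):
        membrane, lnk = self._mk()
        lnk.bound[10:12] = 0.0
        log = kin.BlebEventLog()
        assert not kin.detect_bleb_nucleation(lnk, membrane, log, 0.0,
                                              threshold_nodes=3)

    def test_refractory_window_blocks_recounting(self):
        membrane, lnk = self._mk()
        lnk.bound[10:15] = 0.0
        log = kin.BlebEventLog(refractory=0.5)
        kin.detect_bleb_nucleation(lnk, membrane, log, 0.0)
        kin.detect_bleb_nucleation(lnk, membrane, log, 0.1)
        assert len(log) == 1
        kin.detect_bleb_nucleation(lnk, membrane, log, 1.0)
        assert len(log) == 2

    def test_wrap_around_arc_detected_once(self):
        membrane, lnk = self._mk()
        lnk.bound[-3:] = 0.0
        lnk.bound[:3] = 0.0
        log = kin.BlebEventLog()
        kin.detect_bleb_nucleation(lnk, membrane, log, 0.0)
        assert len(log) == 1
        assert abs(np.degrees(log.angles[0])) < 6.0


class TestAngleArithmetic:
    def test_consecutive_events_wrapped_difference(self):
        assert kin.wrapped_angle_difference_deg(70.0, 10.0) == 60.0
        assert kin.wrapped_angle_difference_deg(10.0, 350.0) == 20.0
        assert kin.wrapped_angle_difference_deg(0.0, 180.0) == 180.0
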