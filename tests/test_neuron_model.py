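"""Morphology, mapping, solver correctness, spikes/IFR."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from loomlab import neuron_model as nm
from loomlab.encode import SynapticEventTrain


@pytest.fixture(scope="module")
def morph():
    return nm.build_morphology()


@pytest.fixture(scope="module")
def channels():
    return nm.load_channelset()


def _event_df(times, polarity="OFF", class_="excitatory", facet_id=0,
              source="visual"):
    n = len(times)
    return pd.DataFrame({
        "time_s": times,
        "polarity": [polarity] * n if isinstance(polarity, str) else polarity,
        "class": [class_] * n if isinstance(class_, str) else class_,
        "facet_id": [facet_id] * n if np.isscalar(facet_id) else facet_id,
        "source": source})


def _single_epsp_map(comp, t=0.05):
    return nm.SynapseMap(times_s=np.array([t]), comp=np.array([comp]),
                         weight=np.array([1.0]), is_exc=np.array([True]))


class TestMorphology:
    def test_default_regions_present(self, morph):
        for region in nm.REGIONS:
            assert morph.ids(region).size > 0
        morph.validate()

    def test_field_c_closer_to_siz_than_field_a(self, morph):
        # passive transfer: equal current steps into terminal compartments,
        # steady depolarization at the SIZ must be larger from field C
        passive = nm.passive_channelset()
        vs = {}
        for name, comp in (("A", int(morph.a_grid[5, -1])),
                           ("C", int(morph.ids("C")[-1]))):
            p = nm.SimParams(t_start_s=0.0, t_end_s=0.3, record=("SIZ",),
                             inj_comp=comp, inj_na=0.1, inj_t0_s=0.05,
                             inj_t1_s=0.3)
            r = nm.simulate(morph, passive, None, p)
            v = r.vm_at(r.rec_comps[0])
            vs[name] = v[-1] - v[0]
        assert vs["C"] > vs["A"] > 0

    def test_input_resistance_matches_sealed_cable_formula(self):
        # uniform passive cylinder; analytic R_in = r_a * lambda * coth(l/lambda)
        n, seg_um, diam_um, ra, rm = 100, 20.0, 2.0, 100.0, 1.0e4
        cable = nm.cylinder_morphology(n=n, length_um=seg_um, diam_um=diam_um,
                                       ra=ra, g_leak=1.0 / rm, e_leak=-65.0)
        d_cm, l_cm = diam_um * 1e-4, n * seg_um * 1e-4
        lam = np.sqrt(rm * d_cm / (4.0 * ra))
        r_axial = 4.0 * ra / (np.pi * d_cm ** 2)
        r_in_analytic = r_axial * lam / np.tanh(l_cm / lam)    # ohm
        p = nm.SimParams(t_start_s=0.0, t_end_s=0.8, record=(0,),
                         inj_comp=0, inj_na=-1.0, inj_t0_s=0.1, inj_t1_s=0.8,
                         settle_ms=200.0)
        r = nm.simulate(cable, nm.passive_channelset(), None, p)
        v = r.vm_at(0)
        dv = v[int(0.09 * 50000)] - v[-1]                      # mV
        r_in_sim = dv / 1.0 * 1e6                              # mV/nA -> ohm
        assert r_in_sim == pytest.approx(r_in_analytic, rel=0.05)

    def test_scale_axial_resistance(self, morph):
        same = nm.scale_axial_resistance(morph, factor=1.0)
        np.testing.assert_array_equal(same.axial_resistivity,
                                      morph.axial_resistivity)
        passive = nm.passive_channelset()
        c_term = int(morph.ids("C")[-1])
        amps = []
        for factor in (1.0, 3.0, 10.0):
            m = nm.scale_axial_resistance(morph, factor=factor)
            p = nm.SimParams(t_start_s=0.0, t_end_s=0.12, record=("SIZ",))
            r = nm.simulate(m, passive, _single_epsp_map(c_term), p)
            v = r.vm_at(r.rec_comps[0])
            amps.append(v.max() - v[100])
        assert amps[0] > amps[1] > amps[2] > 0

    def test_unknown_link_rejected(self, morph):
        with pytest.raises(ValueError):
            nm.scale_axial_resistance(morph, region_link="A_link",
                                      factor=2.0)
        with pytest.raises(ValueError):
            nm.scale_axial_resistance(morph, factor=0.0)

    def test_hcn_absent_from_field_c_enforced(self):
        with pytest.raises(ValueError):
            nm.ChannelSet(densities={"hcn": {"C": 1e-4}}).validate()


class TestMapEvents:
    opts = {"facet_grid_shape": (10, 12)}

    def test_neighboring_facets_map_to_adjacent_field_a_compartments(
            self, morph):
        # facets 5 and 6 are lattice neighbors on a (10, 12) facet grid
        train = SynapticEventTrain(_event_df([0.1, 0.2], facet_id=[5, 6]))
        m = nm.map_events(train, morph, "retinotopic_A", self.opts, seed=0)
        pos = morph.position[m.comp]
        assert np.linalg.norm(pos[1] - pos[0]) <= 1.5 * 30.0
        assert all(morph.region[c] == "A" for c in m.comp)

    def test_random_c_reproducible_and_conserving(self, morph):
        times = np.sort(np.random.default_rng(0).uniform(0, 1, 200))
        train = SynapticEventTrain(_event_df(times))
        a = nm.map_events(train, morph, "random_C", {}, seed=5)
        b = nm.map_events(train, morph, "random_C", {}, seed=5)
        np.testing.assert_array_equal(a.comp, b.comp)
        assert a.n_events == 200
        assert all(morph.region[c] == "C" for c in a.comp[a.is_exc])

    def test_random_c_removal_fraction(self, morph):
        times = np.sort(np.random.default_rng(1).uniform(0, 1, 4000))
        train = SynapticEventTrain(_event_df(times))
        m = nm.map_events(train, morph, "random_C",
                          {"removal_fraction": 0.6}, seed=2)
        assert m.n_events == pytest.approx(1600, rel=0.08)

    def test_conductance_scale_alternative(self, morph):
        train = SynapticEventTrain(_event_df([0.1, 0.2, 0.3]))
        m = nm.map_events(train, morph, "random_C",
                          {"conductance_scale": 0.4}, seed=0)
        assert m.n_events == 3
        np.testing.assert_allclose(m.weight, 0.4)

    def test_split_zero_fraction_equals_retinotopic(self, morph):
        times = np.sort(np.random.default_rng(3).uniform(0, 1, 300))
        fids = np.random.default_rng(4).integers(0, 120, 300)
        train = SynapticEventTrain(_event_df(times, facet_id=fids))
        a = nm.map_events(train, morph, "retinotopic_A", self.opts, seed=7)
        b = nm.map_events(train, morph, "split",
                          {**self.opts, "fraction": 0.0}, seed=7)
        exc_a = a.comp[a.is_exc]
        exc_b = b.comp[b.is_exc]
        np.testing.assert_array_equal(np.sort(exc_a), np.sort(exc_b))

    def test_checkered_routes_by_polarity(self, morph):
        train = SynapticEventTrain(_event_df(
            [0.1, 0.2], polarity=["ON", "OFF"], facet_id=[3, 3]))
        m = nm.map_events(train, morph, "checkered", self.opts, seed=0)
        regions = [morph.region[c] for c in m.comp]
        assert regions == ["C", "A"]

    def test_invalid_options_rejected(self, morph):
        train = SynapticEventTrain(_event_df([0.1]))
        with pytest.raises(ValueError):
            nm.map_events(train, morph, "split",
                          {**self.opts, "fraction": 1.5})
        with pytest.raises(ValueError):
            nm.map_events(train, morph, "clustered_C",
                          {"center": morph.siz_id})
        with pytest.raises(ValueError):
            nm.map_events(train, morph, "nonsense")


class TestSimulate:
    def test_resting_stability(self, morph, channels):
        p = nm.SimParams(t_start_s=0.0, t_end_s=1.0, record=("SIZ",))
        r = nm.simulate(morph, channels, None, p)
        v = r.vm_at(r.rec_comps[0])
        assert r.n_spikes == 0
        assert np.abs(v - v[-1]).max() < 0.5

    def test_two_compartment_epsp_matches_ode_oracle(self):
        # independent dense-output ODE integration of the same passive
        # 2-compartment circuit with one alpha-conductance EPSP
        cable = nm.cylinder_morphology(n=2, length_um=50.0, diam_um=2.0,
                                       ra=100.0, g_leak=1e-4, e_leak=-65.0)
        t_ev = 0.005
        p = nm.SimParams(t_start_s=0.0, t_end_s=0.05, record=(0, 1),
                         settle_ms=50.0)
        r = nm.simulate(cable, nm.passive_channelset(),
                        _single_epsp_map(0, t=t_ev), p)

        area = cable.area_cm2()
        c_nf = cable.cm * area * 1e3
        gl_us = cable.g_leak * area * 1e6
        g_ax = cable.axial_conductance_us()[1]
        gmax, tau, e_rev = 14e-3, 0.15, 10.0      # uS, ms, mV

        def g_syn(t_ms):
            dt = t_ms - t_ev * 1e3
            return np.where(dt > 0,
                            gmax * (dt / tau) * np.exp(1 - dt / tau), 0.0)

        def rhs(t_ms, v):
            v1, v2 = v
            i1 = (gl_us[0] * (-65.0 - v1) + g_ax * (v2 - v1)
                  + g_syn(t_ms) * (e_rev - v1))
            i2 = gl_us[1] * (-65.0 - v2) + g_ax * (v1 - v2)
            return [i1 / c_nf[0], i2 / c_nf[1]]

        sol = solve_ivp(rhs, (0.0, 50.0), [-65.0, -65.0], method="LSODA",
                        t_eval=r.t_s * 1e3, rtol=1e-10, atol=1e-10,
                        max_step=0.05)
        assert np.abs(r.vm_at(0) - sol.y[0]).max() < 0.1
        assert np.abs(r.vm_at(1) - sol.y[1]).max() < 0.1

    def test_field_c_epsp_larger_at_siz_than_field_a(self, morph, channels):
        amps = {}
        for name, comp in (("A", int(morph.a_grid[5, -1])),
                           ("C", int(morph.ids("C")[-1]))):
            p = nm.SimParams(t_start_s=0.0, t_end_s=0.12, record=("SIZ",))
            r = nm.simulate(morph, channels, _single_epsp_map(comp), p)
            v = r.vm_at(r.rec_comps[0])
            amps[name] = v.max() - v[100]
        assert amps["C"] > amps["A"] > 0

    def test_clamped_charge_equals_per_event_sum(self, morph, channels):
        rng = np.random.default_rng(0)
        n = 500
        sm = nm.SynapseMap(times_s=np.sort(rng.uniform(0.01, 0.4, n)),
                           comp=rng.choice(morph.ids("A"), n),
                           weight=np.ones(n), is_exc=np.ones(n, bool))
        p = nm.SimParams(t_start_s=0.0, t_end_s=0.5, record=("SIZ",),
                         clamp_mv=-60.0)
        r = nm.simulate(morph, channels, sm, p)
        per_event_pc = 14.0 * 0.15 * np.e * (10.0 - (-60.0)) * 1e-6  # nC
        assert r.total_excitatory_charge_nc == pytest.approx(
            n * per_event_pc, rel=0.01)

    def test_events_outside_window_ignored_with_warning(self, morph,
                                                        channels):
        sm = nm.SynapseMap(times_s=np.array([0.05, 2.0]),
                           comp=np.array([morph.ids("A")[0]] * 2),
                           weight=np.ones(2), is_exc=np.ones(2, bool))
        p = nm.SimParams(t_start_s=0.0, t_end_s=0.1, record=("SIZ",))
        with pytest.warns(UserWarning):
            nm.simulate(morph, channels, sm, p)

    def test_invalid_dt_rejected(self, morph, channels):
        with pytest.raises(ValueError):
            nm.simulate(morph, channels, None, nm.SimParams(dt_ms=0.0))


class TestDetectSpikesIfr:
    def _result(self, v, dt_ms=0.02):
        n = v.size
        return nm.SimResult(t_s=np.arange(1, n + 1) * dt_ms / 1e3,
                            vm_mv=v[None, :], rec_comps=np.array([0]),
                            spike_times_s=np.empty(0),
                            total_excitatory_charge_nc=0.0, dt_ms=dt_ms)

    def test_no_spikes_zero_ifr(self):
        r = self._result(np.full(5000, -65.0))
        spikes, ifr = nm.detect_spikes_ifr(r, comp=0)
        assert spikes.size == 0
        np.testing.assert_array_equal(ifr, 0.0)

    def test_single_spike_ifr_integrates_to_one(self):
        v = np.full(50000, -65.0)
        v[25000:25050] = 20.0
        r = self._result(v)
        spikes, ifr = nm.detect_spikes_ifr(r, comp=0)
        assert spikes.size == 1
        assert np.trapezoid(ifr, r.t_s) == pytest.approx(1.0, rel=0.01)

    def test_regular_train_plateau_at_rate(self):
        v = np.full(100000, -65.0)              # 2 s at dt = 0.02 ms
        for k in range(500, 100000, 500):       # 100 Hz
            v[k:k + 30] = 20.0
        r = self._result(v)
        spikes, ifr = nm.detect_spikes_ifr(r, comp=0)
        assert spikes.size == 199
        mid = (r.t_s > 0.5) & (r.t_s < 1.5)
        assert np.mean(ifr[mid]) == pytest.approx(100.0, rel=0.02)

    def test_refractory_deduplication(self):
        v = np.full(10000, -65.0)
        v[1000:1010] = 20.0
        v[1030:1040] = 20.0                     # 0.4 ms later: same spike
        r = self._result(v)
        spikes, _ = nm.detect_spikes_ifr(r, comp=0, refractory_ms=2.0)
        assert spikes.size == 1
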