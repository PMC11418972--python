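import math

import numpy as np
import pandas as pd
import pytest

from conftest import dend_cable, passive_table, single_compartment
from dendrokit import fixtures as fx
from dendrokit.distributions import apply_config
from dendrokit.simulator import (IClamp, Population, SimConfig, Synapse,
                                 build_system, hines_solve, integrate, mg_block,
                                 place_population, spike_train, synapse_current)

RM = 1e4  # Ω·cm² for gbar_leak = 1e-4 S/cm²


def passive_system(morph, chans, stimuli=(), recordings=None, g_leak=1e-4,
                   config=None):
    table = passive_table(morph, g_leak=g_leak)
    cfg = config or SimConfig()
    return build_system(morph, table, {"leak": chans["leak"]}, stimuli=stimuli,
                        recordings=recordings or [0], config=cfg)


class TestBuildSystem:
    def test_capacitance_unit_conversion(self, chans):
        m = single_compartment()
        sys_ = passive_system(m, chans)
        area = m.segments[0].area  # 4π·10² µm²
        assert sys_.C[0] == pytest.approx(area * 1e-5)  # 1 µF/cm² -> nF

    def test_axial_conductance_matches_cable_formula(self, chans):
        m = dend_cable(length=100.0, diameter=2.0, nseg=2)
        sys_ = passive_system(m, chans)
        ell = 50.0  # center-to-center distance, µm
        # π d²/(4·Ra·ℓ) with d, ℓ in µm and Ra in Ω·cm -> µS needs the 1e2 factor
        g_expected = math.pi * 2.0 ** 2 / (4.0 * 100.0 * ell) * 1e2  # µS
        assert sys_.g_ax[1] == pytest.approx(g_expected, rel=1e-12)

    def test_missing_reversal_potential_rejected(self, chans):
        from dendrokit.channels import GatedChannel
        m = single_compartment()
        bad = GatedChannel("orphan", "ca", 0.001, None, [])
        table = passive_table(m)
        table["gbar_orphan"] = 0.001
        with pytest.raises(ValueError, match="reversal"):
            build_system(m, table, {"orphan": bad}, config=SimConfig())

    def test_missing_cable_columns_rejected(self, chans):
        m = single_compartment()
        with pytest.raises(ValueError, match="cm"):
            build_system(m, pd.DataFrame({"Ra": [100.0]}), {}, config=SimConfig())


class TestIntegrate:
    def test_passive_step_matches_rc_closed_form(self, chans):
        m = single_compartment()
        cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=50.0)
        sys_ = passive_system(m, chans, stimuli=[IClamp(0, 0.1, 20.0, 100.0)],
                              config=cfg)
        tr = integrate(sys_, cfg)
        area_cm2 = m.segments[0].area * 1e-8
        R = RM / area_cm2 / 1e6  # MΩ
        tau = RM * 1.0 * 1e-3    # ms (Rm·Cm)
        mask = (tr.t >= 20.0) & (tr.t <= 119.0)
        closed = -70.0 + 0.1 * R * (1.0 - np.exp(-(tr.t[mask] - 20.0) / tau))
        err = np.max(np.abs(tr.v[0][mask] - closed)) / (0.1 * R)
        assert err < 0.005

    def test_sealed_cable_dc_attenuation(self, chans):
        m = dend_cable(length=500.0, diameter=2.0, nseg=51)
        cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=100.0)
        n = len(m.segments)
        sys_ = passive_system(m, chans, stimuli=[IClamp(0, 0.05, 0.0, 200.0)],
                              recordings=list(range(n)), config=cfg)
        tr = integrate(sys_, cfg)
        lam = math.sqrt(RM * 2e-4 / (4 * 100.0)) * 1e4  # µm
        L = 500.0
        x = np.array([s.path_distance for s in m.segments])
        dv = np.array([tr.v[i][-1] for i in range(n)]) + 70.0
        ratio = dv / dv[0]
        pred = np.cosh((L - x) / lam) / np.cosh((L - x[0]) / lam)
        assert np.max(np.abs(ratio - pred)) < 0.01

    def test_rest_is_a_fixed_point(self, chans):
        m = fx.ball_and_stick()
        m.build_segments(5)
        cfg = SimConfig(t_stop=50.0, v_init=-70.0, equilibration=300.0)
        table = passive_table(m)
        tab = apply_config(fx.active_config(domains=("soma", "dend")), m)
        sys_ = build_system(m, tab, {k: v for k, v in chans.items()
                                     if k in ("leak", "na", "kdr")},
                            recordings=[0], config=cfg)
        tr = integrate(sys_, cfg)
        dv = np.diff(tr.v[0]) / cfg.dt
        assert np.max(np.abs(dv)) < 1e-6  # mV/ms

    def test_divergence_aborts_with_step_index(self, chans):
        m = single_compartment()
        cfg = SimConfig(t_stop=50.0, v_init=-70.0, equilibration=0.0)
        sys_ = passive_system(m, chans, stimuli=[IClamp(0, 1e6, 0.0, 50.0)],
                              config=cfg)
        from dendrokit.simulator import SimulationDiverged
        with pytest.raises(SimulationDiverged, match="step"):
            integrate(sys_, cfg)

    def test_charge_balance_each_implicit_step(self, chans):
        m = fx.y_tree()
        m.build_segments(3)
        cfg = SimConfig(t_stop=5.0, v_init=-65.0, equilibration=0.0)
        sys_ = passive_system(m, chans, stimuli=[IClamp(0, 0.05, 1.0, 10.0)],
                              config=cfg)
        # re-run the implicit update manually and check the current balance
        N = sys_.N
        V = np.full(N, -65.0)
        lap = sys_.laplacian()
        g_diag, ge = sys_.membrane_terms(V)
        for step in range(1, 41):
            i_ext = np.zeros(N)
            if 1.0 <= step * cfg.dt < 11.0:
                i_ext[0] = 0.05
            diag = sys_.C / cfg.dt + g_diag + sys_.axial_diag
            rhs = sys_.C / cfg.dt * V + ge + i_ext
            V_new = hines_solve(sys_.parent, diag, sys_.g_ax, rhs)
            resid = (sys_.C * (V_new - V) / cfg.dt + g_diag * V_new - ge
                     + lap @ V_new - i_ext)
            assert np.max(np.abs(resid)) < 1e-9
            V = V_new

    def test_tree_solver_matches_dense_solve(self, chans):
        rng = np.random.default_rng(7)
        for depth in (2, 3):
            m = fx.binary_tree(depth=depth)
            m.build_segments(3)
            sys_ = passive_system(m, chans)
            n = sys_.N
            diag = sys_.axial_diag + rng.uniform(0.01, 0.2, n)
            rhs = rng.normal(size=n)
            v_tree = hines_solve(sys_.parent, diag, sys_.g_ax, rhs)
            A = sys_.laplacian() + np.diag(diag - sys_.axial_diag)
            v_dense = np.linalg.solve(A, rhs)
            assert np.max(np.abs(v_tree - v_dense)) < 1e-10

    def test_halving_dt_moves_spike_times_less_than_dt(self, chans):
        m = fx.ball_and_stick()
        m.build_segments(3)
        tab = apply_config(fx.active_config(domains=("soma", "dend")), m)
        active = {k: chans[k] for k in ("leak", "na", "kdr")}
        times = {}
        for dt in (0.025, 0.0125):
            cfg = SimConfig(dt=dt, t_stop=60.0, v_init=-70.0, equilibration=100.0)
            sys_ = build_system(m, tab, active,
                                stimuli=[IClamp(0, 0.3, 10.0, 50.0)],
                                recordings=[0], config=cfg)
            tr = integrate(sys_, cfg)
            from dendrokit.validation import detect_spikes
            times[dt] = detect_spikes(tr.t, tr.v[0], min_height=0.0).peak_times
        assert min(len(times[0.025]), len(times[0.0125])) >= 2
        # first-order scheme: early spikes converge within one coarse step
        assert np.max(np.abs(times[0.025][:2] - times[0.0125][:2])) < 0.025

    def test_identical_seeds_identical_traces(self, chans):
        m = fx.binary_tree(depth=2)
        m.build_segments(3)
        leaf = [s for s in m.sections if not s.children][0]
        out = []
        for _ in range(2):
            pop = Population(kind="AMPA", n=10, targets=leaf.segments,
                             rate=50.0, noise=1.0, onset=5.0, duration=50.0)
            syns = place_population(pop, seed=123)
            cfg = SimConfig(t_stop=60.0, v_init=-70.0, equilibration=20.0)
            sys_ = passive_system(m, chans, config=cfg)
            sys_ = build_system(m, passive_table(m), {"leak": chans["leak"]},
                                synapses=syns, recordings=[0], config=cfg)
            out.append(integrate(sys_, cfg).v[0])
        assert np.array_equal(out[0], out[1])


class TestSynapses:
    def test_double_exponential_peak_location_and_height(self):
        syn = Synapse("AMPA", 0, g_max=2e-3, tau_rise=0.5, tau_decay=5.0,
                      spike_times=[10.0])
        tp = 0.5 * 5.0 / (5.0 - 0.5) * math.log(5.0 / 0.5)
        t = np.linspace(0.0, 40.0, 40001)
        g = syn.conductance(t)
        assert t[np.argmax(g)] == pytest.approx(10.0 + tp, abs=1e-2)
        assert g.max() == pytest.approx(2e-3, rel=1e-4)

    def test_zero_driving_force_zero_current(self):
        syn = Synapse("AMPA", 0, g_max=1e-3, spike_times=[0.0])
        i = synapse_current(syn, V=syn.e, t=2.0)
        assert np.allclose(i, 0.0)

    def test_nmda_block_suppresses_current_at_hyperpolarized_v(self):
        nmda = Synapse("NMDA", 0, g_max=1e-3, spike_times=[0.0])
        ampa = Synapse("AMPA", 0, g_max=1e-3, tau_rise=nmda.tau_rise,
                       tau_decay=nmda.tau_decay, e=nmda.e, spike_times=[0.0])
        t = 2.0
        i_n = abs(synapse_current(nmda, -80.0, t))
        i_a = abs(synapse_current(ampa, -80.0, t))
        assert mg_block(-80.0) < 0.1
        assert i_n < 0.1 * i_a

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError, match="tau_rise"):
            Synapse("AMPA", 0, tau_rise=5.0, tau_decay=1.0)


class TestSpikeTrain:
    def test_regular_train_exact_count_and_spacing(self):
        st = spike_train(rate=25.0, noise=0.0, onset=0.0, duration=200.0)
        assert len(st) == 5
        assert np.allclose(np.diff(st), 40.0)

    def test_poisson_moments(self):
        counts, cvs = [], []
        for seed in range(200):
            st = spike_train(rate=25.0, noise=1.0, onset=0.0, duration=2000.0,
                             seed=seed)
            counts.append(len(st))
            isi = np.diff(st)
            if len(isi) > 2:
                cvs.append(np.std(isi) / np.mean(isi))
        mean_n = np.mean(counts)
        se_n = np.sqrt(50.0) / np.sqrt(200)  # Poisson variance = mean
        assert abs(mean_n - 50.0) < 3 * se_n * 3  # 3 SE with slack for edge effects
        assert abs(np.mean(cvs) - 1.0) < 0.1

    def test_zero_rate_empty(self):
        assert len(spike_train(0.0, 1.0, 0.0, 100.0, seed=0)) == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            spike_train(10.0, 0.5, 0.0, -1.0)


class TestPlacePopulation:
    def test_single_target_gets_all_synapses(self, ball_stick):
        seg = ball_stick.segments[-1]
        pop = Population(kind="AMPA", n=7, targets=[seg])
        syns = place_population(pop, seed=0)
        assert len(syns) == 7
        assert all(s.segment is seg for s in syns)

    def test_equal_length_targets_split_evenly(self):
        m = fx.ball_and_stick(length=200.0)
        m.build_segments(2)
        dend = next(s for s in m.sections if s.domain == "dend")
        a, b = dend.segments
        pop = Population(kind="AMPA", n=2000, targets=[a, b])
        syns = place_population(pop, seed=11)
        n_a = sum(1 for s in syns if s.segment is a)
        se = math.sqrt(2000 * 0.25)
        assert abs(n_a - 1000) < 3 * se

    def test_placement_confined_to_targets(self, binary2):
        leaves = [s for s in binary2.sections if not s.children]
        clustered = [seg for s in leaves[:2] for seg in s.segments]
        spread = [seg for s in leaves for seg in s.segments]
        for targets in (clustered, spread):
            pop = Population(kind="AMPA_NMDA", n=40, targets=targets)
            syns = place_population(pop, seed=3)
            assert all(s.segment in targets for s in syns)

    def test_empty_population_rejected(self, ball_stick):
        with pytest.raises(ValueError):
            Population(kind="AMPA", n=0, targets=[ball_stick.segments[0]])


class TestNMDAIntegration:
    def test_blocking_nmda_lowers_dendritic_plateau(self, chans):
        m = fx.binary_tree(depth=2)
        m.build_segments(5)
        table = passive_table(m)
        leaf = [s for s in m.sections if not s.children][0]
        rng = np.random.default_rng(1)
        probes = leaf.segments[len(leaf.segments) // 2].idx
        peaks, dur = {}, {}
        for ratio in (1.0, 0.0):
            syns = [Synapse("AMPA_NMDA", seg, g_max=5e-4, nmda_ratio=ratio,
                            spike_times=[20.0])
                    for seg in rng.choice(leaf.segments, size=20)]
            cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=100.0)
            sys_ = build_system(m, table, {"leak": chans["leak"]}, synapses=syns,
                                recordings=[probes], config=cfg)
            v = integrate(sys_, cfg).v[probes]
            peaks[ratio] = v.max()
            dur[ratio] = (v > -40.0).sum() * cfg.dt
        assert peaks[0.0] < peaks[1.0]           # block -> strictly lower peak
        assert dur[1.0] > 2.0 * dur[0.0]         # plateau collapses
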