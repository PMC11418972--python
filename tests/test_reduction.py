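import math

import numpy as np
import pytest

from conftest import passive_table
from dendrokit import fixtures as fx
from dendrokit.distributions import Distribution
from dendrokit.reduction import (ImpedancePair, map_channels,
                                 measure_impedances, reduce_all_stems,
                                 reduce_subtree, refit_distribution,
                                 solve_cylinder)

RM, CM, RA = 1e4, 1.0, 100.0  # Ω·cm², µF/cm², Ω·cm


def single_cylinder_morph(length=500.0, diameter=2.0):
    from dendrokit.morphology import Morphology, PointNode
    m = Morphology([
        PointNode(1, 1, 0.0, 0.0, 0.0, 8.0, -1),
        PointNode(2, 3, 8.0, 0.0, 0.0, diameter / 2.0, 1),
        PointNode(3, 3, 8.0 + length, 0.0, 0.0, diameter / 2.0, 2)])
    m.build_segments(5)
    return m, next(s for s in m.sections if s.domain == "dend")


def analytic_cylinder(length, diameter):
    d_cm = diameter * 1e-4
    lam = math.sqrt(RM * d_cm / (4.0 * RA)) * 1e4  # µm
    z_c = (2.0 / math.pi) * math.sqrt(RM * RA) * d_cm ** -1.5 / 1e6  # MΩ
    return (z_c / math.tanh(length / lam), z_c / math.sinh(length / lam))


class TestMeasureImpedances:
    def test_single_cylinder_matches_closed_form(self):
        m, sec = single_cylinder_morph()
        pair = measure_impedances(m, sec, RM, CM, RA, 0.0)
        zin, ztr = analytic_cylinder(500.0, 2.0)
        assert pair.Z_in == pytest.approx(zin, rel=1e-8)
        assert pair.Z_tr == pytest.approx(ztr, rel=1e-8)

    def test_short_cable_limit_is_membrane_only(self):
        m, sec = single_cylinder_morph(length=0.5)
        pair = measure_impedances(m, sec, RM, CM, RA, 0.0)
        area_cm2 = math.pi * 2e-4 * 0.5e-4
        r_mem = RM / area_cm2 / 1e6  # MΩ
        assert pair.Z_in == pytest.approx(r_mem, rel=1e-3)
        assert pair.Z_tr == pytest.approx(pair.Z_in, rel=1e-3)

    def test_rall_y_equals_single_daughter_with_doubled_d32(self):
        y = fx.y_tree(rall=True)
        y.build_segments(3)
        stem = next(s for s in y.sections if s.domain == "dend" and s.children)
        pair = measure_impedances(y, stem, RM, CM, RA, 0.0)
        # Rall equivalent: uniform d=2 cable of electrotonic length
        # L_stem/λ(2) + L_branch/λ(2·2^{-2/3})·(λ ratio) folded into one cable
        lam2 = math.sqrt(RM * 2e-4 / (4 * RA)) * 1e4
        lam_child = lam2 * (2.0 ** (-2.0 / 3.0)) ** 0.5
        L_hat = 100.0 / lam2 + 120.0 / lam_child
        L_eq = L_hat * lam2
        zin, ztr = analytic_cylinder(L_eq, 2.0)
        assert pair.Z_in == pytest.approx(zin, rel=1e-6)
        assert pair.Z_tr == pytest.approx(ztr, rel=1e-6)

    def test_transfer_never_exceeds_input(self):
        for maker in (fx.y_tree, lambda: fx.binary_tree(depth=3)):
            m = maker()
            m.build_segments(3)
            stem = next(s for s in m.sections if s.domain == "dend")
            pair = measure_impedances(m, stem, RM, CM, RA, 0.0)
            assert pair.Z_in >= pair.Z_tr > 0

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            ImpedancePair(Z_in=10.0, Z_tr=20.0)


class TestSolveCylinder:
    def test_identity_on_measured_cylinder(self):
        m, sec = single_cylinder_morph()
        pair = measure_impedances(m, sec, RM, CM, RA, 0.0)
        cyl = solve_cylinder(pair, RM, CM, RA, 0.0)
        assert cyl.diameter == pytest.approx(2.0, rel=1e-6)
        assert cyl.length == pytest.approx(500.0, rel=1e-6)

    def test_forward_check_reproduces_pair(self):
        pair = ImpedancePair(Z_in=300.0, Z_tr=200.0)
        cyl = solve_cylinder(pair, RM, CM, RA, 0.0)
        back = cyl.impedances()
        assert back.Z_in == pytest.approx(pair.Z_in, rel=1e-6)
        assert back.Z_tr == pytest.approx(pair.Z_tr, rel=1e-6)

    def test_isopotential_limit_matches_membrane_area(self):
        z = 100.0  # MΩ with Z_in == Z_tr
        cyl = solve_cylinder(ImpedancePair(z, z), RM, CM, RA, 0.0)
        area_um2 = math.pi * cyl.diameter * cyl.length
        expected = RM / (z * 1e6) * 1e8  # cm² -> µm²
        assert area_um2 == pytest.approx(expected, rel=1e-9)

    def test_doubling_rm_scales_electrotonic_length(self):
        m, sec = single_cylinder_morph()
        p1 = measure_impedances(m, sec, RM, CM, RA, 0.0)
        p2 = measure_impedances(m, sec, 2 * RM, CM, RA, 0.0)
        lhat1 = math.acosh(p1.Z_in / p1.Z_tr)
        lhat2 = math.acosh(p2.Z_in / p2.Z_tr)
        assert lhat2 == pytest.approx(lhat1 / math.sqrt(2.0), rel=1e-9)


class TestReduceSubtree:
    def test_reducing_a_bare_cylinder_is_identity(self):
        m, sec = single_cylinder_morph()
        red, mapping, cyl = reduce_subtree(m, sec, RM, CM, RA)
        assert cyl.diameter == pytest.approx(2.0, rel=1e-6)
        assert cyl.length == pytest.approx(500.0, rel=1e-6)
        new_dend = next(s for s in red.sections if s.domain == "dend")
        assert new_dend.length == pytest.approx(500.0, rel=1e-6)

    def test_full_reduction_leaves_soma_plus_three_cylinders(self):
        m = fx.three_stem_cell()
        m.build_segments(3)
        red, _ = reduce_all_stems(m, RM, CM, RA)
        assert len(red.sections) == 4
        assert sum(1 for s in red.sections if s.domain == "soma") == 1
        assert all(not s.children for s in red.sections if s.domain != "soma")

    def test_partial_reduction_is_between_original_and_full(self):
        m = fx.three_stem_cell()
        m.build_segments(3)
        n_orig = len(m.sections)
        stem = m.root_section.children[0]
        partial, _, _ = reduce_subtree(m, stem, RM, CM, RA)
        full, _ = reduce_all_stems(m, RM, CM, RA)
        assert len(full.sections) < len(partial.sections) < n_orig

    def test_reduction_preserves_subtree_impedances(self):
        m = fx.binary_tree(depth=3)
        m.build_segments(3)
        stem = next(s for s in m.sections if s.domain == "dend" and s.parent.domain == "soma")
        pair = measure_impedances(m, stem, RM, CM, RA, 0.0)
        red, _, _ = reduce_subtree(m, stem, RM, CM, RA)
        new_sec = next(s for s in red.sections if s.domain == "dend")
        back = measure_impedances(red, new_sec, RM, CM, RA, 0.0)
        assert back.Z_in == pytest.approx(pair.Z_in, rel=1e-6)
        assert back.Z_tr == pytest.approx(pair.Z_tr, rel=1e-6)

    def test_somatic_input_resistance_changes_below_two_percent(self, chans):
        from dendrokit.simulator import IClamp, SimConfig, build_system, integrate
        from dendrokit.validation import input_resistance

        def rin_of(morph):
            table = passive_table(morph)
            cfg = SimConfig(t_stop=100.0, v_init=-70.0, equilibration=200.0)
            sys_ = build_system(morph, table, {"leak": chans["leak"]},
                                stimuli=[IClamp(0, -0.05, 10.0, 95.0)],
                                recordings=[0], config=cfg)
            tr = integrate(sys_, cfg)
            return input_resistance(tr.t, tr.v[0], -0.05, 10.0, 85.0)

        m = fx.binary_tree(depth=3)
        m.build_segments(3)
        stem = next(s for s in m.sections if s.domain == "dend" and s.parent.domain == "soma")
        red, _, _ = reduce_subtree(m, stem, RM, CM, RA)
        r0, r1 = rin_of(m), rin_of(red)
        assert abs(r1 - r0) / r0 < 0.02

    def test_soma_cannot_be_reduced(self):
        m = fx.y_tree()
        m.build_segments(3)
        with pytest.raises(ValueError):
            reduce_subtree(m, m.root_section, RM, CM, RA)

    def test_disjoint_stems_reduce_order_independently(self):
        def lengths(morph):
            return sorted(round(s.length, 6) for s in morph.sections)

        m1 = fx.three_stem_cell()
        m1.build_segments(3)
        s1, s2 = m1.root_section.children[0], m1.root_section.children[1]
        a, _, _ = reduce_subtree(m1, s1, RM, CM, RA)
        a_s2 = next(s for s in a.root_section.children
                    if s.domain == s2.domain and s.children)
        ab, _, _ = reduce_subtree(a, a_s2, RM, CM, RA)

        m2 = fx.three_stem_cell()
        m2.build_segments(3)
        t2 = m2.root_section.children[1]
        b, _, _ = reduce_subtree(m2, t2, RM, CM, RA)
        b_s1 = next(s for s in b.root_section.children
                    if s.domain == m2.root_section.children[0].domain and s.children)
        ba, _, _ = reduce_subtree(b, b_s1, RM, CM, RA)
        assert lengths(ab) == pytest.approx(lengths(ba))


class TestMapChannels:
    def _reduced(self):
        m = fx.binary_tree(depth=2)
        m.build_segments(3)
        stem = next(s for s in m.sections if s.domain == "dend"
                    and s.parent.domain == "soma")
        orig_segments = [seg for s in m.subtree_sections(stem) for seg in s.segments]
        red, mapping, _ = reduce_subtree(m, stem, RM, CM, RA)
        return orig_segments, mapping

    def test_uniform_density_is_preserved_exactly(self):
        orig, mapping = self._reduced()
        values = {s: 0.125 for s in orig}
        out = map_channels(values, mapping)
        assert all(v == pytest.approx(0.125) for v in out.values())

    def test_hotspot_keeps_ordering_of_means(self):
        orig, mapping = self._reduced()
        cut = np.median([s.path_distance for s in orig])
        values = {s: (1.0 if s.path_distance >= cut else 0.1) for s in orig}
        out = map_channels(values, mapping)
        far = {r for r, contribs in mapping.contributors.items()
               if contribs and all(values[s] == 1.0 for s in contribs)}
        near = {r for r, contribs in mapping.contributors.items()
                if contribs and all(values[s] == 0.1 for s in contribs)}
        if far and near:
            assert min(out[r] for r in far) >= max(out[r] for r in near)

    def test_count_weighted_mean_is_conserved(self):
        orig, mapping = self._reduced()
        rng = np.random.default_rng(5)
        values = {s: float(rng.uniform(0.01, 1.0)) for s in orig}
        out = map_channels(values, mapping)
        num = sum(out[r] * len(c) for r, c in mapping.contributors.items() if c)
        den = sum(len(c) for c in mapping.contributors.values())
        assert num / den == pytest.approx(np.mean(list(values.values())), rel=1e-12)

    def test_single_contributor_copies_value(self):
        orig, mapping = self._reduced()
        target = next(r for r, c in mapping.contributors.items() if len(c) == 1) \
            if any(len(c) == 1 for c in mapping.contributors.values()) else None
        values = {s: float(i) for i, s in enumerate(orig)}
        out = map_channels(values, mapping)
        if target is not None:
            only = mapping.contributors[target][0]
            assert out[target] == values[only]


class TestRefitDistribution:
    def test_exact_line_selects_linear(self):
        d = np.linspace(0.0, 300.0, 20)
        v = 0.5 + 0.002 * d
        dist, report = refit_distribution(d, v)
        assert dist.kind == "linear"
        assert report["mse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_beats_linear_by_complexity(self):
        d = np.linspace(0.0, 300.0, 20)
        dist, report = refit_distribution(d, np.full(20, 0.7))
        assert dist.kind == "constant"
        assert dist.coefficients == [pytest.approx(0.7)]

    def test_noisy_exponential_recovered_within_ten_percent(self):
        rng = np.random.default_rng(12)
        d = np.linspace(0.0, 400.0, 40)
        true = (2e-4, 5e-4, 180.0)
        v = true[0] + true[1] * np.exp(d / true[2])
        v = v * (1.0 + rng.normal(0.0, 0.002, size=len(d)))
        dist, _ = refit_distribution(d, v)
        assert dist.kind == "exponential"
        for got, want in zip(dist.coefficients, true):
            assert got == pytest.approx(want, rel=0.10)

    def test_minimum_samples_required(self):
        with pytest.raises(ValueError):
            refit_distribution([1.0], [2.0])

    def test_refit_exports_distribution_module_format(self):
        d = np.linspace(0.0, 100.0, 10)
        dist, _ = refit_distribution(d, 3.0 + 0.01 * d)
        assert isinstance(dist, Distribution)
        assert dist.to_dict()["kind"] == dist.kind
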