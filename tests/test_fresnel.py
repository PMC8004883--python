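"""Multilayer Fresnel reflectivity: interface forms, oracles, SPR physics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psprmap import fresnel as fr


def random_stack(rng: np.random.Generator) -> fr.OpticalStack:
    layers = [fr.OpticalLayer("in", 1.0 + rng.uniform(0.2, 1.0), None)]
    for j in range(int(rng.integers(0, 4))):
        n = complex(rng.uniform(0.1, 3.0), rng.uniform(0.0, 4.0))
        layers.append(fr.OpticalLayer(f"l{j}", n, float(rng.uniform(0.0, 200.0))))
    layers.append(fr.OpticalLayer("out", complex(rng.uniform(1.0, 2.0)), None))
    return fr.OpticalStack(tuple(layers), 850.0)


class TestInterface:
    def test_identical_media_reflect_nothing(self):
        assert fr.interface_rp(1.4, 1.4, 37.0) == pytest.approx(0.0, abs=1e-15)
        assert fr.interface_rs(1.4, 1.4, 37.0) == pytest.approx(0.0, abs=1e-15)

    def test_normal_incidence_closed_form(self):
        # (n1-n2)/(n1+n2) = -0.2 magnitude at the 1.0/1.5 interface
        r = fr.interface_rp(1.0, 1.5, 1e-8)
        assert abs(r) == pytest.approx(0.2, abs=1e-6)

    def test_total_internal_reflection_unit_magnitude(self):
        # BK7/water beyond the ~62.1 deg critical angle
        assert abs(fr.interface_rp(1.51, 1.3344, 70.0)) == pytest.approx(1.0, abs=1e-12)
        assert abs(fr.interface_rs(1.51, 1.3344, 70.0)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), 0.0])
    def test_nonfinite_inputs_rejected(self, bad):
        with pytest.raises(fr.FresnelError):
            fr.interface_rp(bad, 1.5, 45.0)


class TestStackReflectivity:
    def test_zero_thickness_layers_are_transparent(self):
        bare = fr.OpticalStack(
            (
                fr.OpticalLayer("prism", fr.N_PRISM, None),
                fr.OpticalLayer("buffer", 1.3344, None),
            )
        )
        dressed = fr.default_stack(au_thickness_nm=0.0, probe_thickness_nm=0.0)
        # zero-thickness Au/probe, but Cr still has 2 nm: zero that too
        layers = [
            lay if lay.semi_infinite else fr.OpticalLayer(lay.label, lay.refractive_index, 0.0)
            for lay in dressed.layers
        ]
        dressed = fr.OpticalStack(tuple(layers))
        for ang in (15.0, 45.0, 70.0):
            a = fr.stack_reflectivity(bare, ang)
            b = fr.stack_reflectivity(dressed, ang)
            assert abs(a.r_p - b.r_p) < 1e-12
            assert abs(a.r_s - b.r_s) < 1e-12

    def test_resonance_dip_location(self):
        # paper-default stack: 48 nm Au, 2 nm Cr, buffer 1.3344, 850 nm
        stack = fr.default_stack(48.0, 0.0, 1.40, 1.3344)
        dip = fr.resonance_angle(stack)
        assert 65.5 <= dip <= 67.5

    def test_recursive_and_matrix_oracles_agree(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            stack = random_stack(rng)
            ang = float(rng.uniform(5.0, 85.0))
            a = fr.stack_reflectivity(stack, ang, method="matrix")
            b = fr.stack_reflectivity(stack, ang, method="recursive")
            assert abs(a.r_p - b.r_p) < 1e-10
            assert abs(a.r_s - b.r_s) < 1e-10

    def test_energy_bound_on_random_passive_stacks(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            stack = random_stack(rng)
            refl = fr.stack_reflectivity(stack, float(rng.uniform(1.0, 89.0)))
            assert 0.0 <= refl.R_p <= 1.0 + 1e-12
            assert 0.0 <= refl.R_s <= 1.0 + 1e-12

    def test_reduction_to_three_layer_analytic_model(self):
        # with Cr and probe at zero thickness the stack is prism/Au/buffer;
        # compare against the independently coded two-interface Airy formula
        stack = fr.default_stack(48.0, 0.0)
        layers = [
            lay if lay.label != "chromium" else fr.OpticalLayer(lay.label, lay.refractive_index, 0.0)
            for lay in stack.layers
        ]
        stack = fr.OpticalStack(tuple(layers))
        n1, n2, n3 = fr.N_PRISM, fr.N_GOLD, 1.3344 + 0j
        d = 48.0
        lam = 850.0
        for ang_deg in (55.0, 66.0, 70.0):
            th = np.deg2rad(ang_deg)
            kx = n1 * np.sin(th)
            ncos = []
            for n in (n1, n2, n3):
                v = np.sqrt(n**2 - kx**2 + 0j)
                if v.imag < 0 or (v.imag == 0 and v.real < 0):
                    v = -v
                ncos.append(v)
            q = [v / n**2 for v, n in zip(ncos, (n1, n2, n3))]
            r12 = (q[0] - q[1]) / (q[0] + q[1])
            r23 = (q[1] - q[2]) / (q[1] + q[2])
            beta = 2.0 * np.pi * d * ncos[1] / lam
            r_airy = (r12 + r23 * np.exp(2j * beta)) / (1 + r12 * r23 * np.exp(2j * beta))
            got = fr.stack_reflectivity(stack, ang_deg).r_p
            assert abs(got - r_airy) < 1e-12

    def test_negative_thickness_rejected(self):
        with pytest.raises(fr.FresnelError):
            fr.OpticalLayer("bad", 1.5, -1.0)

    def test_internal_semi_infinite_rejected(self):
        with pytest.raises(fr.FresnelError):
            fr.OpticalStack(
                (
                    fr.OpticalLayer("a", 1.5, None),
                    fr.OpticalLayer("b", 1.4, None),
                    fr.OpticalLayer("c", 1.33, None),
                )
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ang=st.floats(min_value=30.0, max_value=85.0),
        au=st.floats(min_value=35.0, max_value=60.0),
    )
    def test_phase_difference_principal_branch(self, ang, au):
        refl = fr.stack_reflectivity(fr.default_stack(au), ang)
        assert -np.pi < refl.phi_diff <= np.pi


class TestResonanceShape:
    def test_unique_dip_with_monotone_p_phase(self):
        stack = fr.default_stack(48.0, 0.0, 1.40, 1.3344)
        ang = np.linspace(64.0, 69.0, 1001)
        rp = np.array([fr.stack_reflectivity(stack, a).r_p for a in ang])
        R = np.abs(rp) ** 2
        i_min = int(np.argmin(R))
        assert 0 < i_min < len(ang) - 1
        # single local minimum: R decreases up to the dip and rises afterwards
        assert np.all(np.diff(R[: i_min + 1]) < 0)
        assert np.all(np.diff(R[i_min:]) > 0)
        # p phase sweeps monotonically through the dip; s phase is quiet
        phi_p = np.unwrap(np.angle(rp))
        window = slice(max(i_min - 50, 0), i_min + 50)
        assert np.all(np.diff(phi_p[window]) < 0) or np.all(np.diff(phi_p[window]) > 0)
        rs = np.array([fr.stack_reflectivity(stack, a).r_s for a in ang])
        phi_s = np.unwrap(np.angle(rs))
        assert np.ptp(phi_s[window]) < 0.1 * np.ptp(phi_p[window])


class TestPhaseVsRi:
    def test_baseline_self_reference(self):
        stack = fr.default_stack(46.0, 7.5)
        curve = fr.phase_vs_ri(stack, 66.4, np.linspace(1.333, 1.340, 301), 1.3344)
        i0 = int(np.argmin(np.abs(curve.ri - 1.3344)))
        assert curve.dphase[i0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("angle", [66.3, 66.4, 66.5])
    def test_monotone_sigmoid_mapping_curve(self, angle):
        # 46 nm chip, operating angles just above its dip
        stack = fr.default_stack(46.0, 7.5, 1.40, 1.3344)
        curve = fr.phase_vs_ri(stack, angle, np.linspace(1.333, 1.340, 301), 1.3344)
        d = np.diff(curve.dphase)
        assert np.all(d > 0)
        # sigmoid: slope peaks in the interior and falls off toward both ends
        i_pk = int(np.argmax(d))
        assert 0 < i_pk < d.size - 1
        assert d[0] < 0.5 * d[i_pk] and d[-1] < 0.5 * d[i_pk]

    def test_angle_offset_reduces_measured_step(self):
        # the 1.3344 -> 1.3384 step shrinks when the beam is 0.3 deg below
        # the near-resonance operating angle
        stack = fr.default_stack(46.0, 7.5, 1.40, 1.3344)
        dip = fr.resonance_angle(stack)
        grid = np.union1d(np.linspace(1.3340, 1.3390, 301), [1.3344, 1.3384])

        def step(angle):
            curve = fr.phase_vs_ri(stack, angle, grid, 1.3344)
            return abs(curve.dphase[np.searchsorted(curve.ri, 1.3384)])

        assert step(dip + 0.05) > step(dip + 0.05 - 0.3)

    def test_thickness_controls_mapping_slope(self):
        slopes = []
        for au in (44.0, 45.0, 46.0, 47.0, 48.0):
            stack = fr.default_stack(au, 7.5, 1.40, 1.3340)
            curve = fr.phase_vs_ri(stack, 66.4, np.linspace(1.33376, 1.33664, 301), 1.3340)
            slopes.append(np.max(np.abs(np.gradient(curve.dphase, curve.ri))))
        assert np.all(np.diff(slopes) > 0)

    def test_baseline_outside_grid_rejected(self):
        stack = fr.default_stack()
        with pytest.raises(fr.FresnelError):
            fr.phase_vs_ri(stack, 66.4, np.linspace(1.335, 1.340, 50), 1.3330)
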