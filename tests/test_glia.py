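"""Phase-modulation beating simulation and GLIA demodulation."""

import numpy as np
import pytest
from scipy.special import j1, jv

from psprmap import glia


NULL = glia.j1_null_depth()


class TestModulationDepth:
    def test_no_current_no_modulation(self):
        cfg = glia.ModulatorConfig(delta_i_ma=0.0)
        assert glia.modulation_depth(cfg) == 0.0

    def test_direct_evaluation(self):
        # 2*pi * 0.2 * 0.6 nm/mA * 1 cm * 0.369 mA / (852 nm)^2 ~ 3.83 rad
        cfg = glia.ModulatorConfig(
            ne=2.1573, no=1.9573, length_m=0.01, beta_nm_per_ma=0.6,
            lambda0_nm=852.0, delta_i_ma=0.369,
        )
        assert glia.modulation_depth(cfg) == pytest.approx(3.83, abs=0.01)

    def test_linear_in_current(self):
        cfg = glia.ModulatorConfig(delta_i_ma=0.2)
        cfg2 = glia.ModulatorConfig(delta_i_ma=0.4)
        assert glia.modulation_depth(cfg2) == pytest.approx(
            2 * glia.modulation_depth(cfg), rel=1e-14
        )

    def test_with_depth_inverts_exactly(self):
        cfg = glia.ModulatorConfig().with_depth(NULL)
        assert glia.modulation_depth(cfg) == pytest.approx(NULL, rel=1e-14)


class TestJ1Null:
    def test_four_decimal_value(self):
        assert NULL == pytest.approx(3.8317, abs=5e-5)

    def test_is_a_root_of_j1(self):
        assert abs(j1(NULL)) < 1e-10

    def test_bracketing(self):
        assert 3.0 < NULL < 4.5


class TestSimulateBeating:
    def test_no_contrast_gives_pure_sinusoid(self):
        sig = glia.simulate_beating(0.7, i0=2.0, mu=0.3, m=0.0, depth_rad=NULL)
        expected = 2.0 * (1 + 0.3 * np.sin(sig.omega * sig.t))
        assert np.allclose(sig.intensity, expected, atol=1e-14)

    def test_no_modulation_gives_constant(self):
        cfg = glia.ModulatorConfig(delta_i_ma=0.0)
        sig = glia.simulate_beating(np.pi / 5, i0=1.5, mu=0.0, m=0.4, config=cfg)
        expected = 1.5 * (1 + 0.4 * np.cos(np.pi / 5))
        assert np.allclose(sig.intensity, expected, atol=1e-14)

    def test_jacobi_anger_series_oracle(self):
        # independent reconstruction of the beating from the Bessel series
        phi, mu, m, a = 0.9, 0.12, 0.7, 2.6
        sig = glia.simulate_beating(phi, mu=mu, m=m, depth_rad=a, samples_per_period=256)
        wt = sig.omega * sig.t
        cos_mod = jv(0, a) + 2 * sum(jv(2 * n, a) * np.cos(2 * n * wt) for n in range(1, 40))
        sin_mod = 2 * sum(jv(2 * n - 1, a) * np.sin((2 * n - 1) * wt) for n in range(1, 40))
        series = (1 + mu * np.sin(wt)) * (
            1 + m * (np.cos(phi) * cos_mod + np.sin(phi) * sin_mod)
        )
        assert np.max(np.abs(sig.intensity - series)) < 1e-6

    def test_nonphysical_contrast_rejected(self):
        with pytest.raises(glia.GliaError):
            glia.simulate_beating(0.0, mu=1.2, m=0.5, depth_rad=NULL)
        with pytest.raises(glia.GliaError):
            glia.simulate_beating(0.0, mu=0.0, m=-0.1, depth_rad=NULL)

    def test_intensity_nonnegative(self):
        for phi in np.linspace(-3, 3, 7):
            sig = glia.simulate_beating(phi, i0=1.0, mu=1.0, m=1.0, depth_rad=NULL)
            assert np.all(sig.intensity >= -1e-12)

    def test_noise_is_seeded(self):
        a = glia.simulate_beating(0.1, depth_rad=NULL, noise_sigma=0.01, seed=5)
        b = glia.simulate_beating(0.1, depth_rad=NULL, noise_sigma=0.01, seed=5)
        assert np.array_equal(a.intensity, b.intensity)


class TestLockin:
    def test_zero_contrast_zero_quadratures(self):
        sig = glia.simulate_beating(1.0, mu=0.25, m=0.0, depth_rad=NULL)
        r = glia.lockin_xy(sig)
        assert abs(r.X) < 1e-14 and abs(r.Y) < 1e-14

    def test_cosine_ratio_between_phases(self):
        # X scales with cos(phi) when mu=0, so X(0)/X(pi/3) = 2 regardless of
        # the exact bracketed Bessel coefficient
        x0 = glia.lockin_xy(glia.simulate_beating(0.0, mu=0.0, depth_rad=NULL)).X
        r = glia.lockin_xy(glia.simulate_beating(np.pi / 3, mu=0.0, depth_rad=NULL))
        assert x0 / r.X == pytest.approx(2.0, rel=1e-10)
        y0 = glia.lockin_xy(glia.simulate_beating(0.0, mu=0.0, depth_rad=NULL)).Y
        assert abs(y0) < 1e-12

    def test_numeric_vs_closed_form_quadratures(self):
        worst = 0.0
        for phi in (-2.0, 0.3, 1.4):
            for mu in (0.0, 0.1, 0.3):
                for a in (2.0, NULL, 4.4):
                    sig = glia.simulate_beating(
                        phi, mu=mu, m=0.6, depth_rad=a, samples_per_period=512
                    )
                    r = glia.lockin_xy(sig)
                    xc, yc = glia.closed_form_xy(phi, a, 1.0, mu, 0.6)
                    worst = max(worst, abs(r.X - xc), abs(r.Y - yc))
        assert worst < 1e-8


class TestExtractPhase:
    def test_identity_at_zero(self):
        sig = glia.simulate_beating(0.0, depth_rad=NULL)
        r = glia.lockin_xy(sig)
        assert abs(glia.extract_phase(r, NULL)) < 1e-9

    def test_round_trip_dense(self):
        phis = np.linspace(-np.pi + 1e-3, np.pi - 1e-3, 181)
        for mu in (0.0, 0.05, 0.2):
            for phi in phis:
                sig = glia.simulate_beating(phi, mu=mu, m=0.8, depth_rad=NULL)
                r = glia.lockin_xy(sig)
                err = glia.extract_phase(r, NULL, mu) - phi
                assert abs((err + np.pi) % (2 * np.pi) - np.pi) < 1e-6

    def test_scale_invariance(self):
        sig = glia.simulate_beating(1.2, mu=0.1, m=0.5, depth_rad=NULL)
        r = glia.lockin_xy(sig)
        scaled = glia.LockinResult(X=17.3 * r.X, Y=17.3 * r.Y)
        assert glia.extract_phase(scaled, NULL, 0.1) == pytest.approx(
            glia.extract_phase(r, NULL, 0.1), abs=1e-14
        )

    def test_degenerate_quadratures_rejected(self):
        with pytest.raises(glia.GliaError):
            glia.extract_phase(glia.LockinResult(0.0, 0.0), NULL)

    def test_ram_immunity_at_null_depth(self):
        # the residual-amplitude-modulation offset (the mu*J1(depth) term in Y)
        # cannot be corrected because its scale relative to the quadratures is
        # unknown; at the J1 null it vanishes identically, so the mu-corrected
        # extraction becomes exact, while a detuned depth leaves a first-order
        # mu bias
        phi = 0.8

        def sensitivity(depth):
            outs = []
            for mu in (0.0, 1e-3):
                sig = glia.simulate_beating(phi, mu=mu, m=0.8, depth_rad=depth)
                outs.append(glia.extract_phase(glia.lockin_xy(sig), depth, mu=mu))
            return abs(outs[1] - outs[0]) / 1e-3

        assert sensitivity(NULL) < 1e-6
        assert sensitivity(NULL - 0.6) > 1e-3
        assert sensitivity(NULL) < 1e-2 * sensitivity(NULL - 0.6)

    def test_noise_round_trip_statistics(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 0.001, 100)
        phi0 = 0.5
        errs = []
        for dn in noise:
            sig = glia.simulate_beating(phi0 + dn, mu=0.05, m=0.8, depth_rad=NULL)
            errs.append(glia.extract_phase(glia.lockin_xy(sig), NULL, 0.05) - phi0)
        errs = np.array(errs)
        assert np.sqrt(np.mean(errs**2)) == pytest.approx(0.001, rel=0.5)
        assert abs(np.mean(errs)) < 1e-4
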