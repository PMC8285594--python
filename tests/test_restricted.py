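import numpy as np
import pytest
from scipy import special
from scipy.optimize import brentq

from spherelimits.restricted import (
    RestrictionGeometry,
    apparent_diffusivity,
    attenuation_exponent,
    bessel_extremum_roots,
    lorentzian_lambda,
)
from spherelimits.waveforms import GAMMA, make_lte_pgse, make_pte, make_ste, scale_to_b
from conftest import DELTA, BIG_DELTA, random_rotation


def van_gelderen_rho(g, delta, Delta, radius, d0, n_roots=60):
    """Independent time-domain series for sphere attenuation under a
    rectangular pulsed pair (Murday–Cotts/van Gelderen form)."""
    mu = bessel_extremum_roots("sphere", n_roots)
    am = (mu / radius) ** 2
    t = am * d0
    term = (
        2.0 * delta * t
        - 2.0
        + 2.0 * np.exp(-t * delta)
        + 2.0 * np.exp(-t * Delta)
        - np.exp(-t * (Delta - delta))
        - np.exp(-t * (Delta + delta))
    )
    coef = 1.0 / (t**2 * am * (am * radius**2 - 2.0))
    return 2.0 * GAMMA**2 * g**2 * np.sum(coef * term)


class TestBesselRoots:
    def test_first_roots_match_bracketed_search(self):
        # oracle: bracket sign changes of the derivative functions directly
        def j1p_cyl(x):
            return 0.5 * (special.j0(x) - special.jn(2, x))

        def j1p_sph(x):
            return special.spherical_jn(1, x, derivative=True)

        assert bessel_extremum_roots("cylinder", 1)[0] == pytest.approx(
            brentq(j1p_cyl, 1.5, 2.5, xtol=1e-13), abs=1e-10
        )
        assert bessel_extremum_roots("sphere", 1)[0] == pytest.approx(
            brentq(j1p_sph, 1.5, 2.5, xtol=1e-13), abs=1e-10
        )
        assert bessel_extremum_roots("cylinder", 1)[0] == pytest.approx(
            1.84118, abs=1e-5
        )
        assert bessel_extremum_roots("sphere", 1)[0] == pytest.approx(
            2.08158, abs=1e-5
        )

    @pytest.mark.parametrize("kind", ["cylinder", "sphere"])
    def test_roots_increase_and_satisfy_derivative(self, kind):
        roots = bessel_extremum_roots(kind, 30)
        assert np.all(np.diff(roots) > 0)
        if kind == "cylinder":
            resid = 0.5 * (special.j0(roots) - special.jn(2, roots))
        else:
            resid = special.spherical_jn(1, roots, derivative=True)
        assert np.max(np.abs(resid)) < 1e-10

    @pytest.mark.parametrize("kind", ["cylinder", "sphere"])
    def test_asymptotic_spacing_is_pi(self, kind):
        roots = bessel_extremum_roots(kind, 30)
        spacing = np.diff(roots)[19:29]
        assert np.allclose(spacing, np.pi, atol=5e-3)


class TestLorentzianSpectrum:
    def test_zero_frequency_and_parity(self):
        geom = RestrictionGeometry("sphere", 5.0, 3.0)
        assert lorentzian_lambda(geom, 0.0) == 0.0
        w = np.linspace(-20, 20, 41)
        lam = lorentzian_lambda(geom, w)
        assert np.all(lam >= 0)
        assert np.allclose(lam, lam[::-1])

    @pytest.mark.parametrize("kind,offset", [("cylinder", 1.0), ("sphere", 2.0)])
    def test_high_frequency_plateau_reaches_d0(self, kind, offset):
        # the plateau equals D0 · Σ Bᵢaᵢ; partial-sum oracle Σ 2/(μᵢ²−c)
        geom = RestrictionGeometry(kind, 5.0, 3.0, n_roots=30)
        mu = bessel_extremum_roots(kind, 30)
        partial = np.sum(2.0 / (mu**2 - offset))
        lam_inf = lorentzian_lambda(geom, 1e6)
        assert lam_inf == pytest.approx(3.0 * partial, rel=1e-6)
        assert lam_inf == pytest.approx(3.0, rel=1e-2)

    def test_dimensional_scaling(self):
        # λ/D0 depends only on ωR²/D0
        d0 = 3.0
        for w in (0.3, 1.0, 4.0):
            a = lorentzian_lambda(RestrictionGeometry("sphere", 3.0, d0), w)
            b = lorentzian_lambda(
                RestrictionGeometry("sphere", 6.0, d0), w / 4.0
            )
            assert a / d0 == pytest.approx(b / d0, rel=1e-12)

    def test_zero_radius_returns_zero(self):
        geom = RestrictionGeometry("sphere", 0.0, 3.0)
        assert lorentzian_lambda(geom, 5.0) == 0.0


class TestAttenuationExponent:
    def test_zero_radius_gives_unit_signal(self, pgse):
        geom = RestrictionGeometry("sphere", 0.0, 3.0)
        assert attenuation_exponent(pgse, geom) == 0.0

    @pytest.mark.parametrize("radius", [1.0, 2.0, 5.0, 8.0, 10.0])
    @pytest.mark.parametrize("b", [1.0, 6.0, 10.5])
    def test_sphere_pgse_matches_van_gelderen_series(self, radius, b):
        wf = scale_to_b(make_lte_pgse(DELTA, BIG_DELTA, 60.0), b)
        g = np.max(np.abs(wf.samples))
        rho = attenuation_exponent(
            wf, RestrictionGeometry("sphere", radius, 3.0)
        )
        rho_vg = van_gelderen_rho(g, DELTA, BIG_DELTA, radius, 3.0)
        assert rho == pytest.approx(rho_vg, rel=1e-2)

    def test_cylinder_requires_axis(self, pgse):
        geom = RestrictionGeometry("cylinder", 3.0, 2.0)
        with pytest.raises(ValueError, match="axis"):
            attenuation_exponent(pgse, geom)
        assert attenuation_exponent(pgse, geom, axis=(1, 0, 0)) > 0

    def test_ste_attenuates_sphere_more_than_lte(self):
        geom = RestrictionGeometry("sphere", 3.0, 3.0)
        b = 4.5
        rho = {
            "lte": attenuation_exponent(
                scale_to_b(make_lte_pgse(DELTA, BIG_DELTA, 60.0), b), geom
            ),
            "pte": attenuation_exponent(scale_to_b(make_pte(), b), geom),
            "ste": attenuation_exponent(scale_to_b(make_ste(), b), geom),
        }
        assert rho["ste"] > rho["pte"] > rho["lte"]

    def test_invariance_under_time_reversal_and_rotation(self, pgse, rng):
        geom = RestrictionGeometry("sphere", 5.0, 3.0)
        rho = attenuation_exponent(pgse, geom)
        assert attenuation_exponent(pgse.time_reversed(), geom) == pytest.approx(
            rho, rel=1e-9
        )
        cyl = RestrictionGeometry("cylinder", 4.0, 2.0)
        axis = np.array([0.0, 1.0, 0.0])
        rho_c = attenuation_exponent(pgse, cyl, axis=axis)
        rot = random_rotation(rng)
        rho_rot = attenuation_exponent(pgse.rotated(rot), cyl, axis=rot @ axis)
        assert rho_rot == pytest.approx(rho_c, rel=1e-9)

    def test_rho_linear_in_b_at_fixed_shape(self, pgse):
        geom = RestrictionGeometry("sphere", 5.0, 3.0)
        rho1 = attenuation_exponent(scale_to_b(pgse, 1.0), geom)
        rho9 = attenuation_exponent(scale_to_b(pgse, 9.0), geom)
        assert rho9 == pytest.approx(9.0 * rho1, rel=1e-6)

    @pytest.mark.parametrize("radius", [1.0, 5.0, 10.0])
    def test_root_truncation_converged(self, pgse, radius):
        rhos = [
            attenuation_exponent(
                pgse, RestrictionGeometry("sphere", radius, 3.0, n_roots=n)
            )
            for n in (20, 50)
        ]
        assert rhos[0] == pytest.approx(rhos[1], rel=1e-3)


def test_d_app_table_export(pgse):
    from spherelimits.restricted import d_app_table

    df = d_app_table(pgse, "sphere", radii=(1.0, 5.0, 9.0), d0=3.0)
    assert list(df.columns) == ["family", "b", "R", "D_app"]
    assert np.all(np.diff(df["D_app"]) > 0)  # grows with radius here


class TestApparentDiffusivity:
    def test_zero_radius(self, pgse):
        assert apparent_diffusivity(
            pgse, RestrictionGeometry("sphere", 0.0, 3.0)
        ) == 0.0

    def test_b_zero_raises(self):
        wf = make_lte_pgse(DELTA, BIG_DELTA, 0.0)
        with pytest.raises(ValueError):
            apparent_diffusivity(wf, RestrictionGeometry("sphere", 5.0, 3.0))

    def test_small_radii_barely_differentiated(self, pgse):
        wf = scale_to_b(pgse, 6.0)
        d = {
            r: apparent_diffusivity(wf, RestrictionGeometry("sphere", r, 3.0))
            for r in (1.0, 4.0, 8.0)
        }
        assert d[4.0] - d[1.0] < 0.1 * d[8.0]
        assert d[8.0] <= 3.0

    def test_pte_and_ste_more_sensitive_than_lte(self):
        b = 4.5
        lte = scale_to_b(make_lte_pgse(DELTA, BIG_DELTA, 60.0), b)
        pte = scale_to_b(make_pte(), b)
        ste = scale_to_b(make_ste(), b)
        for r in np.arange(2.0, 10.1, 2.0):
            geom = RestrictionGeometry("sphere", float(r), 3.0)
            d_lte = apparent_diffusivity(lte, geom)
            assert apparent_diffusivity(pte, geom) > d_lte
            assert apparent_diffusivity(ste, geom) > d_lte
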