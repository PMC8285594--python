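import numpy as np
import pytest

from spherelimits.fitting import (
    fit_model,
    fixed_fraction_scan,
    reduced_chi_square,
)
from spherelimits.signal_models import TissueParams, model_signal
from spherelimits.synthetic_data import PowderSignal, generate_dataset


def powder_with_noise(protocol, params, model, sigma, rng):
    """Powder table with independent per-point noise σ/√nᵢ (no shared-S0
    error), the regime in which the weighted residuals are homoscedastic."""
    ref = model_signal(params, protocol, model)
    ni = np.asarray(ref.n_dirs, dtype=float)
    noisy = ref.signal + sigma / np.sqrt(ni) * rng.standard_normal(len(ni))
    noisy[0] = 1.0
    return PowderSignal(family=ref.family, b=ref.b, b_delta=ref.b_delta,
                        n_dirs=ref.n_dirs, signal=np.clip(noisy, 0, None))


class TestFitModel:
    def test_noise_free_stick_ball_identifiable(self, protocol):
        truth = TissueParams(f_stick=0.5, f_ball=0.5, f_sphere=0.0,
                             d_par=2.0, d_ball=0.6)
        data = model_signal(truth, protocol, "stick_ball")
        fit = fit_model(data, protocol, "stick_ball", seed=0)
        assert fit.estimates.f_stick == pytest.approx(0.5, abs=1e-3)
        assert fit.estimates.d_par == pytest.approx(2.0, abs=1e-3)
        assert fit.estimates.d_ball == pytest.approx(0.6, abs=1e-3)
        assert fit.ssr < 1e-12

    def test_noise_free_sphere_model_identifiable(self, protocol):
        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)
        data = model_signal(truth, protocol, "stick_ball_sphere")
        fit = fit_model(data, protocol, "stick_ball_sphere", seed=0)
        assert fit.estimates.f_sphere == pytest.approx(0.4, abs=1e-3)
        assert fit.estimates.r_sphere == pytest.approx(8.0, abs=0.01)

    def test_too_few_points_raises(self, pgse_protocol):
        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)
        data = model_signal(truth, pgse_protocol, "stick_ball_sphere")
        # 5 points (b0 + 4 shells) cannot constrain 5 free params + margin
        with pytest.raises(ValueError):
            fit_model(data, pgse_protocol, "cylinder_ball_sphere", seed=0)

    def test_pinning_fixes_parameter(self, protocol):
        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)
        data = model_signal(truth, protocol, "stick_ball_sphere")
        fit = fit_model(data, protocol, "stick_ball_sphere",
                        fixed={"f_sphere": 0.2}, seed=0)
        assert fit.estimates.f_sphere == 0.2
        assert "f_sphere" not in fit.free_names
        assert fit.ci95["f_sphere"] == (0.2, 0.2)

    def test_releasing_pinned_parameter_never_raises_objective(self, protocol):
        rng = np.random.default_rng(0)
        for child in np.random.SeedSequence(21).spawn(5):
            truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                                 d_par=2.0, d_ball=0.6, r_sphere=6.0)
            data = generate_dataset(truth, protocol, snr=50.0, seed=child)
            pinned = fit_model(data, protocol, "stick_ball_sphere",
                               fixed={"f_sphere": 0.1}, n_starts=6, seed=1)
            warm = np.concatenate([[0.1], pinned.x])
            free = fit_model(data, protocol, "stick_ball_sphere",
                             n_starts=6, seed=2, x0_extra=[warm])
            assert free.ssr <= pinned.ssr * (1 + 1e-10)

    def test_fit_invariant_to_shell_order(self, protocol):
        # the objective sums per-shell residuals, so fits do not depend on
        # how the shells are enumerated
        from spherelimits.synthetic_data import AcquisitionProtocol

        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)
        data = generate_dataset(truth, protocol, snr=100.0, seed=5)
        fit = fit_model(data, protocol, "stick_ball_sphere", n_starts=6, seed=3)

        order = np.arange(len(protocol.shells))[::-1]
        proto_r = AcquisitionProtocol(
            shells=tuple(protocol.shells[i] for i in order),
            n_b0=protocol.n_b0,
        )
        data_r = PowderSignal(
            family=np.concatenate([[data.family[0]], data.family[1:][order]]),
            b=np.concatenate([[0.0], data.b[1:][order]]),
            b_delta=np.concatenate([[0.0], data.b_delta[1:][order]]),
            n_dirs=np.concatenate([[data.n_dirs[0]], data.n_dirs[1:][order]]),
            signal=np.concatenate([[data.signal[0]], data.signal[1:][order]]),
        )
        fit_r = fit_model(data_r, proto_r, "stick_ball_sphere", n_starts=6,
                          seed=3)
        assert fit_r.ssr == pytest.approx(fit.ssr, rel=1e-6)
        assert fit_r.estimates.r_sphere == pytest.approx(
            fit.estimates.r_sphere, rel=1e-3
        )


class TestConfidenceIntervals:
    def test_noise_free_intervals_are_tight(self, protocol):
        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)
        data = model_signal(truth, protocol, "stick_ball_sphere")
        fit = fit_model(data, protocol, "stick_ball_sphere", seed=0)
        for name, (lo, hi) in fit.ci95.items():
            mid = fit.x[fit.free_names.index(name)]
            assert hi - lo < 1e-3 * max(abs(mid), 1e-3)

    def test_interval_width_scales_with_noise(self, protocol, rng):
        truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                             d_par=2.0, d_ball=0.6, r_sphere=8.0)

        def mean_width(sigma, n=8):
            widths = []
            for _ in range(n):
                data = powder_with_noise(protocol, truth,
                                         "stick_ball_sphere", sigma, rng)
                fit = fit_model(data, protocol, "stick_ball_sphere",
                                n_starts=6, seed=0)
                lo, hi = fit.ci95["r_sphere"]
                if np.isfinite(hi - lo):
                    widths.append(hi - lo)
            return np.median(widths)

        ratio = mean_width(0.04) / mean_width(0.02)
        assert 1.4 < ratio < 2.6  # halving SNR roughly doubles the width


class TestReducedChiSquare:
    def test_zero_residuals(self):
        assert reduced_chi_square(np.zeros(10), 10, 3, 0.02) == 0.0

    def test_noise_variance_scaling(self):
        r = np.array([0.1, -0.2, 0.15, 0.05])
        a = reduced_chi_square(r, 4, 1, 0.02)
        b = reduced_chi_square(r, 4, 1, 0.04)
        assert a / b == pytest.approx(4.0)  # χ²red ∝ 1/σ²

    def test_nvoxel_factor(self):
        r = np.array([0.1, -0.2, 0.15, 0.05])
        assert reduced_chi_square(r, 4, 1, 0.02, n_voxel=4) == pytest.approx(
            4.0 * reduced_chi_square(r, 4, 1, 0.02)
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            reduced_chi_square(np.zeros(5), 5, 2, 0.0)
        with pytest.raises(ValueError):
            reduced_chi_square(np.zeros(5), 3, 3, 0.02)

    def test_calibrated_near_unity_for_correct_model(self, protocol, rng):
        truth = TissueParams(f_stick=0.5, f_ball=0.5, f_sphere=0.0,
                             d_par=2.0, d_ball=0.6)
        sigma = 0.02
        chis = []
        for _ in range(25):
            data = powder_with_noise(protocol, truth, "stick_ball", sigma, rng)
            fit = fit_model(data, protocol, "stick_ball", n_starts=6, seed=0,
                            sigma_noise=sigma)
            chis.append(fit.chi2_red)
        assert np.mean(chis) == pytest.approx(1.0, rel=0.2)


class TestCylinderDperpSurface:
    def test_bivariate_table_matches_direct_quadrature(self, protocol):
        from spherelimits.signal_models import (
            cylinder_dperp_interpolator,
            cylinder_dperp_surface,
        )

        wf = protocol.shells[0].waveform
        surf = cylinder_dperp_surface(wf)
        for d0 in (0.5, 2.0, 3.5):
            for r in (1.0, 4.0, 8.0):
                direct = float(cylinder_dperp_interpolator(wf, d0)(r))
                assert float(surf(d0, r, grid=False)) == pytest.approx(
                    direct, rel=1e-3, abs=1e-6
                )


class TestFixedRadiusScan:
    def test_two_time_dependencies_degenerate_at_large_radius(self, protocol):
        """With cylinders (R_c = 4 μm) and spheres both time-dependent, the
        goodness-of-fit valley over a pinned sphere radius is sharp when the
        true radius is 5 μm but flattens for 8 μm spheres, whose decay the
        cylinder compartment can partially mimic."""
        r_grid = np.arange(1.0, 10.01, 1.0)
        sharpness = {}
        for r_true in (5.0, 8.0):
            truth = TissueParams(f_stick=0.3, f_ball=0.3, f_sphere=0.4,
                                 d_par=2.0, d_ball=0.6, r_sphere=r_true,
                                 r_cylinder=4.0)
            data = generate_dataset(truth, protocol,
                                    model="cylinder_ball_sphere",
                                    snr=200.0, scenario="rician", seed=29)
            chis = []
            for r_pin in r_grid:
                fit = fit_model(data, protocol, "cylinder_ball_sphere",
                                fixed={"r_sphere": float(r_pin)},
                                n_starts=4, seed=2, sigma_noise=1.0 / 200.0)
                chis.append(fit.chi2_red)
            chis = np.asarray(chis)
            i_min = int(np.argmin(chis))
            assert r_grid[i_min] == pytest.approx(r_true, abs=1.0)
            neighbors = [chis[j] for j in (i_min - 1, i_min + 1)
                         if 0 <= j < len(chis)]
            sharpness[r_true] = float(np.mean(neighbors) / chis[i_min])
        assert sharpness[8.0] < sharpness[5.0]


class TestFixedFractionScan:
    def test_noise_free_nested_data_has_minimum_at_zero(self, protocol):
        truth = TissueParams(f_stick=0.5, f_ball=0.5, f_sphere=0.0,
                             d_par=2.0, d_ball=0.6)
        data = model_signal(truth, protocol, "stick_ball")
        curve, diag = fixed_fraction_scan(
            data, protocol, fraction_grid=np.linspace(0, 1, 11),
            sigma_noise=0.02, n_starts=4,
        )
        assert diag["f_sphere_min"] == 0.0

    def test_reference_mixture_shows_sharp_valley(self, protocol):
        # mixture with half the signal in 5-μm spheres at SNR 100: the scan
        # localizes the sphere fraction in a narrow chi-square valley
        truth = TissueParams(f_stick=0.25, f_ball=0.25, f_sphere=0.5,
                             d_par=2.0, d_ball=0.6, r_sphere=5.0)
        data = generate_dataset(truth, protocol, snr=100.0,
                                scenario="rician", seed=7)
        curve, diag = fixed_fraction_scan(data, protocol, sigma_noise=0.01,
                                          n_starts=6)
        assert abs(diag["f_sphere_min"] - 0.5) <= 0.075
        assert diag["valley_width"] < 0.15
        # the curve is continuous: neighboring chi2 jumps stay bounded
        chi = curve.loc[~curve["failed"], "chi2_red"].to_numpy()
        steps = np.abs(np.diff(chi))
        assert np.all(steps < 10 * max(np.median(steps), 1e-6) + 1e-9)
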