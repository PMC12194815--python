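"""Damped-sinusoid estimator: pole recovery, back-calculation, refinement."""

import numpy as np
import pytest

from fidcraft import (
    AcquisitionParams,
    FIDRecord,
    FitOptions,
    SpectralLine,
    amplitudes_at_origin,
    fit_segment,
    hankel_poles,
    refine,
    select_order,
    simulate_fid,
)
from fidcraft.damped_fit import FitResult
from fidcraft.nmr_domain import Provenance

PARAMS = AcquisitionParams(500.0, 2000.0, 2048, carrier_ppm=4.7)


def _fid_from(components, noise_sd=0.0, seed=None, params=PARAMS):
    """components: list of (amplitude, phase, freq_hz, decay)."""
    lines = [
        SpectralLine(f"c{i}", params.carrier_ppm + f / params.spectrometer_freq,
                     a, d, ph)
        for i, (a, ph, f, d) in enumerate(components)
    ]
    return simulate_fid(lines, params, noise_sd=noise_sd, seed=seed)


class TestHankelPoles:
    def test_single_component_recovered_to_1e6(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0)])
        (f, lam), = hankel_poles(fid, 1)
        assert f == pytest.approx(50.0, abs=1e-6)
        assert lam == pytest.approx(5.0, abs=1e-6)

    def test_two_close_components_resolved(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 3.0), (0.8, 0.5, 52.0, 3.0)])
        poles = sorted(hankel_poles(fid, 2))
        assert poles[0][0] == pytest.approx(50.0, abs=1e-3)
        assert poles[1][0] == pytest.approx(52.0, abs=1e-3)

    def test_noise_only_pole_pruned_downstream(self):
        rng = np.random.default_rng(0)
        noise = 0.01 * (rng.standard_normal(2048) + 1j * rng.standard_normal(2048))
        fid = FIDRecord(noise, PARAMS)
        assert len(hankel_poles(fid, 1)) == 1  # a pole is always produced
        fit = fit_segment(fid, FitOptions(max_order=1, refine=False))
        assert fit.order_used == 0  # ... but does not survive pruning

    def test_all_zero_input_rejected(self):
        fid = FIDRecord(np.zeros(2048, complex), PARAMS)
        with pytest.raises(ValueError, match="zero"):
            hankel_poles(fid, 1)


class TestSelectOrder:
    OPTS = FitOptions(max_order=10, sv_threshold=0.01)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10, 9, 0.001, 0.0009], 2),
            ([1.0], 1),
            ([5, 5, 5, 5], 4),  # all equal -> all kept (capped at max_order)
        ],
    )
    def test_threshold_rule(self, values, expected):
        assert select_order(np.array(values, float), self.OPTS) == expected

    def test_cap_at_max_order(self):
        opts = FitOptions(max_order=3, sv_threshold=0.01)
        assert select_order(np.ones(8), opts) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_order(np.array([]), self.OPTS)


class TestAmplitudesAtOrigin:
    def test_exact_for_known_pole(self):
        fid = _fid_from([(1.3, 0.4, 50.0, 5.0)])
        (c,) = amplitudes_at_origin(fid, [(50.0, 5.0)])
        assert abs(c) == pytest.approx(1.3, rel=1e-12)
        assert np.angle(c) == pytest.approx(0.4, abs=1e-12)

    def test_back_calculation_compensates_t_start(self):
        # t_start = 0.05 s, lam = 5 /s: stored first point is e^{-0.25} x
        # the t=0 amplitude; the fit must report the t=0 value.
        lam, t_start = 5.0, 0.05
        t = t_start + np.arange(2048) / PARAMS.sweep_width
        samples = 1.3 * np.exp((2j * np.pi * 50.0 - lam) * t)
        seg = FIDRecord(samples, PARAMS, t_start=t_start,
                        provenance=Provenance.SEGMENT)
        (c,) = amplitudes_at_origin(seg, [(50.0, lam)])
        assert abs(c) == pytest.approx(np.exp(lam * t_start) * abs(samples[0]),
                                       rel=1e-9)
        assert abs(c) == pytest.approx(1.3, rel=1e-9)

    def test_two_components_exact(self):
        fid = _fid_from([(1.0, 0.0, 40.0, 4.0), (0.5, 1.0, -30.0, 9.0)])
        c = amplitudes_at_origin(fid, [(40.0, 4.0), (-30.0, 9.0)])
        np.testing.assert_allclose(np.abs(c), [1.0, 0.5], rtol=1e-10)

    def test_ill_conditioned_basis_rejected(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0)])
        duplicated = [(50.0, 5.0), (50.0 + 1e-12, 5.0)]
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            amplitudes_at_origin(fid, duplicated)


class TestRefine:
    OPTS = FitOptions(max_order=4)

    def test_exact_initial_is_fixed_point(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0)])
        c = amplitudes_at_origin(fid, [(50.0, 5.0)])
        from fidcraft.nmr_domain import LorentzianComponent
        initial = FitResult(
            [LorentzianComponent(abs(c[0]), float(np.angle(c[0])), 50.0, 5.0)],
            residual_rms=0.0, order_used=1, converged=True,
        )
        out = refine(fid, initial, self.OPTS)
        assert out.residual_rms <= initial.residual_rms + 1e-15
        assert out.components[0].frequency == pytest.approx(50.0, abs=1e-8)

    def test_perturbed_poles_pulled_back(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0), (0.7, 0.3, 58.0, 12.0)])
        poles = [(49.5, 6.0), (58.8, 10.0)]
        c = amplitudes_at_origin(fid, poles)
        from fidcraft.nmr_domain import LorentzianComponent
        comps = [LorentzianComponent(abs(ck), float(np.angle(ck)), f, d)
                 for ck, (f, d) in zip(c, poles)]
        from fidcraft.damped_fit import _residual_rms
        rms0 = _residual_rms(fid, c, np.array([p[0] for p in poles]),
                             np.array([p[1] for p in poles]))
        initial = FitResult(comps, rms0, 2, True)
        out = refine(fid, initial, self.OPTS)
        assert out.residual_rms < rms0
        freqs = sorted(cp.frequency for cp in out.components)
        assert freqs[0] == pytest.approx(50.0, abs=1e-4)
        assert freqs[1] == pytest.approx(58.0, abs=1e-4)

    def test_residual_never_increases(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0)], noise_sd=0.02, seed=1)
        fit = fit_segment(fid, FitOptions(max_order=1, refine=False))
        out = refine(fid, fit, self.OPTS)
        assert out.residual_rms <= fit.residual_rms + 1e-15


class TestFitSegment:
    def test_noiseless_exact_recovery_all_parameters(self):
        truth = [(1.0, 0.2, 50.0, 5.0), (0.6, -0.7, -80.0, 12.0)]
        fid = _fid_from(truth)
        fit = fit_segment(fid, FitOptions(max_order=6, refine=False))
        assert fit.order_used == 2
        got = sorted(fit.components, key=lambda c: c.frequency)
        want = sorted(truth, key=lambda c: c[2])
        for comp, (a, ph, f, d) in zip(got, want):
            assert comp.amplitude == pytest.approx(a, rel=1e-6)
            assert comp.phase == pytest.approx(ph, abs=1e-6)
            assert comp.frequency == pytest.approx(f, abs=1e-6)
            assert comp.decay == pytest.approx(d, rel=1e-6)

    def test_s0_identity(self):
        fid = _fid_from([(1.0, 0.2, 50.0, 5.0), (0.6, -0.7, -80.0, 12.0)])
        fit = fit_segment(fid, FitOptions(max_order=6, refine=False))
        total = sum(c.complex_amplitude for c in fit.components)
        assert total == pytest.approx(fid.samples[0], rel=1e-8)

    def test_recovery_error_decreases_with_noise(self):
        errors = []
        for noise in (0.05, 0.01, 0.002):
            errs = []
            for seed in range(5):
                fid = _fid_from([(1.0, 0.0, 50.0, 5.0)], noise_sd=noise,
                                seed=seed)
                fit = fit_segment(fid, FitOptions(max_order=1))
                errs.append(abs(fit.components[0].amplitude - 1.0))
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_pruned_components_are_reported_not_lost(self):
        fid = _fid_from([(1.0, 0.0, 50.0, 5.0)], noise_sd=0.01, seed=3)
        fit = fit_segment(fid, FitOptions(max_order=4, sv_threshold=0.001,
                                          refine=False))
        assert fit.order_used + len(fit.diagnostics["pruned"]) >= 2
        for entry in fit.diagnostics["pruned"]:
            assert set(entry) == {"frequency", "decay", "amplitude", "reason"}

    def test_growing_pole_clamped_and_flagged(self, caplog):
        t = np.arange(512) / 2000.0
        samples = np.exp((2j * np.pi * 30 + 0.5) * t)  # growing signal
        p = AcquisitionParams(500.0, 2000.0, 512)
        fid = FIDRecord(samples, p)
        import logging
        with caplog.at_level(logging.WARNING, logger="fidcraft.damped_fit"):
            fit = fit_segment(fid, FitOptions(max_order=1, refine=False))
        assert fit.diagnostics["clamped_poles"] >= 1
        assert all(c.decay > 0 for c in fit.components)
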