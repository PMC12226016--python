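"""Estimation layer: T2 fits, EPG dictionary, IR fitting, MT conversion."""

import numpy as np
import pytest

from memri.epg import mese_echo_train
from memri.errors import (DomainError, FitDegenerateError,
                          PhysicalValidityError)
from memri.relaxometry import (average_echo_trains, build_epg_dictionary,
                               fit_biexp_ir, fit_t2_dictionary,
                               fit_t2_monoexp, mt_from_biexp)
from memri.signals import SignalRecord
from memri.twopool import (BiexpComponents, InversionState, SequenceParams,
                           TwoPoolParams, biexp_recovery_signal,
                           rates_from_twopool)
from oracles import isochromat_mese

TE_GRID_MS = np.geomspace(9.5, 290.5, 50)
TI_GRID_MS = np.geomspace(4.0, 10079.4, 25)


def sese_record(t2_ms, s0=1.0, noise=0.0, rng=None):
    clean = s0 * np.exp(-TE_GRID_MS / t2_ms)
    if noise:
        clean = np.abs(clean + rng.normal(0.0, noise, clean.shape))
    return SignalRecord("c", "b", te_ms=TE_GRID_MS, magnitude=clean,
                        sigma=noise)


def ir_record(comp, noise=0.0, rng=None):
    y = biexp_recovery_signal(comp, TI_GRID_MS / 1e3)
    if noise:
        y = y + rng.normal(0.0, noise, y.shape)
    return SignalRecord("c", "b", te_ms=np.zeros_like(TI_GRID_MS),
                        magnitude=np.abs(y), ti_ms=TI_GRID_MS, sigma=noise)


class TestMonoexpT2:
    def test_noise_free_recovery_at_baseline(self):
        fit = fit_t2_monoexp(sese_record(49.7))
        assert fit.t2 * 1e3 == pytest.approx(49.7, rel=1e-6)
        assert fit.s0 == pytest.approx(1.0, rel=1e-6)

    def test_constant_signal_is_degenerate(self):
        rec = SignalRecord("c", "b", te_ms=TE_GRID_MS,
                           magnitude=np.ones_like(TE_GRID_MS))
        with pytest.raises(FitDegenerateError):
            fit_t2_monoexp(rec)

    def test_growing_signal_is_degenerate(self):
        rec = SignalRecord("c", "b", te_ms=TE_GRID_MS,
                           magnitude=np.exp(TE_GRID_MS / 100.0))
        with pytest.raises(FitDegenerateError):
            fit_t2_monoexp(rec)

    def test_fitted_t2_monotone_in_true_t2(self, rng):
        true = np.linspace(20.0, 120.0, 12)
        fits = [fit_t2_monoexp(sese_record(t, noise=2e-3, rng=rng)).t2
                for t in true]
        assert np.all(np.diff(fits) > 0)


class TestEpgDictionary:
    SEQ = SequenceParams(echo_spacing=7.5e-3, n_echoes_per_ti=20,
                         refocusing_angles=180.0)

    def test_ideal_cpmg_limit_is_exponential(self):
        d = build_epg_dictionary([0.04, 0.08], 1.5, self.SEQ,
                                 slice_profile=np.ones(4))
        n = np.arange(20)
        for i, t2 in enumerate((0.04, 0.08)):
            ideal = np.exp(-n * 7.5e-3 / t2)  # normalized to first echo
            assert np.max(np.abs(d.curves[i] - ideal)) <= 1e-10

    def test_matches_isochromat_oracle_at_120_degrees(self):
        epg = mese_echo_train(0.08, 1.5, 7.5e-3, 20, 120.0)
        brute = isochromat_mese(0.08, 1.5, 7.5e-3, 20, 120.0)
        assert np.max(np.abs(epg - brute)) <= 1e-6

    def test_stimulated_echoes_lift_late_echoes(self):
        seq = SequenceParams(echo_spacing=7.5e-3, n_echoes_per_ti=20,
                             refocusing_angles=120.0)
        d = build_epg_dictionary([0.08], 1.5, seq,
                                 slice_profile=np.ones(1))
        pure = np.exp(-np.arange(20) * 7.5e-3 / 0.08)
        assert np.all(d.curves[0][5:] > pure[5:])

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            build_epg_dictionary([], 1.5, self.SEQ)


class TestDictionaryFit:
    def _dictionary(self, angles=180.0):
        seq = SequenceParams(echo_spacing=7.5e-3, n_echoes_per_ti=20,
                             refocusing_angles=angles)
        grid = np.arange(5.0, 300.5, 1.0) / 1e3
        return build_epg_dictionary(grid, 1.5, seq,
                                    slice_profile=np.ones(8))

    def _record(self, magnitude):
        te = 7.5 * np.arange(1, 21)
        return SignalRecord("c", "b", te_ms=te, magnitude=magnitude)

    def test_self_consistency(self):
        d = self._dictionary()
        idx = int(np.argmin(np.abs(d.t2_grid - 0.040)))
        fit = fit_t2_dictionary(self._record(d.curves[idx]), d)
        assert fit.t2 == pytest.approx(d.t2_grid[idx])
        assert fit.residual_norm < 1e-6

    def test_nearest_grid_recovery_off_grid_truth(self):
        d = self._dictionary(angles=140.0)
        seq = SequenceParams(echo_spacing=7.5e-3, n_echoes_per_ti=20,
                             refocusing_angles=140.0)
        truth = build_epg_dictionary([0.041], 1.5, seq,
                                     slice_profile=np.ones(8))
        fit = fit_t2_dictionary(self._record(truth.curves[0]), d)
        assert fit.t2 * 1e3 == pytest.approx(41.0, abs=1e-9)

    def test_white_noise_flagged_low_confidence(self, rng):
        d = self._dictionary()
        fit = fit_t2_dictionary(
            self._record(rng.normal(0.0, 1.0, 20)), d)
        assert fit.low_confidence

    def test_grid_mismatch_rejected(self):
        d = self._dictionary()
        rec = SignalRecord("c", "b", te_ms=9.5 * np.arange(1, 21),
                           magnitude=np.ones(20))
        with pytest.raises(DomainError):
            fit_t2_dictionary(rec, d)


class TestEchoAveraging:
    def _train_record(self, trains, tis=None):
        trains = np.asarray(trains, float)
        n_ti, n_echo = trains.shape
        tis = np.arange(1, n_ti + 1) * 100.0 if tis is None else tis
        return SignalRecord(
            "c", "b", te_ms=np.tile(9.5 * np.arange(1, n_echo + 1), n_ti),
            magnitude=trains.ravel(),
            ti_ms=np.repeat(tis, n_echo), sigma=0.01)

    def test_identical_echoes_average_to_value(self):
        rec = self._train_record(np.full((5, 16), 0.7))
        avg = average_echo_trains(rec)
        assert np.allclose(avg.magnitude, 0.7)
        assert avg.sigma == pytest.approx(0.01 / 4.0)

    def test_mean_bounded_by_train_extremes(self):
        train = np.exp(-np.arange(1, 17) * 9.5 / 50.0)
        avg = average_echo_trains(self._train_record(train[None, :]))
        assert train[-1] < avg.magnitude[0] < train[0]

    def test_ragged_trains_rejected(self):
        rec = SignalRecord(
            "c", "b", te_ms=np.array([9.5, 19.0, 9.5]),
            magnitude=np.ones(3), ti_ms=np.array([100.0, 100.0, 200.0]))
        with pytest.raises(DomainError):
            average_echo_trains(rec)

    def test_noise_scales_inverse_sqrt_n(self, rng):
        sigma, n_echo, n_rep = 0.01, 16, 1000
        noise = rng.normal(0.0, sigma, (n_rep, n_echo))
        sd_of_means = np.std(noise.mean(axis=1))
        assert sd_of_means == pytest.approx(sigma / 4.0, rel=0.2)


class TestBiexpFit:
    def test_noise_free_recovery(self, baseline_components):
        fit = fit_biexp_ir(ir_record(baseline_components))
        c, t = fit.components, baseline_components
        for got, want in [(c.r1_plus, t.r1_plus),
                          (c.r1_minus, t.r1_minus),
                          (c.bf_plus, t.bf_plus),
                          (c.bf_minus, t.bf_minus)]:
            assert got == pytest.approx(want, rel=1e-4)

    def test_noise_free_sweep_random_operating_points(self, rng):
        """Oracle equivalence across the physiological parameter range.

        Forward signals from rates_from_twopool are refit and must give
        back all four components to 1e-4 relative.
        """
        for _ in range(100):
            psr = rng.uniform(0.01, 0.15)
            kmf = rng.uniform(5.0, 30.0)
            r1 = rng.uniform(0.3, 1.5)
            truth = rates_from_twopool(
                TwoPoolParams(r1f=r1, r1m=r1, kmf=kmf, psr=psr),
                InversionState(-1.0, 0.83))
            fit = fit_biexp_ir(ir_record(truth))
            c = fit.components
            assert c.r1_plus == pytest.approx(truth.r1_plus, rel=1e-4)
            assert c.r1_minus == pytest.approx(truth.r1_minus, rel=1e-4)
            assert c.bf_plus == pytest.approx(truth.bf_plus, rel=1e-4)
            assert c.bf_minus == pytest.approx(truth.bf_minus, rel=1e-4)

    def test_monoexponential_input_flagged_degenerate(self):
        y = np.abs(1.0 - 2.0 * np.exp(-0.5 * TI_GRID_MS / 1e3))
        rec = SignalRecord("c", "b", te_ms=np.zeros_like(TI_GRID_MS),
                           magnitude=y, ti_ms=TI_GRID_MS)
        fit = fit_biexp_ir(rec)
        assert fit.degenerate

    def test_psr_unbiased_under_one_percent_noise(
            self, baseline_components, rng):
        """Median PSR over Monte-Carlo replicates at sigma = 1% of the
        equilibrium magnitude stays within 3% of truth."""
        psrs = []
        for _ in range(200):
            fit = fit_biexp_ir(ir_record(baseline_components, noise=0.01,
                                         rng=rng))
            psrs.append(mt_from_biexp(fit.components, 0.83).psr)
        assert np.median(psrs) == pytest.approx(0.0377, rel=0.03)

    def test_too_few_inversion_times_rejected(self):
        rec = SignalRecord("c", "b", te_ms=np.zeros(4),
                           magnitude=np.ones(4),
                           ti_ms=np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(DomainError):
            fit_biexp_ir(rec)


class TestMTConversion:
    def test_baseline_operating_point(self, baseline_components):
        mt = mt_from_biexp(baseline_components, 0.83)
        assert mt.psr == pytest.approx(0.0377, rel=1e-10)
        assert mt.kmf == pytest.approx(14.8, rel=1e-10)

    def test_round_trip_is_algebraic_inverse(self, rng):
        for _ in range(50):
            psr = rng.uniform(0.005, 0.2)
            kmf = rng.uniform(2.0, 40.0)
            r1 = rng.uniform(0.2, 2.0)
            delta_m = rng.uniform(-0.5, 0.99)
            comp = rates_from_twopool(
                TwoPoolParams(r1f=r1, r1m=r1, kmf=kmf, psr=psr),
                InversionState(-1.0, delta_m))
            mt = mt_from_biexp(comp, delta_m)
            assert mt.psr == pytest.approx(psr, rel=1e-10)
            assert mt.kmf == pytest.approx(kmf, rel=1e-10)

    def test_eq9_consistency_invariant(self, baseline_components):
        mt = mt_from_biexp(baseline_components, 0.83)
        gap = baseline_components.r1_plus - baseline_components.r1_minus
        assert mt.kmf * (1.0 + mt.psr) == pytest.approx(gap, rel=1e-12)

    def test_vanishing_fast_amplitude_flagged(self):
        comp = BiexpComponents(15.0, 0.5, 0.0, -2.0)
        mt = mt_from_biexp(comp, 0.83)
        assert mt.psr == 0.0
        assert not mt.physical

    def test_negative_psr_raises_with_values(self):
        comp = BiexpComponents(15.0, 0.5, 0.05, -2.0)
        with pytest.raises(PhysicalValidityError) as err:
            mt_from_biexp(comp, 0.83)
        assert err.value.values["psr"] < 0
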