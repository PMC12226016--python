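"""Mixed-effects inference, Dunnett comparisons, in vivo contrasts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from memri.errors import DomainError
from memri.stats import (dunnett_pvalue, dunnett_vs_control,
                         fit_fractional_slope, fit_invivo_interaction)
from memri.stats import test_group_interaction as group_interaction
from memri.synthetic import (StudyDataset, StudyDesign,
                             generate_invivo_series,
                             generate_parameter_dataset)

NOISE_FREE = dict(batch_sd_frac=0.0, noise_sd_frac=0.0,
                  kmf_noise_sd_frac=0.0)


class TestFractionalSlope:
    def test_noise_free_recovery_is_exact(self):
        ds = generate_parameter_dataset(StudyDesign(**NOISE_FREE))
        fit = fit_fractional_slope(ds, "t2_ms")
        assert fit.intercept == pytest.approx(49.7, rel=1e-8)
        assert fit.fractional_slope == pytest.approx(0.00687, rel=1e-8)
        fit_psr = fit_fractional_slope(ds, "psr")
        assert fit_psr.fractional_slope == pytest.approx(-0.00542,
                                                         rel=1e-8)

    def test_flat_response_gives_null_slope(self, rng):
        ds = generate_parameter_dataset(StudyDesign(
            slopes={"t2_ms": 0.0, "psr": 0.0, "kmf_hz": 0.0},
            seed=int(rng.integers(2 ** 31))))
        fit = fit_fractional_slope(ds, "t2_ms")
        assert abs(fit.fractional_slope) < 5e-3
        assert fit.slope_p > 0.05

    def test_reml_matches_profiled_likelihood_oracle(self, rng):
        """statsmodels REML vs a direct profiled restricted-likelihood
        search on a small three-batch table."""
        from oracles import profiled_reml
        ds = generate_parameter_dataset(StudyDesign(n_batches=3,
                                                    seed=42))
        df = ds.params
        y = df["t2_ms"].to_numpy()
        X = np.column_stack([np.ones(len(df)), df["delta_vm"].to_numpy()])
        beta, sigma_b2, sigma2 = profiled_reml(y, X,
                                               df["batch_id"].to_numpy())
        fit = fit_fractional_slope(ds, "t2_ms")
        assert fit.intercept == pytest.approx(beta[0], rel=1e-6)
        assert fit.raw_slope == pytest.approx(beta[1], rel=1e-6)
        assert fit.random_intercept_sd ** 2 == pytest.approx(sigma_b2,
                                                             rel=1e-4)

    def test_unit_rescaling_leaves_fractional_slope_invariant(self):
        ds = generate_parameter_dataset(StudyDesign(seed=9))
        fit_ms = fit_fractional_slope(ds, "t2_ms")
        scaled = StudyDataset(params=ds.params.assign(
            t2_ms=ds.params["t2_ms"] * 1e-3))
        fit_s = fit_fractional_slope(scaled, "t2_ms")
        assert fit_s.fractional_slope == pytest.approx(
            fit_ms.fractional_slope, rel=1e-6)
        assert fit_s.intercept == pytest.approx(fit_ms.intercept * 1e-3,
                                                rel=1e-6)

    def test_kmf_slope_rarely_significant_at_study_noise(self):
        """The generating exchange-rate relation is near-null relative to
        its measurement noise; the slope test should rarely reject."""
        rejections = 0
        for k in range(100):
            ds = generate_parameter_dataset(StudyDesign(seed=3000 + k))
            if fit_fractional_slope(ds, "kmf_hz").slope_p < 0.05:
                rejections += 1
        assert rejections <= 15


class TestGroupInteraction:
    def test_identical_slopes_rarely_flagged(self):
        hits = 0
        for k in range(200):
            ds = generate_parameter_dataset(StudyDesign(seed=1000 + k))
            if group_interaction(ds, ["t2_ms"])["t2_ms"] < 0.05:
                hits += 1
        assert hits <= 20  # type-I error near nominal 5%

    def test_doubled_barium_slope_detected(self):
        hits = 0
        for k in range(200):
            design = StudyDesign(seed=2000 + k)
            ds = generate_parameter_dataset(design)
            df = ds.params.copy()
            ba = df["group"] == "barium"
            # regenerate the barium condition with a doubled slope
            extra = 49.7 * 0.00687 * df.loc[ba, "delta_vm"]
            df.loc[ba, "t2_ms"] = df.loc[ba, "t2_ms"] + extra
            if group_interaction(StudyDataset(params=df),
                                      ["t2_ms"])["t2_ms"] < 0.05:
                hits += 1
        assert hits >= 160  # >= 80% power

    def test_single_group_rejected(self):
        ds = generate_parameter_dataset(StudyDesign())
        only_k = ds.params[ds.params.group != "barium"]
        subset = StudyDataset(params=only_k)
        with pytest.raises(DomainError):
            group_interaction(subset)


class TestDunnett:
    def test_single_comparison_reduces_to_t_test(self):
        for t in (0.5, 1.5, 2.1, 3.0):
            p = dunnett_pvalue(t, [np.sqrt(0.5)], 28)
            assert p == pytest.approx(2 * sps.t(28).sf(t), abs=2e-5)

    def test_adjusted_p_monotone_in_family_size(self):
        lam = np.sqrt(0.5)
        ps = [dunnett_pvalue(2.0, [lam] * k, 28) for k in range(1, 7)]
        assert np.all(np.diff(ps) > 0)

    def test_matches_scipy_reference(self, rng):
        """Cross-check against the independent multivariate-t
        implementation in scipy on a balanced random dataset."""
        from scipy.stats import dunnett as scipy_dunnett
        ds = generate_parameter_dataset(StudyDesign(n_batches=8, seed=4))
        df = ds.params
        control = df[df.group == "control"]["t2_ms"].to_numpy()
        labels = [l for l in df.label.unique() if l != "K4.2"]
        samples = [df[df.label == l]["t2_ms"].to_numpy() for l in labels]
        ref = scipy_dunnett(*samples, control=control,
                            random_state=np.random.default_rng(0))
        ours = dunnett_vs_control(ds, "t2_ms")
        got = ours.table.set_index("label")["p_adj"]
        for lab, p_ref in zip(labels, ref.pvalue):
            assert got[lab] == pytest.approx(p_ref, abs=5e-3)

    def test_noise_free_equal_means_give_p_one(self):
        ds = generate_parameter_dataset(StudyDesign(
            slopes={"t2_ms": 0.0, "psr": 0.0, "kmf_hz": 0.0},
            **NOISE_FREE))
        res = dunnett_vs_control(ds, "t2_ms")
        assert (res.table["p_adj"] == 1.0).all()
        assert "K4.2" not in set(res.table["label"])

    def test_adjusted_never_below_unadjusted(self):
        ds = generate_parameter_dataset(StudyDesign(seed=77))
        res = dunnett_vs_control(ds, "psr")
        dof = len(ds.params) - ds.params["label"].nunique()
        for row in res.table.itertuples():
            raw = 2 * sps.t(dof).sf(abs(row.t))
            assert row.p_adj >= raw - 1e-9

    def test_missing_control_rejected(self):
        ds = generate_parameter_dataset(StudyDesign())
        broken = StudyDataset(
            params=ds.params[ds.params.group != "control"])
        with pytest.raises(DomainError):
            dunnett_vs_control(broken, "t2_ms")


class TestInVivoInteraction:
    def test_zero_variance_contrast_is_exact(self):
        series = generate_invivo_series(rat_sd=0.0, noise_sd=0.0)
        res = fit_invivo_interaction(series).set_index("epoch")
        assert res.loc[3, "contrast_ms"] == pytest.approx(1.10 - 0.181,
                                                          abs=1e-10)
        assert res.loc[2, "contrast_ms"] == pytest.approx(0.684 - 0.104,
                                                          abs=1e-10)

    def test_identical_arm_effects_give_null_contrasts(self):
        series = generate_invivo_series(
            modulation_effects=(0.0, 0.1, 0.2, 0.1),
            control_effects=(0.0, 0.1, 0.2, 0.1),
            rat_sd=0.0, noise_sd=0.0)
        res = fit_invivo_interaction(series)
        assert np.allclose(res["contrast_ms"], 0.0, atol=1e-10)

    def test_epoch3_contrast_power(self):
        hits = 0
        for k in range(200):
            series = generate_invivo_series(seed=4000 + k)
            res = fit_invivo_interaction(series).set_index("epoch")
            if res.loc[3, "p"] < 0.05:
                hits += 1
        assert hits >= 160

    def test_model_se_matches_rat_level_bootstrap(self, rng):
        series = generate_invivo_series(seed=8)
        df = series.data
        res = fit_invivo_interaction(series).set_index("epoch")
        mod3 = df[(df.arm == "modulation")
                  & (df.epoch == 3)]["delta_t2_ms"].to_numpy()
        con3 = df[(df.arm == "control")
                  & (df.epoch == 3)]["delta_t2_ms"].to_numpy()
        boots = []
        for _ in range(2000):
            bm = rng.choice(mod3, mod3.size, replace=True)
            bc = rng.choice(con3, con3.size, replace=True)
            boots.append(bm.mean() - bc.mean())
        assert res.loc[3, "se"] == pytest.approx(np.std(boots), rel=0.15)

    def test_single_arm_rejected(self):
        series = generate_invivo_series()
        sub = series.data[series.data.arm == "control"]
        from memri.synthetic import InVivoSeries
        with pytest.raises(DomainError):
            fit_invivo_interaction(InVivoSeries(data=sub.copy()))
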