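"""Unfolding kinetics, chevron arms, and the salt phi-value decomposition."""

import math

import numpy as np
import pytest

from saltfold import (
    FoldingSummary,
    GeneratorSpec,
    KineticTrace,
    build_energy_diagram,
    compute_beta_urea,
    compute_salt_ddG,
    derive_folding_rate,
    fit_lnk_vs_sqrt_ionic_strength,
    fit_unfolding_arm,
    fit_unfolding_trace,
    gen_unfolding_trace,
)
from saltfold.constants import rt_kj
from saltfold.kinetics import NoDecayError

# Published folding/unfolding rate constants used as worked inputs:
# (ku low salt, ku high salt, kf low salt, kf high salt)
ABP_RATES = {"ku_low": 0.088, "ku_high": 0.12, "kf_low": 0.5, "kf_high": 297.0}
FYN_RATES = {"ku_low": 0.08, "ku_high": 0.09, "kf_low": 5.5, "kf_high": 25.0}


class TestTraceFit:
    def test_noiseless_rate_recovered_exactly(self):
        trace = gen_unfolding_trace(0.1, 1.0, 0.0,
                                    spec=GeneratorSpec(seed=0))
        k, amp, off, err = fit_unfolding_trace(trace)
        assert k == pytest.approx(0.1, rel=1e-9)
        assert amp == pytest.approx(1.0, rel=1e-9)
        assert off == pytest.approx(0.0, abs=1e-9)

    def test_flat_trace_raises_no_decay(self):
        trace = KineticTrace(time=np.linspace(0, 60, 30),
                             signal=np.full(30, 0.4))
        with pytest.raises(NoDecayError):
            fit_unfolding_trace(trace)

    def test_noisy_median_relative_error_under_5pct(self):
        """SNR 20 (amplitude 1, noise 0.05), 200 seeds."""
        errs = []
        for seed in range(200):
            trace = gen_unfolding_trace(
                0.1, 1.0, 0.1, spec=GeneratorSpec(seed=seed, noise_sd=0.05))
            k, *_ = fit_unfolding_trace(trace)
            errs.append(abs(k - 0.1) / 0.1)
        assert np.median(errs) < 0.05


class TestUnfoldingArm:
    def test_exact_line(self):
        pts = [(u, math.exp(-6.0 + 0.5 * u)) for u in (7.0, 8.0, 9.0)]
        arm = fit_unfolding_arm(pts)
        assert arm.ln_ku0 == pytest.approx(-6.0, rel=1e-9)
        assert arm.m_ku == pytest.approx(0.5, rel=1e-9)
        assert arm.ku0 == pytest.approx(math.exp(-6.0), rel=1e-9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_unfolding_arm([(7.0, 0.1), (8.0, -0.2), (9.0, 0.3)])

    def test_slope_unbiased_over_seeds(self):
        rng_master = np.random.default_rng(42)
        slopes = []
        for _ in range(500):
            u = np.array([7.0, 7.5, 8.0, 8.5, 9.0])
            lnk = -6.0 + 0.5 * u + rng_master.normal(0, 0.05, 5)
            slopes.append(fit_unfolding_arm(list(zip(u, np.exp(lnk)))).m_ku)
        assert abs(np.mean(slopes) - 0.5) < 0.005


class TestDerivedQuantities:
    def test_kf_equals_ku_at_zero_stability(self):
        kf, _ = derive_folding_rate(0.3, 0.0, 298.15)
        assert kf == pytest.approx(0.3, rel=1e-12)

    def test_kf_inverts_published_rate_ratio(self):
        # dG0 chosen so kf/ku = 0.5/0.088 at 303.15 K
        T = 303.15
        dG0 = rt_kj(T) * math.log(0.5 / 0.088)
        kf, _ = derive_folding_rate(0.088, dG0, T)
        assert kf == pytest.approx(0.5, rel=1e-12)

    def test_kf_hand_evaluation(self):
        kf, _ = derive_folding_rate(1.0, 10.0, 298.15)
        assert kf == pytest.approx(math.exp(10.0 / (0.008314 * 298.15)),
                                   rel=1e-9)
        assert kf == pytest.approx(56.5, rel=2e-3)

    @pytest.mark.parametrize(
        "m_ku, m_eq, T, expected",
        [
            (0.0, 5.0, 303.15, 1.0),
            (5.0 / rt_kj(303.15), 5.0, 303.15, 0.0),
            (0.177, 5.0, 303.15, 1.0 - rt_kj(303.15) * 0.177 / 5.0),
        ],
    )
    def test_beta_urea(self, m_ku, m_eq, T, expected):
        beta, _ = compute_beta_urea(m_ku, m_eq, T)
        assert beta == pytest.approx(expected, abs=1e-12)
        if m_ku == 0.177:
            assert beta == pytest.approx(0.911, abs=1e-3)


class TestSaltDdG:
    def test_published_fyn_decomposition(self):
        """600 mM NaCl jump on the Fyn SH3 R40N rates gives the published
        ddG pair at one decimal place."""
        res = compute_salt_ddG(FYN_RATES["kf_low"], FYN_RATES["kf_high"],
                               FYN_RATES["ku_low"], FYN_RATES["ku_high"],
                               T=293.15)
        assert round(res.ddG_DN, 1) == -3.4
        assert round(res.ddG_Ddagger, 1) == -3.7
        assert res.phi_f_salt > 1.0

    def test_identical_rates_give_zero_and_undefined_phi(self):
        res = compute_salt_ddG(1.0, 1.0, 0.1, 0.1, 298.15)
        assert res.ddG_Ddagger == 0.0
        assert res.ddG_DN == 0.0
        assert not res.phi_defined
        assert math.isnan(res.phi_f_salt)

    def test_pure_folding_rate_change_gives_phi_one(self):
        res = compute_salt_ddG(1.0, 10.0, 0.1, 0.1, 298.15)
        expected = -rt_kj(298.15) * math.log(10.0)
        assert res.ddG_Ddagger == pytest.approx(expected, rel=1e-12)
        assert res.ddG_DN == pytest.approx(expected, rel=1e-12)
        assert res.phi_f_salt == pytest.approx(1.0, abs=1e-12)
        assert expected == pytest.approx(-5.708, abs=2e-3)

    def test_phi_is_temperature_invariant(self):
        """RT cancels in the ratio of logs: phi identical across T."""
        ref = compute_salt_ddG(**{"kf_low": 0.5, "kf_high": 297.0,
                                  "ku_low": 0.088, "ku_high": 0.12},
                               T=273.15).phi_f_salt
        for T in np.linspace(273.15, 373.15, 11):
            for rates in (ABP_RATES, FYN_RATES):
                phi_T = compute_salt_ddG(
                    rates["kf_low"], rates["kf_high"],
                    rates["ku_low"], rates["ku_high"], T=T).phi_f_salt
                phi_ref = compute_salt_ddG(
                    rates["kf_low"], rates["kf_high"],
                    rates["ku_low"], rates["ku_high"], T=293.15).phi_f_salt
                assert abs(phi_T - phi_ref) < 1e-12
        assert ref == pytest.approx(
            compute_salt_ddG(0.5, 297.0, 0.088, 0.12, T=350.0).phi_f_salt,
            abs=1e-12)

    def test_unfolding_rate_ratio_matches_published_rounding(self):
        ratio = ABP_RATES["ku_high"] / ABP_RATES["ku_low"]
        assert round(ratio, 1) == 1.4

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            compute_salt_ddG(0.0, 1.0, 0.1, 0.1)


class TestLnKvsSqrtI:
    def test_exact_line(self):
        pts = [(I, math.exp(1.0 + 2.0 * math.sqrt(I)))
               for I in (0.09, 0.25, 0.49)]
        slope, intercept, r2 = fit_lnk_vs_sqrt_ionic_strength(pts)
        assert slope == pytest.approx(2.0, rel=1e-9)
        assert intercept == pytest.approx(1.0, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_curved_data_has_r2_below_one(self):
        pts = [(I, math.exp(1.0 + 2.0 * math.sqrt(I) + 3.0 * I))
               for I in (0.04, 0.16, 0.36, 0.64)]
        *_, r2 = fit_lnk_vs_sqrt_ionic_strength(pts)
        assert r2 < 1.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_lnk_vs_sqrt_ionic_strength([(0.1, 0.5)])


class TestEnergyDiagram:
    @staticmethod
    def summary(label, ku, kf, T=303.15):
        return FoldingSummary(condition=label, ku0=ku, kf0=kf, m_eq=5.0,
                              m_ku=0.1, beta_urea=0.9, temperature=T)

    def test_identical_conditions_are_flat(self):
        s = self.summary("a", 0.1, 1.0)
        d = build_energy_diagram(s, s)
        assert d.ddG_Ddagger == 0.0
        assert d.ddG_DN == 0.0

    @pytest.mark.parametrize("rates", [ABP_RATES, FYN_RATES])
    def test_consistent_with_ddG_decomposition(self, rates):
        low = self.summary("low", rates["ku_low"], rates["kf_low"])
        high = self.summary("high", rates["ku_high"], rates["kf_high"])
        d = build_energy_diagram(low, high)
        res = compute_salt_ddG(rates["kf_low"], rates["kf_high"],
                               rates["ku_low"], rates["ku_high"], T=303.15)
        assert d.ddG_Ddagger == pytest.approx(res.ddG_Ddagger, rel=1e-12)
        assert d.ddG_DN == pytest.approx(res.ddG_DN, rel=1e-12)

    def test_temperature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            build_energy_diagram(self.summary("a", 0.1, 1.0, T=293.15),
                                 self.summary("b", 0.1, 1.0, T=303.15))


class TestFullPipelineRecovery:
    def test_trace_to_arm_recovery_within_3pct(self):
        """Triplicate trace sets at 5 urea values, SNR 50: trace fits ->
        unfolding arm -> extrapolated ku0 lands within 3% of truth (median
        over 100 seeds).  Triplicates mirror the assay's repeated wells."""
        ku0_true, m_ku_true = 0.088, 0.177
        errs = []
        for seed in range(100):
            points = []
            for k, u in enumerate([7.0, 7.5, 8.0, 8.5, 9.0]):
                ku_true = ku0_true * math.exp(m_ku_true * u)
                fits = []
                for rep in range(3):
                    spec = GeneratorSpec(seed=10_000 * seed + 10 * k + rep,
                                         noise_sd=0.02)
                    trace = gen_unfolding_trace(ku_true, 1.0, 0.1, spec=spec,
                                                urea=u)
                    kfit, *_ = fit_unfolding_trace(trace)
                    fits.append(kfit)
                points.append((u, np.mean(fits)))
            arm = fit_unfolding_arm(points)
            errs.append(abs(arm.ku0 - ku0_true) / ku0_true)
        assert np.median(errs) < 0.03
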