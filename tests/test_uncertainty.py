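"""Delta-method error decomposition: frozen examples, oracles, pooling."""

import numpy as np
import pytest

from trixrd import (
    CalibrationFit,
    CompositionEstimate,
    CompositionVector,
    GenerativeParams,
    RIRSet,
    average_replicates,
    calibration_variance,
    estimate_with_uncertainty,
    intrinsic_variance,
    monte_carlo_se_oracle,
)
from trixrd.uncertainty import rir_partials


class TestIntrinsicVariance:
    def test_worked_example_aragonite(self, pub_fit, worked_heights, mix_50_25_25):
        """phi1^2 = 43.1*0.25/857.1, bracket 0.9662, denominator 2.6150."""
        var = intrinsic_variance(mix_50_25_25, worked_heights, pub_fit)
        assert np.sqrt(var[0]) == pytest.approx(0.0682, abs=2e-4)
        # frozen full-precision values from the closed form
        assert np.sqrt(var) == pytest.approx(
            [0.06815415, 0.04534981, 0.05718782], rel=1e-6
        )

    def test_pure_sample_boundary_zero(self, pub_fit):
        var = intrinsic_variance([1.0, 0.0, 0.0], [900.0, 0.0, 0.0], pub_fit)
        assert var == pytest.approx([0.0, 0.0, 0.0], abs=0)

    def test_doubling_heights_halves_variance(self, pub_fit, worked_heights,
                                              mix_50_25_25):
        v1 = intrinsic_variance(mix_50_25_25, worked_heights, pub_fit)
        v2 = intrinsic_variance(mix_50_25_25, 2 * worked_heights, pub_fit)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_inconsistent_input_error(self, pub_fit):
        with pytest.raises(ValueError, match="inconsistent"):
            intrinsic_variance([0.5, 0.25, 0.25], [0.0, 100.0, 50.0], pub_fit)

    def test_negative_kappa_error(self, worked_heights, mix_50_25_25):
        fit = CalibrationFit.from_values(3.51, 1.49, 43.1)
        object.__setattr__(fit, "kappa", -1.0)
        with pytest.raises(ValueError, match="kappa"):
            intrinsic_variance(mix_50_25_25, worked_heights, fit)

    def test_error_largest_at_half(self, pub_fit):
        """For fixed total intensity and kappa the intrinsic SE of a mineral
        peaks at a 50% weight fraction and vanishes at the boundaries (with
        equal RIRs the closed form reduces to kappa*f*(1-f)/Lambda)."""
        fit = CalibrationFit.from_values(1.0, 1.0, 43.1)
        fracs = np.array([0.02, 0.1, 0.3, 0.5, 0.7, 0.9, 0.98])
        ses = []
        for f in fracs:
            pi = CompositionVector(np.array([f, (1 - f) / 2, (1 - f) / 2]))
            lam = 3000 * pi.fractions
            ses.append(np.sqrt(intrinsic_variance(pi, lam, fit)[0]))
        ses = np.array(ses)
        assert ses.argmax() == np.abs(fracs - 0.5).argmin()
        assert ses[0] < ses[3] and ses[-1] < ses[3]
        assert ses[3] == pytest.approx(np.sqrt(43.1 * 0.25 / 3000), rel=1e-9)
        # the asymmetric published RIRs shift the peak only slightly
        skew = [
            np.sqrt(intrinsic_variance(
                CompositionVector(np.array([f, (1 - f) / 2, (1 - f) / 2])),
                3000 * (pub_fit.rirs.k * np.array([f, (1 - f) / 2, (1 - f) / 2]))
                / (pub_fit.rirs.k @ np.array([f, (1 - f) / 2, (1 - f) / 2])),
                pub_fit)[0])
            for f in (0.02, 0.4, 0.98)
        ]
        assert skew[1] > skew[0] and skew[1] > skew[2]


class TestCalibrationVariance:
    def test_zero_covariance_gives_zero(self, worked_heights):
        fit = CalibrationFit.from_values(3.51, 1.49, 43.1)
        assert calibration_variance(worked_heights, fit) == pytest.approx(
            [0, 0, 0], abs=0
        )

    def test_worked_example_partials_and_sigma(self, pub_fit, worked_heights):
        grads = rir_partials(worked_heights, pub_fit.rirs)
        assert grads[0, 0] == pytest.approx(0.0356, abs=2e-4)
        assert grads[0, 1] == pytest.approx(0.0839, abs=2e-4)
        var = calibration_variance(worked_heights, pub_fit)
        assert np.sqrt(var[0]) == pytest.approx(0.0206, abs=2e-4)

    def test_partials_match_finite_differences(self, pub_rirs):
        """Analytic dpi/dk within 1e-6 relative of central differences."""
        from trixrd import estimate_weight_fractions

        h = np.array([857.1, 1504.3, 638.6])
        grads = rir_partials(h, pub_rirs)
        eps = 1e-6
        for col, j in enumerate((1, 2)):
            k_hi, k_lo = pub_rirs.k.copy(), pub_rirs.k.copy()
            k_hi[j] += eps
            k_lo[j] -= eps
            fd = (
                estimate_weight_fractions(h, RIRSet(k_hi)).fractions
                - estimate_weight_fractions(h, RIRSet(k_lo)).fractions
            ) / (2 * eps)
            assert grads[:, col] == pytest.approx(fd, rel=1e-6)

    def test_bad_covariance_rejected(self, worked_heights):
        with pytest.raises(ValueError, match="Cauchy-Schwarz"):
            CalibrationFit.from_values(
                3.51, 1.49, 43.1, var_k2=0.01, var_k3=0.01, cov_k2k3=0.5
            )


class TestCombinedEstimate:
    def test_worked_example_combined(self, pub_fit, worked_heights):
        est = estimate_with_uncertainty(worked_heights, pub_fit)
        assert est.se_combined[0] == pytest.approx(0.0712, abs=2e-4)
        assert est.se_combined**2 == pytest.approx(
            est.se_intrinsic**2 + est.se_calibration**2, abs=1e-15
        )

    def test_calibration_adds_four_to_five_percent(self, pub_fit, worked_heights):
        """With the published (k2, k3) covariance the combined SE exceeds the
        intrinsic SE by about 4-5% for the 50/25/25 worked example."""
        est = estimate_with_uncertainty(worked_heights, pub_fit)
        inflation = est.se_combined[0] / est.se_intrinsic[0] - 1
        assert 0.03 < inflation < 0.06

    def test_bimineral_input(self, pub_fit):
        from trixrd import PeakHeightVector

        est = estimate_with_uncertainty(
            PeakHeightVector.from_values(800, 600, None), pub_fit
        )
        assert est.composition[0] == pytest.approx(800 / (800 + 600 / 3.51))
        assert est.composition[2] == 0.0
        assert est.se_combined[2] == 0.0
        assert 2 in est.flags["absent"]

    def test_pure_input_all_zero_se(self, pub_fit):
        from trixrd import PeakHeightVector

        est = estimate_with_uncertainty(
            PeakHeightVector.from_values(900, None, None), pub_fit
        )
        assert est.composition.fractions == pytest.approx([1, 0, 0])
        assert est.se_combined == pytest.approx([0, 0, 0], abs=0)
        assert est.flags["boundary"] == [0, 1, 2]


class TestMonteCarloOracle:
    def test_zero_noise_zero_sd(self, pub_rirs, mix_50_25_25):
        sd = monte_carlo_se_oracle(
            mix_50_25_25, GenerativeParams(pub_rirs, 0.0, 3000), 1000, seed=1
        )
        assert sd == pytest.approx([0, 0, 0], abs=0)

    def test_oracle_confirms_closed_form(self, pub_fit, pub_rirs, mix_50_25_25,
                                         worked_heights):
        sd = monte_carlo_se_oracle(
            mix_50_25_25, GenerativeParams(pub_rirs, 43.1, 3000),
            n_sims=100_000, seed=7,
        )
        closed = np.sqrt(
            intrinsic_variance(mix_50_25_25, worked_heights, pub_fit)
        )
        assert sd == pytest.approx(closed, rel=0.05)

    def test_deterministic_given_seed(self, pub_rirs, mix_50_25_25):
        params = GenerativeParams(pub_rirs, 43.1, 3000)
        a = monte_carlo_se_oracle(mix_50_25_25, params, 2000, seed=3)
        b = monte_carlo_se_oracle(mix_50_25_25, params, 2000, seed=3)
        assert np.array_equal(a, b)


def _est(fracs, se_i, se_c=0.0, sid="s1"):
    se_i = np.full(3, se_i, dtype=float)
    se_c = np.full(3, se_c, dtype=float)
    return CompositionEstimate(
        composition=CompositionVector(np.asarray(fracs, float)),
        se_intrinsic=se_i,
        se_calibration=se_c,
        se_combined=np.sqrt(se_i**2 + se_c**2),
        sample_id=sid,
    )


class TestReplicateAveraging:
    def test_root_n_law_for_identical_estimates(self):
        ests = [_est([0.5, 0.3, 0.2], 0.06) for _ in range(4)]
        pooled = average_replicates(ests)
        assert pooled.se_intrinsic == pytest.approx(np.full(3, 0.06 / 2))
        assert pooled.se_combined == pytest.approx(np.full(3, 0.03))

    def test_two_estimate_worked_case(self):
        ests = [
            _est([0.40, 0.35, 0.25], 0.05),
            _est([0.60, 0.15, 0.25], 0.05),
        ]
        pooled = average_replicates(ests)
        assert pooled.composition[0] == pytest.approx(0.50)
        assert pooled.se_intrinsic[0] == pytest.approx(0.0354, abs=2e-4)

    def test_calibration_error_carried_unreduced(self):
        ests = [_est([0.5, 0.3, 0.2], 0.06, se_c=0.01) for _ in range(9)]
        pooled = average_replicates(ests)
        assert pooled.se_intrinsic == pytest.approx(np.full(3, 0.02))
        assert pooled.se_calibration == pytest.approx(np.full(3, 0.01))

    def test_single_estimate_identity(self):
        e = _est([0.5, 0.3, 0.2], 0.05)
        assert average_replicates([e]) is e

    def test_empty_list_error(self):
        with pytest.raises(ValueError, match="empty"):
            average_replicates([])
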