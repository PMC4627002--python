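"""Sampling laws: truncated negative binomial and integer-truncated PERT."""

import numpy as np
import pytest
from scipy import stats

import ltfbias as lb
from ltfbias.distributions import PertSpec, TruncatedNegBinSpec


def _enumerated_pmf(spec):
    """Independent oracle: raw pmf over the support, renormalized by hand."""
    k = np.arange(spec.lower, spec.upper + 1)
    p = stats.nbinom.pmf(k, spec.shape, spec.probability)
    return k, p / p.sum()


class TestTruncatedNegBin:
    def test_one_point_support(self, rng):
        spec = TruncatedNegBinSpec(0.5, 2, 7, 7)
        draws = lb.sample_trunc_negbin(spec, rng, size=1000)
        assert np.all(draws == 7)

    def test_samples_respect_bounds(self, rng):
        spec = TruncatedNegBinSpec(0.02, 3, 0, 338)
        draws = lb.sample_trunc_negbin(spec, rng, size=100_000)
        assert draws.min() >= 0 and draws.max() <= 338

    def test_empirical_pmf_matches_enumeration(self, rng):
        # total-variation distance against hand-normalized pmf; 5e6 draws so
        # the sampling-noise floor (~0.4*sqrt(cells)/sqrt(n)) sits well below
        # the 0.005 bound
        spec = TruncatedNegBinSpec(0.02, 3, 0, 338)
        draws = lb.sample_trunc_negbin(spec, rng, size=5_000_000)
        k, pmf = _enumerated_pmf(spec)
        emp = np.bincount(draws, minlength=339) / draws.size
        tv = 0.5 * np.abs(emp - pmf).sum()
        assert tv < 0.005

    def test_empirical_mode_matches_pmf_argmax(self, rng):
        spec = TruncatedNegBinSpec(0.02, 3, 0, 338)
        k, pmf = _enumerated_pmf(spec)
        analytic_mode = k[np.argmax(pmf)]
        # the untruncated mode (r-1)(1-p)/p = 98 lies inside the support, but
        # pmf(97) and pmf(98) tie to machine precision, so accept either cell
        assert analytic_mode in (97, 98)
        draws = lb.sample_trunc_negbin(spec, rng, size=1_000_000)
        emp_mode = np.bincount(draws).argmax()
        # the pmf is flat near its peak; allow neighbouring cells
        assert abs(emp_mode - 98) <= 3
        assert spec.mode() == analytic_mode

    def test_empirical_mean_matches_enumeration(self, rng):
        spec = TruncatedNegBinSpec(0.027, 2, 0, 338)
        k, pmf = _enumerated_pmf(spec)
        mean = (k * pmf).sum()
        var = ((k - mean) ** 2 * pmf).sum()
        draws = lb.sample_trunc_negbin(spec, rng, size=1_000_000)
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TruncatedNegBinSpec(0.0, 3, 0, 338)
        with pytest.raises(ValueError):
            TruncatedNegBinSpec(0.5, 3, 10, 5)
        with pytest.raises(ValueError):
            TruncatedNegBinSpec(0.5, 0, 0, 338)


class TestFitNegBinFromMode:
    @pytest.mark.parametrize(
        "likeliest, tol", [(104, 6), (37, 2)],
        ids=["peak-104", "peak-37"],
    )
    def test_fitted_mode_near_likeliest(self, likeliest, tol):
        spec = lb.fit_negbin_from_mode(likeliest, 0, 338)
        k, pmf = _enumerated_pmf(spec)
        assert abs(k[np.argmax(pmf)] - likeliest) <= tol

    def test_boundary_mode_zero_uses_shape_one(self):
        spec = lb.fit_negbin_from_mode(0, 0, 338)
        assert spec.shape == 1
        k, pmf = _enumerated_pmf(spec)
        assert k[np.argmax(pmf)] == 0

    def test_precondition(self):
        with pytest.raises(ValueError):
            lb.fit_negbin_from_mode(400, 0, 338)


class TestPert:
    def test_degenerate_point(self, rng):
        spec = PertSpec(0.0, 0.0, 0.0)
        assert lb.sample_pert_int(spec, rng) == 0
        assert np.all(lb.sample_pert_int(spec, rng, size=100) == 0)

    def test_continuous_mean_matches_closed_form(self, rng):
        # classic PERT mean (min + 4*mode + max) / 6
        spec = PertSpec(0.0, 21.2, 104.0)
        assert spec.mean() == pytest.approx((0 + 4 * 21.2 + 104) / 6)
        x = lb.sample_pert(spec, rng, size=1_000_000)
        sd = stats.beta.std(spec.alpha, spec.beta) * 104
        assert abs(x.mean() - spec.mean()) < 3 * sd / np.sqrt(x.size)

    def test_integer_histogram_matches_bin_integrals(self, rng):
        # worked allocation example: mode 3/4 of 21
        spec = PertSpec(0.0, 15.75, 21.0)
        draws = lb.sample_pert_int(spec, rng, size=1_000_000)
        assert draws.min() >= 0 and draws.max() <= 21
        # analytic probability of each integer bin [k, k+1) of the scaled beta
        edges = np.arange(23) / 21.0
        cdf = stats.beta.cdf(np.clip(edges, 0, 1), spec.alpha, spec.beta)
        probs = np.diff(cdf)
        emp = np.bincount(draws, minlength=22) / draws.size
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.005

    def test_lambda_zero_limit_is_uniform(self, rng):
        spec = PertSpec(2.0, 9.0, 12.0, lam=1e-6)
        x = lb.sample_pert(spec, rng, size=200_000)
        assert x.mean() == pytest.approx((2 + 12) / 2, abs=0.05)

    def test_truncation_is_toward_zero(self, rng):
        spec = PertSpec(0.0, 3.5, 7.0)
        cont = lb.sample_pert(spec, np.random.default_rng(5), size=1000)
        ints = lb.sample_pert_int(spec, np.random.default_rng(5), size=1000)
        assert np.all(ints == np.floor(cont).astype(int))

    def test_mode_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            PertSpec(0.0, 25.0, 21.0)
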