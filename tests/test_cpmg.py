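"""CPMG dispersion: R2,eff, error propagation, Rex rule, exchange fits."""

import math

import numpy as np
import pytest

from tandemrrm import cpmg
from tandemrrm.errors import ConfigurationError, InputError
from tandemrrm.synthetic_data import NU_GRID_HZ, gen_cpmg


def profile_from(nu, r2eff, sigma):
    return cpmg.DispersionProfile("p", 1, np.asarray(nu, float),
                                  np.asarray(r2eff, float),
                                  np.asarray(sigma, float))


# ---------------------------------------------------------------- R2,eff
class TestR2eff:
    @pytest.mark.parametrize(
        "i, i0, t, expected",
        [
            (100.0, 100.0, 0.04, 0.0),
            (100.0 * math.exp(-1.0), 100.0, 0.04, 25.0),
            (80.0, 100.0, 0.04, -math.log(0.8) / 0.04),
        ],
    )
    def test_closed_form(self, i, i0, t, expected):
        assert cpmg.compute_r2eff(i, i0, t) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_intensity(self):
        vals = [cpmg.compute_r2eff(i, 100.0, 0.04) for i in (20, 40, 60, 80)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonanalyzable_amplitude(self):
        with pytest.raises(InputError):
            cpmg.compute_r2eff(-1.0, 100.0, 0.04)


# ---------------------------------------------------------------- errors
def make_dataset(r2eff, noise, rng, n_rep=3, r2_args=(0.04, 1.0)):
    t_rlx, i0 = r2_args
    reps = {0.0: i0 * (1 + noise * rng.standard_normal(n_rep))}
    for nu, r in zip(NU_GRID_HZ[: len(r2eff)], r2eff):
        amp = i0 * math.exp(-r * t_rlx)
        reps[float(nu)] = amp * (1 + noise * rng.standard_normal(n_rep))
    return cpmg.DispersionDataset("pk", 1, reps, t_rlx)


class TestPropagateErrors:
    def test_formula_instance(self):
        # sigma_I/I = 1% at T_rlx = 40 ms propagates to 0.25 /s
        reps = {0.0: np.array([1.0]), 100.0: np.array([0.5])}
        ds = cpmg.DispersionDataset("pk", 1, reps, 0.04)
        prof = cpmg.propagate_errors(ds, sigma_i=0.005)
        assert prof.sigma[0] == pytest.approx(0.25)

    def test_identical_replicates_floored(self):
        reps = {0.0: np.array([1.0, 1.0]), 50.0: np.array([0.6, 0.6]),
                200.0: np.array([0.6, 0.6])}
        ds = cpmg.DispersionDataset("pk", 1, reps, 0.04)
        prof = cpmg.propagate_errors(ds)
        assert np.all(prof.sigma > 0)

    def test_no_replicates_requires_sigma(self):
        reps = {0.0: np.array([1.0]), 50.0: np.array([0.6])}
        ds = cpmg.DispersionDataset("pk", 1, reps, 0.04)
        with pytest.raises(ConfigurationError):
            cpmg.propagate_errors(ds)
        prof = cpmg.propagate_errors(ds, sigma_i=0.01)
        assert len(prof.nu) == 1

    def test_monte_carlo_calibration(self):
        # empirical spread of R2,eff matches the propagated sigma within 5%
        rng = np.random.default_rng(8)
        noise, t_rlx, true_r2 = 0.01, 0.04, 12.0
        amp = math.exp(-true_r2 * t_rlx)
        draws = amp * (1 + noise * rng.standard_normal(100000))
        r2 = -np.log(draws[draws > 0]) / t_rlx
        propagated = noise * amp / (amp * t_rlx)     # sigma_I/(I T)
        assert r2.std() == pytest.approx(propagated, rel=0.05)

    def test_negative_intensity_excluded(self):
        reps = {0.0: np.array([1.0, 1.0]), 50.0: np.array([0.5, 0.52]),
                100.0: np.array([-0.1, -0.1])}
        ds = cpmg.DispersionDataset("pk", 1, reps, 0.04)
        prof = cpmg.propagate_errors(ds)
        assert list(prof.nu) == [50.0]


# ---------------------------------------------------------------- Rex rule
class TestRexTest:
    def test_flat_profile_not_significant(self):
        prof = profile_from([25, 500, 1500], [12.0, 12.0, 12.0], [0.3] * 3)
        rt = cpmg.rex_test(prof)
        assert rt.rex == 0.0 and not rt.significant

    def test_direct_arithmetic(self):
        prof = profile_from([25, 1500], [20.0, 15.0], [1.0, 1.0])
        rt = cpmg.rex_test(prof)
        assert rt.rex == pytest.approx(5.0)
        assert rt.sigma_rex == pytest.approx(math.sqrt(2.0))
        assert rt.significant

    def test_null_false_positive_rate(self):
        """1.65 sigma one-sided rule yields ~5% false positives on nulls."""
        datasets, _ = gen_cpmg("flat", seed=17, n_peaks=10000)
        hits = sum(
            cpmg.rex_test(cpmg.propagate_errors(ds)).significant
            for ds in datasets
        )
        rate = hits / len(datasets)
        # binomial sd at n=1e4 is 0.22%; allow for the pooled-sigma
        # estimation effect on top of it
        assert rate == pytest.approx(0.05, abs=0.01)


# ---------------------------------------------------------------- Bloch-McConnell
class TestBlochMcConnell:
    def test_no_exchange_is_flat(self):
        prof = cpmg.simulate_bloch_mcconnell(
            dict(k_ex=1000, p_b=0.0, delta_omega=300, r2a=10.0), NU_GRID_HZ
        )
        np.testing.assert_allclose(prof.r2eff, 10.0, atol=1e-9)

    def test_zero_shift_difference_is_flat(self):
        prof = cpmg.simulate_bloch_mcconnell(
            dict(k_ex=1000, p_b=0.05, delta_omega=0.0, r2a=10.0, r2b=10.0),
            NU_GRID_HZ,
        )
        np.testing.assert_allclose(prof.r2eff, 10.0, atol=1e-9)

    def test_fast_limit_closed_form(self):
        # k_ex/delta_omega = 10: numerical and Luz-Meiboom curves agree < 2%
        p = dict(k_ex=2000.0, p_b=0.05, delta_omega=200.0, r2a=12.0, r2b=12.0)
        prof = cpmg.simulate_bloch_mcconnell(p, NU_GRID_HZ)
        phi = 0.95 * 0.05 * 200.0**2
        ana = cpmg.fast_exchange_model(NU_GRID_HZ, 12.0, phi, 2000.0)
        assert np.max(np.abs(prof.r2eff - ana) / ana) < 0.02

    def test_profile_monotone_and_bounded(self):
        p = dict(k_ex=800.0, p_b=0.04, delta_omega=400.0, r2a=11.0, r2b=13.0)
        prof = cpmg.simulate_bloch_mcconnell(p, NU_GRID_HZ)
        assert np.all(np.diff(prof.r2eff) < 1e-6)        # non-increasing
        floor = 0.96 * 11.0 + 0.04 * 13.0                # pop-weighted rate
        assert np.all(prof.r2eff >= floor - 1e-6)

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(InputError):
            cpmg.simulate_bloch_mcconnell(
                dict(k_ex=-5.0, p_b=0.1, delta_omega=100, r2a=10), NU_GRID_HZ
            )


# ---------------------------------------------------------------- fits
class TestExchangeFits:
    def test_fast_self_consistency(self):
        clean = cpmg.fast_exchange_model(NU_GRID_HZ, 12.0, 5000.0, 1000.0)
        fit = cpmg.fit_fast_exchange(
            profile_from(NU_GRID_HZ, clean, np.full(len(NU_GRID_HZ), 0.05))
        )
        assert fit.r2_0 == pytest.approx(12.0, rel=1e-6)
        assert fit.phi_ex == pytest.approx(5000.0, rel=1e-6)
        assert fit.k_ex == pytest.approx(1000.0, rel=1e-6)

    def test_slow_self_consistency(self):
        clean = cpmg.slow_exchange_model(NU_GRID_HZ, 10.0, 8.0, 1500.0)
        fit = cpmg.fit_slow_exchange(
            profile_from(NU_GRID_HZ, clean, np.full(len(NU_GRID_HZ), 0.05))
        )
        assert fit.r2_0 == pytest.approx(10.0, rel=1e-6)
        assert fit.k_ab == pytest.approx(8.0, rel=1e-6)
        assert fit.delta_omega == pytest.approx(1500.0, rel=1e-6)

    def test_slow_regime_oracle_recovery(self):
        # noiseless numerical-oracle data; the analytic slow limit carries a
        # small O(p_b) bias, recovery within 15%
        p = dict(k_ex=100.0, p_b=0.05, delta_omega=1500.0, r2a=10.0, r2b=10.0)
        prof = cpmg.simulate_bloch_mcconnell(p, NU_GRID_HZ, sigma=0.05)
        fit = cpmg.fit_slow_exchange(prof)
        assert fit.k_ab == pytest.approx(100.0 * 0.05, rel=0.15)

    def test_fast_regime_prefers_fast_model(self):
        p = dict(k_ex=1500.0, p_b=0.03, delta_omega=300.0, r2a=12.0, r2b=12.0)
        prof = cpmg.simulate_bloch_mcconnell(p, NU_GRID_HZ, sigma=0.05)
        fast = cpmg.fit_fast_exchange(prof)
        slow = cpmg.fit_slow_exchange(prof)
        assert fast.aicc < slow.aicc

    def test_kex_recovery_median(self):
        """Median recovered k_ex over 100 noisy replicates within 10%."""
        p = dict(k_ex=1500.0, p_b=0.03, delta_omega=300.0, r2a=12.0, r2b=12.0)
        base = cpmg.simulate_bloch_mcconnell(p, NU_GRID_HZ)
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(100):
            noisy = base.r2eff * (1 + 0.02 * rng.standard_normal(len(NU_GRID_HZ)))
            prof = profile_from(NU_GRID_HZ, noisy, 0.02 * base.r2eff)
            estimates.append(cpmg.fit_fast_exchange(prof).k_ex)
        assert np.median(estimates) == pytest.approx(1500.0, rel=0.10)

    def test_fit_invariant_to_nu_order(self):
        clean = cpmg.fast_exchange_model(NU_GRID_HZ, 12.0, 4000.0, 800.0)
        sig = np.full(len(NU_GRID_HZ), 0.05)
        fwd = cpmg.fit_fast_exchange(profile_from(NU_GRID_HZ, clean, sig))
        perm = np.random.default_rng(0).permutation(len(NU_GRID_HZ))
        rev = cpmg.fit_fast_exchange(
            profile_from(NU_GRID_HZ[perm], clean[perm], sig[perm])
        )
        assert rev.k_ex == pytest.approx(fwd.k_ex, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            cpmg.fit_fast_exchange(profile_from([25, 100, 500],
                                                [14, 13, 12], [0.1] * 3))


# ---------------------------------------------------------------- dataset level
class TestAnalyzeDataset:
    def test_all_flat_noiseless_has_zero_flags(self):
        datasets, _ = gen_cpmg("flat", seed=0, n_peaks=20, noise=0.0)
        table = cpmg.analyze_dataset(datasets)
        assert int(table.significant.sum()) == 0

    def test_single_dataset_single_row(self):
        datasets, _ = gen_cpmg("flat", seed=1, n_peaks=1)
        table = cpmg.analyze_dataset(datasets)
        assert len(table) == 1

    def test_planted_cohorts_recovered(self):
        """RRM1-like vs RRM2-like: planted counts and Rex ratio recovered."""
        tps, ratios = [], []
        for seed in (1, 2, 3):
            res = {}
            for preset, n_planted in (("rrm1_like", 9), ("rrm2_like", 19)):
                ds, truth = gen_cpmg(preset, seed=seed)
                table = cpmg.analyze_dataset(ds)
                m = table.merge(truth, on="peak_id", suffixes=("", "_t"))
                tp = int((m.significant & m.exchanging).sum())
                tps.append((preset, n_planted, tp))
                res[preset] = m
            r1 = res["rrm1_like"]
            r2 = res["rrm2_like"]
            got = (r2[r2.exchanging].rex.mean() / r1[r1.exchanging].rex.mean())
            planted = (
                res["rrm2_like"][res["rrm2_like"].exchanging].rex_t.mean()
                / res["rrm1_like"][res["rrm1_like"].exchanging].rex_t.mean()
            )
            ratios.append((got, planted))
        for preset, n_planted, tp in tps:
            assert abs(tp - n_planted) <= 2
        for got, planted in ratios:
            assert got == pytest.approx(planted, rel=0.30)
            assert 2.0 < got < 6.0        # three-to-four-times regime

    def test_fitted_kex_in_fast_regime_range(self):
        """Fitted k_ex of flagged residues falls in the ~200-2000/s band."""
        ds, truth = gen_cpmg("rrm2_like", seed=5)
        table = cpmg.analyze_dataset(ds, model="fast")
        fitted = table[table.significant & table.k_ex.notna()]
        assert len(fitted) >= 10
        assert ((fitted.k_ex > 100) & (fitted.k_ex < 4000)).mean() >= 0.8
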