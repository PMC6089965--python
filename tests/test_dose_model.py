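"""Domain-flipping dose-response model: closed form vs Monte-Carlo oracle,
fitting, steepness and LOD inversion."""

import math

import numpy as np
import pytest

from zeptoassay import dose_model as dm


class TestExpectedResponse:
    def test_zero_dose(self):
        assert dm.expected_response(0.0, dm.equal_domain_model(6)) == 0.0

    def test_single_domain_closed_form(self):
        model = dm.equal_domain_model(1, r_max=1.0)
        assert dm.expected_response(math.log(2), model) == pytest.approx(0.5, rel=1e-12)

    def test_saturation(self):
        model = dm.DomainModel(fractions=np.array([0.5, 0.5]), r_max=0.65)
        assert dm.expected_response(1e6, model) == pytest.approx(0.65, abs=1e-12)

    def test_monotone_in_lambda_and_eta(self):
        model = dm.dominant_domain_model(0.17, 10, r_max=0.65)
        lam = np.linspace(0, 50, 200)
        r = dm.expected_response(lam, model)
        assert np.all(np.diff(r) >= 0)
        weak = dm.DomainModel(
            fractions=model.fractions, r_max=0.65, capture_efficiency=0.5
        )
        assert dm.expected_response(5.0, weak) < dm.expected_response(5.0, model)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dm.expected_response(-1.0, dm.equal_domain_model(2))


class TestSimulateAssay:
    def test_zero_dose_all_zero(self):
        out = dm.simulate_assay(0.0, dm.equal_domain_model(4), 100, seed=0)
        assert np.all(out == 0.0)

    def test_forced_count_matches_occupancy_formula(self, rng):
        """10 bindings on 10 equal domains flip 10·(1 − 0.9^10) = 6.513 on average."""
        model = dm.equal_domain_model(10, r_max=1.0)
        n = 20000
        flipped = np.array(
            [dm.flip_response_given_count(10, model, rng) for _ in range(n)]
        ) * 10  # response · N = flipped-domain count for equal domains
        expected = 10 * (1 - 0.9**10)
        se = flipped.std(ddof=1) / math.sqrt(n)
        assert abs(flipped.mean() - expected) < 3 * se

    def test_reproducible_given_seed(self):
        model = dm.dominant_domain_model(0.2, 5)
        a = dm.simulate_assay(3.0, model, 1000, seed=42)
        b = dm.simulate_assay(3.0, model, 1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_oracle_matches_closed_form_random_models(self):
        """Closed form equals the Monte-Carlo mean within 3 SE on 20 random models."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(1, 51))
            model = dm.DomainModel(
                fractions=dm.lognormal_fractions(k, 1.0, rng),
                r_max=float(rng.uniform(0.2, 1.0)),
            )
            lam = float(10 ** rng.uniform(-1, 2))
            sim = dm.simulate_assay(lam, model, 100_000, seed=int(rng.integers(2**31)))
            se = sim.std(ddof=1) / math.sqrt(len(sim))
            assert abs(sim.mean() - dm.expected_response(lam, model)) < 3 * max(se, 1e-12)


class TestSteepness:
    def test_single_domain(self):
        assert dm.steepness_index(
            dm.equal_domain_model(1)
        ) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_many_small_domains_limit(self):
        assert dm.steepness_index(dm.equal_domain_model(10**6)) == pytest.approx(
            1e-6, rel=1e-3
        )

    def test_merging_domains_increases_steepness(self):
        split = dm.DomainModel(fractions=np.array([0.25, 0.25, 0.5]), r_max=1.0)
        merged = dm.DomainModel(fractions=np.array([0.5, 0.5]), r_max=1.0)
        assert dm.steepness_index(merged) > dm.steepness_index(split)

    def test_merged_response_dominates_at_single_molecule_dose(self):
        split = dm.equal_domain_model(8, r_max=0.65)
        merged = dm.equal_domain_model(4, r_max=0.65)
        for lam in (0.1, 0.5, 1.0):
            assert dm.expected_response(lam, merged) >= dm.expected_response(lam, split)


class TestInvertForLod:
    def test_single_domain_closed_form(self):
        model = dm.equal_domain_model(1, r_max=0.6)
        c = dm.invert_for_lod(model, 0.116, 100.0)
        lam = -math.log(1 - 0.116 / 0.6)
        assert c == pytest.approx(3.57, abs=0.01)
        assert c == pytest.approx(lam / 6.022e-2, rel=1e-6)

    def test_continuity_at_zero(self):
        model = dm.equal_domain_model(3, r_max=0.6)
        assert dm.invert_for_lod(model, 1e-9, 100.0) < 1e-6

    def test_round_trip(self):
        model = dm.dominant_domain_model(0.17, 10, r_max=0.65)
        c = dm.invert_for_lod(model, 0.2, 100.0)
        lam = dm.lod_dose(model, 0.2)
        assert dm.expected_response(lam, model) == pytest.approx(0.2, rel=1e-8)
        assert c == pytest.approx(lam / 6.022e-2, rel=1e-6)

    def test_unattainable_level(self):
        with pytest.raises(ValueError):
            dm.invert_for_lod(dm.equal_domain_model(1, r_max=0.5), 0.6)

    def test_domain_size_contrast(self):
        """Large (1e11-antibody) domains reach the LOD level at ~100x smaller
        dose than small (1e9) domains."""
        n_total = 5.92e11
        big = dm.equal_domain_model(n_total / 1e11, r_max=0.65)
        small = dm.equal_domain_model(n_total / 1e9, r_max=0.65)
        r_lod = 0.116
        ratio = dm.lod_dose(small, r_lod) / dm.lod_dose(big, r_lod)
        assert 50 <= ratio <= 500
        assert dm.lod_dose(big, r_lod) < 10  # single-molecule scale


class TestFitDoseCurve:
    @staticmethod
    def _dataset(model, lam, noise_sd, seed):
        clean = dm.expected_response(lam, model)
        rng = np.random.default_rng(seed)
        y = clean + (rng.normal(0, noise_sd, len(lam)) if noise_sd else 0.0)
        sig = np.full(len(lam), noise_sd if noise_sd else 0.01)
        return dm.DoseResponseCurve(doses=lam, responses=y, sigmas=sig)

    def test_noiseless_exact_recovery(self):
        model = dm.equal_domain_model(6, r_max=0.65)
        data = self._dataset(model, np.logspace(-1, 3, 12), 0.0, 0)
        fit = dm.fit_dose_curve(data, parametrization="equal")
        assert fit.params["r_max"] == pytest.approx(0.65, abs=1e-6)
        assert fit.params["n_domains"] == pytest.approx(6.0, abs=1e-5)

    def test_ci_coverage_under_noise(self):
        """95% CIs for (r_max, N_D) cover the truth in >= 90% of 200 noisy fits."""
        model = dm.equal_domain_model(6, r_max=0.65)
        lam = np.logspace(-1, 3, 12)
        hits = {"r_max": 0, "n_domains": 0}
        for seed in range(200):
            data = self._dataset(model, lam, 0.02, seed)
            fit = dm.fit_dose_curve(data, parametrization="equal")
            for name, truth in (("r_max", 0.65), ("n_domains", 6.0)):
                lo, hi = fit.conf_interval(name)
                if np.isfinite(lo) and lo <= truth <= hi:
                    hits[name] += 1
        assert hits["r_max"] >= 180
        assert hits["n_domains"] >= 180

    def test_dominant_fraction_recovery(self):
        """Fitted dominant fraction within ±30% of truth in >= 90% of 200 fits.

        The truth model carries the assay-like two-scale structure (one
        dominant ~17% domain plus hundreds of small ones), whose separated
        dose scales make the dominant fraction identifiable from 11
        log-spaced doses at 2% noise.
        """
        model = dm.dominant_domain_model(0.169, 492, r_max=0.65)
        lam = np.logspace(-1, 3.5, 11)
        ok = 0
        for seed in range(200):
            data = self._dataset(model, lam, 0.02, 1000 + seed)
            fit = dm.fit_dose_curve(data, parametrization="dominant")
            if abs(fit.params["a1"] - 0.169) / 0.169 <= 0.30:
                ok += 1
        assert ok >= 180

    def test_under_determined_rejected(self):
        model = dm.equal_domain_model(6)
        data = self._dataset(model, np.array([1.0, 10.0]), 0.0, 0)
        with pytest.raises(ValueError, match="under-determined"):
            dm.fit_dose_curve(data, parametrization="equal")

    def test_all_zero_responses_rejected(self):
        data = dm.DoseResponseCurve(
            doses=np.logspace(0, 2, 6),
            responses=np.zeros(6),
            sigmas=np.full(6, 0.01),
        )
        with pytest.raises(ValueError, match="degenerate"):
            dm.fit_dose_curve(data, parametrization="equal")


class TestDomainModelValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            dm.DomainModel(fractions=np.array([0.5, 0.4]))

    def test_positive_fractions(self):
        with pytest.raises(ValueError):
            dm.DomainModel(fractions=np.array([1.5, -0.5]))

    def test_domain_counts(self):
        model = dm.equal_domain_model(4, n_antibodies=4e11)
        np.testing.assert_allclose(model.domain_counts, np.full(4, 1e11))

    def test_lognormal_fractions_normalized(self, rng):
        f = dm.lognormal_fractions(30, 0.8, rng)
        assert f.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(f > 0)
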