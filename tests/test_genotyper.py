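import itertools
import math

import numpy as np
import pytest

from oracles import mendelian_consistent
from svasm.genotyper import (
    EXPECTED_CENTERS,
    SCALING_GRID,
    STATES,
    AlleleIntensity,
    GenotypeModel,
    call_genotype,
    compute_intensities,
    fit_em,
    mendelian_error_rate,
    phred_gq,
    posterior,
    select_scaling_factor,
    state_likelihood,
)
from svasm.io_formats import Trio
from svasm.simdata import simulate_genotype_cohort, simulate_intensities


def default_model(weights=(1 / 3, 1 / 3, 1 / 3), sd=0.1):
    return GenotypeModel(
        weights=np.array(weights),
        means=EXPECTED_CENTERS.copy(),
        covariances=np.array([np.eye(2) * sd**2 for _ in range(3)]),
    )


class TestIntensities:
    @pytest.mark.parametrize(
        "r,a,depth,expected",
        [
            (10, 0, 10, (1.0, 0.0)),
            (5, 5, 10, (0.5, 0.5)),
            (3, 4, 10, (0.3, 0.4)),  # remainder supports neither allele
        ],
    )
    def test_definition(self, r, a, depth, expected):
        d = compute_intensities(r, a, depth)
        assert (d.r_intensity, d.a_intensity) == expected

    def test_zero_depth_is_missing(self):
        assert compute_intensities(0, 0, 0).missing

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_intensities(-1, 0, 10)


class TestLikelihoodAndPosterior:
    def test_density_peaks_at_the_state_center(self):
        model = default_model()
        for j in range(3):
            d = AlleleIntensity(*EXPECTED_CENTERS[j], 30)
            liks = [state_likelihood(d, model, k) for k in range(3)]
            assert int(np.argmax(liks)) == j

    def test_linear_in_the_weight(self):
        model = default_model()
        doubled = default_model(weights=(2 / 3, 1 / 6, 1 / 6))
        d = AlleleIntensity(0.9, 0.1, 30)
        assert state_likelihood(d, doubled, 0) == pytest.approx(
            2 * state_likelihood(d, model, 0)
        )

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_direct_bivariate_normal_density(self, trial):
        rng = np.random.default_rng(trial)
        model = default_model(sd=0.07)
        d = AlleleIntensity(*rng.random(2), 30)
        for j in range(3):
            mu = model.means[j]
            var = 0.07**2
            x = d.vector() - mu
            direct = (
                model.weights[j]
                * math.exp(-0.5 * float(x @ x) / var)
                / (2 * math.pi * var)
            )
            assert state_likelihood(d, model, j) == pytest.approx(direct)

    def test_balanced_intensity_is_confidently_heterozygous(self):
        post = posterior(AlleleIntensity(0.5, 0.5, 30), default_model())
        assert post[1] > 0.99

    def test_posterior_normalized(self):
        post = posterior(AlleleIntensity(0.7, 0.2, 30), default_model())
        assert post.sum() == pytest.approx(1.0)

    def test_underflow_falls_back_to_uniform(self):
        model = default_model(sd=1e-3)
        with pytest.warns(UserWarning):
            post = posterior(AlleleIntensity(0.25, 0.1, 30), model)
        assert np.allclose(post, 1 / 3)


class TestFitEm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        w = np.array([0.25, 0.5, 0.25])
        comp = rng.choice(3, p=w, size=500)
        X = EXPECTED_CENTERS[comp] + rng.normal(0, 0.05, size=(500, 2))
        model = fit_em(X, 1.0)
        assert np.all(np.abs(model.weights - w) < 0.05)
        assert np.all(np.abs(model.means - EXPECTED_CENTERS) < 0.02)

    def test_degenerate_single_cluster(self):
        X = np.tile([1.0, 0.0], (50, 1)) + np.random.default_rng(0).normal(
            0, 0.01, (50, 2)
        )
        with pytest.warns(UserWarning):
            model = fit_em(X, 1.0)
        assert model.weights[0] > 0.95

    def test_log_likelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(5)
        comp = rng.choice(3, size=200)
        X = EXPECTED_CENTERS[comp] + rng.normal(0, 0.08, size=(200, 2))
        lls = [fit_em(X, 1.0, max_iter=k).log_likelihood for k in range(1, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.array([[0.5, 0.5]]), 1.0)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "p_best,expected",
        [(0.9, 10), (1 / 3, 2), (1.0, 99)],  # -10*log10(2/3) = 1.76 -> 2
    )
    def test_phred_quality(self, p_best, expected):
        assert phred_gq(p_best) == expected

    def test_missing_observation(self):
        call = call_genotype(AlleleIntensity(float("nan"), float("nan"), 0),
                             default_model())
        assert call.gt == "missing"

    def test_tie_breaks_to_first_state(self):
        # RR and AA are mirror images across the diagonal, so a point on
        # the diagonal ties them exactly; with no RA weight the posterior
        # is (0.5, 0, 0.5) and the earlier state in RR < RA < AA wins
        model = default_model(weights=(0.5, 0.0, 0.5))
        call = call_genotype(AlleleIntensity(0.7, 0.7, 30), model)
        assert call.posteriors[0] == pytest.approx(call.posteriors[2])
        assert call.gt == "RR"

    def test_argmax_consistency(self):
        model = default_model()
        for r, a, expected in [(1.0, 0.0, "RR"), (0.5, 0.5, "RA"), (0.0, 1.0, "AA")]:
            assert call_genotype(AlleleIntensity(r, a, 30), model).gt == expected


class TestMendelian:
    def _genotypes(self, triples):
        gts = {}
        for i, (c, f, m) in enumerate(triples):
            gts[f"v{i}"] = {"child0": c, "father0": f, "mother0": m}
        return gts

    def test_single_impossible_locus_in_ten(self):
        trio = [Trio("f", "child0", "father0", "mother0")]
        triples = [("RR", "RR", "RR")] * 9 + [("AA", "RR", "RR")]
        assert mendelian_error_rate(self._genotypes(triples), trio) == 0.1

    def test_all_consistent(self):
        trio = [Trio("f", "child0", "father0", "mother0")]
        triples = [("RA", "RR", "AA"), ("AA", "RA", "AA"), ("RR", "RA", "RA")]
        assert mendelian_error_rate(self._genotypes(triples), trio) == 0.0

    def test_unknown_pedigree_id_rejected(self):
        trio = [Trio("f", "nobody", "father0", "mother0")]
        with pytest.raises(ValueError):
            mendelian_error_rate(self._genotypes([("RR", "RR", "RR")]), trio)

    def test_matches_27_case_enumeration(self):
        trio = [Trio("f", "child0", "father0", "mother0")]
        names = {0: "RR", 1: "RA", 2: "AA"}
        for c, f, m in itertools.product(range(3), repeat=3):
            gts = self._genotypes([(names[c], names[f], names[m])])
            rate = mendelian_error_rate(gts, trio)
            assert rate == (0.0 if mendelian_consistent(c, f, m) else 1.0)


class TestScalingFactor:
    def _intensities(self, seed=0, **sim_kwargs):
        gts = {
            f"v{i}": simulate_genotype_cohort(60, 0.4, seed=seed + i)
            for i in range(30)
        }
        table = simulate_intensities(gts, 30, seed=seed, **sim_kwargs)
        out = {}
        for row in table.itertuples():
            out.setdefault(row.variant_id, {})[row.sample] = compute_intensities(
                row.r_count, row.a_count, row.depth
            )
        return out

    def test_unit_scale_data_selects_m_of_one(self):
        # noise-free intensities sit exactly on the unit-scale centers
        data = self._intensities(seed=2, mismap_noise=0.0, neither_rate=0.0)
        best, models = select_scaling_factor(data)
        assert best == 1.0

    def test_five_rounds_of_training(self):
        data = self._intensities(seed=3)
        best, models = select_scaling_factor(data)
        assert set(models) == set(SCALING_GRID)

    def test_selection_is_deterministic(self):
        data = self._intensities(seed=4)
        assert select_scaling_factor(data)[0] == select_scaling_factor(data)[0]


class TestCohortConcordance:
    def _concordance(self, depth, seed=11):
        gts = {f"v{i}": simulate_genotype_cohort(80, 0.5, seed=seed + i)
               for i in range(25)}
        table = simulate_intensities(gts, depth, seed=seed)
        data = {}
        for row in table.itertuples():
            data.setdefault(row.variant_id, {})[row.sample] = compute_intensities(
                row.r_count, row.a_count, row.depth
            )
        X = np.array([
            d.vector() for per in data.values() for d in per.values() if not d.missing
        ])
        model = fit_em(X, 1.0)
        match = total = 0
        for vid, per in data.items():
            for sample, d in per.items():
                if d.missing:
                    continue
                total += 1
                match += call_genotype(d, model).gt == gts[vid][sample]
        return match / total

    def test_high_concordance_at_depth_30(self):
        assert self._concordance(30) >= 0.98

    def test_concordance_degrades_gracefully_with_depth(self):
        values = [self._concordance(depth) for depth in (40, 20, 10, 5)]
        assert all(b <= a + 0.01 for a, b in zip(values, values[1:]))
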