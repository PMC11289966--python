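import numpy as np
import pytest
from scipy import stats

from slnatlas import (
    BootstrapConfig,
    Cohort,
    TumourRecord,
    build_contingency,
    drainage_bayes,
    drainage_bootstrap,
    drainage_regression,
    drainage_table,
    prevalence_bayes,
    prevalence_bootstrap,
    prevalence_by_field,
    prevalence_table,
)
from slnatlas.render import pct


def toy_cohort(n, k, field="axilla-II", region=2):
    """n singleton patients in one region, k of whom drain to `field`."""
    recs = []
    for i in range(n):
        fields = {field} if i < k else {"axilla-I-anterior"}
        recs.append(
            TumourRecord(
                patient_id=f"T{i:03d}",
                side="L",
                clockface=region,
                nipple_distance_cm=3.0,
                drained_fields=frozenset(fields),
            )
        )
    return Cohort(tuple(recs))


class TestDrainageBayes:
    @pytest.mark.parametrize(
        "n,N,mean,lo,hi",
        [(671, 869, 77.2, 74.3, 79.9), (5, 869, 0.7, 0.3, 1.3), (17, 24, 69.2, 50.6, 85.1)],
    )
    def test_posterior_summaries(self, n, N, mean, lo, hi):
        est = drainage_bayes(n, N)
        assert pct(est.mean) == mean
        assert pct(est.lower) == lo
        assert pct(est.upper) == hi

    def test_zero_successes_closed_form(self):
        est = drainage_bayes(0, 10)
        assert est.mean == pytest.approx(1 / 12)
        # Beta(1, 11) quantile has the closed form 1 - (1 - q)^(1/11)
        assert est.lower == pytest.approx(1 - 0.975 ** (1 / 11), abs=1e-12)
        assert est.upper == pytest.approx(1 - 0.025 ** (1 / 11), abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            drainage_bayes(5, 4)

    def test_conjugacy_against_numerical_integration(self):
        """Closed-form posterior mean/quantiles vs dense integration of the
        unnormalized Beta kernel."""
        rng = np.random.default_rng(7)
        x = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
        for _ in range(8):
            N = int(rng.integers(1, 201))
            n = int(rng.integers(0, N + 1))
            est = drainage_bayes(n, N)
            kernel = np.exp(n * np.log(x) + (N - n) * np.log1p(-x))
            norm = np.trapezoid(kernel, x)
            mean = np.trapezoid(x * kernel, x) / norm
            cdf = np.cumsum(kernel)
            cdf = cdf / cdf[-1]
            lo = np.interp(0.025, cdf, x)
            hi = np.interp(0.975, cdf, x)
            assert est.mean == pytest.approx(mean, abs=1e-6)
            assert est.lower == pytest.approx(lo, abs=1e-6)
            assert est.upper == pytest.approx(hi, abs=1e-6)


class TestDrainageRegression:
    def test_axilla_level_two_cell(self):
        est = drainage_regression(72, 869)
        assert (pct(est.mean), pct(est.lower), pct(est.upper)) == (8.3, 6.6, 10.3)

    def test_seven_oclock_internal_mammary_mean(self):
        assert pct(drainage_regression(17, 24).mean) == 70.8

    def test_logit_symmetry_at_half(self):
        est = drainage_regression(5, 10)
        assert est.mean == 0.5
        assert est.lower + est.upper == pytest.approx(1.0, abs=1e-12)

    def test_matches_statsmodels_glm_fitted_interval(self):
        sm = pytest.importorskip("statsmodels.api")
        for n, N in [(72, 869), (17, 24), (264, 869)]:
            res = sm.GLM(
                np.array([[float(n), float(N - n)]]),
                np.array([[1.0]]),
                family=sm.families.Binomial(),
            ).fit()
            lo, hi = res.get_prediction(np.array([[1.0]])).conf_int()[0]
            est = drainage_regression(n, N)
            assert est.lower == pytest.approx(lo, abs=1e-6)
            assert est.upper == pytest.approx(hi, abs=1e-6)

    @pytest.mark.parametrize("n,N", [(0, 50), (50, 50)])
    def test_degenerate_cells_use_exact_one_sided_bound(self, n, N):
        est = drainage_regression(n, N)
        assert est.degenerate
        if n == 0:
            assert est.lower == 0.0
            assert est.upper == pytest.approx(stats.beta.ppf(0.975, 1, N))
        else:
            assert est.upper == 1.0
            assert est.lower == pytest.approx(stats.beta.ppf(0.025, N, 1))


class TestPrevalenceBayes:
    def test_reference_cells(self, reference_table):
        ests = prevalence_bayes(reference_table.region_totals)
        assert (pct(ests[2].mean), pct(ests[2].lower), pct(ests[2].upper)) == (22.7, 20.0, 25.5)
        assert pct(ests[0].mean) == 12.7

    def test_normalization_with_single_count(self):
        counts = np.zeros(13, dtype=int)
        counts[4] = 1
        ests = prevalence_bayes(counts)
        assert ests[4].mean == pytest.approx(2 / 14)
        assert all(e.mean == pytest.approx(1 / 14) for i, e in enumerate(ests) if i != 4)
        assert sum(e.mean for e in ests) == pytest.approx(1.0, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            prevalence_bayes([1, 2, 3])


class TestBootstrap:
    def test_degenerate_all_drain(self):
        cohort = toy_cohort(15, 15)
        est = drainage_bootstrap(cohort, "axilla-II", cfg=BootstrapConfig(B=500, seed=0))
        assert est.mean == est.lower == est.upper == 1.0

    def test_percentiles_match_exhaustive_binomial_oracle(self):
        """With singleton patients the bootstrap proportion is exactly
        Binomial(n, k/n)/n; large-B percentiles must agree with its quantiles."""
        n, k = 20, 7
        cohort = toy_cohort(n, k)
        est = drainage_bootstrap(cohort, "axilla-II", cfg=BootstrapConfig(B=200_000, seed=3))
        p = k / n
        sd = np.sqrt(p * (1 - p) / n)
        assert est.mean == pytest.approx(p, abs=3 * sd / np.sqrt(200_000))
        assert est.lower == pytest.approx(stats.binom.ppf(0.025, n, p) / n, abs=1 / n)
        assert est.upper == pytest.approx(stats.binom.ppf(0.975, n, p) / n, abs=1 / n)

    def test_mean_converges_to_sample_proportion(self, reference_cohort):
        B = 20_000
        est = drainage_bootstrap(
            reference_cohort, "internal-mammary", cfg=BootstrapConfig(B=B, seed=11)
        )
        p = 264 / 869
        sd = np.sqrt(p * (1 - p) / 869)
        assert est.mean == pytest.approx(p, abs=3 * sd / np.sqrt(B))

    def test_region_filter_restricts_denominator(self, reference_cohort):
        est = drainage_bootstrap(
            reference_cohort, "internal-mammary", region=7, cfg=BootstrapConfig(B=1000, seed=5)
        )
        assert est.n_total == 24
        assert est.n_success == 17

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            drainage_bootstrap(toy_cohort(5, 2), "axilla-II", region=9)

    def test_prevalence_replicates_conserve_mass(self, reference_cohort):
        ests = prevalence_bootstrap(reference_cohort, cfg=BootstrapConfig(B=2000, seed=9))
        assert sum(e.mean for e in ests) == pytest.approx(1.0, abs=1e-12)

    def test_single_region_cohort_degenerate(self):
        ests = prevalence_bootstrap(toy_cohort(10, 4), cfg=BootstrapConfig(B=500, seed=2))
        assert ests[2].mean == ests[2].lower == ests[2].upper == 1.0
        assert all(e.mean == 0.0 for i, e in enumerate(ests) if i != 2)


class TestTables:
    def test_per_region_bayes_seven_oclock_internal_mammary(self, reference_table):
        out = drainage_table(reference_table, methods=("bayes",), scope="per-region")
        assert pct(out[("internal-mammary", 7, "bayes")].mean) == 69.2

    def test_zero_count_cell_bayes_and_degenerate_regression(self, reference_table):
        out = drainage_table(reference_table, methods=("bayes", "regression"), scope="per-region")
        # axilla-III drains from region 7 in 0 of 24 tumours
        bayes = out[("axilla-III", 7, "bayes")]
        assert bayes.mean == pytest.approx(1 / 26)
        assert out[("axilla-III", 7, "regression")].degenerate

    def test_bootstrap_requires_records(self, reference_table):
        with pytest.raises(ValueError, match="record-level"):
            drainage_table(reference_table, methods=("bootstrap",))
        with pytest.raises(ValueError, match="record-level"):
            prevalence_table(reference_table, methods=("bootstrap",))

    def test_prevalence_by_field_restriction(self, reference_table):
        out = prevalence_by_field(reference_table, "axilla-I-anterior", methods=("bayes",))
        assert out[(0, "bayes")].n_success == 87
        assert out[(0, "bayes")].n_total == 671

    def test_prevalence_by_field_conserves_field_totals(self, reference_table):
        from slnatlas import NODE_FIELDS

        for f, total in zip(NODE_FIELDS, reference_table.field_totals):
            out = prevalence_by_field(reference_table, f, methods=("bayes",))
            assert sum(e.n_success for e in out.values()) == total

    def test_single_tumour_field(self):
        cohort = toy_cohort(6, 1, field="supraclavicular", region=3)
        out = prevalence_by_field(build_contingency(cohort), "supraclavicular", methods=("bayes",))
        assert out[(3, "bayes")].mean == pytest.approx(2 / 14)
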