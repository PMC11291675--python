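"""Single-marker tests, conditional scans, variance decomposition, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hlapqtl as h
from hlapqtl.association import LOG10P_CAP, log10p_from_t, marginal_scan


def _simple_ols_oracle(x, y):
    """Closed-form simple regression beta, se, two-sided p."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    resid = yc - beta * xc
    sigma2 = (resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / (xc @ xc))
    t = beta / se
    return beta, se, -(stats.t.logsf(abs(t), n - 2) + np.log(2)) / np.log(10)


class TestSingleMarker:
    def test_printed_toy_matches_closed_form(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([0.1, -0.1, 0.5, 0.4, 1.0, 1.1])
        res = h.single_marker_test(y, x, min_n=3)
        beta, se, log10p = _simple_ols_oracle(x, y)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.log10p == pytest.approx(log10p, rel=1e-8)

    def test_perfect_fit_reports_cap(self, rng):
        x = rng.normal(size=50)
        res = h.single_marker_test(x.copy(), x, min_n=10)
        assert res.beta == pytest.approx(1.0)
        assert res.log10p == LOG10P_CAP

    def test_null_draw_is_not_significant(self, rng):
        x = rng.binomial(2, 0.3, size=1000).astype(float)
        y = rng.normal(size=1000)
        res = h.single_marker_test(y, x)
        assert res.log10p < 4.0  # p > 1e-4 under the null

    def test_constant_dosage_is_flagged_skip_not_crash(self, rng):
        res = h.single_marker_test(rng.normal(size=20), np.ones(20))
        assert res.skipped and res.log10p == 0.0

    def test_oracle_equivalence_on_random_toys(self, rng):
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.3 * x
            res = h.single_marker_test(y, x, min_n=5)
            beta, se, log10p = _simple_ols_oracle(x, y)
            assert res.beta == pytest.approx(beta, rel=1e-8)
            assert res.se == pytest.approx(se, rel=1e-8)

    def test_statsmodels_cross_check_with_covariates(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=100)
        C = rng.normal(size=(100, 2))
        y = 0.4 * x + C @ [0.2, -0.1] + rng.normal(size=100)
        res = h.single_marker_test(y, x, extra_covariates=C)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([C, x]))).fit()
        assert res.beta == pytest.approx(fit.params[-1], rel=1e-8)
        assert res.se == pytest.approx(fit.bse[-1], rel=1e-8)

    def test_complete_case_n_reported(self, rng):
        y = rng.normal(size=100)
        y[:10] = np.nan
        res = h.single_marker_test(y, rng.binomial(2, 0.4, 100).astype(float))
        assert res.n == 90


class TestLogSpaceP:
    def test_finite_and_monotone_up_to_extreme_t(self):
        ts = np.array([1.0, 5.0, 20.0, 50.0, 100.0, 300.0])
        vals = [log10p_from_t(t, 1000) for t in ts]
        assert all(np.isfinite(v) for v in vals)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 300  # far beyond double-precision underflow


class TestThresholds:
    def test_bonferroni_examples(self):
        assert h.bonferroni_threshold(5e-8, 2940) == pytest.approx(1.70e-11, rel=5e-3)
        assert h.bonferroni_threshold(5e-8, 1) == 5e-8
        assert h.bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            h.bonferroni_threshold(0.05, 0)

    def test_discovery_below_genome_wide(self):
        thr = h.SignificanceThresholds(n_proteins=2940)
        assert thr.discovery < thr.genome_wide


class TestSelectLead:
    def _res(self, variant, log10p, beta):
        return h.AssociationResult("P", variant, beta, 0.1, log10p, 100)

    def test_single_and_ordering(self):
        a, b = self._res("v1", 12.0, 0.1), self._res("v2", 9.0, 0.5)
        assert h.select_lead([a]) is a
        assert h.select_lead([a, b]) is a

    def test_tie_breaks_on_abs_beta_then_id(self):
        a, b = self._res("v1", 12.0, -0.3), self._res("v2", 12.0, 0.2)
        assert h.select_lead([a, b]) is a
        c, d = self._res("vB", 12.0, 0.3), self._res("vA", 12.0, -0.3)
        assert h.select_lead([c, d]) is d  # lexicographic on equal |beta|

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            h.select_lead([])


class TestForwardConditional:
    def test_no_signal_gives_empty_list(self, all_variants, rng):
        y = rng.normal(size=all_variants.n_individuals)
        assert h.forward_conditional(y, all_variants) == []

    def test_two_unlinked_causals_recovered_in_order(self, catalog):
        cfg = h.demo_config(n_individuals=3000, n_proteins=2, seed=42)
        c = h.simulate_cohort(cfg, catalog)
        prep = h.prepare_panel(c.phenotypes, c.covariates)
        d = h.full_variant_matrix(c.observed_dosages, catalog)
        chain = h.forward_conditional(
            prep.values["P02"].to_numpy(), d, variant_kinds=["amino_acid"]
        )
        assert [r.variant for r in chain[:2]] == [
            "AA_A_position9_exon2_F", "AA_B_position45_exon2_E"
        ]

    def test_threshold_boundary_stops(self, rng):
        # second-round best -log10 p below -log10(5e-8)=7.301 must not be kept
        x = rng.binomial(2, 0.3, size=2000).astype(float)
        y = 0.3 * x + rng.normal(size=2000)
        variants = [h.VariantDef("v_causal", "two_field", "A"),
                    h.VariantDef("v_noise", "two_field", "B")]
        d = h.DosageMatrix([f"i{k}" for k in range(2000)], variants,
                           np.column_stack([x, rng.binomial(2, 0.3, 2000)]))
        chain = h.forward_conditional(y, d)
        assert [r.variant for r in chain] == ["v_causal"]

    def test_conditioning_on_causal_kills_perfect_proxy(self, rng):
        x = rng.binomial(2, 0.4, size=1500).astype(float)
        y = 0.5 * x + rng.normal(size=1500)
        variants = [h.VariantDef("causal", "two_field", "A"),
                    h.VariantDef("proxy", "two_field", "A")]
        d = h.DosageMatrix([f"i{k}" for k in range(1500)], variants,
                           np.column_stack([x, x]))
        chain = h.forward_conditional(y, d)
        assert len(chain) == 1  # proxy aliased after conditioning


class TestClassAdjusted:
    def test_orthogonal_adjustment_preserves_beta(self, rng):
        x = rng.binomial(2, 0.3, size=3000).astype(float)
        y = 0.4 * x + rng.normal(size=3000)
        opp = h.DosageMatrix(
            [f"i{k}" for k in range(3000)],
            [h.VariantDef("DQB1*02:01", "two_field", "DQB1"),
             h.VariantDef("DQB1*03:01", "two_field", "DQB1")],
            np.column_stack([rng.binomial(2, 0.3, 3000),
                             rng.binomial(2, 0.4, 3000)]).astype(float),
        )
        marg = h.single_marker_test(y, x)
        adj = h.class_adjusted_test(y, x, opp, lead_id="A*01:01")
        assert adj.beta == pytest.approx(marg.beta, abs=3 * marg.se / 10)

    def test_mediated_effect_loses_significance(self, rng):
        conf = rng.binomial(2, 0.4, size=3000).astype(float)
        lead = np.clip(conf + rng.normal(0, 0.3, 3000), 0, 2)  # proxy of conf
        y = 0.4 * conf + rng.normal(size=3000)
        # complete two-allele locus: dosages sum to 2, one gets dropped as ref
        opp = h.DosageMatrix(
            [f"i{k}" for k in range(3000)],
            [h.VariantDef("DRB1*04:01", "two_field", "DRB1"),
             h.VariantDef("DRB1*15:01", "two_field", "DRB1")],
            np.column_stack([conf, 2.0 - conf]),
        )
        adj = h.class_adjusted_test(y, lead, opp, lead_id="B*08:01")
        marg = h.single_marker_test(y, lead)
        assert marg.log10p > 7.3 and adj.log10p < 2.0
        assert len(adj.conditioning_set) == 1  # reference allele dropped

    def test_empty_adjustment_reduces_to_marginal(self, rng):
        x = rng.binomial(2, 0.3, size=500).astype(float)
        y = 0.3 * x + rng.normal(size=500)
        opp = h.DosageMatrix([f"i{k}" for k in range(500)], [], np.empty((500, 0)))
        adj = h.class_adjusted_test(y, x, opp)
        marg = h.single_marker_test(y, x)
        assert adj.beta == pytest.approx(marg.beta, rel=1e-10)
        assert adj.log10p == pytest.approx(marg.log10p, rel=1e-8)

    def test_lead_in_adjustment_set_errors(self, rng, all_variants):
        opp = all_variants.subset(["DRB1*04:01"])
        with pytest.raises(ValueError):
            h.class_adjusted_test(np.zeros(10), np.zeros(10), opp,
                                  lead_id="DRB1*04:01")


class TestCombinedModel:
    def test_noise_external_keeps_hla_signal(self, rng):
        x = rng.binomial(2, 0.3, size=3000).astype(float)
        y = 0.4 * x + rng.normal(size=3000)
        ext = rng.binomial(2, 0.3, size=3000).astype(float)
        out = h.combined_model_test(y, x, ext)
        assert out.label == "hla_driven"

    def test_duplicated_lead_flags_collinearity(self, rng):
        x = rng.binomial(2, 0.3, size=500).astype(float)
        out = h.combined_model_test(rng.normal(size=500), x, x)
        assert out.collinear and out.label == "neither"

    def test_two_independent_signals(self, rng):
        a = rng.binomial(2, 0.4, size=5000).astype(float)
        b = rng.binomial(2, 0.4, size=5000).astype(float)
        y = 0.3 * a + 0.3 * b + rng.normal(size=5000)
        out = h.combined_model_test(y, a, b)
        assert out.label == "both_independent"


class TestVarianceExplained:
    def test_single_variant_matches_analytic_limit(self, rng):
        n = 10_000
        beta, sigma = 0.5, 1.0
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = beta * x + rng.normal(0, sigma, size=n)
        vd = h.variance_explained(y, x[:, None])
        v = x.var()
        expected = beta ** 2 * v / (beta ** 2 * v + sigma ** 2)
        assert vd.total_fraction == pytest.approx(expected, abs=0.01)

    def test_null_variant_fraction_tiny(self, rng):
        n = 5000
        y = rng.normal(size=n)
        vd = h.variance_explained(y, rng.binomial(2, 0.3, n).astype(float)[:, None])
        assert vd.sequential_ss_fraction[0] < 10 / n

    def test_orthogonal_variants_order_invariant(self, rng):
        n = 4000
        X = rng.normal(size=(n, 3))
        X -= X.mean(axis=0)
        q, _ = np.linalg.qr(X)  # exactly orthogonal columns
        X = np.clip(q * 5 + 1, 0, 2)
        X = X - X.mean(axis=0)
        y = X @ [0.3, 0.2, 0.1] + rng.normal(size=n)
        a = h.variance_explained(y, X)
        b = h.variance_explained(y, X[:, ::-1])
        assert a.total_fraction == pytest.approx(b.total_fraction, abs=1e-8)

    def test_total_equals_joint_r2(self, cohort, prepared, all_variants):
        y = prepared.values["P03"].to_numpy()
        sub = all_variants.subset(
            ["AA_DRB1_position11_exon2_V", "AA_DRB1_position86_exon2_V",
             "DRB1*04:01"])
        vd = h.variance_explained(y, sub)
        mask = ~np.isnan(y)
        X = np.column_stack([np.ones(mask.sum()), sub.dosage[mask]])
        yv = y[mask]
        resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        r2 = 1 - (resid @ resid) / ((yv - yv.mean()) @ (yv - yv.mean()))
        assert vd.total_fraction == pytest.approx(r2, abs=1e-8)

    def test_aliased_variant_contributes_zero(self, rng):
        x = rng.binomial(2, 0.3, size=1000).astype(float)
        y = 0.4 * x + rng.normal(size=1000)
        vd = h.variance_explained(y, np.column_stack([x, x]))
        assert vd.sequential_ss_fraction[1] == 0.0


class TestPermutationNull:
    def test_strong_effect_beats_every_permutation(self, rng):
        n = 2000
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = 1.0 * x + rng.normal(size=n)
        d = h.DosageMatrix([f"i{k}" for k in range(n)],
                           [h.VariantDef("v", "two_field", "A")], x[:, None])
        null = h.permutation_null(y, d, n_perm=200, seed=1)
        assert null.empirical_p == pytest.approx(1 / 201)

    def test_null_phenotype_gives_large_empirical_p(self, rng):
        n = 1000
        d = h.DosageMatrix(
            [f"i{k}" for k in range(n)],
            [h.VariantDef(f"v{j}", "two_field", "A") for j in range(5)],
            rng.binomial(2, 0.3, size=(n, 5)).astype(float),
        )
        null = h.permutation_null(rng.normal(size=n), d, n_perm=200, seed=2)
        assert null.empirical_p > 0.01

    def test_seed_determinism(self, rng):
        n = 300
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.normal(size=n)
        d = h.DosageMatrix([f"i{k}" for k in range(n)],
                           [h.VariantDef("v", "two_field", "A")], x[:, None])
        a = h.permutation_null(y, d, n_perm=1, seed=7)
        b = h.permutation_null(y, d, n_perm=1, seed=7)
        np.testing.assert_array_equal(a.null_max_log10p, b.null_max_log10p)
        with pytest.raises(ValueError):
            h.permutation_null(y, d, n_perm=0, seed=1)


class TestReplication:
    def _results(self, betas, log10ps, prefix="v"):
        return [
            h.AssociationResult("P", f"{prefix}{i}", b, 0.1, lp, 100)
            for i, (b, lp) in enumerate(zip(betas, log10ps))
        ]

    def test_identical_results_fully_replicate(self):
        disc = self._results([0.5, -0.3, 0.2], [20, 15, 10])
        out = h.replication_check(disc, disc)
        assert out["fraction_replicated"] == 1.0
        assert out["effect_rank_correlation"] == pytest.approx(1.0)

    def test_negated_betas_are_discordant(self):
        disc = self._results([0.5, -0.3], [20, 15])
        repl = self._results([-0.5, 0.3], [20, 15])
        assert h.replication_check(disc, repl)["fraction_concordant"] == 0.0

    def test_no_shared_keys_errors(self):
        with pytest.raises(ValueError):
            h.replication_check(self._results([0.5], [20]),
                                self._results([0.5], [20], prefix="w"))

    def test_two_cohorts_from_one_truth_concord(self, catalog):
        chains = []
        for seed in (101, 202):
            cfg = h.demo_config(n_individuals=2000, n_proteins=2, seed=seed)
            c = h.simulate_cohort(cfg, catalog)
            prep = h.prepare_panel(c.phenotypes, c.covariates)
            d = h.full_variant_matrix(c.observed_dosages, catalog)
            y = prep.values["P01"].to_numpy()
            beta, se, lp, valid, n, _ = marginal_scan(y, d.dosage)
            chains.append([
                h.AssociationResult("P01", vid, float(beta[j]), float(se[j]),
                                    float(lp[j]), n)
                for j, vid in enumerate(d.variant_ids) if valid[j]
            ])
        out = h.replication_check(chains[0], chains[1])
        lead = h.select_lead(chains[0])
        row = out["table"].set_index("variant").loc[lead.variant]
        assert bool(row["replicated"])
        assert out["effect_rank_correlation"] > 0.8


class TestTypeIError:
    def test_rejection_rate_near_alpha_under_null(self, catalog):
        # pooled over independent null proteins at alpha = 0.05
        cfg = h.demo_config(n_individuals=1000, n_proteins=40, causal_effects={},
                            missing_rate=0.0, seed=17)
        c = h.simulate_cohort(cfg, catalog)
        prep = h.prepare_panel(c.phenotypes, c.covariates)
        d = h.full_variant_matrix(c.observed_dosages, catalog)
        thr = -np.log10(0.05)
        rates = []
        for p in prep.proteins:
            _b, _s, lp, valid, _n, _ = marginal_scan(prep.values[p].to_numpy(),
                                                     d.dosage)
            rates.append((lp[valid] > thr).mean())
        assert 0.03 < np.mean(rates) < 0.07
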