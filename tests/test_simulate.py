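"""Synthetic cohorts: margins, configuration model, injections, groups."""

import numpy as np
import pytest

from mecotest import (
    GroupSpec,
    SimulationConfig,
    estimate_background,
    estimate_binomial_background,
    filter_genes,
    fit_impurity_quantile,
    generate_me_group,
    generate_null_matrix,
    inject_pair,
    sample_group_spec,
    sample_marginals,
    simulate_null_matrix,
)
from mecotest.simulate import QuantileModel


SMALL = SimulationConfig(n_genes=150, n_tumors=200, seed=9,
                         min_alterations_tested=20)


class TestSampleMarginals:
    def test_deterministic_and_balanced(self):
        g1, t1 = sample_marginals(SMALL)
        g2, t2 = sample_marginals(SMALL)
        assert np.array_equal(g1, g2) and np.array_equal(t1, t2)
        assert g1.sum() == t1.sum()
        assert (g1 >= 0).all() and (t1 >= 0).all()

    def test_tumor_loads_overdispersed_by_default(self):
        _, t = sample_marginals(SimulationConfig(seed=4))
        assert t.std() / t.mean() >= 0.5

    def test_zero_dispersion_aligns_binomial_and_entropy_backgrounds(self):
        # with near-constant tumor loads the heterogeneous model nearly
        # reduces to the homogeneous one (residual disagreement comes only
        # from integer rounding of the loads); with strong dispersion the
        # two estimators disagree markedly
        diffs = {}
        for cv in (0.0, 1.5):
            cfg = SimulationConfig(n_genes=80, n_tumors=120,
                                   tumor_dispersion=cv, seed=5)
            X = simulate_null_matrix(cfg)
            P = estimate_background(X)
            Pb = estimate_binomial_background(X)
            diffs[cv] = np.abs(P.probs - Pb.probs).max()
        assert diffs[0.0] < 0.08
        assert diffs[0.0] < diffs[1.5] / 3

    def test_explicit_degree_sequences_pass_through(self):
        cfg = SimulationConfig(n_genes=3, n_tumors=4,
                               gene_degrees=(2, 1, 1), tumor_degrees=(1, 1, 1, 1))
        g, t = sample_marginals(cfg)
        assert g.tolist() == [2, 1, 1]
        assert t.tolist() == [1, 1, 1, 1]

    def test_unbalanced_explicit_sequences_rejected(self):
        with pytest.raises(ValueError, match="equal sums"):
            SimulationConfig(n_genes=2, n_tumors=2,
                             gene_degrees=(1, 1), tumor_degrees=(2, 1))


class TestConfigurationModel:
    def test_unit_degrees_give_permutation_matrix(self):
        X = generate_null_matrix([1, 1], [1, 1], seed=0)
        assert X.values.sum() == 2
        assert X.gene_sums.tolist() == [1, 1]
        assert X.tumor_sums.tolist() == [1, 1]

    def test_margins_are_exact(self):
        g, t = sample_marginals(SMALL)
        X = generate_null_matrix(g, t, seed=1)
        assert np.array_equal(X.gene_sums, g)
        assert np.array_equal(X.tumor_sums, t)
        assert set(np.unique(X.values)) <= {0, 1}

    def test_different_seeds_differ_with_identical_margins(self):
        g, t = sample_marginals(SMALL)
        X1 = generate_null_matrix(g, t, seed=1)
        X2 = generate_null_matrix(g, t, seed=2)
        assert not np.array_equal(X1.values, X2.values)
        assert np.array_equal(X1.gene_sums, X2.gene_sums)

    def test_infeasible_degree_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_null_matrix([2], [2], seed=0)


@pytest.fixture(scope="module")
def small_null():
    return simulate_null_matrix(SMALL)


class TestQuantileModel:
    def test_median_fit_tracks_binned_quantiles(self, small_null):
        qm = fit_impurity_quantile(small_null, tau=0.5, mode="impurity",
                                   min_alterations=20, seed=0)
        Xf = filter_genes(small_null, 20)
        rows = Xf.values.astype(bool)
        cov, imp = [], []
        for i in range(Xf.n_genes):
            for j in range(i + 1, Xf.n_genes):
                c = int((rows[i] | rows[j]).sum())
                o = int((rows[i] & rows[j]).sum())
                cov.append(c)
                imp.append(o / c if c else 0.0)
        cov, imp = np.array(cov), np.array(imp)
        med = np.median(cov)
        for mask in (cov <= med, cov > med):
            pred = qm.predict(cov[mask].mean())
            emp = np.quantile(imp[mask], 0.5)
            assert abs(pred - emp) < 0.05

    def test_quantile_ordering_and_nonnegativity(self, small_null):
        q01 = fit_impurity_quantile(small_null, 0.01, "impurity",
                                    min_alterations=20)
        q99 = fit_impurity_quantile(small_null, 0.99, "impurity",
                                    min_alterations=20)
        coverages = np.array([40.0, 80.0, 120.0])
        assert (q01.predict(coverages) <= q99.predict(coverages) + 1e-9).all()
        assert (q01.predict(coverages) >= 0).all()

    def test_invalid_tau_rejected(self, small_null):
        with pytest.raises(ValueError, match="tau"):
            fit_impurity_quantile(small_null, 1.5, "impurity", min_alterations=20)


class TestInjectPair:
    def test_me_pair_with_zero_bound_has_zero_overlap(self, small_null):
        qm = QuantileModel(tau=0.01, mode="impurity", intercept=0.0, slope=0.0)
        X, (a, b) = inject_pair(small_null, "me", coverage=60, qmodel=qm, seed=3)
        assert int((X.row(a) & X.row(b)).sum()) == 0
        assert int(X.row(a).sum() + X.row(b).sum()) == 60

    def test_co_pair_overlap_exceeds_bound(self, small_null):
        qm = QuantileModel(tau=0.99, mode="overlap", intercept=2.0, slope=0.05)
        X, (a, b) = inject_pair(small_null, "co", coverage=80, qmodel=qm, seed=3)
        overlap = int((X.row(a) & X.row(b)).sum())
        assert overlap > qm.predict(80)

    def test_unsatisfiable_co_bound_raises(self, small_null):
        qm = QuantileModel(tau=0.99, mode="overlap", intercept=1e4, slope=0.0)
        with pytest.raises(ValueError, match="unsatisfiable"):
            inject_pair(small_null, "co", coverage=40, qmodel=qm, seed=0)

    def test_wrong_model_mode_rejected(self, small_null):
        qm = QuantileModel(tau=0.01, mode="overlap", intercept=0, slope=0)
        with pytest.raises(ValueError, match="impurity-mode"):
            inject_pair(small_null, "me", coverage=40, qmodel=qm, seed=0)


class TestMeGroup:
    def test_group_size_within_bounds_and_exclusive_coverage(self, small_null):
        spec = GroupSpec(coverage_fraction=0.2, impurity=0.02)
        # coverage 40 tumors: round(0.02 * 40) = 1 impure tumor at most
        X, labels = generate_me_group(small_null, spec, seed=2,
                                      min_gene_count=10)
        assert 3 <= len(labels) <= 6
        rows = np.vstack([X.row(g) for g in labels])
        per_tumor = rows.sum(axis=0)
        covered = int((per_tumor >= 1).sum())
        impure = int((per_tumor > 1).sum())
        target_cov = round(0.2 * small_null.n_tumors)
        assert abs(covered - target_cov) <= round(0.02 * target_cov)
        assert abs(impure - round(0.02 * target_cov)) <= 1

    def test_realized_impurity_matches_spec(self, small_null):
        spec = GroupSpec(coverage_fraction=0.5, impurity=0.08)
        X, labels = generate_me_group(small_null, spec, seed=6,
                                      min_gene_count=10)
        rows = np.vstack([X.row(g) for g in labels])
        per_tumor = rows.sum(axis=0)
        coverage = round(0.5 * small_null.n_tumors)
        impure = int((per_tumor > 1).sum())
        assert abs(impure - round(0.08 * coverage)) <= 1

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="coverage_fraction"):
            GroupSpec(coverage_fraction=0.1, impurity=0.02)
        with pytest.raises(ValueError, match="impurity"):
            GroupSpec(coverage_fraction=0.4, impurity=0.5)

    def test_sampled_specs_follow_prescription(self):
        rng = np.random.default_rng(0)
        specs = [sample_group_spec(rng) for _ in range(200)]
        covs = np.array([s.coverage_fraction for s in specs])
        assert covs.min() >= 0.2 and covs.max() <= 0.8
        assert abs(covs.mean() - 0.42) < 0.05  # truncation shifts 0.4 up a little
        assert {s.impurity for s in specs} == {0.02, 0.05, 0.08}


def test_operations_are_pure_functions_of_seed(small_null):
    spec = GroupSpec(coverage_fraction=0.3, impurity=0.05)
    X1, l1 = generate_me_group(small_null, spec, seed=7, min_gene_count=10)
    X2, l2 = generate_me_group(small_null, spec, seed=7, min_gene_count=10)
    assert l1 == l2
    assert np.array_equal(X1.values, X2.values)
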