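"""Dirichlet-multinomial mixture: density, EM, Laplace evidence, assignment."""

from itertools import permutations, product

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from sklearn.metrics import adjusted_rand_score

from commtype.dmm import (
    DMMFit,
    _log_prior,
    assign_clusters,
    dm_log_pmf,
    fit_dmm,
    laplace_evidence,
    load_fit,
    save_fit,
)


def lattice(n, S):
    """All count vectors of length S summing to n."""
    for x in product(range(n + 1), repeat=S):
        if sum(x) == n:
            yield np.array(x)


class TestDMLogPmf:
    def test_single_taxon_is_certain(self):
        assert dm_log_pmf([17], [2.3]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_dirichlet_pair(self):
        # Dirichlet(1,1) makes all 3 outcomes of n=2 equiprobable
        assert dm_log_pmf([1, 1], [1.0, 1.0]) == pytest.approx(np.log(1 / 3))

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_normalizes_over_lattice(self, n):
        alpha = np.array([0.5, 2.0, 1.0])
        total = sum(np.exp(dm_log_pmf(x, alpha)) for x in lattice(n, 3))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(123)
        x = np.array([3, 1, 2])
        alpha = np.array([0.5, 2.0, 1.0])
        M = 200_000
        p = rng.dirichlet(alpha, size=M)
        draws = rng.multinomial(6, p)
        hit = (draws == x).all(axis=1).mean()
        se = np.sqrt(hit * (1 - hit) / M)
        assert abs(np.exp(dm_log_pmf(x, alpha)) - hit) < 3 * se

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length mismatch"):
            dm_log_pmf([1, 2], [1.0])
        with pytest.raises(ValueError, match="positive"):
            dm_log_pmf([1, 2], [1.0, 0.0])
        with pytest.raises(ValueError, match="non-negative"):
            dm_log_pmf([1, -1], [1.0, 1.0])


class TestFitDMM:
    def test_k1_matches_direct_optimization(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        X = counts.counts.to_numpy(float)[:50]
        fit = fit_dmm(X, K=1, seed=0, n_starts=1)
        assert fit.pi == pytest.approx([1.0])

        n = X.sum(axis=1)
        const = (gammaln(n + 1) - gammaln(X + 1).sum(axis=1)).sum()

        def neg(lam):
            a = np.exp(lam)
            A = a.sum()
            ll = (
                const
                + len(X) * gammaln(A)
                - gammaln(n + A).sum()
                + (gammaln(X + a) - gammaln(a)).sum()
            )
            return -(ll + _log_prior(a[None, :]))

        res = minimize(neg, np.log(fit.alpha[0]) + 0.3, method="Nelder-Mead",
                       options={"maxiter": 20000, "fatol": 1e-10, "xatol": 1e-8})
        ours = -neg(np.log(fit.alpha[0]))
        assert ours >= -res.fun - 1e-3

    def test_two_component_recovery(self, two_component_cohort):
        spec, counts, truth = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=3)
        labels = fit.responsibilities.argmax(axis=1) + 1
        assert adjusted_rand_score(truth.true_labels, labels) >= 0.9
        err = min(
            np.max(np.abs(fit.pi[list(p)] - spec.mixing_weights))
            for p in permutations(range(2))
        )
        assert err <= 0.05

    def test_multi_start_stability(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        f1 = fit_dmm(counts, K=2, seed=1, n_starts=3, tol=1e-9)
        f2 = fit_dmm(counts, K=2, seed=99, n_starts=3, tol=1e-9)
        assert abs(f1.log_likelihood - f2.log_likelihood) < 1e-4
        l1 = f1.responsibilities.argmax(axis=1)
        l2 = f2.responsibilities.argmax(axis=1)
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)

    def test_penalized_objective_monotone(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=5, n_starts=1)
        obj = np.array(fit.objective_trace)
        assert (np.diff(obj) >= -1e-7 * (np.abs(obj[:-1]) + 1)).all()

    def test_label_permutation_invariance(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=2)
        permuted = DMMFit(
            K=2,
            alpha=fit.alpha[::-1].copy(),
            pi=fit.pi[::-1].copy(),
            responsibilities=fit.responsibilities[:, ::-1].copy(),
            log_likelihood=fit.log_likelihood,
            genus_ids=fit.genus_ids,
        )
        a = assign_clusters(fit, counts)
        b = assign_clusters(permuted, counts)
        assert ((a.labels == 1) == (b.labels == 2)).all()
        np.testing.assert_allclose(a.max_posterior, b.max_posterior, atol=1e-12)

    def test_depth_cap_still_recovers_partition(self, two_component_cohort):
        _, counts, truth = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=1, depth_cap=1000)
        labels = fit.responsibilities.argmax(axis=1) + 1
        assert adjusted_rand_score(truth.true_labels, labels) >= 0.9

    def test_invalid_inputs(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        with pytest.raises(ValueError, match="K"):
            fit_dmm(counts, K=0, seed=0)
        with pytest.raises(ValueError, match="more samples"):
            fit_dmm(counts.counts.to_numpy()[:2], K=2, seed=0)


class TestLaplaceEvidence:
    def test_duplicated_component_scores_worse(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=2)
        base = laplace_evidence(fit, counts)
        dup = DMMFit(
            K=3,
            alpha=np.vstack([fit.alpha, fit.alpha[-1]]),
            pi=np.concatenate([fit.pi[:-1], [fit.pi[-1] / 2, fit.pi[-1] / 2]]),
            responsibilities=np.column_stack(
                [
                    fit.responsibilities[:, :-1],
                    fit.responsibilities[:, -1] / 2,
                    fit.responsibilities[:, -1] / 2,
                ]
            ),
            log_likelihood=fit.log_likelihood,
            genus_ids=fit.genus_ids,
        )
        assert laplace_evidence(dup, counts) > base

    def test_matches_quadrature_oracle(self):
        # tiny instance: K=1, G=4, N=30; integrate the joint over a lambda grid
        rng = np.random.default_rng(7)
        alpha_true = np.array([5.0, 2.0, 1.0, 0.5])
        N, G = 30, 4
        X = np.vstack(
            [rng.multinomial(200, rng.dirichlet(alpha_true)) for _ in range(N)]
        )
        fit = fit_dmm(X, K=1, seed=0, n_starts=1)
        lap = laplace_evidence(fit, X)

        lam_hat = np.log(fit.alpha[0])
        width, npts = 1.2, 21
        axes = [lam_hat[j] + np.linspace(-width, width, npts) for j in range(G)]
        mesh = np.meshgrid(*axes, indexing="ij")
        lam_grid = np.stack([m.ravel() for m in mesh], axis=1)
        n = X.sum(axis=1)
        const = (gammaln(n + 1) - gammaln(X + 1).sum(axis=1)).sum()
        log_joint = np.empty(len(lam_grid))
        for start in range(0, len(lam_grid), 20000):
            lam = lam_grid[start:start + 20000]
            a = np.exp(lam)
            A = a.sum(axis=1)
            ll = (
                const
                + N * gammaln(A)
                - gammaln(n[:, None] + A[None, :]).sum(axis=0)
                + gammaln(X[:, None, :] + a[None, :, :]).sum(axis=(0, 2))
                - N * gammaln(a).sum(axis=1)
            )
            lp = np.array([_log_prior(row[None, :]) for row in a])
            log_joint[start:start + 20000] = ll + lp
        step = 2 * width / (npts - 1)
        neg_log_evidence = -(logsumexp(log_joint) + G * np.log(step))
        assert abs(lap - neg_log_evidence) < 1.0


class TestAssignClusters:
    def test_training_labels_match_responsibilities(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=2)
        assignment = assign_clusters(fit, counts)
        np.testing.assert_array_equal(
            assignment.labels, fit.responsibilities.argmax(axis=1) + 1
        )

    def test_expected_composition_assigned_confidently(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=2)
        m = fit.expected_compositions()
        proto = np.round(m[0] * 1e4).astype(int)[None, :]
        assignment = assign_clusters(fit, proto)
        assert assignment.labels[0] == 1
        assert assignment.max_posterior[0] > 0.99

    def test_identical_components_tie_to_lowest_index(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        alpha = np.ones((3, counts.n_taxa))
        fit = DMMFit(
            K=3,
            alpha=alpha,
            pi=np.full(3, 1 / 3),
            responsibilities=np.full((counts.n_samples, 3), 1 / 3),
            log_likelihood=0.0,
            genus_ids=counts.taxon_ids,
        )
        assignment = assign_clusters(fit, counts)
        assert (assignment.labels == 1).all()

    def test_genus_mismatch_lists_missing(self, two_component_cohort):
        _, counts, _ = two_component_cohort
        fit = fit_dmm(counts, K=2, seed=0, n_starts=1)
        reduced = counts.subset_taxa(counts.taxon_ids[:-1])
        with pytest.raises(ValueError, match=counts.taxon_ids[-1]):
            assign_clusters(fit, reduced)


def test_fit_round_trips_through_disk(two_component_cohort, tmp_path):
    _, counts, _ = two_component_cohort
    fit = fit_dmm(counts, K=2, seed=0, n_starts=1)
    laplace_evidence(fit, counts)
    save_fit(fit, tmp_path / "fit")
    again = load_fit(tmp_path / "fit")
    np.testing.assert_allclose(again.alpha, fit.alpha)
    np.testing.assert_allclose(again.pi, fit.pi)
    assert again.laplace_score == pytest.approx(fit.laplace_score)
    a = assign_clusters(fit, counts)
    b = assign_clusters(again, counts)
    np.testing.assert_array_equal(a.labels, b.labels)
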