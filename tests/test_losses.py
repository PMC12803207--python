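"""Loss components against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from cellstack._autograd import Tensor
from cellstack.losses import (assemble_posttrain_loss, assemble_pretrain_loss,
                              energy_distance, gene_alignment_loss,
                              masked_recon_loss, nb_nll, pearson_residual_hvg,
                              pearson_residual_scores, sliced_wasserstein_prior,
                              zin_sample)


def quadrature_nb_logpmf(x, mu, theta):
    """Independent oracle: NB as a gamma-Poisson mixture by numerical
    integration over the mixing rate (dense trapezoid on the region where
    either factor has mass)."""
    sd = mu / np.sqrt(theta)
    hi = max(mu + 12 * sd, x + 12 * np.sqrt(x + 1), 30.0)
    lam = np.linspace(1e-12, hi, 60_000)
    integrand = stats.poisson.pmf(x, lam) * stats.gamma.pdf(lam, a=theta,
                                                            scale=mu / theta)
    return np.log(np.trapezoid(integrand, lam))


class TestNBNLL:
    def test_geometric_closed_forms(self):
        assert np.isclose(nb_nll(0.0, 1.0, 1.0).item(), np.log(2), atol=1e-6)
        assert np.isclose(nb_nll(1.0, 1.0, 1.0).item(), np.log(4), atol=1e-6)

    def test_matches_quadrature_oracle(self, rng):
        xs = rng.integers(0, 30, size=40)
        mus = rng.uniform(0.2, 20.0, size=40)
        thetas = rng.uniform(0.5, 50.0, size=40)
        ours = nb_nll(xs.astype(float), mus, thetas).data
        oracle = np.array([-quadrature_nb_logpmf(x, m, t)
                           for x, m, t in zip(xs, mus, thetas)])
        assert np.abs(ours - oracle).max() < 1e-6

    def test_stable_at_large_theta(self):
        # theta -> inf approaches Poisson
        val = nb_nll(3.0, 2.5, 1e6).item()
        pois = -stats.poisson.logpmf(3, 2.5)
        assert np.isfinite(val) and abs(val - pois) < 1e-4

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_nll(np.array([-1.0]), np.array([1.0]), np.array([1.0]))


class TestMaskedRecon:
    def test_full_mask_averages_whole_matrix(self, rng):
        counts = rng.poisson(3, size=(4, 6)).astype(float)
        rho = rng.dirichlet(np.ones(6), size=4)
        theta = rng.uniform(1, 5, size=(4, 6))
        lib = counts.sum(axis=1)
        full = masked_recon_loss(counts, range(6), rho, theta, lib)
        direct = nb_nll(counts, lib[:, None] * rho, theta).mean()
        assert np.isclose(full.item(), direct.item(), atol=1e-12)

    def test_invariant_to_unmasked_params(self, rng):
        counts = rng.poisson(3, size=(4, 6)).astype(float)
        rho = rng.dirichlet(np.ones(6), size=4)
        theta = rng.uniform(1, 5, size=(4, 6))
        lib = counts.sum(axis=1)
        a = masked_recon_loss(counts, [1, 4], rho, theta, lib).item()
        rho2, theta2 = rho.copy(), theta.copy()
        rho2[:, [0, 2, 3, 5]] = rng.dirichlet(np.ones(4), size=4)
        theta2[:, [0, 2, 3, 5]] = 99.0
        b = masked_recon_loss(counts, [1, 4], rho2, theta2, lib).item()
        assert a == b

    def test_hand_computed_two_cell_case(self):
        # 2 cells, 2 masked genes, mu = l * rho chosen to give mu=1, theta=1
        counts = np.array([[0.0, 1.0], [1.0, 0.0]])
        rho = np.array([[0.5, 0.5], [0.5, 0.5]])
        theta = np.ones((2, 2))
        lib = np.array([2.0, 2.0])
        # every entry has mu=1, theta=1: nll(0)=log2, nll(1)=log4
        expected = (np.log(2) + np.log(4) + np.log(4) + np.log(2)) / 4
        got = masked_recon_loss(counts, [0, 1], rho, theta, lib).item()
        assert np.isclose(got, expected, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_recon_loss(np.zeros((2, 2)), [], np.ones((2, 2)) / 2,
                              np.ones((2, 2)), np.array([1.0, 1.0]))


class TestSlicedWasserstein:
    def test_self_distance_small(self):
        rng = np.random.default_rng(3)
        emb = rng.standard_normal((128, 16))
        vals = [sliced_wasserstein_prior(emb, n_projections=256,
                                         rng=np.random.default_rng(s)).item()
                for s in range(10)]
        assert np.mean(vals) < 0.05

    def test_single_direction_matches_order_statistic_oracle(self):
        """With nd=1 every unit direction is +-e1, so the loss equals the
        squared 1-D W2 between sorted samples and sorted prior draws."""
        rng = np.random.default_rng(5)
        emb = rng.normal(2.0, 3.0, size=(64, 1))
        seed = 17
        loss = sliced_wasserstein_prior(emb, n_projections=1, subset_range=(64, 64),
                                        rng=np.random.default_rng(seed)).item()
        # replay the same RNG stream to reconstruct the oracle
        r = np.random.default_rng(seed)
        m = int(r.integers(64, 65))
        sub = emb[np.sort(r.choice(64, size=m, replace=False))]
        prior = r.standard_normal((m, 1)) + sub.mean(axis=0, keepdims=True)
        d = r.standard_normal((1, 1))
        sign = np.sign(d / np.abs(d)).item()
        oracle = np.mean((np.sort(sign * sub[:, 0]) - np.sort(sign * prior[:, 0])) ** 2)
        assert np.isclose(loss, oracle, atol=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        emb = rng.standard_normal((100, 8))
        shift = emb + rng.normal(50.0, 1.0, size=(1, 8))
        a = sliced_wasserstein_prior(emb, rng=np.random.default_rng(1)).item()
        b = sliced_wasserstein_prior(shift, rng=np.random.default_rng(1)).item()
        assert np.isclose(a, b, atol=1e-8)

    def test_decreases_along_interpolation_to_prior(self):
        """Embeddings interpolated toward a standard normal cloud move the
        loss toward its self-distance floor (fixed projections)."""
        rng = np.random.default_rng(11)
        start = rng.standard_normal((128, 8)) * 6.0  # far from unit covariance
        goal = rng.standard_normal((128, 8))
        vals = []
        for w in [0.0, 0.5, 1.0]:
            emb = (1 - w) * start + w * goal
            vals.append(np.mean([
                sliced_wasserstein_prior(emb, n_projections=128,
                                         rng=np.random.default_rng(s)).item()
                for s in range(5)]))
        assert vals[0] > vals[1] > vals[2]

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            sliced_wasserstein_prior(np.zeros((1, 4)), rng=np.random.default_rng(0))


class TestEnergyDistance:
    def test_identity_zero(self, rng):
        a = rng.standard_normal((10, 3))
        assert abs(energy_distance(a, a).item()) < 1e-12

    def test_two_point_closed_form(self):
        assert np.isclose(energy_distance([[0.0]], [[3.0]]).item(), 6.0, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        a = rng.standard_normal((20, 3))
        b = rng.standard_normal((15, 3))
        ours = energy_distance(a, b).item()
        ab = np.mean([np.linalg.norm(x - y) for x in a for y in b])
        aa = np.mean([np.linalg.norm(x - y) for x in a for y in a])
        bb = np.mean([np.linalg.norm(x - y) for x in b for y in b])
        assert abs(ours - (2 * ab - aa - bb)) < 1e-10

    def test_symmetric_and_nonnegative(self, rng):
        a = rng.standard_normal((8, 4))
        b = rng.standard_normal((12, 4)) + 1.0
        d1, d2 = energy_distance(a, b).item(), energy_distance(b, a).item()
        assert np.isclose(d1, d2, atol=1e-12) and d1 >= 0


class TestZinSample:
    def test_degenerate_small_mu_gives_zeros(self):
        rng = np.random.default_rng(0)
        rho = np.full((50, 10), 1e-9)
        theta = np.ones((50, 10))
        out = zin_sample(rho, theta, np.ones(50), np.ones(50), rng).data
        assert (out == 0).mean() > 0.99

    def test_moments_match_monte_carlo_nb_oracle(self):
        """Sampled mean/variance of log-normalized values within 2% of an
        explicit NB-simulation oracle."""
        mu, theta, s = 50.0, 1e4, 1.0
        n = 200_000
        rng = np.random.default_rng(1)
        rho = np.full((n, 1), mu)
        out = zin_sample(rho, np.full((n, 1), theta), np.ones(n), np.full(n, s),
                         np.random.default_rng(2)).data.ravel()
        lam = rng.gamma(theta, mu / theta, size=n)
        counts = rng.poisson(lam)
        oracle = np.log1p(s * counts)
        assert abs(out.mean() - oracle.mean()) / abs(oracle.mean()) < 0.02
        assert abs(out.var() - oracle.var()) / oracle.var() < 0.02

    def test_gradient_of_mean_wrt_rate_positive(self):
        rho = Tensor(np.full((1, 1), 5.0), requires_grad=True)
        theta = Tensor(np.full((1, 1), 2.0))
        out = zin_sample(rho, theta, np.ones(1), np.ones(1), np.random.default_rng(3))
        out.mean().backward()
        assert np.isfinite(rho.grad).all() and rho.grad[0, 0] > 0


class TestPearsonResidualHVG:
    def test_constant_gene_with_equal_libraries_scores_zero(self):
        # equal library sizes + constant counts -> exactly zero residual variance
        rng = np.random.default_rng(4)
        counts = np.full((30, 10), 2)
        counts[:, :5] += rng.integers(0, 6, size=(30, 5))
        counts[:, 9] += counts.sum(axis=1).max() - counts.sum(axis=1)  # equalize rows
        assert len(np.unique(counts.sum(axis=1))) == 1
        scores = pearson_residual_scores(counts)
        assert scores[6] == 0.0  # constant gene, untouched by the noise block
        ranked = pearson_residual_hvg(counts, n_top=10)
        assert scores[ranked[-1]] == 0.0

    def test_full_ranking_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        x = rng.poisson(3.0, size=(50, 30)).astype(float)
        x[0, 0] += 1  # ensure non-degenerate
        theta = 100.0
        total = x.sum()
        mu = x.sum(axis=1)[:, None] * x.sum(axis=0)[None, :] / total
        r = (x - mu) / np.sqrt(mu + mu ** 2 / theta)
        oracle = np.argsort(-r.var(axis=0), kind="stable")
        assert np.array_equal(pearson_residual_hvg(x, n_top=30), oracle)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pearson_residual_scores(np.zeros((5, 5)))


class TestGeneAlignment:
    def test_loss_invariant_to_genes_outside_hvg(self, rng):
        k, g = 8, 12
        rho = rng.dirichlet(np.ones(g), size=k)
        lib = np.full(k, 100.0)
        types = np.array(["a"] * 4 + ["b"] * 4)
        target = rng.normal(size=(k, g))
        hvg = np.array([0, 1, 2, 3])
        a = gene_alignment_loss(rho, 10.0, lib, np.ones(k), types, target, types,
                                hvg, np.random.default_rng(5)).item()
        target2 = target.copy()
        target2[:, 6:] += 100.0
        b = gene_alignment_loss(rho, 10.0, lib, np.ones(k), types, target2, types,
                                hvg, np.random.default_rng(5)).item()
        assert np.isclose(a, b, atol=1e-12)

    def test_two_type_case_averages_per_type_distances(self, rng):
        k, g = 10, 6
        rho = rng.dirichlet(np.ones(g), size=k)
        lib = np.full(k, 50.0)
        types = np.array(["a"] * 5 + ["b"] * 5)
        target = rng.normal(size=(k, g))
        hvg = np.arange(g)
        combined = gene_alignment_loss(rho, 5.0, lib, np.ones(k), types, target,
                                       types, hvg, np.random.default_rng(9)).item()
        # manual stratification with the same RNG stream
        r = np.random.default_rng(9)
        parts = []
        from cellstack.losses import zin_sample as zs, energy_distance as ed
        for sel in (slice(0, 5), slice(5, 10)):
            theta_block = np.full((5, g), 5.0)
            sample = zs(rho[sel], theta_block, lib[sel], np.ones(5), r)
            parts.append(ed(sample, target[sel]).item())
        assert np.isclose(combined, np.mean(parts), atol=1e-10)

    def test_no_shared_types_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_alignment_loss(rng.dirichlet(np.ones(4), size=2), 5.0,
                                np.ones(2), np.ones(2), np.array(["a", "a"]),
                                rng.normal(size=(2, 4)), np.array(["b", "b"]),
                                np.arange(4), np.random.default_rng(0))


class TestAssembly:
    def test_zero_components_zero_total(self):
        z = Tensor(0.0)
        total, rep = assemble_posttrain_loss(z, z, z, z, z)
        assert rep.total == 0.0

    def test_sw_weight_ablation(self):
        total, rep = assemble_pretrain_loss(Tensor(2.5), Tensor(7.0), lambda_sw=0.0)
        assert rep.total == 2.5

    def test_posttrain_weighted_arithmetic(self):
        total, rep = assemble_posttrain_loss(Tensor(2.0), Tensor(4.0), Tensor(1.0),
                                             Tensor(1.0), Tensor(1.0))
        assert np.isclose(rep.dist, 3.0)
        assert np.isclose(rep.total, 3.0 + 1.0 + 0.01 + 1.0)
        assert np.isclose(total.item(), 5.01)

    def test_report_reconstructs_total(self):
        rng = np.random.default_rng(8)
        g, e, r, s, c = [Tensor(v) for v in rng.uniform(0.1, 2.0, size=5)]
        total, rep = assemble_posttrain_loss(g, e, r, s, c, lambda_sw=0.3,
                                             lambda_recon=0.7, lambda_cls=1.3)
        lam_sw, lam_rec, lam_cls = rep.weights
        rebuilt = rep.dist + lam_rec * rep.recon + lam_sw * rep.sw + lam_cls * rep.cls
        assert np.isclose(rebuilt, rep.total, atol=1e-6)
        assert np.isclose(rep.dist, 0.5 * (rep.gene + rep.embed), atol=1e-12)
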