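"""Objective components for pretraining and post-training.

All losses are written against the numpy autograd :class:`~cellstack._autograd.Tensor`
and return scalar tensors; plain arrays are accepted and wrapped as
constants. The negative-binomial likelihood uses the (mean mu,
inverse-overdispersion theta) parameterization with variance mu + mu^2/theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor

log = logging.getLogger(__name__)

__all__ = [
    "LossReport",
    "nb_nll",
    "masked_recon_loss",
    "sliced_wasserstein_prior",
    "energy_distance",
    "zin_sample",
    "pearson_residual_scores",
    "pearson_residual_hvg",
    "gene_alignment_loss",
    "assemble_pretrain_loss",
    "assemble_posttrain_loss",
]

_MU_FLOOR = 1e-10


@dataclass(frozen=True)
class LossReport:
    """Scalar loss components plus the weighted total.

    ``total`` reproduces ``recon + lambda_sw * sw`` (pretraining) or
    ``dist + lambda_recon * recon + lambda_sw * sw + lambda_cls * cls``
    (post-training) with ``dist = 0.5 * (gene + embed)``.
    """

    recon: float = 0.0
    sw: float = 0.0
    embed: float = 0.0
    gene: float = 0.0
    dist: float = 0.0
    cls: float = 0.0
    total: float = 0.0
    weights: tuple = (0.01, 1.0, 1.0)  # (lambda_sw, lambda_recon, lambda_cls)


def nb_nll(x, mu, theta) -> Tensor:
    """Elementwise -log NB(x; mu, theta).

    log P(x) = lgamma(x+theta) - lgamma(theta) - lgamma(x+1)
             + theta*log(theta/(theta+mu)) + x*log(mu/(theta+mu)),
    computed with log1p so it stays stable for theta up to ~1e6.
    """
    x_arr = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64)
    if np.any(x_arr < 0):
        raise ValueError("counts must be non-negative")
    x = Tensor(x_arr)
    mu = as_tensor(mu) + _MU_FLOOR
    theta = as_tensor(theta)
    ratio = mu / theta
    log_1p_ratio = ratio.log1p()                       # log((theta+mu)/theta)
    logp = ((x + theta).lgamma() - theta.lgamma() - Tensor(_gammaln(x_arr + 1.0))
            - theta * log_1p_ratio
            + x * (mu.log() - theta.log() - log_1p_ratio))
    return -logp


def _gammaln(a):
    from scipy import special

    return special.gammaln(a)


def masked_recon_loss(counts, masked_genes, rho, theta, library) -> Tensor:
    """Mean NB negative log-likelihood over the K x |M| masked entries only,
    with per-entry mean l_k * rho_kg."""
    masked = np.asarray(sorted(set(int(g) for g in np.atleast_1d(list(masked_genes)))))
    if masked.size == 0:
        raise ValueError("masked gene set must be non-empty")
    counts = np.asarray(counts.data if isinstance(counts, Tensor) else counts)
    lib = np.asarray(library, dtype=np.float64).reshape(-1, 1)
    mu = as_tensor(rho)[:, masked] * Tensor(lib)
    th = as_tensor(theta)[:, masked]
    return nb_nll(counts[:, masked], mu, th).mean()


def sliced_wasserstein_prior(flat, n_projections: int = 64,
                             subset_range: tuple = (32, 128),
                             rng: np.random.Generator | None = None) -> Tensor:
    """Sliced Wasserstein-2 distance between a random subset of the cell
    embeddings and a Gaussian prior centered at the subset mean with identity
    covariance.

    The subset size is drawn uniformly from ``subset_range`` (clamped to K).
    Because the prior is centered on the embeddings themselves, the loss is
    invariant to translating the whole set - it penalizes only the shape of
    the distribution around its mean.
    """
    rng = np.random.default_rng() if rng is None else rng
    flat = as_tensor(flat)
    k, nd = flat.shape
    if k < 2:
        raise ValueError("sliced Wasserstein prior needs at least 2 cells")
    lo, hi = subset_range
    m = int(min(rng.integers(lo, hi + 1), k))
    sub = flat[np.sort(rng.choice(k, size=m, replace=False))]
    center = sub.mean(axis=0, keepdims=True)
    prior = Tensor(rng.standard_normal((m, nd))) + center
    dirs = rng.standard_normal((nd, n_projections))
    dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
    pe = (sub @ Tensor(dirs)).sort(axis=0)
    pp = (prior @ Tensor(dirs)).sort(axis=0)
    diff = pe - pp
    return (diff * diff).mean()


def _pairwise_dist(a: Tensor, b: Tensor) -> Tensor:
    # (m,p) x (q,p) -> (m,q) Euclidean distances (value-exact; sqrt backward
    # treats zero distances as having zero subgradient)
    diff = a.reshape(a.shape[0], 1, a.shape[1]) - b.reshape(1, b.shape[0], b.shape[1])
    return (diff * diff).sum(axis=-1).sqrt()


def energy_distance(a, b) -> Tensor:
    """V-statistic energy distance 2 E||A-B|| - E||A-A'|| - E||B-B'||."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("energy_distance expects (m,p) and (q,p) arrays")
    return (2.0 * _pairwise_dist(a, b).mean()
            - _pairwise_dist(a, a).mean()
            - _pairwise_dist(b, b).mean())


def zin_sample(rho, theta, library, norm_scale, rng: np.random.Generator) -> Tensor:
    """Reparameterized zero-inflated normal surrogate for log-normalized NB draws.

    Per entry: with probability pi = NB(0; mu, theta) the sample is zero;
    otherwise it is a Gaussian draw (mean + sd * standard normal) whose
    mixture mean/variance match a delta-method approximation of the first two
    moments of log1p(s * x) for x ~ NB(mu, theta), where s is the per-cell
    normalization scale. Gradients flow to (rho, theta) through the Gaussian
    branch and through pi's appearance in the moment-matching algebra.
    """
    rho, theta = as_tensor(rho), as_tensor(theta)
    lib = np.asarray(library, dtype=np.float64).reshape(-1, 1)
    s = np.asarray(norm_scale, dtype=np.float64).reshape(-1, 1)
    mu = rho * Tensor(lib) + _MU_FLOOR

    # pi = P(X = 0) = (theta/(theta+mu))^theta
    log_pi = theta * (-(mu / theta).log1p())
    pi = log_pi.exp()

    # third-order delta-method moments of y = log1p(s*x) over the full NB
    # distribution, using NB cumulants k2..k4 (k5, k6 dropped: lower order)
    st = Tensor(s)
    k2 = mu + mu * mu / theta
    k3 = mu + 3.0 * mu * mu / theta + 2.0 * mu * mu * mu / theta ** 2.0
    k4 = (mu + 7.0 * mu * mu / theta + 12.0 * mu * mu * mu / theta ** 2.0
          + 6.0 * mu * mu * mu * mu / theta ** 3.0)
    m4 = k4 + 3.0 * k2 * k2
    m5 = 10.0 * k3 * k2
    m6 = 15.0 * k2 * k2 * k2 + 15.0 * k4 * k2 + 10.0 * k3 * k3
    one_plus = mu * st + 1.0
    a = st / one_plus                        # f'
    b = -0.5 * a * a                         # f''/2
    c = (a * a * a) * (1.0 / 3.0)            # f'''/6
    bias = b * k2 + c * k3
    m_full = (mu * st).log1p() + bias
    v_full = (a * a * k2 + 2.0 * a * b * k3 + (b * b + 2.0 * a * c) * m4
              + 2.0 * b * c * m5 + c * c * m6 - bias * bias)

    # solve the two-component mixture for the Gaussian branch
    keep = 1.0 - pi
    keep_f = Tensor(np.maximum(keep.data, 1e-6)) + (keep - Tensor(keep.data))  # clamp value, keep grad
    m_g = m_full / keep_f
    v_g = (v_full + m_full * m_full) / keep_f - m_g * m_g
    bad = np.sum(v_g.data <= 0)
    if bad:
        log.debug("zin_sample clamped %d non-positive variances", int(bad))
    v_g = v_g.relu() + 1e-6

    zero_mask = rng.uniform(size=mu.shape) < pi.data
    eps = rng.standard_normal(mu.shape)
    gauss = m_g + v_g.sqrt() * Tensor(eps)
    return gauss * Tensor((~zero_mask).astype(np.float64))


def pearson_residual_scores(counts, theta_pr: float = 100.0, zero_variance_rank_last: bool = True
                            ) -> np.ndarray:
    """Per-gene variance of analytic Pearson residuals (HVG score).

    r_kg = (x_kg - mu_kg) / sqrt(mu_kg + mu_kg^2/theta_pr) with
    mu_kg = row_k * col_g / total.
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a K x G matrix with K, G >= 2")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count matrix")
    mu = np.outer(x.sum(axis=1), x.sum(axis=0)) / total
    denom = np.sqrt(mu + mu * mu / theta_pr)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (x - mu) / denom, 0.0)
    return r.var(axis=0)


def pearson_residual_hvg(counts, n_top: int, theta_pr: float = 100.0) -> np.ndarray:
    """Indices of the top ``n_top`` genes ranked by Pearson-residual variance
    (descending; ties broken by gene order)."""
    scores = pearson_residual_scores(counts, theta_pr=theta_pr)
    order = np.argsort(-scores, kind="stable")
    return order[:n_top]


def gene_alignment_loss(rho, shared_theta, library, norm_scale, query_types,
                        target_expr, target_types, hvg, rng: np.random.Generator,
                        min_cells: int = 2) -> Tensor:
    """Energy distance between ZIN-sampled predicted expression and target
    log-normalized expression, restricted to ``hvg`` genes and averaged over
    cell types with at least ``min_cells`` members on both sides.

    ``shared_theta`` is a scalar over-dispersion shared by all query entries
    (median detached over-dispersion from prompt cells)."""
    hvg = np.asarray(hvg)
    rho, target = as_tensor(rho), as_tensor(target_expr)
    query_types = np.asarray(query_types).astype(str)
    target_types = np.asarray(target_types).astype(str)
    lib = np.asarray(library, dtype=np.float64)
    scale = np.asarray(norm_scale, dtype=np.float64)

    types = sorted(set(query_types) & set(target_types))
    terms = []
    for t in types:
        qi = np.flatnonzero(query_types == t)
        ti = np.flatnonzero(target_types == t)
        if len(qi) < min_cells or len(ti) < min_cells:
            continue
        theta_block = as_tensor(shared_theta) * Tensor(np.ones((len(qi), len(hvg))))
        sample = zin_sample(rho[qi][:, hvg], theta_block, lib[qi], scale[qi], rng)
        terms.append(energy_distance(sample, target[ti][:, hvg]))
    if not terms:
        raise ValueError("no cell type has enough cells on both sides")
    out = terms[0]
    for term in terms[1:]:
        out = out + term
    return out / len(terms)


def assemble_pretrain_loss(recon: Tensor, sw: Tensor, lambda_sw: float = 0.01
                           ) -> tuple[Tensor, LossReport]:
    total = recon + lambda_sw * sw
    report = LossReport(recon=float(recon.data), sw=float(sw.data),
                        total=float(total.data), weights=(lambda_sw, 1.0, 1.0))
    return total, report


def assemble_posttrain_loss(gene: Tensor, embed: Tensor, recon: Tensor, sw: Tensor,
                            cls: Tensor, lambda_sw: float = 0.01,
                            lambda_recon: float = 1.0, lambda_cls: float = 1.0
                            ) -> tuple[Tensor, LossReport]:
    dist = 0.5 * (gene + embed)
    total = dist + lambda_recon * recon + lambda_sw * sw + lambda_cls * cls
    report = LossReport(recon=float(recon.data), sw=float(sw.data),
                        embed=float(embed.data), gene=float(gene.data),
                        dist=float(dist.data), cls=float(cls.data),
                        total=float(total.data),
                        weights=(lambda_sw, lambda_recon, lambda_cls))
    return total, report
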