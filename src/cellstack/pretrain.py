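"""Rectangular-mask sampling and the self-supervised pretraining loop.

One optimization step: draw a gene mask shared by every cell of every set in
the mini-batch, encode each set with the masked genes zeroed, decode to NB
parameters, and minimize the masked-gene NB negative log-likelihood plus the
sliced-Wasserstein latent regularizer (weight ``lambda_sw``). The learning
rate follows a linear warmup into cosine annealing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import CellSet
from .losses import (LossReport, assemble_pretrain_loss, masked_recon_loss,
                     sliced_wasserstein_prior)
from .model import StackModel
from .nn import AdamW, warmup_cosine_lr

log = logging.getLogger(__name__)

__all__ = ["MaskSpec", "TrainConfig", "sample_rectangular_mask", "pretrain_step",
           "fit_pretrain", "validate"]


@dataclass(frozen=True)
class MaskSpec:
    """A gene subset masked identically across all cells (rectangular mask)."""

    masked_genes: tuple
    ratio: float
    bounds: tuple

    def __post_init__(self):
        if not self.masked_genes:
            raise ValueError("mask must contain at least one gene")


@dataclass
class TrainConfig:
    epochs: int = 10
    peak_lr: float = 1e-4
    min_lr: float = 0.0
    weight_decay: float = 3e-3
    warmup_epochs: int = 1
    schedule: str = "cosine"
    batch_size: int = 4
    grad_accum: int = 1
    seed: int = 0
    lambda_sw: float = 0.01
    sw_projections: int = 64
    sw_subset_range: tuple = (32, 128)
    mask_bounds: tuple = (0.1, 0.8)
    clip_norm: float = 1.0
    val_every: int = 1

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.grad_accum) < 1 or self.peak_lr <= 0:
            raise ValueError("invalid training configuration")


def sample_rectangular_mask(n_genes: int, bounds: tuple = (0.1, 0.8),
                            rng: np.random.Generator | None = None) -> MaskSpec:
    """Masking ratio ~ Uniform(bounds); |M| = round-half-up(ratio*G), at least
    one gene; genes drawn uniformly without replacement."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes to mask")
    p_min, p_max = bounds
    if not (0 < p_min <= p_max < 1):
        raise ValueError("mask bounds must satisfy 0 < p_min <= p_max < 1")
    rng = np.random.default_rng() if rng is None else rng
    ratio = float(rng.uniform(p_min, p_max))
    m = max(1, int(np.floor(ratio * n_genes + 0.5)))
    genes = tuple(int(g) for g in np.sort(rng.choice(n_genes, size=m, replace=False)))
    return MaskSpec(masked_genes=genes, ratio=ratio, bounds=tuple(bounds))


def _batch_loss(model: StackModel, batch: list[CellSet], mask: MaskSpec,
                cfg: TrainConfig, rng: np.random.Generator):
    genes0 = batch[0].genes
    recon_terms, sw_terms = [], []
    for cs in batch:
        if not np.array_equal(cs.genes, genes0):
            raise ValueError("all sets in a batch must share one gene index")
        emb, params = model.forward_params(cs.counts, cs.library_size,
                                           masked_genes=mask.masked_genes)
        recon_terms.append(masked_recon_loss(cs.counts, mask.masked_genes,
                                             params.rho, params.theta, cs.library_size))
        sw_terms.append(sliced_wasserstein_prior(emb.flat, n_projections=cfg.sw_projections,
                                                 subset_range=cfg.sw_subset_range, rng=rng))
    recon = recon_terms[0]
    sw = sw_terms[0]
    for t in recon_terms[1:]:
        recon = recon + t
    for t in sw_terms[1:]:
        sw = sw + t
    recon = recon / len(batch)
    sw = sw / len(batch)
    return assemble_pretrain_loss(recon, sw, lambda_sw=cfg.lambda_sw)


def pretrain_step(model: StackModel, optimizer: AdamW, batch: list[CellSet],
                  mask: MaskSpec, cfg: TrainConfig,
                  rng: np.random.Generator) -> LossReport:
    total, report = _batch_loss(model, batch, mask, cfg, rng)
    if not np.isfinite(report.total):
        raise FloatingPointError(
            f"non-finite pretraining loss on batch of samples "
            f"{[cs.sample_id for cs in batch]}: {report}")
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return report


def fit_pretrain(model: StackModel, data: list[CellSet], cfg: TrainConfig,
                 val_sets: list[CellSet] | None = None) -> dict:
    """Run the pretraining loop; returns a history dict. When validation sets
    are given, the best-validation weights are restored at the end."""
    if not data:
        raise ValueError("no training sets provided")
    rng = np.random.default_rng(cfg.seed)
    mask_rng = np.random.default_rng(rng.integers(2 ** 31))
    sw_rng = np.random.default_rng(rng.integers(2 ** 31))
    optimizer = AdamW(model.parameters(), lr=cfg.peak_lr,
                      weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    n_batches = int(np.ceil(len(data) / cfg.batch_size))
    total_steps = cfg.epochs * n_batches
    warmup_steps = cfg.warmup_epochs * n_batches
    history = {"train_loss": [], "val": [], "lr": []}
    best = {"loss": np.inf, "state": None, "epoch": -1}
    step = 0
    g = data[0].n_genes
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for b in range(n_batches):
            batch = [data[i] for i in order[b * cfg.batch_size:(b + 1) * cfg.batch_size]]
            mask = sample_rectangular_mask(g, cfg.mask_bounds, mask_rng)
            optimizer.lr = warmup_cosine_lr(step, total_steps, warmup_steps,
                                            cfg.peak_lr, cfg.min_lr)
            report = pretrain_step(model, optimizer, batch, mask, cfg, sw_rng)
            epoch_losses.append(report.total)
            history["lr"].append(optimizer.lr)
            step += 1
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_sets and (epoch + 1) % cfg.val_every == 0:
            metrics = validate(model, val_sets, seed=cfg.seed)
            history["val"].append({"epoch": epoch, **metrics})
            if metrics["masked_nll"] < best["loss"]:
                best = {"loss": metrics["masked_nll"], "state": model.state_dict(),
                        "epoch": epoch}
        log.info("epoch %d loss %.4f", epoch, history["train_loss"][-1])
    if best["state"] is not None:
        model.load_state_dict(best["state"])
        history["best_epoch"] = best["epoch"]
    return history


def validate(model: StackModel, val_sets: list[CellSet], mask_ratio: float = 0.5,
             seed: int = 1234, score_rows: np.ndarray | None = None) -> dict:
    """Deterministic validation at a fixed mask ratio: masked NB NLL and the
    Pearson correlation between log1p predicted means and log1p observed
    counts over masked entries.

    ``score_rows`` restricts scoring to a fixed subset of cells in every set
    (the whole set still provides context), which removes cell-composition
    variance when comparing different context constructions."""
    nlls, preds, obs = [], [], []
    for i, cs in enumerate(val_sets):
        rng = np.random.default_rng(seed + i)
        g = cs.n_genes
        m = max(1, int(np.floor(mask_ratio * g + 0.5)))
        masked = np.sort(rng.choice(g, size=m, replace=False))
        _, params = model.forward_params(cs.counts, cs.library_size, masked_genes=masked)
        rows = np.arange(cs.n_cells) if score_rows is None else np.asarray(score_rows)
        nll = masked_recon_loss(cs.counts[rows], masked, params.rho[rows],
                                params.theta[rows], cs.library_size[rows])
        nlls.append(float(nll.data))
        mu = params.mu(cs.library_size).data[np.ix_(rows, masked)]
        preds.append(np.log1p(mu).ravel())
        obs.append(np.log1p(cs.counts[np.ix_(rows, masked)]).ravel())
    r = stats.pearsonr(np.concatenate(preds), np.concatenate(obs)).statistic
    return {"masked_nll": float(np.mean(nlls)), "masked_pearson": float(r)}
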