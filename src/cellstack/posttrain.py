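"""Prompt/query input construction, cell-type balancing, the EMA teacher,
and the composite distributional-alignment objective.

A post-training example starts from a cell set of one (perturbed) sample.
After cell-type balancing, cells are ordered in randomized type blocks; the
first 25% become prompt-condition cells (used unchanged), the remaining 75%
are split by a Uniform(0,1) kept-ratio into prompt-context positions (whose
expression is resampled from the teacher's NB predictions) and query
positions (filled with type-matched cells from a different context). The
displaced originals are the ground-truth targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from .io_core import CellSet
from .losses import (LossReport, assemble_posttrain_loss, energy_distance,
                     gene_alignment_loss, masked_recon_loss, pearson_residual_hvg,
                     sliced_wasserstein_prior)
from .model import (ROLE_PROMPT_CONDITION, ROLE_PROMPT_CONTEXT, ROLE_QUERY,
                    StackModel, build_causal_mask)
from .nn import AdamW, warmup_cosine_lr
from .pretrain import sample_rectangular_mask

log = logging.getLogger(__name__)

__all__ = ["PromptedInput", "EmaTeacher", "PosttrainConfig", "balance_cell_types",
           "build_prompted_input", "ema_update", "posttrain_step", "fit_posttrain"]


@dataclass
class PromptedInput:
    """Role-annotated assembled input set with aligned ground-truth targets."""

    cells: CellSet                 # X_in: condition | resampled context | query
    roles: np.ndarray              # (K,) role labels
    target: CellSet                # displaced originals, aligned to query positions
    type_of: np.ndarray            # (K,) cell-type labels
    first_instance: np.ndarray     # (K,) False for duplicate copies from balancing
    query_positions: np.ndarray    # indices into cells for query rows
    original_cells: CellSet        # balanced/ordered prompt sample before replacement

    def __post_init__(self):
        k = self.cells.n_cells
        n_cond = int(np.sum(self.roles == ROLE_PROMPT_CONDITION))
        if n_cond != int(round(0.25 * k)):
            raise ValueError("prompt-condition block must be 25% of the set")
        if len(self.query_positions) != self.target.n_cells:
            raise ValueError("targets must align one-to-one with query positions")


@dataclass
class EmaTeacher:
    """Frozen teacher whose weights track the student by EMA."""

    model: StackModel
    decay: float = 0.95
    update_interval: int = 500
    step_count: int = 0

    def state(self) -> dict:
        return self.model.state_dict()


def ema_update(teacher: EmaTeacher, student_state: dict, step: int | None = None
               ) -> EmaTeacher:
    """teacher <- decay * teacher + (1 - decay) * student.

    When ``step`` is given, the blend is applied only when the step counter
    hits the teacher's update interval; otherwise it is applied directly.
    """
    if step is not None and step % teacher.update_interval != 0:
        return teacher
    own = dict(teacher.model.named_parameters())
    if set(own) != set(student_state):
        raise ValueError("teacher/student parameter sets differ")
    d = teacher.decay
    for key, p in own.items():
        if p.data.shape != student_state[key].shape:
            raise ValueError(f"shape mismatch for {key}")
        p.data = d * p.data + (1.0 - d) * student_state[key]
    return teacher


def balance_cell_types(cells: CellSet, rng: np.random.Generator
                       ) -> tuple[CellSet, np.ndarray]:
    """Downsample overrepresented types to the per-type average (rounded
    down), then upsample the pool with replacement back to the original set
    size. Returns the balanced set and first-instance flags (False marks
    duplicate copies)."""
    if cells.cell_type is None:
        raise ValueError("cell_type labels are required for balancing")
    k = cells.n_cells
    if k <= 1:
        return cells, np.ones(k, dtype=bool)
    types = cells.cell_type.astype(str)
    uniq, counts = np.unique(types, return_counts=True)
    avg = k / len(uniq)
    target = int(np.floor(avg))
    pool: list[int] = []
    for t, c in zip(uniq, counts):
        idx = np.flatnonzero(types == t)
        if c > avg:
            idx = rng.choice(idx, size=target, replace=False)
        pool.extend(int(i) for i in idx)
    pool_arr = np.array(sorted(pool))
    extra = rng.choice(pool_arr, size=k - len(pool_arr), replace=True) if k > len(pool_arr) \
        else np.empty(0, dtype=int)
    final = np.concatenate([pool_arr, extra])
    first = np.concatenate([np.ones(len(pool_arr), dtype=bool),
                            np.zeros(len(extra), dtype=bool)])
    return cells.subset(final), first


def _resample_counts_from_teacher(teacher: StackModel, cells: CellSet,
                                  rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer NB draws from the teacher's (mu, theta) for the given rows."""
    _, params = teacher.forward_params(cells.counts, cells.library_size)
    mu = params.mu(cells.library_size).data[rows]
    theta = params.theta.data[rows]
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam).astype(np.int64)


def build_prompted_input(prompt_set: CellSet, query_pool: CellSet,
                         teacher: StackModel, rng: np.random.Generator,
                         balance: bool = True) -> PromptedInput:
    if query_pool.cell_type is None:
        raise ValueError("query pool needs cell_type labels")
    if balance:
        balanced, first = balance_cell_types(prompt_set, rng)
    else:
        balanced, first = prompt_set, np.ones(prompt_set.n_cells, dtype=bool)

    # randomized type-block ordering (cells of one type stay consecutive)
    types = balanced.cell_type.astype(str)
    type_order = rng.permutation(np.unique(types))
    order = np.concatenate([np.flatnonzero(types == t) for t in type_order])
    balanced = balanced.subset(order)
    first = first[order]
    types = balanced.cell_type.astype(str)

    k = balanced.n_cells
    n_cond = int(round(0.25 * k))
    remainder = np.arange(n_cond, k)
    kept_ratio = float(rng.uniform())
    k_kept = int(round(kept_ratio * len(remainder)))
    perm = rng.permutation(len(remainder))
    kept_pos = np.sort(remainder[perm[:k_kept]])
    query_pos = np.sort(remainder[perm[k_kept:]])

    roles = np.empty(k, dtype=object)
    roles[:n_cond] = ROLE_PROMPT_CONDITION
    roles[kept_pos] = ROLE_PROMPT_CONTEXT
    roles[query_pos] = ROLE_QUERY

    counts = balanced.counts.copy()
    cell_ids = balanced.cell_ids.copy()

    if len(kept_pos):
        counts[kept_pos] = _resample_counts_from_teacher(teacher, balanced, kept_pos, rng)

    # fill query positions with type-matched cells from the query pool
    pool_types = query_pool.cell_type.astype(str)
    available = {t: list(rng.permutation(np.flatnonzero(pool_types == t)))
                 for t in np.unique(pool_types)}
    chosen = np.empty(len(query_pos), dtype=int)
    for j, pos in enumerate(query_pos):
        t = types[pos]
        if t not in available:
            raise ValueError(f"query pool has no cells of type {t!r}")
        if not available[t]:  # exhausted: draw with replacement
            available[t] = list(rng.permutation(np.flatnonzero(pool_types == t)))
        chosen[j] = available[t].pop()
    counts[query_pos] = query_pool.counts[chosen]
    cell_ids[query_pos] = query_pool.cell_ids[chosen]

    target = balanced.subset(query_pos)
    x_in = CellSet(counts=counts, genes=balanced.genes, cell_ids=cell_ids,
                   sample_id=balanced.sample_id, cell_type=types.astype(object),
                   condition=balanced.condition)
    return PromptedInput(cells=x_in, roles=roles, target=target,
                         type_of=types.astype(object), first_instance=first,
                         query_positions=query_pos, original_cells=balanced)


@dataclass
class PosttrainConfig:
    epochs: int = 8
    peak_lr: float = 2e-5
    min_lr: float = 5e-6
    weight_decay: float = 3e-3
    warmup_epochs: int = 1
    batch_size: int = 8
    grad_accum: int = 4
    seed: int = 0
    ema_decay: float = 0.95
    ema_interval: int = 500
    lambda_sw: float = 0.01
    lambda_recon: float = 1.0
    lambda_cls: float = 1.0
    mask_bounds: tuple = (0.1, 0.3)
    sw_projections: int = 64
    sw_subset_range: tuple = (32, 128)
    hvg_top: int = 1000
    min_cells: int = 2
    clip_norm: float = 1.0
    new_module_grad_scale: float = 10.0


def _stratified_energy(a_flat: Tensor, b_flat_const: Tensor, types_a, types_b,
                       min_cells: int) -> Tensor:
    types_a = np.asarray(types_a).astype(str)
    types_b = np.asarray(types_b).astype(str)
    terms = []
    for t in sorted(set(types_a) & set(types_b)):
        ai = np.flatnonzero(types_a == t)
        bi = np.flatnonzero(types_b == t)
        if len(ai) < min_cells or len(bi) < min_cells:
            continue
        terms.append(energy_distance(a_flat[ai], b_flat_const[bi]))
    if not terms:
        raise ValueError("no overlapping cell types with enough cells")
    out = terms[0]
    for term in terms[1:]:
        out = out + term
    return out / len(terms)


def posttrain_losses(student: StackModel, teacher: EmaTeacher, pinput: PromptedInput,
                     cfg: PosttrainConfig, rng: np.random.Generator):
    """Forward passes and all six loss components for one prompted input."""
    if teacher.model.config != student.config:
        raise ValueError("teacher/student configurations differ")
    cells, roles = pinput.cells, pinput.roles
    g = cells.n_genes
    mask = sample_rectangular_mask(g, cfg.mask_bounds, rng)
    causal = build_causal_mask(roles)

    emb, params = student.forward_params(cells.counts, cells.library_size,
                                         masked_genes=mask.masked_genes,
                                         roles=roles, mask=causal)
    t_emb, t_params = teacher.model.forward_params(pinput.original_cells.counts,
                                                   pinput.original_cells.library_size)

    qpos = pinput.query_positions
    first_q = qpos[pinput.first_instance[qpos]]
    prompt_pos = np.flatnonzero(roles != ROLE_QUERY)
    cond_pos = np.flatnonzero(roles == ROLE_PROMPT_CONDITION)
    ctx_pos = np.flatnonzero(roles == ROLE_PROMPT_CONTEXT)

    # distributional terms need at least one type with >= min_cells queries;
    # extreme kept-ratio draws can leave (almost) no query positions
    types_q = pinput.type_of[first_q]
    uniq, cnts = (np.unique(types_q.astype(str), return_counts=True)
                  if len(first_q) else (np.array([]), np.array([])))
    if not np.any(cnts >= cfg.min_cells):
        log.debug("no stratifiable cell type among %d query cells; "
                  "distributional terms contribute zero", len(first_q))
        embed = Tensor(0.0)
        gene = Tensor(0.0)
    else:
        # L_embed: student query embeddings vs detached teacher target embeddings
        embed = _stratified_energy(emb.flat[first_q], Tensor(t_emb.flat.data[first_q]),
                                   types_q, types_q, cfg.min_cells)

        # L_gene: ZIN-sampled predicted expression vs log-normalized targets on HVGs
        first_in_target = pinput.first_instance[qpos]
        med_lib = float(np.median(pinput.original_cells.library_size))
        lib_q = cells.library_size[first_q].astype(np.float64)
        scale_q = med_lib / np.maximum(lib_q, 1.0)
        tgt = pinput.target.subset(np.flatnonzero(first_in_target))
        tgt_expr = np.log1p(tgt.counts
                            * (med_lib / np.maximum(tgt.library_size, 1.0))[:, None])
        hvg = pearson_residual_hvg(
            np.vstack([tgt.counts, cells.counts[first_q]]),
            n_top=min(cfg.hvg_top, g))
        shared_theta = float(np.median(t_params.theta.data[prompt_pos]))
        gene = gene_alignment_loss(params.rho[first_q], shared_theta, lib_q, scale_q,
                                   pinput.type_of[first_q], tgt_expr,
                                   tgt.cell_type, hvg, rng, min_cells=cfg.min_cells)

    # L_recon on prompt cells only (condition + context)
    recon = masked_recon_loss(cells.counts[prompt_pos], mask.masked_genes,
                              params.rho[prompt_pos], params.theta[prompt_pos],
                              cells.library_size[prompt_pos])

    # L_SW on embeddings of all cells
    sw = sliced_wasserstein_prior(emb.flat, n_projections=cfg.sw_projections,
                                  subset_range=cfg.sw_subset_range, rng=rng)

    # L_CLS: classify prompt-context (0) vs query (1) from detached embeddings
    prompt_mean = Tensor(emb.flat.data[cond_pos].mean(axis=0))
    cls_pos = np.concatenate([ctx_pos, qpos])
    labels = np.concatenate([np.zeros(len(ctx_pos)), np.ones(len(qpos))])
    if len(ctx_pos) == 0:
        cls = Tensor(0.0)
    else:
        logits = student.classifier_score(prompt_mean, Tensor(emb.flat.data[cls_pos]))
        cls = (logits.softplus() - Tensor(labels) * logits).mean()

    return assemble_posttrain_loss(gene, embed, recon, sw, cls,
                                   lambda_sw=cfg.lambda_sw,
                                   lambda_recon=cfg.lambda_recon,
                                   lambda_cls=cfg.lambda_cls)


def posttrain_step(student: StackModel, teacher: EmaTeacher, pinput: PromptedInput,
                   optimizer: AdamW, cfg: PosttrainConfig,
                   rng: np.random.Generator) -> LossReport:
    total, report = posttrain_losses(student, teacher, pinput, cfg, rng)
    if not np.isfinite(report.total):
        raise FloatingPointError(f"non-finite post-training loss: {report}")
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return report


def enable_new_module_gradient_scaling(student: StackModel, scale: float = 10.0):
    """10x gradient scaling on the query position embedding and classifier."""
    student.query_embedding.grad_scale = float(scale)
    student.classifier.set_grad_scale(scale)


def fit_posttrain(student: StackModel, teacher: EmaTeacher,
                  pairs: list[tuple[CellSet, CellSet]], cfg: PosttrainConfig,
                  val_pairs: list[tuple[CellSet, CellSet]] | None = None) -> dict:
    """Alignment loop over (prompt sample, query pool) pairs with EMA teacher
    updates; restores the best checkpoint by validation L_dist."""
    if not pairs:
        raise ValueError("no training pairs provided")
    rng = np.random.default_rng(cfg.seed)
    build_rng = np.random.default_rng(rng.integers(2 ** 31))
    loss_rng = np.random.default_rng(rng.integers(2 ** 31))
    enable_new_module_gradient_scaling(student, cfg.new_module_grad_scale)
    optimizer = AdamW(student.parameters(), lr=cfg.peak_lr,
                      weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    steps_per_epoch = len(pairs)
    total_steps = cfg.epochs * steps_per_epoch
    warmup_steps = cfg.warmup_epochs * steps_per_epoch
    history = {"train": [], "val": []}
    best = {"dist": np.inf, "state": None, "epoch": -1}
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        reports = []
        for i in order:
            prompt_set, query_pool = pairs[i]
            pinput = build_prompted_input(prompt_set, query_pool, teacher.model,
                                          build_rng)
            optimizer.lr = warmup_cosine_lr(step, total_steps, warmup_steps,
                                            cfg.peak_lr, cfg.min_lr)
            reports.append(posttrain_step(student, teacher, pinput, optimizer,
                                          cfg, loss_rng))
            step += 1
            teacher.step_count += 1
            if teacher.step_count % cfg.ema_interval == 0:
                ema_update(teacher, student.state_dict())
        history["train"].append({
            "epoch": epoch,
            "total": float(np.mean([r.total for r in reports])),
            "dist": float(np.mean([r.dist for r in reports])),
        })
        if val_pairs:
            val_dist = validate_posttrain(student, teacher, val_pairs, cfg)
            history["val"].append({"epoch": epoch, "dist": val_dist})
            if val_dist < best["dist"]:
                best = {"dist": val_dist, "state": student.state_dict(), "epoch": epoch}
        log.info("posttrain epoch %d %s", epoch, history["train"][-1])
    if best["state"] is not None:
        student.load_state_dict(best["state"])
        history["best_epoch"] = best["epoch"]
    return history


def validate_posttrain(student: StackModel, teacher: EmaTeacher,
                       val_pairs, cfg: PosttrainConfig, seed: int = 4321) -> float:
    rng = np.random.default_rng(seed)
    dists = []
    for prompt_set, query_pool in val_pairs:
        pinput = build_prompted_input(prompt_set, query_pool, teacher.model, rng)
        _, report = posttrain_losses(student, teacher, pinput, cfg, rng)
        dists.append(report.dist)
    return float(np.mean(dists))
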