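"""Confidence-guided iterative conditional generation.

Query cells start fully masked (``is_mask`` all True) and carry their
original expression, which encodes cell identity. Each of the T steps runs
a prediction pass conditioned on prompt cells, scores every query cell with
the confidence classifier (positive logit = "still looks like a query
cell"), replaces the lowest-logit masked cells with model predictions until
the masked fraction matches the linear schedule (1 - t/T), then re-masks any
query cell whose logit is still positive. The schedule, not the classifier,
drives termination: the step-t quota is computed from (1 - (t+1)/T), so the
process always ends after exactly T steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .io_core import CellSet
from .model import (ROLE_PROMPT_CONDITION, ROLE_PROMPT_CONTEXT, ROLE_QUERY,
                    StackModel, build_causal_mask)

log = logging.getLogger(__name__)

__all__ = ["GenerationState", "mask_schedule", "context_ratio",
           "generation_step", "generate", "confidence_filter",
           "PROMPT_CONDITION_FRACTION"]

PROMPT_CONDITION_FRACTION = 0.25


def mask_schedule(t: int, T: int) -> float:
    """Linear masking schedule 1 - t/T."""
    if T < 1 or t < 0:
        raise ValueError("need T >= 1 and t >= 0")
    if t > T:
        raise ValueError("t must not exceed T")
    return 1.0 - t / T


def context_ratio(t: int, T: int) -> tuple[float, float]:
    """(prompt-context fraction, prompt-condition fraction) at step t.

    The context fraction rises linearly from 0.2 to 0.4 over the schedule;
    the prompt-condition fraction is constant at 0.25."""
    if T < 1 or t < 0 or t > T:
        raise ValueError("need 0 <= t <= T and T >= 1")
    return 0.2 + 0.2 * (t / T), PROMPT_CONDITION_FRACTION


@dataclass
class GenerationState:
    t: int
    T: int
    is_mask: np.ndarray          # per-query booleans
    current_expr: np.ndarray     # query expression (mix of original and predicted)
    logits: np.ndarray
    schedule_history: list = field(default_factory=list)

    @property
    def schedule_fraction(self) -> float:
        return mask_schedule(self.t, self.T)


def _assemble_batches(n_query: int, set_size: int, ctx_frac: float,
                      rng: np.random.Generator):
    """Split query indices into batches so each assembled set keeps the 25%
    condition / ctx_frac context / remainder query layout."""
    n_cond = max(1, int(round(PROMPT_CONDITION_FRACTION * set_size)))
    n_ctx = max(1, int(round(ctx_frac * set_size)))
    n_q = max(1, set_size - n_cond - n_ctx)
    order = np.arange(n_query)
    return n_cond, n_ctx, [order[i:i + n_q] for i in range(0, n_query, n_q)]


def _sample_rows(pool_size: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if pool_size >= n:
        return rng.choice(pool_size, size=n, replace=False)
    warnings.warn("prompt pool smaller than required context sample; "
                  "sampling with replacement", stacklevel=2)
    return rng.choice(pool_size, size=n, replace=True)


def generation_step(state: GenerationState, model: StackModel,
                    prompt_pool: CellSet, query: CellSet,
                    query_library: np.ndarray, rng: np.random.Generator,
                    set_size: int = 128, sample_counts: bool = False
                    ) -> GenerationState:
    """One prediction / scoring / selective-unmasking / state-update cycle."""
    t, T = state.t, state.T
    if t >= T:
        raise ValueError("generation already terminated")
    n_query = query.n_cells
    ctx_frac, cond_frac = context_ratio(t, T)
    n_cond, n_ctx, batches = _assemble_batches(n_query, set_size, ctx_frac, rng)

    predictions = np.zeros_like(state.current_expr, dtype=np.float64)
    logits = np.zeros(n_query)
    for qidx in batches:
        cond_rows = _sample_rows(prompt_pool.n_cells, n_cond, rng)
        ctx_rows = _sample_rows(prompt_pool.n_cells, n_ctx, rng)
        counts = np.vstack([prompt_pool.counts[cond_rows],
                            prompt_pool.counts[ctx_rows],
                            state.current_expr[qidx]])
        library = np.concatenate([prompt_pool.library_size[cond_rows],
                                  prompt_pool.library_size[ctx_rows],
                                  query_library[qidx]])
        roles = np.array([ROLE_PROMPT_CONDITION] * n_cond
                         + [ROLE_PROMPT_CONTEXT] * n_ctx
                         + [ROLE_QUERY] * len(qidx), dtype=object)
        emb, params = model.forward_params(counts, library, roles=roles,
                                           mask=build_causal_mask(roles))
        mu = params.mu(library).data
        q_slice = slice(n_cond + n_ctx, None)
        if sample_counts:
            theta = params.theta.data[q_slice]
            lam = rng.gamma(shape=theta, scale=np.maximum(mu[q_slice], 1e-12) / theta)
            predictions[qidx] = rng.poisson(lam)
        else:
            predictions[qidx] = mu[q_slice]
        flat = emb.flat.data
        prompt_mean = flat[:n_cond].mean(axis=0)
        logits[qidx] = model.classifier_score(
            Tensor(prompt_mean), Tensor(flat[q_slice])).data

    # selective unmasking: bring masked fraction down to schedule(t+1)
    target_masked = int(round(n_query * mask_schedule(t + 1, T)))
    masked_idx = np.flatnonzero(state.is_mask)
    quota = max(0, len(masked_idx) - target_masked)
    if quota == 0 and mask_schedule(t + 1, T) > 0 and len(masked_idx):
        quota = 1  # keep the schedule moving on tiny query sets
    order = masked_idx[np.argsort(logits[masked_idx], kind="stable")]
    chosen = order[:quota]
    new_expr = state.current_expr.copy()
    new_expr[chosen] = predictions[chosen]
    new_mask = state.is_mask.copy()
    new_mask[chosen] = False
    # state update: re-mask every query cell the classifier still flags
    new_mask[logits > 0] = True

    return GenerationState(t=t + 1, T=T, is_mask=new_mask, current_expr=new_expr,
                           logits=logits,
                           schedule_history=state.schedule_history + [state.schedule_fraction])


def generate(model: StackModel, prompt: CellSet, query: CellSet, T: int = 5,
             set_size: int = 128, rng: np.random.Generator | None = None,
             sample_counts: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Run the full T-step generative procedure.

    Returns the generated expression matrix (rows aligned one-to-one with the
    input query cells; expected counts ``l * rho`` by default) and the final
    per-cell confidence logits."""
    if query.n_cells == 0:
        raise ValueError("query must be non-empty")
    if not np.array_equal(prompt.genes, query.genes):
        raise ValueError("prompt and query must share a gene index")
    rng = np.random.default_rng(0) if rng is None else rng
    prompt_before = prompt.counts.copy()
    state = GenerationState(t=0, T=T,
                            is_mask=np.ones(query.n_cells, dtype=bool),
                            current_expr=query.counts.astype(np.float64).copy(),
                            logits=np.zeros(query.n_cells))
    # generated cells keep the query cell's original library size
    query_library = query.library_size.astype(np.float64)
    while state.t < T:
        state = generation_step(state, model, prompt, query, query_library, rng,
                                set_size=set_size, sample_counts=sample_counts)
    assert np.array_equal(prompt.counts, prompt_before), "prompt cells were mutated"
    return state.current_expr, state.logits


def confidence_filter(cells: np.ndarray, logits: np.ndarray,
                      threshold: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Keep generated rows with logit <= threshold (inclusive boundary)."""
    cells = np.asarray(cells)
    logits = np.asarray(logits)
    if len(cells) != len(logits):
        raise ValueError("cells and logits must align")
    keep = logits <= threshold
    if not keep.any():
        warnings.warn("confidence filter removed every cell", stacklevel=2)
    return cells[keep], keep
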