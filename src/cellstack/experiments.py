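"""Desk-scale study protocols used by the test suite and the acceptance script.

Each function runs one self-contained experiment end to end on simulated
cohorts and returns plain dictionaries of numbers. Problem sizes are chosen
so each experiment completes in minutes on one CPU while preserving the
qualitative regime it probes:

* context benefit - very sparse cells (~20 counts) with strong low-rank
  donor shifts, so a single cell barely constrains its sample's shift while
  an ensemble does; training streams freshly simulated donors every round so
  the only way to reduce validation loss on unseen donors is the in-context
  mechanism rather than donor memorization.
* identifiability - per-set mean embeddings of a model pretrained with the
  sliced-Wasserstein prior are probed for donor module scores with
  donor-grouped ridge regression against a permutation null.
* post-training recovery - one strong perturbation; after alignment
  post-training, generated query cells should shift pseudobulk expression
  toward the prompt condition.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .io_core import CellSet, ChunkPlan, chunk_cell_sets
from .metrics import log_normalize
from .model import ModelConfig, StackModel
from .posttrain import EmaTeacher, PosttrainConfig
from .pretrain import TrainConfig, validate
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "context_sim_config",
    "context_model_config",
    "pretrain_streaming",
    "context_benefit_experiment",
    "identifiability_experiment",
    "recovery_sim_config",
    "posttrain_recovery_experiment",
]

#: cells per set in the context experiments
CONTEXT_SET_SIZE = 128


def context_sim_config(seed: int, n_donors: int = 15) -> SimConfig:
    """Sparse single-type cohorts with strong module-structured donor shifts.

    Two-gene modules at ~20 counts/cell put the sample's shift far beyond a
    single cell's reach (a masked gene's only module-mate carries well under
    one count on average) while a cell ensemble estimates it accurately, so
    inter-cellular attention carries information own-cell inference cannot.
    Shift magnitude 2.0 makes the sample-level signal large enough that a
    trained model's reliance on real (vs shuffled) context is directly
    measurable."""
    return SimConfig(n_genes=60, n_cell_types=1, n_donors=n_donors,
                     n_conditions=1, cells_per_sample=256, module_count=30,
                     donor_effect_sd=2.0, libsize_logmean=3.0,
                     libsize_logsd=0.3, seed=seed)


def context_model_config(inter_cell_attention: bool = True) -> ModelConfig:
    return ModelConfig(n_genes=60, n_layers=2, n_tokens=8, token_dim=8,
                       heads_intra=2, heads_inter=4,
                       inter_cell_attention=inter_cell_attention)


def _cohort_sets(seed: int, n_donors: int = 15):
    sets, truth = simulate_cohort(context_sim_config(seed, n_donors))
    # at ~20 counts/cell the NB occasionally yields empty cells; drop them
    sets = [s.subset(np.flatnonzero(s.library_size > 0)) for s in sets]
    return list(chunk_cell_sets(sets, ChunkPlan(CONTEXT_SET_SIZE))), truth


def pretrain_streaming(model: StackModel, seed: int, rounds: int = 60,
                       peak_lr: float = 3e-3, min_lr: float = 1e-4,
                       weight_decay: float = 1e-3,
                       cohort_fn=None) -> StackModel:
    """Pretrain on a stream of freshly simulated donors (one pass per round)
    with a single persistent optimizer and one global warmup+cosine schedule
    across the whole stream (resetting Adam state every round discards the
    momentum the small steps rely on)."""
    from .nn import AdamW, warmup_cosine_lr
    from .pretrain import pretrain_step, sample_rectangular_mask

    cohort_fn = cohort_fn or (lambda r: _cohort_sets(seed * 10_000 + r)[0])
    cfg = TrainConfig(epochs=1, peak_lr=peak_lr, weight_decay=weight_decay,
                      batch_size=1, seed=seed)
    optimizer = AdamW(model.parameters(), lr=peak_lr, weight_decay=weight_decay,
                      clip_norm=cfg.clip_norm)
    mask_rng = np.random.default_rng(seed + 11)
    sw_rng = np.random.default_rng(seed + 13)
    order_rng = np.random.default_rng(seed + 17)
    first = cohort_fn(0)
    steps_per_round = max(len(first), 1)
    total = rounds * steps_per_round
    warmup = steps_per_round
    step = 0
    for round_ in range(rounds):
        sets = first if round_ == 0 else cohort_fn(round_)
        for i in order_rng.permutation(len(sets)):
            optimizer.lr = warmup_cosine_lr(step, total, warmup, peak_lr, min_lr)
            mask = sample_rectangular_mask(sets[i].n_genes, cfg.mask_bounds, mask_rng)
            pretrain_step(model, optimizer, [sets[i]], mask, cfg, sw_rng)
            step += 1
    return model


def _padded_subset(cs: CellSet, unique: int, total: int = CONTEXT_SET_SIZE) -> CellSet:
    """Repetition padding: cycle the first ``unique`` cells up to ``total``."""
    return cs.subset(np.arange(unique)[np.arange(total) % unique])


#: cells scored in the context experiment (identical under every context
#: construction, so NLL differences reflect context quality alone)
N_PROBE_CELLS = 8


def context_benefit_experiment(seed: int, rounds: int = 60,
                               unique_counts=(8, 32, 64, 128)) -> dict:
    """Train a full and an intra-only model under identical conditions and
    compare validation masked NLL across unique-cell counts.

    Scoring uses a fixed probe subset (the first ``N_PROBE_CELLS`` cells of
    each validation set), present in every repetition-padded context, so the
    comparison across unique-cell counts is not confounded by which cells
    are evaluated. The intra-only ablation factorizes over cells and is
    therefore exactly constant across context constructions.
    """
    # 20 validation donors: context value varies with the donor draw, so a
    # small validation cohort is dominated by donor luck
    val_sets, _ = _cohort_sets(seed * 10_000 + 99_999, n_donors=20)
    probe = np.arange(N_PROBE_CELLS)
    out = {"unique_counts": list(unique_counts), "full": [], "intra_only": []}
    for key, inter in (("full", True), ("intra_only", False)):
        model = StackModel(context_model_config(inter),
                           rng=np.random.default_rng(seed))
        # no weight decay: at this scale decay pins the small-utility
        # cross-cell readout weights at zero before the circuit can form
        pretrain_streaming(model, seed, rounds=rounds, weight_decay=0.0)
        for u in unique_counts:
            metrics = validate(model, [_padded_subset(cs, u) for cs in val_sets],
                               score_rows=probe)
            out[key].append(metrics["masked_nll"])
        # standard whole-set validation for the overall full-vs-ablated check
        out[f"{key}_all_cells"] = validate(model, val_sets)["masked_nll"]
        if key == "full":
            out["full_model"] = model
    out["gaps"] = [b - a for a, b in zip(out["full"], out["intra_only"])]
    out["all_cells_gap"] = out["intra_only_all_cells"] - out["full_all_cells"]
    return out


def identifiability_experiment(model: StackModel, seed: int,
                               n_donors: int = 36, n_permutations: int = 200) -> dict:
    """Do per-set mean embeddings linearly encode donor shifts?

    Ridge-regress per-set mean embeddings onto the donors' module scores with
    donor-grouped train/test splits; compare test R^2 with a null built by
    permuting donor identities (donor-blocked permutation).
    """
    from dataclasses import replace as dc_replace

    from sklearn.linear_model import Ridge

    # several sets per donor: one set per donor leaves the ridge regression
    # too sample-starved to resolve the 30-dimensional module scores
    cfg = dc_replace(context_sim_config(seed * 10_000 + 555, n_donors),
                     cells_per_sample=768)
    raw_sets, truth = simulate_cohort(cfg)
    raw_sets = [s.subset(np.flatnonzero(s.library_size > 0)) for s in raw_sets]
    sets = list(chunk_cell_sets(raw_sets, ChunkPlan(CONTEXT_SET_SIZE)))
    emb, donor_of_set = [], []
    for cs in sets:
        e = model.encode(cs.counts, cs.library_size)
        emb.append(e.flat.data.mean(axis=0))
        donor_of_set.append(int(cs.sample_id.split("_")[0][5:]))
    emb = np.asarray(emb)
    donor_of_set = np.asarray(donor_of_set)
    targets = truth.donor_module_scores[donor_of_set]

    rng = np.random.default_rng(seed)
    donors = np.arange(n_donors)
    test_donors = rng.choice(donors, size=n_donors // 3, replace=False)
    is_test = np.isin(donor_of_set, test_donors)
    alpha_grid = (1.0, 10.0, 100.0, 1000.0)

    def fit_score(y):
        # ridge strength by donor-grouped CV on the training donors
        from sklearn.model_selection import GroupKFold

        xtr, ytr, gtr = emb[~is_test], y[~is_test], donor_of_set[~is_test]
        cv = GroupKFold(n_splits=4)
        best_alpha, best = alpha_grid[0], -np.inf
        for alpha in alpha_grid:
            scores = []
            for tr, va in cv.split(xtr, ytr, groups=gtr):
                reg = Ridge(alpha=alpha).fit(xtr[tr], ytr[tr])
                scores.append(-np.mean((reg.predict(xtr[va]) - ytr[va]) ** 2))
            if np.mean(scores) > best:
                best_alpha, best = alpha, np.mean(scores)
        reg = Ridge(alpha=best_alpha).fit(xtr, ytr)
        pred = reg.predict(emb[is_test])
        ss_res = np.sum((pred - y[is_test]) ** 2)
        ss_tot = np.sum((y[is_test] - ytr.mean(axis=0)) ** 2)
        return 1.0 - ss_res / ss_tot

    r2 = fit_score(targets)
    null = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_donors)
        null.append(fit_score(truth.donor_module_scores[perm[donor_of_set]]))
    null = np.asarray(null)
    return {"r2": float(r2), "null_mean": float(null.mean()),
            "null_q95": float(np.quantile(null, 0.95)),
            "exceeds_null": bool(r2 > np.quantile(null, 0.95))}


# ---------------------------------------------------------------------------
# post-training recovery
# ---------------------------------------------------------------------------

def recovery_sim_config(seed: int, n_genes: int = 500, n_donors: int = 10,
                        cells_per_sample: int = 1000) -> SimConfig:
    """One strong perturbation shared across cell types (20k cells total at
    the defaults). A fifth of the genes are perturbed so the LFC-recovery
    correlation is estimated over ~100 genes; with fewer, cohort-level
    sampling accidents dominate the estimate."""
    return SimConfig(n_genes=n_genes, n_cell_types=4, n_donors=n_donors,
                     n_conditions=2, cells_per_sample=cells_per_sample,
                     module_count=20, donor_effect_sd=0.5,
                     perturbation_effect_sd=2.0, perturbed_gene_fraction=0.2,
                     libsize_logmean=7.0, libsize_logsd=0.3, seed=seed)


def _split_samples(sets):
    controls = {int(s.sample_id.split("_")[0][5:]): s for s in sets
                if np.all(s.condition == "control")}
    perturbed = {int(s.sample_id.split("_")[0][5:]): s for s in sets
                 if not np.all(s.condition == "control")}
    return controls, perturbed


def posttrain_recovery_experiment(seed: int, pretrain_rounds: int = 10,
                                  posttrain_rounds: int = 24, set_size: int = 256,
                                  generation_T: int = 5,
                                  n_genes: int = 500, n_donors: int = 10,
                                  cells_per_sample: int = 1000) -> dict:
    """Full pipeline: pretrain, align, generate, and measure how well the
    generated query cells' pseudobulk LFC over perturbed genes tracks the
    simulator's condition log-fold-changes.

    Both training stages stream freshly simulated cohorts, so every round
    carries a *new* perturbation pattern and new donors: the model can only
    succeed by reading the perturbation from the prompt in context, not by
    memorizing one effect. Post-training pairs mix perturbed and control
    prompts for the same reason. Evaluation runs on a held-out cohort whose
    perturbation the model has never seen; a null (control) prompt provides
    the negative control.
    """
    from .generate import generate

    def cohort(s):
        sets, truth = simulate_cohort(recovery_sim_config(
            s, n_genes=n_genes, n_donors=n_donors,
            cells_per_sample=cells_per_sample))
        return sets, truth

    model_cfg = ModelConfig(n_genes=n_genes, n_layers=2, n_tokens=8, token_dim=8,
                            heads_intra=2, heads_inter=4)
    student = StackModel(model_cfg, rng=np.random.default_rng(seed))

    # ---- pretraining on streaming cohorts
    def pretrain_cohort(r):
        sets, _ = cohort(seed * 10_000 + r)
        return list(chunk_cell_sets(sets, ChunkPlan(set_size)))

    pretrain_streaming(student, seed, rounds=pretrain_rounds, peak_lr=2e-3,
                       weight_decay=0.0, cohort_fn=pretrain_cohort)

    # ---- alignment post-training on streaming prompt/query pairs, with one
    # persistent optimizer and one global schedule
    from .nn import AdamW, warmup_cosine_lr
    from .posttrain import (build_prompted_input, ema_update,
                            enable_new_module_gradient_scaling, posttrain_step)

    teacher = EmaTeacher(model=StackModel(model_cfg, rng=np.random.default_rng(seed)),
                         decay=0.95, update_interval=10)
    teacher.model.load_state_dict(student.state_dict())
    pt_cfg = PosttrainConfig(epochs=1, peak_lr=1e-3, min_lr=2e-4,
                             weight_decay=0.0, seed=seed,
                             sw_subset_range=(32, min(128, set_size)),
                             ema_interval=10, hvg_top=min(1000, n_genes))
    enable_new_module_gradient_scaling(student, pt_cfg.new_module_grad_scale)
    optimizer = AdamW(student.parameters(), lr=pt_cfg.peak_lr,
                      weight_decay=pt_cfg.weight_decay, clip_norm=pt_cfg.clip_norm)
    pt_rng = np.random.default_rng(seed + 3)
    build_rng = np.random.default_rng(seed + 5)
    loss_rng = np.random.default_rng(seed + 6)

    def make_pairs(r):
        sets, _ = cohort(seed * 10_000 + 500 + r)
        controls, perturbed = _split_samples(sets)
        donors = sorted(perturbed)
        pairs = []
        for i, d in enumerate(donors):
            other = donors[(i + 1) % len(donors)]
            # mix perturbed and control prompts so condition identity must be
            # read from the prompt rather than assumed
            prompt_sample = perturbed[d] if pt_rng.uniform() < 0.7 else controls[d]
            # drop prompt cells whose type the query pool cannot supply
            pool_types = set(controls[other].cell_type.astype(str))
            keep = np.isin(prompt_sample.cell_type.astype(str), sorted(pool_types))
            if keep.sum() < set_size:
                continue
            prompt_sample = prompt_sample.subset(np.flatnonzero(keep))
            for pc in chunk_cell_sets([prompt_sample], ChunkPlan(set_size)):
                pairs.append((pc, controls[other]))
        return pairs

    first_pairs = make_pairs(0)
    steps_per_round = max(len(first_pairs), 1)
    total = posttrain_rounds * steps_per_round
    warmup = steps_per_round
    step = 0
    for round_ in range(posttrain_rounds):
        pairs = first_pairs if round_ == 0 else make_pairs(round_)
        for prompt_set, query_pool in pairs:
            pinput = build_prompted_input(prompt_set, query_pool, teacher.model,
                                          build_rng)
            optimizer.lr = warmup_cosine_lr(step, total, warmup,
                                            pt_cfg.peak_lr, pt_cfg.min_lr)
            posttrain_step(student, teacher, pinput, optimizer, pt_cfg, loss_rng)
            step += 1
            teacher.step_count += 1
            if teacher.step_count % pt_cfg.ema_interval == 0:
                ema_update(teacher, student.state_dict())

    # ---- generation on a held-out cohort with an unseen perturbation
    sets, truth = cohort(seed * 10_000 + 900)
    controls, perturbed = _split_samples(sets)
    holdout = {"type0"}
    gen_rng = np.random.default_rng(seed + 7)
    query_all = controls[1]
    query = query_all.subset(np.flatnonzero(
        np.isin(query_all.cell_type.astype(str), sorted(holdout))))
    out = {}
    for label, prompt_sample in (("perturbed_prompt", perturbed[0]),
                                 ("null_prompt", controls[0])):
        prompt = prompt_sample.subset(np.flatnonzero(
            ~np.isin(prompt_sample.cell_type.astype(str), sorted(holdout))))
        expr, logits = generate(student, prompt, query, T=generation_T,
                                set_size=set_size, rng=gen_rng)
        med = float(np.median(query.library_size))
        pb_gen = log_normalize(expr, expr.sum(axis=1), target=med).mean(axis=0)
        pb_query = log_normalize(query.counts, target=med).mean(axis=0)
        lfc = pb_gen - pb_query
        mask = truth.perturbed_mask[1]
        r = stats.pearsonr(lfc[mask], truth.condition_lfcs[1][mask]).statistic
        out[label] = {"lfc_truth_r": float(r),
                      "mean_abs_lfc": float(np.abs(lfc).mean())}
    out["truth_lfc_sd"] = float(truth.condition_lfcs[1][truth.perturbed_mask[1]].std())
    out["model"] = student
    out["query"] = query
    return out
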