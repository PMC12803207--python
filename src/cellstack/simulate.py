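"""Hierarchical synthetic single-cell cohorts with known ground truth.

The generator emulates the structure the cell-set model assumes: multiple
samples (donor x condition) sharing cell types, sample-level shared shifts
(the "context" signal), per-condition perturbation log-fold-changes on a
random gene subset, and NB counts with gene-wise dispersion and log-normal
library sizes.

Gene-level effects compose additively in log space and are normalized with
a softmax before scaling by library size, matching the NB rate
decomposition the model decodes into (library size x normalized rate).
Donor shifts are low-rank: each donor draws one score per gene module and
all genes in a module share it. That correlation structure is what makes
sample identity partially inferable from any gene subset - the property
inter-cellular attention exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_core import CellSet

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "simulate_prompt_query_pair"]

CONTROL = "control"


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    n_cell_types: int = 4
    n_donors: int = 6
    n_conditions: int = 2  # condition 0 is an exact-null control
    cells_per_sample: int = 256
    module_count: int = 10
    donor_effect_sd: float = 0.5
    perturbation_effect_sd: float = 2.0
    perturbed_gene_fraction: float = 0.1
    dispersion_range: tuple = (2.0, 20.0)
    libsize_logmean: float = 7.6  # ~2000 UMIs
    libsize_logsd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_cell_types, self.n_donors, self.n_conditions,
               self.cells_per_sample, self.module_count) < 1:
            raise ValueError("all cohort dimensions must be positive")
        if not (0 < self.perturbed_gene_fraction <= 1):
            raise ValueError("perturbed_gene_fraction must lie in (0, 1]")
        if self.dispersion_range[0] <= 0 or self.dispersion_range[1] < self.dispersion_range[0]:
            raise ValueError("invalid dispersion_range")


@dataclass
class SimTruth:
    """Ground-truth simulator parameters, fully recoverable from the seed."""

    type_logmeans: np.ndarray          # (types, genes)
    donor_shifts: np.ndarray           # (donors, genes), constant within modules
    donor_module_scores: np.ndarray    # (donors, modules)
    module_of_gene: np.ndarray         # (genes,)
    condition_lfcs: np.ndarray         # (conditions, genes); row 0 all zero
    perturbed_mask: np.ndarray         # (conditions, genes) booleans
    dispersions: np.ndarray            # (genes,)
    config: SimConfig = field(default=None)

    def expected_rho(self, cell_type: int, donor: int, condition: int) -> np.ndarray:
        logits = (self.type_logmeans[cell_type] + self.donor_shifts[donor]
                  + self.condition_lfcs[condition])
        e = np.exp(logits - logits.max())
        return e / e.sum()

    def save_json(self, path):
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items() if k != "config"}
        payload["config"] = asdict(self.config)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_json(cls, path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        cfg = None
        raw_cfg = payload.pop("config", None)
        if raw_cfg is not None:
            raw_cfg["dispersion_range"] = tuple(raw_cfg["dispersion_range"])
            cfg = SimConfig(**raw_cfg)
        return cls(config=cfg, **{k: np.asarray(v) for k, v in payload.items()})


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    g, t, d, c = cfg.n_genes, cfg.n_cell_types, cfg.n_donors, cfg.n_conditions
    base = rng.normal(0.0, 1.0, size=g)
    type_dev = rng.normal(0.0, 0.6, size=(t, g))
    type_logmeans = base[None, :] + type_dev

    module_of_gene = rng.permutation(np.arange(g) % cfg.module_count)
    donor_module_scores = rng.normal(0.0, cfg.donor_effect_sd, size=(d, cfg.module_count))
    donor_shifts = donor_module_scores[:, module_of_gene]

    condition_lfcs = np.zeros((c, g))
    perturbed_mask = np.zeros((c, g), dtype=bool)
    n_pert = max(1, int(round(cfg.perturbed_gene_fraction * g)))
    for ci in range(1, c):
        idx = rng.choice(g, size=n_pert, replace=False)
        perturbed_mask[ci, idx] = True
        condition_lfcs[ci, idx] = rng.normal(0.0, cfg.perturbation_effect_sd, size=n_pert)

    dispersions = rng.uniform(*cfg.dispersion_range, size=g)
    return SimTruth(type_logmeans=type_logmeans, donor_shifts=donor_shifts,
                    donor_module_scores=donor_module_scores, module_of_gene=module_of_gene,
                    condition_lfcs=condition_lfcs, perturbed_mask=perturbed_mask,
                    dispersions=dispersions, config=cfg)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Gamma-Poisson mixture draw of NB(mu, theta) counts."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam).astype(np.int64)


def _sample_cells(cfg: SimConfig, truth: SimTruth, donor: int, condition: int,
                  rng: np.random.Generator, n_cells: int | None = None) -> CellSet:
    n = cfg.cells_per_sample if n_cells is None else n_cells
    props = rng.dirichlet(np.full(cfg.n_cell_types, 2.0))
    types = rng.choice(cfg.n_cell_types, size=n, p=props)
    lib = rng.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, size=n)
    rho_by_type = np.stack([truth.expected_rho(t, donor, condition)
                            for t in range(cfg.n_cell_types)])
    mu = lib[:, None] * rho_by_type[types]
    counts = _nb_counts(rng, mu, truth.dispersions[None, :])
    cond_label = CONTROL if condition == 0 else f"cond{condition}"
    sample_id = f"donor{donor}_{cond_label}"
    return CellSet(
        counts=counts,
        genes=np.array([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object),
        cell_ids=np.array([f"{sample_id}:c{i}" for i in range(n)], dtype=object),
        sample_id=sample_id,
        cell_type=np.array([f"type{t}" for t in types], dtype=object),
        condition=np.full(n, cond_label, dtype=object),
    )


def simulate_cohort(config: SimConfig) -> tuple[list[CellSet], SimTruth]:
    """One CellSet per (donor, condition) pair, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    sets = [
        _sample_cells(config, truth, donor, condition, rng)
        for donor in range(config.n_donors)
        for condition in range(config.n_conditions)
    ]
    return sets, truth


def simulate_prompt_query_pair(config: SimConfig, holdout_types: set,
                               condition: int = 1, prompt_donor: int = 0,
                               query_donor: int = 1,
                               ) -> tuple[CellSet, CellSet, CellSet, SimTruth]:
    """Build a (prompt, query, target) triple with a known counterfactual.

    prompt  : perturbed sample of ``prompt_donor`` restricted to non-held-out types
    query   : control cells of held-out types from ``query_donor``
    target  : perturbed cells of held-out types from ``prompt_donor`` (ground truth)

    The three groups are equalized by downsampling to the smallest group.
    """
    holdout = {str(t) for t in holdout_types}
    if not holdout:
        raise ValueError("holdout_types must be non-empty")
    all_types = {f"type{t}" for t in range(config.n_cell_types)}
    if not holdout <= all_types:
        raise ValueError(f"unknown holdout types: {sorted(holdout - all_types)}")
    if holdout == all_types:
        raise ValueError("holding out every cell type leaves an empty prompt")
    if condition < 1 or condition >= config.n_conditions:
        raise ValueError("condition must index a perturbed condition (>= 1)")
    if prompt_donor == query_donor:
        raise ValueError("prompt and query donors must differ")

    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    perturbed = _sample_cells(config, truth, prompt_donor, condition, rng)
    control = _sample_cells(config, truth, query_donor, 0, rng)

    in_holdout = np.isin(perturbed.cell_type.astype(str), sorted(holdout))
    prompt = perturbed.subset(np.flatnonzero(~in_holdout))
    target = perturbed.subset(np.flatnonzero(in_holdout))
    query = control.subset(np.flatnonzero(
        np.isin(control.cell_type.astype(str), sorted(holdout))))
    if min(prompt.n_cells, query.n_cells, target.n_cells) == 0:
        raise ValueError("degenerate partition: one of prompt/query/target is empty")

    n = min(prompt.n_cells, query.n_cells, target.n_cells)
    prompt = prompt.subset(np.sort(rng.choice(prompt.n_cells, n, replace=False)))
    query = query.subset(np.sort(rng.choice(query.n_cells, n, replace=False)))
    target = target.subset(np.sort(rng.choice(target.n_cells, n, replace=False)))
    return prompt, query, target, truth
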