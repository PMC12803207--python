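"""Pseudobulk / differential-expression evaluation metrics and reference
prompting baselines.

DE detection uses two-sided Wilcoxon rank-sum tests per gene on log
normalized expression with Benjamini-Hochberg correction; significance is
adjusted p < alpha with an optional |log2 fold change| floor. Log fold
changes are differences of mean log1p-normalized expression expressed in
log2 units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score
from statsmodels.stats.multitest import multipletests

from .io_core import CellSet

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "MetricsReport",
    "log_normalize",
    "pseudobulk",
    "wilcoxon_de",
    "pearson_delta",
    "de_spearman_lfc",
    "de_direction_match",
    "pr_auc",
    "de_overlap_accuracy",
    "de_precision_at_n",
    "jaccard_de",
    "spearman_effect_size",
    "baseline_predict",
    "evaluate_prediction",
]

_LN2 = np.log(2.0)


@dataclass
class DEResult:
    genes: np.ndarray
    lfc: np.ndarray            # log2 fold change (a vs b)
    pvalue: np.ndarray
    adj_pvalue: np.ndarray
    significant: np.ndarray

    def significant_genes(self) -> set:
        return set(self.genes[self.significant])


@dataclass
class MetricsReport:
    pearson_delta: float | None = None
    de_spearman_lfc: float | None = None
    de_direction_match: float | None = None
    pr_auc: float | None = None
    spearman_effect_size: float | None = None
    de_overlap_accuracy: float | None = None
    de_precision_at_n: float | None = None
    jaccard: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def log_normalize(counts: np.ndarray, library: np.ndarray | None = None,
                  target: float | None = None) -> np.ndarray:
    """log1p of counts scaled per cell to the median library size (or ``target``)."""
    counts = np.asarray(counts, dtype=np.float64)
    lib = counts.sum(axis=1) if library is None else np.asarray(library, float)
    if target is None:
        positive = lib[lib > 0]
        target = float(np.median(positive)) if positive.size else 1.0
    scale = np.where(lib > 0, target / np.maximum(lib, 1e-12), 1.0)
    return np.log1p(counts * scale[:, None])


def pseudobulk(cells: CellSet, groupby: str = "cell_type",
               target: float | None = None) -> dict[str, np.ndarray]:
    """Per-group mean log1p library-normalized expression profiles."""
    labels = getattr(cells, groupby, None)
    if labels is None:
        raise ValueError(f"CellSet has no labels for {groupby!r}")
    labels = np.asarray(labels).astype(str)
    expr = log_normalize(cells.counts, cells.library_size, target=target)
    out = {}
    for lab in np.unique(labels):
        rows = labels == lab
        if not rows.any():
            warnings.warn(f"empty group {lab!r} skipped", stacklevel=2)
            continue
        out[lab] = expr[rows].mean(axis=0)
    return out


def _ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value: exact for small tie-free samples, normal
    approximation with tie correction and continuity correction otherwise."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # constant gene on both sides, by convention
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def wilcoxon_de(a: CellSet, b: CellSet, alpha: float = 0.05,
                lfc_floor: float | None = None, target: float | None = None) -> DEResult:
    """Per-gene DE of ``a`` vs ``b`` (log2 LFC > 0 means higher in ``a``)."""
    if a.n_cells < 2 or b.n_cells < 2:
        raise ValueError("each side needs at least 2 cells")
    if not np.array_equal(a.genes, b.genes):
        raise ValueError("gene indices must match")
    if target is None:
        target = float(np.median(np.concatenate([a.library_size, b.library_size])))
    xa = log_normalize(a.counts, a.library_size, target=target)
    xb = log_normalize(b.counts, b.library_size, target=target)
    pvals = np.array([_ranksum_pvalue(xa[:, g], xb[:, g]) for g in range(a.n_genes)])
    lfc = (xa.mean(axis=0) - xb.mean(axis=0)) / _LN2
    adj = multipletests(pvals, method="fdr_bh")[1]
    sig = adj < alpha
    if lfc_floor is not None:
        sig &= np.abs(lfc) > lfc_floor
    return DEResult(genes=a.genes.astype(str), lfc=lfc, pvalue=pvals,
                    adj_pvalue=adj, significant=sig)


# ---------------------------------------------------------------------------
# metric operators
# ---------------------------------------------------------------------------

def pearson_delta(pred: np.ndarray, truth: np.ndarray, ctrl: np.ndarray) -> float | None:
    """Pearson correlation of |pred - ctrl| with |truth - ctrl| over genes."""
    dp = np.abs(np.asarray(pred, float) - np.asarray(ctrl, float))
    dt = np.abs(np.asarray(truth, float) - np.asarray(ctrl, float))
    if np.std(dp) == 0 or np.std(dt) == 0:
        return None
    return float(stats.pearsonr(dp, dt).statistic)


def de_spearman_lfc(pred_de: DEResult, true_de: DEResult) -> float | None:
    """Spearman correlation of LFCs within the true significant gene set."""
    sig = true_de.significant
    if sig.sum() < 3:
        return None
    res = stats.spearmanr(pred_de.lfc[sig], true_de.lfc[sig])
    return None if np.isnan(res.statistic) else float(res.statistic)


def de_direction_match(pred_de: DEResult, true_de: DEResult) -> float | None:
    """Fraction of genes significant in both whose LFC signs agree."""
    shared = pred_de.significant & true_de.significant
    if not shared.any():
        return None
    return float(np.mean(np.sign(pred_de.lfc[shared]) == np.sign(true_de.lfc[shared])))


def pr_auc(true_sig: np.ndarray, scores: np.ndarray) -> float | None:
    """Average precision with binary DE labels and -log10 p-value scores."""
    true_sig = np.asarray(true_sig, bool)
    if not true_sig.any():
        return None
    return float(average_precision_score(true_sig, np.asarray(scores, float)))


def _top_n(de: DEResult, n: int) -> set:
    sig_idx = np.flatnonzero(de.significant)
    order = sig_idx[np.argsort(-np.abs(de.lfc[sig_idx]), kind="stable")]
    return set(de.genes[order[:n]])


def de_overlap_accuracy(pred_de: DEResult, true_de: DEResult) -> float | None:
    """|top-N true ∩ top-N predicted| / N with N = number of true DE genes."""
    n = int(true_de.significant.sum())
    if n == 0:
        return None
    return len(_top_n(true_de, n) & _top_n(pred_de, n)) / n


def de_precision_at_n(pred_de: DEResult, true_de: DEResult) -> float | None:
    """|top-N true ∩ top-N predicted| / N with N = number of predicted DE genes."""
    n = int(pred_de.significant.sum())
    if n == 0:
        return None
    return len(_top_n(true_de, n) & _top_n(pred_de, n)) / n


def jaccard_de(pred_de: DEResult, true_de: DEResult) -> float | None:
    a, b = pred_de.significant_genes(), true_de.significant_genes()
    if not a and not b:
        return None
    union = a | b
    return len(a & b) / len(union)


def spearman_effect_size(pred_counts, true_counts) -> float | None:
    """Spearman correlation of DE-gene counts across conditions. ``pred_counts``
    may be (n_seeds, n_conditions); predictions are averaged over seeds first."""
    pred = np.asarray(pred_counts, float)
    if pred.ndim == 2:
        pred = pred.mean(axis=0)
    true = np.asarray(true_counts, float)
    if len(pred) < 3:
        raise ValueError("need at least 3 conditions")
    res = stats.spearmanr(pred, true)
    return None if np.isnan(res.statistic) else float(res.statistic)


# ---------------------------------------------------------------------------
# reference prompting baselines
# ---------------------------------------------------------------------------

def baseline_predict(method: str, prompt: CellSet, query: CellSet,
                     auxiliary: CellSet | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Non-model prompting baselines. Returns a predicted expression matrix
    aligned to the query cells (count scale for sampling baselines,
    log-normalized scale handled by the caller for shift_mean)."""
    rng = np.random.default_rng(0) if rng is None else rng
    if method == "original_query":
        return query.counts.copy()
    if method in ("nearest_type", "same_type"):
        if prompt.cell_type is None or query.cell_type is None:
            raise ValueError("cell_type labels required")
        prompt_pb = pseudobulk(prompt)
        query_pb = pseudobulk(query)
        p_types = np.asarray(prompt.cell_type).astype(str)
        # rank prompt types by pseudobulk Pearson correlation for each query type
        nearest: dict[str, list[str]] = {}
        for qt, qvec in query_pb.items():
            ranked = sorted(prompt_pb,
                            key=lambda pt: -np.corrcoef(qvec, prompt_pb[pt])[0, 1])
            nearest[qt] = ranked
        available = {t: list(rng.permutation(np.flatnonzero(p_types == t)))
                     for t in np.unique(p_types)}
        out = np.zeros_like(query.counts)
        for i, qt in enumerate(np.asarray(query.cell_type).astype(str)):
            if method == "same_type":
                if qt not in available:
                    raise ValueError(f"prompt has no cells of type {qt!r}")
                candidates = [qt] + [t for t in nearest.get(qt, []) if t != qt]
            else:
                candidates = nearest[qt]
            row = None
            for t in candidates:  # fall back to next-closest when exhausted
                if available.get(t):
                    row = available[t].pop()
                    break
            if row is None:  # every type exhausted: restart the closest pool
                t = candidates[0]
                available[t] = list(rng.permutation(np.flatnonzero(p_types == t)))
                row = available[t].pop()
            out[i] = prompt.counts[row]
        return out
    if method == "shift_mean":
        if auxiliary is None:
            raise ValueError("shift_mean requires an auxiliary (control) set")
        target = float(np.median(np.concatenate([prompt.library_size,
                                                 auxiliary.library_size,
                                                 query.library_size])))
        prompt_pb = pseudobulk(prompt, target=target)
        aux_pb = pseudobulk(auxiliary, target=target)
        q_expr = log_normalize(query.counts, query.library_size, target=target)
        shared = sorted(set(prompt_pb) & set(aux_pb))
        if not shared:
            raise ValueError("no shared cell types between prompt and auxiliary")
        global_delta = np.mean([prompt_pb[t] - aux_pb[t] for t in shared], axis=0)
        out = np.empty_like(q_expr)
        q_types = (np.asarray(query.cell_type).astype(str) if query.cell_type is not None
                   else np.array(["_"] * query.n_cells))
        for i, qt in enumerate(q_types):
            delta = prompt_pb[qt] - aux_pb[qt] if (qt in prompt_pb and qt in aux_pb) \
                else global_delta
            out[i] = q_expr[i] + delta
        return np.expm1(np.maximum(out, 0.0))  # back to (continuous) count-like scale
    raise ValueError(f"unknown baseline {method!r}")


# ---------------------------------------------------------------------------
# convenience: full metric panel for one prediction
# ---------------------------------------------------------------------------

def evaluate_prediction(pred_counts: np.ndarray, target: CellSet, query: CellSet,
                        alpha: float = 0.05, lfc_floor: float | None = None,
                        hvg_top: int | None = 2000) -> MetricsReport:
    """Compute the metric panel for a predicted query-cell expression matrix
    against ground-truth target cells, with the query condition as control.

    Genes are optionally restricted to the top ``hvg_top`` HVGs of the
    concatenated target and query counts (Pearson residuals)."""
    from .losses import pearson_residual_hvg

    genes = target.genes
    if hvg_top is not None and hvg_top < target.n_genes:
        hvg = np.sort(pearson_residual_hvg(
            np.vstack([target.counts, query.counts]), n_top=hvg_top))
    else:
        hvg = np.arange(target.n_genes)

    def restrict(cs: CellSet, counts=None) -> CellSet:
        c = cs.counts if counts is None else counts
        return CellSet(counts=np.round(np.asarray(c)[:, hvg]).astype(np.int64),
                       genes=genes[hvg], cell_ids=cs.cell_ids,
                       sample_id=cs.sample_id, cell_type=cs.cell_type,
                       condition=cs.condition)

    pred_cs = restrict(query, counts=pred_counts)
    target_cs = restrict(target)
    query_cs = restrict(query)

    pred_de = wilcoxon_de(pred_cs, query_cs, alpha=alpha, lfc_floor=lfc_floor)
    true_de = wilcoxon_de(target_cs, query_cs, alpha=alpha, lfc_floor=lfc_floor)

    target_med = float(np.median(np.concatenate([target_cs.library_size,
                                                 query_cs.library_size])))
    pb_pred = log_normalize(pred_cs.counts, target=target_med).mean(axis=0)
    pb_true = log_normalize(target_cs.counts, target=target_med).mean(axis=0)
    pb_ctrl = log_normalize(query_cs.counts, target=target_med).mean(axis=0)

    return MetricsReport(
        pearson_delta=pearson_delta(pb_pred, pb_true, pb_ctrl),
        de_spearman_lfc=de_spearman_lfc(pred_de, true_de),
        de_direction_match=de_direction_match(pred_de, true_de),
        pr_auc=pr_auc(true_de.significant, -np.log10(np.maximum(pred_de.pvalue, 1e-300))),
        de_overlap_accuracy=de_overlap_accuracy(pred_de, true_de),
        de_precision_at_n=de_precision_at_n(pred_de, true_de),
        jaccard=jaccard_de(pred_de, true_de),
    )
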