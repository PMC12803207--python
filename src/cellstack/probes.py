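"""Donor-grouped probing of cell embeddings.

Probes quantify how much donor- or condition-level information an embedding
carries while guarding against donor leakage: train and test donors never
overlap, and each donor's contribution to the test set is capped so
cell-level scores approximate donor-level averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GroupKFold, GroupShuffleSplit
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

log = logging.getLogger(__name__)

__all__ = ["ProbeResult", "linear_probe", "mlp_probe"]


@dataclass
class ProbeResult:
    scores: dict            # per-cell-type balanced accuracy or Pearson r
    split: dict             # donor -> {"train", "test"} (or train/val/test)
    cap: int
    task: str

    @property
    def mean_score(self) -> float | None:
        vals = [v for v in self.scores.values() if v is not None]
        return float(np.mean(vals)) if vals else None


def _cap_per_donor(idx: np.ndarray, donors: np.ndarray, cap: int,
                   rng: np.random.Generator) -> np.ndarray:
    keep = []
    for d in np.unique(donors[idx]):
        rows = idx[donors[idx] == d]
        if len(rows) > cap:
            rows = rng.choice(rows, size=cap, replace=False)
        keep.append(rows)
    return np.sort(np.concatenate(keep))


def linear_probe(embeddings: np.ndarray, labels: np.ndarray, donor_groups: np.ndarray,
                 cell_types: np.ndarray | None = None, cap: int = 2000,
                 task: str = "classify", seed: int = 42) -> ProbeResult:
    """Per-cell-type regularized linear probe with donor-held-out evaluation.

    80% of donors train the probe (regularization strength selected by
    grouped 5-fold CV); held-out donors are scored with per-donor test caps.
    Classification reports balanced accuracy, regression Pearson r.
    """
    x = np.asarray(embeddings, float)
    y = np.asarray(labels)
    donors = np.asarray(donor_groups).astype(str)
    ctypes = (np.asarray(cell_types).astype(str) if cell_types is not None
              else np.array(["all"] * len(y)))
    rng = np.random.default_rng(seed)

    splitter = GroupShuffleSplit(n_splits=1, train_size=0.8, random_state=seed)
    train_idx, test_idx = next(splitter.split(x, y, groups=donors))
    split = {d: ("train" if d in set(donors[train_idx]) else "test")
             for d in np.unique(donors)}

    scores: dict = {}
    for ct in np.unique(ctypes):
        tr = train_idx[ctypes[train_idx] == ct]
        te = test_idx[ctypes[test_idx] == ct]
        te = _cap_per_donor(te, donors, cap, rng) if len(te) else te
        if len(tr) < 10 or len(te) < 2:
            scores[ct] = None
            continue
        if task == "classify":
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                scores[ct] = None
                continue
            best = _grouped_grid(x[tr], y[tr], donors[tr],
                                 [0.01, 0.1, 1.0, 10.0], seed, classify=True)
            clf = LogisticRegression(C=best, max_iter=2000, random_state=seed)
            clf.fit(x[tr], y[tr])
            scores[ct] = float(balanced_accuracy_score(y[te], clf.predict(x[te])))
        else:
            best = _grouped_grid(x[tr], y[tr].astype(float), donors[tr],
                                 [0.1, 1.0, 10.0, 100.0], seed, classify=False)
            reg = Ridge(alpha=best, random_state=seed)
            reg.fit(x[tr], y[tr].astype(float))
            pred = reg.predict(x[te])
            if np.std(pred) == 0 or np.std(y[te].astype(float)) == 0:
                scores[ct] = None
            else:
                scores[ct] = float(stats.pearsonr(pred, y[te].astype(float)).statistic)
    return ProbeResult(scores=scores, split=split, cap=cap, task=task)


def _grouped_grid(x, y, groups, grid, seed, classify: bool) -> float:
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        return grid[len(grid) // 2]
    cv = GroupKFold(n_splits=min(5, n_groups))
    best_val, best_score = grid[0], -np.inf
    for val in grid:
        fold_scores = []
        for tr, va in cv.split(x, y, groups=groups):
            if classify:
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                    continue
                m = LogisticRegression(C=val, max_iter=2000, random_state=seed)
                m.fit(x[tr], y[tr])
                fold_scores.append(balanced_accuracy_score(y[va], m.predict(x[va])))
            else:
                m = Ridge(alpha=val, random_state=seed)
                m.fit(x[tr], y[tr])
                pred = m.predict(x[va])
                fold_scores.append(-np.mean((pred - y[va]) ** 2))
        score = np.mean(fold_scores) if fold_scores else -np.inf
        if score > best_score:
            best_val, best_score = val, score
    return best_val


def mlp_probe(embeddings: np.ndarray, labels: np.ndarray, donor_groups: np.ndarray,
              cell_types: np.ndarray | None = None, seed: int = 42,
              task: str = "classify", n_top_types: int = 5,
              l2_grid=(0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
              max_epochs: int = 80, patience: int = 12) -> ProbeResult:
    """Single-hidden-layer (128 ReLU units) probe trained jointly on the most
    abundant cell types, with a 70/15/15 donor split; the L2 strength is
    selected on validation loss, early stopping with the given patience."""
    x = np.asarray(embeddings, float)
    y = np.asarray(labels)
    donors = np.asarray(donor_groups).astype(str)
    rng = np.random.default_rng(seed)

    if cell_types is not None:
        ctypes = np.asarray(cell_types).astype(str)
        top = [t for t, _ in sorted(
            zip(*np.unique(ctypes, return_counts=True)), key=lambda p: -p[1])][:n_top_types]
        keep = np.isin(ctypes, top)
        x, y, donors = x[keep], y[keep], donors[keep]

    uniq = rng.permutation(np.unique(donors))
    n = len(uniq)
    n_train = max(1, int(round(0.7 * n)))
    n_val = max(1, int(round(0.15 * n)))
    d_train = set(uniq[:n_train])
    d_val = set(uniq[n_train:n_train + n_val])
    d_test = set(uniq[n_train + n_val:]) or d_val
    split = {d: ("train" if d in d_train else "val" if d in d_val else "test")
             for d in uniq}
    tr = np.isin(donors, list(d_train))
    va = np.isin(donors, list(d_val))
    te = np.isin(donors, list(d_test))

    scaler = StandardScaler().fit(x[tr])
    xs = scaler.transform(x)
    cls = task == "classify"
    Est = MLPClassifier if cls else MLPRegressor

    def fit_one(alpha: float):
        model = Est(hidden_layer_sizes=(128,), activation="relu", solver="adam",
                    learning_rate_init=1e-3, alpha=max(alpha, 1e-12), max_iter=1,
                    warm_start=True, random_state=seed)
        best_loss, best_state, bad = np.inf, None, 0
        import warnings as _w
        for _ in range(max_epochs):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                model.fit(xs[tr], y[tr])
            if cls:
                proba = np.clip(model.predict_proba(xs[va]), 1e-12, 1)
                classes = list(model.classes_)
                idx = np.array([classes.index(v) for v in y[va]])
                loss = float(-np.mean(np.log(proba[np.arange(len(idx)), idx])))
            else:
                loss = float(np.mean((model.predict(xs[va]) - y[va].astype(float)) ** 2))
            if loss < best_loss - 1e-6:
                best_loss, bad = loss, 0
                best_state = [w.copy() for w in model.coefs_], [b.copy() for b in model.intercepts_]
            else:
                bad += 1
                if bad >= patience:
                    break
        if best_state is not None:
            model.coefs_, model.intercepts_ = best_state
        return model, best_loss

    best = min((fit_one(a) for a in l2_grid), key=lambda p: p[1])
    model = best[0]
    if cls:
        score = (float(balanced_accuracy_score(y[te], model.predict(xs[te])))
                 if len(np.unique(y[te])) > 1 else None)
    else:
        pred = model.predict(xs[te])
        score = (float(stats.pearsonr(pred, y[te].astype(float)).statistic)
                 if np.std(pred) > 0 and np.std(y[te].astype(float)) > 0 else None)
    return ProbeResult(scores={"joint": score}, split=split, cap=0, task=task)
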