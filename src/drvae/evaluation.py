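"""Evaluation protocol: grouped/stratified repeated cross-validation,
ranking metrics, paired significance tests, and perturbation-signal
statistics.

The split generator reproduces the protocol used to benchmark response
classifiers trained on mixed viability + perturbation data: repeated
k-fold cross-validation where every cell line's measurements co-locate in
one fold, folds of perturbation-source cell lines are pooled into training
and validation only (test folds contain exclusively singleton-source cell
lines with no post-treatment expression), and singleton folds are
stratified by responder ratio.

ERVR (effect-to-replicate variance ratio) summarizes perturbation signal
strength: across-pair variance of the effect x2 - x1 relative to the pooled
within-group variance of replicate vehicle controls, averaged over genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .gaussian import DimensionError, ValidationError


# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """``n_folds * n_repeats`` train/validation/test index triples.

    Indices refer to positions in the singleton sample list handed to
    :func:`make_splits`; pair-source cell lines never appear in test sets.
    """

    splits: list          # list of (train_ids, val_ids, test_ids) tuples
    n_folds: int
    n_repeats: int
    pair_fold_cell_lines: list = None   # per repeat: fold -> pair cell lines

    def __len__(self) -> int:
        return len(self.splits)


def _stratified_group_folds(cell_lines, cl_label, n_folds, rng):
    """Assign cell lines (groups) to folds, balancing the responder ratio.

    Cell lines are split by their (majority) label, shuffled within each
    class and dealt round-robin, so per-fold positive fractions stay within
    one group of the global fraction."""
    folds = [[] for _ in range(n_folds)]
    offset = 0
    for cls in (1, 0):
        members = [c for c in cell_lines if cl_label[c] == cls]
        members = [members[i] for i in rng.permutation(len(members))]
        for j, c in enumerate(members):
            folds[(j + offset) % n_folds].append(c)
        offset += len(members)
    return folds


def make_splits(cell_line_ids: Sequence[str], labels: Sequence[int],
                pair_cell_lines: Sequence[str] = (),
                n_folds: int = 5, n_repeats: int = 20,
                seed: int = 0) -> SplitPlan:
    """Generate grouped, stratified, repeated k-fold train/val/test splits.

    Parameters
    ----------
    cell_line_ids, labels
        Per-singleton-sample cell line identifier and binary response label.
    pair_cell_lines
        Cell lines that also have perturbation pairs.  Their samples are
        grouped into separate folds that are pooled into training and
        validation splits only; test folds consist exclusively of
        singleton-source cell lines.
    n_folds, n_repeats
        5 x 20 gives the standard 100 splits.

    For repeat ``r`` and fold ``f``, singleton fold ``f`` is the test set,
    fold ``(f+1) mod n_folds`` of both the singleton and pair partitions is
    validation, and everything else is training.
    """
    cell_line_ids = list(map(str, cell_line_ids))
    labels = np.asarray(labels, dtype=int)
    if len(cell_line_ids) != len(labels):
        raise DimensionError("cell_line_ids and labels lengths differ")
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary")
    if np.unique(labels).size < 2:
        raise ValidationError("both response classes must be present")
    pair_set = set(map(str, pair_cell_lines))

    # majority label per cell line (stratification unit is the cell line)
    cl_label: dict = {}
    for cl in sorted(set(cell_line_ids)):
        mask = [c == cl for c in cell_line_ids]
        cl_label[cl] = int(round(labels[mask].mean()))

    singleton_cls = sorted(set(cell_line_ids) - pair_set)
    pair_cls = sorted(pair_set)
    if len(singleton_cls) < n_folds:
        raise ValidationError(
            f"need at least {n_folds} singleton-only cell lines, "
            f"got {len(singleton_cls)}")

    sample_idx: dict = {}
    for i, cl in enumerate(cell_line_ids):
        sample_idx.setdefault(cl, []).append(i)

    rng = np.random.default_rng(seed)
    splits, pair_fold_log = [], []
    for _ in range(n_repeats):
        s_folds = _stratified_group_folds(singleton_cls, cl_label, n_folds, rng)
        p_order = [pair_cls[i] for i in rng.permutation(len(pair_cls))]
        p_folds = [p_order[f::n_folds] for f in range(n_folds)]
        pair_fold_log.append([sorted(f) for f in p_folds])
        for f in range(n_folds):
            v = (f + 1) % n_folds
            test_cls = s_folds[f]
            val_cls = s_folds[v] + p_folds[v]
            train_cls = [c for g in range(n_folds) if g not in (f, v)
                         for c in s_folds[g] + p_folds[g]] + p_folds[f]
            def collect(cls_list):
                return sorted(i for c in cls_list
                              for i in sample_idx.get(c, ()))
            splits.append((collect(train_cls), collect(val_cls),
                           collect(test_cls)))
    return SplitPlan(splits=splits, n_folds=n_folds, n_repeats=n_repeats,
                     pair_fold_cell_lines=pair_fold_log)


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

@dataclass
class MethodScores:
    """Per-split metric values (AUROC or AUPR) for one method."""

    method: str
    per_split: np.ndarray

    def __post_init__(self) -> None:
        self.per_split = np.asarray(self.per_split, dtype=float)
        if np.any((self.per_split < 0) | (self.per_split > 1)):
            raise ValidationError("scores must lie in [0, 1]")


class UndefinedMetric(ValueError):
    """The metric has no value on this input (e.g. a single class)."""


def auroc(scores, labels) -> float:
    """Area under the ROC curve == Mann-Whitney ordering probability
    (ties counted 1/2)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedMetric("AUROC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated)
    average-precision convention."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise UndefinedMetric("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def wilcoxon_compare(a: MethodScores, b: MethodScores, alpha: float = 0.05):
    """One-sided Wilcoxon signed-rank comparison of paired per-split scores.

    Zero differences are discarded (classic convention); the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with continuity correction.  Returns
    ``(verdict, {'a_better': p, 'b_better': p})`` with verdict one of
    ``'a_better' | 'b_better' | 'tie'``.
    """
    x = np.asarray(a.per_split, dtype=float)
    y = np.asarray(b.per_split, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("score vectors must be paired (equal length)")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return "tie", {"a_better": 1.0, "b_better": 1.0}
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) \
        else "approx"
    p_a = float(stats.wilcoxon(d, alternative="greater", method=method,
                               correction=(method == "approx")).pvalue)
    p_b = float(stats.wilcoxon(d, alternative="less", method=method,
                               correction=(method == "approx")).pvalue)
    pvals = {"a_better": p_a, "b_better": p_b}
    if p_a < alpha:
        return "a_better", pvals
    if p_b < alpha:
        return "b_better", pvals
    return "tie", pvals


# ---------------------------------------------------------------------------
# perturbation-prediction statistics
# ---------------------------------------------------------------------------

def rmse_pred(predicted, reference) -> float:
    """Root mean squared elementwise error, averaged over all entries."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise DimensionError(
            f"shape mismatch {predicted.shape} vs {reference.shape}")
    return float(np.sqrt(np.mean((predicted - reference) ** 2)))


def ervr(pair_effects: np.ndarray, control_groups: Sequence[np.ndarray]) -> float:
    """Effect-to-replicate variance ratio.

    Parameters
    ----------
    pair_effects
        (n_pairs, n_genes) matrix of perturbation effects x2 - x1.
    control_groups
        Replicate vehicle-control profiles grouped by well/batch; each
        element is an (n_replicates, n_genes) matrix with >= 2 replicates.

    The numerator is the mean over genes of the across-pair variance of the
    effect; the denominator the mean over genes of the pooled within-group
    replicate variance.  Returns ``inf`` when the replicate variance is
    zero but the effect variance is not.
    """
    pair_effects = np.asarray(pair_effects, dtype=float)
    if pair_effects.shape[0] < 2:
        raise ValidationError("ERVR needs at least 2 pairs")
    groups = [np.asarray(g, dtype=float) for g in control_groups
              if np.asarray(g).shape[0] >= 2]
    if not groups:
        raise ValidationError("ERVR needs a control group with >= 2 replicates")
    num = float(np.mean(pair_effects.var(axis=0, ddof=1)))
    ss, dof = 0.0, 0
    for g in groups:
        ss += float(np.sum((g - g.mean(axis=0)) ** 2))
        dof += (g.shape[0] - 1) * g.shape[1]
    den = ss / dof
    if den == 0.0:
        return float("inf") if num > 0 else 0.0
    return num / den


def ervr_from_pairs(pairs, control_groups) -> float:
    """ERVR from :class:`~drvae.preprocess.PerturbationPair` objects."""
    effects = np.stack([p.x2 - p.x1 for p in pairs])
    return ervr(effects, control_groups)


def improvement_correlation(delta_rmse, covariate):
    """Pearson correlation of per-drug RMSE improvements with a dataset
    statistic (e.g. ERVR x number of cell lines).

    Returns ``(rho, p_value)``; two-sided p."""
    x = np.asarray(delta_rmse, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 drugs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedMetric("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
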