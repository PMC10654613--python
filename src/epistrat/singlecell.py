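"""Per-cell signature module scores, four-group assignment, one-vs-rest DE.

The module score is the mean expression of a gene set minus the mean of an
expression-matched control set: genes are binned by average expression
across cells and each set gene contributes control genes sampled from its
bin (set genes excluded, with replacement when a bin is small). Cells are
called positive for a module when their score exceeds the module's mean
score across cells, which yields the four groups none / poor / better /
both. Differential expression is a two-sided Wilcoxon rank-sum per gene,
one group against all other cells, Bonferroni-corrected within each
comparison.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataContractError

__all__ = ["module_score", "assign_four_groups", "one_vs_rest_de"]


def module_score(cells: pd.DataFrame, gene_set: Sequence[str], n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Control-matched mean-expression score of a gene set per cell.

    Genes are cut into ``n_bins`` equal-size bins of average expression
    across cells; for each set gene, ``n_ctrl`` control genes are sampled
    from its bin (excluding set genes; with replacement when the remaining
    bin is smaller than ``n_ctrl``). The score is mean(set) - mean(control)
    per cell, so a global additive shift of a cell cancels exactly.
    """
    if n_bins < 2:
        raise DataContractError("n_bins must be at least 2")
    in_set = cells.index.isin(set(gene_set))
    if not in_set.any():
        raise DataContractError("no gene of the set is present in the matrix")
    rng = np.random.default_rng(seed)
    avg = cells.mean(axis=1).to_numpy()
    # equal-occupancy bins on the rank scale, as average-expression matching
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.arange(len(avg)) * n_bins // len(avg)

    values = cells.to_numpy(dtype=float)
    set_idx = np.nonzero(in_set)[0]
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.nonzero((bin_of == bin_of[gi]) & ~in_set)[0]
        if pool.size == 0:
            # whole bin is in the set: self-match, so a set equal to the
            # full gene universe scores exactly zero
            ctrl_idx.append(np.array([gi]))
            continue
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    control = np.concatenate(ctrl_idx)
    score = values[set_idx].mean(axis=0) - values[control].mean(axis=0)
    return pd.Series(score, index=cells.columns, name="module_score")


def assign_four_groups(score_poor: pd.Series, score_better: pd.Series,
                       cutoff_rule: str = "mean",
                       fixed_cutoff: float = 0.0) -> pd.DataFrame:
    """Four-way cell classification from two module scores.

    A cell is positive for a module when its score strictly exceeds the
    cutoff — by default the mean of that module's scores across cells
    (``cutoff_rule='fixed'`` uses ``fixed_cutoff`` for both). Positives for
    both modules are "both", for one "poor"/"better", for neither "none".
    """
    if not score_poor.index.equals(score_better.index):
        raise DataContractError("score vectors must cover the same cells")
    if cutoff_rule == "mean":
        cut_poor, cut_better = float(score_poor.mean()), float(score_better.mean())
    elif cutoff_rule == "fixed":
        cut_poor = cut_better = float(fixed_cutoff)
    else:
        raise DataContractError(f"unknown cutoff rule {cutoff_rule!r}")
    pos_p = score_poor.to_numpy() > cut_poor
    pos_b = score_better.to_numpy() > cut_better
    group = np.where(pos_p & pos_b, "both",
                     np.where(pos_p, "poor", np.where(pos_b, "better", "none")))
    return pd.DataFrame({"score_poor": score_poor, "score_better": score_better,
                         "group": group,
                         "cutoff_poor": cut_poor, "cutoff_better": cut_better},
                        index=score_poor.index)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when the pooled size is <= 25 and the
    data are tie-free, normal approximation with tie and continuity
    correction otherwise."""
    exact = (x.size + y.size) <= 25 and np.unique(np.concatenate([x, y])).size == x.size + y.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def one_vs_rest_de(cells: pd.DataFrame, groups: pd.Series,
                   genes: Sequence[str] | None = None,
                   min_cells: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon differential expression per group.

    For each group with at least ``min_cells`` cells, every gene is tested
    two-sided against all remaining cells; the effect is the difference of
    group means; Bonferroni correction is applied across genes within each
    comparison. Undersized groups are reported with a ``too_few_cells``
    reason and no tests.
    """
    if genes is None:
        genes = list(cells.index)
    lab = groups.reindex(cells.columns)
    values = cells.loc[genes].to_numpy(dtype=float)
    rows = []
    for grp in sorted(lab.dropna().unique()):
        mask = (lab == grp).to_numpy()
        if mask.sum() < min_cells:
            rows.append({"group": grp, "gene": "", "effect": np.nan,
                         "p": np.nan, "adj_p": np.nan, "significant": False,
                         "reason": "too_few_cells"})
            continue
        pvals, effects = [], []
        for gi in range(len(genes)):
            x, y = values[gi, mask], values[gi, ~mask]
            effects.append(float(x.mean() - y.mean()))
            if np.ptp(np.concatenate([x, y])) == 0:
                pvals.append(1.0)
            else:
                pvals.append(_wilcoxon_p(x, y))
        adj = np.minimum(np.asarray(pvals) * len(genes), 1.0)
        for gene, eff, p, ap in zip(genes, effects, pvals, adj):
            rows.append({"group": grp, "gene": gene, "effect": eff, "p": p,
                         "adj_p": float(ap), "significant": bool(ap < alpha),
                         "reason": ""})
    return pd.DataFrame(rows)
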