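"""Set-overlap statistics for signatures, complexes and alteration tables.

Fisher's exact test on 2x2 tables, permutation-based protein-complex
enrichment with an empirical null of odds ratios (10,000 label permutations
by default, plus-one p-value rule), alteration-frequency comparison between
clusters with a minimum-frequency filter, hypergeometric overlap of gene
sets, and Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataContractError, NumericalError

__all__ = [
    "fisher_2x2",
    "permutation_enrichment",
    "compare_alteration_frequencies",
    "hypergeometric_overlap",
    "bh_adjust",
]


def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-tailed Fisher's exact test on the table [[a, b], [c, d]].

    Returns ``{"odds_ratio", "p", "flags"}``; a zero cell makes the sample
    odds ratio 0 or infinite and is flagged rather than corrected.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise DataContractError("cells must be nonnegative integers")
    if sum(cells) == 0:
        raise DataContractError("empty contingency table")
    flags = []
    if b * c == 0 and a * d == 0:
        odds = float("nan")
        flags.append("undefined_or")
    elif b * c == 0:
        odds = float("inf")
        flags.append("infinite_or")
    else:
        odds = (a * d) / (b * c)
        if odds == 0:
            flags.append("zero_or")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"odds_ratio": odds, "p": float(p), "flags": flags}


def _odds_ratio_vec(a, n_top, n_member, universe):
    """Sample odds ratios for top-vs-member tables with fixed margins.

    ``a`` is the overlap count; infinite odds ratios (zero off-cell) are
    kept as inf so they rank above every finite value.
    """
    a = np.asarray(a, dtype=float)
    b = n_top - a
    c = n_member - a
    d = universe - n_top - n_member + a
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(b * c > 0, a * d / (b * c),
                        np.where(a * d > 0, np.inf, 0.0))


def permutation_enrichment(top_flags: pd.Series,
                           membership: Mapping[str, Sequence[str]],
                           n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Complex enrichment of a top-gene flag with a permutation null.

    ``top_flags`` is a boolean series over the variable-gene universe;
    ``membership`` maps complex name -> member genes. For each complex the
    observed odds ratio of top-status vs membership is compared with odds
    ratios after permuting the top/not-top labels; the one-sided empirical
    p is ``(1 + #[null OR >= observed]) / (n_perm + 1)`` and is BH-adjusted
    across complexes. Complexes without members in the universe are
    reported with a ``no_members`` reason and no test.
    """
    if n_perm < 1:
        raise DataContractError("n_perm must be at least 1")
    flags = top_flags.astype(bool)
    universe = len(flags)
    n_top = int(flags.sum())
    rng = np.random.default_rng(seed)

    rows = []
    for name, genes in membership.items():
        members = flags.index.intersection(pd.Index(genes))
        n_member = len(members)
        if n_member == 0:
            rows.append({"complex": name, "a": 0, "b": 0, "c": 0, "d": 0,
                         "odds_ratio": np.nan, "p": np.nan,
                         "reason": "no_members"})
            continue
        a = int(flags[members].sum())
        b = n_top - a
        c = n_member - a
        d = universe - n_top - n_member + a
        obs = _odds_ratio_vec(np.array([a]), n_top, n_member, universe)[0]
        # permuting the top labels makes the overlap hypergeometric with
        # fixed margins; draw it directly, one draw per permutation
        null_a = rng.hypergeometric(n_member, universe - n_member, n_top,
                                    size=n_perm)
        null_or = _odds_ratio_vec(null_a, n_top, n_member, universe)
        exceed = int(np.sum(null_or >= obs)) if np.isfinite(obs) else int(
            np.sum(np.isinf(null_or)))
        p = (1.0 + exceed) / (n_perm + 1.0)
        rows.append({"complex": name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(obs), "p": p, "reason": ""})
    table = pd.DataFrame(rows).set_index("complex")
    tested = table.index[table["p"].notna()]
    table["adj_p"] = np.nan
    if len(tested):
        table.loc[tested, "adj_p"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["enriched"] = table["adj_p"] < 0.05
    return table


def compare_alteration_frequencies(alterations: pd.DataFrame, labels: pd.Series,
                                   min_fraction: float = 0.10) -> pd.DataFrame:
    """Per-gene alteration-frequency comparison between two clusters.

    Only genes altered in at least ``min_fraction`` of the samples of
    either cluster are tested (two-tailed Fisher on altered x cluster);
    p-values are BH-corrected across the tested genes.
    """
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise DataContractError("alteration comparison requires two clusters")
    common = alterations.columns.intersection(labels.index)
    alt = alterations[common].astype(int)
    lab = labels[common]
    in1 = (lab == clusters[0]).to_numpy()
    in2 = (lab == clusters[1]).to_numpy()
    n1, n2 = int(in1.sum()), int(in2.sum())
    rows = []
    for gene in alt.index:
        v = alt.loc[gene].to_numpy()
        a1, a2 = int(v[in1].sum()), int(v[in2].sum())
        f1, f2 = a1 / n1, a2 / n2
        if max(f1, f2) < min_fraction:
            continue
        res = fisher_2x2(a1, n1 - a1, a2, n2 - a2)
        rows.append({"gene": gene, "f1": f1, "f2": f2, "p": res["p"]})
    table = pd.DataFrame(rows, columns=["gene", "f1", "f2", "p"]).set_index("gene")
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
    else:
        table["adj_p"] = pd.Series(dtype=float)
    return table


def hypergeometric_overlap(set_a: Sequence[str], set_b: Sequence[str],
                           universe_size: int) -> float:
    """Upper-tail P(X >= |A & B|) for the overlap of two sets drawn from a
    common universe."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise DataContractError("set larger than the universe")
    overlap = len(a & b)
    if overlap > min(len(a), len(b)):  # pragma: no cover - set algebra forbids
        raise DataContractError("overlap exceeds the smaller set")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out
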