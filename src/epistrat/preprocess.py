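"""Sample filtering, count normalization and variable-epifactor selection.

Counts are normalized with median-of-ratios size factors (the DESeq-style
estimator) followed by a log2 transform with pseudocount 1; the clustering
input is then restricted to the annotated epifactor genes whose standard
deviation across samples exceeds a cutoff, chosen automatically so that a
target number of genes (500-600 by default) survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataContractError, NumericalError

__all__ = [
    "filter_samples",
    "size_factors",
    "normalize_log2",
    "select_variable_epifactors",
    "SelectionResult",
]


def filter_samples(clinical: pd.DataFrame, purity_threshold: float = 0.70,
                   min_cohort: int = 70,
                   purity_columns: list[str] | None = None) -> tuple[list[str], bool]:
    """Keep samples whose purity passes the any-metric rule.

    A sample is kept when ANY of its purity metrics is >= ``purity_threshold``
    (missing metrics are ignored for that sample). Returns the kept sample
    ids and an ``undersized`` flag raised when fewer than ``min_cohort``
    samples survive.
    """
    if purity_columns is None:
        purity_columns = [c for c in clinical.columns if c.startswith("purity")]
    if not purity_columns:
        raise DataContractError("clinical table has no purity metric columns")
    purity = clinical[purity_columns].astype(float)
    keep = (purity >= purity_threshold).any(axis=1)
    kept = list(clinical.index[keep])
    return kept, len(kept) < min_cohort


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; for each
    the reference level is the geometric mean across samples, and each
    sample's factor is the median of count / reference over the reference
    genes.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataContractError("counts must be nonnegative")
    reference_rows = np.all(values > 0, axis=1)
    if not reference_rows.any():
        raise NumericalError("no gene has nonzero counts in every sample")
    ref = values[reference_rows]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(counts: pd.DataFrame, factors: pd.Series,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x samples."""
    if pseudocount < 0:
        raise DataContractError("pseudocount must be nonnegative")
    f = np.asarray(factors.reindex(counts.columns), dtype=float)
    if f.shape[0] != counts.shape[1] or np.any(~np.isfinite(f)):
        raise DataContractError("size factors do not match the count columns")
    if np.any(f <= 0):
        raise DataContractError("size factors must be strictly positive")
    return pd.DataFrame(np.log2(counts.to_numpy(dtype=float) / f[None, :] + pseudocount),
                        index=counts.index, columns=counts.columns)


@dataclass
class SelectionResult:
    genes: list[str]
    cutoff: float
    sds: pd.Series
    in_target: bool


def select_variable_epifactors(norm: pd.DataFrame, annotation: pd.DataFrame,
                               target_range: tuple[int, int] = (500, 600),
                               sd_cutoff: float | None = None) -> SelectionResult:
    """Epifactor genes whose per-gene SD across samples exceeds a cutoff.

    With an explicit ``sd_cutoff`` the rule is simply SD > cutoff. In
    automatic mode the cutoff is searched on the grid of SD quantiles of the
    epifactor genes (steps of 0.005) for a count inside ``target_range``;
    when no grid point lands inside, the closest achievable count is
    returned with ``in_target=False``.
    """
    epi = annotation.index[annotation["is_epifactor"].astype(bool)]
    genes = norm.index.intersection(epi)
    if len(genes) == 0:
        raise DataContractError("no annotated epifactor gene found in the matrix")
    sds = norm.loc[genes].std(axis=1, ddof=1)

    if sd_cutoff is not None:
        selected = sds.index[sds > sd_cutoff]
        lo, hi = target_range
        return SelectionResult(list(selected), float(sd_cutoff), sds,
                               lo <= len(selected) <= hi)

    lo, hi = target_range
    grid = np.quantile(sds.to_numpy(), np.arange(0.0, 1.0, 0.005))
    best: tuple[int, float] | None = None  # (distance to range, cutoff)
    for cutoff in grid:
        count = int((sds > cutoff).sum())
        if lo <= count <= hi:
            return SelectionResult(list(sds.index[sds > cutoff]), float(cutoff),
                                   sds, True)
        distance = lo - count if count < lo else count - hi
        if best is None or distance < best[0]:
            best = (distance, float(cutoff))
    assert best is not None
    cutoff = best[1]
    return SelectionResult(list(sds.index[sds > cutoff]), cutoff, sds, False)
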