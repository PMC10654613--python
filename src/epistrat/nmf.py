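"""Consensus NMF stratification: factorization, rank selection, signatures.

The factorization minimizes the generalized Kullback-Leibler divergence
D(V || WH) by multiplicative updates (the Brunet variant), the convention of
expression-based tumor subtyping. Cluster stability is assessed by a
consensus matrix over random restarts; candidate ranks are compared with
three validation metrics (cophenetic coefficient, mean silhouette,
Handl connectivity) and the majority winner is chosen. Cluster-defining
signature genes are extracted with the Kim-Park metagene feature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import cdist, squareform
from sklearn.metrics import silhouette_samples

from .errors import DataContractError, NumericalError

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "SignatureSet",
    "nmf_factorize",
    "consensus_cluster",
    "cophenetic_coefficient",
    "silhouette_score",
    "connectivity",
    "select_rank",
    "extract_top_genes",
    "label_clusters_by_outcome",
]

_EPS = 1e-12


@dataclass
class NMFFactorization:
    W: np.ndarray  # genes x k basis
    H: np.ndarray  # k x samples coefficients
    objective_trace: np.ndarray
    seed: int
    converged: bool


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples co-clustering frequency
    labels: pd.Series  # sample -> cluster in 1..k
    n_runs: int
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class SignatureSet:
    """Per-cluster signature gene lists with Kim-Park scores."""

    genes: dict[int, list[str]]  # cluster -> genes ordered by score, descending
    scores: pd.Series  # gene -> Kim-Park score, selected genes only
    assignment: pd.Series  # gene -> cluster (argmax basis)
    all_scores: pd.Series  # every scored gene
    outcome_labels: dict[int, str] | None = None  # cluster -> poor / better


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # 0 * log 0 = 0 convention on the V side
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))
    return float(term.sum() - V.sum() + WH.sum())


def nmf_factorize(V: np.ndarray, k: int, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-6) -> NMFFactorization:
    """KL multiplicative-update NMF with random uniform initialization.

    Iterates the Lee-Seung updates for D(V || WH) until the relative
    objective change drops below ``tol`` or ``max_iter`` is reached; the
    per-iteration objective trace is recorded and is non-increasing.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise DataContractError("V must be nonnegative")
    if V.ndim != 2:
        raise DataContractError("V must be a matrix")
    if not 1 <= k < min(V.shape):
        raise DataContractError("rank k must satisfy 1 <= k < min(V.shape)")
    rng = np.random.default_rng(seed)
    g, n = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(g, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale

    trace = []
    prev = _kl_divergence(V, W @ H)
    trace.append(prev)
    converged = False
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        if abs(prev - obj) <= tol * max(abs(prev), _EPS):
            converged = True
            break
        prev = obj
    return NMFFactorization(W=W, H=H, objective_trace=np.asarray(trace),
                            seed=seed, converged=converged)


def consensus_cluster(V: pd.DataFrame | np.ndarray, k: int, n_runs: int = 30,
                      seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
                      metric_space: str = "expression",
                      n_neighbors: int = 10) -> ConsensusResult:
    """Consensus clustering of samples over ``n_runs`` NMF restarts.

    Each restart r (seed ``seed + r``) assigns every sample to the argmax
    row of its H column; the consensus matrix holds the fraction of runs in
    which two samples co-cluster, and the final labels come from cutting the
    average-linkage dendrogram of (1 - consensus) at k. Validation metrics
    (cophenetic, silhouette, connectivity) are attached; silhouette and
    connectivity use the expression feature space by default
    (``metric_space='consensus'`` switches to 1 - consensus distances).
    """
    if n_runs < 2:
        raise DataContractError("n_runs must be at least 2")
    if isinstance(V, pd.DataFrame):
        sample_ids = list(V.columns)
        values = V.to_numpy(dtype=float)
    else:
        values = np.asarray(V, dtype=float)
        sample_ids = [f"sample{i}" for i in range(values.shape[1])]
    n = values.shape[1]

    together = np.zeros((n, n))
    for r in range(n_runs):
        fit = nmf_factorize(values, k, seed=seed + r, max_iter=max_iter, tol=tol)
        run_labels = np.argmax(fit.H, axis=0)
        together += run_labels[:, None] == run_labels[None, :]
    consensus = together / n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    Z = average(squareform(1.0 - consensus, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust")

    metrics: dict[str, float] = {}
    metrics["cophenetic"] = cophenetic_coefficient(consensus)
    feats = values.T if metric_space == "expression" else 1.0 - consensus
    if len(np.unique(labels)) >= 2:
        metrics["silhouette"] = silhouette_score(feats, labels)
        metrics["connectivity"] = connectivity(feats, labels,
                                               min(n_neighbors, n - 1))
    else:
        metrics["silhouette"] = float("nan")
        metrics["connectivity"] = float("nan")

    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        n_runs=n_runs,
        metrics=metrics,
    )


def cophenetic_coefficient(consensus: np.ndarray | pd.DataFrame) -> float:
    """Correlation of (1 - consensus) with its average-linkage ultrametric.

    Degenerate (constant-distance) consensus matrices have no defined
    correlation; NaN is returned with a warning.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataContractError("consensus must be square")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise DataContractError("consensus must be symmetric with unit diagonal")
    d = squareform(1.0 - C, checks=False)
    if np.ptp(d) == 0:
        warnings.warn("constant consensus distances: cophenetic undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    coeff, _ = cophenet(average(d), d)
    return float(coeff)


def silhouette_score(data: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width with Euclidean distances.

    Samples in singleton clusters contribute 0.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataContractError("silhouette requires at least two clusters")
    return float(np.mean(silhouette_samples(data, labels, metric="euclidean")))


def connectivity(data: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> float:
    """Handl connectivity: sum of 1/j over the j-th nearest neighbors
    (j = 1..n_neighbors, Euclidean) that carry a different label than their
    anchor point. Lower is better; 0 means every neighborhood is pure.
    Distance ties are broken by sample index.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    n = data.shape[0]
    if not 1 <= n_neighbors <= n - 1:
        raise DataContractError("n_neighbors must lie in [1, n - 1]")
    dist = cdist(data, data)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")  # index order breaks ties
    total = 0.0
    for i in range(n):
        for j in range(n_neighbors):
            if labels[order[i, j]] != labels[i]:
                total += 1.0 / (j + 1)
    return total


def select_rank(metric_table: dict[int, dict[str, float]]) -> int:
    """Majority vote over the three validation metrics.

    Cophenetic and silhouette vote for their highest rank, connectivity for
    its lowest; the rank with most votes wins, and any tie resolves to the
    smallest candidate rank.
    """
    ks = sorted(metric_table)
    if len(ks) < 2:
        raise DataContractError("need at least two candidate ranks")
    for k in ks:
        for m in ("cophenetic", "silhouette", "connectivity"):
            if m not in metric_table[k] or not np.isfinite(metric_table[k][m]):
                raise DataContractError(f"metric {m!r} missing for rank {k}")
    votes: dict[int, int] = {k: 0 for k in ks}
    for m, better_high in (("cophenetic", True), ("silhouette", True),
                           ("connectivity", False)):
        vals = [metric_table[k][m] for k in ks]
        best = max(vals) if better_high else min(vals)
        winner = min(k for k, v in zip(ks, vals) if v == best)
        votes[winner] += 1
    top = max(votes.values())
    return min(k for k, v in votes.items() if v == top)


def kim_park_scores(W: np.ndarray) -> np.ndarray:
    """Kim-Park metagene feature score per gene (row of W).

    score = 1 + (1/log2 k) * sum_q p_q log2 p_q with p the normalized basis
    loadings; 1 for a fully cluster-specific gene, 0 for a uniform one.
    All-zero rows score NaN.
    """
    W = np.asarray(W, dtype=float)
    k = W.shape[1]
    if k < 2:
        raise DataContractError("need at least two basis columns")
    rowsum = W.sum(axis=1)
    score = np.full(W.shape[0], np.nan)
    ok = rowsum > 0
    p = W[ok] / rowsum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    score[ok] = 1.0 + plogp.sum(axis=1) / np.log2(k)
    return np.clip(score, 0.0, 1.0, out=score)


def extract_top_genes(W: np.ndarray | pd.DataFrame,
                      gene_ids: list[str] | None = None) -> SignatureSet:
    """Cluster signature genes by the Kim-Park criterion.

    A gene is selected when its score exceeds mean + 3 SD of all scores and
    its maximal basis loading exceeds the median of all W entries; each
    selected gene is assigned to its argmax basis (ties to the lowest
    cluster index).
    """
    if isinstance(W, pd.DataFrame):
        gene_ids = list(W.index)
        W = W.to_numpy(dtype=float)
    W = np.asarray(W, dtype=float)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(W.shape[0])]
    score = kim_park_scores(W)
    ok = np.isfinite(score)
    mu, sd = score[ok].mean(), score[ok].std(ddof=1)
    med = np.median(W)
    selected = ok & (score > mu + 3.0 * sd) & (W.max(axis=1) > med)
    cluster = W.argmax(axis=1) + 1  # argmax takes the lowest index on ties

    all_scores = pd.Series(score, index=gene_ids, name="kim_park_score")
    sel_ids = [g for g, s in zip(gene_ids, selected) if s]
    scores = all_scores[sel_ids]
    assignment = pd.Series(cluster, index=gene_ids, name="cluster")[sel_ids]
    genes: dict[int, list[str]] = {q: [] for q in range(1, W.shape[1] + 1)}
    for g in scores.sort_values(ascending=False).index:
        genes[int(assignment[g])].append(g)
    return SignatureSet(genes=genes, scores=scores, assignment=assignment,
                        all_scores=all_scores)


def align_signatures(signatures: SignatureSet, H: np.ndarray,
                     labels: pd.Series) -> SignatureSet:
    """Renumber signature clusters to match consensus labels.

    The basis columns of a single NMF fit are ordered arbitrarily relative
    to the consensus dendrogram labels; each basis q is mapped to the
    consensus cluster most frequent among the samples that fit assigns to
    q (argmax over H rows).
    """
    fit_assign = np.argmax(H, axis=0)  # 0-based basis per sample
    lab = labels.to_numpy()
    mapping: dict[int, int] = {}
    used: set[int] = set()
    # assign bases in order of decreasing membership so the dominant basis
    # claims its majority cluster first; the map stays a bijection
    sizes = [(int(np.sum(fit_assign == q)), q) for q in range(H.shape[0])]
    for _, q in sorted(sizes, reverse=True):
        members = lab[fit_assign == q]
        if members.size:
            vals, counts = np.unique(members, return_counts=True)
            for c in vals[np.argsort(-counts)]:
                if int(c) not in used:
                    mapping[q + 1] = int(c)
                    used.add(int(c))
                    break
    leftovers = [c for c in sorted({int(v) for v in lab} | set(range(1, H.shape[0] + 1)))
                 if c not in used]
    for q in range(1, H.shape[0] + 1):
        if q not in mapping:
            mapping[q] = leftovers.pop(0)
    genes = {mapping[q]: g for q, g in signatures.genes.items()}
    assignment = signatures.assignment.map(lambda q: mapping[int(q)])
    return SignatureSet(genes=genes, scores=signatures.scores,
                        assignment=assignment, all_scores=signatures.all_scores,
                        outcome_labels=signatures.outcome_labels)


def label_clusters_by_outcome(labels: pd.Series, clinical: pd.DataFrame,
                              endpoint: str = "pfi") -> tuple[dict[int, str] | None, bool]:
    """Attach poor/better outcome labels to a two-cluster solution.

    The cluster with the lower Kaplan-Meier survival at the cohort's median
    follow-up time is labeled "poor"; an exact tie falls back to the sign of
    the log-rank observed-minus-expected statistic. Returns
    (labels-or-None, flagged) where flagged marks an unlabelable solution
    (no events, or indistinguishable curves).
    """
    from .survival import km_estimate  # local import avoids a cycle

    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise DataContractError("outcome labeling requires exactly two clusters")
    time = clinical.loc[labels.index, f"time_{endpoint}"].to_numpy(dtype=float)
    event = clinical.loc[labels.index, f"event_{endpoint}"].to_numpy(dtype=int)
    if event.sum() == 0:
        return None, True
    t_ref = float(np.median(time))
    surv = {}
    for c in clusters:
        mask = (labels == c).to_numpy()
        if event[mask].sum() == 0:
            return None, True
        km = km_estimate(time[mask], event[mask])
        surv[c] = km.survival_at(t_ref)
    a, b = clusters
    if surv[a] == surv[b]:
        from .survival import _logrank_observed_minus_expected
        o_minus_e = _logrank_observed_minus_expected(
            (labels == b).to_numpy().astype(int), time, event)
        if o_minus_e == 0:
            return None, True
        poor = b if o_minus_e > 0 else a
    else:
        poor = a if surv[a] < surv[b] else b
    better = b if poor == a else a
    return {poor: "poor", better: "better"}, False
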