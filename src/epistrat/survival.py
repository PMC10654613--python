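"""Cluster- and gene-level survival analysis.

Provides the product-limit (Kaplan-Meier) estimator, the Mantel-Cox
log-rank test, a Cox proportional-hazards fit maximizing the Efron partial
likelihood by Newton-Raphson, cluster comparison across endpoints with
configurable adjustment covariates, a per-gene optimal-cutpoint prognostic
screen with Benjamini-Hochberg correction, the meta-PCNA proliferation
covariate, and cross-cohort prognostic residuals with exact sign tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataContractError, NumericalError

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "compare_clusters",
    "optimal_cutpoint",
    "prognostic_screen",
    "meta_pcna",
    "prognostic_residuals",
    "ResidualSummary",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Right-continuous product-limit curve."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Product-limit estimator; samples censored at an event time count as
    at risk at that time."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise DataContractError("empty survival input")
    if np.any(t <= 0):
        raise DataContractError("survival times must be positive")
    event_times = np.unique(t[d == 1])
    surv, out_s, out_r, out_d = 1.0, [], [], []
    for tau in event_times:
        n_risk = int(np.sum(t >= tau))
        n_dead = int(np.sum((t == tau) & (d == 1)))
        surv *= 1.0 - n_dead / n_risk
        out_s.append(surv)
        out_r.append(n_risk)
        out_d.append(n_dead)
    return KMEstimate(times=event_times, survival=np.asarray(out_s),
                      at_risk=np.asarray(out_r), n_events=np.asarray(out_d))


# ---------------------------------------------------------------------------
# log-rank


def _risk_tables(times: np.ndarray, events: np.ndarray):
    """Distinct event times with total at-risk and death counts."""
    taus = np.unique(times[events == 1])
    at_risk = (times[None, :] >= taus[:, None])
    n_j = at_risk.sum(axis=1).astype(float)
    dead = (times[None, :] == taus[:, None]) & (events[None, :] == 1)
    d_j = dead.sum(axis=1).astype(float)
    return taus, at_risk, dead, n_j, d_j


def logrank_test(group_labels: Sequence, times: Sequence[float],
                 events: Sequence[int]) -> dict:
    """Mantel-Cox log-rank test for two or more groups.

    Returns ``{"chi2", "df", "p", "flags"}``; a cohort with zero events
    yields chi2 = 0, p = 1 and a ``no_events`` flag.
    """
    g = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    groups = np.unique(g)
    if len(groups) < 2:
        raise DataContractError("log-rank requires at least two groups")
    for grp in groups:
        if np.sum(g == grp) == 0:  # pragma: no cover - unique() precludes this
            raise DataContractError(f"group {grp!r} is empty")
    m = len(groups)
    if d.sum() == 0:
        return {"chi2": 0.0, "df": m - 1, "p": 1.0, "flags": ["no_events"]}

    taus, at_risk, dead, n_j, d_j = _risk_tables(t, d)
    member = np.stack([(g == grp) for grp in groups])  # m x n
    n_gj = member.astype(float) @ at_risk.T  # m x J
    d_gj = member.astype(float) @ dead.T
    O = d_gj.sum(axis=1)
    E = (d_j[None, :] * n_gj / n_j[None, :]).sum(axis=1)
    # hypergeometric covariance of deaths per group, summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    p_gj = n_gj / n_j[None, :]
    V = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            delta = 1.0 if a == b else 0.0
            V[a, b] = np.sum(scale * p_gj[a] * (delta - p_gj[b]))
    u = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(Vsub, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vsub) @ u)
    p = float(stats.chi2.sf(chi2, m - 1))
    return {"chi2": chi2, "df": m - 1, "p": p, "flags": []}


def _logrank_observed_minus_expected(group: np.ndarray, times: np.ndarray,
                                     events: np.ndarray) -> float:
    """O - E for the indicated (group == 1) arm; positive means excess hazard."""
    taus, at_risk, dead, n_j, d_j = _risk_tables(times, events)
    gmask = group.astype(bool)
    n1 = at_risk[:, gmask].sum(axis=1)
    d1 = dead[:, gmask].sum(axis=1)
    return float(np.sum(d1 - d_j * n1 / n_j))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit."""

    params: pd.DataFrame  # coef, se, hr, hr_low, hr_high, p per covariate
    loglik: float
    iterations: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])

    def p(self, name: str) -> float:
        return float(self.params.loc[name, "p"])


def _efron_loglik(beta, X, times, events):
    """Efron partial log-likelihood with gradient and Hessian."""
    n, p = X.shape
    order = np.argsort(-times, kind="stable")  # descending: risk sets are prefixes
    Xs, ts, ds = X[order], times[order], events[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * Xs, axis=0)
    cum2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        deaths = np.nonzero(ds[i:j + 1] == 1)[0] + i
        dcount = len(deaths)
        if dcount:
            S0R, S1R, S2R = cum0[j], cum1[j], cum2[j]
            wd = w[deaths]
            S0D = wd.sum()
            S1D = (wd[:, None] * Xs[deaths]).sum(axis=0)
            S2D = (wd[:, None, None] * (Xs[deaths][:, :, None]
                                        * Xs[deaths][:, None, :])).sum(axis=0)
            ll += eta[deaths].sum()
            grad += Xs[deaths].sum(axis=0)
            for ell in range(dcount):
                frac = ell / dcount
                phi = S0R - frac * S0D
                z1 = S1R - frac * S1D
                z2 = S2R - frac * S2D
                ll -= np.log(phi)
                grad -= z1 / phi
                hess -= z2 / phi - np.outer(z1, z1) / (phi * phi)
        i = j + 1
    return ll, grad, hess


def cox_fit(design: pd.DataFrame | np.ndarray, times: Sequence[float],
            events: Sequence[int], max_iter: int = 25,
            tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson fit of the Cox model with Efron tie handling.

    Convergence requires a relative partial log-likelihood change below
    ``tol``. Monotone likelihood (perfect separation) is detected through
    diverging coefficients and reported via ``converged=False`` plus a
    ``monotone_likelihood`` flag.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    n, p = X.shape
    if n <= p:
        raise DataContractError("need more samples than covariates")
    if np.any(np.ptp(X, axis=0) == 0):
        raise DataContractError("constant covariate in design matrix")
    if d.sum() == 0:
        raise NumericalError("no events: partial likelihood is flat")

    center = X.mean(axis=0)
    Xc = X - center
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik(beta, Xc, t, d)
    flags: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess = _efron_loglik(new_beta, Xc, t, d)
        halvings = 0
        while new_ll < ll and halvings < 10:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _efron_loglik(new_beta, Xc, t, d)
            halvings += 1
        delta = abs(new_ll - ll)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > 50):
            flags.append("monotone_likelihood")
            break
        if delta <= tol * (abs(ll) + 1.0):
            converged = True
            break

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    # monotone likelihood: the partial likelihood plateaus while the
    # coefficient diverges, so the curvature collapses and se explodes
    if np.any(np.abs(beta) > 10) or np.any(~np.isfinite(se)) or np.any(se > 100):
        if "monotone_likelihood" not in flags:
            flags.append("monotone_likelihood")
        converged = False
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ci = 1.959963984540054 * se
    with np.errstate(over="ignore"):
        params = pd.DataFrame({
            "coef": beta, "se": se, "hr": np.exp(beta),
            "hr_low": np.exp(beta - ci), "hr_high": np.exp(beta + ci),
            "p": pvals,
        }, index=names)
    return CoxFit(params=params, loglik=float(ll), iterations=it,
                  converged=converged, flags=flags)


# ---------------------------------------------------------------------------
# cluster comparison


def _encode_covariates(clinical: pd.DataFrame, adjust_for: Iterable[str],
                       index) -> pd.DataFrame:
    cols = {}
    for name in adjust_for:
        col = clinical.loc[index, name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            cols[name] = col.map({lv: i for i, lv in enumerate(levels)}).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=index)


def compare_clusters(labels: pd.Series, clinical: pd.DataFrame,
                     adjust_for: Sequence[str] = ("age", "sex"),
                     endpoints: Sequence[str] = ("pfi", "dss", "os")) -> dict:
    """Log-rank and covariate-adjusted Cox comparison of two clusters.

    Returns per endpoint a dict with the log-rank result, the CoxFit for
    the cluster indicator plus adjustment covariates, and any flags
    (collinear adjustment covariates are dropped and flagged).
    """
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise DataContractError("cluster comparison requires exactly two clusters")
    idx = labels.index
    indicator = (labels == clusters[1]).astype(float)
    covs = _encode_covariates(clinical, adjust_for, idx)
    flags = []
    keep = []
    for name in covs.columns:
        v = covs[name].to_numpy()
        if np.ptp(v) == 0:
            flags.append(f"constant:{name}")
            continue
        r = np.corrcoef(v, indicator.to_numpy())[0, 1]
        if abs(r) > 1 - 1e-12:
            flags.append(f"collinear:{name}")
            continue
        keep.append(name)
    out = {}
    for endpoint in endpoints:
        tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
        if tcol not in clinical.columns:
            continue
        t = clinical.loc[idx, tcol].to_numpy(dtype=float)
        d = clinical.loc[idx, ecol].to_numpy(dtype=int)
        lr = logrank_test(labels.to_numpy(), t, d)
        design = pd.concat([indicator.rename("cluster"), covs[keep]], axis=1)
        fit = cox_fit(design, t, d)
        out[endpoint] = {"logrank": lr, "cox": fit, "flags": list(flags)}
    return out


# ---------------------------------------------------------------------------
# optimal cutpoint and prognostic screen


def _logrank_z_for_groups(high: np.ndarray, at_risk: np.ndarray,
                          dead: np.ndarray, n_j: np.ndarray,
                          d_j: np.ndarray) -> np.ndarray:
    """Standardized two-group log-rank Z for each column of ``high``.

    ``high`` is an n x c boolean membership matrix; risk tables are shared.
    """
    n1 = at_risk.astype(float) @ high  # J x c
    d1 = dead.astype(float) @ high
    num = (d1 - d_j[:, None] * n1 / n_j[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    p1 = n1 / n_j[:, None]
    var = (scale[:, None] * p1 * (1.0 - p1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, num / np.sqrt(var), 0.0)


def optimal_cutpoint(expression: Sequence[float], times: Sequence[float],
                     events: Sequence[int], minprop: float = 0.1) -> dict:
    """Expression cutpoint maximizing the absolute standardized log-rank
    statistic between the resulting high (> cutpoint) and low groups.

    Candidates leave at least ``ceil(minprop * n)`` samples on each side;
    ties in the statistic resolve to the lowest cutpoint. Returns
    ``{"cutpoint", "statistic", "high"}``.
    """
    x = np.asarray(expression, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    n = x.size
    if np.ptp(x) == 0:
        raise NumericalError("constant expression: no cutpoint exists")
    if not 0 < minprop < 0.5:
        raise DataContractError("minprop must lie in (0, 0.5)")
    m = int(np.ceil(minprop * n))
    values = np.unique(x)
    low_counts = np.searchsorted(np.sort(x), values, side="right")
    ok = (low_counts >= m) & (n - low_counts >= m)
    candidates = values[ok]
    if candidates.size == 0:
        raise NumericalError("no admissible cutpoint under the minprop constraint")
    taus, at_risk, dead, n_j, d_j = _risk_tables(t, d)
    high = x[:, None] > candidates[None, :]
    z = _logrank_z_for_groups(high, at_risk, dead, n_j, d_j)
    best = int(np.argmax(np.abs(z)))  # argmax takes the first (lowest) on ties
    cut = float(candidates[best])
    return {"cutpoint": cut, "statistic": float(z[best]), "high": x > cut}


def prognostic_screen(norm: pd.DataFrame, clinical: pd.DataFrame,
                      genes: Sequence[str],
                      adjust_for: Sequence[str] = ("age", "sex"),
                      alpha: float = 0.05, endpoint: str = "pfi",
                      excluded: Sequence[str] = (),
                      minprop: float = 0.1) -> pd.DataFrame:
    """Per-gene optimal-cutpoint prognostic screen.

    Each gene is dichotomized at its optimal cutpoint, the high/low
    indicator is fitted in a Cox model together with the adjustment
    covariates, and the Wald p-values of the indicator are BH-corrected
    across tested genes; a gene is prognostic when its adjusted p falls
    below ``alpha``. Genes listed in ``excluded`` (e.g. dropped by the
    variability filter) are reported not prognostic with a
    ``non-variable`` reason code. Direction ``poor-with-high`` means the
    high-expression group has hazard ratio > 1.
    """
    from .enrichment import bh_adjust

    idx = clinical.index
    t = clinical[f"time_{endpoint}"].to_numpy(dtype=float)
    d = clinical[f"event_{endpoint}"].to_numpy(dtype=int)
    covs = _encode_covariates(clinical, adjust_for, idx)
    covs = covs.loc[:, covs.apply(lambda c: np.ptp(c.to_numpy()) > 0)]

    rows = []
    for gene in genes:
        row = {"gene": gene, "cutpoint": np.nan, "n_high": 0, "n_low": 0,
               "direction": "", "p": np.nan, "adj_p": np.nan,
               "prognostic": False, "reason": ""}
        if gene in excluded or gene not in norm.index:
            row["reason"] = "non-variable"
            rows.append(row)
            continue
        x = norm.loc[gene, idx].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            row["reason"] = "non-variable"
            rows.append(row)
            continue
        try:
            cp = optimal_cutpoint(x, t, d, minprop=minprop)
        except NumericalError:
            row["reason"] = "no-cutpoint"
            rows.append(row)
            continue
        high = cp["high"].astype(float)
        design = pd.concat(
            [pd.Series(high, index=idx, name="high"), covs], axis=1)
        try:
            fit = cox_fit(design, t, d)
        except (DataContractError, NumericalError):
            row["reason"] = "cox-failed"
            rows.append(row)
            continue
        coef = fit.coef("high")
        row.update({
            "cutpoint": cp["cutpoint"],
            "n_high": int(high.sum()), "n_low": int(len(high) - high.sum()),
            "direction": "poor-with-high" if coef > 0 else "poor-with-low",
            "p": fit.p("high"),
            "reason": "" if fit.converged else "not-converged",
        })
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    tested = table.index[table["p"].notna()]
    if len(tested):
        table.loc[tested, "adj_p"] = bh_adjust(table.loc[tested, "p"].to_numpy())
        table.loc[tested, "prognostic"] = table.loc[tested, "adj_p"] < alpha
    return table


def meta_pcna(norm: pd.DataFrame, anchor_gene: str = "PCNA",
              top_frac: float = 0.01) -> tuple[list[str], pd.Series]:
    """Proliferation signature and per-sample score.

    The signature is the top ``ceil(top_frac * (G - 1))`` genes by Pearson
    correlation with the anchor gene's expression; the per-sample score is
    the median of the signature genes' log2 normalized values, usable as a
    Cox adjustment covariate.
    """
    if anchor_gene not in norm.index:
        raise DataContractError(f"anchor gene {anchor_gene!r} not in matrix")
    anchor = norm.loc[anchor_gene].to_numpy(dtype=float)
    if np.ptp(anchor) == 0:
        raise NumericalError("anchor gene expression is constant")
    others = norm.drop(index=anchor_gene)
    X = others.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.sqrt((xc * xc).sum(axis=1) * (ac * ac).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (xc @ ac) / denom, -np.inf)
    k = int(np.ceil(top_frac * (norm.shape[0] - 1)))
    top_idx = np.argsort(-corr, kind="stable")[:k]
    signature = [others.index[i] for i in top_idx]
    score = norm.loc[signature].median(axis=0)
    score.name = "meta_pcna_score"
    return signature, score


# ---------------------------------------------------------------------------
# prognostic residuals across cohorts


@dataclass
class ResidualSummary:
    """Cross-cohort direction balance of prognostic genes.

    ``residuals`` holds per gene N (cohorts poor-with-high), M (cohorts
    poor-with-low) and the residual N - M; ``group_tests`` holds per
    grouping level the counts of positive and negative residuals and a
    two-sided exact sign test.
    """

    residuals: pd.DataFrame
    group_tests: pd.DataFrame


def prognostic_residuals(tables: Mapping[str, pd.DataFrame],
                         annotation: pd.DataFrame,
                         groupings: Sequence[str] = ("all", "category",
                                                     "subrole", "mark")) -> ResidualSummary:
    """Count, per gene, cohorts where high vs low expression is
    poor-prognostic, and sign-test the residual balance per gene grouping.

    Genes with N = M = 0 are excluded from the sign counts; so are genes
    with a zero residual, which carry no direction information.
    """
    if len(tables) < 2:
        raise DataContractError("need at least two cohorts")
    known = {"all", "category", "subrole", "mark"}
    for gkey in groupings:
        if gkey not in known:
            raise DataContractError(f"unknown grouping {gkey!r}")
    genes = sorted(set().union(*[set(t.index) for t in tables.values()]))
    N = pd.Series(0, index=genes)
    M = pd.Series(0, index=genes)
    for table in tables.values():
        prog = table[table["prognostic"].astype(bool)]
        for gene, row in prog.iterrows():
            if row["direction"] == "poor-with-high":
                N[gene] += 1
            elif row["direction"] == "poor-with-low":
                M[gene] += 1
    residuals = pd.DataFrame({"N": N, "M": M, "residual": N - M})

    informative = residuals[(residuals["N"] + residuals["M"]) > 0]
    rows = []
    for gkey in groupings:
        if gkey == "all":
            levels = {"all": list(informative.index)}
        else:
            ann = annotation.reindex(informative.index)[gkey].fillna("")
            levels = {lv: list(ann.index[ann == lv])
                      for lv in sorted(ann.unique()) if lv}
        for level, members in levels.items():
            res = informative.loc[members, "residual"]
            pos = int((res > 0).sum())
            neg = int((res < 0).sum())
            if pos + neg == 0:
                p = 1.0
            else:
                p = float(stats.binomtest(pos, pos + neg, 0.5).pvalue)
            rows.append({"grouping": gkey, "level": level,
                         "n_positive": pos, "n_negative": neg, "p": p})
    return ResidualSummary(residuals=residuals, group_tests=pd.DataFrame(rows))
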