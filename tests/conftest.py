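"""Shared fixtures: one mid-sized synthetic cohort and its stratification.

The heavy artifacts (cohort generation, consensus clustering) are session
scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import epistrat as es
from epistrat import CohortConfig


SMALL = dict(n_samples=80, n_genes=300, n_epifactors=120, signature_size=15,
             prolif_module_size=20)


@pytest.fixture(scope="session")
def cohort():
    """Default-sized cohort (seed 1) with all four artifacts."""
    cfg = CohortConfig(seed=1)
    counts, clinical, annotation, truth = es.generate_cohort(cfg)
    return dict(config=cfg, counts=counts, clinical=clinical,
                annotation=annotation, truth=truth)


@pytest.fixture(scope="session")
def normalized(cohort):
    kept, _ = es.filter_samples(cohort["clinical"])
    counts = cohort["counts"][kept]
    norm = es.normalize_log2(counts, es.size_factors(counts))
    selection = es.select_variable_epifactors(norm, cohort["annotation"])
    return dict(kept=kept, norm=norm, selection=selection,
                clinical=cohort["clinical"].loc[kept])


@pytest.fixture(scope="session")
def stratified(cohort, normalized):
    """Two-cluster consensus solution with aligned outcome signatures."""
    V = normalized["norm"].loc[normalized["selection"].genes]
    res = es.consensus_cluster(V, 2, n_runs=10, seed=0, max_iter=300, tol=1e-5)
    fit = es.nmf_factorize(V.to_numpy(), 2, seed=0, max_iter=300, tol=1e-5)
    sigs = es.align_signatures(es.extract_top_genes(fit.W, list(V.index)),
                               fit.H, res.labels)
    outcome, flagged = es.label_clusters_by_outcome(res.labels,
                                                    normalized["clinical"])
    sigs.outcome_labels = outcome
    return dict(V=V, consensus=res, fit=fit, signatures=sigs,
                outcome=outcome, outcome_flagged=flagged)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
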