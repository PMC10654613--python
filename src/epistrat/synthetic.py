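"""Synthetic tumor cohorts with planted expression programs and survival structure.

The generator emulates the statistical structure a bulk-expression
stratification analysis assumes: negative-binomial raw counts over a gene
panel that includes an annotated set of epifactor (chromatin-factor) genes,
two or more latent expression programs with planted signature genes, a
proliferation co-expression module anchored on a gene literally named
``PCNA``, censored survival endpoints whose hazard depends on program
membership, tumor-purity metadata, binary alteration tables, and a
single-cell matrix whose cells express program A, program B, both, or
neither. Ground-truth labels are returned alongside every artifact so
recovery of the planted structure can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, DataContractError

__all__ = [
    "CohortConfig",
    "TruthLabels",
    "COMPLEX_NAMES",
    "CATEGORIES",
    "generate_cohort",
    "generate_single_cell",
    "generate_alterations",
]

#: Closed vocabulary of 19 epigenetic multiprotein complexes.
COMPLEX_NAMES = (
    "PRC1", "PRC2", "NuRD", "SWI/SNF", "ISWI", "INO80", "NuA4", "SAGA",
    "COMPASS", "CoREST", "Sin3", "NCoR", "MOZ/MORF", "HBO1", "SRCAP",
    "PR-DUB", "ATAC", "SET1B", "MBD",
)

CATEGORIES = ("DNA modification", "histone modification", "chromatin remodeling", "other")
SUBROLES = ("writer", "eraser", "reader")
MARKS = ("acetylation", "methylation", "phosphorylation", "ubiquitination")

CELL_GROUPS = ("none", "A", "B", "both")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Sizes and rates default to a mid-sized tumor cohort: 200 samples, a
    3000-gene panel of which 720 are annotated epifactors, two latent
    programs of 40 signature genes each separated by a mean log2
    fold-change of 2, a 30-gene proliferation module co-expressed with
    PCNA, and exponential survival with a log hazard ratio of 0.7 for
    program-2 membership and ~40% independent censoring.
    """

    n_samples: int = 200
    n_genes: int = 3000
    n_epifactors: int = 720
    n_programs: int = 2
    signature_size: int = 40
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    libsize_range: tuple[float, float] = (0.5, 2.0)
    prolif_module_size: int = 30
    prolif_cor: float = 0.8
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    cluster_log_hr: float = 0.7
    censor_frac: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_epifactors, self.n_programs,
               self.signature_size, self.prolif_module_size) <= 0:
            raise ConfigurationError("all sizes must be positive integers")
        if self.n_epifactors > self.n_genes:
            raise ConfigurationError("n_epifactors cannot exceed n_genes")
        if self.signature_size * self.n_programs > self.n_epifactors:
            raise ConfigurationError(
                "infeasible role allocation: signature genes exceed the epifactor panel"
            )
        if self.prolif_module_size > self.n_genes - self.n_epifactors:
            raise ConfigurationError(
                "infeasible role allocation: proliferation module exceeds the "
                "non-epifactor panel"
            )
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be nonnegative")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigurationError("libsize_range must be a positive interval")
        if not 0 <= self.censor_frac < 1:
            raise ConfigurationError("censor_frac must lie in [0, 1)")
        if not 0 < self.prolif_cor < 1:
            raise ConfigurationError("prolif_cor must lie in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")


@dataclass
class TruthLabels:
    """Ground truth of a generated artifact.

    ``sample_program`` maps sample id -> 1-based program index;
    ``gene_role`` maps gene id -> ``signature_1``, ``signature_2``, ...,
    ``proliferation`` or ``background``; ``cell_group`` (single-cell
    outputs only) maps barcode -> one of none/A/B/both.
    """

    sample_program: pd.Series | None = None
    gene_role: pd.Series | None = None
    gene_complex: pd.Series | None = None
    gene_category: pd.Series | None = None
    cell_group: pd.Series | None = None

    def signature_genes(self, program: int) -> list[str]:
        if self.gene_role is None:
            raise DataContractError("no gene roles in these labels")
        return list(self.gene_role.index[self.gene_role == f"signature_{program}"])


# ---------------------------------------------------------------------------
# deterministic derivations shared by the generator entry points


def _streams(config: CohortConfig, replicate: int = 0) -> dict[str, np.random.Generator]:
    """Named RNG streams.

    Gene-level structure (signature placement, baselines, annotation) is a
    function of the seed alone; sample-level draws (program assignment,
    counts, survival, covariates, cells, alterations) additionally depend
    on ``replicate``, so ``replicate > 0`` yields held-out cohorts with the
    same planted gene structure but fresh samples.
    """
    gene_ss = np.random.SeedSequence(int(config.seed))
    gene_names = ("roles", "genes", "annotation")
    sample_ss = np.random.SeedSequence((int(config.seed), int(replicate)))
    sample_names = ("programs", "counts", "survival", "covariates", "cells",
                    "alterations")
    streams = {n: np.random.default_rng(c)
               for n, c in zip(gene_names, gene_ss.spawn(len(gene_names)))}
    streams.update({n: np.random.default_rng(c)
                    for n, c in zip(sample_names, sample_ss.spawn(len(sample_names)))})
    return streams


def _gene_ids(config: CohortConfig) -> list[str]:
    ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    # The proliferation anchor keeps its literal name; it is the first
    # non-epifactor gene (see _roles).
    ids[config.n_epifactors] = "PCNA"
    return ids


def _sample_ids(config: CohortConfig) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(config.n_samples)]


def _sample_programs(config: CohortConfig, replicate: int = 0) -> np.ndarray:
    """Balanced 0-based program assignment, deterministic in seed and replicate."""
    rng = _streams(config, replicate)["programs"]
    base = np.arange(config.n_samples) % config.n_programs
    return rng.permutation(base)


def _roles(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(signature_program, is_prolif) per gene index.

    ``signature_program`` is -1 for non-signature genes, else the 0-based
    program the gene marks. Signature genes are drawn from the epifactor
    block (indices < n_epifactors); the proliferation module occupies the
    first ``prolif_module_size`` non-epifactor indices, whose first member
    is PCNA.
    """
    rng = _streams(config)["roles"]
    sig_program = np.full(config.n_genes, -1, dtype=int)
    chosen = rng.choice(config.n_epifactors,
                        size=config.signature_size * config.n_programs,
                        replace=False)
    for q in range(config.n_programs):
        sig_program[chosen[q * config.signature_size:(q + 1) * config.signature_size]] = q
    is_prolif = np.zeros(config.n_genes, dtype=bool)
    is_prolif[config.n_epifactors:config.n_epifactors + config.prolif_module_size] = True
    return sig_program, is_prolif


def _baseline_params(config: CohortConfig, rng: np.random.Generator,
                     sig_program: np.ndarray, is_prolif: np.ndarray):
    """Per-gene log2 baseline, biological noise SD, effect and factor loading."""
    g = config.n_genes
    log2_base = rng.uniform(2.0, 9.0, size=g)
    bio_sd = rng.uniform(0.05, 0.9, size=g)
    # Signature genes: moderate within-program noise so the between-program
    # shift dominates; proliferation module: high baseline, low private noise
    # so the shared factor dominates the correlation with PCNA.
    bio_sd[sig_program >= 0] = 0.3
    log2_base[is_prolif] = 9.0
    bio_sd[is_prolif] = 0.05
    effect = np.zeros(g)
    nsig = int((sig_program >= 0).sum())
    effect[sig_program >= 0] = np.clip(
        rng.normal(config.effect_log2fc, 0.25 * config.effect_log2fc, size=nsig),
        0.25 * config.effect_log2fc, None)
    # Loading of module genes on the shared proliferation factor, sized so
    # the post-noise gene~PCNA correlation targets prolif_cor.  The count
    # noise on the log2 scale at mean mu is ~ sqrt(1/mu + disp)/ln 2.
    mu0 = 2.0 ** 9.0
    sigma_count = np.sqrt(1.0 / mu0 + config.nb_dispersion) / np.log(2.0)
    sigma_tot = np.hypot(sigma_count, 0.05)
    rho = np.sqrt(config.prolif_cor)  # gene-factor correlation target
    loading = np.zeros(g)
    loading[is_prolif] = sigma_tot * rho / np.sqrt(1.0 - rho * rho)
    return log2_base, bio_sd, effect, loading


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _censor_horizon(hazards: np.ndarray, censor_frac: float) -> float:
    """Upper bound of the uniform administrative censoring window.

    For exponential event times with rate h and C ~ U(0, cm), the censoring
    probability is E[(1 - exp(-h cm)) / (h cm)]; solve for the cohort mean.
    """

    def frac(cm: float) -> float:
        x = hazards * cm
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e-6
    while frac(hi) > censor_frac:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid configs
            break
    return float(brentq(lambda c: frac(c) - censor_frac, lo, hi))


# ---------------------------------------------------------------------------
# public generators


def generate_cohort(config: CohortConfig, replicate: int = 0):
    """Generate (counts, clinical, annotation, truth) for one bulk cohort.

    ``replicate`` re-draws every sample-level quantity while keeping the
    planted gene structure, giving held-out cohorts from the same
    population.

    Counts are negative-binomial with mean
    ``libsize_s * 2^(base_g + noise + effect_g * 1[g marks sample s's
    program] + loading_g * factor_s)``; survival times are exponential with
    hazard ``baseline_hazard * exp(cluster_log_hr * 1[program 2] + small
    age effect)`` under uniform administrative censoring; purity metadata
    are two Beta-distributed metrics in [0, 1].
    """
    config.validate()
    rngs = _streams(config, replicate)
    n, g = config.n_samples, config.n_genes
    gene_ids, sample_ids = _gene_ids(config), _sample_ids(config)
    program = _sample_programs(config, replicate)
    sig_program, is_prolif = _roles(config)
    log2_base, bio_sd, effect, loading = _baseline_params(
        config, rngs["genes"], sig_program, is_prolif)

    rng_c = rngs["counts"]
    libsize = rng_c.uniform(*config.libsize_range, size=n)
    factor = rng_c.normal(size=n)  # shared proliferation latent, per sample
    log2_mu = (log2_base[:, None]
               + bio_sd[:, None] * rng_c.normal(size=(g, n))
               + loading[:, None] * factor[None, :])
    member = (sig_program[:, None] >= 0) & (sig_program[:, None] == program[None, :])
    log2_mu = log2_mu + effect[:, None] * member
    mu = libsize[None, :] * np.exp2(log2_mu)
    counts = pd.DataFrame(_nb_draw(rng_c, mu, config.nb_dispersion),
                          index=gene_ids, columns=sample_ids)

    # covariates & purity
    rng_v = rngs["covariates"]
    age = np.clip(rng_v.normal(60.0, 10.0, size=n), 18.0, 90.0)
    sex = np.where(rng_v.random(n) < 0.5, "F", "M")
    purity_cpe = rng_v.beta(8.0, 2.0, size=n)
    purity_chat = rng_v.beta(6.0, 2.0, size=n)

    # survival: one exponential outcome per endpoint, shared hazard model
    rng_s = rngs["survival"]
    log_h = (np.log(config.baseline_hazard)
             + config.cluster_log_hr * (program == 1)
             + 0.1 * (age - 60.0) / 10.0)
    hazards = np.exp(log_h)
    clinical = pd.DataFrame({"sample_id": sample_ids})
    for endpoint in ("pfi", "dss", "os"):
        t = rng_s.exponential(1.0 / hazards)
        if config.censor_frac > 0:
            cm = _censor_horizon(hazards, config.censor_frac)
            c = rng_s.uniform(0.0, cm, size=n)
            clinical[f"time_{endpoint}"] = np.minimum(t, c)
            clinical[f"event_{endpoint}"] = (t <= c).astype(int)
        else:
            clinical[f"time_{endpoint}"] = t
            clinical[f"event_{endpoint}"] = 1
    clinical["age"] = age
    clinical["sex"] = sex
    clinical["purity_cpe"] = purity_cpe
    clinical["purity_chat"] = purity_chat
    clinical = clinical.set_index("sample_id", drop=False)

    annotation, gene_complex, gene_category = _annotation(config, rngs["annotation"])

    role = np.where(is_prolif, "proliferation", "background").astype(object)
    for q in range(config.n_programs):
        role[sig_program == q] = f"signature_{q + 1}"
    truth = TruthLabels(
        sample_program=pd.Series(program + 1, index=sample_ids, name="program"),
        gene_role=pd.Series(role, index=gene_ids, name="role"),
        gene_complex=gene_complex,
        gene_category=gene_category,
    )
    return counts, clinical, annotation, truth


def _annotation(config: CohortConfig, rng: np.random.Generator):
    """Epifactor annotation table with categories, subroles, marks, complexes."""
    gene_ids = _gene_ids(config)
    is_epi = np.zeros(config.n_genes, dtype=bool)
    is_epi[:config.n_epifactors] = True
    category = np.where(is_epi, rng.choice(CATEGORIES, size=config.n_genes,
                                           p=(0.2, 0.45, 0.25, 0.1)), "")
    subrole = np.where(is_epi & (rng.random(config.n_genes) < 0.7),
                       rng.choice(SUBROLES, size=config.n_genes), "")
    mark = np.where(is_epi & (rng.random(config.n_genes) < 0.5),
                    rng.choice(MARKS, size=config.n_genes, p=(0.35, 0.45, 0.1, 0.1)), "")
    membership: dict[str, list[str]] = {gid: [] for gid in gene_ids}
    for name in COMPLEX_NAMES:
        size = int(rng.integers(8, 31))
        for idx in rng.choice(config.n_epifactors, size=size, replace=False):
            membership[gene_ids[idx]].append(name)
    complexes = [";".join(membership[gid]) for gid in gene_ids]
    annotation = pd.DataFrame({
        "gene": gene_ids,
        "is_epifactor": is_epi,
        "category": category,
        "subrole": subrole,
        "mark": mark,
        "complexes": complexes,
    }).set_index("gene", drop=False)
    first = pd.Series([membership[gid][0] if membership[gid] else "" for gid in gene_ids],
                      index=gene_ids, name="complex")
    return annotation, first, pd.Series(category, index=gene_ids, name="category")


def generate_single_cell(config: CohortConfig, n_cells: int,
                         group_fracs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                         replicate: int = 0):
    """Generate a log-normalized single-cell matrix with four planted groups.

    Cells in group ``A`` over-express the program-1 signature genes, ``B``
    the program-2 genes, ``both`` both sets and ``none`` neither; the
    matrix holds log2(1 + depth-normalized counts), genes x cells.
    """
    config.validate()
    if n_cells < 4:
        raise DataContractError("n_cells must be at least 4")
    fracs = np.asarray(group_fracs, dtype=float)
    if fracs.shape != (4,) or np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("group_fracs must be 4 nonnegative values summing to 1")

    rng = _streams(config, replicate)["cells"]
    sizes = np.floor(fracs * n_cells).astype(int)
    for i in np.argsort(-(fracs * n_cells - sizes))[:n_cells - sizes.sum()]:
        sizes[i] += 1
    groups = np.repeat(np.arange(4), sizes)
    groups = rng.permutation(groups)

    gene_ids = _gene_ids(config)
    sig_program, _ = _roles(config)
    log2_base, _, effect, _ = _baseline_params(config, _streams(config)["genes"],
                                               sig_program, np.zeros(config.n_genes, bool))
    # scale bulk baselines down to sparse single-cell depth
    base_mean = np.exp2(log2_base - 7.0)
    up_a = (sig_program == 0)[:, None] & np.isin(groups, (1, 3))[None, :]
    up_b = (sig_program == 1)[:, None] & np.isin(groups, (2, 3))[None, :]
    mu = base_mean[:, None] * np.exp2(effect[:, None] * (up_a | up_b))
    depth = rng.uniform(0.5, 2.0, size=n_cells)
    counts = _nb_draw(rng, mu * depth[None, :], config.nb_dispersion).astype(float)
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    lognorm = np.log2(1.0 + 1e4 * counts / colsum[None, :])

    barcodes = [f"C{i + 1:05d}" for i in range(n_cells)]
    cells = pd.DataFrame(lognorm, index=gene_ids, columns=barcodes)
    truth = TruthLabels(
        gene_role=pd.Series(
            np.where(sig_program >= 0,
                     [f"signature_{q + 1}" if q >= 0 else "" for q in sig_program],
                     "background"),
            index=gene_ids, name="role"),
        cell_group=pd.Series([CELL_GROUPS[gi] for gi in groups], index=barcodes,
                             name="group"),
    )
    return cells, truth


def generate_alterations(config: CohortConfig,
                         freqs_by_cluster: Mapping[str, tuple[float, float]],
                         replicate: int = 0) -> pd.DataFrame:
    """Binary gene x sample alteration matrix.

    Each listed gene is altered independently in program-c samples with
    probability ``freqs_by_cluster[gene][c]``. Program assignment is the
    same as :func:`generate_cohort` for the same config.
    """
    config.validate()
    if config.n_programs != 2:
        raise ConfigurationError("alteration tables are defined for two programs")
    gene_ids = set(_gene_ids(config))
    for gene, fs in freqs_by_cluster.items():
        if gene not in gene_ids:
            raise DataContractError(f"unknown gene {gene!r}")
        if len(fs) != 2 or not all(0 <= f <= 1 for f in fs):
            raise ConfigurationError("alteration frequencies must lie in [0, 1]")
    program = _sample_programs(config, replicate)  # 0-based
    rng = _streams(config, replicate)["alterations"]
    sample_ids = _sample_ids(config)
    rows = {}
    for gene, (f1, f2) in freqs_by_cluster.items():
        p = np.where(program == 0, f1, f2)
        rows[gene] = (rng.random(config.n_samples) < p).astype(int)
    return pd.DataFrame(rows, index=sample_ids).T
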