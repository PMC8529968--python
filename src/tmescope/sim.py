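"""Synthetic data generators for the deconvolution / prognostic pipeline.

Everything downstream (reference building, deconvolution, gene-set scoring,
the association screen and the survival models) is exercised on data produced
here: negative-binomial single-cell pools with planted cell-type markers,
Dirichlet-proportioned pseudo-bulk mixtures built by resampling cells with
replacement, random gene-set collections, and bulk cohorts whose hazard
depends log-linearly on designated gene-set activations.

All generators are deterministic under a fixed seed and every ground truth
(proportions, marker assignments, latent risks) is returned alongside the
data so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsets import GeneSetCollection

__all__ = [
    "SCSimConfig",
    "CellPool",
    "MixtureTruth",
    "SurvCohortTruth",
    "ExprTemplate",
    "SurvivalCohort",
    "simulate_cell_pool",
    "simulate_mixtures",
    "simulate_gene_sets",
    "simulate_survival_cohort",
]


@dataclass
class SCSimConfig:
    """Parameters of the single-cell pool generator.

    ``marker_logfc`` is a natural-log fold change applied to each type's
    marker genes on top of a shared log-normal baseline profile.
    ``nb_dispersion`` is the negative-binomial dispersion phi in
    ``var = mu + phi * mu**2`` (phi = 0 degenerates to Poisson).
    ``libsize_range`` gives the low/high of a log-uniform draw of the target
    per-cell UMI total.  ``frac_qc_fail`` cells are built with a tiny library
    (~50 UMIs) so that they violate the downstream QC thresholds.
    """

    n_types: int = 15
    n_genes: int = 2000
    cells_per_type: int | list[int] = 150
    markers_per_type: int = 25
    marker_logfc: float = 2.0
    nb_dispersion: float = 0.3
    libsize_range: tuple[int, int] = (1000, 5000)
    frac_qc_fail: float = 0.0
    seed: int = 0

    def cells_per_type_list(self) -> list[int]:
        if np.isscalar(self.cells_per_type):
            return [int(self.cells_per_type)] * self.n_types
        return [int(c) for c in self.cells_per_type]

    def validate(self) -> None:
        cpt = self.cells_per_type_list()
        if self.n_types <= 0 or self.n_genes <= 0:
            raise ValueError("n_types and n_genes must be positive")
        if len(cpt) != self.n_types or any(c <= 0 for c in cpt):
            raise ValueError("cells_per_type must list a positive count per type")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be non-negative")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("not enough genes to host the requested markers")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo < hi):
            raise ValueError("libsize_range must satisfy 0 < low < high")
        if not 0.0 <= self.frac_qc_fail <= 1.0:
            raise ValueError("frac_qc_fail must lie in [0, 1]")


@dataclass
class CellPool:
    """A labeled single-cell count pool with its planted ground truth."""

    counts: pd.DataFrame          # genes x cells, non-negative integers
    labels: pd.Series             # cell id -> cell-type name
    types: list[str]              # declared type order
    truth: dict[str, list[str]]   # type -> planted marker gene ids
    qc_fail_cells: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.labels.index):
            raise ValueError("counts columns and labels index must align")
        unknown = set(self.labels) - set(self.types)
        if unknown:
            raise ValueError(f"labels outside declared type list: {sorted(unknown)}")


@dataclass
class MixtureTruth:
    """True Dirichlet proportions behind a set of pseudo-bulk mixtures."""

    proportions: pd.DataFrame     # samples x cell types, rows on the simplex
    cells_per_sample: int
    alpha: np.ndarray

    def __post_init__(self) -> None:
        rs = self.proportions.to_numpy().sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-12):
            raise ValueError("proportion rows must sum to 1")
        if (self.proportions.to_numpy() < 0).any():
            raise ValueError("proportions must be non-negative")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + phi*mu^2."""
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_cell_pool(config: SCSimConfig) -> CellPool:
    """Generate a labeled single-cell pool with planted marker genes.

    Each cell type shares a log-normal baseline expression profile; the
    type's markers get their mean multiplied by ``exp(marker_logfc)``.
    Counts are negative-binomial around ``libsize * profile``.  Exactly
    ``round(frac_qc_fail * n_cells)`` cells are given ~50 total UMIs so they
    fail both the minimum-UMI and minimum-expressed-genes QC thresholds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, T = config.n_genes, config.n_types
    cpt = config.cells_per_type_list()
    n_cells = sum(cpt)

    gene_ids = [f"G{i:05d}" for i in range(G)]
    types = [f"type{t:02d}" for t in range(T)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    # marker genes share one baseline so every type's marker block carries the
    # same total mass: the per-type normalization constant is then identical
    # and non-marker genes stay composition-neutral in pseudo-bulk
    m = config.markers_per_type
    n_marker_genes = m * T
    if n_marker_genes:
        base[:n_marker_genes] = np.median(base)
    profiles = np.tile(base, (T, 1))
    truth: dict[str, list[str]] = {}
    for t in range(T):
        idx = np.arange(t * m, (t + 1) * m)
        profiles[t, idx] *= np.exp(config.marker_logfc)
        truth[types[t]] = [gene_ids[i] for i in idx]
    profiles /= profiles.sum(axis=1, keepdims=True)

    lo, hi = config.libsize_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))

    n_fail = int(round(config.frac_qc_fail * n_cells))
    fail_idx = rng.choice(n_cells, size=n_fail, replace=False) if n_fail else np.array([], int)
    libsizes[fail_idx] = 50.0  # < 500 UMIs and necessarily < 200 expressed genes

    counts = np.empty((G, n_cells), dtype=np.int64)
    labels = []
    pos = 0
    for t in range(T):
        for _ in range(cpt[t]):
            mu = libsizes[pos] * profiles[t]
            counts[:, pos] = _nb_counts(rng, mu, config.nb_dispersion)
            labels.append(types[t])
            pos += 1

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    pool = CellPool(
        counts=pd.DataFrame(counts, index=gene_ids, columns=cell_ids),
        labels=pd.Series(labels, index=cell_ids, name="cell_type"),
        types=types,
        truth=truth,
        qc_fail_cells=[cell_ids[i] for i in sorted(fail_idx)],
    )
    return pool


def simulate_mixtures(
    pool: CellPool,
    n_samples: int,
    cells_per_sample: int,
    alpha: np.ndarray | list[float],
    seed: int = 0,
) -> tuple[pd.DataFrame, MixtureTruth]:
    """Build pseudo-bulk mixtures by resampling pool cells with replacement.

    Per sample: draw proportions from Dirichlet(alpha); allocate
    ``cells_per_sample`` cell draws to types by a multinomial on those
    proportions; within each type draw cells uniformly with replacement; the
    bulk profile is the column sum of the drawn cells' counts.
    """
    alpha = np.asarray(alpha, dtype=float)
    if pool.counts.shape[1] == 0:
        raise ValueError("empty cell pool")
    if alpha.ndim != 1 or len(alpha) != len(pool.types):
        raise ValueError("alpha must have one entry per cell type in the pool")
    if (alpha <= 0).any():
        raise ValueError("alpha entries must be positive")
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")

    rng = np.random.default_rng(seed)
    counts = pool.counts.to_numpy()
    type_cols = {t: np.flatnonzero((pool.labels == t).to_numpy()) for t in pool.types}
    for t, cols in type_cols.items():
        if len(cols) == 0:
            raise ValueError(f"cell type {t!r} has no cells in the pool")

    props = rng.dirichlet(alpha, size=n_samples)
    bulk = np.zeros((counts.shape[0], n_samples), dtype=np.int64)
    for s in range(n_samples):
        n_per_type = rng.multinomial(cells_per_sample, props[s])
        for t, n_t in zip(pool.types, n_per_type):
            if n_t == 0:
                continue
            cols = type_cols[t]
            draws = rng.multinomial(n_t, np.full(len(cols), 1.0 / len(cols)))
            bulk[:, s] += counts[:, cols] @ draws

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    bulk_df = pd.DataFrame(bulk, index=pool.gene_ids, columns=sample_ids)
    truth = MixtureTruth(
        proportions=pd.DataFrame(props, index=sample_ids, columns=pool.types),
        cells_per_sample=cells_per_sample,
        alpha=alpha,
    )
    return bulk_df, truth


def simulate_gene_sets(
    gene_ids: list[str],
    n_sets: int = 200,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    designated: dict[str, list[str]] | None = None,
) -> GeneSetCollection:
    """Random gene-set collection over ``gene_ids``, plus optional designated sets.

    Designated sets (e.g. the ones a survival cohort's hazard depends on) are
    included verbatim under their given names; the remaining sets are uniform
    draws without replacement within each set.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(gene_ids)):
        raise ValueError("invalid size_range for the given gene universe")
    sets: dict[str, list[str]] = {}
    if designated:
        for name, genes in designated.items():
            missing = set(genes) - set(gene_ids)
            if missing:
                raise ValueError(f"designated set {name!r} has unknown genes: {sorted(missing)[:5]}")
            sets[name] = list(genes)
    genes_arr = np.asarray(gene_ids)
    i = 0
    while len(sets) < n_sets:
        size = int(rng.integers(lo, hi + 1))
        members = list(genes_arr[rng.choice(len(genes_arr), size=size, replace=False)])
        name = f"RANDOM_SET_{i:05d}"
        i += 1
        if name not in sets:
            sets[name] = members
    return GeneSetCollection(sets=sets, source="tmescope.simulate_gene_sets")


@dataclass
class SurvCohortTruth:
    """Ground truth of a synthetic survival cohort.

    ``beta_true`` maps designated gene-set names to their log-hazard-ratio
    per unit of latent activation.  Survival times are exponential
    (Weibull shape 1) with scale ``baseline_scale``, so proportional hazards
    holds exactly.  Censoring is an independent exponential competing time
    calibrated so that roughly ``censor_rate`` of samples are censored.
    """

    beta_true: dict[str, float]
    baseline_scale: float = 1.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class ExprTemplate:
    """How to generate the cohort's expression matrix.

    With a ``pool``, bulk profiles are pseudo-bulk mixtures (so they can be
    deconvolved against an RGEP built from the same pool); without one, a
    standalone log-normal matrix over ``n_genes`` genes is used.  Designated
    gene sets' member genes are multiplied by ``exp(effect_size * a)`` where
    ``a`` is the per-sample latent activation; ``couple_to`` optionally ties
    a designated set's activation to a cell type's true proportion with
    correlation ``couple_strength`` (only meaningful with a pool).
    """

    pool: CellPool | None = None
    alpha: np.ndarray | list[float] | None = None
    cells_per_sample: int = 2000
    n_genes: int = 1500
    effect_size: float = 1.0
    couple_to: dict[str, str] = field(default_factory=dict)
    couple_strength: float = 0.8
    sample_noise_sigma: float = 0.2


@dataclass
class SurvivalCohort:
    bulk: pd.DataFrame            # genes x samples, linear scale
    survival: pd.DataFrame        # sample, time, event
    latent_risk: pd.Series        # true linear predictor per sample
    activations: pd.DataFrame     # samples x designated sets (latent truth)
    proportions: pd.DataFrame | None  # true mixture proportions if pool-based


def simulate_survival_cohort(
    n_samples: int,
    gene_sets: GeneSetCollection,
    truth: SurvCohortTruth,
    expr_template: ExprTemplate | None = None,
) -> SurvivalCohort:
    """Bulk cohort whose hazard is log-linear in designated gene-set activations.

    Per sample, each designated set gets a latent activation ``a`` (standard
    normal, optionally correlated with a cell-type proportion); its member
    genes' expression is scaled by ``exp(effect_size * a)``; event times are
    exponential with hazard proportional to ``exp(sum(beta * a))``.
    """
    truth.validate()
    tpl = expr_template or ExprTemplate()
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10 for a fittable cohort")
    missing = set(truth.beta_true) - set(gene_sets.sets)
    if missing:
        raise ValueError(f"designated gene sets absent from collection: {sorted(missing)}")

    rng = np.random.default_rng(truth.seed)
    props = None
    if tpl.pool is not None:
        alpha = tpl.alpha if tpl.alpha is not None else np.ones(len(tpl.pool.types))
        bulk, mix = simulate_mixtures(
            tpl.pool, n_samples, tpl.cells_per_sample, alpha,
            seed=int(rng.integers(2**31 - 1)),
        )
        bulk = bulk.astype(float)
        props = mix.proportions
    else:
        gene_ids = [f"G{i:05d}" for i in range(tpl.n_genes)]
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
        base = rng.lognormal(mean=2.0, sigma=1.0, size=(tpl.n_genes, 1))
        noise = rng.lognormal(mean=0.0, sigma=0.4, size=(tpl.n_genes, n_samples))
        bulk = pd.DataFrame(base * noise, index=gene_ids, columns=sample_ids)

    sample_ids = list(bulk.columns)
    activ = {}
    for name in truth.beta_true:
        a = rng.standard_normal(n_samples)
        ctype = tpl.couple_to.get(name)
        if ctype is not None:
            if props is None:
                raise ValueError("couple_to requires a pool-based template")
            v = props[ctype].to_numpy()
            v = (v - v.mean()) / v.std()
            c = tpl.couple_strength
            a = c * v + np.sqrt(max(0.0, 1 - c**2)) * a
        activ[name] = a
        members = [g for g in gene_sets.sets[name] if g in bulk.index]
        bulk.loc[members] = bulk.loc[members].to_numpy() * np.exp(tpl.effect_size * a)[None, :]

    if tpl.sample_noise_sigma > 0:
        # biological sample-to-sample variability on top of the sampling noise
        # of the pseudo-bulk construction
        noise = rng.lognormal(0.0, tpl.sample_noise_sigma, size=bulk.shape)
        bulk = bulk * noise

    activ_df = pd.DataFrame(activ, index=sample_ids)
    beta = np.array([truth.beta_true[k] for k in activ_df.columns])
    lp = activ_df.to_numpy() @ beta

    t_event = truth.baseline_scale * rng.exponential(1.0, n_samples) * np.exp(-lp)
    if truth.censor_rate > 0:
        lam_c = (truth.censor_rate / (1 - truth.censor_rate)) / truth.baseline_scale
        t_cens = rng.exponential(1.0 / lam_c, n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    surv = pd.DataFrame({"sample": sample_ids, "time": time, "event": event})
    return SurvivalCohort(
        bulk=bulk,
        survival=surv,
        latent_risk=pd.Series(lp, index=sample_ids, name="latent_risk"),
        activations=activ_df,
        proportions=props,
    )
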