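"""Synthetic single-cell populations and pseudo-bulk mixtures.

The generator emulates the statistical structure needed to exercise the
whole deconvolution stack without external data:

* per-cell-type expression profiles with disjoint marker-gene blocks and
  multiplicative log-normal cell-to-cell noise,
* a reserved *hidden* population (by default ~15% of sampled cells) that
  is excluded from the reference matrix and plays the role of an
  uncharacterised background (e.g. cancer cells absent from a healthy
  reference),
* pseudo-bulks formed by averaging 100 sampled cells each, and
* spiked cell-type-specific regulation: for selected (gene, cell type)
  pairs a factor ``a`` from {-1, -0.5, 1, 2} adds ``a * X_jk * C_ki`` to
  the bulk expression, so the implied ground-truth rescaling factor is
  ``Delta_jk = 1 + a``.

Every output is a deterministic function of the configuration and the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import normalize_columns

__all__ = [
    "ALLOWED_FACTORS",
    "CellPopulation",
    "RegulationSpec",
    "MixtureGroundTruth",
    "generate_population",
    "build_reference",
    "sample_mixtures",
    "select_specific_genes",
    "select_unspecific_genes",
    "make_regulation_spec",
    "spike_regulation",
]

#: admissible regulation factors (knockout, halving, doubling, tripling)
ALLOWED_FACTORS = (-1.0, -0.5, 1.0, 2.0)


@dataclass
class CellPopulation:
    """A bank of single-cell-like profiles with cell-type labels."""

    profiles: np.ndarray  #: (p, m) non-negative expression of m cells
    labels: np.ndarray  #: (m,) cell-type label per cell
    celltypes: list  #: declared cell-type names (known + hidden)
    hidden_celltypes: tuple  #: labels excluded from reference building
    gene_ids: list
    seed: int

    @property
    def known_celltypes(self) -> list:
        return [t for t in self.celltypes if t not in self.hidden_celltypes]


@dataclass
class RegulationSpec:
    """Spiked cell-type-specific regulation.

    ``entries`` holds ``(gene_index, celltype_index, factor)`` triples;
    one factor per (gene, type) pair shared across mixtures by default.
    In per-mixture mode ``factors_per_mixture`` holds one factor per
    entry and mixture and ``entries`` carries the mean factor.
    """

    entries: list = field(default_factory=list)
    per_mixture: bool = False
    factors_per_mixture: np.ndarray | None = None

    def __post_init__(self):
        for gene, ctype, a in self.entries:
            if a not in ALLOWED_FACTORS:
                raise ValueError(
                    f"factor {a} for gene {gene} not in {ALLOWED_FACTORS}"
                )

    def delta_true(self, p: int, q: int) -> np.ndarray:
        """Ground-truth rescaling matrix implied by the spike, 1 + a."""
        D = np.ones((p, q))
        for gene, ctype, a in self.entries:
            D[gene, ctype] = 1.0 + a
        return D

    def mask(self, p: int, q: int) -> np.ndarray:
        """Boolean (p, q) mask of spiked entries."""
        M = np.zeros((p, q), dtype=bool)
        for gene, ctype, _ in self.entries:
            M[gene, ctype] = True
        return M


@dataclass
class MixtureGroundTruth:
    C_true: np.ndarray  #: (q, n) known-type cell fractions
    hidden_true: np.ndarray  #: (n,) hidden-cell fraction per mixture
    x_true: np.ndarray  #: (p,) normalized mean profile of hidden cells
    regulation: RegulationSpec | None = None

    def __post_init__(self):
        total = self.C_true.sum(axis=0) + self.hidden_true
        if not np.allclose(total, 1.0, atol=1e-8):
            raise ValueError("known fractions + hidden fraction must sum to 1")


def generate_population(p: int, celltypes, cells_per_type: int = 100,
                        separation: float = 4.0, noise_dispersion: float = 0.5,
                        seed: int = 0, hidden_celltypes=(),
                        type_jitter: float = 1.5,
                        housekeeping_fraction: float = 0.2,
                        ambient_fraction: float = 0.02) -> CellPopulation:
    """Draw a labelled population of single-cell-like profiles.

    Each cell type receives a disjoint marker block (covering half the
    genes across all types) whose mean expression is elevated by a factor
    ``1 + separation`` over a shared log-normal baseline.  On top of the
    marker blocks every type carries genome-wide log-normal jitter of its
    mean (log-sd ``type_jitter``): real cell types differ broadly across
    the transcriptome, not only in marker genes, and without this a
    population left out of the reference would be expressible as a
    combination of the included types.  A ``housekeeping_fraction`` of
    genes (the last block of the gene space) is exempt from the jitter,
    emulating housekeeping genes whose expression is flat across cell
    types.  Every type mean is mixed with ``ambient_fraction`` of the
    across-type average profile, the ambient-RNA floor of droplet-based
    single-cell protocols; this bounds how small a reference entry can
    get relative to the gene's overall level.  Type means are normalized
    to sum
    to one so that cell-count fractions match expression-share
    compositions.  Cells are the type mean times gene-wise log-normal
    noise with unit mean and log-sd ``noise_dispersion``.
    """
    celltypes = list(celltypes)
    T = len(celltypes)
    if p < 10 * T:
        raise ValueError(f"need p >= 10 * n_types = {10 * T}, got {p}")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    hidden_celltypes = tuple(hidden_celltypes)
    for h in hidden_celltypes:
        if h not in celltypes:
            raise ValueError(f"hidden cell type {h!r} not in celltypes")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=p)
    block = p // (2 * T)
    means = np.empty((p, T))
    jitter = (rng.lognormal(mean=0.0, sigma=type_jitter, size=(p, T))
              if type_jitter > 0 else np.ones((p, T)))
    n_hk = int(round(housekeeping_fraction * p))
    if n_hk:
        jitter[p - n_hk:, :] = 1.0
    for t in range(T):
        mult = np.ones(p)
        mult[t * block:(t + 1) * block] = 1.0 + separation
        means[:, t] = base * mult * jitter[:, t]
    if ambient_fraction > 0:
        means = ((1.0 - ambient_fraction) * means
                 + ambient_fraction * means.mean(axis=1, keepdims=True))
    means /= means.sum(axis=0)
    profiles = []
    labels = []
    sigma = noise_dispersion
    for t, name in enumerate(celltypes):
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                              size=(p, cells_per_type)) if sigma > 0 else 1.0
        profiles.append(means[:, [t]] * noise * np.ones((p, cells_per_type)))
        labels.extend([name] * cells_per_type)
    return CellPopulation(
        profiles=np.concatenate(profiles, axis=1),
        labels=np.asarray(labels, dtype=object),
        celltypes=celltypes,
        hidden_celltypes=hidden_celltypes,
        gene_ids=[f"g{j:05d}" for j in range(p)],
        seed=seed,
    )


def build_reference(pop: CellPopulation) -> pd.DataFrame:
    """Average non-hidden cells per type and column-normalize.

    Hidden-labeled cells never contribute.  Raises if a known type has no
    cells.
    """
    cols = {}
    for name in pop.known_celltypes:
        idx = np.flatnonzero(pop.labels == name)
        if idx.size == 0:
            raise ValueError(f"cell type {name!r} has no cells")
        cols[name] = pop.profiles[:, idx].mean(axis=1)
    X = pd.DataFrame(cols, index=pop.gene_ids)
    return normalize_columns(X)


def sample_mixtures(pop: CellPopulation, n: int, cells_per_mixture: int = 100,
                    hidden_fraction_mean: float = 0.15, seed: int = 0,
                    composition_alpha: float = 1.0,
                    hidden_concentration: float = 20.0
                    ) -> tuple[pd.DataFrame, MixtureGroundTruth]:
    """Draw pseudo-bulk mixtures by averaging sampled cells.

    Per mixture, the hidden-cell probability is a Beta draw with mean
    ``hidden_fraction_mean`` and total concentration
    ``hidden_concentration`` (specimen-to-specimen variation in
    background abundance, as for tumor purity in real cohorts); the
    known-type probabilities are a Dirichlet draw (concentration
    ``composition_alpha``) scaled to the remainder.  Cells are then drawn
    multinomially, so the realised hidden fraction also carries the
    sampling noise of ``cells_per_mixture`` cells.  Each bulk column is
    the mean of its cells' profiles, then normalized to sum to one.
    ``hidden_concentration=inf`` fixes the per-mixture hidden probability
    at the population share (purely binomial realisations).

    Returns the bulk matrix and the ground truth (cell-count fractions,
    hidden fractions, and the normalized mean hidden profile).
    """
    rng = np.random.default_rng(seed)
    known = pop.known_celltypes
    qk = len(known)
    hidden_idx_all = np.flatnonzero(np.isin(pop.labels, pop.hidden_celltypes))
    if hidden_fraction_mean > 0 and hidden_idx_all.size == 0:
        raise ValueError("population has no hidden cells but "
                         "hidden_fraction_mean > 0")
    if not 0 <= hidden_fraction_mean < 1:
        raise ValueError("hidden_fraction_mean must be in [0, 1)")
    type_cells = {t: np.flatnonzero(pop.labels == t) for t in known}
    p = pop.profiles.shape[0]
    Y = np.empty((p, n))
    C_true = np.empty((qk, n))
    hidden_true = np.empty(n)
    hm = hidden_fraction_mean
    for i in range(n):
        d = rng.dirichlet(np.full(qk, composition_alpha))
        if hm > 0 and np.isfinite(hidden_concentration):
            hp = rng.beta(hm * hidden_concentration,
                          (1.0 - hm) * hidden_concentration)
        else:
            hp = hm
        probs = np.concatenate([(1.0 - hp) * d, [hp]])
        counts = rng.multinomial(cells_per_mixture, probs)
        drawn = []
        for t, name in enumerate(known):
            if counts[t]:
                drawn.append(rng.choice(type_cells[name], size=counts[t],
                                        replace=True))
        if counts[qk]:
            drawn.append(rng.choice(hidden_idx_all, size=counts[qk],
                                    replace=True))
        cells = np.concatenate(drawn)
        Y[:, i] = pop.profiles[:, cells].mean(axis=1)
        C_true[:, i] = counts[:qk] / cells_per_mixture
        hidden_true[i] = counts[qk] / cells_per_mixture
    Y = normalize_columns(Y)
    if hidden_idx_all.size:
        x_true = pop.profiles[:, hidden_idx_all].mean(axis=1)
        x_true = x_true / x_true.sum()
    else:
        x_true = np.zeros(p)
    Ydf = pd.DataFrame(Y, index=pop.gene_ids,
                       columns=[f"mix{i:05d}" for i in range(n)])
    return Ydf, MixtureGroundTruth(C_true=C_true, hidden_true=hidden_true,
                                   x_true=x_true)


def select_specific_genes(X, top_per_type: int = 20) -> dict:
    """Most cell-type-specific genes per type.

    For each type ``k`` genes where ``k`` attains the row maximum are
    ranked by ``X_jk / mean(X_j, .)`` (ties broken by ascending gene
    index) and the ``top_per_type`` best are returned, as a mapping from
    type index to gene indices.
    """
    V = np.asarray(X, dtype=float)
    p, q = V.shape
    mean = V.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = V / mean[:, None]
    argmax = V.argmax(axis=1)
    pools = {}
    for k in range(q):
        cand = np.flatnonzero((argmax == k) & (mean > 0))
        order = np.lexsort((cand, -ratio[cand, k]))
        pools[k] = cand[order][:top_per_type]
    return pools


def select_unspecific_genes(X, pool_size: int = 120) -> np.ndarray:
    """Genes least specific across types: smallest var/mean over the row.

    Genes with zero row mean are excluded; ties broken by gene index.
    """
    V = np.asarray(X, dtype=float)
    mean = V.mean(axis=1)
    var = V.var(axis=1)
    ok = np.flatnonzero(mean > 0)
    score = var[ok] / mean[ok]
    order = np.lexsort((ok, score))
    return ok[order][:pool_size]


def make_regulation_spec(X, n_specific: int = 30, n_unspecific: int = 30,
                         top_per_type: int = 20, unspecific_pool_size: int = 120,
                         factors=ALLOWED_FACTORS, seed: int = 0,
                         per_mixture: bool = False, n_mixtures: int | None = None
                         ) -> RegulationSpec:
    """Randomly assemble a regulation spike.

    Draws ``n_specific`` genes from the union of per-type specific pools
    (each spiked in the type it marks) and ``n_unspecific`` genes from
    the unspecific pool (each spiked in the type expressing it most: a
    multiplicative regulation factor is only meaningful for a type that
    expresses the gene, and for flat genes the arg-max type is
    arbitrary); every chosen gene receives a factor drawn uniformly from
    ``factors``.  Genes are drawn without replacement across both groups.
    """
    rng = np.random.default_rng(seed)
    V = np.asarray(X, dtype=float)
    q = V.shape[1]
    spec_pools = select_specific_genes(V, top_per_type)
    spec_pairs = [(int(gj), k) for k, genes in spec_pools.items() for gj in genes]
    unspec = [int(j) for j in select_unspecific_genes(V, unspecific_pool_size)]
    factors = np.asarray(factors, dtype=float)

    entries = []
    used = set()
    if spec_pairs:
        order = rng.permutation(len(spec_pairs))
        for idx in order:
            gj, k = spec_pairs[idx]
            if gj in used:
                continue
            entries.append((gj, k, float(rng.choice(factors))))
            used.add(gj)
            if len(entries) >= n_specific:
                break
    unspec = [j for j in unspec if j not in used]
    m = min(n_unspecific, len(unspec))
    argmax = V.argmax(axis=1)
    for gj in rng.choice(np.asarray(unspec), size=m, replace=False) if m else []:
        entries.append((int(gj), int(argmax[gj]), float(rng.choice(factors))))
    spec = RegulationSpec(entries=entries, per_mixture=per_mixture)
    if per_mixture:
        if n_mixtures is None:
            raise ValueError("per-mixture mode needs n_mixtures")
        spec.factors_per_mixture = rng.choice(factors,
                                              size=(len(entries), n_mixtures))
    return spec


def spike_regulation(Y, X, C_true, spec: RegulationSpec):
    """Apply cell-type-specific regulation to bulk mixtures.

    For every entry ``(j, k, a)``, ``a * X_jk * C_true_ki`` is added to
    ``Y_ji`` for all mixtures ``i`` and negative results are clamped to
    zero.  ``Y`` is *not* re-normalized afterwards, so the implied
    ground-truth rescaling ``Delta_jk = 1 + a`` is preserved exactly.
    """
    values = np.asarray(Y, dtype=float).copy()
    V = np.asarray(X, dtype=float)
    C = np.asarray(C_true, dtype=float)
    for e, (gj, k, a) in enumerate(spec.entries):
        if spec.per_mixture and spec.factors_per_mixture is not None:
            amounts = spec.factors_per_mixture[e] * V[gj, k] * C[k]
        else:
            amounts = a * V[gj, k] * C[k]
        values[gj] = np.maximum(0.0, values[gj] + amounts)
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(values, index=Y.index, columns=Y.columns)
    return values
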