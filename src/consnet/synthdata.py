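"""Synthetic multi-dataset, two-condition RNA-seq study generator.

Emulates the study design the pipeline targets: several independent bulk
RNA-seq datasets per brain region, each with a case ("B") and a control ("A")
group, gene co-expression organised into latent modules, a configurable
fraction of modules rewired between conditions, and lncRNAs embedded in
modules whose protein-coding members carry a known functional category.
Every downstream stage therefore has a recoverable ground truth.

Generative model
----------------
Each module m has a per-(dataset, condition) eigengene ``E_m ~ N(0, 1)``
across samples. Gene g in module m has a signed loading ``l_g`` with
``|l_g| = sqrt(within_module_cor)`` so two member genes have latent
correlation ``l_i * l_j`` (negative loadings create negative links; the
downstream networks are signed). The latent log-mean is

    log mu_gs = base_g + latent_scale * (l_g E_ms + sqrt(1 - l_g^2) eps_gs)

and counts are negative-binomial with mean ``s_j * mu_gs`` (log-normal
library-size factors ``s_j``) and constant dispersion (variance
``mu + dispersion * mu^2``).

Rewiring: in condition B a rewired module's genes split into thirds —
loadings kept (conserved links), sign-flipped (reversed links), and detached
to pure noise (condition-specific links) — planting all three differential
link categories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneCatalog

__all__ = ["SynthConfig", "GroundTruth", "generate_study",
           "plant_differential_expression"]


@dataclass
class SynthConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror a desk-scale version of a three-datasets-per-region,
    two-condition brain cohort with ~40 samples per group.
    """

    n_genes: int = 300
    frac_lncrna: float = 0.15
    n_modules: int = 4
    module_sizes: list[int] = field(default_factory=lambda: [70] * 4)
    n_datasets_per_condition: int = 3
    n_samples: int = 40              # per dataset per condition
    rewired_module_fraction: float = 0.25
    within_module_cor: float = 0.9   # latent correlation between members
    neg_loading_frac: float = 0.25   # fraction of members with negative loading
    nb_dispersion: float = 0.08
    mean_log_expression: float = 6.5  # natural-log mean count scale
    gene_log_sd: float = 1.0         # spread of per-gene baseline expression
    latent_scale: float = 1.5        # amplitude of the eigengene in log-mean
    libsize_sigma: float = 0.2       # log-normal sd of library-size factors
    region: str = "CTX"
    seed: int = 0

    def validate(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        for f in (self.frac_lncrna, self.rewired_module_fraction,
                  self.within_module_cor, self.neg_loading_frac):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_genes, self.n_modules, self.n_datasets_per_condition,
               self.n_samples, *self.module_sizes) < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the generated study."""

    module_of: dict[str, int | None]
    lncrna_category_of: dict[str, set[str]]
    rewired_modules: set[int]
    de_genes: dict[str, float] = field(default_factory=dict)

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; Poisson when dispersion~0."""
    if dispersion < 1e-9:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _orthogonal_eigengenes(rng: np.random.Generator, n_modules: int,
                           n_samples: int) -> np.ndarray:
    """Module eigengenes, mutually orthogonal in-sample, unit variance.

    With iid Gaussian eigengenes the chance correlation between two modules'
    eigengenes (sd ~ 1/sqrt(n_samples)) leaks into every member pair's wTO
    denominator and can mask the planted structure at realistic sample
    sizes; orthogonalizing removes that nuisance mode so ground truth stays
    recoverable. Real co-expression modules are of course not orthogonal —
    a documented simplification of the generator.
    """
    q, _ = np.linalg.qr(rng.standard_normal((n_samples, n_modules)))
    return (q * math.sqrt(n_samples)).T


def _loadings(rng: np.random.Generator, size: int, cfg: SynthConfig) -> np.ndarray:
    mag = math.sqrt(cfg.within_module_cor)
    signs = np.where(rng.random(size) < cfg.neg_loading_frac, -1.0, 1.0)
    return mag * signs


def generate_study(cfg: SynthConfig):
    """Generate one CountMatrix per (dataset, condition) plus truth.

    Returns
    -------
    (counts, catalog, category_sets, truth)
        ``counts`` is a list of :class:`CountMatrix` (all datasets x both
        conditions), ``catalog`` a :class:`GeneCatalog`, ``category_sets``
        maps each module's category label to its protein-coding members, and
        ``truth`` is the :class:`GroundTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    # module assignment: first sum(module_sizes) genes, in blocks
    module_of: dict[str, int | None] = {g: None for g in genes}
    pos = 0
    members: dict[int, list[str]] = {}
    for m, size in enumerate(cfg.module_sizes):
        members[m] = genes[pos:pos + size]
        for g in members[m]:
            module_of[g] = m
        pos += size

    # biotype: fixed count of lncRNAs per module (>=1), plus background draws
    biotype = {}
    lnc_truth: dict[str, set[str]] = {}
    category_sets: dict[str, set[str]] = {}
    for m, mem in members.items():
        n_lnc = max(1, round(cfg.frac_lncrna * len(mem)))
        lnc_idx = rng.choice(len(mem), size=n_lnc, replace=False)
        lnc = {mem[i] for i in lnc_idx}
        cat = f"category_m{m}"
        pc = [g for g in mem if g not in lnc]
        category_sets[cat] = set(pc)
        for g in mem:
            biotype[g] = "lncRNA" if g in lnc else "protein_coding"
        for g in lnc:
            lnc_truth[g] = {cat}
    for g in genes[pos:]:
        biotype[g] = "lncRNA" if rng.random() < cfg.frac_lncrna else "protein_coding"
    catalog = GeneCatalog(pd.Series(biotype).reindex(genes))

    n_rewired = round(cfg.rewired_module_fraction * cfg.n_modules)
    rewired = set(rng.choice(cfg.n_modules, size=n_rewired, replace=False).tolist())

    # per-gene loadings, condition A; condition B re-derived for rewired modules
    load_a = np.zeros(cfg.n_genes)
    load_b = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for m, mem in members.items():
        idx = np.array([gene_pos[g] for g in mem])
        la = _loadings(rng, len(mem), cfg)
        load_a[idx] = la
        if m in rewired:
            lb = la.copy()
            perm = rng.permutation(len(mem))
            third = max(1, len(mem) // 3)
            lb[perm[third:2 * third]] *= -1.0       # reversed links
            lb[perm[2 * third:]] = 0.0              # condition-specific links
            load_b[idx] = lb
        else:
            load_b[idx] = la

    base = cfg.mean_log_expression + cfg.gene_log_sd * rng.standard_normal(cfg.n_genes)

    matrices: list[CountMatrix] = []
    for d in range(cfg.n_datasets_per_condition):
        for cond, load in (("A", load_a), ("B", load_b)):
            eig = _orthogonal_eigengenes(rng, cfg.n_modules, cfg.n_samples)
            eps = rng.standard_normal((cfg.n_genes, cfg.n_samples))
            z = np.empty((cfg.n_genes, cfg.n_samples))
            for i, g in enumerate(genes):
                m = module_of[g]
                l = load[i] if m is not None else 0.0
                e = eig[m] if m is not None else 0.0
                z[i] = l * e + math.sqrt(max(0.0, 1.0 - l * l)) * eps[i]
            mu = np.exp(base[:, None] + cfg.latent_scale * z)
            sf = np.exp(cfg.libsize_sigma * rng.standard_normal(cfg.n_samples))
            counts = _nb_counts(rng, mu * sf[None, :], cfg.nb_dispersion)
            samples = [f"d{d}_{cond}_s{j:03d}" for j in range(cfg.n_samples)]
            matrices.append(CountMatrix(
                pd.DataFrame(counts, index=genes, columns=samples),
                dataset_id=f"ds{d}", condition=cond, region=cfg.region))

    truth = GroundTruth(module_of=module_of, lncrna_category_of=lnc_truth,
                        rewired_modules=rewired)
    return matrices, catalog, category_sets, truth


def plant_differential_expression(truth: GroundTruth, counts: CountMatrix,
                                  effects: dict[str, float],
                                  seed: int = 0) -> CountMatrix:
    """Scale per-gene means by 2**effect via stochastic rounding.

    Multiplying a negative-binomial count by a constant scales its mean by
    that constant and leaves the dispersion (squared CV in excess of
    Poisson) unchanged; the fractional remainder is resolved by a Bernoulli
    draw so counts stay integral and the mean scaling stays exact. Effects
    are recorded on ``truth.de_genes`` (log2 scale, positive = up in this
    matrix's condition).
    """
    unknown = set(effects) - set(counts.genes)
    if unknown:
        raise ValueError(f"effects refer to unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    out = counts.counts.copy()
    for g, eff in effects.items():
        truth.de_genes[g] = eff
        if eff == 0:
            continue
        scaled = out.loc[g].to_numpy(dtype=float) * (2.0 ** eff)
        floor = np.floor(scaled)
        out.loc[g] = (floor + (rng.random(scaled.shape) < scaled - floor)).astype(int)
    return CountMatrix(out, counts.dataset_id, counts.condition, counts.region)
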