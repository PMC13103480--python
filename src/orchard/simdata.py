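"""Synthetic multi-collection genotypes and phenotypes.

The genotype generator emulates several partially admixed germplasm
collections (default: three, sized 225/224/161 like the Australian, Chinese
and US mango panels) using a Li–Stephens-style haplotype-copying model: each
sampled haplotype is a mosaic of ancestral-pool haplotypes, with a
per-collection switch rate per bp. A larger switch rate produces shorter
copied segments and therefore faster within-collection LD decay — the single
knob the downstream diversity analyses need. A configurable number of clone
pairs is duplicated across two collections.

The phenotype generator realises the additive multi-environment model

    y = mu_c + g_{c,i} + e,   g_c = X beta_c,
    beta_c = sqrt(1-f) beta_shared + sqrt(f) delta_c,

so a collection-specific genetic-variance fraction ``f`` is equivalent to a
cross-collection genetic correlation of 1-f. Residual noise is calibrated per
collection so the within-collection heritability hits its target. One trait
may be recorded through a "max of k fruits" (or "mean of k fruits") protocol:
per-fruit values add within-tree noise with a configurable coefficient of
variation, which makes a max-of-k recorder a biased, low-heritability
measurement — the in-silico analogue of the Chinese fruit-weight protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable

__all__ = [
    "SimGenoConfig",
    "PhenoSimConfig",
    "Protocol",
    "TrueValues",
    "SimGenoResult",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_protocol",
    "inject_missing",
    "load_config",
]


@dataclass
class SimGenoConfig:
    """Configuration of the haplotype-mosaic genotype simulator.

    Defaults reproduce the study layout: three collections of 225/224/161
    individuals, 20 clone pairs shared between the first and third
    collections, and a faster copying-switch rate (hence faster LD decay) in
    the second collection.
    """

    collection_sizes: tuple = (225, 224, 161)
    collection_names: tuple | None = None
    n_chromosomes: int = 20
    markers_per_chromosome: int = 500
    chromosome_length_bp: int = 20_000_000
    ancestral_pools: int = 3
    haplotypes_per_pool: int = 4
    pool_fst: float = 0.15
    admixture_concentration: tuple | float = 1.0
    copying_switch_rate_per_bp: tuple | float | None = None
    clone_pairs: int = 0
    clone_collections: tuple | None = None
    missing_rate: float = 0.0
    ensure_polymorphic: bool = True
    seed: int = 0

    @classmethod
    def study_default(cls, **overrides) -> "SimGenoConfig":
        """The three-collection study layout: 225/224/161 individuals, 20
        clone pairs between the first and third collections, faster LD decay
        in the second."""
        base = dict(
            collection_sizes=(225, 224, 161),
            collection_names=("AUS", "CHN", "USA"),
            copying_switch_rate_per_bp=(2e-7, 6e-7, 2e-7),
            clone_pairs=20,
            clone_collections=("AUS", "USA"),
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        self.collection_sizes = tuple(int(s) for s in self.collection_sizes)
        if any(s <= 0 for s in self.collection_sizes):
            raise ValueError("collection sizes must be positive")
        c = len(self.collection_sizes)
        if self.collection_names is None:
            self.collection_names = tuple(f"pop{i + 1}" for i in range(c))
        if len(self.collection_names) != c:
            raise ValueError("one name per collection required")
        if self.copying_switch_rate_per_bp is None:
            self.copying_switch_rate_per_bp = 2e-7
        if self.clone_collections is None:
            self.clone_collections = (
                self.collection_names[0],
                self.collection_names[-1],
            )
        self.admixture_concentration = _per_collection(
            self.admixture_concentration, c, "admixture_concentration"
        )
        self.copying_switch_rate_per_bp = _per_collection(
            self.copying_switch_rate_per_bp, c, "copying_switch_rate_per_bp"
        )
        if any(a <= 0 for a in self.admixture_concentration):
            raise ValueError("admixture concentrations must be positive")
        if any(r <= 0 for r in self.copying_switch_rate_per_bp):
            raise ValueError("copying switch rates must be positive")
        if min(self.n_chromosomes, self.markers_per_chromosome) <= 0:
            raise ValueError("chromosome/marker counts must be positive")
        if self.chromosome_length_bp <= self.markers_per_chromosome:
            raise ValueError("chromosome too short for requested marker count")
        if self.ancestral_pools <= 0 or self.haplotypes_per_pool <= 0:
            raise ValueError("ancestral pool sizes must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.clone_pairs < 0:
            raise ValueError("clone_pairs must be non-negative")
        if self.clone_pairs:
            for name in self.clone_collections:
                if name not in self.collection_names:
                    raise ValueError(f"clone collection {name!r} not a collection")
            sizes = dict(zip(self.collection_names, self.collection_sizes))
            cap = min(sizes[n] for n in self.clone_collections)
            if self.clone_pairs > cap:
                raise ValueError("clone_pairs exceeds linked collection size")


def _per_trait(value, t, name):
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, t)
    if arr.size != t:
        raise ValueError(f"{name} must be scalar or one value per trait")
    return tuple(float(v) for v in arr)


def _per_collection(value, c, name):
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, c)
    if arr.size != c:
        raise ValueError(f"{name} must be scalar or one value per collection")
    return tuple(float(v) for v in arr)


@dataclass
class Protocol:
    """Recording protocol for a repeat-measured trait: mean or max of k draws."""

    kind: str = "mean_of_k"
    k: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("mean_of_k", "max_of_k"):
            raise ValueError("protocol kind must be 'mean_of_k' or 'max_of_k'")
        if self.k < 1:
            raise ValueError("protocol k must be >= 1")


@dataclass
class PhenoSimConfig:
    trait_names: tuple = ("FW", "TSS")
    h2_targets: tuple = (0.9, 0.7)
    genetic_correlation_target: np.ndarray | None = None
    n_causal: int = 200
    gxe_variance_fraction: float = 0.1
    environment_means: np.ndarray | None = None  # (collections x traits)
    genetic_sd: tuple | float = 1.0
    protocols: dict = field(default_factory=dict)  # trait -> Protocol | {collection: Protocol}
    within_tree_cv: float = 0.15
    within_tree_skew: float = 0.0  # lognormal shape of per-fruit noise; 0 = normal
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        self.h2_targets = _per_trait(self.h2_targets, t, "h2_targets")
        self.genetic_sd = _per_trait(self.genetic_sd, t, "genetic_sd")
        if any(not (0 < h <= 1) for h in self.h2_targets):
            raise ValueError("h2 targets must be in (0, 1]")
        if self.genetic_correlation_target is None:
            self.genetic_correlation_target = np.eye(t)
        R = np.asarray(self.genetic_correlation_target, dtype=float)
        if R.shape != (t, t) or not np.allclose(R, R.T):
            raise ValueError("correlation target must be a symmetric t x t matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation target must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation target is not positive semidefinite")
        self.genetic_correlation_target = R
        if not (0 <= self.gxe_variance_fraction < 1):
            raise ValueError("gxe_variance_fraction must be in [0, 1)")
        if self.n_causal <= 0:
            raise ValueError("n_causal must be positive")


@dataclass
class TrueValues:
    """Ground truth recorded by the phenotype simulator for recovery tests."""

    breeding_values: np.ndarray  # (n, t) under each individual's own collection
    collection_breeding_values: dict  # collection -> (n, t) under that collection
    collection_deviations: np.ndarray  # (n, t) collection-specific genetic part
    causal_effects: dict  # collection -> (n_causal, t)
    causal_markers: np.ndarray
    realized_h2: np.ndarray  # (t,)


@dataclass
class SimGenoResult:
    genotypes: GenotypeMatrix
    labels: np.ndarray  # collection label per individual
    clone_map: list  # (id_in_first, id_in_second) pairs

    def __iter__(self):  # allow geno, labels = simulate_genotypes(...)
        return iter((self.genotypes, self.labels, self.clone_map))


def _chromosome_positions(rng, n_chrom, m_per_chrom, length):
    positions, chroms = [], []
    for c in range(n_chrom):
        pos = np.sort(
            rng.choice(np.int64(length - 1), size=m_per_chrom, replace=False) + 1
        )
        positions.append(pos)
        chroms.append(np.full(m_per_chrom, f"chr{c + 1}", dtype=object))
    return np.concatenate(chroms), np.concatenate(positions)


def simulate_genotypes(config: SimGenoConfig) -> SimGenoResult:
    """Draw phased genotypes for all collections under the copying model."""
    rng = np.random.default_rng(config.seed)
    P, H = config.ancestral_pools, config.haplotypes_per_pool
    n_chrom, m_c, L = (
        config.n_chromosomes,
        config.markers_per_chromosome,
        config.chromosome_length_bp,
    )
    m = n_chrom * m_c
    chroms, positions = _chromosome_positions(rng, n_chrom, m_c, L)

    # Ancestral pools: Balding-Nichols divergence around a common base frequency.
    base = rng.uniform(0.1, 0.9, size=m)
    f = config.pool_fst
    a, b = base * (1 - f) / f, (1 - base) * (1 - f) / f
    pool_freq = rng.beta(a, b, size=(P, m))
    anc = (rng.uniform(size=(P * H, m)) < np.repeat(pool_freq, H, axis=0)).astype(
        np.int8
    )

    n_total = sum(config.collection_sizes)
    haplotypes = np.empty((n_total, 2, m), dtype=np.int8)
    labels = np.empty(n_total, dtype=object)
    ids = np.empty(n_total, dtype=object)
    chrom_slices = [slice(c * m_c, (c + 1) * m_c) for c in range(n_chrom)]
    marker_idx = np.arange(m_c)

    row = 0
    for name, size, conc, rho in zip(
        config.collection_names,
        config.collection_sizes,
        config.admixture_concentration,
        config.copying_switch_rate_per_bp,
    ):
        for i in range(size):
            pi = rng.dirichlet(np.full(P, conc))
            for h in range(2):
                for sl in chrom_slices:
                    pos = positions[sl]
                    n_seg = 1 + rng.poisson(rho * L)
                    if n_seg > 1:
                        breaks = np.sort(rng.uniform(0, L, n_seg - 1))
                        seg = np.searchsorted(breaks, pos)
                    else:
                        seg = np.zeros(m_c, dtype=int)
                    pools = rng.choice(P, size=n_seg, p=pi)
                    which = rng.integers(0, H, size=n_seg)
                    anc_rows = pools * H + which
                    haplotypes[row, h, sl] = anc[anc_rows[seg], marker_idx]
            labels[row] = name
            ids[row] = f"{name}_{i:04d}"
            row += 1

    # clone targets are overwritten below, so the polymorphic fix avoids them
    clone_src = clone_tgt = np.array([], dtype=int)
    if config.clone_pairs:
        name_a, name_b = config.clone_collections
        clone_src = np.where(labels == name_a)[0][: config.clone_pairs]
        clone_tgt = np.where(labels == name_b)[0][: config.clone_pairs]

    if config.ensure_polymorphic:
        totals = haplotypes.sum(axis=(0, 1))
        mono = np.where((totals == 0) | (totals == 2 * n_total))[0]
        allowed = np.setdiff1d(np.arange(n_total), clone_tgt)
        for j in mono:
            i = allowed[rng.integers(0, len(allowed))]
            h = rng.integers(0, 2)
            haplotypes[i, h, j] = 1 - haplotypes[i, h, j]

    geno = GenotypeMatrix(
        dosages=haplotypes.sum(axis=1).astype(float),
        individual_ids=ids,
        chromosome=chroms,
        position_bp=positions,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        haplotypes=haplotypes,
    )
    if config.missing_rate > 0:
        geno = inject_missing(
            geno, config.missing_rate, seed=int(rng.integers(2**31))
        )

    clone_map = []
    if config.clone_pairs:
        geno.dosages[clone_tgt] = geno.dosages[clone_src]
        if geno.haplotypes is not None:
            geno.haplotypes[clone_tgt] = geno.haplotypes[clone_src]
        clone_map = [(ids[i], ids[j]) for i, j in zip(clone_src, clone_tgt)]
    return SimGenoResult(geno, labels, clone_map)


def inject_missing(geno: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Mask each call independently with probability ``rate`` (seeded)."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must be in [0, 1)")
    if rate == 0:
        return geno
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=geno.dosages.shape) < rate
    dosages = geno.dosages.copy()
    dosages[mask] = np.nan
    haplotypes = geno.haplotypes
    if haplotypes is not None:
        haplotypes = haplotypes.copy()
        haplotypes.transpose(0, 2, 1)[mask] = -1
    return replace(geno, dosages=dosages, haplotypes=haplotypes)


def apply_protocol(per_unit_draws, protocol, k: int | None = None) -> float:
    """Record a trait value from repeated per-unit (per-fruit) measurements."""
    if isinstance(protocol, Protocol):
        kind, k = protocol.kind, protocol.k if k is None else k
    else:
        kind = protocol
        if kind not in ("mean_of_k", "max_of_k"):
            raise ValueError("protocol must be 'mean_of_k' or 'max_of_k'")
        if k is None:
            raise ValueError("k required when protocol is given as a string")
    draws = np.asarray(per_unit_draws, dtype=float)
    if draws.size < k:
        raise ValueError(f"need at least k={k} draws, got {draws.size}")
    head = draws[:k]
    return float(head.mean() if kind == "mean_of_k" else head.max())


def _fruit_noise(rng, shape, skew: float) -> np.ndarray:
    """Unit-variance, zero-mean per-fruit noise.

    ``skew`` > 0 uses a standardized lognormal: fruit-size distributions on a
    tree are right-skewed, which is what makes a max-of-k recorder latch onto
    erratic tail draws.
    """
    if skew <= 0:
        return rng.standard_normal(shape)
    z = rng.lognormal(0.0, skew, size=shape)
    mean = np.exp(skew**2 / 2)
    sd = np.sqrt((np.exp(skew**2) - 1) * np.exp(skew**2))
    return (z - mean) / sd


def _resolve_protocol(config: PhenoSimConfig, trait, collection) -> Protocol | None:
    spec = config.protocols.get(trait)
    if spec is None:
        return None
    if isinstance(spec, Protocol):
        return spec
    return spec.get(collection)


def simulate_phenotypes(
    geno: GenotypeMatrix, labels, config: PhenoSimConfig
):
    """Simulate phenotypes on top of a genotype panel.

    Returns a :class:`PhenotypeTable` (one record per individual, collection
    and trait) and the :class:`TrueValues` ground truth.
    """
    rng = np.random.default_rng(config.seed)
    labels = np.asarray(labels, dtype=object)
    collections = list(dict.fromkeys(labels))
    X = geno.dosages
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    X = X - X.mean(axis=0)

    t = len(config.trait_names)
    R = config.genetic_correlation_target
    Lc = np.linalg.cholesky(R + 1e-12 * np.eye(t))
    n_causal = min(config.n_causal, geno.n_markers)
    causal = rng.choice(geno.n_markers, size=n_causal, replace=False)
    Xc = X[:, causal]

    fgxe = config.gxe_variance_fraction
    beta_shared = rng.standard_normal((n_causal, t)) @ Lc.T
    causal_effects, coll_bv = {}, {}
    for c in collections:
        delta = rng.standard_normal((n_causal, t)) @ Lc.T
        causal_effects[c] = np.sqrt(1 - fgxe) * beta_shared + np.sqrt(fgxe) * delta

    # Scale each trait so the pooled genetic SD equals its target.
    g_own = np.empty((len(labels), t))
    for c in collections:
        rows = labels == c
        g_own[rows] = Xc[rows] @ causal_effects[c]
    sd = g_own.std(axis=0)
    sd[sd == 0] = 1.0
    scale = np.asarray(config.genetic_sd) / sd
    for c in collections:
        causal_effects[c] = causal_effects[c] * scale
        coll_bv[c] = Xc @ causal_effects[c]
    g_own = g_own * scale
    shared_bv = np.sqrt(1 - fgxe) * (Xc @ (beta_shared * scale))
    deviations = g_own - shared_bv

    if config.environment_means is None:
        env_means = np.zeros((len(collections), t))
    else:
        env_means = np.broadcast_to(
            np.asarray(config.environment_means, dtype=float), (len(collections), t)
        )

    y = np.empty((len(labels), t))
    for ci, c in enumerate(collections):
        rows = np.where(labels == c)[0]
        for ti, trait in enumerate(config.trait_names):
            g = g_own[rows, ti]
            h2 = config.h2_targets[ti]
            var_g = g.var()
            mu = env_means[ci, ti]
            proto = _resolve_protocol(config, trait, c)
            if proto is None:
                sigma_e = np.sqrt(var_g * (1 - h2) / h2)
                y[rows, ti] = mu + g + sigma_e * rng.standard_normal(len(rows))
            else:
                # Within-tree (per-fruit) noise: CV is taken against the
                # environment mean when one is supplied, else the genetic SD.
                ref = abs(mu) if mu != 0 else np.sqrt(var_g)
                sigma_fruit = config.within_tree_cv * ref
                var_e = max(
                    var_g * (1 - h2) / h2 - sigma_fruit**2 / proto.k, 0.0
                )
                tree = np.sqrt(var_e) * rng.standard_normal(len(rows))
                fruit = sigma_fruit * _fruit_noise(
                    rng, (len(rows), proto.k), config.within_tree_skew
                )
                per_fruit = mu + (g + tree)[:, None] + fruit
                reducer = (
                    per_fruit.mean(axis=1)
                    if proto.kind == "mean_of_k"
                    else per_fruit.max(axis=1)
                )
                y[rows, ti] = reducer

    realized = np.empty(t)
    for ti in range(t):
        ratios = []
        for c in collections:
            rows = labels == c
            vy = y[rows, ti].var()
            ratios.append(g_own[rows, ti].var() / vy if vy > 0 else np.nan)
        realized[ti] = float(np.nanmean(ratios))

    records = pd.DataFrame(
        {
            "individual_id": np.tile(geno.individual_ids, t),
            "collection": np.tile(labels, t),
            "trait": np.repeat(list(config.trait_names), len(labels)),
            "value": np.concatenate([y[:, ti] for ti in range(t)]),
        }
    )
    covariates = pd.get_dummies(
        pd.Series(labels, index=geno.individual_ids, name="dataset"), dtype=float
    )
    table = PhenotypeTable(records, covariates=covariates)
    truth = TrueValues(
        breeding_values=g_own,
        collection_breeding_values=coll_bv,
        collection_deviations=deviations,
        causal_effects=causal_effects,
        causal_markers=causal,
        realized_h2=realized,
    )
    return table, truth


def load_config(path):
    """Read a YAML/JSON file into (SimGenoConfig, PhenoSimConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    geno_cfg = SimGenoConfig(**raw.get("genotypes", {}))
    pheno_raw = dict(raw.get("phenotypes", {}))
    protocols = {}
    for trait, spec in (pheno_raw.pop("protocols", {}) or {}).items():
        if isinstance(spec, dict) and "kind" in spec:
            protocols[trait] = Protocol(**spec)
        elif isinstance(spec, dict):
            protocols[trait] = {c: Protocol(**s) for c, s in spec.items()}
    pheno_cfg = PhenoSimConfig(protocols=protocols, **pheno_raw)
    return geno_cfg, pheno_cfg
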