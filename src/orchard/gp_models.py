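"""Kernel construction and Bayesian kernel-regression fitting for genomic
prediction.

Five additive models are supported, all special cases of

    y = mu + E + G + T + GE + GT + eps

where each random term has covariance proportional to a named kernel:
V_E = Z_E Z_E' (environment incidence), V_G = Z_G Grm Z_G' (genomic),
V_T = Z_T Z_T' (trait incidence), and the interaction kernels are Hadamard
(elementwise) products V_GE = V_G . V_E and V_GT = V_G . V_T.

    Single : y = mu + G + eps
    EG     : y = mu + E + G + eps
    GxE    : y = mu + E + G + GE + eps
    MT     : y = mu + T + G + eps
    MxT    : y = mu + T + G + GT + eps

Fitting is Bayesian kernel (RKHS) regression by Gibbs sampling: each kernel
is eigendecomposed once and its effect sampled in the rotated basis, variance
components get scaled-inverse-chi-square updates, and missing phenotypes are
imputed by data augmentation each iteration — so records left unphenotyped at
fit time receive genomic estimated breeding values (GEBVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import GRMatrix
from .varcomp import _as_kernel

__all__ = [
    "MODEL_KERNELS",
    "GENETIC_KERNELS",
    "KernelSet",
    "McmcConfig",
    "GpFit",
    "RKHSRegressor",
    "build_kernels",
    "fit_gibbs",
    "predict",
]

MODEL_KERNELS = {
    "Single": ("G",),
    "EG": ("E", "G"),
    "GxE": ("E", "G", "GE"),
    "MT": ("T", "G"),
    "MxT": ("T", "G", "GT"),
}
#: kernels whose effects carry genetic signal and therefore sum into the GEBV
GENETIC_KERNELS = ("G", "GE", "GT")


@dataclass
class KernelSet:
    model_id: str
    kernels: dict  # name -> (n_records, n_records) PSD matrix, model order
    records: pd.DataFrame  # individual_id, collection, trait per record
    grm_index: np.ndarray  # record -> row of the GRM

    _eig: dict = field(default_factory=dict, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def eigensystems(self, tol: float = 1e-8):
        """Eigendecompositions, computed once and cached (reused across CV
        replicates: the kernels depend on the record layout, not on y)."""
        if not self._eig:
            for name, Vk in self.kernels.items():
                vals, vecs = np.linalg.eigh(Vk)
                top = vals.max() if len(vals) else 1.0
                if vals.min() < -1e-6 * max(top, 1.0):
                    raise ValueError(f"kernel {name} is not PSD")
                keep = vals > tol * max(top, 1.0)
                self._eig[name] = (vals[keep], vecs[:, keep])
        return self._eig


@dataclass
class McmcConfig:
    """Gibbs chain settings. The study-scale default is 25k burn-in plus 25k
    sampling iterations; tests use much shorter chains."""

    n_burn_in: int = 25_000
    n_sampling: int = 25_000
    thin: int = 5
    prior_df: float = 5.0
    prior_r2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_burn_in, self.n_sampling, self.thin) < 1 and self.n_burn_in != 0:
            raise ValueError("iteration counts must be positive")
        if self.n_sampling < 1 or self.thin < 1:
            raise ValueError("iteration counts must be positive")
        if self.prior_df <= 0:
            raise ValueError("prior df must be positive")


@dataclass
class GpFit:
    model_id: str
    mu: float
    effects: dict  # kernel name -> posterior-mean effect vector
    varcomp: dict  # component name (kernels + 'eps') -> (post mean, post sd)
    gebv: np.ndarray  # per record
    gebv_sd: np.ndarray
    ess_sigma2_g: float
    records: pd.DataFrame
    missing_mask: np.ndarray


def build_kernels(model_id: str, records, grm: GRMatrix, strict: bool = True) -> KernelSet:
    """Realize one model's kernel list for a record table.

    ``records`` is a long table (or :class:`~orchard.phenotypes.PhenotypeTable`)
    with individual_id / collection / trait columns; every individual must be
    present in the GRM. With ``strict`` (default) a model that needs two or
    more environments/traits refuses a single level; ``strict=False`` builds
    the degenerate kernels anyway (a single environment makes V_E all-ones
    and hence V_GE identical to V_G).
    """
    if model_id not in MODEL_KERNELS:
        raise ValueError(f"unknown model {model_id!r}; choose {list(MODEL_KERNELS)}")
    df = records.records if hasattr(records, "records") else records
    df = df.reset_index(drop=True)
    idx = grm.index_of(df["individual_id"])
    K = _as_kernel(grm)
    VG = K[np.ix_(idx, idx)]
    env = df["collection"].to_numpy()
    trait = df["trait"].to_numpy()
    names = MODEL_KERNELS[model_id]
    if strict and "E" in names and len(set(env)) < 2:
        raise ValueError(f"model {model_id} needs >= 2 environments")
    if strict and "T" in names and len(set(trait)) < 2:
        raise ValueError(f"model {model_id} needs >= 2 traits")
    built = {}
    for name in names:
        if name == "G":
            built[name] = VG
        elif name == "E":
            built[name] = (env[:, None] == env[None, :]).astype(float)
        elif name == "T":
            built[name] = (trait[:, None] == trait[None, :]).astype(float)
        elif name == "GE":
            built[name] = VG * (env[:, None] == env[None, :])
        elif name == "GT":
            built[name] = VG * (trait[:, None] == trait[None, :])
    return KernelSet(model_id=model_id, kernels=built, records=df, grm_index=idx)


class RKHSRegressor(BaseEstimator):
    """Gibbs-sampled Bayesian kernel regression over a :class:`KernelSet`.

    Variance-component priors are scaled-inverse-chi-square with ``prior_df``
    degrees of freedom; each component's prior scale is set so its prior mode
    equals var(y) * prior_r2 / (number of kernels), and the residual's mode
    equals var(y) * (1 - prior_r2). The intercept has a flat prior. Missing
    phenotypes are handled by data augmentation, so their GEBVs are posterior
    means informed through the kernels.
    """

    def __init__(
        self,
        n_burn_in: int = 25_000,
        n_sampling: int = 25_000,
        thin: int = 5,
        prior_df: float = 5.0,
        prior_r2: float = 0.5,
        seed: int = 0,
    ):
        self.n_burn_in = n_burn_in
        self.n_sampling = n_sampling
        self.thin = thin
        self.prior_df = prior_df
        self.prior_r2 = prior_r2
        self.seed = seed

    def fit(self, kernels: KernelSet, y):
        cfg = McmcConfig(
            self.n_burn_in, self.n_sampling, self.thin,
            self.prior_df, self.prior_r2, self.seed,
        )
        y = np.asarray(y, dtype=float)
        n = kernels.n_records
        if len(y) != n:
            raise ValueError("y length does not match kernel dimension")
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError("all phenotypes missing; nothing to fit")
        eig = kernels.eigensystems()
        names = list(kernels.kernels)
        n_k = len(names)
        rng = np.random.default_rng(cfg.seed)

        vy = y[obs].var()
        df0 = cfg.prior_df
        scale_k = vy * cfg.prior_r2 / n_k * (df0 + 2) / df0
        scale_e = vy * (1 - cfg.prior_r2) * (df0 + 2) / df0

        mu = float(y[obs].mean())
        u = {k: np.zeros(n) for k in names}
        sig = {k: vy * cfg.prior_r2 / n_k for k in names}
        sig_e = vy * (1 - cfg.prior_r2)
        e = np.where(obs, y - mu, 0.0)

        keep = max((cfg.n_sampling // cfg.thin), 1)
        sums = {k: np.zeros(n) for k in names}
        mu_sum = 0.0
        gebv_sum = np.zeros(n)
        gebv_sq = np.zeros(n)
        var_chains = {k: np.zeros(keep) for k in names + ["eps"]}
        kept = 0
        total_iters = cfg.n_burn_in + cfg.n_sampling

        for it in range(total_iters):
            # intercept (flat prior)
            e += mu
            mu = e.mean() + rng.standard_normal() * np.sqrt(sig_e / n)
            e -= mu
            # kernel effects in each rotated basis
            for k in names:
                d, U = eig[k]
                e += u[k]
                w = U.T @ e
                c = d * sig[k] / (d * sig[k] + sig_e)
                gamma = c * w + np.sqrt(c * sig_e) * rng.standard_normal(len(d))
                u[k] = U @ gamma
                e -= u[k]
                ss = np.sum(gamma**2 / d)
                sig[k] = (ss + df0 * scale_k) / rng.chisquare(len(d) + df0)
            # residual variance from the augmented data
            sig_e = (e @ e + df0 * scale_e) / rng.chisquare(n + df0)
            # data augmentation for the masked records
            n_miss = int((~obs).sum())
            if n_miss:
                e[~obs] = np.sqrt(sig_e) * rng.standard_normal(n_miss)
            if it >= cfg.n_burn_in and (it - cfg.n_burn_in) % cfg.thin == 0:
                if kept < keep:
                    mu_sum += mu
                    g = np.zeros(n)
                    for k in names:
                        sums[k] += u[k]
                        var_chains[k][kept] = sig[k]
                        if k in GENETIC_KERNELS:
                            g += u[k]
                    var_chains["eps"][kept] = sig_e
                    gebv_sum += g
                    gebv_sq += g**2
                    kept += 1

        inv = 1.0 / kept
        self.mu_ = mu_sum * inv
        self.effects_ = {k: sums[k] * inv for k in names}
        self.varcomp_ = {
            k: (float(ch[:kept].mean()), float(ch[:kept].std()))
            for k, ch in var_chains.items()
        }
        self.gebv_ = gebv_sum * inv
        self.gebv_sd_ = np.sqrt(np.clip(gebv_sq * inv - self.gebv_**2, 0, None))
        self.ess_sigma2_g_ = _effective_sample_size(var_chains["G"][:kept])
        self.missing_mask_ = ~obs
        self.kernels_ = kernels
        return self

    def predict(self, record_indices=None) -> np.ndarray:
        """GEBV (sum of genetic-kernel posterior means) for the given records;
        defaults to the records that were masked at fit time."""
        if record_indices is None:
            record_indices = np.where(self.missing_mask_)[0]
        idx = np.asarray(record_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.gebv_)):
            raise IndexError("record index outside the fitted record set")
        return self.gebv_[idx]

    def result(self) -> GpFit:
        return GpFit(
            model_id=self.kernels_.model_id,
            mu=float(self.mu_),
            effects=self.effects_,
            varcomp=self.varcomp_,
            gebv=self.gebv_,
            gebv_sd=self.gebv_sd_,
            ess_sigma2_g=self.ess_sigma2_g_,
            records=self.kernels_.records,
            missing_mask=self.missing_mask_,
        )


def _effective_sample_size(chain: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation estimator."""
    m = len(chain)
    if m < 3 or chain.std() == 0:
        return float(m)
    c = chain - chain.mean()
    acf = np.correlate(c, c, mode="full")[m - 1 :] / (c @ c)
    s = 0.0
    for t in range(1, m):
        if acf[t] <= 0:
            break
        s += acf[t]
    return float(m / (1 + 2 * s))


def fit_gibbs(y, kernel_set: KernelSet, config: McmcConfig | None = None) -> GpFit:
    """Functional wrapper around :class:`RKHSRegressor`."""
    cfg = config or McmcConfig()
    est = RKHSRegressor(
        n_burn_in=cfg.n_burn_in,
        n_sampling=cfg.n_sampling,
        thin=cfg.thin,
        prior_df=cfg.prior_df,
        prior_r2=cfg.prior_r2,
        seed=cfg.seed,
    ).fit(kernel_set, y)
    return est.result()


def predict(fit: GpFit, record_indices) -> np.ndarray:
    """GEBVs for masked records of a finished fit."""
    idx = np.asarray(record_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= len(fit.gebv)):
        raise IndexError("record index outside the fitted record set")
    return fit.gebv[idx]
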