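"""Mixed-linear-model association scan with polygenic control.

The model per tested marker s is

    y = X b + s beta + g + e,   g ~ N(0, K sigma2_G),  e ~ N(0, I sigma2_e)

with the relationship matrix K eigendecomposed once. By default the variance
components are estimated once under the null (no marker) and reused for every
marker ("P3D"); an exact mode re-optimizes the variance ratio per marker by a
one-dimensional search. Wald p-values are reported, together with the genomic
inflation factor lambda_gc as a calibration diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix, compute_grm, impute_mean
from .varcomp import GREML, _as_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "GwasResult",
    "QtlCluster",
    "MixedModelGWAS",
    "mlm_scan",
    "cluster_qtls",
    "inflation_lambda",
]

CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass
class GwasResult:
    table: pd.DataFrame  # chrom, pos, beta, se, stat, p (NaN p carries a reason)
    n: int
    maf_min: float
    mode: str
    covariate_names: list
    null_sigma2_g: float
    null_sigma2_e: float
    lambda_gc: float


@dataclass
class QtlCluster:
    chromosome: str
    members: list  # marker indices into the scan table
    span: tuple  # (min_pos, max_pos)
    lead_marker: int
    lead_p: float
    tier: str  # 'significant' or 'suggestive'


class MixedModelGWAS(BaseEstimator):
    """Genome scan estimator; ``fit`` runs the scan and stores ``result_``."""

    def __init__(self, maf_min: float = 0.05, mode: str = "p3d"):
        self.maf_min = maf_min
        self.mode = mode

    def fit(self, geno: GenotypeMatrix, y, covariates=None, grm=None):
        if self.mode not in ("p3d", "exact"):
            raise ValueError("mode must be 'p3d' or 'exact'")
        y = np.asarray(y, dtype=float)
        n = len(y)
        if np.isnan(y).any():
            raise ValueError("y must be complete")
        geno_c = impute_mean(geno)
        if grm is None:
            grm = compute_grm(geno_c)
        K = _as_kernel(grm)

        X = np.ones((n, 1))
        cov_names = ["intercept"]
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            # drop covariate columns collinear with the intercept
            keep = C.std(axis=0) > 0
            X = np.column_stack([X, C[:, keep]])
            cov_names += [f"cov{j}" for j in range(int(keep.sum()))]

        p_alt = geno_c.dosages.mean(axis=0) / 2
        maf = np.minimum(p_alt, 1 - p_alt)
        keep = maf > self.maf_min
        markers = np.where(keep)[0]

        null = GREML().fit(K, y, X=X)
        sg, se = null.sigma2_g_, null.sigma2_e_
        S, U = np.linalg.eigh(K)
        S = np.clip(S, 0, None)
        yr = U.T @ y
        Xr = U.T @ X
        Gr = U.T @ geno_c.dosages[:, markers]

        if self.mode == "p3d":
            beta, se_b, pvals = _scan_gls(yr, Xr, Gr, S, sg, se)
        else:
            beta, se_b, pvals = _scan_exact(yr, Xr, Gr, S, sg, se)

        stat = np.where(se_b > 0, (beta / np.where(se_b > 0, se_b, 1.0)) ** 2, np.nan)
        table = pd.DataFrame(
            {
                "marker": markers,
                "chrom": geno.chromosome[markers],
                "pos": geno.position_bp[markers],
                "beta": beta,
                "se": se_b,
                "stat": stat,
                "p": pvals,
            }
        )
        n_collinear = int(np.isnan(pvals).sum())
        if n_collinear:
            logger.info("%d markers collinear with covariates (p set NaN)", n_collinear)
        finite_p = table["p"].dropna().to_numpy()
        lam = inflation_lambda(finite_p) if len(finite_p) >= 2 else np.nan
        self.result_ = GwasResult(
            table=table,
            n=n,
            maf_min=self.maf_min,
            mode=self.mode,
            covariate_names=cov_names,
            null_sigma2_g=sg,
            null_sigma2_e=se,
            lambda_gc=lam,
        )
        return self


def _scan_gls(yr, Xr, Gr, S, sg, se):
    """GLS per marker with fixed variance components (rotated basis)."""
    wi = 1.0 / (S * sg + se)
    Xw = Xr * wi[:, None]
    A0 = Xr.T @ Xw  # p x p
    A0inv = np.linalg.inv(A0)
    d0 = Xw.T @ yr  # p
    Gw = Gr * wi[:, None]
    b = Xr.T @ Gw  # p x m
    a = np.einsum("ij,ij->j", Gr, Gw)  # g' W g per marker
    c = Gw.T @ yr
    A0inv_b = A0inv @ b
    denom = a - np.einsum("ij,ij->j", b, A0inv_b)
    numer = c - b.T @ (A0inv @ d0)
    ok = denom > 1e-10
    beta = np.where(ok, numer / np.where(ok, denom, 1.0), np.nan)
    se_b = np.where(ok, np.sqrt(1.0 / np.where(ok, denom, 1.0)), np.nan)
    with np.errstate(invalid="ignore"):
        pvals = stats.chi2.sf((beta / se_b) ** 2, df=1)
    return beta, se_b, pvals


def _scan_exact(yr, Xr, Gr, S, sg0, se0):
    """Per-marker REML re-optimization of the variance ratio on log-scale."""
    n, m = Gr.shape
    total0 = sg0 + se0
    beta = np.empty(m)
    se_b = np.empty(m)
    pvals = np.empty(m)

    for j in range(m):
        Xj = np.column_stack([Xr, Gr[:, j]])
        p = Xj.shape[1]

        def negremll(log_delta):
            # delta = sigma2_g / sigma2_e; total variance profiled out
            delta = np.exp(log_delta)
            v = S * delta + 1.0
            wi = 1.0 / v
            Xw = Xj * wi[:, None]
            A = Xj.T @ Xw
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            bhat = np.linalg.solve(A, Xw.T @ yr)
            r = yr - Xj @ bhat
            rss = r @ (wi * r)
            df = n - p
            s2 = rss / df
            return 0.5 * (np.sum(np.log(v)) + logdetA + df * np.log(s2) + df)

        res = optimize.minimize_scalar(
            negremll, bounds=(-10, 10), method="bounded"
        )
        delta = np.exp(res.x)
        v = S * delta + 1.0
        wi = 1.0 / v
        Xw = Xj * wi[:, None]
        A = Xj.T @ Xw
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            beta[j] = se_b[j] = pvals[j] = np.nan
            continue
        bhat = Ainv @ (Xw.T @ yr)
        r = yr - Xj @ bhat
        s2 = (r @ (wi * r)) / (n - p)
        var_b = s2 * Ainv[-1, -1]
        if var_b <= 0 or not np.isfinite(var_b):
            beta[j] = se_b[j] = pvals[j] = np.nan
            continue
        beta[j] = bhat[-1]
        se_b[j] = np.sqrt(var_b)
        pvals[j] = stats.chi2.sf(beta[j] ** 2 / var_b, df=1)
    _ = total0
    return beta, se_b, pvals


def mlm_scan(y, covariates=None, grm=None, geno=None, maf_min=0.05, mode="p3d"):
    """Functional wrapper around :class:`MixedModelGWAS`."""
    est = MixedModelGWAS(maf_min=maf_min, mode=mode)
    est.fit(geno, y, covariates=covariates, grm=grm)
    return est.result_


def cluster_qtls(
    result: GwasResult | pd.DataFrame,
    significant_threshold: float,
    suggestive_threshold: float,
    merge_window_bp: int = 200_000,
):
    """Group passing markers into positional QTL clusters.

    Markers with p below the suggestive threshold are sorted by position per
    chromosome; consecutive markers within ``merge_window_bp`` join one
    cluster. A cluster is tiered 'significant' when any member passes the
    significant threshold.
    """
    table = result.table if isinstance(result, GwasResult) else result
    hits = table.dropna(subset=["p"])
    hits = hits[hits["p"] < suggestive_threshold]
    clusters: list[QtlCluster] = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        current: list = []
        last_pos = None
        for _, row in grp.iterrows():
            if last_pos is not None and row["pos"] - last_pos > merge_window_bp:
                clusters.append(_make_cluster(chrom, current, significant_threshold))
                current = []
            current.append(row)
            last_pos = row["pos"]
        if current:
            clusters.append(_make_cluster(chrom, current, significant_threshold))
    return clusters


def _make_cluster(chrom, rows, significant_threshold) -> QtlCluster:
    ps = np.array([r["p"] for r in rows])
    poss = np.array([r["pos"] for r in rows])
    lead = int(np.argmin(ps))
    return QtlCluster(
        chromosome=str(chrom),
        members=[int(r["marker"]) for r in rows],
        span=(int(poss.min()), int(poss.max())),
        lead_marker=int(rows[lead]["marker"]),
        lead_p=float(ps[lead]),
        tier="significant" if ps.min() < significant_threshold else "suggestive",
    )


def inflation_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi2 over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        warnings.warn(
            "fewer than 100 p-values; lambda_gc estimate is noisy", stacklevel=2
        )
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_MEDIAN)
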