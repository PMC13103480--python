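"""Population-structure and linkage-disequilibrium characterization, plus the
multiple-testing calibration used to set genome-wide significance thresholds.

LD is summarized by pairwise r^2: from haplotype frequencies when phase is
available, otherwise as the squared (composite) dosage correlation. A decay
curve bins mean r^2 by physical distance; the "background" threshold is the
99th percentile of r^2 among inter-chromosomal (unlinked) marker pairs, and
the decay distance is read where the smoothed curve first drops below it.

The effective number of independent SNPs Me follows the eigenvalue-correction
family (Li & Ji / Galwey, the approach behind the Genetic type-1 Error
Calculator): markers are processed in consecutive within-chromosome blocks;
per block the correlation-matrix eigenvalues lambda give
Me_block = m_block - sum(lambda_i - 1 for lambda_i > 1), and blocks sum.
The genome-wide significance threshold is alpha/Me and the suggestive
threshold 1/Me.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, GRMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "LDResult",
    "GecResult",
    "pca_from_grm",
    "pairwise_r2",
    "ld_decay",
    "background_threshold",
    "effective_snp_count",
    "gwas_thresholds",
    "independent_snp_fraction",
    "truncate_sigfigs",
]


@dataclass
class PcaResult:
    coordinates: np.ndarray  # (n, k)
    variance_fraction: np.ndarray  # (k,)
    individual_ids: np.ndarray


@dataclass
class LDResult:
    pairs: "np.ndarray | None"  # structured-ish (i, j, distance_bp, r2) columns
    bin_mid_bp: np.ndarray
    mean_r2: np.ndarray
    smoothed_r2: np.ndarray
    background_threshold: float | None
    crossing_distance_bp: float  # inf when the curve never crosses
    mode: str  # 'phased' or 'composite'
    n_pairs_skipped: int = 0


@dataclass
class GecResult:
    effective_snp_count: float
    n_markers: int
    significant_threshold: float
    suggestive_threshold: float
    block_size: int
    n_excluded: int = 0


def pca_from_grm(grm: GRMatrix, n_components: int = 10) -> PcaResult:
    """Principal components from the (double-centered) relationship matrix.

    The variance fraction of component k is lambda_k over the sum of the
    positive eigenvalues.
    """
    G = grm.values
    n = G.shape[0]
    if n_components > n:
        raise ValueError("n_components exceeds the number of individuals")
    row_mean = G.mean(axis=0)
    Gc = G - row_mean[None, :] - row_mean[:, None] + row_mean.mean()
    vals, vecs = np.linalg.eigh(Gc)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos_sum = vals[vals > 0].sum()
    lam = vals[:n_components]
    coords = vecs[:, :n_components] * np.sqrt(np.clip(lam, 0, None))
    frac = np.where(lam > 0, lam, 0.0) / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    return PcaResult(coords, frac, grm.individual_ids)


def _allele_matrix(geno: GenotypeMatrix, phased: bool):
    """Rows = haplotypes (phased) or individuals (composite); columns = markers."""
    if phased:
        if geno.haplotypes is None:
            raise ValueError("phased r2 requested but no haplotypes available")
        H = geno.haplotypes.astype(float)
        H[H < 0] = np.nan
        n, _, m = H.shape
        return H.reshape(n * 2, m), "phased"
    return geno.dosages, "composite"


def _corr_squared(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Squared Pearson correlation between columns of A (and B); NaN-free input."""
    Ac = A - A.mean(axis=0)
    sa = Ac.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        An = Ac / sa
        if B is None:
            r = (An.T @ An) / A.shape[0]
        else:
            Bc = B - B.mean(axis=0)
            Bn = Bc / Bc.std(axis=0)
            r = (An.T @ Bn) / A.shape[0]
    return r**2


def pairwise_r2(
    geno: GenotypeMatrix, markers=None, phased: bool | None = None
):
    """All within-chromosome marker-pair r^2 values for a marker subset.

    Returns an ``LDResult`` whose ``pairs`` field is an (n_pairs, 4) float
    array of (marker_i, marker_j, distance_bp, r2). Monomorphic markers are
    skipped (counted).
    """
    if phased is None:
        phased = geno.haplotypes is not None
    sub = geno if markers is None else geno.take_markers(np.asarray(markers))
    A, mode = _allele_matrix(sub, phased)
    if np.isnan(A).any():
        A = np.where(np.isnan(A), np.nanmean(A, axis=0), A)
    rows = []
    n_skipped = 0
    for chrom in dict.fromkeys(sub.chromosome):
        idx = np.where(sub.chromosome == chrom)[0]
        poly = A[:, idx].std(axis=0) > 0
        n_skipped += int((~poly).sum())
        idx = idx[poly]
        if len(idx) < 2:
            continue
        r2 = _corr_squared(A[:, idx])
        pos = sub.position_bp[idx].astype(float)
        iu, ju = np.triu_indices(len(idx), k=1)
        rows.append(
            np.column_stack(
                [idx[iu], idx[ju], np.abs(pos[ju] - pos[iu]), r2[iu, ju]]
            )
        )
    if n_skipped:
        logger.info("skipped %d monomorphic markers in r2", n_skipped)
    pairs = np.concatenate(rows) if rows else np.empty((0, 4))
    return LDResult(
        pairs=pairs,
        bin_mid_bp=np.array([]),
        mean_r2=np.array([]),
        smoothed_r2=np.array([]),
        background_threshold=None,
        crossing_distance_bp=np.inf,
        mode=mode,
        n_pairs_skipped=n_skipped,
    )


def ld_decay(
    geno: GenotypeMatrix,
    snps_per_chromosome: int = 10_000,
    bin_width_bp: int = 100,
    max_distance_bp: int = 100_000,
    threshold: float | None = None,
    smooth_window: int = 5,
    phased: bool | None = None,
    seed: int = 0,
) -> LDResult:
    """Distance-binned mean r^2 within chromosomes and the threshold crossing.

    ``snps_per_chromosome`` markers are randomly sampled per chromosome (all
    are used, with a log message, when fewer are available). The crossing
    distance is the first bin midpoint at which the running-mean-smoothed
    curve drops below ``threshold``; ``inf`` when never reached.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for chrom in dict.fromkeys(geno.chromosome):
        idx = np.where(geno.chromosome == chrom)[0]
        if len(idx) > snps_per_chromosome:
            idx = np.sort(rng.choice(idx, snps_per_chromosome, replace=False))
        else:
            logger.info(
                "chromosome %s has %d markers (< %d requested); using all",
                chrom,
                len(idx),
                snps_per_chromosome,
            )
        chosen.append(idx)
    subset = np.concatenate(chosen)
    ld = pairwise_r2(geno, markers=subset, phased=phased)
    pairs = ld.pairs
    dist, r2 = pairs[:, 2], pairs[:, 3]
    keep = dist <= max_distance_bp
    dist, r2 = dist[keep], r2[keep]
    edges = np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp)
    which = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(which, weights=r2, minlength=len(edges) - 1)
    counts = np.bincount(which, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2.0

    valid = counts > 0
    smoothed = np.full_like(mean_r2, np.nan)
    if valid.any():
        vm, vmid = mean_r2[valid], mids[valid]
        w = max(1, min(smooth_window, len(vm)))
        kernel = np.ones(w)
        # edge-normalized running mean (plain convolution biases the ends low)
        sm = np.convolve(vm, kernel, mode="same") / np.convolve(
            np.ones_like(vm), kernel, mode="same"
        )
        # enforce monotone non-increase so a single noisy bin cannot fake a crossing
        sm = np.minimum.accumulate(sm)
        smoothed[valid] = sm
        crossing = np.inf
        if threshold is not None:
            below = np.where(sm < threshold)[0]
            if below.size:
                crossing = float(vmid[below[0]])
    else:
        crossing = np.inf
    return LDResult(
        pairs=None,
        bin_mid_bp=mids,
        mean_r2=mean_r2,
        smoothed_r2=smoothed,
        background_threshold=threshold,
        crossing_distance_bp=crossing,
        mode=ld.mode,
        n_pairs_skipped=ld.n_pairs_skipped,
    )


def background_threshold(
    geno: GenotypeMatrix,
    snps_per_chromosome: int = 1000,
    quantile: float = 0.99,
    phased: bool | None = None,
    seed: int = 0,
) -> float:
    """99th percentile of r^2 among marker pairs on different chromosomes."""
    chrom_names = list(dict.fromkeys(geno.chromosome))
    if len(chrom_names) < 2:
        raise ValueError("background threshold needs at least two chromosomes")
    rng = np.random.default_rng(seed)
    if phased is None:
        phased = geno.haplotypes is not None
    chosen = []
    for chrom in chrom_names:
        idx = np.where(geno.chromosome == chrom)[0]
        if len(idx) > snps_per_chromosome:
            idx = np.sort(rng.choice(idx, snps_per_chromosome, replace=False))
        chosen.append(idx)
    subset = np.concatenate(chosen)
    sub = geno.take_markers(subset)
    A, _ = _allele_matrix(sub, phased)
    if np.isnan(A).any():
        A = np.where(np.isnan(A), np.nanmean(A, axis=0), A)
    poly = A.std(axis=0) > 0
    A = A[:, poly]
    chrom_of = sub.chromosome[poly]
    r2 = _corr_squared(A)
    different = chrom_of[:, None] != chrom_of[None, :]
    iu = np.triu_indices(r2.shape[0], k=1)
    vals = r2[iu][different[iu]]
    return float(np.quantile(vals, quantile))


def effective_snp_count(geno: GenotypeMatrix, block_size: int = 200) -> GecResult:
    """Effective number of independent SNPs via block-wise eigenvalue correction."""
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("effective_snp_count requires complete dosages")
    me = 0.0
    n_used = 0
    n_excluded = 0
    for chrom in dict.fromkeys(geno.chromosome):
        idx = np.where(geno.chromosome == chrom)[0]
        poly = X[:, idx].std(axis=0) > 0
        n_excluded += int((~poly).sum())
        idx = idx[poly]
        for start in range(0, len(idx), block_size):
            block = idx[start : start + block_size]
            mb = len(block)
            if mb == 0:
                continue
            if mb == 1:
                me += 1.0
            else:
                Xb = X[:, block]
                Xb = (Xb - Xb.mean(axis=0)) / Xb.std(axis=0)
                lam = np.linalg.eigvalsh((Xb.T @ Xb) / Xb.shape[0])
                me += mb - np.sum(np.clip(lam - 1.0, 0.0, None))
            n_used += mb
    if n_excluded:
        logger.info("excluded %d zero-variance markers from Me", n_excluded)
    sig, sug = gwas_thresholds(me)
    return GecResult(
        effective_snp_count=float(me),
        n_markers=n_used,
        significant_threshold=sig,
        suggestive_threshold=sug,
        block_size=block_size,
        n_excluded=n_excluded,
    )


def gwas_thresholds(me: float, alpha: float = 0.05):
    """Bonferroni-on-Me significance threshold and the 1/Me suggestive one."""
    if me < 1:
        raise ValueError("effective SNP count must be >= 1")
    return alpha / me, 1.0 / me


def independent_snp_fraction(me: float, n_markers: int) -> float:
    """Effective-over-total SNP count as a percentage."""
    return 100.0 * me / n_markers


def truncate_sigfigs(x: float, n_digits: int = 2) -> float:
    """Truncate (not round) to ``n_digits`` significant figures.

    Matches the reporting convention of the effective-test threshold
    calculator, which prints thresholds truncated to two significant figures.
    """
    import math

    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exp - n_digits + 1)
    return math.trunc(x / factor) * factor
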