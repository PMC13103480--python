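"""Genotype containers, VCF I/O, marker filtering, and the genomic relationship matrix.

Dosages count ALT alleles (0/1/2) with ``numpy.nan`` marking missing calls.
Positions are 1-based, as in VCF. The relationship matrix follows VanRaden's
first method with observed-sample allele frequencies:

    G = W W' / (2 * sum_k p_k (1 - p_k)),   W = M - 2p

where ``M`` is the complete dosage matrix and ``p_k`` the ALT frequency of
marker ``k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GRMatrix",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "impute_mean",
    "allele_frequencies",
    "compute_grm",
    "read_grm",
    "write_grm",
]


@dataclass
class GenotypeMatrix:
    """Additive-dosage matrix (individuals x markers) with a marker map.

    ``haplotypes`` is an optional ``(n, 2, m)`` int8 array of phased alleles;
    it is present when the source was fully phased (or simulated) and is
    required only for haplotype-based LD.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if not (len(self.chromosome) == len(self.position_bp) == m):
            raise ValueError("marker map length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual IDs must be unique")
        for chrom in dict.fromkeys(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            chromosome=self.chromosome[idx],
            position_bp=self.position_bp[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            individual_ids=self.individual_ids[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )


@dataclass
class GRMatrix:
    """VanRaden genomic relationship matrix with the frequencies that built it."""

    values: np.ndarray
    individual_ids: np.ndarray
    allele_freqs: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"individual {exc} not present in GRM") from exc


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int = 0
    n_removed_mac: int = 0
    n_removed_singleton: int = 0
    n_removed_maf: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_missing
            - self.n_removed_mac
            - self.n_removed_singleton
            - self.n_removed_maf
        )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped (counted in the log). Phase is ignored
    for dosages, but when every call in the file is phased the haplotypes are
    retained for haplotype-based LD.
    """
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    dosage_cols, hap_cols = [], []
    chroms, positions, refs, alts = [], [], [], []
    n_multi = 0
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples))
        hap = np.empty((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col[i] = np.nan
                hap[i] = -1
                all_phased = False
            else:
                if a0 > 1 or a1 > 1:
                    raise ValueError(f"malformed GT at {var.CHROM}:{var.POS}")
                col[i] = a0 + a1
                hap[i, 0], hap[i, 1] = a0, a1
                if not g[2]:
                    all_phased = False
        dosage_cols.append(col)
        hap_cols.append(hap)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    dosages = np.array(dosage_cols).T if dosage_cols else np.empty((len(samples), 0))
    haplotypes = None
    if all_phased and hap_cols:
        haplotypes = np.stack(hap_cols, axis=2)  # (n, 2, m)
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=samples,
        chromosome=np.array(chroms, dtype=object),
        position_bp=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=haplotypes,
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only). Phased records use '|' separators."""
    n, m = geno.dosages.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(geno.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in geno.individual_ids)
            + "\n"
        )
        for j in range(m):
            fields = [
                str(geno.chromosome[j]),
                str(geno.position_bp[j]),
                f"snp{j}",
                str(geno.ref[j]),
                str(geno.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if geno.haplotypes is not None:
                col = geno.haplotypes[:, :, j]
                gts = [
                    "./." if a0 < 0 else f"{a0}|{a1}" for a0, a1 in col
                ]
            else:
                enc = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                gts = [
                    "./." if np.isnan(d) else enc[float(d)]
                    for d in geno.dosages[:, j]
                ]
            fh.write("\t".join(fields + gts) + "\n")


def filter_variants(
    geno: GenotypeMatrix,
    max_missing_fraction: float = 0.2,
    min_mac: int = 0,
    min_maf: float = 0.0,
    drop_singletons: bool = False,
):
    """Marker QC: missingness -> MAC -> singleton -> MAF, applied in that order.

    Returns the filtered matrix and a :class:`FilterReport` with per-rule
    removal counts (each rule counts only markers that survived earlier rules).
    """
    if not (0 <= max_missing_fraction <= 1):
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if min_maf < 0 or min_maf >= 0.5:
        if min_maf != 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
    report = FilterReport(
        n_input=geno.n_markers,
        thresholds=dict(
            max_missing_fraction=max_missing_fraction,
            min_mac=min_mac,
            min_maf=min_maf,
            drop_singletons=drop_singletons,
        ),
    )
    X = geno.dosages
    n = X.shape[0]
    keep = np.ones(X.shape[1], dtype=bool)

    miss_frac = np.isnan(X).mean(axis=0)
    bad = keep & (miss_frac > max_missing_fraction)
    report.n_removed_missing = int(bad.sum())
    keep &= ~bad

    with np.errstate(invalid="ignore"):
        alt_count = np.nansum(X, axis=0)
        n_obs = np.sum(~np.isnan(X), axis=0)
    mac = np.minimum(alt_count, 2 * n_obs - alt_count)
    bad = keep & (mac < min_mac)
    report.n_removed_mac = int(bad.sum())
    keep &= ~bad

    if drop_singletons:
        bad = keep & (mac == 1)
        report.n_removed_singleton = int(bad.sum())
        keep &= ~bad

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt_count / np.maximum(2 * n_obs, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    bad = keep & ~(maf >= min_maf)  # NaN maf (all-missing) already removed above
    report.n_removed_maf = int(bad.sum())
    keep &= ~bad

    if not keep.any():
        logger.warning("all %d markers removed by filtering", geno.n_markers)
    return geno.take_markers(np.where(keep)[0]), report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-marker mean of observed calls."""
    X = geno.dosages.copy()
    missing = np.isnan(X)
    if not missing.any():
        return geno
    n_obs = (~missing).sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError(
            "marker(s) with all calls missing; run filter_variants first"
        )
    col_mean = np.nansum(X, axis=0) / n_obs
    X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    return replace(geno, dosages=X)


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """ALT allele frequency per marker, missing calls excluded."""
    X = geno.dosages
    n_obs = np.sum(~np.isnan(X), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nansum(X, axis=0) / (2 * n_obs)


def compute_grm(geno: GenotypeMatrix) -> GRMatrix:
    """VanRaden method-1 GRM from complete dosages.

    Monomorphic markers make the scaling degenerate and raise; filter them out
    with :func:`filter_variants` first.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute_mean first")
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic marker(s) present (p in {0,1}); remove with filter_variants"
        )
    W = X - 2 * p
    scale = 2.0 * np.sum(p * (1 - p))
    G = (W @ W.T) / scale
    return GRMatrix(
        values=G, individual_ids=geno.individual_ids, allele_freqs=p, scale=scale
    )


def write_grm(grm: GRMatrix, path) -> None:
    """Square tab-separated matrix with an ID header row and column."""
    ids = [str(i) for i in grm.individual_ids]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for iid, row in zip(ids, grm.values):
            fh.write(iid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_grm(path) -> GRMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    return GRMatrix(
        values=values,
        individual_ids=np.array(df.index, dtype=object),
        allele_freqs=np.array([]),
        scale=float("nan"),
    )
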