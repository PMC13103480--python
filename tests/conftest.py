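import numpy as np
import pytest

from orchard.genotypes import GenotypeMatrix, GRMatrix, compute_grm


def hwe_genotypes(n, m, seed=0, freq_range=(0.1, 0.9), n_chrom=1):
    """Unstructured Hardy-Weinberg panel used as a neutral fixture."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    per_chrom = m // n_chrom
    chroms = np.concatenate(
        [np.full(per_chrom, f"chr{c + 1}", dtype=object) for c in range(n_chrom)]
    )
    if len(chroms) < m:
        chroms = np.concatenate([chroms, np.full(m - len(chroms), chroms[-1])])
    pos = np.concatenate(
        [
            np.sort(rng.choice(10**8, size=(chroms == c).sum(), replace=False)) + 1
            for c in dict.fromkeys(chroms)
        ]
    )
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=np.array([f"ind{i:04d}" for i in range(n)], dtype=object),
        chromosome=chroms,
        position_bp=pos,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
    )


def grm_from_dosages(X):
    """VanRaden GRM computed inline (independent of the package path)."""
    p = X.mean(axis=0) / 2
    W = X - 2 * p
    return W @ W.T / (2 * np.sum(p * (1 - p)))


def make_grm(values, ids=None):
    n = values.shape[0]
    if ids is None:
        ids = np.array([f"ind{i:04d}" for i in range(n)], dtype=object)
    return GRMatrix(values=values, individual_ids=ids, allele_freqs=np.array([]), scale=1.0)


@pytest.fixture(scope="session")
def hwe_panel():
    """Shared 300 x 2000 HWE panel with its GRM."""
    geno = hwe_genotypes(300, 2000, seed=11, n_chrom=4)
    return geno, compute_grm(geno)
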