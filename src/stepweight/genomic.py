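"""Genomic relationship algebra: SNP filtering, the (weighted) VanRaden
G matrix, blending with the pedigree block A22, and the single-step
H-inverse assembly.

G = M D M' / (2 * sum_i p_i (1 - p_i)) with M the matrix of genotypes
centered by twice the allele frequency and D a diagonal matrix of SNP
weights (identity for the unweighted evaluation). The hybrid matrix used
by single-step GBLUP never needs to be formed; only its inverse

    H^-1 = A^-1 + [[0, 0], [0, Gb^-1 - A22^-1]]

with the nonzero block on the genotyped animals, where Gb is G blended
with a small proportion of A22 to guarantee invertibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse


class GenomicError(ValueError):
    pass


@dataclass
class MarkerPanel:
    """Genotype matrix (animals x SNPs, coded 0/1/2) plus marker map.

    The map has columns ``snp, chrom, pos_bp`` and must be ordered by
    (chrom, pos_bp); column j of ``genotypes`` is the SNP in map row j.
    """

    ids: np.ndarray
    genotypes: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.genotypes = np.asarray(self.genotypes)
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.genotypes.ndim != 2:
            raise GenomicError("genotypes must be a 2-D animals x SNPs matrix")
        if len(self.snp_map) != self.genotypes.shape[1]:
            raise GenomicError(
                f"map has {len(self.snp_map)} SNPs but matrix has "
                f"{self.genotypes.shape[1]} columns"
            )
        by_chrom = self.snp_map.groupby("chrom", sort=False)["pos_bp"]
        if not all(g.is_monotonic_increasing for _, g in by_chrom):
            raise GenomicError("positions must be non-decreasing within chromosome")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "MarkerPanel":
        return replace(
            self,
            genotypes=self.genotypes[:, keep],
            snp_map=self.snp_map.loc[np.asarray(keep)].reset_index(drop=True),
        )

    def subset_animals(self, ids) -> "MarkerPanel":
        index = {a: i for i, a in enumerate(self.ids)}
        rows = np.array([index[a] for a in ids], dtype=np.int64)
        return replace(self, ids=np.asarray(ids, dtype=object), genotypes=self.genotypes[rows])


def allele_frequencies(panel: MarkerPanel, warn_monomorphic: bool = True) -> np.ndarray:
    """Observed reference-allele frequency per SNP: column sum / 2n."""
    p = panel.genotypes.sum(axis=0) / (2.0 * panel.n)
    if warn_monomorphic:
        mono = (p <= 0.0) | (p >= 1.0)
        if mono.any():
            warnings.warn(
                f"{int(mono.sum())} monomorphic SNP(s) (p in {{0,1}}); "
                "usable only before filtering",
                stacklevel=2,
            )
    return p


def filter_snps(
    panel: MarkerPanel, maf_min: float = 0.01, hwe_dev_max: float = 0.15
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Drop SNPs failing the minor-allele-frequency or Hardy–Weinberg rule.

    The HWE rule removes SNPs whose observed heterozygote frequency
    deviates from the expectation 2p(1-p) by more than ``hwe_dev_max``.
    Returns the filtered panel and a removal log ``snp, reason, value``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = allele_frequencies(panel)
    maf = np.minimum(p, 1.0 - p)
    het_obs = (panel.genotypes == 1).sum(axis=0) / panel.n
    hwe_dev = np.abs(het_obs - 2.0 * p * (1.0 - p))
    fail_maf = maf < maf_min
    fail_hwe = (~fail_maf) & (hwe_dev > hwe_dev_max)
    records = []
    snps = panel.snp_map["snp"].to_numpy()
    for j in np.flatnonzero(fail_maf):
        records.append((snps[j], "maf", maf[j]))
    for j in np.flatnonzero(fail_hwe):
        records.append((snps[j], "hwe", hwe_dev[j]))
    log = pd.DataFrame(records, columns=["snp", "reason", "value"])
    keep = ~(fail_maf | fail_hwe)
    if not keep.any():
        raise GenomicError("all SNPs removed by filtering; relax maf_min / hwe_dev_max")
    return panel.subset_snps(np.flatnonzero(keep)), log


def center_genotypes(genotypes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """M_ij = genotype_ij - 2 p_j."""
    return np.asarray(genotypes, dtype=np.float64) - 2.0 * np.asarray(p)


def vanraden_denominator(p: np.ndarray) -> float:
    return float(2.0 * np.sum(p * (1.0 - p)))


def build_G(M: np.ndarray, p: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
    """Weighted VanRaden genomic relationship matrix M D M' / (2 Σ p(1-p))."""
    denom = vanraden_denominator(p)
    if denom <= 0.0:
        raise GenomicError("zero VanRaden denominator: all SNPs monomorphic")
    if d is None:
        G = M @ M.T / denom
    else:
        d = np.asarray(d, dtype=np.float64)
        if d.shape != (M.shape[1],):
            raise GenomicError("weight vector length must equal SNP count")
        G = (M * d) @ M.T / denom
    return 0.5 * (G + G.T)


def blend_G(
    G: np.ndarray, A22: np.ndarray, g_coef: float = 0.95, a_coef: float = 0.05
) -> np.ndarray:
    """Gb = g_coef*G + a_coef*A22, verified positive definite."""
    if G.shape != A22.shape:
        raise GenomicError("G and A22 dimensions differ")
    Gb = g_coef * G + a_coef * A22
    try:
        np.linalg.cholesky(Gb)
    except np.linalg.LinAlgError:
        raise GenomicError(
            "blended genomic matrix is not positive definite; increase a_coef"
        ) from None
    return Gb


def build_H_inverse(
    A_inv: sparse.spmatrix,
    Gb: np.ndarray,
    A22: np.ndarray,
    genotyped_index: np.ndarray,
) -> sparse.csr_matrix:
    """H^-1 = A^-1 + scatter(Gb^-1 - A22^-1) on the genotyped animals.

    ``genotyped_index`` maps row k of Gb/A22 to its pedigree position.
    """
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    q = len(genotyped_index)
    if Gb.shape != (q, q) or A22.shape != (q, q):
        raise GenomicError("genotyped_index length does not match Gb/A22 dimension")
    n = A_inv.shape[0]
    if q and (genotyped_index.min() < 0 or genotyped_index.max() >= n):
        raise GenomicError("genotyped_index out of pedigree range")
    base = sparse.coo_matrix(A_inv)
    if not q:
        return base.tocsr()
    delta = np.linalg.inv(Gb) - np.linalg.inv(A22)
    rr = np.repeat(genotyped_index, q)
    cc = np.tile(genotyped_index, q)
    block = sparse.coo_matrix((delta.ravel(), (rr, cc)), shape=(n, n))
    return (base + block).tocsr()
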