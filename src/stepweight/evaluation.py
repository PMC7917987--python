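"""Forward validation and single-step GWAS window decomposition.

Validation follows the forward scheme: animals born up to a cut-off year
train the model (their adjusted phenotypes retained), younger animals
form the validation set with phenotypes masked but pedigree and
genotypes kept. Metrics on the validation set:

* predictive ability r — Pearson correlation of adjusted phenotype and
  EBV/GEBV;
* accuracy — r / sqrt(h2), h2 from the pedigree-based single-trait model;
* bias — slope of regressing adjusted phenotypes on predictions
  (1 = unbiased dispersion);
* RMSE — root mean squared difference (trait units).

The ssGWAS decomposes additive genetic variance over genomic windows:
for window k the variance across genotyped animals of the window's
genomic score sum_{i in k} M_col,i * u_hat_i, as a percentage of
sigma_a2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable


class EvaluationError(ValueError):
    pass


def split_by_birth_year(
    phenotyped_ids, ped: PedigreeTable, cutoff_year: int
) -> tuple[np.ndarray, np.ndarray]:
    """Training = born <= cutoff; validation = born after. Disjoint, exhaustive."""
    ids = np.asarray(phenotyped_ids, dtype=object)
    years = np.array([ped.birth_year[ped.position(a)] for a in ids])
    train = ids[years <= cutoff_year]
    val = ids[years > cutoff_year]
    if len(val) == 0:
        raise EvaluationError(f"no animals born after cutoff year {cutoff_year}")
    if len(train) == 0:
        raise EvaluationError(f"no animals born up to cutoff year {cutoff_year}")
    return train, val


def evaluate(y_adj: pd.Series, predictions: pd.Series, h2: float) -> dict:
    """Validation metrics row; undefined (NaN) when predictions have no spread."""
    common = y_adj.index.intersection(predictions.index)
    if len(common) < 3:
        raise EvaluationError("need at least 3 aligned validation records")
    ya = y_adj.loc[common].to_numpy(dtype=float)
    pr = predictions.loc[common].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((ya - pr) ** 2)))
    if np.std(pr) == 0.0 or np.std(ya) == 0.0:
        r = b = np.nan
    else:
        r = float(np.corrcoef(ya, pr)[0, 1])
        b = float(np.cov(ya, pr, ddof=1)[0, 1] / np.var(pr, ddof=1))
    return {
        "n_val": int(len(common)),
        "predictive_ability": r,
        "accuracy": r / np.sqrt(h2),
        "bias_slope": b,
        "rmse": rmse,
    }


def window_variance_explained(
    M: np.ndarray,
    u_hat: np.ndarray,
    snp_map: pd.DataFrame,
    sigma_a2: float,
    window_bp: int | None = 1_000_000,
    window_snps: int | None = None,
) -> pd.DataFrame:
    """Percent additive genetic variance per genomic window.

    Windows are either fixed-bp spans ``[k*window_bp, (k+1)*window_bp)``
    anchored at position 0 per chromosome, or blocks of ``window_snps``
    consecutive SNPs. Empty windows are simply absent (0% by convention).
    """
    if sigma_a2 <= 0:
        raise EvaluationError("sigma_a2 must be positive")
    u_hat = np.asarray(u_hat, dtype=float)
    if M.shape[1] != len(u_hat) or len(snp_map) != len(u_hat):
        raise EvaluationError("M, u_hat and map must agree in SNP count")
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    if window_snps is not None:
        key = np.empty(len(u_hat), dtype=np.int64)
        start = np.empty(len(u_hat), dtype=np.int64)
        end = np.empty(len(u_hat), dtype=np.int64)
        nxt = 0
        df = pd.DataFrame({"chrom": chrom, "pos": pos})
        for _, idx in df.groupby("chrom", sort=False).indices.items():
            idx = np.sort(idx)
            local = np.arange(len(idx)) // window_snps
            key[idx] = local + nxt
            nxt += local[-1] + 1
        frame = pd.DataFrame({"chrom": chrom, "key": key, "pos": pos})
        bounds = frame.groupby("key").agg(
            chrom=("chrom", "first"), start_bp=("pos", "min"), end_bp=("pos", "max")
        )
    else:
        key_local = pos // window_bp
        frame = pd.DataFrame({"chrom": chrom, "key_local": key_local})
        frame["key"] = frame.groupby(["chrom", "key_local"], sort=True).ngroup()
        bounds = frame.groupby("key").agg(chrom=("chrom", "first"))
        bounds["start_bp"] = frame.groupby("key")["key_local"].first() * window_bp
        bounds["end_bp"] = bounds["start_bp"] + window_bp
        key = frame["key"].to_numpy()
    rows = []
    for k in bounds.index:
        cols = np.flatnonzero(key == k)
        score = M[:, cols] @ u_hat[cols]
        pct = float(np.var(score) / sigma_a2 * 100.0)
        rows.append(
            {
                "chrom": bounds.loc[k, "chrom"],
                "start_bp": int(bounds.loc[k, "start_bp"]),
                "end_bp": int(bounds.loc[k, "end_bp"]),
                "pct_var": pct,
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
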