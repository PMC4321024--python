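"""Library sizes, RPKM normalization, and optional TMM effective sizes.

RPKM (reads per kilobase of transcript per million mapped reads) for gene g
in sample s is

    rpkm(g, s) = 1e9 * c(g, s) / (N_s * L_g)

with c the mapped read count, N_s the library size (column sum of the count
matrix) and L_g the transcript length in nucleotides.  No pseudocount is
applied here; zero counts stay exactly zero so that downstream ratio
statistics can apply their substitution rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CountMatrix, DataError, ExpressionMatrix

__all__ = ["library_sizes", "rpkm", "tmm_factors", "effective_library_sizes"]


def library_sizes(counts: CountMatrix) -> pd.Series:
    """Per-sample library size: the column sum of mapped read counts."""
    sizes = counts.counts.sum(axis=0)
    if (sizes == 0).any():
        empty = sizes.index[sizes == 0].tolist()
        raise DataError(f"all-zero sample column(s): {empty}")
    return sizes.astype(np.int64)


def rpkm(
    counts: CountMatrix,
    lengths: pd.Series,
    libsizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Normalize a count matrix to RPKM.

    Every gene in ``counts`` must have a positive length in ``lengths``;
    ``libsizes`` defaults to the column sums.
    """
    if libsizes is None:
        libsizes = library_sizes(counts)
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise DataError(f"no length for gene(s): {list(missing[:5])}")
    L = lengths.reindex(counts.gene_ids).to_numpy(dtype=float)
    if np.any(L <= 0):
        raise DataError("gene lengths must be positive")
    N = libsizes.reindex(counts.sample_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(N)) or np.any(N <= 0):
        raise DataError("library sizes must be positive for all samples")
    values = 1e9 * counts.counts.to_numpy(dtype=float) / (N[None, :] * L[:, None])
    df = pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, dict(counts.roles))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (doubly trimmed, weighted).

    M-values (log2 relative-abundance ratios vs. a reference sample) are
    trimmed by ``trim_m`` on each side and A-values (average log2 abundance)
    by ``trim_a``; the factor is the precision-weighted mean of the surviving
    M-values, and factors are rescaled to have geometric mean 1.  Genes with
    a zero count in either sample drop out of the comparison.
    """
    mat = counts.counts.to_numpy(dtype=float)
    N = mat.sum(axis=0)
    if np.any(N == 0):
        raise DataError("all-zero sample column")
    if reference is None:
        # sample whose 75th percentile of scaled counts is closest to the mean
        q = np.array([
            np.quantile(mat[:, j] / N[j], 0.75) for j in range(mat.shape[1])
        ])
        reference = counts.sample_ids[int(np.argmin(np.abs(q - q.mean())))]
    r_idx = counts.sample_ids.index(reference)
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == r_idx:
            continue
        y, r = mat[:, j], mat[:, r_idx]
        keep = (y > 0) & (r > 0)
        if keep.sum() < 10:
            continue
        y, r = y[keep], r[keep]
        py, pr = y / N[j], r / N[r_idx]
        M = np.log2(py / pr)
        A = 0.5 * np.log2(py * pr)
        # asymptotic (delta-method) inverse variances of M
        w = 1.0 / ((N[j] - y) / (N[j] * y) + (N[r_idx] - r) / (N[r_idx] * r))
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep2 = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if keep2.sum() == 0:
            continue
        factors[j] = 2 ** (np.sum(w[keep2] * M[keep2]) / np.sum(w[keep2]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def effective_library_sizes(counts: CountMatrix) -> pd.Series:
    """TMM-adjusted library sizes: column sum times the TMM factor."""
    sizes = library_sizes(counts).astype(float)
    return sizes * tmm_factors(counts)
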