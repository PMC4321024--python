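"""Replicate-free two-sample negative-binomial conditional exact test.

With a single library per condition no dispersion can be estimated from the
data, so a fixed biological coefficient of variation (BCV) is assumed and the
negative-binomial dispersion is phi = BCV**2 (variance mu + phi*mu**2).  For
a gene with counts (y1, y2) in libraries of sizes (n1, n2), the null
hypothesis of equal relative abundance is tested by conditioning on the total
s = y1 + y2: under the null both counts are NB with means p*n1 and p*n2 where
p = s/(n1+n2), and the two-sided p-value is the sum of the conditional
probabilities P(Y1 = y | Y1 + Y2 = s) over every partition y whose
conditional probability does not exceed that of the observed y1 (the exact
test convention, with ties counted at relative tolerance 1e-7).

With BCV = 0 the NB degenerates to Poisson and the conditional distribution
is exactly Binomial(s, n1/(n1+n2)).

Unequal library sizes are handled directly through the unequal conditional
means rather than by quantile-equalized pseudo-counts; the two approaches
agree asymptotically and this one is fully enumerable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ConfigError, CountMatrix, SampleRole, ScreenConfig
from .normalization import effective_library_sizes, library_sizes

logger = logging.getLogger("germscreen")

__all__ = ["nb_pmf", "conditional_exact_test", "bh_fdr", "run_contrast", "ContrastResult"]

#: Totals above this switch to a normal approximation of the conditional
#: distribution (never reached in practice at bulk-RNA-seq totals).
NORMAL_APPROX_THRESHOLD = 1_000_000

#: Relative tolerance for counting equi-probable partitions as ties.
_TIE_REL_TOL = 1e-7


def nb_pmf(y, mean: float, phi: float):
    """Negative-binomial probability mass with mean ``mean`` and variance
    ``mean + phi * mean**2``; ``phi = 0`` degenerates to the Poisson pmf.

    ``y`` may be a scalar or array of non-negative integers.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0):
        raise ValueError("y must be non-negative")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    if phi == 0:
        out = stats.poisson.pmf(y_arr, mean)
    else:
        r = 1.0 / phi
        out = stats.nbinom.pmf(y_arr, r, r / (r + mean))
    return out if out.ndim else float(out)


def _conditional_log_weights(s: int, m1: float, m2: float, phi: float) -> np.ndarray:
    """Unnormalized log conditional probabilities of Y1 = 0..s given Y1+Y2=s."""
    y = np.arange(s + 1, dtype=float)
    if phi == 0.0:
        # Poisson: binomial kernel in log space
        logp1, logp2 = np.log(m1), np.log(m2)
        lw = (y * logp1 - gammaln(y + 1)) + ((s - y) * logp2 - gammaln(s - y + 1))
    else:
        r = 1.0 / phi
        lq1 = np.log(m1) - np.log(m1 + r)
        lq2 = np.log(m2) - np.log(m2 + r)
        lw = (
            gammaln(y + r) - gammaln(y + 1) + y * lq1
            + gammaln(s - y + r) - gammaln(s - y + 1) + (s - y) * lq2
        )
    return lw


def conditional_exact_test(y1: int, y2: int, n1: float, n2: float, bcv: float) -> float:
    """Two-sided conditional exact p-value for equal relative abundance.

    Parameters are the two observed counts, the two library sizes, and the
    assumed BCV.  A total of zero carries no information and returns 1.
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if bcv < 0:
        raise ValueError("bcv must be non-negative")
    s = int(y1) + int(y2)
    if s == 0:
        return 1.0
    p_hat = s / (n1 + n2)
    m1, m2 = p_hat * n1, p_hat * n2
    phi = bcv * bcv
    if s > NORMAL_APPROX_THRESHOLD:
        logger.warning(
            "conditional_exact_test: total %d exceeds %d; using a normal "
            "approximation of the conditional distribution", s, NORMAL_APPROX_THRESHOLD,
        )
        v1 = m1 + phi * m1 * m1
        v2 = m2 + phi * m2 * m2
        mu_c = s * m1 / (m1 + m2)
        var_c = 1.0 / (1.0 / v1 + 1.0 / v2)
        z = abs(y1 - mu_c) / np.sqrt(var_c)
        return float(min(1.0, 2.0 * stats.norm.sf(z)))
    lw = _conditional_log_weights(s, m1, m2, phi)
    thresh = lw[int(y1)] + np.log1p(_TIE_REL_TOL)
    selected = lw[lw <= thresh]
    # ratio of log-sums so an all-inclusive selection gives exactly 1
    p = float(np.exp(logsumexp(selected) - logsumexp(lw)))
    return min(1.0, p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene outcome of one pairwise ovary-vs-other comparison.

    ``table`` columns: count_ovary, count_other, logfc (log2 relative
    abundance ratio, ovary over other, with a +0.5 count / +1 library guard
    so it is always finite), p_value, fdr.
    """

    contrast_name: str
    ovary_sample: str
    other_sample: str
    n_ovary: float
    n_other: float
    table: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def run_contrast(
    counts: CountMatrix,
    ovary_role: SampleRole,
    other_role: SampleRole,
    cfg: ScreenConfig,
    use_tmm: bool = False,
) -> ContrastResult:
    """Exact-test one contrast (previtellogenic ovary vs. one other sample)
    across all genes, with BH-FDR over the contrast's p-values.

    ``use_tmm`` switches the library sizes from raw column totals to
    TMM-effective sizes.
    """
    counts.require_roles([ovary_role, other_role])
    sizes = effective_library_sizes(counts) if use_tmm else library_sizes(counts).astype(float)
    s_ov = counts.sample_for_role(ovary_role)
    s_ot = counts.sample_for_role(other_role)
    y1 = counts.counts[s_ov].to_numpy(dtype=np.int64)
    y2 = counts.counts[s_ot].to_numpy(dtype=np.int64)
    n1, n2 = float(sizes[s_ov]), float(sizes[s_ot])

    pvals = np.ones(len(y1))
    totals = y1 + y2
    for i in np.nonzero(totals > 0)[0]:
        pvals[i] = conditional_exact_test(int(y1[i]), int(y2[i]), n1, n2, cfg.bcv)
    logfc = np.log2(((y1 + 0.5) / (n1 + 1.0)) / ((y2 + 0.5) / (n2 + 1.0)))
    table = pd.DataFrame(
        {
            "count_ovary": y1,
            "count_other": y2,
            "logfc": logfc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
        },
        index=counts.gene_ids,
    )
    name = f"{ovary_role.value}_vs_{other_role.value}"
    return ContrastResult(name, s_ov, s_ot, n1, n2, table)
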