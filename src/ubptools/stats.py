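"""Shared statistics: RPKM, binned Pearson correlation, Cohen's d, Fisher's exact."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

#: conventional threshold for a substantial effect size
COHENS_D_SUBSTANTIAL = 0.8


def rpkm(count: float, length_bp: float, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads.

    ``count / ((length/1e3) * (library_size/1e6))``.
    """
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if count < 0:
        raise ValueError("read count must be non-negative")
    return count / ((length_bp / 1e3) * (library_size / 1e6))


def pearson_on_bins(
    counts_a,
    counts_b,
    bin_size: int,
    drop_zero: bool = False,
) -> float:
    """Pearson r between two samples' per-bin coverages after RPKM normalization.

    Both vectors must come from the same genome binning. Each vector is
    RPKM-normalized using its own total as library size and ``bin_size`` as
    region length (a per-vector rescaling that leaves r unchanged but keeps
    units interpretable). ``drop_zero`` removes bins that are zero in both
    samples before correlating.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bin vectors must have identical shape")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if drop_zero:
        keep = (a > 0) | (b > 0)
        a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two bins")
    lib_a, lib_b = a.sum(), b.sum()
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library size is zero")
    ra = a / ((bin_size / 1e3) * (lib_a / 1e6))
    rb = b / ((bin_size / 1e3) * (lib_b / 1e6))
    if np.std(ra) == 0 or np.std(rb) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = sps.pearsonr(ra, rb)
    return float(r)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation.

    Sign follows ``mean(a) - mean(b)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample
    cross-product ratio (inf when the denominator product is zero) and p
    sums hypergeometric probabilities of tables at most as probable as the
    observed one, at fixed margins.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(np.int64)
    odds_ratio, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds_ratio), float(p)


def welch_t_p(a, b) -> float:
    """Two-sided Welch t-test p-value (unequal variances)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.pvalue)
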