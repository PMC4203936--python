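"""Translation-efficiency statistics and sensitivity classification.

TE is the ratio of ribosome-footprint RPKM to mRNA RPKM for a gene; the
treatment effect is the TE ratio (treated over control).  Genes are classified
by the z-score of log2 TE change across all quantified genes: below -1.5 the
gene's translation is called decreased, above +1.5 increased, otherwise
insensitive.  Pool comparisons of 5'UTR features use the two-tailed
Mann-Whitney U test, exact by enumeration for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TEResult",
    "PoolComparison",
    "translation_efficiency",
    "delta_te",
    "zscore_classify",
    "robust_filter",
    "mann_whitney_u",
    "replicate_correlation",
]

Z_LOW, Z_HIGH = -1.5, 1.5
EXACT_MAX_N = 16


@dataclass(frozen=True)
class TEResult:
    gene_id: str
    te_control: float
    te_treated: float
    delta_te: float
    log2_delta_te: float
    zscore: float  # NaN when unquantified
    klass: str  # decreased | increased | insensitive | unquantified


@dataclass(frozen=True)
class PoolComparison:
    metric: str
    n_a: int
    n_b: int
    u: float  # U statistic of pool a
    p_two_sided: float
    mode: str  # exact | normal


def translation_efficiency(rf_rpkm: float, mrna_rpkm: float) -> float:
    """RF RPKM over mRNA RPKM; NaN (unquantified) when mRNA RPKM is zero."""
    if mrna_rpkm <= 0:
        return math.nan
    return rf_rpkm / mrna_rpkm


def delta_te(te_treated: float, te_control: float) -> tuple[float, float]:
    """TE ratio (treated/control) and its log2; NaNs when either TE is not > 0."""
    if not (te_treated > 0 and te_control > 0):
        return math.nan, math.nan
    ratio = te_treated / te_control
    return ratio, math.log2(ratio)


def zscore_classify(log2_delta, gene_ids=None, low: float = Z_LOW,
                    high: float = Z_HIGH) -> pd.DataFrame:
    """z-score each gene's log2 TE change over the quantified population.

    z uses the population standard deviation.  Returns a DataFrame with
    ``log2_delta_te``, ``zscore`` and ``klass`` columns; non-finite inputs are
    classified ``unquantified`` and carry no z-score.
    """
    x = np.asarray(log2_delta, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(x))]
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need >=2 quantified genes to z-score")
    mean = x[finite].mean()
    sd = x[finite].std()  # population sd
    z = np.full_like(x, np.nan)
    if sd == 0:
        import warnings

        warnings.warn("zero variance in log2 dTE; all genes insensitive")
        z[finite] = 0.0
    else:
        z[finite] = (x[finite] - mean) / sd
    klass = np.where(~finite, "unquantified",
                     np.where(z < low, "decreased",
                              np.where(z > high, "increased", "insensitive")))
    return pd.DataFrame({"log2_delta_te": x, "zscore": z, "klass": klass},
                        index=pd.Index(gene_ids, name="gene_id"))


def robust_filter(counts: pd.DataFrame, min_count: int = 32) -> pd.Series:
    """Keep genes with every library's count >= ``min_count``.

    ``counts``: genes x libraries (both RF and mRNA columns).
    """
    return (counts >= min_count).all(axis=1)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def mann_whitney_u(x, y, mode: str = "auto", metric: str = "") -> PoolComparison:
    """Two-tailed Mann-Whitney U test.

    ``mode='exact'`` enumerates every assignment of the pooled values to the
    two groups (permutation-exact, correct under ties); ``'normal'`` uses the
    tie-corrected normal approximation with continuity correction; ``'auto'``
    picks exact for n_x + n_y <= 16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    if mode == "auto":
        mode = "exact" if nx + ny <= EXACT_MAX_N else "normal"
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0

    if mode == "exact":
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        offset = nx * (nx + 1) / 2
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    elif mode == "normal":
        pooled = np.concatenate([x, y])
        n = nx + ny
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PoolComparison(metric, nx, ny, u_obs, float(p), mode)


def replicate_correlation(rpkm_a, rpkm_b, log_transform: bool = True,
                          eps: float = 0.5) -> float:
    """Pearson correlation between replicate RPKM vectors.

    Computed on log2(RPKM + eps) by default, the scale on which sequencing
    replicates are conventionally compared.
    """
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need >=3 finite pairs")
    if log_transform:
        a = np.log2(a + eps)
        b = np.log2(b + eps)
    return float(np.corrcoef(a, b)[0, 1])
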