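"""End-to-end translation-efficiency analysis from per-library gene counts.

Replicates are pooled by summing counts before RPKM (the default;
``replicate_mode='mean-te'`` averages per-replicate TEs instead), TE is
RF-RPKM over mRNA-RPKM per condition, and genes are classified by the
z-score of log2 TE change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .te import delta_te, robust_filter, translation_efficiency, zscore_classify

__all__ = ["rpkm_table", "te_analysis"]


def _rpkm_vec(counts: np.ndarray, lengths: np.ndarray, total: float) -> np.ndarray:
    return counts / ((lengths / 1e3) * (total / 1e6))


def rpkm_table(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-library RPKM for a (genes x libraries) count table."""
    lengths = lengths.reindex(counts.index)
    out = {}
    for col in counts.columns:
        c = counts[col].to_numpy(dtype=float)
        out[col] = _rpkm_vec(c, lengths.to_numpy(dtype=float), c.sum())
    df = pd.DataFrame(out, index=counts.index)
    df.columns = counts.columns
    return df


def te_analysis(counts: pd.DataFrame, lengths: pd.Series,
                control: str = "dmso", treated: str = "silvestrol",
                min_count: int = 32, replicate_mode: str = "pool",
                z_low: float = -1.5, z_high: float = 1.5) -> pd.DataFrame:
    """TE change classification from a multi-library count table.

    ``counts`` columns are (condition, libtype, replicate) tuples as produced
    by :func:`ribosig.simulate.simulate_counts` or assembled from
    :func:`ribosig.quant.quantify` runs.  Genes failing the robust-measurement
    filter (any library below ``min_count``) are reported ``unquantified``.

    Returns a DataFrame with TE per condition, the TE ratio and its log2,
    z-scores over quantified genes and the sensitivity class.
    """
    if replicate_mode not in ("pool", "mean-te"):
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    lengths = lengths.reindex(counts.index).to_numpy(dtype=float)
    keep = robust_filter(counts, min_count)

    te = {}
    for cond in (control, treated):
        sub = counts[cond]
        if replicate_mode == "pool":
            rf = sub["rf"].sum(axis=1).to_numpy(dtype=float)
            mrna = sub["mrna"].sum(axis=1).to_numpy(dtype=float)
            rf_rpkm = _rpkm_vec(rf, lengths, rf.sum())
            mrna_rpkm = _rpkm_vec(mrna, lengths, mrna.sum())
            te[cond] = np.array([translation_efficiency(a, b)
                                 for a, b in zip(rf_rpkm, mrna_rpkm)])
        else:
            reps = sub["rf"].columns
            per_rep = []
            for rep in reps:
                rf = sub["rf"][rep].to_numpy(dtype=float)
                mrna = sub["mrna"][rep].to_numpy(dtype=float)
                rf_rpkm = _rpkm_vec(rf, lengths, rf.sum())
                mrna_rpkm = _rpkm_vec(mrna, lengths, mrna.sum())
                per_rep.append([translation_efficiency(a, b)
                                for a, b in zip(rf_rpkm, mrna_rpkm)])
            te[cond] = np.nanmean(np.array(per_rep), axis=0)

    ratio_log2 = np.array([delta_te(t, c) for t, c in zip(te[treated], te[control])])
    log2_dte = np.where(keep.to_numpy(), ratio_log2[:, 1], np.nan)
    result = zscore_classify(log2_dte, gene_ids=counts.index, low=z_low, high=z_high)
    result.insert(0, "te_control", te[control])
    result.insert(1, "te_treated", te[treated])
    result.insert(2, "delta_te", ratio_log2[:, 0])
    return result
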