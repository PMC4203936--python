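"""5'UTR signature classification.

Assigns each gene's 5'UTR to one of four categories — structured (folding
free energy below a threshold), variant (alternative TSS or 5'UTR intron),
TOP (5'-terminal oligopyrimidine or TOP-like start) or other — under an
explicit precedence, while retaining the raw flags so overlapping membership
remains recoverable.  Also scans for the (CGG)4 guanine-quartet motif
associated with helicase-dependent transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UTRFeatures",
    "Cgg4Scan",
    "classify_top",
    "detect_cgg4",
    "assign_category",
    "signature_summary",
    "DG_STRUCTURED_THRESHOLD",
]

DG_STRUCTURED_THRESHOLD = -104.0  # kcal/mol
CATEGORIES = ("structured", "variant", "TOP", "other")
_PYRIMIDINES = frozenset("CU")

CGG4_MOTIF = "CGGCGGCGGCGG"
CGG3_MOTIF = "CGGCGGCGG"


@dataclass(frozen=True)
class Cgg4Scan:
    has_cgg4: bool  # any 12-nt (CGG)4 occurrence
    positions_12nt: tuple[int, ...]
    positions_9nt: tuple[int, ...]  # 9-nt (CGG)3 matches, reported separately


@dataclass
class UTRFeatures:
    gene_id: str
    length: int
    gc_pct: float
    dg: float  # kcal/mol; NaN if unavailable
    is_variant: bool
    top_class: str  # TOP | TOP-like | none
    has_cgg4: bool = False
    category: str | None = None


def _find_all(seq: str, motif: str) -> tuple[int, ...]:
    out, start = [], 0
    while (hit := seq.find(motif, start)) != -1:
        out.append(hit)
        start = hit + 1  # overlapping matches all reported
    return tuple(out)


def detect_cgg4(seq: str) -> Cgg4Scan:
    """All (overlapping) 12-nt (CGG)4 and 9-nt (CGG)3 occurrences in ``seq``."""
    s = seq.upper().replace("T", "U")
    p12 = _find_all(s, CGG4_MOTIF)
    p9 = _find_all(s, CGG3_MOTIF)
    return Cgg4Scan(bool(p12), p12, p9)


def classify_top(seq: str, min_run: int = 4, max_run: int = 15,
                 toplike_min_run: int = 5, toplike_window: int = 4) -> str:
    """Classify the cap-proximal sequence as TOP, TOP-like or none.

    TOP: the first nucleotide is C and it is followed by an uninterrupted
    pyrimidine run of ``min_run``..``max_run`` bases.  TOP-like: a pyrimidine
    run of >= ``toplike_min_run`` starts within the first ``toplike_window``
    nucleotides but the strict TOP rule fails.
    """
    s = seq.upper().replace("T", "U")
    if not s:
        return "none"

    def run_length(start: int) -> int:
        k = start
        while k < len(s) and s[k] in _PYRIMIDINES:
            k += 1
        return k - start

    if s[0] == "C" and min_run <= run_length(1) <= max_run:
        return "TOP"
    for start in range(min(toplike_window, len(s))):
        if run_length(start) >= toplike_min_run:
            return "TOP-like"
    return "none"


def assign_category(features: UTRFeatures,
                    dg_threshold: float = DG_STRUCTURED_THRESHOLD,
                    precedence: tuple[str, ...] = CATEGORIES) -> str:
    """First matching category under ``precedence``; flags stay available."""
    if features.dg != features.dg and "structured" in precedence:  # NaN
        raise ValueError(f"{features.gene_id}: dG missing, category undetermined")
    matches = {
        "structured": features.dg < dg_threshold,
        "variant": features.is_variant,
        "TOP": features.top_class in ("TOP", "TOP-like"),
        "other": True,
    }
    for cat in precedence:
        if matches[cat]:
            features.category = cat
            return cat
    raise ValueError("precedence does not cover 'other'")


def signature_summary(pool, dg_threshold: float = DG_STRUCTURED_THRESHOLD,
                      precedence: tuple[str, ...] = CATEGORIES) -> dict:
    """Category composition of a gene pool, in percent.

    Returns ``{"n": ..., "single": {...}, "overlap": {...}}``: ``single``
    resolves each gene to one category under ``precedence`` (sums to 100);
    ``overlap`` reports raw-flag membership and may exceed 100 in total.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty gene pool")
    n = len(pool)
    single = {c: 0 for c in CATEGORIES}
    overlap = {c: 0 for c in CATEGORIES}
    for f in pool:
        single[assign_category(f, dg_threshold, precedence)] += 1
        if f.dg < dg_threshold:
            overlap["structured"] += 1
        if f.is_variant:
            overlap["variant"] += 1
        if f.top_class in ("TOP", "TOP-like"):
            overlap["TOP"] += 1
        if not (f.dg < dg_threshold or f.is_variant
                or f.top_class in ("TOP", "TOP-like")):
            overlap["other"] += 1
    return {
        "n": n,
        "single": {c: 100.0 * k / n for c, k in single.items()},
        "overlap": {c: 100.0 * k / n for c, k in overlap.items()},
    }
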