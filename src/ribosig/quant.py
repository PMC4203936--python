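"""Ribosome-footprint and mRNA read quantification.

Aligned reads are collapsed to a single genomic position each — the P-site
(5' end plus a fixed, length-configurable offset) for footprints, the read
midpoint for fragmented mRNA — and counted onto canonical transcripts.
Non-uniquely aligned reads are dropped, and genomic positions covered by more
than one canonical transcript are masked out of both the counts and the RPKM
length denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

__all__ = [
    "AlignedRead",
    "CountProfile",
    "GeneExpression",
    "AssignmentError",
    "psite_position",
    "midpoint_position",
    "read_sam",
    "read_bed",
    "build_count_profiles",
    "rpkm",
    "read_length_histogram",
    "quantify",
    "write_bedgraph",
]

DEFAULT_PSITE_OFFSET = 12


class AssignmentError(ValueError):
    """P-site offset incompatible with the read length."""


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    start: int  # 0-based leftmost aligned base
    length: int
    strand: str
    n_alignments: int = 1

    @property
    def unique(self) -> bool:
        return self.n_alignments == 1


@dataclass
class CountProfile:
    """Per-transcript-position counts plus the exclusion mask."""

    transcript_id: str
    counts: np.ndarray
    excluded_mask: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts[~self.excluded_mask].sum())

    @property
    def effective_length(self) -> int:
        return int((~self.excluded_mask).sum())


@dataclass(frozen=True)
class GeneExpression:
    gene_id: str
    rf_count: int
    mrna_count: int
    effective_length_nt: int
    rf_rpkm: float
    mrna_rpkm: float


def psite_position(read: AlignedRead, offset_table: dict[int, int] | None = None,
                   default_offset: int = DEFAULT_PSITE_OFFSET) -> int:
    """Genomic position of the ribosomal P-site base of a footprint read.

    The offset counts from the read's 5' end: ``start + offset`` on the plus
    strand, mirrored from the 3'-most base on the minus strand.
    """
    offset = (offset_table or {}).get(read.length, default_offset)
    if offset >= read.length:
        raise AssignmentError(
            f"P-site offset {offset} >= read length {read.length}")
    if read.strand == "+":
        return read.start + offset
    return (read.start + read.length - 1) - offset


def midpoint_position(read: AlignedRead) -> int:
    """Genomic position of the read middle (even lengths round toward 5')."""
    half = (read.length - 1) // 2
    if read.strand == "+":
        return read.start + half
    return (read.start + read.length - 1) - half


def read_sam(path: str | Path):
    """Yield :class:`AlignedRead` from a SAM/BAM file (pysam-backed).

    Alignment multiplicity is taken from the ``NH`` tag when present,
    otherwise every primary alignment counts as unique.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            yield AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,
                length=rec.query_length or rec.infer_read_length(),
                strand="-" if rec.is_reverse else "+",
                n_alignments=int(nh),
            )


def read_bed(path: str | Path):
    """Yield reads from 6-column BED (optional 7th column = alignment count)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            n_aln = int(f[6]) if len(f) > 6 else 1
            yield AlignedRead(f[0], int(f[1]), int(f[2]) - int(f[1]), f[5], n_aln)


class _TranscriptIndex:
    """Maps genomic positions to (transcript, transcript-position); marks
    positions covered by more than one canonical transcript as excluded."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = list(transcripts)
        cover: dict[str, dict[int, list[tuple[int, int]]]] = {}
        for idx, t in enumerate(self.transcripts):
            chrom_map = cover.setdefault(t.chrom, {})
            for tpos, gpos in enumerate(t.genomic_positions()):
                chrom_map.setdefault(gpos, []).append((idx, tpos))
        self._lookup: dict[str, dict[int, tuple[int, int]]] = {}
        self.excluded: dict[int, np.ndarray] = {
            i: np.zeros(t.length, dtype=bool) for i, t in enumerate(self.transcripts)
        }
        for chrom, chrom_map in cover.items():
            table = {}
            for gpos, hits in chrom_map.items():
                if len(hits) == 1:
                    table[gpos] = hits[0]
                else:
                    for idx, tpos in hits:
                        self.excluded[idx][tpos] = True
            self._lookup[chrom] = table

    def assign(self, chrom: str, gpos: int):
        table = self._lookup.get(chrom)
        if table is None:
            return None
        return table.get(gpos)

    def known_chrom(self, chrom: str) -> bool:
        return chrom in self._lookup


def build_count_profiles(reads, transcripts: list[TranscriptModel], mode: str,
                         offset_table: dict[int, int] | None = None,
                         default_offset: int = DEFAULT_PSITE_OFFSET,
                         blacklist_chroms: set[str] | None = None):
    """Count reads onto canonical transcripts.

    ``mode`` is ``"rf"`` (P-site assignment) or ``"mrna"`` (midpoint).
    ``blacklist_chroms`` discards reads aligned to the named references
    (e.g. an rRNA contig) before any assignment.  Returns
    ``(profiles, stats)``: per-transcript :class:`CountProfile` and a dict of
    bookkeeping counters satisfying read conservation
    ``counted + blacklisted + dropped_nonunique + skipped_unknown_chrom +
    masked + outside_transcripts == n_input``.
    """
    if mode not in ("rf", "mrna"):
        raise ValueError(f"mode must be 'rf' or 'mrna', got {mode!r}")
    blacklist = blacklist_chroms or set()
    index = _TranscriptIndex(transcripts)
    profiles = {
        t.transcript_id: CountProfile(
            t.transcript_id,
            np.zeros(t.length, dtype=np.int64),
            index.excluded[i].copy(),
        )
        for i, t in enumerate(transcripts)
    }
    order = [t.transcript_id for t in transcripts]
    stats = dict(n_input=0, counted=0, blacklisted=0, dropped_nonunique=0,
                 skipped_unknown_chrom=0, masked=0, outside_transcripts=0)
    for read in reads:
        stats["n_input"] += 1
        if read.chrom in blacklist:
            stats["blacklisted"] += 1
            continue
        if not read.unique:
            stats["dropped_nonunique"] += 1
            continue
        if not index.known_chrom(read.chrom):
            stats["skipped_unknown_chrom"] += 1
            continue
        gpos = (psite_position(read, offset_table, default_offset)
                if mode == "rf" else midpoint_position(read))
        hit = index.assign(read.chrom, gpos)
        if hit is None:
            # either no transcript covers the position, or >1 do (masked)
            if any(index.excluded[i][tp]
                   for i, t in enumerate(transcripts)
                   if (tp := t.genomic_to_transcript(gpos)) is not None
                   and t.chrom == read.chrom):
                stats["masked"] += 1
            else:
                stats["outside_transcripts"] += 1
            continue
        idx, tpos = hit
        profiles[order[idx]].counts[tpos] += 1
        stats["counted"] += 1
    return profiles, stats


def rpkm(count: int, effective_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of (effective) length per million mapped reads."""
    if effective_length_nt <= 0:
        raise ValueError("effective length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return count / ((effective_length_nt / 1e3) * (total_mapped / 1e6))


def read_length_histogram(reads):
    """Exact read-length histogram and mean length."""
    hist: dict[int, int] = {}
    total = n = 0
    for read in reads:
        hist[read.length] = hist.get(read.length, 0) + 1
        total += read.length
        n += 1
    if n == 0:
        raise ValueError("no reads")
    return dict(sorted(hist.items())), total / n


def quantify(rf_profiles, mrna_profiles, transcripts: list[TranscriptModel],
             rf_total: int | None = None, mrna_total: int | None = None,
             length_mode: str = "effective") -> pd.DataFrame:
    """Combine RF and mRNA count profiles into per-gene RPKM rows.

    ``length_mode='effective'`` uses the count of non-excluded transcript
    positions as the RPKM length denominator; ``'full'`` uses the transcript
    length.  Library sizes default to the totals counted in each profile set.
    """
    if length_mode not in ("effective", "full"):
        raise ValueError(f"length_mode must be 'effective' or 'full'")
    rf_total = rf_total or sum(p.total for p in rf_profiles.values()) or 1
    mrna_total = mrna_total or sum(p.total for p in mrna_profiles.values()) or 1
    rows = []
    for t in transcripts:
        rf = rf_profiles[t.transcript_id]
        mr = mrna_profiles[t.transcript_id]
        eff = rf.effective_length if length_mode == "effective" else t.length
        if eff == 0:
            continue
        rows.append(GeneExpression(
            gene_id=t.gene_id,
            rf_count=rf.total,
            mrna_count=mr.total,
            effective_length_nt=eff,
            rf_rpkm=rpkm(rf.total, eff, rf_total),
            mrna_rpkm=rpkm(mr.total, eff, mrna_total),
        ))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("gene_id")


def write_bedgraph(profiles, transcripts: list[TranscriptModel],
                   path: str | Path) -> None:
    """Export per-position counts as bedGraph (genomic coordinates).

    Runs of equal nonzero count are merged; excluded positions are skipped.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    lines = []
    for tid, prof in profiles.items():
        t = by_id[tid]
        gpos = t.genomic_positions()
        for tpos, count in enumerate(prof.counts):
            if count and not prof.excluded_mask[tpos]:
                g = gpos[tpos]
                lines.append((t.chrom, g, g + 1, int(count)))
    lines.sort()
    with open(path, "w") as fh:
        run_start = run_end = None
        run = None
        for chrom, s, e, c in lines + [(None, None, None, None)]:
            if run and run[0] == chrom and s == run_end and c == run[2]:
                run_end = e
                continue
            if run:
                fh.write(f"{run[0]}\t{run_start}\t{run_end}\t{run[2]}\n")
            run, run_start, run_end = (chrom, s, c), s, e
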