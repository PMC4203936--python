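"""Transcript models, annotation ingestion and 5'UTR extraction.

Coordinates are 0-based, half-open genomic intervals (BED convention);
transcript coordinates run 0-based from the transcription start site in
transcript orientation.  The 5'UTR of a transcript is the transcript interval
``[0, cds_start_transcript)``.

Genes producing multiple distinct 5'UTRs — through alternative transcription
start sites or introns within the 5'UTR — are flagged as carrying a
"variant 5'UTR".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TranscriptModel",
    "GeneUTRSet",
    "AnnotationError",
    "load_annotation",
    "write_bed12",
    "write_utr_fasta",
    "extract_five_prime_utr",
    "detect_utr_variants",
]

_COMPLEMENT = str.maketrans("ACGTUN", "UGCAAN")


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure plus the CDS start in transcript coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, ascending
    cds_start_transcript: int
    cds_end_transcript: int | None = None
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s or s < prev_end:
                raise AnnotationError(f"{self.transcript_id}: exons unsorted/overlapping")
            prev_end = e
        if not 0 <= self.cds_start_transcript <= self.length:
            raise AnnotationError(f"{self.transcript_id}: CDS start outside transcript")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        end = self.cds_end_transcript if self.cds_end_transcript is not None else self.length
        return max(end - self.cds_start_transcript, 0)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (0-based)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of each transcript position, 5'->3'."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]

    def genomic_to_transcript(self, gpos: int) -> int | None:
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                t = offset + (gpos - s)
                return t if self.strand == "+" else self.length - 1 - t
            offset += e - s
        return None

    def junctions_transcript(self) -> list[int]:
        """Transcript coordinates of the first base after each exon-exon junction."""
        sizes = [e - s for s, e in self.exons]
        if self.strand == "-":
            sizes = sizes[::-1]
        out, acc = [], 0
        for size in sizes[:-1]:
            acc += size
            out.append(acc)
        return out


@dataclass(frozen=True)
class GeneUTRSet:
    """Per-gene 5'UTR repertoire and variant flags."""

    gene_id: str
    utr_sequences: tuple[str, ...]
    has_alt_tss: bool
    has_utr_intron: bool

    @property
    def is_variant(self) -> bool:
        return self.has_alt_tss or self.has_utr_intron


def _select_canonical(transcripts: list[TranscriptModel]) -> TranscriptModel:
    # longest CDS, tie -> longest transcript, tie -> lexicographically first id
    return min(transcripts, key=lambda t: (-t.cds_length, -t.length, t.transcript_id))


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AnnotationError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(f"line {lineno}: block count mismatch")
    exons = tuple((start + off, start + off + size) for off, size in zip(starts, sizes))
    if exons[-1][1] != end:
        raise AnnotationError(f"line {lineno}: blocks do not span chromEnd")
    gene_id = name.rsplit("|", 1)[-1] if "|" in name else name
    tid = name.split("|", 1)[0]
    t = TranscriptModel(tid, gene_id, chrom, strand, exons, 0)
    if thick_start >= thick_end:  # non-coding
        cds_s, cds_e = t.length, t.length
    else:
        a = t.genomic_to_transcript(thick_start)
        b = t.genomic_to_transcript(thick_end - 1)
        if a is None or b is None:
            raise AnnotationError(f"line {lineno}: CDS outside exons of {tid}")
        cds_s, cds_e = min(a, b), max(a, b) + 1
    return TranscriptModel(tid, gene_id, chrom, strand, exons, cds_s, cds_e)


def _load_gtf(path: Path) -> list[TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise AnnotationError(f"line {lineno}: GTF needs 9 fields")
            feature, chrom, strand = f[2], f[0], f[6]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based closed
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from None
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";") if kv.strip()
            )
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError as exc:
                raise AnnotationError(f"line {lineno}: missing attribute {exc}") from None
            meta[tid] = (gid, chrom, strand)
            (exons if feature == "exon" else cds).setdefault(tid, []).append((start, end))

    out = []
    for tid, (gid, chrom, strand) in meta.items():
        ex = tuple(sorted(exons.get(tid, [])))
        if not ex:
            raise AnnotationError(f"transcript {tid}: no exons")
        t = TranscriptModel(tid, gid, chrom, strand, ex, 0)
        if tid in cds:
            gstarts = [s for s, _ in cds[tid]] + [e - 1 for _, e in cds[tid]]
            tpos = [t.genomic_to_transcript(g) for g in gstarts]
            if any(p is None for p in tpos):
                raise AnnotationError(f"transcript {tid}: CDS outside exons")
            cds_len = sum(e - s for s, e in cds[tid])
            cds_s = min(tpos)
            t = TranscriptModel(tid, gid, chrom, strand, ex, cds_s, cds_s + cds_len)
        else:
            t = TranscriptModel(tid, gid, chrom, strand, ex, t.length, t.length)
        out.append(t)
    return out


def load_annotation(path: str | Path, canonical_policy: str = "longest_cds"):
    """Load a GTF or BED12 annotation.

    Returns ``(transcripts, canonical)`` where ``transcripts`` is the full
    list (one ``TranscriptModel`` each) and ``canonical`` maps each gene_id to
    its canonical transcript under ``canonical_policy`` (currently
    ``longest_cds``: longest CDS, ties broken by transcript length then id).
    """
    if canonical_policy != "longest_cds":
        raise ValueError(f"unknown canonical policy {canonical_policy!r}")
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        transcripts = _load_gtf(path)
    else:
        transcripts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip() and not line.startswith(("#", "track", "browser")):
                    transcripts.append(_parse_bed12_line(line, lineno))
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    canonical = {g: _select_canonical(ts) for g, ts in by_gene.items()}
    return transcripts, canonical


def write_bed12(transcripts, path: str | Path) -> None:
    """Write transcripts as BED12 (name = ``transcript_id|gene_id``)."""
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.exons[0][0], t.exons[-1][1]
            gpos = t.genomic_positions()
            if t.cds_length > 0:
                cds_g = sorted(
                    gpos[t.cds_start_transcript:
                         (t.cds_end_transcript if t.cds_end_transcript is not None
                          else t.length)])
                thick_s, thick_e = cds_g[0], cds_g[-1] + 1
            else:
                thick_s = thick_e = start
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offs = ",".join(str(s - start) for s, _ in t.exons)
            fh.write("\t".join(map(str, [
                t.chrom, start, end, f"{t.transcript_id}|{t.gene_id}", 0, t.strand,
                thick_s, thick_e, 0, len(t.exons), sizes, offs])) + "\n")


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``chrom[start:end]`` from a dict of strings or a pyfaidx-like accessor."""
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not in genome") from None
    return str(record[start:end])


def extract_five_prime_utr(t: TranscriptModel, genome=None) -> str:
    """5'UTR sequence of ``t`` in transcript orientation, RNA alphabet.

    Excludes the start codon (positions from ``cds_start_transcript`` on).
    ``genome`` may be omitted when ``t.sequence`` is set.  Minus-strand
    transcripts are reverse-complemented.
    """
    if t.cds_start_transcript == 0:
        return ""
    if t.sequence is not None:
        seq = t.sequence.upper().replace("T", "U")
    else:
        if genome is None:
            raise ValueError(f"{t.transcript_id}: no sequence and no genome accessor")
        parts = [_fetch(genome, t.chrom, s, e) for s, e in t.exons]
        seq = "".join(parts).upper().replace("T", "U")
        if t.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
    return seq[: t.cds_start_transcript]


def detect_utr_variants(transcripts, genome=None) -> GeneUTRSet:
    """Variant-5'UTR flags for the transcripts of one gene.

    ``has_alt_tss`` — at least two distinct genomic TSS coordinates;
    ``has_utr_intron`` — any exon-exon junction upstream of the CDS start.
    UTR sequences are collected (deduplicated by exact string equality) when
    sequence is available.
    """
    ts = list(transcripts)
    if not ts:
        raise ValueError("detect_utr_variants needs >=1 transcript")
    gene_ids = {t.gene_id for t in ts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(gene_ids)}")
    has_alt_tss = len({(t.chrom, t.strand, t.tss) for t in ts}) > 1
    has_utr_intron = any(
        any(j < t.cds_start_transcript for j in t.junctions_transcript()) for t in ts
    )
    utrs: list[str] = []
    for t in sorted(ts, key=lambda t: t.transcript_id):
        if t.sequence is not None or genome is not None:
            u = extract_five_prime_utr(t, genome)
            if u not in utrs:
                utrs.append(u)
    return GeneUTRSet(gene_ids.pop(), tuple(utrs), has_alt_tss, has_utr_intron)


def write_utr_fasta(transcripts, path: str | Path, genome=None) -> None:
    """Write one 5'UTR record per gene (canonical transcript order as given);
    transcripts with empty UTRs are skipped."""
    with open(path, "w") as fh:
        for t in transcripts:
            utr = extract_five_prime_utr(t, genome)
            if utr:
                fh.write(f">{t.gene_id}\n")
                for i in range(0, len(utr), 70):
                    fh.write(utr[i:i + 70] + "\n")
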