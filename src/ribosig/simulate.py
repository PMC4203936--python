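"""Synthetic ribosome-profiling experiments with known ground truth.

Emulates the structure of a two-condition (vehicle vs helicase-inhibitor)
profiling study: per condition, a ribosome-footprint library (~32-nt
footprints) and a fragmented-mRNA library, in replicate.  A configurable
minority of genes carries a true reduction (or increase) in translation
efficiency with unchanged mRNA abundance, and sensitive genes preferentially
receive long, structured, lower-GC 5'UTRs built with GC-rich
reverse-complementary stem insertions so that localized folding minima
coincide with GC peaks.

Counts are negative-binomial (gamma-Poisson) around library-size-normalized
expected abundances; dispersion -> 0 recovers Poisson sampling.  Everything is
driven by one seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

__all__ = [
    "SimulationConfig",
    "SimulatedTranscriptome",
    "simulate_transcriptome",
    "simulate_counts",
    "emit_alignments",
    "simulate_experiment",
]

CONDITIONS = ("dmso", "silvestrol")
_RC = str.maketrans("ACGU", "UGCA")
_TO_DNA = str.maketrans("U", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generative parameters.

    Fractions of affected genes and the replicate count echo the study design
    (a few percent of genes decreased/increased, n = 2 biological replicates);
    pool-level 5'UTR parameters (lengths ~490 vs ~220 nt, GC ~60 vs ~67%)
    echo the reported pool means.  Library sizes are desk-scale.
    """

    n_genes: int = 2000
    frac_sensitive: float = 0.034
    frac_resistant: float = 0.017
    effect_log2_sensitive: tuple[float, float] = (-2.5, 0.5)  # mean, sd
    effect_log2_resistant: tuple[float, float] = (1.8, 0.4)
    library_size: int = 5_000_000
    nb_dispersion: float = 0.01
    n_replicates: int = 2
    abundance_sigma: float = 1.0
    te_sigma: float = 0.25
    footprint_mean: float = 32.0
    footprint_sd: float = 1.5
    footprint_range: tuple[int, int] = (26, 36)
    mrna_frag_range: tuple[int, int] = (40, 100)
    psite_offset: int = 12
    # 5'UTR generation
    utr_len_mean_structured: float = 490.0
    utr_len_mean_plain: float = 220.0
    utr_len_mean_top: float = 120.0
    utr_len_sigma: float = 0.35
    utr_len_range: tuple[int, int] = (24, 600)
    utr_gc_structured: float = 0.55
    utr_gc_plain: float = 0.669
    utr_gc_top: float = 0.62
    stem_gc: float = 0.9
    sensitive_utr_mix: tuple[float, float, float] = (0.80, 0.15, 0.05)  # structured/plain/top
    insensitive_utr_mix: tuple[float, float, float] = (0.08, 0.88, 0.04)
    cds_len_mean: float = 1200.0
    cds_len_sigma: float = 0.3
    utr3_len: int = 100
    intergenic_gap: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_sensitive <= 1 and 0 <= self.frac_resistant <= 1
                and self.frac_sensitive + self.frac_resistant <= 1):
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.library_size <= 0 or self.n_genes <= 0:
            raise ValueError("n_genes and library_size must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedTranscriptome:
    transcripts: list[TranscriptModel]
    utr_sequences: dict[str, str]  # gene_id -> 5'UTR (RNA)
    truth: pd.DataFrame = field(repr=False)  # gene_id, true_class, shift, utr_class
    genome: dict[str, str] = field(repr=False)  # chrom -> DNA string


def _lognormal_int(rng, mean, sigma, lo, hi, size):
    mu = math.log(mean) - sigma ** 2 / 2
    vals = np.exp(rng.normal(mu, sigma, size))
    return np.clip(np.round(vals).astype(int), lo, hi)


def _random_seq(rng, n, gc):
    return "".join(rng.choice(["G", "C", "A", "U"],
                              p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2],
                              size=n))


def _structured_utr(rng, length, gc, stem_gc):
    """Background sequence with GC-rich stem/reverse-complement insertions."""
    seq = list(_random_seq(rng, length, gc))
    n_stems = max(1, length // 120)
    for _ in range(n_stems):
        stem_len = int(rng.integers(10, 18))
        loop = int(rng.integers(4, 9))
        span = 2 * stem_len + loop
        if span + 2 >= length:
            continue
        start = int(rng.integers(0, length - span))
        stem = _random_seq(rng, stem_len, stem_gc)
        seq[start:start + stem_len] = list(stem)
        rc = stem.translate(_RC)[::-1]
        seq[start + stem_len + loop:start + span] = list(rc)
    return "".join(seq)


def _top_utr(rng, length, gc):
    run = int(rng.integers(5, 13))
    pyr = "".join(rng.choice(["C", "U"], p=[0.6, 0.4], size=run))
    rest = _random_seq(rng, max(length - run - 1, 0), gc)
    return ("C" + pyr + rest)[:length]


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate gene models, 5'UTRs and ground-truth effect classes."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_sens = int(round(config.frac_sensitive * n))
    n_res = int(round(config.frac_resistant * n))
    classes = np.array(["sensitive"] * n_sens + ["resistant"] * n_res
                       + ["insensitive"] * (n - n_sens - n_res))
    rng.shuffle(classes)

    shifts = np.zeros(n)
    m_s, sd_s = config.effect_log2_sensitive
    m_r, sd_r = config.effect_log2_resistant
    shifts[classes == "sensitive"] = rng.normal(m_s, sd_s, n_sens)
    shifts[classes == "resistant"] = rng.normal(m_r, sd_r, n_res)

    utr_kinds = np.empty(n, dtype=object)
    for klass, mix in (("sensitive", config.sensitive_utr_mix),
                       ("resistant", config.insensitive_utr_mix),
                       ("insensitive", config.insensitive_utr_mix)):
        sel = classes == klass
        utr_kinds[sel] = rng.choice(["structured", "plain", "top"],
                                    p=np.array(mix) / sum(mix), size=sel.sum())

    lens = {
        "structured": config.utr_len_mean_structured,
        "plain": config.utr_len_mean_plain,
        "top": config.utr_len_mean_top,
    }
    gcs = {"structured": config.utr_gc_structured, "plain": config.utr_gc_plain,
           "top": config.utr_gc_top}
    lo, hi = config.utr_len_range
    cds_lens = _lognormal_int(rng, config.cds_len_mean, config.cds_len_sigma,
                              300, 10 ** 6, n)
    cds_lens = (cds_lens // 3) * 3

    transcripts, utrs, genome_parts = [], {}, []
    chrom = "chrSim"
    cursor = config.intergenic_gap
    rows = []
    for g in range(n):
        gid = f"gene{g:05d}"
        kind = utr_kinds[g]
        utr_len = int(_lognormal_int(rng, lens[kind], config.utr_len_sigma,
                                     lo, hi, 1)[0])
        if kind == "structured":
            utr = _structured_utr(rng, utr_len, gcs[kind], config.stem_gc)
        elif kind == "top":
            utr = _top_utr(rng, utr_len, gcs[kind])
        else:
            utr = _random_seq(rng, utr_len, gcs[kind])
        cds = "AUG" + _random_seq(rng, int(cds_lens[g]) - 6, 0.5) + "UAA"
        utr3 = _random_seq(rng, config.utr3_len, 0.5)
        tx = utr + cds + utr3
        strand = "+" if g % 2 == 0 else "-"
        start, end = cursor, cursor + len(tx)
        dna = tx.translate(_TO_DNA)
        if strand == "-":
            dna = dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genome_parts.append((start, dna))
        transcripts.append(TranscriptModel(
            transcript_id=f"tx{g:05d}", gene_id=gid, chrom=chrom, strand=strand,
            exons=((start, end),), cds_start_transcript=utr_len,
            cds_end_transcript=utr_len + len(cds), sequence=tx))
        utrs[gid] = utr
        rows.append((gid, classes[g], float(shifts[g]), kind))
        cursor = end + config.intergenic_gap

    chrom_seq = ["N"] * cursor
    for start, dna in genome_parts:
        chrom_seq[start:start + len(dna)] = list(dna)
    truth = pd.DataFrame(rows, columns=["gene_id", "true_class",
                                        "true_log2_te_shift", "utr_class"]
                         ).set_index("gene_id")
    return SimulatedTranscriptome(transcripts, utrs, truth,
                                  {chrom: "".join(chrom_seq)})


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(transcriptome: SimulatedTranscriptome,
                    config: SimulationConfig) -> pd.DataFrame:
    """Per-library gene counts: columns are (condition, libtype, replicate).

    mRNA expected abundance is identical across conditions; RF abundance is
    scaled by ``2**true_log2_te_shift`` in the treated condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = transcriptome.truth
    n = len(truth)
    tx_len = np.array([t.length for t in transcriptome.transcripts], dtype=float)
    cds_len = np.array([t.cds_length for t in transcriptome.transcripts], dtype=float)

    abundance = np.exp(rng.normal(0.0, config.abundance_sigma, n))
    baseline_te = np.exp(rng.normal(0.0, config.te_sigma, n))
    shift = truth["true_log2_te_shift"].to_numpy()

    cols = {}
    for cond in CONDITIONS:
        te = baseline_te * (2.0 ** shift if cond == "silvestrol" else 1.0)
        w_rf = abundance * cds_len * te
        w_mrna = abundance * tx_len
        for libtype, w in (("rf", w_rf), ("mrna", w_mrna)):
            mean = config.library_size * w / w.sum()
            for rep in range(config.n_replicates):
                cols[(cond, libtype, rep)] = _nb_draw(rng, mean, config.nb_dispersion)
    out = pd.DataFrame(cols, index=truth.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["condition", "libtype", "replicate"])
    return out.sort_index(axis=1)


def _trunc_normal_int(rng, mean, sd, lo, hi, size):
    vals = np.round(rng.normal(mean, sd, size)).astype(int)
    while True:
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            return vals
        vals[bad] = np.round(rng.normal(mean, sd, bad.sum())).astype(int)


def emit_alignments(transcriptome: SimulatedTranscriptome, counts: pd.DataFrame,
                    config: SimulationConfig, out_dir) -> dict:
    """Write genome FASTA, BED12 annotation and one SAM file per library.

    RF reads are placed so the P-site (5' end + ``config.psite_offset``) falls
    uniformly within the CDS; mRNA fragment midpoints are uniform over the
    transcript.  Output is deterministic for a given config/seed.
    """
    import pysam

    from .annotation import write_bed12

    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    genome_path = out_dir / "genome.fasta"
    with open(genome_path, "w") as fh:
        for chrom, seq in transcriptome.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    bed_path = out_dir / "annotation.bed12"
    write_bed12(transcriptome.transcripts, bed_path)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in transcriptome.genome.items()],
    }
    tx_by_gene = {t.gene_id: t for t in transcriptome.transcripts}
    lo_f, hi_f = config.footprint_range
    lo_m, hi_m = config.mrna_frag_range
    sam_paths = {}
    for key in counts.columns:
        cond, libtype, rep = key
        path = out_dir / f"{cond}_{libtype}_rep{rep}.sam"
        sam_paths[key] = path
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            serial = 0
            for gid, c in counts[key].items():
                t = tx_by_gene[gid]
                c = int(c)
                if c == 0:
                    continue
                if libtype == "rf":
                    lengths = _trunc_normal_int(rng, config.footprint_mean,
                                                config.footprint_sd, lo_f, hi_f, c)
                    tpos = rng.integers(t.cds_start_transcript,
                                        t.cds_end_transcript, c)
                    t5 = tpos - config.psite_offset  # 5' end, transcript coords
                else:
                    lengths = rng.integers(lo_m, hi_m + 1, c)
                    mid = rng.integers(0, t.length, c)
                    t5 = mid - (lengths - 1) // 2
                exon_start, exon_end = t.exons[0]
                for ln, t5i in zip(lengths, t5):
                    if t.strand == "+":
                        gstart = exon_start + int(t5i)
                    else:
                        g5 = exon_end - 1 - int(t5i)
                        gstart = g5 - int(ln) + 1
                    a = pysam.AlignedSegment()
                    a.query_name = f"{cond}_{libtype}_{rep}_{serial}"
                    serial += 1
                    a.reference_id = 0
                    a.reference_start = int(gstart)
                    a.cigarstring = f"{int(ln)}M"
                    a.flag = 16 if t.strand == "-" else 0
                    a.mapping_quality = 255
                    a.set_tag("NH", 1)
                    fh.write(a)
    return {"genome": genome_path, "bed12": bed_path, "sam": sam_paths}


def simulate_experiment(config: SimulationConfig):
    """Convenience wrapper: transcriptome plus counts."""
    txome = simulate_transcriptome(config)
    counts = simulate_counts(txome, config)
    return txome, counts
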