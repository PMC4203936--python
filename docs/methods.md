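# Methods

This note documents the models behind `ribosig`, the defaults that matter,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Read quantification

Footprint reads are collapsed to the genomic base occupying the ribosomal
P-site, taken as the 5′ end plus a fixed offset.  The offset defaults to
+12 nt — the field-standard value for ~32-nt mammalian footprints — and is
configurable per read length (`offset_table`), since the exact offset table
used in any given study is rarely published.  Fragmented-mRNA reads are
collapsed to the read midpoint (`floor((len−1)/2)` from the 5′ end; even
lengths round toward 5′).

Two exclusion rules are applied, deliberately taking the most conservative
reading of the usual uniqueness criteria: (1) reads reported with more than
one alignment are dropped at the read level, and (2) any genomic position
covered by more than one canonical transcript is masked at the position
level — reads landing there are counted for no gene, and the masked
positions are removed from the RPKM length denominator ("effective length",
the default; `length_mode="full"` uses the plain transcript length).  rRNA
removal is assumed to have happened at alignment time; the package only
offers read-level filtering, not an rRNA index.

RPKM = count / ((ℓ/10³) · (library/10⁶)) with ℓ the effective length and
the library size defaulting to the number of counted reads.

## TE statistics

TE = RPKM_RF / RPKM_mRNA per condition; genes with zero mRNA signal are
"unquantified", never infinities.  The treatment effect is the TE ratio, and
classification happens on **log₂** of that ratio: the observed effect
distribution is approximately symmetric about its center on a log scale,
whereas raw ratios are bounded below by zero and cannot be (``z_space`` is
not exposed as a CLI flag; `zscore_classify` simply takes whatever vector it
is given).  z-scores use the population standard deviation over quantified
genes, so the reported z-vector has mean 0 and sd 1 exactly.  Thresholds
±1.5 define decreased/increased calls.

Replicates are pooled by summing counts before RPKM (`replicate_mode=
"pool"`); `"mean-te"` averages per-replicate TEs instead.  The robust-
measurement filter keeps a gene only when **every** library has ≥
`min_count` reads (default 32, a calibration knob — the field has no
canonical value).  Note a systematic consequence: genes with very strong TE
losses lose footprint coverage in the treated libraries, so under-sequenced
experiments silently drop the strongest responders at this filter (see the
library-depth discussion under "Synthetic data").

The Mann–Whitney U test is implemented with midrank ties; for n₁+n₂ ≤ 16
the two-sided p is permutation-exact by enumerating all C(n,n₁) group
assignments of the pooled observed values (correct in the presence of ties),
otherwise the tie-corrected normal approximation with continuity correction
is used.  Replicate agreement is summarized as Pearson r on log₂(RPKM+ε),
ε = 0.5 by default.

## RNA folding

The folding engine is a parameter-table-driven nearest-neighbor model over
nested secondary structures: hairpins, stacks, bulges, internal loops and
affine-scored multiloops; no pseudoknots; lonely pairs allowed; minimum
hairpin loop 3 nt; `N` never pairs.  Two plain-text tables ship with the
package:

- **`nn37`** (default): a Turner-style 37 °C free-energy set authored for
  this package — published Watson–Crick stack values, representative wobble
  stacks, tabulated loop initiations with Jacobson–Stockmayer
  `1.75·RT·ln(n/n_max)` extrapolation, multiloop offset/branch/unpaired =
  3.4/0.4/0.0 kcal/mol, terminal AU/GU penalty 0.5, internal-loop asymmetry
  0.6 per nt.
- **`mini`**: a compact, GC-counting didactic table for hand-checkable
  examples.

Numerical/semantic choices worth knowing:

- Internal/bulge loops are capped at a combined span of 30 unpaired nt
  (standard practice; keeps the fill O(n³)).
- The terminal AU/GU penalty is charged exactly where a pair borders the
  exterior loop or a multiloop (branches and the multiloop closing pair) —
  not at hairpin or internal-loop closures.  The same rule is used by the
  MFE fill, the partition function, and the exhaustive-enumeration oracle in
  the test suite, which scores structures by explicit loop decomposition.
- Ties in the traceback resolve to the open chain first, then to the
  5′-most opening pair, making `dG == 0 ⇔ fully unpaired` an invariant.
- The O(n³) fill is numba-compiled; a 948-nt sequence folds in about a
  second, and the five bundled reporter UTRs (236–948 nt) fold in a few
  seconds total.
- The McCaskill partition function uses an unambiguous decomposition of the
  same structure space, computed entirely in log space (no overflow for
  arbitrarily stable sequences), with an outside pass giving exact base-pair
  probabilities; both Z and P(i,j) agree with exhaustive enumeration to
  1e-9 relative on small instances.  RT = 0.616 kcal/mol (37 °C); the
  parameters are plain free energies, so an explicit `temperature` only
  rescales RT, it does not re-derive enthalpies.

**Parameter provenance.**  The study this package re-implements reported
5′UTR ΔG values from the CONTRAfold algorithm.  CONTRAfold's learned
parameter set is not redistributable here, so the default `nn37` table is a
thermodynamic nearest-neighbor set instead.  Consequences: the *ordering* of
the five bundled reporter UTRs by stability (ROCK1 < ARF6wt < ARF6mut <
PFN2 < CyclinD1) is reproduced — and cross-checked against an independent
folding engine in the tests — but the absolute ΔG magnitudes differ
systematically from the originally reported numbers (thermodynamic tables
fold GC-rich sequences more stably than CONTRAfold's learned scores; the
structure-disrupted ARF6 mutant shows the largest discrepancy).  Analyses in
this package that depend on ΔG use it comparatively (orderings, pool tests,
a threshold exposed as configuration), which is robust to the
parameterization; absolute printed values are not.

Sliding-window profiles fold every w-nt fragment (default w = 20, step 1)
and report per-window ΔG or GC%; the window count is L − w + 1.

## Mutation design

`design_destructuring_mutations` automates "remove base-pairing without
changing length or GC": candidate moves are the GC-preserving transversions
G↔C and A↔U inside the targeted windows; moves are accepted greedily by
window-ΔG gain; with `check_global` (default) an accepted move must also not
lower the full-length ΔG (a move that stabilizes a new long-range pairing is
vetoed and banned).  Every (CGG)₄ occurrence and the 3′ start-codon context
(last 6 nt) are protected.  Windows that cannot be brought above the target
threshold are *reported* unresolved, not raised.  The procedure it
reconstructs was manual in the original study; acceptance of this module is
property-based (ΔG raised, length/GC/motifs preserved), never base-identity
to any particular published mutant.

## 5′UTR signature

TOP: first base C followed by an uninterrupted pyrimidine run of 4–15 nt;
TOP-like: a pyrimidine run ≥5 starting within the first 4 nt when the strict
rule fails (both bounds configurable — the literature definitions vary).
The (CGG)₄ scan reports all overlapping 12-nt matches, and 9-nt (CGG)₃
matches separately (the repeat length is quoted inconsistently in the
literature; both are reported rather than resolved).  Categories are
assigned under the precedence structured → variant → TOP → other, with
"structured" meaning ΔG below a configurable threshold (default −104
kcal/mol, matching the decreased-pool mean ΔG reported in the source
analysis).  Because the raw flags overlap, `signature_summary` emits both a
precedence-resolved table (sums to 100%) and an overlap table (may exceed
100%); published per-category percentages for such pools typically resemble
the overlap table.

Variant 5′UTRs: a gene is "variant" when its transcripts have ≥2 distinct
genomic TSS coordinates or any exon junction upstream of the CDS start.
Which annotation source defines the transcript set is the caller's choice;
the flags are computed from whatever transcripts are supplied.

## Synthetic data

The generator emulates the *structure* of a two-condition profiling study:
two conditions × {RF, mRNA} × 2 replicates; gene abundances LogNormal(σ=1);
counts Gamma–Poisson (negative binomial, single dispersion 0.01, Poisson in
the dispersion→0 limit); mRNA expected abundance identical across
conditions; RF abundance multiplied by 2^shift in treatment, with shifts
drawn N(−2.5, 0.5) for the sensitive fraction (3.4% by default) and
N(+1.8, 0.4) for the resistant fraction (1.7%).  Sensitive genes
preferentially receive "structured"-class 5′UTRs: longer (LogNormal mean
490 nt vs 220 nt for the plain class, capped at 600 nt to keep desk-scale
folding affordable), lower overall GC (0.55 vs 0.67) but with GC-rich
stem/reverse-complement insertions so window profiles show localized ΔG
minima coinciding with GC peaks; a small TOP class gets C+pyrimidine starts
and short UTRs.  Library size defaults to 5×10⁶ reads per library: the
source study sequenced ~43M reads over ~17,700 transcripts (~2,400
reads/gene/library), and 2,000 genes × ~2,400 preserves that per-gene depth
at desk scale — this matters because shallower libraries push strongly
responding genes below the robust-measurement filter in the treated
condition and silently truncate recall.  Reads are emitted as SAM (plus
genome FASTA and BED12) with footprint lengths ~N(32, 1.5) truncated to
[26, 36] and mRNA fragments uniform on [40, 100]; placement guarantees that
P-sites fall in the CDS and midpoints in the transcript, so re-quantifying
the emitted reads recovers the simulated counts exactly when nothing is
masked.  Everything derives from a single seed; outputs are byte-identical
across runs.

What the generator does **not** emulate: isoform structure (one single-exon
transcript per gene), rRNA contamination, sequence-dependent library bias,
codon-level ribosome dynamics, or correlated dispersion across genes.
Passing recovery tests therefore demonstrates correctness of the pipeline's
inference under its own statistical assumptions, not robustness to the full
messiness of real libraries.

## Scale choices in the test suite

Recovery checks run at 2,000 genes with 7.5% sensitive (so the decreased
pool is large enough for stable pool statistics), 5×10⁶ reads/library, and
full-UTR folding of all genes (~2 minutes); enumeration oracles run on
sequences ≤ 14 nt where exhaustive structure listing is exact.  These sizes
are the package's own desk-scale choices and are trivially adjustable
through `SimulationConfig`.

## Known limitations

- Absolute ΔG values are parameterization-dependent (see above); only
  comparative statements transfer across energy models.
- The energy model omits terminal mismatches, dangles and special-loop
  bonuses; its MFE values are correspondingly less negative than full
  Turner-2004 engines such as ViennaRNA.
- The mutation designer is greedy and single-substitution; it makes no
  optimality claim.
- `robust_filter` interacts with strong effects as described; depth should
  be chosen (or `min_count` lowered) with that in mind.
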