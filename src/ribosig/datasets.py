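"""Bundled sequence fixtures.

The five reporter 5'UTRs (ARF6 wild type and structure-disrupted mutant,
CyclinD1, ROCK1, PFN2) as printed in the source study's materials; the
ARF6mut record keeps its lowercase letters marking mutated residues, and the
reporter sequences carry their cloning context as printed.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

from Bio import SeqIO

__all__ = ["load_reporter_utrs", "REPORTER_NAMES"]

REPORTER_NAMES = ("ARF6wt", "ARF6mut", "CyclinD1", "ROCK1", "PFN2")


def load_reporter_utrs() -> dict[str, str]:
    """Reporter 5'UTR sequences keyed by name (case preserved)."""
    text = resources.files("ribosig.data").joinpath("reporter_5utrs.fasta").read_text()
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(StringIO(text), "fasta")}
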