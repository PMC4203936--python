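"""Structure-disrupting mutation design for 5'UTRs.

Reconstructs, as an automated procedure, the strategy of removing base-pairing
in structured regions by single-nucleotide changes while keeping the sequence
length and overall GC content identical: candidate moves are the GC-preserving
transversions G<->C and A<->U inside the targeted windows, accepted greedily
when they raise the window's folding free energy, optionally vetoed if they
would lower the full-length free energy.  Protected motifs (by default every
(CGG)4 occurrence) and the 3' start-codon context are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy import EnergyModel, load_model
from .fold import mfe_fold
from .signature import CGG4_MOTIF

__all__ = ["MutationReport", "design_destructuring_mutations"]

_SWAP = {"G": "C", "C": "G", "A": "U", "U": "A"}


@dataclass
class MutationReport:
    original: str
    mutant: str  # mutated positions in lowercase
    changes: list[tuple[int, str, str]]  # (position, ref, alt)
    resolved_windows: list[tuple[int, int]]
    unresolved_windows: list[tuple[int, int]]
    dg_before: float
    dg_after: float

    @property
    def sequence(self) -> str:
        return self.mutant.upper()


def _protected_positions(seq: str, motifs, tail: int) -> set[int]:
    out: set[int] = set()
    for motif in motifs:
        start = 0
        while (hit := seq.find(motif, start)) != -1:
            out.update(range(hit, hit + len(motif)))
            start = hit + 1
    out.update(range(max(len(seq) - tail, 0), len(seq)))
    return out


def design_destructuring_mutations(
    seq: str,
    target_windows,
    model: EnergyModel | str = "nn37",
    window_dg_threshold: float = -5.0,
    protect_motifs: tuple[str, ...] = (CGG4_MOTIF,),
    protect_tail: int = 6,
    check_global: bool = True,
    max_changes_per_window: int = 8,
) -> MutationReport:
    """Raise the folding free energy of targeted windows by point mutation.

    ``target_windows`` is a list of (start, end) half-open intervals.  Within
    each window, GC-preserving substitutions are applied greedily (best window
    dG gain first) until the window folds no more stably than
    ``window_dg_threshold`` or no admissible improving move remains; a window
    left below threshold is reported unresolved, never raised as an error.
    With ``check_global`` every accepted move must also not lower the
    full-length free energy.
    """
    if isinstance(model, str):
        model = load_model(model)
    s = seq.upper().replace("T", "U")
    for a, b in target_windows:
        if not (0 <= a < b <= len(s)):
            raise ValueError(f"window ({a}, {b}) outside sequence")
    protected = _protected_positions(s, protect_motifs, protect_tail)
    work = list(s)
    changes: list[tuple[int, str, str]] = []
    dg_before = mfe_fold(s, model).dg if target_windows else 0.0
    current_global = dg_before
    resolved, unresolved = [], []

    for (a, b) in target_windows:
        banned: set[int] = set()
        for _ in range(max_changes_per_window):
            frag = "".join(work[a:b])
            win_dg = mfe_fold(frag, model).dg
            if win_dg >= window_dg_threshold:
                break
            best_gain, best_pos = 0.0, None
            for pos in range(a, b):
                if pos in protected or pos in banned:
                    continue
                ref = work[pos]
                work[pos] = _SWAP[ref]
                gain = mfe_fold("".join(work[a:b]), model).dg - win_dg
                work[pos] = ref
                if gain > best_gain + 1e-9:
                    best_gain, best_pos = gain, pos
            if best_pos is None:
                break
            ref = work[best_pos]
            work[best_pos] = _SWAP[ref]
            if check_global:
                new_global = mfe_fold("".join(work), model).dg
                if new_global < current_global - 1e-9:
                    work[best_pos] = ref  # would stabilize elsewhere; veto
                    banned.add(best_pos)
                    continue
                current_global = new_global
            changes.append((best_pos, ref, _SWAP[ref]))
        final_dg = mfe_fold("".join(work[a:b]), model).dg
        (resolved if final_dg >= window_dg_threshold else unresolved).append((a, b))

    dg_after = mfe_fold("".join(work), model).dg if target_windows else dg_before
    mutated = set(p for p, _, _ in changes)
    mutant = "".join(c.lower() if i in mutated else c for i, c in enumerate(work))
    return MutationReport(s, mutant, changes, resolved, unresolved,
                         dg_before, dg_after)
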