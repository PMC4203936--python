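"""Brute-force reference implementations used only by the test suite.

Exhaustively enumerates all nested secondary structures of short sequences and
scores each one by explicit loop decomposition, independently of the dynamic
programs under test.  Feasible up to ~16 nt.
"""

from __future__ import annotations

import math
from functools import lru_cache

from ribosig.energy import EnergyModel
from ribosig.fold import FoldResult


def _pair_ok(a: str, b: str) -> bool:
    return a + b in ("AU", "UA", "GC", "CG", "GU", "UG")


def enumerate_structures(seq: str, min_hairpin: int = 3) -> list[list[tuple[int, int]]]:
    """All nested pair sets over ``seq`` (upper-case RNA), incl. the open chain."""
    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i + 1 <= 0:
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for l in range(i + min_hairpin + 1, j + 1):
            if _pair_ok(s[i], s[l]):
                for inner in rec(i + 1, l - 1):
                    for rest in rec(l + 1, j):
                        out.append(((i, l),) + inner + rest)
        return tuple(out)

    return [sorted(st) for st in rec(0, len(s) - 1)]


def structure_energy(seq: str, pairs: list[tuple[int, int]], model: EnergyModel) -> float:
    """Score a structure by explicit loop decomposition.

    Terminal AU/GU penalties are charged for pairs adjacent to the exterior
    loop or a multiloop (branches and the multiloop closing pair), matching the
    documented model semantics.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    partner = {i: j for i, j in pairs}
    partner.update({j: i for i, j in pairs})

    def au_pen(i, j):
        return model.terminal_au if s[i] + s[j] not in ("GC", "CG") else 0.0

    def children(i: int, j: int) -> list[tuple[int, int]]:
        """Branches immediately interior to (i, j) (or of the exterior loop)."""
        out = []
        k = i
        while k <= j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    total = 0.0
    # exterior loop: AU penalty per branch, no other term
    for (a, b) in children(0, n - 1):
        total += au_pen(a, b)

    for (i, j) in pairs:
        kids = children(i + 1, j - 1)
        if not kids:
            total += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                from ribosig.energy import PAIR_INDEX
                total += float(model.stack[PAIR_INDEX[s[i] + s[j]], PAIR_INDEX[s[k] + s[l]]])
            elif n1 == 0 or n2 == 0:
                total += model.bulge_energy(n1 + n2)
            else:
                total += model.internal_energy(n1, n2)
            if n1 + n2 > model.max_loop:
                total += 1e9  # outside the permitted two-loop span
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (model.multiloop_offset
                      + model.multiloop_branch * (len(kids) + 1)
                      + model.multiloop_unpaired * unpaired
                      + au_pen(i, j))
            for (a, b) in kids:
                total += au_pen(a, b)
    return total


def brute_force_fold(seq: str, model: EnergyModel) -> FoldResult:
    """MFE by exhaustive enumeration (ties: fewest pairs, then lexicographic)."""
    best, best_pairs = 0.0, []
    for pairs in enumerate_structures(seq, model.min_hairpin):
        e = structure_energy(seq, pairs, model)
        if e < best - 1e-12:
            best, best_pairs = e, pairs
    db = ["."] * len(seq)
    for i, j in best_pairs:
        db[i], db[j] = "(", ")"
    return FoldResult("", seq, best, "".join(db), model.name)


def brute_force_partition(seq: str, model: EnergyModel):
    """(Z, pair-probability dict) by exhaustive enumeration."""
    structures = enumerate_structures(seq, model.min_hairpin)
    z = 0.0
    prob: dict[tuple[int, int], float] = {}
    for pairs in structures:
        w = math.exp(-structure_energy(seq, pairs, model) / model.rt)
        z += w
        for p in pairs:
            prob[p] = prob.get(p, 0.0) + w
    return z, {p: w / z for p, w in prob.items()}
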