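"""Minimum-free-energy RNA secondary structure prediction.

Dynamic program over the nested-structure space (hairpins, stacks, bulges,
internal loops up to a span cap, and affine-scored multiloops), with a
deterministic traceback.  Pseudoknots are excluded; lonely pairs are allowed;
``N`` never pairs.  The terminal AU/GU penalty is charged for pairs bordering
the exterior loop or a multiloop (branches and the multiloop closing pair).

The O(n^3) fill is compiled with numba; a ~950-nt sequence folds in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import (
    INF,
    IS_AU_PAIR,
    PAIR_TABLE,
    EnergyModel,
    encode_sequence,
    load_model,
)

__all__ = ["FoldResult", "WindowProfile", "mfe_fold", "window_profile", "gc_content"]


@dataclass(frozen=True)
class FoldResult:
    """An MFE prediction: free energy (kcal/mol) plus one optimal structure."""

    seq_id: str
    sequence: str
    dg: float
    structure: str
    model: str

    @property
    def pairs(self) -> list[tuple[int, int]]:
        stack, out = [], []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


@dataclass(frozen=True)
class WindowProfile:
    """Per-window metric values along a sequence (step-1 sliding windows)."""

    seq_id: str
    metric: str  # "dG" or "GC"
    window: int
    step: int
    starts: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.starts)


@njit(cache=True)
def _fill(codes, pair_tab, is_au, stack, hp_e, bu_e, in_e, asym,
          max_loop, min_hp, ml_a, ml_b, ml_c, au_pen):  # pragma: no cover
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)   # multiloop segment, >=1 branch
    WM1 = np.full((n, n), INF)  # single branch starting at i, trailing unpaired
    W = np.zeros(n + 1)         # exterior; W[j+1] covers 0..j

    for d in range(min_hp + 1, n):
        for i in range(n - d):
            j = i + d
            p = pair_tab[codes[i], codes[j]]
            if p >= 0:
                best = hp_e[j - i - 1]
                # two-loops: inner pair (k, l), loop sizes n1 + n2 <= max_loop
                kmax = min(j - min_hp - 2, i + max_loop + 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = max(k + min_hp + 1, j - 1 - (max_loop - n1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            e = stack[p, pair_tab[codes[k], codes[l]]]
                        elif n1 == 0 or n2 == 0:
                            e = bu_e[n1 + n2]
                        else:
                            e = in_e[n1 + n2] + asym * abs(n1 - n2)
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop closure: interior = WM[i+1, k-1] + WM1[k, j-1]
                close = ml_a + ml_b + (au_pen if is_au[p] else 0.0)
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                        cand = close + WM[i + 1, k - 1] + WM1[k, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best

            # WM1[i, j]: branch (i, l) plus unpaired tail
            best1 = WM1[i, j - 1] + ml_c if WM1[i, j - 1] < INF else INF
            if V[i, j] < INF:
                pb = pair_tab[codes[i], codes[j]]
                cand = V[i, j] + ml_b + (au_pen if is_au[pb] else 0.0)
                if cand < best1:
                    best1 = cand
            WM1[i, j] = best1

            # WM[i, j]: >=1 branch
            bestm = WM1[i, j]
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_c < bestm:
                bestm = WM[i + 1, j] + ml_c
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM1[k, j] < INF:
                    cand = WM[i, k - 1] + WM1[k, j]
                    if cand < bestm:
                        bestm = cand
            WM[i, j] = bestm

    for j in range(n):
        best = W[j]
        for k in range(j):
            if V[k, j] < INF:
                pb = pair_tab[codes[k], codes[j]]
                cand = W[k] + V[k, j] + (au_pen if is_au[pb] else 0.0)
                if cand < best:
                    best = cand
        if V[0, j] < INF:
            pb = pair_tab[codes[0], codes[j]]
            cand = V[0, j] + (au_pen if is_au[pb] else 0.0)
            if cand < best:
                best = cand
        W[j + 1] = best

    return V, WM, WM1, W


_EPS = 1e-7


def _traceback(codes, V, WM, WM1, W, model: EnergyModel, hp_e, bu_e, in_e):
    """Recover one optimal structure; ties prefer unpaired, then 5'-most pairs."""
    n = len(codes)
    pair_of = np.full(n, -1, dtype=np.int64)
    au = np.where(IS_AU_PAIR, model.terminal_au, 0.0)
    ml_a, ml_b, ml_c = model.multiloop_offset, model.multiloop_branch, model.multiloop_unpaired

    def au_pen(i, j):
        return au[PAIR_TABLE[codes[i], codes[j]]]

    stack_jobs = [("W", 0, n - 1)]
    while stack_jobs:
        kind, i, j = stack_jobs.pop()
        if kind == "W":
            # W indexed as in _fill: W[j+1] over 0..j
            while j >= 0 and abs(W[j + 1] - W[j]) <= _EPS:
                j -= 1
            if j < 0:
                continue
            for k in range(j + 1):
                base = W[k] if k > 0 else 0.0
                if V[k, j] < INF and abs(W[j + 1] - (base + V[k, j] + au_pen(k, j))) <= _EPS:
                    stack_jobs.append(("V", k, j))
                    if k > 0:
                        stack_jobs.append(("W", 0, k - 1))
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in exterior loop")
        elif kind == "V":
            pair_of[i], pair_of[j] = j, i
            p = PAIR_TABLE[codes[i], codes[j]]
            e = V[i, j]
            if abs(e - hp_e[j - i - 1]) <= _EPS:
                continue
            done = False
            kmax = min(j - model.min_hairpin - 2, i + model.max_loop + 1)
            for k in range(i + 1, kmax + 1):
                n1 = k - i - 1
                lmin = max(k + model.min_hairpin + 1, j - 1 - (model.max_loop - n1))
                for l in range(lmin, j):
                    if V[k, l] >= INF:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        le = model.stack[p, PAIR_TABLE[codes[k], codes[l]]]
                    elif n1 == 0 or n2 == 0:
                        le = bu_e[n1 + n2]
                    else:
                        le = in_e[n1 + n2] + model.internal_asym * abs(n1 - n2)
                    if abs(e - (le + V[k, l])) <= _EPS:
                        stack_jobs.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            close = ml_a + ml_b + au_pen(i, j)
            for k in range(i + 2, j - 1):
                if (WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF
                        and abs(e - (close + WM[i + 1, k - 1] + WM1[k, j - 1])) <= _EPS):
                    stack_jobs.append(("M", i + 1, k - 1))
                    stack_jobs.append(("M1", k, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise AssertionError("traceback failure at paired cell")
        elif kind == "M1":
            while j > i and WM1[i, j - 1] < INF and abs(WM1[i, j] - (WM1[i, j - 1] + ml_c)) <= _EPS:
                j -= 1
            stack_jobs.append(("V", i, j))
        else:  # M
            while i < j and WM[i + 1, j] < INF and abs(WM[i, j] - (WM[i + 1, j] + ml_c)) <= _EPS:
                i += 1
            if abs(WM[i, j] - WM1[i, j]) <= _EPS:
                stack_jobs.append(("M1", i, j))
                continue
            for k in range(i + 1, j + 1):
                if (WM[i, k - 1] < INF and WM1[k, j] < INF
                        and abs(WM[i, j] - (WM[i, k - 1] + WM1[k, j])) <= _EPS):
                    stack_jobs.append(("M", i, k - 1))
                    stack_jobs.append(("M1", k, j))
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in multiloop segment")

    out = []
    for i, q in enumerate(pair_of):
        out.append("." if q < 0 else ("(" if q > i else ")"))
    return "".join(out)


def mfe_fold(seq: str, model: EnergyModel | str = "nn37", seq_id: str = "") -> FoldResult:
    """Predict the minimum free energy and one optimal structure of ``seq``.

    Parameters
    ----------
    seq:
        RNA or DNA string over {A,C,G,U,T,N}; case-insensitive, N never pairs.
    model:
        An :class:`~ribosig.energy.EnergyModel` or a shipped table name.

    The returned free energy is <= 0: the open chain (dG = 0) is always an
    admissible structure.
    """
    if isinstance(model, str):
        model = load_model(model)
    codes = encode_sequence(seq)
    n = len(codes)
    if n <= model.min_hairpin + 1:
        return FoldResult(seq_id, seq, 0.0, "." * n, model.name)
    hp_e, bu_e, in_e = model.extended_tables(n)
    au = np.where(IS_AU_PAIR, model.terminal_au, 0.0).astype(np.float64)
    V, WM, WM1, W = _fill(
        codes, PAIR_TABLE, IS_AU_PAIR, model.stack, hp_e, bu_e, in_e,
        model.internal_asym, model.max_loop, model.min_hairpin,
        model.multiloop_offset, model.multiloop_branch, model.multiloop_unpaired,
        model.terminal_au,
    )
    dg = float(W[n])
    if dg >= -_EPS:  # ties resolve to the open chain
        return FoldResult(seq_id, seq, 0.0, "." * n, model.name)
    structure = _traceback(codes, V, WM, WM1, W, model, hp_e, bu_e, in_e)
    return FoldResult(seq_id, seq, dg, structure, model.name)


def gc_content(seq: str) -> float:
    """GC percentage of ``seq`` (case-insensitive; errors on empty input)."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def window_profile(seq: str, w: int = 20, step: int = 1, metric: str = "dG",
                   model: EnergyModel | str = "nn37", seq_id: str = "") -> WindowProfile:
    """Sliding-window dG or GC profile (w-nt windows, default step 1)."""
    if w < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    if metric not in ("dG", "GC"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(model, str) and metric == "dG":
        model = load_model(model)
    starts = np.arange(0, max(len(seq) - w + 1, 0), step)
    values = np.empty(len(starts))
    for idx, s in enumerate(starts):
        frag = seq[s:s + w]
        values[idx] = mfe_fold(frag, model).dg if metric == "dG" else gc_content(frag)
    return WindowProfile(seq_id, metric, w, step, starts, values)
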