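"""McCaskill partition function and base-pair probabilities.

Inside/outside recursions over the same nested-structure space as
:mod:`ribosig.fold`, under an unambiguous decomposition (every structure is
generated exactly once), so that ``Z = sum_s exp(-E(s)/RT)`` including the
open chain.  Computation is carried out entirely in log space, which keeps
arbitrarily long, strongly folding sequences free of overflow.

The shipped parameter tables are 37C free energies; an explicit ``temperature``
only rescales RT (no enthalpy/entropy split is modeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import IS_AU_PAIR, PAIR_TABLE, EnergyModel, encode_sequence, load_model

NEG = -np.inf


@dataclass(frozen=True)
class PartitionResult:
    """Ensemble free energy (kcal/mol) and base-pair probability matrix."""

    seq_id: str
    log_z: float
    ensemble_free_energy: float
    bpp: np.ndarray = field(repr=False)
    model: str = ""


def _logsumexp(arr: np.ndarray) -> float:
    m = np.max(arr)
    if not np.isfinite(m):
        return NEG
    return float(m + np.log(np.sum(np.exp(arr - m))))


def partition_function(seq: str, model: EnergyModel | str = "nn37",
                       temperature: float | None = None,
                       seq_id: str = "") -> PartitionResult:
    """Compute ``-RT ln Z`` and the matrix ``P[i, j] = P(i pairs j)``.

    ``temperature`` is in Kelvin (default 310.15, i.e. 37C).
    """
    if isinstance(model, str):
        model = load_model(model)
    codes = encode_sequence(seq)
    n = len(codes)
    rt = model.rt if temperature is None else model.rt * temperature / 310.15
    bpp = np.zeros((n, n))
    if n <= model.min_hairpin + 1:
        return PartitionResult(seq_id, 0.0, 0.0, bpp, model.name)

    hp_e, bu_e, in_e = model.extended_tables(n)
    minh, cap = model.min_hairpin, model.max_loop
    ml_a, ml_b, ml_c = model.multiloop_offset, model.multiloop_branch, model.multiloop_unpaired
    au = np.where(IS_AU_PAIR, model.terminal_au, 0.0)
    ptab = PAIR_TABLE

    lqc = -ml_c / rt
    lqa = -ml_a / rt

    def lau(i, j):
        return -au[ptab[codes[i], codes[j]]] / rt

    def lqbau(i, j):
        return -(ml_b + au[ptab[codes[i], codes[j]]]) / rt

    def two_loop(i, j, k, l):
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            e = model.stack[ptab[codes[i], codes[j]], ptab[codes[k], codes[l]]]
        elif n1 == 0 or n2 == 0:
            e = bu_e[n1 + n2]
        else:
            e = in_e[n1 + n2] + model.internal_asym * abs(n1 - n2)
        return -e / rt

    lZb = np.full((n, n), NEG)
    lZm = np.full((n, n), NEG)   # multiloop segment, >=1 branch
    lZmF = np.full((n, n), NEG)  # exactly one branch, starting at i
    lZmM = np.full((n, n), NEG)  # branch at i plus >=1 further branch

    # ---- inside ----
    for d in range(minh + 1, n):
        for i in range(n - d):
            j = i + d
            p = ptab[codes[i], codes[j]]
            if p >= 0:
                terms = [-hp_e[j - i - 1] / rt]
                kmax = min(j - minh - 2, i + cap + 1)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + minh + 1, j - 1 - (cap - (k - i - 1)))
                    for l in range(lmin, j):
                        if lZb[k, l] > NEG:
                            terms.append(lZb[k, l] + two_loop(i, j, k, l))
                close = lqa + lqbau(i, j)
                for k in range(i + 2, j - 1):
                    if lZmM[k, j - 1] > NEG:
                        terms.append(close + lqc * (k - i - 1) + lZmM[k, j - 1])
                lZb[i, j] = _logsumexp(np.array(terms))

            # segments with first branch at i
            termsF, termsM = [], []
            for l in range(i + minh + 1, j + 1):
                if lZb[i, l] > NEG:
                    termsF.append(lZb[i, l] + lqbau(i, l) + lqc * (j - l))
                    if l + 1 <= j and lZm[l + 1, j] > NEG:
                        termsM.append(lZb[i, l] + lqbau(i, l) + lZm[l + 1, j])
            if termsF:
                lZmF[i, j] = _logsumexp(np.array(termsF))
            if termsM:
                lZmM[i, j] = _logsumexp(np.array(termsM))
            parts = [lZmF[i, j], lZmM[i, j]]
            if i + 1 <= j and lZm[i + 1, j] > NEG:
                parts.append(lqc + lZm[i + 1, j])
            lZm[i, j] = _logsumexp(np.array(parts))

    # exterior: prefix lZf[k] = log partition of bases 0..k-1
    lZf = np.zeros(n + 1)
    for j in range(n):
        terms = [lZf[j]]
        for k in range(j):
            if lZb[k, j] > NEG:
                terms.append(lZf[k] + lZb[k, j] + lau(k, j))
        lZf[j + 1] = _logsumexp(np.array(terms))
    # suffix lZs[t] = log partition of bases t..n-1
    lZs = np.zeros(n + 1)
    for t in range(n - 1, -1, -1):
        terms = [lZs[t + 1]]
        for l in range(t + minh + 1, n):
            if lZb[t, l] > NEG:
                terms.append(lZb[t, l] + lau(t, l) + lZs[l + 1])
        lZs[t] = _logsumexp(np.array(terms))

    log_z = lZf[n]

    # ---- outside ----
    lOb = np.full((n, n), NEG)   # outside weight of a Zb cell
    lOm = np.full((n, n), NEG)   # outside weight of a Zm cell
    lOmM = np.full((n, n), NEG)  # ZmM-specific: from multiloop closures

    def add(arr, i, j, val):
        arr[i, j] = np.logaddexp(arr[i, j], val)

    # exterior-loop context: the external loop factorizes around a branch
    for i in range(n):
        for j in range(i + minh + 1, n):
            if lZb[i, j] > NEG:
                lOb[i, j] = lZf[i] + lau(i, j) + lZs[j + 1]

    for d in range(n - 1, minh, -1):
        for i in range(n - d):
            j = i + d
            omF = lOm[i, j]  # Zm -> ZmF passes the outside weight unchanged
            omM = np.logaddexp(lOm[i, j], lOmM[i, j])
            # Zm's unpaired-prefix case
            if np.isfinite(lOm[i, j]) and i + 1 <= j:
                add(lOm, i + 1, j, lqc + lOm[i, j])
            # ZmF / ZmM productions emit a branch Zb[i, l]
            if np.isfinite(omF) or np.isfinite(omM):
                for l in range(i + minh + 1, j + 1):
                    if lZb[i, l] > NEG:
                        if np.isfinite(omF):
                            add(lOb, i, l, omF + lqbau(i, l) + lqc * (j - l))
                        if np.isfinite(omM) and l + 1 <= j and lZm[l + 1, j] > NEG:
                            add(lOb, i, l, omM + lqbau(i, l) + lZm[l + 1, j])
                            add(lOm, l + 1, j, omM + lZb[i, l] + lqbau(i, l))
            # outgoing from Ob[i, j]: (i, j) closes a two-loop or a multiloop
            if lOb[i, j] > NEG and ptab[codes[i], codes[j]] >= 0:
                kmax = min(j - minh - 2, i + cap + 1)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + minh + 1, j - 1 - (cap - (k - i - 1)))
                    for l in range(lmin, j):
                        if lZb[k, l] > NEG:
                            add(lOb, k, l, lOb[i, j] + two_loop(i, j, k, l))
                close = lqa + lqbau(i, j)
                for k in range(i + 2, j - 1):
                    add(lOmM, k, j - 1, lOb[i, j] + close + lqc * (k - i - 1))

    for i in range(n):
        for j in range(i + 1, n):
            if lZb[i, j] > NEG and lOb[i, j] > NEG:
                pr = np.exp(lZb[i, j] + lOb[i, j] - log_z)
                bpp[i, j] = bpp[j, i] = min(pr, 1.0)

    return PartitionResult(seq_id, log_z, -rt * log_z, bpp, model.name)
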