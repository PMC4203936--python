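"""Nearest-neighbor energy models for RNA secondary-structure prediction.

A model is a plain-text parameter table: allowed base pairs (the six canonical
and wobble pairs), stacking free energies, loop-initiation tables for hairpin,
bulge and internal loops, an affine multiloop score and a terminal AU/GU
penalty, all in kcal/mol at 37C.  Two tables ship with the package:

``nn37``
    The default table, a Turner-style nearest-neighbor set authored for this
    package.
``mini``
    A compact didactic table with coarse, GC-counting stack values; useful for
    hand-checkable examples.

Loop initiation beyond the tabulated size is extrapolated with the usual
Jacobson-Stockmayer ``1.75*RT*ln(n/n_max)`` term (the coefficient is stored in
the parameter file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

BASES = "ACGUN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: allowed pairs, indexed; N never pairs
PAIR_STRINGS = ("AU", "UA", "GC", "CG", "GU", "UG")
PAIR_INDEX = {p: i for i, p in enumerate(PAIR_STRINGS)}

#: 5x5 base x base -> pair type index, -1 if the pair is disallowed
PAIR_TABLE = np.full((5, 5), -1, dtype=np.int8)
for _p, _i in PAIR_INDEX.items():
    PAIR_TABLE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _i

#: pair types carrying the terminal AU/GU penalty
IS_AU_PAIR = np.array([p not in ("GC", "CG") for p in PAIR_STRINGS], dtype=np.bool_)

INF = 1e9


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,U,T,N}."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as indices into ``BASES`` (T is read as U)."""
    s = seq.upper().replace("T", "U")
    try:
        return np.array([BASE_INDEX[b] for b in s], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"invalid character {exc} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """A parameter-table-driven nearest-neighbor folding model."""

    name: str
    rt: float  # kcal/mol, 37C
    min_hairpin: int  # minimum unpaired bases in a hairpin loop
    max_loop: int  # internal/bulge loop span cap, nt
    loop_log_coef: float
    multiloop_offset: float  # affine multiloop: offset
    multiloop_branch: float  # ... per branch (closing pair included)
    multiloop_unpaired: float  # ... per unpaired base in the loop
    terminal_au: float  # penalty per AU/GU pair bordering an exterior/multi loop
    internal_asym: float  # internal-loop asymmetry penalty per unpaired-size unit
    stack: np.ndarray = field(repr=False)  # (6, 6) outer-pair x inner-pair
    hairpin: np.ndarray = field(repr=False)  # initiation, index = loop size
    bulge: np.ndarray = field(repr=False)
    internal: np.ndarray = field(repr=False)

    def loop_energy(self, table: np.ndarray, size: int) -> float:
        """Loop initiation for ``size``, extrapolating beyond the table."""
        nmax = len(table) - 1
        if size <= nmax:
            return float(table[size])
        return float(table[nmax]) + self.loop_log_coef * math.log(size / nmax)

    def hairpin_energy(self, size: int) -> float:
        return self.loop_energy(self.hairpin, size)

    def bulge_energy(self, size: int) -> float:
        return self.loop_energy(self.bulge, size)

    def internal_energy(self, n1: int, n2: int) -> float:
        return self.loop_energy(self.internal, n1 + n2) + self.internal_asym * abs(n1 - n2)

    def extended_tables(self, n: int):
        """Hairpin/bulge/internal tables extended to size ``n`` (for the DP)."""
        out = []
        for tab in (self.hairpin, self.bulge, self.internal):
            ext = np.full(max(n + 1, len(tab)), INF)
            ext[: len(tab)] = tab
            nmax = len(tab) - 1
            for size in range(len(tab), len(ext)):
                ext[size] = tab[nmax] + self.loop_log_coef * math.log(size / nmax)
            out.append(ext)
        return tuple(out)


def parse_parameter_text(text: str) -> EnergyModel:
    scalars: dict[str, float] = {}
    name = "unnamed"
    stack = np.full((6, 6), INF)
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]
        try:
            if key == "name":
                name = parts[1]
            elif key == "stack":
                stack[PAIR_INDEX[parts[1]], PAIR_INDEX[parts[2]]] = float(parts[3])
            elif key in loops:
                loops[key][int(parts[1])] = float(parts[2])
            else:
                scalars[key] = float(parts[1])
        except (IndexError, KeyError, ValueError) as exc:
            raise ValueError(f"bad parameter line {lineno}: {raw!r} ({exc})") from None

    def loop_array(key: str, start: int) -> np.ndarray:
        tab = loops[key]
        if not tab:
            raise ValueError(f"missing {key} loop table")
        arr = np.full(max(tab) + 1, INF)
        for n, v in tab.items():
            arr[n] = v
        if np.any(arr[start:] >= INF):
            raise ValueError(f"{key} loop table has gaps")
        return arr

    return EnergyModel(
        name=name,
        rt=scalars.get("rt", 0.616),
        min_hairpin=int(scalars.get("min_hairpin", 3)),
        max_loop=int(scalars.get("max_loop", 30)),
        loop_log_coef=scalars.get("loop_log_coef", 1.078),
        multiloop_offset=scalars.get("multiloop_offset", 3.4),
        multiloop_branch=scalars.get("multiloop_branch", 0.4),
        multiloop_unpaired=scalars.get("multiloop_unpaired", 0.0),
        terminal_au=scalars.get("terminal_au", 0.5),
        internal_asym=scalars.get("internal_asym", 0.6),
        stack=stack,
        hairpin=loop_array("hairpin", 3),
        bulge=loop_array("bulge", 1),
        internal=loop_array("internal", 2),
    )


def load_model(name_or_path: str = "nn37") -> EnergyModel:
    """Load a shipped model by name (``nn37``, ``mini``) or a ``.par`` file path."""
    path = Path(name_or_path)
    if path.suffix == ".par" and path.exists():
        return parse_parameter_text(path.read_text())
    ref = resources.files("ribosig.data").joinpath(f"{name_or_path}.par")
    if not ref.is_file():
        raise ValueError(f"unknown energy model {name_or_path!r}")
    return parse_parameter_text(ref.read_text())
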