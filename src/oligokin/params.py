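"""Nearest-neighbor thermodynamic parameter tables.

The packaged default is the Watson-Crick RNA set of Xia et al. (1998):
ten unique dinucleotide stacks, a bimolecular duplex-initiation term, and a
per-helix-end penalty for terminal A-U pairs. Tables are plain JSON and
pluggable, so an alternative parameterization can be substituted by loading
a different file with the same schema.

Stack keys are written 5'-XY-3'/3'-WZ-5'. A stack read in the opposite
direction is the same physical stack, so lookups canonicalize: the stack
with top dinucleotide XY equals the stack with top dinucleotide
complement(Y)complement(X).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .constants import T_37
from .strands import complement_base

_WC_TOPS = [
    "AA", "AU", "UA", "CU", "CA", "GU", "GA", "CG", "GG", "GC",
]


def _top_of_key(key: str) -> str:
    return key.split("/")[0]


def _partner_top(top: str) -> str:
    """Top dinucleotide of the rotationally equivalent stack."""
    return complement_base(top[1]) + complement_base(top[0])


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor dH/dS table for Watson-Crick RNA duplexes.

    ``stack_dH``/``stack_dS`` are keyed by the top-strand dinucleotide
    (5'->3') of the stack; both rotational representatives are present.
    Units: dH kcal/mol, dS kcal/mol/K.
    """

    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    init_dH: float
    init_dS: float
    terminal_au_dH: float
    terminal_au_dS: float
    version: str = "unversioned"

    def __post_init__(self) -> None:
        missing = [t for t in _WC_TOPS if t not in self.stack_dH]
        if missing:
            raise ValueError(f"incomplete NN table, missing stacks: {missing}")
        for k, dh in self.stack_dH.items():
            g37 = dh - T_37 * self.stack_dS[k]
            if not (g37 == g37 and abs(g37) < 1e3):  # finite
                raise ValueError(f"non-finite dG37 for stack {k}")

    def stack_dg(self, top: str, T: float) -> float:
        """dG(T) of the stack whose top-strand dinucleotide is ``top``."""
        try:
            return self.stack_dH[top] - T * self.stack_dS[top]
        except KeyError:
            raise KeyError(
                f"unknown Watson-Crick stack {top!r}; is the pair complementary?"
            ) from None

    def init_dg(self, T: float) -> float:
        return self.init_dH - T * self.init_dS

    def terminal_au_dg(self, T: float) -> float:
        return self.terminal_au_dH - T * self.terminal_au_dS


def _expand(stacks: dict[str, dict[str, float]]) -> tuple[dict, dict]:
    dH: dict[str, float] = {}
    dS: dict[str, float] = {}
    for key, val in stacks.items():
        top = _top_of_key(key)
        for t in {top, _partner_top(top)}:
            dH[t] = val["dH"]
            dS[t] = val["dS"]
    return dH, dS


def load_nn_table(path: str | Path | None = None) -> NNParameterSet:
    """Load an NN parameter set from JSON; default is the packaged RNA table."""
    if path is None:
        text = (
            resources.files("oligokin.data").joinpath("nn_rna_xia1998.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    dH, dS = _expand(raw["stacks"])
    return NNParameterSet(
        stack_dH=dH,
        stack_dS=dS,
        init_dH=raw["initiation"]["dH"],
        init_dS=raw["initiation"]["dS"],
        terminal_au_dH=raw["terminal_au"]["dH"],
        terminal_au_dS=raw["terminal_au"]["dS"],
        version=raw.get("version", "unversioned"),
    )


@dataclass(frozen=True)
class LoopPenalties:
    """Bulge / internal-loop free-energy penalties (kcal/mol, T-independent)."""

    bulge: dict[int, float]
    internal: dict[int, float]
    version: str = "unversioned"

    def _lookup(self, table: dict[int, float], n: int) -> float:
        import math

        if n <= 0:
            raise ValueError("loop size must be positive")
        if n in table:
            return table[n]
        nmax = max(table)
        # Jacobson-Stockmayer entropic extrapolation beyond the table
        return table[nmax] + 1.75 * 1.99e-3 * T_37 * math.log(n / nmax)

    def bulge_dg(self, n_unpaired: int) -> float:
        return self._lookup(self.bulge, n_unpaired)

    def internal_dg(self, n_total_unpaired: int) -> float:
        return self._lookup(self.internal, n_total_unpaired)


def load_loop_penalties(path: str | Path | None = None) -> LoopPenalties:
    if path is None:
        text = (
            resources.files("oligokin.data").joinpath("loop_penalties.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return LoopPenalties(
        bulge={int(k): v for k, v in raw["bulge"].items()},
        internal={int(k): v for k, v in raw["internal"].items()},
        version=raw.get("version", "unversioned"),
    )


DEFAULT_NN = load_nn_table()
DEFAULT_LOOPS = load_loop_penalties()
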