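"""RNA strand container, complementarity helpers and FASTA I/O.

Sequences are restricted to the unmodified RNA alphabet {A, C, G, U}. A
single 2-aminopurine (2Ap) substitution may be marked by position; 2Ap is a
fluorescent adenine analogue and is treated as A for all thermodynamic and
kinetic purposes (its duplex destabilization is negligible at room
temperature). The marker exists only so observables can be modeled.

In FASTA files the 2Ap position is encoded as lowercase ``a``; all other
bases are uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})


@dataclass(frozen=True)
class RnaStrand:
    """A validated RNA strand, written 5'->3'.

    Parameters
    ----------
    name : str
        Label used in FASTA headers and reports.
    bases : str
        Sequence over {A, C, G, U}.
    two_ap_index : int, optional
        0-based position carrying 2-aminopurine instead of adenine. The
        underlying base in ``bases`` must be ``A``.
    """

    name: str
    bases: str
    two_ap_index: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("strand must contain at least one base")
        bad = set(self.bases) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in {self.name!r}: {sorted(bad)}")
        if self.two_ap_index is not None:
            i = self.two_ap_index
            if not 0 <= i < len(self.bases):
                raise ValueError("2Ap index out of range")
            if self.bases[i] != "A":
                raise ValueError("2Ap must substitute an adenine")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc_fraction(self) -> float:
        """Fraction of C+G bases (f_CG)."""
        return sum(b in "CG" for b in self.bases) / len(self.bases)

    def reverse_complement(self, name: Optional[str] = None) -> "RnaStrand":
        rc = "".join(_COMPLEMENT[b] for b in reversed(self.bases))
        return RnaStrand(name or f"{self.name}_rc", rc)


def complement_base(b: str) -> str:
    return _COMPLEMENT[b]


def is_wc_pair(x: str, y: str) -> bool:
    """True if x and y form a Watson-Crick pair."""
    return (x, y) in _WC_PAIRS


def is_full_duplex(a: RnaStrand, b: RnaStrand) -> bool:
    """True if b is exactly the reverse complement of a."""
    return len(a) == len(b) and b.bases == a.reverse_complement().bases


def _to_record(s: RnaStrand) -> SeqRecord:
    seq = s.bases
    if s.two_ap_index is not None:
        i = s.two_ap_index
        seq = seq[:i] + "a" + seq[i + 1 :]
    desc = "" if s.two_ap_index is None else f"2Ap={s.two_ap_index + 1}"
    return SeqRecord(Seq(seq), id=s.name, description=desc)


def write_fasta(strands: Iterable[RnaStrand], path: str | Path) -> None:
    SeqIO.write([_to_record(s) for s in strands], str(path), "fasta")


def read_fasta(path: str | Path) -> list[RnaStrand]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        two_ap = None
        pos = [i for i, c in enumerate(raw) if c == "a"]
        if len(pos) > 1:
            raise ValueError(f"{rec.id}: more than one 2Ap position")
        if pos:
            two_ap = pos[0]
        out.append(RnaStrand(rec.id, raw.upper(), two_ap_index=two_ap))
    return out
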