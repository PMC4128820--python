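"""Aligned nucleotide matrices with codon-position partition labels."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError

__all__ = ["Alignment", "NUC_CODES", "AMBIGUITY_MASKS"]

# bitmask encoding: A=1, C=2, G=4, T=8; IUPAC ambiguity codes are unions;
# gaps and unknowns compare as fully ambiguous
NUC_CODES: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15, ".": 15,
}
_CODE_TO_CHAR = {1: "A", 2: "C", 4: "G", 8: "T", 15: "N"}

# rows indexed by bitmask: indicator over (A, C, G, T)
AMBIGUITY_MASKS = np.zeros((16, 4))
for _m in range(16):
    for _b in range(4):
        if _m >> _b & 1:
            AMBIGUITY_MASKS[_m, _b] = 1.0
AMBIGUITY_MASKS[0] = 1.0  # never produced, but keep it harmless


class Alignment:
    """A rectangular matrix of IUPAC nucleotide codes.

    ``codes`` holds the bitmask encoding (shape ``n_sequences x n_sites``,
    uint8); unambiguous A/C/G/T are 1/2/4/8.  Codon positions are assigned
    cyclically from the first column (position 1, 2, 3, 1, ...), matching a
    reading frame starting at the first site.
    """

    def __init__(self, ids: Sequence[str], sequences: Iterable[str]):
        self.ids = list(ids)
        seqs = [s.upper() for s in sequences]
        if len(self.ids) != len(seqs):
            raise InvalidInputError("ids and sequences must have equal length")
        if not seqs:
            raise InvalidInputError("alignment must contain at least one sequence")
        length = len(seqs[0])
        for ident, s in zip(self.ids, seqs):
            if len(s) != length:
                raise InvalidInputError(
                    f"record {ident!r} has length {len(s)}, expected {length}"
                )
        if length == 0:
            raise InvalidInputError("alignment has zero columns")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidInputError("sequence identifiers must be unique")
        table = np.full(256, 255, dtype=np.uint8)
        for ch, code in NUC_CODES.items():
            table[ord(ch)] = code
        codes = np.zeros((len(seqs), length), dtype=np.uint8)
        for i, s in enumerate(seqs):
            row = table[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            bad = np.flatnonzero(row == 255)
            if bad.size:
                raise InvalidInputError(
                    f"record {self.ids[i]!r}: unknown symbol {s[bad[0]]!r} "
                    f"at column {int(bad[0])}"
                )
            codes[i] = row
        self.codes = codes
        self._raw = seqs  # literal (uppercased) symbols, kept for haplotype identity

    # ------------------------------------------------------------------ shape
    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def codon_positions(self) -> np.ndarray:
        """1-based codon position (1, 2, 3) of each column."""
        return np.arange(self.n_sites) % 3 + 1

    def partition_of_site(self) -> np.ndarray:
        """0 for codon positions 1+2 (linked), 1 for position 3."""
        return (self.codon_positions() == 3).astype(np.int64)

    def sequence(self, i: int) -> str:
        """Literal sequence string (uppercased, ambiguity codes preserved)."""
        return self._raw[i]

    def is_valid_base(self) -> np.ndarray:
        """Boolean mask of unambiguous A/C/G/T cells."""
        return np.isin(self.codes, (1, 2, 4, 8))

    def state_indices(self) -> np.ndarray:
        """0..3 for A,C,G,T; -1 for anything ambiguous."""
        out = np.full(self.codes.shape, -1, dtype=np.int64)
        for k, code in enumerate((1, 2, 4, 8)):
            out[self.codes == code] = k
        return out

    def take_sequences(self, which: Iterable[str | int]) -> "Alignment":
        idx = []
        for w in which:
            idx.append(self.ids.index(w) if isinstance(w, str) else int(w))
        return Alignment([self.ids[i] for i in idx], [self.sequence(i) for i in idx])

    # --------------------------------------------------------------------- IO
    @classmethod
    def from_codes(cls, ids: Sequence[str], codes: np.ndarray) -> "Alignment":
        aln = cls.__new__(cls)
        aln.ids = list(ids)
        aln.codes = np.asarray(codes, dtype=np.uint8)
        if aln.codes.ndim != 2 or aln.codes.shape[0] != len(aln.ids):
            raise InvalidInputError("codes must be (n_sequences, n_sites)")
        chars = np.array([_CODE_TO_CHAR.get(m, "N") for m in range(16)])
        aln._raw = ["".join(chars[row]) for row in aln.codes]
        return aln

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InvalidInputError(f"no FASTA records in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(i)), id=self.ids[i], description="")
            for i in range(self.n_sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
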