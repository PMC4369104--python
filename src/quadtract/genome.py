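"""Genome container and FASTA IO.

Sequences are uppercase-normalized on load and restricted to the
{A, C, G, T, N} alphabet; any other IUPAC ambiguity code is mapped to N.
All coordinates in this package are 0-based half-open internally;
report writers emit 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class Genome(Mapping):
    """An ordered collection of contigs, mapping contig id -> sequence string."""

    def __init__(self, contigs: Mapping[str, str] | list[tuple[str, str]]):
        items = contigs.items() if isinstance(contigs, Mapping) else contigs
        self._contigs: dict[str, str] = {}
        for cid, seq in items:
            if cid in self._contigs:
                raise ValueError(f"duplicate contig id: {cid!r}")
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")
            seq = seq.upper()
            if not set(seq) <= _VALID:
                seq = _NON_ACGTN.sub("N", seq)
            self._contigs[cid] = seq

    # Mapping interface ------------------------------------------------
    def __getitem__(self, cid: str) -> str:
        return self._contigs[cid]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    # ------------------------------------------------------------------
    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())

    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self._contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"coordinates {start}..{end} outside contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def reverse_complemented(self) -> "Genome":
        """Mirror genome (every contig reverse-complemented); used in strand-symmetry checks."""
        return Genome([(cid, revcomp(seq)) for cid, seq in self._contigs.items()])

    # FASTA ------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in self._contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")
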