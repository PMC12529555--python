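"""DNA sequence container with 1-based, strand-aware coordinate access.

All coordinates in this package are 1-based inclusive on the forward
(plus) strand of the contig, matching GFF3. Conversion to 0-based
half-open happens only at BED boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = ["GenomeSequence", "revcomp"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase preserved)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence.

    Parameters
    ----------
    name:
        Contig identifier used in GFF3/BED output.
    seq:
        The forward-strand sequence; stored uppercase.
    """

    name: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of [start, end] (1-based inclusive).

        For ``strand == '-'`` the reverse complement of the interval is
        returned; the coordinates always refer to the plus strand.
        """
        if start < 1 or end > len(self.seq) or end < start:
            raise ValueError(
                f"interval [{start}, {end}] outside contig "
                f"{self.name!r} of length {len(self.seq)}"
            )
        s = self.seq[start - 1 : end]
        return revcomp(s) if strand == "-" else s

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.name, revcomp(self.seq))
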