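"""Recombination signal sequence (RSS) detection and the 12/23 rule.

An RSS is a conserved heptamer and nonamer separated by a spacer of
roughly one (12 bp) or two (23 bp) helical turns. V(D)J recombination
joins one 12-spacer RSS to one 23-spacer RSS (the 12/23 rule). The
scanner below slides both consensus motifs over both strands of a
contig, tolerating a configurable number of mismatches per motif and
+/- 1 bp of spacer slack.

Strand convention
-----------------
A hit's ``strand`` is the strand on which heptamer, spacer and nonamer
read left-to-right in consensus order. A plus-strand hit therefore
serves a plus-strand gene as its *downstream* (3') RSS — V and D 3'
ends — while a minus-strand hit serves a plus-strand gene as its
*upstream* (5') RSS — J and D 5' ends. All reported intervals are
1-based inclusive plus-strand coordinates regardless of hit strand;
the ``orientation`` field is filled in when a hit is linked to a gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .genome import GenomeSequence, revcomp

__all__ = [
    "DEFAULT_HEPTAMER",
    "DEFAULT_NONAMER",
    "RssParams",
    "RSS",
    "scan_rss",
    "check_12_23_pair",
    "write_bed",
]

#: Canonical vertebrate RSS consensus motifs.
DEFAULT_HEPTAMER = "CACAGTG"
DEFAULT_NONAMER = "ACAAAAACC"


@dataclass(frozen=True)
class RssParams:
    """Scanner configuration.

    The defaults are a strict heptamer (at most one mismatch, with the
    5'-CAC-3' bases required exact — RAG cannot engage a heptamer that
    has lost CAC) and a permissive nonamer (up to three mismatches),
    with 12 +/- 1 and 23 +/- 1 bp spacers.
    """

    heptamer_consensus: str = DEFAULT_HEPTAMER
    nonamer_consensus: str = DEFAULT_NONAMER
    spacer_classes: tuple[int, ...] = (12, 23)
    spacer_tolerance: int = 1
    max_heptamer_mismatches: int = 1
    max_nonamer_mismatches: int = 3
    require_cac: bool = True

    def __post_init__(self) -> None:
        for s, n in ((self.heptamer_consensus, 7), (self.nonamer_consensus, 9)):
            if len(s) != n or set(s) - set("ACGT"):
                raise ValueError(f"bad consensus {s!r}: need {n}-mer over ACGT")
        if self.spacer_tolerance < 0:
            raise ValueError("spacer_tolerance must be >= 0")
        if self.max_heptamer_mismatches < 0 or self.max_nonamer_mismatches < 0:
            raise ValueError("mismatch budgets must be >= 0")


@dataclass(frozen=True)
class RSS:
    """One detected recombination signal (see module docstring)."""

    contig: str
    strand: str
    spacer_class: int
    heptamer_interval: tuple[int, int]
    spacer_interval: tuple[int, int]
    nonamer_interval: tuple[int, int]
    heptamer_mismatches: int
    nonamer_mismatches: int
    cac_intact: bool
    orientation: Optional[str] = None  # downstream_of_gene | upstream_of_gene

    @property
    def spacer_len(self) -> int:
        a, b = self.spacer_interval
        return b - a + 1

    @property
    def start(self) -> int:
        return min(self.heptamer_interval[0], self.nonamer_interval[0])

    @property
    def end(self) -> int:
        return max(self.heptamer_interval[1], self.nonamer_interval[1])

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches

    def with_orientation(self, orientation: str) -> "RSS":
        return replace(self, orientation=orientation)


def _mismatch_profile(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of `pattern` at every offset of the byte array."""
    k = len(pattern)
    n = arr.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    out = np.zeros(n, dtype=np.int32)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    for j in range(k):
        out += arr[j : j + n] != pat[j]
    return out


def _exact_profile(arr: np.ndarray, pattern: str) -> np.ndarray:
    return _mismatch_profile(arr, pattern) == 0


def scan_rss(
    genome: GenomeSequence,
    params: RssParams = RssParams(),
    reduce_overlaps: bool = True,
) -> list[RSS]:
    """Detect RSS motifs on both strands of a contig.

    Returns hits sorted by start coordinate (then strand, then class).
    With ``reduce_overlaps`` (the default) clusters of hits whose
    heptamers overlap on the same strand are collapsed to the single
    lowest-total-mismatch hit (ties: spacer closest to its nominal
    class length, then smaller start); the raw candidate set is
    available with ``reduce_overlaps=False``.
    """
    seq = genome.seq
    L = len(seq)
    if L == 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hept, nona = params.heptamer_consensus, params.nonamer_consensus
    hits: list[RSS] = []

    profiles = {
        "h+": _mismatch_profile(arr, hept),
        "n+": _mismatch_profile(arr, nona),
        "h-": _mismatch_profile(arr, revcomp(hept)),
        "n-": _mismatch_profile(arr, revcomp(nona)),
        "cac+": _exact_profile(arr, "CAC"),
        "cac-": _exact_profile(arr, "GTG"),
    }

    spacer_lens = sorted(
        {
            c + d
            for c in params.spacer_classes
            for d in range(-params.spacer_tolerance, params.spacer_tolerance + 1)
            if c + d > 0
        }
    )

    def _cls(s: int) -> int:
        return min(params.spacer_classes, key=lambda c: (abs(s - c), c))

    for s in spacer_lens:
        cls = _cls(s)
        # plus strand: heptamer .. spacer .. nonamer
        hm, nm = profiles["h+"], profiles["n+"]
        n_off = 7 + s
        n = min(hm.size, max(nm.size - n_off, 0))
        if n > 0:
            ok = (hm[:n] <= params.max_heptamer_mismatches) & (
                nm[n_off : n_off + n] <= params.max_nonamer_mismatches
            )
            if params.require_cac:
                ok &= profiles["cac+"][:n]
            for i in np.flatnonzero(ok):
                i = int(i)
                hits.append(
                    RSS(
                        contig=genome.name,
                        strand="+",
                        spacer_class=cls,
                        heptamer_interval=(i + 1, i + 7),
                        spacer_interval=(i + 8, i + 7 + s),
                        nonamer_interval=(i + 8 + s, i + 16 + s),
                        heptamer_mismatches=int(hm[i]),
                        nonamer_mismatches=int(nm[i + n_off]),
                        cac_intact=seq[i : i + 3] == "CAC",
                    )
                )
        # minus strand: revcomp(nonamer) .. spacer .. revcomp(heptamer)
        hm, nm = profiles["h-"], profiles["n-"]
        h_off = 9 + s
        n = min(nm.size, max(hm.size - h_off, 0))
        if n > 0:
            ok = (nm[:n] <= params.max_nonamer_mismatches) & (
                hm[h_off : h_off + n] <= params.max_heptamer_mismatches
            )
            if params.require_cac:
                # heptamer bases 1-3 on the serving strand are the last
                # three of the revcomp window: GTG on the plus strand
                ok &= profiles["cac-"][h_off + 4 : h_off + 4 + n]
            for i in np.flatnonzero(ok):
                i = int(i)
                hits.append(
                    RSS(
                        contig=genome.name,
                        strand="-",
                        spacer_class=cls,
                        heptamer_interval=(i + h_off + 1, i + h_off + 7),
                        spacer_interval=(i + 10, i + 9 + s),
                        nonamer_interval=(i + 1, i + 9),
                        heptamer_mismatches=int(hm[i + h_off]),
                        nonamer_mismatches=int(nm[i]),
                        cac_intact=seq[i + h_off + 4 : i + h_off + 7] == "GTG",
                    )
                )

    if reduce_overlaps:
        hits = _reduce_overlapping(hits, params)
    hits.sort(key=lambda r: (r.contig, r.start, r.strand, r.spacer_class))
    return hits


def _reduce_overlapping(hits: list[RSS], params: RssParams) -> list[RSS]:
    """Collapse same-strand hits with overlapping heptamers to the best one."""
    out: list[RSS] = []
    for strand in ("+", "-"):
        group: list[RSS] = []
        g_end = -1
        for h in sorted(
            (h for h in hits if h.strand == strand),
            key=lambda r: r.heptamer_interval,
        ):
            if group and h.heptamer_interval[0] > g_end:
                out.append(_best_of(group))
                group = []
                g_end = -1
            group.append(h)
            g_end = max(g_end, h.heptamer_interval[1])
        if group:
            out.append(_best_of(group))
    return out


def _best_of(group: list[RSS]) -> RSS:
    return min(
        group,
        key=lambda r: (
            r.total_mismatches,
            abs(r.spacer_len - r.spacer_class),
            r.start,
            r.spacer_class,
        ),
    )


def check_12_23_pair(a: RSS, b: RSS) -> bool:
    """True iff the two signals satisfy the 12/23 rule."""
    return {a.spacer_class, b.spacer_class} == {12, 23}


def write_bed(hits: Iterable[RSS], path) -> None:
    """Export hits as BED6 (0-based half-open; score = total mismatches)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.contig,
                        str(h.start - 1),
                        str(h.end),
                        f"RSS{h.spacer_class}",
                        str(h.total_mismatches),
                        h.strand,
                    )
                )
                + "\n"
            )
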