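"""Naive exact read matcher for synthetic fixtures.

Maps reads to reference sequences (markers or pangenes) by exact substring
search seeded with a k-mer index, on both strands.  This is the built-in
stand-in for an external aligner: alignments are otherwise an input
contract (SAM or tabular records), and any real mapper can be plugged in
upstream.  Only suitable for error-free or near-error-free reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .markerdb import reverse_complement
from .taxprofile import ReadAlignment

__all__ = ["ExactMatcher", "Match", "align_reads_to_markers"]


@dataclass(frozen=True)
class Match:
    target_id: str
    start: int
    end: int
    strand: str


class ExactMatcher:
    """Exact substring search over a set of target sequences.

    A read matches a target when the full read (or its reverse complement)
    occurs verbatim in the target.  The index stores every k-mer start
    position; candidate hits found through the read's first k-mer are
    verified by direct string comparison.
    """

    def __init__(self, targets: Mapping[str, str], k: int = 31):
        self.k = k
        self.targets = dict(targets)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((tid, i))

    def map_read(self, seq: str) -> list[Match]:
        if len(seq) < self.k:
            return []
        hits: set[Match] = set()
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for tid, pos in self._index.get(s[: self.k], ()):
                target = self.targets[tid]
                if target[pos : pos + len(s)] == s:
                    hits.add(Match(tid, pos, pos + len(s), strand))
        return sorted(hits, key=lambda m: (m.target_id, m.start, m.strand))


def align_reads_to_markers(
    reads: Iterable,
    matcher: ExactMatcher,
    mapq: int = 42,
) -> list[ReadAlignment]:
    """Produce marker alignment records for simulated reads.

    ``reads`` yields objects with ``read_id`` and ``sequence`` attributes
    (e.g. :class:`metaprof.simulate.SimRead`).
    """
    out: list[ReadAlignment] = []
    for r in reads:
        for m in matcher.map_read(r.sequence):
            out.append(
                ReadAlignment(
                    read_id=r.read_id,
                    marker_id=m.target_id,
                    mapq=mapq,
                    read_length=len(r.sequence),
                    aligned_start=m.start,
                    aligned_end=m.end,
                )
            )
    return out
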