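"""Strain-level genotyping from per-sample marker pileups.

Reconstructs a majority-rule consensus sequence of each species marker per
sample, filters weakly supported samples and markers, concatenates the
shared marker set into a pseudo-alignment, and builds a neighbor-joining
strain phylogeny from Kimura 2-parameter distances.  Pairwise tree
distances normalized by the total branch length feed a transmission
inference rule: pairs closer than the first percentile of unrelated-pair
distances are called potential transmission events.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "MarkerPileup",
    "ConsensusMarker",
    "ConsensusRejection",
    "StrainDistanceMatrix",
    "TransmissionCallSet",
    "pileup_from_reads",
    "call_consensus",
    "filter_samples_and_markers",
    "trim_consensus",
    "concatenate_alignment",
    "kimura2p_distance",
    "nj_tree",
    "normalized_tree_distances",
    "infer_transmission",
]

DEFAULT_MIN_READS = 8
DEFAULT_MIN_BREADTH = 0.8
DEFAULT_MIN_QUAL = 30.0
DEFAULT_MIN_DOMINANCE = 0.8
DEFAULT_TRIM = 50
DEFAULT_SAMPLE_WITH_N_MARKERS = 20
DEFAULT_MARKER_IN_N_SAMPLES = 0.8

_BASES = "ACGT"


@dataclass
class MarkerPileup:
    """Per-position base and quality observations on one marker."""

    marker_id: str
    marker_length: int
    base_counts: list[dict[str, int]]
    base_quals: list[list[int]]
    n_reads: int

    @classmethod
    def empty(cls, marker_id: str, marker_length: int) -> "MarkerPileup":
        return cls(
            marker_id=marker_id,
            marker_length=marker_length,
            base_counts=[dict() for _ in range(marker_length)],
            base_quals=[[] for _ in range(marker_length)],
            n_reads=0,
        )

    def add_read(self, seq: str, start: int, quals: Sequence[int] | None = None) -> None:
        if quals is None:
            quals = [40] * len(seq)
        end = min(start + len(seq), self.marker_length)
        for pos in range(start, end):
            base = seq[pos - start].upper()
            if base not in _BASES:
                continue
            col = self.base_counts[pos]
            col[base] = col.get(base, 0) + 1
            self.base_quals[pos].append(quals[pos - start])
        self.n_reads += 1


def pileup_from_reads(
    marker_id: str,
    marker_length: int,
    reads: Iterable[tuple[str, int]] | Iterable[tuple[str, int, Sequence[int]]],
) -> MarkerPileup:
    """Build a pileup from (sequence, start[, qualities]) read tuples."""
    pile = MarkerPileup.empty(marker_id, marker_length)
    for read in reads:
        pile.add_read(*read)
    return pile


@dataclass
class ConsensusMarker:
    marker_id: str
    sample_id: str
    sequence: str
    breadth: float
    n_reads: int


@dataclass
class ConsensusRejection:
    marker_id: str
    sample_id: str
    reason: str


def call_consensus(
    pileup: MarkerPileup,
    sample_id: str = "sample",
    min_reads: int = DEFAULT_MIN_READS,
    min_breadth: float = DEFAULT_MIN_BREADTH,
    min_qual: float = DEFAULT_MIN_QUAL,
    min_dominance: float = DEFAULT_MIN_DOMINANCE,
) -> ConsensusMarker | ConsensusRejection:
    """Majority-rule consensus with ambiguity masking.

    A position is called with its most frequent base when the column's mean
    base quality is at least ``min_qual`` and the major allele accounts for
    at least ``min_dominance`` of the observations; otherwise it is N.
    Uncovered positions are N.  Breadth counts called (non-N) positions
    over the marker length; markers reconstructed from fewer than
    ``min_reads`` reads or with breadth below ``min_breadth`` are rejected.
    """
    if pileup.n_reads < min_reads:
        return ConsensusRejection(
            pileup.marker_id, sample_id, f"n_reads {pileup.n_reads} < {min_reads}"
        )
    seq = []
    called = 0
    for counts, quals in zip(pileup.base_counts, pileup.base_quals):
        total = sum(counts.values())
        if total == 0:
            seq.append("N")
            continue
        mean_qual = sum(quals) / len(quals)
        # deterministic majority: highest count, alphabetical tie-break
        base, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if mean_qual < min_qual or count / total < min_dominance:
            seq.append("N")
            continue
        seq.append(base)
        called += 1
    breadth = called / pileup.marker_length
    if breadth < min_breadth:
        return ConsensusRejection(
            pileup.marker_id, sample_id, f"breadth {breadth:.3f} < {min_breadth}"
        )
    return ConsensusMarker(
        marker_id=pileup.marker_id,
        sample_id=sample_id,
        sequence="".join(seq),
        breadth=breadth,
        n_reads=pileup.n_reads,
    )


def filter_samples_and_markers(
    consensus: Mapping[str, Mapping[str, ConsensusMarker]],
    sample_with_n_markers: int = DEFAULT_SAMPLE_WITH_N_MARKERS,
    marker_in_n_samples: float = DEFAULT_MARKER_IN_N_SAMPLES,
) -> tuple[list[str], list[str]]:
    """Iterative sample/marker filtering to a fixed point.

    Drops samples with fewer than ``sample_with_n_markers`` retained
    markers, then markers present in fewer than ``marker_in_n_samples``
    (fraction) of the remaining samples, repeating until stable.  Returns
    (retained sample ids, retained marker ids), both sorted.
    """
    samples = set(consensus)
    markers = {m for per in consensus.values() for m in per}
    while True:
        new_samples = {
            s for s in samples
            if sum(1 for m in consensus[s] if m in markers) >= sample_with_n_markers
        }
        if not new_samples:
            raise ValueError("insufficient data: all samples filtered out")
        new_markers = {
            m for m in markers
            if sum(1 for s in new_samples if m in consensus[s])
            >= marker_in_n_samples * len(new_samples)
        }
        if new_samples == samples and new_markers == markers:
            return sorted(samples), sorted(markers)
        samples, markers = new_samples, new_markers


def trim_consensus(sequence: str, trim: int = DEFAULT_TRIM) -> str | None:
    """Remove the leading and trailing ``trim`` bases (mapping boundary
    effect); returns None (marker dropped) when nothing would remain."""
    if len(sequence) <= 2 * trim:
        warnings.warn(
            f"sequence of length {len(sequence)} too short to trim by {trim}; dropped"
        )
        return None
    return sequence[trim : len(sequence) - trim]


def concatenate_alignment(
    consensus: Mapping[str, Mapping[str, ConsensusMarker]],
    samples: Sequence[str],
    markers: Sequence[str],
    trim: int = DEFAULT_TRIM,
) -> dict[str, str]:
    """Column-wise concatenation of trimmed consensus markers.

    Markers are laid out in lexicographic id order; a sample missing a
    marker is gap-filled with N over that marker's columns.  All consensus
    sequences of one marker must have equal length (they are reconstructed
    over a fixed reference); a mismatch signals indel-containing input that
    needs an external aligner.
    """
    marker_order = sorted(markers)
    lengths: dict[str, int] = {}
    for m in marker_order:
        lens = {
            len(consensus[s][m].sequence) for s in samples if m in consensus[s]
        }
        if len(lens) > 1:
            raise ValueError(f"consensus length mismatch for marker {m}")
        lengths[m] = lens.pop() if lens else 0

    trimmed_len: dict[str, int] = {}
    for m in marker_order:
        trimmed_len[m] = max(lengths[m] - 2 * trim, 0)

    out: dict[str, str] = {}
    for s in samples:
        parts = []
        for m in marker_order:
            if trimmed_len[m] == 0:
                continue
            if m in consensus[s]:
                t = trim_consensus(consensus[s][m].sequence, trim)
                parts.append(t if t is not None else "N" * trimmed_len[m])
            else:
                parts.append("N" * trimmed_len[m])
        out[s] = "".join(parts)
    return out


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def kimura2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance between equal-length sequences.

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q)) with P and Q the transition
    and transversion fractions over sites where both sequences have an
    unambiguous base.  Returns NaN when no sites are comparable and raises
    on saturation (non-positive logarithm argument).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    n = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _BASES or b not in _BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        return float("nan")
    p = transitions / n
    q = transversions / n
    arg = (1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q)
    if arg <= 0.0:
        raise ValueError("Kimura 2-parameter distance saturated")
    return -0.5 * math.log(arg)


def pairwise_distances(
    alignment: Mapping[str, str],
) -> tuple[list[str], np.ndarray]:
    """Kimura 2P distance matrix over all sample pairs of an alignment.

    Vectorized equivalent of calling :func:`kimura2p_distance` per pair.
    """
    ids = sorted(alignment)
    n = len(ids)
    codes = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    mats = []
    for s in ids:
        arr = np.frombuffer(alignment[s].upper().encode(), dtype=np.uint8)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for byte, code in codes.items():
            out[arr == byte] = code
        mats.append(out)
    x = np.stack(mats)
    purine = (x == 0) | (x == 2)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (x[i] >= 0) & (x[j] >= 0)
            m = int(valid.sum())
            if m == 0:
                d[i, j] = d[j, i] = float("nan")
                continue
            diff = (x[i] != x[j]) & valid
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            p, q = ts / m, tv / m
            arg = (1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q)
            if arg <= 0.0:
                raise ValueError("Kimura 2-parameter distance saturated")
            d[i, j] = d[j, i] = -0.5 * math.log(arg)
    return ids, d


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> TreeNode:
    """Neighbor-joining tree (Saitou & Nei) with deterministic tie-breaks.

    Pair choice minimizes the Q criterion, breaking ties by the
    lexicographically smallest (name_i, name_j) pair; negative branch
    lengths are clamped to zero.  Returns an unrooted (trifurcating root)
    tree whose leaves are ``ids``.
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains missing values")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    names: list[str] = list(ids)
    d = dist.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + ["(" + ",".join(sorted((names[i], names[j]))) + ")"]

    root = TreeNode()
    if len(nodes) == 3:
        a, b, c = d[0, 1], d[0, 2], d[1, 2]
        lens = [0.5 * (a + b - c), 0.5 * (a + c - b), 0.5 * (b + c - a)]
        for node, ln in zip(nodes, lens):
            node.length = max(ln, 0.0)
            root.append(node)
    else:  # exactly two nodes
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.append(node)
    return root


@dataclass
class StrainDistanceMatrix:
    sample_ids: list[str]
    distances: np.ndarray
    normalization: str = "raw"

    def distance(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.distances[i, j])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.sample_ids[i], self.sample_ids[j], float(self.distances[i, j])


def normalized_tree_distances(tree: TreeNode) -> StrainDistanceMatrix:
    """Leaf-to-leaf path lengths divided by the tree's total branch length."""
    total = sum(
        node.length or 0.0 for node in tree.traverse() if not node.is_root()
    )
    tips = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=tips)
    mat = np.asarray(dm.data, dtype=float)
    if total > 0:
        mat = mat / total
    else:
        mat = np.zeros_like(mat)
    return StrainDistanceMatrix(
        sample_ids=list(tips), distances=mat, normalization="tree-normalized"
    )


@dataclass
class TransmissionCallSet:
    threshold: float
    events: list[tuple[str, str, float, str]]
    retained_samples: list[str]
    n_unrelated_pairs: int


def infer_transmission(
    distances: StrainDistanceMatrix,
    subjects: Mapping[str, str],
    related_pairs: Iterable[frozenset[str] | tuple[str, str]],
    timestamps: Mapping[str, float] | None = None,
    percentile: float = 1.0,
    percentile_method: str = "lower",
) -> TransmissionCallSet:
    """Call potential transmission events from strain distances.

    One sample per subject is kept (earliest timestamp, ties by sample id);
    samples absent from ``subjects`` are their own singleton subject and
    count as non-related.  The identity threshold is the ``percentile``-th
    percentile of distances between non-related retained samples; related
    pairs closer than the threshold are reported.  ``related_pairs``
    contains subject-id pairs (e.g. mother/infant).

    The default ``percentile_method="lower"`` (nearest rank below) makes
    the fraction of unrelated pairs under the threshold at most
    ``percentile`` percent for every sample size, preserving the intended
    upper bound on the theoretical false-discovery rate; ``"linear"``
    interpolates between order statistics and can overshoot the bound by
    one pair.
    """
    timestamps = timestamps or {}
    related = {frozenset(p) for p in related_pairs}

    per_subject: dict[str, str] = {}
    for s in distances.sample_ids:
        subj = subjects.get(s, f"__singleton__{s}")
        cur = per_subject.get(subj)
        if cur is None or (timestamps.get(s, 0.0), s) < (timestamps.get(cur, 0.0), cur):
            per_subject[subj] = s
    retained = sorted(per_subject.values())
    subject_of = {v: k for k, v in per_subject.items()}

    unrelated_d: list[float] = []
    related_d: list[tuple[str, str, float]] = []
    for a, b, dval in distances.pairs():
        if a not in subject_of or b not in subject_of:
            continue
        if frozenset((subject_of[a], subject_of[b])) in related:
            related_d.append((a, b, dval))
        else:
            unrelated_d.append(dval)

    if len(unrelated_d) < 100:
        warnings.warn(
            f"only {len(unrelated_d)} unrelated pairs; percentile threshold unstable"
        )
    threshold = (
        float(np.percentile(unrelated_d, percentile, method=percentile_method))
        if unrelated_d
        else 0.0
    )
    events = [
        (a, b, dval, "related")
        for a, b, dval in related_d
        if dval < threshold
    ]
    return TransmissionCallSet(
        threshold=threshold,
        events=events,
        retained_samples=retained,
        n_unrelated_pairs=len(unrelated_d),
    )


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
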