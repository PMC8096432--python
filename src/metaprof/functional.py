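"""Tiered functional profiling of gene-family abundances.

Reads are first assigned to species pangenes (nucleotide tier) with a
database-sequence coverage filter; reads left unmapped fall back to a
translated-search tier with an identity floor and a within-1%-of-best
score filter.  Per-family abundances are length-normalized (reads per
kilobase), stratified by contributing species, and can be regrouped to
broader features (EC numbers, 50%-identity families) and renormalized to
copies per million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NucleotideHit",
    "TranslatedHit",
    "FunctionalProfile",
    "AnnotationRecord",
    "coverage_filter",
    "nucleotide_assign",
    "translated_assign",
    "family_abundance",
    "regroup",
    "renormalize_cpm",
    "gold_standard_functional",
]

DEFAULT_MIN_COVERED_FRACTION = 0.5
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_TOP_FRACTION = 0.01

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class NucleotideHit:
    """Read-to-pangene alignment; the pangene carries family + species."""

    read_id: str
    pangene_id: str
    family_id: str
    species: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class TranslatedHit:
    """Read-to-protein-family alignment from translated search."""

    read_id: str
    protein_family_id: str
    percent_identity: float
    score: float
    start: int
    end: int


@dataclass
class AnnotationRecord:
    family50_id: str | None = None
    ec_numbers: tuple[str, ...] = ()
    go_terms: tuple[str, ...] = ()
    length_aa: int = 0


@dataclass
class FunctionalProfile:
    """Stratified per-family abundances: (family, species|unclassified) -> value."""

    abundances: dict[tuple[str, str], float] = field(default_factory=dict)
    units: str = "RPK"

    def community_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for (fam, _), v in self.abundances.items():
            totals[fam] = totals.get(fam, 0.0) + v
        return totals

    def total(self) -> float:
        return sum(self.community_totals().values())

    @property
    def families(self) -> set[str]:
        return {fam for fam, _ in self.abundances}


def _union_covered(intervals: Iterable[tuple[int, int]]) -> int:
    covered = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start >= last_end:
            covered += end - start
            last_end = end
        elif end > last_end:
            covered += end - last_end
            last_end = end
    return covered


def coverage_filter(
    hits: Sequence[NucleotideHit] | Sequence[TranslatedHit],
    target_lengths: Mapping[str, int],
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
) -> list:
    """Discard all hits to database sequences covered below a threshold.

    For every target, the fraction of its positions covered by the union of
    hit intervals must reach ``min_covered_fraction`` (boundary inclusive)
    for any of its hits to survive.  Idempotent and independent of hit
    order.
    """
    def target_of(h):
        return h.pangene_id if isinstance(h, NucleotideHit) else h.protein_family_id

    by_target: dict[str, list] = {}
    for h in hits:
        by_target.setdefault(target_of(h), []).append(h)
    surviving = []
    for target, ths in by_target.items():
        length = target_lengths[target]
        covered = _union_covered((h.start, h.end) for h in ths)
        if covered / length >= min_covered_fraction:
            surviving.extend(ths)
    return surviving


@dataclass
class ReadAssignments:
    """Per-read weights onto (family, stratum) plus the unmapped read set."""

    weights: dict[str, dict[tuple[str, str], float]]
    unmapped: set[str]

    def total_weight(self) -> float:
        return sum(sum(w.values()) for w in self.weights.values())


def nucleotide_assign(
    hits: Sequence[NucleotideHit],
    all_read_ids: Iterable[str],
    multi_hit_k: int = 1,
) -> ReadAssignments:
    """Assign each read to its best pangene(s).

    With ``multi_hit_k=1`` (default) the full read weight goes to the
    highest-scoring pangene (lexicographic pangene id tie-break); with
    k > 1 the weight is split equally among the up-to-k best pangenes.
    Reads with no surviving hit are emitted as unmapped for the translated
    tier.
    """
    by_read: dict[str, list[NucleotideHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)

    weights: dict[str, dict[tuple[str, str], float]] = {}
    unmapped: set[str] = set()
    for read_id in set(all_read_ids) | set(by_read):
        rhits = by_read.get(read_id)
        if not rhits:
            unmapped.add(read_id)
            continue
        ranked = sorted(rhits, key=lambda h: (-h.score, h.pangene_id))
        chosen = ranked[: max(1, multi_hit_k)]
        w = 1.0 / len(chosen)
        read_w: dict[tuple[str, str], float] = {}
        for h in chosen:
            key = (h.family_id, h.species)
            read_w[key] = read_w.get(key, 0.0) + w
        weights[read_id] = read_w
    return ReadAssignments(weights=weights, unmapped=unmapped)


def translated_assign(
    hits: Sequence[TranslatedHit],
    unmapped_reads: Iterable[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> ReadAssignments:
    """Translated-tier assignment with identity and top-score filters.

    Hits below ``min_identity`` percent identity are dropped; among the
    rest, hits scoring at least (1 - top_fraction) of the read's best hit
    share the read weight equally.  All weight lands in the
    "unclassified" stratum.  Reads with no surviving hit stay unmapped.
    """
    by_read: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        if h.percent_identity >= min_identity:
            by_read.setdefault(h.read_id, []).append(h)

    weights: dict[str, dict[tuple[str, str], float]] = {}
    unmapped: set[str] = set()
    for read_id in set(unmapped_reads):
        rhits = by_read.get(read_id)
        if not rhits:
            unmapped.add(read_id)
            continue
        best = max(h.score for h in rhits)
        survivors = [h for h in rhits if h.score >= (1.0 - top_fraction) * best]
        w = 1.0 / len(survivors)
        read_w: dict[tuple[str, str], float] = {}
        for h in survivors:
            key = (h.protein_family_id, UNCLASSIFIED)
            read_w[key] = read_w.get(key, 0.0) + w
        weights[read_id] = read_w
    return ReadAssignments(weights=weights, unmapped=unmapped)


def family_abundance(
    assignments: Sequence[ReadAssignments],
    family_lengths_nt: Mapping[str, int],
) -> FunctionalProfile:
    """Length-normalized abundances: summed read weight per kilobase of
    family sequence (protein families: aa length x 3)."""
    totals: dict[tuple[str, str], float] = {}
    for asg in assignments:
        for read_w in asg.weights.values():
            for key, w in read_w.items():
                totals[key] = totals.get(key, 0.0) + w
    profile: dict[tuple[str, str], float] = {}
    for (fam, stratum), w in totals.items():
        if fam not in family_lengths_nt:
            raise KeyError(f"no length for family {fam!r}")
        profile[(fam, stratum)] = w / (family_lengths_nt[fam] / 1000.0)
    return FunctionalProfile(abundances=profile, units="RPK")


def regroup(
    profile: FunctionalProfile,
    annotations: Mapping[str, AnnotationRecord],
    target: str = "ec",
) -> FunctionalProfile:
    """Regroup family abundances onto EC numbers or 50%-identity families.

    The target feature's abundance is the per-stratum sum of its member
    families; a family annotated with several ECs contributes its full
    abundance to each of them.  Unannotated families are dropped from the
    regrouped output (the source profile is untouched).
    """
    if target not in ("ec", "family50"):
        raise ValueError(f"unknown regroup target {target!r}")
    out: dict[tuple[str, str], float] = {}
    for (fam, stratum), v in profile.abundances.items():
        ann = annotations.get(fam)
        if ann is None:
            continue
        if target == "ec":
            features: Sequence[str] = ann.ec_numbers
        else:
            features = (ann.family50_id,) if ann.family50_id else ()
        for feat in features:
            key = (feat, stratum)
            out[key] = out.get(key, 0.0) + v
    return FunctionalProfile(abundances=out, units=profile.units)


def renormalize_cpm(profile: FunctionalProfile) -> FunctionalProfile:
    """Scale community totals to sum to 1e6 (copies per million); strata are
    scaled by the same global factor so stratum/total ratios are unchanged."""
    total = profile.total()
    if total <= 0:
        raise ValueError("cannot renormalize an all-zero profile")
    factor = 1e6 / total
    return FunctionalProfile(
        abundances={k: v * factor for k, v in profile.abundances.items()},
        units="CPM",
    )


def gold_standard_functional(
    genome_family_counts: Mapping[str, Mapping[str, int]],
    genome_depths: Mapping[str, float],
    genome_species: Mapping[str, str],
    family_lengths_nt: Mapping[str, int],
) -> FunctionalProfile:
    """Ground-truth functional profile of a synthetic community.

    Each genome contributes depth x copy-number for every family it
    carries, normalized by family length in kb — the same normalization as
    :func:`family_abundance` — stratified by the genome's species.
    """
    out: dict[tuple[str, str], float] = {}
    for genome, counts in genome_family_counts.items():
        depth = genome_depths.get(genome, 0.0)
        species = genome_species[genome]
        for fam, n in counts.items():
            key = (fam, species)
            out[key] = out.get(key, 0.0) + depth * n / (family_lengths_nt[fam] / 1000.0)
    return FunctionalProfile(abundances=out, units="RPK")
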