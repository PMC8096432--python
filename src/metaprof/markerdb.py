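"""Species pangenomes and clade-specific marker selection.

Builds per-species pangenomes from annotated genomes, computes
coreness/uniqueness/external-genome statistics for every gene family at two
clustering tiers (90% and 50% identity), and selects up to 150
species-specific marker genes per species through a tiered (A/B/C/U)
iterative procedure.  Markers with no external species are "unique
markers"; markers shared with a short list of other species are
"quasi-markers" and carry that list so the profiler can discount them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Gene",
    "GenomeRecord",
    "PanFamily",
    "Pangenome",
    "PanFamilyStats",
    "MarkerRecord",
    "Taxonomy",
    "MarkerDatabase",
    "flag_low_quality_species",
    "build_pangenome",
    "compute_family_stats",
    "assign_tier",
    "score_marker",
    "select_markers",
    "refine_marker_externality",
    "build_marker_database",
]

# Species-name filter for low-quality taxonomic annotations ("Candidatus",
# "sp.", "bacterium", symbionts, placeholder taxa, ...).  Names use
# underscore-separated tokens.  Case handling is exactly as written.
LOW_QUALITY_REGEX = re.compile(
    r"(C|c)andidat(e|us)"
    r"|_sp(_.*|$)"
    r"|(.*_|^)(b|B)acterium(_.*|)"
    r"|.*(eury|)archaeo(n_|te|n$).*"
    r"|.*(endo|)symbiont.*"
    r"|.*genomosp_.*"
    r"|.*unidentified.*"
    r"|.*_bacteria_.*"
    r"|.*_taxon_.*"
    r"|.*_et_al_.*"
    r"|.*_and_.*"
    r"|.*(cyano|proteo|actinobacterium_.*)"
)

# Candidate markers must encode proteins of 150-1500 amino acids.
MIN_PROTEIN_LEN = 150
MAX_PROTEIN_LEN = 1500

DEFAULT_MAX_MARKERS = 150
DEFAULT_MIN_MARKERS = 10
# If a tier round leaves us with more than this many candidates in total,
# selection stops at that round.
CANDIDATE_STOP = 50


@dataclass(frozen=True)
class Gene:
    """One annotated gene: half-open 0-based coordinates on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_length: int
    family90_id: str
    family50_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene coordinates for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")


@dataclass
class GenomeRecord:
    genome_id: str
    species_taxid: int
    contigs: dict[str, str]
    genes: list[Gene]

    def gene_sequence(self, gene: Gene) -> str:
        seq = self.contigs[gene.contig_id][gene.start : gene.end]
        if gene.strand == "-":
            seq = reverse_complement(seq)
        return seq

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PanFamily:
    """One gene family (90% tier) of a species pangenome."""

    family90_id: str
    family50_id: str
    member_genes: list[tuple[str, Gene]]  # (genome_id, gene)
    representative_genome_id: str
    representative_gene: Gene
    representative_seq: str

    @property
    def member_genomes(self) -> set[str]:
        return {g for g, _ in self.member_genes}

    @property
    def length_nt(self) -> int:
        return len(self.representative_seq)


@dataclass
class Pangenome:
    species_taxid: int
    genome_ids: set[str]
    families: dict[str, PanFamily]

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)


@dataclass(frozen=True)
class PanFamilyStats:
    coreness: float
    uniqueness90: int
    uniqueness50: int
    uniqueness_sp90: int
    uniqueness_sp50: int
    external_genomes90: int
    external_genomes50: int


@dataclass
class MarkerRecord:
    marker_id: str
    species_taxid: int
    sequence: str
    tier: str
    score: float
    ext_species: set[int] = field(default_factory=set)
    taxonomy_path: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_unique(self) -> bool:
        return not self.ext_species


class Taxonomy:
    """Rooted taxonomy tree keyed by integer taxid.

    Each node carries (name, rank, parent taxid, average genome length in
    nt).  The root is its own parent.
    """

    RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
    RANK_PREFIX = dict(
        zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__"))
    )

    def __init__(self) -> None:
        self.nodes: dict[int, dict] = {}

    def add_node(
        self,
        taxid: int,
        name: str,
        rank: str,
        parent: int,
        avg_genome_length: float = 0.0,
    ) -> None:
        self.nodes[taxid] = {
            "name": name,
            "rank": rank,
            "parent": parent,
            "avg_genome_length": avg_genome_length,
        }

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name(self, taxid: int) -> str:
        return self.nodes[taxid]["name"]

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid]["rank"]

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid]["parent"]

    def avg_genome_length(self, taxid: int) -> float:
        return self.nodes[taxid]["avg_genome_length"]

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the highest rank down to ``taxid`` (root excluded)."""
        chain = []
        t = taxid
        while True:
            node = self.nodes[t]
            chain.append(t)
            if node["parent"] == t:
                break
            t = node["parent"]
        chain.reverse()
        # drop an unranked root if present
        return [t for t in chain if self.nodes[t]["rank"] in self.RANKS]

    def path(self, taxid: int) -> str:
        parts = []
        for t in self.lineage(taxid):
            prefix = self.RANK_PREFIX[self.nodes[t]["rank"]]
            parts.append(prefix + self.nodes[t]["name"])
        return "|".join(parts)

    def taxid_path(self, taxid: int) -> str:
        return "|".join(str(t) for t in self.lineage(taxid))


@dataclass
class MarkerDatabase:
    markers: list[MarkerRecord]
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        self._by_species: dict[int, list[MarkerRecord]] = {}
        self._by_id: dict[str, MarkerRecord] = {}
        for m in self.markers:
            self._by_species.setdefault(m.species_taxid, []).append(m)
            self._by_id[m.marker_id] = m

    @property
    def species(self) -> list[int]:
        return sorted(self._by_species)

    def markers_for(self, species_taxid: int) -> list[MarkerRecord]:
        return self._by_species.get(species_taxid, [])

    def marker(self, marker_id: str) -> MarkerRecord:
        return self._by_id[marker_id]

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id


def flag_low_quality_species(species_name: str) -> bool:
    """True when a species name looks like a low-quality placeholder taxon."""
    return bool(LOW_QUALITY_REGEX.search(species_name))


def build_pangenome(genomes: Sequence[GenomeRecord]) -> Pangenome:
    """Union of 90%-identity gene families over all genomes of one species.

    The representative gene of each family is taken from the
    lexicographically smallest genome id, breaking ties by longest gene
    sequence then smallest gene id, so builds are deterministic.
    """
    if not genomes:
        raise ValueError("no genomes")
    taxids = {g.species_taxid for g in genomes}
    if len(taxids) != 1:
        raise ValueError(f"mixed species taxids: {sorted(taxids)}")
    (taxid,) = taxids

    members: dict[str, list[tuple[str, Gene]]] = {}
    fam50: dict[str, str] = {}
    for genome in genomes:
        for gene in genome.genes:
            members.setdefault(gene.family90_id, []).append((genome.genome_id, gene))
            fam50[gene.family90_id] = gene.family50_id

    by_id = {g.genome_id: g for g in genomes}
    families: dict[str, PanFamily] = {}
    for fam, mem in members.items():
        rep_genome_id, rep_gene = min(
            mem, key=lambda m: (m[0], -(m[1].end - m[1].start), m[1].gene_id)
        )
        families[fam] = PanFamily(
            family90_id=fam,
            family50_id=fam50[fam],
            member_genes=mem,
            representative_genome_id=rep_genome_id,
            representative_gene=rep_gene,
            representative_seq=by_id[rep_genome_id].gene_sequence(rep_gene),
        )
    return Pangenome(
        species_taxid=taxid,
        genome_ids={g.genome_id for g in genomes},
        families=families,
    )


def compute_family_stats(
    pangenomes: Mapping[int, Pangenome],
    low_quality_flags: Mapping[int, bool],
) -> dict[tuple[int, str], PanFamilyStats]:
    """Coreness / uniqueness / external-genome statistics per (species, family).

    coreness is the fraction of the species' genomes carrying the family;
    uniqueness the number of OTHER species' pangenomes carrying it (at the
    90% and, via the family's 50% parent, the 50% tier); uniqueness_sp
    excludes species flagged low-quality; external_genomes counts
    other-species genomes rather than species.
    """
    # family -> species set / per-species genome counts, at both tiers
    species90: dict[str, set[int]] = {}
    species50: dict[str, set[int]] = {}
    genomes90: dict[str, dict[int, int]] = {}
    genomes50: dict[str, dict[int, int]] = {}

    for taxid, pg in pangenomes.items():
        fam50_genomes: dict[str, set[str]] = {}
        for fam in pg.families.values():
            species90.setdefault(fam.family90_id, set()).add(taxid)
            genomes90.setdefault(fam.family90_id, {})[taxid] = len(fam.member_genomes)
            fam50_genomes.setdefault(fam.family50_id, set()).update(fam.member_genomes)
        for f50, gset in fam50_genomes.items():
            species50.setdefault(f50, set()).add(taxid)
            genomes50.setdefault(f50, {})[taxid] = len(gset)

    stats: dict[tuple[int, str], PanFamilyStats] = {}
    for taxid, pg in pangenomes.items():
        for fam in pg.families.values():
            f90, f50 = fam.family90_id, fam.family50_id
            others90 = species90[f90] - {taxid}
            others50 = species50[f50] - {taxid}
            stats[(taxid, f90)] = PanFamilyStats(
                coreness=len(fam.member_genomes) / pg.n_genomes,
                uniqueness90=len(others90),
                uniqueness50=len(others50),
                uniqueness_sp90=sum(
                    1 for s in others90 if not low_quality_flags.get(s, False)
                ),
                uniqueness_sp50=sum(
                    1 for s in others50 if not low_quality_flags.get(s, False)
                ),
                external_genomes90=sum(genomes90[f90][s] for s in others90),
                external_genomes50=sum(genomes50[f50][s] for s in others50),
            )
    return stats


# Tier thresholds.  Boundary semantics follow the stated rules: "higher
# than 80%" is strict, the 70-80% band is (0.70, 0.80], "lower than" is
# strict, uniqueness "of 5" is <= 5.
#   tier  coreness        u90    u50    eg90   eg50
#   A     > 0.80          <= 2   <= 2   <= 10  <= 5
#   B     (0.70, 0.80]    <= 5   <= 5   < 15   < 10
#   C     (0.50, 0.70]    < 10   < 15   < 25   < 20
#   U     single-genome species, u90 == 0 and u50 == 0


def assign_tier(stats: PanFamilyStats, n_species_genomes: int) -> str | None:
    """Which tier's thresholds does this family satisfy (A, B, C, U or None)."""
    c = stats.coreness
    u90, u50 = stats.uniqueness90, stats.uniqueness50
    eg90, eg50 = stats.external_genomes90, stats.external_genomes50
    if n_species_genomes == 1:
        if u90 == 0 and u50 == 0:
            return "U"
        return None
    if c > 0.80 and u90 <= 2 and u50 <= 2 and eg90 <= 10 and eg50 <= 5:
        return "A"
    if 0.70 < c <= 0.80 and u90 <= 5 and u50 <= 5 and eg90 < 15 and eg50 < 10:
        return "B"
    if 0.50 < c <= 0.70 and u90 < 10 and u50 < 15 and eg90 < 25 and eg50 < 20:
        return "C"
    return None


def _satisfies_tier(stats: PanFamilyStats, tier: str, n_species_genomes: int) -> bool:
    return assign_tier(stats, n_species_genomes) == tier


_SCORE_CAP = 10_000
_SCORE_EPS = 1e-4


def _s_uniqueness(u: int) -> float:
    """Log-shaped penalty: maximal (~138.155) at u=0, ~0 as u approaches 1e4."""
    if u < 0:
        raise ValueError("uniqueness must be non-negative")
    val = -math.log(1.0 - (_SCORE_CAP - min(_SCORE_CAP, u)) / _SCORE_CAP + _SCORE_EPS) * 15.0
    return max(val, 0.0)


def score_marker(stats: PanFamilyStats) -> float:
    """Candidate-marker ranking score.

    Product of coreness (fraction in [0, 1]) and log-shaped uniqueness terms
    at both clustering tiers; strictly decreasing in each uniqueness count
    below 1e4 and weakly increasing in coreness.
    """
    if not (0.0 <= stats.coreness <= 1.0):
        raise ValueError("coreness must lie in [0, 1]")
    return stats.coreness * _s_uniqueness(stats.uniqueness50) * _s_uniqueness(stats.uniqueness90)


def select_markers(
    pangenome: Pangenome,
    stats_map: Mapping[tuple[int, str], PanFamilyStats],
    ext_species_map: Mapping[str, set[int]],
    max_markers: int = DEFAULT_MAX_MARKERS,
    min_markers: int = DEFAULT_MIN_MARKERS,
    taxonomy: Taxonomy | None = None,
) -> list[MarkerRecord]:
    """Tiered iterative marker selection for one species.

    Candidates (families encoding 150-1500 aa proteins) are examined in
    tier rounds A then B then C (single-genome species use tier U only).
    After any round with more than 50 accumulated candidates, the
    candidates are ranked by score and up to ``max_markers`` are kept and
    selection stops; otherwise the next round's (looser) thresholds are
    tried.  A species ending with fewer than ``min_markers`` markers is
    dropped (empty list returned).
    """
    taxid = pangenome.species_taxid
    n_genomes = pangenome.n_genomes
    candidates = [
        fam
        for fam in pangenome.families.values()
        if MIN_PROTEIN_LEN
        <= fam.representative_gene.protein_length
        <= MAX_PROTEIN_LEN
    ]
    rounds = ["U"] if n_genomes == 1 else ["A", "B", "C"]

    selected: list[tuple[PanFamily, str, float]] = []
    chosen: set[str] = set()
    for tier in rounds:
        for fam in candidates:
            if fam.family90_id in chosen:
                continue
            st = stats_map[(taxid, fam.family90_id)]
            if _satisfies_tier(st, tier, n_genomes):
                selected.append((fam, tier, score_marker(st)))
                chosen.add(fam.family90_id)
        if len(selected) > CANDIDATE_STOP:
            break

    # rank by score (desc), deterministic family-id tie-break; cap at 150
    selected.sort(key=lambda t: (-t[2], t[0].family90_id))
    selected = selected[:max_markers]
    if len(selected) < min_markers:
        return []

    tax_path = taxonomy.path(taxid) if taxonomy is not None else ""
    return [
        MarkerRecord(
            marker_id=f"{taxid}__{fam.family90_id}",
            species_taxid=taxid,
            sequence=fam.representative_seq,
            tier=tier,
            score=score,
            ext_species=set(ext_species_map.get(fam.family90_id, set())) - {taxid},
            taxonomy_path=tax_path,
        )
        for fam, tier, score in selected
    ]


CHUNK_LEN = 150


def refine_marker_externality(
    marker: MarkerRecord,
    genomes: Iterable[GenomeRecord],
    hits: Iterable[str] | None = None,
) -> MarkerRecord:
    """Add to ``ext_species`` every other species whose genome contains at
    least 150 consecutive nucleotides of the marker.

    Detection splits the marker into non-overlapping 150 bp chunks and
    performs an exact substring search against each genome's contigs on
    both strands.  ``hits`` lets a caller substitute genome ids found by an
    external mapper instead (one entry per matched genome).
    """
    if marker.length < CHUNK_LEN:
        raise ValueError("marker shorter than 150 nt")
    genomes = list(genomes)
    found: set[int] = set()
    if hits is not None:
        by_id = {g.genome_id: g.species_taxid for g in genomes}
        found = {by_id[h] for h in hits}
    else:
        chunks = [
            marker.sequence[i : i + CHUNK_LEN]
            for i in range(0, marker.length - CHUNK_LEN + 1, CHUNK_LEN)
        ]
        for genome in genomes:
            if genome.species_taxid == marker.species_taxid:
                continue
            if genome.species_taxid in found:
                continue
            for contig in genome.contigs.values():
                rc = reverse_complement(contig)
                if any(c in contig or c in rc for c in chunks):
                    found.add(genome.species_taxid)
                    break
    new_ext = set(marker.ext_species) | (found - {marker.species_taxid})
    return MarkerRecord(
        marker_id=marker.marker_id,
        species_taxid=marker.species_taxid,
        sequence=marker.sequence,
        tier=marker.tier,
        score=marker.score,
        ext_species=new_ext,
        taxonomy_path=marker.taxonomy_path,
    )


def build_marker_database(
    genomes_by_species: Mapping[int, Sequence[GenomeRecord]],
    taxonomy: Taxonomy,
    max_markers: int = DEFAULT_MAX_MARKERS,
    min_markers: int = DEFAULT_MIN_MARKERS,
    refine: bool = False,
) -> MarkerDatabase:
    """End-to-end database build: pangenomes, stats, selection, refinement.

    ``refine=True`` additionally runs the 150 bp chunk search of every
    selected marker against all other species' genomes (quadratic; intended
    for small inputs).
    """
    pangenomes = {
        taxid: build_pangenome(genomes)
        for taxid, genomes in genomes_by_species.items()
    }
    flags = {
        taxid: flag_low_quality_species(taxonomy.name(taxid))
        for taxid in pangenomes
        if taxid in taxonomy
    }
    stats = compute_family_stats(pangenomes, flags)

    fam_species: dict[str, set[int]] = {}
    for taxid, pg in pangenomes.items():
        for f90 in pg.families:
            fam_species.setdefault(f90, set()).add(taxid)

    all_genomes = [g for gs in genomes_by_species.values() for g in gs]
    markers: list[MarkerRecord] = []
    for taxid in sorted(pangenomes):
        species_markers = select_markers(
            pangenomes[taxid],
            stats,
            fam_species,
            max_markers=max_markers,
            min_markers=min_markers,
            taxonomy=taxonomy,
        )
        if refine:
            species_markers = [
                refine_marker_externality(m, all_genomes) for m in species_markers
            ]
        markers.extend(species_markers)
    return MarkerDatabase(markers=markers, taxonomy=taxonomy)
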