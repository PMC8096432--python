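"""Quantitative taxonomic profiling from read-to-marker alignments.

Per-marker sequencing depths are combined into a per-species coverage by a
quantile-trimmed ("robust") average, aggregated up the taxonomy, and
normalized into per-rank relative abundances, with an estimate of the
fraction of reads from organisms absent from the database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .markerdb import MarkerDatabase, Taxonomy

__all__ = [
    "ReadAlignment",
    "CladeCoverage",
    "TaxonomicProfile",
    "filter_alignments",
    "dedupe_reads",
    "marker_coverage",
    "clade_coverage",
    "aggregate_taxonomy",
    "relative_abundance",
    "estimate_unknown",
    "profile_sample",
    "write_profile",
    "read_profile",
]

DEFAULT_STAT_Q = 0.2
DEFAULT_MIN_READ_LEN = 70
DEFAULT_MIN_MAPQ = 5
# a species is reported only if more than this fraction of its usable
# markers has nonzero depth
DEFAULT_DETECTION_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class ReadAlignment:
    """One read aligned to one marker (0-based half-open interval)."""

    read_id: str
    marker_id: str
    mapq: int
    read_length: int
    aligned_start: int
    aligned_end: int

    @property
    def aligned_bases(self) -> int:
        return self.aligned_end - self.aligned_start


@dataclass
class CladeCoverage:
    taxid: int
    coverage: float
    n_markers_used: int
    n_markers_total: int


@dataclass
class ProfileRow:
    taxonomy_path: str
    taxid_path: str
    rank: str
    relative_abundance: float

    @property
    def taxid(self) -> int:
        return int(self.taxid_path.rsplit("|", 1)[-1])


@dataclass
class TaxonomicProfile:
    rows: list[ProfileRow]
    unknown_fraction: float = 0.0
    total_reads: int = 0
    sample_id: str = "sample"

    def at_rank(self, rank: str) -> list[ProfileRow]:
        return [r for r in self.rows if r.rank == rank]

    def abundance_of(self, taxid: int) -> float:
        for r in self.rows:
            if r.taxid == taxid:
                return r.relative_abundance
        return 0.0

    @property
    def species_taxids(self) -> set[int]:
        return {r.taxid for r in self.at_rank("species")}


def filter_alignments(
    alignments: Iterable[ReadAlignment],
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[ReadAlignment]:
    """Drop reads shorter than 70 bp and alignments with MAPQ below 5."""
    return [
        a
        for a in alignments
        if a.read_length >= min_read_len and a.mapq >= min_mapq
    ]


def dedupe_reads(alignments: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Keep one alignment per read: highest MAPQ, then most aligned bases,
    then lexicographically smallest marker id."""
    best: dict[str, ReadAlignment] = {}
    for a in alignments:
        cur = best.get(a.read_id)
        if cur is None or (-a.mapq, -a.aligned_bases, a.marker_id) < (
            -cur.mapq,
            -cur.aligned_bases,
            cur.marker_id,
        ):
            best[a.read_id] = a
    return list(best.values())


def marker_coverage(
    alignments: Iterable[ReadAlignment],
    marker_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Depth of each hit marker: total aligned bases / marker length."""
    bases: dict[str, int] = {}
    for a in alignments:
        if a.marker_id not in marker_lengths:
            raise KeyError(f"unknown marker {a.marker_id!r}")
        bases[a.marker_id] = bases.get(a.marker_id, 0) + a.aligned_bases
    return {m: b / marker_lengths[m] for m, b in bases.items()}


def clade_coverage(
    depths: Sequence[float],
    stat_q: float = DEFAULT_STAT_Q,
) -> float:
    """Robust (quantile-trimmed) average of per-marker depths.

    Sorts the depth vector (zeros for unhit markers included by the caller)
    and removes floor(stat_q * n) entries from each end before averaging.
    """
    if not 0.0 <= stat_q < 0.5:
        raise ValueError("stat_q must lie in [0, 0.5)")
    n = len(depths)
    if n == 0:
        return 0.0
    k = math.floor(stat_q * n)
    trimmed = sorted(depths)[k : n - k]
    if not trimmed:
        return 0.0
    return float(sum(trimmed) / len(trimmed))


def _species_depth_vectors(
    depths: Mapping[str, float],
    db: MarkerDatabase,
) -> dict[int, dict[str, float]]:
    """Full per-species depth vectors (zero-filled) with quasi-marker
    discounting.

    A species counts as independently detected when at least one of its
    unique markers has nonzero depth.  Quasi-markers whose external-species
    list intersects the detected set are excluded from their own species'
    vector, since their signal may come from the external species.
    """
    detected: set[int] = set()
    for taxid in db.species:
        for m in db.markers_for(taxid):
            if m.is_unique and depths.get(m.marker_id, 0.0) > 0.0:
                detected.add(taxid)
                break

    vectors: dict[int, dict[str, float]] = {}
    for taxid in db.species:
        vec: dict[str, float] = {}
        for m in db.markers_for(taxid):
            if not m.is_unique and m.ext_species & detected:
                continue
            vec[m.marker_id] = depths.get(m.marker_id, 0.0)
        vectors[taxid] = vec
    return vectors


def species_coverages(
    depths: Mapping[str, float],
    db: MarkerDatabase,
    stat_q: float = DEFAULT_STAT_Q,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
) -> dict[int, CladeCoverage]:
    """Trimmed-mean coverage of every detected species."""
    out: dict[int, CladeCoverage] = {}
    for taxid, vec in _species_depth_vectors(depths, db).items():
        values = list(vec.values())
        if not values:
            continue
        nonzero = sum(1 for v in values if v > 0)
        if nonzero / len(values) <= detection_fraction:
            continue
        cov = clade_coverage(values, stat_q)
        if cov > 0:
            out[taxid] = CladeCoverage(
                taxid=taxid,
                coverage=cov,
                n_markers_used=len(values),
                n_markers_total=len(db.markers_for(taxid)),
            )
    return out


def aggregate_taxonomy(
    species_cov: Mapping[int, CladeCoverage] | Mapping[int, float],
    taxonomy: Taxonomy,
) -> dict[int, float]:
    """Coverage of every clade at every rank: sum over detected descendants."""
    cov: dict[int, float] = {}
    for taxid, c in species_cov.items():
        value = c.coverage if isinstance(c, CladeCoverage) else float(c)
        if taxid not in taxonomy:
            raise KeyError(f"taxid {taxid} missing from taxonomy")
        for t in taxonomy.lineage(taxid):
            cov[t] = cov.get(t, 0.0) + value
    return cov


def relative_abundance(
    clade_cov: Mapping[int, float],
    taxonomy: Taxonomy,
) -> TaxonomicProfile:
    """Normalize coverages into percent relative abundances per rank."""
    rank_sums: dict[str, float] = {}
    for taxid, c in clade_cov.items():
        rank_sums[taxonomy.rank(taxid)] = rank_sums.get(taxonomy.rank(taxid), 0.0) + c
    rows = []
    rank_order = {r: i for i, r in enumerate(Taxonomy.RANKS)}
    for taxid in sorted(
        clade_cov, key=lambda t: (rank_order[taxonomy.rank(t)], taxonomy.path(t))
    ):
        total = rank_sums[taxonomy.rank(taxid)]
        if total <= 0:
            continue
        rows.append(
            ProfileRow(
                taxonomy_path=taxonomy.path(taxid),
                taxid_path=taxonomy.taxid_path(taxid),
                rank=taxonomy.rank(taxid),
                relative_abundance=100.0 * clade_cov[taxid] / total,
            )
        )
    return TaxonomicProfile(rows=rows)


def estimate_unknown(
    total_reads: int,
    species_cov: Mapping[int, CladeCoverage] | Mapping[int, float],
    taxonomy: Taxonomy,
    read_length: float,
) -> float:
    """Percent of reads not explained by detected taxa.

    Each species explains coverage * average genome length / read length
    reads; the remainder (if positive) is the unknown fraction.
    """
    if read_length <= 0:
        raise ValueError("read length must be positive")
    if total_reads <= 0:
        return 100.0
    explained = 0.0
    for taxid, c in species_cov.items():
        value = c.coverage if isinstance(c, CladeCoverage) else float(c)
        explained += value * taxonomy.avg_genome_length(taxid) / read_length
    return 100.0 * max(0.0, total_reads - explained) / total_reads


def profile_sample(
    alignments: Iterable[ReadAlignment],
    db: MarkerDatabase,
    total_reads: int,
    stat_q: float = DEFAULT_STAT_Q,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
    sample_id: str = "sample",
) -> TaxonomicProfile:
    """Full profiling pipeline: filter, depth, robust average, normalize."""
    kept = filter_alignments(alignments, min_read_len, min_mapq)
    kept = dedupe_reads(kept)
    lengths = {m.marker_id: m.length for m in db.markers}
    depths = marker_coverage(kept, lengths)
    sp_cov = species_coverages(depths, db, stat_q, detection_fraction)

    mean_read_len = (
        float(np.mean([a.read_length for a in kept])) if kept else 0.0
    )
    if sp_cov and mean_read_len > 0:
        unknown = estimate_unknown(total_reads, sp_cov, db.taxonomy, mean_read_len)
    else:
        unknown = 100.0

    clade_cov = aggregate_taxonomy(sp_cov, db.taxonomy) if sp_cov else {}
    prof = relative_abundance(clade_cov, db.taxonomy)
    scale = (100.0 - unknown) / 100.0
    for row in prof.rows:
        row.relative_abundance *= scale
    prof.unknown_fraction = unknown
    prof.total_reads = total_reads
    prof.sample_id = sample_id
    return prof


# ---------------------------------------------------------------------------
# output formats

_MPA_HEADER = "#clade_name\tNCBI_tax_id\trelative_abundance"
_CAMI_RANKS = "superkingdom|phylum|class|order|family|genus|species"
# our internal rank names <-> CAMI rank names
_RANK_TO_CAMI = dict(zip(Taxonomy.RANKS, _CAMI_RANKS.split("|")))
_CAMI_TO_RANK = {v: k for k, v in _RANK_TO_CAMI.items()}


def write_profile(profile: TaxonomicProfile, format: str = "metaphlan") -> str:
    """Render a profile as text in the 'metaphlan' or 'cami' dialect."""
    if format == "metaphlan":
        lines = [
            f"#SampleID\t{profile.sample_id}",
            f"#total_reads\t{profile.total_reads}",
            _MPA_HEADER,
            f"UNKNOWN\t-1\t{profile.unknown_fraction!r}",
        ]
        for r in profile.rows:
            lines.append(
                f"{r.taxonomy_path}\t{r.taxid_path}\t{r.relative_abundance!r}"
            )
        return "\n".join(lines) + "\n"
    if format == "cami":
        lines = [
            f"@SampleID:{profile.sample_id}",
            "@Version:0.9.1",
            f"@Ranks:{_CAMI_RANKS}",
            "@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE",
        ]
        for r in profile.rows:
            names = "|".join(p[3:] for p in r.taxonomy_path.split("|"))
            lines.append(
                "\t".join(
                    [
                        str(r.taxid),
                        _RANK_TO_CAMI[r.rank],
                        r.taxid_path,
                        names,
                        repr(r.relative_abundance),
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown profile format {format!r}")


def read_profile(text: str, format: str = "metaphlan") -> TaxonomicProfile:
    """Parse text produced by :func:`write_profile` back into a profile."""
    if format == "metaphlan":
        prof = TaxonomicProfile(rows=[])
        for line in text.splitlines():
            if not line:
                continue
            if line.startswith("#SampleID"):
                prof.sample_id = line.split("\t", 1)[1]
            elif line.startswith("#total_reads"):
                prof.total_reads = int(line.split("\t", 1)[1])
            elif line.startswith("#"):
                continue
            elif line.startswith("UNKNOWN"):
                prof.unknown_fraction = float(line.split("\t")[2])
            else:
                path, taxid_path, ab = line.split("\t")
                n_levels = path.count("|")
                prof.rows.append(
                    ProfileRow(
                        taxonomy_path=path,
                        taxid_path=taxid_path,
                        rank=Taxonomy.RANKS[n_levels],
                        relative_abundance=float(ab),
                    )
                )
        return prof
    if format == "cami":
        prof = TaxonomicProfile(rows=[])
        species_sum = 0.0
        have_species = False
        for line in text.splitlines():
            if not line or line.startswith("@@"):
                continue
            if line.startswith("@SampleID:"):
                prof.sample_id = line.split(":", 1)[1]
                continue
            if line.startswith("@"):
                continue
            taxid, cami_rank, taxpath, names, pct = line.split("\t")
            rank = _CAMI_TO_RANK[cami_rank]
            prefixes = [Taxonomy.RANK_PREFIX[Taxonomy.RANKS[i]] for i in range(taxpath.count("|") + 1)]
            tax_path = "|".join(p + n for p, n in zip(prefixes, names.split("|")))
            prof.rows.append(
                ProfileRow(
                    taxonomy_path=tax_path,
                    taxid_path=taxpath,
                    rank=rank,
                    relative_abundance=float(pct),
                )
            )
            if rank == "species":
                have_species = True
                species_sum += float(pct)
        if have_species:
            prof.unknown_fraction = max(0.0, 100.0 - species_sum)
        else:
            prof.unknown_fraction = 100.0
        return prof
    raise ValueError(f"unknown profile format {format!r}")
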