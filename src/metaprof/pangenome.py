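"""Gene-family presence/absence strain typing from pangenome coverage.

Per-gene sequencing depths are normalized into gene-family coverages, the
family coverage curve of a species in a sample is inspected for a plateau
indicating a present strain, and families are called present or absent
relative to the plateau level.  Also provides Jaccard/Ward clustering of
the binary matrix and an empirical test for physical clustering of
co-occurring families along a contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "FamilyCoverageVector",
    "PresenceAbsenceCall",
    "PresenceAbsenceMatrix",
    "GeneClusterTest",
    "family_coverage",
    "call_presence_absence",
    "build_matrix",
    "prefilter_matrix",
    "cluster_families",
    "gene_cluster_pvalue",
    "write_matrix",
    "read_matrix",
]

DEFAULT_MIN_COVERAGE = 2.0
DEFAULT_LEFT_MAX = 1.25
DEFAULT_RIGHT_MIN = 0.75


@dataclass
class FamilyCoverageVector:
    sample_id: str
    species_taxid: int
    coverage: dict[str, float]


@dataclass
class PresenceAbsenceCall:
    sample_id: str
    detectable: bool
    presence: dict[str, bool]
    plateau: float


@dataclass
class PresenceAbsenceMatrix:
    """Binary family x sample matrix; columns only for detectable samples."""

    matrix: pd.DataFrame  # bool, families as index, samples as columns
    min_coverage: float = DEFAULT_MIN_COVERAGE
    left_max: float = DEFAULT_LEFT_MAX
    right_min: float = DEFAULT_RIGHT_MIN

    @property
    def families(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)


def family_coverage(
    gene_depths: Mapping[str, float],
    gene_lengths: Mapping[str, int],
    family_map: Mapping[str, str],
    sample_id: str = "sample",
    species_taxid: int = 0,
) -> FamilyCoverageVector:
    """Normalize per-gene depths into per-family coverages.

    cov(F) = sum over genes of depth * length, divided by the family's
    average gene length.  The base-count numerator makes the value
    invariant to splitting a gene's alignments into fragments.  Genes
    absent from ``gene_depths`` count as depth 0.
    """
    fam_genes: dict[str, list[str]] = {}
    for gene, fam in family_map.items():
        fam_genes.setdefault(fam, []).append(gene)
    cov: dict[str, float] = {}
    for fam, genes in fam_genes.items():
        if not genes:
            raise ValueError(f"empty family {fam}")
        lengths = [gene_lengths[g] for g in genes]
        if any(l <= 0 for l in lengths):
            raise ValueError(f"non-positive gene length in family {fam}")
        bases = sum(gene_depths.get(g, 0.0) * gene_lengths[g] for g in genes)
        cov[fam] = bases / (sum(lengths) / len(lengths))
    return FamilyCoverageVector(
        sample_id=sample_id, species_taxid=species_taxid, coverage=cov
    )


def call_presence_absence(
    vector: FamilyCoverageVector,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    left_max: float = DEFAULT_LEFT_MAX,
    right_min: float = DEFAULT_RIGHT_MIN,
) -> PresenceAbsenceCall:
    """Strain detection and per-family presence calls for one sample.

    The family coverages are sorted descending into a coverage curve over
    the k families with nonzero coverage; the plateau level is the median
    of that curve.  The sample is detectable when the plateau reaches
    ``min_coverage`` and the curve values at the quartile edges (ranks
    0.25k and 0.75k) stay within ``left_max`` / ``right_min`` times the
    plateau — a steeply decaying curve indicates no resident strain.  In a
    detectable sample a family is present when its coverage reaches half
    the plateau (with an absolute floor of min_coverage / 2).
    """
    values = np.sort(np.asarray(list(vector.coverage.values()), dtype=float))[::-1]
    nonzero = values[values > 0]
    k = len(nonzero)
    if k == 0:
        return PresenceAbsenceCall(vector.sample_id, False, {}, 0.0)
    plateau = float(np.median(nonzero))
    left_idx = min(int(0.25 * k), k - 1)
    right_idx = min(int(0.75 * k), k - 1)
    detectable = (
        plateau >= min_coverage
        and nonzero[left_idx] <= left_max * plateau
        and nonzero[right_idx] >= right_min * plateau
    )
    if not detectable:
        return PresenceAbsenceCall(vector.sample_id, False, {}, plateau)
    threshold = max(plateau / 2.0, min_coverage / 2.0)
    presence = {f: c >= threshold for f, c in vector.coverage.items()}
    return PresenceAbsenceCall(vector.sample_id, True, presence, plateau)


def build_matrix(
    calls: Iterable[PresenceAbsenceCall],
    families: Sequence[str],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    left_max: float = DEFAULT_LEFT_MAX,
    right_min: float = DEFAULT_RIGHT_MIN,
) -> PresenceAbsenceMatrix:
    """Assemble detectable samples into a binary family x sample matrix."""
    cols = {}
    for call in calls:
        if not call.detectable:
            continue
        cols[call.sample_id] = [call.presence.get(f, False) for f in families]
    df = pd.DataFrame(cols, index=list(families), dtype=bool)
    return PresenceAbsenceMatrix(df, min_coverage, left_max, right_min)


def prefilter_matrix(
    pa: PresenceAbsenceMatrix,
    min_samples_present: int = 2,
    min_absences: int = 6,
    extreme_low: float = 0.05,
    extreme_high: float = 0.95,
) -> PresenceAbsenceMatrix:
    """Two-round family filter used before clustering/visualization.

    First discards families present in fewer than two samples or absent in
    five or fewer; a second, more stringent round removes families present
    in more than 95% or less than 5% of the remaining samples.
    """
    df = pa.matrix
    n = df.shape[1]
    present = df.sum(axis=1)
    keep = (present >= min_samples_present) & ((n - present) >= min_absences)
    df = df.loc[keep]
    frac = df.sum(axis=1) / n
    df = df.loc[(frac >= extreme_low) & (frac <= extreme_high)]
    return PresenceAbsenceMatrix(df, pa.min_coverage, pa.left_max, pa.right_min)


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_clusters: dict[str, int]


def cluster_families(
    pa: PresenceAbsenceMatrix,
    n_clusters: int = 2,
) -> ClusterResult:
    """Hierarchical (Ward) clustering of Jaccard fingerprints.

    Clusters both gene families (rows) and samples (columns); leaf order is
    the deterministic scipy dendrogram order.
    """
    df = pa.matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("matrix too small to cluster")
    x = df.to_numpy(dtype=bool)
    row_link = hierarchy.linkage(pdist(x, metric="jaccard"), method="ward")
    col_link = hierarchy.linkage(pdist(x.T, metric="jaccard"), method="ward")
    row_order = [df.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [df.columns[i] for i in hierarchy.leaves_list(col_link)]
    labels = hierarchy.fcluster(row_link, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        row_clusters=dict(zip(df.index, (int(l) for l in labels))),
    )


@dataclass
class GeneClusterTest:
    genes: list[str]
    statistic: float
    p_value: float
    n_permutations: int


def _span_statistic(coords: Sequence[tuple[int, int]]) -> float:
    """Sum of gene lengths over the total span (max end - min start)."""
    total = sum(e - s for s, e in coords)
    span = max(e for _, e in coords) - min(s for s, _ in coords)
    return total / span if span > 0 else 1.0


def gene_cluster_pvalue(
    cluster_genes: Mapping[str, tuple[int, int]],
    contig_genes: Mapping[str, tuple[int, int]],
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> GeneClusterTest:
    """Empirical p-value for physical proximity of a gene group on a contig.

    The observed statistic is the summed gene length of the group divided
    by its span along the contig (1 for perfectly adjacent genes).  The
    null draws random same-size gene sets from the contig's genes;
    p = (1 + #null >= observed) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    missing = set(cluster_genes) - set(contig_genes)
    if missing:
        raise ValueError(f"cluster genes not on contig: {sorted(missing)}")
    k = len(cluster_genes)
    observed = _span_statistic(list(cluster_genes.values()))
    rng = np.random.default_rng(seed)
    all_coords = list(contig_genes.values())
    hits = 0
    for _ in range(n_permutations):
        idx = rng.choice(len(all_coords), size=k, replace=False)
        if _span_statistic([all_coords[i] for i in idx]) >= observed:
            hits += 1
    return GeneClusterTest(
        genes=sorted(cluster_genes),
        statistic=observed,
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


def write_matrix(pa: PresenceAbsenceMatrix) -> str:
    """Presence/absence matrix as TSV (families x samples, 0/1 entries)."""
    df = pa.matrix.astype(int)
    return df.to_csv(sep="\t", index_label="family")


def read_matrix(text: str) -> PresenceAbsenceMatrix:
    import io as _io

    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col="family")
    return PresenceAbsenceMatrix(df.astype(bool))
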