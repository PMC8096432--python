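"""Readers and writers for the on-disk interchange formats.

Genomes travel as FASTA plus a gene-coordinate TSV; taxonomies as TSV;
marker databases as FASTA plus a metadata TSV and a JSON manifest; read
alignments as SAM (reference names are marker/pangene ids) or a simple
tabular format.  Binary formats are handled by the established libraries
(Biopython for FASTA, pysam for SAM/BAM).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .markerdb import (
    Gene,
    GenomeRecord,
    MarkerDatabase,
    MarkerRecord,
    Taxonomy,
)
from .taxprofile import ReadAlignment

GENE_TABLE_COLUMNS = [
    "gene_id",
    "genome_id",
    "contig",
    "start",
    "end",
    "strand",
    "family90",
    "family50",
    "protein_len",
    "species_taxid",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genomes(
    genomes: Sequence[GenomeRecord], fasta_path: str | Path, genes_path: str | Path
) -> None:
    """One FASTA of all contigs plus the gene coordinate table."""
    contigs = {}
    rows = []
    for g in genomes:
        for cid, seq in g.contigs.items():
            contigs[cid] = seq
        for gene in g.genes:
            rows.append(
                [
                    gene.gene_id,
                    g.genome_id,
                    gene.contig_id,
                    gene.start,
                    gene.end,
                    gene.strand,
                    gene.family90_id,
                    gene.family50_id,
                    gene.protein_length,
                    g.species_taxid,
                ]
            )
    write_fasta(contigs, fasta_path)
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(
        genes_path, sep="\t", index=False
    )


def read_genomes(
    fasta_path: str | Path, genes_path: str | Path
) -> dict[int, list[GenomeRecord]]:
    """Rebuild GenomeRecords grouped by species taxid."""
    contigs = read_fasta(fasta_path)
    table = pd.read_csv(genes_path, sep="\t")
    by_genome: dict[str, dict] = {}
    for row in table.itertuples(index=False):
        entry = by_genome.setdefault(
            row.genome_id,
            {"species_taxid": int(row.species_taxid), "contigs": {}, "genes": []},
        )
        entry["contigs"][row.contig] = contigs[row.contig]
        entry["genes"].append(
            Gene(
                gene_id=row.gene_id,
                contig_id=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                protein_length=int(row.protein_len),
                family90_id=row.family90,
                family50_id=row.family50,
            )
        )
    out: dict[int, list[GenomeRecord]] = {}
    for genome_id, entry in by_genome.items():
        out.setdefault(entry["species_taxid"], []).append(
            GenomeRecord(
                genome_id=genome_id,
                species_taxid=entry["species_taxid"],
                contigs=entry["contigs"],
                genes=entry["genes"],
            )
        )
    return out


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        [taxid, node["parent"], node["rank"], node["name"], node["avg_genome_length"]]
        for taxid, node in taxonomy.nodes.items()
    ]
    pd.DataFrame(
        rows, columns=["taxid", "parent_taxid", "rank", "name", "avg_genome_length"]
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Taxonomy:
    tax = Taxonomy()
    for row in pd.read_csv(path, sep="\t").itertuples(index=False):
        tax.add_node(
            int(row.taxid),
            row.name,
            row.rank,
            int(row.parent_taxid),
            float(row.avg_genome_length),
        )
    return tax


def write_marker_database(db: MarkerDatabase, out_dir: str | Path) -> None:
    """Marker FASTA + metadata TSV + taxonomy TSV + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({m.marker_id: m.sequence for m in db.markers}, out / "markers.fna")
    rows = [
        [
            m.marker_id,
            m.species_taxid,
            m.tier,
            m.score,
            m.length,
            ",".join(str(t) for t in sorted(m.ext_species)),
            m.taxonomy_path,
        ]
        for m in db.markers
    ]
    pd.DataFrame(
        rows,
        columns=["marker_id", "taxid", "tier", "score", "length", "ext_species", "taxonomy_path"],
    ).to_csv(out / "markers.tsv", sep="\t", index=False)
    write_taxonomy(db.taxonomy, out / "taxonomy.tsv")
    digest = hashlib.sha256(
        "".join(m.marker_id + m.sequence for m in db.markers).encode()
    ).hexdigest()
    manifest = {
        "n_markers": len(db.markers),
        "n_species": len(db.species),
        "content_sha256": digest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_marker_database(db_dir: str | Path) -> MarkerDatabase:
    db_dir = Path(db_dir)
    seqs = read_fasta(db_dir / "markers.fna")
    meta = pd.read_csv(db_dir / "markers.tsv", sep="\t", keep_default_na=False)
    markers = []
    for row in meta.itertuples(index=False):
        ext = (
            {int(t) for t in str(row.ext_species).split(",") if t}
            if row.ext_species
            else set()
        )
        markers.append(
            MarkerRecord(
                marker_id=row.marker_id,
                species_taxid=int(row.taxid),
                sequence=seqs[row.marker_id],
                tier=row.tier,
                score=float(row.score),
                ext_species=ext,
                taxonomy_path=row.taxonomy_path,
            )
        )
    return MarkerDatabase(markers=markers, taxonomy=read_taxonomy(db_dir / "taxonomy.tsv"))


def read_sam_alignments(path: str | Path) -> list[ReadAlignment]:
    """Read-to-marker alignments from SAM/BAM (reference names = marker ids)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    marker_id=rec.reference_name,
                    mapq=rec.mapping_quality,
                    read_length=rec.query_length or len(rec.query_sequence or ""),
                    aligned_start=rec.reference_start,
                    aligned_end=rec.reference_end or rec.reference_start,
                )
            )
    return out


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    rows = [
        [a.read_id, a.marker_id, a.mapq, a.read_length, a.aligned_start, a.aligned_end]
        for a in alignments
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "marker_id", "mapq", "read_length", "aligned_start", "aligned_end"],
    ).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> list[ReadAlignment]:
    return [
        ReadAlignment(
            read_id=row.read_id,
            marker_id=row.marker_id,
            mapq=int(row.mapq),
            read_length=int(row.read_length),
            aligned_start=int(row.aligned_start),
            aligned_end=int(row.aligned_end),
        )
        for row in pd.read_csv(path, sep="\t").itertuples(index=False)
    ]
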