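"""Synthetic genomes, pangenomes, strains, communities and reads.

Every downstream module is testable without downloads: this module builds
species pangenomes with core and accessory gene families, multi-species
communities with log-normal abundances, strain variants differing by placed
SNVs and accessory-family deletions, and (optionally paired) reads with a
configurable substitution error rate — together with gold-standard
taxonomic, functional and strain truths.  All randomness flows from an
explicit seed; outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .markerdb import Gene, GenomeRecord, Taxonomy, reverse_complement
from .taxprofile import TaxonomicProfile, aggregate_taxonomy, relative_abundance

__all__ = [
    "CommunitySpec",
    "StrainSpec",
    "SimRead",
    "StrainTruth",
    "simulate_pangenome",
    "simulate_universe",
    "simulate_reads",
    "gold_taxonomic_profile",
    "simulate_strain",
    "simulate_strain_cohort",
    "tile_reads",
    "reads_to_fastq",
]

_BASES = np.array(list("ACGT"))

DEFAULT_GENE_LEN_RANGE = (600, 1500)  # nt, realistic bacterial gene sizes
DEFAULT_SPACER_RANGE = (60, 150)  # intergenic spacers, nt
DEFAULT_MINUS_FRACTION = 0.3


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str
    species_taxid: int
    genome_id: str
    contig_id: str
    start: int
    strand: str
    mate: int = 0  # 0 = unpaired, 1/2 = mate number


@dataclass
class CommunitySpec:
    """A synthetic community: species, abundance model and read parameters."""

    species: list[int]
    n_reads: int = 50_000
    read_length: int = 150
    paired: bool = False
    error_rate: float = 0.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def draw_abundances(self) -> dict[int, float]:
        """Log-normal cell-ratio abundances, sum-normalized to 1."""
        rng = np.random.default_rng(self.seed)
        raw = rng.lognormal(self.lognormal_mu, self.lognormal_sigma, len(self.species))
        raw = raw / raw.sum()
        return dict(zip(self.species, raw.tolist()))


@dataclass
class StrainSpec:
    strain_id: str
    n_snvs: int = 20
    deletion_fraction: float = 0.0
    seed: int = 0


def simulate_pangenome(
    species_taxid: int,
    n_genomes: int,
    n_core: int,
    n_accessory: int,
    seed: int = 0,
    gene_len_range: tuple[int, int] = DEFAULT_GENE_LEN_RANGE,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
    minus_fraction: float = DEFAULT_MINUS_FRACTION,
    family_prefix: str | None = None,
) -> list[GenomeRecord]:
    """Simulate the genomes of one species sharing a pangenome.

    Core families appear in every genome with an identical sequence;
    each accessory family appears in a random nonempty proper subset of the
    genomes (when more than one genome is simulated).  Genes are laid out
    on a single contig separated by random spacers; a fraction is placed on
    the minus strand.  Each 90%-identity family gets its own 50%-identity
    parent family.
    """
    if n_core + n_accessory < 1:
        raise ValueError("need at least one gene family")
    rng = np.random.default_rng(seed)
    prefix = family_prefix or f"S{species_taxid}"

    fam_ids = [f"{prefix}_F{i:04d}" for i in range(n_core + n_accessory)]
    lengths = {
        f: 3 * int(rng.integers(gene_len_range[0] // 3, gene_len_range[1] // 3 + 1))
        for f in fam_ids
    }
    sequences = {f: _random_seq(rng, lengths[f]) for f in fam_ids}
    core = fam_ids[:n_core]
    accessory = fam_ids[n_core:]

    # which genomes carry each accessory family (nonempty subsets)
    carriers: dict[str, set[int]] = {}
    for f in accessory:
        if n_genomes == 1:
            carriers[f] = {0}
        else:
            size = int(rng.integers(1, n_genomes))
            carriers[f] = set(rng.choice(n_genomes, size=size, replace=False).tolist())

    genomes = []
    for gi in range(n_genomes):
        genome_id = f"G{species_taxid}.{gi}"
        fams = core + [f for f in accessory if gi in carriers[f]]
        order = list(rng.permutation(len(fams)))
        contig_parts = []
        genes = []
        pos = 0
        contig_id = f"{genome_id}_c0"
        for idx in order:
            fam = fams[idx]
            spacer = _random_seq(rng, int(rng.integers(*spacer_range)))
            contig_parts.append(spacer)
            pos += len(spacer)
            seq = sequences[fam]
            strand = "-" if rng.random() < minus_fraction else "+"
            placed = reverse_complement(seq) if strand == "-" else seq
            contig_parts.append(placed)
            genes.append(
                Gene(
                    gene_id=f"{genome_id}|{fam}",
                    contig_id=contig_id,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                    protein_length=len(seq) // 3,
                    family90_id=fam,
                    family50_id=fam + "_50",
                )
            )
            pos += len(seq)
        contig_parts.append(_random_seq(rng, int(rng.integers(*spacer_range))))
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                species_taxid=species_taxid,
                contigs={contig_id: "".join(contig_parts)},
                genes=genes,
            )
        )
    return genomes


def build_taxonomy(
    genomes_by_species: Mapping[int, Sequence[GenomeRecord]],
    species_names: Mapping[int, str] | None = None,
    species_per_genus: int = 2,
) -> Taxonomy:
    """A small rank-complete taxonomy over the simulated species.

    All species share one kingdom/phylum/class/order/family chain and are
    grouped into genera of ``species_per_genus``.
    """
    tax = Taxonomy()
    chain = [
        (2, "Bacteria", "kingdom"),
        (1224, "Simulatota", "phylum"),
        (1236, "Simulatia", "class"),
        (91347, "Simulatales", "order"),
        (543, "Simulataceae", "family"),
    ]
    parent = 2
    for taxid, name, rank in chain:
        tax.add_node(taxid, name, rank, parent)
        parent = taxid
    for i, taxid in enumerate(sorted(genomes_by_species)):
        genus_idx = i // species_per_genus
        genus_taxid = 10_000 + genus_idx
        if genus_taxid not in tax:
            tax.add_node(genus_taxid, f"Simulatus_{genus_idx}", "genus", 543)
        genomes = genomes_by_species[taxid]
        avg_len = float(np.mean([g.length for g in genomes]))
        name = (
            species_names[taxid]
            if species_names
            else f"Simulatus_{genus_idx}_species_{taxid}"
        )
        tax.add_node(taxid, name, "species", genus_taxid, avg_genome_length=avg_len)
    return tax


def simulate_universe(
    n_species: int = 10,
    genomes_per_species: int | Sequence[int] = 3,
    n_core: int = 40,
    n_accessory: int = 10,
    seed: int = 0,
    shared_family_pairs: int = 0,
    **pangenome_kwargs,
) -> tuple[dict[int, list[GenomeRecord]], Taxonomy]:
    """Multiple species pangenomes plus a matching taxonomy.

    ``shared_family_pairs`` plants a core family of one species into a
    genome of another, creating quasi-marker candidates with nonzero
    uniqueness.
    """
    rng = np.random.default_rng(seed)
    if isinstance(genomes_per_species, int):
        counts = [genomes_per_species] * n_species
    else:
        counts = list(genomes_per_species)
        if len(counts) != n_species:
            raise ValueError("genomes_per_species length mismatch")
    taxids = [1000 + i for i in range(n_species)]
    genomes_by_species = {
        taxid: simulate_pangenome(
            taxid,
            counts[i],
            n_core,
            n_accessory,
            seed=int(rng.integers(0, 2**31 - 1)),
            **pangenome_kwargs,
        )
        for i, taxid in enumerate(taxids)
    }

    for _ in range(shared_family_pairs):
        donor, recipient = rng.choice(taxids, size=2, replace=False).tolist()
        donor_genome = genomes_by_species[donor][0]
        core_genes = [g for g in donor_genome.genes if g.family90_id.endswith("0000")]
        gene = core_genes[0] if core_genes else donor_genome.genes[0]
        seq = donor_genome.gene_sequence(gene)
        target = genomes_by_species[recipient][0]
        contig_id = next(iter(target.contigs))
        start = len(target.contigs[contig_id])
        target.contigs[contig_id] += seq
        target.genes.append(
            Gene(
                gene_id=f"{target.genome_id}|{gene.family90_id}",
                contig_id=contig_id,
                start=start,
                end=start + len(seq),
                strand="+",
                protein_length=len(seq) // 3,
                family90_id=gene.family90_id,
                family50_id=gene.family50_id,
            )
        )

    taxonomy = build_taxonomy(genomes_by_species)
    return genomes_by_species, taxonomy


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    errs = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in errs:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


def simulate_reads(
    spec: CommunitySpec,
    genomes_by_species: Mapping[int, Sequence[GenomeRecord]],
) -> tuple[list[SimRead], dict[int, float], dict[int, float]]:
    """Sample community reads and return them with both gold scales.

    Read counts per species are multinomial with probability proportional
    to abundance x genome length (cells x genome size); start positions are
    uniform; strands are random; substitution errors occur at the spec'd
    per-base rate with Phred qualities encoded to match.  Returns (reads,
    gold coverage-scale percent, gold read-fraction percent): the coverage
    scale is the cell-ratio truth a coverage-based profiler estimates, the
    read fraction is what a read-counting profiler estimates.
    """
    rng = np.random.default_rng(spec.seed)
    abundances = spec.draw_abundances()
    genomes = {t: genomes_by_species[t][0] for t in spec.species}
    lengths = {t: genomes[t].length for t in spec.species}

    weights = np.array([abundances[t] * lengths[t] for t in spec.species])
    probs = weights / weights.sum()
    counts = rng.multinomial(spec.n_reads, probs)

    qual_char = chr(
        min(40, int(round(-10 * np.log10(max(spec.error_rate, 1e-4))))) + 33
    )
    quality = qual_char * spec.read_length

    reads: list[SimRead] = []
    rid = 0
    for taxid, n in zip(spec.species, counts):
        genome = genomes[taxid]
        contig_id, contig = next(iter(genome.contigs.items()))
        max_start = len(contig) - spec.read_length
        starts = rng.integers(0, max_start + 1, size=int(n))
        strands = rng.random(int(n)) < 0.5
        for start, minus in zip(starts.tolist(), strands.tolist()):
            frag = contig[start : start + spec.read_length]
            if minus:
                frag = reverse_complement(frag)
            frag = _apply_errors(rng, frag, spec.error_rate)
            reads.append(
                SimRead(
                    read_id=f"r{rid:07d}",
                    sequence=frag,
                    quality=quality,
                    species_taxid=taxid,
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    start=int(start),
                    strand="-" if minus else "+",
                )
            )
            rid += 1

    total_ab = sum(abundances.values())
    gold_coverage = {t: 100.0 * abundances[t] / total_ab for t in spec.species}
    total_w = weights.sum()
    gold_reads = {
        t: 100.0 * abundances[t] * lengths[t] / total_w for t in spec.species
    }
    return reads, gold_coverage, gold_reads


def gold_taxonomic_profile(
    gold_species_percent: Mapping[int, float],
    taxonomy: Taxonomy,
) -> TaxonomicProfile:
    """Expand per-species gold percentages into a rank-complete profile."""
    clade = aggregate_taxonomy(dict(gold_species_percent), taxonomy)
    return relative_abundance(clade, taxonomy)


@dataclass
class StrainTruth:
    strain_id: str
    snvs: list[tuple[str, int, str, str]]  # (contig, position, ref, alt)
    deleted_families: set[str]
    snv_genes: dict[str, list[int]] = field(default_factory=dict)  # gene -> offsets


def simulate_strain(
    base: GenomeRecord,
    spec: StrainSpec,
    core_families: set[str] | None = None,
) -> tuple[GenomeRecord, StrainTruth]:
    """Derive a strain genome: accessory deletions then placed SNVs.

    A ``deletion_fraction`` of the genome's accessory families (those not
    in ``core_families``; none deleted when the set is None and the
    fraction is 0) is excised, then ``n_snvs`` substitutions are placed at
    distinct positions inside the remaining genes.
    """
    rng = np.random.default_rng(spec.seed)

    deleted: set[str] = set()
    if spec.deletion_fraction > 0:
        accessory = sorted(
            {g.family90_id for g in base.genes}
            - (core_families or set())
        )
        n_del = int(round(spec.deletion_fraction * len(accessory)))
        if n_del > 0:
            deleted = set(
                np.array(accessory)[
                    rng.choice(len(accessory), size=n_del, replace=False)
                ].tolist()
            )

    # rebuild each contig without deleted gene intervals
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    for contig_id, seq in base.contigs.items():
        kept = sorted(
            (g for g in base.genes if g.contig_id == contig_id),
            key=lambda g: g.start,
        )
        parts = []
        pos = 0
        cursor = 0
        for g in kept:
            parts.append(seq[cursor : g.start])
            pos += g.start - cursor
            if g.family90_id in deleted:
                cursor = g.end
                continue
            parts.append(seq[g.start : g.end])
            genes.append(
                Gene(
                    gene_id=g.gene_id,
                    contig_id=contig_id,
                    start=pos,
                    end=pos + (g.end - g.start),
                    strand=g.strand,
                    protein_length=g.protein_length,
                    family90_id=g.family90_id,
                    family50_id=g.family50_id,
                )
            )
            pos += g.end - g.start
            cursor = g.end
        parts.append(seq[cursor:])
        contigs[contig_id] = "".join(parts)

    # SNVs at distinct positions inside retained genes
    gene_positions = [
        (g, off) for g in genes for off in range(0, g.end - g.start)
    ]
    if spec.n_snvs > len(gene_positions):
        raise ValueError("more SNVs requested than available gene positions")
    idx = rng.choice(len(gene_positions), size=spec.n_snvs, replace=False)
    snvs = []
    snv_genes: dict[str, list[int]] = {}
    mutable = {c: list(s) for c, s in contigs.items()}
    for i in sorted(idx.tolist()):
        g, off = gene_positions[i]
        pos = g.start + off
        ref = mutable[g.contig_id][pos]
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        mutable[g.contig_id][pos] = alt
        snvs.append((g.contig_id, pos, ref, alt))
        snv_genes.setdefault(g.gene_id, []).append(off)

    strain = GenomeRecord(
        genome_id=f"{base.genome_id}|{spec.strain_id}",
        species_taxid=base.species_taxid,
        contigs={c: "".join(s) for c, s in mutable.items()},
        genes=genes,
    )
    return strain, StrainTruth(
        strain_id=spec.strain_id,
        snvs=snvs,
        deleted_families=deleted,
        snv_genes=snv_genes,
    )


def simulate_strain_cohort(
    base: GenomeRecord,
    n_private_subjects: int,
    n_transmission_pairs: int,
    n_snvs: int = 20,
    samples_per_subject: int = 1,
    seed: int = 0,
) -> tuple[dict[str, GenomeRecord], dict[str, str], list[frozenset[str]], dict[str, StrainTruth]]:
    """A strain cohort with private strains plus transmission pairs.

    Every subject carries one strain derived from ``base`` by ``n_snvs``
    random substitutions; both subjects of a transmission pair carry the
    identical strain; longitudinal resamples of a subject are identical.
    Returns (samples, sample -> subject map, related subject pairs, per-
    subject strain truths).
    """
    rng = np.random.default_rng(seed)
    samples: dict[str, GenomeRecord] = {}
    subjects: dict[str, str] = {}
    related: list[frozenset[str]] = []
    truths: dict[str, StrainTruth] = {}

    def add_subject(subject_id: str, strain: GenomeRecord) -> None:
        for k in range(samples_per_subject):
            sample_id = f"{subject_id}_t{k}"
            samples[sample_id] = strain
            subjects[sample_id] = subject_id

    si = 0
    for _ in range(n_private_subjects):
        subject = f"subj{si:03d}"
        spec = StrainSpec(
            strain_id=subject, n_snvs=n_snvs, seed=int(rng.integers(0, 2**31 - 1))
        )
        strain, truth = simulate_strain(base, spec)
        truths[subject] = truth
        add_subject(subject, strain)
        si += 1
    for _ in range(n_transmission_pairs):
        donor, recipient = f"subj{si:03d}", f"subj{si + 1:03d}"
        si += 2
        spec = StrainSpec(
            strain_id=donor, n_snvs=n_snvs, seed=int(rng.integers(0, 2**31 - 1))
        )
        strain, truth = simulate_strain(base, spec)
        truths[donor] = truths[recipient] = truth
        add_subject(donor, strain)
        add_subject(recipient, strain)
        related.append(frozenset((donor, recipient)))
    return samples, subjects, related, truths


def tile_reads(
    sequence: str,
    depth: float,
    read_length: int,
    seed: int = 0,
    mode: str = "random",
) -> list[tuple[str, int]]:
    """Error-free reads over one sequence at an expected depth.

    ``mode="random"`` draws uniform random start positions (Poisson-like
    per-base depth); ``mode="uniform"`` spaces starts evenly so every
    position not closer than a read length to the end is covered at the
    requested depth exactly (up to rounding).
    """
    L = len(sequence)
    if L < read_length:
        return []
    n = max(1, int(round(depth * L / read_length)))
    if mode == "random":
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, L - read_length + 1, size=n).tolist()
    elif mode == "uniform":
        starts = np.floor(np.linspace(0, L - read_length, n)).astype(int).tolist()
    else:
        raise ValueError(f"unknown tiling mode {mode!r}")
    return [(sequence[s : s + read_length], int(s)) for s in starts]


def reads_to_fastq(reads: Sequence[SimRead]) -> str:
    """FASTQ (Phred+33) rendering of simulated reads."""
    out = []
    for r in reads:
        out.append(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}")
    return "\n".join(out) + "\n"
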