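"""End-to-end validation scenarios on synthetic communities.

Each function builds a fully synthetic input with known ground truth, runs
the corresponding pipeline, and returns the recovery metrics.  Where a
quantity has a simple independent definition (trimmed means, tier
thresholds, the marker score), the verification here re-derives it from
first principles rather than calling the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from . import simulate as sim
from .functional import (
    AnnotationRecord,
    NucleotideHit,
    TranslatedHit,
    coverage_filter,
    family_abundance,
    gold_standard_functional,
    nucleotide_assign,
    regroup,
    translated_assign,
)
from .markerdb import build_marker_database, build_pangenome
from .matcher import ExactMatcher, align_reads_to_markers
from .pangenome import call_presence_absence, family_coverage
from .strainprofile import (
    ConsensusMarker,
    ConsensusRejection,
    call_consensus,
    concatenate_alignment,
    filter_samples_and_markers,
    infer_transmission,
    nj_tree,
    normalized_tree_distances,
    pairwise_distances,
    pileup_from_reads,
)
from .taxprofile import clade_coverage, profile_sample


def _bray_curtis_similarity(a: dict, b: dict) -> float:
    keys = sorted(set(a) | set(b))
    x = np.array([a.get(k, 0.0) for k in keys], dtype=float)
    y = np.array([b.get(k, 0.0) for k in keys], dtype=float)
    x = x / x.sum()
    y = y / y.sum()
    return float(1.0 - 0.5 * np.abs(x - y).sum())


def evaluate_taxonomic_recovery(
    seed: int = 1,
    n_species: int = 15,
    n_reads: int = 50_000,
    read_length: int = 150,
) -> dict:
    """Species recovery on a log-normal community of error-free reads.

    Builds a complete marker database for the simulated universe, samples
    reads, maps them with the exact matcher and profiles the sample.
    Returns false positive / false negative species counts and the
    Bray-Curtis similarity to the coverage-scale gold standard.
    """
    genomes, tax = sim.simulate_universe(
        n_species=n_species,
        genomes_per_species=2,
        n_core=30,
        n_accessory=8,
        seed=seed,
        gene_len_range=(600, 1200),
    )
    db = build_marker_database(genomes, tax)
    spec = sim.CommunitySpec(
        species=sorted(genomes),
        n_reads=n_reads,
        read_length=read_length,
        lognormal_mu=0.0,
        lognormal_sigma=1.0,
        error_rate=0.0,
        seed=seed,
    )
    reads, gold_cov, _ = sim.simulate_reads(spec, genomes)
    matcher = ExactMatcher({m.marker_id: m.sequence for m in db.markers})
    alignments = align_reads_to_markers(reads, matcher)
    prof = profile_sample(alignments, db, total_reads=len(reads))
    truth = set(spec.species)
    found = prof.species_taxids
    est = {t: prof.abundance_of(t) for t in found}
    return {
        "false_positives": len(found - truth),
        "false_negatives": len(truth - found),
        "bray_curtis": _bray_curtis_similarity(est, gold_cov),
        "n": n_reads,
    }


def evaluate_trimmed_mean_oracle(max_n: int = 12) -> dict:
    """Exhaustive agreement of the robust average with sort-and-slice.

    The trimmed mean is permutation-invariant, so enumerating multisets
    (combinations with replacement over a 5-value alphabet) covers every
    distinct input of length <= max_n.
    """
    alphabet = (0.0, 0.25, 1.0, 3.5, 10.0)
    worst = 0.0
    n_cases = 0
    for n in range(1, max_n + 1):
        for combo in itertools.combinations_with_replacement(alphabet, n):
            for q in (0.0, 0.1, 0.2, 0.3):
                k = math.floor(q * n)
                sliced = sorted(combo)[k : n - k]
                expect = sum(sliced) / len(sliced) if sliced else 0.0
                got = clade_coverage(list(combo), q)
                worst = max(worst, abs(got - expect))
                n_cases += 1
    return {"max_abs_error": worst, "n": n_cases}


def _independent_tier(c, u90, u50, eg90, eg50, n_genomes):
    """Tier thresholds restated from the published rules."""
    if n_genomes == 1:
        return "U" if (u90 == 0 and u50 == 0) else None
    if c > 0.80 and u90 <= 2 and u50 <= 2 and eg90 <= 10 and eg50 <= 5:
        return "A"
    if 0.70 < c <= 0.80 and u90 <= 5 and u50 <= 5 and eg90 < 15 and eg50 < 10:
        return "B"
    if 0.50 < c <= 0.70 and u90 < 10 and u50 < 15 and eg90 < 25 and eg50 < 20:
        return "C"
    return None


def _independent_score(c, u90, u50):
    def su(u):
        return max(-math.log(1 - (1e4 - min(1e4, u)) / 1e4 + 1e-4) * 15, 0.0)

    return c * su(u50) * su(u90)


def evaluate_marker_selection(seed: int = 1, n_universes: int = 20) -> dict:
    """Re-verify selected markers against brute-force statistics.

    For every marker of every species in seeded synthetic universes, the
    coreness/uniqueness/external-genome statistics are recomputed by a
    direct double loop over genomes and the tier, score and the 150/10
    cap/floor are re-checked.  Returns the number of violations (0 when
    the selection is correct) and the number of markers audited.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    n_markers = 0
    for u in range(n_universes):
        n_species = int(rng.integers(3, 11))
        genomes_per = [int(rng.integers(1, 5)) for _ in range(n_species)]
        genomes, tax = sim.simulate_universe(
            n_species=n_species,
            genomes_per_species=genomes_per,
            n_core=int(rng.integers(12, 25)),
            n_accessory=int(rng.integers(4, 12)),
            seed=int(rng.integers(0, 2**31 - 1)),
            shared_family_pairs=int(rng.integers(0, 4)),
            gene_len_range=(450, 900),
        )
        db = build_marker_database(genomes, tax)
        pangenomes = {t: build_pangenome(g) for t, g in genomes.items()}
        for taxid in db.species:
            markers = db.markers_for(taxid)
            if not 10 <= len(markers) <= 150:
                violations += 1
            scores = [m.score for m in markers]
            if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
                violations += 1  # not ranked by score
            n_sp_genomes = len(genomes[taxid])
            for m in markers:
                n_markers += 1
                fam = m.marker_id.split("__", 1)[1]
                f50s = {
                    f.family50_id
                    for f in pangenomes[taxid].families.values()
                    if f.family90_id == fam
                }
                member = sum(
                    1
                    for gr in genomes[taxid]
                    if any(g.family90_id == fam for g in gr.genes)
                )
                u90 = u50 = eg90 = eg50 = 0
                for other, ogs in genomes.items():
                    if other == taxid:
                        continue
                    c90 = sum(
                        1 for gr in ogs if any(g.family90_id == fam for g in gr.genes)
                    )
                    c50 = sum(
                        1 for gr in ogs if any(g.family50_id in f50s for g in gr.genes)
                    )
                    u90 += c90 > 0
                    u50 += c50 > 0
                    eg90 += c90
                    eg50 += c50
                c = member / n_sp_genomes
                if _independent_tier(c, u90, u50, eg90, eg50, n_sp_genomes) != m.tier:
                    violations += 1
                if not math.isclose(
                    m.score, _independent_score(c, u90, u50), rel_tol=1e-9
                ):
                    violations += 1
    return {"violations": violations, "n": n_markers}


def evaluate_consensus_fidelity(
    seed: int = 1, n_strains: int = 30, depth: float = 10.0
) -> dict:
    """Consensus reconstruction from error-free reads at 10x.

    For each random strain, reads are tiled over its marker genes, pileups
    are built, and the consensus is compared base-by-base with the strain's
    true sequence at every covered (non-N) position.  Also injects a
    breadth-0.75 marker and a 7-read marker and checks both are rejected.
    """
    genomes, _ = sim.simulate_universe(
        n_species=1, genomes_per_species=1, n_core=8, n_accessory=2,
        seed=seed, gene_len_range=(450, 900),
    )
    base = genomes[1000][0]
    rng = np.random.default_rng(seed + 1)
    mismatches = covered = 0
    for k in range(n_strains):
        strain, _ = sim.simulate_strain(
            base, sim.StrainSpec(f"s{k}", n_snvs=15, seed=int(rng.integers(2**31)))
        )
        for g in strain.genes:
            truth = strain.gene_sequence(g)
            reads = sim.tile_reads(truth, depth, 150, seed=int(rng.integers(2**31)))
            pile = pileup_from_reads(g.family90_id, len(truth), reads)
            out = call_consensus(pile, sample_id=f"s{k}")
            if isinstance(out, ConsensusRejection):
                continue
            for got, want in zip(out.sequence, truth):
                if got == "N":
                    continue
                covered += 1
                mismatches += got != want
    # rejection checks
    g = base.genes[0]
    seq = base.gene_sequence(g)
    L = len(seq)
    partial = pileup_from_reads(
        "m", L, [(seq[: int(0.75 * L)], 0)] * 10
    )  # breadth 0.75
    breadth_rejected = isinstance(call_consensus(partial), ConsensusRejection)
    seven = pileup_from_reads("m", L, [(seq, 0)] * 7)
    reads_rejected = isinstance(call_consensus(seven), ConsensusRejection)
    eight = pileup_from_reads("m", L, [(seq, 0)] * 8)
    eight_accepted = isinstance(call_consensus(eight), ConsensusMarker)
    return {
        "identity_pct": 100.0 * (covered - mismatches) / covered if covered else 0.0,
        "n": covered,
        "breadth_rejected": int(breadth_rejected),
        "low_reads_rejected": int(reads_rejected and eight_accepted),
    }


def evaluate_transmission(
    seed: int = 1,
    n_unrelated: int = 40,
    n_pairs: int = 10,
    n_snvs: int = 25,
    depth: float = 10.0,
) -> dict:
    """Transmission inference on a seeded strain cohort.

    Unrelated subjects carry private strains; each transmission pair shares
    an identical strain.  Runs the full consensus -> filter -> concatenate
    -> distances -> tree -> threshold pipeline and reports how many pairs
    were called, whether the threshold separates them, and the fraction of
    unrelated pairs under the threshold.
    """
    genomes, _ = sim.simulate_universe(
        n_species=1, genomes_per_species=1, n_core=25, n_accessory=0,
        seed=seed, gene_len_range=(450, 750),
    )
    base = genomes[1000][0]
    samples, subjects, related, _ = sim.simulate_strain_cohort(
        base, n_unrelated, n_pairs, n_snvs=n_snvs, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    consensus = {}
    for sid, genome in samples.items():
        per = {}
        for g in genome.genes:
            truth = genome.gene_sequence(g)
            reads = sim.tile_reads(truth, depth, 150, seed=int(rng.integers(2**31)))
            out = call_consensus(
                pileup_from_reads(g.family90_id, len(truth), reads), sample_id=sid
            )
            if isinstance(out, ConsensusMarker):
                per[g.family90_id] = out
        consensus[sid] = per
    kept_samples, kept_markers = filter_samples_and_markers(consensus)
    aln = concatenate_alignment(consensus, kept_samples, kept_markers)
    ids, d = pairwise_distances(aln)
    tree = nj_tree(ids, d)
    norm = normalized_tree_distances(tree)
    calls = infer_transmission(norm, subjects, related)
    related_set = set(related)
    sep_ok = True
    below = 0
    for a, b, v in norm.pairs():
        if a not in calls.retained_samples or b not in calls.retained_samples:
            continue
        pair = frozenset((subjects[a], subjects[b]))
        if pair in related_set:
            sep_ok &= v < calls.threshold
        else:
            below += v < calls.threshold
    return {
        "events_detected": len(calls.events),
        "n": n_pairs,
        "separation_ok": int(sep_ok),
        "unrelated_below_threshold_pct": 100.0 * below / calls.n_unrelated_pairs,
    }


def evaluate_presence_absence(
    seed: int = 1,
    deletion_fraction: float = 0.10,
    depth: float = 4.0,
    low_depth: float = 1.2,
) -> dict:
    """Gene-repertoire recovery for a strain with accessory deletions.

    Reads at uniform depth from the strain genome are mapped to the
    reference pangenes; family coverages are called present/absent with the
    default thresholds and compared with the deletion truth.  Also checks
    that the same strain sequenced at 1.2x is flagged not-detectable.
    """
    genomes, _ = sim.simulate_universe(
        n_species=1, genomes_per_species=3, n_core=60, n_accessory=140,
        seed=seed, gene_len_range=(600, 1200),
    )
    pan = build_pangenome(genomes[1000])
    core = {f for f, fam in pan.families.items() if len(fam.member_genomes) == 3}
    base = genomes[1000][0]
    strain, truth = sim.simulate_strain(
        base,
        sim.StrainSpec("s", n_snvs=0, deletion_fraction=deletion_fraction, seed=seed + 1),
        core_families=core,
    )
    gene_seqs = {g.gene_id: base.gene_sequence(g) for g in base.genes}
    gene_lengths = {g.gene_id: g.end - g.start for g in base.genes}
    fam_map = {g.gene_id: g.family90_id for g in base.genes}
    matcher = ExactMatcher(gene_seqs)
    contig = next(iter(strain.contigs.values()))

    def call_at(d):
        bases: dict[str, int] = {}
        for frag, _ in sim.tile_reads(contig, d, 150, seed=seed + 2, mode="uniform"):
            hits = matcher.map_read(frag)
            if hits:
                h = hits[0]
                bases[h.target_id] = bases.get(h.target_id, 0) + (h.end - h.start)
        depths = {g: b / gene_lengths[g] for g, b in bases.items()}
        vec = family_coverage(depths, gene_lengths, fam_map, "s", 1000)
        return call_presence_absence(vec)

    call = call_at(depth)
    present_truth = {g.family90_id for g in strain.genes}
    fams = set(fam_map.values())
    tp = sum(1 for f in fams if call.presence.get(f) and f in present_truth)
    tn = sum(1 for f in fams if not call.presence.get(f) and f not in present_truth)
    fp = sum(1 for f in fams if call.presence.get(f) and f not in present_truth)
    fn = sum(1 for f in fams if not call.presence.get(f) and f in present_truth)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    low = call_at(low_depth)
    return {
        "balanced_accuracy": (sens + spec) / 2.0 if call.detectable else 0.0,
        "n": len(fams),
        "detectable_at_target_depth": int(call.detectable),
        "low_coverage_flagged": int(not low.detectable),
    }


def evaluate_functional(
    seed: int = 1, n_species: int = 10, n_reads: int = 100_000
) -> dict:
    """Functional profiling recovery and filter behavior.

    Runs the nucleotide tier end-to-end on a simulated community against
    the complete pangene database, regroups to EC numbers, and compares
    with the depth-weighted gold standard.  Also verifies weight
    conservation exactly and the identity / within-1%-score filters on
    constructed hit lists.
    """
    genomes, _ = sim.simulate_universe(
        n_species=n_species, genomes_per_species=2, n_core=40, n_accessory=10,
        seed=seed, gene_len_range=(600, 1500),
    )
    pangenes: dict[str, str] = {}
    meta: dict[str, tuple[str, str]] = {}
    for taxid, gs in genomes.items():
        pan = build_pangenome(gs)
        for f, fam in pan.families.items():
            pid = f"{taxid}|{f}"
            pangenes[pid] = fam.representative_seq
            meta[pid] = (f, str(taxid))
    spec = sim.CommunitySpec(species=sorted(genomes), n_reads=n_reads, seed=seed + 1)
    reads, _, _ = sim.simulate_reads(spec, genomes)
    matcher = ExactMatcher(pangenes)
    hits = []
    for r in reads:
        for m in matcher.map_read(r.sequence):
            fam, species = meta[m.target_id]
            hits.append(
                NucleotideHit(r.read_id, m.target_id, fam, species, m.start, m.end, 100.0)
            )
    lengths = {p: len(s) for p, s in pangenes.items()}
    surviving = coverage_filter(hits, lengths)
    asg = nucleotide_assign(surviving, [r.read_id for r in reads])
    conservation_error = abs(asg.total_weight() + len(asg.unmapped) - len(reads))

    fam_lengths = {meta[p][0]: lengths[p] for p in pangenes}
    annotations = {}
    ec_pool = [f"{a}.{b}.{c}.{d}" for a in (1, 2) for b in (1, 2) for c in (1, 2, 3) for d in range(1, 4)]
    for i, fam in enumerate(sorted(fam_lengths)):
        annotations[fam] = AnnotationRecord(
            family50_id=fam + "_50",
            ec_numbers=(ec_pool[i % len(ec_pool)],),
            length_aa=fam_lengths[fam] // 3,
        )
    est_ec = regroup(family_abundance([asg], fam_lengths), annotations, "ec")

    abundances = spec.draw_abundances()
    genome_counts, genome_depths, genome_species = {}, {}, {}
    for taxid, gs in genomes.items():
        g0 = gs[0]
        counts: dict[str, int] = {}
        for g in g0.genes:
            counts[g.family90_id] = counts.get(g.family90_id, 0) + 1
        genome_counts[g0.genome_id] = counts
        genome_depths[g0.genome_id] = abundances[taxid]
        genome_species[g0.genome_id] = str(taxid)
    gold_ec = regroup(
        gold_standard_functional(genome_counts, genome_depths, genome_species, fam_lengths),
        annotations,
        "ec",
    )
    bc = _bray_curtis_similarity(est_ec.community_totals(), gold_ec.community_totals())

    # per-species EC precision for species at >= 1x depth
    total_bases = n_reads * spec.read_length
    weight_sum = sum(abundances[t] * genomes[t][0].length for t in abundances)
    precisions = []
    for taxid in genomes:
        # per-base depth: species bases / genome length
        depth = abundances[taxid] * genomes[taxid][0].length / weight_sum
        depth *= total_bases / genomes[taxid][0].length
        if depth < 1.0:
            continue
        est_fams = {
            f for (f, s) in est_ec.abundances if s == str(taxid) and est_ec.abundances[(f, s)] > 0
        }
        gold_fams = {f for (f, s) in gold_ec.abundances if s == str(taxid)}
        if est_fams:
            precisions.append(len(est_fams & gold_fams) / len(est_fams))
    species_precision = min(precisions) if precisions else 1.0

    # identity floor: 79 excluded, 80 retained
    t_hits = [
        TranslatedHit("r1", "U79", 79.0, 100.0, 0, 50),
        TranslatedHit("r1", "U80", 80.0, 90.0, 0, 50),
    ]
    t_asg = translated_assign(t_hits, ["r1"])
    identity_ok = t_asg.weights.get("r1", {}) == {("U80", "unclassified"): 1.0}
    # within-1%-of-best on a constructed score list
    s_hits = [
        TranslatedHit("r2", "S100", 90.0, 100.0, 0, 50),
        TranslatedHit("r2", "S995", 90.0, 99.5, 0, 50),
        TranslatedHit("r2", "S98", 90.0, 98.0, 0, 50),
    ]
    s_asg = translated_assign(s_hits, ["r2"])
    top_ok = s_asg.weights.get("r2", {}) == {
        ("S100", "unclassified"): 0.5,
        ("S995", "unclassified"): 0.5,
    }
    return {
        "weight_conservation_error": conservation_error,
        "ec_bray_curtis": bc,
        "species_ec_precision": species_precision,
        "identity_filter_ok": int(identity_ok),
        "top_score_filter_ok": int(top_ok),
        "n": n_reads,
    }


def evaluate_round_trips(seed: int = 1, n_cases: int = 10) -> dict:
    """Fuzzed read(write(x)) == x checks for every text format."""
    from .pangenome import PresenceAbsenceMatrix, read_matrix, write_matrix
    from .strainprofile import read_newick, write_newick
    from .taxprofile import (
        aggregate_taxonomy,
        read_profile,
        relative_abundance,
        write_profile,
    )
    from .markerdb import Taxonomy
    import pandas as pd

    rng = np.random.default_rng(seed)
    failures = 0
    total = 0
    for case in range(n_cases):
        # taxonomic profile (both dialects)
        tax = Taxonomy()
        tax.add_node(2, "Bacteria", "kingdom", 2)
        tax.add_node(10, "P", "phylum", 2)
        tax.add_node(11, "C", "class", 10)
        tax.add_node(12, "O", "order", 11)
        tax.add_node(13, "F", "family", 12)
        n_sp = int(rng.integers(1, 6))
        cov = {}
        for gi in range(n_sp):
            tax.add_node(20 + gi, f"G{gi}", "genus", 13)
            tax.add_node(100 + gi, f"G{gi}_s", "species", 20 + gi, 1e6)
            cov[100 + gi] = float(rng.uniform(0.1, 5))
        prof = relative_abundance(aggregate_taxonomy(cov, tax), tax)
        unknown = float(rng.uniform(0, 30))
        for r in prof.rows:
            r.relative_abundance *= (100 - unknown) / 100
        prof.unknown_fraction = unknown
        prof.total_reads = int(rng.integers(100, 10_000))
        prof.sample_id = f"case{case}"
        for fmt in ("metaphlan", "cami"):
            total += 1
            again = read_profile(write_profile(prof, fmt), fmt)
            same = len(again.rows) == len(prof.rows) and all(
                a.taxonomy_path == b.taxonomy_path
                and a.taxid_path == b.taxid_path
                and abs(a.relative_abundance - b.relative_abundance) < 1e-9
                for a, b in zip(prof.rows, again.rows)
            )
            same &= abs(again.unknown_fraction - prof.unknown_fraction) < 1e-9
            failures += not same

        # newick
        total += 1
        n = int(rng.integers(4, 8))
        pts = rng.random((n, 2)) * 4
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(ids, d)
        again_tree = read_newick(write_newick(tree))
        before = normalized_tree_distances(tree)
        after = normalized_tree_distances(again_tree)
        failures += not (
            before.sample_ids == after.sample_ids
            and np.allclose(before.distances, after.distances)
        )

        # presence/absence matrix
        total += 1
        df = pd.DataFrame(
            rng.integers(0, 2, size=(6, 4)).astype(bool),
            index=[f"F{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(4)],
        )
        pa = PresenceAbsenceMatrix(df)
        failures += not read_matrix(write_matrix(pa)).matrix.equals(pa.matrix)
    return {"failures": failures, "n": total}
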