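import math

import numpy as np
import pytest

from metaprof import simulate as sim
from metaprof.markerdb import (
    Gene,
    GenomeRecord,
    PanFamily,
    PanFamilyStats,
    Pangenome,
    assign_tier,
    build_pangenome,
    compute_family_stats,
    flag_low_quality_species,
    refine_marker_externality,
    score_marker,
    select_markers,
)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Candidatus_Foo_bar", True),
        ("candidate_division_TM7", True),
        ("Ruminococcus_bromii", False),
        ("Clostridium_sp_ABC", True),
        ("Clostridium_sp", True),
        ("Sulfolobus_spindle_virus", False),  # _sp must end the token
        ("marine_bacterium_X", True),
        ("uncultured_archaeon_Y", True),
        ("Buchnera_endosymbiont_of_aphid", True),
        ("Escherichia_coli", False),
        ("Prevotella_genomosp_P6", True),
        ("unidentified_phage", True),
        ("Candida_albicans", False),  # "Candida" lacks the "andidat" stem
        ("", False),
    ],
)
def test_low_quality_species_name_filter(name, expected):
    assert flag_low_quality_species(name) is expected


def _toy_genome(genome_id, taxid, fam_ids, gene_len=300, fam50=None):
    spacer = "T" * 20
    rng = np.random.default_rng(abs(hash(genome_id)) % 2**31)
    contig = []
    genes = []
    pos = 0
    for fam in fam_ids:
        contig.append(spacer)
        pos += len(spacer)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, gene_len)])
        contig.append(seq)
        genes.append(
            Gene(
                gene_id=f"{genome_id}|{fam}",
                contig_id=f"{genome_id}_c0",
                start=pos,
                end=pos + gene_len,
                strand="+",
                protein_length=gene_len // 3,
                family90_id=fam,
                family50_id=(fam50 or {}).get(fam, fam + "_50"),
            )
        )
        pos += gene_len
    return GenomeRecord(
        genome_id=genome_id,
        species_taxid=taxid,
        contigs={f"{genome_id}_c0": "".join(contig)},
        genes=genes,
    )


class TestBuildPangenome:
    def test_family_union(self):
        g1 = _toy_genome("g1", 7, ["a", "b", "c"])
        g2 = _toy_genome("g2", 7, ["b", "c", "d"])
        pan = build_pangenome([g1, g2])
        assert set(pan.families) == {"a", "b", "c", "d"}
        assert pan.families["b"].member_genomes == {"g1", "g2"}
        assert pan.families["a"].member_genomes == {"g1"}

    def test_member_counts(self):
        genomes = [_toy_genome(f"g{i}", 7, ["x", f"y{i}"]) for i in range(3)]
        pan = build_pangenome(genomes)
        assert len(pan.families["x"].member_genes) == 3

    def test_representative_is_deterministic(self):
        g1 = _toy_genome("g1", 7, ["a"])
        g2 = _toy_genome("g0", 7, ["a"])
        pan = build_pangenome([g1, g2])
        assert pan.families["a"].representative_genome_id == "g0"

    def test_errors(self):
        with pytest.raises(ValueError, match="no genomes"):
            build_pangenome([])
        with pytest.raises(ValueError, match="mixed"):
            build_pangenome([_toy_genome("g1", 7, ["a"]), _toy_genome("g2", 8, ["a"])])


class TestFamilyStats:
    def setup_method(self):
        # species 1: 10 genomes, family "f" in 8 of them
        self.sp1 = [
            _toy_genome(f"a{i}", 1, ["f", "g"] if i < 8 else ["g"]) for i in range(10)
        ]
        # species 2 (2 genomes, both carry f) and species 3 (1 genome with f),
        # species 3 flagged low-quality
        self.sp2 = [_toy_genome(f"b{i}", 2, ["f"]) for i in range(2)]
        self.sp3 = [_toy_genome("c0", 3, ["f"])]
        self.pangenomes = {
            1: build_pangenome(self.sp1),
            2: build_pangenome(self.sp2),
            3: build_pangenome(self.sp3),
        }
        self.flags = {1: False, 2: False, 3: True}

    def test_coreness_fraction(self):
        stats = compute_family_stats(self.pangenomes, self.flags)
        assert stats[(1, "f")].coreness == pytest.approx(0.8)
        assert stats[(1, "g")].coreness == pytest.approx(1.0)

    def test_uniqueness_and_low_quality_exclusion(self):
        stats = compute_family_stats(self.pangenomes, self.flags)
        st = stats[(1, "f")]
        assert st.uniqueness90 == 2
        assert st.uniqueness_sp90 == 1
        assert st.external_genomes90 == 3  # 2 genomes of sp2 + 1 of sp3

    def test_brute_force_agreement(self):
        """Statistics match an independent double loop over species x genomes."""
        genomes_by_species, _ = sim.simulate_universe(
            n_species=5, genomes_per_species=2, n_core=6, n_accessory=4,
            seed=33, shared_family_pairs=2, gene_len_range=(450, 600),
        )
        pangenomes = {t: build_pangenome(g) for t, g in genomes_by_species.items()}
        flags = {t: False for t in pangenomes}
        stats = compute_family_stats(pangenomes, flags)
        for taxid, genomes in genomes_by_species.items():
            fams = {g.family90_id for gr in genomes for g in gr.genes}
            for fam in fams:
                f50s = {
                    g.family50_id
                    for gr in genomes
                    for g in gr.genes
                    if g.family90_id == fam
                }
                n_member = sum(
                    1 for gr in genomes if any(g.family90_id == fam for g in gr.genes)
                )
                u90 = eg90 = u50 = eg50 = 0
                for other, ogs in genomes_by_species.items():
                    if other == taxid:
                        continue
                    carrying90 = [
                        gr for gr in ogs if any(g.family90_id == fam for g in gr.genes)
                    ]
                    carrying50 = [
                        gr for gr in ogs if any(g.family50_id in f50s for g in gr.genes)
                    ]
                    u90 += bool(carrying90)
                    eg90 += len(carrying90)
                    u50 += bool(carrying50)
                    eg50 += len(carrying50)
                st = stats[(taxid, fam)]
                assert st.coreness == pytest.approx(n_member / len(genomes))
                assert (st.uniqueness90, st.external_genomes90) == (u90, eg90)
                assert (st.uniqueness50, st.external_genomes50) == (u50, eg50)


def _stats(c, u90=0, u50=0, eg90=0, eg50=0):
    return PanFamilyStats(c, u90, u50, 0, 0, eg90, eg50)


class TestTiers:
    @pytest.mark.parametrize(
        "stats,n_genomes,expected",
        [
            (_stats(0.85, 1, 1, 5, 2), 10, "A"),
            (_stats(0.75, 5, 5, 14, 9), 10, "B"),
            (_stats(0.60, 9, 14, 24, 19), 10, "C"),
            (_stats(0.80, 0, 0, 0, 0), 10, "B"),   # 0.80 is not "higher than 80%"
            (_stats(0.85, 3, 0, 0, 0), 10, None),  # u90 too high for A, coreness too high for B
            (_stats(0.50, 0, 0, 0, 0), 10, None),  # coreness band is strict at 0.50
            (_stats(1.0, 0, 0, 0, 0), 1, "U"),
            (_stats(1.0, 1, 0, 0, 0), 1, None),    # tier U requires zero uniqueness
        ],
    )
    def test_threshold_boundaries(self, stats, n_genomes, expected):
        assert assign_tier(stats, n_genomes) == expected

    def test_tier_bands_mutually_exclusive(self):
        """No statistics vector satisfies two tiers at once (grid check)."""

        def tier_a(s):
            return (s.coreness > 0.80 and s.uniqueness90 <= 2 and s.uniqueness50 <= 2
                    and s.external_genomes90 <= 10 and s.external_genomes50 <= 5)

        def tier_b(s):
            return (0.70 < s.coreness <= 0.80 and s.uniqueness90 <= 5
                    and s.uniqueness50 <= 5 and s.external_genomes90 < 15
                    and s.external_genomes50 < 10)

        def tier_c(s):
            return (0.50 < s.coreness <= 0.70 and s.uniqueness90 < 10
                    and s.uniqueness50 < 15 and s.external_genomes90 < 25
                    and s.external_genomes50 < 20)

        for c100 in range(50, 101):
            for u in (0, 2, 3, 5, 6, 9, 10):
                for eg in (0, 5, 9, 10, 14, 19, 24):
                    s = _stats(c100 / 100.0, u, u, eg, eg)
                    assert tier_a(s) + tier_b(s) + tier_c(s) <= 1
                    got = assign_tier(s, 10)
                    expected = (
                        "A" if tier_a(s) else "B" if tier_b(s) else "C" if tier_c(s) else None
                    )
                    assert got == expected


class TestScore:
    def test_zero_uniqueness_value(self):
        # -log(1e-4) * 15 for each uniqueness term
        s = score_marker(_stats(1.0, 0, 0))
        assert s == pytest.approx((-math.log(1e-4) * 15) ** 2, rel=1e-9)
        assert s == pytest.approx(19086.8, rel=1e-4)

    def test_saturated_uniqueness_clamped_to_zero(self):
        assert score_marker(_stats(1.0, 10_000, 0)) == 0.0
        assert score_marker(_stats(1.0, 20_000, 20_000)) == 0.0

    def test_strictly_decreasing_in_uniqueness(self):
        grid = [0, 1, 2, 5, 10, 100, 1000, 9999]
        for lo, hi in zip(grid, grid[1:]):
            assert score_marker(_stats(0.9, hi, 0)) < score_marker(_stats(0.9, lo, 0))
            assert score_marker(_stats(0.9, 0, hi)) < score_marker(_stats(0.9, 0, lo))

    def test_weakly_increasing_in_coreness(self):
        vals = [score_marker(_stats(c / 100, 3, 3)) for c in range(0, 101, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            score_marker(_stats(0.5, -1, 0))


def _fake_pangenome(taxid, fam_stats, n_genomes=5, protein_len=300):
    """Pangenome + stats map from a mapping family -> PanFamilyStats."""
    families = {}
    stats_map = {}
    for fam, st in fam_stats.items():
        gene = Gene(fam, "c0", 0, protein_len * 3, "+", protein_len, fam, fam + "_50")
        families[fam] = PanFamily(fam, fam + "_50", [("g0", gene)], "g0", gene, "A" * protein_len * 3)
        stats_map[(taxid, fam)] = st
    pan = Pangenome(species_taxid=taxid, genome_ids={f"g{i}" for i in range(n_genomes)}, families=families)
    return pan, stats_map


class TestSelectMarkers:
    def test_cap_at_150_highest_scoring(self):
        fam_stats = {
            f"f{i:03d}": _stats(0.81 + 0.0009 * i, 0, 0) for i in range(200)
        }
        pan, stats_map = _fake_pangenome(9, fam_stats)
        markers = select_markers(pan, stats_map, {})
        assert len(markers) == 150
        assert all(m.tier == "A" for m in markers)
        # the 150 highest coreness values were kept
        kept = {m.marker_id.split("__")[1] for m in markers}
        assert kept == {f"f{i:03d}" for i in range(50, 200)}

    def test_tiers_accumulate_when_few_candidates(self):
        fam_stats = {f"a{i}": _stats(0.9, 0, 0) for i in range(30)}
        fam_stats.update({f"b{i}": _stats(0.75, 0, 0) for i in range(40)})
        pan, stats_map = _fake_pangenome(9, fam_stats)
        markers = select_markers(pan, stats_map, {})
        assert len(markers) == 70
        assert {m.tier for m in markers} == {"A", "B"}

    def test_species_dropped_below_minimum(self):
        fam_stats = {f"f{i}": _stats(0.9, 0, 0) for i in range(4)}
        pan, stats_map = _fake_pangenome(9, fam_stats)
        assert select_markers(pan, stats_map, {}) == []

    def test_protein_length_filter(self):
        fam_stats = {f"f{i}": _stats(0.9, 0, 0) for i in range(20)}
        pan, stats_map = _fake_pangenome(9, fam_stats, protein_len=100)  # below 150 aa
        assert select_markers(pan, stats_map, {}) == []

    def test_single_genome_species_gets_tier_u(self):
        fam_stats = {f"f{i}": _stats(1.0, 0, 0) for i in range(15)}
        pan, stats_map = _fake_pangenome(9, fam_stats, n_genomes=1)
        markers = select_markers(pan, stats_map, {})
        assert len(markers) == 15
        assert all(m.tier == "U" for m in markers)

    def test_quasi_marker_ext_species_recorded(self):
        fam_stats = {f"f{i}": _stats(0.9, 1, 1) for i in range(12)}
        pan, stats_map = _fake_pangenome(9, fam_stats)
        ext_map = {f"f{i}": {9, 77} for i in range(12)}
        markers = select_markers(pan, stats_map, ext_map)
        assert all(m.ext_species == {77} for m in markers)
        assert not any(m.is_unique for m in markers)


class TestRefineExternality:
    def _marker(self, seq, taxid=1):
        from metaprof.markerdb import MarkerRecord

        return MarkerRecord("m1", taxid, seq, "A", 1.0, set())

    def test_forward_chunk_found(self):
        rng = np.random.default_rng(0)
        marker_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        foreign = _toy_genome("z0", 99, ["q"])
        cid = next(iter(foreign.contigs))
        foreign.contigs[cid] += marker_seq[:150]
        out = refine_marker_externality(self._marker(marker_seq), [foreign])
        assert out.ext_species == {99}

    def test_reverse_complement_chunk_found(self):
        from metaprof.markerdb import reverse_complement

        rng = np.random.default_rng(1)
        marker_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        foreign = _toy_genome("z0", 99, ["q"])
        cid = next(iter(foreign.contigs))
        foreign.contigs[cid] += reverse_complement(marker_seq[150:300])
        out = refine_marker_externality(self._marker(marker_seq), [foreign])
        assert out.ext_species == {99}

    def test_no_shared_kmer_leaves_ext_unchanged(self):
        marker_seq = "AC" * 150
        foreign = _toy_genome("z0", 99, ["q"])
        out = refine_marker_externality(self._marker(marker_seq), [foreign])
        assert out.ext_species == set()

    def test_naive_scan_oracle_agreement(self):
        """Chunk search agrees with an all-substring scan on small genomes."""
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        for trial in range(5):
            marker_seq = "".join(bases[rng.integers(0, 4, 450)])
            genome_seq = "".join(bases[rng.integers(0, 4, 2000)])
            if trial % 2 == 0:  # plant one chunk half the time
                ins = int(rng.integers(0, len(genome_seq) - 150))
                chunk = int(rng.integers(0, 3)) * 150
                genome_seq = (
                    genome_seq[:ins] + marker_seq[chunk : chunk + 150] + genome_seq[ins:]
                )
            foreign = GenomeRecord("z", 99, {"c": genome_seq}, [])
            out = refine_marker_externality(self._marker(marker_seq), [foreign])
            from metaprof.markerdb import reverse_complement

            rc = reverse_complement(genome_seq)
            expected = any(
                marker_seq[i : i + 150] in genome_seq or marker_seq[i : i + 150] in rc
                for i in range(0, 301, 150)
            )
            assert (99 in out.ext_species) is expected

    def test_short_marker_rejected(self):
        with pytest.raises(ValueError):
            refine_marker_externality(self._marker("ACGT" * 10), [])

    def test_external_hit_list_interface(self):
        marker_seq = "ACGT" * 50
        genomes = [_toy_genome("z0", 99, ["q"]), _toy_genome("z1", 98, ["q"])]
        out = refine_marker_externality(self._marker(marker_seq), genomes, hits=["z1"])
        assert out.ext_species == {98}


class TestDatabaseInvariants:
    def test_marker_counts_and_tiers(self, small_db, small_universe):
        genomes_by_species, _ = small_universe
        pangenomes = {t: build_pangenome(g) for t, g in genomes_by_species.items()}
        flags = {t: False for t in pangenomes}
        stats = compute_family_stats(pangenomes, flags)
        assert len(small_db) > 0
        for taxid in small_db.species:
            markers = small_db.markers_for(taxid)
            assert 10 <= len(markers) <= 150
            for m in markers:
                fam = m.marker_id.split("__", 1)[1]
                assert assign_tier(stats[(taxid, fam)], pangenomes[taxid].n_genomes) == m.tier
                assert m.score == pytest.approx(score_marker(stats[(taxid, fam)]))
                assert 450 <= m.length <= 4500
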