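import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from metaprof import simulate as sim
from metaprof.strainprofile import (
    ConsensusMarker,
    ConsensusRejection,
    MarkerPileup,
    StrainDistanceMatrix,
    call_consensus,
    concatenate_alignment,
    filter_samples_and_markers,
    infer_transmission,
    kimura2p_distance,
    nj_tree,
    normalized_tree_distances,
    pairwise_distances,
    pileup_from_reads,
    read_newick,
    trim_consensus,
    write_newick,
)


def _pileup_one_column(counts, qual=35, marker_len=1, n_reads=None):
    pile = MarkerPileup.empty("m", marker_len)
    col = pile.base_counts[0]
    col.update(counts)
    pile.base_quals[0] = [qual] * sum(counts.values())
    pile.n_reads = n_reads if n_reads is not None else sum(counts.values())
    return pile


class TestConsensus:
    def test_dominant_base_called(self):
        pile = _pileup_one_column({"A": 9, "G": 1})
        out = call_consensus(pile, min_breadth=0.0)
        assert isinstance(out, ConsensusMarker)
        assert out.sequence == "A"

    def test_polymorphic_column_masked(self):
        pile = _pileup_one_column({"A": 7, "G": 3})
        out = call_consensus(pile, min_breadth=0.0)
        assert out.sequence == "N"

    def test_low_quality_column_masked(self):
        pile = _pileup_one_column({"A": 10}, qual=20)
        out = call_consensus(pile, min_breadth=0.0)
        assert out.sequence == "N"

    def test_breadth_rejection(self):
        # 100 nt marker, 75 positions covered -> breadth 0.75 < 0.8
        pile = MarkerPileup.empty("m", 100)
        pile.add_read("A" * 75, 0)
        pile.n_reads = 10
        out = call_consensus(pile)
        assert isinstance(out, ConsensusRejection)
        assert "breadth" in out.reason

    def test_read_count_rejection(self):
        pile = MarkerPileup.empty("m", 10)
        for _ in range(7):
            pile.add_read("ACGTACGTAC", 0)
        out = call_consensus(pile)
        assert isinstance(out, ConsensusRejection)
        assert "n_reads" in out.reason

    def test_uncovered_positions_are_n_and_reduce_breadth(self):
        pile = MarkerPileup.empty("m", 10)
        for _ in range(8):
            pile.add_read("ACGTACGT", 0)
        out = call_consensus(pile)
        assert out.sequence == "ACGTACGTNN"
        assert out.breadth == pytest.approx(0.8)

    def test_error_free_reads_recover_truth(self):
        """Consensus equals the source sequence at every covered position."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for trial in range(10):
            truth = "".join(bases[rng.integers(0, 4, 400)])
            reads = sim.tile_reads(truth, 10, 100, seed=trial)
            pile = pileup_from_reads("m", len(truth), reads)
            out = call_consensus(pile, sample_id="s")
            assert isinstance(out, ConsensusMarker)
            for got, want in zip(out.sequence, truth):
                assert got in ("N", want)
            assert "".join(c for c in out.sequence if c != "N")  # something called


class TestSampleMarkerFiltering:
    def _consensus(self, layout):
        """layout: sample -> list of marker ids present."""
        return {
            s: {m: ConsensusMarker(m, s, "ACGT", 1.0, 10) for m in ms}
            for s, ms in layout.items()
        }

    def test_sample_below_marker_floor_dropped(self):
        markers = [f"m{i}" for i in range(25)]
        layout = {"good1": markers, "good2": markers, "bad": markers[:19]}
        samples, kept = filter_samples_and_markers(self._consensus(layout))
        assert samples == ["good1", "good2"]

    def test_rare_marker_dropped(self):
        markers = [f"m{i:02d}" for i in range(25)]
        layout = {f"s{j}": list(markers) for j in range(10)}
        for j in range(3):  # m24 present in 7/10 samples = 70% < 80%
            layout[f"s{j}"] = markers[:-1]
        samples, kept = filter_samples_and_markers(self._consensus(layout))
        assert "m24" not in kept and len(kept) == 24

    def test_all_retained_when_thresholds_met(self):
        markers = [f"m{i}" for i in range(25)]
        layout = {f"s{j}": markers for j in range(3)}
        samples, kept = filter_samples_and_markers(self._consensus(layout))
        assert len(samples) == 3 and len(kept) == 25

    def test_fixed_point_satisfies_both_thresholds(self):
        rng = np.random.default_rng(11)
        markers = [f"m{i:02d}" for i in range(40)]
        layout = {
            f"s{j}": [m for m in markers if rng.random() < 0.8] for j in range(12)
        }
        samples, kept = filter_samples_and_markers(self._consensus(layout))
        for s in samples:
            assert sum(1 for m in layout[s] if m in kept) >= 20
        for m in kept:
            present = sum(1 for s in samples if m in layout[s])
            assert present >= 0.8 * len(samples)

    def test_all_samples_dropped_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            filter_samples_and_markers(self._consensus({"s": ["m1"]}))


class TestTrimAndConcatenate:
    def test_trim_boundaries(self):
        assert len(trim_consensus("A" * 300)) == 200
        assert len(trim_consensus("A" * 101)) == 1
        with pytest.warns(UserWarning):
            assert trim_consensus("A" * 100) is None

    def test_concatenation_layout(self):
        cons = {
            "s1": {
                "mA": ConsensusMarker("mA", "s1", "A" * 110, 1.0, 10),
                "mB": ConsensusMarker("mB", "s1", "C" * 120, 1.0, 10),
            },
            "s2": {
                "mA": ConsensusMarker("mA", "s2", "G" * 110, 1.0, 10),
            },
        }
        aln = concatenate_alignment(cons, ["s1", "s2"], ["mB", "mA"], trim=50)
        assert len(aln["s1"]) == 10 + 20  # trimmed mA (10) + trimmed mB (20)
        assert aln["s1"] == "A" * 10 + "C" * 20
        assert aln["s2"] == "G" * 10 + "N" * 20  # missing marker N-padded

    def test_length_mismatch_raises(self):
        cons = {
            "s1": {"mA": ConsensusMarker("mA", "s1", "A" * 110, 1.0, 10)},
            "s2": {"mA": ConsensusMarker("mA", "s2", "A" * 111, 1.0, 10)},
        }
        with pytest.raises(ValueError, match="length mismatch"):
            concatenate_alignment(cons, ["s1", "s2"], ["mA"])


class TestKimura:
    def test_identical_sequences(self):
        assert kimura2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_transitions_only_closed_form(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90  # 10 transitions, 0 transversions
        assert kimura2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_all_n_overlap_is_missing(self):
        assert math.isnan(kimura2p_distance("NNNN", "ACGT"))

    def test_sites_with_n_excluded(self):
        # distance computed over the 100 unambiguous sites only
        a = "N" * 50 + "A" * 100
        b = "C" * 50 + "G" * 10 + "A" * 90
        assert kimura2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fuzz_against_site_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), 50))
        # mutate a little so saturation never occurs
        b = list(a)
        for pos in rng.choice(50, size=5, replace=False):
            b[pos] = bases[(bases.index(b[pos]) + int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        purines = {"A", "G"}
        p = sum(
            1 for x, y in zip(a, b) if x != y and (x in purines) == (y in purines)
        ) / 50
        q = sum(
            1 for x, y in zip(a, b) if x != y and (x in purines) != (y in purines)
        ) / 50
        expect = -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
        assert kimura2p_distance(a, b) == pytest.approx(expect)


def test_pairwise_matrix_matches_scalar_kimura():
    rng = np.random.default_rng(17)
    bases = "ACGT"
    root = rng.choice(list(bases), 200)
    aln = {}
    for i in range(5):
        seq = root.copy()
        for pos in rng.choice(200, size=12, replace=False):
            seq[pos] = bases[(bases.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
        for pos in rng.choice(200, size=10, replace=False):
            seq[pos] = "N"
        aln[f"s{i}"] = "".join(seq)
    ids, d = pairwise_distances(aln)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert d[i, j] == pytest.approx(kimura2p_distance(aln[a], aln[b]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(["a", "b", "c"], d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(1), "b": pytest.approx(1), "c": pytest.approx(3)}

    def test_additive_matrix_recovered(self):
        # distances from a known 5-taxon tree ((a:1,b:2):1,(c:3,d:1):2,e:4)
        ids = ["a", "b", "c", "d", "e"]
        d = np.array(
            [
                [0, 3, 7, 5, 6],
                [3, 0, 8, 6, 7],
                [7, 8, 0, 4, 9],
                [5, 6, 4, 0, 7],
                [6, 7, 9, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(ids, d)
        dm = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert dm[a, b] == pytest.approx(d[i, j])

    def test_matches_skbio_oracle_distances(self):
        rng = np.random.default_rng(3)
        n = 6
        coords = rng.random((n, 3)) * 5
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(ids, d).tip_tip_distances(endpoints=ids)
        theirs = skbio_nj(DistanceMatrix(d, ids)).tip_tip_distances(endpoints=ids)
        assert np.allclose(np.asarray(ours.data), np.asarray(theirs.data), atol=1e-8)

    def test_zero_distance_cherry(self):
        d = np.array([[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float)
        tree = nj_tree(["a", "b", "c", "d"], d)
        dm = tree.tip_tip_distances()
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_missing_distance_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], d)


class TestNormalizedDistances:
    def test_three_leaf_tree(self):
        tree = read_newick("(a:1,b:1,c:3);")
        dist = normalized_tree_distances(tree)
        assert dist.distance("a", "b") == pytest.approx(2 / 5)
        assert dist.distance("a", "a") == 0.0

    def test_scale_invariance(self):
        t1 = read_newick("((a:1,b:2):1,(c:3,d:1):2);")
        t2 = read_newick("((a:10,b:20):10,(c:30,d:10):20);")
        d1 = normalized_tree_distances(t1)
        d2 = normalized_tree_distances(t2)
        assert np.allclose(d1.distances, d2.distances)

    def test_newick_round_trip(self):
        tree = read_newick("((a:1,b:2):1,(c:3,d:1):2);")
        again = read_newick(write_newick(tree))
        assert np.allclose(
            normalized_tree_distances(tree).distances,
            normalized_tree_distances(again).distances,
        )


class TestTransmission:
    def _matrix(self, pair_values, related_value=0.5):
        """15 samples; one related pair (s00,s01) at related_value, the other
        104 pair distances set from pair_values."""
        ids = [f"s{i:02d}" for i in range(15)]
        d = np.zeros((15, 15))
        vals = iter(pair_values)
        for i in range(15):
            for j in range(i + 1, 15):
                v = related_value if (i, j) == (0, 1) else next(vals)
                d[i, j] = d[j, i] = v
        return StrainDistanceMatrix(ids, d, "tree-normalized")

    def test_threshold_is_first_percentile_of_unrelated(self):
        unrelated = list(range(1, 105))
        dist = self._matrix(unrelated)
        subjects = {s: f"subj_{s}" for s in dist.sample_ids}
        related = [("subj_s00", "subj_s01")]
        calls = infer_transmission(dist, subjects, related)
        assert calls.threshold == pytest.approx(
            np.percentile(unrelated, 1.0, method="lower")
        )
        assert [(e[0], e[1]) for e in calls.events] == [("s00", "s01")]
        # the linear-interpolation variant matches the numpy oracle too
        linear = infer_transmission(
            dist, subjects, related, percentile_method="linear"
        )
        assert linear.threshold == pytest.approx(np.percentile(unrelated, 1.0))

    def test_related_pair_above_threshold_not_reported(self):
        dist = self._matrix(list(range(1, 105)), related_value=50.0)
        subjects = {s: f"subj_{s}" for s in dist.sample_ids}
        calls = infer_transmission(dist, subjects, [("subj_s00", "subj_s01")])
        assert calls.events == []

    def test_one_sample_per_subject_earliest(self):
        ids = ["a1", "a2", "b1"]
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        dist = StrainDistanceMatrix(ids, d)
        subjects = {"a1": "A", "a2": "A", "b1": "B"}
        with pytest.warns(UserWarning):
            calls = infer_transmission(
                dist, subjects, [], timestamps={"a1": 5.0, "a2": 1.0}
            )
        assert calls.retained_samples == ["a2", "b1"]
        assert calls.n_unrelated_pairs == 1

    def test_fdr_bound_by_construction(self):
        """At most 1% of unrelated pairs fall below the inferred threshold."""
        rng = np.random.default_rng(9)
        n = 40
        ids = [f"u{i:02d}" for i in range(n)]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = rng.uniform(0.1, 1.0)
        dist = StrainDistanceMatrix(ids, d)
        calls = infer_transmission(dist, {s: s for s in ids}, [])
        below = sum(1 for _, _, v in dist.pairs() if v < calls.threshold)
        assert below <= 0.01 * calls.n_unrelated_pairs


class TestStrainSeparation:
    def test_within_subject_below_threshold_between_above(self):
        """Private strains separate; longitudinal resamples look identical."""
        genomes, _ = sim.simulate_universe(
            n_species=1, genomes_per_species=1, n_core=22, n_accessory=3,
            seed=21, gene_len_range=(450, 750),
        )
        base = genomes[1000][0]
        samples, subjects, related, _ = sim.simulate_strain_cohort(
            base, n_private_subjects=6, n_transmission_pairs=2,
            n_snvs=25, samples_per_subject=2, seed=22,
        )
        consensus = {}
        rng = np.random.default_rng(23)
        for sid, genome in samples.items():
            per = {}
            for g in genome.genes:
                seq = genome.gene_sequence(g)
                reads = sim.tile_reads(seq, 12, 120, seed=int(rng.integers(2**31)))
                pile = pileup_from_reads(g.family90_id, len(seq), reads)
                out = call_consensus(pile, sample_id=sid)
                if isinstance(out, ConsensusMarker):
                    per[g.family90_id] = out
            consensus[sid] = per
        kept_samples, kept_markers = filter_samples_and_markers(consensus)
        aln = concatenate_alignment(consensus, kept_samples, kept_markers)
        ids, d = pairwise_distances(aln)
        tree = nj_tree(ids, d)
        norm = normalized_tree_distances(tree)
        subj = subjects
        for a, b, v in norm.pairs():
            if subj[a] == subj[b] or frozenset((subj[a], subj[b])) in set(related):
                assert v < 0.01
            else:
                assert v > 0.01
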