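import itertools

import numpy as np
import pytest

from tmic7 import seqkit as sk
from tmic7.synthetic_data import (FamilySpec, make_family_sequences,
                                  make_gene_model)
from tmic7.topology import TMSegment, TopologyModel


def _tm_model(n_tm, length=120):
    segs, pos, side = [], 0, "inside"
    segs.append(TMSegment(0, 10, side))
    pos = 10
    for i in range(n_tm):
        segs.append(TMSegment(pos, pos + 20, "membrane"))
        pos += 20
        side = "outside" if side == "inside" else "inside"
        segs.append(TMSegment(pos, pos + 5, side))
        pos += 5
    return TopologyModel(segs)


@pytest.fixture()
def curation_fixture():
    """10 records: 2 partial, 1 ambiguous, 2 identical (1 redundant), 1
    with three TMs, 4 clean -> 5 kept."""
    rng = np.random.default_rng(0)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seqs = ["".join(aas[i] for i in rng.integers(0, 20, 185)) for _ in range(8)]
    recs = [
        sk.SeqRecord("p1", "partial", seqs[0]),
        sk.SeqRecord("p2", "hypothetical, partial", seqs[1]),
        sk.SeqRecord("amb", "", seqs[2][:90] + "X" + seqs[2][91:]),
        sk.SeqRecord("dupA", "", seqs[3]),
        sk.SeqRecord("dupB", "copy", seqs[3]),
        sk.SeqRecord("threeTM", "", seqs[4]),
        sk.SeqRecord("ok1", "", seqs[5]),
        sk.SeqRecord("ok2", "", seqs[6]),
        sk.SeqRecord("ok3", "", seqs[7]),
        sk.SeqRecord("ok4", "", seqs[5][::-1]),
    ]
    topo = {r.id: _tm_model(7) for r in recs}
    topo["threeTM"] = _tm_model(3)
    return recs, topo


class TestCurate:
    def test_fixture_counts_exact(self, curation_fixture):
        recs, topo = curation_fixture
        kept, report = sk.curate(recs, topo)
        assert len(kept) == 5
        assert report["partial"] == 2
        assert report["ambiguous"] == 1
        assert report["redundant"] == 1
        assert report["low_tm"] == 1
        assert {r.id for r in kept} == {"dupA", "ok1", "ok2", "ok3", "ok4"}

    def test_counts_sum_to_removed(self, curation_fixture):
        recs, topo = curation_fixture
        kept, report = sk.curate(recs, topo)
        removed = report["partial"] + report["low_quality"] + \
            report["ambiguous"] + report["redundant"] + report["low_tm"]
        assert removed == len(recs) - len(kept)

    def test_idempotent(self, curation_fixture):
        recs, topo = curation_fixture
        kept, _ = sk.curate(recs, topo)
        kept2, report2 = sk.curate(kept, topo)
        assert [r.id for r in kept2] == [r.id for r in kept]
        assert sum(v for k, v in report2.items() if k != "unassessed") == 0

    def test_missing_topology_kept_and_counted(self):
        recs = [sk.SeqRecord("a", "", "ACDEFGHIKLMNPQRSTVWY" * 3)]
        kept, report = sk.curate(recs, {})
        assert len(kept) == 1
        assert report["unassessed"] == 1


class TestClustering:
    def test_identical_pair_one_representative(self):
        r = [sk.SeqRecord("a", "", "MKTAYIAKQRQISFVKSHFSRQ"),
             sk.SeqRecord("b", "", "MKTAYIAKQRQISFVKSHFSRQ")]
        reps = sk.cluster_representatives(r, 0.9)
        assert [x.id for x in reps] == ["a"]

    def test_dissimilar_pair_both_kept(self):
        r = [sk.SeqRecord("a", "", "MKTAYIAKQRQISFVKSHFSRQ"),
             sk.SeqRecord("b", "", "GGGPLLWDDNNCCEEHHPPGGG")]
        assert len(sk.cluster_representatives(r, 0.9)) == 2

    def test_planted_families_longest_representative(self):
        recs, labels = make_family_sequences(FamilySpec(seed=11))
        reps = sk.cluster_representatives(recs, 0.9)
        assert len(reps) == 3
        by_family = {}
        for r in recs:
            by_family.setdefault(labels[r.id], []).append(r)
        for rep in reps:
            fam = by_family[labels[rep.id]]
            assert len(rep.sequence) == max(len(m.sequence) for m in fam)

    def test_threshold_outside_range_warns(self):
        r = [sk.SeqRecord("a", "", "MKTAYIAKQRQISFVKSHFSRQ")]
        with pytest.warns(UserWarning):
            sk.cluster_representatives(r, 0.5)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sk.cluster_representatives([], 0.9)


class TestNetwork:
    def test_duplicate_pair_strong_edge(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ" * 3
        net = sk.all_vs_all([sk.SeqRecord("a", "", seq),
                             sk.SeqRecord("b", "", seq)])
        assert len(net.edges) == 1
        assert net.edges[0][2] < 1e-50

    def test_no_self_edges_and_symmetric_storage(self):
        recs, _ = make_family_sequences(FamilySpec(seed=1, n_families=2,
                                                   members_per_family=3))
        net = sk.all_vs_all(recs)
        seen = set()
        for a, b, _ in net.edges:
            assert a != b
            assert (a, b) not in seen and (b, a) not in seen
            seen.add((a, b))

    def test_weak_edge_tagged_in_export(self, tmp_path):
        net = sk.SimilarityNetwork(["a", "b", "c"],
                                   [("a", "b", 1e-30), ("b", "c", 5.0)])
        p = tmp_path / "net.tsv"
        net.to_tsv(p)
        lines = p.read_text().splitlines()
        assert "weak" not in lines[0]
        assert lines[1].endswith("weak")

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            sk.SimilarityNetwork(["a"], [("a", "a", 1e-5)])


class TestGraphSplit:
    def test_two_tight_pairs_quartet(self):
        """Two strongly-linked pairs weakly interconnected must split as
        ((a,b),(c,d)) — checked against cut weights of all 3 quartets."""
        edges = [("a", "b", 1e-20), ("c", "d", 1e-20),
                 ("a", "c", 1e-1), ("b", "d", 1e-1)]
        net = sk.SimilarityNetwork(["a", "b", "c", "d"], edges)
        # exhaustive: cut {ab|cd} severs weight 2, {ac|bd} severs 40+..., so
        # the Fiedler split must find the lightest cut
        tree = sk.graph_split(net)
        clades = {n.leaves for n in tree.internal_nodes()}
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"c", "d"}) in clades

    def test_leaf_set_preserved_star(self):
        edges = [("hub", x, 1e-10) for x in "bcde"]
        net = sk.SimilarityNetwork(["hub", "b", "c", "d", "e"], edges)
        tree = sk.graph_split(net)
        assert tree.leaves == frozenset(["hub", "b", "c", "d", "e"])

    def test_planted_blocks_recovered_as_clades(self):
        rng = np.random.default_rng(42)
        nodes = [f"n{i}" for i in range(12)]
        blocks = {n: i // 4 for i, n in enumerate(nodes)}
        edges = []
        for x, y in itertools.combinations(nodes, 2):
            if blocks[x] == blocks[y]:
                edges.append((x, y, 10.0 ** (-rng.uniform(15, 25))))
            elif rng.random() < 0.3:
                edges.append((x, y, 10.0 ** (-rng.uniform(0.2, 1.0))))
        net = sk.SimilarityNetwork(nodes, edges)
        tree = sk.graph_split(net)
        clades = {n.leaves for n in tree.internal_nodes()}
        for b in range(3):
            assert frozenset(n for n in nodes if blocks[n] == b) in clades

    def test_disconnected_components_handled(self):
        net = sk.SimilarityNetwork(["a", "b", "c", "d"],
                                   [("a", "b", 1e-9), ("c", "d", 1e-9)])
        tree = sk.graph_split(net)
        assert tree.leaves == frozenset("abcd")


class TestSupports:
    def _blocks_net(self, seed=42):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(12)]
        blocks = {n: i // 4 for i, n in enumerate(nodes)}
        edges = []
        for x, y in itertools.combinations(nodes, 2):
            if blocks[x] == blocks[y]:
                edges.append((x, y, 10.0 ** (-rng.uniform(15, 25))))
            elif rng.random() < 0.4:
                edges.append((x, y, 10.0 ** (-rng.uniform(0.2, 1.0))))
        return sk.SimilarityNetwork(nodes, edges), blocks

    def test_zero_noise_gives_all_100(self):
        net, _ = self._blocks_net()
        tree = sk.edge_perturbation_support(net, replicates=10, seed=0, sigma=0.0)
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_block_branches_high_support(self):
        net, blocks = self._blocks_net()
        tree = sk.edge_perturbation_support(net, replicates=100, seed=0)
        nodes = list(tree.internal_nodes())
        for b in range(3):
            block = frozenset(n for n in blocks if blocks[n] == b)
            match = [n for n in nodes if n.leaves == block]
            assert match and match[0].support >= 95.0

    def test_supports_in_range_and_deterministic(self):
        net, _ = self._blocks_net(7)
        t1 = sk.edge_perturbation_support(net, replicates=25, seed=3)
        t2 = sk.edge_perturbation_support(net, replicates=25, seed=3)
        s1 = [n.support for n in t1.internal_nodes() if n.support is not None]
        s2 = [n.support for n in t2.internal_nodes() if n.support is not None]
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)


class TestMotif:
    def test_canonical_motif_truth_table(self):
        pat = sk.MotifPattern.parse("TYhhhhhQF")
        cases = {
            "TYLLIVAQF": True,      # all hydrophobic core
            "TYLLIVAQY": False,     # F position violated
            "TALLIVAQF": False,     # Y position violated
            "TYGGGGGQF": False,     # glycines are not hydrophobic
        }
        for seq, expect in cases.items():
            m = sk.match_motif({"s": seq}, (0, len(seq)), pat)[0]
            assert m.full_match is expect, seq

    def test_variant_motif(self):
        pat = sk.MotifPattern.parse("T(H/N)(S/A)hhhhQ(Y/F/W)")
        assert sk.match_motif({"s": "TNALLIVQW"}, (0, 9), pat)[0].full_match
        assert sk.match_motif({"s": "THSFFFFQY"}, (0, 9), pat)[0].full_match
        assert not sk.match_motif({"s": "TQALLIVQW"}, (0, 9), pat)[0].full_match

    def test_all_glycine_no_match(self):
        pat = sk.MotifPattern.parse("TYhhhhhQF")
        m = sk.match_motif({"s": "G" * 30}, (0, 30), pat)[0]
        assert not m.full_match
        assert m.conformity < 0.3

    def test_gapped_alignment_region(self):
        pat = sk.MotifPattern.parse("TYhhhhhQF")
        aln = {"s": "--TY-LLIVA--QF--"}
        m = sk.match_motif(aln, (0, 16), pat)[0]
        assert m.full_match

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            sk.match_motif({}, (0, 5), sk.MotifPattern.parse("TY"))


class TestIntron:
    def test_phase0_before_residue_100(self):
        gm = [(0, 300), (300, 900)]
        aln = {"g": "A" * 300}
        mark = sk.map_intron_to_alignment(gm, aln, "g")
        assert (mark.phase, mark.residue_index, mark.alignment_column) == (0, 100, 100)

    def test_phase1(self):
        gm = [(0, 301), (301, 900)]
        mark = sk.map_intron_to_alignment(gm, {"g": "A" * 300}, "g")
        assert mark.phase == 1

    def test_homologous_introns_share_column(self):
        # gene g1: 100 residues, intron after residue 40 (phase 0)
        # gene g2: 95 residues, same intron position in the alignment
        aln = {
            "g1": "A" * 40 + "C" * 60,
            "g2": "A" * 35 + "-----" + "C" * 60,
        }
        m1 = sk.map_intron_to_alignment([(0, 120), (120, 300)], aln, "g1")
        m2 = sk.map_intron_to_alignment([(0, 105), (105, 285)], aln, "g2")
        # g2 residue 35 sits at column 40 via its 5-column gap, matching g1
        assert m1.alignment_column == 40
        assert m2.alignment_column == m1.alignment_column
        # and the planted generator round-trips
        recs, _ = make_family_sequences(FamilySpec(seed=0, n_families=1,
                                                   members_per_family=1))
        gm = make_gene_model(recs[0], 100, 0)
        mark = sk.map_intron_to_alignment(gm, {recs[0].id: recs[0].sequence},
                                          recs[0].id)
        assert (mark.residue_index, mark.phase) == (100, 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            sk.map_intron_to_alignment([(0, 299), (299, 899)], {"g": "A" * 300}, "g")
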