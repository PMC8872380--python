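"""TE trees and evidence: donor-consensus curation at relaxed
thresholds, neighbor-joining correctness (cross-checked against an
independent implementation), and the three-part HTT evidence score."""

import dendropy
import numpy as np
import pytest

from httdetect._seqs import random_seq
from httdetect.aligncore import local_align_oracle
from httdetect.calibrate import DivergenceCalibration
from httdetect.curation import ConsensusFamily
from httdetect.httscreen import PanelGenome, PresenceEntry, PresenceRow
from httdetect.simgenome import PlantedFamilySpec, SimulationConfig, mutate_sequence, simulate_panel
from httdetect.ttree import (
    TETree,
    build_nj_tree,
    curate_donor_consensuses,
    nj_tree_from_msa,
    score_evidence,
)


def random_additive_tree(n, rng):
    """A random topology with positive branch lengths and its exact
    patristic distance matrix."""
    labels = [f"t{i}" for i in range(n)]
    frags = labels[:]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), 2, replace=False))
        a = frags.pop(j)
        b = frags.pop(i)
        la, lb = rng.uniform(0.05, 1.0, 2)
        frags.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    tree = dendropy.Tree.get(data=frags[0] + ";", schema="newick")
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, d, tree


def patristic_matrix(newick, labels, namespace=None):
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=namespace)
    t.is_rooted = False
    pdm = t.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return d, t


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = build_nj_tree(d, ["a", "b", "c"])
        assert t.newick == "('a':0.1,'b':0.2,'c':0.4);"

    def test_four_taxon_additive_exact(self):
        # hand-drawn tree ((a:1,b:2):1,(c:3,d:4));
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        t = build_nj_tree(d, ["a", "b", "c", "d"])
        got, _ = patristic_matrix(t.newick, ["a", "b", "c", "d"])
        assert np.allclose(got, d)

    def test_equal_distances_resolve_by_label_order(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = build_nj_tree(d, ["a", "b", "c", "d"])
        t2 = build_nj_tree(d, ["a", "b", "c", "d"])
        assert t1.newick == t2.newick
        assert t1.newick.index("'a'") < t1.newick.index("'c'")

    def test_negative_lengths_clamped(self):
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.1], [0.5, 0.1, 0]])
        t = build_nj_tree(d, ["a", "b", "c"])
        assert ":-" not in t.newick

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_additive_recovery_matches_independent_nj(self):
        """Random additive matrices: exact topology + lengths, agreeing
        with scikit-bio's independent NJ implementation."""
        import io

        import skbio

        rng = np.random.default_rng(55)
        for _ in range(15):
            n = int(rng.integers(5, 9))
            labels, d, true_tree = random_additive_tree(n, rng)
            ours = build_nj_tree(d, labels)
            got, est = patristic_matrix(
                ours.newick, labels, namespace=true_tree.taxon_namespace
            )
            assert np.allclose(got, d, atol=1e-8)
            assert (
                dendropy.calculate.treecompare.symmetric_difference(true_tree, est) == 0
            )
            ref = skbio.tree.nj(
                skbio.DistanceMatrix(d, ids=labels)
            )
            ref_dp = dendropy.Tree.get(
                data=str(ref), schema="newick",
                taxon_namespace=true_tree.taxon_namespace,
            )
            ref_dp.is_rooted = False
            ref_dp.collapse_basal_bifurcation()
            assert (
                dendropy.calculate.treecompare.symmetric_difference(est, ref_dp) == 0
            )


class TestDonorConsensuses:
    def test_recovers_donor_master(self):
        fam = PlantedFamilySpec("h", "htt", copy_number=20, divergence=0.03,
                                master_length=700,
                                htt_recipients=frozenset({"A"}), htt_donor="B")
        cfg = SimulationConfig(seed=81, species_tree="(A:0.02,B:0.02)r;",
                               genome_length=200_000, te_families=[fam])
        genomes, truth = simulate_panel(cfg)
        consensus = ConsensusFamily("h", truth.masters["h"])
        panel = [PanelGenome("A", genomes["A"], "focal"),
                 PanelGenome("B", genomes["B"], "distant")]
        out = curate_donor_consensuses(consensus, panel)
        assert set(out) == {"A", "B"}
        h = local_align_oracle(out["B"][0], truth.masters["h"])
        assert h.percent_identity >= 98.0

    def test_low_copy_genome_yields_none(self):
        rng = np.random.default_rng(82)
        master = random_seq(600, 0.45, rng)
        fragment = mutate_sequence(master[:250], 0.25, seed=1)
        bg = random_seq(50_000, 0.45, rng)
        genome = {"chr1": bg[:25_000] + fragment + bg[25_000:]}
        panel = [PanelGenome("X", genome, "distant")]
        out = curate_donor_consensuses(ConsensusFamily("m", master), panel)
        assert out == {}

    def test_two_subfamilies_split(self):
        """Two planted subfamilies ~12% apart in one genome produce two
        consensuses."""
        rng = np.random.default_rng(83)
        master = random_seq(700, 0.45, rng)
        sub_a = master
        sub_b = mutate_sequence(master, 0.13, seed=2)
        parts = []
        for i in range(8):
            parts.append(random_seq(4_000, 0.45, rng))
            parts.append(mutate_sequence(sub_a, 0.015, seed=10 + i))
        for i in range(8):
            parts.append(random_seq(4_000, 0.45, rng))
            parts.append(mutate_sequence(sub_b, 0.015, seed=30 + i))
        parts.append(random_seq(4_000, 0.45, rng))
        genome = {"chr1": "".join(parts)}
        panel = [PanelGenome("X", genome, "distant")]
        out = curate_donor_consensuses(ConsensusFamily("m", master), panel,
                                       max_copies=16)
        assert len(out["X"]) == 2


CALIB = DivergenceCalibration(100, 60, 93.0, 90.0, 98.0, 95.0, 96.0, 80.0)
PANEL = [
    PanelGenome("F1", "x", "focal", "serpentes"),
    PanelGenome("R1", "x", "relative", "serpentes"),
    PanelGenome("D1", "x", "distant", "fish"),
]


def _row(**idents):
    row = PresenceRow("fam")
    for sp, v in idents.items():
        row.entries[sp] = PresenceEntry(v, 500 if v else 0, v >= 80)
    return row


class TestEvidence:
    def _tree(self, newick, labels):
        return TETree(newick, labels)

    def test_htt_pattern_all_true(self):
        row = _row(F1=98, R1=0, D1=96)
        tree = self._tree(
            "('F1::fam':0.01,'D1::fam':0.01,'R1_out::other':0.4);",
            ["F1::fam", "D1::fam", "R1_out::other"],
        )
        ev = score_evidence(ConsensusFamily("fam", "ACGT" * 50), row, tree, PANEL, CALIB)
        assert ev.patchy and ev.excess_similarity
        assert ev.incongruent
        assert ev.nearest_neighbor_species == "D1"

    def test_relative_presence_breaks_patchiness(self):
        row = _row(F1=98, R1=85, D1=96)
        ev = score_evidence(ConsensusFamily("fam", "ACGT" * 50), row, None, PANEL, CALIB)
        assert not ev.patchy

    def test_relative_sister_breaks_incongruence(self):
        row = _row(F1=98, R1=0, D1=96)
        tree = self._tree(
            "('F1::fam':0.01,'R1::fam':0.01,'D1::fam':0.4);",
            ["F1::fam", "R1::fam", "D1::fam"],
        )
        ev = score_evidence(ConsensusFamily("fam", "ACGT" * 50), row, tree, PANEL, CALIB)
        assert not ev.incongruent

    def test_low_neighbor_identity_breaks_excess(self):
        row = _row(F1=98, R1=0, D1=78)
        ev = score_evidence(ConsensusFamily("fam", "ACGT" * 50), row, None, PANEL, CALIB)
        assert not ev.excess_similarity


class TestNJFromMSA:
    def test_tree_over_msa_rows(self):
        from httdetect.aligncore import progressive_msa

        rng = np.random.default_rng(84)
        master = random_seq(400, 0.45, rng)
        seqs = [mutate_sequence(master, d, seed=i) for i, d in enumerate([0.01, 0.02, 0.2, 0.22])]
        msa = progressive_msa(seqs, ids=["a", "b", "c", "d"], method="fast")
        tree = nj_tree_from_msa(msa)
        d, _ = patristic_matrix(tree.newick, ["a", "b", "c", "d"])
        # close pair stays closer than the diverged pair
        assert d[0, 1] < d[0, 2]
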