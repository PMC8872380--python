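"""Curation chain: purge rules, copy collection, flank handling,
consensus calling, TSD detection and structural classification."""

import numpy as np
import pytest

from httdetect._seqs import random_seq, revcomp
from httdetect.aligncore import MSA, local_align_oracle
from httdetect.curation import (
    ConsensusFamily,
    ExtendedCopy,
    MotifTable,
    SeedFamily,
    build_consensus,
    classify_family,
    collect_top_copies,
    curate_family,
    detect_tsd_and_trim,
    extend_flanks,
    purge_redundant,
    trim_nonhomologous_flanks,
)
from httdetect.simgenome import (
    PlantedFamilySpec,
    SimulationConfig,
    mutate_sequence,
    simulate_panel,
)


def planted_genome(seed, n_copies=30, divergence=0.05, tsd=8, master_length=800,
                   genome_length=150_000):
    fam = PlantedFamilySpec("f1", "lineage_recent", copy_number={"A": n_copies},
                            divergence=divergence, tsd_length=tsd,
                            master_length=master_length)
    cfg = SimulationConfig(seed=seed, species_tree="(A:0.0):0.0;",
                           genome_length=genome_length, te_families=[fam])
    genomes, truth = simulate_panel(cfg)
    return genomes["A"], truth


class TestPurge:
    def _family(self, fid, seq):
        return SeedFamily(fid, seq)

    def test_contained_family_removed(self):
        rng = np.random.default_rng(0)
        a = random_seq(1000, 0.45, rng)
        # B: 400 bp block of A at ~97% identity + 100 bp unique = 0.80 coverage
        block = mutate_sequence(a[200:600], 0.03, seed=1)
        b = block + random_seq(100, 0.45, rng)
        kept = purge_redundant([self._family("A", a), self._family("B", b)])
        assert [f.family_id for f in kept] == ["A"]

    def test_below_coverage_retained(self):
        rng = np.random.default_rng(1)
        a = random_seq(1000, 0.45, rng)
        # 350 of 500 bp aligning = 0.70 < 0.75 -> retained
        b = mutate_sequence(a[200:550], 0.03, seed=2) + random_seq(150, 0.45, rng)
        kept = purge_redundant([self._family("A", a), self._family("B", b)])
        assert sorted(f.family_id for f in kept) == ["A", "B"]

    def test_unrelated_families_retained(self):
        rng = np.random.default_rng(2)
        fams = [self._family("A", random_seq(600, 0.45, rng)),
                self._family("B", random_seq(400, 0.45, rng))]
        kept = purge_redundant(fams)
        assert sorted(f.family_id for f in kept) == ["A", "B"]

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        a = random_seq(1000, 0.45, rng)
        b = mutate_sequence(a[:800], 0.02, seed=3)
        c = random_seq(500, 0.45, rng)
        fams = [self._family(x, s) for x, s in [("A", a), ("B", b), ("C", c)]]
        ref = sorted(f.family_id for f in purge_redundant(fams))
        for perm in ([2, 0, 1], [1, 2, 0]):
            got = sorted(f.family_id for f in purge_redundant([fams[i] for i in perm]))
            assert got == ref

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            purge_redundant([])


class TestCollectTopCopies:
    def test_truncates_to_n(self):
        genome, truth = planted_genome(seed=21, n_copies=50, genome_length=200_000)
        seed_fam = SeedFamily("f1", truth.masters["f1"])
        hits = collect_top_copies(seed_fam, genome, n=30)
        assert len(hits) == 30

    def test_returns_all_when_few(self):
        genome, truth = planted_genome(seed=22, n_copies=7)
        hits = collect_top_copies(SeedFamily("f1", truth.masters["f1"]), genome, n=30)
        assert len(hits) == 7

    def test_single_copy_dropped_with_warning(self, caplog):
        genome, truth = planted_genome(seed=23, n_copies=1)
        with caplog.at_level("WARNING", logger="httdetect.curation"):
            hits = collect_top_copies(SeedFamily("f1", truth.masters["f1"]), genome)
        assert hits == []
        assert "no consensus possible" in caplog.text

    def test_full_length_ranks_above_truncated(self):
        rng = np.random.default_rng(5)
        master = random_seq(800, 0.45, rng)
        pieces = []
        for i in range(3):
            pieces.append(mutate_sequence(master, 0.02, seed=10 + i))  # full
        for i in range(3):
            pieces.append(mutate_sequence(master[:400], 0.02, seed=20 + i))  # 50%
        bg = random_seq(120_000, 0.45, rng)
        parts = [bg[:10_000]]
        for p in pieces:
            parts.append(p)
            parts.append(bg[len("".join(parts)) : len("".join(parts)) + 10_000])
        genome = {"chr1": "".join(parts)}
        hits = collect_top_copies(SeedFamily("m", master), genome, n=6)
        lens = [h.query_len for h in hits]
        assert all(l > 700 for l in lens[:3])
        assert all(l < 500 for l in lens[3:])


class TestExtendFlanks:
    def _hit(self, contig, start, end, strand="+"):
        from httdetect.aligncore import RepeatHit

        return RepeatHit("q", contig, (0, end - start), (start, end), strand, 100, 99.0)

    def test_extension_arithmetic(self):
        genome = {"c": random_seq(30_000, 0.5, np.random.default_rng(0))}
        out = extend_flanks([self._hit("c", 10_000, 11_000)], genome, flank=4000)
        assert out[0].seq == genome["c"][6_000:15_000]
        assert (out[0].elem_start, out[0].elem_end) == (4000, 5000)

    def test_truncated_at_contig_start(self):
        genome = {"c": random_seq(20_000, 0.5, np.random.default_rng(1))}
        out = extend_flanks([self._hit("c", 500, 1_500)], genome, flank=4000)
        assert out[0].seq == genome["c"][0:5_500]
        assert out[0].elem_start == 500

    def test_minus_strand_reverse_complemented(self):
        genome = {"c": random_seq(20_000, 0.5, np.random.default_rng(2))}
        out = extend_flanks([self._hit("c", 8_000, 9_000, "-")], genome, flank=1000)
        assert out[0].seq == revcomp(genome["c"][7_000:10_000])
        assert (out[0].elem_start, out[0].elem_end) == (1000, 2000)


class TestTrimFlanks:
    def test_unique_flanks_trimmed_to_boundary(self):
        genome, truth = planted_genome(seed=31, n_copies=12, tsd=8)
        seed_fam = SeedFamily("f1", truth.masters["f1"])
        hits = collect_top_copies(seed_fam, genome, n=12)
        copies = extend_flanks(hits, genome, flank=2000)
        trimmed = trim_nonhomologous_flanks(copies, min_support=2, pad=25)
        for c in trimmed:
            # residual flank: boundary uncertainty (<=20 bp) plus pad
            assert c.elem_start <= 25 + 20
            assert len(c.seq) - c.elem_end <= 25 + 20
            assert c.elem_end - c.elem_start >= 700

    def test_segmental_duplication_support_threshold(self):
        """A 1 kb flank shared by exactly two copies survives at
        min_support=1 but is removed at min_support=2."""
        rng = np.random.default_rng(6)
        master = random_seq(600, 0.45, rng)
        shared = random_seq(1000, 0.45, rng)
        copies = []
        for i in range(6):
            elem = mutate_sequence(master, 0.02, seed=40 + i)
            left = shared if i < 2 else random_seq(1000, 0.45, rng)
            right = random_seq(1000, 0.45, rng)
            copies.append(ExtendedCopy(left + elem + right, 1000, 1000 + len(elem)))
        keep1 = trim_nonhomologous_flanks(copies, min_support=1, pad=10)
        assert keep1[0].elem_start >= 900  # shared flank retained
        keep2 = trim_nonhomologous_flanks(copies, min_support=2, pad=10)
        assert keep2[0].elem_start <= 10 + 20  # shared flank removed

    def test_zero_length_flanks_unchanged(self):
        rng = np.random.default_rng(7)
        master = random_seq(500, 0.45, rng)
        copies = [
            ExtendedCopy(mutate_sequence(master, 0.02, seed=50 + i), 0, 500)
            for i in range(4)
        ]
        out = trim_nonhomologous_flanks(copies, pad=25)
        for c, o in zip(copies, out):
            assert o.seq == c.seq


class TestConsensus:
    def test_plurality_column(self):
        msa = MSA([("a", "A"), ("b", "A"), ("c", "A"), ("d", "G")])
        assert build_consensus(msa) == "A"

    def test_tie_becomes_iupac(self):
        msa = MSA([("a", "A"), ("b", "A"), ("c", "G"), ("d", "G")])
        assert build_consensus(msa) == "R"

    def test_gappy_column_dropped(self):
        msa = MSA([("a", "AC"), ("b", "A-"), ("c", "A-"), ("d", "A-")])
        assert build_consensus(msa) == "A"

    @pytest.mark.parametrize("divergence,n_copies", [(0.01, 10), (0.05, 30), (0.10, 20)])
    def test_master_recovery_grid(self, divergence, n_copies):
        genome, truth = planted_genome(
            seed=int(100 * divergence + n_copies), n_copies=n_copies,
            divergence=divergence, master_length=600, genome_length=120_000,
        )
        master = truth.masters["f1"]
        seed_fam = SeedFamily("f1", mutate_sequence(master, 0.02, seed=99))
        cf = curate_family(seed_fam, genome, flank=1000, msa_method="fast")
        h = local_align_oracle(cf.consensus, master)
        assert h.percent_identity >= 99.0
        assert (h.target_span[1] - h.target_span[0]) >= 0.98 * len(master)


class TestTSD:
    def test_planted_tsd_recovered(self):
        genome, truth = planted_genome(seed=41, tsd=8, divergence=0.03)
        cf = curate_family(SeedFamily("f1", truth.masters["f1"]), genome,
                           flank=1000, msa_method="fast")
        assert cf.tsd_length == 8

    def test_no_tsd_gives_none(self):
        genome, truth = planted_genome(seed=42, tsd=0, divergence=0.03)
        cf = curate_family(SeedFamily("f1", truth.masters["f1"]), genome,
                           flank=1000, msa_method="fast")
        assert cf.tsd_length is None

    def test_random_flanks_no_signal(self):
        """Rows with randomized flanks and no planted TSD never reach the
        support threshold."""
        rng = np.random.default_rng(8)
        master = random_seq(400, 0.45, rng)
        copies = []
        rows = []
        for i in range(10):
            elem = mutate_sequence(master, 0.02, seed=60 + i)
            seq = random_seq(30, 0.5, rng) + elem + random_seq(30, 0.5, rng)
            copies.append(ExtendedCopy(seq, 30, 30 + len(elem)))
            rows.append((f"r{i}", seq + "-" * (500 - len(seq))))
        width = max(len(c.seq) for c in copies)
        rows = [(rid, s[:width].ljust(width, "-")) for rid, s in rows]
        _, tsd = detect_tsd_and_trim(MSA(rows), copies)
        assert tsd is None


class TestClassify:
    def test_motif_rule_first(self):
        motifs = MotifTable([("tnp1", "DNA/hAT", "ATGGCGTTTAAACGTGCA")])
        cons = random_seq(200, 0.5, np.random.default_rng(9)) + "ATGGCGTTTAAACGTGCA" \
            + random_seq(200, 0.5, np.random.default_rng(10))
        cf = classify_family(ConsensusFamily("x", cons, tsd_length=8), motifs)
        assert cf.classification == "DNA/hAT"

    def test_tir_tsd_rule(self):
        rng = np.random.default_rng(11)
        core = random_seq(300, 0.5, rng)
        tir = random_seq(15, 0.5, rng)
        cons = tir + core + revcomp(tir)
        cf = classify_family(ConsensusFamily("x", cons, tsd_length=2), motifs=None)
        assert cf.tir
        assert cf.classification == "DNA/Tc1-Mariner"

    def test_tir_unknown_tsd_length(self):
        rng = np.random.default_rng(12)
        core = random_seq(300, 0.5, rng)
        tir = random_seq(15, 0.5, rng)
        cf = classify_family(
            ConsensusFamily("x", tir + core + revcomp(tir), tsd_length=6), motifs=None
        )
        assert cf.classification == "DNA/Unknown-TIR"

    def test_polya_tsd_line_rule(self):
        rng = np.random.default_rng(13)
        cons = random_seq(400, 0.3, rng) + "AAAAAA"
        cf = classify_family(ConsensusFamily("x", cons, tsd_length=10), motifs=None)
        assert cf.classification == "LINE/Unknown"

    def test_random_sequence_unknown(self):
        # GC-rich sequence: no poly-A tail, no TIRs, no motifs
        cons = random_seq(400, 0.8, np.random.default_rng(14))
        cf = classify_family(ConsensusFamily("x", cons), motifs=None)
        assert cf.classification == "Unknown"


class TestIdempotence:
    def test_recurated_consensus_stable(self):
        genome, truth = planted_genome(seed=51, n_copies=20, divergence=0.04)
        first = curate_family(SeedFamily("f1", truth.masters["f1"]), genome,
                              flank=1000, msa_method="fast")
        import re

        # seed libraries are ACGTN: collapse any consensus ambiguity codes
        reseed = re.sub(r"[^ACGT]", "N", first.consensus)
        second = curate_family(SeedFamily("f1", reseed), genome,
                               flank=1000, msa_method="fast")
        h = local_align_oracle(second.consensus, first.consensus)
        assert h.percent_identity >= 99.0
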