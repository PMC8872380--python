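"""Synthetic multi-species genomes with planted TE families and truth.

The generator emulates the statistical structure that the downstream
inference chain relies on, without pretending to be a full genome
simulator:

* neutral background sequence that diverges along a species tree at the
  branch lengths given (expected substitutions/site, Jukes–Cantor);
* TE family bursts: copies derived independently from a master sequence
  at a controllable per-copy divergence, inserted with exact target-site
  duplications (TSDs) and unique random flanks;
* three planting modes — ``ancestral`` (inserted in the root genome and
  inherited by every species, so copies are orthologous at identical
  coordinates), ``lineage_recent`` (inserted in named extant species
  only), and ``htt`` (inserted at high identity in a set of recipient
  species and one distant donor, absent from all intermediates).

Background and inherited sequence evolve by substitutions only, so
coordinates of ancestral insertions are identical across genomes; the
optional indel process applies only when copies are generated from a
master. Every planted copy is recorded in a machine-readable truth
object for downstream scoring.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._seqs import indices_to_seq, random_seq, revcomp, seq_to_indices, write_fasta
from .trees import load_tree, mrca_branch

__all__ = [
    "PlantedFamilySpec",
    "SimulationConfig",
    "InsertionRecord",
    "SyntheticTruth",
    "mutate_sequence",
    "expected_mismatch_fraction",
    "simulate_panel",
    "simulate_coverage",
    "random_master",
    "write_panel",
]


def expected_mismatch_fraction(divergence: float) -> float:
    """Observable per-site mismatch probability after ``divergence``
    expected substitutions/site under the Jukes–Cantor model."""
    return 0.75 * (1.0 - np.exp(-4.0 * divergence / 3.0))


@dataclass
class PlantedFamilySpec:
    """One TE family to plant in the panel.

    ``copy_number`` is an integer (ancestral: copies in the root genome;
    htt: copies per carrier genome) or a {species: n} map for
    ``lineage_recent`` families. ``master_sequence=None`` generates a
    random master (with terminal inverted repeats / TSD capability as
    requested).
    """

    family_id: str
    mode: str  # ancestral | lineage_recent | htt
    copy_number: int | dict = 20
    divergence: float = 0.05
    master_sequence: str | None = None
    master_length: int = 800
    tsd_length: int = 0
    tir_length: int = 0
    classification_hint: str = "Unknown"
    htt_recipients: frozenset = frozenset()
    htt_donor: str | None = None
    # ancestral mode only: plant in the MRCA of these species (default:
    # the tree root) and optionally add a recent burst in extant species
    # (continued expansion), at its own lower divergence
    ancestor_of: frozenset = frozenset()
    recent_copy_number: dict = field(default_factory=dict)
    recent_divergence: float = 0.02

    def __post_init__(self):
        if self.mode not in {"ancestral", "lineage_recent", "htt"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        if self.master_sequence is not None and len(self.master_sequence) < 80:
            raise ValueError("master length must be >= 80 bp")
        if self.master_sequence is None and self.master_length < 80:
            raise ValueError("master length must be >= 80 bp")
        if self.mode == "htt":
            rec = set(self.htt_recipients)
            if not rec or not self.htt_donor:
                raise ValueError("htt mode requires recipients and a donor")
            if self.htt_donor in rec:
                raise ValueError("htt donor and recipients must be disjoint")
            self.htt_recipients = frozenset(rec)
        if self.mode == "lineage_recent" and not isinstance(self.copy_number, dict):
            raise ValueError("lineage_recent requires a {species: n} copy_number map")


@dataclass
class SimulationConfig:
    seed: int
    species_tree: str  # Newick, branch lengths in expected substitutions/site
    genome_length: int
    te_families: list[PlantedFamilySpec]
    gc_content: float = 0.42
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        tree = load_tree(self.species_tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")


@dataclass
class InsertionRecord:
    species: str
    family_id: str
    contig: str
    start: int  # 0-based half-open, element only (TSDs excluded)
    end: int
    strand: str
    true_divergence: float  # expected substitutions/site vs the family master
    tsd_sequence: str


@dataclass
class SyntheticTruth:
    insertions: list[InsertionRecord] = field(default_factory=list)
    htt_labels: dict = field(default_factory=dict)
    masters: dict = field(default_factory=dict)  # family_id -> master sequence

    def records_for(self, species: str, family_id: str | None = None):
        return [
            r
            for r in self.insertions
            if r.species == species and (family_id is None or r.family_id == family_id)
        ]


def random_master(
    length: int, gc: float, rng: np.random.Generator, tir_length: int = 0, tail_a: int = 0
) -> str:
    """A random TE master; optional reverse-complementary termini (TIRs)
    and a 3' poly-A tail."""
    seq = random_seq(length, gc, rng)
    if tail_a:
        seq = seq[: length - tail_a] + "A" * tail_a
    if tir_length:
        left = seq[:tir_length]
        seq = left + seq[tir_length : length - tir_length] + revcomp(left)
    return seq


def mutate_sequence(
    seq: str, divergence: float, indel_rate: float = 0.0, seed: int | np.random.Generator = 0
) -> str:
    """An independently mutated copy of ``seq``.

    Substitutions follow a Jukes–Cantor process with ``divergence``
    expected substitutions/site (each hit site flips to one of the three
    other bases uniformly; the observable mismatch fraction is
    :func:`expected_mismatch_fraction`). With ``indel_rate`` > 0, that
    fraction of mutation events become 1–5 bp indels instead.
    """
    if not (0.0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = seq_to_indices(seq)
    n = len(idx)
    p = expected_mismatch_fraction(divergence)
    hit = rng.random(n) < p
    offsets = rng.integers(1, 4, size=n)
    out = idx.copy()
    out[hit] = (idx[hit] + offsets[hit]) % 4
    if indel_rate > 0.0:
        event_sites = np.flatnonzero(hit)
        is_indel = rng.random(event_sites.size) < indel_rate
        indel_sites = event_sites[is_indel]
        if indel_sites.size:
            # revert substitution at indel sites; apply indels right-to-left
            out[indel_sites] = idx[indel_sites]
            pieces = out
            s = indices_to_seq(pieces)
            chars = list(s)
            for pos in sorted(indel_sites.tolist(), reverse=True):
                size = int(rng.integers(1, 6))
                if rng.random() < 0.5:  # deletion
                    del chars[pos : pos + size]
                else:  # insertion of random bases
                    ins = indices_to_seq(rng.integers(0, 4, size=size).astype(np.uint8))
                    chars[pos:pos] = list(ins)
            return "".join(chars)
    return indices_to_seq(out)


def _evolve_background(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    """Substitution-only neutral evolution along one branch."""
    if branch_length <= 0:
        return seq
    idx = seq_to_indices(seq)
    p = expected_mismatch_fraction(branch_length)
    hit = rng.random(len(idx)) < p
    offsets = rng.integers(1, 4, size=len(idx))
    idx[hit] = (idx[hit] + offsets[hit]) % 4
    return indices_to_seq(idx)


def _insert_fragments(seq: str, inserts: list[tuple[int, str]], existing: list) -> list[tuple[int, int]]:
    """Plan coordinates after inserting fragments at background positions.

    ``inserts`` are (position, fragment) in current coordinates; returns
    final (start, end) of each fragment and shifts ``existing`` records
    (mutated in place via their .start/.end attributes).
    """
    order = sorted(range(len(inserts)), key=lambda k: inserts[k][0])
    spans = [None] * len(inserts)
    shift = 0
    for k in order:
        pos, frag = inserts[k]
        spans[k] = (pos + shift, pos + shift + len(frag))
        shift += len(frag)
    # shift pre-existing records
    positions = sorted(p for p, _ in inserts)
    lengths = {p: len(f) for p, f in inserts}
    for rec in existing:
        add = sum(lengths[p] for p in positions if p <= rec.start)
        rec.start += add
        rec.end += add
    return spans


def _splice(seq: str, inserts: list[tuple[int, str]]) -> str:
    parts = []
    last = 0
    for pos, frag in sorted(inserts, key=lambda x: x[0]):
        parts.append(seq[last:pos])
        parts.append(frag)
        last = pos
    parts.append(seq[last:])
    return "".join(parts)


def _choose_positions(
    n: int, genome_len: int, occupied: list[tuple[int, int]], rng: np.random.Generator, margin: int = 60
) -> list[int]:
    """Uniform insertion points avoiding existing planted intervals."""
    chosen: list[int] = []
    occ = list(occupied)
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ValueError("could not place insertions: genome too crowded")
        pos = int(rng.integers(margin, genome_len - margin))
        if all(pos < s - margin or pos > e + margin for s, e in occ):
            chosen.append(pos)
            occ.append((pos, pos))
    return chosen


def _make_copy(
    master: str, spec: PlantedFamilySpec, divergence: float,
    rng: np.random.Generator, indel_rate: float
) -> tuple[str, str, str, int]:
    """One planted fragment: TSD + (possibly reverse-complemented) mutated
    copy + TSD. Returns (fragment, strand, tsd_seq, offset of element)."""
    copy = mutate_sequence(master, divergence, indel_rate, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        copy = revcomp(copy)
    tsd = random_seq(spec.tsd_length, 0.5, rng) if spec.tsd_length else ""
    return tsd + copy + tsd, strand, tsd, len(tsd)


def simulate_panel(config: SimulationConfig) -> tuple[dict[str, dict[str, str]], SyntheticTruth]:
    """Simulate one genome per species-tree leaf plus complete truth.

    Returns ({species: {contig: sequence}}, SyntheticTruth). Deterministic
    for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = load_tree(config.species_tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    truth = SyntheticTruth()

    # master sequences
    masters: dict[str, str] = {}
    for spec in config.te_families:
        if spec.master_sequence is not None:
            m = spec.master_sequence.upper()
            if spec.tir_length:
                m = m[: len(m) - spec.tir_length] + revcomp(m[: spec.tir_length])
        else:
            tail = 8 if spec.classification_hint.startswith("LINE") else 0
            m = random_master(spec.master_length, config.gc_content, rng, spec.tir_length, tail)
        masters[spec.family_id] = m
    truth.masters = masters

    # --- plan plantings: which tree node receives which (spec, n, divergence) ---
    leaf_node = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    root = tree.seed_node
    plantings: dict[int, list[tuple[PlantedFamilySpec, int, float]]] = {}

    def _plant_at(node, spec, n, div):
        if n > 0:
            plantings.setdefault(id(node), []).append((spec, int(n), float(div)))

    total_planted = 0
    for spec in config.te_families:
        m_len = len(masters[spec.family_id]) + 2 * spec.tsd_length
        if spec.mode == "ancestral":
            node = (
                tree.mrca(taxon_labels=sorted(spec.ancestor_of))
                if spec.ancestor_of and len(spec.ancestor_of) > 1
                else (leaf_node[next(iter(spec.ancestor_of))] if spec.ancestor_of else root)
            )
            _plant_at(node, spec, int(spec.copy_number), spec.divergence)
            total_planted += int(spec.copy_number) * m_len
            for sp, n in sorted(spec.recent_copy_number.items()):
                _plant_at(leaf_node[sp], spec, n, spec.recent_divergence)
                total_planted += n * m_len
        elif spec.mode == "lineage_recent":
            for sp, n in sorted(spec.copy_number.items()):
                _plant_at(leaf_node[sp], spec, n, spec.divergence)
                total_planted += n * m_len
        else:  # htt
            for sp in sorted(spec.htt_recipients | {spec.htt_donor}):
                _plant_at(leaf_node[sp], spec, int(spec.copy_number), spec.divergence)
                total_planted += int(spec.copy_number) * m_len
    if total_planted > 0.8 * config.genome_length * len(leaves):
        raise ValueError("total planted length exceeds genome capacity")

    # --- evolve along the tree, planting at the assigned nodes ---
    node_seq: dict[int, str] = {}
    node_records: dict[int, list[InsertionRecord]] = {}
    genomes: dict[str, dict[str, str]] = {}
    leaf_records: dict[str, list[InsertionRecord]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = random_seq(config.genome_length, config.gc_content, rng)
            records: list[InsertionRecord] = []
        else:
            bl = node.edge.length or 0.0
            child_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            seq = _evolve_background(node_seq[id(node.parent_node)], bl, child_rng)
            records = [
                InsertionRecord(
                    r.species, r.family_id, r.contig, r.start, r.end, r.strand,
                    r.true_divergence + bl, r.tsd_sequence,
                )
                for r in node_records[id(node.parent_node)]
            ]
        for spec, n, div in plantings.get(id(node), []):
            occupied = [(r.start, r.end) for r in records]
            positions = _choose_positions(n, len(seq), occupied, rng)
            inserts = []
            meta = []
            for pos in positions:
                frag, strand, tsd, off = _make_copy(
                    masters[spec.family_id], spec, div, rng, config.indel_rate
                )
                inserts.append((pos, frag))
                meta.append((strand, tsd, off, len(frag)))
            spans = _insert_fragments(seq, inserts, records)
            seq = _splice(seq, inserts)
            for k, (strand, tsd, off, fraglen) in enumerate(meta):
                s0, _ = spans[k]
                records.append(
                    InsertionRecord(
                        "", spec.family_id, "chr1", s0 + off, s0 + fraglen - off,
                        strand, div, tsd,
                    )
                )
        node_seq[id(node)] = seq
        node_records[id(node)] = records
        if node.is_leaf():
            sp = node.taxon.label
            genomes[sp] = {"chr1": seq}
            leaf_records[sp] = [
                InsertionRecord(sp, r.family_id, r.contig, r.start, r.end, r.strand,
                                r.true_divergence, r.tsd_sequence)
                for r in records
            ]

    for sp in leaves:
        truth.insertions.extend(sorted(leaf_records[sp], key=lambda r: (r.contig, r.start)))

    for spec in config.te_families:
        if spec.mode == "htt":
            branch = mrca_branch(tree, set(spec.htt_recipients))
            truth.htt_labels[spec.family_id] = {
                "mode": "htt",
                "recipients": sorted(spec.htt_recipients),
                "donor": spec.htt_donor,
                "expected_branch": branch,
            }
        elif spec.mode == "ancestral":
            if spec.ancestor_of and len(spec.ancestor_of) > 1:
                node = tree.mrca(taxon_labels=sorted(spec.ancestor_of))
                carriers = sorted(lf.taxon.label for lf in node.leaf_iter())
            elif spec.ancestor_of:
                carriers = sorted(spec.ancestor_of)
            else:
                carriers = sorted(leaves)
            truth.htt_labels[spec.family_id] = {
                "mode": "ancestral",
                "recipients": carriers,
                "donor": None,
                "expected_branch": mrca_branch(tree, set(carriers)),
            }
        else:
            carriers = sorted(s for s, n in spec.copy_number.items() if n > 0)
            truth.htt_labels[spec.family_id] = {
                "mode": "lineage_recent",
                "recipients": carriers,
                "donor": None,
                "expected_branch": mrca_branch(tree, set(carriers)),
            }
    return genomes, truth


def simulate_coverage(length: int, expressed: bool, seed: int = 0) -> np.ndarray:
    """A per-base read-coverage vector emulating the RNA-seq expression proxy.

    Expressed families get full-length coverage (≥ 1 everywhere); silent
    families get a single short island of spurious coverage at most,
    leaving most of the sequence at zero.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    if expressed:
        return 1 + rng.poisson(9.0, size=length)
    cov = np.zeros(length, dtype=np.int64)
    island_len = max(1, length // 8)
    start = int(rng.integers(0, max(1, length // 10)))
    cov[start : start + island_len] = 1 + rng.poisson(3.0, size=min(island_len, length - start))
    return cov


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_panel(genomes: dict, truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write one FASTA per species, truth as BED6+3 and htt labels as JSON.

    Returns {species: fasta_path}.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sp, contigs in genomes.items():
        p = os.path.join(outdir, f"{sp}.fa")
        write_fasta(contigs, p)
        paths[sp] = p
    with open(os.path.join(outdir, "truth.bed"), "w") as fh:
        for r in truth.insertions:
            fh.write(
                f"{r.species}:{r.contig}\t{r.start}\t{r.end}\t{r.family_id}\t0\t{r.strand}"
                f"\t{r.family_id}\t{r.true_divergence:.4f}\t{r.tsd_sequence}\n"
            )
    with open(os.path.join(outdir, "htt_labels.json"), "w") as fh:
        json.dump(truth.htt_labels, fh, indent=2, sort_keys=True)
    write_fasta(truth.masters, os.path.join(outdir, "masters.fa"))
    return paths
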