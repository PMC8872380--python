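"""End-to-end orchestration: seeds → curation → annotation → calibration
→ recent-expansion detection → panel screen → HTT calls → evidence.

Also provides :func:`benchmark_config`, the package's standard synthetic
study: a seven-genome panel (four focal snake-like species, one close
relative, two distant aquatic donors) with six ancestral and three
horizontally transferred planted families, used by the test-suite's
end-to-end checks and the acceptance script.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from ._seqs import read_fasta, write_fasta
from .aligncore import ScoringScheme
from .annotate import AnnotationRecord, annotate_genome, records_to_bed, subfamily_recent_mass
from .calibrate import (
    DivergenceCalibration,
    calibrate_thresholds,
    find_orthologues,
    sample_te_loci,
)
from .config import PipelineConfig
from .curation import ConsensusFamily, MotifTable, SeedFamily, curate_library
from .httscreen import (
    HTTCall,
    PanelGenome,
    PresenceRow,
    cluster_representatives,
    expression_filter,
    find_recent_subfamilies,
    presence_matrix_frame,
    screen_panel,
)
from .simgenome import (
    PlantedFamilySpec,
    SimulationConfig,
    mutate_sequence,
    simulate_coverage,
    simulate_panel,
)
from .trees import load_tree
from .ttree import HTTEvidence, TETree, curate_donor_consensuses, nj_tree_from_msa, score_evidence
from .aligncore import progressive_msa

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "benchmark_config", "write_result"]


@dataclass
class PipelineResult:
    library: list[ConsensusFamily]
    annotations: dict[str, list[AnnotationRecord]]
    calibration: DivergenceCalibration
    recent_families: list[str]
    representatives: list[ConsensusFamily]
    expressed: dict[str, bool]
    presence_rows: list[PresenceRow]
    calls: list[HTTCall]
    evidence: dict[str, HTTEvidence] = field(default_factory=dict)
    te_trees: dict[str, TETree] = field(default_factory=dict)

    @property
    def htt_calls(self) -> list[HTTCall]:
        return [c for c in self.calls if c.status == "htt"]


def _load_genome(path_or_dict) -> dict[str, str]:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    return read_fasta(path_or_dict)


def run_pipeline(
    seeds: dict[str, list[SeedFamily]],
    panel: list[PanelGenome],
    species_tree: str,
    motifs: MotifTable | None = None,
    coverage: dict[str, np.ndarray] | None = None,
    config: PipelineConfig | None = None,
    scoring: ScoringScheme | None = None,
    calibration_pair: tuple[str, str] | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full inference chain on a genome panel.

    ``seeds`` maps a source species (must be focal) to its raw seed
    families; each species' library is curated against its own genome.
    ``calibration_pair`` names the (focal, relative) genomes used for
    orthologue calibration; defaults to the first focal and first
    relative of the panel. ``coverage`` optionally supplies per-family
    read-coverage vectors for the expression proxy; families without a
    vector pass the filter unexamined.
    """
    cfg = config or PipelineConfig()
    s = scoring or ScoringScheme()
    tree = load_tree(species_tree)
    genomes = {g.species: _load_genome(g.path) for g in panel}
    panel_mem = [PanelGenome(g.species, genomes[g.species], g.role, g.group) for g in panel]
    focal = [g.species for g in panel if g.role == "focal"]
    relatives = [g.species for g in panel if g.role == "relative"]
    if calibration_pair is None:
        calibration_pair = (focal[0], relatives[0])

    # 1. curation, per source genome
    library: list[ConsensusFamily] = []
    for sp, fams in sorted(seeds.items()):
        curated = curate_library(
            fams,
            genomes[sp],
            motifs,
            n_copies=cfg.curation_copies,
            flank=cfg.curation_flank,
            min_support=cfg.flank_min_support,
            max_tsd=cfg.max_tsd,
            s=s,
            msa_method=cfg.msa_method,
        )
        library.extend(curated)
    if not library:
        raise ValueError("curation produced no consensus families")

    # 2. annotation of every focal genome
    annotations = {
        sp: annotate_genome(
            genomes[sp], library,
            min_identity=cfg.annotate_min_identity, min_len=cfg.annotate_min_len,
            s=s, overlap_tolerance=cfg.overlap_tolerance,
        )
        for sp in focal
    }

    # 3. orthologue calibration on the designated genome pair
    sp_a, sp_b = calibration_pair
    loci = sample_te_loci(
        annotations[sp_a], genomes[sp_a],
        n=cfg.calib_sample_n, min_len=cfg.calib_min_te_len,
        flank=cfg.calib_flank, seed=seed,
    )
    pairs = find_orthologues(
        loci, genomes[sp_b],
        min_te_bp=cfg.calib_min_te_bp, min_flank_bp=cfg.calib_min_flank_bp, s=s,
    )
    calibration = calibrate_thresholds(
        pairs, loci, min_pairs=cfg.calib_min_pairs,
        ancestral_detect_override=cfg.ancestral_detect_override,
    )

    # 4. recent expansions (union over focal species), clustered
    recent: set[str] = set()
    for sp in focal:
        mass = subfamily_recent_mass(annotations[sp], cfg.recent_identity)
        recent.update(find_recent_subfamilies(mass, cfg.recent_min_mass))
    recent_families = sorted(recent)
    candidates = [cf for cf in library if cf.family_id in recent]
    if not candidates:
        log.warning("no recently expanding families found")
    representatives = (
        cluster_representatives(candidates, ident=cfg.cluster_identity, s=s)
        if candidates
        else []
    )

    # 5. expression proxy (only where coverage is supplied)
    expressed: dict[str, bool] = {}
    if coverage is not None:
        kept = []
        for cf in representatives:
            vec = coverage(cf) if callable(coverage) else coverage.get(cf.family_id)
            if vec is not None:
                ok = expression_filter(
                    cf, vec, motifs, min_frac=cfg.expression_min_frac
                )
            else:
                ok = True
            expressed[cf.family_id] = ok
            if ok:
                kept.append(cf)
        representatives = kept

    # 6. panel screen, classification, placement
    presence_rows, calls = screen_panel(
        representatives, panel_mem, tree,
        threshold=cfg.presence_threshold, min_len=cfg.presence_min_len, s=s,
    )

    # 7. donor consensuses, TE trees, evidence for the HTT candidates
    evidence: dict[str, HTTEvidence] = {}
    te_trees: dict[str, TETree] = {}
    row_of = {r.family_id: r for r in presence_rows}
    for call in calls:
        cf = next(c for c in representatives if c.family_id == call.family_id)
        te_tree = None
        if call.status == "htt":
            per_species = curate_donor_consensuses(
                cf, panel_mem,
                ident=cfg.donor_identity, cov=cfg.donor_coverage,
                flank=cfg.donor_flank, min_support=cfg.flank_min_support,
                s=s, bimodal_gap=cfg.bimodal_gap,
            )
            labels = []
            seqs = []
            for sp, conss in sorted(per_species.items()):
                for k, cons in enumerate(conss):
                    suffix = f".{k}" if len(conss) > 1 else ""
                    labels.append(f"{sp}::{cf.family_id}{suffix}")
                    seqs.append(cons)
            if len(seqs) >= 3:
                msa = progressive_msa(seqs, ids=labels, method=cfg.msa_method)
                te_tree = nj_tree_from_msa(msa)
                te_trees[call.family_id] = te_tree
        evidence[call.family_id] = score_evidence(
            cf, row_of[call.family_id], te_tree, panel_mem, calibration
        )
    return PipelineResult(
        library, annotations, calibration, recent_families, representatives,
        expressed, presence_rows, calls, evidence, te_trees,
    )


# ---------------------------------------------------------------------------
# the standard synthetic benchmark panel
# ---------------------------------------------------------------------------

BENCHMARK_TREE = (
    "(((((Aipysurus:0.025,Notechis:0.025)sea_tiger:0.015,Pseudonaja:0.04)"
    "core_hydrophiines:0.015,Laticauda:0.055)Hydrophiinae:0.035,Naja:0.07)"
    "elapids:0.3,(Danio:0.25,Limnodynastes:0.25)aquatic_outgroups:0.15)root;"
)

BENCHMARK_ROLES = {
    "Aipysurus": ("focal", "serpentes"),
    "Notechis": ("focal", "serpentes"),
    "Pseudonaja": ("focal", "serpentes"),
    "Laticauda": ("focal", "serpentes"),
    "Naja": ("relative", "serpentes"),
    "Danio": ("distant", "fish"),
    "Limnodynastes": ("distant", "amphibian"),
}


def benchmark_config(
    seed: int,
    genome_length: int = 2_000_000,
    n_ancestral: int = 6,
    n_htt: int = 3,
    ancestral_copies: int = 20,
    burst_copies: int = 90,
    htt_copies: int = 90,
    master_length: int = 1200,
) -> tuple[SimulationConfig, list[tuple[str, str]]]:
    """The standard planted-panel study: returns the simulation config and
    the (species, role) panel roles.

    Ancestral families arise in the elapid-like ancestor (focal clade +
    relative) and keep expanding in the focal species; HTT families are
    present at high identity in their recipients and one distant donor
    only. Copy numbers are sized so every family clears the 100 kb
    recent-mass gate in at least one focal genome.
    """
    focal = ["Aipysurus", "Notechis", "Pseudonaja", "Laticauda"]
    elapids = frozenset(focal + ["Naja"])
    fams: list[PlantedFamilySpec] = []
    for k in range(n_ancestral):
        fams.append(
            PlantedFamilySpec(
                f"anc{k}", "ancestral",
                copy_number=ancestral_copies, divergence=0.02,
                master_length=master_length, tsd_length=8 if k % 2 == 0 else 0,
                ancestor_of=elapids,
                recent_copy_number={sp: burst_copies for sp in focal},
                recent_divergence=0.02,
            )
        )
    htt_specs = [
        (frozenset(focal), "Danio"),
        (frozenset({"Laticauda"}), "Danio"),
        (frozenset({"Notechis"}), "Limnodynastes"),
    ]
    for k in range(n_htt):
        recipients, donor = htt_specs[k % len(htt_specs)]
        fams.append(
            PlantedFamilySpec(
                f"htt{k}", "htt",
                copy_number=htt_copies, divergence=0.02,
                master_length=master_length, tsd_length=8,
                htt_recipients=recipients, htt_donor=donor,
            )
        )
    cfg = SimulationConfig(
        seed=seed, species_tree=BENCHMARK_TREE, genome_length=genome_length,
        te_families=fams,
    )
    roles = [(sp, BENCHMARK_ROLES[sp][0]) for sp in BENCHMARK_ROLES]
    return cfg, roles


def run_benchmark(
    seed: int,
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    seed_noise: float = 0.02,
):
    """Simulate the benchmark panel and run the pipeline on it.

    Seed families are noisy copies of the planted masters (mimicking
    ab initio discovery output); each family's seed is assigned to one
    focal genome that carries it. Returns (result, truth, sim_config).
    """
    if sim_config is None:
        sim_config, _ = benchmark_config(seed)
    genomes, truth = simulate_panel(sim_config)
    panel = [
        PanelGenome(sp, genomes[sp], BENCHMARK_ROLES[sp][0], BENCHMARK_ROLES[sp][1])
        for sp in BENCHMARK_ROLES
        if sp in genomes
    ]
    rng = np.random.default_rng(seed + 1)
    seeds: dict[str, list[SeedFamily]] = {}
    for spec in sim_config.te_families:
        fid = spec.family_id
        carriers = truth.htt_labels[fid]["recipients"]
        focal_carriers = [sp for sp in carriers if BENCHMARK_ROLES.get(sp, ("",))[0] == "focal"]
        source = sorted(focal_carriers)[0]
        noisy = mutate_sequence(truth.masters[fid], seed_noise, seed=rng)
        seeds.setdefault(source, []).append(SeedFamily(fid, noisy, source))
    coverage = lambda cf: simulate_coverage(len(cf.consensus), expressed=True, seed=seed + 13)  # noqa: E731
    result = run_pipeline(
        seeds, panel, sim_config.species_tree,
        coverage=coverage, config=config, seed=seed,
    )
    return result, truth, sim_config


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def write_result(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(
        [(cf.header(), cf.consensus) for cf in result.library],
        os.path.join(outdir, "library.fa"),
    )
    for sp, records in result.annotations.items():
        records_to_bed(records, os.path.join(outdir, f"{sp}.annotation.bed"))
    result.calibration.to_json(os.path.join(outdir, "calibration.json"))
    presence_matrix_frame(result.presence_rows).to_csv(
        os.path.join(outdir, "presence_matrix.tsv"), sep="\t", index=False
    )
    calls = [
        {
            "family_id": c.family_id,
            "status": c.status,
            "recipients": c.recipients,
            "donor_candidates": c.donor_candidates,
            "branch": c.branch,
            "evidence": (
                {
                    "patchy": result.evidence[c.family_id].patchy,
                    "excess_similarity": result.evidence[c.family_id].excess_similarity,
                    "incongruent": result.evidence[c.family_id].incongruent,
                    "nearest_neighbor_species": result.evidence[c.family_id].nearest_neighbor_species,
                    "nearest_neighbor_identity": result.evidence[c.family_id].nearest_neighbor_identity,
                }
                if c.family_id in result.evidence
                else None
            ),
        }
        for c in result.calls
    ]
    with open(os.path.join(outdir, "htt_calls.json"), "w") as fh:
        json.dump(calls, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "te_trees.nwk"), "w") as fh:
        for fid, t in sorted(result.te_trees.items()):
            fh.write(f"{fid}\t{t.newick}\n")
    # per-branch summary of htt placements
    per_branch: dict[str, list[str]] = {}
    for c in result.calls:
        if c.status == "htt" and c.branch:
            per_branch.setdefault(c.branch, []).append(c.family_id)
    with open(os.path.join(outdir, "branch_summary.tsv"), "w") as fh:
        fh.write("branch\tn_events\tfamilies\n")
        for branch, fams in sorted(per_branch.items()):
            fh.write(f"{branch}\t{len(fams)}\t{','.join(sorted(fams))}\n")
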