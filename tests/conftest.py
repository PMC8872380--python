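"""Shared fixtures: the full benchmark panel run and the two-genome
calibration fixture are expensive, so they are built once per session
and reused by the unit, property and acceptance tests."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from httdetect.annotate import annotate_genome
from httdetect.calibrate import calibrate_thresholds, find_orthologues, sample_te_loci
from httdetect.curation import ConsensusFamily
from httdetect.pipeline import run_benchmark
from httdetect.simgenome import PlantedFamilySpec, SimulationConfig, simulate_panel

logging.getLogger("httdetect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bench():
    """Full-scale benchmark: 7 genomes × 2 Mb, 6 ancestral + 3 HTT planted
    families, complete pipeline run."""
    result, truth, sim = run_benchmark(seed=1)
    return {"result": result, "truth": truth, "sim": sim}


CALIB_TREE = "(A:0.045,B:0.045)root;"
SEGDUP_BLOCK = (500_000, 560_000)


@pytest.fixture(scope="session")
def calib_fx():
    """Two-genome calibration fixture: ancestral (pre-split) families in
    both genomes, recent (post-split) families in A only, plus a
    segmental duplication planted in B by copying a 60 kb block."""
    fams = [
        PlantedFamilySpec(
            f"anc{k}", "ancestral", copy_number=80, divergence=0.02,
            master_length=800, tsd_length=0,
        )
        for k in range(8)
    ] + [
        PlantedFamilySpec(
            f"rec{k}", "lineage_recent", copy_number={"A": 60}, divergence=0.02,
            master_length=800,
        )
        for k in range(3)
    ]
    sim = SimulationConfig(
        seed=5, species_tree=CALIB_TREE, genome_length=2_000_000, te_families=fams
    )
    genomes, truth = simulate_panel(sim)
    library = [ConsensusFamily(fid, seq) for fid, seq in truth.masters.items()]
    ann = annotate_genome(genomes["A"], library)
    s0, e0 = SEGDUP_BLOCK
    genome_b_dup = {"chr1": genomes["B"]["chr1"] + genomes["B"]["chr1"][s0:e0]}
    loci = sample_te_loci(ann, genomes["A"], n=500, min_len=500, flank=1000, seed=1)
    pairs = find_orthologues(loci, genome_b_dup)
    calib = calibrate_thresholds(pairs, loci)
    return {
        "sim": sim,
        "genomes": genomes,
        "genome_b_dup": genome_b_dup,
        "truth": truth,
        "library": library,
        "annotations": ann,
        "loci": loci,
        "pairs": pairs,
        "calib": calib,
    }


def truth_interval_map(truth, species_a: str, species_b: str, prefix: str = "anc"):
    """Map each pre-split insertion's interval in genome A to its
    orthologous interval in genome B (same planting order per family)."""
    from collections import defaultdict

    a_by = defaultdict(list)
    b_by = defaultdict(list)
    for r in truth.records_for(species_a):
        if r.family_id.startswith(prefix):
            a_by[r.family_id].append(r)
    for r in truth.records_for(species_b):
        if r.family_id.startswith(prefix):
            b_by[r.family_id].append(r)
    out = {}
    for fid in a_by:
        for ra, rb in zip(
            sorted(a_by[fid], key=lambda r: r.start),
            sorted(b_by[fid], key=lambda r: r.start),
        ):
            out[(ra.start, ra.end)] = (rb.start, rb.end)
    return out


def match_truth_interval(record, interval_map, min_frac: float = 0.8):
    """The truth interval a given annotation record covers, if any."""
    for (a_start, a_end), b_iv in interval_map.items():
        ov = min(a_end, record.end) - max(a_start, record.start)
        if ov > min_frac * (a_end - a_start):
            return (a_start, a_end), b_iv
    return None, None
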