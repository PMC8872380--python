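"""TE consensus phylogenies and horizontal-transfer evidence scoring.

For each transfer candidate, consensus sequences are re-curated from
every panel genome carrying the family at relaxed thresholds (70%
identity, 50% coverage — low enough to pull in divergent relatives that
serve as outgroups), aligned, and summarised as a neighbor-joining tree
on p-distances. Three lines of evidence are then scored, all of which a
genuine horizontal transfer must satisfy:

* patchy distribution — present in the focal lineage and in distant
  taxa but absent from close relatives;
* excess similarity — the nearest non-focal sequence is more similar
  than vertical inheritance allows (above the calibrated
  ancestral-detectability floor) and comes from a distant group;
* phylogenetic incongruence — in the TE tree the focal consensus is
  closer to a distant-group consensus than to any relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .aligncore import (
    MSA,
    ScoringScheme,
    batch_search,
    p_distance_matrix,
    progressive_msa,
)
from .calibrate import DivergenceCalibration
from .curation import ConsensusFamily, ExtendedCopy, build_consensus, extend_flanks, trim_nonhomologous_flanks
from .httscreen import PanelGenome, PresenceRow
from ._seqs import read_fasta

log = logging.getLogger(__name__)

__all__ = [
    "TETree",
    "HTTEvidence",
    "curate_donor_consensuses",
    "build_nj_tree",
    "nj_tree_from_msa",
    "score_evidence",
]


@dataclass
class TETree:
    newick: str
    leaf_labels: list[str]
    method: str = "nj-pdistance"

    def as_dendropy(self):
        from .trees import load_tree

        return load_tree(self.newick)


@dataclass
class HTTEvidence:
    family_id: str
    patchy: bool
    excess_similarity: bool
    incongruent: bool
    nearest_neighbor_species: str | None = None
    nearest_neighbor_identity: float = 0.0

    @property
    def supported(self) -> bool:
        return self.patchy and self.excess_similarity and self.incongruent


# ---------------------------------------------------------------------------
# donor-consensus curation (relaxed thresholds)
# ---------------------------------------------------------------------------


def _split_bimodal(msa: MSA, gap_points: float = 8.0) -> list[list[int]]:
    """2-medoid split of MSA rows when two clearly distinct subfamilies
    are present (mean within-cluster identity exceeds between-cluster
    identity by ≥ ``gap_points`` percentage points); else one cluster."""
    n = len(msa.rows)
    if n < 4:
        return [list(range(n))]
    d = p_distance_matrix(msa)
    d = np.nan_to_num(d, nan=1.0)
    # seed medoids with the most distant pair, assign rows to nearest
    i0, j0 = np.unravel_index(np.argmax(d), d.shape)
    assign = [0 if d[k, i0] <= d[k, j0] else 1 for k in range(n)]
    a = [k for k in range(n) if assign[k] == 0]
    b = [k for k in range(n) if assign[k] == 1]
    if len(a) < 2 or len(b) < 2:
        return [list(range(n))]
    within = np.concatenate(
        [d[np.ix_(a, a)][np.triu_indices(len(a), 1)], d[np.ix_(b, b)][np.triu_indices(len(b), 1)]]
    )
    between = d[np.ix_(a, b)].ravel()
    if (between.mean() - within.mean()) * 100.0 >= gap_points:
        return [a, b]
    return [list(range(n))]


def curate_donor_consensuses(
    family: ConsensusFamily,
    panel: list[PanelGenome],
    ident: float = 70.0,
    cov: float = 0.5,
    max_copies: int = 20,
    flank: int = 1000,
    min_support: int = 2,
    s: ScoringScheme | None = None,
    msa_method: str = "fast",
    bimodal_gap: float = 8.0,
) -> dict[str, list[str]]:
    """Per-species consensus(es) of a family re-curated from each panel
    genome with hits at ≥ ``ident``% identity covering ≥ ``cov`` of the
    consensus. Genomes with < 2 usable copies yield none (logged); when
    the per-species alignment splits into two distinct subfamilies, two
    consensuses are emitted."""
    s = s or ScoringScheme()
    out: dict[str, list[str]] = {}
    min_len = int(np.ceil(cov * len(family.consensus)))
    for genome_meta in panel:
        genome = genome_meta.path
        if isinstance(genome, (str,)):
            genome = read_fasta(genome)
        hits = batch_search(
            {family.family_id: family.consensus}, genome, s,
            min_identity=ident, min_len=min_len,
        )
        if len(hits) < 2:
            if hits:
                log.info(
                    "%s / %s: only one usable copy; no consensus",
                    family.family_id, genome_meta.species,
                )
            continue
        hits = hits[:max_copies]
        copies = extend_flanks(hits, genome, flank=flank)
        copies = trim_nonhomologous_flanks(copies, min_support=min_support, s=s)
        msa = progressive_msa([c.seq for c in copies], method=msa_method)
        clusters = _split_bimodal(msa, gap_points=bimodal_gap)
        consensuses = []
        for rows in clusters:
            if len(rows) < 2:
                continue
            sub = MSA([msa.rows[k] for k in rows])
            cons = build_consensus(sub)
            if cons:
                consensuses.append(cons)
        if consensuses:
            out[genome_meta.species] = consensuses
    return out


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def build_nj_tree(dist: np.ndarray, labels: list[str], method_tag: str = "nj-pdistance") -> TETree:
    """Neighbor joining on a distance matrix.

    Standard Saitou–Nei agglomeration; negative branch lengths are
    clamped to zero; Q-ties are broken deterministically by the sorted
    label pair. With all distances equal the star therefore resolves in
    label order.
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")
    # node fragments and an ordering key (smallest contained leaf label);
    # labels are quoted so characters like ':' survive Newick round-trips
    frags = ["'" + lab.replace("'", "''") + "'" for lab in labels]
    keys = list(labels)
    active = list(range(n))

    def fmt(x: float) -> str:
        return f"{max(0.0, x):.10g}"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new_frag = f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})"
        new_key = min(keys[i], keys[j])
        # distances to the new node
        dnew = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew[:-1]
        d[:-1, -1] = dnew[:-1]
        frags.append(new_frag)
        keys.append(new_key)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    order = sorted([(keys[i], i, li), (keys[j], j, lj), (keys[k], k, lk)])
    parts = ",".join(f"{frags[idx]}:{fmt(ln)}" for _, idx, ln in order)
    newick = f"({parts});"
    return TETree(newick, sorted(labels), method_tag)


def nj_tree_from_msa(msa: MSA) -> TETree:
    """NJ tree over the rows of an MSA using p-distances."""
    d = p_distance_matrix(msa)
    if np.isnan(d).any():
        raise ValueError("undefined p-distance (no shared non-gap columns)")
    return build_nj_tree(d, msa.ids)


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------


def score_evidence(
    family: ConsensusFamily,
    row: PresenceRow,
    te_tree: TETree | None,
    panel: list[PanelGenome],
    calib: DivergenceCalibration,
) -> HTTEvidence:
    """Score the three horizontal-transfer evidence criteria for a family.

    Tree leaves are labelled ``species::family_id``; the focal leaf's
    nearest *non-focal* leaf by patristic distance decides incongruence.
    """
    role = {g.species: g.role for g in panel}
    focal = {sp for sp, r in role.items() if r == "focal"}
    relatives = {sp for sp, r in role.items() if r == "relative"}
    distant = {sp for sp, r in role.items() if r == "distant"}

    present = {sp: e.present for sp, e in row.entries.items()}
    patchy = (
        any(present.get(sp, False) for sp in focal)
        and any(present.get(sp, False) for sp in distant)
        and not any(present.get(sp, False) for sp in relatives)
    )

    # nearest non-focal neighbour by cross-genome identity
    candidates = [
        (e.identity, sp)
        for sp, e in row.entries.items()
        if sp not in focal and e.identity > 0
    ]
    if candidates:
        nn_ident, nn_sp = max(candidates, key=lambda t: (t[0], t[1]))
    else:
        nn_ident, nn_sp = 0.0, None
    excess = (
        nn_sp is not None
        and nn_ident > calib.ancestral_detect_threshold
        and nn_sp in distant
    )

    if te_tree is not None and len(te_tree.leaf_labels) >= 3:
        incongruent = _tree_incongruent(te_tree, focal, distant)
    else:
        # with fewer than three consensuses a tree carries no topology;
        # the criterion degenerates to the nearest-neighbour comparison
        incongruent = nn_sp is not None and nn_sp in distant
    return HTTEvidence(family.family_id, patchy, excess, incongruent, nn_sp, nn_ident)


def _tree_incongruent(te_tree: TETree, focal: set[str], distant: set[str]) -> bool:
    import dendropy

    tree = te_tree.as_dendropy()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    species_of = {t: t.label.split("::")[0] for t in taxa}
    focal_taxa = [t for t in taxa if species_of[t] in focal]
    if not focal_taxa:
        return False
    for ft in focal_taxa:
        others = [
            (pdm.patristic_distance(ft, t), species_of[t], t)
            for t in taxa
            if t is not ft and species_of[t] not in focal
        ]
        if not others:
            continue
        dmin, sp, _ = min(others, key=lambda x: (x[0], x[1]))
        if sp in distant:
            return True
    return False
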