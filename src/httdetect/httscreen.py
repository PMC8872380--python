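"""Panel-wide screening for horizontal transposon transfer.

Given curated consensus families that are expanding recently in a focal
lineage, the screen asks each genome of a panel — focal species, close
relatives, and distant outgroup genomes — whether the family is present
at or above a conservative identity floor. The decision logic is
deliberately asymmetric: presence in *any* relative genome is enough to
call a family ancestral (vertical inheritance with loss elsewhere is
always the more parsimonious explanation), while a horizontal-transfer
call requires absence from every relative *and* presence in at least
one distant genome. Calls are placed on the species tree by single-gain
(Dollo-like) parsimony: the branch above the most recent common
ancestor of the recipient species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligncore import ScoringScheme, batch_search, global_align
from .curation import ConsensusFamily, MotifTable
from .trees import load_tree, mrca_branch

log = logging.getLogger(__name__)

__all__ = [
    "PanelGenome",
    "PresenceEntry",
    "PresenceRow",
    "HTTCall",
    "find_recent_subfamilies",
    "cluster_representatives",
    "expression_filter",
    "presence_screen",
    "classify_htt",
    "place_on_tree",
    "screen_panel",
    "presence_matrix_frame",
    "read_panel_tsv",
]


@dataclass
class PanelGenome:
    species: str
    path: str  # FASTA path (or an in-memory {contig: seq} dict)
    role: str  # focal | relative | distant
    group: str = ""

    def __post_init__(self):
        if self.role not in {"focal", "relative", "distant"}:
            raise ValueError(f"unknown role {self.role!r}")


def read_panel_tsv(path) -> list[PanelGenome]:
    """Panel metadata TSV: species, fasta path, role, taxonomic group."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(PanelGenome(f[0], f[1], f[2], f[3] if len(f) > 3 else ""))
    roles = {g.role for g in out}
    if not {"focal", "relative", "distant"} <= roles:
        raise ValueError("panel needs at least one focal, relative and distant genome")
    return out


@dataclass
class PresenceEntry:
    identity: float
    aligned_bp: int
    present: bool


@dataclass
class PresenceRow:
    family_id: str
    entries: dict[str, PresenceEntry] = field(default_factory=dict)


@dataclass
class HTTCall:
    family_id: str
    status: str  # ancestral | htt | undetermined
    recipients: list[str] = field(default_factory=list)
    donor_candidates: list[str] = field(default_factory=list)
    branch: str | None = None


def find_recent_subfamilies(mass: dict[str, int], min_mass: int = 100_000) -> list[str]:
    """Families whose recent (high-identity) copy mass reaches
    ``min_mass`` bp, sorted by mass descending."""
    hits = [(fid, bp) for fid, bp in mass.items() if bp >= min_mass]
    hits.sort(key=lambda x: (-x[1], x[0]))
    return [fid for fid, _ in hits]


def cluster_representatives(
    consensuses: list[ConsensusFamily], ident: float = 95.0, s: ScoringScheme | None = None
) -> list[ConsensusFamily]:
    """Greedy length-sorted clustering (CD-HIT style): each sequence joins
    the first representative it matches at ≥ ``ident`` percent global
    identity over the shorter sequence; otherwise it founds a cluster.
    The result is invariant to input order (internal length/id sort)."""
    if not consensuses:
        raise ValueError("need at least one consensus")
    s = s or ScoringScheme()
    ordered = sorted(consensuses, key=lambda c: (-len(c.consensus), c.family_id))
    reps: list[ConsensusFamily] = []
    for cf in ordered:
        joined = False
        for rep in reps:
            qa, qb, _ = global_align(cf.consensus, rep.consensus, s)
            matches = sum(
                1 for a, b in zip(qa, qb) if a != "-" and b != "-" and a == b
            )
            shorter = min(len(cf.consensus), len(rep.consensus))
            if 100.0 * matches / shorter >= ident:
                joined = True
                break
        if not joined:
            reps.append(cf)
    return reps


def expression_filter(
    family: ConsensusFamily,
    coverage: np.ndarray,
    motifs: MotifTable | None = None,
    min_frac: float = 0.95,
) -> bool:
    """Expression proxy from read coverage over the consensus.

    Retrotransposons (LINE/LTR/Penelope) must be covered (≥ 1×) over ≥
    ``min_frac`` of their full length; DNA transposons only over their
    coding interval (taken from the motif-hit span, falling back to the
    full length when no motif is annotated).
    """
    if len(coverage) != len(family.consensus):
        raise ValueError("coverage length must equal consensus length")
    covered = np.asarray(coverage) >= 1
    cls = family.classification
    if cls.startswith("DNA"):
        interval = motifs.coding_interval(family.consensus) if motifs else None
        if interval is None:
            interval = (0, len(family.consensus))
        lo, hi = interval
        region = covered[lo:hi]
    else:
        region = covered
    if region.size == 0:
        return False
    return float(region.mean()) >= min_frac


def presence_screen(
    family: ConsensusFamily,
    panel: list[PanelGenome],
    threshold: float = 80.0,
    min_len: int = 100,
    s: ScoringScheme | None = None,
) -> PresenceRow:
    """Best hit of one family in every panel genome, with presence flags."""
    rows = _screen_families([family], panel, threshold, min_len, s)
    return rows[0]


def _screen_families(
    families: list[ConsensusFamily],
    panel: list[PanelGenome],
    threshold: float,
    min_len: int,
    s: ScoringScheme | None,
) -> list[PresenceRow]:
    s = s or ScoringScheme()
    queries = {cf.family_id: cf.consensus for cf in families}
    rows = {cf.family_id: PresenceRow(cf.family_id) for cf in families}
    for genome in panel:
        hits = batch_search(queries, genome.path, s, min_identity=0.0, min_len=min_len)
        best: dict[str, tuple[float, int]] = {}
        for h in hits:
            ident, bp = best.get(h.query_id, (0.0, 0))
            if h.percent_identity > ident:
                best[h.query_id] = (h.percent_identity, h.query_len)
        for cf in families:
            ident, bp = best.get(cf.family_id, (0.0, 0))
            present = ident >= threshold and bp >= min_len
            rows[cf.family_id].entries[genome.species] = PresenceEntry(
                round(ident, 3), bp, present
            )
    return [rows[cf.family_id] for cf in families]


def classify_htt(row: PresenceRow, panel: list[PanelGenome]) -> HTTCall:
    """Ancestral / horizontally-transferred / undetermined for one family.

    Present in any relative genome → ancestral (conservative). Absent
    from all relatives and present in ≥ 1 distant genome → htt. Absent
    everywhere outside the focal lineage → undetermined.
    """
    by_role: dict[str, list[PanelGenome]] = {"focal": [], "relative": [], "distant": []}
    for g in panel:
        by_role[g.role].append(g)
    present = lambda g: row.entries[g.species].present  # noqa: E731
    recipients = sorted(g.species for g in by_role["focal"] if present(g))
    if any(present(g) for g in by_role["relative"]):
        return HTTCall(row.family_id, "ancestral", recipients)
    distant_present = [g for g in by_role["distant"] if present(g)]
    if distant_present:
        donors = sorted(
            (g.species for g in distant_present),
            key=lambda sp: (-row.entries[sp].identity, sp),
        )
        return HTTCall(row.family_id, "htt", recipients, donors)
    return HTTCall(row.family_id, "undetermined", recipients)


def place_on_tree(recipients, tree) -> str:
    """Single-gain placement: the branch above the recipients' MRCA."""
    if isinstance(tree, str):
        tree = load_tree(tree)
    return mrca_branch(tree, set(recipients))


def presence_matrix_frame(rows: list[PresenceRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        for sp, e in row.entries.items():
            records.append(
                {
                    "family_id": row.family_id,
                    "species": sp,
                    "identity": e.identity,
                    "aligned_bp": e.aligned_bp,
                    "present": e.present,
                }
            )
    return pd.DataFrame(records, columns=["family_id", "species", "identity", "aligned_bp", "present"])


def screen_panel(
    families: list[ConsensusFamily],
    panel: list[PanelGenome],
    tree,
    threshold: float = 80.0,
    min_len: int = 100,
    s: ScoringScheme | None = None,
) -> tuple[list[PresenceRow], list[HTTCall]]:
    """Presence screen + classification + branch placement for a set of
    candidate families."""
    if isinstance(tree, str):
        tree = load_tree(tree)
    rows = _screen_families(families, panel, threshold, min_len, s)
    calls = []
    for row in rows:
        call = classify_htt(row, panel)
        if call.status == "htt" and call.recipients:
            call.branch = place_on_tree(call.recipients, tree)
        calls.append(call)
    return rows, calls
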