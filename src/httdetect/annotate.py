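"""Genome annotation with a consensus library, divergence landscapes and
composition summaries.

Annotation runs the seeded search for every library family, then
resolves overlapping hits greedily by score: the highest-scoring record
at a locus is kept intact and lower-scoring overlaps are trimmed to
their non-overlapping residue (dropped when the residue is shorter than
the minimum length). Landscapes bin annotated base pairs by integer
percent identity to the consensus — the classic repeat divergence
landscape, with young copies piling up near 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aligncore import RepeatHit, ScoringScheme, batch_search
from .curation import ConsensusFamily

__all__ = [
    "AnnotationRecord",
    "annotate_genome",
    "divergence_landscape",
    "composition_summary",
    "subfamily_recent_mass",
    "plot_landscape",
    "records_to_bed",
    "records_from_bed",
]


@dataclass
class AnnotationRecord:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    family_id: str
    classification: str
    percent_identity: float
    score: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("identity must be in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


def _resolve_overlaps(
    hits: list[tuple[RepeatHit, str]], min_len: int, tolerance: int
) -> list[AnnotationRecord]:
    """Greedy by score; lower-scoring records overlapping a kept record by
    more than ``tolerance`` bp are trimmed to their largest free residue."""
    ordered = sorted(
        hits, key=lambda hc: (-hc[0].score, hc[0].target_contig, hc[0].target_span[0],
                              hc[0].query_id)
    )
    kept: dict[str, list[tuple[int, int]]] = {}
    out: list[AnnotationRecord] = []
    for h, classification in ordered:
        contig = h.target_contig
        s0, e0 = h.target_span
        intervals = kept.setdefault(contig, [])
        # subtract already-kept intervals (allowing `tolerance` slack per overlap)
        free = [(s0, e0)]
        for ks, ke in intervals:
            nxt = []
            for fs, fe in free:
                ov = min(fe, ke) - max(fs, ks)
                if ov <= tolerance:
                    nxt.append((fs, fe))
                    continue
                if ks > fs:
                    nxt.append((fs, min(fe, ks)))
                if ke < fe:
                    nxt.append((max(fs, ke), fe))
            free = [(a, b) for a, b in nxt if b - a > 0]
            if not free:
                break
        if not free:
            continue
        fs, fe = max(free, key=lambda iv: (iv[1] - iv[0], -iv[0]))
        if fe - fs < min_len:
            continue
        intervals.append((fs, fe))
        out.append(
            AnnotationRecord(
                contig, fs, fe, h.strand, h.query_id, classification,
                round(h.percent_identity, 3), h.score,
            )
        )
    out.sort(key=lambda r: (r.contig, r.start, r.end, r.family_id))
    return out


def annotate_genome(
    genome: dict[str, str] | str,
    library: list[ConsensusFamily],
    min_identity: float = 60.0,
    min_len: int = 80,
    s: ScoringScheme | None = None,
    overlap_tolerance: int = 10,
) -> list[AnnotationRecord]:
    """Annotate a genome with every family of a consensus library."""
    if not library:
        raise ValueError("library must be non-empty")
    if isinstance(genome, dict) and all(len(v) == 0 for v in genome.values()):
        return []
    s = s or ScoringScheme()
    queries = {cf.family_id: cf.consensus for cf in library}
    classif = {cf.family_id: cf.classification for cf in library}
    hits = batch_search(queries, genome, s, min_identity=min_identity, min_len=min_len)
    return _resolve_overlaps([(h, classif[h.query_id]) for h in hits], min_len, overlap_tolerance)


def divergence_landscape(records: list[AnnotationRecord]) -> pd.DataFrame:
    """bp mass per (classification, integer identity bin in [50, 100])."""
    rows = []
    for r in records:
        b = int(np.floor(r.percent_identity))
        b = min(max(b, 50), 100)
        rows.append((r.classification, b, r.length))
    if not rows:
        return pd.DataFrame(columns=["classification", "identity_bin", "bp"])
    df = pd.DataFrame(rows, columns=["classification", "identity_bin", "bp"])
    return (
        df.groupby(["classification", "identity_bin"], as_index=False)["bp"]
        .sum()
        .sort_values(["classification", "identity_bin"], ignore_index=True)
    )


def composition_summary(records: list[AnnotationRecord], genome_length: int) -> pd.DataFrame:
    """Repeat composition: bp and % of genome per classification, plus a
    'Total interspersed repeats' row."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    per: dict[str, int] = {}
    for r in records:
        per[r.classification] = per.get(r.classification, 0) + r.length
    rows = [
        {"classification": c, "bp": bp, "percent": round(100.0 * bp / genome_length, 2)}
        for c, bp in sorted(per.items())
    ]
    total = sum(per.values())
    rows.append(
        {
            "classification": "Total interspersed repeats",
            "bp": total,
            "percent": round(100.0 * total / genome_length, 2),
        }
    )
    return pd.DataFrame(rows, columns=["classification", "bp", "percent"])


def subfamily_recent_mass(
    records: list[AnnotationRecord], threshold: float
) -> dict[str, int]:
    """Total annotated bp per family at identity ≥ ``threshold``."""
    mass: dict[str, int] = {}
    for r in records:
        if r.percent_identity >= threshold:
            mass[r.family_id] = mass.get(r.family_id, 0) + r.length
    return mass


def plot_landscape(landscape: pd.DataFrame, path, title: str | None = None) -> None:
    """Stacked-bar divergence landscape (PNG/SVG by file extension).

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = np.arange(50, 101)
    fig, ax = plt.subplots(figsize=(9, 4))
    bottom = np.zeros(len(bins))
    for cls, sub in landscape.groupby("classification"):
        mass = np.zeros(len(bins))
        for _, row in sub.iterrows():
            mass[int(row.identity_bin) - 50] = row.bp
        ax.bar(bins, mass / 1000, bottom=bottom / 1000, width=0.9, label=cls)
        bottom += mass
    ax.set_xlabel("percent identity to consensus")
    ax.set_ylabel("kb")
    ax.invert_xaxis()  # oldest (most diverged) on the left
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# BED I/O (BED6 + family_id, classification, identity)
# ---------------------------------------------------------------------------


def records_to_bed(records: list[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.family_id}\t{r.score}\t{r.strand}"
                f"\t{r.family_id}\t{r.classification}\t{r.percent_identity:.3f}\n"
            )


def records_from_bed(path) -> list[AnnotationRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                AnnotationRecord(
                    f[0], int(f[1]), int(f[2]), f[5], f[6], f[7], float(f[8]), int(f[4])
                )
            )
    return out
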