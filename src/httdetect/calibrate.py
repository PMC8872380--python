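"""Divergence calibration from orthologous TE insertions.

Insertions shared at the same locus by two genomes must predate their
split, so the identity of such copies to the consensus that found them
estimates how divergent *ancestral* insertions look. Sampling TE loci
in genome A, finding single-copy orthologues (TE + flank) in genome B,
and comparing the identity distribution of the orthologue-backed subset
against all sampled TEs yields two operating thresholds:

* ``recent_threshold`` — copies at or above this identity to consensus
  are too similar to be ancestral (insertions postdating the split);
* ``ancestral_detect_threshold`` — the minimum cross-genome identity a
  vertically inherited family is expected to retain; families absent at
  this identity from related genomes become horizontal-transfer
  candidates.

Loci with more than one flank-containing hit in genome B are excluded
as potential segmental duplications.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .aligncore import ScoringScheme, batch_search, percent_identity
from .annotate import AnnotationRecord

log = logging.getLogger(__name__)

__all__ = [
    "SampledLocus",
    "OrthologuePair",
    "DivergenceCalibration",
    "sample_te_loci",
    "find_orthologues",
    "calibrate_thresholds",
]


@dataclass
class SampledLocus:
    locus_id: str
    seq: str  # TE plus up to `flank` bp each side
    te_span: tuple[int, int]  # TE interval within seq
    record: AnnotationRecord


@dataclass
class OrthologuePair:
    locus_id: str
    te_identity_to_consensus_in_A: float
    te_identity_A_vs_B: float
    te_bp_aligned: int
    flank_bp_aligned: int
    n_flanked_hits: int


@dataclass
class DivergenceCalibration:
    n_sampled: int
    n_orthologous: int
    median_identity_all: float
    median_identity_ancestral: float
    q95_all: float
    q95_ancestral: float
    recent_threshold: float
    ancestral_detect_threshold: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DivergenceCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def sample_te_loci(
    records: list[AnnotationRecord],
    genome: dict[str, str],
    n: int = 5000,
    min_len: int = 500,
    flank: int = 1000,
    seed: int = 0,
) -> list[SampledLocus]:
    """Uniform sample (without replacement) of annotated TEs ≥ ``min_len``
    bp, extracted with up to ``flank`` bp of genomic context each side."""
    qualifying = [r for r in records if r.length >= min_len]
    if not qualifying:
        log.warning("no annotation records of length >= %d; empty sample", min_len)
        return []
    rng = np.random.default_rng(seed)
    if len(qualifying) > n:
        idx = rng.choice(len(qualifying), size=n, replace=False)
        chosen = [qualifying[i] for i in sorted(idx)]
    else:
        if len(qualifying) < n:
            log.warning("only %d qualifying records (asked for %d); sampling all",
                        len(qualifying), n)
        chosen = qualifying
    out = []
    for k, r in enumerate(chosen):
        contig = genome[r.contig]
        lo = max(0, r.start - flank)
        hi = min(len(contig), r.end + flank)
        out.append(
            SampledLocus(f"locus{k}", contig[lo:hi], (r.start - lo, r.end - lo), r)
        )
    return out


def find_orthologues(
    loci: list[SampledLocus],
    genome_b: dict[str, str] | str,
    min_te_bp: int = 250,
    min_flank_bp: int = 250,
    s: ScoringScheme | None = None,
    min_identity: float = 60.0,
) -> list[OrthologuePair]:
    """Single-copy orthologues of sampled loci in a second genome.

    A locus is accepted when exactly one hit covers ≥ ``min_te_bp`` of
    the TE and ≥ ``min_flank_bp`` of flank; loci with two or more
    flank-containing hits are treated as segmental duplications and
    dropped.
    """
    if not loci:
        return []
    s = s or ScoringScheme()
    queries = {loc.locus_id: loc.seq for loc in loci}
    by_id = {loc.locus_id: loc for loc in loci}
    hits = batch_search(queries, genome_b, s, min_identity=min_identity, min_len=100)
    grouped: dict[str, list] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    out: list[OrthologuePair] = []
    for locus_id, loc in by_id.items():
        ts, te = loc.te_span
        qualifying = []
        n_flanked = 0
        for h in grouped.get(locus_id, []):
            qs, qe = h.query_span
            te_bp = max(0, min(qe, te) - max(qs, ts))
            flank_bp = (qe - qs) - te_bp
            if flank_bp >= min_flank_bp:
                n_flanked += 1
            if te_bp >= min_te_bp and flank_bp >= min_flank_bp:
                qualifying.append((h, te_bp, flank_bp))
        if len(qualifying) != 1 or n_flanked > 1:
            continue
        h, te_bp, flank_bp = qualifying[0]
        # identity over the TE portion of the alignment only
        te_ident = _te_identity(h, ts, te)
        out.append(
            OrthologuePair(
                locus_id,
                loc.record.percent_identity,
                round(te_ident, 3),
                te_bp,
                flank_bp,
                1,
            )
        )
    return out


def _te_identity(hit, ts: int, te: int) -> float:
    """Percent identity of the alignment columns falling inside the TE."""
    qa, qb = hit.alignment
    qpos = hit.query_span[0]
    cols_a = []
    cols_b = []
    for ca, cb in zip(qa, qb):
        if ts <= qpos < te:
            cols_a.append(ca)
            cols_b.append(cb)
        if ca != "-":
            qpos += 1
    if not cols_a:
        return hit.percent_identity
    return percent_identity("".join(cols_a), "".join(cols_b))


def _round_half_up(x: float) -> float:
    return float(np.floor(x + 0.5))


def calibrate_thresholds(
    pairs: list[OrthologuePair],
    sampled: list[SampledLocus],
    min_pairs: int = 50,
    ancestral_detect_override: float | None = 80.0,
) -> DivergenceCalibration:
    """Medians and 95% quantiles of identity-to-consensus for all sampled
    TEs vs the orthologue-backed (ancestral) subset, and the derived
    operating thresholds.

    Quantiles use linear interpolation between order statistics. The
    recent threshold is the 95% quantile of the ancestral distribution
    rounded half-up to an integer. The ancestral-detectability threshold
    defaults to the configured override (80, the conservative floor used
    in practice); with ``ancestral_detect_override=None`` it is derived
    as the floor of the 1st percentile of cross-genome TE identity.
    """
    if len(pairs) < min_pairs:
        raise ValueError(
            f"only {len(pairs)} orthologue pairs (need >= {min_pairs}); "
            "increase the locus sample size"
        )
    all_ident = np.array([loc.record.percent_identity for loc in sampled], dtype=float)
    anc_ident = np.array([p.te_identity_to_consensus_in_A for p in pairs], dtype=float)
    cross = np.array([p.te_identity_A_vs_B for p in pairs], dtype=float)
    q95_anc = float(np.percentile(anc_ident, 95, method="linear"))
    if ancestral_detect_override is not None:
        detect = float(ancestral_detect_override)
    else:
        detect = float(np.floor(np.percentile(cross, 1, method="linear")))
    return DivergenceCalibration(
        n_sampled=len(sampled),
        n_orthologous=len(pairs),
        median_identity_all=float(np.median(all_ident)),
        median_identity_ancestral=float(np.median(anc_ident)),
        q95_all=float(np.percentile(all_ident, 95, method="linear")),
        q95_ancestral=q95_anc,
        recent_threshold=_round_half_up(q95_anc),
        ancestral_detect_threshold=detect,
    )
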