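"""Consensus curation: from raw seed repeat families to curated subfamilies.

Implements the "search, extend, align, trim" protocol used for manual
repeat-library curation, automated: purge redundant seed families, pull
the best genomic copies of each survivor, extend their flanks, trim
flank sequence not shared with other copies, align, cut at target-site
duplications, call a majority-rule consensus and classify it from
sequence structure (protein-coding motifs, terminal inverted repeats,
TSD length, poly-A tails).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from ._seqs import GAP, IUPAC_MASKS, MASK_TO_CODE, revcomp
from .aligncore import (
    MSA,
    RepeatHit,
    ScoringScheme,
    batch_search,
    local_align_oracle,
    progressive_msa,
)

log = logging.getLogger(__name__)

__all__ = [
    "SeedFamily",
    "ConsensusFamily",
    "MotifTable",
    "ExtendedCopy",
    "purge_redundant",
    "collect_top_copies",
    "extend_flanks",
    "trim_nonhomologous_flanks",
    "build_consensus",
    "detect_tsd_and_trim",
    "classify_family",
    "curate_family",
    "curate_library",
]

_SEED_ALPHABET = re.compile(r"^[ACGTN]+$")

# default mapping from detected TSD length to DNA-transposon superfamily
# (TIR + TSD route); anything unlisted falls back to DNA/Unknown-TIR
DEFAULT_TSD_RULES = {2: "DNA/Tc1-Mariner", 8: "DNA/hAT", 3: "DNA/PIF-Harbinger"}


@dataclass
class SeedFamily:
    family_id: str
    sequence: str
    source_species: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 80:
            raise ValueError(f"{self.family_id}: seed families must be >= 80 bp")
        if not _SEED_ALPHABET.match(self.sequence):
            raise ValueError(f"{self.family_id}: alphabet must be ACGTN")


@dataclass
class ConsensusFamily:
    family_id: str
    consensus: str
    classification: str = "Unknown"
    tsd_length: int | None = None
    tir: bool = False
    n_copies_used: int = 0
    provenance: list = field(default_factory=list)  # (contig, start, end, strand)

    def header(self) -> str:
        tsd = self.tsd_length if self.tsd_length is not None else 0
        return (
            f"{self.family_id}#{self.classification} "
            f"tsd={tsd} tir={int(self.tir)} n={self.n_copies_used}"
        )


class MotifTable:
    """Rows of (motif_id, superfamily classification, IUPAC DNA motif)."""

    def __init__(self, rows: list[tuple[str, str, str]]):
        for _, _, motif in rows:
            if not all(c in IUPAC_MASKS for c in motif.upper()):
                raise ValueError(f"invalid IUPAC motif: {motif}")
        self.rows = [(m, s, seq.upper()) for m, s, seq in rows]

    @classmethod
    def from_tsv(cls, path) -> "MotifTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                motif_id, superfamily, motif = line.split("\t")[:3]
                rows.append((motif_id, superfamily, motif))
        return cls(rows)

    @staticmethod
    def _regex(motif: str) -> re.Pattern:
        classes = {
            code: "[" + "".join(b for b in "ACGT" if IUPAC_MASKS[b] & mask) + "]"
            for code, mask in IUPAC_MASKS.items()
        }
        return re.compile("".join(classes[c] for c in motif))

    def scan(self, seq: str) -> list[tuple[str, str]]:
        """(motif_id, superfamily) for every motif found on either strand."""
        seq = seq.upper()
        rc = revcomp(seq)
        found = []
        for motif_id, superfamily, motif in self.rows:
            pat = self._regex(motif)
            if pat.search(seq) or pat.search(rc):
                found.append((motif_id, superfamily))
        return found

    def coding_interval(self, seq: str) -> tuple[int, int] | None:
        """Span of the union of motif hits on the forward strand (used as
        the coding-region stand-in for DNA transposons)."""
        seq = seq.upper()
        spans = []
        for _, _, motif in self.rows:
            m = self._regex(motif).search(seq)
            if m:
                spans.append(m.span())
        if not spans:
            return None
        return min(s for s, _ in spans), max(e for _, e in spans)


# ---------------------------------------------------------------------------
# purge
# ---------------------------------------------------------------------------


def _union_coverage(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def purge_redundant(
    families: list[SeedFamily],
    cov: float = 0.75,
    ident: float = 90.0,
    s: ScoringScheme | None = None,
) -> list[SeedFamily]:
    """Drop seed families largely contained in a longer family.

    A family is removed when ≥ ``cov`` of its length aligns at
    ≥ ``ident`` percent identity to a strictly longer *retained* family
    (coverage = union of non-overlapping aligned query positions).
    "Longer" ties are broken lexicographically by family_id, so the
    result is invariant to input order.
    """
    if not families:
        raise ValueError("families must be non-empty")
    s = s or ScoringScheme()
    order = sorted(families, key=lambda f: (-len(f.sequence), f.family_id))
    seqs = {f.family_id: f.sequence for f in order}
    if len(order) == 1:
        return list(order)
    hits = batch_search(seqs, seqs, s, min_identity=ident, min_len=1)
    by_query: dict[str, list[RepeatHit]] = {}
    for h in hits:
        if h.query_id != h.target_contig:
            by_query.setdefault(h.query_id, []).append(h)
    retained: list[SeedFamily] = []
    retained_keys: set[str] = set()
    keyrank = {f.family_id: i for i, f in enumerate(order)}
    for fam in order:
        spans = [
            h.query_span
            for h in by_query.get(fam.family_id, [])
            if h.target_contig in retained_keys
            and keyrank[h.target_contig] < keyrank[fam.family_id]
        ]
        covered = _union_coverage(spans)
        if covered >= cov * len(fam.sequence):
            log.info("purged %s (%.2f covered by longer family)", fam.family_id,
                     covered / len(fam.sequence))
            continue
        retained.append(fam)
        retained_keys.add(fam.family_id)
    return retained


# ---------------------------------------------------------------------------
# collect / extend / trim
# ---------------------------------------------------------------------------


def collect_top_copies(
    family: SeedFamily,
    genome,
    n: int = 30,
    s: ScoringScheme | None = None,
    min_identity: float = 60.0,
    min_len: int = 80,
) -> list[RepeatHit]:
    """Best ``n`` genomic copies of a family, by alignment score."""
    hits = batch_search(
        {family.family_id: family.sequence}, genome, s or ScoringScheme(),
        min_identity=min_identity, min_len=min_len,
    )
    if len(hits) < 2:
        log.warning("family %s: %d hit(s); no consensus possible", family.family_id, len(hits))
        return []
    return hits[:n]


@dataclass
class ExtendedCopy:
    """One genomic copy co-oriented with its family, with flank context."""

    seq: str
    elem_start: int  # element interval within seq, 0-based half-open
    elem_end: int
    source: tuple = ()  # (contig, start, end, strand) in genome coordinates

    @property
    def element(self) -> str:
        return self.seq[self.elem_start : self.elem_end]


def extend_flanks(hits: list[RepeatHit], genome: dict[str, str], flank: int = 4000) -> list[ExtendedCopy]:
    """Extract each hit ± ``flank`` bp (truncated at contig ends);
    minus-strand hits are reverse-complemented so all copies co-orient."""
    out = []
    for h in hits:
        contig = genome[h.target_contig]
        ts, te = h.target_span
        lo = max(0, ts - flank)
        hi = min(len(contig), te + flank)
        seq = contig[lo:hi]
        es, ee = ts - lo, te - lo
        if h.strand == "-":
            seq = revcomp(seq)
            es, ee = len(seq) - ee, len(seq) - es
        out.append(ExtendedCopy(seq, es, ee, (h.target_contig, ts, te, h.strand)))
    return out


def trim_nonhomologous_flanks(
    extended: list[ExtendedCopy],
    min_support: int = 2,
    pad: int = 25,
    s: ScoringScheme | None = None,
    min_identity: float = 60.0,
) -> list[ExtendedCopy]:
    """Cut flanks back to the outermost positions aligning to ≥
    ``min_support`` other copies.

    Support is counted per position from all-vs-all local alignments of
    the extended copies and the cut extends outward contiguously from
    the element, so unique flanks are removed while genuinely shared
    sequence (the element itself, or segmental-duplication flanks when
    ``min_support`` allows) is kept. A ``pad`` of residual flank is
    retained on each side so target-site duplications stay available
    for detection downstream.
    """
    if len(extended) < 2:
        raise ValueError("need >= 2 extended copies")
    s = s or ScoringScheme()
    seqs = {f"c{i}": c.seq for i, c in enumerate(extended)}
    hits = batch_search(seqs, seqs, s, min_identity=min_identity, min_len=30)
    support = {k: np.zeros(len(v), dtype=np.int32) for k, v in seqs.items()}
    seen_pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.query_id == h.target_contig:
            continue
        seen_pairs.setdefault((h.query_id, h.target_contig), []).append(h.query_span)
    for (q, _t), spans in seen_pairs.items():
        # each other copy contributes at most 1 unit of support per position
        mask = np.zeros(len(seqs[q]), dtype=bool)
        for qs, qe in spans:
            mask[qs:qe] = True
        support[q] += mask
    out = []
    for i, c in enumerate(extended):
        sup = support[f"c{i}"]
        left = c.elem_start
        while left > 0 and sup[left - 1] >= min_support:
            left -= 1
        right = c.elem_end
        while right < len(c.seq) and sup[right] >= min_support:
            right += 1
        lo = max(0, left - pad)
        hi = min(len(c.seq), right + pad)
        out.append(
            ExtendedCopy(c.seq[lo:hi], c.elem_start - lo, c.elem_end - lo, c.source)
        )
    return out


# ---------------------------------------------------------------------------
# consensus / TSD / classification
# ---------------------------------------------------------------------------


def build_consensus(msa: MSA, min_frac: float = 0.5) -> str:
    """Majority-rule consensus: columns with gap fraction > ``min_frac``
    are dropped; otherwise the plurality base, with ties collapsed to
    the IUPAC code covering the tied bases."""
    if len(msa.rows) < 2:
        raise ValueError("consensus needs >= 2 rows")
    rows = [s for _, s in msa.rows]
    n = len(rows)
    cols = np.array([[c for c in r] for r in rows])
    out = []
    for j in range(cols.shape[1]):
        col = cols[:, j]
        gaps = int((col == GAP).sum())
        if gaps > min_frac * n:
            continue
        counts = {}
        for b in col:
            if b == GAP or b == "N":
                continue
            counts[b] = counts.get(b, 0) + 1
        if not counts:
            continue
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) == 1:
            out.append(tied[0])
        else:
            mask = 0
            for b in tied:
                mask |= IUPAC_MASKS[b]
            out.append(MASK_TO_CODE[mask])
    return "".join(out)


def _ungapped_to_col(row: str) -> np.ndarray:
    """Map ungapped position -> MSA column index for one row."""
    idx = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP))
    return idx


def detect_tsd_and_trim(
    msa: MSA,
    copies: list[ExtendedCopy],
    max_tsd: int = 20,
    wobble: int = 5,
    min_row_frac: float = 0.5,
) -> tuple[MSA, int | None]:
    """Find target-site duplications at the element boundaries and trim
    the MSA to element + TSD.

    Per row and per candidate length ``k`` (longest first), an exact
    repeat is sought with the left copy ending within ``wobble`` bp of
    the left element boundary and the right copy starting within
    ``wobble`` bp of the right boundary. A length is called when its
    row support reaches ``min_row_frac`` *and* clearly exceeds the
    chance rate of an exact k-mer repeat inside the wobble window —
    without that correction, 2–3 bp "TSDs" would be found in almost any
    alignment, since short exact repeats near a fuzzy boundary are
    nearly certain by chance.
    """

    def _row_has_k(seq: str, lb: int, rb: int, k: int) -> bool:
        for dl in range(-wobble, wobble + 1):
            ls = lb + dl - k
            if ls < 0 or lb + dl > len(seq):
                continue
            left = seq[ls : lb + dl]
            for dr in range(-wobble, wobble + 1):
                rs = rb + dr
                if rs < 0 or rs + k > len(seq):
                    continue
                if seq[rs : rs + k] == left:
                    return True
        return False

    ungapped = [
        (row.replace(GAP, ""), copy.elem_start, copy.elem_end)
        for (_rid, row), copy in zip(msa.rows, copies)
    ]
    n_rows = len(ungapped)
    n_offsets = (2 * wobble + 1) ** 2
    tsd_len: int | None = None
    eligible: list[tuple[int, int]] = []  # (k, support)
    for k in range(max_tsd, 1, -1):
        chance = 1.0 - (1.0 - 0.25**k) ** n_offsets
        if chance > 0.6:
            # repeats this short arise by chance in most rows given the
            # boundary uncertainty: below the detection noise floor
            continue
        support = sum(1 for seq, lb, rb in ungapped if _row_has_k(seq, lb, rb, k))
        if support >= max(min_row_frac, chance + 0.25) * n_rows:
            eligible.append((k, support))
    if eligible:
        # a true k-repeat implies (shifted) k−1 support, so support is
        # non-increasing in k; a chance one-base extension of the true
        # TSD shows markedly lower support than the TSD itself — take
        # the largest length whose support is near the maximum
        smax = max(s for _, s in eligible)
        tsd_len = max(k for k, s in eligible if s >= 0.95 * smax)
    keep = tsd_len or 0
    # trim columns outside element +/- TSD
    lo_col = None
    hi_col = None
    for (rid, row), copy in zip(msa.rows, copies):
        colmap = _ungapped_to_col(row)
        lb = max(0, copy.elem_start - keep)
        rb = min(len(colmap), copy.elem_end + keep)
        if rb <= lb:
            continue
        lo = colmap[lb]
        hi = colmap[rb - 1] + 1
        lo_col = lo if lo_col is None else min(lo_col, lo)
        hi_col = hi if hi_col is None else max(hi_col, hi)
    if lo_col is None:
        return msa, tsd_len
    return msa.column_slice(lo_col, hi_col), tsd_len


def _has_tir(consensus: str, term: int = 30, min_len: int = 10, min_ident: float = 80.0) -> bool:
    if len(consensus) < 2 * term:
        term = len(consensus) // 2
    if term < min_len:
        return False
    left = consensus[:term]
    right_rc = revcomp(consensus[-term:])
    hit = local_align_oracle(left, right_rc)
    return len(hit.alignment[0]) >= min_len and hit.percent_identity >= min_ident


def _has_polya(consensus: str, min_a: int = 3) -> bool:
    tail = consensus[-10:]
    return "A" * min_a in tail


def classify_family(
    cf: ConsensusFamily,
    motifs: MotifTable | None = None,
    tsd_rules: dict[int, str] | None = None,
) -> ConsensusFamily:
    """Assign a classification by ordered structural rules.

    1. a motif hit fixes the superfamily;
    2. terminal inverted repeats + a TSD make a DNA transposon, with the
       TSD length refining the superfamily via the rule table;
    3. a 3' poly-A tract + a TSD suggest a LINE;
    4. otherwise Unknown.
    """
    tsd_rules = DEFAULT_TSD_RULES if tsd_rules is None else tsd_rules
    cf.tir = _has_tir(cf.consensus)
    if motifs is not None:
        found = motifs.scan(cf.consensus)
        if found:
            cf.classification = found[0][1]
            return cf
    if cf.tir and cf.tsd_length:
        cf.classification = tsd_rules.get(cf.tsd_length, "DNA/Unknown-TIR")
        return cf
    if _has_polya(cf.consensus) and cf.tsd_length:
        cf.classification = "LINE/Unknown"
        return cf
    cf.classification = "Unknown"
    return cf


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def curate_family(
    family: SeedFamily,
    genome: dict[str, str],
    motifs: MotifTable | None = None,
    n_copies: int = 30,
    flank: int = 4000,
    min_support: int = 2,
    max_tsd: int = 20,
    s: ScoringScheme | None = None,
    msa_method: str = "localpair",
) -> ConsensusFamily | None:
    """Full curation chain for one seed family; None when < 2 copies."""
    s = s or ScoringScheme()
    hits = collect_top_copies(family, genome, n=n_copies, s=s)
    if not hits:
        return None
    copies = extend_flanks(hits, genome, flank=flank)
    copies = trim_nonhomologous_flanks(copies, min_support=min_support, s=s)
    msa = progressive_msa([c.seq for c in copies], method=msa_method)
    msa, tsd_len = detect_tsd_and_trim(msa, copies, max_tsd=max_tsd)
    consensus = build_consensus(msa)
    if not consensus:
        log.warning("family %s: empty consensus", family.family_id)
        return None
    cf = ConsensusFamily(
        family_id=family.family_id,
        consensus=consensus,
        tsd_length=tsd_len,
        n_copies_used=len(copies),
        provenance=[c.source for c in copies],
    )
    return classify_family(cf, motifs)


def curate_library(
    families: list[SeedFamily],
    genome: dict[str, str],
    motifs: MotifTable | None = None,
    exclusion: dict[str, str] | None = None,
    **kwargs,
) -> list[ConsensusFamily]:
    """Purge redundancy, curate every surviving family, and optionally
    screen out consensuses matching an exclusion set (e.g. host genes)
    at ≥ 90% identity."""
    kept = purge_redundant(families)
    out = []
    for fam in kept:
        cf = curate_family(fam, genome, motifs, **kwargs)
        if cf is None:
            continue
        if exclusion:
            bad = batch_search({cf.family_id: cf.consensus}, exclusion,
                               min_identity=90.0, min_len=80)
            if bad:
                log.info("excluded %s: matches exclusion set", cf.family_id)
                continue
        out.append(cf)
    return out
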