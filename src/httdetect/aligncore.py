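"""Pairwise and multiple alignment primitives.

Two alignment routes coexist deliberately:

* :func:`local_align_oracle` — an exact affine-gap Smith–Waterman
  (Gotoh) dynamic program, numba-compiled, used as the ground-truth
  aligner in property tests and for small on-demand alignments
  (terminal-inverted-repeat checks, clustering).
* :func:`seeded_search` — the fast genome-scale search used everywhere a
  genome is scanned, backed by the ``blastn`` executable (discontiguous
  megablast by default, the standard choice for divergent repeat
  detection). Scores and identities of reported hits are recomputed from
  the returned alignment strings under the package's own
  :class:`ScoringScheme`, so the meaning of "percent identity" (matches
  over all alignment columns, gaps included in the denominator) is fixed
  here and not delegated.

Percent-identity convention: matches / total alignment columns × 100,
where gap columns count in the denominator and IUPAC ambiguity codes
count as a match against any compatible base.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seqs import GAP, encode_masks, encode_masks_fast, read_fasta, revcomp, write_fasta

__all__ = [
    "ScoringScheme",
    "RepeatHit",
    "MSA",
    "local_align_oracle",
    "global_align",
    "seeded_search",
    "batch_search",
    "percent_identity",
    "alignment_score",
    "progressive_msa",
    "p_distance_matrix",
    "hits_to_table",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch and affine gap scores plus the seeding word size.

    Defaults are the classic megablast-compatible scheme (+2/−3, gap of
    length k costing 5 + 2k), which keeps the exact DP oracle and the
    blastn-backed search directly comparable.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 11

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")


@dataclass
class RepeatHit:
    """A local alignment of a query (family) against a target sequence.

    Spans are 0-based half-open. ``target_span`` always refers to the
    plus strand of the target; ``strand == '-'`` means the query matched
    the reverse complement of that interval, and ``alignment[1]`` is
    given in query orientation.
    """

    query_id: str
    target_contig: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    score: int
    percent_identity: float
    alignment: tuple[str, str] = field(repr=False, default=("", ""))

    @property
    def query_len(self) -> int:
        return self.query_span[1] - self.query_span[0]

    @property
    def target_len(self) -> int:
        return self.target_span[1] - self.target_span[0]


@dataclass
class MSA:
    """A multiple sequence alignment: rows of (id, aligned string)."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if self.rows:
            n = len(self.rows[0][1])
            if any(len(s) != n for _, s in self.rows):
                raise ValueError("MSA rows must have equal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def ungapped(self, idx: int) -> str:
        return self.rows[idx][1].replace(GAP, "")

    def column_slice(self, start: int, end: int) -> "MSA":
        return MSA([(i, s[start:end]) for i, s in self.rows])


# ---------------------------------------------------------------------------
# exact affine-gap DP (Gotoh), numba-compiled
# ---------------------------------------------------------------------------

_NEG = -(10**9)


@njit(cache=False)
def _gotoh_fill(a, b, match, mismatch, go, ge, local):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    pH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    pE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended
    pF = np.zeros((n + 1, m + 1), np.uint8)
    if not local:
        for j in range(1, m + 1):
            E[0, j] = go + ge * j
            H[0, j] = E[0, j]
            pH[0, j] = 2
            pE[0, j] = 1 if j > 1 else 0
        for i in range(1, n + 1):
            F[i, 0] = go + ge * i
            H[i, 0] = F[i, 0]
            pH[i, 0] = 3
            pF[i, 0] = 1 if i > 1 else 0
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            op = H[i, j - 1] + go + ge
            ex = E[i, j - 1] + ge
            if op >= ex:
                E[i, j] = op
                pE[i, j] = 0
            else:
                E[i, j] = ex
                pE[i, j] = 1
            op = H[i - 1, j] + go + ge
            ex = F[i - 1, j] + ge
            if op >= ex:
                F[i, j] = op
                pF[i, j] = 0
            else:
                F[i, j] = ex
                pF[i, j] = 1
            s = match if (a[i - 1] & b[j - 1]) != 0 else mismatch
            d = H[i - 1, j - 1] + s
            h = d
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if local and h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            pH[i, j] = p
            if local and h > best:
                best = h
                bi = i
                bj = j
    if not local:
        best = H[n, m]
        bi = n
        bj = m
    return pH, pE, pF, best, bi, bj


def _traceback(a: str, b: str, pH, pE, pF, bi: int, bj: int, local: bool):
    i, j = bi, bj
    qa: list[str] = []
    qb: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if i == 0 and j == 0:
                break
            p = pH[i, j]
            if p == 0:  # start of the local alignment
                break
            if p == 1:
                qa.append(a[i - 1])
                qb.append(b[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append(GAP)
            qb.append(b[j - 1])
            came = pE[i, j]
            j -= 1
            state = "E" if came == 1 else "H"
        else:
            qa.append(a[i - 1])
            qb.append(GAP)
            came = pF[i, j]
            i -= 1
            state = "F" if came == 1 else "H"
    return "".join(reversed(qa)), "".join(reversed(qb)), i, j


def local_align_oracle(a: str, b: str, s: ScoringScheme | None = None) -> RepeatHit:
    """Optimal local alignment of ``a`` against ``b`` by exact Gotoh DP.

    Deterministic: score ties are resolved toward the smallest alignment
    end position in row-major (a-then-b) order.
    """
    s = s or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea = encode_masks(a)
    eb = encode_masks(b)
    pH, pE, pF, best, bi, bj = _gotoh_fill(
        ea, eb, s.match, s.mismatch, s.gap_open, s.gap_extend, True
    )
    if best <= 0:
        return RepeatHit("a", "b", (0, 0), (0, 0), "+", 0, 0.0, ("", ""))
    qa, qb, i0, j0 = _traceback(a, b, pH, pE, pF, bi, bj, True)
    pid = percent_identity(qa, qb)
    return RepeatHit("a", "b", (i0, bi), (j0, bj), "+", int(best), pid, (qa, qb))


def global_align(a: str, b: str, s: ScoringScheme | None = None) -> tuple[str, str, int]:
    """End-to-end (Needleman–Wunsch, affine gap) alignment of two strings."""
    s = s or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea = encode_masks(a)
    eb = encode_masks(b)
    pH, pE, pF, best, bi, bj = _gotoh_fill(
        ea, eb, s.match, s.mismatch, s.gap_open, s.gap_extend, False
    )
    qa, qb, _, _ = _traceback(a, b, pH, pE, pF, bi, bj, False)
    return qa, qb, int(best)


# ---------------------------------------------------------------------------
# identity / score on alignment strings
# ---------------------------------------------------------------------------


def percent_identity(aligned_a: str, aligned_b: str | None = None) -> float:
    """Identity of a pairwise alignment: 100 × matches / columns.

    Gap columns count in the denominator; columns gapped in both rows
    (possible when the pair is extracted from a larger MSA) are dropped.
    IUPAC ambiguity codes match any compatible base.
    """
    if aligned_b is None:
        aligned_a, aligned_b = aligned_a  # alignment tuple
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    ma = encode_masks(aligned_a)
    mb = encode_masks(aligned_b)
    keep = (ma > 0) | (mb > 0)
    if not keep.any():
        raise ValueError("alignment has no non-gap columns")
    matches = int(((ma & mb) > 0).sum())
    return 100.0 * matches / int(keep.sum())


def alignment_score(aligned_a: str, aligned_b: str, s: ScoringScheme) -> int:
    """Score of an existing alignment under the scheme (gap = open + k·extend)."""
    ma = encode_masks(aligned_a)
    mb = encode_masks(aligned_b)
    gap_a = ma == 0
    gap_b = mb == 0
    sub = (~gap_a) & (~gap_b)
    matches = int(((ma & mb) > 0)[sub].sum())
    mismatches = int(sub.sum()) - matches
    gaps = gap_a | gap_b
    n_gap_cols = int(gaps.sum())
    # a gap run opens where a gap column follows a non-gap column (or starts)
    n_opens = int((gaps & ~np.concatenate(([False], gaps[:-1]))).sum())
    return (
        matches * s.match
        + mismatches * s.mismatch
        + n_opens * s.gap_open
        + n_gap_cols * s.gap_extend
    )


# ---------------------------------------------------------------------------
# seeded genome search (blastn)
# ---------------------------------------------------------------------------

_BLAST_FIELDS = "qseqid sseqid qstart qend sstart send qseq sseq"


def _require(tool: str) -> str:
    path = shutil.which(tool)
    if path is None:
        raise RuntimeError(f"required executable not found on PATH: {tool}")
    return path


def _as_fasta_path(seqs, tmpdir: str, name: str) -> str:
    if isinstance(seqs, (str, os.PathLike)) and os.path.exists(str(seqs)):
        return str(seqs)
    path = os.path.join(tmpdir, name)
    if isinstance(seqs, str):
        write_fasta({"query": seqs}, path)
    else:
        write_fasta(seqs, path)
    return path


def batch_search(
    queries: dict[str, str] | str,
    genome,
    s: ScoringScheme | None = None,
    min_identity: float = 0.0,
    min_len: int = 1,
    task: str = "dc-megablast",
    evalue: float = 1e-4,
    max_hits_per_query: int | None = None,
) -> list[RepeatHit]:
    """Run blastn for one or many queries against a genome (path or dict).

    Hits are filtered on recomputed identity (≥ ``min_identity``) and
    aligned query length (≥ ``min_len``), and sorted by score descending
    with deterministic ties (contig, target start, '+' before '−').
    """
    s = s or ScoringScheme()
    blastn = _require("blastn")
    if isinstance(queries, str) and not os.path.exists(queries):
        queries = {"query": queries}
    with tempfile.TemporaryDirectory(prefix="httdetect_blast_") as tmp:
        qpath = _as_fasta_path(queries, tmp, "query.fa")
        spath = _as_fasta_path(genome, tmp, "subject.fa")
        # an indexed database is much faster for genome-scale subjects;
        # plain -subject avoids the indexing cost for small ones
        if os.path.getsize(spath) > 500_000:
            makeblastdb = _require("makeblastdb")
            db = os.path.join(tmp, "subject_db")
            res = subprocess.run(
                [makeblastdb, "-in", spath, "-dbtype", "nucl", "-out", db],
                capture_output=True, text=True,
            )
            if res.returncode != 0:
                raise RuntimeError(f"makeblastdb failed: {res.stderr.strip()}")
            target_args = ["-db", db]
        else:
            target_args = ["-subject", spath]
        cmd = [
            blastn,
            "-task",
            task,
            "-query",
            qpath,
            *target_args,
            "-outfmt",
            f"6 {_BLAST_FIELDS}",
            "-dust",
            "no",
            "-soft_masking",
            "false",
            "-evalue",
            str(evalue),
            "-max_target_seqs",
            "5000",
        ]
        if min_identity > 2:
            # pre-filter inside blast (same identity convention); final
            # filtering still uses the recomputed identity below
            cmd += ["-perc_identity", str(max(0.0, min_identity - 2))]
        if task == "blastn":
            cmd += ["-word_size", str(s.word_size)]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"blastn failed: {res.stderr.strip()}")
        out = res.stdout
    hits: list[RepeatHit] = []
    for line in out.splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 8:
            continue
        qid, sid, qstart, qend, sstart, send, qseq, sseq = parts
        qs, qe = int(qstart) - 1, int(qend)
        ss, se = int(sstart), int(send)
        if ss <= se:
            strand = "+"
            tspan = (ss - 1, se)
        else:
            strand = "-"
            tspan = (se - 1, ss)
        qseq = qseq.upper()
        sseq = sseq.upper()
        pid = percent_identity(qseq, sseq)
        score = alignment_score(qseq, sseq, s)
        if score <= 0:
            continue
        if pid < min_identity or (qe - qs) < min_len:
            continue
        hits.append(RepeatHit(qid, sid, (qs, qe), tspan, strand, score, pid, (qseq, sseq)))
    hits.sort(
        key=lambda h: (
            -h.score,
            h.query_id,
            h.target_contig,
            h.target_span[0],
            0 if h.strand == "+" else 1,
        )
    )
    if max_hits_per_query is not None:
        kept: list[RepeatHit] = []
        counts: dict[str, int] = {}
        for h in hits:
            c = counts.get(h.query_id, 0)
            if c < max_hits_per_query:
                kept.append(h)
                counts[h.query_id] = c + 1
        hits = kept
    return hits


def seeded_search(
    query: str,
    genome,
    s: ScoringScheme | None = None,
    min_identity: float = 0.0,
    min_len: int = 1,
    **kwargs,
) -> list[RepeatHit]:
    """Search one query sequence against a genome on both strands."""
    s = s or ScoringScheme()
    if len(query) < s.word_size:
        raise ValueError("query shorter than the seeding word size")
    return batch_search({"query": query}, genome, s, min_identity, min_len, **kwargs)


def hits_to_table(hits: list[RepeatHit]):
    """Hits as a pandas DataFrame in a documented column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "target_contig": h.target_contig,
                "query_start": h.query_span[0],
                "query_end": h.query_span[1],
                "target_start": h.target_span[0],
                "target_end": h.target_span[1],
                "strand": h.strand,
                "score": h.score,
                "percent_identity": round(h.percent_identity, 2),
            }
            for h in hits
        ],
        columns=[
            "query_id",
            "target_contig",
            "query_start",
            "query_end",
            "target_start",
            "target_end",
            "strand",
            "score",
            "percent_identity",
        ],
    )


# ---------------------------------------------------------------------------
# multiple alignment (mafft) and p-distances
# ---------------------------------------------------------------------------


def progressive_msa(seqs: list[str], ids: list[str] | None = None, method: str = "localpair") -> MSA:
    """Multiple alignment of ≥ 2 sequences via MAFFT (single-threaded).

    ``method='localpair'`` reproduces the L-INS style pairwise-local
    guide alignments used for repeat curation; ``method='fast'`` uses
    the quicker FFT-NS-2 strategy for large batch jobs.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    mafft = _require("mafft")
    args = {"localpair": ["--localpair"], "fast": ["--retree", "2"]}[method]
    with tempfile.TemporaryDirectory(prefix="httdetect_mafft_") as tmp:
        inpath = os.path.join(tmp, "in.fa")
        # positional ids keep mafft happy with arbitrary characters in names
        write_fasta([(f"r{i}", s) for i, s in enumerate(seqs)], inpath)
        res = subprocess.run(
            [mafft, "--thread", "1", "--quiet", *args, inpath],
            capture_output=True,
            text=True,
        )
        if res.returncode != 0:
            raise RuntimeError(f"mafft failed: {res.stderr.strip()}")
    aligned: dict[str, list[str]] = {}
    current = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            aligned[current] = []
        elif current is not None:
            aligned[current].append(line.strip())
    rows = [(ids[i], "".join(aligned[f"r{i}"]).upper()) for i in range(len(seqs))]
    return MSA(rows)


def p_distance_matrix(msa: MSA) -> np.ndarray:
    """Pairwise p-distances over shared non-gap columns; NaN if none shared."""
    n = len(msa.rows)
    enc = np.vstack([encode_masks_fast(s) for _, s in msa.rows])
    nongap = enc > 0
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            total = int(shared.sum())
            if total == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            matches = int(((enc[i] & enc[j]) > 0)[shared].sum())
            d[i, j] = d[j, i] = 1.0 - matches / total
    return d
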