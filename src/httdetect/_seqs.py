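"""Low-level DNA sequence utilities shared across the package.

Sequences are plain Python strings over the IUPAC nucleotide alphabet.
Internally, alignment and identity computations encode bases as 4-bit
masks (A=1, C=2, G=4, T=8; ambiguity codes are unions) so that an IUPAC
code is counted as matching any base it is compatible with.
"""

from __future__ import annotations

import numpy as np

IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

# reverse lookup: bitmask -> canonical IUPAC code
MASK_TO_CODE = {v: k for k, v in IUPAC_MASKS.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

GAP = "-"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_masks(seq: str) -> np.ndarray:
    """Encode a sequence as an array of 4-bit base masks (gap/unknown -> 0)."""
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq.upper()):
        out[i] = IUPAC_MASKS.get(c, 0)
    return out


_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASKS.items():
    _ENCODE_LUT[ord(_c)] = _m
    _ENCODE_LUT[ord(_c.lower())] = _m


def encode_masks_fast(seq: str) -> np.ndarray:
    """Vectorised mask encoding for long sequences."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """An i.i.d. random DNA string with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def seq_to_indices(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(seq), 4, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        out[raw == ord(b)] = i
    return out


def indices_to_seq(idx: np.ndarray) -> str:
    return _BASES[np.asarray(idx, dtype=np.uint8)].tobytes().decode("ascii")


def read_fasta(path) -> dict:
    """Read a (multi-)FASTA file into an ordered {id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records, path, width: int = 60) -> None:
    """Write {id: seq} pairs (dict or iterable of tuples) as wrapped FASTA."""
    items = records.items() if hasattr(records, "items") else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
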