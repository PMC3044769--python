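"""Small sequence helpers: RNA normalization, complements, FASTA reading."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

__all__ = ["normalize_rna", "reverse_complement", "read_fasta", "can_pair", "is_wc", "is_gu"]

_RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

_WC = {"AU", "UA", "CG", "GC"}
_GU = {"GU", "UG"}
_CANONICAL = _WC | _GU


def normalize_rna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the RNA alphabet."""
    out = seq.strip().upper().replace("T", "U")
    bad = set(out) - _RNA
    if bad:
        raise ValueError(f"{name} contains non-RNA characters: {sorted(bad)}")
    return out


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def can_pair(a: str, b: str) -> bool:
    return a + b in _CANONICAL


def is_wc(a: str, b: str) -> bool:
    return a + b in _WC


def is_gu(a: str, b: str) -> bool:
    return a + b in _GU


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: normalized RNA sequence} dict."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = normalize_rna(str(rec.seq), name=rec.id)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records
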