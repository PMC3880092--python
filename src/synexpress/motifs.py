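"""Promoter extraction and exact IUPAC consensus scanning.

Promoter windows of +/- 2 kb around each strand-aware TSS are pulled from an
indexed genome FASTA and scanned on both strands for matches to a degenerate
consensus such as the Stat6 palindrome TTCNNNNGAA.  Matching is positional:
each pattern symbol's IUPAC class must contain the sequence base, with an
optional mismatch allowance (0 by default).  A sequence base ``N`` is treated
as unknown and matches only the pattern symbol ``N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",  # pattern N accepts anything, including unknown bases
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifPattern:
    pattern: str = "TTCNNNNGAA"
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC)
        if bad or not pat:
            raise ValueError(f"invalid IUPAC pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based match start on the forward strand
    strand: str  # "+" or "-" ("+" when a palindrome matches both)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _match_offsets(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Forward-strand 0-based offsets where the pattern matches the sequence."""
    m = len(pattern)
    n = len(seq)
    if n < m:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    mismatches = np.zeros(n - m + 1, dtype=np.int32)
    for j, sym in enumerate(pattern.pattern):
        allowed = np.zeros(256, dtype=bool)
        for base in IUPAC[sym]:
            allowed[ord(base)] = True
        mismatches += ~allowed[arr[j : j + n - m + 1]]
    return np.flatnonzero(mismatches <= pattern.max_mismatches)


def scan_iupac(
    sequence: str,
    pattern: MotifPattern | str = MotifPattern(),
    strands: str = "both",
    sequence_id: str = "",
) -> list[MotifHit]:
    """All matches of an IUPAC consensus in a sequence.

    Reverse-strand matches (the pattern's reverse complement read on the
    forward strand) are reported at their forward-strand offset; a position
    matching on both strands — as every position of a palindromic consensus
    does — is reported once, on "+".
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    if strands not in {"both", "+", "-"}:
        raise ValueError("strands must be 'both', '+' or '-'")
    fwd: set[int] = set()
    rev: set[int] = set()
    if strands in {"both", "+"}:
        fwd = set(_match_offsets(sequence, pattern).tolist())
    if strands in {"both", "-"}:
        rc_pat = MotifPattern(
            reverse_complement(pattern.pattern), pattern.max_mismatches
        )
        rev = set(_match_offsets(sequence, rc_pat).tolist())
    hits = [
        MotifHit(sequence_id, off, "+" if off in fwd else "-")
        for off in sorted(fwd | rev)
    ]
    return hits


def promoter_windows(
    models, genome: str | Path | Fasta, flank: int = 2000
) -> dict[str, str]:
    """Per-gene promoter sequence: ``flank`` bp either side of the TSS.

    ``models`` is the gene-model table from
    :func:`~synexpress.peaks.read_gene_models`.  Windows are clipped to
    chromosome bounds (logged) and reported 5'->3' on the gene's strand
    (reverse-complemented for "-" genes).  Genes on chromosomes missing from
    the FASTA are skipped with a log message.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    windows: dict[str, str] = {}
    for _, gene in models.iterrows():
        chrom = gene["chrom"]
        if chrom not in fasta:
            logger.warning("gene %s: chromosome %s not in FASTA; skipped", gene["symbol"], chrom)
            continue
        length = len(fasta[chrom])
        lo = max(0, int(gene["tss"]) - flank)
        hi = min(length, int(gene["tss"]) + flank)
        if hi - lo < 2 * flank:
            logger.info("gene %s: promoter window clipped to [%d, %d)", gene["symbol"], lo, hi)
        seq = str(fasta[chrom][lo:hi]).upper()
        if gene["strand"] == "-":
            seq = reverse_complement(seq)
        windows[gene["symbol"]] = seq
    return windows


def hits_to_bed_rows(
    hits: Iterable[MotifHit], pattern: MotifPattern
) -> list[tuple[str, int, int, str, str, str]]:
    """BED6 rows (id, start, end, pattern, '.', strand) for motif hits."""
    m = len(pattern)
    return [
        (h.sequence_id, h.offset, h.offset + m, pattern.pattern, ".", h.strand)
        for h in hits
    ]
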