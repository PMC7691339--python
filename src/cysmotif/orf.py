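"""Six-frame stop-to-stop ORF extraction.

A lightweight stand-in for a full coding-region predictor: every maximal
stop-to-stop interval in all six reading frames is reported, optionally
trimmed to the first ATG, filtered by a minimum protein length (in
residues), and sorted longest-first.  ORFs running off a sequence end
without a stop are reported and flagged (fragmentary transcripts are common
in de novo assemblies).  Homology-based retention is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from Bio.Seq import Seq

from .records import SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

_FRAME_ORDER = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}


@dataclass(frozen=True)
class OrfRecord:
    source_id: str
    frame: int                # +1 +2 +3 -1 -2 -3
    nt_start: int             # 0-based half-open, forward strand
    nt_end: int
    protein: SequenceRecord
    has_start_codon: bool
    has_stop_codon: bool      # False for ORFs running off the sequence end

    def __post_init__(self):
        assert (self.nt_end - self.nt_start) % 3 == 0


def _revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _translate(codon_str: str) -> str:
    # Ambiguity (N) translates to X unless the codon is unambiguous.
    return str(Seq(codon_str).translate())


def find_orfs(dna: SequenceRecord, min_len: int = 100,
              require_start: bool = False) -> List[OrfRecord]:
    """All maximal six-frame ORFs with protein length >= ``min_len``.

    With ``require_start`` each stop-to-stop interval is trimmed to its
    first ATG (intervals without one are dropped) before re-filtering.
    Result is sorted by descending protein length, ties broken by frame
    (+1,+2,+3,-1,-2,-3) then by nt_start, both ascending.
    """
    if dna.alphabet != "dna":
        raise ValueError(f"find_orfs needs a DNA record, got {dna.alphabet!r}")
    seq = dna.residues
    L = len(seq)
    results: List[OrfRecord] = []

    for strand, s in ((1, seq), (-1, _revcomp(seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            n_codons = (L - offset) // 3
            if n_codons == 0:
                continue
            aa = _translate(s[offset:offset + 3 * n_codons])
            # split stop-to-stop; track codon index ranges
            start_codon = 0
            segments = []
            for ci, ch in enumerate(aa):
                if ch == "*":
                    segments.append((start_codon, ci, True))
                    start_codon = ci + 1
            if start_codon < n_codons:
                segments.append((start_codon, n_codons, False))

            for c0, c1, has_stop in segments:
                prot = aa[c0:c1]
                if require_start:
                    m = prot.find("M")
                    if m < 0:
                        continue
                    c0 += m
                    prot = prot[m:]
                if len(prot) < min_len or not prot:
                    continue
                # codon span on this strand's coordinates (incl. stop codon)
                nt0 = offset + 3 * c0
                nt1 = offset + 3 * (c1 + (1 if has_stop else 0))
                if strand == 1:
                    nt_start, nt_end = nt0, nt1
                else:
                    nt_start, nt_end = L - nt1, L - nt0
                results.append(OrfRecord(
                    source_id=dna.id,
                    frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    protein=SequenceRecord(
                        id=f"{dna.id}|{frame:+d}:{nt_start}-{nt_end}",
                        residues=prot,
                        description=f"ORF frame {frame:+d}",
                        alphabet="protein",
                    ),
                    has_start_codon=prot.startswith("M") and (
                        s[offset + 3 * c0: offset + 3 * c0 + 3] == "ATG"),
                    has_stop_codon=has_stop,
                ))

    results.sort(key=lambda o: (-len(o.protein.residues),
                                _FRAME_ORDER[o.frame], o.nt_start))
    return results


def longest_orf(dna: SequenceRecord, min_len: int = 100,
                require_start: bool = False) -> Optional[OrfRecord]:
    """The top-ranked ORF of :func:`find_orfs`, or ``None`` when empty."""
    orfs = find_orfs(dna, min_len=min_len, require_start=require_start)
    return orfs[0] if orfs else None
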