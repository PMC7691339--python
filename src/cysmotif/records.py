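"""Core domain types: sequence records and run configuration.

Every coordinate in this package is 0-based, half-open.  The conserved-Cys
scaffold patterns are usually quoted in the literature in 1-based prose
(``C1-X23-44-C2-...``); the spacer ("gap") counts are identical in both
conventions, only anchor indices shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .alphabet import DNA_ALPHABET, PROTEIN_ALPHABET

Alphabet = Literal["protein", "dna"]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide sequence.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier (the FASTA header token before the
        first whitespace).
    residues : str
        Upper-case residues over the declared alphabet; ``X``/``N`` are
        allowed as unknowns.
    description : str
        Free-text remainder of the FASTA header.
    alphabet : {"protein", "dna"}
    """

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = "protein"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        residues = self.residues.upper()
        if residues != self.residues:
            object.__setattr__(self, "residues", residues)
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(residues):
            if ch not in allowed:
                raise ValueError(
                    f"sequence {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def check_unique_ids(records) -> None:
    """Raise ``ValueError`` naming the first duplicated record id, if any."""
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)


@dataclass
class RunConfig:
    """Per-family analysis parameters.

    Defaults follow the study conditions this pipeline reproduces: soluble
    families (OBP/CSP) are mined for up to 8 motifs of width 6-10, the
    membrane family (SNMP) for up to 10 motifs of width 45-95, and motifs
    are retained at p < 1e-4.  ``orf_min_len`` is in residues (codons).
    """

    family: Literal["obp", "csp", "snmp"] = "obp"
    orf_min_len: int = 100
    motif_minw: int = 6
    motif_maxw: int = 10
    motif_n: int = 8
    motif_p_threshold: float = 1e-4
    seed: int = 0
    tm_window: int = 19
    tm_threshold: float = 1.6
    min_loop: int = 100
    plus_c_min_extra_cys: int = 7

    def __post_init__(self):
        if self.family == "snmp" and (self.motif_minw, self.motif_maxw, self.motif_n) == (6, 10, 8):
            # family-specific discovery defaults
            self.motif_minw, self.motif_maxw, self.motif_n = 45, 95, 10
        if self.motif_minw > self.motif_maxw:
            raise ValueError("motif_minw must be <= motif_maxw")
        if self.motif_n < 1:
            raise ValueError("motif_n must be >= 1")
        if not (0.0 < self.motif_p_threshold < 1.0):
            raise ValueError("motif_p_threshold must be in (0, 1)")
        if self.orf_min_len < 1:
            raise ValueError("orf_min_len must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)
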