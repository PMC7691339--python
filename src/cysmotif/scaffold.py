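"""Scaffold matching, OBP/CSP subclass calls, and the hydropathy TM screen.

The subclass rules implement the family definitions used throughout the
insect chemosensory literature:

* plus-C:  classic six-Cys scaffold match AND at least ``min_extra_cys``
  further cysteines downstream of C6 AND a proline after the last of them;
* classic: classic scaffold match without the plus-C extension;
* minus-C: match to the derived four-anchor scaffold (C2 and C5 absent)
  and no classic match;
* CSP:     match to the four-Cys CSP scaffold.

Precedence plus-C > classic > minus-C makes the calls mutually exclusive: a
classic match always embeds a minus-C-compatible cysteine subset.

SNMP-like topology is screened with a sliding Kyte-Doolittle hydropathy
window: an in-house stand-in for a dedicated transmembrane predictor, kept
deliberately simple (two terminal hydrophobic segments separated by a long
loop is the family's CD36-like layout).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .alphabet import KYTE_DOOLITTLE
from .patterns import (BUILTIN_PATTERNS, Extras, PLUSC_EXTRAS, ScaffoldMatch,
                       ScaffoldPattern)
from .records import SequenceRecord


@dataclass(frozen=True)
class TmSegment:
    """A candidate transmembrane segment: the union of consecutive windows
    whose mean hydropathy reaches the threshold."""

    start: int
    end: int
    mean_hydropathy: float


@dataclass
class SubclassCall:
    sequence_id: str
    family: str            # obp | csp | snmp | unclassified
    subclass: str          # classic | minus-C | plus-C | "-"
    evidence: List[Union[ScaffoldMatch, TmSegment]] = field(default_factory=list)
    total_cys: int = 0


def match_scaffold(seq: SequenceRecord, pattern: ScaffoldPattern) -> List[ScaffoldMatch]:
    """All placements of ``pattern`` in ``seq``, in lexicographic order of
    anchor-position tuples; empty when none."""
    residues = seq.residues
    # anchor residue -> sorted positions
    pos_by_res = {}
    for a in pattern.anchors:
        if a.residue not in pos_by_res:
            pos_by_res[a.residue] = [i for i, ch in enumerate(residues) if ch == a.residue]

    matches: List[ScaffoldMatch] = []
    anchors = pattern.anchors
    n = len(anchors)

    def extend(idx: int, chosen: List[int]) -> None:
        if idx == n:
            matches.append(ScaffoldMatch(pattern.name, tuple(chosen)))
            return
        a = anchors[idx]
        positions = pos_by_res[a.residue]
        if idx == 0:
            for p in positions:
                extend(1, [p])
            return
        prev = chosen[-1]
        lo, hi = prev + 1 + a.gap_min, prev + 1 + a.gap_max
        i = bisect_left(positions, lo)
        while i < len(positions) and positions[i] <= hi:
            chosen.append(positions[i])
            extend(idx + 1, chosen)
            chosen.pop()
            i += 1

    extend(0, [])
    return matches


def _has_plusc_extension(residues: str, c6_pos: int, extras: Extras) -> bool:
    tail = residues[c6_pos + 1:]
    extra_positions = [c6_pos + 1 + i for i, ch in enumerate(tail) if ch == extras.residue]
    if len(extra_positions) < extras.min_extra:
        return False
    if extras.trailing_residue is None:
        return True
    last = extra_positions[-1]
    return extras.trailing_residue in residues[last + 1:]


def classify_obp(
    seq: SequenceRecord,
    classic: Optional[ScaffoldPattern] = None,
    minusc: Optional[ScaffoldPattern] = None,
    extras: Optional[Extras] = None,
) -> SubclassCall:
    """Call the OBP subclass of a protein (plus-C > classic > minus-C)."""
    classic = classic or BUILTIN_PATTERNS["classic_obp"]
    minusc = minusc or BUILTIN_PATTERNS["minusc_obp"]
    extras = extras or PLUSC_EXTRAS
    total_cys = seq.residues.count("C")

    classic_matches = match_scaffold(seq, classic)
    if classic_matches:
        plusc = [m for m in classic_matches
                 if _has_plusc_extension(seq.residues, m.anchor_positions[-1], extras)]
        if plusc:
            return SubclassCall(seq.id, "obp", "plus-C", plusc, total_cys)
        return SubclassCall(seq.id, "obp", "classic", classic_matches, total_cys)

    minus_matches = match_scaffold(seq, minusc)
    if minus_matches:
        return SubclassCall(seq.id, "obp", "minus-C", minus_matches, total_cys)
    return SubclassCall(seq.id, "unclassified", "-", [], total_cys)


def classify_csp(seq: SequenceRecord,
                 pattern: Optional[ScaffoldPattern] = None) -> SubclassCall:
    pattern = pattern or BUILTIN_PATTERNS["csp"]
    matches = match_scaffold(seq, pattern)
    total_cys = seq.residues.count("C")
    if matches:
        return SubclassCall(seq.id, "csp", "-", matches, total_cys)
    return SubclassCall(seq.id, "unclassified", "-", [], total_cys)


def hydropathy_profile(seq: SequenceRecord, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy per window start.

    Returns a vector of length ``len(seq) - window + 1``; ``window`` must be
    odd and no longer than the sequence.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    values = np.array([KYTE_DOOLITTLE[ch] for ch in seq.residues], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tm_segments(seq: SequenceRecord, window: int = 19,
                        threshold: float = 1.6) -> List[TmSegment]:
    """Maximal runs of window starts with mean hydropathy >= threshold,
    merged when their windows overlap; each run becomes one segment spanning
    the union of its windows."""
    profile = hydropathy_profile(seq, window)
    above = profile >= threshold
    runs: List[List[int]] = []      # [start, end) spans of window unions
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        span = [i, j + window]
        if runs and span[0] < runs[-1][1]:   # window spans overlap: merge
            runs[-1][1] = span[1]
        else:
            runs.append(span)
        i = j + 1
    segments: List[TmSegment] = []
    for a, b in runs:
        vals = profile[a:b - window + 1]
        segments.append(TmSegment(a, b, float(vals[vals >= threshold].mean())))
    return segments


def classify_snmp(seq: SequenceRecord, window: int = 19, threshold: float = 1.6,
                  min_loop: int = 100) -> SubclassCall:
    """SNMP-like topology call: exactly two TM segments, one starting in the
    N-terminal quarter and one ending in the C-terminal quarter, separated
    by a loop of at least ``min_loop`` residues.

    The SNMP1/SNMP2 subfamily split is not called here; in the literature it
    is resolved by phylogeny, not by a sequence rule.
    """
    total_cys = seq.residues.count("C")
    segments = predict_tm_segments(seq, window, threshold)
    L = len(seq)
    if len(segments) == 2:
        first, second = segments
        loop = second.start - first.end
        if (first.start <= L / 4 and second.end >= 3 * L / 4 and loop >= min_loop):
            return SubclassCall(seq.id, "snmp", "-", list(segments), total_cys)
    return SubclassCall(seq.id, "unclassified", "-", [], total_cys)
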