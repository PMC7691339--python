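"""Per-sequence motif fingerprints and frequency-ranked pattern groups.

A fingerprint is the ordered (left-to-right) list of motifs present in a
sequence; sequences sharing an identical ordered list form one numbered
pattern, ranked by descending membership (``1c``, ``2c``, ... with a family
suffix).  Motif identity is the discovery rank within a run; comparison
across runs should go through consensus strings instead.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Dict, List, Sequence

from .motifs import MotifModel, MotifOccurrence
from .records import SequenceRecord


@dataclass(frozen=True)
class Fingerprint:
    sequence_id: str
    ordered_motifs: tuple          # motif ids sorted by occurrence start

    def __iter__(self):
        return iter(self.ordered_motifs)


@dataclass
class PatternGroup:
    pattern_id: str                # e.g. "3c"
    ordered_motifs: tuple
    member_ids: List[str]
    count: int
    fraction: float


def resolve_overlaps(occurrences: Sequence[MotifOccurrence],
                     widths: Dict[int, int]) -> List[MotifOccurrence]:
    """Greedy cross-motif overlap resolution for one sequence: keep
    occurrences by descending score per column (so a wide weak match cannot
    displace a compact high-information one), dropping any that overlap a
    kept occurrence.  ``widths`` maps motif id -> width."""
    kept: List[MotifOccurrence] = []
    spans: List[tuple] = []
    for occ in sorted(occurrences,
                      key=lambda o: (-o.score / widths[o.motif_id], o.start, o.motif_id)):
        a, b = occ.start, occ.start + widths[occ.motif_id]
        if any(a < e and s < b for s, e in spans):
            continue
        kept.append(occ)
        spans.append((a, b))
    kept.sort(key=lambda o: o.start)
    return kept


def build_fingerprint(record: SequenceRecord,
                      occurrences: Sequence[MotifOccurrence],
                      widths: Dict[int, int] | None = None) -> Fingerprint:
    """Fingerprint of one record from its (non-overlapping) occurrences.

    A motif occurring more than once keeps only its best-scoring occurrence
    (zero-or-one semantics).  Overlapping occurrences raise ``ValueError``;
    the scanner guarantees non-overlap within a motif and
    :func:`resolve_overlaps` across motifs.
    """
    occs = [o for o in occurrences if o.sequence_id == record.id]
    if len(occs) != len(list(occurrences)):
        raise ValueError(f"occurrences do not all belong to record {record.id!r}")
    # ZOOPS: best occurrence per motif
    best: Dict[int, MotifOccurrence] = {}
    for o in occs:
        if o.motif_id not in best or o.score > best[o.motif_id].score:
            best[o.motif_id] = o
    chosen = sorted(best.values(), key=lambda o: o.start)
    if widths is not None:
        for a, b in zip(chosen, chosen[1:]):
            if a.start + widths[a.motif_id] > b.start:
                raise ValueError(
                    f"overlapping occurrences at {a.start} and {b.start} "
                    f"in record {record.id!r}")
    return Fingerprint(record.id, tuple(o.motif_id for o in chosen))


def group_patterns(fingerprints: Sequence[Fingerprint],
                   family_suffix: str = "") -> List[PatternGroup]:
    """Group identical ordered motif lists into numbered patterns.

    Ids are ``1<suffix>``, ``2<suffix>``, ... by descending count, ties by
    first-member input order; fractions sum to 1 over all groups.
    """
    ids = [fp.sequence_id for fp in fingerprints]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    buckets: "OrderedDict[tuple, List[str]]" = OrderedDict()
    for fp in fingerprints:
        buckets.setdefault(fp.ordered_motifs, []).append(fp.sequence_id)
    total = len(fingerprints)
    ranked = sorted(buckets.items(),
                    key=lambda kv: (-len(kv[1]), list(buckets).index(kv[0])))
    return [
        PatternGroup(f"{r}{family_suffix}", motifs, members, len(members),
                     len(members) / total)
        for r, (motifs, members) in enumerate(ranked, start=1)
    ]


def prevalence_table(motifs: Sequence[MotifModel],
                     fingerprints: Sequence[Fingerprint]) -> Dict[int, float]:
    """Fraction of fingerprints containing each motif id."""
    n = len(fingerprints)
    out: Dict[int, float] = {}
    for m in motifs:
        if n == 0:
            out[m.id] = 0.0
        else:
            out[m.id] = sum(m.id in fp.ordered_motifs for fp in fingerprints) / n
    return out
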