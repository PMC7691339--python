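"""End-to-end analysis: classify, discover motifs, scan, fingerprint, group.

The per-family pipeline mirrors the analysis this package reproduces: a
family set of proteins is classified against the conserved-Cys scaffolds
(or the TM-topology screen for SNMP-like proteins), mined for ungapped
motifs, each accepted motif is scanned back over the unmasked sequences,
per-sequence fingerprints are built, and identical fingerprints are grouped
into frequency-ranked motif patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .fingerprint import (Fingerprint, PatternGroup, build_fingerprint,
                          group_patterns, prevalence_table, resolve_overlaps)
from .motifs import MotifModel, MotifOccurrence, discover_motifs, scan_motif
from .records import RunConfig, SequenceRecord
from .scaffold import SubclassCall, classify_csp, classify_obp, classify_snmp

FAMILY_SUFFIX = {"obp": "c", "csp": "", "snmp": ""}


@dataclass
class PipelineResult:
    records: List[SequenceRecord]
    calls: List[SubclassCall]
    motifs: List[MotifModel]
    occurrences: List[MotifOccurrence]
    fingerprints: List[Fingerprint]
    groups: List[PatternGroup]
    prevalence: Dict[int, float]


def classify_family(records: Sequence[SequenceRecord], config: RunConfig
                    ) -> List[SubclassCall]:
    if config.family == "obp":
        return [classify_obp(r) for r in records]
    if config.family == "csp":
        return [classify_csp(r) for r in records]
    return [classify_snmp(r, config.tm_window, config.tm_threshold,
                          config.min_loop) for r in records]


def scan_and_fingerprint(records: Sequence[SequenceRecord],
                         motifs: Sequence[MotifModel],
                         threshold_bits: Optional[float] = None):
    """Scan every motif over every record, resolve cross-motif overlaps, and
    build one fingerprint per record."""
    widths = {m.id: m.width for m in motifs}
    occurrences: List[MotifOccurrence] = []
    fingerprints: List[Fingerprint] = []
    for rec in records:
        occs = []
        for m in motifs:
            occs.extend(scan_motif(m, rec, threshold_bits))
        occs = resolve_overlaps(occs, widths)
        occurrences.extend(occs)
        fingerprints.append(build_fingerprint(rec, occs, widths))
    return occurrences, fingerprints


def run_family_pipeline(records: Sequence[SequenceRecord], config: RunConfig,
                        pattern_suffix: Optional[str] = None,
                        **discover_kwargs) -> PipelineResult:
    calls = classify_family(records, config)
    motifs = discover_motifs(
        records, config.motif_minw, config.motif_maxw, config.motif_n,
        p_threshold=config.motif_p_threshold, seed=config.seed,
        **discover_kwargs)
    occurrences, fingerprints = scan_and_fingerprint(records, motifs)
    suffix = pattern_suffix if pattern_suffix is not None else FAMILY_SUFFIX.get(config.family, "")
    groups = group_patterns(fingerprints, suffix)
    prevalence = prevalence_table(motifs, fingerprints)
    return PipelineResult(list(records), calls, motifs, occurrences,
                          fingerprints, groups, prevalence)


def match_motif_to_consensus(motifs: Sequence[MotifModel], consensus: str,
                             min_identity: float = 0.8) -> Optional[MotifModel]:
    """The discovered motif best matching a known consensus.

    Identity is the best fraction of matching positions over all ungapped
    alignments of the motif consensus against the target, normalized by the
    shorter of the two; returns None below ``min_identity``.
    """
    best_model, best_ident = None, 0.0
    for m in motifs:
        ident = consensus_identity(m.consensus, consensus)
        if ident > best_ident:
            best_model, best_ident = m, ident
    if best_ident >= min_identity:
        return best_model
    return None


def consensus_identity(a: str, b: str) -> float:
    """Best ungapped-alignment identity between two consensus strings.

    All lags with an overlap of at least half the shorter string are
    considered; identity is matches over the overlap length.
    """
    if not a or not b:
        return 0.0
    min_overlap = max(3, min(len(a), len(b)) // 2)
    best = 0.0
    for lag in range(-(len(a) - min_overlap), len(b) - min_overlap + 1):
        seg_a = a[max(0, -lag): len(a) if lag + len(a) <= len(b) else len(b) - lag]
        seg_b = b[max(0, lag): max(0, lag) + len(seg_a)]
        if len(seg_a) < min_overlap:
            continue
        best = max(best, sum(x == y for x, y in zip(seg_a, seg_b)) / len(seg_a))
    return best
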