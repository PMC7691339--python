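"""Scaffold matching vs brute force, subclass calls, hydropathy TM screen."""

from itertools import combinations

import numpy as np
import pytest

from cysmotif.patterns import (Anchor, BUILTIN_PATTERNS, Extras,
                               ScaffoldPattern, derive_minus_pattern)
from cysmotif.records import SequenceRecord
from cysmotif.scaffold import (classify_csp, classify_obp, classify_snmp,
                               hydropathy_profile, match_scaffold,
                               predict_tm_segments)
from cysmotif.synthetic import (FamilySpec, generate_family_set,
                                make_classic_obp_set, make_csp_set,
                                make_minusc_obp_set, make_snmp_set)

from conftest import random_protein


def _brute_force_matches(seq: str, pattern: ScaffoldPattern):
    """Oracle: enumerate every combination of anchor-residue positions and
    filter by the gap bounds."""
    out = []
    positions = {a.residue: [i for i, ch in enumerate(seq) if ch == a.residue]
                 for a in pattern.anchors}
    pools = [positions[a.residue] for a in pattern.anchors]
    # all index combinations drawn per anchor (with repetition across pools)
    def rec(i, chosen):
        if i == len(pools):
            out.append(tuple(chosen))
            return
        for p in pools[i]:
            if chosen and p <= chosen[-1]:
                continue
            if chosen:
                gap = p - chosen[-1] - 1
                a = pattern.anchors[i]
                if not (a.gap_min <= gap <= a.gap_max):
                    continue
            rec(i + 1, chosen + [p])
    rec(0, [])
    return sorted(out)


def test_csp_forced_match():
    seq = list("A" * 35)
    for p in (0, 7, 26, 29):
        seq[p] = "C"
    matches = match_scaffold(SequenceRecord("x", "".join(seq)),
                             BUILTIN_PATTERNS["csp"])
    assert [m.anchor_positions for m in matches] == [(0, 7, 26, 29)]


def test_cysteine_free_sequence():
    assert match_scaffold(SequenceRecord("x", "AGHKLMNW" * 10),
                          BUILTIN_PATTERNS["csp"]) == []


@pytest.mark.parametrize("pattern_name,length,cys_freq", [
    ("csp", 60, 0.15),
    ("csp", 120, 0.10),
    ("classic_obp", 120, 0.10),
])
def test_brute_force_equivalence(rng, pattern_name, length, cys_freq):
    pattern = BUILTIN_PATTERNS[pattern_name]
    p = np.full(20, (1 - cys_freq) / 19)
    p[1] = cys_freq  # index of C in the AA order
    for _ in range(100):
        seq = random_protein(rng, length, p=p)
        got = [m.anchor_positions for m in
               match_scaffold(SequenceRecord("x", seq), pattern)]
        assert got == _brute_force_matches(seq, pattern)
        assert got == sorted(got)  # lexicographic enumeration


def test_gap_boundary_monotonicity():
    pattern = ScaffoldPattern("toy", (Anchor("C"), Anchor("C", 2, 4)))
    at_min = "CAAC"           # gap 2
    at_max = "CAAAAC"         # gap 4
    assert match_scaffold(SequenceRecord("x", at_min), pattern)
    assert match_scaffold(SequenceRecord("x", at_max), pattern)
    # deleting inside a gap at its lower bound destroys the match
    assert not match_scaffold(SequenceRecord("x", "CAC"), pattern)
    # inserting at the upper bound destroys it
    assert not match_scaffold(SequenceRecord("x", "CAAAAAC"), pattern)


def test_derived_minus_pattern_gaps():
    minus = BUILTIN_PATTERNS["minusc_obp"]
    gaps = [(a.gap_min, a.gap_max) for a in minus.anchors[1:]]
    assert gaps == [(27, 48), (36, 43), (17, 21)]
    assert derive_minus_pattern(BUILTIN_PATTERNS["classic_obp"], (2, 5)).anchors == minus.anchors


def test_classify_obp_subclasses():
    recs, truth = make_classic_obp_set(n=5, seed=2)
    for rec in recs:
        call = classify_obp(rec)
        assert (call.family, call.subclass) == ("obp", "classic")
        assert call.evidence and call.total_cys == 6

    # removing C2 and C5 turns a classic record into minus-C
    rec = recs[0]
    anchors = truth.records[rec.id].anchor_positions
    res = list(rec.residues)
    res[anchors[1]] = "A"
    res[anchors[4]] = "A"
    call = classify_obp(SequenceRecord("m", "".join(res)))
    assert (call.family, call.subclass) == ("obp", "minus-C")

    # classic scaffold + 7 extra downstream Cys + trailing proline -> plus-C
    plus_spec = FamilySpec("plusc_obp", n=5, length_range=(185, 210), seed=3)
    plus_recs, _ = generate_family_set(plus_spec)
    for rec in plus_recs:
        call = classify_obp(rec)
        assert (call.family, call.subclass) == ("obp", "plus-C")
        assert call.total_cys == 13


def test_classify_obp_deterministic_single_subclass():
    recs, _ = make_classic_obp_set(n=10, seed=9)
    for rec in recs:
        calls = {(classify_obp(rec).family, classify_obp(rec).subclass)
                 for _ in range(3)}
        assert len(calls) == 1


def test_classify_csp():
    recs, _ = make_csp_set(n=5, seed=5)
    for rec in recs:
        call = classify_csp(rec)
        assert call.family == "csp"
        assert call.evidence and call.total_cys == 4
    classic, _ = make_classic_obp_set(n=5, seed=2)
    for rec in classic:
        assert classify_csp(rec).family == "unclassified"
    assert classify_csp(SequenceRecord("x", "AAAA")).family == "unclassified"


def test_hydropathy_profile_values():
    assert hydropathy_profile(SequenceRecord("i", "I" * 19), 19) == pytest.approx([4.5])
    assert hydropathy_profile(SequenceRecord("d", "D" * 19), 19) == pytest.approx([-3.5])
    with pytest.raises(ValueError):
        hydropathy_profile(SequenceRecord("x", "MK"), 19)
    with pytest.raises(ValueError, match="odd"):
        hydropathy_profile(SequenceRecord("x", "MKWLIV"), 4)


def test_hydropathy_profile_brute_force(rng):
    from cysmotif.alphabet import KYTE_DOOLITTLE
    seq = random_protein(rng, 120)
    window = 9
    prof = hydropathy_profile(SequenceRecord("x", seq), window)
    for i in range(len(seq) - window + 1):
        expect = np.mean([KYTE_DOOLITTLE[c] for c in seq[i:i + window]])
        assert prof[i] == pytest.approx(expect)


def test_tm_segment_detection():
    seq = "D" * 40 + "I" * 25 + "D" * 40
    segs = predict_tm_segments(SequenceRecord("x", seq), window=19, threshold=1.6)
    assert len(segs) == 1
    assert segs[0].start >= 30 and segs[0].end <= 75
    assert predict_tm_segments(SequenceRecord("y", "DENQKR" * 20)) == []


def test_snmp_topology_calls():
    recs, truth = make_snmp_set(n=6, seed=7)
    for rec in recs:
        call = classify_snmp(rec)
        assert call.family == "snmp"
        segs = call.evidence
        assert len(segs) == 2
        assert segs[0].start < 60 and segs[1].end > len(rec) - 60

    # one or three TM stretches are not SNMP-like
    one_tm = "D" * 40 + "I" * 25 + "D" * 200
    assert classify_snmp(SequenceRecord("x", one_tm)).family == "unclassified"
    three_tm = ("I" * 25 + "D" * 110) * 3
    assert classify_snmp(SequenceRecord("y", three_tm)).family == "unclassified"


def _planted_label(rec):
    obp = classify_obp(rec)
    if obp.family == "obp":
        return {"classic": "classic_obp", "minus-C": "minusc_obp",
                "plus-C": "plusc_obp"}[obp.subclass]
    if classify_csp(rec).family == "csp":
        return "csp"
    if classify_snmp(rec).family == "snmp":
        return "snmp"
    return "unclassified"


def test_confusion_matrix_is_identity_on_clean_families():
    """Every record of every clean synthetic family receives its planted
    label (n = 50 per family, stray cysteines suppressed)."""
    sets = {
        "classic_obp": make_classic_obp_set(n=50, seed=11)[0],
        "minusc_obp": make_minusc_obp_set(n=50, n_subset=45, seed=12)[0],
        "plusc_obp": generate_family_set(
            FamilySpec("plusc_obp", n=50, length_range=(185, 215), seed=13))[0],
        "csp": make_csp_set(n=50, seed=14)[0],
        "snmp": make_snmp_set(n=50, seed=15)[0],
    }
    for family, records in sets.items():
        labels = {_planted_label(r) for r in records}
        assert labels == {family}, f"{family}: got {labels}"
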