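"""ZOOPS-EM discovery: closed-form toy oracle, EM guarantees, planted-motif
recovery, shuffle-null calibration, scanning."""

import math

import numpy as np
import pytest

from cysmotif.motifs import (MotifModel, discover_motifs, em_zoops,
                             model_from_consensus, motif_significance,
                             null_fit, scan_motif)
from cysmotif.records import SequenceRecord
from cysmotif.synthetic import (CLASSIC_MOTIF, make_classic_obp_set,
                                make_csp_set)

from conftest import random_protein


def _plant(rng, n, length, consensus, prefix="s"):
    """Random proteins with one exact planted occurrence each."""
    recs, sites = [], {}
    w = len(consensus)
    for i in range(n):
        res = list(random_protein(rng, length))
        p = int(rng.integers(0, length - w + 1))
        res[p:p + w] = consensus
        rid = f"{prefix}{i}"
        recs.append(SequenceRecord(rid, "".join(res)))
        sites[rid] = p
    return recs, sites


# --------------------------------------------------------------------------
# EM core
# --------------------------------------------------------------------------

def test_em_zoops_matches_grid_search_oracle(rng):
    """On a two-letter, width-1 toy the EM fixed point attains the global
    maximum found by brute-force grid search over (gamma, theta)."""
    seqs = ["AACAAAAC", "AAAACAAA", "CAAAAAAA", "AAAAAAAC", "ACAAAAAA", "AAAAAAAA"]
    records = [SequenceRecord(f"t{i}", s) for i, s in enumerate(seqs)]
    counts = {"A": sum(s.count("A") for s in seqs), "C": sum(s.count("C") for s in seqs)}
    total = sum(counts.values())
    bg = {ch: (counts[ch] + 1) / (total + 20) for ch in "AC"}

    def llr(gamma, theta_a):
        theta = {"A": theta_a, "C": 1 - theta_a}
        out = 0.0
        for s in seqs:
            m = len(s)
            site = sum(theta[c] / bg[c] for c in s) / m
            out += math.log((1 - gamma) + gamma * site)
        return out

    grid = max(llr(g, t)
               for g in np.linspace(0.01, 0.99, 197)
               for t in np.linspace(0.01, 0.99, 197))
    best = max(em_zoops(records, 1, start).log_likelihood_ratio
               for start in ("A", "C"))
    assert best >= grid - 0.05
    assert best <= grid + 0.05


def test_llr_history_monotone_and_deterministic():
    recs, _ = make_classic_obp_set(n=15, seed=21)
    m1 = em_zoops(recs, 8, CLASSIC_MOTIF)
    m2 = em_zoops(recs, 8, CLASSIC_MOTIF)
    assert np.allclose(m1.ppm, m2.ppm) and m1.history == m2.history
    diffs = np.diff(m1.history)
    assert (diffs >= -1e-9).all()
    # PPM is row-stochastic and strictly positive after fitting
    assert np.allclose(m1.ppm.sum(axis=1), 1.0, atol=1e-9)
    assert (m1.ppm > 0).all()


def test_identical_copies_give_degenerate_columns(rng):
    base = random_protein(rng, 50)
    records = [SequenceRecord(f"c{i}", base) for i in range(20)]
    model = em_zoops(records, 8, base[10:18])
    assert (model.ppm.max(axis=1) >= 0.98).all()


def test_em_zoops_input_validation():
    recs = [SequenceRecord("a", "MKWLIVHQEN"), SequenceRecord("b", "MKWLIVHQEN")]
    with pytest.raises(ValueError, match="length"):
        em_zoops(recs, 6, "MKW")
    with pytest.raises(ValueError, match="shape"):
        em_zoops(recs, 6, np.ones((3, 20)))


# --------------------------------------------------------------------------
# discovery
# --------------------------------------------------------------------------

def test_planted_motif_recovery(rng):
    """Headline recovery property: the top discovered motif reproduces the
    planted consensus and at least 90% of planted sites at exact offset."""
    recs, sites = _plant(rng, 20, 120, CLASSIC_MOTIF)
    models = discover_motifs(recs, 6, 10, 2, 1e-4, seed=3,
                             discovery_shuffles=199)
    assert models, "planted motif not accepted"
    top = models[0]
    assert top.width == 8 and top.consensus == CLASSIC_MOTIF
    hits = 0
    for rec in recs:
        occ = scan_motif(top, rec)
        hits += any(o.start == sites[rec.id] for o in occ)
    assert hits >= 0.9 * len(recs)
    assert (np.diff(top.history) >= -1e-9).all()


def test_discovery_requires_two_records_and_long_enough():
    with pytest.raises(ValueError, match="at least 2"):
        discover_motifs([SequenceRecord("a", "MKWLIVHQEN")], 6, 8, 1)
    recs = [SequenceRecord("a", "MKW"), SequenceRecord("b", "MKWLIVHQEN")]
    with pytest.raises(ValueError, match="'a'"):
        discover_motifs(recs, 6, 8, 1)


def test_noise_yields_no_motifs(rng):
    """On i.i.d. background sequences discovery accepts nothing in at least
    95% of independent runs."""
    accepted_runs = 0
    for seed in range(20):
        r = np.random.default_rng(1000 + seed)
        recs = [SequenceRecord(f"n{i}", random_protein(r, 60)) for i in range(20)]
        models = discover_motifs(recs, 6, 10, 8, 1e-4, seed=seed,
                                 discovery_shuffles=499)
        accepted_runs += bool(models)
    assert accepted_runs <= 1


def test_masked_positions_are_never_rescanned(rng):
    res = list(random_protein(rng, 60))
    res[20:30] = "X" * 10
    rec = SequenceRecord("m", "".join(res))
    model = model_from_consensus("WDYKHGNE")
    for occ in scan_motif(model, rec, threshold_bits=-1e9):
        assert occ.start + 8 <= 20 or occ.start >= 30


def test_multi_motif_discovery_sites_disjoint():
    recs, truth = make_csp_set(n=12, seed=5)
    models = discover_motifs(recs, 6, 10, 8, 1e-4, seed=8,
                             discovery_shuffles=99)
    assert len(models) >= 3
    for rec in recs:
        spans = []
        for m in models:
            for o in scan_motif(m, rec):
                spans.append((o.start, o.start + m.width, m.id))
        # occurrences of distinct discovered motifs never collide exactly
        starts = [s for s, _, _ in spans]
        assert len(set(starts)) == len(starts)


# --------------------------------------------------------------------------
# significance
# --------------------------------------------------------------------------

def test_significance_floor_for_strong_motif(rng):
    recs, _ = _plant(rng, 10, 60, CLASSIC_MOTIF)
    model = em_zoops(recs, 8, CLASSIC_MOTIF)
    p = motif_significance(model, recs, n_shuffles=99, seed=1)
    assert p == pytest.approx(1 / 100)


def test_significance_add_one_formula_bounds(rng):
    recs = [SequenceRecord(f"r{i}", random_protein(rng, 40)) for i in range(6)]
    model = null_fit(recs, 6, seed=0)
    p = motif_significance(model, recs, n_shuffles=9, seed=2)
    assert 0 < p <= 1
    assert p in {k / 10 for k in range(1, 11)}
    with pytest.raises(ValueError, match="n_shuffles"):
        motif_significance(model, recs, n_shuffles=0, seed=0)


def test_significance_calibration_on_noise():
    """A model fit on background-only data gets an approximately uniform
    p-value: the statistic is exchangeable with its shuffle null."""
    low = 0
    for trial in range(20):
        r = np.random.default_rng(7000 + trial)
        recs = [SequenceRecord(f"x{i}", random_protein(r, 50)) for i in range(10)]
        model = null_fit(recs, 6, seed=trial)
        p = motif_significance(model, recs, n_shuffles=19, seed=500 + trial)
        low += (p <= 0.05)
    assert low <= 2  # >= 90% of trials above 0.05


# --------------------------------------------------------------------------
# scanning
# --------------------------------------------------------------------------

def test_scan_consensus_scores_max(rng):
    model = model_from_consensus("WDYKHGNE")
    rec = SequenceRecord("c", random_protein(rng, 30) + "WDYKHGNE" + random_protein(rng, 30))
    occs = scan_motif(model, rec)
    assert any(o.start == 30 for o in occs)
    best = max(o.score for o in occs)
    assert best == pytest.approx(model.max_score_bits)


def test_scan_background_only_is_empty(rng):
    model = model_from_consensus("WDYKHGNE")
    hits = [scan_motif(model, SequenceRecord(f"b{i}", random_protein(rng, 150)))
            for i in range(20)]
    assert sum(len(h) for h in hits) == 0


def test_scan_greedy_non_overlap():
    model = model_from_consensus("WWWW")
    rec = SequenceRecord("w", "AAAWWWWWWAAA")
    occs = scan_motif(model, rec, threshold_bits=0.0)
    spans = [(o.start, o.start + 4) for o in occs]
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 <= a2
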