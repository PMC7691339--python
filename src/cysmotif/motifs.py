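"""De novo ungapped motif discovery by ZOOPS expectation-maximization.

The site model is ZOOPS (zero-or-one occurrence per sequence): each sequence
carries at most one site of a fixed-width motif, drawn from a position
probability matrix (PPM), against an i.i.d. background estimated from the
data.  Discovery is greedy: per round, every distinct subsequence of each
candidate width seeds a starting model, starts are ranked by a one-pass
ZOOPS log-likelihood-ratio screen, EM is run to convergence from the best
few, widths are compared by LLR per free parameter, and the winning model is
tested against an empirical within-sequence residue-shuffle null before its
sites are masked out and the next round begins.

Significance is an explicit shuffle null rather than an analytic E-value:
``motif_significance`` recomputes a fixed capped-start fit statistic on the
observed data and on each shuffled dataset and reports the add-one
empirical p-value  p = (1 + #exceedances) / (1 + n_shuffles); using the
same procedure on both sides keeps the statistic exchangeable under the
null.  Inside ``discover_motifs`` this per-width p is Sidak-corrected for
the number of widths examined; see ``docs/methods.md`` for the selection
rule and its calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .alphabet import AA, MASK_CODE, decode_protein, encode_protein
from .records import SequenceRecord, check_unique_ids

PSEUDOCOUNT = 0.01          # total Dirichlet mass per PPM column, spread as 0.01*bg per cell
SEED_IDENTITY = 0.6         # match probability of a seed-subsequence start model
GAMMA_INIT = 0.5
EM_TOL = 1e-6
EM_MAX_ITER = 500


@dataclass
class MotifModel:
    """A fitted fixed-width motif: PPM + background + fit statistics."""

    id: int
    width: int
    ppm: np.ndarray                  # (w, 20), rows sum to 1, entries > 0
    background: np.ndarray           # (20,)
    n_sites: float                   # expected site count (sum of posteriors)
    log_likelihood_ratio: float      # nats, vs background-only model
    significance: Optional[float] = None
    converged: bool = True
    history: List[float] = field(default_factory=list, repr=False)

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.ppm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(w, 21) base-2 log-odds; the masked-residue column scores 0."""
        lo = np.zeros((self.width, 21))
        lo[:, :20] = np.log2(self.ppm / self.background)
        return lo

    @property
    def max_score_bits(self) -> float:
        return float(self.log_odds()[:, :20].max(axis=1).sum())

    @property
    def information_content_bits(self) -> float:
        return float((self.ppm * np.log2(self.ppm / self.background)).sum())


@dataclass(frozen=True)
class MotifOccurrence:
    sequence_id: str
    motif_id: int
    start: int
    score: float                     # base-2 log-odds of the window

    @property
    def end(self):
        raise AttributeError("width lives on the model; use start + model.width")


# --------------------------------------------------------------------------
# corpus encoding
# --------------------------------------------------------------------------

class _Corpus:
    """Encoded sequences with per-width valid-window tables.

    A window is valid when it contains no masked residue; masked spans are
    thereby excluded both from candidate starts and from site placement.
    """

    def __init__(self, seqs: Sequence[np.ndarray], background: Optional[np.ndarray] = None):
        self.seqs = [np.asarray(s, dtype=np.int8) for s in seqs]
        if background is None:
            counts = np.ones(20)
            for s in self.seqs:
                counts += np.bincount(s[s < 20], minlength=20)
            background = counts / counts.sum()
        self.background = background

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord],
                     background: Optional[np.ndarray] = None) -> "_Corpus":
        return cls([encode_protein(r.residues) for r in records], background)

    def windows(self, w: int):
        """Return (X, starts, m_per_seq, seq_of_window, origin) where X is the
        (Nw, w) stacked valid windows of all sequences in input order."""
        rows, seq_of, origin = [], [], []
        m_per_seq = np.zeros(len(self.seqs), dtype=int)
        for i, s in enumerate(self.seqs):
            if len(s) < w:
                continue
            sl = np.lib.stride_tricks.sliding_window_view(s, w)
            ok = (sl < 20).all(axis=1)
            idx = np.nonzero(ok)[0]
            m_per_seq[i] = len(idx)
            if len(idx):
                rows.append(sl[idx])
                seq_of.append(np.full(len(idx), i))
                origin.append(idx)
        if not rows:
            return (np.empty((0, w), dtype=np.int8), np.array([], dtype=int),
                    m_per_seq, np.array([], dtype=int), np.array([], dtype=int))
        X = np.concatenate(rows)
        seq_of_window = np.concatenate(seq_of)
        origin = np.concatenate(origin)
        # reduceat boundaries: first window row of each sequence WITH windows
        starts = np.flatnonzero(np.r_[1, np.diff(seq_of_window)])
        return X, starts, m_per_seq, seq_of_window, origin


# --------------------------------------------------------------------------
# EM core
# --------------------------------------------------------------------------

def _seed_theta(seed_codes: np.ndarray, bg: np.ndarray,
                identity: float = SEED_IDENTITY) -> np.ndarray:
    w = len(seed_codes)
    theta = np.tile((1.0 - identity) * bg, (w, 1))
    for j, c in enumerate(seed_codes):
        if c < 20:
            theta[j, c] += identity
        else:
            theta[j] = bg
    return theta / theta.sum(axis=1, keepdims=True)


def _window_scores(theta: np.ndarray, bg: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-window log probability ratio (nats) under a single model."""
    lr = np.log(theta / bg)          # (w, 20)
    scores = np.zeros(len(X))
    for j in range(theta.shape[0]):
        scores += lr[j, X[:, j]]
    return scores


def _zoops_eval(scores, starts, group_idx, log_m, gamma):
    """ZOOPS mixture terms for one model.

    Returns (llr_total, per_seq_llr, es, mx) where ``es`` is
    exp(score - per-seq max), reused by the E-step.
    """
    mx = np.maximum.reduceat(scores, starts)
    es = np.exp(scores - mx[group_idx])
    A = mx + np.log(np.add.reduceat(es, starts))
    per_seq = np.logaddexp(math.log1p(-gamma), math.log(gamma) - log_m + A)
    return float(per_seq.sum()), per_seq, es, mx


def _em_single(X, starts, m_per_seq, seq_of_window, theta, bg,
               gamma=GAMMA_INIT, max_iter=EM_MAX_ITER, tol=EM_TOL):
    """EM to convergence for one start.  Returns a dict of fitted state.

    The tracked objective is the MAP objective (LLR plus the Dirichlet
    pseudocount prior term), which EM ascends monotonically.
    """
    w = theta.shape[0]
    m_active = m_per_seq[m_per_seq > 0].astype(float)
    log_m = np.log(m_active)
    n_seq_total = len(m_per_seq)
    group_idx = np.searchsorted(starts, np.arange(len(X)), "right") - 1
    history = []
    converged = False
    z = np.zeros(len(X))
    alpha_bg = PSEUDOCOUNT * bg

    def posteriors(per_seq, es, mx):
        factor = np.exp(math.log(gamma) - log_m + mx - per_seq)
        return es * factor[group_idx]

    for _ in range(max_iter):
        scores = _window_scores(theta, bg, X)
        llr, per_seq, es, mx = _zoops_eval(scores, starts, group_idx, log_m, gamma)
        prior = float(alpha_bg @ np.log(theta).sum(axis=0))
        obj = llr + prior
        history.append(obj)
        if len(history) > 1 and abs(history[-1] - history[-2]) <= tol * max(1.0, abs(history[-1])):
            converged = True
            break
        # E-step
        z = posteriors(per_seq, es, mx)
        Q = np.add.reduceat(z, starts)
        # M-step
        gamma = float(np.clip(Q.sum() / n_seq_total, 1e-6, 1 - 1e-6))
        counts = np.tile(alpha_bg, (w, 1))
        for j in range(w):
            counts[j] += np.bincount(X[:, j], weights=z, minlength=21)[:20]
        theta = counts / counts.sum(axis=1, keepdims=True)

    scores = _window_scores(theta, bg, X)
    llr, per_seq, es, mx = _zoops_eval(scores, starts, group_idx, log_m, gamma)
    z = posteriors(per_seq, es, mx)
    Q = np.add.reduceat(z, starts)
    return {
        "theta": theta, "gamma": gamma, "llr": float(llr),
        "history": history, "converged": converged,
        "z": z, "Q": Q, "n_sites": float(Q.sum()),
    }


def _screen_starts(X, starts, m_per_seq, bg, candidates, chunk=1024):
    """Rank candidate seed windows by one-pass ZOOPS LLR of their seed model.

    The seed-model window score is affine in per-residue-weighted match
    counts, so all candidates are scored with one one-hot matrix product.
    """
    Nw, w = X.shape
    g = np.log1p(SEED_IDENTITY / ((1.0 - SEED_IDENTITY) * bg))   # (20,)
    base = w * math.log1p(-SEED_IDENTITY)
    # one-hot of all windows weighted by g(residue): (Nw, w*20)
    Wt = np.zeros((Nw, w * 20), dtype=np.float32)
    flat_idx = X.astype(np.int64) + 20 * np.arange(w)
    gw = g[X.astype(np.int64)].astype(np.float32)
    np.put_along_axis(Wt, flat_idx, gw, axis=1)

    m_active = m_per_seq[m_per_seq > 0].astype(float)
    seq_idx = np.searchsorted(starts, np.arange(Nw), "right") - 1
    llrs = np.empty(len(candidates))
    Oh = np.zeros((chunk, w * 20), dtype=np.float32)
    for lo in range(0, len(candidates), chunk):
        C = candidates[lo:lo + chunk]
        Oh[:len(C)].fill(0.0)
        cflat = C.astype(np.int64) + 20 * np.arange(w)
        np.put_along_axis(Oh[:len(C)], cflat, np.float32(1.0), axis=1)
        S = Wt @ Oh[:len(C)].T                     # (Nw, |C|)
        S += np.float32(base)
        mx = np.maximum.reduceat(S, starts, axis=0)
        ex = np.exp(S - mx[seq_idx])
        A = mx + np.log(np.add.reduceat(ex, starts, axis=0))
        site = math.log(GAMMA_INIT) - np.log(m_active)[:, None] + A
        llrs[lo:lo + len(C)] = np.logaddexp(math.log1p(-GAMMA_INIT), site).sum(axis=0)
    return llrs


def _fit_width(corpus: _Corpus, w: int, rng: np.random.Generator,
               max_starts: Optional[int] = None, n_em_starts: int = 3,
               max_iter: int = EM_MAX_ITER, tol: float = EM_TOL,
               screen_cap: Optional[int] = 2500):
    """Best converged ZOOPS model at width ``w``: screen distinct window
    seeds, EM from the top ``n_em_starts``.  Returns None when no windows.

    Candidate starts are every distinct valid window; when the corpus holds
    more than ``screen_cap`` windows the screening pass ranks starts against
    a seeded subsample of whole sequences (EM always runs on all data).
    """
    X, starts, m_per_seq, seq_of_window, _ = corpus.windows(w)
    if len(X) == 0 or (m_per_seq > 0).sum() < 2:
        return None
    candidates, counts = np.unique(X, axis=0, return_counts=True)
    if max_starts is not None and len(candidates) > max_starts:
        # keep repeated windows first (multiplicity is motif evidence),
        # breaking ties with a seeded shuffle
        order = np.lexsort((rng.random(len(candidates)), -counts))
        candidates = candidates[np.sort(order[:max_starts])]

    sX, sstarts, sm = X, starts, m_per_seq[m_per_seq > 0]
    if screen_cap is not None and len(X) > screen_cap:
        sizes = np.diff(np.r_[starts, len(X)])
        m_act = m_per_seq[m_per_seq > 0]
        perm = rng.permutation(len(starts))
        chosen, total = [], 0
        for g in perm:
            chosen.append(int(g))
            total += int(sizes[g])
            if total >= screen_cap:
                break
        chosen.sort()
        rows = np.concatenate([np.arange(starts[g], starts[g] + sizes[g])
                               for g in chosen])
        sX = X[rows]
        sstarts = np.r_[0, np.cumsum(sizes[chosen])[:-1]]
        sm = m_act[chosen]
    llrs = _screen_starts(sX, sstarts, sm, corpus.background, candidates)
    order = np.argsort(-llrs, kind="stable")[:n_em_starts]
    best = None
    for k in order:
        theta = _seed_theta(candidates[k], corpus.background)
        fit = _em_single(X, starts, m_per_seq, seq_of_window, theta,
                         corpus.background, max_iter=max_iter, tol=tol)
        if best is None or fit["llr"] > best["llr"]:
            best = fit
    best["width"] = w
    best["windows"] = (X, starts, m_per_seq, seq_of_window)
    return best


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def em_zoops(records: Sequence[SequenceRecord], w: int,
             start_point: Union[str, np.ndarray],
             max_iter: int = EM_MAX_ITER, tol: float = EM_TOL) -> MotifModel:
    """Run ZOOPS EM at fixed width from one start.

    ``start_point`` is either a seed subsequence of length ``w`` or a prior
    (w, 20) PPM.  Non-convergence at ``max_iter`` is flagged on the returned
    model, not raised.
    """
    corpus = _Corpus.from_records(records)
    X, starts, m_per_seq, seq_of_window, _ = corpus.windows(w)
    if len(X) == 0:
        raise ValueError(f"no sequence admits a window of width {w}")
    if isinstance(start_point, str):
        if len(start_point) != w:
            raise ValueError("seed subsequence length must equal w")
        theta = _seed_theta(encode_protein(start_point), corpus.background)
    else:
        theta = np.asarray(start_point, dtype=float)
        if theta.shape != (w, 20):
            raise ValueError(f"prior ppm must have shape ({w}, 20)")
        theta = np.clip(theta, 1e-9, None)
        theta = theta / theta.sum(axis=1, keepdims=True)
    fit = _em_single(X, starts, m_per_seq, seq_of_window, theta,
                     corpus.background, max_iter=max_iter, tol=tol)
    return MotifModel(
        id=0, width=w, ppm=fit["theta"], background=corpus.background,
        n_sites=fit["n_sites"], log_likelihood_ratio=fit["llr"],
        significance=None, converged=fit["converged"], history=fit["history"],
    )


def _shuffle_corpus(corpus: _Corpus, rng: np.random.Generator) -> _Corpus:
    """Shuffle residues within each sequence (masked positions stay put)."""
    shuffled = []
    for s in corpus.seqs:
        t = s.copy()
        free = np.nonzero(t < 20)[0]
        t[free] = t[free[rng.permutation(len(free))]]
        shuffled.append(t)
    return _Corpus(shuffled, corpus.background)


def null_fit(records: Sequence[SequenceRecord], w: int, seed: int = 0,
             max_starts: int = 128, n_em_starts: int = 2,
             max_iter: int = 100, tol: float = 1e-4) -> MotifModel:
    """Fit the best width-``w`` motif with the same capped-start routine the
    shuffle null uses.  Exposed so calibration studies can make the observed
    statistic exchangeable with the null by construction."""
    corpus = _Corpus.from_records(records)
    rng = np.random.default_rng(seed)
    fit = _fit_width(corpus, w, rng, max_starts=max_starts,
                     n_em_starts=n_em_starts, max_iter=max_iter, tol=tol)
    if fit is None:
        raise ValueError(f"no sequence admits a window of width {w}")
    return MotifModel(
        id=0, width=w, ppm=fit["theta"], background=corpus.background,
        n_sites=fit["n_sites"], log_likelihood_ratio=fit["llr"],
        significance=None, converged=fit["converged"], history=fit["history"],
    )


def motif_significance(model: MotifModel, records: Sequence[SequenceRecord],
                       n_shuffles: int = 999, seed: int = 0, *,
                       max_starts: int = 128, n_em_starts: int = 2,
                       max_iter: int = 100, tol: float = 1e-4,
                       background: Optional[np.ndarray] = None,
                       early_reject_at: Optional[int] = None) -> float:
    """Empirical p-value of a motif's width under a residue-shuffle null.

    The test statistic is the best LLR found by a fixed capped-start fitting
    procedure at the model's width.  It is recomputed on the observed
    sequences and on each of ``n_shuffles`` datasets that shuffle residues
    within every sequence, and p = (1 + #{null >= observed}) / (1 + n_shuffles).
    Applying the *same* procedure to observed and shuffled data keeps the
    statistic exchangeable under the null, so p is calibrated regardless of
    how hard the reported model itself was optimized.  With
    ``early_reject_at=k`` the loop stops once k exceedances are seen and the
    corresponding lower bound on p is returned.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    corpus = _Corpus.from_records(records, background)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(n_shuffles + 2)]

    def statistic(data, rng):
        fit = _fit_width(data, model.width, rng, max_starts=max_starts,
                         n_em_starts=n_em_starts, max_iter=max_iter, tol=tol)
        return -math.inf if fit is None else fit["llr"]

    observed = statistic(corpus, rngs[-1])
    exceed = 0
    for b in range(n_shuffles):
        shuf = _shuffle_corpus(corpus, rngs[b])
        if statistic(shuf, rngs[-2]) >= observed:
            exceed += 1
            if early_reject_at is not None and exceed >= early_reject_at:
                break
    return (1 + exceed) / (1 + n_shuffles)


def scan_motif(model: MotifModel, seq: SequenceRecord,
               threshold_bits: Optional[float] = None) -> List[MotifOccurrence]:
    """All non-overlapping windows scoring at least ``threshold_bits``
    (default 60% of the motif's maximum attainable log-odds), selected
    greedily by descending score."""
    if threshold_bits is None:
        threshold_bits = 0.6 * model.max_score_bits
    codes = encode_protein(seq.residues)
    w = model.width
    if len(codes) < w:
        return []
    lo = model.log_odds()
    sl = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (sl < 20).all(axis=1)
    scores = np.zeros(len(sl))
    for j in range(w):
        scores += lo[j, sl[:, j]]
    hits = [(float(scores[p]), int(p)) for p in np.nonzero(valid & (scores >= threshold_bits))[0]]
    hits.sort(key=lambda t: (-t[0], t[1]))
    chosen: List[Tuple[float, int]] = []
    occupied = np.zeros(len(codes), dtype=bool)
    for score, p in hits:
        if not occupied[p:p + w].any():
            occupied[p:p + w] = True
            chosen.append((score, p))
    chosen.sort(key=lambda t: t[1])
    return [MotifOccurrence(seq.id, model.id, p, score) for score, p in chosen]


def discover_motifs(records: Sequence[SequenceRecord], minw: int, maxw: int,
                    nmotifs: int, p_threshold: float = 1e-4, seed: int = 0, *,
                    widths: Optional[Sequence[int]] = None,
                    width_step: int = 1,
                    max_starts: Optional[int] = None,
                    n_em_starts: int = 3,
                    discovery_shuffles: int = 499,
                    null_max_starts: int = 128,
                    null_em_starts: int = 2,
                    null_max_iter: int = 100,
                    max_iter: int = EM_MAX_ITER) -> List[MotifModel]:
    """Greedy motif discovery with iterative masking.

    Per round the best converged model per width (``minw``..``maxw``, or an
    explicit ``widths`` list) is fit, widths are compared by LLR per free
    parameter (LLR / (19 w)), and the winner is kept only if its
    Sidak-corrected shuffle-null p-value is no larger than
    ``max(p_threshold, smallest attainable p)`` — at the defaults this keeps
    a motif only when no shuffled dataset's refit matches its LLR.  Accepted
    sites are masked before the next round; motifs are numbered by rank.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("discovery needs at least 2 records")
    check_unique_ids(records)
    too_short = [r.id for r in records if len(r) < minw]
    if too_short:
        raise ValueError(f"records shorter than minw={minw}: {too_short}")
    if widths is None:
        widths = list(range(minw, maxw + 1, width_step))
        if widths[-1] != maxw:
            widths.append(maxw)
    widths = sorted(set(widths))
    n_widths = len(widths)

    base = _Corpus.from_records(records)
    work = _Corpus([s.copy() for s in base.seqs], base.background)
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.spawn(nmotifs)

    p_floor = 1.0 - (1.0 - 1.0 / (1 + discovery_shuffles)) ** n_widths
    accept_at = max(p_threshold, p_floor * (1 + 1e-9))

    accepted: List[MotifModel] = []
    for rank in range(1, nmotifs + 1):
        rng = np.random.default_rng(round_seeds[rank - 1])
        best = None
        for w in widths:
            fit = _fit_width(work, w, rng, max_starts=max_starts,
                             n_em_starts=n_em_starts, max_iter=max_iter)
            if fit is None:
                continue
            fit["per_param"] = fit["llr"] / (19.0 * w)
            if best is None or fit["per_param"] > best["per_param"]:
                best = fit
        if best is None:
            break

        model = MotifModel(
            id=rank, width=best["width"], ppm=best["theta"],
            background=base.background, n_sites=best["n_sites"],
            log_likelihood_ratio=best["llr"], converged=best["converged"],
            history=best["history"],
        )
        # shuffle-null test with early rejection: one exceedance already
        # pushes p past any threshold at or below the attainable floor.
        shuffle_seed = int(rng.integers(2 ** 31))
        p_w = motif_significance(
            model, _corpus_records(work, records), n_shuffles=discovery_shuffles,
            seed=shuffle_seed, max_starts=null_max_starts,
            n_em_starts=null_em_starts, max_iter=null_max_iter,
            background=base.background,
            early_reject_at=_early_k(discovery_shuffles, n_widths, accept_at),
        )
        p_sel = 1.0 - (1.0 - p_w) ** n_widths
        if p_sel > accept_at:
            break
        model.significance = p_sel
        accepted.append(model)
        _mask_sites(work, best)
    return accepted


def _early_k(B: int, n_widths: int, accept_at: float) -> int:
    """Smallest exceedance count that already forces rejection."""
    for k in range(1, B + 2):
        p_w = (1 + k) / (1 + B)
        if 1.0 - (1.0 - p_w) ** n_widths > accept_at:
            return k
    return B + 1


def _corpus_records(corpus: _Corpus, originals: Sequence[SequenceRecord]):
    """Materialize the (possibly masked) working corpus as records."""
    out = []
    for rec, codes in zip(originals, corpus.seqs):
        out.append(SequenceRecord(rec.id, decode_protein(codes),
                                  rec.description, "protein"))
    return out


def _mask_sites(corpus: _Corpus, fit: dict, q_threshold: float = 0.5) -> None:
    """Mask each sequence's MAP site when its posterior presence >= 0.5."""
    X, starts, m_per_seq, seq_of_window = fit["windows"]
    w = fit["width"]
    z = fit["z"]
    Q = fit["Q"]
    active = np.nonzero(m_per_seq > 0)[0]
    # recompute window origins on the working corpus
    for gi, seq_i in enumerate(active):
        if Q[gi] < q_threshold:
            continue
        lo = starts[gi]
        hi = starts[gi + 1] if gi + 1 < len(starts) else len(z)
        best_local = int(np.argmax(z[lo:hi]))
        # origin of that window within the sequence
        s = corpus.seqs[seq_i]
        sl = np.lib.stride_tricks.sliding_window_view(s, w)
        ok = np.nonzero((sl < 20).all(axis=1))[0]
        p = int(ok[best_local])
        corpus.seqs[seq_i][p:p + w] = MASK_CODE


# --------------------------------------------------------------------------
# helpers for planted motifs and output formats
# --------------------------------------------------------------------------

def ppm_from_consensus(consensus: str, background: Optional[np.ndarray] = None,
                       identity: float = 0.95) -> np.ndarray:
    """A (w, 20) PPM concentrating ``identity`` mass on each consensus
    residue, the rest spread as the background."""
    if background is None:
        background = np.full(20, 1 / 20)
    return _seed_theta(encode_protein(consensus), background, identity)


def model_from_consensus(consensus: str, motif_id: int = 0,
                         background: Optional[np.ndarray] = None,
                         identity: float = 0.95) -> MotifModel:
    if background is None:
        background = np.full(20, 1 / 20)
    ppm = ppm_from_consensus(consensus, background, identity)
    return MotifModel(id=motif_id, width=len(consensus), ppm=ppm,
                      background=np.asarray(background, dtype=float),
                      n_sites=0.0, log_likelihood_ratio=0.0)


def write_meme_minimal(models: Sequence[MotifModel], path) -> None:
    """Write motifs in MEME minimal motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA + "\n\n")
        if models:
            bg = models[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{a} {f:.6f}" for a, f in zip(AA, bg)) + "\n\n")
        for m in models:
            fh.write(f"MOTIF motif_{m.id} {m.consensus}\n")
            sig = m.significance if m.significance is not None else 1.0
            fh.write(f"letter-probability matrix: alength= 20 w= {m.width} "
                     f"nsites= {max(1, round(m.n_sites))} E= {sig:.3g}\n")
            for row in m.ppm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
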