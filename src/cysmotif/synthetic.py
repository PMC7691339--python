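"""Labeled synthetic protein families and transcripts.

The generator emulates the statistical structure the downstream analysis
assumes so every stage is testable offline: protein families carrying the
conserved-cysteine scaffolds at their published spacings, planted ungapped
motifs at configured prevalences in a fixed left-to-right order, hydrophobic
transmembrane stretches near both termini (the SNMP/CD36-like layout), and
transcripts embedding a reverse-translated ORF between stop-disrupted UTRs.

Design choices (see docs/methods.md):

* Background cysteine frequency outside anchors is 0 by default, so
  subclass labels on clean data are unambiguous (the families are defined
  by conserved Cys counts; stray Cys would confound the truth labels).
* Motif carrier assignment is deterministic: the first round(prevalence*n)
  records of a seeded shuffle, so planted prevalences are exact.
* A transcript's ORF is "ATG" + one codon per residue after the initial Met
  + one stop codon (the leading Met is its start codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .alphabet import AA
from .patterns import BUILTIN_PATTERNS, ScaffoldPattern
from .records import SequenceRecord, check_unique_ids

FAMILIES = ("classic_obp", "minusc_obp", "plusc_obp", "csp", "snmp")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(_TABLE.stop_codons)
_CODONS_FOR = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

# reverse-strand stop codons as they read on the forward strand
_REV_STOPS = ("TTA", "CTA", "TCA")

HYDROPHOBIC = "ILVF"


@dataclass
class MotifPlan:
    """One planted motif: consensus residues, fraction of records carrying
    it, and its left-to-right order rank within each carrier."""

    consensus: str
    prevalence: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if any(ch not in AA for ch in self.consensus):
            raise ValueError(f"motif consensus has non-standard residues: {self.consensus!r}")


@dataclass
class TmPlan:
    n_segments: int = 2
    segment_length: int = 25
    margin: int = 8          # max distance of a segment from its terminus


@dataclass
class FamilySpec:
    family: str
    n: int
    length_range: Tuple[int, int] = (130, 160)
    scaffold: Optional[ScaffoldPattern] = None
    motif_plan: List[MotifPlan] = field(default_factory=list)
    tm_plan: Optional[TmPlan] = None
    seed: int = 0
    background: Optional[np.ndarray] = None     # over AA order; C is zeroed unless cys_background set
    cys_background: float = 0.0
    plusc_extra_cys: int = 7
    plusc_spacer_range: Tuple[int, int] = (1, 6)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.scaffold is None and self.family != "snmp":
            base = {"classic_obp": "classic_obp", "minusc_obp": "minusc_obp",
                    "plusc_obp": "classic_obp", "csp": "csp"}[self.family]
            self.scaffold = BUILTIN_PATTERNS[base]
        if self.family == "snmp" and self.tm_plan is None:
            self.tm_plan = TmPlan()
        bg = self.background
        if bg is None:
            bg = np.full(20, 1 / 20)
            if self.family == "snmp":
                # emulate a hydrophilic extracellular loop: stray hydrophobic
                # 19-windows would confound the planted TM topology labels,
                # just as stray cysteines would confound scaffold labels
                for ch in HYDROPHOBIC:
                    bg[AA.index(ch)] *= 0.5
        bg = np.asarray(bg, dtype=float).copy()
        c = AA.index("C")
        bg[c] = self.cys_background
        bg = bg / bg.sum()
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must normalize")
        self.background = bg
        self._check_feasible()

    def _reserved_max(self) -> int:
        total = 0
        if self.scaffold is not None:
            total += self.scaffold.span_bounds()[1]
        if self.family == "plusc_obp":
            total += self.plusc_extra_cys * (self.plusc_spacer_range[1] + 1) + 4
        if self.tm_plan is not None:
            total += self.tm_plan.n_segments * self.tm_plan.segment_length
        return total

    def _check_feasible(self):
        need = self._reserved_max() + sum(len(m.consensus) for m in self.motif_plan)
        if self.length_range[0] < need:
            raise ValueError(
                f"length_range {self.length_range} too short for scaffold + "
                f"planted motifs (need >= {need})")


@dataclass
class RecordTruth:
    family: str
    anchor_positions: List[int]
    motif_sites: List[Tuple[int, int]]       # (motif rank 1-based, start)
    tm_segments: List[Tuple[int, int]]


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic set."""

    records: Dict[str, RecordTruth]
    motif_consensus: Dict[int, str]          # rank -> planted consensus


def _greedy_earliest(widths: Sequence[int], free: np.ndarray, lo: int) -> bool:
    """Can motifs of ``widths`` be placed in order, non-overlapping, starting
    at or after ``lo``, each window within currently free positions?"""
    pos = lo
    for w in widths:
        placed = False
        while pos + w <= len(free):
            if free[pos:pos + w].all():
                pos += w
                placed = True
                break
            pos += 1
        if not placed:
            return False
    return True


def generate_family_set(spec: FamilySpec) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """Generate ``spec.n`` labeled records plus ground truth.

    Each record carries exactly one scaffold instance with spacers drawn
    uniformly within the pattern's gap bounds; planted motifs overwrite
    background at anchor-free positions in plan order (left to right) for a
    deterministic prevalence-exact subset of records.  Identical spec+seed
    gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # deterministic carrier assignment per motif
    carriers: List[set] = []
    for m in spec.motif_plan:
        k = int(round(m.prevalence * n))
        order = rng.permutation(n)
        carriers.append(set(order[:k].tolist()))

    records: List[SequenceRecord] = []
    truths: Dict[str, RecordTruth] = {}
    aa_arr = np.array(list(AA))

    for i in range(n):
        for _attempt in range(500):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = aa_arr[rng.choice(20, size=L, p=spec.background)]
            reserved = np.zeros(L, dtype=bool)
            anchors: List[int] = []

            if spec.scaffold is not None:
                gaps = [int(rng.integers(a.gap_min, a.gap_max + 1))
                        for a in spec.scaffold.anchors[1:]]
                span = 1 + sum(g + 1 for g in gaps)
                extra_positions: List[int] = []
                trailing_p = None
                if spec.family == "plusc_obp":
                    lo_s, hi_s = spec.plusc_spacer_range
                    cursor = span - 1
                    for _ in range(spec.plusc_extra_cys):
                        cursor += int(rng.integers(lo_s, hi_s + 1)) + 1
                        extra_positions.append(cursor)
                    trailing_p = extra_positions[-1] + int(rng.integers(1, 4))
                    total_span = trailing_p + 1
                else:
                    total_span = span
                if total_span > L:
                    continue
                start = int(rng.integers(0, L - total_span + 1))
                pos = start
                anchors.append(pos)
                for g in gaps:
                    pos += g + 1
                    anchors.append(pos)
                for p in anchors:
                    seq[p] = "C"
                    reserved[p] = True
                for off in extra_positions:
                    seq[start + off] = "C"
                    reserved[start + off] = True
                if trailing_p is not None:
                    seq[start + trailing_p] = "P"
                    reserved[start + trailing_p] = True

            tm_segments: List[Tuple[int, int]] = []
            if spec.tm_plan is not None:
                tp = spec.tm_plan
                s1 = int(rng.integers(0, tp.margin + 1))
                e2 = L - int(rng.integers(0, tp.margin + 1))
                segs = [(s1, s1 + tp.segment_length),
                        (e2 - tp.segment_length, e2)][:tp.n_segments]
                ok = all(not reserved[a:b].any() and 0 <= a < b <= L for a, b in segs)
                if not ok:
                    continue
                for a, b in segs:
                    seq[a:b] = np.array(list(HYDROPHOBIC))[
                        rng.integers(0, len(HYDROPHOBIC), size=b - a)]
                    reserved[a:b] = True
                tm_segments = segs

            # ordered motif placement on anchor-free positions
            my_motifs = [(rank + 1, m) for rank, m in enumerate(spec.motif_plan)
                         if i in carriers[rank]]
            free = ~reserved
            sites: List[Tuple[int, int]] = []
            lo = 0
            feasible = True
            for k, (rank, m) in enumerate(my_motifs):
                w = len(m.consensus)
                rest = [len(mm.consensus) for _, mm in my_motifs[k + 1:]]
                cands = [p for p in range(lo, L - w + 1)
                         if free[p:p + w].all()
                         and _greedy_earliest(rest, free & _window_mask(L, p, w), p + w)]
                if not cands:
                    feasible = False
                    break
                p = int(cands[rng.integers(0, len(cands))])
                seq[p:p + w] = list(m.consensus)
                free[p:p + w] = False
                sites.append((rank, p))
                lo = p + w
            if not feasible:
                continue

            rec_id = f"{spec.family}_{i + 1:03d}"
            records.append(SequenceRecord(rec_id, "".join(seq),
                                          f"synthetic {spec.family}", "protein"))
            truths[rec_id] = RecordTruth(spec.family, anchors, sites,
                                         [tuple(s) for s in tm_segments])
            break
        else:
            raise ValueError(
                f"infeasible placement for record {i} of family {spec.family} "
                f"(length too short for scaffold + motifs)")

    truth = SyntheticTruth(
        records=truths,
        motif_consensus={r + 1: m.consensus for r, m in enumerate(spec.motif_plan)},
    )
    return records, truth


def _window_mask(L: int, p: int, w: int) -> np.ndarray:
    m = np.ones(L, dtype=bool)
    m[p:p + w] = False
    return m


# --------------------------------------------------------------------------
# transcripts
# --------------------------------------------------------------------------

@dataclass
class TranscriptTruth:
    protein_id: str
    orf_start: int           # 0-based half-open, on the emitted forward strand
    orf_end: int
    frame: int
    orf_protein: str         # translation of the embedded ORF (leading Met)


def _disrupt_long_orfs(seq: list, protected: Tuple[int, int],
                       rng: np.random.Generator, max_run: int = 30) -> None:
    """Insert stop codons into UTR regions so no reading frame keeps a
    stopless run longer than ``max_run`` codons outside the planted ORF."""
    L = len(seq)
    lo, hi = protected
    for _ in range(10):
        changed = False
        for strand in (1, -1):
            for offset in range(3):
                if strand == 1:
                    frame_start = offset
                    stops = STOP_CODONS
                else:
                    frame_start = (L - offset) % 3
                    stops = _REV_STOPS
                run = 0
                for p in range(frame_start, L - 2, 3):
                    codon = "".join(seq[p:p + 3])
                    inside_utr = p + 3 <= lo or p >= hi
                    if codon in stops:
                        run = 0
                        continue
                    run += 1
                    if run > max_run and inside_utr:
                        seq[p:p + 3] = list(stops[rng.integers(0, len(stops))])
                        run = 0
                        changed = True
        if not changed:
            return


def generate_transcript(protein: SequenceRecord, utr5: int = 150, utr3: int = 150,
                        strand: str = "+", seed: int = 0
                        ) -> Tuple[SequenceRecord, TranscriptTruth]:
    """Embed a reverse-translated ORF for ``protein`` between random UTRs.

    Codons are drawn uniformly per residue; a stop codon is appended and the
    ORF begins with ATG (merged with a leading Met).  UTRs carry in-frame
    stops disrupting spurious long ORFs, and the 5' UTR ends with an
    in-frame stop so the stop-to-stop interval equals the planted ORF.  On
    the minus strand the whole transcript is reverse-complemented.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    rng = np.random.default_rng(seed)
    residues = protein.residues
    orf_protein = residues if residues.startswith("M") else "M" + residues
    codons = ["ATG"]
    for aa in orf_protein[1:]:
        options = _CODONS_FOR[aa] if aa in _CODONS_FOR else ["NNN"]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    orf = "".join(codons)

    nts = np.array(list("ACGT"))
    u5 = list(nts[rng.integers(0, 4, size=utr5)])
    u3 = list(nts[rng.integers(0, 4, size=utr3)])
    if utr5 >= 3:
        u5[-3:] = list(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    seq = u5 + list(orf) + u3
    orf_start, orf_end = utr5, utr5 + len(orf)
    _disrupt_long_orfs(seq, (orf_start, orf_end), rng)

    forward = "".join(seq)
    L = len(forward)
    if strand == "+":
        emitted = forward
        start, end = orf_start, orf_end
        frame = start % 3 + 1
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        emitted = "".join(comp[c] for c in reversed(forward))
        start, end = L - orf_end, L - orf_start
        frame = -((L - end) % 3 + 1)

    rec = SequenceRecord(f"{protein.id}_tx", emitted,
                         f"synthetic transcript of {protein.id} ({strand})", "dna")
    return rec, TranscriptTruth(protein.id, start, end, frame, orf_protein)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def generate_labeled_tree(records: Sequence[SequenceRecord],
                          pattern_labels: Sequence[str], seed: int = 0) -> dendropy.Tree:
    """A rooted random binary tree over the record ids.

    Records sharing a pattern label are joined into a subtree first, so
    planted label structure is reflected in the topology (useful for
    clade-homogeneity studies); group subtrees are then joined randomly.
    """
    if len(records) != len(pattern_labels):
        raise ValueError("one label per record required")
    check_unique_ids(records)
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(rec):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(rec.id)
        node.edge.length = float(rng.uniform(0.05, 1.0))
        return node

    def join_all(nodes):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            parent.edge.length = float(rng.uniform(0.05, 1.0))
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        return nodes[0]

    groups: Dict[str, list] = {}
    for rec, lab in zip(records, pattern_labels):
        groups.setdefault(lab, []).append(leaf(rec))
    roots = [join_all(nodes) for _, nodes in sorted(groups.items())]
    tree.seed_node = join_all(roots)
    tree.is_rooted = True
    return tree


# --------------------------------------------------------------------------
# canonical synthetic study sets (shared by tests and the acceptance script)
# --------------------------------------------------------------------------

CLASSIC_MOTIF = "WDYKHGNE"
MINUSC_UNIVERSAL = ("FWEHKYDG", "LPQRSTVN", "YGKWNEHD")
MINUSC_SUBSET = "DHYWGQEK"
CSP_MOTIFS = ("WEHKYDGN", "FPLQRSTV", "YGWNHEKD")


def make_classic_obp_set(n: int = 30, seed: int = 1,
                         length_range=(130, 160)) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """Classic-OBP study set: one universal planted 8-mer motif."""
    spec = FamilySpec("classic_obp", n=n, length_range=length_range,
                      motif_plan=[MotifPlan(CLASSIC_MOTIF, 1.0)], seed=seed)
    return generate_family_set(spec)


def make_minusc_obp_set(n: int = 51, n_subset: int = 46, seed: int = 4,
                        length_range=(155, 195)) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """Minus-C study set: three universal 8-mers plus one planted in a
    deterministic subset of ``n_subset`` records."""
    plan = [MotifPlan(c, 1.0) for c in MINUSC_UNIVERSAL]
    plan.append(MotifPlan(MINUSC_SUBSET, n_subset / n))
    spec = FamilySpec("minusc_obp", n=n, length_range=length_range,
                      motif_plan=plan, seed=seed)
    return generate_family_set(spec)


def make_csp_set(n: int = 20, seed: int = 5,
                 length_range=(120, 150)) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """CSP study set: three universal non-overlapping planted 8-mers."""
    spec = FamilySpec("csp", n=n, length_range=length_range,
                      motif_plan=[MotifPlan(c, 1.0) for c in CSP_MOTIFS], seed=seed)
    return generate_family_set(spec)


def make_snmp_set(n: int = 12, seed: int = 7, motif_width: int = 45,
                  n_motifs: int = 4,
                  length_range=(330, 380)) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """SNMP study set: two terminal hydrophobic stretches and four long
    universal motifs in the extracellular loop."""
    rng = np.random.default_rng(seed + 104729)
    letters = np.array([a for a in AA if a != "C"])
    plan = [MotifPlan("".join(letters[rng.integers(0, len(letters), size=motif_width)]), 1.0)
            for _ in range(n_motifs)]
    spec = FamilySpec("snmp", n=n, length_range=length_range,
                      motif_plan=plan, seed=seed)
    return generate_family_set(spec)
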