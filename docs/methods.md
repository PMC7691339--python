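# Methods

`cysmotif` implements the sequence-analysis core of a nonreceptor
chemosensory-gene survey: classifying candidate proteins into the insect
odorant-binding protein (OBP), chemosensory protein (CSP) and sensory
neuron membrane protein (SNMP) families, discovering ungapped sequence
motifs de novo, condensing them into per-protein motif patterns, and
placing those patterns on a phylogeny.  This note records the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Scaffold model and subclass rules

A family scaffold is an ordered list of anchors, each a required residue
preceded by a bounded spacer (`X_min–max`).  The shipped profiles encode the
conserved-cysteine scaffolds reported for Coleoptera:

| profile | anchors | spacers |
|---|---|---|
| classic OBP | 6 × C | 23–44, 3, 36–43, 8–12, 8 |
| minus-C OBP | 4 × C | 27–48, 36–43, 17–21 (derived, see below) |
| CSP | 4 × C | 6, 18, 2 |

Matching enumerates, in lexicographic order, every anchor-position tuple
satisfying residue and gap constraints; patterns are matched anywhere in the
sequence because signal-peptide boundaries are not always predictable (one
of the study proteins lacks a predicted signal peptide), and signal-peptide
prediction is out of scope.

The minus-C subclass is defined in the literature by the *absence* of
cysteines C2 and C5; no explicit minus-C spacing is published.  The shipped
minus-C profile is therefore derived mechanically from the classic profile:
deleting an anchor merges its flanking gaps by summing their bounds plus
one for the absorbed anchor position.  The derivation is overridable in the
pattern YAML.

Subclass calls use the precedence **plus-C > classic > minus-C**.  A classic
match always embeds a cysteine subset compatible with the minus-C profile,
and plus-C is "classic plus extras", so precedence is what makes the three
counts mutually exclusive.  The plus-C rule requires a classic match, at
least `min_extra_cys` further cysteines strictly downstream of C6, and a
proline after the last of them.  The default `min_extra_cys = 7` matches the
one plus-C archetype characterised in the source data (family-wide
descriptions cite 4–6 extra cysteines; the parameter is configurable).
Every call reports the total cysteine count so users can audit assignments.

## Transmembrane screen (SNMP topology)

The SNMP families are CD36-like: two transmembrane helices near the termini
with a long extracellular loop.  Dedicated TM predictors are external
tools; the screen here is a deliberate in-house stand-in: the sliding-window
mean of Kyte–Doolittle hydropathy indices (window 19, threshold 1.6 —
standard hydropathy-screen values), with maximal above-threshold runs of
window starts merged into segments when their windows overlap.  A protein is
called SNMP-like when it shows exactly two segments, one starting in the
N-terminal quarter and one ending in the C-terminal quarter, separated by a
loop of ≥ 100 residues.  The SNMP1/SNMP2 subfamily split is *not* called:
in the literature it is resolved by phylogeny, not by a sequence rule.

## ORF extraction

Six-frame, stop-to-stop, with a minimum protein length in residues
(default 100, the common convention for transcriptome ORF prediction) and
optional trimming to the first ATG.  Dangling ORFs that run off a sequence
end are reported and flagged because fragmentary transcripts are common in
de novo assemblies.  Ambiguous codons translate to `X`.  Homology-based ORF
retention and coding-potential models are out of scope.  Ordering is
deterministic: descending protein length, ties by frame (+1,+2,+3,−1,−2,−3)
then start.

## Motif discovery

The site model is ZOOPS (zero or one occurrence per sequence), matching
both the default of the standard motif-discovery tools and the fingerprint
semantics (a motif is present or absent per protein).  Parameters per
round:

* widths: every integer in `[minw, maxw]` (defaults 6–10 for OBP/CSP,
  45–95 for SNMP; an explicit width list or stride is available for wide
  ranges, where the fitted motif is insensitive to ±5 in width),
* starts: every distinct valid window of the data seeds a candidate start
  (identity 0.6 on the seed residue); candidates are ranked by a one-pass
  ZOOPS likelihood screen computed with a single one-hot matrix product,
  and EM runs to convergence from the best 3.  When starts must be capped,
  repeated windows are kept first — multiplicity is itself motif evidence —
  with seeded random tie-breaking,
* EM: pseudocount 0.01·background per cell, relative tolerance 1e-6, max
  500 iterations.  The tracked objective is the penalised (MAP) likelihood
  ratio, which EM ascends monotonically; with the tiny pseudocount it is
  numerically indistinguishable from the raw LLR,
* width selection: best LLR per free parameter, LLR/(19·w).  The
  per-sequence ZOOPS normalisation (−log m_i) makes this criterion peak at
  the planted width rather than saturating across widths,
* masking: the accepted motif's maximum-posterior site is replaced by `X`
  in every sequence with posterior presence ≥ 0.5; `X` windows are excluded
  from subsequent starts, sites, and background counts.

### Significance

Significance is an explicit empirical null, not an analytic E-value (the
E-values of existing tools are not reproducible without reimplementing
their internals; an explicit null is transparent).  `motif_significance`
shuffles residues within each sequence and reports the add-one estimate
p = (1 + #exceedances)/(1 + n_shuffles).  The test statistic is the best
LLR found by a *fixed capped-start fitting procedure* at the motif's width,
recomputed both on the observed data and on every shuffled dataset.
Re-running the same procedure on both sides keeps the statistic
exchangeable under the null — the p-value stays calibrated no matter how
hard the reported model itself was optimised — which the calibration test
verifies empirically (p uniform on background-only data).

Inside `discover_motifs` the per-width p is Šidák-corrected for the number
of widths examined, and a motif is accepted when the corrected p is at most
`max(p_threshold, smallest attainable p)`.  An empirical null of B shuffles
cannot produce p below ≈ n_widths/(B+1); with the default B = 499 and a
threshold of 1e-4 the rule therefore reduces to "keep a motif only if no
shuffled dataset's refit ever reaches its LLR", and rejection can stop at
the first exceedance.  The false-acceptance rate this implies
(≈ n_widths/(B+1) per round) is what the noise test bounds.

### Scanning and fingerprints

Accepted motifs are scanned back over the unmasked sequences; windows
scoring at least 60% of the motif's maximum attainable log-odds (base 2)
are reported, greedily non-overlapping per motif.  Cross-motif overlaps are
resolved by score *per column*, so a wide weak match cannot displace a
compact high-information one.  A fingerprint is the ordered (by start) list
of motifs present; a motif occurring twice keeps its best occurrence
(ZOOPS semantics).  Identical fingerprints form numbered pattern groups
(`1c`, `2c`, … by descending count, ties by first-member input order).
Motif ids are per-run ranks; cross-run comparisons should use consensus
strings.

## Tree annotation

Tree inference (Bayesian or otherwise) is fully delegated to external
software; any single-tree newick is consumed, polytomies included.  Leaves
are coloured by pattern rank from a fixed 20-colour palette (overflow wraps
with a warning) and written as an iTOL `DATASET_COLORSTRIP` text dataset.
Clade–pattern concordance is quantified per internal node as the
majority-pattern fraction of its annotated leaves; the root's value equals
the global majority fraction.

## Synthetic data: what it emulates, and what it does not

The generator produces labeled families with the statistical structure the
analysis assumes: exactly one scaffold instance per record (spacers uniform
within the published bounds), planted exact-consensus motifs at configured
prevalences in a fixed left-to-right order, and, for SNMP, two hydrophobic
(I/L/V/F) terminal stretches of 25 residues.  Ground truth (anchor
positions, motif sites, TM segments) is emitted with every set.

Deliberate idealisations, chosen so that clean-data truth labels are
unambiguous:

* background cysteine frequency outside anchors is 0 by default — the
  families are *defined* by conserved Cys counts, so stray cysteines would
  confound the labels (configurable),
* the SNMP loop background halves the hydrophobic residue frequencies,
  emulating a hydrophilic extracellular loop; otherwise random loops throw
  spurious TM windows at the known false-positive rate of any hydropathy
  screen,
* motif carriers are assigned deterministically (first round(p·n) records
  of a seeded shuffle), making planted prevalences exact rather than
  binomial,
* planted motifs are exact consensus copies (information content ≈ 34 bits
  for an 8-mer), well above the ≥ 10-bit regime the recovery property
  tests target.

Real data differ in every one of these respects: residue composition is
not uniform, motif instances degenerate, prevalences noisy, and cysteines
occur outside scaffolds.  Passing the synthetic suites therefore shows the
*machinery* is correct (patterns match what they should, EM recovers what
was planted, prevalences are counted right) — not that real transcriptome
noise is handled; the scaled-down study sets are calibration fixtures, not
simulations of a transcriptome.  One consequence worth knowing: on
synthetic SNMP sets the planted TM stretches are themselves real, alignable,
shuffle-destroyed structure, and discovery may legitimately accept extra
low-prevalence motifs reflecting them; the planted loop motifs remain the
only universal ones.

Transcripts embed a reverse-translated ORF (`ATG` + uniform codon per
residue + stop; a leading Met is encoded by the start codon) between random
UTRs.  The 5' UTR ends with an in-frame stop so the stop-to-stop interval
equals the planted ORF, and both UTRs are post-processed so no frame keeps
a stopless run longer than 30 codons outside the ORF.

## Problem sizes and defaults used in the shipped analyses

The canonical study sets are scaled to desk size as the package's own
benchmark conditions: classic OBP n=30 (one universal 8-mer), minus-C n=51
with one motif in 46 (prevalence 46/51 = 90.2%), CSP n=20 (three universal
8-mers), SNMP n=12 (four 45-mers plus two TM stretches).  Discovery runs
with 499 null shuffles (99 and a width stride for the wide SNMP motifs);
the acceptance script reruns the first three sets end to end from a single
command-line seed.

## Known limitations

* The hydropathy screen is a heuristic, far below a dedicated TM predictor
  on real membrane proteins (no helix model, no topology grammar).
* The empirical null prices motif significance relative to within-sequence
  composition only; correlated columns or repeat families in real proteins
  are not represented in the null.
* Greedy masking can split a long repeated element into adjacent motifs.
* No gapped or palindromic motifs; no OOPS/ANR site models.
* Pattern groups require exact fingerprint identity; near-miss patterns are
  deliberately kept distinct.
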