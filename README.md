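# cysmotif

Conserved-cysteine scaffold classification and de novo motif fingerprinting
for insect chemosensory protein families.

Bark beetles and other insects sense their chemical world through a small
set of nonreceptor olfactory proteins: odorant-binding proteins (OBPs) and
chemosensory proteins (CSPs), which solubilize and carry hydrophobic
odorants, and sensory neuron membrane proteins (SNMPs), CD36-family
membrane proteins implicated in pheromone detection.  Annotating these
families in a new transcriptome is a sequence-analysis exercise with a
specific shape: the families are defined not by overall similarity but by
**conserved-cysteine scaffolds** — ordered cysteines at stereotyped
spacings — and by the **motif patterns** their members share.  `cysmotif`
implements that exercise as a tested, reusable pipeline for people
annotating chemosensory gene repertoires:

* six-frame ORF extraction from transcripts (stop-to-stop, minimum length,
  optional ATG trimming);
* scaffold classification against the Coleoptera profiles
  `C1-X23–44-C2-X3-C3-X36–43-C4-X8–12-C5-X8-C6` (classic OBP, with the
  minus-C subclass lacking C2/C5 and the plus-C subclass adding ≥7 extra
  cysteines and a conserved proline) and `C1-X6-C2-X18-C3-X2-C4` (CSP),
  plus a Kyte–Doolittle hydropathy screen for the SNMP two-TM topology;
* de novo ungapped motif discovery by ZOOPS expectation–maximization with
  an explicit residue-shuffle significance null;
* per-protein **motif fingerprints** (the ordered list of motifs present)
  grouped into frequency-ranked patterns (`1c`, `2c`, …);
* annotation of those patterns onto any newick phylogeny (iTOL colorstrip
  output) with a clade-homogeneity summary;
* a synthetic-data generator that emits labeled families with ground truth,
  so every stage is testable offline.

All coordinates are 0-based, half-open (the scaffold prose above is the
field's 1-based notation; spacer counts are identical in both).
The model details, defaults and design decisions are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a 12-protein synthetic classic-OBP family carrying one universal
8-mer motif and a second motif in half the records, then run the full
pipeline:

```sh
cysmotif generate --family classic_obp -n 12 \
    --length-min 140 --length-max 170 \
    --motif WDYKHGNE:1.0 --motif FPLQRSTV:0.5 --seed 13 \
    --out-fasta obp.fa --out-truth truth.tsv --out-tree obp.nwk
cysmotif pipeline obp.fa --family obp --seed 2 --tree obp.nwk --outdir out
```

The run logs `pipeline complete: 2 motifs, 2 patterns` and writes four
files.  `out/classification.tsv` shows every record matched the classic
scaffold with its six anchored cysteines:

```
id               family  subclass  total_cys
classic_obp_001  obp     classic   6
classic_obp_002  obp     classic   6
...
```

`out/prevalence.json` reports the fraction of proteins carrying each
discovered motif — motif 1 (consensus `WDYKHGNE`) in 100% of records,
motif 2 in exactly the planted half:

```json
{"1": 1.0, "2": 0.5}
```

and `out/patterns.tsv` groups the per-protein fingerprints into two motif
patterns, ranked by membership:

```
pattern_id  ordered_motifs  count  fraction
1c          1-2             6      0.5000
2c          1               6      0.5000
```

Six proteins show motif 1 followed by motif 2 (pattern `1c`), six show
motif 1 alone (pattern `2c`) — the planted design recovered exactly.
`out/colorstrip.txt` is an iTOL `DATASET_COLORSTRIP` dataset colouring each
tree leaf by its pattern.

The same stages are importable as a library
(`cysmotif.discover_motifs`, `cysmotif.classify_obp`,
`cysmotif.run_family_pipeline`, …) and each CLI subcommand (`generate`,
`orfs`, `classify`, `motifs`, `fingerprint`, `annotate-tree`, `pipeline`)
wraps one of them.

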