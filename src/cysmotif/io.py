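"""FASTA and newick I/O.

FASTA parsing is delegated to Biopython's ``SeqIO`` and newick parsing to
dendropy; this module adds the validation contracts the pipeline relies on
(non-empty input, unique ids, alphabet checks with positions).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, List

import dendropy
from Bio import SeqIO

from .records import Alphabet, SequenceRecord, check_unique_ids


def read_fasta(path, alphabet: Alphabet = "protein") -> List[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The id is the header token before the first whitespace; the remainder is
    kept as the description.  Residues are upper-cased.  Raises ``ValueError``
    on an empty file, a duplicated id, or a residue outside the declared
    alphabet (reported with its 0-based position).
    """
    path = Path(path)
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        desc = seq_rec.description
        if desc.startswith(seq_rec.id):
            desc = desc[len(seq_rec.id):].strip()
        records.append(
            SequenceRecord(
                id=seq_rec.id,
                residues=str(seq_rec.seq).upper(),
                description=desc,
                alphabet=alphabet,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns.

    ``read_fasta`` inverts this for any valid record set.  An empty record
    list writes an empty file.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_newick(path) -> dendropy.Tree:
    """Read a single-tree newick file.

    Leaf labels are preserved verbatim.  Raises ``ValueError`` on a parse
    error (unbalanced parentheses etc.) or duplicated leaf labels.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise ValueError(f"duplicate leaf labels in {path}: {exc}") from exc
        raise ValueError(f"newick parse error in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in {path}: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def sha256_of(path) -> str:
    """Hex digest of a file, logged with every CLI run for provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
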