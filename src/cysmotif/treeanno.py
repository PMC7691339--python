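"""Placing motif-pattern fingerprints onto a phylogenetic tree.

Tree inference itself is out of scope (delegated to external Bayesian/ML
software); this module annotates the leaves of any user-supplied newick
tree with pattern ids, emits an iTOL ``DATASET_COLORSTRIP`` text dataset,
and quantifies clade-pattern concordance as the majority-pattern fraction
per internal node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import dendropy

from .fingerprint import PatternGroup

#: Fixed palette indexed by pattern rank; overflow wraps (with a warning in
#: the emitted file header) so output stays deterministic and diffable.
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
]


@dataclass(frozen=True)
class TreeAnnotation:
    leaf_label: str
    pattern_id: str
    color: str


@dataclass(frozen=True)
class CladeHomogeneity:
    node_id: str
    n_leaves: int
    majority_pattern: str
    homogeneity: float       # majority pattern count / annotated leaves


def _pattern_rank(pattern_id: str) -> int:
    digits = "".join(ch for ch in pattern_id if ch.isdigit())
    return int(digits) if digits else 1


def annotate_leaves(tree: dendropy.Tree, pattern_groups: Sequence[PatternGroup]
                    ) -> Tuple[List[TreeAnnotation], List[str]]:
    """One annotation per tree leaf covered by a pattern group.

    Returns (annotations, warnings); leaves absent from every group are
    reported as warnings, never as errors.  Color assignment is a fixed
    palette indexed by pattern rank.
    """
    by_member: Dict[str, PatternGroup] = {}
    for g in pattern_groups:
        for member in g.member_ids:
            by_member[member] = g
    annotations: List[TreeAnnotation] = []
    warnings: List[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        g = by_member.get(label)
        if g is None:
            warnings.append(f"leaf {label!r} has no pattern assignment")
            continue
        color = PALETTE[(_pattern_rank(g.pattern_id) - 1) % len(PALETTE)]
        annotations.append(TreeAnnotation(label, g.pattern_id, color))
    n_patterns = len({g.pattern_id for g in pattern_groups})
    if n_patterns > len(PALETTE):
        warnings.append(f"{n_patterns} patterns exceed the {len(PALETTE)}-color "
                        "palette; colors wrap")
    return annotations, warnings


def write_colorstrip(annotations: Sequence[TreeAnnotation], path,
                     dataset_label: str = "motif patterns",
                     warnings: Sequence[str] = ()) -> None:
    """Write an iTOL DATASET_COLORSTRIP annotation file."""
    with open(path, "w") as fh:
        fh.write("DATASET_COLORSTRIP\n")
        fh.write("SEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\t{dataset_label}\n")
        fh.write("COLOR\t#000000\n")
        for w in warnings:
            fh.write(f"#WARNING\t{w}\n")
        fh.write("DATA\n")
        for a in annotations:
            fh.write(f"{a.leaf_label}\t{a.color}\t{a.pattern_id}\n")


def read_colorstrip(path) -> List[TreeAnnotation]:
    """Parse a file written by :func:`write_colorstrip` (round-trip)."""
    annotations = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "DATA":
                in_data = True
                continue
            if not in_data or not line or line.startswith("#"):
                continue
            label, color, pattern_id = line.split("\t")
            annotations.append(TreeAnnotation(label, pattern_id, color))
    return annotations


def clade_homogeneity(tree: dendropy.Tree,
                      annotations: Sequence[TreeAnnotation]) -> List[CladeHomogeneity]:
    """Majority-pattern fraction for every internal node with at least two
    annotated leaves (nodes without annotated leaves are skipped).

    The root's homogeneity equals the global majority-pattern fraction.
    """
    pattern_of = {a.leaf_label: a.pattern_id for a in annotations}
    out: List[CladeHomogeneity] = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        patterns = [pattern_of[l.taxon.label] for l in node.leaf_iter()
                    if l.taxon.label in pattern_of]
        if len(patterns) < 2:
            continue
        counts: Dict[str, int] = {}
        for p in patterns:
            counts[p] = counts.get(p, 0) + 1
        majority = max(sorted(counts), key=lambda k: counts[k])
        out.append(CladeHomogeneity(f"n{idx}", len(patterns), majority,
                                    counts[majority] / len(patterns)))
    return out
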