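"""Spacing-constrained conserved-residue scaffold patterns.

A scaffold pattern is an ordered list of anchors, each a required residue
preceded by a bounded-length spacer (``X_min-max`` in the field's prose
notation).  The shipped profiles encode the conserved-cysteine scaffolds of
the insect odorant-binding protein (OBP) and chemosensory protein (CSP)
families as reported for Coleoptera:

* classic OBP:  C1-X(23-44)-C2-X(3)-C3-X(36-43)-C4-X(8-12)-C5-X(8)-C6
* CSP:          C1-X(6)-C2-X(18)-C3-X(2)-C4
* minus-C OBP:  classic scaffold with C2 and C5 absent; its gap bounds are
  derived by summing each deleted anchor's flanking gaps plus one for the
  absorbed anchor position: C1-X(27-48)-C3-X(36-43)-C4-X(17-21)-C6
* plus-C OBP:   the classic scaffold plus a C-terminal extension of extra
  cysteines (default minimum 7, the archetype count) ending in a conserved
  proline.

Patterns can be overridden from a YAML file with the same structure as the
shipped ``data/patterns.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import yaml


@dataclass(frozen=True)
class Anchor:
    """One required residue; ``gap_min``/``gap_max`` bound the spacer
    *preceding* it (both ignored on the first anchor)."""

    residue: str
    gap_min: int = 0
    gap_max: int = 0

    def __post_init__(self):
        if len(self.residue) != 1 or not self.residue.isalpha():
            raise ValueError(f"anchor residue must be one letter, got {self.residue!r}")
        if self.gap_min > self.gap_max:
            raise ValueError(f"anchor {self.residue}: gap_min > gap_max")
        if self.gap_min < 0:
            raise ValueError(f"anchor {self.residue}: negative gap")


@dataclass(frozen=True)
class Extras:
    """C-terminal extension requirement (the plus-C rule): at least
    ``min_extra`` further copies of ``residue`` after the last anchor, and a
    required trailing residue after the last of them."""

    residue: str = "C"
    min_extra: int = 7
    trailing_residue: Optional[str] = "P"


@dataclass(frozen=True)
class ScaffoldPattern:
    name: str
    anchors: Tuple[Anchor, ...]
    extras: Optional[Extras] = None

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("pattern needs at least one anchor")
        object.__setattr__(self, "anchors", tuple(self.anchors))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_bounds(self) -> Tuple[int, int]:
        """(min, max) total span in residues from first to last anchor,
        inclusive of the anchors themselves."""
        lo = hi = 1
        for a in self.anchors[1:]:
            lo += a.gap_min + 1
            hi += a.gap_max + 1
        return lo, hi

    def gap_string(self) -> str:
        parts = [self.anchors[0].residue + "1"]
        for i, a in enumerate(self.anchors[1:], start=2):
            g = (f"{a.gap_min}" if a.gap_min == a.gap_max
                 else f"{a.gap_min}-{a.gap_max}")
            parts.append(f"X({g})-{a.residue}{i}")
        return "-".join(parts)


@dataclass(frozen=True)
class ScaffoldMatch:
    """One placement of a pattern: strictly increasing anchor indices whose
    consecutive differences minus one respect each anchor's gap bounds."""

    pattern_name: str
    anchor_positions: Tuple[int, ...]

    @property
    def span(self) -> Tuple[int, int]:
        return self.anchor_positions[0], self.anchor_positions[-1] + 1


def _cys(gap_min: int, gap_max: int | None = None) -> Anchor:
    return Anchor("C", gap_min, gap_max if gap_max is not None else gap_min)


def derive_minus_pattern(classic: ScaffoldPattern, drop: Sequence[int],
                         name: str = "minusc_obp") -> ScaffoldPattern:
    """Delete anchors (1-based ranks in ``drop``) from ``classic``, merging
    each deleted anchor's flanking gaps by summing bounds plus one for the
    absorbed anchor position."""
    drop_set = set(drop)
    kept: List[Anchor] = []
    carry_min = carry_max = 0
    for rank, a in enumerate(classic.anchors, start=1):
        if rank in drop_set:
            if rank == 1:
                raise ValueError("cannot delete the first anchor")
            carry_min += a.gap_min + 1
            carry_max += a.gap_max + 1
            continue
        kept.append(Anchor(a.residue, a.gap_min + carry_min, a.gap_max + carry_max))
        carry_min = carry_max = 0
    return ScaffoldPattern(name, tuple(kept))


CLASSIC_OBP = ScaffoldPattern(
    "classic_obp",
    (
        _cys(0),          # C1
        _cys(23, 44),     # C2
        _cys(3),          # C3
        _cys(36, 43),     # C4
        _cys(8, 12),      # C5
        _cys(8),          # C6
    ),
)

MINUSC_OBP = derive_minus_pattern(CLASSIC_OBP, drop=(2, 5))

PLUSC_EXTRAS = Extras(residue="C", min_extra=7, trailing_residue="P")

CSP = ScaffoldPattern(
    "csp",
    (
        _cys(0),        # C1
        _cys(6),        # C2
        _cys(18),       # C3
        _cys(2),        # C4
    ),
)

BUILTIN_PATTERNS = {
    "classic_obp": CLASSIC_OBP,
    "minusc_obp": MINUSC_OBP,
    "csp": CSP,
}


def _pattern_from_dict(name: str, d: dict) -> ScaffoldPattern:
    anchors = tuple(
        Anchor(a["residue"], a.get("gap_min", 0), a.get("gap_max", a.get("gap_min", 0)))
        for a in d["anchors"]
    )
    extras = None
    if "extras" in d and d["extras"]:
        e = d["extras"]
        extras = Extras(e.get("residue", "C"), e.get("min_extra", 7),
                        e.get("trailing_residue", "P"))
    return ScaffoldPattern(name, anchors, extras)


def load_patterns(path=None) -> dict:
    """Load scaffold profiles from YAML; with no path, load the shipped
    defaults (which mirror :data:`BUILTIN_PATTERNS`)."""
    if path is None:
        text = resources.files("cysmotif").joinpath("data/patterns.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _pattern_from_dict(name, d) for name, d in raw.items()}
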