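"""LinearCode glycan notation: parsing, composition and Oxford-style tags.

LinearCode writes a glycan as a linear string with the reducing end rightmost,
single/double-letter residue symbols, anomeric+position linkage tokens and
parenthesised branches.  This module implements the N-glycan subset needed for
glycosylation reaction networks in mammalian (e.g. CHO) cells:

===========  ==============  =======
symbol       monosaccharide  example
===========  ==============  =======
``M``        Man             ``Ma3``
``GN``       GlcNAc          ``GNb2``
``A``        Gal             ``Ab4``
``F``        Fuc             ``Fa6``
``NN``       Neu5Ac          ``NNa3``
``G``        Glc             ``Gb3``
===========  ==============  =======

Compositional (Oxford-style) tags collapse structural isomers onto a single
composition-level name: ``M5`` (Man5GlcNAc2 high mannose), ``FA2``
(core-fucosylated agalactosylated biantennary), ``FA2G2S1`` and so on.  The
mapping LinearCode -> tag is many-to-one; the reverse lookup over a network is
provided by :func:`glycokin.network.tag_to_nodes`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOSACCHARIDES",
    "LinearCodeError",
    "CompositionError",
    "GlycanResidue",
    "GlycanStructure",
    "parse_linear_code",
    "composition_to_tag",
    "structure_tag",
    "count_residue_tokens",
]

#: Monosaccharides recognised by this dialect, in canonical order.
MONOSACCHARIDES = ("Man", "GlcNAc", "Gal", "Fuc", "Neu5Ac", "Glc")

_TWO_CHAR = {"GN": "GlcNAc", "NN": "Neu5Ac"}
_ONE_CHAR = {"M": "Man", "A": "Gal", "F": "Fuc", "G": "Glc"}

#: Grammar of every tag this module emits (B for bisecting GlcNAc is reserved
#: but never produced; see :func:`composition_to_tag`).
TAG_PATTERN = re.compile(r"^(F?A[0-9]+(G[0-9]+)?(S[0-9]+)?|M[0-9]+(A[0-9]+)?)$")


class LinearCodeError(ValueError):
    """Raised when a LinearCode string cannot be parsed."""


class CompositionError(ValueError):
    """Raised for negative or mutually inconsistent monosaccharide counts."""


@dataclass
class GlycanResidue:
    """A node of the parsed glycan tree (children are towards the non-reducing end)."""

    residue: str
    linkage: str | None = None
    children: list["GlycanResidue"] = field(default_factory=list)


@dataclass
class GlycanStructure:
    """A glycan as LinearCode string plus monosaccharide composition and tag."""

    linear_code: str
    composition: dict[str, int]
    tag: str | None = None
    root: GlycanResidue | None = field(default=None, repr=False, compare=False)

    @property
    def total_residues(self) -> int:
        return sum(self.composition.values())


def _tokenize(code: str) -> list[tuple[str, str]]:
    """Return (kind, text) tokens; kind in {residue, linkage, open, close}."""
    tokens: list[tuple[str, str]] = []
    i = 0
    n = len(code)
    while i < n:
        two = code[i : i + 2]
        ch = code[i]
        if two in _TWO_CHAR:
            tokens.append(("residue", two))
            i += 2
        elif ch in _ONE_CHAR or ch == "M":
            tokens.append(("residue", ch))
            i += 1
        elif ch in "ab":
            if i + 1 >= n or not code[i + 1].isdigit():
                raise LinearCodeError(
                    f"anomeric token {ch!r} at position {i} lacks a linkage digit"
                )
            j = i + 1
            while j < n and code[j].isdigit():
                j += 1
            tokens.append(("linkage", code[i:j]))
            i = j
        elif ch == "(":
            tokens.append(("open", ch))
            i += 1
        elif ch == ")":
            tokens.append(("close", ch))
            i += 1
        else:
            raise LinearCodeError(f"unknown residue symbol {ch!r} at position {i}")
    return tokens


def parse_linear_code(code: str) -> GlycanStructure:
    """Parse a LinearCode string into a :class:`GlycanStructure`.

    The composition is obtained by traversing the string; branch nesting is
    validated (balanced parentheses).  An optional trailing ``;`` is ignored.

    Raises
    ------
    LinearCodeError
        On empty input, unbalanced parentheses or an unknown residue symbol.
    """
    if code is None or not code.strip():
        raise LinearCodeError("empty LinearCode string")
    text = code.strip().rstrip(";")
    if not text:
        raise LinearCodeError("empty LinearCode string")

    tokens = _tokenize(text)
    stack: list[list[GlycanResidue]] = []
    pending: list[GlycanResidue] = []
    for kind, tok in tokens:
        if kind == "residue":
            node = GlycanResidue(residue=tok, children=pending)
            pending = [node]
        elif kind == "linkage":
            if not pending:
                raise LinearCodeError(f"linkage token {tok!r} without a residue")
            pending[-1].linkage = tok
        elif kind == "open":
            stack.append(pending)
            pending = []
        else:  # close
            if not stack:
                raise LinearCodeError("unbalanced parentheses: unexpected ')'")
            if len(pending) != 1:
                raise LinearCodeError("branch must contain exactly one chain")
            branch = pending[0]
            pending = stack.pop()
            pending.append(branch)
    if stack:
        raise LinearCodeError("unbalanced parentheses: missing ')'")
    if len(pending) != 1:
        raise LinearCodeError("dangling branch without an attachment residue")
    root = pending[0]

    composition = {name: 0 for name in MONOSACCHARIDES}
    todo = [root]
    while todo:
        node = todo.pop()
        name = _TWO_CHAR.get(node.residue) or _ONE_CHAR[node.residue]
        composition[name] += 1
        todo.extend(node.children)
    composition = {k: v for k, v in composition.items() if v > 0}

    struct = GlycanStructure(linear_code=code.strip(), composition=composition, root=root)
    try:
        struct.tag = structure_tag(struct)
    except CompositionError:
        # syntactically valid but biosynthetically inconsistent (e.g. more Gal
        # than antennae): parse succeeds, no tag is assigned
        struct.tag = None
    return struct


def count_residue_tokens(code: str) -> int:
    """Number of residue tokens in a LinearCode string (no tree construction)."""
    text = code.strip().rstrip(";")
    return sum(1 for kind, _ in _tokenize(text) if kind == "residue")


def _core_fucose(root: GlycanResidue) -> bool:
    # Core fucose: a Fuc attached directly to the reducing-end GlcNAc.
    if root.residue != "GN":
        return False
    return any(child.residue == "F" for child in root.children)


def _antenna_count(composition: dict[str, int]) -> int:
    # Antenna GlcNAc beyond the chitobiose core; bisecting GlcNAc (GnTIII) and
    # poly-LacNAc GlcNAc (iGnT) do not occur in the pruned CHO networks handled
    # here, so every extra GlcNAc opens an antenna.
    return max(composition.get("GlcNAc", 0) - 2, 0)


def composition_to_tag(
    structure_or_composition, core_fucose: bool = False, antennae: int = 0
) -> str:
    """Oxford-style compositional tag for a glycan composition.

    High-mannose structures (GlcNAc == 2, no Gal/Fuc/Neu5Ac) map to ``M<n>``;
    the trimmed Man3GlcNAc2 core maps to ``A0``.  Complex structures map to
    ``F?A<antennae>G<gal>S<sia>`` with the G/S parts present only for positive
    counts; hybrid structures retaining mannose (Man > 3 with antennae) map to
    ``M<man>A<antennae>`` (e.g. ``M5A1``).
    """
    if isinstance(structure_or_composition, GlycanStructure):
        comp = structure_or_composition.composition
    else:
        comp = dict(structure_or_composition)
    for name, count in comp.items():
        if name not in MONOSACCHARIDES:
            raise CompositionError(f"unknown monosaccharide {name!r}")
        if not isinstance(count, int) or count < 0:
            raise CompositionError(f"negative or non-integer count for {name}: {count}")
    if antennae < 0:
        raise CompositionError(f"antenna count must be >= 0, got {antennae}")

    man = comp.get("Man", 0)
    gn = comp.get("GlcNAc", 0)
    gal = comp.get("Gal", 0)
    fuc = comp.get("Fuc", 0)
    sia = comp.get("Neu5Ac", 0)

    if gal > antennae:
        raise CompositionError(
            f"composition has Gal={gal} exceeding antenna count {antennae}"
        )
    if sia > gal:
        raise CompositionError(f"composition has Neu5Ac={sia} exceeding Gal={gal}")

    if gn == 2 and gal == 0 and fuc == 0 and sia == 0:
        if man == 3:
            return "A0"  # trimmed core sorts with complex types
        return f"M{man}"

    prefix = "F" if core_fucose else ""
    if man > 3:
        # hybrid with retained mannose, e.g. M5A1
        return f"{prefix}M{man}A{antennae}"
    tag = f"{prefix}A{antennae}"
    if gal > 0:
        tag += f"G{gal}"
    if sia > 0:
        tag += f"S{sia}"
    return tag


def structure_tag(struct: GlycanStructure) -> str:
    """Tag for a parsed structure, deriving core-fucose and antenna flags."""
    if struct.root is None:
        raise CompositionError("structure has no parse tree; use composition_to_tag")
    return composition_to_tag(
        struct.composition,
        core_fucose=_core_fucose(struct.root),
        antennae=_antenna_count(struct.composition),
    )
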