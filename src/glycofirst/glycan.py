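"""Glycan compositions, rooted tree structures and glycan databases.

A glycan *composition* is a count vector over monosaccharide symbols
(H, N, F, A, G, aH, pH), compared componentwise: ``g <= G`` means g is a
subglycan of G.  A glycan *structure* is a rooted labeled tree whose root is
the reducing-end unit; it is serialized to a canonical string that is
invariant to sibling order, so two drawings of the same topology collapse to
one database entry.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .chem import (
    PROTON,
    SYMBOL_ORDER,
    UnknownMonosaccharideError,
    residue_mass_of,
)

__all__ = [
    "GlycanComposition",
    "GlycanNode",
    "GlycanStructure",
    "GlycanEntry",
    "GlycanDB",
    "MalformedGlycanError",
    "parse_composition",
    "parse_structure",
    "subcompositions",
    "oxonium_mz",
    "N_GLYCAN_CORE",
    "O_GLYCAN_CORE",
    "MAX_GLYCAN_ID",
]

MAX_GLYCAN_ID = 2**31 - 1  # glycan ids are packed into 31 bits of an int32

_IDX = {s: i for i, s in enumerate(SYMBOL_ORDER)}


class MalformedGlycanError(ValueError):
    """Raised for unparseable glycan strings or non-tree structures."""


@dataclass(frozen=True, order=False)
class GlycanComposition:
    """Immutable monosaccharide count vector aligned to ``SYMBOL_ORDER``."""

    counts: tuple[int, ...] = (0,) * len(SYMBOL_ORDER)

    def __post_init__(self) -> None:
        if len(self.counts) != len(SYMBOL_ORDER):
            raise ValueError("counts must align to the fixed symbol order")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative monosaccharide count")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GlycanComposition":
        counts = [0] * len(SYMBOL_ORDER)
        for sym, n in d.items():
            if sym not in _IDX:
                raise UnknownMonosaccharideError(sym)
            counts[_IDX[sym]] += n
        return cls(tuple(counts))

    def __getitem__(self, symbol: str) -> int:
        return self.counts[_IDX[symbol]]

    @property
    def total_units(self) -> int:
        return sum(self.counts)

    @property
    def mass(self) -> float:
        return sum(
            n * residue_mass_of(s) for s, n in zip(SYMBOL_ORDER, self.counts) if n
        )

    def __bool__(self) -> bool:
        return self.total_units > 0

    def __le__(self, other: "GlycanComposition") -> bool:
        return all(a <= b for a, b in zip(self.counts, other.counts))

    def __lt__(self, other: "GlycanComposition") -> bool:
        return self <= other and self.counts != other.counts

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            tuple(a + b for a, b in zip(self.counts, other.counts))
        )

    def __sub__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            tuple(a - b for a, b in zip(self.counts, other.counts))
        )

    def __str__(self) -> str:
        return "".join(
            f"{s}({n})" for s, n in zip(SYMBOL_ORDER, self.counts) if n
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanComposition({str(self) or 'empty'})"


EMPTY = GlycanComposition()

_COMP_TOKEN = re.compile(r"([A-Za-z]+)\((\d+)\)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse ``H(5)N(4)A(2)`` style composition strings."""
    text = text.strip()
    if not text:
        return EMPTY
    pos = 0
    counts: dict[str, int] = {}
    for m in _COMP_TOKEN.finditer(text):
        if m.start() != pos:
            raise MalformedGlycanError(f"bad composition string {text!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2))
        pos = m.end()
    if pos != len(text):
        raise MalformedGlycanError(f"bad composition string {text!r}")
    try:
        return GlycanComposition.from_dict(counts)
    except UnknownMonosaccharideError as exc:
        raise MalformedGlycanError(f"unknown symbol in {text!r}: {exc}") from None


# ---------------------------------------------------------------------------
# structures


class GlycanNode:
    """Tree node: one monosaccharide plus its outward (non-reducing) children."""

    __slots__ = ("symbol", "children")

    def __init__(self, symbol: str, children: Sequence["GlycanNode"] = ()) -> None:
        if symbol not in _IDX:
            raise UnknownMonosaccharideError(symbol)
        self.symbol = symbol
        self.children = list(children)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GlycanNode({self.symbol}, {len(self.children)} children)"


@dataclass(frozen=True)
class GlycanStructure:
    """Rooted glycan tree; root is the reducing-end unit attached to the peptide."""

    root: GlycanNode

    def canonical_string(self) -> str:
        return _canonical(self.root, set())

    @property
    def composition(self) -> GlycanComposition:
        counts = [0] * len(SYMBOL_ORDER)
        for node in self._walk():
            counts[_IDX[node.symbol]] += 1
        return GlycanComposition(tuple(counts))

    def _walk(self) -> Iterator[GlycanNode]:
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise MalformedGlycanError("cycle detected in glycan structure")
            seen.add(id(node))
            stack.extend(node.children)
            yield node

    def __str__(self) -> str:
        return self.canonical_string()


def _canonical(node: GlycanNode, onpath: set[int]) -> str:
    if id(node) in onpath:
        raise MalformedGlycanError("cycle detected in glycan structure")
    onpath.add(id(node))
    parts = sorted(_canonical(c, onpath) for c in node.children)
    onpath.discard(id(node))
    return "(" + node.symbol + "".join(parts) + ")"


def parse_structure(text: str) -> GlycanStructure:
    """Parse the nested-parenthesis canonical form, e.g. ``(N(N(H(H)(H))))``."""
    text = text.strip()
    node, pos = _parse_node(text, 0)
    if pos != len(text):
        raise MalformedGlycanError(f"trailing characters in glycan string {text!r}")
    return GlycanStructure(node)


_SYM = re.compile(r"[A-Za-z]+")


def _parse_node(text: str, pos: int) -> tuple[GlycanNode, int]:
    if pos >= len(text) or text[pos] != "(":
        raise MalformedGlycanError(f"expected '(' at position {pos} in {text!r}")
    m = _SYM.match(text, pos + 1)
    if not m:
        raise MalformedGlycanError(f"expected symbol at position {pos + 1} in {text!r}")
    symbol = m.group(0)
    pos = m.end()
    children = []
    while pos < len(text) and text[pos] == "(":
        child, pos = _parse_node(text, pos)
        children.append(child)
    if pos >= len(text) or text[pos] != ")":
        raise MalformedGlycanError(f"expected ')' at position {pos} in {text!r}")
    return GlycanNode(symbol, children), pos + 1


# ---------------------------------------------------------------------------
# enumeration


def subcompositions(G: GlycanComposition) -> list[GlycanComposition]:
    """All g <= G, ordered by (total units, counts lexicographically).

    The length is F = prod(G_i + 1); the ordering is the fixed row order of
    the localization score table, so it must be stable across runs.
    """
    ranges = [range(c + 1) for c in G.counts]
    subs = [GlycanComposition(t) for t in itertools.product(*ranges)]
    subs.sort(key=lambda g: (g.total_units, g.counts))
    return subs


def oxonium_mz(comp: GlycanComposition) -> float:
    """m/z of the singly protonated B/oxonium ion of a glycan fragment."""
    if not comp:
        raise ValueError("oxonium ion of an empty composition is undefined")
    return comp.mass + PROTON


# ---------------------------------------------------------------------------
# database

#: Reducing-end core Y ladder for N-glycans (Y0, +HexNAc, +HexNAc,
#: trimannosyl Hex steps).  Y0 (the naked peptide) is always core.
N_GLYCAN_CORE: frozenset[GlycanComposition] = frozenset(
    parse_composition(s) for s in ("", "N(1)", "N(2)", "H(1)N(2)", "H(2)N(2)", "H(3)N(2)")
)
#: O-glycans have no conserved core beyond Y0.
O_GLYCAN_CORE: frozenset[GlycanComposition] = frozenset([EMPTY])


@dataclass(frozen=True)
class GlycanEntry:
    """One database glycan: structure when known, otherwise composition only."""

    glycan_id: int
    composition: GlycanComposition
    structure: Optional[GlycanStructure] = None

    def __post_init__(self) -> None:
        if not (0 <= self.glycan_id <= MAX_GLYCAN_ID):
            raise ValueError(f"glycan id {self.glycan_id} does not fit in 31 bits")

    def y_compositions(self) -> list[GlycanComposition]:
        """All glycan parts of possible Y ions (always includes Y0 = empty).

        With a structure: compositions of all root-containing subtrees; with a
        composition only: every subcomposition.
        """
        if self.structure is None:
            return subcompositions(self.composition)
        seen = {EMPTY.counts, self.composition.counts}
        for counts in _subtree_compositions(self.structure.root):
            seen.add(counts)
        out = [GlycanComposition(c) for c in seen]
        out.sort(key=lambda g: (g.total_units, g.counts))
        return out


def _subtree_compositions(root: GlycanNode) -> set[tuple[int, ...]]:
    """Count vectors of all downward-closed subtrees containing ``root``."""

    def rec(node: GlycanNode) -> set[tuple[int, ...]]:
        base = [0] * len(SYMBOL_ORDER)
        base[_IDX[node.symbol]] = 1
        options: set[tuple[int, ...]] = {tuple(base)}
        for child in node.children:
            child_opts = rec(child) | {(0,) * len(SYMBOL_ORDER)}
            options = {
                tuple(a + b for a, b in zip(opt, c))
                for opt in options
                for c in child_opts
            }
        return options

    return rec(root)


@dataclass
class GlycanDB:
    """A glycan search space plus its designated core Y compositions."""

    entries: list[GlycanEntry]
    glyco_type: str = "N"  # "N" or "O"
    core_y_set: frozenset[GlycanComposition] = field(default=N_GLYCAN_CORE)

    def __post_init__(self) -> None:
        if self.glyco_type not in ("N", "O"):
            raise ValueError("glyco_type must be 'N' or 'O'")
        if EMPTY not in self.core_y_set:
            self.core_y_set = frozenset(self.core_y_set) | {EMPTY}
        ids = [e.glycan_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate glycan ids")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GlycanEntry]:
        return iter(self.entries)

    def is_core(self, comp: GlycanComposition) -> bool:
        return comp in self.core_y_set

    @classmethod
    def default_core(cls, glyco_type: str) -> frozenset[GlycanComposition]:
        return N_GLYCAN_CORE if glyco_type == "N" else O_GLYCAN_CORE

    @classmethod
    def from_entries(
        cls,
        items: Iterable[GlycanStructure | GlycanComposition | str],
        glyco_type: str = "N",
        core_y_set: Optional[frozenset[GlycanComposition]] = None,
    ) -> "GlycanDB":
        entries = []
        for i, item in enumerate(items):
            if isinstance(item, str):
                item = parse_structure(item) if item.startswith("(") else parse_composition(item)
            if isinstance(item, GlycanStructure):
                entries.append(GlycanEntry(i, item.composition, item))
            else:
                entries.append(GlycanEntry(i, item))
        return cls(entries, glyco_type, core_y_set or cls.default_core(glyco_type))

    @classmethod
    def read(
        cls,
        path: str | Path,
        glyco_type: str = "N",
        core_y_set: Optional[frozenset[GlycanComposition]] = None,
    ) -> "GlycanDB":
        """Read a ``id<TAB>canonical_string_or_composition`` text file."""
        entries = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                id_str, body = line.split("\t")
                gid = int(id_str)
                if body.startswith("("):
                    structure = parse_structure(body)
                    entries.append(GlycanEntry(gid, structure.composition, structure))
                else:
                    entries.append(GlycanEntry(gid, parse_composition(body)))
            except (ValueError, MalformedGlycanError) as exc:
                raise MalformedGlycanError(f"{path}:{lineno}: {exc}") from exc
        return cls(entries, glyco_type, core_y_set or cls.default_core(glyco_type))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                body = e.structure.canonical_string() if e.structure else str(e.composition)
                fh.write(f"{e.glycan_id}\t{body}\n")

    def expand_modified_units(
        self, base_symbol: str, modified_symbol: str, max_per_glycan: int
    ) -> "GlycanDB":
        """Add variants with 1..max base units substituted by the modified unit.

        Structures are expanded node-by-node and deduplicated by canonical
        string, so chemically distinct substitution positions (terminal versus
        branching Hex, say) stay distinct while symmetric ones collapse.
        Original entries are retained; new ids continue after the current
        maximum.
        """
        if modified_symbol not in _IDX:
            raise UnknownMonosaccharideError(modified_symbol)
        if base_symbol not in _IDX:
            raise UnknownMonosaccharideError(base_symbol)
        if max_per_glycan < 1:
            raise ValueError("max_per_glycan must be >= 1")

        new_entries = list(self.entries)
        next_id = max((e.glycan_id for e in self.entries), default=-1) + 1
        seen_structures = {
            e.structure.canonical_string() for e in self.entries if e.structure
        }
        seen_compositions = {
            e.composition.counts for e in self.entries if e.structure is None
        }
        for entry in self.entries:
            if entry.structure is not None:
                for variant in _substituted_structures(
                    entry.structure, base_symbol, modified_symbol, max_per_glycan
                ):
                    key = variant.canonical_string()
                    if key not in seen_structures:
                        seen_structures.add(key)
                        new_entries.append(
                            GlycanEntry(next_id, variant.composition, variant)
                        )
                        next_id += 1
            else:
                n_base = entry.composition[base_symbol]
                for k in range(1, min(max_per_glycan, n_base) + 1):
                    counts = list(entry.composition.counts)
                    counts[_IDX[base_symbol]] -= k
                    counts[_IDX[modified_symbol]] += k
                    comp = GlycanComposition(tuple(counts))
                    if comp.counts not in seen_compositions:
                        seen_compositions.add(comp.counts)
                        new_entries.append(GlycanEntry(next_id, comp))
                        next_id += 1
        return GlycanDB(new_entries, self.glyco_type, self.core_y_set)


def _substituted_structures(
    structure: GlycanStructure, base: str, mod: str, max_subs: int
) -> list[GlycanStructure]:
    nodes = list(structure._walk())
    base_positions = [i for i, n in enumerate(nodes) if n.symbol == base]
    out: dict[str, GlycanStructure] = {}
    for k in range(1, min(max_subs, len(base_positions)) + 1):
        for subset in itertools.combinations(base_positions, k):
            variant = _copy_with_substitution(structure.root, set(subset), nodes, mod)
            s = variant.canonical_string()
            out.setdefault(s, variant)
    return list(out.values())


def _copy_with_substitution(
    root: GlycanNode, subs: set[int], nodes: list[GlycanNode], mod: str
) -> GlycanStructure:
    index = {id(n): i for i, n in enumerate(nodes)}

    def copy(node: GlycanNode) -> GlycanNode:
        symbol = mod if index[id(node)] in subs else node.symbol
        return GlycanNode(symbol, [copy(c) for c in node.children])

    return GlycanStructure(copy(root))
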