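"""NEXUS / newick input-output and the core in-memory containers.

Morphological matrices are grids of *state sets*: an observed cell holds one
state, a polymorphic cell several, and missing (``?``) / inapplicable (``-``)
cells hold no explicit state and are interpreted downstream as "any permitted
state".  Trees are unrooted leaf-labelled topologies, optionally with branch
lengths (Bayesian samples) and provenance (which analysis, run and generation
a tree came from).

Parsing of NEXUS standard-datatype matrices and of newick/NEXUS tree files is
delegated to :mod:`dendropy`; serialisation is done by a small emitter here so
that cell symbols (``-`` vs ``?``, ``{..}`` polymorphisms) and taxon-group
metadata (written as a standard ``SETS`` block) survive a round trip exactly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "CellState",
    "MISSING",
    "INAPPLICABLE",
    "CharacterMatrix",
    "Tree",
    "TreeRecord",
    "Provenance",
    "NexusParseError",
    "parse_matrix",
    "serialize_matrix",
    "parse_trees",
    "serialize_trees",
    "tree_from_newick",
    "tree_from_splits",
]


class NexusParseError(ValueError):
    """Raised when a NEXUS/newick source violates the supported dialect."""


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

_KINDS = ("observed", "polymorphic", "missing", "inapplicable")


@dataclass(frozen=True)
class CellState:
    """One cell of a morphological matrix.

    ``states`` is the explicit state set: exactly one state for an observed
    cell, two or more for a polymorphic cell, and empty for missing or
    inapplicable cells (which downstream computations treat as compatible
    with every permitted state).
    """

    states: frozenset[int]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        n = len(self.states)
        if self.kind == "observed" and n != 1:
            raise ValueError("observed cell must hold exactly one state")
        if self.kind == "polymorphic" and n < 2:
            raise ValueError("polymorphic cell must hold >= 2 states")
        if self.kind in ("missing", "inapplicable") and n != 0:
            raise ValueError(f"{self.kind} cell must hold no explicit states")
        if any(s < 0 for s in self.states):
            raise ValueError("states must be non-negative")

    # -- constructors -------------------------------------------------
    @staticmethod
    def observed(state: int) -> "CellState":
        return CellState(frozenset({int(state)}), "observed")

    @staticmethod
    def polymorphic(states: Iterable[int]) -> "CellState":
        return CellState(frozenset(int(s) for s in states), "polymorphic")

    @property
    def is_gap(self) -> bool:
        """True for missing *or* inapplicable cells (no explicit scoring)."""
        return self.kind in ("missing", "inapplicable")

    def symbol(self) -> str:
        if self.kind == "missing":
            return "?"
        if self.kind == "inapplicable":
            return "-"
        if self.kind == "observed":
            return str(next(iter(self.states)))
        return "{" + "".join(str(s) for s in sorted(self.states)) + "}"


MISSING = CellState(frozenset(), "missing")
INAPPLICABLE = CellState(frozenset(), "inapplicable")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of :class:`CellState` with taxon metadata.

    ``taxon_flags`` marks each taxon ``"extant"`` or ``"fossil"``;
    ``group_map`` names taxon groups (opabiniids, radiodonts, deuteropods,
    the Castle Bank terminal(s), outgroup, ...) used by the hypothesis tests.
    """

    taxon_names: list[str]
    cells: list[list[CellState]]
    char_labels: list[str] = field(default_factory=list)
    taxon_flags: dict[str, str] = field(default_factory=dict)
    group_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dupes = {t for t in self.taxon_names if self.taxon_names.count(t) > 1}
            raise ValueError(f"duplicate taxon names: {sorted(dupes)}")
        if len(self.cells) != len(self.taxon_names):
            raise ValueError("one cell row required per taxon")
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise ValueError(f"ragged matrix: row lengths {sorted(widths)}")
        if not self.char_labels:
            self.char_labels = [f"char_{j + 1}" for j in range(self.nchar)]
        if len(self.char_labels) != self.nchar:
            raise ValueError("char_labels length != nchar")
        taxa = set(self.taxon_names)
        for g, members in self.group_map.items():
            extra = set(members) - taxa
            if extra:
                raise ValueError(f"group {g!r} names unknown taxa {sorted(extra)}")
            self.group_map[g] = frozenset(members)
        for t, flag in self.taxon_flags.items():
            if flag not in ("extant", "fossil"):
                raise ValueError(f"taxon flag for {t!r} must be extant|fossil")

    @property
    def ntax(self) -> int:
        return len(self.taxon_names)

    @property
    def nchar(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> list[CellState]:
        return self.cells[self.taxon_names.index(taxon)]

    def column(self, j: int) -> list[CellState]:
        return [row[j] for row in self.cells]

    def columns(self) -> Iterator[list[CellState]]:
        for j in range(self.nchar):
            yield self.column(j)

    def observed_states(self, j: int) -> frozenset[int]:
        """Union of explicitly scored states in character ``j``."""
        out: set[int] = set()
        for row in self.cells:
            out |= row[j].states
        return frozenset(out)

    def cell_kind_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(_KINDS, 0)
        for row in self.cells:
            for c in row:
                counts[c.kind] += 1
        return counts

    def fossil_taxa(self) -> list[str]:
        return [t for t in self.taxon_names if self.taxon_flags.get(t) == "fossil"]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxon_names=list(self.taxon_names),
            cells=[list(row) for row in self.cells],
            char_labels=list(self.char_labels),
            taxon_flags=dict(self.taxon_flags),
            group_map={g: frozenset(m) for g, m in self.group_map.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxon_names == other.taxon_names
            and self.cells == other.cells
            and self.char_labels == other.char_labels
            and self.taxon_flags == other.taxon_flags
            and self.group_map == other.group_map
        )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Tree:
    """Mutable unrooted leaf-labelled tree.

    Nodes are integers; ``adj`` is the adjacency map, ``leaf_label`` labels
    the degree-one nodes, and ``blen`` (optional) maps the unordered edge
    ``frozenset({u, v})`` to a non-negative branch length.  Degree-two nodes
    are never kept (rooted input is suppressed on construction), so every
    internal node of a binary tree has degree three.
    """

    __slots__ = ("adj", "leaf_label", "blen", "_next_id")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.leaf_label: dict[int, str] = {}
        self.blen: dict[frozenset[int], float] | None = None
        self._next_id = 0

    # -- construction helpers -----------------------------------------
    def new_node(self, label: str | None = None) -> int:
        v = self._next_id
        self._next_id += 1
        self.adj[v] = []
        if label is not None:
            self.leaf_label[v] = label
        return v

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)
        if length is not None:
            if self.blen is None:
                self.blen = {}
            self.blen[frozenset((u, v))] = float(length)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        if self.blen is not None:
            self.blen.pop(frozenset((u, v)), None)

    def delete_node(self, v: int) -> None:
        for u in list(self.adj[v]):
            self.remove_edge(u, v)
        del self.adj[v]
        self.leaf_label.pop(v, None)

    def suppress_degree_two(self) -> None:
        """Splice out unlabelled degree-2 nodes, summing branch lengths."""
        for v in [n for n in self.adj if len(self.adj[n]) == 2 and n not in self.leaf_label]:
            a, b = self.adj[v]
            la = self.edge_length(a, v)
            lb = self.edge_length(b, v)
            self.remove_edge(a, v)
            self.remove_edge(b, v)
            del self.adj[v]
            length = None
            if la is not None and lb is not None:
                length = la + lb
            self.add_edge(a, b, length)

    # -- basic queries -------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(self.leaf_label.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for (u, v) in self.edges()
            if u not in self.leaf_label and v not in self.leaf_label
        ]

    def edge_length(self, u: int, v: int) -> float | None:
        if self.blen is None:
            return None
        return self.blen.get(frozenset((u, v)))

    def set_edge_length(self, u: int, v: int, length: float) -> None:
        if self.blen is None:
            self.blen = {}
        self.blen[frozenset((u, v))] = float(length)

    def total_length(self) -> float:
        if self.blen is None:
            return 0.0
        return float(sum(self.blen.values()))

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {v: list(nb) for v, nb in self.adj.items()}
        t.leaf_label = dict(self.leaf_label)
        t.blen = None if self.blen is None else dict(self.blen)
        t._next_id = self._next_id
        return t

    # -- traversal -----------------------------------------------------
    def rooted_view(self, root: int | None = None) -> tuple[list[int], dict[int, list[int]], dict[int, int | None]]:
        """Post-order node list, children map and parent map rooted at ``root``.

        The default root is a neighbour of the smallest leaf, so leaf cells
        stay at the tips of the traversal.
        """
        if root is None:
            ref = min(self.leaf_label)
            root = self.adj[ref][0] if self.adj[ref] else ref
        parent: dict[int, int | None] = {root: None}
        children: dict[int, list[int]] = {}
        order: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            kids = [u for u in self.adj[v] if u != parent[v]]
            children[v] = kids
            for u in kids:
                parent[u] = v
                stack.append(u)
        order.reverse()  # post-order: children before parents
        return order, children, parent

    # -- splits ---------------------------------------------------------
    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions as canonical leaf-name sets.

        Each split is stored as the side *not* containing the reference leaf
        (the lexicographically smallest label), making split sets directly
        comparable across trees on the same taxa.
        """
        names = self.leaf_names
        if len(names) < 4:
            return frozenset()
        ref = min(names)
        order, children, _ = self.rooted_view()
        below: dict[int, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for v in order:
            if v in self.leaf_label:
                below[v] = frozenset({self.leaf_label[v]})
            else:
                acc: frozenset[str] = frozenset()
                for c in children[v]:
                    acc |= below[c]
                below[v] = acc
        for v in order[:-1]:  # every node except the root marks an edge
            side = below[v]
            if ref in side:
                side = names - side
            if 2 <= len(side) <= len(names) - 2:
                out.add(side)
        return frozenset(out)

    def is_binary(self) -> bool:
        return all(
            len(nb) == (1 if v in self.leaf_label else 3) for v, nb in self.adj.items()
        )

    # -- newick ---------------------------------------------------------
    def to_newick(self, include_lengths: bool | None = None) -> str:
        if include_lengths is None:
            include_lengths = self.blen is not None
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            return f"({next(iter(self.leaf_label.values()))});"
        root = next(v for v in self.adj if v not in self.leaf_label) if self.n_leaves > 2 else min(self.leaf_label)
        order, children, parent = self.rooted_view(root)

        def fmt(v: int) -> str:
            if v in self.leaf_label:
                s = _quote_label(self.leaf_label[v])
            else:
                s = "(" + ",".join(fmt(c) for c in children[v]) + ")"
            p = parent[v]
            if include_lengths and p is not None:
                length = self.edge_length(v, p)
                if length is not None:
                    s += f":{length:.10g}"
            return s

        if root in self.leaf_label:  # 2-leaf tree
            other = children[root][0]
            return f"({_quote_label(self.leaf_label[root])},{fmt(other)});"
        return "(" + ",".join(fmt(c) for c in children[root]) + ");"

    def __repr__(self) -> str:
        return f"<Tree {self.n_leaves} leaves>"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]{}']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass(frozen=True)
class Provenance:
    analysis: str = ""
    run: int | None = None
    index: int | None = None


@dataclass
class TreeRecord:
    """An unrooted topology plus optional branch lengths and provenance."""

    tree: Tree
    provenance: Provenance = field(default_factory=Provenance)

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.tree.leaf_names

    def splits(self) -> frozenset[frozenset[str]]:
        return self.tree.splits()

    def to_newick(self, include_lengths: bool | None = None) -> str:
        return self.tree.to_newick(include_lengths)


def as_tree(t: "Tree | TreeRecord") -> Tree:
    return t.tree if isinstance(t, TreeRecord) else t


# ---------------------------------------------------------------------------
# Matrix parsing (dendropy-backed)
# ---------------------------------------------------------------------------


def parse_matrix(source: str) -> CharacterMatrix:
    """Parse a NEXUS standard-datatype matrix into a :class:`CharacterMatrix`.

    Symbols 0-9 map to states, ``?`` to missing, ``-`` to inapplicable and
    ``{..}`` / ``(..)`` to polymorphisms.  A ``SETS`` block, if present, is
    read for ``TAXSET fossil/extant`` flags and ``TAXSET group_<name>``
    group definitions (the same dialect :func:`serialize_matrix` emits).
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=source, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NexusParseError(f"could not parse NEXUS matrix: {exc}") from exc

    taxon_names: list[str] = []
    cells: list[list[CellState]] = []
    for tax in dmat.taxon_namespace:
        if tax.label in taxon_names:
            raise NexusParseError(f"duplicate taxon {tax.label!r}")
        seq = dmat[tax] if tax in dmat else None
        if seq is None:
            raise NexusParseError(f"taxon {tax.label!r} has no character row")
        row: list[CellState] = []
        for j, st in enumerate(seq):
            row.append(_cell_from_dendropy_state(st, tax.label, j))
        taxon_names.append(tax.label)
        cells.append(row)

    widths = {len(r) for r in cells}
    if len(widths) > 1:
        raise NexusParseError(f"ragged matrix: row lengths {sorted(widths)}")

    ntax_decl, nchar_decl = _declared_dims(source)
    if ntax_decl is not None and ntax_decl != len(taxon_names):
        raise NexusParseError(f"NTAX={ntax_decl} but {len(taxon_names)} taxa parsed")
    if nchar_decl is not None and cells and nchar_decl != len(cells[0]):
        raise NexusParseError(f"NCHAR={nchar_decl} but {len(cells[0])} characters parsed")

    taxon_flags, group_map = _parse_sets_block(source, set(taxon_names))
    return CharacterMatrix(
        taxon_names=taxon_names,
        cells=cells,
        taxon_flags=taxon_flags,
        group_map=group_map,
    )


def _cell_from_dendropy_state(st, taxon: str, j: int) -> CellState:
    sym = st.symbol
    if sym == "?":
        return MISSING
    if sym == "-":
        return INAPPLICABLE
    if sym is not None:
        if not sym.isdigit():
            raise NexusParseError(
                f"unsupported state symbol {sym!r} (taxon {taxon!r}, character {j + 1})"
            )
        return CellState.observed(int(sym))
    members = st.member_states
    if not members:
        raise NexusParseError(f"unreadable cell (taxon {taxon!r}, character {j + 1})")
    vals = []
    for ms in members:
        if ms.symbol in ("?", "-"):
            continue
        if not ms.symbol.isdigit():
            raise NexusParseError(
                f"unsupported state symbol {ms.symbol!r} (taxon {taxon!r}, character {j + 1})"
            )
        vals.append(int(ms.symbol))
    if len(vals) < 2:
        return MISSING
    return CellState.polymorphic(vals)


def _declared_dims(source: str) -> tuple[int | None, int | None]:
    m_ntax = re.search(r"\bNTAX\s*=\s*(\d+)", source, re.IGNORECASE)
    m_nchar = re.search(r"\bNCHAR\s*=\s*(\d+)", source, re.IGNORECASE)
    return (
        int(m_ntax.group(1)) if m_ntax else None,
        int(m_nchar.group(1)) if m_nchar else None,
    )


_TAXSET_RE = re.compile(r"TAXSET\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE)


def _parse_sets_block(source: str, taxa: set[str]) -> tuple[dict[str, str], dict[str, frozenset[str]]]:
    m = re.search(r"BEGIN\s+SETS\s*;(.*?)END\s*;", source, re.IGNORECASE | re.DOTALL)
    taxon_flags: dict[str, str] = {}
    group_map: dict[str, frozenset[str]] = {}
    if not m:
        return taxon_flags, group_map
    for name, body in _TAXSET_RE.findall(m.group(1)):
        members = frozenset(t.strip().strip("'") for t in body.split() if t.strip())
        unknown = members - taxa
        if unknown:
            raise NexusParseError(f"TAXSET {name} names unknown taxa {sorted(unknown)}")
        if name.lower() in ("fossil", "extant"):
            for t in members:
                taxon_flags[t] = name.lower()
        elif name.lower().startswith("group_"):
            group_map[name[len("group_"):]] = members
    return taxon_flags, group_map


def serialize_matrix(m: CharacterMatrix) -> str:
    """Emit a NEXUS standard-datatype file that :func:`parse_matrix` inverts."""
    states = set()
    for j in range(m.nchar):
        states |= m.observed_states(j)
    if any(s > 9 for s in states):
        raise ValueError("only state symbols 0-9 are supported")
    symbols = "".join(str(s) for s in range(max(states) + 1)) if states else "01"
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"    DIMENSIONS NTAX={m.ntax} NCHAR={m.nchar};\n")
    buf.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    buf.write("    MATRIX\n")
    width = max((len(_quote_label(t)) for t in m.taxon_names), default=0) + 2
    for t, row in zip(m.taxon_names, m.cells):
        buf.write(f"        {_quote_label(t):<{width}}")
        buf.write("".join(c.symbol() for c in row))
        buf.write("\n")
    buf.write("    ;\nEND;\n")
    taxsets: list[tuple[str, Iterable[str]]] = []
    for flag in ("extant", "fossil"):
        members = [t for t in m.taxon_names if m.taxon_flags.get(t) == flag]
        if members:
            taxsets.append((flag, members))
    for g in sorted(m.group_map):
        taxsets.append((f"group_{g}", sorted(m.group_map[g])))
    if taxsets:
        buf.write("\nBEGIN SETS;\n")
        for name, members in taxsets:
            joined = " ".join(_quote_label(t) for t in members)
            buf.write(f"    TAXSET {name} = {joined};\n")
        buf.write("END;\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Tree parsing / serialisation
# ---------------------------------------------------------------------------


def _from_dendropy(dt: dendropy.Tree) -> Tree:
    t = Tree()
    node_map: dict = {}
    for nd in dt.preorder_node_iter():
        label = nd.taxon.label if nd.taxon is not None else None
        v = t.new_node(label if nd.is_leaf() else None)
        if nd.is_leaf() and label is None:
            raise NexusParseError("leaf without a label")
        node_map[nd] = v
        if nd.parent_node is not None:
            t.add_edge(node_map[nd.parent_node], v, nd.edge.length)
    if len(set(t.leaf_label.values())) != t.n_leaves:
        raise NexusParseError("duplicate leaf labels")
    t.suppress_degree_two()  # store unrooted: splice out the root if degree 2
    if t.blen is not None and not t.blen:
        t.blen = None
    return t


def tree_from_newick(newick: str) -> Tree:
    """Parse a single newick string into an unrooted :class:`Tree`."""
    try:
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NexusParseError(f"could not parse newick: {exc}") from exc
    return _from_dendropy(dt)


def parse_trees(source: str, analysis: str = "") -> list[TreeRecord]:
    """Parse a newick or NEXUS trees file into a list of :class:`TreeRecord`.

    Records receive sequential indices; rooting in the input is discarded
    (degree-two root nodes are suppressed).
    """
    schema = "nexus" if source.lstrip().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=source,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NexusParseError(f"could not parse trees: {exc}") from exc
    out = []
    for i, dt in enumerate(tl):
        out.append(TreeRecord(_from_dendropy(dt), Provenance(analysis=analysis, index=i)))
    return out


def serialize_trees(trees: Sequence[TreeRecord | Tree]) -> str:
    """One newick per line; branch lengths included when present."""
    return "".join(as_tree(t).to_newick() + "\n" for t in trees)


# ---------------------------------------------------------------------------
# Building trees from splits (used by consensus methods)
# ---------------------------------------------------------------------------


def tree_from_splits(
    leaf_names: Iterable[str],
    splits: Iterable[frozenset[str]],
    split_weights: Mapping[frozenset[str], float] | None = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Assemble the tree displaying exactly a compatible set of splits.

    Splits are given in the canonical orientation of :meth:`Tree.splits`
    (side excluding the smallest leaf).  Returns the tree and a map from
    split to ``split_weights`` value (e.g. consensus frequencies) restricted
    to the splits actually used.  Incompatible splits raise ``ValueError``.
    """
    names = sorted(set(leaf_names))
    ref = names[0]
    splits = sorted(set(splits), key=len)  # small clades first -> nest inward
    for s in splits:
        if ref in s or not (2 <= len(s) <= len(names) - 2):
            raise ValueError(f"split {sorted(s)} is not in canonical orientation")

    t = Tree()
    root = t.new_node()
    for name in names:
        t.add_edge(root, t.new_node(name))

    used: dict[frozenset[str], float] = {}
    for s in splits:
        # group the maximal subtrees whose leaves all fall inside s; a
        # compatible split finds them hanging off one common node
        top_nodes, parent = _maximal_nodes_within(t, root, s)
        parent_set = {parent[v] for v in top_nodes}
        if len(parent_set) != 1 or None in parent_set:
            raise ValueError(f"incompatible split {sorted(s)}")
        (p,) = parent_set
        new = t.new_node()
        for v in top_nodes:
            t.remove_edge(p, v)
            t.add_edge(new, v)
        t.add_edge(p, new)
        used[s] = split_weights[s] if split_weights and s in split_weights else 1.0
    t.suppress_degree_two()
    return t, used


def _maximal_nodes_within(
    t: Tree, root: int, member_names: frozenset[str]
) -> tuple[list[int], dict[int, int | None]]:
    """Nodes whose leaf sets are maximal subsets of ``member_names``."""
    order, children, parent = t.rooted_view(root)
    below: dict[int, frozenset[str]] = {}
    for v in order:
        if v in t.leaf_label:
            below[v] = frozenset({t.leaf_label[v]})
        else:
            acc: frozenset[str] = frozenset()
            for c in children[v]:
                acc |= below[c]
            below[v] = acc
    inside = {v for v in order if below[v] and below[v] <= member_names}
    return [v for v in inside if parent[v] not in inside], parent
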