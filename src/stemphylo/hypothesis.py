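"""Bipartition-hypothesis classification of sampled trees.

Each tree in a posterior sample or most-parsimonious set is classified by
where it places the Castle Bank terminal(s) relative to the named clades:

* ``monophyletic_proboscis`` — the Castle Bank terminal(s) plus the
  opabiniids (*Opabinia*, *Utaurora*) form an exclusive clade: a
  monophyletic group of proboscis-bearing stem euarthropods.
* ``paraphyletic_grade`` — the Castle Bank terminal(s) plus Radiodonta plus
  Deuteropoda form an exclusive clade that excludes the opabiniids: the
  proboscis-bearing taxa are then a grade, with the Castle Bank material
  closer to the arthropodized lineages.
* ``other`` — any remaining topology; the subcategory records the smallest
  clade containing the Castle Bank terminal(s).

Categories are evaluated in that order; on binary trees the first two are
mutually exclusive.  With two Castle Bank terminals the strict rule is used:
both terminals must sit inside the defining clade, and trees that split the
terminals across patterns fall to ``other``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .nexus_io import CharacterMatrix, Tree, TreeRecord, as_tree

__all__ = [
    "CladeDefinitions",
    "HypothesisCategory",
    "ClassificationTable",
    "contains_clade",
    "classify_tree",
    "classify_sample",
    "tabulate_proportions",
    "CATEGORIES",
]

CATEGORIES = ("monophyletic_proboscis", "paraphyletic_grade", "other")


@dataclass(frozen=True)
class CladeDefinitions:
    """Named taxon sets that parameterise the classification.

    Membership lists are data (read from the matrix's group map or a config
    file), not hard-coded: only the group *roles* are fixed here.
    """

    opabiniids: frozenset[str]
    radiodonts: frozenset[str]
    deuteropods: frozenset[str]
    castle_bank: frozenset[str]
    outgroup: frozenset[str]

    def __post_init__(self) -> None:
        if not self.outgroup:
            raise ValueError("outgroup must be non-empty")
        named = [self.opabiniids, self.radiodonts, self.deuteropods,
                 self.castle_bank, self.outgroup]
        for i, a in enumerate(named):
            for b in named[i + 1:]:
                if a & b:
                    raise ValueError(f"overlapping clade definitions: {sorted(a & b)}")

    @classmethod
    def from_matrix(cls, m: CharacterMatrix) -> "CladeDefinitions":
        g = m.group_map
        missing = {"opabiniids", "radiodonts", "deuteropods", "castle_bank", "outgroup"} - set(g)
        if missing:
            raise ValueError(f"matrix group_map lacks groups {sorted(missing)}")
        return cls(
            opabiniids=g["opabiniids"],
            radiodonts=g["radiodonts"],
            deuteropods=g["deuteropods"],
            castle_bank=g["castle_bank"],
            outgroup=g["outgroup"],
        )

    def rename(self, old: str, new: str) -> "CladeDefinitions":
        """Propagate a terminal rename (e.g. after a merge) through all sets."""
        def swap(s: frozenset[str]) -> frozenset[str]:
            return frozenset(new if t == old else t for t in s)

        return CladeDefinitions(
            opabiniids=swap(self.opabiniids),
            radiodonts=swap(self.radiodonts),
            deuteropods=swap(self.deuteropods),
            castle_bank=swap(self.castle_bank),
            outgroup=swap(self.outgroup),
        )


@dataclass(frozen=True)
class HypothesisCategory:
    category: str
    subcategory: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _edge_bipartitions(tree: Tree) -> list[frozenset[str]]:
    """Leaf sets below every edge (including pendant edges), oriented away
    from the reference leaf."""
    names = tree.leaf_names
    ref = min(names)
    order, children, _ = tree.rooted_view()
    below: dict[int, frozenset[str]] = {}
    sides = []
    for v in order:
        if not children[v]:
            below[v] = frozenset({tree.leaf_label[v]})
        else:
            acc: frozenset[str] = frozenset()
            for c in children[v]:
                acc |= below[c]
            if v in tree.leaf_label:
                acc |= frozenset({tree.leaf_label[v]})
            below[v] = acc
    for v in order[:-1]:
        side = below[v]
        if ref in side:
            side = names - side
        sides.append(side)
    return sides


def contains_clade(tree: Tree | TreeRecord, members: Iterable[str],
                   outgroup: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``members``
    (restricted to taxa present) from a side holding the full outgroup."""
    t = as_tree(tree)
    mem = frozenset(members)
    og = frozenset(outgroup)
    if mem & og:
        raise ValueError(f"members and outgroup overlap: {sorted(mem & og)}")
    leaves = t.leaf_names
    mem &= leaves
    if not mem:
        return False
    if not og <= leaves:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(og - leaves)}")
    if mem == leaves - og and og:
        # everything except the outgroup: the edge below the outgroup's
        # attachment always provides this split on a tree where og is a clade
        return contains_clade(t, og, mem) if len(og) > 1 else True
    for side in _edge_bipartitions(t):
        if side == mem and og <= (leaves - side):
            return True
        other = leaves - side
        if other == mem and og <= side:
            return True
    return False


def _smallest_containing_clade(tree: Tree, members: frozenset[str],
                               outgroup: frozenset[str]) -> frozenset[str]:
    """Smallest edge-defined leaf set containing ``members`` with the
    outgroup on the far side (i.e. the containing clade once rooted on the
    outgroup)."""
    t = tree
    leaves = t.leaf_names
    best = leaves - outgroup
    for side in _edge_bipartitions(t):
        for cand in (side, leaves - side):
            if (members < cand and not (outgroup & cand)
                    and len(members) < len(cand) < len(best)):
                best = cand
    return best


def classify_tree(tree: Tree | TreeRecord, defs: CladeDefinitions,
                  scheme: str = "strict") -> HypothesisCategory:
    """Assign one tree to a placement category (see module docstring).

    ``scheme='strict'`` is the supported rule: with two Castle Bank
    terminals both must participate in the defining clade.
    """
    if scheme != "strict":
        raise ValueError(f"unknown classification scheme {scheme!r}")
    t = as_tree(tree)
    leaves = t.leaf_names
    needed = defs.castle_bank | defs.outgroup
    missing = needed - leaves
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    cb = defs.castle_bank
    opab = defs.opabiniids & leaves
    if contains_clade(t, cb | opab, defs.outgroup) and opab:
        return HypothesisCategory("monophyletic_proboscis")
    rad = defs.radiodonts & leaves
    deut = defs.deuteropods & leaves
    if (rad or deut) and contains_clade(t, cb | rad | deut, defs.outgroup):
        return HypothesisCategory("paraphyletic_grade")
    clade = _smallest_containing_clade(t, cb, defs.outgroup)
    inside = clade - cb
    touched = [
        name
        for name, group in (
            ("opabiniids", opab),
            ("radiodonts", rad),
            ("deuteropods", deut),
        )
        if group & inside
    ]
    sub = f"smallest_clade={len(clade)};with={','.join(touched) if touched else 'none'}"
    return HypothesisCategory("other", sub)


def classify_sample(trees: Sequence[TreeRecord | Tree], defs: CladeDefinitions,
                    scheme: str = "strict") -> list[HypothesisCategory]:
    return [classify_tree(t, defs, scheme) for t in trees]


@dataclass
class ClassificationTable:
    """Per-analysis category counts and percentages (0.1% precision)."""

    table: pd.DataFrame

    def percentages(self, analysis: str) -> dict[str, float]:
        row = self.table.loc[self.table["analysis"] == analysis]
        if row.empty:
            raise KeyError(analysis)
        return {c: float(row.iloc[0][f"pct_{c}"]) for c in CATEGORIES}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def tabulate_proportions(samples: Mapping[str, Sequence[TreeRecord | Tree]],
                         defs: CladeDefinitions, scheme: str = "strict",
                         pooled: bool = False) -> ClassificationTable:
    """Category counts and percentages per analysis label.

    With ``pooled=True`` an extra row aggregates all analyses, weighting
    each tree equally (so analyses contribute proportionally to their
    sample sizes).
    """
    if not samples:
        raise ValueError("no samples given")
    rows = []
    pooled_counts: Counter = Counter()
    pooled_n = 0
    for label, trees in samples.items():
        trees = list(trees)
        if not trees:
            raise ValueError(f"empty tree list for analysis {label!r}")
        cats = Counter(c.category for c in classify_sample(trees, defs, scheme))
        n = len(trees)
        row = {"analysis": label, "n_trees": n}
        for c in CATEGORIES:
            row[f"count_{c}"] = cats.get(c, 0)
            row[f"pct_{c}"] = round(100.0 * cats.get(c, 0) / n, 1)
        rows.append(row)
        pooled_counts.update(cats)
        pooled_n += n
    if pooled:
        row = {"analysis": "POOLED", "n_trees": pooled_n}
        for c in CATEGORIES:
            row[f"count_{c}"] = pooled_counts.get(c, 0)
            row[f"pct_{c}"] = round(100.0 * pooled_counts.get(c, 0) / pooled_n, 1)
        rows.append(row)
    return ClassificationTable(pd.DataFrame(rows))
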