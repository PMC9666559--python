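"""Matrix variants: terminal merging, sensitivity taxa, convergence recoding.

The analyses run on a grid of matrix variants built from one base matrix:

* one vs two Castle Bank terminals (merging the two specimens when they are
  interpreted as ontogenetic stages of a single species);
* added sensitivity taxa (*Kylinxia*, *Parapeytoia* under alternative
  protocerebral/deutocerebral scorings, the latter bringing one extra
  character into the matrix);
* convergence recodings that let a shared feature (carapace, proboscis
  dorsal spines, internal strengthening rays) evolve independently in the
  focal group, either by splitting a character in two (one copy applicable
  only to the focal group; net +1 character) or by moving the focal group's
  derived scorings to a previously unused state (net +0 characters).

The feature-to-action mapping that reproduces the published character
counts is: carapace and dorsal spines are splits, strengthening rays is an
added state (all three together: 129 + 2 = 131 characters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .nexus_io import (
    INAPPLICABLE,
    MISSING,
    CellState,
    CharacterMatrix,
)

__all__ = [
    "MergeConflictWarning",
    "FeatureAction",
    "AddedTaxon",
    "ExtraCharacter",
    "RecodingPlan",
    "MatrixVariant",
    "CONVERGENT_FEATURES",
    "cells_from_string",
    "merge_terminals",
    "add_sensitivity_taxon",
    "apply_convergence_recoding",
    "build_matrix_variant",
    "default_feature_actions",
]

CONVERGENT_FEATURES = ("carapace", "proboscis_dorsal_spines", "strengthening_rays")


class MergeConflictWarning(UserWarning):
    """Two merged terminals carry different observed states for a character."""


def cells_from_string(s: str) -> list[CellState]:
    """Parse a compact scoring string: digits, ``?``, ``-``, ``{..}``/``(..)``."""
    out: list[CellState] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "?":
            out.append(MISSING)
            i += 1
        elif ch == "-":
            out.append(INAPPLICABLE)
            i += 1
        elif ch.isdigit():
            out.append(CellState.observed(int(ch)))
            i += 1
        elif ch in "{(":
            close = "}" if ch == "{" else ")"
            j = s.index(close, i)
            out.append(CellState.polymorphic(int(c) for c in s[i + 1:j] if c.isdigit()))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            raise ValueError(f"unsupported scoring symbol {ch!r}")
    return out


@dataclass(frozen=True)
class FeatureAction:
    """How one feature is made convergent.

    ``kind='split_character'`` duplicates ``char_index``; the focal group
    keeps its scorings on the copy and becomes inapplicable on the original,
    all other taxa become inapplicable on the copy.  ``kind='add_state'``
    rewrites the focal group's derived scorings on ``char_index`` to
    ``new_state``.  ``derived_states`` (default: every non-zero state)
    selects which scorings count as the derived condition being recoded.
    """

    kind: str
    char_index: int
    focal_group: str
    new_state: int | None = None
    derived_states: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("split_character", "add_state"):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.kind == "add_state" and self.new_state is None:
            raise ValueError("add_state requires new_state")


@dataclass(frozen=True)
class ExtraCharacter:
    """A character column inserted when a sensitivity taxon is added."""

    index: int
    default: CellState | Mapping[str, CellState] = MISSING
    label: str = ""


@dataclass(frozen=True)
class AddedTaxon:
    name: str
    scoring: tuple[CellState, ...]
    variant_label: str = ""
    flag: str = "fossil"
    extra_char: ExtraCharacter | None = None
    groups: tuple[str, ...] = ()

    @staticmethod
    def from_string(name: str, scoring: str, **kw) -> "AddedTaxon":
        return AddedTaxon(name=name, scoring=tuple(cells_from_string(scoring)), **kw)


@dataclass
class RecodingPlan:
    """Declarative description of one matrix variant."""

    merge: tuple[str, str, str] | None = None  # (taxon_a, taxon_b, merged_name)
    add_taxa: list[AddedTaxon] = field(default_factory=list)
    convergent_features: tuple[str, ...] = ()
    feature_actions: dict[str, FeatureAction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.convergent_features:
            if f not in CONVERGENT_FEATURES:
                raise ValueError(f"unknown convergent feature {f!r}")

    @property
    def n_split_actions(self) -> int:
        return sum(
            1
            for f in self.convergent_features
            if self.feature_actions[f].kind == "split_character"
        )


@dataclass
class MatrixVariant:
    matrix: CharacterMatrix
    label: str
    expected_dims: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.expected_dims is not None:
            got = (self.matrix.ntax, self.matrix.nchar)
            if got != tuple(self.expected_dims):
                raise ValueError(
                    f"variant {self.label!r}: dims {got} != expected {self.expected_dims}"
                )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _merge_cells(a: CellState, b: CellState) -> tuple[CellState, bool]:
    """Combine two terminals' scorings for one character.

    A gap cell (missing/inapplicable) defers to the other cell; equal
    observed sets are kept; conflicting observed sets union into a
    polymorphism (flagged as a conflict).
    """
    if a.is_gap:
        return b, False
    if b.is_gap:
        return a, False
    if a.states == b.states:
        return a, False
    union = a.states | b.states
    return CellState(frozenset(union), "polymorphic"), True


def merge_terminals(m: CharacterMatrix, a: str, b: str, name: str) -> CharacterMatrix:
    """Merge terminals ``a`` and ``b`` into one taxon ``name``.

    Used when two specimens are reinterpreted as ontogenetic stages of one
    species.  Conflicting observed scorings become polymorphic with a
    :class:`MergeConflictWarning` naming the characters, keeping conflicts
    auditable.
    """
    if a == b:
        raise ValueError("cannot merge a taxon with itself")
    for t in (a, b):
        if t not in m.taxon_names:
            raise ValueError(f"unknown taxon {t!r}")
    if name != a and name != b and name in m.taxon_names:
        raise ValueError(f"merged name {name!r} already in matrix")
    ia, ib = m.taxon_names.index(a), m.taxon_names.index(b)
    merged_row: list[CellState] = []
    conflicts: list[int] = []
    for j in range(m.nchar):
        cell, conflict = _merge_cells(m.cells[ia][j], m.cells[ib][j])
        merged_row.append(cell)
        if conflict:
            conflicts.append(j + 1)
    if conflicts:
        warnings.warn(
            f"merge {a!r}+{b!r}: conflicting scorings at characters {conflicts} "
            "recorded as polymorphisms",
            MergeConflictWarning,
            stacklevel=2,
        )
    first = min(ia, ib)
    taxon_names = [t for t in m.taxon_names if t not in (a, b)]
    taxon_names.insert(first, name)
    cells = [row for t, row in zip(m.taxon_names, m.cells) if t not in (a, b)]
    cells.insert(first, merged_row)
    flags = {t: f for t, f in m.taxon_flags.items() if t not in (a, b)}
    if a in m.taxon_flags or b in m.taxon_flags:
        flags[name] = m.taxon_flags.get(a, m.taxon_flags.get(b))
    groups = {}
    for g, members in m.group_map.items():
        new_members = set(members) - {a, b}
        if a in members or b in members:
            new_members.add(name)
        groups[g] = frozenset(new_members)
    return CharacterMatrix(
        taxon_names=taxon_names,
        cells=cells,
        char_labels=list(m.char_labels),
        taxon_flags=flags,
        group_map=groups,
    )


def add_sensitivity_taxon(m: CharacterMatrix, name: str,
                          scoring: Sequence[CellState],
                          extra_char: ExtraCharacter | None = None,
                          flag: str = "fossil",
                          groups: Iterable[str] = ()) -> CharacterMatrix:
    """Append a taxon; optionally insert a new character column.

    With ``extra_char``, the scoring vector must cover the enlarged matrix
    (nchar + 1) and every pre-existing taxon receives the column's default
    scoring at the stated index.
    """
    if name in m.taxon_names:
        raise ValueError(f"taxon {name!r} already present")
    expected = m.nchar + (1 if extra_char is not None else 0)
    if len(scoring) != expected:
        raise ValueError(f"scoring length {len(scoring)} != {expected}")
    out = m.copy()
    if extra_char is not None:
        idx = extra_char.index
        if not (0 <= idx <= m.nchar):
            raise ValueError(f"extra character index {idx} out of range")
        for t, row in zip(out.taxon_names, out.cells):
            if isinstance(extra_char.default, CellState):
                cell = extra_char.default
            else:
                cell = extra_char.default.get(t, MISSING)
            row.insert(idx, cell)
        out.char_labels.insert(idx, extra_char.label or f"char_extra_{idx + 1}")
    out.taxon_names.append(name)
    out.cells.append(list(scoring))
    out.taxon_flags[name] = flag
    for g in groups:
        out.group_map[g] = out.group_map.get(g, frozenset()) | {name}
    return CharacterMatrix(
        taxon_names=out.taxon_names,
        cells=out.cells,
        char_labels=out.char_labels,
        taxon_flags=out.taxon_flags,
        group_map=out.group_map,
    )


def _apply_action(m: CharacterMatrix, action: FeatureAction) -> CharacterMatrix:
    j = action.char_index
    if not (0 <= j < m.nchar):
        raise ValueError(f"character index {j} out of range")
    focal = m.group_map.get(action.focal_group)
    if focal is None:
        raise ValueError(f"focal group {action.focal_group!r} not defined in matrix")
    out = m.copy()
    if action.kind == "split_character":
        for t, row in zip(out.taxon_names, out.cells):
            original = row[j]
            if t in focal:
                row[j] = INAPPLICABLE
                row.insert(j + 1, original)
            else:
                row.insert(j + 1, INAPPLICABLE)
        out.char_labels.insert(j + 1, f"{out.char_labels[j]}_convergent")
    else:  # add_state
        observed = m.observed_states(j)
        if action.new_state in observed:
            raise ValueError(
                f"new state {action.new_state} already observed in character {j + 1}"
            )
        derived = action.derived_states
        if derived is None:
            derived = frozenset(s for s in observed if s != 0)
        for t, row in zip(out.taxon_names, out.cells):
            if t not in focal:
                continue
            cell = row[j]
            if cell.states & derived:
                new_states = (cell.states - derived) | {action.new_state}
                kind = "observed" if len(new_states) == 1 else "polymorphic"
                row[j] = CellState(frozenset(new_states), kind)
    return CharacterMatrix(
        taxon_names=out.taxon_names,
        cells=out.cells,
        char_labels=out.char_labels,
        taxon_flags=out.taxon_flags,
        group_map=out.group_map,
    )


def apply_convergence_recoding(m: CharacterMatrix, plan: RecodingPlan,
                               label: str = "convergent") -> MatrixVariant:
    """Apply the plan's convergence actions; nchar grows by one per split."""
    out = m
    for f in plan.convergent_features:
        if f not in plan.feature_actions:
            raise ValueError(f"no action defined for feature {f!r}")
    # apply in descending character index so earlier indices stay valid
    ordered = sorted(
        plan.convergent_features,
        key=lambda f: plan.feature_actions[f].char_index,
        reverse=True,
    )
    for f in ordered:
        out = _apply_action(out, plan.feature_actions[f])
    expected_nchar = m.nchar + plan.n_split_actions
    return MatrixVariant(out, label, expected_dims=(out.ntax, expected_nchar))


def build_matrix_variant(base: CharacterMatrix, plan: RecodingPlan, label: str,
                         expected_dims: tuple[int, int] | None = None) -> MatrixVariant:
    """Merge, then taxon additions, then convergence recodings."""
    m = base
    if plan.merge is not None:
        a, b, name = plan.merge
        m = merge_terminals(m, a, b, name)
    for added in plan.add_taxa:
        m = add_sensitivity_taxon(
            m, added.name, list(added.scoring), extra_char=added.extra_char,
            flag=added.flag, groups=added.groups,
        )
    if plan.convergent_features:
        m = apply_convergence_recoding(m, plan, label).matrix
    return MatrixVariant(m, label, expected_dims=expected_dims)


def default_feature_actions(carapace_char: int, spines_char: int, rays_char: int,
                            focal_group: str = "castle_bank",
                            rays_new_state: int | None = None,
                            rays_observed: Iterable[int] = (0, 1)) -> dict[str, FeatureAction]:
    """The action assignment that reproduces the published variant sizes:
    carapace and dorsal spines split, strengthening rays adds a state."""
    if rays_new_state is None:
        rays_new_state = max(rays_observed) + 1
    return {
        "carapace": FeatureAction("split_character", carapace_char, focal_group),
        "proboscis_dorsal_spines": FeatureAction("split_character", spines_char, focal_group),
        "strengthening_rays": FeatureAction(
            "add_state", rays_char, focal_group, new_state=rays_new_state
        ),
    }
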