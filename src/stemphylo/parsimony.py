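"""Maximum parsimony under implied weighting.

Characters are unordered (non-additive).  Tree length per character is the
Fitch minimum number of state changes; implied weighting scores a tree by the
summed concave fit ``k / (k + e)`` where ``e`` is the character's extra steps
beyond its theoretical minimum and ``k`` the concavity constant (the study
setting is ``k = 3``).  The heuristic search is multi-start random stepwise
addition followed by TBR (tree bisection-reconnection) hill climbing, with
the retention rule that the best score must be hit independently a required
number of times (100 in the study) before the search stops.

Setting ``concavity_k = math.inf`` selects equal-weights parsimony: trees are
then ranked by total steps (the fit of every character degenerates to 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .nexus_io import (
    CellState,
    CharacterMatrix,
    Provenance,
    Tree,
    TreeRecord,
    as_tree,
    tree_from_splits,
)

__all__ = [
    "SearchSettings",
    "ParsimonyScore",
    "MPSearchResult",
    "fitch_steps",
    "char_min_steps",
    "implied_fit",
    "score_tree",
    "search_mp",
    "strict_consensus",
    "random_addition_tree",
    "tbr_neighbors",
    "all_unrooted_topologies",
]

_TOL = 1e-9  # score-comparison tolerance


@dataclass
class SearchSettings:
    """Heuristic-search control knobs.

    ``required_hits`` is the number of independent addition-sequence starts
    that must recover the best score before the search stops (study rule:
    100); ``n_random_addition_starts`` caps the start budget.
    """

    concavity_k: float = 3.0
    required_hits: int = 100
    n_random_addition_starts: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.concavity_k > 0:
            raise ValueError("concavity_k must be positive")
        if self.required_hits < 1:
            raise ValueError("required_hits must be >= 1")


@dataclass
class ParsimonyScore:
    per_char_steps: np.ndarray
    per_char_min: np.ndarray
    per_char_extra: np.ndarray
    fit_total: float
    distortion_total: float
    steps_total: int
    concavity_k: float

    @property
    def objective(self) -> float:
        """Quantity maximised by the search (higher is better)."""
        if math.isinf(self.concavity_k):
            return -float(self.steps_total)
        return self.fit_total


# ---------------------------------------------------------------------------
# Character encoding: one bitmask per cell
# ---------------------------------------------------------------------------


def _column_masks(column: Sequence[CellState]) -> np.ndarray:
    """Bitmask per taxon for one character; gap/missing cells receive the
    union of the column's observed states (their full permitted set)."""
    observed = 0
    for c in column:
        for s in c.states:
            observed |= 1 << s
    if observed == 0:
        observed = 1  # all-missing column: any single dummy state
    out = np.empty(len(column), dtype=np.int64)
    for i, c in enumerate(column):
        if c.states:
            m = 0
            for s in c.states:
                m |= 1 << s
            out[i] = m
        else:
            out[i] = observed
    return out


def encode_matrix(m: CharacterMatrix) -> np.ndarray:
    """(ntax, nchar) int64 bitmask array, taxa in matrix order."""
    cols = [_column_masks(m.column(j)) for j in range(m.nchar)]
    return np.stack(cols, axis=1) if cols else np.zeros((m.ntax, 0), dtype=np.int64)


# ---------------------------------------------------------------------------
# Fitch step counting
# ---------------------------------------------------------------------------


def _fitch_all(tree: Tree, masks: np.ndarray, taxon_index: dict[str, int]) -> np.ndarray:
    """Vector of Fitch step counts, one per character.

    Exact for binary trees: the tree is rooted through the smallest leaf so
    every internal node combines exactly two children, plus a final
    intersection with the root leaf itself.
    """
    ref = min(tree.leaf_label, key=lambda v: tree.leaf_label[v])
    order, children, _ = tree.rooted_view(root=ref)
    nchar = masks.shape[1]
    steps = np.zeros(nchar, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for v in order:
        if v in tree.leaf_label and v != ref:
            state[v] = masks[taxon_index[tree.leaf_label[v]]]
            continue
        kids = children[v]
        if not kids:  # isolated ref leaf (2-taxon tree edge case)
            state[v] = masks[taxon_index[tree.leaf_label[v]]]
            continue
        acc = state[kids[0]]
        for c in kids[1:]:
            inter = acc & state[c]
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | state[c], inter)
        if v == ref:  # fold the root leaf's own state set in
            own = masks[taxon_index[tree.leaf_label[v]]]
            inter = acc & own
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | own, inter)
        state[v] = acc
    return steps


def fitch_steps(tree: Tree | TreeRecord, char_column: Sequence[CellState],
                taxon_names: Sequence[str] | None = None) -> int:
    """Minimum number of state changes for one unordered character.

    ``taxon_names`` gives the order of ``char_column``; by default leaves are
    matched by sorted label order.  Missing/inapplicable/polymorphic cells
    contribute their full permitted state set.
    """
    t = as_tree(tree)
    if taxon_names is None:
        taxon_names = sorted(t.leaf_names)
    if len(taxon_names) != len(char_column):
        raise ValueError("char_column length != number of taxa")
    missing_leaves = t.leaf_names - set(taxon_names)
    if missing_leaves:
        raise ValueError(f"no cell for leaves {sorted(missing_leaves)}")
    idx = {name: i for i, name in enumerate(taxon_names)}
    masks = _column_masks(char_column)[:, None]
    return int(_fitch_all(t, masks, idx)[0])


def char_min_steps(char_column: Sequence[CellState]) -> int:
    """Minimum steps attainable on *any* tree: the smallest number of states
    that can cover every observed cell, minus one (a minimum hitting set;
    polymorphic cells are satisfied by any member state)."""
    sets = [c.states for c in char_column if c.states]
    if not sets:
        return 0
    universe = sorted(set().union(*sets))
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                return size - 1
    return len(universe) - 1  # unreachable


def implied_fit(extra_steps: float, k: float) -> float:
    """Goloboff concave fit ``k / (k + e)`` in (0, 1]."""
    if extra_steps < 0:
        raise ValueError("extra_steps must be >= 0")
    if math.isinf(k):
        return 1.0
    return k / (k + extra_steps)


def score_tree(tree: Tree | TreeRecord, m: CharacterMatrix, k: float = 3.0,
               _masks: np.ndarray | None = None,
               _min_steps: np.ndarray | None = None) -> ParsimonyScore:
    """Full implied-weighting score of one tree against a matrix."""
    t = as_tree(tree)
    if t.leaf_names != frozenset(m.taxon_names):
        raise ValueError("tree leaf set != matrix taxon set")
    masks = encode_matrix(m) if _masks is None else _masks
    idx = {name: i for i, name in enumerate(m.taxon_names)}
    steps = _fitch_all(t, masks, idx)
    if _min_steps is None:
        _min_steps = np.array([char_min_steps(col) for col in m.columns()], dtype=np.int64)
    extra = steps - _min_steps
    if np.any(extra < 0):
        raise AssertionError("steps below theoretical minimum")
    if math.isinf(k):
        fit = np.ones_like(extra, dtype=float)
        dist = np.zeros_like(extra, dtype=float)
    else:
        fit = k / (k + extra)
        dist = extra / (k + extra)
    return ParsimonyScore(
        per_char_steps=steps,
        per_char_min=_min_steps,
        per_char_extra=extra,
        fit_total=float(fit.sum()),
        distortion_total=float(dist.sum()),
        steps_total=int(steps.sum()),
        concavity_k=k,
    )


# ---------------------------------------------------------------------------
# Tree moves
# ---------------------------------------------------------------------------


def random_addition_tree(m: CharacterMatrix, rng: np.random.Generator,
                         k: float = 3.0,
                         masks: np.ndarray | None = None,
                         min_steps: np.ndarray | None = None) -> Tree:
    """Greedy random stepwise addition: taxa join in shuffled order at the
    attachment edge that maximises the implied-weights objective."""
    names = list(m.taxon_names)
    if len(names) < 4:
        raise ValueError("need >= 4 taxa")
    if masks is None:
        masks = encode_matrix(m)
    if min_steps is None:
        min_steps = np.array([char_min_steps(col) for col in m.columns()], dtype=np.int64)
    idx = {name: i for i, name in enumerate(names)}
    order = list(rng.permutation(len(names)))

    t = Tree()
    hub = t.new_node()
    for i in order[:3]:
        t.add_edge(hub, t.new_node(names[i]))

    def objective(tree: Tree) -> float:
        steps = _fitch_all(tree, masks, idx)
        extra = steps - min_steps
        if math.isinf(k):
            return -float(steps.sum())
        return float((k / (k + extra)).sum())

    for i in order[3:]:
        best: tuple[float, tuple[int, int]] | None = None
        candidates = t.edges()
        rng.shuffle(candidates)
        for (u, v) in candidates:
            trial = t.copy()
            mid = trial.new_node()
            trial.remove_edge(u, v)
            trial.add_edge(u, mid)
            trial.add_edge(mid, v)
            trial.add_edge(mid, trial.new_node(names[i]))
            sc = objective(trial)
            if best is None or sc > best[0] + _TOL:
                best = (sc, (u, v))
        u, v = best[1]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(mid, t.new_node(names[i]))
    return t


def tbr_neighbors(tree: Tree, rng: np.random.Generator | None = None) -> Iterator[Tree]:
    """Yield every TBR rearrangement of a binary unrooted tree.

    Each tree edge is bisected and the two fragments rejoined across every
    pair of fragment edges (a lone-leaf fragment reattaches by the leaf
    itself, which makes leaf-SPR a subset of the neighbourhood).  Order is
    shuffled when ``rng`` is given.
    """
    edges = tree.edges()
    if rng is not None:
        rng.shuffle(edges)
    for (u, v) in edges:
        base = tree.copy()
        base.remove_edge(u, v)
        comp_u = _component(base, u)
        # suppress the cut endpoints if they became degree-2 internals
        for w in (u, v):
            if w not in base.leaf_label and len(base.adj[w]) == 2:
                a, b = base.adj[w]
                base.remove_edge(a, w)
                base.remove_edge(b, w)
                del base.adj[w]
                base.add_edge(a, b)
        comp_u = {n for n in comp_u if n in base.adj}
        edges_u = [(a, b) for (a, b) in base.edges() if a in comp_u]
        edges_v = [(a, b) for (a, b) in base.edges() if a not in comp_u]
        att_u = edges_u if edges_u else [next(iter(n for n in comp_u))]
        att_v = edges_v if edges_v else [next(iter(n for n in base.adj if n not in comp_u))]
        if rng is not None:
            rng.shuffle(att_u)
            rng.shuffle(att_v)
        for ea in att_u:
            for eb in att_v:
                t2 = base.copy()
                na = _attach_point(t2, ea)
                nb = _attach_point(t2, eb)
                t2.add_edge(na, nb)
                yield t2


def _component(tree: Tree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in tree.adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _attach_point(t: Tree, spec) -> int:
    if isinstance(spec, tuple):
        a, b = spec
        mid = t.new_node()
        t.remove_edge(a, b)
        t.add_edge(a, mid)
        t.add_edge(mid, b)
        return mid
    return spec


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


class MPSearchResult(Sequence):
    """Sequence of optimal :class:`TreeRecord` plus search metadata."""

    def __init__(self, trees: list[TreeRecord], best_score: ParsimonyScore,
                 hits: int, n_starts_used: int, budget_exhausted: bool):
        self.trees = trees
        self.best_score = best_score
        self.hits = hits
        self.n_starts_used = n_starts_used
        self.budget_exhausted = budget_exhausted

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def __repr__(self) -> str:
        return (
            f"<MPSearchResult {len(self.trees)} trees, objective "
            f"{self.best_score.objective:.4f}, hits {self.hits}, "
            f"starts {self.n_starts_used}>"
        )


def _hill_climb(tree: Tree, objective, rng: np.random.Generator,
                plateau_cap: int = 200) -> tuple[float, dict]:
    """First-improvement TBR hill climbing, then a bounded plateau walk that
    collects distinct equal-best topologies (deduplicated by split set)."""
    cur = tree
    cur_score = objective(cur)
    improved = True
    while improved:
        improved = False
        for nb in tbr_neighbors(cur, rng):
            sc = objective(nb)
            if sc > cur_score + _TOL:
                cur, cur_score = nb, sc
                improved = True
                break
    # plateau: explore equal-score neighbours breadth-first
    pool: dict[frozenset, Tree] = {cur.splits(): cur}
    frontier = [cur]
    while frontier and len(pool) < plateau_cap:
        nxt = frontier.pop()
        for nb in tbr_neighbors(nxt, rng):
            key = nb.splits()
            if key in pool:
                continue
            sc = objective(nb)
            if abs(sc - cur_score) <= _TOL:
                pool[key] = nb
                frontier.append(nb)
                if len(pool) >= plateau_cap:
                    break
    return cur_score, pool


def search_mp(m: CharacterMatrix, s: SearchSettings) -> MPSearchResult:
    """Multi-start random-addition + TBR search under implied weighting.

    Stops once the best objective has been recovered by ``required_hits``
    independent starts, or when the start budget runs out (the result is
    then flagged ``budget_exhausted`` and a warning is raised).
    """
    if m.ntax < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(s.seed)
    masks = encode_matrix(m)
    min_steps = np.array([char_min_steps(col) for col in m.columns()], dtype=np.int64)
    idx = {name: i for i, name in enumerate(m.taxon_names)}
    k = s.concavity_k

    def objective(tree: Tree) -> float:
        steps = _fitch_all(tree, masks, idx)
        if math.isinf(k):
            return -float(steps.sum())
        extra = steps - min_steps
        return float((k / (k + extra)).sum())

    best_score = -math.inf
    best_pool: dict[frozenset, Tree] = {}
    hits = 0
    starts_used = 0
    for _ in range(s.n_random_addition_starts):
        starts_used += 1
        start = random_addition_tree(m, rng, k=k, masks=masks, min_steps=min_steps)
        sc, pool = _hill_climb(start, objective, rng)
        if sc > best_score + _TOL:
            best_score, best_pool, hits = sc, dict(pool), 1
        elif abs(sc - best_score) <= _TOL:
            best_pool.update(pool)
            hits += 1
        if hits >= s.required_hits:
            break
    budget_exhausted = hits < s.required_hits
    if budget_exhausted:
        warnings.warn(
            f"start budget exhausted: best score hit {hits} < {s.required_hits} times",
            stacklevel=2,
        )
    trees = [
        TreeRecord(t, Provenance(analysis="mp", index=i))
        for i, (_, t) in enumerate(sorted(best_pool.items(), key=lambda kv: sorted(map(sorted, kv[0]))))
    ]
    final = score_tree(trees[0], m, k, _masks=masks, _min_steps=min_steps)
    return MPSearchResult(trees, final, hits, starts_used, budget_exhausted)


def strict_consensus(trees: Sequence[TreeRecord | Tree]) -> TreeRecord:
    """Tree displaying exactly the splits common to every input tree."""
    if not trees:
        raise ValueError("need >= 1 tree")
    ts = [as_tree(t) for t in trees]
    leaves = ts[0].leaf_names
    for t in ts[1:]:
        if t.leaf_names != leaves:
            raise ValueError("leaf sets differ")
    common = ts[0].splits()
    for t in ts[1:]:
        common &= t.splits()
    tree, _ = tree_from_splits(leaves, common)
    return TreeRecord(tree, Provenance(analysis="strict_consensus"))


# ---------------------------------------------------------------------------
# Exhaustive enumeration (small-n oracle and exact search)
# ---------------------------------------------------------------------------


def all_unrooted_topologies(leaf_names: Sequence[str]) -> Iterator[Tree]:
    """Generate all (2n-5)!! unrooted binary topologies by sequential leaf
    insertion; intended for n <= 8."""
    names = list(leaf_names)
    if len(names) < 3:
        raise ValueError("need >= 3 leaves")

    base = Tree()
    hub = base.new_node()
    for nm in names[:3]:
        base.add_edge(hub, base.new_node(nm))

    def expand(t: Tree, rest: list[str]) -> Iterator[Tree]:
        if not rest:
            yield t
            return
        nm = rest[0]
        for (u, v) in t.edges():
            t2 = t.copy()
            mid = t2.new_node()
            t2.remove_edge(u, v)
            t2.add_edge(u, mid)
            t2.add_edge(mid, v)
            t2.add_edge(mid, t2.new_node(nm))
            yield from expand(t2, rest[1:])

    yield from expand(base, names[3:])
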