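"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from stemphylo.nexus_io import CellState, CharacterMatrix, MISSING, Tree
from stemphylo import synthdata
from stemphylo.hypothesis import CladeDefinitions
from stemphylo.mk_mcmc import transition_prob


# ---------------------------------------------------------------------------
# Oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------


def brute_force_fitch(tree: Tree, column, taxon_names) -> int:
    """Minimum state changes by exhaustive enumeration of internal-node
    labelings over the union of permitted states."""
    idx = {n: i for i, n in enumerate(taxon_names)}
    allowed: set[int] = set()
    for c in column:
        allowed |= c.states
    if not allowed:
        return 0
    states = sorted(allowed)
    order, children, parent = tree.rooted_view()
    internal = [v for v in order if children[v]]
    best = math.inf
    for assign in itertools.product(states, repeat=len(internal)):
        amap = dict(zip(internal, assign))
        # leaves may take any permitted state: minimise per leaf
        cost = 0
        for v in order[:-1]:
            p = parent[v]
            if v in tree.leaf_label:
                cell = column[idx[tree.leaf_label[v]]]
                perm = cell.states if cell.states else set(states)
                cost += 0 if amap[p] in perm else 1
            else:
                cost += 0 if amap[v] == amap[p] else 1
        best = min(best, cost)
    return int(best)


def brute_force_loglik(tree: Tree, column, k: int, taxon_names) -> float:
    """Column likelihood by exhaustive summation over internal states."""
    idx = {n: i for i, n in enumerate(taxon_names)}
    order, children, parent = tree.rooted_view()
    internal = [v for v in order if children[v]]
    pmats: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        if t not in pmats:
            pmats[t] = transition_prob(k, t)
        return pmats[t]

    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = 1.0 / k  # uniform prior on the root state
        for v in order[:-1]:
            par = parent[v]
            bl = tree.edge_length(v, par)
            if v in tree.leaf_label:
                cell = column[idx[tree.leaf_label[v]]]
                perm = cell.states if cell.states else set(range(k))
                p *= sum(P(bl)[amap[par], s] for s in perm)
            else:
                p *= P(bl)[amap[par], amap[v]]
        total += p
    return math.log(total)


def splits_by_enumeration(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial splits via explicit edge removal and flood fill —
    independent of Tree.splits()'s traversal bookkeeping."""
    names = tree.leaf_names
    ref = min(names)
    out: set[frozenset[str]] = set()
    for (u, v) in tree.edges():
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in tree.adj[x]:
                if y == v and x == u:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(tree.leaf_label[x] for x in seen if x in tree.leaf_label)
        if ref in side:
            side = names - side
        if 2 <= len(side) <= len(names) - 2:
            out.add(side)
    return out


def random_column(rng: np.random.Generator, n: int, k: int = 2,
                  p_missing: float = 0.15, p_poly: float = 0.1):
    out = []
    for _ in range(n):
        u = rng.uniform()
        if u < p_missing:
            out.append(MISSING)
        elif u < p_missing + p_poly and k >= 2:
            pair = rng.choice(k, size=2, replace=False)
            out.append(CellState.polymorphic(int(s) for s in pair))
        else:
            out.append(CellState.observed(int(rng.integers(k))))
    return out


def random_binary_tree(names, rng: np.random.Generator) -> Tree:
    names = list(names)
    t = Tree()
    hub = t.new_node()
    order = list(rng.permutation(names))
    for nm in order[:3]:
        t.add_edge(hub, t.new_node(nm))
    for nm in order[3:]:
        edges = t.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(mid, t.new_node(nm))
    return t


def random_matrix(rng: np.random.Generator, ntax: int, nchar: int,
                  k: int = 2, **kw) -> CharacterMatrix:
    names = [f"t{i}" for i in range(ntax)]
    cols = [random_column(rng, ntax, k, **kw) for _ in range(nchar)]
    return CharacterMatrix(
        taxon_names=names,
        cells=[[cols[j][i] for j in range(nchar)] for i in range(ntax)],
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_suite():
    """Study-shaped synthetic fixture set (57 x 129 with groups)."""
    return synthdata.generate_fixture_suite(synthdata.SimConfig(seed=20))


@pytest.fixture(scope="session")
def toy_defs() -> CladeDefinitions:
    return CladeDefinitions(
        opabiniids=frozenset({"Opa", "Uta"}),
        radiodonts=frozenset({"R1", "R2"}),
        deuteropods=frozenset({"D1", "D2"}),
        castle_bank=frozenset({"CB"}),
        outgroup=frozenset({"OG"}),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
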