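"""Synthetic trees, matrices and tree samples for end-to-end testing.

The generator emulates the structure of the study matrix — ~57 taxa (11
extant, 46 fossil) by ~129 unordered multistate characters, with missing
data concentrated in the fossil taxa and a clade template containing
opabiniid, radiodont, deuteropod, Castle Bank and outgroup groups — so that
every pipeline stage can be exercised without any download.  Trees are
pure-birth (Yule) with optional monophyly constraints; characters evolve
forward under the same Mk process the inference assumes; missingness is
independent per cell at taxon-class rates.  Every stochastic operation takes
an explicit seed and the fixture manifest records all seeds and truths, so
fixtures regenerate exactly.

Yule trees are a deliberate simplification (no extinction or fossil
sampling): the fixtures need topological truth and a realistic spread of
branch lengths, not a realistic diversification process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mk_mcmc import transition_prob
from .nexus_io import (
    CellState,
    CharacterMatrix,
    MISSING,
    Provenance,
    Tree,
    TreeRecord,
    as_tree,
    serialize_matrix,
    serialize_trees,
)

__all__ = [
    "SimConfig",
    "FixtureSuite",
    "simulate_yule_tree",
    "simulate_characters",
    "apply_missingness",
    "simulate_category_tree_sample",
    "generate_fixture_suite",
    "default_group_template",
]


def default_group_template() -> dict[str, list[str]]:
    """Clade template mirroring the study groups at the study's matrix size."""
    return {
        "outgroup": ["og1", "og2"],
        "opabiniids": ["opabiniid1", "opabiniid2"],
        "castle_bank": ["castle_bank1", "castle_bank2"],
        "radiodonts": [f"radiodont{i}" for i in range(1, 7)],
        "deuteropods": [f"deuteropod{i}" for i in range(1, 26)],
    }


def scaled_group_template(n_taxa: int) -> dict[str, list[str]]:
    """The default template shrunk to smaller matrices (>= 10 taxa): the
    outgroup, opabiniid and Castle Bank pairs are kept, radiodont and
    deuteropod group sizes scale with the taxon count."""
    if n_taxa < 10:
        raise ValueError("need >= 10 taxa for the full group template")
    if n_taxa >= 37:
        return default_group_template()
    spare = n_taxa - 8  # after og/opabiniid/castle_bank pairs and 2 free taxa
    n_rad = max(1, spare // 3)
    n_deut = max(1, spare - n_rad - spare // 4)
    return {
        "outgroup": ["og1", "og2"],
        "opabiniids": ["opabiniid1", "opabiniid2"],
        "castle_bank": ["castle_bank1", "castle_bank2"],
        "radiodonts": [f"radiodont{i}" for i in range(1, n_rad + 1)],
        "deuteropods": [f"deuteropod{i}" for i in range(1, n_deut + 1)],
    }


@dataclass
class SimConfig:
    """Study-shaped defaults: 57 taxa (11 extant, 46 fossil) x 129 characters.

    ``state_count_distribution`` reflects a mostly-binary morphological
    matrix; missing-data rates put the bulk of the gaps in fossil taxa;
    ``char_rate`` scales branch lengths (the generating tree is rescaled to
    unit mean root-to-tip depth) to a moderately informative regime.
    """

    n_taxa: int = 57
    n_chars: int = 129
    state_count_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.75, 3: 0.15, 4: 0.10}
    )
    fossil_fraction: float = 46 / 57
    missing_fraction_fossil: float = 0.45
    missing_fraction_extant: float = 0.05
    tree_model: str = "yule"
    birth_rate: float = 1.0
    char_rate: float = 0.4
    group_template: dict[str, list[str]] = field(default_factory=default_group_template)
    n_extant: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.state_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("state_count_distribution must sum to 1")
        for f in (self.fossil_fraction, self.missing_fraction_fossil,
                  self.missing_fraction_extant):
            if not (0 <= f <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.tree_model != "yule":
            raise ValueError("only the yule tree model is supported")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _yule_rooted(labels: Sequence[str], birth_rate: float,
                 rng: np.random.Generator, tree: Tree | None = None) -> tuple[Tree, int]:
    """Grow a rooted ultrametric pure-birth tree over ``labels`` inside
    ``tree`` (a fresh one by default); returns (tree, root node)."""
    t = tree if tree is not None else Tree()
    if len(labels) == 1:
        return t, t.new_node(labels[0])
    root = t.new_node()
    pending: dict[int, tuple[int | None, float]] = {root: (None, 0.0)}
    active = [root]
    now = 0.0
    while len(active) < len(labels):
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        v = active.pop(int(rng.integers(len(active))))
        parent, tb = pending.pop(v)
        if parent is not None:
            t.add_edge(parent, v, now - tb)
        for _ in range(2):
            c = t.new_node()
            pending[c] = (v, now)
            active.append(c)
    end = now + rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(len(active))
    for slot, lab in zip(order, labels):
        v = active[int(slot)]
        parent, tb = pending.pop(v)
        t.leaf_label[v] = lab
        t.add_edge(parent, v, end - tb)
    return t, root


def _subtree_height(t: Tree, root: int) -> float:
    order, children, parent = t.rooted_view(root)
    depth = {root: 0.0}
    for v in reversed(order):  # pre-order
        for c in children[v]:
            depth[c] = depth[v] + (t.edge_length(c, v) or 0.0)
    return max(depth[v] for v in t.adj if v in depth)


def _scale_subtree(t: Tree, root: int, factor: float) -> None:
    order, _, parent = t.rooted_view(root)
    for v in order[:-1]:
        p = parent[v]
        t.set_edge_length(v, p, (t.edge_length(v, p) or 0.0) * factor)


def simulate_yule_tree(n_taxa: int, birth_rate: float = 1.0,
                       constraints: Mapping[str, Sequence[str]] | None = None,
                       seed: int = 0,
                       free_labels: Sequence[str] | None = None) -> TreeRecord:
    """Pure-birth tree with ``n_taxa`` leaves and branch lengths.

    ``constraints`` maps group names to member labels; each group is grown
    as its own Yule subtree grafted onto a backbone Yule tree over group
    placeholders and free taxa, so every named group is monophyletic.  The
    result is rescaled to unit root-to-tip height and returned unrooted.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng((seed, 104729))
    constraints = dict(constraints or {})
    grouped: list[str] = []
    for g, members in constraints.items():
        if not members:
            raise ValueError(f"constraint group {g!r} is empty")
        overlap = set(members) & set(grouped)
        if overlap:
            raise ValueError(f"taxa in multiple constraint groups: {sorted(overlap)}")
        grouped.extend(members)
    n_free = n_taxa - len(grouped)
    if n_free < 0:
        raise ValueError("constraint groups name more taxa than n_taxa")
    if free_labels is None:
        free_labels = [f"t{i + 1}" for i in range(n_free)]
    if len(free_labels) != n_free:
        raise ValueError("free_labels length mismatch")
    clash = set(free_labels) & set(grouped)
    if clash:
        raise ValueError(f"free labels collide with group members: {sorted(clash)}")

    unit_labels = [f"__group__{g}" for g in constraints] + list(free_labels)
    if len(unit_labels) == 1:
        raise ValueError("constraints collapse the backbone to a single unit")
    t, root = _yule_rooted(unit_labels, birth_rate, rng)
    # graft group subtrees onto their placeholder leaves
    for g, members in constraints.items():
        placeholder = next(v for v, lab in t.leaf_label.items() if lab == f"__group__{g}")
        parent = t.adj[placeholder][0]
        pendant = t.edge_length(placeholder, parent) or 1.0
        del t.leaf_label[placeholder]
        if len(members) == 1:
            t.leaf_label[placeholder] = members[0]
            continue
        t.remove_edge(placeholder, parent)
        t.delete_node(placeholder)
        _, sub_root = _yule_rooted(list(members), birth_rate, rng, tree=t)
        h = _subtree_height(t, sub_root)
        if h > 0:
            _scale_subtree(t, sub_root, (pendant / 2.0) / h)
        t.add_edge(parent, sub_root, pendant / 2.0)
    height = _subtree_height(t, root)
    if height > 0:
        _scale_subtree(t, root, 1.0 / height)
    t.suppress_degree_two()
    return TreeRecord(t, Provenance(analysis="yule"))


# ---------------------------------------------------------------------------
# Characters and missingness
# ---------------------------------------------------------------------------


def simulate_characters(tree: Tree | TreeRecord, n_chars: int,
                        state_count_distribution: Mapping[int, float],
                        char_rate: float = 0.4, seed: int = 0) -> CharacterMatrix:
    """Evolve unordered characters forward along the tree under Mk.

    Per character: the state count k is drawn from the distribution, the
    root state uniformly, and states propagate with the Mk transition
    probabilities over ``branch length x char_rate``.
    """
    t = as_tree(tree)
    if t.blen is None:
        raise ValueError("branch lengths required")
    rng = np.random.default_rng((seed, 15485863))
    ks = sorted(state_count_distribution)
    probs = np.array([state_count_distribution[k] for k in ks], dtype=float)
    order, children, parent = t.rooted_view()
    preorder = list(reversed(order))
    taxon_names = sorted(t.leaf_names)
    cols: dict[str, list[CellState]] = {nm: [] for nm in taxon_names}
    for _ in range(n_chars):
        k = int(ks[rng.choice(len(ks), p=probs)])
        P_cache: dict[float, np.ndarray] = {}
        state: dict[int, int] = {}
        root = preorder[0]
        state[root] = int(rng.integers(k))
        for v in preorder[1:]:
            p = parent[v]
            bl = (t.edge_length(v, p) or 0.0) * char_rate
            P = P_cache.get(bl)
            if P is None:
                P = transition_prob(k, bl)
                P_cache[bl] = P
            state[v] = int(rng.choice(k, p=P[state[p]]))
        for v, lab in t.leaf_label.items():
            cols[lab].append(CellState.observed(state[v]))
    return CharacterMatrix(
        taxon_names=taxon_names,
        cells=[cols[nm] for nm in taxon_names],
    )


def apply_missingness(m: CharacterMatrix, fossil_taxa: Sequence[str],
                      f_fossil: float, f_extant: float, seed: int = 0) -> CharacterMatrix:
    """Independently blank cells to missing at the taxon-class rate."""
    for f in (f_fossil, f_extant):
        if not (0 <= f <= 1):
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng((seed, 32452843))
    fossil = set(fossil_taxa)
    out = m.copy()
    for t, row in zip(out.taxon_names, out.cells):
        rate = f_fossil if t in fossil else f_extant
        if rate == 0:
            continue
        hits = rng.uniform(size=len(row)) < rate
        for j, h in enumerate(hits):
            if h:
                row[j] = MISSING
    return out


# ---------------------------------------------------------------------------
# Labelled tree samples with known category mixture
# ---------------------------------------------------------------------------


def _rand_subtree(t: Tree, labels: Sequence[str], rng: np.random.Generator) -> int:
    """Random binary subtree over ``labels`` built inside ``t``; returns its
    root (degree 2 internal, or the leaf itself for one label)."""
    nodes = [t.new_node(lab) for lab in labels]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        p = t.new_node()
        t.add_edge(p, a)
        t.add_edge(p, b)
        nodes.append(p)
    return nodes[0]


def _join_all(t: Tree, roots: list[int], rng: np.random.Generator) -> int:
    while len(roots) > 1:
        a = roots.pop(int(rng.integers(len(roots))))
        b = roots.pop(int(rng.integers(len(roots))))
        p = t.new_node()
        t.add_edge(p, a)
        t.add_edge(p, b)
        roots.append(p)
    return roots[0]


def _category_tree(category: str, defs, free_taxa: Sequence[str],
                   rng: np.random.Generator) -> Tree:
    cb = sorted(defs.castle_bank)
    opab = sorted(defs.opabiniids)
    rad = sorted(defs.radiodonts)
    deut = sorted(defs.deuteropods)
    og = sorted(defs.outgroup)
    t = Tree()
    free_roots = [t.new_node(x) for x in free_taxa]
    if category == "monophyletic_proboscis":
        focal = _rand_subtree(t, cb + opab, rng)
        rest = [focal, _rand_subtree(t, rad, rng), _rand_subtree(t, deut, rng)] + free_roots
        top = _join_all(t, rest, rng)
    elif category == "paraphyletic_grade":
        rd = t.new_node()
        t.add_edge(rd, _rand_subtree(t, rad, rng))
        t.add_edge(rd, _rand_subtree(t, deut, rng))
        p = t.new_node()
        t.add_edge(p, _rand_subtree(t, cb, rng))
        t.add_edge(p, rd)
        rest = [p, _rand_subtree(t, opab, rng)] + free_roots
        top = _join_all(t, rest, rng)
    elif category == "other":
        if len(opab) < 2:
            raise ValueError("the 'other' generator needs >= 2 opabiniids")
        inner = _rand_subtree(t, cb + [opab[0]], rng)
        a = t.new_node()
        t.add_edge(a, inner)
        t.add_edge(a, _rand_subtree(t, rad, rng))
        b = t.new_node()
        t.add_edge(b, a)
        t.add_edge(b, _rand_subtree(t, deut, rng))
        rest = [b] + [t.new_node(opab[i]) for i in range(1, len(opab))] + free_roots
        top = _join_all(t, rest, rng)
    else:
        raise ValueError(f"unknown category {category!r}")
    root = t.new_node()
    t.add_edge(root, top)
    t.add_edge(root, _rand_subtree(t, og, rng))
    t.suppress_degree_two()
    return t


def simulate_category_tree_sample(defs, mixture: Mapping[str, float], n: int,
                                  free_taxa: Sequence[str] = (), seed: int = 0,
                                  analysis: str = "synthetic_posterior"
                                  ) -> tuple[list[TreeRecord], list[str]]:
    """Tree sample with a known placement-category mixture.

    Categories are drawn i.i.d. from ``mixture`` (binomial sampling), so
    recovered proportions concentrate around the mixture at rate 1/sqrt(n).
    Returns (trees, true category labels).
    """
    probs = {k: v for k, v in mixture.items()}
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1")
    rng = np.random.default_rng((seed, 49979687))
    cats = list(probs)
    p = np.array([probs[c] for c in cats])
    draws = rng.choice(len(cats), size=n, p=p)
    trees: list[TreeRecord] = []
    truth: list[str] = []
    for i, d in enumerate(draws):
        cat = cats[int(d)]
        tree = _category_tree(cat, defs, free_taxa, rng)
        trees.append(TreeRecord(tree, Provenance(analysis=analysis, index=i)))
        truth.append(cat)
    return trees, truth


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------


@dataclass
class FixtureSuite:
    paper_shaped_matrix: CharacterMatrix
    generating_tree: TreeRecord
    oracle_matrices: list[CharacterMatrix]
    oracle_trees: list[TreeRecord]
    category_sample: list[TreeRecord]
    category_truth: list[str]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "paper_shaped.nex").write_text(serialize_matrix(self.paper_shaped_matrix))
        (out / "generating_tree.nwk").write_text(serialize_trees([self.generating_tree]))
        for i, (m, t) in enumerate(zip(self.oracle_matrices, self.oracle_trees)):
            (out / f"oracle_{i}.nex").write_text(serialize_matrix(m))
            (out / f"oracle_tree_{i}.nwk").write_text(serialize_trees([t]))
        (out / "category_sample.nwk").write_text(serialize_trees(self.category_sample))
        (out / "category_truth.tsv").write_text(
            "tree_index\tcategory\n"
            + "".join(f"{i}\t{c}\n" for i, c in enumerate(self.category_truth))
        )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def generate_fixture_suite(cfg: SimConfig | None = None,
                           out_dir: str | Path | None = None) -> FixtureSuite:
    """Build the full fixture set: a study-shaped matrix with named groups
    and fossil-biased missingness, small oracle matrices for exhaustive
    checks, and a labelled tree sample with a known category mixture."""
    cfg = cfg or SimConfig()
    template = {g: list(members) for g, members in cfg.group_template.items()}
    rec = simulate_yule_tree(cfg.n_taxa, cfg.birth_rate, constraints=template,
                             seed=cfg.seed)
    m = simulate_characters(rec, cfg.n_chars, cfg.state_count_distribution,
                            cfg.char_rate, seed=cfg.seed)
    # extant taxa: crown-ward deuteropods plus any surplus from the outgroup
    deut = template.get("deuteropods", [])
    og = template.get("outgroup", [])
    extant = (deut[: cfg.n_extant] + og)[: cfg.n_extant]
    flags = {t: ("extant" if t in extant else "fossil") for t in m.taxon_names}
    m.taxon_flags = flags
    m.group_map = {g: frozenset(members) for g, members in template.items()}
    fossil = [t for t, f in flags.items() if f == "fossil"]
    m = apply_missingness(m, fossil, cfg.missing_fraction_fossil,
                          cfg.missing_fraction_extant, seed=cfg.seed)

    oracle_matrices: list[CharacterMatrix] = []
    oracle_trees: list[TreeRecord] = []
    for i in range(2):
        otree = simulate_yule_tree(6, cfg.birth_rate, seed=cfg.seed + 1000 + i)
        om = simulate_characters(otree, 20, {2: 1.0}, cfg.char_rate,
                                 seed=cfg.seed + 1000 + i)
        oracle_matrices.append(om)
        oracle_trees.append(otree)

    from .hypothesis import CladeDefinitions

    defs = CladeDefinitions.from_matrix(m)
    free = sorted(
        set(m.taxon_names)
        - set().union(*(set(v) for v in template.values()))
    )
    mixture = {"monophyletic_proboscis": 0.3, "paraphyletic_grade": 0.6, "other": 0.1}
    sample, truth = simulate_category_tree_sample(
        defs, mixture, n=500, free_taxa=free, seed=cfg.seed
    )

    manifest = {
        "seed": cfg.seed,
        "n_taxa": cfg.n_taxa,
        "n_chars": cfg.n_chars,
        "char_rate": cfg.char_rate,
        "missing_fraction_fossil": cfg.missing_fraction_fossil,
        "missing_fraction_extant": cfg.missing_fraction_extant,
        "groups": {g: sorted(v) for g, v in template.items()},
        "extant": sorted(extant),
        "category_mixture": mixture,
        "category_sample_size": len(sample),
        "generating_tree_newick": rec.to_newick(),
    }
    suite = FixtureSuite(
        paper_shaped_matrix=m,
        generating_tree=rec,
        oracle_matrices=oracle_matrices,
        oracle_trees=oracle_trees,
        category_sample=sample,
        category_truth=truth,
        manifest=manifest,
    )
    if out_dir is not None:
        suite.write(out_dir)
    return suite
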