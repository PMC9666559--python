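"""Bayesian inference of topology under the Mk model.

The Mk model is the k-state symmetric Markov process: all transitions share
one rate and the stationary distribution is uniform.  With the rate matrix
normalised so branch lengths are expected substitutions per character, the
transition probability has the closed form

    P(same state, t) = 1/k + (k-1)/k * exp(-k t / (k-1))
    P(specific different state, t) = 1/k - 1/k * exp(-k t / (k-1))

Likelihoods are computed by Felsenstein pruning with uniform root
frequencies; missing/inapplicable cells contribute a partial vector of ones
and polymorphic cells a 0/1 indicator over their member states.  The Mkv
ascertainment correction divides each character's likelihood by the
probability of a variable column on the same tree, compensating for the fact
that constant morphological characters are never scored.

Sampling is Metropolis-coupled MCMC: several independent runs, each with one
cold chain and geometrically heated companions that exchange states, mixing
NNI and SPR topology proposals with branch-length multipliers.  Convergence
is assessed by the average standard deviation of split frequencies across
runs (ASDSF, study threshold < 0.01) and per-parameter effective sample
sizes (study threshold > 200).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

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
    "MkModelConfig",
    "RunSettings",
    "PosteriorSample",
    "transition_prob",
    "char_loglik",
    "matrix_loglik",
    "run_mcmc",
    "compute_asdsf",
    "compute_ess",
    "majority_consensus",
    "strategy_preset",
    "discrete_gamma_rates",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class MkModelConfig:
    """Model side of an analysis.

    ``strategy`` names the preset ('maximise_information' shares one
    exponential branch-length prior with fixed mean; 'minimise_assumptions'
    frees the prior mean as a sampled hyperparameter).  These presets are a
    documented reconstruction: the study defers exact per-strategy parameter
    blocks to its deposited run files, so every field here is overridable.
    """

    strategy: str = "maximise_information"
    gamma_rate_variation: bool = True
    n_rate_categories: int = 4
    ascertainment: str = "variable_only"  # or "none"
    branch_length_prior_mean: float = 0.1
    sample_prior_mean: bool = False  # hierarchical prior on the mean
    prior_only: bool = False  # validation mode: likelihood forced constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rate_categories < 1:
            raise ValueError("need >= 1 rate category")
        if self.branch_length_prior_mean <= 0:
            raise ValueError("branch length prior mean must be > 0")
        if self.ascertainment not in ("none", "variable_only"):
            raise ValueError("ascertainment must be 'none' or 'variable_only'")


def strategy_preset(name: str, **overrides) -> MkModelConfig:
    """Named model presets for the two analysis strategies."""
    if name == "maximise_information":
        cfg = MkModelConfig(strategy=name, gamma_rate_variation=True,
                            n_rate_categories=4, sample_prior_mean=False)
    elif name == "minimise_assumptions":
        cfg = MkModelConfig(strategy=name, gamma_rate_variation=True,
                            n_rate_categories=4, sample_prior_mean=True)
    else:
        raise ValueError(f"unknown strategy {name!r}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class RunSettings:
    """MCMC run geometry.  Defaults are desk scale; :meth:`paper_scale`
    returns the study's four runs of four chains at 20M generations."""

    n_runs: int = 2
    n_chains_per_run: int = 2
    n_generations: int = 200_000
    sample_every: int = 200
    burnin_fraction: float = 0.25
    heating_increment: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction in [0, 1)")
        if self.heating_increment <= 0:
            raise ValueError("heating_increment must be > 0")
        if self.n_generations <= 0:
            raise ValueError("n_generations must be > 0")

    @classmethod
    def desk_scale(cls) -> "RunSettings":
        return cls()

    @classmethod
    def paper_scale(cls) -> "RunSettings":
        return cls(n_runs=4, n_chains_per_run=4, n_generations=20_000_000,
                   sample_every=1000)


@dataclass
class PosteriorSample:
    """Post-burnin posterior sample pooled over runs.

    ``trees`` carry run/index provenance; ``lnL_trace`` and each entry of
    ``parameter_traces`` hold one post-burnin vector per run.
    """

    trees: list[TreeRecord]
    lnL_trace: list[np.ndarray]
    parameter_traces: dict[str, list[np.ndarray]]
    burnin_applied: bool
    n_runs: int
    settings: RunSettings | None = None

    def trees_by_run(self) -> list[list[TreeRecord]]:
        out: list[list[TreeRecord]] = [[] for _ in range(self.n_runs)]
        for rec in self.trees:
            out[rec.provenance.run].append(rec)
        return out


# ---------------------------------------------------------------------------
# Transition probabilities and likelihood
# ---------------------------------------------------------------------------


def transition_prob(k_states: int, t: float) -> np.ndarray:
    """Mk transition matrix for branch length ``t`` (expected substitutions
    per character)."""
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if t < 0:
        raise ValueError("t must be >= 0")
    k = k_states
    e = math.exp(-k * t / (k - 1))
    same = 1.0 / k + (k - 1) / k * e
    diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), diff)
    np.fill_diagonal(P, same)
    return P


def discrete_gamma_rates(shape: float, n_cat: int) -> np.ndarray:
    """Mean-one discrete gamma rates (median of equal-probability classes,
    renormalised to mean 1)."""
    if n_cat == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    q = (2 * np.arange(n_cat) + 1) / (2 * n_cat)
    r = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return r / r.mean()


@dataclass
class _CharGroup:
    k: int
    char_indices: list[int]
    partials: np.ndarray  # (ntax, nchar_group, k) 0/1 leaf partials


@dataclass
class MkData:
    """Matrix encoded for pruning, characters grouped by state count."""

    taxon_names: list[str]
    groups: list[_CharGroup]
    nchar: int


def encode_mk(m: CharacterMatrix) -> MkData:
    """Group characters by their state count (distinct observed states,
    minimum 2) and build 0/1 leaf partials with per-character state maps."""
    per_char: list[tuple[int, np.ndarray]] = []
    for j in range(m.nchar):
        obs = sorted(m.observed_states(j))
        k = max(2, len(obs))
        remap = {s: i for i, s in enumerate(obs)}
        part = np.ones((m.ntax, k))
        for i, row in enumerate(m.cells):
            cell = row[j]
            if cell.states:
                part[i, :] = 0.0
                for s in cell.states:
                    part[i, remap[s]] = 1.0
        per_char.append((k, part))
    groups: dict[int, list[int]] = {}
    for j, (k, _) in enumerate(per_char):
        groups.setdefault(k, []).append(j)
    out = []
    for k, idxs in sorted(groups.items()):
        stacked = np.stack([per_char[j][1] for j in idxs], axis=1)
        out.append(_CharGroup(k=k, char_indices=idxs, partials=stacked))
    return MkData(taxon_names=list(m.taxon_names), groups=out, nchar=m.nchar)


def _prune_group(tree: Tree, partials: np.ndarray, k: int,
                 taxon_index: Mapping[str, int], rates: np.ndarray,
                 traversal=None) -> np.ndarray:
    """(ncat, nchar) log-likelihoods for one state-count group, all rate
    categories evaluated in a single post-order pass."""
    order, children, _ = traversal if traversal is not None else tree.rooted_view()
    ncat = len(rates)
    nc = partials.shape[1]
    logscale = np.zeros((ncat, nc))
    rates_col = np.asarray(rates, dtype=float)[:, None, None]
    L: dict[int, np.ndarray] = {}
    for v in order:
        kids = children[v]
        if not kids:
            L[v] = np.broadcast_to(partials[taxon_index[tree.leaf_label[v]]],
                                   (ncat, nc, k))
            continue
        acc = None
        for c in kids:
            t = tree.edge_length(c, v)
            if t is None:
                raise ValueError("branch lengths required for likelihood")
            e = np.exp((-k / (k - 1)) * max(t, 0.0) * rates_col)
            diff = (1.0 - e) / k
            Lc = L[c]
            term = diff * Lc.sum(axis=2, keepdims=True) + e * Lc
            acc = term if acc is None else acc * term
        if v in tree.leaf_label:  # tree rooted at a leaf (2-leaf case)
            acc = acc * partials[taxon_index[tree.leaf_label[v]]]
        mx = acc.max(axis=2)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        L[v] = acc / mx[:, :, None]
    root = order[-1]
    site = L[root].sum(axis=2) / k  # uniform root frequencies
    with np.errstate(divide="ignore"):
        return np.log(site) + logscale


def _group_site_logliks(tree: Tree, grp: _CharGroup, taxon_index, rates: np.ndarray,
                        ascertainment: str, traversal=None) -> np.ndarray:
    """Per-character log-likelihoods, gamma-averaged, optionally corrected
    for the probability of a variable column (Mkv)."""
    per_cat = _prune_group(tree, grp.partials, grp.k, taxon_index, rates, traversal)
    mx = per_cat.max(axis=0)
    site = np.log(np.exp(per_cat - mx).mean(axis=0)) + mx
    if ascertainment == "variable_only":
        ntax = grp.partials.shape[0]
        const_part = np.zeros((ntax, 1, grp.k))
        const_part[:, 0, 0] = 1.0  # all leaves in state 0; symmetry covers the rest
        per_cat0 = _prune_group(tree, const_part, grp.k, taxon_index, rates, traversal)
        p0 = float(np.exp(per_cat0[:, 0]).mean())
        p_const = grp.k * p0
        if p_const >= 1.0:
            raise FloatingPointError("constant-column probability reached 1")
        site = site - math.log1p(-p_const)
    return site


def char_loglik(tree: Tree | TreeRecord, char_column: Sequence[CellState],
                k_states: int, rate: float = 1.0,
                taxon_names: Sequence[str] | None = None,
                ascertainment: str = "none",
                rates: Sequence[float] | None = None) -> float:
    """Pruning log-likelihood of one character column.

    States are taken at face value on ``0..k_states-1``; polymorphic cells
    become indicator vectors, missing/inapplicable all-ones.  ``rates`` (a
    mixture of equiprobable rate multipliers, e.g. discrete-gamma classes)
    overrides the single ``rate``; ``ascertainment='variable_only'`` applies
    the Mkv correction at this fixed ``k_states``.
    """
    t = as_tree(tree)
    if taxon_names is None:
        taxon_names = sorted(t.leaf_names)
    if len(taxon_names) != len(char_column):
        raise ValueError("char_column length != number of taxa")
    max_obs = max((max(c.states) for c in char_column if c.states), default=0)
    if k_states < max_obs + 1:
        raise ValueError(f"k_states={k_states} < max observed state + 1")
    part = np.ones((len(taxon_names), 1, k_states))
    for i, cell in enumerate(char_column):
        if cell.states:
            part[i, 0, :] = 0.0
            for s in cell.states:
                part[i, 0, s] = 1.0
    idx = {name: i for i, name in enumerate(taxon_names)}
    grp = _CharGroup(k=k_states, char_indices=[0], partials=part)
    rate_vec = np.asarray(rates, dtype=float) if rates is not None else np.array([rate])
    return float(_group_site_logliks(t, grp, idx, rate_vec, ascertainment)[0])


def matrix_loglik(tree: Tree | TreeRecord, m: CharacterMatrix | MkData,
                  cfg: MkModelConfig, gamma_shape: float = 1.0) -> float:
    """Total log-likelihood of a matrix: characters grouped by state count,
    integrated over discrete-gamma rate categories when enabled, and divided
    per character by P(variable) when ``ascertainment='variable_only'``."""
    t = as_tree(tree)
    data = m if isinstance(m, MkData) else encode_mk(m)
    if t.leaf_names != frozenset(data.taxon_names):
        raise ValueError("tree leaf set != matrix taxon set")
    idx = {name: i for i, name in enumerate(data.taxon_names)}
    rates = (
        discrete_gamma_rates(gamma_shape, cfg.n_rate_categories)
        if cfg.gamma_rate_variation
        else np.ones(1)
    )
    traversal = t.rooted_view()
    total = 0.0
    for grp in data.groups:
        total += float(
            _group_site_logliks(t, grp, idx, rates, cfg.ascertainment, traversal).sum()
        )
    return total


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


class _ChainState:
    __slots__ = ("tree", "gamma_shape", "prior_mean", "loglik", "logprior", "beta")

    def __init__(self, tree, gamma_shape, prior_mean, loglik, logprior, beta):
        self.tree = tree
        self.gamma_shape = gamma_shape
        self.prior_mean = prior_mean
        self.loglik = loglik
        self.logprior = logprior
        self.beta = beta


def _random_start_tree(taxon_names: Sequence[str], rng: np.random.Generator,
                       mean_bl: float) -> Tree:
    names = list(rng.permutation(list(taxon_names)))
    t = Tree()
    hub = t.new_node()
    for nm in names[:3]:
        t.add_edge(hub, t.new_node(nm), rng.exponential(mean_bl))
    for nm in names[3:]:
        edges = t.edges()
        u, v = edges[rng.integers(len(edges))]
        length = t.edge_length(u, v)
        mid = t.new_node()
        t.remove_edge(u, v)
        half = rng.uniform()
        t.add_edge(u, mid, length * half)
        t.add_edge(mid, v, length * (1 - half))
        t.add_edge(mid, t.new_node(nm), rng.exponential(mean_bl))
    return t


def _log_prior(tree: Tree, gamma_shape: float, prior_mean: float,
               cfg: MkModelConfig) -> float:
    n_edges = len(tree.edges())
    total = tree.total_length()
    lp = -n_edges * math.log(prior_mean) - total / prior_mean
    if cfg.gamma_rate_variation:
        lp += -gamma_shape  # Exp(1) prior on the gamma shape
    if cfg.sample_prior_mean:
        lp += -prior_mean / cfg.branch_length_prior_mean - math.log(cfg.branch_length_prior_mean)
    return lp


def _propose(state: _ChainState, data: MkData, cfg: MkModelConfig,
             rng: np.random.Generator) -> tuple[_ChainState, float]:
    """Return (proposed state, log Hastings ratio)."""
    moves = ["blen", "blen", "nni", "spr"]
    if cfg.gamma_rate_variation:
        moves.append("shape")
    if cfg.sample_prior_mean:
        moves.append("mean")
    move = moves[rng.integers(len(moves))]
    t = state.tree
    log_h = 0.0
    new_shape = state.gamma_shape
    new_mean = state.prior_mean

    if move == "blen":
        t = t.copy()
        edges = t.edges()
        u, v = edges[rng.integers(len(edges))]
        old = t.edge_length(u, v)
        factor = math.exp(1.0 * (rng.uniform() - 0.5))
        t.set_edge_length(u, v, old * factor)
        log_h = math.log(factor)
    elif move == "shape":
        factor = math.exp(1.0 * (rng.uniform() - 0.5))
        new_shape = state.gamma_shape * factor
        log_h = math.log(factor)
    elif move == "mean":
        factor = math.exp(1.0 * (rng.uniform() - 0.5))
        new_mean = state.prior_mean * factor
        log_h = math.log(factor)
    elif move == "nni":
        t = t.copy()
        internal = t.internal_edges()
        if internal:
            u, v = internal[rng.integers(len(internal))]
            us = [x for x in t.adj[u] if x != v]
            vs = [x for x in t.adj[v] if x != u]
            a = us[rng.integers(len(us))]
            c = vs[rng.integers(len(vs))]
            la = t.edge_length(a, u)
            lc = t.edge_length(c, v)
            t.remove_edge(a, u)
            t.remove_edge(c, v)
            t.add_edge(a, v, la)
            t.add_edge(c, u, lc)
    elif move == "spr":
        t, log_h = _spr_move(t.copy(), rng)

    loglik = (
        0.0
        if cfg.prior_only
        else matrix_loglik(t, data, cfg, gamma_shape=new_shape)
    )
    logprior = _log_prior(t, new_shape, new_mean, cfg)
    return (
        _ChainState(t, new_shape, new_mean, loglik, logprior, state.beta),
        log_h,
    )


def _spr_move(t: Tree, rng: np.random.Generator) -> tuple[Tree, float]:
    """Prune a subtree at a directed edge and regraft it onto a uniformly
    chosen edge at a uniform position.  The log-Hastings term is
    log(l_target / l_merged), the Jacobian of merging the two origin edges
    and splitting the target."""
    edges = t.edges()
    u, v = edges[rng.integers(len(edges))]
    if rng.uniform() < 0.5:
        u, v = v, u
    # move the subtree hanging at v away from attachment node u
    if u in t.leaf_label:  # cannot prune at a leaf's own pendant side
        u, v = v, u
        if u in t.leaf_label:
            return t, 0.0  # two-leaf tree: no-op
    pendant = t.edge_length(u, v)
    t.remove_edge(u, v)
    nb = list(t.adj[u])
    if len(nb) != 2:
        # u was the hub of a non-binary node; put the edge back, no-op
        t.add_edge(u, v, pendant)
        return t, 0.0
    a, b = nb
    la = t.edge_length(a, u)
    lb = t.edge_length(b, u)
    t.remove_edge(a, u)
    t.remove_edge(b, u)
    del t.adj[u]
    merged = la + lb
    t.add_edge(a, b, merged)
    # target edge in the component not containing v
    comp_v = {v}
    stack = [v]
    while stack:
        x = stack.pop()
        for y in t.adj.get(x, []):
            if y not in comp_v:
                comp_v.add(y)
                stack.append(y)
    cand = [(x, y) for (x, y) in t.edges() if x not in comp_v and y not in comp_v]
    x, y = cand[rng.integers(len(cand))]
    l_target = t.edge_length(x, y)
    frac = rng.uniform()
    mid = t.new_node()
    t.remove_edge(x, y)
    t.add_edge(x, mid, l_target * frac)
    t.add_edge(mid, y, l_target * (1 - frac))
    t.add_edge(mid, v, pendant)
    return t, math.log(l_target / merged)


def run_mcmc(m: CharacterMatrix, cfg: MkModelConfig, rs: RunSettings) -> PosteriorSample:
    """Metropolis-coupled MCMC, ``rs.n_runs`` independent runs.

    Chain ``i`` of a run is heated with inverse temperature
    ``1 / (1 + i * heating_increment)``; one state-swap between a random
    adjacent pair is attempted per generation.  The cold chain is sampled
    every ``rs.sample_every`` generations; the burnin fraction is applied
    before pooling.  Fully deterministic under ``cfg.seed``.
    """
    if m.ntax < 4:
        raise ValueError("need >= 4 taxa")
    data = encode_mk(m)
    trees: list[TreeRecord] = []
    lnL_traces: list[np.ndarray] = []
    param_traces: dict[str, list[np.ndarray]] = {"tree_length": []}
    if cfg.gamma_rate_variation:
        param_traces["gamma_shape"] = []
    if cfg.sample_prior_mean:
        param_traces["prior_mean"] = []

    for run in range(rs.n_runs):
        rng = np.random.default_rng((cfg.seed, 7919, run))
        chains: list[_ChainState] = []
        for c in range(rs.n_chains_per_run):
            t0 = _random_start_tree(m.taxon_names, rng, cfg.branch_length_prior_mean)
            shape0 = 1.0
            mean0 = cfg.branch_length_prior_mean
            ll = 0.0 if cfg.prior_only else matrix_loglik(t0, data, cfg, gamma_shape=shape0)
            lp = _log_prior(t0, shape0, mean0, cfg)
            beta = 1.0 / (1.0 + c * rs.heating_increment)
            chains.append(_ChainState(t0, shape0, mean0, ll, lp, beta))

        run_lnL: list[float] = []
        run_params: dict[str, list[float]] = {k: [] for k in param_traces}
        run_trees: list[TreeRecord] = []
        for gen in range(1, rs.n_generations + 1):
            for ci, ch in enumerate(chains):
                prop, log_h = _propose(ch, data, cfg, rng)
                log_acc = (
                    ch.beta * (prop.loglik - ch.loglik)
                    + (prop.logprior - ch.logprior)
                    + log_h
                )
                if log_acc >= 0 or rng.uniform() < math.exp(log_acc):
                    prop.beta = ch.beta
                    chains[ci] = prop
            if len(chains) > 1:
                i = int(rng.integers(len(chains) - 1))
                a, b = chains[i], chains[i + 1]
                log_sw = (a.beta - b.beta) * (b.loglik - a.loglik)
                if log_sw >= 0 or rng.uniform() < math.exp(log_sw):
                    a.beta, b.beta = b.beta, a.beta
                    chains[i], chains[i + 1] = b, a
            if gen % rs.sample_every == 0:
                cold = chains[0]
                run_lnL.append(cold.loglik)
                run_params["tree_length"].append(cold.tree.total_length())
                if cfg.gamma_rate_variation:
                    run_params["gamma_shape"].append(cold.gamma_shape)
                if cfg.sample_prior_mean:
                    run_params["prior_mean"].append(cold.prior_mean)
                run_trees.append(
                    TreeRecord(
                        cold.tree.copy(),
                        Provenance(analysis="bi", run=run, index=gen),
                    )
                )

        n = len(run_trees)
        keep = math.ceil((1 - rs.burnin_fraction) * n)
        start = n - keep
        trees.extend(run_trees[start:])
        lnL_traces.append(np.asarray(run_lnL[start:]))
        for k in param_traces:
            param_traces[k].append(np.asarray(run_params[k][start:]))

    return PosteriorSample(
        trees=trees,
        lnL_trace=lnL_traces,
        parameter_traces=param_traces,
        burnin_applied=True,
        n_runs=rs.n_runs,
        settings=rs,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _split_frequencies(trees: Iterable[TreeRecord]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    n = 0
    for rec in trees:
        n += 1
        for s in rec.splits():
            counts[s] = counts.get(s, 0) + 1
    if n == 0:
        raise ValueError("empty tree sample")
    return {s: c / n for s, c in counts.items()}


def compute_asdsf(runs, min_freq: float = 0.1) -> float:
    """Average across-run (sample) standard deviation of split frequencies,
    over splits reaching ``min_freq`` in at least one run.

    ``runs`` may be a multi-run :class:`PosteriorSample`, a list of
    single-run samples, or a list of tree lists.
    """
    tree_sets = _as_run_tree_sets(runs)
    if len(tree_sets) < 2:
        raise ValueError("need >= 2 runs for ASDSF")
    leaf_sets = {frozenset(rec.leaf_names) for ts in tree_sets for rec in ts[:1]}
    if len(leaf_sets) > 1:
        raise ValueError("runs have different leaf sets")
    freqs = [_split_frequencies(ts) for ts in tree_sets]
    qualifying = {s for f in freqs for s, v in f.items() if v >= min_freq}
    if not qualifying:
        return 0.0
    sds = []
    for s in qualifying:
        vals = np.array([f.get(s, 0.0) for f in freqs])
        sds.append(vals.std(ddof=1))
    return float(np.mean(sds))


def _as_run_tree_sets(runs) -> list[list[TreeRecord]]:
    if isinstance(runs, PosteriorSample):
        return runs.trees_by_run()
    out: list[list[TreeRecord]] = []
    for item in runs:
        if isinstance(item, PosteriorSample):
            out.extend(item.trees_by_run())
        else:
            out.append(list(item))
    return out


def compute_ess(trace: Sequence[float]) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator.

    A constant trace is returned as ESS = length (zero autocorrelation time
    by convention) with a warning.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short (need >= 10)")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        warnings.warn("constant trace: ESS defined as trace length", stacklevel=2)
        return float(n)
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while they stay positive
    tau = -1.0
    k = 0
    while 2 * k + 1 < n:
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        tau += 2.0 * g
        k += 1
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def majority_consensus(sample: PosteriorSample | Sequence[TreeRecord],
                       threshold: float = 0.5) -> TreeRecord:
    """Majority-rule consensus: splits at frequency > ``threshold``, each
    annotated (``record.split_frequencies``) with its frequency."""
    trees = sample.trees if isinstance(sample, PosteriorSample) else list(sample)
    if not trees:
        raise ValueError("empty sample")
    if threshold < 0.5:
        raise ValueError("threshold < 0.5 can select incompatible splits")
    freqs = _split_frequencies(trees)
    keep = {s: f for s, f in freqs.items() if f > threshold}
    leaves = trees[0].leaf_names
    tree, used = tree_from_splits(leaves, keep.keys(), keep)
    rec = TreeRecord(tree, Provenance(analysis="majority_consensus"))
    rec.split_frequencies = used  # type: ignore[attr-defined]
    return rec
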