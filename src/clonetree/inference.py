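"""Posterior sampling over (tree, clustering, outliers).

The sampler grows rooted forests bottom-up with sequential Monte
Carlo, embedded in a particle Gibbs scheme that treats the data
ordering as an auxiliary variable, and augments it with two
topology-respecting MCMC moves (subtree prune-regraft and per-datum
node reassignment).  Data points are pre-clustered blocks; a block's
emission is the sum of its members' grid log likelihoods, so blocks
move through the sampler as single super-data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from ._logconv import log_conv
from .emission import GridLikelihood, PrevalenceGrid, compute_grid_likelihood
from .io_formats import PreClustering, SnvTable, ValidationError
from .tree_model import (
    ROOT,
    CloneTree,
    ModelConfig,
    joint_log_prob,
    log_simplex_norm,
    node_log_weight,
    root_log_weight,
)

logger = logging.getLogger("clonetree")


# ---------------------------------------------------------------------------
# Block data
# ---------------------------------------------------------------------------


@dataclass
class BlockData:
    """Pre-clustered data prepared for inference.

    One item per block; singleton blocks when no pre-clustering is
    supplied.  ``gl`` holds block-summed grid log likelihoods; the
    outlier marginal of a block is the sum of its members' independent
    uniform-prevalence marginals.
    """

    gl: GridLikelihood
    sizes: np.ndarray
    log_inlier: np.ndarray
    log_outlier_prior: np.ndarray
    outlier_marginals: np.ndarray
    q_out: np.ndarray
    members: Tuple[Tuple[int, ...], ...]

    @property
    def num_blocks(self) -> int:
        return len(self.members)

    @property
    def num_samples(self) -> int:
        return self.gl.num_samples


def make_block_data(
    gl: GridLikelihood,
    clusters: Optional[Sequence[Sequence[int]]] = None,
    nu: Optional[np.ndarray] = None,
    config: Optional[ModelConfig] = None,
) -> BlockData:
    """Aggregate a mutation-level grid likelihood into blocks.

    ``clusters`` lists member mutation indices per block (default:
    one singleton block per mutation).  ``nu`` gives per-mutation
    prior outlier probabilities (default: ``config.outlier_prob_low``
    or zero).
    """
    n = gl.num_items
    if clusters is None:
        clusters = [(i,) for i in range(n)]
    members = tuple(tuple(sorted(c)) for c in clusters)
    covered = [i for c in members for i in c]
    if sorted(covered) != list(range(n)):
        raise ValidationError("blocks must partition the mutation indices")
    if nu is None:
        nu = np.full(n, config.outlier_prob_low if config is not None else 0.0)
    nu = np.asarray(nu, float)
    with np.errstate(divide="ignore"):
        log_nu = np.log(nu)
        log_one_minus = np.log1p(-nu)
    mut_marg = gl.outlier_marginals()
    B = len(members)
    loglik = np.stack([gl.loglik[list(c)].sum(axis=0) for c in members])
    sizes = np.array([len(c) for c in members])
    log_inlier = np.array([log_one_minus[list(c)].sum() for c in members])
    log_outlier_prior = np.array([log_nu[list(c)].sum() for c in members])
    out_marg = np.array([mut_marg[list(c)].sum() for c in members])
    q_out = 1.0 - np.exp(log_inlier)
    q_out = np.where(q_out > 0, np.clip(q_out, 1e-6, 0.5), 0.0)
    bgl = GridLikelihood(loglik, gl.grid, gl.density_kind, gl.precision)
    return BlockData(
        gl=bgl,
        sizes=sizes,
        log_inlier=log_inlier,
        log_outlier_prior=log_outlier_prior,
        outlier_marginals=out_marg,
        q_out=q_out,
        members=members,
    )


def block_joint(tree: CloneTree, bd: BlockData, config: ModelConfig) -> float:
    """Collapsed joint log probability of a block-level tree."""
    return joint_log_prob(
        tree,
        bd.gl,
        config,
        item_sizes=bd.sizes,
        outlier_marginals=bd.outlier_marginals,
        log_inlier=bd.log_inlier,
        log_outlier_prior=bd.log_outlier_prior,
    )


def expand_tree(tree: CloneTree, members: Sequence[Sequence[int]]) -> CloneTree:
    """Map a block-level tree to mutation-index space."""
    clusters = {
        v: frozenset(i for b in c for i in members[b])
        for v, c in tree.clusters.items()
    }
    outliers = frozenset(i for b in tree.outliers for i in members[b])
    return CloneTree(parent=dict(tree.parent), clusters=clusters, outliers=outliers)


# ---------------------------------------------------------------------------
# SMC state
# ---------------------------------------------------------------------------


class _DPContext:
    """Shared grid weights and normalization cache for one sweep."""

    def __init__(self, config: ModelConfig, num_samples: int):
        self.config = config
        self.S = num_samples
        self.G = config.grid_size
        self.w = node_log_weight(self.G, config.kappa)
        self.r = root_log_weight(self.G, config.kappa, config.root_has_mass)

    def norm(self, num_nodes: int) -> float:
        return log_simplex_norm(
            num_nodes, self.G, self.config.kappa, self.config.root_has_mass
        )


class _SubtreeNode:
    """Immutable rooted subtree with cached per-sample DP messages.

    ``tag`` is the block that created the node; it is stable across a
    sweep and identifies nodes during reference replay.
    """

    __slots__ = (
        "tag",
        "blocks",
        "children",
        "data",
        "pre",
        "msg",
        "own_items",
        "n_items",
        "n_nodes",
        "n_blocks",
        "log_orders",
        "lgamma_sum",
    )

    def __init__(self, tag, blocks, children, data, pre, own_items):
        self.tag = tag
        self.blocks = tuple(sorted(blocks))
        self.children = tuple(children)
        self.data = data
        self.pre = pre
        self.msg = pre + data
        self.own_items = own_items
        self.n_items = own_items + sum(c.n_items for c in children)
        self.n_nodes = 1 + sum(c.n_nodes for c in children)
        self.n_blocks = len(self.blocks) + sum(c.n_blocks for c in children)
        # number of valid build orderings of this subtree's blocks:
        # uniform merge of children orderings, then own blocks last
        below = sum(c.n_blocks for c in children)
        self.log_orders = (
            float(gammaln(1 + below))
            - sum(float(gammaln(1 + c.n_blocks)) for c in children)
            + sum(c.log_orders for c in children)
            + float(gammaln(1 + len(self.blocks)))
        )
        self.lgamma_sum = float(gammaln(own_items)) + sum(
            c.lgamma_sum for c in children
        )


def _make_node(tag, blocks, children, bd: BlockData, ctx: _DPContext) -> _SubtreeNode:
    data = bd.gl.loglik[list(blocks)].sum(axis=0)
    pre = np.empty((ctx.S, ctx.G))
    for s in range(ctx.S):
        acc = ctx.w
        for c in children:
            acc = log_conv(acc, c.msg[s])
        pre[s] = acc
    own = int(bd.sizes[list(blocks)].sum())
    return _SubtreeNode(tag, blocks, children, data, pre, own)


def _node_with_block(node: _SubtreeNode, b: int, bd: BlockData) -> _SubtreeNode:
    data = node.data + bd.gl.loglik[b]
    own = node.own_items + int(bd.sizes[b])
    return _SubtreeNode(
        node.tag, node.blocks + (b,), node.children, data, node.pre, own
    )


def _forest_marginal(roots: Sequence[_SubtreeNode], ctx: _DPContext) -> float:
    K = sum(r.n_nodes for r in roots)
    total = 0.0
    for s in range(ctx.S):
        if ctx.config.root_has_mass:
            acc = ctx.r
            rest = roots
        elif roots:
            acc = roots[0].msg[s]
            rest = roots[1:]
        else:
            continue
        for rt in rest:
            acc = log_conv(acc, rt.msg[s])
        total += float(acc[-1])
    return total - ctx.S * ctx.norm(K)


def _state_target(
    roots: Sequence[_SubtreeNode],
    prior_terms: float,
    ctx: _DPContext,
    config: ModelConfig,
    num_outliers: int = 0,
) -> float:
    """Collapsed partial target of a forest state.

    Joint of the data seen so far with the partial forest adopted by
    the dummy root, divided by the number of valid build orderings of
    the state (the auxiliary ordering is uniform over valid orders, so
    the sigma-conditioned target carries a 1/nu(T, b) factor).
    """
    K = sum(r.n_nodes for r in roots)
    out = prior_terms + _forest_marginal(roots, ctx)
    if K > 0:
        n_in = sum(r.n_items for r in roots)
        lg = sum(r.lgamma_sum for r in roots)
        alpha = config.alpha
        out += K * np.log(alpha) + lg - (gammaln(alpha + n_in) - gammaln(alpha))
        out += -(K - 1) * np.log(K + 1)
    # log nu: uniform merge of root orderings and outlier singletons
    b_seen = sum(r.n_blocks for r in roots) + num_outliers
    log_nu = (
        float(gammaln(1 + b_seen))
        - sum(float(gammaln(1 + r.n_blocks)) for r in roots)
        + sum(r.log_orders for r in roots)
    )
    return out - log_nu


@dataclass(frozen=True)
class Particle:
    """A partially built rooted forest over the data seen so far."""

    roots: Tuple[_SubtreeNode, ...] = ()
    outliers: FrozenSet[int] = frozenset()
    prior_terms: float = 0.0
    log_target: float = 0.0
    generation: int = 0
    log_weight: float = 0.0


def empty_particle() -> Particle:
    return Particle()


# ---------------------------------------------------------------------------
# Proposal / extension
# ---------------------------------------------------------------------------


def smc_propose_extension(
    particle: Particle,
    next_datum: int,
    bd: BlockData,
    config: ModelConfig,
    rng: np.random.Generator,
    ctx: Optional[_DPContext] = None,
    forced: Optional[tuple] = None,
    proposal: str = "semi-adapted",
    new_node_prob: float = 0.5,
) -> Tuple[Particle, float]:
    """Extend a particle with one datum; returns the new particle and
    the log incremental weight (partial-target ratio over proposal
    probability).

    ``forced`` replays a reference action: ``("out",)``,
    ``("join", tag)`` or ``("new", frozenset_of_children_tags)``.
    """
    if ctx is None:
        ctx = _DPContext(config, bd.num_samples)
    b = next_datum
    roots = particle.roots
    q_out = float(bd.q_out[b])
    t_old = particle.log_target

    if forced is not None:
        kind = forced[0]
    else:
        if q_out > 0 and rng.random() < q_out:
            kind = "out"
        elif not roots:
            kind = "new"
        elif proposal == "fully-adapted":
            kind = "full"
        else:
            kind = "new" if rng.random() < new_node_prob else "join"
    if forced is not None and proposal == "fully-adapted" and kind in ("join", "new"):
        kind = "full"

    log_not_out = np.log1p(-q_out) if q_out > 0 else 0.0

    n_out = len(particle.outliers)

    if kind == "out":
        if q_out <= 0:
            raise RuntimeError("outlier action proposed with zero outlier prior")
        inc_prior = float(bd.log_outlier_prior[b] + bd.outlier_marginals[b])
        t_new = _state_target(
            roots, particle.prior_terms + inc_prior, ctx, config, n_out + 1
        )
        new = Particle(
            roots=roots,
            outliers=particle.outliers | {b},
            prior_terms=particle.prior_terms + inc_prior,
            log_target=t_new,
            generation=particle.generation + 1,
        )
        return new, t_new - t_old - np.log(q_out)

    prior_terms = particle.prior_terms + float(bd.log_inlier[b])

    def join_candidates():
        cands = []
        for i, rt in enumerate(roots):
            nr = _node_with_block(rt, b, bd)
            new_roots = roots[:i] + (nr,) + roots[i + 1 :]
            cands.append(
                (new_roots, _state_target(new_roots, prior_terms, ctx, config, n_out))
            )
        return cands

    def new_node_state(children_idx):
        children = tuple(roots[i] for i in children_idx)
        rest = tuple(roots[i] for i in range(len(roots)) if i not in children_idx)
        node = _make_node(b, (b,), children, bd, ctx)
        new_roots = rest + (node,)
        return new_roots, _state_target(new_roots, prior_terms, ctx, config, n_out)

    if kind == "join":
        if not roots:
            raise RuntimeError("join action with no existing roots")
        cands = join_candidates()
        ts = np.array([t for _, t in cands])
        if proposal == "prior":
            if forced is not None:
                i = next(j for j, rt in enumerate(roots) if rt.tag == forced[1])
            else:
                i = int(rng.integers(len(roots)))
            log_q = log_not_out + np.log1p(-new_node_prob) - np.log(len(roots))
            inc = ts[i] - t_old - log_q
        else:  # semi-adapted: Gibbs over roots
            lse = float(logsumexp(ts))
            if forced is not None:
                i = next(j for j, rt in enumerate(roots) if rt.tag == forced[1])
            else:
                p = np.exp(ts - lse)
                i = int(rng.choice(len(roots), p=p / p.sum()))
            inc = lse - t_old - log_not_out - np.log1p(-new_node_prob)
        new_roots, t_new = cands[i]
    elif kind == "new":
        if forced is not None:
            want = forced[1]
            children_idx = {
                i for i, rt in enumerate(roots) if rt.tag in want
            }
            if len(children_idx) != len(want):
                raise RuntimeError("reference children not present among roots")
        else:
            children_idx = {i for i in range(len(roots)) if rng.random() < 0.5}
        new_roots, t_new = new_node_state(children_idx)
        inc = t_new - t_old - log_not_out + len(roots) * np.log(2.0)
        if roots:
            inc -= np.log(new_node_prob)
    elif kind == "full":
        # fully adapted: Gibbs over every join and every children subset
        if len(roots) > 12:
            raise ValidationError(
                "fully-adapted proposal is limited to 12 concurrent roots"
            )
        options = []
        for i, (new_roots_i, t_i) in enumerate(join_candidates()):
            options.append((("join", roots[i].tag), new_roots_i, t_i))
        from itertools import combinations

        idx = list(range(len(roots)))
        for r_ in range(len(roots) + 1):
            for comb in combinations(idx, r_):
                nr, t_ = new_node_state(set(comb))
                options.append(
                    (("new", frozenset(roots[i].tag for i in comb)), nr, t_)
                )
        ts = np.array([t for _, _, t in options])
        lse = float(logsumexp(ts))
        if forced is not None:
            key = (forced[0], forced[1])
            i = next(j for j, (k, _, _) in enumerate(options) if k == key)
        else:
            p = np.exp(ts - lse)
            i = int(rng.choice(len(options), p=p / p.sum()))
        _, new_roots, t_new = options[i]
        inc = lse - t_old - log_not_out
    else:  # pragma: no cover
        raise RuntimeError(f"unknown action {kind!r}")

    new = Particle(
        roots=new_roots,
        outliers=particle.outliers,
        prior_terms=prior_terms,
        log_target=t_new,
        generation=particle.generation + 1,
    )
    return new, float(inc)


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------


def _merge_uniform(seqs: List[List[int]], rng: np.random.Generator) -> List[int]:
    if not seqs:
        return []
    labels = np.repeat(np.arange(len(seqs)), [len(s) for s in seqs])
    rng.shuffle(labels)
    iters = [iter(s) for s in seqs]
    return [next(iters[l]) for l in labels]


def sample_permutation(tree: CloneTree, rng: np.random.Generator) -> List[int]:
    """Draw a data ordering uniformly among those the bottom-up SMC
    construction could use to build ``tree``.

    Within each subtree, all items of strict descendants precede every
    item of the node; disjoint subtrees interleave uniformly; outlier
    items are inserted at uniform positions.
    """
    ch = tree.children_map()

    def rec(v: int) -> List[int]:
        merged = _merge_uniform([rec(c) for c in ch.get(v, [])], rng)
        own = sorted(tree.clusters.get(v, ())) if v != ROOT else []
        if own:
            own = [own[i] for i in rng.permutation(len(own))]
        return merged + own

    order = rec(ROOT)
    for o in sorted(tree.outliers):
        pos = int(rng.integers(len(order) + 1))
        order.insert(pos, o)
    return order


def permutation_is_valid(tree: CloneTree, order: Sequence[int]) -> bool:
    """Check that the SMC construction can realize ``tree`` under ``order``."""
    pos = {b: i for i, b in enumerate(order)}
    if set(pos) != tree.items():
        return False
    ch = tree.children_map()

    def subtree_max(v: int) -> int:
        m = max((pos[i] for i in tree.clusters.get(v, ())), default=-1)
        for c in ch.get(v, []):
            m = max(m, subtree_max(c))
        return m

    for v in tree.nodes:
        own_min = min(pos[i] for i in tree.clusters[v])
        for c in ch.get(v, []):
            if subtree_max(c) > own_min:
                return False
    return True


def _reference_actions(tree: CloneTree, order: Sequence[int]) -> List[tuple]:
    pos = {b: i for i, b in enumerate(order)}
    assign = tree.assignment()
    ch = tree.children_map()
    first = {v: min(c, key=pos.__getitem__) for v, c in tree.clusters.items()}
    actions: List[tuple] = []
    for b in order:
        if b in tree.outliers:
            actions.append(("out",))
            continue
        v = assign[b]
        if b == first[v]:
            actions.append(
                ("new", frozenset(first[c] for c in ch.get(v, [])))
            )
        else:
            actions.append(("join", first[v]))
    return actions


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _systematic_resample(
    weights: np.ndarray, rng: np.random.Generator, keep_first: bool
) -> np.ndarray:
    P = len(weights)
    positions = (rng.random() + np.arange(P)) / P
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions)
    if keep_first:
        idx[0] = 0
    return idx


def smc_sweep(
    sigma: Sequence[int],
    bd: BlockData,
    config: ModelConfig,
    num_particles: int,
    rng: np.random.Generator,
    reference: Optional[CloneTree] = None,
    proposal: str = "semi-adapted",
    new_node_prob: float = 0.5,
) -> Tuple[List[Particle], np.ndarray, float]:
    """Run one (conditional) SMC sweep over the data ordering ``sigma``.

    Returns the final particles, their normalized log weights, and the
    log marginal likelihood estimate.  When ``reference`` is given the
    sweep is conditional: particle 0 replays the reference trajectory
    and survives every resampling step.
    """
    ctx = _DPContext(config, bd.num_samples)
    actions = _reference_actions(reference, sigma) if reference is not None else None
    P = num_particles
    particles = [empty_particle() for _ in range(P)]
    log_w = np.full(P, -np.log(P))
    log_z = 0.0
    for t, b in enumerate(sigma):
        incs = np.empty(P)
        new_particles: List[Particle] = []
        for i in range(P):
            forced = actions[t] if (actions is not None and i == 0) else None
            p_new, inc = smc_propose_extension(
                particles[i],
                b,
                bd,
                config,
                rng,
                ctx=ctx,
                forced=forced,
                proposal=proposal,
                new_node_prob=new_node_prob,
            )
            new_particles.append(p_new)
            incs[i] = inc
        particles = new_particles
        lw = log_w + incs
        norm = float(logsumexp(lw))
        if np.isneginf(norm):
            raise RuntimeError(
                f"all particle weights vanished at generation {t}"
            )
        log_z += norm
        log_w = lw - norm
        if t < len(sigma) - 1:
            ess = 1.0 / np.exp(logsumexp(2 * log_w))
            if ess < P / 2:
                idx = _systematic_resample(
                    np.exp(log_w), rng, keep_first=reference is not None
                )
                particles = [particles[j] for j in idx]
                log_w = np.full(P, -np.log(P))
    return particles, log_w, log_z


def particle_to_tree(particle: Particle) -> CloneTree:
    """Materialize a particle's forest as a block-level clone tree."""
    parent: Dict[int, int] = {}
    clusters: Dict[int, FrozenSet[int]] = {}
    counter = [0]

    def walk(node: _SubtreeNode, par: int) -> None:
        nid = counter[0]
        counter[0] += 1
        parent[nid] = par
        clusters[nid] = frozenset(node.blocks)
        for c in sorted(node.children, key=lambda n: n.tag):
            walk(c, nid)

    for rt in sorted(particle.roots, key=lambda n: n.tag):
        walk(rt, ROOT)
    return CloneTree(parent=parent, clusters=clusters, outliers=particle.outliers)


def particle_gibbs_update(
    current: CloneTree,
    bd: BlockData,
    config: ModelConfig,
    num_particles: int,
    rng: np.random.Generator,
    proposal: str = "semi-adapted",
    new_node_prob: float = 0.5,
) -> CloneTree:
    """One particle Gibbs update of (T, b, o) with auxiliary ordering.

    Samples a valid ordering for the current tree, runs a conditional
    SMC sweep retaining the current tree as the reference trajectory,
    and draws the new tree from the final particle weights.
    """
    sigma = sample_permutation(current, rng)
    particles, log_w, _ = smc_sweep(
        sigma,
        bd,
        config,
        num_particles,
        rng,
        reference=current,
        proposal=proposal,
        new_node_prob=new_node_prob,
    )
    ref_tree = particle_to_tree(particles[0])
    if ref_tree.canonical_key() != current.canonical_key():
        raise RuntimeError(
            "conditional SMC failed to reproduce the reference trajectory"
        )
    p = np.exp(log_w)
    i = int(rng.choice(len(particles), p=p / p.sum()))
    return particle_to_tree(particles[i])


# ---------------------------------------------------------------------------
# MCMC moves
# ---------------------------------------------------------------------------


def _gibbs_pick(
    log_probs: np.ndarray, rng: np.random.Generator
) -> int:
    lse = logsumexp(log_probs)
    p = np.exp(log_probs - lse)
    return int(rng.choice(len(log_probs), p=p / p.sum()))


def prune_regraft_move(
    tree: CloneTree, bd: BlockData, config: ModelConfig, rng: np.random.Generator
) -> CloneTree:
    """Detach a random subtree and Gibbs-sample its attachment point."""
    if tree.num_nodes < 2:
        return tree
    nodes = tree.nodes
    u = nodes[int(rng.integers(len(nodes)))]
    sub = set(tree.subtree_nodes(u))
    candidates = [ROOT] + [v for v in nodes if v not in sub]
    joints = np.array(
        [block_joint(tree.with_parent(u, c), bd, config) for c in candidates]
    )
    return tree.with_parent(u, candidates[_gibbs_pick(joints, rng)])


def _tree_without_block(tree: CloneTree, b: int) -> CloneTree:
    if b in tree.outliers:
        return CloneTree(
            parent=dict(tree.parent),
            clusters=dict(tree.clusters),
            outliers=tree.outliers - {b},
        )
    clusters = dict(tree.clusters)
    for v, c in clusters.items():
        if b in c:
            clusters[v] = c - {b}
            break
    return CloneTree(parent=dict(tree.parent), clusters=clusters, outliers=tree.outliers)


def _tree_with_block_at(tree: CloneTree, b: int, node: Optional[int]) -> CloneTree:
    if node is None:
        return CloneTree(
            parent=dict(tree.parent),
            clusters=dict(tree.clusters),
            outliers=tree.outliers | {b},
        )
    clusters = dict(tree.clusters)
    clusters[node] = clusters[node] | {b}
    return CloneTree(parent=dict(tree.parent), clusters=clusters, outliers=tree.outliers)


def node_reassignment_move(
    tree: CloneTree, bd: BlockData, config: ModelConfig, rng: np.random.Generator
) -> CloneTree:
    """Gibbs-resample block-to-node assignments on the fixed topology.

    Blocks are visited in a freshly shuffled order; a block is movable
    when removing it does not empty its node (outlier blocks are
    always movable).  The outlier state is a candidate whenever the
    block has a positive prior outlier probability.
    """
    blocks = sorted(tree.items())
    order = [blocks[i] for i in rng.permutation(len(blocks))]
    assign = tree.assignment()
    for b in order:
        if b in tree.outliers:
            movable = True
        else:
            v = assign[b]
            movable = len(tree.clusters[v]) > 1
        if not movable:
            continue
        base = _tree_without_block(tree, b)
        candidates: List[Optional[int]] = list(base.nodes)
        if bd.q_out[b] > 0:
            candidates.append(None)
        trees = [_tree_with_block_at(base, b, c) for c in candidates]
        joints = np.array([block_joint(t, bd, config) for t in trees])
        tree = trees[_gibbs_pick(joints, rng)]
        assign = tree.assignment()
    return tree


# ---------------------------------------------------------------------------
# Top-level sampler
# ---------------------------------------------------------------------------


@dataclass
class TraceSample:
    chain: int
    iteration: int
    tree: CloneTree
    log_prob: float


@dataclass
class PosteriorTrace:
    """Pooled MCMC trace over all chains."""

    samples: List[TraceSample] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    burnin: int = 0
    block_members: Tuple[Tuple[int, ...], ...] = ()

    def post_burnin(self) -> List[TraceSample]:
        return [s for s in self.samples if s.iteration >= self.burnin]

    def map_tree(self) -> CloneTree:
        pool = self.post_burnin() or self.samples
        if not pool:
            raise ValidationError("trace is empty")
        best = max(pool, key=lambda s: s.log_prob)
        return best.tree


def initial_tree(bd: BlockData, init_outliers: bool = False) -> CloneTree:
    """Single-node starting state; optionally seed blocks with a high
    prior outlier probability in the outlier state, which helps the
    sampler discover loss configurations early."""
    blocks = range(bd.num_blocks)
    if init_outliers:
        out = frozenset(b for b in blocks if bd.q_out[b] > 0.01)
        rest = frozenset(b for b in blocks if b not in out)
        if not rest:
            return CloneTree(parent={}, clusters={}, outliers=out)
        return CloneTree(parent={0: ROOT}, clusters={0: rest}, outliers=out)
    return CloneTree(parent={0: ROOT}, clusters={0: frozenset(blocks)})


def run_sampler(
    table: SnvTable,
    preclustering: Optional[PreClustering] = None,
    config: ModelConfig = ModelConfig(),
    chains: int = 4,
    burnin: int = 100,
    iters: int = 5000,
    particles: int = 100,
    seed: Optional[int] = None,
    loss_flags: Optional[Sequence[bool]] = None,
    max_time: Optional[float] = None,
    proposal: str = "semi-adapted",
    new_node_prob: float = 0.5,
    init_outliers: bool = False,
) -> Tuple[PosteriorTrace, CloneTree]:
    """Run the full sampler and return the trace and the MAP tree.

    Per chain, each iteration interleaves one particle Gibbs update,
    one prune-regraft move, and one node-reassignment scan.  Mutations
    flagged by ``loss_flags`` receive the high-tier prior outlier
    probability; all others the low tier.  The returned MAP tree is in
    block space; expand with :func:`expand_tree` and
    ``trace.block_members``.
    """
    grid = PrevalenceGrid(config.grid_size)
    gl = compute_grid_likelihood(table, grid, config.density_kind, config.precision)
    if loss_flags is None:
        nu = np.full(table.num_mutations, config.outlier_prob_low)
    else:
        flags = np.asarray(loss_flags, bool)
        nu = np.where(flags, config.outlier_prob_high, config.outlier_prob_low)
    clusters = None
    if preclustering is not None:
        preclustering.validate_against(table)
        K = preclustering.num_clusters
        clusters = [[] for _ in range(K)]
        for i, m in enumerate(table.mutations):
            clusters[preclustering.assignment[m]].append(i)
    bd = make_block_data(gl, clusters, nu, config)

    trace = PosteriorTrace(
        config={
            "alpha": config.alpha,
            "kappa": config.kappa,
            "outlier_prob_low": config.outlier_prob_low,
            "outlier_prob_high": config.outlier_prob_high,
            "grid_size": config.grid_size,
            "density_kind": config.density_kind,
            "precision": config.precision,
            "chains": chains,
            "burnin": burnin,
            "iters": iters,
            "particles": particles,
            "proposal": proposal,
        },
        seed=seed,
        burnin=burnin,
        block_members=bd.members,
    )
    start = time.monotonic()
    seeds = np.random.SeedSequence(seed).spawn(chains)
    stopped = False
    for chain in range(chains):
        rng = np.random.default_rng(seeds[chain])
        tree = initial_tree(bd, init_outliers=init_outliers)
        for it in range(burnin + iters):
            tree = particle_gibbs_update(
                tree, bd, config, particles, rng,
                proposal=proposal, new_node_prob=new_node_prob,
            )
            tree = prune_regraft_move(tree, bd, config, rng)
            tree = node_reassignment_move(tree, bd, config, rng)
            trace.samples.append(
                TraceSample(chain, it, tree, block_joint(tree, bd, config))
            )
            if max_time is not None and time.monotonic() - start > max_time:
                logger.warning(
                    "wall-clock budget exceeded at chain %d iteration %d; "
                    "returning partial trace",
                    chain,
                    it,
                )
                stopped = True
                break
        if stopped:
            break
    return trace, trace.map_tree()
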