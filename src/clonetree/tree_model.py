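"""Forest-structured CRP prior and collapsed tree density.

The latent state is a rooted multifurcating tree with a distinguished
empty root.  Clonal prevalences are Dirichlet on the (K+1)-simplex
(one coordinate per node including the root) and are marginalized by a
bottom-up dynamic program on a shared prevalence grid: each node
carries a log mass vector over its subtree's total cellular
prevalence, built by convolving its children's vectors with the node's
own clonal-mass weight and multiplying in the node's data term.  The
root reads off total mass one, and a topology-independent prior-mass
constant normalizes the quadrature so a data-free tree scores exactly
zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from ._logconv import log_conv
from .emission import GridLikelihood, PrevalenceGrid, outlier_marginal_loglik
from .io_formats import ValidationError

logger = logging.getLogger("clonetree")

#: Identifier of the dummy root node.
ROOT = -1


@dataclass(frozen=True)
class ModelConfig:
    """Model hyper-parameters and discretization settings."""

    alpha: float = 1.0
    kappa: float = 1.0
    outlier_prob_low: float = 0.0
    outlier_prob_high: float = 0.4
    grid_size: int = 101
    density_kind: str = "beta-binomial"
    precision: float = 400.0
    root_has_mass: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        if not (0 <= self.outlier_prob_low <= 1 and 0 <= self.outlier_prob_high <= 1):
            raise ValidationError("outlier probabilities must be in [0, 1]")


@dataclass(frozen=True)
class CloneTree:
    """Rooted tree over mutation clusters plus an outlier set.

    ``parent`` maps every non-root node to its parent (:data:`ROOT`
    for top-level nodes); ``clusters`` maps every non-root node to a
    non-empty frozen set of item indices.  ``outliers`` holds item
    indices excluded from the tree.
    """

    parent: Dict[int, int]
    clusters: Dict[int, FrozenSet[int]]
    outliers: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent", dict(self.parent))
        object.__setattr__(
            self, "clusters", {v: frozenset(c) for v, c in self.clusters.items()}
        )
        object.__setattr__(self, "outliers", frozenset(self.outliers))

    # -- structure ---------------------------------------------------------
    @property
    def nodes(self) -> List[int]:
        return sorted(self.parent)

    @property
    def num_nodes(self) -> int:
        """Number of non-root nodes."""
        return len(self.parent)

    def children_map(self) -> Dict[int, List[int]]:
        ch: Dict[int, List[int]] = {ROOT: []}
        for v in sorted(self.parent):
            ch.setdefault(v, [])
        for v, p in self.parent.items():
            ch.setdefault(p, []).append(v)
        for v in ch:
            ch[v] = sorted(ch[v])
        return ch

    def subtree_nodes(self, v: int) -> List[int]:
        ch = self.children_map()
        out: List[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(ch.get(u, []))
        return out

    def items(self) -> FrozenSet[int]:
        out = set(self.outliers)
        for c in self.clusters.values():
            out |= c
        return frozenset(out)

    def assignment(self) -> Dict[int, int]:
        """Item -> node map over non-outlier items."""
        return {i: v for v, c in self.clusters.items() for i in c}

    def validate(self) -> None:
        if set(self.parent) != set(self.clusters):
            raise ValidationError("parent and cluster maps cover different nodes")
        for v, p in self.parent.items():
            if p != ROOT and p not in self.parent:
                raise ValidationError(f"unknown parent {p} for node {v}")
        # acyclicity / single-rootedness
        for v in self.parent:
            seen = {v}
            u = v
            while u != ROOT:
                u = self.parent[u]
                if u in seen:
                    raise ValidationError("parent map contains a cycle")
                seen.add(u)
        seen_items: set = set(self.outliers)
        for v, c in self.clusters.items():
            if not c:
                raise ValidationError(f"node {v} has an empty cluster")
            if c & seen_items:
                raise ValidationError("clusters/outliers are not disjoint")
            seen_items |= c

    def canonical_key(self):
        """Hashable key identifying the tree up to node relabelling."""
        ch = self.children_map()

        def key(v):
            return (
                self.clusters.get(v, frozenset()),
                frozenset(key(c) for c in ch.get(v, [])),
            )

        return (key(ROOT), self.outliers)

    def with_parent(self, node: int, new_parent: int) -> "CloneTree":
        parent = dict(self.parent)
        parent[node] = new_parent
        return replace(self, parent=parent)


def single_node_tree(items: Iterable[int]) -> CloneTree:
    return CloneTree(parent={0: ROOT}, clusters={0: frozenset(items)})


@dataclass
class PrevalenceMatrix:
    """Clonal and cellular prevalence per node (rows) per sample (columns)."""

    nodes: List[int]
    clonal: np.ndarray
    cellular: np.ndarray

    def row(self, node: int) -> int:
        return self.nodes.index(node)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def crp_log_prior(clusters, alpha: float) -> float:
    """Log CRP probability of a partition.

    ``clusters`` is either an iterable of cluster contents or an
    iterable of integer cluster sizes.  Returns
    ``log[ alpha^K * prod (|b|-1)! / prod_{i<n} (alpha+i) ]``; the
    empty partition of zero items scores 0.
    """
    sizes = [c if isinstance(c, (int, np.integer)) else len(c) for c in clusters]
    if any(s <= 0 for s in sizes):
        raise ValidationError("cluster sizes must be positive")
    n = sum(sizes)
    if n == 0:
        return 0.0
    K = len(sizes)
    return float(
        K * np.log(alpha)
        + sum(gammaln(s) for s in sizes)
        - (gammaln(alpha + n) - gammaln(alpha))
    )


def forest_log_prior(num_nodes: int) -> float:
    """Log probability of one rooted labelled forest on K nodes.

    There are ``(K+1)^(K-1)`` rooted forests on K labelled nodes, so
    the uniform prior contributes ``-(K-1) * log(K+1)``.
    """
    if num_nodes < 1:
        raise ValidationError("forest prior requires at least one node")
    return -(num_nodes - 1) * np.log(num_nodes + 1)


# ---------------------------------------------------------------------------
# Grid weights and the marginalization DP
# ---------------------------------------------------------------------------


def node_log_weight(G: int, kappa: float) -> np.ndarray:
    """Dirichlet kernel ``rho^(kappa-1)`` over a node's clonal-mass grid.

    Quadrature endpoint weights live inside the convolution kernel,
    not here.  For kappa < 1 the singular endpoint is evaluated at
    half a grid step to keep the weight finite.
    """
    vals = np.linspace(0.0, 1.0, G)
    w = np.zeros(G)
    if kappa != 1.0:
        with np.errstate(divide="ignore"):
            w = w + (kappa - 1.0) * np.log(vals)
        if kappa < 1.0:
            w[0] = (kappa - 1.0) * np.log(0.5 / (G - 1))
    return w


def root_log_weight(G: int, kappa: float, root_has_mass: bool = True) -> np.ndarray:
    """Dirichlet kernel for the dummy root's clonal mass.

    With ``root_has_mass=False`` the root coordinate is dropped from
    the simplex entirely (callers skip the root factor), so this
    returns the identity weight only for the mass-carrying case.
    """
    return node_log_weight(G, kappa)


_NORM_CACHE: Dict[Tuple[int, int, float, bool], float] = {}


def log_simplex_norm(
    num_nodes: int, G: int, kappa: float, root_has_mass: bool = True
) -> float:
    """Log prior mass of the grid quadrature for K nodes plus root.

    This is the data-free value of the DP readout; dividing by it
    normalizes the quadrature so the marginal likelihood of a
    data-free tree is exactly zero.
    """
    key = (num_nodes, G, kappa, root_has_mass)
    if key not in _NORM_CACHE:
        w = node_log_weight(G, kappa)
        if root_has_mass:
            acc = root_log_weight(G, kappa)
            count = num_nodes
        elif num_nodes == 0:
            return 0.0
        else:
            acc = w
            count = num_nodes - 1
        for _ in range(count):
            acc = log_conv(acc, w)
        _NORM_CACHE[key] = float(acc[-1])
    return _NORM_CACHE[key]


def _postorder(tree: CloneTree) -> List[int]:
    ch = tree.children_map()
    order: List[int] = []

    def visit(v: int) -> None:
        for c in ch.get(v, []):
            visit(c)
        order.append(v)

    visit(ROOT)
    return order


def _sample_messages(
    tree: CloneTree, gl: GridLikelihood, config: ModelConfig, sample: int
):
    """Bottom-up messages for one sample.

    Returns (messages, stacks) where ``messages[v]`` is the log mass
    vector of node v over its subtree-total grid index, and
    ``stacks[v]`` holds the prefix convolutions needed for the
    backward pass: ``stacks[v] = (parts, prefixes, has_own)`` with
    ``parts = [own-weight?, child msgs...]``.
    """
    G = config.grid_size
    if gl.grid.size != G:
        raise ValidationError("grid likelihood does not match configured grid size")
    w = node_log_weight(G, config.kappa)
    ch = tree.children_map()
    messages: Dict[int, np.ndarray] = {}
    stacks: Dict[int, Tuple[List[np.ndarray], List[np.ndarray], bool]] = {}
    for v in _postorder(tree):
        has_own = v != ROOT or config.root_has_mass
        parts = ([w] if has_own else []) + [messages[c] for c in ch.get(v, [])]
        if not parts:  # massless root with no children (empty tree)
            msg = np.zeros(G)
            messages[v] = msg
            stacks[v] = ([], [msg], False)
            continue
        prefixes = [parts[0]]
        for p in parts[1:]:
            prefixes.append(log_conv(prefixes[-1], p))
        msg = prefixes[-1]
        if v != ROOT:
            items = sorted(tree.clusters[v])
            if items:
                msg = msg + gl.loglik[items, sample, :].sum(axis=0)
        messages[v] = msg
        stacks[v] = (parts, prefixes, has_own)
    return messages, stacks


def marginal_loglik(tree: CloneTree, gl: GridLikelihood, config: ModelConfig) -> float:
    """Collapsed log likelihood of the non-outlier data given (T, b).

    Grid approximation to ``∫ Dir(rho | kappa) prod_n f(x_n |
    cellular(v_n)) drho`` computed per sample by the bottom-up DP and
    summed over samples.
    """
    for v, c in tree.clusters.items():
        for i in c:
            if i >= gl.num_items:
                raise ValidationError(f"item {i} has no grid likelihood")
    K = tree.num_nodes
    norm = log_simplex_norm(K, config.grid_size, config.kappa, config.root_has_mass)
    total = 0.0
    for s in range(gl.num_samples):
        messages, _ = _sample_messages(tree, gl, config, s)
        total += float(messages[ROOT][-1]) - norm
    return total


def joint_log_prob(
    tree: CloneTree,
    gl: GridLikelihood,
    config: ModelConfig,
    nu: Optional[np.ndarray] = None,
    item_sizes: Optional[np.ndarray] = None,
    outlier_marginals: Optional[np.ndarray] = None,
    log_inlier: Optional[np.ndarray] = None,
    log_outlier_prior: Optional[np.ndarray] = None,
) -> float:
    """Collapsed joint log probability of (T, b, o) and the data.

    Sums the outlier terms, the CRP partition prior, the uniform
    forest prior, and the marginalized tree likelihood.  ``nu`` gives
    the per-item prior outlier probability (default
    ``config.outlier_prob_low``).  When items are pre-clustered
    blocks, per-item aggregates can be supplied directly via
    ``item_sizes`` (mutations per block), ``log_inlier``
    (sum of log(1-nu) over members) and ``log_outlier_prior``
    (sum of log nu over members).
    """
    n_items = gl.num_items
    if nu is None:
        nu = np.full(n_items, config.outlier_prob_low)
    nu = np.asarray(nu, float)
    if log_inlier is None:
        with np.errstate(divide="ignore"):
            log_inlier = np.log1p(-nu)
    if log_outlier_prior is None:
        with np.errstate(divide="ignore"):
            log_outlier_prior = np.log(nu)
    if item_sizes is None:
        item_sizes = np.ones(n_items, dtype=int)
    if outlier_marginals is None:
        outlier_marginals = gl.outlier_marginals()

    total = 0.0
    for i in sorted(tree.outliers):
        total += float(log_outlier_prior[i]) + float(outlier_marginals[i])
    inlier_items = sorted(set().union(*tree.clusters.values())) if tree.clusters else []
    for i in inlier_items:
        total += float(log_inlier[i])

    if tree.num_nodes > 0:
        sizes = [int(sum(item_sizes[i] for i in c)) for c in tree.clusters.values()]
        total += crp_log_prior(sizes, config.alpha)
        total += forest_log_prior(tree.num_nodes)
        total += marginal_loglik(tree, gl, config)
    return total


# ---------------------------------------------------------------------------
# Prevalence reinstatement
# ---------------------------------------------------------------------------


def _backward_split(
    parts: List[np.ndarray],
    prefixes: List[np.ndarray],
    total: int,
    mode: str,
    rng: np.random.Generator,
) -> List[int]:
    """Allocate ``total`` grid mass among the stack parts, last-first.

    Returns one grid index per part (part 0 is the node's own clonal
    mass).  ``mode`` selects the argmax path ("map") or a draw from
    the DP's conditional ("sample").
    """
    alloc = [0] * len(parts)
    s = total
    for j in range(len(parts) - 1, 0, -1):
        logits = prefixes[j - 1][s::-1] + parts[j][: s + 1]
        if s > 0:  # trapezoid endpoint weights of this convolution
            logits = logits.copy()
            logits[0] += np.log(0.5)
            logits[-1] += np.log(0.5)
        if mode == "map":
            y = int(np.argmax(logits))
        else:
            norm = logsumexp(logits)
            if np.isneginf(norm):
                y = 0
            else:
                probs = np.exp(logits - norm)
                y = int(rng.choice(s + 1, p=probs / probs.sum()))
        alloc[j] = y
        s -= y
    alloc[0] = s
    return alloc


def reinstate_prevalences(
    tree: CloneTree,
    gl: GridLikelihood,
    config: ModelConfig,
    mode: str = "map",
    seed: Optional[int] = None,
) -> PrevalenceMatrix:
    """Reinstate clonal and cellular prevalences after tree inference.

    Per sample, walks back through the stored DP messages, either
    maximizing ("map") or sampling ("sample") the conditional at each
    split.  The returned matrix satisfies the simplex and recursion
    invariants exactly on the grid.
    """
    if mode not in ("map", "sample"):
        raise ValidationError(f"unknown mode {mode!r}")
    if tree.num_nodes < 1:
        raise ValidationError("cannot reinstate prevalences for an empty tree")
    if mode == "sample" and seed is None:
        seed = int(np.random.default_rng().integers(2**31))
        logger.info("reinstate_prevalences: sampling with generated seed %d", seed)
    rng = np.random.default_rng(seed)
    G = config.grid_size
    grid = np.linspace(0.0, 1.0, G)
    nodes = [ROOT] + tree.nodes
    S = gl.num_samples
    clonal = np.zeros((len(nodes), S))
    cellular = np.zeros((len(nodes), S))
    ch = tree.children_map()
    row = {v: i for i, v in enumerate(nodes)}
    for s in range(S):
        _, stacks = _sample_messages(tree, gl, config, s)
        totals = {ROOT: G - 1}
        stack = [ROOT]
        while stack:
            v = stack.pop()
            parts, prefixes, has_own = stacks[v]
            alloc = _backward_split(parts, prefixes, totals[v], mode, rng)
            kids = ch.get(v, [])
            kid_alloc = alloc[1:] if has_own else alloc
            clonal[row[v], s] = grid[alloc[0]] if has_own else 0.0
            cellular[row[v], s] = grid[totals[v]]
            for c, a in zip(kids, kid_alloc):
                totals[c] = a
                stack.append(c)
    return PrevalenceMatrix(nodes=nodes, clonal=clonal, cellular=cellular)
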