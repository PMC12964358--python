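"""Synthetic clone trees and read counts with known ground truth.

Trees come from either the forest CRP prior or a tree-structured
stick-breaking prior; mutation loss is injected by subtracting a
descendant clone's cellular prevalence from a co-located set of
mutations; reads are emitted as diploid-heterozygous binomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx
import numpy as np

from .emission import enumerate_genotype_states, expected_vaf
from .io_formats import SnvObservation, SnvTable, ValidationError
from .tree_model import ROOT, CloneTree, PrevalenceMatrix

DIPLOID_HET_STATES = enumerate_genotype_states(1, 1, 2)


@dataclass
class GroundTruth:
    """A simulated clone tree with prevalences and optional loss."""

    tree: CloneTree
    prevalences: PrevalenceMatrix
    num_samples: int
    lost_mutations: FrozenSet[int] = frozenset()
    loss_node: Optional[int] = None
    origin_node: Optional[int] = None
    chromosomes: Dict[int, str] = field(default_factory=dict)

    @property
    def num_mutations(self) -> int:
        return len(self.tree.items())

    def node_cellular(self, node: int) -> np.ndarray:
        return self.prevalences.cellular[self.prevalences.row(node)]

    def effective_prevalence(self) -> np.ndarray:
        """Per-mutation, per-sample cellular prevalence actually carried
        by sequenceable cells; lost mutations have the loss node's
        cellular prevalence subtracted from their origin's."""
        assign = self.tree.assignment()
        out = np.zeros((self.num_mutations, self.num_samples))
        for n in range(self.num_mutations):
            out[n] = self.node_cellular(assign[n])
            if n in self.lost_mutations:
                out[n] = out[n] - self.node_cellular(self.loss_node)
        return np.clip(out, 0.0, 1.0)

    def labels(self) -> np.ndarray:
        """True cluster label per mutation."""
        assign = self.tree.assignment()
        return np.array([assign[n] for n in range(self.num_mutations)])


def _crp_partition(num_items: int, alpha: float, rng: np.random.Generator) -> List[List[int]]:
    clusters: List[List[int]] = []
    for i in range(num_items):
        probs = np.array([len(c) for c in clusters] + [alpha], float)
        j = rng.choice(len(probs), p=probs / probs.sum())
        if j == len(clusters):
            clusters.append([i])
        else:
            clusters[j].append(i)
    return clusters


def sample_uniform_forest(num_nodes: int, rng: np.random.Generator) -> Dict[int, int]:
    """Uniform rooted labelled forest on K nodes as a parent map.

    Equivalent to a uniform labelled tree on K+1 vertices rooted at
    the extra vertex, sampled by a random Pruefer sequence.
    """
    k = num_nodes
    if k == 1:
        return {0: ROOT}
    seq = [int(x) for x in rng.integers(0, k + 1, size=k - 1)]
    tree = nx.from_prufer_sequence(seq)
    parent: Dict[int, int] = {}
    for u, v in nx.bfs_edges(tree, 0):
        parent[v - 1] = ROOT if u == 0 else u - 1
    return parent


def _prevalences_for_tree(
    tree: CloneTree, num_samples: int, kappa: float, rng: np.random.Generator
) -> PrevalenceMatrix:
    nodes = [ROOT] + tree.nodes
    K = len(nodes)
    clonal = rng.dirichlet(np.full(K, kappa), size=num_samples).T  # (K, S)
    cellular = clonal.copy()
    ch = tree.children_map()
    order: List[int] = []

    def visit(v: int) -> None:
        for c in ch.get(v, []):
            visit(c)
        order.append(v)

    visit(ROOT)
    row = {v: i for i, v in enumerate(nodes)}
    for v in order:
        for c in ch.get(v, []):
            cellular[row[v]] += cellular[row[c]]
    return PrevalenceMatrix(nodes=nodes, clonal=clonal, cellular=cellular)


def simulate_fscrp(
    num_snvs: int,
    alpha: float = 1.0,
    num_samples: int = 1,
    kappa: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Draw a clone tree and prevalences from the forest CRP prior."""
    if num_snvs < 1:
        raise ValidationError("need at least one SNV")
    rng = rng if rng is not None else np.random.default_rng()
    part = _crp_partition(num_snvs, alpha, rng)
    parent = sample_uniform_forest(len(part), rng)
    tree = CloneTree(
        parent=parent, clusters={i: frozenset(c) for i, c in enumerate(part)}
    )
    prev = _prevalences_for_tree(tree, num_samples, kappa, rng)
    chroms = {n: f"chr{int(rng.integers(1, 23))}" for n in range(num_snvs)}
    return GroundTruth(
        tree=tree, prevalences=prev, num_samples=num_samples, chromosomes=chroms
    )


def inject_loss(
    gt: GroundTruth, loss_proportion: float, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Mark a co-located set of mutations as lost below their origin.

    Picks an origin node with at least one proper descendant, selects
    ``round(loss_proportion * N)`` of its mutations, places them on a
    dedicated chromosome, and records the loss node; downstream
    prevalence subtraction happens in :meth:`GroundTruth.effective_prevalence`.
    """
    if not 0 <= loss_proportion < 1:
        raise ValidationError("loss proportion must be in [0, 1)")
    if loss_proportion == 0:
        return gt
    rng = rng if rng is not None else np.random.default_rng()
    tree = gt.tree
    if tree.num_nodes < 2:
        raise ValidationError("loss requires a tree with a proper descendant")
    n_lose = int(round(loss_proportion * gt.num_mutations))
    if n_lose == 0:
        return gt
    ch = tree.children_map()
    eligible = [v for v in tree.nodes if ch.get(v)]
    if not eligible:
        raise ValidationError("no node has a proper descendant")
    with_enough = [v for v in eligible if len(tree.clusters[v]) >= n_lose]
    if with_enough:
        origin = with_enough[int(rng.integers(len(with_enough)))]
    else:
        origin = max(eligible, key=lambda v: len(tree.clusters[v]))
        n_lose = len(tree.clusters[origin])
    descendants = [v for v in tree.subtree_nodes(origin) if v != origin]
    loss_node = descendants[int(rng.integers(len(descendants)))]
    members = sorted(tree.clusters[origin])
    lost = frozenset(
        members[i] for i in rng.choice(len(members), size=n_lose, replace=False)
    )
    chroms = dict(gt.chromosomes)
    loss_chrom = "chrLoss"
    for n in chroms:
        if n in lost:
            chroms[n] = loss_chrom
        elif chroms[n] == loss_chrom:
            chroms[n] = "chr1"
    return replace(
        gt,
        lost_mutations=lost,
        loss_node=loss_node,
        origin_node=origin,
        chromosomes=chroms,
    )


# ---------------------------------------------------------------------------
# Tree-structured stick breaking
# ---------------------------------------------------------------------------


def _tssb_assignments(
    num_items: int,
    gamma: float,
    lam: float,
    decay: float,
    rng: np.random.Generator,
    max_depth: int = 12,
):
    """Sample node paths for each item from a lazily built stick tree."""
    stop: Dict[tuple, float] = {}
    sticks: Dict[tuple, List[float]] = {}
    paths = []
    for _ in range(num_items):
        path: tuple = ()
        while True:
            if path not in stop:
                depth = len(path)
                stop[path] = rng.beta(1.0, lam * decay**depth)
                sticks[path] = []
            if len(path) >= max_depth or rng.random() < stop[path]:
                paths.append(path)
                break
            # descend: pick a child stick (GEM)
            u = rng.random()
            acc = 0.0
            remaining = 1.0
            child = None
            for i, psi in enumerate(sticks[path]):
                seg = remaining * psi
                if u < acc + seg:
                    child = i
                    break
                acc += seg
                remaining -= seg
            while child is None:
                psi = rng.beta(1.0, gamma)
                seg = remaining * psi
                if u < acc + seg:
                    child = len(sticks[path])
                    sticks[path].append(psi)
                    break
                acc += seg
                remaining -= seg
                sticks[path].append(psi)
            path = path + (child,)
    return paths


def simulate_tssb(
    num_snvs: int,
    num_samples: int = 1,
    stick_params: Tuple[float, float, float] = (1.0, 0.5, 1.0),
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Draw a clone tree from a tree-structured stick-breaking prior.

    ``stick_params`` is (gamma, lambda, depth decay).  Items are
    assigned to stick-tree nodes; occupied nodes are connected to
    their nearest occupied ancestor (or the dummy root) so the
    returned tree is a connected subtree of the stick tree.  Clonal
    prevalences are then drawn from a symmetric Dirichlet over the
    occupied nodes plus root.
    """
    if num_snvs < 1:
        raise ValidationError("need at least one SNV")
    rng = rng if rng is not None else np.random.default_rng()
    gamma, lam, decay = stick_params
    paths = _tssb_assignments(num_snvs, gamma, lam, decay, rng)
    occupied = sorted(set(paths), key=lambda p: (len(p), p))
    node_id = {p: i for i, p in enumerate(occupied)}
    parent: Dict[int, int] = {}
    for p in occupied:
        q = p[:-1]
        while q and q not in node_id:
            q = q[:-1]
        parent[node_id[p]] = node_id[q] if (q and q in node_id) else (
            node_id.get((), ROOT) if p != () else ROOT
        )
    # the empty path, when occupied, is always a top-level node
    if () in node_id:
        parent[node_id[()]] = ROOT
    clusters: Dict[int, FrozenSet[int]] = {}
    for n, p in enumerate(paths):
        clusters.setdefault(node_id[p], set()).add(n)  # type: ignore[arg-type]
    tree = CloneTree(
        parent=parent, clusters={v: frozenset(c) for v, c in clusters.items()}
    )
    prev = _prevalences_for_tree(tree, num_samples, 1.0, rng)
    chroms = {n: f"chr{int(rng.integers(1, 23))}" for n in range(num_snvs)}
    return GroundTruth(
        tree=tree, prevalences=prev, num_samples=num_samples, chromosomes=chroms
    )


def emit_reads(
    gt: GroundTruth,
    depth: int = 1000,
    tumour_content: float = 1.0,
    error_rate: float = 0.001,
    rng: Optional[np.random.Generator] = None,
) -> SnvTable:
    """Emit diploid-heterozygous binomial read counts for every
    mutation in every sample."""
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    prev = gt.effective_prevalence()
    obs = []
    for n in range(gt.num_mutations):
        for s in range(gt.num_samples):
            xi = expected_vaf(
                float(prev[n, s]), tumour_content, DIPLOID_HET_STATES, error_rate
            )
            alt = int(rng.binomial(depth, xi))
            obs.append(
                SnvObservation(
                    mutation_id=f"m{n}",
                    sample_id=f"s{s}",
                    ref_counts=depth - alt,
                    alt_counts=alt,
                    major_cn=1,
                    minor_cn=1,
                    normal_cn=2,
                    tumour_content=tumour_content,
                    error_rate=error_rate,
                )
            )
    return SnvTable(observations=obs)
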