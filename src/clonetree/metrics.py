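"""Evaluation metrics for inferred clone trees.

V-measure for clustering accuracy, ancestor-descendant pair F-score
for topology, log perplexity ratio for prevalence reconstruction, and
an exhaustive-enumeration relationship reconstruction error for small
clone sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

from .emission import loglik_at
from .io_formats import SnvTable, ValidationError
from .tree_model import ROOT, CloneTree, PrevalenceMatrix


@dataclass
class AdCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class EvaluationReport:
    v_measure: float
    ad_f_score: float
    lpr: Optional[float] = None
    rre: Optional[float] = None
    counts: Optional[AdCounts] = None

    def to_dict(self) -> dict:
        out = {"v_measure": self.v_measure, "ad_f_score": self.ad_f_score}
        if self.lpr is not None:
            out["lpr"] = self.lpr
        if self.rre is not None:
            out["rre"] = self.rre
        if self.counts is not None:
            out["ad_counts"] = vars(self.counts)
        return out


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(true_labels: Sequence, pred_labels: Sequence) -> float:
    """Harmonic mean of homogeneity and completeness.

    Computed from the conditional entropies of the label contingency
    table; invariant to relabelling on either side.
    """
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValidationError("label vectors differ in length")
    if not true_labels:
        raise ValidationError("label vectors are empty")
    t_ids = {l: i for i, l in enumerate(dict.fromkeys(true_labels))}
    p_ids = {l: i for i, l in enumerate(dict.fromkeys(pred_labels))}
    cont = np.zeros((len(t_ids), len(p_ids)))
    for t, p in zip(true_labels, pred_labels):
        cont[t_ids[t], p_ids[p]] += 1
    n = cont.sum()
    h_t = _entropy(cont.sum(axis=1))
    h_p = _entropy(cont.sum(axis=0))
    # conditional entropies H(T|P), H(P|T)
    h_t_given_p = 0.0
    for j in range(cont.shape[1]):
        col = cont[:, j]
        if col.sum() > 0:
            h_t_given_p += col.sum() / n * _entropy(col)
    h_p_given_t = 0.0
    for i in range(cont.shape[0]):
        row = cont[i]
        if row.sum() > 0:
            h_p_given_t += row.sum() / n * _entropy(row)
    hom = 1.0 if h_t == 0 else 1.0 - h_t_given_p / h_t
    comp = 1.0 if h_p == 0 else 1.0 - h_p_given_t / h_p
    if hom + comp == 0:
        return 0.0
    return 2 * hom * comp / (hom + comp)


def _ancestor_descendant_pairs(tree: CloneTree, keep: Set[int]) -> Set[Tuple[int, int]]:
    ch = tree.children_map()
    pairs: Set[Tuple[int, int]] = set()

    def descend_items(v: int) -> Set[int]:
        out: Set[int] = set()
        for c in ch.get(v, []):
            out |= set(tree.clusters[c]) | descend_items(c)
        return out

    for v in tree.nodes:
        below = descend_items(v) & keep
        for a in set(tree.clusters[v]) & keep:
            for d in below:
                pairs.add((a, d))
    return pairs


def ad_f_score(
    true_tree: CloneTree, pred_tree: CloneTree
) -> Tuple[float, AdCounts]:
    """F1 of predicted vs true ordered ancestor-descendant SNV pairs.

    Mutations marked outlier in either tree are dropped from both pair
    sets.  Empty-vs-nonempty pair sets score zero; two empty pair sets
    score one.
    """
    t_items = true_tree.items()
    p_items = pred_tree.items()
    if not (t_items & p_items):
        raise ValidationError("trees share no mutations")
    keep = (t_items & p_items) - true_tree.outliers - pred_tree.outliers
    true_pairs = _ancestor_descendant_pairs(true_tree, keep)
    pred_pairs = _ancestor_descendant_pairs(pred_tree, keep)
    tp = len(true_pairs & pred_pairs)
    fp = len(pred_pairs - true_pairs)
    fn = len(true_pairs - pred_pairs)
    n = len(keep)
    tn = n * (n - 1) - tp - fp - fn
    counts = AdCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    if not true_pairs and not pred_pairs:
        return 1.0, counts
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0, counts
    return 2 * precision * recall / (precision + recall), counts


def lpr(
    pred_cellular: PrevalenceMatrix,
    table: SnvTable,
    true_cellular: PrevalenceMatrix,
    pred_assign: Dict[int, int],
    true_assign: Dict[int, int],
    density_kind: str = "binomial",
    precision: Optional[float] = None,
) -> float:
    """Log perplexity ratio of predicted vs true cellular prevalences.

    Difference of the mean per-(mutation, sample) negative log
    emission likelihood under the predicted and true prevalence
    matrices, in nats; lower (negative) is better.  Mutations missing
    from either assignment are skipped.
    """
    total = 0.0
    cells = 0
    for n, mut in enumerate(table.mutations):
        if n not in pred_assign or n not in true_assign:
            continue
        p_row = pred_cellular.row(pred_assign[n])
        t_row = true_cellular.row(true_assign[n])
        for s, samp in enumerate(table.samples):
            obs = table.get(mut, samp)
            ll_p = loglik_at(
                obs, float(pred_cellular.cellular[p_row, s]), density_kind, precision
            )
            ll_t = loglik_at(
                obs, float(true_cellular.cellular[t_row, s]), density_kind, precision
            )
            total += ll_t - ll_p
            cells += 1
    return total / cells if cells else 0.0


def _relation(parent: Dict[int, int], i: int, j: int) -> str:
    def ancestors(v: int) -> Set[int]:
        out = set()
        u = parent[v]
        while u != ROOT:
            out.add(u)
            u = parent[u]
        return out

    if i in ancestors(j):
        return "anc"
    if j in ancestors(i):
        return "desc"
    return "branched"


def rre_small(
    pred_tree: CloneTree,
    true_cellular: np.ndarray,
    max_nodes: int = 8,
    tol: float = 0.01,
) -> float:
    """Relationship reconstruction error against all valid topologies.

    ``true_cellular`` is a (clones, samples) cellular-prevalence
    matrix; ``pred_tree`` must be a tree whose nodes each hold exactly
    one clone index.  Every rooted forest over the clones consistent
    with the matrix (children sums not exceeding the parent, top-level
    sums not exceeding one, within ``tol``) is enumerated; the error
    is the fraction of clone pairs whose pairwise relation in the
    prediction disagrees, averaged over the valid set.
    """
    from .enumeration import rooted_forests

    k = true_cellular.shape[0]
    if k > max_nodes:
        raise ValidationError(f"rre_small supports at most {max_nodes} clones")
    for c in pred_tree.clusters.values():
        if len(c) != 1:
            raise ValidationError("rre_small expects one clone per node")
    # translate node-space parents into clone-space parents
    node_clone = {v: next(iter(c)) for v, c in pred_tree.clusters.items()}
    pred_parent = {
        node_clone[v]: (ROOT if p == ROOT else node_clone[p])
        for v, p in pred_tree.parent.items()
    }

    valid = []
    for parent in rooted_forests(k):
        ok = True
        child_sum = np.zeros((k + 1, true_cellular.shape[1]))
        for i in range(k):
            p = parent[i]
            child_sum[p if p != ROOT else k] += true_cellular[i]
        for i in range(k):
            if np.any(child_sum[i] > true_cellular[i] + tol):
                ok = False
                break
        if ok and np.any(child_sum[k] > 1.0 + tol):
            ok = False
        if ok:
            valid.append(parent)
    if not valid:
        raise ValidationError(
            "no topology is consistent with the prevalence matrix"
        )
    pairs = list(combinations(range(k), 2))
    if not pairs:
        return 0.0
    err = 0.0
    for parent in valid:
        dis = sum(
            1
            for i, j in pairs
            if _relation(parent, i, j) != _relation(pred_parent, i, j)
        )
        err += dis / len(pairs)
    return err / len(valid)


def evaluate(
    true_tree: CloneTree,
    pred_tree: CloneTree,
    table: Optional[SnvTable] = None,
    pred_cellular: Optional[PrevalenceMatrix] = None,
    true_cellular: Optional[PrevalenceMatrix] = None,
    density_kind: str = "binomial",
    precision: Optional[float] = None,
) -> EvaluationReport:
    """Convenience wrapper computing all applicable metrics."""
    common = sorted(true_tree.items() & pred_tree.items())
    t_assign = true_tree.assignment()
    p_assign = pred_tree.assignment()
    t_labels = [
        t_assign.get(n, "outlier") for n in common
    ]
    p_labels = [p_assign.get(n, "outlier") for n in common]
    vm = v_measure(t_labels, p_labels)
    f1, counts = ad_f_score(true_tree, pred_tree)
    lpr_val = None
    if table is not None and pred_cellular is not None and true_cellular is not None:
        lpr_val = lpr(
            pred_cellular,
            table,
            true_cellular,
            p_assign,
            t_assign,
            density_kind,
            precision,
        )
    return EvaluationReport(v_measure=vm, ad_f_score=f1, lpr=lpr_val, counts=counts)
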