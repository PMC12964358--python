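"""Reading and writing the tabular input/output dialects.

The SNV table is a tab-separated file with one row per mutation per
sample, carrying allele counts, allele-specific copy number, and
tumour content.  Pre-clusterings are two-column TSVs mapping
``mutation_id`` to ``cluster_id``.  Run results are written as an
edge-list TSV, a mutation-assignment TSV, a JSON summary, and an
optional Newick string.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("clonetree")

REQUIRED_COLUMNS = [
    "mutation_id",
    "sample_id",
    "ref_counts",
    "alt_counts",
    "major_cn",
    "minor_cn",
]

ROOT_LABEL = "root"


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a semantic invariant."""


@dataclass(frozen=True)
class SnvObservation:
    """One mutation's allele counts and copy-number context in one sample."""

    mutation_id: str
    sample_id: str
    ref_counts: int
    alt_counts: int
    major_cn: int
    minor_cn: int
    normal_cn: int = 2
    tumour_content: float = 1.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.ref_counts < 0 or self.alt_counts < 0:
            raise ValidationError(
                f"negative read counts for {self.mutation_id}/{self.sample_id}"
            )
        if self.minor_cn > self.major_cn:
            raise ValidationError(
                f"minor_cn > major_cn for {self.mutation_id}/{self.sample_id}"
            )
        if self.major_cn < 1:
            raise ValidationError(
                f"major_cn must be >= 1 for {self.mutation_id}/{self.sample_id}"
            )
        if not 0.0 <= self.tumour_content <= 1.0:
            raise ValidationError(
                f"tumour_content outside [0, 1] for {self.mutation_id}"
            )

    @property
    def depth(self) -> int:
        return self.ref_counts + self.alt_counts


@dataclass
class SnvTable:
    """Rectangular mutation-by-sample table of :class:`SnvObservation`.

    Mutation and sample orders are fixed at construction (first
    appearance order) and stable for the lifetime of the run.
    """

    observations: List[SnvObservation]
    mutations: List[str] = field(default_factory=list)
    samples: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mutations or not self.samples:
            muts: List[str] = []
            samps: List[str] = []
            for obs in self.observations:
                if obs.mutation_id not in muts:
                    muts.append(obs.mutation_id)
                if obs.sample_id not in samps:
                    samps.append(obs.sample_id)
            self.mutations = self.mutations or muts
            self.samples = self.samples or samps
        self._index: Dict[tuple, SnvObservation] = {}
        for obs in self.observations:
            key = (obs.mutation_id, obs.sample_id)
            if key in self._index:
                raise ValidationError(f"duplicate row for {key}")
            self._index[key] = obs
        missing = [
            (m, s)
            for m in self.mutations
            for s in self.samples
            if (m, s) not in self._index
        ]
        if missing:
            raise ValidationError(
                f"non-rectangular table; missing (mutation, sample) pairs: {missing}"
            )

    @property
    def num_mutations(self) -> int:
        return len(self.mutations)

    @property
    def num_samples(self) -> int:
        return len(self.samples)

    def get(self, mutation_id: str, sample_id: str) -> SnvObservation:
        return self._index[(mutation_id, sample_id)]

    def rows(self):
        """Iterate observations in (mutation-major, sample-minor) order."""
        for m in self.mutations:
            for s in self.samples:
                yield self._index[(m, s)]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "mutation_id": o.mutation_id,
                "sample_id": o.sample_id,
                "ref_counts": o.ref_counts,
                "alt_counts": o.alt_counts,
                "major_cn": o.major_cn,
                "minor_cn": o.minor_cn,
                "normal_cn": o.normal_cn,
                "tumour_content": o.tumour_content,
                "error_rate": o.error_rate,
            }
            for o in self.rows()
        ]
        return pd.DataFrame.from_records(recs)


@dataclass
class PreClustering:
    """Total assignment of mutations to dense cluster indices 0..K-1."""

    assignment: Dict[str, int]

    @property
    def num_clusters(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def validate_against(self, table: SnvTable) -> None:
        missing = [m for m in table.mutations if m not in self.assignment]
        if missing:
            raise ValidationError(
                f"mutations absent from pre-clustering: {missing}"
            )


def read_snv_table(
    path: str,
    tumour_content: Optional[float] = None,
    error_rate: float = 0.001,
) -> SnvTable:
    """Read a tab-separated SNV table.

    Parameters
    ----------
    path
        TSV with header columns ``mutation_id, sample_id, ref_counts,
        alt_counts, major_cn, minor_cn`` and optionally ``normal_cn``,
        ``tumour_content`` and ``error_rate``.
    tumour_content
        If given, broadcast to every row, overriding any column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"SNV table {path!r} is missing column {col!r}")
    if "tumour_content" not in df.columns and tumour_content is None:
        raise FormatError(
            f"SNV table {path!r} is missing column 'tumour_content' and no "
            "per-run tumour content was supplied"
        )
    obs = []
    for rec in df.to_dict("records"):
        obs.append(
            SnvObservation(
                mutation_id=str(rec["mutation_id"]),
                sample_id=str(rec["sample_id"]),
                ref_counts=int(rec["ref_counts"]),
                alt_counts=int(rec["alt_counts"]),
                major_cn=int(rec["major_cn"]),
                minor_cn=int(rec["minor_cn"]),
                normal_cn=int(rec.get("normal_cn", 2)),
                tumour_content=float(
                    tumour_content
                    if tumour_content is not None
                    else rec["tumour_content"]
                ),
                error_rate=float(rec.get("error_rate", error_rate)),
            )
        )
    return SnvTable(observations=obs)


def write_snv_table(table: SnvTable, path: str) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_preclustering(path: str, table: Optional[SnvTable] = None) -> PreClustering:
    """Read a two-column (mutation_id, cluster_id) TSV.

    Cluster ids are re-indexed densely, 0..K-1, in first-appearance
    order.  Mutations not present in ``table`` are dropped with a
    warning; mutations of ``table`` missing from the file are an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("mutation_id", "cluster_id"):
        if col not in df.columns:
            raise FormatError(f"pre-clustering {path!r} is missing column {col!r}")
    dense: Dict[str, int] = {}
    assignment: Dict[str, int] = {}
    known = set(table.mutations) if table is not None else None
    extras = []
    for rec in df.to_dict("records"):
        mut = str(rec["mutation_id"])
        raw = rec["cluster_id"]
        if known is not None and mut not in known:
            extras.append(mut)
            continue
        if raw not in dense:
            dense[raw] = len(dense)
        assignment[mut] = dense[raw]
    if extras:
        logger.warning(
            "pre-clustering contains %d mutations absent from the SNV table; ignored",
            len(extras),
        )
    pc = PreClustering(assignment=assignment)
    if table is not None:
        pc.validate_against(table)
    return pc


def _tree_to_newick(parent: Dict[str, Optional[str]]) -> str:
    children: Dict[Optional[str], List[str]] = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)

    def fmt(node: str) -> str:
        kids = sorted(children.get(node, []))
        if not kids:
            return str(node)
        return "(" + ",".join(fmt(k) for k in kids) + ")" + str(node)

    return fmt(ROOT_LABEL) + ";"


def write_results(trace, map_tree, out_dir: str, mutation_ids=None) -> None:
    """Write the MAP tree, mutation assignments, and a run summary.

    Parameters
    ----------
    trace
        A :class:`clonetree.inference.PosteriorTrace`.
    map_tree
        The selected :class:`clonetree.tree_model.CloneTree`; cluster
        items are interpreted as indices into ``mutation_ids`` when
        given, else used verbatim.
    """
    from .tree_model import ROOT

    if not trace.samples:
        raise ValidationError("cannot write results from an empty trace")
    os.makedirs(out_dir, exist_ok=True)

    def label(node):
        return ROOT_LABEL if node == ROOT else f"node{node}"

    def mut_label(item):
        return mutation_ids[item] if mutation_ids is not None else str(item)

    edges = [
        {"child_node": label(v), "parent_node": label(p)}
        for v, p in sorted(map_tree.parent.items())
    ]
    pd.DataFrame.from_records(edges, columns=["child_node", "parent_node"]).to_csv(
        os.path.join(out_dir, "map_tree_edges.tsv"), sep="\t", index=False
    )

    rows = []
    for v in sorted(map_tree.parent):
        for item in sorted(map_tree.clusters[v]):
            rows.append(
                {"mutation_id": mut_label(item), "node": label(v), "is_outlier": False}
            )
    for item in sorted(map_tree.outliers):
        rows.append({"mutation_id": mut_label(item), "node": "", "is_outlier": True})
    pd.DataFrame.from_records(
        rows, columns=["mutation_id", "node", "is_outlier"]
    ).to_csv(os.path.join(out_dir, "map_tree_assignments.tsv"), sep="\t", index=False)

    summary = {
        "log_prob_trace": [float(s.log_prob) for s in trace.samples],
        "iterations": [int(s.iteration) for s in trace.samples],
        "chains": [int(s.chain) for s in trace.samples],
        "seed": trace.seed,
        "config": trace.config,
        "map_log_prob": float(
            max(s.log_prob for s in trace.samples)
        ),
    }
    with open(os.path.join(out_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    parent_labels = {label(v): label(p) for v, p in map_tree.parent.items()}
    with open(os.path.join(out_dir, "map_tree.nwk"), "w") as fh:
        fh.write(_tree_to_newick(parent_labels) + "\n")


def read_edge_list(path: str) -> Dict[str, Optional[str]]:
    """Read back an edge-list TSV as a child -> parent label map."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["child_node"]): str(r["parent_node"]) for r in df.to_dict("records")
    }
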