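"""Exploratory Ward clustering of patients on clinical variables.

Builds a complete-case, z-standardized patient x variable matrix (binary
phenotypes as 0/1, sex as 0/1, deletion size in Mb) and agglomerates it
with Ward's variance-minimizing linkage on Euclidean distances (the
Ward.D2 convention).  Standardization keeps the deletion size, measured in
megabases, from dominating the binary variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cohort import (
    Cohort,
    TriState,
    UndefinedStatisticError,
    ValidationError,
    locus_deletion_start,
)

__all__ = [
    "ClusterResult",
    "DELETION_SIZE_VARS",
    "feature_matrix",
    "ward_clusters",
    "cluster_summary",
    "to_newick",
]

#: variable names resolving to the locus deletion size in Mb
DELETION_SIZE_VARS = ("deletion_size", "delsize")


@dataclass(frozen=True)
class ClusterResult:
    assignments: dict[str, int]  # patient_id -> cluster label in 1..k
    k: int
    merge_tree: np.ndarray  # scipy linkage matrix (heights non-decreasing)
    variable_spec: tuple[tuple[str, str, str], ...]  # (variable, type, transform)
    dropped: tuple[str, ...]  # zero-variance columns removed


def _deletion_size_mb(p, locus) -> float | None:
    dels = p.locus_deletions(locus)
    if not dels:
        return None
    # size of the qualifying (most proximal) locus deletion
    bp = min(c.interval.start for c in dels)
    best = max((c for c in dels if c.interval.start == bp), key=lambda c: c.interval.length)
    return best.interval.length / 1e6


def feature_matrix(
    cohort: Cohort, variables: Sequence[str]
) -> tuple[np.ndarray, list[str], ClusterResult | None, list[tuple]]:
    """Complete-case, standardized matrix for clustering.

    Returns (matrix, included patient ids, None, variable records) where
    each record is (name, type, transform-note).  Patients missing any
    requested variable are dropped; zero-variance columns are removed and
    recorded with transform "dropped:zero-variance".
    """
    raw_cols: dict[str, list[float | None]] = {v: [] for v in variables}
    ids_all = []
    for p in cohort:
        ids_all.append(p.id)
        for v in variables:
            if v == "sex":
                val = {"M": 0.0, "F": 1.0}.get(p.sex)
            elif v in DELETION_SIZE_VARS:
                val = _deletion_size_mb(p, cohort.locus)
            else:
                st = p.phenotypes.values.get(v, TriState.UNKNOWN)
                val = None if st is TriState.UNKNOWN else float(st is TriState.PRESENT)
            raw_cols[v].append(val)

    keep_rows = [
        i for i in range(len(ids_all))
        if all(raw_cols[v][i] is not None for v in variables)
    ]
    if len(keep_rows) < 2:
        raise UndefinedStatisticError("fewer than 2 complete cases for clustering")
    ids = [ids_all[i] for i in keep_rows]

    cols, records = [], []
    for v in variables:
        vtype = "continuous" if v in DELETION_SIZE_VARS else "binary"
        x = np.array([raw_cols[v][i] for i in keep_rows], dtype=float)
        sd = x.std()  # population sd; only the ratio matters
        if sd == 0.0:
            records.append((v, vtype, "dropped:zero-variance"))
            continue
        cols.append((x - x.mean()) / sd)
        records.append((v, vtype, "z-standardized"))
    if not cols:
        raise UndefinedStatisticError("all clustering variables have zero variance")
    return np.column_stack(cols), ids, None, records


def ward_clusters(
    matrix: np.ndarray, k: int, ids: Sequence[str] | None = None,
    variable_records: Sequence[tuple] = (),
) -> ClusterResult:
    """Ward agglomeration of the rows of `matrix`, cut at k clusters.

    Euclidean distances, Ward.D2 linkage (merge heights are the square
    root of twice the within-cluster variance increase).  Cluster labels
    are renumbered 1..k in order of first appearance by row index, so the
    labelling is deterministic.
    """
    n = matrix.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    Z = hierarchy.linkage(matrix, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    if ids is None:
        ids = [str(i) for i in range(n)]
    return ClusterResult(
        assignments={pid: int(l) for pid, l in zip(ids, labels)},
        k=k,
        merge_tree=Z,
        variable_spec=tuple(
            (str(a), str(b), str(c)) for a, b, c in variable_records
        ),
        dropped=tuple(
            v for v, _, t in variable_records if t.startswith("dropped")
        ),
    )


def cluster_summary(
    cohort: Cohort, result: ClusterResult, features: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-cluster size, mean deletion size (Mb) and feature percentages.

    Percentages are over informative cluster members only; NaN where no
    member is informative (or no member has a locus deletion).
    """
    rows = []
    by_cluster: dict[int, list] = {}
    for pid, lab in result.assignments.items():
        by_cluster.setdefault(lab, []).append(cohort.patient(pid))
    for lab in sorted(by_cluster):
        members = by_cluster[lab]
        sizes = [
            _deletion_size_mb(p, cohort.locus)
            for p in members
            if locus_deletion_start(p, cohort.locus) is not None
        ]
        row = {
            "cluster": lab,
            "n": len(members),
            "mean_deletion_mb": float(np.mean(sizes)) if sizes else np.nan,
        }
        for f in features:
            stats = [
                p.phenotypes.values.get(f, TriState.UNKNOWN) for p in members
            ]
            inf = [s for s in stats if s is not TriState.UNKNOWN]
            row[f"pct_{f}"] = (
                100.0 * sum(s is TriState.PRESENT for s in inf) / len(inf)
                if inf
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def to_newick(result: ClusterResult, ids: Sequence[str] | None = None) -> str:
    """Newick rendering of the merge tree, branch lengths = height deltas."""
    if ids is None:
        ids = list(result.assignments)
    tree = hierarchy.to_tree(result.merge_tree)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{ids[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
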