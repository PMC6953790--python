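"""Drift statistics over a reduced-segment matrix.

Euclidean distances between per-sample log2 vectors quantify genetic
drift; hierarchical clustering groups samples; the unique-vs-shared
tabulation and Fisher's exact test compare how random the accumulated
CNAs of two groups are (unique = called in exactly one in-scope sample,
shared = the same reduced segment called in the same direction in >= 2
in-scope samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

from segstack.genome_model import SegstackError, ValidationError
from segstack.reduced_segments import CnaCall, ReducedMatrix, baseline


@dataclass
class DistanceResult:
    """Symmetric sample x sample Euclidean distance table.

    ``n_complete`` reports, per pair, how many reduced segments were
    present in both samples (pairwise-complete handling of missing
    values), so distances remain comparable."""

    distances: pd.DataFrame
    n_complete: pd.DataFrame


def distance_matrix(
    matrix: ReducedMatrix,
    relative_to_baseline: bool = False,
    control_ids: Sequence[str] | None = None,
) -> DistanceResult:
    """Pairwise Euclidean distances over reduced-segment log2 vectors.

    With ``relative_to_baseline`` the vectors are deltas from the
    control mean; the distances themselves are invariant to subtracting
    a common baseline wherever data are complete, but both modes are
    exposed for matrices with missing values.
    """
    if len(matrix.sample_ids) < 2:
        raise ValidationError("distance matrix requires >= 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    if relative_to_baseline:
        if not control_ids:
            raise ValidationError("relative_to_baseline requires control_ids")
        X = X - baseline(matrix, control_ids).to_numpy(dtype=float)
    ids = matrix.sample_ids
    n = len(ids)
    D = np.zeros((n, n))
    C = np.zeros((n, n), dtype=np.int64)
    finite = np.isfinite(X)
    for i in range(n):
        C[i, i] = int(finite[i].sum())
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            diff = X[i, mask] - X[j, mask]
            d = float(np.sqrt(np.sum(diff * diff)))
            D[i, j] = D[j, i] = d
            C[i, j] = C[j, i] = int(mask.sum())
    return DistanceResult(
        distances=pd.DataFrame(D, index=ids, columns=ids),
        n_complete=pd.DataFrame(C, index=ids, columns=ids),
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering of a distance matrix.

    ``linkage`` is a scipy linkage matrix over ``labels`` (sorted
    lexicographically before clustering so ties break deterministically);
    ``leaf_order`` is the dendrogram leaf ordering.
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels (1..k) from cutting the tree at k clusters."""
        assignment = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.left, node.right
            parts = []
            for child in (left, right):
                bl = node.dist - (0.0 if child.is_leaf() else child.dist)
                parts.append(f"{rec(child)}:{bl:g}")
            return f"({parts[0]},{parts[1]})"

        return rec(tree) + ";"


def hierarchical_cluster(
    distances: pd.DataFrame, method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering (average linkage by default) of a
    symmetric distance table; deterministic for identical input."""
    labels = sorted(str(l) for l in distances.index)
    D = distances.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    np.fill_diagonal(D, 0.0)
    condensed = ssd.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=method)
    leaves = sch.leaves_list(Z)
    return ClusterResult(
        linkage=Z, labels=labels, leaf_order=[labels[i] for i in leaves]
    )


@dataclass
class UniqueSharedResult:
    unique: int
    shared: int
    calls: list[CnaCall]

    @property
    def ratio(self) -> float:
        """unique/shared; NaN (flagged undefined) when shared == 0."""
        if self.shared == 0:
            return float("nan")
        return self.unique / self.shared


def unique_shared(
    calls: Sequence[CnaCall], samples_in_scope: Iterable[str]
) -> UniqueSharedResult:
    """Tally unique vs shared call occurrences among in-scope samples.

    A call is *shared* when any of its reduced-segment tiles is called
    in the same direction in >= 2 in-scope samples; otherwise unique.
    Calls must derive from one ReducedMatrix (same tile frame); counts
    are per call occurrence.  The returned calls carry the ``shared``
    annotation.
    """
    scope = set(samples_in_scope)
    in_scope = [c for c in calls if c.sample_id in scope]
    support: dict[tuple[int, str], set[str]] = {}
    for c in in_scope:
        if not c.tiles:
            raise ValidationError(
                f"call {c.sample_id} {c.chrom}:{c.start}-{c.end} carries no "
                "reduced-segment tiles; derive calls from one ReducedMatrix"
            )
        for t in c.tiles:
            support.setdefault((t, c.direction), set()).add(c.sample_id)
    unique = shared = 0
    for c in in_scope:
        is_shared = any(len(support[(t, c.direction)]) >= 2 for t in c.tiles)
        c.shared = is_shared
        if is_shared:
            shared += 1
        else:
            unique += 1
    return UniqueSharedResult(unique=unique, shared=shared, calls=in_scope)


def fisher_randomness(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[unique_a, shared_a],
    [unique_b, shared_b]] (point-probability rule).

    A degenerate table (any zero margin) yields p = 1 with a warning.
    """
    ua, sa = group_a
    ub, sb = group_b
    if min(ua, sa, ub, sb) < 0:
        raise ValidationError("counts must be >= 0")
    if ua + sa + ub + sb == 0:
        raise ValidationError("all-zero table")
    table = np.array([[ua, sa], [ub, sb]])
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        odds = np.nan
        if sa > 0 and ub > 0:
            odds = (ua * sb) / (sa * ub)
        return float(odds), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class DriftResult:
    """Bundle of all drift analyses for one cohort."""

    distance: DistanceResult
    cluster: ClusterResult
    unique_shared: dict[str, UniqueSharedResult]
    ratios: dict[str, float]
    fisher_tests: list[tuple[str, str, float, float]]


def analyze_drift(
    matrix: ReducedMatrix,
    calls: Sequence[CnaCall],
    groups: Mapping[str, Sequence[str]],
    scope: str = "within-group",
) -> DriftResult:
    """Distances, clustering and unique/shared statistics per group.

    ``scope``: ``"within-group"`` evaluates sharedness among each
    group's own samples (default); ``"cohort"`` evaluates it across all
    grouped samples while still tallying per group.
    """
    if scope not in ("within-group", "cohort"):
        raise ValidationError(f"unknown scope {scope!r}")
    dist = distance_matrix(matrix)
    cluster = hierarchical_cluster(dist.distances)
    us: dict[str, UniqueSharedResult] = {}
    if scope == "cohort":
        all_ids = [sid for ids in groups.values() for sid in ids]
        pooled = unique_shared(list(calls), all_ids)
        for group, ids in groups.items():
            members = [c for c in pooled.calls if c.sample_id in set(ids)]
            us[group] = UniqueSharedResult(
                unique=sum(1 for c in members if c.shared is False),
                shared=sum(1 for c in members if c.shared),
                calls=members,
            )
    else:
        for group, ids in groups.items():
            us[group] = unique_shared(list(calls), ids)
    ratios = {g: r.ratio for g, r in us.items()}
    names = list(groups)
    tests = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            odds, p = fisher_randomness(
                (us[a].unique, us[a].shared), (us[b].unique, us[b].shared)
            )
            tests.append((a, b, odds, p))
    return DriftResult(
        distance=dist,
        cluster=cluster,
        unique_shared=us,
        ratios=ratios,
        fisher_tests=tests,
    )
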