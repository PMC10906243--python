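"""Universal Training Set design by K-means clustering of descriptor space.

The combinatorial library is too large to screen, so a compact training
set is designed without any selectivity data: building blocks are
clustered in the reduced descriptor space, the member nearest each
centroid becomes that cluster's exemplar, a few residues may be added by
expert choice, and the training set is the combinatorial tripeptide
library over the resulting pool.  An elbow scan of distortion versus
cluster count informs the (user-made) choice of k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .building_blocks import AminoAcid, CatalystLibrary, enumerate_library
from .errors import ValidationError

__all__ = [
    "ClusterScan",
    "ExemplarSet",
    "DistributionSummary",
    "kmeans_scan",
    "select_exemplars",
    "augment_manual",
    "build_uts",
    "summarize_distribution",
]


@dataclass(frozen=True)
class ClusterScan:
    """Best-of-restarts K-means solutions over a range of cluster counts.

    ``distortion[k]`` is the mean squared Euclidean distance of points
    to their assigned centroid (the elbow-method convention); it is
    non-increasing in k because each k's search additionally warm-starts
    from the previous k's centroids plus the worst-fit point.
    """

    points: np.ndarray
    ids: tuple[str, ...]
    k_values: tuple[int, ...]
    distortions: dict[int, float]
    assignments: dict[int, np.ndarray]
    centroids: dict[int, np.ndarray]
    seed: int
    n_restarts: int


@dataclass(frozen=True)
class ExemplarSet:
    """Cluster exemplars (nearest members to centroids) plus manual additions."""

    exemplars: tuple[str, ...]
    centroid_distances: tuple[float, ...]
    manual_additions: tuple[str, ...] = ()

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.exemplars + self.manual_additions

    def __len__(self) -> int:
        return len(self.all_ids)


@dataclass(frozen=True)
class DistributionSummary:
    """Shape diagnostics of a selectivity sample against normality."""

    n: int
    mean: float
    std: float
    skewness: float
    excess_kurtosis: float
    ks_statistic: float
    ks_pvalue: float


def kmeans_scan(
    points: np.ndarray,
    k_range=range(1, 51),
    n_restarts: int = 25,
    seed: int = 0,
    ids: tuple[str, ...] | None = None,
) -> ClusterScan:
    """Cluster reduced-space coordinates for every k in ``k_range``.

    Each k runs ``n_restarts`` k-means++ initializations plus one
    warm start that extends the previous k's best centroids with the
    point farthest from its centroid; the lowest-distortion solution
    wins.  Deterministic under a fixed seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array (n_points, n_dims)")
    n = points.shape[0]
    k_values = tuple(sorted(set(int(k) for k in k_range)))
    if not k_values or k_values[0] < 1:
        raise ValidationError("k range must contain integers >= 1")
    if k_values[-1] > n:
        raise ValidationError(
            f"k_max={k_values[-1]} exceeds the number of points ({n})"
        )
    if ids is None:
        ids = tuple(f"P{i:04d}" for i in range(n))
    if len(ids) != n:
        raise ValidationError("ids length must match the number of points")

    distortions: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    centroids: dict[int, np.ndarray] = {}
    previous_centroids: np.ndarray | None = None
    for k in k_values:
        best = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=seed,
            tol=1e-6,
        ).fit(points)
        best_inertia = best.inertia_
        best_labels = best.labels_
        best_centers = best.cluster_centers_
        if previous_centroids is not None and previous_centroids.shape[0] == k - 1:
            # warm start: previous centroids + the currently worst-fit point
            dist2 = (
                np.linalg.norm(points[:, None, :] - previous_centroids[None], axis=2)
                ** 2
            )
            worst = int(np.argmax(dist2.min(axis=1)))
            init = np.vstack([previous_centroids, points[worst]])
            warm = KMeans(n_clusters=k, init=init, n_init=1, tol=1e-6).fit(points)
            if warm.inertia_ < best_inertia:
                best_inertia = warm.inertia_
                best_labels = warm.labels_
                best_centers = warm.cluster_centers_
        distortions[k] = float(best_inertia) / n
        assignments[k] = best_labels.copy()
        centroids[k] = best_centers.copy()
        previous_centroids = best_centers
    return ClusterScan(
        points=points,
        ids=tuple(ids),
        k_values=k_values,
        distortions=distortions,
        assignments=assignments,
        centroids=centroids,
        seed=seed,
        n_restarts=n_restarts,
    )


def select_exemplars(scan: ClusterScan, k: int) -> ExemplarSet:
    """Pick the member nearest each centroid (ties broken by lowest id)."""
    if k not in scan.distortions:
        raise ValidationError(f"k={k} was not part of the scan {scan.k_values}")
    labels = scan.assignments[k]
    centers = scan.centroids[k]
    exemplars: list[str] = []
    dists: list[float] = []
    for cluster in range(k):
        member_idx = np.flatnonzero(labels == cluster)
        if member_idx.size == 0:
            raise ValidationError(f"cluster {cluster} of k={k} is empty")
        d = np.linalg.norm(scan.points[member_idx] - centers[cluster], axis=1)
        best = min(
            range(member_idx.size),
            key=lambda i: (round(float(d[i]), 12), scan.ids[member_idx[i]]),
        )
        exemplars.append(scan.ids[member_idx[best]])
        dists.append(float(d[best]))
    return ExemplarSet(exemplars=tuple(exemplars), centroid_distances=tuple(dists))


def augment_manual(
    exemplars: ExemplarSet,
    additions: list[str],
    blocks: list[AminoAcid],
) -> ExemplarSet:
    """Add expert-chosen building blocks, kept disjoint from the exemplars."""
    known = {b.id for b in blocks}
    for addition in additions:
        if addition not in known:
            raise ValidationError(f"manual addition {addition!r} is not a known building block")
        if addition in exemplars.exemplars or addition in exemplars.manual_additions:
            raise ValidationError(
                f"manual addition {addition!r} duplicates an existing exemplar"
            )
    return ExemplarSet(
        exemplars=exemplars.exemplars,
        centroid_distances=exemplars.centroid_distances,
        manual_additions=exemplars.manual_additions + tuple(additions),
    )


def build_uts(
    exemplars: ExemplarSet,
    fixed_first: AminoAcid,
    blocks: list[AminoAcid],
    c_terminus: str = "amide",
) -> CatalystLibrary:
    """Combinatorial training set over the exemplar pool (|pool|^2 peptides)."""
    if len(exemplars) == 0:
        raise ValidationError("exemplar set is empty")
    by_id = {b.id: b for b in blocks}
    missing = [i for i in exemplars.all_ids if i not in by_id]
    if missing:
        raise ValidationError(f"exemplar ids not in building-block set: {missing}")
    pool = [by_id[i] for i in exemplars.all_ids]
    return enumerate_library(fixed_first, pool, c_terminus=c_terminus)


def summarize_distribution(values) -> DistributionSummary:
    """Sample skewness, excess kurtosis, and a KS test against a fitted normal.

    Moments use the population (uncorrected) estimators, for which a
    symmetric two-point sample has skewness 0 and excess kurtosis -2.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 4:
        raise ValidationError("distribution summary needs a 1-D sample with n >= 4")
    mean = float(values.mean())
    std = float(values.std(ddof=0))
    if std == 0:
        raise ValidationError("sample is constant; distribution shape undefined")
    ks_stat, ks_p = stats.kstest(values, "norm", args=(mean, std))
    return DistributionSummary(
        n=values.size,
        mean=mean,
        std=std,
        skewness=float(stats.skew(values, bias=True)),
        excess_kurtosis=float(stats.kurtosis(values, fisher=True, bias=True)),
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
    )
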