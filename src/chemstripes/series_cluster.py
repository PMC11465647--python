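"""Time-series clustering and outlier scoring of per-CID yearly patent counts.

The interesting signal in a chemical's patent history is its *shape* — e.g.
an abrupt decrease after a regulatory action — not its magnitude, so each
series is z-normalised (constant series map to zero and are flagged) before
Euclidean k-means clustering with seeded k-means++ initialisation. Outliers
are scored by distance to the assigned cluster centroid: a series far from
every typical temporal pattern ranks high. When k is not given it is chosen
by the mean silhouette over a small candidate range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .patent_core import DEFAULT_DATE_PREFERENCE, DatePreference, PatentRecord
from .stripes import DEFAULT_YEAR_RANGE, YearRange, bin_counts

__all__ = [
    "SeriesMatrix",
    "ClusterResult",
    "series_matrix_from_records",
    "normalize_series",
    "cluster_series",
    "outlier_scores",
    "choose_k",
    "rank_outliers",
]


@dataclass(frozen=True)
class SeriesMatrix:
    """cid x year matrix of counts (or z-scores once normalised)."""

    cids: tuple[int, ...]
    years: YearRange
    values: np.ndarray
    normalized: bool = False
    constant_rows: frozenset[int] = frozenset()  # cids whose raw row was constant

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.cids), len(self.years)):
            raise ValueError(
                f"values shape {values.shape} != "
                f"({len(self.cids)} cids, {len(self.years)} years)"
            )

    def row(self, cid: int) -> np.ndarray:
        return self.values[self.cids.index(cid)]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.values, index=list(self.cids),
                          columns=list(self.years.years()))
        df.rename_axis("cid").to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeriesMatrix":
        df = pd.read_csv(path, index_col=0)
        years = [int(c) for c in df.columns]
        return cls(
            cids=tuple(int(i) for i in df.index),
            years=YearRange(min(years), max(years)),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ClusterResult:
    """Cluster labels, centroids and outlier scores with run parameters."""

    labels: Mapping[int, int]  # cid -> cluster id
    centroids: Mapping[int, np.ndarray]
    outlier_scores: Mapping[int, float] = field(default_factory=dict)
    parameters: Mapping[str, object] = field(default_factory=dict)


def series_matrix_from_records(
    records: Iterable[PatentRecord],
    cids: Sequence[int],
    years: YearRange = DEFAULT_YEAR_RANGE,
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
    dedupe_mode: str = "publication",
) -> SeriesMatrix:
    """One row of yearly deduplicated counts per CID of interest."""
    records = list(records)
    rows = []
    for cid in cids:
        mine = [r for r in records if cid in r.cids]
        if mine:
            yc = bin_counts(mine, years, pref, dedupe_mode, subject=(cid,))
            rows.append(yc.values())
        else:
            rows.append(np.zeros(len(years)))
    return SeriesMatrix(cids=tuple(cids), years=years,
                        values=np.array(rows, dtype=float))


def normalize_series(matrix: SeriesMatrix) -> SeriesMatrix:
    """Z-normalise each row to mean 0, variance 1 (population std).

    Constant rows — including all-zero series — carry no shape information;
    they map to the zero vector and are flagged in ``constant_rows``.
    """
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    constant = std.ravel() == 0.0
    safe_std = np.where(std == 0.0, 1.0, std)
    z = (values - mean) / safe_std
    z[constant, :] = 0.0
    return replace(
        matrix,
        values=z,
        normalized=True,
        constant_rows=frozenset(c for c, flag in zip(matrix.cids, constant) if flag),
    )


def cluster_series(matrix: SeriesMatrix, k: int, seed: int = 0) -> ClusterResult:
    """Euclidean k-means over normalised series.

    Seeded k-means++ initialisation with 10 restarts, keeping the lowest
    inertia, so identical seeds give identical labels. Requires a normalised
    matrix and at least k rows.
    """
    if not matrix.normalized:
        raise ValueError("cluster_series requires a normalized SeriesMatrix")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(matrix.cids)
    if n < k:
        raise ValueError(f"need at least k={k} series, have {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.values)
    return ClusterResult(
        labels={cid: int(lab) for cid, lab in zip(matrix.cids, labels)},
        centroids={i: km.cluster_centers_[i].copy() for i in range(k)},
        parameters={"k": k, "seed": seed, "distance": "euclidean",
                    "init": "k-means++", "n_init": 10,
                    "inertia": float(km.inertia_)},
    )


def outlier_scores(matrix: SeriesMatrix, result: ClusterResult) -> ClusterResult:
    """Score each series by Euclidean distance to its cluster centroid.

    A singleton cluster's sole member coincides with its own centroid and
    would self-mask with a score of 0; such series are scored by distance to
    the nearest *other* centroid instead, so an isolated atypical series
    still surfaces at the top of the ranking.
    """
    sizes: dict[int, int] = {}
    for lab in result.labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    scores: dict[int, float] = {}
    for i, cid in enumerate(matrix.cids):
        lab = result.labels[cid]
        row = matrix.values[i]
        if sizes[lab] == 1 and len(result.centroids) > 1:
            d = min(
                float(np.linalg.norm(row - c))
                for other, c in result.centroids.items()
                if other != lab
            )
        else:
            d = float(np.linalg.norm(row - result.centroids[lab]))
        scores[cid] = d
    return replace(result, outlier_scores=scores)


def choose_k(
    matrix: SeriesMatrix,
    k_range: Iterable[int] = range(2, 9),
    seed: int = 0,
) -> int:
    """Pick k by maximal mean silhouette; ties go to the smallest k."""
    if not matrix.normalized:
        raise ValueError("choose_k requires a normalized SeriesMatrix")
    n = len(matrix.cids)
    best_k, best_score = None, -np.inf
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        result = cluster_series(matrix, k, seed)
        labels = np.array([result.labels[c] for c in matrix.cids])
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(matrix.values, labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no feasible k in range for this matrix")
    return best_k


def rank_outliers(result: ClusterResult) -> list[tuple[int, float]]:
    """Series ranked by outlier score descending, ties by ascending CID."""
    return sorted(result.outlier_scores.items(), key=lambda kv: (-kv[1], kv[0]))


def plot_centroids(matrix: SeriesMatrix, result: ClusterResult,
                   path: str | Path) -> Path:
    """One line per cluster centroid over the year axis."""
    path = Path(path)
    years = list(matrix.years.years())
    fig, ax = plt.subplots(figsize=(8, 4), dpi=100)
    for lab, centroid in sorted(result.centroids.items()):
        size = sum(1 for v in result.labels.values() if v == lab)
        ax.plot(years, centroid, label=f"cluster {lab} (n={size})")
    ax.set_xlabel("year")
    ax.set_ylabel("z-normalised count")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "chemstripes"})
    plt.close(fig)
    return path
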