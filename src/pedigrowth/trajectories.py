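"""K-means clustering of longitudinal body-weight trajectories.

Individual growth curves are binned onto a common age grid, individuals with
fewer than 6 observed bins are dropped, gaps are imputed (linear
interpolation, edge copy), and Lloyd k-means with Euclidean distance on the
trajectory vectors partitions individuals into growth clusters.  The number
of clusters is selected by the Calinski-Harabasz criterion,
CH = [B/(k-1)] / [W/(n-k)], and clusters are relabelled so that cluster 1 is
the "heavy" one (largest mean terminal trajectory value).  Sexes are
clustered separately to accommodate dimorphic growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "TrajectoryMatrix",
    "ClusterAssignment",
    "build_trajectory_matrix",
    "impute_missing",
    "kmeans_trajectories",
    "calinski_harabasz",
    "select_k_and_cluster",
    "TrajectoryKMeans",
]

MIN_MEASURES = 6


@dataclass
class TrajectoryMatrix:
    """Individuals x age-grid matrix of a longitudinal trait (NaN = missing)."""

    ids: list
    ages: np.ndarray
    values: np.ndarray

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{a:g}" for a in self.ages])
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryMatrix":
        df = pd.read_csv(path)
        ages = np.array([float(c) for c in df.columns[1:]])
        return cls(list(df["id"]), ages, df.iloc[:, 1:].to_numpy(dtype=float))


def build_trajectory_matrix(
    measurements: pd.DataFrame,
    trait: str = "bw",
    grid_step: float = 1.0,
    min_measures: int = MIN_MEASURES,
    exclude_pregnant: bool = True,
) -> TrajectoryMatrix:
    """Bin each individual's measures to the nearest grid age (mean per bin).

    Pregnant-flagged visits are excluded; individuals with fewer than
    ``min_measures`` non-missing bins are dropped.
    """
    m = measurements.dropna(subset=["age", trait]).copy()
    if exclude_pregnant and "pregnant" in m.columns:
        m = m[~m["pregnant"].astype(bool)]
    if m.empty:
        raise ValueError("no usable measurements")
    m["bin"] = np.round(m["age"].astype(float) / grid_step).astype(int)
    binned = m.groupby(["id", "bin"])[trait].mean().unstack("bin")
    counts = binned.notna().sum(axis=1)
    binned = binned.loc[counts >= min_measures]
    if binned.empty:
        raise ValueError(f"no individual has >= {min_measures} non-missing bins")
    binned = binned.sort_index()
    ages = binned.columns.to_numpy(dtype=float) * grid_step
    return TrajectoryMatrix(list(binned.index), ages, binned.to_numpy(dtype=float))


def impute_missing(tm: TrajectoryMatrix) -> TrajectoryMatrix:
    """Fill gaps: linear interpolation inside, nearest-value copy at edges."""
    obs = np.isfinite(tm.values).sum(axis=1)
    if np.any(obs < 2):
        bad = [tm.ids[i] for i in np.where(obs < 2)[0]]
        raise ValueError(f"rows with < 2 observed bins cannot be imputed: {bad[:5]}")
    df = pd.DataFrame(tm.values.T)  # interpolate along the age axis
    filled = df.interpolate(method="linear", limit_direction="both", axis=0)
    return TrajectoryMatrix(list(tm.ids), tm.ages.copy(), filled.to_numpy().T)


@dataclass
class ClusterAssignment:
    ids: list
    labels: np.ndarray  # 1..k; cluster 1 = heavy
    k: int
    ch_score: float
    n_starts: int
    seed: int
    inertia: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.labels,
                             "k": self.k, "ch": self.ch_score})


def _relabel_heavy_first(values: np.ndarray, labels0: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters so cluster 1 has the largest mean terminal value."""
    term = values[:, -1]
    means = [term[labels0 == c].mean() for c in range(k)]
    order = np.argsort(means)[::-1]  # heavy first
    remap = {int(old): new + 1 for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in labels0])


def kmeans_trajectories(tm: TrajectoryMatrix, k: int, n_starts: int = 50,
                        seed: int = 0) -> ClusterAssignment:
    """Lloyd k-means on complete trajectory vectors; best of n_starts."""
    if not tm.complete:
        raise ValueError("trajectory matrix must be complete; impute first")
    n = len(tm.ids)
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for {n} rows")
    km = KMeans(n_clusters=k, init="random", n_init=n_starts,
                algorithm="lloyd", random_state=seed)
    labels0 = km.fit_predict(tm.values)
    labels = _relabel_heavy_first(tm.values, labels0, k)
    ch = calinski_harabasz(tm.values, labels)
    return ClusterAssignment(list(tm.ids), labels, k, ch, n_starts, seed,
                             inertia=float(km.inertia_))


def calinski_harabasz(values: np.ndarray | TrajectoryMatrix, labels) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] on flattened trajectory vectors."""
    X = values.values if isinstance(values, TrajectoryMatrix) else np.asarray(values, float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    k, n = len(clusters), X.shape[0]
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if k >= n:
        raise ValueError("k must be < n for the CH criterion")
    grand = X.mean(axis=0)
    B = W = 0.0
    for c in clusters:
        Xc = X[labels == c]
        cent = Xc.mean(axis=0)
        B += len(Xc) * float(np.sum((cent - grand) ** 2))
        W += float(np.sum((Xc - cent) ** 2))
    if W == 0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


def select_k_and_cluster(tm: TrajectoryMatrix, k_range=range(2, 7),
                         n_starts: int = 50, seed: int = 0) -> ClusterAssignment:
    """Cluster at each k in k_range and return the CH-maximising assignment."""
    best = None
    for k in k_range:
        if k >= len(tm.ids):
            continue
        asg = kmeans_trajectories(tm, k, n_starts=n_starts, seed=seed)
        if best is None or asg.ch_score > best.ch_score:
            best = asg
    if best is None:
        raise ValueError("k_range contains no feasible k")
    return best


class TrajectoryKMeans:
    """Model-style wrapper: build -> impute -> select k by CH -> Results.

    Parameters mirror the functional API; ``fit()`` returns the winning
    :class:`ClusterAssignment` along with the per-k CH profile.
    """

    def __init__(self, measurements: pd.DataFrame, trait: str = "bw",
                 grid_step: float = 1.0, min_measures: int = MIN_MEASURES,
                 k_range=range(2, 7), n_starts: int = 50):
        self.tm = impute_missing(
            build_trajectory_matrix(measurements, trait=trait, grid_step=grid_step,
                                    min_measures=min_measures)
        )
        self.k_range = list(k_range)
        self.n_starts = n_starts

    def fit(self, seed: int = 0) -> "TrajectoryKMeansResults":
        profile = {}
        best = None
        for k in self.k_range:
            if k >= len(self.tm.ids):
                continue
            asg = kmeans_trajectories(self.tm, k, n_starts=self.n_starts, seed=seed)
            profile[k] = asg.ch_score
            if best is None or asg.ch_score > best.ch_score:
                best = asg
        if best is None:
            raise ValueError("no feasible k in k_range")
        return TrajectoryKMeansResults(self.tm, best, profile)


@dataclass
class TrajectoryKMeansResults:
    tm: TrajectoryMatrix
    assignment: ClusterAssignment
    ch_profile: dict

    @property
    def k(self) -> int:
        return self.assignment.k

    @property
    def labels(self) -> np.ndarray:
        return self.assignment.labels

    def summary(self) -> str:
        prof = "  ".join(f"k={k}: {v:.1f}" for k, v in sorted(self.ch_profile.items()))
        sizes = pd.Series(self.labels).value_counts().sort_index()
        return (
            f"Trajectory k-means: selected k={self.k} "
            f"(CH={self.assignment.ch_score:.1f})\n"
            f"  CH profile: {prof}\n"
            f"  cluster sizes (1=heavy): {sizes.to_dict()}"
        )
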