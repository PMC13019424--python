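"""Error metrics, composition summaries, and median-linkage clustering.

Two deliberately different dispersion denominators coexist here, both as the
field prints them: the root-mean-square error of calibration / prediction
(RMSEC / RMSEP) divides by n and measures accuracy against reference values,
while the replicate standard deviation divides by n-1 and measures precision
between repeated analyses.  The standard error sd/sqrt(n) scales a per-sample
dispersion to the dispersion expected of an n-sample mean.

Composition summaries follow the reporting convention of fatty-acid tables:
per-acyl mean +/- SD, the total of the five quantified groups, and an
"unknown" remainder 100 - total (negative if predictions over-sum; flagged,
never clipped).

Per-sample composition vectors are clustered by Euclidean-distance-based
median linkage (WPGMC): a merged cluster is represented by the midpoint of
its parents, via the Lance-Williams update on squared distances
d2(k, ij) = d2(k,i)/2 + d2(k,j)/2 - d2(i,j)/4, with merge heights reported as
square roots.  Median linkage can produce height inversions; the tree remains
well formed and is cut by unwinding the k-1 highest remaining merges from the
root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import SPECIES

__all__ = [
    "EvaluationReport",
    "CompositionSummary",
    "LinkageTree",
    "rmse",
    "r_squared",
    "sample_sd",
    "standard_error",
    "composition_summary",
    "hca_median",
    "cut_tree",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Calibration / prediction accuracy of one per-acyl model, in mole %."""

    species: str
    rmsec: float
    rmsep: float
    r2_cal: float
    r2_pred: float
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsep < 0:
            raise ValueError("RMSE values must be >= 0")
        if self.r2_cal > 1 + 1e-12 or self.r2_pred > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def _check_pair(y_hat, y) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_hat, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return a, b


def rmse(y_hat, y) -> float:
    """Root-mean-square error with denominator n (RMSEC / RMSEP role)."""
    a, b = _check_pair(y_hat, y)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(y_hat, y) -> float:
    """1 - SS_res / SS_tot; requires the reference values to vary."""
    a, b = _check_pair(y_hat, y)
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("reference values have zero variance")
    return 1.0 - float(np.sum((a - b) ** 2)) / ss_tot


def sample_sd(values) -> float:
    """Replicate standard deviation with denominator n-1 (precision)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(np.sqrt(np.sum((v - v.mean()) ** 2) / (v.size - 1)))


def standard_error(sd: float, n: int) -> float:
    """Standard error of an n-sample mean: sd / sqrt(n)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sd) / float(np.sqrt(n))


@dataclass(frozen=True)
class CompositionSummary:
    """Per-acyl mean / SD / SE plus the unknown remainder, all in mole %."""

    mean: dict[str, float]
    sd: dict[str, float]
    se: dict[str, float]
    n: int
    total_known: float
    unknown: float
    over_summed: bool

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Table-style view: one row per acyl group plus unknown and total."""
        rows = [
            {"component": sp, "mean": round(self.mean[sp], decimals),
             "sd": round(self.sd[sp], decimals), "se": round(self.se[sp], decimals)}
            for sp in self.mean
        ]
        rows.append({"component": "unknown", "mean": round(self.unknown, decimals),
                     "sd": np.nan, "se": np.nan})
        rows.append({"component": "total_known", "mean": round(self.total_known, decimals),
                     "sd": np.nan, "se": np.nan})
        return pd.DataFrame(rows)


def composition_summary(predictions, species: Sequence[str] = SPECIES,
                        se_n: int | None = None) -> CompositionSummary:
    """Summarise a samples x species prediction table.

    ``se_n`` overrides the n used in the standard error (e.g. the dispersion
    expected of a 30-droplet mean from per-droplet SDs); defaults to the
    number of rows.
    """
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 samples to summarise")
    if P.shape[1] != len(species):
        raise ValueError("prediction width does not match species list")
    n_eff = se_n if se_n is not None else P.shape[0]
    mean = {sp: float(P[:, j].mean()) for j, sp in enumerate(species)}
    sd = {sp: sample_sd(P[:, j]) for j, sp in enumerate(species)}
    se = {sp: standard_error(sd[sp], n_eff) for sp in species}
    total = float(sum(mean.values()))
    return CompositionSummary(
        mean=mean, sd=sd, se=se, n=P.shape[0],
        total_known=total, unknown=100.0 - total, over_summed=total > 100.0,
    )


@dataclass
class LinkageTree:
    """Agglomerative merge history: (cluster_a, cluster_b, height, size).

    Leaves are 0..n-1; the merge at step t creates cluster n+t (the scipy /
    R convention).  Heights are Euclidean and need not be monotone under
    median linkage.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.merges) + 1
        if self.labels and len(self.labels) != n:
            raise ValueError("label count must equal leaf count")
        for a, b, h, size in self.merges:
            if h < 0:
                raise ValueError("merge heights must be >= 0")

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1

    def to_matrix(self) -> np.ndarray:
        """R-style merge matrix: rows (a, b, height, size)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def hca_median(points, labels: Sequence[str] | None = None) -> LinkageTree:
    """Median-linkage (WPGMC) agglomerative clustering on Euclidean distances.

    Works on squared distances with the Lance-Williams median update and
    reports sqrt heights.  Ties are broken by the lowest pair index
    (lexicographic over active-cluster positions).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    if d == 0:
        raise ValueError("points need at least 1 dimension")
    # squared distance matrix among active clusters
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    active = list(range(n))          # cluster ids, 0..n-1 leaves
    sizes = {i: 1 for i in range(n)}
    D = sq.astype(float)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        m = len(active)
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if D[i, j] < best[0]:
                    best = (D[i, j], i, j)
        d2, i, j = best
        a, b = active[i], active[j]
        size = sizes[a] + sizes[b]
        merges.append((a, b, float(np.sqrt(max(d2, 0.0))), size))
        # Lance-Williams median update against all other active clusters
        newrow = 0.5 * D[i, :] + 0.5 * D[j, :] - 0.25 * d2
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newrow[keep]
        D2[:-1, -1] = newrow[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [next_id]
        sizes[next_id] = size
        next_id += 1
    return LinkageTree(merges, list(labels) if labels is not None else [])


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Partition the leaves into k clusters by undoing the top k-1 merges.

    Maintains the current set of subtree roots (initially the final merge) and
    repeatedly splits the root whose merge height is largest, which stays well
    defined even when median-linkage heights invert.  Returns integer labels
    per leaf, numbered by first leaf occurrence.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    children = {n + t: (a, b) for t, (a, b, _, _) in enumerate(tree.merges)}
    heights = {n + t: h for t, (_, _, h, _) in enumerate(tree.merges)}
    roots = [n + len(tree.merges) - 1]
    while len(roots) < k:
        internal = [r for r in roots if r >= n]
        split = max(internal, key=lambda r: (heights[r], r))
        roots.remove(split)
        roots.extend(children[split])

    labels = np.empty(n, dtype=int)
    for ci, r in enumerate(roots):
        stack = [r]
        while stack:
            node = stack.pop()
            if node < n:
                labels[node] = ci
            else:
                stack.extend(children[node])
    # renumber by first occurrence for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def evaluate_predictions(
    species: str,
    y_train_hat, y_train, y_test_hat, y_test,
) -> EvaluationReport:
    """Bundle RMSEC / RMSEP / R^2 for one per-acyl model."""
    return EvaluationReport(
        species=species,
        rmsec=rmse(y_train_hat, y_train),
        rmsep=rmse(y_test_hat, y_test),
        r2_cal=r_squared(y_train_hat, y_train),
        r2_pred=r_squared(y_test_hat, y_test),
        n_train=len(np.asarray(y_train).ravel()),
        n_test=len(np.asarray(y_test).ravel()),
    )
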