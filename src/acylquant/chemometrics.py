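"""Regression backends for spectral unmixing and calibration.

Three routes to composition from a mixture spectrum:

* **CLSR** — classical least squares against the pure-component spectra
  (unconstrained; coefficients may be negative).
* **NNLSR** — the same fit with coefficients constrained >= 0
  (Lawson-Hanson active set via :func:`scipy.optimize.nnls`).
* **PLS1** — NIPALS partial least squares with one response per acyl group;
  needs no pure spectra, only a calibration set, and is the backend the
  TAG-transfer pipeline trains.

Plus the model-selection machinery: k-fold cross-validated latent-variable
choice and greedy forward selection of spectral windows over a fixed
breakpoint partition of the fingerprint region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .spectra import SpectrumSet, WindowSet, extract_windows
from .synth import SPECIES

__all__ = [
    "TABLE_WINDOWS",
    "REGION_BREAKPOINTS",
    "default_region_pool",
    "PureSpectraMatrix",
    "PLSRModel",
    "CVReport",
    "WindowSearchResult",
    "clsr_predict",
    "nnlsr_predict",
    "plsr_fit",
    "plsr_predict",
    "select_n_lv",
    "optimize_windows",
]

#: Published optimized window sets of the five acyl-group PLS models
#: (hi-lo dialect, descending).
TABLE_WINDOWS: dict[str, str] = {
    "MA": "1800-1700,1500-1380,1200-1110,930-650",
    "PA": "1800-1700,1380-1280,1110-800",
    "SA": "1800-1700,1500-1280,1200-650",
    "OA": "1800-1380,1280-930,800-650",
    "LA": "1800-1500,1380-1280,1200-930,800-650",
}

#: Breakpoints of the window-search region partition.
REGION_BREAKPOINTS = (650.0, 800.0, 930.0, 1110.0, 1200.0, 1280.0, 1380.0,
                      1500.0, 1700.0, 1800.0)


def default_region_pool() -> list[tuple[float, float]]:
    """Candidate regions between consecutive breakpoints, descending."""
    bp = REGION_BREAKPOINTS
    return [(bp[i], bp[i + 1]) for i in range(len(bp) - 1)][::-1]


@dataclass
class PureSpectraMatrix:
    """Preprocessed pure-component spectra as columns (channels x components)."""

    components: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.components):
            raise ValueError("matrix must be channels x components")

    @classmethod
    def from_spectra(cls, spectra: dict[str, "np.ndarray"]) -> "PureSpectraMatrix":
        comps = [sp for sp in SPECIES if sp in spectra] or list(spectra)
        cols = []
        for sp in comps:
            v = spectra[sp]
            cols.append(np.asarray(getattr(v, "intensity", v), dtype=float))
        return cls(comps, np.column_stack(cols))


def _as_rows(s) -> np.ndarray:
    x = np.asarray(getattr(s, "intensity", s), dtype=float)
    return np.atleast_2d(x)


def clsr_predict(pures: PureSpectraMatrix, s, percent: bool = False) -> np.ndarray:
    """Unconstrained least-squares unmixing coefficients.

    Solves ``min_c ||K c - s||_2`` with K the pure-spectra matrix.  With
    ``percent=True`` coefficients are scaled x100 to mole % (pure columns are
    unit-fraction spectra).  Returns one coefficient vector per input row;
    a single spectrum yields a 1-D vector.
    """
    K = pures.matrix
    if np.linalg.matrix_rank(K) < K.shape[1]:
        raise np.linalg.LinAlgError("pure-spectra matrix is rank deficient")
    X = _as_rows(s)
    if X.shape[1] != K.shape[0]:
        raise ValueError("spectrum channel count does not match pure spectra")
    C, *_ = np.linalg.lstsq(K, X.T, rcond=None)
    out = C.T * (100.0 if percent else 1.0)
    return out[0] if out.shape[0] == 1 and np.ndim(getattr(s, "intensity", s)) == 1 else out


def nnlsr_predict(pures: PureSpectraMatrix, s, percent: bool = False) -> np.ndarray:
    """Nonnegative least-squares unmixing (Lawson-Hanson active set)."""
    K = pures.matrix
    X = _as_rows(s)
    if X.shape[1] != K.shape[0]:
        raise ValueError("spectrum channel count does not match pure spectra")
    rows = [_scipy_nnls(K, x)[0] for x in X]
    out = np.vstack(rows) * (100.0 if percent else 1.0)
    return out[0] if out.shape[0] == 1 and np.ndim(getattr(s, "intensity", s)) == 1 else out


@dataclass
class PLSRModel:
    """One NIPALS PLS1 calibration model for a single acyl group.

    Prediction is affine: ``y_hat = (x - x_mean) @ coef + y_mean``.
    """

    species: str
    windows: WindowSet | None
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # channels x n_lv (W)
    x_loadings: np.ndarray    # channels x n_lv (P)
    y_loadings: np.ndarray    # n_lv (q)
    n_lv: int
    coef: np.ndarray
    channel_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if self.coef.shape != self.x_mean.shape:
            raise ValueError("coef and x_mean lengths differ")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "windows": self.windows.to_string() if self.windows else None,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "n_lv": self.n_lv,
            "coef": self.coef.tolist(),
            "channel_map": None if self.channel_map is None else self.channel_map.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        n_lv = int(d["n_lv"])
        p = len(d["coef"])
        return cls(
            species=d["species"],
            windows=WindowSet.from_string(d["windows"]) if d["windows"] else None,
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            weights=np.zeros((p, n_lv)),
            x_loadings=np.zeros((p, n_lv)),
            y_loadings=np.zeros(n_lv),
            n_lv=n_lv,
            coef=np.array(d["coef"]),
            channel_map=None if d["channel_map"] is None else np.array(d["channel_map"]),
        )


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    species: str = "",
    windows: WindowSet | None = None,
    channel_map: np.ndarray | None = None,
) -> PLSRModel:
    """Fit a PLS1 model by NIPALS.

    Per component: ``w = X^T y`` normalized, ``t = X w``, ``p = X^T t/(t^T t)``,
    ``q = y^T t/(t^T t)``, then deflate X and y.  The regression vector is
    ``b = W (P^T W)^{-1} q``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X row count and y length differ")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, min(n-1, channels)] = [1, {min(n - 1, p)}]")
    if np.var(y) == 0:
        raise ValueError("degenerate target: y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn == 0:  # y residual fully explained; stop deflating
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_lv = max(a, 1)
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_lv = max(a, 1)
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        species=species, windows=windows, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, n_lv=n_lv, coef=coef,
        channel_map=channel_map,
    )


def plsr_predict(model: PLSRModel, X) -> np.ndarray:
    """Predict mole % for windowed, preprocessed spectra (raw, not clipped)."""
    Xr = _as_rows(X)
    if Xr.shape[1] != model.coef.size:
        raise ValueError(
            f"channel count {Xr.shape[1]} does not match model ({model.coef.size})"
        )
    yhat = (Xr - model.x_mean) @ model.coef + model.y_mean
    return float(yhat[0]) if (np.ndim(getattr(X, "intensity", X)) == 1) else yhat


def _pls_cv_predictions(
    X: np.ndarray, y: np.ndarray, max_lv: int, k_folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold predictions for every LV count 1..max_lv (nested NIPALS fits)."""
    n = len(y)
    if k_folds < 2 or k_folds > n:
        raise ValueError("k_folds must lie in [2, n]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    preds = np.full((max_lv, n), np.nan)
    for hold in folds:
        if hold.size == 0:
            raise ValueError("cross-validation fold with zero samples")
        tr = np.setdiff1d(order, hold)
        cap = min(max_lv, len(tr) - 1, X.shape[1])
        model = plsr_fit(X[tr], y[tr], cap)
        # rebuild per-LV coefficients from the nested NIPALS factors
        W, P, q = model.weights, model.x_loadings, model.y_loadings
        for a in range(1, cap + 1):
            b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            preds[a - 1, hold] = (X[hold] - model.x_mean) @ b + model.y_mean
        for a in range(cap + 1, max_lv + 1):  # fold too small for a factors
            preds[a - 1, hold] = preds[cap - 1, hold]
    return preds


@dataclass
class CVReport:
    """Cross-validated RMSECV per candidate latent-variable count."""

    rmsecv: np.ndarray
    chosen_n_lv: int

    def __post_init__(self) -> None:
        if int(np.argmin(self.rmsecv)) + 1 != self.chosen_n_lv:
            raise ValueError("chosen_n_lv must attain the first minimum of rmsecv")


def select_n_lv(
    X: np.ndarray, y: np.ndarray, max_lv: int, k_folds: int = 10, seed: int = 0
) -> CVReport:
    """Choose the LV count minimizing k-fold RMSECV (smallest count on ties)."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    preds = _pls_cv_predictions(X, y, max_lv, k_folds, seed)
    rmsecv = np.sqrt(np.mean((preds - y) ** 2, axis=1))
    return CVReport(rmsecv=rmsecv, chosen_n_lv=int(np.argmin(rmsecv)) + 1)


@dataclass
class WindowSearchResult:
    """Greedy forward-selection outcome over the candidate region pool."""

    selected: WindowSet
    cv_score: float
    search_trace: list[tuple[str, float]] = field(default_factory=list)


def optimize_windows(
    spectra: SpectrumSet,
    y: np.ndarray,
    region_pool: Sequence[tuple[float, float]] | None = None,
    max_lv: int = 10,
    k_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
) -> WindowSearchResult:
    """Greedy forward selection of spectral windows by cross-validated RMSECV.

    Starting from the empty set, repeatedly add the candidate region whose
    inclusion most lowers the RMSECV of a PLS1 model (LV count itself chosen
    by the same folds); stop when no addition improves by more than ``tol``.
    Ties prefer the higher-wavenumber region.
    """
    pool = list(region_pool) if region_pool is not None else default_region_pool()
    if not pool:
        raise ValueError("empty region pool")
    # sort pool descending by upper edge so tie-breaks are positional
    pool = sorted(pool, key=lambda w: -w[1])
    y = np.asarray(y, dtype=float).ravel()

    def score(regions: list[tuple[float, float]]) -> float:
        X, _ = extract_windows(spectra, WindowSet(list(regions)))
        cap = min(max_lv, len(y) - 1, X.shape[1])
        rep = select_n_lv(X, y, cap, k_folds=k_folds, seed=seed)
        return float(rep.rmsecv[rep.chosen_n_lv - 1])

    selected: list[tuple[float, float]] = []
    remaining = list(pool)
    best_score = np.inf
    trace: list[tuple[str, float]] = []
    while remaining:
        cand_scores = []
        for r in remaining:
            sc = score(selected + [r])
            cand_scores.append(sc)
            trace.append((WindowSet(selected + [r]).to_string(), sc))
        i = int(np.argmin(cand_scores))  # first minimum = highest-wavenumber tie-break
        if best_score - cand_scores[i] <= tol:
            break
        selected.append(remaining.pop(i))
        best_score = cand_scores[i]
    if not selected:  # even the best singleton did not beat +inf: cannot happen
        raise RuntimeError("window search selected no region")
    return WindowSearchResult(
        selected=WindowSet(selected), cv_score=best_score, search_trace=trace
    )
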