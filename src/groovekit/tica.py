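"""Time-lagged independent component analysis, 2D landscapes and
microstate clustering.

The generalized eigenproblem C_TL v = lambda C v is solved by whitening:
the instantaneous covariance C is diagonalized, small eigenvalues are
truncated, and the symmetrized time-lagged covariance is diagonalized in
the whitened basis.  Covariances are accumulated per trajectory over valid
(t, t+tau) pairs only, never across trajectory boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TicaModel",
    "MicrostateModel",
    "fit_tica",
    "project",
    "cluster_microstates",
    "density_landscape",
]


@dataclass(frozen=True)
class TicaModel:
    mean: np.ndarray          # (d,)
    C: np.ndarray             # (d, d) instantaneous covariance
    C_TL: np.ndarray          # (d, d) symmetrized lagged covariance
    tau: int
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # (d, m) columns, C-orthonormal
    n_samples: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tau": self.tau,
            "n_samples": self.n_samples,
            "mean": self.mean.tolist(),
            "C": self.C.tolist(),
            "C_TL": self.C_TL.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TicaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]),
            C=np.array(d["C"]),
            C_TL=np.array(d["C_TL"]),
            tau=int(d["tau"]),
            eigenvalues=np.array(d["eigenvalues"]),
            eigenvectors=np.array(d["eigenvectors"]),
            n_samples=int(d["n_samples"]),
        )


@dataclass(frozen=True)
class MicrostateModel:
    centers: np.ndarray       # (k, m)
    assignments: np.ndarray   # (T,)
    populations: np.ndarray   # (k,), sums to 1
    inertia: float
    seed: int


def _as_trajectory_list(series) -> list[np.ndarray]:
    if isinstance(series, np.ndarray):
        return [np.asarray(series, dtype=float)]
    return [np.asarray(s, dtype=float) for s in series]


def fit_tica(
    series: np.ndarray | Sequence[np.ndarray],
    tau: int,
    *,
    trunc: float = 1e-8,
) -> TicaModel:
    """Fit a tICA model at lag ``tau`` (frames) to one or more trajectories.

    Both covariances are estimated mean-free over the lagged pair set,
    symmetrically in t and t+tau; C_TL is symmetrized before solving so the
    spectrum is real.  Eigenpairs are sorted by descending eigenvalue with a
    deterministic sign convention (largest-magnitude loading positive).
    """
    trajs = _as_trajectory_list(series)
    if tau < 1:
        raise ValueError("tau must be >= 1 frame")
    d = trajs[0].shape[1] if trajs[0].ndim > 1 else 1
    trajs = [t.reshape(len(t), -1) for t in trajs]
    usable = [t for t in trajs if len(t) > tau]
    if not usable:
        raise ValueError(f"no trajectory longer than tau={tau} frames")

    n_pairs = sum(len(t) - tau for t in usable)
    # mean over both members of every valid pair
    mean = np.zeros(d)
    for t in usable:
        mean += t[:-tau].sum(axis=0) + t[tau:].sum(axis=0)
    mean /= 2 * n_pairs

    C = np.zeros((d, d))
    C_TL = np.zeros((d, d))
    for t in usable:
        x0 = t[:-tau] - mean
        x1 = t[tau:] - mean
        C += 0.5 * (x0.T @ x0 + x1.T @ x1)
        C_TL += 0.5 * (x0.T @ x1 + x1.T @ x0)
    C /= n_pairs
    C_TL /= n_pairs

    evals_C, U = np.linalg.eigh(C)
    keep = evals_C > trunc * evals_C.max()
    if not np.any(keep):
        raise ValueError("covariance is rank-deficient after truncation")
    L = U[:, keep] / np.sqrt(evals_C[keep])   # whitening transform, (d, r)
    M = L.T @ C_TL @ L
    lam, W = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = L @ W[:, order]                       # C-orthonormal eigenvectors
    # deterministic sign: largest-|.| loading positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return TicaModel(
        mean=mean, C=C, C_TL=C_TL, tau=tau,
        eigenvalues=lam, eigenvectors=V, n_samples=n_pairs,
    )


def project(model: TicaModel, series: np.ndarray, m: int = 2) -> np.ndarray:
    """Project mean-free features onto the first ``m`` eigenvectors."""
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"series dimension {x.shape[1]} != model dimension "
            f"{model.mean.shape[0]}"
        )
    m = min(m, model.eigenvectors.shape[1])
    return (x - model.mean) @ model.eigenvectors[:, :m]


def cluster_microstates(
    coords: np.ndarray, k: int = 8, seed: int = 0, n_init: int = 10
) -> MicrostateModel:
    """k-means discretization of the projected space (k-means++ init)."""
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(coords) < k:
        raise ValueError(f"need at least k={k} frames, got {len(coords)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(coords)
    populations = np.bincount(assignments, minlength=k) / len(assignments)
    return MicrostateModel(
        centers=km.cluster_centers_,
        assignments=assignments,
        populations=populations,
        inertia=float(km.inertia_),
        seed=seed,
    )


def density_landscape(
    coords: np.ndarray, bins: int | Sequence[int] = 60
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """2D probability histogram and -ln(p) surface (empty bins masked).

    Returns ``(p, neg_log_p, (x_edges, y_edges))``; ``p`` sums to 1 and
    ``neg_log_p`` is a masked array over empty bins.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    H, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins)
    p = H / H.sum()
    neg_log = np.ma.masked_where(p == 0, -np.log(np.where(p > 0, p, 1.0)))
    return p, neg_log, (xe, ye)
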