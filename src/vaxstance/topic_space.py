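"""Interpreting the embedding space: 2-D PCA maps, term coordinates and
per-class density surfaces.

User embedding vectors are projected to two dimensions by PCA fitted on a
chosen user subset (e.g. skeptic users only).  A term used by a set of users
is placed at the mean 2-D coordinate of those users, and per-class Gaussian
kernel densities over the plane expose whether stance classes occupy
separate regions of the embedding space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .node_embedding import EmbeddingMatrix


@dataclass
class PCA2D:
    """Fitted 2-D projection: coords for the fitted subset + reusable axes."""

    coords: pd.DataFrame  # index = user id; columns = x, y
    components: np.ndarray  # (2, dim)
    mean: np.ndarray  # (dim,)
    explained_variance: np.ndarray

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (np.asarray(vectors, dtype=float) - self.mean) @ self.components.T


def pca_2d(embedding: EmbeddingMatrix, subset=None) -> PCA2D:
    """Project a user subset onto its own top-2 principal axes.

    The projection is mean-centered and fitted on the subset only.  For
    determinism each axis's sign is fixed so that its largest-magnitude
    loading is positive.  Raises on fewer than 3 users or rank < 2.
    """
    if subset is None:
        ids = list(embedding.node_ids)
    else:
        ids = [u for u in subset if u in embedding]
    if len(ids) < 3:
        raise ValueError("pca_2d needs at least 3 users with embeddings")
    X = np.stack([embedding.row(u) for u in ids])
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise ValueError("embedding subset is rank-deficient (< 2 nonzero variances)")
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            proj[:, i] = -proj[:, i]
    coords = pd.DataFrame(proj, columns=["x", "y"], index=pd.Index(ids, name="user_id"))
    return PCA2D(
        coords=coords,
        components=comps,
        mean=pca.mean_,
        explained_variance=pca.explained_variance_,
    )


def term_coordinates(term_users: dict, coords: pd.DataFrame) -> pd.DataFrame:
    """Per-term mean coordinate of the users who used the term.

    ``term_users`` maps term -> iterable of user ids; ``coords`` is a
    user-indexed (x, y) frame as produced by :func:`pca_2d`.  Terms whose
    user set is empty (or entirely absent from ``coords``) are skipped with
    a warning.
    """
    rows = []
    for term, users in term_users.items():
        users = [u for u in users if u in coords.index]
        if not users:
            warnings.warn(f"term {term!r} has no users with coordinates; skipped")
            continue
        xy = coords.loc[users, ["x", "y"]].to_numpy(dtype=float)
        rows.append({"term": term, "x": xy[:, 0].mean(), "y": xy[:, 1].mean(),
                     "n_users": len(users)})
    return pd.DataFrame(rows, columns=["term", "x", "y", "n_users"])


@dataclass
class DensitySurface:
    x: np.ndarray  # grid x coordinates (nx,)
    y: np.ndarray  # grid y coordinates (ny,)
    density: np.ndarray  # (ny, nx)

    @property
    def cell_mass(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.density.sum() * dx * dy)


def class_density(
    coords: np.ndarray,
    labels,
    gridsize: int = 100,
    bandwidth: float | str | None = None,
    margin: float = 0.25,
) -> dict[str, DensitySurface]:
    """Gaussian-kernel density of each class over a shared regular grid.

    Bandwidth follows Scott's rule unless ``bandwidth`` overrides it.  The
    grid covers the pooled data extended by ``margin`` of its range on each
    side.  Classes need >= 2 non-degenerate points.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    pad = (hi - lo) * margin
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], gridsize)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], gridsize)
    mx, my = np.meshgrid(gx, gy)
    grid_pts = np.stack([mx.ravel(), my.ravel()])

    out: dict[str, DensitySurface] = {}
    for cls in pd.unique(labels):
        pts = coords[labels == cls]
        if len(pts) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 points")
        if np.allclose(pts.std(axis=0), 0):
            raise ValueError(f"class {cls!r} points are degenerate (identical)")
        try:
            kde = gaussian_kde(pts.T, bw_method=bandwidth)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"class {cls!r} covariance is singular") from exc
        out[str(cls)] = DensitySurface(
            x=gx, y=gy, density=kde(grid_pts).reshape(gridsize, gridsize)
        )
    return out


def separation_statistic(coords: np.ndarray, is_positive) -> float:
    """Centroid distance between two groups over their mean within-group
    RMS spread; > 1 indicates visible separation in the 2-D map."""
    coords = np.asarray(coords, dtype=float)
    mask = np.asarray(is_positive, dtype=bool)
    a, b = coords[mask], coords[~mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    centroid_dist = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    spread = np.mean(
        [
            np.sqrt(np.mean(np.sum((g - g.mean(axis=0)) ** 2, axis=1)))
            for g in (a, b)
        ]
    )
    return centroid_dist / float(spread)
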