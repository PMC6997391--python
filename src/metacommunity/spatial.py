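"""Spatial eigenvector (PCNM) predictors and environmental preprocessing.

PCNM builds multiscale spatial predictors from site coordinates: the
pairwise Euclidean distance matrix is truncated at a neighbourhood threshold
(by default the longest edge of the minimum spanning tree, which keeps the
site network connected), distances beyond the threshold are replaced by four
times the threshold, and the principal coordinates of the result are
extracted.  Eigenvectors with positive eigenvalues describe broad-to-fine
spatial waves along the sampling design and serve as predictors in RDA.

Environmental variables are z-score standardized and pruned of collinearity
by iteratively removing the predictor with the largest variance inflation
factor until all VIFs fall below a threshold (default 3).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, lstsq
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)


@dataclass
class SpatialEigenvectors:
    """Full PCNM eigen-decomposition; only positive-eigenvalue vectors are
    exposed as predictors."""

    eigenvalues: np.ndarray  # descending
    vectors: np.ndarray      # columns aligned with eigenvalues
    threshold: float
    n_positive: int
    site_index: pd.Index | None = None

    @property
    def predictors(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.n_positive)]
        idx = self.site_index if self.site_index is not None else pd.RangeIndex(len(self.vectors))
        return pd.DataFrame(self.vectors[:, : self.n_positive], index=idx, columns=cols)

    def to_csv(self, path) -> None:
        self.predictors.to_csv(path)


def project_lonlat(lon, lat) -> np.ndarray:
    """Equirectangular projection (degrees -> metres at the mean latitude);
    adequate for the few-kilometre extents of single estuaries."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    r_earth = 6_371_000.0
    lat0 = np.deg2rad(lat.mean())
    x = np.deg2rad(lon) * r_earth * np.cos(lat0)
    y = np.deg2rad(lat) * r_earth
    return np.column_stack([x, y])


def pcnm(coords, truncation: float | None = None) -> SpatialEigenvectors:
    """Principal coordinates of the truncated distance matrix.

    ``truncation=None`` uses the longest minimum-spanning-tree edge.
    Coordinates are treated as planar; project lon/lat first if needed.
    """
    if isinstance(coords, pd.DataFrame):
        idx = coords.index
        pts = coords[["x", "y"]].to_numpy(dtype=float)
    else:
        idx = None
        pts = np.asarray(coords, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need at least 3 distinct points")
    d = squareform(pdist(pts))
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst[mst > 0].max())
    if truncation <= 0:
        raise ValueError("truncation threshold must be positive")
    dt = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dt, 0.0)
    a = -0.5 * dt ** 2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    eps = 1e-8 * max(abs(vals[0]), abs(vals[-1]), 1.0)
    n_pos = int((vals > eps).sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues: degenerate configuration")
    return SpatialEigenvectors(vals, vecs, truncation, n_pos, idx)


# ---------------------------------------------------------------------------
# Environmental predictors
# ---------------------------------------------------------------------------

def zscore_standardize(env: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Centre each column to mean 0 and scale to sd 1 (sample sd, n-1)."""
    sd = env.std(ddof=ddof)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    return (env - env.mean()) / sd


@dataclass
class VifReport:
    retained: dict = field(default_factory=dict)  # name -> final VIF
    dropped: list = field(default_factory=list)   # (name, VIF at removal), in order
    threshold: float = 3.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"predictor": k, "vif": v, "status": "retained"}
            for k, v in self.retained.items()
        ] + [
            {"predictor": k, "vif": v, "status": f"dropped_{i + 1}"}
            for i, (k, v) in enumerate(self.dropped)
        ]
        return pd.DataFrame(rows)


def variance_inflation(env: pd.DataFrame) -> pd.Series:
    """VIF_k = 1/(1 - R^2) of predictor k regressed on all others.

    Exact collinearity gives +inf.
    """
    x = env.to_numpy(dtype=float)
    n, p = x.shape
    out = {}
    for k, name in enumerate(env.columns):
        others = np.column_stack([np.ones(n), np.delete(x, k, axis=1)])
        y = x[:, k]
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            out[name] = np.inf
            continue
        coef, *_ = lstsq(others, y)
        ssr = ((y - others @ coef) ** 2).sum()
        r2 = 1.0 - ssr / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(env: pd.DataFrame, threshold: float = 3.0) -> VifReport:
    """Iteratively drop the largest-VIF predictor until all VIFs < threshold.

    Terminates in at most (n_predictors - 1) iterations; the report records
    the removal order and the final VIF of every retained predictor.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    report = VifReport(threshold=threshold)
    current = env.copy()
    while current.shape[1] >= 2:
        vifs = variance_inflation(current)
        worst = vifs.idxmax()
        if vifs[worst] < threshold:
            break
        log.info("VIF prune: dropping %s (VIF = %.3g)", worst, vifs[worst])
        report.dropped.append((worst, float(vifs[worst])))
        current = current.drop(columns=worst)
    final = variance_inflation(current) if current.shape[1] >= 2 else pd.Series(
        {current.columns[0]: 1.0}
    )
    report.retained = {k: float(v) for k, v in final.items()}
    return report
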