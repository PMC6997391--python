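"""Reciprocal averaging (correspondence analysis) for incidence matrices.

Only the first non-trivial CA axis is used: sites and taxa are reordered by
their first-axis scores, which recovers the latent gradient when one
dominates the data.  All structure metrics downstream are computed on this
ordinated matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd


class DegenerateOrdinationError(ValueError):
    """Matrix of rank < 2 (e.g. all rows identical): no gradient to recover."""


def ca_first_axis(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First non-trivial CA axis scores for rows and columns.

    Computed by SVD of the chi-square standardized correspondence matrix
    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}.  Row/column principal scores are
    the leading singular vectors rescaled by the weights.  The axis is
    oriented so its correlation with the input row order is non-negative
    (pure reporting convention: every metric downstream is invariant to it).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or min(m.shape) < 2:
        raise DegenerateOrdinationError("need at least a 2x2 matrix")
    if (m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any():
        raise ValueError("drop all-zero rows/columns before ordination")
    total = m.sum()
    p = m / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sing, vt = svd(s, full_matrices=False)
    if sing[0] <= 1e-10:
        raise DegenerateOrdinationError("degenerate ordination: matrix rank < 2")
    row = u[:, 0] / np.sqrt(r) * sing[0]
    col = vt[0] / np.sqrt(c) * sing[0]
    n = len(row)
    idx = np.arange(n) - (n - 1) / 2
    if float(row @ idx) < 0:
        row, col = -row, -col
    return row, col


@dataclass
class OrdinatedMatrix:
    """Incidence matrix reordered along the first CA axis.

    ``matrix`` equals the input indexed by ``row_order`` then ``col_order``;
    scores are stored in the reordered (ascending) order.
    """

    matrix: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    row_scores: np.ndarray
    col_scores: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    @property
    def shape(self):
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        idx = self.row_labels if self.row_labels is not None else np.arange(len(self.row_order))
        cols = self.col_labels if self.col_labels is not None else np.arange(len(self.col_order))
        return pd.DataFrame(self.matrix, index=pd.Index(idx, name="sample"), columns=cols)

    def to_csv(self, path) -> None:
        """Sites as rows in ordination order (presence/absence plot export)."""
        self.to_frame().to_csv(path)


def correspondence_ordination(inc) -> OrdinatedMatrix:
    """Ordinate an incidence matrix by its first CA axis.

    Ties in scores are broken by original index order (stable sort), so the
    result is deterministic.  Scores are invariant (up to sign) under
    row/column shuffling of the input.
    """
    if hasattr(inc, "values"):
        arr = np.asarray(inc.values)
        row_labels = ["/".join(map(str, k)) for k in inc.sample_keys] if hasattr(inc, "sample_keys") else None
        col_labels = list(inc.taxa) if hasattr(inc, "taxa") else None
    else:
        arr = np.asarray(inc)
        row_labels = col_labels = None
    rscore, cscore = ca_first_axis(arr)
    ro = np.argsort(rscore, kind="stable")
    co = np.argsort(cscore, kind="stable")
    return OrdinatedMatrix(
        matrix=np.ascontiguousarray(arr[ro][:, co].astype(np.int8)),
        row_order=ro,
        col_order=co,
        row_scores=rscore[ro],
        col_scores=cscore[co],
        row_labels=[row_labels[i] for i in ro] if row_labels else None,
        col_labels=[col_labels[i] for i in co] if col_labels else None,
    )
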