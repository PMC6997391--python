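"""Hellinger transformation, (partial) RDA and three-way variation partitioning.

Redundancy analysis is multivariate multiple regression of a (Hellinger-
transformed) community matrix on a predictor set; its R^2 is the fraction of
total community variance captured by the fitted values, adjusted with the
Ezekiel formula adj R^2 = 1 - (1 - R^2)(n - 1)/(n - m - 1).  Partial RDA
residualizes both community and predictors on a conditioning set first.
Permutation tests use the Freedman-Lane scheme: rows of the conditioned
community residuals are permuted and the pseudo-F recomputed.

Variation among three predictor sets — environment (E), space (S) and time
(T, sampling-occasion dummies) — is partitioned into pure, pairwise-shared
and triple-shared adjusted-R^2 fractions by inclusion-exclusion over the
seven set unions; the eight fractions (with the residual) sum to one by
construction.  Pure fractions are testable by partial RDA; shared ones are
not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq

log = logging.getLogger(__name__)

FRACTION_NAMES = (
    "env", "spa", "time",
    "env_spa", "env_time", "spa_time", "env_spa_time", "residual",
)


def hellinger(ab) -> pd.DataFrame | np.ndarray:
    """Square root of site-relative abundances: y'_ij = sqrt(y_ij / y_i.).

    Every transformed row has unit sum of squares; a zero-sum row is an
    error naming the site.
    """
    df = None
    if isinstance(ab, pd.DataFrame):
        df = ab.astype(float)
    elif hasattr(ab, "data") and isinstance(ab.data, pd.DataFrame):
        df = ab.data.astype(float)
    if df is not None:
        sums = df.sum(axis=1)
        if (sums == 0).any():
            bad = sums.index[sums == 0][0]
            raise ValueError(f"zero-sum site {bad!r}: Hellinger undefined")
        return np.sqrt(df.div(sums, axis=0))
    arr = np.asarray(ab, dtype=float)
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        raise ValueError(f"zero-sum site at row {int(np.argmax(sums == 0))}")
    return np.sqrt(arr / sums[:, None])


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment; may be negative for weak models."""
    if n - m - 1 <= 0:
        raise ValueError("need n > m + 1 for the adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class RDAResults:
    r2: float
    adj_r2: float
    n: int
    m: int
    q: int = 0               # conditioning rank
    perm_p: float | None = None
    pseudo_f: float | None = None
    n_perm: int = 0

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  n = {self.n} sites, m = {self.m} predictors"
            + (f", {self.q} conditioned" if self.q else ""),
            f"  R2 = {self.r2:.4f}   adj R2 = {self.adj_r2:.4f}",
        ]
        if self.perm_p is not None:
            lines.append(
                f"  pseudo-F = {self.pseudo_f:.3f}   P = {self.perm_p:.4f}"
                f"  ({self.n_perm} permutations)"
            )
        return "\n".join(lines)


def _as_matrix(x) -> np.ndarray:
    if x is None:
        return None
    arr = x.to_numpy(dtype=float) if isinstance(x, (pd.DataFrame, pd.Series)) else np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _residualize(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    ones = np.ones((len(y), 1))
    design = np.column_stack([ones, w]) if w is not None else ones
    coef, *_ = lstsq(design, y)
    return y - design @ coef


class RDA:
    """Model-style RDA: ``RDA(Y, X, condition=W).fit(n_perm=999, seed=...)``.

    Y is the (transformed) community matrix; X the predictors; W an optional
    conditioning set (partial RDA).  ``fit`` raises on a singular predictor
    matrix; with ``n_perm=0`` no permutation p is computed.
    """

    def __init__(self, Y, X, condition=None):
        self.Y = _as_matrix(Y)
        self.X = _as_matrix(X)
        self.W = _as_matrix(condition)
        n = len(self.Y)
        if len(self.X) != n or (self.W is not None and len(self.W) != n):
            raise ValueError("Y, X and condition must have equal row counts")
        self.n = n
        self.m = self.X.shape[1]
        self.q = 0 if self.W is None else int(np.linalg.matrix_rank(
            self.W - self.W.mean(axis=0)))
        if np.linalg.matrix_rank(self.X) < self.m:
            raise np.linalg.LinAlgError("singular predictor matrix")
        if n <= self.m + self.q + 1:
            raise ValueError("need n > m + conditioning rank + 1")

    def fit(self, n_perm: int = 0, seed=None) -> RDAResults:
        yr = _residualize(self.Y, self.W)
        xr = _residualize(self.X, self.W)
        stat, r2 = self._stat(yr, xr)
        adj = adjusted_r2(r2, self.n, self.m) if self.W is None else np.nan
        perm_p = None
        if n_perm:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(self.n)
                s, _ = self._stat(yr[perm], xr)
                if s >= stat:
                    count += 1
            perm_p = (count + 1) / (n_perm + 1)
        return RDAResults(r2, adj, self.n, self.m, self.q, perm_p, stat, n_perm)

    def _stat(self, yr: np.ndarray, xr: np.ndarray) -> tuple[float, float]:
        coef, *_ = lstsq(xr, yr)
        fitted = xr @ coef
        ss_fit = float((fitted ** 2).sum())
        ss_tot = float((yr ** 2).sum())
        r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
        dof = self.n - self.m - self.q - 1
        f = (ss_fit / self.m) / ((ss_tot - ss_fit) / dof) if dof > 0 else np.inf
        return f, r2


def rda_fit(Y, X, condition=None, n_perm: int = 0, seed=None) -> RDAResults:
    """Functional wrapper: fit an (optionally partial) RDA in one call."""
    return RDA(Y, X, condition).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Forward selection with the double-stopping criterion
# ---------------------------------------------------------------------------

@dataclass
class ForwardSelectionResult:
    selected: list = field(default_factory=list)  # (name, cumulative adj R2, step p)
    global_adj_r2: float = np.nan
    global_p: float | None = None
    alpha: float = 0.05
    reason: str = ""

    @property
    def names(self) -> list:
        return [s[0] for s in self.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.selected, columns=["predictor", "cum_adj_r2", "p"]
        ).assign(global_adj_r2=self.global_adj_r2)


def forward_select(Y, X: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 199, seed=None) -> ForwardSelectionResult:
    """Greedy forward selection gated by a global test and double-stopping.

    The full model must be permutation-significant at ``alpha`` first.  At
    each step the candidate adding the most explained variance is admitted
    only if its conditional permutation p < alpha AND the cumulative adjusted
    R^2 stays at or below the full-model adjusted R^2; selection stops when
    either criterion fails.  Each column (e.g. each spatial eigenvector)
    counts as one predictor.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    rng = np.random.default_rng(seed)
    glob = RDA(Y, X).fit(n_perm=n_perm, seed=rng.integers(2 ** 31))
    if glob.perm_p is None or glob.perm_p >= alpha:
        return ForwardSelectionResult([], glob.adj_r2, glob.perm_p, alpha,
                                      reason="global test non-significant")
    selected: list = []
    remaining = list(X.columns)
    result = ForwardSelectionResult([], glob.adj_r2, glob.perm_p, alpha)
    while remaining:
        best, best_r2 = None, -np.inf
        for cand in remaining:
            cols = [s[0] for s in selected] + [cand]
            try:
                fit = RDA(Y, X[cols]).fit()
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit.r2 > best_r2:
                best, best_r2, best_adj = cand, fit.r2, fit.adj_r2
        if best is None:
            result.reason = "no admissible candidate"
            break
        if best_adj > glob.adj_r2 + 1e-12:
            result.reason = "adjusted R2 bound reached"
            break
        cond = X[[s[0] for s in selected]] if selected else None
        step = RDA(Y, X[[best]], condition=cond).fit(
            n_perm=n_perm, seed=rng.integers(2 ** 31))
        if step.perm_p >= alpha:
            result.reason = "candidate non-significant"
            break
        selected.append((best, float(best_adj), float(step.perm_p)))
        remaining.remove(best)
    result.selected = selected
    if not result.reason:
        result.reason = "all predictors selected"
    return result


# ---------------------------------------------------------------------------
# Three-way variation partitioning
# ---------------------------------------------------------------------------

def time_dummies(periods) -> pd.DataFrame:
    """One-hot encode sampling occasions, dropping the first level."""
    s = pd.Series(periods, name="period").astype(str)
    d = pd.get_dummies(s, prefix="period", drop_first=True).astype(float)
    d.index = s.index
    return d


@dataclass
class VarPartResults:
    """Adjusted-R^2 fractions of community variation for E, S and T.

    Negative fractions are reported as computed (preserving the
    inclusion-exclusion identity); consumers may floor at zero for display.
    """

    fractions: pd.Series
    pure_p: dict
    n: int
    set_sizes: dict
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Variation partitioning (adjusted R2)",
            "=" * 44,
            f"n = {self.n} rows; predictors: "
            + ", ".join(f"{k}={v}" for k, v in self.set_sizes.items()),
            "-" * 44,
        ]
        pretty = {
            "env": "Pure environment [a]",
            "spa": "Pure space       [b]",
            "time": "Pure time        [c]",
            "env_spa": "Env & Spa shared",
            "env_time": "Env & Time shared",
            "spa_time": "Spa & Time shared",
            "env_spa_time": "Triple shared",
            "residual": "Residual",
        }
        for name in FRACTION_NAMES:
            p = self.pure_p.get(name)
            tail = f"   P = {p:.4f}" if p is not None else ""
            lines.append(f"{pretty[name]:22}{self.fractions[name]:>9.4f}{tail}")
        lines.append("-" * 44)
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions.index,
                "adj_r2": self.fractions.values,
                "p": [self.pure_p.get(k) for k in self.fractions.index],
            }
        )


class VariationPartitioning:
    """Model-style three-set partition: ``VariationPartitioning(Y, E, S, T)``.

    Empty sets (None or zero columns) are allowed: every fraction involving
    an empty set is fixed at 0 and noted in the results.
    """

    def __init__(self, Y, env=None, spa=None, time=None):
        self.Y = _as_matrix(Y)
        self.sets = {"env": _as_matrix(env), "spa": _as_matrix(spa),
                     "time": _as_matrix(time)}
        for k, v in self.sets.items():
            if v is not None and v.shape[1] == 0:
                self.sets[k] = None

    def _adj(self, keys: tuple) -> float:
        mats = [self.sets[k] for k in keys if self.sets[k] is not None]
        if not mats:
            return 0.0
        x = np.column_stack(mats)
        # collapse exact duplicates of columns to keep the union full rank
        x = _drop_dependent_columns(x)
        return RDA(self.Y, x).fit().adj_r2

    def fit(self, n_perm: int = 999, seed=None) -> VarPartResults:
        rng = np.random.default_rng(seed)
        a_e = self._adj(("env",))
        a_s = self._adj(("spa",))
        a_t = self._adj(("time",))
        a_es = self._adj(("env", "spa"))
        a_et = self._adj(("env", "time"))
        a_st = self._adj(("spa", "time"))
        a_est = self._adj(("env", "spa", "time"))
        pure_e = a_est - a_st
        pure_s = a_est - a_et
        pure_t = a_est - a_es
        g = a_e + a_s + a_t - a_es - a_et - a_st + a_est
        d = (a_e + a_s - a_es) - g   # env & spa only
        e = (a_e + a_t - a_et) - g   # env & time only
        f = (a_s + a_t - a_st) - g   # spa & time only
        fractions = pd.Series(
            {
                "env": pure_e, "spa": pure_s, "time": pure_t,
                "env_spa": d, "env_time": e, "spa_time": f,
                "env_spa_time": g, "residual": 1.0 - a_est,
            }
        )
        notes = [f"{k} set empty: its fractions fixed at 0"
                 for k, v in self.sets.items() if v is None]
        if (fractions.drop("residual") < 0).any():
            notes.append("negative fractions reported as computed (not truncated)")
        pure_p = {}
        for key in ("env", "spa", "time"):
            if self.sets[key] is None:
                continue
            others = [v for k, v in self.sets.items() if k != key and v is not None]
            cond = _drop_dependent_columns(np.column_stack(others)) if others else None
            try:
                res = RDA(self.Y, self.sets[key], condition=cond).fit(
                    n_perm=n_perm, seed=rng.integers(2 ** 31))
                pure_p[key] = res.perm_p
            except np.linalg.LinAlgError:
                notes.append(f"pure {key} untestable: rank-deficient after conditioning")
        sizes = {k: (0 if v is None else v.shape[1]) for k, v in self.sets.items()}
        return VarPartResults(fractions, pure_p, len(self.Y), sizes, notes)


def _drop_dependent_columns(x: np.ndarray) -> np.ndarray:
    """Keep a maximal linearly independent subset of columns (after centring),
    preserving order; protects unions of overlapping predictor sets."""
    xc = x - x.mean(axis=0)
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = xc[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < x.shape[1]:
        log.info("dropped %d linearly dependent columns from predictor union",
                 x.shape[1] - len(keep))
    return x[:, keep]


def variation_partition(Y, env=None, spa=None, time=None,
                        n_perm: int = 999, seed=None) -> VarPartResults:
    """Functional wrapper around :class:`VariationPartitioning`."""
    return VariationPartitioning(Y, env, spa, time).fit(n_perm=n_perm, seed=seed)
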