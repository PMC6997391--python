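"""Elements of metacommunity structure: coherence, turnover, boundary clumping.

The three elements are evaluated hierarchically on the CA-ordinated incidence
matrix:

* coherence — embedded absences (gaps inside species ranges / site
  compositions) against a fixed-row, proportional-column (r1) null in which
  every simulated matrix is independently re-ordinated;
* turnover — species replacements between site pairs on the range-filled
  matrix, against a null that shifts entire ranges to uniform positions;
* boundary clumping — Morisita's index of range-endpoint aggregation with a
  chi-square goodness-of-fit test.

A decision tree over the three results assigns one of the six idealized
structures (checkerboard, random, nested, evenly spaced, Gleasonian,
Clementsian), the nested species-loss subtype, and the quasi- variants that
arise when coherence is significant but turnover is not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import (
    DegenerateOrdinationError,
    OrdinatedMatrix,
    correspondence_ordination,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class NullModelConfig:
    """Settings for the randomization tests.

    ``fixed_proportional_r1`` keeps each site's richness fixed and draws
    species with probability proportional to their observed frequency;
    ``range_shift`` places each species' contiguous range uniformly among its
    feasible positions.
    """

    method: str = "fixed_proportional_r1"
    iterations: int = 1000
    seed: int | None = None
    allow_empty: bool = False

    def __post_init__(self):
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        if self.method not in ("fixed_proportional_r1", "range_shift"):
            raise ValueError(f"unknown null model {self.method!r}")


@dataclass
class NullSummary:
    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    p: float
    n_iterations: int = 0
    n_skipped: int = 0
    degenerate: bool = False  # sim_sd == 0: p undefined

    @classmethod
    def from_simulations(cls, observed, sims, n_skipped=0, empirical_p=False):
        sims = np.asarray(sims, dtype=float)
        mean = float(sims.mean())
        sd = float(sims.std(ddof=1)) if len(sims) > 1 else 0.0
        if sd == 0:
            log.warning("null distribution degenerate (sd = 0); p undefined")
            return cls(float(observed), mean, 0.0, np.nan, np.nan,
                       len(sims), n_skipped, degenerate=True)
        z = (float(observed) - mean) / sd
        if empirical_p:
            tail = min((sims <= observed).mean(), (sims >= observed).mean())
            p = min(1.0, 2 * (tail * len(sims) + 1) / (len(sims) + 1))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        return cls(float(observed), mean, sd, z, p, len(sims), n_skipped)


@dataclass
class ClumpingResult:
    morisita_index: float
    chi2: float
    p: float
    df: int
    n_positions: int = 0
    n_boundaries: int = 0


@dataclass
class StructureLabel:
    family: str  # checkerboard | random | nested | evenly_spaced | gleasonian | clementsian
    quasi: bool = False
    nested_loss: str = "not_applicable"  # clumped | random | hyperdispersed

    def __post_init__(self):
        if (self.nested_loss != "not_applicable") != (self.family == "nested"):
            raise ValueError("nested_loss applies iff family == 'nested'")

    def __str__(self):
        names = {
            "checkerboard": "Checkerboard",
            "random": "Random",
            "nested": "Nested",
            "evenly_spaced": "Evenly spaced",
            "gleasonian": "Gleasonian",
            "clementsian": "Clementsian",
        }
        out = names[self.family]
        if self.family == "nested":
            out += f" ({self.nested_loss} species loss)"
        if self.quasi:
            out = "Quasi-" + out[0].lower() + out[1:]
        return out


@dataclass
class EMSResult:
    """Fitted elements of metacommunity structure for one incidence matrix."""

    coherence: NullSummary
    turnover: NullSummary
    clumping: ClumpingResult
    label: StructureLabel
    alpha: float = 0.05
    n_sites: int = 0
    n_species: int = 0
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        c, t, m = self.coherence, self.turnover, self.clumping
        lines = [
            "Elements of Metacommunity Structure",
            "=" * 51,
            f"Matrix: {self.n_sites} sites x {self.n_species} species   alpha = {self.alpha}",
            "-" * 51,
            f"{'':14}{'observed':>10}{'null mean':>11}{'z':>8}{'p':>8}",
            f"{'Coherence':14}{c.observed:>10.0f}{c.sim_mean:>11.1f}{c.z:>8.2f}{c.p:>8.4f}",
            f"{'Turnover':14}{t.observed:>10.0f}{t.sim_mean:>11.1f}{t.z:>8.2f}{t.p:>8.4f}",
            f"{'Clumping I':14}{m.morisita_index:>10.2f}{'':>11}{m.chi2:>8.2f}{m.p:>8.4f}",
            "-" * 51,
            f"Structure: {self.label}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def _ranges(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(first, last, occupied) indices of the 1-run hull of each column."""
    occ = m.any(axis=0)
    idx = np.arange(m.shape[0])[:, None]
    first = np.where(occ, np.where(m > 0, idx, m.shape[0]).min(axis=0), -1)
    last = np.where(occ, np.where(m > 0, idx, -1).max(axis=0), -1)
    return first, last, occ


def count_embedded_absences(om, axis: str = "both") -> int:
    """Zeros strictly inside species ranges (columns) and, when
    ``axis='both'``, inside site compositions (rows) of the ordinated matrix."""
    m = om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    first, last, occ = _ranges(m)
    span = np.where(occ, last - first + 1, 0)
    total = int((span - m.sum(axis=0)).sum())
    if axis == "both":
        firstr, lastr, occr = _ranges(m.T)
        spanr = np.where(occr, lastr - firstr + 1, 0)
        total += int((spanr - m.sum(axis=1)).sum())
    elif axis != "columns":
        raise ValueError("axis must be 'both' or 'columns'")
    return total


def fill_ranges(om) -> np.ndarray:
    """Impute embedded absences: set every cell inside each species' range
    (column direction) to 1 — the 'range perspective' used for turnover."""
    m = (om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)).copy()
    first, last, occ = _ranges(m)
    idx = np.arange(m.shape[0])[:, None]
    inside = (idx >= first[None, :]) & (idx <= last[None, :]) & occ[None, :]
    m[inside] = 1
    return m.astype(np.int8)


def count_replacements(filled: np.ndarray) -> int:
    """Species replacements: over all unordered species pairs and site pairs,
    instances where one species is present at one site and absent at the
    other while the second species shows the opposite pattern.

    For a species pair the count is |sites with A only| x |sites with B only|.
    """
    m = np.asarray(filled, dtype=np.int64)
    n1 = m.sum(axis=0)
    shared = m.T @ m
    a10 = n1[:, None] - shared
    a01 = n1[None, :] - shared
    return int((a10 * a01).sum() // 2)


def species_range_lengths(filled: np.ndarray) -> np.ndarray:
    first, last, occ = _ranges(np.asarray(filled))
    return np.where(occ, last - first + 1, 0)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def r1_null_matrix(row_sums: np.ndarray, col_weights: np.ndarray, rng) -> np.ndarray:
    """One fixed-row, proportional-column (r1) random matrix.

    Each row receives its observed richness of presences, species drawn
    without replacement with probability proportional to the observed column
    totals (exponential-race weighted sampling, vectorized over rows).
    """
    r, c = len(row_sums), len(col_weights)
    keys = rng.exponential(size=(r, c)) / col_weights
    rank = np.argsort(np.argsort(keys, axis=1), axis=1)
    return (rank < row_sums[:, None]).astype(np.int8)


def simulate_coherence_null(inc, cfg: NullModelConfig, axis: str = "both",
                            rng=None, empirical_p: bool = False) -> NullSummary:
    """Coherence test: observed embedded absences vs the r1 null.

    Every simulated matrix is independently re-ordinated before counting.
    Simulated matrices with empty columns have those columns dropped; draws
    whose ordination is degenerate are retried once, then skipped (logged).
    """
    if cfg.method != "fixed_proportional_r1":
        raise ValueError("coherence null must be fixed_proportional_r1")
    arr = np.asarray(inc.values if hasattr(inc, "values") else inc)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    om = correspondence_ordination(arr)
    observed = count_embedded_absences(om, axis=axis)
    row_sums = arr.sum(axis=1)
    w = arr.sum(axis=0).astype(float)
    w = w / w.sum()
    sims, skipped = [], 0
    for _ in range(cfg.iterations):
        val = None
        for _attempt in range(2):
            sim = r1_null_matrix(row_sums, w, rng)
            keep = sim.sum(axis=0) > 0
            if not cfg.allow_empty:
                sim = sim[:, keep]
            try:
                som = correspondence_ordination(sim)
            except DegenerateOrdinationError:
                continue
            val = count_embedded_absences(som, axis=axis)
            break
        if val is None:
            skipped += 1
        else:
            sims.append(val)
    if skipped:
        log.info("coherence null: skipped %d degenerate draws", skipped)
    return NullSummary.from_simulations(observed, sims, skipped, empirical_p)


def _replacements_from_ranges(starts, lengths) -> int:
    ends = starts + lengths - 1
    shared = np.clip(
        np.minimum(ends[:, None], ends[None, :])
        - np.maximum(starts[:, None], starts[None, :])
        + 1,
        0,
        None,
    )
    a10 = lengths[:, None] - shared
    a01 = lengths[None, :] - shared
    return int((a10 * a01).sum() // 2)


def simulate_turnover_null(filled, cfg: NullModelConfig, rng=None,
                           empirical_p: bool = False) -> NullSummary:
    """Turnover test: observed replacements vs the range-shift null.

    Each species' contiguous range of length L is placed uniformly among the
    (n_sites - L + 1) positions, independently across species, no wrap-around.
    Species occupying every site contribute no randomness.
    """
    if cfg.method != "range_shift":
        raise ValueError("turnover null must be range_shift")
    m = np.asarray(filled)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = m.shape[0]
    lengths = species_range_lengths(m)
    lengths = lengths[lengths > 0]
    observed = count_replacements(m)
    if (lengths == n).all():
        log.warning("all species occupy every site: turnover null is degenerate")
    sims = np.empty(cfg.iterations)
    slots = n - lengths + 1
    for i in range(cfg.iterations):
        starts = (rng.random(len(lengths)) * slots).astype(np.int64)
        sims[i] = _replacements_from_ranges(starts, lengths)
    return NullSummary.from_simulations(observed, sims, 0, empirical_p)


# ---------------------------------------------------------------------------
# Boundary clumping
# ---------------------------------------------------------------------------

def morisita_index(f: np.ndarray) -> float:
    """Morisita's index of dispersion over boundary counts per site position:
    I = n * sum f(f-1) / (F(F-1)).  1 = random, >1 clumped, <1 even."""
    f = np.asarray(f, dtype=float)
    n = len(f)
    big_f = f.sum()
    if big_f < 2:
        raise ValueError("need at least 2 boundaries")
    return float(n * (f * (f - 1)).sum() / (big_f * (big_f - 1)))


def boundary_counts(om, include_edges: bool = False) -> np.ndarray:
    """Range-endpoint counts per ordinated site position.

    By default endpoints lying on the first/last site are censored: a range
    reaching the matrix edge has no observable boundary there (its true
    endpoint may lie beyond the sampled gradient).  ``include_edges=True``
    counts every start and end.
    """
    m = om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    n = m.shape[0]
    first, last, occ = _ranges(m)
    f = np.zeros(n, dtype=np.int64)
    for a, b, o in zip(first, last, occ):
        if not o:
            continue
        if include_edges or a > 0:
            f[a] += 1
        if include_edges or b < n - 1:
            f[b] += 1
    return f


def boundary_clumping(om, include_edges: bool = False) -> ClumpingResult:
    """Morisita's index on range boundaries plus a chi-square goodness-of-fit
    test against a uniform distribution over site positions (df = n - 1).

    The chi-square tail matches the direction of the index: upper tail for
    I >= 1 (clumping), lower tail for I < 1 (evenness).
    """
    m = om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 species")
    f = boundary_counts(om, include_edges=include_edges)
    if not include_edges:
        # censored endpoints can only fall on interior positions; the uniform
        # reference must live on the same support
        f = f[1:-1]
    n = len(f)
    big_f = f.sum()
    if big_f < 2:
        raise ValueError("fewer than 2 range boundaries")
    i_mor = morisita_index(f)
    expected = big_f / n
    chi2 = float(((f - expected) ** 2 / expected).sum())
    df = n - 1
    p = float(stats.chi2.sf(chi2, df) if i_mor >= 1 else stats.chi2.cdf(chi2, df))
    return ClumpingResult(i_mor, chi2, p, df, n, int(big_f))


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

def _clump_branch(clump: ClumpingResult, alpha: float, quasi: bool) -> StructureLabel:
    """Three-way branch on the clumping result for positive turnover."""
    significant = clump.p < alpha
    if significant and clump.morisita_index > 1:
        return StructureLabel("clementsian", quasi=quasi)
    if significant and clump.morisita_index < 1:
        return StructureLabel("evenly_spaced", quasi=quasi)
    return StructureLabel("gleasonian", quasi=quasi)


def _nested_label(clump: ClumpingResult, alpha: float, quasi: bool) -> StructureLabel:
    significant = clump.p < alpha
    if significant and clump.morisita_index > 1:
        loss = "clumped"
    elif significant and clump.morisita_index < 1:
        loss = "hyperdispersed"
    else:
        loss = "random"
    return StructureLabel("nested", quasi=quasi, nested_loss=loss)


def classify(coh: NullSummary, tur: NullSummary, clump: ClumpingResult,
             alpha: float = 0.05) -> StructureLabel:
    """Assign the metacommunity structure from the three elements.

    Coherence: significantly negative (more gaps than the null) ->
    checkerboard; non-significant -> random; significantly positive ->
    branch on turnover.  Significant negative turnover -> nested (loss
    subtype from clumping); significant positive -> Clementsian / Gleasonian
    / evenly spaced by clumping.  Non-significant turnover -> the same
    branches by the sign of the deviation, flagged quasi-.
    """
    if np.isnan(coh.p):
        raise ValueError("coherence null summary undefined (sd = 0)")
    if coh.p >= alpha:
        return StructureLabel("random")
    if coh.observed > coh.sim_mean:
        return StructureLabel("checkerboard")
    # positive coherence: fewer embedded absences than expected
    tur_sig = (not np.isnan(tur.p)) and tur.p < alpha
    negative_turnover = tur.observed < tur.sim_mean
    if tur_sig:
        if negative_turnover:
            return _nested_label(clump, alpha, quasi=False)
        return _clump_branch(clump, alpha, quasi=False)
    if negative_turnover:
        return _nested_label(clump, alpha, quasi=True)
    return _clump_branch(clump, alpha, quasi=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def ems_analysis(inc, cfg: NullModelConfig | None = None, alpha: float = 0.05,
                 axis: str = "both", include_edges: bool = False,
                 empirical_p: bool = False) -> EMSResult:
    """Full EMS workflow on one incidence matrix.

    Drops empty rows/columns, ordinates, runs the coherence and turnover
    nulls and the clumping test, and applies the decision tree.  Fully
    determined by ``cfg.seed``.
    """
    if cfg is None:
        cfg = NullModelConfig()
    arr = np.asarray(inc.values if hasattr(inc, "values") else inc)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateOrdinationError("matrix degenerate after dropping empties")
    rng = np.random.default_rng(cfg.seed)
    coh_cfg = NullModelConfig("fixed_proportional_r1", cfg.iterations,
                              allow_empty=cfg.allow_empty)
    coh = simulate_coherence_null(arr, coh_cfg, axis=axis, rng=rng,
                                  empirical_p=empirical_p)
    om = correspondence_ordination(arr)
    filled = fill_ranges(om)
    tur_cfg = NullModelConfig("range_shift", cfg.iterations)
    tur = simulate_turnover_null(filled, tur_cfg, rng=rng, empirical_p=empirical_p)
    clump = boundary_clumping(om, include_edges=include_edges)
    label = classify(coh, tur, clump, alpha=alpha)
    return EMSResult(coh, tur, clump, label, alpha,
                     n_sites=arr.shape[0], n_species=arr.shape[1])


class EMS:
    """Model-style interface: ``EMS(incidence).fit(seed=...)`` -> EMSResult.

    Parameters mirror :func:`ems_analysis`; ``fit`` accepts the seed so the
    same model object can be refit reproducibly.
    """

    def __init__(self, incidence, iterations: int = 1000, alpha: float = 0.05,
                 axis: str = "both", include_edges: bool = False):
        self.incidence = incidence
        self.iterations = iterations
        self.alpha = alpha
        self.axis = axis
        self.include_edges = include_edges

    def fit(self, seed: int | None = None) -> EMSResult:
        cfg = NullModelConfig(iterations=self.iterations, seed=seed)
        return ems_analysis(self.incidence, cfg, alpha=self.alpha,
                            axis=self.axis, include_edges=self.include_edges)


def ems_table(results: list[tuple[str, str, EMSResult]]) -> pd.DataFrame:
    """Campaign-level results table (one row per estuary x period)."""
    rows = []
    for estuary, period, r in results:
        rows.append(
            {
                "estuary": estuary,
                "period": period,
                "embAbs": r.coherence.observed,
                "coh_z": r.coherence.z,
                "coh_p": r.coherence.p,
                "coh_sim_mean": r.coherence.sim_mean,
                "coh_sim_sd": r.coherence.sim_sd,
                "turnover": r.turnover.observed,
                "tur_z": r.turnover.z,
                "tur_p": r.turnover.p,
                "tur_sim_mean": r.turnover.sim_mean,
                "tur_sim_sd": r.turnover.sim_sd,
                "morisita": r.clumping.morisita_index,
                "clump_p": r.clumping.p,
                "df": r.clumping.df,
                "interpretation": str(r.label),
            }
        )
    return pd.DataFrame(rows)
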