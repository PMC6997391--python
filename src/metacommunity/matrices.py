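"""Site-by-taxon containers, CSV I/O and sample-based rarefaction.

Survey samples are keyed by (estuary, period, station, site): an estuary is
sampled on several occasions (periods); each occasion covers an upstream-
downstream series of stations with replicate sites per station.  Counts are
individuals per taxon (family level in the motivating surveys).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_KEY_FIELDS = ("estuary", "period", "station", "site")

#: canonical environmental predictors: surface salinity plus the eight
#: grain-size fractions of the sediment sample.
ENV_VARIABLES = (
    "salinity",
    "pebble",
    "gravel",
    "very_coarse_sand",
    "coarse_sand",
    "medium_sand",
    "fine_sand",
    "very_fine_sand",
    "silt_clay",
)

log = logging.getLogger(__name__)


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _coerce_key_index(df: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(df.index, pd.MultiIndex) or tuple(df.index.names) != SAMPLE_KEY_FIELDS:
        raise DataValidationError(
            f"row index must be a MultiIndex on {SAMPLE_KEY_FIELDS}, got {df.index.names}"
        )
    return df


class AbundanceMatrix:
    """Sites x taxa matrix of non-negative integer counts.

    Rows are indexed by the sample key (estuary, period, station, site);
    columns are taxon identifiers.  This is the common source of both the
    incidence branch (EMS, NODF) and the Hellinger/RDA branch.
    """

    def __init__(self, data: pd.DataFrame):
        data = _coerce_key_index(data)
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise DataValidationError(f"duplicate sample key {dup!r}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()][0]
            raise DataValidationError(f"duplicate taxon {dup!r}")
        vals = data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataValidationError("counts must be numeric")
        if np.any(~np.isfinite(vals)):
            raise DataValidationError("counts must be finite")
        if np.any(vals < 0):
            raise DataValidationError("counts must be >= 0")
        if np.any(vals != np.round(vals)):
            raise DataValidationError("counts must be integers")
        if not np.any(vals > 0):
            raise DataValidationError("matrix has no positive entry")
        self.data = data.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    @property
    def sample_keys(self) -> pd.MultiIndex:
        return self.data.index

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        r, c = self.data.shape
        return f"<AbundanceMatrix {r} samples x {c} taxa>"

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        required = set(SAMPLE_KEY_FIELDS) | {"taxon", "count"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"long table missing columns {sorted(missing)}")
        extra = set(df.columns) - required
        if extra:
            log.warning("ignoring unknown columns %s", sorted(extra))
        keycols = list(SAMPLE_KEY_FIELDS) + ["taxon"]
        dup = df.duplicated(subset=keycols)
        if dup.any():
            row = df.loc[dup.idxmax(), keycols]
            raise DataValidationError(
                f"duplicate (sample, taxon) record: {tuple(row)}"
            )
        wide = (
            df.pivot(index=list(SAMPLE_KEY_FIELDS), columns="taxon", values="count")
            .fillna(0)
            .sort_index()
        )
        wide = wide[sorted(wide.columns)]
        wide.columns.name = None
        return cls(wide)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        missing = set(SAMPLE_KEY_FIELDS) - set(df.columns)
        if missing:
            raise DataValidationError(f"wide table missing key columns {sorted(missing)}")
        wide = df.set_index(list(SAMPLE_KEY_FIELDS)).sort_index()
        wide = wide[sorted(wide.columns)]
        return cls(wide)

    # -- serialization ---------------------------------------------------
    def to_long(self, keep_zeros: bool = True) -> pd.DataFrame:
        out = (
            self.data.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_4": "taxon"})
        )
        out.columns = list(SAMPLE_KEY_FIELDS) + ["taxon", "count"]
        if not keep_zeros:
            out = out[out["count"] > 0].reset_index(drop=True)
        return out.sort_values(list(SAMPLE_KEY_FIELDS) + ["taxon"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        """Write the canonical long-format CSV (all cells, zeros included)."""
        self.to_long().to_csv(path, index=False)

    # -- derived ---------------------------------------------------------
    def to_incidence(self, drop_empty: bool = False) -> "IncidenceMatrix":
        return to_incidence(self, drop_empty=drop_empty)


class IncidenceMatrix:
    """Binary presence/absence matrix, same row/column layout as abundances."""

    def __init__(self, data: pd.DataFrame):
        data = _coerce_key_index(data)
        vals = data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataValidationError("incidence values must be 0/1")
        if not np.any(vals > 0):
            raise DataValidationError("matrix has no presence")
        self.data = data.astype(np.int8)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    @property
    def sample_keys(self) -> pd.MultiIndex:
        return self.data.index

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        r, c = self.data.shape
        return f"<IncidenceMatrix {r} samples x {c} taxa>"

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False)


def to_incidence(ab, drop_empty: bool = False) -> IncidenceMatrix:
    """Convert counts to presence/absence; optionally drop empty rows/columns.

    Idempotent on binary input.  Raises if the matrix is empty after dropping.
    """
    data = ab.data if isinstance(ab, (AbundanceMatrix, IncidenceMatrix)) else _coerce_key_index(ab)
    inc = (data > 0).astype(np.int8)
    if drop_empty:
        row_keep = inc.to_numpy().sum(axis=1) > 0
        col_keep = inc.to_numpy().sum(axis=0) > 0
        n_r, n_c = (~row_keep).sum(), (~col_keep).sum()
        if n_r:
            log.info("dropping %d empty sample rows", n_r)
        if n_c:
            log.info("dropping %d empty taxon columns", n_c)
        inc = inc.loc[row_keep, inc.columns[col_keep]]
        if inc.shape[0] == 0 or inc.shape[1] == 0:
            raise DataValidationError("matrix empty after dropping empty rows/columns")
    return IncidenceMatrix(inc)


# ---------------------------------------------------------------------------
# CSV loaders
# ---------------------------------------------------------------------------

def load_abundance(path, dialect: str = "auto") -> AbundanceMatrix:
    """Load a species CSV in long (estuary,period,station,site,taxon,count)
    or wide (one column per taxon) dialect; ``auto`` sniffs the header."""
    df = pd.read_csv(path, dtype={k: str for k in SAMPLE_KEY_FIELDS})
    if dialect == "auto":
        dialect = "long" if {"taxon", "count"} <= set(df.columns) else "wide"
    if dialect == "long":
        return AbundanceMatrix.from_long(df)
    if dialect == "wide":
        return AbundanceMatrix.from_wide(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def load_environment(path, samples: pd.MultiIndex | None = None) -> pd.DataFrame:
    """Load the environmental CSV (salinity + grain-size fractions).

    When the file has no ``site`` column, station-level measurements are
    broadcast to every site of that station present in ``samples`` (one log
    line per broadcast), mirroring field protocols that measure salinity and
    sediment once per station.
    """
    df = pd.read_csv(path, dtype={k: str for k in SAMPLE_KEY_FIELDS if k != "site"} | {"site": str})
    missing = ({"estuary", "period", "station"} | set(ENV_VARIABLES)) - set(df.columns)
    if missing:
        raise DataValidationError(f"environment table missing columns {sorted(missing)}")
    if (df["salinity"] < 0).any():
        raise DataValidationError("salinity must be >= 0")
    if "site" in df.columns:
        out = df.set_index(list(SAMPLE_KEY_FIELDS)).sort_index()
    else:
        if samples is None:
            raise DataValidationError(
                "environment table has no 'site' column; pass the species sample keys "
                "to broadcast station-level values"
            )
        sites = (
            samples.to_frame(index=False)
            .drop_duplicates()
            .astype(str)
        )
        merged = sites.merge(df, on=["estuary", "period", "station"], how="left")
        if merged[list(ENV_VARIABLES)].isna().any().any():
            bad = merged[merged["salinity"].isna()].iloc[0]
            raise DataValidationError(
                f"no environmental record for station {tuple(bad[list(SAMPLE_KEY_FIELDS)])}"
            )
        for _, row in sites.iterrows():
            log.info(
                "broadcast station-level environment %s/%s/%s -> site %s",
                row["estuary"], row["period"], row["station"], row["site"],
            )
        out = merged.set_index(list(SAMPLE_KEY_FIELDS)).sort_index()
    out = out[list(ENV_VARIABLES)].astype(float)
    if out.index.duplicated().any():
        raise DataValidationError("duplicate sample key in environment table")
    return out


def load_coordinates(path) -> pd.DataFrame:
    """Load station (or site) coordinates: estuary,station[,site],x,y."""
    df = pd.read_csv(path, dtype={"estuary": str, "station": str, "site": str})
    missing = {"estuary", "station", "x", "y"} - set(df.columns)
    if missing:
        raise DataValidationError(f"coordinate table missing columns {sorted(missing)}")
    keys = ["estuary", "station"] + (["site"] if "site" in df.columns else [])
    out = df.set_index(keys)[["x", "y"]].astype(float).sort_index()
    if out.index.duplicated().any():
        raise DataValidationError("duplicate key in coordinate table")
    if not np.isfinite(out.to_numpy()).all():
        raise DataValidationError("coordinates must be finite")
    return out


# ---------------------------------------------------------------------------
# Sample-based rarefaction (sample adequacy)
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    """Mean +- sd of accumulated taxon richness over random sample orderings."""

    n_samples: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_samples": self.n_samples,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def rarefaction_curve(ab, n_perm: int = 100, seed=None) -> RarefactionCurve:
    """Sample-based accumulation curve (random addition order, no replacement).

    The endpoint always equals the pooled (gamma) richness; the mean at k = 1
    is the average per-sample richness.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pres = (ab.values > 0) if hasattr(ab, "values") else (np.asarray(ab) > 0)
    n, s = pres.shape
    if n < 2:
        log.warning("rarefaction on a single sample: curve of length 1")
        rich = np.array([pres.sum()], dtype=float)
        return RarefactionCurve(np.array([1]), rich, np.zeros(1), n_perm)
    rng = np.random.default_rng(seed)
    acc = np.empty((n_perm, n))
    ks = np.arange(1, n + 1)
    for p in range(n_perm):
        order = rng.permutation(n)
        m = pres[order]
        # first sample (in this ordering) at which each taxon appears
        seen = m.any(axis=0)
        first = np.where(seen, m.argmax(axis=0), n)
        acc[p] = np.cumsum(np.bincount(first, minlength=n + 1)[:n])
    return RarefactionCurve(
        ks, acc.mean(axis=0), acc.std(axis=0, ddof=1 if n_perm > 1 else 0), n_perm
    )
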