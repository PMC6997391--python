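"""End-to-end study orchestration.

Stages mirror the analysis of a multi-estuary survey:

* EMS + NODF per campaign (estuary x sampling period);
* per-estuary variation partitioning: VIF-pruned environmental predictors,
  PCNM spatial eigenvectors, sampling-occasion dummies, global RDA gates,
  forward selection, three-way partition;
* sample-based rarefaction per estuary.

A single seed in :class:`RunConfig` determines every stochastic output.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ems import EMS, ems_table
from .matrices import (
    AbundanceMatrix,
    load_abundance,
    load_coordinates,
    load_environment,
    rarefaction_curve,
    to_incidence,
)
from .nestedness import nodf_significance
from .ordination import DegenerateOrdinationError
from .spatial import pcnm, vif_prune, zscore_standardize
from .varpart import forward_select, rda_fit, time_dummies, variation_partition

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    species: str = ""
    env: str = ""
    coords: str = ""
    out_dir: str = "results"
    aggregation: str = "site"       # site | station
    null_iterations: int = 1000
    permutations: int = 999
    alpha: float = 0.05
    vif_threshold: float = 3.0
    seed: int = 0
    rarefaction_permutations: int = 100

    def __post_init__(self):
        if self.aggregation not in ("site", "station"):
            raise ValueError("aggregation must be 'site' or 'station'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def _aggregate(ab: AbundanceMatrix, level: str) -> AbundanceMatrix:
    if level == "site":
        return ab
    pooled = ab.data.groupby(level=["estuary", "period", "station"]).sum()
    pooled.index = pd.MultiIndex.from_arrays(
        [
            pooled.index.get_level_values("estuary"),
            pooled.index.get_level_values("period"),
            pooled.index.get_level_values("station"),
            ["pooled"] * len(pooled),
        ],
        names=ab.data.index.names,
    )
    return AbundanceMatrix(pooled)


def _seed_for(cfg: RunConfig, *tags) -> int:
    """Stable per-task child seed derived from the run seed and a tag.

    Uses CRC32 of the tag repr (not Python's randomized hash) so reruns are
    byte-identical across processes.
    """
    import zlib

    tag_hash = zlib.crc32(repr(tags).encode()) % (2 ** 31)
    h = np.random.SeedSequence([cfg.seed, tag_hash])
    return int(h.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Stage 1: EMS + NODF per campaign
# ---------------------------------------------------------------------------

def run_ems_stage(cfg: RunConfig, ab: AbundanceMatrix | None = None):
    """One EMS row and one NODF row per estuary x period campaign.

    Campaigns whose matrix is degenerate are reported with an error note,
    not fatal.  Returns (ems_table, nodf_table) and writes both CSVs.
    """
    if ab is None:
        ab = load_abundance(cfg.species)
    ab = _aggregate(ab, cfg.aggregation)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = ab.data.groupby(level=["estuary", "period"], sort=True)
    if not len(groups):
        raise ValueError("no campaigns found in species data")
    ems_rows, nodf_rows, failures = [], [], []
    for (estuary, period), block in groups:
        try:
            inc = to_incidence(AbundanceMatrix(block), drop_empty=True)
            seed = _seed_for(cfg, "ems", estuary, period)
            res = EMS(inc, iterations=cfg.null_iterations, alpha=cfg.alpha).fit(seed=seed)
            ems_rows.append((estuary, period, res))
            nres = nodf_significance(
                inc, iters=cfg.null_iterations,
                seed=_seed_for(cfg, "nodf", estuary, period),
            )
            nodf_rows.append(
                {
                    "estuary": estuary, "period": period,
                    "nodf_total": nres.nodf_total, "nodf_rows": nres.nodf_rows,
                    "nodf_cols": nres.nodf_cols,
                    "null_method": nres.null_method,
                    "null_mean": nres.null.sim_mean, "null_sd": nres.null.sim_sd,
                    "z": nres.null.z, "p": nres.null.p,
                }
            )
        except (DegenerateOrdinationError, ValueError) as exc:
            log.warning("campaign %s/%s failed: %s", estuary, period, exc)
            failures.append({"estuary": estuary, "period": period, "error": str(exc)})
    ems_df = ems_table(ems_rows)
    nodf_df = pd.DataFrame(nodf_rows)
    ems_df.to_csv(out / "ems_results.csv", index=False)
    nodf_df.to_csv(out / "nodf_results.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out / "ems_failures.csv", index=False)
    return ems_df, nodf_df


# ---------------------------------------------------------------------------
# Stage 2: per-estuary variation partitioning
# ---------------------------------------------------------------------------

def _estuary_varpart(cfg: RunConfig, estuary: str, ab_block: pd.DataFrame,
                     env: pd.DataFrame, coords: pd.DataFrame, out: Path) -> dict:
    from .varpart import hellinger

    block = ab_block.loc[:, ab_block.sum(axis=0) > 0]
    block = block.loc[block.sum(axis=1) > 0]
    y = hellinger(np.asarray(block, dtype=float))
    rows = block.index

    # --- environmental set: z-score, VIF prune, gate, forward select
    env_rows = env.loc[rows]
    env_rows = env_rows.loc[:, env_rows.std(ddof=1) > 0]
    dropped_const = set(env.columns) - set(env_rows.columns)
    if dropped_const:
        log.info("%s: dropped constant environmental columns %s", estuary, sorted(dropped_const))
    envz = zscore_standardize(env_rows)
    vif_report = vif_prune(envz, threshold=cfg.vif_threshold)
    envz = envz[list(vif_report.retained)]
    vif_report.to_frame().to_csv(out / f"vif_{estuary}.csv", index=False)
    env_sel = forward_select(y, envz, alpha=cfg.alpha, n_perm=cfg.permutations,
                             seed=_seed_for(cfg, "fsel_env", estuary))

    # --- spatial set: PCNM at site level, repeated across periods
    site_keys = rows.droplevel("period").unique()
    cpts = coords.reset_index()
    if "site" in cpts.columns and cpts["site"].notna().all():
        cpts = cpts.set_index(["estuary", "station", "site"])
        site_coords = cpts.loc[[(e, st, si) for (e, st, si) in
                                [(estuary, k[1], k[2]) for k in site_keys]]]
    else:
        cpts = cpts.set_index(["estuary", "station"])
        site_coords = cpts.loc[[(estuary, k[1]) for k in site_keys]]
    eig = pcnm(site_coords.reset_index(drop=True))
    space_site = eig.predictors
    space_site.index = site_keys
    eig.to_csv(out / f"pcnm_{estuary}.csv")
    spa = space_site.loc[rows.droplevel("period")]
    spa.index = rows
    spa_sel = forward_select(y, spa, alpha=cfg.alpha, n_perm=cfg.permutations,
                             seed=_seed_for(cfg, "fsel_spa", estuary))

    # --- temporal set
    periods = rows.get_level_values("period")
    tdum = time_dummies(pd.Series(periods)) if periods.nunique() > 1 else None

    env_x = envz[env_sel.names] if env_sel.names else None
    spa_x = spa[spa_sel.names] if spa_sel.names else None
    vp = variation_partition(
        y, env=env_x, spa=spa_x, time=tdum,
        n_perm=cfg.permutations, seed=_seed_for(cfg, "varpart", estuary),
    )

    trace = pd.concat(
        [
            env_sel.to_frame().assign(set="env"),
            spa_sel.to_frame().assign(set="spa"),
        ],
        ignore_index=True,
    )
    trace.to_csv(out / f"forward_selection_{estuary}.csv", index=False)
    vp.to_frame().to_csv(out / f"varpart_{estuary}.csv", index=False)
    return {
        "estuary": estuary,
        "global_env": env_sel,
        "global_spa": spa_sel,
        "varpart": vp,
    }


def run_varpart_stage(cfg: RunConfig, ab: AbundanceMatrix | None = None,
                      env: pd.DataFrame | None = None,
                      coords: pd.DataFrame | None = None) -> dict:
    """Per-estuary predictor construction, selection and 3-way partition.

    Periods are pooled into one site x period response per estuary with
    sampling occasion as the temporal predictor set.  A non-significant
    global gate leaves that predictor set empty (recorded, not fatal).
    """
    if ab is None:
        ab = load_abundance(cfg.species)
    ab = _aggregate(ab, cfg.aggregation)
    if env is None:
        env = load_environment(cfg.env, samples=ab.sample_keys)
    if cfg.aggregation == "station":
        env = env.groupby(level=["estuary", "period", "station"]).mean()
        env = env.set_axis(
            pd.MultiIndex.from_arrays(
                [env.index.get_level_values(0), env.index.get_level_values(1),
                 env.index.get_level_values(2), ["pooled"] * len(env)],
                names=ab.data.index.names,
            )
        )
    if coords is None:
        coords = load_coordinates(cfg.coords)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for estuary, block in ab.data.groupby(level="estuary", sort=True):
        results[estuary] = _estuary_varpart(cfg, estuary, block, env, coords, out)
    summary = pd.concat(
        {e: r["varpart"].fractions for e, r in results.items()}, axis=1
    )
    summary.to_csv(out / "varpart_summary.csv")
    return results


# ---------------------------------------------------------------------------
# Stage 3: sample adequacy
# ---------------------------------------------------------------------------

def run_adequacy_stage(cfg: RunConfig, ab: AbundanceMatrix | None = None) -> dict:
    """Rarefaction (mean +- sd accumulation) per estuary across campaigns."""
    if ab is None:
        ab = load_abundance(cfg.species)
    ab = _aggregate(ab, cfg.aggregation)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = {}
    for estuary, block in ab.data.groupby(level="estuary", sort=True):
        curve = rarefaction_curve(
            block.to_numpy(), n_perm=cfg.rarefaction_permutations,
            seed=_seed_for(cfg, "rarefaction", estuary),
        )
        curve.to_frame().to_csv(out / f"rarefaction_{estuary}.csv", index=False)
        curves[estuary] = curve
    return curves


def run_all(cfg: RunConfig) -> dict:
    ab = load_abundance(cfg.species)
    env = load_environment(cfg.env, samples=ab.sample_keys)
    coords = load_coordinates(cfg.coords)
    ems_df, nodf_df = run_ems_stage(cfg, ab)
    vp = run_varpart_stage(cfg, ab, env, coords)
    curves = run_adequacy_stage(cfg, ab)
    return {"ems": ems_df, "nodf": nodf_df, "varpart": vp, "rarefaction": curves}
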