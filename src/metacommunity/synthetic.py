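"""Synthetic metacommunities: idealized incidence structures and
Gaussian-niche gradient communities.

Two generators make every pipeline stage testable without field data:

* :func:`generate_structure` realizes each idealized structure (nested with
  clumped / random / hyperdispersed species loss, Clementsian, Gleasonian,
  evenly spaced, checkerboard, random) as an incidence matrix whose sites
  lie on a latent gradient.  Rows are emitted in a recorded random
  permutation so downstream analyses must recover the order by ordination;
  the gradient position is preserved in the station labels.

* :func:`generate_gradient_community` draws abundances from Gaussian niches
  along a monotone salinity-like gradient (salinity decreasing from the
  seaward station), with AR(1) spatially autocorrelated sediment fractions
  and multiplicative period effects — the shape of a multi-campaign estuary
  survey.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml

from .matrices import AbundanceMatrix, IncidenceMatrix, SAMPLE_KEY_FIELDS, ENV_VARIABLES

STRUCTURES = (
    "nested_clumped", "nested_random", "nested_hyperdispersed",
    "clementsian", "gleasonian", "evenly_spaced", "checkerboard", "random",
)


@dataclass
class StructureSpec:
    structure: str
    n_sites: int = 20
    n_species: int = 40
    fill: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.n_sites < 4 or self.n_species < 4:
            raise ValueError("need n_sites >= 4 and n_species >= 4")
        if not 0 < self.fill < 1:
            raise ValueError("fill must be in (0, 1)")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "StructureSpec":
        return cls(**yaml.safe_load(text))


def _ranges_to_matrix(starts, lengths, n_sites, n_species) -> np.ndarray:
    m = np.zeros((n_sites, n_species), dtype=np.int8)
    idx = np.arange(n_sites)[:, None]
    starts = np.asarray(starts)
    ends = starts + np.asarray(lengths) - 1
    m[(idx >= starts[None, :]) & (idx <= ends[None, :])] = 1
    return m


def _length_cap(spec: StructureSpec) -> int:
    """Largest drawable range so the mean length can sit near fill * n_sites
    while endpoints stay observable (strictly inside the gradient)."""
    return int(np.clip(round(2 * spec.fill * spec.n_sites), 2, spec.n_sites - 1))


def _structure_array(spec: StructureSpec, rng) -> np.ndarray:
    n, s = spec.n_sites, spec.n_species
    lbar = spec.fill * n
    cap = _length_cap(spec)
    if spec.structure == "nested_clumped":
        k = min(3, cap)
        values = rng.choice(np.arange(1, cap + 1), size=k, replace=False)
        lengths = rng.choice(values, size=s)
        return _ranges_to_matrix(np.zeros(s, int), lengths, n, s)
    if spec.structure == "nested_random":
        lengths = rng.integers(1, cap + 1, size=s)
        return _ranges_to_matrix(np.zeros(s, int), lengths, n, s)
    if spec.structure == "nested_hyperdispersed":
        lattice = np.tile(np.arange(1, cap + 1), int(np.ceil(s / cap)))[:s]
        rng.shuffle(lattice)
        return _ranges_to_matrix(np.zeros(s, int), lattice, n, s)
    if spec.structure == "clementsian":
        g = min(4, max(2, n // 4))
        length = int(np.clip(round(lbar), 2, n - 1))
        starts_g = np.round(np.linspace(0, n - length, g)).astype(int)
        groups = rng.permutation(np.arange(s) % g)
        starts = starts_g[groups]
        return _ranges_to_matrix(starts, np.full(s, length), n, s)
    if spec.structure == "gleasonian":
        # staggered-tiling backbone with boundary jitter near half a range:
        # boundaries land quasi-uniformly (non-clumped) while ranges stay
        # dispersed enough for positive turnover
        length = int(np.clip(round(lbar), 2, n - 1))
        jitter = max(1, round(0.4 * length))
        return _staggered_ranges(n, s, length, jitter, rng)
    if spec.structure == "evenly_spaced":
        # range boundaries on a regular staggered lattice; sub-lattice jitter
        # (less than half the inter-boundary spacing) collapses under integer
        # site positions, so evenness is exact by construction
        length = int(np.clip(round(lbar), 2, n - 1))
        if round(lbar) < 2:
            raise ValueError(
                "evenly_spaced infeasible: fill * n_sites < 2 gives no lattice"
            )
        return _staggered_ranges(n, s, length, 0, rng)
    if spec.structure == "checkerboard":
        return _checkerboard(spec, rng)
    # random
    return (rng.random((n, s)) < spec.fill).astype(np.int8)


def _staggered_ranges(n: int, s: int, length: int, jitter: int, rng) -> np.ndarray:
    """Layers of end-to-end tiles of ``length`` sites, each layer shifted by
    one position, cycled until every species has a range; optional integer
    jitter perturbs each boundary."""
    pairs = []
    shift = 0
    while len(pairs) < s:
        start = (shift % length) - length
        while start < n:
            a, b = max(start, 0), min(start + length - 1, n - 1)
            if b >= a:
                if jitter:
                    a2 = int(np.clip(a + rng.integers(-jitter, jitter + 1), 0, n - 1))
                    b2 = int(np.clip(b + rng.integers(-jitter, jitter + 1), 0, n - 1))
                    if b2 >= a2:
                        a, b = a2, b2
                pairs.append((a, b))
            start += length
        shift += 1
    order = rng.permutation(len(pairs))[:s]
    starts = np.array([pairs[i][0] for i in order])
    lengths = np.array([pairs[i][1] - pairs[i][0] + 1 for i in order])
    return _ranges_to_matrix(starts, lengths, n, s)


def _checkerboard(spec: StructureSpec, rng, moves: int = 3000) -> np.ndarray:
    """Mutually exclusive species pairs arranged to resist any gradient.

    Pairs share a site pool split disjointly (zero co-occurrence at every
    site, an invariant every move preserves).  A hill climb then perturbs
    presences to maximize the embedded absences of the CA-ordinated matrix:
    a checkerboard metacommunity is definitionally one with more
    interruptions than chance under its best gradient ordering, and random
    disjoint splits alone are statistically indistinguishable from the
    fixed-row null.
    """
    from .ems import count_embedded_absences
    from .ordination import DegenerateOrdinationError, correspondence_ordination

    n, s = spec.n_sites, spec.n_species

    def embabs(m):
        keep = m.sum(axis=0) > 0
        try:
            om = correspondence_ordination(m[:, keep])
        except DegenerateOrdinationError:
            return -1
        return count_embedded_absences(om)

    m = np.zeros((n, s), dtype=np.int8)
    pool = int(np.clip(round(2 * spec.fill * n), 2, n))
    partner = {}
    for a in range(0, s - 1, 2):
        sites = rng.choice(n, size=pool, replace=False)
        split = rng.random(pool) < 0.5
        m[sites[split], a] = 1
        m[sites[~split], a + 1] = 1
        partner[a] = a + 1
        partner[a + 1] = a
    if s % 2:  # odd species count: last species is an unpaired random set
        sites = rng.choice(n, size=max(1, pool // 2), replace=False)
        m[sites, s - 1] = 1
    cur = embabs(m)
    for _ in range(moves):
        c = int(rng.integers(0, s))
        p = partner.get(c)
        pres = np.flatnonzero(m[:, c])
        if p is None or len(pres) == 0:
            continue
        i = pres[rng.integers(len(pres))]
        if rng.random() < 0.5:  # reassign site i from c to its partner
            m[i, c], m[i, p] = 0, 1
            if (new := embabs(m)) > cur:
                cur = new
            else:
                m[i, c], m[i, p] = 1, 0
        else:  # move a presence of c to a site outside the pair's pool
            free = np.flatnonzero((m[:, c] == 0) & (m[:, p] == 0))
            if len(free) == 0:
                continue
            j = free[rng.integers(len(free))]
            m[i, c], m[j, c] = 0, 1
            if (new := embabs(m)) > cur:
                cur = new
            else:
                m[i, c], m[j, c] = 1, 0
    return m


def generate_structure(spec: StructureSpec) -> IncidenceMatrix:
    """Realize one idealized structure; same seed -> identical matrix.

    Rows are labeled by gradient position (station "01" is one gradient end)
    and emitted in a random order, so the latent ordering is recoverable
    only through ordination (or by sorting the index).
    """
    rng = np.random.default_rng(spec.seed)
    arr = _structure_array(spec, rng)
    perm = rng.permutation(spec.n_sites)
    idx = pd.MultiIndex.from_arrays(
        [
            ["synthetic"] * spec.n_sites,
            ["p1"] * spec.n_sites,
            [f"{i + 1:02d}" for i in perm],
            ["a"] * spec.n_sites,
        ],
        names=SAMPLE_KEY_FIELDS,
    )
    df = pd.DataFrame(arr[perm], index=idx,
                      columns=[f"T{j + 1:03d}" for j in range(spec.n_species)])
    return IncidenceMatrix(df)


# ---------------------------------------------------------------------------
# Gradient communities
# ---------------------------------------------------------------------------

@dataclass
class GradientCommunitySpec:
    """Gaussian-niche community along a salinity-like gradient.

    Expected abundance of species i at site j is
    ``max_abundance * exp(-(s_j - mu_i)^2 / (2 sd^2)) * period_multiplier``
    with optima mu_i uniform over the salinity range and Poisson counts.
    """

    n_stations: int = 10
    sites_per_station: int = 2
    n_periods: int = 4
    n_species: int = 40
    salinity_range: tuple = (0.5, 40.0)
    niche_breadth_sd: float = 6.0
    max_abundance: float = 20.0
    env_spatial_autocorr: float = 0.7
    period_effect_sd: float = 0.3
    seed: int = 0
    estuary: str = "synthetic"
    station_spacing_m: float = 1000.0

    def __post_init__(self):
        if self.n_stations < 2 or self.sites_per_station < 1:
            raise ValueError("need >= 2 stations and >= 1 site per station")
        if self.niche_breadth_sd < 0 or self.period_effect_sd < 0:
            raise ValueError("all sds must be >= 0")
        lo, hi = self.salinity_range
        if not lo < hi:
            raise ValueError("salinity_range must be increasing (min, max)")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["salinity_range"] = list(d["salinity_range"])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "GradientCommunitySpec":
        d = yaml.safe_load(text)
        d["salinity_range"] = tuple(d["salinity_range"])
        return cls(**d)


def _ar1(n: int, rho: float, rng) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(max(1 - rho ** 2, 0.0))
    for t in range(1, n):
        z[t] = rho * z[t - 1] + innov[t - 1]
    return z


def generate_gradient_community(spec: GradientCommunitySpec):
    """Return (AbundanceMatrix, environment table, coordinate table).

    Stations are equally spaced on a line; salinity declines linearly from
    the seaward station (station 01, maximum) to the most upstream one.
    Sediment fractions are a softmax of AR(1) latent series per station
    (percentages summing to 100).  Environment is measured at station level
    and broadcast to sites; coordinates get a small site offset so replicate
    sites are distinct points.
    """
    rng = np.random.default_rng(spec.seed)
    ns, nk = spec.n_stations, spec.sites_per_station
    lo, hi = spec.salinity_range
    salinity = np.linspace(hi, lo, ns)
    grain = np.stack([_ar1(ns, spec.env_spatial_autocorr, rng) for _ in ENV_VARIABLES[1:]])
    grain_pct = 100.0 * np.exp(grain) / np.exp(grain).sum(axis=0, keepdims=True)

    stations = [f"{i + 1:02d}" for i in range(ns)]
    sites = [chr(ord("a") + k) for k in range(nk)]
    periods = [f"P{t + 1}" for t in range(spec.n_periods)]

    x = np.arange(ns) * spec.station_spacing_m
    coord_rows = []
    for i, st in enumerate(stations):
        for k, si in enumerate(sites):
            coord_rows.append(
                {
                    "estuary": spec.estuary, "station": st, "site": si,
                    "x": x[i] + rng.normal(0, spec.station_spacing_m * 0.02),
                    "y": (k - (nk - 1) / 2) * 50.0 + rng.normal(0, 5.0),
                }
            )
    coords = pd.DataFrame(coord_rows).set_index(["estuary", "station", "site"]).sort_index()

    mu = rng.uniform(lo, hi, size=spec.n_species)
    if spec.niche_breadth_sd > 0:
        niche = np.exp(-((salinity[:, None] - mu[None, :]) ** 2)
                       / (2 * spec.niche_breadth_sd ** 2))
    else:
        niche = (salinity[:, None] == mu[None, :]).astype(float)
    period_mult = (
        np.exp(rng.normal(0, spec.period_effect_sd, size=(spec.n_periods, spec.n_species)))
        if spec.period_effect_sd > 0
        else np.ones((spec.n_periods, spec.n_species))
    )

    ab_rows, env_rows = [], []
    taxa = [f"T{j + 1:03d}" for j in range(spec.n_species)]
    for t, per in enumerate(periods):
        lam_station = spec.max_abundance * niche * period_mult[t][None, :]
        for i, st in enumerate(stations):
            for si in sites:
                counts = rng.poisson(lam_station[i])
                ab_rows.append((spec.estuary, per, st, si, *counts))
                env_rows.append(
                    (spec.estuary, per, st, si, salinity[i], *grain_pct[:, i])
                )
    ab = pd.DataFrame(ab_rows, columns=list(SAMPLE_KEY_FIELDS) + taxa)
    abundance = AbundanceMatrix.from_wide(ab)
    env = (
        pd.DataFrame(env_rows, columns=list(SAMPLE_KEY_FIELDS) + list(ENV_VARIABLES))
        .set_index(list(SAMPLE_KEY_FIELDS))
        .sort_index()
    )
    return abundance, env, coords


# ---------------------------------------------------------------------------
# The full multi-estuary study bundle
# ---------------------------------------------------------------------------

#: survey design of the motivating study: stations x replicate sites x
#: sampling occasions for each estuary (10x2x4, 10x2x4, 11x2x5 -> 270 samples).
STUDY_DESIGN = {
    "Jaguaripe": {"n_stations": 10, "n_periods": 4},
    "Paraguacu": {"n_stations": 10, "n_periods": 4},
    "Subae": {"n_stations": 11, "n_periods": 5},
}


def generate_study(seed: int = 0, design: dict | None = None,
                   **overrides):
    """Generate the full three-estuary synthetic bundle.

    Returns (AbundanceMatrix, environment, coordinates) pooled over
    estuaries; the default design mirrors the motivating survey (13
    campaigns, 270 site-samples).
    """
    design = STUDY_DESIGN if design is None else design
    seeds = np.random.SeedSequence(seed).spawn(len(design))
    abs_, envs, coords = [], [], []
    for (name, d), ss in zip(design.items(), seeds):
        spec = GradientCommunitySpec(
            n_stations=d["n_stations"], n_periods=d["n_periods"],
            seed=int(ss.generate_state(1)[0] % (2 ** 31)), estuary=name,
            **overrides,
        )
        a, e, c = generate_gradient_community(spec)
        abs_.append(a.data)
        envs.append(e)
        coords.append(c)
    ab = AbundanceMatrix(pd.concat(abs_).fillna(0).astype(int).sort_index())
    return ab, pd.concat(envs).sort_index(), pd.concat(coords).sort_index()


def write_bundle(out_dir, abundance: AbundanceMatrix, env: pd.DataFrame,
                 coords: pd.DataFrame) -> dict:
    """Write the species/environment/coordinates CSV triple; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": out / "species.csv",
        "env": out / "environment.csv",
        "coords": out / "coordinates.csv",
    }
    abundance.to_csv(paths["species"])
    env.reset_index().to_csv(paths["env"], index=False)
    coords.reset_index().to_csv(paths["coords"], index=False)
    return paths
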