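"""Synthetic inputs with known injected structure.

Every input the pipeline consumes can be generated here with its governing
parameters known exactly, so downstream stages are testable as recovery
problems: daily hydrographs with seasonal cycles, AR(1) log-noise, dry
spells whose expected annual total grows linearly, and an optional drift in
log-discharge; daily climate with seasonal temperature plus a linear trend
and zero-inflated precipitation; occurrence records drawn by inverting the
Poisson random-intercept richness model; and trait tables paired with
pure-birth phylogenies carrying a binary conservation-status character
evolved under a symmetric Markov (Mk) model.

All draws flow from a single ``numpy.random.Generator`` seeded per call —
the same seed reproduces output bit for bit.  Dates are real calendar dates
(leap years included) so water-year logic is exercised downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .hexgrid import HexGrid, hex_centroid

__all__ = [
    "HydroSimParams",
    "ClimateSimParams",
    "AssemblageSimParams",
    "gen_discharge",
    "gen_climate",
    "gen_assemblage",
    "gen_traits_and_tree",
    "simulate_binary_states",
]

IUCN_CONCERN = ("NT", "VU", "EN", "CR", "EX")
LISTING_REASONS = ("habitat", "overuse", "disease", "other_factors", "small_range")


def _check_finite(**kwargs):
    for name, v in kwargs.items():
        if v is None:
            continue
        if not np.all(np.isfinite(v)):
            raise ValueError(f"parameter {name!r} must be finite, got {v!r}")


@dataclass
class HydroSimParams:
    """Parameters of the daily discharge generator.

    ``seasonal_amplitude`` is the fractional amplitude of the sinusoidal
    seasonal cycle around ``mean_flow``; AR(1) noise acts on log10
    discharge with innovation scale ``noise_sd``; ``dry_spell_trend`` is
    the number of days/yr added to the *expected total* zero-flow days per
    water year (so it is directly the recoverable Theil–Sen slope of annual
    zero-flow days); ``trend_naa`` is a drift in log10 discharge per year,
    which appears downstream as an NAA trend of ~365.25*trend_naa per year.
    """

    n_years: int = 40
    mean_flow: float = 1.0               # m3/s
    seasonal_amplitude: float = 0.5      # fraction of mean, < 1
    ar1_coef: float = 0.7
    noise_sd: float = 0.1                # log10 units
    dry_spell_rate_per_year: float = 0.0  # expected spells per water year
    dry_spell_base_days: float = 10.0    # expected total dry days in year 0
    dry_spell_trend: float = 0.0         # days/yr added to expected total
    trend_naa: float = 0.0               # log10-units/yr drift
    flow_reversal_days_per_year: float = 0.0
    stage_scale: float = 1.0
    start_year: int = 1980
    seed: int = 0

    def __post_init__(self):
        _check_finite(**{k: v for k, v in self.__dict__.items()})
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.mean_flow <= 0:
            raise ValueError("mean_flow must be positive")


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, n)
    x = lfilter([1.0], [1.0, -coef], innov)
    return x


def gen_discharge(params: HydroSimParams) -> pd.DataFrame:
    """Daily gauge series (date, discharge, stage) with injected structure.

    Dry spells are contiguous blocks placed in the low-flow season of each
    water year (Oct-start convention): the number of spells is Poisson with
    the configured rate, the total dry-day count is Poisson with mean
    ``dry_spell_base_days + dry_spell_trend * year_index``.  Stage is zero
    on dry days, positive otherwise, except on injected flow-reversal days
    (discharge zero, stage clearly positive).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dates = pd.date_range(f"{p.start_year}-10-01",
                          periods=round(p.n_years * 365.25), freq="D")
    n = len(dates)
    t = np.arange(n)
    seasonal = 1.0 + p.seasonal_amplitude * np.sin(2 * np.pi * t / 365.25)
    log10q = (np.log10(p.mean_flow * seasonal)
              + p.trend_naa * t / 365.25
              + _ar1(n, p.ar1_coef, p.noise_sd, rng))
    q = 10.0 ** log10q

    dry = np.zeros(n, dtype=bool)
    if p.dry_spell_rate_per_year > 0:
        wy_index = (dates - dates[0]).days // 365  # generator-internal year blocks
        for y in range(p.n_years):
            mean_total = p.dry_spell_base_days + p.dry_spell_trend * y
            if mean_total <= 0:
                continue
            total = rng.poisson(mean_total)
            if total == 0:
                continue
            n_spells = max(1, rng.poisson(p.dry_spell_rate_per_year))
            lengths = rng.multinomial(total, np.full(n_spells, 1.0 / n_spells))
            lengths = lengths[lengths > 0]
            year_days = np.flatnonzero(wy_index == y)
            if year_days.size == 0:
                continue
            # low-flow window: centred on the seasonal minimum (sin = -1 at
            # t = 0.75*365.25 within the cycle), +/- 90 days
            phase = (t[year_days] / 365.25) % 1.0
            window = year_days[(phase > 0.5) & (phase < 1.0)]
            if window.size == 0:
                window = year_days
            for L in lengths:
                start = rng.choice(window)
                dry[start:start + int(L)] = True
    q[dry] = 0.0

    stage = p.stage_scale * np.power(
        np.maximum(q / p.mean_flow, 0.0), 0.4, where=q > 0, out=np.zeros(n))
    stage[dry] = 0.0
    if p.flow_reversal_days_per_year > 0:
        n_rev = rng.poisson(p.flow_reversal_days_per_year * p.n_years)
        wet = np.flatnonzero(~dry)
        if wet.size and n_rev:
            rev = rng.choice(wet, size=min(n_rev, wet.size), replace=False)
            q[rev] = 0.0
            stage[rev] = max(0.5, p.stage_scale * 0.5)
    return pd.DataFrame({"date": dates, "discharge": q, "stage": stage})


@dataclass
class ClimateSimParams:
    """Parameters of the daily climate generator.

    Temperature is a seasonal sinusoid around ``temp_mean`` with linear
    trend ``temp_trend`` (deg/yr) and Gaussian noise; tmin/tmax bracket the
    daily mean by ``diurnal_range``.  Precipitation is zero-inflated:
    Bernoulli(``p_wet``) wet days with Gamma-distributed intensities of
    mean ``intensity_mean`` mm (``intensity_shape=None`` makes every wet
    day exactly ``intensity_mean`` — the noise-free case).  ``precip_trend``
    (mm/yr) scales wet-day amounts so the *expected annual total* changes
    linearly by that much per year.
    """

    n_years: int = 42
    temp_trend: float = 0.0          # degrees / yr
    precip_trend: float = 0.0        # mm / yr on the annual total
    p_wet: float = 0.3
    intensity_mean: float = 5.0      # mm per wet day
    intensity_shape: float | None = 1.0
    temp_mean: float = 18.0
    temp_seasonal_amp: float = 9.0
    temp_noise_sd: float = 1.5
    diurnal_range: float = 10.0
    start_year: int = 1980
    seed: int = 0

    def __post_init__(self):
        _check_finite(n_years=self.n_years, temp_trend=self.temp_trend,
                      precip_trend=self.precip_trend, p_wet=self.p_wet,
                      intensity_mean=self.intensity_mean)
        if not 0 <= self.p_wet <= 1:
            raise ValueError("p_wet must lie in [0, 1]")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")


def gen_climate(params: ClimateSimParams) -> pd.DataFrame:
    """Daily climate series (date, tmin, tmax, precip)."""
    p = params
    rng = np.random.default_rng(p.seed)
    dates = pd.date_range(f"{p.start_year}-01-01", f"{p.start_year + p.n_years - 1}-12-31",
                          freq="D")
    n = len(dates)
    t = np.arange(n)
    years = t / 365.25
    tmean = (p.temp_mean
             + p.temp_seasonal_amp * np.cos(2 * np.pi * (t - 200) / 365.25)
             + p.temp_trend * years)
    if p.temp_noise_sd > 0:
        tmean = tmean + rng.normal(0.0, p.temp_noise_sd, n)
    tmin = tmean - p.diurnal_range / 2.0
    tmax = tmean + p.diurnal_range / 2.0

    wet = rng.random(n) < p.p_wet if p.p_wet < 1 else np.ones(n, bool)
    if p.p_wet == 0:
        wet = np.zeros(n, bool)
    if p.intensity_shape is None:
        amount = np.full(n, p.intensity_mean)
    else:
        amount = rng.gamma(p.intensity_shape,
                           p.intensity_mean / p.intensity_shape, n)
    base_annual = p.p_wet * 365.25 * p.intensity_mean
    scale = np.maximum(0.0, 1.0 + (p.precip_trend * years) / base_annual) \
        if base_annual > 0 else np.zeros(n)
    precip = np.where(wet, amount * scale, 0.0)
    return pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax,
                         "precip": precip})


@dataclass
class AssemblageSimParams:
    """Parameters of the occurrence-record generator.

    Annual richness in hex ``i``, year ``t`` is Poisson with
    ``log lambda_it = richness_intercept + richness_year_slope * t + u_i``,
    ``u_i ~ Normal(0, hex_random_sd^2)`` — the richness model run forward.
    ``year_index`` runs 0..n_years-1.
    """

    n_hexes: int = 23
    n_years: int = 30
    richness_intercept: float = 2.0      # log-count
    richness_year_slope: float = -0.02   # per-year change in log richness
    hex_random_sd: float = 0.3
    species_pool_size: int = 183
    start_year: int = 1985
    grid: HexGrid = field(default_factory=HexGrid)
    seed: int = 0

    def __post_init__(self):
        if self.n_hexes < 1 or self.n_years < 1:
            raise ValueError("n_hexes and n_years must be positive")
        if self.species_pool_size < 1:
            raise ValueError("species_pool_size must be positive")


def species_pool(n: int) -> list[str]:
    """Canonical binomial-style names for a synthetic species pool."""
    return [f"Xerichthys sp{i:03d}" for i in range(1, n + 1)]


def gen_assemblage(params: AssemblageSimParams):
    """Occurrence records per hex/year plus the latent truth table.

    Returns ``(occurrences, truth)``: occurrence rows are
    (species, lat, lon, date, source, hexid); ``truth`` carries the latent
    ``u_i``, ``lambda_it`` and drawn richness for recovery tests.  Richness
    draws above the pool size are truncated with a warning.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    pool = np.array(species_pool(p.species_pool_size))
    u = rng.normal(0.0, p.hex_random_sd, p.n_hexes)
    # spread hexes on a coarse diagonal so every one lands in its own cell
    hex_qr = [(3 * i, 2 * i) for i in range(p.n_hexes)]

    occ_rows, truth_rows = [], []
    truncated = 0
    for i, (q_ax, r_ax) in enumerate(hex_qr):
        lon, lat = hex_centroid(q_ax, r_ax, p.grid)
        for yix in range(p.n_years):
            year = p.start_year + yix
            lam = math.exp(p.richness_intercept
                           + p.richness_year_slope * yix + u[i])
            rich = rng.poisson(lam)
            if rich > p.species_pool_size:
                truncated += 1
                rich = p.species_pool_size
            sp = rng.choice(pool, size=rich, replace=False)
            day = rng.integers(120, 280)  # mid-year sampling
            date = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(int(day), "D")
            jl = rng.uniform(-0.02, 0.02, size=(rich, 2)) if rich else np.zeros((0, 2))
            for k, s in enumerate(sp):
                occ_rows.append((s, lat + jl[k, 0], lon + jl[k, 1],
                                 date.date().isoformat(), "synthetic"))
            truth_rows.append(dict(hexid=f"{q_ax}_{r_ax}", hex_index=i,
                                   year=year, year_index=yix, u=u[i],
                                   lam=lam, richness=int(rich)))
    if truncated:
        warnings.warn(f"{truncated} hex-years had richness draws above the "
                      "species pool size and were truncated")
    occurrences = pd.DataFrame(occ_rows,
                               columns=["species", "lat", "lon", "date", "source"])
    occurrences["lat_text"] = occurrences["lat"].map(lambda v: f"{v:.4f}")
    occurrences["lon_text"] = occurrences["lon"].map(lambda v: f"{v:.4f}")
    return occurrences, pd.DataFrame(truth_rows)


def simulate_binary_states(tree: dendropy.Tree, q: float,
                           rng: np.random.Generator) -> dict[str, int]:
    """Evolve a two-state symmetric Markov character down a tree.

    Root state drawn from the (0.5, 0.5) prior; along a branch of length t
    the state flips with probability ``(1 - exp(-2 q t)) / 2``.
    """
    states: dict[int, int] = {}
    root = tree.seed_node
    states[id(root)] = int(rng.random() < 0.5)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_flip = 0.5 * (1.0 - math.exp(-2.0 * q * t))
        parent_state = states[id(node.parent_node)]
        flip = rng.random() < p_flip
        states[id(node)] = parent_state ^ int(flip)
    return {leaf.taxon.label: states[id(leaf)]
            for leaf in tree.leaf_node_iter()}


def gen_traits_and_tree(n_species: int = 100, n_concern: int | None = None,
                        q_true: float | None = 0.3,
                        size_effect: float = 0.0, trophic_effect: float = 0.0,
                        longevity_effect: float = 0.0,
                        reason_probs: dict[str, float] | None = None,
                        freshwater_fraction: float = 1.0,
                        seed: int = 0):
    """Trait table + pure-birth tree + binary conservation-status tip states.

    If ``q_true`` is given the status character is simulated under the
    symmetric Mk model at that rate; otherwise exactly ``n_concern`` random
    tips are flagged.  Listed species have body size, trophic level and
    longevity shifted *down* by the stated effect sizes (in within-group SD
    units on the trait's modelling scale).  Listing reasons are independent
    Bernoulli draws per reason with a guaranteed minimum of one reason.

    Returns ``(traits, tree, tip_states)`` with ``tree`` a dendropy Tree.
    """
    if n_concern is not None and n_concern > n_species:
        raise ValueError("n_concern cannot exceed n_species")
    rng = np.random.default_rng(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=_DendropyRng(rng))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"Xerichthys sp{i:03d}"

    if q_true is not None:
        tip_states = simulate_binary_states(tree, q_true, rng)
    else:
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        flagged = set(rng.choice(labels, size=int(n_concern or 0), replace=False))
        tip_states = {lab: int(lab in flagged) for lab in labels}

    reason_probs = reason_probs or {"habitat": 0.9, "overuse": 0.0,
                                    "disease": 0.25, "other_factors": 0.75,
                                    "small_range": 0.5}
    cat_probs = np.array([5, 15, 16, 6, 0], dtype=float)  # NT VU EN CR EX mix
    cat_probs /= cat_probs.sum()

    rows = []
    for label, state in tip_states.items():
        concern = bool(state)
        log_len = rng.normal(math.log(30.0), 0.5) - (size_effect * 0.5 if concern else 0)
        trophic = rng.normal(3.2, 0.45) - (trophic_effect * 0.45 if concern else 0)
        log_lon = rng.normal(math.log(8.0), 0.6) - (longevity_effect * 0.6 if concern else 0)
        if concern:
            category = IUCN_CONCERN[rng.choice(len(cat_probs), p=cat_probs)]
            reasons = [r for r in LISTING_REASONS
                       if rng.random() < reason_probs.get(r, 0.0)]
            if not reasons:
                reasons = ["habitat"]
        else:
            category = "DD" if rng.random() < 0.05 else "LC"
            reasons = []
        rows.append(dict(species=label,
                         max_length=math.exp(log_len),
                         trophic_level=trophic,
                         longevity=math.exp(log_lon),
                         freshwater=bool(rng.random() < freshwater_fraction),
                         iucn_category=category,
                         listing_reasons=";".join(reasons)))
    return pd.DataFrame(rows), tree, tip_states


class _DendropyRng:
    """Adapter exposing the stdlib ``random.Random`` surface dendropy uses
    on top of a numpy Generator, so one seeded source drives everything."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma)) if sigma else float(mu)

    def randrange(self, *args):
        return int(self._rng.integers(*args)) if len(args) > 1 \
            else int(self._rng.integers(args[0]))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)
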