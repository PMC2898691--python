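"""Rejection-ABC over divergence-timing scenarios.

Four hypotheses about when U.S. weedy rice split from its crop progenitor
are encoded as scenarios over the founder-bottleneck model:

* ``founding_us`` — divergence at the time of founding in the U.S.
  (tau_s = tau_f);
* ``post_domestication`` — divergence in Asia after domestication
  (tau_f < tau_s <= 12,000 ybp);
* ``domestication`` — divergence at the time of domestication
  (tau_s fixed at 12,000 ybp by default);
* ``pre_domestication`` — divergence from wild populations before
  domestication (12,000 <= tau_s <= 50,000 ybp).

Timing parameters and the progenitor size ratio are drawn from a discrete
prior grid; the two size ratios (eta_r/eta_c and eta_b/eta_r) are drawn
continuously. Each draw is simulated, summarized by the eight pooled
statistics, and accepted when its standardized Euclidean distance to the
observed vector falls within the tolerance. The proportion of accepted
simulations is the scenario's approximate likelihood, so the
standardization constants and tolerance are shared across scenarios.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .demography_sim import (
    CoalescentConfig,
    DemographicModel,
    ScalingConfig,
    simulate_dataset,
)
from .popgen_stats import STAT_NAMES, SummaryVector, summary_vector_from_arrays

__all__ = [
    "ScenarioSpec",
    "PriorGrid",
    "ReferenceTable",
    "ABCResult",
    "LikelihoodSurface",
    "SCENARIO_NAMES",
    "default_scenarios",
    "build_prior_grid",
    "simulate_reference_table",
    "run_abc",
    "approximate_likelihood",
    "posterior_density",
    "likelihood_surface",
    "rejection_sample",
]

SCENARIO_NAMES = (
    "founding_us", "post_domestication", "domestication", "pre_domestication",
)

#: Domestication of Asian rice, years before present.
DOMESTICATION_YBP = 12_000.0

PARAM_NAMES = ("tau_g", "tau_f", "tau_s", "eta_c_ratio",
               "eta_r_over_eta_c", "eta_b_over_eta_r")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One divergence-timing hypothesis with its prior ranges.

    tau_g (expansion) is bounded by the onset of rapid rice-belt expansion
    (~140 years before a ~2008 sampling date); tau_f (U.S. founding) by the
    introduction of cultivated rice (< 400 ybp); eta_c is gridded as a
    fraction of the reference size 4N (range from the observed
    crop-to-wild silent diversity ratio); the size ratios eta_r/eta_c and
    eta_b/eta_r are uniform on (0, 1].
    """

    name: str
    tau_g_max: float = 140.0
    tau_f_max: float = 400.0
    tau_s_range: tuple[float, float] | None = None   # None: tied to tau_f
    eta_c_ratio_range: tuple[float, float] = (0.1, 0.7)

    def __post_init__(self) -> None:
        if self.tau_g_max <= 0 or self.tau_f_max <= 0:
            raise ConfigError("timing ranges must be positive")
        if self.tau_s_range is not None:
            lo, hi = self.tau_s_range
            if hi < lo:
                raise ConfigError(f"{self.name}: empty tau_s range")

    @property
    def ties_split_to_founding(self) -> bool:
        return self.tau_s_range is None


def default_scenarios(tau_g_max: float = 140.0,
                      tau_f_max: float = 400.0) -> dict[str, ScenarioSpec]:
    return {
        "founding_us": ScenarioSpec("founding_us", tau_g_max, tau_f_max,
                                    tau_s_range=None),
        "post_domestication": ScenarioSpec(
            "post_domestication", tau_g_max, tau_f_max,
            tau_s_range=(tau_f_max, DOMESTICATION_YBP)),
        "domestication": ScenarioSpec(
            "domestication", tau_g_max, tau_f_max,
            tau_s_range=(DOMESTICATION_YBP, DOMESTICATION_YBP)),
        "pre_domestication": ScenarioSpec(
            "pre_domestication", tau_g_max, tau_f_max,
            tau_s_range=(DOMESTICATION_YBP, 50_000.0)),
    }


@dataclass(frozen=True)
class PriorGrid:
    """Discrete grid cells over the timing parameters and eta_c ratio.

    Each cell is a (tau_g, tau_f, tau_s, eta_c_ratio) tuple; invalid
    orderings (tau_f <= tau_g or tau_s < tau_f) are excluded and counted.
    The two size ratios are drawn uniformly per simulation, not gridded.
    """

    scenario: str
    cells: tuple[tuple[float, float, float, float], ...]
    n_excluded: int

    def __len__(self) -> int:
        return len(self.cells)


def _grid_points(lo: float, hi: float, k: int, open_lower: bool) -> np.ndarray:
    """k points covering (lo, hi]; the lower endpoint is excluded by
    shifting half a step in when the range is open below."""
    if k < 2:
        raise ConfigError("grid resolution must be >= 2 per parameter")
    if hi == lo:
        return np.array([hi])
    pts = np.linspace(lo, hi, k + 1)[1:] if open_lower else np.linspace(lo, hi, k)
    return pts


def build_prior_grid(spec: ScenarioSpec,
                     resolution: dict | int = 5) -> PriorGrid:
    """Lay out the scenario's discrete prior grid.

    ``resolution`` is either one count for every gridded parameter or a
    dict with keys tau_g, tau_f, tau_s, eta_c.
    """
    if isinstance(resolution, int):
        res = {k: resolution for k in ("tau_g", "tau_f", "tau_s", "eta_c")}
    else:
        res = dict(resolution)
    tau_g_pts = _grid_points(0.0, spec.tau_g_max, res["tau_g"], open_lower=True)
    tau_f_pts = _grid_points(0.0, spec.tau_f_max, res["tau_f"], open_lower=True)
    eta_pts = _grid_points(*spec.eta_c_ratio_range, res["eta_c"],
                           open_lower=False)
    if spec.ties_split_to_founding:
        tau_s_pts = None
    else:
        lo, hi = spec.tau_s_range
        tau_s_pts = _grid_points(lo, hi, res["tau_s"], open_lower=False)

    cells, excluded = [], 0
    for tg, tf, ec in itertools.product(tau_g_pts, tau_f_pts, eta_pts):
        if tf <= tg:
            excluded += len(tau_s_pts) if tau_s_pts is not None else 1
            continue
        if tau_s_pts is None:
            cells.append((float(tg), float(tf), float(tf), float(ec)))
        else:
            for ts in tau_s_pts:
                if ts < tf:
                    excluded += 1
                    continue
                cells.append((float(tg), float(tf), float(ts), float(ec)))
    if not cells:
        raise ConfigError(f"{spec.name}: prior grid is empty")
    return PriorGrid(spec.name, tuple(cells), excluded)


# ---------------------------------------------------------------------------
# Reference-table simulation


@dataclass
class ReferenceTable:
    """Simulated parameter draws and their summary vectors, per scenario.

    The table depends only on the priors and simulation settings, never on
    observed data, so one table can serve many observed datasets.
    """

    scenarios: tuple[str, ...]
    params: dict[str, np.ndarray]        # scenario -> (sims, 6) PARAM_NAMES
    stats: dict[str, np.ndarray]         # scenario -> (sims, 8) STAT_NAMES
    scaling: ScalingConfig
    config: CoalescentConfig
    seed: int

    def pooled_stats(self) -> np.ndarray:
        return np.vstack([self.stats[s] for s in self.scenarios])


def _draw_parameters(grid: PriorGrid, n_sims: int,
                     rng: np.random.Generator,
                     size_floor: float) -> np.ndarray:
    """Cycle deterministically through grid cells; draw the two size ratios
    uniformly on (floor, 1] per simulation."""
    out = np.empty((n_sims, 6))
    n_cells = len(grid.cells)
    for i in range(n_sims):
        tg, tf, ts, ec = grid.cells[i % n_cells]
        r_ratio = rng.uniform(size_floor, 1.0)
        b_ratio = rng.uniform(size_floor, 1.0)
        out[i] = (tg, tf, ts, ec, r_ratio, b_ratio)
    return out


def model_from_params(params, scaling: ScalingConfig,
                      weed_selfing: bool = True) -> DemographicModel:
    """Instantiate the founder model from one parameter draw, flooring
    sizes at one individual."""
    tg, tf, ts, ec, r_ratio, b_ratio = params
    eta_c = max(ec * scaling.n_ref, 1.0)
    eta_r = max(r_ratio * eta_c, 1.0)
    eta_b = max(b_ratio * eta_r, 1.0)
    return DemographicModel(eta_c=eta_c, eta_b=eta_b, eta_r=eta_r,
                            tau_s=ts, tau_f=tf, tau_g=tg,
                            weed_selfing=weed_selfing)


def simulate_reference_table(
    scenarios: dict[str, ScenarioSpec],
    sims_per_scenario: int,
    scaling: ScalingConfig,
    config: CoalescentConfig,
    seed: int,
    grid_resolution: dict | int = 5,
    size_floor: float = 1e-4,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``sims_per_scenario`` datasets per scenario and summarize
    each with the eight pooled statistics.

    Per-scenario random streams are derived from ``seed`` and the scenario
    name, so acceptance sets do not depend on the order scenarios are run.
    """
    if sims_per_scenario < 1:
        raise ConfigError("sims_per_scenario must be >= 1")
    names = tuple(scenarios)
    params: dict[str, np.ndarray] = {}
    stats: dict[str, np.ndarray] = {}
    for name in names:
        spec = scenarios[name]
        key = int(np.frombuffer(name.encode().ljust(8, b"\0")[:8],
                                dtype=np.uint32)[0])
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(key,)))
        grid = build_prior_grid(spec, grid_resolution)
        draws = _draw_parameters(grid, sims_per_scenario, rng, size_floor)
        svecs = np.empty((sims_per_scenario, len(STAT_NAMES)))
        for i in range(sims_per_scenario):
            model = model_from_params(draws[i], scaling)
            sim_seed = int(rng.integers(2**31 - 1))
            ds = simulate_dataset(model, scaling, config, sim_seed)
            svecs[i] = summary_vector_from_arrays(
                ds.locus_arrays(), config.n_weed, ds.total_length_bp)
            if progress and (i + 1) % 1000 == 0:
                print(f"  {name}: {i + 1}/{sims_per_scenario} simulations")
        params[name] = draws
        stats[name] = svecs
    return ReferenceTable(names, params, stats, scaling, config, seed)


# ---------------------------------------------------------------------------
# Rejection


@dataclass
class ABCResult:
    """Acceptance counts and accepted draws for one observed dataset."""

    observed: np.ndarray                    # the 8 observed statistics
    scale: np.ndarray                       # per-statistic standardization
    tolerance: float                        # standardized distance threshold
    n_simulated: dict[str, int]
    n_accepted: dict[str, int]
    accepted_params: dict[str, np.ndarray]  # scenario -> (k, 6)
    accepted_distances: dict[str, np.ndarray]

    @property
    def likelihoods(self) -> dict[str, float]:
        return {s: self.n_accepted[s] / self.n_simulated[s]
                for s in self.n_simulated}

    def best_scenario(self) -> str:
        return max(self.likelihoods, key=lambda s: (self.likelihoods[s], s))


def robust_scale(pooled_stats: np.ndarray) -> np.ndarray:
    """Per-statistic median absolute deviation over a cross-scenario pilot
    pool; statistics with zero spread are standardized by 1."""
    med = np.median(pooled_stats, axis=0)
    mad = np.median(np.abs(pooled_stats - med), axis=0)
    zero = mad == 0
    if np.any(zero):
        warnings.warn(
            f"zero pilot variance for statistics "
            f"{[STAT_NAMES[i] for i in np.flatnonzero(zero)]}; scaled by 1",
            stacklevel=2)
        mad = np.where(zero, 1.0, mad)
    return mad


def rejection_sample(observed: np.ndarray, stats: np.ndarray,
                     scale: np.ndarray, tolerance: float) -> np.ndarray:
    """Indices of simulations whose standardized Euclidean distance to the
    observed vector is within the tolerance."""
    z = (stats - observed[None, :]) / scale[None, :]
    dist = np.sqrt(np.sum(z * z, axis=1))
    if math.isinf(tolerance):
        return np.arange(len(stats))
    return np.flatnonzero(dist <= tolerance)


def _distances(observed, stats, scale):
    z = (stats - observed[None, :]) / scale[None, :]
    return np.sqrt(np.sum(z * z, axis=1))


def run_abc(observed: SummaryVector | np.ndarray,
            table: ReferenceTable,
            tolerance: float,
            tolerance_mode: str = "absolute",
            transform: str = "log1p") -> ABCResult:
    """Rejection step against a simulated reference table.

    ``tolerance_mode`` 'absolute' accepts at a fixed standardized distance;
    'pooled-quantile' reads ``tolerance`` as a fraction and derives the
    absolute threshold as that quantile of distances over the pooled
    cross-scenario table (one shared threshold, so acceptance proportions
    remain comparable across scenarios).

    ``transform`` 'log1p' applies the variance-stabilizing log(1+x) to the
    summaries before standardization — the statistics are pooled counts
    (or near-counts), whose sampling noise grows with their mean, and the
    transform keeps low-count contrasts from being swamped by the spread
    of the large counts; 'none' standardizes the raw statistics.
    """
    obs = observed.to_array() if isinstance(observed, SummaryVector) else \
        np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ConfigError("observed summary vector must be finite")
    if transform == "log1p":
        obs = np.log1p(obs)
        pooled = np.log1p(table.pooled_stats())
        stats_by_scenario = {s: np.log1p(table.stats[s])
                             for s in table.scenarios}
    elif transform == "none":
        pooled = table.pooled_stats()
        stats_by_scenario = dict(table.stats)
    else:
        raise ConfigError(f"unknown transform {transform!r}")
    scale = robust_scale(pooled)

    if tolerance_mode == "pooled-quantile":
        if not (0 < tolerance <= 1):
            raise ConfigError("pooled-quantile tolerance must be in (0, 1]")
        pooled_d = _distances(obs, pooled, scale)
        threshold = float(np.quantile(pooled_d, tolerance))
    elif tolerance_mode == "absolute":
        threshold = float(tolerance)
    else:
        raise ConfigError(f"unknown tolerance mode {tolerance_mode!r}")

    n_sim, n_acc, acc_p, acc_d = {}, {}, {}, {}
    for name in table.scenarios:
        d = _distances(obs, stats_by_scenario[name], scale)
        if math.isinf(threshold):
            idx = np.arange(len(d))
        else:
            idx = np.flatnonzero(d <= threshold)
        n_sim[name] = len(d)
        n_acc[name] = len(idx)
        acc_p[name] = table.params[name][idx]
        acc_d[name] = d[idx]
    return ABCResult(obs, scale, threshold, n_sim, n_acc, acc_p, acc_d)


def approximate_likelihood(result: ABCResult, scenario: str) -> float:
    """Accepted / simulated for one scenario (exact integer ratio)."""
    if scenario not in result.n_simulated:
        raise KeyError(f"scenario {scenario!r} was not simulated")
    from fractions import Fraction
    return float(Fraction(result.n_accepted[scenario],
                          result.n_simulated[scenario]))


# ---------------------------------------------------------------------------
# Posterior summaries


@dataclass
class LikelihoodSurface:
    """2-D acceptance density over (eta_r/eta_c, bottleneck intensity)."""

    x_edges: np.ndarray        # eta_r / eta_c
    y_edges: np.ndarray        # percent decline during the bottleneck
    density: np.ndarray        # (len(y)-1, len(x)-1)
    empty: bool

    def mode(self) -> tuple[float, float]:
        """Cell-center (x, y) of the highest-density cell."""
        if self.empty:
            raise ValueError("empty surface has no mode")
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        x = 0.5 * (self.x_edges[ix] + self.x_edges[ix + 1])
        y = 0.5 * (self.y_edges[iy] + self.y_edges[iy + 1])
        return float(x), float(y)


def _accepted_column(result: ABCResult, scenario: str, parameter: str):
    if scenario not in result.accepted_params:
        raise KeyError(f"scenario {scenario!r} was not simulated")
    if parameter not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {parameter!r}; "
                       f"expected one of {PARAM_NAMES}")
    draws = result.accepted_params[scenario]
    return draws[:, PARAM_NAMES.index(parameter)]


def posterior_density(result: ABCResult, scenario: str, parameter: str,
                      bins: int = 20,
                      prior_range: tuple[float, float] | None = None):
    """Histogram density of one parameter over the accepted draws.

    Returns (edges, density, empty_flag); density integrates to 1 whenever
    any draw was accepted.
    """
    vals = _accepted_column(result, scenario, parameter)
    if len(vals) == 0:
        warnings.warn(f"{scenario}: no accepted draws", stacklevel=2)
        edges = np.linspace(*(prior_range or (0.0, 1.0)), bins + 1)
        return edges, np.zeros(bins), True
    rng_lo, rng_hi = prior_range if prior_range else (vals.min(), vals.max())
    if rng_hi == rng_lo:           # all draws identical: single-bin spike
        rng_hi = rng_lo + max(abs(rng_lo), 1.0) * 1e-9
    density, edges = np.histogram(vals, bins=bins, range=(rng_lo, rng_hi),
                                  density=True)
    return edges, density, False


def likelihood_surface(result: ABCResult, scenario: str,
                       bins: tuple[int, int] = (10, 10)) -> LikelihoodSurface:
    """Acceptance density over current-size ratio (eta_r/eta_c) and
    bottleneck intensity, 100*(1 - eta_b/eta_r), clipped to [0, 100]."""
    x = _accepted_column(result, scenario, "eta_r_over_eta_c")
    b_ratio = _accepted_column(result, scenario, "eta_b_over_eta_r")
    y = np.clip(100.0 * (1.0 - b_ratio), 0.0, 100.0)
    x_edges = np.linspace(0.0, 1.0, bins[0] + 1)
    y_edges = np.linspace(0.0, 100.0, bins[1] + 1)
    if len(x) == 0:
        warnings.warn(f"{scenario}: no accepted draws", stacklevel=2)
        return LikelihoodSurface(
            x_edges, y_edges, np.zeros((bins[1], bins[0])), True)
    density, _, _ = np.histogram2d(y, x, bins=(y_edges, x_edges))
    return LikelihoodSurface(x_edges, y_edges, density, False)
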