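"""Monte Carlo population viability analysis from ordinal census classes.

Each taxon is projected cell by cell over decadal steps,

    N_i(t+1) = N_i(t) * r_i(t),

with the initial size drawn log-uniformly within the recorded size class and
the decadal rate of change r_i(t) drawn, independently at every step of every
replication, from one of two frequency-weighted pools of observed change
entities: pool 1 (the taxon's records across all its cells) with probability
``p_pool1``, otherwise pool 2 (all taxa's records within the cell).  A cell is
locally extinct once N < 1; the taxon is extinct when every cell is.  The
cumulative extinction probability per decade is the fraction of replications
extinct by then.

Log-uniform interval draws make the expected draw equal to the geometric mean
of the class bounds; the open-ended size classes contribute their point values
(1000 and 10 000) exactly.  A population recorded extinct at the second census
is assigned the forced rate 1/10 000, which removes any first-census size
class in a single step.

Cells with a second-census size start the projection there and run ten steps;
cells with only a first-census size start a decade earlier and run eleven, the
extra step acting as burn-in so that all populations end at the same time.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import RateClass, SizeClass
from .records import ChangeEntity, PopulationRecord, RatePools, build_rate_pools

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ExtinctionTrajectory",
    "ExtinctionRiskModel",
    "PVAResults",
    "run_pva",
    "draw_initial_size",
    "draw_rate",
    "select_pool",
    "expected_extinction_time",
]

_NEVER = np.iinfo(np.int64).max


@dataclass(frozen=True)
class ScenarioConfig:
    """Tunable parameters of one PVA scenario.

    ``p_pool1`` is the a-priori probability of drawing each decadal rate from
    the taxon-wise pool rather than the cell-wise pool (the scenario axis of
    the projection: 1.0 = "what happened here may happen there", 0.0 = "what
    happened here will happen here again").
    """

    p_pool1: float = 1.0
    n_replications: int = 1000
    n_steps: int = 10
    step_years: float = 10.0
    forced_extinction_rate: float = 1.0 / 10_000
    threatened_threshold: float = 0.10
    waiting_time_horizon: float = 500.0
    tail_hazard_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_pool1 <= 1.0:
            raise ValueError("p_pool1 must lie in [0, 1]")
        if self.n_steps < 1 or self.n_replications < 1:
            raise ValueError("n_steps and n_replications must be >= 1")
        if not 0.0 < self.threatened_threshold < 1.0:
            raise ValueError("threatened_threshold must lie in (0, 1)")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class ExtinctionTrajectory:
    """Per-decade cumulative extinction probability of one taxon."""

    taxon_id: str
    cum_prob: np.ndarray  # indexed by decade 1..n_steps
    t_expected: float  # restricted mean time to extinction, years

    def __post_init__(self):
        self.cum_prob = np.asarray(self.cum_prob, dtype=float)
        if np.any(np.diff(self.cum_prob) < -1e-12):
            raise ValueError("cumulative extinction probability must be non-decreasing")


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------


def draw_initial_size(cls: SizeClass, rng: np.random.Generator, size=None):
    """Log-uniform draw within a size class; open classes give their point value."""
    if cls.is_extinct:
        raise ValueError("cannot draw an initial size from the 'extinct' class")
    lo, hi = cls.bounds()
    if lo == hi:
        return lo if size is None else np.full(size, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _log_uniform(lo: float, hi: float, rng: np.random.Generator) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def draw_rate(
    entity: ChangeEntity,
    rng: np.random.Generator,
    forced_extinction_rate: float = 1.0 / 10_000,
) -> float:
    """One decadal rate of change implied by a change entity.

    Class pairs divide an independent log-uniform draw from the second-census
    class by one from the first-census class; decline scores draw log-uniformly
    within the rate class; forced extinctions return the forced rate exactly.
    """
    if entity.kind == "forced_extinction":
        return forced_extinction_rate
    if entity.kind == "class_pair":
        first = _log_uniform(*entity.first_class.bounds(), rng)
        second = _log_uniform(*entity.second_class.bounds(), rng)
        return second / first
    if entity.kind == "decline_score":
        return _log_uniform(*entity.rate_class.bounds(), rng)
    raise ValueError(f"unknown entity kind {entity.kind!r}")


def _effective_pools(taxon_id, cell_id, pools: RatePools):
    """Pool-1-first and pool-2-first entity lists after the fallback chain.

    An empty chosen pool falls back to the other pool, then to the global
    pool (the rule covering taxa with size information but no computable rate
    of change of their own).
    """
    p1 = pools.pool1.get(taxon_id, [])
    p2 = pools.pool2.get(cell_id, [])
    eff1 = p1 or p2 or pools.global_pool
    eff2 = p2 or p1 or pools.global_pool
    if not eff1:
        raise ValueError("all rate pools are empty: dataset has no change information")
    return eff1, eff2


def select_pool(
    taxon_id: str,
    cell_id: str,
    pools: RatePools,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> list:
    """The entity list one step's rate will be drawn from."""
    eff1, eff2 = _effective_pools(taxon_id, cell_id, pools)
    return eff1 if rng.random() < cfg.p_pool1 else eff2


# ---------------------------------------------------------------------------
# vectorized simulation internals
# ---------------------------------------------------------------------------


def _entity_log_bounds(
    entities: Sequence[ChangeEntity], forced_rate: float
) -> np.ndarray:
    """(n, 4) array of log bounds; log r = LU(cols 2:4) - LU(cols 0:2)."""
    out = np.zeros((len(entities), 4))
    for i, ent in enumerate(entities):
        if ent.kind == "class_pair":
            lo1, hi1 = ent.first_class.bounds()
            lo2, hi2 = ent.second_class.bounds()
            out[i] = (np.log(lo1), np.log(hi1), np.log(lo2), np.log(hi2))
        elif ent.kind == "decline_score":
            lo, hi = ent.rate_class.bounds()
            out[i] = (0.0, 0.0, np.log(lo), np.log(hi))
        elif ent.kind == "forced_extinction":
            lf = np.log(forced_rate)
            out[i] = (0.0, 0.0, lf, lf)
        else:  # pragma: no cover
            raise ValueError(ent.kind)
    return out


def _sample_log_rates(
    mat1: np.ndarray,
    mat2: np.ndarray,
    p_pool1: float,
    shape: tuple,
    rng: np.random.Generator,
) -> np.ndarray:
    """i.i.d. log rates for every (replication, step) draw."""
    use1 = rng.random(shape) < p_pool1
    idx1 = rng.integers(0, len(mat1), size=shape)
    idx2 = rng.integers(0, len(mat2), size=shape)
    rows = np.where(use1[..., None], mat1[idx1], mat2[idx2])
    u_first = rng.random(shape)
    u_second = rng.random(shape)
    log_first = rows[..., 0] + (rows[..., 1] - rows[..., 0]) * u_first
    log_second = rows[..., 2] + (rows[..., 3] - rows[..., 2]) * u_second
    return log_second - log_first


def _classify_cell(rec: PopulationRecord) -> tuple[str, SizeClass | None]:
    """How a record's cell enters the simulation.

    Returns ("sim", start_class) for a cell starting at the second census,
    ("burnin", start_class) for a first-census start (one extra step),
    ("dead0", None) for an observed extinction with a known first-census size
    (the forced rate removes it before the common clock), or ("ignore", None)
    for cells with no usable starting size.
    """
    if rec.size_second is not None and not rec.size_second.is_extinct:
        return "sim", rec.size_second
    if rec.size_second is not None and rec.size_second.is_extinct:
        if rec.size_first is not None:
            return "dead0", None
        return "ignore", None
    if rec.size_first is not None:
        return "burnin", rec.size_first
    return "ignore", None


def _simulate_cell_log_paths(
    start_class: SizeClass,
    n_steps: int,
    mat1: np.ndarray,
    mat2: np.ndarray,
    p_pool1: float,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(reps,) 1-based step index of local extinction (``_NEVER`` if alive)."""
    log_n0 = np.log(draw_initial_size(start_class, rng, size=n_reps))
    log_r = _sample_log_rates(mat1, mat2, p_pool1, (n_reps, n_steps), rng)
    path = log_n0[:, None] + np.cumsum(log_r, axis=1)
    dead = path < 0.0  # N < 1
    any_dead = dead.any(axis=1)
    first = dead.argmax(axis=1) + 1
    return np.where(any_dead, first, _NEVER)


def simulate_taxon(
    taxon_records: Sequence[PopulationRecord],
    pools: RatePools,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> ExtinctionTrajectory | None:
    """Extinction trajectory of one taxon, or None if it cannot be simulated.

    Simulation covers every cell with a usable starting size; the taxon's
    extinction decade in a replication is the last decade at which any cell
    still held N >= 1.  Returns None (flagged upstream) when no cell offers a
    starting size.
    """
    taxon_id = taxon_records[0].taxon_id
    ext_decade = None  # per-replication taxon extinction decade
    n_cells_used = 0
    for rec in taxon_records:
        role, start = _classify_cell(rec)
        if role == "ignore":
            continue
        n_cells_used += 1
        if role == "dead0":
            cell_decade = np.zeros(cfg.n_replications, dtype=np.int64)
        else:
            mat1_entities, mat2_entities = _effective_pools(
                taxon_id, rec.cell_id, pools
            )
            mat1 = _entity_log_bounds(mat1_entities, cfg.forced_extinction_rate)
            mat2 = _entity_log_bounds(mat2_entities, cfg.forced_extinction_rate)
            burnin = role == "burnin"
            steps = cfg.n_steps + (1 if burnin else 0)
            ext_step = _simulate_cell_log_paths(
                start, steps, mat1, mat2, cfg.p_pool1, cfg.n_replications, rng
            )
            # burn-in cells map step k to decade k-1 (decade 0 precedes the clock)
            cell_decade = np.where(
                ext_step == _NEVER, _NEVER, ext_step - (1 if burnin else 0)
            )
        ext_decade = (
            cell_decade if ext_decade is None else np.maximum(ext_decade, cell_decade)
        )
    if ext_decade is None:
        logger.warning("taxon %s has no simulatable cell; excluded", taxon_id)
        return None
    decades = np.arange(1, cfg.n_steps + 1)
    cum_prob = (ext_decade[None, :] <= decades[:, None]).mean(axis=1)
    t_exp = expected_extinction_time(cum_prob, cfg)
    return ExtinctionTrajectory(taxon_id, cum_prob, t_exp)


# ---------------------------------------------------------------------------
# expected waiting time to extinction
# ---------------------------------------------------------------------------


def expected_extinction_time(
    cum_prob: np.ndarray | Sequence[float], cfg: ScenarioConfig | None = None
) -> float:
    """Restricted mean time to extinction, in years, from a decadal CDF.

    Survival beyond the simulated horizon is extrapolated geometrically with
    the average per-decade hazard of the simulated window,
    h = 1 - (1 - c_n)^(1/n), floored at ``tail_hazard_floor`` so the mean is
    finite, and the mean is truncated at ``waiting_time_horizon``.  This tail
    keeps T monotone decreasing under any pointwise increase of the CDF.  An
    identically-zero CDF returns the horizon (maximal waiting time).
    """
    cfg = cfg or ScenarioConfig()
    c = np.asarray(cum_prob, dtype=float)
    n = len(c)
    step = cfg.step_years
    horizon_decades = cfg.waiting_time_horizon / step
    if np.all(c <= 0.0):
        return float(cfg.waiting_time_horizon)
    s = np.concatenate([[1.0], 1.0 - c])  # survival at decades 0..n
    if horizon_decades <= n:
        return float(step * s[: int(horizon_decades)].sum())
    h_tail = 1.0 - (1.0 - c[-1]) ** (1.0 / n)
    h_tail = max(h_tail, cfg.tail_hazard_floor)
    head = s[:n].sum()
    m = horizon_decades - n  # tail decades
    if np.isinf(m):
        tail = s[n] / h_tail
    else:
        tail = s[n] * (1.0 - (1.0 - h_tail) ** m) / h_tail
    return float(step * (head + tail))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def _taxon_rng(seed: int, taxon_id: str) -> np.random.Generator:
    """Taxon-specific stream, stable under record reordering."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(taxon_id.encode())])
    )


class ExtinctionRiskModel:
    """National-scale PVA over a set of census records.

    Parameters
    ----------
    records : iterable of PopulationRecord
    config : ScenarioConfig, optional
    pools : RatePools, optional
        Prebuilt pools; rebuilt from the records when omitted.
    """

    def __init__(
        self,
        records: Iterable[PopulationRecord],
        config: ScenarioConfig | None = None,
        pools: RatePools | None = None,
    ):
        self.records = list(records)
        if not self.records:
            raise ValueError("no census records supplied")
        self.config = config or ScenarioConfig()
        self.pools = pools if pools is not None else build_rate_pools(self.records)
        self._by_taxon: dict[str, list[PopulationRecord]] = {}
        for rec in self.records:
            self._by_taxon.setdefault(rec.taxon_id, []).append(rec)

    @classmethod
    def from_csv(cls, records_path, config: ScenarioConfig | None = None):
        from .records import read_census_table

        return cls(read_census_table(records_path), config=config)

    @property
    def taxa(self) -> list[str]:
        return list(self._by_taxon)

    def fit(self, seed: int | None = None) -> "PVAResults":
        """Run the Monte Carlo projection for every taxon."""
        cfg = self.config if seed is None else self.config.with_(seed=seed)
        trajectories: dict[str, ExtinctionTrajectory] = {}
        unsimulated: list[str] = []
        for taxon_id, recs in self._by_taxon.items():
            rng = _taxon_rng(cfg.seed, taxon_id)
            traj = simulate_taxon(recs, self.pools, cfg, rng)
            if traj is None:
                unsimulated.append(taxon_id)
            else:
                trajectories[taxon_id] = traj
        return PVAResults(self, cfg, trajectories, unsimulated)


class PVAResults:
    """Fitted extinction trajectories and the quantities derived from them."""

    def __init__(
        self,
        model: ExtinctionRiskModel,
        config: ScenarioConfig,
        trajectories: dict[str, ExtinctionTrajectory],
        unsimulated: list[str],
    ):
        self.model = model
        self.config = config
        self.trajectories = trajectories
        self.unsimulated = unsimulated

    @property
    def n_taxa(self) -> int:
        return len(self.trajectories)

    @property
    def loss_curve(self) -> np.ndarray:
        """Expected cumulative number of extinct taxa per decade."""
        if not self.trajectories:
            return np.zeros(self.config.n_steps)
        return np.sum([t.cum_prob for t in self.trajectories.values()], axis=0)

    @property
    def threatened(self) -> list[str]:
        """Taxa with P(extinct within the simulated century) >= threshold."""
        thr = self.config.threatened_threshold
        return sorted(
            tid
            for tid, traj in self.trajectories.items()
            if traj.cum_prob[-1] >= thr
        )

    @property
    def expected_times(self) -> dict[str, float]:
        return {tid: t.t_expected for tid, t in self.trajectories.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, decade, p)
            for tid, traj in self.trajectories.items()
            for decade, p in enumerate(traj.cum_prob, start=1)
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "decade", "cum_prob"])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Population viability analysis (Monte Carlo)",
            "=" * 45,
            f"taxa simulated      : {self.n_taxa}",
            f"taxa unsimulatable  : {len(self.unsimulated)}",
            f"replications        : {cfg.n_replications}",
            f"p_pool1             : {cfg.p_pool1}",
            f"horizon             : {cfg.n_steps * cfg.step_years:.0f} years",
            f"expected losses     : {self.loss_curve[-1]:.1f} taxa",
            f"threatened (P>={cfg.threatened_threshold:.2f}) : "
            f"{len(self.threatened)} taxa",
        ]
        return "\n".join(lines)


def run_pva(
    records: Iterable[PopulationRecord],
    config: ScenarioConfig | None = None,
    pools: RatePools | None = None,
) -> PVAResults:
    """Convenience wrapper: build the model and fit it in one call."""
    return ExtinctionRiskModel(records, config=config, pools=pools).fit()
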