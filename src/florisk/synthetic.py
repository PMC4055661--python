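"""Synthetic census datasets with known ground truth.

The original national census database is not public, so downstream stages are
exercised on generated data that reproduces the structure the analysis
assumes: heavy-tailed range sizes (most threatened taxa occupy very few map
cells), a mixture of record-completeness types (both censuses / one census
plus a decline score / one census only / a decline score only), decline
probability decreasing with protected-area coverage, and pressure labels
whose composition shifts with protection.

Range sizes follow a discretized lognormal over cells-per-taxon, truncated at
the number of cells; with the default shape (mu=1.445, sigma=1.518 on the log
scale) about 18% of taxa are single-cell and about two-thirds occupy fewer
than ten cells.  The completeness mixture defaults to the relative frequencies
of the four record types in the national census (9115 : 4755 : 9600 : 1413).

The decline model is mechanistic: a population "would decline" with a
cell-specific probability (the baseline log-odds plus a per-cell habitat
quality random effect, so cells genuinely differ in severity); if it would,
protection rescues it with probability ``protection_effect * pa_proportion``.
Under this mechanism the
saved-fraction conservation effectiveness at full coverage equals
``protection_effect`` exactly, which is the generator's recoverable ground
truth.  Declining populations receive a latent decadal rate drawn from the
declining rate classes; stable ones from the increase class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import RateClass, SizeClass
from .records import CellAttributes, PopulationRecord

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "generate_dataset",
    "make_worked_fixture",
    "worked_fixture_cells",
    "sample_decline_observations",
    "range_size_pmf",
]

#: relative frequencies of the four record-information types
#: (both censuses, one census + decline, one census only, decline only)
COMPLETENESS_MIX_DEFAULT = (9115.0, 4755.0, 9600.0, 1413.0)

DECLINE_CLASS_LABELS = ("<1/100", "1/100-1/10", "1/10-1/2", "1/2-1")
#: frequency of the four declining rate classes among declining populations;
#: the censuses report no empirical distribution, so these are free parameters
#: (documented as such) skewed toward moderate decline.
DECLINE_CLASS_WEIGHTS = (0.05, 0.20, 0.40, 0.35)

PRESSURE_MENU_DEFAULT = (
    "development",
    "exploitation",
    "succession",
    "recreation",
    "herbivory",
    "wetland_drainage",
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic census dataset."""

    n_cells: int = 60
    n_taxa: int = 80
    range_size_mu: float = 1.445
    range_size_sigma: float = 1.518
    baseline_decline_prob: float = 0.6
    protection_effect: float = 0.6
    cell_severity_sd: float = 1.5
    completeness_mix: tuple = COMPLETENESS_MIX_DEFAULT
    pa_zero_fraction: float = 0.6
    pressure_menu: tuple = PRESSURE_MENU_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_taxa < 1:
            raise ValueError("scenario needs at least one cell and one taxon")
        if not 0.0 <= self.baseline_decline_prob <= 1.0:
            raise ValueError("baseline_decline_prob must lie in [0,1]")
        if not 0.0 <= self.protection_effect <= 1.0:
            raise ValueError("protection_effect must lie in [0,1]")
        if len(self.completeness_mix) != 4 or any(
            w < 0 for w in self.completeness_mix
        ):
            raise ValueError("completeness_mix needs four non-negative weights")
        if sum(self.completeness_mix) <= 0:
            raise ValueError("completeness_mix must have positive mass")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    scenario: SyntheticScenario
    pa_by_cell: dict
    range_sizes: dict  # taxon_id -> number of occupied cells
    latent: pd.DataFrame  # per population: declined flag, rate class, true rate

    @property
    def protection_effect(self) -> float:
        return self.scenario.protection_effect

    def true_extinction_cdf(
        self,
        taxon_id: str,
        n_steps: int = 10,
        n_replications: int = 2000,
        seed: int = 0,
    ) -> np.ndarray:
        """Extinction CDF implied by the latent generating process.

        Each population keeps redrawing decadal rates log-uniformly within its
        own latent rate class, starting from its true second-census abundance;
        this is the definition of the generating-process CDF, independent of
        the pooled PVA machinery.
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        sub = self.latent[self.latent["taxon_id"] == taxon_id]
        if sub.empty:
            raise KeyError(taxon_id)
        alive_any = np.zeros((n_replications, n_steps), dtype=bool)
        for _, row in sub.iterrows():
            if row["n_second"] < 1.0:
                continue  # already extinct at the second census
            cls = RateClass.parse(row["rate_class"])
            lo, hi = np.log(cls.lower), np.log(cls.upper)
            logr = rng.uniform(lo, hi, size=(n_replications, n_steps))
            path = np.log(row["n_second"]) + np.cumsum(logr, axis=1)
            # local extinction (N < 1) is absorbing
            alive_any |= np.minimum.accumulate(path, axis=1) >= 0.0
        return 1.0 - alive_any.mean(axis=0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protection_effect": self.scenario.protection_effect,
            "baseline_decline_prob": self.scenario.baseline_decline_prob,
            "n_cells": self.scenario.n_cells,
            "n_taxa": self.scenario.n_taxa,
            "seed": self.scenario.seed,
            "pa_by_cell": self.pa_by_cell,
            "range_sizes": self.range_sizes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def range_size_pmf(n_cells: int, mu: float, sigma: float) -> np.ndarray:
    """Discretized lognormal over 1..n_cells occupied cells."""
    k = np.arange(1, n_cells + 1, dtype=float)
    w = np.exp(-((np.log(k) - mu) ** 2) / (2.0 * sigma**2)) / k
    return w / w.sum()


def _classify_first(n: float) -> str:
    if n < 10:
        return "1-9"
    if n < 100:
        return "10-99"
    if n < 1000:
        return "100-999"
    return ">=1000"


def _classify_second(n: float) -> str:
    if n < 1:
        return "extinct"
    if n < 10:
        return "1-9"
    if n < 50:
        return "10-49"
    if n < 100:
        return "50-99"
    if n < 1000:
        return "100-999"
    if n < 10_000:
        return "1000-9999"
    return ">=10000"


def _pressure_weights(menu: tuple, pa: float) -> np.ndarray:
    # development-type pressures recede inside protected cells; biotic and
    # recreational pressures do not
    w = []
    for label in menu:
        if label in ("development", "exploitation", "wetland_drainage"):
            w.append(1.2 - pa)
        else:
            w.append(1.0)
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def generate_dataset(
    scn: SyntheticScenario,
) -> tuple[list[PopulationRecord], list[CellAttributes], GroundTruth]:
    """One reproducible synthetic census dataset.

    Returns records, cell attributes and the ground truth of the generating
    process.  A fixed seed yields an identical dataset; per-taxon sub-streams
    are derived deterministically so datasets are stable under reordering.
    """
    master = np.random.default_rng(np.random.SeedSequence([scn.seed, 0]))

    # --- cells -------------------------------------------------------------
    cell_ids = [f"c{i:04d}" for i in range(1, scn.n_cells + 1)]
    pa = np.where(
        master.random(scn.n_cells) < scn.pa_zero_fraction,
        0.0,
        master.random(scn.n_cells),
    )
    core = pa * master.beta(2.0, 5.0, size=scn.n_cells)
    # per-cell habitat quality: a random effect on the decline log-odds, so
    # cells genuinely differ in severity (some are refuges, some are sinks)
    base_logit = np.log(scn.baseline_decline_prob / (1.0 - scn.baseline_decline_prob))
    cell_logit = base_logit + scn.cell_severity_sd * master.standard_normal(
        scn.n_cells
    )
    p_would_cell = 1.0 / (1.0 + np.exp(-cell_logit))
    cells = [
        CellAttributes(cid, float(p), float(c))
        for cid, p, c in zip(cell_ids, pa, core)
    ]
    pa_by_cell = {c.cell_id: c.pa_proportion for c in cells}

    pmf = range_size_pmf(scn.n_cells, scn.range_size_mu, scn.range_size_sigma)
    mix = np.asarray(scn.completeness_mix, dtype=float)
    mix = mix / mix.sum()

    records: list[PopulationRecord] = []
    latent_rows = []
    range_sizes = {}
    for t_idx in range(scn.n_taxa):
        taxon_id = f"t{t_idx:04d}"
        rng = np.random.default_rng(np.random.SeedSequence([scn.seed, 1, t_idx]))
        k = int(rng.choice(scn.n_cells, p=pmf)) + 1
        range_sizes[taxon_id] = k
        occupied = rng.choice(scn.n_cells, size=k, replace=False)
        for ci in occupied:
            cid = cell_ids[ci]
            p_decline = p_would_cell[ci] * (1.0 - scn.protection_effect * pa[ci])
            declined = rng.random() < p_decline
            if declined:
                label = str(
                    rng.choice(DECLINE_CLASS_LABELS, p=DECLINE_CLASS_WEIGHTS)
                )
            else:
                label = ">1"
            cls = RateClass.parse(label)
            r = float(np.exp(rng.uniform(np.log(cls.lower), np.log(cls.upper))))
            n_first = float(np.exp(rng.uniform(0.0, np.log(1000.0))))
            n_second = n_first * r

            ctype = int(rng.choice(4, p=mix))
            size_first = size_second = decline_score = None
            if ctype == 0:  # both censuses
                size_first = SizeClass.parse(_classify_first(n_first), "first")
                size_second = SizeClass.parse(_classify_second(n_second), "second")
            elif ctype == 1:  # one census + decline score
                if rng.random() < 0.5:
                    size_first = SizeClass.parse(_classify_first(n_first), "first")
                else:
                    size_second = SizeClass.parse(
                        _classify_second(n_second), "second"
                    )
                decline_score = cls
            elif ctype == 2:  # one census only
                if rng.random() < 0.5:
                    size_first = SizeClass.parse(_classify_first(n_first), "first")
                else:
                    size_second = SizeClass.parse(
                        _classify_second(n_second), "second"
                    )
            else:  # decline score only
                decline_score = cls

            pressures: frozenset = frozenset()
            if declined:
                n_p = 1 + int(rng.random() < 0.4)
                weights = _pressure_weights(scn.pressure_menu, pa[ci])
                chosen = rng.choice(
                    len(scn.pressure_menu), size=n_p, replace=False, p=weights
                )
                pressures = frozenset(scn.pressure_menu[j] for j in chosen)

            records.append(
                PopulationRecord(
                    taxon_id=taxon_id,
                    cell_id=cid,
                    size_first=size_first,
                    size_second=size_second,
                    decline_score=decline_score,
                    pressures=pressures,
                )
            )
            latent_rows.append(
                (taxon_id, cid, bool(declined), label, r, n_first, n_second)
            )

    latent = pd.DataFrame(
        latent_rows,
        columns=[
            "taxon_id",
            "cell_id",
            "declined",
            "rate_class",
            "r",
            "n_first",
            "n_second",
        ],
    )
    truth = GroundTruth(scn, pa_by_cell, range_sizes, latent)
    return records, cells, truth


def sample_decline_observations(
    n: int,
    baseline_decline_prob: float = 0.6,
    protection_effect: float = 0.6,
    pa_zero_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary decline observations straight from the decline model.

    Populations would decline with the baseline probability; protection
    rescues a would-decliner with probability ``protection_effect * pa``.  The
    saved-fraction effectiveness of this process equals ``protection_effect``
    and its decline log-odds decrease monotonically in coverage, giving exact
    ground truth for the logistic-regression stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    pa = np.where(rng.random(n) < pa_zero_fraction, 0.0, rng.random(n))
    would = rng.random(n) < baseline_decline_prob
    saved = rng.random(n) < protection_effect * pa
    declined = would & ~saved
    return pd.DataFrame({"pa_proportion": pa, "declined": declined.astype(int)})


# ---------------------------------------------------------------------------
# hand-written worked fixture
# ---------------------------------------------------------------------------


def make_worked_fixture() -> tuple[list[PopulationRecord], list[CellAttributes]]:
    """A tiny analytically tractable dataset used by oracle tests.

    * ``doomed``       - one cell, recorded extinct at the second census with a
      known first-census size: certain extinction in the first decade.
    * ``always_grows`` - a single increase entity: extinction probability 0.
    * ``coinflip``     - pool of one guaranteed-survival and one
      forced-extinction entity, one simulated cell: per-decade hazard 1/2,
      so the CDF follows the geometric law 1 - 0.5**t.
    * ``shared_a``/``shared_b`` - two declining class-pair taxa in one cell,
      carrying pressure labels for the tallies.
    """
    P = PopulationRecord
    sz = SizeClass.parse
    rc = RateClass.parse
    records = [
        P("doomed", "c1", size_first=sz("1-9", "first"),
          size_second=sz("extinct", "second")),
        P("always_grows", "c2", size_second=sz("10-49", "second"),
          decline_score=rc(">1")),
        P("coinflip", "c3", size_second=sz("1-9", "second"),
          decline_score=rc(">1")),
        P("coinflip", "c4", size_second=sz("extinct", "second")),
        P("shared_a", "c5", size_first=sz("100-999", "first"),
          size_second=sz("1-9", "second"),
          pressures=frozenset({"succession"})),
        P("shared_b", "c5", size_first=sz("100-999", "first"),
          size_second=sz("1-9", "second"),
          pressures=frozenset({"succession", "development"})),
    ]
    cells = worked_fixture_cells()
    return records, cells


def worked_fixture_cells() -> list[CellAttributes]:
    return [
        CellAttributes("c1", 0.0, 0.0),
        CellAttributes("c2", 1.0, 0.5),
        CellAttributes("c3", 0.2, 0.0),
        CellAttributes("c4", 0.0, 0.0),
        CellAttributes("c5", 0.5, 0.1),
    ]
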