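"""Empirical assessment of protected-area effectiveness.

Every census record with change information is labelled *declined* or *not
declined* and the binary outcome is related to the proportion of protected
area (or strict core zone) in the record's map cell by logistic regression,
with no other covariates.  The fitted curve yields two effectiveness numbers:

* the saved fraction (default): of the populations that would decline without
  protection, the fraction saved at full coverage,
  ``E = [P_nd(1) - P_nd(0)] / [1 - P_nd(0)]`` with ``P_nd(x)`` the fitted
  probability of non-decline at coverage x; and
* the literal ratio ``E' = P_nd(1) / P_decline(0)``, the probability of
  avoided decline under full protection divided by the probability of decline
  with none — reported alongside for comparability, though it is not bounded
  by 1.

Model support against the no-effect null is summarized by the AIC difference
(null minus covariate model; positive favours the covariate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import CellAttributes, ChangeEntity, PopulationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DeclineObservation",
    "label_decline",
    "build_decline_observations",
    "DeclineLogit",
    "EffectivenessResults",
    "tally_pressures",
]


@dataclass(frozen=True)
class DeclineObservation:
    """One local population's binary decline outcome and its cell's coverage."""

    taxon_id: str
    cell_id: str
    declined: int  # 1 = decreased, 0 = constant or increased
    covariate: float  # pa or core proportion of the cell


def label_decline(rec: PopulationRecord) -> int | None:
    """1 if the record shows local decline, 0 if constant/increase, None if
    it carries no change information.

    Class pairs are compared by the geometric midpoints of the two classes
    (point values for the open-ended classes); equal midpoints count as
    constant.  An observed extinction is a decline.  Decline scores below 1
    (including 1/2-1) are declines; the increase score is not.
    """
    ent = ChangeEntity.from_record(rec)
    if ent is None:
        return None
    if ent.kind == "forced_extinction":
        return 1
    if ent.kind == "class_pair":
        first = ent.first_class.geometric_midpoint()
        second = ent.second_class.geometric_midpoint()
        return int(second < first)
    return int(ent.rate_class.is_decline)


def build_decline_observations(
    records: Iterable[PopulationRecord],
    cells: Sequence[CellAttributes] | Mapping[str, CellAttributes],
    covariate: str = "pa",
) -> list[DeclineObservation]:
    """Join labelled records with their cell's PA (or core-zone) coverage."""
    if covariate not in ("pa", "core"):
        raise ValueError("covariate must be 'pa' or 'core'")
    if not isinstance(cells, Mapping):
        cells = {c.cell_id: c for c in cells}
    obs = []
    for rec in records:
        lab = label_decline(rec)
        if lab is None:
            continue
        cell = cells.get(rec.cell_id)
        if cell is None:
            raise KeyError(f"record references unknown cell {rec.cell_id!r}")
        x = cell.pa_proportion if covariate == "pa" else cell.core_proportion
        obs.append(DeclineObservation(rec.taxon_id, rec.cell_id, lab, x))
    return obs


class DeclineLogit:
    """Logistic regression of local decline on protected-area coverage."""

    def __init__(self, declined: Sequence[int], covariate: Sequence[float]):
        self.endog = np.asarray(declined, dtype=float)
        self.exog_x = np.asarray(covariate, dtype=float)
        if self.endog.shape != self.exog_x.shape:
            raise ValueError("declined and covariate must have equal length")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("both outcome classes must be present")
        if len(np.unique(self.exog_x)) < 2:
            raise ValueError("need at least two distinct covariate values")

    @classmethod
    def from_records(
        cls,
        records: Iterable[PopulationRecord],
        cells,
        covariate: str = "pa",
    ) -> "DeclineLogit":
        obs = build_decline_observations(records, cells, covariate)
        return cls([o.declined for o in obs], [o.covariate for o in obs])

    @classmethod
    def from_observations(cls, obs: Sequence[DeclineObservation]) -> "DeclineLogit":
        return cls([o.declined for o in obs], [o.covariate for o in obs])

    def fit(self) -> "EffectivenessResults":
        """Maximum-likelihood fit, with the intercept-only null alongside.

        Perfect separation falls back to an L2-penalized fit, flagged in the
        results.
        """
        exog = sm.add_constant(self.exog_x)
        null_exog = np.ones((len(self.endog), 1))
        penalized = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.endog, exog).fit(disp=False)
                if not np.all(np.isfinite(res.params)) or not np.all(
                    np.isfinite(res.bse)
                ):
                    raise ValueError("non-finite MLE (separation)")
            except Exception:
                logger.warning(
                    "perfect separation detected; falling back to a penalized fit"
                )
                penalized = True
                res = sm.Logit(self.endog, exog).fit_regularized(
                    alpha=1e-4, L1_wt=0.0, disp=False
                )
            null = sm.Logit(self.endog, null_exog).fit(disp=False)
        return EffectivenessResults(self, res, null, penalized=penalized)


class EffectivenessResults:
    """Fitted decline model, AIC comparison and effectiveness values."""

    def __init__(self, model: DeclineLogit, res, null_res, penalized: bool = False):
        self.model = model
        self._res = res
        self._null = null_res
        self.penalized = penalized
        self.intercept = float(res.params[0])
        self.slope = float(res.params[1])
        self.slope_se = float(res.bse[1]) if np.all(np.isfinite(res.bse)) else np.nan
        self.aic_model = float(2 * 2 - 2 * res.llf)
        self.aic_null = float(2 * 1 - 2 * null_res.llf)
        self.delta_aic = self.aic_null - self.aic_model
        self.nobs = int(len(model.endog))

    def predict_decline(self, x: float) -> float:
        """Fitted probability of decline at coverage x."""
        z = self.intercept + self.slope * x
        return float(1.0 / (1.0 + np.exp(-z)))

    @property
    def effectiveness_saved(self) -> float:
        """Saved fraction: share of would-decline populations protected at
        full coverage; clamped to [0, 1]."""
        p_nd0 = 1.0 - self.predict_decline(0.0)
        p_nd1 = 1.0 - self.predict_decline(1.0)
        if p_nd0 >= 1.0:
            raise ZeroDivisionError(
                "no decline at zero coverage: effectiveness undefined"
            )
        return float(np.clip((p_nd1 - p_nd0) / (1.0 - p_nd0), 0.0, 1.0))

    @property
    def effectiveness_literal(self) -> float:
        """P(avoided decline | full coverage) / P(decline | no coverage)."""
        p_d0 = self.predict_decline(0.0)
        if p_d0 <= 0.0 or 1.0 - p_d0 >= 1.0:
            raise ZeroDivisionError(
                "no decline at zero coverage: effectiveness undefined"
            )
        return float((1.0 - self.predict_decline(1.0)) / p_d0)

    def to_dict(self) -> dict:
        return {
            "n_obs": self.nobs,
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "aic_model": self.aic_model,
            "aic_null": self.aic_null,
            "delta_aic": self.delta_aic,
            "p_decline_at_0": self.predict_decline(0.0),
            "p_decline_at_1": self.predict_decline(1.0),
            "effectiveness_saved": self.effectiveness_saved,
            "effectiveness_literal": self.effectiveness_literal,
            "penalized": self.penalized,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Decline ~ protected-area coverage (logistic regression)",
            "=" * 56,
            f"observations            : {d['n_obs']}",
            f"intercept               : {d['intercept']: .4f}",
            f"slope (coverage)        : {d['slope']: .4f}  (SE {d['slope_se']:.4f})",
            f"AIC (model / null)      : {d['aic_model']:.1f} / {d['aic_null']:.1f}",
            f"delta AIC (null-model)  : {d['delta_aic']:.1f}",
            f"P(decline) at 0% / 100% : {d['p_decline_at_0']:.3f} / {d['p_decline_at_1']:.3f}",
            f"effectiveness (saved)   : {d['effectiveness_saved']:.3f}",
            f"effectiveness (literal) : {d['effectiveness_literal']:.3f}",
        ]
        if self.penalized:
            lines.append("note: penalized fit (perfect separation)")
        return "\n".join(lines)


def tally_pressures(
    records: Iterable[PopulationRecord],
    cells,
    subset_rule: str = "all",
    coverage_threshold: float = 0.2,
) -> dict[str, int]:
    """Counts of declining (taxon, cell) records per pressure type.

    ``subset_rule`` restricts the tally to all cells, cells with more than
    ``coverage_threshold`` protected-area coverage (``pa_gt20``), or cells
    with more than that core-zone coverage (``core_gt20``).  A record with k
    pressure labels contributes to k tallies.
    """
    if subset_rule not in ("all", "pa_gt20", "core_gt20"):
        raise ValueError(f"unknown subset rule {subset_rule!r}")
    if not isinstance(cells, Mapping):
        cells = {c.cell_id: c for c in cells}
    counts: dict[str, int] = {}
    for rec in records:
        if label_decline(rec) != 1:
            continue
        cell = cells.get(rec.cell_id)
        if cell is None:
            raise KeyError(f"record references unknown cell {rec.cell_id!r}")
        if subset_rule == "pa_gt20" and not cell.pa_proportion > coverage_threshold:
            continue
        if subset_rule == "core_gt20" and not cell.core_proportion > coverage_threshold:
            continue
        for p in rec.pressures:
            counts[p] = counts.get(p, 0) + 1
    return counts
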