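"""Electron donor/acceptor budgets, stoichiometric conversions and scale-up.

Accounting layer around the rate estimators: cumulative sulfate delivery
from flow logs, molar H2:sulfate supply ratios, conversion of sulfate-
reduction rates to H2-oxidation rates via the 4:1 reaction stoichiometry
(4 H2 + SO4^2- + H+ -> HS- + 4 H2O), Fe:S atomic-ratio interpretation of
the iron-sulfide precipitates, methanogenesis gas-mole bookkeeping
(4 H2 + CO2 -> CH4 + 2 H2O consumes five gas moles per CH4), and the
repository-scale extrapolation asking what fraction of gallery backfill
suffices to consume the full anoxic-corrosion H2 inventory.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .reactor_sim import SimResult, UL_MIN_TO_CM3_DAY

__all__ = [
    "SupplyLedger",
    "ScaleUpParams",
    "GasBalance",
    "round_half_up",
    "cumulative_sulfate_supplied",
    "molar_ratios",
    "supply_ledger",
    "h2_rate_from_sulfate",
    "backfill_rate",
    "backfill_fraction_required",
    "methanogenesis_gas_balance",
    "classify_fe_s_ratio",
    "sulfide_iron_budget",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how the tables are displayed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SupplyLedger:
    """Per-reactor electron donor/acceptor supply and molar ratios."""

    reactor: str
    duration: float            # days
    sulfate_water: float       # mmol sulfate delivered by porewater
    gypsum: float              # mmol sulfate in gypsum
    h2_total: float            # mmol H2 injected
    ratio_water: float         # molar H2:sulfate, porewater sulfate only
    ratio_total: float         # molar H2:sulfate, porewater + gypsum

    def __post_init__(self) -> None:
        for name in ("duration", "sulfate_water", "gypsum", "h2_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ratio_total > self.ratio_water + 1e-12:
            raise ValueError("ratio_total cannot exceed ratio_water")


@dataclass(frozen=True)
class ScaleUpParams:
    """Repository-scale H2 production scenario.

    Defaults: 900e6 mol of H2 produced by anoxic canister corrosion over a
    1,000-year safety horizon, to be consumed within 390,000 m3 of gallery
    backfill at 45% porosity.
    """

    porosity: float = 0.45
    h2_inventory: float = 900e6    # mol
    horizon: float = 1000.0        # years
    backfill_volume: float = 390_000.0  # m3
    days_per_year: float = 365.25

    def __post_init__(self) -> None:
        if not (0 < self.porosity <= 1):
            raise ValueError("porosity must be in (0, 1]")
        for name in ("h2_inventory", "horizon", "backfill_volume", "days_per_year"):
            if not getattr(self, name) > 0:
                if name == "h2_inventory" and self.h2_inventory == 0:
                    continue  # a zero inventory is a valid degenerate scenario
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GasBalance:
    """Gas-mole bookkeeping of hydrogenotrophic methanogenesis."""

    ch4: float            # mol CH4 produced
    gas_consumed: float   # mol of gas consumed (4 H2 + 1 CO2 per CH4)
    net_gas_change: float  # mol; negative = net pressure-reducing


def cumulative_sulfate_supplied(flow_log: pd.Series | Sequence[float],
                                c_in: float,
                                fill_missing: bool = False) -> float:
    """Total sulfate delivered by the porewater inflow, in mmol.

    ``flow_log`` holds one mean flow (uL/min) per day, indexed by integer
    day when a pandas Series.  Each day contributes flow * 1440 min * 1e-6
    L/uL * c_in mmol/L (rectangle rule).  Gaps in the day index are an
    error unless ``fill_missing`` requests zero-fill.
    """
    if c_in < 0:
        raise ValueError("c_in must be non-negative")
    s = pd.Series(flow_log, dtype=float) if not isinstance(flow_log, pd.Series) \
        else flow_log.astype(float)
    if (s < 0).any():
        raise ValueError("flow rates must be non-negative")
    idx = np.asarray(s.index, dtype=float)
    if len(idx) > 1:
        expected = np.arange(idx.min(), idx.min() + len(idx))
        contiguous = np.array_equal(np.sort(idx), np.arange(idx.min(), idx.max() + 1))
        if not contiguous and not fill_missing:
            raise ValueError("flow log has missing days; pass fill_missing=True "
                             "to zero-fill them")
    liters = float(s.sum()) * 1440.0 * 1e-6
    return liters * c_in


def molar_ratios(h2_total: float, sulfate_water: float,
                 gypsum: float) -> tuple[float, float, float, float]:
    """Molar H2:sulfate supply ratios, raw and display-rounded.

    Returns (ratio_water, ratio_total, ratio_water_rounded,
    ratio_total_rounded); the water ratio counts porewater sulfate only,
    the total ratio adds the gypsum inventory.  Display rounding is
    half-up to one decimal.
    """
    if sulfate_water <= 0:
        raise ValueError("sulfate_water must be positive")
    if gypsum < 0 or h2_total < 0:
        raise ValueError("h2_total and gypsum must be non-negative")
    rw = h2_total / sulfate_water
    rt = h2_total / (sulfate_water + gypsum)
    return rw, rt, round_half_up(rw, 1), round_half_up(rt, 1)


def supply_ledger(reactor: str, duration: float, sulfate_water: float,
                  h2_total: float, gypsum: float = 8.2) -> SupplyLedger:
    """Assemble a supply ledger row; gypsum defaults to the ~8.2 mmol
    sulfate inventory of the bentonite charge."""
    rw, rt, _, _ = molar_ratios(h2_total, sulfate_water, gypsum)
    return SupplyLedger(reactor=reactor, duration=duration,
                        sulfate_water=sulfate_water, gypsum=gypsum,
                        h2_total=h2_total, ratio_water=rw, ratio_total=rt)


def h2_rate_from_sulfate(rate_so4: float) -> float:
    """H2-oxidation rate from a sulfate-reduction rate: exactly 4x
    (4 mol H2 per mol sulfate), same units."""
    return 4.0 * rate_so4


def backfill_rate(rate_void: float, porosity: float = 0.45) -> tuple[float, float]:
    """Convert a per-void-volume rate to a per-backfill-volume rate.

    umol/(day*cm3 void) * porosity == mol/(day*m3 backfill), exploiting
    umol/cm3 == mol/m3.  Returns (raw, half-up 1-decimal display value).
    """
    if not (0 < porosity <= 1):
        raise ValueError("porosity must be in (0, 1]")
    raw = rate_void * porosity
    return raw, round_half_up(raw, 1)


def backfill_fraction_required(scale: ScaleUpParams,
                               rate_backfill: float) -> float:
    """Percent of the backfill volume needed to consume the H2 inventory.

    100 * [inventory / (horizon * days_per_year)] / (rate * volume):
    the daily H2 production divided by the daily consumption capacity of
    the full backfill.
    """
    if rate_backfill <= 0:
        raise ValueError("rate_backfill must be positive")
    daily_production = scale.h2_inventory / (scale.horizon * scale.days_per_year)
    capacity = rate_backfill * scale.backfill_volume
    if capacity <= 0:
        raise ValueError("backfill consumption capacity must be positive")
    return 100.0 * daily_production / capacity


def methanogenesis_gas_balance(ch4: float) -> GasBalance:
    """Gas moles consumed and net gas change for a given CH4 production.

    Five gas moles (4 H2 + 1 CO2) are consumed per mole of CH4 produced,
    so the net change is -4 mol of gas per mol CH4: methanogenesis reduces
    pressure despite producing gas.
    """
    if ch4 < 0:
        raise ValueError("ch4 must be non-negative")
    return GasBalance(ch4=ch4, gas_consumed=5.0 * ch4, net_gas_change=-4.0 * ch4)


#: Target Fe:S atomic ratios of the two candidate iron-sulfide phases.
PYRITE_RATIO = 0.5       # FeS2
MACKINAWITE_RATIO = 1.0  # FeS


def classify_fe_s_ratio(fe_to_s: float, tol: float = 0.25) -> str:
    """Classify an Fe:S atomic ratio against iron-sulfide stoichiometries.

    Below pyrite - tol: "sulfur-excess"; above mackinawite + tol:
    "iron-excess"; inside [pyrite - tol, mackinawite + tol] the nearest
    target wins ("pyrite-like" at 0.5, "mackinawite-like" at 1.0), with
    boundary values (including the midpoint) assigned to the lower class.
    """
    if fe_to_s < 0:
        raise ValueError("Fe:S ratio must be non-negative")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    lo = PYRITE_RATIO - tol
    hi = MACKINAWITE_RATIO + tol
    mid = (PYRITE_RATIO + MACKINAWITE_RATIO) / 2.0
    if fe_to_s < lo:
        return "sulfur-excess"
    if fe_to_s > hi:
        return "iron-excess"
    return "pyrite-like" if fe_to_s <= mid else "mackinawite-like"


def sulfide_iron_budget(sim: SimResult,
                        fe_inflow_log: pd.Series | None = None
                        ) -> tuple[float, float, float]:
    """Sulfide/iron mineral budget of a simulated run, in mmol.

    Returns (cumulative sulfide produced, cumulative iron delivered
    [initial + inflow], iron-sulfide-bound sulfur).  An optional daily
    Fe inflow log (uL/min paired with the config's inflow Fe) can be
    supplied as a cross-check; it must span the simulated duration.
    """
    cfg = sim.config
    sulfide_produced = float(sim.consumed_so4_mmol[-1])
    fe_initial = cfg.c0_fe / 1000.0 * cfg.v_voids / 1000.0
    fe_delivered = fe_initial + float(sim.inflow_fe_mmol[-1])
    fes = float(sim.fes_mmol[-1])
    if fe_inflow_log is not None:
        days = np.asarray(fe_inflow_log.index, dtype=float)
        if len(days) and (days.min() > 0 or days.max() < cfg.duration - 1.0):
            raise ValueError("Fe inflow log does not span the simulated duration")
        fe_check = fe_initial + cumulative_sulfate_supplied(
            fe_inflow_log, cfg.c_in_fe / 1000.0)  # same L*mM arithmetic
        if fe_check > 0 and abs(fe_check - fe_delivered) / fe_check > 0.05:
            raise ValueError("Fe inflow log inconsistent with the simulated inflow")
    if fes > min(sulfide_produced, fe_delivered) * (1 + 1e-9) + 1e-12:
        raise AssertionError("FeS sulfur exceeds available sulfide or iron")
    return sulfide_produced, fe_delivered, fes
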