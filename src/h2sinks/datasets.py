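"""Published summary numbers from the Mont Terri sand-bentonite H2 reactors.

These are the printed per-reactor supply totals and sulfate-reduction
rates of the four in-situ flow-through reactors (the raw monitoring series
are deposited externally and are not shipped).  They serve as inputs for
the worked-number checks: supply ratios, cross-reactor rate summaries,
stoichiometric conversions and the repository scale-up.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_supply",
    "reference_rates",
    "GYPSUM_INVENTORY_MMOL",
    "GYPSUM_EQ_BALANCE_MMOL",
    "DEFAULT_POROSITY",
]

#: Sulfate inventory of the gypsum in one reactor's bentonite charge (mmol),
#: as constrained by the equilibration-phase dissolution measurements.
GYPSUM_INVENTORY_MMOL = 8.2

#: Gypsum-dissolution term used in the global mass balance (mmol).
GYPSUM_EQ_BALANCE_MMOL = 10.0

#: Backfill porosity consistent with the published void/backfill rate pairs.
DEFAULT_POROSITY = 0.45

_SUPPLY = [
    # reactor, setup, duration_days, sulfate_water_mmol, h2_total_mmol
    ("1", "serial", 108.0, 10.1, 49.1),
    ("2", "serial", 108.0, 8.1, 49.0),
    ("3", "parallel", 73.0, 16.1, 32.6),
    ("4", "parallel", 79.0, 22.9, 33.1),
]

_RATES = [
    # reactor, linear-regression rate / slope SE / adjusted R^2, mass-balance rate
    # rates in umol/(day*cm3 void)
    ("1", 1.548, 0.090, 0.958, 0.35),
    ("2", 1.920, 0.124, 0.952, 0.27),
    ("3", 1.630, 0.277, 0.794, 0.62),
    ("4", 1.911, 0.114, 0.969, 0.52),
]


def reference_supply() -> pd.DataFrame:
    """Per-reactor water/H2 supply totals (durations in days, moles in mmol)."""
    return pd.DataFrame(
        _SUPPLY, columns=["reactor", "setup", "duration_days",
                          "sulfate_water_mmol", "h2_total_mmol"])


def reference_rates() -> pd.DataFrame:
    """Per-reactor sulfate-reduction rates from the two estimators."""
    return pd.DataFrame(
        _RATES, columns=["reactor", "linear_rate", "linear_se",
                         "linear_adj_r2", "mass_balance_rate"])
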