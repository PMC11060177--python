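"""Sulfate-reduction rate estimators for flow-through reactor monitoring.

Two estimators are provided, mirroring how such experiments are analyzed:

* ``linear_rate`` -- zero-order (linear-regression) rate: ordinary least
  squares of outflow sulfate concentration against time; the rate is the
  negative slope.  Because concentrations are in mM == umol/cm3 of void
  porewater, the slope in mM/day is numerically the volumetric rate in
  umol/(day*cm3 void).
* ``mass_balance_rate`` -- a global sulfate mass balance over the whole
  run: everything injected (including the initial void-saturation water)
  plus gypsum dissolution, minus everything that left in the outflow and
  what remains dissolved in the voids, divided by duration times void
  volume.

Rates are normalized per cm3 of VOID volume throughout; conversion to
per-backfill-volume lives in :mod:`h2sinks.budgets`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .reactor_sim import PorewaterSeries, SimResult

__all__ = [
    "MassBalanceInputs",
    "RateEstimate",
    "RateSummary",
    "linear_rate",
    "mass_balance_rate",
    "mass_balance_from_sim",
    "windowed_rate",
    "summarize_rates",
]


@dataclass(frozen=True)
class MassBalanceInputs:
    """Every term of the global sulfate mass balance.

    ``v_in_tot`` is the TOTAL water volume injected (L), including the
    water that initially saturated the voids; ``c_in`` the volume-weighted
    inflow sulfate concentration (mM); ``n_gypsum`` the sulfate released
    from gypsum (mmol); ``weekly_outflow`` pairs of (outflow volume L,
    mean outflow sulfate mM) per week; ``v_voids`` the void volume (cm3);
    ``c_out_end`` the final outflow sulfate (mM); ``days`` the duration.
    """

    v_in_tot: float
    c_in: float
    n_gypsum: float
    weekly_outflow: Sequence[tuple[float, float]]
    v_voids: float
    c_out_end: float
    days: float

    def __post_init__(self) -> None:
        if self.v_in_tot < 0 or self.v_voids <= 0:
            raise ValueError("volumes must be non-negative and v_voids positive")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if self.c_in < 0 or self.c_out_end < 0 or self.n_gypsum < 0:
            raise ValueError("concentrations and gypsum must be non-negative")
        vw = sum(v for v, _ in self.weekly_outflow)
        if vw < 0 or any(v < 0 or c < 0 for v, c in self.weekly_outflow):
            raise ValueError("weekly outflow volumes/concentrations must be >= 0")
        if vw > self.v_in_tot + self.v_voids / 1000.0 + 1e-9:
            raise ValueError("weekly outflow volumes exceed the injected water")


@dataclass(frozen=True)
class RateEstimate:
    """A volumetric sulfate-reduction rate in umol/(day*cm3 void).

    ``se`` (slope standard error) and ``adj_r2`` are present only for the
    regression estimator; ``sulfate_consumed_mmol`` (the mass-balance
    numerator) only for the mass balance.
    """

    rate: float
    method: str
    window: tuple[float, float]
    se: float | None = None
    adj_r2: float | None = None
    sulfate_consumed_mmol: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("linear_regression", "mass_balance"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be non-negative")
        if self.adj_r2 is not None and not np.isnan(self.adj_r2) \
                and self.adj_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


@dataclass(frozen=True)
class RateSummary:
    mean: float
    sd: float
    rsd_percent: float
    n: int


def linear_rate(series: PorewaterSeries,
                window: tuple[float, float] | None = None) -> RateEstimate:
    """Zero-order rate: OLS of mean sulfate concentration vs day.

    The rate is the negative slope (depletion positive) in
    umol/(day*cm3 void); a rising sulfate trend yields a negative rate,
    which is reported, not raised.  Standard error is the OLS slope SE and
    adjusted R^2 uses n-2 residual degrees of freedom.  For a constant
    series the slope is zero and R^2 is undefined (NaN).
    """
    df = series.for_analyte("sulfate")
    if window is not None:
        lo, hi = window
        df = df[(df["day"] >= lo - 1e-12) & (df["day"] <= hi + 1e-12)]
    else:
        window = (float(df["day"].min()), float(df["day"].max())) if len(df) else (0.0, 0.0)
    t = df["day"].to_numpy(dtype=float)
    y = df["mean"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 sampling days in the window")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in sampling days")

    if np.ptp(y) == 0:
        # flat series: slope 0 exactly, R^2 undefined (0/0)
        return RateEstimate(rate=0.0, se=0.0, adj_r2=float("nan"),
                            method="linear_regression",
                            window=(float(t.min()), float(t.max())))

    fit = stats.linregress(t, y)
    n = len(t)
    r2 = fit.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RateEstimate(rate=-float(fit.slope), se=float(fit.stderr),
                        adj_r2=float(adj), method="linear_regression",
                        window=(float(t.min()), float(t.max())))


def mass_balance_rate(inputs: MassBalanceInputs) -> RateEstimate:
    """Global sulfate mass balance rate.

    rate = [V_in_tot*c_in + n_gypsum - sum_w V_w*c_out_w
            - (V_voids/1000)*c_out_end] / (days * V_voids)

    with L*mM = mmol throughout; the numerator (mmol of sulfate consumed)
    is attached to the result.  A negative numerator (net sulfate
    accumulation) is permitted but triggers a warning.
    """
    mb = inputs
    out = sum(v * c for v, c in mb.weekly_outflow)
    numerator = (mb.v_in_tot * mb.c_in + mb.n_gypsum - out
                 - (mb.v_voids / 1000.0) * mb.c_out_end)  # mmol
    if numerator < 0:
        warnings.warn("negative sulfate consumption: net accumulation in the "
                      "reactor", stacklevel=2)
    rate = numerator * 1000.0 / (mb.days * mb.v_voids)  # umol/(day*cm3)
    return RateEstimate(rate=float(rate), method="mass_balance",
                        window=(0.0, float(mb.days)),
                        sulfate_consumed_mmol=float(numerator))


def mass_balance_from_sim(sim: SimResult, n_weeks: int | None = None) -> MassBalanceInputs:
    """Build exact mass-balance inputs from a simulator run.

    The injected volume includes the initial void-saturation water (at the
    initial concentration) so the balance covers the full inventory; the
    outflow record is binned into ``n_weeks`` bins (default: ceil(days/7))
    with flow-weighted mean concentrations, which keeps the binning exact.
    """
    cfg = sim.config
    vv_l = cfg.v_voids / 1000.0
    # rigid saturated reactor: cumulative injected water == cumulative outflow
    inflow_vol = float(sim.outflow_volume_L[-1])
    v_in_tot = vv_l + inflow_vol
    total_in_so4 = cfg.c0_sulfate * vv_l + float(sim.inflow_so4_mmol[-1])
    c_in_eff = total_in_so4 / v_in_tot if v_in_tot > 0 else 0.0

    if n_weeks is None:
        n_weeks = max(1, int(np.ceil(cfg.duration / 7.0)))
    edges = np.linspace(0.0, cfg.duration, n_weeks + 1)
    cum_vol = np.interp(edges, sim.day, sim.outflow_volume_L)
    cum_out = np.interp(edges, sim.day, sim.exported_so4_mmol)
    weekly = []
    for w in range(n_weeks):
        v = float(cum_vol[w + 1] - cum_vol[w])
        m = float(cum_out[w + 1] - cum_out[w])
        weekly.append((v, m / v if v > 0 else 0.0))

    n_gyp = float(cfg.gypsum0 - sim.gypsum_mmol[-1])
    return MassBalanceInputs(
        v_in_tot=v_in_tot, c_in=c_in_eff, n_gypsum=n_gyp,
        weekly_outflow=weekly, v_voids=cfg.v_voids,
        c_out_end=float(sim.sulfate_mM[-1]), days=float(cfg.duration))


def windowed_rate(series: PorewaterSeries,
                  breakpoint: float) -> tuple[RateEstimate | None, RateEstimate | None]:
    """Fit the zero-order rate separately before and after a breakpoint.

    Windows are [start, breakpoint] and (breakpoint, end].  A side with
    fewer than 3 sampling days yields None with a warning rather than
    aborting the other side.
    """
    df = series.for_analyte("sulfate")
    days = df["day"].to_numpy(dtype=float)
    if not (days.min() <= breakpoint <= days.max()):
        raise ValueError("breakpoint outside the observed day range")
    out: list[RateEstimate | None] = []
    masks = (
        (df["day"] >= days.min() - 1e-12) & (df["day"] <= breakpoint + 1e-12),
        (df["day"] > breakpoint + 1e-12) & (df["day"] <= days.max() + 1e-12),
    )
    for mask in masks:
        sub = df[mask]
        if len(sub) < 3:
            warnings.warn("a side of the breakpoint has fewer than 3 points; "
                          "skipped", stacklevel=2)
            out.append(None)
            continue
        piece = PorewaterSeries(sub.assign(analyte="sulfate"))
        out.append(linear_rate(piece))
    return out[0], out[1]


def summarize_rates(rates: Sequence[RateEstimate]) -> RateSummary:
    """Cross-reactor summary: mean, sample SD (n-1) and RSD percent."""
    if len(rates) < 2:
        raise ValueError("need at least 2 rates to summarize")
    methods = {r.method for r in rates}
    if len(methods) != 1:
        raise ValueError(f"mixed estimation methods: {sorted(methods)}")
    vals = np.array([r.rate for r in rates], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("inf")
    return RateSummary(mean=mean, sd=sd, rsd_percent=rsd, n=len(vals))
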