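"""Forward model of a flow-through sand-bentonite reactor fed with H2.

The model emulates the Mont Terri-type microcosm experiment: a porous
sand-bentonite column saturated with sulfate-rich Opalinus Clay porewater,
receiving a variable gravity-driven inflow and a daily pulse of pure H2.
Hydrogenotrophic sulfate reducers consume sulfate (4 H2 + SO4^2- + H+ ->
HS- + 4 H2O), gypsum in the bentonite dissolves toward saturation and
replenishes sulfate, biogenic sulfide scavenges dissolved ferrous iron as
iron sulfide, and methanogens (4 H2 + CO2 -> CH4 + 2 H2O) switch on when
sulfate is locally depleted.

State variables are well-mixed porewater concentrations (the reactor is
treated as a single stirred tank over the void volume); units follow the
package convention of mM == umol/cm3 for concentrations and cm3 for
volumes.  The integrator is a fixed-step classical Runge-Kutta (RK4)
scheme with iron-sulfide precipitation applied by operator splitting after
each chemistry step, which keeps every run bit-reproducible.

Randomness only enters through the observation sampler and the ASV-grid
generator; the chemistry itself is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReactorConfig",
    "KineticParams",
    "SimResult",
    "PorewaterSeries",
    "Hotspot",
    "ASVTable",
    "simulate_reactor",
    "sample_observations",
    "generate_asv_table",
    "sulfur_balance",
    "iron_balance",
    "GRID_COLUMNS",
    "GRID_ROWS",
    "ANALYTES",
]

#: Radial column labels of the post-mortem sampling grid, left to right:
#: outer left, center left, center, center right, outer right.
GRID_COLUMNS = ("OL", "CL", "C", "CR", "OR")
#: Vertical sampling rows, numbered top (1) to bottom (7).
GRID_ROWS = tuple(range(1, 8))

ANALYTES = ("sulfate", "sulfide", "fe")

# Flow logs are recorded in uL/min; internal volumes are cm3 and time is days.
UL_MIN_TO_CM3_DAY = 1440.0 * 1e-3

Profile = float | Sequence[tuple[float, float]]


def _as_profile(p: Profile) -> tuple[tuple[float, float], ...]:
    """Normalize a scalar or [(day, value), ...] into sorted breakpoints."""
    if isinstance(p, (int, float)):
        return ((0.0, float(p)),)
    pts = tuple(sorted((float(d), float(v)) for d, v in p))
    if not pts:
        raise ValueError("profile must contain at least one (day, value) pair")
    return pts


def _profile_value(pts: tuple[tuple[float, float], ...], t: float) -> float:
    """Piecewise-constant lookup: value of the latest breakpoint <= t."""
    v = pts[0][1]
    for day, val in pts:
        if t >= day - 1e-12:
            v = val
        else:
            break
    return v


@dataclass(frozen=True)
class ReactorConfig:
    """Geometry, inflow chemistry and supply schedules of one reactor.

    Defaults describe the study conditions: a 12 cm x 10 cm diameter
    cylinder (~940 cm3) at ~45% porosity, ~15 mM sulfate porewater,
    ~120 uM ferrous iron, ~8.2 mmol of gypsum-bound sulfate in the
    bentonite, a few uL/min of inflow, and sub-mmol daily H2 pulses.
    """

    v_voids: float = 424.0        # porewater-filled void volume, cm3
    v_total: float = 942.0        # reactor interior volume, cm3
    c_in_sulfate: float = 15.0    # inflow sulfate, mM
    c_in_fe: float = 120.0        # inflow ferrous iron, uM
    c0_sulfate: float = 15.0      # initial (post-equilibration) sulfate, mM
    c0_fe: float = 120.0          # initial ferrous iron, uM
    gypsum0: float = 8.2          # initial gypsum sulfate inventory, mmol
    c_sat: float = 20.0           # sulfate concentration at gypsum saturation, mM
    duration: float = 100.0       # days
    flow_profile: Profile = 4.0   # inflow rate, uL/min (scalar or [(day, rate)])
    h2_schedule: Profile = 0.5    # daily H2 pulse, mmol/day (scalar or [(day, pulse)])

    def __post_init__(self) -> None:
        if not self.v_voids > 0:
            raise ValueError("v_voids must be positive")
        if self.v_voids > self.v_total:
            raise ValueError("v_voids cannot exceed v_total")
        for name in ("c_in_sulfate", "c_in_fe", "c0_sulfate", "c0_fe",
                     "gypsum0", "c_sat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        for day, rate in _as_profile(self.flow_profile):
            if rate < 0:
                raise ValueError(f"flow_profile rate at day {day} is negative")
        for day, pulse in _as_profile(self.h2_schedule):
            if pulse < 0:
                raise ValueError(f"h2_schedule pulse at day {day} is negative")


@dataclass(frozen=True)
class KineticParams:
    """Microbial and mineral kinetic parameters of the forward model.

    ``vmax_sr`` is the maximum volumetric sulfate-reduction rate in
    umol/(day*cm3 void); sulfate limitation is Monod with half-saturation
    ``k_so4`` (mM).  H2 limitation is a pulse-budget switch: reduction and
    methanogenesis proceed while the day's cumulative H2 consumption is
    below ``k_h2`` times that day's pulse, and stop otherwise.  Gypsum
    dissolves by first-order relaxation toward saturation with rate
    constant ``k_gyp`` (1/day).  Methanogenesis runs at ``vmax_meth``
    (umol CH4/(day*cm3)) only while sulfate is below ``so4_gate`` (mM),
    encoding the hypothesis that methanogens outcompete sulfate reducers
    only under sulfate depletion.  ``growth`` is a logistic carrying-
    capacity multiplier on biomass activity (1 = constant activity).
    """

    vmax_sr: float = 0.25
    k_h2: float = 1.0
    k_so4: float = 0.5
    k_gyp: float = 0.02
    vmax_meth: float = 0.05
    so4_gate: float = 0.5
    growth: float = 1.0
    growth_rate: float = 0.1  # 1/day, logistic ramp when growth > 1

    def __post_init__(self) -> None:
        for name in ("vmax_sr", "k_h2", "k_gyp", "vmax_meth", "so4_gate",
                     "growth", "growth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.k_so4 > 0:
            raise ValueError("k_so4 must be positive")

    def biomass_factor(self, t: float) -> float:
        """Logistic activity multiplier at time t (1.0 when growth == 1)."""
        g = self.growth
        if g == 1.0:
            return 1.0
        if g == 0.0:
            return 0.0
        return g / (1.0 + (g - 1.0) * math.exp(-self.growth_rate * t))


@dataclass
class SimResult:
    """Latent trajectories and exact consumption bookkeeping of one run.

    Concentration trajectories are porewater values on the integration
    day grid; cumulative quantities are in mmol.  ``truth`` is the
    time-averaged volumetric sulfate-reduction rate,
    cumulative consumed / (duration * v_voids), in umol/(day*cm3).
    """

    day: np.ndarray
    sulfate_mM: np.ndarray
    sulfide_uM: np.ndarray
    fe_uM: np.ndarray
    gypsum_mmol: np.ndarray
    fes_mmol: np.ndarray            # cumulative FeS precipitated (as S), mmol
    ch4_mmol: np.ndarray            # cumulative CH4 produced, mmol
    consumed_so4_mmol: np.ndarray   # cumulative sulfate reduced, mmol
    exported_so4_mmol: np.ndarray
    exported_hs_mmol: np.ndarray
    inflow_so4_mmol: np.ndarray
    inflow_fe_mmol: np.ndarray
    exported_fe_mmol: np.ndarray
    outflow_volume_L: np.ndarray    # cumulative outflow water volume, L
    truth: float
    config: ReactorConfig
    params: KineticParams
    step: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Trajectories as a tidy DataFrame, one row per time step."""
        return pd.DataFrame({
            "day": self.day,
            "sulfate_mM": self.sulfate_mM,
            "sulfide_uM": self.sulfide_uM,
            "fe_uM": self.fe_uM,
            "gypsum_mmol": self.gypsum_mmol,
            "fes_mmol": self.fes_mmol,
            "ch4_mmol": self.ch4_mmol,
            "consumed_so4_mmol": self.consumed_so4_mmol,
            "exported_so4_mmol": self.exported_so4_mmol,
            "exported_hs_mmol": self.exported_hs_mmol,
            "outflow_volume_L": self.outflow_volume_L,
        })


def simulate_reactor(config: ReactorConfig,
                     params: KineticParams | None = None,
                     step: float = 0.01,
                     seed: int = 0) -> SimResult:
    """Integrate the reactor chemistry with a fixed-step RK4 scheme.

    Parameters
    ----------
    config, params
        Reactor geometry/supply and kinetic parameters.
    step
        Integration step in days; must be <= 0.05 for the daily H2 budget
        bookkeeping to stay meaningful.
    seed
        Recorded for provenance; the chemistry itself is deterministic.

    Returns
    -------
    SimResult with full latent trajectories, cumulative mole bookkeeping
    and the ground-truth time-averaged sulfate-reduction rate.

    Raises
    ------
    ValueError if the step is too large (any state drifting below -1e-9),
    with advice to reduce it.
    """
    if params is None:
        params = KineticParams()
    if step <= 0 or step > 0.05:
        raise ValueError("step must be in (0, 0.05] day")

    cfg, kp = config, params
    vv = cfg.v_voids
    flow = _as_profile(cfg.flow_profile)
    pulses = _as_profile(cfg.h2_schedule)
    fe_in = cfg.c_in_fe / 1000.0  # uM -> mM

    n_steps = int(round(cfg.duration / step))
    if abs(n_steps * step - cfg.duration) > 1e-9:
        n_steps = int(math.ceil(cfg.duration / step))

    # State: concentrations in mM, gypsum in mmol, cumulatives in mmol / L.
    s, gyp = cfg.c0_sulfate, cfg.gypsum0
    hs = 0.0
    fe = cfg.c0_fe / 1000.0
    cons = ch4 = out_s = out_hs = in_s = in_fe = out_fe = out_vol = fes = 0.0

    nrec = n_steps + 1
    rec = {k: np.empty(nrec) for k in (
        "day", "s", "hs", "fe", "gyp", "fes", "ch4", "cons",
        "out_s", "out_hs", "in_s", "in_fe", "out_fe", "out_vol")}

    def record(i: int, t: float) -> None:
        rec["day"][i] = t
        rec["s"][i], rec["hs"][i], rec["fe"][i], rec["gyp"][i] = s, hs, fe, gyp
        rec["fes"][i], rec["ch4"][i], rec["cons"][i] = fes, ch4, cons
        rec["out_s"][i], rec["out_hs"][i] = out_s, out_hs
        rec["in_s"][i], rec["in_fe"][i], rec["out_fe"][i] = in_s, in_fe, out_fe
        rec["out_vol"][i] = out_vol

    record(0, 0.0)

    current_day = -1
    h2_budget = 0.0

    for i in range(1, nrec):
        t0 = (i - 1) * step
        t1 = min(i * step, cfg.duration)
        dt = t1 - t0
        if dt <= 0:
            record(i, t0)
            continue

        day_idx = int(math.floor(t0 + 1e-12))
        if day_idx != current_day:
            current_day = day_idx
            h2_budget = kp.k_h2 * _profile_value(pulses, float(day_idx))
        h2_on = 1.0 if h2_budget > 0.0 else 0.0

        q = _profile_value(flow, t0) * UL_MIN_TO_CM3_DAY  # cm3/day
        dil = q / vv

        def deriv(t, y):
            ys, yhs, yfe, ygyp = y[0], y[1], y[2], y[3]
            b = kp.biomass_factor(t)
            s_pos = max(ys, 0.0)
            r_sr = kp.vmax_sr * b * h2_on * s_pos / (kp.k_so4 + s_pos)
            diss = kp.k_gyp * (cfg.c_sat - ys) if ygyp > 0.0 else 0.0
            r_meth = kp.vmax_meth * b * h2_on if ys < kp.so4_gate else 0.0
            return (
                dil * (cfg.c_in_sulfate - ys) + diss - r_sr,   # dS/dt
                r_sr - dil * yhs,                              # dHS/dt
                dil * (fe_in - yfe),                           # dFe/dt
                -diss * vv / 1000.0,                           # dGyp/dt, mmol
                r_sr * vv / 1000.0,                            # consumed SO4, mmol/day
                r_meth * vv / 1000.0,                          # CH4, mmol/day
                q * ys / 1000.0,                               # exported SO4
                q * yhs / 1000.0,                              # exported HS
                q * cfg.c_in_sulfate / 1000.0,                 # inflow SO4
                q * fe_in / 1000.0,                            # inflow Fe
                q * yfe / 1000.0,                              # exported Fe
                q / 1000.0 / 1000.0,                           # outflow volume, L/day (cm3 -> L)
            )

        y0 = (s, hs, fe, gyp, cons, ch4, out_s, out_hs, in_s, in_fe, out_fe, out_vol)
        k1 = deriv(t0, y0)
        k2 = deriv(t0 + dt / 2, tuple(y0[j] + dt / 2 * k1[j] for j in range(12)))
        k3 = deriv(t0 + dt / 2, tuple(y0[j] + dt / 2 * k2[j] for j in range(12)))
        k4 = deriv(t0 + dt, tuple(y0[j] + dt * k3[j] for j in range(12)))
        y1 = [y0[j] + dt / 6 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
              for j in range(12)]

        (s, hs, fe, gyp, cons_new, ch4_new, out_s, out_hs,
         in_s, in_fe, out_fe, out_vol) = y1

        # Gypsum exhaustion: return any overshoot to the dissolved pool so
        # that sulfur is conserved, then pin the inventory at zero.
        if gyp < 0.0:
            s += gyp * 1000.0 / vv
            gyp = 0.0

        if min(s, hs, fe) < -1e-9:
            raise ValueError(
                "integration unstable: a concentration went below -1e-9; "
                "use a smaller step")
        s, hs, fe = max(s, 0.0), max(hs, 0.0), max(fe, 0.0)

        # Daily H2 budget: 4 mol H2 per mol sulfate reduced and per mol CH4.
        h2_budget -= 4.0 * ((cons_new - cons) + (ch4_new - ch4))
        cons, ch4 = cons_new, ch4_new

        # Operator splitting: instantaneous FeS precipitation of the lesser
        # of dissolved Fe(II) and sulfide.
        p = min(fe, hs)
        if p > 0.0:
            fe -= p
            hs -= p
            fes += p * vv / 1000.0

        record(i, t1)

    truth = cons * 1000.0 / (cfg.duration * vv)
    return SimResult(
        day=rec["day"], sulfate_mM=rec["s"], sulfide_uM=rec["hs"] * 1000.0,
        fe_uM=rec["fe"] * 1000.0, gypsum_mmol=rec["gyp"], fes_mmol=rec["fes"],
        ch4_mmol=rec["ch4"], consumed_so4_mmol=rec["cons"],
        exported_so4_mmol=rec["out_s"], exported_hs_mmol=rec["out_hs"],
        inflow_so4_mmol=rec["in_s"], inflow_fe_mmol=rec["in_fe"],
        exported_fe_mmol=rec["out_fe"], outflow_volume_L=rec["out_vol"],
        truth=truth, config=cfg, params=kp, step=step, seed=seed)


def sulfur_balance(sim: SimResult) -> float:
    """Relative sulfur-conservation residual of a run.

    (initial dissolved + gypsum + inflow) minus (final dissolved SO4 + HS,
    remaining gypsum, FeS sulfur, exported SO4 + HS), divided by total
    sulfur throughput.  Should be ~0 (well within 1e-3).
    """
    cfg = sim.config
    vv = cfg.v_voids
    init = (cfg.c0_sulfate * vv / 1000.0) + cfg.gypsum0
    sources = init + sim.inflow_so4_mmol[-1]
    final_diss = (sim.sulfate_mM[-1] + sim.sulfide_uM[-1] / 1000.0) * vv / 1000.0
    sinks = (final_diss + sim.gypsum_mmol[-1] + sim.fes_mmol[-1]
             + sim.exported_so4_mmol[-1] + sim.exported_hs_mmol[-1])
    return (sources - sinks) / max(sources, 1e-30)


def iron_balance(sim: SimResult) -> float:
    """Relative iron-conservation residual (FeS binds Fe:S 1:1 here)."""
    cfg = sim.config
    vv = cfg.v_voids
    sources = cfg.c0_fe / 1000.0 * vv / 1000.0 + sim.inflow_fe_mmol[-1]
    sinks = (sim.fe_uM[-1] / 1000.0 * vv / 1000.0 + sim.fes_mmol[-1]
             + sim.exported_fe_mmol[-1])
    return (sources - sinks) / max(sources, 1e-30)


# ---------------------------------------------------------------------------
# Observation model


@dataclass
class PorewaterSeries:
    """Weekly replicate-averaged porewater monitoring series.

    ``data`` has columns day, analyte, mean, sd, n; days are strictly
    increasing within each analyte, SDs are sample SDs (n-1 denominator).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "analyte", "mean", "sd", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"PorewaterSeries missing columns: {sorted(missing)}")
        if (self.data["n"] < 1).any():
            raise ValueError("replicate counts must be >= 1")
        if (self.data["sd"] < 0).any():
            raise ValueError("replicate SDs must be non-negative")
        for analyte, grp in self.data.groupby("analyte"):
            d = grp["day"].to_numpy()
            if not (np.diff(d) > 0).all():
                raise ValueError(f"days not strictly increasing for {analyte!r}")

    def for_analyte(self, analyte: str) -> pd.DataFrame:
        if analyte not in set(self.data["analyte"]):
            raise ValueError(f"unknown analyte {analyte!r}")
        return (self.data[self.data["analyte"] == analyte]
                .sort_values("day").reset_index(drop=True))


DEFAULT_NOISE_SD: Mapping[str, float] = {"sulfate": 0.5, "sulfide": 10.0, "fe": 5.0}


def sample_observations(sim: SimResult,
                        schedule: Sequence[float],
                        noise_sd: Mapping[str, float] | float | None = None,
                        n_reps: int = 3,
                        seed: int = 0) -> PorewaterSeries:
    """Draw replicate outflow observations around the latent trajectories.

    Emulates weekly triplicate sampling: for each scheduled day and analyte,
    ``n_reps`` independent Gaussian draws around the latent value, truncated
    at zero (clipped), summarized as mean / sample SD / n.  Noise SDs are in
    the analyte's reporting unit (sulfate mM, sulfide and iron uM).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sched = np.asarray(list(schedule), dtype=float)
    if sched.size == 0:
        raise ValueError("schedule is empty")
    if sched.min() < sim.day[0] - 1e-9 or sched.max() > sim.day[-1] + 1e-9:
        raise ValueError("schedule day outside the simulated range")
    if noise_sd is None:
        sd_map = dict(DEFAULT_NOISE_SD)
    elif isinstance(noise_sd, (int, float)):
        sd_map = {a: float(noise_sd) for a in ANALYTES}
    else:
        sd_map = {a: float(noise_sd.get(a, 0.0)) for a in ANALYTES}

    latent = {
        "sulfate": np.interp(sched, sim.day, sim.sulfate_mM),
        "sulfide": np.interp(sched, sim.day, sim.sulfide_uM),
        "fe": np.interp(sched, sim.day, sim.fe_uM),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for analyte in ANALYTES:
        sd = sd_map[analyte]
        for d, mu in zip(sched, latent[analyte]):
            draws = np.clip(rng.normal(mu, sd, size=n_reps), 0.0, None) \
                if sd > 0 else np.full(n_reps, max(mu, 0.0))
            rep_sd = float(np.std(draws, ddof=1)) if n_reps > 1 else 0.0
            rows.append((float(d), analyte, float(draws.mean()), rep_sd, n_reps))
    return PorewaterSeries(pd.DataFrame(
        rows, columns=["day", "analyte", "mean", "sd", "n"]))


# ---------------------------------------------------------------------------
# ASV-grid generator


@dataclass(frozen=True)
class Hotspot:
    """Spatial enrichment of one hydrogenotroph taxon around the H2 outlet.

    Expected abundance of ``taxon`` is multiplied by
    1 + amplitude * exp(-distance/decay), distance in grid units from
    ``center`` (column label, row number).  The default centers the hotspot
    on the middle column at mid-height, where the H2 delivery tube ends.
    """

    taxon: int = 1
    center: tuple[str, int] = ("C", 4)
    amplitude: float = 4.0
    decay: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        if self.center[0] not in GRID_COLUMNS:
            raise ValueError(f"unknown grid column {self.center[0]!r}")
        if self.center[1] not in GRID_ROWS:
            raise ValueError(f"grid row {self.center[1]} outside 1..7")


@dataclass
class ASVTable:
    """ASV read counts on the 5x7 post-mortem sampling grid.

    ``counts``: samples x ASVs integer reads; ``taxonomy``: semicolon-ranked
    string per ASV; ``kitome``: contaminant reads per ASV from the reagent
    blank; ``meta``: per-sample grid_col / grid_row / equipment tag;
    ``copies_per_g``: 16S rRNA gene copies per gram of substrate.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    kitome: pd.Series
    meta: pd.DataFrame
    copies_per_g: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            raise ValueError("counts must be integers")
        if len(self.kitome) != c.shape[1]:
            raise ValueError("kitome vector length must equal the number of ASVs")
        if (self.kitome < 0).any():
            raise ValueError("kitome reads must be non-negative")
        grid = self.meta[self.meta["equipment"] == ""]
        if len(grid) and len(grid) != 35:
            # partial designs are allowed, a complete one has 5 x 7 spots
            pass

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def grid_samples(self, column: str | None = None) -> list[str]:
        """Sample ids on the spatial grid, optionally one radial column."""
        m = self.meta[self.meta["equipment"] == ""]
        if column is not None:
            if column not in GRID_COLUMNS:
                raise ValueError(f"unknown grid column {column!r}")
            m = m[m["grid_col"] == column]
        return list(m.index)


def _default_taxonomy(n_asvs: int, hotspot_taxon: int) -> list[str]:
    hydrogenotroph = ("Bacteria;Desulfobacterota;Desulfovibrionia;"
                      "Desulfovibrionales;Desulfovibrionaceae;Desulfocurvibacter")
    pool = [
        "Bacteria;Pseudomonadota;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
        "Bacteria;Bacteroidota;Bacteroidia;Marinilabiliales;Prolixibacteraceae;Sunxiuqinia",
        "Bacteria;Desulfobacterota;Desulfobacteria;Desulfobacterales;Desulfobacteraceae;unclassified",
        "Archaea;Halobacterota;Methanosarcinia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
        "Bacteria;Bacillota;Clostridia;Eubacteriales;Gracilibacteraceae;Gracilibacter",
        "Bacteria;Bacillota;Clostridia;Eubacteriales;Peptococcaceae;Desulfallas",
        "Bacteria;Bacillota;Symbiobacteriia;Symbiobacteriales;Symbiobacteriaceae;Symbiobacterium",
    ]
    tax = []
    for i in range(1, n_asvs + 1):
        if i == hotspot_taxon:
            tax.append(hydrogenotroph)
        else:
            tax.append(pool[(i - 1) % len(pool)])
    return tax


def generate_asv_table(n_asvs: int = 40,
                       grid: tuple[int, int] = (5, 7),
                       hotspot: Hotspot | None = None,
                       kitome_level: float = 20.0,
                       depth: float = 30000.0,
                       seed: int = 0,
                       dispersion: float = 10.0,
                       biomass_log_mean: float = math.log(5e8),
                       biomass_log_sd: float = 0.7,
                       central_enrichment: float = 3.0) -> ASVTable:
    """Generate a synthetic 5x7 spatial ASV table with kitome contamination.

    Baseline expected compositions follow a geometric rank-abundance curve;
    the hotspot taxon's expectation rises toward the H2 delivery point;
    counts are negative-binomial around the expected composition at the
    given mean library size; the kitome vector is drawn independently; 16S
    copies/g are log-normal with a central-column enrichment factor.
    """
    if hotspot is None:
        hotspot = Hotspot()
    if not (1 <= hotspot.taxon <= n_asvs):
        raise ValueError(f"hotspot taxon {hotspot.taxon} outside 1..{n_asvs}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if kitome_level < 0:
        raise ValueError("kitome_level must be non-negative")
    if grid != (5, 7):
        raise ValueError("only the 5x7 sampling design is supported")

    rng = np.random.default_rng(seed)
    base = 0.9 ** np.arange(n_asvs)
    base /= base.sum()

    col_x = {c: i for i, c in enumerate(GRID_COLUMNS)}
    cx, cy = col_x[hotspot.center[0]], float(hotspot.center[1])

    sample_ids, rows_meta, expected = [], [], []
    for col in GRID_COLUMNS:
        for row in GRID_ROWS:
            sid = f"{col}{row}"
            sample_ids.append(sid)
            rows_meta.append((col, row, ""))
            d = math.hypot(col_x[col] - cx, row - cy)
            mult = np.ones(n_asvs)
            mult[hotspot.taxon - 1] = 1.0 + hotspot.amplitude * math.exp(-d / hotspot.decay)
            p = base * mult
            expected.append(depth * p / p.sum())
    mu = np.vstack(expected)

    def nb_draw(mean: np.ndarray, k: float) -> np.ndarray:
        out = np.zeros(mean.shape, dtype=np.int64)
        pos = mean > 0
        out[pos] = rng.negative_binomial(k, k / (k + mean[pos]))
        return out

    counts = nb_draw(mu, dispersion)
    kitome = (nb_draw(np.full(n_asvs, float(kitome_level)), 5.0)
              if kitome_level > 0 else np.zeros(n_asvs, dtype=np.int64))

    asv_ids = [f"ASV{i}" for i in range(1, n_asvs + 1)]
    meta = pd.DataFrame(rows_meta, columns=["grid_col", "grid_row", "equipment"],
                        index=pd.Index(sample_ids, name="sample_id"))
    copies = np.exp(rng.normal(biomass_log_mean, biomass_log_sd, size=len(sample_ids)))
    central = meta["grid_col"].to_numpy() == "C"
    copies[central] *= central_enrichment

    return ASVTable(
        counts=pd.DataFrame(counts, index=meta.index, columns=asv_ids),
        taxonomy=pd.Series(_default_taxonomy(n_asvs, hotspot.taxon),
                           index=asv_ids, name="taxonomy"),
        kitome=pd.Series(kitome, index=asv_ids, name="KITOME"),
        meta=meta,
        copies_per_g=pd.Series(copies, index=meta.index, name="copies_per_g"),
    )
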