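"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Each generator emulates one instrument at realistic operating conditions:

* DVS: stepwise water-activity schedule with first-order exponential
  approach to Park-model equilibria (the simplest kinetic law satisfying a
  dm/dt equilibrium criterion).
* DSC: stepwise-isothermal melting traces whose per-hold Gaussian endotherm
  areas encode a chosen pore-size distribution plus bulk free water
  (endotherm-positive sign convention).
* Imaging: two-channel (counterstain + immunolabel) z-stacks over a
  honeycomb-like cell-wall lattice with a declining focal-attenuation
  profile through depth.
* Grouped measurements: labelled i.i.d. draws from stated distributions.

All noise is additive Gaussian unless stated otherwise; every generator
takes a mandatory seed and is byte-deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dvs import SorptionIsotherm, SorptionKineticTrace
from .errors import DomainError
from .imaging import TwoChannelImageStack
from .park import ParkParameters, park_model
from .stats import GroupedMeasurements
from .thermoporometry import (
    DSCThermogram,
    GibbsThomsonConstants,
    DEFAULT_CONSTANTS,
    PoreSizeDistribution,
    StepProgram,
    melting_temperature_for_diameter,
)

__all__ = [
    "SimulationSpec",
    "DEFAULT_PARK_PARAMS",
    "DEFAULT_DVS_SCHEDULE",
    "HoneycombGeometry",
    "gen_park_isotherm",
    "gen_dvs_kinetics",
    "gen_dsc_thermogram",
    "gen_image_stack",
    "gen_grouped_measurements",
]

#: wood-like Park parameters used as the default study condition: mass gain
#: ~2.4% at a_w = 0.1 rising to ~27.5% at a_w = 0.9, the scale typical of
#: lignocellulosic samples at 25 C.
DEFAULT_PARK_PARAMS = ParkParameters(A_L=2.0, b_L=15.0, k_H=12.0, k_a=1e-8, n=8.0)

#: default DVS schedule: relaxation time tau = 20 min, holds of 6*tau,
#: activities ascending 0.1..0.9 then descending 0.8..0.0.
DEFAULT_TAU_S = 1200.0
_ASC = [round(0.1 * i, 1) for i in range(1, 10)]
_DESC = [round(0.1 * i, 1) for i in range(8, -1, -1)]
DEFAULT_DVS_SCHEDULE: list[tuple[float, float]] = [
    (a, 6 * DEFAULT_TAU_S) for a in _ASC + _DESC
]


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one simulation (CLI/config plumbing)."""

    seed: int
    kind: str  # dvs | dsc | image | groups
    parameters: dict = field(default_factory=dict)
    noise_model: str = "gaussian-additive"

    def __post_init__(self) -> None:
        if self.kind not in ("dvs", "dsc", "image", "groups"):
            raise DomainError(f"unknown simulation kind {self.kind!r}")


# ---------------------------------------------------------------------------
# DVS


def gen_park_isotherm(
    params: ParkParameters,
    activity_grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SorptionIsotherm:
    """Equilibrium sorption isotherm from the Park model.

    ``noise_sd`` is the relative scale of multiplicative Gaussian noise
    (0.01 = 1% relative); 0 reproduces the model exactly.
    """
    a = np.asarray(activity_grid, float)
    if a.ndim != 1 or a.size == 0:
        raise DomainError("activity grid must be a non-empty 1-D array")
    if np.any(a < 0) or np.any(a >= 1):
        raise DomainError("activities must satisfy 0 <= a_w < 1")
    if a.size > 1 and np.any(np.diff(a) <= 0):
        raise DomainError("activity grid must be strictly increasing")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    m = np.asarray(park_model(params, a), float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m * (1.0 + noise_sd * rng.standard_normal(a.size))
    return SorptionIsotherm("sorption", a, m)


def gen_dvs_kinetics(
    params: ParkParameters = DEFAULT_PARK_PARAMS,
    schedule: list[tuple[float, float]] | None = None,
    tau: float = DEFAULT_TAU_S,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dry_mass_mg: float = 20.0,
    dry_duration_s: float = 3600.0,
    dt_s: float = 6.0,
) -> SorptionKineticTrace:
    """Stepwise DVS kinetic trace with exponential approach to equilibrium.

    A dry (a_w = 0) hold of ``dry_duration_s`` precedes the schedule, pinning
    the dry mass. Within each hold the mass follows
    m(t) = m_eq - (m_eq - m_start) * exp(-t/tau) toward the Park equilibrium
    for that activity. ``noise_sd`` is additive Gaussian noise in mg.
    """
    if schedule is None:
        schedule = DEFAULT_DVS_SCHEDULE
    if not schedule:
        raise DomainError("schedule must contain >= 1 hold")
    if tau <= 0 or dt_s <= 0 or dry_mass_mg <= 0 or dry_duration_s <= 0:
        raise DomainError("tau, dt, dry mass and dry duration must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    holds = [(0.0, float(dry_duration_s))] + [(float(a), float(d)) for a, d in schedule]
    times, masses, setpoints = [], [], []
    t0 = 0.0
    m_start = dry_mass_mg
    for aw, duration in holds:
        m_eq = dry_mass_mg * (1.0 + park_model(params, aw) / 100.0)
        n = max(2, int(round(duration / dt_s)))
        t_local = np.linspace(0.0, duration, n, endpoint=False) + dt_s
        m = m_eq - (m_eq - m_start) * np.exp(-t_local / tau)
        times.append(t0 + t_local)
        masses.append(m)
        setpoints.append(np.full(n, aw))
        t0 += duration
        m_start = float(m[-1])
    time = np.concatenate(times)
    mass = np.concatenate(masses)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mass = mass + noise_sd * rng.standard_normal(mass.size)
    return SorptionKineticTrace(
        time_s=time,
        mass_mg=np.clip(mass, 0, None),
        aw_setpoint=np.concatenate(setpoints),
    )


# ---------------------------------------------------------------------------
# DSC


def gen_dsc_thermogram(
    pore_dist: PoreSizeDistribution,
    program: StepProgram,
    free_water_fraction: float | None = None,
    sample_mass_mg: float = 8.0,
    peak_width_s: float = 30.0,
    baseline_mw: float = 0.0,
    baseline_slope_mw_per_s: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    constants: GibbsThomsonConstants = DEFAULT_CONSTANTS,
    ramp_rate_K_per_min: float = 1.0,
    dt_s: float = 1.0,
) -> DSCThermogram:
    """Stepwise-isothermal DSC melting trace encoding a pore distribution.

    Each pore bin's water melts as a Gaussian endotherm (sigma =
    ``peak_width_s``) centred mid-way through the hold whose temperature
    matches the bin's upper diameter edge via the Gibbs-Thomson relation
    (program temperatures must be consistent with the bin edges). Free water
    melts at the final hold. Peak areas equal water mass (mg) times Hf
    (J/g), i.e. mJ, so heat flow is in mW on a time axis in seconds;
    endotherms are positive ("exo down"), declared in the metadata.
    """
    if noise_sd < 0 or peak_width_s <= 0 or sample_mass_mg <= 0 or dt_s <= 0:
        raise DomainError("noise, peak width, sample mass and dt must be positive")
    if free_water_fraction is None:
        free_water_fraction = pore_dist.free_water_fraction
    total_frac = sum(b[2] for b in pore_dist.bins) + free_water_fraction
    if abs(total_frac - 100.0) > 0.5:
        raise DomainError("bin fractions + free water must sum to 100")
    hold_temps = program.temperatures
    # map each bin to the hold whose temperature matches its upper edge
    water_at_hold = np.zeros(hold_temps.size)
    for lo, hi, frac in pore_dist.bins:
        t_expect = melting_temperature_for_diameter(hi, constants)
        k = int(np.argmin(np.abs(hold_temps - t_expect)))
        if abs(hold_temps[k] - t_expect) > 0.05:
            raise DomainError(
                f"no program hold matches bin upper edge {hi * 1e9:.2f} nm "
                f"(expected hold at {t_expect:.2f} K)"
            )
        water_at_hold[k] += frac / 100.0 * pore_dist.total_freezing_water_mg
    water_at_hold[-1] += free_water_fraction / 100.0 * pore_dist.total_freezing_water_mg

    ramp_per_s = ramp_rate_K_per_min / 60.0
    times, temps, flows = [], [], []
    t0 = 0.0
    prev_T = None
    for (hold_T, duration), water_mg in zip(program.holds, water_at_hold):
        if prev_T is not None and hold_T > prev_T:
            ramp_dur = (hold_T - prev_T) / ramp_per_s
            n = max(2, int(round(ramp_dur / dt_s)))
            t_local = np.linspace(0.0, ramp_dur, n, endpoint=False) + dt_s
            times.append(t0 + t_local)
            temps.append(prev_T + t_local * ramp_per_s)
            flows.append(np.zeros(n))
            t0 += ramp_dur
        n = max(2, int(round(duration / dt_s)))
        t_local = np.linspace(0.0, duration, n, endpoint=False) + dt_s
        hf = np.zeros(n)
        if water_mg > 0:
            area_mj = water_mg * constants.Hf  # mg * J/g = mJ
            centre = duration / 2.0
            amp = area_mj / (peak_width_s * np.sqrt(2.0 * np.pi))
            hf = amp * np.exp(-0.5 * ((t_local - centre) / peak_width_s) ** 2)
        times.append(t0 + t_local)
        temps.append(np.full(n, hold_T))
        flows.append(hf)
        t0 += duration
        prev_T = hold_T
    time = np.concatenate(times)
    temp = np.concatenate(temps)
    flow = np.concatenate(flows) + baseline_mw + baseline_slope_mw_per_s * time
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + noise_sd * rng.standard_normal(flow.size)
    return DSCThermogram(
        time_s=time,
        temperature_K=temp,
        heat_flow_mw=flow,
        sample_mass_mg=sample_mass_mg,
        metadata={"sign_convention": "endotherm_up", "instrument": "synthetic"},
    )


# ---------------------------------------------------------------------------
# imaging


@dataclass(frozen=True)
class HoneycombGeometry:
    """Honeycomb-like cell-wall lattice: circular lumina on a hexagonal grid,
    walls as the interstitial space. Produces realistic wall/lumen pixel
    ratios without biological imagery."""

    cell_radius_px: float = 12.0
    wall_thickness_px: float = 4.0

    def wall_mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        ny, nx = shape_yx
        spacing = 2.0 * self.cell_radius_px + self.wall_thickness_px
        dy = spacing * np.sqrt(3.0) / 2.0
        centers = []
        row = 0
        y = 0.0
        while y < ny + spacing:
            x0 = (spacing / 2.0) if row % 2 else 0.0
            x = x0
            while x < nx + spacing:
                centers.append((y, x))
                x += spacing
            y += dy
            row += 1
        tree = cKDTree(np.array(centers))
        yy, xx = np.mgrid[0:ny, 0:nx]
        dist, _ = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
        wall = (dist.reshape(ny, nx) > self.cell_radius_px)
        if not wall.any() or wall.all():
            raise DomainError("degenerate wall geometry (covers none or all pixels)")
        return wall


def gen_image_stack(
    shape: tuple[int, int, int] = (3, 96, 96),
    wall_geometry: HoneycombGeometry | None = None,
    counterstain_level: float = 120.0,
    target_levels: tuple[float, float] = (100.0, 10.0),
    noise_sd: float = 5.0,
    seed: int | None = None,
    focal_profile: tuple[float, ...] | None = None,
    bit_depth: int = 8,
) -> TwoChannelImageStack:
    """Two-channel z-stack over a honeycomb wall lattice with ground truth.

    Channel 1 (counterstain) carries signal only on wall pixels; channel 2
    (target) is ``wall_level`` on walls and ``background`` elsewhere. Slices
    are attenuated by ``focal_profile`` (default geometric decay 0.8**i from
    the focal plane, emulating depth attenuation so that maximum projection
    recovers the focal-plane intensity), then per-voxel Gaussian noise of
    scale ``noise_sd`` is added and values are clipped to the bit depth. The
    ground-truth wall mask travels on the returned stack (``truth_mask``).
    """
    z, ny, nx = shape
    if z < 1 or ny < 8 or nx < 8:
        raise DomainError("stack must have z >= 1 and at least 8x8 pixels")
    wall_level, background = target_levels
    if wall_level <= background:
        raise DomainError("wall intensity must exceed background")
    top = 2**bit_depth - 1
    if not (0 <= background and wall_level <= top and 0 < counterstain_level <= top):
        raise DomainError("intensity levels must lie within the declared bit depth")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    geometry = wall_geometry or HoneycombGeometry()
    wall = geometry.wall_mask((ny, nx))
    if focal_profile is None:
        focal_profile = tuple(0.8**i for i in range(z))
    if len(focal_profile) != z:
        raise DomainError("focal profile length must equal z")
    rng = np.random.default_rng(seed)
    counter = np.empty((z, ny, nx))
    target = np.empty((z, ny, nx))
    for i, f in enumerate(focal_profile):
        counter[i] = np.where(wall, counterstain_level * f, 0.0)
        target[i] = np.where(wall, wall_level * f, background * f)
    if noise_sd > 0:
        counter = counter + noise_sd * rng.standard_normal(counter.shape)
        target = target + noise_sd * rng.standard_normal(target.shape)
    return TwoChannelImageStack(
        counterstain=np.clip(counter, 0, top),
        target=np.clip(target, 0, top),
        bit_depth=bit_depth,
        truth_mask=wall,
    )


# ---------------------------------------------------------------------------
# grouped measurements

_DISTRIBUTIONS = ("normal", "lognormal", "uniform")


def gen_grouped_measurements(
    group_specs: list[tuple[str, str, float, float, int]],
    seed: int | None = None,
) -> GroupedMeasurements:
    """Labelled i.i.d. samples per group.

    Each spec is (label, distribution, mean, sd, n) with n >= 3. For
    ``normal``, mean/sd are the distribution's moments (sd = 0 yields
    constants); for ``lognormal`` they parameterise the underlying normal on
    the log scale; for ``uniform`` they are matched moments (width =
    sd * sqrt(12)).
    """
    if not group_specs:
        raise DomainError("need >= 1 group spec")
    rng = np.random.default_rng(seed)
    rows = []
    for label, dist, mean, sd, n in group_specs:
        if n < 3:
            raise DomainError(f"group {label!r}: n must be >= 3")
        if sd < 0:
            raise DomainError(f"group {label!r}: sd must be >= 0")
        if dist == "normal":
            vals = mean + sd * rng.standard_normal(n)
        elif dist == "lognormal":
            vals = np.exp(mean + sd * rng.standard_normal(n))
        elif dist == "uniform":
            half = sd * np.sqrt(3.0)
            vals = rng.uniform(mean - half, mean + half, n)
        else:
            raise DomainError(
                f"unsupported distribution {dist!r}; choose from {_DISTRIBUTIONS}"
            )
        rows.extend((label, float(v)) for v in vals)
    return GroupedMeasurements(pd.DataFrame(rows, columns=["group", "value"]))
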