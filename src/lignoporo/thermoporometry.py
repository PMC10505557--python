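"""DSC thermoporosimetry: Gibbs-Thomson pore sizing from stepwise melting.

Water confined in a pore melts below the bulk melting point T0; for
cylindrical pores the depression maps to the pore diameter through the
Gibbs-Thomson relation

    D = 4 * T0 * gamma * cos(theta) / ((Tm - T0) * rho * Hf)

with T0 the bulk melting temperature, gamma the ice/pore-wall surface energy,
theta the contact angle (180 deg for a non-wetting ice front, so cos(theta)
cancels the negative depression), rho the density of water and Hf its
enthalpy of fusion. In a stepwise-isothermal DSC experiment the sample is
cooled well below T0 and then held at a series of increasing sub-zero
temperatures; the endotherm integrated over the hold at T_k measures the mass
of water melting between the previous hold temperature and T_k, i.e. the
water held in pores with diameters between D(T_{k-1}) and D(T_k). Holds at or
just below T0 measure bulk ("free") water.

All internal computation is in SI units (K, m, kg, J); constants are accepted
in the units they are conventionally quoted in (mJ m^-2, J g^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DomainError, SegmentationError

__all__ = [
    "GibbsThomsonConstants",
    "StepProgram",
    "DSCThermogram",
    "StepWindow",
    "PoreSizeDistribution",
    "WaterContent",
    "gibbs_thomson_diameter",
    "melting_temperature_for_diameter",
    "segment_steps",
    "integrate_endotherm",
    "pore_distribution",
    "total_water_content",
    "Thermoporometry",
]

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class GibbsThomsonConstants:
    """Physical constants of the Gibbs-Thomson inversion (defaults: water/ice
    in wood cell-wall pores, the values conventional for this measurement).

    T0 : bulk melting temperature, K.
    gamma : ice / pore-wall surface energy, mJ m^-2.
    theta : contact angle, degrees (180 = non-wetting ice front).
    rho : water density, kg m^-3.
    Hf : enthalpy of fusion, J g^-1.
    """

    T0: float = 273.15
    gamma: float = 12.1
    theta: float = 180.0
    rho: float = 1000.0
    Hf: float = 334.0

    def __post_init__(self) -> None:
        if self.T0 <= 0 or self.gamma <= 0 or self.rho <= 0 or self.Hf <= 0:
            raise DomainError("T0, gamma, rho and Hf must be positive")


DEFAULT_CONSTANTS = GibbsThomsonConstants()


def gibbs_thomson_diameter(Tm, constants: GibbsThomsonConstants = DEFAULT_CONSTANTS):
    """Pore diameter D (m) whose confined water melts at ``Tm`` (K).

    Requires Tm < T0 strictly; D diverges as Tm -> T0. Vectorised over Tm.
    """
    t = np.asarray(Tm, float)
    if np.any(t >= constants.T0):
        raise DomainError("Tm must be strictly below T0 (finite depression)")
    gamma_si = constants.gamma * 1e-3  # mJ m^-2 -> J m^-2
    hf_si = constants.Hf * 1e3  # J g^-1 -> J kg^-1
    d = (
        4.0
        * constants.T0
        * gamma_si
        * np.cos(np.deg2rad(constants.theta))
        / ((t - constants.T0) * constants.rho * hf_si)
    )
    return float(d) if np.isscalar(Tm) else d


def melting_temperature_for_diameter(D, constants: GibbsThomsonConstants = DEFAULT_CONSTANTS):
    """Algebraic inverse of :func:`gibbs_thomson_diameter`: Tm (K) for D (m)."""
    d = np.asarray(D, float)
    if np.any(d <= 0):
        raise DomainError("pore diameter must be positive")
    gamma_si = constants.gamma * 1e-3
    hf_si = constants.Hf * 1e3
    t = constants.T0 + 4.0 * constants.T0 * gamma_si * np.cos(
        np.deg2rad(constants.theta)
    ) / (d * constants.rho * hf_si)
    return float(t) if np.isscalar(D) else t


@dataclass
class StepProgram:
    """Ordered isothermal hold schedule: (temperature K, duration s) pairs,
    strictly increasing in temperature, typically ending at/above T0 for the
    bulk-water melt."""

    holds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.holds:
            raise DomainError("step program needs >= 1 hold")
        temps = [h[0] for h in self.holds]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise DomainError("hold temperatures must be strictly increasing")
        if any(h[1] <= 0 for h in self.holds):
            raise DomainError("hold durations must be positive")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([h[0] for h in self.holds])

    @classmethod
    def from_celsius(cls, holds_c: list[tuple[float, float]]) -> "StepProgram":
        return cls([(t + CELSIUS_OFFSET, d) for t, d in holds_c])


#: default hold schedule (degrees C, 600 s each): a deep-frozen start, a
#: ladder through the mesopore melting range, and a final above-zero hold for
#: the bulk free-water melt. Fully configurable.
DEFAULT_STEP_PROGRAM = StepProgram.from_celsius(
    [(-30.0, 600.0), (-10.0, 600.0), (-5.0, 600.0), (-3.0, 600.0), (-2.0, 600.0),
     (-1.2, 600.0), (-0.6, 600.0), (-0.2, 600.0), (2.0, 600.0)]
)


@dataclass
class DSCThermogram:
    """Heat-flow trace of a stepwise-isothermal DSC run.

    heat_flow_mw is endotherm-positive ("exo down"); the sign convention is
    carried in ``metadata['sign_convention']``.
    """

    time_s: np.ndarray
    temperature_K: np.ndarray
    heat_flow_mw: np.ndarray
    sample_mass_mg: float
    metadata: dict = field(default_factory=lambda: {"sign_convention": "endotherm_up"})

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.temperature_K = np.asarray(self.temperature_K, float)
        self.heat_flow_mw = np.asarray(self.heat_flow_mw, float)
        if not (self.time_s.shape == self.temperature_K.shape == self.heat_flow_mw.shape):
            raise DomainError("time, temperature and heat flow must have equal length")
        if self.time_s.size < 2 or np.any(np.diff(self.time_s) <= 0):
            raise DomainError("time must be strictly increasing")
        if self.sample_mass_mg <= 0:
            raise DomainError("sample mass must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "temperature_C": self.temperature_K - CELSIUS_OFFSET,
                "heat_flow_mW": self.heat_flow_mw,
            }
        )


@dataclass(frozen=True)
class StepWindow:
    """Index window of a thermogram corresponding to one isothermal hold."""

    start: int
    stop: int  # exclusive
    hold_temperature_K: float

    def __len__(self) -> int:
        return self.stop - self.start


def segment_steps(
    thermogram: DSCThermogram,
    program: StepProgram,
    temperature_tolerance: float = 0.1,
) -> list[StepWindow]:
    """Locate each programmed hold in the temperature trace.

    For every hold, the longest contiguous run of samples within
    ``temperature_tolerance`` K of the hold temperature (after the previous
    hold's window) becomes its window. A hold the trace never reaches raises
    :class:`SegmentationError` naming the temperature.
    """
    temp = thermogram.temperature_K
    windows: list[StepWindow] = []
    search_from = 0
    for hold_T, _dur in program.holds:
        in_band = np.abs(temp - hold_T) <= temperature_tolerance
        in_band[:search_from] = False
        best = None
        run_start = None
        for i, flag in enumerate(np.concatenate([in_band, [False]])):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if best is None or i - run_start > best[1] - best[0]:
                    best = (run_start, i)
                run_start = None
        if best is None or best[1] - best[0] < 2:
            raise SegmentationError(
                f"hold at {hold_T - CELSIUS_OFFSET:.2f} C not found in thermogram"
            )
        windows.append(StepWindow(best[0], best[1], hold_T))
        search_from = best[1]
    return windows


def integrate_endotherm(
    window: StepWindow,
    thermogram: DSCThermogram,
    baseline: str = "linear",
) -> float:
    """Endotherm enthalpy over a hold window, in J per g of sample.

    The baseline is anchored at the window endpoints (``linear``; each
    endpoint averaged over a few samples for noise robustness) or at the
    pre-peak plateau (``flat``). Heat flow in mW integrated over seconds
    yields mJ; dividing by the sample mass in mg gives J/g directly. Negative
    integrated areas (a noise artifact) are clipped to zero with a warning.
    """
    if len(window) < 2:
        raise DomainError("zero-length integration window")
    t = thermogram.time_s[window.start : window.stop]
    hf = thermogram.heat_flow_mw[window.start : window.stop]
    k = max(1, min(5, len(t) // 10))
    if baseline == "linear":
        y0, y1 = float(np.mean(hf[:k])), float(np.mean(hf[-k:]))
        base = y0 + (y1 - y0) * (t - t[0]) / (t[-1] - t[0])
    elif baseline == "flat":
        base = float(np.mean(hf[:k]))
    else:
        raise DomainError(f"unknown baseline mode {baseline!r}")
    area_mj = float(np.trapezoid(hf - base, t))
    if area_mj < 0:
        if area_mj < -1e-12:
            warnings.warn(
                f"negative endotherm area ({area_mj:.3g} mJ) clipped to zero", stacklevel=2
            )
        area_mj = 0.0
    return area_mj / thermogram.sample_mass_mg


@dataclass
class PoreSizeDistribution:
    """Gibbs-Thomson pore-size histogram.

    ``bins`` rows: (D_low m, D_high m, water_fraction % of total freezing
    water). ``free_water_fraction`` is the bulk-melt share; bin fractions plus
    the free fraction sum to 100.
    """

    bins: list[tuple[float, float, float]]
    free_water_fraction: float
    total_freezing_water_mg: float

    def __post_init__(self) -> None:
        for lo, hi, frac in self.bins:
            if lo <= 0 or hi <= lo:
                raise DomainError("bin edges must be positive with D_low < D_high")
            if frac < 0:
                raise DomainError("water fractions must be non-negative")
        total = sum(b[2] for b in self.bins) + self.free_water_fraction
        if abs(total - 100.0) > 0.5:
            raise DomainError(f"fractions must sum to 100 +- 0.5, got {total:.3f}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"d_low_nm": lo * 1e9, "d_high_nm": hi * 1e9, "freezing_water_pct": f}
                for lo, hi, f in self.bins
            ]
        )

    def summary(self) -> str:
        lines = [
            "Pore-size distribution (Gibbs-Thomson)",
            "=" * 46,
            f"{'d_low (nm)':>12}{'d_high (nm)':>12}{'water (%)':>12}",
        ]
        for lo, hi, f in self.bins:
            lines.append(f"{lo * 1e9:>12.2f}{hi * 1e9:>12.2f}{f:>12.2f}")
        lines += [
            "-" * 46,
            f"free (bulk) water: {self.free_water_fraction:.2f} %",
            f"total freezing water: {self.total_freezing_water_mg:.3f} mg",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of freezing-water share per diameter bin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        labels = [f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(df.d_low_nm, df.d_high_nm)]
        ax.bar(range(len(df)), df.freezing_water_pct)
        ax.set_xticks(range(len(df)), labels, rotation=45, ha="right")
        ax.set_xlabel("pore diameter (nm)")
        ax.set_ylabel("freezing water (%)")
        return ax


def pore_distribution(
    step_enthalpies: list[tuple[float, float]],
    constants: GibbsThomsonConstants = DEFAULT_CONSTANTS,
    free_water_cutoff: float = 0.2,
    sample_mass_mg: float = 1.0,
    start_temperature_K: float | None = None,
) -> PoreSizeDistribution:
    """Convert per-hold enthalpies into a pore-size distribution.

    Parameters
    ----------
    step_enthalpies : list of (hold temperature K, enthalpy J/g of sample)
        Strictly increasing in temperature, enthalpies >= 0.
    free_water_cutoff : float
        Holds within this many K of T0 (or above it) are pooled as bulk free
        water; the Gibbs-Thomson relation diverges there.
    start_temperature_K : float, optional
        Temperature defining the lower diameter edge of the first pore bin
        (the thermogram's cooling minimum). Defaults to 5 K below the first
        hold.

    Water melting at hold T_k is assigned to the diameter bin
    [D(T_{k-1}), D(T_k)]; the water mass at each hold is
    enthalpy * sample_mass / Hf. Fractions are normalised to total freezing
    water (pore + free) = 100 %.
    """
    if not step_enthalpies:
        raise DomainError("no step enthalpies")
    temps = np.array([t for t, _ in step_enthalpies])
    enths = np.array([h for _, h in step_enthalpies])
    if np.any(np.diff(temps) <= 0):
        raise DomainError("hold temperatures must be strictly increasing")
    if np.any(enths < 0):
        raise DomainError("enthalpies must be non-negative")
    if np.all(enths == 0):
        raise DegenerateDataError("all step enthalpies are zero")
    # J/g of sample * mg of sample / (J/g of water) -> mg of water
    masses_mg = enths * sample_mass_mg / constants.Hf
    is_free = temps >= constants.T0 - free_water_cutoff
    free_mass = float(masses_mg[is_free].sum())
    pore_T = temps[~is_free]
    pore_m = masses_mg[~is_free]
    total = free_mass + float(pore_m.sum())
    if total <= 0:
        raise DegenerateDataError("no freezing water detected")
    prev_T = start_temperature_K if start_temperature_K is not None else float(temps[0]) - 5.0
    bins: list[tuple[float, float, float]] = []
    carry = 0.0  # mass from degenerate-range holds (start temp == hold temp)
    for T, m in zip(pore_T, pore_m):
        lo = gibbs_thomson_diameter(prev_T, constants)
        hi = gibbs_thomson_diameter(T, constants)
        if hi > lo:
            bins.append((lo, hi, float((m + carry) / total * 100.0)))
            carry = 0.0
        else:
            if m > 0:
                warnings.warn(
                    f"hold at {T:.2f} K has no diameter range; merging its "
                    "water into the next bin",
                    stacklevel=2,
                )
            carry += float(m)
        prev_T = T
    if carry > 0:
        if not bins:
            raise DomainError("no hold defines a valid diameter range")
        lo, hi, f = bins[-1]
        bins[-1] = (lo, hi, f + float(carry / total * 100.0))
    return PoreSizeDistribution(
        bins=bins,
        free_water_fraction=free_mass / total * 100.0,
        total_freezing_water_mg=total,
    )


@dataclass(frozen=True)
class WaterContent:
    """Gravimetric water content of a saturated DSC sample."""

    saturated_mass_mg: float
    oven_dry_mass_mg: float

    @property
    def total_water_pct(self) -> float:
        return total_water_content(self.saturated_mass_mg, self.oven_dry_mass_mg)


def total_water_content(saturated_mass, oven_dry_mass) -> float:
    """Total water as % of saturated mass: (saturated - dry)/saturated * 100."""
    if saturated_mass <= 0 or oven_dry_mass <= 0:
        raise DomainError("masses must be positive")
    if oven_dry_mass > saturated_mass:
        raise DomainError("oven-dry mass exceeds saturated mass")
    return float((saturated_mass - oven_dry_mass) / saturated_mass * 100.0)


class Thermoporometry:
    """Model-style wrapper: thermogram + program -> pore-size distribution.

    >>> result = Thermoporometry(thermogram, program).fit()
    >>> print(result.summary())
    """

    def __init__(
        self,
        thermogram: DSCThermogram,
        program: StepProgram = DEFAULT_STEP_PROGRAM,
        constants: GibbsThomsonConstants = DEFAULT_CONSTANTS,
    ):
        self.thermogram = thermogram
        self.program = program
        self.constants = constants

    def fit(
        self,
        baseline: str = "linear",
        free_water_cutoff: float = 0.2,
        temperature_tolerance: float = 0.1,
    ) -> PoreSizeDistribution:
        windows = segment_steps(self.thermogram, self.program, temperature_tolerance)
        enthalpies = [
            (w.hold_temperature_K, integrate_endotherm(w, self.thermogram, baseline))
            for w in windows
        ]
        return pore_distribution(
            enthalpies,
            self.constants,
            free_water_cutoff=free_water_cutoff,
            sample_mass_mg=self.thermogram.sample_mass_mg,
            start_temperature_K=float(self.thermogram.temperature_K.min()),
        )
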