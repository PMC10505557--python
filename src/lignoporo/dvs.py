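"""Dynamic vapour sorption (DVS) kinetics: equilibrium extraction and isotherms.

A DVS instrument records sample mass against time while the water activity
(a_w = RH/100) of the surrounding gas is stepped through a programmed
schedule, classically 0 (dry nitrogen, defining the dry mass m_d) then
0.1 ... 0.9 and back down to 0. Each hold is considered equilibrated once the
rate of mass change falls below a predefined threshold; the equilibrium mass
gains

    M = (m_eq - m_d) / m_d * 100        [% of dry mass]

plotted against a_w form the sorption and desorption branches of the
isotherm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "SorptionKineticTrace",
    "SorptionIsotherm",
    "EquilibriumPoint",
    "mass_gain",
    "detect_equilibria",
    "build_isotherm",
    "hysteresis",
]

#: default equilibrium criterion: |dm/dt| below this, in % of dry mass per
#: minute, estimated over the trailing window
DEFAULT_DMDT_THRESHOLD = 0.002
#: default trailing-window length, minutes
DEFAULT_WINDOW_MIN = 10.0


@dataclass
class SorptionKineticTrace:
    """Raw DVS time series.

    ``time_s`` strictly increasing; ``aw_setpoint`` is piecewise constant; the
    dry mass may be carried explicitly or derived from an initial a_w = 0
    segment by the analysis.
    """

    time_s: np.ndarray
    mass_mg: np.ndarray
    aw_setpoint: np.ndarray
    dry_mass_mg: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.mass_mg = np.asarray(self.mass_mg, float)
        self.aw_setpoint = np.asarray(self.aw_setpoint, float)
        if not (self.time_s.shape == self.mass_mg.shape == self.aw_setpoint.shape):
            raise DomainError("time, mass and setpoint must have equal length")
        if self.time_s.size < 2 or np.any(np.diff(self.time_s) <= 0):
            raise DomainError("time must be strictly increasing with >= 2 samples")
        if np.any(self.mass_mg < 0):
            raise DomainError("mass must be non-negative")
        if np.any((self.aw_setpoint < 0) | (self.aw_setpoint > 1)):
            raise DomainError("activity setpoints must lie in [0, 1]")
        if self.dry_mass_mg is not None and self.dry_mass_mg <= 0:
            raise DomainError("dry mass must be positive")

    def holds(self) -> list[tuple[float, slice]]:
        """Contiguous constant-setpoint segments as (a_w, index slice)."""
        change = np.flatnonzero(np.diff(self.aw_setpoint) != 0) + 1
        edges = np.concatenate(([0], change, [self.aw_setpoint.size]))
        return [
            (float(self.aw_setpoint[edges[i]]), slice(int(edges[i]), int(edges[i + 1])))
            for i in range(edges.size - 1)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "mass_mg": self.mass_mg, "aw_setpoint": self.aw_setpoint}
        )


@dataclass(frozen=True)
class EquilibriumPoint:
    """Detected equilibrium for one activity hold."""

    aw: float
    m_eq_mg: float
    equilibrated: bool
    dmdt_pct_per_min: float


@dataclass
class SorptionIsotherm:
    """One branch (sorption or desorption) of an equilibrium isotherm."""

    branch: str
    activity: np.ndarray
    mass_gain_pct: np.ndarray

    def __post_init__(self) -> None:
        if self.branch not in ("sorption", "desorption"):
            raise DomainError("branch must be 'sorption' or 'desorption'")
        self.activity = np.asarray(self.activity, float)
        self.mass_gain_pct = np.asarray(self.mass_gain_pct, float)
        if self.activity.shape != self.mass_gain_pct.shape:
            raise DomainError("activity and mass gain must have equal length")
        if self.activity.size > 1:
            d = np.diff(self.activity)
            ok = np.all(d > 0) if self.branch == "sorption" else np.all(d < 0)
            if not ok:
                raise DomainError(f"{self.branch} branch activities must be monotone")

    def __len__(self) -> int:
        return int(self.activity.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": self.branch,
                "aw": self.activity,
                "mass_gain_pct": self.mass_gain_pct,
            }
        )


def mass_gain(m_eq, m_d) -> np.ndarray | float:
    """Water mass gain M = (m_eq - m_d)/m_d * 100, in % of dry mass.

    Negative values (desorption equilibria below the dry reference) are
    allowed but flagged with a warning.
    """
    m_eq_a = np.asarray(m_eq, float)
    if np.any(np.asarray(m_d, float) <= 0):
        raise DomainError("dry mass must be positive")
    m = (m_eq_a - m_d) / m_d * 100.0
    if np.any(m < 0):
        warnings.warn("equilibrium mass below dry reference (negative M)", stacklevel=2)
    return float(m) if np.isscalar(m_eq) else m


def detect_equilibria(
    trace: SorptionKineticTrace,
    dmdt_threshold: float = DEFAULT_DMDT_THRESHOLD,
    window: float = DEFAULT_WINDOW_MIN,
) -> list[EquilibriumPoint]:
    """Extract one equilibrium mass per activity hold.

    For each hold, the mass slope over the final ``window`` minutes is
    estimated by linear regression; if |dm/dt| (as % of dry mass per minute)
    is below ``dmdt_threshold`` the hold is equilibrated and m_eq is the mean
    mass over that window. Holds never meeting the criterion are reported with
    ``equilibrated=False`` and the terminal-window mean as provisional mass.

    The dry reference for the %-scale of the slope is ``trace.dry_mass_mg`` if
    set, else the first sample's mass.
    """
    if dmdt_threshold < 0:
        raise DomainError("dm/dt threshold must be >= 0")
    m_ref = trace.dry_mass_mg if trace.dry_mass_mg is not None else float(trace.mass_mg[0])
    if m_ref <= 0:
        raise DomainError("reference dry mass must be positive")
    win_s = window * 60.0
    out: list[EquilibriumPoint] = []
    for aw, sl in trace.holds():
        t = trace.time_s[sl]
        m = trace.mass_mg[sl]
        hold_len = t[-1] - t[0]
        if win_s > hold_len:
            raise ConfigurationError(
                f"window ({window} min) longer than hold at a_w={aw} ({hold_len / 60:.1f} min)"
            )
        tail = t >= t[-1] - win_s
        slope_mg_per_s = float(np.polyfit(t[tail], m[tail], 1)[0])
        dmdt = slope_mg_per_s * 60.0 / m_ref * 100.0  # % dry mass / min
        out.append(
            EquilibriumPoint(
                aw=aw,
                m_eq_mg=float(np.mean(m[tail])),
                equilibrated=bool(abs(dmdt) < dmdt_threshold),
                dmdt_pct_per_min=dmdt,
            )
        )
    return out


def build_isotherm(
    trace: SorptionKineticTrace,
    dmdt_threshold: float = DEFAULT_DMDT_THRESHOLD,
    window: float = DEFAULT_WINDOW_MIN,
) -> tuple[SorptionIsotherm, SorptionIsotherm]:
    """Split a kinetic trace into sorption and desorption isotherm branches.

    The dry mass m_d is taken from the initial a_w = 0 segment (terminal-
    window mean) unless ``trace.dry_mass_mg`` is set. Branches are partitioned
    at the maximum-activity hold, the peak itself assigned to the sorption
    branch. The initial dry segment defines m_d and is not an isotherm point.
    """
    points = detect_equilibria(trace, dmdt_threshold, window)
    has_dry_lead = points and points[0].aw == 0.0
    if trace.dry_mass_mg is not None:
        m_d = trace.dry_mass_mg
    elif has_dry_lead:
        m_d = points[0].m_eq_mg
    else:
        raise DomainError("no initial a_w=0 segment and no explicit dry mass: m_d undefined")
    if has_dry_lead:
        points = points[1:]
    if not points:
        raise DomainError("trace contains no activity holds after the dry segment")
    aw = np.array([p.aw for p in points])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gains = np.array([mass_gain(p.m_eq_mg, m_d) for p in points])
    peak = int(np.argmax(aw))  # ties broken toward sorption by argmax-first
    sorption = SorptionIsotherm("sorption", aw[: peak + 1], gains[: peak + 1])
    desorption = SorptionIsotherm("desorption", aw[peak + 1 :], gains[peak + 1 :])
    return sorption, desorption


def hysteresis(sorption: SorptionIsotherm, desorption: SorptionIsotherm) -> pd.DataFrame:
    """Sorption/desorption gap dM = M_des - M_sorp on the shared activity grid.

    The desorption branch is linearly interpolated onto the sorption
    activities that fall inside its range.
    """
    if len(sorption) == 0 or len(desorption) == 0:
        raise DomainError("both branches must be non-empty")
    des_a = desorption.activity[::-1]  # ascending for interpolation
    des_m = desorption.mass_gain_pct[::-1]
    lo, hi = des_a[0], des_a[-1]
    inside = (sorption.activity >= lo) & (sorption.activity <= hi)
    if not inside.any():
        raise DomainError("sorption and desorption activity ranges do not overlap")
    aw = sorption.activity[inside]
    delta = np.interp(aw, des_a, des_m) - sorption.mass_gain_pct[inside]
    return pd.DataFrame({"aw": aw, "delta_m_pct": delta})
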