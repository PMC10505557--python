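"""Park sorption-isotherm model: forward evaluation, fitting and goodness of fit.

The Park model describes equilibrium water uptake of a hygroscopic solid as the
sum of three physically interpretable contributions,

    M(a_w) = A_L * b_L * a_w / (1 + b_L * a_w)   (Langmuir adsorption on
                                                  specific sorption sites)
           + k_H * a_w                            (Henry-type dissolution)
           + n * k_H**n * k_a * a_w**n            (clustering of n water
                                                  molecules at high activity)

where ``a_w`` is the water activity (relative humidity / 100), ``M`` the mass
gain in grams of water per 100 g of dry sample (i.e. percent), ``A_L`` the
Langmuir capacity (%), ``b_L`` the dimensionless Langmuir affinity, ``k_H``
Henry's solubility coefficient (% per unit activity), ``k_a`` the clustering
equilibrium constant and ``n`` the mean number of water molecules per cluster.

Fit quality is reported through the mean relative percentage deviation modulus

    MRD = (100 / N) * sum_i |m_i - m_p,i| / m_i

where a value below 10% is the conventional good-fit bound for sorption
isotherms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError

__all__ = ["ParkParameters", "park_model", "mrd", "ParkSorptionModel", "ParkFitResults"]

#: default box bounds for the fit, (lower, upper) per parameter in the order
#: (A_L, b_L, k_H, k_a, n); wide but finite so trial points cannot overflow.
DEFAULT_BOUNDS = (
    np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
    np.array([1e4, 1e6, 1e3, 1e6, 12.0]),
)


@dataclass(frozen=True)
class ParkParameters:
    """Parameters of the three-term Park sorption model.

    All parameters are non-negative; ``n`` (mean cluster size) is treated as a
    continuous quantity >= 1.
    """

    A_L: float
    b_L: float
    k_H: float
    k_a: float
    n: float

    def __post_init__(self) -> None:
        vals = (self.A_L, self.b_L, self.k_H, self.k_a, self.n)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise DomainError("Park parameters must be finite and non-negative")
        if self.n < 1:
            raise DomainError(f"mean cluster size n must be >= 1, got {self.n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A_L, self.b_L, self.k_H, self.k_a, self.n], float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParkParameters":
        return cls(*(float(v) for v in x))


def park_model(params: ParkParameters, a_w) -> np.ndarray | float:
    """Evaluate the Park model mass gain M (%) at water activity ``a_w``.

    ``a_w`` may be a scalar or array; values must lie in [0, 1).
    """
    a = np.asarray(a_w, dtype=float)
    if np.any(a < 0) or np.any(a >= 1):
        raise DomainError("water activity must satisfy 0 <= a_w < 1")
    p = params
    langmuir = p.A_L * p.b_L * a / (1.0 + p.b_L * a)
    henry = p.k_H * a
    # written as n*k_a*(k_H*a)**n to keep intermediate magnitudes tame
    cluster = p.n * p.k_a * np.power(p.k_H * a, p.n)
    m = langmuir + henry + cluster
    return float(m) if np.isscalar(a_w) else m


def mrd(observed, predicted) -> float:
    """Mean relative percentage deviation modulus between two mass-gain vectors.

    Zero-valued observed points are excluded (the relative residual is
    undefined there) with a warning; N is reduced accordingly.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError("observed and predicted must have equal length")
    if obs.size == 0:
        raise DomainError("MRD of empty vectors is undefined")
    keep = obs != 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-valued observed point(s) from MRD",
            stacklevel=2,
        )
    obs, pred = obs[keep], pred[keep]
    if obs.size == 0:
        raise DomainError("all observed values are zero; MRD undefined")
    return float(100.0 / obs.size * np.sum(np.abs(obs - pred) / np.abs(obs)))


def _residuals(x: np.ndarray, a: np.ndarray, m: np.ndarray) -> np.ndarray:
    p = ParkParameters.from_array(np.maximum(x, [0, 0, 0, 0, 1]))
    return park_model(p, a) - m


def _jacobian(x: np.ndarray, a: np.ndarray, m: np.ndarray) -> np.ndarray:
    A_L, b_L, k_H, k_a, n = np.maximum(x, [0, 0, 0, 0, 1])
    kha = k_H * a
    with np.errstate(divide="ignore", invalid="ignore"):
        pow_n = np.power(kha, n)
        pow_nm1 = np.power(kha, n - 1.0)
        log_kha = np.where(kha > 0, np.log(np.where(kha > 0, kha, 1.0)), 0.0)
    pow_n = np.where(kha > 0, pow_n, 0.0)
    pow_nm1 = np.where(kha > 0, pow_nm1, 0.0)
    denom = 1.0 + b_L * a
    jac = np.empty((a.size, 5))
    jac[:, 0] = b_L * a / denom
    jac[:, 1] = A_L * a / denom**2
    jac[:, 2] = a + n * n * k_a * a * pow_nm1
    jac[:, 3] = n * pow_n
    jac[:, 4] = k_a * pow_n * (1.0 + n * log_kha)
    return jac


class ParkSorptionModel:
    """Park-model fit of an equilibrium sorption isotherm.

    Parameters
    ----------
    activity : array-like
        Water activities in [0, 1), at least 5 points (the model has 5 free
        parameters).
    mass_gain : array-like
        Equilibrium mass gains M in % of dry mass, one per activity.

    Examples
    --------
    >>> model = ParkSorptionModel(activity, mass_gain)
    >>> res = model.fit()
    >>> res.params.k_H, res.mrd
    """

    def __init__(self, activity, mass_gain):
        a = np.asarray(activity, dtype=float)
        m = np.asarray(mass_gain, dtype=float)
        if a.ndim != 1 or a.shape != m.shape:
            raise DomainError("activity and mass_gain must be 1-D and equal length")
        if a.size < 5:
            raise DomainError("Park fit needs >= 5 isotherm points (5 parameters)")
        if np.any(a < 0) or np.any(a >= 1):
            raise DomainError("water activity must satisfy 0 <= a_w < 1")
        if np.all(m == 0):
            raise DegenerateDataError("all mass gains are zero; fit is degenerate")
        order = np.argsort(a)
        self.activity = a[order]
        self.mass_gain = m[order]
        self.nobs = int(a.size)

    @classmethod
    def from_isotherm(cls, isotherm) -> "ParkSorptionModel":
        """Build from a :class:`~lignoporo.dvs.SorptionIsotherm`."""
        return cls(isotherm.activity, isotherm.mass_gain_pct)

    # -- multi-start initialisation ------------------------------------------
    def _starts(self, init: ParkParameters | None) -> list[np.ndarray]:
        if init is not None:
            return [init.as_array()]
        a, m = self.activity, self.mass_gain
        pos = m > 0
        kH0 = float(m[pos][0] / a[pos][0]) if pos.any() else 1.0
        AL0 = max(float(m[pos][0]) / 2.0, 1e-3) if pos.any() else 1.0
        starts = []
        for bL0 in (1.0, 10.0, 100.0):
            for ka0 in (1e-8, 0.3):
                for n0 in (2.0, 4.0, 8.0):
                    starts.append(np.array([AL0, bL0, kH0, ka0, n0]))
        return starts

    def fit(
        self,
        init: ParkParameters | None = None,
        bounds: tuple | None = None,
    ) -> "ParkFitResults":
        """Fit by trust-region nonlinear least squares with multi-start.

        The objective is the unweighted residual sum of squares; MRD is
        reported as a diagnostic, not optimised. Without an explicit ``init``
        a 3x3x3 lattice over (b_L, k_a, n) seeds the search and the
        lowest-cost solution is returned.
        """
        lb, ub = bounds if bounds is not None else DEFAULT_BOUNDS
        # an essentially-exact fit ends the start sweep early
        stop_cost = 1e-16 * max(float(np.sum(self.mass_gain**2)), 1.0)
        best = None
        for x0 in self._starts(init):
            x0c = np.clip(x0, lb, ub)
            try:
                sol = least_squares(
                    _residuals,
                    x0c,
                    jac=_jacobian,
                    bounds=(lb, ub),
                    args=(self.activity, self.mass_gain),
                    method="trf",
                    x_scale=np.maximum(np.abs(x0c), 1e-3),
                    xtol=1e-13,
                    ftol=1e-13,
                    gtol=1e-13,
                    max_nfev=1000,
                )
            except Exception:  # a pathological start must not kill the sweep
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost < stop_cost:
                break
        if best is None:
            raise RuntimeError("all Park-fit starts failed")
        params = ParkParameters.from_array(np.maximum(best.x, [0, 0, 0, 0, 1]))
        predicted = park_model(params, self.activity)
        residuals = self.mass_gain - predicted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_mrd = mrd(self.mass_gain, predicted)
        cov = _covariance(best, self.nobs)
        return ParkFitResults(
            model=self,
            params=params,
            mrd=fit_mrd,
            residuals=residuals,
            converged=bool(best.status > 0),
            cost=float(best.cost),
            cov_params=cov,
        )


def _covariance(sol, nobs: int) -> np.ndarray | None:
    """Gauss-Newton covariance estimate from the final Jacobian (may be
    singular for degenerate fits, in which case None is returned)."""
    dof = nobs - sol.x.size
    if dof <= 0:
        return None
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * (2.0 * sol.cost / dof)
    except np.linalg.LinAlgError:
        return None
    return cov


@dataclass
class ParkFitResults:
    """Results of a Park-model fit.

    Attributes
    ----------
    params : ParkParameters
        Best-fit parameters.
    mrd : float
        Mean relative percentage deviation modulus (%); < 10 is the
        conventional good-fit bound.
    residuals : ndarray
        Observed minus predicted mass gain, per point.
    converged : bool
        Whether the optimiser reported convergence for the winning start.
    cov_params : ndarray or None
        Gauss-Newton parameter covariance (None if not estimable).
    """

    model: ParkSorptionModel
    params: ParkParameters
    mrd: float
    residuals: np.ndarray
    converged: bool
    cost: float
    cov_params: np.ndarray | None = None
    param_names: tuple = field(default=("A_L", "b_L", "k_H", "k_a", "n"), repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def bse(self) -> np.ndarray | None:
        """Approximate standard errors of the parameters."""
        if self.cov_params is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    def predict(self, a_w) -> np.ndarray | float:
        return park_model(self.params, a_w)

    def summary(self) -> str:
        lines = [
            "Park sorption model fit",
            "=" * 47,
            f"{'n points':<20}{self.nobs:>10d}",
            f"{'converged':<20}{str(self.converged):>10}",
            f"{'MRD (%)':<20}{self.mrd:>10.4f}   (<10: good fit)",
            f"{'RSS':<20}{2 * self.cost:>10.4g}",
            "-" * 47,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        bse = self.bse
        for i, name in enumerate(self.param_names):
            se = f"{bse[i]:>14.4g}" if bse is not None else f"{'--':>14}"
            lines.append(f"{name:<8}{self.params.as_array()[i]:>14.6g}{se}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observed points and the fitted isotherm curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.activity, self.model.mass_gain, "o", label="observed")
        grid = np.linspace(0, min(self.model.activity.max() * 1.05, 0.999), 200)
        ax.plot(grid, park_model(self.params, grid), "-", label="Park fit")
        ax.set_xlabel("water activity $a_w$")
        ax.set_ylabel("mass gain M (%)")
        ax.legend()
        return ax


def fit_park(isotherm, init: ParkParameters | None = None, bounds=None) -> ParkFitResults:
    """Functional wrapper: fit the Park model to a sorption isotherm."""
    return ParkSorptionModel.from_isotherm(isotherm).fit(init=init, bounds=bounds)
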