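"""Two-state equilibrium denaturation and the ionic-strength dependence of
protein stability.

A cooperative two-state unfolder N <-> D in a chemical denaturant obeys the
linear extrapolation model (LEM): the unfolding free energy is linear in
denaturant, dG(u) = dG0 - m_eq*u, and the observed fluorescence is a
population-weighted average of two linear baselines,

    signal(u) = [F_N + a*u + (F_D + b*u) * K(u)] / (1 + K(u)),
    K(u)      = exp(-(dG0 - m_eq*u) / RT),

with K the [D]/[N] equilibrium constant (dG0 > 0 means the folded state is
favoured in water).  Stability of a highly charged domain additionally
depends on salt: Debye-Hueckel screening predicts dG linear in sqrt(I)
(ionic strength I), whereas direct ion binding or Hofmeister effects predict
linearity in I, and a log dependence is the signature of a site-binding
isotherm.  This module fits single curves, fits the three competing salt
models, and ranks them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .constants import rt_kj

__all__ = [
    "DenaturationCurve",
    "TwoStateEqFit",
    "StabilitySeries",
    "SaltModelFit",
    "NoTransitionError",
    "compute_ionic_strength",
    "two_state_signal",
    "fraction_unfolded",
    "fit_equilibrium_curve",
    "fit_salt_model",
    "compare_salt_models",
    "SALT_MODELS",
]

DEFAULT_TEMPERATURE = 303.15  # K; plate-reader experiments at 30 C


class NoTransitionError(ValueError):
    """Raised when a denaturation curve shows no resolvable transition."""


@dataclass
class DenaturationCurve:
    """Equilibrium fluorescence vs denaturant at one salt condition."""

    urea: np.ndarray  # M
    signal: np.ndarray  # fluorescence, arbitrary units
    temperature: float = DEFAULT_TEMPERATURE  # K
    salt_label: str = ""
    ionic_strength: float = 0.0  # M

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.urea.shape != self.signal.shape:
            raise ValueError("urea and signal must have the same length")
        if np.any(self.urea < 0):
            raise ValueError("urea concentrations must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class TwoStateEqFit:
    """Parameters of a two-state LEM fit with linear baselines."""

    dG0: float  # kJ/mol, unfolding free energy at 0 M urea
    m_eq: float  # kJ/mol/M
    baseline_native: tuple[float, float]  # (intercept, slope)
    baseline_denatured: tuple[float, float]
    dG0_err: float
    m_eq_err: float
    baseline_native_err: tuple[float, float]
    baseline_denatured_err: tuple[float, float]
    rss: float
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def Cm(self) -> float:
        """Denaturation midpoint, M (only meaningful for dG0 > 0)."""
        return self.dG0 / self.m_eq


@dataclass
class StabilitySeries:
    """Unfolding free energy vs ionic strength for one salt."""

    ionic_strength: np.ndarray  # M
    dG: np.ndarray  # kJ/mol
    dG_errors: np.ndarray | None = None
    salt_type: str = "NaCl"

    def __post_init__(self) -> None:
        self.ionic_strength = np.asarray(self.ionic_strength, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if self.ionic_strength.shape != self.dG.shape:
            raise ValueError("ionic_strength and dG must have the same length")
        if np.any(self.ionic_strength < 0):
            raise ValueError("ionic strength must be non-negative")
        if self.dG_errors is not None:
            self.dG_errors = np.asarray(self.dG_errors, dtype=float)
            if self.dG_errors.shape != self.dG.shape:
                raise ValueError("dG_errors must match dG length")


@dataclass
class SaltModelFit:
    """One salt model (sqrt_I, linear_I or log_I) fitted to a series."""

    model: str
    slope: float  # m_eq_salt, kJ/mol per model-specific unit
    intercept: float  # dG at zero predictor, kJ/mol
    slope_err: float
    intercept_err: float
    r_squared: float
    rss: float


SALT_MODELS = ("sqrt_I", "linear_I", "log_I")

_TRANSFORMS = {
    "sqrt_I": np.sqrt,
    "linear_I": lambda x: x,
    "log_I": np.log,
}


def compute_ionic_strength(salt_concentrations) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i^2) over ionic species.

    Parameters
    ----------
    salt_concentrations
        Iterable of ``(species, concentration_M, charge)`` triples, one per
        ionic species actually in solution (a 1:1 salt contributes two
        entries).  Buffer components are excluded unless explicitly listed.
    """
    total = 0.0
    for entry in salt_concentrations:
        try:
            species, conc, charge = entry
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"each entry must be (species, concentration, charge): {entry!r}"
            ) from exc
        if charge is None:
            raise ValueError(f"missing charge for species {species!r}")
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"negative concentration for {species!r}")
        total += conc * float(charge) ** 2
    return 0.5 * total


def two_state_signal(urea, dG0, m_eq, fN, aN, fD, aD, temperature=DEFAULT_TEMPERATURE):
    """Observed signal of the two-state LEM with linear baselines."""
    u = np.asarray(urea, dtype=float)
    K = np.exp(-(dG0 - m_eq * u) / rt_kj(temperature))
    return ((fN + aN * u) + (fD + aD * u) * K) / (1.0 + K)


def fraction_unfolded(urea, dG0, m_eq, temperature=DEFAULT_TEMPERATURE):
    """Equilibrium denatured-state population K/(1+K) at each urea value."""
    u = np.asarray(urea, dtype=float)
    K = np.exp(-(dG0 - m_eq * u) / rt_kj(temperature))
    return K / (1.0 + K)


def _estimate_noise(signal: np.ndarray) -> float:
    # second differences cancel smooth trends; var of d2 = 6 sigma^2
    if len(signal) < 3:
        return 0.0
    d2 = np.diff(signal, n=2)
    return float(np.sqrt(np.mean(d2**2) / 6.0))


def fit_equilibrium_curve(curve: DenaturationCurve) -> TwoStateEqFit:
    """Fit the six-parameter two-state LEM to one denaturation curve.

    Nonlinear least squares with a deterministic 8-point multistart over
    (dG0, m_eq); baselines are seeded from the curve ends.  Standard errors
    come from the covariance of the best fit.

    Raises
    ------
    NoTransitionError
        If the signal range does not exceed three times the estimated noise
        (flat, baseline-like data).
    """
    u, y = curve.urea, curve.signal
    if len(u) < 6:
        raise ValueError("need at least 6 points to fit a two-state curve")
    T = curve.temperature
    noise = _estimate_noise(y)
    span = float(np.ptp(y))
    if span <= 3.0 * noise or span == 0.0:
        raise NoTransitionError(
            "no transition detected: signal range does not exceed noise"
        )

    order = np.argsort(u)
    u, y = u[order], y[order]
    n_end = max(2, len(u) // 4)
    fN0, fD0 = float(np.mean(y[:n_end])), float(np.mean(y[-n_end:]))

    umax = float(u.max())
    # deterministic multistart grid over the thermodynamic parameters
    starts = [
        (dG0_s, m_s)
        for dG0_s in (2.0, 5.0, 10.0, 20.0)
        for m_s in (2.0, 8.0)
    ]

    def residuals(p):
        return two_state_signal(u, *p, temperature=T) - y

    best = None
    for dG0_s, m_s in starts:
        p0 = np.array([dG0_s, m_s, fN0, 0.0, fD0, 0.0])
        try:
            sol = least_squares(residuals, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("equilibrium fit failed to converge from any start")
    rss, sol = best
    p = sol.x.copy()
    jac = sol.jac
    # the model is exactly invariant under swapping the state labels
    # (dG0, m_eq, native, denatured) -> (-dG0, -m_eq, denatured, native);
    # canonicalise to the m_eq > 0 branch
    if p[1] < 0:
        p = np.array([-p[0], -p[1], p[4], p[5], p[2], p[3]])
        jac = jac[:, [0, 1, 4, 5, 2, 3]] * np.array([-1, -1, 1, 1, 1, 1])
    if p[1] <= 0 or not (0.0 < p[0] / p[1] < umax):
        raise NoTransitionError(
            "no transition detected: fitted midpoint outside the data range"
        )
    # baseline-like data can be absorbed entirely by the baselines; demand a
    # real amplitude between the native and denatured branches at the midpoint
    cm = p[0] / p[1]
    sep = abs((p[2] + p[3] * cm) - (p[4] + p[5] * cm))
    if sep < 0.1 * span:
        raise NoTransitionError(
            "no transition detected: fitted transition amplitude below "
            "10% of the signal range"
        )

    # covariance from the Jacobian at the solution
    dof = max(1, len(u) - len(p))
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        perr = np.full(len(p), np.nan)

    return TwoStateEqFit(
        dG0=float(p[0]),
        m_eq=float(p[1]),
        baseline_native=(float(p[2]), float(p[3])),
        baseline_denatured=(float(p[4]), float(p[5])),
        dG0_err=float(perr[0]),
        m_eq_err=float(perr[1]),
        baseline_native_err=(float(perr[2]), float(perr[3])),
        baseline_denatured_err=(float(perr[4]), float(perr[5])),
        rss=rss,
        temperature=T,
    )


def fit_salt_model(series: StabilitySeries, model: str) -> SaltModelFit:
    """Least-squares fit of dG on a transformed ionic-strength predictor.

    ``sqrt_I`` is the Debye-Hueckel limiting-law form dG = dG0 + m*sqrt(I);
    ``linear_I`` and ``log_I`` are the competing direct-binding/Hofmeister
    forms.  Weighted by 1/dG_errors^2 when errors are present (equal weights
    reduce to ordinary least squares).
    """
    if model not in _TRANSFORMS:
        raise ValueError(f"unknown model {model!r}; expected one of {SALT_MODELS}")
    I, dG = series.ionic_strength, series.dG
    if len(I) < 3:
        raise ValueError("need at least 3 points to fit a salt model")
    if model == "log_I" and np.any(I <= 0):
        raise ValueError("log_I model requires strictly positive ionic strength")
    x = _TRANSFORMS[model](I)
    X = sm.add_constant(x)
    if series.dG_errors is not None and np.all(series.dG_errors > 0):
        res = sm.WLS(dG, X, weights=1.0 / series.dG_errors**2).fit()
    else:
        res = sm.OLS(dG, X).fit()
    rss = float(np.sum(res.resid**2))
    return SaltModelFit(
        model=model,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_err=float(res.bse[1]),
        intercept_err=float(res.bse[0]),
        r_squared=float(res.rsquared),
        rss=rss,
    )


def compare_salt_models(series: StabilitySeries) -> list[SaltModelFit]:
    """Fit all three salt models and rank them (best first) by R-squared.

    Ties in R-squared are broken by residual sum of squares.  All three fits
    are always returned; with fewer than 4 points the models are not
    distinguishable and an error is raised.
    """
    if len(series.ionic_strength) < 4:
        raise ValueError(
            "salt models are indistinguishable with fewer than 4 points"
        )
    fits = [fit_salt_model(series, m) for m in SALT_MODELS]
    fits.sort(key=lambda f: (-f.r_squared, f.rss))
    return fits
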