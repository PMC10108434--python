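"""Unfolding kinetics, chevron unfolding-arm analysis, and the salt
phi-value decomposition.

For a two-state folder the observed unfolding relaxation at high denaturant
is a single exponential, signal(t) = offset + amplitude*exp(-k_u*t).  The
unfolding arm of the chevron plot is linear, ln k_u(u) = ln k_u0 + m_ku*u,
and extrapolates the water unfolding rate k_u0.  The folding rate follows
from detailed balance, k_f0 = k_u0 * exp(dG0/RT), with dG0 the equilibrium
unfolding free energy.  Two derived quantities place the transition state:

* Tanford beta, beta_urea = 1 - RT*m_ku/m_eq — the fraction of the
  equilibrium m-value accrued before the transition state (near 1 means a
  compact, native-like transition state);
* the salt phi-value, phi_f_salt = ddG(D->TS) / ddG(D->N), where
  ddG(D->TS) = -RT*ln(kf_high/kf_low) and ddG(D->N) = -RT*ln(K_high/K_low)
  with K = kf/ku — phi > 1 means salt stabilises the transition state more
  than the native state, i.e. electrostatic strain peaks at the transition
  state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .constants import rt_kj
from .equilibrium import DEFAULT_TEMPERATURE

__all__ = [
    "KineticTrace",
    "ChevronFit",
    "FoldingSummary",
    "SaltDdG",
    "EnergyDiagram",
    "fit_unfolding_trace",
    "fit_unfolding_arm",
    "derive_folding_rate",
    "compute_beta_urea",
    "compute_salt_ddG",
    "fit_lnk_vs_sqrt_ionic_strength",
    "build_energy_diagram",
]

#: |ddG(D->N)| below which phi_f_salt is reported as undefined, kJ/mol.
PHI_UNDEFINED_TOL = 0.1


class NoDecayError(ValueError):
    """Raised when a kinetic trace shows no resolvable exponential decay."""


@dataclass
class KineticTrace:
    """Single unfolding time course at one urea/salt condition."""

    time: np.ndarray  # s
    signal: np.ndarray
    urea: float = 0.0  # M
    ionic_strength: float = 0.0  # M
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if len(self.time) < 10:
            raise ValueError("kinetic trace needs at least 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ChevronFit:
    """Linear fit of ln k_u vs urea over the unfolding arm."""

    ln_ku0: float  # intercept at 0 M urea
    m_ku: float  # 1/M
    ln_ku0_err: float
    m_ku_err: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    urea_range: tuple[float, float]

    @property
    def ku0(self) -> float:
        """Extrapolated water unfolding rate, 1/s."""
        return math.exp(self.ln_ku0)

    @property
    def ku0_err(self) -> float:
        return self.ku0 * self.ln_ku0_err


@dataclass
class FoldingSummary:
    """Per-condition bundle of kinetic and thermodynamic folding parameters."""

    condition: str
    ku0: float  # 1/s
    kf0: float  # 1/s
    m_eq: float  # kJ/mol/M
    m_ku: float  # 1/M
    beta_urea: float
    temperature: float  # K
    ku0_err: float = float("nan")
    kf0_err: float = float("nan")
    m_eq_err: float = float("nan")
    m_ku_err: float = float("nan")
    beta_urea_err: float = float("nan")
    dG0: float = float("nan")  # kJ/mol
    dG0_err: float = float("nan")


@dataclass
class SaltDdG:
    """Salt-induced free-energy changes and the salt phi-value.

    Sign convention: negative means salt stabilises (lowers) the relevant
    state gap, matching -RT*ln(rate ratio).
    """

    ddG_Ddagger: float  # kJ/mol, D->TS
    ddG_DN: float  # kJ/mol, D->N
    phi_f_salt: float  # nan when undefined
    phi_defined: bool
    ddG_Ddagger_err: float = float("nan")
    ddG_DN_err: float = float("nan")
    phi_f_salt_err: float = float("nan")


def fit_unfolding_trace(trace: KineticTrace):
    """Fit offset + amplitude*exp(-k*t) to an unfolding trace.

    Returns ``(k_obs, amplitude, offset, errors)`` with ``errors`` a dict of
    standard errors from the fit covariance.

    Raises
    ------
    NoDecayError
        For flat traces with no resolvable amplitude.
    """
    t, y = trace.time, trace.signal
    span = float(np.ptp(y))
    # noise estimate from second differences (trend-free)
    d2 = np.diff(y, n=2)
    noise = float(np.sqrt(np.mean(d2**2) / 6.0)) if len(d2) else 0.0
    if span == 0.0 or span <= 3.0 * noise:
        raise NoDecayError("no decay: trace amplitude not resolvable above noise")

    off0 = float(np.mean(y[-max(3, len(y) // 10):]))
    amp0 = float(y[0] - off0)
    # crude rate guess: time to reach half amplitude
    half = off0 + amp0 / 2.0
    below = np.nonzero((y - half) * np.sign(amp0) <= 0)[0]
    t_half = t[below[0]] if len(below) else t[len(t) // 2]
    k0 = math.log(2.0) / max(t_half - t[0], (t[1] - t[0]))

    def model(tt, k, amp, off):
        return off + amp * np.exp(-k * tt)

    kmax = 10.0 / (t[1] - t[0])
    popt, pcov = curve_fit(
        model, t, y, p0=[k0, amp0, off0],
        bounds=([1e-12, -np.inf, -np.inf], [kmax, np.inf, np.inf]),
        maxfev=10000, xtol=1e-15, ftol=1e-15,
    )
    if popt[0] >= 0.99 * kmax or popt[0] <= 1.01e-12:
        raise NoDecayError("rate estimate pinned at search bound")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    errors = {"k_obs": float(perr[0]), "amplitude": float(perr[1]),
              "offset": float(perr[2])}
    return float(popt[0]), float(popt[1]), float(popt[2]), errors


def fit_unfolding_arm(points) -> ChevronFit:
    """Ordinary least squares of ln k_u on urea over the unfolding arm.

    ``points`` is an iterable of ``(urea_M, ku_per_s)`` pairs, all on the
    unfolding limb of the chevron.
    """
    pts = [(float(u), float(k)) for u, k in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 urea points for the unfolding arm")
    urea = np.array([p[0] for p in pts])
    ku = np.array([p[1] for p in pts])
    if np.any(ku <= 0):
        raise ValueError("unfolding rates must be positive")
    X = sm.add_constant(urea)
    res = sm.OLS(np.log(ku), X).fit()
    return ChevronFit(
        ln_ku0=float(res.params[0]),
        m_ku=float(res.params[1]),
        ln_ku0_err=float(res.bse[0]),
        m_ku_err=float(res.bse[1]),
        cov=np.asarray(res.cov_params()),
        urea_range=(float(urea.min()), float(urea.max())),
    )


def derive_folding_rate(ku0, dG0, T=DEFAULT_TEMPERATURE, ku0_err=0.0, dG0_err=0.0):
    """Folding rate from detailed balance: kf0 = ku0 * exp(dG0/RT).

    Returns ``(kf0, kf0_err)`` with the error from first-order propagation
    of the (independent) errors on ku0 and dG0.
    """
    if ku0 <= 0:
        raise ValueError("ku0 must be positive")
    RT = rt_kj(T)
    kf0 = ku0 * math.exp(dG0 / RT)
    rel2 = (ku0_err / ku0) ** 2 + (dG0_err / RT) ** 2
    return kf0, kf0 * math.sqrt(rel2)


def compute_beta_urea(m_ku, m_eq, T=DEFAULT_TEMPERATURE, m_ku_err=0.0, m_eq_err=0.0):
    """Tanford beta from the kinetic and equilibrium m-values.

    beta = 1 - RT*m_ku/m_eq, the fraction of the equilibrium m-value accrued
    between the denatured and transition states.  Returns ``(beta, beta_err)``.
    """
    if m_eq <= 0:
        raise ValueError("m_eq must be positive")
    RT = rt_kj(T)
    ratio = RT * m_ku / m_eq
    beta = 1.0 - ratio
    if ratio != 0:
        rel2 = (m_ku_err / m_ku) ** 2 if m_ku else 0.0
        rel2 += (m_eq_err / m_eq) ** 2
        err = abs(ratio) * math.sqrt(rel2)
    else:
        err = RT * m_ku_err / m_eq
    return beta, err


def compute_salt_ddG(kf_low, kf_high, ku_low, ku_high, T=DEFAULT_TEMPERATURE,
                     kf_low_err=0.0, kf_high_err=0.0,
                     ku_low_err=0.0, ku_high_err=0.0) -> SaltDdG:
    """Salt-induced ddG decomposition between a low- and high-salt condition.

    ddG(D->TS) = -RT*ln(kf_high/kf_low); ddG(D->N) = -RT*ln(K_high/K_low)
    with K = kf/ku; phi_f_salt is their ratio, flagged undefined (not an
    exception) when |ddG(D->N)| < 0.1 kJ/mol.
    """
    rates = (kf_low, kf_high, ku_low, ku_high)
    if any(r <= 0 for r in rates):
        raise ValueError("all rate constants must be positive")
    RT = rt_kj(T)
    ddG_ts = -RT * math.log(kf_high / kf_low)
    ddG_dn = -RT * math.log((kf_high / ku_high) / (kf_low / ku_low))

    rel = {
        "kf_low": kf_low_err / kf_low,
        "kf_high": kf_high_err / kf_high,
        "ku_low": ku_low_err / ku_low,
        "ku_high": ku_high_err / ku_high,
    }
    ddG_ts_err = RT * math.hypot(rel["kf_low"], rel["kf_high"])
    ddG_dn_err = RT * math.sqrt(sum(v**2 for v in rel.values()))

    defined = abs(ddG_dn) >= PHI_UNDEFINED_TOL
    if defined:
        phi = ddG_ts / ddG_dn
        phi_err = abs(phi) * math.sqrt(
            (ddG_ts_err / ddG_ts) ** 2 + (ddG_dn_err / ddG_dn) ** 2
        ) if ddG_ts != 0 else ddG_ts_err / abs(ddG_dn)
    else:
        phi, phi_err = float("nan"), float("nan")
    return SaltDdG(
        ddG_Ddagger=ddG_ts, ddG_DN=ddG_dn,
        phi_f_salt=phi, phi_defined=defined,
        ddG_Ddagger_err=ddG_ts_err, ddG_DN_err=ddG_dn_err,
        phi_f_salt_err=phi_err,
    )


def fit_lnk_vs_sqrt_ionic_strength(points):
    """Least squares of ln k_u on sqrt(I) (Debye-Hueckel form for rates).

    ``points`` is an iterable of ``(ionic_strength_M, ku_per_s)``; returns
    ``(slope, intercept, r_squared)``.
    """
    pts = [(float(i), float(k)) for i, k in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    I = np.array([p[0] for p in pts])
    ku = np.array([p[1] for p in pts])
    if np.any(I <= 0):
        raise ValueError("ionic strength must be positive")
    if np.any(ku <= 0):
        raise ValueError("rates must be positive")
    X = sm.add_constant(np.sqrt(I))
    res = sm.OLS(np.log(ku), X).fit()
    return float(res.params[1]), float(res.params[0]), float(res.rsquared)


@dataclass
class EnergyDiagram:
    """Relative D / TS / N free-energy levels at two salt conditions.

    The denatured state is fixed at 0 in both conditions and only
    between-condition differences of the TS and N levels are physical (the
    absolute barrier height contains an arbitrary kinetic prefactor that
    cancels between conditions).
    """

    ddG_Ddagger: float  # G_TS(high) - G_TS(low), kJ/mol
    ddG_DN: float  # G_N(high) - G_N(low), kJ/mol
    dG_DN_low: float  # G_N - G_D at low salt, kJ/mol
    dG_DN_high: float
    temperature: float


def build_energy_diagram(low: FoldingSummary, high: FoldingSummary) -> EnergyDiagram:
    """Two-condition folding free-energy diagram from rate constants."""
    if abs(low.temperature - high.temperature) > 1e-9:
        raise ValueError("summaries must share a temperature")
    RT = rt_kj(low.temperature)
    # with D at 0: G_TS = -RT ln kf + const, G_N = -RT ln(kf/ku)
    ddG_ts = -RT * math.log(high.kf0 / low.kf0)
    g_n_low = -RT * math.log(low.kf0 / low.ku0)
    g_n_high = -RT * math.log(high.kf0 / high.ku0)
    return EnergyDiagram(
        ddG_Ddagger=ddG_ts,
        ddG_DN=g_n_high - g_n_low,
        dG_DN_low=g_n_low,
        dG_DN_high=g_n_high,
        temperature=low.temperature,
    )
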