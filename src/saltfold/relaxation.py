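"""Backbone amide NMR relaxation analysis: chemical-shift perturbations,
off-resonance R1rho -> R2 conversion, and Lipari-Szabo model-free fitting.

The model-free spectral density for an isotropically tumbling molecule is

    J(w) = (2/5) * [ S^2*tc/(1+(w tc)^2) + (1-S^2)*t/(1+(w t)^2) ],
    1/t  = 1/tc + 1/te,

with S^2 the generalized order parameter, te the effective internal
correlation time and tc the global rotational correlation time.  "Model 2"
fits (S^2, te) per residue with a single shared tc, from 15N R1, R2 and
{1H}-15N NOE through the standard dipolar + CSA expressions.  R2 itself is
obtained from the measured off-resonance R1rho via
R1rho = R1*cos^2(theta) + R2*sin^2(theta), theta = atan(nu_SL/Omega).

Isotropic tumbling is the implemented diffusion model; an axially symmetric
tensor would require per-residue N-H orientation vectors, which the CSV
interface does not carry, and is left as an extension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import constants as c

__all__ = [
    "CSPRecord",
    "RelaxationRecord",
    "ModelFreeParams",
    "SpectrometerConfig",
    "ModelFreeResult",
    "compute_csp",
    "r2_from_r1rho",
    "spectral_density",
    "predict_relaxation_rates",
    "r1rho_from_r1_r2",
    "fit_model2",
]


@dataclass
class CSPRecord:
    """Per-residue chemical shift perturbation between two conditions."""

    residue: int
    dH: float  # ppm
    dN: float  # ppm

    @property
    def csp(self) -> float:
        return compute_csp(self.dH, self.dN)


@dataclass
class SpectrometerConfig:
    """Field and physical constants for amide 15N relaxation.

    Defaults are a 600 MHz (14.1 T) spectrometer with the usual
    N-H bond length (1.02 A) and 15N CSA (-160 ppm).
    """

    proton_frequency: float = 600.0e6  # Hz
    rNH: float = c.R_NH  # m
    csa: float = c.CSA_N  # unitless (ppm * 1e-6)
    gamma_H: float = c.GAMMA_H  # rad/s/T
    gamma_N: float = c.GAMMA_N  # rad/s/T

    def __post_init__(self) -> None:
        if self.proton_frequency <= 0:
            raise ValueError("proton frequency must be positive")

    @property
    def B0(self) -> float:
        """Static field, tesla."""
        return 2.0 * math.pi * self.proton_frequency / self.gamma_H

    @property
    def omega_H(self) -> float:
        """1H Larmor frequency magnitude, rad/s."""
        return abs(self.gamma_H) * self.B0

    @property
    def omega_N(self) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return abs(self.gamma_N) * self.B0

    @property
    def d(self) -> float:
        """Dipolar coupling constant magnitude, rad/s."""
        return (
            c.MU0_OVER_4PI * c.HBAR * abs(self.gamma_H) * abs(self.gamma_N)
            / self.rNH**3
        )

    @property
    def c_csa(self) -> float:
        """CSA interaction constant magnitude, rad/s."""
        return self.omega_N * abs(self.csa) / math.sqrt(3.0)


@dataclass
class ModelFreeParams:
    """Lipari-Szabo parameters for one residue."""

    S2: float  # order parameter, [0, 1]
    tau_e: float  # s, internal correlation time
    tau_c: float  # s, global rotational correlation time

    def __post_init__(self) -> None:
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError(f"S2 must be in [0, 1], got {self.S2}")
        if not 0.0 < self.tau_e < self.tau_c:
            raise ValueError("require 0 < tau_e < tau_c")


@dataclass
class RelaxationRecord:
    """Measured 15N relaxation rates for one residue."""

    residue: int
    R1: float  # 1/s
    R1rho: float  # 1/s
    NOE: float
    nu_SL: float = 2000.0  # Hz, spin-lock strength
    Omega: float = 0.0  # Hz, offset from the 15N carrier
    R2: float = float("nan")  # 1/s, derived
    R1_err: float = float("nan")
    R1rho_err: float = float("nan")
    R2_err: float = float("nan")
    NOE_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R1rho <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.NOE > 1.0:
            warnings.warn(
                f"residue {self.residue}: NOE > 1 is unphysical for 15N "
                "at these fields", stacklevel=2,
            )


@dataclass
class ModelFreeResult:
    """Outcome of a model-2 fit: per-residue parameters plus global tau_c."""

    params: dict[int, ModelFreeParams]
    tau_c: float  # s
    chi2: float
    excluded: list[int] = field(default_factory=list)


def compute_csp(dH: float, dN: float) -> float:
    """Weighted 1H/15N chemical-shift distance sqrt((0.1*dN)^2 + dH^2), ppm."""
    return math.hypot(0.1 * dN, dH)


def _theta(nu_SL: float, Omega: float) -> float:
    if nu_SL <= 0:
        raise ValueError("spin-lock strength must be positive")
    if Omega == 0:
        return math.pi / 2.0
    return math.atan(nu_SL / abs(Omega))


def r2_from_r1rho(R1: float, R1rho: float, nu_SL: float, Omega: float) -> float:
    """Recover R2 from off-resonance R1rho.

    R1rho = R1*cos^2(theta) + R2*sin^2(theta) with theta = atan(nu_SL/Omega);
    theta -> 90 deg on resonance (Omega -> 0), where R2 = R1rho.
    """
    th = _theta(nu_SL, Omega)
    cos2, sin2 = math.cos(th) ** 2, math.sin(th) ** 2
    r2 = (R1rho - R1 * cos2) / sin2
    if r2 <= 0:
        raise ValueError(
            f"inconsistent input: R1rho={R1rho} below the R1 projection "
            f"at theta={math.degrees(th):.1f} deg implies R2 <= 0"
        )
    return r2


def r1rho_from_r1_r2(R1: float, R2: float, nu_SL: float, Omega: float) -> float:
    """Forward composition R1rho = R1*cos^2(theta) + R2*sin^2(theta)."""
    th = _theta(nu_SL, Omega)
    return R1 * math.cos(th) ** 2 + R2 * math.sin(th) ** 2


def spectral_density(omega, params: ModelFreeParams):
    """Model-free spectral density J(omega), s/rad (even in omega)."""
    w = np.asarray(omega, dtype=float)
    tc, te, S2 = params.tau_c, params.tau_e, params.S2
    tau = 1.0 / (1.0 / tc + 1.0 / te)
    J = 0.4 * (
        S2 * tc / (1.0 + (w * tc) ** 2)
        + (1.0 - S2) * tau / (1.0 + (w * tau) ** 2)
    )
    return J if J.shape else float(J)


def _rates_from_arrays(S2, tau_e, tau_c, config: SpectrometerConfig):
    """Vectorized (R1, R2, NOE) for arrays of model-free parameters."""
    S2 = np.asarray(S2, dtype=float)
    tau_e = np.asarray(tau_e, dtype=float)
    wH, wN = config.omega_H, config.omega_N
    d2_4 = config.d**2 / 4.0
    c2 = config.c_csa**2

    tau = 1.0 / (1.0 / tau_c + 1.0 / tau_e)

    def J(w):
        return 0.4 * (
            S2 * tau_c / (1.0 + (w * tau_c) ** 2)
            + (1.0 - S2) * tau / (1.0 + (w * tau) ** 2)
        )

    J0 = J(0.0)
    JN = J(wN)
    JHmN = J(wH - wN)
    JH = J(wH)
    JHpN = J(wH + wN)

    R1 = d2_4 * (JHmN + 3.0 * JN + 6.0 * JHpN) + c2 * JN
    R2 = (d2_4 / 2.0) * (4.0 * J0 + JHmN + 3.0 * JN + 6.0 * JH + 6.0 * JHpN) \
        + (c2 / 6.0) * (4.0 * J0 + 3.0 * JN)
    sigma = d2_4 * (6.0 * JHpN - JHmN)
    NOE = 1.0 + (config.gamma_H / config.gamma_N) * sigma / R1
    return R1, R2, NOE


def predict_relaxation_rates(params: ModelFreeParams,
                             config: SpectrometerConfig | None = None):
    """Forward-calculate (R1, R2, NOE) from model-free parameters.

    Standard dipolar + CSA expressions; the NOE carries the signed
    gamma_H/gamma_N ratio, so 15N NOEs are below 1.
    """
    config = config or SpectrometerConfig()
    R1, R2, NOE = _rates_from_arrays(params.S2, params.tau_e, params.tau_c, config)
    return float(R1), float(R2), float(NOE)


def _fit_residue(obs, sigma, tau_c, config, te_floor_ps=0.1):
    """Grid + bounded refinement of (S2, te) for one residue at fixed tau_c.

    Internally parameterised as (S2, te_ps): finite-difference Jacobians on
    SI-scale correlation times are hopelessly ill-conditioned.
    """
    obs = np.asarray(obs)
    sigma = np.asarray(sigma)
    te_cap_ps = 0.999 * tau_c * 1e12

    def resid(p):
        S2 = min(max(p[0], 0.0), 1.0)
        te = min(max(p[1], te_floor_ps), te_cap_ps) * 1e-12
        R1, R2, NOE = _rates_from_arrays(S2, te, tau_c, config)
        return (np.array([R1, R2, NOE]) - obs) / sigma

    S2_grid = np.linspace(0.05, 1.0, 12)
    te_grid = np.geomspace(1.0, tau_c * 1e12 / 3.0, 12)
    SS, TT = np.meshgrid(S2_grid, te_grid, indexing="ij")
    R1g, R2g, NOEg = _rates_from_arrays(SS.ravel(), TT.ravel() * 1e-12,
                                        tau_c, config)
    chi2_grid = (((np.stack([R1g, R2g, NOEg], axis=1) - obs) / sigma) ** 2
                 ).sum(axis=1)
    order = np.argsort(chi2_grid)
    scored = [(float(chi2_grid[k]), (SS.ravel()[k], TT.ravel()[k]))
              for k in order[:3]]
    # refine from the three best grid cells; the (S2, te) surface has
    # shallow secondary valleys that can trap a single start
    best = None
    for _, start in scored[:3]:
        sol = least_squares(
            resid, np.array(start),
            bounds=([0.0, te_floor_ps], [1.0, te_cap_ps]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        chi2 = float(sol.fun @ sol.fun)
        if best is None or chi2 < best[0]:
            best = (chi2, sol.x)
    return np.array([best[1][0], best[1][1] * 1e-12]), best[0]


def fit_model2(records, config: SpectrometerConfig | None = None,
               tau_c_bounds=(1e-9, 20e-9)) -> ModelFreeResult:
    """Fit Lipari-Szabo model 2 (per-residue S2, te; one global tau_c).

    Chi-square over (R1, R2, NOE) per residue, weighted by the per-rate
    errors when present (equal weights otherwise).  R2 is taken from the
    record, or derived from R1rho/nu_SL/Omega when absent.  The global tau_c
    is found by a bounded 1-D search and the whole parameter set is then
    polished jointly.  Residues whose R2 < R1 (impossible for ns-scale
    tumbling) are excluded with a warning.
    """
    config = config or SpectrometerConfig()
    records = list(records)
    if len(records) < 5:
        raise ValueError("need at least 5 residues with complete rates")

    obs, sig, resids, excluded = [], [], [], []
    for rec in records:
        R2 = rec.R2
        if not np.isfinite(R2):
            R2 = r2_from_r1rho(rec.R1, rec.R1rho, rec.nu_SL, rec.Omega)
        if R2 < rec.R1:
            warnings.warn(
                f"residue {rec.residue}: R2 < R1 is inconsistent with "
                "ns-scale tumbling; excluded from the model-free fit",
                stacklevel=2,
            )
            excluded.append(rec.residue)
            continue
        o = np.array([rec.R1, R2, rec.NOE])
        s = np.array([rec.R1_err, rec.R2_err if np.isfinite(rec.R2_err)
                      else rec.R1rho_err, rec.NOE_err])
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            s = np.ones(3)
        obs.append(o)
        sig.append(s)
        resids.append(rec.residue)
    if len(obs) < 5:
        raise ValueError("fewer than 5 physically consistent residues remain")

    def total_chi2(tau_c):
        return sum(_fit_residue(o, s, tau_c, config)[1]
                   for o, s in zip(obs, sig))

    outer = minimize_scalar(total_chi2, bounds=tau_c_bounds, method="bounded",
                            options={"xatol": 1e-12})
    tau_c = float(outer.x)

    per = [np.asarray(_fit_residue(o, s, tau_c, config)[0])
           for o, s in zip(obs, sig)]

    # joint Levenberg-Marquardt polish of (tau_c, all S2, all te), in
    # (ns, unitless, ps) units so the Jacobian is well conditioned
    n = len(obs)
    obs_arr = np.array(obs)
    sig_arr = np.array(sig)

    def joint_resid(y):
        tc = abs(y[0]) * 1e-9
        S2 = y[1:][0::2]
        te = np.abs(y[1:][1::2]) * 1e-12
        R1, R2, NOE = _rates_from_arrays(S2, te, tc, config)
        calc = np.stack([R1, R2, NOE], axis=1)
        return ((calc - obs_arr) / sig_arr).ravel()

    y0 = np.empty(1 + 2 * n)
    y0[0] = tau_c * 1e9
    y0[1:][0::2] = [p[0] for p in per]
    y0[1:][1::2] = [p[1] * 1e12 for p in per]
    sol = least_squares(joint_resid, y0, method="lm", max_nfev=50000,
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    tau_c = abs(float(sol.x[0])) * 1e-9
    S2_fit = sol.x[1:][0::2]
    te_fit = np.minimum(np.abs(sol.x[1:][1::2]) * 1e-12, 0.999 * tau_c)
    chi2 = float(sol.fun @ sol.fun)

    params = {
        rid: ModelFreeParams(S2=float(min(max(s2, 0.0), 1.0)),
                             tau_e=float(te), tau_c=tau_c)
        for rid, s2, te in zip(resids, S2_fit, te_fit)
    }
    return ModelFreeResult(params=params, tau_c=tau_c, chi2=chi2,
                           excluded=excluded)
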