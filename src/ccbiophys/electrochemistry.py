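"""Protein-film voltammetry of an adsorbed one-electron redox couple.

Simulation and analysis of cyclic voltammetry of a surface-confined
Fe(III)/Fe(II) heme couple (cytochrome c electrostatically immobilized on a
SAM-coated gold electrode):

* :func:`simulate_surface_voltammogram` — Butler–Volmer kinetics of an
  adsorbed couple, integrated over a triangular potential sweep.
* :func:`extract_peaks` / :func:`midpoint_potential` — anodic/cathodic peak
  potentials and the midpoint potential E1/2, with Ag/AgCl → NHE correction.
* :func:`reduction_thermodynamics` — reduction entropy ΔS°rc and enthalpy
  ΔH°rc from the temperature dependence of E1/2.
* :func:`fit_trumpet` — standard heterogeneous electron-transfer rate
  constant ks (and transfer coefficient alpha) from the growth of the
  anodic/cathodic peak separation with scan rate (trumpet plot), matched
  against the numerically simulated working curve.
* :func:`fit_arrhenius` / :func:`predict_arrhenius` — pre-exponential factor
  A and activation enthalpy from the temperature dependence of ks.

Conventions: potentials are handled in mV externally and volts internally;
one electron is transferred (n = 1); current amplitudes are in arbitrary
units since only peak *positions* carry the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "N_ELECTRONS",
    "NHE_OFFSET_MV",
    "Voltammogram",
    "RedoxThermo",
    "ETKinetics",
    "simulate_surface_voltammogram",
    "extract_peaks",
    "midpoint_potential",
    "reduction_thermodynamics",
    "gibbs_helmholtz_potential",
    "fit_trumpet",
    "fit_arrhenius",
    "predict_arrhenius",
]

# Physical constants (SI) and the reference-electrode correction.
FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)
N_ELECTRONS = 1  # heme Fe3+/Fe2+ couple
#: Correction added to potentials measured vs. Ag/AgCl/NaCl(sat.) to place
#: them on the normal hydrogen electrode scale.
NHE_OFFSET_MV = 192.0

_EXP_CLIP = 700.0  # exponent clip guarding against overflow


@dataclass
class Voltammogram:
    """One triangular-sweep voltammogram of a surface-confined couple.

    Attributes
    ----------
    potential_mV : np.ndarray
        Electrode potential along the sweep (forward then reverse), mV.
    current : np.ndarray
        Faradaic current in arbitrary units (∝ dθ/dt, θ the oxidized
        fraction); positive = anodic.
    scan_rate : float
        Sweep rate v in V/s.
    temperature : float
        Cell temperature in K.
    reference : str
        ``"Ag/AgCl"`` or ``"NHE"`` — the scale of ``potential_mV``.
    """

    potential_mV: np.ndarray
    current: np.ndarray
    scan_rate: float
    temperature: float
    reference: str = "NHE"

    def __post_init__(self) -> None:
        self.potential_mV = np.asarray(self.potential_mV, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential_mV.shape != self.current.shape:
            raise ValueError("potential and current must have the same length")
        if self.scan_rate <= 0:
            raise ValueError("scan rate must be positive")
        if self.reference not in ("Ag/AgCl", "NHE"):
            raise ValueError(f"unknown reference electrode {self.reference!r}")


@dataclass
class RedoxThermo:
    """Reduction thermodynamics from the temperature dependence of E1/2."""

    temperatures_K: np.ndarray
    e_half_mV: np.ndarray  # vs NHE
    dS_rc: float  # J/(K mol)
    dS_rc_err: float
    dH_rc: float  # kJ/mol
    dH_rc_err: float
    slope_E_vs_T: float  # V/K
    slope_EoverT_vs_invT: float  # V (slope of E/T vs 1/T)

    def to_dict(self) -> dict:
        return {
            "temperatures_K": list(map(float, self.temperatures_K)),
            "e_half_mV_vs_NHE": list(map(float, self.e_half_mV)),
            "dS_rc_J_per_K_mol": self.dS_rc,
            "dS_rc_err": self.dS_rc_err,
            "dH_rc_kJ_per_mol": self.dH_rc,
            "dH_rc_err": self.dH_rc_err,
        }


@dataclass
class ETKinetics:
    """Interfacial electron-transfer kinetics of the adsorbed couple.

    Depending on provenance, holds a per-temperature ks from trumpet-plot
    fitting (with alpha and the fitted E0) and/or the Arrhenius parameters
    A and dH_act from a ks(T) series.
    """

    ks: float | None = None  # s^-1, at self.temperature
    ks_err: float | None = None
    alpha: float | None = None
    alpha_err: float | None = None
    e0_mV: float | None = None
    temperature: float | None = None  # K
    A: float | None = None  # s^-1 pre-exponential
    A_err: float | None = None
    dH_act: float | None = None  # kJ/mol activation enthalpy
    dH_act_err: float | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _sweep_grid(e0_mV: float, half_width_mV: float, step_mV: float) -> np.ndarray:
    """Triangular potential program: up-sweep then down-sweep, in mV."""
    lo = e0_mV - half_width_mV
    hi = e0_mV + half_width_mV
    n = max(int(round((hi - lo) / step_mV)), 10)
    up = np.linspace(lo, hi, n + 1)
    down = up[::-1][1:]
    return np.concatenate([up, down])


def _integrate_theta(potential_mV: np.ndarray, e0_mV: float, ks: float,
                     alpha: float, v: float, T: float) -> np.ndarray:
    """Oxidized fraction θ along the sweep (exact exponential stepping).

    dθ/dt = kf(E)(1-θ) - kb(E)θ with kf = ks e^{(1-α)f(E-E0)} (oxidation)
    and kb = ks e^{-αf(E-E0)} (reduction), f = F/RT.  Over each potential
    step the rates are evaluated at the step midpoint and the linear ODE is
    advanced exactly, which is unconditionally stable (no silent NaN even
    for stiff, highly irreversible steps).
    """
    f = FARADAY / (GAS_CONSTANT * T)  # 1/V
    e_mid = 0.5 * (potential_mV[1:] + potential_mV[:-1])
    xi = f * (e_mid - e0_mV) * 1e-3  # dimensionless overpotential
    kf = ks * np.exp(np.clip((1.0 - alpha) * xi, -_EXP_CLIP, _EXP_CLIP))
    kb = ks * np.exp(np.clip(-alpha * xi, -_EXP_CLIP, _EXP_CLIP))
    s = kf + kb
    theta_eq = kf / s
    dt = np.abs(np.diff(potential_mV)) * 1e-3 / v  # s per step
    decay = np.exp(-s * dt)

    theta = np.empty(potential_mV.size)
    # start fully reduced at the negative vertex
    th = 0.0
    theta[0] = th
    for k in range(theta_eq.size):
        th = theta_eq[k] + (th - theta_eq[k]) * decay[k]
        theta[k + 1] = th
    return theta


def simulate_surface_voltammogram(e0_mV: float, ks: float, alpha: float,
                                  v: float, T: float,
                                  half_width_mV: float = 300.0,
                                  step_mV: float = 0.1,
                                  reference: str = "NHE") -> Voltammogram:
    """Simulate one full (forward + reverse) sweep of an adsorbed couple.

    Parameters
    ----------
    e0_mV : formal potential of the couple on the ``reference`` scale.
    ks : standard heterogeneous electron-transfer rate constant, 1/s.
    alpha : transfer coefficient, 0 < alpha < 1.
    v : scan rate, V/s.
    T : temperature, K.
    half_width_mV : half-width of the sweep window around ``e0_mV``; must
        give at least ±200 mV around the formal potential.
    step_mV : potential resolution of the integration grid.

    Returns
    -------
    Voltammogram
        Current ∝ dθ/dt evaluated on the mid-step grid and mapped back to
        the sweep grid; the up-sweep carries the anodic (positive) wave.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if ks <= 0 or v <= 0 or T <= 0:
        raise ValueError("ks, v and T must be positive")
    if half_width_mV < 200.0:
        raise ValueError("sweep window must span E0 by at least 200 mV each side")

    grid = _sweep_grid(e0_mV, half_width_mV, step_mV)
    theta = _integrate_theta(grid, e0_mV, ks, alpha, v, T)
    dt = np.abs(np.diff(grid)) * 1e-3 / v
    current = np.diff(theta) / dt  # ∝ dθ/dt; >0 anodic
    # assign currents to mid-step potentials
    e_mid = 0.5 * (grid[1:] + grid[:-1])
    if not np.all(np.isfinite(current)):
        raise FloatingPointError("voltammogram integration produced non-finite current")
    return Voltammogram(e_mid, current, scan_rate=v, temperature=T,
                        reference=reference)


# ---------------------------------------------------------------------------
# Peak analysis
# ---------------------------------------------------------------------------

def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Sub-grid peak position via a parabola through the 3 points at argmax."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[i] + delta * (x[i + 1] - x[i]))


def _branch_peak(e: np.ndarray, i: np.ndarray, anodic: bool,
                 baseline_deg: int = 2, tail_frac: float = 0.15,
                 min_snr: float = 3.0) -> float:
    """Peak potential of one sweep branch after tail-baseline subtraction."""
    y = i if anodic else -i
    n = e.size
    k = max(int(tail_frac * n), 3)
    tail_idx = np.r_[0:k, n - k:n]
    coef = np.polyfit(e[tail_idx], y[tail_idx], min(baseline_deg, 2))
    resid = y - np.polyval(coef, e)
    noise = np.std(np.concatenate([resid[:k], resid[-k:]]))
    if resid.max() <= min_snr * max(noise, 1e-12 * max(abs(resid).max(), 1e-300)):
        raise ValueError("no peak detected above baseline noise")
    return _parabolic_peak(e, resid)


def extract_peaks(vg: Voltammogram) -> tuple[float, float]:
    """Anodic and cathodic peak potentials (Epa, Epc) of a voltammogram, mV.

    Each branch is baseline-corrected with a polynomial (degree ≤ 2) fitted
    to its tails before the extremum is located, so a sloping capacitive
    baseline does not bias the peak positions.
    """
    e, i = vg.potential_mV, vg.current
    vertex = int(np.argmax(e))
    if vertex in (0, e.size - 1):
        # sweep started high: cathodic branch first
        vertex = int(np.argmin(e))
        ec, ic = e[: vertex + 1], i[: vertex + 1]
        ea, ia = e[vertex:], i[vertex:]
    else:
        ea, ia = e[: vertex + 1], i[: vertex + 1]
        ec, ic = e[vertex:], i[vertex:]
    epa = _branch_peak(ea, ia, anodic=True)
    epc = _branch_peak(ec, ic, anodic=False)
    return epa, epc


def midpoint_potential(epa_mV: float, epc_mV: float,
                       reference: str = "Ag/AgCl") -> float:
    """Midpoint potential E1/2 = (Epa + Epc)/2 on the NHE scale, mV.

    The +192 mV correction is applied exactly once, keyed on the reference
    label of the input peak potentials.
    """
    e = 0.5 * (epa_mV + epc_mV)
    if reference == "Ag/AgCl":
        return e + NHE_OFFSET_MV
    if reference == "NHE":
        return e
    raise ValueError(f"unknown reference electrode {reference!r}")


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

def reduction_thermodynamics(temperatures_K, e_half_mV) -> RedoxThermo:
    """ΔS°rc and ΔH°rc from the temperature dependence of E1/2.

    The reduction entropy is taken from the slope of E1/2 vs T
    (ΔS°rc = nF·dE/dT) and the reduction enthalpy from the slope of
    E1/2/T vs 1/T (ΔH°rc = −nF·d(E/T)/d(1/T)); both by ordinary least
    squares with standard errors propagated from the slope uncertainties.
    """
    T = np.asarray(temperatures_K, dtype=float)
    e_mV = np.asarray(e_half_mV, dtype=float)
    if T.size < 3:
        raise ValueError("reduction thermodynamics needs at least 3 temperatures")
    E = e_mV * 1e-3  # volts internally
    nF = N_ELECTRONS * FARADAY

    res1 = stats.linregress(T, E)
    res2 = stats.linregress(1.0 / T, E / T)
    dS = nF * res1.slope  # J/(K mol)
    dS_err = nF * res1.stderr
    dH = -nF * res2.slope / 1000.0  # kJ/mol
    dH_err = nF * res2.stderr / 1000.0
    return RedoxThermo(T, e_mV, dS, dS_err, dH, dH_err,
                       slope_E_vs_T=res1.slope,
                       slope_EoverT_vs_invT=res2.slope)


def gibbs_helmholtz_potential(dS: float, dH: float, T: float = 298.15) -> float:
    """Midpoint potential implied by (ΔS°rc, ΔH°rc) at temperature T, mV.

    E = (T·ΔS°rc − ΔH°rc)/(nF) with ΔS°rc in J/(K mol) and ΔH°rc in kJ/mol;
    the inverse of :func:`reduction_thermodynamics` on noise-free data.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    e_V = (T * dS - dH * 1000.0) / (N_ELECTRONS * FARADAY)
    return e_V * 1000.0


# ---------------------------------------------------------------------------
# Kinetics: trumpet plot and Arrhenius analysis
# ---------------------------------------------------------------------------

def laviron_irreversible_peak(e0_mV: float, ks: float, alpha: float,
                              v: float, T: float, anodic: bool) -> float:
    """Closed-form peak potential in the fully irreversible limit, mV.

    Cathodic: Ep = E0 − (RT/αF)·ln(αFv/(RT·ks));
    anodic:   Ep = E0 + (RT/(1−α)F)·ln((1−α)Fv/(RT·ks)).
    Valid when the corresponding dimensionless rate ratio exceeds ~10.
    """
    f = FARADAY / (GAS_CONSTANT * T)
    if anodic:
        a = 1.0 - alpha
        return e0_mV + 1000.0 / (a * f) * np.log(a * f * v / ks)
    return e0_mV - 1000.0 / (alpha * f) * np.log(alpha * f * v / ks)


def _model_peaks(e0_mV: float, ks: float, alpha: float, v: float, T: float,
                 step_mV: float = 0.2) -> tuple[float, float]:
    """Simulated (Epa, Epc) with a window wide enough for the peak shift."""
    f = FARADAY / (GAS_CONSTANT * T)
    shift = 1000.0 / (min(alpha, 1.0 - alpha) * f) * max(
        np.log(max(f * v / ks, 1.0)), 0.0)
    half_width = min(250.0 + 1.5 * shift, 1500.0)
    vg = simulate_surface_voltammogram(e0_mV, ks, alpha, v, T,
                                       half_width_mV=half_width,
                                       step_mV=step_mV)
    e, i = vg.potential_mV, vg.current
    vertex = int(np.argmax(e))
    epa = _parabolic_peak(e[: vertex + 1], i[: vertex + 1])
    epc = _parabolic_peak(e[vertex:], -i[vertex:])
    return epa, epc


def fit_trumpet(scan_rates, epa_mV, epc_mV, T: float = 298.15,
                fit_alpha: bool = True) -> ETKinetics:
    """Fit ks (and alpha, E0) to the peak-potential trumpet plot at fixed T.

    The observed anodic/cathodic peak potentials as a function of scan rate
    are matched, by nonlinear least squares, against peak positions obtained
    from the Butler–Volmer surface-voltammetry simulation — a working curve
    valid across the reversible, quasi-reversible and irreversible regimes
    (no closed-form Laviron approximation is assumed).

    Parameters
    ----------
    scan_rates : array of v in V/s (≥ 6, spanning reversible → irreversible).
    epa_mV, epc_mV : observed anodic/cathodic peak potentials, mV (any
        consistent reference; E0 is fitted on the same scale).
    T : temperature in K.
    fit_alpha : fit the transfer coefficient (default) or hold it at 0.5.

    Returns
    -------
    ETKinetics with ks, alpha, fitted e0_mV and asymptotic standard errors.
    A ``"ks_lower_bound_only"`` flag is set when every point is in the
    reversible regime (peak separations all < 5 mV), where the data only
    bound ks from below.
    """
    v = np.asarray(scan_rates, dtype=float)
    epa = np.asarray(epa_mV, dtype=float)
    epc = np.asarray(epc_mV, dtype=float)
    if v.size < 6:
        raise ValueError("trumpet fitting needs at least 6 scan rates")
    if not (v.size == epa.size == epc.size):
        raise ValueError("scan_rates, epa and epc must have equal lengths")

    flags = []
    dEp = epa - epc
    if np.all(dEp < 5.0):
        flags.append("ks_lower_bound_only")

    order = np.argsort(v)
    e0_init = 0.5 * (epa[order[0]] + epc[order[0]])
    # crude ks init from the irreversible cathodic asymptote at the fastest scan
    f = FARADAY / (GAS_CONSTANT * T)
    j = order[-1]
    sep = max(e0_init - epc[j], 10.0) * 1e-3
    ks_init = 0.5 * f * v[j] / np.exp(0.5 * f * sep)
    ks_init = float(np.clip(ks_init, 1e-2, 1e6))

    def residuals(p):
        e0, ln_ks = p[0], p[1]
        alpha = p[2] if fit_alpha else 0.5
        ks = np.exp(ln_ks)
        r = np.empty(2 * v.size)
        for k, vk in enumerate(v):
            pa, pc = _model_peaks(e0, ks, alpha, vk, T)
            r[2 * k] = pa - epa[k]
            r[2 * k + 1] = pc - epc[k]
        return r

    p0 = [e0_init, np.log(ks_init)]
    lb = [e0_init - 200.0, np.log(1e-3)]
    ub = [e0_init + 200.0, np.log(1e8)]
    if fit_alpha:
        p0.append(0.5)
        lb.append(0.05)
        ub.append(0.95)
    sol = optimize.least_squares(residuals, p0, bounds=(lb, ub),
                                 diff_step=1e-3, xtol=1e-10, ftol=1e-10)
    dof = max(2 * v.size - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        perr = np.full(sol.x.size, np.nan)

    ks = float(np.exp(sol.x[1]))
    ks_err = float(ks * perr[1])
    alpha = float(sol.x[2]) if fit_alpha else 0.5
    alpha_err = float(perr[2]) if fit_alpha else 0.0
    return ETKinetics(ks=ks, ks_err=ks_err, alpha=alpha, alpha_err=alpha_err,
                      e0_mV=float(sol.x[0]), temperature=T, flags=flags)


def fit_arrhenius(temperatures_K, ks_values) -> ETKinetics:
    """Arrhenius analysis of a ks(T) series.

    Ordinary least squares of ln ks vs 1/T; the activation enthalpy is
    −R·slope (reported in kJ/mol) and the pre-exponential factor is
    exp(intercept) (1/s).
    """
    T = np.asarray(temperatures_K, dtype=float)
    ks = np.asarray(ks_values, dtype=float)
    if T.size < 3:
        if T.size < 2:
            raise ValueError("Arrhenius analysis needs at least 2 temperatures")
        warnings.warn("Arrhenius fit with only 2 points: exact line, no error "
                      "estimate", stacklevel=2)
    if np.any(ks <= 0):
        raise ValueError("all ks values must be positive")
    res = stats.linregress(1.0 / T, np.log(ks))
    dH_act = -GAS_CONSTANT * res.slope / 1000.0  # kJ/mol
    A = float(np.exp(res.intercept))
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    int_err = res.intercept_stderr if np.isfinite(res.intercept_stderr) else 0.0
    return ETKinetics(A=A, A_err=A * int_err,
                      dH_act=float(dH_act),
                      dH_act_err=float(GAS_CONSTANT * stderr / 1000.0))


def predict_arrhenius(A: float, dH_act: float, T: float = 298.15) -> float:
    """ks = A·exp(−ΔH‡/(RT)) with A in 1/s, ΔH‡ in kJ/mol, T in K."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(A * np.exp(-dH_act * 1000.0 / (GAS_CONSTANT * T)))
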