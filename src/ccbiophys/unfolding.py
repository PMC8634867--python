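"""Multi-state thermal unfolding analysis of spectral melt series.

A temperature ramp of full spectra (far-UV CD, near-UV/Vis CD or
fluorescence) is reduced by principal component analysis; the first
principal component P1(T) is then fitted to a sequential multi-state
unfolding model

    S0 <-> S1 <-> ... <-> S(n-1)

in which each transition i obeys a two-state van't Hoff equilibrium
(ΔCp = 0)

    K_i(T) = exp[(ΔHvH_i / R) (1/Tm_i − 1/T)]      (T, Tm in kelvin)

and each state contributes a constant signal (optionally a linear baseline
on the first and last states).  The fractional populations are

    f_j(T) = Π_{i≤j} K_i / Σ_k Π_{i≤k} K_i .

Midpoint melting temperatures Tm are reported in °C; the van't Hoff
enthalpies, which only set the sharpness of each transition, are treated as
nuisance parameters bounded to 50–1000 kJ/mol.  Model order (number of
states) is chosen by AICc with a parsimony tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import PCA

from .electrochemistry import GAS_CONSTANT

__all__ = [
    "PCAResult",
    "UnfoldingModelParams",
    "UnfoldingFit",
    "pca_decompose",
    "state_populations",
    "fit_unfolding",
    "select_model",
]

KELVIN = 273.15
_DH_BOUNDS = (50.0, 1000.0)  # kJ/mol, nuisance-parameter range


@dataclass
class PCAResult:
    """PCA of a spectral ramp: scores per temperature, loadings per wavelength."""

    temperatures: np.ndarray  # °C
    scores: np.ndarray  # (n_T, n_components)
    loadings: np.ndarray  # (n_components, n_wavelengths), orthonormal rows
    variance_fraction: np.ndarray
    mean_spectrum: np.ndarray
    degenerate: bool = False

    @property
    def p1(self) -> np.ndarray:
        """First principal component score series over temperature."""
        return self.scores[:, 0]


@dataclass
class UnfoldingModelParams:
    """Sequential multi-state unfolding model parameters.

    transitions: list of (Tm in °C, ΔHvH in kJ/mol), strictly increasing Tm.
    state_signals: per-state signal intercepts (length n_states).
    state_slopes: optional per-state linear slopes vs T (°C); zero where a
        state's signal is temperature independent.
    """

    n_states: int
    transitions: list[tuple[float, float]]
    state_signals: np.ndarray | None = None
    state_slopes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if len(self.transitions) != self.n_states - 1:
            raise ValueError("number of transitions must equal n_states - 1")
        tms = [t for t, _ in self.transitions]
        if any(b <= a for a, b in zip(tms, tms[1:])):
            raise ValueError("Tm values must be strictly increasing")
        if any(dh <= 0 for _, dh in self.transitions):
            raise ValueError("van't Hoff enthalpies must be positive")
        if self.state_signals is not None:
            self.state_signals = np.asarray(self.state_signals, dtype=float)
            if self.state_signals.size != self.n_states:
                raise ValueError("one signal per state required")
        if self.state_slopes is not None:
            self.state_slopes = np.asarray(self.state_slopes, dtype=float)

    @property
    def tm_values(self) -> np.ndarray:
        return np.array([t for t, _ in self.transitions])

    @property
    def dh_values(self) -> np.ndarray:
        return np.array([d for _, d in self.transitions])


@dataclass
class UnfoldingFit:
    """Result of fitting P1(T) to a sequential unfolding model."""

    params: UnfoldingModelParams
    tm_err: np.ndarray
    dh_err: np.ndarray
    rss: float
    aicc: float
    n_points: int
    n_free_params: int
    success: bool
    message: str = ""
    fitted_curve: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "n_states": self.params.n_states,
            "Tm_C": [float(t) for t in self.params.tm_values],
            "Tm_err_C": [float(e) for e in self.tm_err],
            "dHvH_kJ_per_mol": [float(d) for d in self.params.dh_values],
            "dHvH_err": [float(e) for e in self.dh_err],
            "state_signals": [float(s) for s in self.params.state_signals],
            "rss": self.rss,
            "aicc": self.aicc,
            "success": self.success,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_decompose(ramp, n_components: int = 3) -> PCAResult:
    """Mean-centered PCA of a spectral ramp.

    Spectra (one per temperature) are the observations and wavelengths the
    features; each wavelength channel is centered across temperatures.  The
    sign of P1 is fixed so that P1 at the highest temperature exceeds P1 at
    the lowest, making "unfolded" the high-P1 end by convention.
    """
    X = np.asarray(ramp.signal, dtype=float)  # (n_wl, n_T)
    temps = np.asarray(ramp.temperatures, dtype=float)
    if temps.size < 3 or X.shape[0] < 2:
        raise ValueError("ramp must have >= 3 temperatures and >= 2 wavelengths")
    obs = X.T  # (n_T, n_wl)
    degenerate = bool(np.allclose(obs.var(axis=0), 0.0))
    k = min(n_components, temps.size - 1, X.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(obs)
    loadings = pca.components_.copy()
    if scores[-1, 0] < scores[0, 0]:
        scores[:, 0] *= -1.0
        loadings[0] *= -1.0
    return PCAResult(
        temperatures=temps,
        scores=scores,
        loadings=loadings,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        mean_spectrum=pca.mean_.copy(),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Sequential van't Hoff model
# ---------------------------------------------------------------------------

def state_populations(params: UnfoldingModelParams, T_K) -> np.ndarray:
    """Fractional state populations on a kelvin temperature grid.

    Returns an (n_states, n_T) matrix whose columns sum to one.  Computed in
    log space for numerical stability at large |ΔHvH|·ΔT.
    """
    T = np.atleast_1d(np.asarray(T_K, dtype=float))
    tm_K = params.tm_values + KELVIN
    dh_J = params.dh_values * 1000.0
    # ln K_i(T), shape (n_trans, n_T)
    lnK = (dh_J[:, None] / GAS_CONSTANT) * (1.0 / tm_K[:, None] - 1.0 / T[None, :])
    # cumulative ln of products: state j has Σ_{i<=j} ln K_i, state 0 has 0
    cum = np.vstack([np.zeros_like(T), np.cumsum(lnK, axis=0)])
    cum -= cum.max(axis=0, keepdims=True)  # guard overflow
    w = np.exp(cum)
    return w / w.sum(axis=0, keepdims=True)


def _design_matrix(tm, dh, T_K, baselines: bool) -> np.ndarray:
    p = UnfoldingModelParams(len(tm) + 1,
                             list(zip(tm, dh)))
    f = state_populations(p, T_K)  # (n_states, n_T)
    cols = [f.T]
    if baselines:
        t_c = T_K - KELVIN
        t_c = (t_c - t_c.mean()) / max(np.ptp(t_c), 1.0)
        cols.append((f[0] * t_c)[:, None])
        cols.append((f[-1] * t_c)[:, None])
    return np.hstack(cols)


def _tm_start_candidates(T_C: np.ndarray, y: np.ndarray, n_trans: int,
                         n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Initial Tm guesses from |dP1/dT| peaks plus seeded jitter."""
    win = max(3, T_C.size // 20)
    kernel = np.ones(win) / win
    ys = np.convolve(y, kernel, mode="same")
    dy = np.abs(np.gradient(ys, T_C))
    # primary guess: temperatures at quantiles of the cumulative derivative mass
    cdf = np.cumsum(dy)
    cdf /= cdf[-1] if cdf[-1] > 0 else 1.0
    qs = (np.arange(1, n_trans + 1)) / (n_trans + 1)
    base = np.interp(qs, cdf, T_C)
    # local maxima of |dy| as an alternative start
    interior = np.where((dy[1:-1] >= dy[:-2]) & (dy[1:-1] >= dy[2:]))[0] + 1
    peaks = interior[np.argsort(dy[interior])[::-1]]
    starts = [np.sort(base)]
    if peaks.size >= n_trans:
        starts.append(np.sort(T_C[peaks[:n_trans]]))
    span = np.ptp(T_C)
    while len(starts) < n_starts:
        jitter = rng.normal(scale=0.05 * span, size=n_trans)
        cand = np.sort(np.clip(base + jitter, T_C.min() + 1, T_C.max() - 1))
        starts.append(cand)
    return starts[:n_starts]


def _pack(tm_C, dh):
    """(Tm list, dH list) -> optimizer vector [tm1, gaps..., dH...] (°C, kJ/mol)."""
    tm = np.asarray(tm_C, dtype=float)
    return np.concatenate([[tm[0]], np.diff(tm), dh])


def _unpack(x, n_trans):
    tm = x[0] + np.concatenate([[0.0], np.cumsum(x[1:n_trans])])
    dh = x[n_trans : 2 * n_trans]
    return tm, dh


def fit_unfolding(T_C, y, n_states: int, baselines: bool = False,
                  n_starts: int = 8, seed: int = 0) -> UnfoldingFit:
    """Least-squares fit of a P1-vs-temperature series to a sequential model.

    The state signals enter the model linearly, so for each trial of the
    nonlinear parameters (Tm_i, ΔHvH_i) they are profiled out by linear
    least squares (variable projection); the nonlinear search is repeated
    from ``n_starts`` seeded initializations derived from the derivative of
    the smoothed curve, and the best solution is polished with all
    parameters free to obtain asymptotic standard errors.

    Parameters
    ----------
    T_C : temperatures in °C (≥ 10 points).
    y : P1 (or any single-channel melt signal) at those temperatures.
    n_states : 2, 3 or 4.
    baselines : add linear temperature baselines on the first/last states.
    """
    T_C = np.asarray(T_C, dtype=float)
    y = np.asarray(y, dtype=float)
    if T_C.size < 10:
        raise ValueError("need at least 10 points to fit an unfolding model")
    if n_states not in (2, 3, 4):
        raise ValueError("n_states must be 2, 3 or 4")
    n_trans = n_states - 1
    T_K = T_C + KELVIN
    rng = np.random.default_rng(seed)

    def proj_residuals(x):
        tm, dh = _unpack(x, n_trans)
        F = _design_matrix(tm, dh, T_K, baselines)
        s, *_ = np.linalg.lstsq(F, y, rcond=None)
        return F @ s - y

    lb = np.concatenate([[T_C.min() - 20.0],
                         np.full(n_trans - 1, 0.5),
                         np.full(n_trans, _DH_BOUNDS[0])])
    ub = np.concatenate([[T_C.max() + 20.0],
                         np.full(n_trans - 1, np.ptp(T_C)),
                         np.full(n_trans, _DH_BOUNDS[1])])

    best = None
    for tm0 in _tm_start_candidates(T_C, y, n_trans, n_starts, rng):
        x0 = np.clip(_pack(tm0, np.full(n_trans, 300.0)), lb, ub)
        try:
            sol = optimize.least_squares(proj_residuals, x0, bounds=(lb, ub),
                                         xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all multi-start fits failed")

    # full-parameter polish for standard errors
    tm, dh = _unpack(best.x, n_trans)
    F = _design_matrix(tm, dh, T_K, baselines)
    s, *_ = np.linalg.lstsq(F, y, rcond=None)

    def full_residuals(p):
        tm_, dh_ = _unpack(p[: 2 * n_trans], n_trans)
        F_ = _design_matrix(tm_, dh_, T_K, baselines)
        return F_ @ p[2 * n_trans :] - y

    p0 = np.concatenate([best.x, s])
    n_lin = F.shape[1]
    lb_f = np.concatenate([lb, np.full(n_lin, -np.inf)])
    ub_f = np.concatenate([ub, np.full(n_lin, np.inf)])
    sol = optimize.least_squares(full_residuals, p0, bounds=(lb_f, ub_f),
                                 xtol=1e-12, ftol=1e-12)
    success = sol.status > 0
    tm, dh = _unpack(sol.x[: 2 * n_trans], n_trans)
    lin = sol.x[2 * n_trans :]

    n, p = y.size, sol.x.size
    rss = float(np.sum(sol.fun ** 2))
    dof = max(n - p, 1)
    try:
        cov = (rss / dof) * np.linalg.inv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = None
        perr = np.full(p, np.nan)
        success = False
    # propagate the gap parametrization: Tm_j = tm1 + Σ_{i<=j} gap_i
    tm_err = np.full(n_trans, np.nan)
    if cov is not None:
        for j in range(n_trans):
            g = np.zeros(p)
            g[0] = 1.0
            g[1 : j + 1] = 1.0
            tm_err[j] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    dh_err = perr[n_trans : 2 * n_trans]

    order = np.argsort(tm)
    params = UnfoldingModelParams(
        n_states,
        [(float(tm[i]), float(dh[i])) for i in order],
        state_signals=lin[:n_states],
        state_slopes=lin[n_states:] if baselines else None,
    )
    k = p + 1  # + residual variance
    aicc = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)
    fitted = full_residuals(sol.x) + y
    return UnfoldingFit(params=params, tm_err=tm_err[order], dh_err=dh_err[order],
                        rss=rss, aicc=float(aicc), n_points=n, n_free_params=p,
                        success=success, message="" if success else sol.message,
                        fitted_curve=fitted)


def select_model(T_C, y, candidate_states=(2, 3, 4), **fit_kwargs):
    """Fit all candidate state counts and return the AICc-best fit.

    Ties (ΔAICc < 2 relative to the minimum) resolve to the model with
    fewer states.  Returns ``(chosen_fit, comparison)`` where comparison is
    a DataFrame with one row per candidate.
    """
    candidates = sorted(candidate_states)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    fits, errors = {}, {}
    for ns in candidates:
        try:
            fits[ns] = fit_unfolding(T_C, y, ns, **fit_kwargs)
        except Exception as exc:  # keep diagnostics per candidate
            errors[ns] = str(exc)
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {errors}")
    best_aicc = min(f.aicc for f in fits.values())
    chosen = next(ns for ns in candidates
                  if ns in fits and fits[ns].aicc - best_aicc < 2.0)
    table = pd.DataFrame(
        [{"n_states": ns, "aicc": fits[ns].aicc, "rss": fits[ns].rss,
          "delta_aicc": fits[ns].aicc - best_aicc,
          "chosen": ns == chosen} for ns in fits]
    ).sort_values("n_states").reset_index(drop=True)
    return fits[chosen], table
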