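"""Steady-state BLI binding analysis of the cytochrome c1 - cytochrome c complex.

Equilibrium wavelength shifts from bio-layer interferometry are fitted to a
single-site isotherm with a linear nonspecific term

    Y = Bmax * X / (KD + X) + NS * X

with X the analyte concentration (uM), Bmax the saturating shift (nm), KD
the dissociation constant (uM) and NS the nonspecific slope (nm/uM).
Replicates are fitted pooled, preserving the error structure of duplicate
measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = [
    "BindingIsotherm",
    "BindingFit",
    "Sensorgram",
    "binding_isotherm_model",
    "steady_state_response",
    "fit_binding_isotherm",
]


@dataclass
class BindingIsotherm:
    """Equilibrium shifts vs analyte concentration, replicate-tagged."""

    concentration_uM: np.ndarray
    shift_nm: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=float)
        self.shift_nm = np.asarray(self.shift_nm, dtype=float)
        if self.concentration_uM.size != self.shift_nm.size:
            raise ValueError("concentration and shift must have equal lengths")
        if np.any(self.concentration_uM <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(self.concentration_uM).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        if self.replicate is None:
            self.replicate = np.zeros(self.shift_nm.size, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)


@dataclass
class BindingFit:
    """Fitted isotherm parameters."""

    Bmax: float
    KD: float
    NS: float
    Bmax_err: float
    KD_err: float
    NS_err: float
    rss: float
    residuals: np.ndarray
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"Bmax_nm": self.Bmax, "Bmax_err": self.Bmax_err,
                "KD_uM": self.KD, "KD_err": self.KD_err,
                "NS_nm_per_uM": self.NS, "NS_err": self.NS_err,
                "rss": self.rss, "flags": self.flags}


@dataclass
class Sensorgram:
    """Wavelength-shift time trace for one concentration step."""

    time_s: np.ndarray
    shift_nm: np.ndarray
    phase: np.ndarray  # per-point labels: baseline | association | dissociation

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.shift_nm = np.asarray(self.shift_nm, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (self.time_s.size == self.shift_nm.size == self.phase.size):
            raise ValueError("time, shift and phase must have equal lengths")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


def binding_isotherm_model(X, Bmax, KD, NS):
    X = np.asarray(X, dtype=float)
    return Bmax * X / (KD + X) + NS * X


def steady_state_response(s: Sensorgram, window: float | None = None) -> float:
    """Baseline-subtracted mean shift over the end of the association phase.

    window: averaging window length in seconds measured back from the end of
    the association phase; defaults to the final 10% of that phase.
    """
    assoc = s.phase == "association"
    if not assoc.any():
        raise ValueError("sensorgram has no association phase")
    t_assoc = s.time_s[assoc]
    t_end = t_assoc[-1]
    if window is None:
        window = 0.1 * (t_end - t_assoc[0])
    if window <= 0 or t_end - window < t_assoc[0] - 1e-9:
        raise ValueError("window outside the association phase")
    sel = assoc & (s.time_s >= t_end - window)
    base = s.phase == "baseline"
    baseline = float(np.mean(s.shift_nm[base])) if base.any() else 0.0
    return float(np.mean(s.shift_nm[sel])) - baseline


def fit_binding_isotherm(iso: BindingIsotherm) -> BindingFit:
    """Pooled nonlinear least-squares fit of the single-site isotherm.

    KD values falling outside [min(X)/100, 100*max(X)] are returned but
    flagged ``poorly_constrained`` (and a warning is emitted), since the
    sampled concentration range then carries no information on them.
    """
    X, Y = iso.concentration_uM, iso.shift_nm
    model = Model(binding_isotherm_model, independent_vars=["X"])
    b0 = float(Y.max()) if Y.max() > 0 else 1.0
    params = model.make_params(
        Bmax={"value": b0, "min": 1e-12},
        KD={"value": float(np.median(X)), "min": 1e-9},
        NS={"value": 0.0},
    )
    res = model.fit(Y, params, X=X)

    def err(name):
        se = res.params[name].stderr
        return float(se) if se is not None else float("nan")

    kd = float(res.params["KD"].value)
    flags = []
    if not (X.min() / 100.0 <= kd <= 100.0 * X.max()):
        flags.append("poorly_constrained")
        warnings.warn(f"fitted KD {kd:.3g} uM lies outside the informative "
                      f"range of the sampled concentrations", stacklevel=2)
    return BindingFit(
        Bmax=float(res.params["Bmax"].value), KD=kd,
        NS=float(res.params["NS"].value),
        Bmax_err=err("Bmax"), KD_err=err("KD"), NS_err=err("NS"),
        rss=float(np.sum(res.residual ** 2)), residuals=res.residual.copy(),
        flags=flags,
    )
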