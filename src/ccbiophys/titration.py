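"""Alkaline-transition pKa from the 699 nm charge-transfer band.

The heme Fe–Met80(Sδ) bond of oxidized cytochrome c produces a weak
absorption band near 699 nm that is lost when rising pH drives the alkaline
transition (a lysine displacing Met80 as the sixth axial heme ligand).
The band intensity vs pH is fitted to a Henderson–Hasselbalch sigmoid

    Y = Absmin + (Absmax − Absmin) / (1 + exp[(X − pKa)/NS])

where X is pH, Absmax/Absmin are the acidic/alkaline plateaus, pKa is the
apparent transition pKa and NS the sigmoid slope in pH units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = [
    "TitrationCurve",
    "AlkalineFit",
    "henderson_hasselbalch",
    "fit_alkaline_transition",
    "predict_titration",
    "TransitionNotDetectedError",
]


class TransitionNotDetectedError(ValueError):
    """Raised when no alkaline transition is detectable in a titration."""


@dataclass
class TitrationCurve:
    """pH-titration of the 699 nm band intensity."""

    pH: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.pH.size != self.absorbance.size:
            raise ValueError("pH and absorbance must have the same length")
        if self.pH.size < 6:
            raise ValueError("titration needs at least 6 points")
        if np.any((self.pH < 0) | (self.pH > 14)):
            raise ValueError("pH values must lie within 0-14")


@dataclass
class AlkalineFit:
    """Fitted sigmoid parameters for the alkaline transition."""

    pKa: float
    NS: float
    Absmax: float
    Absmin: float
    pKa_err: float
    NS_err: float
    Absmax_err: float
    Absmin_err: float
    rss: float
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pKa": self.pKa, "pKa_err": self.pKa_err,
            "NS": self.NS, "NS_err": self.NS_err,
            "Absmax": self.Absmax, "Absmax_err": self.Absmax_err,
            "Absmin": self.Absmin, "Absmin_err": self.Absmin_err,
            "rss": self.rss,
        }


def henderson_hasselbalch(pH, pKa, NS, Absmax, Absmin):
    """Sigmoid titration model; decreasing toward Absmin at high pH."""
    pH = np.asarray(pH, dtype=float)
    return Absmin + (Absmax - Absmin) / (1.0 + np.exp((pH - pKa) / NS))


def _noise_estimate(y: np.ndarray) -> float:
    # successive-difference noise estimate, robust to the smooth sigmoid trend
    return float(np.std(np.diff(y)) / np.sqrt(2.0)) if y.size > 1 else 0.0


def fit_alkaline_transition(curve: TitrationCurve) -> AlkalineFit:
    """Nonlinear least-squares fit of the titration sigmoid.

    Initial values follow the data: plateaus from the extremes, pKa from the
    half-amplitude crossing, NS = 0.5.  Raises
    :class:`TransitionNotDetectedError` when the amplitude does not exceed
    three times the point-to-point noise estimate.
    """
    x, y = curve.pH, curve.absorbance
    amp = float(y.max() - y.min())
    noise = _noise_estimate(y)
    if amp <= 3.0 * noise or amp == 0.0:
        raise TransitionNotDetectedError(
            f"no transition detectable: amplitude {amp:.3g} <= 3 x noise "
            f"estimate {noise:.3g}")

    half = 0.5 * (y.max() + y.min())
    order = np.argsort(x)
    pka0 = float(np.interp(half, y[order][::-1], x[order][::-1]))
    if not np.isfinite(pka0) or pka0 <= x.min() or pka0 >= x.max():
        pka0 = float(np.median(x))

    model = Model(henderson_hasselbalch, independent_vars=["pH"])
    params = model.make_params(
        pKa={"value": pka0, "min": x.min() - 2, "max": x.max() + 2},
        NS={"value": 0.5, "min": 1e-3, "max": 5.0},
        Absmax={"value": float(y.max())},
        Absmin={"value": float(y.min())},
    )
    res = model.fit(y, params, pH=x)

    def err(name):
        se = res.params[name].stderr
        return float(se) if se is not None else float("nan")

    return AlkalineFit(
        pKa=float(res.params["pKa"].value), NS=float(res.params["NS"].value),
        Absmax=float(res.params["Absmax"].value),
        Absmin=float(res.params["Absmin"].value),
        pKa_err=err("pKa"), NS_err=err("NS"),
        Absmax_err=err("Absmax"), Absmin_err=err("Absmin"),
        rss=float(np.sum(res.residual ** 2)), residuals=res.residual.copy(),
    )


def predict_titration(fit: AlkalineFit, pH):
    """Evaluate the fitted sigmoid at the given pH value(s)."""
    return henderson_hasselbalch(pH, fit.pKa, fit.NS, fit.Absmax, fit.Absmin)
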