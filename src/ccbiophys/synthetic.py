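"""Seeded synthetic instrument data for every analysis stream in the package.

The generators emulate, with the model structure used by the corresponding
analysis module plus i.i.d. Gaussian noise:

* spectral temperature ramps (CD / fluorescence melts) from a sequential
  multi-state unfolding model rendered through per-state basis spectra;
* alkaline-transition pH titrations (Henderson-Hasselbalch sigmoid);
* steady-state BLI binding isotherms (single-site + linear nonspecific term);
* variable-temperature cyclic voltammogram sets of an adsorbed redox couple
  with a linear E0(T) (reduction entropy) and Arrhenius ks(T).

Also small utilities: neutral peptide masses (monoisotopic/average) for
tryptic-fragment checks, and Beer-Lambert concentration determination.
All randomness is driven by a :class:`NoiseSpec` seed, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingIsotherm, binding_isotherm_model
from .electrochemistry import (
    FARADAY,
    Voltammogram,
    predict_arrhenius,
    simulate_surface_voltammogram,
)
from .titration import TitrationCurve, henderson_hasselbalch
from .unfolding import UnfoldingModelParams, state_populations

__all__ = [
    "SpectralRamp",
    "BasisSpectrumSet",
    "NoiseSpec",
    "VoltammogramSet",
    "TECHNIQUE_RANGES",
    "gaussian_basis",
    "gen_spectral_ramp",
    "gen_titration_curve",
    "gen_binding_data",
    "gen_voltammogram_set",
    "peptide_mass",
    "beer_lambert_concentration",
    "DEFAULT_BLI_SERIES",
    "write_ramp_csv",
    "read_ramp_csv",
    "write_curve_csv",
    "write_cv_csv",
    "read_cv_csv",
]

#: Wavelength windows (nm) per spectroscopic technique.
TECHNIQUE_RANGES = {
    "far-UV CD": (185.0, 250.0),
    "near-UV/Vis CD": (300.0, 600.0),
    "fluorescence": (300.0, 450.0),
}

#: Twofold BLI dilution series, 10 uM down to 0.3125 uM.
DEFAULT_BLI_SERIES = (10.0, 5.0, 2.5, 1.25, 0.625, 0.3125)


@dataclass
class NoiseSpec:
    """Gaussian observation-noise level (signal units) and RNG seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SpectralRamp:
    """Wavelength x temperature signal matrix from a melt experiment."""

    wavelengths: np.ndarray  # nm
    temperatures: np.ndarray  # deg C, strictly increasing
    signal: np.ndarray  # (n_wavelengths, n_temperatures)
    technique: str = "far-UV CD"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.wavelengths.size, self.temperatures.size):
            raise ValueError("signal must be (n_wavelengths, n_temperatures)")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains missing or non-finite values")


@dataclass
class BasisSpectrumSet:
    """Per-state spectral profiles and amplitudes used to render populations."""

    wavelengths: np.ndarray
    profiles: np.ndarray  # (n_states, n_wavelengths)
    amplitudes: np.ndarray  # (n_states,)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.profiles.shape[1] != self.wavelengths.size:
            raise ValueError("profiles must be sampled on the wavelength grid")
        if self.amplitudes.size != self.profiles.shape[0]:
            raise ValueError("one amplitude per state profile required")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("profiles must be finite")

    @property
    def n_states(self) -> int:
        return self.profiles.shape[0]


@dataclass
class VoltammogramSet:
    """Voltammograms tagged with (temperature, scan rate) plus ground truth."""

    voltammograms: list
    e0_ref_mV: float | None = None
    meta: dict = field(default_factory=dict)

    def at(self, T: float, v: float) -> Voltammogram:
        for vg in self.voltammograms:
            if np.isclose(vg.temperature, T) and np.isclose(vg.scan_rate, v):
                return vg
        raise KeyError(f"no voltammogram at T={T} K, v={v} V/s")

    @property
    def temperatures(self) -> np.ndarray:
        return np.unique([vg.temperature for vg in self.voltammograms])

    @property
    def scan_rates(self) -> np.ndarray:
        return np.unique([vg.scan_rate for vg in self.voltammograms])


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gaussian_basis(wavelengths=None, n_states: int = 2,
                   technique: str = "far-UV CD",
                   amplitudes=None) -> BasisSpectrumSet:
    """Distinct Gaussian band per state over the technique's wavelength range.

    Band centers are spread evenly across the window and widths set to a
    sixth of it; amplitudes default to a decreasing 1.0, 0.7, 0.49, ...
    sequence so states are spectrally distinguishable.  When no wavelength
    grid is given, a 1 nm grid over the technique's range is used.
    """
    if wavelengths is None:
        lo, hi = TECHNIQUE_RANGES[technique]
        wavelengths = np.arange(lo, hi + 1e-9, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    lo, hi = wl.min(), wl.max()
    centers = np.linspace(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo), n_states)
    width = (hi - lo) / 6.0
    profiles = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / width) ** 2)
    if amplitudes is None:
        amplitudes = 0.7 ** np.arange(n_states)
    return BasisSpectrumSet(wl, profiles, np.asarray(amplitudes, dtype=float))


def gen_spectral_ramp(model: UnfoldingModelParams, basis: BasisSpectrumSet,
                      temps_C, noise: NoiseSpec,
                      technique: str = "far-UV CD") -> SpectralRamp:
    """Render state populations through basis spectra on a temperature ramp.

    signal(wl, T) = sum_j f_j(T) * amp_j * profile_j(wl) + Gaussian noise.
    """
    temps = np.asarray(temps_C, dtype=float)
    if np.any((temps < -10.0) | (temps > 120.0)):
        raise ValueError("temperatures must lie within -10..120 deg C")
    if basis.n_states != model.n_states:
        raise ValueError(
            f"basis has {basis.n_states} state profiles but the model has "
            f"{model.n_states} states")
    f = state_populations(model, temps + 273.15)  # (n_states, n_T)
    weighted = basis.profiles * basis.amplitudes[:, None]  # (n_states, n_wl)
    clean = weighted.T @ f  # (n_wl, n_T)
    sig = clean + noise.rng().normal(0.0, noise.sigma, size=clean.shape) \
        if noise.sigma > 0 else clean.copy()
    return SpectralRamp(basis.wavelengths, temps, sig, technique=technique)


def gen_titration_curve(pKa: float, NS: float, Absmax: float, Absmin: float,
                        pH_grid=None, noise: NoiseSpec = NoiseSpec()) -> TitrationCurve:
    """Henderson-Hasselbalch sigmoid plus Gaussian noise on a pH grid."""
    if pH_grid is None:
        pH_grid = np.arange(6.0, 12.5 + 1e-9, 0.25)
    pH = np.asarray(pH_grid, dtype=float)
    if Absmax <= Absmin:
        warnings.warn("Absmax <= Absmin: generating an inverted transition",
                      stacklevel=2)
    y = henderson_hasselbalch(pH, pKa, NS, Absmax, Absmin)
    if noise.sigma > 0:
        y = y + noise.rng().normal(0.0, noise.sigma, size=y.shape)
    return TitrationCurve(pH, y)


def gen_binding_data(Bmax: float, KD: float, NS: float,
                     concentrations=DEFAULT_BLI_SERIES, replicates: int = 2,
                     noise: NoiseSpec = NoiseSpec()) -> BindingIsotherm:
    """Single-site isotherm responses, replicate-tagged, plus Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    X = np.tile(conc, replicates)
    rep = np.repeat(np.arange(replicates), conc.size)
    y = binding_isotherm_model(X, Bmax, KD, NS)
    if noise.sigma > 0:
        y = y + noise.rng().normal(0.0, noise.sigma, size=y.shape)
    return BindingIsotherm(X, y, rep)


def gen_voltammogram_set(e0_ref_mV: float, dS: float, A: float, dH_act: float,
                         alpha: float, scan_rates, temperatures,
                         noise: NoiseSpec = NoiseSpec(),
                         t_ref: float = 298.15, **sim_kwargs) -> VoltammogramSet:
    """Variable-temperature CV set with linear E0(T) and Arrhenius ks(T).

    For each temperature T and scan rate v:
    E0(T) = e0_ref + (dS/F)(T - t_ref) (mV, dS in J/(K mol)) and
    ks(T) = A exp(-dH_act/(RT)) (dH_act in kJ/mol).  Each sweep's current is
    normalized to unit peak amplitude (amplitudes are arbitrary; only peak
    positions carry information) before Gaussian noise of sd ``noise.sigma``
    is added.
    """
    rng = noise.rng()
    vgs = []
    for T in np.asarray(temperatures, dtype=float):
        e0_T = e0_ref_mV + dS / FARADAY * (T - t_ref) * 1000.0
        ks_T = predict_arrhenius(A, dH_act, T)
        for v in np.asarray(scan_rates, dtype=float):
            vg = simulate_surface_voltammogram(e0_T, ks_T, alpha, v, T,
                                               **sim_kwargs)
            i = vg.current / np.abs(vg.current).max()
            if noise.sigma > 0:
                i = i + rng.normal(0.0, noise.sigma, size=i.shape)
            vgs.append(Voltammogram(vg.potential_mV, i, scan_rate=v,
                                    temperature=T, reference=vg.reference))
    return VoltammogramSet(vgs, e0_ref_mV=e0_ref_mV,
                           meta={"dS": dS, "A": A, "dH_act": dH_act,
                                 "alpha": alpha, "t_ref": t_ref})


# ---------------------------------------------------------------------------
# Mass and concentration utilities
# ---------------------------------------------------------------------------

# Residue (amino-acid minus water) masses, Da.
_MONO_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_AVG_MASS = {
    "G": 57.05130, "A": 71.07790, "S": 87.07730, "P": 97.11520,
    "V": 99.13110, "T": 101.10390, "C": 103.14290, "L": 113.15760,
    "I": 113.15760, "N": 114.10260, "D": 115.08740, "Q": 128.12920,
    "K": 128.17230, "E": 129.11400, "M": 131.19610, "H": 137.13930,
    "F": 147.17390, "R": 156.18570, "Y": 163.17330, "W": 186.20990,
}
_WATER = {"monoisotopic": 18.010565, "average": 18.01528}


def peptide_mass(sequence: str, mode: str = "average") -> float:
    """Neutral peptide mass: sum of residue masses plus one water, Da."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if mode not in _WATER:
        raise ValueError("mode must be 'monoisotopic' or 'average'")
    table = _MONO_MASS if mode == "monoisotopic" else _AVG_MASS
    try:
        total = sum(table[aa] for aa in sequence.upper())
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    return total + _WATER[mode]


def beer_lambert_concentration(absorbance: float, epsilon_mM: float,
                               pathlength_cm: float = 1.0) -> float:
    """Concentration in mM from A = epsilon * c * l."""
    if epsilon_mM <= 0 or pathlength_cm <= 0:
        raise ValueError("epsilon and pathlength must be positive")
    return absorbance / (epsilon_mM * pathlength_cm)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_ramp_csv(ramp: SpectralRamp, path) -> None:
    """Wide matrix CSV: header of temperatures, first column of wavelengths."""
    df = pd.DataFrame(ramp.signal, index=ramp.wavelengths,
                      columns=ramp.temperatures)
    df.index.name = "wavelength_nm"
    df.to_csv(path)


def read_ramp_csv(path, technique: str = "far-UV CD") -> SpectralRamp:
    df = pd.read_csv(path, index_col=0)
    return SpectralRamp(df.index.to_numpy(dtype=float),
                        np.array([float(c) for c in df.columns]),
                        df.to_numpy(dtype=float), technique=technique)


def write_curve_csv(x, y, path, x_name: str, y_name: str, replicate=None) -> None:
    """Two/three-column curve CSV (x, y[, replicate])."""
    data = {x_name: x, y_name: y}
    if replicate is not None:
        data["replicate"] = replicate
    pd.DataFrame(data).to_csv(path, index=False)


def write_cv_csv(cvset: VoltammogramSet, path) -> None:
    """Long-format CV CSV: temperature_K, scan_rate_V_per_s, potential_mV, current."""
    frames = [pd.DataFrame({
        "temperature_K": vg.temperature,
        "scan_rate_V_per_s": vg.scan_rate,
        "potential_mV": vg.potential_mV,
        "current": vg.current,
    }) for vg in cvset.voltammograms]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cv_csv(path, reference: str = "NHE") -> VoltammogramSet:
    df = pd.read_csv(path)
    vgs = []
    for (T, v), grp in df.groupby(["temperature_K", "scan_rate_V_per_s"],
                                  sort=True):
        vgs.append(Voltammogram(grp["potential_mV"].to_numpy(),
                                grp["current"].to_numpy(),
                                scan_rate=float(v), temperature=float(T),
                                reference=reference))
    return VoltammogramSet(vgs)
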