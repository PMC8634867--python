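# ccbiophys

Analysis pipelines for the quantitative biophysical characterization of
cytochrome *c* (Cc) variants — in particular acetyl-mimetic Lys→Gln point
mutants — covering five instrument streams:

1. **Thermal stability** — spectral temperature ramps (far-UV CD,
   near-UV/Vis CD, fluorescence) are reduced by PCA and the first principal
   component P1(T) is fitted to a sequential multi-state van't Hoff model to
   extract midpoint melting temperatures *T*<sub>m</sub>.
2. **Alkaline transition** — the pH titration of the 699 nm Fe–Met80
   charge-transfer band is fitted to a Henderson–Hasselbalch sigmoid for the
   apparent p*K*<sub>a</sub>.
3. **Partner binding** — steady-state bio-layer interferometry (BLI)
   responses for the Cc<sub>1</sub>–Cc complex are fitted to a single-site
   isotherm with a linear nonspecific term for *K*<sub>D</sub>.
4. **Interfacial electron transfer** — variable-temperature protein-film
   cyclic voltammetry of Cc adsorbed on SAM-modified gold: *E*<sub>1/2</sub>
   extraction with Ag/AgCl→NHE correction, reduction entropy/enthalpy
   (ΔS°<sub>rc</sub>, ΔH°<sub>rc</sub>) from *E*<sub>1/2</sub>(T),
   trumpet-plot fitting of the standard electron-transfer rate constant
   *k*<sub>s</sub>, and Arrhenius activation analysis (A, ΔH<sup>‡</sup>).
5. **Structural perturbation** — per-residue chemical-shift perturbations
   between ¹H–¹⁵N HSQC peak lists, with relative-threshold significance
   classification.

A seeded synthetic-data module emulates each instrument stream from the same
model structure the fits assume, so every pipeline is validated by parameter
recovery.

## Core models

* Sequential unfolding: transition *i* has
  *K<sub>i</sub>*(T) = exp[(ΔH<sub>vH,i</sub>/R)(1/*T*<sub>m,i</sub> − 1/T)],
  state populations *f<sub>j</sub>* = Π<sub>i≤j</sub>K<sub>i</sub> /
  Σ<sub>k</sub>Π<sub>i≤k</sub>K<sub>i</sub>, and
  P1(T) = Σ<sub>j</sub> *f<sub>j</sub>*(T)·*s<sub>j</sub>*.
* Titration: Y = Abs<sub>min</sub> + (Abs<sub>max</sub> − Abs<sub>min</sub>) /
  (1 + e<sup>(X − pKa)/NS</sup>).
* Binding: Y = B<sub>max</sub>·X/(K<sub>D</sub> + X) + NS·X.
* Adsorbed-couple voltammetry (Butler–Volmer):
  dθ/dt = k<sub>f</sub>(E)(1−θ) − k<sub>b</sub>(E)θ with
  k<sub>f</sub> = k<sub>s</sub>e<sup>(1−α)f(E−E⁰)</sup>,
  k<sub>b</sub> = k<sub>s</sub>e<sup>−αf(E−E⁰)</sup>, f = F/RT;
  ΔS°<sub>rc</sub> = nF·dE<sub>1/2</sub>/dT,
  ΔH°<sub>rc</sub> = −nF·d(E<sub>1/2</sub>/T)/d(1/T),
  k<sub>s</sub> = A·e<sup>−ΔH‡/RT</sup>.
* CSP: Δδ = √(Δδ<sub>H</sub>² + (0.2·Δδ<sub>N</sub>)²).

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import numpy as np
import ccbiophys as cc

# synthetic far-UV CD melt with two unfolding transitions
model = cc.UnfoldingModelParams(3, [(55.5, 300.0), (87.1, 500.0)])
basis = cc.gaussian_basis(n_states=3, technique="far-UV CD")
temps = np.arange(10.0, 105.0 + 1e-9, 1.0)
ramp = cc.gen_spectral_ramp(model, basis, temps, cc.NoiseSpec(sigma=0.01, seed=7))

# PCA + multi-state van't Hoff fit of P1 with AICc model selection
pca = cc.pca_decompose(ramp)
fit, table = cc.select_model(pca.temperatures, pca.p1, [3, 4])
print("variance captured by P1: %.3f" % pca.variance_fraction[0])
print("chosen model: %d states" % fit.params.n_states)
for (tm, dh), err in zip(fit.params.transitions, fit.tm_err):
    print("Tm = %.1f +/- %.1f C  (dHvH = %.0f kJ/mol)" % (tm, err, dh))

# alkaline-transition pKa from a synthetic titration
curve = cc.gen_titration_curve(9.48, 0.3, 1.0, 0.0, noise=cc.NoiseSpec(0.01, 7))
pka = cc.fit_alkaline_transition(curve)
print("pKa = %.2f +/- %.2f" % (pka.pKa, pka.pKa_err))

# redox thermodynamic / kinetic consistency at 25 C
print("E1/2 from (dS, dH) = %.0f mV vs NHE" % cc.gibbs_helmholtz_potential(-142, -60))
print("ks from (A, dH_act) = %.0f 1/s" % cc.predict_arrhenius(3.1e5, 13.6))
```

prints

```
variance captured by P1: 0.838
chosen model: 3 states
Tm = 55.5 +/- 0.0 C  (dHvH = 302 kJ/mol)
Tm = 87.1 +/- 0.1 C  (dHvH = 518 kJ/mol)
pKa = 9.49 +/- 0.01
E1/2 from (dS, dH) = 183 mV vs NHE
ks from (A, dH_act) = 1284 1/s
```

The melt fit recovers both ground-truth melting temperatures (55.5 and
87.1 °C); AICc prefers the three-state model over the four-state one. The
titration refit lands on the generating pKa of 9.48 within its standard
error. The last two lines show that published reduction entropy/enthalpy and
Arrhenius parameters are internally consistent with the measured midpoint
potential (184 mV) and rate constant (1300 s⁻¹).

A command-line interface exposes the same pipelines
(`ccbiophys simulate|fit-unfolding|fit-pka|fit-kd|fit-echem|csp --help`).

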