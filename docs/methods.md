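# Methods

## Thermal unfolding of spectral melts

A melt experiment records full spectra on a temperature ramp (default
10–105 °C in 1 °C steps, matching a 1 °C·min⁻¹ ramp sampled once a minute).
The wavelength × temperature matrix is reduced by PCA with spectra as
observations and wavelength channels as mean-centered features
(`sklearn.decomposition.PCA`); the first score series P1(T) carries the
dominant thermal response. The sign of P1 is fixed so the high-temperature
end is high, making "unfolded" the upper plateau by convention.

P1(T) is fitted to a **sequential multi-state model**: states
S₀ ↔ S₁ ↔ … ↔ S_{n−1}, each transition an independent two-state van't Hoff
equilibrium with ΔCp = 0,

K_i(T) = exp[(ΔH_vH,i / R)(1/T_m,i − 1/T)],  f_j(T) = Π_{i≤j}K_i / Σ_k Π_{i≤k}K_i,

and each state contributing a constant signal s_j (linear baselines on the
first and last states are available but off by default; synthetic recovery
does not need them and they add parameters a 96-point curve constrains
poorly). This is the minimal model consistent with describing melts as
"three-state" or "four-state"; it ignores ΔCp and kinetic (scan-rate)
effects. The van't Hoff enthalpies only set transition sharpness and are
treated as nuisance parameters bounded to 50–1000 kJ/mol (protein-scale
cooperativity; the lower bound keeps transitions from degenerating into
baselines). Temperatures are converted to kelvin internally; T_m is
reported in °C.

Fitting uses variable projection: for each trial of the nonlinear
parameters the state signals are profiled out by linear least squares.
T_m values are parametrized as (T_m,1, gaps ≥ 0.5 °C) so they stay ordered.
The nonlinear search starts from 8 seeded initializations built from the
quantiles and local maxima of |dP1/dT| of the smoothed curve; the best
solution is re-polished with all parameters free, and standard errors come
from the asymptotic covariance (the gap parametrization is propagated to
each T_m). Model order is chosen by AICc (k = free parameters + 1 for the
residual variance); candidates within ΔAICc < 2 of the minimum resolve to
the model with fewer states. Populations are evaluated in log space with a
max-subtraction guard, so extreme ΔH·ΔT products cannot overflow.

## Alkaline-transition titration

The 699 nm band intensity vs pH is fitted (lmfit, least squares) to
Y = Absmin + (Absmax − Absmin)/(1 + e^{(X − pKa)/NS}); Y decreases toward
Absmin at high pH as the band is lost. Initial values: plateaus from the
data extremes, pKa from the half-amplitude crossing, NS = 0.5. A curve
whose amplitude does not exceed 3× a successive-difference noise estimate
is rejected as "no transition detectable". Parameter uncertainties are
asymptotic standard errors, matching the ± SD convention of the source
tables. The fitted pKa is invariant under affine rescaling of Y.

## BLI binding isotherm

Steady-state responses are the baseline-subtracted mean shift over the
final 10% (configurable) of the association phase. The isotherm
Y = Bmax·X/(K_D + X) + NS·X is fitted to all replicate points **pooled**
rather than averaged, preserving the duplicate error structure. The default
synthetic design is the twofold dilution series 10 → 0.3125 µM in
duplicate. A fitted K_D outside [min(X)/100, 100·max(X)] is flagged
`poorly_constrained`: the sampled range then carries no curvature
information about it.

## Protein-film voltammetry

The adsorbed couple is simulated with Butler–Volmer kinetics,
dθ/dt = k_f(E)(1−θ) − k_b(E)θ, k_f = k_s e^{(1−α)f(E−E⁰)},
k_b = k_s e^{−αf(E−E⁰)}, f = F/RT, integrated over a triangular sweep by
exact exponential stepping with rates evaluated at step midpoints
(unconditionally stable; default grid 0.1 mV). Current ∝ dθ/dt with
arbitrary amplitude — no electrode-area or coverage model — because only
peak positions carry the analysis. Peak potentials are located per branch
after subtracting a degree-≤2 polynomial baseline fitted to the branch
tails, with parabolic sub-grid refinement; a peak below 3× the tail noise
is an error, never a silent NaN.

E_1/2 = (E_pa + E_pc)/2, corrected to NHE by +192 mV exactly once when the
input reference is Ag/AgCl. Reduction entropy and enthalpy come from
ordinary least squares: ΔS°_rc = nF·slope(E_1/2 vs T),
ΔH°_rc = −nF·slope(E_1/2/T vs 1/T), n = 1, with errors propagated from the
slope standard errors; `gibbs_helmholtz_potential` is the exact inverse on
noise-free data.

k_s is extracted by **trumpet-plot fitting**: observed anodic/cathodic peak
potentials over ≥ 6 scan rates are matched, via nonlinear least squares in
(E⁰, ln k_s, α), against peak positions from the same ODE simulation. This
working-curve approach is valid in all regimes, unlike closed-form
irreversible-limit expressions (which the simulator nevertheless reproduces
to < 1 mV where they apply, and which seed the initial k_s guess). The
sweep window adapts to the expected irreversible shift so peaks never leave
the simulated range. When all points are reversible (ΔE_p < 5 mV) the fit
only bounds k_s from below and is flagged. Arrhenius analysis is OLS of
ln k_s vs 1/T: ΔH‡ = −R·slope, A = e^{intercept}; ΔH‡ is read as a
straight-Arrhenius activation enthalpy (no Ea − RT correction), the reading
consistent with the published (A, ΔH‡, k_s) triples.

## Chemical-shift perturbations

CSP_i = √(Δδ_H² + (w_N·Δδ_N)²) over residues present in both peak lists,
w_N = 0.2 (the conventional γ_N/γ_H-scaled weight), exposed as a parameter
since conventions vary. Residues in only one list are reported but excluded
from statistics. Significance defaults to CSP strictly greater than
mean + 1 SD (population SD), computed with the mutated-site residue
excludable from the statistics while remaining eligible for flagging; the
rule is scale-equivariant and flags nothing when all CSPs are equal.

## Synthetic data

Generators share the model structure of the corresponding fit plus i.i.d.
Gaussian noise on the observed signal — the standard instrument-noise
assumption — with all randomness from a single integer seed (bit-identical
repeats). Spectral ramps render state populations through per-state
Gaussian basis bands spread across the technique's wavelength window
(185–250 nm far-UV CD, 300–600 nm near-UV/Vis), with decreasing amplitudes
1, 0.7, 0.49, … so states are spectrally distinct; real CD basis spectra
are broader and partially overlapping, so recovery results show the
pipeline's correctness, not the identifiability of any particular protein's
spectra. Voltammogram sets use a linear E⁰(T) (reduction entropy) and
Arrhenius k_s(T), with each sweep normalized to unit peak current before
noise is added. What the generators do **not** emulate: baseline drift and
instrument response functions, correlated noise, aggregation or
irreversibility during melts, mass-transport or double-layer contributions
to CV, and kinetic (association/dissociation-phase) BLI traces beyond a
simple exponential carrier used in tests.

## Problem sizes and determinism

Recovery studies use 20 seeded replicates; melt fits use the 96-point
(1 °C) temperature grid and 66 far-UV wavelength channels; trumpet fits use
nine scan rates from 1 to 500 V/s with 2 mV peak-potential noise, where the
k_s estimator shows a ~2–3% relative spread across seeds. All multi-start
and noise seeds are explicit function arguments.

## Known limitations

- ΔCp = 0 and equilibrium sampling are assumed in melts; strongly coupled
  transitions closer than ~5 °C are not resolvable by AICc at realistic
  noise, which is expected behavior for nearly degenerate models.
- The trumpet fit assumes a single immobilized population with
  potential-independent α; dispersion in k_s broadens real peaks.
- The binding module does not model multi-site binding (isotherms hinting
  at two binding events need a different functional form) or kon/koff
  global kinetics.
- CSP significance is a relative, per-spectrum criterion; it does not test
  against a null distribution.
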