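# hydshell

Analysis pipeline for the structure and dynamics of supercooled water in
the hydration layer of a water-soluble polymer — poly(ethylene glycol)
(PEG) being the reference system. It is aimed at neutron-scattering and
simulation groups who want a scripted, testable route from reduced
quasi-elastic neutron scattering (QENS) spectra, small-angle neutron
scattering (SANS) curves and MD-style trajectories to the quantities that
characterise hydration-water dynamics: dynamical-transition onset
temperatures, stretched-exponential relaxation times and their q-scaling,
fragile/strong kinetic parameters, chain conformation, hydrogen-bond
lifetimes and the geometry of interfacial water pools.

Because instrument and microsecond-MD data are rarely redistributable,
the package ships a first-class synthetic-data module (`hydshell.synth`)
that emulates every input with known ground truth, so the whole pipeline
is exercised end to end by the test suite.

## Models

**Relaxation kinetics.** The temperature dependence of a relaxation time
τ(T) is fitted either as Arrhenius,

    τ = τ₀ · exp(E_A / k_B T),

or super-Arrhenius (Vogel–Fulcher–Tammann, VFT),

    τ = τ₀ · exp(K·T₀ / (T − T₀)),

with the divergence temperature T₀ a *fixed* input (compared across
literature values 124, 136, 176 K) and K the fragility constant. Both
laws are linear in a transformed abscissa, so fitting is exact weighted
linear regression of ln τ; extrapolations carry first-order propagated
uncertainties. A crossover temperature between the two laws is located by
bisection.

**QENS reduction.** The intermediate scattering function is the Fourier
transform of the incoherent dynamic structure factor,

    S_inc(q, ΔE) = (1/2π) ∫ F(q,t) · exp(−i ΔE t / ħ) dt,

computed here as a symmetrized cosine transform with time-domain division
by the transform of the measured resolution function (deconvolution).
F(q,t) is fitted with the Kohlrausch–Williams–Watts stretched exponential

    F(q,t) = A · exp(−(t/τ)^β),

and the mean relaxation time ⟨τ⟩ = (τ/β)·Γ(1/β) is regressed on q in
log–log space; exponents steeper than 2 signal sub-diffusive motion.
Elastic scans (window-integrated intensity vs temperature, normalized to
the lowest T) are fitted with a continuous two-segment line to locate the
onset of anharmonic motion; because the energy window is the instrument
resolution, the onset is resolution-dependent — the signature of a
dynamic rather than thermodynamic transition.

**SANS contrast variation.** For a mixed h/d chain population the
scattered intensity splits into a single-chain term weighted by the h/d
contrast and a total term weighted by the average contrast against the
solvent; the latter vanishes at the zero-average-contrast (ZAC) match
point, located from the sign-unfolded linearity of √I in the D₂O
fraction. Single chains follow the excluded-volume form factor
(incomplete-gamma representation) with P(qR_g ≫ 1) ~ q^(−1/ν), ν the
excluded-volume parameter (3/5 swollen, 1/2 Gaussian, 1/3 collapsed).

**Trajectory observables.** Geometric hydrogen bonds (O···O ≤ 3.5 Å,
O–H···O angle at the hydrogen ≥ 150°) feed the intermittent and
continuous bond correlators

    C(t) = ⟨h(0)h(t)⟩ / ⟨h⟩,   S(t) = ⟨h(0)H(t)⟩ / ⟨h⟩,

whose 1/e times are the structural relaxation time τ_R and the bond
lifetime τ_HB (always τ_R ≥ τ_HB). Also provided: g_OO(r), the self
intermediate scattering function ⟨sinc(q·|Δr(t)|)⟩, a Monte-Carlo water
volume-distribution function V(r) whose initial-slope intercept is the
confining length of a water pool and whose large-r asymptote is the water
volume fraction, and coarse-grained jump/residence statistics for the
trap-and-jump (trapping-site diffusion) picture.

## Worked example

Fit a hydration-water τ(T) table with the VFT law at T₀ = 176 K and
extrapolate into the supercooled regime:

```sh
$ hydshell kinetics --input tau.csv --law vft --t0 176 --eval-at 220
tau0_ns=0.00019999999999999985
K=3.6000000000000023
T0_K=176.0
tau_ns_at_220K=358.8149545212459
```

Here τ₀ ≈ 2.0×10⁻⁴ ns and K ≈ 3.6 are the fitted VFT parameters and the
relaxation time extrapolated to 220 K is ≈ 359 ns — water in the PEG
hydration layer relaxes about five orders of magnitude slower at 220 K
than at ambient temperature.

Generate a synthetic elastic scan with a known dynamical-transition
temperature and recover it:

```sh
$ hydshell --seed 7 synth-elastic --break-at 220 --noise 0.003 -o scan.csv
$ hydshell onset --input scan.csv --tmin 10 --tmax 300
T_onset_K=218.0
slope_low=-0.00035845828662976005
slope_high=-0.0012573909535546616
```

The piecewise-linear fit places the onset at 218 K (true value 220 K, one
grid step away at this noise level); the ~3.5× steeper high-temperature
slope is the anharmonic regime.

The same operations are available as library functions
(`hydshell.kinetics.fit_super_arrhenius`, `hydshell.qens.detect_onset`,
…) on the in-memory containers in `hydshell.io`.

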