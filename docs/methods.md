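# Methods

This note documents the models, numerical choices and known limitations
of the hydshell pipeline, module by module, together with what the
synthetic-data generators do and do not emulate.

## Units and containers

One unit system throughout: energies μeV, times ps (relaxation times in
kinetic fits: ns), lengths Å, momentum transfer Å⁻¹, temperatures K.
The only physical constants used are ħ = 658.2119569 μeV·ps and
k_B = 0.08617333 meV/K, held in a single frozen `Constants` object so
energy↔time conversions cannot pick up inconsistent factors.

File formats are plain text: CSV with `#`-prefixed `key=value` metadata
for spectra and curves (one temperature per spectrum file), extended XYZ
(`Lattice=`, `time=` in the comment line) or GRO (nm on disk, Å in
memory) for trajectories, and a tab-separated topology sidecar mapping
each 0-based atom index to a molecule id and a role token (OW, HW,
O_ether, C, H_peg). Topology is a sidecar because XYZ carries no molecule
identity. Only orthorhombic boxes are supported — the simulations this
pipeline targets use cubic boxes — and triclinic lattices are rejected
with an explicit error. The frame timestep is inferred from successive
`time=` values and must be uniform to 1e-6 ps. A water molecule must
carry exactly one OW and either two or zero HW; the zero-HW form admits
the bare-oxygen walkers produced by the synthetic generators.

## Relaxation kinetics

Both laws are fitted in log space: ln τ is linear in 1/(k_B T)
(Arrhenius; slope = E_A) and in T₀/(T − T₀) (VFT; slope = K). Weighted
linear least squares with weights 1/σ², σ = err/τ (multiplicative error
model), reduces to ordinary least squares when no errors are given. This
is exact and reproducible, and on noiseless synthetic data the fit→
evaluate round trip is the identity to machine precision; a nonlinear
refinement adds nothing for these two-parameter laws and is not
implemented.

T₀ is always a fixed input. Joint three-parameter VFT fits on the five
measured temperatures are badly conditioned (τ₀ and T₀ trade off almost
perfectly), and the scientific protocol is a comparison across the three
literature divergence temperatures of water (124, 136, 176 K), each
yielding its own (τ₀, K).

Extrapolation uncertainties are first-order: var(ln τ) = J Σ Jᵀ with
J = (1, x) and Σ the 2×2 fit covariance of (ln τ₀, slope). How the
published ± bands on extrapolated times were obtained is not documented
at the source; ours are fit-covariance propagation and agree with those
bands in order of magnitude only.

Note that τ₀ is the 1/T → 0 (or T → ∞) intercept, extrapolated far
outside the measured window: its relative uncertainty is roughly six
times that of the slope for a 260–318 K span. Tests tolerate this.

The crossover temperature between an Arrhenius and a VFT parameter set is
the bisection root of the log-difference, to 0.01 K; a bracket without a
sign change is an error rather than a silent extrapolation.

## QENS reduction

**Elastic scans.** Per temperature, S(q, ΔE) is trapezoid-integrated over
|ΔE| ≤ W with W the elastic energy window, summed with uniform weight
over the chosen q range, and normalized by the lowest-temperature value.
The window defaults to the instrument resolution FWHM (1 μeV for a
backscattering instrument, 17.5 μeV for an inverted-geometry TOF
spectrometer) and is the parameter that makes the apparent onset
resolution-dependent: a relaxation of width Γ(T) leaves a narrow window
at lower temperature than a wide one, so the better-resolved instrument
reports the lower onset. The q-range weighting within the sum is uniform
(the measured counts-weighting of a specific detector bank is not
knowable from reduced data).

**Onset detection.** A continuous two-segment piecewise-linear model
(hinge parameterisation, three linear parameters) is solved by exact
least squares at every interior grid temperature with at least four
points per segment, and the breakpoint minimizing the SSE is returned.
The exhaustive search avoids the local-minimum pitfalls of gradient
methods on a non-smooth objective; on noiseless bilinear data it recovers
the break to within one grid step for any distinct slope pair.

**Spectrum → ISF.** F_s(t) = ∫ S(ΔE) cos(ΔE·t/ħ) d(ΔE) by trapezoid on
the measured window; the symmetrized cosine transform treats the spectrum
as classical (detailed-balance asymmetry is ignored, valid for
ħω ≪ k_B T). Resolution deconvolution is division in the time domain,
F = F_s/F_res, normalized to F(0) = 1; points where |F_res(t)| has
decayed below 1% of F_res(0) are dropped (and counted in the curve
metadata) because the division amplifies noise without bound. When the
spectrum carries per-point errors they are propagated through the
trapezoid transform, giving each retained F(t) a one-sigma uncertainty
σ_F(t) ∝ 1/|F_res(t)| that grows toward the resolution limit.

**KWW fitting.** A·exp(−(t/τ)^β) by Levenberg–Marquardt with three
starting values β ∈ {0.3, 0.6, 0.9}, tie-broken by SSE; β is bounded to
(0.1, 1.0]. When the ISF carries propagated uncertainties the residuals
are weighted by 1/σ_F — without this, the noisy points near the
resolution cutoff visibly bias β and hence the q-scaling slope.
"Average relaxation time" is ambiguous in parts of the literature; both
the bare τ and ⟨τ⟩ = (τ/β)Γ(1/β) are reported, and the q-scaling
regression uses ⟨τ⟩ (with constant β the two give identical slopes).

**q-scaling.** Ordinary least squares of ln τ on ln q. The signed slope
is returned (negative for sub-diffusion) along with the prefactor
(τ at q = 1) and the slope standard error.

## SANS contrast

SLDs are computed from bound coherent scattering lengths
(b_H = −3.739 fm, b_D = 6.671 fm, b_C = 6.646 fm, b_O = 5.803 fm) and
the mass density; mixtures are volume-fraction linear.

The two-term contrast intensity is evaluated literally: a single-chain
term weighted by (ρ_d − ρ_s)²·x_d·x_h and a total term weighted by the
squared average contrast, with P_T = P_S + φ_P·P_I. The equivalent
three-term partial-structure-factor expansion uses the decomposition
S_dd = x_d²S_T + x_d x_h S₁, S_hh = x_h²S_T, S_hd = x_d x_h S_T
(S_T the total, S₁ the single-chain factor), which reproduces the
two-term form identically and serves as an algebraic cross-check in the
tests. (The compact identity sometimes quoted for equal h/d chains,
relating S_dd, S_hh and S_hd directly, appears in garbled form in parts
of the literature; the decomposition above is used instead of guessing
the intended identity.)

**Match point.** Intensity is quadratic in contrast, so √I is the
absolute value of a line in the D₂O fraction. The sign is flipped past
the intensity minimum; both candidate flip positions (at the minimum and
just after it) are fitted by weighted least squares and the lower-SSE
assignment kept. The match point is the root of the line, with a
first-order standard error from the fit covariance. A minimum sitting on
the edge of the fraction series is a hard error: the match point must be
bracketed.

**Excluded-volume form factor.** P(q) from the two lower-incomplete-gamma
terms with U = q²R_g²(2ν+1)(2ν+2)/6; γ(a, x) is evaluated as
Γ(a)·P(a, x) with the regularized function from scipy. The printed
formula is 0/0 at U = 0, so below U = 1e-4 a Taylor expansion through
O(U³) is used, making P(0) = 1 exact. At ν = 1/2 the expression reduces
analytically to the Debye function (verified to 1e-6 over qR_g ∈ [0,10]);
the high-q log-log slope is −1/ν (the Porod exponent m = 1/ν).

**Curve fitting.** scale·P(q; R_g, ν) + background by weighted nonlinear
least squares (lmfit), multi-start over R_g (Guinier-scale guess ×
{0.5, 1, 2}) and ν initials {0.42, 0.5, 0.6}; ν may be fixed (1/2, 3/5)
for hypothesis comparison. Instrument resolution smearing (wavelength
spreads of order 18% are typical for reactor SANS) is *not* modelled and
should be treated as a systematic when interpreting fitted R_g.

## Trajectory observables

**Hydrogen bonds.** Geometric criterion: donor–acceptor O···O minimum-
image distance ≤ 3.5 Å and O–H···O angle ≥ 150°, measured at the
hydrogen (180° = linear). The hydrogen vertex is the standard reading of
the "O–H···O angle"; a donor-vertex reading would give systematically
more bonds. Default selection is polymer–water: water O–H donates to the
polymer ether oxygen (the role scheme models no chain-end hydroxyls, so
the polymer has no donors); water–water bonding is available by role
selection, with intra-molecular pairs excluded.

**Correlators.** The pair universe is every triple bonded in at least one
frame — ⟨h⟩ would be undefined over never-bonded pairs. C(t) and S(t)
use multiple time origins restricted to t₀ ∈ [0, T−1−t_max], the same
origin set for every lag, so both estimators equal 1 at t = 0 exactly and
S(t) (a product of h over all intermediate frames — strict continuity,
no grace period) is monotone non-increasing by construction. The shared
denominator is Σ h(t₀) over pairs and origins. 1/e times come from
linear interpolation between the bracketing samples of the first
crossing; a curve that never crosses raises an error carrying its last
value rather than extrapolating.

**RDF.** Minimum-image pair histogram (KD-tree with periodic boxsize),
normalized per frame by N_pairs·V_shell/V_box, with same-species pairs
counted once; r_max may not exceed half the smallest box edge.

**Self ISF and MSD.** Coordinates are unwrapped by accumulating per-step
minimum-image displacements, valid while no atom moves more than half a
box edge between frames (true for any reasonably sampled trajectory).
F(q,t) = ⟨sinc(q·|Δr|)⟩ over atoms and all origins; MSD likewise by
multiple origins. Jump statistics coarse-grain the unwrapped positions by
block averaging (default 10 frames): a coarse displacement above the
threshold between consecutive blocks is a jump, and residence times are
the uncensored inter-jump intervals. A jump landing near a block boundary
splits its displacement between two consecutive coarse steps, so
thresholds should sit near half the expected jump length.

**Volume distribution.** The water region is the periodic union of
spheres of radius 1.7 Å (≈ a water-oxygen van-der-Waals scale; default,
configurable) around the water oxygens. Probe centres are drawn uniformly
*inside* the region by rejection; V(r) is the Monte-Carlo fraction of a
radius-r sphere around each centre that lies inside the region, averaged
over centres, with the standard error over centres reported per radius.
This probe-sphere definition reproduces both diagnostics of interest: the
x-intercept of the initial slope is the confining length of a water pool,
and for r much larger than the box the wrapped samples become uniform so
V(r) tends to the water volume fraction. The confining length is the
x-intercept of a straight line fitted on a small-r window (≥ 3 points,
negative slope required).

## Synthetic data

All generators are seeded (`numpy.random.default_rng`); identical
arguments including the seed give bit-identical output, and every
generator returns a truth record holding its parameters and derived
ground-truth values.

* **KWW spectra** — per q, the cosine transform of exp(−(t/τ(q))^β)
  multiplied by the Gaussian resolution's time-domain envelope
  (equivalent to energy-domain convolution), τ(q) = τ₁·q^power, plus
  multiplicative Gaussian noise; the companion resolution spectrum is the
  analytic Gaussian. The stretched exponential's non-analytic short-time
  behaviour gives the spectrum heavy |ΔE|^−(1+β) tails, so the energy
  window must be wide — the generator refuses a window capturing < 90% of
  the analytic norm. The shipped study conditions (q = 0.53–1.85 Å⁻¹,
  τ₁ = 30 ps, power −2.65, β = 0.6, 17.5 μeV FWHM, 1% noise) use a
  ±3 meV window at 2 μeV spacing.
* **Telegraph bonds** — stationary two-state Markov chains with *exact*
  per-step transition probabilities (p + (1−p)e^{−kΔt} etc.), started
  from the equilibrium occupancy; C(t) then matches
  p + (1−p)e^{−(k_on+k_off)t} exactly at the sampled lags and the
  survival decay approaches e^{−k_off t} for Δt·k ≪ 1.
* **Trap-and-jump walkers** — isotropic Gaussian libration about simple-
  cubic lattice sites (the simplest topology honouring the "pools"
  picture), exponential residence, uniform hops to one of the 6
  neighbours; sites tracked unwrapped so the truth jump counts are exact.
  Libration-only walkers have an MSD plateau of 6σ² and an elastic
  incoherent structure factor exp(−q²σ²).
* **SANS curves / contrast series** — forward model plus noise; the
  contrast series defaults to a zero h/d split so the intensity is a
  perfect square in the D₂O fraction (√I exactly piecewise linear, match
  point recoverable to machine precision); a positive split adds the
  non-vanishing single-chain floor of real series.
* **Two-phase boxes** — slab geometry tiles the nominal sub-volume with a
  jittered regular grid inset by exactly √(w² − s²/2) (the depth to which
  a plane of spacing s fully covers), so the covered region matches the
  nominal slab; the truth record also carries a deterministic Monte-Carlo
  measurement of the actually covered fraction, which is the right
  comparison target for asymptote tests. Sphere geometry places
  non-overlapping spheres.
* **Elastic scans** — q-set average of exp(−q²⟨u²⟩/3) with ⟨u²⟩(T)
  piecewise linear (the harmonic/anharmonic bilinear picture); ⟨u²⟩ is
  synthetic scaffolding, not an analysis output.

What the generators do *not* emulate: multiple scattering, detector
efficiency and detailed-balance asymmetry in spectra; instrument
resolution smearing in SANS; atomistic force-field structure (no real
g_OO(r) peaks, no cooperative hydrogen-bond networks); non-exponential
residence-time distributions. Passing tests therefore demonstrate the
correctness of the estimators under the stated stochastic models, not
the fidelity of any particular force field or instrument.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes —
5 q values with ~3000-point energy grids for the spectrum pipeline,
3×10⁴–6×10⁴ frames × 30–40 pairs for telegraph correlators, 10⁴ frames ×
40 walkers for trap-jump statistics, a few hundred probes × ~10² sphere
samples for the volume distribution — chosen so estimator errors sit
well inside the asserted tolerances while the whole suite completes in
well under a minute of compute per heavy test.

## Known limitations

* Spectra are assumed symmetrized; strongly quantum regimes (ħω ≳ k_B T)
  need a detailed-balance correction upstream.
* Time-domain deconvolution discards data beyond the resolution limit
  instead of regularising; relaxations slower than ~½ the inverse
  resolution width are only constrained through their early decay.
* The two-segment onset model is a diagnostic, not a physical model; for
  scans with curvature on both sides of the transition the recovered
  break depends on the fit range.
* Published microsecond-MD hydrogen-bond times (τ_R of tens of ns at
  220 K) require trajectories this package does not generate; the
  correlator machinery is validated against the telegraph closed forms
  and the universal C ≥ S, τ_R ≥ τ_HB orderings instead.
* Fitted chain radii from SANS ignore resolution smearing and
  concentration effects (structure factor assumed unity at the fitted
  concentrations).
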