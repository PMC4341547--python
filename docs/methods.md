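# Methods

## Model

`burstfield` simulates a two-dimensional neural field model of
electrocortical activity on a toroidal sheet. Two interacting populations
— excitatory (e) and inhibitory (i) — are described by their mean soma
membrane potentials h_e(x, t), h_i(x, t), evolving as conductance-weighted
leaky integrators:

    τ_k ∂h_k/∂t = h^r_k − h_k + Σ_l ψ_lk(h_k) I_lk ,
    ψ_lk(h) = (h^eq_lk − h) / |h^eq_lk − h^r_k| ,

so that excitatory input depolarises with weight +1 at rest, weakens
linearly toward the excitatory reversal potential, and reverses beyond it
(and symmetrically for inhibition). Population firing rates are
instantaneous sigmoids S_k(h) = S^max_k / (1 + exp[−√2 (h − μ_k)/σ_k]).

Each of the four synaptic classes lk ∈ {ee, ei, ie, ii} low-pass filters
its incoming pulse rate A_lk through a bi-exponential (two-rate) kernel,

    (γ⁻¹∂t + 1)(γ̃⁻¹∂t + 1) I_lk = e^{γδ} Γ_lk γ⁻¹ A_lk ,

whose impulse response peaks at the rise time δ_lk with amplitude Γ_lk
regardless of the shape parameter ε = ln(γ̃/γ). This decouples the rise
time (held fixed) from the decay time (prolonged by anesthesia, below).

Excitatory activity also propagates through long-range cortico-cortical
fibres as a damped wave,

    [(v⁻¹∂t + λ⁻¹)² − ∇²] Φ_ek = λ⁻² C_e S_e(h_e) ,

with conduction velocity v and exponential footprint λ. Inhibitory axons
are local. Extracortical (thalamic) drive enters as p_ee (stochastic,
below) and p_ei (constant).

### Anesthetic action (isoflurane)

The aqueous concentration c (mM) enters through Hill curves fitted to
laboratory data in earlier work on this model family:

* amplitude scaling Γ_lk(c) = Γ⁰_lk H_l(c), with H_e → 0 and H_i → 0.56
  as c → ∞;
* prolongation of the inhibitory PSP decay time by
  κ(c) = (0.32^2.7 + 4.7 c^2.7)/(0.32^2.7 + c^2.7), the excitatory decay
  unaffected (κ_ek ≡ 1).

κ is translated into the kernel shape parameter ε by inverting the
closed-form decay time of the bi-exponential response (the time beyond the
peak at which the response has fallen to Γ/e, measured from onset). A
published closed-form approximation using the W₋₁ branch of the Lambert-W
function supplies the starting value; because its worst-case fidelity is
~1.5 % over κ ∈ [1, 4.7] while the package's own tolerance for the
decay-time ratio is 1 %, `epsilon_from_kappa` refines it by a bracketed
root solve on the exact decay-time ratio (`refine=False` exposes the raw
formula). During concentration ramps the simulation interpolates all
concentration-derived scalars from a 513-node table over [0, c_max];
interpolation error is ~1e-7 relative and is shared bit-for-bit between
the compiled and reference steppers.

Clinical units are linear anchors: 1 MAC = 1.17 % inspired = 0.243 mM.
Temperature dependence is out of scope.

### Slow synaptic depletion and recovery (the bursting mechanism)

The peak amplitudes Γ_lk become slow state variables: pre-synaptic firing
depletes them, and they recover toward a resting value Γ^r_lk = Γ⁰_lk(1+f_l)
with time constant τ^rec_l (800 ms excitatory, 600 ms inhibitory). In
scaled form only two efficacy fields are integrated,

    τ^rec_l ∂C_l/∂t = 1 + f_l − (1 + f_l S_l/S⁰_l) C_l ,   Γ_lk = Γ⁰_lk C_l ,

with S⁰_l the firing rates of the zero-anesthesia equilibrium, frozen at
run start. Freezing S⁰_l is what makes the constructed initial state
exactly stationary; C_l = 1 there, and C_l ≤ 1 + f_l always. Under
anesthesia the effective amplitude is Γ⁰_lk C_l(x,t) H_l(c). Depletion
multiplies the firing rates inside the pulse-rate sums and the wave
source (pre-synaptic bookkeeping); the alternative post-synaptic
bookkeeping (separate efficacies for local and conduction-delayed input)
is documented but deliberately not implemented. Extracortical input is
not depleted.

The mechanism of burst suppression: anesthesia depresses h_e, firing
drops, reservoirs refill (C_l rises toward 1+f_l), excitatory PSPs grow
until self-excitation destabilises the sheet into a burst, the burst
depletes C_e within ~100 ms, the sheet falls near-isoelectric, and the
cycle repeats on the recovery time scale.

## Equilibrium and initial state

With the drive at its mean, the ten-field homogeneous steady state
reduces to two unknowns (h_e, h_i): all PSP levels are slaved to the
firing rates through the steady kernel gains e^{γδ}Γ/γ, and the steady
flux equals C_e S_e. The root is found by nested bracketed solves (the
inhibitory equation is monotone in h_i at fixed h_e), continued from the
resting potentials; a coarse scan over [−90, −40] mV reports any further
sign changes (none occur for the shipped set). Every run starts from the
zero-anesthesia equilibrium with C_l = 1 and static wave history;
noise-free integration stays on it to ~1e-11 over 1 s. Fixed-concentration
experiments switch c on at t = 0 and discard an initial transient
(4–10 s depending on the experiment, stated below).

For the shipped parameters the equilibrium sits 4.67 σ_e below the mean
firing threshold μ_e at c = 0 and 5.25 σ_e below it at 1 MAC — the
firing nonlinearity operates deep in its low tail under anesthesia, which
is what turns roughly symmetric h_e oscillations into sharp firing-rate
spikes during bursts.

## Stochastic drive

p_ee is a spatiotemporally correlated Gaussian field: independent knot
fields are drawn on the grid, lowpass-filtered in the spatial Fourier
domain, and interpolated in time by a Catmull-Rom spline over the knots.
Target statistics: mean p_ee from the parameter table, standard deviation
10 % of the mean, −3 dB at 75 Hz in time and at 2 cycles/cm in space.
The cited prior work does not print its filter shapes, so the package
uses calibrated stand-ins:

* spatial transfer |T(k)|² = 2^−(k/k_c)² (radially symmetric Gaussian),
  exactly −3 dB at k_c = 2/cm; the resulting field decorrelates beyond
  ~0.5 cm;
* the knot interval h solves ν_c/h = 75 Hz, where ν_c ≈ 0.2694 is the
  dimensionless half-power frequency of the Catmull-Rom kernel, computed
  numerically once from its Fourier transform;
* a final renormalisation divides by the time-averaged variance of the
  interpolant (≈ 0.84 for unit knots) so the long-run per-point sd hits
  the target regardless of filter settings. The interpolated process is
  weakly cyclostationary (its variance dips mid-interval by ~35 %); the
  renormalisation targets the time average.

The stream is a pure function of (spec, grid, Δx, Δt, seed). Burst-phase
behaviour does not depend on these details (the instability is intrinsic);
the noise only seeds spatial heterogeneity.

## Numerics

Forward Euler for every field at a single Δt = 0.05 ms (stored in ms:
the internal unit system is ms/mm/mV/mM throughout, matching the
parameter table as printed). The damped-wave flux is advanced by a
three-level scheme — centred second and first time differences on
(previous, current, future), solved for the future value — with a
five-point periodic Laplacian at Δx = 1 mm (CFL number vΔt/Δx ≈ 0.11).
Because λ_ee = λ_ei and v_ee = v_ei in the shipped set, the two
excitatory flux classes satisfy the same PDE with the same source and are
stored as one field; the state constructor splits them automatically if
the parameters ever differ. No operator splitting: all subsystems advance
from the same time level in one sweep.

The production stepper is a single numba-compiled kernel fused per grid
point, advancing one noise-knot interval (~5.4 ms, 108 steps) per call;
per-substep anesthetic scalars are table-interpolated by the driver. A
plain-numpy reference stepper implements identical operations and the two
are regression-tested to agree to ~1e-12 per step sequence. A divergence
detector checks every 0.25 s that fields are finite, h stays within the
reversal-potential range ±10 mV, and C_l ∈ (0, 1+f_l]; violations abort
with diagnostics. Recordings decimate to 250 Hz in float32 (h_e and C_e);
full precision is kept internally.

Near-degenerate kernel rates (γ̃ → γ, ε → 0) use explicit series/limit
branches below ε = 1e-8; the bi-exponential response uses the alpha form
below relative rate splits of 1e-10 to avoid 0/0.

## Analysis chain

Per-grid-point Welch PSDs (2.5 s Hann windows, 50 % overlap, per-segment
mean removal — the window and detrending are this package's choices, as
the source analyses leave them unstated) are averaged over all grid
points; a unit-area-normalised variant is provided for visual comparison.
"Total power" integrates the raw average over (0, f_Nyq], excluding the
0 Hz bin, so plateaus with different mean potentials compare by their
fluctuation power.

Burst peaks are detected on the effective amplitude
Γ_ee(t) = Γ⁰_ee C_e H_e(c): each maximal run of samples with
Γ_ee ≤ 0.05 contributes the time of its deepest minimum (earliest on
ties). The 0.05 threshold is interpreted as absolute millivolts (≈ 27 %
of Γ⁰_ee); a normalised-threshold mode (on C_e H_e) is available via
`ibi_statistics(..., normalized_threshold=True)`. Censoring removes
"double-dipping": while any consecutive peak pair is closer than 1.0 s,
the shallower peak of the closest pair is dropped. The source analyses
state only that short intervals are removed; dropping the shallower peak
is this package's estimator and is tested as such. Inter-burst intervals
are pooled over the grid for mean ± sd.

## Study experiments and the scales used

Full-scale ("paper") configurations use the 512 × 512 grid at Δx = 1 mm
(2,621.44 cm², roughly one human cortex) and the full protocol durations;
they are cluster-sized. All shipped tests and the acceptance script use
reduced ("desk") configurations chosen to preserve the property each
experiment probes:

* **Induction staircase** — plateaus at 0, 0.5, 1.0, 1.5 MAC with 10 s
  linear ramps (the ramp to 1.0 MAC is taken as 10 s like the others; its
  duration is not stated in the source). Desk scale: 64 × 64 grid, 10 s
  plateaus with the bursting plateau shortened to 15 s, final 2.5 MAC ramp
  omitted (the test suite uses 48 × 48 with 8 s plateaus). On these grids
  the bi-phasic power surge (0.5 MAC / awake total-power ratio) measures
  ≈ 1.3–1.45 against 1.26 reported at full scale, and the post-burst
  plateau ratio ≈ 1.44–1.47 against 1.44; burst suppression appears only
  on the 1 MAC plateau, with power two orders of magnitude above rest.
  Small grids synchronise more than the full sheet, so the full-scale
  power factor of 131 on the bursting plateau is not reproduced
  quantitatively at desk scale (the desk property is ratio > 20).
* **Connectivity-scale sweep** — λ_ek ∈ {2.7, 2.4, 2.1} cm at 0.25 mM
  with identical noise streams across λ. Desk scale: 64 × 64, 20 s with a
  4 s discarded transient. Desk-scale inter-burst intervals are shorter
  and more regular than the full-scale values (4.44 ± 0.26 s, 4.0 ± 1.1 s,
  3.5 ± 1.5 s), again because small tori synchronise; the preserved
  properties are the orderings (mean IBI decreasing, spread increasing as
  λ shrinks) and a standard-λ mean in the seconds range. Spatial
  pattern-size shrinkage is *not* resolvable at this scale: on a 6.4 cm
  torus every burst recruits essentially the whole sheet for all three λ
  values, and the instantaneous fields additionally carry pixel-scale
  timing jitter (neighbouring points dip below the burst threshold a few
  samples apart), so the FFT autocorrelation length of snapshots reflects
  that jitter rather than burst-patch size. The
  `pattern_correlation_length` diagnostic is provided (and verified on
  synthetic fields) for full-scale use.
* **Heterogeneity patch** — f_i raised from 0.175 to 1.25 in a circular
  patch at 0.25 mM. The suppression mechanism depends on λ (shrinking λ
  to fit a small torus lets bursts regenerate through the patch), so the
  desk configuration keeps the standard λ = 2.4 cm and the printed patch
  radius 9.6 cm = 4λ, and coarsens instead: Δx = 2 mm on a 128 × 128 grid
  (25.6 cm torus), 22 s with a 10 s transient. The patch then covers 44 %
  of the sheet (11 % at full scale), which strengthens rim spill-in
  relative to the original geometry but preserves the result: bursts
  outside, a quiet centre (Γ_ee never approaches the detection threshold),
  sub-threshold "quasi-burst" fluctuations at the rim (probe at
  radius − λ), and no suppression when the patch uses f_i = 0.5. Probes
  are the patch centre, radius − λ, and the antipodal point (at this
  geometry the point two radii from the centre is still inside the patch,
  so "outside" is taken maximally distant).

## Known limitations

* The torus with homogeneous isotropic connectivity is an anatomical null
  model; folded geometry, patchy connectivity and dispersive (multi-
  velocity) propagation are out of scope, as are other agents,
  pharmacokinetics, anesthetic modulation of thalamic input, and fast-slow
  bifurcation analysis.
* Desk-scale grids (6.4–25.6 cm tori) synchronise more than a full
  cortex; absolute burst statistics are grid-size dependent and only the
  full 512 × 512 configuration reproduces the full-scale numbers.
* The noise filter shapes are calibrated stand-ins matching the stated
  −3 dB points and correlation length, not reconstructions of the cited
  implementations.
* Forward Euler at Δt = 0.05 ms trades speed for robustness; halving Δt
  moves quasi-linear trajectories by well under 1 %, but inside the
  bursting regime pointwise trajectories decorrelate (sensitivity of the
  instability), where only statistics are meaningful.
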