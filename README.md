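# burstfield

Neural field simulation of burst suppression under isoflurane anesthesia.

Burst suppression — quasi-periodic alternation of high-amplitude EEG
bursts with near-isoelectric suppression — marks deep anesthesia and
severe brain insults. Intracranial recordings show it is not the global,
synchronous state it was long assumed to be: bursts can be asynchronous
across cortex and confined to circumscribed regions. `burstfield`
implements a mean-field model that produces this spatially heterogeneous
bursting mechanistically, for computational neuroscientists who want to
simulate, perturb and analyse it: a two-dimensional excitatory/inhibitory
neural field on a toroidal cortical sheet (mean soma potentials h_e, h_i;
sigmoidal firing rates; conductance-weighted synaptic reversal),
bi-exponential synaptic kinetics whose inhibitory decay time and peak
amplitudes follow Hill-equation isoflurane concentration-response curves,
damped-wave cortico-cortical propagation
[(v⁻¹∂t + λ⁻¹)² − ∇²]Φ = λ⁻²C_eS_e, and a slow activity-dependent
synaptic resource system

    τ^rec_l ∂C_l/∂t = 1 + f_l − (1 + f_l S_l/S⁰_l) C_l ,
    Γ_lk(x, t, c) = Γ⁰_lk C_l(x, t) H_l(c) ,

whose depletion/recovery cycle generates bursting at surgical
concentrations. The package ships the published "bi-phasic" parameter
set, the anesthesia-induction, heterogeneity-patch and connectivity-scale
experiments, and the analysis chain (grid-averaged Welch spectra, plateau
power ratios, burst-peak detection, inter-burst-interval statistics).

See `docs/methods.md` for the model, numerics and design choices.

## Worked example

```python
import burstfield as bf

p = bf.default_parameters()

# concentration-derived quantities at 1 MAC isoflurane (0.243 mM)
st = bf.anesthetic_state(p, bf.concentration_from_mac(1.0))
print(f"H_e = {st.H_e:.4f}, H_i = {st.H_i:.4f}, "
      f"kappa_i = {st.kappa['ie']:.4f}, eps_i = {st.eps['ie']:.4f}")

# resting PSP amplitudes at 0.25 mM, standard vs raised inhibitory depletion
std = bf.resting_amplitudes(p, 0.25)
hi  = bf.resting_amplitudes(p, 0.25, f_override={"i": 1.25})
print(f"Gamma_r_ie = {std['ie']:.4f} mV (f_i = 0.175) "
      f"-> {hi['ie']:.4f} mV (f_i = 1.25)")

# homogeneous equilibrium: how far h_e sits below the firing threshold
for mac in (0.0, 1.0):
    eq = bf.fixed_point(p, bf.concentration_from_mac(mac))
    print(f"{mac} MAC: h_e* = {eq.h_e:.3f} mV, "
          f"depth = {(p.mu_e - eq.h_e)/p.sigma_e:.2f} sigma_e")
```

prints

```
H_e = 0.9146, H_i = 0.9804, kappa_i = 2.1925, eps_i = 2.8095
Gamma_r_ie = 1.8369 mV (f_i = 0.175) -> 3.5174 mV (f_i = 1.25)
0.0 MAC: h_e* = -65.038 mV, depth = 4.67 sigma_e
1.0 MAC: h_e* = -66.678 mV, depth = 5.24 sigma_e
```

H_e, H_i are the anesthetic amplitude factors, κ_i the inhibitory
decay-time prolongation and ε_i the kernel shape parameter achieving it.
The Γ^r values show how raising the inhibitory depletion factor f_i
boosts the resting inhibitory amplitude by the factor (1+1.25)/(1+0.175)
≈ 1.91 — the manipulation that locally abolishes bursting in the patch
experiment. The equilibrium depth (σ_e below threshold μ_e) is why firing
is so strongly rectified under anesthesia.

A full induction simulation — 0 → 1.5 MAC staircase on a 64 × 64 mm
sheet, with per-plateau spectra and burst statistics (a few minutes):

```python
res = bf.run_figure2(scale="desk", seed=1)
print(res.power_ratios)       # total h_e power per plateau vs awake
print(res.bursting_plateaus)  # ['E'] - bursting only at 1 MAC
print(res.bursts["E"].mean_ibi, res.bursts["E"].sd_ibi)
```

or from the shell:

```
burstfield experiment figure2 --scale desk --seed 1 --out results/fig2
burstfield experiment patch   --scale desk --seed 7 --out results/patch
burstfield experiment lambda  --scale desk --seed 7 --out results/lambda
burstfield run --protocol constant --c-mm 0.25 --duration 30 \
               --grid 64x64 --seed 7 --out run.h5
burstfield analyze bursts --in run.h5 --t0 5 --t1 30
```

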