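# Methods

This note documents the model equations, the provenance and meaning of the
default parameters, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Receptor kinetics

Both GABA-A receptor subtypes use one 8-state ligand-gated scheme:

```
        2·k_on·c        k_on·c
   C  <--------->  AC <---------> A2C
        k_off           2·k_off
   AC <-> AO   (b1 opening / a1 closing)
   A2C <-> A2O (b2 opening / a2 closing)
   AC <-> AD   (d1 / r1)        A2C <-> A2D (d2 / r2)
   AD <-> A2D  (d1d2·c / r1r2)  A2C <-> A2Df (d3 / r3)
```

`c` is the GABA concentration (mM). The two binding steps carry the
canonical statistical factors of two identical sites. The gating pairs
follow the Greek-letter convention of the ligand-gated-channel literature
(`a` = α = closing, `b` = β = opening); under this reading the published
α6 rate set yields a steady-state EC50 of 1.56 μM — matching the ~1.5 μM
reported for α6β2/3γ2-class receptors — and the α1 set yields 12.7 μM,
inside the 10–100 μM range characteristic of α1-containing receptors.
Under the opposite reading both EC50s come out an order of magnitude too
low regardless of topology, which is why the convention is fixed this way
and guarded by a test. The fast-desensitized state is entered from the
doubly-bound closed state; entry from the open state is available as a
flag and changes the EC50 calibration only mildly.

Occupancies evolve as `dx/dt = Q(c)x` with `Q(c) = Q0 + c·Q1`.
Propagation applies the exact matrix exponential per step on a
piecewise-constant concentration grid; the rates span five orders of
magnitude, so explicit integration would be stiffness-limited.  The trial
engine precomputes `expm(dt·Q)` on a 480-level logarithmic concentration
grid (≈3.4 % resolution, 0.1 nM–20 mM plus an exact zero level) and snaps
concentrations to the nearest level: the only additional error is the
concentration discretization, bounded well below the kinetic sensitivity
of the schemes (verified against Radau integration to 1e−6).

Both open states conduct with equal weight; the current is ohmic,
`I = g_max·P_open·(V − E_Cl)` with `E_Cl = −65 mV`.

## Release

Each synapse has three independent releasing sites.  Deterministically, a
spike at time `t` releases the fraction `u·x` of the site's resource,
where `x` recovers toward 1 with τ_REC between spikes and `u ≡ p` when
τ_FAC = 0 (the fitted value; with τ_FAC > 0 the standard facilitation
recursion applies).  The quantal variant holds at most one releasable
vesicle per site: refill is a Poisson event with rate 1/τ_REC and a
uniform draw against `Y = u·x` (binary `x`) decides release, so the trial
mean equals the deterministic fraction exactly — asserted by a
law-of-large-numbers test.

Fitted parameters (train fits): p = 0.42 (control) / 0.67 (GABA-B
receptors blocked), τ_REC = 38.7 ms, τ_FAC = 0.

## Transmitter field

A PSD sees the sum of a direct pulse — 1 mM for 1 ms per release at its
facing site, scaled by the released fraction in deterministic mode — and
spillover from neighboring releases at the single fitted distance
r = 1.07 μm.  The fitted source A = 10 573 molecules is a per-synapse
quantity; each site's quantum carries A/3, mirroring the division of the
postsynaptic conductance across sites.

The spillover Green's function is selectable.  The default is the
three-dimensional point-source solution

    C(r,t) = (A/3) / (8 (π D_eff t)^{3/2}) · exp(−r²/(4 D_eff t)),

with D_eff = 0.221 μm²/ms, which produces sub-μM to few-μM transients —
the range in which high-affinity α6 receptors physiologically operate —
and decays as t^{-3/2}.  The two-dimensional disc solution
`(A/3)/(4πh·D_eff·t)·exp(−r²/4D_eff t)` with cleft thickness h = 50 nm is
also implemented (`geometry="disc"`); it confines transmitter to the
cleft indefinitely, so after a train the glomerular GABA floor remains in
the tens of μM for hundreds of milliseconds.  With a non-desensitizing
α6 receptor that floor acts as a second tonic conductance: the simulated
train charge comes out 4–6× the measured ~1.2 pC and burst disinhibition
overshoots the measured effects several-fold, which is why the point
solution is the default study condition.  Under it the deterministic
4-pulse 100 Hz train at the −10 mV recording potential transfers 1.30 pC
of charge at p = 0.42 and 1.34 pC at p = 0.67 (measured over the
stimulation period), with the α6 component carrying the larger share.

## Granule cell

Single compartment, C_m = 3 pF.  Channels: fast transient Na (m³h, with
instantaneous activation), persistent Na (0.22 nS, Boltzmann activation
at −52 mV — it sustains firing tails after brief excitation),
delayed-rectifier K (n⁴), A-type K (a³b, delaying spike onset),
high-voltage-activated Ca (s², the recorded VDCC current) and leak
(0.55 nS at −71 mV).  The cell rests near −70 mV, has ≈1.5 GΩ input
resistance, a rheobase of ~8 pA and a monotone f–I curve with no
spontaneous firing — the hallmark granule-cell phenotype.  Gates advance
by Rush–Larsen, the potential by exponential Euler; dt = 0.025 ms
(halving dt moves spike times by < 0.35 ms on the burst protocol).

Channel densities are not transcriptions of a published listing; they
were calibrated once against the package's experimental anchors: the
unitary EPSC scale (≈ −26 pA per mossy fiber), the measured burst
disinhibition at the five matched fiber configurations (spike number
+69 %, time window +113 %, first-spike latency ≈ unchanged; the model
reproduces these with a regression slope ≈ 0.95–1.05 against the
measured changes) and the requirement of multi-spike responses to single
pulses.  Excitatory synapses use two-state transmitter-driven AMPA
(730 pS/synapse, fast) and NMDA (650 pS, τ ≈ 67 ms, standard Mg-block
factor) conductances reversing at 0 mV, driven through the same
release/diffusion machinery with glutamate parameters equal to the GABA
ones (the two transmitters share the diffusion space and have nearly the
same diffusion coefficient).

Tonic inhibition is a fixed 391 pS chloride conductance — the Ohmic match
to the measured 21.5 pA tonic current at the −10 mV holding potential —
independent of the number of active synapses.

## Protocols and metrics

Burst: 4 excitatory pulses at 100 Hz starting at t = 50 ms of a 300 ms
trial; inhibition follows the same train delayed 5 ms (feed-forward
delay).  Phase protocol: one pulse each to excitation and inhibition with
lag θ ∈ [−100, +100] ms (positive = inhibition later).  Per condition,
seeded trials give: sn (mean spike count, zero-spike trials included),
ttfs (mean first-spike latency from the first excitatory stimulus), tw
(mean last-spike time minus first stimulus), fssd (SD of per-trial ttfs)
— zero-spike trials are excluded from the timing metrics and their count
reported — plus mean VDCC and NMDA currents over a 130 ms window from the
first stimulus.  Timing metrics use per-trial spikes (matching fssd's
construction), not the pooled PSTH.  Release randomness depends only on
(seed, circuit size, stimulus count), so paired conditions (switch-offs,
tonic variation) run on common random numbers and their differences are
free of release-sampling noise.

Receptor switch-offs (α1-OFF, α6-OFF, phasic-OFF, tonic-OFF, all-OFF) set
the corresponding conductances to zero, leaving everything else
untouched.

## Analysis

E/I maps index cells by `S_E = MF + Pe`, `S_I = GoC + Pi` with 9-level
probability grids (0.1…0.9); the full control space has
4×9×5×9 = 1620 cells.  Lorentzian fits of phase-lag curves use bounded
least squares with multi-start over θ_max (ω ∈ (0, 400] ms,
θ_max ∈ [−100, 100] ms); non-convergence is flagged, never silent.  The
coding fraction discretizes per-trial metrics (sn as integers; tw/ttfs in
1 ms bins; a dedicated no-spike symbol), computes plug-in mutual
information against the equiprobable configuration identity, subtracts
the Panzeri–Treves bias term and normalizes by `H(S) = log₂(n_configs)`.

## Fitting

Bounded least squares (trust-region reflective) on time-domain residuals,
multi-start from log-uniform draws over the bounds, seeds logged.
Single-eIPSC fits free (g_max_α1, g_max_α6, A, r) with h and D_eff fixed;
train fits free (τ_REC, τ_FAC, p); control/CGP pairs share all parameters
except p.  Full-trace residuals are used (no per-pulse weighting).
Fitting simulations run at dt = 0.1 ms, which keeps an objective
evaluation under ~50 ms without biasing the recovered parameters
(noiseless self-recovery is within 2 %).

## Problem sizes

Simulation-heavy checks run at reduced scale, chosen as the smallest
sizes at which the paired-comparison estimators are stable: burst
properties use 12–20 sampled configurations × 80–100 trials; the
phase-lag analysis uses 9 lags × two configurations × 40 trials with
difference curves averaged over configurations (as in the source
analysis, which averages over the response space); tonic-sensitivity uses
the five experimentally matched configurations × 3 conductance levels ×
100 trials; coding-fraction direction checks use a 16-cell reduced grid ×
30 trials.  The full study scale (1620 configurations × 500 trials) is
reachable through `sweep_ei_space`'s resumable checkpointing but is a
multi-hour computation.

## What the synthetic fixtures show — and what they do not

Fixture traces are generated by the same forward model that the fitters
invert, plus additive Gaussian noise; parameter-recovery tests therefore
establish identifiability and optimizer correctness, not robustness to
model mismatch (real recordings carry series-resistance filtering,
baseline drift and quantal variability that the fixtures omit).  Raster
fixtures with prescribed count/latency statistics validate the metric and
information estimators independently of the biophysics.

## Known limitations

- The granule cell is a reduced channel set: no resurgent Na, Ca-dependent
  K, inward rectifier or slow K, and no intracellular Ca pool; the
  electrode/series-resistance stage is not modeled.  Its first spike
  follows the EPSP onset within ~1.5–3 ms, faster than the full published
  cell.  Two documented consequences: the phase-lag resonance of the
  α1-OFF difference curve sits at slightly negative lag (≈ −1.5 ms)
  instead of the reported ≈ +10 ms (an IPSC arriving after excitation
  cannot precede a first spike that early), and inhibition carries little
  first-spike-timing information, so the coding fraction of ttfs does not
  increase under receptor switch-off at desk scale.  The α6 signatures —
  negative-lag, broad (±50 ms-class) tuning, dominance of inhibitory
  charge and of burst-metric control — reproduce robustly.
- Spillover uses one effective distance for all site pairs; no uptake,
  transporters or glial geometry.
- Metabotropic (GABA-B/mGluR) signaling is excluded by design.
- AMPA/NMDA kinetics are two-state reductions, not the multi-state
  schemes of the source excitatory model.
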