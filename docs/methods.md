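# Model and methods

This document describes the model equations, the provenance of the shipped
parameter values, the numerical methods, and the known limitations of the
calibrated model.  Weights are reported relative to baseline 1.0 (100%).

## Model overview

A single isopotential MSN compartment receives one cortical input.  A
presynaptic spike releases a glutamate transient (amplitude `G_max`,
exponential decay `tau_G`); a postsynaptic "spike" is a 30-ms
depolarizing current step plus a back-propagating action potential
modeled as a delayed decaying action current.  The spike timing
`dt_STDP = t_post + delta - t_pre` is negative for post-pre pairings.

### Membrane and calcium sources

- AMPAR and NMDAR follow two-state (closed/open) kinetics driven by
  glutamate; the NMDAR current carries the voltage-dependent magnesium
  block (Boltzmann form in V).
- Cav1.3-type VSCCs use Hodgkin–Huxley `m·h` gating.
- TRPV1 is a voltage-gated channel whose activation curve is shifted by
  AEA (a partial endovanilloid agonist).
- Cytosolic calcium collects NMDAR, VSCC and TRPV1 influx, exchanges with
  the ER through an IP3R channel (Li–Rinzel `m_inf³ h³` gating with a slow
  calcium-inactivation gate), a Hill-type SERCA pump, and a passive leak,
  and is cleared to baseline with time constant `tau_Cab`.  Fast
  endogenous buffering appears as the rapid-buffer factor
  `T(x) = 1 + B_T·K_dB/(K_dB + x)²` scaling both compartments;
  `rho_ER = 0.185` is the ER-to-cytosol volume ratio.

### IP3 and the coincidence detector

IP3 is produced by mGluR-activated PLCβ and calcium-activated PLCδ and
degraded by IP-5P and CaMKII-dependent IP3K.  PLCβ requires *both*
glutamate (Hill exponent `n_G`) and calcium as a cofactor (Hill exponent
`n_pi = 4`, `K_pi = 0.52 µM`): this conjunction makes PLCβ the timing
detector of the presynaptic pathway.  Pre-post pairings, in which the bAP
calcium rise overlaps the glutamate transient, produce far more IP3 (and
DAG) than either input alone, and the IP3R then amplifies the difference
through calcium-induced calcium release.

### Endocannabinoids and CB1R

DAG, co-produced with IP3, is converted to 2-AG by DAGLα, whose
calcium-activated fraction `phi` follows
`dphi/dt = r_k C^4 (1-phi) - r_p phi`.  AEA follows a reduced NAPE
pathway, produced proportionally to calcium and degraded by FAAH
(Michaelis–Menten).  The effective CB1R agonist is
`eCB = 2-AG + 0.10·AEA`.  CB1R is a closed three-state scheme — open
`x`, desensitized `d`, inactivated `i = 1 - x - d` — with agonist-driven
opening and slow recovery from desensitization; cumulative
desensitization across pairings shapes the decay of the per-pairing
response envelope.

### Plasticity rules

The presynaptic drive is `y_CB1R = k_CB1R·x + D_1`.  The target function
Ω(y) is 1 below `theta_LTD_start`, `1 - A_LTD` in the LTD band
(`theta_LTD_start < y < theta_LTD_stop`), 1 in the dead zone, and
`1 + A_LTP` above `theta_LTP_start`.  `W_pre` relaxes toward Ω with the
drive-dependent time constant `tau(y) = P_1/(P_2^P_3 + y^P_3) + P_4`
(fast above the band, effectively frozen near rest) and is clipped at
3.0 by derivative truncation.  A smooth variant replaces the sharp
branches by products of logistic sigmoids with steepness `k_S`
(`use_smooth_omega = 1`); at `k_S = 2` the resulting maps agree in sign
with the sharp rule everywhere the effect exceeds ±10%.

The postsynaptic side is a bistable CaMKII switch.  The six-subunit
holoenzyme ring is tracked by its 14 rotation classes; subunits
autophosphorylate by initiation (two adjacent calmodulin-bound subunits)
or directed propagation (phosphorylated neighbor plus bound calmodulin)
and are dephosphorylated by PP1.  PP1 is controlled by phosphorylated
inhibitor-1, whose balance is set by calcium-driven PKA and calcineurin.
At basal calcium the subsystem has a down state (no phosphorylation) and
an up state near saturation (`S_up ≈ 32.5 µM` of 33.3 possible).
`W_post = 1 + 3.5·CaMKII_act/CaMKII_act_max`, so the ceiling is 450% of
baseline.  `W_total = W_pre·W_post`.

## Parameter provenance

No complete published value set was available to this implementation, so
the shipped defaults combine:

1. **Printed/structural constants** — protocol geometry (30-ms step, 1 Hz
   pairings), threshold ordering, the 0.10 AEA agonism factor, the 450%
   `W_post` ceiling and 3.0 `W_pre` ceiling, and the sensitivity design
   (uniform `[0.1, 1.9]·p_ref`, variance `0.27·p_ref²`).
2. **Literature-standard kinetics** for each subsystem: two-state
   receptor schemes and magnesium block, Li–Rinzel IP3R constants,
   Hill-type SERCA, rapid-buffer approximation, sequential calmodulin
   binding, and the ring-CaMKII/PP1/I1 switch architecture.
3. **Calibration** of the remaining free constants against the model's
   published qualitative outcomes: the ordering and approximate location
   of the eCB-LTP, gap, NMDAR-LTP and LTD domains in the (Δt, N) plane,
   the biphasic per-pairing envelopes, progressive ER store depletion,
   rest bistability of CaMKII, the knockout dissociations, and the
   frequency dependence.  Calibration targeted these qualitative
   outcomes, not the test assertions.

With the shipped defaults (Δt = −15 ms, 1 Hz unless noted): eCB-tLTP for
N ≈ 3–15 (peak `W_total` 1.47 at N = 10), a plasticity gap
(0.98–1.08) for N ≈ 20–40, `W_total` crossing 1.1 near N = 45 and
reaching 1.30 at N = 100; pre-post tLTD 0.67–0.92 with onset near
N ≈ 12–15; NMDAR knockout preserves only the low-N LTP; CB1R knockout
removes all presynaptic change; 100 presynaptic-only stimulations leave
the weight at 1.00; at N = 10 pre-post pairings become potentiating at
3 Hz.

## Numerics

- The full model is a flat 32-state ODE system (membrane 5, calcium/IP3 4,
  eCB 6, CaMKII ring 14 + PP1 + I1P, `W_pre`), compiled with numba when
  available (bit-identical pure-Python fallback).
- Integration uses LSODA with `rtol = atol = 1e-7`; the integrator is
  restarted at every stimulus discontinuity (glutamate onset, step edges,
  bAP onset) so no event is smoothed over.
- Initial conditions come from a cached steady-state solve (long
  unstimulated relaxation, then Newton polish) with `W_pre` pinned at its
  baseline; runs start from the model's own rest.  Enzyme-inhibition
  scenarios start from the *control* rest state because the inhibitor is
  applied acutely — and a complete MAGL block removes the only 2-AG sink,
  so the fully inhibited model has no finite rest state of its own.
- Weights are read after a 300-s post-protocol settle; runs are flagged if
  `W_pre` or CaMKII activation still drift at the horizon.
- Everything is deterministic; repeated runs are bitwise identical.  The
  only randomness in the package is the seeded Monte-Carlo sampling of the
  sensitivity module.
- Plasticity maps blur `W_pre` and `W_post` separately along the Δt axis
  with a normalized 3-ms-s.d. Gaussian (emulating experimental spike-time
  jitter) before recomposing `W_total`.

## Sensitivity analysis

`sensitivity.run_sensitivity` samples each free parameter uniformly on
`[0.1, 1.9]·p_ref` (variance `0.27·p_ref²`), computes an RMS weight-map
distance to the reference parameter set over a small (Δt, N) grid, and
fits ordinary least squares of the distance on the parameters;
standardized regression coefficients `SRC_k = b_k·sqrt(Var(p_k)/Var(D))`
rank the parameters.  Degenerate designs (zero-variance distance) are
reported as all-zero with a warning; rank-deficient designs raise.

## Limitations

The calibrated model reproduces the domain structure and dissociations
listed above but deviates from the published behavior in four documented
ways.  Each is encoded in `tests/test_acceptance.py` at its target value
and marked `xfail`:

1. **Graded, not thresholded, CaMKII recruitment.**  The subsystem is
   genuinely bistable at rest, but 100 post-pre pairings raise the
   activated fraction only to ~0.13 — the down→up transition that should
   occur at 50–60 pairings never fires.  The calcium envelope peaks at
   pairings 3–6 (CICR ignition) and front-loads calmodulin activation, so
   any transducer fast enough to commit by pairing 60 already commits by
   pairing ~10; the ring topology additionally bounds the phosphorylation
   autocatalysis.  The configuration shipped favors clean rejection of
   pre-post pairings (activated fraction ≤ 0.004) over a sharp pairing
   threshold; `W_total` still crosses +10% near N = 45–55 because `W_pre`
   recovers while `W_post` grows.  A corollary is that `W_total` keeps
   creeping beyond N = 100 (+0.06 at N = 120) instead of saturating.
2. **Compressed eCB-LTP window.**  Per-pairing CB1R peaks exceed the LTP
   threshold for pairings ~2–12 (target ~5–30) and the eCB-LTP domain
   closes near N ≈ 15–18 (target ≈ 40), for the same early-ignition
   reason.  Stretching the envelope (slower CB1R desensitization or
   faster recovery) widens the window but erases the plasticity gap and
   the second LTP domain, which were prioritized.
3. **4-Hz NMDAR component appears too early.**  At 4 Hz, calcium
   summation recruits the postsynaptic pathway from the first pairings,
   so the control-vs-NMDAR-knockout difference is large already at N = 5
   (target: only for N > 12).
4. **MAGL-block scenario directions.**  Under a full MAGL block the
   three-state CB1R settles at a sustained open fraction
   `x ≈ ε/(γ+ε) ≈ 0.026`, i.e. the drive plateaus *below* the LTD band;
   after the amplified 2-AG transient the drive descends slowly through
   the band and `W_pre` then relaxes toward baseline, erasing the
   predicted extra LTP (5-pairing scenario: 115% vs control 143%;
   100-pre-only scenario: 98% vs 100%; the 50-pairing scenario moves in
   the right direction but its control is already weak LTP because the
   calibrated gap sits at 20–40 pairings).  Raising the recovery rate so
   the plateau lands above the LTP threshold flips all three scenarios
   correctly but destroys the gap and the second LTP domain, so the map
   structure was kept.
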