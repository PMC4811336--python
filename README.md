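# striatal-stdp

A mechanistic simulator of spike-timing-dependent plasticity (STDP) at the
corticostriatal synapse onto medium-sized spiny neurons (MSNs).  The model
couples two biochemical pathways that read the same pre/post spike timing
and jointly set the synaptic weight:

- **Postsynaptic pathway** — NMDAR calcium activates calmodulin, which
  drives a bistable CaMKII ring switch (six-subunit holoenzyme, PP1/
  inhibitor-1/PKA/calcineurin control).  The phosphorylated-CaMKII
  concentration sets the postsynaptic weight `W_post` (up to 450% of
  baseline at full phosphorylation).
- **Presynaptic (endocannabinoid) pathway** — mGluR/PLCβ acts as a
  coincidence detector of presynaptic glutamate and postsynaptic calcium,
  producing IP3 (which gates calcium-induced calcium release from the ER)
  and DAG.  Calcium-activated DAGLα converts DAG to 2-AG; the NAPE pathway
  produces anandamide (AEA, also a TRPV1 agonist).  Both act retrogradely
  on presynaptic CB1 receptors (a three-state open/desensitized/inactivated
  scheme).  CB1R activation `y_CB1R` moves the presynaptic weight `W_pre`
  through a three-threshold rule: moderate activation depresses (LTD band),
  strong activation potentiates (ceiling 3.0).

The reported weight is the product `W_total = W_pre · W_post` (1.0 = 100% =
no change).  With the shipped parameters the model reproduces the
hallmarks of corticostriatal STDP: endocannabinoid-mediated tLTP for a
small number of post-pre pairings, a no-plasticity gap at intermediate
pairing numbers, NMDAR-mediated LTP for many post-pre pairings,
endocannabinoid tLTD for pre-post pairings, and the frequency dependence
of both.  Known deviations are documented in
[docs/methods.md](docs/methods.md#limitations).

## Quick start

```python
from striatal_stdp import (
    load_default_parameters, build_stdp_protocol, run_protocol,
)

params = load_default_parameters()

# 10 post-pre pairings (dt_STDP = -15 ms) at 1 Hz
proto = build_stdp_protocol(n_pairings=10, dt_stdp_ms=-15.0,
                            frequency=1.0, params=params)
res = run_protocol(params, proto)
print(res.w_pre, res.w_post, res.w_total)
# 1.206 1.222 1.474   -> 147% of baseline: eCB-mediated tLTP
```

The same protocol with 100 pairings gives `W_total ≈ 1.30` (NMDAR-driven
LTP), while 100 *pre-post* pairings (`dt_stdp_ms=+15.0`) give
`W_total ≈ 0.78` (eCB-tLTD), and 100 presynaptic-only stimulations leave
the weight unchanged.

Knockouts and enzyme inhibitions are parameter variants:

```python
from striatal_stdp import ModelVariant, apply_variant

ko = apply_variant(params, ModelVariant(nmdar_knockout=True))
run_protocol(ko, proto).w_total        # ≈ 1.20: eCB-tLTP survives NMDAR block
proto100 = build_stdp_protocol(100, -15.0, 1.0, ko)
run_protocol(ko, proto100).w_total     # ≈ 0.91: the high-N LTP does not
```

## Command line

```sh
striatal-stdp run --dt -15 --n 10 --out results/run10
striatal-stdp map --dt-min -40 --dt-max 40 --dt-step 5 --n-list 5,10,30,50,100 --out results/map
striatal-stdp freqmap --out results/freqmap
striatal-stdp scenarios --out results/scenarios
striatal-stdp sensitivity --n-samples 200 --seed 1 --out results/src
striatal-stdp validate-params my_params.yaml
```

Every output directory receives a `manifest.json` (command, options,
parameter digest) and a `params.json` snapshot for provenance.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains unit and property-based tests per module plus
`tests/test_acceptance.py`, which encodes the quantitative acceptance
criteria.  Criteria the calibrated model does not meet are kept at their
stated numeric targets and marked `xfail` with the measured behavior in
the reason string (see [docs/methods.md](docs/methods.md#limitations)).

## Package layout

| module | contents |
| --- | --- |
| `parameters` | parameter schema, validation, YAML I/O, model variants |
| `stimuli` | STDP/pre-only/post-only protocols, glutamate and action-current forcing |
| `membrane` | membrane potential, AMPAR/NMDAR kinetics, Mg block, VSCC, TRPV1 |
| `calcium` | cytosolic/ER calcium, IP3R (Li–Rinzel), SERCA, PLCβ/PLCδ IP3 dynamics |
| `camkii` | calmodulin binding, six-subunit ring switch, PP1/I1/PKA/CaN |
| `ecb` | DAGLα, 2-AG, AEA, three-state CB1R |
| `plasticity` | Ω threshold rule, τ(x), W_pre dynamics, W_post readout |
| `engine` | flat 32-state ODE system, LSODA integration, steady-state init |
| `experiments` | (Δt, N) and (Δt, f) plasticity maps, jitter blur, domain extraction, knockout/inhibition scenarios |
| `sensitivity` | Monte-Carlo sampling and standardized regression coefficients |
| `cli` | `striatal-stdp` command-line tool |
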