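# spikelang

A modeling language and processing toolchain for hybrid neuron and synapse
models, with a reference time-driven network simulator.

Computational neuroscientists describe spiking cells and plastic synapses
as *hybrid dynamical systems*: continuous dynamics d**x**/dt = f(t, **x**)
punctuated by instantaneous events -- spike trains s(t) = Σ_k δ(t − t_k)
that jump state variables or are filtered through response kernels.
`spikelang` lets you write such models in a compact, Python-like plain-text
syntax with physical units, and then does the rest mechanically:

* **Frontend** -- tokenizer, parser, and pretty-printer (every transformed
  model prints back to valid source).
* **Static checking** -- scoped symbol tables and a battery of context
  conditions, including full dimensional analysis: `V_m + g_L` (mV + nS)
  is rejected, `E_L + 0.5 V` silently gains the 10³ prefix factor.
* **Lowering** -- `convolve(K, port)` becomes auxiliary states with
  per-spike jumps (an alpha kernel (e/τ)·t·e^(−t/τ) yields two states with
  jump e/τ on the auxiliary); higher-order equations become companion
  chains.
* **Solver planning** -- the maximal linear constant-coefficient subsystem
  is integrated *exactly* with propagator matrices P = expm(A·h); the
  nonlinear remainder uses classical RK4.
* **Co-generation** -- synaptic state that depends only on postsynaptic
  spiking (e.g. the postsynaptic STDP trace and its time constant) is
  moved into the paired neuron model automatically, with the synapse's
  references rewritten to accessor calls, eliminating per-synapse
  redundancy without changing observable behavior.
* **Simulation** -- a vectorized, deterministic, time-driven kernel with
  ring-buffered delayed spike delivery, lazy event-driven synapse updates,
  devices (step currents, Poisson drive, spike trains), and plain-text
  recording export.  Optionally, models can be emitted as standalone
  Python source against a documented runtime API; emitted and interpreted
  paths are bitwise identical.

The packaged model zoo contains an adaptive exponential integrate-and-fire
neuron (AdEx: membrane potential with exponential spike initiation,
adaptation current, alpha-shaped synaptic currents, threshold/reset rule),
a pair-based STDP synapse (Δw = λ_p·e^(−Δt/τ_p) for causal pairs,
−λ_d·e^(−|Δt|/τ_d) for anti-causal, via exponentially decaying traces),
and a balanced excitatory/inhibitory benchmark network with fixed
in-degrees (1000 onto E, 250 onto I) whose population statistics stay
constant as the network scales.

## A worked example

```python
import spikelang as sl
from spikelang.compiler import compile_model
from spikelang.network import Network, StepCurrent

adex = compile_model(sl.load_model_text("adex_neuron"))
print(adex.plan.analytic_states)   # exact propagator part
print(adex.plan.numeric_states)    # RK4 part

net = Network(h=0.1, seed=1)
pop = net.create(adex, 1)
net.attach_current(pop, "I_stim", StepCurrent(amplitude=800.0, start=25.0))
net.record(pop, ["V_m"])
rec = net.simulate(200.0)
print(rec.spikes(pop.name)[0])
```

prints

```
['__conv_K_syn_spikes_in', '__conv_K_syn_spikes_in__d1']
['V_m', 'I_adap']
[ 42.7  60.5  86.5 127.7 187.2]
```

The two convolution states (the alpha-kernel value and its auxiliary) are
solved exactly; membrane potential and adaptation current are stepped
numerically.  The step current switches on at 25 ms and the neuron fires
five times in 200 ms with the intervals lengthening from 17.8 ms to
59.5 ms -- spike-frequency adaptation from the current that increments by
b = 80.5 pA at each spike and decays with τ = 144 ms.

The same pipeline is scriptable from a shell:

```sh
spikelang validate mymodel.sl
spikelang generate adex.sl stdp.sl --options pairs.json --out generated/
spikelang simulate --config sim.json
spikelang benchmark --out bench/
```

where `pairs.json` names the neuron/synapse pairs and the postsynaptic
ports for co-generation:

```json
{"neuron_synapse_pairs": [{"neuron": "adex_neuron",
                           "synapse": "stdp_synapse",
                           "post_ports": ["post_spikes"]}]}
```

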