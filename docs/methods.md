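# Methods

`spikelang` implements a small modeling language for hybrid dynamical
systems -- neurons and synapses whose continuous dynamics are ordinary
differential equations and whose discrete events (spikes) jump state
variables instantaneously -- together with the processing toolchain
(parsing, static checking, lowering, solver planning) and a reference
time-driven network simulator.  This note records the model of computation,
the numerical choices, and the places where the design was genuinely open.

## The modeling formalism

A model is a hybrid system: a state vector **x** with dynamics
d**x**/dt = f(t, **x**) + g(t), where g collects event-driven input.  Spike
trains are sums of Dirac deltas s(t) = Σ_k δ(t − t_k) with implicit
dimension time⁻¹, so a quantity such as a current can multiply a spike
train and integrate to a finite per-spike contribution.  Event handling is
expressed either as a convolution of the spike train with a response
kernel inside the equations, or as an imperative event handler
(`onReceive`) that jumps state variables; the two are equivalent for
linear kernels and both are supported.  `onCondition` blocks express
threshold-type rules (emit a spike, reset, increment an adaptation
current) as conditions over the state rather than as timestep-bound code.

## Physical units

Every expression is statically typed.  A quantity type is a vector of 7
integer exponents over the SI base dimensions plus a decadic scale (mV =
volt at scale −3).  Addition, subtraction, and comparison require equal
dimensions; when only the prefixes differ, the checker records a numeric
factor of 10^Δscale on the operand, which the evaluator folds in -- so
`E_L + 0.5 V` with `E_L` in mV is computed correctly in millivolts.
Dimension mismatches (mV + nS) are errors.  Any dimensionful quantity
converts to `real` with a warning (the magnitude is taken at its own
scale); `real` converts to `integer` with a warning, truncating toward
zero.  Scales are restricted to integer powers of ten: prefixed SI units
only, no minutes, no offset units.

## Lowering and solver planning

Convolutions are lowered to auxiliary states.  A kernel of
polynomial-times-exponential form satisfies a linear constant-coefficient
ODE; the package finds the minimal annihilating ODE symbolically (by
equating coefficients over the monomial-exponential basis) and represents
the convolution as a companion chain whose per-spike jumps are the kernel
derivatives at 0⁺.  An exponential kernel yields one state with jump 1;
the alpha kernel (e/τ)·t·exp(−t/τ) yields a value state (jump 0) and an
auxiliary state (jump e/τ).  Higher-order equations are reduced to
first-order companion form.

The lowered system is then partitioned.  States whose derivatives are
affine in the state with parameter-only coefficients, with no dependence
on t or on continuous inputs, and closed under dependency (an exactly
solvable state may drive the numeric part, never the reverse) form the
*analytic* part; it is advanced by the propagator matrix P = expm(A·h),
materialized numerically per (subsystem, h) -- affine offsets are handled
through the augmented matrix, which is exact even for singular A.  The
remaining states are advanced with classical fixed-step RK4 (configurable
substeps, default 1), with the analytic values frozen at their
start-of-step values during the RK4 stages.  Conditions are checked only
after the full step h, not inside substeps; this is one of the legitimate
integration-loop choices and is the main source of small discrepancies
against simulators that check thresholds inside an adaptive inner loop.

For the adaptive exponential integrate-and-fire (AdEx) neuron this yields:
synaptic alpha-kernel states exact by propagator; membrane potential and
adaptation current by RK4 (the spike-initiation current
g_L·Δ_T·exp((V−V_th)/Δ_T) is nonlinear).  Inside that exponential the
membrane potential is clamped at V_peak so the fixed-step suprathreshold
upswing stays bounded; this standard safeguard does not affect
subthreshold dynamics.  The fixture's membrane equation subtracts the
synaptic current (its printed sign convention), so excitatory connections
carry negative weights.

## The simulation loop

Time advances on a fixed grid of resolution h (default 0.1 ms), with the
clock kept as an integer step count.  Per step at time t: (1) events
scheduled to arrive at t are delivered -- plastic synapses run their
presynaptic handlers and forward the (possibly updated) weight, arriving
weights jump convolution states or queue for neuron-side `onReceive`
handlers ordered by handler priority (larger runs earlier, absent = 0)
and source id; (2) the update block runs, integrating over [t, t+h];
(3) `onCondition` handlers are evaluated in declaration order on the
post-update state, and emitted spikes are stamped t+h; (4) spikes are
routed: scheduled on each outgoing connection at emission + delay, and on
each incoming plastic connection as a postsynaptic notification with the
same delay.  Everything is vectorized over instances (a population's
state is a dict of (n,) arrays), which is what makes the desk-scale
benchmark tractable in pure numpy.

Delays must be positive multiples of h.  Input devices: step currents
(evaluated at step start), independent Poisson spike sources per target,
and explicit spike-time trains whose arrival times round *up* to the next
grid point -- the discretization that produces the spike-count discrepancy
between a coarse grid and a fine one in the packaged demonstration.  In
the LIF demonstration model, buffered spike input is applied to the
membrane after the leak integration of the step (the delta-input
convention of exact integration).

## Plasticity and the event timeline

Synapse instances are updated lazily, only at their own events, with
state between events reconstructed analytically (the trace dynamics are
decoupled exponential decays).  All synapse bookkeeping lives on the
*emission-side* timeline: an event processed at arrival time t with
connection delay d is anchored at t − d.  Since presynaptic arrivals and
postsynaptic notifications travel with the same per-connection delay,
anchor times are monotone per synapse, and a pre/post pair with emission
times t_pre, t_post changes the weight by exactly the closed-form kernels
λ_p·exp(−(t_post−t_pre)/τ_p) and −λ_d·exp(−(t_pre−t_post)/τ_d),
independent of the delay.  With this convention the weight-change curve's
discontinuity sits at Δt = 0; conventions that pair at arrival times
instead shift the curve by the dendritic delay, and the choice is
configurable in principle but fixed here for exactness of the closed
form.  At equal timestamps the postsynaptic handler runs first (and the
packaged STDP model declares matching priorities).

## Co-generation

Synaptic state that depends only on postsynaptic spiking -- detected as a
fixed point over the variable-dependency graph, together with parameters
used exclusively by that state -- is moved into the paired neuron model:
declarations, equations, and the jump statements, which are inserted into
every spike-emitting `onCondition` block of the neuron.  Colliding names
are renamed (`<name>__for_<synapse>`), and the synapse's remaining reads
become accessor calls `__post__<name>()` resolved against the
postsynaptic instance.  The neuron maintains a grid-sampled history ring
of each moved trace over a window covering the largest incoming delay;
the accessor returns the value at the event's anchor time t_arrival − d.
Because the per-step propagator factors are exact exponentials anchored
at the last postsynaptic spike, accessor values agree with the
synapse-local reconstruction to rounding error (~1e-15 per event), far
inside the 1e-12 equivalence bound the tests enforce.  Pairing is
configured externally (`post_ports` in the code-generation options);
nothing in the language marks a port as pre- or postsynaptic.

## The benchmark network and its operating point

The benchmark wires the AdEx neuron to the STDP synapse in a sparse
random network: 80% excitatory, 20% inhibitory; every excitatory neuron
receives 1000 connections and every inhibitory neuron 250, drawn without
replacement from the joint pool (autapses allowed, multapses not), so the
in-degrees stay fixed as N scales.  Learning rates are zero: the
plasticity bookkeeping runs on every spike but weights never change.
Default desk scale: N = 5000, 6 s simulated at h = 0.1 ms with a 1 s
warm-up excluded from analysis.

Neuron parameters are the standard values for this model (C_m 281 pF,
g_L 30 nS, E_L −70.6 mV, V_th −50.4 mV, Δ_T 2 mV, τ_adap 144 ms, a 4 nS,
b 80.5 pA, V_reset −60.6 mV, τ_syn 2 ms; V_peak −40 mV as the detection
cutoff).  The free network constants -- synaptic weight magnitude w, the
inhibition ratio g, and the per-neuron Poisson drive -- were fixed once by
a grid calibration at desk scale targeting a population mean rate of
~15 spikes/s with ISI CV ~0.25, and are frozen in
`models/benchmark_params.json` (w = 14 pA, g = 5, delay 1.5 ms, drive
39.2 kHz per neuron with the same weight).

One structural property of this connectivity deserves honesty: because
both sub-populations sample the same pool with in-degrees in a fixed 4:1
ratio, the recurrent input vectors to E and I cells are exactly
proportional (a rank-1 coupling).  A linearization shows a state with
*both* sub-populations firing at 15 spikes/s is unstable unless
inhibition outweighs excitation by a factor larger than the slope ratio
allows; with the AdEx exponential onset this could not be stabilized in
any calibration we ran (stronger g, heterogeneous drive, warm-started
adaptation).  The frozen operating point is the stable configuration: the
strongly inhibited excitatory majority sits below threshold, the
low-in-degree inhibitory population fires irregularly, and the
*population* statistics -- mean rate ≈ 15 spikes/s, mean ISI CV ≈ 0.26
over neurons with at least 3 intervals -- are stationary, seed-robust,
and invariant across network sizes.  Initial conditions are
desynchronized (membrane potentials uniform between rest and threshold,
adaptation currents near their stationary mean) to avoid an onset burst.

## What the synthetic protocols do and do not show

All inputs here are synthetic: Poisson drives, deterministic spike
trains, and step currents.  They exercise the numerics (exactness of
propagators, convolution lowering, plasticity closed forms, co-generation
equivalence, determinism) under controlled conditions; they do not probe
heterogeneous real-cell parameter distributions, conductance-based
synapses, or delay distributions, and the benchmark's dynamical regime is
one operating point of one connectivity, not a survey of balanced-network
states.

## Numerical conventions

All times are in ms, potentials in mV, currents in pA, conductances in
nS, capacitances in pF; each variable is stored in its declared unit with
prefix conversions folded in at check time.  Randomness comes from one
seeded PCG64 generator per network; identical configuration and seed give
bitwise-identical recordings.  `integrate_odes()` with explicit state
arguments advances only those states (by RK4, others frozen) -- the exact
path applies to the no-argument form.  Non-finite states abort the run
naming the variable, instance, and time.  Emitted Python code (the
`generate --target emit-source` path) is written against the documented
runtime API in `spikelang.runtime` and reproduces the interpreted path
bit for bit; the tests assert this.

## Known limitations

No delay differential equations, no stiffness analysis or adaptive step
control, no gap junctions, no MPI/threading, no event-queue scheduler.
Vector-valued states parse and validate but are supported only by the
interpreted scalar path, not by code emission.  Synapse models must have
decoupled exponential-decay continuous dynamics for the lazy update
scheme (the STDP family); nonlinear synapse ODEs are rejected with a
diagnostic.
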