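model lif_toy:
    """Minimal leaky integrate-and-fire neuron whose incoming spikes jump the
membrane potential directly.

Arriving spike weights are collected into a buffer and applied to V_m at the
end of the timestep's update, after the leak integration -- the standard
convention for delta-shaped synaptic input under exact integration, where a
spike processed during the step [t, t+h) takes effect at t+h.

Used to demonstrate how forcing spike times to a coarse grid can change the
spike count: two input spikes falling inside one coarse timestep are
processed simultaneously and can cross threshold together, whereas at fine
resolution the leak between them keeps the trajectory subthreshold.
"""
    state:
        V_m mV = 0 mV
        dV_buf mV = 0 mV     # summed spike input awaiting application
    parameters:
        tau_m ms = 0.5 ms    # membrane time constant
        V_theta mV = 1.0 mV  # firing threshold
        V_reset mV = 0 mV    # reset potential
    equations:
        V_m' = -V_m / tau_m
    input:
        spikes_in <- spike
    output:
        spike
    update:
        integrate_odes()
        V_m += dV_buf
        dV_buf = 0 mV
    onReceive(spikes_in):
        dV_buf += spikes_in * mV  # event weight interpreted in mV
    onCondition(V_m >= V_theta):
        emit_spike()
        V_m = V_reset
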