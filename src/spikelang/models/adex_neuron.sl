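model adex_neuron:
    """Adaptive exponential integrate-and-fire neuron with alpha-shaped
postsynaptic currents.

Subthreshold dynamics couple the membrane potential V_m to an adaptation
current I_adap.  An exponential spike-initiation current I_spike drives the
upswing once V_m approaches the soft threshold V_th; when V_m reaches the
detection cutoff V_peak, a spike is emitted, V_m is reset and the adaptation
current is incremented by b.  Synaptic input arrives as spike events whose
weights (in pA) are filtered by an alpha-shaped (rise-and-decay) kernel; a
continuous port adds an external stimulus current.

Inside the spike-initiation current the membrane potential is clamped at
V_peak so that the exponential stays bounded during the suprathreshold
upswing between grid points; this is the standard safeguard for fixed-step
integration of this model and does not affect subthreshold dynamics.
"""
    state:
        V_m mV = E_L        # membrane potential
        I_adap pA = 0 pA    # spike-triggered adaptation current
    parameters:
        C_m pF = 281 pF        # membrane capacitance
        g_L nS = 30 nS         # leak conductance
        E_L mV = -70.6 mV      # leak reversal (resting) potential
        tau_adap ms = 144 ms   # adaptation time constant
        a nS = 4 nS            # subthreshold adaptation conductance
        b pA = 80.5 pA         # spike-triggered adaptation increment
        Delta_T mV = 2 mV      # spike-initiation slope factor
        V_th mV = -50.4 mV     # exponential-onset threshold
        V_peak mV = -40 mV     # spike-detection cutoff
        V_reset mV = -60.6 mV  # post-spike reset potential
        tau_syn ms = 2 ms      # synaptic-current time constant
    equations:
        kernel K_syn = (e / tau_syn) * t * exp(-t / tau_syn)
        inline I_syn pA = convolve(K_syn, spikes_in) * pA
        inline I_spike pA = g_L * Delta_T * exp((min(V_m, V_peak) - V_th) / Delta_T)
        V_m' = (-g_L * (V_m - E_L) + I_spike - I_syn - I_adap + I_stim) / C_m
        I_adap' = (a * (V_m - E_L) - I_adap) / tau_adap
    input:
        spikes_in <- spike
        I_stim pA <- continuous
    output:
        spike
    update:
        integrate_odes()
    onCondition(V_m >= V_peak):
        emit_spike()
        V_m = V_reset
        I_adap += b
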