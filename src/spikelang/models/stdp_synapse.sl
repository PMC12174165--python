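model stdp_synapse:
    """Spike-timing dependent plasticity synapse with exponential trace
variables.

A pre/post spike pair at times t_pre and t_post changes the weight w by

    dw = lambda_p * exp(-(t_post - t_pre) / tau_p)     if t_post > t_pre
       - lambda_d * exp(-(t_pre - t_post) / tau_d)     if t_pre > t_post

implemented with two traces that are incremented by 1 on each own-side spike
and decay back to zero exponentially: tr_pre drives potentiation when a
postsynaptic spike arrives; tr_post drives depression when a presynaptic
spike arrives.  When pre- and postsynaptic events coincide on the grid the
postsynaptic handler runs first (higher priority).

The presynaptic spike is forwarded to the target with the updated weight.
"""
    state:
        w real = 1.0        # synaptic weight (pA as seen by the target port)
        tr_pre real = 0.0   # presynaptic trace
        tr_post real = 0.0  # postsynaptic trace
    parameters:
        lambda_p real = 0.01  # potentiation rate
        lambda_d real = 0.01  # depression rate
        tau_p ms = 20 ms      # potentiation trace time constant
        tau_d ms = 20 ms      # depression trace time constant
    equations:
        tr_pre' = -tr_pre / tau_p
        tr_post' = -tr_post / tau_d
    input:
        pre_spikes <- spike
        post_spikes <- spike
    output:
        spike
    update:
        integrate_odes()
    onReceive(post_spikes, priority=2):
        w += lambda_p * tr_pre
        tr_post += 1.0
    onReceive(pre_spikes, priority=1):
        w -= lambda_d * tr_post
        tr_pre += 1.0
        deliver_spike(w)
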