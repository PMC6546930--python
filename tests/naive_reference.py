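"""Independent scalar-loop reference simulator.

Written before the vectorized implementation was finalized and kept free of
any liquidens simulation code: plain Python floats, per-neuron per-step
loops, the same documented step order (deliver -> decay -> integrate ->
threshold).  Used only as an oracle in equivalence tests.
"""

import math


def naive_run(topology, input_events, T, dt, p):
    """Simulate a liquid step by step with scalar loops.

    ``input_events`` is a list of (line_index, time_ms); ``p`` is a
    NeuronParams-like object.  Returns a list of (neuron_index, time_ms).
    """
    n_e, n_i = topology.n_e, topology.n_i
    n = n_e + n_i
    n_steps = round(T / dt)

    def pop(j):
        return "e" if j < n_e else "i"

    tau_mem = {"e": p.tau_mem_e, "i": p.tau_mem_i}
    e_rest = {"e": p.e_rest_e, "i": p.e_rest_i}
    thresh = {"e": p.thresh_e, "i": p.thresh_i}
    v_reset = {"e": p.v_reset_e, "i": p.v_reset_i}
    t_refrac = {"e": p.t_refrac_e, "i": p.t_refrac_i}

    # weight lookup: w[post][pre] for the full population, inputs separate
    w_e = [[0.0] * n_e for _ in range(n)]  # from excitatory pre
    w_i = [[0.0] * n_i for _ in range(n)]  # from inhibitory pre
    w_in = [[0.0] * topology.n_inputs for _ in range(n)]
    for post in range(n_e):
        for pre in range(topology.n_inputs):
            w_in[post][pre] = float(topology.weights["in_e"][post][pre])
    for post in range(n_e):
        for pre in range(n_e):
            w_e[post][pre] = float(topology.weights["e_e"][post][pre])
        for pre in range(n_i):
            w_i[post][pre] = float(topology.weights["i_e"][post][pre])
    for post in range(n_i):
        for pre in range(n_e):
            w_e[n_e + post][pre] = float(topology.weights["e_i"][post][pre])
        for pre in range(n_i):
            w_i[n_e + post][pre] = float(topology.weights["i_i"][post][pre])

    v = [e_rest[pop(j)] for j in range(n)]
    g_e = [0.0] * n
    g_i = [0.0] * n
    refr_until = [0.0] * n

    fired_prev = []
    out = []
    for k in range(n_steps):
        t_start = k * dt
        # 1. deliver input spikes binned into this step, then recurrent
        for line, t_sp in input_events:
            step = min(int(t_sp // dt), n_steps - 1)
            if step == k:
                for j in range(n):
                    g_e[j] += w_in[j][line]
        for f in fired_prev:
            if f < n_e:
                for j in range(n):
                    g_e[j] += w_e[j][f]
            else:
                for j in range(n):
                    g_i[j] += w_i[j][f - n_e]
        # 2. decay conductances
        for j in range(n):
            g_e[j] *= math.exp(-dt / p.tau_ge)
            g_i[j] *= math.exp(-dt / p.tau_gi)
        # 3. integrate (exact exponential, conductances frozen)
        for j in range(n):
            q = pop(j)
            if t_start < refr_until[j] - 1e-9:
                v[j] = v_reset[q]
                continue
            b = 1.0 + g_e[j] + g_i[j]
            v_inf = (e_rest[q] + g_e[j] * p.e_exc + g_i[j] * p.e_inh) / b
            v[j] = v_inf + (v[j] - v_inf) * math.exp(-b * dt / tau_mem[q])
        # 4. threshold and reset
        t_end = (k + 1) * dt
        fired_prev = []
        for j in range(n):
            q = pop(j)
            if v[j] >= thresh[q]:
                v[j] = v_reset[q]
                refr_until[j] = t_end + t_refrac[q]
                fired_prev.append(j)
                out.append((j, t_end))
    return out
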