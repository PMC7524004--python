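"""Independent brute-force reference integrator used as a test oracle.

Deliberately written with plain Python loops and lists — no vectorization,
no shared code with the package integrator — so agreement is evidence of
correctness rather than of shared bugs.
"""
import math


def reference_trajectory(C, tau_steps, x0, y0, n_steps, dt=0.5,
                         a=0.8, b=0.008, gamma=0.0033, drives=None):
    """Integrate the delay-coupled network naively.

    C is a nested list (row = target); history before t=0 is the constant
    initial state.  ``drives`` maps step index -> list of per-node additive
    terms.  Returns the list of x-state lists at steps 0..n_steps-1.
    """
    n = len(C)
    xs = [list(x0)]
    x = list(x0)
    y = list(y0)
    for t in range(n_steps - 1):
        # delayed state: step t - tau_steps, constant extension before 0
        td = t - tau_steps
        x_del = xs[td] if td >= 0 else list(x0)
        new_x = []
        new_y = []
        for i in range(n):
            coupling = 0.0
            for j in range(n):
                if i == j:
                    continue
                h = 0.5 * (1.0 + math.tanh(x_del[j]))
                coupling += C[i][j] * h
            drive = 0.0
            if drives is not None and t in drives:
                drive = drives[t][i]
            dx = x[i] * (a - x[i]) * (x[i] - 1.0) - y[i] + coupling + drive
            dy = b * x[i] - gamma * y[i]
            new_x.append(x[i] + dt * dx)
            new_y.append(y[i] + dt * dy)
        x, y = new_x, new_y
        xs.append(list(x))
    return xs
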