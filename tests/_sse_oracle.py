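"""Independent reference implementation of the SSE pruning likelihood.

Deliberately separate from the package's implementation: per-branch
integration of the joint (E, D) system with scipy's generic ODE solver and
a recursive postorder traversal.  Slow but straightforward; used to verify
the package's epoch/fundamental-matrix computation on small trees.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from edgsim.sse.likelihood import equilibrium_frequencies


def reference_sse_loglik(td, tip_states, spec, params,
                         condition_on_survival=True) -> float:
    lam, mu, Q = spec.build_rates(params)
    k = spec.n_states
    n = td.n_tips
    birth = np.zeros(2 * n - 1)
    birth[n:] = td.merge_ages
    states = [tip_states[label] for label in td.tip_labels]
    D = {}
    E_at = {}
    logsc = {}
    for i, s in enumerate(states):
        D[i] = spec.tip_state_vector(s)
        E_at[i] = np.zeros(k)
        logsc[i] = 0.0

    def rhs(_t, y):
        E, Dv = y[:k], y[k:]
        dE = mu - (lam + mu) * E + lam * E * E + Q @ E
        dD = -(lam + mu) * Dv + 2 * lam * E * Dv + Q @ Dv
        return np.concatenate([dE, dD])

    for j in range(n - 1):
        age = float(td.merge_ages[j])
        parent = n + j
        acc = None
        ls = 0.0
        E_par = None
        for c in td.merge_children[j]:
            y0 = np.concatenate([E_at[c], D[c]])
            if age > float(birth[c]):
                sol = solve_ivp(rhs, (float(birth[c]), age), y0,
                                rtol=1e-11, atol=1e-13)
                y1 = sol.y[:, -1]
            else:
                y1 = y0
            E_par = y1[:k]
            acc = y1[k:] if acc is None else acc * y1[k:]
            ls += logsc[c]
        Dp = lam * acc
        s = np.abs(Dp).max()
        if s <= 0:
            return -np.inf
        D[parent] = Dp / s
        logsc[parent] = ls + np.log(s)
        E_at[parent] = E_par

    pi = equilibrium_frequencies(Q)
    lik = float(pi @ D[2 * n - 2])
    if condition_on_survival:
        denom = float((pi * lam * (1.0 - E_at[2 * n - 2]) ** 2).sum())
        lik /= denom
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logsc[2 * n - 2])
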