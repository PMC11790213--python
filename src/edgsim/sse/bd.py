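"""Closed-form constant-rate birth-death and Mk likelihoods.

These are reference quantities: when speciation, extinction and transition
rates are shared across states, the state-dependent likelihood factorizes
into a constant-rate birth-death term (closed form below, same root
conditioning conventions as :func:`edgsim.sse.likelihood.sse_loglik`) and a
plain Markov (Mk) likelihood of the tip states.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

from .likelihood import TreeData, as_tree_data, _states_to_array, \
    _resolve_root_prior

__all__ = ["bd_loglik", "mk_loglik"]


def _log_psi(t: float, lam: float, mu: float) -> float:
    """log of the branch propagator of the birth-death D equation."""
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, mu, 1.0):
        return -2.0 * math.log1p(lam * t)
    return r * t + 2.0 * (math.log(abs(r)) - math.log(abs(lam * math.exp(r * t) - mu)))


def _extinction_prob(t: float, lam: float, mu: float) -> float:
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, mu, 1.0):
        return lam * t / (1.0 + lam * t)
    ert = math.exp(r * t)
    return mu * (ert - 1.0) / (lam * ert - mu)


def bd_loglik(tree, lam: float, mu: float,
              condition_on_survival: bool = True) -> float:
    """Constant-rate birth-death log-likelihood of an ultrametric tree.

    Computed from the closed-form solution of the pruning equations (no
    numerical integration): every internal node contributes ``log lam`` and
    every branch the log-ratio of the propagator at its two endpoints;
    conditioning divides by ``lam * (1 - E(root_age))**2``.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("lam must be positive and mu nonnegative")
    td = as_tree_data(tree)
    n = td.n_tips
    birth = np.zeros(2 * n - 1)
    birth[n:] = td.merge_ages
    ll = (n - 1) * math.log(lam)
    for j in range(n - 1):
        age = float(td.merge_ages[j])
        for c in td.merge_children[j]:
            ll += _log_psi(age, lam, mu) - _log_psi(float(birth[c]), lam, mu)
    if condition_on_survival:
        E_root = _extinction_prob(td.height, lam, mu)
        ll -= math.log(lam) + 2.0 * math.log1p(-E_root)
    return ll


def mk_loglik(tree, tip_states, Q: np.ndarray,
              root_prior="equilibrium") -> float:
    """Felsenstein pruning likelihood of discrete tip states under a Markov
    transition-rate generator ``Q`` (matrix exponentials per branch)."""
    td = as_tree_data(tree)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    states = _states_to_array(td, tip_states)
    n = td.n_tips
    D = np.zeros((2 * n - 1, k))
    logscale = np.zeros(2 * n - 1)
    for i, s in enumerate(states):
        if s is None:
            D[i] = 1.0
        else:
            D[i, s] = 1.0
    birth = np.zeros(2 * n - 1)
    birth[n:] = td.merge_ages
    for j in range(n - 1):
        age = float(td.merge_ages[j])
        parent = n + j
        acc = np.ones(k)
        ls = 0.0
        for c in td.merge_children[j]:
            P = expm(Q * (age - float(birth[c])))
            acc = acc * (P @ D[c])
            ls += logscale[c]
        s = np.abs(acc).max()
        if s <= 0:
            return -math.inf
        D[parent] = acc / s
        logscale[parent] = ls + math.log(s)
    pi = _resolve_root_prior(root_prior, Q, k)
    lik = float(pi @ D[2 * n - 2])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale[2 * n - 2]
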