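"""State-dependent speciation-extinction likelihood on ultrametric trees.

The likelihood follows the classic pruning formulation: along every branch
the extinction probabilities ``E_i(t)`` and the conditional likelihoods
``D_i(t)`` of the observed subtree evolve by

    dE_i/dt = mu_i - (lambda_i + mu_i) E_i + lambda_i E_i^2 + (Q E)_i
    dD_i/dt = [-(lambda_i + mu_i) + 2 lambda_i E_i] D_i + (Q D)_i

(time measured from the tips rootward, ``Q`` the transition-rate
generator).  At an internal node the daughter likelihoods combine as
``lambda_i * D_left,i * D_right,i``; at the root the states are averaged
over a prior and, optionally, the likelihood is conditioned on the survival
of both root lineages.

Because the tree is ultrametric with complete (or uniformly sampled) tips,
``E`` is a single global function of time, and the ``D`` equation is linear
given ``E``.  The implementation integrates, once per inter-node epoch, the
joint system of ``E`` and the fundamental matrix ``Phi`` of the ``D``
equation, then pushes every live lineage through the epoch with one matrix
product.  This is exact (to integrator tolerance) and fast enough for
repeated optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from numba import njit

from .models import SSEModelSpec

__all__ = ["TreeData", "sse_loglik", "equilibrium_frequencies"]

_ULTRAMETRIC_RTOL = 1e-5


@dataclass
class TreeData:
    """A rooted binary ultrametric tree flattened for likelihood pruning.

    Lineages 0..n-1 are the tips; lineage ``n + j`` is the branch above the
    j-th internal node when nodes are ordered by age (time before present).
    ``merges[j] = (age, left_lineage, right_lineage)``; the last merge is
    the root.
    """

    n_tips: int
    tip_labels: list[str]
    merge_ages: np.ndarray       # (n_tips - 1,)
    merge_children: np.ndarray   # (n_tips - 1, 2) lineage indices

    @property
    def height(self) -> float:
        return float(self.merge_ages[-1])

    @property
    def branch_lengths_total(self) -> float:
        total = 0.0
        birth = np.zeros(2 * self.n_tips - 1)
        birth[self.n_tips:] = self.merge_ages
        for j, (a, b) in enumerate(self.merge_children):
            age = self.merge_ages[j]
            total += (age - birth[a]) + (age - birth[b])
        return float(total)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeData":
        tree = tree.clone(depth=1)
        if tree.seed_node is None:
            raise ValueError("empty tree")
        # depths from the root
        depth = {}
        for nd in tree.preorder_node_iter():
            el = nd.edge.length or 0.0
            depth[nd] = (depth[nd.parent_node] + el) if nd.parent_node else 0.0
        leaves = [nd for nd in tree.leaf_node_iter()]
        n = len(leaves)
        if n < 2:
            raise ValueError("tree must have at least two tips")
        for nd in tree.preorder_internal_node_iter():
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly binary "
                                 f"(node with {len(nd.child_nodes())} children)")
        height = max(depth[leaf] for leaf in leaves)
        if height <= 0:
            raise ValueError("tree has zero height")
        for leaf in leaves:
            if abs(depth[leaf] - height) > _ULTRAMETRIC_RTOL * height:
                raise ValueError("tree is not ultrametric: tip "
                                 f"{leaf.taxon.label if leaf.taxon else '?'} at "
                                 f"depth {depth[leaf]:g} vs height {height:g}")
        # ages (time before present); tips pinned to zero
        age = {nd: max(height - depth[nd], 0.0) for nd in tree}
        for leaf in leaves:
            age[leaf] = 0.0
        tip_index = {}
        tip_labels = []
        for i, leaf in enumerate(leaves):
            label = leaf.taxon.label if leaf.taxon else f"tip{i}"
            tip_index[leaf] = i
            tip_labels.append(label)
        internals = sorted(tree.preorder_internal_node_iter(), key=lambda nd: age[nd])
        lineage = dict(tip_index)
        merge_ages = np.empty(n - 1)
        merge_children = np.empty((n - 1, 2), dtype=np.int64)
        for j, nd in enumerate(internals):
            c1, c2 = nd.child_nodes()
            merge_ages[j] = age[nd]
            merge_children[j] = (lineage[c1], lineage[c2])
            lineage[nd] = n + j
        if not (np.diff(merge_ages) >= -1e-12).all():  # pragma: no cover
            raise AssertionError("internal nodes not sorted by age")
        return cls(n_tips=n, tip_labels=tip_labels, merge_ages=merge_ages,
                   merge_children=merge_children)

    @classmethod
    def from_newick(cls, source: str) -> "TreeData":
        tree = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_dendropy(tree)


def as_tree_data(tree) -> TreeData:
    if isinstance(tree, TreeData):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeData.from_dendropy(tree)
    if isinstance(tree, str):
        return TreeData.from_newick(tree)
    raise TypeError("tree must be a TreeData, dendropy.Tree or newick string")


# ----------------------------------------------------------------------
# epoch integrator: joint (E, Phi) Dormand-Prince 5(4)
# ----------------------------------------------------------------------

@njit(cache=True)
def _rhs(y, lam, mu, Q, k, out):
    # y = [E (k), Phi (k*k, row-major)]
    for i in range(k):
        e = y[i]
        acc = mu[i] - (lam[i] + mu[i]) * e + lam[i] * e * e
        for j in range(k):
            acc += Q[i, j] * y[j]
        out[i] = acc
    for i in range(k):
        diag = -(lam[i] + mu[i]) + 2.0 * lam[i] * y[i]
        for j in range(k):
            acc = diag * y[k + i * k + j]
            for m in range(k):
                acc += Q[i, m] * y[k + m * k + j]
            out[k + i * k + j] = acc


@njit(cache=True)
def _integrate_epoch(y, lam, mu, Q, k, dt_total, rtol, atol):
    """Advance y over dt_total with adaptive Dormand-Prince 5(4).

    Returns 0 on success, 1 if the step size underflowed (caller treats the
    likelihood as invalid)."""
    n = y.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); y5 = np.empty(n)
    t = 0.0
    h = dt_total
    min_h = max(dt_total * 1e-12, 1e-300)
    _rhs(y, lam, mu, Q, k, k1)
    n_steps = 0
    while t < dt_total:
        if h > dt_total - t:
            h = dt_total - t
        # Dormand-Prince tableau
        for i in range(n):
            ytmp[i] = y[i] + h * (1/5) * k1[i]
        _rhs(ytmp, lam, mu, Q, k, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (3/40 * k1[i] + 9/40 * k2[i])
        _rhs(ytmp, lam, mu, Q, k, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (44/45 * k1[i] - 56/15 * k2[i] + 32/9 * k3[i])
        _rhs(ytmp, lam, mu, Q, k, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (19372/6561 * k1[i] - 25360/2187 * k2[i]
                                  + 64448/6561 * k3[i] - 212/729 * k4[i])
        _rhs(ytmp, lam, mu, Q, k, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (9017/3168 * k1[i] - 355/33 * k2[i]
                                  + 46732/5247 * k3[i] + 49/176 * k4[i]
                                  - 5103/18656 * k5[i])
        _rhs(ytmp, lam, mu, Q, k, k6)
        for i in range(n):
            y5[i] = y[i] + h * (35/384 * k1[i] + 500/1113 * k3[i]
                                + 125/192 * k4[i] - 2187/6784 * k5[i]
                                + 11/84 * k6[i])
        _rhs(y5, lam, mu, Q, k, k7)
        # embedded 4th-order error estimate
        err = 0.0
        for i in range(n):
            e4 = h * (71/57600 * k1[i] - 71/16695 * k3[i] + 71/1920 * k4[i]
                      - 17253/339200 * k5[i] + 22/525 * k6[i] - 1/40 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            err += (e4 / sc) ** 2
        err = math.sqrt(err / n)
        if err <= 1.0:
            t += h
            for i in range(n):
                y[i] = y5[i]
                k1[i] = k7[i]  # FSAL
        factor = 0.9 * (err + 1e-16) ** (-0.2)
        if factor < 0.2:
            factor = 0.2
        elif factor > 5.0:
            factor = 5.0
        h *= factor
        if h < min_h:
            return 1
        n_steps += 1
        if n_steps > 100000:
            return 1
    return 0


def equilibrium_frequencies(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition-rate generator.

    Falls back to the uniform distribution when the chain is degenerate
    (e.g. all rates zero)."""
    k = Q.shape[0]
    if not np.any(Q):
        return np.full(k, 1.0 / k)
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if s <= 0 or not np.isfinite(s):
        return np.full(k, 1.0 / k)
    return pi / s


def _resolve_root_prior(root_prior, Q: np.ndarray, k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "equilibrium":
            return equilibrium_frequencies(Q)
        if root_prior == "uniform":
            return np.full(k, 1.0 / k)
        raise ValueError("root_prior must be 'equilibrium', 'uniform' or a vector")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or pi.sum() <= 0 or (pi < 0).any():
        raise ValueError("root prior must be a nonnegative vector over states")
    return pi / pi.sum()


def _states_to_array(tree: TreeData, tip_states) -> list:
    if isinstance(tip_states, Mapping):
        missing = [l for l in tree.tip_labels if l not in tip_states]
        if missing:
            raise ValueError(f"no state for tips: {missing[:5]}")
        out = [tip_states[l] for l in tree.tip_labels]
    else:
        out = list(tip_states)
        if len(out) != tree.n_tips:
            raise ValueError("tip_states length does not match the tip count")
    clean = []
    for s in out:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            clean.append(None)
        else:
            clean.append(int(s))
    return clean


def sse_loglik(tree, tip_states, spec: SSEModelSpec, params,
               root_prior="equilibrium", condition_on_survival: bool = True,
               sampling_fraction: float = 1.0,
               rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Log-likelihood of a model spec and parameter vector.

    Parameters follow ``spec.param_names``: diversification rates first,
    then the transition parameters.  ``tip_states`` maps tip label ->
    elevational band (0, 1, 2) or None for a missing state.  Invalid or
    numerically failed parameter regions return ``-inf``.
    """
    td = as_tree_data(tree)
    states = _states_to_array(td, tip_states)
    lam, mu, Q = spec.build_rates(params)
    if not 0 < sampling_fraction <= 1:
        raise ValueError("sampling_fraction must be in (0, 1]")
    k = spec.n_states
    n = td.n_tips

    D = np.zeros((2 * n - 1, k))
    logscale = np.zeros(2 * n - 1)
    for i, s in enumerate(states):
        D[i] = spec.tip_state_vector(s) * sampling_fraction
    E = np.full(k, 1.0 - sampling_fraction)

    birth = np.zeros(2 * n - 1)
    birth[n:] = td.merge_ages
    alive = list(range(n))
    t_cur = 0.0
    for j in range(n - 1):
        t_node = float(td.merge_ages[j])
        dt = t_node - t_cur
        if dt > 0:
            y = np.empty(k + k * k)
            y[:k] = E
            y[k:] = np.eye(k).ravel()
            status = _integrate_epoch(y, lam, mu, Q, k, dt, rtol, atol)
            if status != 0:
                return -math.inf
            E = y[:k].copy()
            Phi = y[k:].reshape(k, k)
            idx = np.asarray(alive)
            D[idx] = D[idx] @ Phi.T
            smax = np.abs(D[idx]).max(axis=1)
            bad = smax <= 0
            if bad.any():
                return -math.inf
            D[idx] /= smax[:, None]
            logscale[idx] += np.log(smax)
        c1, c2 = td.merge_children[j]
        parent = n + j
        D[parent] = lam * D[c1] * D[c2]
        logscale[parent] = logscale[c1] + logscale[c2]
        alive.remove(int(c1))
        alive.remove(int(c2))
        alive.append(parent)
        t_cur = t_node

    d_root = D[2 * n - 2]
    ls_root = logscale[2 * n - 2]
    pi = _resolve_root_prior(root_prior, Q, k)
    lik = float(pi @ d_root)
    if condition_on_survival:
        denom = float((pi * lam * (1.0 - E) ** 2).sum())
        if denom <= 0:
            return -math.inf
        lik /= denom
    if lik <= 0 or not math.isfinite(lik):
        return -math.inf
    return math.log(lik) + ls_root
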