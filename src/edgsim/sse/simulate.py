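"""Forward simulation of birth-death trees with Markov state changes.

Generates ultrametric trees plus tip states under any of the fifteen model
structures, for testing the likelihood machinery and for simulation-based
calibration of model selection.  Lineages speciate, go extinct and switch
states at the rates the spec assigns to their current (possibly concealed)
state; the process stops when the target number of extant lineages is first
reached (tips are sampled just before the following event) and extinct
subtrees are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .likelihood import equilibrium_frequencies
from .models import SSEModelSpec

__all__ = ["SimulatedTree", "simulate_sse_tree"]


@dataclass
class SimulatedTree:
    """A simulated ultrametric tree with observed tip states."""

    newick: str
    tip_states: dict[str, int]       # label -> observed band (0, 1, 2)
    tip_full_states: dict[str, int]  # label -> full (possibly concealed) state
    spec: SSEModelSpec
    params: np.ndarray
    n_tries: int

    @property
    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")


class _Node:
    __slots__ = ("t_birth", "t_end", "children", "tip_id")

    def __init__(self, t_birth: float):
        self.t_birth = t_birth
        self.t_end = None      # speciation/extinction time, or t_stop for tips
        self.children = []
        self.tip_id = None


def _attempt(lam, mu, Q, n_tips, root_state, rng, max_time, max_events):
    qrow = -np.diag(Q)
    per_state = lam + mu + qrow
    root = _Node(0.0)
    live_nodes = [root]
    live_states = [root_state]
    t = 0.0
    for _ in range(max_events):
        rates = per_state[np.asarray(live_states)]
        total = float(rates.sum())
        if total <= 0:
            return None
        dt = rng.exponential(1.0 / total)
        if len(live_nodes) == n_tips:
            # stop just before the next event; tips sampled at that moment
            t_stop = t + dt
            return (root, live_nodes, live_states, t_stop) \
                if t_stop <= max_time else None
        t += dt
        if t > max_time:
            return None
        u = rng.random() * total
        csum = np.cumsum(rates)
        i = int(np.searchsorted(csum, u, side="right"))
        node, s = live_nodes[i], live_states[i]
        u_local = u - (csum[i - 1] if i else 0.0)
        if u_local < lam[s]:
            node.t_end = t
            c1, c2 = _Node(t), _Node(t)
            node.children = [c1, c2]
            live_nodes[i] = c1
            live_nodes.append(c2)
            live_states.append(s)
        elif u_local < lam[s] + mu[s]:
            node.t_end = t
            live_nodes.pop(i)
            live_states.pop(i)
            if not live_nodes:
                return None
        else:
            w = u_local - lam[s] - mu[s]
            cum = 0.0
            for j in range(Q.shape[0]):
                if j == s:
                    continue
                cum += Q[s, j]
                if w < cum:
                    live_states[i] = j
                    break
    return None


def _to_newick(root: _Node, t_stop: float) -> str | None:
    """Newick of the pruned surviving tree, rooted at the survivors' MRCA.

    Returns (recursively) the subtree fragment, the time of its node event
    and the birth time of its retained stem; extinct subtrees vanish and
    pass-through (single-surviving-child) nodes are spliced into one edge.
    """

    def rec(node):
        if not node.children:
            if node.tip_id is None:
                return None
            return f"t{node.tip_id}", t_stop, node.t_birth
        kept = [r for r in (rec(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            core, t_core, _ = kept[0]
            return core, t_core, node.t_birth
        parts = [f"{core}:{t_core - t_top:.12g}" for core, t_core, t_top in kept]
        return f"({','.join(parts)})", node.t_end, node.t_birth

    out = rec(root)
    if out is None:
        return None
    core, _, _ = out
    return core + ";"


def simulate_sse_tree(spec: SSEModelSpec, params, n_tips: int,
                      seed: int | np.random.Generator = 0,
                      root_state: int | None = None,
                      max_time: float = np.inf,
                      max_events: int = 1_000_000,
                      max_tries: int = 1000) -> SimulatedTree:
    """Simulate a tree with ``n_tips`` extant tips under a model spec.

    The root state is drawn from the equilibrium frequencies of the
    transition generator unless given.  Attempts in which the clade dies
    out or exceeds the time/event caps are retried (up to ``max_tries``).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lam, mu, Q = spec.build_rates(params)
    pi = equilibrium_frequencies(Q)
    for tri in range(1, max_tries + 1):
        rs = int(rng.choice(len(pi), p=pi)) if root_state is None else root_state
        out = _attempt(lam, mu, Q, n_tips, rs, rng, max_time, max_events)
        if out is None:
            continue
        root, live_nodes, live_states, t_stop = out
        tip_states, tip_full = {}, {}
        for i, (node, s) in enumerate(zip(live_nodes, live_states)):
            node.tip_id = i
            node.t_end = t_stop
            tip_full[f"t{i}"] = int(s)
            tip_states[f"t{i}"] = int(s) % 3
        newick = _to_newick(root, t_stop)
        if newick is None or newick.count(",") != n_tips - 1:
            continue
        return SimulatedTree(newick=newick, tip_states=tip_states,
                             tip_full_states=tip_full, spec=spec,
                             params=np.asarray(params, dtype=float),
                             n_tries=tri)
    raise RuntimeError(f"no surviving tree with {n_tips} tips in "
                       f"{max_tries} attempts")
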