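"""Model space for state-dependent diversification across elevational bands.

Species are classified into three elevational bands (lowland, midland,
highland) cut at equal widths between the lowest and highest elevations
recorded in the clade.  Fifteen models arise from crossing five transition
structures for movement between bands with three diversification
structures:

Transition structures (free transition parameters in brackets):
  a  adjacent bands only, uphill = downhill            [1]
  b  adjacent bands only, uphill != downhill           [2]
  c  any band, uphill = downhill                       [1]
  d  any band, uphill != downhill                      [2]
  e  every movement has its own rate                   [6]

Diversification structures:
  CR   constant rates: one speciation and one extinction rate for all bands
  ETD  examined-trait-dependent: speciation depends on the elevational band
  CTD  concealed-trait-dependent: speciation depends on a hidden three-state
       trait whose transition rates mirror (and are tied to) the elevational
       transition parameters of the same structure

CR and ETD act on the three observed states; CTD expands the state space to
nine (observed x concealed) states, with tips summed over the concealed
states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "TRANSITION_STRUCTURES",
    "DIVERSIFICATION_STRUCTURES",
    "SSEModelSpec",
    "enumerate_models",
    "ElevationBandAssignment",
    "assign_bands",
]

STATE_NAMES = ("lowland", "midland", "highland")
TRANSITION_STRUCTURES = ("a", "b", "c", "d", "e")
DIVERSIFICATION_STRUCTURES = ("CR", "ETD", "CTD")

# ordered off-diagonal (from, to) pairs for structure e
_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_UP = [(0, 1), (1, 2), (0, 2)]
_DOWN = [(1, 0), (2, 1), (2, 0)]

_TRANSITION_PARAMS = {
    "a": ["q"],
    "b": ["q_up", "q_down"],
    "c": ["q"],
    "d": ["q_up", "q_down"],
    "e": [f"q_{STATE_NAMES[i][0].upper()}{STATE_NAMES[j][0].upper()}"
          for i, j in _PAIRS],
}

_DIV_PARAMS = {
    "CR": ["lambda", "mu"],
    "ETD": ["lambda_lowland", "lambda_midland", "lambda_highland", "mu"],
    "CTD": ["lambda_A", "lambda_B", "lambda_C", "mu"],
}


def _q3(structure: str, qp: np.ndarray) -> np.ndarray:
    """3x3 transition-rate generator (negative diagonal) for a structure."""
    Q = np.zeros((3, 3))
    if structure == "a":
        Q[0, 1] = Q[1, 0] = Q[1, 2] = Q[2, 1] = qp[0]
    elif structure == "b":
        up, down = qp
        Q[0, 1] = Q[1, 2] = up
        Q[1, 0] = Q[2, 1] = down
    elif structure == "c":
        for i, j in _PAIRS:
            Q[i, j] = qp[0]
    elif structure == "d":
        up, down = qp
        for i, j in _UP:
            Q[i, j] = up
        for i, j in _DOWN:
            Q[i, j] = down
    elif structure == "e":
        for (i, j), q in zip(_PAIRS, qp):
            Q[i, j] = q
    else:  # pragma: no cover
        raise ValueError(f"unknown transition structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class SSEModelSpec:
    """One of the fifteen transition x diversification model structures."""

    transition: str
    diversification: str

    def __post_init__(self):
        if self.transition not in TRANSITION_STRUCTURES:
            raise ValueError(f"unknown transition structure {self.transition!r}")
        if self.diversification not in DIVERSIFICATION_STRUCTURES:
            raise ValueError(
                f"unknown diversification structure {self.diversification!r}")

    @property
    def model_id(self) -> str:
        return f"{self.transition}_{self.diversification}"

    @property
    def n_observed(self) -> int:
        return 3

    @property
    def n_concealed(self) -> int:
        return 3 if self.diversification == "CTD" else 1

    @property
    def n_states(self) -> int:
        return self.n_observed * self.n_concealed

    @property
    def n_transition_params(self) -> int:
        return len(_TRANSITION_PARAMS[self.transition])

    @property
    def param_names(self) -> list[str]:
        return _DIV_PARAMS[self.diversification] + _TRANSITION_PARAMS[self.transition]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # families used for pooled AIC weights
    @property
    def symmetric_dispersal(self) -> bool:
        return self.transition in ("a", "c")

    @property
    def adjacent_only(self) -> bool:
        return self.transition in ("a", "b")

    def split_params(self, params) -> tuple[np.ndarray, np.ndarray]:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"{self.model_id} expects {self.n_params} parameters "
                f"({', '.join(self.param_names)}), got {params.shape}")
        nd = len(_DIV_PARAMS[self.diversification])
        return params[:nd], params[nd:]

    def build_rates(self, params) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand a parameter vector into (lambda, mu, Q) on the model's
        full state space (3 states for CR/ETD, 9 for CTD)."""
        dp, qp = self.split_params(params)
        if (np.asarray(params) < 0).any():
            raise ValueError("rates must be nonnegative")
        Qobs = _q3(self.transition, qp)
        if self.diversification == "CR":
            lam = np.full(3, dp[0])
            mu = np.full(3, dp[1])
            return lam, mu, Qobs
        if self.diversification == "ETD":
            lam = dp[:3].copy()
            mu = np.full(3, dp[3])
            return lam, mu, Qobs
        # CTD: state index = observed + 3 * concealed
        lam = np.repeat(dp[:3], 3)          # lambda depends on concealed state
        mu = np.full(9, dp[3])
        Qcon = _q3(self.transition, qp)      # concealed transitions tied
        obs_off = Qobs - np.diag(np.diag(Qobs))
        con_off = Qcon - np.diag(np.diag(Qcon))
        Q = np.kron(np.eye(3), obs_off) + np.kron(con_off, np.eye(3))
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return lam, mu, Q

    def tip_state_vector(self, observed: int | None) -> np.ndarray:
        """Initial conditional-likelihood vector for a tip (missing state =
        None, integrated over all states)."""
        k = self.n_states
        if observed is None:
            return np.ones(k)
        if not 0 <= observed < 3:
            raise ValueError("observed state must be 0, 1, 2 or None")
        v = np.zeros(k)
        v[observed::3] = 1.0  # every concealed copy of the observed state
        return v


def enumerate_models() -> list[SSEModelSpec]:
    """All fifteen model structures in a fixed order."""
    return [SSEModelSpec(t, d) for d in DIVERSIFICATION_STRUCTURES
            for t in TRANSITION_STRUCTURES]


# ----------------------------------------------------------------------
# elevational band discretizer
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ElevationBandAssignment:
    """Species -> band mapping with the band boundaries in meters."""

    bands: dict[str, int]
    boundaries: tuple[float, float]
    elevation_range: tuple[float, float]

    def band_name(self, label: str) -> str:
        return STATE_NAMES[self.bands[label]]


def assign_bands(species_elevations: Mapping[str, float]) -> ElevationBandAssignment:
    """Classify species into three equal-width elevational bands.

    The bands span [min, max] of the recorded elevations with cut points at
    one and two thirds of the range; a species exactly on a cut point is
    assigned to the lower band.
    """
    if not species_elevations:
        raise ValueError("no species elevations provided")
    elev = {k: float(v) for k, v in species_elevations.items()}
    lo, hi = min(elev.values()), max(elev.values())
    if hi == lo:
        raise ValueError("all recorded elevations are equal: "
                         "equal-width bands are degenerate")
    c1 = lo + (hi - lo) / 3.0
    c2 = lo + 2.0 * (hi - lo) / 3.0
    bands = {}
    for label, e in elev.items():
        if e <= c1:
            bands[label] = 0
        elif e <= c2:
            bands[label] = 1
        else:
            bands[label] = 2
    return ElevationBandAssignment(bands=bands, boundaries=(c1, c2),
                                   elevation_range=(lo, hi))
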