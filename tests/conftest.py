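"""Shared fixtures.

The heavy simulation batches are session-scoped so that the scenario-level
properties and the acceptance checks share one set of runs.  Problem sizes
(250-cell cone, modest replicate counts) are desk-scale versions of the
full study conditions; seeds are fixed.
"""

from __future__ import annotations

import pandas as pd
import pytest

from edgsim.engine import ScenarioConfig
from edgsim.experiments import run_replicates

SIM_CELLS = 250
SIM_KW = dict(total_cells=SIM_CELLS, record_events=False, check_every=50,
              max_events=600_000)


@pytest.fixture(scope="session")
def uniform_cone_runs() -> pd.DataFrame:
    """50 replicates of the geometry-only scenario (uniform K and lambda,
    cone, no local adaptation, lowland origin)."""
    cfg = ScenarioConfig(**SIM_KW)
    df, _ = run_replicates(cfg, 50, base_seed=101)
    return df


@pytest.fixture(scope="session")
def counteraction_runs() -> pd.DataFrame:
    """Replicates of the counteracting scenario: lambda increases nine-fold
    with elevation while niche width K decreases four-fold."""
    cfg = ScenarioConfig(lambda_direction="increase", K_direction="decrease",
                         **SIM_KW)
    df, _ = run_replicates(cfg, 16, base_seed=202)
    return df


@pytest.fixture(scope="session")
def nine_scenario_runs() -> pd.DataFrame:
    """The 3x3 K x lambda direction grid (no adaptation, lowland origin),
    four replicates each."""
    frames = []
    for kdir in ("increase", "decrease", "uniform"):
        for ldir in ("increase", "decrease", "uniform"):
            cfg = ScenarioConfig(K_direction=kdir, lambda_direction=ldir,
                                 **SIM_KW)
            df, _ = run_replicates(cfg, 4, base_seed=303)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def sse_recovery_runs() -> list[dict]:
    """Twenty trees simulated under the adjacent-symmetric constant-rate
    model, each fitted with the full fifteen-model set; returns the pooled
    diversification-family AIC weights per replicate."""
    from edgsim.sse import SSEModelSpec, fit_model_set, simulate_sse_tree
    gen = SSEModelSpec("a", "CR")
    true_params = [0.7, 0.15, 0.25]
    out = []
    for rep in range(20):
        sim = simulate_sse_tree(gen, true_params, n_tips=40, seed=1000 + rep)
        ms = fit_model_set(sim.newick, sim.tip_states, n_starts=1, seed=rep)
        out.append({
            "families": ms.family_weights("diversification"),
            "symmetry": ms.family_weights("dispersal_symmetry"),
            "weights_sum": float(sum(ms.family_weights("diversification")
                                     .values())),
            "best": ms.best.model_id,
        })
    return out
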