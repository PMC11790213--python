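"""Maximum-likelihood fitting and AIC model selection.

`ElevationSSE` is the model object (tree + tip states + one of the fifteen
structures); `fit()` maximizes the likelihood from several dispersed start
points and returns an `ElevationSSEResults` with the estimates, standard
errors (inverse observed information on the log-rate scale, delta method)
and a `summary()` table.  `fit_model_set` fits all fifteen structures and
assembles AIC weights and pooled family weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import TreeData, as_tree_data, sse_loglik
from .models import SSEModelSpec, assign_bands, enumerate_models

__all__ = ["ElevationSSE", "ElevationSSEResults", "ModelSetResults",
           "fit_model_set", "aic_weights"]

_RATE_LO, _RATE_HI = 1e-6, 1e3


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights of a model set: exp(-dAIC/2), normalized to sum 1."""
    a = np.asarray(aics, dtype=float)
    w = np.exp(-(a - np.nanmin(a)) / 2.0)
    w = np.where(np.isfinite(a), w, 0.0)
    s = w.sum()
    if s <= 0:
        raise ValueError("no finite AIC values")
    return w / s


class ElevationSSE:
    """State-dependent diversification model for a clade on a mountain.

    Parameters
    ----------
    tree : newick string, dendropy.Tree or TreeData (rooted, binary,
        ultrametric).
    tip_states : mapping tip label -> band (0 lowland, 1 midland,
        2 highland; None = unknown), or a mapping of elevations in meters
        (use :meth:`from_elevations`).
    transition, diversification : structure codes (see
        :class:`~edgsim.sse.models.SSEModelSpec`), or pass ``spec``.
    root_prior : 'equilibrium' (default), 'uniform' or a probability vector.
    condition_on_survival : condition the likelihood on both root lineages
        surviving (default True).
    sampling_fraction : global probability that an extant species is in the
        tree (default 1).
    """

    def __init__(self, tree, tip_states, transition: str = "a",
                 diversification: str = "CR",
                 spec: SSEModelSpec | None = None,
                 root_prior="equilibrium",
                 condition_on_survival: bool = True,
                 sampling_fraction: float = 1.0):
        self.tree = as_tree_data(tree)
        self.spec = spec or SSEModelSpec(transition, diversification)
        self.tip_states = dict(tip_states) if isinstance(tip_states, Mapping) \
            else dict(zip(self.tree.tip_labels, tip_states))
        self.root_prior = root_prior
        self.condition_on_survival = condition_on_survival
        self.sampling_fraction = sampling_fraction

    @classmethod
    def from_elevations(cls, tree, species_elevations: Mapping[str, float],
                        **kwargs) -> "ElevationSSE":
        """Build the model from raw elevations (meters); species are cut
        into three equal-width bands over the clade's elevational span."""
        assignment = assign_bands(species_elevations)
        return cls(tree, assignment.bands, **kwargs)

    @classmethod
    def from_files(cls, tree_path, states_path, **kwargs) -> "ElevationSSE":
        """Read a newick tree and a two-column TSV (species, elevation_m or
        band)."""
        with open(tree_path) as fh:
            tree = fh.read()
        df = pd.read_csv(states_path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        label_col = df.columns[0]
        if "band" in cols:
            states = dict(zip(df[label_col], df[cols["band"]].astype(int)))
            return cls(tree, states, **kwargs)
        if "elevation_m" in cols:
            elev = dict(zip(df[label_col], df[cols["elevation_m"]].astype(float)))
            return cls.from_elevations(tree, elev, **kwargs)
        raise ValueError("states file needs a 'band' or 'elevation_m' column")

    # ------------------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names

    @property
    def k_params(self) -> int:
        return self.spec.n_params

    def loglik(self, params) -> float:
        return sse_loglik(self.tree, self.tip_states, self.spec, params,
                          root_prior=self.root_prior,
                          condition_on_survival=self.condition_on_survival,
                          sampling_fraction=self.sampling_fraction)

    def _moment_start(self) -> np.ndarray:
        """Method-of-moments style initial guess: net diversification from
        the tip count and tree height, transitions of order one per height."""
        n, h = self.tree.n_tips, self.tree.height
        r0 = max(math.log(max(n, 3) / 2.0) / h, 1e-3)
        lam0, mu0 = 1.5 * r0, 0.5 * r0
        q0 = 1.0 / h
        start = []
        for name in self.param_names:
            if name.startswith("lambda"):
                start.append(lam0)
            elif name.startswith("mu"):
                start.append(mu0)
            else:
                start.append(q0)
        return np.asarray(start)

    def start_points(self, n_starts: int = 3,
                     seed: int | np.random.Generator | None = 0) -> list[np.ndarray]:
        """Dispersed start points: the moment guess plus log-uniform
        perturbations within a factor of ten around it."""
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        base = self._moment_start()
        pts = [base]
        for _ in range(max(0, n_starts - 1)):
            f = np.exp(rng.uniform(-math.log(10.0), math.log(10.0), size=base.size))
            pts.append(np.clip(base * f, _RATE_LO * 10, _RATE_HI / 10))
        return pts

    def fit(self, n_starts: int = 3, seed: int | np.random.Generator | None = 0,
            extra_starts: Sequence | None = None,
            maxiter: int = 500) -> "ElevationSSEResults":
        """Maximize the likelihood from ``n_starts`` dispersed start points
        (bounded quasi-Newton on log-transformed rates); the best optimum
        is retained."""
        starts = self.start_points(n_starts, seed)
        if extra_starts is not None:
            starts += [np.asarray(s, dtype=float) for s in extra_starts]
        lo, hi = math.log(_RATE_LO), math.log(_RATE_HI)

        def negll(x):
            v = self.loglik(np.exp(x))
            return -v if math.isfinite(v) else 1e12

        best = None
        best_start = None
        n_ok = 0
        for s in starts:
            x0 = np.clip(np.log(np.maximum(s, _RATE_LO)), lo, hi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(negll, x0, method="L-BFGS-B",
                               bounds=[(lo, hi)] * len(x0),
                               options={"maxiter": maxiter, "ftol": 1e-11,
                                        "gtol": 1e-6})
            if not math.isfinite(res.fun) or res.fun >= 1e11:
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best, best_start = res, s
        if best is None:
            return ElevationSSEResults(model=self, params=None,
                                       loglik=-math.inf, converged=False,
                                       start=None, n_starts_ok=0)
        return ElevationSSEResults(model=self, params=np.exp(best.x),
                                   loglik=-float(best.fun), converged=True,
                                   start=best_start, n_starts_ok=n_ok)


@dataclass
class ElevationSSEResults:
    """Fit of one model structure: estimates, logL, AIC, standard errors."""

    model: ElevationSSE
    params: np.ndarray | None
    loglik: float
    converged: bool
    start: np.ndarray | None
    n_starts_ok: int
    _bse: np.ndarray | None = field(default=None, repr=False)

    @property
    def spec(self) -> SSEModelSpec:
        return self.model.spec

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    @property
    def k(self) -> int:
        return self.spec.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def params_dict(self) -> dict[str, float]:
        if self.params is None:
            return {}
        return dict(zip(self.spec.param_names, map(float, self.params)))

    def bse(self, rel_step: float = 1e-4) -> np.ndarray:
        """Approximate standard errors of the rate estimates.

        Observed information from a central finite-difference Hessian of
        the log-likelihood in log-rate space, mapped to the rate scale by
        the delta method; NaN where the information matrix is not positive
        definite."""
        if self._bse is not None:
            return self._bse
        if self.params is None:
            return np.array([])
        x = np.log(self.params)
        p = len(x)
        H = np.empty((p, p))
        h = rel_step * np.maximum(np.abs(x), 1.0)

        def f(v):
            val = self.model.loglik(np.exp(v))
            return val if math.isfinite(val) else -1e12

        f0 = f(x)
        for i in range(p):
            for j in range(i, p):
                xi, xj = np.zeros(p), np.zeros(p)
                xi[i], xj[j] = h[i], h[j]
                if i == j:
                    H[i, i] = (f(x + xi) - 2 * f0 + f(x - xi)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(x + xi + xj) - f(x + xi - xj)
                        - f(x - xi + xj) + f(x - xi - xj)) / (4 * h[i] * h[j])
        se = np.full(p, np.nan)
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            ok = d > 0
            se[ok] = np.sqrt(d[ok]) * self.params[ok]  # delta method
        except np.linalg.LinAlgError:
            pass
        self._bse = se
        return se

    def summary(self) -> str:
        lines = [
            "State-dependent diversification fit",
            "=" * 52,
            f"model:            {self.model_id} "
            f"(transition {self.spec.transition}, {self.spec.diversification})",
            f"tips:             {self.model.tree.n_tips}",
            f"log-likelihood:   {self.loglik:.4f}",
            f"free parameters:  {self.k}",
            f"AIC:              {self.aic:.4f}",
            f"converged:        {self.converged} ({self.n_starts_ok} start(s))",
            "-" * 52,
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}",
        ]
        if self.params is not None:
            se = self.bse()
            for name, v, s in zip(self.spec.param_names, self.params, se):
                lines.append(f"{name:<20}{v:>12.5g}{s:>12.4g}")
        return "\n".join(lines)


# family groupings used for pooled AIC weights
FAMILIES: dict[str, Callable[[SSEModelSpec], str]] = {
    "diversification": lambda s: s.diversification,
    "dispersal_symmetry": lambda s: ("symmetric" if s.symmetric_dispersal
                                     else "asymmetric"),
    "adjacency": lambda s: "adjacent" if s.adjacent_only else "any_band",
}


@dataclass
class ModelSetResults:
    """Fits of the full model set with AIC weights and family pooling."""

    results: list[ElevationSSEResults]

    @property
    def converged(self) -> list[ElevationSSEResults]:
        return [r for r in self.results if r.converged]

    @property
    def table(self) -> pd.DataFrame:
        ok = self.converged
        if not ok:
            raise RuntimeError("no model converged")
        w = aic_weights([r.aic for r in ok])
        rows = []
        wi = iter(w)
        for r in self.results:
            row = {"model_id": r.model_id, "transition": r.spec.transition,
                   "diversification": r.spec.diversification, "k": r.k,
                   "logL": r.loglik, "AIC": r.aic,
                   "weight": next(wi) if r.converged else np.nan,
                   "converged": r.converged}
            row.update(r.params_dict)
            rows.append(row)
        df = pd.DataFrame(rows)
        df["dAIC"] = df["AIC"] - df.loc[df["converged"], "AIC"].min()
        return df.sort_values("AIC").reset_index(drop=True)

    def family_weights(self, family: str = "diversification") -> dict[str, float]:
        """Pooled AIC weights over a model family grouping
        ('diversification', 'dispersal_symmetry' or 'adjacency')."""
        keyfn = FAMILIES[family]
        ok = self.converged
        w = aic_weights([r.aic for r in ok])
        out: dict[str, float] = {}
        for r, wi in zip(ok, w):
            out[keyfn(r.spec)] = out.get(keyfn(r.spec), 0.0) + float(wi)
        return out

    @property
    def best(self) -> ElevationSSEResults:
        return min(self.converged, key=lambda r: r.aic)

    def summary(self) -> str:
        df = self.table
        lines = ["Model set comparison (AIC weights)", "=" * 60]
        lines.append(df[["model_id", "k", "logL", "AIC", "dAIC", "weight"]]
                     .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        for fam in FAMILIES:
            fw = self.family_weights(fam)
            pooled = ", ".join(f"{k}: {v:.1%}" for k, v in sorted(fw.items()))
            lines.append(f"pooled {fam}: {pooled}")
        return "\n".join(lines)


def fit_model_set(tree, tip_states, n_starts: int = 3,
                  seed: int | np.random.Generator | None = 0,
                  specs: Sequence[SSEModelSpec] | None = None,
                  maxiter: int = 500, **model_kwargs) -> ModelSetResults:
    """Fit every model structure (default: all fifteen) to one dataset.

    Each model is maximized from ``n_starts`` dispersed start points; models
    for which no start converges are flagged and excluded from the AIC
    weights with a warning.
    """
    td = as_tree_data(tree)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    results = []
    for spec in (specs or enumerate_models()):
        m = ElevationSSE(td, tip_states, spec=spec, **model_kwargs)
        r = m.fit(n_starts=n_starts, seed=rng, maxiter=maxiter)
        if not r.converged:
            warnings.warn(f"model {spec.model_id} did not converge from any "
                          "start; excluded from AIC weights")
        results.append(r)
    return ModelSetResults(results=results)
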