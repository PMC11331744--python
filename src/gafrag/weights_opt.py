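"""Bayesian optimisation of the penalty weights.

The objective balances fragment-volume quality against the fragmentation
energy error over a dataset of systems:

    f = α · (1/n) Σ_i p_vol^i + (1−α) · (1/n) Σ_i S(ΔE_i)

with α = 0.5 by default and S a mirrored-logistic normaliser whose
boundary points sit at 1 and 4 kJ/mol.  ΔE_i is the MBE2 error of system i
under a pluggable inner energy model (the expensive ab initio objective is
out of scope; any deterministic backend slots in).  A Gaussian-process
surrogate (RBF kernel, unit noise variance and length scale) with the
expected-improvement acquisition proposes new weight vectors on the
probability simplex via Dirichlet candidate sampling.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .driver import Fragmenter
from .forcefield import EnergyBackend, BondedToyBackend
from .ga import GAConfig
from .scoring import PenaltyWeights

#: sigmoid boundary points for the energy-error normaliser, kJ/mol
ENERGY_BOUNDS = (1.0, 4.0)


def energy_error_normaliser(delta_e: float,
                            bounds: tuple[float, float] = ENERGY_BOUNDS
                            ) -> float:
    """Mirrored logistic in [0, 1], within 5 % of its asymptotes at the
    boundary points (applied to the magnitude of the error)."""
    lo, hi = bounds
    d = 0.5 * (lo + hi)
    lam = 2.0 * math.log(19.0) / (hi - lo)
    from .scoring import logistic

    x = abs(delta_e)
    return logistic(lam * (x - d)) + logistic(lam * (-x - d))


# the 16 grid rows seeding the surrogate: (pe, conj, hyper, vol, comp, vrange)
_INITIAL_GRID = (
    (0.2, 0.1, 0.1, 0.2, 0.1, 0.3),
    (0.2, 0.1, 0.1, 0.2, 0.2, 0.2),
    (0.2, 0.1, 0.1, 0.3, 0.1, 0.2),
    (0.2, 0.1, 0.1, 0.4, 0.1, 0.1),
    (0.2, 0.1, 0.2, 0.2, 0.1, 0.2),
    (0.2, 0.1, 0.2, 0.3, 0.1, 0.1),
    (0.2, 0.1, 0.3, 0.2, 0.1, 0.1),
    (0.2, 0.2, 0.1, 0.2, 0.1, 0.2),
    (0.2, 0.2, 0.1, 0.3, 0.1, 0.1),
    (0.2, 0.2, 0.2, 0.2, 0.1, 0.1),
    (0.2, 0.3, 0.1, 0.2, 0.1, 0.1),
    (0.3, 0.1, 0.1, 0.2, 0.1, 0.2),
    (0.3, 0.1, 0.1, 0.3, 0.1, 0.1),
    (0.3, 0.1, 0.2, 0.2, 0.1, 0.1),
    (0.3, 0.2, 0.1, 0.2, 0.1, 0.1),
    (0.4, 0.1, 0.1, 0.2, 0.1, 0.1),
)


def initial_grid() -> list[tuple[float, ...]]:
    """The 16 grid-search weight vectors seeding the optimisation (0.1-step
    grid with β_pe and β_vol floored at 0.2; every row sums to one)."""
    return [tuple(row) for row in _INITIAL_GRID]


@dataclass
class ObjectiveConfig:
    alpha: float = 0.5
    target_size: int = 20
    seed: int = 0
    inner_backend: EnergyBackend = field(
        default_factory=lambda: BondedToyBackend(order=3))
    scoring_backend: EnergyBackend = field(default_factory=BondedToyBackend)
    ga_config: GAConfig = field(default_factory=GAConfig)
    mbe_level: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def objective_f(weights, dataset, config: ObjectiveConfig) -> float:
    """Evaluate the dataset objective for one weight vector.

    Each system is fragmented with the candidate weights; its volume
    penalty and the (inner-model) MBE error enter the two averages.
    Systems whose fragmentation fails are skipped with a warning.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    w = (weights if isinstance(weights, PenaltyWeights)
         else PenaltyWeights.from_sequence(weights))
    p_vols, s_terms = [], []
    for structure in dataset:
        try:
            res = Fragmenter(structure, config.target_size, weights=w,
                             backend=config.scoring_backend,
                             ga_config=config.ga_config).fit(config.seed)
            terms = res.mbe(config.inner_backend, level=config.mbe_level)
        except Exception as exc:  # noqa: BLE001
            _warnings.warn(f"skipping {structure.name!r}: {exc}")
            continue
        p_vols.append(res.score.p_vol)
        s_terms.append(energy_error_normaliser(terms.fragmentation_error))
    if not p_vols:
        raise RuntimeError("every system in the dataset failed")
    return (config.alpha * float(np.mean(p_vols))
            + (1.0 - config.alpha) * float(np.mean(s_terms)))


@dataclass
class BOState:
    sampled: list[tuple[float, ...]]
    values: list[float]
    best_trace: list[float]

    @property
    def best(self) -> tuple[tuple[float, ...], float]:
        k = int(np.argmin(self.values))
        return self.sampled[k], self.values[k]


def bayes_optimise(objective, seed: int = 0,
                   stagnation_limit: int = 200,
                   max_iterations: int = 1000,
                   n_candidates: int = 4096,
                   initial: list[tuple[float, ...]] | None = None) -> BOState:
    """Minimise a weight-vector objective on the simplex.

    ``objective`` maps a 6-tuple of weights (summing to one) to a scalar.
    A GP surrogate (RBF kernel, noise variance and length scale 1.0) is
    refit each iteration; expected improvement is maximised over Dirichlet
    candidate samples.  Terminates when the minimum has not improved for
    ``stagnation_limit`` iterations.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF

    rng = np.random.default_rng(seed)
    xs = [tuple(map(float, row)) for row in (initial or initial_grid())]
    for x in xs:
        if abs(sum(x) - 1.0) > 1e-9 or any(v < 0 for v in x):
            raise ValueError(f"initial weights {x} are not on the simplex")
    ys = [float(objective(x)) for x in xs]
    state = BOState(list(xs), list(ys), [min(ys[:k + 1])
                                         for k in range(len(ys))])
    stagnation = 0
    for _it in range(max_iterations):
        X = np.asarray(state.sampled)
        y = np.asarray(state.values)
        gp = GaussianProcessRegressor(kernel=RBF(length_scale=1.0),
                                      alpha=1.0, normalize_y=True,
                                      random_state=int(rng.integers(2 ** 31)))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            gp.fit(X, y)
        cand = rng.dirichlet(np.ones(6), size=n_candidates)
        mu, sigma = gp.predict(cand, return_std=True)
        best = float(np.min(y))
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        # expected improvement for minimisation
        from math import erf, sqrt
        cdf = 0.5 * (1.0 + np.vectorize(erf)(z / sqrt(2.0)))
        pdf = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        ei = (best - mu) * cdf + sigma * pdf
        x_next = tuple(map(float, cand[int(np.argmax(ei))]))
        y_next = float(objective(x_next))
        state.sampled.append(x_next)
        state.values.append(y_next)
        improved = y_next < state.best_trace[-1] - 1e-15
        state.best_trace.append(min(state.best_trace[-1], y_next))
        stagnation = 0 if improved else stagnation + 1
        if stagnation >= stagnation_limit:
            break
    return state
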