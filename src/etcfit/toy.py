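"""Two-parameter bimodal benchmark landscape.

A fitness surface with exactly two global maxima of value 1 at (1, 1) and
(-1, -1) and a saddle at the origin:

    f(x, y) = 1 / (1 + ((x-1)² + (y-1)²) · ((x+1)² + (y+1)²))

With an isotropic normal prior N(0, 0.2²) on each coordinate, the true
posterior is symmetric about the origin and equally concentrated around the
two optima — so an inference method that ends every run near only one of
them has collapsed a mode.  Both engines run on this landscape through the
same interfaces they use for thermal-parameter inference (the two
coordinates are unconstrained, so the thermal admissibility machinery is
bypassed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .particles import FitnessBreakdown

TOY_PRIOR_STD = 0.2
TOY_PARAM_NAMES = ("x", "y")


def toy_fitness(x: float, y: float) -> float:
    """Bimodal fitness in (0, 1]; equals 1 only at (1, 1) and (-1, -1)."""
    d1 = (x - 1.0) ** 2 + (y - 1.0) ** 2
    d2 = (x + 1.0) ** 2 + (y + 1.0) ** 2
    return 1.0 / (1.0 + d1 * d2)


def toy_fitness_gradient(x: float, y: float, h: float = 1e-6
                         ) -> np.ndarray:
    """Central-difference gradient of the toy fitness."""
    gx = (toy_fitness(x + h, y) - toy_fitness(x - h, y)) / (2 * h)
    gy = (toy_fitness(x, y + h) - toy_fitness(x, y - h)) / (2 * h)
    return np.array([gx, gy])


def toy_evaluator(values: np.ndarray) -> FitnessBreakdown:
    """Evaluator adapter for the inference engines."""
    f = toy_fitness(values[0], values[1])
    return FitnessBreakdown(components={"toy": f}, overall=f)


def toy_prior_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent draws of (x, y) ~ N(0, 0.2²) each; shape (n, 2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.normal(0.0, TOY_PRIOR_STD, size=(n, 2))


def locate_toy_optima(grid_resolution: float = 0.01,
                      domain: tuple[float, float] = (-2.0, 2.0)
                      ) -> list[tuple[float, float]]:
    """Brute-force global-maximum locator (test oracle).

    Scans a grid over the square domain for local maxima (8-neighbour
    comparison), polishes each with a derivative-free local ascent, and
    returns the distinct points attaining the global maximum within 1e-9
    in function value.
    """
    if grid_resolution > 0.05:
        raise ValueError("grid resolution must be <= 0.05 for a reliable scan")
    lo, hi = domain
    xs = np.arange(lo, hi + grid_resolution / 2, grid_resolution)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    F = 1.0 / (1.0 + (((X - 1) ** 2 + (Y - 1) ** 2)
                      * ((X + 1) ** 2 + (Y + 1) ** 2)))
    candidates = []
    n = len(xs)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            patch = F[i - 1:i + 2, j - 1:j + 2]
            if F[i, j] >= patch.max():
                candidates.append((X[i, j], Y[i, j]))
    polished = []
    for x0, y0 in candidates:
        res = minimize(lambda p: -toy_fitness(p[0], p[1]), x0=[x0, y0],
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12,
                                "maxiter": 2000})
        polished.append((res.x[0], res.x[1], -res.fun))
    best = max(f for _, _, f in polished)
    optima: list[tuple[float, float]] = []
    for x, y, f in polished:
        if best - f > 1e-9:
            continue
        if any(abs(x - ox) < 1e-4 and abs(y - oy) < 1e-4 for ox, oy in optima):
            continue
        optima.append((x, y))
    return sorted(optima)


@dataclass
class ToyProblem:
    """Bundles the toy landscape into the engines' problem interface."""

    param_names: tuple[str, ...] = TOY_PARAM_NAMES

    dim: int = 2

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, TOY_PRIOR_STD, size=2)

    def repair(self, values: np.ndarray, mean: np.ndarray, std: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        return values  # unconstrained

    def update_ok(self, values: np.ndarray, k: int) -> bool:
        return True

    def evaluate(self, values: np.ndarray) -> FitnessBreakdown:
        return toy_evaluator(values)
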