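"""Analytic oracles and toy generators for validating the analysis chain.

These live outside the cardiac model so that estimator bugs and model bugs
are separable: the Sobol/Jansen machinery is validated against functions
with closed-form variance decompositions, and the influence/sloppiness
chain against a constructed two-parameter system with one stiff and one
sloppy direction.  All generators are pure functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gsa import ParameterSpace

__all__ = [
    "AnalyticTestFunction",
    "linear_function",
    "ishigami_function",
    "toy_two_parameter_model",
    "ToyTwoParameterModel",
]


@dataclass(frozen=True)
class AnalyticTestFunction:
    """A callable on a box with closed-form Sobol indices attached."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]     # (rows, d) -> (rows,)
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    S1: np.ndarray
    ST: np.ndarray
    variance: float

    def space(self) -> ParameterSpace:
        """A ParameterSpace over the function's own box (the base point is
        the box centre; it only matters for bookkeeping)."""
        names = tuple(f"x{i + 1}" for i in range(self.dimension))
        base = 0.5 * (self.lower + self.upper)
        return ParameterSpace(names, base, self.lower.copy(),
                              self.upper.copy(), base.copy(),
                              np.arange(self.dimension))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.fn(np.atleast_2d(np.asarray(X, dtype=float)))


def linear_function(weights) -> AnalyticTestFunction:
    """f(x) = sum a_i x_i on independent U(0, 1) inputs.

    With equal box widths the variance decomposition is exactly additive:
    S_1,i = S_T,i = a_i^2 / sum_k a_k^2.
    """
    a = np.asarray(weights, dtype=float)
    if a.ndim != 1 or a.size == 0 or np.all(a == 0.0):
        raise ValueError("need at least one nonzero weight")
    d = a.size
    V = (a ** 2).sum() / 12.0
    S = a ** 2 / (a ** 2).sum()
    return AnalyticTestFunction(
        name=f"linear{tuple(a.tolist())}",
        fn=lambda X: X @ a,
        dimension=d,
        lower=np.zeros(d), upper=np.ones(d),
        S1=S.copy(), ST=S.copy(), variance=float(V))


def ishigami_function(a: float = 7.0, b: float = 0.1
                      ) -> AnalyticTestFunction:
    """f = sin x1 + a sin^2 x2 + b x3^4 sin x1 on [-pi, pi]^3.

    Closed-form decomposition: V = a^2/8 + b pi^4/5 + b^2 pi^8/18 + 1/2,
    V1 = (1 + b pi^4/5)^2 / 2, V2 = a^2/8, V3 = 0 and the only interaction
    V13 = 8 b^2 pi^8 / 225.
    """
    pi4 = np.pi ** 4
    pi8 = np.pi ** 8
    V = a ** 2 / 8.0 + b * pi4 / 5.0 + b ** 2 * pi8 / 18.0 + 0.5
    V1 = 0.5 * (1.0 + b * pi4 / 5.0) ** 2
    V2 = a ** 2 / 8.0
    V13 = 8.0 * b ** 2 * pi8 / 225.0
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])

    def f(X):
        return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
                + b * X[:, 2] ** 4 * np.sin(X[:, 0]))

    return AnalyticTestFunction(
        name=f"ishigami(a={a},b={b})", fn=f, dimension=3,
        lower=np.full(3, -np.pi), upper=np.full(3, np.pi),
        S1=S1, ST=ST, variance=float(V))


@dataclass(frozen=True)
class ToyTwoParameterModel:
    """Two-parameter, two-output map with one stiff and one sloppy
    direction, mirroring the contour-plot picture of a cost surface with a
    steep and a flat valley axis.

    ``sensitivity`` is the constructed 2x2 sensitivity matrix whose Fisher
    information F = S^T S has eigenvalue ratio 1/epsilon^2 >= 1e6 by
    construction; ``fn`` is the matching output map for end-to-end smoke
    tests of the sampling -> estimation -> sloppiness chain.
    """

    epsilon: float
    lower: np.ndarray
    upper: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return np.array([[1.0, self.epsilon], [1.0, -self.epsilon]])

    @property
    def parameter_names(self) -> tuple[str, str]:
        return ("p_stiff", "p_sloppy")

    def fn(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y1 = X[:, 0] + self.epsilon * X[:, 1]
        y2 = X[:, 0] - self.epsilon * X[:, 1]
        return np.column_stack([y1, y2])

    def space(self) -> ParameterSpace:
        base = 0.5 * (self.lower + self.upper)
        return ParameterSpace(self.parameter_names, base,
                              self.lower.copy(), self.upper.copy(),
                              base.copy(), np.arange(2))


def toy_two_parameter_model(epsilon: float = 1e-3) -> ToyTwoParameterModel:
    """Stiff/sloppy toy: outputs respond with unit gain to p_stiff and
    with gain epsilon (default 1e-3) to p_sloppy, so the constructed FIM
    eigenvalues are 2 and 2 epsilon^2 (ratio 1e6 at the default)."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    return ToyTwoParameterModel(epsilon, np.array([0.5, 0.5]),
                                np.array([1.5, 1.5]))
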