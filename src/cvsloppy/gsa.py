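"""Variance-based global sensitivity analysis over the +/-50% parameter box.

Sampling follows the pick-and-freeze scheme: a scrambled Sobol'
low-discrepancy sequence supplies two independent N x n blocks A and B, and
the substituted matrices AB_i replace column i of A with column i of B.
First and total-order indices are computed with the Jansen estimators

    S_T,i = sum_r (f(A)_r - f(AB_i)_r)^2 / (2 N' Vhat)
    S_1,i = 1 - sum_r (f(B)_r - f(AB_i)_r)^2 / (2 N' Vhat)

with Vhat the sample variance of the pooled f(A), f(B) values.  Confidence
intervals come from a seeded percentile bootstrap over rows.  Model
evaluations that fail (diverged solves, or invalid activation timings under
the strict policy) are removed by complete-case row deletion across A, B
and every AB_i, preserving the pairing the estimators require.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .cardiac_model import (ModelParameters, PARAM_NAMES, SimulationConfig,
                            SimulationFailure, VARIED_PARAMETERS, simulate,
                            table1)
from .measurements import ExperimentalDesign, evaluate_design

__all__ = [
    "ParameterSpace",
    "SobolDesign",
    "EnsembleOutputs",
    "SensitivityMatrix",
    "EnsembleRetentionError",
    "build_parameter_space",
    "sobol_matrices",
    "evaluate_ensemble",
    "evaluate_function_ensemble",
    "jansen_indices",
    "bootstrap_ci",
    "time_averaged_sensitivity",
]


class EnsembleRetentionError(RuntimeError):
    """Raised when too few paired-complete rows survive failure masking."""


@dataclass(frozen=True)
class ParameterSpace:
    """Uniform box over the varied parameters: [base*(1-f), base*(1+f)]."""

    names: tuple[str, ...]
    base: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    base_full: np.ndarray        # all 38 parameters, fixed ones included
    varied_idx: np.ndarray       # indices of the varied entries in the 38

    @property
    def dimension(self) -> int:
        return len(self.names)

    def expand(self, X: np.ndarray) -> np.ndarray:
        """Embed (rows, n_varied) draws into full 38-parameter vectors."""
        X = np.atleast_2d(X)
        full = np.tile(self.base_full, (X.shape[0], 1))
        full[:, self.varied_idx] = X
        return full


def build_parameter_space(base: ModelParameters | None = None,
                          fraction: float = 0.5) -> ParameterSpace:
    """The 36-dimensional input space of the global analysis.

    All chamber and circulation parameters vary except the ventricular
    activation shifts (identically zero); the period and initial volumes
    are fixed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if base is None:
        base = table1()
    theta = base.to_array()
    idx = np.array([PARAM_NAMES.index(n) for n in VARIED_PARAMETERS])
    b = theta[idx]
    if np.any(b == 0.0):
        zero = [VARIED_PARAMETERS[i] for i in np.flatnonzero(b == 0.0)]
        raise ValueError(f"zero-valued varied parameters {zero}: a "
                         f"relative box would be degenerate")
    lo = b * (1.0 - fraction)
    hi = b * (1.0 + fraction)
    return ParameterSpace(tuple(VARIED_PARAMETERS), b,
                          np.minimum(lo, hi), np.maximum(lo, hi),
                          theta, idx)


@dataclass(frozen=True)
class SobolDesign:
    """Pick-and-freeze sample: blocks A, B and column-substituted AB_i."""

    space: ParameterSpace
    N: int
    A: np.ndarray
    B: np.ndarray
    seed: int | None

    @property
    def n(self) -> int:
        return self.space.dimension

    @property
    def total_evaluations(self) -> int:
        return self.N * (self.n + 2)

    def AB(self, i: int) -> np.ndarray:
        M = self.A.copy()
        M[:, i] = self.B[:, i]
        return M


def sobol_matrices(space: ParameterSpace, N: int,
                   seed: int | None = None) -> SobolDesign:
    """Draw A and B by the Saltelli construction: one scrambled Sobol'
    sequence in 2n dimensions, columns split into the two blocks, mapped
    through the box (power-of-two N recommended).  Consecutive blocks of a
    single n-dimensional sequence would be deterministically coupled and
    break the pick-and-freeze estimators."""
    if N < 8:
        raise ValueError("N must be at least 8")
    n = space.dimension
    sampler = qmc.Sobol(d=2 * n, scramble=True, seed=seed)
    U = sampler.random(N)
    A = qmc.scale(U[:, :n], space.lower, space.upper)
    B = qmc.scale(U[:, n:], space.lower, space.upper)
    return SobolDesign(space, N, A, B, seed)


@dataclass
class EnsembleOutputs:
    """Model outputs across the pick-and-freeze sample.

    ``fA``/``fB`` have shape (N, m) and ``fAB`` shape (n, N, m); ``mask``
    marks paired-complete rows (every one of the n + 2 points of that row
    evaluated successfully).
    """

    fA: np.ndarray
    fB: np.ndarray
    fAB: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...]
    parameter_names: tuple[str, ...]

    @property
    def N(self) -> int:
        return self.fA.shape[0]

    @property
    def m(self) -> int:
        return self.fA.shape[1]

    @property
    def n(self) -> int:
        return self.fAB.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    @property
    def n_dropped(self) -> int:
        return self.N - self.n_retained

    def select(self, columns: Sequence[int],
               labels: Sequence[str] | None = None) -> "EnsembleOutputs":
        """A view on a subset of outputs (shared solves, new extraction)."""
        cols = np.asarray(columns)
        labs = tuple(labels) if labels is not None else tuple(
            self.labels[c] for c in cols)
        return EnsembleOutputs(self.fA[:, cols], self.fB[:, cols],
                               self.fAB[:, :, cols], self.mask, labs,
                               self.parameter_names)

    def output_variance(self) -> np.ndarray:
        """Pooled sample variance of f(A), f(B) per output (retained rows)."""
        pooled = np.concatenate([self.fA[self.mask], self.fB[self.mask]])
        return pooled.var(axis=0, ddof=1)


def _iter_rows(design: SobolDesign):
    """Canonical evaluation order: A block, B block, then AB_1..AB_n."""
    yield "A", None, design.A
    yield "B", None, design.B
    for i in range(design.n):
        yield "AB", i, design.AB(i)


def evaluate_function_ensemble(design: SobolDesign,
                               fn: Callable[[np.ndarray], np.ndarray],
                               labels: Sequence[str] | None = None,
                               ) -> EnsembleOutputs:
    """Evaluate a vectorised test function (rows -> (rows, m) or (rows,))
    over the design; no failures are possible on analytic functions."""
    out = {}
    for block, i, X in _iter_rows(design):
        vals = np.asarray(fn(X), dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        out[(block, i)] = vals
    m = out[("A", None)].shape[1]
    fAB = np.stack([out[("AB", i)] for i in range(design.n)])
    labs = tuple(labels) if labels is not None else tuple(
        f"y{j}" for j in range(m))
    mask = np.ones(design.N, dtype=bool)
    return EnsembleOutputs(out[("A", None)], out[("B", None)], fAB, mask,
                           labs, design.space.names)


def evaluate_ensemble(design: SobolDesign,
                      exp_design: ExperimentalDesign,
                      sim_config: SimulationConfig = SimulationConfig(),
                      rng: np.random.Generator | None = None,
                      *,
                      strict_timing: bool = False,
                      failure_floor: float = 0.9,
                      ef_denominator: str = "min",
                      progress: bool = False,
                      ) -> EnsembleOutputs:
    """One simulation + measurement evaluation per design point.

    Failures are recorded in the row mask and removed consistently across
    A, B and every AB_i (complete-case deletion).  Aborts with
    :class:`EnsembleRetentionError` when fewer than ``failure_floor`` of
    rows survive.
    """
    def output_fn(traj):
        res = evaluate_design(traj, exp_design, rng, ef_denominator)
        return None if isinstance(res, SimulationFailure) else res.values

    labels = tuple(exp_design.labels)
    return _evaluate_points(design, output_fn, exp_design.m, labels,
                            sim_config, strict_timing, failure_floor,
                            progress)


def _evaluate_points(design: SobolDesign,
                     output_fn: Callable,
                     m: int,
                     labels: tuple[str, ...],
                     sim_config: SimulationConfig,
                     strict_timing: bool,
                     failure_floor: float,
                     progress: bool) -> EnsembleOutputs:
    N, n = design.N, design.n
    fA = np.full((N, m), np.nan)
    fB = np.full((N, m), np.nan)
    fAB = np.full((n, N, m), np.nan)
    point_ok = {"A": np.zeros(N, bool), "B": np.zeros(N, bool)}
    ab_ok = np.zeros((n, N), bool)
    n_failed = 0

    iterator = _iter_rows(design)
    bar = None
    if progress:
        from tqdm import tqdm
        bar = tqdm(total=N * (n + 2), desc="model evaluations", unit="run")
    for block, i, X in iterator:
        full = design.space.expand(X)
        for r in range(N):
            params = ModelParameters.from_array(full[r])
            traj = simulate(params, sim_config, strict_timing=strict_timing)
            vals = output_fn(traj)
            if vals is None:
                n_failed += 1
            elif block == "A":
                fA[r] = vals
                point_ok["A"][r] = True
            elif block == "B":
                fB[r] = vals
                point_ok["B"][r] = True
            else:
                fAB[i, r] = vals
                ab_ok[i, r] = True
            if bar is not None:
                bar.update(1)
    if bar is not None:
        bar.close()

    mask = point_ok["A"] & point_ok["B"] & ab_ok.all(axis=0)
    retained = mask.mean()
    if retained < failure_floor:
        raise EnsembleRetentionError(
            f"only {retained:.1%} of rows are paired-complete "
            f"({n_failed} failed evaluations); floor is {failure_floor:.0%}")
    return EnsembleOutputs(fA, fB, fAB, mask, labels, design.space.names)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMatrix:
    """m x n matrix of Sobol indices with optional bootstrap CIs.

    Rows whose output had (numerically) zero variance are flagged in
    ``undefined_outputs`` and filled with NaN rather than silently zeroed.
    """

    values: np.ndarray
    order: str                              # 'first' | 'total'
    parameter_names: tuple[str, ...]
    output_labels: tuple[str, ...]
    n_effective: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    undefined_outputs: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.output_labels),
                            columns=list(self.parameter_names))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("output").to_csv(path)


_VAR_FLOOR = 1e-300


def _jansen_arrays(fA, fB, fAB):
    """Core Jansen formulas on already-masked arrays.

    fA, fB: (N', m); fAB: (n, N', m).  Returns (S1, ST, Vhat) with NaN
    columns where Vhat is zero.
    """
    Np = fA.shape[0]
    n, m = fAB.shape[0], fA.shape[1]
    pooled = np.concatenate([fA, fB])
    Vhat = pooled.var(axis=0, ddof=1)
    ok = Vhat > _VAR_FLOOR
    ST = np.empty((n, m))
    S1c = np.empty((n, m))
    for i in range(n):                    # per-parameter to bound memory
        d = fA - fAB[i]
        ST[i] = np.einsum("rm,rm->m", d, d) / (2.0 * Np)
        d = fB - fAB[i]
        S1c[i] = np.einsum("rm,rm->m", d, d) / (2.0 * Np)
    with np.errstate(divide="ignore", invalid="ignore"):
        ST = np.where(ok[None, :], ST / Vhat[None, :], np.nan)
        S1 = np.where(ok[None, :], 1.0 - S1c / Vhat[None, :], np.nan)
    return S1.T, ST.T, Vhat                  # -> (m, n)


def jansen_indices(outputs: EnsembleOutputs, clip: bool = True
                   ) -> tuple[SensitivityMatrix, SensitivityMatrix]:
    """First and total-order Jansen estimates over retained rows.

    Sobol indices are variance fractions and lie in [0, 1] by definition;
    with ``clip=True`` (default) finite-sample estimates outside that range
    are truncated to it.  This matters for heavy-tailed outputs such as
    diode-valve flows near their opening time, where the raw ratio
    estimator can exceed 1 by orders of magnitude long before convergence
    and would otherwise dominate any matrix built from the indices.
    """
    if outputs.n_retained < 2:
        raise ValueError("need at least 2 retained rows")
    msk = outputs.mask
    S1, ST, Vhat = _jansen_arrays(outputs.fA[msk], outputs.fB[msk],
                                  outputs.fAB[:, msk, :])
    if clip:
        S1 = np.clip(S1, 0.0, 1.0)
        ST = np.clip(ST, 0.0, 1.0)
    undef = np.flatnonzero(~(Vhat > _VAR_FLOOR))
    mk = lambda vals, order: SensitivityMatrix(
        vals, order, outputs.parameter_names, outputs.labels,
        outputs.n_retained, undefined_outputs=undef)
    return mk(S1, "first"), mk(ST, "total")


def bootstrap_ci(outputs: EnsembleOutputs, B: int = 1000,
                 seed: int | None = None, alpha: float = 0.05,
                 clip: bool = True,
                 ) -> tuple[SensitivityMatrix, SensitivityMatrix]:
    """Percentile bootstrap over retained rows (resampled with
    replacement); returns first/total matrices with CIs attached."""
    if B < 1:
        raise ValueError("B must be >= 1")
    S1_hat, ST_hat = jansen_indices(outputs, clip)
    msk = outputs.mask
    fA, fB, fAB = outputs.fA[msk], outputs.fB[msk], outputs.fAB[:, msk, :]
    Np = fA.shape[0]
    rng = np.random.default_rng(seed)
    S1_b = np.empty((B,) + S1_hat.values.shape)
    ST_b = np.empty_like(S1_b)
    for b in range(B):
        idx = rng.integers(0, Np, size=Np)
        S1_b[b], ST_b[b], _ = _jansen_arrays(fA[idx], fB[idx], fAB[:, idx, :])
    if clip:
        np.clip(S1_b, 0.0, 1.0, out=S1_b)
        np.clip(ST_b, 0.0, 1.0, out=ST_b)
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    S1_hat.ci_low, S1_hat.ci_high = np.nanpercentile(S1_b, qs, axis=0)
    ST_hat.ci_low, ST_hat.ci_high = np.nanpercentile(ST_b, qs, axis=0)
    return S1_hat, ST_hat


def time_averaged_sensitivity(S_rows: np.ndarray,
                              variances: np.ndarray) -> np.ndarray:
    """Variance-weighted time average of per-timepoint indices.

    ``S_rows`` is (T, n) for one waveform; ``variances`` the per-timepoint
    output variances.  Timepoints of zero variance receive zero weight; an
    all-zero variance vector is an error.
    """
    S_rows = np.asarray(S_rows, dtype=float)
    w = np.asarray(variances, dtype=float)
    if S_rows.shape[0] != w.shape[0]:
        raise ValueError("mismatched number of timepoints")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero variances: weighted average undefined")
    return (S_rows * w[:, None]).sum(axis=0) / total
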