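"""Iterative experimental-design sweep.

For each measurement set of a mode the workflow is: define the output set,
estimate the total-order sensitivity matrix over the +/-50% parameter box,
form the Fisher information F = S^T S, record the influence ranking and the
eigen-spectrum / sloppiness verdict, then move to the next set.

Because the parameter draws depend only on the space (not on the outputs),
the model solves can be shared across every set of a sweep: one ensemble is
evaluated on the union of all requested measurements and each set is then a
column extraction.  This "shared-ensemble" mode is on by default; a strict
per-set resampling mode exists for independence checks.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cardiac_model import SimulationConfig, table1
from .gsa import (EnsembleOutputs, SobolDesign, bootstrap_ci,
                  build_parameter_space, evaluate_ensemble, jansen_indices,
                  sobol_matrices)
from .measurements import (ExperimentalDesign, MeasurementSpec, MODES,
                           design_library)
from .sloppiness import (InfluenceRanking, SloppinessVerdict,
                         classify_sloppiness, eigenspectrum,
                         fisher_information, influence_scores)

__all__ = [
    "SweepConfig",
    "SetResult",
    "SweepResult",
    "superset_design",
    "design_columns",
    "analyse_design",
    "run_sweep",
    "influence_table",
    "spectrum_export",
]


@dataclass(frozen=True)
class SweepConfig:
    """A sweep is a pure function of this configuration."""

    mode: str = "discrete"
    sets: tuple[str, ...] | None = None       # None = all sets in mode order
    N: int = 1024
    seed: int = 0
    waveform_points: int = 150
    bootstrap_B: int = 0
    fraction: float = 0.5
    n_cycles: int = 30
    rel_tol: float = 1e-6
    abs_tol: float = 1e-6
    bpn_noise_sd: float = 0.1
    shared_ensemble: bool = True
    strict_timing: bool = False
    failure_floor: float = 0.9
    out_dir: str | None = None
    progress: bool = False

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(n_cycles=self.n_cycles,
                                rel_tol=self.rel_tol, abs_tol=self.abs_tol,
                                waveform_points=self.waveform_points)


@dataclass
class SetResult:
    set_id: str
    mode: str
    m: int
    ranking: InfluenceRanking
    eigenvalues: np.ndarray
    verdict: SloppinessVerdict
    n_retained: int
    runtime_s: float
    error: str | None = None

    @property
    def span_decades(self) -> float:
        pos = self.eigenvalues[self.eigenvalues > 0]
        if pos.size < 2:
            return 0.0
        return float(np.log10(pos.max() / pos.min()))


@dataclass
class SweepResult:
    config: SweepConfig
    sets: list[SetResult]

    def get(self, set_id: str) -> SetResult:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


# ---------------------------------------------------------------------------
# Shared-ensemble plumbing
# ---------------------------------------------------------------------------

def superset_design(designs: list[ExperimentalDesign]
                    ) -> ExperimentalDesign:
    """Union of all specs across designs, in first-appearance order."""
    seen: dict[MeasurementSpec, None] = {}
    for d in designs:
        for s in d.specs:
            seen.setdefault(s, None)
    return ExperimentalDesign("shared", "superset", tuple(seen))


def design_columns(design: ExperimentalDesign,
                   superset: ExperimentalDesign) -> np.ndarray:
    """Column indices of a design's outputs inside the superset vector."""
    offsets = {}
    pos = 0
    for s in superset.specs:
        offsets[s] = pos
        pos += s.dimension
    cols = []
    for s in design.specs:
        o = offsets[s]
        cols.extend(range(o, o + s.dimension))
    return np.asarray(cols, dtype=int)


def analyse_design(outputs: EnsembleOutputs, design: ExperimentalDesign,
                   superset: ExperimentalDesign | None = None,
                   bootstrap_B: int = 0, bootstrap_seed: int | None = None,
                   ) -> SetResult:
    """Total-order indices -> FIM -> influence + sloppiness for one set."""
    t0 = time.perf_counter()
    if superset is not None:
        cols = design_columns(design, superset)
        outputs = outputs.select(cols, design.labels)
    if bootstrap_B > 0:
        _, ST = bootstrap_ci(outputs, bootstrap_B, bootstrap_seed)
    else:
        _, ST = jansen_indices(outputs)
    fim = fisher_information(ST, provenance=f"{design.mode}:{design.set_id}")
    spec = eigenspectrum(fim)
    ranking = influence_scores(spec, set_id=design.set_id)
    verdict = classify_sloppiness(spec)
    return SetResult(design.set_id, design.mode, design.m, ranking,
                     spec.eigenvalues.copy(), verdict, outputs.n_retained,
                     time.perf_counter() - t0)


def build_shared_ensemble(designs: list[ExperimentalDesign],
                          sobol: SobolDesign,
                          sim_config: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          *, strict_timing: bool = False,
                          failure_floor: float = 0.9,
                          progress: bool = False,
                          ) -> tuple[EnsembleOutputs, ExperimentalDesign]:
    """Evaluate one ensemble on the union of the designs' measurements."""
    sup = superset_design(designs)
    out = evaluate_ensemble(sobol, sup, sim_config, rng,
                            strict_timing=strict_timing,
                            failure_floor=failure_floor, progress=progress)
    return out, sup


# ---------------------------------------------------------------------------
# Sweep driver
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, k: int) -> list[int]:
    """Independent sub-seeds, kept below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(k)]


def run_sweep(config: SweepConfig) -> SweepResult:
    """Execute the design loop for one mode; per-set failures are recorded
    and the sweep continues.  Artefacts are written incrementally when
    ``out_dir`` is set."""
    if config.mode not in MODES:
        raise ValueError(f"unknown mode {config.mode!r}")
    library = design_library(config.mode, config.waveform_points,
                             config.bpn_noise_sd)
    if config.sets is not None:
        by_id = {d.set_id: d for d in library}
        missing = [s for s in config.sets if s not in by_id]
        if missing:
            raise KeyError(f"unknown sets {missing} in mode {config.mode}")
        designs = [by_id[s] for s in config.sets]
    else:
        designs = library

    sobol_seed, rng_seed, boot_seed = _child_seeds(config.seed, 3)
    space = build_parameter_space(table1(), config.fraction)
    sobol = sobol_matrices(space, config.N, sobol_seed)
    sim_config = config.sim_config()
    rng = np.random.default_rng(rng_seed)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: list[SetResult] = []
    shared = None
    superset = None
    if config.shared_ensemble:
        shared, superset = build_shared_ensemble(
            designs, sobol, sim_config, rng,
            strict_timing=config.strict_timing,
            failure_floor=config.failure_floor, progress=config.progress)

    for d in designs:
        try:
            if config.shared_ensemble:
                res = analyse_design(shared, d, superset,
                                     config.bootstrap_B, boot_seed)
            else:
                out = evaluate_ensemble(sobol, d, sim_config, rng,
                                        strict_timing=config.strict_timing,
                                        failure_floor=config.failure_floor,
                                        progress=config.progress)
                res = analyse_design(out, d, None,
                                     config.bootstrap_B, boot_seed)
        except Exception as exc:  # per-set failure: record and continue
            res = SetResult(d.set_id, d.mode, d.m,
                            InfluenceRanking(np.zeros(sobol.n),
                                             space.names, d.set_id),
                            np.zeros(0), SloppinessVerdict(
                                False, 0.0, np.nan, np.zeros(0), 0,
                                "analysis failed"),
                            0, 0.0, error=f"{type(exc).__name__}: {exc}")
        results.append(res)
        if out_dir:
            _write_artifacts(SweepResult(config, results), out_dir)

    sweep = SweepResult(config, results)
    if out_dir:
        _write_artifacts(sweep, out_dir)
    return sweep


# ---------------------------------------------------------------------------
# Artefacts
# ---------------------------------------------------------------------------

def influence_table(result: SweepResult):
    """Wide per-set table of (parameter, E) pairs in decreasing influence,
    2-decimal rendering, one pair of columns per set (empty sets keep
    their header)."""
    import pandas as pd

    blocks = []
    depth = max((s.ranking.n_influential for s in result.sets if not s.error),
                default=0)
    for s in result.sets:
        rows = [] if s.error else s.ranking.ordered
        names = [n for n, _ in rows] + [""] * (depth - len(rows))
        vals = [f"{e:.2f}" for _, e in rows] + [""] * (depth - len(rows))
        blocks.append(pd.DataFrame({f"P_{s.set_id}": names,
                                    f"E_{s.set_id}": vals}))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame()


def spectrum_export(result: SweepResult):
    """Long-format eigen-spectrum table (set, eigen-rank, value, log10)."""
    import pandas as pd

    rows = []
    for s in result.sets:
        for k, lam in enumerate(s.eigenvalues, start=1):
            rows.append({"set": s.set_id, "eigen_rank": k,
                         "eigenvalue": lam,
                         "log10": np.log10(lam) if lam > 0 else np.nan})
    return pd.DataFrame(rows)


def plot_spectrum(result: SweepResult, path: str | Path) -> None:
    """Log-scale eigenvalue strip plot, one column per measurement set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(result.sets), 4.5))
    for x, s in enumerate(result.sets):
        lam = s.eigenvalues[s.eigenvalues > 0]
        ax.plot(np.full(lam.size, x), lam, "_", markersize=14)
    ax.set_yscale("log")
    ax.set_xticks(range(len(result.sets)))
    ax.set_xticklabels([s.set_id for s in result.sets])
    ax.set_xlabel("measurement set")
    ax.set_ylabel("FIM eigenvalue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _write_artifacts(result: SweepResult, out_dir: Path) -> None:
    mode = result.config.mode
    influence_table(result).to_csv(out_dir / f"influence_{mode}.csv",
                                   index=False)
    spectrum_export(result).to_csv(out_dir / f"eigenvalues_{mode}.csv",
                                   index=False)
    diag = {
        "config": {k: v for k, v in dataclasses.asdict(
            result.config).items()},
        "sets": [{
            "set_id": s.set_id, "m": s.m, "n_retained": s.n_retained,
            "n_influential": None if s.error else s.ranking.n_influential,
            "sloppy": s.verdict.label, "span_decades": s.verdict.span_decades,
            "void_fraction": s.verdict.void_fraction,
            "full_span_decades": s.span_decades,
            "runtime_s": s.runtime_s, "error": s.error,
        } for s in result.sets],
    }
    (out_dir / "diagnostics.json").write_text(json.dumps(diag, indent=1))
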