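"""Clinical measurement metrics and the additive experimental-design library.

A measurement set (experimental design) is an ordered list of specs drawn
from five kinds:

* ``BP``   - systolic/diastolic arterial pressure ratio max(P_sa)/min(P_sa),
  a single scalar (the dimension bookkeeping of the discrete library forces
  the one-dimensional ratio reading);
* ``BPN``  - the same ratio with multiplicative Gaussian noise (1 + eps),
  emulating a noisy at-home cuff reading;
* ``EF``   - chamber ejection fraction (max(V) - min(V)) / min(V).  The
  minimum-volume denominator is kept as-is; clinical EF divides by the
  maximum, and a config switch is provided;
* ``MaxQ`` - peak of a flow signal over the cycle;
* ``waveform`` - a full signal sampled at ``n_points`` uniform times over
  the extraction cycle (half-open grid).

Designs grow additively: each set in a mode's sequence contains every
earlier measurement plus one new one, except mixed set 2 (noise-free BP)
which replaces set 1 (BPN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac_model import (FLOW_LABELS, PRESSURE_LABELS, SimulationFailure,
                            Trajectory, VOLUME_LABELS)

__all__ = [
    "MeasurementSpec",
    "ExperimentalDesign",
    "OutputVector",
    "waveform_sample",
    "blood_pressure_metric",
    "noisy_blood_pressure",
    "ejection_fraction",
    "max_flow",
    "design_library",
    "evaluate_design",
    "MODES",
    "WAVEFORM_SIGNALS",
]

MODES = ("discrete", "continuous", "mixed")

#: The 16 waveform signals of the continuous library, in invasiveness order.
WAVEFORM_SIGNALS = ("Q_s", "Q_p", "Q_lv", "Q_la", "Q_rv", "Q_ra",
                    "V_lv", "V_rv", "V_la", "V_ra",
                    "P_lv", "P_sa", "P_rv", "P_pa", "P_ra", "P_pv")

_EF_TARGETS = ("lv", "rv", "la", "ra")


@dataclass(frozen=True)
class MeasurementSpec:
    kind: str                  # BP | BPN | EF | MaxQ | waveform
    target: str                # compartment / valve / signal label
    n_points: int = 1          # waveform only
    noise_sd: float = 0.0      # BPN only (relative sd)

    def __post_init__(self):
        if self.kind in ("BP", "BPN"):
            if self.target != "sa":
                raise ValueError("BP/BPN read the systemic arterial pressure")
        elif self.kind == "EF":
            if self.target not in _EF_TARGETS:
                raise ValueError(f"EF target must be a chamber, got "
                                 f"{self.target!r}")
        elif self.kind == "MaxQ":
            if self.target not in FLOW_LABELS:
                raise ValueError(f"MaxQ target must be a flow, got "
                                 f"{self.target!r}")
        elif self.kind == "waveform":
            k, _, comp = self.target.partition("_")
            valid = (k == "V" and comp in VOLUME_LABELS) or \
                    (k == "P" and comp in PRESSURE_LABELS) or \
                    (k == "Q" and comp in FLOW_LABELS)
            if not valid:
                raise ValueError(f"unknown waveform signal {self.target!r}")
            if self.n_points < 2:
                raise ValueError("waveform needs n_points >= 2")
        else:
            raise ValueError(f"unknown measurement kind {self.kind!r}")

    @property
    def dimension(self) -> int:
        return self.n_points if self.kind == "waveform" else 1

    @property
    def name(self) -> str:
        if self.kind in ("BP", "BPN"):
            return self.kind
        if self.kind == "EF":
            return f"EF_{self.target}"
        if self.kind == "MaxQ":
            return f"MaxQ_{self.target}"
        return self.target


@dataclass(frozen=True)
class ExperimentalDesign:
    """One measurement set: its mode, table label and cumulative specs."""

    mode: str
    set_id: str
    specs: tuple[MeasurementSpec, ...]

    @property
    def m(self) -> int:
        """Total output dimension."""
        return sum(s.dimension for s in self.specs)

    @property
    def labels(self) -> list[str]:
        out = []
        for s in self.specs:
            if s.kind == "waveform":
                out += [f"{s.name}[{k}]" for k in range(s.n_points)]
            else:
                out.append(s.name)
        return out

    def __repr__(self):
        return (f"ExperimentalDesign({self.mode}:{self.set_id}, "
                f"m={self.m}, specs={[s.name for s in self.specs]})")


@dataclass(frozen=True)
class OutputVector:
    values: np.ndarray
    labels: tuple[str, ...]
    design: ExperimentalDesign

    def __post_init__(self):
        if len(self.values) != len(self.labels):
            raise ValueError("values/labels length mismatch")

    def to_csv(self, path) -> None:
        lines = ["label,value"]
        lines += [f"{l},{v!r}" for l, v in zip(self.labels, self.values)]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def waveform_sample(traj: Trajectory, signal: str, n_points: int
                    ) -> np.ndarray:
    """Sample a signal over the extraction cycle.

    The grid is half-open: n_points uniform samples on [t0, t0 + tau), the
    period-start sample included once.  When n_points matches the stored
    per-cycle resolution the solver samples are returned directly;
    otherwise the stored cycle (including its closing endpoint) is linearly
    interpolated.
    """
    sl = traj.extraction_slice()
    series = traj.signal(signal)
    if n_points == traj.config.waveform_points:
        return series[sl].copy()
    t = traj.time
    t0 = t[sl.start]
    tau = traj.params.tau
    # stored cycle plus its closing sample (always present on the grid)
    xs = t[sl.start:sl.stop + 1] - t0
    ys = series[sl.start:sl.stop + 1]
    grid = np.arange(n_points) * (tau / n_points)
    return np.interp(grid, xs, ys)


def blood_pressure_metric(P_sa: np.ndarray) -> float:
    """max/min ratio of the systemic arterial pressure over a cycle."""
    P_sa = np.asarray(P_sa, dtype=float)
    if P_sa.size == 0:
        raise ValueError("empty pressure series")
    lo = P_sa.min()
    if lo <= 0:
        raise ValueError("nonpositive arterial pressure minimum")
    return float(P_sa.max() / lo)


def noisy_blood_pressure(bp: float, noise_sd: float,
                         rng: np.random.Generator) -> float:
    """bp * (1 + eps) with eps ~ N(0, noise_sd); reproducible under seed."""
    if bp <= 0:
        raise ValueError("blood pressure metric must be positive")
    eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    return bp * (1.0 + eps)


def ejection_fraction(V: np.ndarray, denominator: str = "min") -> float:
    """(max(V) - min(V)) / min(V) over a cycle.

    ``denominator='max'`` switches to the conventional clinical definition
    (stroke volume over end-diastolic volume).
    """
    V = np.asarray(V, dtype=float)
    lo, hi = V.min(), V.max()
    if lo <= 0:
        raise ValueError("nonpositive volume minimum")
    den = lo if denominator == "min" else hi
    return float((hi - lo) / den)


def max_flow(Q: np.ndarray) -> float:
    Q = np.asarray(Q, dtype=float)
    if Q.size == 0:
        raise ValueError("empty flow series")
    return float(Q.max())


# ---------------------------------------------------------------------------
# Design library
# ---------------------------------------------------------------------------

def _bp():
    return MeasurementSpec("BP", "sa")


def _bpn(noise_sd):
    return MeasurementSpec("BPN", "sa", noise_sd=noise_sd)


def _ef(c):
    return MeasurementSpec("EF", c)


def _maxq(f):
    return MeasurementSpec("MaxQ", f)


def _wf(sig, n):
    return MeasurementSpec("waveform", sig, n_points=n)


def _cumulative(mode, seq):
    designs, acc = [], []
    for set_id, spec in seq:
        acc.append(spec)
        designs.append(ExperimentalDesign(mode, set_id, tuple(acc)))
    return designs


def design_library(mode: str, waveform_points: int = 150,
                   bpn_noise_sd: float = 0.1) -> list[ExperimentalDesign]:
    """The full additive measurement-set sequence for one mode.

    Discrete: 11 sets ending at 3F (m = 11).  Continuous: 16 waveform sets
    ending at 4D (m = 16 * waveform_points).  Mixed: 26 sets ending at 7D;
    set 2 (noise-free BP) replaces set 1 (BPN), everything else accumulates.
    """
    if mode == "discrete":
        seq = [("1", _bp())]
        seq += [(f"2{s}", _ef(c)) for s, c in zip("ABCD", _EF_TARGETS)]
        seq += [(f"3{s}", _maxq(f))
                for s, f in zip("ABCDEF", ("s", "p", "lv", "la", "rv", "ra"))]
        return _cumulative(mode, seq)

    if mode == "continuous":
        wp = waveform_points
        seq = [(f"1{s}", _wf(sig, wp))
               for s, sig in zip("ABCDEF", WAVEFORM_SIGNALS[:6])]
        seq += [(f"2{s}", _wf(sig, wp))
                for s, sig in zip("ABCD", WAVEFORM_SIGNALS[6:10])]
        seq += [(f"3{s}", _wf(sig, wp))
                for s, sig in zip("AB", WAVEFORM_SIGNALS[10:12])]
        seq += [(f"4{s}", _wf(sig, wp))
                for s, sig in zip("ABCD", WAVEFORM_SIGNALS[12:16])]
        return _cumulative(mode, seq)

    if mode == "mixed":
        wp = waveform_points
        designs = [ExperimentalDesign(mode, "1", (_bpn(bpn_noise_sd),))]
        # set 2 replaces the noisy reading with the in-hospital one
        acc = [_bp()]
        designs.append(ExperimentalDesign(mode, "2", tuple(acc)))
        seq = [(f"3{s}", _ef(c)) for s, c in zip("ABCD", _EF_TARGETS)]
        seq += [(f"4{s}", _wf(sig, wp))
                for s, sig in zip("ABCDEF", WAVEFORM_SIGNALS[:6])]
        seq += [(f"5{s}", _maxq(f))
                for s, f in zip("ABCD", ("lv", "la", "rv", "ra"))]
        # 5E-5H: chamber volume waveforms (5H is the left atrium, completing
        # the four chambers; 6A is the left ventricular pressure, the first
        # catheter measurement, with 6B the systemic arterial pressure)
        seq += [(f"5{s}", _wf(sig, wp))
                for s, sig in zip("EFGH", ("V_lv", "V_rv", "V_ra", "V_la"))]
        seq += [(f"6{s}", _wf(sig, wp)) for s, sig in zip("AB",
                                                          ("P_lv", "P_sa"))]
        seq += [(f"7{s}", _wf(sig, wp))
                for s, sig in zip("ABCD", ("P_rv", "P_pa", "P_ra", "P_pv"))]
        for set_id, spec in seq:
            acc.append(spec)
            designs.append(ExperimentalDesign(mode, set_id, tuple(acc)))
        return designs

    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def get_design(mode: str, set_id: str, waveform_points: int = 150,
               **kw) -> ExperimentalDesign:
    for d in design_library(mode, waveform_points, **kw):
        if d.set_id == set_id:
            return d
    raise KeyError(f"no set {set_id!r} in mode {mode!r}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_design(traj: Trajectory | SimulationFailure,
                    design: ExperimentalDesign,
                    rng: np.random.Generator | None = None,
                    ef_denominator: str = "min",
                    ) -> OutputVector | SimulationFailure:
    """Measurement function: map a steady-state trajectory to the ordered
    output vector of a design.  Only BPN consumes the rng; with
    ``noise_sd = 0`` the result is bit-identical with or without one.
    A failed trajectory propagates as its failure record."""
    if isinstance(traj, SimulationFailure):
        return traj
    values = np.empty(design.m)
    pos = 0
    for spec in design.specs:
        if spec.kind in ("BP", "BPN"):
            wp = traj.config.waveform_points
            bp = blood_pressure_metric(waveform_sample(traj, "P_sa", wp))
            if spec.kind == "BPN" and spec.noise_sd > 0:
                if rng is None:
                    raise ValueError("BPN with noise requires an rng")
                bp = noisy_blood_pressure(bp, spec.noise_sd, rng)
            values[pos] = bp
            pos += 1
        elif spec.kind == "EF":
            wp = traj.config.waveform_points
            v = waveform_sample(traj, f"V_{spec.target}", wp)
            values[pos] = ejection_fraction(v, ef_denominator)
            pos += 1
        elif spec.kind == "MaxQ":
            wp = traj.config.waveform_points
            q = waveform_sample(traj, f"Q_{spec.target}", wp)
            values[pos] = max_flow(q)
            pos += 1
        else:
            values[pos:pos + spec.n_points] = waveform_sample(
                traj, spec.target, spec.n_points)
            pos += spec.n_points
    return OutputVector(values, tuple(design.labels), design)
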