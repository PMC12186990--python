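"""Closed-loop four-chamber lumped-parameter cardiovascular model.

The heart is modelled as four time-varying-elastance chambers (Shi double
cosine activation) connected by Ohmic diode valves; the systemic and
pulmonary circulations are CRRCR chains (arterial compliance - arterial
resistance - vascular-bed resistance - venous compliance - venous
resistance).  Eliminating the algebraic pressure/flow relations reduces the
system to 8 ordinary differential equations in compartment volume, which are
integrated with an adaptive Dormand-Prince 5(4) scheme compiled with numba
(scipy's DOP853 serves as an independent cross-check in the test suite).

Compartment labels: lv, rv, la, ra (chambers), sa, sv, pa, pv (passive
compliance nodes) plus the algebraic mid-nodes svb, pvb of the vascular
beds.  Pressures are in mmHg, volumes in mL, flows in mL/s, times in s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ChamberParameters",
    "CirculationParameters",
    "ModelParameters",
    "SimulationConfig",
    "Trajectory",
    "SimulationFailure",
    "InvalidTimingError",
    "activation",
    "elastance",
    "chamber_pressure",
    "valve_flow",
    "state_derivative",
    "simulate",
    "periodicity_residual",
    "table1",
    "PARAM_NAMES",
    "VARIED_PARAMETERS",
    "VOLUME_LABELS",
    "PRESSURE_LABELS",
    "FLOW_LABELS",
    "TAU",
]

# Fixed cardiac period (s).
TAU = 0.81

VOLUME_LABELS = ("lv", "rv", "la", "ra", "sa", "sv", "pa", "pv")
PRESSURE_LABELS = ("lv", "rv", "la", "ra", "sa", "svb", "sv", "pa", "pvb", "pv")
FLOW_LABELS = ("lv", "la", "rv", "ra", "s", "p")

_CHAMBER_FIELDS = ("E_max", "E_min", "V0", "tau_es", "tau_ep", "E_shift", "R_valve")
_CHAMBERS = ("lv", "rv", "la", "ra")
_CIRC_FIELDS = ("R_sa", "R_svb", "R_sv", "R_pa", "R_pvb", "R_pv",
                "C_sa", "C_sv", "C_pa", "C_pv")

#: Canonical ordering of the 38 model parameters in the flat vector handed
#: to the compiled right-hand side.
PARAM_NAMES: tuple[str, ...] = tuple(
    f"{f}_{c}" for c in _CHAMBERS for f in _CHAMBER_FIELDS
) + _CIRC_FIELDS

#: The 36 parameters varied in the global analysis: everything except the
#: ventricular activation shifts, which are identically zero.
VARIED_PARAMETERS: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n not in ("E_shift_lv", "E_shift_rv")
)

_UNITS = {}
for _c in _CHAMBERS:
    _UNITS.update({
        f"E_max_{_c}": "mmHg/mL", f"E_min_{_c}": "mmHg/mL",
        f"V0_{_c}": "mL", f"tau_es_{_c}": "s", f"tau_ep_{_c}": "s",
        f"E_shift_{_c}": "fraction of tau", f"R_valve_{_c}": "mmHg.s/mL",
    })
for _n in _CIRC_FIELDS:
    _UNITS[_n] = "mmHg.s/mL" if _n.startswith("R") else "mL/mmHg"


class InvalidTimingError(ValueError):
    """Raised when an activation is requested with tau_ep <= tau_es."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberParameters:
    """Time-varying elastance chamber with an Ohmic diode outflow valve.

    ``E_max``/``E_min`` (mmHg/mL) bound the elastance cycle, ``V0`` (mL) is
    the unstressed volume, ``tau_es``/``tau_ep`` (s) the end-systolic and
    end-pulse activation times, ``E_shift`` the activation shift as a
    fraction of the cardiac period, and ``R_valve`` (mmHg.s/mL) the
    resistance of the valve at the chamber outflow.
    """

    E_max: float
    E_min: float
    V0: float
    tau_es: float
    tau_ep: float
    E_shift: float
    R_valve: float

    def validate(self, tau: float = TAU) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        bad = []
        if not (self.E_max >= self.E_min > 0):
            bad.append("requires E_max >= E_min > 0")
        if self.V0 < 0:
            bad.append("requires V0 >= 0")
        if self.R_valve <= 0:
            bad.append("requires R_valve > 0")
        if not (0 < self.tau_es < self.tau_ep <= tau):
            bad.append("requires 0 < tau_es < tau_ep <= tau")
        return bad


@dataclass(frozen=True)
class CirculationParameters:
    """Resistances (mmHg.s/mL) and compliances (mL/mmHg) of the systemic
    and pulmonary CRRCR chains."""

    R_sa: float
    R_svb: float
    R_sv: float
    R_pa: float
    R_pvb: float
    R_pv: float
    C_sa: float
    C_sv: float
    C_pa: float
    C_pv: float

    def validate(self) -> list[str]:
        return [f"requires {n} > 0" for n in _CIRC_FIELDS
                if getattr(self, n) <= 0]


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterisation: four chambers, the circulation, the fixed
    period ``tau`` and the 8 initial compartment volumes (mL, in
    ``VOLUME_LABELS`` order).  The initial volumes are treated as stressed
    volumes, so passive pressures start at V(0)/C."""

    lv: ChamberParameters
    rv: ChamberParameters
    la: ChamberParameters
    ra: ChamberParameters
    circulation: CirculationParameters
    tau: float = TAU
    initial_volumes: tuple[float, ...] = ()

    @property
    def total_volume(self) -> float:
        """Total blood volume (mL): the conserved quantity of the loop."""
        return float(sum(self.initial_volumes))

    def chamber(self, label: str) -> ChamberParameters:
        return getattr(self, label)

    def to_array(self) -> np.ndarray:
        """Flat length-38 vector in ``PARAM_NAMES`` order."""
        vals = []
        for c in _CHAMBERS:
            ch = getattr(self, c)
            vals.extend(getattr(ch, f) for f in _CHAMBER_FIELDS)
        vals.extend(getattr(self.circulation, n) for n in _CIRC_FIELDS)
        return np.asarray(vals, dtype=np.float64)

    @classmethod
    def from_array(cls, theta: np.ndarray, tau: float = TAU,
                   initial_volumes: tuple[float, ...] | None = None,
                   ) -> "ModelParameters":
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (38,):
            raise ValueError(f"expected 38 parameters, got {theta.shape}")
        chambers = {}
        for i, c in enumerate(_CHAMBERS):
            o = 7 * i
            chambers[c] = ChamberParameters(*theta[o:o + 7])
        circ = CirculationParameters(*theta[28:38])
        if initial_volumes is None:
            initial_volumes = table1().initial_volumes
        return cls(**chambers, circulation=circ, tau=tau,
                   initial_volumes=tuple(initial_volumes))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_array().tolist()))

    def validate(self) -> list[str]:
        """All invariant violations, prefixed by the offending component."""
        bad = []
        for c in _CHAMBERS:
            bad += [f"{c}: {m}" for m in getattr(self, c).validate(self.tau)]
        bad += self.circulation.validate()
        if len(self.initial_volumes) != 8:
            bad.append("requires 8 initial volumes")
        return bad

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {"parameters": self.to_dict(), "tau": self.tau,
                   "initial_volumes": dict(zip(VOLUME_LABELS,
                                               self.initial_volumes)),
                   "units": _UNITS}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        theta = np.array([payload["parameters"][n] for n in PARAM_NAMES])
        vols = tuple(payload["initial_volumes"][k] for k in VOLUME_LABELS)
        return cls.from_array(theta, tau=payload.get("tau", TAU),
                              initial_volumes=vols)

    def to_csv(self, path: str | Path) -> None:
        lines = ["name,value,unit"]
        lines += [f"{n},{v!r},{_UNITS[n]}" for n, v in self.to_dict().items()]
        lines += [f"V_init_{k},{v!r},mL"
                  for k, v in zip(VOLUME_LABELS, self.initial_volumes)]
        lines.append(f"tau,{self.tau!r},s")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModelParameters":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        df = df.set_index("name")["value"]
        theta = np.array([df[n] for n in PARAM_NAMES])
        vols = tuple(float(df[f"V_init_{k}"]) for k in VOLUME_LABELS)
        return cls.from_array(theta, tau=float(df.get("tau", TAU)),
                              initial_volumes=vols)


def table1() -> ModelParameters:
    """Baseline physiological parameterisation (fixed period tau = 0.81 s).

    Timing parameters are stored in seconds (fraction of the cycle times
    tau); activation shifts are dimensionless fractions of the cycle.
    """
    def ch(emax, emin, v0, fes, fep, shift, rv):
        return ChamberParameters(emax, emin, v0, fes * TAU, fep * TAU,
                                 shift, rv)

    return ModelParameters(
        lv=ch(2.8, 0.07, 20.0, 0.269, 0.452, 0.0, 0.01),
        rv=ch(0.45, 0.035, 30.0, 0.269, 0.452, 0.0, 0.01),
        la=ch(0.13, 0.09, 3.0, 0.11, 0.18, 0.85, 0.005),
        ra=ch(0.09, 0.045, 7.0, 0.11, 0.18, 0.85, 0.005),
        circulation=CirculationParameters(
            R_sa=0.0448, R_svb=0.824, R_sv=0.0269,
            R_pa=0.003, R_pvb=0.0552, R_pv=0.0018,
            C_sa=0.983, C_sv=29.499, C_pa=6.7, C_pv=15.8),
        tau=TAU,
        # lv, rv, la, ra, sa, sv, pa, pv
        initial_volumes=(149.6, 189.2, 71.0, 67.0,
                         98.3, 117.996, 100.5, 126.4),
    )


# ---------------------------------------------------------------------------
# Elementary relations (validated scalar API)
# ---------------------------------------------------------------------------

def activation(t_tilde: float, tau_es: float, tau_ep: float,
               tau: float = TAU) -> float:
    """Double-cosine chamber activation e(t~) in [0, 1].

    Rises as (1-cos)/2 on [0, tau_es), relaxes as (1+cos)/2 on
    [tau_es, tau_ep) and is 0 on [tau_ep, tau).
    """
    if tau_ep <= tau_es:
        raise InvalidTimingError(
            f"tau_ep ({tau_ep}) must exceed tau_es ({tau_es})")
    return _activation(t_tilde, tau_es, tau_ep)


def elastance(t: float, chamber: ChamberParameters, tau: float = TAU) -> float:
    """Chamber elastance E(t) (mmHg/mL), periodic with period tau.

    The activation argument is t~ = mod(t + (1 - E_shift) * tau, tau), so a
    shift of 0.85 delays the activation peak by 0.85 of a cycle.
    """
    if chamber.tau_ep <= chamber.tau_es:
        raise InvalidTimingError(
            f"tau_ep ({chamber.tau_ep}) must exceed tau_es ({chamber.tau_es})")
    t_tilde = math.fmod(t + (1.0 - chamber.E_shift) * tau, tau)
    if t_tilde < 0.0:
        t_tilde += tau
    e = _activation(t_tilde, chamber.tau_es, chamber.tau_ep)
    return (chamber.E_max - chamber.E_min) * e + chamber.E_min


def chamber_pressure(V: float, t: float, chamber: ChamberParameters,
                     tau: float = TAU) -> float:
    """P = E(t) * (V - V0) (mmHg); negative when V < V0."""
    return elastance(t, chamber, tau) * (V - chamber.V0)


def valve_flow(P_up: float, P_down: float, R: float) -> float:
    """Ohmic diode valve: (P_up - P_down)/R forward, zero backward."""
    return (P_up - P_down) / R if P_up > P_down else 0.0


def state_derivative(t: float, V_vector: np.ndarray,
                     params: ModelParameters) -> np.ndarray:
    """dV/dt (mL/s) for the 8 compartment volumes; sums to zero exactly."""
    V = np.asarray(V_vector, dtype=np.float64)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite volume state")
    dV = np.empty(8)
    P = np.empty(10)
    Q = np.empty(6)
    _rhs(t, V, params.to_array(), params.tau, dV, P, Q)
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite pressure")
    return dV


# ---------------------------------------------------------------------------
# Compiled right-hand side and integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _activation(t_tilde, tau_es, tau_ep):
    # Ordered branches: still well defined when tau_ep <= tau_es (the
    # relaxation branch is then empty and e drops to 0 at tau_es).
    if t_tilde < tau_es:
        return 0.5 * (1.0 - math.cos(math.pi * t_tilde / tau_es))
    elif t_tilde < tau_ep:
        return 0.5 * (1.0 + math.cos(math.pi * (t_tilde - tau_es)
                                     / (tau_ep - tau_es)))
    return 0.0


@njit(cache=True)
def _rhs(t, V, theta, tau, dV, P, Q):
    """Volume-formulation RHS; also fills the 10 pressures and 6 flows.

    P order: lv rv la ra sa svb sv pa pvb pv.  Q order: lv la rv ra s p
    (aortic, mitral, pulmonary, tricuspid valves; systemic and pulmonary
    vascular-bed flows).
    """
    # Chamber pressures P = E(t) (V - V0)
    for c in range(4):
        o = 7 * c
        E_max = theta[o]
        E_min = theta[o + 1]
        V0 = theta[o + 2]
        tau_es = theta[o + 3]
        tau_ep = theta[o + 4]
        shift = theta[o + 5]
        tt = (t + (1.0 - shift) * tau) % tau
        e = _activation(tt, tau_es, tau_ep)
        P[c] = ((E_max - E_min) * e + E_min) * (V[c] - V0)
    P_lv, P_rv, P_la, P_ra = P[0], P[1], P[2], P[3]
    R_lv = theta[6]
    R_rv = theta[13]
    R_la = theta[20]
    R_ra = theta[27]
    R_sa = theta[28]
    R_svb = theta[29]
    R_sv = theta[30]
    R_pa = theta[31]
    R_pvb = theta[32]
    R_pv = theta[33]
    # Passive node pressures from stressed volumes
    P_sa = V[4] / theta[34]
    P_sv = V[5] / theta[35]
    P_pa = V[6] / theta[36]
    P_pv = V[7] / theta[37]
    # Diode valves
    Q_lv = (P_lv - P_sa) / R_lv if P_lv > P_sa else 0.0   # aortic
    Q_la = (P_la - P_lv) / R_la if P_la > P_lv else 0.0   # mitral
    Q_rv = (P_rv - P_pa) / R_rv if P_rv > P_pa else 0.0   # pulmonary
    Q_ra = (P_ra - P_rv) / R_ra if P_ra > P_rv else 0.0   # tricuspid
    # Series vascular beds and venous returns
    Q_s = (P_sa - P_sv) / (R_sa + R_svb)
    Q_sv = (P_sv - P_ra) / R_sv
    Q_p = (P_pa - P_pv) / (R_pa + R_pvb)
    Q_pvn = (P_pv - P_la) / R_pv
    dV[0] = Q_la - Q_lv    # lv
    dV[1] = Q_ra - Q_rv    # rv
    dV[2] = Q_pvn - Q_la   # la
    dV[3] = Q_sv - Q_ra    # ra
    dV[4] = Q_lv - Q_s     # sa
    dV[5] = Q_s - Q_sv     # sv
    dV[6] = Q_rv - Q_p     # pa
    dV[7] = Q_p - Q_pvn    # pv
    P[4] = P_sa
    P[5] = P_sa - Q_s * R_sa   # vascular-bed mid-node
    P[6] = P_sv
    P[7] = P_pa
    P[8] = P_pa - Q_p * R_pa
    P[9] = P_pv
    Q[0] = Q_lv
    Q[1] = Q_la
    Q[2] = Q_rv
    Q[3] = Q_ra
    Q[4] = Q_s
    Q[5] = Q_p


# Dormand-Prince 5(4) tableau.
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_DP_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192,
                  -2187 / 6784, 11 / 84, 0.0])
_DP_E = _DP_B - np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                          -92097 / 339200, 187 / 2100, 1 / 40])

OK = 0
FAIL_NONFINITE = 1
FAIL_STEPSIZE = 2


@njit(cache=True)
def _integrate(y0, theta, tau, out_times, rtol, atol, max_steps):
    """Adaptive DP5(4) integration landing exactly on each output time.

    Returns (Y, status) with Y of shape (len(out_times), 8); on failure the
    status is nonzero and Y must be discarded.
    """
    n = 8
    n_out = out_times.shape[0]
    Y = np.empty((n_out, n))
    y = y0.copy()
    dV = np.empty(n)
    P = np.empty(10)
    Q = np.empty(6)
    K = np.empty((7, n))
    ytmp = np.empty(n)
    t = 0.0
    iout = 0
    if out_times[0] <= 0.0:
        Y[0] = y
        iout = 1
    _rhs(t, y, theta, tau, dV, P, Q)
    K[0] = dV
    h = 1e-4
    h_max = tau / 10.0
    steps = 0
    while iout < n_out:
        target = out_times[iout]
        while t < target:
            steps += 1
            if steps > max_steps:
                return Y, FAIL_STEPSIZE
            if h < 1e-12:
                return Y, FAIL_STEPSIZE
            h_try = h
            if h_try > h_max:
                h_try = h_max
            last = False
            if t + h_try >= target:
                h_try = target - t
                last = True
            # stages (k1 already in K[0] via FSAL)
            for s in range(1, 6):
                for j in range(n):
                    acc = y[j]
                    for q in range(s):
                        acc += h_try * _DP_A[s, q] * K[q, j]
                    ytmp[j] = acc
                _rhs(t + _DP_C[s] * h_try, ytmp, theta, tau, dV, P, Q)
                K[s] = dV
            # 7th stage = 5th-order solution (FSAL)
            for j in range(n):
                acc = y[j]
                for q in range(6):
                    acc += h_try * _DP_B[q] * K[q, j]
                ytmp[j] = acc
            _rhs(t + h_try, ytmp, theta, tau, dV, P, Q)
            K[6] = dV
            # error norm
            err = 0.0
            ok = True
            for j in range(n):
                if not math.isfinite(ytmp[j]):
                    ok = False
                    break
                ej = 0.0
                for q in range(7):
                    ej += _DP_E[q] * K[q, j]
                ej *= h_try
                sc = atol + rtol * max(abs(y[j]), abs(ytmp[j]))
                err += (ej / sc) ** 2
            if not ok:
                h *= 0.25
                _rhs(t, y, theta, tau, dV, P, Q)
                K[0] = dV
                continue
            err = math.sqrt(err / n)
            if err <= 1.0:
                t = target if last else t + h_try
                for j in range(n):
                    y[j] = ytmp[j]
                K[0] = K[6]
                fac = 2.0 if err == 0.0 else 0.9 * err ** -0.2
                if fac > 2.0:
                    fac = 2.0
                h = h_try * fac
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h = h_try * fac
                _rhs(t, y, theta, tau, dV, P, Q)
                K[0] = dV
        for j in range(n):
            if not math.isfinite(y[j]):
                return Y, FAIL_NONFINITE
        Y[iout] = y
        iout += 1
    return Y, OK


@njit(cache=True)
def _derived_outputs(times, Y, theta, tau):
    """Pressures (T, 10) and flows (T, 6) along a volume trajectory."""
    T = times.shape[0]
    Ps = np.empty((T, 10))
    Qs = np.empty((T, 6))
    dV = np.empty(8)
    for k in range(T):
        _rhs(times[k], Y[k], theta, tau, dV, Ps[k], Qs[k])
    return Ps, Qs


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``waveform_points`` sets the per-cycle output grid; the solver lands on
    every grid time exactly, so stored samples are solution values, not
    interpolants.  ``extraction_cycle = -1`` reads measurements from the
    final cycle, justified by the periodic steady state reached after the
    default 30 cycles.
    """

    n_cycles: int = 30
    rel_tol: float = 1e-6
    abs_tol: float = 1e-6
    extraction_cycle: int = -1
    waveform_points: int = 150
    max_steps: int = 2_000_000

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.waveform_points < 2:
            raise ValueError("waveform_points must be >= 2")


@dataclass(frozen=True)
class SimulationFailure:
    """Structured failure record; never a partial trajectory."""

    reason: str
    params: ModelParameters | None = None

    @property
    def ok(self) -> bool:
        return False


@dataclass
class Trajectory:
    """Time-resolved volumes with reconstructed pressures and flows.

    The time grid is ``waveform_points`` uniform samples per cycle over the
    whole run, half-open per cycle, plus the closing endpoint.
    """

    time: np.ndarray                 # (T,)
    volumes: np.ndarray              # (T, 8) in VOLUME_LABELS order
    pressures: np.ndarray            # (T, 10) in PRESSURE_LABELS order
    flows: np.ndarray                # (T, 6) in FLOW_LABELS order
    params: ModelParameters
    config: SimulationConfig

    @property
    def ok(self) -> bool:
        return True

    @property
    def n_cycles(self) -> int:
        return self.config.n_cycles

    def signal(self, label: str) -> np.ndarray:
        """Series for a label like ``'V_lv'``, ``'P_sa'`` or ``'Q_s'``."""
        kind, _, comp = label.partition("_")
        try:
            if kind == "V":
                return self.volumes[:, VOLUME_LABELS.index(comp)]
            if kind == "P":
                return self.pressures[:, PRESSURE_LABELS.index(comp)]
            if kind == "Q":
                return self.flows[:, FLOW_LABELS.index(comp)]
        except ValueError:
            pass
        raise KeyError(f"unknown signal label {label!r}")

    def cycle_indices(self, cycle: int) -> slice:
        """Half-open sample range [t0, t0 + tau) of one cycle."""
        wp = self.config.waveform_points
        if cycle < 0:
            cycle += self.n_cycles
        if not 0 <= cycle < self.n_cycles:
            raise IndexError(f"cycle {cycle} outside 0..{self.n_cycles - 1}")
        return slice(cycle * wp, (cycle + 1) * wp)

    def extraction_slice(self) -> slice:
        return self.cycle_indices(self.config.extraction_cycle)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        cols = {"time": self.time}
        for i, k in enumerate(VOLUME_LABELS):
            cols[f"V_{k}"] = self.volumes[:, i]
        for i, k in enumerate(PRESSURE_LABELS):
            cols[f"P_{k}"] = self.pressures[:, i]
        for i, k in enumerate(FLOW_LABELS):
            cols[f"Q_{k}"] = self.flows[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)
        units = {"time": "s", "V": "mL", "P": "mmHg", "Q": "mL/s"}
        Path(str(path) + ".units.json").write_text(json.dumps(units))


def output_grid(n_cycles: int, waveform_points: int, tau: float = TAU
                ) -> np.ndarray:
    """Uniform per-cycle sample times plus the closing endpoint."""
    T = n_cycles * waveform_points
    grid = np.arange(T + 1, dtype=np.float64) * (tau / waveform_points)
    grid[-1] = n_cycles * tau
    return grid


def simulate(params: ModelParameters,
             config: SimulationConfig = SimulationConfig(),
             *, strict_timing: bool = False,
             ) -> Trajectory | SimulationFailure:
    """Integrate the closed loop over ``config.n_cycles`` cycles.

    Returns a :class:`Trajectory` on success or a
    :class:`SimulationFailure` record on a diverged solve.  With
    ``strict_timing=True`` any chamber whose sampled activation timings
    violate tau_es < tau_ep is reported as a failure instead of being
    integrated with the (well-defined, discontinuous) ordered-branch
    activation.
    """
    theta = params.to_array()
    if strict_timing:
        for c in _CHAMBERS:
            ch = params.chamber(c)
            if ch.tau_ep <= ch.tau_es:
                return SimulationFailure(
                    f"invalid timing: tau_ep <= tau_es for chamber {c}",
                    params)
    y0 = np.asarray(params.initial_volumes, dtype=np.float64)
    if config.n_cycles == 0:
        times = np.zeros(1)
        Y = y0[None, :].copy()
        Ps, Qs = _derived_outputs(times, Y, theta, params.tau)
        return Trajectory(times, Y, Ps, Qs, params, config)
    times = output_grid(config.n_cycles, config.waveform_points, params.tau)
    Y, status = _integrate(y0, theta, params.tau, times,
                           config.rel_tol, config.abs_tol, config.max_steps)
    if status == FAIL_NONFINITE:
        return SimulationFailure("non-finite state during integration", params)
    if status == FAIL_STEPSIZE:
        return SimulationFailure("step-size collapse / step budget exhausted",
                                 params)
    Ps, Qs = _derived_outputs(times, Y, theta, params.tau)
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(Ps))):
        return SimulationFailure("non-finite output", params)
    return Trajectory(times, Y, Ps, Qs, params, config)


def periodicity_residual(traj: Trajectory, tau: float | None = None) -> float:
    """Max over volume states of the relative L2 gap between the last two
    cycles; a small value certifies a periodic steady state."""
    if traj.n_cycles < 2:
        raise ValueError("need at least 2 simulated cycles")
    a = traj.volumes[traj.cycle_indices(traj.n_cycles - 2)]
    b = traj.volumes[traj.cycle_indices(traj.n_cycles - 1)]
    num = np.linalg.norm(b - a, axis=0)
    den = np.linalg.norm(a, axis=0)
    den[den == 0.0] = 1.0
    return float(np.max(num / den))
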