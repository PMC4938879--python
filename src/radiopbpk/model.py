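"""Seven-compartment perfusion-limited kinetic model.

Each tissue is a well-stirred compartment in which the emergent venous
blood is in instantaneous equilibrium with the tissue, so the venous-side
concentration leaving tissue ``T`` is ``C_T / P_T`` where ``P_T`` is the
tissue-to-blood partition coefficient.  Kidney and liver additionally
remove tracer irreversibly at a rate ``CL_T * C_T / P_T`` governed by an
intrinsic clearance ``CL_T`` [ml/min].

With concentrations ``C_T`` [Bq/ml], volumes ``V_T`` [ml] and flows
``Q_T`` [ml/min] the balances are::

    non-clearing T (BR, RB):  V_T dC_T/dt = Q_T (C_A - C_T/P_T) - lam V_T C_T
    clearing T (K, L):        V_T dC_T/dt = Q_T (C_A - C_T/P_T)
                                             - CL_T C_T/P_T - lam V_T C_T
    lungs:     V_Lu dC_Lu/dt = Q_C (C_V - C_Lu/P_Lu) - lam V_Lu C_Lu
    arterial:  V_A  dC_A/dt  = Q_C (C_Lu/P_Lu - C_A) - lam V_A C_A
    venous:    V_V  dC_V/dt  = sum_T Q_T C_T/P_T - Q_C C_V - lam V_V C_V

where ``lam`` is an optional physical-decay constant (default 0: the data
are decay-uncorrected count rates, so the fitted clearances absorb decay).
The system is linear with constant coefficients and Metzler structure, so
non-negative initial states stay non-negative and, for ``lam = 0``, total
activity in the body plus cumulative cleared activity is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .physiology import COMPARTMENTS, SYSTEMIC_ORGANS, CompartmentSet

__all__ = [
    "ModelParameters",
    "TimeActivityCurves",
    "initial_state",
    "rhs",
    "system_matrix",
    "simulate",
    "equilibrium_state",
    "SimulationError",
]

_IDX = {c: i for i, c in enumerate(COMPARTMENTS)}
_CLEARING = ("K", "L")


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or returns unphysical output."""


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic parameters of the perfusion-limited model.

    partition
        Tissue-to-blood partition coefficients ``P_T`` (dimensionless) for
        Lu, K, L, BR, RB.
    clearance
        Intrinsic clearances ``CL_T`` [ml/min] for K and L (0 allowed).
    decay_constant
        Physical decay constant lambda [1/min], >= 0.
    detection_scale
        Dimensionless factor applied to *reported* activities, bridging
        detector count rate and absolute activity.
    """

    partition: dict[str, float]
    clearance: dict[str, float] = field(default_factory=lambda: {"K": 0.0, "L": 0.0})
    decay_constant: float = 0.0
    detection_scale: float = 1.0

    def __post_init__(self) -> None:
        missing = {"Lu", "K", "L", "BR", "RB"} - set(self.partition)
        if missing:
            raise ValueError(f"partition missing tissues: {sorted(missing)}")
        for t, p in self.partition.items():
            if not p > 0:
                raise ValueError(f"partition coefficient must be > 0: {t}={p}")
        for t, cl in self.clearance.items():
            if t not in _CLEARING:
                raise ValueError(f"clearance only defined for K and L, got {t}")
            if cl < 0:
                raise ValueError(f"clearance must be >= 0: {t}={cl}")
        if self.decay_constant < 0:
            raise ValueError("decay_constant must be >= 0")
        if not self.detection_scale > 0:
            raise ValueError("detection_scale must be > 0")

    def with_(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def cl(self, tissue: str) -> float:
        return self.clearance.get(tissue, 0.0)


@dataclass(frozen=True)
class TimeActivityCurves:
    """Simulated organ time-activity curves.

    Attributes
    ----------
    time : (n,) array, minutes
    activity : dict code -> (n,) array, organ activity C_T*V_T [Bq]
        (multiplied by ``detection_scale``).
    concentration : dict code -> (n,) array [Bq/ml] (internal, unscaled).
    cleared : (n,) array, cumulative irreversibly cleared activity [Bq].
    a0 : administered activity [Bq].
    """

    time: np.ndarray
    activity: dict[str, np.ndarray]
    concentration: dict[str, np.ndarray]
    cleared: np.ndarray
    a0: float

    def total_body(self) -> np.ndarray:
        """Total activity residing in the body at each time [Bq, unscaled]."""
        return np.sum(
            [self.concentration[c] * self._volumes[c] for c in COMPARTMENTS],
            axis=0,
        )

    # volumes are stashed at construction so mass balance can be checked
    # without re-supplying the CompartmentSet
    _volumes: dict[str, float] = field(default_factory=dict)


def initial_state(a0: float, compartments: CompartmentSet) -> np.ndarray:
    """State vector right after an intravenous bolus of ``a0`` [Bq].

    The whole dose starts in the venous compartment: C_V = a0 / V_V, all
    other concentrations zero.
    """
    if a0 < 0:
        raise ValueError(f"administered activity must be >= 0, got {a0}")
    c = np.zeros(len(COMPARTMENTS))
    c[_IDX["V"]] = a0 / compartments.volumes["V"]
    return c


def system_matrix(
    params: ModelParameters, compartments: CompartmentSet
) -> np.ndarray:
    """Dense matrix ``A`` with ``dC/dt = A @ C`` in compartment order."""
    n = len(COMPARTMENTS)
    a = np.zeros((n, n))
    v = compartments.volumes
    q = compartments.flows
    p = params.partition
    lam = params.decay_constant

    i_lu, i_a, i_v = _IDX["Lu"], _IDX["A"], _IDX["V"]
    q_c = compartments.q_c
    # lungs: fed by venous return, drains to arterial side
    a[i_lu, i_v] += q_c / v["Lu"]
    a[i_lu, i_lu] -= q_c / (p["Lu"] * v["Lu"])
    # arterial: fed by lung outflow
    a[i_a, i_lu] += q_c / (p["Lu"] * v["A"])
    a[i_a, i_a] -= q_c / v["A"]
    # systemic organs
    for t in SYSTEMIC_ORGANS:
        i_t = _IDX[t]
        a[i_t, i_a] += q[t] / v[t]
        a[i_t, i_t] -= q[t] / (p[t] * v[t])
        if t in _CLEARING:
            a[i_t, i_t] -= params.cl(t) / (p[t] * v[t])
        # venous collects the organ's venous-equilibrium outflow
        a[i_v, i_t] += q[t] / (p[t] * v["V"])
    a[i_v, i_v] -= q_c / v["V"]
    if lam:
        a -= lam * np.eye(n)
    return a


def rhs(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    compartments: CompartmentSet,
) -> np.ndarray:
    """Time derivative of the concentration state (pure function)."""
    return system_matrix(params, compartments) @ np.asarray(state, dtype=float)


def simulate(
    params: ModelParameters,
    compartments: CompartmentSet,
    a0: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    negative_tol: float = 1e-6,
) -> TimeActivityCurves:
    """Integrate the model from an IV bolus and return time-activity curves.

    Parameters
    ----------
    t_grid : increasing array of output times [min], starting at 0.
    rtol, atol, method : passed to the ODE solver.  The system is linear
        and moderately stiff (fast lung/blood exchange against multi-day
        washout), hence the stiffness-switching default.
    negative_tol : concentrations below ``-negative_tol`` times the peak
        concentration raise an error; smaller negative excursions are
        clamped to 0.

    Returns cumulative cleared activity alongside the curves; for zero
    decay, ``body + cleared == a0`` at every output time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")

    a = system_matrix(params, compartments)
    cl_row = np.zeros(len(COMPARTMENTS))
    for t in _CLEARING:
        cl_row[_IDX[t]] = params.cl(t) / params.partition[t]

    n = len(COMPARTMENTS)
    a_aug = np.zeros((n + 1, n + 1))
    a_aug[:n, :n] = a
    a_aug[n, :n] = cl_row

    def aug_rhs(_t, y):
        return a_aug @ y

    y0 = np.concatenate([initial_state(a0, compartments), [0.0]])
    sol = solve_ivp(
        aug_rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=lambda _t, _y: a_aug,  # linear system: constant Jacobian
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")

    conc = sol.y[:-1]
    scale = max(float(np.max(np.abs(conc))), atol)
    if np.min(conc) < -negative_tol * scale:
        raise SimulationError(
            f"negative concentrations beyond tolerance: min={np.min(conc):g}"
        )
    conc = np.clip(conc, 0.0, None)
    cleared = np.clip(sol.y[-1], 0.0, None)

    volumes = dict(compartments.volumes)
    concentration = {c: conc[_IDX[c]].copy() for c in COMPARTMENTS}
    activity = {
        c: params.detection_scale * concentration[c] * volumes[c]
        for c in COMPARTMENTS
    }
    return TimeActivityCurves(
        time=t_grid.copy(),
        activity=activity,
        concentration=concentration,
        cleared=cleared,
        a0=a0,
        _volumes=volumes,
    )


def equilibrium_state(
    params: ModelParameters, compartments: CompartmentSet, a0: float
) -> np.ndarray:
    """Conserved long-time equilibrium for the clearance-free, decay-free model.

    With no elimination the system relaxes to a state where every blood-side
    concentration equals a common level ``c`` and each tissue sits at
    ``P_T * c``; conservation fixes ``c = a0 / (V_A + V_V + sum P_T V_T)``.
    """
    if any(params.cl(t) != 0.0 for t in _CLEARING) or params.decay_constant != 0.0:
        raise ValueError("equilibrium_state requires all CL = 0 and decay = 0")
    v = compartments.volumes
    denom = v["A"] + v["V"] + sum(
        params.partition[t] * v[t] for t in ("Lu", "K", "L", "BR", "RB")
    )
    c = a0 / denom
    state = np.empty(len(COMPARTMENTS))
    for code in COMPARTMENTS:
        if code in ("A", "V"):
            state[_IDX[code]] = c
        else:
            state[_IDX[code]] = params.partition[code] * c
    return state
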