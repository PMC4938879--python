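"""Per-patient model calibration.

Calibration finds the partition coefficients and intrinsic clearances for
which the simulated organ activities best match a patient's scintigraphy
time-activity data, in the least-squares sense.  The minimizer is a
trust-region method: at each iterate the objective is replaced by a local
quadratic model built from a finite-difference gradient and a BFGS-updated
Hessian approximation, and the model is minimized inside a ball of radius
``D`` subject to the physical constraint that all parameters stay positive.
Steps are accepted or rejected by comparing achieved and predicted
reduction, and ``D`` adapts accordingly.

The pieces are exposed individually (:func:`objective`,
:func:`gradient_fd`, :func:`bfgs_update`, :func:`solve_subproblem`) so
each can be exercised against independent oracles; :func:`fit` wires them
into the full loop and :func:`fit_multistart` adds a deterministic
log-spaced multistart for poorly scaled problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import ORGANS, WBSDataset
from .model import ModelParameters, SimulationError, simulate
from .physiology import CompartmentSet

__all__ = [
    "PARAMETER_NAMES",
    "DEFAULT_FREE_PARAMETERS",
    "ObjectiveSpec",
    "TrustRegionConfig",
    "FitResult",
    "params_to_vector",
    "vector_to_params",
    "default_initial_parameters",
    "objective",
    "make_objective",
    "gradient_fd",
    "bfgs_update",
    "solve_subproblem",
    "minimize_trust_region",
    "gauss_newton_hessian",
    "fit",
    "fit_multistart",
]

#: Every scalar parameter the calibration can free.
PARAMETER_NAMES: tuple[str, ...] = (
    "P_Lu",
    "P_K",
    "P_L",
    "P_BR",
    "P_RB",
    "CL_K",
    "CL_L",
    "detection_scale",
)

#: Default free set: the organ partitions and clearances that the observed
#: organs (liver, kidney, brain) can inform.  P_Lu and detection_scale stay
#: fixed at 1 — freeing all eight on three observed organs is
#: under-determined.
DEFAULT_FREE_PARAMETERS: tuple[str, ...] = (
    "P_K",
    "P_L",
    "P_BR",
    "P_RB",
    "CL_K",
    "CL_L",
)

_WEIGHTINGS = ("uniform", "relative", "poisson")


def default_initial_parameters() -> ModelParameters:
    """Neutral starting point: all partitions 1, both clearances 1 ml/min."""
    return ModelParameters(
        partition={"Lu": 1.0, "K": 1.0, "L": 1.0, "BR": 1.0, "RB": 1.0},
        clearance={"K": 1.0, "L": 1.0},
    )


def params_to_vector(params: ModelParameters, free: tuple[str, ...]) -> np.ndarray:
    """Extract the free parameters into a vector, in ``free`` order."""
    out = np.empty(len(free))
    for i, name in enumerate(free):
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter name {name!r}")
        if name.startswith("P_"):
            out[i] = params.partition[name[2:]]
        elif name.startswith("CL_"):
            out[i] = params.clearance[name[3:]]
        else:
            out[i] = params.detection_scale
    return out


def vector_to_params(
    vec: np.ndarray, free: tuple[str, ...], base: ModelParameters
) -> ModelParameters:
    """Insert a free-parameter vector into ``base`` (fixed values kept)."""
    partition = dict(base.partition)
    clearance = dict(base.clearance)
    detection_scale = base.detection_scale
    for name, value in zip(free, vec, strict=True):
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter name {name!r}")
        if name.startswith("P_"):
            partition[name[2:]] = float(value)
        elif name.startswith("CL_"):
            clearance[name[3:]] = float(value)
        else:
            detection_scale = float(value)
    return replace(
        base,
        partition=partition,
        clearance=clearance,
        detection_scale=detection_scale,
    )


@dataclass(frozen=True)
class ObjectiveSpec:
    """What is being fitted to what.

    weighting
        ``uniform`` — unweighted squared residuals (zero-valued
        observations kept as genuine zeros); ``relative`` — weights
        ``1/data**2`` (zero-valued observations dropped, their weight is
        undefined); ``poisson`` — weights ``1/data`` (zeros dropped).
    Zero-time rows are never residuals: the model is exactly zero there.
    """

    dataset: WBSDataset
    organs_fitted: tuple[str, ...] = ("liver", "kidney", "brain")
    weighting: str = "uniform"
    parameters_free: tuple[str, ...] = DEFAULT_FREE_PARAMETERS
    base_params: ModelParameters = field(default_factory=default_initial_parameters)
    #: ODE tolerances for objective evaluations.  Deep descents into a
    #: flat residual valley need the integration error well below the
    #: objective changes being compared, hence user control.
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.organs_fitted:
            raise ValueError("organs_fitted must be non-empty")
        unknown = set(self.organs_fitted) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organs: {sorted(unknown)}")
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(
                f"weighting must be one of {_WEIGHTINGS}, got {self.weighting!r}"
            )
        for organ in self.organs_fitted:
            if not any(
                o == organ and t > 0 for t, o, _ in self.dataset.observations
            ):
                raise ValueError(f"no post-injection observations for {organ!r}")

    def residual_observations(self) -> tuple[tuple[float, str, float], ...]:
        """Observations entering the objective, weighting rules applied."""
        obs = [
            (t, o, v)
            for t, o, v in self.dataset.nonzero_time_observations()
            if o in self.organs_fitted
        ]
        if self.weighting in ("relative", "poisson"):
            obs = [row for row in obs if row[2] > 0]
        return tuple(obs)

    def weights(self) -> np.ndarray:
        values = np.array([v for _, _, v in self.residual_observations()])
        if self.weighting == "uniform":
            return np.ones_like(values)
        if self.weighting == "relative":
            return 1.0 / values**2
        return 1.0 / values


def _model_values(
    params: ModelParameters,
    spec: ObjectiveSpec,
    compartments: CompartmentSet,
) -> np.ndarray:
    """Simulated organ activities at each residual observation [Bq]."""
    obs = spec.residual_observations()
    times_min = np.unique([t * 60.0 for t, _, _ in obs])
    t_grid = np.concatenate([[0.0], times_min]) if times_min[0] > 0 else times_min
    curves = simulate(
        params,
        compartments,
        spec.dataset.a0_bq,
        t_grid,
        rtol=spec.solver_rtol,
        atol=spec.solver_atol,
    )
    index = {t: i for i, t in enumerate(t_grid)}
    out = np.empty(len(obs))
    for i, (t_h, organ, _) in enumerate(obs):
        out[i] = curves.activity[ORGANS[organ]][index[t_h * 60.0]]
    return out


def objective(
    params: ModelParameters,
    spec: ObjectiveSpec,
    compartments: CompartmentSet,
) -> float:
    """Weighted sum of squared model-data differences, F >= 0."""
    try:
        model = _model_values(params, spec, compartments)
    except SimulationError as exc:
        raise SimulationError(f"{exc} (parameters: {params})") from exc
    data = np.array([v for _, _, v in spec.residual_observations()])
    return float(np.sum(spec.weights() * (model - data) ** 2))


def gauss_newton_hessian(
    spec: ObjectiveSpec,
    params: ModelParameters,
    compartments: CompartmentSet,
    rel_step: float = 1e-5,
    floor: float = 1e-8,
) -> np.ndarray:
    """Gauss-Newton Hessian ``2 J^T J`` of the objective at ``params``.

    ``J`` is the central finite-difference Jacobian of the weighted
    residuals with respect to the free parameters.  For a least-squares
    objective this captures the full curvature structure up to the
    second-order residual term, which makes it a far better starting
    Hessian than the identity when the residual surface has strongly
    anisotropic (sloppy) directions.
    """
    free = spec.parameters_free
    data = np.array([v for _, _, v in spec.residual_observations()])
    sqw = np.sqrt(spec.weights())

    def residuals(vec: np.ndarray) -> np.ndarray:
        p = vector_to_params(vec, free, spec.base_params)
        return sqw * (_model_values(p, spec, compartments) - data)

    p0 = params_to_vector(params, free)
    jac = np.empty((data.size, p0.size))
    for j in range(p0.size):
        h = rel_step * max(abs(p0[j]), floor)
        up, dn = p0.copy(), p0.copy()
        up[j] += h
        dn[j] = max(dn[j] - h, 0.0) if dn[j] - h < 0 else dn[j] - h
        jac[:, j] = (residuals(up) - residuals(dn)) / (up[j] - dn[j])
    return 2.0 * jac.T @ jac


def make_objective(spec: ObjectiveSpec, compartments: CompartmentSet):
    """Objective as a function of the free-parameter vector."""

    def fn(vec: np.ndarray) -> float:
        params = vector_to_params(vec, spec.parameters_free, spec.base_params)
        return objective(params, spec, compartments)

    return fn


@dataclass(frozen=True)
class TrustRegionConfig:
    """Tuning knobs for the trust-region loop (textbook defaults)."""

    initial_radius: float = 1.0
    max_radius: float = 1e3
    min_radius: float = 1e-12
    eta_accept: float = 0.1
    eta_expand: float = 0.75
    shrink: float = 0.25
    expand: float = 2.0
    fd_rel_step: float = 1e-5
    fd_floor: float = 1e-8
    gradient_tol: float = 1e-6
    step_tol: float = 1e-10
    objective_tol: float = 1e-12
    max_iterations: int = 200
    lower_bound: float = 1e-12
    curvature_floor: float = 1e-12
    update_hessian: bool = True
    initial_hessian: np.ndarray | None = None
    #: start from the Gauss-Newton Hessian 2 J^T J instead of the identity
    #: (ignored when an explicit initial_hessian is given)
    gauss_newton_start: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.eta_accept < self.eta_expand < 1:
            raise ValueError("need 0 < eta_accept < eta_expand < 1")
        if not 0 < self.shrink < 1 < self.expand:
            raise ValueError("need 0 < shrink < 1 < expand")
        for name in ("gradient_tol", "step_tol", "objective_tol", "lower_bound"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FitResult:
    """Outcome of one calibration run."""

    params: ModelParameters
    objective: float
    convergence: str
    iterations: list[dict]
    parameters_free: tuple[str, ...]
    observations: tuple[tuple[float, str, float], ...]
    model_values: np.ndarray
    residuals: np.ndarray
    n_objective_evaluations: int = 0
    #: final BFGS Hessian approximation (free-parameter space); lets a
    #: follow-up fit resume without re-learning the curvature
    hessian: np.ndarray | None = None

    def accepted_objectives(self) -> np.ndarray:
        return np.array(
            [rec["objective"] for rec in self.iterations if rec["accepted"]]
        )

    def to_dict(self) -> dict:
        return {
            "params": {
                "partition": dict(self.params.partition),
                "clearance": dict(self.params.clearance),
                "decay_constant": self.params.decay_constant,
                "detection_scale": self.params.detection_scale,
            },
            "objective": self.objective,
            "convergence": self.convergence,
            "iterations": self.iterations,
            "parameters_free": list(self.parameters_free),
            "observations": [list(row) for row in self.observations],
            "model_values": self.model_values.tolist(),
            "residuals": self.residuals.tolist(),
            "n_objective_evaluations": self.n_objective_evaluations,
            "hessian": None if self.hessian is None else self.hessian.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FitResult":
        params = ModelParameters(
            partition=doc["params"]["partition"],
            clearance=doc["params"]["clearance"],
            decay_constant=doc["params"]["decay_constant"],
            detection_scale=doc["params"]["detection_scale"],
        )
        return cls(
            params=params,
            objective=doc["objective"],
            convergence=doc["convergence"],
            iterations=list(doc["iterations"]),
            parameters_free=tuple(doc["parameters_free"]),
            observations=tuple(
                (row[0], row[1], row[2]) for row in doc["observations"]
            ),
            model_values=np.array(doc["model_values"]),
            residuals=np.array(doc["residuals"]),
            n_objective_evaluations=doc["n_objective_evaluations"],
            hessian=None if doc.get("hessian") is None else np.array(doc["hessian"]),
        )


def gradient_fd(
    objective_fn,
    p: np.ndarray,
    rel_step: float = 1e-5,
    floor: float = 1e-8,
    lower_bound: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference gradient of ``objective_fn`` at ``p``.

    Central differences with per-component step ``rel_step * max(|p_j|,
    floor)``; where the downward point would cross ``lower_bound`` a
    one-sided forward difference is used instead.  Returns ``(gradient,
    one_sided_mask)`` so callers can log the fallback.
    """
    p = np.asarray(p, dtype=float)
    g = np.empty_like(p)
    one_sided = np.zeros(p.shape, dtype=bool)
    f0 = None
    for j in range(p.size):
        h = rel_step * max(abs(p[j]), floor)
        if p[j] - h < lower_bound:
            one_sided[j] = True
            if f0 is None:
                f0 = objective_fn(p)
            up = p.copy()
            up[j] += h
            g[j] = (objective_fn(up) - f0) / h
        else:
            up, dn = p.copy(), p.copy()
            up[j] += h
            dn[j] -= h
            g[j] = (objective_fn(up) - objective_fn(dn)) / (2.0 * h)
    return g, one_sided


def bfgs_update(
    h: np.ndarray,
    s: np.ndarray,
    y: np.ndarray,
    curvature_floor: float = 1e-12,
    symmetry_tol: float = 1e-8,
) -> np.ndarray:
    """Rank-two secant update of the Hessian approximation.

    ``H' = H - (H s s^T H)/(s^T H s) + (y y^T)/(y^T s)``; the update is
    skipped (H returned unchanged) when the curvature ``y^T s`` is at or
    below ``curvature_floor``, preserving positive definiteness.  When
    applied, ``H' s = y`` holds algebraically (the secant condition).
    """
    h = np.asarray(h, dtype=float)
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    scale = max(float(np.max(np.abs(h))), 1.0)
    if np.max(np.abs(h - h.T)) > symmetry_tol * scale:
        raise ValueError("Hessian approximation must be symmetric")
    ys = float(y @ s)
    if ys <= curvature_floor:
        return h.copy()
    hs = h @ s
    shs = float(s @ hs)
    if abs(shs) < np.finfo(float).tiny:
        return h.copy()
    return h - np.outer(hs, hs) / shs + np.outer(y, y) / ys


def _quad_model(g: np.ndarray, h: np.ndarray, step: np.ndarray) -> float:
    """Change in the local quadratic model for a candidate step."""
    return float(g @ step + 0.5 * step @ h @ step)


def solve_subproblem(
    g: np.ndarray,
    h: np.ndarray,
    radius: float,
    p: np.ndarray,
    lower_bound: float,
    polish_iterations: int = 60,
) -> np.ndarray:
    """Approximately minimize the quadratic model in the feasible region.

    The feasible region is the intersection of the trust ball ``|step| <=
    radius`` with the positivity box ``p + step >= lower_bound``.  A dogleg
    step is computed on the ball, projected into the box, and compared with
    the box-constrained Cauchy point; the best candidate is then polished
    by projected gradient descent on the model.  The returned step is
    always feasible and never worse (in model value) than the constrained
    Cauchy point.
    """
    if radius <= 0:
        raise ValueError("trust radius must be > 0")
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    p = np.asarray(p, dtype=float)
    lo = np.minimum(lower_bound - p, 0.0)  # step lower bounds, <= 0

    def project(step: np.ndarray) -> np.ndarray:
        # clip into the box (cannot increase the norm, since lo <= 0),
        # then scale into the ball (keeps the box, since 0 is feasible)
        step = np.maximum(step, lo)
        nrm = np.linalg.norm(step)
        if nrm > radius:
            step = step * (radius / nrm)
        return step

    def ball_dogleg(gv: np.ndarray, hv: np.ndarray, rad: float) -> np.ndarray:
        """Dogleg minimizer of the quadratic model on the ball alone."""
        gn = np.linalg.norm(gv)
        if gn == 0:
            return np.zeros_like(gv)
        try:
            newton = -np.linalg.solve(hv, gv)
            if not np.all(np.isfinite(newton)) or float(gv @ hv @ gv) <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            dhd = float(gv @ hv @ gv)
            alpha = gn**2 / dhd if dhd > 0 else rad / gn
            return -min(alpha, rad / gn) * gv
        if np.linalg.norm(newton) <= rad:
            return newton
        dhd = float(gv @ hv @ gv)
        pu = -(gn**2 / dhd) * gv
        if np.linalg.norm(pu) >= rad:
            return -(rad / gn) * gv
        diff = newton - pu
        aa = float(diff @ diff)
        bb = 2.0 * float(pu @ diff)
        cc = float(pu @ pu) - rad**2
        tau = (-bb + math.sqrt(max(bb * bb - 4 * aa * cc, 0.0))) / (2 * aa)
        return pu + min(max(tau, 0.0), 1.0) * diff

    def active_set_dogleg(
        gv: np.ndarray, hv: np.ndarray, rad: float, lov: np.ndarray, depth: int
    ) -> np.ndarray:
        """Dogleg with box faces pinned recursively when they activate."""
        s = ball_dogleg(gv, hv, rad)
        active = s < lov
        if not active.any() or depth == 0 or active.all():
            return np.maximum(s, lov)
        free = ~active
        s_a = lov[active]
        rem2 = rad**2 - float(s_a @ s_a)
        out = np.array(lov, dtype=float)
        out[free] = 0.0
        if rem2 > 0:
            g_red = gv[free] + hv[np.ix_(free, active)] @ s_a
            h_red = hv[np.ix_(free, free)]
            out[free] = active_set_dogleg(
                g_red, h_red, math.sqrt(rem2), lov[free], depth - 1
            )
        out[active] = s_a
        return out

    candidates: list[np.ndarray] = [np.zeros_like(p)]
    candidates.append(project(active_set_dogleg(g, h, radius, lo, p.size)))

    # constrained Cauchy point: steepest descent clipped to the region
    gnorm = np.linalg.norm(g)
    if gnorm > 0:
        d = -g
        alpha_max = radius / gnorm
        neg = d < 0
        if np.any(neg):
            alpha_max = min(alpha_max, float(np.min(lo[neg] / d[neg])))
        dhd = float(d @ h @ d)
        alpha = gnorm**2 / dhd if dhd > 0 else alpha_max
        alpha = min(max(alpha, 0.0), alpha_max)
        candidates.append(alpha * d)
        cauchy = candidates[-1]
    else:
        cauchy = candidates[0]

    # plain dogleg on the ball, projected into the box
    candidates.append(project(ball_dogleg(g, h, radius)))

    best = min(candidates, key=lambda s: _quad_model(g, h, s))

    # projected-gradient polish of the model
    hnorm = float(np.linalg.norm(h, 2)) if h.size else 0.0
    eta = 1.0 / hnorm if hnorm > 0 else 1.0
    s = best.copy()
    best_m = _quad_model(g, h, best)
    for _ in range(polish_iterations):
        s = project(s - eta * (g + h @ s))
        m = _quad_model(g, h, s)
        if m < best_m:
            best, best_m = s.copy(), m

    # never worse than the constrained Cauchy point
    if best_m > _quad_model(g, h, cauchy):
        best = cauchy
    return best


def minimize_trust_region(
    fn,
    p0: np.ndarray,
    trcfg: TrustRegionConfig,
    initial_hessian: np.ndarray | None = None,
):
    """Positivity-constrained trust-region/BFGS minimization of ``fn``.

    Generic core shared by :func:`fit`: iterates subproblem solves with a
    finite-difference gradient and a BFGS-updated quadratic model until a
    gradient, step or objective-change tolerance is met, the radius
    collapses (``stalled``), or the iteration budget runs out.  Returns
    ``(p, f, log, convergence, hessian, n_evals)``; the accepted-iterate
    objective sequence is non-increasing by construction.
    """
    n_evals = 0

    def counted(vec):
        nonlocal n_evals
        n_evals += 1
        return fn(vec)

    p = np.array(p0, dtype=float)
    if np.any(p < trcfg.lower_bound):
        raise ValueError("initial parameters must satisfy the positivity bound")
    n = p.size
    f = counted(p)
    g, one_sided = gradient_fd(
        counted, p, trcfg.fd_rel_step, trcfg.fd_floor, trcfg.lower_bound
    )
    if initial_hessian is not None:
        h = np.array(initial_hessian, dtype=float)
        h_is_default = False
    else:
        h = np.eye(n)
        h_is_default = True
    radius = trcfg.initial_radius

    log: list[dict] = []
    convergence = "max_iterations"
    for _ in range(trcfg.max_iterations):
        if np.linalg.norm(g) <= trcfg.gradient_tol:
            convergence = "gradient_tolerance"
            break
        step = solve_subproblem(g, h, radius, p, trcfg.lower_bound)
        step_norm = float(np.linalg.norm(step))
        if step_norm <= trcfg.step_tol and not np.array_equal(h, np.eye(n)):
            # a collapsed step with a large gradient usually means the BFGS
            # approximation went ill-conditioned; restart it once from scratch
            h = np.eye(n)
            step = solve_subproblem(g, h, radius, p, trcfg.lower_bound)
            step_norm = float(np.linalg.norm(step))
        predicted = -_quad_model(g, h, step)
        if step_norm <= trcfg.step_tol:
            convergence = "step_tolerance"
            break
        f_new = counted(p + step)
        rho = (f - f_new) / predicted if predicted > 0 else -np.inf
        accepted = rho > trcfg.eta_accept and f_new < f
        log.append(
            {
                "objective": f_new if accepted else f,
                "objective_trial": f_new,
                "gradient_norm": float(np.linalg.norm(g)),
                "radius": radius,
                "step_norm": step_norm,
                "rho": float(rho),
                "accepted": bool(accepted),
                "one_sided_gradient": bool(one_sided.any()),
            }
        )
        if accepted:
            g_new, one_sided = gradient_fd(
                counted, p + step, trcfg.fd_rel_step, trcfg.fd_floor, trcfg.lower_bound
            )
            if trcfg.update_hessian:
                y = g_new - g
                ys = float(y @ step)
                if h_is_default and ys > trcfg.curvature_floor:
                    # rescale the unit initial Hessian to the observed
                    # curvature before the first secant update
                    h = (float(y @ y) / ys) * np.eye(n)
                    h_is_default = False
                h = bfgs_update(h, step, y, trcfg.curvature_floor)
            df = f - f_new
            p, f, g = p + step, f_new, g_new
            if df <= trcfg.objective_tol * (1.0 + abs(f)):
                convergence = "objective_tolerance"
                # radius bookkeeping below still applies
        if rho > trcfg.eta_expand and step_norm >= 0.99 * radius:
            radius = min(trcfg.expand * radius, trcfg.max_radius)
        elif rho <= trcfg.eta_accept:
            radius *= trcfg.shrink
            if radius < trcfg.min_radius:
                convergence = "stalled"
                break
        if convergence == "objective_tolerance":
            break

    return p, f, log, convergence, h, n_evals


def fit(
    spec: ObjectiveSpec,
    init_params: ModelParameters | None = None,
    trcfg: TrustRegionConfig | None = None,
    compartments: CompartmentSet | None = None,
) -> FitResult:
    """Calibrate the free parameters against one dataset.

    Thin wrapper building the weighted least-squares objective for the
    dataset and handing it to :func:`minimize_trust_region`; the fitted
    curves and residuals at the observation times are attached to the
    result.
    """
    if compartments is None:
        from .physiology import build_compartments, default_physiology

        compartments = build_compartments(default_physiology())
    trcfg = trcfg or TrustRegionConfig()
    init_params = init_params or spec.base_params
    free = spec.parameters_free

    spec_init = replace(spec, base_params=init_params)
    fn = make_objective(spec_init, compartments)
    if trcfg.initial_hessian is not None:
        h0 = np.array(trcfg.initial_hessian, dtype=float)
    elif trcfg.gauss_newton_start:
        h0 = gauss_newton_hessian(
            spec_init, init_params, compartments, trcfg.fd_rel_step, trcfg.fd_floor
        )
    else:
        h0 = None

    p0 = params_to_vector(init_params, free)
    p, f, log, convergence, h, n_evals = minimize_trust_region(fn, p0, trcfg, h0)

    final_params = vector_to_params(p, free, init_params)
    obs = spec.residual_observations()
    model = _model_values(final_params, spec, compartments)
    data = np.array([v for _, _, v in obs])
    return FitResult(
        params=final_params,
        objective=f,
        convergence=convergence,
        iterations=log,
        parameters_free=free,
        observations=obs,
        model_values=model,
        residuals=model - data,
        n_objective_evaluations=n_evals,
        hessian=h,
    )


def fit_multistart(
    spec: ObjectiveSpec,
    trcfg: TrustRegionConfig | None = None,
    compartments: CompartmentSet | None = None,
    n_starts: int = 5,
    low: float = 1e-3,
    high: float = 1e3,
    seed: int = 0,
) -> FitResult:
    """Best fit over a deterministic log-uniform multistart.

    Start ``0`` is always the neutral all-ones point; the remaining starts
    draw each free parameter log-uniformly from ``[low, high]`` with a
    seeded generator, so the whole procedure is reproducible.
    """
    trcfg = trcfg or TrustRegionConfig()
    rng = np.random.default_rng(seed)
    free = spec.parameters_free
    starts = [params_to_vector(spec.base_params, free)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.exp(rng.uniform(math.log(low), math.log(high), size=len(free)))
        )
    best: FitResult | None = None
    for start in starts:
        init = vector_to_params(np.asarray(start), free, spec.base_params)
        result = fit(spec, init, trcfg, compartments)
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best
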